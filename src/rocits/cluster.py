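"""Genus-level clustering: 16S extraction, greedy identity clustering,
small-cluster exclusion, taxonomy assignment, and the reference pre-filter.

The 16S gene is defined as the span between the universal 27F and 1492R
primer sites, inclusive, found by IUPAC-aware exact-position matching with
a bounded mismatch count (no indels).  Sequences whose primer sites are
mutated are rescued by similarity against a seed set of 16S genes taken
from high-confidence consensus sequences.  Clustering is cd-hit style:
length-sorted greedy assignment to the first representative within the
identity threshold, with a k-mer prefilter for speed; identity excludes
end gaps (the overhang of the longer sequence is not charged).  The
reference pre-filter instead uses full-length global identity.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from math import ceil

from ._align import best_infix_hit, global_identity, infix_identity, kmer_set
from .config import ClusterConfig
from .consensus import RocItsSequence
from .seqio import SeqRecord

# IUPAC degenerate primer patterns (sense strand).  The reverse primers are
# written as their sense-strand (reverse-complemented) sites.
PRIMER_27F = "AGAGTTTGATCMTGGCTCAG"
PRIMER_1492R_SITE = "AAGTCGTAACAAGGTAMCCGTA"
PRIMER_515F = "GTGYCAGCMGCCGCGGTAA"
PRIMER_806R_SITE = "ATTAGAWACCCBNGTAGTCC"

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def _motif_sets(motif: str) -> list[frozenset]:
    return [frozenset(_IUPAC[c]) for c in motif]


def find_motif(seq: str, motif: str, max_mismatch: int = 0) -> tuple[int, int] | None:
    """Best gap-free placement of an IUPAC motif; (start, end) or None.

    Scans every offset, counts mismatches against the degenerate pattern,
    and returns the lowest-mismatch hit within the budget (ties: leftmost).
    """
    sets = _motif_sets(motif)
    m = len(sets)
    best = None
    for i in range(len(seq) - m + 1):
        mm = 0
        for j in range(m):
            if seq[i + j] not in sets[j]:
                mm += 1
                if mm > max_mismatch:
                    break
        else:
            if best is None or mm < best[0]:
                best = (mm, i)
                if mm == 0:
                    break
    if best is None:
        return None
    return best[1], best[1] + m


@dataclass
class Cluster:
    cluster_id: str
    level: str                     # "genus" | "rrn"
    identity_threshold: float
    member_ids: list[str]
    representative_id: str
    consensus: str | None = None
    taxonomy: str | None = None
    taxonomy_fraction: float | None = None

    def __post_init__(self) -> None:
        if not self.member_ids:
            raise ValueError("cluster must have at least one member")
        if self.representative_id not in self.member_ids:
            raise ValueError("representative must be a member")

    @property
    def size(self) -> int:
        return len(self.member_ids)


def extract_16s(
    seq: RocItsSequence | str,
    fwd_primer: str = PRIMER_27F,
    rev_primer: str = PRIMER_1492R_SITE,
    max_mismatch: int = 0,
) -> str | None:
    """The 16S gene: bases between the 27F and 1492R sites, inclusive."""
    s = seq.seq if isinstance(seq, RocItsSequence) else seq
    fwd = find_motif(s, fwd_primer, max_mismatch)
    if fwd is None:
        return None
    rev = find_motif(s[fwd[1]:], rev_primer, max_mismatch)
    if rev is None:
        return None
    return s[fwd[0] : fwd[1] + rev[1]]


def similarity_rescue_16s(
    unmatched: list[RocItsSequence],
    seed_16s: list[str],
    min_identity: float = 0.90,
) -> dict[str, str]:
    """Extract 16S spans by similarity to a seed 16S set.

    Each seed is infix-aligned into the query; the best seed's footprint on
    the query is the extracted 16S.  Queries below ``min_identity`` to every
    seed stay unextracted.  Returns {sequence id: 16S string}.
    """
    if not seed_16s:
        raise ValueError("empty 16S seed set")
    out: dict[str, str] = {}
    for rs in unmatched:
        best = None
        for seed in seed_16s:
            k = int((1.0 - min_identity) * len(seed)) + 1
            hit = best_infix_hit(seed, rs.seq, k=k)
            if hit is None:
                continue
            start, end, ed = hit
            if best is None or ed < best[2]:
                best = (start, end, ed, seed)
        if best is None:
            continue
        start, end, ed, seed = best
        if 1.0 - ed / len(seed) >= min_identity:
            out[rs.id] = rs.seq[start:end]
    return out


def greedy_cluster(
    seqs: list[tuple[str, str]],
    identity: float,
    cfg: ClusterConfig | None = None,
    level: str = "genus",
) -> list[Cluster]:
    """cd-hit-style greedy clustering.

    Sequences are sorted by length descending (ties by id); each joins the
    first existing cluster whose representative it matches at >= the
    identity threshold (k-mer prefilter, then infix alignment of the
    shorter into the longer; identity = matches / alignment columns with
    end gaps excluded), otherwise it founds a new cluster.
    """
    if not seqs:
        raise ValueError("no sequences to cluster")
    cfg = cfg or ClusterConfig()
    order = sorted(seqs, key=lambda t: (-len(t[1]), t[0]))
    reps: list[tuple[str, str, set[str]]] = []  # (id, seq, kmers)
    members: dict[str, list[str]] = {}
    k = cfg.kmer_size
    for sid, seq in order:
        km = kmer_set(seq, k)
        min_shared = int(cfg.prefilter_min_shared_fraction * len(km) * identity)
        placed = False
        for rep_id, rep_seq, rep_km in reps:
            if len(km & rep_km) < min_shared:
                continue
            if infix_identity(seq, rep_seq) >= identity:
                members[rep_id].append(sid)
                placed = True
                break
        if not placed:
            reps.append((sid, seq, km))
            members[sid] = [sid]
    clusters = []
    for i, (rep_id, _seq, _km) in enumerate(reps):
        clusters.append(
            Cluster(
                cluster_id=f"{level}_{i:03d}",
                level=level,
                identity_threshold=identity,
                member_ids=members[rep_id],
                representative_id=rep_id,
            )
        )
    clusters.sort(key=lambda c: (-c.size, c.cluster_id))
    return clusters


def filter_small_clusters(
    clusters: list[Cluster],
    min_members: int | None = None,
    input_fraction: float | None = None,
    rescue_min_members: int | None = None,
) -> tuple[list[Cluster], list[str]]:
    """Keep clusters above the size floor; return (kept, excluded ids).

    Genus stage: floor is ``min_members``.  rrn stage: floor is
    ``ceil(input_fraction x total input)`` unless ``rescue_min_members``
    overrides it (the rescue keeps low-abundance isolates from being
    dropped as putative chimeras).
    """
    total = sum(c.size for c in clusters)
    if rescue_min_members is not None:
        floor = rescue_min_members
    elif input_fraction is not None:
        floor = ceil(input_fraction * total)
    elif min_members is not None:
        floor = min_members
    else:
        raise ValueError("one of min_members / input_fraction is required")
    kept, excluded = [], []
    for c in clusters:
        if c.size >= floor:
            kept.append(c)
        else:
            excluded.extend(c.member_ids)
    return kept, excluded


def assign_taxonomy(
    cluster: Cluster,
    seqs_by_id: dict[str, str],
    v4_refs: list[SeqRecord],
    v4_fwd: str = PRIMER_515F,
    v4_rev: str = PRIMER_806R_SITE,
    max_mismatch: int = 2,
) -> Cluster:
    """Label a cluster by the modal best-matching V4 reference taxon.

    Per member the V4 span (515F..806R sites inclusive) is extracted and
    assigned the label (reference description, falling back to id) of the
    best-identity V4 reference; the cluster label is the modal member label
    with its supporting fraction.  Members without a V4 span abstain; a
    cluster where every member abstains is ``unassigned``.
    """
    if not v4_refs:
        raise ValueError("empty V4 reference set")
    labels = []
    for sid in cluster.member_ids:
        seq = seqs_by_id.get(sid)
        if seq is None:
            continue
        fwd = find_motif(seq, v4_fwd, max_mismatch)
        if fwd is None:
            continue
        rev = find_motif(seq[fwd[1]:], v4_rev, max_mismatch)
        if rev is None:
            continue
        v4 = seq[fwd[0] : fwd[1] + rev[1]]
        best_label, best_ident = None, -1.0
        for ref in v4_refs:
            # infix identity: robust whether the reference is a bare V4
            # amplicon or a longer sequence containing it
            if len(v4) <= len(ref.seq):
                ident = infix_identity(v4, ref.seq)
            else:
                ident = infix_identity(ref.seq, v4)
            if ident > best_ident:
                best_ident = ident
                best_label = ref.description or ref.id
        labels.append(best_label)
    if not labels:
        cluster.taxonomy = "unassigned"
        cluster.taxonomy_fraction = 0.0
        return cluster
    counts = Counter(labels)
    top, n = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0]
    cluster.taxonomy = top
    cluster.taxonomy_fraction = n / len(labels)
    return cluster


def global_identity_prefilter(
    seqs: list[tuple[str, str]],
    refs: list[str],
    min_identity: float = 0.95,
) -> tuple[list[tuple[str, str]], list[str]]:
    """Keep sequences >= ``min_identity`` full-length global identity to at
    least one reference 16S-ITS sequence (end gaps charged).

    Note this deliberately does NOT remove chimeras of two references: a
    50/50 chimera is still ~97% identical to either parent.
    """
    if not refs:
        raise ValueError("empty reference set")
    kept, discarded = [], []
    for sid, seq in seqs:
        best = max(global_identity(seq, ref) for ref in refs)
        if best >= min_identity:
            kept.append((sid, seq))
        else:
            discarded.append(sid)
    return kept, discarded
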