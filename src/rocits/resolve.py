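"""rrn-copy resolution within a genus, and reference-based chimera calls.

Distinct rrn copies of one genome differ at only a handful of alignment
columns, so full-length identity clustering cannot separate them at any
reasonable threshold.  Instead, the columns of the corrected genus MSA
where the majority character falls under 95% are extracted together with
their four neighboring columns; these concatenated sub-sequences carry all
the discriminating signal and are re-clustered across a ladder of identity
thresholds (the identity sweep).  Sub-sequence clusters below 5% of the
input are dropped as putative chimeras; surviving clusters are mapped back
to the full-length sequences and collapsed to per-rrn consensus sequences.

When vetted references exist, chimeras are instead called directly: a
candidate is chimeric when the best two-parent model (prefix of one
reference followed by the suffix of another, single breakpoint) beats the
best single reference by a margin in both absolute edits and identity.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from ._align import (
    GAP,
    center_star_rows,
    edit_distance,
    prefix_distance,
    suffix_distance,
)
from .cluster import Cluster, filter_small_clusters
from .config import ResolveConfig
from .consensus import column_consensus
from .seqio import Msa, msa_from_rows, ungap


@dataclass
class RrnCall:
    genus: str
    identity_used: float
    clusters: list[Cluster]
    cluster_count_curve: dict[float, int]
    raw_count_curve: dict[float, int] = field(default_factory=dict)
    excluded_ids: list[str] = field(default_factory=list)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)


@dataclass
class ChimeraVerdict:
    is_chimera: bool
    parents: tuple[int, int] | None = None
    breakpoint: int | None = None
    single_parent_edits: int = 0
    two_parent_edits: int = 0


def variable_columns(msa: Msa, cfg: ResolveConfig | None = None) -> list[int]:
    """Columns whose plurality character (over non-N rows) is under the
    variable-majority threshold."""
    cfg = cfg or ResolveConfig()
    mat = np.array([list(r) for r in msa.matrix])
    out = []
    for j in range(mat.shape[1]):
        col = mat[:, j]
        col = col[col != "N"]
        if col.size == 0:
            continue
        top = Counter(col).most_common(1)[0][1]
        if top / col.size < cfg.variable_majority_fraction:
            out.append(j)
    return out


def extract_subsequences(
    msa: Msa, columns: list[int], cfg: ResolveConfig | None = None
) -> list[tuple[str, str]]:
    """Per row, the concatenated variable-column windows (gaps retained).

    Each variable column contributes itself plus ``flank_columns`` on each
    side; overlapping windows are merged, and windows are clipped at the
    alignment bounds.
    """
    cfg = cfg or ResolveConfig()
    if not columns:
        raise ValueError("no_variable_columns: genus appears single-rrn")
    windows: list[list[int]] = []
    for j in sorted(columns):
        lo = max(0, j - cfg.flank_columns)
        hi = min(msa.width - 1, j + cfg.flank_columns)
        if windows and lo <= windows[-1][1] + 1:
            windows[-1][1] = max(windows[-1][1], hi)
        else:
            windows.append([lo, hi])
    out = []
    for rid, row in zip(msa.row_ids, msa.matrix):
        sub = "".join(row[lo : hi + 1] for lo, hi in windows)
        out.append((rid, sub))
    return out


def _hamming_identity(a: str, b: str) -> float:
    """Column-wise identity on aligned windows; N is a wildcard."""
    if len(a) != len(b):
        raise ValueError("window sub-sequences must have equal width")
    if not a:
        return 1.0
    matches = sum(1 for x, y in zip(a, b) if x == y or x == "N" or y == "N")
    return matches / len(a)


def _greedy_hamming_cluster(
    subseqs: list[tuple[str, str]], identity: float
) -> list[list[str]]:
    """Greedy clustering of equal-width window strings (input order)."""
    reps: list[str] = []
    members: list[list[str]] = []
    for sid, sub in subseqs:
        placed = False
        for i, rep in enumerate(reps):
            if _hamming_identity(sub, rep) >= identity:
                members[i].append(sid)
                placed = True
                break
        if not placed:
            reps.append(sub)
            members.append([sid])
    return members


def sweep_cluster(
    subseqs: list[tuple[str, str]],
    full_seqs: dict[str, str],
    cfg: ResolveConfig | None = None,
    genus: str = "genus",
    target_count: int | None = None,
) -> RrnCall:
    """Cluster the variable-column sub-sequences across the identity sweep.

    At each identity the sub-sequences are greedily clustered, clusters
    under the small-cluster floor are dropped, and the surviving cluster
    count recorded.  The reported call uses the lowest identity achieving
    ``target_count`` when given, else the plateau (modal) count across the
    sweep.  Full-length clusters mirror the surviving sub-sequence
    clusters; sequences whose sub-sequence cluster was dropped are excluded.
    """
    cfg = cfg or ResolveConfig()
    n_input = len(subseqs)
    curve: dict[float, int] = {}
    raw_curve: dict[float, int] = {}
    survivors_at: dict[float, list[list[str]]] = {}
    for ident in cfg.sweep_identities:
        groups = _greedy_hamming_cluster(subseqs, ident)
        raw_curve[ident] = len(groups)
        clusters = [
            Cluster(f"tmp_{i}", "rrn", ident, m, m[0]) for i, m in enumerate(groups)
        ]
        kept, _ = filter_small_clusters(
            clusters,
            input_fraction=cfg.min_cluster_input_fraction,
            rescue_min_members=cfg.rescue_min_members,
        )
        curve[ident] = len(kept)
        survivors_at[ident] = [c.member_ids for c in kept]

    counts = list(curve.values())
    if target_count is not None:
        chosen = next(
            (i for i in cfg.sweep_identities if curve[i] == target_count), None
        )
        if chosen is None:
            chosen = cfg.sweep_identities[-1]
    else:
        modal = Counter(counts).most_common()
        best_count = sorted(modal, key=lambda kv: (-kv[1], -kv[0]))[0][0]
        chosen = next(i for i in cfg.sweep_identities if curve[i] == best_count)

    clusters: list[Cluster] = []
    clustered_ids: set[str] = set()
    for i, member_ids in enumerate(survivors_at[chosen]):
        cons = cluster_consensus([full_seqs[m] for m in member_ids])
        clusters.append(
            Cluster(
                cluster_id=f"{genus}_rrn_{i:02d}",
                level="rrn",
                identity_threshold=chosen,
                member_ids=member_ids,
                representative_id=member_ids[0],
                consensus=cons,
            )
        )
        clustered_ids.update(member_ids)
    excluded = [sid for sid, _ in subseqs if sid not in clustered_ids]
    return RrnCall(genus, chosen, clusters, curve, raw_curve, excluded)


def cluster_consensus(full_seqs: list[str]) -> str:
    """Plurality consensus of one rrn cluster's full-length sequences."""
    if not full_seqs:
        raise ValueError("empty cluster")
    if len(full_seqs) == 1:
        return full_seqs[0]
    rows = center_star_rows(full_seqs)
    msa = msa_from_rows([f"m{i}" for i in range(len(rows))], rows)
    return ungap(column_consensus(msa)).replace("N", "")


def detect_chimera_ref(
    candidate: str,
    refs: list[str],
    cfg: ResolveConfig | None = None,
    coarse_step: int = 25,
) -> ChimeraVerdict:
    """Two-parent breakpoint test against vetted references.

    The best single-parent global edit distance is compared with the best
    two-parent model: over a coarse grid of candidate breakpoints (refined
    to single-base resolution around the optimum), the prefix is scored
    against every reference's prefixes and the suffix against every
    reference's suffixes.  Chimeric iff the two-parent parents differ and
    the model saves >= ``chimera_min_edits_saved`` edits and >=
    ``chimera_min_identity_gain`` of the candidate length.
    """
    if len(refs) < 2:
        raise ValueError("need at least two references")
    cfg = cfg or ResolveConfig()
    n = len(candidate)
    single = [edit_distance(candidate, r) for r in refs]
    best_single = min(single)

    def two_parent_at(i: int) -> tuple[int, int, int]:
        pre = [prefix_distance(candidate[:i], r) for r in refs]
        suf = [suffix_distance(candidate[i:], r) for r in refs]
        a = int(np.argmin(pre))
        b = int(np.argmin(suf))
        return pre[a] + suf[b], a, b

    grid = list(range(coarse_step, n, coarse_step)) or [n // 2]
    scored = [(two_parent_at(i), i) for i in grid]
    (best_ed, a, b), best_i = min(scored, key=lambda t: (t[0][0], t[1]))
    lo = max(1, best_i - coarse_step)
    hi = min(n - 1, best_i + coarse_step)
    for i in range(lo, hi + 1, max(1, coarse_step // 12)):
        ed, pa, pb = two_parent_at(i)
        if ed < best_ed:
            best_ed, a, b, best_i = ed, pa, pb, i

    saved = best_single - best_ed
    is_chimera = (
        a != b
        and saved >= cfg.chimera_min_edits_saved
        and saved / n >= cfg.chimera_min_identity_gain
    )
    return ChimeraVerdict(
        is_chimera=is_chimera,
        parents=(a, b) if is_chimera else None,
        breakpoint=best_i if is_chimera else None,
        single_parent_edits=best_single,
        two_parent_edits=best_ed,
    )
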