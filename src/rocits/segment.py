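"""Concatemer read segmentation: splint finding, barcode validation, clipping.

A rolling-circle read is ``splint (unit splint) x k`` on one strand or the
other.  Splint copies are located by infix edit-distance alignment of the
splint against the read (iterative best-hit masking, so all copies are
found); the intervals between consecutive splint hits are candidate
sub-reads.  Each interval carries the forward unique primer + 5-bp barcode
at its start and the 3' barcode + reverse unique primer at its end; the two
barcode consensuses must be clean and consistent or the whole read is
discarded as a mixed-template artifact.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from ._align import GAP, center_star_rows, find_all_infix, revcomp
from .config import ConstructModel, SegmentConfig
from .seqio import SeqRecord

REJECTED = "REJECTED"


@dataclass
class JunctionHit:
    """One splint placement on a read (0-based half-open, read coordinates)."""

    read_id: str
    start: int
    end: int
    orientation: str
    score: int        # edits saved vs the rejection threshold (higher = better)
    identity: float   # 1 - edits / splint length

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("junction end must exceed start")


@dataclass
class SubReadSet:
    read_id: str
    sub_reads: list[str] = field(default_factory=list)
    bc5_observations: list[str] = field(default_factory=list)
    bc3_observations: list[str] = field(default_factory=list)
    bc5_consensus: str | None = None
    bc3_consensus: str | None = None
    discard_reason: str | None = None
    n_size_discarded: int = 0


def find_junctions(
    read: SeqRecord, construct: ConstructModel, cfg: SegmentConfig
) -> list[JunctionHit]:
    """Locate every splint copy on either strand of a read.

    Both strands are scanned; the orientation with more hits (ties: lower
    total edit distance, then '+') wins and only its hits are returned,
    sorted by start coordinate.
    """
    splint = construct.splint
    max_edits = int(cfg.junction_max_error * len(splint))
    hits_by_strand: dict[str, list[tuple[int, int, int]]] = {}
    for strand, query in (("+", splint), ("-", revcomp(splint))):
        hits_by_strand[strand] = find_all_infix(query, read.seq, max_edits)
    plus, minus = hits_by_strand["+"], hits_by_strand["-"]
    if len(plus) != len(minus):
        strand = "+" if len(plus) > len(minus) else "-"
    else:
        ed_plus = sum(h[2] for h in plus)
        ed_minus = sum(h[2] for h in minus)
        strand = "+" if ed_plus <= ed_minus else "-"
    out = []
    for start, end, ed in hits_by_strand[strand]:
        out.append(
            JunctionHit(
                read_id=read.id,
                start=start,
                end=end,
                orientation=strand,
                score=max_edits - ed,
                identity=1.0 - ed / len(splint),
            )
        )
    return out


def split_read(
    read: SeqRecord,
    junctions: list[JunctionHit],
    construct: ConstructModel,
    cfg: SegmentConfig,
) -> SubReadSet:
    """Cut the read at splint junctions into barcode-clipped sub-reads.

    Sub-reads are reported in canonical (+) orientation regardless of the
    sequenced strand.  Intervals outside [min_sub_len, max_sub_len] (after
    clipping the unique primers and barcodes) are dropped with reason
    ``size``; a read with no junctions is discarded whole (``no_junction``).
    """
    out = SubReadSet(read_id=read.id)
    if not junctions:
        out.discard_reason = "no_junction"
        return out
    seq = read.seq
    coords = [(j.start, j.end) for j in junctions]
    if junctions[0].orientation == "-":
        L = len(seq)
        seq = revcomp(seq)
        coords = sorted((L - e, L - s) for s, e in coords)

    bc = construct.barcode_len
    fu, ru = len(construct.fwd_unique), len(construct.rev_unique)
    for (_, prev_end), (next_start, _) in zip(coords, coords[1:]):
        u_start, u_end = prev_end, next_start
        core_start = u_start + fu + bc
        core_end = u_end - ru - bc
        if core_end <= core_start:
            out.n_size_discarded += 1
            continue
        core = seq[core_start:core_end]
        if not (cfg.min_sub_len <= len(core) <= cfg.max_sub_len):
            out.n_size_discarded += 1
            continue
        out.sub_reads.append(core)
        out.bc5_observations.append(seq[u_start + fu : u_start + fu + bc])
        out.bc3_observations.append(seq[u_end - ru - bc : u_end - ru])
    return out


def barcode_consensus(
    observations: list[str], cutoff: float, max_len: int
) -> str:
    """Cross-repeat consensus of the barcode observations of one read.

    The observations are multiply aligned; per column the plurality
    character is taken: a gap-plurality column is dropped, a base reaching
    ``cutoff`` is emitted, and a below-cutoff base column is kept as an
    ambiguous ``N``.  A consensus longer than ``max_len`` means the read
    mixes barcodes from different template molecules -> ``REJECTED``.
    """
    if not observations:
        raise ValueError("need at least one barcode observation")
    obs = [o for o in observations if o]
    if not obs:
        return REJECTED
    if len(obs) == 1:
        return obs[0] if len(obs[0]) <= max_len else REJECTED
    rows = center_star_rows(obs)
    width = len(rows[0])
    consensus = []
    for j in range(width):
        counts = Counter(r[j] for r in rows)
        # ties: base before gap, then alphabetical
        top, top_n = sorted(
            counts.items(), key=lambda kv: (-kv[1], kv[0] == GAP, kv[0])
        )[0]
        if top == GAP:
            continue
        if top_n / len(rows) >= cutoff:
            consensus.append(top)
        else:
            consensus.append("N")
    result = "".join(consensus)
    if len(result) > max_len:
        return REJECTED
    return result


def validate_and_clip(srs: SubReadSet, cfg: SegmentConfig) -> SubReadSet:
    """Compute both barcode consensuses; reject mixed-barcode reads.

    The barcodes were already clipped from the sub-read cores during
    :func:`split_read`; this step only validates their consistency.
    """
    if srs.discard_reason:
        return srs
    if not srs.sub_reads:
        srs.discard_reason = "no_valid_subread"
        return srs
    srs.bc5_consensus = barcode_consensus(
        srs.bc5_observations, cfg.barcode_consensus_cutoff, cfg.max_barcode_len
    )
    srs.bc3_consensus = barcode_consensus(
        srs.bc3_observations, cfg.barcode_consensus_cutoff, cfg.max_barcode_len
    )
    if REJECTED in (srs.bc5_consensus, srs.bc3_consensus):
        srs.discard_reason = "mixed_barcode"
    return srs


def segment_read(
    read: SeqRecord, construct: ConstructModel, cfg: SegmentConfig
) -> SubReadSet:
    """find_junctions -> split_read -> validate_and_clip for one read."""
    junctions = find_junctions(read, construct, cfg)
    srs = split_read(read, junctions, construct, cfg)
    return validate_and_clip(srs, cfg)
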