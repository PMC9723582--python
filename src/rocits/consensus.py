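"""Per-read consensus: sub-read MSA, iterative outlier pruning, collapse.

The sub-reads of one read are ~98% identical copies of the same molecule,
so a center-star alignment against the median-length sub-read is an
adequate and fully deterministic MSA.  The per-column plurality consensus
(base or gap) is used to score each sub-read: 1 point per agreeing column,
0.5 per column where the sub-read has a gap under a consensus base, 0
otherwise.  Sub-reads scoring under 65% of the alignment width are removed
and the MSA rebuilt, iterating until nothing is removed or three or fewer
sub-reads remain.  Reads whose surviving support falls under five sub-reads
are discarded.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from ._align import GAP, center_star_rows
from .config import ConsensusConfig
from .segment import SubReadSet
from .seqio import Msa, ungap

_ORDER = {b: i for i, b in enumerate("ACGTN" + GAP)}


@dataclass
class RocItsSequence:
    """The consensus sequence of one concatemer read."""

    id: str
    seq: str
    n_subreads_final: int
    n_subreads_initial: int
    read_id: str

    def __post_init__(self) -> None:
        if self.n_subreads_final > self.n_subreads_initial:
            raise ValueError("final sub-read count cannot exceed initial")


def align_subreads(sub_reads: list[str], cfg: ConsensusConfig | None = None,
                   ids: list[str] | None = None) -> Msa:
    """Center-star MSA of the sub-reads of one read (deterministic)."""
    if len(sub_reads) < 2:
        raise ValueError("need at least two sub-reads to build an alignment")
    if ids is None:
        ids = [f"sr{i}" for i in range(len(sub_reads))]
    rows = center_star_rows(sub_reads)
    return Msa(list(ids), rows)


def _matrix(msa: Msa) -> np.ndarray:
    return np.array([list(r) for r in msa.matrix])


def column_consensus(msa: Msa) -> str:
    """Plurality character (base or gap) per column.

    Ties break base-before-gap, then A<C<G<T<N; the fixed rule favors
    retaining sequence.
    """
    if msa.n_rows == 0:
        raise ValueError("empty alignment")
    mat = _matrix(msa)
    out = []
    for j in range(mat.shape[1]):
        counts = Counter(mat[:, j])
        top = sorted(
            counts.items(),
            key=lambda kv: (-kv[1], kv[0] == GAP, _ORDER.get(kv[0], 9)),
        )[0][0]
        out.append(top)
    return "".join(out)


def score_subread(row: str, consensus: str) -> float:
    """Column score of one gapped sub-read against the gapped consensus."""
    if len(row) != len(consensus):
        raise ValueError("row and consensus must have equal width")
    r = np.array(list(row))
    c = np.array(list(consensus))
    match = r == c
    half = (r == GAP) & (c != GAP)
    return float(match.sum() + 0.5 * (half & ~match).sum())


def prune_outliers(msa: Msa, cfg: ConsensusConfig) -> tuple[Msa, list[str]]:
    """Iteratively remove sub-reads scoring below the threshold.

    Each iteration scores every row against the current plurality consensus
    and removes all rows under ``outlier_score_fraction x width``; the MSA
    is rebuilt from the survivors (removal of a divergent row can shift
    columns).  Stops when no row is removed or the row count reaches
    ``stop_at_subreads``.
    """
    removed: list[str] = []
    current = msa
    while current.n_rows > cfg.stop_at_subreads:
        cons = column_consensus(current)
        threshold = cfg.outlier_score_fraction * current.width
        keep_ids, keep_seqs = [], []
        dropped = False
        for rid, row in zip(current.row_ids, current.matrix):
            if score_subread(row, cons) < threshold:
                removed.append(rid)
                dropped = True
            else:
                keep_ids.append(rid)
                keep_seqs.append(ungap(row))
        if not dropped:
            break
        if len(keep_seqs) < 2:
            current = Msa(keep_ids, keep_seqs)
            break
        current = align_subreads(keep_seqs, cfg, ids=keep_ids)
    return current, removed


def build_rocits_sequence(
    srs: SubReadSet, cfg: ConsensusConfig
) -> RocItsSequence | None:
    """align -> prune -> consensus -> strip gaps; None if support is too low."""
    n_initial = len(srs.sub_reads)
    if n_initial < max(2, cfg.min_final_subreads):
        return None
    msa = align_subreads(srs.sub_reads, cfg)
    pruned, _removed = prune_outliers(msa, cfg)
    if pruned.n_rows < cfg.min_final_subreads:
        return None
    seq = ungap(column_consensus(pruned))
    return RocItsSequence(
        id=f"{srs.read_id}/consensus",
        seq=seq,
        n_subreads_final=pruned.n_rows,
        n_subreads_initial=n_initial,
        read_id=srs.read_id,
    )
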