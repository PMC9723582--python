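"""Per-genus MSA construction, two-pass column correction, and trimming.

Consensus sequences of one genus are multiply aligned (center-star, same
engine as the per-read consensus), locally repaired where gapping is
inconsistent, then corrected column by column: a column with a dominant
character (>= 98% by default) has its minorities corrected to it, while a
genuinely polymorphic column (two or more characters each >= 2%) has its
sub-2% characters masked to N.  Correction is two-pass: the first pass only
counts prospective corrections and excludes sequences with an excess
(> 0.05% of their ungapped length -- typically large-indel or chimeric
artifacts); the second pass recomputes column statistics on the survivors
and applies the corrections, so excluded outliers never influence the final
result.  Finally the ragged alignment ends are trimmed to the first and
last columns that are >= 98% non-gap.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from ._align import GAP, center_star_rows
from .config import RefineConfig
from .seqio import Msa, ungap

_CHARS = np.array(list("ACGT" + GAP + "N"))
_INDEX = {c: i for i, c in enumerate(_CHARS)}
_N_IDX = _INDEX["N"]
_GAP_IDX = _INDEX[GAP]


@dataclass
class ColumnAction:
    action: str                       # none | corrected_to_dominant | minority_to_N
    dominant: str | None = None
    corrected_chars: frozenset = frozenset()


@dataclass
class CorrectionReport:
    counted: dict[str, int] = field(default_factory=dict)
    applied: dict[str, int] = field(default_factory=dict)
    excluded: list[str] = field(default_factory=list)
    column_actions: list[str] = field(default_factory=list)


def _codes(msa: Msa) -> np.ndarray:
    mat = np.array([list(r) for r in msa.matrix])
    codes = np.zeros(mat.shape, dtype=np.int8)
    for c, i in _INDEX.items():
        codes[mat == c] = i
    return codes


def build_genus_msa(seqs: list[tuple[str, str]], cfg: RefineConfig | None = None) -> Msa:
    """Center-star MSA of a genus cluster with local repair.

    Windows whose columns disagree beyond ``realign_window_min_disagreement``
    and contain gaps are extracted with flanking columns and re-aligned
    against the window's own plurality sequence, which irons out
    inconsistent gap placements.  Deterministic.
    """
    if len(seqs) < 2:
        raise ValueError("need at least two sequences for a genus alignment")
    cfg = cfg or RefineConfig()
    ids = [sid for sid, _ in seqs]
    rows = center_star_rows([s for _, s in seqs])
    rows = _repair_rows(rows, cfg)
    return Msa(ids, rows)


def _repair_rows(rows: list[str], cfg: RefineConfig) -> list[str]:
    mat = np.array([list(r) for r in rows])
    n, width = mat.shape
    disagree = np.zeros(width)
    has_gap = np.zeros(width, dtype=bool)
    for j in range(width):
        counts = Counter(mat[:, j])
        top = max(counts.values())
        disagree[j] = 1.0 - top / n
        has_gap[j] = GAP in counts
    bad = (disagree > cfg.realign_window_min_disagreement) & has_gap
    if not bad.any():
        return rows
    # merge flagged columns into windows with flanks
    windows: list[list[int]] = []
    for j in np.where(bad)[0]:
        lo, hi = max(0, j - cfg.repair_flank), min(width, j + cfg.repair_flank + 1)
        if windows and lo <= windows[-1][1]:
            windows[-1][1] = hi
        else:
            windows.append([lo, hi])
    out = [list(r) for r in rows]
    offset = 0  # widths may change as windows are rebuilt
    for lo, hi in windows:
        lo += offset
        hi += offset
        block = ["".join(row[lo:hi]) for row in out]
        contents = [ungap(b) for b in block]
        if len(set(contents)) <= 1:
            continue
        rebuilt = center_star_rows(contents)
        new_w = len(rebuilt[0])
        for row, piece in zip(out, rebuilt):
            row[lo:hi] = list(piece)
        offset += new_w - (hi - lo)
    return ["".join(r) for r in out]


def analyze_column(column: list[str] | str, cfg: RefineConfig) -> ColumnAction:
    """Classify one MSA column under the dominant/minority rules.

    Gap characters participate exactly like bases; N never counts as a
    dominant character and is itself never corrected.
    """
    chars = list(column)
    n = len(chars)
    if n == 0:
        raise ValueError("empty column")
    counts = Counter(c for c in chars if c != "N")
    if not counts:
        return ColumnAction("none")
    top, top_n = sorted(
        counts.items(), key=lambda kv: (-kv[1], kv[0] == GAP, kv[0])
    )[0]
    if top_n / n >= cfg.dominant_fraction:
        minors = frozenset(c for c in counts if c != top)
        if minors:
            return ColumnAction("corrected_to_dominant", top, minors)
        return ColumnAction("none", top)
    frequent = [c for c, k in counts.items() if k / n >= cfg.minority_to_N_fraction]
    if len(frequent) >= 2:
        rare = frozenset(c for c, k in counts.items() if k / n < cfg.minority_to_N_fraction)
        if rare:
            return ColumnAction("minority_to_N", top, rare)
    return ColumnAction("none", top)


def _count_corrections(msa: Msa, cfg: RefineConfig,
                       active: np.ndarray) -> tuple[np.ndarray, list[ColumnAction]]:
    """Per-row prospective correction counts using only ``active`` rows for
    the column statistics (but counting corrections for every row)."""
    mat = np.array([list(r) for r in msa.matrix])
    n_rows, width = mat.shape
    counts = np.zeros(n_rows, dtype=int)
    actions: list[ColumnAction] = []
    for j in range(width):
        act = analyze_column(mat[active, j].tolist(), cfg)
        actions.append(act)
        if act.action == "none" or not act.corrected_chars:
            continue
        hit = np.isin(mat[:, j], list(act.corrected_chars))
        counts += hit
    return counts, actions


def correct_msa(
    msa: Msa, cfg: RefineConfig | None = None
) -> tuple[Msa, CorrectionReport, list[str]]:
    """Two-pass column correction; returns (corrected MSA of survivors,
    report, excluded ids)."""
    cfg = cfg or RefineConfig()
    report = CorrectionReport()
    if msa.n_rows == 0:
        return Msa([], []), report, []
    active = np.ones(msa.n_rows, dtype=bool)

    counts, _ = _count_corrections(msa, cfg, active)
    limits = np.array(
        [cfg.max_correction_fraction * len(ungap(r)) for r in msa.matrix]
    )
    for i, rid in enumerate(msa.row_ids):
        report.counted[rid] = int(counts[i])
        if counts[i] > limits[i]:
            report.excluded.append(rid)
            active[i] = False

    if not active.any():
        return Msa([], []), report, list(report.excluded)

    counts2, actions = _count_corrections(msa, cfg, active)
    mat = np.array([list(r) for r in msa.matrix])
    for j, act in enumerate(actions):
        report.column_actions.append(act.action)
        if act.action == "none" or not act.corrected_chars:
            continue
        hit = np.isin(mat[:, j], list(act.corrected_chars)) & active
        if act.action == "corrected_to_dominant":
            mat[hit, j] = act.dominant
        else:
            mat[hit, j] = "N"
    survivor_ids = [rid for rid, a in zip(msa.row_ids, active) if a]
    survivor_rows = ["".join(mat[i]) for i in np.where(active)[0]]
    for i, rid in enumerate(msa.row_ids):
        if active[i]:
            report.applied[rid] = int(counts2[i])
        else:
            report.applied[rid] = 0
    corrected = Msa(survivor_ids, survivor_rows).compact()
    return corrected, report, list(report.excluded)


def trim_msa(
    msa: Msa, cfg: RefineConfig | None = None,
    end_motifs: tuple[str, str] | None = None,
) -> tuple[Msa, int, int]:
    """Trim ragged alignment ends.

    Keeps columns [left, right] inclusive, where left/right are the first
    and last columns whose non-gap fraction >= ``trim_nongap_fraction``.
    ``end_motifs`` optionally masks residual primer bases overlapping the
    boundaries (a motif found straddling an end advances the boundary past
    it).  Raises if no column qualifies.
    """
    cfg = cfg or RefineConfig()
    if msa.n_rows == 0:
        raise ValueError("empty alignment")
    mat = np.array([list(r) for r in msa.matrix])
    nongap = (mat != GAP).mean(axis=0)
    ok = np.where(nongap >= cfg.trim_nongap_fraction)[0]
    if ok.size == 0:
        raise ValueError("empty_after_trim: no column satisfies the non-gap rule")
    left, right = int(ok[0]), int(ok[-1])
    if end_motifs:
        from .cluster import find_motif

        cons = "".join(
            sorted(Counter(mat[:, j]).items(), key=lambda kv: -kv[1])[0][0]
            for j in range(mat.shape[1])
        )
        fwd, rev = end_motifs
        if fwd:
            hit = find_motif(ungap(cons[left : left + 2 * len(fwd)]), fwd, 2)
            if hit is not None and hit[0] <= 2:
                left = _advance_columns(mat, left, hit[1])
        if rev:
            tail = ungap(cons[max(left, right + 1 - 2 * len(rev)) : right + 1])
            hit = find_motif(tail, rev, 2)
            if hit is not None and len(tail) - hit[1] <= 2:
                right = _retreat_columns(mat, right, len(tail) - hit[0])
    trimmed = Msa(list(msa.row_ids), ["".join(r[left : right + 1]) for r in mat])
    return trimmed, left, right


def _advance_columns(mat: np.ndarray, left: int, n_bases: int) -> int:
    """Advance ``left`` past ``n_bases`` consensus (non-gap-majority) columns."""
    seen = 0
    j = left
    while j < mat.shape[1] and seen < n_bases:
        counts = Counter(mat[:, j])
        if sorted(counts.items(), key=lambda kv: -kv[1])[0][0] != GAP:
            seen += 1
        j += 1
    return j


def _retreat_columns(mat: np.ndarray, right: int, n_bases: int) -> int:
    seen = 0
    j = right
    while j >= 0 and seen < n_bases:
        counts = Counter(mat[:, j])
        if sorted(counts.items(), key=lambda kv: -kv[1])[0][0] != GAP:
            seen += 1
        j -= 1
    return j
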