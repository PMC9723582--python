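"""Quantitative summaries: error rates, uniformity tests, cross-platform
abundance agreement, informative sites, and stage-survival tables.

Correlations and the chi-square goodness-of-fit test are thin, documented
wrappers over scipy.stats so every number the pipeline reports has a single
authoritative definition.  Correlations are computed on raw counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._align import cigar_stats, revcomp
from .seqio import Msa
import edlib


@dataclass
class ErrorEstimate:
    per_sequence: pd.DataFrame
    mean_identity: float
    sd_identity: float

    @property
    def mean_error(self) -> float:
        return 100.0 - self.mean_identity


def estimate_error(
    seqs: list[tuple[str, str]],
    refs: list[str],
) -> ErrorEstimate:
    """Percent identity of each sequence against its best reference.

    Each reference is infix-aligned into the sequence on both strands; the
    best (lowest-edit) reference wins.  Percent identity is identities over
    alignment columns (the reference is fully consumed by the infix
    alignment, so no unaligned reference bases remain to add).
    """
    if not refs:
        raise ValueError("empty reference set")
    if not seqs:
        raise ValueError("no sequences to score")
    rows = []
    for sid, seq in seqs:
        best = None
        for ri, ref in enumerate(refs):
            for strand_ref in (ref, revcomp(ref)):
                res = edlib.align(strand_ref, seq, mode="HW", task="path")
                if res["editDistance"] < 0:
                    continue
                if best is None or res["editDistance"] < best[0]:
                    best = (res["editDistance"], ri, res["cigar"])
        ed, ri, cigar = best
        matches, columns = cigar_stats(cigar)
        rows.append(
            {
                "id": sid,
                "best_ref": ri,
                "identities": matches,
                "alignment_length": columns,
                "percent_identity": 100.0 * matches / columns,
            }
        )
    df = pd.DataFrame(rows)
    return ErrorEstimate(
        per_sequence=df,
        mean_identity=float(df["percent_identity"].mean()),
        sd_identity=float(df["percent_identity"].std(ddof=1)) if len(df) > 1 else 0.0,
    )


def chisq_uniform(counts: list[int]) -> tuple[float, int, float]:
    """Goodness-of-fit chi-square against equal category abundances.

    Returns (statistic, degrees of freedom, upper-tail p-value).
    """
    counts = np.asarray(counts, dtype=float)
    if counts.size < 2:
        raise ValueError("need at least two categories")
    total = counts.sum()
    if total <= 0:
        raise ValueError("zero total count")
    expected = total / counts.size
    statistic = float(((counts - expected) ** 2 / expected).sum())
    df = counts.size - 1
    p = float(sps.chi2.sf(statistic, df))
    return statistic, df, p


def _check_xy(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("x and y must have equal length >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance input")
    return x, y


def pearson(x, y) -> float:
    x, y = _check_xy(x, y)
    return float(sps.pearsonr(x, y).statistic)


def spearman(x, y) -> float:
    """Pearson correlation on mid-ranks (average ranks for ties)."""
    x, y = _check_xy(x, y)
    return float(sps.spearmanr(x, y).statistic)


def r_squared(x, y) -> float:
    """R-squared of the least-squares fit of y on x."""
    x, y = _check_xy(x, y)
    return float(sps.linregress(x, y).rvalue ** 2)


def informative_sites(msa: Msa, mode: str = "variable") -> int:
    """Alignment columns that differentiate sequences.

    ``variable``: >= 2 distinct non-N characters.  ``parsimony``: >= 2
    characters each occurring >= 2 times.  Gaps count as characters.
    """
    if msa.n_rows < 2:
        raise ValueError("need at least two rows")
    if mode not in ("variable", "parsimony"):
        raise ValueError("mode must be 'variable' or 'parsimony'")
    mat = np.array([list(r) for r in msa.matrix])
    count = 0
    for j in range(mat.shape[1]):
        col = mat[:, j]
        col = col[col != "N"]
        vals, freqs = np.unique(col, return_counts=True)
        if mode == "variable":
            count += int(len(vals) >= 2)
        else:
            count += int((freqs >= 2).sum() >= 2)
    return count


def survival_table(stage_counts: pd.DataFrame) -> pd.DataFrame:
    """Per-genus processing-survival metrics plus a totals row.

    Expects columns ``genus``, ``initial_clustering``, ``largest_cluster``,
    ``after_full_analysis``; adds ``largest_cluster_pct`` (largest cluster
    over initial count) and ``surviving_pct`` (final over initial), both as
    percentages rounded to one decimal.
    """
    required = {"genus", "initial_clustering", "largest_cluster", "after_full_analysis"}
    missing = required - set(stage_counts.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    bad = stage_counts["after_full_analysis"] > stage_counts["initial_clustering"]
    if bad.any():
        raise ValueError(
            "conservation violated: final exceeds initial for "
            + ", ".join(stage_counts.loc[bad, "genus"])
        )
    df = stage_counts.copy()
    df["largest_cluster_pct"] = (
        100.0 * df["largest_cluster"] / df["initial_clustering"]
    ).round(1)
    df["surviving_pct"] = (
        100.0 * df["after_full_analysis"] / df["initial_clustering"]
    ).round(1)
    totals = {c: df[c].sum() for c in df.columns if df[c].dtype.kind in "if"}
    totals["genus"] = "Total"
    totals["largest_cluster_pct"] = np.nan
    totals["surviving_pct"] = round(
        100.0 * df["after_full_analysis"].sum() / df["initial_clustering"].sum(), 1
    )
    return pd.concat([df, pd.DataFrame([totals])], ignore_index=True)


def load_community_stage_counts() -> pd.DataFrame:
    """The published per-genus stage counts of the artificial-community
    benchmark (input data for the agreement statistics)."""
    with resources.files("rocits.data").joinpath("community_stage_counts.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
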