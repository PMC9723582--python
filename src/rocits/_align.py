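"""Internal pairwise-alignment primitives and the center-star MSA engine.

All pairwise DNA alignment in the package goes through edlib (bit-parallel
edit-distance alignment).  Three modes are used:

* ``NW``  -- global alignment, end gaps penalized; used for identity between
  near-full-length sequences and for merging sub-reads into an MSA.
* ``HW``  -- infix alignment (query fully aligned somewhere inside the
  target, target end gaps free); used to scan a read for splint copies and
  for cd-hit-style identity where end gaps are excluded.
* ``SHW`` -- prefix alignment (target end gap free at the 3' end only);
  used for the prefix/suffix score arrays of the chimera test.

edlib CIGAR convention (verified): ``=`` match, ``X`` mismatch, ``I`` bases
present only in the *query*, ``D`` bases present only in the *target*.
"""

from __future__ import annotations

import re
from typing import Sequence

import edlib

GAP = "-"
_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N self-complementary)."""
    return seq.translate(_COMPLEMENT)[::-1]


def parse_cigar(cigar: str) -> list[tuple[str, int]]:
    """Parse an extended CIGAR into (op, length) tuples."""
    return [(op, int(n)) for n, op in _CIGAR_RE.findall(cigar)]


def _align(query: str, target: str, mode: str, task: str = "path", k: int = -1):
    res = edlib.align(query, target, mode=mode, task=task, k=k)
    return res


def edit_distance(a: str, b: str) -> int:
    """Global (NW) edit distance."""
    return _align(a, b, "NW", task="distance")["editDistance"]


def cigar_stats(cigar: str) -> tuple[int, int]:
    """(matches, columns) of an alignment path."""
    matches = 0
    columns = 0
    for op, n in parse_cigar(cigar):
        columns += n
        if op == "=":
            matches += n
    return matches, columns


def global_identity(a: str, b: str) -> float:
    """matches / alignment columns under global alignment (end gaps count)."""
    if not a or not b:
        return 0.0
    res = _align(a, b, "NW")
    matches, columns = cigar_stats(res["cigar"])
    return matches / columns if columns else 0.0


def infix_identity(query: str, target: str) -> float:
    """matches / alignment columns with target end gaps excluded.

    The shorter sequence should be the query; this mirrors cd-hit's notion
    of identity where the overhang of the longer sequence is not charged.
    """
    if not query or not target:
        return 0.0
    res = _align(query, target, "HW")
    matches, columns = cigar_stats(res["cigar"])
    return matches / columns if columns else 0.0


def best_infix_hit(query: str, target: str, k: int = -1):
    """Best placement of ``query`` inside ``target``.

    Returns (start, end, edit_distance) with end exclusive, or None if no
    alignment within ``k`` edits exists.
    """
    res = _align(query, target, "HW", task="locations", k=k)
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    start, end = res["locations"][0]
    return start, end + 1, res["editDistance"]


def find_all_infix(query: str, target: str, max_edits: int) -> list[tuple[int, int, int]]:
    """All non-overlapping placements of ``query`` in ``target`` with at most
    ``max_edits`` edits, best first, found by iterative best-hit masking.

    Returned sorted by start coordinate.
    """
    masked = list(target)
    hits: list[tuple[int, int, int]] = []
    while True:
        hit = best_infix_hit(query, "".join(masked), k=max_edits)
        if hit is None:
            break
        start, end, ed = hit
        hits.append((start, end, ed))
        masked[start:end] = "X" * (end - start)
    hits.sort()
    return hits


def prefix_distance(query: str, target: str) -> int:
    """Edit distance of ``query`` to the best-matching *prefix* of ``target``."""
    if not query:
        return 0
    return _align(query, target, "SHW", task="distance")["editDistance"]


def suffix_distance(query: str, target: str) -> int:
    """Edit distance of ``query`` to the best-matching *suffix* of ``target``."""
    if not query:
        return 0
    return _align(query[::-1], target[::-1], "SHW", task="distance")["editDistance"]


def pairwise_gapped(query: str, target: str) -> tuple[str, str]:
    """Global alignment of two sequences as a pair of gapped rows."""
    res = _align(query, target, "NW")
    q_row: list[str] = []
    t_row: list[str] = []
    qi = ti = 0
    for op, n in parse_cigar(res["cigar"]):
        if op in "=XM":
            q_row.append(query[qi : qi + n])
            t_row.append(target[ti : ti + n])
            qi += n
            ti += n
        elif op == "I":  # query-only bases
            q_row.append(query[qi : qi + n])
            t_row.append(GAP * n)
            qi += n
        elif op == "D":  # target-only bases
            q_row.append(GAP * n)
            t_row.append(target[ti : ti + n])
            ti += n
    return "".join(q_row), "".join(t_row)


def _walk_vs_center(seq: str, center: str) -> tuple[dict[int, str], list[str]]:
    """Align ``seq`` to ``center``; return (insertions before each center
    position, per-center-position aligned char)."""
    res = _align(seq, center, "NW")
    ins: dict[int, str] = {}
    aligned: list[str] = []
    qi = ti = 0
    for op, n in parse_cigar(res["cigar"]):
        if op in "=XM":
            aligned.extend(seq[qi : qi + n])
            qi += n
            ti += n
        elif op == "I":
            ins[ti] = ins.get(ti, "") + seq[qi : qi + n]
            qi += n
        elif op == "D":
            aligned.extend(GAP * n)
            ti += n
    return ins, aligned


def center_star_rows(seqs: Sequence[str], center_index: int | None = None) -> list[str]:
    """Center-star multiple alignment of near-identical sequences.

    Every sequence is globally aligned to a center sequence (by default the
    median-length input, ties to the earlier index); the pairwise alignments
    are merged with the classic "once a gap, always a gap" rule.  Fully
    deterministic for a fixed input order.
    """
    seqs = list(seqs)
    if len(seqs) == 1:
        return [seqs[0]]
    if center_index is None:
        center_index = median_length_index(seqs)
    center = seqs[center_index]
    L = len(center)

    walks = []
    for i, s in enumerate(seqs):
        if i == center_index:
            walks.append(({}, list(center)))
        else:
            walks.append(_walk_vs_center(s, center))

    master = [0] * (L + 1)
    for ins, _ in walks:
        for pos, chars in ins.items():
            if len(chars) > master[pos]:
                master[pos] = len(chars)

    rows: list[str] = []
    for ins, aligned in walks:
        parts: list[str] = []
        for i in range(L):
            own = ins.get(i, "")
            parts.append(own + GAP * (master[i] - len(own)))
            parts.append(aligned[i])
        own = ins.get(L, "")
        parts.append(own + GAP * (master[L] - len(own)))
        rows.append("".join(parts))
    return rows


def median_length_index(seqs: Sequence[str]) -> int:
    """Index of the median-length sequence (lower median).

    Ties break on sequence content, so the center choice -- and hence the
    resulting MSA columns -- is invariant to input permutation."""
    order = sorted(range(len(seqs)), key=lambda i: (len(seqs[i]), seqs[i], i))
    return order[(len(order) - 1) // 2]


def drop_gap_only_columns(rows: list[str]) -> list[str]:
    """Remove columns that are gaps in every row."""
    if not rows:
        return rows
    width = len(rows[0])
    keep = [j for j in range(width) if any(r[j] != GAP for r in rows)]
    if len(keep) == width:
        return rows
    return ["".join(r[j] for j in keep) for r in rows]


def kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(0, max(0, len(seq) - k + 1))}
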