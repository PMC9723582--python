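"""Synthetic communities, rrn templates, and rolling-circle concatemer reads.

The generator emulates the data the pipeline consumes: multi-copy rrn
template sets whose copies diverge by anything from a single SNP to a
tRNA-sized ITS insertion, taxon abundances spread over orders of magnitude,
concatemer geometry (splint + barcoded insert repeated k times), an
indel-rich ~2% per-base error process with per-read rate jitter, and
single-breakpoint template-swap chimeras.  Every read is paired with a
truth row so downstream stages can be scored exactly.

Synthetic templates carry concrete instances of the conserved primer sites
(27F, 1492R, V4 515F/806R) at their biological positions, so primer-based
16S and V4 extraction works on simulated data just as on real amplicons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ._align import revcomp
from .config import ConstructModel
from .seqio import SeqRecord

BASES = np.array(list("ACGT"))

# concrete instances of conserved sites, written on the 16S sense strand
SITE_27F = "AGAGTTTGATCATGGCTCAG"            # matches config.FWD_ANNEAL
SITE_1492R = "AAGTCGTAACAAGGTAACCGTA"        # rc of the 1492R primer
SITE_V4_F = "GTGCCAGCAGCCGCGGTAA"            # 515F instance
SITE_V4_R = "ATTAGATACCCTGGTAGTCC"           # rc of an 806R instance


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(BASES, size=n))


def make_template(
    rng_seed,
    core16s_len: int = 1400,
    its_len: int = 450,
) -> tuple[str, int]:
    """One synthetic 16S-ITS template.

    Layout: 27F site, 16S body containing the V4 region bounded by concrete
    515F/806R sites, the 1492R site closing the 16S gene, then a random ITS
    and the reverse annealing site.  Returns (sequence, its_start) where
    ``its_start`` is the 0-based offset of the first ITS base.
    """
    rng = _rng(rng_seed)
    pre_v4 = 230
    v4 = 252
    fixed = len(SITE_27F) + pre_v4 + len(SITE_V4_F) + v4 + len(SITE_V4_R) + len(SITE_1492R)
    tail = max(0, core16s_len - fixed)
    seq16s = (
        SITE_27F
        + _random_dna(rng, pre_v4)
        + SITE_V4_F
        + _random_dna(rng, v4)
        + SITE_V4_R
        + _random_dna(rng, tail)
        + SITE_1492R
    )
    its = _random_dna(rng, its_len)
    from .config import REV_ANNEAL

    template = seq16s + its + revcomp(REV_ANNEAL)
    return template, len(seq16s)


def _apply_edits(seq: str, ops: Sequence, rng: np.random.Generator,
                 region: tuple[int, int]) -> str:
    lo, hi = region
    s = list(seq)
    for op in ops:
        kind = op[0]
        if kind == "snp":
            n = op[1]
            positions = rng.choice(np.arange(lo, hi), size=n, replace=False)
            for p in positions:
                old = s[p]
                choices = [b for b in "ACGT" if b != old]
                s[p] = choices[rng.integers(len(choices))]
        elif kind == "del":
            length = op[1]
            if length >= len(s):
                raise ValueError("deletion longer than sequence")
            p = int(rng.integers(lo, max(lo + 1, hi - length)))
            del s[p : p + length]
            hi = min(hi, len(s))
        elif kind == "ins":
            length = op[1]
            p = int(rng.integers(lo, hi))
            s[p:p] = list(_random_dna(rng, length))
            hi = min(hi + length, len(s))
        elif kind == "trna_ins":
            length = int(rng.integers(80, 101))
            p = int(rng.integers(lo, hi))
            s[p:p] = list(_random_dna(rng, length))
            hi = min(hi + length, len(s))
        else:
            raise ValueError(f"unknown edit op {kind!r}")
    return "".join(s)


def make_rrn_set(
    base_template: str,
    n_copies: int,
    edits_per_copy: Sequence | None,
    rng_seed,
    its_start: int | None = None,
) -> list[str]:
    """Derive ``n_copies`` rrn copies from a base template.

    Copy 0 is the base; each subsequent copy applies its entry of
    ``edits_per_copy``: an int (that many SNPs), a list of edit ops
    (``("snp", n)``, ``("del", len)``, ``("ins", len)``, ``("trna_ins",)``),
    or ``("dup", j)`` to duplicate an earlier copy exactly.  Edits land in
    the ITS portion when ``its_start`` is given (intragenomic rrn copies
    diverge mostly in the ITS), otherwise anywhere.
    """
    if n_copies < 1:
        raise ValueError("n_copies must be >= 1")
    rng = _rng(rng_seed)
    copies = [base_template]
    if n_copies == 1:
        return copies
    edits = list(edits_per_copy or [])
    if len(edits) != n_copies - 1:
        raise ValueError("edits_per_copy must have n_copies - 1 entries")
    region = (its_start, len(base_template)) if its_start is not None else (0, len(base_template))
    for spec in edits:
        if isinstance(spec, int):
            spec = [("snp", spec)]
        if isinstance(spec, tuple) and spec[0] == "dup":
            copies.append(copies[spec[1]])
            continue
        copies.append(_apply_edits(base_template, spec, rng, region))
    return copies


@dataclass
class ErrorModel:
    """Per-base Nanopore-like error process.

    Defaults give a 2% total error rate, indel-rich, with per-read rate
    jitter such that sub-read identity is ~98% with ~1% standard deviation.
    """

    mismatch_rate: float = 0.008
    ins_rate: float = 0.006
    del_rate: float = 0.006
    homopolymer_indel_multiplier: float = 1.0
    per_read_jitter: float = 0.5  # relative sd of the per-read rate scale

    @property
    def total_rate(self) -> float:
        return self.mismatch_rate + self.ins_rate + self.del_rate

    @classmethod
    def error_free(cls) -> "ErrorModel":
        return cls(0.0, 0.0, 0.0, 1.0, 0.0)


def _homopolymer_mask(arr: np.ndarray, min_run: int = 3) -> np.ndarray:
    if arr.size == 0:
        return np.zeros(0, dtype=bool)
    change = np.empty(arr.size, dtype=bool)
    change[0] = True
    change[1:] = arr[1:] != arr[:-1]
    group = np.cumsum(change) - 1
    lengths = np.bincount(group)
    return lengths[group] >= min_run


def apply_errors(seq: str, error: ErrorModel, rng_seed, return_map: bool = False):
    """Corrupt a sequence under the error model.

    With ``return_map`` also returns an array mapping each clean-sequence
    coordinate (0..n inclusive) to its coordinate on the corrupted read, so
    truth features stay addressable after indels shift positions.
    """
    rng = _rng(rng_seed)
    n = len(seq)
    if n == 0 or error.total_rate == 0.0:
        # still consume a jitter draw for stream stability
        if error.per_read_jitter:
            rng.normal(1.0, error.per_read_jitter)
        if return_map:
            return seq, np.arange(n + 1)
        return seq
    scale = 1.0
    if error.per_read_jitter:
        scale = max(0.05, rng.normal(1.0, error.per_read_jitter))
    arr = np.array(list(seq))
    hp = _homopolymer_mask(arr)
    mult = np.where(hp, error.homopolymer_indel_multiplier, 1.0)
    p_mm = np.full(n, error.mismatch_rate * scale)
    p_ins = error.ins_rate * scale * mult
    p_del = error.del_rate * scale * mult

    mm = rng.random(n) < p_mm
    dl = rng.random(n) < p_del
    ins = rng.random(n) < p_ins

    out = arr.astype(object)
    if mm.any():
        idx = np.where(mm)[0]
        base_idx = np.searchsorted(BASES, arr[idx])
        shift = rng.integers(1, 4, size=idx.size)
        valid = np.isin(arr[idx], BASES)
        new = arr[idx].copy()
        new[valid] = BASES[(base_idx[valid] + shift[valid]) % 4]
        out[idx] = new
    if dl.any():
        out[dl] = ""
    if ins.any():
        idx = np.where(ins)[0]
        extra = rng.choice(BASES, size=idx.size)
        out[idx] = out[idx] + extra
    result = "".join(out.tolist())
    if return_map:
        out_len = np.ones(n, dtype=int)
        out_len[dl] -= 1
        out_len[ins] += 1
        coord = np.zeros(n + 1, dtype=int)
        coord[1:] = np.cumsum(out_len)
        return result, coord
    return result


def simulate_concatemer_read(
    template: str,
    construct: ConstructModel,
    k_repeats: int,
    barcodes: tuple[str, str],
    error: ErrorModel,
    rng_seed,
    read_id: str = "read",
    orientation: str | None = None,
) -> tuple[SeqRecord, dict]:
    """One rolling-circle concatemer read plus its truth row.

    The linear product starts at the phi29 priming site adjacent to the
    splint, so an error-free read is ``splint + (unit + splint) * k``.
    ``orientation`` forces the sequenced strand ('+'/'-'); None draws it.
    """
    if k_repeats < 0:
        raise ValueError("k_repeats must be >= 0")
    rng = _rng(rng_seed)
    bc5, bc3 = barcodes
    unit = construct.unit(template, bc5, bc3)
    clean = construct.splint + (unit + construct.splint) * k_repeats
    period = len(unit) + len(construct.splint)
    noisy, coord = apply_errors(clean, error, rng, return_map=True)
    # splint coordinates on the corrupted (pre-strand-flip) read
    splint_starts = [int(coord[i * period]) for i in range(k_repeats + 1)]
    if orientation is None:
        orientation = "+" if rng.random() < 0.5 else "-"
    if orientation == "-":
        noisy = revcomp(noisy)
    rec = SeqRecord(read_id, noisy, qual=[20] * len(noisy))
    truth = {
        "read_id": read_id,
        "k": k_repeats,
        "bc5": bc5,
        "bc3": bc3,
        "orientation": orientation,
        "template_len": len(template),
        "splint_starts": splint_starts,
        "is_chimera": False,
        "breakpoint": -1,
    }
    return rec, truth


@dataclass
class TaxonSpec:
    taxon_id: str
    weight: float
    templates: list[str]

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValueError("abundance weight must be > 0")
        if not self.templates:
            raise ValueError("each taxon needs at least one rrn template")


@dataclass
class CommunitySpec:
    taxa: list[TaxonSpec]

    def __post_init__(self) -> None:
        if not self.taxa:
            raise ValueError("community spec is empty")

    def flattened(self) -> list[tuple[str, int, float]]:
        """(taxon_id, rrn_index, weight) per template copy; a taxon's
        sampling mass is its weight times its rrn copy number."""
        out = []
        for t in self.taxa:
            for i in range(len(t.templates)):
                out.append((t.taxon_id, i, t.weight))
        return out

    def template(self, taxon_id: str, rrn_index: int) -> str:
        for t in self.taxa:
            if t.taxon_id == taxon_id:
                return t.templates[rrn_index]
        raise KeyError(taxon_id)


def simulate_community_run(
    spec: CommunitySpec,
    n_reads: int,
    error: ErrorModel | None = None,
    chimera_rate: float = 0.0,
    k_p: float = 0.25,
    k_min: int = 1,
    rng_seed=0,
) -> tuple[list[SeqRecord], pd.DataFrame]:
    """Simulate a sequencing run over a community.

    Templates are sampled proportional to taxon weight x rrn copy number;
    repeat counts follow a shifted geometric ``k = k_min - 1 + Geom(k_p)``
    (short reads dominate, so most reads fail the >=5 sub-read filter);
    chimeric inserts are single-breakpoint crossovers between two sampled
    templates.  Deterministic for a fixed seed.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    rng = _rng(rng_seed)
    error = error if error is not None else ErrorModel()
    entries = spec.flattened()
    weights = np.array([w for _, _, w in entries], dtype=float)
    probs = weights / weights.sum()
    construct = ConstructModel()

    records: list[SeqRecord] = []
    rows: list[dict] = []
    for i in range(n_reads):
        read_id = f"sim{i:05d}"
        choice = int(rng.choice(len(entries), p=probs))
        taxon, rrn_idx, _ = entries[choice]
        template = spec.template(taxon, rrn_idx)
        is_chimera = bool(rng.random() < chimera_rate)
        breakpoint = -1
        taxon2, rrn2 = "", -1
        if is_chimera:
            other = int(rng.choice(len(entries), p=probs))
            while other == choice and len(entries) > 1:
                other = int(rng.choice(len(entries), p=probs))
            taxon2, rrn2, _ = entries[other]
            mate = spec.template(taxon2, rrn2)
            breakpoint = int(rng.integers(1, len(template)))
            frac = breakpoint / len(template)
            template = template[:breakpoint] + mate[int(frac * len(mate)):]
        k = int(k_min - 1 + rng.geometric(k_p))
        bc5 = _random_dna(rng, construct.barcode_len)
        bc3 = _random_dna(rng, construct.barcode_len)
        rec, truth = simulate_concatemer_read(
            template, construct, k, (bc5, bc3), error, rng, read_id=read_id
        )
        truth.update(
            taxon=taxon,
            rrn=rrn_idx,
            is_chimera=is_chimera,
            breakpoint=breakpoint,
            taxon2=taxon2,
            rrn2=rrn2,
        )
        records.append(rec)
        rows.append(truth)
    truth_df = pd.DataFrame(rows)
    return records, truth_df


# ---------------------------------------------------------------------------
# Synthetic stand-ins for reference rrn sets.
#
# These encode the documented *structure* of two well-characterized genomes
# (7 distinct rrn operons for an E. coli-like genome; 10 operons of which
# two are identical and a third differs from them by a 2-bp deletion for a
# B. subtilis-like genome) on top of synthetic template sequences.  They are
# synthetic fixtures, not the real genomic sequences.
# ---------------------------------------------------------------------------


def ecoli_like_rrn_set(rng_seed=7) -> list[str]:
    """Seven pairwise-distinct synthetic rrn templates for one genome.

    One copy carries a tRNA-sized ITS insertion (mirroring the natural
    presence/absence of ITS tRNA genes); the rest differ by small SNP and
    indel combinations, every pair at least two edits apart.
    """
    rng = _rng(rng_seed)
    base, its_start = make_template(rng)
    edits = [
        [("trna_ins",)],
        [("snp", 4)],
        [("snp", 4), ("ins", 6)],
        [("del", 12), ("snp", 2)],
        [("snp", 3), ("del", 3)],
        [("snp", 5)],
    ]
    return make_rrn_set(base, 7, edits, rng, its_start=its_start)


def bacillus_like_rrn_set(rng_seed=10) -> list[tuple[str, str]]:
    """Ten synthetic rrn operons (named A..J) with nine distinct sequences.

    Operons F and G are identical and operon I differs from them by only a
    two-base deletion; the remaining operons are pairwise distinct.
    """
    rng = _rng(rng_seed)
    base, its_start = make_template(rng)
    # copies: A=base, B..E distinct, F distinct, G=dup(F), H distinct,
    # I = F with a 2-bp deletion, J distinct.
    edits = [
        [("snp", 3)],                    # B
        [("snp", 2), ("ins", 4)],        # C
        [("trna_ins",)],                 # D
        [("snp", 4)],                    # E
        [("snp", 2), ("del", 5)],        # F
        ("dup", 5),                      # G == F
        [("snp", 3), ("ins", 3)],        # H
        [("snp", 6)],                    # J (placeholder slot, reordered below)
        [("snp", 2), ("snp", 2)],        # spare
    ]
    copies = make_rrn_set(base, 10, edits, rng, its_start=its_start)
    f_seq = copies[5]
    # I: remove two adjacent bases from F's ITS
    pos = its_start + 40
    i_seq = f_seq[:pos] + f_seq[pos + 2:]
    names = list("ABCDEFGHIJ")
    seqs = copies[:8] + [i_seq] + [copies[8]]
    return list(zip(names, seqs))
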