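"""Pipeline configuration: one dataclass per stage plus the construct model.

Every threshold of the pipeline lives here with its default, so a run is
fully described by a single :class:`PipelineConfig`, serializable to a flat
``key=value`` text file (section-prefixed keys, e.g. ``segment.min_sub_len``).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._align import revcomp

# RoC-ITS primer components (printed construct sequences).  The "unique"
# halves are assay-specific tails; the "anneal" halves target conserved rRNA
# sites (27F-derived forward, 189R-derived reverse, written 5'->3' on the
# primer).  Degenerate positions are resolved to a concrete base for
# simulation; pattern matching elsewhere uses IUPAC-aware motifs.
FWD_UNIQUE = "AATGATACGGCGACCACCGAGAT"
FWD_ANNEAL = "AGAGTTTGATCATGGCTCAG"          # 27F instance (M->A)
REV_UNIQUE = "ATGGAAGACGCCAAAAACATAAAGGCTGC"
REV_ANNEAL = "TACTTAGATGTTTCACTTC"           # 189R instance (D->T, S->C)

_SPLINT_LEN = 386
_SPLINT_SEED = 43861  # frozen; the splint is a documented fixture


def default_splint(length: int = _SPLINT_LEN, seed: int = _SPLINT_SEED) -> str:
    """Deterministic pseudo-random splint stand-in.

    The real splint is a 386-bp lambda-phage subsequence that is not part of
    this package; junction detection takes the splint as input either way,
    so a fixed random sequence of the right length serves as the default.
    """
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), size=length))


@dataclass
class ConstructModel:
    """Layout of one circularized repeat unit.

    On the sequenced strand each repeat reads::

        splint - fwd_unique - bc5 - fwd_anneal - insert core -
        rc(rev_anneal) - bc3 - rc(rev_unique) - splint ...

    where ``insert`` (the 16S-ITS product interior) already carries the
    annealing primer sites at its ends, and bc5/bc3 are 5-base random
    molecular barcodes identical across repeats of one molecule.
    """

    splint: str = field(default_factory=default_splint)
    fwd_unique: str = FWD_UNIQUE
    rev_unique: str = REV_UNIQUE
    fwd_anneal: str = FWD_ANNEAL
    rev_anneal: str = REV_ANNEAL
    barcode_len: int = 5

    def __post_init__(self) -> None:
        if self.barcode_len < 1:
            raise ValueError("barcode_len must be >= 1")
        if len(self.splint) < 50:
            raise ValueError("splint must be at least 50 bp")

    def unit(self, insert: str, bc5: str, bc3: str) -> str:
        """Assemble one repeat unit (without the flanking splints)."""
        return (
            self.fwd_unique + bc5 + insert + bc3 + revcomp(self.rev_unique)
        )


@dataclass
class SegmentConfig:
    min_sub_len: int = 1500
    max_sub_len: int = 3500
    junction_max_error: float = 0.35      # max edits / splint length
    junction_min_score: float = 0.0       # min fraction of splint aligned (reserved)
    barcode_consensus_cutoff: float = 0.6
    max_barcode_len: int = 5

    def __post_init__(self) -> None:
        if not self.min_sub_len < self.max_sub_len:
            raise ValueError("min_sub_len must be < max_sub_len")
        if not 0.5 < self.barcode_consensus_cutoff <= 1.0:
            raise ValueError("barcode_consensus_cutoff must be in (0.5, 1]")


@dataclass
class ConsensusConfig:
    min_final_subreads: int = 5
    outlier_score_fraction: float = 0.65
    stop_at_subreads: int = 3
    band_width: int = 64                  # reserved: edlib bands internally
    hi_conf_subreads: int = 15

    def __post_init__(self) -> None:
        if not self.stop_at_subreads < self.min_final_subreads:
            raise ValueError("stop_at_subreads must be < min_final_subreads")


@dataclass
class ClusterConfig:
    genus_identity: float = 0.95
    min_cluster_members: int = 5
    kmer_size: int = 12
    prefilter_min_shared_fraction: float = 0.3
    rescue_min_members: int | None = None
    prefilter_identity: float = 0.95
    v4_max_mismatch: int = 2

    def __post_init__(self) -> None:
        if not 0 < self.genus_identity <= 1:
            raise ValueError("genus_identity must be in (0, 1]")


@dataclass
class RefineConfig:
    dominant_fraction: float = 0.98
    minority_to_N_fraction: float = 0.02
    max_correction_fraction: float = 0.0005   # of the ungapped sequence length
    trim_nongap_fraction: float = 0.98
    correction_passes: int = 2
    realign_window_min_disagreement: float = 0.2
    repair_flank: int = 10

    def __post_init__(self) -> None:
        if not self.minority_to_N_fraction < self.dominant_fraction:
            raise ValueError("minority_to_N_fraction must be < dominant_fraction")
        if self.correction_passes < 2:
            raise ValueError("correction_passes must be >= 2")


def default_sweep() -> list[float]:
    return [round(x, 4) for x in np.arange(0.90, 0.9991, 0.005)]


@dataclass
class ResolveConfig:
    variable_majority_fraction: float = 0.95
    flank_columns: int = 4
    sweep_identities: list[float] = field(default_factory=default_sweep)
    min_cluster_input_fraction: float = 0.05
    rescue_min_members: int | None = None
    chimera_min_edits_saved: int = 4
    chimera_min_identity_gain: float = 0.015

    def __post_init__(self) -> None:
        if list(self.sweep_identities) != sorted(self.sweep_identities):
            raise ValueError("sweep_identities must be sorted ascending")


@dataclass
class PipelineConfig:
    construct: ConstructModel = field(default_factory=ConstructModel)
    segment: SegmentConfig = field(default_factory=SegmentConfig)
    consensus: ConsensusConfig = field(default_factory=ConsensusConfig)
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    refine: RefineConfig = field(default_factory=RefineConfig)
    resolve: ResolveConfig = field(default_factory=ResolveConfig)
    seed: int = 0

    def to_text(self) -> str:
        lines: list[str] = []
        for section, obj in self._sections():
            for f in dataclasses.fields(obj):
                value = getattr(obj, f.name)
                if isinstance(value, list):
                    value = ",".join(str(v) for v in value)
                lines.append(f"{section}.{f.name}={value}")
        lines.append(f"seed={self.seed}")
        return "\n".join(lines) + "\n"

    def _sections(self):
        return [
            ("construct", self.construct),
            ("segment", self.segment),
            ("consensus", self.consensus),
            ("cluster", self.cluster),
            ("refine", self.refine),
            ("resolve", self.resolve),
        ]

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_text())

    @classmethod
    def from_text(cls, text: str) -> "PipelineConfig":
        cfg = cls()
        sections = dict(cfg._sections())
        for lineno, raw in enumerate(text.splitlines(), 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"config line {lineno}: expected key=value")
            key, value = line.split("=", 1)
            key = key.strip()
            value = value.strip()
            if key == "seed":
                cfg.seed = int(value)
                continue
            if "." not in key:
                raise ValueError(f"config line {lineno}: unknown key {key!r}")
            section, name = key.split(".", 1)
            obj = sections.get(section)
            if obj is None or name not in {f.name for f in dataclasses.fields(obj)}:
                raise ValueError(f"config line {lineno}: unknown key {key!r}")
            current = getattr(obj, name)
            setattr(obj, name, _coerce(value, current))
        for _, obj in cfg._sections():
            if hasattr(obj, "__post_init__"):
                obj.__post_init__()
        return cfg

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_text(Path(path).read_text())


def _coerce(value: str, current):
    if isinstance(current, bool):
        return value.lower() in ("1", "true", "yes")
    if isinstance(current, int) and not isinstance(current, bool):
        return int(value)
    if isinstance(current, float):
        return float(value)
    if isinstance(current, list):
        return [float(v) for v in value.split(",") if v]
    if current is None:
        return None if value in ("None", "") else int(value)
    return value
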