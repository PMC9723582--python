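"""End-to-end glue: reads -> consensus sequences -> genus -> rrn clusters.

Thin orchestration over the stage modules, with StageLedger accounting, so
the command-line interface, the test-suite and scripted analyses all run
the identical pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .cluster import Cluster, extract_16s, filter_small_clusters, greedy_cluster
from .config import PipelineConfig
from .consensus import RocItsSequence, build_rocits_sequence
from .refine import build_genus_msa, correct_msa, trim_msa
from .resolve import RrnCall, extract_subsequences, sweep_cluster, variable_columns
from .segment import segment_read
from .seqio import Msa, SeqRecord, StageLedger


def reads_to_rocits(
    records: Iterable[SeqRecord],
    cfg: PipelineConfig | None = None,
    ledger: StageLedger | None = None,
) -> list[RocItsSequence]:
    """Segment every read, validate barcodes, and collapse to consensus
    sequences with at least the minimum final sub-read support."""
    cfg = cfg or PipelineConfig()
    records = list(records)
    if ledger is not None:
        ledger.open_stage("consensus", len(records))
    out: list[RocItsSequence] = []
    for rec in records:
        srs = segment_read(rec, cfg.construct, cfg.segment)
        if srs.discard_reason:
            if ledger is not None:
                ledger.discard("consensus", srs.discard_reason)
            continue
        rocits = build_rocits_sequence(srs, cfg.consensus)
        if rocits is None:
            if ledger is not None:
                ledger.discard("consensus", "too_few_subreads")
            continue
        if ledger is not None:
            ledger.retain("consensus")
        out.append(rocits)
    if ledger is not None:
        ledger.check()
    return out


def genus_clusters(
    rocits_seqs: list[RocItsSequence],
    cfg: PipelineConfig | None = None,
    ledger: StageLedger | None = None,
) -> tuple[list[Cluster], dict[str, str]]:
    """Extract 16S genes and greedily cluster them at the genus threshold;
    small clusters are excluded.  Returns (kept clusters, 16S by id)."""
    cfg = cfg or PipelineConfig()
    six_by_id: dict[str, str] = {}
    if ledger is not None:
        ledger.open_stage("genus", len(rocits_seqs))
    no_16s = 0
    for rs in rocits_seqs:
        s16 = extract_16s(rs)
        if s16 is None:
            no_16s += 1
            if ledger is not None:
                ledger.discard("genus", "no_16s")
            continue
        six_by_id[rs.id] = s16
    clusters = greedy_cluster(
        sorted(six_by_id.items()), cfg.cluster.genus_identity, cfg.cluster
    )
    kept, excluded = filter_small_clusters(
        clusters, min_members=cfg.cluster.min_cluster_members
    )
    if ledger is not None:
        ledger.discard("genus", "small_cluster", len(excluded))
        ledger.retain("genus", sum(c.size for c in kept))
        ledger.check()
    return kept, six_by_id


@dataclass
class GenusResolution:
    msa: Msa
    corrected: Msa
    trimmed: Msa
    excluded_ids: list[str]
    call: RrnCall


def resolve_genus(
    seqs: list[tuple[str, str]],
    cfg: PipelineConfig | None = None,
    genus: str = "genus",
    target_count: int | None = None,
) -> GenusResolution:
    """Align, correct, trim and resolve one genus into rrn clusters."""
    cfg = cfg or PipelineConfig()
    msa = build_genus_msa(seqs, cfg.refine)
    corrected, _report, excluded = correct_msa(msa, cfg.refine)
    trimmed, _left, _right = trim_msa(corrected, cfg.refine)
    cols = variable_columns(trimmed, cfg.resolve)
    full = {rid: trimmed.ungapped(rid) for rid in trimmed.row_ids}
    if not cols:
        call = RrnCall(
            genus=genus,
            identity_used=cfg.resolve.sweep_identities[0],
            clusters=[
                Cluster(
                    cluster_id=f"{genus}_rrn_00",
                    level="rrn",
                    identity_threshold=cfg.resolve.sweep_identities[0],
                    member_ids=list(trimmed.row_ids),
                    representative_id=trimmed.row_ids[0],
                )
            ],
            cluster_count_curve={i: 1 for i in cfg.resolve.sweep_identities},
        )
        return GenusResolution(msa, corrected, trimmed, excluded, call)
    subseqs = extract_subsequences(trimmed, cols, cfg.resolve)
    call = sweep_cluster(subseqs, full, cfg.resolve, genus=genus,
                         target_count=target_count)
    return GenusResolution(msa, corrected, trimmed, excluded, call)
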