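"""End-to-end orchestration of the targeted-alignment pipeline.

``run_targeted`` wires the stages together: build the junction libraries
(intragenic, readthrough, shifted control), align the reads, apply the
filter cascade, call events, and run the identical cascade against the
control junctions to estimate the false discovery rate.  A stage-attrition
log records the candidate count after every filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import event_caller, junction_aligner, junction_builder
from .event_caller import FdrEstimate, JunctionCluster, TicEvent
from .genome_model import GeneModel, catalog_splice_sites
from .junction_aligner import JunctionAlignment, JunctionIndex
from .junction_builder import JunctionTarget


@dataclass
class PipelineConfig:
    max_distance: int = 200_000
    flank: int = 80
    overhang_tic: int = 8
    overhang_intragenic: int = 11
    consistency_window: int = 11
    homology_fraction: float = 0.90
    homology_window: tuple[int, int] = (40, 50)
    exon_max: int = 300
    min_fusion_reads: int = 2
    anchor_min: int = 14
    seed_k: int = 12
    max_mismatches: int = 1
    strict_adjacency: bool = False


@dataclass
class TargetedResult:
    events: list[TicEvent]
    fdr: FdrEstimate
    attrition: dict[str, int]
    clusters: list[JunctionCluster]
    control_survivors: int
    rejections: dict[str, int] = field(default_factory=dict)


def _run_arm(
    reads,
    arm_index: JunctionIndex,
    intragenic_index: JunctionIndex | None,
    model: GeneModel,
    config: PipelineConfig,
    attrition: dict[str, int],
    prefix: str,
):
    """Alignment + filter cascade against one target library (real or
    control); returns the surviving clusters."""
    targets_by_id = {t.junction_id: t for t in arm_index.targets}
    read_seqs: dict[str, str] = {}
    alignments: list[JunctionAlignment] = []
    rejections: dict[str, int] = {}
    for read in reads:
        result = junction_aligner.align_read(
            read, arm_index, config.max_mismatches
        )
        if isinstance(result, JunctionAlignment):
            alignments.append(result)
            read_seqs[result.read_id] = read.sequence
        else:
            rejections[result.reason] = rejections.get(result.reason, 0) + 1
    attrition[f"{prefix}alignments"] = len(alignments)

    surviving = event_caller.filter_intragenic_equivalents(
        alignments, targets_by_id
    )
    attrition[f"{prefix}post_intragenic_equivalence"] = len(surviving)

    if intragenic_index is not None:
        surviving = [
            a
            for a in surviving
            if junction_aligner.prefer_intragenic(
                a, read_seqs[a.read_id], intragenic_index, config.max_mismatches
            )
        ]
    attrition[f"{prefix}post_intragenic_preference"] = len(surviving)

    surviving = [
        a
        for a in surviving
        if junction_aligner.supports_junction(a, config.overhang_tic)
    ]
    attrition[f"{prefix}post_overhang"] = len(surviving)

    clusters = event_caller.cluster_alignments(surviving, targets_by_id)
    attrition[f"{prefix}clusters"] = len(clusters)

    clusters = [
        c
        for c in clusters
        if event_caller.consistency_filter(c, config.consistency_window)[0]
    ]
    attrition[f"{prefix}post_consistency"] = len(clusters)

    kept = []
    for c in clusters:
        genes5 = sorted(c.target.donor.gene_ids)
        genes3 = sorted(c.target.acceptor.gene_ids)
        seqs5: dict[str, str] = {}
        seqs3: dict[str, str] = {}
        for g in genes5:
            seqs5.update(model.gene_sequences(g))
        for g in genes3:
            seqs3.update(model.gene_sequences(g))
        ok, _ = event_caller.homology_filter(
            seqs5,
            seqs3,
            fragment=c.junction_fragment(),
            fraction=config.homology_fraction,
            min_matches=config.homology_window[0],
            window=config.homology_window[1],
        )
        if ok:
            kept.append(c)
    attrition[f"{prefix}post_homology"] = len(kept)
    return kept, rejections


def run_targeted(
    model: GeneModel,
    reads,
    config: PipelineConfig | None = None,
) -> TargetedResult:
    """The full targeted-alignment analysis on a read collection.

    ``reads`` must be re-iterable (a list or similar): both the real and the
    control arm scan every read.
    """
    if config is None:
        config = PipelineConfig()
    donors, acceptors = catalog_splice_sites(model.transcripts)
    tic_targets = junction_builder.build_tic_targets(
        donors,
        acceptors,
        model,
        max_distance=config.max_distance,
        flank=config.flank,
        strict_adjacency=config.strict_adjacency,
    )
    intragenic_targets = junction_builder.build_intragenic_targets(
        model, flank=config.flank
    )
    control_targets, _ = junction_builder.build_control_targets(tic_targets)

    attrition = {
        "tic_targets": len(tic_targets),
        "intragenic_targets": len(intragenic_targets),
        "control_targets": len(control_targets),
    }
    tic_index = JunctionIndex(tic_targets, config.seed_k)
    intragenic_index = JunctionIndex(intragenic_targets, config.seed_k)

    clusters, rejections = _run_arm(
        reads, tic_index, intragenic_index, model, config, attrition, ""
    )
    events = event_caller.call_events(clusters)
    attrition["events"] = len(events)

    n_control = run_control_arm(
        reads, control_targets, intragenic_index, model, config, attrition
    )
    return TargetedResult(
        events=events,
        fdr=event_caller.estimate_fdr(n_control, len(events)),
        attrition=attrition,
        clusters=clusters,
        control_survivors=n_control,
        rejections=rejections,
    )


def run_coding(
    model: GeneModel,
    events: list[TicEvent],
    min_orf_codons: int = 30,
):
    """CDS/NMD classification for called readthrough events.

    For each event the representative donor/acceptor transcripts are taken
    from the junction's site labels (lexicographically smallest accession);
    returns per-event rows plus a frame-class percentage summary.
    """
    from . import chimera_coding
    from .genome_model import catalog_splice_sites

    donors, acceptors = catalog_splice_sites(model.transcripts)
    rows = []
    for e in events:
        _, chrom, strand, dpos, apos = e.junction_id.split("|")
        dsite = donors.get((chrom, strand, int(dpos), "donor"))
        asite = acceptors.get((chrom, strand, int(apos), "acceptor"))
        if dsite is None or asite is None:
            raise ValueError(
                f"event {e.gene5}>{e.gene3} references unknown splice sites"
            )
        dlab = min(sorted(dsite.labels, key=lambda l: l.accession))
        alab = min(sorted(asite.labels, key=lambda l: l.accession))
        t5 = model.by_accession[dlab.accession]
        t3 = model.by_accession[alab.accession]
        chim = chimera_coding.assemble_chimera(
            t5, dlab.exon_index, t3, alab.exon_index, model.genome
        )
        call = chimera_coding.predict_cds(
            chim, t5.cds, t3.cds, min_orf_codons=min_orf_codons
        )
        rows.append(
            {
                "gene5": e.gene5,
                "gene3": e.gene3,
                "donor_label": e.donor_label,
                "acceptor_label": e.acceptor_label,
                "start_class": call.start_class,
                "frame_class": call.frame_class,
                "termination_class": call.termination_class,
                "nmd_flag": call.nmd_flag,
                "protein_length": len(call.protein),
            }
        )
    summary: dict[str, float] = {}
    if rows:
        for cls in ("full_cds", "shift_3p", "new_tss"):
            n = sum(1 for r in rows if r["frame_class"] == cls)
            summary[cls] = round(100.0 * n / len(rows), 1)
    return rows, summary


def run_control_arm(
    reads,
    control_targets: list[JunctionTarget],
    intragenic_index: JunctionIndex | None,
    model: GeneModel,
    config: PipelineConfig,
    attrition: dict[str, int] | None = None,
) -> int:
    """The identical alignment and filtering cascade against the shifted
    control junctions; returns the surviving candidate count."""
    if not control_targets:
        return 0
    if attrition is None:
        attrition = {}
    control_index = JunctionIndex(control_targets, config.seed_k)
    clusters, _ = _run_arm(
        reads, control_index, intragenic_index, model, config, attrition, "control_"
    )
    return len(clusters)
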