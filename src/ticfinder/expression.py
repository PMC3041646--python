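"""Gene expression (RPKM), readthrough splice expression and efficiency.

RPKM = exon reads / (kilobases of merged exonic sequence x million total
reads).  A read counts toward every gene whose merged exons it overlaps
(configurable to fractional assignment).

Readthrough splice expression from RNA-Seq is a read-count proxy: the
number of junction-supporting reads, normalized per million and - for the
efficiency estimator - per available read start position, so that dividing
by the equally normalized 5' gene expression recovers the per-transcript
splice-through probability (efficiency) directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import math

from intervaltree import IntervalTree

from .genome_model import GeneModel

DEFAULT_MAX_DISTANCE = 200_000


@dataclass
class ExpressionRecord:
    gene_id: str
    sample_id: str
    exon_reads: int
    exon_kb: float
    total_reads: int

    @property
    def rpkm(self) -> float:
        return compute_rpkm(self.exon_reads, self.exon_kb, self.total_reads)


def compute_rpkm(exon_reads: int, exon_kb: float, total_reads: int) -> float:
    """Reads per kilobase of exon per million total reads."""
    if exon_kb <= 0:
        raise ValueError("exon length must be positive")
    if total_reads <= 0:
        raise ValueError("library size must be positive")
    return exon_reads / (exon_kb * total_reads / 1e6)


def merged_exon_intervals(model: GeneModel) -> dict[str, list[tuple[int, int]]]:
    """Merged exonic intervals per gene (union over isoforms)."""
    merged: dict[str, list[tuple[int, int]]] = {}
    for gene_id, txs in model.by_gene.items():
        ivs = sorted(iv for t in txs for iv in (tuple(sorted((s, e))) for s, e in t.exons))
        out: list[tuple[int, int]] = []
        for s, e in ivs:
            if out and s <= out[-1][1]:
                out[-1] = (out[-1][0], max(out[-1][1], e))
            else:
                out.append((s, e))
        merged[gene_id] = out
    return merged


class ExonCounter:
    """Count reads over merged gene exons from genomic alignment blocks."""

    def __init__(self, model: GeneModel):
        self.model = model
        self.merged = merged_exon_intervals(model)
        self.trees: dict[str, IntervalTree] = {}
        for gene_id, ivs in self.merged.items():
            chrom = model.by_gene[gene_id][0].chrom
            tree = self.trees.setdefault(chrom, IntervalTree())
            for s, e in ivs:
                tree.addi(s, e, gene_id)

    def exon_kb(self, gene_id: str) -> float:
        return sum(e - s for s, e in self.merged[gene_id]) / 1000.0

    def genes_overlapping(self, chrom: str, blocks) -> set[str]:
        tree = self.trees.get(chrom)
        if tree is None:
            return set()
        genes: set[str] = set()
        for start, end in blocks:
            for iv in tree.overlap(start, end):
                genes.add(iv.data)
        return genes

    def count(self, alignments) -> dict[tuple[str, str], int]:
        """``alignments``: iterable of (sample_id, chrom, blocks).  A read
        overlapping exons of two genes counts toward both."""
        counts: dict[tuple[str, str], int] = {}
        for sample_id, chrom, blocks in alignments:
            for gene in self.genes_overlapping(chrom, blocks):
                key = (gene, sample_id)
                counts[key] = counts.get(key, 0) + 1
        return counts


def expression_table(
    model: GeneModel,
    alignments,
    total_reads: dict[str, int],
) -> list[ExpressionRecord]:
    """Per-gene, per-sample expression records from genomic alignments."""
    counter = ExonCounter(model)
    counts = counter.count(alignments)
    records = []
    for sample_id, n_total in sorted(total_reads.items()):
        for gene_id in sorted(model.by_gene):
            records.append(
                ExpressionRecord(
                    gene_id=gene_id,
                    sample_id=sample_id,
                    exon_reads=counts.get((gene_id, sample_id), 0),
                    exon_kb=counter.exon_kb(gene_id),
                    total_reads=n_total,
                )
            )
    return records


def splicing_efficiency(
    tic_splice_expression: float, gene5_expression: float
) -> float | None:
    """Readthrough splice expression divided by 5' gene expression; NA when
    the 5' gene is unexpressed.  Spans orders of magnitude; report on a log
    scale (see :func:`log_efficiency`)."""
    if gene5_expression <= 0:
        return None
    return tic_splice_expression / gene5_expression


def log_efficiency(efficiency: float | None) -> float | None:
    if efficiency is None or efficiency <= 0:
        return None
    return math.log10(efficiency)


def estimate_splicing_efficiency(
    junction_reads: int,
    junction_positions: int,
    gene_reads: int,
    gene_positions: int,
) -> float | None:
    """Per-start-position efficiency estimate.

    ``junction_positions`` is the number of read placements that would
    support the junction (L - 2*overhang + 1 for reads of length L at
    overhang threshold k); ``gene_positions`` the number of read start
    positions on the 5' transcript (L_t - L + 1).  The normalization makes
    the ratio an unbiased estimate of the fraction of 5' transcripts that
    splice through into the chimera.
    """
    if junction_positions <= 0 or gene_positions <= 0:
        raise ValueError("position counts must be positive")
    return splicing_efficiency(
        junction_reads / junction_positions, gene_reads / gene_positions
    )


def genes_with_potential_partner(
    donors,
    acceptors,
    max_distance: int = DEFAULT_MAX_DISTANCE,
) -> tuple[set[str], set[str]]:
    """Genes with a potential readthrough partner within the window.

    Returns (genes with a qualifying downstream acceptor = potential 5'
    genes, genes with a qualifying upstream donor = potential 3' genes).
    """
    from .junction_builder import qualifies_as_tic_pair

    five: set[str] = set()
    three: set[str] = set()
    by_cs: dict[tuple[str, str], list] = {}
    for a in acceptors.values():
        by_cs.setdefault((a.chrom, a.strand), []).append(a)
    for d in donors.values():
        for a in by_cs.get((d.chrom, d.strand), []):
            if qualifies_as_tic_pair(d, a, max_distance):
                five |= d.gene_ids
                three |= a.gene_ids
    return five, three


def tic_conditioned_expression_report(
    events,
    records: list[ExpressionRecord],
    donors,
    acceptors,
    intragenic_spliced: dict[str, set[str]],
    max_distance: int = DEFAULT_MAX_DISTANCE,
):
    """Paired expression distributions for genes with vs without an observed
    readthrough, per sample and per side.

    Conditioning: a gene enters a sample's distributions only if it has at
    least one observed intragenic splice in that sample
    (``intragenic_spliced[sample]``) and a potential readthrough partner
    within ``max_distance``.  Returns a tidy DataFrame with columns
    (sample, side, group, gene, rpkm).
    """
    import pandas as pd

    five_pot, three_pot = genes_with_potential_partner(
        donors, acceptors, max_distance
    )
    with5: dict[str, set[str]] = {}
    with3: dict[str, set[str]] = {}
    for e in events:
        for s in e.samples:
            with5.setdefault(s, set()).add(e.gene5)
            with3.setdefault(s, set()).add(e.gene3)

    rows = []
    by_sample: dict[str, list[ExpressionRecord]] = {}
    for r in records:
        by_sample.setdefault(r.sample_id, []).append(r)
    for sample, recs in sorted(by_sample.items()):
        spliced = intragenic_spliced.get(sample, set())
        for r in recs:
            if r.gene_id not in spliced:
                continue
            for side, potential, observed in (
                ("5p", five_pot, with5.get(sample, set())),
                ("3p", three_pot, with3.get(sample, set())),
            ):
                if r.gene_id not in potential:
                    continue
                rows.append(
                    {
                        "sample": sample,
                        "side": side,
                        "group": "with_tic" if r.gene_id in observed else "without_tic",
                        "gene": r.gene_id,
                        "rpkm": r.rpkm,
                    }
                )
    return pd.DataFrame(rows, columns=["sample", "side", "group", "gene", "rpkm"])


def write_expression_tsv(records: list[ExpressionRecord], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tsample_id\texon_reads\texon_kb\ttotal_reads\trpkm\n")
        for r in records:
            fh.write(
                f"{r.gene_id}\t{r.sample_id}\t{r.exon_reads}\t"
                f"{r.exon_kb:.3f}\t{r.total_reads}\t{r.rpkm:.4f}\n"
            )
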