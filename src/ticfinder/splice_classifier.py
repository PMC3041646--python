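"""Taxonomy of split/spliced alignments and intervening-exon detection.

A split alignment carries two genomic segments in read order; the implied
donor site is the 3' end of the first segment and the acceptor site the 5'
end of the second.  Records are classified with a fixed decision order so
the six categories are mutually exclusive and exhaustive:

    different chromosomes            -> translocation
    opposite strands, one chromosome -> inversion
    acceptor upstream of donor       -> scrambled
    distance > 200,000 bp            -> long_range
    different genes                  -> readthrough
    otherwise                        -> intragenic

Intervening-exon candidates (a readthrough chimera that includes a short
novel exon between the two genes) are found by pairing, within a sample, a
known-donor/novel-acceptor splice with a novel-donor/known-acceptor splice
whose two novel sites delimit an interval of at most 300 bp on the same
strand, with the known sites on different coding genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from intervaltree import IntervalTree

from .genome_model import GeneModel, SpliceSite, exon_label
from .event_caller import homology_filter

DEFAULT_MAX_LOCAL = 200_000
DEFAULT_EXON_MAX = 300
MIN_ANCHOR = 14

CATEGORIES = (
    "intragenic",
    "readthrough",
    "long_range",
    "scrambled",
    "inversion",
    "translocation",
)


@dataclass
class Segment:
    chrom: str
    strand: str
    start: int
    end: int  # 0-based half-open

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SplitAlignmentRecord:
    read_id: str
    sample_id: str
    segment_a: Segment  # first segment in read order (donor side)
    segment_b: Segment  # second segment (acceptor side)
    site_a_known: bool | None = None
    site_b_known: bool | None = None

    def __post_init__(self) -> None:
        for seg in (self.segment_a, self.segment_b):
            if seg.length <= 0:
                raise ValueError(f"{self.read_id}: empty segment")

    @property
    def donor_pos(self) -> int:
        """Genomic boundary at the 3' end of segment A (strand-aware)."""
        return self.segment_a.end if self.segment_a.strand == "+" else self.segment_a.start

    @property
    def acceptor_pos(self) -> int:
        return self.segment_b.start if self.segment_b.strand == "+" else self.segment_b.end


@dataclass
class FusionCall:
    category: str
    donor_gene: str | None
    donor_exon_label: str | None
    acceptor_gene: str | None
    acceptor_exon_label: str | None
    distance: int | None  # NA iff translocation
    n_reads: int
    samples: set[str]
    key: tuple = ()


@dataclass
class TicieCandidate:
    gene5: str
    gene3: str
    upstream_splice: tuple[int, int]  # (known donor pos, novel acceptor pos)
    downstream_splice: tuple[int, int]  # (novel donor pos, known acceptor pos)
    intervening_exon: tuple[str, str, int, int]  # chrom, strand, start, end
    location_class: str
    samples: set[str]
    n_reads: int
    same_read_support: bool = False

    @property
    def exon_length(self) -> int:
        return self.intervening_exon[3] - self.intervening_exon[2]


class GeneLocator:
    """Assign genomic positions to genes via interval lookup per chrom+strand."""

    def __init__(self, model: GeneModel):
        self.model = model
        self.trees: dict[tuple[str, str], IntervalTree] = {}
        for gene_id in model.by_gene:
            chrom, strand, lo, hi = model.gene_span(gene_id)
            self.trees.setdefault((chrom, strand), IntervalTree()).addi(
                lo, hi, gene_id
            )

    def gene_at(self, chrom: str, strand: str, pos: int) -> str | None:
        tree = self.trees.get((chrom, strand))
        if tree is None:
            return None
        hits = sorted(iv.data for iv in tree.at(pos))
        return hits[0] if hits else None


def _upstream_of(strand: str, acceptor_pos: int, donor_pos: int) -> bool:
    """Is the acceptor upstream of the donor in transcription orientation?"""
    if strand == "+":
        return acceptor_pos < donor_pos
    return acceptor_pos > donor_pos


def classify_split(
    record: SplitAlignmentRecord,
    locator: GeneLocator | None = None,
    max_local: int = DEFAULT_MAX_LOCAL,
) -> FusionCall:
    """Classify one record; genes are annotated when a locator is given."""
    a, b = record.segment_a, record.segment_b
    donor_gene = acceptor_gene = None
    if locator is not None:
        donor_gene = locator.gene_at(a.chrom, a.strand, max(a.start, record.donor_pos - 1))
        acceptor_gene = locator.gene_at(b.chrom, b.strand, min(b.end - 1, record.acceptor_pos))

    if a.chrom != b.chrom:
        category, distance = "translocation", None
    elif a.strand != b.strand:
        category = "inversion"
        distance = abs(record.acceptor_pos - record.donor_pos)
    elif _upstream_of(a.strand, record.acceptor_pos, record.donor_pos):
        category = "scrambled"
        distance = abs(record.acceptor_pos - record.donor_pos)
    else:
        distance = abs(record.acceptor_pos - record.donor_pos)
        if distance > max_local:
            category = "long_range"
        elif (
            donor_gene is not None
            and acceptor_gene is not None
            and donor_gene == acceptor_gene
        ):
            category = "intragenic"
        else:
            category = "readthrough"

    return FusionCall(
        category=category,
        donor_gene=donor_gene,
        donor_exon_label=None,
        acceptor_gene=acceptor_gene,
        acceptor_exon_label=None,
        distance=distance,
        n_reads=1,
        samples={record.sample_id},
        key=(
            category,
            a.chrom,
            a.strand,
            record.donor_pos,
            b.chrom,
            b.strand,
            record.acceptor_pos,
        ),
    )


def classify_records(
    records,
    locator: GeneLocator | None = None,
    max_local: int = DEFAULT_MAX_LOCAL,
) -> list[FusionCall]:
    """Classify and aggregate records by (category, donor site, acceptor site)."""
    calls: dict[tuple, FusionCall] = {}
    for rec in records:
        call = classify_split(rec, locator, max_local)
        agg = calls.get(call.key)
        if agg is None:
            calls[call.key] = call
        else:
            agg.n_reads += 1
            agg.samples |= call.samples
    return sorted(calls.values(), key=lambda c: c.key)


def filter_multiread(
    calls: list[FusionCall], min_reads: int = 2
) -> list[FusionCall]:
    """Keep distant-fusion calls with multi-read support.

    Readthrough (and intragenic) calls pass through untouched: readthrough
    events are accepted on single-read evidence by the targeted pipeline,
    while distant fusions require multiple reads.
    """
    kept = []
    for c in calls:
        if c.category in ("readthrough", "intragenic"):
            kept.append(c)
        elif c.n_reads >= min_reads:
            kept.append(c)
    return kept


# ---------------------------------------------------------------------------
# Intervening exons (TICIE)


def annotate_known_sites(
    records: list[SplitAlignmentRecord],
    donors: dict[tuple, SpliceSite],
    acceptors: dict[tuple, SpliceSite],
) -> None:
    """Fill site_a_known/site_b_known by catalog membership."""
    for rec in records:
        a, b = rec.segment_a, rec.segment_b
        rec.site_a_known = (
            (a.chrom, a.strand, rec.donor_pos, "donor") in donors
        )
        rec.site_b_known = (
            (b.chrom, b.strand, rec.acceptor_pos, "acceptor") in acceptors
        )


def _interval_overlaps(lo1, hi1, lo2, hi2) -> bool:
    return lo1 < hi2 and lo2 < hi1


def _classify_location(
    model: GeneModel, gene5: str, gene3: str, chrom: str, lo: int, hi: int
) -> str:
    """Where does the intervening interval fall relative to the gene pair?"""
    last_exons_5 = [t.exons[-1] for t in model.by_gene[gene5]]
    first_exons_3 = [t.exons[0] for t in model.by_gene[gene3]]
    if any(_interval_overlaps(lo, hi, s, e) for s, e in last_exons_5):
        return "overlaps_5p_last_exon"
    if any(_interval_overlaps(lo, hi, s, e) for s, e in first_exons_3):
        return "overlaps_3p_first_exon"
    for gene in (gene5, gene3):
        for t in model.by_gene[gene]:
            if any(_interval_overlaps(lo, hi, s, e) for s, e in t.exons):
                return "internal_novel"
    return "intergenic"


def detect_ticie(
    records: list[SplitAlignmentRecord],
    model: GeneModel,
    locator: GeneLocator | None = None,
    exon_max: int = DEFAULT_EXON_MAX,
    max_local: int = DEFAULT_MAX_LOCAL,
    apply_homology: bool = True,
) -> list[TicieCandidate]:
    """Pair novel-site splices into intervening-exon candidates, per sample.

    Both flanking splices must span <= max_local; the two novel sites must
    delimit an interval <= exon_max on the same chrom/strand; the known
    sites must belong to different, coding genes.  Candidate gene pairs are
    passed through the gene-vs-gene homology filter.  Pairs may come from
    different reads within a sample; same-read support is flagged.
    """
    if locator is None:
        locator = GeneLocator(model)
    upstream: dict[str, list[SplitAlignmentRecord]] = {}
    downstream: dict[str, list[SplitAlignmentRecord]] = {}
    for rec in records:
        if rec.site_a_known is None or rec.site_b_known is None:
            raise ValueError(
                f"{rec.read_id}: known-site flags missing; call "
                "annotate_known_sites first"
            )
        a, b = rec.segment_a, rec.segment_b
        if a.chrom != b.chrom or a.strand != b.strand:
            continue
        if abs(rec.acceptor_pos - rec.donor_pos) > max_local:
            continue
        if rec.site_a_known and not rec.site_b_known:
            upstream.setdefault(rec.sample_id, []).append(rec)
        elif rec.site_b_known and not rec.site_a_known:
            downstream.setdefault(rec.sample_id, []).append(rec)

    found: dict[tuple, TicieCandidate] = {}
    for sample in sorted(set(upstream) & set(downstream)):
        for u in upstream[sample]:
            for d in downstream[sample]:
                cand = _pair_candidate(
                    u, d, model, locator, exon_max, sample
                )
                if cand is None:
                    continue
                key = (
                    cand.gene5,
                    cand.gene3,
                    cand.upstream_splice,
                    cand.downstream_splice,
                )
                agg = found.get(key)
                if agg is None:
                    found[key] = cand
                else:
                    agg.samples |= cand.samples
                    agg.n_reads += cand.n_reads
                    agg.same_read_support |= cand.same_read_support

    out = []
    for cand in found.values():
        if apply_homology:
            ok, _ = homology_filter(
                model.gene_sequences(cand.gene5),
                model.gene_sequences(cand.gene3),
                fragment=None,
            )
            if not ok:
                continue
        out.append(cand)
    return sorted(out, key=lambda c: (c.gene5, c.gene3, c.upstream_splice))


def _pair_candidate(
    u: SplitAlignmentRecord,
    d: SplitAlignmentRecord,
    model: GeneModel,
    locator: GeneLocator,
    exon_max: int,
    sample: str,
) -> TicieCandidate | None:
    a, b = u.segment_a, d.segment_b
    if a.chrom != b.chrom or a.strand != b.strand:
        return None
    strand = a.strand
    novel_acc = u.acceptor_pos  # 5' end of intervening exon
    novel_don = d.donor_pos  # 3' end of intervening exon
    lo, hi = min(novel_acc, novel_don), max(novel_acc, novel_don)
    if hi - lo == 0 or hi - lo > exon_max:
        return None
    # the exon runs acceptor -> donor in transcription orientation
    if strand == "+" and novel_don <= novel_acc:
        return None
    if strand == "-" and novel_don >= novel_acc:
        return None
    gene5 = locator.gene_at(a.chrom, strand, max(a.start, u.donor_pos - 1))
    gene3 = locator.gene_at(b.chrom, strand, min(b.end - 1, d.acceptor_pos))
    if gene5 is None or gene3 is None or gene5 == gene3:
        return None
    if not any(t.coding_flag for t in model.by_gene[gene5]):
        return None
    if not any(t.coding_flag for t in model.by_gene[gene3]):
        return None
    location = _classify_location(model, gene5, gene3, a.chrom, lo, hi)
    return TicieCandidate(
        gene5=gene5,
        gene3=gene3,
        upstream_splice=(u.donor_pos, novel_acc),
        downstream_splice=(novel_don, d.acceptor_pos),
        intervening_exon=(a.chrom, strand, lo, hi),
        location_class=location,
        samples={sample},
        n_reads=2 if u.read_id != d.read_id else 1,
        same_read_support=u.read_id == d.read_id,
    )


# ---------------------------------------------------------------------------
# I/O


def read_split_records_tsv(path: str) -> list[SplitAlignmentRecord]:
    """Canonical 10-column TSV: read, sample, chromA, strandA, startA, endA,
    chromB, strandB, startB, endB."""
    records = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("read_id\t"):
                continue
            f = line.split("\t")
            if len(f) < 10:
                raise ValueError(f"split record has {len(f)} columns: {line!r}")
            records.append(
                SplitAlignmentRecord(
                    read_id=f[0],
                    sample_id=f[1],
                    segment_a=Segment(f[2], f[3], int(f[4]), int(f[5])),
                    segment_b=Segment(f[6], f[7], int(f[8]), int(f[9])),
                )
            )
    return records


def read_split_records_sam(path: str, sample_id: str = "S1"):
    """Extract split records from SAM alignments with an N CIGAR operation,
    splitting each read at its largest intron gap."""
    import pysam

    records = []
    with pysam.AlignmentFile(path, "r") as sam:
        for aln in sam:
            if aln.is_unmapped or aln.cigartuples is None:
                continue
            gaps = [
                (length, i)
                for i, (op, length) in enumerate(aln.cigartuples)
                if op == 3  # N
            ]
            if not gaps:
                continue
            _, split_at = max(gaps)
            strand = "-" if aln.is_reverse else "+"
            ref = aln.reference_name
            pos = aln.reference_start
            blocks_a, blocks_b = [], []
            for i, (op, length) in enumerate(aln.cigartuples):
                if op in (0, 7, 8, 2):  # M/=/X/D consume reference
                    (blocks_a if i < split_at else blocks_b).append(
                        (pos, pos + length)
                    )
                    pos += length
                elif op == 3:
                    pos += length
            if not blocks_a or not blocks_b:
                continue
            records.append(
                SplitAlignmentRecord(
                    read_id=aln.query_name,
                    sample_id=sample_id,
                    segment_a=Segment(ref, strand, blocks_a[0][0], blocks_a[-1][1]),
                    segment_b=Segment(ref, strand, blocks_b[0][0], blocks_b[-1][1]),
                )
            )
    return records


def write_fusion_calls_tsv(calls: list[FusionCall], path: str) -> None:
    with open(path, "w") as fh:
        fh.write(
            "category\tdonor_gene\tacceptor_gene\tdistance\tn_reads\tsamples\n"
        )
        for c in calls:
            fh.write(
                f"{c.category}\t{c.donor_gene or 'NA'}\t"
                f"{c.acceptor_gene or 'NA'}\t"
                f"{'NA' if c.distance is None else c.distance}\t"
                f"{c.n_reads}\t{','.join(sorted(c.samples))}\n"
            )
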