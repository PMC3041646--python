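"""Gene/transcript model and splice-site catalogs.

Readthrough-fusion detection starts from an annotated gene model: every
internal exon boundary of a multi-exon transcript defines a donor (5' end of
an intron) or acceptor (3' end of an intron) splice site.  Sites shared by
several isoforms are deduplicated and labeled with the exons of *all*
transcripts containing them, because a single genomic site may be "e4/5" in
one isoform and "e4/6" in another.

Coordinates are 0-based half-open internally.  A splice-site position is the
boundary coordinate between the exonic and the intronic base, so on the plus
strand a donor sits at ``exon.end`` and an acceptor at ``exon.start``; on the
minus strand the roles of the two boundaries swap.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import reverse_complement

VALID_BASES = set("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _clean_sequence(seq: str) -> str:
    """Uppercase and map anything outside {A,C,G,T,N} to N."""
    seq = seq.upper()
    if set(seq) <= VALID_BASES:
        return seq
    return "".join(c if c in VALID_BASES else "N" for c in seq)


def load_genome(path: str) -> dict[str, str]:
    """Load a multi-record FASTA into a ``{chrom: sequence}`` dict.

    Names are the first whitespace-delimited token of each header; sequences
    are uppercased with non-ACGTN characters mapped to N.  Duplicate names
    and empty files are hard errors.
    """
    genome: dict[str, str] = {}
    for record in SeqIO.parse(path, "fasta"):
        name = record.id
        if name in genome:
            raise ValueError(f"duplicate chromosome name in FASTA: {name!r}")
        genome[name] = _clean_sequence(str(record.seq))
    if not genome:
        raise ValueError(f"no FASTA records found in {path!r}")
    return genome


def fetch(genome: dict[str, str], chrom: str, start: int, end: int) -> str:
    seq = genome[chrom]
    if start < 0 or end > len(seq) or start > end:
        raise IndexError(
            f"requested {chrom}:{start}-{end} outside [0, {len(seq)})"
        )
    return seq[start:end]


@dataclass
class Transcript:
    """A transcript with exons in transcription order.

    ``exons`` are genomic 0-based half-open intervals ordered 5'->3' along the
    transcript: ascending genomic starts on '+', strictly descending on '-'.
    ``cds`` is an optional (start, end) in *transcript* coordinates.
    """

    accession: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds: tuple[int, int] | None = None
    coding_flag: bool = False

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        for start, end in self.exons:
            if start >= end:
                raise ValueError(
                    f"{self.accession}: empty/inverted exon {start}-{end}"
                )
        starts = [e[0] for e in self.exons]
        if self.strand == "+":
            ok = all(a[1] < b[0] for a, b in zip(self.exons, self.exons[1:]))
        else:
            ok = all(b[1] < a[0] for a, b in zip(self.exons, self.exons[1:]))
        if not ok:
            raise ValueError(
                f"{self.accession}: exons overlap or are out of "
                f"transcription order on strand {self.strand}: {starts}"
            )

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    @property
    def length(self) -> int:
        return sum(end - start for start, end in self.exons)

    @property
    def genomic_span(self) -> tuple[int, int]:
        return (
            min(s for s, _ in self.exons),
            max(e for _, e in self.exons),
        )

    def sequence(self, genome: dict[str, str]) -> str:
        parts = []
        for start, end in self.exons:
            s = fetch(genome, self.chrom, start, end)
            parts.append(s if self.strand == "+" else reverse_complement(s))
        return "".join(parts)

    def exon_offsets(self) -> list[int]:
        """Transcript coordinate at which each exon begins."""
        offs, pos = [], 0
        for start, end in self.exons:
            offs.append(pos)
            pos += end - start
        return offs

    def project(self, tx_start: int, tx_end: int) -> list[tuple[int, int]]:
        """Map a transcript interval onto genomic blocks (strand-aware)."""
        if not (0 <= tx_start <= tx_end <= self.length):
            raise IndexError(
                f"{self.accession}: transcript interval {tx_start}-{tx_end} "
                f"outside [0, {self.length}]"
            )
        blocks, pos = [], 0
        for start, end in self.exons:
            elen = end - start
            lo, hi = max(tx_start, pos), min(tx_end, pos + elen)
            if lo < hi:
                if self.strand == "+":
                    blocks.append((start + (lo - pos), start + (hi - pos)))
                else:
                    blocks.append((end - (hi - pos), end - (lo - pos)))
            pos += elen
        return blocks


@dataclass
class GeneModel:
    """Transcript collection grouped by gene, plus the genome it annotates."""

    transcripts: list[Transcript]
    genome: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.by_gene: dict[str, list[Transcript]] = {}
        self.by_accession: dict[str, Transcript] = {}
        for t in self.transcripts:
            self.by_gene.setdefault(t.gene_id, []).append(t)
            self.by_accession[t.accession] = t

    def gene_span(self, gene_id: str) -> tuple[str, str, int, int]:
        txs = self.by_gene[gene_id]
        return (
            txs[0].chrom,
            txs[0].strand,
            min(t.genomic_span[0] for t in txs),
            max(t.genomic_span[1] for t in txs),
        )

    def gene_sequences(self, gene_id: str) -> dict[str, str]:
        return {
            t.accession: t.sequence(self.genome) for t in self.by_gene[gene_id]
        }


@dataclass(frozen=True)
class SpliceLabel:
    accession: str
    exon_index: int  # 1-based, transcription order
    exon_count: int


@dataclass
class SpliceSite:
    chrom: str
    strand: str
    pos: int  # boundary between exonic and intronic base
    kind: str  # "donor" | "acceptor"
    labels: set[SpliceLabel] = field(default_factory=set)
    gene_ids: set[str] = field(default_factory=set)

    @property
    def key(self) -> tuple[str, str, int, str]:
        return (self.chrom, self.strand, self.pos, self.kind)

    @property
    def accessions(self) -> set[str]:
        return {lab.accession for lab in self.labels}

    def intron_dinucleotide(self, genome: dict[str, str]) -> str:
        """The 2 genomic bases immediately intronic of the site (stranded)."""
        if self.kind == "donor":
            if self.strand == "+":
                return fetch(genome, self.chrom, self.pos, self.pos + 2)
            return reverse_complement(
                fetch(genome, self.chrom, self.pos - 2, self.pos)
            )
        if self.strand == "+":
            return fetch(genome, self.chrom, self.pos - 2, self.pos)
        return reverse_complement(
            fetch(genome, self.chrom, self.pos, self.pos + 2)
        )


def exon_label(exon_index: int, exon_count: int) -> str:
    """Render the field's exon notation, e.g. (4, 5) -> "e4/5"."""
    if not 1 <= exon_index <= exon_count:
        raise ValueError(
            f"exon index {exon_index} out of range 1..{exon_count}"
        )
    return f"e{exon_index}/{exon_count}"


def donor_boundary(t: Transcript, exon_index: int) -> int:
    """Genomic boundary coordinate of the donor at the 3' end of exon i."""
    start, end = t.exons[exon_index - 1]
    return end if t.strand == "+" else start


def acceptor_boundary(t: Transcript, exon_index: int) -> int:
    """Genomic boundary coordinate of the acceptor at the 5' end of exon i."""
    start, end = t.exons[exon_index - 1]
    return start if t.strand == "+" else end


def catalog_splice_sites(
    transcripts: list[Transcript],
) -> tuple[dict[tuple, SpliceSite], dict[tuple, SpliceSite]]:
    """Build deduplicated donor and acceptor catalogs.

    One donor per internal exon 3' boundary and one acceptor per internal
    exon 5' boundary, keyed by (chrom, strand, pos, kind), with labels and
    gene ids merged over all transcripts sharing a site.  Terminal exon
    boundaries (transcript start/end) are not splice sites, so single-exon
    transcripts contribute nothing.
    """
    donors: dict[tuple, SpliceSite] = {}
    acceptors: dict[tuple, SpliceSite] = {}

    def add(catalog: dict, chrom, strand, pos, kind, label, gene_id) -> None:
        key = (chrom, strand, pos, kind)
        site = catalog.get(key)
        if site is None:
            site = SpliceSite(chrom, strand, pos, kind)
            catalog[key] = site
        site.labels.add(label)
        site.gene_ids.add(gene_id)

    for t in transcripts:
        n = t.exon_count
        for i in range(1, n + 1):
            if i < n:  # internal 3' boundary -> donor
                add(
                    donors, t.chrom, t.strand, donor_boundary(t, i),
                    "donor", SpliceLabel(t.accession, i, n), t.gene_id,
                )
            if i > 1:  # internal 5' boundary -> acceptor
                add(
                    acceptors, t.chrom, t.strand, acceptor_boundary(t, i),
                    "acceptor", SpliceLabel(t.accession, i, n), t.gene_id,
                )
    return donors, acceptors


# ---------------------------------------------------------------------------
# Annotation readers


def _detect_format(path: str, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    ext = os.path.splitext(path)[1].lower()
    if ext in (".gtf",):
        return "gtf"
    if ext in (".gff", ".gff3"):
        return "gff3"
    if ext in (".bed", ".bed12"):
        return "bed12"
    raise ValueError(f"cannot detect annotation dialect from {path!r}")


def _check_bounds(t: Transcript, genome: dict[str, str]) -> None:
    if t.chrom not in genome:
        raise ValueError(f"{t.accession}: chromosome {t.chrom!r} not in genome")
    clen = len(genome[t.chrom])
    for start, end in t.exons:
        if start < 0 or end > clen:
            raise ValueError(
                f"{t.accession}: exon {start}-{end} outside {t.chrom} "
                f"[0, {clen})"
            )


def _orient(exons: list[tuple[int, int]], strand: str) -> list[tuple[int, int]]:
    exons = sorted(exons)
    return exons if strand == "+" else exons[::-1]


def _tx_coord(exons_tx_order, strand, genomic_pos) -> int:
    """Transcript coordinate of a genomic position that lies in an exon."""
    off = 0
    for start, end in exons_tx_order:
        if start <= genomic_pos <= end:
            return off + (
                genomic_pos - start if strand == "+" else end - genomic_pos
            )
        off += end - start
    raise ValueError(f"genomic position {genomic_pos} not exonic")


def _cds_from_genomic(exons_tx_order, strand, cds_lo, cds_hi):
    """Map a genomic CDS span onto transcript coordinates."""
    if strand == "+":
        a = _tx_coord(exons_tx_order, strand, cds_lo)
        b = _tx_coord(exons_tx_order, strand, cds_hi)
    else:
        a = _tx_coord(exons_tx_order, strand, cds_hi)
        b = _tx_coord(exons_tx_order, strand, cds_lo)
    return (a, b)


def load_transcripts(
    path: str,
    genome: dict[str, str],
    fmt: str | None = None,
    coding_attribute: str | None = None,
) -> GeneModel:
    """Load transcripts from GTF, GFF3 or BED12 into a :class:`GeneModel`.

    ``coding_flag`` is set from the accession prefix ("NM_") unless
    ``coding_attribute`` names a GTF/GFF attribute to use instead.
    """
    kind = _detect_format(path, fmt)
    if kind == "bed12":
        transcripts = _read_bed12(path)
    else:
        transcripts = _read_gxf(path, kind, coding_attribute)
    for t in transcripts:
        _check_bounds(t, genome)
    return GeneModel(transcripts, genome)


def _read_gxf(path: str, dialect: str, coding_attribute: str | None):
    import gffutils

    db = gffutils.create_db(
        path,
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    exons_by_tx: dict[str, list] = {}
    cds_by_tx: dict[str, list] = {}
    meta: dict[str, dict] = {}
    for feat in db.all_features():
        ftype = feat.featuretype.lower()
        if ftype not in ("exon", "cds"):
            continue
        if dialect == "gtf":
            tx_ids = feat.attributes.get("transcript_id", [])
            gene_ids = feat.attributes.get("gene_id", ["NA"])
        else:
            tx_ids = feat.attributes.get("Parent", [])
            gene_ids = feat.attributes.get("gene_id", ["NA"])
        for tx_id in tx_ids:
            info = meta.setdefault(
                tx_id,
                {
                    "chrom": feat.seqid,
                    "strand": feat.strand,
                    "gene_id": gene_ids[0],
                    "coding_attr": None,
                },
            )
            if info["chrom"] != feat.seqid:
                raise ValueError(f"{tx_id}: features span two chromosomes")
            if coding_attribute and coding_attribute in feat.attributes:
                info["coding_attr"] = feat.attributes[coding_attribute][0]
            target = exons_by_tx if ftype == "exon" else cds_by_tx
            target.setdefault(tx_id, []).append((feat.start - 1, feat.end))

    transcripts = []
    for tx_id, exons in sorted(exons_by_tx.items()):
        info = meta[tx_id]
        exons_tx = _orient(exons, info["strand"])
        cds = None
        if tx_id in cds_by_tx:
            spans = cds_by_tx[tx_id]
            cds = _cds_from_genomic(
                exons_tx,
                info["strand"],
                min(s for s, _ in spans),
                max(e for _, e in spans),
            )
        if info["coding_attr"] is not None:
            coding = info["coding_attr"].lower() in ("true", "1", "yes", "nm")
        else:
            coding = tx_id.startswith("NM_")
        transcripts.append(
            Transcript(
                accession=tx_id,
                gene_id=info["gene_id"],
                chrom=info["chrom"],
                strand=info["strand"],
                exons=exons_tx,
                cds=cds,
                coding_flag=coding,
            )
        )
    return transcripts


def _read_bed12(path: str) -> list[Transcript]:
    transcripts = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"BED12 line has {len(f)} columns: {line!r}")
            chrom, chrom_start, name = f[0], int(f[1]), f[3]
            strand = f[5]
            thick_start, thick_end = int(f[6]), int(f[7])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = [
                (chrom_start + st, chrom_start + st + sz)
                for st, sz in zip(starts, sizes)
            ]
            exons_tx = _orient(exons, strand)
            if ":" in name:
                gene_id, accession = name.split(":", 1)
            else:
                gene_id, accession = name, name
            cds = None
            if thick_end > thick_start:
                cds = _cds_from_genomic(exons_tx, strand, thick_start, thick_end)
            transcripts.append(
                Transcript(
                    accession=accession,
                    gene_id=gene_id,
                    chrom=chrom,
                    strand=strand,
                    exons=exons_tx,
                    cds=cds,
                    coding_flag=accession.startswith("NM_"),
                )
            )
    return transcripts


def write_gtf(model: GeneModel, path: str) -> None:
    """Write exon and CDS features with gene_id/transcript_id attributes."""
    with open(path, "w") as fh:
        for t in model.transcripts:
            attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.accession}";'
            for start, end in sorted(t.exons):
                fh.write(
                    f"{t.chrom}\tticfinder\texon\t{start + 1}\t{end}\t.\t"
                    f"{t.strand}\t.\t{attrs}\n"
                )
            if t.cds is not None:
                for start, end in sorted(t.project(*t.cds)):
                    fh.write(
                        f"{t.chrom}\tticfinder\tCDS\t{start + 1}\t{end}\t.\t"
                        f"{t.strand}\t0\t{attrs}\n"
                    )


def write_bed12(model: GeneModel, path: str) -> None:
    with open(path, "w") as fh:
        for t in model.transcripts:
            exons = sorted(t.exons)
            chrom_start, chrom_end = exons[0][0], exons[-1][1]
            if t.cds is not None:
                blocks = sorted(t.project(*t.cds))
                thick_start, thick_end = blocks[0][0], blocks[-1][1]
            else:
                thick_start = thick_end = chrom_start
            sizes = ",".join(str(e - s) for s, e in exons)
            starts = ",".join(str(s - chrom_start) for s, _ in exons)
            fh.write(
                f"{t.chrom}\t{chrom_start}\t{chrom_end}\t"
                f"{t.gene_id}:{t.accession}\t0\t{t.strand}\t"
                f"{thick_start}\t{thick_end}\t0\t{len(exons)}\t"
                f"{sizes},\t{starts},\n"
            )
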