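"""Seeded synthetic genomes, annotations, planted chimeras and reads.

The generator builds a toy genome whose genes have controlled coding
structure (an ATG, a stop-free codon body, and a stop codon inside the last
exon), canonical GT/AG motifs at all annotated introns, exponential
intergenic distances, and then plants chimeric transcripts:

* readthrough (TIC) events between adjacent same-strand genes, drawing the
  donor/acceptor exon pattern so the (n-1)->+2 geometry dominates (54% by
  default) and a configurable fraction of gene pairs carries a second
  isoform sharing one splice site;
* intervening-exon (TICIE) events with a novel exon of <= 300 bp planted in
  the intergenic gap;
* one distant fusion per requested category (long_range, scrambled,
  inversion, translocation), using gene pairs with the right geometry;
* decoy paralog pairs: a gene duplicated at ~92% identity with a planted
  decoy chimera, so paralog-junction reads deterministically reach - and
  must be rejected by - the homology filter.

Reads are sampled uniformly along transcripts with i.i.d. substitution
errors (default 1%), with read counts multinomial over expression x number
of start positions, so a transcript's read count is proportional to its
molar abundance times its insert capacity.  Chimera abundance is
``epsilon x 5'-gene abundance`` - the leakage model of readthrough
transcription.  Every emitted read is recorded in a provenance table;
junction-spanning reads with >= 14 nt on both sides of a splice are also
emitted as split-alignment records, emulating what a spliced aligner could
detect.

All randomness flows from ``numpy.random.default_rng`` streams derived from
the single config seed, so outputs are byte-identical across runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .genome_model import GeneModel, Transcript, exon_label
from .junction_aligner import ShortRead
from .splice_classifier import Segment, SplitAlignmentRecord

BASES = np.frombuffer(b"ACGT", dtype="S1")
STOPS = {"TAA", "TAG", "TGA"}
NONSTOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOPS
]


@dataclass
class SimulationConfig:
    seed: int = 0
    n_chroms: int = 2
    n_genes: int = 20
    exons_per_gene: tuple[int, int] = (3, 6)
    exon_len: tuple[int, int] = (90, 200)
    intron_len: tuple[int, int] = (200, 1200)
    intergenic_mean: float = 4000.0  # exponential tail above the minimum
    intergenic_min: int = 300
    utr_len: tuple[int, int] = (15, 45)
    read_length: int = 50
    error_rate: float = 0.01
    total_reads: int = 20_000
    expression_sigma: float = 1.0  # log-normal abundances
    expression_overrides: dict[str, float] = field(default_factory=dict)
    sample_id: str = "S1"
    anchor_min: int = 14
    # planted events
    n_tic: int = 0
    tic_epsilon: float | list[float] = 0.05
    # (n-1)->+2, other-donor->+2, (n-1)->other-acceptor, both-other
    pattern_weights: tuple[float, float, float, float] = (0.54, 0.25, 0.10, 0.11)
    tic_isoform_fraction: float = 0.11
    n_ticie: int = 0
    ticie_exon_len: tuple[int, int] = (60, 300)
    ticie_epsilon: float = 0.05
    fusion_categories: tuple[str, ...] = ()
    fusion_epsilon: float = 0.2
    n_decoy_pairs: int = 0
    decoy_identity: float = 0.92
    decoy_epsilon: float = 0.05
    long_gap: int = 250_000

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stage])


@dataclass
class PlantedEvent:
    kind: str  # tic | ticie | decoy | long_range | scrambled | inversion | translocation
    gene5: str
    gene3: str
    donor_exon: int
    acceptor_exon: int
    donor_label: str
    acceptor_label: str
    donor_pos: int
    acceptor_pos: int
    chimera_name: str
    epsilon: float
    pattern_flag: bool
    intervening_exon: tuple[str, str, int, int] | None = None


@dataclass
class SimTranscript:
    """A read source: a gene transcript or a planted chimera.

    ``segments`` are (chrom, strand, start, end) genomic intervals in
    transcription order; ``junctions`` are the transcript coordinates of
    chimeric splices (empty for ordinary gene transcripts).
    """

    name: str
    segments: list[tuple[str, str, int, int]]
    sequence: str
    kind: str = "gene"
    gene_id: str | None = None
    junctions: list[int] = field(default_factory=list)
    expression: float = 0.0

    @property
    def length(self) -> int:
        return len(self.sequence)

    def n_start_positions(self, read_length: int) -> int:
        return max(self.length - read_length + 1, 1)

    def project(self, tx_start: int, tx_end: int):
        """Genomic blocks of a transcript interval, with segment indices."""
        blocks, pos = [], 0
        for idx, (chrom, strand, start, end) in enumerate(self.segments):
            elen = end - start
            lo, hi = max(tx_start, pos), min(tx_end, pos + elen)
            if lo < hi:
                if strand == "+":
                    g = (start + (lo - pos), start + (hi - pos))
                else:
                    g = (end - (hi - pos), end - (lo - pos))
                blocks.append((idx, chrom, strand, g[0], g[1]))
            pos += elen
        return blocks


@dataclass
class SyntheticTruth:
    events: list[PlantedEvent] = field(default_factory=list)
    expression: dict[str, float] = field(default_factory=dict)
    # provenance: filled by simulate_reads (parallel arrays)
    read_source: np.ndarray | None = None  # transcript index per read
    read_start: np.ndarray | None = None
    source_names: list[str] = field(default_factory=list)

    def provenance(self, read_index: int) -> tuple[str, int]:
        return (
            self.source_names[int(self.read_source[read_index])],
            int(self.read_start[read_index]),
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "events": [asdict(e) for e in self.events],
                "expression": self.expression,
            },
            indent=1,
            default=list,
        )


@dataclass
class SimulatedData:
    config: SimulationConfig
    genome: dict[str, str]
    model: GeneModel
    transcripts: list[SimTranscript]  # gene transcripts then chimeras
    truth: SyntheticTruth
    decoy_pairs: list[tuple[str, str]] = field(default_factory=list)
    long_pair: tuple[str, str] | None = None

    @property
    def chimeras(self) -> list[SimTranscript]:
        return [t for t in self.transcripts if t.kind != "gene"]

    def by_name(self, name: str) -> SimTranscript:
        for t in self.transcripts:
            if t.name == name:
                return t
        raise KeyError(name)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(BASES, size=n).tobytes().decode()


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        current = arr[i]
        choices = BASES[BASES != current]
        arr[i] = choices[rng.integers(0, len(choices))]
    return arr.tobytes().decode()


@dataclass
class _GenePlan:
    gene_id: str
    accession: str
    exon_lens: list[int]
    intron_lens: list[int]
    pre_mrna: str  # transcript orientation
    cds: tuple[int, int]  # transcript coords

    @property
    def block_len(self) -> int:
        return sum(self.exon_lens) + sum(self.intron_lens)


def _plan_gene(rng: np.random.Generator, cfg: SimulationConfig, idx: int) -> _GenePlan:
    n_exons = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
    exon_lens = [
        int(rng.integers(cfg.exon_len[0], cfg.exon_len[1] + 1))
        for _ in range(n_exons)
    ]
    intron_lens = [
        int(rng.integers(cfg.intron_len[0], cfg.intron_len[1] + 1))
        for _ in range(n_exons - 1)
    ]
    total = sum(exon_lens)
    utr5 = int(rng.integers(cfg.utr_len[0], cfg.utr_len[1] + 1))
    # stop codon inside the last exon, a little before the transcript end
    last_start = total - exon_lens[-1]
    utr3_max = min(cfg.utr_len[1], total - last_start - 4)
    utr3 = int(rng.integers(cfg.utr_len[0], max(cfg.utr_len[0], utr3_max) + 1))
    utr3 = min(utr3, utr3_max)
    cds_len = total - utr5 - utr3
    cds_len -= cds_len % 3
    utr3 = total - utr5 - cds_len
    if cds_len < 60:
        raise ValueError("exon lengths too short to host a coding region")
    n_codons = cds_len // 3 - 2
    body = "".join(
        rng.choice(np.array(NONSTOP_CODONS), size=n_codons).tolist()
    )
    tx = (
        _random_seq(rng, utr5)
        + "ATG"
        + body
        + "TAA"
        + _random_seq(rng, utr3)
    )
    assert len(tx) == total
    # splice the introns in (transcript orientation), with GT..AG motifs
    parts, pos = [], 0
    for i, elen in enumerate(exon_lens):
        parts.append(tx[pos : pos + elen])
        pos += elen
        if i < n_exons - 1:
            ilen = intron_lens[i]
            parts.append("GT" + _random_seq(rng, ilen - 4) + "AG")
    return _GenePlan(
        gene_id=f"G{idx:04d}",
        accession=f"NM_{idx:06d}",
        exon_lens=exon_lens,
        intron_lens=intron_lens,
        pre_mrna="".join(parts),
        cds=(utr5, utr5 + cds_len),
    )


def _materialize(
    plan: _GenePlan, chrom: str, strand: str, gstart: int
) -> Transcript:
    """Genomic exon coordinates for a plan placed at ``gstart``."""
    offsets, pos = [], 0
    for i, elen in enumerate(plan.exon_lens):
        offsets.append(pos)
        pos += elen
        if i < len(plan.intron_lens):
            pos += plan.intron_lens[i]
    block = plan.block_len
    exons = []
    for off, elen in zip(offsets, plan.exon_lens):
        if strand == "+":
            exons.append((gstart + off, gstart + off + elen))
        else:
            exons.append((gstart + block - off - elen, gstart + block - off))
    return Transcript(
        accession=plan.accession,
        gene_id=plan.gene_id,
        chrom=chrom,
        strand=strand,
        exons=exons,
        cds=plan.cds,
        coding_flag=True,
    )


def generate_genome(config: SimulationConfig) -> SimulatedData:
    """Build the genome, annotation and gene model (no events yet)."""
    from Bio.Seq import reverse_complement

    rng = config.rng(1)
    plans = [_plan_gene(rng, config, i + 1) for i in range(config.n_genes)]

    # decoy paralogs: mutated copies of the last n_decoy_pairs genes,
    # placed immediately downstream of their originals
    decoy_of: dict[int, _GenePlan] = {}
    for d in range(config.n_decoy_pairs):
        src_idx = config.n_genes - 1 - d
        if src_idx < 0:
            raise ValueError("more decoy pairs requested than genes")
        src = plans[src_idx]
        mutated = _mutate(rng, src.pre_mrna, 1.0 - config.decoy_identity)
        # keep the annotated splice motifs canonical in the paralog copy
        arr = list(mutated)
        pos = 0
        for i, elen in enumerate(src.exon_lens[:-1]):
            pos += elen
            ilen = src.intron_lens[i]
            arr[pos : pos + 2] = "GT"
            arr[pos + ilen - 2 : pos + ilen] = "AG"
            pos += ilen
        decoy_of[src_idx] = _GenePlan(
            gene_id=f"G{config.n_genes + d + 1:04d}P",
            accession=f"NM_{config.n_genes + d + 1:06d}",
            exon_lens=list(src.exon_lens),
            intron_lens=list(src.intron_lens),
            pre_mrna="".join(arr),
            cds=src.cds,
        )

    chrom_parts: dict[str, list[str]] = {}
    cursors: dict[str, int] = {}
    transcripts: list[Transcript] = []

    def place(plan: _GenePlan, chrom: str, strand: str, min_gap: int | None = None):
        parts = chrom_parts.setdefault(chrom, [])
        cur = cursors.get(chrom, 0)
        gap = (
            min_gap
            if min_gap is not None
            else config.intergenic_min + int(rng.exponential(config.intergenic_mean))
        )
        parts.append(_random_seq(rng, gap))
        gstart = cur + gap
        block = plan.pre_mrna if strand == "+" else reverse_complement(plan.pre_mrna)
        parts.append(block)
        cursors[chrom] = gstart + len(block)
        transcripts.append(_materialize(plan, chrom, strand, gstart))

    for i, plan in enumerate(plans):
        chrom = f"chr{i % config.n_chroms + 1}"
        strand = "+" if rng.random() < 0.5 else "-"
        place(plan, chrom, strand)
        if i in decoy_of:
            place(decoy_of[i], chrom, strand)

    long_pair = None
    if "long_range" in config.fusion_categories:
        a = _plan_gene(rng, config, config.n_genes + config.n_decoy_pairs + 1)
        b = _plan_gene(rng, config, config.n_genes + config.n_decoy_pairs + 2)
        place(a, "chrL", "+")
        place(b, "chrL", "+", min_gap=config.long_gap)
        long_pair = (a.gene_id, b.gene_id)

    genome = {}
    for chrom, parts in chrom_parts.items():
        parts.append(_random_seq(rng, config.intergenic_min))
        genome[chrom] = "".join(parts)

    model = GeneModel(transcripts, genome)
    sim = SimulatedData(
        config=config,
        genome=genome,
        model=model,
        transcripts=[
            SimTranscript(
                name=t.accession,
                segments=[(t.chrom, t.strand, s, e) for s, e in t.exons],
                sequence=t.sequence(genome),
                kind="gene",
                gene_id=t.gene_id,
            )
            for t in transcripts
        ],
        truth=SyntheticTruth(),
        decoy_pairs=[
            (plans[i].gene_id, decoy_of[i].gene_id) for i in sorted(decoy_of)
        ],
        long_pair=long_pair,
    )
    return sim


# ---------------------------------------------------------------------------
# Event planting


def _adjacent_same_strand_pairs(model: GeneModel) -> list[tuple[str, str]]:
    """(gene5, gene3) for adjacent same-strand gene pairs, in transcription
    orientation (on '-', the genomically downstream gene is the 5' one)."""
    by_chrom: dict[str, list[tuple[int, str, str]]] = {}
    for gene_id in model.by_gene:
        chrom, strand, lo, hi = model.gene_span(gene_id)
        by_chrom.setdefault(chrom, []).append((lo, gene_id, strand))
    pairs = []
    for chrom in sorted(by_chrom):
        genes = sorted(by_chrom[chrom])
        for (l1, g1, s1), (l2, g2, s2) in zip(genes, genes[1:]):
            if s1 != s2:
                continue
            pairs.append((g1, g2) if s1 == "+" else (g2, g1))
    return pairs


def _pattern_indices(
    rng: np.random.Generator,
    cfg: SimulationConfig,
    n5: int,
    n3: int,
) -> tuple[int, int, bool]:
    """Draw (donor exon, acceptor exon) per the pattern weights."""
    w = np.asarray(cfg.pattern_weights, dtype=float)
    cat = int(rng.choice(4, p=w / w.sum()))
    donor_choices_up = list(range(1, n5 - 1))  # internal donors above (n-1)
    acc_choices_down = list(range(3, n3 + 1))
    d, a = n5 - 1, 2  # the dominant (n-1) -> +2 geometry
    if cat in (1, 3) and donor_choices_up:
        d = int(rng.choice(donor_choices_up))
    if cat in (2, 3) and acc_choices_down:
        a = int(rng.choice(acc_choices_down))
    return d, a, (d == n5 - 1 and a == 2)


def _chimera(
    sim: SimulatedData,
    name: str,
    kind: str,
    t5: Transcript,
    d: int,
    t3: Transcript,
    a: int,
    intervening: tuple[str, str, int, int] | None = None,
) -> SimTranscript:
    from .chimera_coding import assemble_chimera

    chim = assemble_chimera(
        t5, d, t3, a, sim.genome, intervening_exon=intervening
    )
    segs = [
        (s.chrom, s.strand, s.start, s.end) for s in chim.segments
    ]
    junctions = [chim.five_prime_len]
    if intervening is not None:
        junctions.append(chim.five_prime_len + chim.intervening_len)
    return SimTranscript(
        name=name,
        segments=segs,
        sequence=chim.sequence,
        kind=kind,
        gene_id=None,
        junctions=junctions,
    )


def _site_positions(t5: Transcript, d: int, t3: Transcript, a: int):
    from .genome_model import donor_boundary, acceptor_boundary

    return donor_boundary(t5, d), acceptor_boundary(t3, a)


def plant_events(sim: SimulatedData, config: SimulationConfig) -> SimulatedData:
    """Add planted chimeric transcripts and their truth records."""
    rng = config.rng(2)
    model = sim.model
    pairs = _adjacent_same_strand_pairs(model)
    decoy_genes = {g for pair in sim.decoy_pairs for g in pair}
    free = [
        p
        for p in pairs
        if p[0] not in decoy_genes and p[1] not in decoy_genes
        and (sim.long_pair is None or set(p) != set(sim.long_pair))
    ]

    def take_pairs(n: int, label: str):
        if len(free) < n:
            raise ValueError(
                f"requested {n} {label} events but only {len(free)} "
                "adjacent same-strand gene pairs are available"
            )
        taken, rest = free[:n], free[n:]
        free[:] = rest
        return taken

    counter = 0

    def eps_for(i: int):
        if isinstance(config.tic_epsilon, (list, tuple)):
            return float(config.tic_epsilon[i])
        return float(config.tic_epsilon)

    # --- readthrough events
    tic_pairs = take_pairs(config.n_tic, "tic")
    for i, (g5, g3) in enumerate(tic_pairs):
        t5 = model.by_gene[g5][0]
        t3 = model.by_gene[g3][0]
        d, a, flag = _pattern_indices(rng, config, t5.exon_count, t3.exon_count)
        counter += 1
        name = f"TIC{counter:03d}"
        chim_list = [(name, t5, d, t3, a, flag)]
        if rng.random() < config.tic_isoform_fraction and t5.exon_count > 2:
            d2 = d - 1 if d > 1 else d + 1
            if 1 <= d2 <= t5.exon_count - 1 and d2 != d:
                counter += 1
                name2 = f"TIC{counter:03d}"
                chim_list.append(
                    (name2, t5, d2, t3, a, d2 == t5.exon_count - 1 and a == 2)
                )
        for name_i, t5_i, d_i, t3_i, a_i, flag_i in chim_list:
            c = _chimera(sim, name_i, "tic", t5_i, d_i, t3_i, a_i)
            c.gene_id = g5
            sim.transcripts.append(c)
            dpos, apos = _site_positions(t5_i, d_i, t3_i, a_i)
            sim.truth.events.append(
                PlantedEvent(
                    kind="tic",
                    gene5=g5,
                    gene3=g3,
                    donor_exon=d_i,
                    acceptor_exon=a_i,
                    donor_label=exon_label(d_i, t5_i.exon_count),
                    acceptor_label=exon_label(a_i, t3_i.exon_count),
                    donor_pos=dpos,
                    acceptor_pos=apos,
                    chimera_name=name_i,
                    epsilon=eps_for(i),
                    pattern_flag=flag_i,
                )
            )

    # --- intervening-exon events
    ticie_pairs = take_pairs(config.n_ticie, "ticie")
    for g5, g3 in ticie_pairs:
        t5 = model.by_gene[g5][0]
        t3 = model.by_gene[g3][0]
        strand = t5.strand
        # intergenic gap between the two genes, in genomic coordinates
        _, _, lo5, hi5 = model.gene_span(g5)
        _, _, lo3, hi3 = model.gene_span(g3)
        gap_lo, gap_hi = (hi5, lo3) if strand == "+" else (hi3, lo5)
        elen = int(rng.integers(config.ticie_exon_len[0], config.ticie_exon_len[1] + 1))
        margin = (gap_hi - gap_lo - elen) // 2
        if margin < 20:
            raise ValueError(f"intergenic gap too small for a planted exon ({g5}>{g3})")
        estart = gap_lo + margin
        exon = (t5.chrom, strand, estart, estart + elen)
        counter += 1
        name = f"TICIE{counter:03d}"
        c = _chimera(sim, name, "ticie", t5, t5.exon_count - 1, t3, 2, intervening=exon)
        c.gene_id = g5
        sim.transcripts.append(c)
        dpos, apos = _site_positions(t5, t5.exon_count - 1, t3, 2)
        sim.truth.events.append(
            PlantedEvent(
                kind="ticie",
                gene5=g5,
                gene3=g3,
                donor_exon=t5.exon_count - 1,
                acceptor_exon=2,
                donor_label=exon_label(t5.exon_count - 1, t5.exon_count),
                acceptor_label=exon_label(2, t3.exon_count),
                donor_pos=dpos,
                acceptor_pos=apos,
                chimera_name=name,
                epsilon=config.ticie_epsilon,
                pattern_flag=True,
                intervening_exon=exon,
            )
        )

    # --- distant fusions, one per requested category
    used = {g for p in tic_pairs + ticie_pairs for g in p} | decoy_genes
    all_genes = [
        (model.gene_span(g), g) for g in sorted(model.by_gene) if g not in used
    ]
    if sim.long_pair is not None:
        used |= set(sim.long_pair)

    def pick_pair(category: str) -> tuple[str, str]:
        if category == "long_range":
            if sim.long_pair is None:
                raise ValueError("no long-distance gene pair was generated")
            return sim.long_pair
        avail = [(span, g) for span, g in all_genes if g not in used]
        for (c1, s1, l1, h1), g1 in avail:
            for (c2, s2, l2, h2), g2 in avail:
                if g1 == g2:
                    continue
                if category == "translocation" and c1 != c2:
                    return g1, g2
                if category == "inversion" and c1 == c2 and s1 != s2:
                    return g1, g2
                if category == "scrambled" and c1 == c2 and s1 == s2:
                    # acceptor gene upstream of the donor gene
                    if (s1 == "+" and l2 < l1) or (s1 == "-" and l2 > l1):
                        return g1, g2
        raise ValueError(f"no gene pair available for a {category} fusion")

    for category in config.fusion_categories:
        g5, g3 = pick_pair(category)
        used |= {g5, g3}
        t5 = model.by_gene[g5][0]
        t3 = model.by_gene[g3][0]
        d, a = max(1, t5.exon_count - 1), 2
        counter += 1
        name = f"FUS_{category.upper()}{counter:03d}"
        c = _chimera(sim, name, category, t5, d, t3, a)
        c.gene_id = g5
        sim.transcripts.append(c)
        dpos, apos = _site_positions(t5, d, t3, a)
        sim.truth.events.append(
            PlantedEvent(
                kind=category,
                gene5=g5,
                gene3=g3,
                donor_exon=d,
                acceptor_exon=a,
                donor_label=exon_label(d, t5.exon_count),
                acceptor_label=exon_label(a, t3.exon_count),
                donor_pos=dpos,
                acceptor_pos=apos,
                chimera_name=name,
                epsilon=config.fusion_epsilon,
                pattern_flag=False,
            )
        )

    # --- decoy paralog chimeras
    for g5, g3 in sim.decoy_pairs:
        t5 = model.by_gene[g5][0]
        t3 = model.by_gene[g3][0]
        d, a = max(1, t5.exon_count - 1), 2
        counter += 1
        name = f"DECOY{counter:03d}"
        c = _chimera(sim, name, "decoy", t5, d, t3, a)
        c.gene_id = g5
        sim.transcripts.append(c)
        dpos, apos = _site_positions(t5, d, t3, a)
        sim.truth.events.append(
            PlantedEvent(
                kind="decoy",
                gene5=g5,
                gene3=g3,
                donor_exon=d,
                acceptor_exon=a,
                donor_label=exon_label(d, t5.exon_count),
                acceptor_label=exon_label(a, t3.exon_count),
                donor_pos=dpos,
                acceptor_pos=apos,
                chimera_name=name,
                epsilon=config.decoy_epsilon,
                pattern_flag=False,
            )
        )
    return sim


# ---------------------------------------------------------------------------
# Read simulation


@dataclass
class SimulatedReads:
    config: SimulationConfig
    sim: SimulatedData
    sequences: list[str]
    read_source: np.ndarray  # transcript index per read
    read_start: np.ndarray
    split_records: list[SplitAlignmentRecord]

    @property
    def n_reads(self) -> int:
        return len(self.sequences)

    def read_id(self, i: int) -> str:
        return f"r{i}"

    def iter_short_reads(self):
        sample = self.config.sample_id
        for i, seq in enumerate(self.sequences):
            yield ShortRead(read_id=f"r{i}", sequence=seq, sample_id=sample)

    def iter_alignment_blocks(self):
        """(sample_id, chrom, [(start, end), ...]) per read, from provenance."""
        L = self.config.read_length
        sample = self.config.sample_id
        txs = self.sim.transcripts
        for i in range(self.n_reads):
            t = txs[int(self.read_source[i])]
            s = int(self.read_start[i])
            blocks = t.project(s, s + L)
            chrom = blocks[0][1]
            yield sample, chrom, [(b[3], b[4]) for b in blocks if b[1] == chrom]

    def write_fastq(self, path: str) -> None:
        with open(path, "w") as fh:
            for i, seq in enumerate(self.sequences):
                fh.write(f"@r{i}\n{seq}\n+\n{'I' * len(seq)}\n")

    def write_split_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(
                "read_id\tsample_id\tchromA\tstrandA\tstartA\tendA\t"
                "chromB\tstrandB\tstartB\tendB\n"
            )
            for r in self.split_records:
                a, b = r.segment_a, r.segment_b
                fh.write(
                    f"{r.read_id}\t{r.sample_id}\t{a.chrom}\t{a.strand}\t"
                    f"{a.start}\t{a.end}\t{b.chrom}\t{b.strand}\t"
                    f"{b.start}\t{b.end}\n"
                )


def expected_read_counts(
    sim: SimulatedData, config: SimulationConfig
) -> dict[str, float]:
    """Expected reads per transcript under the multinomial read model."""
    weights = _weights(sim, config)
    total = weights.sum()
    return {
        t.name: config.total_reads * w / total
        for t, w in zip(sim.transcripts, weights)
    }


def expected_junction_support(
    sim: SimulatedData, config: SimulationConfig, chimera_name: str, overhang: int
) -> float:
    """Expected number of reads supporting a chimera's first junction with
    >= overhang nt on both sides (before sequencing error losses)."""
    counts = expected_read_counts(sim, config)
    t = sim.by_name(chimera_name)
    L = config.read_length
    support = max(L - 2 * overhang + 1, 0)
    return counts[chimera_name] * support / t.n_start_positions(L)


def _assign_expression(sim: SimulatedData, config: SimulationConfig) -> None:
    rng = config.rng(3)
    expr: dict[str, float] = {}
    for t in sim.transcripts:
        if t.kind == "gene":
            if t.gene_id in config.expression_overrides:
                expr[t.name] = float(config.expression_overrides[t.gene_id])
            else:
                expr[t.name] = float(
                    np.exp(rng.normal(0.0, config.expression_sigma))
                )
    for t in sim.transcripts:
        if t.kind != "gene":
            event = next(
                e for e in sim.truth.events if e.chimera_name == t.name
            )
            host = sim.model.by_gene[event.gene5][0].accession
            expr[t.name] = event.epsilon * expr[host]
    for t in sim.transcripts:
        t.expression = expr[t.name]
    sim.truth.expression = expr


def _weights(sim: SimulatedData, config: SimulationConfig) -> np.ndarray:
    if not sim.truth.expression:
        _assign_expression(sim, config)
    L = config.read_length
    return np.array(
        [t.expression * t.n_start_positions(L) for t in sim.transcripts]
    )


def simulate_reads(
    sim: SimulatedData, config: SimulationConfig | None = None
) -> SimulatedReads:
    """Sample reads, apply substitution errors, and emit provenance plus
    split-alignment records for junction-spanning reads."""
    if config is None:
        config = sim.config
    rng = config.rng(4)
    L = config.read_length
    weights = _weights(sim, config)
    counts = rng.multinomial(config.total_reads, weights / weights.sum())

    sequences: list[str] = []
    src_idx: list[np.ndarray] = []
    starts_all: list[np.ndarray] = []
    split_records: list[SplitAlignmentRecord] = []
    read_no = 0

    for tidx, (t, m) in enumerate(zip(sim.transcripts, counts)):
        if m == 0:
            continue
        npos = t.n_start_positions(L)
        starts = rng.integers(0, npos, size=m)
        src_idx.append(np.full(m, tidx, dtype=np.int32))
        starts_all.append(starts.astype(np.int64))
        # substitution errors, chunked
        for lo in range(0, m, 50_000):
            chunk = starts[lo : lo + 50_000]
            n = len(chunk)
            err = rng.random((n, L)) < config.error_rate
            rows = np.nonzero(err.any(axis=1))[0]
            muts: dict[int, list[int]] = {
                int(r): np.nonzero(err[r])[0].tolist() for r in rows
            }
            for j in range(n):
                s = int(chunk[j])
                seq = t.sequence[s : s + L]
                if j in muts:
                    arr = list(seq)
                    for p in muts[j]:
                        others = [b for b in "ACGT" if b != arr[p]]
                        arr[p] = others[int(rng.integers(0, 3))]
                    seq = "".join(arr)
                rid = f"r{read_no}"
                read_no += 1
                sequences.append(seq)
                rec = _split_record(t, s, L, rid, config)
                if rec is not None:
                    split_records.append(rec)

    reads = SimulatedReads(
        config=config,
        sim=sim,
        sequences=sequences,
        read_source=np.concatenate(src_idx) if src_idx else np.empty(0, np.int32),
        read_start=np.concatenate(starts_all) if starts_all else np.empty(0, np.int64),
        split_records=split_records,
    )
    sim.truth.read_source = reads.read_source
    sim.truth.read_start = reads.read_start
    sim.truth.source_names = [t.name for t in sim.transcripts]
    return reads


def _split_record(
    t: SimTranscript, start: int, L: int, read_id: str, config: SimulationConfig
) -> SplitAlignmentRecord | None:
    """Split record for a read crossing a chimeric junction with >= 14-nt
    anchors, as a spliced aligner could detect it."""
    for j in t.junctions:
        left = j - start
        right = start + L - j
        if left >= config.anchor_min and right >= config.anchor_min:
            blocks = t.project(start, start + L)
            before = [b for b in blocks if b[0] == _segment_before(t, j)]
            after = [b for b in blocks if b[0] == _segment_before(t, j) + 1]
            if not before or not after:
                return None
            _, ca, sa, a0, a1 = before[-1]
            _, cb, sb, b0, b1 = after[0]
            return SplitAlignmentRecord(
                read_id=read_id,
                sample_id=config.sample_id,
                segment_a=Segment(ca, sa, a0, a1),
                segment_b=Segment(cb, sb, b0, b1),
            )
    return None


def _segment_before(t: SimTranscript, junction_tx: int) -> int:
    """Index of the segment whose 3' end sits at the junction."""
    pos = 0
    for idx, (_, _, s, e) in enumerate(t.segments):
        pos += e - s
        if pos == junction_tx:
            return idx
    raise ValueError(f"{t.name}: no segment boundary at {junction_tx}")


def generate_dataset(
    config: SimulationConfig,
) -> tuple[SimulatedData, SimulatedReads]:
    """Genome + annotation + planted events + reads, all from one seed."""
    sim = generate_genome(config)
    plant_events(sim, config)
    reads = simulate_reads(sim, config)
    return sim, reads


def write_genome_fasta(sim: SimulatedData, path: str) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(sim.genome):
            fh.write(f">{chrom}\n")
            seq = sim.genome[chrom]
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def write_truth_json(sim: SimulatedData, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(sim.truth.to_json())
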