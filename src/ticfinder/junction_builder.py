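"""Artificial exon-exon junction targets.

Targeted alignment detects readthrough chimeras by aligning short reads to a
pre-built library of candidate junction sequences instead of the genome:

* intragenic targets - every ordered exon pair (i, j), i < j, within one
  transcript, regardless of distance;
* readthrough (TIC) targets - every donor/acceptor pair on the same strand
  within a distance window (default 200,000 bp) whose sites share no
  transcript;
* shifted control targets - each TIC target with the 5 bases at positions
  -10..-6 and +6..+10 relative to the junction deleted, forming a null set
  for false-discovery-rate estimation (a read that truly spans the original
  junction cannot match the shifted copy without piling up mismatches).

Each target carries ``flank`` nt of *spliced transcript* sequence on both
sides of the junction (default 80, so full-length targets are 160 nt).
Flanks cross upstream/downstream exon boundaries when the junction exon is
shorter than the flank, taking the transcript that yields the longest flank
(ties broken by lexicographic accession).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .genome_model import (
    GeneModel,
    SpliceLabel,
    SpliceSite,
    Transcript,
    catalog_splice_sites,
    donor_boundary,
    acceptor_boundary,
    exon_label,
)

DEFAULT_MAX_DISTANCE = 200_000
DEFAULT_FLANK = 80


@dataclass
class JunctionTarget:
    junction_id: str
    kind: str  # "intragenic" | "tic" | "control"
    donor: SpliceSite
    acceptor: SpliceSite
    left_seq: str
    right_seq: str
    splice_distance: int
    intergenic_distance: int | None = None
    source_junction_id: str | None = None
    truncated_flank: bool = False

    @property
    def sequence(self) -> str:
        return self.left_seq + self.right_seq

    @property
    def junction_offset(self) -> int:
        """Target coordinate of the first base on the acceptor side."""
        return len(self.left_seq)

    @property
    def coords(self) -> tuple[str, str, int, int]:
        """Deduplication key: (chrom, strand, donor pos, acceptor pos)."""
        return (
            self.donor.chrom,
            self.donor.strand,
            self.donor.pos,
            self.acceptor.pos,
        )

    def describe(self) -> str:
        d5 = ",".join(sorted(self.donor.gene_ids))
        d3 = ",".join(sorted(self.acceptor.gene_ids))
        lab5 = ",".join(
            sorted(exon_label(l.exon_index, l.exon_count) for l in self.donor.labels)
        )
        lab3 = ",".join(
            sorted(
                exon_label(l.exon_index, l.exon_count)
                for l in self.acceptor.labels
            )
        )
        return (
            f"kind={self.kind} genes={d5}>{d3} labels={lab5}>{lab3} "
            f"distance={self.splice_distance}"
        )


def splice_distance(donor: SpliceSite, acceptor: SpliceSite) -> int:
    """Genomic gap between the two boundaries (positive when the acceptor is
    downstream of the donor in transcription orientation)."""
    if donor.strand == "+":
        return acceptor.pos - donor.pos
    return donor.pos - acceptor.pos


def _flank_upstream(
    model: GeneModel, site: SpliceSite, flank: int
) -> tuple[str, bool]:
    """Spliced sequence immediately upstream of a donor site.

    Uses the label whose transcript offers the longest context; flags
    truncation when even the best transcript is shorter than ``flank``.
    """
    best: tuple[int, str, str] | None = None  # (-len, accession, seq)
    for lab in site.labels:
        t = model.by_accession[lab.accession]
        seq = t.sequence(model.genome)
        end = sum(e - s for s, e in t.exons[: lab.exon_index])
        piece = seq[max(0, end - flank) : end]
        key = (-len(piece), lab.accession)
        if best is None or key < (best[0], best[1]):
            best = (-len(piece), lab.accession, piece)
    assert best is not None
    return best[2], len(best[2]) < flank


def _flank_downstream(
    model: GeneModel, site: SpliceSite, flank: int
) -> tuple[str, bool]:
    """Spliced sequence immediately downstream of an acceptor site."""
    best: tuple[int, str, str] | None = None
    for lab in site.labels:
        t = model.by_accession[lab.accession]
        seq = t.sequence(model.genome)
        start = sum(e - s for s, e in t.exons[: lab.exon_index - 1])
        piece = seq[start : start + flank]
        key = (-len(piece), lab.accession)
        if best is None or key < (best[0], best[1]):
            best = (-len(piece), lab.accession, piece)
    assert best is not None
    return best[2], len(best[2]) < flank


def _tic_id(donor: SpliceSite, acceptor: SpliceSite) -> str:
    return (
        f"tic|{donor.chrom}|{donor.strand}|{donor.pos}|{acceptor.pos}"
    )


def qualifies_as_tic_pair(
    donor: SpliceSite,
    acceptor: SpliceSite,
    max_distance: int = DEFAULT_MAX_DISTANCE,
) -> bool:
    """The pairing predicate: same chrom and strand, acceptor strictly
    downstream in transcription orientation within the window, and no
    transcript in common between the two sites."""
    if donor.chrom != acceptor.chrom or donor.strand != acceptor.strand:
        return False
    dist = splice_distance(donor, acceptor)
    if not 0 < dist <= max_distance:
        return False
    return not (donor.accessions & acceptor.accessions)


def _gene_extents(model: GeneModel) -> dict[str, tuple[int, int]]:
    return {
        g: model.gene_span(g)[2:4] for g in model.by_gene
    }


def _intergenic_distance(
    model: GeneModel,
    extents: dict[str, tuple[int, int]],
    donor: SpliceSite,
    acceptor: SpliceSite,
) -> int | None:
    """bp between the 5' gene end and the 3' gene start, when resolvable."""
    if len(donor.gene_ids) != 1 or len(acceptor.gene_ids) != 1:
        return None
    g5, g3 = next(iter(donor.gene_ids)), next(iter(acceptor.gene_ids))
    lo5, hi5 = extents[g5]
    lo3, hi3 = extents[g3]
    if donor.strand == "+":
        return lo3 - hi5
    return lo5 - hi3


def build_tic_targets(
    donors: dict[tuple, SpliceSite],
    acceptors: dict[tuple, SpliceSite],
    model: GeneModel,
    max_distance: int = DEFAULT_MAX_DISTANCE,
    flank: int = DEFAULT_FLANK,
    strict_adjacency: bool = False,
) -> list[JunctionTarget]:
    """Enumerate readthrough junction targets from the site catalogs.

    Pairs are generated with a per-(chrom, strand) sorted sweep, which on
    real annotations is far below the all-pairs bound.  With
    ``strict_adjacency`` pairs that skip over an intervening gene (a gene
    whose extent lies wholly between donor and acceptor) are dropped.
    """
    extents = _gene_extents(model)
    by_cs: dict[tuple[str, str], list[SpliceSite]] = {}
    for site in acceptors.values():
        by_cs.setdefault((site.chrom, site.strand), []).append(site)
    for sites in by_cs.values():
        sites.sort(key=lambda s: s.pos)

    targets = []
    for donor in sorted(donors.values(), key=lambda s: (s.chrom, s.strand, s.pos)):
        candidates = by_cs.get((donor.chrom, donor.strand), [])
        for acceptor in candidates:
            if not qualifies_as_tic_pair(donor, acceptor, max_distance):
                continue
            if strict_adjacency and _skips_gene(
                extents, donor, acceptor
            ):
                continue
            left, ltrunc = _flank_upstream(model, donor, flank)
            right, rtrunc = _flank_downstream(model, acceptor, flank)
            targets.append(
                JunctionTarget(
                    junction_id=_tic_id(donor, acceptor),
                    kind="tic",
                    donor=donor,
                    acceptor=acceptor,
                    left_seq=left,
                    right_seq=right,
                    splice_distance=splice_distance(donor, acceptor),
                    intergenic_distance=_intergenic_distance(
                        model, extents, donor, acceptor
                    ),
                    truncated_flank=ltrunc or rtrunc,
                )
            )
    return targets


def _skips_gene(extents, donor: SpliceSite, acceptor: SpliceSite) -> bool:
    lo = min(donor.pos, acceptor.pos)
    hi = max(donor.pos, acceptor.pos)
    partner_genes = donor.gene_ids | acceptor.gene_ids
    for gene, (glo, ghi) in extents.items():
        if gene in partner_genes:
            continue
        if lo <= glo and ghi <= hi:
            return True
    return False


def build_intragenic_targets(
    model: GeneModel,
    flank: int = DEFAULT_FLANK,
) -> list[JunctionTarget]:
    """All ordered exon pairs (i, j), i < j, within each transcript,
    deduplicated across isoforms by junction coordinates."""
    donors, acceptors = catalog_splice_sites(model.transcripts)
    seen: dict[tuple, JunctionTarget] = {}
    for t in model.transcripts:
        n = t.exon_count
        for i in range(1, n):
            dkey = (t.chrom, t.strand, donor_boundary(t, i), "donor")
            for j in range(i + 1, n + 1):
                akey = (t.chrom, t.strand, acceptor_boundary(t, j), "acceptor")
                donor, acceptor = donors[dkey], acceptors[akey]
                coords = (t.chrom, t.strand, donor.pos, acceptor.pos)
                if coords in seen:
                    continue
                left, ltrunc = _flank_upstream(model, donor, flank)
                right, rtrunc = _flank_downstream(model, acceptor, flank)
                seen[coords] = JunctionTarget(
                    junction_id=(
                        f"intra|{t.chrom}|{t.strand}|{donor.pos}|{acceptor.pos}"
                    ),
                    kind="intragenic",
                    donor=donor,
                    acceptor=acceptor,
                    left_seq=left,
                    right_seq=right,
                    splice_distance=splice_distance(donor, acceptor),
                    truncated_flank=ltrunc or rtrunc,
                )
    return list(seen.values())


def shift_left_flank(left_seq: str) -> str:
    """Delete positions -10..-6 (1-based, counting away from the junction)."""
    return left_seq[:-10] + left_seq[-5:]


def shift_right_flank(right_seq: str) -> str:
    """Delete positions +6..+10."""
    return right_seq[:5] + right_seq[10:]


def build_control_targets(
    targets: list[JunctionTarget],
) -> tuple[list[JunctionTarget], int]:
    """Shifted-junction null targets for FDR estimation.

    Each input target loses 5 bases on both sides at the -10..-6 / +6..+10
    positions; the 5 junction-proximal bases are preserved and rejoined to
    the shifted distal sequence.  Targets with a flank under 10 nt are
    skipped; the skip count is returned alongside the controls.
    """
    controls, skipped = [], 0
    for t in targets:
        if len(t.left_seq) < 10 or len(t.right_seq) < 10:
            skipped += 1
            continue
        controls.append(
            JunctionTarget(
                junction_id="ctrl|" + t.junction_id,
                kind="control",
                donor=t.donor,
                acceptor=t.acceptor,
                left_seq=shift_left_flank(t.left_seq),
                right_seq=shift_right_flank(t.right_seq),
                splice_distance=t.splice_distance,
                intergenic_distance=t.intergenic_distance,
                source_junction_id=t.junction_id,
            )
        )
    return controls, skipped


def write_targets_fasta(targets: list[JunctionTarget], path: str) -> None:
    with open(path, "w") as fh:
        for t in targets:
            fh.write(f">{t.junction_id} {t.describe()}\n{t.sequence}\n")


def write_targets_tsv(targets: list[JunctionTarget], path: str) -> None:
    with open(path, "w") as fh:
        fh.write(
            "junction_id\tkind\tchrom\tstrand\tdonor_pos\tacceptor_pos\t"
            "splice_distance\tintergenic_distance\tgenes5\tgenes3\n"
        )
        for t in targets:
            fh.write(
                f"{t.junction_id}\t{t.kind}\t{t.donor.chrom}\t"
                f"{t.donor.strand}\t{t.donor.pos}\t{t.acceptor.pos}\t"
                f"{t.splice_distance}\t"
                f"{'' if t.intergenic_distance is None else t.intergenic_distance}\t"
                f"{','.join(sorted(t.donor.gene_ids))}\t"
                f"{','.join(sorted(t.acceptor.gene_ids))}\n"
            )
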