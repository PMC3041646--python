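"""From junction alignments to called readthrough events.

The filter cascade mirrors the targeted-alignment analysis:

1. intragenic-equivalence filter - a "TIC" junction whose donor and acceptor
   genes intersect actually joins two isoforms of one gene (an unannotated
   alternative splice), and is removed;
2. overhang support - a candidate alignment must extend >= 8 nt past the
   junction on both sides;
3. clustering by junction, building a per-position match profile (a compact
   multiple alignment of the supporting reads against the target);
4. consistency filter - on each side of the junction the first 11 positions
   must each be covered by at least one read that matches the target there,
   and no covered position anywhere may be mismatched by *every* covering
   read (for a singleton cluster this reduces to one read matching all 11 bp
   on both sides);
5. homology filter - the junction fragment (longest observed left overhang +
   longest observed right overhang) must not locally align over >= 90% of
   its length to any transcript of either component gene, and no 5'-gene /
   3'-gene transcript pair may share a local alignment window of 50 columns
   with >= 40 matches (the paralog trap: e.g. two genes at 92% identity).

Running the identical cascade against the shifted control junctions gives
the false-discovery-rate numerator: fdr = n_control / n_real.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .genome_model import GeneModel, exon_label
from .junction_aligner import JunctionAlignment
from .junction_builder import JunctionTarget

CONSISTENCY_WINDOW = 11
CANDIDATE_OVERHANG = 8
JUNCTION_HOMOLOGY_FRACTION = 0.90
HOMOLOGY_WINDOW = (40, 50)  # >= 40 matches within 50 alignment columns


@dataclass
class JunctionCluster:
    target: JunctionTarget
    alignments: list[JunctionAlignment]

    @property
    def junction_id(self) -> str:
        return self.target.junction_id

    def profile(self) -> tuple[list[int], list[int]]:
        """Per target position: (covering reads, covering reads that match)."""
        n = len(self.target.sequence)
        coverage = [0] * n
        matches = [0] * n
        for a in self.alignments:
            span_end = a.target_offset + a.left_overhang + a.right_overhang
            for p in range(a.target_offset, span_end):
                coverage[p] += 1
                if p not in a.mismatch_positions:
                    matches[p] += 1
        return coverage, matches

    @property
    def max_left_overhang(self) -> int:
        return max(a.left_overhang for a in self.alignments)

    @property
    def max_right_overhang(self) -> int:
        return max(a.right_overhang for a in self.alignments)

    def junction_fragment(self) -> str:
        """Longest observed left overhang + longest observed right overhang,
        concatenated across the junction."""
        j = self.target.junction_offset
        return (
            self.target.left_seq[j - self.max_left_overhang :]
            + self.target.right_seq[: self.max_right_overhang]
        )


@dataclass
class TicEvent:
    gene5: str
    gene3: str
    donor_label: str
    acceptor_label: str
    splice_distance: int
    intergenic_distance: int | None
    n_reads: int
    samples: set[str]
    pattern_flag: bool  # (n-1) -> +2 geometry
    isoform_group: str
    junction_id: str
    shared_site: str | None = None  # "donor"/"acceptor" within the group


@dataclass
class FdrEstimate:
    n_control: int
    n_real: int

    @property
    def fdr(self) -> float | None:
        if self.n_real == 0:
            return None
        return self.n_control / self.n_real

    @property
    def percent(self) -> float | None:
        """Percentage rendering, rounded to one decimal (5/339 -> 1.5)."""
        if self.fdr is None:
            return None
        return round(100.0 * self.fdr, 1)

    def __str__(self) -> str:
        if self.fdr is None:
            return "NA"
        return f"{self.n_control}/{self.n_real} = {self.percent}%"


def estimate_fdr(n_control: int, n_real: int) -> FdrEstimate:
    if n_control < 0 or n_real < 0:
        raise ValueError("counts must be non-negative")
    return FdrEstimate(n_control, n_real)


# ---------------------------------------------------------------------------
# Filters


def filter_intragenic_equivalents(
    alignments: list[JunctionAlignment],
    targets_by_id: dict[str, JunctionTarget],
) -> list[JunctionAlignment]:
    """Drop alignments whose junction joins two transcripts of one gene."""
    kept = []
    for a in alignments:
        t = targets_by_id[a.junction_id]
        if t.donor.gene_ids & t.acceptor.gene_ids:
            continue
        kept.append(a)
    return kept


def cluster_alignments(
    alignments: list[JunctionAlignment],
    targets_by_id: dict[str, JunctionTarget],
) -> list[JunctionCluster]:
    groups: dict[str, list[JunctionAlignment]] = {}
    for a in alignments:
        groups.setdefault(a.junction_id, []).append(a)
    return [
        JunctionCluster(targets_by_id[jid], group)
        for jid, group in sorted(groups.items())
    ]


def consistency_filter(
    cluster: JunctionCluster, window: int = CONSISTENCY_WINDOW
) -> tuple[bool, str]:
    """Require `window` consistent match positions on both sides of the
    junction and veto any consistently mismatched position.

    A consistent match position is one where at least one covering read
    matches the target.  PASS implies max overhang >= window on both sides.
    """
    if not cluster.alignments:
        return False, "empty_cluster"
    coverage, matches = cluster.profile()
    j = cluster.target.junction_offset
    n = len(cluster.target.sequence)
    for i in range(1, window + 1):
        left = j - i
        right = j + i - 1
        if left < 0 or right >= n:
            return False, "window_outside_target"
        if coverage[left] == 0 or matches[left] == 0:
            return False, f"left_side_inconsistent_at_-{i}"
        if coverage[right] == 0 or matches[right] == 0:
            return False, f"right_side_inconsistent_at_+{i}"
    for p in range(n):
        if coverage[p] > 0 and matches[p] == 0:
            return False, f"consistent_mismatch_at_{p}"
    return True, "pass"


def _homology_aligner():
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -1
    return aligner


def _match_column_count(alignment, seq_a: str, seq_b: str) -> int:
    """Number of *matching* columns in a local alignment.

    Mismatch and gap columns do not count as "aligned" here: a local
    aligner will happily pair random sequence across small gaps, so a true
    chimeric fragment (one half genuinely from each gene) would otherwise
    routinely exceed any coverage threshold against its own 3' gene.
    Counting identities keeps the screen aimed at genuine homology.
    """
    blocks_a, blocks_b = alignment.aligned
    n = 0
    for (a0, a1), (b0, b1) in zip(blocks_a, blocks_b):
        n += sum(1 for i in range(a1 - a0) if seq_a[a0 + i] == seq_b[b0 + i])
    return n


def _match_columns(alignment, seq_a: str, seq_b: str) -> list[int]:
    """0/1 match indicator per alignment column (gap columns are 0)."""
    blocks_a, blocks_b = alignment.aligned
    cols: list[int] = []
    prev_a = prev_b = None
    for (a0, a1), (b0, b1) in zip(blocks_a, blocks_b):
        if prev_a is not None:
            cols.extend([0] * ((a0 - prev_a) + (b0 - prev_b)))
        for i in range(a1 - a0):
            cols.append(1 if seq_a[a0 + i] == seq_b[b0 + i] else 0)
        prev_a, prev_b = a1, b1
    return cols


def has_homology_window(
    seq_a: str,
    seq_b: str,
    min_matches: int = HOMOLOGY_WINDOW[0],
    window: int = HOMOLOGY_WINDOW[1],
    aligner=None,
) -> bool:
    """Does the best local alignment of the two sequences contain a window
    of `window` columns with >= `min_matches` matches?"""
    if aligner is None:
        aligner = _homology_aligner()
    if not seq_a or not seq_b:
        return False
    alignments = aligner.align(seq_a, seq_b)
    try:
        best = alignments[0]
    except IndexError:
        return False
    cols = _match_columns(best, seq_a, seq_b)
    if len(cols) < window:
        return sum(cols) >= min_matches
    running = sum(cols[:window])
    if running >= min_matches:
        return True
    for i in range(window, len(cols)):
        running += cols[i] - cols[i - window]
        if running >= min_matches:
            return True
    return False


def junction_fragment_homologous(
    fragment: str,
    transcript_seqs: list[str],
    fraction: float = JUNCTION_HOMOLOGY_FRACTION,
    aligner=None,
) -> bool:
    """Does >= `fraction` of the junction fragment align (as identities) to
    any of the component-gene transcripts?"""
    if aligner is None:
        aligner = _homology_aligner()
    for seq in transcript_seqs:
        if not seq:
            continue
        alignments = aligner.align(fragment, seq)
        try:
            best = alignments[0]
        except IndexError:
            continue
        if _match_column_count(best, fragment, seq) / len(fragment) >= fraction:
            return True
    return False


def homology_filter(
    transcripts5: dict[str, str],
    transcripts3: dict[str, str],
    fragment: str | None = None,
    fraction: float = JUNCTION_HOMOLOGY_FRACTION,
    min_matches: int = HOMOLOGY_WINDOW[0],
    window: int = HOMOLOGY_WINDOW[1],
) -> tuple[bool, str]:
    """PASS/FAIL with reason for the two homology criteria.

    ``transcripts5``/``transcripts3`` map accession -> transcript sequence
    for the 5' and 3' component genes.  ``fragment`` is the cluster's
    junction fragment; when None (e.g. intervening-exon candidates, which
    have no targeted cluster) only the gene-vs-gene criterion is applied.
    """
    if not transcripts5 or not transcripts3:
        raise ValueError("missing transcript sequences for a component gene")
    aligner = _homology_aligner()
    if fragment is not None:
        seqs = list(transcripts5.values()) + list(transcripts3.values())
        if junction_fragment_homologous(fragment, seqs, fraction, aligner):
            return False, "junction_homology"
    for s5 in transcripts5.values():
        for s3 in transcripts3.values():
            if has_homology_window(s5, s3, min_matches, window, aligner):
                return False, "gene_homology"
    return True, "pass"


# ---------------------------------------------------------------------------
# Event assembly


def _label_pairs(target: JunctionTarget):
    """(donor label, acceptor label) pairs as (index, count) tuples."""
    return (
        sorted((l.exon_index, l.exon_count) for l in target.donor.labels),
        sorted((l.exon_index, l.exon_count) for l in target.acceptor.labels),
    )


def _pattern_flag(target: JunctionTarget) -> bool:
    """(n-1) -> +2: penultimate donor exon joined to the second exon."""
    donors, acceptors = _label_pairs(target)
    donor_nm1 = any(idx == cnt - 1 for idx, cnt in donors)
    acceptor_p2 = any(idx == 2 for idx, _ in acceptors)
    return donor_nm1 and acceptor_p2


def call_events(
    clusters: list[JunctionCluster],
) -> list[TicEvent]:
    """One event per surviving junction cluster, with isoform grouping.

    Events sharing (gene5, gene3) form an isoform group; groups with more
    than one event are annotated with the splice site the isoforms share,
    when there is one.
    """
    events: list[TicEvent] = []
    for c in clusters:
        t = c.target
        donors, acceptors = _label_pairs(t)
        gene5 = ",".join(sorted(t.donor.gene_ids))
        gene3 = ",".join(sorted(t.acceptor.gene_ids))
        events.append(
            TicEvent(
                gene5=gene5,
                gene3=gene3,
                donor_label=",".join(exon_label(i, n) for i, n in donors),
                acceptor_label=",".join(exon_label(i, n) for i, n in acceptors),
                splice_distance=t.splice_distance,
                intergenic_distance=t.intergenic_distance,
                n_reads=len(c.alignments),
                samples={a.sample_id for a in c.alignments},
                pattern_flag=_pattern_flag(t),
                isoform_group=f"{gene5}>{gene3}",
                junction_id=t.junction_id,
            )
        )

    by_group: dict[str, list[TicEvent]] = {}
    by_group_targets: dict[str, list[JunctionTarget]] = {}
    for e, c in zip(events, clusters):
        by_group.setdefault(e.isoform_group, []).append(e)
        by_group_targets.setdefault(e.isoform_group, []).append(c.target)
    for group, members in by_group.items():
        if len(members) < 2:
            continue
        targets = by_group_targets[group]
        donor_positions = {t.donor.pos for t in targets}
        acceptor_positions = {t.acceptor.pos for t in targets}
        shared = None
        if len(donor_positions) == 1:
            shared = "donor"
        elif len(acceptor_positions) == 1:
            shared = "acceptor"
        for e in members:
            e.shared_site = shared
    return sorted(events, key=lambda e: e.junction_id)


def write_events_tsv(events: list[TicEvent], path: str) -> None:
    with open(path, "w") as fh:
        fh.write(
            "gene5\tgene3\tdonor_label\tacceptor_label\tsplice_distance\t"
            "intergenic_distance\tn_reads\tsamples\tpattern_nm1_p2\t"
            "isoform_group\tshared_site\tjunction_id\texternal_support\n"
        )
        for e in events:
            fh.write(
                f"{e.gene5}\t{e.gene3}\t{e.donor_label}\t{e.acceptor_label}\t"
                f"{e.splice_distance}\t"
                f"{'' if e.intergenic_distance is None else e.intergenic_distance}\t"
                f"{e.n_reads}\t{','.join(sorted(e.samples))}\t"
                f"{int(e.pattern_flag)}\t{e.isoform_group}\t"
                f"{e.shared_site or ''}\t{e.junction_id}\t\n"
            )
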