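"""Seed-and-extend alignment of short reads to junction targets.

The engine indexes every exact k-mer of every target (default k = 12) and,
for each read, tries every exact k-mer seed, extending each candidate
placement ungapped over the full read length.  A read is accepted as
junction evidence only when

* its best placement has at most one mismatch and no indels,
* exactly one distinct junction attains that best mismatch count, and
* the read crosses the junction midpoint (>= 1 nt on both sides).

N bases never count as matches.  For reads of length >= 2k the seed search
is complete for the <= 1-mismatch acceptance set: a single mismatch always
leaves an exact stretch of at least k on one side.

Targets duplicated across isoforms are collapsed by junction coordinates
before indexing, so alternative-transcript copies of the same junction do
not destroy uniqueness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .junction_builder import JunctionTarget

DEFAULT_K = 12

# rejection reasons
NO_HIT = "no_hit"
MULTI_MAPPED = "multi_mapped"
TOO_MANY_MISMATCHES = "too_many_mismatches"
NO_JUNCTION_OVERLAP = "no_junction_overlap"
CLIPPED = "clipped"


@dataclass
class ShortRead:
    read_id: str
    sequence: str
    sample_id: str = "S1"
    qualities: str | None = None


@dataclass
class JunctionAlignment:
    read_id: str
    sample_id: str
    junction_id: str
    target_offset: int
    mismatch_positions: frozenset[int]  # target coordinates
    left_overhang: int
    right_overhang: int
    unique_flag: bool = True

    @property
    def n_mismatches(self) -> int:
        return len(self.mismatch_positions)

    @property
    def min_overhang(self) -> int:
        return min(self.left_overhang, self.right_overhang)


@dataclass
class Rejection:
    read_id: str
    reason: str


class JunctionIndex:
    """Exact k-mer postings over a collapsed target set."""

    def __init__(self, targets: list[JunctionTarget], k: int = DEFAULT_K):
        if not targets:
            raise ValueError("cannot index an empty target set")
        if k < 8:
            raise ValueError(f"seed length {k} too unspecific (minimum 8)")
        self.k = k
        # collapse duplicated junctions (same coords + kind) before indexing
        collapsed: dict[tuple, JunctionTarget] = {}
        for t in targets:
            collapsed.setdefault((t.kind,) + t.coords, t)
        self.targets: list[JunctionTarget] = list(collapsed.values())
        self.postings: dict[str, list[tuple[int, int]]] = {}
        for tidx, t in enumerate(self.targets):
            seq = t.sequence
            for off in range(len(seq) - k + 1):
                kmer = seq[off : off + k]
                if "N" in kmer:
                    continue
                self.postings.setdefault(kmer, []).append((tidx, off))

    @property
    def n_postings(self) -> int:
        return sum(len(v) for v in self.postings.values())


def build_index(targets: list[JunctionTarget], k: int = DEFAULT_K) -> JunctionIndex:
    """Build the k-mer junction index (k must satisfy 2k <= read length for
    the <= 1-mismatch search to be exhaustive)."""
    return JunctionIndex(targets, k)


def _count_mismatches(read: str, target: str, start: int, limit: int):
    """Mismatch positions of an ungapped full-length placement, aborting
    once more than ``limit`` are seen (returns None on abort)."""
    L = len(read)
    window = target[start : start + L]
    if read == window and "N" not in read:
        return []
    positions = []
    for i in range(L):
        a = read[i]
        b = window[i]
        if a != b or a == "N":
            positions.append(start + i)
            if len(positions) > limit:
                return None
    return positions


def align_read(
    read: ShortRead,
    index: JunctionIndex,
    max_mismatches: int = 1,
):
    """Align one read; returns a :class:`JunctionAlignment` or a
    :class:`Rejection` carrying the reason."""
    seq = read.sequence
    L = len(seq)
    k = index.k
    if L < k:
        return Rejection(read.read_id, NO_HIT)

    candidates: set[tuple[int, int]] = set()
    any_posting = False
    clipped_only = False
    for s in range(L - k + 1):
        kmer = seq[s : s + k]
        postings = index.postings.get(kmer)
        if not postings:
            continue
        any_posting = True
        for tidx, off in postings:
            candidates.add((tidx, off - s))

    placements = []  # (mismatch_count, tidx, start, positions)
    for tidx, start in candidates:
        target = index.targets[tidx]
        if start < 0 or start + L > len(target.sequence):
            clipped_only = True
            continue
        positions = _count_mismatches(seq, target.sequence, start, max_mismatches)
        if positions is not None:
            placements.append((len(positions), tidx, start, positions))

    if not placements:
        if any_posting and clipped_only:
            return Rejection(read.read_id, CLIPPED)
        if any_posting:
            return Rejection(read.read_id, TOO_MANY_MISMATCHES)
        return Rejection(read.read_id, NO_HIT)

    best = min(p[0] for p in placements)
    winners = [p for p in placements if p[0] == best]
    junctions = {p[1] for p in winners}
    if len(junctions) > 1:
        return Rejection(read.read_id, MULTI_MAPPED)

    _, tidx, start, positions = min(winners)
    target = index.targets[tidx]
    left = target.junction_offset - start
    right = L - left
    if left < 1 or right < 1:
        return Rejection(read.read_id, NO_JUNCTION_OVERLAP)
    return JunctionAlignment(
        read_id=read.read_id,
        sample_id=read.sample_id,
        junction_id=target.junction_id,
        target_offset=start,
        mismatch_positions=frozenset(positions),
        left_overhang=left,
        right_overhang=right,
    )


def best_hit_mismatches(
    seq: str, index: JunctionIndex, max_mismatches: int = 1
) -> int | None:
    """Minimum mismatch count of *any* full-length placement of ``seq`` on
    the index (uniqueness and junction overlap not required), or None when
    no placement achieves <= max_mismatches.  Used to ask whether an
    intragenic target admits the read at least as well as a TIC target."""
    L, k = len(seq), index.k
    if L < k:
        return None
    best: int | None = None
    seen: set[tuple[int, int]] = set()
    for s in range(L - k + 1):
        postings = index.postings.get(seq[s : s + k])
        if not postings:
            continue
        for tidx, off in postings:
            start = off - s
            if (tidx, start) in seen:
                continue
            seen.add((tidx, start))
            target = index.targets[tidx]
            if start < 0 or start + L > len(target.sequence):
                continue
            positions = _count_mismatches(
                seq, target.sequence, start, max_mismatches
            )
            if positions is not None:
                n = len(positions)
                if best is None or n < best:
                    best = n
                    if best == 0:
                        return 0
    return best


def supports_junction(alignment: JunctionAlignment, overhang_min: int) -> bool:
    """Does the alignment extend past the junction midpoint by at least
    ``overhang_min`` nt on both sides?  Default thresholds in the pipeline
    are 8 for TIC/control candidates and 11 for intragenic reporting."""
    return alignment.min_overhang >= overhang_min


def prefer_intragenic(
    tic_alignment: JunctionAlignment,
    read_seq: str,
    intragenic_index: JunctionIndex,
    max_mismatches: int = 1,
) -> bool:
    """Keep (True) or drop (False) a TIC alignment given the intragenic
    target library.  The alignment is dropped when any intragenic target
    admits the read with no more mismatches than the TIC placement (ties
    are dropped: the conservative choice)."""
    best = best_hit_mismatches(read_seq, intragenic_index, max_mismatches)
    if best is None:
        return True
    return best > tic_alignment.n_mismatches


def align_reads(
    reads,
    index: JunctionIndex,
    max_mismatches: int = 1,
):
    """Align an iterable of reads; returns (alignments, rejection counts).

    The result is independent of read order; alignments are returned in
    read order for reproducibility of downstream reports.
    """
    alignments: list[JunctionAlignment] = []
    reasons: dict[str, int] = {}
    for read in reads:
        result = align_read(read, index, max_mismatches)
        if isinstance(result, JunctionAlignment):
            alignments.append(result)
        else:
            reasons[result.reason] = reasons.get(result.reason, 0) + 1
    return alignments, reasons


def read_fastq(path: str, sample_id: str = "S1"):
    """Load FASTQ (or FASTA) reads as :class:`ShortRead` objects."""
    from Bio import SeqIO

    fmt = "fasta"
    with open(path) as fh:
        first = fh.read(1)
        if first == "@":
            fmt = "fastq"
    reads = []
    for rec in SeqIO.parse(path, fmt):
        reads.append(
            ShortRead(
                read_id=rec.id,
                sequence=str(rec.seq).upper(),
                sample_id=sample_id,
            )
        )
    return reads


def write_alignments_tsv(alignments, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(
            "read_id\tsample_id\tjunction_id\ttarget_offset\t"
            "n_mismatches\tleft_overhang\tright_overhang\n"
        )
        for a in alignments:
            fh.write(
                f"{a.read_id}\t{a.sample_id}\t{a.junction_id}\t"
                f"{a.target_offset}\t{a.n_mismatches}\t"
                f"{a.left_overhang}\t{a.right_overhang}\n"
            )
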