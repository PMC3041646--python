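"""Coding potential of chimeric transcripts.

A readthrough chimera is assembled by concatenating exons 1..d of the 5'
transcript, an optional intervening exon, and exons a..n of the 3'
transcript.  Its coding region is predicted as follows: if the 5' gene's
original start codon survives in the chimera, translation extends from it
to the first in-frame stop; otherwise a new start is predicted from the
longest open reading frame.  The resulting frame classes are

* ``full_cds``  - the stop coincides with the 3' gene's original stop,
* ``shift_3p``  - translation from the original start runs out of the 3'
                  gene's frame,
* ``new_tss``   - the breakpoint precedes the original start codon.

Termination is classified TLE (stop in the last exon) or PTC (premature
termination codon, before the last exon) - PTC transcripts are expected
substrates of nonsense-mediated decay.

Domain preservation compares a chimeric protein with the original proteins
by exact prefix/suffix identity: a 5' domain survives iff its interval lies
within the longest common prefix of the chimeric and original 5' proteins,
a 3' domain iff within the longest common suffix against the 3' protein.
Junction-spanning codons belong to neither.  Statuses follow the
ND / Null / Subset / Cover scheme (no original domains / none preserved /
some / all).
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field

from Bio.Seq import Seq, reverse_complement

from .genome_model import GeneModel, Transcript, fetch

STOP_CODONS = ("TAA", "TAG", "TGA")
DEFAULT_MIN_ORF_CODONS = 30


@dataclass
class ExonSegment:
    chrom: str
    strand: str
    start: int
    end: int
    source: str  # "5p" | "intervening" | "3p"


@dataclass
class ChimericTranscript:
    segments: list[ExonSegment]
    sequence: str
    junction_positions: list[int]  # transcript coordinate of each splice
    last_exon_start: int
    five_prime_len: int  # length of the 5'-gene portion
    intervening_len: int
    three_prime_offset: int  # 3' transcript coordinate where the suffix starts
    transcript5: Transcript | None = None
    transcript3: Transcript | None = None


@dataclass
class CdsCall:
    start_class: str  # "original_tss" | "new_tss"
    cds_interval: tuple[int, int] | None  # transcript coords, stop included
    frame_class: str  # "full_cds" | "shift_3p" | "new_tss"
    termination_class: str  # "TLE" | "PTC"
    protein: str
    stop_pos: int | None = None  # transcript coordinate of the stop codon
    nmd_flag: bool = False
    noncoding: bool = False


@dataclass
class DomainInterval:
    name: str
    start: int  # 1-based aa, inclusive
    end: int


@dataclass
class DomainComparison:
    side: str  # "5p" | "3p"
    status: str  # "ND" | "Null" | "Subset" | "Cover"
    preserved: set[str]
    original: set[str]


def assemble_chimera(
    transcript5: Transcript,
    donor_exon_index: int,
    transcript3: Transcript,
    acceptor_exon_index: int,
    genome: dict[str, str],
    intervening_exon: tuple[str, str, int, int] | None = None,
) -> ChimericTranscript:
    """Concatenate exons 1..donor of the 5' transcript, the optional
    intervening exon (chrom, strand, start, end), and exons acceptor..n of
    the 3' transcript."""
    if not 1 <= donor_exon_index <= transcript5.exon_count:
        raise IndexError(
            f"donor exon index {donor_exon_index} out of range for "
            f"{transcript5.accession}"
        )
    if not 1 <= acceptor_exon_index <= transcript3.exon_count:
        raise IndexError(
            f"acceptor exon index {acceptor_exon_index} out of range for "
            f"{transcript3.accession}"
        )
    segments: list[ExonSegment] = []
    parts: list[str] = []

    def add(chrom, strand, start, end, source):
        s = fetch(genome, chrom, start, end)
        parts.append(s if strand == "+" else reverse_complement(s))
        segments.append(ExonSegment(chrom, strand, start, end, source))

    for start, end in transcript5.exons[:donor_exon_index]:
        add(transcript5.chrom, transcript5.strand, start, end, "5p")
    if intervening_exon is not None:
        add(*intervening_exon, "intervening")
    for start, end in transcript3.exons[acceptor_exon_index - 1 :]:
        add(transcript3.chrom, transcript3.strand, start, end, "3p")

    lengths = [seg.end - seg.start for seg in segments]
    junctions, pos = [], 0
    for ln in lengths[:-1]:
        pos += ln
        junctions.append(pos)
    five_len = sum(
        e - s for s, e in transcript5.exons[:donor_exon_index]
    )
    iv_len = 0 if intervening_exon is None else (
        intervening_exon[3] - intervening_exon[2]
    )
    three_off = sum(
        e - s for s, e in transcript3.exons[: acceptor_exon_index - 1]
    )
    return ChimericTranscript(
        segments=segments,
        sequence="".join(parts),
        junction_positions=junctions,
        last_exon_start=sum(lengths[:-1]),
        five_prime_len=five_len,
        intervening_len=iv_len,
        three_prime_offset=three_off,
        transcript5=transcript5,
        transcript3=transcript3,
    )


def _first_stop_in_frame(seq: str, start: int) -> int | None:
    """Transcript coordinate of the first in-frame stop codon at/after start."""
    for pos in range(start, len(seq) - 2, 3):
        if seq[pos : pos + 3] in STOP_CODONS:
            return pos
    return None


def _longest_orf(seq: str, min_codons: int) -> tuple[int, int | None] | None:
    """Longest ATG-initiated open reading frame; ties broken by the 5'-most
    start.  Returns (start, stop or None-when-running-to-the-end)."""
    stops_by_frame: list[list[int]] = [[], [], []]
    for pos in range(len(seq) - 2):
        if seq[pos : pos + 3] in STOP_CODONS:
            stops_by_frame[pos % 3].append(pos)
    best: tuple[int, int, int | None] | None = None  # (-codons, start, stop)
    for pos in range(len(seq) - 2):
        if seq[pos : pos + 3] != "ATG":
            continue
        stops = stops_by_frame[pos % 3]
        i = bisect_left(stops, pos)
        stop = stops[i] if i < len(stops) else None
        end = stop if stop is not None else pos + ((len(seq) - pos) // 3) * 3
        codons = (end - pos) // 3
        if codons < min_codons:
            continue
        key = (-codons, pos, stop)
        if best is None or key < best:
            best = key
    if best is None:
        return None
    return best[1], best[2]


def translate(seq: str) -> str:
    """Translate a CDS (without its stop codon) into protein."""
    usable = seq[: (len(seq) // 3) * 3]
    return str(Seq(usable).translate())


def predict_cds(
    chimera: ChimericTranscript,
    cds5: tuple[int, int] | None,
    cds3: tuple[int, int] | None,
    min_orf_codons: int = DEFAULT_MIN_ORF_CODONS,
) -> CdsCall:
    """Predict the chimera's coding region, frame class and NMD status.

    ``cds5``/``cds3`` are the original CDS intervals in the 5'/3' parent
    transcript coordinates (stop codon included).  When translation starts
    from the retained original start, an ATG is required there.
    """
    seq = chimera.sequence
    P = chimera.five_prime_len

    original_start_retained = cds5 is not None and cds5[0] + 3 <= P
    if original_start_retained:
        start = cds5[0]
        if seq[start : start + 3] != "ATG":
            raise ValueError(
                "no start codon at the 5' CDS start of the assembled chimera"
            )
        start_class = "original_tss"
        stop = _first_stop_in_frame(seq, start + 3)
    else:
        start_class = "new_tss"
        orf = _longest_orf(seq, min_orf_codons)
        if orf is None:
            return CdsCall(
                start_class="new_tss",
                cds_interval=None,
                frame_class="new_tss",
                termination_class="TLE",
                protein="",
                noncoding=True,
            )
        start, stop = orf

    # the 3' gene's original stop codon mapped into chimera coordinates
    stop3_pos = None
    if cds3 is not None and cds3[1] - 3 >= chimera.three_prime_offset:
        stop3_pos = (
            P + chimera.intervening_len + (cds3[1] - 3 - chimera.three_prime_offset)
        )

    if start_class == "new_tss":
        frame_class = "new_tss"
    elif stop is not None and stop3_pos is not None and stop == stop3_pos:
        frame_class = "full_cds"
    else:
        frame_class = "shift_3p"

    if stop is None:
        termination = "TLE"  # runs to the transcript end (no stop codon)
        cds_end = start + ((len(seq) - start) // 3) * 3
        protein = translate(seq[start:cds_end])
        interval = (start, cds_end)
        stop_coord = None
    else:
        termination = "PTC" if stop < chimera.last_exon_start else "TLE"
        protein = translate(seq[start:stop])
        interval = (start, stop + 3)
        stop_coord = stop

    return CdsCall(
        start_class=start_class,
        cds_interval=interval,
        frame_class=frame_class,
        termination_class=termination,
        protein=protein,
        stop_pos=stop_coord,
        nmd_flag=termination == "PTC",
    )


def intervening_exon_frame_effect(
    call_with: CdsCall,
    call_without: CdsCall,
    exon_length: int,
    exon_end_in_chimera: int,
) -> str:
    """Effect of an intervening exon on the chimera's coding potential.

    Compares the coding calls of the chimera with and without the exon:
    ``out_of_frame`` (3' frame lost), ``into_frame`` (3' frame restored),
    ``stop_to_different_stop`` (one premature stop replaced by another), or
    ``no_effect`` (including the case where translation starts from a new
    TSS downstream of the exon).
    """
    if (
        call_with.start_class == "new_tss"
        and call_with.cds_interval is not None
        and call_with.cds_interval[0] >= exon_end_in_chimera
    ):
        return "no_effect"
    without_in_frame = call_without.frame_class == "full_cds"
    with_in_frame = call_with.frame_class == "full_cds"
    if without_in_frame and not with_in_frame:
        return "out_of_frame"
    if not without_in_frame and with_in_frame:
        return "into_frame"
    if (
        call_with.termination_class == "PTC"
        and call_without.termination_class == "PTC"
    ):
        # same stop iff the with-exon stop is the without-exon stop shifted
        # by the exon length (stops upstream of the exon are unshifted)
        if call_with.stop_pos is not None and call_without.stop_pos is not None:
            shifted = call_with.stop_pos - exon_length == call_without.stop_pos
            same = call_with.stop_pos == call_without.stop_pos or shifted
            if not same:
                return "stop_to_different_stop"
    return "no_effect"


def _common_prefix_len(a: str, b: str) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            break
        n += 1
    return n


def _common_suffix_len(a: str, b: str) -> int:
    return _common_prefix_len(a[::-1], b[::-1])


def _status(preserved: set[str], original: set[str]) -> str:
    if not original:
        return "ND"
    if not preserved:
        return "Null"
    if preserved == original:
        return "Cover"
    return "Subset"


def compare_domains(
    domains5: list[DomainInterval],
    domains3: list[DomainInterval],
    protein5: str,
    protein3: str,
    call: CdsCall,
) -> tuple[DomainComparison, DomainComparison]:
    """Domain preservation on the 5' and 3' sides of a chimeric protein."""
    for d in domains5:
        if not 1 <= d.start <= d.end <= len(protein5):
            raise ValueError(
                f"domain {d.name} [{d.start},{d.end}] outside 5' protein "
                f"of length {len(protein5)}"
            )
    for d in domains3:
        if not 1 <= d.start <= d.end <= len(protein3):
            raise ValueError(
                f"domain {d.name} [{d.start},{d.end}] outside 3' protein "
                f"of length {len(protein3)}"
            )
    prefix = _common_prefix_len(call.protein, protein5)
    preserved5 = {d.name for d in domains5 if d.end <= prefix}
    if call.termination_class == "PTC":
        preserved3: set[str] = set()
    else:
        suffix = _common_suffix_len(call.protein, protein3)
        cut = len(protein3) - suffix  # first preserved aa index (0-based)
        preserved3 = {d.name for d in domains3 if d.start - 1 >= cut}
    orig5 = {d.name for d in domains5}
    orig3 = {d.name for d in domains3}
    return (
        DomainComparison("5p", _status(preserved5, orig5), preserved5, orig5),
        DomainComparison("3p", _status(preserved3, orig3), preserved3, orig3),
    )


def read_domain_table(path: str) -> dict[str, list[DomainInterval]]:
    """TSV of (protein_id, domain_name, aa_start, aa_end[, score])."""
    import pandas as pd

    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        names=["protein_id", "domain_name", "aa_start", "aa_end"],
        header=None,
        usecols=[0, 1, 2, 3],
    )
    # tolerate an optional header row
    df = df[pd.to_numeric(df["aa_start"], errors="coerce").notna()]
    tables: dict[str, list[DomainInterval]] = {}
    for row in df.itertuples(index=False):
        tables.setdefault(row.protein_id, []).append(
            DomainInterval(row.domain_name, int(row.aa_start), int(row.aa_end))
        )
    return tables


def original_protein(transcript: Transcript, genome: dict[str, str]) -> str:
    """Protein of the parent transcript's annotated CDS (stop trimmed)."""
    if transcript.cds is None:
        raise ValueError(f"{transcript.accession} has no annotated CDS")
    seq = transcript.sequence(genome)[transcript.cds[0] : transcript.cds[1]]
    if seq[-3:] in STOP_CODONS:
        seq = seq[:-3]
    return translate(seq)
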