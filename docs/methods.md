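# Methods notes

This note documents the models, parameter choices, numerical decisions and
known limitations of `ticfinder`, in the order the pipeline runs.

## Gene model and splice-site catalogs

Coordinates are 0-based half-open internally; emitted reports use 1-based
inclusive coordinates. A splice site is the boundary coordinate between the
exonic and intronic base: on the plus strand a donor sits at the exon's
half-open end and an acceptor at the exon's start; the two boundaries swap
roles on the minus strand. Terminal exon boundaries (transcript start/end)
are not splice sites, so single-exon genes contribute no sites and cannot
participate in readthrough calls. Sites are deduplicated by
(chrom, strand, position, kind) with exon labels merged over all isoforms;
exon counts differ between truncated isoforms, so labels such as "e4/5" are
reported per transcript rather than for a chosen canonical isoform. "Same
gene" is decided by the annotation's `gene_id` attribute; coding status by
the accession prefix ("NM_") or a configurable attribute. Canonical GT/AG
intron motifs are *not* enforced on input annotations (the synthetic
generator writes them, but real annotations need not obey them).

## Junction targets

* Intragenic: every ordered exon pair (i, j), i < j, within a transcript,
  regardless of distance, deduplicated across isoforms by junction
  coordinates.
* Readthrough (TIC): every donor–acceptor pair on one strand with
  0 < distance ≤ 200,000 bp whose sites share no transcript. The pairing
  predicate is deliberately *not* gene adjacency, so pairs that skip an
  intervening gene are generated; a `strict_adjacency` flag (off by
  default) removes pairs whose interval wholly contains another gene.
* Flanks: 80 nt per side measured along the *spliced* transcript, crossing
  exon boundaries when the junction exon is short, using the transcript
  that yields the longest flank (ties broken by lexicographic accession).
  This maximises alignable context and is deterministic; flanks truncated
  at a transcript end are flagged, not errors.
* Controls: each target with ≥ 10 nt per side loses the bases at positions
  −10..−6 and +6..+10 relative to the junction (the five junction-proximal
  bases on each side are kept and rejoined to the shifted distal sequence).
  A genuine junction read overlapping the junction by ≥ 8 nt on each side
  therefore cannot match its control without accumulating roughly five or
  more mismatches, making the control library an alignment-level null.

## Junction aligner

Exact k-mer postings (k = 12 by default) over targets collapsed by junction
coordinates; every read k-mer seeds an ungapped, full-length extension.
Acceptance requires a unique best junction at ≤ 1 mismatch that crosses the
junction midpoint; ties across distinct junctions are rejected as
multi-mapped (the conservative choice), and uniqueness is evaluated over
collapsed junctions so duplicate isoform targets cannot destroy it. N bases
never match. For reads of length L ≥ 2k the seed search is exhaustive for
the ≤ 1-mismatch acceptance set (one error leaves an exact k-mer on one
side); the library precondition k ≤ L/2 enforces this. Qualities are
ignored throughout. A TIC alignment is discarded whenever any intragenic
target admits the same read with no more mismatches (ties drop), which
suppresses false TIC hits from ordinary alternative splicing.

Overhang thresholds: 8 nt per side for TIC/control candidates, 11 nt for
intragenic reporting. For uniform junction crossings of a length-L read the
supported fraction at threshold k is (L − 2k + 1)/(L − 1).

## Event calling

Filters run in the order: intragenic-equivalence (drop junctions whose
donor and acceptor gene sets intersect) → intragenic preference → overhang
≥ 8 → clustering by junction → consistency → homology; stage counts are
logged for attrition reports. The consistency rule requires, for the first
11 positions on *both* sides of the junction, at least one covering read
that matches the target there, and additionally vetoes any covered position
that every covering read mismatches. For a singleton cluster this reduces
to "one read matches all 11 bp on both sides"; it also means a lone read
with a sequencing error at a position it alone covers fails the cluster —
a deliberate strictness that trades a few percent recall for robustness to
consistent misalignment. (The alternative reading — "same-base mismatch in
two or more reads" — is weaker and was not adopted.)

Homology screening uses local alignment (match +1, mismatch −1, gap open
−2, gap extend −1; all configurable). The junction fragment (longest
observed left + right overhangs concatenated) fails if its *identity*
columns cover ≥ 90% of its length against any component-gene transcript.
Identities, not aligned columns, are counted: an optimal local trace will
gap-bridge chance matches across the non-homologous half of a genuine
chimeric fragment, so a matches-plus-mismatches coverage measure rejects
true events systematically, while an identity measure reproduces the
intended cases exactly (a verbatim substring scores 100%; paralogs at 92%
identity score ≈ 92%; a genuine junction scores ≈ 50–70%). The gene-pair
screen fails on any 50-column window containing ≥ 40 matches in the best
local alignment trace of any 5′-gene vs 3′-gene transcript pair.

FDR: the identical cascade runs against the control library;
fdr = n_control / n_real, rendered as a percentage to one decimal, NA when
no events were accepted.

## Split-read taxonomy and intervening exons

The decision order — translocation (different chromosomes) > inversion
(opposite strands) > scrambled (acceptor upstream of the donor in
transcription orientation) > long-range (> 200 kb) > readthrough
(different genes) > intragenic — is fixed so every record receives exactly
one label; the order itself is a design choice, since geometry alone does
not force one. Records with unassignable genes keep their geometric
category with genes reported as NA. Distant categories require ≥ 2
supporting reads; readthrough calls tolerate single reads (the asymmetric
evidence policy: the prior for a local same-strand readthrough is far
higher than for a distant rearrangement). The canonical input is a
10-column TSV of segment pairs; SAM records with N CIGAR operations are
also accepted (split at the largest gap). Producing spliced alignments is
out of scope — records are consumed, not computed, except by the
simulator.

Intervening-exon (TICIE) detection pairs, per sample, a known-donor→novel-
acceptor splice with a novel-donor→known-acceptor splice whose novel sites
delimit an interval of 1..300 bp in transcription orientation, both splices
≤ 200 kb, known sites on different coding genes, and the gene pair passing
the homology screen. Pairs may come from different reads within a sample
(the read lengths make same-read support unlikely); same-read support is
flagged separately. The intervening interval is classified by ≥ 1-bp
overlap against the 5′ gene's last exon, then the 3′ gene's first exon,
then any other exon, else intergenic.

## Coding potential and domains

Chimeras concatenate exons 1..d of the 5′ transcript, an optional
intervening exon, and exons a..n of the 3′ transcript. If the 5′ CDS start
codon is wholly retained, translation proceeds from it to the first
in-frame stop; `full_cds` means that stop coincides with the 3′ gene's
original stop mapped into the chimera, otherwise `shift_3p`. If the
breakpoint precedes the start codon, the longest ATG-initiated open
reading frame is used (`new_tss`), ties broken by the 5′-most start, with
a minimum of 30 codons (configurable) to avoid micro-ORFs; with no
qualifying ORF the chimera is flagged noncoding. Stops are TAA/TAG/TGA;
starts strictly ATG. Termination is PTC when the stop codon begins before
the last exon's first base, else TLE; PTC flags the transcript as an NMD
substrate. Intervening-exon effects compare the with/without calls:
out-of-frame, into-frame, stop-to-different-stop (premature stops that do
not correspond under the exon-length shift), or no effect (including a new
TSS downstream of the exon).

Domain preservation is decided by interval containment in the longest
common prefix (5′ side) / suffix (3′ side) of the chimeric and original
proteins; junction-spanning codons belong to neither, and PTC chimeras
preserve no 3′ domains. This replaces an HMM re-scan of the chimeric
protein while keeping the same comparison semantics; a hook accepts
externally produced chimeric domain tables for users who want the scan.

## Expression and efficiency

RPKM = exon reads / (kilobases of merged exonic sequence × million total
reads); a read overlapping merged exons of two genes counts toward both
(fractional assignment is a configuration choice left to the caller).
TIC splice expression from RNA-Seq is a read-count proxy (the original
measurements behind the efficiency figures were qRT-PCR): the efficiency
estimator divides junction-supporting reads by the number of supporting
placements (L − 2·8 + 1) and the 5′-gene reads by its start-position count
(L_t − L + 1) before taking the ratio, which makes the estimate an
unbiased per-transcript splice-through probability under uniform sampling.
The conditioned expression report restricts both the with- and without-TIC
distributions to genes with an observed intragenic splice in the sample
and a potential partner within 200 kb, per side.

## Synthetic data

The generator emulates: exponential intergenic distances (default mean
4 kb above a 300-bp minimum — desk-scale stand-ins for the exponential
splice-distance regime), read lengths 33/50/75 nt, i.i.d. substitution
errors at 1% by default, log-normal expression, the (n−1)→+2 pattern at
weight 0.54 (with 0.25 / 0.10 / 0.11 for the alternative donor/acceptor
categories), a second TIC isoform sharing one site for 11% of gene pairs,
TICIE exons of ≤ 300 bp, one distant fusion per requested category, and
decoy paralog pairs at 92% identity. Genes have controlled coding
structure (ATG, stop-free codon body, stop inside the last exon) so
frame-class expectations are exact by construction; all annotated introns
carry GT/AG. Chimera abundance is ε × the 5′ gene's abundance — the
leakage model of readthrough transcription — and read counts are
multinomial over abundance × start positions, so expected junction support
is analytic (`expected_junction_support`). Split records are emitted for
junction reads with ≥ 14-nt anchors, emulating spliced-aligner
detectability without requiring an aligner.

Decoy pairs deserve a note: with error-free reads no read would ever cross
a paralog junction, so a decoy with no transcript would exercise the
homology filter only through rare error coincidences. The generator
therefore emits a *decoy chimeric transcript* (marked `decoy` in the truth
manifest and excluded from expected recoveries) so paralog-junction reads
deterministically reach — and must be rejected by — the homology filter.

What passing tests on these data do **not** show: robustness to indels,
quality-correlated errors, PCR duplicates, alternative polyadenylation or
alternative TSS (which can change the predicted last exon and CDS), repeat-
and low-complexity-rich genomes, or annotation errors. Those belong to
real-data validation.

## Problem sizes and determinism

Test and acceptance runs use desk-scale problems chosen as the package's
own study conditions: recovery runs use ~60 genes with 20 planted
readthroughs whose expected junction support is ≈ 15–25 reads (well above
the regime of λ near 3, where Poisson zero-counts and the strict
consistency rule would make single-event recovery a coin flip rather than
a test of the method); efficiency recovery uses a 10⁶-read library with short (~130-nt),
highly expressed upstream transcripts so that even ε = 10⁻⁴ yields a
junction Poisson mean ≫ 1 — a fixture requirement that follows from the
arithmetic ε × coverage, not a property of the estimator. All randomness
flows from per-stage `numpy.random.default_rng` streams derived from one
seed; outputs are byte-identical across runs and platforms.

## Known limitations

* Converging/diverging (opposite-strand) local fusions are out of scope by
  design, as is genome-wide all-pairs junction enumeration (quadratic in
  site count).
* The homology screen evaluates the best local alignment trace only; a
  40/50 window hiding in a suboptimal alignment is not seen.
* The aligner is ungapped and quality-blind; indel-containing junction
  reads are rejected rather than rescued.
* Single-end logic throughout; no mate-pair evidence is modelled.
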