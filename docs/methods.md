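# Methods

`repeataudit` audits how completely a chromosome-scale assembly represents
the repeat fraction of a genome. It estimates repeat abundance directly
from raw data — long reads, optical-map molecules, Hi-C contact matrices,
ChIP/input libraries — and compares those estimates with what the assembly
contains. Every analysis step can be exercised on synthetic data with exact
ground truth; this note describes the models, the estimators, the defaults,
and what the synthetic experiments do and do not demonstrate.

## Coverage-normalized abundance

The central quantity is the *non-redundant size* of a repeat class: the
cumulative length of that repeat observed across reads, divided by the
sequencing depth,

    total_bp = cumulative_observed / depth,        per_unit = total_bp / n_units

with `n_units` = 14 chromosome arms or 7 chromosomes. The estimator is
unbiased when coverage is uniform; arrays clipped by read ends are counted
at their observed length, so very long arrays (longer than the read length)
are systematically underestimated — an inherent property of read-based
repeat sizing, not a defect of the implementation. Which depth to use
(mean/median/mode, dataset-wide) is the caller's choice; the synthetic
pipelines use the realized depth (total read bases / genome length), making
the recovery tests self-consistent. Uncertainty is quantified by a
bootstrap over reads (resampling per-read cumulative observations, 200
replicates by default).

## Tandem array detection

Arrays with motifs up to 2 kb are detected by self-comparison:

1. **Candidate periods.** Periods ≤ 60 bp are tested directly by comparing
   the sequence with itself at lag *p*; larger periods are proposed by
   recurrence distances of exact 21-mers.
2. **Candidate regions.** A moving average (window = max(16, 2p)) of the
   lag-match indicator must exceed `max(2·min_purity − 1, 0.55)`; regions
   separated by short sub-threshold dips (local error clusters) are
   bridged.
3. **Refinement.** A majority-vote consensus motif is built from the
   candidate core; the interval is extended while the running score
   (match − min_purity per base) stays profitable and then snapped so that
   both boundaries sit on a run of up to six consecutive consensus matches.
   Purity is the fraction of bases matching the consensus tiling; N never
   matches, and arrays are split at runs of ≥ 10 Ns.
4. **Reporting.** Overlapping candidates are resolved by preferring the
   smallest period whose purity is within 0.02 of the local maximum (the
   primitive motif over its multiples), intervals are made disjoint, the
   motif is canonicalized (lexicographic minimum over all rotations of the
   motif and its reverse complement), and `copy_count` is interval length /
   motif length.

Default `min_purity` is 0.8. The detector is a deliberate simplification
of alignment-based tandem repeat finders: no parity with any external tool
is promised; the contract, enforced by tests, is exact recovery of planted
arrays on clean sequence and interval recovery within a few bases at 5%
substitution divergence.

## Monomer quantification

Known monomers (subtelomeric 118 bp and 336 bp satellites, the 809 bp
retroelement integrase domain, a ~7 kb complete element, 8.9/9.8 kb rDNA
units, the 120 bp 5S gene) are located by exact 11-mer seeds shared on a
diagonal (support ≥ 2), verified with edlib edit-distance alignment of the
seed-supported monomer span (± 30 bp margin), and end-trimmed to the best
local block under a +1 match / −2 mismatch-or-gap column score. Identity is
matches / alignment columns, so gaps count as non-matches; a policy
(minimum alignment length, minimum identity) filters hits per monomer.
Eleven-base seeds were chosen because short monomer copies at 5%
divergence frequently contain no clean 15-mer, which costs recall exactly
where the recovery tests look. Overlapping hits are merged for
cumulative-length accounting but counted individually for copy-number
summaries.

rDNA-bearing reads are classified {both, 5H_only, 6H_only, none} from
policy-filtered hits against the two unit references. The synthetic unit
pair shares an 8 kb core (the length difference is an intergenic-spacer
insertion), so reads from either locus align to both references above a
5 kb / 90% policy — mirroring the situation in real data where the two
units differ mainly in spacer length.

## Read placement

Reads are placed by assembly-unique k-mers (k = 51 by default, identified
via a 64-bit polynomial rolling hash; collisions are negligible at the
tens-of-megabases scale this package targets). A read is **unique** when
≥ 3 unique anchors on one strand agree on an offset within ± 500 bp,
**ambiguous** when anchors conflict, **unplaced** otherwise. This
trichotomy stands in for a full aligner's mapping-quality cuts; it cannot
reproduce graded MAPQ thresholds. Distance-to-feature classification
measures from the placement position to the nearest interval edge, ties
counting as "near"; ambiguous reads are reported with the unplaced
fraction, as a mapper would leave them below the confidence cut.

## Genome size estimation

*Depth route:* GSE = total sequenced bases / median alignment depth, with
depths summarized in 1 kb windows; the mode depth is computed on 0.1-fold
bins. *Chloroplast correction:* reads whose merged cp-seed coverage spans
≥ 90% of the read are flagged and their bases subtracted from the total
before division.

*k-mer route (simplified):* canonical k-mer multiplicity histogram; the
error cutoff is the first local minimum of the 5-point-smoothed spectrum;
the homozygous peak is the smoothed mode above it. Because a finite read
sample leaves the raw histogram lumpy (coverage is correlated along
reads), the peak depth is refined to the count-weighted mean multiplicity
over [mode/2, 1.5·mode]. GSE = k-mer mass above the cutoff / peak depth.
If no peak rises above the valley the estimator refuses
("spectrum uninformative") rather than guessing — the expected outcome for
high-error long reads at k = 21. Heterozygosity and the iterative
spectrum-fitting refinements of dedicated tools are intentionally out of
scope; the acceptance surface is recovery on synthetic data.

## Optical-map profiling

Label-spacing runs are maximal blocks of consecutive inter-label intervals
each within a *strict* relative tolerance (default 0.1) of the block's
median interval; blocks need ≥ 6 intervals, cannot be extended in either
direction, and molecules < 150 kb are discarded first. The strictness
matters at the boundary: an interval exactly at tolerance breaks a run.
Unit sizes are corrected for the map's stretch (default coefficient 0.952,
undoing a 4.8% expansion) and histogrammed weighted by interval count; the
45S class defaults to corrected sizes in [8 400, 10 100) bp.

For locus sizing, class totals count *spanned units*: a run of n intervals
touches n + 1 labels, i.e. about n + 1 units of the underlying array;
counting bare intervals would understate coverage-normalized locus sizes
by one unit per molecule (≈ 3% at the simulated molecule lengths). Locus
size = class base total / coverage. In the synthetic experiments the
denominator is the realized coverage over the locus computed from molecule
provenance, because on a small toy genome interior loci are covered ~10%
above the genome-wide average (molecules cannot overhang chromosome ends);
on a real dataset, where the genome is thousands of times longer than a
molecule, the genome-wide coverage is the natural choice.

## Hi-C directionality and centromere calling

For bin *b*, with A and B the contact sums to the w = 20 bins up- and
downstream (windows symmetrically truncated at matrix edges) and
E = (A+B)/2:

    DI(b) = sign(B − A) · ((A − E)² + (B − E)²) / E,    DI = 0 if E = 0 or A = B.

In a Rabl-configured chromosome DI is positive on the short-arm side of
the centromere and negative beyond it; the centromere is called at the
sign-changing transition with the largest |ΔDI|, returning the crossing
bin and the jump magnitude as a confidence score. Callers must check the
score: without an anti-diagonal (no Rabl signal) the maximal jump is noise
and an order of magnitude smaller than a true flip.

The synthetic matrix model is E[i,j] = f(|i−j|) + w_rabl · f(|i+j−2c|)
with f(d) = exp(−rate·d) and symmetric multiplicative noise. The default
decay rate 0.5 per bin gives a ridge a couple of bins wide; with a much
broader ridge the DI crossing becomes gradual and the largest-jump rule is
dominated by noise — real barley-like contact maps show a narrow cross,
and the generator models that regime.

## ChIP/input enrichment

Each read is assigned to the repeat class of its best qualifying monomer
alignment (background otherwise); the per-class ratio is
(chip_count/chip_total)/(input_count/input_total). If a class occupies a
fraction *f* of the genome and ChIP enriches it by factor *w*, the expected
measured ratio is w/(1 + (w−1)f) — only ≈ w for small f. The generator
allocates per-class read counts by largest-remainder quota on the per-base
weight mass (positions uniform within class intervals), so realized class
proportions equal their expectation exactly; with multinomial sampling the
input count of a sub-percent class (a few hundred reads) would dominate
the variance of the ratio and swamp the quantity under test. The null
(all factors 1) therefore yields a ratio of exactly 1 up to classification
error.

## Gap audit

Gaps are maximal runs of ≥ 10 consecutive Ns (the threshold is a
convention; datasets define gaps upstream of this package). Each gap's
1 kb flanks are scanned for tandem arrays; a gap is *repeat_adjacent* when
either flank carries an array ≥ 500 bp, with the dominant motif taken from
the longest qualifying array, symmetrically in left/right. Flank arrays
are measured only within the flank window, so an array longer than the
flank is reported at the window length.

## The synthetic genome

`GenomeSpec` plants, per chromosome: terminal telomeric arrays (TTTAGGG,
G-rich strand outward), subtelomeric monomer blocks, a centromere of
satellite (AGAGGG) interrupted by retroelement insertions (19% full-length
by default, the remainder 5′ fragments of 25–90% length), trinucleotide
microsatellite arrays by position class, rDNA loci (one CTTAAG label site
per unit), and N-gaps with optional flanking arrays; features are separated
by ≥ 2 kb of i.i.d. random background. All monomers except the short
satellite motifs are synthetic stand-ins: random sequences with the
field-standard lengths and structure, not the natural sequences. Two
generator choices deserve emphasis:

- **Boundary breakers.** The base on each side of a planted array is forced
  to break the array's periodicity. Otherwise a flanking background base
  continues the pattern with probability 1/4 and the planted boundary is
  genuinely ill-defined; with breakers, planted and detectable boundaries
  coincide on clean sequence, which the exact-recovery tests rely on.
- **Terminal coverage.** Read, ChIP and molecule sampling allows fragment
  starts to overhang chromosome ends (reads are clipped), so features at
  chromosome tips — telomeres above all — receive the same expected depth
  as the interior.

Reads: HiFi-like = uniform 15–22 kb lengths, error-free by default;
ONT-like = log-normal with 20 kb median capped at 300 kb; errors are
i.i.d. substitutions only. GA-rich dropout multiplies the sampling weight
of 1 kb windows whose A+G (or T+C) fraction exceeds 0.8; the depth
reduction is realized in regions longer than a read length, not in
isolated windows. Chloroplast contamination adds reads from a separate
135 kb sequence at a stated fraction of all read bases. Everything is
deterministic in (spec, seed); identical inputs give byte-identical
FASTA/FASTQ/TSV outputs.

What the synthetic data does *not* model: indels and realistic long-read
error profiles, heterozygosity, structural variation, sequence-dependent
coverage biases beyond the GA-dropout toggle, higher-order repeat
structure, and satellite sequence divergence within an array. Passing
recovery tests therefore demonstrates correctness of the estimators under
idealized noise, not robustness to every artefact of real instruments.

## Problem sizes in the shipped experiments

The recovery experiments run on a 5 Mb single-chromosome genome at 30×
(repeat abundance; both error-free and 5%-substitution reads), a 4 Mb
genome with a 300-unit rDNA array at 200× molecule coverage (optical), 20
Rabl matrices of 200 bins (Hi-C), 50 000 read pairs against a 2 Mb genome
with a 0.4% enriched class (ChIP), and a 3 Mb genome with a four-gap plan
(gap audit). These sizes keep the full suite in the minutes range while
leaving every estimator's bias and variance measurable; all scale linearly
if larger runs are wanted.

## Known limitations

- Fractional copy numbers are interval/motif length by definition; impure
  arrays therefore count partial copies pro rata.
- The read-based abundance of arrays much longer than the read length is a
  lower bound (clipped arrays), exactly as in real long-read data.
- The placement surrogate reports one confidence class, not a MAPQ
  spectrum; analyses that depend on two different MAPQ cuts collapse to
  one here.
- The k-mer estimator requires a visible homozygous peak; it aborts on
  high-error spectra instead of extrapolating.
- `gse_from_kmers` and the tandem detector hold the whole read set in
  memory; at the shipped problem sizes this is tens to hundreds of MB.
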