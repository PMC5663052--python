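# Methods

## Rate definitions and read classification

The unit of evidence is the junction-spanning read. A read spans an intron
when it has at least `min_anchor` aligned nucleotides beyond both intron
boundaries (default 1 for the abstract read table; 8 is the realistic choice
when parsing spliced alignments from short-read aligners). A spanning read
is *canonical* when one alignment gap matches the annotated intron exactly,
*IR* when it covers the intron without a gap, and *ASSV* when a gap overlaps
but mismatches the intron at one or both ends. Every counted gap must match
the GT/AG consensus on the coding strand; gaps that fail are discarded — in
a highly polyploid ciliate macronucleus this removes internal-eliminated-
sequence excision variants that would otherwise masquerade as splice
variants. A read contributes independently to every element it spans. PCIs
(exon-internal 20–35 nt GT..AG segments, enumerated with every GT paired to
every in-window AG) are *spliced* only on an exact gap match, *unspliced*
when covered without a gap.

Canonical forms are defined from wild-type evidence only: an intron enters
the reference set when it has ≥10 WT spanning reads, at least one spliced
read, and a WT retention fraction below 50% (otherwise the annotated spliced
form is a minor form and variant labels would be inverted). Rates are
IR = n3/(n1+n2+n3), ASSV = n2/(n1+n2+n3), PCI splice rate = m2/(m1+m2);
zero-denominator elements are excluded rather than set to 0.

## Expression binning and pooled rates

Per-element rates at realistic depth are dominated by sampling noise, so
rates are pooled: elements are sorted by gene expression (WT RPKM, id as
tie-break) and cut into bins of equal sample size; the bin rate is the
proportion of variant reads among all spanning reads in the bin. When the
element count is not divisible by the bin count, the larger bins sit at the
low-expression end (a deterministic choice; the alternative changes nothing
detectable). CIs are Wilson score intervals at 95% — chosen over
normal-approximation intervals because pooled AS rates live near 0; the
choice is isolated in `rates.wilson_interval` and swappable. Stratified
analyses (intron-number groups 1 / 2–3 / >3; CDS-length groups <750 /
750–1400 / >1400 bp; NMD class) bin within each stratum independently.
Human-style per-intron averaging over samples is provided separately: a
sample qualifies at >10 (or ≥10) spanning reads, an intron needs ≥10
qualifying samples, and mean rates ≥50% are dropped as minor forms.

## NMD-visibility classification

Each event is applied to the annotated CDS (IR inserts the intron, a PCI
splice deletes its segment, ASSV swaps the excised interval) and the variant
is scanned for a premature termination codon from the annotated start: an
in-frame stop ending before the final codon is a PTC. Variants fall into
PTC-inducing (NMD-visible), 3n-no-PTC, or non-3n-no-PTC. In paramecium mode
any PTC counts, under the ciliate code (TGA the sole stop; running this mode
with the standard code is refused without `force=True`, since TAA/TAG encode
glutamine and would be miscalled as stops). In human mode a PTC counts only
when more than 50 nt upstream of the variant's last exon–exon junction, and
events affecting last introns are NMD-invisible outright; a PTC failing the
positional rule classifies by frame. A frameshift that reaches the end of
the CDS without any stop is categorized non-3n-no-PTC with a read-through
flag — the pathway for such transcripts (non-stop decay) is outside the
model, and the flag makes them recoverable.

## Error-proportion estimators

With r_i the ratio of a bin's pooled AS rate to the rate in the highly
constrained reference set (top-decile expression intersected with >3
introns for IR/ASSV or CDS >1400 bp for PCIs; the packaged human preset
uses >21 introns), the estimators are P = 1 − 1/r_i (simplified) and
P = 1 − AS^f/(r_i·(AS_h^e + AS^f)) (extended). Both assume the functional
AS rate is class-independent. The simplified estimator understates the
error proportion by exactly AS_h^e/AS_i, which is not negligible whenever
the reference set's own error rate is within an order of magnitude of the
functional floor — on synthetic data this bias is visible and expected, and
the parameter-recovery check therefore feeds the generator's known
functional floor to the extended estimator, computed on the NMD-deficient
condition where observed frequencies equal intrinsic ones. On real data the
floor is unobservable and the simplified value is reported as a lower
bound. r_i is computed from pooled bin rates, not per-gene means. The
"median" bin is the lower-middle bin (bin 5 of 10); both middle bins are
reported. Ratios below 1 yield negative P and are flagged out-of-model
rather than clipped silently.

## Synthetic-data generator

The generator emulates the study conditions, not a dial to turn:

- **Genome.** Genes have 0–8 introns (weights giving a mean of ~2.3
  introns/gene and ~80% intron-containing genes), CDS of 80–800 codons
  (240–2400 bp, spanning the three CDS-length strata), A/T-rich composition
  (70% A+T), no in-frame stops under the active code, no UTRs. Introns are
  20–35 nt, all GT..AG, 75% matching the GTA..TAG extended consensus (the
  observed fractions in NMD-visible/invisible introns bracket this), each
  carrying a planted secondary GT at offset 3 that serves as the single
  alternate donor: the resulting ASSV changes transcript length by +3
  without a frameshift. Both strands are used; ~25 genes per contig.
- **Expression and depth.** RPKM is log-uniform on [1, 1000] — the dynamic
  range over which junction evidence is informative at realistic depth. The
  junction depth per element is Poisson(0.346 × RPKM), i.e. a mean of ~50
  spanning reads per intron under the default expression law, the scale of
  a deeply sequenced bulk experiment.
- **Error model.** Per-intron intrinsic error rate
  ε0·RPKM^(−α)·n_introns^(−β), clipped to [1e-6, 0.5], with ε0 = 0.15: at
  the default α = 0.5, β = 0.3 this yields a mean per-intron AS rate of
  3–4%, matching the observed marginal IR+ASSV scale, split 5:1 between IR
  and ASSV as observed. PCI rates are scaled by 0.01 (two orders below
  intron rates, as observed) and decrease with CDS length via the same β.
  A constant functional floor f = 0.001 is added to every element; its
  error share is tracked exactly, so the per-bin true error proportion is
  available to machine precision.
- **NMD.** PTC-bearing variant frequencies are multiplied by (1 − d)
  (d = 0.9 in "WT", 0 in "NMD") and frequencies renormalized — steady-state
  sampling of the surviving polyA pool. Visibility labels are computed by
  an incremental frame-walk (only codons that an insertion/deletion can
  change are rescanned); a test verifies exact agreement with the full
  reconstruction in the NMD classifier, keeping generator truth and
  pipeline classification independent code paths.
- **SNPs.** Per-site Bernoulli placement on the boundary windows:
  third-codon positions at π3 = 0.026/bp independent of expression, splice
  sites at π3·g(RPKM) with g non-increasing (built-ins: g ≡ 1 and
  g = min(1, c/E)), intron bodies and first/second codon positions at fixed
  fractions of π3.

What the generator does *not* emulate: sequencing errors and base
qualities, mappability and multimapper artifacts, fragment-length effects,
genomic-DNA contamination, multi-isoform annotation, UTR introns,
IES-excision heterogeneity, linkage between sites. Passing tests therefore
demonstrate correctness of the estimators and classifiers under the stated
generative model, not robustness to alignment artifacts on real data.

## Polymorphism analysis

Boundary windows are the last 20 exonic nt + first 30 intronic nt (donor)
and last 30 intronic + first 20 exonic nt (acceptor); splice sites are the
first and last 2 intronic nt. For the very short ciliate-like introns the
two windows overlap and intronic positions are deduplicated per intron.
Density denominators count surveyed intron-position pairs: a genomic site
shared by two introns' windows counts once per intron, and π_3 uses third
codon positions from the flanking windows only (not genome-wide thirds).
π_spl/π_3 CIs use the Katz log-ratio method with a 0.5 continuity
correction at zero counts.

## Statistical design of the validation checks

The validation suite runs a scaled study: 2000 genes (~4800 introns,
~110k PCIs), mean junction depth ~50 reads/intron, 10 expression bins, and
20 replicate SNP simulations; these sizes make every check's power explicit
and are fixed in the tests. Two checks need care with only 10 bins:

- *No-trend control on π_3*: a 10-point rank correlation has SD 1/3 under
  the null, so a single simulation cannot certify |ρ| < 0.2. The check
  averages ρ over the 20 replicate SNP draws (SD ≈ 0.075).
- *Unit-ratio control under g ≡ 1*: requiring ten independent 95% CIs to
  each cover 1 would fail ~40% of the time by construction; the familywise
  rate is controlled at 5% with per-bin 99.5% CIs (Bonferroni).

Point tolerances (±0.05 on recovered error proportions, p < 0.01 on rank
tests) are asserted as stated, on single seeded runs.

## Numerical and degenerate-input choices

Zero spanning reads exclude an element or bin (never a silent 0 rate);
zero reference-set rate is an error; equal expression keys are ordered by
element id; multi-gap reads are classified per overlapping gap and
discarded whole if any counted gap fails GT/AG; annotation with a CDS not
divisible by 3 is kept but flagged invalid with a warning; multi-isoform
GFF3 is rejected rather than silently collapsed; VCF parsing keeps only
biallelic SNVs and reports the dropped count.

## Known limitations

The abstract read table carries no alignment uncertainty, so the classifier
oracle-equivalence results say nothing about aligner-induced biases. PCIs
are enumerated within genomic coding exons only, not across exon–exon
junctions of the mature mRNA (cryptic splicing across junctions is assumed
negligible for 20–35 nt windows). The human last-intron rule is applied as
a blanket override even when a frameshift creates an upstream PTC — a
deliberate approximation. Uncertainty on P^e is propagated only through the
reported CIs on rates and ratios; a bootstrap over genes would be the
natural extension.
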