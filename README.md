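# splicenoise

Tools for asking a blunt question of a transcriptome: **how much alternative
splicing is just the spliceosome making mistakes?**

RNA-seq of any eukaryote reveals abundant splice variants — retained introns,
alternative splice-site usage, excision of "cryptic" introns inside exons.
Some variants are functional; many are errors. `splicenoise` implements a
selection–mutation–drift test that separates the two at the genome scale,
together with everything needed to run it end to end on data with known
ground truth: a junction-read classifier, an NMD-visibility classifier, a
binned rate engine, a splice-site polymorphism analysis, and a synthetic-data
generator that emulates a *Paramecium*-like genome (20–35 nt GT..AG introns,
ciliate genetic code) or a human-like one (standard code, 50-nt/last-intron
NMD rule).

It is written for computational biologists studying splicing fidelity, noisy
gene expression, or drift-barrier effects, and for anyone who needs a tested,
seedable simulator of junction-spanning read evidence.

## The model

For each annotated intron, reads spanning both flanking exons are counted as
canonical (n1), alternative splice-site variants (ASSV, n2) or intron
retention (IR, n3); exon-internal 20–35 nt GT..AG segments ("potential
cryptic introns", PCIs) are counted as unspliced (m1) or spliced (m2):

    IR rate   = n3 / (n1 + n2 + n3)
    ASSV rate = n2 / (n1 + n2 + n3)
    PCI rate  = m2 / (m1 + m2)

Rates are pooled within expression bins of equal sample size (Wilson 95%
CIs). The AS rate in bin *i* decomposes into errors and functional events,
AS_i = AS_i^e + AS_i^f. Writing r_i = AS_i / AS_h for the ratio of a bin's
rate to the rate in *highly constrained* genes h (top-decile expression with
many introns, or a long CDS), and assuming the functional rate AS^f is the
same in both classes, the proportion of errors among observed variants is

    P_i^e = 1 − AS^f / (r_i · (AS_h^e + AS^f))     (extended)
    P_i^e = 1 − 1 / r_i                            (simplified, AS_h^e ≈ 0)

The simplified form is a lower bound whenever the reference set still makes
errors. Under selection–mutation–drift, error rates should fall with
expression level and intron number, and purifying selection on splice sites
(measured as π_spl/π_3, the SNP density at splice-site dinucleotides over
that at flanking third codon positions) should strengthen with expression —
both patterns are first-class outputs of the package.

## Worked example

Simulate a 2000-gene *Paramecium*-like study, keep the introns whose
canonical form is identifiable (≥10 wild-type reads, major form spliced),
and fit the error model on the NMD-deficient condition:

```python
import splicenoise as sn
from splicenoise.events import determine_canonical_forms, REFERENCE
from splicenoise.model import SplicingErrorModel

params = sn.TruthParams(n_genes=2000, seed=42)
genome, truth = sn.generate_genome(params)
wt  = sn.simulate_junction_reads(truth, "WT")
nmd = sn.simulate_junction_reads(truth, "NMD")
ref = determine_canonical_forms(wt).pipe(lambda s: s.index[s == REFERENCE])

model = SplicingErrorModel.from_counts(
    sn.JunctionCounts(introns=nmd.introns.loc[ref], pcis=nmd.pcis),
    truth.genes, truth.introns["gene_id"],
    event_class="AS", functional_floor=params.functional_as_rate)
res = model.fit()
print(res.summary())
```

```
Splicing-error model (AS events, 10 expression bins)
reference set: 63 genes, AS_h = 0.00408 [0.00367, 0.00452], 85635 reads
median-expression bin: 4 (middle bins (4, 5))
                      Pooled AS rates and error proportions
=================================================================================
bin median RPKM reads AS rate       95% CI       r_i  P_e (simple) P_e (extended)
---------------------------------------------------------------------------------
  0       31.51  2804 0.02068 [0.01604, 0.02665] 5.08       0.8030         0.9517
  1       49.07  4368 0.01397 [0.01089, 0.01790] 3.43       0.7082         0.9284
  ...
  4      147.12 12777 0.01033 [0.00872, 0.01224] 2.53       0.6055         0.9032
  ...
  9      822.89 72057 0.00440 [0.00394, 0.00491] 1.08       0.0736         0.7727
---------------------------------------------------------------------------------
```

Reading it: the pooled AS rate falls five-fold from the lowest to the
highest expression decile, as drift-barrier reasoning predicts. At the
median-expression bin the simplified estimator says at least 61% of observed
variants are errors; supplying the generator's known functional floor
(0.001) to the extended estimator gives 0.903, against a ground-truth error
proportion of 0.895 for those same introns — the estimator recovers the
planted truth. `res.plot()` draws the rate–expression curve;
`splicenoise simulate/detect/rates/error-model` expose the same steps on the
command line.

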