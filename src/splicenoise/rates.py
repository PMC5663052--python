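"""Expression binning and pooled alternative-splicing rates.

Per-element AS rates are noisy at low read depth, so rates are pooled:
elements are sorted into bins of equal sample size by gene expression (RPKM)
and the bin rate is the proportion of variant reads among all spanning reads
in the bin, with a Wilson score 95% CI. Stratification (intron-number
groups, CDS-length groups, NMD class) bins each stratum independently.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

#: Count columns aggregated per element class, and the variant columns that
#: define each reported rate.
_CLASS_SPEC = {
    "intron": (["n1", "n2", "n3"], {"IR": ["n3"], "ASSV": ["n2"], "AS": ["n2", "n3"]}),
    "pci": (["m1", "m2"], {"PCI": ["m2"]}),
}


def compute_rpkm(
    gene_read_count: float, gene_exonic_length_bp: int, total_mapped_reads: int
) -> float:
    """Reads per kilobase of exon model per million mapped reads."""
    if gene_exonic_length_bp <= 0:
        raise ValueError("gene exonic length must be positive")
    if total_mapped_reads <= 0:
        raise ValueError("total mapped reads must be positive")
    return gene_read_count / (gene_exonic_length_bp / 1000) / (total_mapped_reads / 1e6)


def assign_equal_size_bins(keys: pd.Series, n_bins: int = 10) -> pd.Series:
    """Split elements into ``n_bins`` contiguous equal-size groups by key.

    Elements are sorted by (key, element id) — the id tie-break makes the
    assignment deterministic — and split into groups whose sizes differ by at
    most one, larger groups at the low-key end. Returns a bin-index Series
    (0 = lowest keys) aligned to ``keys``.
    """
    n = len(keys)
    if n < n_bins:
        raise ValueError(f"cannot split {n} elements into {n_bins} bins")
    order = sorted(range(n), key=lambda i: (keys.iloc[i], str(keys.index[i])))
    bins = np.empty(n, dtype=int)
    for b, chunk in enumerate(np.array_split(np.asarray(order), n_bins)):
        bins[chunk] = b
    return pd.Series(bins, index=keys.index, name="bin")


def wilson_interval(count: int, nobs: int, alpha: float = 0.05) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    lo, hi = proportion_confint(count, nobs, alpha=alpha, method="wilson")
    # the exact Wilson bounds at the extremes; avoids float dust from the
    # quadratic form
    if count == 0:
        lo = 0.0
    if count == nobs:
        hi = 1.0
    return float(lo), float(hi)


def pooled_rate(variant_reads: int, total_reads: int) -> tuple[float, float, float]:
    """Pooled proportion of variant reads with its Wilson 95% CI."""
    if total_reads <= 0:
        raise ValueError("pooled rate undefined for zero spanning reads")
    lo, hi = wilson_interval(variant_reads, total_reads)
    return variant_reads / total_reads, lo, hi


def intron_number_stratum(n_introns: int) -> str:
    """Intron-number groups: genes with 1, 2-3, or more than 3 introns."""
    if n_introns <= 1:
        return "1"
    return "2-3" if n_introns <= 3 else ">3"


def cds_length_stratum(cds_length_bp: int) -> str:
    """CDS-length groups: <750 bp, 750-1400 bp, >1400 bp."""
    if cds_length_bp < 750:
        return "<750"
    return "750-1400" if cds_length_bp <= 1400 else ">1400"


def stratified_rate_table(
    elements: pd.DataFrame,
    n_bins: int = 10,
    element_class: str = "intron",
) -> pd.DataFrame:
    """Pooled AS rates per expression bin within each stratum.

    ``elements`` is indexed by element id with an ``expression`` column, the
    per-element count columns of the class (n1/n2/n3 or m1/m2) and an
    optional ``stratum`` column (a single global stratum otherwise). Binning
    is performed within each stratum independently; empty strata are omitted
    with a warning; bins without spanning reads get NaN rates (excluded).
    """
    count_cols, forms = _CLASS_SPEC[element_class]
    df = elements.copy()
    if "stratum" not in df:
        df["stratum"] = "all"
    rows = []
    for stratum, sub in df.groupby("stratum", sort=True):
        if sub.empty:
            warnings.warn(f"stratum {stratum!r} is empty; omitted", stacklevel=2)
            continue
        bins = assign_equal_size_bins(sub["expression"], n_bins)
        for b, grp_idx in bins.groupby(bins).groups.items():
            grp = sub.loc[grp_idx]
            total = int(grp[count_cols].to_numpy().sum())
            for form, cols in forms.items():
                variant = int(grp[cols].to_numpy().sum())
                if total > 0:
                    rate, lo, hi = pooled_rate(variant, total)
                else:
                    rate = lo = hi = float("nan")
                rows.append(
                    {
                        "stratum": stratum,
                        "bin": int(b),
                        "form": form,
                        "rate": rate,
                        "ci_low": lo,
                        "ci_high": hi,
                        "n_elements": len(grp),
                        "n_reads": total,
                        "mean_expression": float(grp["expression"].mean()),
                        "median_expression": float(grp["expression"].median()),
                    }
                )
    out = pd.DataFrame(rows)
    return out.sort_values(["stratum", "form", "bin"], kind="stable").reset_index(
        drop=True
    )


def mean_rate_across_samples(
    rates: pd.DataFrame,
    spanning_reads: pd.DataFrame,
    min_reads: int = 10,
    min_samples: int = 10,
    minor_cutoff: float = 0.5,
    inclusive_depth: bool = False,
) -> pd.Series:
    """Per-element mean rate over qualifying samples (human averaging rule).

    A sample qualifies when its spanning-read depth exceeds ``min_reads``
    (or meets it, with ``inclusive_depth``). Elements quantified in fewer
    than ``min_samples`` qualifying samples, or whose mean rate reaches
    ``minor_cutoff`` (minor splice forms), are excluded (NaN).
    """
    depth_ok = (
        spanning_reads >= min_reads if inclusive_depth else spanning_reads > min_reads
    )
    qualified = rates.where(depth_ok)
    n_ok = qualified.notna().sum(axis=1)
    mean = qualified.mean(axis=1)
    mean[n_ok < min_samples] = np.nan
    mean[mean >= minor_cutoff] = np.nan
    mean.name = "mean_rate"
    return mean
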