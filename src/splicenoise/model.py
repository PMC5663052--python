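"""Model/Results interface for the splicing-error analysis.

`SplicingErrorModel` bundles junction counts with gene expression, bins
elements by expression, and `fit()` returns a `SplicingErrorResults` with
pooled per-bin AS rates (Wilson 95% CIs), the highly-constrained reference
rate AS_h, per-bin ratios r_i = AS_i/AS_h and error proportions under the
simplified (P = 1 - 1/r_i) and, when a functional floor is supplied, the
extended model. The usage pattern mirrors statsmodels: construct from data,
fit, inspect `summary()`, plot.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .error import ErrorEstimate, ReferenceSetSpec, select_reference_set
from .events import JunctionCounts
from .rates import assign_equal_size_bins, pooled_rate

_VARIANT_COLS = {
    "AS": (["n2", "n3"], ["n1", "n2", "n3"]),
    "IR": (["n3"], ["n1", "n2", "n3"]),
    "ASSV": (["n2"], ["n1", "n2", "n3"]),
    "PCI": (["m2"], ["m1", "m2"]),
}


class SplicingErrorModel:
    """Binned AS-rate model with a highly-constrained reference set.

    Parameters
    ----------
    elements : DataFrame indexed by element id with a ``gene_id`` column,
        an ``expression`` column (WT RPKM of the gene) and the count columns
        of the event class (n1/n2/n3 for introns, m1/m2 for PCIs).
    genes : DataFrame indexed by gene id with ``expression`` and, as the
        reference spec requires, ``n_introns`` / ``cds_length``.
    event_class : 'AS' (IR+ASSV pooled), 'IR', 'ASSV' or 'PCI'.
    functional_floor : known functional AS rate AS^f, enabling the extended
        estimator; None restricts fitting to the simplified model.
    """

    def __init__(
        self,
        elements: pd.DataFrame,
        genes: pd.DataFrame,
        event_class: str = "AS",
        n_bins: int = 10,
        reference: ReferenceSetSpec | None = None,
        functional_floor: float | None = None,
    ) -> None:
        if event_class not in _VARIANT_COLS:
            raise ValueError(f"unknown event class {event_class!r}")
        self.elements = elements
        self.genes = genes
        self.event_class = event_class
        self.n_bins = n_bins
        self.reference = reference if reference is not None else (
            ReferenceSetSpec.paramecium_pci() if event_class == "PCI"
            else ReferenceSetSpec()
        )
        self.functional_floor = functional_floor

    @classmethod
    def from_counts(
        cls,
        counts: JunctionCounts,
        genes: pd.DataFrame,
        element_genes: pd.Series,
        **kwargs,
    ) -> "SplicingErrorModel":
        """Build from a :class:`JunctionCounts` and an element->gene mapping."""
        event_class = kwargs.get("event_class", "AS")
        table = counts.pcis if event_class == "PCI" else counts.introns
        elements = table.copy()
        elements["gene_id"] = element_genes.reindex(elements.index)
        elements["expression"] = genes.loc[
            elements["gene_id"], "expression"
        ].to_numpy()
        return cls(elements, genes, **kwargs)

    def fit(self) -> "SplicingErrorResults":
        variant_cols, total_cols = _VARIANT_COLS[self.event_class]
        el = self.elements
        bins = assign_equal_size_bins(el["expression"], self.n_bins)

        ref_genes = select_reference_set(self.genes, self.reference)
        ref_el = el[el["gene_id"].isin(ref_genes)]
        ref_variant = int(ref_el[variant_cols].to_numpy().sum())
        ref_total = int(ref_el[total_cols].to_numpy().sum())
        as_h, as_h_lo, as_h_hi = pooled_rate(ref_variant, ref_total)
        if as_h == 0:
            raise ValueError("reference-set AS rate is zero; ratios undefined")

        rows = []
        estimates = []
        for b in range(self.n_bins):
            grp = el.loc[bins.index[bins == b]]
            variant = int(grp[variant_cols].to_numpy().sum())
            total = int(grp[total_cols].to_numpy().sum())
            if total == 0:
                rows.append(
                    {"bin": b, "rate": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                     "n_elements": len(grp), "n_reads": 0,
                     "mean_expression": float(grp["expression"].mean()),
                     "median_expression": float(grp["expression"].median()),
                     "r": np.nan, "p_simple": np.nan, "p_extended": np.nan}
                )
                continue
            rate, lo, hi = pooled_rate(variant, total)
            est = ErrorEstimate.from_rates(
                b, rate, as_h, as_f=self.functional_floor
            ) if rate > 0 else None
            estimates.append(est)
            rows.append(
                {
                    "bin": b, "rate": rate, "ci_low": lo, "ci_high": hi,
                    "n_elements": len(grp), "n_reads": total,
                    "mean_expression": float(grp["expression"].mean()),
                    "median_expression": float(grp["expression"].median()),
                    "r": est.r if est else np.nan,
                    "p_simple": est.p_simple if est else np.nan,
                    "p_extended": (
                        est.p_extended if est and est.p_extended is not None
                        else np.nan
                    ),
                }
            )
        return SplicingErrorResults(
            model=self,
            bin_table=pd.DataFrame(rows),
            as_h=as_h,
            as_h_ci=(as_h_lo, as_h_hi),
            reference_genes=list(ref_genes),
            n_reference_reads=ref_total,
            estimates=[e for e in estimates if e is not None],
        )


@dataclass
class SplicingErrorResults:
    """Fitted per-bin rates, ratios and error proportions."""

    model: SplicingErrorModel
    bin_table: pd.DataFrame
    as_h: float
    as_h_ci: tuple[float, float]
    reference_genes: list[str]
    n_reference_reads: int
    estimates: list[ErrorEstimate] = field(default_factory=list)

    @property
    def median_bin(self) -> int:
        """Bin holding the median element (lower-middle bin, 0-based)."""
        return self.model.n_bins // 2 - 1

    @property
    def middle_bins(self) -> tuple[int, int]:
        return self.median_bin, self.median_bin + 1

    def error_proportion(self, bin_index: int | None = None, model: str = "simple") -> float:
        """P^e estimate at a bin (default: the median-expression bin)."""
        b = self.median_bin if bin_index is None else bin_index
        col = "p_simple" if model == "simple" else "p_extended"
        return float(self.bin_table.loc[self.bin_table["bin"] == b, col].iloc[0])

    def summary(self) -> str:
        from statsmodels.iolib.table import SimpleTable

        t = self.bin_table
        header = [
            f"Splicing-error model ({self.model.event_class} events, "
            f"{self.model.n_bins} expression bins)",
            f"reference set: {len(self.reference_genes)} genes, "
            f"AS_h = {self.as_h:.5f} "
            f"[{self.as_h_ci[0]:.5f}, {self.as_h_ci[1]:.5f}], "
            f"{self.n_reference_reads} reads",
            f"median-expression bin: {self.median_bin} "
            f"(middle bins {self.middle_bins})",
        ]
        data = [
            [
                f"{int(r['bin'])}", f"{r['median_expression']:.2f}",
                f"{int(r['n_reads'])}", f"{r['rate']:.5f}",
                f"[{r['ci_low']:.5f}, {r['ci_high']:.5f}]",
                f"{r['r']:.2f}", f"{r['p_simple']:.4f}",
                "-" if np.isnan(r["p_extended"]) else f"{r['p_extended']:.4f}",
            ]
            for _, r in t.iterrows()
        ]
        table = SimpleTable(
            data,
            headers=["bin", "median RPKM", "reads", "AS rate", "95% CI",
                     "r_i", "P_e (simple)", "P_e (extended)"],
            title="Pooled AS rates and error proportions",
        )
        return "\n".join(header) + "\n" + table.as_text()

    def plot(self, ax=None):
        """Pooled rate vs log expression with Wilson CIs (one line per fit)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.bin_table
        x = np.log10(t["median_expression"])
        yerr = np.vstack([t["rate"] - t["ci_low"], t["ci_high"] - t["rate"]])
        ax.errorbar(x, t["rate"], yerr=yerr, fmt="o-", capsize=2,
                    label=self.model.event_class)
        ax.set_xlabel("log10 expression (RPKM)")
        ax.set_ylabel("pooled AS rate")
        ax.legend()
        return ax
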