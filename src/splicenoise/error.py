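"""Selection-mutation-drift error-proportion estimators.

The observed AS rate in an expression bin i decomposes into errors and
functional events, AS_i = AS_i^e + AS_i^f. Assuming the functional rate is
constant across gene classes (AS_h^f = AS_i^f = AS^f), the proportion of
errors among observed variants in bin i can be written

    P_i^e = 1 - AS^f / (r_i * (AS_h^e + AS^f))        (extended model)

where r_i = AS_i / AS_h is the ratio of the bin's rate to the rate in a
"highly constrained" reference gene set (top-decile expression combined with
many introns or a long CDS). When selection keeps the reference set's error
rate negligible (AS_h^e << AS^f), this simplifies to

    P_i^e = 1 - 1 / r_i                               (simplified model)

The simplified estimator is a lower bound whenever AS_h^e > 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ReferenceSetSpec:
    """Definition of the highly constrained reference gene set.

    ``expression_quantile`` keeps the top (1 - q) expression fraction
    (default top 10%). The constraint criterion is a minimum intron count
    (>3 introns; human preset >21) for IR/ASSV, or a minimum CDS length
    (>1400 bp) for cryptic-intron splicing.
    """

    expression_quantile: float = 0.9
    min_introns: int | None = 4
    min_cds_length: int | None = None

    @staticmethod
    def paramecium_pci() -> "ReferenceSetSpec":
        return ReferenceSetSpec(min_introns=None, min_cds_length=1401)

    @staticmethod
    def human() -> "ReferenceSetSpec":
        """Top 10% expression and > 21 introns (top 33% of human genes)."""
        return ReferenceSetSpec(min_introns=22)


def select_reference_set(genes: pd.DataFrame, spec: ReferenceSetSpec) -> pd.Index:
    """Gene ids in the reference set: expression top slice ∩ constraint filter.

    ``genes`` is indexed by gene id with columns ``expression`` and, as
    needed, ``n_introns`` / ``cds_length``.
    """
    n_top = int(np.ceil(len(genes) * (1 - spec.expression_quantile)))
    if n_top < 1:
        raise ValueError("expression quantile leaves no genes")
    ranked = genes.loc[
        sorted(genes.index, key=lambda g: (-genes.at[g, "expression"], str(g)))
    ]
    top = ranked.iloc[:n_top]
    mask = pd.Series(True, index=top.index)
    if spec.min_introns is not None:
        mask &= top["n_introns"] >= spec.min_introns
    if spec.min_cds_length is not None:
        mask &= top["cds_length"] >= spec.min_cds_length
    selected = top.index[mask]
    if len(selected) == 0:
        raise ValueError(
            f"reference set is empty: {n_top} top-expression genes, none "
            "satisfying the constraint criterion"
        )
    return selected


def as_ratio(as_i: float, as_h: float) -> float:
    """r_i: AS rate in an expression bin over the reference-set AS rate."""
    if as_h <= 0:
        raise ValueError("reference AS rate must be positive")
    if as_i < 0:
        raise ValueError("AS rate must be non-negative")
    return as_i / as_h


def error_proportion_simple(r_i: float) -> float:
    """Simplified error proportion P = 1 - 1/r_i.

    Valid as an estimate when the reference set's error rate is negligible;
    r_i < 1 yields a negative value, reported as-is (out of model).
    """
    if r_i <= 0:
        raise ValueError("ratio must be positive")
    return 1.0 - 1.0 / r_i


def error_proportion_extended(r_i: float, as_f: float, as_h_err: float) -> float:
    """Extended error proportion P = 1 - AS^f / (r_i (AS_h^e + AS^f)).

    Reduces exactly to the simplified form when the reference error rate
    ``as_h_err`` is zero; is larger otherwise.
    """
    if r_i <= 0:
        raise ValueError("ratio must be positive")
    if as_f < 0 or as_h_err < 0:
        raise ValueError("rates must be non-negative")
    denom = r_i * (as_h_err + as_f)
    if denom == 0:
        raise ValueError("AS_h^e + AS^f must be positive")
    return 1.0 - as_f / denom


@dataclass
class ErrorEstimate:
    """Per-bin error-proportion estimate and its inputs."""

    bin: int
    as_i: float
    as_h: float
    r: float
    p_simple: float
    p_extended: float | None = None
    out_of_model: bool = False  # r < 1: more AS in reference than in bin

    @staticmethod
    def from_rates(
        bin_index: int,
        as_i: float,
        as_h: float,
        as_f: float | None = None,
        as_h_err: float | None = None,
    ) -> "ErrorEstimate":
        r = as_ratio(as_i, as_h)
        p_simple = error_proportion_simple(r) if r > 0 else float("nan")
        p_ext = None
        if as_f is not None:
            if as_h_err is None:
                as_h_err = max(as_h - as_f, 0.0)
            p_ext = error_proportion_extended(r, as_f, as_h_err)
        return ErrorEstimate(
            bin=bin_index, as_i=as_i, as_h=as_h, r=r,
            p_simple=p_simple, p_extended=p_ext, out_of_model=r < 1,
        )
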