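"""Telomere-association regressions: simple and multiple OLS of telomere outcomes
on gene Δtranscripts.

Two outcomes are supported: ``delta_telomere`` (MPNST−NF content change during
transformation) and ``mpnst_telomere`` (the malignant sample's content).  In
*simple* mode each gene gets its own univariate regression; in *multiple* mode
all genes enter one joint OLS and each coefficient is adjusted for the others.
Patients missing telomere values are dropped listwise and the n used is
reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import DeltaMatrix, PairedCohort, compute_deltas
from .linreg import LRResult, fit_simple_lr, ols_inference

__all__ = ["AssociationSpec", "AssociationResults", "TelomereAssociation", "associate"]

OUTCOMES = ("delta_telomere", "mpnst_telomere")
MODES = ("simple", "multiple")


@dataclass(frozen=True)
class AssociationSpec:
    outcome: str  # delta_telomere | mpnst_telomere
    genes: tuple  # ordered covariates, e.g. (NELL2, PAX7, RAD52, H2AFX, RAD51)
    mode: str = "simple"

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise ValueError(f"outcome must be one of {OUTCOMES}")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if not self.genes:
            raise ValueError("gene list must be non-empty")


def _deltas(data) -> DeltaMatrix:
    if isinstance(data, PairedCohort):
        return compute_deltas(data)
    if isinstance(data, DeltaMatrix):
        return data
    raise TypeError("expected a PairedCohort or DeltaMatrix")


def associate(data, spec: AssociationSpec) -> pd.DataFrame:
    """Per-gene coefficient table (B, 95% CI, p, n) for the requested outcome/mode."""
    deltas = _deltas(data)
    for g in spec.genes:
        if g not in deltas.values.index:
            raise ValueError(f"gene {g!r} not present in expression data")
    outcome = (
        deltas.delta_telomere if spec.outcome == "delta_telomere" else deltas.mpnst_telomere
    )
    if outcome is None:
        raise ValueError("telomere content is required for association analysis")
    patients = list(outcome.index)
    y = outcome.to_numpy(dtype=float)
    X = deltas.values.loc[list(spec.genes), patients].to_numpy(dtype=float).T
    keep = np.isfinite(y) & np.isfinite(X).all(axis=1)
    y, X = y[keep], X[keep]
    n = len(y)

    rows = []
    if spec.mode == "simple":
        for j, gene in enumerate(spec.genes):
            res: LRResult = fit_simple_lr(X[:, j], y)
            rows.append((gene, res.slope, res.ci_low, res.ci_high, res.p_value, res.n))
    else:
        k = len(spec.genes)
        if n < k + 2:
            raise ValueError(
                f"multiple mode with {k} genes needs at least {k + 2} complete patients, got {n}"
            )
        design = np.column_stack([np.ones(n), X])
        coefs, se, pvals, lo, hi, df, _ = ols_inference(design, y)
        for j, gene in enumerate(spec.genes, start=1):
            rows.append((gene, float(coefs[j]), float(lo[j]), float(hi[j]), float(pvals[j]), n))
    return pd.DataFrame(
        rows, columns=["gene", "B", "ci_low", "ci_high", "p_value", "n"]
    ).set_index("gene")


class TelomereAssociation:
    """Model object producing a Table-3-shaped association report.

    ``fit`` evaluates simple and multiple regressions of both telomere
    outcomes on the configured genes.
    """

    DEFAULT_GENES = ("NELL2", "PAX7", "RAD52", "H2AFX", "RAD51")

    def __init__(self, data, genes=None):
        self.data = data
        self.genes = tuple(genes) if genes else self.DEFAULT_GENES

    def fit(self) -> "AssociationResults":
        tables = {}
        for outcome in OUTCOMES:
            for mode in MODES:
                spec = AssociationSpec(outcome=outcome, genes=self.genes, mode=mode)
                tables[(outcome, mode)] = associate(self.data, spec)
        return AssociationResults(self, tables)


class AssociationResults:
    def __init__(self, model: TelomereAssociation, tables: dict):
        self.model = model
        self.tables = tables

    def table(self, outcome: str, mode: str) -> pd.DataFrame:
        return self.tables[(outcome, mode)]

    def to_frame(self) -> pd.DataFrame:
        parts = []
        for (outcome, mode), tab in self.tables.items():
            part = tab.copy()
            part.insert(0, "outcome", outcome)
            part.insert(1, "mode", mode)
            parts.append(part.reset_index())
        return pd.concat(parts, ignore_index=True)

    def summary(self) -> str:
        lines = ["Telomere association (OLS of telomere outcome on gene dtranscripts)"]
        for (outcome, mode), tab in self.tables.items():
            lines.append(f"  {outcome} / {mode} (n={int(tab['n'].iloc[0])}):")
            for gene, row in tab.iterrows():
                lines.append(
                    f"    {gene:<8s} B={row.B:9.3f} ({row.ci_low:9.3f} to {row.ci_high:9.3f})"
                    f"  p={row.p_value:.3f}"
                )
        return "\n".join(lines)
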