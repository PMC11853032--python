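"""Paired differential-expression selection.

A gene is a DEG when its average fold change between malignant and benign
samples exceeds the fold-change gate and the per-gene paired t-test on the
per-patient Δlog2(TPM+1) values is below the p gate (default: fold change ≥ 2,
p < 0.001, with no multiple-testing correction at this stage).

Fold change is measured on the log scale by default: |mean Δlog2| ≥
log2(fc_threshold), i.e. a geometric-mean fold change.  An arithmetic mode
(mean TPM ratio) is available via ``fc_mode="arithmetic"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import DeltaMatrix

__all__ = ["TTestResult", "DEGResult", "paired_t_test", "select_degs", "DegScreen", "DegScreenResults"]


@dataclass(frozen=True)
class TTestResult:
    t_stat: float
    df: int
    p_value: float
    flag: str | None = None  # "zero_variance" when sd of deltas is 0


@dataclass(frozen=True)
class DEGResult:
    gene: str
    mean_delta: float  # log2 units
    fold_change: float  # 2**mean_delta
    t_stat: float
    p_value: float
    direction: str  # "up" | "down"
    selected: bool
    n: int
    flag: str | None = None


def paired_t_test(deltas) -> TTestResult:
    """Two-sided paired t-test on per-patient deltas (one-sample t on Δ).

    t = mean / (sd/√n), df = n−1.  Degenerate inputs: zero variance with a
    nonzero mean is a 0-limit (t = ±inf, p = 0, flagged); zero variance with
    zero mean is undefined (NaN, flagged).
    """
    d = np.asarray(deltas, dtype=float)
    d = d[np.isfinite(d)]
    n = len(d)
    if n < 2:
        raise ValueError(f"need at least 2 finite deltas, got {n}")
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    df = n - 1
    if sd == 0.0:
        if mean == 0.0:
            return TTestResult(float("nan"), df, float("nan"), flag="zero_variance")
        return TTestResult(float(np.sign(mean)) * float("inf"), df, 0.0, flag="zero_variance")
    t = mean / (sd / np.sqrt(n))
    p = float(2 * stats.t.sf(abs(t), df))
    return TTestResult(float(t), df, p)


def select_degs(
    deltas: DeltaMatrix,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.001,
    fc_mode: str = "geometric",
    gene_list: list[str] | None = None,
) -> list[DEGResult]:
    """Score every gene and flag those passing both the fold-change and p gates.

    The fold-change gate is inclusive (≥), the p gate strict (<).  ``gene_list``
    optionally restricts the screen (e.g. to coding genes).  Results are in
    input gene order and sortable by p.
    """
    if fc_mode not in ("geometric", "arithmetic"):
        raise ValueError(f"unknown fc_mode {fc_mode!r}")
    values = deltas.values
    if gene_list is not None:
        keep = [g for g in values.index if g in set(gene_list)]
        values = values.loc[keep]
    if values.size == 0:
        raise ValueError("empty delta matrix")
    log_gate = np.log2(fc_threshold)
    results: list[DEGResult] = []
    for gene in values.index:
        d = values.loc[gene].to_numpy(dtype=float)
        tt = paired_t_test(d)
        mean_delta = float(np.mean(d))
        if fc_mode == "geometric":
            fc = float(2.0 ** mean_delta)
            fc_pass = abs(mean_delta) >= log_gate
        else:
            # arithmetic-mean ratio of TPM-scale values reconstructed per patient
            mp = (2.0 ** deltas.mpnst_log.loc[gene].to_numpy(dtype=float)) - 1.0
            nf = (2.0 ** (deltas.mpnst_log.loc[gene] - values.loc[gene]).to_numpy(dtype=float)) - 1.0
            mean_nf, mean_mp = float(np.mean(nf)), float(np.mean(mp))
            if mean_nf <= 0 and mean_mp <= 0:
                fc = 1.0
            elif mean_nf <= 0 or mean_mp <= 0:
                fc = float("inf")
            else:
                fc = mean_mp / mean_nf if mean_mp >= mean_nf else mean_nf / mean_mp
            fc_pass = fc >= fc_threshold
            fc = float(2.0 ** mean_delta) if not np.isfinite(fc) else fc
        p_pass = np.isfinite(tt.p_value) and tt.p_value < p_threshold
        results.append(
            DEGResult(
                gene=gene,
                mean_delta=mean_delta,
                fold_change=float(2.0 ** mean_delta),
                t_stat=tt.t_stat,
                p_value=tt.p_value,
                direction="up" if mean_delta >= 0 else "down",
                selected=bool(fc_pass and p_pass),
                n=len(d),
                flag=tt.flag,
            )
        )
    return results


class DegScreen:
    """Model object for the paired DEG screen.

    Parameters
    ----------
    deltas:
        The per-patient Δlog2(TPM+1) matrix.
    fc_threshold, p_threshold:
        Gates applied jointly (fold change inclusive, p strict).
    """

    def __init__(
        self,
        deltas: DeltaMatrix,
        fc_threshold: float = 2.0,
        p_threshold: float = 0.001,
        fc_mode: str = "geometric",
        gene_list: list[str] | None = None,
    ):
        self.deltas = deltas
        self.fc_threshold = fc_threshold
        self.p_threshold = p_threshold
        self.fc_mode = fc_mode
        self.gene_list = gene_list

    def fit(self) -> "DegScreenResults":
        res = select_degs(
            self.deltas, self.fc_threshold, self.p_threshold, self.fc_mode, self.gene_list
        )
        return DegScreenResults(self, res)


class DegScreenResults:
    def __init__(self, model: DegScreen, results: list[DEGResult]):
        self.model = model
        self.results = results

    @property
    def selected(self) -> list[str]:
        return [r.gene for r in self.results if r.selected]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "gene": r.gene,
                    "mean_delta": r.mean_delta,
                    "fold_change": r.fold_change,
                    "t_stat": r.t_stat,
                    "p_value": r.p_value,
                    "direction": r.direction,
                    "selected": r.selected,
                    "n": r.n,
                    "flag": r.flag or "",
                }
                for r in self.results
            ]
        ).set_index("gene")

    def summary(self) -> str:
        df = self.to_frame()
        hits = df[df["selected"]].sort_values("p_value")
        lines = [
            "Paired differential-expression screen",
            f"  genes tested: {len(df)}   patients: {self.model.deltas.values.shape[1]}",
            f"  gates: |mean dlog2| >= {np.log2(self.model.fc_threshold):g} "
            f"(FC >= {self.model.fc_threshold:g}), paired-t p < {self.model.p_threshold:g}",
            f"  selected: {len(hits)}",
        ]
        for gene, row in hits.iterrows():
            lines.append(
                f"    {gene:<12s} meanD={row.mean_delta:+.3f}  FC={row.fold_change:8.3f}  "
                f"p={row.p_value:.3g}  {row.direction}"
            )
        return "\n".join(lines)
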