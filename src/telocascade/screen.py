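"""Composite transcriptional-cascade screen with telomere-interaction filtering.

For every ordered gene pair (A, B) the screen fits three models on the paired
cohort:

1. ``lr_delta``   — OLS of ΔB on ΔA (Δ = per-patient MPNST−NF log2(TPM+1));
2. ``lr_target``  — OLS of the MPNST-sample B expression on ΔA;
3. ``glm_telomere`` — Gaussian-identity GLM of MPNST-sample telomere content
   on ΔA and ΔB (the reported coefficient is configurable: the ΔA·ΔB
   interaction by default, the ΔA main effect, or a joint F-test of both).

All p-values from the three families are pooled into a single vector and
controlled with the Benjamini–Hochberg step-up procedure at FDR 0.1.  A pair
is a *hit* (transcriptional activation feeding the telomere-maintenance axis)
when all three of its tests survive B-H **and** both OLS slopes are positive;
the GLM coefficient's sign is not constrained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort import DeltaMatrix, PairedCohort, compute_deltas
from .linreg import LRResult, fit_simple_lr, ols_inference
from . import genelists

__all__ = [
    "EdgePair",
    "EdgeStats",
    "ScreenResult",
    "bh_adjust",
    "fit_telomere_glm",
    "screen_pairs",
    "CascadeScreen",
    "preset_pairs",
]

GLM_SPECS = ("interaction", "main_effect_A", "joint")
EPS = float(np.finfo(float).eps)


@dataclass(frozen=True)
class EdgePair:
    source: str
    target: str
    label: str = ""

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise ValueError(f"self-pair {self.source!r} is not a valid edge")


@dataclass(frozen=True)
class EdgeStats:
    pair: EdgePair
    lr_delta: LRResult
    lr_target: LRResult
    glm_telomere: LRResult
    bh_delta: bool = False
    bh_target: bool = False
    bh_glm: bool = False
    is_hit: bool = False

    @property
    def p_values(self) -> tuple[float, float, float]:
        return (self.lr_delta.p_value, self.lr_target.p_value, self.glm_telomere.p_value)


@dataclass(frozen=True)
class ScreenResult:
    """Outcome of one screen run: per-pair statistics, pooled B-H bookkeeping, hits."""

    edges: list[EdgeStats]
    skipped: list[tuple[EdgePair, str]]
    fdr: float
    pooling: str
    glm_spec: str

    @property
    def pooled_p_count(self) -> int:
        return 3 * len(self.edges)

    @property
    def hits(self) -> list[EdgeStats]:
        return [e for e in self.edges if e.is_hit]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.edges:
            rows.append(
                {
                    "source": e.pair.source,
                    "target": e.pair.target,
                    "label": e.pair.label,
                    "delta_B": e.lr_delta.slope,
                    "delta_ci_low": e.lr_delta.ci_low,
                    "delta_ci_high": e.lr_delta.ci_high,
                    "delta_p": e.lr_delta.p_value,
                    "target_B": e.lr_target.slope,
                    "target_ci_low": e.lr_target.ci_low,
                    "target_ci_high": e.lr_target.ci_high,
                    "target_p": e.lr_target.p_value,
                    "glm_B": e.glm_telomere.slope,
                    "glm_ci_low": e.glm_telomere.ci_low,
                    "glm_ci_high": e.glm_telomere.ci_high,
                    "glm_p": e.glm_telomere.p_value,
                    "glm_n": e.glm_telomere.n,
                    "bh_delta": e.bh_delta,
                    "bh_target": e.bh_target,
                    "bh_glm": e.bh_glm,
                    "is_hit": e.is_hit,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "Transcriptional-cascade screen",
            f"  pairs tested: {len(self.edges)} (skipped: {len(self.skipped)})",
            f"  pooled p-values under B-H: {self.pooled_p_count} "
            f"(pooling={self.pooling}, FDR={self.fdr:g}, glm={self.glm_spec})",
            f"  hits: {len(self.hits)}",
        ]
        for e in self.hits:
            lines.append(
                f"    {e.pair.source} -> {e.pair.target}: "
                f"dB={e.lr_delta.slope:.3f} (p={e.lr_delta.p_value:.2e}), "
                f"targetB={e.lr_target.slope:.3f} (p={e.lr_target.p_value:.2e}), "
                f"glmB={e.glm_telomere.slope:.3f} (p={e.glm_telomere.p_value:.2e})"
            )
        return "\n".join(lines)


def bh_adjust(p_values, fdr: float = 0.1) -> np.ndarray:
    """Benjamini–Hochberg step-up rejection flags, returned in input order.

    Sort p ascending, find the largest k with p_(k) ≤ k·fdr/m, reject all
    p ≤ p_(k).  NaN p-values are rejected as invalid input.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.isnan(p).any():
        raise ValueError("NaN p-values are not allowed in B-H adjustment")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=fdr, method="fdr_bh")
    return reject


def _delta_inputs(data) -> DeltaMatrix:
    if isinstance(data, PairedCohort):
        return compute_deltas(data)
    if isinstance(data, DeltaMatrix):
        return data
    raise TypeError("expected a PairedCohort or DeltaMatrix")


def fit_telomere_glm(data, source: str, target: str, glm_spec: str = "interaction") -> LRResult:
    """Gaussian-identity GLM of MPNST-sample telomere content on a gene pair.

    ``glm_spec`` selects the reported statistic:

    * ``interaction``   — model 1 + ΔA + ΔB + ΔA·ΔB; interaction coefficient.
    * ``main_effect_A`` — model 1 + ΔA + ΔB; ΔA coefficient.
    * ``joint``         — model 1 + ΔA + ΔB; F-test that ΔA and ΔB are jointly
      zero (p), with the ΔA coefficient and CI reported alongside.

    Uses patients with complete telomere pairs only (n reported).
    """
    if glm_spec not in GLM_SPECS:
        raise ValueError(f"glm_spec must be one of {GLM_SPECS}")
    deltas = _delta_inputs(data)
    if deltas.mpnst_telomere is None:
        raise ValueError("telomere content is required for the telomere GLM")
    patients = list(deltas.mpnst_telomere.index)
    da = deltas.values.loc[source, patients].to_numpy(dtype=float)
    db = deltas.values.loc[target, patients].to_numpy(dtype=float)
    y = deltas.mpnst_telomere.to_numpy(dtype=float)
    keep = np.isfinite(da) & np.isfinite(db) & np.isfinite(y)
    da, db, y = da[keep], db[keep], y[keep]
    n = len(y)
    if n < 4:
        raise ValueError(f"telomere GLM needs >= 4 complete patients, got {n}")
    ones = np.ones(n)
    if glm_spec == "interaction":
        X = np.column_stack([ones, da, db, da * db])
        idx = 3
    else:
        X = np.column_stack([ones, da, db])
        idx = 1
    coefs, se, pvals, lo, hi, df, rss = ols_inference(X, y)
    if glm_spec == "joint":
        # F-test of the two-gene model against intercept-only
        tss = float(np.sum((y - y.mean()) ** 2))
        q = 2
        if rss <= EPS * max(1.0, tss):
            p = 1.0 if tss <= EPS else 0.0
        elif tss <= rss:
            p = 1.0
        else:
            f = ((tss - rss) / q) / (rss / df)
            p = float(stats.f.sf(f, q, df))
        return LRResult(float(coefs[idx]), float(lo[idx]), float(hi[idx]), p, n, float(se[idx]))
    return LRResult(
        float(coefs[idx]), float(lo[idx]), float(hi[idx]), float(pvals[idx]), n, float(se[idx])
    )


def screen_pairs(
    data,
    sources: list[str],
    targets: list[str],
    fdr: float = 0.1,
    glm_spec: str = "interaction",
    pooling: str = "pooled",
    label: str = "",
) -> ScreenResult:
    """Run the composite screen over every ordered (source, target) pair.

    All three p-value families are pooled into one B-H vector by default
    (``pooling="pooled"``); ``"per_family"`` adjusts each family separately.
    Pairs whose statistics cannot be computed (constant Δsource, too few
    complete telomere patients) are reported as skipped, never silently
    dropped.  Output ordering is deterministic: sources outer, targets inner,
    in the given order.
    """
    if not sources or not targets:
        raise ValueError("source and target gene sets must be non-empty")
    if pooling not in ("pooled", "per_family"):
        raise ValueError(f"unknown pooling mode {pooling!r}")
    if not (0 < fdr < 1):
        raise ValueError("FDR must be in (0, 1)")
    deltas = _delta_inputs(data)
    genes = set(deltas.genes)
    for g in list(sources) + list(targets):
        if g not in genes:
            raise ValueError(f"gene {g!r} not present in expression data")

    raw: list[tuple[EdgePair, LRResult, LRResult, LRResult]] = []
    skipped: list[tuple[EdgePair, str]] = []
    for a in sources:
        da = deltas.values.loc[a].to_numpy(dtype=float)
        for b in targets:
            if a == b:
                continue
            pair = EdgePair(a, b, label)
            db = deltas.values.loc[b].to_numpy(dtype=float)
            mb = deltas.mpnst_log.loc[b].to_numpy(dtype=float)
            try:
                lr_delta = fit_simple_lr(da, db)
                lr_target = fit_simple_lr(da, mb)
                glm = fit_telomere_glm(deltas, a, b, glm_spec)
            except ValueError as exc:
                skipped.append((pair, str(exc)))
                continue
            raw.append((pair, lr_delta, lr_target, glm))

    edges: list[EdgeStats] = []
    if raw:
        # floor exact-fit 0-limit p-values at machine epsilon before B-H
        p_delta = np.array([max(r[1].p_value, EPS) for r in raw])
        p_target = np.array([max(r[2].p_value, EPS) for r in raw])
        p_glm = np.array([max(r[3].p_value, EPS) for r in raw])
        if pooling == "pooled":
            flags = bh_adjust(np.concatenate([p_delta, p_target, p_glm]), fdr)
            m = len(raw)
            f_delta, f_target, f_glm = flags[:m], flags[m : 2 * m], flags[2 * m :]
        else:
            f_delta = bh_adjust(p_delta, fdr)
            f_target = bh_adjust(p_target, fdr)
            f_glm = bh_adjust(p_glm, fdr)
        for (pair, lr_d, lr_t, glm), bd, bt, bg in zip(raw, f_delta, f_target, f_glm):
            hit = bool(bd and bt and bg and lr_d.slope > 0 and lr_t.slope > 0)
            edges.append(EdgeStats(pair, lr_d, lr_t, glm, bool(bd), bool(bt), bool(bg), hit))
    return ScreenResult(edges=edges, skipped=skipped, fdr=fdr, pooling=pooling, glm_spec=glm_spec)


def preset_pairs(name: str, tmm_path: str | None = None, damage_rule: str = "exclude_self"):
    """Source/target gene lists for the three shipped screen configurations.

    * ``deg_pax``    — the 22 transformation DEGs × the 9 PAX genes (198 pairs).
    * ``pax_tmm``    — {PAX7, PAX5} × the 100 TMM genes (200 pairs).
    * ``damage_tmm`` — the 4 DNA-damage markers × TMM genes.  The published
      total for this stage (396 = 4 × 99) corresponds to excluding only the
      self-pair (``damage_rule="exclude_self"``); ``"exclude_damage"`` instead
      removes all four markers from the target side (4 × 96 = 384).
    """
    if name == "deg_pax":
        return list(genelists.DEG_GENES), list(genelists.PAX_GENES)
    if name == "pax_tmm":
        return ["PAX7", "PAX5"], genelists.tmm_genes(tmm_path)
    if name == "damage_tmm":
        tmm = genelists.tmm_genes(tmm_path)
        if damage_rule == "exclude_self":
            return list(genelists.DAMAGE_GENES), tmm
        if damage_rule == "exclude_damage":
            targets = [g for g in tmm if g not in set(genelists.DAMAGE_GENES)]
            return list(genelists.DAMAGE_GENES), targets
        raise ValueError(f"unknown damage_rule {damage_rule!r}")
    raise ValueError(f"unknown preset {name!r}")


class CascadeScreen:
    """Model object for the composite pair screen.

    Built from a :class:`PairedCohort` (or precomputed :class:`DeltaMatrix`)
    plus source/target gene lists; :meth:`fit` returns a :class:`ScreenResult`.
    """

    def __init__(
        self,
        data,
        sources: list[str],
        targets: list[str],
        fdr: float = 0.1,
        glm_spec: str = "interaction",
        pooling: str = "pooled",
        label: str = "",
    ):
        self.data = data
        self.sources = list(sources)
        self.targets = list(targets)
        self.fdr = fdr
        self.glm_spec = glm_spec
        self.pooling = pooling
        self.label = label

    @classmethod
    def from_preset(cls, data, preset: str, tmm_path: str | None = None, **kwargs) -> "CascadeScreen":
        sources, targets = preset_pairs(preset, tmm_path, kwargs.pop("damage_rule", "exclude_self"))
        return cls(data, sources, targets, label=preset, **kwargs)

    def fit(self) -> ScreenResult:
        return screen_pairs(
            self.data, self.sources, self.targets, self.fdr, self.glm_spec, self.pooling, self.label
        )
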