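"""Dichotomized survival comparison and grade association.

Patients are split by whether a chosen factor increased during malignant
transformation: *increased* means Δfactor > 0; Δfactor ≤ 0 (including exactly
0) is *not increased*.  The factor is a gene's Δlog2(TPM+1) transcript or the
telomere-content change.  Endpoints are overall survival (OS; death from any
cause) and metastasis-free survival (MFS; restricted to metastasis-evaluable
patients).  Group comparison uses a univariate Cox proportional-hazards model
(Breslow tie handling by default, Efron by flag), Kaplan–Meier curves describe
the groups, and association with high FNCLCC grade uses logistic regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from lifelines import KaplanMeierFitter
from statsmodels.duration.hazard_regression import PHReg

from .cohort import ClinicalTable, DeltaMatrix

__all__ = [
    "GroupAssignment",
    "SurvivalResult",
    "KMCurve",
    "LogisticResult",
    "dichotomize",
    "cox_fit",
    "km_curve",
    "grade_logistic",
    "CoxSurvival",
]

INCREASED = "increased"
NOT_INCREASED = "not_increased"


@dataclass(frozen=True)
class GroupAssignment:
    """Patient → group from the strict-positive Δfactor rule."""

    factor: str
    groups: pd.Series  # patient -> INCREASED / NOT_INCREASED
    excluded: tuple = ()  # patients without a Δ value

    @property
    def comparable(self) -> bool:
        return self.groups.nunique() == 2

    @property
    def n_increased(self) -> int:
        return int((self.groups == INCREASED).sum())

    @property
    def n_not_increased(self) -> int:
        return int((self.groups == NOT_INCREASED).sum())


@dataclass(frozen=True)
class SurvivalResult:
    endpoint: str  # "OS" | "MFS"
    factor: str
    hazard_ratio: float
    ci_low: float
    ci_high: float
    wald_p: float
    n_increased: int
    n_not_increased: int
    events_increased: int
    events_not_increased: int
    ties: str = "breslow"
    flag: str | None = None  # "monotone_likelihood" when all events sit in one group

    def __post_init__(self) -> None:
        if np.isfinite(self.hazard_ratio) and self.hazard_ratio <= 0:
            raise ValueError("hazard ratio must be positive")

    def summary(self) -> str:
        return (
            f"{self.endpoint} ~ {self.factor} increased vs not: "
            f"HR = {self.hazard_ratio:.3f} ({self.ci_low:.3f} to {self.ci_high:.3f}), "
            f"Wald p = {self.wald_p:.3f} "
            f"[n = {self.n_increased}/{self.n_not_increased}, "
            f"events = {self.events_increased}/{self.events_not_increased}, ties={self.ties}]"
            + (f"  ({self.flag})" if self.flag else "")
        )


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival estimate for one group: a right-continuous step function."""

    group: str
    times: np.ndarray  # event times (months), ascending
    survival: np.ndarray  # S(t) just after each time; starts from S(0)=1
    censor_times: np.ndarray
    n: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "survival": self.survival, "group": self.group})


@dataclass(frozen=True)
class LogisticResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    flag: str | None = None  # "separation": Wald statistics suppressed


def dichotomize(deltas: DeltaMatrix, factor: str) -> GroupAssignment:
    """Assign patients to increased (Δ > 0) / not-increased (Δ ≤ 0) groups.

    ``factor`` is a gene symbol or ``"telomere"`` (the content change).
    Patients without a Δ value are excluded and reported, not imputed.
    """
    if factor == "telomere":
        if deltas.delta_telomere is None:
            raise ValueError("cohort has no telomere data to dichotomize on")
        series = deltas.delta_telomere
        excluded = tuple(p for p in deltas.patients if p not in series.index)
    else:
        series = deltas.gene_deltas(factor)
        excluded = tuple(series.index[~np.isfinite(series)])
        series = series[np.isfinite(series)]
    groups = pd.Series(
        np.where(series.to_numpy() > 0, INCREASED, NOT_INCREASED), index=series.index, name="group"
    )
    return GroupAssignment(factor=factor, groups=groups, excluded=excluded)


def _endpoint_frame(clinical: ClinicalTable | pd.DataFrame, endpoint: str) -> pd.DataFrame:
    tab = clinical.table if isinstance(clinical, ClinicalTable) else clinical
    endpoint = endpoint.upper()
    if endpoint == "OS":
        return pd.DataFrame({"time": tab["os_time"], "event": tab["os_event"]})
    if endpoint == "MFS":
        ev = tab[tab["mfs_evaluable"] == 1] if "mfs_evaluable" in tab.columns else tab
        return pd.DataFrame({"time": ev["mfs_time"], "event": ev["mfs_event"]})
    raise ValueError(f"unknown endpoint {endpoint!r}; use OS or MFS")


def cox_fit(
    records: ClinicalTable | pd.DataFrame,
    groups: GroupAssignment,
    endpoint: str = "OS",
    ties: str = "breslow",
) -> SurvivalResult:
    """Univariate Cox proportional-hazards fit of the binary group indicator.

    HR = exp(coefficient) with Wald 95% CI and p.  When every event falls in
    one group the partial likelihood is monotone; the fit is flagged and the
    CI reported as unbounded rather than trusted.
    """
    if ties not in ("breslow", "efron"):
        raise ValueError("ties must be 'breslow' or 'efron'")
    frame = _endpoint_frame(records, endpoint).join(groups.groups, how="inner")
    frame = frame.dropna()
    if not groups.comparable or frame["group"].nunique() < 2:
        raise ValueError(f"factor {groups.factor!r} yields a single group; HR not comparable")
    x = (frame["group"] == INCREASED).to_numpy(dtype=float)
    time = frame["time"].to_numpy(dtype=float)
    event = frame["event"].to_numpy(dtype=int)
    if event.sum() == 0:
        raise ValueError("no events observed; Cox model is not identified")

    ev_inc = int(event[x == 1].sum())
    ev_not = int(event[x == 0].sum())
    flag = None
    if ev_inc == 0 or ev_not == 0:
        flag = "monotone_likelihood"

    model = PHReg(time, x[:, None], status=event, ties=ties)
    try:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # monotone likelihoods trip optimizer warnings
            fit = model.fit(disp=False)
        coef = float(fit.params[0])
        se = float(fit.bse[0])
    except Exception:
        if flag is None:
            raise
        coef, se = float("inf"), float("inf")
    if flag or not np.isfinite(se) or se > 1e3:
        flag = flag or "monotone_likelihood"
        hr = float(np.exp(coef)) if np.isfinite(coef) else float("inf")
        return SurvivalResult(
            endpoint.upper(), groups.factor, hr, 0.0, float("inf"), float("nan"),
            int(x.sum()), int((1 - x).sum()), ev_inc, ev_not, ties, flag,
        )
    z = coef / se
    p = float(2 * stats.norm.sf(abs(z)))
    zq = stats.norm.ppf(0.975)
    return SurvivalResult(
        endpoint=endpoint.upper(),
        factor=groups.factor,
        hazard_ratio=float(np.exp(coef)),
        ci_low=float(np.exp(coef - zq * se)),
        ci_high=float(np.exp(coef + zq * se)),
        wald_p=p,
        n_increased=int(x.sum()),
        n_not_increased=int((1 - x).sum()),
        events_increased=ev_inc,
        events_not_increased=ev_not,
        ties=ties,
        flag=flag,
    )


def km_curve(
    records: ClinicalTable | pd.DataFrame,
    groups: GroupAssignment,
    endpoint: str = "OS",
) -> dict[str, KMCurve]:
    """Kaplan–Meier product-limit curves per group, with censoring marks."""
    frame = _endpoint_frame(records, endpoint).join(groups.groups, how="inner").dropna()
    curves: dict[str, KMCurve] = {}
    for name, sub in frame.groupby("group", sort=True):
        if len(sub) == 0:
            raise ValueError(f"group {name!r} is empty")
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], event_observed=sub["event"])
        sf = kmf.survival_function_
        curves[str(name)] = KMCurve(
            group=str(name),
            times=sf.index.to_numpy(dtype=float),
            survival=sf.iloc[:, 0].to_numpy(dtype=float),
            censor_times=sub.loc[sub["event"] == 0, "time"].to_numpy(dtype=float),
            n=len(sub),
        )
    return curves


def grade_logistic(
    groups: GroupAssignment,
    clinical: ClinicalTable | pd.DataFrame,
    high_grades: tuple = (3,),
) -> LogisticResult:
    """Logistic regression of the high-grade indicator on the group indicator.

    High grade defaults to FNCLCC 3 vs {1, 2}.  Complete separation is flagged
    and Wald statistics suppressed (the MLE does not exist).
    """
    tab = clinical.table if isinstance(clinical, ClinicalTable) else clinical
    frame = pd.DataFrame({"grade": tab["fnclcc_grade"]}).join(groups.groups, how="inner").dropna()
    y = frame["grade"].isin(high_grades).to_numpy(dtype=float)
    x = (frame["group"] == INCREASED).to_numpy(dtype=float)
    n = len(y)
    if n < 4 or len(np.unique(x)) < 2:
        raise ValueError("need both groups represented and at least 4 patients")
    # 2x2 margins decide existence of the MLE
    a = float(((x == 1) & (y == 1)).sum())
    b = float(((x == 1) & (y == 0)).sum())
    c = float(((x == 0) & (y == 1)).sum())
    d = float(((x == 0) & (y == 0)).sum())
    if min(a, b, c, d) == 0:
        or_point = 0.0 if (a == 0 or d == 0) else float("inf")
        return LogisticResult(or_point, float("nan"), float("nan"), float("nan"), n, "separation")

    import statsmodels.api as sm

    fit = sm.Logit(y, sm.add_constant(x)).fit(disp=False)
    coef = float(fit.params[1])
    se = float(fit.bse[1])
    zq = stats.norm.ppf(0.975)
    return LogisticResult(
        odds_ratio=float(np.exp(coef)),
        ci_low=float(np.exp(coef - zq * se)),
        ci_high=float(np.exp(coef + zq * se)),
        p_value=float(fit.pvalues[1]),
        n=n,
    )


class CoxSurvival:
    """Model object for the dichotomized survival comparison.

    Built from a cohort's :class:`DeltaMatrix` and clinical table, a factor
    (gene symbol or ``"telomere"``) and an endpoint; :meth:`fit` returns a
    :class:`SurvivalResult`, :meth:`km_curves` the group step functions.
    """

    def __init__(
        self,
        deltas: DeltaMatrix,
        clinical: ClinicalTable | pd.DataFrame,
        factor: str,
        endpoint: str = "OS",
        ties: str = "breslow",
    ):
        self.deltas = deltas
        self.clinical = clinical
        self.factor = factor
        self.endpoint = endpoint
        self.ties = ties
        self.groups = dichotomize(deltas, factor)

    def fit(self) -> SurvivalResult:
        return cox_fit(self.clinical, self.groups, self.endpoint, self.ties)

    def km_curves(self) -> dict[str, KMCurve]:
        return km_curve(self.clinical, self.groups, self.endpoint)

    def grade_association(self, high_grades: tuple = (3,)) -> LogisticResult:
        return grade_logistic(self.groups, self.clinical, high_grades)
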