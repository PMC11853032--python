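"""Cohort data model, TSV readers/writers, log transform, paired deltas, summaries.

The central container is :class:`PairedCohort`: a gene × sample TPM matrix plus
a patient→(NF sample, MPNST sample) pairing, optional per-sample telomere
content, and an optional clinical table.  All downstream analyses consume the
per-patient :class:`DeltaMatrix` of MPNST−NF differences on the log2(TPM+1)
scale.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExpressionMatrix",
    "LogExpression",
    "ClinicalTable",
    "PairedCohort",
    "DeltaMatrix",
    "read_expression",
    "write_expression",
    "read_pairs",
    "read_telomere",
    "read_clinical",
    "load_cohort",
    "log_transform",
    "compute_deltas",
    "summarize_cohort",
]

CLINICAL_COLUMNS = {
    "age_at_mpnst": float,
    "sex": str,
    "ajcc_stage": str,
    "fnclcc_grade": int,
    "os_time": float,
    "os_event": int,
    "mfs_time": float,
    "mfs_event": int,
    "mfs_evaluable": int,
}
# Optional per-arm tumor sizes (cm); present in descriptive summaries when given.
OPTIONAL_CLINICAL_COLUMNS = {"nf_size_cm": float, "mpnst_size_cm": float}


def _check_unique(labels: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            raise ValueError(f"duplicate {what}: {lab!r}")
        seen.add(lab)


@dataclass(frozen=True)
class ExpressionMatrix:
    """Gene × sample matrix of non-negative TPM values.

    Gene symbols and sample IDs are unique and case-sensitive; input ordering
    is preserved.
    """

    values: pd.DataFrame  # index = genes, columns = samples

    def __post_init__(self) -> None:
        df = self.values
        _check_unique(list(df.index), "gene symbol")
        _check_unique(list(df.columns), "sample ID")
        arr = df.to_numpy(dtype=float, copy=False)
        if not np.all(np.isfinite(arr)):
            r, c = np.argwhere(~np.isfinite(arr))[0]
            raise ValueError(
                f"non-finite expression value at gene {df.index[r]!r}, "
                f"sample {df.columns[c]!r}"
            )
        if (arr < 0).any():
            r, c = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative expression value at gene {df.index[r]!r}, "
                f"sample {df.columns[c]!r}"
            )

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class LogExpression:
    """Same shape as :class:`ExpressionMatrix`; values are log2(TPM+1) ≥ 0."""

    values: pd.DataFrame

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


@dataclass(frozen=True)
class ClinicalTable:
    """Per-patient clinical variables (times in months, events as 0/1 flags)."""

    table: pd.DataFrame  # index = patient IDs

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"clinical table missing columns: {missing}")
        for col in ("os_time", "mfs_time"):
            if (df[col].to_numpy(dtype=float) < 0).any():
                raise ValueError(f"negative {col} in clinical table")
        for col in ("os_event", "mfs_event", "mfs_evaluable"):
            if not df[col].isin([0, 1]).all():
                raise ValueError(f"{col} must be 0/1")
        if not df["fnclcc_grade"].isin([1, 2, 3]).all():
            raise ValueError("fnclcc_grade must be in {1,2,3}")

    @property
    def patients(self) -> list[str]:
        return list(self.table.index)


@dataclass(frozen=True)
class PairedCohort:
    """A paired benign/malignant cohort keyed by patient.

    ``pairs`` maps each patient to exactly one NF and one MPNST sample, both of
    which must exist in the expression matrix; the two roles are disjoint.
    ``telomere`` may omit samples (telomere-dependent analyses use complete
    pairs only and report the n used).
    """

    expression: ExpressionMatrix
    pairs: pd.DataFrame  # index = patient, columns = nf_sample, mpnst_sample
    telomere: pd.Series | None = None  # sample → tel_content
    clinical: ClinicalTable | None = None

    def __post_init__(self) -> None:
        _check_unique(list(self.pairs.index), "patient ID")
        for col in ("nf_sample", "mpnst_sample"):
            if col not in self.pairs.columns:
                raise ValueError(f"pairs table missing column {col!r}")
        known = set(self.expression.samples)
        nf = list(self.pairs["nf_sample"])
        mp = list(self.pairs["mpnst_sample"])
        for pat, s in zip(self.pairs.index, nf):
            if s not in known:
                raise ValueError(f"patient {pat!r}: NF sample {s!r} not in expression matrix")
        for pat, s in zip(self.pairs.index, mp):
            if s not in known:
                raise ValueError(f"patient {pat!r}: MPNST sample {s!r} not in expression matrix")
        _check_unique(nf + mp, "sample role assignment")
        if self.clinical is not None:
            extra = set(self.clinical.patients) - set(self.pairs.index)
            if extra:
                raise ValueError(f"clinical table has unknown patients: {sorted(extra)}")

    @property
    def patients(self) -> list[str]:
        return list(self.pairs.index)

    @property
    def n_patients(self) -> int:
        return len(self.pairs)

    def nf_sample(self, patient: str) -> str:
        return self.pairs.at[patient, "nf_sample"]

    def mpnst_sample(self, patient: str) -> str:
        return self.pairs.at[patient, "mpnst_sample"]

    def swap_roles(self) -> "PairedCohort":
        """Return the cohort with NF and MPNST roles exchanged (for antisymmetry checks)."""
        swapped = self.pairs.rename(
            columns={"nf_sample": "mpnst_sample", "mpnst_sample": "nf_sample"}
        )
        return replace(self, pairs=swapped[["nf_sample", "mpnst_sample"]])

    def log_expression(self) -> LogExpression:
        return log_transform(self.expression)

    def deltas(self) -> "DeltaMatrix":
        return compute_deltas(self)


@dataclass(frozen=True)
class DeltaMatrix:
    """Per-patient, per-gene MPNST−NF differences of log2(TPM+1) (the Δtranscript).

    ``mpnst_log`` keeps the malignant-sample log expression (patient-indexed)
    because the cascade screen regresses it alongside the deltas.
    ``delta_telomere``/``mpnst_telomere`` cover the patients with complete
    telomere pairs only.
    """

    values: pd.DataFrame  # index = genes, columns = patients
    mpnst_log: pd.DataFrame  # index = genes, columns = patients
    delta_telomere: pd.Series | None = None  # patient → MPNST−NF content
    mpnst_telomere: pd.Series | None = None  # patient → MPNST content
    nf_telomere: pd.Series | None = None  # patient → NF content

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def patients(self) -> list[str]:
        return list(self.values.columns)

    def gene_deltas(self, gene: str) -> pd.Series:
        if gene not in self.values.index:
            raise KeyError(f"gene {gene!r} not in delta matrix")
        return self.values.loc[gene]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a gene × sample TPM TSV (first column gene symbols, header sample IDs)."""
    with open(path) as fh:  # pandas silently mangles duplicate headers; check raw
        header = fh.readline().rstrip("\n").split("\t")
    if len(header) < 2:
        raise ValueError(f"{path}: expected a gene column plus at least one sample column")
    _check_unique(header[1:], "sample ID")
    df = pd.read_csv(path, sep="\t", dtype={0: str}, float_precision="round_trip")
    gene_col = df.columns[0]
    _check_unique(list(df[gene_col]), "gene symbol")
    body = df.set_index(gene_col)
    body.index.name = "gene"
    for col in body.columns:
        vals = pd.to_numeric(body[col], errors="coerce")
        bad = vals.isna() | ~np.isfinite(vals)
        if bad.any():
            gene = body.index[bad.to_numpy().argmax()]
            raise ValueError(f"{path}: non-numeric value at gene {gene!r}, sample {col!r}")
        body[col] = vals
    return ExpressionMatrix(values=body.astype(float))


def write_expression(matrix: ExpressionMatrix | LogExpression, path: str | Path) -> None:
    out = matrix.values.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t", float_format="%.17g")


def read_pairs(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"patient_id", "nf_sample", "mpnst_sample"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: pairs table must have columns {sorted(required)}")
    return df.set_index("patient_id")[["nf_sample", "mpnst_sample"]]


def read_telomere(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str}, float_precision="round_trip")
    if not {"sample_id", "tel_content"}.issubset(df.columns):
        raise ValueError(f"{path}: telomere table must have sample_id and tel_content columns")
    _check_unique(list(df["sample_id"]), "sample ID")
    ser = df.set_index("sample_id")["tel_content"].astype(float)
    if (ser < 0).any():
        raise ValueError(f"{path}: negative telomere content")
    return ser


def read_clinical(path: str | Path) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str})
    if "patient_id" not in df.columns:
        raise ValueError(f"{path}: clinical table must have a patient_id column")
    return ClinicalTable(table=df.set_index("patient_id"))


def load_cohort(
    expression_tsv: str | Path,
    pairs_tsv: str | Path,
    telomere_tsv: str | Path | None = None,
    clinical_tsv: str | Path | None = None,
) -> PairedCohort:
    """Assemble a :class:`PairedCohort` from the four standard TSV files."""
    return PairedCohort(
        expression=read_expression(expression_tsv),
        pairs=read_pairs(pairs_tsv),
        telomere=read_telomere(telomere_tsv) if telomere_tsv else None,
        clinical=read_clinical(clinical_tsv) if clinical_tsv else None,
    )


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def log_transform(m: ExpressionMatrix) -> LogExpression:
    """Elementwise log2(TPM+1); zero TPM maps to exactly 0."""
    arr = m.values.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("negative TPM values cannot be log-transformed")
    return LogExpression(values=pd.DataFrame(np.log2(arr + 1.0), index=m.values.index, columns=m.values.columns))


def compute_deltas(cohort: PairedCohort) -> DeltaMatrix:
    """Per-patient MPNST−NF differences on the log2(TPM+1) scale.

    Telomere deltas are attached for patients whose NF and MPNST samples both
    have telomere content; others are omitted (not imputed).
    """
    log = cohort.log_expression().values
    nf_cols = [cohort.nf_sample(p) for p in cohort.patients]
    mp_cols = [cohort.mpnst_sample(p) for p in cohort.patients]
    mpnst = log[mp_cols].to_numpy()
    nf = log[nf_cols].to_numpy()
    deltas = pd.DataFrame(mpnst - nf, index=log.index, columns=cohort.patients)
    mpnst_log = pd.DataFrame(mpnst, index=log.index, columns=cohort.patients)

    d_tel = m_tel = n_tel = None
    if cohort.telomere is not None:
        tel = cohort.telomere
        rows = {}
        for p in cohort.patients:
            s_nf, s_mp = cohort.nf_sample(p), cohort.mpnst_sample(p)
            if s_nf in tel.index and s_mp in tel.index:
                rows[p] = (float(tel[s_mp]) - float(tel[s_nf]), float(tel[s_mp]), float(tel[s_nf]))
        if rows:
            frame = pd.DataFrame(rows, index=["delta", "mpnst", "nf"]).T
            d_tel, m_tel, n_tel = frame["delta"], frame["mpnst"], frame["nf"]
    return DeltaMatrix(
        values=deltas,
        mpnst_log=mpnst_log,
        delta_telomere=d_tel,
        mpnst_telomere=m_tel,
        nf_telomere=n_tel,
    )


# ---------------------------------------------------------------------------
# descriptive summaries
# ---------------------------------------------------------------------------

def _mean_sd(x: np.ndarray) -> tuple[float, float]:
    return float(np.mean(x)), float(np.std(x, ddof=1)) if len(x) > 1 else float("nan")


def summarize_cohort(cohort: PairedCohort) -> dict:
    """Descriptive cohort summary: per-arm telomere/size means ± SD, a paired
    two-sided t-test for telomere content over complete pairs, and counts per
    categorical clinical field.

    With fewer than 2 complete telomere pairs, or zero paired variance, the
    paired-t p is reported as NaN (undefined), never 0 or 1.
    """
    if cohort.n_patients == 0:
        raise ValueError("cohort has no patients")
    out: dict = {"n_patients": cohort.n_patients}

    if cohort.telomere is not None:
        deltas = compute_deltas(cohort)
        if deltas.mpnst_telomere is not None:
            nf = deltas.nf_telomere.to_numpy()
            mp = deltas.mpnst_telomere.to_numpy()
            p = float("nan")
            if len(nf) >= 2 and np.std(mp - nf, ddof=1) > 0:
                p = float(stats.ttest_rel(mp, nf).pvalue)
            out["telomere"] = {
                "n_pairs": int(len(nf)),
                "nf_mean": _mean_sd(nf)[0],
                "nf_sd": _mean_sd(nf)[1],
                "mpnst_mean": _mean_sd(mp)[0],
                "mpnst_sd": _mean_sd(mp)[1],
                "mean_difference": float(np.mean(mp - nf)),
                "paired_t_p": p,
            }

    if cohort.clinical is not None:
        tab = cohort.clinical.table
        out["age_at_mpnst_mean"] = float(tab["age_at_mpnst"].mean())
        out["age_at_mpnst_sd"] = float(tab["age_at_mpnst"].std(ddof=1))
        for col in ("sex", "ajcc_stage", "fnclcc_grade"):
            out[f"{col}_counts"] = tab[col].value_counts().to_dict()
        out["os_events"] = int(tab["os_event"].sum())
        evaluable = tab[tab["mfs_evaluable"] == 1]
        out["mfs_evaluable_n"] = int(len(evaluable))
        out["mfs_events"] = int(evaluable["mfs_event"].sum())
        if {"nf_size_cm", "mpnst_size_cm"}.issubset(tab.columns):
            sizes = tab[["nf_size_cm", "mpnst_size_cm"]].dropna()
            if len(sizes) >= 2:
                diff = sizes["mpnst_size_cm"] - sizes["nf_size_cm"]
                p = float("nan")
                if np.std(diff, ddof=1) > 0:
                    p = float(stats.ttest_rel(sizes["mpnst_size_cm"], sizes["nf_size_cm"]).pvalue)
                out["size"] = {
                    "n_pairs": int(len(sizes)),
                    "nf_mean": float(sizes["nf_size_cm"].mean()),
                    "nf_sd": float(sizes["nf_size_cm"].std(ddof=1)),
                    "mpnst_mean": float(sizes["mpnst_size_cm"].mean()),
                    "mpnst_sd": float(sizes["mpnst_size_cm"].std(ddof=1)),
                    "paired_t_p": p,
                }
    return out
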