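"""Synthetic paired-cohort generator with planted ground truth.

Generates cohorts with the statistical structure the downstream analyses
assume, so every stage is testable without external data:

* per-gene NF log2(TPM+1) baselines drawn Normal(mu_g, sigma_g);
* MPNST = NF + planted DEG shift + within-pair noise;
* a planted linear cascade on the Δ scale: for each edge (A→B, beta, sd),
  ΔB = beta·ΔA + Normal(0, sd), with the malignant B value reconstructed as
  NF_B + ΔB so both regression criteria of the screen are satisfiable;
* telomere content: NF = alpha0 + noise, MPNST = alpha0 + offset +
  Σ alpha_g·Δg + noise (offset models transformation-wide telomere attrition
  unrelated to the planted cascade);
* survival: exponential event times whose hazard is multiplied by exp(logHR)
  in the Δfactor > 0 group, censored administratively at a horizon plus
  uniform dropout.

All randomness flows through a single seeded generator, so the same config +
seed reproduces the cohort bit for bit.  TPM is emitted as 2**log − 1 with
log values clipped at 0 (TPM is never negative); the clipped values are what
every downstream quantity (cascade, telomere, ground truth) is built from, so
a round trip through the TSV readers is exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import genelists
from .cohort import ClinicalTable, ExpressionMatrix, PairedCohort, write_expression

__all__ = [
    "CascadeEdge",
    "TelomereModel",
    "SurvivalModel",
    "SimulationConfig",
    "GroundTruth",
    "simulate_cohort",
    "paper_shaped_config",
    "null_config",
    "make_fixture_suite",
]


@dataclass(frozen=True)
class CascadeEdge:
    source: str
    target: str
    beta: float
    noise_sd: float = 0.1

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("edge noise sd must be >= 0")
        if self.source == self.target:
            raise ValueError("cascade edge cannot be a self-loop")


@dataclass(frozen=True)
class TelomereModel:
    """MPNST telomere = alpha0 + mpnst_offset + Σ coef_g·Δg + noise; NF = alpha0 + noise."""

    alpha0: float = 1000.0
    coefficients: dict = field(default_factory=dict)  # gene -> alpha_g (content units per Δlog2)
    noise_sd: float = 50.0
    mpnst_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("telomere noise sd must be > 0")


@dataclass(frozen=True)
class SurvivalModel:
    """Group-dependent exponential survival with administrative + uniform censoring.

    ``factor`` is a gene symbol or ``"telomere"``; patients with Δfactor > 0
    have their hazard multiplied by exp(log_hr).  Hazards are per month.
    """

    factor: str = "telomere"
    os_baseline_hazard: float = 0.02
    mfs_baseline_hazard: float = 0.025
    os_log_hr: float = float(np.log(3.8))
    mfs_log_hr: float = float(np.log(3.8))
    admin_horizon: float = 60.0
    dropout_max: float = 120.0
    n_mfs_evaluable: int | None = None  # None: all patients evaluable

    def __post_init__(self) -> None:
        if self.os_baseline_hazard <= 0 or self.mfs_baseline_hazard <= 0:
            raise ValueError("baseline hazards must be > 0")
        if self.admin_horizon <= 0 or self.dropout_max <= 0:
            raise ValueError("censoring parameters must be > 0")


@dataclass(frozen=True)
class SimulationConfig:
    n_patients: int = 20
    genes: tuple = ()
    baseline_mu: float | dict = 5.0  # scalar, or gene -> mu; "uniform" draws U(3, 8)
    baseline_sigma: float | dict = 1.0
    mu_overrides: dict = field(default_factory=dict)  # per-gene exceptions
    sigma_overrides: dict = field(default_factory=dict)
    pair_noise_sd: float = 0.8  # within-pair (NF→MPNST) log2 noise
    deg_shifts: dict = field(default_factory=dict)  # gene -> d, |d| >= 1
    cascade_edges: tuple = ()
    telomere: TelomereModel | None = None
    survival: SurvivalModel | None = None
    missing_telomere_patients: int = 0  # trailing patients emitted without telomere values
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 3:
            raise ValueError("need at least 3 patients")
        if not self.genes:
            raise ValueError("gene list must be non-empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene symbols in config")
        if self.pair_noise_sd < 0:
            raise ValueError("pair noise sd must be >= 0")
        gset = set(self.genes)
        for g, d in self.deg_shifts.items():
            if g not in gset:
                raise ValueError(f"DEG gene {g!r} not among simulated genes")
            if abs(d) < 1:
                raise ValueError(f"planted DEG shift for {g!r} must satisfy |d| >= 1, got {d}")
        targets = set()
        for e in self.cascade_edges:
            if e.source not in gset or e.target not in gset:
                raise ValueError(f"cascade edge {e.source}->{e.target} references unknown gene")
            if e.target in targets:
                raise ValueError(f"gene {e.target!r} is the target of two cascade edges")
            targets.add(e.target)
            if e.target in self.deg_shifts:
                raise ValueError(
                    f"gene {e.target!r} cannot carry both a DEG shift and a cascade-target role"
                )
        if self.telomere is not None:
            for g in self.telomere.coefficients:
                if g not in gset:
                    raise ValueError(f"telomere coefficient references unknown gene {g!r}")
        if self.survival is not None and self.survival.factor != "telomere":
            if self.survival.factor not in gset:
                raise ValueError(f"survival factor gene {self.survival.factor!r} unknown")
        if not 0 <= self.missing_telomere_patients < self.n_patients:
            raise ValueError("missing_telomere_patients must be in [0, n_patients)")


@dataclass(frozen=True)
class GroundTruth:
    """Generating parameters of an emitted cohort, for recovery checks."""

    deg_shifts: dict
    cascade_edges: tuple
    telomere: TelomereModel | None
    survival: SurvivalModel | None
    os_true_hr: float | None
    mfs_true_hr: float | None
    seed: int


def _per_gene(value, genes: list[str], rng: np.random.Generator, what: str) -> np.ndarray:
    if isinstance(value, str) and value == "uniform":
        return rng.uniform(3.0, 8.0, size=len(genes))
    if isinstance(value, dict):
        missing = [g for g in genes if g not in value]
        if missing:
            raise ValueError(f"{what} missing for genes {missing[:3]}...")
        return np.array([float(value[g]) for g in genes])
    return np.full(len(genes), float(value))


def simulate_cohort(config: SimulationConfig) -> tuple[PairedCohort, GroundTruth]:
    """Draw one paired cohort (and its ground truth) from the generating model."""
    rng = np.random.default_rng(config.seed)
    genes = list(config.genes)
    n, g = config.n_patients, len(genes)
    patients = [f"P{i + 1:03d}" for i in range(n)]
    nf_ids = [f"{p}_NF" for p in patients]
    mp_ids = [f"{p}_MP" for p in patients]

    mu = _per_gene(config.baseline_mu, genes, rng, "baseline_mu")
    sigma = _per_gene(config.baseline_sigma, genes, rng, "baseline_sigma")
    for gene, v in config.mu_overrides.items():
        mu[genes.index(gene)] = float(v)
    for gene, v in config.sigma_overrides.items():
        sigma[genes.index(gene)] = float(v)
    if (sigma <= 0).any():
        raise ValueError("baseline sigma must be > 0")

    nf_log = mu[:, None] + sigma[:, None] * rng.standard_normal((g, n))
    shift = np.array([config.deg_shifts.get(gene, 0.0) for gene in genes])
    mp_log = nf_log + shift[:, None] + config.pair_noise_sd * rng.standard_normal((g, n))

    gene_idx = {gene: i for i, gene in enumerate(genes)}
    for edge in config.cascade_edges:  # processed in order, so chains propagate
        ia, ib = gene_idx[edge.source], gene_idx[edge.target]
        delta_a = mp_log[ia] - nf_log[ia]
        delta_b = edge.beta * delta_a + edge.noise_sd * rng.standard_normal(n)
        mp_log[ib] = nf_log[ib] + delta_b

    # TPM must be non-negative: clip on the log scale, then derive everything
    # downstream from the clipped values so emitted TSVs round-trip exactly.
    nf_log = np.maximum(nf_log, 0.0)
    mp_log = np.maximum(mp_log, 0.0)
    deltas = mp_log - nf_log

    tpm = np.concatenate([nf_log, mp_log], axis=1)
    expr = ExpressionMatrix(
        values=pd.DataFrame(2.0 ** tpm - 1.0, index=genes, columns=nf_ids + mp_ids)
    )
    pairs = pd.DataFrame(
        {"nf_sample": nf_ids, "mpnst_sample": mp_ids}, index=pd.Index(patients, name="patient_id")
    )

    telomere = None
    delta_tel = None
    if config.telomere is not None:
        tm = config.telomere
        nf_tel = tm.alpha0 + tm.noise_sd * rng.standard_normal(n)
        mp_tel = tm.alpha0 + tm.mpnst_offset + tm.noise_sd * rng.standard_normal(n)
        for gene, alpha in tm.coefficients.items():
            mp_tel = mp_tel + alpha * deltas[gene_idx[gene]]
        nf_tel = np.maximum(nf_tel, 0.0)
        mp_tel = np.maximum(mp_tel, 0.0)
        delta_tel = mp_tel - nf_tel
        keep = n - config.missing_telomere_patients
        telomere = pd.Series(
            dict(
                list(zip(nf_ids[:keep], nf_tel[:keep]))
                + list(zip(mp_ids[:keep], mp_tel[:keep]))
            ),
            name="tel_content",
        )

    clinical = None
    os_hr = mfs_hr = None
    if config.survival is not None:
        sv = config.survival
        if sv.factor == "telomere":
            if delta_tel is None:
                raise ValueError("survival factor 'telomere' requires a telomere model")
            group = (delta_tel > 0).astype(int)
        else:
            group = (deltas[gene_idx[sv.factor]] > 0).astype(int)
        os_rate = sv.os_baseline_hazard * np.exp(sv.os_log_hr * group)
        mfs_rate = sv.mfs_baseline_hazard * np.exp(sv.mfs_log_hr * group)
        t_os = rng.exponential(1.0 / os_rate)
        t_mfs = rng.exponential(1.0 / mfs_rate)
        c_os = np.minimum(sv.admin_horizon, rng.uniform(0, sv.dropout_max, n))
        c_mfs = np.minimum(sv.admin_horizon, rng.uniform(0, sv.dropout_max, n))
        os_time = np.minimum(t_os, c_os)
        os_event = (t_os <= c_os).astype(int)
        mfs_time = np.minimum(t_mfs, c_mfs)
        mfs_event = (t_mfs <= c_mfs).astype(int)
        evaluable = np.ones(n, dtype=int)
        if sv.n_mfs_evaluable is not None and sv.n_mfs_evaluable < n:
            chosen = rng.choice(n, size=sv.n_mfs_evaluable, replace=False)
            evaluable = np.zeros(n, dtype=int)
            evaluable[chosen] = 1
        age = np.clip(rng.normal(36.55, 14.58, n), 16, 75)
        sex = np.array(["male", "female"])[np.arange(n) % 2]
        stage = rng.choice(["I", "II-IIIA", "IIIB-IV"], size=n, p=[0.2, 0.5, 0.3])
        grade = rng.choice([1, 2, 3], size=n, p=[0.2, 0.3, 0.5])
        nf_size = np.clip(rng.normal(5.31, 5.57, n), 0.5, None)
        mp_size = np.clip(rng.normal(7.44, 3.49, n), 0.5, None)
        clinical = ClinicalTable(
            table=pd.DataFrame(
                {
                    "age_at_mpnst": np.round(age, 1),
                    "sex": sex,
                    "ajcc_stage": stage,
                    "fnclcc_grade": grade,
                    "os_time": np.round(os_time, 3),
                    "os_event": os_event,
                    "mfs_time": np.round(mfs_time, 3),
                    "mfs_event": mfs_event,
                    "mfs_evaluable": evaluable,
                    "nf_size_cm": np.round(nf_size, 2),
                    "mpnst_size_cm": np.round(mp_size, 2),
                },
                index=pd.Index(patients, name="patient_id"),
            )
        )
        os_hr = float(np.exp(sv.os_log_hr))
        mfs_hr = float(np.exp(sv.mfs_log_hr))

    cohort = PairedCohort(expression=expr, pairs=pairs, telomere=telomere, clinical=clinical)
    truth = GroundTruth(
        deg_shifts=dict(config.deg_shifts),
        cascade_edges=tuple(config.cascade_edges),
        telomere=config.telomere,
        survival=config.survival,
        os_true_hr=os_hr,
        mfs_true_hr=mfs_hr,
        seed=config.seed,
    )
    return cohort, truth


# ---------------------------------------------------------------------------
# canonical configurations
# ---------------------------------------------------------------------------

def default_gene_panel() -> list[str]:
    """The 131-gene panel: 22 transformation DEGs, 9 PAX genes, 100 TMM genes."""
    return list(genelists.DEG_GENES) + list(genelists.PAX_GENES) + genelists.tmm_genes()


def paper_shaped_config(seed: int = 0) -> SimulationConfig:
    """The study-shaped fixture: 20 patients, 131 genes, one missing telomere pair.

    Plants ±2 log2 shifts on the 22 DEGs, the NELL2→PAX7→RAD52 cascade
    (slopes 0.335 and 0.8, edge noise 0.1), a RAD52→telomere effect
    (+400 content units per Δlog2, noise sd 50) on top of a −273 content
    transformation-wide attrition, and telomere-group-dependent survival
    (HR 3.8 for both endpoints, 14 of 20 patients metastasis-evaluable).
    """
    shifts = {g: 2.0 for g in genelists.DEG_GENES_UP}
    shifts.update({g: -2.0 for g in genelists.DEG_GENES_DOWN})
    return SimulationConfig(
        n_patients=20,
        genes=tuple(default_gene_panel()),
        baseline_mu="uniform",
        baseline_sigma=1.0,
        # cascade targets are near-silent / tightly regulated in the benign
        # state, so the malignant-sample level tracks the planted delta
        mu_overrides={"PAX7": 0.5, "RAD52": 3.0},
        sigma_overrides={"PAX7": 0.2, "RAD52": 0.15},
        pair_noise_sd=1.0,
        deg_shifts=shifts,
        cascade_edges=(
            CascadeEdge("NELL2", "PAX7", beta=0.335, noise_sd=0.1),
            CascadeEdge("PAX7", "RAD52", beta=0.8, noise_sd=0.1),
        ),
        telomere=TelomereModel(
            alpha0=1000.0, coefficients={"RAD52": 400.0}, noise_sd=50.0, mpnst_offset=-273.0
        ),
        survival=SurvivalModel(factor="telomere", n_mfs_evaluable=14),
        missing_telomere_patients=1,
        seed=seed,
    )


def null_config(seed: int = 0, n_patients: int = 20) -> SimulationConfig:
    """Same shape, no planted effects: DEG/cascade/telomere couplings all absent."""
    return SimulationConfig(
        n_patients=n_patients,
        genes=tuple(default_gene_panel()),
        baseline_mu="uniform",
        baseline_sigma=1.0,
        pair_noise_sd=1.0,
        deg_shifts={},
        cascade_edges=(),
        telomere=TelomereModel(alpha0=1000.0, coefficients={}, noise_sd=420.0),
        survival=SurvivalModel(factor="telomere", os_log_hr=0.0, mfs_log_hr=0.0),
        missing_telomere_patients=0,
        seed=seed,
    )


def _write_config(config: SimulationConfig, path: Path) -> None:
    def enc(v):
        if isinstance(v, (TelomereModel, SurvivalModel)):
            return json.dumps(asdict(v))
        if isinstance(v, tuple) and v and isinstance(v[0], CascadeEdge):
            return json.dumps([asdict(e) for e in v])
        if isinstance(v, (dict, tuple, list)):
            return json.dumps(list(v) if isinstance(v, tuple) else v)
        return str(v)

    lines = [f"{k}={enc(v)}" for k, v in asdict(config).items()]
    path.write_text("\n".join(lines) + "\n")


def write_cohort(cohort: PairedCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write the four standard TSVs for a cohort; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"expression": out / "expression.tsv", "pairs": out / "samples.tsv"}
    write_expression(cohort.expression, paths["expression"])
    cohort.pairs.reset_index().to_csv(paths["pairs"], sep="\t", index=False)
    if cohort.telomere is not None:
        paths["telomere"] = out / "telomere.tsv"
        tel = cohort.telomere.rename("tel_content").rename_axis("sample_id").reset_index()
        tel.to_csv(paths["telomere"], sep="\t", index=False, float_format="%.17g")
    if cohort.clinical is not None:
        paths["clinical"] = out / "clinical.tsv"
        cohort.clinical.table.reset_index().to_csv(paths["clinical"], sep="\t", index=False)
    return paths


def make_fixture_suite(out_dir: str | Path, seed: int = 0) -> dict[str, dict[str, Path]]:
    """Write the study-shaped fixture and a null fixture under ``out_dir``.

    Each fixture directory holds the four TSVs the cohort readers consume,
    the generating config as a flat key-value file, and the ground truth as
    JSON.
    """
    out = Path(out_dir)
    written: dict[str, dict[str, Path]] = {}
    for name, config in (("paper_shaped", paper_shaped_config(seed)), ("null", null_config(seed))):
        sub = out / name
        cohort, truth = simulate_cohort(config)
        paths = write_cohort(cohort, sub)
        _write_config(config, sub / "config.txt")
        truth_dict = {
            "deg_shifts": truth.deg_shifts,
            "cascade_edges": [asdict(e) for e in truth.cascade_edges],
            "telomere": asdict(truth.telomere) if truth.telomere else None,
            "survival": asdict(truth.survival) if truth.survival else None,
            "os_true_hr": truth.os_true_hr,
            "mfs_true_hr": truth.mfs_true_hr,
            "seed": truth.seed,
        }
        (sub / "ground_truth.json").write_text(json.dumps(truth_dict, indent=1))
        paths["config"] = sub / "config.txt"
        paths["ground_truth"] = sub / "ground_truth.json"
        written[name] = paths
    return written
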