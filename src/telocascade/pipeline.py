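"""End-to-end orchestration: DEG selection → cascade screens → association → survival.

``run_pipeline`` executes the full workflow on the four input TSVs and writes
every stage's table plus a run log and a summary report.  The report layer
only re-prints numbers already written to stage TSVs; nothing is recomputed
there.  Given fixed inputs and configuration the outputs are byte-identical
across reruns (the analysis stages draw no random numbers).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from importlib.metadata import version as _dist_version

from . import genelists
from .association import TelomereAssociation
from .cohort import compute_deltas, load_cohort, summarize_cohort
from .deg import DegScreen
from .screen import CascadeScreen
from .survival import CoxSurvival

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the underlying cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    expression_tsv: str
    pairs_tsv: str
    telomere_tsv: str | None = None
    clinical_tsv: str | None = None
    out_dir: str = "telocascade_out"
    fc_threshold: float = 2.0
    p_threshold: float = 0.001
    fdr: float = 0.1
    glm_spec: str = "interaction"
    pooling: str = "pooled"
    stage1_sources: list = field(default_factory=list)  # default: selected DEGs
    stage1_targets: list = field(default_factory=lambda: list(genelists.PAX_GENES))
    stage2_targets: list = field(default_factory=list)  # default: packaged TMM list
    association_genes: list = field(default_factory=list)
    survival_factors: list = field(default_factory=list)  # default: telomere + hit genes
    ties: str = "breslow"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.fdr < 1):
            raise ValueError("FDR must be in (0, 1)")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Parse a flat key=value config file (JSON values allowed for lists)."""
        kwargs: dict = {}
        for raw in Path(path).read_text().splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"malformed config line: {raw!r}")
            key, value = line.split("=", 1)
            key, value = key.strip(), value.strip()
            try:
                kwargs[key] = json.loads(value)
            except json.JSONDecodeError:
                kwargs[key] = value
        return cls(**kwargs)


def _write(df: pd.DataFrame, path: Path) -> Path:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path


def run_pipeline(config: PipelineConfig) -> dict:
    """Run deg → screen (DEG×PAX) → screen (hits×TMM) → associate → survive.

    Returns a dict with the stage results and output paths; raises
    :class:`PipelineError` naming the failed stage (earlier outputs are kept).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        pkg_version = _dist_version("telocascade")
    except Exception:
        pkg_version = "unknown"
    log_lines = [
        f"telocascade {pkg_version}",
        f"seed={config.seed}",
        f"thresholds: fc={config.fc_threshold} p={config.p_threshold} fdr={config.fdr} "
        f"glm_spec={config.glm_spec} pooling={config.pooling} ties={config.ties}",
        f"inputs: expression={config.expression_tsv} pairs={config.pairs_tsv} "
        f"telomere={config.telomere_tsv} clinical={config.clinical_tsv}",
    ]
    results: dict = {"paths": {}}

    def stage(name):
        log_lines.append(f"stage: {name}")

    try:
        stage("load")
        cohort = load_cohort(
            config.expression_tsv, config.pairs_tsv, config.telomere_tsv, config.clinical_tsv
        )
        deltas = compute_deltas(cohort)
        results["cohort_summary"] = summarize_cohort(cohort)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("load", exc) from exc

    try:
        stage("deg")
        deg_res = DegScreen(deltas, config.fc_threshold, config.p_threshold).fit()
        results["deg"] = deg_res
        results["paths"]["degs"] = _write(deg_res.to_frame().reset_index(), out / "degs.tsv")
    except Exception as exc:
        raise PipelineError("deg", exc) from exc

    try:
        stage("screen_stage1")
        genes = set(deltas.genes)
        sources = [g for g in (config.stage1_sources or deg_res.selected) if g in genes]
        targets = [g for g in config.stage1_targets if g in genes]
        if not sources or not targets:
            raise ValueError(
                f"stage-1 screen needs non-empty source ({len(sources)}) and "
                f"target ({len(targets)}) sets present in the expression matrix"
            )
        screen1 = CascadeScreen(
            deltas, sources, targets, config.fdr, config.glm_spec, config.pooling, "stage1"
        ).fit()
        results["screen_stage1"] = screen1
        results["paths"]["edges_stage1"] = _write(screen1.to_frame(), out / "edges_stage1.tsv")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("screen_stage1", exc) from exc

    try:
        stage("screen_stage2")
        # follow up the first stage's activated targets against the TMM panel
        stage2_sources = sorted({e.pair.target for e in screen1.hits})
        stage2 = None
        if stage2_sources:
            tmm = config.stage2_targets or genelists.tmm_genes()
            stage2_targets = [g for g in tmm if g in genes]
            if stage2_targets:
                stage2 = CascadeScreen(
                    deltas, stage2_sources, stage2_targets,
                    config.fdr, config.glm_spec, config.pooling, "stage2",
                ).fit()
                results["paths"]["edges_stage2"] = _write(
                    stage2.to_frame(), out / "edges_stage2.tsv"
                )
        results["screen_stage2"] = stage2
        hit_frames = [s.to_frame().query("is_hit") for s in (screen1, stage2) if s is not None]
        results["paths"]["hits"] = _write(
            pd.concat(hit_frames, ignore_index=True), out / "hits.tsv"
        )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("screen_stage2", exc) from exc

    try:
        stage("associate")
        assoc = None
        if cohort.telomere is not None:
            assoc_genes = [
                g for g in (config.association_genes or TelomereAssociation.DEFAULT_GENES)
                if g in genes
            ]
            if assoc_genes:
                assoc = TelomereAssociation(deltas, assoc_genes).fit()
                results["paths"]["association"] = _write(
                    assoc.to_frame(), out / "association.tsv"
                )
        results["association"] = assoc
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("associate", exc) from exc

    try:
        stage("survive")
        surv_rows = []
        km_rows = []
        if cohort.clinical is not None:
            factors = config.survival_factors
            if not factors:
                factors = (["telomere"] if cohort.telomere is not None else [])
                hit_genes: list[str] = []
                for scr in (screen1, stage2):
                    if scr is not None:
                        for e in scr.hits:
                            hit_genes.extend([e.pair.source, e.pair.target])
                factors += sorted(set(hit_genes))
            for factor in factors:
                for endpoint in ("OS", "MFS"):
                    try:
                        model = CoxSurvival(
                            deltas, cohort.clinical, factor, endpoint, config.ties
                        )
                        res = model.fit()
                    except ValueError as exc:
                        surv_rows.append(
                            {"factor": factor, "endpoint": endpoint, "error": str(exc)}
                        )
                        continue
                    surv_rows.append(
                        {
                            "factor": factor,
                            "endpoint": endpoint,
                            "hazard_ratio": res.hazard_ratio,
                            "ci_low": res.ci_low,
                            "ci_high": res.ci_high,
                            "wald_p": res.wald_p,
                            "n_increased": res.n_increased,
                            "n_not_increased": res.n_not_increased,
                            "events_increased": res.events_increased,
                            "events_not_increased": res.events_not_increased,
                            "ties": res.ties,
                            "flag": res.flag or "",
                        }
                    )
                    for curve in model.km_curves().values():
                        frame = curve.to_frame()
                        frame.insert(0, "factor", factor)
                        frame.insert(1, "endpoint", endpoint)
                        km_rows.append(frame)
        surv_df = pd.DataFrame(surv_rows)
        results["survival"] = surv_df
        if len(surv_rows):
            results["paths"]["survival"] = _write(surv_df, out / "survival.tsv")
        if km_rows:
            results["paths"]["km"] = _write(pd.concat(km_rows, ignore_index=True), out / "km.tsv")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("survive", exc) from exc

    # report: re-print stage outputs only
    report = ["# telocascade pipeline report", ""]
    report.append(f"patients: {cohort.n_patients}")
    report.append(f"DEGs selected: {len(deg_res.selected)} -> {', '.join(deg_res.selected)}")
    report.append(
        f"stage-1 screen: {len(screen1.edges)} pairs, "
        f"{screen1.pooled_p_count} pooled p-values, hits: "
        + (", ".join(f"{e.pair.source}->{e.pair.target}" for e in screen1.hits) or "none")
    )
    if stage2 is not None:
        report.append(
            f"stage-2 screen: {len(stage2.edges)} pairs, "
            f"{stage2.pooled_p_count} pooled p-values, hits: "
            + (", ".join(f"{e.pair.source}->{e.pair.target}" for e in stage2.hits) or "none")
        )
    if assoc is not None:
        report.append("")
        report.append(assoc.summary())
    if len(surv_df):
        report.append("")
        report.append("survival (dichotomized Cox):")
        report.append(surv_df.to_string(index=False))
    (out / "report.txt").write_text("\n".join(report) + "\n")
    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    results["paths"]["report"] = out / "report.txt"
    results["paths"]["run_log"] = out / "run_log.txt"
    results["config"] = asdict(config)
    return results
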