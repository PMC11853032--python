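import numpy as np
import pandas as pd
import pytest

from telocascade.cohort import ExpressionMatrix, PairedCohort, compute_deltas
from telocascade.simulate import null_config, paper_shaped_config, simulate_cohort


@pytest.fixture(scope="session")
def paper_cohort():
    cohort, truth = simulate_cohort(paper_shaped_config(seed=1))
    return cohort, truth


@pytest.fixture(scope="session")
def paper_deltas(paper_cohort):
    cohort, _ = paper_cohort
    return compute_deltas(cohort)


@pytest.fixture(scope="session")
def null_deltas():
    cohort, _ = simulate_cohort(null_config(seed=3))
    return compute_deltas(cohort)


def tiny_cohort(nf_values: dict, mpnst_values: dict, genes: list[str], telomere=None, clinical=None):
    """Build a small paired cohort from per-sample TPM dicts (sample -> list per gene)."""
    values = {**nf_values, **mpnst_values}
    expr = ExpressionMatrix(values=pd.DataFrame(values, index=genes, dtype=float))
    patients = [s[:-3] for s in nf_values]
    pairs = pd.DataFrame(
        {
            "nf_sample": list(nf_values),
            "mpnst_sample": list(mpnst_values),
        },
        index=pd.Index(patients, name="patient_id"),
    )
    tel = pd.Series(telomere, dtype=float) if telomere is not None else None
    return PairedCohort(expression=expr, pairs=pairs, telomere=tel, clinical=clinical)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
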