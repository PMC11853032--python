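"""OLS core, B-H step-up control, the telomere GLM, and the composite pair screen."""

import itertools

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st

from telocascade.cohort import DeltaMatrix, compute_deltas
from telocascade.linreg import fit_simple_lr
from telocascade.screen import CascadeScreen, bh_adjust, fit_telomere_glm, preset_pairs, screen_pairs
from telocascade.simulate import (
    CascadeEdge,
    SimulationConfig,
    TelomereModel,
    simulate_cohort,
)


def brute_force_bh(p, fdr):
    """Literal step-up definition: largest k with p_(k) <= k*fdr/m, reject p <= p_(k)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.sort(p)
    k_star = 0
    for k in range(1, m + 1):
        if order[k - 1] <= k * fdr / m:
            k_star = k
    if k_star == 0:
        return np.zeros(m, dtype=bool)
    return p <= order[k_star - 1]


# ---------------------------------------------------------------------------
# simple OLS
# ---------------------------------------------------------------------------

def test_perfect_fit_reports_zero_limit_p():
    x = np.arange(5.0)
    res = fit_simple_lr(x, 2 * x + 1)
    assert res.slope == pytest.approx(2.0, abs=1e-12)
    assert res.p_value == 0.0
    assert res.ci_low == res.ci_high == res.slope


def test_orthogonal_construction_gives_zero_slope():
    res = fit_simple_lr([-1.0, 0.0, 1.0], [1.0, -2.0, 1.0])
    assert res.slope == pytest.approx(0.0, abs=1e-12)


def test_ols_matches_statsmodels(rng):
    x = rng.normal(size=8)
    y = 1.5 * x + rng.normal(size=8)
    ours = fit_simple_lr(x, y)
    ref = sm.OLS(y, sm.add_constant(x)).fit()
    assert ours.slope == pytest.approx(ref.params[1], abs=1e-10)
    assert ours.p_value == pytest.approx(ref.pvalues[1], abs=1e-10)
    lo, hi = ref.conf_int()[1]
    assert ours.ci_low == pytest.approx(lo, abs=1e-10)
    assert ours.ci_high == pytest.approx(hi, abs=1e-10)


def test_ols_rejects_degenerate_inputs():
    with pytest.raises(ValueError, match="constant"):
        fit_simple_lr([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
    with pytest.raises(ValueError, match="at least 3"):
        fit_simple_lr([1.0, 2.0], [1.0, 2.0])


@given(
    shift=st.floats(-100, 100),
    scale=st.floats(0.01, 100),
    seed=st.integers(0, 1000),
)
@settings(max_examples=40, derandomize=True)
def test_slope_shift_and_scale_equivariance(shift, scale, seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=10)
    y = rng.normal(size=10)
    base = fit_simple_lr(x, y)
    shifted = fit_simple_lr(x + shift, y + shift)
    scaled = fit_simple_lr(x * scale, y)
    assert shifted.slope == pytest.approx(base.slope, rel=1e-6, abs=1e-9)
    assert scaled.slope == pytest.approx(base.slope / scale, rel=1e-6, abs=1e-9)


# ---------------------------------------------------------------------------
# Benjamini–Hochberg
# ---------------------------------------------------------------------------

def test_bh_trivial_cases():
    assert not bh_adjust([1.0, 1.0, 1.0], 0.1).any()
    assert bh_adjust([0.01], 0.1).all()  # m=1: reject iff p <= fdr
    flags = bh_adjust([0.001, 0.02, 0.03, 0.9], 0.1)
    assert flags.tolist() == [True, True, True, False]
    assert (flags == brute_force_bh([0.001, 0.02, 0.03, 0.9], 0.1)).all()


def test_bh_matches_brute_force_exhaustively():
    grid = [0.0, 0.01, 0.03, 0.05, 0.3, 1.0]
    for length in (1, 2, 3):
        for vec in itertools.product(grid, repeat=length):
            assert (bh_adjust(vec, 0.1) == brute_force_bh(vec, 0.1)).all(), vec


def test_bh_matches_brute_force_on_random_vectors(rng):
    grid = np.round(np.arange(0, 1.0001, 0.01), 2)
    for _ in range(400):
        length = rng.integers(1, 7)
        vec = rng.choice(grid, size=length)
        for fdr in (0.05, 0.1, 0.25):
            assert (bh_adjust(vec, fdr) == brute_force_bh(vec, fdr)).all(), (vec, fdr)


def test_bh_rejections_monotone_in_fdr(rng):
    p = rng.uniform(size=60)
    lo = bh_adjust(p, 0.05)
    hi = bh_adjust(p, 0.2)
    assert (hi | ~lo).all()  # rejections at 0.05 are a subset of those at 0.2


def test_bh_rejects_nan_input():
    with pytest.raises(ValueError, match="NaN"):
        bh_adjust([0.1, float("nan")])


# ---------------------------------------------------------------------------
# telomere GLM
# ---------------------------------------------------------------------------

def _toy_deltas(rng, n=12, tel=None):
    da = rng.normal(0, 1, n)
    db = rng.normal(0, 1, n)
    patients = [f"P{i}" for i in range(n)]
    values = pd.DataFrame([da, db], index=["A", "B"], columns=patients)
    mp = values + 5.0
    tel_series = pd.Series(tel if tel is not None else rng.normal(1000, 50, n), index=patients)
    return DeltaMatrix(values=values, mpnst_log=mp, mpnst_telomere=tel_series), da, db


def test_glm_constant_telomere_gives_null_coefficients(rng):
    deltas, _, _ = _toy_deltas(rng, tel=np.full(12, 1000.0))
    res = fit_telomere_glm(deltas, "A", "B", "interaction")
    assert res.slope == pytest.approx(0.0, abs=1e-8)
    assert res.p_value > 0.99


def test_glm_exact_interaction_recovered(rng):
    deltas, da, db = _toy_deltas(rng)
    deltas = DeltaMatrix(
        values=deltas.values,
        mpnst_log=deltas.mpnst_log,
        mpnst_telomere=pd.Series(5.0 * da * db, index=deltas.mpnst_telomere.index),
    )
    res = fit_telomere_glm(deltas, "A", "B", "interaction")
    assert res.slope == pytest.approx(5.0, abs=1e-8)
    assert res.p_value <= 1e-12  # zero-residual 0-limit


def test_glm_main_effect_recovery_large_n(rng):
    n = 400
    deltas, da, db = _toy_deltas(rng, n=n)
    tel = 1000 + 120 * da + rng.normal(0, 80, n)
    deltas = DeltaMatrix(
        values=deltas.values,
        mpnst_log=deltas.mpnst_log,
        mpnst_telomere=pd.Series(tel, index=[f"P{i}" for i in range(n)]),
    )
    res = fit_telomere_glm(deltas, "A", "B", "main_effect_A")
    assert abs(res.slope - 120) <= 3 * res.stderr


def test_glm_rejects_rank_deficient_design(rng):
    deltas, da, _ = _toy_deltas(rng)
    # make B an exact copy of A: interaction design loses rank? no - duplicate column does
    values = deltas.values.copy()
    values.loc["B"] = values.loc["A"]
    deltas = DeltaMatrix(
        values=values, mpnst_log=deltas.mpnst_log, mpnst_telomere=deltas.mpnst_telomere
    )
    with pytest.raises(ValueError, match="rank|condition"):
        fit_telomere_glm(deltas, "A", "B", "main_effect_A")


# ---------------------------------------------------------------------------
# the composite screen
# ---------------------------------------------------------------------------

def test_deg_pax_preset_pools_594_pvalues(paper_deltas):
    sources, targets = preset_pairs("deg_pax")
    assert (len(sources), len(targets)) == (22, 9)
    result = screen_pairs(paper_deltas, sources, targets, glm_spec="joint")
    assert len(result.edges) == 198
    assert result.pooled_p_count == 594


def test_follow_up_presets_have_published_pair_counts():
    sources, targets = preset_pairs("pax_tmm")
    assert len(sources) * len(targets) == 200
    d_sources, d_targets = preset_pairs("damage_tmm", damage_rule="exclude_self")
    n_pairs = sum(1 for a in d_sources for b in d_targets if a != b)
    assert n_pairs == 396  # 4 damage genes x 99 non-self TMM genes
    alt_sources, alt_targets = preset_pairs("damage_tmm", damage_rule="exclude_damage")
    assert sum(1 for a in alt_sources for b in alt_targets if a != b) == 384


def test_planted_edge_is_the_unique_hit():
    config = SimulationConfig(
        n_patients=20,
        genes=tuple(f"G{i}" for i in range(12)),
        baseline_mu=6.0,
        baseline_sigma=1.0,
        sigma_overrides={"G1": 0.15},
        pair_noise_sd=1.0,
        cascade_edges=(CascadeEdge("G0", "G1", beta=0.4, noise_sd=0.08),),
        telomere=TelomereModel(alpha0=1000.0, coefficients={"G1": 400.0}, noise_sd=40.0),
        seed=21,
    )
    deltas = compute_deltas(simulate_cohort(config)[0])
    result = screen_pairs(
        deltas, sources=["G0", "G2", "G3"], targets=["G1", "G4", "G5"], glm_spec="joint"
    )
    hits = {(e.pair.source, e.pair.target) for e in result.hits}
    assert hits == {("G0", "G1")}
    edge = next(e for e in result.edges if e.pair.source == "G0" and e.pair.target == "G1")
    assert abs(edge.lr_delta.slope - 0.4) <= 3 * edge.lr_delta.stderr


def test_screen_invariant_to_patient_order(paper_deltas):
    sources, targets = ["NELL2", "BUB1"], ["PAX7", "PAX3"]
    base = screen_pairs(paper_deltas, sources, targets, glm_spec="joint").to_frame()
    perm = np.random.default_rng(0).permutation(len(paper_deltas.patients))
    cols = [paper_deltas.patients[i] for i in perm]
    shuffled = DeltaMatrix(
        values=paper_deltas.values[cols],
        mpnst_log=paper_deltas.mpnst_log[cols],
        delta_telomere=paper_deltas.delta_telomere,
        mpnst_telomere=paper_deltas.mpnst_telomere,
        nf_telomere=paper_deltas.nf_telomere,
    )
    other = screen_pairs(shuffled, sources, targets, glm_spec="joint").to_frame()
    pd.testing.assert_frame_equal(base, other, atol=1e-10, rtol=1e-10)


def test_screen_rejects_empty_gene_sets(paper_deltas):
    with pytest.raises(ValueError, match="non-empty"):
        screen_pairs(paper_deltas, [], ["PAX7"])


def test_skipped_pairs_are_reported():
    rng = np.random.default_rng(4)
    n = 10
    patients = [f"P{i}" for i in range(n)]
    values = pd.DataFrame(
        [np.zeros(n), rng.normal(0, 1, n), rng.normal(0, 1, n)],
        index=["CONST", "A", "B"],
        columns=patients,
    )
    deltas = DeltaMatrix(
        values=values,
        mpnst_log=values + 3.0,
        mpnst_telomere=pd.Series(rng.normal(1000, 50, n), index=patients),
    )
    result = screen_pairs(deltas, ["CONST", "A"], ["B"])
    assert len(result.edges) == 1
    assert len(result.skipped) == 1
    assert result.skipped[0][0].source == "CONST"
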