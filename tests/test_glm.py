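"""GLM betas, group t, BH-FDR, permutation null and HRF convolution."""

import numpy as np
import pandas as pd
import pytest

from dtwspec import (
    MEASURE_NAMES,
    StatsConfig,
    TrialMeasures,
    TrialTable,
    bold_comparison,
    fdr_bh,
    fit_trial_glm,
    generate_bold,
    generate_null_measures,
    group_ttest,
    hrf_convolve,
    hrf_kernel,
    permutation_test,
    run_comparison,
    trial_regressor,
)


def _measures(values):
    return TrialMeasures(table=pd.DataFrame(values, columns=list(MEASURE_NAMES)))


def test_glm_recovers_exact_linear_target(rng):
    vals = rng.standard_normal((60, 6))
    pred = vals[:, 0]  # dtw_sd
    vals[:, 2] = (pred - pred.mean()) / pred.std()  # sse = z(dtw_sd)
    betas = fit_trial_glm(_measures(vals), "sse")
    assert betas["dtw_sd"] == pytest.approx(1.0, abs=1e-10)
    for name in ("dft_sd", "ms_length", "mean_gfp", "ava_length"):
        assert betas[name] == pytest.approx(0.0, abs=1e-10)


def test_glm_matches_normal_equations(rng):
    vals = rng.standard_normal((40, 6))
    betas = fit_trial_glm(_measures(vals), "mean_gfp")
    # closed-form oracle
    idx = [i for i, n in enumerate(MEASURE_NAMES) if n != "mean_gfp"]
    X = vals[:, idx]
    X = (X - X.mean(0)) / X.std(0)
    X = np.column_stack([np.ones(40), X])
    y = vals[:, MEASURE_NAMES.index("mean_gfp")]
    expected = np.linalg.solve(X.T @ X, X.T @ y)[1:]
    assert np.allclose(betas.to_numpy(), expected, atol=1e-8)


def test_glm_rejects_singular_design(rng):
    vals = rng.standard_normal((40, 6))
    vals[:, 1] = vals[:, 0]  # duplicated predictor column
    with pytest.raises(np.linalg.LinAlgError):
        fit_trial_glm(_measures(vals), "sse")


def test_glm_needs_enough_trials(rng):
    with pytest.raises(ValueError, match="few"):
        fit_trial_glm(_measures(rng.standard_normal((5, 6))), "sse")


def test_group_ttest_textbook_value():
    b = np.array([1.0, 2, 3, 4, 5])
    t, p = group_ttest(b)
    assert t == pytest.approx(b.mean() / (b.std(ddof=1) / np.sqrt(5)))
    from scipy import stats

    assert p == pytest.approx(2 * stats.t.sf(t, df=4))


def test_group_ttest_edge_cases():
    assert group_ttest(np.zeros(5)) == (0.0, 1.0)
    with pytest.raises(ValueError, match="degenerate.*\\+2"):
        group_ttest(np.full(5, 2.0))
    with pytest.raises(ValueError, match=">= 2"):
        group_ttest([1.0])


def test_bh_stepup_hand_computation():
    reject, p_adj = fdr_bh([0.01, 0.02, 0.03, 0.5], alpha=0.05)
    assert list(reject) == [True, True, True, False]
    # adjusted: p_(i) * m / i with step-up monotonicity
    assert np.allclose(p_adj, [0.04, 0.04, 0.04, 0.5])
    assert not fdr_bh([1.0, 1.0, 1.0])[0].any()
    assert fdr_bh([0.01])[0][0]
    with pytest.raises(ValueError):
        fdr_bh([0.5, 1.5])


def test_bh_rejections_superset_of_bonferroni(rng):
    for _ in range(20):
        p = rng.random(15) ** 2
        bh = set(np.flatnonzero(fdr_bh(p, 0.05)[0]))
        bonf = set(np.flatnonzero(p < 0.05 / len(p)))
        assert bonf <= bh


def test_permutation_floor_for_strongest_effect():
    """Target identical to predictor: no permutation can beat observed t."""
    rng = np.random.default_rng(0)
    meas = []
    for s in range(6):
        vals = rng.standard_normal((40, 6))
        vals[:, 2] = vals[:, 0]  # sse == dtw_sd exactly
        meas.append(_measures(vals))
    cfg = StatsConfig(n_perm=99, seed=1)
    p = permutation_test(meas, "sse", "dtw_sd", cfg)
    assert p == pytest.approx(1 / 100)


def test_permutation_p_bounds(rng):
    meas = generate_null_measures(5, 30, seed=3)
    cfg = StatsConfig(n_perm=50, seed=2)
    p = permutation_test(meas, "sse", "dft_sd", cfg)
    assert 1 / 51 <= p <= 1.0


def test_hrf_kernel_shape_and_impulse():
    h = hrf_kernel(50.0)
    assert h.max() == pytest.approx(1.0)
    peak_s = np.argmax(h) / 50.0
    assert 4.0 <= peak_s <= 8.0
    assert h.min() < 0  # undershoot present
    imp = np.zeros(2000)
    imp[0] = 1.0
    conv = hrf_convolve(imp, 50.0)
    assert np.allclose(conv[: len(h)], h)
    assert np.allclose(hrf_convolve(np.zeros(100), 50.0), 0.0)


def test_hrf_convolution_linearity(rng):
    a, b = rng.standard_normal(300), rng.standard_normal(300)
    lhs = hrf_convolve(a + b, 50.0)
    rhs = hrf_convolve(a, 50.0) + hrf_convolve(b, 50.0)
    assert np.allclose(lhs, rhs, atol=1e-10)


def test_run_comparison_shape_and_planted_effect():
    meas = generate_null_measures(10, 80, seed=4, coupling=[("sse", "dtw_sd", 0.8)])
    res = run_comparison(meas, cfg=StatsConfig(n_perm=99, seed=4))
    assert len(res.table) == 6 * 5  # off-diagonal cells, one condition
    cell = res.cell("all", "sse", "dtw_sd")
    assert cell.p_fdr < 0.05 and cell.p_perm == pytest.approx(1 / 100)
    assert cell.mean_beta > 0.5
    # an uncoupled cell stays null-ish
    assert res.cell("all", "dft_sd", "ms_length").p_fdr > 0.05


def test_run_comparison_single_rep_equals_list_of_one():
    meas = generate_null_measures(6, 40, seed=8)
    cfg = StatsConfig(n_perm=19, seed=0)
    a = run_comparison(meas, cfg=cfg)
    b = run_comparison([meas], cfg=cfg)
    pd.testing.assert_frame_equal(a.table, b.table)


def test_run_comparison_splits_conditions():
    rng = np.random.default_rng(2)
    meas, trials = [], []
    for s in range(6):
        vals = rng.standard_normal((60, 6))
        vals[:30, 2] = vals[:30, 0] * 1.0 + 0.1 * rng.standard_normal(30)  # task only
        meas.append(_measures(vals))
        trials.append(
            TrialTable(
                np.arange(60) * 100 + 100,
                np.repeat([0, 1], 30),
                ["task"] * 30 + ["rest"] * 30,
            )
        )
    res = run_comparison(meas, trials, StatsConfig(n_perm=99, seed=0))
    assert set(res.table.condition) == {"task", "rest"}
    assert res.cell("task", "sse", "dtw_sd").p_fdr < 0.05
    assert res.cell("rest", "sse", "dtw_sd").p_fdr > 0.05


def test_repetition_averaging_reduces_beta_variance():
    """20-rep averaged betas vary less across reruns than single-run betas."""
    rng = np.random.default_rng(0)

    def one_dataset(seed, n_reps):
        # same latent coupling, rep-specific measurement noise
        reps = []
        base = generate_null_measures(8, 60, seed=seed)
        for r in range(n_reps):
            rep = []
            for m in base:
                v = m.values().copy()
                v[:, 2] = 0.5 * v[:, 0] + np.random.default_rng(seed * 100 + r).standard_normal(60)
                rep.append(_measures(v))
            reps.append(rep)
        return reps

    singles, averaged = [], []
    for seed in range(8):
        reps = one_dataset(seed, 5)
        cfg = StatsConfig(n_perm=1, seed=0)
        singles.append(run_comparison(reps[0], cfg=cfg).cell("all", "sse", "dtw_sd").mean_beta)
        averaged.append(run_comparison(reps, cfg=cfg).cell("all", "sse", "dtw_sd").mean_beta)
    assert np.var(averaged) < np.var(singles)


def test_bold_generation_and_recovery():
    """Planted network coupling is recovered by the BOLD GLM layer."""
    n_samples, rate, tr = 10000, 50.0, 2.0
    rng = np.random.default_rng(6)
    meas, trials, bolds = [], [], []
    for s in range(10):
        tt = TrialTable(np.arange(60) * 160 + 200, np.zeros(60, int), ["task"] * 60)
        m = _measures(rng.standard_normal((60, 6)))
        bd = generate_bold(
            m, tt, n_samples, rate, tr,
            coupling=[("net_a", "mean_gfp", 1.0)],
            noise_sd=1.0, n_null_networks=1, seed=s,
        )
        meas.append(m)
        trials.append(tt)
        bolds.append(bd)
    res = bold_comparison(meas, trials, bolds, n_samples, rate, tr, StatsConfig(n_perm=99, seed=0))
    assert res.cell("bold", "net_a", "mean_gfp").p_fdr < 0.05
    null_cells = res.table[res.table.target == "null0"]
    assert (null_cells.p_fdr < 0.05).sum() == 0


def test_bold_zero_noise_equals_scaled_regressor():
    rng = np.random.default_rng(1)
    tt = TrialTable(np.arange(20) * 200 + 100, np.zeros(20, int), ["task"] * 20)
    m = _measures(rng.standard_normal((20, 6)))
    bd = generate_bold(m, tt, 5000, 50.0, 2.0, coupling=[("n", "sse", 2.0)], noise_sd=0.0)
    reg = trial_regressor(m.table["sse"].to_numpy(), tt, 5000, 50.0, 2.0)
    assert np.allclose(bd["n"].to_numpy(), 2.0 * reg / reg.std())
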