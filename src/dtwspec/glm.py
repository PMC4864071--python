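"""Cross-prediction statistics: per-subject GLMs, group tests, FDR, permutations.

Each of the six trial-wise measures is predicted, per subject, from the five
others by ordinary least squares (predictors z-scored within subject,
intercept included).  The per-subject beta of every (target, predictor) cell
is then tested against zero across subjects with a one-sample t-test;
p-values are Benjamini-Hochberg corrected over all off-diagonal cells of one
condition's matrix, and an empirical permutation p accompanies each cell.

The permutation null shuffles the target variable's row order within each
subject (predictor covariance preserved), refits the GLMs and recomputes the
group t; ``p = (1 + #{|t_perm| >= |t_obs|}) / (n_perm + 1)``.

For BOLD-style network time courses the same machinery applies with the
network course as target and HRF-convolved, TR-resampled trial measures as
regressors.  Stochastic pipeline stages (MLP, k-means) can be averaged over
repetitions: betas from repeated measure extractions are averaged before the
group test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import MEASURE_NAMES, TrialMeasures, TrialTable

__all__ = [
    "StatsConfig",
    "ComparisonResult",
    "fit_trial_glm",
    "group_ttest",
    "fdr_bh",
    "permutation_test",
    "hrf_kernel",
    "hrf_convolve",
    "trial_regressor",
    "run_comparison",
    "bold_comparison",
]


@dataclass
class StatsConfig:
    alpha: float = 0.05
    n_perm: int = 5000
    n_reps: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")


@dataclass
class ComparisonResult:
    """Long-format (condition, target, predictor) table of group statistics."""

    table: pd.DataFrame  # columns: condition target predictor mean_beta t p_raw p_fdr p_perm

    def cell(self, condition: str, target: str, predictor: str) -> pd.Series:
        t = self.table
        row = t[
            (t.condition == condition) & (t.target == target) & (t.predictor == predictor)
        ]
        if len(row) != 1:
            raise KeyError((condition, target, predictor))
        return row.iloc[0]

    def pivot(self, condition: str, value: str = "p_fdr") -> pd.DataFrame:
        t = self.table[self.table.condition == condition]
        return t.pivot(index="target", columns="predictor", values=value)


def _zscore_cols(X: np.ndarray) -> np.ndarray:
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return (X - X.mean(axis=0)) / sd


def _design(values: np.ndarray, target_idx: int) -> tuple[np.ndarray, np.ndarray]:
    """(X with intercept, y) for one target column; predictors z-scored."""
    pred_idx = [j for j in range(values.shape[1]) if j != target_idx]
    X = _zscore_cols(values[:, pred_idx])
    X = np.column_stack([np.ones(len(X)), X])
    return X, values[:, target_idx]


def fit_trial_glm(measures: TrialMeasures, target: str) -> pd.Series:
    """OLS betas of the five non-target measures predicting the target."""
    if target not in MEASURE_NAMES:
        raise KeyError(f"unknown measure {target!r}")
    values = measures.values()
    tgt = MEASURE_NAMES.index(target)
    if len(values) < values.shape[1] + 2:
        raise ValueError("too few trials for the GLM")
    X, y = _design(values, tgt)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("singular design (collinear predictors)")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    names = [m for m in MEASURE_NAMES if m != target]
    return pd.Series(beta[1:], index=names, name=target)


def group_ttest(betas) -> tuple[float, float]:
    """One-sample two-sided t-test of per-subject betas against zero."""
    b = np.asarray(betas, dtype=float)
    if b.size < 2:
        raise ValueError("need >= 2 subjects")
    if b.std(ddof=1) == 0:
        if b.mean() == 0:
            return 0.0, 1.0
        raise ValueError(
            f"degenerate group: all betas identical at {b.mean():+g} (zero variance)"
        )
    res = stats.ttest_1samp(b, 0.0)
    return float(res.statistic), float(res.pvalue)


def fdr_bh(pvals, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (reject flags, adjusted p)."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
    return reject, p_adj


def _perm_group_t(
    designs: list[tuple[np.ndarray, np.ndarray]],
    col: int,
    n_perm: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Group t per permutation; target rows shuffled within each subject.

    ``designs`` holds one (X, y) per subject (X includes the intercept);
    ``col`` indexes the tested column of X.  Each subject list entry may also
    be a list of per-repetition (X, y) pairs whose betas are averaged.
    """
    n_subj = len(designs)
    betas = np.empty((n_perm, n_subj))
    for s, entry in enumerate(designs):
        reps = entry if isinstance(entry, list) else [entry]
        acc = np.zeros(n_perm)
        for X, y in reps:
            pinv_row = np.linalg.pinv(X)[col]
            perms = np.argsort(rng.random((n_perm, len(y))), axis=1)
            acc += y[perms] @ pinv_row
        betas[:, s] = acc / len(reps)
    mean = betas.mean(axis=1)
    sd = betas.std(axis=1, ddof=1)
    sd[sd == 0] = np.inf
    return mean / (sd / np.sqrt(n_subj))


def permutation_test(
    measures: list[TrialMeasures],
    target: str,
    predictor: str,
    cfg: StatsConfig,
) -> float:
    """Permutation p for one (target, predictor) cell across subjects."""
    if target == predictor:
        raise ValueError("target and predictor must differ")
    tgt = MEASURE_NAMES.index(target)
    pred_names = [m for m in MEASURE_NAMES if m != target]
    col = 1 + pred_names.index(predictor)
    designs = [_design(m.values(), tgt) for m in measures]
    obs = np.array([np.linalg.lstsq(X, y, rcond=None)[0][col] for X, y in designs])
    t_obs, _ = group_ttest(obs)
    rng = np.random.default_rng(cfg.seed)
    t_perm = _perm_group_t(designs, col, cfg.n_perm, rng)
    return float((1 + np.sum(np.abs(t_perm) >= abs(t_obs))) / (cfg.n_perm + 1))


# ---------------------------------------------------------------------------
# hemodynamic response


def hrf_kernel(rate: float, duration: float = 32.0) -> np.ndarray:
    """Canonical double-gamma HRF sampled at ``rate``; peak-normalized.

    Response gamma with shape 6, undershoot gamma with shape 16 (unit scale,
    seconds), undershoot ratio 1/6; the positive peak falls near 5 s.
    """
    t = np.arange(0.0, duration, 1.0 / rate)
    h = stats.gamma.pdf(t, a=6.0) - stats.gamma.pdf(t, a=16.0) / 6.0
    return h / h.max()


def hrf_convolve(regressor, rate: float) -> np.ndarray:
    """Linear convolution with the double-gamma HRF, truncated to input length."""
    x = np.asarray(regressor, dtype=float).ravel()
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite regressor")
    return np.convolve(x, hrf_kernel(rate))[: x.size]


def trial_regressor(
    values: np.ndarray,
    trials: TrialTable,
    n_samples: int,
    rate: float,
    tr: float | None = None,
) -> np.ndarray:
    """Impulse train of per-trial values, HRF-convolved, optionally TR-resampled."""
    impulses = np.zeros(n_samples)
    impulses[trials.trial_sample] = np.asarray(values, dtype=float)
    course = hrf_convolve(impulses, rate)
    if tr is None:
        return course
    frame_idx = np.arange(0, n_samples, int(round(tr * rate)))
    return course[frame_idx]


# ---------------------------------------------------------------------------
# group comparisons


def _as_reps(measures) -> list[list[TrialMeasures]]:
    """Normalize input to a list over repetitions of per-subject lists."""
    if isinstance(measures[0], TrialMeasures):
        return [list(measures)]
    return [list(rep) for rep in measures]


def _condition_measures(
    m: TrialMeasures, trials: TrialTable | None, condition: str
) -> TrialMeasures:
    if trials is None or condition == "all":
        return m
    mask = trials.condition_mask(condition)
    return TrialMeasures(table=m.table[mask].reset_index(drop=True), subject_id=m.subject_id)


def run_comparison(
    measures,
    trials: list[TrialTable] | None = None,
    cfg: StatsConfig | None = None,
) -> ComparisonResult:
    """All-pairs cross-prediction matrix per condition.

    ``measures`` is a per-subject list of :class:`TrialMeasures`, or a list of
    such lists (one per pipeline repetition; betas are averaged across
    repetitions before the group test).  When ``trials`` is given the analysis
    is run separately on task and rest trials; otherwise one condition
    ``"all"`` is used.
    """
    cfg = cfg or StatsConfig()
    reps = _as_reps(measures)
    n_subj = len(reps[0])
    conditions = ("task", "rest") if trials is not None else ("all",)
    rows = []
    for cond in conditions:
        # per subject: list over reps of (X, y) per target
        cond_designs: dict[str, list] = {t: [] for t in MEASURE_NAMES}
        betas: dict[str, np.ndarray] = {}
        for target in MEASURE_NAMES:
            tgt = MEASURE_NAMES.index(target)
            per_subj_betas = np.zeros((n_subj, len(MEASURE_NAMES) - 1))
            for s in range(n_subj):
                rep_designs = []
                for rep in reps:
                    mc = _condition_measures(rep[s], trials[s] if trials else None, cond)
                    if not mc.is_complete():
                        raise ValueError(f"incomplete measures for subject {s}")
                    X, y = _design(mc.values(), tgt)
                    rep_designs.append((X, y))
                    per_subj_betas[s] += np.linalg.lstsq(X, y, rcond=None)[0][1:]
                per_subj_betas[s] /= len(reps)
                cond_designs[target].append(rep_designs)
            betas[target] = per_subj_betas
        # group tests over the off-diagonal family
        cells = []
        for target in MEASURE_NAMES:
            pred_names = [m for m in MEASURE_NAMES if m != target]
            for k, predictor in enumerate(pred_names):
                t_stat, p_raw = group_ttest(betas[target][:, k])
                cells.append([cond, target, predictor, betas[target][:, k].mean(), t_stat, p_raw])
        reject, p_adj = fdr_bh([c[5] for c in cells], cfg.alpha)
        rng = np.random.default_rng(cfg.seed)
        for c, padj in zip(cells, p_adj):
            _, target, predictor, _, t_stat, _ = c
            pred_names = [m for m in MEASURE_NAMES if m != target]
            col = 1 + pred_names.index(predictor)
            t_perm = _perm_group_t(cond_designs[target], col, cfg.n_perm, rng)
            p_perm = float((1 + np.sum(np.abs(t_perm) >= abs(t_stat))) / (cfg.n_perm + 1))
            rows.append(c + [padj, p_perm])
    table = pd.DataFrame(
        rows,
        columns=["condition", "target", "predictor", "mean_beta", "t", "p_raw", "p_fdr", "p_perm"],
    )
    return ComparisonResult(table=table)


def bold_comparison(
    measures: list[TrialMeasures],
    trials: list[TrialTable],
    bold: list[pd.DataFrame],
    n_samples: int,
    rate: float,
    tr: float,
    cfg: StatsConfig | None = None,
) -> ComparisonResult:
    """Network time courses as GLM targets of HRF-convolved trial measures.

    ``bold[s]`` holds subject s's network courses (rows = TR frames, columns =
    network names).  Per subject each course is regressed on the six
    convolved, TR-resampled, z-scored measure regressors; group t, BH-FDR
    (family = all network x measure cells) and permutation p (target frames
    shuffled) follow as in :func:`run_comparison`.
    """
    cfg = cfg or StatsConfig()
    networks = list(bold[0].columns)
    designs: dict[str, list] = {}
    betas: dict[str, np.ndarray] = {}
    for s, (m, tt, bd) in enumerate(zip(measures, trials, bold)):
        regs = np.column_stack(
            [
                trial_regressor(m.table[name].to_numpy(), tt, n_samples, rate, tr)
                for name in MEASURE_NAMES
            ]
        )
        X = np.column_stack([np.ones(len(regs)), _zscore_cols(regs)])
        for net in networks:
            y = bd[net].to_numpy(dtype=float)
            if len(y) != len(X):
                raise ValueError("BOLD frame count does not match TR grid")
            designs.setdefault(net, []).append((X, y))
            b = np.linalg.lstsq(X, y, rcond=None)[0][1:]
            betas.setdefault(net, np.zeros((len(measures), len(MEASURE_NAMES))))[s] = b
    cells = []
    for net in networks:
        for k, name in enumerate(MEASURE_NAMES):
            t_stat, p_raw = group_ttest(betas[net][:, k])
            cells.append(["bold", net, name, betas[net][:, k].mean(), t_stat, p_raw])
    _, p_adj = fdr_bh([c[5] for c in cells], cfg.alpha)
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for c, padj in zip(cells, p_adj):
        _, net, name, _, t_stat, _ = c
        col = 1 + MEASURE_NAMES.index(name)
        t_perm = _perm_group_t(designs[net], col, cfg.n_perm, rng)
        p_perm = float((1 + np.sum(np.abs(t_perm) >= abs(t_stat))) / (cfg.n_perm + 1))
        rows.append(c + [padj, p_perm])
    table = pd.DataFrame(
        rows,
        columns=["condition", "target", "predictor", "mean_beta", "t", "p_raw", "p_fdr", "p_perm"],
    )
    return ComparisonResult(table=table)
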