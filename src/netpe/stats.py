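"""Group comparison and classification statistics.

Group differences are assessed with a nonparametric permutation test on the
absolute difference of group means, per ROI: subject labels are randomly
repartitioned (preserving group sizes) and the p-value is the proportion of
partitions whose statistic is at least the observed one.  The default
p-value includes the +1 Monte-Carlo correction, ``p = (b + 1) / (n_perm + 1)``,
which guarantees p > 0; the literal proportion is available via
``plus_one=False``.  Multiple comparisons across ROIs are controlled with
Benjamini–Hochberg FDR; significance is declared at q < 0.05.

Single-feature diagnostic value is summarized by an unregularized logistic
regression with in-sample ROC/AUC (trapezoidal) and a DeLong 95% CI, and by
a one-way ANCOVA of the outcome on group with a continuous covariate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.metrics import roc_curve
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

__all__ = [
    "GroupComparison",
    "ClassificationReport",
    "AncovaReport",
    "permutation_test",
    "fdr_bh",
    "logistic_auc",
    "ancova_oneway",
]


@dataclass(frozen=True)
class GroupComparison:
    """Per-ROI permutation-test results with FDR correction."""

    per_roi_stat: np.ndarray
    p: np.ndarray
    q: np.ndarray
    significant: np.ndarray
    n_permutations: int
    seed: int
    alpha_q: float = 0.05


@dataclass(frozen=True)
class ClassificationReport:
    """Single-feature logistic classification summary."""

    auc: float
    ci_low: float
    ci_high: float
    roc_points: np.ndarray  # ordered (FPR, TPR) pairs
    coefficients: tuple[float, float]  # (intercept, slope)
    perfect_separation: bool = False


@dataclass(frozen=True)
class AncovaReport:
    """One-way ANCOVA of an outcome on a binary group with one covariate."""

    F: float
    df: tuple[int, int]
    p: float
    eta_sq: float


def permutation_test(
    group_a,
    group_b,
    n_perm: int = 10_000,
    seed: int = 0,
    alpha_q: float = 0.05,
    plus_one: bool = True,
) -> GroupComparison:
    """Two-sided permutation test of group mean differences, per ROI.

    ``group_a`` and ``group_b`` are ``subjects x ROIs`` arrays.  The
    statistic is ``|mean_a - mean_b|`` per ROI; all ROIs share the same
    ``n_perm`` random repartitions.  Reproducible given ``seed``.
    """
    a = np.atleast_2d(np.asarray(group_a, dtype=float))
    b = np.atleast_2d(np.asarray(group_b, dtype=float))
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("each group needs at least 2 subjects")
    if a.shape[1] != b.shape[1]:
        raise ValueError(f"ROI counts differ: {a.shape[1]} vs {b.shape[1]}")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    n_a, n_b = a.shape[0], b.shape[0]
    pooled = np.vstack([a, b])
    t_obs = np.abs(a.mean(axis=0) - b.mean(axis=0))

    rng = np.random.default_rng(seed)
    # 0/1 membership matrix for the permuted "group a": n_perm x n_subjects
    order = np.argsort(rng.random((n_perm, n_a + n_b)), axis=1)
    member = np.zeros((n_perm, n_a + n_b))
    np.put_along_axis(member, order[:, :n_a], 1.0, axis=1)
    mean_a = member @ pooled / n_a
    mean_b = (1.0 - member) @ pooled / n_b
    t_perm = np.abs(mean_a - mean_b)

    exceed = (t_perm >= t_obs[None, :]).sum(axis=0)
    if plus_one:
        p = (exceed + 1) / (n_perm + 1)
    else:
        p = exceed / n_perm
    q = fdr_bh(np.clip(p, np.finfo(float).tiny, 1.0))
    return GroupComparison(
        per_roi_stat=t_obs,
        p=p,
        q=q,
        significant=q < alpha_q,
        n_permutations=n_perm,
        seed=seed,
        alpha_q=alpha_q,
    )


def fdr_bh(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values).

    Input p-values must lie in (0, 1]; output preserves ties and the input
    order, and is elementwise >= the input.
    """
    p = np.asarray(p, dtype=float).ravel()
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _delong_auc_variance(pos: np.ndarray, neg: np.ndarray) -> tuple[float, float]:
    """AUC and its DeLong variance from feature values of the two classes.

    Uses midranks, so ties contribute 1/2; the AUC equals the Mann–Whitney
    U statistic divided by ``n_pos * n_neg``.
    """
    m, n = pos.size, neg.size
    combined = np.concatenate([pos, neg])
    rank_all = sps.rankdata(combined)  # midranks
    rank_pos = sps.rankdata(pos)
    rank_neg = sps.rankdata(neg)
    auc = (rank_all[:m].sum() - m * (m + 1) / 2) / (m * n)
    # structural components V10 (cases), V01 (controls)
    v10 = (rank_all[:m] - rank_pos) / n
    v01 = 1.0 - (rank_all[m:] - rank_neg) / m
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(auc), float(s10 / m + s01 / n)


def logistic_auc(feature, labels) -> ClassificationReport:
    """Diagnostic value of one feature via unregularized logistic regression.

    Fits ``logit P(label=1) = b0 + b1 * feature`` by maximum likelihood,
    computes the in-sample ROC over fitted probabilities, the AUC by
    trapezoidal integration of that ROC (equivalently the midrank
    Mann–Whitney U of the model score divided by ``n1 * n2``), and a 95% CI
    by the DeLong method (clipped to [0, 1]).  If the classes are
    perfectly separated the ML fit diverges; the report is then flagged and
    the score falls back to the feature ranks, oriented by the direction of
    separation.
    """
    x = np.asarray(feature, dtype=float).ravel()
    y = np.asarray(labels).ravel()
    if x.size != y.size:
        raise ValueError("feature and labels differ in length")
    if not np.all(np.isfinite(x)):
        raise ValueError("feature contains non-finite values")
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"need exactly two classes, got {classes.size}")
    y01 = (y == classes[1]).astype(float)

    separated = False
    coef = (np.nan, np.nan)
    design = sm.add_constant(x, has_constant="add")
    score = None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            fit = sm.Logit(y01, design).fit(disp=0, warn_convergence=False)
        coef = (float(fit.params[0]), float(fit.params[1]))
        if not (np.all(np.isfinite(fit.params)) and np.all(np.isfinite(fit.bse))):
            separated = True
        if np.all(np.isfinite(fit.params)):
            score = np.asarray(fit.predict(design), dtype=float)
    except (PerfectSeparationError, PerfectSeparationWarning, np.linalg.LinAlgError):
        separated = True
    if score is None or not np.all(np.isfinite(score)):
        # ROC/AUC depend only on the ranking; orient by direction of separation
        direction = np.sign(x[y01 == 1].mean() - x[y01 == 0].mean()) or 1.0
        score = direction * x

    fpr, tpr, _ = roc_curve(y01, score)
    roc_points = np.column_stack([fpr, tpr])
    auc, var = _delong_auc_variance(score[y01 == 1], score[y01 == 0])
    half = 1.959963984540054 * np.sqrt(var)
    return ClassificationReport(
        auc=auc,
        ci_low=float(np.clip(auc - half, 0.0, auc)),
        ci_high=float(np.clip(auc + half, auc, 1.0)),
        roc_points=roc_points,
        coefficients=coef,
        perfect_separation=separated,
    )


def ancova_oneway(y, group, covariate) -> AncovaReport:
    """One-way ANCOVA: ``y ~ intercept + covariate + group`` (group binary).

    Reports the F statistic of the group term with ``(1, N - 3)`` degrees
    of freedom and the partial effect size
    ``eta_sq = SS_group / (SS_group + SS_residual)``.
    """
    y = np.asarray(y, dtype=float).ravel()
    g = np.asarray(group).ravel()
    cov = np.asarray(covariate, dtype=float).ravel()
    if not (y.size == g.size == cov.size):
        raise ValueError("y, group and covariate must have equal length")
    classes = np.unique(g)
    if classes.size != 2:
        raise ValueError("group must be binary")
    g01 = (g == classes[1]).astype(float)
    if min((g01 == 0).sum(), (g01 == 1).sum()) < 3:
        raise ValueError("each group needs at least 3 subjects")

    full = sm.OLS(y, sm.add_constant(np.column_stack([cov, g01]))).fit()
    reduced = sm.OLS(y, sm.add_constant(cov)).fit()
    ss_group = reduced.ssr - full.ssr
    df_resid = int(full.df_resid)
    if full.ssr <= 0 or df_resid <= 0:
        raise ValueError("zero residual variance: covariate/group collinear with outcome")
    F = max(0.0, ss_group) / (full.ssr / df_resid)
    p = float(sps.f.sf(F, 1, df_resid))
    eta_sq = max(0.0, ss_group) / (max(0.0, ss_group) + full.ssr)
    return AncovaReport(F=float(F), df=(1, df_resid), p=p, eta_sq=float(eta_sq))
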