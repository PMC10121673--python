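"""Classification metrics, bootstrap intervals, permutation tests and
decision-curve analysis.

Point estimates a with 95 % bootstrap confidence intervals [a-b, a+c]
follow the a^{+c}_{-b} reporting convention and are stored as the triple
(a, b, c). Model comparisons on the same samples use a paired permutation
test (scores swapped per sample); estimates from disjoint cohorts use an
unpaired permutation test (group membership permuted).

Net benefit at threshold probability p_t values a treat-by-model policy as
TP/n - (FP/n) * p_t/(1-p_t); the untreated side credits true negatives as
TN/n - (FN/n) * (1-p_t)/p_t. The combined curve is their sum, integrated
over the threshold grid by the trapezoid rule, with median/IQR taken over
cohort bootstrap resamples.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .refit import round_half_away


# ---------------------------------------------------------------------------
# Cohort summary pooling
# ---------------------------------------------------------------------------

def pooled_mean(means, ns) -> float:
    """Sample-size-weighted mean across subgroups (groups with missing data
    contribute their observed n only)."""
    means = np.asarray(means, dtype=float)
    ns = np.asarray(ns, dtype=float)
    if (ns <= 0).any():
        raise ValueError("group sizes must be positive")
    return float((means * ns).sum() / ns.sum())


def pooled_percentage(counts, totals) -> float:
    """Pooled event percentage across subgroups, on the 0-100 scale."""
    c = float(np.sum(counts))
    n = float(np.sum(totals))
    if n <= 0 or c < 0 or c > n:
        raise ValueError("invalid counts/totals")
    return 100.0 * c / n


# ---------------------------------------------------------------------------
# Confusion-matrix metrics
# ---------------------------------------------------------------------------

def confusion_metrics(tp: int, fp: int, tn: int, fn: int) -> dict[str, float]:
    """Sensitivity, specificity, accuracy and F1 from confusion counts,
    rounded half-away-from-zero to two decimals; undefined metrics (empty
    denominator) are reported as NaN."""
    for name, v in (("tp", tp), ("fp", fp), ("tn", tn), ("fn", fn)):
        if v < 0 or v != int(v):
            raise ValueError(f"{name} must be a non-negative integer")
    total = tp + fp + tn + fn

    def safe(num, den):
        return round_half_away(num / den, 2) if den > 0 else float("nan")

    return {
        "sensitivity": safe(tp, tp + fn),
        "specificity": safe(tn, tn + fp),
        "accuracy": safe(tp + tn, total),
        "f1": safe(2 * tp, 2 * tp + fp + fn),
    }


def _binary(labels) -> np.ndarray:
    y = np.asarray(labels)
    if y.dtype.kind in "USO":
        y = (y == "yes").astype(int)
    return y.astype(int)


def roc_auc(scores, labels) -> float:
    """ROC AUC as pairwise concordance with half credit for score ties."""
    y = _binary(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC AUC requires both classes")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def average_precision(scores, labels) -> float:
    y = _binary(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("average precision requires both classes")
    return float(average_precision_score(y, np.asarray(scores, dtype=float)))


# ---------------------------------------------------------------------------
# Bootstrap confidence intervals
# ---------------------------------------------------------------------------

def bootstrap_ci(metric, scores, labels, n_boot: int = 1000,
                 rng=None) -> tuple[float, float, float]:
    """95 % percentile bootstrap interval for `metric(scores, labels)`.

    Returns (a, b, c) for the a^{+c}_{-b} notation. Resamples that end up
    with a single class (on which rank metrics are undefined) are redrawn.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    s = np.asarray(scores, dtype=float)
    y = _binary(labels)
    point = float(metric(s, y))
    both_classes = len(np.unique(y)) == 2
    stats = np.empty(n_boot)
    for i in range(n_boot):
        for _ in range(1000):
            idx = gen.integers(0, len(y), size=len(y))
            if not both_classes or len(np.unique(y[idx])) == 2:
                break
        else:  # pragma: no cover - pathological inputs only
            raise RuntimeError("could not draw a two-class bootstrap resample")
        stats[i] = metric(s[idx], y[idx])
    lo, hi = np.percentile(stats, [2.5, 97.5])
    return point, point - float(lo), float(hi) - point


# ---------------------------------------------------------------------------
# Permutation tests
# ---------------------------------------------------------------------------

def paired_permutation_test(scores_a, scores_b, labels, metric,
                            n_perm: int = 10_000, rng=None) -> float:
    """Paired comparison of two models scored on the same samples.

    The null swaps the two models' scores per sample with probability 1/2;
    two-sided p = (1 + #{|delta*| >= |delta|}) / (R + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired scores must have the same length")
    y = _binary(labels)
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    observed = abs(metric(a, y) - metric(b, y))
    hits = 0
    for _ in range(n_perm):
        swap = gen.random(len(a)) < 0.5
        a_p = np.where(swap, b, a)
        b_p = np.where(swap, a, b)
        if abs(metric(a_p, y) - metric(b_p, y)) >= observed - 1e-15:
            hits += 1
    return (1 + hits) / (n_perm + 1)


def unpaired_permutation_test(scores_1, labels_1, scores_2, labels_2, metric,
                              n_perm: int = 10_000, rng=None) -> float:
    """Compare a metric between two disjoint cohorts by permuting cohort
    membership of the (score, label) pairs."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    s1, s2 = np.asarray(scores_1, float), np.asarray(scores_2, float)
    y1, y2 = _binary(labels_1), _binary(labels_2)
    if len(s1) == 0 or len(s2) == 0:
        raise ValueError("both groups must be non-empty")
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    pool_s = np.concatenate([s1, s2])
    pool_y = np.concatenate([y1, y2])
    n1 = len(s1)
    observed = abs(metric(s1, y1) - metric(s2, y2))
    hits = 0
    for _ in range(n_perm):
        perm = gen.permutation(len(pool_s))
        g1, g2 = perm[:n1], perm[n1:]
        if len(np.unique(pool_y[g1])) < 2 or len(np.unique(pool_y[g2])) < 2:
            hits += 1  # metric undefined under this shuffle; count conservatively
            continue
        if abs(metric(pool_s[g1], pool_y[g1])
               - metric(pool_s[g2], pool_y[g2])) >= observed - 1e-15:
            hits += 1
    return (1 + hits) / (n_perm + 1)


# ---------------------------------------------------------------------------
# Decision-curve analysis
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class DecisionCurve:
    thresholds: np.ndarray
    nb_model: np.ndarray           # treated-side net benefit of the model
    nb_untreated: np.ndarray       # untreated-side net benefit of the model
    nb_treat_all: np.ndarray
    nb_combined: np.ndarray
    integrated_combined: float     # trapezoid over the grid (point estimate)
    bootstrap_median: float | None = None
    bootstrap_iqr: tuple[float, float] | None = None


def net_benefit(predictions, labels, p_t: float) -> float:
    """Treated-side net benefit of acting on binary predictions at
    threshold probability p_t."""
    if not 0.0 < p_t < 1.0:
        raise ValueError("p_t must be strictly inside (0, 1)")
    pred = _binary(predictions).astype(bool)
    y = _binary(labels).astype(bool)
    n = len(y)
    tp = int((pred & y).sum())
    fp = int((pred & ~y).sum())
    return tp / n - (fp / n) * p_t / (1.0 - p_t)


def net_benefit_untreated(predictions, labels, p_t: float) -> float:
    """Untreated-side net benefit: value of withholding treatment from
    predicted non-beneficiaries."""
    if not 0.0 < p_t < 1.0:
        raise ValueError("p_t must be strictly inside (0, 1)")
    pred = _binary(predictions).astype(bool)
    y = _binary(labels).astype(bool)
    n = len(y)
    tn = int((~pred & ~y).sum())
    fn = int((~pred & y).sum())
    return tn / n - (fn / n) * (1.0 - p_t) / p_t


def decision_curve(posteriors, labels, thresholds=None,
                   integration_range: tuple[float, float] = (0.3, 0.6),
                   n_boot: int = 1000, rng=None) -> DecisionCurve:
    """Decision curve over a threshold grid (default 0.01..0.99 step 0.01).

    The classifier treats at posterior >= p_t. The integrated combined net
    benefit is reported over `integration_range` (the clinically discussed
    threshold band); its median and IQR come from `n_boot` cohort
    bootstrap resamples.
    """
    post = np.asarray(posteriors, dtype=float)
    y = _binary(labels)
    grid = (np.round(np.arange(0.01, 1.0, 0.01), 2) if thresholds is None
            else np.asarray(thresholds, dtype=float))
    prevalence = y.mean()

    def curves(post_, y_):
        nb_m = np.empty(len(grid))
        nb_u = np.empty(len(grid))
        nb_all = np.empty(len(grid))
        for i, p_t in enumerate(grid):
            pred = (post_ >= p_t).astype(int)
            nb_m[i] = net_benefit(pred, y_, p_t)
            nb_u[i] = net_benefit_untreated(pred, y_, p_t)
            prev = y_.mean()
            nb_all[i] = prev - (1 - prev) * p_t / (1 - p_t)
        return nb_m, nb_u, nb_all

    def integrated(post_, y_):
        nb_m, nb_u, _ = curves(post_, y_)
        combined = nb_m + nb_u
        lo, hi = integration_range
        mask = (grid >= lo) & (grid <= hi)
        return float(np.trapezoid(combined[mask], grid[mask]))

    nb_model, nb_untr, nb_all = curves(post, y)
    point = integrated(post, y)

    median = iqr = None
    if n_boot:
        gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        vals = np.empty(n_boot)
        for i in range(n_boot):
            idx = gen.integers(0, len(y), size=len(y))
            vals[i] = integrated(post[idx], y[idx])
        median = float(np.median(vals))
        iqr = (float(np.percentile(vals, 25)), float(np.percentile(vals, 75)))
    return DecisionCurve(thresholds=grid, nb_model=nb_model, nb_untreated=nb_untr,
                         nb_treat_all=nb_all, nb_combined=nb_model + nb_untr,
                         integrated_combined=point,
                         bootstrap_median=median, bootstrap_iqr=iqr)


def calibration_curve(posteriors, labels, bins: int = 10) -> pd.DataFrame:
    """Reliability diagram data: per equal-width bin on [0, 1], the mean
    posterior and the observed benefit rate; empty bins are omitted."""
    if bins < 2:
        raise ValueError("bins must be >= 2")
    post = np.asarray(posteriors, dtype=float)
    y = _binary(labels)
    edges = np.linspace(0.0, 1.0, bins + 1)
    idx = np.clip(np.digitize(post, edges[1:-1]), 0, bins - 1)
    rows = []
    for b in range(bins):
        mask = idx == b
        if not mask.any():
            continue
        rows.append({"bin": b, "mean_posterior": float(post[mask].mean()),
                     "observed_rate": float(y[mask].mean()),
                     "count": int(mask.sum())})
    return pd.DataFrame(rows)
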