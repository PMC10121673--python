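"""Univariate screening: signature-outcome tests and signature-gene correlation.

Per-signature attribution distributions are compared between durable-
benefit strata with a two-sided Kolmogorov-Smirnov test, corrected across
the signatures of one channel system by Benjamini-Hochberg (significance
at q <= 0.05). Signature-gene association uses tie-corrected Kendall
tau-b across a gene panel (non-mutated genes excluded first), Fisher's
exact test for tumor-suppressor/oncogene enrichment, and a logistic
regression check for whether a gene confounds tumor mutational burden.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .io_formats import logger

SIGNIFICANCE_LEVEL = 0.05
CONFOUNDING_CHANGE = 0.10


# ---------------------------------------------------------------------------
# Elementary tests
# ---------------------------------------------------------------------------

def ks_two_sample(a, b) -> tuple[float, float]:
    """Two-sided two-sample Kolmogorov-Smirnov test.

    The p-value is exact (enumeration over orderings) for tie-free samples
    with n_a + n_b <= 12, asymptotic otherwise; the D statistic is exact
    in both regimes.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("ks_two_sample requires non-empty samples")
    pooled = np.concatenate([a, b])
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (a.size + b.size <= 12 and tie_free) else "asymp"
    res = scipy.stats.ks_2samp(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (q-values).

    q_(i) = min_{j >= i} p_(j) * N / j, capped at 1, returned in the
    input order.
    """
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    q = np.empty(n)
    q[order] = q_sorted
    return q


def kendall_tau(x, y) -> tuple[float, float]:
    """Kendall tau-b with tie correction; two-sided p from the
    tie-adjusted normal approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("kendall_tau requires equal-length inputs")
    if x.size < 2:
        raise ValueError("kendall_tau requires n >= 2")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("kendall_tau undefined for zero-variance input")
    res = scipy.stats.kendalltau(x, y, variant="b", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p: total hypergeometric mass of tables (at
    fixed margins) no more probable than the observed one."""
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("fisher_exact_2x2 requires a 2x2 table")
    if (t < 0).any() or not np.issubdtype(t.dtype, np.integer):
        if (t < 0).any() or not np.allclose(t, np.round(t)):
            raise ValueError("table entries must be non-negative integers")
        t = t.astype(int)
    return float(scipy.stats.fisher_exact(t, alternative="two-sided")[1])


# ---------------------------------------------------------------------------
# Screens
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ScreenResult:
    """Per-feature screening statistics (one table per test battery)."""

    table: pd.DataFrame  # columns: statistic, p, q, significant

    @property
    def significant(self) -> list[str]:
        return list(self.table.index[self.table["significant"]])


def _finalise(stats: dict[str, float], pvals: dict[str, float],
              alpha: float) -> ScreenResult:
    names = list(pvals)
    q = benjamini_hochberg([pvals[k] for k in names])
    table = pd.DataFrame({
        "statistic": [stats[k] for k in names],
        "p": [pvals[k] for k in names],
        "q": q,
    }, index=names)
    table["significant"] = table["q"] <= alpha
    return ScreenResult(table=table)


def screen_signatures(per_mb: pd.DataFrame, db_labels: pd.Series,
                      alpha: float = SIGNIFICANCE_LEVEL) -> ScreenResult:
    """K-S screen of every signature between durable-benefit strata.

    Samples with unknown label are excluded; B-H correction is applied
    across the signatures in `per_mb` (one channel system per call).
    """
    labels = db_labels.reindex(per_mb.index)
    known = labels.isin(["yes", "no"])
    block = per_mb.loc[known]
    lab = labels.loc[known]
    if (lab == "yes").sum() == 0 or (lab == "no").sum() == 0:
        raise ValueError("both durable-benefit strata must be non-empty")
    stats, pvals = {}, {}
    for sig in block.columns:
        d, p = ks_two_sample(block.loc[lab == "yes", sig],
                             block.loc[lab == "no", sig])
        stats[sig], pvals[sig] = d, p
    return _finalise(stats, pvals, alpha)


def gene_correlation(signature_values: pd.Series, gene_counts: pd.DataFrame,
                     tmb: pd.Series | None = None,
                     alpha: float = SIGNIFICANCE_LEVEL) -> ScreenResult:
    """Kendall tau-b of a signature's attribution against per-gene mutation
    counts, B-H corrected across the panel.

    Genes with no mutation in any sample are excluded before correction
    (their correlation is trivially zero). With `tmb` given, the signature
    is normalised by tumor mutational burden first.
    """
    values = signature_values.copy()
    if tmb is not None:
        t = tmb.reindex(values.index).astype(float)
        values = values / t.replace(0.0, np.nan)
    counts = gene_counts.reindex(values.index)
    mutated = counts.columns[counts.sum(axis=0) > 0]
    dropped = set(counts.columns) - set(mutated)
    if dropped:
        logger.info("gene_correlation: excluded %d non-mutated genes", len(dropped))
    stats, pvals = {}, {}
    for gene in mutated:
        mask = values.notna() & counts[gene].notna()
        try:
            tau, p = kendall_tau(values[mask], counts.loc[mask, gene])
        except ValueError:
            continue  # zero-variance gene among the retained samples
        stats[gene], pvals[gene] = tau, p
    if not pvals:
        return ScreenResult(table=pd.DataFrame(
            columns=["statistic", "p", "q", "significant"]))
    return _finalise(stats, pvals, alpha)


@dataclasses.dataclass
class ConfoundingResult:
    coef_without: float
    coef_with: float
    change_ratio: float
    confounded: bool
    converged: bool
    gene_p: float | None = None


def logistic_confounding(db_labels, tmb, gene_indicator) -> ConfoundingResult:
    """Does adding a gene covariate move the TMB coefficient by > 10 %?

    Fits logistic models of durable benefit on TMB, with and without the
    gene indicator (maximum likelihood via iteratively reweighted least
    squares). Perfect separation is flagged as non-converged.
    """
    y = np.asarray(db_labels, dtype=float)
    t = np.asarray(tmb, dtype=float)
    g = np.asarray(gene_indicator, dtype=float)
    base = sm.Logit(y, sm.add_constant(t))
    full = sm.Logit(y, sm.add_constant(np.column_stack([t, g])))
    try:
        fit0 = base.fit(disp=0)
        fit1 = full.fit(disp=0)
        converged = bool(fit0.mle_retvals["converged"] and fit1.mle_retvals["converged"])
    except (sm.tools.sm_exceptions.PerfectSeparationError, np.linalg.LinAlgError):
        return ConfoundingResult(np.nan, np.nan, np.nan, False, False)
    coef0 = float(fit0.params[1])
    coef1 = float(fit1.params[1])
    change = abs(coef1 - coef0) / abs(coef0) if coef0 != 0 else np.inf
    return ConfoundingResult(
        coef_without=coef0, coef_with=coef1, change_ratio=change,
        confounded=bool(converged and change > CONFOUNDING_CHANGE),
        converged=converged, gene_p=float(fit1.pvalues[2]),
    )
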