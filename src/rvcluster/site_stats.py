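"""Per-site association P-values, direction classes, and Madsen–Browning weights.

Each variant site contributes three ingredients to the region statistic: a
per-site P-value (Fisher mid-P on the 2x2 allele table by default, or a
logistic-regression Wald P when covariate adjustment is needed), a direction
class (deleterious-inclined when the minor allele is strictly more frequent in
cases than controls, protective-inclined when strictly less, tied otherwise),
and a Madsen–Browning weight w = 1/sqrt(n*q*(1-q)) built from the smoothed
control minor-allele frequency q = (m_U + 1)/(2*n_U + 2), which up-weights
sites rare in controls.

The 2x2 tables use allele counts (two alleles per subject).  The mid-P uses
the probability-based two-sided rule: the sum of hypergeometric outcome
probabilities strictly smaller than the observed one, plus half of the tied
probabilities.  Tie classification is done in exact integer arithmetic
(binomial-coefficient weights), so near-equal floating point pmf values cannot
be misgrouped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache
from math import comb, sqrt

import numpy as np

logger = logging.getLogger(__name__)

DELETERIOUS = "deleterious_inclined"
PROTECTIVE = "protective_inclined"
TIED = "tied"


@dataclass(frozen=True)
class SiteSummary:
    """Per-site ingredients of the region statistic."""

    site_id: str
    position: int
    p_value: float
    direction: str  # deleterious_inclined | protective_inclined | tied
    weight: float
    maf_combined: float


@lru_cache(maxsize=262144)
def _midp_support(n_case_alleles: int, n_ctrl_alleles: int, m: int):
    """Mid-P values for every attainable case minor-allele count at fixed margins.

    For the 2x2 table with ``m`` total minor alleles split between
    ``n_case_alleles`` case and ``n_ctrl_alleles`` control alleles, returns
    ``(a_min, values)`` where ``values[a - a_min]`` is the two-sided mid-P of
    observing ``a`` minor alleles in cases.  Outcome probabilities under the
    hypergeometric null are proportional to the exact integer weights
    C(N1, a) * C(N2, m - a); comparisons between them are exact.

    A degenerate margin (only one attainable table, e.g. a monomorphic site)
    returns the conventional P of 1.0.
    """
    a_min = max(0, m - n_ctrl_alleles)
    a_max = min(m, n_case_alleles)
    weights = [comb(n_case_alleles, a) * comb(n_ctrl_alleles, m - a)
               for a in range(a_min, a_max + 1)]
    k = len(weights)
    if k == 1:
        return a_min, (1.0,)
    total = sum(weights)
    order = sorted(range(k), key=weights.__getitem__)
    out = [0.0] * k
    below = 0
    i = 0
    while i < k:
        j = i
        while j + 1 < k and weights[order[j + 1]] == weights[order[i]]:
            j += 1
        group = order[i:j + 1]
        gsum = sum(weights[g] for g in group)
        p = (2 * below + gsum) / (2 * total)  # below + 0.5*gsum, exact big-int ratio
        p = min(p, 1.0)
        for g in group:
            out[g] = p
        below += gsum
        i = j + 1
    return a_min, tuple(out)


def fisher_mid_p(a: int, b: int, n_case_alleles: int, n_ctrl_alleles: int) -> float:
    """Two-sided Fisher mid-P for the 2x2 minor/major allele table.

    Parameters
    ----------
    a, b : int
        Minor-allele counts in cases and controls.
    n_case_alleles, n_ctrl_alleles : int
        Allele totals (2 x number of subjects) in each group.
    """
    a, b = int(a), int(b)
    n1, n2 = int(n_case_alleles), int(n_ctrl_alleles)
    if a < 0 or b < 0:
        raise ValueError("negative allele counts")
    if a > n1 or b > n2:
        raise ValueError("minor-allele count exceeds allele margin")
    a_min, vals = _midp_support(n1, n2, a + b)
    return vals[a - a_min]


def _midp_lookup(n_case_alleles: int, n_ctrl_alleles: int, m_per_site: np.ndarray) -> np.ndarray:
    """Padded (K, max(m)+1) table of mid-P values indexed by [site, case minor count]."""
    m_per_site = np.asarray(m_per_site, dtype=np.int64)
    tab = np.ones((m_per_site.size, int(m_per_site.max()) + 1))
    for k, m in enumerate(m_per_site):
        a_min, vals = _midp_support(n_case_alleles, n_ctrl_alleles, int(m))
        tab[k, a_min:a_min + len(vals)] = vals
    return tab


def madsen_browning_weight(m_U: int, n_U: int, n_total: int) -> float:
    """Madsen–Browning weight w = 1/sqrt(n_total * q * (1-q)).

    ``q = (m_U + 1)/(2*n_U + 2)`` is the +1-smoothed minor-allele frequency in
    the unaffected subjects; ``n_total`` is the number of subjects genotyped at
    the site.  Rarer-in-controls sites receive larger weights (w is strictly
    decreasing in m_U while q < 0.5).
    """
    if n_U < 1 or n_total < n_U:
        raise ValueError("need n_total >= n_U >= 1")
    if not (0 <= m_U <= 2 * n_U):
        raise ValueError("m_U outside [0, 2*n_U]")
    q = (m_U + 1) / (2 * n_U + 2)
    return 1.0 / sqrt(n_total * q * (1.0 - q))


def per_site_pvalues_logistic(panel, pheno, covariates=None) -> np.ndarray:
    """Per-site Wald P-values for the dosage term in a logistic model.

    Fits status ~ intercept + minor-allele count (+ covariates) per site.
    Sites where the fit fails (non-convergence, separation, singular design)
    get P = 1 with a warning.
    """
    import statsmodels.api as sm

    y = pheno.status.astype(float)
    X = panel.counts.astype(float)
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != panel.n_subjects:
            if cov.shape[1] == panel.n_subjects:
                cov = cov.T
            else:
                raise ValueError("covariate row count does not match subjects")
        if np.linalg.matrix_rank(cov) < cov.shape[1]:
            raise ValueError("covariate matrix is rank deficient")
    else:
        cov = np.empty((panel.n_subjects, 0))
    pvals = np.ones(panel.n_sites)
    for k in range(panel.n_sites):
        exog = sm.add_constant(np.column_stack([X[:, k], cov]), has_constant="add")
        try:
            with np.errstate(all="ignore"):
                res = sm.Logit(y, exog).fit(disp=0, maxiter=200)
            p = float(res.pvalues[1])
            converged = bool(res.mle_retvals.get("converged", True))
            if not converged or not np.isfinite(p) or abs(res.params[1]) > 30:
                raise ValueError("unstable fit")
        except Exception:  # separation / singular design / no convergence
            logger.warning("logistic fit failed at site %s; P set to 1",
                           panel.site_ids[k])
            p = 1.0
        pvals[k] = min(max(p, np.nextafter(0, 1)), 1.0)
    return pvals


def per_site_summaries(panel, pheno, engine: str = "fisher_mid_p",
                       covariates=None) -> list:
    """One :class:`SiteSummary` per site (order preserved).

    Direction comes from the strict comparison of case vs control minor-allele
    frequencies; weights from the current control labels, so the permutation
    engine can rebuild them under each shuffle.
    """
    y = pheno.status
    if y.size != panel.n_subjects:
        raise ValueError("phenotype not aligned to panel")
    n_case = int(y.sum())
    n_ctrl = panel.n_subjects - n_case
    a = y @ panel.counts.astype(np.int64)        # minor alleles in cases
    m = panel.counts.astype(np.int64).sum(axis=0)
    b = m - a
    n1, n2 = 2 * n_case, 2 * n_ctrl
    if engine == "fisher_mid_p":
        pvals = np.array([fisher_mid_p(int(a[k]), int(b[k]), n1, n2)
                          for k in range(panel.n_sites)])
    elif engine == "logistic":
        pvals = per_site_pvalues_logistic(panel, pheno, covariates)
    else:
        raise ValueError(f"unknown engine {engine!r}")
    out = []
    for k in range(panel.n_sites):
        lhs, rhs = int(a[k]) * n2, int(b[k]) * n1  # cross-multiplied freq compare
        direction = DELETERIOUS if lhs > rhs else (PROTECTIVE if lhs < rhs else TIED)
        f = m[k] / (2.0 * panel.n_subjects)
        out.append(SiteSummary(
            site_id=panel.site_ids[k],
            position=int(panel.positions[k]),
            p_value=float(pvals[k]),
            direction=direction,
            weight=madsen_browning_weight(int(b[k]), n_ctrl, panel.n_subjects),
            maf_combined=float(min(f, 1.0 - f)),
        ))
    return out


def summaries_to_frame(summaries):
    """Per-site summary table (site, position, p, direction, weight, MAF)."""
    import pandas as pd

    return pd.DataFrame({
        "site_id": [s.site_id for s in summaries],
        "position": [s.position for s in summaries],
        "p_value": [s.p_value for s in summaries],
        "direction": [s.direction for s in summaries],
        "weight": [s.weight for s in summaries],
        "maf_combined": [s.maf_combined for s in summaries],
    })
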