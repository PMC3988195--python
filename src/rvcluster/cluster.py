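"""The spatial adaptive P-value truncation test (CLUSTER) and its ADA special case.

For each candidate truncation threshold tau_j, the per-site evidence is split
into a deleterious-inclined vector u_del and a protective-inclined vector
u_pro, with elements delta_i * w_i * g(p_i) * 1[p_i < tau_j] (g(p) = 1 by
default).  The per-threshold statistic is the sum of the two quadratic forms

    S_j = u_del' C u_del + u_pro' C u_pro

through the spatial kernel C; the two direction classes are never
cross-multiplied (a pooled variant that does mix them is available).
Significance is assessed by B label permutations: per-threshold P-values are
rank proportions against the permuted statistics, the minimum over thresholds
is taken for the observed and every permuted sample alike, and the reported
adjusted P-value is (1 + #{permuted minP <= observed minP}) / (B + 1).

With an identity kernel the statistic reduces to the adaptive combination of
P-values (ADA) test.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .kernel import KernelMatrix, identity_kernel, pairwise_distances, triweight_kernel, DEFAULT_D_MAX
from .site_stats import (
    DELETERIOUS,
    PROTECTIVE,
    _midp_lookup,
    per_site_pvalues_logistic,
    per_site_summaries,
    summaries_to_frame,
)

logger = logging.getLogger(__name__)


def default_thresholds() -> np.ndarray:
    """The default truncation-threshold grid 0.10, 0.11, ..., 0.20."""
    return np.round(np.arange(10, 21) / 100.0, 10)


def _validate_thresholds(thresholds) -> np.ndarray:
    t = np.asarray(thresholds, dtype=np.float64)
    if t.ndim != 1 or t.size < 1:
        raise ValueError("need at least one truncation threshold")
    if not ((t > 0) & (t < 1)).all():
        raise ValueError("thresholds must lie in (0, 1)")
    if t.size > 1 and not np.all(np.diff(t) > 0):
        raise ValueError("thresholds must be strictly ascending")
    return t


@dataclass(frozen=True)
class ClusterResult:
    """Result of a CLUSTER/ADA run: per-threshold statistics, min-P, adjusted P."""

    method: str                       # "CLUSTER" | "ADA"
    statistic_variant: str            # "split" | "pooled"
    thresholds: np.ndarray
    per_threshold_stats: np.ndarray
    per_threshold_pvalues: np.ndarray
    min_p_observed: float
    adjusted_p: float
    B: int
    seed: int
    n_subjects: int
    n_sites: int
    site_summaries: list = field(default=None, repr=False)

    def to_dict(self) -> dict:
        d = {
            "method": self.method,
            "statistic_variant": self.statistic_variant,
            "thresholds": [float(t) for t in self.thresholds],
            "per_threshold_stats": [float(s) for s in self.per_threshold_stats],
            "per_threshold_pvalues": [float(p) for p in self.per_threshold_pvalues],
            "min_p_observed": float(self.min_p_observed),
            "adjusted_p": float(self.adjusted_p),
            "B": int(self.B),
            "seed": int(self.seed),
            "n_subjects": int(self.n_subjects),
            "n_sites": int(self.n_sites),
        }
        if self.site_summaries is not None:
            d["site_summaries"] = summaries_to_frame(self.site_summaries).to_dict("records")
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def signal_vectors(summaries, tau: float, transform: str = "indicator"):
    """Direction-split signal vectors under one truncation threshold.

    u_del[i] = delta_del_i * w_i * g(p_i) * 1[p_i < tau] and likewise u_pro;
    tied sites contribute to neither.  ``transform`` selects g: "indicator"
    (g = 1) or "neglog10" (g = -log10 p).
    """
    K = len(summaries)
    u_del = np.zeros(K)
    u_pro = np.zeros(K)
    for i, s in enumerate(summaries):
        if s.p_value >= tau:
            continue
        g = 1.0 if transform == "indicator" else -np.log10(s.p_value)
        if s.direction == DELETERIOUS:
            u_del[i] = s.weight * g
        elif s.direction == PROTECTIVE:
            u_pro[i] = s.weight * g
    return u_del, u_pro


def threshold_statistic(u_del: np.ndarray, u_pro: np.ndarray, C: KernelMatrix) -> float:
    """S = u_del' C u_del + u_pro' C u_pro (direction classes kept separate)."""
    u_del = np.asarray(u_del, dtype=float)
    u_pro = np.asarray(u_pro, dtype=float)
    if u_del.shape != (C.n_sites,) or u_pro.shape != (C.n_sites,):
        raise ValueError("signal vector length does not match kernel dimension")
    M = C.values
    return float(u_del @ M @ u_del + u_pro @ M @ u_pro)


def _stats_for_labels(X: np.ndarray, Ycase: np.ndarray, thresholds: np.ndarray,
                      C: np.ndarray, transform: str, variant: str,
                      P: np.ndarray | None = None) -> np.ndarray:
    """Per-threshold statistics for many labelings at once.

    X: (n, K) minor-allele counts; Ycase: (L, n) 0/1 case indicators, each row
    with the same case total.  Returns (L, J) statistics.  When ``P`` is None
    the Fisher mid-P engine is used via a per-site hypergeometric lookup table
    (the total minor count per site is invariant under label shuffles, so the
    mid-P depends only on the case minor count).
    """
    Xl = X.astype(np.int64)
    Yl = Ycase.astype(np.int64)
    n = Xl.shape[0]
    n_case = int(Yl[0].sum())
    n_ctrl = n - n_case
    n1, n2 = 2 * n_case, 2 * n_ctrl
    A = Yl @ Xl                      # (L, K) minor alleles in cases
    m = Xl.sum(axis=0)               # invariant per site
    if P is None:
        tab = _midp_lookup(n1, n2, m)
        P = tab[np.arange(Xl.shape[1])[None, :], A]
    lhs = A * n2
    rhs = (m[None, :] - A) * n1
    del_mask = lhs > rhs
    pro_mask = lhs < rhs
    q = (m[None, :] - A + 1) / (n2 + 2)
    W = 1.0 / np.sqrt(n * q * (1.0 - q))
    if transform == "indicator":
        G = W
    elif transform == "neglog10":
        G = W * (-np.log10(P))
    else:
        raise ValueError(f"unknown per-site transform {transform!r}")
    J = thresholds.size
    S = np.empty((Ycase.shape[0], J))
    for j, tau in enumerate(thresholds):
        incl = P < tau
        if variant == "split":
            Ud = G * (del_mask & incl)
            Up = G * (pro_mask & incl)
            S[:, j] = ((Ud @ C) * Ud).sum(axis=1) + ((Up @ C) * Up).sum(axis=1)
        elif variant == "pooled":
            U = G * ((del_mask | pro_mask) & incl)
            S[:, j] = ((U @ C) * U).sum(axis=1)
        else:
            raise ValueError(f"unknown statistic variant {variant!r}")
    return S


def _minp_adjust(S_obs: np.ndarray, S_perm: np.ndarray):
    """Min-P adjustment from observed and permuted per-threshold statistics.

    Per-threshold P-values are rank proportions against the B permuted
    statistics (#{b: S_j^(b) >= S} / B, self-inclusive for permuted samples);
    the adjusted P is (1 + #{b: minP^(b) <= minP_obs}) / (B + 1).
    """
    B, J = S_perm.shape
    p_obs = np.empty(J)
    p_perm = np.empty((B, J))
    for j in range(J):
        s = np.sort(S_perm[:, j])
        p_obs[j] = (B - np.searchsorted(s, S_obs[j], side="left")) / B
        p_perm[:, j] = (B - np.searchsorted(s, S_perm[:, j], side="left")) / B
    minp_obs = float(p_obs.min())
    minp_perm = p_perm.min(axis=1)
    adjusted = (1 + int((minp_perm <= minp_obs).sum())) / (B + 1)
    return p_obs, minp_obs, minp_perm, adjusted


def run_cluster_test(panel, pheno, thresholds=None, C: KernelMatrix | None = None,
                     B: int = 1000, seed: int = 0, engine: str = "fisher_mid_p",
                     transform: str = "indicator", variant: str = "split",
                     d_max: float = DEFAULT_D_MAX, covariates=None,
                     include_site_summaries: bool = True) -> ClusterResult:
    """Run the CLUSTER test (or ADA when C is the identity kernel).

    Parameters
    ----------
    panel, pheno : GenotypePanel, PhenotypeVector
        MAF-filtered genotypes and aligned case/control labels.
    thresholds : sequence of float, optional
        Truncation-threshold grid; default 0.10..0.20 step 0.01.
    C : KernelMatrix, optional
        Spatial kernel; default tri-weight over the panel positions with
        ``d_max`` (20 kb).
    B : int
        Number of label permutations.
    engine : {"fisher_mid_p", "logistic"}
        Per-site P-value engine.  The Fisher engine is vectorized through a
        hypergeometric lookup; the logistic engine refits every site under
        every permutation and is much slower.
    transform : {"indicator", "neglog10"}
        Per-site magnitude g(p).
    variant : {"split", "pooled"}
        Whether direction classes are kept in separate quadratic forms
        (recommended) or pooled into one vector.
    """
    if B < 1:
        raise ValueError("need at least one permutation")
    if pheno.status.size != panel.n_subjects:
        raise ValueError("phenotype not aligned to panel")
    t = _validate_thresholds(default_thresholds() if thresholds is None else thresholds)
    if C is None:
        C = triweight_kernel(pairwise_distances(panel.positions), d_max)
    if C.n_sites != panel.n_sites:
        raise ValueError("kernel dimension does not match panel site count")

    y = pheno.status.astype(np.int8)
    rng = np.random.default_rng(seed)
    Yperm = np.tile(y, (B, 1))
    rng.permuted(Yperm, axis=1, out=Yperm)
    labels = np.vstack([y[None, :], Yperm])

    if engine == "fisher_mid_p":
        S = _stats_for_labels(panel.counts, labels, t, C.values, transform, variant)
    elif engine == "logistic":
        from .dataio import PhenotypeVector

        S = np.empty((B + 1, t.size))
        for i, lab in enumerate(labels):
            P = per_site_pvalues_logistic(panel, PhenotypeVector(lab), covariates)
            S[i] = _stats_for_labels(panel.counts, lab[None, :], t, C.values,
                                     transform, variant, P=P[None, :])[0]
    else:
        raise ValueError(f"unknown engine {engine!r}")

    if not np.any(S[0] > 0):
        logger.warning("no site passed any truncation threshold in the observed "
                       "sample (all tied/monomorphic or p >= max threshold)")
    p_obs, minp_obs, _, adjusted = _minp_adjust(S[0], S[1:])
    summaries = per_site_summaries(panel, pheno, engine="fisher_mid_p"
                                   if engine == "fisher_mid_p" else "logistic",
                                   covariates=covariates) if include_site_summaries else None
    return ClusterResult(
        method="ADA" if C.is_identity else "CLUSTER",
        statistic_variant=variant,
        thresholds=t,
        per_threshold_stats=S[0].copy(),
        per_threshold_pvalues=p_obs,
        min_p_observed=minp_obs,
        adjusted_p=float(adjusted),
        B=B,
        seed=int(seed),
        n_subjects=panel.n_subjects,
        n_sites=panel.n_sites,
        site_summaries=summaries,
    )


def run_ada_test(panel, pheno, thresholds=None, B: int = 1000, seed: int = 0,
                 engine: str = "fisher_mid_p", transform: str = "indicator",
                 variant: str = "split", covariates=None,
                 include_site_summaries: bool = True) -> ClusterResult:
    """Adaptive combination of P-values: CLUSTER with an identity kernel."""
    return run_cluster_test(panel, pheno, thresholds=thresholds,
                            C=identity_kernel(panel.n_sites), B=B, seed=seed,
                            engine=engine, transform=transform, variant=variant,
                            covariates=covariates,
                            include_site_summaries=include_site_summaries)
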