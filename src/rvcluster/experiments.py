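"""Type-I error and power experiment drivers over the simulator.

Each replicate builds a fresh haplotype pool, samples a case-control dataset,
applies the MAF filter, and runs the requested tests; rejection rates per
nominal level come with binomial standard errors.  All randomness derives
from one seed through ``numpy.random.SeedSequence``, so every rejection
decision is bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time

import numpy as np

from .baselines import run_ws_test
from .cluster import run_ada_test, run_cluster_test
from .dataio import NothingToTestError, maf_filter
from .simulate import SimulationConfig, simulate_dataset

logger = logging.getLogger(__name__)

METHODS = ("CLUSTER", "ADA", "WS")


def reduced_scale_config(par: float = 0.0, n_protective: int = 0,
                         n_deleterious: int = 10, clustered: bool = True,
                         seed: int = 0) -> SimulationConfig:
    """Desk-scale study conditions: 200+200 subjects, ~60 rare sites over 20 kb.

    The site count (70, of which ~15% are common) keeps about 60 rare sites in
    the region; the causal set is the 10-variant scenario, placed within a
    6 kb window when clustered so the window reliably holds enough rare sites
    at this density.
    """
    return SimulationConfig(n_sites=70, n_cases=200, n_controls=200,
                            n_causal=n_protective + n_deleterious,
                            n_protective=n_protective,
                            n_deleterious=n_deleterious,
                            clustered=clustered, cluster_span=6000,
                            par=par, seed=seed)


@dataclasses.dataclass
class ExperimentReport:
    """Rejection counts/rates per method and nominal level for one scenario."""

    scenario: dict
    methods: tuple
    alphas: tuple
    replicates: int
    B: int
    seed: int
    rejections: dict           # method -> {alpha: count}
    rates: dict                # method -> {alpha: rate}
    standard_errors: dict      # method -> {alpha: binomial SE}
    pvalues: dict              # method -> list of adjusted P-values
    runtime_seconds: float

    def to_dict(self, include_pvalues: bool = False) -> dict:
        d = dataclasses.asdict(self)
        if not include_pvalues:
            d.pop("pvalues")
        return d

    def to_json(self, path, include_pvalues: bool = False) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(include_pvalues), fh, indent=2)


def _scenario_dict(config: SimulationConfig) -> dict:
    return {
        "par": config.par,
        "clustered": config.clustered,
        "n_causal": config.n_causal,
        "n_protective": config.n_protective,
        "n_deleterious": config.n_deleterious,
        "n_cases": config.n_cases,
        "n_controls": config.n_controls,
        "n_sites": config.n_sites,
    }


def _run_replicates(config: SimulationConfig, methods, replicates: int, B: int,
                    alphas, seed: int, max_maf: float = 0.05,
                    d_max: float = 20_000.0) -> ExperimentReport:
    for m in methods:
        if m not in METHODS:
            raise ValueError(f"unknown method {m!r}")
    t0 = time.time()
    ss = np.random.SeedSequence(seed)
    pvals = {m: np.ones(replicates) for m in methods}
    for r, child in enumerate(ss.spawn(replicates)):
        rng = np.random.default_rng(child)
        panel, pheno, _ = simulate_dataset(config, rng)
        try:
            filtered = maf_filter(panel, pheno, max_maf=max_maf)
        except NothingToTestError:
            logger.warning("replicate %d: no testable site; all P set to 1", r)
            continue
        test_seed = int(rng.integers(2 ** 31))
        for m in methods:
            if m == "CLUSTER":
                res = run_cluster_test(filtered, pheno, B=B, seed=test_seed,
                                       d_max=d_max, include_site_summaries=False)
                pvals[m][r] = res.adjusted_p
            elif m == "ADA":
                res = run_ada_test(filtered, pheno, B=B, seed=test_seed,
                                   include_site_summaries=False)
                pvals[m][r] = res.adjusted_p
            else:
                pvals[m][r] = run_ws_test(filtered, pheno, B=B, seed=test_seed).p_value
    alphas = tuple(float(a) for a in alphas)
    rejections = {m: {a: int((pvals[m] <= a).sum()) for a in alphas} for m in methods}
    rates = {m: {a: rejections[m][a] / replicates for a in alphas} for m in methods}
    ses = {m: {a: float(np.sqrt(rates[m][a] * (1 - rates[m][a]) / replicates))
               for a in alphas} for m in methods}
    return ExperimentReport(
        scenario=_scenario_dict(config),
        methods=tuple(methods),
        alphas=alphas,
        replicates=replicates,
        B=B,
        seed=int(seed),
        rejections=rejections,
        rates=rates,
        standard_errors=ses,
        pvalues={m: [float(p) for p in pvals[m]] for m in methods},
        runtime_seconds=time.time() - t0,
    )


def run_type1(config: SimulationConfig, methods=("CLUSTER", "WS"),
              replicates: int = 2000, B: int = 500,
              alphas=(0.01, 0.03, 0.05), seed: int = 0,
              allow_small: bool = False, max_maf: float = 0.05,
              d_max: float = 20_000.0) -> ExperimentReport:
    """Empirical type-I error rates under the null (PAR = 0).

    Each replicate draws a fresh pool and sample; the rejection rate of each
    method at each nominal level is reported with a binomial SE.
    """
    if config.par != 0:
        raise ValueError("type-I error runs require par = 0")
    if replicates < 1:
        raise ValueError("need at least one replicate")
    if replicates < 100 and not allow_small:
        raise ValueError("fewer than 100 replicates is too noisy to interpret; "
                         "pass allow_small=True to override")
    return _run_replicates(config, methods, replicates, B, alphas, seed,
                           max_maf=max_maf, d_max=d_max)


def run_power(configs, methods=("CLUSTER", "WS"), replicates: int = 300,
              B: int = 500, alpha: float = 0.05, seed: int = 0,
              allow_small: bool = False, max_maf: float = 0.05,
              d_max: float = 20_000.0) -> list:
    """Empirical power per scenario (list of configs) at one nominal level.

    The same seed bank is used for every scenario, so power comparisons across
    PAR levels share Monte-Carlo noise.
    """
    configs = list(configs)
    if not any(c.par > 0 for c in configs):
        raise ValueError("power runs require at least one nonzero PAR")
    if replicates < 100 and not allow_small:
        raise ValueError("fewer than 100 replicates is too noisy to interpret; "
                         "pass allow_small=True to override")
    return [_run_replicates(c, methods, replicates, B, (alpha,), seed,
                            max_maf=max_maf, d_max=d_max) for c in configs]


def summarize_orderings(reports, alpha: float = 0.05) -> dict:
    """Qualitative flags over a set of power reports.

    Emits, where the scenarios allow, whether CLUSTER beats WS in
    all-protective scenarios and whether each method loses power going from
    clustered to non-clustered causal placement.
    """
    flags = {}
    prot = [r for r in reports
            if r.scenario["n_deleterious"] == 0 and r.scenario["par"] > 0
            and "CLUSTER" in r.methods and "WS" in r.methods]
    if prot:
        flags["cluster_beats_ws_all_protective"] = all(
            r.rates["CLUSTER"][alpha] > r.rates["WS"][alpha] for r in prot)
    by_key = {}
    for r in reports:
        key = (r.scenario["par"], r.scenario["n_protective"],
               r.scenario["n_deleterious"])
        by_key.setdefault(key, {})[r.scenario["clustered"]] = r
    contrasts = {}
    for key, d in by_key.items():
        if True in d and False in d:
            for m in d[True].methods:
                contrasts.setdefault(m, []).append(
                    d[True].rates[m][alpha] - d[False].rates[m][alpha])
    if contrasts:
        flags["clustered_minus_nonclustered_power"] = {
            m: float(np.mean(v)) for m, v in contrasts.items()}
    return flags


def plot_power(reports, path, alpha: float = 0.05) -> None:
    """Power vs PAR, one line per method (optional matplotlib dependency)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    methods = reports[0].methods
    order = np.argsort([r.scenario["par"] for r in reports])
    pars = [reports[i].scenario["par"] for i in order]
    for m in methods:
        ax.plot(pars, [reports[i].rates[m][alpha] for i in order],
                marker="o", label=m)
    ax.set_xlabel("PAR per causal variant")
    ax.set_ylabel(f"empirical power at alpha={alpha}")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
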