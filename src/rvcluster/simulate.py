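"""Case-control disease simulator: haplotype pool, causal placement, PAR-based risks.

The generator emulates a resequenced ~20 kb region: a pool of H haplotypes
whose site frequencies follow a rare-skewed 1/x spectrum truncated to
[1/H, 0.05], plus a configurable fraction of common sites (to exercise the
MAF filter).  Causal variants are placed either clustered inside a short
window or approximately equally spaced across the region, each assigned a
population attributable risk (PAR) that is converted to a genotype relative
risk given its pool frequency.  Disease status follows a multiplicative
per-allele penetrance risk = f0 * prod_j GRR_j^{g_j} (baseline f0 = 1%), and
subjects are drawn from the pool with replacement until the case and control
quotas are both filled.

Sites are independent by default (rare variants carry little linkage
disequilibrium); an optional block-copy mixing step can induce local LD.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .dataio import GenotypePanel, PhenotypeVector

DELETERIOUS = "deleterious"
PROTECTIVE = "protective"


@dataclass
class SimulationConfig:
    """Study-design and disease-model parameters.

    Defaults reproduce the simulation conditions of the reference study
    design: a 10,000-haplotype pool over a 20 kb region with ~330 variant
    sites, 20 causal variants (clustered within 6 kb when ``clustered``),
    per-variant PAR up to 1%, baseline penetrance 1%, and 500 cases + 500
    controls.
    """

    H: int = 10_000                  # haplotype pool size
    region_length: int = 20_000      # bp
    n_sites: int = 330
    n_causal: int = 20
    clustered: bool = True
    cluster_span: int = 6_000        # bp (use 3000 with n_causal=10)
    n_protective: int = 0
    n_deleterious: int = 20
    par: float = 0.0                 # per-causal-variant population attributable risk
    f0: float = 0.01                 # baseline penetrance
    n_cases: int = 500
    n_controls: int = 500
    common_fraction: float = 0.15    # fraction of sites with pool MAF in (0.05, 0.5)
    ld_mix_rounds: int = 0           # optional block-copy LD mixing
    max_draw_factor: int = 100       # draw budget multiplier over the expected need
    seed: int = 0

    def validate(self) -> None:
        if self.n_causal != self.n_protective + self.n_deleterious:
            raise ValueError("n_causal must equal n_protective + n_deleterious")
        if self.n_causal > self.n_sites:
            raise ValueError("n_causal exceeds n_sites")
        if not (0 <= self.par < 1):
            raise ValueError("par must lie in [0, 1)")
        if not (0 < self.f0 < 1):
            raise ValueError("f0 must lie in (0, 1)")
        if self.cluster_span > self.region_length:
            raise ValueError("cluster_span exceeds region_length")
        if self.n_sites > self.region_length:
            raise ValueError("more sites than base pairs in the region")
        if self.H < 2:
            raise ValueError("need at least 2 haplotypes")
        if not (0 <= self.common_fraction <= 1):
            raise ValueError("common_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class HaplotypePool:
    """H x S binary matrix of minor-allele presence plus site positions."""

    haplotypes: np.ndarray
    positions: np.ndarray

    def __post_init__(self):
        h = np.asarray(self.haplotypes, dtype=np.int8)
        p = np.asarray(self.positions, dtype=np.int64)
        object.__setattr__(self, "haplotypes", h)
        object.__setattr__(self, "positions", p)
        if h.ndim != 2 or h.shape[0] < 2:
            raise ValueError("need an H x S matrix with H >= 2")
        if p.shape != (h.shape[1],) or (p.size > 1 and not np.all(np.diff(p) > 0)):
            raise ValueError("positions must be strictly increasing, one per site")
        s = h.sum(axis=0)
        if ((s == 0) | (s == h.shape[0])).any():
            raise ValueError("every site must be polymorphic in the pool")

    @property
    def frequencies(self) -> np.ndarray:
        return self.haplotypes.mean(axis=0)


@dataclass(frozen=True)
class CausalTruth:
    """Bookkeeping for power analyses: which sites are causal and how."""

    site_indices: np.ndarray
    directions: tuple
    pool_mafs: np.ndarray
    grrs: np.ndarray

    def to_dict(self) -> dict:
        return {
            "site_indices": [int(i) for i in self.site_indices],
            "directions": list(self.directions),
            "pool_mafs": [float(f) for f in self.pool_mafs],
            "grrs": [float(g) for g in self.grrs],
        }


def build_haplotype_pool(config: SimulationConfig, rng=None) -> HaplotypePool:
    """Draw positions, site frequencies and haplotype alleles for the pool.

    Rare-site frequencies follow f(x) ~ 1/x truncated to [1/H, 0.05]
    (inverse-CDF sampling); common sites are uniform on (0.05, 0.5).  Alleles
    are independent across sites; sites drawn monomorphic are redrawn.
    """
    config.validate()
    rng = np.random.default_rng(config.seed) if rng is None else rng
    positions = np.sort(rng.choice(config.region_length, size=config.n_sites,
                                   replace=False)) + 1
    common = rng.random(config.n_sites) < config.common_fraction
    fmin, fmax = 1.0 / config.H, 0.05
    u = rng.random(config.n_sites)
    freqs = fmin * (fmax / fmin) ** u            # 1/x spectrum on [fmin, fmax]
    freqs[common] = rng.uniform(0.05, 0.5, size=int(common.sum()))
    haps = (rng.random((config.H, config.n_sites)) < freqs[None, :]).astype(np.int8)
    for _ in range(1000):
        s = haps.sum(axis=0)
        bad = np.flatnonzero((s == 0) | (s == config.H))
        if bad.size == 0:
            break
        haps[:, bad] = (rng.random((config.H, bad.size)) < freqs[None, bad]).astype(np.int8)
    for _ in range(config.ld_mix_rounds):
        # copy a random contiguous site block between haplotype pairs to
        # induce local allele sharing
        n_pairs = config.H // 4
        src = rng.integers(config.H, size=n_pairs)
        dst = rng.integers(config.H, size=n_pairs)
        start = rng.integers(config.n_sites, size=n_pairs)
        width = rng.integers(1, max(2, config.n_sites // 10), size=n_pairs)
        for s_i, d_i, a, w in zip(src, dst, start, width):
            haps[d_i, a:a + w] = haps[s_i, a:a + w]
        s = haps.sum(axis=0)
        bad = np.flatnonzero((s == 0) | (s == config.H))
        if bad.size:
            haps[:, bad] = (rng.random((config.H, bad.size)) < freqs[None, bad]).astype(np.int8)
    return HaplotypePool(haps, positions)


def select_causal_sites(pool: HaplotypePool, config: SimulationConfig, rng=None):
    """Choose causal site indices and direction labels.

    Clustered mode picks a random window of ``cluster_span`` bp containing at
    least ``n_causal`` rare sites and samples the causal sites inside it;
    non-clustered mode assigns each of ``n_causal`` ideal equally spaced grid
    points its nearest unused rare site.  Direction labels distribute
    ``n_protective`` and ``n_deleterious`` uniformly at random.
    """
    config.validate()
    rng = np.random.default_rng(config.seed) if rng is None else rng
    freqs = pool.frequencies
    rare = np.flatnonzero(freqs <= 0.05)
    if rare.size < config.n_causal:
        raise ValueError("not enough rare sites in the pool")
    pos = pool.positions
    if config.clustered:
        chosen = None
        hi = max(1, config.region_length - config.cluster_span)
        for _ in range(100):
            start = int(rng.integers(1, hi + 1))
            inside = rare[(pos[rare] >= start) & (pos[rare] <= start + config.cluster_span)]
            if inside.size >= config.n_causal:
                chosen = np.sort(rng.choice(inside, size=config.n_causal, replace=False))
                break
        if chosen is None:
            raise ValueError("no cluster window with enough rare sites after 100 tries")
    else:
        grid = (np.arange(config.n_causal) + 0.5) * config.region_length / config.n_causal
        used = np.zeros(rare.size, dtype=bool)
        picks = []
        for g in grid:
            d = np.abs(pos[rare].astype(float) - g)
            d[used] = np.inf
            k = int(np.argmin(d))
            used[k] = True
            picks.append(rare[k])
        chosen = np.sort(np.array(picks))
    labels = np.array([PROTECTIVE] * config.n_protective
                      + [DELETERIOUS] * config.n_deleterious, dtype=object)
    labels = rng.permutation(labels)
    return chosen, tuple(labels)


def par_to_grr(par: float, maf: float, protective: bool) -> float:
    """Genotype relative risk implied by a population attributable risk.

    Deleterious: GRR = par / (maf * (1 - par)) + 1 >= 1; protective variants
    use the reciprocal, so the minor allele reduces risk.
    """
    if not (0 <= par < 1):
        raise ValueError("par must lie in [0, 1)")
    if not (0 < maf <= 0.5):
        raise ValueError("maf must lie in (0, 0.5]")
    grr = par / (maf * (1.0 - par)) + 1.0
    return 1.0 / grr if protective else grr


def penetrance(genotype_counts, grrs, f0: float) -> float:
    """Multiplicative per-allele penetrance: min(f0 * prod_j GRR_j^{g_j}, 1)."""
    g = np.asarray(genotype_counts, dtype=float)
    r = np.asarray(grrs, dtype=float)
    if g.shape != r.shape:
        raise ValueError("genotype and GRR vectors must align")
    return float(min(f0 * np.prod(r ** g), 1.0))


def sample_case_control(pool: HaplotypePool, causal_indices, directions,
                        config: SimulationConfig, rng=None):
    """Draw subjects from the pool until the case and control quotas fill.

    Each subject is a pair of haplotypes drawn with replacement; disease is a
    Bernoulli draw at the multiplicative penetrance evaluated on the subject's
    causal-site genotype.  GRRs use POOL frequencies (PAR is a population
    quantity).  Surplus subjects of an already-filled class are discarded.

    Returns (GenotypePanel, PhenotypeVector, CausalTruth); the panel contains
    all sites (apply :func:`rvcluster.maf_filter` downstream).
    """
    config.validate()
    rng = np.random.default_rng(config.seed) if rng is None else rng
    causal_indices = np.asarray(causal_indices, dtype=np.int64)
    pool_mafs = pool.frequencies[causal_indices]
    grrs = np.array([par_to_grr(config.par, f, d == PROTECTIVE)
                     for f, d in zip(pool_mafs, directions)])
    log_grr = np.log(grrs)
    H = pool.haplotypes.shape[0]
    Hc = pool.haplotypes[:, causal_indices].astype(np.float64)

    need = config.n_cases + config.n_controls
    # expected draws scale as quota / min(f0, 1-f0); budget is a safety multiple
    budget = config.max_draw_factor * int(
        np.ceil(config.n_cases / min(config.f0, 0.5) + config.n_controls / 0.5)) + need
    case_pairs, ctrl_pairs = [], []
    drawn = 0
    batch = max(4 * need, int(2 * config.n_cases / config.f0) if config.f0 < 0.5 else need)
    while (len(case_pairs) < config.n_cases or len(ctrl_pairs) < config.n_controls):
        if drawn >= budget:
            raise RuntimeError(
                f"failed to recruit {config.n_cases}+{config.n_controls} subjects "
                f"within {budget} draws (f0={config.f0})")
        b = min(batch, budget - drawn)
        i1 = rng.integers(H, size=b)
        i2 = rng.integers(H, size=b)
        risk = np.minimum(config.f0 * np.exp((Hc[i1] + Hc[i2]) @ log_grr), 1.0)
        is_case = rng.random(b) < risk
        drawn += b
        for idx in range(b):
            if is_case[idx]:
                if len(case_pairs) < config.n_cases:
                    case_pairs.append((i1[idx], i2[idx]))
            elif len(ctrl_pairs) < config.n_controls:
                ctrl_pairs.append((i1[idx], i2[idx]))
        batch = need  # smaller follow-up batches once the big first pass ran

    pairs = np.array(case_pairs + ctrl_pairs)
    counts = (pool.haplotypes[pairs[:, 0]] + pool.haplotypes[pairs[:, 1]]).astype(np.int8)
    # re-code to the sample minor allele where a common site drifted past 0.5,
    # so the emitted panel honours the minor-allele-count contract
    flip = counts.sum(axis=0) > counts.shape[0]
    if flip.any():
        counts[:, flip] = 2 - counts[:, flip]
    subject_ids = [f"case{i}" for i in range(config.n_cases)] + \
                  [f"ctrl{i}" for i in range(config.n_controls)]
    site_ids = [f"s{p}" for p in pool.positions]
    panel = GenotypePanel(subject_ids, site_ids, pool.positions, counts)
    status = np.r_[np.ones(config.n_cases, dtype=np.int8),
                   np.zeros(config.n_controls, dtype=np.int8)]
    truth = CausalTruth(causal_indices, tuple(directions), pool_mafs, grrs)
    return panel, PhenotypeVector(status), truth


def simulate_dataset(config: SimulationConfig, rng=None):
    """Pool -> causal placement -> case-control sample, in one call."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    pool = build_haplotype_pool(config, rng)
    causal, directions = select_causal_sites(pool, config, rng)
    return sample_case_control(pool, causal, directions, config, rng)


def write_truth(truth: CausalTruth, config: SimulationConfig, path) -> None:
    """Dump the causal-variant truth record plus full config (seed included)."""
    with open(path, "w") as fh:
        json.dump({"config": asdict(config), "truth": truth.to_dict()}, fh, indent=2)


def write_vcf(panel: GenotypePanel, path, chrom: str = "1") -> None:
    """Write a panel as a minimal VCF (minor allele coded as ALT)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(map(str, panel.subject_ids)) + "\n")
        gt = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j in range(panel.n_sites):
            fields = [chrom, str(int(panel.positions[j])), str(panel.site_ids[j]),
                      "A", "T", ".", "PASS", ".", "GT"]
            fields += [gt[int(c)] for c in panel.counts[:, j]]
            fh.write("\t".join(fields) + "\n")
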