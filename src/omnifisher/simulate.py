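"""Synthetic multi-omics generators and the Type I error / power harnesses.

Three feature pools emulate the structure the method cares about:

* **haplotypes** — 10,000 binary haplotypes over a 200-kb region.  Allele
  frequencies follow a neutral-spectrum (density ~ 1/f) draw truncated to
  [0.005, 0.5]; linkage disequilibrium comes from a latent Gaussian AR
  process whose correlation decays exponentially with physical distance.
* **methylation** — M-values ``log2(beta/(1-beta))`` with beta drawn from a
  two-component (hypo/hyper-methylated) beta mixture, correlated within
  gene-sized blocks through a Gaussian copula.
* **expression** — one log-scale value per gene per sample, grand mean
  anchored at 7.45.

A simulated gene carries 50 SNPs, 5 CpGs and 1 expression value.  Disease
models follow the four phenotype-generating equations (logistic intercept
log(0.05/0.95) = -2.94 for 5% prevalence, covariates X1 ~ N(20,1) and
X2 ~ Bernoulli(0.5), genotype effects 0.3 or 0.2, methylation effect 0.9,
expression effect 1 on the mean-centred value).  Binary datasets keep the
first 500 cases and 500 controls; continuous datasets use n = 1000 with
standard-normal noise.  Null datasets are obtained by permuting the traits
of causal datasets (10 permutations each), which preserves the marginal
omics distributions exactly.  The genotype-expression coupling device
``E* = E + G_causal1`` makes two layers dependent without touching the
trait, which is precisely what inflates the uncorrected Fisher combination.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist
from scipy.stats import norm

from .fisher_combine import omnibus_fisher_combine, usual_fisher_combine
from .km_score import OmicsBlock, km_test
from .null_model import Phenotype, fit_null
from .perturbation import (PerturbConfig, estimate_cov, optimal_test,
                           perturb_layer_pvalues)

__all__ = ["PoolConfig", "PoolSet", "ScenarioSpec", "GeneDataset",
           "build_pools", "simulate_gene_dataset", "permuted_null_datasets",
           "analyze_dataset", "type1_harness", "power_harness", "HarnessResult"]


# ---------------------------------------------------------------------------
# pools


@dataclass(frozen=True)
class PoolConfig:
    n_haplotypes: int = 10000
    n_snp_sites: int = 200
    region_kb: float = 200.0
    ld_decay_kb: float = 30.0          # latent-correlation decay length
    maf_min: float = 1e-4              # singleton frequency in a 10k pool
    maf_max: float = 0.5
    methyl_samples: int = 689
    methyl_sites: int = 500
    methyl_block: int = 5              # CpGs per simulated gene
    methyl_block_rho: float = 0.6
    expr_samples: int = 142
    expr_genes: int = 327
    expr_mean: float = 7.45
    expr_between_sd: float = 1.2       # gene-to-gene spread of means
    expr_within_sd: float = 0.15       # sample-to-sample spread within a gene
    methyl_concentration: float = 1500.0  # beta-mixture concentration per CpG
    methyl_means: tuple[float, float] = (0.12, 0.88)   # hypo / hyper


@dataclass
class PoolSet:
    haplotypes: np.ndarray             # H x S, uint8 in {0, 1}
    snp_pos_kb: np.ndarray             # S physical positions
    methyl_pool: np.ndarray            # samples x CpGs, M-values
    expr_pool: np.ndarray              # samples x genes, log-scale
    config: PoolConfig

    @property
    def allele_freq(self) -> np.ndarray:
        return self.haplotypes.mean(axis=0)


def _neutral_maf(rng, size, lo, hi):
    """Frequencies with density proportional to 1/f on [lo, hi]."""
    u = rng.uniform(size=size)
    return lo * (hi / lo) ** u


def build_pools(config: PoolConfig | None = None, seed: int = 0) -> PoolSet:
    """Generate the three feature pools from a single seed."""
    cfg = config or PoolConfig()
    if cfg.n_snp_sites < 2 or cfg.n_haplotypes < 2 or cfg.methyl_block < 1:
        raise ValueError("invalid pool configuration")
    if not (0 < cfg.maf_min < cfg.maf_max <= 0.5):
        raise ValueError("invalid allele-frequency bounds")
    rng = np.random.default_rng(seed)

    # haplotypes: latent AR across sites, thresholded at Phi^-1(f_s)
    pos = np.sort(rng.uniform(0.0, cfg.region_kb, size=cfg.n_snp_sites))
    freq = _neutral_maf(rng, cfg.n_snp_sites, cfg.maf_min, cfg.maf_max)
    rho = np.exp(-np.diff(pos) / cfg.ld_decay_kb)
    z = np.empty((cfg.n_haplotypes, cfg.n_snp_sites))
    z[:, 0] = rng.standard_normal(cfg.n_haplotypes)
    innov = rng.standard_normal((cfg.n_haplotypes, cfg.n_snp_sites - 1))
    for s in range(1, cfg.n_snp_sites):
        r = rho[s - 1]
        z[:, s] = r * z[:, s - 1] + np.sqrt(1.0 - r * r) * innov[:, s - 1]
    haplos = (z < norm.ppf(freq)[None, :]).astype(np.uint8)

    # methylation: two-component beta mixture through a block-AR copula;
    # the concentration sets per-CpG M-value spread (~0.3 at the default),
    # matching the stable hypo/hyper bimodality of array methylation data
    conc = cfg.methyl_concentration
    mu_hypo, mu_hyper = cfg.methyl_means
    a_hypo, b_hypo = mu_hypo * conc, (1 - mu_hypo) * conc
    a_hyper, b_hyper = mu_hyper * conc, (1 - mu_hyper) * conc
    hyper = rng.uniform(size=cfg.methyl_sites) < 0.5
    zm = np.empty((cfg.methyl_samples, cfg.methyl_sites))
    zm[:, 0] = rng.standard_normal(cfg.methyl_samples)
    innov_m = rng.standard_normal((cfg.methyl_samples, cfg.methyl_sites - 1))
    for s in range(1, cfg.methyl_sites):
        r = 0.0 if s % cfg.methyl_block == 0 else cfg.methyl_block_rho
        zm[:, s] = r * zm[:, s - 1] + np.sqrt(1.0 - r * r) * innov_m[:, s - 1]
    u = norm.cdf(zm)
    a = np.where(hyper, a_hyper, a_hypo)[None, :]
    b = np.where(hyper, b_hyper, b_hypo)[None, :]
    bvals = beta_dist.ppf(np.clip(u, 1e-12, 1 - 1e-12), a, b)
    bvals = np.clip(bvals, 1e-6, 1 - 1e-6)
    mpool = np.log2(bvals / (1.0 - bvals))

    # expression: gene-level means around the configured grand mean
    mu_g = cfg.expr_mean + cfg.expr_between_sd * rng.standard_normal(cfg.expr_genes)
    epool = mu_g[None, :] + cfg.expr_within_sd * rng.standard_normal(
        (cfg.expr_samples, cfg.expr_genes))
    epool += cfg.expr_mean - epool.mean()

    return PoolSet(haplos, pos, mpool, epool, cfg)


# ---------------------------------------------------------------------------
# scenarios


_SCENARIO_NAMES = {
    # (trait, coupling, causal)
    "1.1": ("continuous", "independent", ()),
    "1.2": ("continuous", "independent", ("G",)),
    "1.3": ("continuous", "independent", ("G", "M")),
    "1.4": ("continuous", "independent", ("G", "M", "E")),
    "1.5": ("binary", "independent", ()),
    "1.6": ("binary", "independent", ("G",)),
    "1.7": ("binary", "independent", ("G", "M")),
    "1.8": ("binary", "independent", ("G", "M", "E")),
    "2.1": ("continuous", "correlated", ()),
    "2.2": ("continuous", "correlated", ("G",)),
    "2.3": ("continuous", "correlated", ("G", "M")),
    "2.4": ("binary", "correlated", ()),
    "2.5": ("binary", "correlated", ("G",)),
    "2.6": ("binary", "correlated", ("G", "M")),
}


@dataclass(frozen=True)
class ScenarioSpec:
    """One simulation scenario: trait family, layer coupling, causal set."""

    trait: str = "binary"                       # {"binary", "continuous"}
    coupling: str = "independent"               # {"independent", "correlated"}
    causal: tuple[str, ...] = ()
    n_cases: int = 500
    n_controls: int = 500
    n: int = 1000                               # continuous-trait sample size
    intercept: float = -2.94                    # log(0.05 / 0.95)
    beta_x1: float = 0.001
    beta_x2: float = 0.001
    beta_m: float = 0.9
    beta_e: float = 1.0
    expr_center: float = 7.45
    n_snps: int = 50
    n_cpgs: int = 5
    n_causal_snps: int = 5
    n_causal_cpgs: int = 2
    max_subjects: int = 2_000_000

    @property
    def beta_g(self) -> float:
        # 0.3 when G alone drives the trait, 0.2 alongside M (and E)
        return 0.3 if self.causal == ("G",) else 0.2

    def __post_init__(self):
        if self.trait not in ("binary", "continuous"):
            raise ValueError("trait must be binary or continuous")
        if self.coupling not in ("independent", "correlated"):
            raise ValueError("coupling must be independent or correlated")
        if not set(self.causal) <= {"G", "M", "E"}:
            raise ValueError("causal set must be a subset of {G, M, E}")

    @classmethod
    def from_name(cls, name: str) -> "ScenarioSpec":
        """Parse 'causal-G-b-ind' / 'null-c-cor' style names or '1.1'-'2.6'."""
        key = name.strip()
        if key in _SCENARIO_NAMES:
            trait, coupling, causal = _SCENARIO_NAMES[key]
            return cls(trait=trait, coupling=coupling, causal=causal)
        parts = key.split("-")
        if len(parts) < 3:
            raise ValueError(f"unrecognised scenario {name!r}")
        kind, *mid, trait_code, coup_code = parts
        causal: tuple[str, ...] = ()
        if kind == "causal":
            causal = tuple(mid[0]) if mid else ()
        elif kind != "null":
            raise ValueError(f"unrecognised scenario {name!r}")
        trait = {"b": "binary", "c": "continuous"}[trait_code]
        coupling = {"ind": "independent", "cor": "correlated"}[coup_code]
        return cls(trait=trait, coupling=coupling, causal=causal)


@dataclass
class GeneDataset:
    """One simulated gene: omics blocks, trait and covariates for n subjects."""

    G: np.ndarray
    M: np.ndarray
    E: np.ndarray                       # n x 1 (already coupled if requested)
    y: np.ndarray
    X: np.ndarray                       # n x 2: X1, X2 (intercept added at fit)
    spec: ScenarioSpec
    causal_snps: np.ndarray
    causal_cpgs: np.ndarray

    @property
    def n(self) -> int:
        return self.y.size

    def subject_ids(self) -> np.ndarray:
        return np.arange(self.n)

    def blocks(self) -> dict[str, OmicsBlock]:
        ids = self.subject_ids()
        return {
            "G": OmicsBlock(self.G, "G", ids),
            "M": OmicsBlock(self.M, "M", ids),
            "E": OmicsBlock(self.E, "E", ids),
        }

    def phenotype(self) -> Phenotype:
        family = "binomial" if self.spec.trait == "binary" else "gaussian"
        return Phenotype(self.y.astype(float), family, self.subject_ids())


def _draw_features(spec: ScenarioSpec, pools: PoolSet, n: int,
                   rng: np.random.Generator, gene_ctx: dict):
    """Sample n subjects' G/M/E rows for the gene fixed in ``gene_ctx``."""
    H = pools.haplotypes.shape[0]
    win = gene_ctx["snp_window"]
    h1 = rng.integers(0, H, size=n)
    h2 = rng.integers(0, H, size=n)
    G = (pools.haplotypes[h1][:, win] + pools.haplotypes[h2][:, win]).astype(float)
    mrows = rng.integers(0, pools.methyl_pool.shape[0], size=n)
    M = pools.methyl_pool[mrows][:, gene_ctx["cpg_cols"]]
    erows = rng.integers(0, pools.expr_pool.shape[0], size=n)
    E = pools.expr_pool[erows, gene_ctx["expr_col"]].copy()
    return G, M, E


def _linear_predictor(spec: ScenarioSpec, G, M, E, X, m_center):
    """Covariate + causal-feature contribution to the trait's linear scale.

    The expression effect acts on the deviation from the pool grand mean
    (anchor 7.45); the methylation effect likewise acts on deviations from
    the pool means of the causal CpGs, keeping the logistic intercept's
    baseline prevalence at its designed 5% regardless of whether the drawn
    CpGs are hypo- or hyper-methylated.
    """
    lp = spec.beta_x1 * X[:, 0] + spec.beta_x2 * X[:, 1]
    causal = set(spec.causal)
    if "G" in causal:
        lp = lp + spec.beta_g * G[:, : spec.n_causal_snps].sum(axis=1)
    if "M" in causal:
        k = spec.n_causal_cpgs
        lp = lp + spec.beta_m * (M[:, :k] - m_center[None, :k]).sum(axis=1)
    if "E" in causal:
        lp = lp + spec.beta_e * (E - spec.expr_center)
    return lp


def simulate_gene_dataset(spec: ScenarioSpec, pools: PoolSet,
                          rng: np.random.Generator) -> GeneDataset:
    """Simulate one gene-level dataset under the scenario.

    Causal SNPs/CpGs are drawn fresh for each dataset; for convenience the
    returned matrices are column-permuted so that causal features occupy
    the leading columns, with the chosen indices recorded.  Under the
    correlated setting the first causal SNP's genotype is added to the
    expression value (``E* = E + G1``) before any trait is generated.
    """
    cfg = pools.config
    S = pools.haplotypes.shape[1]
    start = rng.integers(0, S - spec.n_snps + 1)
    snp_window = np.arange(start, start + spec.n_snps)
    # causal SNPs are drawn among segregating sites (pool MAF >= 0.1%, i.e.
    # expected carriers at cohort scale): a monomorphic "causal" variant
    # influences nothing.  The coupling SNP G1 (the E* = E + G1 device
    # models a cis-eQTL, which requires a segregating variant) is the most
    # common causal SNP — a labelling choice, as causal SNPs are
    # exchangeable in the phenotype models.
    freq = pools.allele_freq[snp_window]
    eligible = np.nonzero(freq >= 0.001)[0]
    if eligible.size < spec.n_causal_snps:
        eligible = np.argsort(freq)[::-1][: spec.n_causal_snps]
    causal_snps = rng.choice(eligible, size=spec.n_causal_snps, replace=False)
    causal_snps = causal_snps[np.argsort(freq[causal_snps])[::-1]]
    order_g = np.concatenate([causal_snps,
                              np.setdiff1d(np.arange(spec.n_snps), causal_snps)])
    n_blocks = pools.methyl_pool.shape[1] // cfg.methyl_block
    blk = rng.integers(0, n_blocks)
    cpg_cols = np.arange(blk * cfg.methyl_block, blk * cfg.methyl_block + spec.n_cpgs)
    causal_cpgs = rng.choice(spec.n_cpgs, size=spec.n_causal_cpgs, replace=False)
    order_m = np.concatenate([causal_cpgs,
                              np.setdiff1d(np.arange(spec.n_cpgs), causal_cpgs)])
    expr_col = rng.integers(0, pools.expr_pool.shape[1])
    ctx = {"snp_window": snp_window, "cpg_cols": cpg_cols, "expr_col": expr_col}
    m_center = pools.methyl_pool[:, cpg_cols].mean(axis=0)[order_m]

    def sample(n):
        G, M, E = _draw_features(spec, pools, n, rng, ctx)
        G = G[:, order_g]
        M = M[:, order_m]
        if spec.coupling == "correlated":
            E = E + G[:, 0]
        X = np.column_stack([20.0 + rng.standard_normal(n),
                             (rng.uniform(size=n) < 0.5).astype(float)])
        return G, M, E, X

    if spec.trait == "continuous":
        G, M, E, X = sample(spec.n)
        y = _linear_predictor(spec, G, M, E, X, m_center) + rng.standard_normal(spec.n)
    else:
        need_cases, need_controls = spec.n_cases, spec.n_controls
        parts: list[tuple] = []
        drawn = 0
        chunk = 4 * (spec.n_cases + spec.n_controls)
        while need_cases > 0 or need_controls > 0:
            if drawn >= spec.max_subjects:
                raise ValueError(
                    "case/control accrual infeasible: prevalence too extreme "
                    f"(drew {drawn} subjects, still need {need_cases} cases, "
                    f"{need_controls} controls)")
            G, M, E, X = sample(chunk)
            drawn += chunk
            lp = spec.intercept + _linear_predictor(spec, G, M, E, X, m_center)
            yi = (rng.uniform(size=chunk) < 1.0 / (1.0 + np.exp(-lp))).astype(float)
            case_idx = np.nonzero(yi == 1)[0][:need_cases]
            ctrl_idx = np.nonzero(yi == 0)[0][:need_controls]
            keep = np.concatenate([case_idx, ctrl_idx])
            parts.append((G[keep], M[keep], E[keep], X[keep], yi[keep]))
            need_cases -= case_idx.size
            need_controls -= ctrl_idx.size
            chunk = min(max(chunk, 2048), 1 << 18)
        G = np.concatenate([p[0] for p in parts])
        M = np.concatenate([p[1] for p in parts])
        E = np.concatenate([p[2] for p in parts])
        X = np.concatenate([p[3] for p in parts])
        y = np.concatenate([p[4] for p in parts])

    return GeneDataset(G=G, M=M, E=E[:, None] if E.ndim == 1 else E, y=y, X=X,
                       spec=spec, causal_snps=causal_snps, causal_cpgs=causal_cpgs)


def permuted_null_datasets(dataset: GeneDataset, n_perm: int,
                           rng: np.random.Generator):
    """Yield null datasets by permuting the trait of a causal dataset.

    Permutation breaks every trait-omics association while leaving the
    marginal distributions of G, M and E untouched.
    """
    for _ in range(n_perm):
        perm = rng.permutation(dataset.n)
        yield replace_dataset_y(dataset, dataset.y[perm])


def replace_dataset_y(dataset: GeneDataset, y: np.ndarray) -> GeneDataset:
    return GeneDataset(G=dataset.G, M=dataset.M, E=dataset.E, y=y, X=dataset.X,
                       spec=dataset.spec, causal_snps=dataset.causal_snps,
                       causal_cpgs=dataset.causal_cpgs)


# ---------------------------------------------------------------------------
# harnesses


METHODS = ("optimal", "omnibus", "fisher")


def analyze_dataset(dataset: GeneDataset, methods=METHODS,
                    config: PerturbConfig | None = None,
                    rng: np.random.Generator | None = None) -> dict[str, float]:
    """Gene-level p-value of each requested method on one dataset.

    All three layers share subjects and covariates here, so a single null
    model backs the three kernel-machine tests.
    """
    config = config or PerturbConfig()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    fit = fit_null(dataset.phenotype(), dataset.X)
    km = {l: km_test(fit, b) for l, b in dataset.blocks().items()}
    p3 = [km[l].p_value for l in ("G", "M", "E")]
    out: dict[str, float] = {}
    if "fisher" in methods:
        out["fisher"] = usual_fisher_combine(p3)
    if "omnibus" in methods:
        draws = perturb_layer_pvalues(km, config.B_cov, rng)
        cov_hat = estimate_cov(draws, config.include_observed_in_cov)
        out["omnibus"] = omnibus_fisher_combine(p3, cov_hat.to_numpy())
    if "optimal" in methods:
        out["optimal"], _ = optimal_test(km, config, rng)
    return out


@dataclass
class HarnessResult:
    rates: pd.DataFrame                 # alpha x method rejection rates
    se: pd.DataFrame                    # binomial standard errors
    pvalues: pd.DataFrame               # dataset x method raw p-values


def _run_harness(datasets, methods, alphas, config, rng) -> HarnessResult:
    rows = []
    for ds in datasets:
        child = np.random.default_rng(rng.integers(0, 2**63))
        rows.append(analyze_dataset(ds, methods, config, child))
    pvals = pd.DataFrame(rows, columns=list(methods))
    n = len(pvals)
    rates = pd.DataFrame({m: [(pvals[m] < a).mean() for a in alphas]
                          for m in methods}, index=list(alphas))
    se = pd.DataFrame({m: [np.sqrt(a * (1 - a) / n) for a in alphas]
                       for m in methods}, index=list(alphas))
    rates.index.name = se.index.name = "alpha"
    return HarnessResult(rates=rates, se=se, pvalues=pvals)


def _warn_sizes(n_datasets: int, alphas) -> None:
    if n_datasets < 100:
        warnings.warn(f"only {n_datasets} datasets: rejection rates will be noisy",
                      UserWarning, stacklevel=3)
    for a in alphas:
        if a < 10.0 / n_datasets:
            warnings.warn(
                f"alpha={a} needs >= {int(np.ceil(10 / a))} datasets for "
                "resolution; interpret with care", UserWarning, stacklevel=3)


def type1_harness(spec: ScenarioSpec, n_datasets: int, methods=METHODS,
                  alphas=(0.05, 0.01, 0.001), seed: int = 0,
                  config: PerturbConfig | None = None, pools: PoolSet | None = None,
                  n_perm: int = 10) -> HarnessResult:
    """Empirical Type I error rates under permutation-derived null datasets.

    ``spec`` names the *causal* scenario whose datasets are trait-permuted
    (``n_perm`` times each) to produce the null collection; a null spec
    (empty causal set) is promoted to its causal-G counterpart, matching
    how the null scenarios are defined.
    """
    _warn_sizes(n_datasets, alphas)
    if not spec.causal:
        spec = replace(spec, causal=("G",))
    rng = np.random.default_rng(seed)
    pools = pools or build_pools(seed=int(rng.integers(0, 2**31)))
    n_causal = int(np.ceil(n_datasets / n_perm))

    def gen():
        produced = 0
        for _ in range(n_causal):
            ds = simulate_gene_dataset(spec, pools, rng)
            for nd in permuted_null_datasets(ds, n_perm, rng):
                if produced >= n_datasets:
                    return
                produced += 1
                yield nd

    return _run_harness(gen(), methods, alphas, config, rng)


def power_harness(spec: ScenarioSpec, n_datasets: int, methods=METHODS,
                  alphas=(0.05, 0.01), seed: int = 0,
                  config: PerturbConfig | None = None,
                  pools: PoolSet | None = None) -> HarnessResult:
    """Empirical power on causal datasets of the given scenario."""
    if not spec.causal:
        raise ValueError("power_harness needs a causal scenario")
    _warn_sizes(n_datasets, alphas)
    rng = np.random.default_rng(seed)
    pools = pools or build_pools(seed=int(rng.integers(0, 2**31)))
    datasets = (simulate_gene_dataset(spec, pools, rng) for _ in range(n_datasets))
    return _run_harness(datasets, methods, alphas, config, rng)
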