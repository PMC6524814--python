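"""Perturbation machinery: p-value covariance estimation and the optimal
(min-p over disease models) gene-level test.

Observed score statistics are quadratic forms in (approximately)
standard-normal residual vectors.  Replacing the standardised residual by a
fresh standard-normal draw — one entry per subject, *shared across layers* —
regenerates the whole set of layer statistics under the null while
preserving their cross-layer dependence.  Concretely, per layer ``l`` with
eigen-pairs (Lambda_l, V_l) of ``P0^(1/2) D_l W_l D_l' P0^(1/2)``:

    r^(b) ~ N(0, I_n_union)            (one draw per subject in the union)
    r_l^(b) = V_l' r^(b)[subjects of l]
    Q_l^(b) = r_l^(b)' Lambda_l r_l^(b)  ->  p_l^(b)

Numerically the rotation is folded into one m x n operator ``A_l`` with
``A_l A_l' = W^(1/2) D' P0 D W^(1/2)`` so that ``Q_l^(b) = ||A_l r||^2``;
this is algebraically identical to the eigenvector route.

The draws serve two purposes: the off-diagonal entries of
``cov(-2 ln p_G, -2 ln p_M, -2 ln p_E)`` for the corrected Fisher
combination, and the reference distribution of the min-p statistic over the
seven disease models {G, M, E, GM, GE, ME, GME} for the optimal test, whose
final p-value is the resampling estimate

    p = (1 + sum_b I(p^(b) <= p^(0))) / (1 + B)

computed on a stepwise-escalated B so that small p-values get the
resolution they need.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fisher_combine import (OmnibusWarning, omnibus_fisher_combine,
                             omnibus_fisher_combine_batch)
from .km_score import LAYERS, KMTestResult, OmicsBlock, km_test
from .null_model import NullModelFit, Phenotype, fit_null
from .quadform import mixture_sf_batch

__all__ = ["PerturbConfig", "PerturbationDraws", "GeneResult",
           "perturb_layer_pvalues", "estimate_cov", "combine_all_models",
           "optimal_test", "run_gene"]


@dataclass(frozen=True)
class PerturbConfig:
    """Tunables of the resampling machinery.

    ``B_cov`` draws feed the covariance estimate behind the regular
    corrected combination (200 by default).  The optimal test escalates
    through ``B_stage_schedule`` while its p-value estimate stays below
    ``escalation_threshold / B`` — resolution is proportional to 1/B, so
    only small p-values pay for large B.
    """

    B_cov: int = 200
    B_stage_schedule: tuple[int, ...] = (1000, 10000, 100000)
    escalation_threshold: float = 10.0
    include_observed_in_cov: bool = True
    seed: int = 0


@dataclass
class PerturbationDraws:
    """Perturbed per-layer p-values: column ``l`` holds p_l^(b), b = 1..B."""

    layers: tuple[str, ...]
    p_perturbed: np.ndarray          # B x n_layers
    p_observed: np.ndarray           # n_layers, evaluated on the same scale
    B: int

    def stacked(self) -> np.ndarray:
        """(B+1) x n_layers with the observed draw as row 0."""
        return np.vstack([self.p_observed[None, :], self.p_perturbed])


def _union_subjects(km_results: dict[str, KMTestResult]) -> pd.Index:
    ids: pd.Index | None = None
    for res in km_results.values():
        idx = pd.Index(res.subject_ids)
        ids = idx if ids is None else ids.union(idx)
    return ids.sort_values()


def _layer_operators(km_results: dict[str, KMTestResult], union: pd.Index):
    """Per-layer (row-positions, operator) pairs on the union subject axis.

    The cheap P0 factor is valid when all layers are backed by one and the
    same null fit (the common case: identical subjects and covariates);
    otherwise each layer uses the symmetric root of its own P0 so that
    subject-wise sharing of the normal draw carries the exact cross-layer
    covariance.
    """
    fits = {id(res.null_fit) for res in km_results.values()}
    exact_root = len(fits) > 1
    out = {}
    for layer, res in km_results.items():
        pos = union.get_indexer(pd.Index(res.subject_ids))
        if np.any(pos < 0):
            raise ValueError(f"layer {layer} has subjects outside the union index")
        out[layer] = (pos, res.perturbation_operator(exact_root=exact_root))
    return out


def perturb_layer_pvalues(km_results: dict[str, KMTestResult], B: int,
                          rng: np.random.Generator) -> PerturbationDraws:
    """Generate B shared-draw perturbed p-values per available layer.

    ``B = 0`` returns empty draws (only the observed p-values, re-evaluated
    with the same batch tail evaluator used for the draws so that observed
    and perturbed values are exactly comparable).
    """
    if B < 0:
        raise ValueError("B must be nonnegative")
    layers = tuple(l for l in LAYERS if l in km_results)
    if not layers:
        raise ValueError("no layers supplied")
    union = _union_subjects(km_results)
    ops = _layer_operators(km_results, union)

    p_obs = np.array([
        mixture_sf_batch(np.array([km_results[l].Q]), km_results[l].eigenvalues)[0]
        if km_results[l].eigenvalues.size else 1.0
        for l in layers
    ])
    if B == 0:
        return PerturbationDraws(layers, np.empty((0, len(layers))), p_obs, 0)

    n_union = len(union)
    R = rng.standard_normal((n_union, B))
    p_pert = np.empty((B, len(layers)))
    for j, layer in enumerate(layers):
        pos, A = ops[layer]
        lam = km_results[layer].eigenvalues
        if lam.size == 0:
            p_pert[:, j] = 1.0
            continue
        if pos.size == n_union and np.array_equal(pos, np.arange(n_union)):
            Z = A @ R                     # avoid a full fancy-index copy
        else:
            Z = A @ R[pos, :]
        Qb = np.einsum("ij,ij->j", Z, Z)
        p_pert[:, j] = mixture_sf_batch(Qb, lam)
    return PerturbationDraws(layers, p_pert, p_obs, B)


def estimate_cov(draws: PerturbationDraws,
                 include_observed: bool = True) -> pd.DataFrame:
    """Empirical covariance of (-2 ln p_l) across draws (b = 0 included by
    default, following the estimator's definition over b in {0, ..., B}).

    Returns a layers x layers DataFrame.  The diagonal is the *estimated*
    variance; downstream combination replaces it by the exact value 4.
    Degenerate (constant) columns yield zero rows with a warning.
    """
    if draws.B < 2:
        raise ValueError("need at least 2 perturbation draws to estimate a covariance")
    mat = draws.stacked() if include_observed else draws.p_perturbed
    x = -2.0 * np.log(np.maximum(mat, 1e-300))
    sd = x.std(axis=0)
    degenerate = sd < 1e-12
    if np.any(degenerate):
        warnings.warn("degenerate perturbed p-value column; covariance row set to 0",
                      OmnibusWarning, stacklevel=2)
    cov = np.cov(x, rowvar=False)
    cov = np.atleast_2d(cov)
    cov[degenerate, :] = 0.0
    cov[:, degenerate] = 0.0
    return pd.DataFrame(cov, index=list(draws.layers), columns=list(draws.layers))


def model_subsets(layers: tuple[str, ...]) -> list[tuple[str, ...]]:
    """The nonempty layer subsets, singletons first: up to 7 disease models."""
    out: list[tuple[str, ...]] = []
    for size in (1, 2, 3):
        for combo in _combos(layers, size):
            out.append(combo)
    return out


def _combos(layers, size):
    from itertools import combinations
    return combinations(layers, size)


def combine_all_models(draws: PerturbationDraws,
                       cov_hat: pd.DataFrame) -> dict[tuple[str, ...], np.ndarray]:
    """Corrected-Fisher p-values of every disease model, for b = 0..B.

    Pairwise and triple models use the corresponding sub-block of the
    estimated covariance; singleton models pass the layer p-value through.
    Returns arrays of length B+1 with the observed value first.
    """
    stacked = draws.stacked()
    cols = {l: j for j, l in enumerate(draws.layers)}
    cov = cov_hat.loc[list(draws.layers), list(draws.layers)].to_numpy()
    out = {}
    for model in model_subsets(draws.layers):
        idx = np.array([cols[l] for l in model])
        out[model] = omnibus_fisher_combine_batch(stacked[:, idx],
                                                  cov[np.ix_(idx, idx)])
    return out


@dataclass
class GeneResult:
    """Per-gene p-values: per layer, per model combination, and overall."""

    layers: tuple[str, ...]
    p_layer: dict[str, float]
    p_model: dict[str, float]          # keyed "GM", "GME", ... observed combos
    cov_hat: pd.DataFrame | None
    p_omnibus: float
    p_optimal: float | None
    B_used: int
    warnings_: list[str] = field(default_factory=list)

    def as_row(self) -> dict:
        row = {}
        for l in LAYERS:
            row[f"p_{l}"] = self.p_layer.get(l, np.nan)
        for key in ("GM", "GE", "ME", "GME"):
            row[f"p_{key}"] = self.p_model.get(key, np.nan)
        row["p_omnibus"] = self.p_omnibus
        row["p_optimal"] = np.nan if self.p_optimal is None else self.p_optimal
        if self.cov_hat is not None:
            for i, a in enumerate(self.cov_hat.index):
                for b in self.cov_hat.columns[i + 1:]:
                    row[f"cov_{a}{b}"] = float(self.cov_hat.loc[a, b])
        row["B_used"] = self.B_used
        return row


def optimal_test(km_results: dict[str, KMTestResult], config: PerturbConfig,
                 rng: np.random.Generator) -> tuple[float, int]:
    """Min-p over all disease models, calibrated by perturbation.

    Per stage B: draw, estimate the covariance from those draws (observed
    draw included), combine every model identically for b = 0..B, take the
    row-wise minimum, and estimate ``p = (1 + #{p^(b) <= p^(0)}) / (1 + B)``
    (the add-one guard keeps the estimate strictly positive).  Escalates to
    the next stage while p is below ``escalation_threshold / B``.
    """
    p_final = None
    B_used = 0
    for B in config.B_stage_schedule:
        draws = perturb_layer_pvalues(km_results, B, rng)
        cov_hat = estimate_cov(draws, config.include_observed_in_cov)
        models = combine_all_models(draws, cov_hat)
        all_p = np.column_stack(list(models.values()))   # (B+1) x n_models
        minp = all_p.min(axis=1)
        p_final = (1.0 + float(np.sum(minp[1:] <= minp[0]))) / (1.0 + B)
        B_used = B
        if p_final >= config.escalation_threshold / B:
            break
    return p_final, B_used


def run_gene(phenotype: Phenotype, blocks: dict[str, OmicsBlock],
             covariates=None, config: PerturbConfig | None = None,
             rng: np.random.Generator | None = None,
             compute_optimal: bool = True) -> GeneResult:
    """End-to-end gene-level analysis over up to three omics blocks.

    ``covariates`` may be a single matrix (shared across layers) or a dict
    keyed by layer; each layer's null model is refitted on exactly that
    layer's subjects.  Subjects present in a block but absent from the
    phenotype are dropped from that block.
    """
    if not blocks:
        raise ValueError("at least one omics block is required")
    config = config or PerturbConfig()
    rng = rng if rng is not None else np.random.default_rng(config.seed)

    pheno_idx = pd.Index(phenotype.subject_ids)
    km_results: dict[str, KMTestResult] = {}
    shared_fit: NullModelFit | None = None
    caught: list[str] = []
    for layer in LAYERS:
        if layer not in blocks:
            continue
        block = blocks[layer]
        keep = pd.Index(block.subject_ids).intersection(pheno_idx)
        if len(keep) == 0:
            raise ValueError(f"layer {layer}: no subjects overlap the phenotype")
        pos_b = pd.Index(block.subject_ids).get_indexer(keep)
        pos_p = pheno_idx.get_indexer(keep)
        sub_block = OmicsBlock(block.matrix[pos_b], layer, keep.to_numpy(),
                               block.weights)
        cov_l = covariates[layer] if isinstance(covariates, dict) else covariates
        X = None if cov_l is None else np.asarray(cov_l, dtype=float)[pos_p]
        sub_pheno = Phenotype(phenotype.values[pos_p], phenotype.family,
                              keep.to_numpy())
        if (shared_fit is not None and len(keep) == shared_fit.n
                and np.array_equal(shared_fit.subject_ids, keep.to_numpy())
                and not isinstance(covariates, dict)):
            fit = shared_fit
        else:
            fit = fit_null(sub_pheno, X)
            if shared_fit is None and not isinstance(covariates, dict):
                shared_fit = fit
        km_results[layer] = km_test(fit, sub_block)

    layers = tuple(km_results)
    p_layer = {l: km_results[l].p_value for l in layers}

    with warnings.catch_warnings(record=True) as wrec:
        warnings.simplefilter("always", OmnibusWarning)
        if len(layers) >= 2:
            draws = perturb_layer_pvalues(km_results, config.B_cov, rng)
            cov_hat = estimate_cov(draws, config.include_observed_in_cov)
            p_model = {}
            for model in model_subsets(layers):
                if len(model) < 2:
                    continue
                sub = cov_hat.loc[list(model), list(model)].to_numpy()
                p_model["".join(model)] = omnibus_fisher_combine(
                    [p_layer[l] for l in model], sub)
            p_omnibus = (p_model["".join(layers)] if len(layers) > 1
                         else p_layer[layers[0]])
            B_used = config.B_cov
        else:
            cov_hat, p_model = None, {}
            p_omnibus = p_layer[layers[0]]
            B_used = 0

        p_optimal = None
        if compute_optimal:
            p_optimal, B_opt = optimal_test(km_results, config, rng)
            B_used = max(B_used, B_opt)
    caught.extend(str(w.message) for w in wrec)

    return GeneResult(layers=layers, p_layer=p_layer, p_model=p_model,
                      cov_hat=cov_hat, p_omnibus=p_omnibus, p_optimal=p_optimal,
                      B_used=B_used, warnings_=caught)
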