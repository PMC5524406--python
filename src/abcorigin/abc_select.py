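"""ABC model choice: rejection plus local weighted multinomial logistic
regression.

The procedure follows the classic regression-based model-choice recipe:
simulated summary-statistic vectors from all candidate models are pooled,
standardized by their pooled mean and standard deviation, and ranked by
Euclidean distance to the (identically standardized) observed vector.  The
``n_keep`` closest simulations are retained; the model indicator is then
regressed on the statistics by weighted maximum likelihood with
Epanechnikov weights ``w(d) = 1 - (d / d_max)^2``, and each model's
posterior probability is the fitted probability evaluated at the observed
vector.  Retention is repeated at several thresholds to check stability.

The multinomial fit is Newton-Raphson on the baseline-coded likelihood with
an optional ridge term; quasi-separation triggers a ridge refit, and a
degenerate retention (one model only) falls back to a weighted counting
estimator with a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .formats_io import ReferenceTable
from .sumstats import SummaryVector

_RIDGE_FALLBACK = 1e-6


class SelectionError(ValueError):
    """The selection stage was asked for something impossible."""


# ---------------------------------------------------------------------------
# standardization


@dataclass
class Standardization:
    """Pooled moments used to scale the table and the observed vector."""

    stat_names: list[str]
    mean: np.ndarray
    sd: np.ndarray
    dropped: list[str]
    imputed_observed: list[str]


def standardize(table: ReferenceTable, observed: SummaryVector):
    """Center/scale every statistic by the pooled simulation moments.

    Zero-variance statistics are dropped from both sides; undefined entries
    (NaN) in table rows or in the observed vector are imputed by the pooled
    mean, i.e. standardized to zero, and recorded.
    """
    if observed.names != table.stat_names:
        raise SelectionError("observed and table statistic names differ")
    stats = table.stats.copy()
    mean = np.nanmean(stats, axis=0)
    if np.isnan(mean).any():
        bad = [n for n, m in zip(table.stat_names, mean) if np.isnan(m)]
        raise SelectionError(f"statistics undefined in every row: {bad}")
    sd = np.nanstd(stats, axis=0, ddof=0)
    keep = sd > 0
    if not keep.any():
        raise SelectionError("no statistic varies across simulations")

    obs = observed.values.copy()
    imputed_observed = [n for n, v in zip(observed.names, obs) if np.isnan(v)]
    nan_cells = np.isnan(stats)
    stats[nan_cells] = np.broadcast_to(mean, stats.shape)[nan_cells]
    obs[np.isnan(obs)] = mean[np.isnan(obs)]

    kept_names = [n for n, k in zip(table.stat_names, keep) if k]
    dropped = [n for n, k in zip(table.stat_names, keep) if not k]
    z = (stats[:, keep] - mean[keep]) / sd[keep]
    z_obs = (obs[keep] - mean[keep]) / sd[keep]

    table_std = ReferenceTable(
        model_ids=table.model_ids,
        param_names=table.param_names,
        params=table.params,
        stat_names=kept_names,
        stats=z,
        flags=table.flags,
    )
    info = Standardization(kept_names, mean[keep], sd[keep], dropped,
                           imputed_observed)
    return table_std, z_obs, info


# ---------------------------------------------------------------------------
# rejection


def rejection(observed_std: np.ndarray, table_std: ReferenceTable,
              n_keep: int):
    """Retain the ``n_keep`` simulations closest to the observed vector in
    Euclidean distance; ties broken by simulation index (stable sort)."""
    if n_keep <= 0:
        raise SelectionError("n_keep must be positive")
    if n_keep > table_std.n_rows:
        raise SelectionError(
            f"n_keep={n_keep} exceeds the {table_std.n_rows} available rows"
        )
    delta = table_std.stats - observed_std[None, :]
    distances = np.sqrt((delta * delta).sum(axis=1))
    order = np.argsort(distances, kind="stable")[:n_keep]
    return order, distances[order]


# ---------------------------------------------------------------------------
# weighted multinomial logistic regression


@dataclass
class RegressionFit:
    """Baseline-coded coefficients of the local weighted logit."""

    model_order: list[str]          # class 0 is the baseline
    beta: np.ndarray                # (K-1) x (1 + n_stats)
    converged: bool
    ridge: float
    weights: np.ndarray = field(repr=False, default=None)  # type: ignore


def _softmax_probs(X: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Class probabilities with implicit baseline class 0."""
    eta = X @ beta.T
    z = np.hstack([np.zeros((X.shape[0], 1)), eta])
    z -= z.max(axis=1, keepdims=True)
    p = np.exp(z)
    p /= p.sum(axis=1, keepdims=True)
    return p


def weighted_multinomial_logit(X: np.ndarray, y_idx: np.ndarray,
                               w: np.ndarray, n_classes: int,
                               ridge: float = 0.0, max_iter: int = 200,
                               tol: float = 1e-10):
    """Weighted maximum-likelihood multinomial logit via Newton-Raphson.

    ``X`` must already include the intercept column; ``y_idx`` codes the
    class of each row (0 = baseline).  Returns (beta, converged).
    """
    n, p = X.shape
    K = n_classes
    beta = np.zeros((K - 1, p))
    converged = False
    for _ in range(max_iter):
        P = _softmax_probs(X, beta)
        grad = np.concatenate([
            X.T @ (w * ((y_idx == k).astype(float) - P[:, k]))
            - ridge * beta[k - 1]
            for k in range(1, K)
        ])
        m = (K - 1) * p
        H = np.empty((m, m))
        for k in range(1, K):
            for l in range(1, K):
                diag = w * P[:, k] * ((k == l) - P[:, l])
                H[(k - 1) * p:k * p, (l - 1) * p:l * p] = \
                    X.T @ (diag[:, None] * X)
        H[np.diag_indices(m)] += ridge
        try:
            delta = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            return beta, False
        if not np.all(np.isfinite(delta)):
            return beta, False
        beta = beta + delta.reshape(K - 1, p)
        if np.abs(delta).max() < tol:
            converged = True
            break
    if not np.all(np.isfinite(beta)) or np.abs(beta).max() > 1e8:
        converged = False
    return beta, converged


@dataclass
class ThresholdResult:
    """Model posteriors for one retention threshold."""

    n_keep: int
    posteriors: dict[str, float]
    retained_counts: dict[str, int]
    max_distance: float
    converged: bool
    degenerate: bool
    fit: RegressionFit | None

    def __post_init__(self) -> None:
        total = sum(self.posteriors.values())
        if abs(total - 1.0) > 1e-9:
            raise RuntimeError(f"posteriors sum to {total}, not 1")


def lr_model_choice(retained: ReferenceTable, distances: np.ndarray,
                    observed_std: np.ndarray,
                    model_order: list[str] | None = None) -> ThresholdResult:
    """Fit the local weighted logit on retained rows and evaluate each
    model's probability at the observed vector."""
    if model_order is None:
        model_order = sorted(set(retained.model_ids.tolist()))
    counts = {m: int((retained.model_ids == m).sum()) for m in model_order}
    d_max = float(distances.max()) if len(distances) else 0.0
    if d_max > 0:
        w = 1.0 - (distances / d_max) ** 2
    else:
        w = np.ones_like(distances)
    present = [m for m in model_order if counts[m] > 0]

    if len(present) < 2:
        posteriors = {m: 1.0 if counts[m] > 0 else 0.0 for m in model_order}
        return ThresholdResult(
            n_keep=retained.n_rows, posteriors=posteriors,
            retained_counts=counts, max_distance=d_max, converged=True,
            degenerate=True, fit=None)

    X = np.hstack([np.ones((retained.n_rows, 1)), retained.stats])
    code = {m: i for i, m in enumerate(model_order)}
    y_idx = np.array([code[m] for m in retained.model_ids])
    K = len(model_order)

    beta, converged = weighted_multinomial_logit(X, y_idx, w, K)
    ridge = 0.0
    if not converged:
        beta, converged = weighted_multinomial_logit(
            X, y_idx, w, K, ridge=_RIDGE_FALLBACK)
        ridge = _RIDGE_FALLBACK

    if converged:
        x0 = np.hstack([[1.0], observed_std])[None, :]
        probs = _softmax_probs(x0, beta)[0]
        posteriors = {m: float(probs[code[m]]) for m in model_order}
    else:
        # weighted counting fallback, reported with converged=False
        wsum = w.sum()
        posteriors = {
            m: float(w[retained.model_ids == m].sum() / wsum)
            for m in model_order
        }
    fit = RegressionFit(model_order=model_order, beta=beta,
                        converged=converged, ridge=ridge, weights=w)
    return ThresholdResult(
        n_keep=retained.n_rows, posteriors=posteriors, retained_counts=counts,
        max_distance=d_max, converged=converged, degenerate=False, fit=fit)


# ---------------------------------------------------------------------------
# the full model-choice run


DEFAULT_THRESHOLDS = (25_000, 50_000, 75_000, 100_000)


@dataclass
class ModelPosterior:
    """Posterior probabilities per retention threshold."""

    model_order: list[str]
    results: dict[int, ThresholdResult]
    standardization: Standardization

    def table(self):
        """threshold x model probability matrix as a pandas DataFrame."""
        import pandas as pd

        return pd.DataFrame(
            {m: [self.results[t].posteriors[m] for t in self.results]
             for m in self.model_order},
            index=list(self.results),
        ).rename_axis("threshold")


def model_choice_run(observed: SummaryVector,
                     table_admixture: ReferenceTable,
                     table_treelike: ReferenceTable,
                     thresholds=DEFAULT_THRESHOLDS) -> ModelPosterior:
    """Pool both models' reference tables and run rejection + local logit
    at every retention threshold."""
    pooled = ReferenceTable.concatenate([table_admixture, table_treelike])
    model_order = sorted(set(pooled.model_ids.tolist()))
    for t in thresholds:
        if t > pooled.n_rows:
            raise SelectionError(
                f"threshold {t} exceeds the pooled table size {pooled.n_rows}"
            )
    table_std, obs_std, info = standardize(pooled, observed)
    results: dict[int, ThresholdResult] = {}
    for t in thresholds:
        idx, dist = rejection(obs_std, table_std, t)
        retained = ReferenceTable(
            model_ids=table_std.model_ids[idx],
            param_names=table_std.param_names,
            params=table_std.params[idx],
            stat_names=table_std.stat_names,
            stats=table_std.stats[idx],
            flags=table_std.flags[idx],
        )
        results[int(t)] = lr_model_choice(retained, dist, obs_std,
                                          model_order=model_order)
    return ModelPosterior(model_order=model_order, results=results,
                          standardization=info)


# ---------------------------------------------------------------------------
# model-recovery experiment (pseudo-observed datasets)


@dataclass
class RecoverySettings:
    """Scaled-down production settings for a model-recovery study."""

    marker_type: str
    sample_sizes: dict[str, int]
    mutation_config: "object"
    n_sims_per_model: int
    n_keep: int
    pod_priors: dict[str, "object"] | None = None  # per-model POD priors


@dataclass
class RecoverySummary:
    """How often model choice recovers the generating model."""

    mean_posterior: dict[str, float]   # posterior of the generating model
    frac_preferred: dict[str, float]   # fraction of PODs with posterior > 0.5
    pod_posteriors: dict[str, list[float]]


def default_recovery_settings(n_sims_per_model: int = 20_000,
                              n_keep: int = 1_000) -> RecoverySettings:
    """The canonical model-recovery study design.

    HVRI-type data for 25 samples per group: the sequence statistic suite
    carries between-group distances and Fst, which separate the two
    demographies, whereas the Y-STR suite is within-population only.  PODs
    are drawn from identifiable sub-regions of the default priors (central
    admixture proportion, recent admixture pulse, deep MK split, moderate
    population sizes); reference tables use the full default priors.
    """
    from .coalsim import MutationConfig, PriorSet

    base = PriorSet.default().bounds
    moderate_n = {f"N_{g}": (1_000.0, 20_000.0)
                  for g in ("MK", "KM", "TK", "anc")}
    pod_tree = PriorSet({**base, **moderate_n, "T2": (1_000.0, 4_000.0)})
    pod_adm = PriorSet({**base, **moderate_n,
                        "alpha": (0.3, 0.7), "Tadm": (10.0, 40.0)})
    return RecoverySettings(
        marker_type="HVRI",
        sample_sizes={"MK": 25, "KM": 25, "TK": 25},
        mutation_config=MutationConfig(),
        n_sims_per_model=n_sims_per_model,
        n_keep=n_keep,
        pod_priors={"tree_like": pod_tree, "admixture": pod_adm},
    )


def model_recovery(priors, settings: RecoverySettings, n_pods_per_model: int,
                   rng: np.random.Generator) -> RecoverySummary:
    """Simulate PODs from each model, run model choice against shared
    reference tables, and summarize how much posterior mass lands on the
    generating model."""
    from . import coalsim

    tables = {
        m: coalsim.simulate_reference_table(
            m, priors, settings.n_sims_per_model, settings.marker_type,
            settings.sample_sizes, settings.mutation_config, rng)
        for m in coalsim.MODELS
    }
    pops = [d for d in coalsim.DEMES if settings.sample_sizes.get(d, 0) > 0]
    pod_posteriors: dict[str, list[float]] = {m: [] for m in coalsim.MODELS}
    for m in coalsim.MODELS:
        gen_priors = priors if settings.pod_priors is None \
            else settings.pod_priors[m]
        for _ in range(n_pods_per_model):
            params = coalsim.draw_params(gen_priors, m, rng)
            panel = coalsim.simulate_dataset(
                params, settings.marker_type, settings.sample_sizes,
                settings.mutation_config, rng)
            vec = coalsim._summary(panel, settings.marker_type, pops)
            mp = model_choice_run(
                vec, tables[coalsim.MODEL_ADMIXTURE],
                tables[coalsim.MODEL_TREELIKE],
                thresholds=(settings.n_keep,))
            pod_posteriors[m].append(
                mp.results[settings.n_keep].posteriors[m])
    return RecoverySummary(
        mean_posterior={m: float(np.mean(v))
                        for m, v in pod_posteriors.items()},
        frac_preferred={m: float(np.mean(np.array(v) > 0.5))
                        for m, v in pod_posteriors.items()},
        pod_posteriors=pod_posteriors,
    )
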