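"""Naive-Bayes classification with per-class Gaussian mixture densities.

Each class label (normal / abnormal) gets its own density model

    F(x | C_l) = Σ_{i=1..s_l} h_i · N(x; μ_i, Σ_i),

a mixture of full-covariance Gaussians fitted by expectation-
maximization on that class's training vectors.  The number of
components s_l is chosen per class by mean held-out log-likelihood over
random validation splits, and the decision is the Bayes rule

    P(abnormal | x) = F(x|ab)·F(ab) / Σ_l F(x|C_l)·F(C_l)  ≥  τ,

with the class priors F(C_l) estimated as training proportions.  τ
defaults to 0.5 (the MAP rule); screening applications lower it so that
recall of the abnormal class is favoured over precision.

All densities are computed in log space (log-sum-exp) so that far-tail
points never underflow to a hard zero.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from typing import Sequence, Tuple

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.special import expit, logsumexp

logger = logging.getLogger("ghcs.gmm_nb")

MODEL_SCHEMA_VERSION = 1

NORMAL, ABNORMAL = "normal", "abnormal"


# ---------------------------------------------------------------------------
# model containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GaussianComponent:
    weight: float
    mean: np.ndarray          # (q,)
    cov: np.ndarray           # (q, q), symmetric positive-definite

    def __post_init__(self):
        object.__setattr__(self, "mean", np.asarray(self.mean, dtype=np.float64))
        object.__setattr__(self, "cov", np.asarray(self.cov, dtype=np.float64))


@dataclass(frozen=True)
class ClassGMM:
    """One class's mixture density plus its prior probability."""

    label: str
    components: Tuple[GaussianComponent, ...]
    prior: float = 1.0

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def weights(self) -> np.ndarray:
        return np.array([c.weight for c in self.components])

    @property
    def means(self) -> np.ndarray:
        return np.stack([c.mean for c in self.components])


@dataclass(frozen=True)
class EMConfig:
    """Hyperparameters of the EM fit and component-count search."""

    max_iter: int = 200
    tol: float = 1e-6            # relative log-likelihood change
    reg_covar: float = 1e-6      # ridge added to covariance diagonals
    seed: int = 0
    n_init: int = 5
    component_grid: Tuple[int, ...] = tuple(range(1, 11))
    n_val_splits: int = 5
    val_fraction: float = 0.3
    #: parsimony margin (nats/sample): the smallest s whose mean held-out
    #: log-likelihood is within this margin of the best is selected.  A
    #: redundant extra component can win by a sliver of sampling noise;
    #: the margin is the one-standard-error rule's analogue here.
    selection_margin: float = 5e-3

    def __post_init__(self):
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if not self.component_grid:
            raise ValueError("component_grid must be non-empty")
        if not (0.0 < self.val_fraction < 1.0):
            raise ValueError("val_fraction must be in (0, 1)")


@dataclass(frozen=True)
class FittedModel:
    """Two-class GMM naive-Bayes model with its feature standardization."""

    classes: Tuple[ClassGMM, ClassGMM]   # (normal, abnormal)
    feature_mean: np.ndarray
    feature_std: np.ndarray
    tau: float = 0.5

    @property
    def normal(self) -> ClassGMM:
        return self.classes[0]

    @property
    def abnormal(self) -> ClassGMM:
        return self.classes[1]


# ---------------------------------------------------------------------------
# densities
# ---------------------------------------------------------------------------

def log_gaussian_pdf(X: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Log of the multivariate normal density, via Cholesky."""
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    q = X.shape[1]
    try:
        chol = cho_factor(cov, lower=True)
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError(
            f"covariance not positive-definite even after regularization: {e}"
        ) from e
    diff = X - mean
    solved = cho_solve(chol, diff.T).T
    maha = np.einsum("ij,ij->i", diff, solved)
    logdet = 2.0 * np.log(np.diag(chol[0])).sum()
    return -0.5 * (q * np.log(2.0 * np.pi) + logdet + maha)


def gaussian_pdf(x: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> float:
    """Multivariate normal density N(x; μ, Σ) at a single point."""
    return float(np.exp(log_gaussian_pdf(x, mean, cov)[0]))


def log_class_conditional(X: np.ndarray, gmm: ClassGMM) -> np.ndarray:
    """log F(x | C_l) = log Σ_i h_i N(x; μ_i, Σ_i), per row of X."""
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if X.shape[1] != gmm.components[0].mean.shape[0]:
        raise ValueError(
            f"dimension mismatch: x has {X.shape[1]} features, "
            f"model expects {gmm.components[0].mean.shape[0]}"
        )
    parts = np.stack(
        [np.log(c.weight) + log_gaussian_pdf(X, c.mean, c.cov) for c in gmm.components]
    )
    return logsumexp(parts, axis=0)


def class_conditional(x: np.ndarray, gmm: ClassGMM) -> float:
    """Mixture density F(x | C_l) at a single point."""
    return float(np.exp(log_class_conditional(x, gmm)[0]))


# ---------------------------------------------------------------------------
# EM fitting
# ---------------------------------------------------------------------------

def _kmeans_pp_means(X: np.ndarray, s: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++-style spread-out seeding of component means."""
    n = X.shape[0]
    idx = [int(rng.integers(n))]
    for _ in range(1, s):
        d2 = np.min(
            ((X[:, None, :] - X[idx][None, :, :]) ** 2).sum(-1), axis=1
        )
        total = d2.sum()
        if total <= 0:
            idx.append(int(rng.integers(n)))
        else:
            idx.append(int(rng.choice(n, p=d2 / total)))
    return X[idx].copy()


def _em_single(
    X: np.ndarray, s: int, config: EMConfig, rng: np.random.Generator
) -> tuple[list[GaussianComponent], float, list[float]]:
    n, q = X.shape
    reg = config.reg_covar * np.eye(q)
    pooled = np.cov(X.T, bias=True).reshape(q, q) + reg
    means = _kmeans_pp_means(X, s, rng)
    covs = np.repeat(pooled[None], s, axis=0)
    weights = np.full(s, 1.0 / s)

    trace: list[float] = []
    prev_ll = -np.inf
    for _ in range(config.max_iter):
        # E-step
        log_parts = np.stack(
            [
                np.log(weights[i]) + log_gaussian_pdf(X, means[i], covs[i])
                for i in range(s)
            ]
        )  # (s, n)
        log_norm = logsumexp(log_parts, axis=0)
        ll = float(log_norm.sum())
        trace.append(ll)
        resp = np.exp(log_parts - log_norm)  # (s, n)

        # M-step
        nk = resp.sum(axis=1)
        for i in range(s):
            if nk[i] < 1e-8 * n:
                logger.warning("component %d collapsed; re-seeding from data", i)
                means[i] = X[int(rng.integers(n))]
                covs[i] = pooled.copy()
                nk[i] = 1.0
                continue
            means[i] = resp[i] @ X / nk[i]
            diff = X - means[i]
            covs[i] = (resp[i][:, None] * diff).T @ diff / nk[i] + reg
        weights = nk / nk.sum()

        if np.isfinite(prev_ll) and abs(ll - prev_ll) <= config.tol * abs(prev_ll):
            break
        prev_ll = ll

    comps = [
        GaussianComponent(weight=float(weights[i]), mean=means[i], cov=covs[i])
        for i in range(s)
    ]
    return comps, trace[-1], trace


def em_fit(
    X: np.ndarray, s: int, config: EMConfig | None = None, label: str = ""
) -> ClassGMM:
    """Fit an s-component full-covariance GMM by EM.

    Means are seeded k-means++-style from the data, covariances start at
    the pooled sample covariance and weights uniform; ``n_init`` seeded
    restarts are run and the best final log-likelihood kept.  The
    observed-data log-likelihood trace is checked to be non-decreasing
    (a structural property of EM) on every restart.
    """
    config = config or EMConfig()
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    n, q = X.shape
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in feature matrix")
    if n < s * (q + 1):
        raise ValueError(
            f"need at least s(q+1) = {s * (q + 1)} samples for s={s}, q={q}; got {n}"
        )
    master = np.random.default_rng(config.seed)
    best: tuple[list[GaussianComponent], float] | None = None
    for _ in range(config.n_init):
        comps, ll, trace = _em_single(X, s, config, master)
        drops = np.diff(trace) < -1e-8 * np.maximum(1.0, np.abs(trace[:-1]))
        if drops.any():
            logger.warning("EM log-likelihood decreased at iterations %s",
                           np.nonzero(drops)[0].tolist())
        if best is None or ll > best[1]:
            best = (comps, ll)
    assert best is not None
    return ClassGMM(label=label, components=tuple(best[0]), prior=1.0)


def log_likelihood(X: np.ndarray, gmm: ClassGMM) -> float:
    """Total observed-data log-likelihood of X under the mixture."""
    return float(log_class_conditional(X, gmm).sum())


def select_num_components(X: np.ndarray, config: EMConfig | None = None) -> int:
    """Pick the component count by mean held-out log-likelihood.

    For each s in the grid, ``n_val_splits`` random train/validation
    splits are scored; the smallest s whose mean per-sample held-out
    log-likelihood lies within ``selection_margin`` of the best wins
    (exact ties therefore also resolve to the smallest s).
    """
    config = config or EMConfig()
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    n, q = X.shape
    rng = np.random.default_rng(config.seed)
    splits = []
    n_val = max(1, int(round(config.val_fraction * n)))
    for _ in range(config.n_val_splits):
        perm = rng.permutation(n)
        splits.append((perm[n_val:], perm[:n_val]))

    scores: dict[int, float] = {}
    for s in config.component_grid:
        vals = []
        for k, (tr, va) in enumerate(splits):
            if len(tr) < s * (q + 1):
                break
            try:
                sub = replace(config, seed=config.seed + 1000 * s + k, n_init=config.n_init)
                gmm = em_fit(X[tr], s, sub)
            except (ValueError, np.linalg.LinAlgError) as e:
                logger.warning("EM fit failed for s=%d split %d: %s", s, k, e)
                continue
            vals.append(log_likelihood(X[va], gmm) / len(va))
        if vals:
            scores[s] = float(np.mean(vals))
        else:
            logger.warning("all validation fits failed for s=%d; skipping", s)
    if not scores:
        # dataset too small for held-out scoring: fall back to the
        # smallest grid value the full data can support
        feasible = [s for s in config.component_grid if n >= s * (q + 1)]
        if feasible:
            s0 = min(feasible)
            logger.warning(
                "no grid value could be validated on held-out splits "
                "(n=%d, q=%d); falling back to s=%d", n, q, s0,
            )
            return s0
        raise RuntimeError("component selection failed for every grid value")
    best_score = max(scores.values())
    return min(
        s for s, v in scores.items() if v >= best_score - config.selection_margin
    )


# ---------------------------------------------------------------------------
# the two-class classifier
# ---------------------------------------------------------------------------

def fit_classifier(
    X: np.ndarray,
    labels: Sequence[str],
    config: EMConfig | None = None,
    tau: float = 0.5,
) -> FittedModel:
    """Fit the two-class GMM naive-Bayes model.

    Features are z-scored with training-set statistics (stored in the
    model), each class's component count is selected independently, and
    priors are the training class proportions.
    """
    config = config or EMConfig()
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    labels = np.asarray(labels)
    present = set(labels.tolist())
    if present != {NORMAL, ABNORMAL}:
        raise ValueError(
            f"training data must contain both classes {{{NORMAL!r}, {ABNORMAL!r}}}; got {sorted(present)}"
        )
    mu = X.mean(axis=0)
    sd = np.maximum(X.std(axis=0), 1e-12)
    Z = (X - mu) / sd

    fitted = []
    for offset, lab in enumerate((NORMAL, ABNORMAL)):
        Xl = Z[labels == lab]
        sub = replace(config, seed=config.seed + offset)
        s_star = select_num_components(Xl, sub)
        gmm = em_fit(Xl, s_star, sub, label=lab)
        prior = float(len(Xl) / len(Z))
        fitted.append(ClassGMM(label=lab, components=gmm.components, prior=prior))
        logger.info("class %s: s*=%d, prior=%.3f", lab, s_star, prior)
    return FittedModel(
        classes=(fitted[0], fitted[1]), feature_mean=mu, feature_std=sd, tau=tau
    )


def posterior_abnormal(X: np.ndarray, model: FittedModel) -> np.ndarray:
    """P(abnormal | x) for each row, computed on log-densities."""
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    Z = (X - model.feature_mean) / model.feature_std
    log_norm = log_class_conditional(Z, model.normal) + np.log(model.normal.prior)
    log_abn = log_class_conditional(Z, model.abnormal) + np.log(model.abnormal.prior)
    # sigmoid of the log-odds: numerically stable and exact at ties
    return expit(log_abn - log_norm)


def predict(X: np.ndarray, model: FittedModel, tau: float | None = None):
    """Bayes decision per row: ``abnormal`` iff P(abnormal|x) ≥ τ.

    Returns ``(labels, posterior_abnormal)``.  τ = 0.5 is the MAP rule;
    the ≥ comparison resolves exact ties toward the abnormal class
    (screening-friendly).
    """
    tau = model.tau if tau is None else tau
    post = posterior_abnormal(X, model)
    labels = np.where(post >= tau, ABNORMAL, NORMAL)
    return labels, post


# ---------------------------------------------------------------------------
# model file I/O
# ---------------------------------------------------------------------------

def save_model(model: FittedModel, path) -> None:
    """Write the model as schema-versioned JSON (lossless round trip)."""
    doc = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "standardization": {
            "mean": model.feature_mean.tolist(),
            "std": model.feature_std.tolist(),
        },
        "tau": model.tau,
        "classes": [
            {
                "label": g.label,
                "prior": g.prior,
                "components": [
                    {
                        "weight": c.weight,
                        "mean": c.mean.tolist(),
                        "cov": c.cov.tolist(),
                    }
                    for c in g.components
                ],
            }
            for g in model.classes
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_model(path) -> FittedModel:
    """Load a model file written by :func:`save_model`."""
    with open(path, encoding="utf-8") as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as e:
            raise ValueError(f"corrupt or truncated model file {path}: {e}") from e
    version = doc.get("schema_version")
    if version != MODEL_SCHEMA_VERSION:
        raise ValueError(
            f"model schema version {version} unsupported (expected {MODEL_SCHEMA_VERSION})"
        )
    classes = []
    for g in doc["classes"]:
        comps = tuple(
            GaussianComponent(
                weight=float(c["weight"]),
                mean=np.array(c["mean"], dtype=np.float64),
                cov=np.array(c["cov"], dtype=np.float64),
            )
            for c in g["components"]
        )
        classes.append(ClassGMM(label=g["label"], components=comps, prior=float(g["prior"])))
    by_label = {g.label: g for g in classes}
    return FittedModel(
        classes=(by_label[NORMAL], by_label[ABNORMAL]),
        feature_mean=np.array(doc["standardization"]["mean"], dtype=np.float64),
        feature_std=np.array(doc["standardization"]["std"], dtype=np.float64),
        tau=float(doc["tau"]),
    )
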