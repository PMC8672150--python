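"""Synthetic cytometry benchmarks and their evaluation metrics.

Samples are drawn from 10-dimensional Gaussian mixtures whose component
means have entries 0 ("not expressed") or 8 ("expressed"), covariances
with variances uniform in [1, 2] and random correlation, and per-sample
mean perturbations of integer-rounded N(0, 1/2) per coordinate.  Cluster
abundances follow a fixed reference weight vector (127 components in
dyadic blocks); the responder benchmark uses two fixed 125-component
vectors in which a single predictive component doubles from 0.0011 to
0.0022 between classes, all other weights proportionally reduced.  A
non-Gaussian variant transforms every margin by the elementwise map
Gamma(1 + |x/4|).

Evaluation: adjusted Rand index against the generating component labels,
the smallest-p "top cluster" under the per-phenotype binomial GLMM, and
the 5-fold cross-validated AUC of a logistic model on the top cluster's
frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gamma as gamma_fn
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import adjusted_rand_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from ._weights import (
    NONRESPONDER_WEIGHTS,
    PREDICTIVE_INDEX,
    REFERENCE_WEIGHTS,
    RESPONDER_WEIGHTS,
)
from .io_core import ExpressionMatrix
from .stats_models import fit_binomial_glmm

__all__ = [
    "SimulatedExperiment",
    "reference_weights",
    "responder_weights",
    "simulate_gaussian_experiment",
    "simulate_responder_experiment",
    "transform_nongaussian",
    "adjusted_rand_index",
    "top_cluster",
    "five_fold_cv_auc",
    "PREDICTIVE_INDEX",
]


@dataclass
class SimulatedExperiment:
    samples: list  # ExpressionMatrix per sample
    labels: dict  # sample_id -> per-cell true component index
    responder: dict = field(default_factory=dict)  # sample_id -> 0/1
    means: np.ndarray | None = None
    weights: np.ndarray | None = None
    predictive_component: int | None = None
    seed: int | None = None

    @property
    def sample_ids(self) -> list:
        return [s.sample_id for s in self.samples]

    def concatenated_labels(self) -> np.ndarray:
        return np.concatenate([self.labels[s.sample_id] for s in self.samples])


def reference_weights() -> np.ndarray:
    """The 127-component reference abundance vector (decreasing)."""
    return REFERENCE_WEIGHTS.copy()


def responder_weights() -> tuple:
    """(non-responder, responder) 125-component weight vectors."""
    return NONRESPONDER_WEIGHTS.copy(), RESPONDER_WEIGHTS.copy()


def _distinct_mean_vectors(n_clusters: int, dim: int, rng) -> np.ndarray:
    if n_clusters > 2**dim:
        raise ValueError(
            f"cannot draw {n_clusters} distinct mean vectors in "
            f"{{0,8}}^{dim}"
        )
    seen = set()
    means = []
    while len(means) < n_clusters:
        v = tuple(rng.choice([0.0, 8.0], size=dim))
        if v not in seen:
            seen.add(v)
            means.append(v)
    return np.array(means)


def _random_covariance(dim: int, rng) -> np.ndarray:
    w = rng.normal(size=(dim, dim))
    s = w @ w.T
    d = np.sqrt(np.diag(s))
    corr = s / np.outer(d, d)
    var = rng.uniform(1.0, 2.0, size=dim)
    sd = np.sqrt(var)
    return corr * np.outer(sd, sd)


def _draw_sample(sample_id, means, weights, n_obs, rng, transform):
    dim = means.shape[1]
    counts = rng.multinomial(n_obs, weights)
    xs = []
    labels = []
    for c, (mu, nc) in enumerate(zip(means, counts)):
        if nc == 0:
            continue
        shift = np.round(rng.normal(0.0, 0.5, size=dim))
        cov = _random_covariance(dim, rng)
        chol = np.linalg.cholesky(cov)
        z = rng.normal(size=(nc, dim))
        xs.append(z @ chol.T + mu + shift)
        labels.append(np.full(nc, c))
    x = np.vstack(xs)
    lab = np.concatenate(labels)
    perm = rng.permutation(x.shape[0])
    x, lab = x[perm], lab[perm]
    if transform:
        x = transform_nongaussian(x)
    markers = [f"V{i + 1}" for i in range(dim)]
    return ExpressionMatrix(sample_id=sample_id, markers=markers, values=x), lab


def simulate_gaussian_experiment(n_clusters: int, n_samples: int = 10,
                                 n_obs: int = 25_000, dim: int = 10,
                                 seed: int = 0,
                                 transform: bool = False) -> SimulatedExperiment:
    """Cluster-number benchmark: ``n_clusters`` components shared across
    ``n_samples`` samples, abundances from the reference vector with the
    residual mass spread uniformly."""
    if not 1 <= n_clusters <= REFERENCE_WEIGHTS.size:
        raise ValueError(
            f"n_clusters must be in [1, {REFERENCE_WEIGHTS.size}]"
        )
    rng = np.random.default_rng(seed)
    w = REFERENCE_WEIGHTS[:n_clusters].copy()
    w += (1.0 - w.sum()) / n_clusters
    means = _distinct_mean_vectors(n_clusters, dim, rng)
    samples = []
    labels = {}
    for i in range(n_samples):
        sid = f"sample{i + 1:02d}"
        em, lab = _draw_sample(sid, means, w, n_obs, rng, transform)
        samples.append(em)
        labels[sid] = lab
    return SimulatedExperiment(samples=samples, labels=labels, means=means,
                               weights=w, seed=seed)


def simulate_responder_experiment(seed: int = 0, transform: bool = False,
                                  n_samples: int = 20, n_obs: int = 25_000,
                                  dim: int = 10) -> SimulatedExperiment:
    """Responder benchmark: half the samples are responders whose
    predictive-component weight is doubled (0.0011 -> 0.0022)."""
    rng = np.random.default_rng(seed)
    k = NONRESPONDER_WEIGHTS.size
    means = _distinct_mean_vectors(k, dim, rng)
    resp_ids = rng.choice(n_samples, size=n_samples // 2, replace=False)
    samples = []
    labels = {}
    responder = {}
    for i in range(n_samples):
        sid = f"sample{i + 1:02d}"
        is_resp = int(i in resp_ids)
        w = RESPONDER_WEIGHTS if is_resp else NONRESPONDER_WEIGHTS
        em, lab = _draw_sample(sid, means, w / w.sum(), n_obs, rng, transform)
        samples.append(em)
        labels[sid] = lab
        responder[sid] = is_resp
    return SimulatedExperiment(
        samples=samples, labels=labels, responder=responder, means=means,
        predictive_component=PREDICTIVE_INDEX, seed=seed,
    )


def transform_nongaussian(x: np.ndarray) -> np.ndarray:
    """Elementwise Gamma(1 + |x/4|) map (makes margins non-Gaussian)."""
    return gamma_fn(1.0 + np.abs(np.asarray(x, dtype=float) / 4.0))


def adjusted_rand_index(labels_a, labels_b, restrict_to=None) -> float:
    """Hubert-Arabie adjusted Rand index, optionally on a row subset."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("label vectors must have equal length")
    if restrict_to is not None:
        a = a[restrict_to]
        b = b[restrict_to]
    return float(adjusted_rand_score(a, b))


def top_cluster(count_matrix, responder):
    """Phenotype with the smallest GLMM p-value for responder status.

    Ties favour the smaller column index.  Returns (phenotype, list of
    per-phenotype results).
    """
    cols = list(count_matrix.counts.columns)
    if not cols:
        raise ValueError("empty count matrix")
    y = np.asarray(
        [responder[s] for s in count_matrix.counts.index], dtype=float
    )
    n = count_matrix.totals.loc[count_matrix.counts.index].to_numpy(float)
    results = []
    for p in cols:
        c = count_matrix.counts[p].to_numpy(float)
        try:
            results.append(fit_binomial_glmm(c, n, y, phenotype=p))
        except ValueError:
            continue
    finite = [r for r in results if np.isfinite(r.p_value)]
    if not finite:
        raise ValueError("all differential-abundance fits failed")
    best = min(
        enumerate(finite), key=lambda t: (t[1].p_value, t[0])
    )[1]
    return best.phenotype, results


def five_fold_cv_auc(frequencies, responder_labels, seed: int = 0) -> float:
    """Mean AUC over stratified 5-fold CV of a univariate logistic model."""
    x = np.asarray(frequencies, dtype=float).reshape(-1, 1)
    y = np.asarray(responder_labels, dtype=int)
    if x.shape[0] < 10 or len(set(y)) < 2:
        raise ValueError("need >= 10 samples with both classes present")
    skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
    aucs = []
    for train, test in skf.split(x, y):
        clf = LogisticRegression().fit(x[train], y[train])
        scores = clf.decision_function(x[test])
        aucs.append(roc_auc_score(y[test], scores))
    return float(np.mean(aucs))
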