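"""Per-grid-cell Gaussian-mixture likelihoods and their goodness-of-fit test.

One variational-Bayes Gaussian mixture is fitted to the 3-D PCA scores of
the simulated segments of every (g_i, g_c) grid cell; together with the
fitted feature transform these mixtures form the forward model
``P(score | g)`` evaluated by the inference module.  Fit quality is checked
with the two-sample energy test (logarithmic distance kernel, permutation
p-values).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy.spatial.distance import cdist
from scipy.special import logsumexp
from sklearn.mixture import BayesianGaussianMixture

from ._utils import derive_seed
from .feature_space import FeatureTransform
from .surrogate_sim import ParameterGrid

DEFAULT_MAX_K = 20
#: components below this weight count as pruned when reporting effective K
PRUNE_WEIGHT = 1e-3
_REG_COVAR = 1e-6


@dataclass(frozen=True)
class CellGMM:
    """Gaussian mixture over the 3-D score space of one grid cell."""

    weights: np.ndarray
    means: np.ndarray  # (K, d)
    covariances: np.ndarray  # (K, d, d)
    n_samples: int = 0  # fitting sample count; informs the pruning threshold

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        for k, cov in enumerate(np.asarray(self.covariances)):
            if not np.allclose(cov, cov.T, atol=1e-10):
                raise ValueError(f"covariance {k} is not symmetric")
            if np.any(np.linalg.eigvalsh(cov) <= 0):
                raise ValueError(f"covariance {k} is not positive-definite")

    @property
    def n_components(self) -> int:
        return int(np.asarray(self.weights).size)

    @property
    def effective_k(self) -> int:
        """Number of components carrying non-negligible weight.

        The threshold is the larger of PRUNE_WEIGHT and two expected points,
        so single-point components of small fitting samples count as pruned.
        """
        thresh = PRUNE_WEIGHT
        if self.n_samples > 0:
            thresh = max(thresh, 2.0 / self.n_samples)
        return int(np.sum(np.asarray(self.weights) > thresh))

    def log_density(self, y: np.ndarray) -> np.ndarray | float:
        """Log mixture density at one point or an (n, d) array of points."""
        y = np.asarray(y, dtype=float)
        single = y.ndim == 1
        pts = np.atleast_2d(y)
        d = pts.shape[1]
        comps = np.empty((pts.shape[0], self.n_components))
        for k in range(self.n_components):
            chol = np.linalg.cholesky(self.covariances[k])
            diff = pts - self.means[k]
            sol = np.linalg.solve(chol, diff.T)
            maha = np.sum(sol**2, axis=0)
            logdet = 2.0 * np.sum(np.log(np.diag(chol)))
            comps[:, k] = (
                np.log(self.weights[k])
                - 0.5 * (d * np.log(2.0 * np.pi) + logdet + maha)
            )
        out = logsumexp(comps, axis=1)
        return float(out[0]) if single else out


def fit_cell_gmm(
    scores: np.ndarray, max_K: int = DEFAULT_MAX_K, seed: int = 0
) -> CellGMM:
    """Fit a variational-Bayes Gaussian mixture to one cell's scores.

    Components are determined automatically (weight-concentration prior
    ``1/max_K``); three restarts keep the highest evidence.  Fewer than 10
    points fall back to a single Gaussian with a warning.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    n, d = scores.shape
    if n < 10:
        warnings.warn(
            f"only {n} points; falling back to a single-Gaussian cell model",
            stacklevel=2,
        )
        cov = np.atleast_2d(np.cov(scores, rowvar=False, ddof=1)) if n > 1 else np.eye(d)
        cov = cov + _REG_COVAR * np.eye(d)
        return CellGMM(
            weights=np.ones(1),
            means=scores.mean(axis=0, keepdims=True),
            covariances=cov[None, :, :],
            n_samples=n,
        )
    k = min(max_K, n)
    reg = _REG_COVAR
    last_err: Exception | None = None
    for attempt in range(4):
        gmm = BayesianGaussianMixture(
            n_components=k,
            covariance_type="full",
            weight_concentration_prior_type="dirichlet_process",
            weight_concentration_prior=1.0 / max_K,
            reg_covar=reg,
            tol=1e-5,
            max_iter=500,
            n_init=3,
            random_state=seed,
        )
        try:
            with warnings.catch_warnings():
                warnings.filterwarnings("ignore", message=".*did not converge.*")
                gmm.fit(scores)
            break
        except ValueError as err:  # rank-deficient scores
            last_err = err
            reg *= 1000.0
            warnings.warn(
                f"degenerate scores; refitting with reg_covar={reg:g}",
                stacklevel=2,
            )
    else:
        raise RuntimeError("cell mixture fit failed at maximal regularization") from last_err
    w = gmm.weights_ / gmm.weights_.sum()
    return CellGMM(
        weights=w, means=gmm.means_, covariances=gmm.covariances_, n_samples=n
    )


@dataclass
class ForwardModel:
    """Per-cell mixtures plus the shared feature transform."""

    grid: ParameterGrid
    cells: dict[tuple[int, int], CellGMM]
    transform: FeatureTransform | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for i, j, _, _ in self.grid.cells():
            if (i, j) not in self.cells:
                raise ValueError(f"forward model is missing grid cell {(i, j)}")

    @property
    def mean_effective_k(self) -> float:
        return float(np.mean([c.effective_k for c in self.cells.values()]))

    def log_likelihood(self, y: np.ndarray, g: tuple[float, float]) -> float:
        """Log density of one score under the mixture of an on-grid cell."""
        i, j = self.grid.index_of(*g)
        return float(self.cells[(i, j)].log_density(np.asarray(y, dtype=float)))

    def loglik_grid(self, y: np.ndarray) -> np.ndarray:
        """Log density of one score under every cell; shape (n_gi, n_gc)."""
        out = np.empty(self.grid.shape)
        for (i, j), gmm in self.cells.items():
            out[i, j] = gmm.log_density(np.asarray(y, dtype=float))
        return out


def build_forward_model(
    scores_by_cell: Mapping[tuple[int, int], np.ndarray],
    grid: ParameterGrid,
    max_K: int = DEFAULT_MAX_K,
    seed: int = 0,
    transform: FeatureTransform | None = None,
) -> ForwardModel:
    """Fit one cell mixture per grid cell (independent, order-invariant seeds)."""
    cells: dict[tuple[int, int], CellGMM] = {}
    n_cols = grid.shape[1]
    for i, j, _, _ in grid.cells():
        if (i, j) not in scores_by_cell:
            raise ValueError(f"no scores for grid cell {(i, j)}")
        cell_seed = derive_seed(seed, i * n_cols + j)
        cells[(i, j)] = fit_cell_gmm(
            scores_by_cell[(i, j)], max_K=max_K, seed=cell_seed
        )
    fm = ForwardModel(grid=grid, cells=cells, transform=transform)
    fm.metadata["mean_effective_k"] = fm.mean_effective_k
    return fm


def energy_test(
    sample_a: np.ndarray,
    sample_b: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    eps: float = 1e-12,
) -> tuple[float, float]:
    """Two-sample energy test with logarithmic kernel R(r) = -ln(r + eps).

    Returns the statistic and a permutation p-value
    ``(1 + #{perm >= observed}) / (n_perm + 1)``; deterministic under seed.
    """
    a = np.atleast_2d(np.asarray(sample_a, dtype=float))
    b = np.atleast_2d(np.asarray(sample_b, dtype=float))
    if len(a) < 10 or len(b) < 10:
        raise ValueError("each sample needs at least 10 points")
    pooled = np.vstack([a, b])
    n_a, n_b = len(a), len(b)
    n = n_a + n_b
    R = -np.log(cdist(pooled, pooled) + eps)
    np.fill_diagonal(R, 0.0)

    def _stat(mask: np.ndarray) -> float:
        za = mask.astype(float)
        zb = 1.0 - za
        within_a = 0.5 * (za @ R @ za)
        within_b = 0.5 * (zb @ R @ zb)
        cross = za @ R @ zb
        return float(within_a / n_a**2 + within_b / n_b**2 - cross / (n_a * n_b))

    obs_mask = np.zeros(n, dtype=bool)
    obs_mask[:n_a] = True
    obs = _stat(obs_mask)

    rng = np.random.default_rng(seed)
    masks = np.zeros((n_perm, n), dtype=float)
    for p in range(n_perm):
        perm = rng.permutation(n)
        masks[p, perm[:n_a]] = 1.0
    quad = np.einsum("pi,ij,pj->p", masks, R, masks)
    row = masks @ R.sum(axis=1)
    total = R.sum()
    within_a = 0.5 * quad
    within_b = 0.5 * (total - 2.0 * row + quad)
    cross = row - quad
    stats = within_a / n_a**2 + within_b / n_b**2 - cross / (n_a * n_b)
    p_value = (1.0 + np.sum(stats >= obs)) / (n_perm + 1.0)
    return obs, float(p_value)


# --- persistence ----------------------------------------------------------

def _transform_to_dict(tf: FeatureTransform) -> dict:
    pca = tf.pca
    return {
        "mi": tf.ranking.mi.tolist(),
        "order": tf.ranking.order.tolist(),
        "selected": tf.ranking.selected.tolist(),
        "mean": pca.mean.tolist(),
        "scale": pca.scale.tolist(),
        "loadings": pca.loadings.tolist(),
        "eigenvalues": pca.eigenvalues.tolist(),
        "n_components": pca.n_components,
        "kept_columns": pca.kept_columns.tolist(),
        "train_min": pca.train_min.tolist(),
        "train_max": pca.train_max.tolist(),
    }


def _transform_from_dict(d: dict) -> FeatureTransform:
    from .feature_space import MIRanking, PCAModel

    ranking = MIRanking(
        mi=np.asarray(d["mi"]),
        order=np.asarray(d["order"], dtype=int),
        selected=np.asarray(d["selected"], dtype=int),
    )
    pca = PCAModel(
        mean=np.asarray(d["mean"]),
        scale=np.asarray(d["scale"]),
        loadings=np.asarray(d["loadings"]),
        eigenvalues=np.asarray(d["eigenvalues"]),
        n_components=int(d["n_components"]),
        kept_columns=np.asarray(d["kept_columns"], dtype=int),
        train_min=np.asarray(d["train_min"]),
        train_max=np.asarray(d["train_max"]),
    )
    return FeatureTransform(ranking=ranking, pca=pca)


def save_forward_model(fm: ForwardModel, path: str | Path) -> None:
    """Serialize a forward model, including its feature transform, to JSON."""
    payload = {
        "gi_values": fm.grid.gi_values.tolist(),
        "gc_values": fm.grid.gc_values.tolist(),
        "step": fm.grid.step,
        "metadata": fm.metadata,
        "transform": _transform_to_dict(fm.transform) if fm.transform else None,
        "cells": {
            f"{i},{j}": {
                "weights": gmm.weights.tolist(),
                "means": gmm.means.tolist(),
                "covariances": gmm.covariances.tolist(),
                "n_samples": gmm.n_samples,
            }
            for (i, j), gmm in fm.cells.items()
        },
    }
    Path(path).write_text(json.dumps(payload))


def load_forward_model(path: str | Path) -> ForwardModel:
    payload = json.loads(Path(path).read_text())
    grid = ParameterGrid(
        gi_values=np.asarray(payload["gi_values"]),
        gc_values=np.asarray(payload["gc_values"]),
        step=payload["step"],
    )
    cells = {}
    for key, val in payload["cells"].items():
        i, j = (int(x) for x in key.split(","))
        cells[(i, j)] = CellGMM(
            weights=np.asarray(val["weights"]),
            means=np.asarray(val["means"]),
            covariances=np.asarray(val["covariances"]),
            n_samples=int(val.get("n_samples", 0)),
        )
    transform = (
        _transform_from_dict(payload["transform"]) if payload.get("transform") else None
    )
    return ForwardModel(
        grid=grid, cells=cells, transform=transform, metadata=payload.get("metadata", {})
    )
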