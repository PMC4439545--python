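"""Conductance estimation: segmental hierarchical Bayes, non-segmental
Bayes, and the minimum-score-error baseline.

All estimators work on a :class:`ConditionPair` (per-segment 3-D scores for
a control recording and a paired pharmacological recording) plus a forward
model.  A delta-function commonality prior ties the pharmacologically
unaffected conductance to control exactly: the PIX pairing shares g_c, the
CBX pairing shares g_i, so the constrained neuron-level lattice has three
free axes.  The segmental estimator additionally lets segment-level
parameters jitter around the neuron-level values with axis-wise discrete
Gaussian priors whose standard deviations (sigma1, sigma2, sigma3) are
chosen by exhaustive evidence maximization on a sigma lattice.

All accumulation is carried out in log space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import logsumexp

from .forward_model import ForwardModel
from .surrogate_sim import ParameterGrid

#: default sigma search lattice: {0, 0.025, ..., 0.5}
DEFAULT_SIGMA_LATTICE = tuple(np.round(np.arange(0.0, 0.5 + 1e-9, 0.025), 3))

PHA_LABELS = ("PIX", "CBX")


@dataclass(frozen=True)
class ConditionPair:
    """Per-segment scores of one neuron under control and one drug condition."""

    y_con: np.ndarray  # (T, d)
    y_pha: np.ndarray  # (T, d)
    pha_label: str

    def __post_init__(self) -> None:
        yc = np.atleast_2d(np.asarray(self.y_con, dtype=float))
        yp = np.atleast_2d(np.asarray(self.y_pha, dtype=float))
        object.__setattr__(self, "y_con", yc)
        object.__setattr__(self, "y_pha", yp)
        if yc.shape != yp.shape:
            raise ValueError("control and drug conditions must share T and d")
        if self.pha_label not in PHA_LABELS:
            raise ValueError(f"pha_label must be one of {PHA_LABELS}")

    @property
    def n_segments(self) -> int:
        return self.y_con.shape[0]


@dataclass(frozen=True)
class HyperParams:
    """Segment-level prior standard deviations (conductance units)."""

    s1: float
    s2: float
    s3: float

    def __post_init__(self) -> None:
        if min(self.s1, self.s2, self.s3) < 0:
            raise ValueError("sigma values must be >= 0")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.s1, self.s2, self.s3)


@dataclass(frozen=True)
class LikelihoodTable:
    """Per-segment log-likelihood over all grid cells, both conditions."""

    log_con: np.ndarray  # (T, n_gi, n_gc)
    log_pha: np.ndarray  # (T, n_gi, n_gc)
    pha_label: str
    grid: ParameterGrid

    @property
    def n_segments(self) -> int:
        return self.log_con.shape[0]


@dataclass(frozen=True)
class PosteriorMap:
    """Discrete joint posterior over the constrained neuron-level lattice.

    Axes are (gi_con, gi_pha, gc_shared) for the PIX pairing and
    (gi_shared, gc_con, gc_pha) for the CBX pairing; C-order argmax then
    realizes the smallest-g_i / smallest-g_c / condition-order tie-break.
    """

    axes: tuple[str, str, str]
    axis_values: tuple[np.ndarray, np.ndarray, np.ndarray]
    prob: np.ndarray
    evidence: float
    pha_label: str

    def __post_init__(self) -> None:
        p = np.asarray(self.prob, dtype=float)
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("posterior probabilities must be >= 0 and sum to 1")

    @property
    def map_index(self) -> tuple[int, int, int]:
        idx = np.unravel_index(int(np.argmax(self.prob)), self.prob.shape)
        return tuple(int(i) for i in idx)  # type: ignore[return-value]

    @property
    def map_params(self) -> dict[str, float]:
        """MAP conductances per condition; commonality holds exactly."""
        a, b, c = self.map_index
        v = self.axis_values
        if self.pha_label == "PIX":
            return {
                "gi_con": float(v[0][a]),
                "gi_pha": float(v[1][b]),
                "gc_con": float(v[2][c]),
                "gc_pha": float(v[2][c]),
            }
        return {
            "gi_con": float(v[0][a]),
            "gi_pha": float(v[0][a]),
            "gc_con": float(v[1][b]),
            "gc_pha": float(v[2][c]),
        }


@dataclass(frozen=True)
class EstimateResult:
    """Outcome of one estimator run on one neuron's condition pair."""

    method: str
    con: tuple[float, float]  # (g_i, g_c) under control
    pha: tuple[float, float]  # (g_i, g_c) under the drug
    pha_label: str
    hyperparams: HyperParams | None = None
    evidence: float | None = None
    posterior: PosteriorMap | None = None
    diagnostics: dict = field(default_factory=dict)


# --- likelihood assembly --------------------------------------------------

def segment_likelihood_table(pair: ConditionPair, fm: ForwardModel) -> LikelihoodTable:
    """Evaluate every segment score under every grid cell's mixture."""
    log_con = np.stack([fm.loglik_grid(y) for y in pair.y_con])
    log_pha = np.stack([fm.loglik_grid(y) for y in pair.y_pha])
    return LikelihoodTable(
        log_con=log_con, log_pha=log_pha, pha_label=pair.pha_label, grid=fm.grid
    )


# --- hierarchical prior ---------------------------------------------------

def _axis_weights(values: np.ndarray, sigma: float) -> np.ndarray:
    """Discrete Gaussian weights W[s, n] = P(segment value s | neuron value n).

    Columns are normalized to sum 1; sigma 0 degenerates to a point mass
    (the identity), which keeps the sigma->0 reduction bit-exact.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return np.eye(values.size)
    d = values[:, None] - values[None, :]
    w = np.exp(-0.5 * (d / sigma) ** 2)
    return w / w.sum(axis=0, keepdims=True)


def condition_sigmas(
    hp: HyperParams, pha_label: str
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Map (sigma1, sigma2, sigma3) onto the (g_i, g_c) axes per condition.

    PIX pairing: control (sigma1, sigma2), drug (sigma3, sigma2) - the
    shared-g_c axes share sigma2.  CBX pairing: control (sigma1, sigma2),
    drug (sigma1, sigma3) - the shared-g_i axes share sigma1.
    """
    if pha_label == "PIX":
        return (hp.s1, hp.s2), (hp.s3, hp.s2)
    if pha_label == "CBX":
        return (hp.s1, hp.s2), (hp.s1, hp.s3)
    raise ValueError(f"unknown pha label {pha_label!r}")


def hierarchical_prior(
    grid: ParameterGrid,
    neuron_g: tuple[float, float],
    sigma_gi: float,
    sigma_gc: float,
) -> np.ndarray:
    """Joint prior over segment-level grid cells around one neuron-level cell.

    Product of the two axis-wise discrete Gaussians; sums to 1.
    """
    i, j = grid.index_of(*neuron_g)
    w_i = _axis_weights(grid.gi_values, sigma_gi)[:, i]
    w_c = _axis_weights(grid.gc_values, sigma_gc)[:, j]
    return np.outer(w_i, w_c)


def _integrated_log_table(
    log_table: np.ndarray, gi_values: np.ndarray, gc_values: np.ndarray,
    sigma_gi: float, sigma_gc: float,
) -> np.ndarray:
    """Per-segment log of (likelihood integrated under the segment prior).

    Input and output have shape (T, n_gi, n_gc); the output is indexed by
    the neuron-level cell.  With both sigmas zero the input is returned
    unchanged (point-mass prior), preserving bit-exact reduction.
    """
    if sigma_gi == 0 and sigma_gc == 0:
        return log_table
    w_i = _axis_weights(gi_values, sigma_gi)
    w_c = _axis_weights(gc_values, sigma_gc)
    out = np.empty_like(log_table)
    for t in range(log_table.shape[0]):
        m = np.max(log_table[t])
        if not np.isfinite(m):
            out[t] = m
            continue
        a = np.exp(log_table[t] - m)
        integrated = w_i.T @ a @ w_c
        with np.errstate(divide="ignore"):
            out[t] = np.log(integrated) + m
    return out


def integrate_segment_likelihood(
    table: LikelihoodTable,
    neuron_g: tuple[float, float, float, float],
    hp: HyperParams,
) -> float:
    """Log joint likelihood of all segments given one neuron-level parameter set.

    ``neuron_g`` is (gi_con, gc_con, gi_pha, gc_pha); segment-level cells
    are summed out under the hierarchical prior, then log-likelihoods are
    accumulated across segments and conditions.
    """
    (sc_i, sc_c), (sp_i, sp_c) = condition_sigmas(hp, table.pha_label)
    gi_con, gc_con, gi_pha, gc_pha = neuron_g
    total = 0.0
    for log_tab, g, sigmas in (
        (table.log_con, (gi_con, gc_con), (sc_i, sc_c)),
        (table.log_pha, (gi_pha, gc_pha), (sp_i, sp_c)),
    ):
        prior = hierarchical_prior(table.grid, g, *sigmas)
        with np.errstate(divide="ignore"):
            log_prior = np.log(prior)
        for t in range(log_tab.shape[0]):
            total += float(logsumexp(log_tab[t] + log_prior))
    return total


# --- posterior ------------------------------------------------------------

def _condition_sums(
    table: LikelihoodTable, hp: HyperParams
) -> tuple[np.ndarray, np.ndarray]:
    """Sum the integrated per-segment log tables over segments per condition."""
    (sc_i, sc_c), (sp_i, sp_c) = condition_sigmas(hp, table.pha_label)
    gi, gc = table.grid.gi_values, table.grid.gc_values
    s_con = _integrated_log_table(table.log_con, gi, gc, sc_i, sc_c).sum(axis=0)
    s_pha = _integrated_log_table(table.log_pha, gi, gc, sp_i, sp_c).sum(axis=0)
    return s_con, s_pha


def _combine(
    s_con: np.ndarray, s_pha: np.ndarray, pha_label: str, grid: ParameterGrid
) -> PosteriorMap:
    """Combine per-condition summed log-likelihoods on the constrained lattice."""
    gi, gc = grid.gi_values, grid.gc_values
    if pha_label == "PIX":
        ll = s_con[:, None, :] + s_pha[None, :, :]  # (gi_con, gi_pha, gc)
        axes = ("gi_con", "gi_pha", "gc_shared")
        axis_values = (gi, gi, gc)
    else:
        ll = s_con[:, :, None] + s_pha[:, None, :]  # (gi, gc_con, gc_pha)
        axes = ("gi_shared", "gc_con", "gc_pha")
        axis_values = (gi, gc, gc)
    log_z = float(logsumexp(ll))
    if not np.isfinite(log_z):
        raise ValueError("likelihood is zero everywhere; model cannot explain data")
    evidence = log_z - np.log(ll.size)  # uniform P0 over the constrained lattice
    prob = np.exp(ll - log_z)
    prob = prob / prob.sum()
    return PosteriorMap(
        axes=axes,
        axis_values=axis_values,
        prob=prob,
        evidence=evidence,
        pha_label=pha_label,
    )


def posterior_and_evidence(table: LikelihoodTable, hp: HyperParams) -> PosteriorMap:
    """Posterior over the constrained lattice for fixed hyperparameters."""
    s_con, s_pha = _condition_sums(table, hp)
    return _combine(s_con, s_pha, table.pha_label, table.grid)


def _evidence_only(
    s_con: np.ndarray, s_pha: np.ndarray, pha_label: str
) -> float:
    """Model evidence without materializing the 3-D lattice."""
    if pha_label == "PIX":
        u = logsumexp(s_con, axis=0)  # over gi_con -> (n_gc,)
        v = logsumexp(s_pha, axis=0)  # over gi_pha -> (n_gc,)
        log_z = float(logsumexp(u + v))
        n = s_con.shape[0] * s_pha.shape[0] * s_con.shape[1]
    else:
        u = logsumexp(s_con, axis=1)  # over gc_con -> (n_gi,)
        v = logsumexp(s_pha, axis=1)  # over gc_pha -> (n_gi,)
        log_z = float(logsumexp(u + v))
        n = s_con.shape[0] * s_con.shape[1] * s_pha.shape[1]
    return log_z - np.log(n)


def optimize_hyperparams(
    table: LikelihoodTable,
    sigma_lattice: Sequence[float] = DEFAULT_SIGMA_LATTICE,
) -> tuple[HyperParams, PosteriorMap]:
    """Exhaustive evidence maximization over the (sigma1, sigma2, sigma3) lattice.

    Ties break toward lexicographically smaller (sigma1, sigma2, sigma3).
    """
    sigmas = sorted(float(s) for s in sigma_lattice)
    if not sigmas:
        raise ValueError("sigma lattice must be non-empty")
    gi, gc = table.grid.gi_values, table.grid.gc_values
    pha = table.pha_label

    # cache the summed integrated tables per (sigma_gi, sigma_gc) pair
    con_cache: dict[tuple[float, float], np.ndarray] = {}
    pha_cache: dict[tuple[float, float], np.ndarray] = {}

    def _sum(log_tab: np.ndarray, key: tuple[float, float], cache: dict) -> np.ndarray:
        if key not in cache:
            cache[key] = _integrated_log_table(log_tab, gi, gc, *key).sum(axis=0)
        return cache[key]

    best: tuple[float, HyperParams] | None = None
    for s1 in sigmas:
        for s2 in sigmas:
            for s3 in sigmas:
                hp = HyperParams(s1, s2, s3)
                (c_i, c_c), (p_i, p_c) = condition_sigmas(hp, pha)
                s_con = _sum(table.log_con, (c_i, c_c), con_cache)
                s_pha = _sum(table.log_pha, (p_i, p_c), pha_cache)
                ev = _evidence_only(s_con, s_pha, pha)
                if best is None or ev > best[0]:
                    best = (ev, hp)
    assert best is not None
    hp = best[1]
    return hp, posterior_and_evidence(table, hp)


# --- estimators -----------------------------------------------------------

def _result_from_posterior(
    method: str, post: PosteriorMap, hp: HyperParams | None, diagnostics: dict
) -> EstimateResult:
    p = post.map_params
    return EstimateResult(
        method=method,
        con=(p["gi_con"], p["gc_con"]),
        pha=(p["gi_pha"], p["gc_pha"]),
        pha_label=post.pha_label,
        hyperparams=hp,
        evidence=post.evidence,
        posterior=post,
        diagnostics=diagnostics,
    )


def _segment_map_trajectory(table: LikelihoodTable) -> dict[str, list]:
    """Per-segment unconstrained MAP cells, kept for diagnostics."""
    out: dict[str, list] = {"con": [], "pha": []}
    for name, tab in (("con", table.log_con), ("pha", table.log_pha)):
        for t in range(tab.shape[0]):
            i, j = np.unravel_index(int(np.argmax(tab[t])), tab[t].shape)
            out[name].append(
                (float(table.grid.gi_values[i]), float(table.grid.gc_values[j]))
            )
    return out


def estimate_segmental(
    pair: ConditionPair,
    fm: ForwardModel,
    sigma_lattice: Sequence[float] = DEFAULT_SIGMA_LATTICE,
) -> EstimateResult:
    """Segmental hierarchical Bayes: evidence-optimized sigma, then MAP."""
    table = segment_likelihood_table(pair, fm)
    hp, post = optimize_hyperparams(table, sigma_lattice)
    diag = {"segment_map": _segment_map_trajectory(table)}
    return _result_from_posterior("segmental", post, hp, diag)


def estimate_non_segmental(pair: ConditionPair, fm: ForwardModel) -> EstimateResult:
    """Non-segmental Bayes: product-over-segments likelihood, no jitter prior."""
    table = segment_likelihood_table(pair, fm)
    s_con = table.log_con.sum(axis=0)
    s_pha = table.log_pha.sum(axis=0)
    post = _combine(s_con, s_pha, table.pha_label, table.grid)
    return _result_from_posterior("non_segmental", post, None, {})


def estimate_min_error(
    pair: ConditionPair,
    sim_scores_by_cell: Mapping[tuple[int, int], np.ndarray],
    grid: ParameterGrid,
) -> EstimateResult:
    """Minimum-score-error baseline.

    Per segment and condition, pick the cell whose nearest simulated score
    is closest (ties to smaller g_i then g_c); aggregate per condition as
    the mode over segments with the same tie-break.
    """
    cells = [(i, j) for i, j, _, _ in grid.cells()]  # lexicographic (gi, gc)
    per_condition: dict[str, tuple[float, float]] = {}
    diag: dict[str, list] = {}
    for name, ys in (("con", pair.y_con), ("pha", pair.y_pha)):
        chosen: list[tuple[int, int]] = []
        for y in ys:
            best_cell, best_d = None, np.inf
            for cell in cells:
                pts = np.atleast_2d(sim_scores_by_cell[cell])
                d = float(np.min(np.linalg.norm(pts - y, axis=1)))
                if d < best_d - 1e-12:
                    best_cell, best_d = cell, d
            chosen.append(best_cell)  # type: ignore[arg-type]
        counts: dict[tuple[int, int], int] = {}
        for cell in chosen:
            counts[cell] = counts.get(cell, 0) + 1
        mode_cell = min(counts, key=lambda c: (-counts[c], c))
        per_condition[name] = (
            float(grid.gi_values[mode_cell[0]]),
            float(grid.gc_values[mode_cell[1]]),
        )
        diag[f"segment_cells_{name}"] = [
            (float(grid.gi_values[i]), float(grid.gc_values[j])) for i, j in chosen
        ]
    return EstimateResult(
        method="min_error",
        con=per_condition["con"],
        pha=per_condition["pha"],
        pha_label=pair.pha_label,
        diagnostics=diag,
    )


def pca_error_rate(
    est: EstimateResult,
    pair: ConditionPair,
    sim_scores_by_cell: Mapping[tuple[int, int], np.ndarray],
    grid: ParameterGrid,
) -> float:
    """Mean distance between data segments and the estimated cell's scores.

    For each condition the estimated (g_i, g_c) selects a grid cell; the
    error is the mean over segments of the distance to the nearest simulated
    score in that cell, averaged over the two conditions.
    """
    errors = []
    for g, ys in ((est.con, pair.y_con), (est.pha, pair.y_pha)):
        cell = grid.index_of(*g)
        pts = np.atleast_2d(sim_scores_by_cell[cell])
        for y in ys:
            errors.append(float(np.min(np.linalg.norm(pts - y, axis=1))))
    return float(np.mean(errors))
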