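"""Steady-state flux sampling: corner-based and artificial-centering hit-and-run.

Corner-based sampling (CBS) draws a random linear objective — each
coefficient i.i.d. uniform on [-1, 1] by default — and records the
optimal vertex of the flux polytope, repeating per requested sample;
the result concentrates on the polytope's corners and is embarrassingly
reproducible (the seed fixes the objective stream).

The hit-and-run sampler is a single-chain artificial-centering walk:
warmup points are the 2n flux-variability extreme solutions at
fraction 0; directions are drawn as (random stored point - running
center), so every step stays inside the steady-state null space; the
step length is uniform on the feasible chord; every ``thinning``-th
point is kept.  The walk is periodically re-projected onto the null
space of S to stop round-off drift.

Both samplers require a bounded feasible region (checked via FVA at
fraction 0) and guarantee that every returned row satisfies
``max|S·v| <= 1e-6`` and the bounds to the same tolerance.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .flux_core import LPProblem, STEADY_STATE_TOL, _solve, fva

__all__ = [
    "sample_cbs",
    "sample_hit_and_run",
    "summarize_fluxes",
    "batch_samples",
    "validate_frame",
]

_BOUND_TOL = 1e-6
_REPROJECT_EVERY = 100


class UnboundedRegionError(RuntimeError):
    pass


def _check_bounded(problem: LPProblem) -> dict[str, tuple[float, float]]:
    ranges = fva(problem, fraction_of_optimum=0.0)
    bad = [r for r, (lo, hi) in ranges.items() if not (np.isfinite(lo) and np.isfinite(hi))]
    if bad or not np.all(np.isfinite(problem.lower)) or not np.all(np.isfinite(problem.upper)):
        raise UnboundedRegionError(
            "feasible region is unbounded in some direction; close open "
            f"exchange bounds before sampling (reactions: {bad})"
        )
    return ranges


def _frame(points: np.ndarray, problem: LPProblem, provenance: str, seed: int) -> pd.DataFrame:
    frame = pd.DataFrame(
        points,
        columns=problem.reaction_ids,
        index=[f"{provenance}_{i}" for i in range(len(points))],
    )
    frame.attrs["provenance"] = provenance
    frame.attrs["seed"] = int(seed)
    return frame


def sample_cbs(problem: LPProblem, n_samples: int, seed: int,
               dist: str = "uniform") -> pd.DataFrame:
    """Corner-based sampling: one optimal vertex per random objective.

    ``dist`` selects the cost-coefficient distribution: ``"uniform"``
    (i.i.d. on [-1, 1], the default) or ``"normal"`` (standard normal).
    Identical seeds give identical frames.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    _check_bounded(problem)
    rng = np.random.default_rng(seed)
    n = problem.n_reactions
    points = np.empty((n_samples, n))
    for i in range(n_samples):
        if dist == "uniform":
            c = rng.uniform(-1.0, 1.0, size=n)
        elif dist == "normal":
            c = rng.standard_normal(n)
        else:
            raise ValueError(f"unknown CBS objective distribution {dist!r}")
        res = _solve(-c, problem)  # maximize c·v
        if res.status != 0:
            raise RuntimeError(f"CBS draw {i} failed with solver status {res.status}")
        points[i] = res.x
    return _frame(points, problem, "cbs", seed)


def _null_space_projector(S: np.ndarray) -> np.ndarray:
    """Orthogonal projector onto ker(S) (used to undo numerical drift)."""
    if S.shape[0] == 0:
        return np.eye(S.shape[1])
    pinv = np.linalg.pinv(S)
    return np.eye(S.shape[1]) - pinv @ S


def sample_hit_and_run(problem: LPProblem, n_samples: int,
                       thinning: int = 100, seed: int = 0) -> pd.DataFrame:
    """Artificial-centering hit-and-run over the steady-state polytope.

    Warmup points are all FVA-extreme solutions at fraction 0; the chain
    starts at their centroid, draws directions toward randomly chosen
    stored points relative to the running center, and keeps every
    ``thinning``-th step until ``n_samples`` rows are collected.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if thinning < 1:
        raise ValueError("thinning must be >= 1")
    _check_bounded(problem)
    _, warmup = fva(problem, fraction_of_optimum=0.0, return_vectors=True)
    warmup_arr = np.unique(np.round(np.array(warmup), 12), axis=0)
    rng = np.random.default_rng(seed)
    projector = _null_space_projector(problem.S)
    lower, upper = problem.lower, problem.upper

    store = list(warmup_arr)
    center = warmup_arr.mean(axis=0)
    x = center.copy()
    kept = np.empty((n_samples, problem.n_reactions))
    n_kept = 0
    step = 0
    max_steps = max(10_000, 50 * thinning * n_samples)
    while n_kept < n_samples:
        step += 1
        if step > max_steps:
            raise RuntimeError("hit-and-run failed to collect enough samples")
        ref = store[rng.integers(len(store))]
        # project the direction onto ker(S): round-off in stored points
        # would otherwise be amplified by normalization + long chords
        d = projector @ (ref - center)
        norm = np.linalg.norm(d)
        if norm < 1e-10:
            continue
        d = d / norm
        # feasible chord: lb <= x + a*d <= ub per coordinate
        with np.errstate(divide="ignore"):
            lo_dist = np.where(np.abs(d) > 1e-12, (lower - x) / d, -np.inf)
            hi_dist = np.where(np.abs(d) > 1e-12, (upper - x) / d, np.inf)
        a_min = np.max(np.minimum(lo_dist, hi_dist))
        a_max = np.min(np.maximum(lo_dist, hi_dist))
        if a_max <= a_min:
            continue
        x = x + rng.uniform(a_min, a_max) * d
        if step % _REPROJECT_EVERY == 0:
            x = np.clip(projector @ x, lower, upper)
        center = center + (x - center) / (len(store) + 1)
        store.append(x.copy())
        if step % thinning == 0:
            kept[n_kept] = x
            n_kept += 1
    return _frame(kept, problem, "hit_and_run", seed)


def summarize_fluxes(frame: pd.DataFrame,
                     quantiles: Sequence[float] = (0.25, 0.75)) -> pd.DataFrame:
    """Per-reaction mean, median, and requested quantiles of a flux frame."""
    if frame.empty:
        raise ValueError("flux frame is empty")
    out = pd.DataFrame(index=frame.columns)
    out.index.name = "reaction_id"
    out["mean"] = frame.mean(axis=0)
    out["median"] = frame.median(axis=0)
    for q in quantiles:
        if not 0.0 <= q <= 1.0:
            raise ValueError(f"quantile {q} outside [0, 1]")
        out[f"q{q:g}"] = frame.quantile(q, axis=0)
    return out


def batch_samples(problem: LPProblem, n_samples: int, n_batches: int,
                  seed: int, method: str = "cbs",
                  thinning: int = 100) -> list[pd.DataFrame]:
    """Split sampling into batches; batch ``i`` runs with seed ``seed + i``.

    Batch sizes differ by at most one and concatenate to exactly
    ``n_samples`` rows; a single batch reproduces the direct call.
    """
    if n_batches < 1:
        raise ValueError("n_batches must be >= 1")
    if n_samples < n_batches:
        raise ValueError("need at least one sample per batch")
    base, rem = divmod(n_samples, n_batches)
    sizes = [base + (1 if i < rem else 0) for i in range(n_batches)]
    frames = []
    for i, size in enumerate(sizes):
        if method == "cbs":
            frames.append(sample_cbs(problem, size, seed + i))
        elif method in ("hr", "hit_and_run"):
            frames.append(sample_hit_and_run(problem, size, thinning=thinning, seed=seed + i))
        else:
            raise ValueError(f"unknown sampling method {method!r}")
    return frames


def validate_frame(problem: LPProblem, frame: pd.DataFrame,
                   tol: float = STEADY_STATE_TOL) -> bool:
    """True iff every row satisfies steady state and bounds within ``tol``."""
    points = frame[problem.reaction_ids].to_numpy(dtype=float)
    if problem.S.shape[0]:
        if np.max(np.abs(problem.S @ points.T)) > tol:
            return False
    if (points < problem.lower - tol).any() or (points > problem.upper + tol).any():
        return False
    return True
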