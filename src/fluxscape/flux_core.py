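"""Linear-programming backbone: FBA, parsimonious FBA, FVA, reaction deletion.

All routines operate on an :class:`LPProblem` — the steady-state flux
polytope ``{v : S·v = 0, lb <= v <= ub}`` with a linear objective — and
solve with scipy's HiGHS interface.  Contract tolerances: optimal flux
vectors satisfy ``max|S·v| <= 1e-6`` and respect bounds to the same
tolerance (the solver itself works at 1e-9); optimum-fraction
constraints are applied as ``>= (1 - 1e-9) * fraction * optimum`` to
absorb round-off.

Infeasible or unbounded problems are reported through
:attr:`FluxVector.status`, never as exceptions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import linprog

from .bounds import BoundsSet
from .model_io import ModelStruct

__all__ = [
    "LPProblem",
    "FluxVector",
    "build_lp",
    "fba",
    "pfba",
    "fva",
    "single_reaction_deletion",
]

STEADY_STATE_TOL = 1e-6
_OPT_SLACK = 1e-9


@dataclass
class LPProblem:
    """Stoichiometric LP: maximize (or minimize) ``c·v`` s.t. ``S·v = 0``, bounds."""

    S: np.ndarray            # metabolites x reactions
    lower: np.ndarray        # per-reaction lower bounds
    upper: np.ndarray        # per-reaction upper bounds
    c: np.ndarray            # objective coefficients
    reaction_ids: list[str]
    metabolite_ids: list[str] = field(default_factory=list)
    sense: str = "max"

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        self.c = np.asarray(self.c, dtype=float)
        n = self.S.shape[1]
        if not (len(self.lower) == len(self.upper) == len(self.c) == n == len(self.reaction_ids)):
            raise ValueError("inconsistent LP dimensions")
        if (self.lower > self.upper).any():
            bad = self.reaction_ids[int(np.argmax(self.lower > self.upper))]
            raise ValueError(f"reaction {bad!r}: lower bound exceeds upper bound")
        if self.sense not in ("max", "min"):
            raise ValueError("sense must be 'max' or 'min'")

    @property
    def n_reactions(self) -> int:
        return self.S.shape[1]

    def with_bounds(self, rxn_id: str, lo: float, hi: float) -> "LPProblem":
        idx = self.reaction_ids.index(rxn_id)
        lower, upper = self.lower.copy(), self.upper.copy()
        lower[idx], upper[idx] = lo, hi
        return LPProblem(self.S, lower, upper, self.c, list(self.reaction_ids),
                         list(self.metabolite_ids), self.sense)


@dataclass
class FluxVector:
    """One flux distribution with its objective value and solver status."""

    label: str
    values: dict[str, float]
    objective_value: float
    status: str  # optimal | infeasible | unbounded

    def as_array(self, reaction_ids: list[str]) -> np.ndarray:
        return np.array([self.values[r] for r in reaction_ids])


def build_lp(model: ModelStruct, bounds: Optional[BoundsSet] = None) -> LPProblem:
    """Assemble the steady-state LP from a model and optional per-sample bounds."""
    rxn_ids = [r.id for r in model.reactions]
    met_ids = [m for m, _ in model.metabolites]
    met_index = {m: i for i, m in enumerate(met_ids)}
    rxn_index = {r: j for j, r in enumerate(rxn_ids)}
    S = np.zeros((len(met_ids), len(rxn_ids)))
    for (m, r), coeff in model.stoichiometry.items():
        S[met_index[m], rxn_index[r]] = coeff
    if bounds is not None:
        lower = np.array([bounds.bounds[r][0] for r in rxn_ids])
        upper = np.array([bounds.bounds[r][1] for r in rxn_ids])
    else:
        lower = np.array([r.lower_bound for r in model.reactions])
        upper = np.array([r.upper_bound for r in model.reactions])
    c = np.zeros(len(rxn_ids))
    for r, coeff in model.objective.items():
        c[rxn_index[r]] = coeff
    return LPProblem(S, lower, upper, c, rxn_ids, met_ids)


_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded", 4: "numerical"}


def _solve(c_min: np.ndarray, problem: LPProblem,
           A_ub=None, b_ub=None):
    """Minimize ``c_min·v`` over the problem's polytope (raw scipy result)."""
    return linprog(
        c_min,
        A_eq=problem.S if problem.S.shape[0] else None,
        b_eq=np.zeros(problem.S.shape[0]) if problem.S.shape[0] else None,
        A_ub=A_ub,
        b_ub=b_ub,
        bounds=list(zip(problem.lower, problem.upper)),
        method="highs",
    )


def _to_flux_vector(problem: LPProblem, res, label: str) -> FluxVector:
    status = _STATUS.get(res.status, "numerical")
    if status != "optimal":
        return FluxVector(label, {r: np.nan for r in problem.reaction_ids},
                          np.nan, status)
    v = np.asarray(res.x)
    obj = float(problem.c @ v)
    return FluxVector(label, dict(zip(problem.reaction_ids, map(float, v))), obj, "optimal")


def fba(problem: LPProblem, label: str = "fba") -> FluxVector:
    """Flux balance analysis: optimize ``c·v`` over the steady-state polytope."""
    sign = -1.0 if problem.sense == "max" else 1.0
    res = _solve(sign * problem.c, problem)
    return _to_flux_vector(problem, res, label)


def _optimum_row(problem: LPProblem, optimum: float, fraction: float):
    """Inequality keeping the objective at >= fraction of its optimum.

    For maximization: ``c·v >= f·opt`` i.e. ``-c·v <= -f·opt``; signs flip
    for minimization.  A tiny slack absorbs solver round-off.
    """
    target = fraction * optimum
    slack = _OPT_SLACK * max(1.0, abs(optimum))
    if problem.sense == "max":
        return -problem.c[None, :], np.array([-(target - slack)])
    return problem.c[None, :], np.array([target + slack])


def pfba(problem: LPProblem, fraction_of_optimum: float = 1.0,
         label: str = "pfba") -> FluxVector:
    """Parsimonious FBA: minimize total absolute flux at (near-)optimal objective.

    Each flux splits into non-negative forward and reverse parts
    (``v = v+ - v-``); the sum of parts is minimized subject to the
    original constraints plus ``c·v >= fraction * optimum``.  The
    reported ``objective_value`` is the original objective's value at
    the parsimonious solution.
    """
    if not 0.0 < fraction_of_optimum <= 1.0:
        raise ValueError("fraction_of_optimum must be in (0, 1]")
    base = fba(problem)
    if base.status != "optimal":
        return FluxVector(label, base.values, np.nan, base.status)
    n = problem.n_reactions
    m = problem.S.shape[0]
    # variables: [v+, v-], v = v+ - v-; part bounds chosen so that the
    # difference spans exactly [lb, ub] even when 0 is outside the range
    S2 = np.hstack([problem.S, -problem.S])
    lb2 = np.concatenate([np.maximum(problem.lower, 0.0),
                          np.maximum(-problem.upper, 0.0)])
    ub2 = np.concatenate([np.maximum(problem.upper, 0.0),
                          np.maximum(-problem.lower, 0.0)])
    c_min = np.ones(2 * n)
    row, rhs = _optimum_row(problem, base.objective_value, fraction_of_optimum)
    A_ub = np.hstack([row, -row])
    res = linprog(
        c_min,
        A_eq=S2 if m else None,
        b_eq=np.zeros(m) if m else None,
        A_ub=A_ub,
        b_ub=rhs,
        bounds=list(zip(lb2, ub2)),
        method="highs",
    )
    status = _STATUS.get(res.status, "numerical")
    if status != "optimal":
        return FluxVector(label, {r: np.nan for r in problem.reaction_ids}, np.nan, status)
    v = np.asarray(res.x[:n]) - np.asarray(res.x[n:])
    # clip split-variable round-off back inside the original bounds
    v = np.clip(v, problem.lower, problem.upper)
    obj = float(problem.c @ v)
    return FluxVector(label, dict(zip(problem.reaction_ids, map(float, v))), obj, "optimal")


def fva(problem: LPProblem, fraction_of_optimum: float = 1.0,
        return_vectors: bool = False):
    """Flux variability analysis: per-reaction min/max at constrained optimum.

    Returns ``{reaction_id: (min, max)}``; reactions whose sub-problem
    fails to solve map to ``(nan, nan)``.  With ``return_vectors`` the
    2n extreme flux vectors are returned as well (used as sampler
    warmup points).
    """
    if not 0.0 <= fraction_of_optimum <= 1.0:
        raise ValueError("fraction_of_optimum must be in [0, 1]")
    A_ub = b_ub = None
    if fraction_of_optimum > 0:
        base = fba(problem)
        if base.status != "optimal":
            raise RuntimeError(f"FVA requires an optimal base solution, got {base.status}")
        A_ub, b_ub = _optimum_row(problem, base.objective_value, fraction_of_optimum)
    ranges: dict[str, tuple[float, float]] = {}
    vectors: list[np.ndarray] = []
    n = problem.n_reactions
    for j, rid in enumerate(problem.reaction_ids):
        cj = np.zeros(n)
        cj[j] = 1.0
        lo_hi = []
        for sign in (1.0, -1.0):
            res = _solve(sign * cj, problem, A_ub=A_ub, b_ub=b_ub)
            if res.status != 0:
                lo_hi.append(np.nan)
                continue
            lo_hi.append(float(res.x[j]))
            if return_vectors:
                vectors.append(np.asarray(res.x, dtype=float))
        ranges[rid] = (lo_hi[0], lo_hi[1])
    if return_vectors:
        return ranges, vectors
    return ranges


def single_reaction_deletion(problem: LPProblem) -> dict[str, dict]:
    """Objective value after knocking out each reaction in turn.

    Each reaction's bounds are forced to (0, 0) and the LP re-solved.
    Infeasible knockouts report objective 0.0 with ``status
    "infeasible"``; others report the re-optimized objective.
    """
    out: dict[str, dict] = {}
    n = problem.n_reactions
    sign = -1.0 if problem.sense == "max" else 1.0
    for j, rid in enumerate(problem.reaction_ids):
        lower, upper = problem.lower.copy(), problem.upper.copy()
        lower[j] = upper[j] = 0.0
        res = linprog(
            sign * problem.c,
            A_eq=problem.S if problem.S.shape[0] else None,
            b_eq=np.zeros(problem.S.shape[0]) if problem.S.shape[0] else None,
            bounds=list(zip(lower, upper)),
            method="highs",
        )
        status = _STATUS.get(res.status, "numerical")
        if status == "optimal":
            out[rid] = {"objective": float(problem.c @ res.x), "status": "optimal"}
        else:
            out[rid] = {"objective": 0.0, "status": status}
    return out


def steady_state_residual(problem: LPProblem, flux: FluxVector) -> float:
    """``max|S·v|`` for a flux vector (contract: <= 1e-6 when optimal)."""
    v = flux.as_array(problem.reaction_ids)
    if problem.S.shape[0] == 0:
        return 0.0
    return float(np.max(np.abs(problem.S @ v)))
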