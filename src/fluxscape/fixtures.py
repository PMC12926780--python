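"""Deterministic toy fixtures: models, maps, expression data, planted effects.

Everything any pipeline stage needs can be generated here at toy scale
(<= 20 reactions, <= 10 genes, 2-3 groups) with a seed: linear
chain/parallel-route models with exchange reactions and GPR rules, a
matching minimal SVG map (one ``<path>`` per reaction, ids
``R_{reaction_id}``), medium tables, and expression matrices with
multiplicative lognormal noise and planted group effects on chosen
genes.

Expression noise is lognormal with a configurable coefficient of
variation (default 0.2) and mean-corrected so the expectation equals
``baseline_mean x planted factor`` exactly; the ground-truth table of
expected RAS shifts is derived *symbolically* from the GPR structure
(sum/min over expected expression values), independent of the RAS code
under test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .bounds import Medium
from .gpr import eval_ras, parse_gpr
from .model_io import ModelStruct, ReactionRec

__all__ = [
    "ToySpec",
    "ExpressionSpec",
    "make_toy_model",
    "make_svg",
    "make_expression",
    "make_branched_model",
    "make_twogroup_fixture",
]

DEFAULT_UB = 1000.0


@dataclass
class ToySpec:
    """Parallel-route toy model: shared source/sink, one route per path."""

    n_parallel_paths: int = 1
    path_lengths: tuple[int, ...] = (1,)
    uptake_limit: float = 10.0
    gpr_assignment: dict[str, str] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.path_lengths) != self.n_parallel_paths:
            raise ValueError("need one path length per parallel path")
        if any(l < 1 for l in self.path_lengths):
            raise ValueError("path lengths must be >= 1")


@dataclass
class ExpressionSpec:
    """Two-or-more-group expression matrix with planted multiplicative effects."""

    n_samples_per_group: int = 10
    groups: tuple[str, ...] = ("g1", "g2")
    baseline_mean: float = 100.0
    planted_effects: dict[tuple[str, str], float] = field(default_factory=dict)
    noise_cv: float = 0.2
    seed: int = 0


def make_toy_model(spec: ToySpec) -> ModelStruct:
    """Build the parallel-route model: EX_A -> paths(A..B) -> EX_B (objective).

    A single path of length 1 is the canonical 3-reaction chain; several
    paths of length 1 give the redundancy fixture.  Path *p*, step *k*
    is reaction ``P{p}R{k}``; intermediates live in compartment ``c``,
    boundary metabolites in ``e``.
    """
    metabolites: list[tuple[str, str]] = [("A[e]", "e"), ("B[e]", "e")]
    reactions: list[ReactionRec] = []
    stoich: dict[tuple[str, str], float] = {}

    reactions.append(ReactionRec("EX_A", -spec.uptake_limit, DEFAULT_UB))
    stoich[("A[e]", "EX_A")] = -1.0
    for p in range(1, spec.n_parallel_paths + 1):
        length = spec.path_lengths[p - 1]
        prev = "A[e]"
        for k in range(1, length + 1):
            rid = f"P{p}R{k}"
            if k == length:
                nxt = "B[e]"
            else:
                nxt = f"M{p}_{k}[c]"
                metabolites.append((nxt, "c"))
            reactions.append(ReactionRec(rid, 0.0, DEFAULT_UB))
            stoich[(prev, rid)] = -1.0
            stoich[(nxt, rid)] = 1.0
            prev = nxt
    reactions.append(ReactionRec("EX_B", 0.0, DEFAULT_UB))
    stoich[("B[e]", "EX_B")] = -1.0

    for rec in reactions:
        text = spec.gpr_assignment.get(rec.id, "")
        if text:
            rec.gpr_text = text
            rec.gpr = parse_gpr(text)
    return ModelStruct(
        metabolites=metabolites,
        reactions=reactions,
        stoichiometry=stoich,
        objective={"EX_B": 1.0},
    )


def make_svg(model: ModelStruct, id_pattern: str = "R_{reaction_id}") -> str:
    """Minimal SVG map: one horizontal ``<path>`` per reaction, ids per pattern."""
    lines = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        '<svg xmlns="http://www.w3.org/2000/svg" width="420" '
        f'height="{40 + 24 * len(model.reactions)}">',
    ]
    for i, rec in enumerate(model.reactions):
        y = 30 + 24 * i
        el_id = id_pattern.format(reaction_id=rec.id)
        lines.append(
            f'  <path id="{el_id}" d="M 40 {y} L 220 {y}" '
            'stroke="#000000" stroke-width="2" fill="none"/>'
        )
        lines.append(
            f'  <text x="230" y="{y + 4}" font-size="10">{rec.id}</text>'
        )
    lines.append("</svg>")
    return "\n".join(lines)


def _lognormal_factor(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Multiplicative noise with unit mean and coefficient of variation cv."""
    if cv <= 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return np.exp(rng.normal(-sigma * sigma / 2.0, sigma, size=size))


def make_expression(
    spec: ExpressionSpec, model: ModelStruct
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate an expression matrix plus a symbolic ground-truth table.

    Each value is ``baseline_mean x factor(group, gene) x lognormal
    noise`` (unit-mean, CV ``noise_cv``); samples are named
    ``{group}_s{i}``.  The ground-truth table gives, per GPR-bearing
    reaction, the noise-free expected RAS in each group (GPR evaluated
    on expected expression) and the shift direction of the first group
    against each other group — derived from the sum/min structure, not
    from the RAS implementation.
    """
    genes = sorted(model.genes())
    for (group, gene) in spec.planted_effects:
        if gene not in genes:
            raise ValueError(f"planted gene {gene!r} not in any model GPR")
        if group not in spec.groups:
            raise ValueError(f"planted group {group!r} not in groups")
    rng = np.random.default_rng(spec.seed)
    columns: dict[str, np.ndarray] = {}
    for group in spec.groups:
        factors = np.array(
            [spec.planted_effects.get((group, g), 1.0) for g in genes]
        )
        for i in range(spec.n_samples_per_group):
            noise = _lognormal_factor(rng, spec.noise_cv, len(genes))
            columns[f"{group}_s{i}"] = spec.baseline_mean * factors * noise
    expr = pd.DataFrame(columns, index=genes)
    expr.index.name = "gene_id"

    expected = {
        group: {
            g: spec.baseline_mean * spec.planted_effects.get((group, g), 1.0)
            for g in genes
        }
        for group in spec.groups
    }
    rows = []
    first = spec.groups[0]
    for rec in model.reactions:
        if rec.gpr is None:
            continue
        ras = {g: eval_ras(rec.gpr, expected[g]) for g in spec.groups}
        row = {"reaction_id": rec.id}
        for g in spec.groups:
            row[f"expected_ras_{g}"] = ras[g]
        for g in spec.groups[1:]:
            diff = (ras[first] or 0.0) - (ras[g] or 0.0)
            row[f"shift_{first}_vs_{g}"] = (
                "up" if diff > 1e-9 else "down" if diff < -1e-9 else "none"
            )
        rows.append(row)
    truth = pd.DataFrame(rows)
    return expr, truth


# -- independent-branch topology for group comparisons ------------------

_BRANCH_GPRS = ["{a} and {b}", "{a} or {b}", "{a}"]


def make_branched_model(n_branches: int = 3, uptake_limit: float = 10.0) -> ModelStruct:
    """Independent branches, each: EX_S -> U (GPR, capacity) -> C -> EX_P.

    Branches share nothing, so a planted effect on one branch's genes
    moves that branch's fluxes and no others.  The GPR-bearing capacity
    reaction ``U{p}`` has upper bound ``uptake_limit``, making the
    normalized RAS the binding constraint; branch GPR shapes cycle
    through and-of-two, or-of-two, single-gene.
    """
    metabolites: list[tuple[str, str]] = []
    reactions: list[ReactionRec] = []
    stoich: dict[tuple[str, str], float] = {}
    objective: dict[str, float] = {}
    for p in range(1, n_branches + 1):
        src, mid, prod = f"S{p}[e]", f"I{p}[c]", f"P{p}[e]"
        metabolites += [(src, "e"), (mid, "c"), (prod, "e")]
        gpr = _BRANCH_GPRS[(p - 1) % len(_BRANCH_GPRS)].format(a=f"g{p}a", b=f"g{p}b")
        reactions.append(ReactionRec(f"EX_S{p}", -uptake_limit, 0.0))
        stoich[(src, f"EX_S{p}")] = -1.0
        reactions.append(ReactionRec(f"U{p}", 0.0, uptake_limit, gpr_text=gpr,
                                     pathway=f"branch{p}"))
        stoich[(src, f"U{p}")] = -1.0
        stoich[(mid, f"U{p}")] = 1.0
        reactions.append(ReactionRec(f"C{p}", 0.0, DEFAULT_UB, pathway=f"branch{p}"))
        stoich[(mid, f"C{p}")] = -1.0
        stoich[(prod, f"C{p}")] = 1.0
        reactions.append(ReactionRec(f"EX_P{p}", 0.0, DEFAULT_UB))
        stoich[(prod, f"EX_P{p}")] = -1.0
        objective[f"EX_P{p}"] = 1.0
    return ModelStruct(
        metabolites=metabolites,
        reactions=reactions,
        stoichiometry=stoich,
        objective=objective,
    )


def make_twogroup_fixture(
    seed: int = 0,
    n_samples_per_group: int = 25,
    effect: float = 3.0,
    planted_branch: int = 1,
    n_branches: int = 3,
    noise_cv: float = 0.2,
    uptake_limit: float = 10.0,
) -> dict:
    """Everything for a two-group end-to-end run with one up-scaled branch.

    Group ``tumor`` carries an ``effect``-fold up-scaling of every gene
    of ``planted_branch``; group ``normal`` is baseline.  Returns the
    model, its SVG map, the expression matrix, the sample->group
    assignment, a medium covering all source metabolites, the symbolic
    RAS ground truth, and ``expected_flux_shift``: the signed expected
    direction of each reaction's flux mean (``tumor`` vs ``normal``),
    where uptake exchanges flip sign because uptake is negative flux.
    """
    model = make_branched_model(n_branches=n_branches, uptake_limit=uptake_limit)
    groups = ("tumor", "normal")
    planted = {
        ("tumor", gene): effect
        for gene in sorted(model.genes())
        if gene.startswith(f"g{planted_branch}")
    }
    espec = ExpressionSpec(
        n_samples_per_group=n_samples_per_group,
        groups=groups,
        planted_effects=planted,
        noise_cv=noise_cv,
        seed=seed,
    )
    expr, truth = make_expression(espec, model)
    assignment = {
        f"{g}_s{i}": g for g in groups for i in range(n_samples_per_group)
    }
    medium = Medium({f"S{p}[e]": uptake_limit for p in range(1, n_branches + 1)})

    # flux-level ground truth: each branch's flux follows its capacity
    # reaction's RAS shift; the uptake exchange runs negative, so its
    # signed mean moves opposite to the flux magnitude
    expected_flux_shift: dict[str, str] = {}
    shift_col = f"shift_{groups[0]}_vs_{groups[1]}"
    branch_shift = {
        int(row["reaction_id"][1:]): row[shift_col]
        for _, row in truth.iterrows()
        if row["reaction_id"].startswith("U")
    }
    for p in range(1, n_branches + 1):
        direction = branch_shift.get(p, "none")
        flipped = {"up": "down", "down": "up", "none": "none"}[direction]
        expected_flux_shift[f"EX_S{p}"] = flipped
        for rid in (f"U{p}", f"C{p}", f"EX_P{p}"):
            expected_flux_shift[rid] = direction
    return {
        "model": model,
        "svg": make_svg(model),
        "expression": expr,
        "assignment": assignment,
        "groups": groups,
        "medium": medium,
        "ras_truth": truth,
        "expected_flux_shift": expected_flux_shift,
        "seed": seed,
    }
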