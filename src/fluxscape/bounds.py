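"""Per-sample reaction bounds from normalized activity scores and a medium.

The RAS matrix is normalized per reaction by its maximum across samples
(scores land in [0, 1] and stay comparable across samples); each
normalized score then multiplies both bounds of its reaction, shrinking
the feasible flux range in proportion to transcript availability.
Medium composition constrains exchange reactions: a metabolite listed
with uptake rate ``u`` opens its exchange to a lower bound of ``-u``
(uptake is negative flux, the standard sign convention), and every
exchange whose metabolite is not listed is closed to uptake.

Reactions whose score is MISSING keep their original bounds, and rows
whose maximum RAS is zero are treated as MISSING by default rather
than closing the reaction in every sample (``zero_ras_closes=True``
restores the harsher reading).  Exchange reactions are exempt from RAS
scaling by default — the medium governs them — unless
``scale_exchanges=True``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .model_io import ModelStruct

__all__ = [
    "Medium",
    "BoundsSet",
    "read_medium",
    "normalize_ras",
    "apply_ras_to_bounds",
    "apply_medium",
    "build_sample_models",
]

logger = logging.getLogger(__name__)


@dataclass
class Medium:
    """Extracellular availability: metabolite id -> maximal uptake rate (>= 0)."""

    entries: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for mid, rate in self.entries.items():
            if rate < 0:
                raise ValueError(f"medium rate for {mid!r} must be >= 0, got {rate}")

    def __contains__(self, mid: str) -> bool:
        return mid in self.entries

    def __iter__(self):
        return iter(self.entries)


@dataclass
class BoundsSet:
    """Per-sample bounds: reaction id -> (lower, upper), every reaction present."""

    sample: str
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for rid, (lo, hi) in self.bounds.items():
            if lo > hi:
                raise ValueError(f"reaction {rid!r}: lower bound {lo} > upper bound {hi}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(rid, lo, hi) for rid, (lo, hi) in self.bounds.items()],
            columns=["reaction_id", "lower_bound", "upper_bound"],
        ).set_index("reaction_id")


def read_medium(path) -> Medium:
    """Read a two-column TSV (metabolite_id, uptake_rate) with a header row."""
    table = pd.read_csv(path, sep="\t")
    mid_col, rate_col = table.columns[:2]
    return Medium({str(r[mid_col]).strip(): float(r[rate_col]) for _, r in table.iterrows()})


def _default_bounds(model: ModelStruct) -> dict[str, tuple[float, float]]:
    return {r.id: (r.lower_bound, r.upper_bound) for r in model.reactions}


def normalize_ras(ras: pd.DataFrame, zero_ras_closes: bool = False) -> pd.DataFrame:
    """Divide each reaction's scores by its maximum across samples.

    Output values lie in [0, 1]; NaN (MISSING) propagates.  Rows whose
    maximum is zero become all-MISSING (bounds will stay untouched)
    unless ``zero_ras_closes`` is set, in which case they become 0 and
    will close the reaction in every sample.
    """
    if ras.shape[1] < 1:
        raise ValueError("RAS matrix needs at least one sample")
    values = ras.to_numpy(dtype=float)
    row_max = np.nanmax(np.where(np.isnan(values), -np.inf, values), axis=1)
    out = np.full_like(values, np.nan)
    for i, mx in enumerate(row_max):
        if not np.isfinite(mx):
            continue  # all-MISSING row
        if mx <= 0:
            if zero_ras_closes:
                out[i] = np.where(np.isnan(values[i]), np.nan, 0.0)
            continue
        out[i] = values[i] / mx
    return pd.DataFrame(out, index=ras.index, columns=ras.columns)


def apply_ras_to_bounds(
    model: ModelStruct,
    norm_ras_column: Mapping[str, float],
    sample: str = "",
    base: Optional[BoundsSet] = None,
    scale_exchanges: bool = False,
) -> BoundsSet:
    """Scale each reaction's bounds by its normalized RAS.

    Both bounds are multiplied by the same factor ``r`` in [0, 1], so a
    reversible range shrinks symmetrically and never changes direction.
    MISSING scores (NaN/None) and reactions without a GPR leave bounds
    untouched, as do exchange reactions unless ``scale_exchanges``.
    ``base`` supplies starting bounds (e.g. after medium refinement);
    the model's own bounds are used when absent.
    """
    start = dict(base.bounds) if base is not None else _default_bounds(model)
    out: dict[str, tuple[float, float]] = {}
    for rec in model.reactions:
        lo, hi = start[rec.id]
        r = norm_ras_column.get(rec.id)
        scalable = rec.gpr is not None and (scale_exchanges or not rec.is_exchange)
        if scalable and r is not None and not (isinstance(r, float) and np.isnan(r)):
            r = float(r)
            if not 0.0 <= r <= 1.0:
                raise ValueError(
                    f"normalized RAS for {rec.id!r} must be in [0, 1], got {r}"
                )
            lo, hi = lo * r, hi * r
        out[rec.id] = (lo, hi)
    return BoundsSet(sample=sample, bounds=out)


def apply_medium(model: ModelStruct, medium: Medium, sample: str = "",
                 base: Optional[BoundsSet] = None) -> BoundsSet:
    """Constrain exchange lower bounds from medium availability.

    Exchanges for metabolites in the medium get lower bound ``-rate``;
    all other exchanges are closed to uptake (lower bound 0).  Upper
    bounds and internal reactions are untouched.  Medium metabolites
    without a matching exchange reaction trigger a warning, not an
    error.  ``base`` supplies starting bounds; the model's own are used
    when absent.
    """
    out = dict(base.bounds) if base is not None else _default_bounds(model)
    matched: set[str] = set()
    for rec in model.reactions:
        if not rec.is_exchange:
            continue
        met = model.exchange_metabolite(rec.id)
        lo, hi = out[rec.id]
        if met in medium:
            matched.add(met)
            out[rec.id] = (-float(medium.entries[met]), hi)
        else:
            out[rec.id] = (max(lo, 0.0), hi)
    orphans = sorted(set(medium) - matched)
    if orphans:
        logger.warning(
            "medium metabolites with no exchange reaction (ignored): %s", orphans
        )
    return BoundsSet(sample=sample, bounds=out)


def build_sample_models(
    model: ModelStruct,
    norm_ras: pd.DataFrame,
    medium: Optional[Medium] = None,
    scale_exchanges: bool = False,
) -> list[BoundsSet]:
    """One BoundsSet per sample: medium refinement first, then RAS scaling."""
    base = apply_medium(model, medium) if medium is not None else None
    out = []
    for sample in norm_ras.columns:
        column = norm_ras[sample].to_dict()
        out.append(
            apply_ras_to_bounds(
                model, column, sample=str(sample), base=base,
                scale_exchanges=scale_exchanges,
            )
        )
    return out
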