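"""End-to-end composition: expression -> RAS -> bounds -> fluxes -> comparison."""

from __future__ import annotations

from typing import Mapping, Optional

import pandas as pd

from . import bounds as bounds_mod
from . import enrichment, gpr
from .flux_core import build_lp, fba, fva, pfba, single_reaction_deletion
from .model_io import ModelStruct
from .sampling import batch_samples


def sample_flux_frame(
    model: ModelStruct,
    expression: pd.DataFrame,
    medium: Optional[bounds_mod.Medium] = None,
    method: str = "pfba",
    n_samples: int = 100,
    thinning: int = 100,
    seed: int = 0,
    zero_ras_closes: bool = False,
    scale_exchanges: bool = False,
) -> pd.DataFrame:
    """One flux row per expression sample (samples x reactions).

    ``method="pfba"`` solves one parsimonious FBA per sample's
    transcriptionally constrained model; ``"cbs"``/``"hr"`` instead draw
    ``n_samples`` flux samples per constrained model and record their
    per-reaction means.
    """
    ras = gpr.expression_to_ras(model, expression)
    norm = bounds_mod.normalize_ras(ras, zero_ras_closes=zero_ras_closes)
    sets = bounds_mod.build_sample_models(
        model, norm, medium=medium, scale_exchanges=scale_exchanges
    )
    rows = {}
    for i, bset in enumerate(sets):
        problem = build_lp(model, bset)
        if method == "pfba":
            flux = pfba(problem)
            if flux.status != "optimal":
                raise RuntimeError(
                    f"sample {bset.sample!r}: pFBA status {flux.status}"
                )
            rows[bset.sample] = flux.values
        elif method in ("cbs", "hr", "hit_and_run"):
            frames = batch_samples(problem, n_samples, 1, seed + i,
                                   method=method, thinning=thinning)
            rows[bset.sample] = frames[0].mean(axis=0).to_dict()
        else:
            raise ValueError(f"unknown flux method {method!r}")
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame = frame[[r.id for r in model.reactions]]
    return frame


def compare_flux_frame(
    frame: pd.DataFrame,
    assignment: Mapping[str, str],
    mode: str = "one_vs_one",
    control: Optional[str] = None,
    **kwargs,
) -> list[tuple[str, pd.DataFrame]]:
    """Split a flux frame by group assignment and run the comparisons."""
    groups = enrichment.group_fluxes(frame, assignment)
    return enrichment.compare_groups(groups, mode=mode, control=control, **kwargs)
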