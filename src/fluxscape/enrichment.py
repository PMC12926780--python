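"""Flux enrichment analysis: compare flux distributions between sample groups.

For each reaction and each pair of groups the module computes a
two-sample p-value (Kolmogorov–Smirnov by default; Mann–Whitney and
Welch's t available), a signed bounded fold change

    FC = (avg1 - avg2) / (|avg1| + |avg2|)        in [-1, 1],

a Welch z-score, and the two group means.  A reaction is flagged only
when it passes both the p-value threshold (default 0.05) and the
fold-change threshold (default 1.2, read as "at least a 20%
difference"): the ratio criterion ``|avg1 - avg2| >= (t - 1) *
min(|avg1|, |avg2|)``.  The bounded FC statistic is what gets reported
and drives arrow widths; the ratio test is what gates significance
(``fc_on_eq1=True`` instead applies the threshold directly to the
bounded statistic as ``|FC| >= (t-1)/(t+1)``).

Style classes for map rendering: ``up``/``down`` when the first group's
mean is higher/lower, ``sign_flip_up``/``sign_flip_down`` when the two
means have opposite signs (a reversible reaction running backwards in
one group — qualitatively significant whenever the p-test passes),
``not_significant`` otherwise.

Comparison modes: every pair (1-vs-1), each group against all other
samples pooled (1-vs-All), or each non-control group against a control
group (1-vs-Control).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "fold_change",
    "test_reaction",
    "z_score",
    "compare_groups",
    "group_fluxes",
    "RECORD_COLUMNS",
]

RECORD_COLUMNS = [
    "reaction_id", "p_value", "fold_change", "z_score", "avg1", "avg2", "style_class",
]


def fold_change(avg1: float, avg2: float) -> float:
    """Signed bounded fold change ``(avg1 - avg2) / (|avg1| + |avg2|)``.

    Returns 0 when both averages are 0 (no signal, no direction).
    """
    denom = abs(avg1) + abs(avg2)
    if denom == 0:
        return 0.0
    return (avg1 - avg2) / denom


def test_reaction(values1: Sequence[float], values2: Sequence[float],
                  test: str = "ks") -> float:
    """Two-sided p-value of the chosen two-sample test.

    ``test`` is ``"ks"`` (Kolmogorov–Smirnov), ``"mannwhitney"``, or
    ``"ttest"`` (Welch).  Two identical constant samples give p = 1 by
    convention.
    """
    v1 = np.asarray(values1, dtype=float)
    v2 = np.asarray(values2, dtype=float)
    if len(v1) < 2 or len(v2) < 2:
        raise ValueError("each group needs at least 2 values")
    if v1.std() == 0 and v2.std() == 0 and v1[0] == v2[0]:
        return 1.0
    if test == "ks":
        return float(stats.ks_2samp(v1, v2, alternative="two-sided").pvalue)
    if test == "mannwhitney":
        return float(stats.mannwhitneyu(v1, v2, alternative="two-sided").pvalue)
    if test == "ttest":
        return float(stats.ttest_ind(v1, v2, equal_var=False).pvalue)
    raise ValueError(f"unknown test {test!r}")


test_reaction.__test__ = False  # plain function despite the name; not a pytest item


def z_score(values1: Sequence[float], values2: Sequence[float]) -> float:
    """Welch two-sample z: ``(mean1 - mean2) / sqrt(s1²/n1 + s2²/n2)``.

    Sample variances use the n-1 denominator.  Returns NaN (undefined)
    when both variances are zero, 0 for identical lists.
    """
    v1 = np.asarray(values1, dtype=float)
    v2 = np.asarray(values2, dtype=float)
    if len(v1) < 2 or len(v2) < 2:
        raise ValueError("each group needs at least 2 values")
    var1 = v1.var(ddof=1)
    var2 = v2.var(ddof=1)
    diff = v1.mean() - v2.mean()
    if var1 == 0 and var2 == 0:
        return 0.0 if diff == 0 else float("nan")
    return float(diff / np.sqrt(var1 / len(v1) + var2 / len(v2)))


def _fc_passes(avg1: float, avg2: float, fc_threshold: float,
               fc_on_eq1: bool) -> bool:
    if fc_on_eq1:
        cut = (fc_threshold - 1.0) / (fc_threshold + 1.0)
        return abs(fold_change(avg1, avg2)) >= cut
    return abs(avg1 - avg2) >= (fc_threshold - 1.0) * min(abs(avg1), abs(avg2))


def _classify(avg1: float, avg2: float, p: float, p_threshold: float,
              fc_threshold: float, fc_on_eq1: bool) -> str:
    if not np.isfinite(p) or p > p_threshold:
        return "not_significant"
    if avg1 * avg2 < 0:
        # direction reversal: qualitatively significant once the p-test passes
        return "sign_flip_up" if avg1 > avg2 else "sign_flip_down"
    if not _fc_passes(avg1, avg2, fc_threshold, fc_on_eq1):
        return "not_significant"
    if avg1 == avg2:
        return "not_significant"
    return "up" if avg1 > avg2 else "down"


def _compare_pair(frame1: pd.DataFrame, frame2: pd.DataFrame, test: str,
                  p_threshold: float, fc_threshold: float,
                  fc_on_eq1: bool, correction: Optional[str]) -> pd.DataFrame:
    records = []
    reactions = list(frame1.columns)
    pvals = []
    for rid in reactions:
        v1 = frame1[rid].to_numpy(dtype=float)
        v2 = frame2[rid].to_numpy(dtype=float)
        pvals.append(test_reaction(v1, v2, test=test))
    pvals = np.asarray(pvals)
    if correction == "bh":
        order = np.argsort(pvals)
        ranked = pvals[order] * len(pvals) / (np.arange(len(pvals)) + 1)
        adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty_like(pvals)
        out[order] = np.minimum(adjusted, 1.0)
        pvals = out
    elif correction is not None:
        raise ValueError(f"unknown correction {correction!r}")
    for rid, p in zip(reactions, pvals):
        v1 = frame1[rid].to_numpy(dtype=float)
        v2 = frame2[rid].to_numpy(dtype=float)
        avg1, avg2 = float(v1.mean()), float(v2.mean())
        records.append({
            "reaction_id": rid,
            "p_value": float(p),
            "fold_change": fold_change(avg1, avg2),
            "z_score": z_score(v1, v2),
            "avg1": avg1,
            "avg2": avg2,
            "style_class": _classify(avg1, avg2, float(p), p_threshold,
                                     fc_threshold, fc_on_eq1),
        })
    return pd.DataFrame(records, columns=RECORD_COLUMNS)


def group_fluxes(frame: pd.DataFrame, assignment: Mapping[str, str]) -> dict[str, pd.DataFrame]:
    """Split one samples-x-reactions frame into per-group frames."""
    missing = [s for s in frame.index if s not in assignment]
    if missing:
        raise ValueError(f"samples without group assignment: {missing}")
    groups: dict[str, pd.DataFrame] = {}
    for name in dict.fromkeys(assignment.values()):
        members = [s for s in frame.index if assignment[s] == name]
        if members:
            groups[name] = frame.loc[members]
    return groups


def compare_groups(
    groups: Mapping[str, pd.DataFrame],
    mode: str = "one_vs_one",
    control: Optional[str] = None,
    test: str = "ks",
    p_threshold: float = 0.05,
    fc_threshold: float = 1.2,
    fc_on_eq1: bool = False,
    correction: Optional[str] = None,
) -> list[tuple[str, pd.DataFrame]]:
    """Run all comparisons of the chosen mode.

    ``groups`` maps group name to a samples-x-reactions flux frame with
    identical reaction columns.  Returns ``(label, table)`` pairs, one
    table of :data:`RECORD_COLUMNS` per comparison; labels read
    ``"A_vs_B"`` (``"A_vs_rest"`` in 1-vs-All mode).
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    cols = None
    for name, frame in groups.items():
        if frame.empty:
            raise ValueError(f"group {name!r} is empty")
        if cols is None:
            cols = list(frame.columns)
        elif list(frame.columns) != cols:
            raise ValueError("all groups must share the same reaction list")
    kwargs = dict(test=test, p_threshold=p_threshold, fc_threshold=fc_threshold,
                  fc_on_eq1=fc_on_eq1, correction=correction)
    results: list[tuple[str, pd.DataFrame]] = []
    if mode == "one_vs_one":
        for a, b in itertools.combinations(names, 2):
            results.append((f"{a}_vs_{b}", _compare_pair(groups[a], groups[b], **kwargs)))
    elif mode == "one_vs_all":
        for a in names:
            rest = pd.concat([groups[b] for b in names if b != a], axis=0)
            results.append((f"{a}_vs_rest", _compare_pair(groups[a], rest, **kwargs)))
    elif mode == "one_vs_control":
        if control is None or control not in groups:
            raise ValueError(
                f"mode one_vs_control requires a control group; available: {names}"
            )
        for a in names:
            if a == control:
                continue
            results.append((f"{a}_vs_{control}",
                            _compare_pair(groups[a], groups[control], **kwargs)))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return results
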