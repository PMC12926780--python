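"""Style SVG metabolic maps from comparison results or flux summaries.

Reaction arrows are located by element id using a configurable
template (default ``R_{reaction_id}``, the convention of
Escher-exported maps).  In comparison maps the stroke color encodes
the style class (orange up, sky blue down, red/blue for sign flips,
grey for non-significant) and the stroke width scales linearly with
the magnitude of the bounded fold change; in magnitude maps the width
scales with |mean| or |median| flux, rescaled so the largest value
hits ``width_max``, under a sequential light-to-dark color ramp.

Styling is idempotent and non-destructive: elements not matched by the
id template are not touched, and a legend group (replaced on re-runs)
is appended under a fixed id.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from lxml import etree

__all__ = [
    "MapStyleConfig",
    "MapRenderError",
    "style_comparison_map",
    "style_magnitude_map",
]

SVG_NS = "http://www.w3.org/2000/svg"
LEGEND_ID = "fluxscape-legend"


class MapRenderError(ValueError):
    pass


@dataclass
class MapStyleConfig:
    """Colors, stroke-width range, and the reaction-id element template."""

    color_up: str = "#FFA500"        # orange
    color_down: str = "#87CEEB"      # sky blue
    color_flip_up: str = "#FF0000"   # red
    color_flip_down: str = "#0000FF" # blue
    color_ns: str = "#BEBEBE"        # light grey
    ramp_low: str = "#FFF5C0"        # magnitude ramp endpoints
    ramp_high: str = "#B22222"
    width_min: float = 2.0
    width_max: float = 12.0
    id_pattern: str = "R_{reaction_id}"

    def __post_init__(self) -> None:
        if not self.width_min < self.width_max:
            raise ValueError("width_min must be < width_max")

    def class_color(self, style_class: str) -> str:
        return {
            "up": self.color_up,
            "down": self.color_down,
            "sign_flip_up": self.color_flip_up,
            "sign_flip_down": self.color_flip_down,
            "not_significant": self.color_ns,
        }[style_class]

    def width_for(self, magnitude: float) -> float:
        mag = min(max(float(magnitude), 0.0), 1.0)
        return self.width_min + (self.width_max - self.width_min) * mag


@dataclass
class UnmatchedReport:
    """Ids present on only one side of the records/map join."""

    unmatched_record_ids: list[str] = field(default_factory=list)
    unmatched_map_ids: list[str] = field(default_factory=list)


def _parse_svg(svg_in) -> etree._ElementTree:
    try:
        if isinstance(svg_in, (str, bytes)) and not str(svg_in).lstrip().startswith("<"):
            tree = etree.parse(str(svg_in))
        elif isinstance(svg_in, bytes):
            tree = etree.ElementTree(etree.fromstring(svg_in))
        else:
            tree = etree.ElementTree(etree.fromstring(svg_in.encode()))
    except (etree.XMLSyntaxError, OSError) as exc:
        raise MapRenderError(f"malformed SVG input: {exc}") from exc
    return tree


def _elements_by_id(tree) -> dict[str, etree._Element]:
    out = {}
    for el in tree.getroot().iter():
        el_id = el.get("id")
        if el_id is not None:
            out[el_id] = el
    return out


def _arrow_ids(config: MapStyleConfig, reaction_ids) -> dict[str, str]:
    return {rid: config.id_pattern.format(reaction_id=rid) for rid in reaction_ids}


def _apply_stroke(el, color: str, width: float) -> None:
    el.set("stroke", color)
    el.set("stroke-width", f"{width:g}")


def _replace_legend(root, entries: list[tuple[str, str]]) -> None:
    for old in root.findall(f".//{{{SVG_NS}}}g[@id='{LEGEND_ID}']"):
        old.getparent().remove(old)
    legend = etree.SubElement(root, f"{{{SVG_NS}}}g", id=LEGEND_ID)
    for i, (color, label) in enumerate(entries):
        y = 10 + 16 * i
        etree.SubElement(legend, f"{{{SVG_NS}}}rect", x="10", y=str(y),
                         width="12", height="12", fill=color)
        text = etree.SubElement(legend, f"{{{SVG_NS}}}text", x="26", y=str(y + 10))
        text.set("font-size", "10")
        text.text = label


def _serialize(tree) -> bytes:
    return etree.tostring(tree, xml_declaration=True, encoding="UTF-8")


def style_comparison_map(
    svg_in,
    records: pd.DataFrame,
    config: Optional[MapStyleConfig] = None,
    out_path=None,
) -> tuple[bytes, UnmatchedReport]:
    """Color and size reaction arrows from a comparison record table.

    ``records`` needs columns ``reaction_id``, ``fold_change``,
    ``style_class``.  Stroke width is ``width_min + (width_max -
    width_min) * |fold_change|`` (clamped to [0, 1]); non-significant
    arrows get ``color_ns`` at ``width_min``.  Returns the styled SVG
    bytes and a report of ids present on one side only; zero matches is
    a hard error.
    """
    config = config or MapStyleConfig()
    tree = _parse_svg(svg_in)
    by_id = _elements_by_id(tree)
    targets = _arrow_ids(config, records["reaction_id"])
    report = UnmatchedReport()
    matched_el_ids = set()
    for _, row in records.iterrows():
        el = by_id.get(targets[row["reaction_id"]])
        if el is None:
            report.unmatched_record_ids.append(row["reaction_id"])
            continue
        matched_el_ids.add(targets[row["reaction_id"]])
        style_class = row["style_class"]
        if style_class == "not_significant":
            _apply_stroke(el, config.color_ns, config.width_min)
        else:
            _apply_stroke(el, config.class_color(style_class),
                          config.width_for(abs(row["fold_change"])))
    if not matched_el_ids:
        raise MapRenderError(
            "no record reaction id matched any SVG element id; check id_pattern "
            f"({config.id_pattern!r})"
        )
    prefix, _, suffix = config.id_pattern.partition("{reaction_id}")
    for el_id in by_id:
        if el_id.startswith(prefix) and el_id.endswith(suffix) and el_id != LEGEND_ID:
            if el_id not in matched_el_ids:
                report.unmatched_map_ids.append(el_id)
    _replace_legend(tree.getroot(), [
        (config.color_up, "up in group 1"),
        (config.color_down, "down in group 1"),
        (config.color_flip_up, "sign flip (up)"),
        (config.color_flip_down, "sign flip (down)"),
        (config.color_ns, "not significant"),
    ])
    data = _serialize(tree)
    if out_path is not None:
        with open(out_path, "wb") as fh:
            fh.write(data)
    return data, report


def _lerp_color(low: str, high: str, t: float) -> str:
    lo = np.array([int(low[i:i + 2], 16) for i in (1, 3, 5)])
    hi = np.array([int(high[i:i + 2], 16) for i in (1, 3, 5)])
    rgb = np.round(lo + (hi - lo) * min(max(t, 0.0), 1.0)).astype(int)
    return "#{:02X}{:02X}{:02X}".format(*rgb)


def style_magnitude_map(
    svg_in,
    summary: pd.DataFrame,
    statistic: str = "mean",
    config: Optional[MapStyleConfig] = None,
    out_path=None,
) -> tuple[bytes, UnmatchedReport]:
    """Size arrows by |mean| or |median| flux, colored on a sequential ramp.

    The largest |statistic| maps to ``width_max`` and zero to
    ``width_min`` (an all-zero summary leaves every arrow at
    ``width_min``); the rescaling is invariant under multiplying all
    values by a constant.  Net-flux direction is not re-encoded: arrow
    geometry is left as drawn.
    """
    if statistic not in ("mean", "median"):
        raise ValueError("statistic must be 'mean' or 'median'")
    config = config or MapStyleConfig()
    tree = _parse_svg(svg_in)
    by_id = _elements_by_id(tree)
    mags = summary[statistic].abs()
    top = float(mags.max())
    targets = _arrow_ids(config, summary.index)
    report = UnmatchedReport()
    matched = 0
    for rid in summary.index:
        el = by_id.get(targets[rid])
        if el is None:
            report.unmatched_record_ids.append(rid)
            continue
        matched += 1
        t = float(mags[rid]) / top if top > 0 else 0.0
        _apply_stroke(el, _lerp_color(config.ramp_low, config.ramp_high, t),
                      config.width_min + (config.width_max - config.width_min) * t)
    if not matched:
        raise MapRenderError("no summary reaction id matched any SVG element id")
    _replace_legend(tree.getroot(), [
        (config.ramp_low, "low |flux|"),
        (config.ramp_high, "high |flux|"),
    ])
    data = _serialize(tree)
    if out_path is not None:
        with open(out_path, "wb") as fh:
            fh.write(data)
    return data, report
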