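"""Metabolic model import/export and the flat tabular schema.

Models are held in :class:`ModelStruct`, a minimal constraint-based
representation: metabolites with compartments, reactions with bounds
and GPR rules, a sparse stoichiometry map, and a linear objective.
Standard formats (SBML Level 3 + fbc, COBRA JSON, MATLAB ``.mat``
structs, YAML) are read and written through cobrapy; the flat
tab-separated ``ModelTable`` schema — one row per reaction with a
human-readable equation string — is this package's own, and round-trips
through every supported format.

The tabular column set is a reconstruction (the upstream description of
the flat file does not fix an exact schema): ``reaction_id``,
``equation_string``, ``lower_bound``, ``upper_bound``, ``gpr_text``,
``objective_coefficient``, ``in_medium``, ``pathway``.

Equation-string dialect: ``A[c] + 2 B[c] --> C[e]`` for irreversible
reactions, ``<=>`` for reversible ones (negative lower bound);
compartment suffixes stay inside metabolite ids.  An exchange reaction
has one side empty, e.g. ``glc[e] -->``.
"""

from __future__ import annotations

import bz2
import gzip
import io
import re
import shutil
import tempfile
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from .gpr import GPRNode, GPRParseError, parse_gpr, gpr_genes

__all__ = [
    "ReactionRec",
    "ModelStruct",
    "ModelFormatError",
    "import_model",
    "export_model",
    "model_to_table",
    "table_to_model",
    "read_table",
    "write_table",
    "model_summary",
]

TABLE_COLUMNS = [
    "reaction_id",
    "equation_string",
    "lower_bound",
    "upper_bound",
    "gpr_text",
    "objective_coefficient",
    "in_medium",
    "pathway",
]


class ModelFormatError(ValueError):
    """Unreadable, ambiguous, or inconsistent model input."""


@dataclass
class ReactionRec:
    """One reaction: bounds in mmol·gDW⁻¹·h⁻¹, optional GPR and pathway."""

    id: str
    lower_bound: float
    upper_bound: float
    gpr: Optional[GPRNode] = None
    gpr_text: str = ""
    pathway: str = ""
    is_exchange: bool = False

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise ModelFormatError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )
        if self.gpr is None and self.gpr_text.strip():
            self.gpr = parse_gpr(self.gpr_text)
        if self.gpr is not None and not self.gpr_text:
            self.gpr_text = self.gpr.to_text()


@dataclass
class ModelStruct:
    """In-memory constraint-based model.

    ``metabolites`` is a list of ``(id, compartment)`` pairs,
    ``stoichiometry`` maps ``(metabolite_id, reaction_id)`` to its
    coefficient, and ``objective`` maps reaction ids to linear objective
    coefficients.  ``validate()`` checks id uniqueness and referential
    integrity and derives the structural exchange flag (a reaction is an
    exchange iff it touches exactly one metabolite).
    """

    metabolites: list[tuple[str, str]] = field(default_factory=list)
    reactions: list[ReactionRec] = field(default_factory=list)
    stoichiometry: dict[tuple[str, str], float] = field(default_factory=dict)
    objective: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- structure -----------------------------------------------------
    def validate(self) -> None:
        met_ids = [m for m, _ in self.metabolites]
        rxn_ids = [r.id for r in self.reactions]
        if len(set(met_ids)) != len(met_ids):
            raise ModelFormatError("duplicate metabolite ids")
        if len(set(rxn_ids)) != len(rxn_ids):
            raise ModelFormatError("duplicate reaction ids")
        met_set, rxn_set = set(met_ids), set(rxn_ids)
        for (m, r), coeff in self.stoichiometry.items():
            if m not in met_set:
                raise ModelFormatError(f"stoichiometry references unknown metabolite {m!r}")
            if r not in rxn_set:
                raise ModelFormatError(f"stoichiometry references unknown reaction {r!r}")
        for r in self.objective:
            if r not in rxn_set:
                raise ModelFormatError(f"objective references unknown reaction {r!r}")
        counts = {r.id: 0 for r in self.reactions}
        for (m, r), coeff in self.stoichiometry.items():
            if coeff != 0:
                counts[r] += 1
        for rec in self.reactions:
            rec.is_exchange = counts[rec.id] == 1

    def reaction(self, rxn_id: str) -> ReactionRec:
        for rec in self.reactions:
            if rec.id == rxn_id:
                return rec
        raise KeyError(rxn_id)

    def reaction_metabolites(self, rxn_id: str) -> dict[str, float]:
        return {
            m: c for (m, r), c in self.stoichiometry.items() if r == rxn_id and c != 0
        }

    def exchange_metabolite(self, rxn_id: str) -> Optional[str]:
        """Metabolite id of an exchange reaction, ``None`` for internal ones."""
        mets = self.reaction_metabolites(rxn_id)
        if len(mets) == 1:
            return next(iter(mets))
        return None

    def genes(self) -> set[str]:
        out: set[str] = set()
        for rec in self.reactions:
            if rec.gpr is not None:
                out |= gpr_genes(rec.gpr)
        return out

    def copy(self) -> "ModelStruct":
        return ModelStruct(
            metabolites=list(self.metabolites),
            reactions=[
                ReactionRec(
                    id=r.id,
                    lower_bound=r.lower_bound,
                    upper_bound=r.upper_bound,
                    gpr=r.gpr,
                    gpr_text=r.gpr_text,
                    pathway=r.pathway,
                )
                for r in self.reactions
            ],
            stoichiometry=dict(self.stoichiometry),
            objective=dict(self.objective),
        )


# -- cobra conversion --------------------------------------------------

def _to_cobra(model: ModelStruct):
    import cobra

    cm = cobra.Model("fluxscape")
    mets = {
        mid: cobra.Metabolite(mid, compartment=comp or "c")
        for mid, comp in model.metabolites
    }
    rxns = []
    for rec in model.reactions:
        rxn = cobra.Reaction(rec.id)
        rxn.lower_bound = rec.lower_bound
        rxn.upper_bound = rec.upper_bound
        rxns.append(rxn)
    cm.add_reactions(rxns)
    for rxn, rec in zip(rxns, model.reactions):
        rxn.add_metabolites(
            {mets[m]: c for m, c in model.reaction_metabolites(rec.id).items()}
        )
        if rec.gpr_text:
            rxn.gene_reaction_rule = rec.gpr_text
        if rec.pathway:
            rxn.subsystem = rec.pathway
    if model.objective:
        cm.objective = {
            cm.reactions.get_by_id(r): c for r, c in model.objective.items()
        }
    return cm


def _from_cobra(cm) -> ModelStruct:
    from cobra.util.solver import linear_reaction_coefficients

    metabolites = [(m.id, m.compartment or "") for m in cm.metabolites]
    stoich: dict[tuple[str, str], float] = {}
    reactions: list[ReactionRec] = []
    for rxn in cm.reactions:
        text = rxn.gene_reaction_rule or ""
        try:
            gpr = parse_gpr(text) if text.strip() else None
        except GPRParseError as exc:
            raise ModelFormatError(
                f"reaction {rxn.id!r}: cannot parse GPR {text!r}: {exc}"
            ) from exc
        reactions.append(
            ReactionRec(
                id=rxn.id,
                lower_bound=float(rxn.lower_bound),
                upper_bound=float(rxn.upper_bound),
                gpr=gpr,
                gpr_text=text,
                pathway=getattr(rxn, "subsystem", "") or "",
            )
        )
        for met, coeff in rxn.metabolites.items():
            stoich[(met.id, rxn.id)] = float(coeff)
    objective = {
        rxn.id: float(c)
        for rxn, c in linear_reaction_coefficients(cm).items()
        if c
    }
    return ModelStruct(
        metabolites=metabolites,
        reactions=reactions,
        stoichiometry=stoich,
        objective=objective,
    )


# -- format dispatch ---------------------------------------------------

_EXT_FORMAT = {
    ".xml": "sbml",
    ".sbml": "sbml",
    ".json": "json",
    ".mat": "mat",
    ".yml": "yaml",
    ".yaml": "yaml",
    ".tsv": "tabular",
    ".tab": "tabular",
    ".csv": "tabular",
    ".txt": "tabular",
}
_COMPRESSED = {".gz", ".bz2", ".zip"}


def _decompress(path: Path) -> tuple[Path, Optional[tempfile.TemporaryDirectory]]:
    """Unpack a .gz/.bz2/.zip container holding exactly one model file."""
    suffix = path.suffix.lower()
    if suffix not in _COMPRESSED:
        return path, None
    tmp = tempfile.TemporaryDirectory(prefix="fluxscape_")
    if suffix == ".zip":
        with zipfile.ZipFile(path) as zf:
            names = [n for n in zf.namelist() if not n.endswith("/")]
            if len(names) != 1:
                raise ModelFormatError(
                    f"zip archive must contain exactly one model file, found {len(names)}"
                )
            inner = Path(tmp.name) / Path(names[0]).name
            with zf.open(names[0]) as src, open(inner, "wb") as dst:
                shutil.copyfileobj(src, dst)
        return inner, tmp
    opener = gzip.open if suffix == ".gz" else bz2.open
    inner = Path(tmp.name) / path.name[: -len(suffix)]
    with opener(path, "rb") as src, open(inner, "wb") as dst:
        shutil.copyfileobj(src, dst)
    return inner, tmp


def import_model(path, format_hint: str = "auto") -> ModelStruct:
    """Read a metabolic model from SBML/JSON/MAT/YAML/tabular into a ModelStruct.

    ``format_hint="auto"`` dispatches on the file extension; ``.gz``,
    ``.bz2`` and ``.zip`` containers are transparently unpacked (they
    must hold exactly one model file).  Raises
    :class:`ModelFormatError` for unknown or ambiguous formats, naming
    the detected extension.
    """
    import cobra.io

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    inner, tmp = _decompress(path)
    try:
        if format_hint == "auto":
            fmt = _EXT_FORMAT.get(inner.suffix.lower())
            if fmt is None:
                raise ModelFormatError(
                    f"cannot infer model format from extension {inner.suffix!r}"
                )
        else:
            fmt = format_hint
        if fmt == "sbml":
            cm = cobra.io.read_sbml_model(str(inner))
        elif fmt == "json":
            cm = cobra.io.load_json_model(str(inner))
        elif fmt == "mat":
            cm = cobra.io.load_matlab_model(str(inner))
        elif fmt == "yaml":
            cm = cobra.io.load_yaml_model(str(inner))
        elif fmt == "tabular":
            return table_to_model(read_table(inner))
        else:
            raise ModelFormatError(f"unknown format {fmt!r}")
        return _from_cobra(cm)
    finally:
        if tmp is not None:
            tmp.cleanup()


def export_model(table: pd.DataFrame, format: str, path) -> None:
    """Write a ModelTable out as SBML, JSON, YAML, or the tabular schema.

    The table is first rebuilt into a :class:`ModelStruct` (equation
    strings are re-parsed), so a failed row raises an error naming the
    reaction.
    """
    import cobra.io

    path = Path(path)
    if format == "tabular":
        write_table(table, path)
        return
    model = table_to_model(table)
    cm = _to_cobra(model)
    if format == "sbml":
        cobra.io.write_sbml_model(cm, str(path))
    elif format == "json":
        cobra.io.save_json_model(cm, str(path))
    elif format == "yaml":
        cobra.io.save_yaml_model(cm, str(path))
    else:
        raise ModelFormatError(f"unknown export format {format!r}")


# -- equation strings --------------------------------------------------

def format_equation(model: ModelStruct, rxn_id: str) -> str:
    rec = model.reaction(rxn_id)
    mets = model.reaction_metabolites(rxn_id)
    lhs, rhs = [], []
    for mid in sorted(mets):
        coeff = mets[mid]
        side = lhs if coeff < 0 else rhs
        mag = abs(coeff)
        term = mid if mag == 1 else f"{mag:g} {mid}"
        side.append(term)
    arrow = "<=>" if rec.lower_bound < 0 else "-->"
    return f"{' + '.join(lhs)} {arrow} {' + '.join(rhs)}".strip()


_TERM_RE = re.compile(r"^(?:(\d+(?:\.\d+)?(?:[eE][+-]?\d+)?)\s+)?(\S.*)$")


def _parse_side(side: str) -> dict[str, float]:
    side = side.strip()
    if not side:
        return {}
    out: dict[str, float] = {}
    for term in side.split(" + "):
        term = term.strip()
        if not term:
            continue
        match = _TERM_RE.match(term)
        if match is None:
            raise ModelFormatError(f"cannot parse equation term {term!r}")
        coeff = float(match.group(1)) if match.group(1) else 1.0
        mid = match.group(2).strip()
        out[mid] = out.get(mid, 0.0) + coeff
    return out


def parse_equation(text: str) -> dict[str, float]:
    """Parse an equation string into metabolite -> signed coefficient."""
    for arrow in ("<=>", "-->", "<--", "->"):
        if arrow in text:
            left, right = text.split(arrow, 1)
            break
    else:
        raise ModelFormatError(f"equation {text!r} has no reaction arrow")
    stoich: dict[str, float] = {}
    for mid, coeff in _parse_side(left).items():
        stoich[mid] = stoich.get(mid, 0.0) - coeff
    for mid, coeff in _parse_side(right).items():
        stoich[mid] = stoich.get(mid, 0.0) + coeff
    if not stoich:
        raise ModelFormatError(f"equation {text!r} has no metabolites")
    return stoich


_COMPARTMENT_RE = re.compile(r"\[([^\[\]]+)\]$")


def _compartment_of(met_id: str) -> str:
    match = _COMPARTMENT_RE.search(met_id)
    return match.group(1) if match else "c"


# -- tabular schema ----------------------------------------------------

def model_to_table(model: ModelStruct, medium: Optional[Mapping[str, float]] = None) -> pd.DataFrame:
    """Flatten a model into the one-row-per-reaction ModelTable.

    ``in_medium`` is true for exchange reactions whose metabolite
    appears in ``medium``; with no medium given, for exchange reactions
    with a negative lower bound (i.e. uptake currently allowed).
    """
    rows = []
    for rec in model.reactions:
        if rec.is_exchange:
            if medium is not None:
                met = model.exchange_metabolite(rec.id)
                in_medium = met in medium
            else:
                in_medium = rec.lower_bound < 0
        else:
            in_medium = False
        rows.append(
            {
                "reaction_id": rec.id,
                "equation_string": format_equation(model, rec.id),
                "lower_bound": rec.lower_bound,
                "upper_bound": rec.upper_bound,
                "gpr_text": rec.gpr_text,
                "objective_coefficient": model.objective.get(rec.id, 0.0),
                "in_medium": bool(in_medium),
                "pathway": rec.pathway,
            }
        )
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def table_to_model(table: pd.DataFrame) -> ModelStruct:
    """Rebuild a ModelStruct from a ModelTable (inverse of model_to_table)."""
    missing = [c for c in TABLE_COLUMNS if c not in table.columns and c not in ("in_medium", "pathway")]
    if missing:
        raise ModelFormatError(f"model table is missing columns {missing}")
    metabolites: dict[str, str] = {}
    stoich: dict[tuple[str, str], float] = {}
    reactions: list[ReactionRec] = []
    objective: dict[str, float] = {}
    for _, row in table.iterrows():
        rid = str(row["reaction_id"])
        try:
            coeffs = parse_equation(str(row["equation_string"]))
            gpr_text = row.get("gpr_text", "")
            gpr_text = "" if pd.isna(gpr_text) else str(gpr_text)
            pathway = row.get("pathway", "")
            pathway = "" if pd.isna(pathway) else str(pathway)
            rec = ReactionRec(
                id=rid,
                lower_bound=float(row["lower_bound"]),
                upper_bound=float(row["upper_bound"]),
                gpr_text=gpr_text,
                pathway=pathway,
            )
        except (ModelFormatError, GPRParseError, ValueError) as exc:
            raise ModelFormatError(f"row for reaction {rid!r}: {exc}") from exc
        reactions.append(rec)
        for mid, coeff in coeffs.items():
            metabolites.setdefault(mid, _compartment_of(mid))
            stoich[(mid, rid)] = coeff
        obj = float(row.get("objective_coefficient", 0.0) or 0.0)
        if obj:
            objective[rid] = obj
    return ModelStruct(
        metabolites=list(metabolites.items()),
        reactions=reactions,
        stoichiometry=stoich,
        objective=objective,
    )


def read_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    if "in_medium" in table.columns:
        table["in_medium"] = table["in_medium"].astype(bool)
    return table


def write_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def model_summary(model: ModelStruct) -> dict[str, int]:
    """Counts of metabolites, reactions, and distinct genes across GPRs."""
    return {
        "n_metabolites": len(model.metabolites),
        "n_reactions": len(model.reactions),
        "n_genes": len(model.genes()),
    }
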