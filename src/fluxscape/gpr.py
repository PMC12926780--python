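"""Gene-protein-reaction (GPR) rules and Reaction Activity Scores.

A GPR rule is a Boolean expression over gene identifiers, e.g.
``(g1 and g2) or g3``, describing which gene products can catalyse a
reaction: ``and`` joins subunits of a complex, ``or`` joins isoenzymes.

The Reaction Activity Score (RAS) turns such a rule into a quantitative
proxy for a reaction's catalytic capacity given an expression profile:
``or`` is evaluated as a *sum* (isoenzymes are redundant, capacities
add) and ``and`` as a *minimum* (a complex is limited by its scarcest
subunit).  Genes absent from the expression data are dropped from sums
and minima; a node whose operands are all absent evaluates to MISSING,
represented as ``None`` at the scalar level and ``NaN`` inside
matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GPRNode",
    "GPRParseError",
    "parse_gpr",
    "eval_ras",
    "gpr_genes",
    "expression_to_ras",
    "read_expression",
    "write_ras",
]

logger = logging.getLogger(__name__)


class GPRParseError(ValueError):
    """Raised when a GPR string cannot be parsed; carries the token position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at token {position})")
        self.position = position


@dataclass(frozen=True)
class GPRNode:
    """Node of a GPR expression tree.

    ``kind`` is one of ``"gene"``, ``"and"``, ``"or"``.  Gene leaves
    carry ``gene_id``; internal nodes carry at least two ``children``.
    """

    kind: str
    gene_id: Optional[str] = None
    children: tuple["GPRNode", ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.kind == "gene":
            if not self.gene_id:
                raise ValueError("gene node requires gene_id")
        elif self.kind in ("and", "or"):
            if len(self.children) < 2:
                raise ValueError(f"{self.kind!r} node requires >= 2 children")
        else:
            raise ValueError(f"unknown GPR node kind {self.kind!r}")

    def genes(self) -> Iterator[str]:
        """Yield every gene id in the tree (with repeats, in order)."""
        if self.kind == "gene":
            yield self.gene_id  # type: ignore[misc]
        else:
            for child in self.children:
                yield from child.genes()

    def to_text(self) -> str:
        if self.kind == "gene":
            return self.gene_id  # type: ignore[return-value]
        sep = f" {self.kind} "
        parts = []
        for child in self.children:
            text = child.to_text()
            # parenthesize an 'or' child under an 'and' parent
            if self.kind == "and" and child.kind == "or":
                text = f"({text})"
            parts.append(text)
        return sep.join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_text()


def _tokenize(text: str) -> list[str]:
    tokens: list[str] = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch.isspace():
            i += 1
        elif ch in "()":
            tokens.append(ch)
            i += 1
        else:
            j = i
            while j < len(text) and not text[j].isspace() and text[j] not in "()":
                j += 1
            tokens.append(text[i:j])
            i = j
    return tokens


def parse_gpr(text: str) -> GPRNode:
    """Parse a GPR rule string into a :class:`GPRNode` tree.

    ``and`` binds tighter than ``or``; both operators are
    case-insensitive; parentheses override precedence.  Raises
    :class:`GPRParseError` with a 1-based token position on malformed
    input (unbalanced parentheses, dangling operators, empty text).
    """
    tokens = _tokenize(text)
    if not tokens:
        raise GPRParseError("empty GPR expression", 0)
    pos = 0

    def peek() -> Optional[str]:
        return tokens[pos] if pos < len(tokens) else None

    def is_op(tok: Optional[str], op: str) -> bool:
        return tok is not None and tok.lower() == op

    def parse_atom() -> GPRNode:
        nonlocal pos
        tok = peek()
        if tok is None:
            raise GPRParseError("unexpected end of expression", pos + 1)
        if tok == "(":
            pos += 1
            node = parse_or()
            if peek() != ")":
                raise GPRParseError("unbalanced parenthesis", pos + 1)
            pos += 1
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise GPRParseError(f"unexpected token {tok!r}", pos + 1)
        pos += 1
        return GPRNode("gene", gene_id=tok)

    def parse_and() -> GPRNode:
        nonlocal pos
        operands = [parse_atom()]
        while is_op(peek(), "and"):
            pos += 1
            operands.append(parse_atom())
        if len(operands) == 1:
            return operands[0]
        return GPRNode("and", children=tuple(operands))

    def parse_or() -> GPRNode:
        nonlocal pos
        operands = [parse_and()]
        while is_op(peek(), "or"):
            pos += 1
            operands.append(parse_and())
        if len(operands) == 1:
            return operands[0]
        return GPRNode("or", children=tuple(operands))

    node = parse_or()
    if pos != len(tokens):
        raise GPRParseError(f"unexpected token {tokens[pos]!r}", pos + 1)
    return node


def eval_ras(node: GPRNode, expr: Mapping[str, float]) -> Optional[float]:
    """Evaluate a RAS for one GPR tree against one expression profile.

    ``expr`` maps gene id to a non-negative expression value; genes not
    in the mapping are treated as absent.  Returns ``None`` (MISSING)
    when every gene of the rule is absent.
    """
    if node.kind == "gene":
        value = expr.get(node.gene_id)  # type: ignore[arg-type]
        return None if value is None else float(value)
    parts = [eval_ras(child, expr) for child in node.children]
    present = [p for p in parts if p is not None]
    if not present:
        return None
    if node.kind == "or":
        return float(sum(present))
    return float(min(present))


def gpr_genes(node: GPRNode) -> set[str]:
    """Distinct gene ids referenced by a GPR tree."""
    return set(node.genes())


def expression_to_ras(model, expr: pd.DataFrame) -> pd.DataFrame:
    """Compute the RAS matrix (reactions x samples) for a model.

    Parameters
    ----------
    model:
        A :class:`~fluxscape.model_io.ModelStruct` whose reactions carry
        parsed GPRs.
    expr:
        Expression matrix, genes as index, samples as columns, values
        non-negative.  Gene ids are matched by exact string comparison
        after stripping surrounding whitespace; duplicated gene ids are
        an error.

    Returns
    -------
    pandas.DataFrame
        Reactions x samples; ``NaN`` marks MISSING (no GPR, or no gene
        of the GPR present in the data).  ``result.attrs["gene_coverage"]``
        holds the fraction of the model's genes found in the expression
        data; it is also logged.

    Raises
    ------
    ValueError
        If the expression index contains duplicates or shares no gene
        with the model.
    """
    expr = expr.copy()
    expr.index = expr.index.astype(str).str.strip()
    dup = expr.index[expr.index.duplicated()].unique()
    if len(dup):
        raise ValueError(f"duplicate gene ids in expression data: {sorted(dup)}")
    if (expr.to_numpy(dtype=float) < 0).any():
        raise ValueError("expression values must be non-negative")

    model_genes: set[str] = set()
    for rec in model.reactions:
        if rec.gpr is not None:
            model_genes |= gpr_genes(rec.gpr)
    found = model_genes & set(expr.index)
    if model_genes and not found:
        raise ValueError(
            "no overlap between model genes and expression genes; "
            f"model has {len(model_genes)} genes, expression has {len(expr.index)} rows"
        )
    coverage = len(found) / len(model_genes) if model_genes else 0.0
    logger.info("gene coverage: %d/%d model genes found (%.1f%%)",
                len(found), len(model_genes), 100 * coverage)

    columns = {
        sample: {g: float(v) for g, v in expr[sample].items() if pd.notna(v)}
        for sample in expr.columns
    }
    rows = {}
    for rec in model.reactions:
        if rec.gpr is None:
            rows[rec.id] = [np.nan] * len(expr.columns)
            continue
        scores = []
        for sample in expr.columns:
            value = eval_ras(rec.gpr, columns[sample])
            scores.append(np.nan if value is None else value)
        rows[rec.id] = scores
    ras = pd.DataFrame.from_dict(rows, orient="index", columns=list(expr.columns))
    ras.attrs["gene_coverage"] = coverage
    return ras


def read_expression(path) -> pd.DataFrame:
    """Read a tab-separated expression table (gene id column first, header row)."""
    expr = pd.read_csv(path, sep="\t", index_col=0)
    expr.index = expr.index.astype(str).str.strip()
    return expr


def write_ras(ras: pd.DataFrame, path) -> None:
    """Write a RAS matrix as TSV; MISSING cells serialize as ``None``."""
    out = ras.copy()
    out.index.name = "reaction_id"
    out.to_csv(path, sep="\t", na_rep="None")
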