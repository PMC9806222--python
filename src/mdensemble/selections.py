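"""Mini selection grammar over :class:`~mdensemble.structure_io.StructureModel`.

Grammar (case-insensitive keywords, names matched case-sensitively except
elements):

    expr      := term ( 'or' term )*
    term      := factor ( 'and' factor )*
    factor    := 'not' factor | '(' expr ')' | primitive
    primitive := 'name' WORD+ | 'resname' WORD+ | 'chain' WORD+
               | 'element' WORD+ | 'resid' RANGE+ | 'water' | 'protein'
               | 'hetero' | 'all'
    RANGE     := INT | INT '-' INT | INT ':' INT

``water`` matches common water residue names; ``protein`` matches standard
amino-acid residue names.  Unknown chain or residue-name tokens raise a
:class:`SelectionError` listing what the model actually contains; ``resid``
ranges over gaps simply match nothing (missing residues are not an error).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .constants import AMINO_ACIDS, WATER_RESNAMES
from .errors import SelectionError

_KEYWORDS = {"name", "resname", "chain", "element", "resid",
             "water", "protein", "hetero", "all", "and", "or", "not"}


@dataclass(frozen=True)
class AtomSelection:
    """Ordered unique atom indices with the expression that produced them."""

    indices: np.ndarray
    expression: str
    label: str

    def __post_init__(self):
        idx = np.asarray(self.indices, dtype=int)
        if idx.size and (np.any(np.diff(idx) <= 0) or idx.min() < 0):
            raise SelectionError("selection indices must be unique and ascending")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return int(self.indices.size)


def _tokenize(expression: str) -> list[str]:
    tokens = re.findall(r"\(|\)|[^\s()]+", expression)
    if not tokens:
        raise SelectionError("empty selection expression")
    return tokens


class _Parser:
    def __init__(self, model, tokens):
        self.model = model
        self.tokens = tokens
        self.pos = 0

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self):
        tok = self.peek()
        if tok is None:
            raise SelectionError("unexpected end of selection expression")
        self.pos += 1
        return tok

    def parse(self):
        mask = self.expr()
        if self.peek() is not None:
            raise SelectionError(f"unexpected token {self.peek()!r}")
        return mask

    def expr(self):
        mask = self.term()
        while self.peek() is not None and self.peek().lower() == "or":
            self.next()
            mask = mask | self.term()
        return mask

    def term(self):
        mask = self.factor()
        while self.peek() is not None and self.peek().lower() == "and":
            self.next()
            mask = mask & self.factor()
        return mask

    def factor(self):
        tok = self.peek()
        if tok is None:
            raise SelectionError("dangling operator in selection expression")
        if tok.lower() == "not":
            self.next()
            return ~self.factor()
        if tok == "(":
            self.next()
            mask = self.expr()
            if self.next() != ")":
                raise SelectionError("unbalanced parentheses in selection")
            return mask
        return self.primitive()

    def _values(self):
        vals = []
        while True:
            tok = self.peek()
            if tok is None or tok.lower() in _KEYWORDS or tok in "()":
                break
            vals.append(self.next())
        if not vals:
            raise SelectionError("selection keyword expects at least one value")
        return vals

    def primitive(self):
        m = self.model
        n = m.n_atoms
        tok = self.next().lower()
        if tok == "all":
            return np.ones(n, dtype=bool)
        if tok == "water":
            return np.isin(m.resname, list(WATER_RESNAMES))
        if tok == "protein":
            return np.isin(m.resname, list(AMINO_ACIDS))
        if tok == "hetero":
            return m.hetero.copy()
        if tok == "name":
            return np.isin(m.name, self._values())
        if tok == "element":
            vals = [v.upper() for v in self._values()]
            return np.isin(np.char.upper(m.element.astype(str)), vals)
        if tok == "chain":
            vals = self._values()
            available = sorted(set(m.chain.tolist()))
            unknown = [v for v in vals if v not in available]
            if unknown:
                raise SelectionError(
                    f"unknown chain(s) {unknown}; available chains: {available}"
                )
            return np.isin(m.chain, vals)
        if tok == "resname":
            vals = self._values()
            available = sorted(set(m.resname.tolist()))
            unknown = [v for v in vals if v not in available]
            if unknown:
                raise SelectionError(
                    f"unknown residue name(s) {unknown}; available: {available}"
                )
            return np.isin(m.resname, vals)
        if tok == "resid":
            mask = np.zeros(n, dtype=bool)
            for val in self._values():
                rng = re.fullmatch(r"(-?\d+)\s*[-:]\s*(-?\d+)", val)
                if rng:
                    lo, hi = int(rng.group(1)), int(rng.group(2))
                    mask |= (m.resid >= lo) & (m.resid <= hi)
                elif re.fullmatch(r"-?\d+", val):
                    mask |= m.resid == int(val)
                else:
                    raise SelectionError(f"bad resid token {val!r}")
            return mask
        raise SelectionError(f"unknown selection keyword {tok!r}")


def evaluate_selection(model, expression: str) -> np.ndarray:
    """Boolean atom mask for ``expression`` over ``model``."""
    return _Parser(model, _tokenize(expression)).parse()
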