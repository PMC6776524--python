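"""A small atom-selection language.

Supports the keywords needed by the analyses in this package::

    all
    backbone                      # atoms named N, CA, C, O
    heavy                         # element != H
    name CA CB ...
    element C N O ...
    resname POP YOD ...
    resid 1961-2063 2091 ...      # integers and inclusive ranges (also 'a:b')
    chain A B ...
    index 0-99 ...                # 0-based atom indices

combined with ``and``, ``or``, ``not`` and parentheses; ``not`` binds
tightest, then ``and``, then ``or``.  Evaluation returns a sorted array of
0-based atom indices.
"""

from __future__ import annotations

import re

import numpy as np

BACKBONE_ATOMS = ("N", "CA", "C", "O")

_KEYWORDS = {"name", "element", "resname", "resid", "chain", "index"}
_NULLARY = {"all", "backbone", "heavy"}
_OPERATORS = {"and", "or", "not", "(", ")"}

_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


class SelectionError(ValueError):
    """Raised for syntax errors or unknown keywords in a selection string."""


def _tokenize(expr: str) -> list[str]:
    tokens = _TOKEN_RE.findall(expr)
    if not tokens:
        raise SelectionError("empty selection string")
    return tokens


class _Parser:
    def __init__(self, tokens: list[str], topology):
        self.tokens = tokens
        self.pos = 0
        self.top = topology

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self):
        tok = self.peek()
        self.pos += 1
        return tok

    def parse(self) -> np.ndarray:
        mask = self.expr()
        if self.peek() is not None:
            raise SelectionError(f"unexpected token {self.peek()!r}")
        return mask

    def expr(self) -> np.ndarray:
        left = self.term()
        while self.peek() == "or":
            self.next()
            left = left | self.term()
        return left

    def term(self) -> np.ndarray:
        left = self.factor()
        while self.peek() == "and":
            self.next()
            left = left & self.factor()
        return left

    def factor(self) -> np.ndarray:
        tok = self.peek()
        if tok == "not":
            self.next()
            return ~self.factor()
        if tok == "(":
            self.next()
            inner = self.expr()
            if self.next() != ")":
                raise SelectionError("unbalanced parenthesis")
            return inner
        return self.primary()

    def _args(self) -> list[str]:
        args = []
        while True:
            tok = self.peek()
            if tok is None or tok in _OPERATORS or tok in _KEYWORDS or tok in _NULLARY:
                break
            args.append(self.next())
        if not args:
            raise SelectionError("keyword requires at least one argument")
        return args

    def primary(self) -> np.ndarray:
        top = self.top
        tok = self.next()
        if tok is None:
            raise SelectionError("incomplete selection expression")
        if tok == "all":
            return np.ones(top.n_atoms, dtype=bool)
        if tok == "backbone":
            return np.isin(top.names, BACKBONE_ATOMS)
        if tok == "heavy":
            return top.elements != "H"
        if tok == "name":
            return np.isin(top.names, self._args())
        if tok == "element":
            wanted = [a.capitalize() for a in self._args()]
            return np.isin(top.elements, wanted)
        if tok == "resname":
            return np.isin(top.resnames, self._args())
        if tok == "chain":
            return np.isin(top.chains, self._args())
        if tok in ("resid", "index"):
            values = top.resids if tok == "resid" else np.arange(top.n_atoms)
            mask = np.zeros(top.n_atoms, dtype=bool)
            for arg in self._args():
                lo, hi = _parse_range(arg)
                mask |= (values >= lo) & (values <= hi)
            return mask
        if tok in top.named_selections:
            mask = np.zeros(top.n_atoms, dtype=bool)
            mask[top.named_selections[tok]] = True
            return mask
        raise SelectionError(f"unknown selection keyword {tok!r}")


def _parse_range(arg: str) -> tuple[int, int]:
    m = re.fullmatch(r"(-?\d+)(?:[-:](-?\d+))?", arg)
    if m is None:
        raise SelectionError(f"cannot parse integer or range {arg!r}")
    lo = int(m.group(1))
    hi = int(m.group(2)) if m.group(2) is not None else lo
    if hi < lo:
        lo, hi = hi, lo
    return lo, hi


def select(topology, expr: str) -> np.ndarray:
    """Evaluate selection ``expr`` against ``topology`` → sorted atom indices."""
    mask = _Parser(_tokenize(expr), topology).parse()
    return np.flatnonzero(mask)
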