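"""Minimal atom-selection grammar.

Expressions combine field tests with ``and`` / ``or`` and parentheses::

    residue_name == CER
    atom_name in {HG, OD1} and residue_id != 3
    (residue_name == CER or residue_name == FFA) and atom_name == HG

Supported fields: ``residue_name``, ``atom_name``, ``residue_id``,
``element``. Operators: ``==``, ``!=``, ``in {a, b, ...}``. Values are bare
words (no quoting); ``residue_id`` values must be integers. Selection
returns a sorted tuple of atom indices and is deterministic.
"""

from __future__ import annotations

import re
from typing import Callable

from .model import AtomRecord, LabeledFrame, SelectionError

__all__ = ["select_atoms", "compile_selector"]

_FIELDS = {"residue_name", "atom_name", "residue_id", "element"}

_TOKEN_RE = re.compile(r"\s*(==|!=|\{|\}|\(|\)|,|[^\s(){},=!]+|=|!)")


def _tokenize(expr: str) -> list[str]:
    tokens: list[str] = []
    pos = 0
    while pos < len(expr):
        m = _TOKEN_RE.match(expr, pos)
        if m is None:
            if expr[pos:].strip():
                raise SelectionError(f"cannot tokenize selector at: {expr[pos:]!r}")
            break
        tok = m.group(1)
        if tok in ("=", "!"):
            raise SelectionError(f"unexpected {tok!r} in selector {expr!r}")
        tokens.append(tok)
        pos = m.end()
    return tokens


Predicate = Callable[[AtomRecord], bool]


class _Parser:
    """Recursive descent over:  or_expr -> and_expr ('or' and_expr)*
    and_expr -> atom ('and' atom)* ; atom -> '(' or_expr ')' | test."""

    def __init__(self, tokens: list[str], expr: str):
        self.tokens = tokens
        self.pos = 0
        self.expr = expr

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise SelectionError(f"unexpected end of selector: {self.expr!r}")
        self.pos += 1
        return tok

    def expect(self, want: str) -> None:
        tok = self.next()
        if tok != want:
            raise SelectionError(
                f"expected {want!r}, got {tok!r} in selector {self.expr!r}"
            )

    def parse(self) -> Predicate:
        pred = self.or_expr()
        if self.peek() is not None:
            raise SelectionError(
                f"trailing tokens {self.tokens[self.pos:]} in selector {self.expr!r}"
            )
        return pred

    def or_expr(self) -> Predicate:
        parts = [self.and_expr()]
        while self.peek() == "or":
            self.next()
            parts.append(self.and_expr())
        if len(parts) == 1:
            return parts[0]
        return lambda a: any(p(a) for p in parts)

    def and_expr(self) -> Predicate:
        parts = [self.atom()]
        while self.peek() == "and":
            self.next()
            parts.append(self.atom())
        if len(parts) == 1:
            return parts[0]
        return lambda a: all(p(a) for p in parts)

    def atom(self) -> Predicate:
        if self.peek() == "(":
            self.next()
            pred = self.or_expr()
            self.expect(")")
            return pred
        return self.test()

    def test(self) -> Predicate:
        field = self.next()
        if field not in _FIELDS:
            raise SelectionError(
                f"unknown field {field!r} (expected one of {sorted(_FIELDS)})"
            )
        op = self.next()
        if op == "in":
            self.expect("{")
            values: set[str] = set()
            while True:
                tok = self.next()
                if tok == "}":
                    break
                if tok == ",":
                    continue
                values.add(tok)
            converted = _convert_set(field, values)
            return lambda a, f=field, vs=converted: _get(a, f) in vs
        if op in ("==", "!="):
            value = _convert(field, self.next())
            if op == "==":
                return lambda a, f=field, v=value: _get(a, f) == v
            return lambda a, f=field, v=value: _get(a, f) != v
        raise SelectionError(f"unknown operator {op!r} in selector {self.expr!r}")


def _convert(field: str, value: str):
    if field == "residue_id":
        try:
            return int(value)
        except ValueError as exc:
            raise SelectionError(
                f"residue_id comparison needs an integer, got {value!r}"
            ) from exc
    return value


def _convert_set(field: str, values: set[str]) -> set:
    return {_convert(field, v) for v in values}


def _get(atom: AtomRecord, field: str):
    return getattr(atom, field)


def compile_selector(expr: str) -> Predicate:
    """Parse a selection expression into a reusable predicate."""
    tokens = _tokenize(expr)
    if not tokens:
        raise SelectionError("empty selector expression")
    return _Parser(tokens, expr).parse()


def select_atoms(frame: LabeledFrame, selector: str | Predicate) -> tuple[int, ...]:
    """Evaluate a selector against a frame.

    Returns atom indices in ascending order; a selector matching nothing
    returns an empty tuple (not an error).
    """
    pred = compile_selector(selector) if isinstance(selector, str) else selector
    return tuple(i for i, a in enumerate(frame.atoms) if pred(a))
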