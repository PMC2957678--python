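"""Bounded Linear Temporal Logic over timed traces.

Formulas are built from atomic propositions ``e1 ~ e2`` (arithmetic
expressions over species counts, compared with >=, <=, <, >, =), boolean
connectives, and the bounded until ``phi1 U^t phi2``.  The derived operators
are stored as their definitions: ``F^t phi == true U^t phi`` and
``G^t phi == !F^t !phi``; the printer recognizes the patterns and prints the
sugar back.

Semantics over a trace sigma = (s0,t0),(s1,t1),... with sojourn times t_i:
``sigma^k |= phi1 U^t phi2`` iff there is an i >= 0 with (a) the cumulative
sojourn of states k..k+i-1 at most t, (b) phi2 holding at state k+i, and
(c) phi1 holding at every state k..k+i-1.  Atomic propositions are evaluated
on single states; traces are piecewise constant so no interpolation is
involved.  Evaluation is vectorized: each subformula is evaluated at every
trace index in O(n log n), which makes checking multi-million-event
stochastic traces practical.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .simulate import Trace

__all__ = [
    "BLTLSyntaxError",
    "HorizonError",
    "Expression",
    "Var",
    "Const",
    "BinOp",
    "AtomicProposition",
    "Formula",
    "Not",
    "And",
    "Or",
    "Until",
    "F",
    "G",
    "TRUE",
    "parse_formula",
    "check",
    "required_horizon",
]


class BLTLSyntaxError(ValueError):
    """Formula text could not be parsed; carries the character position."""

    def __init__(self, message: str, pos: int | None = None):
        if pos is not None:
            message = f"{message} (at position {pos})"
        super().__init__(message)
        self.pos = pos


class HorizonError(ValueError):
    """Trace too short to decide the formula."""


# ---------------------------------------------------------------------------
# arithmetic expressions


@dataclass(frozen=True)
class Var:
    name: str

    def __str__(self) -> str:
        return self.name


@dataclass(frozen=True)
class Const:
    value: float

    def __str__(self) -> str:
        v = self.value
        return str(int(v)) if float(v).is_integer() and abs(v) < 1e15 else repr(v)


@dataclass(frozen=True)
class BinOp:
    op: str  # + - * / ^
    left: "Expression"
    right: "Expression"

    def __str__(self) -> str:
        return f"({self.left} {self.op} {self.right})"


Expression = Var | Const | BinOp


def _eval_expression(expr: Expression, trace: Trace) -> np.ndarray:
    if isinstance(expr, Const):
        return np.full(len(trace), float(expr.value))
    if isinstance(expr, Var):
        try:
            return trace.series(expr.name)
        except KeyError:
            raise NameError(
                f"unknown identifier {expr.name!r}; trace species: "
                f"{', '.join(trace.species)}"
            ) from None
    left = _eval_expression(expr.left, trace)
    right = _eval_expression(expr.right, trace)
    if expr.op == "+":
        return left + right
    if expr.op == "-":
        return left - right
    if expr.op == "*":
        return left * right
    if expr.op == "/":
        with np.errstate(divide="ignore", invalid="ignore"):
            return left / right
    if expr.op == "^":
        return left ** right
    raise AssertionError(expr.op)


# ---------------------------------------------------------------------------
# formulas


@dataclass(frozen=True)
class AtomicProposition:
    left: Expression
    cmp: str  # >= <= < > =
    right: Expression

    def __str__(self) -> str:
        return f"{self.left} {self.cmp} {self.right}"


@dataclass(frozen=True)
class Not:
    phi: "Formula"

    def __str__(self) -> str:
        return _print_formula(self)


@dataclass(frozen=True)
class And:
    left: "Formula"
    right: "Formula"

    def __str__(self) -> str:
        return _print_formula(self)


@dataclass(frozen=True)
class Or:
    left: "Formula"
    right: "Formula"

    def __str__(self) -> str:
        return _print_formula(self)


@dataclass(frozen=True)
class Until:
    left: "Formula"
    right: "Formula"
    bound: float

    def __post_init__(self) -> None:
        if not self.bound > 0:
            raise BLTLSyntaxError("temporal bound must be positive")

    def __str__(self) -> str:
        return _print_formula(self)


Formula = AtomicProposition | Not | And | Or | Until

#: Canonical always-true atom used by the derived F operator.
TRUE = AtomicProposition(Const(0.0), "<", Const(1.0))


def F(bound: float, phi: Formula) -> Until:
    """Bounded eventually: ``F^t phi == true U^t phi``."""
    return Until(TRUE, phi, bound)


def G(bound: float, phi: Formula) -> Not:
    """Bounded globally: ``G^t phi == !F^t !phi``."""
    return Not(F(bound, Not(phi)))


def _print_formula(phi: Formula) -> str:
    """Recursive printer recognizing the F/G derived-operator patterns."""
    if isinstance(phi, AtomicProposition):
        return f"{phi.left} {phi.cmp} {phi.right}"
    if isinstance(phi, Not):
        inner = phi.phi
        # G sugar: !(true U^t !psi)
        if isinstance(inner, Until) and inner.left == TRUE and isinstance(inner.right, Not):
            return f"G^{Const(inner.bound)}({_print_formula(inner.right.phi)})"
        return f"!({_print_formula(inner)})"
    if isinstance(phi, And):
        return f"({_print_formula(phi.left)}) & ({_print_formula(phi.right)})"
    if isinstance(phi, Or):
        return f"({_print_formula(phi.left)}) | ({_print_formula(phi.right)})"
    if isinstance(phi, Until):
        if phi.left == TRUE:
            return f"F^{Const(phi.bound)}({_print_formula(phi.right)})"
        return f"({_print_formula(phi.left)}) U^{Const(phi.bound)} ({_print_formula(phi.right)})"
    raise TypeError(f"not a formula: {phi!r}")


def required_horizon(phi: Formula) -> float:
    """Cumulative sojourn sufficient to decide ``phi`` on any trace.

    AP -> 0; !phi -> h(phi); and/or -> max of the sides;
    ``phi1 U^t phi2`` -> t + max(h(phi1), h(phi2)).
    """
    if isinstance(phi, AtomicProposition):
        return 0.0
    if isinstance(phi, Not):
        return required_horizon(phi.phi)
    if isinstance(phi, (And, Or)):
        return max(required_horizon(phi.left), required_horizon(phi.right))
    if isinstance(phi, Until):
        return phi.bound + max(
            required_horizon(phi.left), required_horizon(phi.right)
        )
    raise TypeError(f"not a formula: {phi!r}")


# ---------------------------------------------------------------------------
# evaluation


def _next_true(b: np.ndarray) -> np.ndarray:
    """next_true[k] = smallest index >= k where b holds, len(b) if none."""
    from ._kernels import next_true_scan

    return next_true_scan(np.ascontiguousarray(b))


def _eval_formula(phi: Formula, trace: Trace, cache: dict) -> np.ndarray:
    # frozen dataclasses hash structurally, so equal subformulas share work
    key = phi
    if key in cache:
        return cache[key]
    if isinstance(phi, AtomicProposition):
        left = _eval_expression(phi.left, trace)
        right = _eval_expression(phi.right, trace)
        if phi.cmp == ">=":
            out = left >= right
        elif phi.cmp == "<=":
            out = left <= right
        elif phi.cmp == ">":
            out = left > right
        elif phi.cmp == "<":
            out = left < right
        elif phi.cmp == "=":
            out = left == right
        else:  # pragma: no cover
            raise AssertionError(phi.cmp)
    elif isinstance(phi, Not):
        out = ~_eval_formula(phi.phi, trace, cache)
    elif isinstance(phi, And):
        out = _eval_formula(phi.left, trace, cache) & _eval_formula(
            phi.right, trace, cache
        )
    elif isinstance(phi, Or):
        out = _eval_formula(phi.left, trace, cache) | _eval_formula(
            phi.right, trace, cache
        )
    elif isinstance(phi, Until):
        b2 = _eval_formula(phi.right, trace, cache)
        from ._kernels import window_end

        # j_k: largest index whose cumulative sojourn from k is within the
        # bound, i.e. entry_time <= entry_time[k] + t  (clause (a), <=)
        j = window_end(trace.times, float(phi.bound))
        nt2 = _next_true(b2)
        if phi.left == TRUE:  # derived F: clause (c) vacuous
            out = nt2 <= j
        else:
            b1 = _eval_formula(phi.left, trace, cache)
            nf1 = _next_true(~b1)
            out = (nt2 <= j) & (nt2 <= nf1)
    else:
        raise TypeError(f"not a formula: {phi!r}")
    cache[key] = out
    return out


def check(formula: Formula, trace: Trace, start_index: int = 0) -> bool:
    """Decide ``trace^start_index |= formula``.

    Raises :class:`HorizonError` when the trace's cumulative sojourn past the
    start index is shorter than :func:`required_horizon` (never silently
    false), and :class:`NameError` for unknown identifiers.
    """
    if not 0 <= start_index < len(trace):
        raise IndexError(f"start index {start_index} outside trace")
    needed = required_horizon(formula)
    available = trace.horizon - trace.times[start_index]
    if available < needed:
        raise HorizonError(
            f"trace horizon {available:g} min from state {start_index} is "
            f"shorter than the {needed:g} min the formula requires"
        )
    return bool(_eval_formula(formula, trace, {})[start_index])


def check_many(formulas, trace: Trace) -> list[bool]:
    """Check several formulas on one trace, sharing subformula evaluations.

    Equivalent to ``[check(f, trace) for f in formulas]`` but evaluates
    common subformulas (and the trace's species series) once, which matters
    on multi-million-event stochastic traces.
    """
    cache: dict = {}
    out = []
    for phi in formulas:
        if trace.horizon < required_horizon(phi):
            raise HorizonError(
                f"trace horizon {trace.horizon:g} min is shorter than the "
                f"{required_horizon(phi):g} min the formula requires"
            )
        out.append(bool(_eval_formula(phi, trace, cache)[0]))
    return out


# ---------------------------------------------------------------------------
# parser (recursive descent)

_TOKEN_RE = re.compile(
    r"""\s*(?:
      (?P<number>(?:\d+\.\d*|\.\d+|\d+)(?:[eE][+-]?\d+)?)
    | (?P<ident>[A-Za-z_][A-Za-z0-9_]*)
    | (?P<op>>=|<=|≥|≤|&&|\|\||[-+*/^()<>=!&|¬∧∨×÷])
    )""",
    re.VERBOSE,
)

_CMP_MAP = {">=": ">=", "≥": ">=", "<=": "<=", "≤": "<=", ">": ">", "<": "<", "=": "="}
_CMP_SET = set(_CMP_MAP)


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.tokens: list[tuple[str, str, int]] = []
        pos = 0
        while pos < len(text):
            m = _TOKEN_RE.match(text, pos)
            if m is None or m.end() == pos:
                if text[pos:].strip():
                    raise BLTLSyntaxError(
                        f"unexpected character {text[pos]!r}", pos
                    )
                break
            for kind in ("number", "ident", "op"):
                tok = m.group(kind)
                if tok is not None:
                    self.tokens.append((kind, tok, m.start(kind)))
                    break
            pos = m.end()
        self.i = 0

    # -- token helpers ----------------------------------------------------

    def peek(self, offset: int = 0):
        j = self.i + offset
        return self.tokens[j] if j < len(self.tokens) else (None, None, len(self.text))

    def next(self):
        tok = self.peek()
        self.i += 1
        return tok

    def expect(self, value: str) -> None:
        kind, tok, pos = self.next()
        if tok != value:
            raise BLTLSyntaxError(f"expected {value!r}, found {tok!r}", pos)

    # -- grammar ----------------------------------------------------------

    def parse(self) -> Formula:
        phi = self.parse_or()
        kind, tok, pos = self.peek()
        if kind is not None:
            raise BLTLSyntaxError(f"unexpected trailing {tok!r}", pos)
        return phi

    def parse_or(self) -> Formula:
        phi = self.parse_and()
        while self.peek()[1] in ("|", "||", "∨"):
            self.next()
            phi = Or(phi, self.parse_and())
        return phi

    def parse_and(self) -> Formula:
        phi = self.parse_until()
        while self.peek()[1] in ("&", "&&", "∧"):
            self.next()
            phi = And(phi, self.parse_until())
        return phi

    def parse_until(self) -> Formula:
        phi = self.parse_unary()
        if self.peek()[1] == "U":
            self.next()
            self.expect("^")
            bound = self.parse_bound()
            return Until(phi, self.parse_unary(), bound)
        return phi

    def parse_bound(self) -> float:
        kind, tok, pos = self.next()
        if kind != "number":
            raise BLTLSyntaxError("temporal bound must be a number", pos)
        bound = float(tok)
        # allow 10^3-style bounds
        if self.peek()[1] == "^":
            self.next()
            k2, t2, p2 = self.next()
            if k2 != "number":
                raise BLTLSyntaxError("exponent must be a number", p2)
            bound = bound ** float(t2)
        if not bound > 0:
            raise BLTLSyntaxError(f"temporal bound must be positive, got {bound:g}", pos)
        return bound

    def parse_unary(self) -> Formula:
        kind, tok, pos = self.peek()
        if tok in ("!", "¬"):
            self.next()
            return Not(self.parse_unary())
        if kind == "ident" and tok in ("F", "G") and self.peek(1)[1] == "^":
            self.next()
            self.next()  # ^
            bound = self.parse_bound()
            self.expect("(")
            phi = self.parse_or()
            self.expect(")")
            return F(bound, phi) if tok == "F" else G(bound, phi)
        if kind == "ident" and tok in ("true", "false"):
            self.next()
            return TRUE if tok == "true" else Not(TRUE)
        if tok == "(":
            # '(' may group a formula or start an arithmetic expression;
            # try the formula reading first, backtrack to a comparison
            save = self.i
            self.next()
            try:
                phi = self.parse_or()
                self.expect(")")
            except BLTLSyntaxError:
                self.i = save
            else:
                nxt = self.peek()[1]
                if nxt not in _CMP_SET and nxt not in ("+", "-", "*", "/", "^", "×", "÷"):
                    return phi
                self.i = save
        return self.parse_comparison()

    def parse_comparison(self) -> AtomicProposition:
        left = self.parse_arith()
        kind, tok, pos = self.next()
        if tok not in _CMP_SET:
            raise BLTLSyntaxError(f"expected comparison operator, found {tok!r}", pos)
        right = self.parse_arith()
        return AtomicProposition(left, _CMP_MAP[tok], right)

    def parse_arith(self) -> Expression:
        left = self.parse_term()
        while self.peek()[1] in ("+", "-"):
            op = self.next()[1]
            left = BinOp(op, left, self.parse_term())
        return left

    def parse_term(self) -> Expression:
        left = self.parse_factor()
        while self.peek()[1] in ("*", "/", "×", "÷"):
            op = self.next()[1]
            op = {"×": "*", "÷": "/"}.get(op, op)
            left = BinOp(op, left, self.parse_factor())
        return left

    def parse_factor(self) -> Expression:
        kind, tok, pos = self.peek()
        if tok == "-":
            self.next()
            return BinOp("-", Const(0.0), self.parse_factor())
        atom = self.parse_atom()
        if self.peek()[1] == "^":
            self.next()
            return BinOp("^", atom, self.parse_factor())  # right-assoc
        return atom

    def parse_atom(self) -> Expression:
        kind, tok, pos = self.next()
        if kind == "number":
            return Const(float(tok))
        if kind == "ident":
            return Var(tok)
        if tok == "(":
            e = self.parse_arith()
            self.expect(")")
            return e
        raise BLTLSyntaxError(f"expected expression, found {tok!r}", pos)


def parse_formula(text: str) -> Formula:
    """Parse a BLTL formula string.

    Grammar (loosest to tightest): ``|``, ``&``, ``U^t``, ``!``/``F^t``/
    ``G^t``, comparisons over infix arithmetic (+ - * / ^, parentheses,
    numbers like ``5.3*10^4``).  Species identifiers may use the ``_a``/
    ``_p`` active/phosphorylated suffixes and ``X_tot`` conserved totals.
    """
    return _Parser(text).parse()


def format_formula(phi: Formula) -> str:
    """Canonical string form; ``parse_formula`` round-trips it."""
    return _print_formula(phi)
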