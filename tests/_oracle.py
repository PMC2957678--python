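"""Brute-force reference evaluator for BLTL, independent of the main checker.

Implements the four semantic clauses by naive recursion over state indices:
for the bounded until it enumerates every candidate index i and explicitly
sums sojourn times, with no vectorization or sliding windows.  Used only to
cross-check :func:`hmgb1smc.bltl.check` on small traces.
"""

from hmgb1smc.bltl import And, AtomicProposition, Formula, Not, Or, Until
from hmgb1smc.simulate import Trace


def _eval_expr(expr, trace: Trace, k: int) -> float:
    from hmgb1smc.bltl import BinOp, Const, Var

    if isinstance(expr, Const):
        return float(expr.value)
    if isinstance(expr, Var):
        return float(trace.series(expr.name)[k])
    assert isinstance(expr, BinOp)
    left = _eval_expr(expr.left, trace, k)
    right = _eval_expr(expr.right, trace, k)
    if expr.op == "+":
        return left + right
    if expr.op == "-":
        return left - right
    if expr.op == "*":
        return left * right
    if expr.op == "/":
        return left / right if right != 0 else float("inf") * (1 if left > 0 else -1 if left < 0 else 0)
    if expr.op == "^":
        return left ** right
    raise AssertionError(expr.op)


def oracle_check(phi: Formula, trace: Trace, k: int = 0) -> bool:
    """Naive recursive evaluation of ``trace^k |= phi``."""
    n = len(trace)
    sojourns = trace.sojourns()
    if isinstance(phi, AtomicProposition):
        left = _eval_expr(phi.left, trace, k)
        right = _eval_expr(phi.right, trace, k)
        return {
            ">=": left >= right,
            "<=": left <= right,
            ">": left > right,
            "<": left < right,
            "=": left == right,
        }[phi.cmp]
    if isinstance(phi, Not):
        return not oracle_check(phi.phi, trace, k)
    if isinstance(phi, And):
        return oracle_check(phi.left, trace, k) and oracle_check(phi.right, trace, k)
    if isinstance(phi, Or):
        return oracle_check(phi.left, trace, k) or oracle_check(phi.right, trace, k)
    assert isinstance(phi, Until)
    for i in range(n - k):
        elapsed = sum(sojourns[k + l] for l in range(i))  # clause (a)
        if elapsed > phi.bound:
            break
        if oracle_check(phi.right, trace, k + i):  # clause (b)
            if all(oracle_check(phi.left, trace, k + j) for j in range(i)):  # (c)
                return True
    return False
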