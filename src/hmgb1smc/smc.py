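"""Bayesian statistical model checking by sequential hypothesis testing.

Decides between H0: p >= theta and H1: p < theta, where p is the (unknown)
probability that a sampled trace satisfies a BLTL formula.  Each simulated
trace contributes one Bernoulli outcome; after each sample the Bayes factor

    B_n = P(data | H0) / P(data | H1)
        = (P(H1) / P(H0)) * (1 / F_(x+alpha, n-x+beta)(theta) - 1)

is evaluated in closed form through the regularized incomplete Beta function
F (no numerical integration), where x is the number of successes among n
samples and Beta(alpha, beta) is the prior on p.  Sampling stops as soon as
B > T (accept H0) or B < 1/T (reject H0); the error probability of the
procedure is bounded by 1/T.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

from scipy.special import betainc

from .bltl import Formula, check, parse_formula, required_horizon
from .reaction_model import ReactionNetwork
from .simulate import SimulationConfig, simulate_ssa

__all__ = [
    "HypothesisTestSpec",
    "SMCResult",
    "bayes_factor",
    "smc_decide",
    "error_bound",
    "verify_property",
]


@dataclass(frozen=True)
class HypothesisTestSpec:
    """Test configuration: threshold theta, Bayes-factor threshold T, prior.

    The default prior is the uniform Beta(1, 1) with equal hypothesis priors.
    ``max_samples`` caps the sequential procedure (verdict "undecided" when
    reached) so the tool always terminates.
    """

    theta: float = 0.9
    bayes_threshold: float = 1000.0
    alpha: float = 1.0
    beta: float = 1.0
    p_h0: float = 0.5
    p_h1: float = 0.5
    max_samples: int = 100_000

    def __post_init__(self) -> None:
        if not 0.0 < self.theta < 1.0:
            raise ValueError("theta must lie in (0, 1)")
        if self.bayes_threshold <= 1.0:
            raise ValueError("Bayes factor threshold T must exceed 1")
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("Beta prior parameters must be positive")
        if self.p_h0 <= 0 or self.p_h1 <= 0:
            raise ValueError("prior hypothesis probabilities must be positive")
        if abs(self.p_h0 + self.p_h1 - 1.0) > 1e-12:
            raise ValueError("prior hypothesis probabilities must sum to 1")
        if self.max_samples < 1:
            raise ValueError("max_samples must be positive")


@dataclass(frozen=True)
class SMCResult:
    """Outcome of a sequential run."""

    verdict: str  # accept_h0 | reject_h0 | undecided
    n: int
    x: int
    final_bayes_factor: float
    sample_log: tuple = ()

    @property
    def satisfied(self) -> bool | None:
        """True/False for decided runs, None when undecided."""
        if self.verdict == "accept_h0":
            return True
        if self.verdict == "reject_h0":
            return False
        return None


def bayes_factor(x: int, n: int, spec: HypothesisTestSpec) -> float:
    """Bayes factor of H0: p >= theta vs H1: p < theta after n samples.

    Exact closed form via the regularized incomplete Beta function; with
    zero samples it reduces to the prior odds times (1/F_prior(theta) - 1).
    """
    if not 0 <= x <= n:
        raise ValueError(f"need 0 <= x <= n, got x={x}, n={n}")
    F = float(betainc(x + spec.alpha, n - x + spec.beta, spec.theta))
    if F <= 0.0:
        # mathematically impossible for theta in (0,1) with positive prior
        # parameters; reachable only through floating-point underflow
        raise ArithmeticError(
            "posterior mass below theta underflowed; Bayes factor overflows"
        )
    return (spec.p_h1 / spec.p_h0) * (1.0 / F - 1.0)


def error_bound(spec: HypothesisTestSpec) -> float:
    """Upper bound 1/T on the probability of a wrong verdict."""
    return 1.0 / spec.bayes_threshold


def smc_decide(
    sampler: Callable[[], int],
    spec: HypothesisTestSpec,
    record_log: bool = False,
) -> SMCResult:
    """Run the sequential test, drawing Bernoulli samples one at a time.

    ``sampler()`` must return 0 or 1 (1 = the trace satisfied the formula).
    Stops with ``accept_h0`` when B > T, ``reject_h0`` when B < 1/T, and
    ``undecided`` if ``max_samples`` is exhausted while 1/T <= B <= T.
    """
    n = 0
    x = 0
    log: list[int] = []
    B = bayes_factor(0, 0, spec)
    while n < spec.max_samples:
        try:
            outcome = int(sampler())
        except Exception as e:
            raise RuntimeError(f"sampler failed at sample {n + 1}: {e}") from e
        if outcome not in (0, 1):
            raise ValueError(f"sampler returned {outcome!r}, expected 0 or 1")
        n += 1
        x += outcome
        if record_log:
            log.append(outcome)
        B = bayes_factor(x, n, spec)
        if B > spec.bayes_threshold:
            return SMCResult("accept_h0", n, x, B, tuple(log))
        if B < 1.0 / spec.bayes_threshold:
            return SMCResult("reject_h0", n, x, B, tuple(log))
    return SMCResult("undecided", n, x, B, tuple(log))


def verify_property(
    network: ReactionNetwork,
    formula: Formula | str,
    spec: HypothesisTestSpec,
    base_seed: int,
    t_end: float | None = None,
) -> SMCResult:
    """Statistically model check ``Pr>=theta[formula]`` on a network.

    Draws SSA traces with seeds ``base_seed, base_seed + 1, ...`` (each
    recorded in the sample log as ``(seed, outcome)`` so any individual
    trace can be replayed), checks the formula on each, and feeds the
    outcomes to :func:`smc_decide`.  The trace horizon defaults to the
    formula's required horizon.
    """
    if isinstance(formula, str):
        formula = parse_formula(formula)
    horizon = required_horizon(formula)
    if horizon <= 0:
        horizon = 1.0  # state formulas need any positive-length trace
    if t_end is None:
        t_end = horizon
    elif t_end < horizon:
        raise ValueError(f"t_end {t_end:g} shorter than required horizon {horizon:g}")

    counter = {"i": 0}
    seeds_log: list[tuple[int, int]] = []

    def sampler() -> int:
        seed = base_seed + counter["i"]
        counter["i"] += 1
        trace = simulate_ssa(network, SimulationConfig(t_end=t_end, seed=seed))
        outcome = int(check(formula, trace))
        seeds_log.append((seed, outcome))
        return outcome

    result = smc_decide(sampler, spec)
    return SMCResult(
        result.verdict, result.n, result.x, result.final_bayes_factor,
        tuple(seeds_log),
    )
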