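"""Approximate probabilistic model checking of PBLSTL statements.

Whether ``P ~ theta [ psi ]`` holds for a stochastic model is decided from
Bernoulli observations -- the truth value of ``psi`` on successive sampled
traces -- using one of five algorithms:

* ``frequentist_hypothesis`` -- Wald sequential probability ratio test (SPRT)
  with an indifference region ``[theta - delta, theta + delta]`` and
  user-set type I/II error bounds;
* ``frequentist_estimate`` -- fixed-sample estimation with the
  Chernoff-Hoeffding sample-size bound;
* ``bayesian_hypothesis`` -- sequential Bayes-factor test on a Beta prior;
* ``bayesian_estimate`` -- sequential posterior-mean estimation stopping at
  a target credible-interval coverage;
* ``black_box`` -- fixed-sample verdict with an exact one-sided binomial
  p-value; never requests additional traces.

All sequential methods fall back to the black-box verdict on the
observations gathered so far when the trace provider is exhausted before a
decision is reached.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, replace

from scipy import stats

from .errors import (
    ParameterError,
    ProviderError,
    ProviderExhaustedError,
    UndecidableError,
)
from .logic.ast import PblstlStatement
from .logic.evaluator import evaluate_blstl
from .providers import TraceProvider

METHODS = (
    "frequentist_hypothesis",
    "frequentist_estimate",
    "bayesian_hypothesis",
    "bayesian_estimate",
    "black_box",
)


@dataclass
class CheckerConfig:
    """Parameters of the probabilistic checking algorithms.

    Only the parameters of the selected method are used.  ``type_i_error``
    / ``type_ii_error`` bound the SPRT error probabilities;
    ``indifference_half_width`` is the half-width of its indifference region
    around theta.  ``estimate_epsilon`` / ``estimate_delta`` are the
    Chernoff-Hoeffding approximation bound and its failure probability.
    ``bayes_factor_threshold`` is the decision threshold T of the Bayes
    factor test and ``prior_alpha``/``prior_beta`` the Beta prior;
    ``credible_half_width``/``credible_coverage`` are the stopping rule of
    the Bayesian estimate.  ``chernoff_constant`` is the numerator constant
    of the sample-size formula ``n = ceil(ln(constant / delta) / (2 eps^2))``
    (2 for the two-sided Hoeffding bound; some statistical checkers use 4).
    """

    method: str = "frequentist_hypothesis"
    type_i_error: float = 0.05
    type_ii_error: float = 0.05
    indifference_half_width: float = 0.05
    estimate_epsilon: float = 0.05
    estimate_delta: float = 0.05
    chernoff_constant: float = 2.0
    bayes_factor_threshold: float = 100.0
    prior_alpha: float = 1.0
    prior_beta: float = 1.0
    credible_half_width: float = 0.05
    credible_coverage: float = 0.95
    max_traces: int | None = None
    max_seconds: float | None = None

    def validate(self, theta: float | None = None) -> None:
        if self.method not in METHODS:
            raise ParameterError(f"unknown method {self.method!r}; "
                                 f"choose one of {METHODS}")
        for name in ("type_i_error", "type_ii_error", "estimate_epsilon",
                     "estimate_delta", "credible_coverage"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ParameterError(f"{name} must lie in (0, 1), got {v}")
        if self.bayes_factor_threshold <= 1.0:
            raise ParameterError("bayes_factor_threshold must be > 1")
        if self.prior_alpha <= 0 or self.prior_beta <= 0:
            raise ParameterError("prior_alpha and prior_beta must be > 0")
        if self.credible_half_width <= 0:
            raise ParameterError("credible_half_width must be > 0")
        if self.chernoff_constant <= 1.0:
            raise ParameterError("chernoff_constant must be > 1")
        if theta is not None and self.method == "frequentist_hypothesis":
            if not (0 < self.indifference_half_width < min(theta, 1.0 - theta)):
                raise ParameterError(
                    "indifference_half_width must lie in "
                    f"(0, min(theta, 1 - theta)) = (0, {min(theta, 1 - theta)}); "
                    f"got {self.indifference_half_width}"
                )


@dataclass
class CheckingResult:
    """Outcome of checking one statement over a collection of traces."""

    verdict: bool
    method_used: str
    n_total: int
    n_true: int
    n_false: int
    confidence: float
    exhausted: bool = False

    def __post_init__(self):
        assert self.n_total == self.n_true + self.n_false


def sample_next(provider: TraceProvider, formula) -> bool:
    """One Bernoulli observation: the formula's truth on the next trace."""
    trace = provider.next_trace()
    return bool(evaluate_blstl(formula, trace, 0))


def _estimate_verdict(p_hat: float, theta: float, comparator: str) -> bool:
    """Compare an estimate with theta; ties resolve to the closed side."""
    if p_hat == theta:
        return comparator in (">=", "<=")
    if comparator in (">=", ">"):
        return p_hat > theta
    return p_hat < theta


def chernoff_sample_size(epsilon: float, delta: float, constant: float = 2.0) -> int:
    """Hoeffding sample size ``ceil(ln(constant/delta) / (2 epsilon^2))``."""
    if not (0 < epsilon < 1):
        raise ParameterError(f"epsilon must lie in (0, 1), got {epsilon}")
    if not (0 < delta < 1):
        raise ParameterError(f"delta must lie in (0, 1), got {delta}")
    return math.ceil(math.log(constant / delta) / (2.0 * epsilon * epsilon))


# --- sequential decision engines -------------------------------------------

class _SequentialTest:
    """Incremental decision engine fed one Bernoulli observation at a time."""

    def __init__(self):
        self.n_true = 0
        self.n_false = 0
        self.decided = False
        self.verdict: bool | None = None
        self.confidence = float("nan")

    @property
    def n_total(self) -> int:
        return self.n_true + self.n_false

    def update(self, x: bool) -> None:
        if x:
            self.n_true += 1
        else:
            self.n_false += 1
        self._advance()

    def _advance(self) -> None:
        raise NotImplementedError


class SprtTest(_SequentialTest):
    """Wald SPRT of H0: p >= theta + delta against H1: p <= theta - delta.

    The log-likelihood ratio (of H1 over H0) is updated per observation;
    acceptance thresholds are the classical Wald bounds ``ln(beta/(1-alpha))``
    and ``ln((1-beta)/alpha)``.  ``confidence`` reports the log-likelihood
    ratio at the decision.
    """

    def __init__(self, statement: PblstlStatement, cfg: CheckerConfig):
        super().__init__()
        theta = statement.threshold
        delta = cfg.indifference_half_width
        cfg.validate(theta)
        self.comparator = statement.comparator
        self.p0 = theta + delta
        self.p1 = theta - delta
        self.log_accept_h0 = math.log(cfg.type_ii_error / (1.0 - cfg.type_i_error))
        self.log_accept_h1 = math.log((1.0 - cfg.type_ii_error) / cfg.type_i_error)
        self.inc_true = math.log(self.p1 / self.p0)
        self.inc_false = math.log((1.0 - self.p1) / (1.0 - self.p0))
        self.llr = 0.0

    def update(self, x: bool) -> None:
        self.llr += self.inc_true if x else self.inc_false
        super().update(x)

    def _advance(self) -> None:
        if self.llr <= self.log_accept_h0:
            accepted_h0 = True
        elif self.llr >= self.log_accept_h1:
            accepted_h0 = False
        else:
            return
        self.decided = True
        self.confidence = self.llr
        # H0 (p high) makes >=/> true; H1 (p low) makes </<= true
        if self.comparator in (">=", ">"):
            self.verdict = accepted_h0
        else:
            self.verdict = not accepted_h0


class ChernoffTest(_SequentialTest):
    """Fixed-sample frequentist estimate with the Hoeffding guarantee."""

    def __init__(self, statement: PblstlStatement, cfg: CheckerConfig):
        super().__init__()
        cfg.validate()
        self.comparator = statement.comparator
        self.theta = statement.threshold
        self.delta = cfg.estimate_delta
        self.n_required = chernoff_sample_size(cfg.estimate_epsilon,
                                               cfg.estimate_delta,
                                               cfg.chernoff_constant)

    def _advance(self) -> None:
        if self.n_total >= self.n_required:
            self.decided = True
            p_hat = self.n_true / self.n_total
            self.verdict = _estimate_verdict(p_hat, self.theta, self.comparator)
            self.confidence = self.delta


class BayesianHypothesisTest(_SequentialTest):
    """Sequential Bayes-factor test of H0 = {p : p ~ theta} on a Beta prior."""

    def __init__(self, statement: PblstlStatement, cfg: CheckerConfig):
        super().__init__()
        cfg.validate()
        self.comparator = statement.comparator
        self.theta = statement.threshold
        self.a = cfg.prior_alpha
        self.b = cfg.prior_beta
        self.threshold = cfg.bayes_factor_threshold
        self.bayes_factor = self._factor()

    def _h0_mass(self, a: float, b: float) -> float:
        upper = float(stats.beta.sf(self.theta, a, b))
        return upper if self.comparator in (">=", ">") else 1.0 - upper

    def _factor(self) -> float:
        prior = self._h0_mass(self.a, self.b)
        posterior = self._h0_mass(self.a + self.n_true, self.b + self.n_false)
        prior_odds = prior / (1.0 - prior) if prior < 1.0 else math.inf
        if posterior >= 1.0:
            return math.inf
        posterior_odds = posterior / (1.0 - posterior)
        return posterior_odds / prior_odds if prior_odds > 0 else math.inf

    def _advance(self) -> None:
        self.bayes_factor = self._factor()
        if self.bayes_factor >= self.threshold:
            self.decided, self.verdict = True, True
        elif self.bayes_factor <= 1.0 / self.threshold:
            self.decided, self.verdict = True, False
        self.confidence = self.bayes_factor


class BayesianEstimateTest(_SequentialTest):
    """Posterior-mean estimation; stops at the target credible coverage."""

    def __init__(self, statement: PblstlStatement, cfg: CheckerConfig):
        super().__init__()
        cfg.validate()
        self.comparator = statement.comparator
        self.theta = statement.threshold
        self.a = cfg.prior_alpha
        self.b = cfg.prior_beta
        self.half_width = cfg.credible_half_width
        self.coverage = cfg.credible_coverage

    def posterior_mean(self) -> float:
        return (self.a + self.n_true) / (self.a + self.b + self.n_total)

    def _advance(self) -> None:
        a = self.a + self.n_true
        b = self.b + self.n_false
        mean = self.posterior_mean()
        lo = max(0.0, mean - self.half_width)
        hi = min(1.0, mean + self.half_width)
        mass = float(stats.beta.cdf(hi, a, b) - stats.beta.cdf(lo, a, b))
        if mass >= self.coverage:
            self.decided = True
            self.verdict = _estimate_verdict(mean, self.theta, self.comparator)
            self.confidence = mass


_TEST_CLASSES = {
    "frequentist_hypothesis": SprtTest,
    "frequentist_estimate": ChernoffTest,
    "bayesian_hypothesis": BayesianHypothesisTest,
    "bayesian_estimate": BayesianEstimateTest,
}


# --- black box --------------------------------------------------------------

def black_box_result(statement: PblstlStatement, n_true: int, n_total: int,
                     method_used: str = "black_box",
                     exhausted: bool = False) -> CheckingResult:
    """Fixed-sample verdict with an exact one-sided binomial p-value.

    The p-value is the probability, under ``p = theta``, of an outcome at
    least as extreme as the observed success count in the direction of the
    concluded side (smaller = stronger support for the verdict).
    """
    if n_total == 0:
        raise UndecidableError("no observations available for a verdict")
    theta = statement.threshold
    p_hat = n_true / n_total
    verdict = _estimate_verdict(p_hat, theta, statement.comparator)
    if p_hat >= theta:  # concluded side: p at or above theta
        p_value = float(stats.binom.sf(n_true - 1, n_total, theta))
    else:
        p_value = float(stats.binom.cdf(n_true, n_total, theta))
    return CheckingResult(verdict=verdict, method_used=method_used,
                          n_total=n_total, n_true=n_true,
                          n_false=n_total - n_true, confidence=p_value,
                          exhausted=exhausted)


def check_black_box(statement: PblstlStatement, provider: TraceProvider,
                    cfg: CheckerConfig) -> CheckingResult:
    """Consume all available traces (or ``max_traces``) and decide once."""
    cfg.validate()
    n_true = n_total = 0
    while cfg.max_traces is None or n_total < cfg.max_traces:
        try:
            x = sample_next(provider, statement.formula)
        except ProviderExhaustedError:
            break
        n_true += int(x)
        n_total += 1
    return black_box_result(statement, n_true, n_total)


# --- sequential drivers ------------------------------------------------------

def _run_sequential(test: _SequentialTest, statement: PblstlStatement,
                    provider: TraceProvider, cfg: CheckerConfig,
                    method: str) -> CheckingResult:
    started = time.monotonic()
    exhausted = False
    while not test.decided:
        if cfg.max_traces is not None and test.n_total >= cfg.max_traces:
            exhausted = True
            break
        if cfg.max_seconds is not None \
                and time.monotonic() - started > cfg.max_seconds:
            exhausted = True
            break
        try:
            x = sample_next(provider, statement.formula)
        except ProviderExhaustedError:
            exhausted = True
            break
        test.update(x)
    if test.decided:
        return CheckingResult(verdict=test.verdict, method_used=method,
                              n_total=test.n_total, n_true=test.n_true,
                              n_false=test.n_false, confidence=test.confidence,
                              exhausted=False)
    # not enough traces for the requested method: black-box fallback on the
    # observations gathered so far
    return black_box_result(statement, test.n_true, test.n_total,
                            method_used="black_box", exhausted=True)


def _checker(method: str):
    def check(statement: PblstlStatement, provider: TraceProvider,
              cfg: CheckerConfig) -> CheckingResult:
        cfg = replace(cfg, method=method)
        cfg.validate(statement.threshold if method == "frequentist_hypothesis"
                     else None)
        test = _TEST_CLASSES[method](statement, cfg)
        return _run_sequential(test, statement, provider, cfg, method)
    return check


check_sprt = _checker("frequentist_hypothesis")
check_chernoff = _checker("frequentist_estimate")
check_bayesian_hypothesis = _checker("bayesian_hypothesis")
check_bayesian_estimate = _checker("bayesian_estimate")


def check_statement(statement: PblstlStatement, provider: TraceProvider,
                    cfg: CheckerConfig) -> CheckingResult:
    """Check one statement with the method selected in the configuration."""
    cfg.validate(statement.threshold)
    if cfg.method == "black_box":
        return check_black_box(statement, provider, cfg)
    test = _TEST_CLASSES[cfg.method](statement, cfg)
    return _run_sequential(test, statement, provider, cfg, cfg.method)


def check_specification(statements: list[PblstlStatement],
                        provider: TraceProvider,
                        cfg: CheckerConfig) -> list[CheckingResult]:
    """Check all statements in a single pass over the trace stream.

    Each loaded trace is evaluated against every statement still undecided,
    so every trace is read exactly once; the per-statement sequential tests
    advance independently and the results are identical to checking each
    statement alone against the same ordered provider.
    """
    if not statements:
        raise ParameterError("specification must contain at least one statement")
    cfg.validate()
    if cfg.method == "black_box":
        counts = [[0, 0] for _ in statements]  # n_true, n_total
        while cfg.max_traces is None or counts[0][1] < cfg.max_traces:
            try:
                trace = provider.next_trace()
            except ProviderExhaustedError:
                break
            for s, c in zip(statements, counts):
                c[0] += int(evaluate_blstl(s.formula, trace, 0))
                c[1] += 1
        return [black_box_result(s, c[0], c[1])
                for s, c in zip(statements, counts)]

    if cfg.method == "frequentist_hypothesis":
        for s in statements:
            cfg.validate(s.threshold)
    tests = [_TEST_CLASSES[cfg.method](s, cfg) for s in statements]
    started = time.monotonic()
    exhausted = False
    while not all(t.decided for t in tests):
        if cfg.max_traces is not None \
                and max(t.n_total for t in tests if not t.decided) >= cfg.max_traces:
            exhausted = True
            break
        if cfg.max_seconds is not None \
                and time.monotonic() - started > cfg.max_seconds:
            exhausted = True
            break
        try:
            trace = provider.next_trace()
        except ProviderExhaustedError:
            exhausted = True
            break
        for s, t in zip(statements, tests):
            if not t.decided:
                t.update(bool(evaluate_blstl(s.formula, trace, 0)))

    results = []
    for s, t in zip(statements, tests):
        if t.decided:
            results.append(CheckingResult(
                verdict=t.verdict, method_used=cfg.method, n_total=t.n_total,
                n_true=t.n_true, n_false=t.n_false, confidence=t.confidence,
                exhausted=False))
        else:
            results.append(black_box_result(s, t.n_true, t.n_total,
                                            method_used="black_box",
                                            exhausted=True))
    return results
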