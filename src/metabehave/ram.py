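"""Radial-arm-maze (RAM) working-memory scoring and Monte Carlo null models.

A trial is an ordered sequence of arm visits that ends when every arm has
been visited (or a visit cap was reached).  Revisits to already-visited
arms count as working-memory errors.  Observed error counts are compared
against two behavioural null models:

* a *random* null — arms drawn uniformly with replacement until all are
  visited (the coupon-collector process; for 8 arms the expected error
  count is 8*H_8 - 8 ~ 13.74);
* a *stereotypic* null — a first-order Markov chain whose transition
  matrix is estimated from the observed visit sequences, capturing fixed
  movement rules such as always turning clockwise.

The random model allows an immediate return to the arm just left; this is
the variant whose mean matches the coupon-collector expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy import stats

__all__ = [
    "RAMTrial",
    "TransitionMatrix",
    "NullDistribution",
    "TTestResult",
    "count_errors",
    "simulate_random_null",
    "estimate_transition_matrix",
    "simulate_stereotypic_null",
    "compare_to_null",
    "expected_random_errors",
    "random_errors_variance",
]


class RAMError(ValueError):
    """Invalid trial data or simulation parameters."""


@dataclass
class RAMTrial:
    """One chick's ordered arm-visit sequence in an n-arm maze."""

    chick_id: str
    trial_number: int
    visits: np.ndarray
    n_arms: int = 8

    def __post_init__(self) -> None:
        self.visits = np.asarray(self.visits, dtype=int)
        if self.visits.size == 0:
            raise RAMError("trial must contain at least one visit")
        if self.n_arms < 2:
            raise RAMError("a maze needs at least 2 arms")
        if self.visits.min() < 0 or self.visits.max() >= self.n_arms:
            raise RAMError("arm indices must lie in [0, n_arms)")

    @property
    def completed(self) -> bool:
        return len(np.unique(self.visits)) == self.n_arms


def count_errors(trial: RAMTrial) -> int:
    """Number of revisits: total visits minus distinct arms entered."""
    return int(len(trial.visits) - len(np.unique(trial.visits)))


# ---------------------------------------------------------------------------
# analytic coupon-collector moments (oracle for the random null)


def expected_random_errors(n_arms: int) -> float:
    """E[errors] = n*H_n - n for uniform draws with replacement."""
    k = np.arange(1, n_arms + 1)
    return float(n_arms * np.sum(1.0 / k) - n_arms)


def random_errors_variance(n_arms: int) -> float:
    """Var[errors] = sum_i (1 - p_i) / p_i^2 with p_i = (n-i+1)/n."""
    p = (n_arms - np.arange(n_arms)) / n_arms
    return float(np.sum((1.0 - p) / p**2))


# ---------------------------------------------------------------------------
# null distributions


@dataclass
class NullDistribution:
    """Simulated error-count distribution under a behavioural null model."""

    model: str
    iterations: int
    errors: np.ndarray
    completed: np.ndarray = field(default=None)  # per-iteration completion flag

    def __post_init__(self) -> None:
        self.errors = np.asarray(self.errors)
        if self.iterations < 1 or len(self.errors) != self.iterations:
            raise RAMError("iterations must match the simulated series")
        if self.completed is None:
            self.completed = np.ones(self.iterations, dtype=bool)

    @property
    def mean(self) -> float:
        return float(np.mean(self.errors))

    @property
    def sem(self) -> float:
        return float(np.std(self.errors, ddof=1) / np.sqrt(self.iterations))


def _as_rng(seed: Union[int, np.random.Generator, None]) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_random_null(
    n_arms: int = 8,
    iterations: int = 10_000,
    seed: Union[int, np.random.Generator, None] = None,
    visit_cap: Optional[int] = None,
) -> NullDistribution:
    """Monte Carlo null for a maze solved by uniform random arm choice.

    Each iteration draws arms uniformly with replacement until all
    ``n_arms`` have been seen (or ``visit_cap`` visits were spent).  The
    number of draws decomposes into a sum of geometric stage lengths
    (time to find the k-th new arm has success probability (n-k+1)/n),
    which is sampled directly; this is an exact, vectorised equivalent of
    drawing the sequence arm by arm.
    """
    if iterations < 1:
        raise RAMError("iterations must be >= 1")
    if n_arms < 1:
        raise RAMError("n_arms must be >= 1")
    rng = _as_rng(seed)
    # stage k (k = 1..n) needs Geometric(p_k) draws, p_k = (n-k+1)/n
    p = (n_arms - np.arange(n_arms)) / n_arms  # p_1 = 1, ..., p_n = 1/n
    stages = np.empty((iterations, n_arms), dtype=np.int64)
    stages[:, 0] = 1
    if n_arms > 1:
        stages[:, 1:] = rng.geometric(p[1:], size=(iterations, n_arms - 1))
    total = stages.sum(axis=1)
    completed = np.ones(iterations, dtype=bool)
    if visit_cap is not None:
        if visit_cap < 1:
            raise RAMError("visit_cap must be >= 1")
        cum = np.cumsum(stages, axis=1)
        distinct = (cum <= visit_cap).sum(axis=1)
        truncated = total > visit_cap
        total = np.where(truncated, visit_cap, total)
        distinct = np.where(truncated, distinct, n_arms)
        completed = ~truncated
        errors = total - distinct
    else:
        errors = total - n_arms
    return NullDistribution("random", iterations, errors, completed)


@dataclass
class TransitionMatrix:
    """First-order movement rules pooled over trials.

    ``mode`` is ``absolute`` (an n x n matrix indexed by current and next
    arm) or ``relative_offset`` (transition probabilities depend only on
    the clockwise offset (next - current) mod n, giving a circulant
    matrix).  Rows with no observed transitions fall back to uniform.
    ``start_probs`` is the empirical distribution of first visits.
    """

    counts: np.ndarray
    probs: np.ndarray
    mode: str = "absolute"
    start_probs: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[0] != self.probs.shape[1]:
            raise RAMError("transition matrix must be square")
        if np.any(self.probs < -1e-12):
            raise RAMError("transition probabilities must be non-negative")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise RAMError("transition matrix rows must sum to 1")

    @property
    def n_arms(self) -> int:
        return self.probs.shape[0]


def estimate_transition_matrix(
    trials: Sequence[RAMTrial], mode: str = "absolute"
) -> TransitionMatrix:
    """Pool consecutive visit pairs over all trials and chicks."""
    if mode not in ("absolute", "relative_offset"):
        raise RAMError(f"unknown transition-matrix mode {mode!r}")
    if not trials:
        raise RAMError("no trials supplied")
    n = trials[0].n_arms
    counts = np.zeros((n, n), dtype=np.int64)
    start_counts = np.zeros(n, dtype=np.int64)
    n_transitions = 0
    for tr in trials:
        if tr.n_arms != n:
            raise RAMError("all trials must share n_arms")
        v = tr.visits
        start_counts[v[0]] += 1
        if len(v) >= 2:
            np.add.at(counts, (v[:-1], v[1:]), 1)
            n_transitions += len(v) - 1
    if n_transitions == 0:
        raise RAMError("no transitions observed in any trial")
    if mode == "relative_offset":
        offset_counts = np.zeros(n, dtype=np.int64)
        for d in range(n):
            offset_counts[d] = np.trace(counts, offset=d) + np.trace(
                counts, offset=d - n
            )
        p_off = offset_counts / offset_counts.sum()
        probs = np.empty((n, n))
        for i in range(n):
            probs[i] = np.roll(p_off, i)
        counts_out = offset_counts
    else:
        row_sums = counts.sum(axis=1, keepdims=True)
        probs = np.where(row_sums > 0, counts / np.maximum(row_sums, 1), 1.0 / n)
        counts_out = counts
    start_probs = (
        start_counts / start_counts.sum() if start_counts.sum() else None
    )
    return TransitionMatrix(counts_out, probs, mode=mode, start_probs=start_probs)


def simulate_stereotypic_null(
    tm: TransitionMatrix,
    iterations: int = 10_000,
    seed: Union[int, np.random.Generator, None] = None,
    start_rule: str = "uniform",
    visit_cap: Optional[int] = None,
    max_steps: int = 10_000,
) -> NullDistribution:
    """Monte Carlo null for a maze solved by first-order movement rules.

    Sequences follow the Markov chain defined by ``tm`` until all arms
    are visited or ``visit_cap`` visits are spent.  Without a cap, a
    chain that fails to cover all arms within ``max_steps`` raises (the
    chain may be absorbing).
    """
    if iterations < 1:
        raise RAMError("iterations must be >= 1")
    if start_rule not in ("uniform", "empirical"):
        raise RAMError(f"unknown start rule {start_rule!r}")
    rng = _as_rng(seed)
    n = tm.n_arms
    cum = np.cumsum(tm.probs, axis=1)
    cum[:, -1] = 1.0
    if start_rule == "empirical":
        if tm.start_probs is None:
            raise RAMError("transition matrix carries no empirical start distribution")
        start_cum = np.cumsum(tm.start_probs)
    else:
        start_cum = np.cumsum(np.full(n, 1.0 / n))
    start_cum[-1] = 1.0

    limit = visit_cap if visit_cap is not None else max_steps
    errors = np.empty(iterations, dtype=np.int64)
    completed = np.empty(iterations, dtype=bool)
    u_all = rng.random(size=(iterations, min(limit, max_steps)))
    for it in range(iterations):
        u = u_all[it]
        arm = int(np.searchsorted(start_cum, u[0], side="right"))
        seen = 1 << arm
        full = (1 << n) - 1
        visits = 1
        while seen != full and visits < limit:
            arm = int(np.searchsorted(cum[arm], u[visits], side="right"))
            seen |= 1 << arm
            visits += 1
        done = seen == full
        if not done and visit_cap is None:
            raise RAMError(
                f"chain failed to cover all arms within {max_steps} steps; "
                "it may be absorbing (supply visit_cap to allow truncation)"
            )
        errors[it] = visits - bin(seen).count("1")
        completed[it] = done
    return NullDistribution("stereotypic", iterations, errors, completed)


# ---------------------------------------------------------------------------
# observed-vs-null comparison


@dataclass
class TTestResult:
    """One-sample t-test of observed errors against a null mean."""

    t: float
    df: int
    p: float
    observed_mean: float
    null_mean: float
    alternative: str = "less"


def compare_to_null(
    observed: Sequence[float], null: NullDistribution
) -> TTestResult:
    """One-sample t-test, one-sided (observed mean < simulated null mean).

    With zero observed variance the t statistic is degenerate and the
    comparison of means is exact: p = 0 if the common observed value lies
    below the null mean, 1 if above, 0.5 if equal.
    """
    obs = np.asarray(observed, dtype=float)
    if obs.size < 2:
        raise RAMError("need at least 2 observed trials")
    mu0 = null.mean
    if np.ptp(obs) == 0.0:
        m = float(obs[0])
        p = 0.0 if m < mu0 else (1.0 if m > mu0 else 0.5)
        t_val = -np.inf if m < mu0 else (np.inf if m > mu0 else 0.0)
        return TTestResult(t_val, obs.size - 1, p, m, mu0)
    res = stats.ttest_1samp(obs, popmean=mu0, alternative="less")
    return TTestResult(
        float(res.statistic), obs.size - 1, float(res.pvalue), float(obs.mean()), mu0
    )
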