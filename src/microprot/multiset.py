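"""Exact statistics for intersections of m sets drawn from a finite background.

For sets of sizes n_1..n_m drawn uniformly at random (without replacement)
from a background of N elements, the size of their common intersection has an
exact distribution obtained by chaining hypergeometrics:

    X_1 = n_1
    X_t | X_{t-1} ~ Hypergeometric(N, X_{t-1}, n_t)     t = 2..m

because, conditional on the running intersection, the next set is an
independent uniform draw.  The dynamic program below propagates that chain in
log space.  The expected intersection size is N * prod(n_i / N), fold
enrichment is observed / expected, and the upper-tail p-value P(X >= x_obs)
is the significance of the overlap.  For m = 2 this reduces exactly to the
one-sided Fisher / hypergeometric test.

p-values below the smallest positive double are reported with the
conventional "< 1.0e-307" flag; the exact log-probability is kept alongside.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.special import logsumexp

from .errors import ValidationError

#: preset background: number of reviewed mouse proteome entries in a standard
#: curated search database
MOUSE_REVIEWED_PROTEOME = 16972

#: smallest p-value printed before flooring, mirroring the "< 1.0e-307" convention
P_FLOOR = 1.0e-307

#: combinatorial cap on the number of sets in a sweep
MAX_SETS = 12


@dataclass(frozen=True)
class IntersectionSpec:
    set_sizes: tuple[int, ...]
    background_size: int
    observed: int

    def __post_init__(self) -> None:
        if self.background_size < 1:
            raise ValidationError("background size must be >= 1")
        for n in self.set_sizes:
            if not (0 <= n <= self.background_size):
                raise ValidationError(
                    f"set size {n} outside [0, N={self.background_size}]"
                )
        if not (0 <= self.observed <= min(self.set_sizes, default=0)):
            raise ValidationError("observed intersection exceeds the smallest set")


@dataclass(frozen=True)
class IntersectionResult:
    """Observed vs expected overlap of one set combination."""

    members: tuple[str, ...]
    set_sizes: tuple[int, ...]
    background_size: int
    observed: int
    expected: float
    fold_enrichment: float
    p_value: float  # floored at P_FLOOR
    log_p: float  # natural-log upper-tail probability, not floored
    p_floored: bool

    @property
    def p_display(self) -> str:
        return "< 1.0e-307" if self.p_floored else format(self.p_value, ".3g")


@dataclass(frozen=True)
class FamilySummary:
    """FE_avg and combined p over a named family of combinations."""

    family: str
    fe_avg: float
    combined_p: float
    combined_log_p: float
    combined_p_floored: bool
    method: str = "fisher"
    n_combinations: int = 0


def _log_pmf(n: Sequence[int], N: int) -> np.ndarray:
    """log pmf of the m-set intersection size, support 0..min(n)."""
    if len(n) < 1:
        raise ValidationError("need at least one set")
    spec_check = IntersectionSpec(tuple(int(v) for v in n), int(N), 0)
    n = spec_check.set_sizes
    N = spec_check.background_size
    # X_1 is degenerate at n_1
    cur_top = n[0]
    log_pmf = np.full(cur_top + 1, -np.inf)
    log_pmf[cur_top] = 0.0
    for n_t in n[1:]:
        new_top = min(cur_top, n_t)
        j = np.arange(cur_top + 1)  # previous intersection size
        k = np.arange(new_top + 1)  # new intersection size
        # log P(k | j) for drawing n_t of N with j marked
        with np.errstate(divide="ignore"):
            trans = stats.hypergeom.logpmf(k[None, :], N, j[:, None], n_t)
        new_log = logsumexp(trans + log_pmf[:, None], axis=0)
        log_pmf = new_log
        cur_top = new_top
    return log_pmf


def intersection_pmf(n: Sequence[int], N: int) -> np.ndarray:
    """Exact pmf of the intersection size of m random sets; support 0..min(n)."""
    return np.exp(_log_pmf(n, N))


def expected_intersection(n: Sequence[int], N: int) -> float:
    e = float(N)
    for v in n:
        e *= v / N
    return e


def intersection_test(
    spec: IntersectionSpec, members: tuple[str, ...] = ()
) -> IntersectionResult:
    """Exact upper-tail test of the observed overlap against independence."""
    e = expected_intersection(spec.set_sizes, spec.background_size)
    if e == 0 and spec.observed > 0:
        raise ValidationError("expected intersection 0 but observed > 0: impossible")
    fe = spec.observed / e if e > 0 else 0.0
    log_pmf = _log_pmf(spec.set_sizes, spec.background_size)
    log_p = float(logsumexp(log_pmf[spec.observed :]))
    log_p = min(log_p, 0.0)  # numerical guard
    p = math.exp(log_p)
    floored = p < P_FLOOR and spec.observed > 0
    return IntersectionResult(
        members=members,
        set_sizes=spec.set_sizes,
        background_size=spec.background_size,
        observed=spec.observed,
        expected=e,
        fold_enrichment=fe,
        p_value=max(p, P_FLOOR) if floored else p,
        log_p=log_p,
        p_floored=floored,
    )


def combination_sweep(
    sets: Mapping[str, set],
    background: int | str = MOUSE_REVIEWED_PROTEOME,
) -> list[IntersectionResult]:
    """Exact test for every combination of >= 2 named sets (2^m - m - 1 total).

    ``background`` is either an integer population size (default: the reviewed
    mouse proteome preset) or the string ``"union"`` for the union of the
    supplied sets.
    """
    names = list(sets)
    m = len(names)
    if m > MAX_SETS:
        raise ValidationError(f"too many sets ({m} > {MAX_SETS})")
    if m < 2:
        raise ValidationError("need at least two sets to sweep combinations")
    if background == "union":
        N = len(set().union(*sets.values()))
    else:
        N = int(background)
    results = []
    for order in range(2, m + 1):
        for combo in itertools.combinations(names, order):
            inter = set.intersection(*(set(sets[c]) for c in combo))
            spec = IntersectionSpec(
                tuple(len(sets[c]) for c in combo), N, len(inter)
            )
            results.append(intersection_test(spec, members=combo))
    return results


def summarize_family(
    results: Sequence[IntersectionResult],
    family: str = "all",
    order: int | None = None,
) -> FamilySummary:
    """FE_avg (arithmetic mean of FE) and Fisher's combined p over a family.

    ``order`` restricts the family to combinations of that many sets (e.g. 2
    for all pairwise overlaps).  Fisher's statistic -2*sum(ln p) uses the
    exact log p-values, so members below the display floor still combine
    correctly; the combined p is itself floored for display.
    """
    group = [r for r in results if order is None or len(r.members) == order]
    if not group:
        raise ValidationError(f"no combinations of order {order} in the sweep")
    fe_avg = float(np.mean([r.fold_enrichment for r in group]))
    chi = -2.0 * sum(r.log_p for r in group)
    log_p = float(stats.chi2.logsf(chi, df=2 * len(group)))
    p = math.exp(log_p)
    floored = p < P_FLOOR
    return FamilySummary(
        family=family,
        fe_avg=fe_avg,
        combined_p=max(p, P_FLOOR) if floored else p,
        combined_log_p=log_p,
        combined_p_floored=floored,
        method="fisher",
        n_combinations=len(group),
    )


def count_in_at_least(replicate_sets: Sequence[set], k: int) -> int:
    """Number of elements present in at least k of the given sets."""
    from collections import Counter

    counts = Counter(itertools.chain.from_iterable(replicate_sets))
    return sum(1 for v in counts.values() if v >= k)


def display_fe(fe: float) -> str:
    """Report-style rounding: integers at >= 10, one decimal below 10."""
    if not math.isfinite(fe):
        return "inf"
    return f"{fe:.0f}" if fe >= 10 else f"{fe:.1f}"
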