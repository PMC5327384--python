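"""Exhaustive permutation null: every group assignment of size n1.

Brute-force validation counterpart of the sampled conditional null.  All
``C(n, n1)`` assignments are enumerated stratum by stratum (choose k event
subjects, then n1-k censored ones, lexicographic subject order within each
factor), which also verifies the stratum partition: concatenating strata
yields exactly the full permutation distribution.
"""

from __future__ import annotations

import math

import numpy as np

from .survival import GroupAssignment, SurvivalCohort, cooccurrence, score_profile
from .conditional import stratum_sums

DEFAULT_MAX_COMBINATIONS = 10_000_000
_ORACLE_TIE_PERMS = 100
_ORACLE_TIE_SEED = 20170217  # fixed so oracle and sampler average the same quantity


def _scores(cohort: SurvivalCohort):
    return score_profile(cohort, _ORACLE_TIE_PERMS, _ORACLE_TIE_SEED)[0]


def exact_null_by_stratum(cohort: SurvivalCohort, n1: int,
                          max_combinations: int = DEFAULT_MAX_COMBINATIONS):
    """Exhaustive statistic values grouped by co-occurrence stratum.

    Returns ``{k: ndarray of C(n-d, n1-k)*C(d, k) values}``.
    """
    n, d = cohort.n, cohort.d
    if not (1 <= n1 <= n - 1):
        raise ValueError(f"need 1 <= n1 <= n-1, got n1={n1}")
    total = math.comb(n, n1)
    if total > max_combinations:
        raise ValueError(
            f"C({n}, {n1}) = {total} combinations exceed the enumeration "
            f"bound {max_combinations}"
        )
    scores = _scores(cohort)
    ev = scores[cohort.events == 1]
    cs = scores[cohort.events == 0]
    out = {}
    for k in range(min(n1, d) + 1):
        if n1 - k > n - d:
            continue
        out[k] = stratum_sums(ev, cs, n1, k, None, None)
    return out


def exact_null(cohort: SurvivalCohort, n1: int,
               max_combinations: int = DEFAULT_MAX_COMBINATIONS) -> np.ndarray:
    """All C(n, n1) log-rank statistic values, one per assignment.

    Mixed tie blocks are handled with the same ordering-averaged scores the
    sampler uses (fixed seed), so oracle and sampled values are comparable.
    """
    strata = exact_null_by_stratum(cohort, n1, max_combinations)
    return np.concatenate([strata[k] for k in sorted(strata)])


def exact_pvalue(cohort: SurvivalCohort, group: GroupAssignment,
                 tail: str = "two_sided",
                 max_combinations: int = DEFAULT_MAX_COMBINATIONS) -> float:
    """Inclusive tail proportion of the observed L over the exact null."""
    if tail not in ("left", "right", "two_sided"):
        raise ValueError(f"unknown tail {tail!r}")
    scores = _scores(cohort)
    L_obs = float(group.x @ scores)
    values = exact_null(cohort, group.n1, max_combinations)
    return tail_proportion(values, L_obs, tail)


def tail_proportion(values: np.ndarray, L_obs: float, tail: str = "two_sided",
                    atol: float = 1e-12) -> float:
    """Inclusive tail fraction of a finite distribution, with fp-safe ties."""
    m = values.size
    p_left = np.count_nonzero(values <= L_obs + atol) / m
    p_right = np.count_nonzero(values >= L_obs - atol) / m
    if tail == "left":
        return float(p_left)
    if tail == "right":
        return float(p_right)
    return float(min(1.0, 2.0 * min(p_left, p_right)))


def exact_cdf(values: np.ndarray, xs) -> np.ndarray:
    """Empirical CDF of the enumerated null on a vector of points."""
    s = np.sort(values)
    xs = np.atleast_1d(np.asarray(xs, dtype=float))
    return np.searchsorted(s, xs, side="right") / s.size


def cooccurrence_of(cohort: SurvivalCohort, group: GroupAssignment) -> int:
    """Convenience re-export for partition checks."""
    return cooccurrence(cohort, group)
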