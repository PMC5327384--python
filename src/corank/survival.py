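"""Log-rank statistic, variance, chi-square approximation and rank scores.

The two-group log-rank statistic is written here in two equivalent forms:

* the grouped form ``L = sum_t (O_1t - E_1t)`` over distinct event times,
  with ``E_1t = R_1t * O_t / R_t`` the hypergeometric expectation, and
* the per-subject score form ``L = sum_j x_j * s_j`` with
  ``s_j = c_j - NA(t_j)``, where ``NA`` is the Nelson-Aalen cumulative
  hazard evaluated at the subject's own follow-up time (hazard at tied
  times included).

The two are algebraically identical for any tie pattern.  The score form
exposes the decomposition ``L = k + middle - s1`` on which the conditional
null is built: ``k = sum_j c_j x_j`` is the event/mutation co-occurrence
count, ``s1 = n1 * NA(inf)`` depends only on the cohort and the group size,
and ``middle = sum_j x_j (NA(inf) - NA(t_j))`` is non-negative, giving the
envelope ``k - s1 <= L <= k`` within each co-occurrence stratum.

Tied times that mix events and censored observations make the risk-set
bookkeeping ambiguous; they are resolved by randomly ordering the subjects
inside each mixed block (the block becomes a run of distinct pseudo-times)
and averaging the statistic over orderings.  Because ``L`` is linear in the
scores, the average over orderings equals the statistic computed with the
ordering-averaged score vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

DEFAULT_TIE_PERMS = 100


class DegenerateGroupError(ValueError):
    """Group covers no subjects or all subjects; the test is undefined."""


class NoEventsError(ValueError):
    """Cohort has no events; the log-rank statistic is undefined for testing."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SurvivalCohort:
    """Follow-up times and event indicators, stored sorted by time.

    Parameters
    ----------
    times : array of float
        Non-negative follow-up times, ascending.
    events : array of int
        1 = event observed, 0 = censored, aligned with `times`.
    sample_ids : tuple of str, optional
        Subject identifiers aligned with the sorted order (used when the
        cohort was read from, or is written to, a clinical table).
    """

    times: np.ndarray
    events: np.ndarray
    sample_ids: tuple | None = None

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        events = np.asarray(self.events, dtype=np.int8)
        if times.ndim != 1 or events.shape != times.shape:
            raise ValueError("times and events must be 1-d and aligned")
        if times.size < 2:
            raise ValueError("cohort needs at least 2 subjects")
        if np.any(times < 0) or not np.all(np.isfinite(times)):
            raise ValueError("times must be finite and non-negative")
        if not np.all((events == 0) | (events == 1)):
            raise ValueError("events must be 0/1")
        if np.any(np.diff(times) < 0):
            raise ValueError("subjects must be sorted by time ascending")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "events", events)
        if self.sample_ids is not None and len(self.sample_ids) != times.size:
            raise ValueError("sample_ids length mismatch")

    @classmethod
    def from_unsorted(cls, times, events, sample_ids=None) -> "SurvivalCohort":
        """Build a cohort from unsorted inputs (stable sort by time)."""
        times = np.asarray(times, dtype=float)
        order = np.argsort(times, kind="stable")
        events = np.asarray(events)[order]
        ids = None if sample_ids is None else tuple(np.asarray(sample_ids, dtype=object)[order])
        return cls(times[order], events, ids)

    @property
    def n(self) -> int:
        return self.times.size

    @property
    def d(self) -> int:
        return int(self.events.sum())

    @property
    def r(self) -> int:
        """Number of distinct follow-up times."""
        return int(np.unique(self.times).size)

    @property
    def tie_blocks(self) -> list[tuple[int, int]]:
        """Half-open index ranges [start, stop) of equal-time runs, size >= 2."""
        edges = np.flatnonzero(np.r_[True, np.diff(self.times) != 0, True])
        return [(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:]) if b - a >= 2]

    @property
    def mixed_tie_blocks(self) -> list[tuple[int, int]]:
        """Tie blocks containing at least one event and one censored subject."""
        out = []
        for a, b in self.tie_blocks:
            s = int(self.events[a:b].sum())
            if 0 < s < b - a:
                out.append((a, b))
        return out


@dataclass(frozen=True)
class GroupAssignment:
    """Binary membership vector aligned with a cohort's sorted subject order."""

    x: np.ndarray

    def __post_init__(self):
        x = np.asarray(self.x, dtype=np.int8)
        if x.ndim != 1 or not np.all((x == 0) | (x == 1)):
            raise ValueError("x must be a 1-d 0/1 vector")
        object.__setattr__(self, "x", x)

    @property
    def n1(self) -> int:
        return int(self.x.sum())

    def complement(self) -> "GroupAssignment":
        return GroupAssignment(1 - self.x)


@dataclass(frozen=True)
class RankDecomposition:
    """Decomposition L = k + middle - s1 of the log-rank statistic."""

    k: int
    middle: float
    s1: float

    @property
    def L(self) -> float:
        return self.k + self.middle - self.s1


# ---------------------------------------------------------------------------
# grouped (distinct event time) computations
# ---------------------------------------------------------------------------

def _check(cohort: SurvivalCohort, group: GroupAssignment) -> None:
    if group.x.size != cohort.n:
        raise ValueError("group vector not aligned with cohort")
    if group.n1 in (0, cohort.n):
        raise DegenerateGroupError(f"degenerate group: n1={group.n1} of n={cohort.n}")
    if cohort.d == 0:
        raise NoEventsError("cohort has no events")


def _grouped_counts(cohort: SurvivalCohort, x: np.ndarray):
    """Per distinct time: O_t, R_t, R_1t, O_1t (vectorized)."""
    t = cohort.times
    c = cohort.events.astype(float)
    xf = x.astype(float)
    # distinct-time block boundaries on the sorted cohort
    starts = np.flatnonzero(np.r_[True, np.diff(t) != 0])
    stops = np.r_[starts[1:], t.size]
    csum_c = np.r_[0.0, np.cumsum(c)]
    csum_x = np.r_[0.0, np.cumsum(xf)]
    csum_cx = np.r_[0.0, np.cumsum(c * xf)]
    O = csum_c[stops] - csum_c[starts]
    O1 = csum_cx[stops] - csum_cx[starts]
    n, n1 = t.size, xf.sum()
    R = n - starts.astype(float)
    R1 = n1 - csum_x[starts]
    return O, R, R1, O1


def logrank_statistic(cohort: SurvivalCohort, group: GroupAssignment) -> float:
    """Observed minus expected events in the group, summed over event times."""
    _check(cohort, group)
    O, R, R1, O1 = _grouped_counts(cohort, group.x)
    return float(np.sum(O1 - R1 * O / R))


def logrank_variance(cohort: SurvivalCohort, group: GroupAssignment) -> float:
    """Hypergeometric variance of the log-rank statistic.

    Per-time terms with a risk set of one subject are defined as zero (the
    hypergeometric variance is degenerate there).
    """
    _check(cohort, group)
    O, R, R1, O1 = _grouped_counts(cohort, group.x)
    with np.errstate(divide="ignore", invalid="ignore"):
        v = R1 * (R - R1) * O * (R - O) / (R * R * (R - 1.0))
    v[R <= 1] = 0.0
    return float(v.sum())


def alrt_pvalue(L: float, V: float) -> float:
    """Approximate log-rank test: upper chi-square(1) tail of L^2/V."""
    if not V > 0:
        raise ValueError(f"variance must be positive, got {V}")
    return float(stats.chi2.sf(L * L / V, df=1))


def cooccurrence(cohort: SurvivalCohort, group: GroupAssignment) -> int:
    """Number of subjects that are both in the group and had the event."""
    if group.x.size != cohort.n:
        raise ValueError("group vector not aligned with cohort")
    return int(np.sum(cohort.events * group.x))


# ---------------------------------------------------------------------------
# per-subject scores and the rank decomposition
# ---------------------------------------------------------------------------

def _score_groups(cohort: SurvivalCohort, rng: np.random.Generator | None = None):
    """Processing groups for score computation.

    Distinct times and non-mixed tie blocks are single groups; mixed tie
    blocks are expanded into per-subject singletons in a random order (the
    tie-break).  Without an rng, mixed blocks stay grouped (canonical form).
    """
    n = cohort.n
    starts = np.flatnonzero(np.r_[True, np.diff(cohort.times) != 0])
    stops = np.r_[starts[1:], n]
    mixed = set(cohort.mixed_tie_blocks) if rng is not None else set()
    groups = []
    for a, b in zip(starts, stops):
        if (int(a), int(b)) in mixed:
            idx = np.arange(a, b)
            rng.shuffle(idx)
            groups.extend([i] for i in idx)
        else:
            groups.append(range(a, b))
    return groups


def _scores_from_groups(cohort: SurvivalCohort, groups) -> tuple[np.ndarray, float]:
    """Log-rank scores c_j - NA(t_j) and the total hazard NA(inf)."""
    c = cohort.events
    scores = np.empty(cohort.n, dtype=float)
    R = cohort.n
    A = 0.0
    for g in groups:
        idx = np.fromiter(g, dtype=np.intp) if not isinstance(g, range) else np.arange(g.start, g.stop)
        O = int(c[idx].sum())
        if O:
            A += O / R
        scores[idx] = c[idx] - A
        R -= idx.size
    return scores, A


def score_profile(cohort: SurvivalCohort, n_tie_perms: int = DEFAULT_TIE_PERMS,
                  rng_seed=None) -> tuple[np.ndarray, float]:
    """Per-subject log-rank scores and total hazard NA(inf); L(x) = x . scores.

    Without mixed tie blocks these are the canonical grouped scores.  With
    mixed blocks, both outputs are averages over ``n_tie_perms`` random
    within-block orderings, so ``x . scores`` is the tie-averaged statistic.
    Scores always sum to zero; ``s1 = n1 * NA(inf)`` is the constant term of
    the rank decomposition.
    """
    if not cohort.mixed_tie_blocks:
        return _scores_from_groups(cohort, _score_groups(cohort))
    if n_tie_perms < 1:
        raise ValueError("n_tie_perms must be >= 1")
    rng = np.random.default_rng(rng_seed)
    acc = np.zeros(cohort.n)
    tot = 0.0
    for _ in range(n_tie_perms):
        s, a = _scores_from_groups(cohort, _score_groups(cohort, rng))
        acc += s
        tot += a
    return acc / n_tie_perms, tot / n_tie_perms


def logrank_scores(cohort: SurvivalCohort, n_tie_perms: int = DEFAULT_TIE_PERMS,
                   rng_seed=None) -> np.ndarray:
    """Per-subject log-rank scores (see :func:`score_profile`)."""
    return score_profile(cohort, n_tie_perms, rng_seed)[0]


def tie_averaged_logrank(cohort: SurvivalCohort, group: GroupAssignment,
                         n_tie_perms: int = DEFAULT_TIE_PERMS, rng_seed=None) -> float:
    """Log-rank statistic averaged over random orderings of mixed tie blocks.

    Equals :func:`logrank_statistic` exactly when no mixed tie block exists;
    deterministic given ``rng_seed``.
    """
    _check(cohort, group)
    scores = logrank_scores(cohort, n_tie_perms, rng_seed)
    return float(group.x @ scores)


def rank_decomposition(cohort: SurvivalCohort, group: GroupAssignment) -> RankDecomposition:
    """Split L into co-occurrence count, middle term and constant s1.

    Requires a cohort without mixed tie blocks (use
    :func:`tie_averaged_logrank` otherwise).  The reconstruction
    ``k + middle - s1`` equals :func:`logrank_statistic` exactly.
    """
    _check(cohort, group)
    if cohort.mixed_tie_blocks:
        raise ValueError("cohort has mixed tie blocks; use tie_averaged_logrank")
    scores, na_total = score_profile(cohort)
    na = cohort.events - scores          # NA(t_j) per subject
    k = cooccurrence(cohort, group)
    middle = float(group.x @ (na_total - na))
    s1 = group.n1 * na_total
    return RankDecomposition(k=k, middle=middle, s1=s1)
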