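# Methods

## Model and statistic

Subjects $i = 1..n$ carry a follow-up time $t_i \ge 0$ and an event flag
$c_i$ (1 = event, 0 = censored); a binary vector $x$ with $n_1 = \sum x_i$
marks the group of interest (mutation carriers). The two-group log-rank
statistic is

$$L = \sum_{\text{distinct event times } \tau}
      \Big( O_{1\tau} - \frac{R_{1\tau} O_\tau}{R_\tau} \Big),$$

with $O$ event counts and $R$ risk-set sizes (overall and in the group).
Under the null hypothesis that group labels are exchangeable, $O_{1\tau}$
is hypergeometric; the classical test refers $L^2/V$ (with $V$ the summed
hypergeometric variance) to $\chi^2_1$.

### Per-subject score form

Let $\hat\Lambda(t) = \sum_{\tau \le t} O_\tau / R_\tau$ be the
Nelson–Aalen cumulative hazard, evaluated *inclusive* of the hazard at $t$
itself, and define per-subject scores $s_i = c_i - \hat\Lambda(t_i)$.
Then, algebraically and for any tie pattern,

$$L = \sum_i x_i s_i,$$

because $\sum_i x_i \hat\Lambda(t_i) = \sum_\tau (O_\tau/R_\tau) R_{1\tau}$
(each hazard increment is counted once per group member still at risk).
Scores sum to zero over the cohort, so the mean of $L$ over all
$\binom{n}{n_1}$ assignments is exactly zero.

Splitting $\hat\Lambda(t_i) = \hat\Lambda(\infty) - B_i$ gives the
decomposition the conditional null rests on:

$$L = k + \underbrace{\textstyle\sum_i x_i B_i}_{\text{middle}, \ \ge 0}
      - \underbrace{n_1 \hat\Lambda(\infty)}_{s_1},
  \qquad k = \sum_i c_i x_i,$$

whence $k - s_1 \le L \le k$ within the co-occurrence stratum $k$. The
bounds are attainable (e.g. $L = k - s_1$ exactly when every carrier is
censored after the last event), so the package treats the envelope as
inclusive; strict inequality holds generically.

## The conditional mixture null

For $n_1 \ll n$ the strata barely overlap, so the permutation null is
estimated as

$$P(L) = \sum_{k=0}^{\min(n_1, d)} w_k \, P(L \mid k), \qquad
  w_k = \binom{n-d}{n_1-k}\binom{d}{k} \Big/ \binom{n}{n_1},$$

with the combination counts kept as exact integers (their sum is checked
against $\binom{n}{n_1}$; for $n=100, d=10, n_1=7$ it is
16,007,560,800). Each stratum draws `size` assignments by choosing $k$ of
the $d$ event subjects and $n_1 - k$ of the $n - d$ others uniformly
without replacement (draws independent across samples, duplicates
allowed), and evaluates $L$ as a score sum — $O(n_1)$ per draw,
vectorised. A stratum is enumerated exhaustively (outer sum of the two
subset-sum lists, lexicographic order) when its allocation exceeds half
its combination count.

Tail probabilities are weighted per-stratum proportions with *inclusive*
counting (`>=` right, `<=` left), which is conservative under
discreteness; the two-sided value is twice the smaller tail, capped at 1.
A reported 0 means no stored sample reached the observed statistic; the
resolution floor of stratum $k$ is $w_k / ss_k$ and is recoverable from
the null's metadata. No smoothing is applied.

### Parameters

| parameter | default | meaning |
|---|---|---|
| `ss` | 100,000 | total Monte-Carlo budget for one null |
| `ss_min` | 1,000 | per-stratum floor, applied before the exhaustive check |
| `n_tie_perms` | 100 (observed statistic), 10 (per null build) | tie orderings averaged |
| `max_combinations` | 10^7 | refusal bound of the exhaustive oracle |

`ss_k = max(round(w_k · ss), ss_min)` with half-up rounding. The defaults
resolve two-sided p-values to about $10^{-5}$; at `ss = 10,000`
independently seeded runs are already nearly indistinguishable
(Kolmogorov–Smirnov distance of the mixtures ≈ 0.01–0.02, remeasured by
the acceptance script).

### Ties

Tied times that mix events and censorings make the risk-set bookkeeping
ambiguous. They are resolved by randomly ordering the subjects inside each
mixed block — the block becomes a run of distinct pseudo-times, while
(c, x) pairs stay attached to their subjects so the co-occurrence count is
preserved — and averaging the statistic over `n_tie_perms` orderings.
Because $L$ is linear in the scores, the average over orderings equals a
single score product with the ordering-averaged score vector; the sampler
and the exhaustive oracle both exploit this, and the oracle fixes its own
ordering seed so sampled and enumerated values estimate the same quantity.
Ties among events only, or among censorings only, need no resolution: the
grouped statistic is exact there, and equals the score form identically.
Time equality is exact floating-point equality after parsing; no epsilon
merging is performed.

### Randomness

Every build threads one `numpy` `SeedSequence`: it spawns a tie-ordering
stream and one independent stream per stratum, so strata are reproducible
in isolation. The screening pipeline seeds the null for carrier count
$n_1$ as `[seed, n1]`, making the per-$n_1$ null identical whether it is
shared across genes or rebuilt for one gene.

## Screening pipeline

Fixed stage order: coding-variant filter → clinical join → hypermutated
sample removal → minimum-mutation gene filter → testing; the
Benjamini–Hochberg correction runs over exactly the post-filter gene set.
Design choices where the procedure was genuinely open:

* **Hypermutation.** A sample is removed only if all three clauses hold
  (> 500 mutated genes, ≥ 95th percentile of per-sample counts, > median
  + 4·MAD). MAD is unscaled by default (`mad_scale=1.4826` gives the
  normal-consistent variant). The conjunction deliberately spares cohorts
  whose mutation counts are globally low.
* **Gene filter threshold.** 4 carriers for cohorts of ≥ 75 subjects with
  survival data, 3 below; applied after sample removal, so a gene may drop
  out because its remaining carriers fell under the threshold.
* **FDR.** Benjamini–Hochberg step-up (via statsmodels); genes are called
  at q < 0.333 by default. Strict inequality.
* **Hazard ratio.** Univariate Cox proportional-hazards fit (lifelines);
  when the fit is degenerate the observed/expected ratio
  $(O_1/E_1)/(O_0/E_0)$ is used instead, and `hr_method="oe"` selects that
  estimator directly (used in large simulation sweeps, where per-gene Cox
  fits dominate runtime). A group with zero events reports 0 or ∞ with an
  explanatory note rather than a fitted number.
* **Sidedness.** Two-sided by default; one-sided via `tail=`.

## Synthetic data

The generator produces the structures the pipeline consumes, under one
seed:

* **Cohorts.** Exponential baseline event times. An exact event count `d`
  is realised by drawing the event-indicator vector uniformly at random
  over subjects — the canonical exchangeable null, with events interleaved
  through the censoring. `censoring="administrative"` instead cuts off
  follow-up after the d-th latent event (events early, censorings late),
  the fixed-horizon trial shape. Expected event fractions use independent
  exponential censoring with the rate matched to the requested fraction.
  Optional tied times: a configurable fraction of subjects copy another
  subject's time.
* **Mutations.** Background genes are independent Bernoulli per sample at
  per-gene frequencies drawn from a configurable range. Planted effect
  genes multiply their carriers' event hazard and the latent times are
  regenerated jointly (proportional hazards by construction); carrier sets
  of planted genes are drawn disjointly so planted effects are never
  confounded with each other. A hypermutated fraction of samples gets an
  inflated per-gene mutation probability. A truth table records planted
  multipliers and realised carrier counts.

What this emulates — and what it does not: independent per-gene mutation,
exponential hazards, and exchangeable censoring are idealisations. Real
cohorts have correlated mutations (signatures, gene length), non-PH
effects, and informative censoring; passing tests on these fixtures
establishes the estimator's calibration and power under its own model
assumptions, not robustness to those violations.

## Validation conditions (acceptance script)

Problem sizes were chosen so every check runs on one CPU in about a
minute total:

* Mixture-vs-enumeration agreement on five cohorts with
  $\binom{n}{n_1} \le 10^6$ (n = 30–40, $n_1$ = 5–6, event fractions
  0.4–0.6), `ss = 100,000`: KS distance of the weighted mixture against
  the exhaustive distribution, and p-value error at 20 probe statistics
  spanning both tails of each instance.
* Balanced-design convergence at $n = 100$, $n_1 = 50$, $d = 50$:
  Pearson correlation between conditional and $\chi^2$ two-sided p-values
  over 200 random assignments.
* $\chi^2$ bias direction at $n = 100$, $n_1 = 7$, $d = 50$ under
  administrative censoring — the fixed-horizon design in which a gene
  whose carriers are all censored is maximally surprising. The mean
  p-value difference is negative in the top-$k$ stratum
  (anti-conservative $\chi^2$) and positive at $k = 0$ (conservative
  $\chi^2$). Under fully interleaved censoring the $k=0$ stratum carries
  enough mixture weight that the pattern attenuates and can reverse; the
  fixed-horizon condition isolates the phenomenon.
* Stability: two independently seeded mixtures at `ss = 10,000`
  ($n = 100$, $d = 30$, $n_1 = 7$), KS distance.
* Exact permutation mean on three instances with
  $\binom{n}{n_1} \le 10^5$.
* Screen calibration on a 500-gene null fixture ($n = 150$, event
  fraction 0.5, carrier frequencies 2–10%) at `ss = 100,000`: fraction of
  genes with $p < 0.05$ and $p < 0.01$.
* Recovery: 50 replicates of a 100-background-gene fixture with one
  hazard-ratio-8 and one hazard-ratio-0.05 gene (10 disjoint carriers
  each) at `ss = 10,000`; both planted genes must rank in the top 5
  p-values. The background panel is sized so that the top-5 bar reflects
  the method rather than extreme-value noise among null genes: with
  several hundred background genes, order statistics alone put ~1 null
  gene below the p-value an HR=8 gene attains whenever it draws $k \le 8$
  carriers dead, and no calibrated test could clear the bar.
* Filter rules re-evaluated against hand-computed kept/removed sets.

## Known limitations

* The mixture is built per carrier count $n_1$; screening cohorts with
  many distinct $n_1$ values pay one null build each (sub-second at
  default sizes, but linear in the number of distinct counts).
* P-values below the stratum resolution $w_k/ss_k$ truncate to 0; raise
  `ss` (or enumerate, for small cohorts) when the extreme tail matters.
* The tie average is itself a Monte-Carlo estimate; cohorts dominated by
  large mixed tie blocks inherit its (seeded) variability.
* Stratified, weighted (Fleming–Harrington) and multivariable tests are
  out of scope; the hazard ratio column is a univariate summary, not an
  adjusted effect estimate.
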