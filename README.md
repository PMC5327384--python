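# corank

Conditional co-occurrence null distributions for the log-rank test, with a
cohort-screening pipeline for rare-mutation survival analysis.

## The problem

Testing whether carriers of a rarely mutated gene live shorter (or longer)
than non-carriers is a two-group survival comparison with severely
unbalanced groups: a cancer cohort of hundreds of patients may contain only
a handful of carriers. The standard log-rank test handles this statistic

$$L = \sum_j \left(O_{1j} - \frac{R_{1j}\,O_j}{R_j}\right)$$

(observed minus hypergeometrically expected events in the carrier group,
summed over distinct event times) by referring $L^2/V$ to a
$\chi^2_1$ distribution. That approximation assumes large, similar group
sizes; with $n_1 \ll n$ it is badly biased — anti-conservative for genes
whose few carriers die, conservative for protective genes whose carriers
survive — which distorts genome-wide screens in both directions.

## The method

Written in per-subject rank form, $L = k + m(x) - s_1$, where
$k = \sum_j c_j x_j$ counts subjects that are both carriers and events
(the *co-occurrence*), $s_1 = n_1 \hat\Lambda(\infty)$ is a constant of the
cohort and group size ($\hat\Lambda$ the Nelson–Aalen cumulative hazard),
and the middle term $m(x) \in [0, s_1]$ varies only mildly with carrier
placement. Hence $k - s_1 \le L \le k$: for small $n_1$ the permutation
null of $L$ is a mixture of well-separated components indexed by $k$.

`corank` estimates that mixture explicitly:

$$P(L) = \sum_{k=0}^{\min(n_1,d)} w_k\, P(L \mid k), \qquad
  w_k = \frac{\binom{n-d}{\,n_1-k\,}\binom{d}{k}}{\binom{n}{n_1}},$$

with exact integer weights (a Vandermonde partition of all
$\binom{n}{n_1}$ assignments) and Monte-Carlo sampling within each
stratum — a budget `ss` split proportionally to $w_k$ with a per-stratum
floor `ss_min`, and exhaustive enumeration whenever the allocation exceeds
half the stratum. P-values are weighted per-stratum tail counts; tied
follow-up times mixing events and censorings are handled by averaging the
statistic over random within-tie orderings. The defaults `ss = 100,000`,
`ss_min = 1,000` resolve two-sided p-values to roughly $10^{-5}$ in a few
hundred milliseconds, independent of how many combinations exist (a cohort
of 100 with 10 deaths and 7 carriers already has 16,007,560,800).

The screening pipeline wraps the estimator for cohort studies: MAF-dialect
mutation tables are collapsed to a binary gene × sample matrix (coding
variant classes only), hypermutated samples are removed by a three-clause
rule (more than 500 mutated genes AND top 5% of the cohort AND above
median + 4·MAD), genes mutated in fewer than 4 subjects (3 for cohorts of
at most 74) are dropped, one null is built per distinct carrier count and
shared across genes, and results carry Benjamini–Hochberg q-values, risk
direction (high when $L > 0$) and a Cox hazard ratio.

## Worked example

```python
import corank as cr

# synthetic cohort: 150 patients, ~50% deaths, 40 background genes plus a
# planted high-risk gene (hazard x8) and a protective gene (hazard x0.05),
# 10 carriers each
spec = cr.SimulationSpec(n=150, event_fraction=0.5, n_genes=40,
                         mutation_freq=(0.03, 0.10),
                         planted_effects={"DRIVER": 8.0, "SHIELD": 0.05},
                         planted_n1=10, seed=7)
matrix, truth, cohort = cr.simulate_dataset(spec)
matrix = matrix.restrict_genes(cr.min_mutation_filter(matrix, cohort.n))
results = cr.screen(matrix, cohort, ss=100_000, seed=7)
print(results.head(4).to_string(index=False))
```

```
  gene  n1  k         L  p_conditional       p_alrt        q direction  hazard_ratio
DRIVER  10  9  7.909408       0.000015 7.651458e-15 0.000591      high     12.965086
SHIELD  10  0 -8.812812       0.000203 1.387217e-03 0.004063       low      0.000000
 G0024   7  5  3.543677       0.044964 2.729022e-03 0.474382      high      3.815802
 G0014   6  4  2.985752       0.069664 2.694165e-03 0.474382      high      4.246684
```

Both planted genes top the list. The pattern in the two p-value columns is
the method's point: for `DRIVER` (9 of 10 carriers died, $k=9$) the
$\chi^2$ approximation `p_alrt` overstates the evidence by seven orders of
magnitude, while for the protective `SHIELD` (no carrier died, $k=0$,
hazard ratio reported as 0 because the carrier group has no events) it
understates it — the conditional p-value is the calibrated one in both
regimes. `q` is the BH-adjusted value over the 40 genes that survived the
minimum-mutation filter.

The same screen is available from a shell:

```sh
corank simulate fixture/ --n 150 --n-genes 40 --plant DRIVER=8 --plant SHIELD=0.05 \
       --planted-n1 10 --seed 7
corank screen fixture/mutations.maf.tsv fixture/clinical.tsv out/ --seed 7
```

plus `corank test` (one group against survival) and `corank null`
(build, cache and tabulate a mixture null for plotting).

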