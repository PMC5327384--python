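"""Cohort screening: mutations + clinical follow-up -> per-gene survival tests.

Stages, in fixed order:

1. read mutation records (MAF dialect) keeping only coding-effect variant
   classes, collapse to a binary gene x sample incidence matrix;
2. read the clinical table and join on sample identifiers;
3. remove hypermutated samples (three-clause rule: more than 500 mutated
   genes AND within the top 5% most mutated samples AND above
   median + 4 * MAD of the per-sample mutated-gene counts);
4. drop genes mutated in fewer than 4 subjects (3 when the joined cohort
   has 74 or fewer subjects);
5. test every remaining gene: conditional-mixture p-value (one null built
   per distinct n1 and shared by all genes with that n1), chi-square
   approximation, Benjamini-Hochberg q-values over the tested set, risk
   direction and hazard ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .survival import (
    GroupAssignment,
    SurvivalCohort,
    alrt_pvalue,
    cooccurrence,
    logrank_scores,
    logrank_variance,
)
from .conditional import DEFAULT_SS, DEFAULT_SS_MIN, build_null, null_pvalue

log = logging.getLogger(__name__)

#: MAF variant classes with a clear coding effect (missense, nonsense,
#: frame-shift and in-frame indels, splicing); intronic/UTR/silent classes
#: are excluded.
QUALIFYING_CLASSES = frozenset({
    "Missense_Mutation",
    "Nonsense_Mutation",
    "Nonstop_Mutation",
    "Frame_Shift_Del",
    "Frame_Shift_Ins",
    "In_Frame_Del",
    "In_Frame_Ins",
    "Splice_Site",
    "Translation_Start_Site",
})

HYPERMUTATED_MIN_GENES = 500
HYPERMUTATED_TOP_QUANTILE = 0.95
HYPERMUTATED_MAD_FACTOR = 4.0
MIN_MUTATION_LARGE_COHORT = 4   # cohorts with >= 75 subjects
MIN_MUTATION_SMALL_COHORT = 3   # cohorts with <= 74 subjects
LARGE_COHORT_N = 75
DEFAULT_FDR = 0.333


class SchemaError(ValueError):
    """An input table is missing a required column or has malformed rows."""


@dataclass
class MutationMatrix:
    """Binary gene x sample incidence (1 = at least one qualifying mutation)."""

    incidence: pd.DataFrame  # index: gene, columns: sample, values 0/1 int8

    def __post_init__(self):
        self.incidence = self.incidence.astype(np.int8)
        if not self.incidence.isin([0, 1]).all().all():
            raise ValueError("incidence must be binary")

    @property
    def genes(self) -> list:
        return list(self.incidence.index)

    @property
    def samples(self) -> list:
        return list(self.incidence.columns)

    def genes_per_sample(self) -> pd.Series:
        """Number of mutated genes per sample (hypermutation metric)."""
        return self.incidence.sum(axis=0)

    def samples_per_gene(self) -> pd.Series:
        return self.incidence.sum(axis=1)

    def restrict_samples(self, samples) -> "MutationMatrix":
        return MutationMatrix(self.incidence.loc[:, list(samples)])

    def restrict_genes(self, genes) -> "MutationMatrix":
        return MutationMatrix(self.incidence.loc[list(genes)])


@dataclass
class GeneResult:
    gene: str
    n1: int
    k: int
    L: float
    p_conditional: float
    p_alrt: float
    q: float = np.nan
    direction: str = ""
    hazard_ratio: float = np.nan
    notes: str = ""


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_maf(path, qualifying_classes=QUALIFYING_CLASSES,
             gene_col: str = "Hugo_Symbol",
             sample_col: str = "Tumor_Sample_Barcode",
             class_col: str = "Variant_Classification",
             barcode_length: int | None = None) -> MutationMatrix:
    """Collapse a MAF-dialect TSV to a binary gene x sample matrix.

    Only records whose variant classification is in ``qualifying_classes``
    are kept; multiple records per gene-sample pair collapse to 1.
    ``barcode_length`` truncates sample barcodes (TCGA barcodes carry
    portion/analyte suffixes) before matching.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in (gene_col, sample_col, class_col):
        if col not in df.columns:
            raise SchemaError(f"mutation file {path} lacks required column {col!r}")
    df = df[df[class_col].isin(qualifying_classes)]
    if barcode_length is not None:
        df = df.assign(**{sample_col: df[sample_col].str[:barcode_length]})
    if df.empty:
        log.warning("no qualifying mutation records in %s", path)
        return MutationMatrix(pd.DataFrame(dtype=np.int8))
    inc = (
        df.groupby([gene_col, sample_col]).size().unstack(fill_value=0) > 0
    ).astype(np.int8)
    inc.index.name, inc.columns.name = "gene", "sample"
    return MutationMatrix(inc)


def read_matrix(path) -> MutationMatrix:
    """Read an already-binary gene x sample 0/1 TSV (genes as rows)."""
    inc = pd.read_csv(path, sep="\t", index_col=0)
    return MutationMatrix((inc > 0).astype(np.int8))


_EVENT_VOCAB = {
    "1": 1, "0": 0, "dead": 1, "deceased": 1, "death": 1, "event": 1,
    "alive": 0, "living": 0, "censored": 0, "true": 1, "false": 0,
}


def read_clinical(path, sample_col: str = "sample", time_col: str = "time",
                  event_col: str = "event") -> tuple[SurvivalCohort, dict]:
    """Read a clinical TSV into a sorted cohort plus sample -> row mapping.

    Event flags accept 0/1 or dead/alive vocabulary.  Row-level problems
    (negative time, unparseable flag) raise with 1-based line numbers;
    duplicate sample ids are an error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in (sample_col, time_col, event_col):
        if col not in df.columns:
            raise SchemaError(f"clinical file {path} lacks required column {col!r}")
    errors = []
    times, events = [], []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        try:
            t = float(row[time_col])
            if not np.isfinite(t) or t < 0:
                raise ValueError
        except (TypeError, ValueError):
            errors.append(f"line {line}: bad time {row[time_col]!r}")
            t = np.nan
        flag = str(row[event_col]).strip().lower()
        if flag not in _EVENT_VOCAB:
            errors.append(f"line {line}: bad event flag {row[event_col]!r}")
            events.append(-1)
        else:
            events.append(_EVENT_VOCAB[flag])
        times.append(t)
    if errors:
        raise SchemaError(f"clinical file {path}: " + "; ".join(errors))
    ids = df[sample_col].astype(str)
    if ids.duplicated().any():
        dups = sorted(ids[ids.duplicated()].unique())
        raise SchemaError(f"clinical file {path}: duplicate sample ids {dups}")
    cohort = SurvivalCohort.from_unsorted(times, events, tuple(ids))
    mapping = {sid: pos for pos, sid in enumerate(cohort.sample_ids)}
    return cohort, mapping


def join_samples(matrix: MutationMatrix, cohort: SurvivalCohort
                 ) -> tuple[MutationMatrix, SurvivalCohort]:
    """Intersect mutation and clinical sample sets; drops are logged."""
    if cohort.sample_ids is None:
        raise ValueError("cohort carries no sample ids; read it with read_clinical")
    shared = [s for s in cohort.sample_ids if s in set(matrix.samples)]
    dropped_clin = [s for s in cohort.sample_ids if s not in set(matrix.samples)]
    dropped_mut = [s for s in matrix.samples if s not in set(shared)]
    if dropped_clin:
        log.info("join: %d clinical samples lack mutation data", len(dropped_clin))
    if dropped_mut:
        log.info("join: %d mutation samples lack clinical data", len(dropped_mut))
    keep = [s in set(shared) for s in cohort.sample_ids]
    idx = np.flatnonzero(keep)
    sub = SurvivalCohort(cohort.times[idx], cohort.events[idx],
                         tuple(np.asarray(cohort.sample_ids, dtype=object)[idx]))
    return matrix.restrict_samples(sub.sample_ids), sub


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def filter_hypermutated(matrix: MutationMatrix, mad_scale: float = 1.0):
    """Remove samples satisfying all three hypermutation clauses.

    A sample is removed iff its mutated-gene count exceeds 500, is within
    the top 5% of counts, and exceeds median + 4 * MAD.  ``mad_scale`` of
    1.4826 gives the normal-consistent MAD; the default is the raw median
    absolute deviation.

    Returns (kept matrix, removed sample list, diagnostics DataFrame).
    """
    counts = matrix.genes_per_sample()
    med = float(counts.median())
    mad = float((counts - med).abs().median()) * mad_scale
    q95 = float(counts.quantile(HYPERMUTATED_TOP_QUANTILE))
    removed_mask = (
        (counts > HYPERMUTATED_MIN_GENES)
        & (counts >= q95)
        & (counts > med + HYPERMUTATED_MAD_FACTOR * mad)
    )
    diagnostics = pd.DataFrame({
        "mutated_genes": counts,
        "gt_500": counts > HYPERMUTATED_MIN_GENES,
        "top_5pct": counts >= q95,
        "gt_median_4mad": counts > med + HYPERMUTATED_MAD_FACTOR * mad,
        "removed": removed_mask,
    })
    diagnostics.attrs.update(median=med, mad=mad, quantile_95=q95)
    removed = list(counts.index[removed_mask])
    kept = matrix.restrict_samples(counts.index[~removed_mask])
    return kept, removed, diagnostics


def min_mutation_filter(matrix: MutationMatrix, n_subjects_with_survival: int) -> list:
    """Genes mutated often enough to test: >= 4 carriers (>= 3 if n <= 74)."""
    thr = (MIN_MUTATION_LARGE_COHORT if n_subjects_with_survival >= LARGE_COHORT_N
           else MIN_MUTATION_SMALL_COHORT)
    counts = matrix.samples_per_gene()
    return list(counts.index[counts >= thr])


def fdr_bh(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be finite and in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# per-gene summaries and the screen
# ---------------------------------------------------------------------------

def hazard_summary(cohort: SurvivalCohort, group: GroupAssignment,
                   method: str = "cox") -> tuple[str, float, str]:
    """Risk direction and hazard ratio for one gene.

    Direction is 'high' when carriers show more events than expected
    (L > 0).  ``method='cox'`` fits a univariate proportional-hazards model
    (falling back to the observed/expected event-ratio estimator when the
    fit is degenerate); ``method='oe'`` uses the O/E estimator directly.
    When one group has no events the ratio is reported as 0 or inf with an
    explanatory note instead of a fitted number.
    """
    L = tie_L = float(group.x @ logrank_scores(cohort, rng_seed=0))
    direction = "high" if L > 0 else "low"
    d1 = int(np.sum(cohort.events * group.x))
    d0 = cohort.d - d1
    if d1 == 0:
        return direction, 0.0, "no events among carriers"
    if d0 == 0:
        return direction, np.inf, "no events among non-carriers"

    # O/E ratio estimator: (O1/E1)/(O0/E0), E from the hypergeometric null
    E1 = d1 - tie_L
    E0 = cohort.d - E1
    oe = (d1 / E1) / (d0 / E0) if E1 > 0 and E0 > 0 else np.nan

    if method == "oe":
        return direction, float(oe), ""
    try:
        from lifelines import CoxPHFitter

        df = pd.DataFrame({
            "time": cohort.times, "event": cohort.events.astype(int),
            "carrier": group.x.astype(int),
        })
        cph = CoxPHFitter()
        cph.fit(df, duration_col="time", event_col="event")
        hr = float(np.exp(cph.params_["carrier"]))
        if not np.isfinite(hr):
            raise ValueError("non-finite Cox estimate")
        return direction, hr, ""
    except Exception as exc:  # degenerate fits fall back to the O/E ratio
        log.debug("Cox fit failed (%s); using O/E estimator", exc)
        return direction, float(oe), "o/e fallback"


def screen(matrix: MutationMatrix, cohort: SurvivalCohort,
           ss: int = DEFAULT_SS, ss_min: int = DEFAULT_SS_MIN, seed: int = 0,
           fdr_threshold: float = DEFAULT_FDR, tail: str = "two_sided",
           hr_method: str = "cox", n_tie_perms: int = 10) -> pd.DataFrame:
    """Test every gene in the matrix against survival.

    One conditional null is built per distinct carrier count n1 (seeded by
    ``(seed, n1)``, so rebuilding for a single gene reproduces the shared
    null exactly) and reused across all genes with that n1.  Genes whose
    carrier set is empty or covers the whole cohort are skipped.

    Returns a DataFrame with one row per tested gene, sorted by
    ``p_conditional``; ``significant`` marks q < ``fdr_threshold``.
    """
    if cohort.sample_ids is None:
        raise ValueError("cohort must carry sample ids aligned with the matrix")
    if list(matrix.samples) != list(cohort.sample_ids):
        matrix = matrix.restrict_samples(cohort.sample_ids)

    scores = logrank_scores(cohort, n_tie_perms, rng_seed=int(seed))
    inc = matrix.incidence.to_numpy()
    nulls: dict[int, object] = {}
    results: list[GeneResult] = []
    for gi, gene in enumerate(matrix.genes):
        x = inc[gi]
        n1 = int(x.sum())
        if n1 == 0 or n1 == cohort.n:
            log.info("skipping %s: degenerate carrier count n1=%d", gene, n1)
            continue
        group = GroupAssignment(x)
        if n1 not in nulls:
            nulls[n1] = build_null(cohort, n1, ss=ss, ss_min=ss_min,
                                   rng_seed=[int(seed), n1],
                                   n_tie_perms=n_tie_perms)
        L = float(x @ scores)
        k = cooccurrence(cohort, group)
        p_cond = null_pvalue(nulls[n1], L, tail)
        V = logrank_variance(cohort, group)
        p_alrt = alrt_pvalue(L, V) if V > 0 else 1.0
        direction, hr, note = hazard_summary(cohort, group, method=hr_method)
        results.append(GeneResult(gene=gene, n1=n1, k=k, L=L,
                                  p_conditional=p_cond, p_alrt=p_alrt,
                                  direction=direction, hazard_ratio=hr,
                                  notes=note))
    if not results:
        return pd.DataFrame(columns=["gene", "n1", "k", "L", "p_conditional",
                                     "p_alrt", "q", "direction",
                                     "hazard_ratio", "notes", "significant"])
    table = pd.DataFrame([vars(r) for r in results])
    table["q"] = fdr_bh(table["p_conditional"].to_numpy())
    table["significant"] = table["q"] < fdr_threshold
    return table.sort_values("p_conditional", kind="stable").reset_index(drop=True)
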