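"""Synthetic cohorts and mutation matrices with known ground truth.

The generator emulates the structure the screening pipeline consumes:

* follow-up times with exponential baseline hazard; an exact event count d
  is produced by drawing the event-indicator vector uniformly at random
  over subjects (events interleaved with censoring, the canonical null
  construction), while planted effect genes multiply their carriers' event
  hazard in a coherent process with independent exponential censoring
  (administrative cutoff available as an option);
* background genes mutated independently across samples at configurable
  per-gene frequencies, with an optional hypermutated sample fraction whose
  per-gene mutation probability is inflated;
* optional tied follow-up times (a configurable fraction of subjects copy
  another subject's time).

Everything is driven by one seed; a truth table records each planted
gene's hazard multiplier so recovery can be checked.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pipeline import QUALIFYING_CLASSES, MutationMatrix
from .survival import SurvivalCohort


@dataclass
class SimulationSpec:
    """Parameters of one synthetic dataset.

    ``d`` requests an exact number of events: the event indicators are then
    placed uniformly at random over subjects (with an administrative cutoff
    instead when ``censoring='administrative'``).  ``event_fraction``
    requests an expected fraction under the censoring mechanism.  Planted
    hazard effects always run the coherent time-to-event process, so there
    ``d`` guides the expected fraction only.
    """

    n: int = 100
    d: int | None = None
    event_fraction: float = 0.5
    censoring: str = "random"            # or "administrative"
    tie_intensity: float = 0.0           # fraction of subjects given a copied time
    n_genes: int = 100
    mutation_freq: tuple = (0.02, 0.10)  # per-gene carrier frequency range
    planted_effects: dict = field(default_factory=dict)  # gene name -> hazard multiplier
    planted_n1: int | None = None        # carriers per planted gene (default: freq draw)
    hypermutated_fraction: float = 0.0
    hypermutated_rate: float = 0.95      # per-gene mutation prob in hypermutated samples
    baseline_hazard: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.d is not None and self.d > self.n:
            raise ValueError(f"d={self.d} exceeds n={self.n}")
        for frac in (self.event_fraction, self.tie_intensity, self.hypermutated_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.censoring not in ("administrative", "random"):
            raise ValueError(f"unknown censoring mechanism {self.censoring!r}")


def _sample_ids(n: int) -> tuple:
    return tuple(f"S{i:05d}" for i in range(n))


def _apply_ties(times: np.ndarray, intensity: float, rng) -> np.ndarray:
    if intensity <= 0:
        return times
    n = times.size
    m = int(round(intensity * n))
    pick = rng.choice(n, size=m, replace=False)
    donors = rng.integers(0, n, size=m)
    times = times.copy()
    times[pick] = times[donors]
    return times


def _assemble_cohort(latent: np.ndarray, spec: SimulationSpec, rng,
                     planted: bool = False) -> SurvivalCohort:
    """Censor latent event times according to the spec."""
    n = spec.n
    if spec.d is not None and spec.censoring == "random" and not planted:
        # exact d, events interleaved: uniform random event-indicator vector
        times = latent
        events = np.zeros(n, dtype=np.int8)
        events[rng.choice(n, size=spec.d, replace=False)] = 1
    elif spec.censoring == "random":
        frac = spec.event_fraction if spec.d is None else spec.d / n
        # exponential censoring rate tuned so P(event) ~= frac for the baseline
        lam_c = spec.baseline_hazard * (1.0 - frac) / max(frac, 1e-9)
        cens = rng.exponential(1.0 / max(lam_c, 1e-12), size=n)
        times = np.minimum(latent, cens)
        events = (latent <= cens).astype(np.int8)
    else:
        d = spec.d if spec.d is not None else int(round(spec.event_fraction * n))
        d = min(max(d, 0), n)
        order = np.argsort(latent)
        events = np.zeros(n, dtype=np.int8)
        times = np.empty(n)
        if d > 0:
            cut = latent[order[d - 1]]
            events[order[:d]] = 1
            times[order[:d]] = latent[order[:d]]
        else:
            cut = float(np.min(latent)) * 0.5
        # everyone alive at the cutoff is censored between cutoff and horizon
        idx = order[d:]
        horizon = max(float(latent.max()), cut) * 1.05 + 1e-9
        times[idx] = rng.uniform(cut, horizon, size=idx.size)
    times = _apply_ties(times, spec.tie_intensity, rng)
    return SurvivalCohort.from_unsorted(times, events, _sample_ids(n))


def simulate_cohort(spec: SimulationSpec, rng=None) -> SurvivalCohort:
    """Cohort with the requested n (exact d when specified and unplanted)."""
    rng = np.random.default_rng(spec.seed if rng is None else rng)
    latent = rng.exponential(1.0 / spec.baseline_hazard, size=spec.n)
    return _assemble_cohort(latent, spec, rng)


def simulate_mutations(spec: SimulationSpec, cohort: SurvivalCohort | None = None,
                       rng=None):
    """Mutation matrix, truth table and (possibly regenerated) cohort.

    Background genes are independent Bernoulli per sample.  Planted effect
    genes multiply their carriers' event hazard, so when any effect is
    planted the latent event times are regenerated jointly with the carrier
    assignment (the input cohort's spec parameters are reused); without
    planted effects the input cohort passes through unchanged.
    """
    rng = np.random.default_rng(spec.seed + 1 if rng is None else rng)
    n = spec.n
    ids = _sample_ids(n)

    gene_names = [f"G{i:04d}" for i in range(spec.n_genes)]
    for g in spec.planted_effects:
        if g not in gene_names:
            gene_names.append(g)
    lo, hi = spec.mutation_freq
    freqs = rng.uniform(lo, hi, size=len(gene_names))

    n_hyper = int(round(spec.hypermutated_fraction * n))
    hyper_idx = rng.choice(n, size=n_hyper, replace=False) if n_hyper else np.empty(0, int)

    inc = np.zeros((len(gene_names), n), dtype=np.int8)
    planted = set(spec.planted_effects)
    # planted carrier sets are disjoint so each planted effect is unconfounded
    free = np.arange(n)
    for gi, (gene, f) in enumerate(zip(gene_names, freqs)):
        if gene in planted and spec.planted_n1 is not None:
            if free.size < spec.planted_n1:
                raise ValueError("not enough subjects for disjoint planted genes")
            pick = rng.choice(free.size, size=spec.planted_n1, replace=False)
            inc[gi, free[pick]] = 1
            free = np.delete(free, pick)
        else:
            inc[gi] = rng.random(n) < f
    if n_hyper:
        boost = rng.random((len(gene_names), n_hyper)) < spec.hypermutated_rate
        inc[:, hyper_idx] |= boost.astype(np.int8)

    # per-subject hazard multipliers from planted genes carried
    mult = np.ones(n)
    for gene, rho in spec.planted_effects.items():
        gi = gene_names.index(gene)
        mult *= np.where(inc[gi] == 1, float(rho), 1.0)

    if spec.planted_effects or cohort is None:
        latent = rng.exponential(1.0 / (spec.baseline_hazard * mult))
        cohort = _assemble_cohort(latent, spec, rng, planted=bool(spec.planted_effects))
    # align matrix columns with the cohort's (sorted) sample order
    frame = pd.DataFrame(inc, index=gene_names, columns=ids)
    frame = frame.loc[:, list(cohort.sample_ids)]
    frame.index.name, frame.columns.name = "gene", "sample"
    matrix = MutationMatrix(frame)

    truth = pd.DataFrame({
        "gene": gene_names,
        "frequency": freqs,
        "n1": inc.sum(axis=1),
        "hazard_multiplier": [spec.planted_effects.get(g, 1.0) for g in gene_names],
        "planted": [g in planted for g in gene_names],
    }).set_index("gene")
    truth.attrs["hypermutated_samples"] = [ids[i] for i in sorted(hyper_idx)]
    return matrix, truth, cohort


def simulate_dataset(spec: SimulationSpec):
    """One-call generator: (matrix, truth, cohort) under a single seed."""
    rng = np.random.default_rng(spec.seed)
    cohort = simulate_cohort(spec, rng)
    return simulate_mutations(spec, cohort, rng)


def write_fixture(matrix: MutationMatrix, cohort: SurvivalCohort, outdir,
                  seed: int = 0) -> dict:
    """Write MAF-dialect and clinical TSVs that round-trip through the readers.

    Each gene-sample incidence becomes one MAF record with a qualifying
    variant class drawn at random (seeded).  Returns the written paths.
    """
    import os

    os.makedirs(outdir, exist_ok=True)
    rng = np.random.default_rng(seed)
    classes = sorted(QUALIFYING_CLASSES)
    maf_path = os.path.join(outdir, "mutations.maf.tsv")
    clin_path = os.path.join(outdir, "clinical.tsv")

    rows = []
    inc = matrix.incidence
    for gene in inc.index:
        for sample in inc.columns[inc.loc[gene].to_numpy() == 1]:
            rows.append((gene, sample, classes[rng.integers(len(classes))]))
    pd.DataFrame(rows, columns=["Hugo_Symbol", "Tumor_Sample_Barcode",
                                "Variant_Classification"]).to_csv(
        maf_path, sep="\t", index=False)

    if cohort.sample_ids is None:
        raise ValueError("cohort must carry sample ids to be written")
    pd.DataFrame({
        "sample": list(cohort.sample_ids),
        "time": cohort.times,
        "event": cohort.events.astype(int),
    }).to_csv(clin_path, sep="\t", index=False)
    return {"maf": maf_path, "clinical": clin_path}
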