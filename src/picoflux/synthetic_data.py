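"""Synthetic 13C-labeling experiments with known ground truth.

Emulates an inorganic-carbon tracer experiment in a photosynthetic
picocyanobacterium: a 13C-bicarbonate spike doubles the dissolved inorganic
carbon pool (0.6 mM added on 0.6 mM ambient, so the substrate label fraction
is ~0.5), cultures are sampled at 0/30/60/90 min with triplicate technical
measurements, and each metabolite pool turns over by first-order kinetics.

Generative model per metabolite (carbon count c, pool turnover rate k,
precursor-enrichment rate k_pre):

* precursor atom enrichment rises as ``e(t) = p_sub * (1 - exp(-k_pre t))``
  (fixation products equilibrate with the spiked DIC pool);
* molecules synthesized at time s carry carbons labeled i.i.d. with
  probability e(s), i.e. an isotopologue distribution ``Binomial(c, e(s))``;
* the fraction of the pool renewed by time t is ``f(t) = 1 - exp(-k t)``, so

      MDV(t) = exp(-k t) * delta_0
               + integral_0^t k exp(-k (t-s)) Binomial(c, e(s)) ds

  evaluated by discrete time stepping (exact survival weights per step,
  midpoint enrichment);
* 13C natural abundance is applied to the remaining unlabeled carbon
  positions by binomial convolution, so t = 0 samples (drawn before the
  spike) show the pure natural-abundance pattern;
* ion counts are the MDV scaled so the expected TIC equals
  pool_size * cell_density, then multiplied by lognormal noise with the
  configured CV.

The same noise-free forward model is re-exported by the kinetics module so
fitting diagnostics and simulation cannot drift apart.  Ground truth (e, f,
true FC, k, pool size) is recorded for every metabolite/time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import (
    NATURAL_13C_ABUNDANCE,
    natural_abundance_matrix,
    natural_abundance_vector,
)
from .physiology import (
    C14Assay,
    DEFAULT_DIC_MOL_L,
    DEFAULT_SPIKE_ACTIVITY_DPM,
    GLYCOGEN_STANDARDS_MG_ML,
    GlycogenAssay,
)

__all__ = [
    "MetabolitePoolSpec",
    "LabelingExperimentConfig",
    "LabelingExperiment",
    "ConditionPair",
    "SIM_DT_MIN",
    "precursor_enrichment",
    "mdv_progression",
    "true_fractional_contribution",
    "simulate_labeling_experiment",
    "simulate_condition_pair",
    "simulate_c14_assay",
    "simulate_glycogen_assay",
    "default_metabolite_panel",
]

#: Time step (minutes) for the synthesis integral; discretization error is far
#: below the 5 % measurement noise.  Validation oracles should use a finer step.
SIM_DT_MIN = 0.1


@dataclass(frozen=True)
class MetabolitePoolSpec:
    """One metabolite pool: backbone size, abundance and turnover.

    ``pool_size`` is the per-cell relative abundance (expected TIC per
    cell/ml of culture); ``turnover_rate`` k (1/min) is the first-order rate
    at which pool molecules are replaced by newly synthesized ones;
    ``precursor_rise`` k_pre (1/min) is the rate at which the atom
    enrichment of the biosynthetic precursor approaches the substrate label
    fraction.  Large pools with small k are "large slow-moving pools".
    """

    name: str
    c: int
    pool_size: float
    turnover_rate: float
    precursor_rise: float

    def __post_init__(self):
        if self.c < 1:
            raise ValueError(f"{self.name}: carbon count must be >= 1")
        if self.pool_size <= 0:
            raise ValueError(f"{self.name}: pool_size must be > 0")
        if self.turnover_rate < 0 or self.precursor_rise < 0:
            raise ValueError(f"{self.name}: rates must be >= 0")


@dataclass(frozen=True)
class LabelingExperimentConfig:
    """Design of one labeling experiment.

    Defaults reproduce the study conditions: a 50 % substrate label fraction
    (0.6 mM 13C spike on 0.6 mM ambient bicarbonate), sampling at
    0/30/60/90 min, 3 technical x 2 biological replicates, 13C natural
    abundance 1.07 %, 5 % multiplicative ion-count noise, and a cell density
    at the chemostat steady-state plateau.
    """

    substrate_label_fraction: float = 0.5
    timepoints: tuple = (0.0, 30.0, 60.0, 90.0)
    n_technical: int = 3
    n_biological: int = 2
    natural_abundance: float = NATURAL_13C_ABUNDANCE
    noise_cv: float = 0.05
    cell_density: float = 4.5e7
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.substrate_label_fraction <= 1.0:
            raise ValueError("substrate_label_fraction must be in [0, 1]")
        if not 0.0 <= self.natural_abundance <= 1.0:
            raise ValueError("natural_abundance must be in [0, 1]")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        t = tuple(float(x) for x in self.timepoints)
        if len(t) < 1 or t[0] != 0.0 or any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("timepoints must be strictly increasing and start at 0")
        if self.n_technical < 1 or self.n_biological < 1:
            raise ValueError("replicate counts must be >= 1")
        if self.cell_density <= 0:
            raise ValueError("cell_density must be > 0")
        object.__setattr__(self, "timepoints", t)


# ---------------------------------------------------------------------------
# Noise-free forward model (shared with kinetics.predict_mdv_progression)
# ---------------------------------------------------------------------------

def precursor_enrichment(t, k_pre: float, p_sub: float):
    """Atom enrichment of the biosynthetic precursor, e(t) = p_sub (1 - e^{-k_pre t})."""
    t = np.asarray(t, dtype=float)
    if math.isinf(k_pre):
        return np.where(t > 0, p_sub, 0.0)
    return p_sub * (1.0 - np.exp(-k_pre * t))


def mdv_progression(
    t: float,
    c: int,
    k: float,
    k_pre: float,
    p_sub: float,
    p_na: float = 0.0,
    dt: float = SIM_DT_MIN,
) -> np.ndarray:
    """Noise-free pool MDV at time t under first-order turnover.

    The synthesis integral is evaluated on a fixed grid: each interval
    [s_j, s_{j+1}] contributes its exact surviving pool mass
    ``exp(-k (t - s_{j+1})) - exp(-k (t - s_j))`` with the binomial
    isotopologue distribution at the midpoint enrichment; the unrenewed
    fraction ``exp(-k t)`` stays at the unlabeled pattern.  Natural
    abundance is then applied to the unlabeled positions by binomial
    convolution, so at t = 0 (or k = 0) the result is the pure
    natural-abundance pattern Binomial(c, p_na).
    """
    if t < 0:
        raise ValueError("time must be >= 0")
    if k < 0 or k_pre < 0:
        raise ValueError("rates must be >= 0")
    i = np.arange(c + 1)
    if t == 0.0 or k == 0.0:
        return natural_abundance_vector(c, p_na) if p_na > 0 else stats.binom.pmf(i, c, 0.0)
    if math.isinf(k):
        # Instantly equilibrated pool: tracks the precursor at the current time.
        e_now = float(precursor_enrichment(t, k_pre, p_sub))
        mdv = stats.binom.pmf(i, c, e_now)
    else:
        n_steps = max(1, int(math.ceil(t / dt)))
        edges = np.linspace(0.0, t, n_steps + 1)
        survive = np.exp(-k * (t - edges))
        weights = survive[1:] - survive[:-1]  # exact mass synthesized per interval
        mids = 0.5 * (edges[:-1] + edges[1:])
        e_mid = precursor_enrichment(mids, k_pre, p_sub)
        pmf = stats.binom.pmf(i[:, None], c, e_mid[None, :])  # (c+1, n_steps)
        mdv = pmf @ weights
        mdv[0] += math.exp(-k * t)  # unrenewed fraction, still unlabeled
    if p_na > 0:
        mdv = natural_abundance_matrix(c, p_na) @ mdv
    return mdv


def true_fractional_contribution(
    t: float,
    c: int,
    k: float,
    k_pre: float,
    p_sub: float,
    p_na: float = 0.0,
    dt: float = SIM_DT_MIN,
) -> float:
    """Ground-truth FC implied by the forward model (mean label fraction)."""
    mdv = mdv_progression(t, c, k, k_pre, p_sub, p_na=p_na, dt=dt)
    return float(np.dot(mdv, np.arange(c + 1)) / c)


# ---------------------------------------------------------------------------
# Experiment simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LabelingExperiment:
    """A simulated experiment: tidy isotopologue table plus ground truth."""

    table: pd.DataFrame
    ground_truth: pd.DataFrame
    condition: str
    config: LabelingExperimentConfig
    specs: tuple


def _replicate_rng(
    seed: int, condition_index: int, bio: int, tech: int, met_index: int, time_index: int
) -> np.random.Generator:
    # Deterministic, order-independent substream per condition/replicate/sample
    # derived from the one master seed.
    return np.random.default_rng([seed, condition_index, bio, tech, met_index, time_index])


def simulate_labeling_experiment(
    specs: Sequence[MetabolitePoolSpec],
    config: LabelingExperimentConfig,
    condition: str = "N-replete",
    condition_index: int = 0,
) -> LabelingExperiment:
    """Simulate one labeling experiment for a panel of metabolite pools.

    Returns a tidy table (metabolite, i, c, condition, biological_replicate,
    technical_replicate, time_min, ion_count) together with a ground-truth
    table carrying, per metabolite and timepoint, the precursor enrichment
    e(t), renewed pool fraction f(t), true FC (natural abundance included),
    the turnover rate k and the pool size.  Time-zero samples are drawn from
    the unspiked model and show only natural abundance.  Replicate noise is
    lognormal and multiplicative per isotopologue entry with mean 1 and the
    configured CV; with ``noise_cv = 0`` the counts are the exact noise-free
    expectations.  Same seed, same output, bit for bit.
    """
    specs = tuple(specs)
    if not specs:
        raise ValueError("need at least one metabolite spec")
    p_sub = config.substrate_label_fraction
    p_na = config.natural_abundance
    cv = config.noise_cv
    sigma = math.sqrt(math.log1p(cv * cv)) if cv > 0 else 0.0

    rows = []
    truth_rows = []
    for met_index, spec in enumerate(specs):
        expected_tic = spec.pool_size * config.cell_density
        for time_index, t in enumerate(config.timepoints):
            mdv = mdv_progression(
                t, spec.c, spec.turnover_rate, spec.precursor_rise, p_sub, p_na=p_na
            )
            e_t = float(np.asarray(precursor_enrichment(t, spec.precursor_rise, p_sub)))
            f_t = (
                1.0
                if math.isinf(spec.turnover_rate) and t > 0
                else 1.0 - math.exp(-spec.turnover_rate * t)
            )
            fc_true = float(np.dot(mdv, np.arange(spec.c + 1)) / spec.c)
            truth_rows.append(
                dict(
                    metabolite=spec.name,
                    condition=condition,
                    time_min=t,
                    precursor_enrichment=e_t,
                    renewed_fraction=f_t,
                    fc_true=fc_true,
                    turnover_rate=spec.turnover_rate,
                    pool_size=spec.pool_size,
                )
            )
            mean_counts = mdv * expected_tic
            for bio in range(1, config.n_biological + 1):
                for tech in range(1, config.n_technical + 1):
                    if sigma > 0:
                        rng = _replicate_rng(
                            config.seed, condition_index, bio, tech, met_index, time_index
                        )
                        # mean-1 lognormal per isotopologue entry
                        noise = rng.lognormal(-0.5 * sigma * sigma, sigma, spec.c + 1)
                    else:
                        noise = np.ones(spec.c + 1)
                    counts = mean_counts * noise
                    for i, ic in enumerate(counts):
                        rows.append(
                            dict(
                                metabolite=spec.name,
                                i=i,
                                c=spec.c,
                                condition=condition,
                                biological_replicate=bio,
                                technical_replicate=tech,
                                time_min=t,
                                ion_count=float(ic),
                            )
                        )
    table = pd.DataFrame(rows)
    truth = pd.DataFrame(truth_rows)
    return LabelingExperiment(
        table=table, ground_truth=truth, condition=condition, config=config, specs=specs
    )


@dataclass(frozen=True)
class ConditionPair:
    """Matched N-replete / N-limited experiments from a shared panel."""

    replete: LabelingExperiment
    limited: LabelingExperiment
    limitation_factor: float


def simulate_condition_pair(
    specs: Sequence[MetabolitePoolSpec],
    config: LabelingExperimentConfig,
    limitation_factor: float = 3.0,
    *,
    allow_unit_factor: bool = False,
) -> ConditionPair:
    """Simulate an N-replete / N-limited pair from one metabolite panel.

    Nitrogen limitation is encoded as "large slow-moving pools": each pool
    size is multiplied by ``limitation_factor`` and each turnover rate
    divided by it, preserving the flux proxy k x pool.  The factor must be
    > 1 (``allow_unit_factor=True`` admits exactly 1 for null-contrast
    checks).  The two conditions use independent noise substreams of the
    same master seed.
    """
    if limitation_factor < 1.0 or (limitation_factor == 1.0 and not allow_unit_factor):
        raise ValueError(f"limitation_factor must be > 1, got {limitation_factor}")
    limited_specs = [
        replace(
            s,
            pool_size=s.pool_size * limitation_factor,
            turnover_rate=s.turnover_rate / limitation_factor,
        )
        for s in specs
    ]
    replete = simulate_labeling_experiment(specs, config, "N-replete", condition_index=0)
    limited = simulate_labeling_experiment(
        limited_specs, config, "N-limited", condition_index=1
    )
    return ConditionPair(replete=replete, limited=limited, limitation_factor=limitation_factor)


# ---------------------------------------------------------------------------
# Bulk physiology generators
# ---------------------------------------------------------------------------

def simulate_c14_assay(
    true_fixation_rate: float,
    particulate_fraction: float,
    dark_rate: float = 2.0e-19,
    counting_noise: float = 0.0,
    seed: int = 0,
    *,
    spike_activity: float = DEFAULT_SPIKE_ACTIVITY_DPM,
    dic: float = DEFAULT_DIC_MOL_L,
    volume_l: float = 0.002,
    duration_h: float = 1.0,
    cell_density: float = 4.5e7,
    n_replicates: int = 3,
) -> tuple[C14Assay, C14Assay]:
    """Simulate triplicate light/dark scintillation readings for TOC and POC.

    ``true_fixation_rate`` and ``dark_rate`` are per-cell rates
    (mol C/cell/h); the particulate fraction scales the POC light signal.
    Counts are the deterministic DPM expectations under the standard
    light-minus-dark rate equation plus Gaussian counting noise of standard
    deviation ``counting_noise`` (DPM), truncated at zero.  With zero noise
    the downstream rate estimator recovers the configured rates exactly.
    """
    if not 0.0 <= particulate_fraction <= 1.0:
        raise ValueError("particulate_fraction must be in [0, 1]")
    if true_fixation_rate < 0 or dark_rate < 0:
        raise ValueError("rates must be >= 0")
    rng = np.random.default_rng([seed, 14])
    volume_ml = volume_l * 1000.0
    cells = cell_density * volume_ml
    to_dpm = spike_activity * duration_h * cells / (dic * volume_l)

    def triplicate(rate_mean: float) -> tuple:
        mean_dpm = rate_mean * to_dpm
        vals = mean_dpm + rng.normal(0.0, counting_noise, n_replicates) if counting_noise > 0 else np.full(n_replicates, mean_dpm)
        return tuple(float(max(v, 0.0)) for v in vals)

    common = dict(
        spike_activity=spike_activity,
        dic=dic,
        volume_l=volume_l,
        duration_h=duration_h,
        cell_density=cell_density,
    )
    toc = C14Assay(
        light_counts=triplicate(dark_rate + true_fixation_rate),
        dark_counts=triplicate(dark_rate),
        fraction_label="TOC",
        **common,
    )
    poc = C14Assay(
        light_counts=triplicate(dark_rate + true_fixation_rate * particulate_fraction),
        dark_counts=triplicate(dark_rate),
        fraction_label="POC",
        **common,
    )
    return toc, poc


def simulate_glycogen_assay(
    true_conc: float,
    slope: float = 0.004,
    intercept: float = 0.02,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> GlycogenAssay:
    """Simulate the phenol-sulfuric acid glucose standard curve plus one sample.

    Absorbance follows ``A = slope * conc + intercept + N(0, noise_sd)`` at
    the six glucose standards (250/100/75/50/25/10 mg/ml) and the sample.
    """
    if slope <= 0:
        raise ValueError("slope must be > 0")
    if true_conc < 0:
        raise ValueError("true_conc must be >= 0")
    rng = np.random.default_rng([seed, 488])
    concs = np.asarray(GLYCOGEN_STANDARDS_MG_ML)
    noise = rng.normal(0.0, noise_sd, concs.size + 1) if noise_sd > 0 else np.zeros(concs.size + 1)
    std_abs = slope * concs + intercept + noise[:-1]
    sample_abs = slope * true_conc + intercept + noise[-1]
    return GlycogenAssay(
        standard_concs=tuple(concs),
        standard_abs=tuple(std_abs),
        sample_abs=float(sample_abs),
    )


# ---------------------------------------------------------------------------
# Default panel
# ---------------------------------------------------------------------------

def default_metabolite_panel() -> list[MetabolitePoolSpec]:
    """Central-carbon/nitrogen panel with field-realistic sizes and turnover.

    Carbon counts are the true backbone lengths.  Pool sizes (per-cell
    relative abundance, arbitrary ion-count units) and first-order rates are
    chosen to span the observed behaviors: fast-labeling Calvin-cycle
    intermediates (G3P, PEP) that saturate within ~30 min, slower sugar
    phosphates, and amino-acid pools.  Precursor rise rates are faster than
    pool turnover since fixation products feed the pools.
    """
    return [
        MetabolitePoolSpec("G3P", 3, 0.8, 0.12, 0.30),
        MetabolitePoolSpec("PEP", 3, 0.6, 0.10, 0.30),
        MetabolitePoolSpec("F6P", 6, 2.5, 0.05, 0.20),
        MetabolitePoolSpec("G6P", 6, 2.0, 0.045, 0.20),
        MetabolitePoolSpec("S7P", 7, 1.8, 0.04, 0.20),
        MetabolitePoolSpec("citrate", 6, 1.2, 0.02, 0.10),
        MetabolitePoolSpec("2-oxoglutarate", 5, 1.5, 0.025, 0.10),
        MetabolitePoolSpec("glutamate", 5, 8.0, 0.03, 0.10),
        MetabolitePoolSpec("glutamine", 5, 1.0, 0.035, 0.10),
        MetabolitePoolSpec("aspartate", 4, 2.2, 0.04, 0.12),
        MetabolitePoolSpec("N-acetyl-glutamate", 7, 0.5, 0.015, 0.08),
    ]
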