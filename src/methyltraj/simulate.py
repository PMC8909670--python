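"""Synthetic methylation cohorts with a latent aging state.

The generator draws per-sample ages, maps them to a latent state through a
saturating sum-of-two-exponentials trend, and emits beta values that respond
linearly to the state at a configurable fraction of sites, with Gaussian
noise on the beta scale.  The generating parameters are retained so that
downstream estimators can be tested for parameter recovery.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Optional, Sequence, Tuple

import numpy as np

from .datasets import InputError, MethylationDataset

logger = logging.getLogger(__name__)

#: Default latent-trend coefficients (a, b, c, d) for a blood-like cohort.
BLOOD_TREND = (14.487, 0.019, 0.307, 0.105)


class ParameterError(ValueError):
    """Raised for invalid simulation parameters."""


@dataclasses.dataclass
class SimulationConfig:
    """Parameters of a synthetic cohort.

    ``latent_form_params`` are the (a, b, c, d) coefficients of the latent
    trend ``a * (1 + c - exp(-b*age) - c*exp(-d*age))``; ``frac_age_associated``
    is the fraction of sites whose mean responds linearly to the latent state.
    """

    n_samples: int = 200
    age_range: Tuple[float, float] = (0.0, 99.0)
    age_distribution: str = "uniform"  # or "right-skewed"
    n_sites: int = 500
    frac_age_associated: float = 0.5
    latent_form_params: Tuple[float, float, float, float] = BLOOD_TREND
    site_intercept_range: Tuple[float, float] = (0.1, 0.9)
    site_rate_range: Tuple[float, float] = (0.015, 0.03)
    noise_sd: float = 0.02
    state_noise_sd: float = 0.0
    probe_type_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2 or self.n_sites < 2:
            raise ParameterError("need n_samples >= 2 and n_sites >= 2")
        if self.noise_sd < 0 or self.state_noise_sd < 0:
            raise ParameterError("noise standard deviations must be >= 0")
        if not 0.0 <= self.frac_age_associated <= 1.0:
            raise ParameterError("frac_age_associated must lie in [0, 1]")
        if not 0.0 <= self.probe_type_fraction <= 1.0:
            raise ParameterError("probe_type_fraction must lie in [0, 1]")
        if self.age_distribution not in ("uniform", "right-skewed"):
            raise ParameterError(f"unknown age_distribution {self.age_distribution!r}")
        a, b, c, d = self.latent_form_params
        if a <= 0 or b <= 0 or d <= 0:
            raise ParameterError("latent trend requires a > 0, b > 0, d > 0")
        lo, hi = self.age_range
        if lo < 0 or hi <= lo:
            raise ParameterError("age_range must satisfy 0 <= min < max")
        ages = np.linspace(lo, hi, 512)
        if (latent_trend(ages, self.latent_form_params) < -1e-12).any():
            raise ParameterError("latent trend is negative inside age_range")
        if self.site_rate_range[0] < 0 or self.site_rate_range[0] > self.site_rate_range[1]:
            raise ParameterError("site_rate_range must be 0 <= lo <= hi")


@dataclasses.dataclass
class SyntheticTruth:
    """Generating values kept aside for parameter-recovery tests."""

    latent_states: np.ndarray     # per-sample true state
    site_intercepts: np.ndarray   # per-site baseline methylation
    site_rates: np.ndarray        # per-site response; exactly 0 for null sites
    seed_used: int
    sample_ids: Optional[list] = None
    probe_ids: Optional[list] = None

    def __post_init__(self) -> None:
        self.latent_states = np.asarray(self.latent_states, dtype=float)
        self.site_intercepts = np.asarray(self.site_intercepts, dtype=float)
        self.site_rates = np.asarray(self.site_rates, dtype=float)

    def states_for(self, dataset: MethylationDataset) -> np.ndarray:
        """Generating latent states aligned to the samples of ``dataset``."""
        if self.sample_ids is None:
            raise InputError("truth carries no sample identifiers")
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        return self.latent_states[[pos[s] for s in dataset.sample_ids]]


def latent_trend(ages: np.ndarray, form_params: Sequence[float]) -> np.ndarray:
    """Noise-free latent state: ``a * (1 + c - exp(-b*x) - c*exp(-d*x))``."""
    a, b, c, d = form_params
    ages = np.asarray(ages, dtype=float)
    return a * (1.0 + c - np.exp(-b * ages) - c * np.exp(-d * ages))


def simulate_states(ages, form_params, state_noise_sd: float = 0.0,
                    seed: int = 0, rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Latent states for the given ages: deterministic trend plus Gaussian noise.

    Deterministic given ``seed`` (or an explicitly supplied generator).
    """
    ages = np.asarray(ages, dtype=float)
    if (ages < 0).any():
        raise ParameterError("ages must be >= 0")
    a, b, c, d = form_params
    if a <= 0 or b <= 0 or d <= 0:
        raise ParameterError("latent trend requires a > 0, b > 0, d > 0")
    if state_noise_sd < 0:
        raise ParameterError("state_noise_sd must be >= 0")
    states = latent_trend(ages, form_params)
    if state_noise_sd > 0:
        gen = rng if rng is not None else np.random.default_rng(seed)
        states = states + gen.normal(0.0, state_noise_sd, size=ages.shape)
    return states


def _draw_ages(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    lo, hi = config.age_range
    if config.age_distribution == "uniform":
        return rng.uniform(lo, hi, size=config.n_samples)
    # adult-heavy mixture: 25% uniform over the full range, 75% over the
    # upper 70% of the range
    from_full = rng.random(config.n_samples) < 0.25
    ages = rng.uniform(lo + 0.3 * (hi - lo), hi, size=config.n_samples)
    ages[from_full] = rng.uniform(lo, hi, size=int(from_full.sum()))
    return ages


def simulate_betas(states, config: SimulationConfig,
                   rng: Optional[np.random.Generator] = None
                   ) -> Tuple[MethylationDataset, SyntheticTruth]:
    """Emit a beta matrix responding linearly to the latent states.

    For age-associated sites ``beta = clip(m0 + r*s + eps, 0, 1)``; the
    remaining sites are constant-mean plus noise (rate exactly 0).  Rate signs
    are drawn symmetrically and intercepts are placed so the noise-free mean
    stays inside [0, 1] over the observed state range; when that is impossible
    a warning is logged and values are clipped.
    """
    states = np.asarray(states, dtype=float)
    if states.shape != (config.n_samples,):
        raise ParameterError("states length must equal config.n_samples")
    gen = rng if rng is not None else np.random.default_rng(config.seed)

    n_assoc = int(round(config.frac_age_associated * config.n_sites))
    n_null = config.n_sites - n_assoc
    s_lo, s_hi = float(states.min()), float(states.max())
    margin = 0.02

    rates = np.zeros(config.n_sites)
    intercepts = np.empty(config.n_sites)

    signs = np.where(gen.random(n_assoc) < 0.5, -1.0, 1.0)
    mags = gen.uniform(*config.site_rate_range, size=n_assoc)
    r = signs * mags
    lo_b = np.where(r > 0, margin - r * s_lo, margin - r * s_hi)
    hi_b = np.where(r > 0, 1 - margin - r * s_hi, 1 - margin - r * s_lo)
    draw = gen.uniform(*config.site_intercept_range, size=n_assoc)
    infeasible = lo_b > hi_b
    if infeasible.any():
        logger.warning("%d sites cannot keep mean betas inside [0,1]; clipping",
                       int(infeasible.sum()))
        mid = 0.5 * (lo_b + hi_b)
        lo_b, hi_b = np.minimum(lo_b, mid), np.maximum(hi_b, mid)
    m0 = np.clip(draw, lo_b, hi_b)
    rates[:n_assoc] = r
    intercepts[:n_assoc] = m0
    intercepts[n_assoc:] = gen.uniform(0.1, 0.9, size=n_null)

    mean = intercepts[:, None] + rates[:, None] * states[None, :]
    noise = gen.normal(0.0, config.noise_sd, size=mean.shape) if config.noise_sd > 0 else 0.0
    raw = mean + noise
    n_clipped = int(((raw < 0) | (raw > 1)).sum())
    if n_clipped:
        logger.warning("clipped %d beta values to [0, 1]", n_clipped)
    betas = np.clip(raw, 0.0, 1.0)

    probe_types = np.where(gen.random(config.n_sites) < config.probe_type_fraction,
                           "II", "I").astype(object)
    dataset = MethylationDataset(
        betas=betas,
        sample_ids=[f"S{j:05d}" for j in range(config.n_samples)],
        ages=np.zeros(config.n_samples),  # placeholder; caller sets real ages
        probe_ids=[f"cg{i:07d}" for i in range(config.n_sites)],
        probe_types=probe_types,
    )
    truth = SyntheticTruth(latent_states=states.copy(), site_intercepts=intercepts,
                           site_rates=rates, seed_used=config.seed,
                           sample_ids=list(dataset.sample_ids),
                           probe_ids=list(dataset.probe_ids))
    return dataset, truth


def stratified_split(ages, fractions: Sequence[float], rng: np.random.Generator):
    """Age-stratified split labels with exact global counts.

    Samples are ordered by age (random tie-breaking) and assigned to splits by
    a largest-deficit quota walk, so each age window contains every split in
    close to its global proportion while final counts match ``round(n * f)``
    exactly (largest-remainder apportionment).
    Returns an integer label per sample, 0..len(fractions)-1.
    """
    fractions = np.asarray(fractions, dtype=float)
    if abs(fractions.sum() - 1.0) > 1e-9 or (fractions < 0).any():
        raise ParameterError("split fractions must be non-negative and sum to 1")
    n = len(ages)
    base = np.floor(fractions * n).astype(int)
    remainder = fractions * n - base
    short = n - base.sum()
    for i in np.argsort(-remainder, kind="stable")[:short]:
        base[i] += 1
    targets = base

    shuffle = rng.permutation(n)
    order = shuffle[np.argsort(np.asarray(ages, dtype=float)[shuffle], kind="stable")]
    labels = np.empty(n, dtype=int)
    assigned = np.zeros(len(fractions), dtype=int)
    for step, sample in enumerate(order, start=1):
        deficit = targets * step / n - assigned
        deficit[assigned >= targets] = -np.inf
        labels[sample] = int(np.argmax(deficit))
        assigned[labels[sample]] += 1
    return labels


def simulate_cohort(config: SimulationConfig,
                    split_fractions: Sequence[float] = (0.3, 0.1, 0.6)):
    """Full cohort: draw ages, simulate states and betas, split by age strata.

    Returns ``(train, validation, test, truth)`` where the three datasets are
    disjoint and exhaustive.  Split fractions default to 0.3/0.1/0.6.
    Bit-identical for identical ``(config, split_fractions)``.
    """
    fractions = np.asarray(split_fractions, dtype=float)
    if abs(fractions.sum() - 1.0) > 1e-9:
        raise ParameterError("split fractions must sum to 1")
    ss = np.random.SeedSequence(config.seed)
    age_rng, state_rng, beta_rng, split_rng = (np.random.default_rng(c)
                                               for c in ss.spawn(4))
    ages = _draw_ages(config, age_rng)
    states = simulate_states(ages, config.latent_form_params,
                             config.state_noise_sd, rng=state_rng)
    dataset, truth = simulate_betas(states, config, rng=beta_rng)
    dataset.ages = ages.copy()
    labels = stratified_split(ages, fractions, split_rng)
    splits = [dataset.select_samples(np.flatnonzero(labels == k)) for k in range(3)]
    return splits[0], splits[1], splits[2], truth
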