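"""Synthetic assay generator.

Every input the analysis pipeline consumes can be generated here with the
statistical structure the estimators assume: Poisson plaque counts over
serial dilutions, exponential free-phage decay during adsorption, a
piecewise one-step growth curve (baseline -> rise at the latent period ->
plateau at burst-size fold change), percent-viability stability curves, and
killing curves sampled at the standard 0/2/4/6/24 h marks.

Three named presets carry the kinetic parameters of the characterized
phages: an *Escherichia* podovirus (adsorption rate constant 1.1e-9 mL/min,
latent period 26 min, burst 110), a *Klebsiella* podovirus (4.35e-9 mL/min,
40 min, 120) and an *Enterobacter* myovirus (2.8e-9 mL/min, 11 min, 135).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .errors import InvalidParameterError
from .series import KineticSeries, StabilitySeries
from .titer import TiterMeasurement

__all__ = [
    "PhagePreset",
    "NoiseModel",
    "StabilityPreset",
    "PHAGE_PRESETS",
    "STABILITY_PRESETS",
    "DEFAULT_ADSORPTION_TIMES",
    "DEFAULT_ONESTEP_TIMES",
    "DEFAULT_KILLING_TIMES_H",
    "make_plaque_counts",
    "make_adsorption_series",
    "make_onestep_series",
    "make_stability_series",
    "make_killing_series",
]

# Default sampling grids of the wet-lab assays being emulated:
# adsorption sampled every 4 min to 40 min, one-step growth every 5 min to
# 80 min, killing assays at 0/2/4/6/24 h.
DEFAULT_ADSORPTION_TIMES = np.arange(0.0, 41.0, 4.0)
DEFAULT_ONESTEP_TIMES = np.arange(0.0, 81.0, 5.0)
DEFAULT_KILLING_TIMES_H = np.array([0.0, 2.0, 4.0, 6.0, 24.0])


@dataclass(frozen=True)
class PhagePreset:
    """Kinetic parameters of a single phage.

    Attributes
    ----------
    phage_id : str
        Label used in outputs.
    k_ads : float
        Adsorption rate constant, mL/min (mass-action attachment rate).
    latent_min : float
        Latent period, minutes: time from adsorption to first progeny release.
    burst : float
        Burst size, progeny phage released per infected cell.
    """

    phage_id: str
    k_ads: float
    latent_min: float
    burst: float

    def __post_init__(self):
        if not self.k_ads > 0:
            raise InvalidParameterError(f"k_ads must be > 0, got {self.k_ads}")
        if not self.latent_min > 0:
            raise InvalidParameterError(f"latent_min must be > 0, got {self.latent_min}")
        if not self.burst >= 1:
            raise InvalidParameterError(f"burst must be >= 1, got {self.burst}")


#: Kinetic presets of the three characterized phages (reported values).
PHAGE_PRESETS: dict[str, PhagePreset] = {
    "escherichia_myPSH2311": PhagePreset("escherichia_myPSH2311", 1.1e-9, 26.0, 110.0),
    "klebsiella_myPSH1235": PhagePreset("klebsiella_myPSH1235", 4.35e-9, 40.0, 120.0),
    "enterobacter_myPSH1140": PhagePreset("enterobacter_myPSH1140", 2.8e-9, 11.0, 135.0),
}


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise configuration for generated assays.

    ``titer_cv`` applies multiplicative lognormal noise (mean-preserving) to
    the underlying titer, emulating replicate-to-replicate variability.
    ``count_noise`` additionally emulates the plaque-counting step: each
    point is re-plated at the dilution that would give ~``target_count``
    plaques and the count drawn from a Poisson distribution, giving the
    familiar 1/sqrt(count) relative counting error.

    Identical seed and parameters reproduce identical output.
    """

    count_noise: bool = False
    titer_cv: float = 0.0
    seed: int = 0
    target_count: int = 100

    def __post_init__(self):
        if self.titer_cv < 0:
            raise InvalidParameterError("titer_cv must be >= 0")
        if self.target_count <= 0:
            raise InvalidParameterError("target_count must be positive")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def with_seed(self, seed: int) -> "NoiseModel":
        return replace(self, seed=seed)


#: Noiseless deterministic generation.
EXACT = NoiseModel()


def _apply_noise(expected: np.ndarray, noise: NoiseModel | None) -> np.ndarray:
    values = np.asarray(expected, dtype=float).copy()
    if noise is None:
        return values
    rng = noise.rng()
    if noise.titer_cv > 0:
        sigma = math.sqrt(math.log1p(noise.titer_cv**2))
        values *= rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=values.shape)
    if noise.count_noise:
        positive = values > 0
        factor = np.ones_like(values)
        factor[positive] = noise.target_count / values[positive]
        values = rng.poisson(values * factor) / factor
    return values


def make_plaque_counts(
    true_titer: float,
    dilutions,
    plated_volume: float,
    noise: NoiseModel = EXACT,
) -> list[TiterMeasurement]:
    """Emulate serial-dilution plating of a lysate of known titer.

    The expected plaque count at each dilution is
    ``true_titer * dilution * plated_volume``; with ``count_noise`` on, the
    observed count is Poisson with that mean.  Counts outside the countable
    range are flagged (not discarded) by :class:`~phagechar.titer.TiterMeasurement`.
    """
    if not true_titer > 0:
        raise InvalidParameterError(f"true_titer must be > 0, got {true_titer}")
    if not plated_volume > 0:
        raise InvalidParameterError(f"plated_volume must be > 0, got {plated_volume}")
    dilutions = np.asarray(dilutions, dtype=float)
    if dilutions.size == 0:
        raise InvalidParameterError("no dilutions given")
    if np.any(dilutions <= 0) or np.any(dilutions > 1):
        raise InvalidParameterError("dilution factors must lie in (0, 1]")

    rng = noise.rng()
    titer = true_titer
    if noise.titer_cv > 0:
        sigma = math.sqrt(math.log1p(noise.titer_cv**2))
        titer = true_titer * rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma)
    expected = titer * dilutions * plated_volume
    if noise.count_noise:
        counts = rng.poisson(expected)
    else:
        counts = np.rint(expected).astype(int)
    return [
        TiterMeasurement(plaque_count=int(c), dilution=float(d), plated_volume=plated_volume)
        for c, d in zip(counts, dilutions)
    ]


def make_adsorption_series(
    preset: PhagePreset,
    host_density: float,
    p0: float = 1e5,
    times=None,
    noise: NoiseModel = EXACT,
) -> KineticSeries:
    """Free-phage titer during adsorption to a dense host culture.

    Under mass-action attachment the free phage decay exponentially,
    ``P(t) = p0 * exp(-k_ads * host_density * t)``; the noiseless series is
    exactly that expectation.
    """
    if not host_density > 0 or not p0 > 0:
        raise InvalidParameterError("host_density and p0 must be positive")
    times = DEFAULT_ADSORPTION_TIMES if times is None else np.asarray(times, dtype=float)
    if times.size == 0:
        raise InvalidParameterError("time grid is empty")
    expected = p0 * np.exp(-preset.k_ads * host_density * times)
    values = _apply_noise(expected, noise)
    return KineticSeries(
        assay_kind="adsorption",
        times=times,
        values=values,
        metadata={
            "phage_id": preset.phage_id,
            "host_density": host_density,
            "p0": p0,
            "seed": noise.seed,
        },
    )


def _onestep_expectation(times, p0, latent, burst, rise_width):
    """Piecewise one-step growth curve.

    Baseline p0 up to the latent period; a log-space cubic smoothstep ramp of
    ``rise_width`` minutes up to the plateau ``burst * p0``.  The ramp starts
    exactly at the latent period, so the titer equals the baseline for
    t < latent and the plateau for t > latent + rise_width.
    """
    x = np.clip((np.asarray(times, float) - latent) / rise_width, 0.0, 1.0)
    smooth = x * x * (3.0 - 2.0 * x)
    return p0 * np.power(burst, smooth)


def make_onestep_series(
    preset: PhagePreset,
    host_density: float = 1e8,
    moi: float = 0.001,
    times=None,
    noise: NoiseModel = EXACT,
    rise_width: float = 5.0,
) -> KineticSeries:
    """One-step growth curve: free-phage titer over a single infection cycle.

    The initial free-phage titer is ``p0 = moi * host_density``; the curve
    stays at p0 until the latent period, rises over ``rise_width`` minutes
    (default: one sampling interval) and plateaus at ``burst * p0``.
    """
    if not moi > 0:
        raise InvalidParameterError("moi must be positive")
    if not host_density > 0:
        raise InvalidParameterError("host_density must be positive")
    if not rise_width > 0:
        raise InvalidParameterError("rise_width must be positive")
    times = DEFAULT_ONESTEP_TIMES if times is None else np.asarray(times, dtype=float)
    if times.size == 0:
        raise InvalidParameterError("time grid is empty")
    p0 = moi * host_density
    expected = _onestep_expectation(times, p0, preset.latent_min, preset.burst, rise_width)
    values = _apply_noise(expected, noise)
    series = KineticSeries(
        assay_kind="onestep",
        times=times,
        values=values,
        metadata={
            "phage_id": preset.phage_id,
            "host_density": host_density,
            "moi": moi,
            "p0": p0,
            "seed": noise.seed,
        },
    )
    if times[-1] < preset.latent_min + 20.0:
        series.warn(
            f"time span {times[-1]:g} min is shorter than latent period "
            f"{preset.latent_min:g} min + 20 min; plateau may not be reached"
        )
    return series


@dataclass(frozen=True)
class StabilityPreset:
    """Piecewise viability profile against an environmental gradient.

    Viability is 100% inside ``[stable_lo, stable_hi]``, 0% at or beyond
    ``[dead_lo, dead_hi]``, and interpolates linearly in between.  Open-ended
    bounds (None) pin viability at 100% out to the end of the tested range.
    """

    kind: str
    stable_lo: float | None
    stable_hi: float | None
    dead_lo: float | None
    dead_hi: float | None


#: Stability profiles of the characterized phages: viable from pH 4 to 11,
#: inactivated at pH <= 3 and >= 12; thermally stable up to 55 deg C with a
#: steep loss of activity above (below half viability by the 60 deg C test
#: condition, fully inactivated by ~64 deg C).
STABILITY_PRESETS: dict[str, StabilityPreset] = {
    "pH": StabilityPreset("pH", stable_lo=4.0, stable_hi=11.0, dead_lo=3.0, dead_hi=12.0),
    "temperature": StabilityPreset(
        "temperature", stable_lo=None, stable_hi=55.0, dead_lo=None, dead_hi=64.0
    ),
}

#: Condition grids of the stability assays (pH 1-14; the tested temperatures).
DEFAULT_PH_CONDITIONS = np.arange(1.0, 15.0)
DEFAULT_TEMPERATURE_CONDITIONS = np.array([4.0, 20.0, 35.0, 45.0, 50.0, 55.0, 60.0, 70.0, 80.0])


def _stability_expectation(preset: StabilityPreset, conditions: np.ndarray) -> np.ndarray:
    via = np.full(conditions.shape, 100.0)
    if preset.stable_lo is not None and preset.dead_lo is not None:
        lo_ramp = (conditions - preset.dead_lo) / (preset.stable_lo - preset.dead_lo)
        via = np.minimum(via, 100.0 * np.clip(lo_ramp, 0.0, 1.0))
    if preset.stable_hi is not None and preset.dead_hi is not None:
        hi_ramp = (preset.dead_hi - conditions) / (preset.dead_hi - preset.stable_hi)
        via = np.minimum(via, 100.0 * np.clip(hi_ramp, 0.0, 1.0))
    return via


def make_stability_series(
    kind: str,
    conditions=None,
    noise: NoiseModel = EXACT,
    breakpoints: StabilityPreset | None = None,
) -> StabilitySeries:
    """Percent-viability stability curve over pH or temperature conditions."""
    if kind not in STABILITY_PRESETS:
        raise InvalidParameterError(
            f"unknown stability kind {kind!r}; expected one of {tuple(STABILITY_PRESETS)}"
        )
    preset = breakpoints if breakpoints is not None else STABILITY_PRESETS[kind]
    if conditions is None:
        conditions = DEFAULT_PH_CONDITIONS if kind == "pH" else DEFAULT_TEMPERATURE_CONDITIONS
    conditions = np.asarray(conditions, dtype=float)
    if conditions.size == 0:
        raise InvalidParameterError("conditions are empty")
    expected = _stability_expectation(preset, conditions)
    viability = np.clip(_apply_noise(expected, noise), 0.0, None)
    return StabilitySeries(
        kind=kind,
        conditions=conditions,
        viability=viability,
        metadata={"seed": noise.seed, "preset": preset},
    )


def make_killing_series(
    times_h=None,
    counts_cfu=None,
    noise: NoiseModel = EXACT,
    metadata: dict | None = None,
) -> KineticSeries:
    """Package a killing-curve expectation (CFU/mL at hour marks) as a series.

    The mechanistic killing dynamics live in :mod:`phagechar.cocktail`; this
    helper only adds measurement noise and series metadata, for building
    pipeline fixtures from simulated trajectories.
    """
    times_h = DEFAULT_KILLING_TIMES_H if times_h is None else np.asarray(times_h, dtype=float)
    if counts_cfu is None:
        raise InvalidParameterError("counts_cfu is required")
    values = np.clip(_apply_noise(np.asarray(counts_cfu, float), noise), 0.0, None)
    md = {"seed": noise.seed}
    md.update(metadata or {})
    return KineticSeries(assay_kind="killing", times=times_h, values=values, metadata=md)
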