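"""Estimators for phage growth kinetics and stability profiles.

Adsorption: free phage attaching to host cells at density B decay as
P(t) = P0 exp(-k B t); the rate constant k (mL/min) is recovered as the
negative least-squares slope of ln(fraction free) against time, divided by
B.  Regression over all usable points is preferred over the two-point
endpoint formula for noise robustness.

One-step growth: the latent period is detected as the first sample whose
titer exceeds ``rise_factor`` times the running baseline, interpolated to
the midpoint of that sampling interval; the burst size is the plateau
titer divided by the baseline titer (final over initial free phage).

Stability: viability = 100 x titer / initial titer per condition; the
stable window is the maximal contiguous run of conditions at or above the
viability floor (default 50%); viability below 1% is reported as
inactivated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import EstimationError, InvalidParameterError, InvalidReferenceError
from .series import KineticSeries, StabilitySeries

__all__ = [
    "GrowthParams",
    "LatentBurstEstimate",
    "StabilityReport",
    "fit_adsorption",
    "estimate_latent_burst",
    "stability_profile",
]


@dataclass
class GrowthParams:
    """Per-phage growth parameters with fit diagnostics."""

    phage_id: str = ""
    k_ads: float = float("nan")  # mL/min
    latent_min: float = float("nan")  # min
    burst: float = float("nan")  # phage per infected cell
    diagnostics: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)


def fit_adsorption(
    series: KineticSeries,
    host_density: float,
    lower_cutoff: float = 0.01,
) -> GrowthParams:
    """Adsorption rate constant from a free-phage decay series.

    Parameters
    ----------
    series
        Adsorption assay series (absolute titers or fractions; only ratios
        matter).
    host_density
        Host cell density B (CFU/mL) during adsorption.  It must be supplied
        explicitly: the rate constant has units mL/min and cannot be
        recovered from the decay alone.
    lower_cutoff
        Points whose fraction free has dropped below this value are excluded
        from the regression (dominated by counting noise near detection).
    """
    if series.assay_kind != "adsorption":
        raise InvalidParameterError(f"expected an adsorption series, got {series.assay_kind!r}")
    if host_density <= 0:
        raise InvalidParameterError("host_density must be positive")

    frac = series.fraction_free()
    usable = (frac > 0) & (frac >= lower_cutoff)
    if usable.sum() < 3:
        raise EstimationError(
            f"need >=3 usable points above the {lower_cutoff:g} cutoff, have {int(usable.sum())}"
        )
    t = series.times[usable]
    y = np.log(frac[usable])
    fit = stats.linregress(t, y)

    params = GrowthParams(phage_id=series.metadata.get("phage_id", ""))
    params.diagnostics = {
        "slope_per_min": fit.slope,
        "intercept": fit.intercept,
        "r_squared": fit.rvalue**2,
        "residual_sd": float(np.std(y - (fit.intercept + fit.slope * t), ddof=2))
        if usable.sum() > 2
        else 0.0,
        "n_points": int(usable.sum()),
        "host_density": host_density,
    }
    if fit.slope >= 0:
        params.k_ads = 0.0
        params.warnings.append("no adsorption detected (non-negative slope); k set to 0")
    else:
        params.k_ads = -fit.slope / host_density
    return params


@dataclass
class LatentBurstEstimate:
    """One-step growth estimates: latent period and burst size."""

    latent_min: float
    burst: float
    baseline: float
    plateau: float
    burst_is_lower_bound: bool = False
    diagnostics: dict = field(default_factory=dict)


def estimate_latent_burst(
    series: KineticSeries,
    rise_factor: float = 2.0,
    plateau_tolerance: float = 0.15,
) -> LatentBurstEstimate:
    """Latent period and burst size from a one-step growth curve.

    The rise is the first sample exceeding ``rise_factor`` times the mean of
    all earlier samples; the latent period is the midpoint between that
    sample and the previous one (resolution: half a sampling interval).
    The plateau is the mean of the trailing run of samples whose 3-point
    moving average stays within ``plateau_tolerance`` of the final smoothed
    value, and burst = plateau / baseline.  Referencing the smoothed final
    value rather than the raw maximum avoids the upward selection bias the
    maximum acquires under plate-counting noise.  If fewer than two samples
    sit on the plateau the curve may still be rising and the burst is
    flagged as a lower bound.
    """
    if series.assay_kind != "onestep":
        raise InvalidParameterError(f"expected a onestep series, got {series.assay_kind!r}")
    if len(series) < 5:
        raise EstimationError("need at least 5 samples in a one-step series")
    values = series.values
    times = series.times
    if values[0] <= 0:
        raise EstimationError("initial titer must be positive")

    rise_idx = None
    for i in range(1, len(values)):
        if values[i] > rise_factor * values[:i].mean():
            rise_idx = i
            break
    if rise_idx is None:
        raise EstimationError(
            f"no burst detected: no sample exceeds {rise_factor:g}x the running baseline"
        )

    baseline = float(values[:rise_idx].mean())
    latent = float(0.5 * (times[rise_idx - 1] + times[rise_idx]))

    # trailing contiguous run whose smoothed value sits near the final level
    kernel = np.ones(3) / 3.0
    padded = np.concatenate([values[:1], values, values[-1:]])
    smoothed = np.convolve(padded, kernel, mode="valid")
    reference = smoothed[-1]
    plateau_mask = np.abs(smoothed - reference) <= plateau_tolerance * reference
    j = len(values)
    while j > 0 and plateau_mask[j - 1]:
        j -= 1
    plateau_points = values[j:]
    lower_bound = plateau_points.size < 2
    plateau = float(plateau_points.mean()) if plateau_points.size else float(values[-1])

    return LatentBurstEstimate(
        latent_min=latent,
        burst=plateau / baseline,
        baseline=baseline,
        plateau=plateau,
        burst_is_lower_bound=lower_bound,
        diagnostics={
            "rise_index": rise_idx,
            "n_baseline": rise_idx,
            "n_plateau": int(plateau_points.size),
            "rise_factor": rise_factor,
            "plateau_tolerance": plateau_tolerance,
        },
    )


@dataclass
class StabilityReport:
    """Viability profile with its stable window and inactivated conditions."""

    series: StabilitySeries
    stable_window: tuple[float, float] | None
    inactivated_conditions: np.ndarray
    viability_floor: float


def stability_profile(
    kind: str,
    conditions,
    titers,
    reference: float,
    viability_floor: float = 50.0,
    detection_floor: float = 1.0,
) -> StabilityReport:
    """Percent viability per condition, with the stable window.

    Parameters
    ----------
    kind
        ``temperature`` or ``pH``.
    conditions, titers
        Surviving titer measured after exposure at each condition.
    reference
        Initial (unexposed) titer; viability = 100 x titer / reference,
        capped at 100 for reporting.
    viability_floor
        Percent viability a condition must retain to count as stable.
    detection_floor
        Viability below this percent is reported as inactivated.
    """
    if reference <= 0:
        raise InvalidReferenceError(f"reference titer must be > 0, got {reference}")
    conditions = np.asarray(conditions, dtype=float)
    titers = np.asarray(titers, dtype=float)
    viability = np.clip(100.0 * titers / reference, 0.0, 100.0)
    series = StabilitySeries(kind=kind, conditions=conditions, viability=viability)

    stable = viability >= viability_floor
    best: tuple[float, float] | None = None
    best_len = 0
    run_start = None
    for i, ok in enumerate(np.append(stable, False)):
        if ok and run_start is None:
            run_start = i
        elif not ok and run_start is not None:
            if i - run_start > best_len:
                best_len = i - run_start
                best = (float(conditions[run_start]), float(conditions[i - 1]))
            run_start = None

    return StabilityReport(
        series=series,
        stable_window=best,
        inactivated_conditions=conditions[viability < detection_floor],
        viability_floor=viability_floor,
    )
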