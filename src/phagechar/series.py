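"""Containers for timed assay series.

A :class:`KineticSeries` holds one replicate of a timed titer assay
(adsorption, one-step growth, or killing curve); a :class:`StabilitySeries`
holds percent viability across an ordered set of conditions (pH or
temperature).  Both are thin, validated dataclasses around numpy arrays —
the estimators in :mod:`phagechar.kinetics` consume them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError

ASSAY_KINDS = ("adsorption", "onestep", "killing")
STABILITY_KINDS = ("temperature", "pH")


@dataclass
class KineticSeries:
    """Timestamped titer series with assay metadata.

    Parameters
    ----------
    assay_kind
        One of ``adsorption``, ``onestep``, ``killing``.
    times
        Sampling times, strictly increasing and starting at 0.  Minutes for
        adsorption/one-step assays, hours for killing assays.
    values
        Non-negative measurements: PFU/mL for phage titers, CFU/mL for
        killing curves.  Adsorption series store absolute free-phage titers;
        use :meth:`fraction_free` for the normalized curve.
    metadata
        Free-form assay context (``host_density``, ``moi``, ``phage_id``,
        ``replicate``, ``warnings`` ...).
    """

    assay_kind: str
    times: np.ndarray
    values: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.assay_kind not in ASSAY_KINDS:
            raise InvalidParameterError(
                f"assay_kind must be one of {ASSAY_KINDS}, got {self.assay_kind!r}"
            )
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.size == 0:
            raise InvalidParameterError("time grid is empty")
        if self.times.size != self.values.size:
            raise InvalidParameterError("times and values differ in length")
        if self.times[0] != 0:
            raise InvalidParameterError("time grid must start at 0")
        if np.any(np.diff(self.times) <= 0):
            raise InvalidParameterError("times must be strictly increasing")
        if np.any(self.values < 0):
            raise InvalidParameterError("series values must be non-negative")

    def __len__(self):
        return self.times.size

    def fraction_free(self) -> np.ndarray:
        """Values normalized to the t=0 measurement (adsorption curves)."""
        if self.values[0] <= 0:
            raise InvalidParameterError("first value must be positive to normalize")
        return self.values / self.values[0]

    def warn(self, message: str) -> None:
        self.metadata.setdefault("warnings", []).append(message)


@dataclass
class StabilitySeries:
    """Percent viability (of the initial titer) across ordered conditions."""

    kind: str  # "temperature" (deg C) or "pH" (unitless)
    conditions: np.ndarray
    viability: np.ndarray  # percent of initial viral count, in [0, 100]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in STABILITY_KINDS:
            raise InvalidParameterError(
                f"stability kind must be one of {STABILITY_KINDS}, got {self.kind!r}"
            )
        self.conditions = np.asarray(self.conditions, dtype=float)
        self.viability = np.asarray(self.viability, dtype=float)
        if self.conditions.size == 0:
            raise InvalidParameterError("conditions are empty")
        if self.conditions.size != self.viability.size:
            raise InvalidParameterError("conditions and viability differ in length")
        if np.any(self.viability < 0):
            raise InvalidParameterError("viability cannot be negative")

    def __len__(self):
        return self.conditions.size
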