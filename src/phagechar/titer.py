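"""Plaque-count titer arithmetic, MOI, and efficiency of plating (EOP).

The titer estimator pools plaque counts across dilutions as a Poisson
maximum-likelihood estimate: with counts c_d observed after plating volume v
at dilution d, the titer estimate is sum(c) / sum(d * v) PFU/mL with
standard error sqrt(sum(c)) / sum(d * v).

EOP is the ratio of the phage titer on a test bacterium to the titer on the
reference host at equal input dose, classified into four levels:
High (EOP >= 0.5), Moderate (0.1 < EOP < 0.5), Low (0.001 <= EOP <= 0.1),
and No activity (EOP < 0.001).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

from .errors import (
    EstimationError,
    InvalidParameterError,
    InvalidReferenceError,
    UndefinedMOIError,
)

#: Plaque counts a technician would call countable on a single plate.
COUNTABLE_RANGE = (30, 300)


@dataclass
class TiterMeasurement:
    """A plaque count at one dilution, convertible to PFU/mL.

    ``countable_flag`` is True when the count lies in the countable range
    [30, 300]; out-of-range plates are kept but flagged, and the pooled
    estimator uses only countable plates (unless none exist and all counts
    are zero, which is reported as below detection).
    """

    plaque_count: int
    dilution: float
    plated_volume: float
    countable_flag: bool = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.plaque_count < 0:
            raise InvalidParameterError("plaque_count must be >= 0")
        if not 0 < self.dilution <= 1:
            raise InvalidParameterError("dilution must lie in (0, 1]")
        if not self.plated_volume > 0:
            raise InvalidParameterError("plated_volume must be > 0")
        if self.countable_flag is None:
            lo, hi = COUNTABLE_RANGE
            self.countable_flag = lo <= self.plaque_count <= hi

    @property
    def pfu_per_ml(self) -> float:
        """Single-plate titer: count / (dilution x volume)."""
        return self.plaque_count / (self.dilution * self.plated_volume)


@dataclass(frozen=True)
class TiterEstimate:
    """Pooled titer estimate with its Poisson standard error."""

    pfu_per_ml: float
    se: float
    n_used: int
    below_detection: bool = False


def titer_from_counts(measurements, include_flagged: bool = False) -> TiterEstimate:
    """Pooled Poisson MLE of the lysate titer from plaque counts.

    Parameters
    ----------
    measurements
        TiterMeasurement records from one or more dilutions of the same lysate.
    include_flagged
        Pool all plates regardless of the countable-range flag.  The pooled
        MLE is exact for any subset; excluding uncountable plates guards
        against plate-saturation bias in real data.
    """
    measurements = list(measurements)
    if not measurements:
        raise EstimationError("no measurements given")

    if all(m.plaque_count == 0 for m in measurements):
        return TiterEstimate(0.0, 0.0, len(measurements), below_detection=True)

    usable = [m for m in measurements if include_flagged or m.countable_flag]
    if not usable:
        raise EstimationError(
            "all plates fall outside the countable range [30, 300]; "
            "re-plate at other dilutions or pass include_flagged=True"
        )
    total_count = sum(m.plaque_count for m in usable)
    total_dv = sum(m.dilution * m.plated_volume for m in usable)
    return TiterEstimate(
        pfu_per_ml=total_count / total_dv,
        se=math.sqrt(total_count) / total_dv,
        n_used=len(usable),
    )


def moi(pfu: float, cfu: float) -> float:
    """Multiplicity of infection: phage per bacterium (PFU/CFU)."""
    if cfu <= 0:
        raise UndefinedMOIError(f"MOI undefined for cfu={cfu}")
    if pfu < 0:
        raise InvalidParameterError("pfu must be >= 0")
    return pfu / cfu


class EOPClass(str, enum.Enum):
    HIGH = "High"
    MODERATE = "Moderate"
    LOW = "Low"
    NO_ACTIVITY = "NoActivity"


#: Class boundaries (closed as printed): High >= 0.5; 0.1 < Moderate < 0.5;
#: 0.001 <= Low <= 0.1; NoActivity < 0.001.
EOP_HIGH = 0.5
EOP_MODERATE_LO = 0.1
EOP_DETECTION = 0.001


def classify_eop(eop: float) -> EOPClass:
    """Assign the four-level plating-efficiency class."""
    if eop < 0:
        raise InvalidParameterError(f"EOP cannot be negative, got {eop}")
    if eop >= EOP_HIGH:
        return EOPClass.HIGH
    if eop > EOP_MODERATE_LO:
        return EOPClass.MODERATE
    if eop >= EOP_DETECTION:
        return EOPClass.LOW
    return EOPClass.NO_ACTIVITY


@dataclass(frozen=True)
class EOPRecord:
    """Efficiency of plating of one phage on one test isolate."""

    phage_id: str
    test_isolate_id: str
    pfu_test: float
    pfu_host: float
    eop: float
    eop_class: EOPClass
    dose_corrected: bool = False


def compute_eop(
    pfu_test: float,
    pfu_host: float,
    phage_id: str = "",
    test_isolate_id: str = "",
    dose_test: float | None = None,
    dose_host: float | None = None,
) -> EOPRecord:
    """EOP = PFU on the test bacterium / PFU on the reference host.

    Both titers must come from equal input phage dose; if ``dose_test`` and
    ``dose_host`` differ, the test titer is rescaled linearly and the record
    flagged ``dose_corrected``.
    """
    if pfu_host <= 0:
        raise InvalidReferenceError(f"host titer must be > 0, got {pfu_host}")
    if pfu_test < 0:
        raise InvalidParameterError("test titer must be >= 0")
    corrected = False
    if dose_test is not None and dose_host is not None and dose_test != dose_host:
        if dose_test <= 0 or dose_host <= 0:
            raise InvalidParameterError("doses must be positive")
        pfu_test = pfu_test * (dose_host / dose_test)
        corrected = True
    eop = pfu_test / pfu_host
    return EOPRecord(
        phage_id=phage_id,
        test_isolate_id=test_isolate_id,
        pfu_test=pfu_test,
        pfu_host=pfu_host,
        eop=eop,
        eop_class=classify_eop(eop),
        dose_corrected=corrected,
    )
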