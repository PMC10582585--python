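"""Threshold classifiers mapping polyQ metrics to vocalization classes.

Chiropteran species separate in the (Q1+Q2 sum, Q1/Q2 ratio) plane into four
regions matching their echolocation call type: non-echolocating megabats
(NE) have sum > 60, and ultrasound-emitting species (sum <= 60) split by
ratio into constant-frequency (CF, ratio < 1), multi-harmonic frequency-
modulated (FM2, ratio 1-2.1) and single-harmonic frequency-modulated (FM1,
ratio 2.1-3.5) callers.  Mammal-wide, the FOXP2 ratio separates species with
ultrasonic (<= 3.5), sonic/human-like (3.5-4.5) and infrasonic/low-frequency
(> 4.5) vocalization ranges; the FOXP1 ratio has its own taxon-specific
bands (below 0.2 on extreme Q2 expansion, 0.2-0.5 intermediate-low, >= 2 on
Q1 elongation).

Boundary conventions (membership of s = 60 and of interior ratio edges) are
not fixed by the published thresholds; this module assigns s = 60 to the
USV branch, lets FM2 own both of its printed endpoints, and uses left-open/
right-closed ratio bands.  All thresholds live in :class:`ClassifierConfig`
so the conventions are overridable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .errors import PolyqvocError

# USV type labels
NE, CF, FM1, FM2, UNASSIGNED = "NE", "CF", "FM1", "FM2", "UNASSIGNED"

# ratio band labels
LOW, INTERMEDIATE, HIGH = "LOW", "INTERMEDIATE", "HIGH"
EXTREME_LOW, MID = "EXTREME_LOW", "MID"

#: Collen call-type codes grouped by harmonic structure: single harmonic or
#: peak harmonic as the fundamental -> FM1; multi-harmonic -> FM2.
COLLEN_FM1_CODES = frozenset({3, 7, 8, 10})
COLLEN_FM2_CODES = frozenset({4, 5, 6, 9})


class UnmappedCallTypeError(PolyqvocError):
    """Collen code outside the published FM groupings."""


@dataclass(frozen=True)
class ClassifierConfig:
    """All classification thresholds, in one overridable place."""

    ne_sum_threshold: float = 60.0
    cf_ratio_max: float = 1.0
    fm2_ratio_max: float = 2.1
    fm1_ratio_max: float = 3.5
    mammal_low_max: float = 3.5
    mammal_high_min: float = 4.5
    foxp1_extreme_max: float = 0.2
    foxp1_low_max: float = 0.5
    foxp1_high_min: float = 2.0

    def __post_init__(self):
        if not (self.cf_ratio_max < self.fm2_ratio_max < self.fm1_ratio_max):
            raise ValueError("require cf_ratio_max < fm2_ratio_max < fm1_ratio_max")
        if not self.mammal_low_max < self.mammal_high_min:
            raise ValueError("require mammal_low_max < mammal_high_min")


def classify_usv_type(
    sum_s: Optional[int],
    ratio_r: Optional[float],
    cfg: ClassifierConfig = ClassifierConfig(),
) -> str:
    """Chiropteran call-type from the (sum, ratio) pair.

    NE iff sum > 60; otherwise CF (< 1), FM2 ([1, 2.1]), FM1 ((2.1, 3.5])
    by increasing ratio; ratios above the chiropteran range (or undefined
    metrics from flagged calls) give UNASSIGNED.
    """
    if sum_s is None or ratio_r is None:
        return UNASSIGNED
    if sum_s > cfg.ne_sum_threshold:
        return NE
    if ratio_r < cfg.cf_ratio_max:
        return CF
    if ratio_r <= cfg.fm2_ratio_max:
        return FM2
    if ratio_r <= cfg.fm1_ratio_max:
        return FM1
    return UNASSIGNED


def classify_ratio_band(
    ratio_r: Optional[float],
    scheme: str = "FOXP2_MAMMAL",
    cfg: ClassifierConfig = ClassifierConfig(),
) -> str:
    """Mammal-wide FOXP2 or FOXP1 ratio band.

    FOXP2_MAMMAL: LOW (r <= 3.5), INTERMEDIATE (3.5 < r <= 4.5),
    HIGH (r > 4.5).  FOXP1: EXTREME_LOW (r < 0.2), LOW (0.2 <= r < 0.5),
    MID (0.5 <= r < 2), HIGH (r >= 2).
    """
    if ratio_r is None:
        return UNASSIGNED
    if scheme == "FOXP2_MAMMAL":
        if ratio_r <= cfg.mammal_low_max:
            return LOW
        if ratio_r <= cfg.mammal_high_min:
            return INTERMEDIATE
        return HIGH
    if scheme == "FOXP1":
        if ratio_r < cfg.foxp1_extreme_max:
            return EXTREME_LOW
        if ratio_r < cfg.foxp1_low_max:
            return LOW
        if ratio_r < cfg.foxp1_high_min:
            return MID
        return HIGH
    raise ValueError(f"unknown band scheme {scheme!r}")


def call_type_from_collen(code: int) -> str:
    """Map a Collen FM call-type code to FM1/FM2.

    Only the FM codes are published for this grouping; any other code raises
    :class:`UnmappedCallTypeError` rather than guessing CF/NE membership.
    """
    if code in COLLEN_FM1_CODES:
        return FM1
    if code in COLLEN_FM2_CODES:
        return FM2
    raise UnmappedCallTypeError(f"unmapped_call_type: Collen code {code}")
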