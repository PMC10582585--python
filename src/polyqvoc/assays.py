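"""Quantification formulas for the wet-lab assays of the analysis.

Circular dichroism (CD) signals are converted to mean residue ellipticity

    [theta] = theta * mw / (10 * (n - 1) * c * pl)

with theta the measured ellipticity (mdeg), mw the peptide molecular weight
(g/mol), n the residue count, c the concentration (mg/mL) and pl the cuvette
pathlength (cm).  Spectral features of interest are the low-minus-high
temperature subtraction spectrum, the 222/208 nm ellipticity ratio (> 1 is a
coiled-coil signature) and the thermal melt of the 222 nm MRE normalized to
its value at the lowest temperature.

FRAP traces are doubly normalized (each series by its own pre-bleach mean,
then the bleached series pointwise by the mean of the normalized controls —
cancelling acquisition photobleaching shared with the controls) and fit to a
single-exponential recovery F(t) = F0 + (P - F0)(1 - exp(-t/tau)); the
half-time is tau*ln 2 and the mobile fraction (P - F0)/(1 - F0) on the
doubly normalized scale where pre-bleach is 1.

Dual-luciferase plates normalize firefly luminescence by Renilla per well
and then by the mean firefly/Renilla ratio of the control group, so the
control mean is exactly 1.  Condensate burden is the condensate area over
the nuclear/cell reference area, optionally renormalized to a control mean.
Cochlear landmark sets yield the cochlear-width/basicranial-width (CW/BW)
and cochlear height/width ratios from Euclidean landmark distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .errors import DegenerateDataError, FitError

NO_RECOVERY = "no_recovery"


# --------------------------------------------------------------------------
# circular dichroism
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MREParams:
    """Peptide parameters for mean-residue-ellipticity conversion."""

    mw: float
    n_residues: int
    conc_mg_ml: float
    pathlength_cm: float

    def __post_init__(self):
        if self.n_residues < 2:
            raise ValueError("n_residues must be >= 2 (zero divisor otherwise)")
        if self.conc_mg_ml <= 0 or self.pathlength_cm <= 0:
            raise ValueError("concentration and pathlength must be positive")


def mean_residue_ellipticity(theta_mdeg: float, params: MREParams) -> float:
    """[theta] = theta * mw / (10 * (n - 1) * c * pl)."""
    return (
        theta_mdeg
        * params.mw
        / (10.0 * (params.n_residues - 1) * params.conc_mg_ml * params.pathlength_cm)
    )


@dataclass
class CDSpectrum:
    """One blank-subtracted CD spectrum at a given temperature."""

    wavelengths_nm: np.ndarray
    ellipticity_mdeg: np.ndarray
    temperature_c: float
    mre: Optional[np.ndarray] = None

    def __post_init__(self):
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.ellipticity_mdeg = np.asarray(self.ellipticity_mdeg, dtype=float)
        if self.wavelengths_nm.shape != self.ellipticity_mdeg.shape:
            raise ValueError("wavelength and ellipticity grids differ in length")
        if np.any(np.diff(self.wavelengths_nm) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.mre is not None:
            self.mre = np.asarray(self.mre, dtype=float)

    def with_mre(self, params: MREParams) -> "CDSpectrum":
        return CDSpectrum(
            self.wavelengths_nm,
            self.ellipticity_mdeg,
            self.temperature_c,
            mre=mean_residue_ellipticity(self.ellipticity_mdeg, params),
        )

    def value_at(self, wavelength_nm: float, use_mre: bool = True) -> float:
        """Value at the nearest grid point within 1 nm (else error)."""
        idx = int(np.argmin(np.abs(self.wavelengths_nm - wavelength_nm)))
        if abs(self.wavelengths_nm[idx] - wavelength_nm) > 1.0:
            raise ValueError(
                f"no grid point within 1 nm of {wavelength_nm} nm"
            )
        series = self.mre if (use_mre and self.mre is not None) else self.ellipticity_mdeg
        return float(series[idx])


def subtraction_spectrum(low_t: CDSpectrum, high_t: CDSpectrum) -> np.ndarray:
    """Pointwise low-temperature minus high-temperature spectrum."""
    if not np.array_equal(low_t.wavelengths_nm, high_t.wavelengths_nm):
        raise ValueError("spectra are on different wavelength grids")
    a = low_t.mre if low_t.mre is not None else low_t.ellipticity_mdeg
    b = high_t.mre if high_t.mre is not None else high_t.ellipticity_mdeg
    return a - b


def ratio_222_208(spectrum: CDSpectrum) -> float:
    """Ellipticity ratio at 222 vs 208 nm (MRE values when available)."""
    denom = spectrum.value_at(208.0)
    if denom == 0:
        raise DegenerateDataError("zero ellipticity at 208 nm")
    return spectrum.value_at(222.0) / denom


def melt_curve(spectra: Sequence[CDSpectrum]) -> tuple[np.ndarray, np.ndarray]:
    """222 nm MRE across temperatures, normalized to the lowest temperature.

    Returns (temperatures, normalized MRE); the first point is exactly 1.
    """
    ordered = sorted(spectra, key=lambda s: s.temperature_c)
    temps = np.array([s.temperature_c for s in ordered])
    values = np.array([s.value_at(222.0) for s in ordered])
    if values[0] == 0:
        raise DegenerateDataError("zero MRE at the normalization temperature")
    return temps, values / values[0]


@dataclass(frozen=True)
class CDFeatures:
    subtraction: np.ndarray
    ratio_222_208_low: float
    ratio_222_208_subtraction: float
    melt_temperatures: np.ndarray
    melt_normalized: np.ndarray


def cd_features(
    spectra: Sequence[CDSpectrum],
    low_temp_c: Optional[float] = None,
    high_temp_c: Optional[float] = None,
) -> CDFeatures:
    """Bundle the standard spectral features of a temperature series.

    By default the subtraction pairs the lowest- and highest-temperature
    spectra (e.g. 5 degC minus 75 degC).
    """
    ordered = sorted(spectra, key=lambda s: s.temperature_c)
    if len(ordered) < 2:
        raise ValueError("need spectra at >=2 temperatures")
    by_t = {s.temperature_c: s for s in ordered}
    low = by_t[low_temp_c] if low_temp_c is not None else ordered[0]
    high = by_t[high_temp_c] if high_temp_c is not None else ordered[-1]
    sub = subtraction_spectrum(low, high)
    sub_spec = CDSpectrum(low.wavelengths_nm, sub, low.temperature_c, mre=sub)
    temps, melt = melt_curve(ordered)
    return CDFeatures(
        subtraction=sub,
        ratio_222_208_low=ratio_222_208(low),
        ratio_222_208_subtraction=ratio_222_208(sub_spec),
        melt_temperatures=temps,
        melt_normalized=melt,
    )


# --------------------------------------------------------------------------
# FRAP
# --------------------------------------------------------------------------

@dataclass
class FRAPTrace:
    """Raw bleached-region trace plus unbleached control series.

    ``time_s`` is increasing; the first ``n_prebleach`` samples precede the
    bleach.  Post-bleach time is measured from the first post-bleach frame.
    """

    time_s: np.ndarray
    bleached_intensity: np.ndarray
    control_intensities: np.ndarray  # (n_controls, n_timepoints)
    n_prebleach: int = 3

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.bleached_intensity = np.asarray(self.bleached_intensity, dtype=float)
        self.control_intensities = np.atleast_2d(
            np.asarray(self.control_intensities, dtype=float)
        )
        n = len(self.time_s)
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time_s must be strictly increasing")
        if len(self.bleached_intensity) != n or self.control_intensities.shape[1] != n:
            raise ValueError("all series must share the time grid")
        if not (1 <= self.n_prebleach < n):
            raise ValueError("n_prebleach must be >=1 and < series length")


@dataclass(frozen=True)
class FRAPFit:
    t_half_s: float
    mobile_fraction: float
    tau_s: float
    plateau: float
    f0: float
    residual_rms: float
    flags: frozenset[str] = field(default_factory=frozenset)


def frap_normalize(trace: FRAPTrace) -> np.ndarray:
    """Double normalization of the bleached series.

    Step 1 divides every series by its own pre-bleach mean; step 2 divides
    the bleached series pointwise by the mean of the normalized controls.
    On the resulting scale the pre-bleach mean of the bleached series is 1.
    """
    pre = slice(0, trace.n_prebleach)
    bleach_pre = trace.bleached_intensity[pre].mean()
    if bleach_pre <= 0:
        raise ValueError("pre-bleach mean of the bleached series must be > 0")
    ctrl_pre = trace.control_intensities[:, pre].mean(axis=1)
    if np.any(ctrl_pre <= 0) or np.any(trace.control_intensities <= 0):
        raise ValueError("control intensities must be positive")
    bleached = trace.bleached_intensity / bleach_pre
    controls = trace.control_intensities / ctrl_pre[:, None]
    return bleached / controls.mean(axis=0)


def _recovery(t, f0, p, tau):
    return f0 + (p - f0) * (1.0 - np.exp(-t / tau))


def frap_normalize_fit(trace: FRAPTrace) -> tuple[FRAPFit, np.ndarray]:
    """Doubly normalize a trace and fit the single-exponential recovery.

    Returns the fit (tau, half-time tau*ln2, plateau, mobile fraction) and
    the full normalized curve.  Initialization uses crude estimates (F0 =
    first post-bleach value, P = mean of the last points, tau from the time
    to half recovery); bounds keep F0 in [0, 1] and P in [0, 1.5].
    """
    norm = frap_normalize(trace)
    post = slice(trace.n_prebleach, None)
    t = trace.time_s[post] - trace.time_s[trace.n_prebleach]
    y = norm[post]

    f0_guess = float(np.clip(y[0], 0.0, 1.0))
    p_guess = float(np.clip(np.mean(y[-min(10, len(y)):]), f0_guess + 1e-6, 1.5))
    half_level = f0_guess + 0.5 * (p_guess - f0_guess)
    above = np.nonzero(y >= half_level)[0]
    tau_guess = float(t[above[0]] / np.log(2)) if above.size and t[above[0]] > 0 else max(
        float(t[-1]) / 4.0, 1e-3
    )
    try:
        popt, _ = curve_fit(
            _recovery,
            t,
            y,
            p0=[f0_guess, p_guess, tau_guess],
            bounds=([0.0, 0.0, 1e-9], [1.0, 1.5, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise FitError(f"FRAP fit did not converge: {exc}") from exc
    f0, plateau, tau = map(float, popt)
    residuals = y - _recovery(t, *popt)
    flags: set[str] = set()
    if plateau < f0:
        flags.add(NO_RECOVERY)
    mobile = (plateau - f0) / (1.0 - f0) if f0 < 1.0 else np.nan
    return (
        FRAPFit(
            t_half_s=tau * np.log(2),
            mobile_fraction=float(np.clip(mobile, 0.0, 1.0)),
            tau_s=tau,
            plateau=plateau,
            f0=f0,
            residual_rms=float(np.sqrt(np.mean(residuals**2))),
            flags=frozenset(flags),
        ),
        norm,
    )


# --------------------------------------------------------------------------
# dual luciferase
# --------------------------------------------------------------------------

def luciferase_normalize(
    firefly: Sequence[float],
    renilla: Sequence[float],
    group_labels: Sequence[object],
    control_group: object,
) -> np.ndarray:
    """Per-well firefly/Renilla ratio normalized to the control-group mean.

    The control group's mean output is exactly 1 by construction.
    """
    ff = np.asarray(firefly, dtype=float)
    rl = np.asarray(renilla, dtype=float)
    labels = np.asarray(group_labels)
    if ff.shape != rl.shape or ff.shape != labels.shape:
        raise ValueError("firefly, renilla and group_labels must align")
    bad = np.nonzero(rl <= 0)[0]
    if bad.size:
        raise ValueError(f"non-positive Renilla reading in well {int(bad[0])}")
    ratio = ff / rl
    mask = labels == control_group
    if not mask.any():
        raise ValueError(f"control group {control_group!r} has no wells")
    return ratio / ratio[mask].mean()


# --------------------------------------------------------------------------
# condensate area
# --------------------------------------------------------------------------

def condensate_relative_area(
    condensate_area: float,
    reference_area: float,
    control_mean: Optional[float] = None,
) -> tuple[float, Optional[float]]:
    """Proportion of the cell/nuclear area occupied by condensates.

    Returns (relative area, relative area normalized to ``control_mean``)
    where the second element is None if no control mean is given.
    """
    if reference_area <= 0:
        raise ValueError("reference_area must be > 0")
    relative = condensate_area / reference_area
    if control_mean is None:
        return relative, None
    if control_mean <= 0:
        raise ValueError("control_mean must be > 0")
    return relative, relative / control_mean


# --------------------------------------------------------------------------
# cochlear landmark ratios
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LandmarkSet:
    """Labeled 3-D landmark pairs from a basicranial scan."""

    cochlear_width: tuple[tuple[float, float, float], tuple[float, float, float]]
    cochlear_height: tuple[tuple[float, float, float], tuple[float, float, float]]
    basicranial_width: tuple[tuple[float, float, float], tuple[float, float, float]]

    def __post_init__(self):
        for pair in (self.cochlear_width, self.cochlear_height, self.basicranial_width):
            if not np.all(np.isfinite(np.asarray(pair, dtype=float))):
                raise ValueError("landmark coordinates must be finite")


def _distance(pair) -> float:
    a, b = (np.asarray(p, dtype=float) for p in pair)
    return float(np.linalg.norm(a - b))


def cochlear_ratios(landmarks: LandmarkSet) -> tuple[float, float]:
    """(cochlear width / basicranial width, cochlear height / width)."""
    cw = _distance(landmarks.cochlear_width)
    ch = _distance(landmarks.cochlear_height)
    bw = _distance(landmarks.basicranial_width)
    if bw == 0 or cw == 0:
        raise ValueError("zero denominator landmark distance")
    return cw / bw, ch / cw
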