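"""From raw images to analysable measures.

The chain is: pixel intensities -> biomass (a monotone calibration) ->
stationarity check via the radially averaged Fourier power spectrum ->
absolute-gradient transform when the spectral exponent indicates
nonstationarity (beta > 1) -> normalization to a unit-mass measure.

The gradient step matters because box-counting moment estimates are only
stable on (broad-sense) stationary data: a surface with a steep spectrum
(beta > 1) has trends that masquerade as large-scale structure.  Taking
the magnitude of local first differences is the canonical fix for
geophysical and cloud fields and is adopted here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .fields import BiomassField, DegenerateFieldError, MeasureField

__all__ = [
    "Calibration",
    "SpectrumFit",
    "image_to_biomass",
    "power_spectrum",
    "gradient_transform",
    "normalize_measure",
]

#: spectral exponent above which a surface is treated as nonstationary
STATIONARITY_BETA = 1.0

#: geometric ratio between successive radial frequency bins
_BIN_RATIO = 2.0 ** 0.25


@dataclass(frozen=True)
class Calibration:
    """Monotone map from pixel intensity to biomass.

    ``linear``: a*x + b with a > 0 (clipped at 0 afterwards).
    ``exponential``: a * exp(c*x) with a > 0, c > 0.

    The default is the identity (linear, a=1, b=0): dimension estimates
    are invariant to any affine recalibration of mass, so the identity
    loses nothing when the true grayscale-to-chlorophyll curve is
    unknown.
    """

    kind: str = "linear"
    a: float = 1.0
    b: float = 0.0
    c: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "exponential"):
            raise ValueError(f"unknown calibration kind {self.kind!r}")
        if self.a <= 0:
            raise ValueError("calibration slope/scale a must be > 0")
        if self.kind == "exponential" and self.c <= 0:
            raise ValueError("exponential calibration requires c > 0")

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.kind == "linear":
            return np.clip(self.a * x + self.b, 0.0, None)
        return self.a * np.exp(self.c * x)

    @classmethod
    def parse(cls, text: str) -> "Calibration":
        """Parse ``linear:a,b`` / ``exponential:a,c`` / ``identity``."""
        if text in ("identity", ""):
            return cls()
        kind, _, params = text.partition(":")
        vals = [float(v) for v in params.split(",")] if params else []
        if kind == "linear":
            a, b = (vals + [0.0])[:2] if vals else (1.0, 0.0)
            return cls("linear", a=a, b=b)
        if kind == "exponential":
            a, c = (vals + [1.0])[:2] if vals else (1.0, 1.0)
            return cls("exponential", a=a, c=c)
        raise ValueError(f"cannot parse calibration {text!r}")


def image_to_biomass(image, calibration: Calibration | None = None) -> BiomassField:
    """Apply a monotone intensity-to-biomass calibration element-wise."""
    cal = calibration if calibration is not None else Calibration()
    return BiomassField(cal(np.asarray(image, dtype=float)))


@dataclass(frozen=True)
class SpectrumFit:
    """Radially averaged power spectrum with its log-log slope fit.

    ``beta_hat`` is the magnitude of the fitted slope of log power
    against log radial wavenumber (cycles per image side); surfaces with
    ``beta_hat`` <= 1 are treated as stationary.
    """

    wavenumbers: np.ndarray
    power: np.ndarray
    beta_hat: float
    r_squared: float

    @property
    def stationary(self) -> bool:
        return self.beta_hat <= STATIONARITY_BETA


def power_spectrum(field: BiomassField) -> SpectrumFit:
    """Periodogram-based estimate of the isotropic spectral exponent.

    The mean is removed, the 2-D periodogram is averaged over log-spaced
    radial bins (ratio 2**(1/4)), and the slope is fitted by least
    squares over bins from the second-lowest up to half the Nyquist
    frequency — the lowest bin leaks DC/trend power and the top octave
    is alias-dominated.
    """
    v = field.values
    n = min(v.shape)
    if v.shape[0] < 16 or v.shape[1] < 16:
        raise ValueError("power spectrum needs at least a 16x16 field")
    centered = v - v.mean()
    if np.allclose(centered, 0.0):
        raise DegenerateFieldError("constant field has a zero power spectrum")
    p2d = np.abs(np.fft.fft2(centered)) ** 2
    ky = np.fft.fftfreq(v.shape[0], d=1.0 / v.shape[0])
    kx = np.fft.fftfreq(v.shape[1], d=1.0 / v.shape[1])
    kr = np.hypot(ky[:, None], kx[None, :])

    nyquist = n / 2.0
    n_bins = int(np.ceil(np.log(nyquist) / np.log(_BIN_RATIO)))
    edges = _BIN_RATIO ** np.arange(n_bins + 1)  # from k = 1 upward
    centers, mean_power = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (kr >= lo) & (kr < hi)
        if mask.any():
            centers.append(np.sqrt(lo * hi))
            mean_power.append(p2d[mask].mean())
    centers = np.asarray(centers)
    mean_power = np.asarray(mean_power)

    in_range = (np.arange(len(centers)) >= 1) & (centers <= nyquist / 2.0)
    usable = in_range & (mean_power > 0)
    if usable.sum() < 3:
        raise DegenerateFieldError("too few spectral bins for a slope fit")
    res = stats.linregress(np.log(centers[usable]), np.log(mean_power[usable]))
    return SpectrumFit(
        wavenumbers=centers,
        power=mean_power,
        beta_hat=float(-res.slope),
        r_squared=float(res.rvalue ** 2),
    )


def gradient_transform(field: BiomassField) -> BiomassField:
    """Magnitude of local first differences (stationarity transform).

    out(i,j) = sqrt(d_row^2 + d_col^2) with forward differences; the last
    row and column fall back to backward differences so the output keeps
    the input's (dyadic) dimensions.  Nonnegative by construction.
    """
    b = field.values
    d_row = np.empty_like(b)
    d_row[:-1, :] = b[1:, :] - b[:-1, :]
    d_row[-1, :] = b[-1, :] - b[-2, :]
    d_col = np.empty_like(b)
    d_col[:, :-1] = b[:, 1:] - b[:, :-1]
    d_col[:, -1] = b[:, -1] - b[:, -2]
    return BiomassField(np.hypot(d_row, d_col))


def normalize_measure(field: BiomassField) -> MeasureField:
    """mu(i,j) = b(i,j) / sum(b); requires strictly positive total mass."""
    total = field.values.sum()
    if total <= 0:
        raise DegenerateFieldError("cannot normalize a zero-mass field")
    return MeasureField(field.values / total)
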