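"""Grid containers for biomass surfaces and normalized measures.

A :class:`BiomassField` is a plain nonnegative 2-D grid of biomass per
pixel (arbitrary mass units); a :class:`MeasureField` is the same grid
normalized to unit total mass, i.e. a probability measure mu over the
pixels.  Both are thin, validated wrappers around numpy arrays; every
estimator in the package operates on these two types.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BiomassField",
    "MeasureField",
    "DegenerateFieldError",
    "read_field_csv",
    "write_field_csv",
    "read_field_image",
    "write_field_image",
]


class DegenerateFieldError(ValueError):
    """Raised when a field cannot support the requested operation
    (constant surface for spectral fitting, zero total mass for
    normalization, ...)."""


@dataclass(frozen=True)
class BiomassField:
    """Nonnegative 2-D biomass grid.

    Row 0 is the top of the image; indices are 0-based.  Values carry
    arbitrary mass units per pixel — every dimension estimate downstream
    is invariant to an overall rescaling.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 2:
            raise ValueError(f"field must be 2-D, got shape {arr.shape}")
        if arr.shape[0] < 2 or arr.shape[1] < 2:
            raise ValueError(f"field must be at least 2x2, got {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("field contains non-finite values")
        if np.any(arr < 0):
            raise ValueError("field contains negative biomass")
        object.__setattr__(self, "values", arr)

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def total_mass(self) -> float:
        return float(self.values.sum())


@dataclass(frozen=True)
class MeasureField:
    """Normalized nonnegative grid summing to one (the measure mu)."""

    mu: np.ndarray
    _ATOL: float = field(default=1e-9, repr=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.mu, dtype=float)
        if arr.ndim != 2:
            raise ValueError(f"measure must be 2-D, got shape {arr.shape}")
        if np.any(arr < 0) or not np.all(np.isfinite(arr)):
            raise ValueError("measure entries must be finite and >= 0")
        total = arr.sum()
        if abs(total - 1.0) > self._ATOL:
            raise ValueError(f"measure must sum to 1, got {total!r}")
        object.__setattr__(self, "mu", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.mu.shape


# ---------------------------------------------------------------------------
# plain-text and image I/O
# ---------------------------------------------------------------------------

def read_field_csv(path) -> BiomassField:
    """Read a biomass field from a headerless CSV matrix."""
    return BiomassField(np.loadtxt(path, delimiter=","))


def write_field_csv(field: BiomassField, path) -> None:
    np.savetxt(path, field.values, delimiter=",")


def read_field_image(path) -> np.ndarray:
    """Read a grayscale 8/16-bit PNG/TIFF as an integer intensity grid.

    Color images are rejected rather than silently converted; intensity
    calibration to biomass is a separate, explicit step
    (:func:`mfbiomass.preprocess.image_to_biomass`).
    """
    import imageio.v3 as iio

    arr = iio.imread(path)
    if arr.ndim != 2:
        raise ValueError(
            f"expected a single-channel grayscale image, got shape {arr.shape}"
        )
    return np.asarray(arr)


def write_field_image(field: BiomassField, path) -> None:
    """Write a field as 16-bit grayscale, rescaled to the full range."""
    import imageio.v3 as iio

    v = field.values
    vmax = v.max()
    scaled = np.zeros_like(v) if vmax == 0 else v / vmax
    iio.imwrite(path, np.round(scaled * 65535).astype(np.uint16))
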