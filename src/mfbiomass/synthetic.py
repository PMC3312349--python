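"""Synthetic inputs with known scaling properties.

Three generators cover everything the analysis pipeline consumes:

* multiplicative cascades on a dyadic 2-D grid, whose generalized
  dimension spectrum D(q) has a closed form and therefore serves as the
  verification oracle for the box-counting estimators;
* fractional-Brownian-type surfaces with a prescribed isotropic spectral
  exponent beta, used to exercise the stationarity assessment;
* succession series — weekly ensembles of cascade plates whose spatial
  heterogeneity relaxes toward uniformity while community evenness
  declines, coupling the information dimension D(1) (upward) and Shannon
  diversity H (downward) the way a maturing attached-algae community does.

All randomness flows through ``numpy.random.default_rng``; a generator
called twice with the same seed returns identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .fields import BiomassField

__all__ = [
    "CascadeSpec",
    "CommunitySample",
    "SuccessionSeries",
    "generate_cascade",
    "theoretical_dq",
    "generate_fbm_surface",
    "generate_succession_series",
    "generate_community",
    "shuffle_field",
]

_WEIGHT_ATOL = 1e-12

#: quadrant order used at every subdivision: reading order
#: (top-left, top-right, bottom-left, bottom-right).
_QUADRANT_ORDER = ((0, 0), (0, 1), (1, 0), (1, 1))


def _check_weights(weights) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    if w.shape != (4,):
        raise ValueError("exactly four quadrant weights are required")
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    if abs(w.sum() - 1.0) > _WEIGHT_ATOL:
        raise ValueError(f"weights must sum to 1, got {w.sum()!r}")
    return w


@dataclass(frozen=True)
class CascadeSpec:
    """Parameters of a quadrant multiplicative cascade.

    ``weights`` are the four mass fractions a cell passes to its children
    at each subdivision; ``levels`` sets the field side 2**levels.
    ``mode``:

    - ``deterministic`` — weights go to quadrants in fixed reading order
      at every level (seed ignored);
    - ``microcanonical`` — the four weights are randomly permuted,
      independently at every subdivision, so mass is conserved exactly
      while the spatial arrangement is random;
    - ``canonical`` — each subdivision perturbs the weights by i.i.d.
      log-normal multipliers (sigma = ``sigma``) renormalized to sum 1,
      keeping every cell positive so negative-q moments stay finite.

    Deterministic and microcanonical cascades share the exact spectrum
    ``theoretical_dq(weights, q)``.
    """

    weights: tuple[float, float, float, float]
    levels: int
    mode: str = "microcanonical"
    seed: int | None = None
    sigma: float = 0.2

    def __post_init__(self) -> None:
        w = _check_weights(self.weights)
        object.__setattr__(self, "weights", tuple(float(x) for x in w))
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if self.mode not in ("deterministic", "microcanonical", "canonical"):
            raise ValueError(f"unknown cascade mode {self.mode!r}")
        if self.mode == "canonical" and self.sigma <= 0:
            raise ValueError("canonical mode requires sigma > 0")

    @property
    def side(self) -> int:
        return 2 ** self.levels


def generate_cascade(spec: CascadeSpec) -> BiomassField:
    """Build the cascade field; total mass is exactly 1 up to rounding."""
    return _cascade_with_rng(spec, np.random.default_rng(spec.seed))


def theoretical_dq(weights, q: float) -> float:
    """Closed-form generalized dimension of the quadrant cascade.

    D_q = -log2(sum_i w_i**q) / (q - 1) for q != 1 and the base-2 entropy
    -sum_i w_i log2 w_i at q = 1 (continuous limit).  Exact for the
    deterministic and microcanonical modes.  Any zero weight makes the
    negative-q moments diverge, so that case is rejected for q < 0.
    """
    w = _check_weights(weights)
    q = float(q)
    if np.any(w == 0) and q < 0:
        raise ValueError("zero weights make D(q) diverge for q < 0")
    pos = w[w > 0]
    if abs(q - 1.0) < 1e-9:
        return float(-np.sum(pos * np.log2(pos)))
    return float(-np.log2(np.sum(pos ** q)) / (q - 1.0))


def generate_fbm_surface(beta: float, size: int, seed: int | None = None) -> BiomassField:
    """Spectral synthesis of a surface with isotropic power spectrum ~ k**(-beta).

    Fourier amplitudes are scaled by k**(-beta/2), phases come from
    complex Gaussian noise, and the real part of the inverse transform is
    shifted so its minimum is zero (fields are biomass-like, nonnegative).
    beta about 0 gives white noise (stationary); beta > 1 gives the
    nonstationary, fBm-like surfaces the gradient transform is for.
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    if size < 2 or size & (size - 1):
        raise ValueError("size must be a power of 2")
    rng = np.random.default_rng(seed)
    k = np.fft.fftfreq(size, d=1.0 / size)  # integer cycles per image side
    kr = np.hypot(k[:, None], k[None, :])
    amp = np.zeros_like(kr)
    nonzero = kr > 0
    amp[nonzero] = kr[nonzero] ** (-beta / 2.0)
    noise = rng.standard_normal((size, size)) + 1j * rng.standard_normal((size, size))
    surf = np.fft.ifft2(amp * noise).real
    return BiomassField(surf - surf.min())


def shuffle_field(field: BiomassField, seed: int | None = None) -> BiomassField:
    """Uniformly random permutation of pixel positions.

    The multiset of pixel values — hence the total mass and every
    value-based statistic — is preserved exactly; only the spatial
    arrangement is destroyed.  This is the null model behind the
    randomization envelope.
    """
    rng = np.random.default_rng(seed)
    flat = field.values.ravel().copy()
    rng.shuffle(flat)
    return BiomassField(flat.reshape(field.shape))


# ---------------------------------------------------------------------------
# communities and succession series
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CommunitySample:
    """Species abundance vector with derived richness and Shannon H (bits)."""

    abundances: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.abundances, dtype=float)
        if a.ndim != 1 or np.any(a < 0):
            raise ValueError("abundances must be a 1-D nonnegative vector")
        object.__setattr__(self, "abundances", a)

    @property
    def richness(self) -> int:
        return int(np.count_nonzero(self.abundances))

    @property
    def shannon_h(self) -> float:
        from .inference import shannon_index

        return shannon_index(self.abundances)


def generate_community(
    n_species: int,
    evenness: float,
    n_individuals: int = 500,
    seed: int | None = None,
) -> CommunitySample:
    """Sample a community from a geometric-series (niche preemption) model.

    Expected relative abundances follow p_i ~ evenness**i for species
    i = 0..n_species-1, with ``evenness`` in (0, 1): values near 1 give
    nearly even communities (high H), small values give steep dominance
    (low H).  Counts are a single multinomial draw of ``n_individuals``,
    so rare species can be missed — observed richness varies below
    ``n_species`` just as microscope counts do.
    """
    if not 0 < evenness < 1:
        raise ValueError("evenness must be in (0, 1)")
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    rng = np.random.default_rng(seed)
    p = evenness ** np.arange(n_species, dtype=float)
    p /= p.sum()
    counts = rng.multinomial(n_individuals, p)
    return CommunitySample(counts.astype(float))


@dataclass(frozen=True)
class SuccessionSeries:
    """Weekly ensembles of replicate plates plus one community per week."""

    weeks: tuple
    plates: tuple  # per week, tuple of BiomassField
    communities: tuple  # per week, CommunitySample
    week_weights: tuple = dc_field(default=())  # cascade weights per week

    def __post_init__(self) -> None:
        if len(self.weeks) != len(self.plates) or len(self.weeks) != len(self.communities):
            raise ValueError("weeks, plates and communities must align")
        shapes = {p.shape for wk in self.plates for p in wk}
        if any(len(wk) < 1 for wk in self.plates):
            raise ValueError("every week needs at least one plate")
        if len(shapes) > 1:
            raise ValueError("all plates must share grid dimensions")

    @property
    def n_weeks(self) -> int:
        return len(self.weeks)

    def theoretical_d1(self) -> np.ndarray:
        """Closed-form D(1) of each week's cascade weights."""
        return np.array([theoretical_dq(w, 1.0) for w in self.week_weights])


def generate_succession_series(
    n_weeks: int = 6,
    start_weights=(0.55, 0.25, 0.15, 0.05),
    end_weights=(0.25, 0.25, 0.25, 0.25),
    plates_per_week: int = 5,
    levels: int = 9,
    community_size: int = 20,
    start_evenness: float = 0.85,
    evenness_decay: float = 0.07,
    n_individuals: int = 500,
    seed: int | None = None,
) -> SuccessionSeries:
    """Generate a coupled heterogeneity/diversity succession.

    Week w uses cascade weights interpolated linearly from
    ``start_weights`` to ``end_weights`` (renormalized); moving along a
    straight line toward the uniform vector can only raise the weight
    entropy, so the theoretical D(1) sequence is nondecreasing — the
    spatial pattern flattens as the community matures.  Communities come
    from the geometric-series model with evenness dropping by
    ``evenness_decay`` per week, so Shannon H trends down.  Plates are
    microcanonical cascades; each plate's generator is seeded from
    (seed, week index, plate index) so one master seed reproduces the
    whole series.
    """
    if n_weeks < 2:
        raise ValueError("n_weeks must be >= 2")
    w0 = _check_weights(start_weights)
    w1 = _check_weights(end_weights)
    base = 0 if seed is None else int(seed)
    weeks, plates, comms, week_w = [], [], [], []
    for wk in range(n_weeks):
        t = wk / (n_weeks - 1)
        w = (1 - t) * w0 + t * w1
        w = w / w.sum()
        week_plates = []
        for p in range(plates_per_week):
            spec = CascadeSpec(tuple(w), levels=levels, mode="microcanonical",
                               seed=None)
            rng_seed = np.random.SeedSequence([base, wk, p])
            field = _cascade_with_rng(spec, np.random.default_rng(rng_seed))
            week_plates.append(field)
        evenness = start_evenness - evenness_decay * wk
        if not 0 < evenness < 1:
            raise ValueError(
                "evenness_decay drives evenness outside (0, 1) at week "
                f"{wk + 1}: {evenness}"
            )
        comms.append(
            generate_community(
                community_size, evenness, n_individuals,
                seed=np.random.SeedSequence([base, wk, 10_000]),
            )
        )
        weeks.append(wk + 1)
        plates.append(tuple(week_plates))
        week_w.append(tuple(w))
    return SuccessionSeries(tuple(weeks), tuple(plates), tuple(comms), tuple(week_w))


def _cascade_with_rng(spec: CascadeSpec, rng: np.random.Generator) -> BiomassField:
    """generate_cascade with an externally managed random generator."""
    w = np.asarray(spec.weights)
    out = np.ones((1, 1))
    for _ in range(spec.levels):
        s = out.shape[0]
        if spec.mode == "deterministic":
            mult = np.broadcast_to(w, (s, s, 4))
        elif spec.mode == "microcanonical":
            mult = rng.permuted(np.broadcast_to(w, (s, s, 4)).copy(), axis=2)
        else:
            noise = rng.lognormal(mean=0.0, sigma=spec.sigma, size=(s, s, 4))
            mult = w * noise
            mult = mult / mult.sum(axis=2, keepdims=True)
        children = out[:, :, None] * mult
        out = children.reshape(s, s, 2, 2).transpose(0, 2, 1, 3).reshape(2 * s, 2 * s)
    return BiomassField(out)
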