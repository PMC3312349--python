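"""Statistical layer: permutation tests on D(q) curves, pixel-shuffle
randomization envelopes, Holm adjustment, Shannon diversity, Kendall
correlation and quantile regression of diversity on D(1).

The permutation test compares two groups of plates by the two-sample
Welch t statistic computed per moment order q and averaged over the q
grid; significance comes from reallocating whole plates between the
groups, so the strong dependence of D(q) across q within a plate is
respected.  The randomization envelope asks a different question — is
one plate's spatial arrangement distinguishable from a random scatter
of the same pixel values? — by re-running the full estimation pipeline
on pixel shuffles of the observed field.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .fields import BiomassField
from .multifractal import SpectrumResult, analyze_field
from .synthetic import shuffle_field

__all__ = [
    "PermutationResult",
    "RandomizationEnvelope",
    "QuantileFit",
    "shannon_index",
    "permutation_test_dq",
    "holm_adjust",
    "pairwise_week_tests",
    "randomization_envelope",
    "kendall_correlation",
    "quantile_regression_dh",
]


def shannon_index(abundances) -> float:
    """Shannon diversity H = -sum p_i log2 p_i, in bits."""
    a = np.asarray(abundances, dtype=float)
    if a.ndim != 1 or np.any(a < 0):
        raise ValueError("abundances must be a 1-D nonnegative vector")
    total = a.sum()
    if total <= 0:
        raise ValueError("at least one positive count is required")
    p = a[a > 0] / total
    return float(-np.sum(p * np.log2(p)))


# ---------------------------------------------------------------------------
# permutation comparison of D(q) curves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PermutationResult:
    """Outcome of the mean-over-q Welch-t permutation test."""

    observed_stat: float
    p_value: float
    n_perm: int
    seed: int | None = None

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (f"mean-t over q = {self.observed_stat:.4f}, "
                f"p = {self.p_value:.4g} ({self.n_perm} permutations)")


def _dq_matrix(group) -> np.ndarray:
    rows = []
    q0 = None
    for s in group:
        if isinstance(s, SpectrumResult):
            q, d = s.q_grid, s.dq
        else:
            q, d = None, np.asarray(s, dtype=float)
        if q is not None:
            if q0 is None:
                q0 = q
            elif not np.allclose(q, q0):
                raise ValueError("spectra are on different q grids")
        rows.append(d)
    mat = np.asarray(rows, dtype=float)
    if mat.ndim != 2:
        raise ValueError("group spectra have inconsistent lengths")
    return mat


def _welch_t(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Per-column Welch t; 0/0 (identical degenerate columns) maps to 0.

    a, b have shape (..., n_group, n_q); reduction is over axis -2.
    """
    na, nb = a.shape[-2], b.shape[-2]
    ma, mb = a.mean(axis=-2), b.mean(axis=-2)
    va, vb = a.var(axis=-2, ddof=1), b.var(axis=-2, ddof=1)
    denom = np.sqrt(va / na + vb / nb)
    diff = ma - mb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / denom
        t = np.where(denom == 0,
                     np.where(diff == 0, 0.0, np.sign(diff) * np.inf), t)
    return t


def _mean_t_over_q(t: np.ndarray) -> np.ndarray:
    """Average the per-q t statistic over the q where it is finite.

    t is undefined (infinite) at q where both groups are exactly
    constant yet different — a degenerate split.  Averaging the defined
    entries keeps the statistic a symmetric function of the group
    labels; a split with no defined entry at all is scored infinitely
    extreme, which can only enlarge the p-value of a finite observed
    statistic.
    """
    masked = np.where(np.isfinite(t), t, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        out = np.nanmean(masked, axis=-1)
    return np.where(np.isnan(out), np.inf, out)


def permutation_test_dq(
    group_a,
    group_b,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> PermutationResult:
    """Two-sided permutation test comparing D(q) curves between groups.

    The statistic is the Welch two-sample t between the groups' D(q)
    values, computed at every q and averaged over the grid.  Whole
    spectra (plates) are reallocated between the two groups, keeping the
    group sizes, and the two-sided p-value is
    (1 + #{|T*| >= |T_obs|}) / (n_perm + 1).
    """
    A = _dq_matrix(group_a)
    B = _dq_matrix(group_b)
    if A.shape[1] != B.shape[1]:
        raise ValueError("groups are on different q grids")
    if A.shape[0] < 2 or B.shape[0] < 2:
        raise ValueError("each group needs at least 2 spectra")
    na = A.shape[0]
    X = np.vstack([A, B])
    if np.all(A.var(axis=0) == 0) and np.all(B.var(axis=0) == 0):
        raise ValueError("zero variance at every q in both groups: t undefined")

    t_obs = float(_mean_t_over_q(_welch_t(A, B)))
    if np.isinf(t_obs):
        raise ValueError("test statistic undefined: both groups exactly "
                         "constant but different at every q")

    rng = np.random.default_rng(seed)
    order = np.argsort(rng.random((n_perm, X.shape[0])), axis=1)
    perm_a = X[order[:, :na]]       # (n_perm, na, n_q)
    perm_b = X[order[:, na:]]
    t_perm = _mean_t_over_q(_welch_t(perm_a, perm_b))

    n_extreme = int(np.sum(np.abs(t_perm) >= abs(t_obs)))
    p = (1 + n_extreme) / (n_perm + 1)
    return PermutationResult(observed_stat=t_obs, p_value=float(p),
                             n_perm=n_perm, seed=seed)


def holm_adjust(p_values) -> np.ndarray:
    """Step-down Bonferroni (Holm) adjustment, in the input order."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to adjust")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if p.size == 1:
        return p.copy()
    return multipletests(p, method="holm")[1]


def pairwise_week_tests(series, n_perm: int = 10_000, seed: int | None = None):
    """All unordered pairwise permutation tests with Holm adjustment.

    ``series`` is a list of (label, [SpectrumResult, ...]) pairs; the
    returned DataFrame has one row per pair with the observed mean-t,
    raw and adjusted p-values.
    """
    import pandas as pd

    if len(series) < 2:
        raise ValueError("need at least 2 labelled groups")
    pairs = list(itertools.combinations(range(len(series)), 2))
    child_seeds = np.random.SeedSequence(seed).spawn(len(pairs))
    rows = []
    for (i, j), ss in zip(pairs, child_seeds):
        la, ga = series[i]
        lb, gb = series[j]
        res = permutation_test_dq(ga, gb, n_perm=n_perm,
                                  seed=int(ss.generate_state(1)[0] % (2**31)))
        rows.append({"label_a": la, "label_b": lb,
                     "t_obs": res.observed_stat, "p_raw": res.p_value})
    table = pd.DataFrame(rows)
    table["p_adj"] = holm_adjust(table["p_raw"].to_numpy())
    return table


# ---------------------------------------------------------------------------
# pixel-shuffle randomization envelope
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RandomizationEnvelope:
    """Per-q confidence band for D(q) under random pixel arrangement.

    ``outside`` flags the q where the observed D(q) escapes the band;
    ``any_outside`` is the paper-style verdict that the spatial pattern
    is not random.
    """

    q_grid: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    observed: np.ndarray
    n_rep: int
    alpha: float

    @property
    def outside(self) -> np.ndarray:
        return (self.observed < self.lower) | (self.observed > self.upper)

    @property
    def any_outside(self) -> bool:
        return bool(self.outside.any())


def randomization_envelope(
    field: BiomassField,
    q_grid=None,
    box_sizes=None,
    gradient: str = "auto",
    n_rep: int = 1000,
    alpha: float = 0.01,
    seed: int | None = None,
) -> RandomizationEnvelope:
    """Shuffle pixel positions n_rep times and band the resulting D(q).

    Every shuffle goes through the identical estimation pipeline; the
    gradient decision is frozen to whatever the observed field got, so
    observed and null spectra are strictly comparable.  Bounds are the
    alpha/2 and 1-alpha/2 percentiles per q.  A constant field yields a
    degenerate band equal to the observed curve (nothing flagged).
    """
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    observed = analyze_field(field, q_grid=q_grid, box_sizes=box_sizes,
                             gradient=gradient)
    policy = "always" if observed.gradient_applied else "never"
    child_seeds = np.random.SeedSequence(seed).spawn(n_rep)
    reps = np.empty((n_rep, len(observed.q_grid)))
    for r, ss in enumerate(child_seeds):
        shuffled = shuffle_field(field, seed=ss)
        reps[r] = analyze_field(shuffled, q_grid=observed.q_grid,
                                box_sizes=box_sizes, gradient=policy).dq
    lower = np.quantile(reps, alpha / 2.0, axis=0)
    upper = np.quantile(reps, 1.0 - alpha / 2.0, axis=0)
    return RandomizationEnvelope(
        q_grid=observed.q_grid, lower=lower, upper=upper,
        observed=observed.dq, n_rep=n_rep, alpha=alpha,
    )


# ---------------------------------------------------------------------------
# diversity-heterogeneity association
# ---------------------------------------------------------------------------

def kendall_correlation(x, y) -> tuple[float, float]:
    """Kendall tau-b with two-sided p (exact for small untied samples)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("x and y must be equal-length 1-D vectors, n >= 3")
    res = stats.kendalltau(x, y)
    if np.isnan(res.statistic):
        raise ValueError("Kendall tau undefined (all values tied)")
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class QuantileFit:
    """Linear conditional-quantile fits of Shannon H on D(1)."""

    tau_levels: np.ndarray
    intercepts: np.ndarray
    slopes: np.ndarray
    slope_ses: np.ndarray
    p_values: np.ndarray

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "tau": self.tau_levels,
                "intercept": self.intercepts,
                "slope": self.slopes,
                "slope_se": self.slope_ses,
                "p_slope": self.p_values,
            }
        )

    def predict(self, d1, level: float) -> np.ndarray:
        idx = np.nonzero(np.isclose(self.tau_levels, level))[0]
        if idx.size == 0:
            raise KeyError(f"no fit at quantile level {level}")
        i = idx[0]
        return self.intercepts[i] + self.slopes[i] * np.asarray(d1, dtype=float)


def quantile_regression_dh(
    d1_values,
    h_values,
    tau_levels=None,
    se: str = "asymptotic",
    n_boot: int = 200,
    seed: int | None = None,
) -> QuantileFit:
    """Quantile regression of diversity H on the information dimension D(1).

    Each conditional quantile is a straight line fitted by minimizing the
    asymmetric absolute-deviation (pinball) loss.  The upper quantiles
    bound the diversity attainable at a given heterogeneity, which is how
    the relationship is read ecologically: the 90% line gives the minimum
    diversity to expect of a site once its D(1) is known.

    ``se`` selects slope uncertainty: ``asymptotic`` (kernel-based
    sandwich estimate) or ``bootstrap`` (pair resampling, ``n_boot``
    draws).
    """
    import statsmodels.api as sm

    x = np.asarray(d1_values, dtype=float)
    y = np.asarray(h_values, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("d1 and H must be equal-length 1-D vectors")
    if len(x) < 5:
        raise ValueError("need at least 5 (D1, H) pairs")
    if np.ptp(x) == 0:
        raise ValueError("degenerate predictor: all D(1) values equal")
    if se not in ("asymptotic", "bootstrap"):
        raise ValueError("se must be 'asymptotic' or 'bootstrap'")
    tau_levels = np.round(np.arange(0.1, 0.95, 0.1), 10) if tau_levels is None \
        else np.asarray(tau_levels, dtype=float)
    if np.any((tau_levels <= 0) | (tau_levels >= 1)):
        raise ValueError("quantile levels must be in (0, 1)")

    exog = sm.add_constant(x)
    model = sm.QuantReg(y, exog)
    inter, slope, ses, pvals = [], [], [], []
    rng = np.random.default_rng(seed)
    for tau in tau_levels:
        fit = model.fit(q=float(tau))
        inter.append(fit.params[0])
        slope.append(fit.params[1])
        if se == "bootstrap":
            boots = np.empty(n_boot)
            for b in range(n_boot):
                idx = rng.integers(0, len(x), len(x))
                while np.ptp(x[idx]) == 0:
                    idx = rng.integers(0, len(x), len(x))
                bf = sm.QuantReg(y[idx], sm.add_constant(x[idx])).fit(q=float(tau))
                boots[b] = bf.params[1]
            s = float(boots.std(ddof=1))
            z = slope[-1] / s if s > 0 else np.inf * np.sign(slope[-1])
            ses.append(s)
            pvals.append(float(2 * stats.norm.sf(abs(z))))
        else:
            ses.append(float(fit.bse[1]))
            pvals.append(float(fit.pvalues[1]))
    return QuantileFit(
        tau_levels=tau_levels,
        intercepts=np.asarray(inter),
        slopes=np.asarray(slope),
        slope_ses=np.asarray(ses),
        p_values=np.asarray(pvals),
    )
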