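"""End-to-end succession analysis.

A :class:`SuccessionStudy` bundles weekly ensembles of plates with one
community sample per week; ``fit()`` estimates every plate's D(q)
spectrum once and reuses the spectra for the weekly summary table,
pairwise permutation tests (Holm-adjusted), the Kendall correlation
between D(1) and Shannon H, and the quantile regression of H on D(1).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fields import BiomassField, read_field_csv, read_field_image, write_field_csv
from .inference import (
    QuantileFit,
    kendall_correlation,
    pairwise_week_tests,
    quantile_regression_dh,
    shannon_index,
)
from .multifractal import MultifractalModel, default_q_grid
from .preprocess import Calibration, image_to_biomass
from .synthetic import CommunitySample, SuccessionSeries

__all__ = [
    "RunConfig",
    "SuccessionStudy",
    "SuccessionReport",
    "run_succession_analysis",
    "make_figures",
    "write_series",
]


@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration of one analysis run (plain-text serializable)."""

    q_min: float = -5.0
    q_max: float = 5.0
    q_step: float = 0.5
    box_rule: str = "dyadic"
    gradient: str = "auto"
    n_perm: int = 10_000
    n_rep: int = 1000
    alpha: float = 0.01
    seed: int | None = None
    calibration: str = "identity"

    def __post_init__(self) -> None:
        if self.gradient not in ("auto", "always", "never"):
            raise ValueError(f"gradient policy {self.gradient!r} invalid")
        if self.box_rule != "dyadic":
            raise ValueError("only the dyadic box-size rule is implemented")

    def q_grid(self) -> np.ndarray:
        return default_q_grid(self.q_min, self.q_max, self.q_step)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


@dataclass(frozen=True)
class SuccessionReport:
    """Tables and test results of one succession run."""

    week_table: pd.DataFrame       # label, n_plates, d1_mean, d1_sd, richness, shannon_h
    pairwise: pd.DataFrame         # label_a, label_b, t_obs, p_raw, p_adj
    kendall_plate: tuple[float, float]   # per-plate D(1) vs weekly H
    kendall_week: tuple[float, float]    # weekly mean D(1) vs H
    quantile_fit: QuantileFit
    spectra: dict = dc_field(repr=False, default_factory=dict)
    config: RunConfig = dc_field(default_factory=RunConfig)

    def summary(self) -> str:
        tau_p, p_p = self.kendall_plate
        tau_w, p_w = self.kendall_week
        n_sig = int((self.pairwise["p_adj"] <= 0.01).sum())
        lines = [
            "Succession analysis",
            "=" * 46,
            self.week_table.to_string(index=False,
                                      float_format=lambda v: f"{v:.4f}"),
            "",
            f"pairwise tests: {len(self.pairwise)} "
            f"({n_sig} with Holm-adjusted p <= 0.01)",
            f"Kendall tau, per-plate D(1) vs weekly H: {tau_p:.3f} (p = {p_p:.3g})",
            f"Kendall tau, weekly means:               {tau_w:.3f} (p = {p_w:.3g})",
            "quantile-regression slopes of H on D(1): "
            + ", ".join(f"{t:.1f}: {s:.2f}" for t, s in
                        zip(self.quantile_fit.tau_levels, self.quantile_fit.slopes)),
        ]
        return "\n".join(lines)

    def save(self, outdir) -> None:
        """Write every table (and the resolved config) as plain text."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.week_table.to_csv(out / "week_table.csv", index=False)
        self.pairwise.to_csv(out / "pairwise_tests.csv", index=False)
        self.quantile_fit.to_frame().to_csv(out / "quantile_fit.csv", index=False)
        pd.DataFrame(
            {
                "comparison": ["plate_level", "weekly_means"],
                "tau": [self.kendall_plate[0], self.kendall_week[0]],
                "p": [self.kendall_plate[1], self.kendall_week[1]],
            }
        ).to_csv(out / "kendall.csv", index=False)
        rows = []
        for label, specs in self.spectra.items():
            for p_idx, s in enumerate(specs):
                for i, q in enumerate(s.q_grid):
                    rows.append({"week": label, "plate": p_idx, "q": q,
                                 "Kq": s.kq[i], "Dq": s.dq[i],
                                 "R2": s.r_squared[i], "SE": s.slope_se[i]})
        pd.DataFrame(rows).to_csv(out / "spectra.csv", index=False)
        self.config.to_yaml(out / "config.yaml")


class SuccessionStudy:
    """Model object for a weekly succession of plates plus communities.

    Construct from an in-memory :class:`SuccessionSeries`
    (:meth:`from_series`) or from plain-text inputs on disk
    (:meth:`from_manifest`); ``fit`` runs the whole analysis.
    """

    def __init__(self, weeks, plates, communities, config: RunConfig | None = None):
        if len(weeks) < 2:
            raise ValueError("need at least 2 weeks")
        if len(plates) != len(weeks) or len(communities) != len(weeks):
            raise ValueError("weeks, plates and communities must align")
        self.weeks = list(weeks)
        self.plates = [list(p) for p in plates]
        self.communities = list(communities)
        self.config = config or RunConfig()

    @classmethod
    def from_series(cls, series: SuccessionSeries,
                    config: RunConfig | None = None) -> "SuccessionStudy":
        return cls(series.weeks, series.plates, series.communities, config)

    @classmethod
    def from_manifest(cls, manifest_csv, abundances_csv,
                      config: RunConfig | None = None) -> "SuccessionStudy":
        """Load plates from a week,plate,path manifest and communities
        from a week,species,count table (both CSV with headers)."""
        config = config or RunConfig()
        cal = Calibration.parse(config.calibration)
        manifest = pd.read_csv(manifest_csv)
        abund = pd.read_csv(abundances_csv)
        for col in ("week", "plate", "path"):
            if col not in manifest.columns:
                raise ValueError(f"manifest is missing column {col!r}")
        weeks = sorted(manifest["week"].unique())
        plates, communities = [], []
        for wk in weeks:
            paths = (manifest[manifest["week"] == wk]
                     .sort_values("plate")["path"].tolist())
            fields = []
            for p in paths:
                p = Path(p)
                if not p.exists():
                    raise FileNotFoundError(f"plate file missing: {p}")
                if p.suffix.lower() == ".csv":
                    fields.append(read_field_csv(p))
                else:
                    fields.append(image_to_biomass(read_field_image(p), cal))
            plates.append(fields)
            counts = abund[abund["week"] == wk]["count"].to_numpy(dtype=float)
            if counts.size == 0:
                raise ValueError(f"no abundance rows for week {wk!r}")
            communities.append(CommunitySample(counts))
        return cls(weeks, plates, communities, config)

    def fit(self) -> SuccessionReport:
        cfg = self.config
        q_grid = cfg.q_grid()
        shapes = {f.shape for wk in self.plates for f in wk}
        if len(shapes) > 1:
            raise ValueError(f"plates have mismatched grids: {sorted(shapes)}")

        # one spectrum per plate, computed once and reused everywhere
        spectra = {
            label: [MultifractalModel(f, q_grid=q_grid, gradient=cfg.gradient).fit()
                    for f in fields]
            for label, fields in zip(self.weeks, self.plates)
        }

        rows = []
        for label, comm in zip(self.weeks, self.communities):
            d1s = np.array([s.d1 for s in spectra[label]])
            rows.append(
                {
                    "week": label,
                    "n_plates": len(d1s),
                    "d1_mean": d1s.mean(),
                    "d1_sd": d1s.std(ddof=1) if len(d1s) > 1 else np.nan,
                    "richness": comm.richness,
                    "shannon_h": comm.shannon_h,
                }
            )
        week_table = pd.DataFrame(rows)

        pairwise = pairwise_week_tests(
            [(label, spectra[label]) for label in self.weeks],
            n_perm=cfg.n_perm, seed=cfg.seed,
        )

        plate_d1 = np.concatenate(
            [[s.d1 for s in spectra[label]] for label in self.weeks])
        plate_h = np.concatenate(
            [[comm.shannon_h] * len(spectra[label])
             for label, comm in zip(self.weeks, self.communities)])
        kendall_plate = kendall_correlation(plate_d1, plate_h)
        kendall_week = kendall_correlation(
            week_table["d1_mean"].to_numpy(), week_table["shannon_h"].to_numpy())
        qfit = quantile_regression_dh(plate_d1, plate_h, seed=cfg.seed)

        return SuccessionReport(
            week_table=week_table,
            pairwise=pairwise,
            kendall_plate=kendall_plate,
            kendall_week=kendall_week,
            quantile_fit=qfit,
            spectra=spectra,
            config=cfg,
        )


def run_succession_analysis(manifest_csv, abundances_csv,
                            config: RunConfig | None = None,
                            outdir=None) -> SuccessionReport:
    """Load, fit and (optionally) save one succession run."""
    report = SuccessionStudy.from_manifest(manifest_csv, abundances_csv, config).fit()
    if outdir is not None:
        report.save(outdir)
    return report


def make_figures(report: SuccessionReport, outdir) -> list[Path]:
    """Write the standard figures; plots are artifacts, not results."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    # mean D(q) curve per week
    fig, ax = plt.subplots()
    for label, specs in report.spectra.items():
        dq = np.mean([s.dq for s in specs], axis=0)
        ax.plot(specs[0].q_grid, dq, marker="o", ms=3, label=f"week {label}")
    ax.axhline(2.0, color="gray", lw=0.8, ls="--")
    ax.set_xlabel("moment order q")
    ax.set_ylabel("D(q)")
    ax.legend(fontsize=8)
    path = out / "dq_spectra.png"
    fig.savefig(path, dpi=150)
    plt.close(fig)
    written.append(path)

    # scaling fits for the first plate
    first = next(iter(report.spectra.values()))[0]
    if first.partition is not None:
        fig, ax = plt.subplots()
        first.plot_scaling(ax=ax)
        path = out / "xq_scaling.png"
        fig.savefig(path, dpi=150)
        plt.close(fig)
        written.append(path)

    # D(1) vs H with quantile lines
    fig, ax = plt.subplots()
    d1 = np.concatenate([[s.d1 for s in specs] for specs in report.spectra.values()])
    h = np.concatenate(
        [[row.shannon_h] * row.n_plates for row in report.week_table.itertuples()])
    ax.scatter(d1, h, s=12)
    grid = np.linspace(d1.min(), d1.max(), 50)
    for tau in report.quantile_fit.tau_levels:
        ax.plot(grid, report.quantile_fit.predict(grid, tau), lw=0.8,
                label=f"tau={tau:.1f}")
    ax.set_xlabel("information dimension D(1)")
    ax.set_ylabel("Shannon H (bits)")
    ax.legend(fontsize=7, ncol=2)
    path = out / "d1_vs_h.png"
    fig.savefig(path, dpi=150)
    plt.close(fig)
    written.append(path)
    return written


def write_series(series: SuccessionSeries, outdir) -> tuple[Path, Path]:
    """Export a synthetic series as CSV plates + manifest + abundances.

    Returns (manifest_path, abundances_path); the layout round-trips
    through :meth:`SuccessionStudy.from_manifest`.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    man_rows, ab_rows = [], []
    for label, fields, comm in zip(series.weeks, series.plates, series.communities):
        for p_idx, f in enumerate(fields):
            path = out / f"week{label}_plate{p_idx}.csv"
            write_field_csv(f, path)
            man_rows.append({"week": label, "plate": p_idx, "path": str(path)})
        for s_idx, count in enumerate(comm.abundances):
            ab_rows.append({"week": label, "species": s_idx, "count": count})
    manifest = out / "manifest.csv"
    abundances = out / "abundances.csv"
    pd.DataFrame(man_rows).to_csv(manifest, index=False)
    pd.DataFrame(ab_rows).to_csv(abundances, index=False)
    return manifest, abundances
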