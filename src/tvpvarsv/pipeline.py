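"""End-to-end orchestration: simulate/load -> preprocess -> ADF -> fit -> IRF -> report.

`run_pipeline` executes the whole analysis from a single `PipelineConfig`
and writes a reproducible report bundle (CSV tables, optional figures, and a
JSON manifest carrying the full config, seed, package versions and output
checksums).  Identical config + seed give byte-identical CSV outputs.

Two MCMC profiles are provided: ``paper`` (10,000 sweeps, 1,000 burn-in —
the study configuration) and ``fast`` (2,000 / 200) for smoke runs and
continuous testing.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import ModelSpec, PriorConfig
from .irf import equal_interval_slices, timepoint_slices, tv_irf
from .mcmc import MCMCConfig, diagnose, run_mcmc
from .preprocess import (
    describe,
    impute_missing,
    read_baseline,
    read_panel,
    seasonal_adjust,
)
from .stationarity import adf_table
from .synthetic import StudyScenarioConfig, make_study_like_panel

__all__ = ["PipelineConfig", "PipelineError", "DataError", "NumericalError",
           "run_pipeline", "PROFILES"]

logger = logging.getLogger(__name__)

PROFILES = {"paper": (10_000, 1_000), "fast": (2_000, 200)}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


class DataError(ValueError):
    """Bad or missing input data."""


class NumericalError(FloatingPointError):
    """Numerical failure inside estimation."""


@dataclass
class PipelineConfig:
    """Everything one run needs; serializable to/from YAML."""

    outdir: str = "tvpvarsv_out"
    input_panel: str | None = None      # None -> simulate the study-like scenario
    baseline: str | None = None
    seed: int = 0
    profile: str = "fast"
    names: tuple[str, ...] = ("new", "pas", "pek")
    lag: int = 1
    include_intercept: bool = False
    n_imputations: int = 5
    n_draws: int | None = None          # None -> profile default
    burn_in: int | None = None
    thin: int = 1
    irf_horizon: int = 14
    irf_horizons: tuple[int, ...] = (1, 7, 14)
    irf_dates: tuple[str, ...] = ("2020-01-22", "2020-03-30", "2020-06-17")
    irf_convention: str = "average_volatility"
    scenario: StudyScenarioConfig | None = None
    make_plots: bool = False
    save_draws: bool = False

    def resolved_mcmc(self) -> MCMCConfig:
        if self.profile not in PROFILES:
            raise ValueError(f"unknown profile {self.profile!r}")
        nd, bi = PROFILES[self.profile]
        return MCMCConfig(
            n_draws=self.n_draws if self.n_draws is not None else nd,
            burn_in=self.burn_in if self.burn_in is not None else bi,
            thin=self.thin, seed=self.seed,
        )

    def model_spec(self) -> ModelSpec:
        return ModelSpec(names=self.names, lag=self.lag,
                         include_intercept=self.include_intercept)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["names"] = list(self.names)
        d["irf_horizons"] = list(self.irf_horizons)
        d["irf_dates"] = list(self.irf_dates)
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        if d.get("scenario") is not None:
            d["scenario"] = StudyScenarioConfig(**d["scenario"])
        for key in ("names", "irf_horizons", "irf_dates"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the manifest (also written to the bundle).

    Any stage failure aborts with :class:`PipelineError` naming the stage.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    timings: dict[str, float] = {}

    def stage(name):
        class _Stage:
            def __enter__(self_inner):
                logger.info("stage %s: start", name)
                self_inner.t0 = time.perf_counter()
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self_inner.t0, 3)
                if exc is not None:
                    logger.error("stage %s: failed (%s)", name, exc)
                    if not isinstance(exc, PipelineError):
                        raise PipelineError(name, exc) from exc
                    return False
                logger.info("stage %s: done in %.2fs", name, timings[name])
                return False
        return _Stage()

    def emit(frame: pd.DataFrame, name: str, **to_csv_kw) -> None:
        path = outdir / name
        frame.to_csv(path, **to_csv_kw)
        written.append(path)

    with stage("input"):
        if config.input_panel is None:
            scenario = config.scenario or StudyScenarioConfig(seed=config.seed)
            panel, baseline = make_study_like_panel(scenario)
        else:
            panel = read_panel(config.input_panel)
            if config.baseline is None:
                raise DataError("an input panel requires a --baseline CSV")
            if not Path(config.baseline).exists():
                raise FileNotFoundError(f"baseline file not found: {config.baseline}")
            baseline = read_baseline(config.baseline)

    with stage("preprocess"):
        imputed = impute_missing(panel, config.n_imputations, seed=config.seed)
        adjusted = seasonal_adjust(imputed.consensus, baseline)
        stats = describe(adjusted)
        emit(stats.table.reset_index(names="Variables"), "descriptives.csv", index=False)

    with stage("adf"):
        adf = adf_table(adjusted)
        emit(adf, "adf.csv", index=False)

    with stage("fit"):
        spec = config.model_spec()
        draws = run_mcmc(adjusted, spec, PriorConfig(), config.resolved_mcmc())
        if config.save_draws:
            draws.save(outdir / "draws")
        states = draws.posterior_mean_states()
        mean_states = pd.DataFrame(
            np.hstack([states.beta, states.alpha, states.h]),
            index=pd.DatetimeIndex(draws.dates).strftime("%Y-%m-%d"),
            columns=[f"beta_{i + 1}" for i in range(spec.k_beta)]
            + [f"alpha_{i + 1}" for i in range(spec.k_alpha)]
            + [f"h_{name}" for name in spec.names],
        )
        emit(mean_states, "posterior_mean_states.csv", index_label="date")

    with stage("diagnostics"):
        diags = diagnose(draws, acf_lags=min(500, draws.n_retained - 1))
        emit(diags.summary(), "diagnostics.csv", index=False)
        if config.make_plots:
            _plot_diagnostics(diags, outdir, written)

    with stage("irf"):
        surface = tv_irf(draws, spec, H=config.irf_horizon,
                         convention=config.irf_convention, compute_bands=True)
        emit(surface.to_long_frame(), "irf_surface.csv", index=False)
        shock, response = spec.names[0], spec.names[-1]
        eq = equal_interval_slices(surface, shock, response, config.irf_horizons)
        emit(eq, "irf_equal_interval.csv", date_format="%Y-%m-%d")
        in_range = [d for d in config.irf_dates
                    if surface.dates[0] <= pd.Timestamp(d) <= surface.dates[-1]]
        if in_range:
            tp = timepoint_slices(surface, shock, response, tuple(in_range))
            emit(tp, "irf_timepoints.csv")
        if config.make_plots:
            _plot_irf(surface, eq, outdir, written)

    with stage("report"):
        manifest = {
            "package": "tvpvarsv",
            "version": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "seed": config.seed,
            "config": config.to_dict(),
            "timings_s": timings,
            "outputs": {p.name: _sha256(p) for p in written},
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _plot_diagnostics(diags, outdir: Path, written: list[Path]) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = list(diags.scalars)
    fig, axes = plt.subplots(3, len(names), figsize=(3 * len(names), 7), squeeze=False)
    for c, name in enumerate(names):
        s = diags.scalars[name]
        axes[0, c].plot(s.acf[:min(s.acf.size, 500)], lw=0.8)
        axes[0, c].set_title(name, fontsize=8)
        axes[1, c].plot(s.trace, lw=0.4)
        axes[2, c].plot(s.density_x, s.density_pdf, lw=0.8)
    for ax, label in zip(axes[:, 0], ("ACF", "trace", "density")):
        ax.set_ylabel(label)
    fig.tight_layout()
    path = outdir / "diagnostics.png"
    fig.savefig(path, dpi=110)
    plt.close(fig)
    written.append(path)


def _plot_irf(surface, eq_slices, outdir: Path, written: list[Path]) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax0, ax1) = plt.subplots(1, 2, figsize=(10, 4))
    for col in eq_slices.columns:
        ax0.plot(eq_slices.index, eq_slices[col], label=col, lw=0.9)
    ax0.axhline(0.0, color="k", lw=0.5)
    ax0.legend(fontsize=8)
    ax0.set_title("equal-interval responses", fontsize=9)
    i, j = len(surface.names) - 1, 0
    im = ax1.imshow(surface.mean[:, :, i, j].T, aspect="auto", origin="lower",
                    cmap="RdBu_r")
    fig.colorbar(im, ax=ax1)
    ax1.set_xlabel("date index")
    ax1.set_ylabel("horizon")
    ax1.set_title("response surface", fontsize=9)
    fig.tight_layout()
    path = outdir / "irf.png"
    fig.savefig(path, dpi=110)
    plt.close(fig)
    written.append(path)
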