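"""End-to-end orchestration: cohort I/O, binned outcome rates, the results
table mirroring the headline analysis layout, sensitivity sweeps, the
falsification report, figures, and deterministic machine-readable output.

All machine-readable artifacts are pure functions of (cohort, config, seed):
no timestamps, sorted keys, full float precision. Display formatting rounds
percentage-point estimates to 1 decimal and bandwidths to 2.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .density_diagnostics import score_histogram
from .errors import ConfigError, PipelineError, SchemaError, ValidationError
from .falsification import FalsificationReport, FalsificationSettings, run_falsification
from .rd_core import (
    BINARY_OUTCOMES,
    KernelSpec,
    RDFit,
    SensitivityCurve,
    bandwidth_sweep,
    cct_bandwidth,
    rd_estimate,
    resolve_outcome,
)
from .synthetic_cohort import COLUMNS, Cohort, CohortConfig, generate_cohort

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = list(COLUMNS)
FLAG_COLUMNS = ["treated", "rrt", "icu_transfer", "arrest", "death"]

#: offset applied to the master seed when generating the placebo cohort
PLACEBO_SEED_OFFSET = 1_000_003


# ----------------------------------------------------------------------
# Cohort I/O
# ----------------------------------------------------------------------

def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort as comma-separated text with a header row.

    Float columns are serialized with ``repr`` (shortest round-trip form), so
    write-then-read reproduces every analyzed field bit-exactly.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame = cohort.data.copy()
    for col in frame.columns:
        if frame[col].dtype.kind == "f":
            frame[col] = ["" if np.isnan(v) else repr(float(v)) for v in frame[col]]
    frame.to_csv(path, index=False)


def read_cohort(path, threshold: float = 65.0) -> Cohort:
    """Read a cohort table, validating schema and value ranges.

    Unknown columns are preserved; missing required columns are fatal.
    Malformed or out-of-range rows are reported with 1-based file line
    numbers (header is line 1).
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"cohort file not found: {path}")
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = [col for col in REQUIRED_COLUMNS if col not in frame.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    def lines(mask) -> str:
        return ", ".join(str(i + 2) for i in frame.index[mask][:10])

    scores = pd.to_numeric(frame["max_score"], errors="coerce")
    bad = scores.isna()
    if bad.any():
        raise ValidationError(f"non-numeric max_score at line(s) {lines(bad)}")
    out_of_range = (scores < 0.0) | (scores > 100.0)
    if out_of_range.any():
        raise ValidationError(f"max_score outside [0, 100] at line(s) {lines(out_of_range)}")
    for col in FLAG_COLUMNS:
        vals = pd.to_numeric(frame[col], errors="coerce")
        bad = vals.isna() | ~vals.isin([0, 1])
        if bad.any():
            raise ValidationError(f"column {col!r} must be 0/1; bad line(s) {lines(bad)}")
        frame[col] = vals.astype(np.int8)
    frame["max_score"] = scores.astype(float)
    return Cohort(frame, threshold=threshold, provenance={"source": str(path)})


# ----------------------------------------------------------------------
# Binned outcome rates
# ----------------------------------------------------------------------

def bin_outcome_rates(
    cohort: Cohort, outcome_label: str, bin_width: float = 1.0, c: Optional[float] = None
) -> pd.DataFrame:
    """Per-bin event rate and count; bins left-closed right-open with the
    threshold on a bin edge (records at exactly c fall in the bin above)."""
    c = cohort.threshold if c is None else c
    x, y = resolve_outcome(cohort, outcome_label)
    sub = Cohort(pd.DataFrame({"id": np.arange(x.size), "max_score": x}), threshold=c)
    hist = score_histogram(sub, bin_width, c)
    edges = np.append(hist["bin_left"].to_numpy(), hist["bin_left"].iloc[-1] + bin_width)
    idx = np.clip(np.digitize(x, edges) - 1, 0, len(edges) - 2)
    sums = np.bincount(idx, weights=y, minlength=len(edges) - 1)
    counts = hist["count"].to_numpy().astype(float)
    rate = np.where(counts > 0, sums / np.maximum(counts, 1.0), np.nan)
    return hist.assign(rate=rate)


# ----------------------------------------------------------------------
# Analysis configuration & results table
# ----------------------------------------------------------------------

DEFAULT_OUTCOMES = ("secondary", "death", "icu_transfer", "rrt_or_arrest")


@dataclass
class AnalysisConfig:
    threshold: float = 65.0
    manual_bandwidth: float = 7.0
    sweep_grid: Sequence[float] = tuple(range(1, 16))
    orders: Sequence[int] = (1, 2)
    alpha: float = 0.05
    outcomes: Sequence[str] = DEFAULT_OUTCOMES
    figure_bin_width: float = 1.0
    kernel: str = "triangular"
    input_path: Optional[str] = None
    placebo_path: Optional[str] = None
    output_dir: str = "rdalert_output"
    seed: int = 0
    run_sweep: bool = True
    make_figures: bool = True
    cohort_config: CohortConfig = field(default_factory=CohortConfig)

    def validate(self) -> None:
        if self.manual_bandwidth <= 0:
            raise ConfigError("manual_bandwidth must be positive")
        grid = list(self.sweep_grid)
        if any(h <= 0 for h in grid) or any(b <= a for a, b in zip(grid, grid[1:])):
            raise ConfigError("sweep_grid must be positive and strictly increasing")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError("alpha must be in (0, 1)")
        if self.figure_bin_width <= 0:
            raise ConfigError("figure_bin_width must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sweep_grid"] = list(self.sweep_grid)
        d["orders"] = list(self.orders)
        d["outcomes"] = list(self.outcomes)
        return d

    @classmethod
    def from_dict(cls, raw: dict) -> "AnalysisConfig":
        raw = dict(raw)
        cohort_raw = raw.pop("cohort_config", None)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown analysis config key(s): {', '.join(sorted(unknown))}")
        cfg = cls(**raw)
        if cohort_raw is not None:
            cohort_known = {f.name for f in dataclasses.fields(CohortConfig)}
            extra = set(cohort_raw) - cohort_known - {"score_beta_resolved"}
            if extra:
                raise ConfigError(f"unknown cohort config key(s): {', '.join(sorted(extra))}")
            cohort_raw = {k: v for k, v in cohort_raw.items() if k in cohort_known
                          and k not in ("covariates", "trajectory")}
            cfg.cohort_config = CohortConfig(**cohort_raw)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError("analysis config file must contain a mapping")
        return cls.from_dict(raw)


@dataclass(frozen=True)
class ResultRow:
    outcome_label: str
    bandwidth_source: str  # manual | cct | cct_quadratic
    fit: RDFit


def _fit_to_dict(fit: RDFit, scale: float = 1.0) -> dict:
    return {
        "estimate": fit.estimate * scale,
        "se": fit.se * scale,
        "ci_low": fit.ci_low * scale,
        "ci_high": fit.ci_high * scale,
        "p_value": fit.p_value,
        "bandwidth": fit.bandwidth,
        "order": fit.order,
        "kernel": fit.kernel,
        "n_left": fit.n_left,
        "n_right": fit.n_right,
    }


@dataclass
class ResultsTable:
    """One row per (outcome, bandwidth source); binary outcomes in percentage points."""

    rows: list = field(default_factory=list)  # list[ResultRow]

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for row in self.rows:
            scale = 100.0 if row.outcome_label in BINARY_OUTCOMES else 1.0
            recs.append(
                {
                    "outcome": row.outcome_label,
                    "bandwidth_source": row.bandwidth_source,
                    **_fit_to_dict(row.fit, scale),
                }
            )
        return pd.DataFrame(recs)

    def format_text(self) -> str:
        lines = [
            f"{'Outcome':<28}{'Spec':<16}{'Bandwidth':>10}{'Estimate (95% CI)':>28}{'P value':>10}"
        ]
        for row in self.rows:
            scale = 100.0 if row.outcome_label in BINARY_OUTCOMES else 1.0
            f = row.fit
            est = f"{f.estimate * scale:.1f} ({f.ci_low * scale:.1f} to {f.ci_high * scale:.1f})"
            lines.append(
                f"{row.outcome_label:<28}{row.bandwidth_source:<16}"
                f"{f.bandwidth:>10.2f}{est:>28}{f.p_value:>10.3f}"
            )
        return "\n".join(lines) + "\n"


# ----------------------------------------------------------------------
# Orchestration
# ----------------------------------------------------------------------

@dataclass
class AnalysisResult:
    table: ResultsTable
    falsification: FalsificationReport
    sweeps: dict  # outcome label -> SensitivityCurve
    cohort: Cohort
    placebo_cohort: Optional[Cohort]
    config: AnalysisConfig
    figures: list = field(default_factory=list)


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise PipelineError(f"stage '{name}' failed: {exc}") from exc
    return wrap


def _load_or_generate(config: AnalysisConfig) -> tuple:
    if config.input_path:
        cohort = read_cohort(config.input_path, threshold=config.threshold)
    else:
        gen = dataclasses.replace(
            config.cohort_config, seed=config.seed, threshold=config.threshold
        )
        cohort = generate_cohort(gen)
    if config.placebo_path:
        placebo = read_cohort(config.placebo_path, threshold=config.threshold)
    elif config.input_path:
        placebo = None
    else:
        placebo_cfg = dataclasses.replace(
            config.cohort_config,
            seed=config.seed + PLACEBO_SEED_OFFSET,
            threshold=config.threshold,
            tau=0.0,
            contamination_rate=0.0,
            period="pre_implementation",
        )
        placebo = generate_cohort(placebo_cfg)
    return cohort, placebo


def run_analysis(
    config: AnalysisConfig,
    cohort: Optional[Cohort] = None,
    placebo_cohort: Optional[Cohort] = None,
) -> AnalysisResult:
    """Run the full analysis: primary outcome at the manual bandwidth, at the
    MSE-optimal bandwidth, and with a local quadratic at its own optimal
    bandwidth; every other configured outcome at its own optimal bandwidth;
    sensitivity sweeps for the primary and secondary composites; and the
    falsification suite. Results are returned in memory; ``write_outputs``
    persists them."""
    config.validate()
    if cohort is None or (placebo_cohort is None and not config.input_path):
        loaded_cohort, loaded_placebo = _stage("load")(_load_or_generate, config)
        cohort = cohort if cohort is not None else loaded_cohort
        placebo_cohort = placebo_cohort if placebo_cohort is not None else loaded_placebo

    c = config.threshold
    kern = config.kernel
    rows = []

    def estimate(label, h, order, source):
        fit = rd_estimate(cohort, label, c, KernelSpec(kern, h),
                          order=order, alpha=config.alpha)
        rows.append(ResultRow(label, source, fit))
        return fit

    run = _stage("primary-estimates")
    run(estimate, "primary", config.manual_bandwidth, 1, "manual")
    h_cct = run(cct_bandwidth, cohort, "primary", c, kern, 1)
    run(estimate, "primary", h_cct, 1, "cct")
    if 2 in config.orders:
        h_q = run(cct_bandwidth, cohort, "primary", c, kern, 2)
        run(estimate, "primary", h_q, 2, "cct_quadratic")

    run = _stage("secondary-estimates")
    for label in config.outcomes:
        h = run(cct_bandwidth, cohort, label, c, kern, 1)
        run(estimate, label, h, 1, "cct")

    sweeps = {}
    if config.run_sweep:
        run = _stage("sensitivity-sweep")
        for label in ("primary", "secondary"):
            sweeps[label] = run(
                bandwidth_sweep, cohort, label, c, list(config.sweep_grid),
                kernel=kern, alpha=config.alpha,
            )

    settings = FalsificationSettings(
        alpha=config.alpha, kernel=kern,
        assignment_bin_width=config.figure_bin_width,
    )
    falsification = _stage("falsification")(
        run_falsification, cohort, placebo_cohort, settings
    )

    return AnalysisResult(
        table=ResultsTable(rows),
        falsification=falsification,
        sweeps=sweeps,
        cohort=cohort,
        placebo_cohort=placebo_cohort,
        config=config,
    )


# ----------------------------------------------------------------------
# Persistence & figures
# ----------------------------------------------------------------------

def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="list")
    raise TypeError(f"not JSON serializable: {type(obj)}")


def falsification_to_dict(report: FalsificationReport) -> dict:
    out = {"verdicts": report.verdicts, "errors": report.errors}
    out["covariates"] = {k: _fit_to_dict(f) for k, f in report.covariate_fits.items()}
    if report.placebo_fit is not None:
        out["placebo"] = _fit_to_dict(report.placebo_fit, scale=100.0)
    if report.assignment_jump is not None:
        out["assignment_jump"] = _fit_to_dict(report.assignment_jump)
    if report.density_result is not None:
        d = report.density_result
        out["density"] = {
            "theta": d.theta, "se": d.se, "p_value": d.p_value,
            "bin_size": d.bin_size, "smoothing_bandwidth": d.smoothing_bandwidth,
        }
    return out


def write_outputs(result: AnalysisResult, output_dir=None) -> list:
    """Persist all artifacts; machine-readable files are byte-deterministic."""
    out = Path(output_dir if output_dir is not None else result.config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    frame = result.table.to_frame()
    frame.to_csv(out / "results_table.csv", index=False)
    (out / "results_table.txt").write_text(result.table.format_text())
    written += ["results_table.csv", "results_table.txt"]

    payload = falsification_to_dict(result.falsification)
    (out / "falsification.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True, default=_json_default) + "\n"
    )
    written.append("falsification.json")

    for label, curve in result.sweeps.items():
        name = f"sensitivity_{label}.csv"
        curve.to_frame().to_csv(out / name, index=False)
        written.append(name)

    log = {
        "config": result.config.to_dict(),
        "n_records": len(result.cohort),
        "n_placebo": len(result.placebo_cohort) if result.placebo_cohort is not None else 0,
    }
    (out / "run_log.json").write_text(
        json.dumps(log, indent=2, sort_keys=True, default=_json_default) + "\n"
    )
    written.append("run_log.json")

    if result.config.make_figures:
        written += make_figures(result, out)
    return written


def make_figures(result: AnalysisResult, out: Path) -> list:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cfg = result.config
    c = cfg.threshold
    cohort = result.cohort
    written = []

    # assignment proportions by score bin
    if result.falsification.assignment_table is not None:
        tab = result.falsification.assignment_table
        fig, ax = plt.subplots(figsize=(7, 4))
        ax.scatter(tab["bin_center"], tab["proportion_treated"], s=12, color="tab:blue")
        ax.axvline(c, color="black", lw=1)
        ax.set_xlabel("maximum score")
        ax.set_ylabel("proportion alerted")
        fig.savefig(out / "assignment_discontinuity.png", dpi=120)
        plt.close(fig)
        written.append("assignment_discontinuity.png")

    # binned primary rates with side-wise fitted lines at the manual bandwidth
    rates = bin_outcome_rates(cohort, "primary", cfg.figure_bin_width, c)
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.scatter(rates["bin_center"], rates["rate"], s=12, color="tab:blue")
    h = cfg.manual_bandwidth
    spec = KernelSpec(cfg.kernel, h)
    from .rd_core import fit_side
    for side, lo, hi in (("below", c - h, c), ("above", c, c + h)):
        try:
            sf = fit_side(cohort, "primary", side, c, spec, order=1)
        except Exception:
            continue
        xs = np.linspace(lo, hi, 50)
        ax.plot(xs, sf.intercept + sf.slopes[0] * (xs - c), color="tab:red", lw=1.5)
    ax.axvline(c, color="black", lw=1)
    ax.set_xlabel("maximum score")
    ax.set_ylabel("primary outcome rate")
    fig.savefig(out / "primary_outcome_rates.png", dpi=120)
    plt.close(fig)
    written.append("primary_outcome_rates.png")

    # score histogram
    hist = score_histogram(cohort, cfg.figure_bin_width, c)
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.bar(hist["bin_center"], hist["count"], width=cfg.figure_bin_width, color="tab:gray")
    ax.axvline(c, color="black", lw=1)
    ax.set_xlabel("maximum score")
    ax.set_ylabel("hospitalizations")
    fig.savefig(out / "score_histogram.png", dpi=120)
    plt.close(fig)
    written.append("score_histogram.png")

    # sensitivity curves
    for label, curve in result.sweeps.items():
        frame = curve.to_frame()
        if frame.empty:
            continue
        fig, ax = plt.subplots(figsize=(7, 4))
        ax.errorbar(
            frame["bandwidth"], 100 * frame["estimate"],
            yerr=[100 * (frame["estimate"] - frame["ci_low"]),
                  100 * (frame["ci_high"] - frame["estimate"])],
            fmt="o-", ms=3, lw=1, capsize=2,
        )
        ax.axhline(0, color="black", lw=1)
        ax.set_xlabel("bandwidth")
        ax.set_ylabel(f"{label} effect (percentage points)")
        name = f"sensitivity_{label}.png"
        fig.savefig(out / name, dpi=120)
        plt.close(fig)
        written.append(name)
    return written
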