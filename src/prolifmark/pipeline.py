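"""End-to-end experiment: simulate -> render -> count -> IOD -> stats -> model check.

The cohort's marker counts come from the fast Poisson path of
:mod:`prolifmark.synthetic_cohort`; a configurable subset of tumors is
additionally rendered as pixel fields and pushed through the five-step
counting algorithm and the IOD measurement, verifying that the image route
recovers the simulated truth. All stages are seeded and every reported
number is recomputable from the written tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from prolifmark import plots
from prolifmark.cell_cycle_model import CellCycleDurations
from prolifmark.cohort_stats import (
    MARKER_VARIABLES,
    ContingencyTable2x2,
    RegressionFit,
    classify_above_line,
    correlation_matrix,
    fisher_exact_2x2,
    grade_summary,
    ols_fit,
    two_sample_t,
)
from prolifmark.errors import InvalidParameterError
from prolifmark.ihc_counting import CountingConfig, count_field
from prolifmark.iod_measurement import sample_nuclei_masks, tumor_iod
from prolifmark.synthetic_cohort import (
    CohortConfig,
    TumorSpec,
    sample_cell_snapshots,
    simulate_cohort,
    tumor_rng,
    write_cohort_csvs,
)
from prolifmark.synthetic_imaging import (
    NucleusRecord,
    RenderConfig,
    StainVectors,
    SyntheticField,
    ground_truth_counts,
    place_nuclei,
    render_field,
)

__all__ = [
    "ExperimentConfig",
    "ExperimentReport",
    "render_tumor_field",
    "run_experiment",
    "compare_to_model",
    "load_config",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExperimentConfig:
    """Single config driving every stage; any nested default is overridable."""

    cohort: CohortConfig = CohortConfig()
    render: RenderConfig = RenderConfig()
    counting: CountingConfig = CountingConfig()
    n_render_tumors: int = 3
    render_frame: tuple[int, int] = (300, 400)  # (height, width) of verification fields
    save_fields: bool = False
    save_figures: bool = True
    seed: int = 0

    def with_seed(self, seed: int) -> "ExperimentConfig":
        return dataclasses.replace(
            self, seed=seed, cohort=dataclasses.replace(self.cohort, seed=seed)
        )


def load_config(path) -> ExperimentConfig:
    """Build an :class:`ExperimentConfig` from a YAML mapping of overrides."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    cohort = CohortConfig(**raw.get("cohort", {}))
    render = RenderConfig(**raw.get("render", {}))
    counting_kw = dict(raw.get("counting", {}))
    if "vectors" in counting_kw:
        counting_kw["vectors"] = StainVectors(**counting_kw["vectors"])
    counting = CountingConfig(**counting_kw)
    top = {k: v for k, v in raw.items() if k not in ("cohort", "render", "counting")}
    if "render_frame" in top:
        top["render_frame"] = tuple(top["render_frame"])
    cfg = ExperimentConfig(cohort=cohort, render=render, counting=counting, **top)
    return cfg.with_seed(cfg.seed)


def render_tumor_field(
    spec: TumorSpec,
    cohort_config: CohortConfig,
    render_config: RenderConfig,
    stain_mode: str,
    rng: np.random.Generator,
    frame: tuple[int, int] | None = None,
    vectors: StainVectors | None = None,
) -> SyntheticField:
    """Render one microscope field of a simulated tumor for the given stain.

    The nucleus count scales the tumor's nuclei-per-10x-field expectation by
    the frame's area fraction; each nucleus carries marker flags and DNA
    content drawn from the tumor's cell-snapshot model.
    """
    h, w = frame if frame is not None else (render_config.height, render_config.width)
    area_scale = (h * w) / (2560.0 * 1920.0)
    n = int(rng.poisson(spec.nuclei_per_field * area_scale))
    cfg = dataclasses.replace(render_config, width=w, height=h)
    geoms = place_nuclei(n, cfg, rng)
    snaps = sample_cell_snapshots(spec, cohort_config, n, rng)
    records = [
        NucleusRecord(
            label=i + 1,
            geometry=g,
            mib1_pos=bool(snaps["mib1_pos"].iat[i]),
            phh3_pos=bool(snaps["phh3_pos"].iat[i]),
            mitotically_visible=bool(snaps["mitotically_visible"].iat[i]),
            dna_content=float(snaps["dna_content"].iat[i]),
            phase=str(snaps["phase"].iat[i]),
        )
        for i, g in enumerate(geoms)
    ]
    return render_field(records, stain_mode, vectors or StainVectors(), cfg, rng,
                        frame=(h, w))


@dataclass
class ExperimentReport:
    """Everything the experiment produced, recomputable from the stored tables."""

    config: ExperimentConfig
    cohort: pd.DataFrame
    correlations_measured: pd.DataFrame
    correlations_truth: pd.DataFrame
    fit: RegressionFit
    contingency: ContingencyTable2x2
    fisher_p: float
    grade_tests: dict[str, tuple[float, float]]
    summary: pd.DataFrame
    model_comparison: pd.DataFrame
    imaging_check: pd.DataFrame
    seed: int


def compare_to_model(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-tumor predicted vs observed PhH3/MIB-1 ratio.

    Predicted = T_m / (T_m + T_i) from the tumor's true durations; observed =
    measured PhH3 / MIB-1 per field. Tumors with a zero MIB-1 count are
    flagged (NaN observed ratio) and excluded from the error summary.
    """
    pred = cohort["t_m"] / (cohort["t_m"] + cohort["t_i"])
    with np.errstate(divide="ignore", invalid="ignore"):
        obs = np.where(cohort["mib1_per_field"] > 0,
                       cohort["phh3_per_field"] / cohort["mib1_per_field"], np.nan)
    out = pd.DataFrame({
        "tumor_id": cohort["tumor_id"],
        "predicted_ratio": pred,
        "observed_ratio": obs,
    })
    out["relative_error"] = (out["observed_ratio"] - out["predicted_ratio"]) / out["predicted_ratio"]
    out["flagged"] = ~np.isfinite(obs)
    return out


def _truth_expected_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Noise-free expected marker values from the ground-truth columns."""
    ratio = cohort["t_m"] / cohort["t_c"]
    return pd.DataFrame({
        "mib1_per_field": cohort["nuclei_per_field"] * cohort["p_cycling"],
        "phh3_per_field": cohort["nuclei_per_field"] * cohort["p_cycling"] * ratio,
        "mitoses_per_10hpf": cohort["nuclei_per_field"] * cohort["p_cycling"] * ratio,
        "iod": cohort["dna_index"],
    })


def _imaging_check(cohort: pd.DataFrame, config: ExperimentConfig) -> pd.DataFrame:
    """Render a tumor subset and compare image-route measurements with truth."""
    rows = []
    n = min(config.n_render_tumors, len(cohort))
    if n == 0:
        return pd.DataFrame(columns=["tumor_id", "stain", "ground_truth", "image_count"])
    # spread the subset across the grade range
    picks = np.linspace(0, len(cohort) - 1, n).astype(int)
    for idx in picks:
        row = cohort.iloc[idx]
        spec = TumorSpec(
            tumor_id=row["tumor_id"], grade=int(row["grade"]),
            p_cycling=float(row["p_cycling"]),
            durations=CellCycleDurations(row["t_g1"], row["t_s"], row["t_g2"], row["t_m"]),
            dna_index=float(row["dna_index"]),
            nuclei_per_field=float(row["nuclei_per_field"]),
            n_fields=int(row["n_fields"]),
        )
        rng = tumor_rng(config.cohort, 100_000 + int(idx))
        for stain in ("MIB1", "PHH3"):
            fld = render_tumor_field(spec, config.cohort, config.render, stain,
                                     rng, frame=config.render_frame)
            rows.append({
                "tumor_id": row["tumor_id"], "stain": stain,
                "ground_truth": ground_truth_counts(fld, stain),
                "image_count": count_field(fld.rgb, config.counting),
            })
        he = render_tumor_field(spec, config.cohort, config.render, "HE",
                                rng, frame=config.render_frame)
        n_iod = min(config.cohort.iod_nuclei_per_tumor, len(he.records))
        if n_iod:
            masks = sample_nuclei_masks(he, n_iod, rng)
            iod = tumor_iod([(he.rgb, m) for m in masks],
                            config.counting.vectors,
                            config.counting.background_intensity,
                            expected_n=n_iod)
            rows.append({"tumor_id": row["tumor_id"], "stain": "HE_IOD",
                         "ground_truth": float(np.mean([r.dna_content for r in he.records])),
                         "image_count": iod})
    return pd.DataFrame(rows)


def run_experiment(config: ExperimentConfig | str | Path,
                   out_dir: str | Path | None = None) -> ExperimentReport:
    """Run every stage and (optionally) write all outputs under ``out_dir``."""
    if not isinstance(config, ExperimentConfig):
        config = load_config(config)

    logger.info("simulating cohort (%s tumors)", sum(config.cohort.n_per_grade))
    cohort = simulate_cohort(config.cohort)
    if cohort.empty:
        raise InvalidParameterError("empty cohort; nothing to analyse")

    logger.info("cohort statistics")
    corr_meas = correlation_matrix(cohort)
    corr_truth = correlation_matrix(_truth_expected_table(cohort))
    fit = ols_fit(cohort["phh3_per_field"], cohort["mib1_per_field"])
    above, ct = classify_above_line(cohort, fit)
    cohort = cohort.assign(above_line=above)
    p = fisher_exact_2x2(ct)
    low = cohort["grade"].isin([1, 2])
    grade_tests = {}
    for v in MARKER_VARIABLES:
        try:
            grade_tests[v] = two_sample_t(cohort.loc[low, v], cohort.loc[~low, v])
        except InvalidParameterError:
            grade_tests[v] = (float("nan"), float("nan"))  # degenerate tiny cohort
    summary = grade_summary(cohort)

    logger.info("model comparison")
    model_cmp = compare_to_model(cohort)

    logger.info("imaging verification on %d tumors", config.n_render_tumors)
    imaging = _imaging_check(cohort, config)

    report = ExperimentReport(
        config=config, cohort=cohort,
        correlations_measured=corr_meas, correlations_truth=corr_truth,
        fit=fit, contingency=ct, fisher_p=p, grade_tests=grade_tests,
        summary=summary, model_comparison=model_cmp, imaging_check=imaging,
        seed=config.seed,
    )
    if out_dir is not None:
        write_report(report, out_dir)
    return report


def write_report(report: ExperimentReport, out_dir: str | Path) -> None:
    """Write CSV/JSON/PNG outputs for an experiment."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_cohort_csvs(report.cohort, out / "cohort_measured.csv", out / "cohort_truth.csv")
    report.cohort.to_csv(out / "cohort_full.csv", index=False)
    report.correlations_measured.to_csv(out / "correlations_measured.csv")
    report.correlations_truth.to_csv(out / "correlations_truth.csv")
    report.model_comparison.to_csv(out / "model_comparison.csv", index=False)
    report.imaging_check.to_csv(out / "imaging_check.csv", index=False)
    report.summary.to_csv(out / "grade_summary.csv")

    valid = report.model_comparison.loc[~report.model_comparison["flagged"]]
    rank_r = float(valid["predicted_ratio"].corr(valid["observed_ratio"], method="spearman"))
    payload = {
        "seed": report.seed,
        "regression": dataclasses.asdict(report.fit),
        "contingency": dataclasses.asdict(report.contingency),
        "fisher_p": report.fisher_p,
        "grade_t_tests": {k: {"t": t, "p": p} for k, (t, p) in report.grade_tests.items()},
        "model_rank_correlation": rank_r,
        "model_mean_abs_relative_error": float(valid["relative_error"].abs().mean()),
        "config": _config_echo(report.config),
    }
    (out / "report.json").write_text(json.dumps(payload, indent=1, default=str))

    if report.config.save_figures:
        figdir = out / "figures"
        figdir.mkdir(exist_ok=True)
        plots.scatter_matrix_plot(report.cohort, figdir / "scatter_matrix.png")
        plots.grade_scatter_plot(report.cohort, figdir / "mib1_vs_phh3.png", fit=report.fit)
        plots.grade_scatter_plot(report.cohort, figdir / "mitoses_vs_phh3.png",
                                 x_col="phh3_per_field", y_col="mitoses_per_10hpf")


def _config_echo(config: ExperimentConfig) -> dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj):
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, dict):
            return {str(k): enc(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [enc(v) for v in obj]
        return obj
    return enc(config)
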