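"""Synthetic grade-stratified tumor cohorts with explicit cell-cycle kinetics.

Each simulated tumor carries ground-truth kinetics: a proliferating fraction
``p_cycling``, phase durations (G1, S, G2, M) and a DNA index whose excess
over diploid lengthens S phase (aneuploid tumors replicate more DNA, and
reported S-phase lengthenings are on the order of 25-30%).  Mitosis duration
is drawn independently of ploidy.  Marker counts per microscope field are
Poisson around the phase-occupancy expectations of
:mod:`prolifmark.cell_cycle_model`, so the cohort reproduces the statistical
structure the downstream correlation analysis assumes: PhH3 and mitotic
counts proportional up to noise, MIB-1 decoupled from both through
between-tumor variation of interphase duration.

Grade defaults are calibrated so that cohort MIB-1 means per 10x field fall
near 181 / 324 / 907 for grades 1 / 2 / 3, with grade proportions near the
16% / 43% / 41% mix typical of consecutive breast-carcinoma accrual.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from prolifmark.cell_cycle_model import CellCycleDurations, expected_marker_fractions
from prolifmark.errors import InvalidParameterError

__all__ = [
    "GradeParams",
    "CohortConfig",
    "TumorSpec",
    "CellSnapshot",
    "sample_tumor_spec",
    "sample_cell_snapshot",
    "sample_cell_snapshots",
    "simulate_field_counts",
    "simulate_tumor_iod",
    "simulate_cohort",
    "write_cohort_csvs",
    "TRUTH_COLUMNS",
    "MEASURED_COLUMNS",
]

PHASES = ("G0", "G1", "S", "G2", "M")


@dataclass(frozen=True)
class GradeParams:
    """Per-grade distribution parameters for tumor-level draws.

    ``p_cycling`` is gamma-distributed (right-skewed, like the reported
    per-grade count spreads) and clipped to [0, 0.95]; the DNA-index excess
    over 1.0 is gamma-distributed, keeping dna_index >= 1.
    """

    p_cycling_mean: float
    p_cycling_sd: float
    dna_index_mean: float
    dna_index_sd: float


def _default_grade_params() -> dict[int, GradeParams]:
    return {
        1: GradeParams(0.065, 0.050, 1.05, 0.05),
        2: GradeParams(0.115, 0.100, 1.25, 0.15),
        3: GradeParams(0.320, 0.220, 1.60, 0.30),
    }


@dataclass(frozen=True)
class CohortConfig:
    """Free parameters of the cohort generator.

    Baseline phase durations are normal draws (hours, truncated positive);
    ``t_s`` is the baseline S-phase duration of a diploid tumor, lengthened by
    ``s_phase_ploidy_factor`` per unit of DNA-index excess.  Field geometry:
    marker counts are particles per 10x field; mitoses are counted over
    ``n_hpf`` high-power (40x) fields, each covering 1/``hpf_per_field`` of a
    10x field's area.
    """

    n_per_grade: tuple[int, int, int] = (16, 43, 41)
    grade_params: Mapping[int, GradeParams] = field(default_factory=_default_grade_params)

    t_g1_mean: float = 16.0
    t_g1_sd: float = 12.0
    t_s_base_mean: float = 10.0
    t_s_base_sd: float = 4.0
    t_g2_mean: float = 4.0
    t_g2_sd: float = 2.0
    t_m_mean: float = 1.0
    t_m_sd: float = 0.30

    s_phase_ploidy_factor: float = 0.30

    mib1_sensitivity: float = 0.95
    phh3_window_factor: float = 1.0     # x t_m; >1 reaches into late G2
    mitvis_window_factor: float = 0.8   # x t_m; manual counting misses early/late figures
    detection_prob_mitosis: float = 0.9

    nuclei_per_field_mean: float = 3000.0
    nuclei_per_field_sd: float = 450.0
    n_fields_range: tuple[int, int] = (4, 12)
    hpf_per_field: float = 16.0         # 40x HPF area = 1/16 of a 10x field (4x linear mag)
    n_hpf: int = 10

    iod_nuclei_per_tumor: int = 15
    iod_area_mean_px2: float = 700.0
    iod_area_sd_px2: float = 150.0
    iod_od_per_dna_per_px: float = 0.9
    iod_noise_cv: float = 0.08

    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.n_per_grade):
            raise InvalidParameterError("n_per_grade entries must be >= 0")
        for name in ("mib1_sensitivity", "detection_prob_mitosis"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidParameterError(f"{name} must lie in [0, 1], got {v!r}")
        lo, hi = self.n_fields_range
        if not (1 <= lo <= hi):
            raise InvalidParameterError("n_fields_range must satisfy 1 <= lo <= hi")


@dataclass(frozen=True)
class TumorSpec:
    """Ground-truth parameters of one simulated tumor."""

    tumor_id: str
    grade: int
    p_cycling: float
    durations: CellCycleDurations
    dna_index: float
    nuclei_per_field: float
    n_fields: int


@dataclass(frozen=True)
class CellSnapshot:
    """State of a single cell at the staining instant."""

    phase: str
    mib1_pos: bool
    phh3_pos: bool
    mitotically_visible: bool
    dna_content: float


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float, low: float,
                  size=None) -> np.ndarray | float:
    """Normal draw, resampled-by-clipping below ``low`` (sd == 0 passes through)."""
    if sd == 0:
        return np.full(size, mean) if size is not None else mean
    return np.maximum(rng.normal(mean, sd, size=size), low)


def _gamma_from_moments(rng: np.random.Generator, mean: float, sd: float,
                        size=None) -> np.ndarray | float:
    if mean <= 0 or sd == 0:
        return np.full(size, mean) if size is not None else mean
    shape = (mean / sd) ** 2
    scale = sd**2 / mean
    return rng.gamma(shape, scale, size=size)


def tumor_rng(config: CohortConfig, index: int) -> np.random.Generator:
    """Per-tumor generator keyed by (cohort seed, tumor index).

    Draws for one tumor are unaffected by how many other tumors exist or in
    what order they are simulated.
    """
    return np.random.default_rng(np.random.SeedSequence((config.seed, index)))


def sample_tumor_spec(grade: int, config: CohortConfig,
                      rng: np.random.Generator, tumor_id: str = "T0") -> TumorSpec:
    """Draw one tumor's ground-truth parameters for the given grade.

    S phase is lengthened multiplicatively by the DNA-index excess,
    ``t_s = t_s_base * (1 + factor * (dna_index - 1))``; mitosis duration is
    drawn independently of ploidy.
    """
    if grade not in (1, 2, 3):
        raise InvalidParameterError(f"grade must be 1, 2 or 3, got {grade!r}")
    gp = config.grade_params[grade]
    p = float(np.clip(_gamma_from_moments(rng, gp.p_cycling_mean, gp.p_cycling_sd), 0.0, 0.95))
    dna_index = 1.0 + float(
        _gamma_from_moments(rng, max(gp.dna_index_mean - 1.0, 0.0), gp.dna_index_sd)
    )
    # gamma draws: strictly positive, right-skewed like reported cycle-time spreads
    t_g1 = max(float(_gamma_from_moments(rng, config.t_g1_mean, config.t_g1_sd)), 0.5)
    t_s_base = max(float(_gamma_from_moments(rng, config.t_s_base_mean, config.t_s_base_sd)), 0.5)
    t_g2 = max(float(_gamma_from_moments(rng, config.t_g2_mean, config.t_g2_sd)), 0.2)
    t_m = max(float(_gamma_from_moments(rng, config.t_m_mean, config.t_m_sd)), 0.2)
    t_s = t_s_base * (1.0 + config.s_phase_ploidy_factor * (dna_index - 1.0))
    nuclei = float(_trunc_normal(rng, config.nuclei_per_field_mean,
                                 config.nuclei_per_field_sd, 50.0))
    lo, hi = config.n_fields_range
    n_fields = int(rng.integers(lo, hi + 1))
    return TumorSpec(
        tumor_id=tumor_id,
        grade=grade,
        p_cycling=p,
        durations=CellCycleDurations(t_g1=t_g1, t_s=t_s, t_g2=t_g2, t_m=t_m),
        dna_index=dna_index,
        nuclei_per_field=nuclei,
        n_fields=n_fields,
    )


def _windows(spec: TumorSpec, config: CohortConfig) -> tuple[float, float]:
    d = spec.durations
    phh3_w = min(config.phh3_window_factor * d.t_m, d.t_c)
    mitvis_w = min(config.mitvis_window_factor * d.t_m, d.t_m)
    return phh3_w, mitvis_w


def sample_cell_snapshots(spec: TumorSpec, config: CohortConfig,
                          n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Vectorised snapshot draws; one row per cell.

    A cell is cycling with probability ``p_cycling``; a cycling cell's
    position is uniform over [0, t_c) (asynchronous steady state), which makes
    phase occupancy proportional to phase duration.  The PhH3 window ends at
    cytokinesis and extends ``phh3_window`` hours back (into late G2 when
    longer than t_m); the mitotic-visibility window sits centered within M.
    DNA content ramps linearly from dna_index to 2*dna_index across S phase.
    """
    d = spec.durations
    phh3_w, mitvis_w = _windows(spec, config)
    cycling = rng.random(n) < spec.p_cycling
    pos = rng.random(n) * d.t_c

    b_g1 = d.t_g1
    b_s = d.t_g1 + d.t_s
    b_g2 = d.t_i
    phase_idx = np.zeros(n, dtype=np.int8)  # 0=G0
    phase_idx[cycling] = 1
    phase_idx[cycling & (pos >= b_g1)] = 2
    phase_idx[cycling & (pos >= b_s)] = 3
    phase_idx[cycling & (pos >= b_g2)] = 4

    mib1 = cycling & (rng.random(n) < config.mib1_sensitivity)
    phh3 = cycling & (pos >= d.t_c - phh3_w)
    mit_start = d.t_i + (d.t_m - mitvis_w) / 2.0
    in_mit_window = cycling & (pos >= mit_start) & (pos < mit_start + mitvis_w)
    mitvis = in_mit_window & (rng.random(n) < config.detection_prob_mitosis)

    frac_s = np.clip((pos - b_g1) / d.t_s, 0.0, 1.0) if d.t_s > 0 else np.zeros(n)
    ramp = np.ones(n)
    ramp[cycling & (phase_idx == 2)] = 1.0 + frac_s[cycling & (phase_idx == 2)]
    ramp[phase_idx >= 3] = 2.0
    dna = spec.dna_index * ramp

    return pd.DataFrame({
        "phase": np.array(PHASES)[phase_idx],
        "mib1_pos": mib1,
        "phh3_pos": phh3,
        "mitotically_visible": mitvis,
        "dna_content": dna,
    })


def sample_cell_snapshot(spec: TumorSpec, config: CohortConfig,
                         rng: np.random.Generator) -> CellSnapshot:
    """Draw a single cell's staining-instant state."""
    row = sample_cell_snapshots(spec, config, 1, rng).iloc[0]
    return CellSnapshot(
        phase=str(row["phase"]),
        mib1_pos=bool(row["mib1_pos"]),
        phh3_pos=bool(row["phh3_pos"]),
        mitotically_visible=bool(row["mitotically_visible"]),
        dna_content=float(row["dna_content"]),
    )


def simulate_field_counts(spec: TumorSpec, config: CohortConfig,
                          rng: np.random.Generator) -> dict:
    """Poisson per-field marker counts for one tumor.

    Returns arrays ``mib1_per_10x_field`` and ``phh3_per_10x_field`` of
    length ``n_fields`` and a scalar ``mitoses_per_10hpf``.  Expected counts
    are nuclei-per-field times the phase-occupancy marker fractions; a 40x
    HPF covers 1/``hpf_per_field`` of a 10x field, so the expected mitotic
    count over ``n_hpf`` HPF is scaled by ``n_hpf / hpf_per_field``.
    """
    d = spec.durations
    phh3_w, mitvis_w = _windows(spec, config)
    fr = expected_marker_fractions(
        d, spec.p_cycling,
        mib1_sensitivity=config.mib1_sensitivity,
        phh3_window=phh3_w,
        mitvis_window=mitvis_w,
    )
    lam_mib1 = spec.nuclei_per_field * fr.f_mib1
    lam_phh3 = spec.nuclei_per_field * fr.f_phh3
    lam_mit_10hpf = (spec.nuclei_per_field * fr.f_mitotic
                     * config.detection_prob_mitosis
                     * config.n_hpf / config.hpf_per_field)
    return {
        "mib1_per_10x_field": rng.poisson(lam_mib1, size=spec.n_fields),
        "phh3_per_10x_field": rng.poisson(lam_phh3, size=spec.n_fields),
        "mitoses_per_10hpf": int(rng.poisson(lam_mit_10hpf)),
    }


def simulate_tumor_iod(spec: TumorSpec, config: CohortConfig,
                       rng: np.random.Generator) -> float:
    """Mean integrated optical density over sampled nuclei (fast path).

    Emulates the measurement made on rendered H&E nuclei without rasterising:
    IOD = (OD per unit DNA per pixel) x dna_content x nuclear area, with
    multiplicative measurement noise.  The rendering-based route through
    :mod:`prolifmark.iod_measurement` computes the same quantity from pixels.
    """
    n = config.iod_nuclei_per_tumor
    snaps = sample_cell_snapshots(spec, config, n, rng)
    areas = _trunc_normal(rng, config.iod_area_mean_px2, config.iod_area_sd_px2, 50.0, size=n)
    noise = 1.0 + rng.normal(0.0, config.iod_noise_cv, size=n)
    iods = config.iod_od_per_dna_per_px * snaps["dna_content"].to_numpy() * areas * noise
    return float(np.mean(np.maximum(iods, 0.0)))


TRUTH_COLUMNS = ["tumor_id", "grade", "p_cycling", "t_g1", "t_s", "t_g2",
                 "t_m", "t_i", "t_c", "dna_index", "nuclei_per_field", "n_fields"]
MEASURED_COLUMNS = ["tumor_id", "grade", "mib1_per_field", "phh3_per_field",
                    "mitoses_per_10hpf", "iod"]


def simulate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Simulate a full cohort; one row per tumor.

    The returned frame carries both the measured columns (per-field counts
    averaged, mitoses per 10 HPF, mean nuclear IOD) and the ground-truth
    kinetic columns.  Reproducible: the same config (including seed) yields
    the same table.
    """
    rows = []
    index = 0
    for grade, n in zip((1, 2, 3), config.n_per_grade):
        for _ in range(n):
            rng = tumor_rng(config, index)
            tumor_id = f"T{index:03d}"
            spec = sample_tumor_spec(grade, config, rng, tumor_id=tumor_id)
            counts = simulate_field_counts(spec, config, rng)
            iod = simulate_tumor_iod(spec, config, rng)
            d = spec.durations
            rows.append({
                "tumor_id": tumor_id,
                "grade": grade,
                "mib1_per_field": float(np.mean(counts["mib1_per_10x_field"])),
                "phh3_per_field": float(np.mean(counts["phh3_per_10x_field"])),
                "mitoses_per_10hpf": counts["mitoses_per_10hpf"],
                "iod": iod,
                "p_cycling": spec.p_cycling,
                "t_g1": d.t_g1, "t_s": d.t_s, "t_g2": d.t_g2, "t_m": d.t_m,
                "t_i": d.t_i, "t_c": d.t_c,
                "dna_index": spec.dna_index,
                "nuclei_per_field": spec.nuclei_per_field,
                "n_fields": spec.n_fields,
            })
            index += 1
    columns = MEASURED_COLUMNS + [c for c in TRUTH_COLUMNS if c not in MEASURED_COLUMNS]
    return pd.DataFrame(rows, columns=columns)


def write_cohort_csvs(table: pd.DataFrame, measured_path, truth_path) -> None:
    """Write the measured and ground-truth views of a cohort to two CSVs."""
    table[MEASURED_COLUMNS].to_csv(measured_path, index=False)
    table[TRUTH_COLUMNS].to_csv(truth_path, index=False)
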