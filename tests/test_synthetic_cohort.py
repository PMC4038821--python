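"""Cohort generator: tumor draws, snapshot occupancy, field counts, tables."""

import numpy as np
import pandas as pd
import pytest

from prolifmark.cell_cycle_model import CellCycleDurations
from prolifmark.errors import InvalidParameterError
from prolifmark.synthetic_cohort import (
    CohortConfig,
    GradeParams,
    TumorSpec,
    sample_cell_snapshot,
    sample_cell_snapshots,
    sample_tumor_spec,
    simulate_cohort,
    simulate_field_counts,
    simulate_tumor_iod,
)


def make_spec(t_m=1.0, t_i=23.0, p=0.5, dna_index=1.0, nuclei=3000.0, n_fields=8):
    return TumorSpec(
        tumor_id="T0", grade=2, p_cycling=p,
        durations=CellCycleDurations.from_interphase(t_m, t_i),
        dna_index=dna_index, nuclei_per_field=nuclei, n_fields=n_fields,
    )


class TestTumorSpecSampling:
    def test_invalid_grade_rejected(self, rng):
        with pytest.raises(InvalidParameterError):
            sample_tumor_spec(4, CohortConfig(), rng)

    def test_ploidy_lengthens_s_phase_deterministically(self, rng):
        # dna_index 2 with factor 0.30 and base 10 h -> t_s = 13 h
        cfg = CohortConfig(
            grade_params={g: GradeParams(0.2, 0.0, 2.0, 0.0) for g in (1, 2, 3)},
            t_s_base_mean=10.0, t_s_base_sd=0.0,
        )
        spec = sample_tumor_spec(2, cfg, rng)
        assert spec.dna_index == 2.0
        assert spec.durations.t_s == pytest.approx(13.0)

    def test_zero_factor_and_sds_give_identical_durations_across_grades(self, rng):
        cfg = CohortConfig(
            grade_params={g: GradeParams(0.2, 0.0, 1.0 + 0.3 * g, 0.0) for g in (1, 2, 3)},
            s_phase_ploidy_factor=0.0,
            t_g1_sd=0.0, t_s_base_sd=0.0, t_g2_sd=0.0, t_m_sd=0.0,
        )
        specs = [sample_tumor_spec(g, cfg, np.random.default_rng(0)) for g in (1, 2, 3)]
        durations = {(s.durations.t_g1, s.durations.t_s, s.durations.t_g2, s.durations.t_m)
                     for s in specs}
        assert len(durations) == 1

    def test_grade3_cycles_more_than_grade1_on_average(self):
        cfg = CohortConfig(seed=5)
        draws = {g: [sample_tumor_spec(g, cfg, np.random.default_rng(1000 + i)).p_cycling
                     for i in range(1000)] for g in (1, 3)}
        assert np.mean(draws[3]) > np.mean(draws[1])

    def test_mitosis_duration_independent_of_ploidy(self):
        # correlation between t_m and dna_index across many draws ~ 0
        cfg = CohortConfig()
        specs = [sample_tumor_spec(3, cfg, np.random.default_rng(i)) for i in range(800)]
        t_m = np.array([s.durations.t_m for s in specs])
        di = np.array([s.dna_index for s in specs])
        assert abs(np.corrcoef(t_m, di)[0, 1]) < 0.1


class TestCellSnapshots:
    def test_quiescent_tumor_all_negative(self, rng):
        spec = make_spec(p=0.0)
        snaps = sample_cell_snapshots(spec, CohortConfig(), 500, rng)
        assert (snaps["phase"] == "G0").all()
        assert not snaps[["mib1_pos", "phh3_pos", "mitotically_visible"]].any().any()

    def test_g2_cell_dna_content_is_twice_dna_index(self, rng):
        spec = TumorSpec("T0", 2, 1.0,
                         CellCycleDurations(t_g1=10, t_s=8, t_g2=4, t_m=1), 1.5, 3000, 8)
        snaps = sample_cell_snapshots(spec, CohortConfig(), 2000, rng)
        g2 = snaps[snaps["phase"].isin(["G2", "M"])]
        assert len(g2) > 0
        assert np.allclose(g2["dna_content"], 3.0)

    def test_dna_content_bounded_by_ploidy(self, rng):
        spec = TumorSpec("T0", 3, 0.8,
                         CellCycleDurations(t_g1=10, t_s=8, t_g2=4, t_m=1), 1.3, 3000, 8)
        snaps = sample_cell_snapshots(spec, CohortConfig(), 5000, rng)
        assert (snaps["dna_content"] >= 1.3 - 1e-9).all()
        assert (snaps["dna_content"] <= 2.6 + 1e-9).all()

    def test_phh3_implies_late_cycle_and_mib1_implies_cycling(self, rng):
        spec = make_spec(p=0.7)
        cfg = CohortConfig(mib1_sensitivity=1.0)
        snaps = sample_cell_snapshots(spec, cfg, 20000, rng)
        assert snaps.loc[snaps["phh3_pos"], "phase"].isin(["G2", "M"]).all()
        assert (snaps.loc[snaps["mib1_pos"], "phase"] != "G0").all()

    def test_conditional_phh3_fraction_converges_to_occupancy_ratio(self):
        # fraction(phh3 | mib1) -> t_m/(t_m + t_i) = 1/24 at perfect sensitivity
        spec = make_spec(t_m=1.0, t_i=23.0, p=0.5)
        cfg = CohortConfig(mib1_sensitivity=1.0, phh3_window_factor=1.0)
        snaps = sample_cell_snapshots(spec, cfg, 10**6, np.random.default_rng(11))
        n_mib1 = int(snaps["mib1_pos"].sum())
        frac = snaps["phh3_pos"].sum() / n_mib1
        p_true = 1 / 24
        se = np.sqrt(p_true * (1 - p_true) / n_mib1)
        assert abs(frac - p_true) < 3 * se

    def test_scalar_snapshot_wrapper(self, rng):
        snap = sample_cell_snapshot(make_spec(p=0.0), CohortConfig(), rng)
        assert snap.phase == "G0" and not snap.mib1_pos


class TestFieldCounts:
    def test_zero_marker_fraction_gives_zero_counts(self, rng):
        counts = simulate_field_counts(make_spec(p=0.0), CohortConfig(), rng)
        assert not counts["mib1_per_10x_field"].any()
        assert not counts["phh3_per_10x_field"].any()
        assert counts["mitoses_per_10hpf"] == 0

    def test_poisson_mean_recovers_expectation(self):
        # expected MIB-1/field = nuclei * p * sensitivity = 500
        spec = make_spec(p=0.5, nuclei=1000.0, n_fields=10000)
        cfg = CohortConfig(mib1_sensitivity=1.0)
        counts = simulate_field_counts(spec, cfg, np.random.default_rng(3))
        mean = counts["mib1_per_10x_field"].mean()
        se = np.sqrt(500 / 10000)
        assert abs(mean - 500) < 3 * se

    def test_hpf_area_scaling_of_mitotic_counts(self):
        # E[mitoses/10 HPF] = E[mitotic per 10x field] * n_hpf / hpf_per_field
        spec = make_spec(t_m=1.0, t_i=23.0, p=0.5, nuclei=4000.0)
        cfg = CohortConfig(mitvis_window_factor=0.8, detection_prob_mitosis=0.9)
        lam_field = 4000 * 0.5 * (0.8 / 24) * 0.9
        lam_expected = lam_field * 10 / 16
        draws = [simulate_field_counts(spec, cfg, np.random.default_rng(i))["mitoses_per_10hpf"]
                 for i in range(3000)]
        se = np.sqrt(lam_expected / 3000)
        assert np.mean(draws) == pytest.approx(lam_expected, abs=3 * se)


class TestCohortTable:
    def test_empty_cohort(self):
        table = simulate_cohort(CohortConfig(n_per_grade=(0, 0, 0)))
        assert table.empty

    def test_same_seed_reproduces_table(self):
        cfg = CohortConfig(n_per_grade=(3, 3, 3), seed=9)
        pd.testing.assert_frame_equal(simulate_cohort(cfg), simulate_cohort(cfg))

    def test_tumor_draws_stable_under_cohort_extension(self):
        # per-tumor RNG streams keyed by index: tumor 0 identical in both
        small = simulate_cohort(CohortConfig(n_per_grade=(2, 0, 0), seed=4))
        large = simulate_cohort(CohortConfig(n_per_grade=(2, 5, 5), seed=4))
        pd.testing.assert_series_equal(small.iloc[0], large.iloc[0])

    def test_grade3_mib1_exceeds_grade1(self):
        table = simulate_cohort(CohortConfig(seed=2))
        means = table.groupby("grade")["mib1_per_field"].mean()
        assert means[3] > means[1]

    def test_mib1_means_near_calibration_targets(self):
        # grade means should approximate 181 / 324 / 907 per 10x field
        tables = [simulate_cohort(CohortConfig(seed=s)) for s in range(40, 50)]
        means = pd.concat(tables).groupby("grade")["mib1_per_field"].mean()
        for grade, target in ((1, 181.1), (2, 324.1), (3, 906.6)):
            assert means[grade] == pytest.approx(target, rel=0.35)

    def test_iod_fast_path_monotone_in_dna_index(self):
        # rank correlation of per-tumor IOD vs dna_index > 0.9
        cfg = CohortConfig()
        dna = np.linspace(1.0, 2.2, 30)
        iods = []
        for i, di in enumerate(dna):
            spec = TumorSpec(f"T{i}", 2, 0.2,
                             CellCycleDurations(16, 10, 4, 1), float(di), 3000, 8)
            iods.append(simulate_tumor_iod(spec, cfg, np.random.default_rng(i)))
        rho = pd.Series(iods).corr(pd.Series(dna), method="spearman")
        assert rho > 0.9
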