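import numpy as np
import pytest

from oligoscreen.chromatograms import RetentionWindow, integrate_peak
from oligoscreen.errors import ConfigurationError, GenerationError
from oligoscreen.panels import DETECTION_WINDOW_MIN, TransitionKey
from oligoscreen.quantify import adjust_creatinine, compute_ratio_profile
from oligoscreen.reference import build_reference, compute_mom
from oligoscreen.screen import screen_sample
from oligoscreen.synthetic_data import (SIGNATURES, SimulationConfig,
                                        control_baseline, gen_chromatogram,
                                        gen_control_cohort, gen_patient,
                                        gen_qc_mix)

SIAL_KEY = TransitionKey(1200.4, 1099.4, "negative")


def pipeline_mom(registry, config, patient, cohort=None, matrix="urine"):
    cohort = cohort or gen_control_cohort(config, matrix, 11, registry)
    profs = [adjust_creatinine(compute_ratio_profile(t, registry), m)
             for m, t in cohort]
    ref = build_reference(profs, matrix)
    meta, areas = patient
    prof = adjust_creatinine(compute_ratio_profile(areas, registry), meta)
    return compute_mom(prof, ref)


class TestControlCohort:
    def test_seed_determinism(self, registry):
        config = SimulationConfig(seed=42)
        a = gen_control_cohort(config, "urine", 5, registry)
        b = gen_control_cohort(config, "urine", 5, registry)
        for (ma, ta), (mb, tb) in zip(a, b):
            assert ma == mb
            assert ta.entries == tb.entries

    def test_different_seeds_differ(self, registry):
        a = gen_control_cohort(SimulationConfig(seed=1), "urine", 1, registry)
        b = gen_control_cohort(SimulationConfig(seed=2), "urine", 1, registry)
        assert a[0][1].entries != b[0][1].entries

    def test_zero_dispersion_ratios_equal_baselines(self, registry):
        config = SimulationConfig(seed=0, cv=0.0)
        cohort = gen_control_cohort(config, "urine", 10, registry)
        profs = [adjust_creatinine(compute_ratio_profile(t, registry), m)
                 for m, t in cohort]
        ref = build_reference(profs, "urine")
        for key, med in ref.medians.items():
            assert med == pytest.approx(
                control_baseline(config, key, "urine"), rel=1e-9)

    def test_dus_baselines_below_urine(self, registry):
        config = SimulationConfig()
        for t in registry.analyte_transitions():
            assert (control_baseline(config, t.key, "dus")
                    <= control_baseline(config, t.key, "urine"))

    def test_unknown_matrix_rejected(self, registry):
        with pytest.raises(ConfigurationError):
            gen_control_cohort(SimulationConfig(), "plasma", 5, registry)

    def test_generated_samples_satisfy_invariants(self, registry):
        for seed in range(10):
            cohort = gen_control_cohort(SimulationConfig(seed=seed), "dus", 3, registry)
            for meta, areas in cohort:
                assert meta.creatinine_mM > 0
                assert meta.dilution_applied == (meta.creatinine_mM >= 1.0)
                assert all(a is None or a >= 0 for a in areas.entries.values())


class TestPatients:
    def test_explicit_fold_recovered_exactly_at_zero_dispersion(self, registry):
        config = SimulationConfig(seed=0, cv=0.0)
        patient = gen_patient(config, "sialidosis", "urine", fold_spec=102.0,
                              registry=registry, creatinine_mM=1.0)
        mom = pipeline_mom(registry, config, patient)
        assert mom.moms[SIAL_KEY] == pytest.approx(102.0, rel=1e-12)

    def test_sub_1mM_creatinine_path_recovers_fold(self, registry):
        config = SimulationConfig(seed=0, cv=0.0)
        patient = gen_patient(config, "danon", "urine", fold_spec=45.0,
                              registry=registry, creatinine_mM=0.5)
        mom = pipeline_mom(registry, config, patient)
        glc4 = registry.panel("GLC4").most_characteristic.key
        assert mom.moms[glc4] == pytest.approx(45.0, rel=1e-9)

    def test_range_draw_stays_inside_signature(self, registry):
        config = SimulationConfig(seed=7, cv=0.0)
        lo, hi = SIGNATURES["gm1_gangliosidosis"].folds["urine"]["GM1"]
        patient = gen_patient(config, "gm1_gangliosidosis", "urine", registry=registry,
                              creatinine_mM=1.0)
        mom = pipeline_mom(registry, config, patient)
        gm1 = registry.panel("GM1").most_characteristic.key
        assert lo <= mom.moms[gm1] <= hi

    def test_tay_sachs_always_screens_negative(self, registry):
        config = SimulationConfig(seed=5)
        for matrix in ("urine", "dus"):
            patient = gen_patient(config, "gm2_tay_sachs", matrix, registry=registry)
            mom = pipeline_mom(registry, config, patient,
                               cohort=gen_control_cohort(config, matrix, 11, registry),
                               matrix=matrix)
            rep = screen_sample(mom, registry)
            assert rep.interpretation == "negative", matrix

    def test_unknown_disorder_lists_known_signatures(self, registry):
        with pytest.raises(GenerationError, match="sialidosis"):
            gen_patient(SimulationConfig(), "unknownitis", "urine", registry=registry)

    def test_unreported_matrix_rejected(self, registry):
        with pytest.raises(GenerationError, match="yunis_varon"):
            gen_patient(SimulationConfig(), "yunis_varon", "urine", registry=registry)

    def test_signature_table_covers_all_screened_disorders(self):
        expected = {"sialidosis", "alpha_mannosidosis", "beta_mannosidosis",
                    "fucosidosis", "aspartylglucosaminuria", "gm1_gangliosidosis",
                    "gm2_sandhoff", "gm2_tay_sachs", "pompe", "vici_severe",
                    "yunis_varon", "danon", "mucolipidosis_ii", "mucolipidosis_iii",
                    "mps_ivb"}
        assert set(SIGNATURES) == expected
        assert SIGNATURES["gm2_tay_sachs"].folds == {"urine": {}, "dus": {}}
        lo, hi = SIGNATURES["mps_ivb"].folds["dus"]["GLC4"]
        assert 1.0 <= lo and hi <= 2.0  # sub-threshold by construction


class TestQCMix:
    def test_empty_mix_is_control_like(self, registry):
        config = SimulationConfig(seed=0, cv=0.0)
        _, areas = gen_qc_mix(config, "urine", constituents=(), registry=registry)
        for t in registry.analyte_transitions():
            expected = config.is_total_area * control_baseline(config, t.key, "urine")
            assert areas.entries[t.key] == pytest.approx(expected, rel=1e-9)

    def test_seed_determinism(self, registry):
        a = gen_qc_mix(SimulationConfig(seed=9), registry=registry)
        b = gen_qc_mix(SimulationConfig(seed=9), registry=registry)
        assert a[1].entries == b[1].entries


class TestChromatogramSynthesis:
    def test_round_trip_recovers_area_within_one_percent(self, registry):
        config = SimulationConfig(seed=0, cv=0.0)
        _, areas = gen_patient(config, "sialidosis", "urine", fold_spec=102.0,
                               registry=registry, creatinine_mM=1.0)
        traces = gen_chromatogram(areas, config, registry)
        defs = {t.key: t for t in registry.all_transitions()}
        checked = 0
        for tr in traces:
            tdef = defs[tr.key]
            window = RetentionWindow(tdef.expected_rt_min, tdef.rt_window_min)
            got, _ = integrate_peak(tr, window)
            want = areas.entries[tr.key]
            if want > 1e-9:
                assert got == pytest.approx(want, rel=0.01)
                checked += 1
        assert checked > 50

    def test_zero_area_yields_flat_trace(self, registry):
        config = SimulationConfig(seed=0, cv=0.0)
        key = SIAL_KEY
        from oligoscreen.quantify import PeakAreaTable
        areas = PeakAreaTable(sample_id="s", entries={key: 0.0})
        (tr,) = gen_chromatogram(areas, config, registry)
        assert np.allclose(tr.intensities, config.chrom_baseline)

    def test_all_peaks_inside_detection_window(self, registry):
        config = SimulationConfig(seed=0)
        _, areas = gen_qc_mix(config, registry=registry)
        for tr in gen_chromatogram(areas, config, registry):
            assert tr.times[0] >= 0
            assert tr.times[-1] <= DETECTION_WINDOW_MIN

    def test_missing_window_raises(self, registry):
        from oligoscreen.quantify import PeakAreaTable
        areas = PeakAreaTable(sample_id="s",
                              entries={TransitionKey(500.0, 100.0, "positive"): 5.0})
        with pytest.raises(GenerationError, match="window"):
            gen_chromatogram(areas, SimulationConfig(), registry)

    def test_full_chromatogram_pipeline_recovers_fold(self, registry):
        config = SimulationConfig(seed=0, cv=0.0)
        from oligoscreen.workflow import integrate_sample
        cohort = gen_control_cohort(config, "urine", 10, registry)
        integrated = []
        for meta, areas in cohort:
            table = integrate_sample(gen_chromatogram(areas, config, registry), registry)
            integrated.append((meta, table))
        meta, areas = gen_patient(config, "sialidosis", "urine", fold_spec=102.0,
                                  registry=registry, creatinine_mM=1.0)
        ptable = integrate_sample(gen_chromatogram(areas, config, registry), registry)
        mom = pipeline_mom(registry, config, (meta, ptable), cohort=integrated)
        assert mom.moms[SIAL_KEY] == pytest.approx(102.0, rel=0.01)
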