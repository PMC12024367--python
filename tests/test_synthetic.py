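"""Synthetic cohort generator: defaults, determinism, class contrasts."""

import dataclasses

import numpy as np
import pytest

import spectrafuse as sf
from spectrafuse.data_model import WavenumberGrid, read_cohort
from spectrafuse.synthetic import (
    BandSpec,
    CohortConfig,
    default_config,
    generate_cohort,
    write_cohort,
)

AMIDE_I = 1650.0


def _amide_i_band(config):
    (band,) = [b for b in config.bands if b.center == AMIDE_I]
    return band


class TestDefaults:
    def test_cohort_composition_matches_study_conditions(self):
        cfg = default_config()
        assert cfg.n_positive_subjects == 36
        assert cfg.n_other_subjects == 24
        assert cfg.n_healthy_subjects == 24
        assert cfg.replicates_per_sample == 5

    def test_panel_has_36_indicators_with_stated_effect_structure(self):
        cfg = default_config()
        assert len(cfg.indicators) == 36
        by_name = {i.name: i for i in cfg.indicators}
        for big in ("albumin_g_l", "total_protein_g_l", "ldh_u_l"):
            assert abs(by_name[big].class_shift) >= 1.5
        for small in ("potassium_mmol_l", "uric_acid_umol_l"):
            assert abs(by_name[small].class_shift) <= 0.2

    def test_default_grid_has_1801_points(self):
        assert default_config().grid.n_points == 1801

    def test_band_set_covers_named_regions(self):
        centers = [b.center for b in default_config().bands]
        for region in (1650, 1540, 1050):
            assert any(abs(c - region) < 30 for c in centers)
        assert any(2850 <= c <= 2980 for c in centers)  # CH stretch

    def test_water_band_only_when_requested(self):
        dry = default_config()
        wet = default_config(water_band=True)
        assert len(wet.bands) == len(dry.bands) + 1
        assert max(b.width for b in wet.bands) >= 150


class TestGeneration:
    def test_same_seed_gives_bit_identical_cohorts(self, small_config):
        a = generate_cohort(small_config)
        b = generate_cohort(small_config)
        Xa_f, Xa_c, ya = a.features()
        Xb_f, Xb_c, yb = b.features()
        assert np.array_equal(Xa_f, Xb_f)
        assert np.array_equal(Xa_c, Xb_c)
        assert np.array_equal(ya, yb)
        assert [s.sample_id for s in a.samples] == [s.sample_id for s in b.samples]

    def test_default_cohort_shapes(self):
        cohort = generate_cohort(default_config(seed=2))
        assert len(cohort.subject_ids()) == 84  # 36 + 24 + 24
        s = cohort.samples[0]
        assert s.spectrum.absorbance.shape == (1801,)
        assert s.panel.values.shape == (36,)

    def test_noise_free_positive_spectra_identical_with_scaled_amide_i(self):
        cfg = dataclasses.replace(
            default_config(seed=9), noise_sd=0.0, subject_sd=0.0,
            baseline_drift=0.0, n_positive_subjects=3, n_other_subjects=1,
            n_healthy_subjects=1, samples_per_subject=(2, 2),
        )
        cohort = generate_cohort(cfg)
        pos = [s.spectrum.absorbance for s in cohort.samples if s.label == 1]
        for v in pos[1:]:
            assert np.array_equal(v, pos[0])
        band = _amide_i_band(cfg)
        idx = int((AMIDE_I - cfg.grid.start) / cfg.grid.step)
        # neighbouring band tails contribute < 1e-3 at the amide I centre
        assert pos[0][idx] == pytest.approx(band.amplitude * band.class_effect,
                                            abs=1e-3)

    def test_all_generated_values_finite(self, small_cohort):
        X_f, X_c, _ = small_cohort.features()
        assert np.all(np.isfinite(X_f)) and np.all(np.isfinite(X_c))

    def test_amide_i_class_contrast_matches_configured_factor(self):
        # Monte-Carlo: >= 200 samples per class on a narrowed grid, default
        # band set and noise levels
        cfg = dataclasses.replace(
            default_config(seed=31),
            grid=WavenumberGrid(1400.0, 1900.0, 2.0),
            n_positive_subjects=120, n_other_subjects=60,
            n_healthy_subjects=60, samples_per_subject=(2, 2),
        )
        cohort = generate_cohort(cfg)
        band = _amide_i_band(cfg)
        idx = int((AMIDE_I - cfg.grid.start) / cfg.grid.step)
        X_f, _, y = cohort.features()
        peak = X_f[:, idx]
        pos, neg = peak[y == 1], peak[y == 0]
        assert len(pos) >= 200 and len(neg) >= 200
        ratio = pos.mean() / neg.mean()
        se = ratio * np.sqrt(
            pos.std(ddof=1) ** 2 / (len(pos) * pos.mean() ** 2)
            + neg.std(ddof=1) ** 2 / (len(neg) * neg.mean() ** 2)
        )
        assert abs(ratio - band.class_effect) < 3 * se

    def test_indicator_effect_sizes_large_for_ldh_small_for_potassium(self):
        cfg = dataclasses.replace(
            default_config(seed=17),
            grid=WavenumberGrid(1000.0, 1008.0, 4.0),  # spectra irrelevant here
            bands=[BandSpec(center=1004.0, width=4.0, amplitude=0.1)],
            n_positive_subjects=250, n_other_subjects=1,
            n_healthy_subjects=250, samples_per_subject=(2, 2),
        )
        cohort = generate_cohort(cfg)
        _, X_c, y = cohort.features()
        names = [i.name for i in cfg.indicators]
        assert (y == 1).sum() >= 500 and (y == 0).sum() >= 500

        def smd(col):
            a, b = X_c[y == 1, col], X_c[y == 0, col]
            pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2)
            return abs(a.mean() - b.mean()) / pooled

        assert smd(names.index("ldh_u_l")) >= 1.0
        assert smd(names.index("potassium_mmol_l")) <= 0.4


class TestWriteCohort:
    def test_write_then_read_round_trips_the_cohort(self, small_cohort, tmp_path):
        write_cohort(small_cohort, tmp_path)
        back = read_cohort(tmp_path)
        Xa_f, Xa_c, ya = small_cohort.features()
        Xb_f, Xb_c, yb = back.features()
        assert np.array_equal(ya, yb)
        assert np.array_equal(Xa_f, Xb_f)
        assert np.array_equal(Xa_c, Xb_c)
        assert back.subject_groups() == small_cohort.subject_groups()

    def test_replicate_column_present_iff_replicates_retained(
        self, small_config, tmp_path
    ):
        with_reps = generate_cohort(
            dataclasses.replace(small_config, keep_replicates=True)
        )
        write_cohort(with_reps, tmp_path / "reps")
        header = (tmp_path / "reps" / "spectra.csv").read_text().splitlines()[0]
        assert "replicate" in header

        without = generate_cohort(small_config)
        write_cohort(without, tmp_path / "avg")
        header = (tmp_path / "avg" / "spectra.csv").read_text().splitlines()[0]
        assert "replicate" not in header

    def test_manifest_written_with_class_column(self, small_cohort, tmp_path):
        paths = write_cohort(small_cohort, tmp_path)
        header = paths["manifest"].read_text().splitlines()[0]
        assert header == "subject_id,class"

    def test_averaged_replicates_match_sample_spectra(self, small_config):
        cohort = generate_cohort(
            dataclasses.replace(small_config, keep_replicates=True)
        )
        from spectrafuse.data_model import average_replicates

        averaged = {r.sample_id: r.absorbance
                    for r in average_replicates(cohort.replicates)}
        for s in cohort.samples:
            assert np.allclose(averaged[s.sample_id], s.spectrum.absorbance,
                               rtol=0, atol=1e-12)
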