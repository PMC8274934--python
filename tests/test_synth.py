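"""Tests for the seeded synthetic-data generators."""

import numpy as np
import pytest

from fisbkit.binding import langmuir_fraction_bound, read_titration_csv
from fisbkit.exceptions import ConfigurationError
from fisbkit.quantify import read_bleach_csv, read_calibration_csv, read_spots_csv
from fisbkit.synth import (
    SimulationSpec,
    gen_bleach_traces,
    gen_brownian_tracks,
    gen_calibration_and_spots,
    gen_titration,
    stage_rng,
)
from fisbkit.tracking import read_tracks_csv, write_tracks_csv


class TestSpecValidation:
    def test_seed_mandatory(self):
        with pytest.raises(TypeError):
            SimulationSpec()

    def test_physical_parameters_validated(self):
        with pytest.raises(ConfigurationError):
            SimulationSpec(seed=1, diffusivity=-1.0)
        with pytest.raises(ConfigurationError):
            SimulationSpec(seed=1, labeling_p=1.5)
        with pytest.raises(ConfigurationError):
            SimulationSpec(seed=1, conc_min=1e-4, conc_max=1e-8)


class TestDeterminism:
    def test_same_seed_reproduces_all_stages(self):
        a, b = SimulationSpec(seed=42), SimulationSpec(seed=42)
        ta, tb = gen_brownian_tracks(a), gen_brownian_tracks(b)
        assert all(
            np.array_equal(x.x, y.x) and np.array_equal(x.y, y.y)
            for x, y in zip(ta, tb)
        )
        assert np.array_equal(
            gen_titration(a).fraction_bound, gen_titration(b).fraction_bound
        )
        assert np.array_equal(
            gen_bleach_traces(a).step_counts, gen_bleach_traces(b).step_counts
        )

    def test_different_seeds_differ(self):
        a = gen_brownian_tracks(SimulationSpec(seed=1, n_tracks=1, n_frames=10))
        b = gen_brownian_tracks(SimulationSpec(seed=2, n_tracks=1, n_frames=10))
        assert not np.array_equal(a[0].x, b[0].x)

    def test_stage_streams_are_decoupled(self):
        # the titration draw must not depend on whether tracks were drawn
        s = SimulationSpec(seed=5)
        t1 = gen_titration(s).fraction_bound
        gen_brownian_tracks(s)
        t2 = gen_titration(s).fraction_bound
        assert np.array_equal(t1, t2)
        assert stage_rng(5, "tracks").integers(0, 1 << 30) != stage_rng(
            5, "titration"
        ).integers(0, 1 << 30)


class TestBrownianTracks:
    def test_zero_diffusivity_is_stationary(self):
        tracks = gen_brownian_tracks(
            SimulationSpec(seed=3, diffusivity=1e-300, n_tracks=2, n_frames=10)
        )
        assert np.allclose(tracks[0].x, 0.0, atol=1e-140)

    def test_increment_variance_matches_2_d_dt(self):
        spec = SimulationSpec(seed=6, n_tracks=4, n_frames=25_001)
        tracks = gen_brownian_tracks(spec)
        incs = np.concatenate([np.diff(tr.x) for tr in tracks])
        target = 2 * spec.diffusivity * spec.dt_s
        n = incs.size  # 1e5 increments
        se = target * np.sqrt(2.0 / n)
        assert abs(incs.var() - target) < 3 * se

    def test_confinement_bounds_excursions(self):
        free = gen_brownian_tracks(SimulationSpec(seed=9, n_frames=500))
        pinned = gen_brownian_tracks(
            SimulationSpec(seed=9, n_frames=500, confinement_rate=0.5)
        )
        spread = lambda trs: np.mean([tr.x.var() + tr.y.var() for tr in trs])
        assert spread(pinned) < 0.1 * spread(free)


class TestTitration:
    def test_noise_free_matches_isotherm(self):
        spec = SimulationSpec(seed=1, titration_noise_sd=0.0)
        data = gen_titration(spec)
        assert data.fraction_bound == pytest.approx(
            langmuir_fraction_bound(data.lipid_conc, spec.true_kd), rel=1e-12
        )
        assert data.lipid_conc.min() == pytest.approx(1e-8)
        assert data.lipid_conc.max() == pytest.approx(1e-4)

    def test_replicate_mean_converges_to_isotherm(self):
        # CLT at mid-curve points, where clipping is negligible
        base = SimulationSpec(seed=0)
        truth = langmuir_fraction_bound(
            gen_titration(base).lipid_conc, base.true_kd
        )
        reps = np.stack(
            [
                gen_titration(SimulationSpec(seed=s)).fraction_bound
                for s in range(1000)
            ]
        )
        mid = (truth > 0.2) & (truth < 0.8)
        se = base.titration_noise_sd / np.sqrt(1000)
        assert np.all(np.abs(reps.mean(axis=0)[mid] - truth[mid]) < 3 * se)


class TestCalibrationAndBleach:
    def test_zero_cv_is_exact_line(self):
        spec = SimulationSpec(seed=2, intensity_cv=0.0)
        calib, spots = gen_calibration_and_spots(spec)
        assert calib["intensity_au"].to_numpy() == pytest.approx(
            spec.slope * calib["copies"].to_numpy(), rel=1e-12
        )
        corrected = spots["spot_sum_au"] - spots["background_sum_au"]
        assert corrected.to_numpy() == pytest.approx(
            spec.slope * spec.emitters_per_spot, rel=1e-12
        )

    def test_default_copies_are_the_standards_set(self):
        assert SimulationSpec(seed=1).copies == (4, 20, 40, 56, 80)

    def test_full_labeling_boundary(self):
        traces = gen_bleach_traces(SimulationSpec(seed=3, labeling_p=1.0))
        assert np.all(traces.step_counts == traces.n_sites)

    def test_bleach_mean_matches_binomial(self):
        spec = SimulationSpec(seed=4, n_traces=10_000)
        traces = gen_bleach_traces(spec)
        p_emp = traces.step_counts.mean() / spec.n_sites
        se = np.sqrt(0.8 * 0.2 / (spec.n_traces * spec.n_sites))
        assert abs(p_emp - spec.labeling_p) < 3 * se


class TestSchemaCompatibility:
    def test_outputs_pass_readers_unchanged(self, tmp_path):
        import pandas as pd

        spec = SimulationSpec(seed=12, n_tracks=3, n_frames=20)
        write_tracks_csv(gen_brownian_tracks(spec), tmp_path / "tracks.csv")
        assert len(read_tracks_csv(tmp_path / "tracks.csv")) == 3

        t = gen_titration(spec)
        pd.DataFrame(
            {"lipid_conc_M": t.lipid_conc, "fraction_bound": t.fraction_bound}
        ).to_csv(tmp_path / "tit.csv", index=False)
        assert len(read_titration_csv(tmp_path / "tit.csv")) == spec.n_conc

        calib, spots = gen_calibration_and_spots(spec)
        calib.to_csv(tmp_path / "cal.csv", index=False)
        spots.to_csv(tmp_path / "spots.csv", index=False)
        c, i = read_calibration_csv(tmp_path / "cal.csv")
        assert len(c) == len(i) == len(calib)
        assert len(read_spots_csv(tmp_path / "spots.csv")) == spec.n_spots

        b = gen_bleach_traces(spec)
        pd.DataFrame(
            {"trace_id": np.arange(len(b.step_counts)), "steps": b.step_counts}
        ).to_csv(tmp_path / "bleach.csv", index=False)
        back = read_bleach_csv(tmp_path / "bleach.csv", n_sites=5)
        assert np.array_equal(back.step_counts, b.step_counts)
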