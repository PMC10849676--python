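"""Arc coordinates, upper-quantile normalization, LOESS with confidence
bands (statsmodels lowess oracle), and binned axis profiles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from statsmodels.nonparametric.smoothers_lowess import lowess

import bmptargets.simulate as sim
from bmptargets.gradient import (
    assign_arc_positions,
    axis_profile,
    loess_profile,
    normalize_upper_quantile,
)


def nucleus_table(n, embryo="e1", layer="endoderm", intensity=None):
    if intensity is None:
        intensity = np.ones(n)
    return pd.DataFrame(
        {
            "embryo_id": embryo,
            "layer": layer,
            "seq_index": np.arange(1, n + 1),
            "raw_intensity": intensity,
        }
    )


class TestArcPositions:
    def test_first_nucleus_maps_to_pi_over_n(self):
        out = assign_arc_positions(nucleus_table(10))
        assert out["theta"].iloc[0] == pytest.approx(np.pi / 10)

    def test_last_nucleus_maps_to_pi_exactly(self):
        out = assign_arc_positions(nucleus_table(10))
        assert out["theta"].iloc[-1] == pytest.approx(np.pi)

    @given(st.integers(3, 200))
    def test_strictly_increasing_per_embryo(self, n):
        out = assign_arc_positions(nucleus_table(n))
        assert (np.diff(out["theta"]) > 0).all()

    def test_gap_in_index_names_embryo(self):
        df = nucleus_table(5)
        df.loc[2, "seq_index"] = 7
        with pytest.raises(ValueError, match="e1"):
            assign_arc_positions(df)

    def test_intensity_multiset_unchanged(self, rng):
        vals = rng.uniform(0, 10, 20)
        out = assign_arc_positions(nucleus_table(20, intensity=vals))
        assert sorted(out["raw_intensity"]) == pytest.approx(sorted(vals))


class TestUpperQuantileNormalization:
    def test_constant_pool_becomes_one(self):
        out = normalize_upper_quantile(np.full(30, 7.0))
        assert out == pytest.approx(np.ones(30))

    def test_interpolated_quantile_1_to_100(self):
        pool = np.arange(1, 101, dtype=float)
        out = normalize_upper_quantile(pool)
        assert out[-1] == pytest.approx(100 / 75.25)  # divisor 75.25

    def test_scale_invariance(self, rng):
        vals = rng.uniform(1, 50, 40)
        a = normalize_upper_quantile(vals)
        b = normalize_upper_quantile(vals * 13.7)
        assert a == pytest.approx(b)

    def test_pool_quantile_of_normalized_is_one(self, rng):
        vals = rng.uniform(1, 50, 101)
        out = normalize_upper_quantile(vals, q=0.75)
        assert np.quantile(out, 0.75) == pytest.approx(1.0)

    def test_nonpositive_divisor_rejected(self):
        with pytest.raises(ValueError):
            normalize_upper_quantile(np.array([-5.0] * 10 + [1.0]))

    def test_dataframe_adds_norm_column(self):
        df = nucleus_table(4, intensity=np.array([1.0, 2.0, 3.0, 4.0]))
        out = normalize_upper_quantile(df)
        assert "norm_intensity" in out.columns


class TestLoessProfile:
    def test_constant_input_flat_fit_zero_ci(self):
        theta = np.linspace(0.1, np.pi, 40)
        prof = loess_profile(theta, np.full(40, 3.0))
        assert prof.fit == pytest.approx(np.full(100, 3.0))
        assert (prof.ci_high - prof.ci_low) == pytest.approx(np.zeros(100), abs=1e-12)

    def test_linear_data_reproduced_exactly(self):
        theta = np.linspace(0.1, np.pi, 60)
        y = 2.0 + 3.0 * theta
        prof = loess_profile(theta, y, grid=theta)
        assert prof.fit == pytest.approx(y, abs=1e-6)

    def test_ci_monotone_in_level(self, rng):
        theta = np.linspace(0.1, np.pi, 80)
        y = np.cos(theta) + rng.normal(0, 0.3, 80)
        lo = loess_profile(theta, y, level=0.95)
        hi = loess_profile(theta, y, level=0.99)
        assert ((hi.ci_high - hi.ci_low) >= (lo.ci_high - lo.ci_low) - 1e-12).all()

    def test_ci_brackets_fit(self, rng):
        theta = np.linspace(0.1, np.pi, 50)
        y = np.cos(theta) + rng.normal(0, 0.2, 50)
        prof = loess_profile(theta, y)
        assert (prof.ci_low <= prof.fit + 1e-12).all()
        assert (prof.fit <= prof.ci_high + 1e-12).all()

    def test_matches_statsmodels_lowess(self, rng):
        theta = np.sort(rng.uniform(0.05, np.pi, 120))
        y = 1 + 5 * (1 + np.cos(theta)) / 2 + rng.normal(0, 0.4, 120)
        prof = loess_profile(theta, y, span=0.5, grid=theta)
        sm = lowess(y, theta, frac=0.5, it=0, return_sorted=True)
        assert prof.fit == pytest.approx(sm[:, 1], abs=1e-8)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            loess_profile(np.linspace(0, 1, 5), np.zeros(5))

    def test_amplitude_recovery_control_vs_flattened(self, default_cfg):
        # full-pipeline recovery: normalized LOESS fit separates the ends
        # by at least half the planted amplitude
        ctrl = assign_arc_positions(sim.gen_nuclei_tables(default_cfg, "control"))
        flat = assign_arc_positions(sim.gen_nuclei_tables(default_cfg, "flattened"))
        pool = pd.concat([ctrl, flat], ignore_index=True)
        divisor = float(np.quantile(pool["raw_intensity"], 0.75))
        prof = loess_profile(
            ctrl["theta"].to_numpy(), ctrl["raw_intensity"].to_numpy() / divisor
        )
        at = lambda frac: prof.fit[np.argmin(np.abs(prof.grid - frac * np.pi))]  # noqa: E731
        planted_amp_norm = default_cfg.gradient_amp / divisor
        assert at(0.1) - at(0.9) >= 0.5 * planted_amp_norm


class TestAxisProfile:
    def test_uniform_image_flat_profile(self):
        prof = axis_profile(np.full((10, 400), 2.5), np.ones((10, 400), bool))
        valid = ~np.isnan(prof.mean_intensity)
        assert prof.mean_intensity[valid] == pytest.approx(2.5)

    def test_four_column_toy_matrix(self):
        img = np.array([[1.0, 2.0, 3.0, 4.0], [3.0, 4.0, 5.0, 6.0]])
        mask = np.ones_like(img, dtype=bool)
        prof = axis_profile(img, mask, bin_pct=25.0, trim_pct=0.0)
        # columns at 12.5/37.5/62.5/87.5% -> one column per 25% bin
        assert prof.mean_intensity == pytest.approx([2.0, 3.0, 4.0, 5.0])

    def test_default_binning_retains_180_bins(self):
        prof = axis_profile(np.ones((5, 1000)), np.ones((5, 1000), bool))
        assert len(prof.bin_centers) == 180
        assert prof.bin_centers[0] == pytest.approx(5.25)
        assert prof.bin_centers[-1] == pytest.approx(94.75)

    def test_background_self_subtraction_zeroes_profile(self):
        img = np.outer(np.ones(8), np.linspace(1, 9, 600))
        mask = np.ones_like(img, dtype=bool)
        raw = axis_profile(img, mask, background=None)
        full = axis_profile(img, mask, trim_pct=0.0)
        again = axis_profile(img, mask, background=[full.mean_intensity])
        valid = ~np.isnan(again.mean_intensity)
        assert again.mean_intensity[valid] == pytest.approx(np.zeros(valid.sum()), abs=1e-12)
        assert raw.background_subtracted is False
        assert again.background_subtracted is True

    def test_masked_columns_skipped_and_counted(self):
        img = np.ones((4, 300))
        mask = np.ones_like(img, dtype=bool)
        mask[:, 100:110] = False
        prof = axis_profile(img, mask)
        assert prof.n_empty_columns == 10

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            axis_profile(np.ones((3, 3)), np.zeros((3, 3), bool))


class TestSyntheticNuclei:
    def test_first_nucleus_formula(self):
        cfg = sim.SynthConfig(
            gradient_amp=10.0, gradient_base=1.0, gradient_noise_sd=0.0,
            n_nuclei_per_embryo=10, n_embryos=1,
        )
        df = sim.gen_nuclei_tables(cfg, "control")
        expected = 1 + 10 * (1 + np.cos(np.pi / 10)) / 2
        assert df["raw_intensity"].iloc[0] == pytest.approx(expected)

    def test_control_above_flattened_at_high_signal_end(self, default_cfg):
        ctrl = sim.gen_nuclei_tables(default_cfg, "control")
        flat = sim.gen_nuclei_tables(default_cfg, "flattened")
        first_bin = lambda df: df[df["seq_index"] <= 6]["raw_intensity"].mean()  # noqa: E731
        assert first_bin(ctrl) > first_bin(flat)

    def test_expanded_widens_plateau(self):
        cfg = sim.SynthConfig(gradient_noise_sd=0.0, n_nuclei_per_embryo=20, n_embryos=1)
        ctrl = sim.gen_nuclei_tables(cfg, "control")
        exp = sim.gen_nuclei_tables(cfg, "expanded")
        mid = 10
        assert exp["raw_intensity"].iloc[mid] > ctrl["raw_intensity"].iloc[mid]

    def test_zero_amplitude_gives_flat_loess(self):
        cfg = sim.SynthConfig(
            gradient_amp=0.0, gradient_base=2.0, gradient_noise_sd=0.0,
            n_nuclei_per_embryo=30, n_embryos=2,
        )
        df = assign_arc_positions(sim.gen_nuclei_tables(cfg, "control"))
        prof = loess_profile(df["theta"].to_numpy(), df["raw_intensity"].to_numpy())
        assert prof.fit == pytest.approx(np.full(100, 2.0), abs=1e-9)

    def test_negative_noise_rejected(self):
        cfg = sim.SynthConfig(gradient_noise_sd=-0.1)
        with pytest.raises(ValueError):
            sim.gen_nuclei_tables(cfg, "control")
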