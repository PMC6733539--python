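"""Time-series cleaning, motion summaries and connectivity statistics."""

import numpy as np
import pytest

from inflammetry.containers import GridMeta, NodeTimeSeries
from inflammetry.connectivity import (
    build_nuisance_design,
    clean_timeseries,
    compute_fd_rms,
    connectivity_vector,
    dct_basis,
    extract_node_series,
    group_connectivity_stats,
    standardize,
    tissue_mean_signal,
)

T, TR = 263, 2.43


def _design(T=T, tr=TR, rng=None, passband=(0.0078, 0.1)):
    rng = rng or np.random.default_rng(0)
    return build_nuisance_design(
        motion_params=0.1 * rng.standard_normal((T, 6)),
        wm_signal=rng.standard_normal(T),
        csf_signal=rng.standard_normal(T),
        tr=tr,
        passband=passband,
    )


class TestSphereExtraction:
    def setup_method(self):
        self.grid = GridMeta((6, 6, 6), np.diag([2.0, 2.0, 2.0, 1.0]))

    def test_single_voxel_sphere_returns_standardized_series(self, rng):
        V = self.grid.n_voxels
        vox = rng.standard_normal((V, 50))
        out = extract_node_series(vox, [0.0, 0.0, 0.0], self.grid,
                                  radius_mm=1.0)
        assert np.allclose(out, standardize(vox[0]))

    def test_identical_voxels_give_mean_signal(self, rng):
        s = rng.standard_normal(40)
        vox = np.tile(s, (self.grid.n_voxels, 1))
        out = extract_node_series(vox, [4.0, 4.0, 4.0], self.grid,
                                  radius_mm=5.0)
        assert np.corrcoef(out, s)[0, 1] == pytest.approx(1.0)

    def test_sign_follows_majority_population(self, rng):
        s = rng.standard_normal(60)
        vox = np.zeros((self.grid.n_voxels, 60))
        sphere_idx = np.arange(10)
        vox[sphere_idx[:6]] = s       # 60% in phase
        vox[sphere_idx[6:]] = -s      # 40% anti-phase
        vox += 0.01 * rng.standard_normal(vox.shape)
        out = extract_node_series(vox, [0.0, 0.0, 0.0], self.grid,
                                  radius_mm=100.0)
        assert np.corrcoef(out, s)[0, 1] > 0

    def test_empty_sphere_names_the_node(self):
        with pytest.raises(ValueError, match="vACC"):
            extract_node_series(np.zeros((self.grid.n_voxels, 20)),
                                [500.0, 0.0, 0.0], self.grid,
                                radius_mm=1.0, node_name="vACC")


class TestNuisanceDesign:
    def test_dct_frequency_selection(self):
        # enumerate DCT frequencies k/(2 T TR) and count the excluded set
        _, freqs = dct_basis(T, TR)
        outside = (freqs < 0.0078) | (freqs > 0.1)
        design = _design()
        n_dct = sum(lab.startswith("dct") for lab in design.labels)
        assert n_dct == int(outside.sum())
        # spot values: k=9 is below the low cut, k=128 above the high cut
        assert freqs[8] < 0.0078 < freqs[9]
        assert freqs[126] < 0.1 < freqs[127]

    def test_exactly_one_intercept_and_expected_blocks(self):
        design = _design()
        assert design.labels.count("intercept") == 1
        assert sum(lab.startswith("motion") for lab in design.labels) == 24
        assert sum(lab.startswith("tissue") or lab in ("wm", "csf")
                   for lab in design.labels) == 8

    def test_zero_motion_columns_dropped(self, caplog):
        rng = np.random.default_rng(1)
        with caplog.at_level("INFO"):
            design = build_nuisance_design(
                np.zeros((T, 6)), rng.standard_normal(T),
                rng.standard_normal(T), TR,
            )
        assert not any(lab.startswith("motion") for lab in design.labels)
        assert "dropping constant nuisance columns" in caplog.text

    def test_invalid_passband_rejected(self):
        with pytest.raises(ValueError, match="passband"):
            _design(passband=(0.01, 0.5))  # above Nyquist for TR=2.43


class TestCleaning:
    def test_design_column_is_annihilated(self):
        design = _design()
        ts = NodeTimeSeries(
            values=np.vstack([design.regressors[:, 5],
                              design.regressors[:, 10]]),
            tr=TR, node_names=["a", "b"],
        )
        out = clean_timeseries(ts, design)
        assert np.abs(out.values).max() < 1e-8

    @pytest.mark.parametrize("freq,retained", [(0.2, False), (0.05, True)])
    def test_frequency_contract(self, freq, retained):
        # no collinear nuisance: zero motion/tissue input leaves only the
        # intercept, trend and DCT columns, so the passband verdict is pure
        t = np.arange(T) * TR
        sig = np.sin(2 * np.pi * freq * t)
        design = build_nuisance_design(
            np.zeros((T, 6)), np.zeros(T), np.zeros(T), TR,
        )
        rng = np.random.default_rng(2)
        ts = NodeTimeSeries(
            values=np.vstack([sig, rng.standard_normal(T)]),
            tr=TR, node_names=["sig", "noise"],
        )
        out = clean_timeseries(ts, design)
        frac = out.values[0].var() / sig.var()
        if retained:
            assert frac > 0.95     # in-band variance survives
        else:
            assert frac < 0.01     # out-of-band variance removed

    def test_residuals_orthogonal_to_design(self, rng):
        design = _design(rng=rng)
        ts = NodeTimeSeries(values=rng.standard_normal((3, T)), tr=TR,
                            node_names=["a", "b", "c"])
        out = clean_timeseries(ts, design)
        proj = design.regressors.T @ out.values.T
        assert np.abs(proj).max() < 1e-6

    def test_rank_deficient_design_logs_drop(self, caplog, rng):
        X = rng.standard_normal((50, 3))
        from inflammetry.connectivity import NuisanceDesign

        design = NuisanceDesign(
            regressors=np.column_stack([np.ones(50), X, X[:, 0]]),
            labels=["intercept", "x1", "x2", "x3", "dup"],
        )
        ts = NodeTimeSeries(values=rng.standard_normal((2, 50)), tr=2.0,
                            node_names=["a", "b"])
        with caplog.at_level("INFO"):
            clean_timeseries(ts, design)
        assert "rank-deficient" in caplog.text

    def test_bandpass_power_fraction_on_white_noise(self, rng):
        design = _design(rng=rng)
        ts = NodeTimeSeries(values=rng.standard_normal((2, T)), tr=TR,
                            node_names=["a", "b"])
        out = clean_timeseries(ts, design)
        from scipy.signal import periodogram

        f, pxx = periodogram(out.values[0], fs=1.0 / TR)
        outside = (f < 0.0078) | (f > 0.1)
        assert pxx[outside].sum() / pxx.sum() < 0.05


class TestMotionSummary:
    def test_zero_and_constant_motion_give_zero(self):
        assert compute_fd_rms(np.zeros((20, 6))) == 0.0
        assert compute_fd_rms(np.full((20, 6), 0.7)) == 0.0

    def test_unit_translation_step(self):
        motion = np.zeros((2, 6))
        motion[1, 0] = 1.0
        assert compute_fd_rms(motion) == pytest.approx(1.0)

    def test_rotation_scaled_to_50mm_sphere(self):
        motion = np.zeros((2, 6))
        motion[1, 3] = 0.01  # rad
        assert compute_fd_rms(motion) == pytest.approx(0.5)

    def test_wrong_column_count_rejected(self):
        with pytest.raises(ValueError):
            compute_fd_rms(np.zeros((10, 5)))


class TestConnectivity:
    def test_13_nodes_give_78_pairs_in_lexicographic_order(self, rng):
        ts = NodeTimeSeries(values=rng.standard_normal((13, 100)), tr=2.0,
                            node_names=[f"n{i}" for i in range(13)])
        vec = connectivity_vector(ts)
        assert len(vec.r) == 78
        assert vec.pair_index[0] == ("n0", "n1")
        assert vec.pair_index[-1] == ("n11", "n12")

    def test_duplicate_and_antiphase_series(self, rng):
        s = rng.standard_normal(80)
        ts = NodeTimeSeries(values=np.vstack([s, s, -s]), tr=2.0,
                            node_names=["a", "b", "c"])
        vec = connectivity_vector(ts)
        r = dict(zip(vec.labels, vec.r))
        assert r["a—b"] == pytest.approx(1.0)
        assert r["a—c"] == pytest.approx(-1.0)

    def test_constant_node_named_in_error(self, rng):
        vals = rng.standard_normal((3, 50))
        vals[1] = 2.5
        ts = NodeTimeSeries(values=vals, tr=2.0, node_names=["a", "bad", "c"])
        with pytest.raises(ValueError, match="bad"):
            connectivity_vector(ts)


class TestGroupStats:
    def test_identical_groups_give_zero_t(self, rng):
        R = np.tile(rng.uniform(-0.5, 0.5, 78), (10, 1))
        out = group_connectivity_stats(
            R, np.array(["A"] * 5 + ["B"] * 5), patient_label="A",
        )
        assert np.allclose(out["t"], 0.0)
        assert len(out) == 78

    def test_planted_difference_has_largest_t(self):
        hits = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            Z = 0.3 * rng.standard_normal((42, 78))
            Z[:28, 17] += 1.0  # planted z-difference on one connection
            R = np.tanh(Z)
            out = group_connectivity_stats(
                R, np.array(["A"] * 28 + ["B"] * 14), patient_label="A",
            )
            hits += np.argmax(np.abs(out["t"])) == 17
        assert hits >= 38

    def test_small_group_rejected(self, rng):
        with pytest.raises(ValueError):
            group_connectivity_stats(
                rng.standard_normal((3, 78)) * 0.1,
                np.array(["A", "A", "B"]), patient_label="A",
            )


def test_tissue_mean_uses_probability_threshold(rng):
    vox = rng.standard_normal((10, 30))
    prob = np.r_[np.full(4, 0.9), np.full(6, 0.5)]
    out = tissue_mean_signal(vox, prob)
    assert np.allclose(out, vox[:4].mean(axis=0))
    with pytest.raises(ValueError):
        tissue_mean_signal(vox, np.full(10, 0.5))
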