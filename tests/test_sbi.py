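"""Source-based inflammetry: masking, order selection, ICA, selection, Grubbs."""

import numpy as np
import pytest
from scipy import stats

from inflammetry.containers import GridMeta, PKMapStack
from inflammetry.sbi import (
    AmbiguousSelectionError,
    ComponentTests,
    NoSelectionError,
    apply_mask,
    build_group_mask,
    decompose,
    estimate_n_components,
    grubbs_critical_value,
    grubbs_test,
    match_sources,
    reconstruction,
    select_component,
)
from inflammetry.sbi import test_loading_gm_association as loading_gm_association
from inflammetry.sbi import test_loading_group_difference as loading_group_difference


def _stack(maps):
    maps = np.asarray(maps, dtype=float)
    return PKMapStack(
        maps=maps,
        mask=np.ones(maps.shape[1], dtype=bool),
        grid=GridMeta((maps.shape[1], 1, 1), np.eye(4)),
        subject_ids=[f"s{i}" for i in range(maps.shape[0])],
    )


class TestGroupMask:
    def test_uniform_above_threshold_keeps_everything(self):
        assert build_group_mask(np.full((4, 100), 0.31)).all()

    def test_boundary_is_strict(self):
        with pytest.raises(ValueError, match="empty"):
            build_group_mask(np.full((4, 100), 0.30))

    def test_mean_across_subjects_rule(self):
        probs = np.array([[0.2], [0.5]])
        assert build_group_mask(probs)[0]  # mean 0.35 > 0.3

    def test_probabilities_validated(self):
        with pytest.raises(ValueError):
            build_group_mask(np.array([[1.2, 0.4]]))


class TestOrderSelection:
    def test_rank_one_stack(self, rng):
        maps = np.outer(rng.standard_normal(10), rng.standard_normal(500))
        assert estimate_n_components(_stack(maps)) == 1

    def test_recovers_planted_order(self, default_stack_truth):
        stack, _ = default_stack_truth
        assert estimate_n_components(stack) == 5

    def test_white_noise_selects_low_order(self):
        low = 0
        for seed in range(20):
            maps = np.random.default_rng(seed).standard_normal((42, 2000))
            low += estimate_n_components(_stack(maps)) <= 2
        assert low >= 18

    def test_degenerate_spectrum_returns_one(self, caplog):
        maps = np.eye(6) * 2.0  # equal eigenvalues after centering? use iid
        maps = np.tile(np.arange(6.0)[:, None], (1, 50))
        with caplog.at_level("WARNING"):
            k = estimate_n_components(_stack(maps + np.eye(6, 50) * 0))
        assert k >= 1


class TestDecomposition:
    def test_planted_sources_recovered(self, default_stack_truth):
        stack, truth = default_stack_truth
        d = decompose(stack, 5, seed=1)
        _, rs = match_sources(d.sources, truth.true_sources)
        assert (rs > 0.9).all()

    def test_rank_one_exact(self, rng):
        src = np.abs(rng.standard_normal(800))  # skewed positive source
        maps = np.outer(rng.standard_normal(12), src)
        d = decompose(_stack(maps), 1, seed=0)
        r = np.corrcoef(d.sources[0], src)[0, 1]
        assert abs(r) > 0.999

    def test_deterministic_given_seed(self, default_stack_truth):
        stack, _ = default_stack_truth
        d1 = decompose(stack, 5, seed=3)
        d2 = decompose(stack, 5, seed=3)
        assert np.array_equal(d1.sources, d2.sources)
        assert np.array_equal(d1.loadings, d2.loadings)

    def test_reconstruction_matches_pca_truncation(self, default_stack_truth):
        stack, _ = default_stack_truth
        d = decompose(stack, 5, seed=1)
        X = stack.maps
        resid_ica = X - reconstruction(d)
        Xc = X - X.mean(axis=1, keepdims=True)
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        pca5 = (U[:, :5] * s[:5]) @ Vt[:5]
        ev_ica = 1 - (resid_ica ** 2).sum() / (X ** 2).sum()
        ev_pca = 1 - ((Xc - pca5) ** 2).sum() / (X ** 2).sum()
        assert ev_ica >= ev_pca - 1e-6

    def test_sources_unit_variance_positive_skew(self, default_stack_truth):
        stack, _ = default_stack_truth
        d = decompose(stack, 5, seed=1)
        assert np.allclose(d.sources.std(axis=1), 1.0)
        assert (stats.skew(d.sources, axis=1) >= 0).all()

    def test_subject_order_invariance(self, default_stack_truth):
        stack, _ = default_stack_truth
        perm = np.random.default_rng(0).permutation(stack.n_subjects)
        permuted = PKMapStack(
            maps=stack.maps[perm], mask=stack.mask, grid=stack.grid,
            subject_ids=[stack.subject_ids[i] for i in perm],
        )
        d1 = decompose(stack, 5, seed=1)
        d2 = decompose(permuted, 5, seed=1)
        assign, rs = match_sources(d2.sources, d1.sources)
        assert (rs > 0.999).all()
        for comp_orig, comp_perm in enumerate(assign):
            r = np.corrcoef(d1.loadings[perm, comp_orig],
                            d2.loadings[:, comp_perm])[0, 1]
            assert abs(r) > 0.999


class TestSelection:
    def _tests_from(self, group_p, gm_p, gm_r):
        import pandas as pd

        return ComponentTests(table=pd.DataFrame({
            "component": range(len(group_p)),
            "group_p_perm": group_p,
            "gm_p_patients": gm_p,
            "gm_r_patients": gm_r,
        }))

    def test_unique_candidate_selected(self):
        t = self._tests_from([0.5, 0.01, 0.7], [0.2, 0.003, 0.9],
                             [0.1, -0.6, 0.2])
        assert select_component(t) == 1

    def test_no_candidate_raises(self):
        t = self._tests_from([0.5, 0.4], [0.2, 0.3], [-0.1, -0.2])
        with pytest.raises(NoSelectionError):
            select_component(t)

    def test_positive_gm_association_does_not_qualify(self):
        t = self._tests_from([0.01], [0.01], [+0.6])
        with pytest.raises(NoSelectionError):
            select_component(t)

    def test_multiple_candidates_listed(self):
        t = self._tests_from([0.01, 0.02], [0.01, 0.01], [-0.5, -0.4])
        with pytest.raises(AmbiguousSelectionError) as err:
            select_component(t)
        assert err.value.candidates == [0, 1]

    def test_dual_effect_cohort_is_ambiguous(self):
        # two planted group-differentiating, GM-coupled components
        rng = np.random.default_rng(8)
        lam = 0.5 * rng.standard_normal((42, 3))
        lam[:28, 0] += 1.5
        lam[:28, 2] += 1.5
        gm = np.empty(42)
        shared = rng.standard_normal(28)
        gm[:28] = -(lam[:28, 0] - lam[:28, 0].mean()) \
            - (lam[:28, 2] - lam[:28, 2].mean()) + 0.3 * shared
        gm[28:] = rng.standard_normal(14)
        is_pat = np.r_[np.ones(28, bool), np.zeros(14, bool)]

        class FakeDecomp:
            loadings = lam
            n_components = 3

        gt = loading_group_difference(FakeDecomp, is_pat,
                                           n_perm=2000, seed=0)
        ga = loading_gm_association(FakeDecomp, gm, is_pat)
        with pytest.raises(AmbiguousSelectionError):
            select_component(gt.merged(ga))


class TestLoadingTests:
    def test_identical_groups_null(self):
        lam = np.tile(np.arange(14.0), 3)[:42, None]

        class FakeDecomp:
            loadings = lam
            n_components = 1

        is_pat = np.r_[np.ones(28, bool), np.zeros(14, bool)]
        # symmetric construction: both groups share the same values
        lam[:, 0] = np.r_[np.tile(np.arange(14.0), 2), np.arange(14.0)]
        out = loading_group_difference(FakeDecomp, is_pat,
                                            n_perm=500, seed=0)
        assert out.table["group_p_perm"].iloc[0] > 0.5

    def test_perfect_negative_gm_association(self):
        gm = np.linspace(500, 700, 42)

        class FakeDecomp:
            loadings = (-gm)[:, None]
            n_components = 1

        is_pat = np.r_[np.ones(28, bool), np.zeros(14, bool)]
        out = loading_gm_association(FakeDecomp, gm, is_pat).table
        for stratum in ("all", "patients", "controls"):
            assert out[f"gm_r_{stratum}"].iloc[0] == pytest.approx(-1.0)

    def test_constant_gm_stratum_skipped(self, caplog, rng):
        gm = np.r_[np.full(28, 600.0), rng.normal(600, 50, 14)]

        class FakeDecomp:
            loadings = rng.standard_normal((42, 1))
            n_components = 1

        is_pat = np.r_[np.ones(28, bool), np.zeros(14, bool)]
        with caplog.at_level("INFO"):
            out = loading_gm_association(FakeDecomp, gm, is_pat).table
        assert np.isnan(out["gm_r_patients"].iloc[0])

    def test_independent_gm_mostly_uncorrelated(self):
        hits = 0
        for seed in range(30):
            rng = np.random.default_rng(seed)

            class FakeDecomp:
                loadings = rng.standard_normal((28, 1))
                n_components = 1

            gm = rng.normal(600, 50, 28)
            is_pat = np.ones(28, bool)
            is_pat[-4:] = False  # tiny control stratum just for the API
            out = loading_gm_association(FakeDecomp, gm, is_pat).table
            hits += abs(out["gm_r_patients"].iloc[0]) < 0.4
        assert hits >= 27


class TestGrubbs:
    def test_textbook_outlier(self):
        # G = (50 - 12)/sd ≈ 1.79 > 1.71 at n=5
        assert grubbs_test([1, 2, 3, 4, 50]) == [4]
        assert grubbs_critical_value(5) == pytest.approx(1.715, abs=0.005)

    def test_symmetric_sample_clean(self):
        assert grubbs_test([-2, -1, 0, 1, 2]) == []

    def test_zero_variance_logged_empty(self, caplog):
        with caplog.at_level("INFO"):
            out = grubbs_test([5.0, 5.0, 5.0, 5.0])
        assert out == []

    def test_iterative_removal_of_two_outliers(self):
        # the gross outlier is flagged first; removing it unmasks the second
        x = [0.1, 0.2, -0.1, 0.05, -0.2, 0.15, 8.0, 100.0]
        flagged = grubbs_test(x)
        assert set(flagged) == {6, 7}

    def test_matches_brute_force_oracle(self):
        # oracle: recursively delete the max-deviation point while its G
        # statistic exceeds the critical value, re-deriving G from scratch
        def oracle(values, alpha=0.05):
            vals = list(enumerate(values))
            out = []
            while len(vals) >= 3:
                arr = np.array([v for _, v in vals])
                if arr.std(ddof=1) == 0:
                    break
                dev = np.abs(arr - arr.mean()) / arr.std(ddof=1)
                n = len(arr)
                t2 = stats.t.ppf(1 - alpha / (2 * n), n - 2) ** 2
                crit = (n - 1) / np.sqrt(n) * np.sqrt(t2 / (n - 2 + t2))
                j = int(np.argmax(dev))
                if dev[j] > crit:
                    out.append(vals.pop(j)[0])
                else:
                    break
            return sorted(out)

        rng = np.random.default_rng(7)
        for _ in range(200):
            n = int(rng.integers(3, 9))
            x = rng.standard_normal(n)
            if rng.random() < 0.5:
                x[int(rng.integers(n))] += rng.choice([-8, 8])
            if np.ptp(x) == 0:
                continue
            assert grubbs_test(x.tolist()) == oracle(x.tolist())


def test_apply_mask_roundtrip(default_stack_truth):
    stack, _ = default_stack_truth
    mask = np.zeros(stack.grid.n_voxels, dtype=bool)
    mask[::3] = True
    sub = apply_mask(stack, mask)
    assert sub.maps.shape == (42, mask.sum())
    assert np.array_equal(sub.maps, stack.maps[:, mask])
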