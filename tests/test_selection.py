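"""Greedy selection vs brute-force oracles, patterns, budget CV."""

import numpy as np
import pytest

from bcgomp.core import ChannelSubset, Recording, ValidationError
from bcgomp.estimators import OmpBcgInference
from bcgomp.montage import ten_twenty_subset
from bcgomp.selection import (
    cross_validate_budget,
    fit_inference,
    lines_pattern,
    omp_select,
    patches_pattern,
    random_pattern,
)


def naive_omp(X: np.ndarray, budget: int):
    """Literal greedy loop: per-candidate score, argmax, full LS refit."""
    C, _ = X.shape
    selected = []
    R = X.copy()
    for _ in range(budget):
        best_i, best_score = None, -np.inf
        for i in range(C):
            if i in selected:
                continue
            ni = np.linalg.norm(X[i])
            if ni == 0:
                score = 0.0
            else:
                score = sum(float(R[j] @ X[i] / ni) ** 2 for j in range(C))
            if score > best_score + 1e-12:
                best_i, best_score = i, score
        selected.append(best_i)
        Xs = X[selected]
        W = X @ Xs.T @ np.linalg.pinv(Xs @ Xs.T)
        R = X - W @ Xs
    return selected


class TestFitInference:
    def test_full_subset_gives_identity_and_zero_residual(
            self, random_recording):
        sub = ChannelSubset(list(range(1, 7)), 6)
        model = fit_inference(random_recording, sub)
        X = random_recording.data
        resid = X - model.W_expanded @ X[sub.row_indices]
        assert np.abs(resid).max() < 1e-8

    def test_rank_one_single_channel_exact(self):
        rng = np.random.default_rng(11)
        base = rng.standard_normal(30)
        X = np.outer([1.0, -2.0, 0.5], base)
        model = fit_inference(Recording(X), ChannelSubset([1], 3))
        resid = X - model.W_expanded @ X[[0]]
        assert np.abs(resid).max() < 1e-10

    def test_matches_normal_equations_oracle(self, random_recording):
        X = random_recording.data
        sub = ChannelSubset([2, 5], 6)
        model = fit_inference(random_recording, sub)
        Xs = X[sub.row_indices]
        W_oracle = X @ Xs.T @ np.linalg.inv(Xs @ Xs.T)
        assert np.abs(model.W_expanded - W_oracle).max() < 1e-8
        # identity block on the selected rows
        assert np.allclose(model.W_expanded[sub.row_indices], np.eye(2),
                           atol=1e-8)

    def test_residual_orthogonal_to_selected_rows(self, random_recording):
        X = random_recording.data
        sub = ChannelSubset([1, 4, 6], 6)
        model = fit_inference(random_recording, sub)
        R = X - model.W_expanded @ X[sub.row_indices]
        G = R @ X[sub.row_indices].T
        assert np.abs(G).max() < 1e-8 * np.abs(X).max() ** 2

    def test_rank_deficiency_min_norm_with_warning(self):
        X = np.vstack([np.zeros(20), np.random.default_rng(1).random(20)])
        with pytest.warns(RuntimeWarning):
            model = fit_inference(Recording(X), ChannelSubset([1], 2))
        assert np.all(np.isfinite(model.W_expanded))

    def test_empty_subset_rejected(self, random_recording):
        with pytest.raises(ValidationError):
            fit_inference(random_recording, ChannelSubset([], 6))


class TestOmpSelect:
    def test_step2_scores_on_handworked_matrix(self):
        # rows r1, r2 orthogonal unit-ish, r3 = r1 + r2: the shared channel
        # scores highest (3 vs 2 vs 2) and is selected first
        X = np.zeros((3, 6))
        X[0, 0] = 1.0
        X[1, 1] = 1.0
        X[2, 0] = X[2, 1] = 1.0
        X[2] /= np.linalg.norm(X[2])
        scores = []
        for i in range(3):
            ni = np.linalg.norm(X[i])
            scores.append(sum(float(X[j] @ X[i] / ni) ** 2
                              for j in range(3)))
        assert np.argmax(scores) == 2
        model, trace = omp_select(Recording(X), budget=1)
        assert model.subset.indices == [3]

    def test_budget_c_drives_residual_to_zero(self, random_recording):
        model, trace = omp_select(random_recording, budget=6)
        assert trace.residual_norms[-1] < 1e-8 * np.linalg.norm(
            random_recording.data)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_naive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        # low-rank + noise keeps the instance non-degenerate but structured
        X = (rng.standard_normal((10, 3)) @ rng.standard_normal((3, 200))
             + 0.1 * rng.standard_normal((10, 200)))
        model, trace = omp_select(Recording(X), budget=5)
        oracle = [i + 1 for i in naive_omp(X, 5)]
        assert model.subset.indices == oracle

    def test_residual_norms_non_increasing(self, bcg_session):
        _, trace = omp_select(bcg_session["rec"], budget=8)
        r = np.asarray(trace.residual_norms)
        assert np.all(np.diff(r) <= 1e-9 * r[0])

    def test_scale_covariance(self, bcg_session):
        rec = bcg_session["rec"]
        m1, _ = omp_select(rec, budget=5)
        m2, _ = omp_select(rec.copy_with(rec.data * 37.5), budget=5)
        assert m1.subset.indices == m2.subset.indices
        assert np.allclose(m1.W, m2.W, atol=1e-8)

    def test_budget_out_of_range(self, random_recording):
        with pytest.raises(ValidationError):
            omp_select(random_recording, budget=0)
        with pytest.raises(ValidationError):
            omp_select(random_recording, budget=7)


class TestPatterns:
    def test_lines_default_has_20_unique(self, montage256):
        sub = lines_pattern(montage256)
        assert len(sub) == 20
        assert len(set(sub.indices)) == 20

    def test_lines_runs_are_nearest_neighbour_chains(self, montage256):
        sub = lines_pattern(montage256)
        idx = sub.row_indices.reshape(4, 5)
        for group in idx:
            for a, b in zip(group[:-1], group[1:]):
                d = np.linalg.norm(montage256 - montage256[a], axis=1)
                nearest8 = set(np.argsort(d)[1:9])
                assert b in nearest8

    def test_lines_degenerate_single_channel(self, montage256):
        sub = lines_pattern(montage256, groups=1, per_group=1)
        assert len(sub) == 1

    def test_patches_default_and_geometry(self, montage256):
        sub = patches_pattern(montage256)
        assert len(sub) == 20 and len(set(sub.indices)) == 20
        groups = sub.row_indices.reshape(4, 5)
        centers = montage256[groups[:, 0]]
        intra = max(
            np.linalg.norm(montage256[g] - montage256[g[0]], axis=1).max()
            for g in groups)
        inter = min(np.linalg.norm(centers[i] - centers[j])
                    for i in range(4) for j in range(i + 1, 4))
        assert intra < inter

    def test_patches_centers_only(self, montage256):
        sub = patches_pattern(montage256, per_group=1)
        assert len(sub) == 4

    def test_missing_positions_rejected(self):
        with pytest.raises(ValidationError):
            lines_pattern(None)

    def test_ten_twenty_subset_size(self, montage256):
        assert len(set(ten_twenty_subset(montage256))) == 20


class TestRandomPattern:
    def test_budget_c_is_permutation(self):
        sub = random_pattern(8, 8, seed=0)
        assert sorted(sub.indices) == list(range(1, 9))

    def test_seeds_differ(self):
        subs = {tuple(sorted(random_pattern(64, 20, seed=s).indices))
                for s in range(10)}
        assert len(subs) > 1

    def test_uniform_inclusion_frequency(self):
        hits = sum(1 in random_pattern(64, 20, seed=s).indices
                   for s in range(2000))
        assert abs(hits / 2000 - 20 / 64) < 0.05


class TestCrossValidateBudget:
    def test_noiseless_rank_r_floor_and_monotone(self):
        from bcgomp.simulate import BcgSimConfig, simulate_bcg

        cfg = BcgSimConfig(C=16, T=250 * 16, spatial_rank=3, noise_std=0,
                           amp_drift=0, seed=13)
        rec, *_ = simulate_bcg(cfg)
        table = cross_validate_budget(rec, budgets=[1, 2, 3, 4, 5],
                                      n_folds=4)
        err = table["mean_ave_nrmse"].to_numpy()
        assert np.all(np.diff(err) <= 1e-9 + 1e-3 * err[:-1])
        assert err[2] < 1e-4    # budget >= rank: exact representation

    def test_single_fold_matches_training_residual(self, bcg_session):
        rec = bcg_session["rec"]
        table = cross_validate_budget(rec, budgets=[4], n_folds=1)
        model, trace = omp_select(rec, budget=4)
        sub = model.subset
        pred = model.W @ rec.data[sub.row_indices]
        from bcgomp.evaluation import ave_nrmse

        expected = ave_nrmse(rec.data[sub.complement().row_indices], pred)
        assert abs(table["mean_ave_nrmse"].iloc[0] - expected) < 1e-9

    def test_too_many_folds_rejected(self, bcg_session):
        with pytest.raises(ValidationError):
            cross_validate_budget(bcg_session["rec"], budgets=[2],
                                  n_folds=1000)
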