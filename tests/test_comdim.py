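"""ComDim/CCSWA: normalization contracts, PCA equivalence on one block,
salience behavior, deflation orthogonality, projection consistency and the
multiblock one-class classifier."""

import math

import numpy as np
import pytest

from specfuse.comdim import (
    Block,
    apply_block_normalization,
    evaluate_occ,
    explained_variance,
    fit_comdim,
    fit_mb_occ,
    normalize_blocks,
    occ_distance,
    project,
)
from specfuse.errors import ConfigError, DataError


def random_block(n=30, p=15, seed=0, scale=1.0):
    rng = np.random.default_rng(seed)
    return scale * rng.standard_normal((n, p)) @ np.diag(np.linspace(2, 0.5, p))


class TestNormalizeBlocks:
    def test_unit_frobenius_norm(self):
        blocks = normalize_blocks(
            [Block(random_block(seed=1), "a"), Block(random_block(seed=2), "b")]
        )
        for b in blocks:
            assert np.linalg.norm(b.matrix) == pytest.approx(1.0, abs=1e-12)

    def test_scale_invariance(self):
        X = random_block()
        a = normalize_blocks([Block(X, "x")])[0]
        b = normalize_blocks([Block(10.0 * X, "x")])[0]
        np.testing.assert_allclose(a.matrix, b.matrix, atol=1e-14)

    def test_wildly_different_scales_equalize_total_variance(self):
        b1 = Block(random_block(seed=1, scale=1e-6), "small")
        b2 = Block(random_block(seed=2, scale=1e6), "big")
        out = normalize_blocks([b1, b2])
        v1 = np.sum(out[0].matrix**2)
        v2 = np.sum(out[1].matrix**2)
        assert v1 == pytest.approx(v2, rel=1e-12)

    def test_zero_block_rejected(self):
        with pytest.raises(DataError, match="zero norm"):
            normalize_blocks([Block(np.zeros((5, 3)), "z")])

    def test_replay_reproduces_training_normalization(self):
        X = random_block()
        trained = normalize_blocks([Block(X, "x")])[0]
        replayed = apply_block_normalization(X, trained)
        np.testing.assert_allclose(replayed, trained.matrix, atol=1e-15)


class TestFitComdim:
    def test_single_block_cds_equal_pca_scores(self):
        Xc = random_block(seed=3)
        Xc = Xc - Xc.mean(axis=0)
        m = fit_comdim(normalize_blocks([Block(Xc, "x")]), 3)
        U, _, _ = np.linalg.svd(Xc, full_matrices=False)
        for k in range(3):
            r = abs(np.corrcoef(m.global_scores[:, k], U[:, k])[0, 1])
            assert r > 0.9999

    def test_identical_blocks_get_equal_saliences(self):
        Xc = random_block(seed=4)
        m = fit_comdim(
            normalize_blocks([Block(Xc, "a"), Block(Xc.copy(), "b")]), 3
        )
        assert np.max(np.abs(m.saliences[0] - m.saliences[1])) < 1e-9

    def test_orthogonal_blocks_salience_concentrates_on_high_energy_block(self):
        """Two blocks spanning orthogonal row spaces: the first CD's salience
        share lands on the block carrying more energy."""
        rng = np.random.default_rng(5)
        t1 = rng.standard_normal(24)
        t2 = rng.standard_normal(24)
        t2 -= t1 * (t1 @ t2) / (t1 @ t1)
        b1 = Block(3.0 * np.outer(t1, rng.standard_normal(10)), "strong")
        b2 = Block(1.0 * np.outer(t2, rng.standard_normal(12)), "weak")
        # intentionally unnormalized: energy imbalance is the point
        m = fit_comdim([b1, b2], 1)
        share = m.saliences[0, 0] / m.saliences[:, 0].sum()
        assert share > 0.99

    def test_cd_scores_mutually_orthogonal(self):
        blocks = normalize_blocks(
            [Block(random_block(seed=6), "a"), Block(random_block(seed=7), "b")]
        )
        m = fit_comdim(blocks, 4)
        G = m.global_scores.T @ m.global_scores
        assert np.max(np.abs(G - np.eye(4))) < 1e-9

    def test_salience_equals_block_variance_explained_by_cd(self):
        """Per CD, each block's salience equals the block energy removed by
        that CD's deflation (computed independently here)."""
        blocks = normalize_blocks(
            [Block(random_block(seed=8), "a"), Block(random_block(seed=9), "b")]
        )
        m = fit_comdim(blocks, 3)
        Xs = [b.matrix.copy() for b in blocks]
        for k in range(3):
            q = m.global_scores[:, k]
            for b, X in enumerate(Xs):
                explained = float(np.sum((np.outer(q, X.T @ q)) ** 2))
                assert m.saliences[b, k] == pytest.approx(explained, rel=1e-9)
                Xs[b] = X - np.outer(q, X.T @ q)

    def test_n_cd_bounded_by_samples(self):
        with pytest.raises(ConfigError, match="smaller than n_samples"):
            fit_comdim([Block(random_block(n=5), "x")], 5)


class TestExplainedVariance:
    def test_full_depth_exhausts_variance(self):
        X = random_block(n=10, p=20, seed=1)
        X = X - X.mean(axis=0)
        m = fit_comdim(normalize_blocks([Block(X, "x")]), 9)
        _, cum = explained_variance(m)
        assert cum[-1] >= 99.99

    def test_rank3_data_saturates_with_three_cds(self):
        rng = np.random.default_rng(2)
        T = rng.standard_normal((20, 3))
        b1 = Block(T @ rng.standard_normal((3, 12)), "a")
        b2 = Block(T @ rng.standard_normal((3, 17)), "b")
        m = fit_comdim(normalize_blocks([b1, b2]), 3)
        assert m.cumulative_variance[-1] >= 99.99

    def test_cdwise_values_sum_to_cumulative(self):
        blocks = normalize_blocks(
            [Block(random_block(seed=3), "a"), Block(random_block(seed=4), "b")]
        )
        m = fit_comdim(blocks, 5)
        per, cum = explained_variance(m)
        assert abs(per.sum() - cum[-1]) < 1e-9
        assert (np.diff(cum) >= -1e-12).all()


class TestProject:
    def test_training_samples_reproduce_training_scores(self):
        blocks = normalize_blocks(
            [Block(random_block(seed=5), "a"), Block(random_block(seed=6), "b")]
        )
        m = fit_comdim(blocks, 3)
        scores, _ = project(m, [b.matrix for b in blocks])
        assert np.max(np.abs(scores - m.global_scores)) < 1e-9

    def test_duplicate_of_training_sample_gets_identical_scores(self):
        blocks = normalize_blocks(
            [Block(random_block(seed=7), "a"), Block(random_block(seed=8), "b")]
        )
        m = fit_comdim(blocks, 3)
        new = [b.matrix[4:5] for b in blocks]
        scores, _ = project(m, new)
        np.testing.assert_allclose(scores[0], m.global_scores[4], atol=1e-10)

    def test_variable_mismatch_rejected(self):
        blocks = normalize_blocks([Block(random_block(), "a")])
        m = fit_comdim(blocks, 2)
        with pytest.raises(DataError, match="variable count"):
            project(m, [np.zeros((2, 3))])

    def test_held_out_samples_land_near_their_class(self):
        """Generator-truth oracle: held-out replicate rows project nearest to
        their own class centroid in CD space (>= 90% across 20 seeds)."""
        from specfuse.synthetic import SyntheticConfig, generate_fusion_dataset

        hits = total = 0
        for seed in range(20):
            cfg = SyntheticConfig(
                n_samples_per_class=5, n_replicates=2,
                em_grid=(250.0, 530.0, 2.0), rng_seed=seed,
            )
            table, eem_df, meta, _ = generate_fusion_dataset(cfg, contrast="both")
            labels = meta["class_label"].to_numpy()
            # hold out the last replicate of each sample
            held = meta["replicate_id"].to_numpy() == "r2"
            blocks = normalize_blocks([
                Block(table.matrix[~held], "nmr"),
                Block(eem_df.to_numpy()[~held], "eem"),
            ])
            m = fit_comdim(blocks, 3)
            centered = m.global_scores - m.global_scores.mean(axis=0)
            centroids = {
                lab: centered[labels[~held] == lab].mean(axis=0)
                for lab in np.unique(labels)
            }
            new = [
                apply_block_normalization(table.matrix[held], blocks[0]),
                apply_block_normalization(eem_df.to_numpy()[held], blocks[1]),
            ]
            scores, _ = project(m, new)
            scores = scores - m.global_scores.mean(axis=0)
            for s, lab in zip(scores, labels[held]):
                nearest = min(
                    centroids, key=lambda c: np.linalg.norm(s - centroids[c])
                )
                hits += nearest == lab
                total += 1
        assert hits / total >= 0.90


class TestMultiblockOCC:
    def test_centroid_sample_has_zero_score_distance(self):
        X1, X2 = random_block(seed=1), random_block(seed=2)
        occ = fit_mb_occ([Block(X1, "a"), Block(X2, "b")], n_cd=3)
        T = occ.comdim.global_scores
        sd2 = np.einsum(
            "ij,jk,ik->i",
            T - occ.score_mean, occ.score_cov_inv, T - occ.score_mean,
        )
        # the training score closest to the mean has near-minimal SD
        assert sd2.min() >= 0.0
        centroid_blocks = [X1.mean(axis=0), X2.mean(axis=0)]
        # a sample built from the training means projects near the score mean
        d_centroid = occ_distance(occ, centroid_blocks)
        assert d_centroid[0] < np.median(occ_distance(occ, [X1, X2]))

    def test_sample_at_both_limits_has_distance_sqrt2(self):
        """Synthetic SD/OD pair exactly at the two limits combines to
        sqrt(2) under the reduced-distance rule."""
        X1, X2 = random_block(seed=3), random_block(seed=4)
        occ = fit_mb_occ([Block(X1, "a"), Block(X2, "b")], n_cd=2)
        sd = occ.sd_limit_95
        od = occ.od_limit_95
        d = math.sqrt((sd / occ.sd_limit_95) ** 2 + (od / occ.od_limit_95) ** 2)
        assert d == pytest.approx(math.sqrt(2.0))

    def test_occ_distance_matches_manual_recomputation(self):
        X1, X2 = random_block(seed=5), random_block(seed=6)
        occ = fit_mb_occ([Block(X1, "a"), Block(X2, "b")], n_cd=3)
        d = occ_distance(occ, [X1[:7], X2[:7]])
        norm = [
            apply_block_normalization(X1[:7], occ.trained_blocks[0]),
            apply_block_normalization(X2[:7], occ.trained_blocks[1]),
        ]
        T, residuals = project(occ.comdim, norm)
        sd = np.sqrt(np.einsum(
            "ij,jk,ik->i",
            T - occ.score_mean, occ.score_cov_inv, T - occ.score_mean,
        ))
        od = sum(np.sum(R**2, axis=1) for R in residuals)
        expected = np.sqrt(
            (sd / occ.sd_limit_95) ** 2 + (od / occ.od_limit_95) ** 2
        )
        np.testing.assert_allclose(d, expected, atol=1e-12)

    def test_n_cd_must_be_below_target_count(self):
        with pytest.raises(ConfigError, match="target sample count"):
            fit_mb_occ([Block(random_block(n=6), "a")], n_cd=6)

    def test_single_block_occ_agrees_with_simca(self):
        """On one block, the multiblock classifier reduces to SIMCA-like
        behavior: accept/reject decisions agree on >= 95% of samples."""
        from specfuse.simca import fit_simca, reduced_distance

        rng = np.random.default_rng(9)
        agree = total = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            scores = rng.standard_normal((40, 3)) * np.array([3.0, 2.0, 1.5])
            load = rng.standard_normal((3, 30))
            X = scores @ load + 0.3 * rng.standard_normal((40, 30))
            Xc = X - X.mean(axis=0)
            train, test = Xc[:30], np.vstack([Xc[30:], Xc[30:] + 4.0])
            simca = fit_simca(train, 3)
            occ = fit_mb_occ([Block(train, "x")], n_cd=3)
            a1 = reduced_distance(simca, test) <= simca.threshold
            a2 = occ_distance(occ, [test]) <= occ.threshold
            agree += int(np.sum(a1 == a2))
            total += len(test)
        assert agree / total >= 0.95

    def test_evaluate_occ_confusion_counts(self):
        X1, X2 = random_block(seed=7), random_block(seed=8)
        occ = fit_mb_occ([Block(X1, "a"), Block(X2, "b")], n_cd=2,
                         target_label="t")
        far1, far2 = X1[:5] + 30.0, X2[:5] + 30.0
        labels = np.array(["t"] * 5 + ["other"] * 5)
        m = evaluate_occ(
            occ, [np.vstack([X1[:5], far1]), np.vstack([X2[:5], far2])], labels
        )
        assert m.tn == 5 and m.fp == 0
        assert m.tp + m.fn == 5
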