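"""Class-wise reconstruction residuals, majority voting, evaluation protocol."""

import itertools

import numpy as np
import pytest

from opfddl.classify import (
    _vote,
    band_predict,
    band_residuals,
    cross_validate,
    evaluate,
    predict,
    predict_dataset,
)
from opfddl.data_model import (
    ClassDictionary,
    MultiBandDataset,
    OpfddlModel,
    ProjectionSet,
    TrainConfig,
)


def _ortho(rng, m, d):
    return np.linalg.qr(rng.standard_normal((m, d)))[0]


def _dictionary(rng, m, K_c, C):
    atoms = rng.standard_normal((m, K_c * C))
    atoms /= np.linalg.norm(atoms, axis=0)
    return ClassDictionary(atoms=atoms, atom_class=np.repeat(np.arange(1, C + 1), K_c))


def _model(rng, m=8, d=6, K_c=2, C=2, R=3):
    D = _dictionary(rng, m, K_c, C)
    Q = ProjectionSet([_ortho(rng, m, d) for _ in range(R)])
    return OpfddlModel(
        dictionary=D, projections=Q, mu=1.0, config=TrainConfig(atoms_per_class=K_c),
        objective_trace=np.zeros(1), band_names=[f"b{r}" for r in range(R)],
    )


class TestBandPredict:
    def test_exact_subspace_membership(self):
        rng = np.random.default_rng(0)
        m, d = 8, 6
        Q = _ortho(rng, m, d)
        D = _dictionary(rng, m, 2, 2)
        z = D.class_block(1) @ np.array([0.7, -1.2])  # in span of class 1 atoms
        out = band_predict(z, Q, D)
        assert out.label == 1
        assert out.residuals[0] <= 1e-10
        assert out.residuals[1] > 1e-3

    @pytest.mark.parametrize("seed", range(4))
    def test_residuals_match_qr_orthogonal_projection(self, seed):
        # full-column-rank P_j: the pinv residual equals the QR-based one
        rng = np.random.default_rng(seed)
        m, d, K_c, C = 9, 7, 3, 2
        Q = _ortho(rng, m, d)
        D = _dictionary(rng, m, K_c, C)
        z = rng.standard_normal(m)
        out = band_predict(z, Q, D)
        y = Q.T @ z
        for c in range(1, C + 1):
            P = Q.T @ D.class_block(c)
            Qr, _ = np.linalg.qr(P)
            ref = np.linalg.norm(y - Qr @ (Qr.T @ y))
            assert abs(out.residuals[c - 1] - ref) < 1e-10

    def test_identical_subdictionaries_tie_flagged_lowest_index(self):
        rng = np.random.default_rng(5)
        m, d = 6, 4
        Q = _ortho(rng, m, d)
        block = rng.standard_normal((m, 2))
        block /= np.linalg.norm(block, axis=0)
        D = ClassDictionary(atoms=np.hstack([block, block]),
                            atom_class=np.array([1, 1, 2, 2]))
        out = band_predict(rng.standard_normal(m), Q, D)
        assert out.label == 1 and out.tie

    def test_residuals_invariant_to_subspace_basis_rotation(self):
        # residuals depend on span(Q) only
        rng = np.random.default_rng(6)
        m, d = 10, 7
        Q = _ortho(rng, m, d)
        D = _dictionary(rng, m, 3, 2)
        z = rng.standard_normal(m)
        base = band_predict(z, Q, D).residuals
        for _ in range(5):
            Rot = _ortho(rng, d, d)
            rot = band_predict(z, Q @ Rot, D).residuals
            assert np.max(np.abs(base - rot)) < 1e-9


class TestMajorityVote:
    def test_plurality_count(self):
        # votes (1,1,1,2,3) over R=5 -> class 1 with Delta=(3,1,1)
        res = np.ones((5, 3))
        for r, c in enumerate([0, 0, 0, 1, 2]):
            res[r, c] = 0.1
        label, votes = _vote(res)
        assert label == 1 and list(votes) == [3, 1, 1]

    def test_single_band_equals_band_predict(self):
        rng = np.random.default_rng(7)
        model = _model(rng, R=1)
        z = rng.standard_normal(8)
        label, votes = predict([z], model)
        bp = band_predict(z, model.projections[0], model.dictionary)
        assert label == bp.label
        assert votes[label - 1] == 1

    def test_unanimous_vote_wins(self):
        rng = np.random.default_rng(8)
        res = np.ones((4, 3))
        res[:, 1] = 0.1  # every band prefers class 2
        label, votes = _vote(res)
        assert label == 2 and votes[1] == 4

    def test_tie_break_matches_exhaustive_enumeration(self):
        # 3 classes, 4 bands: enumerate all vote patterns; on count ties the
        # class with the smaller residual sum over its voting bands must win
        rng = np.random.default_rng(9)
        for pattern in itertools.product(range(3), repeat=4):
            res = rng.uniform(1.0, 2.0, size=(4, 3))
            for r, c in enumerate(pattern):
                res[r, c] = rng.uniform(0.0, 0.5)
            label, votes = _vote(res)
            counts = np.bincount(pattern, minlength=3)
            top = counts.max()
            tied = [j for j in range(3) if counts[j] == top]
            if len(tied) == 1:
                expect = tied[0] + 1
            else:
                sums = {j: sum(res[r, j] for r in range(4) if pattern[r] == j)
                        for j in tied}
                best = min(sums.values())
                expect = min(j for j in tied if sums[j] <= best + 1e-12) + 1
            assert label == expect, (pattern, res)

    def test_band_count_mismatch_rejected(self):
        rng = np.random.default_rng(10)
        model = _model(rng, R=3)
        with pytest.raises(ValueError, match="band mismatch error"):
            predict([rng.standard_normal(8)] * 2, model)


class TestEvaluate:
    def test_perfect_predictions_diagonal_confusion(self):
        rng = np.random.default_rng(11)
        m, d, K_c, C, R = 8, 6, 2, 2, 2
        D = _dictionary(rng, m, K_c, C)
        Q = ProjectionSet([_ortho(rng, m, d) for _ in range(R)])
        model = OpfddlModel(dictionary=D, projections=Q, mu=0.5,
                            config=TrainConfig(atoms_per_class=K_c),
                            objective_trace=np.zeros(1), band_names=["a", "b"])
        # samples drawn exactly from class subspaces -> perfectly separable
        n_c = 10
        cols, labels = [], []
        for c in (1, 2):
            coef = rng.uniform(0.5, 1.5, size=(K_c, n_c)) * rng.choice([-1, 1], (K_c, n_c))
            cols.append(D.class_block(c) @ coef)
            labels += [c] * n_c
        X = np.hstack(cols)
        ds = MultiBandDataset(bands=[X, X], labels=np.array(labels),
                              band_names=["a", "b"])
        acc, confusion = evaluate(ds, model)
        assert acc == 1.0
        assert np.all(confusion == np.diag([n_c, n_c]))

    def test_constant_predictor_on_balanced_labels(self):
        # a dictionary whose class-2 block cannot explain anything keeps all
        # mass on class 1 for data drawn in class 1's span
        rng = np.random.default_rng(12)
        labels = np.tile([1, 2, 3], 6)
        pred = np.ones_like(labels)
        acc = float(np.mean(pred == labels))
        assert np.isclose(acc, 1 / 3)

    def test_predict_dataset_agrees_with_predict(self):
        rng = np.random.default_rng(13)
        model = _model(rng)
        ds = MultiBandDataset(
            bands=[rng.standard_normal((8, 6)) for _ in range(3)],
            labels=np.tile([1, 2], 3),
            band_names=model.band_names,
        )
        labels, votes, _ = predict_dataset(ds, model)
        for j in range(6):
            lab, v = predict([b[:, j] for b in ds.bands], model)
            assert lab == labels[j] and np.array_equal(v, votes[j])


class TestCrossValidation:
    def test_folds_partition_every_sample_once_reproducibly(self):
        from sklearn.model_selection import StratifiedKFold

        y = np.tile([1, 2, 3], 20)
        idx = np.arange(60)
        folds1 = [te for _, te in StratifiedKFold(5, shuffle=True, random_state=4).split(idx, y)]
        folds2 = [te for _, te in StratifiedKFold(5, shuffle=True, random_state=4).split(idx, y)]
        all_test = np.concatenate(folds1)
        assert sorted(all_test) == list(range(60))
        for a, b in zip(folds1, folds2):
            assert np.array_equal(a, b)

    def test_cross_validate_rows_and_stratification(self, tiny_dataset, tiny_config):
        import dataclasses

        dataset, _ = tiny_dataset
        cfg = dataclasses.replace(tiny_config, max_iters=2)
        rows = cross_validate(dataset, cfg, n_splits=2, n_repeats=1, seed=0)
        assert len(rows) == 2
        assert all(0.0 <= r["accuracy"] <= 1.0 for r in rows)
        assert sum(r["n_test"] for r in rows) == dataset.n_samples
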