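import numpy as np
import pytest
from sklearn.decomposition import PCA

from stepspace.steps import EpochMatrix
from stepspace.template_rds import (
    RDSProjection, TemplateModel, build_template, combine_features, project,
    reconstruct,
)


def random_rows(n, p, seed=0):
    return np.random.default_rng(seed).normal(size=(n, p))


class TestBuildTemplate:
    def test_matches_dense_covariance_eigendecomposition(self):
        rows = random_rows(5, 4, seed=1)
        model = build_template(rows, n_pc=3)
        cov = np.cov(rows, rowvar=False, ddof=1)
        w, v = np.linalg.eigh(cov)
        order = np.argsort(w)[::-1]
        w, v = w[order], v[:, order]
        np.testing.assert_allclose(model.eigenvalues, w[:3], atol=1e-10)
        # subspace agreement: projectors equal
        p_model = model.components.T @ model.components
        p_brute = v[:, :3] @ v[:, :3].T
        assert np.abs(p_model - p_brute).max() < 1e-8

    def test_planted_component_recovered(self):
        rng = np.random.default_rng(4)
        u = rng.normal(size=50)
        u /= np.linalg.norm(u)
        rows = np.outer(rng.normal(0, 5, 200), u) + rng.normal(0, 0.05, (200, 50))
        model = build_template(rows, n_pc=2)
        cos = abs(model.components[0] @ u)
        assert cos > 0.99

    def test_variance_fractions_sum_to_one_at_full_rank(self):
        rows = random_rows(30, 6, seed=2)
        model = build_template(rows, n_pc=6)
        assert model.variance_fraction.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.all(np.diff(model.eigenvalues) <= 1e-12)

    def test_agrees_with_sklearn_pca(self):
        rows = random_rows(40, 12, seed=9)
        model = build_template(rows, n_pc=4)
        sk = PCA(n_components=4).fit(rows)
        np.testing.assert_allclose(model.eigenvalues, sk.explained_variance_,
                                   rtol=1e-10)
        np.testing.assert_allclose(
            np.abs(model.components @ sk.components_.T), np.eye(4), atol=1e-8)

    def test_zero_variance_rejected(self):
        rows = np.tile(np.arange(5.0), (10, 1))
        with pytest.raises(ValueError, match="zero total variance"):
            build_template(rows, n_pc=2)

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            build_template(random_rows(3, 8), n_pc=3)

    def test_sign_convention_deterministic(self):
        rows = random_rows(20, 10, seed=6)
        model = build_template(rows, n_pc=3)
        for comp in model.components:
            assert comp[np.argmax(np.abs(comp))] > 0


class TestProjectReconstruct:
    def test_reference_projections_centered(self):
        rows = random_rows(25, 8, seed=3)
        model = build_template(rows, n_pc=3)
        proj = project(model, rows)
        np.testing.assert_allclose(proj.coords.mean(axis=0), 0, atol=1e-9)

    def test_component_multiple_recovers_coordinates(self):
        rows = random_rows(10, 6, seed=5)
        model = build_template(rows, n_pc=3)
        row = model.mean + 2.0 * model.components[0]
        proj = project(model, row[None, :])
        np.testing.assert_allclose(proj.coords[0], [2.0, 0.0, 0.0], atol=1e-9)

    def test_projecting_mean_gives_zero(self):
        model = build_template(random_rows(10, 6), n_pc=2)
        proj = project(model, model.mean[None, :])
        np.testing.assert_allclose(proj.coords, 0, atol=1e-12)

    def test_full_rank_round_trip(self):
        rows = random_rows(10, 6, seed=7)
        model = build_template(rows, n_pc=6)
        back = reconstruct(model, project(model, rows))
        assert np.abs(back - rows).max() < 1e-8

    def test_zero_coordinates_reconstruct_mean(self):
        model = build_template(random_rows(10, 6), n_pc=3)
        out = reconstruct(model, np.zeros((1, 3)))
        np.testing.assert_allclose(out[0], model.mean)

    def test_truncation_error_equals_discarded_eigenvalues(self):
        rows = random_rows(40, 10, seed=8)
        full = build_template(rows, n_pc=10)
        model = build_template(rows, n_pc=3)
        recon = reconstruct(model, project(model, rows))
        mse = np.sum((rows - recon) ** 2) / (rows.shape[0] - 1)
        discarded = full.eigenvalues[3:].sum()
        assert mse == pytest.approx(discarded, abs=1e-8)

    def test_projection_linearity_in_offset(self):
        rows = random_rows(12, 7, seed=10)
        model = build_template(rows, n_pc=3)
        c = np.random.default_rng(1).normal(size=7)
        shifted = project(model, rows + c).coords
        base = project(model, rows).coords
        np.testing.assert_allclose(shifted - base,
                                   np.tile(model.components @ c, (12, 1)),
                                   atol=1e-9)

    def test_length_mismatch_rejected(self):
        model = build_template(random_rows(10, 6), n_pc=2)
        with pytest.raises(ValueError, match="length"):
            project(model, np.zeros((2, 5)))
        with pytest.raises(ValueError, match="n_pc"):
            reconstruct(model, np.zeros((2, 3)))


class TestSerialization:
    def test_json_round_trip(self, tmp_path):
        em = EpochMatrix("lumbar", "left", "acceleration",
                         random_rows(10, 9, seed=12), np.arange(10))
        model = build_template(em, n_pc=3)
        path = tmp_path / "template.json"
        model.to_json(path)
        back = TemplateModel.from_json(path)
        np.testing.assert_allclose(back.components, model.components)
        np.testing.assert_allclose(back.mean, model.mean)
        assert back.sensor == "lumbar" and back.scope == "cohort"


class TestCombineFeatures:
    def _proj(self, coords, ids):
        return RDSProjection(np.asarray(coords, float), np.asarray(ids))

    def test_blocks_concatenated_acc_first(self):
        acc = self._proj([[1, 2, 3], [4, 5, 6]], [10, 20])
        vel = self._proj([[7, 8, 9], [1, 1, 1]], [10, 20])
        out = combine_features(acc, vel)
        assert out.shape == (2, 6)
        np.testing.assert_array_equal(out[0], [1, 2, 3, 7, 8, 9])

    def test_empty_projections_give_empty_output(self):
        acc = self._proj(np.zeros((0, 3)), [])
        vel = self._proj(np.zeros((0, 3)), [])
        assert combine_features(acc, vel).shape[0] == 0

    def test_step_id_mismatch_rejected(self):
        acc = self._proj([[1, 2, 3]], [10])
        vel = self._proj([[1, 2, 3]], [11])
        with pytest.raises(ValueError, match="step ids"):
            combine_features(acc, vel)
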