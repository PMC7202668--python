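import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate

from popdim.information import (
    DegenerateNoiseError,
    information,
    nearest_centroid_mahalanobis,
    pairing_report,
    predicted_error,
    principal_angle,
    project,
    stacked_projection,
)


class TestProjection:
    def test_unit_projection(self):
        rng = np.random.default_rng(0)
        w = rng.standard_normal(8)
        basis = np.stack([w, np.zeros(8)], axis=1)
        x = np.stack([w / (w @ w), np.zeros(8)], axis=1)
        z = project(x, basis)
        assert z[0] == pytest.approx(1.0)
        assert z[1] == pytest.approx(0.0)

    def test_orthogonal_activity_projects_to_zero(self):
        basis = np.eye(6)[:, :2]
        x = np.zeros((6, 2))
        x[5, :] = 3.0
        np.testing.assert_allclose(project(x, basis), 0.0)

    def test_preserves_inner_products_with_subspace_elements(self):
        rng = np.random.default_rng(1)
        q = np.linalg.qr(rng.standard_normal((10, 2)))[0]
        x = rng.standard_normal((10, 5, 2))
        z = project(x, q)
        # activity component inside the subspace is fully recovered per bin
        for b in range(2):
            np.testing.assert_allclose(z[:, b], x[:, :, b].T @ q[:, b])

    def test_stacked_projection_is_sum_of_bins(self):
        rng = np.random.default_rng(2)
        basis = rng.standard_normal((7, 2))
        x = rng.standard_normal((7, 4, 2))
        np.testing.assert_allclose(stacked_projection(x, basis),
                                   project(x, basis).sum(axis=1))

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError):
            project(np.zeros((5, 2)), np.zeros((6, 2)))


class TestInformation:
    def test_one_d_gaussian_closed_form(self):
        rng = np.random.default_rng(3)
        n = 10_000
        x1 = rng.normal(0.0, 1.0, size=(n, 1))
        x2 = rng.normal(2.0, 1.0, size=(n, 1))
        res = information((x1, x2), np.array([1.0]))
        assert res.information == pytest.approx(4.0, abs=0.25)

    def test_orthogonal_direction_carries_no_information(self):
        rng = np.random.default_rng(4)
        n = 4000
        mu = np.array([2.0, 0.0])
        x1 = rng.standard_normal((n, 2)) - mu / 2
        x2 = rng.standard_normal((n, 2)) + mu / 2
        res = information((x1, x2), np.array([0.0, 1.0]))
        assert res.information == pytest.approx(0.0, abs=0.01)
        assert res.predicted_error == pytest.approx(0.5, abs=0.02)

    def test_invariant_to_rescaling_of_direction(self):
        rng = np.random.default_rng(5)
        x1 = rng.standard_normal((50, 3))
        x2 = rng.standard_normal((50, 3)) + 1
        w = np.array([1.0, -2.0, 0.5])
        a = information((x1, x2), w).information
        b = information((x1, x2), 7.3 * w).information
        assert a == pytest.approx(b, rel=1e-12)

    def test_zero_direction_rejected(self):
        with pytest.raises(ValueError):
            information((np.ones((3, 2)), np.ones((3, 2))), np.zeros(2))

    def test_degenerate_noise_raises(self):
        x1 = np.ones((5, 1))
        x2 = 2 * np.ones((5, 1))
        with pytest.raises(DegenerateNoiseError):
            information((x1, x2), np.array([1.0]))

    def test_optimal_direction_matches_fisher_information(self):
        # with w = Q^-1 dmu the measure equals dmu' Q^-1 dmu
        rng = np.random.default_rng(6)
        a = rng.standard_normal((3, 3))
        q = a @ a.T + np.eye(3)
        dmu = np.array([1.0, -0.5, 0.3])
        fisher = dmu @ np.linalg.solve(q, dmu)
        n = 40_000
        chol = np.linalg.cholesky(q)
        x1 = rng.standard_normal((n, 3)) @ chol.T
        x2 = x1 * 0 + rng.standard_normal((n, 3)) @ chol.T + dmu
        res = information((x1, x2), np.linalg.solve(q, dmu))
        assert res.information == pytest.approx(fisher, rel=0.05)


class TestPredictedError:
    def test_zero_information_gives_chance(self):
        assert predicted_error(0.0) == 0.5

    def test_matches_quadrature_of_gaussian_tail(self):
        val, _ = integrate.quad(
            lambda y: np.exp(-y**2 / 2) / np.sqrt(2 * np.pi),
            np.sqrt(4.0) / 2, np.inf)
        assert predicted_error(4.0) == pytest.approx(val, abs=1e-6)
        assert predicted_error(4.0) == pytest.approx(0.15866, abs=1e-5)

    def test_large_information_limit(self):
        assert predicted_error(1e4) < 1e-10

    @settings(max_examples=40, deadline=None)
    @given(st.floats(0.0, 100.0), st.floats(0.001, 10.0))
    def test_strictly_decreasing(self, i, di):
        assert predicted_error(i + di) < predicted_error(i)

    def test_negative_information_rejected(self):
        with pytest.raises(ValueError):
            predicted_error(-0.1)


class TestPrincipalAngle:
    def test_identical_subspaces(self):
        rng = np.random.default_rng(7)
        w = rng.standard_normal((20, 2))
        assert principal_angle(w, 3.0 * w) == pytest.approx(0.0, abs=1e-6)

    def test_orthogonal_subspaces(self):
        assert principal_angle(np.eye(6)[:, :2], np.eye(6)[:, 2:4]) == \
            pytest.approx(90.0)

    def test_random_subspaces_concentrate_near_orthogonal(self):
        rng = np.random.default_rng(8)
        angles = [principal_angle(rng.standard_normal((500, 2)),
                                  rng.standard_normal((500, 2)))
                  for _ in range(50)]
        assert np.mean(angles) > 80.0

    def test_zero_basis_rejected(self):
        with pytest.raises(ValueError):
            principal_angle(np.zeros((5, 2)), np.eye(5)[:, :2])


class TestDecodeCore:
    def _clouds(self, rng, mu, n=200, d=4):
        z1 = rng.standard_normal((n, d)) - mu / 2
        z2 = rng.standard_normal((n, d)) + mu / 2
        z = np.vstack([z1, z2])
        lab = np.repeat([1, 2], n)
        return z, lab

    def test_separated_clouds_decode_well(self):
        rng = np.random.default_rng(9)
        mu = np.zeros(4)
        mu[0] = 4.0
        z, lab = self._clouds(rng, mu)
        res = nearest_centroid_mahalanobis(z, lab, np.eye(4))
        assert res.fraction_correct > 0.95

    def test_identity_and_matched_covariance_agree_on_isotropic_noise(self):
        rng = np.random.default_rng(10)
        mu = np.zeros(4)
        mu[0] = 2.0
        z, lab = self._clouds(rng, mu)
        a = nearest_centroid_mahalanobis(z, lab, np.eye(4)).fraction_correct
        b = nearest_centroid_mahalanobis(z, lab, 3.7 * np.eye(4)).fraction_correct
        assert a == b  # scale-invariant metric

    def test_rotation_within_subspace_preserves_accuracy(self):
        """Re-estimating boundaries after projection makes decoding invariant
        to rotations of the class means inside the source subspace, while a
        move into the orthogonal complement drives accuracy to chance."""
        rng = np.random.default_rng(11)
        dim = 12
        basis = np.linalg.qr(rng.standard_normal((dim, 2)))[0]
        v = rng.standard_normal(dim)
        v -= basis @ (basis.T @ v)          # true orthogonal complement
        ortho = (v / np.linalg.norm(v))[:, None]

        def run(mean_dir):
            x1 = rng.standard_normal((dim, 150)) - mean_dir[:, None] / 2
            x2 = rng.standard_normal((dim, 150)) + mean_dir[:, None] / 2
            x = np.stack([np.concatenate([x1, x2], axis=1)] * 2, axis=2)
            z = project(x, basis)
            lab = np.repeat([1, 2], 150)
            return nearest_centroid_mahalanobis(z, lab, np.eye(2)).fraction_correct

        v = 4.0 * basis[:, 0]
        rotated = 4.0 * basis[:, 1]          # 90 degrees, still in-subspace
        outside = 4.0 * ortho[:, 0]
        acc_v, acc_rot, acc_out = run(v), run(rotated), run(outside)
        assert acc_v > 0.9 and acc_rot > 0.9
        assert abs(acc_v - acc_rot) < 0.05
        assert abs(acc_out - 0.5) < 0.07


class TestPairingReport:
    def test_within_decoding_lands_in_calibrated_band(self, default_session):
        session, _ = default_session
        rep = pairing_report(session, pairings=("within",))
        for cond in ("What", "Where"):
            frac = rep.loc[rep.condition == cond, "fraction_correct"].mean()
            assert 0.7 < frac < 0.95

    def test_identity_covariance_gives_similar_accuracy(self, default_session):
        # replacing the pooled noise covariance by the identity changes
        # decoding only marginally
        from popdim.information import _Cells, _projection_tables, _q_loo
        from popdim.subspaces import build_W, usable_blocks

        session, _ = default_session
        blocks = usable_blocks(session)[:8]
        w = build_W(session, blocks)
        cells = _Cells(session, blocks, "choice", 5)
        zmap, ss, df = _projection_tables(cells, w)
        diffs = []
        for target in cells.cells[:8]:
            for src in cells.sources(target, "x-block")[:3]:
                z = zmap[src][target]
                lab = cells.labels[target]
                q = _q_loo(ss[src], df[src], exclude_block=target[0])
                a = nearest_centroid_mahalanobis(z, lab, q).fraction_correct
                b = nearest_centroid_mahalanobis(z, lab, np.eye(2)).fraction_correct
                diffs.append(abs(a - b))
        assert np.mean(diffs) < 0.1

    def test_single_pairing_table_consistency(self, default_session):
        from popdim.information import decode
        session, _ = default_session
        rep = pairing_report(session, pairings=("within",))
        one = decode(session, "within",
                     target=(int(rep.block_id.iloc[0]), rep.phase.iloc[0]))
        assert one["fraction_correct"].iloc[0] == pytest.approx(
            rep["fraction_correct"].iloc[0])
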