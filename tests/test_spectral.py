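import numpy as np
import pandas as pd
import pytest

from cyclicity import (
    LeadMatrix,
    QuadraticForm,
    average_rank,
    dominance_ratio,
    eigendecompose,
    elliptic_rank,
    fit_ellipse,
    lead_matrix,
    leading_constellation,
    normalize,
    ordering_histogram,
    phase_order,
)
from cyclicity.exceptions import (
    DegenerateConstellationError,
    NotSkewSymmetricError,
    ValidationError,
)
from cyclicity.replicate import coom_recording, cyclic_order_matches
from cyclicity.spectral import Constellation


def _lm(entries, labels=None):
    entries = np.asarray(entries, dtype=float)
    labels = labels or [f"c{i}" for i in range(entries.shape[0])]
    return LeadMatrix(entries=entries, channel_labels=labels)


def _constellation(points, labels=None):
    points = np.asarray(points, dtype=complex)
    labels = labels or [f"c{i}" for i in range(points.size)]
    return Constellation(
        points=points,
        channel_labels=labels,
        eigenvalue_magnitude=1.0,
        orientation_reference=(labels[0], labels[1]),
    )


class TestEigendecompose:
    def test_rank2_outer_product_matrix(self):
        u = np.array([1.0, 0.0, 0.0])
        v = np.array([0.0, 1.0, 0.0])
        Q = np.outer(u, v) - np.outer(v, u)
        d = eigendecompose(_lm(Q))
        np.testing.assert_allclose(d.eigenvalue_magnitudes, [1.0, 0.0], atol=1e-12)
        w = d.eigenvectors[:, 0]
        # eigenvector of +i spanned by (-i, 1, 0): check Q w = i w
        np.testing.assert_allclose(Q @ w, 1j * w, atol=1e-12)

    def test_zero_matrix_and_odd_dimension(self):
        d = eigendecompose(_lm(np.zeros((3, 3))))
        np.testing.assert_allclose(d.eigenvalue_magnitudes, [0.0, 0.0])

    def test_random_skew_spectrum_is_imaginary_conjugate_pairs(self):
        rng = np.random.default_rng(0)
        M = rng.normal(size=(6, 6))
        A = M - M.T
        d = eigendecompose(_lm(A))
        assert d.eigenvalue_magnitudes.size == 3
        full = np.linalg.eigvals(A)
        assert np.max(np.abs(full.real)) <= 1e-9 * np.max(np.abs(full))
        for s in range(3):
            lam = 1j * d.eigenvalue_magnitudes[s]
            w = d.eigenvectors[:, s]
            np.testing.assert_allclose(A @ w, lam * w, atol=1e-9)

    def test_rank2_eigenvalue_is_sin_theta_u_v(self):
        rng = np.random.default_rng(7)
        u, v = rng.normal(size=(2, 5))
        Q = np.outer(u, v) - np.outer(v, u)
        cos_t = u @ v / (np.linalg.norm(u) * np.linalg.norm(v))
        expected = np.sqrt(1 - cos_t**2) * np.linalg.norm(u) * np.linalg.norm(v)
        d = eigendecompose(_lm(Q))
        assert d.eigenvalue_magnitudes[0] == pytest.approx(expected, abs=1e-9)

    def test_non_skew_input_rejected(self):
        with pytest.raises(NotSkewSymmetricError):
            eigendecompose(_lm(np.eye(3)))


class TestDominanceRatio:
    def test_arithmetic_and_rank2_sentinel(self):
        rng = np.random.default_rng(1)
        M = rng.normal(size=(4, 4))
        d = eigendecompose(_lm(M - M.T))
        expected = d.eigenvalue_magnitudes[0] / d.eigenvalue_magnitudes[1]
        assert dominance_ratio(d) == pytest.approx(expected)
        u, v = rng.normal(size=(2, 4))
        d2 = eigendecompose(_lm(np.outer(u, v) - np.outer(v, u)))
        assert dominance_ratio(d2) == np.inf

    def test_needs_at_least_four_channels(self):
        d = eigendecompose(_lm(np.zeros((3, 3))))
        with pytest.raises(ValidationError):
            dominance_ratio(d)


class TestLeadingConstellation:
    def test_two_channel_leader_precedes_follower(self):
        rec, _ = coom_recording(0, n=2, snr=None)
        A = lead_matrix(normalize(rec))
        con = leading_constellation(A)
        k, l = con.orientation_reference
        angle = np.angle(con.point(l) / con.point(k))
        assert np.sign(angle) == np.sign(A.entry(k, l))

    def test_never_returns_the_conjugate_orientation(self):
        rec, _ = coom_recording(3, n=6, snr=None)
        A = lead_matrix(normalize(rec))
        con = leading_constellation(A)
        k, l = con.orientation_reference
        conj_angle = np.angle(np.conj(con.point(l)) / np.conj(con.point(k)))
        assert np.sign(conj_angle) != np.sign(A.entry(k, l))

    def test_cyclic_order_matches_planted_offsets(self):
        for seed in range(5):
            rec, spec = coom_recording(seed, n=10, snr=None)
            A = lead_matrix(normalize(rec))
            con = leading_constellation(A)
            recovered = [
                con.channel_labels[i]
                for i in np.argsort(np.angle(con.points), kind="stable")
            ]
            planted = [
                rec.channel_labels[i]
                for i in np.argsort(spec.offsets, kind="stable")
            ]
            assert cyclic_order_matches(recovered, planted)

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(DegenerateConstellationError):
            leading_constellation(_lm(np.zeros((4, 4))))


class TestFitEllipse:
    def test_circle_radius_two(self):
        ang = np.linspace(0, 2 * np.pi, 17)[:-1]
        q = fit_ellipse(2.0 * np.exp(1j * ang))
        assert (q.a, q.b, q.c) == pytest.approx((0.25, 0.0, 1 / 4), abs=1e-9)
        assert not q.degenerate

    def test_axis_aligned_ellipse(self):
        ang = np.linspace(0, 2 * np.pi, 23)[:-1]
        pts = 2.0 * np.cos(ang) + 1j * np.sin(ang)  # x^2/4 + y^2 = 1
        q = fit_ellipse(pts)
        assert (q.a, q.b, q.c) == pytest.approx((0.25, 0.0, 1.0), abs=1e-9)

    def test_generic_ellipse_recovered_exactly(self):
        A = np.array([[0.7, 0.2], [0.2, 1.9]])
        L = np.linalg.cholesky(np.linalg.inv(A))
        ang = np.linspace(0, 2 * np.pi, 31)[:-1]
        xy = L @ np.vstack([np.cos(ang), np.sin(ang)])
        q = fit_ellipse(xy[0] + 1j * xy[1])
        np.testing.assert_allclose(q.matrix, A, atol=1e-9)

    def test_collinear_points_flagged_but_positive_definite(self):
        pts = np.array([1 + 1j, 2 + 2j, -1 - 1j, 0.5 + 0.5j])
        q = fit_ellipse(pts)
        assert q.degenerate
        assert q.is_positive_definite()

    def test_too_few_points(self):
        with pytest.raises(ValidationError):
            fit_ellipse(np.array([1 + 0j, 0 + 1j]))


class TestEllipticRank:
    def test_euclidean_case_orders_by_radius(self):
        con = _constellation([3.0, 2.0j, -1.0], ["x", "y", "z"])
        df = elliptic_rank(con, QuadraticForm(1.0, 0.0, 1.0))
        assert df.set_index("channel")["rank"].to_dict() == {"x": 1, "y": 2, "z": 3}

    def test_elliptic_metric_beats_euclidean(self):
        con = _constellation([1.0 + 0j, 1.5j], ["p", "q"])
        df = elliptic_rank(con, QuadraticForm(4.0, 0.0, 1.0))
        by = df.set_index("channel")
        assert by.loc["p", "norm"] == pytest.approx(2.0)
        assert by.loc["q", "norm"] == pytest.approx(1.5)
        assert by.loc["p", "rank"] == 1

    def test_ties_broken_by_label(self):
        con = _constellation([1.0, 1.0, 1.0], ["b", "a", "c"])
        df = elliptic_rank(con, QuadraticForm(1.0, 0.0, 1.0))
        assert df.set_index("channel")["rank"].to_dict() == {"a": 1, "b": 2, "c": 3}


class TestAverageRank:
    def _ranking(self, mapping):
        return pd.DataFrame(
            {"channel": list(mapping), "norm": 0.0, "rank": list(mapping.values())}
        )

    def test_mean_of_ranks(self):
        out = average_rank(
            [self._ranking({"u": 1, "v": 2}), self._ranking({"u": 3, "v": 1})]
        )
        assert out.set_index("channel")["mean_rank"].to_dict() == {"v": 1.5, "u": 2.0}

    def test_identical_rankings_keep_common_order(self):
        r = self._ranking({"a": 2, "b": 1, "c": 3})
        out = average_rank([r, r, r])
        assert list(out["channel"]) == ["b", "a", "c"]

    def test_reversed_rankings_tie_broken_by_label(self):
        out = average_rank(
            [self._ranking({"m": 1, "z": 2}), self._ranking({"m": 2, "z": 1})]
        )
        assert list(out["channel"]) == ["m", "z"]

    def test_channel_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            average_rank([self._ranking({"a": 1}), self._ranking({"b": 1})])


class TestPhaseOrder:
    def test_identity_when_centroid_already_positive_real(self):
        con = _constellation([2.0 + 0.1j, 2.0 - 0.1j, 3.0], ["u", "v", "w"])
        po = phase_order(con)
        assert po.rotation == pytest.approx(0.0, abs=1e-12)
        assert po.channels == ["v", "w", "u"]
        assert np.all(np.diff(po.phases) >= 0)

    def test_coom_offsets_in_half_circle_recovered_in_order(self):
        from cyclicity import CoomSpec, FourierSeed, coom_series, lead_matrix

        offsets = np.linspace(0.0, np.pi * 0.9, 10)
        spec = CoomSpec(
            n=10, amplitudes=np.ones(10), offsets=offsets,
            seed_function=FourierSeed([0.5]), omega=2 * np.pi / 50,
            duration=200.0, dt=0.1,
        )
        rec = coom_series(spec)
        con = leading_constellation(lead_matrix(normalize(rec)))
        po = phase_order(con)
        assert po.channels == rec.channel_labels

    def test_global_rotation_leaves_ordering_unchanged(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=8) + 1j * rng.normal(size=8) + 3.0
        con = _constellation(pts)
        base = phase_order(con).channels
        for rot in (0.5, 2.0, -1.3):
            rotated = _constellation(pts * np.exp(1j * rot))
            assert phase_order(rotated).channels == base

    def test_centroid_at_origin_rejected(self):
        con = _constellation([1.0, -1.0, 1j, -1j])
        with pytest.raises(DegenerateConstellationError):
            phase_order(con)


class TestOrderingHistogram:
    def test_identical_orderings_give_permutation_matrix(self):
        rec, _ = coom_recording(0, n=6, snr=None)
        con = leading_constellation(lead_matrix(normalize(rec)))
        po = phase_order(con, keep=sorted(rec.channel_labels))
        H = ordering_histogram([po] * 5)
        assert set(np.unique(H.to_numpy())) == {0.0, 1.0}
        np.testing.assert_allclose(H.sum(axis=1), 1.0)

    def test_modal_positions_match_ground_truth_under_noise(self):
        orderings = []
        for seed in range(30):
            rec, spec = coom_recording(
                seed, n=6, snr=10.0, duration=400.0, dt=0.72, min_separation=0.6
            )
            con = leading_constellation(lead_matrix(normalize(rec)))
            # restrict to a half-plane subset so the centroid rotation is
            # well defined: keep the 4 earliest-offset channels
            keep = sorted(
                np.array(rec.channel_labels)[np.argsort(spec.offsets)][:4]
            )
            orderings.append(phase_order(con, keep=keep))
        H = ordering_histogram(orderings)
        modal = H.to_numpy().argmax(axis=1) + 1
        mean_pos = (H.to_numpy() * np.arange(1, 5)).sum(axis=1)
        assert np.all(np.diff(mean_pos) >= 0)
        assert np.all(np.diff(modal) >= 0)
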