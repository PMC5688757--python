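"""Watershed segmentation, intensity measurement and ± classification."""

import numpy as np
import pytest

from retinamech import profile_segmentation as ps
from retinamech.profile_segmentation import ProfileLabel
from retinamech.surface_projection import Projection2D


def proj(image, px=1.0):
    return Projection2D(np.asarray(image, float), "ch", 2.0, px)


class TestSegment:
    def test_single_seed_blank_image_covers_field(self):
        p = ps.segment_profiles(proj(np.zeros((10, 12))), [(5.0, 4.0)])
        assert len(p) == 1 and p[0].pixel_mask.all()

    def test_bright_wall_splits_two_seeds(self):
        img = np.zeros((20, 21))
        img[:, 10] = 1.0
        profs = ps.segment_profiles(proj(img), [(4.0, 10.0), (16.0, 10.0)])
        assert len(profs) == 2
        # the shared boundary must hug the wall: each region stays on its side
        left = profs[0].pixel_mask
        cols = np.nonzero(left.any(axis=0))[0]
        assert cols.max() <= 10 and not left[:, 11:].any()

    def test_lattice_round_trip_one_region_per_site(self, lattice, membrane_stack):
        from retinamech import surface_projection as sp
        surf = sp.reconstruct_olm_surface(membrane_stack, "ZO1")
        boundary = sp.project_at_surface(membrane_stack, "ZO1", surf)
        profs = ps.segment_profiles(boundary, lattice.positions)
        assert len(profs) == lattice.n_sites
        cents = np.array([p.centroid for p in profs])
        err = np.linalg.norm(cents - lattice.positions, axis=1)
        assert np.median(err) <= boundary.pixel_size * 2

    def test_seed_on_excluded_pixel_dropped_with_warning(self):
        img = np.zeros((10, 10))
        excl = np.zeros((10, 10), bool)
        excl[0:3, 0:3] = True
        with pytest.warns(UserWarning):
            profs = ps.segment_profiles(
                proj(img), [(1.0, 1.0), (7.0, 7.0)], exclusion_mask=excl
            )
        assert len(profs) == 1

    def test_no_usable_seeds_rejected(self):
        excl = np.ones((10, 10), bool)
        with pytest.raises(ValueError), pytest.warns(UserWarning):
            ps.segment_profiles(proj(np.zeros((10, 10))), [(5.0, 5.0)],
                                exclusion_mask=excl)

    def test_regions_tile_field_without_overlap(self, lattice, membrane_stack):
        from retinamech import surface_projection as sp
        surf = sp.reconstruct_olm_surface(membrane_stack, "ZO1")
        boundary = sp.project_at_surface(membrane_stack, "ZO1", surf)
        profs = ps.segment_profiles(boundary, lattice.positions)
        total = np.zeros(boundary.image.shape, int)
        for p in profs:
            total += p.pixel_mask
        assert np.all(total == 1)


class TestMeasure:
    def _two_profiles(self):
        img = np.zeros((8, 8))
        img[:, 4] = 1.0
        return ps.segment_profiles(proj(img), [(1.0, 4.0), (7.0, 4.0)])

    def test_uniform_reporter_gives_constant_mean(self):
        profs = ps.measure_intensity(self._two_profiles(), proj(np.full((8, 8), 3.5)))
        assert all(p.mean_intensity["ch"] == pytest.approx(3.5) for p in profs)

    def test_indicator_reporter_selects_one_profile(self):
        profs = self._two_profiles()
        rep = np.zeros((8, 8))
        rep[profs[0].pixel_mask] = 1.0
        ps.measure_intensity(profs, proj(rep))
        assert profs[0].mean_intensity["ch"] == pytest.approx(1.0)
        assert profs[1].mean_intensity["ch"] == pytest.approx(0.0)

    def test_means_match_bruteforce_sums(self, lattice, membrane_stack):
        from retinamech import surface_projection as sp
        surf = sp.reconstruct_olm_surface(membrane_stack, "ZO1")
        boundary = sp.project_at_surface(membrane_stack, "ZO1", surf)
        profs = ps.segment_profiles(boundary, lattice.positions)
        ps.measure_intensity(profs, boundary)
        for p in profs[::17]:
            rows, cols = np.nonzero(p.pixel_mask)
            brute = sum(boundary.image[r, c] for r, c in zip(rows, cols)) / len(rows)
            assert p.mean_intensity["ZO1"] == pytest.approx(brute, rel=1e-12)


class TestClassify:
    def _profiles_with(self, values):
        profs = []
        for i, v in enumerate(values):
            m = np.zeros((1, len(values)), bool)
            m[0, i] = True
            p = ps.CellProfile(i, m, np.array([i, 0.0]), 1.0)
            p.mean_intensity["ch"] = float(v)
            profs.append(p)
        return profs

    def test_bimodal_intensities_split_correctly(self):
        vals = [0.1] * 10 + [0.9] * 10
        profs = ps.classify_kmeans(self._profiles_with(vals), "ch")
        labels = [p.label for p in profs]
        assert labels[:10] == [ProfileLabel.NEGATIVE] * 10
        assert labels[10:] == [ProfileLabel.POSITIVE] * 10

    def test_order_invariance(self):
        rng = np.random.default_rng(4)
        vals = np.r_[rng.normal(0.1, 0.02, 15), rng.normal(0.8, 0.05, 7)]
        perm = rng.permutation(len(vals))
        a = ps.classify_kmeans(self._profiles_with(vals), "ch")
        b = ps.classify_kmeans(self._profiles_with(vals[perm]), "ch")
        la = np.array([p.label is ProfileLabel.POSITIVE for p in a])
        lb = np.array([p.label is ProfileLabel.POSITIVE for p in b])
        np.testing.assert_array_equal(la[perm], lb)

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_solver_matches_bruteforce_partition(self, seed):
        """The default classifier must find the SSE-optimal 1D 2-partition,
        verified by exhaustive search over all sorted splits."""
        rng = np.random.default_rng(seed)
        vals = rng.random(18)
        profs = ps.classify_kmeans(self._profiles_with(vals), "ch")
        got = frozenset(i for i, p in enumerate(profs)
                        if p.label is ProfileLabel.POSITIVE)
        order = np.argsort(vals)
        best, best_set = np.inf, None
        for k in range(1, len(vals)):
            lo, hi = vals[order[:k]], vals[order[k:]]
            sse = ((lo - lo.mean()) ** 2).sum() + ((hi - hi.mean()) ** 2).sum()
            if sse < best:
                best, best_set = sse, frozenset(order[k:].tolist())
        assert got == best_set

    def test_identical_intensities_rejected(self):
        with pytest.raises(ValueError):
            ps.classify_kmeans(self._profiles_with([0.5] * 6), "ch")

    def test_sklearn_backend_agrees_on_separated_data(self):
        vals = [0.05] * 8 + [0.95] * 4
        a = ps.classify_kmeans(self._profiles_with(vals), "ch", method="exact")
        b = ps.classify_kmeans(self._profiles_with(vals), "ch", method="kmeans")
        assert [p.label for p in a] == [p.label for p in b]


class TestRatio:
    def test_arithmetic(self):
        profs = []
        for i in range(780):
            p = ps.CellProfile(i, np.ones((1, 1), bool), np.zeros(2), 1.0)
            p.label = ProfileLabel.POSITIVE if i < 130 else ProfileLabel.NEGATIVE
            profs.append(p)
        r = ps.compute_ratio(profs)
        assert r.ratio == (1.0, 5.0)
        assert (r.n_positive, r.n_negative) == (130, 650)

    def test_conservation_and_excluded_not_counted(self):
        profs = []
        for i, lab in enumerate([ProfileLabel.POSITIVE] * 3 +
                                [ProfileLabel.NEGATIVE] * 5 +
                                [ProfileLabel.EXCLUDED] * 2):
            p = ps.CellProfile(i, np.ones((1, 1), bool), np.zeros(2), 1.0)
            p.label = lab
            profs.append(p)
        r = ps.compute_ratio(profs)
        assert r.n_positive + r.n_negative + r.n_excluded == len(profs)
        assert r.ratio == (1.0, 5 / 3)

    def test_zero_positive_rejected(self):
        p = ps.CellProfile(0, np.ones((1, 1), bool), np.zeros(2), 1.0)
        p.label = ProfileLabel.NEGATIVE
        with pytest.raises(ValueError):
            ps.compute_ratio([p])
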