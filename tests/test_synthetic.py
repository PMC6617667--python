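import math

import numpy as np
import pytest

from conftest import SQRT3
from l1npi.cloud_io import pairwise_distances, read_xyz_frames, write_xyz_frames
from l1npi.synthetic import (
    GeneratorSpec,
    generate_ensemble,
    make_hexagon,
    make_lattice_box,
    make_noisy_circle,
    make_pair,
    make_square,
    make_torus_sample,
)


def offdiag(cloud):
    d = pairwise_distances(cloud).d
    return d[np.triu_indices_from(d, k=1)]


class TestExactFixtures:
    @pytest.mark.parametrize("d", [1.0, 2.5])
    def test_hexagon_distance_spectrum(self, d):
        dist = offdiag(make_hexagon(d))
        expected = sorted([d] * 6 + [SQRT3 * d] * 6 + [2 * d] * 3)
        np.testing.assert_allclose(sorted(dist), expected, atol=1e-12)

    def test_hexagon_centroid_at_origin(self):
        np.testing.assert_allclose(make_hexagon(1.0).coords.mean(axis=0), 0, atol=1e-12)

    def test_square_and_pair(self):
        sq = offdiag(make_square(2.0))
        np.testing.assert_allclose(sorted(sq), [2, 2, 2, 2, 2 * math.sqrt(2), 2 * math.sqrt(2)])
        assert offdiag(make_pair(0.8))[0] == pytest.approx(0.8)

    def test_invalid_spacings(self):
        for fn in (make_hexagon, make_square, make_pair):
            with pytest.raises(ValueError):
                fn(-1.0)


class TestCircleAndTorus:
    def test_zero_noise_is_exact_radius(self):
        cloud = make_noisy_circle(50, radius=2.0, noise_sd=0.0, seed=5)
        radii = np.linalg.norm(cloud.coords[:, :2], axis=1)
        np.testing.assert_allclose(radii, 2.0, atol=1e-12)
        assert np.all(cloud.coords[:, 2] == 0)

    def test_seed_determinism(self):
        a = make_noisy_circle(30, 1.0, 0.1, seed=7)
        b = make_noisy_circle(30, 1.0, 0.1, seed=7)
        np.testing.assert_array_equal(a.coords, b.coords)
        c = make_noisy_circle(30, 1.0, 0.1, seed=8)
        assert not np.array_equal(a.coords, c.coords)

    def test_min_points(self):
        with pytest.raises(ValueError, match="at least 3"):
            make_noisy_circle(2)

    def test_torus_points_lie_on_surface(self):
        R, r = 2.5, 1.0
        cloud = make_torus_sample(R, r, 200, seed=3)
        xy = np.linalg.norm(cloud.coords[:, :2], axis=1)
        dist_to_core = np.sqrt((xy - R) ** 2 + cloud.coords[:, 2] ** 2)
        np.testing.assert_allclose(dist_to_core, r, atol=1e-9)

    def test_torus_tiny_sample_ok(self):
        assert make_torus_sample(2.0, 0.5, 4, seed=0).n_points == 4

    def test_self_intersecting_torus_rejected(self):
        with pytest.raises(ValueError, match="self-intersect"):
            make_torus_sample(1.0, 1.0, 10)


class TestLattice:
    def test_diamond_nearest_neighbour_closed_form(self):
        a = 6.4
        cloud = make_lattice_box("diamond", 2, a, jitter_sd=0.0, subsample_fraction=1.0)
        assert cloud.n_points == 64
        d = offdiag(cloud)
        assert d.min() == pytest.approx(a * SQRT3 / 4)
        np.testing.assert_allclose(cloud.box, 2 * a)

    def test_cubic_nearest_neighbour(self):
        cloud = make_lattice_box("cubic", 3, 2.0)
        assert cloud.n_points == 27
        assert offdiag(cloud).min() == pytest.approx(2.0)

    def test_random_subsample_count_and_determinism(self):
        a = make_lattice_box("diamond", 2, 6.4, 0.1, 0.75, seed=9)
        b = make_lattice_box("diamond", 2, 6.4, 0.1, 0.75, seed=9)
        assert a.n_points == 48
        np.testing.assert_array_equal(a.coords, b.coords)

    def test_block_subsample_preserves_local_structure(self):
        full = make_lattice_box("diamond", 2, 6.4, 0.0, 1.0)
        block = make_lattice_box(
            "diamond", 2, 6.4, 0.0, 0.75, subsample_mode="block"
        )
        # every block site is a site of the full lattice (no vacancies inside)
        full_set = {tuple(np.round(c, 6)) for c in full.coords}
        assert all(tuple(np.round(c, 6)) in full_set for c in block.coords)
        assert offdiag(block).min() == pytest.approx(6.4 * SQRT3 / 4)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="fewer than 4"):
            make_lattice_box("cubic", 2, 1.0, subsample_fraction=0.2)

    def test_bad_parameters(self):
        with pytest.raises(ValueError, match="lattice"):
            make_lattice_box("fcc", 2, 1.0)
        with pytest.raises(ValueError, match="subsample_mode"):
            make_lattice_box("cubic", 2, 1.0, subsample_mode="slab")
        with pytest.raises(ValueError, match="cells_per_side"):
            make_lattice_box("cubic", 1, 1.0)


class TestEnsembles:
    def spec(self, n_frames=5, seed=4):
        return GeneratorSpec(
            kind="lattice_box",
            parameters={
                "lattice": "diamond",
                "cells_per_side": 2,
                "spacing": 6.4,
                "jitter_sd": 0.2,
            },
            seed=seed,
            n_frames=n_frames,
            label="lat",
        )

    def test_ensemble_determinism(self):
        a = generate_ensemble(self.spec())
        b = generate_ensemble(self.spec())
        assert len(a) == 5
        for ca, cb in zip(a, b):
            np.testing.assert_array_equal(ca.coords, cb.coords)

    def test_frames_are_distinct(self):
        clouds = generate_ensemble(self.spec())
        assert not np.array_equal(clouds[0].coords, clouds[1].coords)

    def test_frame_stream_stability(self):
        short = generate_ensemble(self.spec(n_frames=3))
        long = generate_ensemble(self.spec(n_frames=8))
        for i in range(3):
            np.testing.assert_array_equal(short[i].coords, long[i].coords)

    def test_xyz_roundtrip(self, tmp_path):
        clouds = generate_ensemble(self.spec(n_frames=2))
        path = tmp_path / "ens.xyz"
        write_xyz_frames(clouds, path)
        back = read_xyz_frames(path)
        assert len(back) == 2
        for a, b in zip(clouds, back):
            np.testing.assert_allclose(a.coords, b.coords, atol=1e-9)

    def test_spec_json_roundtrip(self):
        spec = self.spec()
        again = GeneratorSpec.from_json(spec.to_json())
        assert again == spec

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown generator"):
            GeneratorSpec(kind="sphere")

    def test_deterministic_kinds_ignore_frame_seed(self):
        spec = GeneratorSpec(kind="hexagon", parameters={"d": 1.5}, n_frames=2)
        a, b = generate_ensemble(spec)
        np.testing.assert_array_equal(a.coords, b.coords)
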