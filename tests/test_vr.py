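import math
from itertools import permutations

import numpy as np
import pytest

from conftest import SQRT3, random_cloud
from l1npi.cloud_io import DistanceMatrix, PointCloud, pairwise_distances
from l1npi.vr import (
    FilteredSimplex,
    Filtration,
    betti_at,
    brute_force_betti,
    build_vr_filtration,
    compute_persistence,
    dominant_features,
    read_diagram_csv,
    vr_diagram,
    write_diagram_csv,
)


def comb(n, k):
    return math.comb(n, k)


class TestFiltration:
    def test_equilateral_triangle_closure(self):
        cloud = PointCloud(
            np.array([[0, 0, 0], [1, 0, 0], [0.5, SQRT3 / 2, 0]], float)
        )
        f = build_vr_filtration(pairwise_distances(cloud), 2.0, max_dim=2)
        assert len(f) == 7  # 3 vertices + 3 edges + 1 triangle
        tri = [s for s in f.simplices if s.dim == 2]
        assert len(tri) == 1 and tri[0].value == pytest.approx(1.0)

    def test_hexagon_below_first_merge_is_vertices_only(self, hexagon_cloud):
        f = build_vr_filtration(pairwise_distances(hexagon_cloud), 0.5, max_dim=2)
        assert len(f) == 6
        assert all(s.dim == 0 for s in f.simplices)

    @pytest.mark.parametrize("n", [4, 5, 6])
    def test_complete_complex_counts(self, rng, n):
        cloud = random_cloud(rng, n)
        dm = pairwise_distances(cloud)
        f = build_vr_filtration(dm, dm.d.max() + 1.0, max_dim=3)
        assert len(f) == comb(n, 1) + comb(n, 2) + comb(n, 3) + comb(n, 4)

    def test_faces_precede_cofaces_and_values_monotone(self, rng):
        cloud = random_cloud(rng, 7)
        f = build_vr_filtration(pairwise_distances(cloud), 1.2, max_dim=3)
        seen = set()
        values = [s.value for s in f.simplices]
        assert values == sorted(values)
        for s in f.simplices:
            if s.dim > 0:
                for i in range(len(s.vertices)):
                    face = s.vertices[:i] + s.vertices[i + 1 :]
                    assert face in seen
            seen.add(s.vertices)

    def test_simplex_value_is_longest_edge(self, rng):
        cloud = random_cloud(rng, 6)
        dm = pairwise_distances(cloud)
        f = build_vr_filtration(dm, 2.0, max_dim=3)
        for s in f.simplices:
            if s.dim > 0:
                expected = max(
                    dm.d[a, b]
                    for i, a in enumerate(s.vertices)
                    for b in s.vertices[i + 1 :]
                )
                assert s.value == pytest.approx(expected, abs=1e-15)

    def test_parameter_validation(self, hexagon_cloud):
        dm = pairwise_distances(hexagon_cloud)
        with pytest.raises(ValueError, match="delta_max"):
            build_vr_filtration(dm, 0.0)
        with pytest.raises(ValueError, match="max_dim"):
            build_vr_filtration(dm, 1.0, max_dim=4)


class TestPersistence:
    def test_two_points_merge(self):
        cloud = PointCloud(np.array([[0, 0, 0], [0.7, 0, 0]], float))
        dg = vr_diagram(pairwise_distances(cloud), 1.0, max_degree=0)
        deaths = sorted(p.death for p in dg.of_degree(0))
        assert deaths[0] == pytest.approx(0.7)
        assert math.isinf(deaths[1])

    def test_hexagon_full_barcode(self, hexagon_diagram):
        deg0 = hexagon_diagram.of_degree(0)
        assert len(deg0) == 6
        finite0 = [p for p in deg0 if math.isfinite(p.death)]
        assert len(finite0) == 5
        assert all(p.birth == 0 and p.death == pytest.approx(1.0) for p in finite0)
        loops = hexagon_diagram.of_degree(1, drop_trivial=True)
        assert len(loops) == 1
        assert loops[0].birth == pytest.approx(1.0)
        assert loops[0].death == pytest.approx(SQRT3)
        voids = hexagon_diagram.of_degree(2, drop_trivial=True)
        assert len(voids) == 1
        assert voids[0].birth == pytest.approx(SQRT3)
        assert voids[0].death == pytest.approx(2.0)

    def test_unit_square_loop(self):
        cloud = PointCloud(
            np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], float)
        )
        dg = vr_diagram(pairwise_distances(cloud), 2.0, max_degree=1)
        loops = dg.of_degree(1, drop_trivial=True)
        assert len(loops) == 1
        assert loops[0].birth == pytest.approx(1.0)
        assert loops[0].death == pytest.approx(math.sqrt(2.0))

    def test_tetrahedron_fills_immediately(self):
        v = np.array(
            [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
        )
        dm = pairwise_distances(PointCloud(v))
        edge = dm.d[0, 1]
        dg = vr_diagram(dm, edge * 1.01, max_degree=2)
        counts = betti_at(dg, edge * 1.005)
        assert (counts[0], counts[1], counts[2]) == (1, 0, 0)

    def test_degree0_pair_count_equals_points(self, rng):
        for n in (3, 6, 9):
            cloud = random_cloud(rng, n)
            dg = vr_diagram(pairwise_distances(cloud), 0.8, max_degree=1)
            assert len(dg.of_degree(0)) == n

    def test_permutation_invariance(self, rng):
        coords = rng.uniform(size=(7, 3))
        base = vr_diagram(
            pairwise_distances(PointCloud(coords)), 1.5, max_degree=2
        )
        perm = rng.permutation(7)
        shuffled = vr_diagram(
            pairwise_distances(PointCloud(coords[perm])), 1.5, max_degree=2
        )
        assert sorted(base.pairs) == pytest.approx(sorted(shuffled.pairs))

    def test_scale_equivariance(self, rng):
        coords = rng.uniform(size=(6, 3))
        s = 2.75
        dg1 = vr_diagram(pairwise_distances(PointCloud(coords)), 1.5, max_degree=2)
        dg2 = vr_diagram(
            pairwise_distances(PointCloud(coords * s)), 1.5 * s, max_degree=2
        )
        for p1, p2 in zip(sorted(dg1.pairs), sorted(dg2.pairs)):
            assert p1.degree == p2.degree
            assert p2.birth == pytest.approx(s * p1.birth)
            if math.isinf(p1.death):
                assert math.isinf(p2.death)
            else:
                assert p2.death == pytest.approx(s * p1.death)

    def test_missing_face_is_structural_error(self):
        broken = Filtration(
            (
                FilteredSimplex((0,), 0.0),
                FilteredSimplex((1,), 0.0),
                FilteredSimplex((2,), 0.0),
                FilteredSimplex((0, 1), 1.0),
                FilteredSimplex((0, 2), 1.0),
                # (1, 2) missing
                FilteredSimplex((0, 1, 2), 1.0),
            ),
            delta_max=2.0,
            n_points=3,
        )
        with pytest.raises(ValueError, match="not closed under faces"):
            compute_persistence(broken, max_degree=1)

    def test_max_degree_needs_higher_simplices(self, hexagon_cloud):
        f = build_vr_filtration(pairwise_distances(hexagon_cloud), 2.5, max_dim=2)
        with pytest.raises(ValueError, match="max_degree"):
            compute_persistence(f, max_degree=2)


class TestBetti:
    def test_hexagon_betti_narrative(self, hexagon_diagram):
        assert betti_at(hexagon_diagram, 0.0)[0] == 6
        mid = betti_at(hexagon_diagram, 1.2)
        assert (mid[0], mid[1], mid[2]) == (1, 1, 0)
        sphere = betti_at(hexagon_diagram, 1.8)
        assert (sphere[0], sphere[1], sphere[2]) == (1, 0, 1)
        filled = betti_at(hexagon_diagram, 2.0)
        assert (filled[0], filled[1], filled[2]) == (1, 0, 0)

    def test_single_point(self):
        dm = DistanceMatrix(np.zeros((1, 1)))
        assert brute_force_betti(dm, 0.5) == {0: 1, 1: 0, 2: 0}

    def test_brute_force_refuses_large_clouds(self, rng):
        cloud = random_cloud(rng, 11)
        with pytest.raises(ValueError, match="limited"):
            brute_force_betti(pairwise_distances(cloud), 0.5)

    def test_oracle_agreement_on_hexagon_sweep(self, hexagon_cloud, hexagon_diagram, rng):
        dm = pairwise_distances(hexagon_cloud)
        for delta in rng.uniform(0.0, 2.4, 20):
            expected = brute_force_betti(dm, delta)
            got = betti_at(hexagon_diagram, delta)
            assert got == expected, f"mismatch at delta={delta}"

    def test_euler_characteristic(self, rng):
        # small clouds where max_dim=3 covers the full complex (n=4)
        for _ in range(5):
            cloud = random_cloud(rng, 4)
            dm = pairwise_distances(cloud)
            f = build_vr_filtration(dm, 2.0, max_dim=3)
            dg = compute_persistence(f, max_degree=2)
            for delta in rng.uniform(0.0, 1.8, 5):
                simp = sum(
                    (-1) ** s.dim for s in f.simplices if s.value <= delta
                )
                betti = betti_at(dg, delta)
                assert simp == betti[0] - betti[1] + betti[2]


class TestSerialisation:
    def test_diagram_csv_roundtrip(self, tmp_path, hexagon_diagram):
        path = tmp_path / "dg.csv"
        write_diagram_csv(hexagon_diagram, path)
        text = path.read_text().splitlines()
        assert text[0] == "degree,birth,death"
        assert any(line.endswith(",inf") for line in text[1:])
        back = read_diagram_csv(path)
        assert back.pairs == hexagon_diagram.pairs

    def test_diagram_csv_rejects_bad_header(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("a,b\n")
        with pytest.raises(ValueError, match="header"):
            read_diagram_csv(path)


def test_dominant_features_caps_essential_classes(hexagon_diagram):
    # degree-1: single loop, trivially dominant
    loops = dominant_features(hexagon_diagram, 1)
    assert len(loops) == 1 and loops[0].birth == pytest.approx(1.0)
    # degree-0: five unit bars plus the essential class capped at delta_max
    bars = dominant_features(hexagon_diagram, 0, ratio=0.3)
    assert len(bars) == 6
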