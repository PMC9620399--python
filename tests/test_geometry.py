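import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rnaweave import (
    HelixParams,
    bp_count_for_edge,
    embed_design,
    optimize_phases_and_linkers,
    radius_of_gyration,
    route,
    spanning_tree,
    split_kl_edge,
)
from rnaweave.geometry import (
    _transition_cost,
    _transition_geometry,
    open_variant_coordinates,
)


class TestBpCount:
    def test_exact_division(self, params):
        assert bp_count_for_edge(2.81, params) == 10

    def test_clamp_with_warning(self, params):
        with pytest.warns(UserWarning, match="clamped"):
            assert bp_count_for_edge(0.1, params) == params.min_edge_bp

    def test_zero_length_rejected(self, params):
        with pytest.raises(ValueError):
            bp_count_for_edge(0.0, params)

    @given(st.floats(min_value=2.5, max_value=200.0))
    @settings(max_examples=200, deadline=None)
    def test_rounding_property(self, length):
        params = HelixParams()
        bp = bp_count_for_edge(length, params)
        assert abs(bp * params.rise_per_bp - length) <= params.rise_per_bp / 2 + 1e-12


class TestSplitKlEdge:
    def test_balanced(self, params):
        assert split_kl_edge(20, params) == (7, 7)

    def test_odd_split(self, params):
        assert split_kl_edge(21, params) == (7, 8)

    def test_too_short(self, params):
        with pytest.raises(ValueError, match="too short"):
            split_kl_edge(7, params)

    @given(st.integers(min_value=8, max_value=300))
    @settings(max_examples=100, deadline=None)
    def test_partition_property(self, bp):
        params = HelixParams()
        a, b = split_kl_edge(bp, params)
        assert a + params.kl_pair_len + b == bp
        assert abs(a - b) <= 1


class TestCoordinates:
    def test_one_bp_duplex_backbone_distance(self, params):
        from rnaweave.geometry import _frame_for_edge

        frame = _frame_for_edge(np.zeros(3), np.array([0.0, 0.0, 5.0]), 1, params)
        a = frame.backbone_point(0, False, params)
        b = frame.backbone_point(0, True, params)
        delta = params.backbone_offset_rad
        expected = 2 * params.helix_radius * math.sin(delta / 2)
        assert np.linalg.norm(a - b) == pytest.approx(expected, abs=1e-12)

    def test_full_turn_after_11_steps(self, params):
        # 11 steps of 32.7 deg = 359.7 deg: first and last backbone points
        # come back to nearly the same azimuth
        from rnaweave.geometry import _frame_for_edge

        frame = _frame_for_edge(np.zeros(3), np.array([0.0, 0.0, 5.0]), 12, params)
        p0 = frame.backbone_point(0, False, params)
        p11 = frame.backbone_point(11, False, params)
        a0 = math.atan2(p0[1], p0[0])
        a11 = math.atan2(p11[1], p11[0])
        diff = math.degrees((a11 - a0 + math.pi) % (2 * math.pi) - math.pi)
        assert diff == pytest.approx(-0.3, abs=1e-9)

    def test_intra_strand_step_is_helix_chord(self, single_edge_mesh, params):
        plan = route(single_edge_mesh, spanning_tree(single_edge_mesh))
        emb = embed_design(single_edge_mesh, plan, seed=0)
        coords = emb.coordinates()
        chord = params.backbone_step()
        # check consecutive steps inside each helical domain
        pos = 0
        for d in emb.domains:
            if d.kind in ("stem5", "stem3"):
                for k in range(d.length - 1):
                    step = np.linalg.norm(coords[pos + k + 1] - coords[pos + k])
                    assert step == pytest.approx(chord, abs=1e-9)
            pos += d.length

    def test_total_length_two_ways(self, tetra_embedded, params):
        # domain-sum formula vs coordinate count
        plan = tetra_embedded.plan
        tree_bp = sum(tetra_embedded.frames[e].bp for e in plan.tree_edges)
        kl_terms = 0
        for e in plan.kl_edges:
            sa, sb = tetra_embedded.kl_splits[e]
            kl_terms += 2 * (sa + sb) + 2 * (params.kl_pair_len + 2 * params.kl_flank_unpaired)
        expected = 2 * tree_bp + kl_terms + sum(tetra_embedded.linker_counts)
        assert tetra_embedded.total_length == expected
        assert len(tetra_embedded.coordinates()) == expected

    def test_paired_rows_within_duplex_diameter(self, tetra_embedded, params):
        from rnaweave import build_strand_model

        strand = build_strand_model(tetra_embedded)
        coords = tetra_embedded.coordinates()
        tol = 0.2
        dists = [
            np.linalg.norm(coords[i] - coords[j]) for i, j in strand.pairs()
        ]
        assert min(dists) >= 2 * params.helix_radius - tol
        assert max(dists) <= 2 * params.helix_radius + tol

    def test_coordinates_finite_and_ordered(self, tetra_embedded):
        coords = tetra_embedded.coordinates()
        assert np.all(np.isfinite(coords))
        assert len(coords) == tetra_embedded.total_length


class TestOptimizer:
    def test_descent_invariant(self, tetra_embedded):
        h = tetra_embedded.cost_history
        assert all(a >= b - 1e-12 for a, b in zip(h, h[1:]))

    def test_optimized_not_worse_than_start(self, tetra_embedded):
        assert tetra_embedded.cost <= tetra_embedded.cost_history[0] + 1e-12

    def test_deterministic(self, tetra_mesh, tetra_plan):
        e1 = optimize_phases_and_linkers(tetra_mesh, tetra_plan, seed=4)
        e2 = optimize_phases_and_linkers(tetra_mesh, tetra_plan, seed=4)
        assert e1.cost == e2.cost
        assert e1.linker_counts == e2.linker_counts
        assert all(
            e1.frames[k].phase == e2.frames[k].phase for k in e1.frames
        )

    def test_coaxial_matched_phase_needs_no_linkers(self, params):
        from rnaweave.geometry import _best_linkers

        # coaxial continuation: gap of one rise, negligible bend
        L, _ = _best_linkers(params.rise_per_bp, 0.1, params)
        assert L == 0

    def test_exhaustive_linker_oracle_path_mesh(self, path3_mesh, params):
        # brute force over all linker configurations (0..3 per transition)
        # at the optimizer's final phases must not beat the optimizer
        emb = optimize_phases_and_linkers(path3_mesh, route(path3_mesh, [0, 1, 2]), seed=2)
        geo = [_transition_geometry(t, emb.frames, params) for t in emb.transitions]

        def total(linkers):
            return sum(
                _transition_cost(g, ang, L, params) for (g, ang), L in zip(geo, linkers)
            )

        best = min(
            total(cfg) for cfg in itertools.product(range(4), repeat=len(emb.transitions))
        )
        assert total(emb.linker_counts) <= best + 1e-9

    def test_exhaustive_linker_oracle_tetrahedron_reduced(self, tetra_embedded, params):
        # tetrahedron has 12 transitions; brute-force a reduced 0..1 grid
        geo = [
            _transition_geometry(t, tetra_embedded.frames, params)
            for t in tetra_embedded.transitions
        ]

        def total(linkers):
            return sum(
                _transition_cost(g, ang, L, params) for (g, ang), L in zip(geo, linkers)
            )

        best = min(
            total(cfg) for cfg in itertools.product(range(2), repeat=len(geo))
        )
        assert total(tetra_embedded.linker_counts) <= best + 1e-9

    def test_linker_counts_within_bounds(self, tetra_embedded, params):
        assert all(
            0 <= L <= params.max_linkers_per_transition
            for L in tetra_embedded.linker_counts
        )


class TestRadiusOfGyration:
    def test_single_point(self):
        assert radius_of_gyration(np.array([[1.0, 2.0, 3.0]])) == 0.0

    def test_two_points(self):
        pts = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 4.0]])
        assert radius_of_gyration(pts) == pytest.approx(2.0)

    def test_against_double_loop_oracle(self):
        rng = np.random.default_rng(11)
        pts = rng.normal(size=(100, 3))
        n = len(pts)
        # independent formula: Rg^2 = (1 / 2N^2) * sum_ij |ri - rj|^2
        acc = 0.0
        for i in range(n):
            for j in range(n):
                acc += float(np.sum((pts[i] - pts[j]) ** 2))
        oracle = math.sqrt(acc / (2 * n * n))
        assert radius_of_gyration(pts) == pytest.approx(oracle, abs=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            radius_of_gyration(np.empty((0, 3)))


class TestOpenVariant:
    def test_same_strand_length(self, tetra_embedded):
        open_coords = open_variant_coordinates(tetra_embedded)
        assert len(open_coords) == tetra_embedded.total_length
        assert np.all(np.isfinite(open_coords))

    def test_closed_design_more_compact(self, tetra_embedded):
        # mirrors the folded-vs-open compactness ordering
        closed = radius_of_gyration(tetra_embedded.coordinates())
        opened = radius_of_gyration(open_variant_coordinates(tetra_embedded))
        assert closed < opened


class TestHelixParams:
    def test_defaults_valid(self):
        HelixParams().validate()

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"rise_per_bp": -1.0},
            {"twist_per_bp": 0.0},
            {"twist_per_bp": 400.0},
            {"kl_pair_len": 3},
        ],
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            HelixParams(**kwargs).validate()

    def test_backbone_step_closed_form(self, params):
        chord = 2 * params.helix_radius * math.sin(math.radians(params.twist_per_bp) / 2)
        assert params.backbone_step() == pytest.approx(
            math.sqrt(params.rise_per_bp**2 + chord**2)
        )
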