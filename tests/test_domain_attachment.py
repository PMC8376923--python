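import itertools
import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from confenum.domain_attachment import (
    AttachmentSpec,
    SecondDomainSpec,
    attach_second_domain,
    candidate_grid,
    gyration_radius,
    merge_domain_linker,
    place_domain,
    rotation_between,
    search_placements,
)
from confenum.geometry_core import Conformation, GeometryError, build_backbone


def _ca_chain(positions, start=1, resname="ALA"):
    n = len(positions)
    return Conformation(
        np.arange(start, start + n), [resname] * n, ["CA"] * n, ["C"] * n,
        np.asarray(positions, dtype=float),
    )


class TestGyrationRadius:
    def test_single_atom_is_zero(self):
        assert gyration_radius(_ca_chain([[1.0, 2.0, 3.0]])) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_two_equal_masses_two_angstrom_apart(self):
        conf = _ca_chain([[0, 0, 0], [2.0, 0, 0]])
        assert gyration_radius(conf) == pytest.approx(1.0)

    def test_cube_corners(self):
        corners = [[x, y, z] for x in (0, 2.0) for y in (0, 2.0) for z in (0, 2.0)]
        assert gyration_radius(_ca_chain(corners)) == pytest.approx(math.sqrt(3.0))

    def test_mass_weighting_shifts_centroid(self):
        conf = Conformation(
            np.array([1, 2]), ["ALA"] * 2, ["CA", "O"], ["C", "O"],
            np.array([[0.0, 0, 0], [2.0, 0, 0]]),
        )
        assert gyration_radius(conf, mass_weighted=True) != pytest.approx(
            gyration_radius(conf, mass_weighted=False)
        )


class TestCandidateGrid:
    def test_matches_triple_loop_oracle(self, params):
        linker = build_backbone("AVLKEQ", [(-120, 130)] * 6, params, start_resid=230)
        spec = AttachmentSpec(anchor_a=232, anchor_b=235)
        r_g, spacing = 8.0, 3.0
        grid = candidate_grid(linker, spec, r_g, spacing)
        ca = linker.ca_coords()
        anchor = linker.coords[linker.index_of(235, "CA")]
        lo, hi = ca.min(axis=0) - r_g, ca.max(axis=0) + r_g
        expected = []
        axes = [np.arange(lo[k], hi[k] + spacing / 2, spacing) for k in range(3)]
        for p in itertools.product(*axes):
            p = np.array(p)
            if (
                np.linalg.norm(p - anchor) < r_g
                and np.linalg.norm(ca - p, axis=1).min() > 2.0
            ):
                expected.append(p)
        assert grid.shape[0] == len(expected)

    def test_boundary_point_at_exactly_rg_is_excluded(self):
        linker = _ca_chain([[0.0, 0, 0]], start=238)
        spec = AttachmentSpec(anchor_a=237, anchor_b=238)
        # lattice spans [-5, 5] with spacing 2.5: points at exactly |x| = 5
        grid = candidate_grid(linker, spec, r_g=5.0, spacing=2.5)
        dists = np.linalg.norm(grid, axis=1)
        assert (dists < 5.0).all() and (dists > 2.0).all()

    def test_infeasible_geometry_is_an_error(self):
        linker = _ca_chain([[0.0, 0, 0]], start=238)
        spec = AttachmentSpec(anchor_a=237, anchor_b=238, grid_exclusion=6.0)
        with pytest.raises(GeometryError, match="no candidate placements"):
            candidate_grid(linker, spec, r_g=5.0, spacing=2.0)


class TestRotationBetween:
    def test_identity_for_parallel_vectors(self):
        assert np.allclose(rotation_between([2, 0, 0], [5, 0, 0]), np.eye(3))

    def test_antiparallel_gives_half_turn(self):
        rot = rotation_between([1.0, 0, 0], [-1.0, 0, 0])
        assert np.allclose(rot @ [1.0, 0, 0], [-1.0, 0, 0], atol=1e-9)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)

    def test_alignment_within_1e9(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            a, b = rng.normal(size=3), rng.normal(size=3)
            rot = rotation_between(a, b)
            aligned = rot @ (a / np.linalg.norm(a))
            assert np.allclose(aligned, b / np.linalg.norm(b), atol=1e-9)

    def test_zero_vector_is_an_error(self):
        with pytest.raises(GeometryError, match="degenerate anchors"):
            rotation_between([0.0, 0, 0], [1.0, 0, 0])


class TestPlaceDomain:
    def _linker(self):
        # straight CA chain along x, residues 230..237
        return _ca_chain([[3.8 * k, 0, 0] for k in range(8)], start=230)

    def test_coincident_anchors_accept_with_identity_motion(self):
        linker = self._linker()
        spec = AttachmentSpec(anchor_a=232, anchor_b=235)
        domain = _ca_chain(
            [linker.coords[linker.index_of(232, "CA")],
             linker.coords[linker.index_of(235, "CA")]],
            start=0,
        )
        domain.resids = np.array([232, 235])
        placed, accepted, diag = place_domain(
            domain, linker, domain.coords.mean(axis=0), spec
        )
        assert accepted
        assert diag["mean_anchor_distance"] == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(placed.coords, domain.coords, atol=1e-9)

    def test_mean_anchor_distance_rule_boundary(self):
        linker = self._linker()
        spec = AttachmentSpec(anchor_a=232, anchor_b=235)
        for offset, expect in ((11.8, True), (12.2, False)):
            # stretch the anchor vector: after T-translation the residual
            # splits evenly, mean anchor distance = offset / 2
            domain = _ca_chain(
                [linker.coords[linker.index_of(232, "CA")],
                 linker.coords[linker.index_of(235, "CA")] + np.array([offset, 0, 0])],
                start=0,
            )
            domain.resids = np.array([232, 235])
            _placed, accepted, diag = place_domain(
                domain, linker, domain.coords.mean(axis=0), spec
            )
            assert diag["mean_anchor_distance"] == pytest.approx(offset / 2, abs=1e-9)
            assert accepted is expect

    def test_ca_clash_rule_boundary(self):
        linker = self._linker()
        spec = AttachmentSpec(anchor_a=232, anchor_b=235)
        anchor_pts = [
            linker.coords[linker.index_of(232, "CA")],
            linker.coords[linker.index_of(235, "CA")],
        ]
        # anchors coincide (2 clashes); a third coinciding CA tips it over
        near_third = linker.coords[linker.index_of(237, "CA")] + np.array([0.5, 0, 0])
        domain2 = _ca_chain(anchor_pts, start=0)
        domain2.resids = np.array([232, 235])
        domain3 = _ca_chain(anchor_pts + [near_third], start=0)
        domain3.resids = np.array([232, 235, 300])
        _p, ok2, d2 = place_domain(domain2, linker, domain2.coords.mean(axis=0), spec)
        assert d2["n_ca_clashes"] == 2 and ok2
        _p, ok3, d3 = place_domain(domain3, linker, domain3.coords.mean(axis=0), spec)
        assert d3["n_ca_clashes"] == 3 and not ok3

    def test_rigid_motion_preserves_internal_geometry(self, params):
        linker = build_backbone("AVLKEQ", [(-120, 130)] * 6, params, start_resid=230)
        domain = build_backbone("AVLK", [(-63, -43)] * 4, params, start_resid=232)
        placed, _ok, _diag = place_domain(
            domain, linker, np.array([5.0, 5.0, 5.0]),
            AttachmentSpec(anchor_a=232, anchor_b=235),
        )
        d_before = np.linalg.norm(
            domain.coords[:, None, :] - domain.coords[None, :, :], axis=2
        )
        d_after = np.linalg.norm(
            placed.coords[:, None, :] - placed.coords[None, :, :], axis=2
        )
        assert np.max(np.abs(d_before - d_after)) < 1e-9

    def test_acceptance_invariant_under_global_rigid_motion(self, params):
        linker = build_backbone("AVLKEQ", [(-120, 130)] * 6, params, start_resid=230)
        domain = build_backbone("AVLK", [(-63, -43)] * 4, params, start_resid=232)
        spec = AttachmentSpec(anchor_a=232, anchor_b=235)
        grid_point = np.array([4.0, 2.0, -1.0])
        _p1, ok1, diag1 = place_domain(domain, linker, grid_point, spec)
        rot = Rotation.from_rotvec([0.3, 0.9, -0.5]).as_matrix()
        t = np.array([7.0, -2.0, 3.0])
        _p2, ok2, diag2 = place_domain(
            domain.transformed(rot, t),
            linker.transformed(rot, t),
            rot @ grid_point + t,
            spec,
        )
        assert ok1 == ok2
        assert diag1["mean_anchor_distance"] == pytest.approx(
            diag2["mean_anchor_distance"], abs=1e-9
        )

    def test_search_placements_returns_only_accepted(self, params):
        linker = build_backbone("AVLKEQ", [(-120, 130)] * 6, params, start_resid=230)
        domain = build_backbone(
            "AVLKEQWTYDAV", [(-120, 130)] * 12, params, start_resid=226
        )
        spec = AttachmentSpec(anchor_a=232, anchor_b=235)
        accepted = search_placements(domain, linker, spec, spacing=6.0, n_spin=2)
        for _placed, diag in accepted:
            assert diag["n_ca_clashes"] < spec.max_ca_clashes
            assert diag["mean_anchor_distance"] < spec.max_anchor_distance


class TestMerge:
    def test_stated_ranges_give_145_residues(self):
        domain = _ca_chain([[k * 3.8, 0, 0] for k in range(103)], start=136)
        linker = _ca_chain([[k * 3.8, 10, 0] for k in range(42)], start=239)
        merged = merge_domain_linker(domain, linker, 238)
        assert len(merged.residue_ids()) == 145

    def test_sides_of_the_split_come_from_the_right_chain(self):
        domain = _ca_chain([[k * 1.0, 0, 0] for k in range(5)], start=1)
        linker = _ca_chain([[k * 1.0, 9, 0] for k in range(5)], start=4)
        merged = merge_domain_linker(domain, linker, 5)
        assert np.allclose(merged.coords[merged.index_of(5, "CA")][1], 0)
        assert np.allclose(merged.coords[merged.index_of(6, "CA")][1], 9)

    def test_gap_in_numbering_is_an_error(self):
        domain = _ca_chain([[k * 1.0, 0, 0] for k in range(3)], start=1)
        linker = _ca_chain([[k * 1.0, 9, 0] for k in range(3)], start=6)
        with pytest.raises(ValueError, match="not continuous"):
            merge_domain_linker(domain, linker, 4)


class TestSecondDomain:
    def test_identical_partial_gives_zero_bridge_and_accepts(self, params):
        ref = build_backbone("AVLKEQWT", [(-63, -43)] * 8, params, start_resid=1)
        spec = SecondDomainSpec(1, 4, 6, (1, 5), (6, 8))
        model, accepted, diag = attach_second_domain(ref, ref, spec)
        assert accepted
        assert np.linalg.norm(diag["v_bridge"]) < 1e-9
        assert diag["n_atom_clashes"] == 0
        assert list(model.residue_ids()) == list(range(1, 9))

    @pytest.mark.parametrize("n_planted,expect", [(49, True), (50, False)])
    def test_atom_clash_count_boundary(self, params, n_planted, expect):
        partial = build_backbone("AVLKEQWTYDAVLKEQWTYDAVLKE", [(-120, 130)] * 25, params)
        spec = SecondDomainSpec(1, 8, 9, (1, 8), (9, 25))
        ref = partial.copy()
        # plant exactly n_planted second-range atoms onto first-range atoms;
        # park the remainder far away, keeping the bridge CA in place
        first_idx = [
            i for i in range(partial.n_atoms) if partial.resids[i] <= 8
        ]
        second_idx = [
            i for i in range(partial.n_atoms) if partial.resids[i] >= 9
        ]
        bridge_i = partial.index_of(9, "CA")
        movable = [i for i in second_idx if i != bridge_i]
        assert len(movable) >= n_planted
        for k, i in enumerate(movable):
            if k < n_planted:
                ref.coords[i] = partial.coords[first_idx[k % len(first_idx)]]
            else:
                ref.coords[i] = np.array([500.0 + k, 500.0, 500.0])
        _model, accepted, diag = attach_second_domain(ref, partial, spec)
        assert diag["n_atom_clashes"] == n_planted
        assert accepted is expect
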