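"""Toy-structure energetics: LK solvation, SASA, LJ, dihedrals."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from pdzlie.energetics import (
    Atom,
    SingularStructureError,
    Structure,
    UndefinedDihedralError,
    delta_binding,
    dihedral,
    is_bound_conformation,
    lj_interaction,
    lk_solvation,
    phi_psi,
    phi_psi_chain,
    sasa,
)
from pdzlie.synthetic import build_backbone, gen_structure

PARAMS = dict(
    radius=1.9, volume=14.7, lk_g_ref=-0.5, lk_g_free=-1.0, lk_lambda=3.5,
    lj_epsilon=0.1, lj_rmin_half=2.0,
)


def atom(i, xyz, tag="protein", **over):
    p = {**PARAMS, **over}
    return Atom(
        id=i, element="C", xyz=np.asarray(xyz, float), chain_tag=tag,
        residue_index=i, name="C", **p,
    )


def rigid_transform(s: Structure, seed=0) -> Structure:
    rng = np.random.default_rng(seed)
    # random rotation via QR of a gaussian matrix
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    t = rng.normal(scale=10.0, size=3)
    out = []
    for a in s.atoms:
        out.append(Atom(**{**a.__dict__, "xyz": q @ a.xyz + t}))
    return Structure(out)


class TestLKSolvation:
    def test_isolated_atom_is_reference_energy(self):
        s = Structure([atom(1, [0, 0, 0])])
        assert lk_solvation(s) == PARAMS["lk_g_ref"]

    def test_two_atoms_hand_formula(self):
        """Pair value equals direct evaluation of the gaussian exclusion density."""
        r = 4.0
        s = Structure([atom(1, [0, 0, 0]), atom(2, [r, 0, 0], "peptide")])
        g = (
            PARAMS["lk_g_free"]
            / (2 * math.pi**1.5 * PARAMS["lk_lambda"] * r**2)
            * math.exp(-(((r - PARAMS["radius"]) / PARAMS["lk_lambda"]) ** 2))
        )
        expected = 2 * PARAMS["lk_g_ref"] - 2 * g * PARAMS["volume"]
        assert lk_solvation(s) == pytest.approx(expected, rel=1e-12)

    def test_matches_double_loop_oracle(self):
        s = gen_structure("random-dimer", seed=21, n_protein=12, n_peptide=9,
                          separation=6.0)
        total = 0.0
        for a in s.atoms:
            total += a.lk_g_ref
            for b in s.atoms:
                if b is a:
                    continue
                r = float(np.linalg.norm(a.xyz - b.xyz))
                g = (
                    a.lk_g_free
                    / (2 * math.pi**1.5 * a.lk_lambda * r**2)
                    * math.exp(-(((r - a.radius) / a.lk_lambda) ** 2))
                )
                total -= g * b.volume
        assert lk_solvation(s) == pytest.approx(total, rel=1e-10)

    def test_binding_change_matches_oracle(self):
        s = gen_structure("random-dimer", seed=8, n_protein=10, n_peptide=10,
                          separation=5.0)
        def oracle(st):
            return lk_solvation(st)
        direct = delta_binding(s, lk_solvation)
        manual = oracle(s) - oracle(s.chain("protein")) - oracle(s.chain("peptide"))
        assert direct == pytest.approx(manual, rel=1e-12)

    def test_coincident_atoms_raise(self):
        s = Structure([atom(1, [0, 0, 0]), atom(2, [0, 0, 0], "peptide")])
        with pytest.raises(SingularStructureError):
            lk_solvation(s)

    def test_rigid_motion_invariance(self):
        s = gen_structure("random-dimer", seed=31, n_protein=8, n_peptide=8)
        moved = rigid_transform(s, seed=1)
        assert lk_solvation(moved) == pytest.approx(lk_solvation(s), rel=1e-8)

    def test_buried_atom_limit(self):
        """A densely caged atom loses its solvation: net value approaches zero.

        G_free is parameterised so that the spatial integral of the exclusion
        density equals G_ref (the fully-buried balance).  The cage is a dense
        spherical shell of neighbour atoms whose volumes carry radial
        quadrature weights, so their screening sum approximates that integral.
        """
        R, lam, g_ref = PARAMS["radius"], PARAMS["lk_lambda"], PARAMS["lk_g_ref"]
        integrand = lambda r: (
            4 * math.pi * r**2
            / (2 * math.pi**1.5 * lam * r**2)
            * math.exp(-(((r - R) / lam) ** 2))
        )
        full, _ = quad(integrand, 0, 60)
        g_free = g_ref / full

        # Gauss-Legendre radii on [0.3, 12] A; each cage atom owns the shell
        # volume of its quadrature slice, placed in a random direction
        nodes, weights = np.polynomial.legendre.leggauss(64)
        a, b = 0.3, 12.0
        radii = 0.5 * (b - a) * nodes + 0.5 * (b + a)
        vols = 0.5 * (b - a) * weights * 4 * math.pi * radii**2
        rng = np.random.default_rng(6)
        dirs = rng.normal(size=(64, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)

        center = atom(1, [0, 0, 0], lk_g_free=g_free)
        cage = [
            atom(i + 2, radii[i] * dirs[i], volume=float(vols[i]), lk_g_free=g_free)
            for i in range(64)
        ]
        total = lk_solvation(Structure([center] + cage))
        cage_only = lk_solvation(Structure(cage))
        # cross-screening of cage atoms by the centre's volume (hand formula)
        cross = sum(
            g_free
            / (2 * math.pi**1.5 * lam * r**2)
            * math.exp(-(((r - R) / lam) ** 2))
            * PARAMS["volume"]
            for r in radii
        )
        center_net = total - cage_only + cross
        assert abs(center_net) <= 0.1 * abs(g_ref)


class TestSasa:
    def test_single_sphere_closed_form(self):
        s = Structure([atom(1, [0, 0, 0])])
        _, total = sasa(s, probe_radius=1.4, n_points=960)
        assert total == pytest.approx(4 * math.pi * (1.9 + 1.4) ** 2, rel=0.01)

    def test_far_apart_additivity(self):
        s = Structure([atom(1, [0, 0, 0]), atom(2, [50, 0, 0], "peptide")])
        _, total = sasa(s)
        assert total == pytest.approx(2 * 4 * math.pi * 3.3**2, rel=0.01)

    def test_overlapping_spheres_spherical_cap(self):
        """Two equal overlapping spheres: exposed area from the cap formula."""
        d = 3.0
        R = 1.9 + 1.4  # expanded radius
        s = Structure([atom(1, [0, 0, 0]), atom(2, [d, 0, 0], "peptide")])
        _, total = sasa(s, n_points=2000)
        cap_height = R - d / 2.0
        exposed = 2 * (4 * math.pi * R**2 - 2 * math.pi * R * cap_height)
        assert total == pytest.approx(exposed, rel=0.02)

    def test_delta_binding_zero_when_separated(self):
        s = Structure([atom(1, [0, 0, 0]), atom(2, [50, 0, 0], "peptide")])
        dA = delta_binding(s, lambda st: sasa(st)[1])
        assert dA == pytest.approx(0.0, abs=1.0)

    def test_delta_binding_negative_on_contact(self):
        s = gen_structure("random-dimer", seed=12, separation=4.0)
        assert delta_binding(s, lambda st: sasa(st)[1]) < 0

    def test_monotone_burial_on_approach(self):
        prev = math.inf
        for d in (50.0, 20.0, 8.0, 5.0, 3.0):
            s = Structure([atom(1, [0, 0, 0]), atom(2, [d, 0, 0], "peptide")])
            total = sasa(s)[1]
            assert total <= prev + 1e-6
            prev = total

    def test_invalid_point_count(self):
        with pytest.raises(ValueError):
            sasa(Structure([atom(1, [0, 0, 0])]), n_points=8)


class TestLJ:
    def test_minimum_depth_at_rmin(self):
        s = Structure([atom(1, [0, 0, 0]), atom(2, [4.0, 0, 0], "peptide")])
        assert lj_interaction(s) == pytest.approx(-0.1, rel=1e-12)

    def test_decay_beyond_50A(self):
        s = Structure([atom(1, [0, 0, 0]), atom(2, [50.0, 0, 0], "peptide")])
        assert abs(lj_interaction(s)) < 1e-6

    def test_matches_pair_loop_oracle(self):
        s = gen_structure("random-dimer", seed=17, n_protein=20, n_peptide=20,
                          separation=7.0)
        total = 0.0
        for a in s.chain("protein").atoms:
            for b in s.chain("peptide").atoms:
                r = float(np.linalg.norm(a.xyz - b.xyz))
                eps = math.sqrt(a.lj_epsilon * b.lj_epsilon)
                rmin = a.lj_rmin_half + b.lj_rmin_half
                total += eps * ((rmin / r) ** 12 - 2 * (rmin / r) ** 6)
        assert lj_interaction(s) == pytest.approx(total, rel=1e-10)

    def test_rigid_motion_invariance(self):
        s = gen_structure("random-dimer", seed=19, separation=6.0)
        moved = rigid_transform(s, seed=2)
        assert lj_interaction(moved) == pytest.approx(lj_interaction(s), rel=1e-8)

    def test_coincident_interchain_atoms_guarded(self):
        s = Structure([atom(1, [0, 0, 0]), atom(2, [0, 0, 0], "peptide")])
        with pytest.raises(SingularStructureError):
            lj_interaction(s)

    def test_intra_chain_pairs_excluded(self):
        # two protein atoms at clashing distance contribute nothing
        s = Structure(
            [atom(1, [0, 0, 0]), atom(2, [0.5, 0, 0]), atom(3, [30, 0, 0], "peptide")]
        )
        assert abs(lj_interaction(s)) < 1e-3


class TestDihedrals:
    def test_against_reference_implementation(self):
        from Bio.PDB.vectors import Vector, calc_dihedral

        rng = np.random.default_rng(44)
        for _ in range(25):
            pts = rng.normal(size=(4, 3))
            mine = dihedral(*pts)
            ref = math.degrees(calc_dihedral(*[Vector(p) for p in pts]))
            assert mine == pytest.approx(ref, abs=1e-9)

    def test_collinear_is_undefined(self):
        with pytest.raises(UndefinedDihedralError):
            dihedral([0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0])

    @pytest.mark.parametrize(
        "phi,psi", [(-120.0, 130.0), (-57.0, -47.0), (-75.0, 145.0)]
    )
    def test_builder_roundtrip(self, phi, psi):
        """phi_psi of a backbone built at exact torsions returns those torsions."""
        s = build_backbone([(phi, psi)] * 5)
        for res in (2, 3, 4):
            got = phi_psi(s, res)
            assert got[0] == pytest.approx(phi, abs=1e-6)
            assert got[1] == pytest.approx(psi, abs=1e-6)

    def test_terminal_angles_flagged_nan(self):
        s = build_backbone([(-120.0, 130.0)] * 3)
        with pytest.warns(UserWarning, match="phi undefined"):
            first = phi_psi(s, 1)
        assert math.isnan(first[0]) and not math.isnan(first[1])
        with pytest.warns(UserWarning, match="psi undefined"):
            last = phi_psi(s, 3)
        assert math.isnan(last[1])


class TestBetaRegionClassification:
    def test_all_beta_is_bound(self):
        assert is_bound_conformation([(-120.0, 130.0)] * 5)

    def test_single_helical_residue_breaks_it(self):
        tors = [(-120.0, 130.0)] * 4 + [(-60.0, -45.0)]
        assert not is_bound_conformation(tors)

    def test_boundary_inclusive(self):
        assert is_bound_conformation([(-30.0, 60.0)] * 5)
        assert is_bound_conformation([(-30.0, -150.0)] * 5)
        assert not is_bound_conformation([(-29.9, 60.0)] * 5)
        assert not is_bound_conformation([(-30.0, 59.9)] * 5)

    def test_missing_angle_is_conservative(self):
        tors = [(-120.0, 130.0)] * 4 + [(math.nan, 130.0)]
        with pytest.warns(UserWarning, match="missing torsion"):
            assert not is_bound_conformation(tors)

    def test_wrong_length_raises(self):
        with pytest.raises(ValueError):
            is_bound_conformation([(-120.0, 130.0)] * 4)
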