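"""Structure-based quantities derived from MD snapshots of toy complexes.

Implements the per-snapshot ingredients of the binding free energy function
on explicit atomic structures: the Lazaridis-Karplus gaussian implicit
solvation free energy, solvent-accessible surface area and its change upon
binding, the protein-peptide Lennard-Jones (12-6) interaction energy, and
backbone phi/psi dihedrals with the beta-region test used to classify a
peptide frame as binding-competent ("folded").

Atoms carry their own parameters (radii, volumes, LK reference/free
energies, LJ well depths); no force-field assignment is performed here.
SASA is delegated to biotite's Shrake-Rupley implementation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Structure",
    "SingularStructureError",
    "UndefinedDihedralError",
    "lk_solvation",
    "sasa",
    "delta_binding",
    "lj_interaction",
    "dihedral",
    "phi_psi",
    "phi_psi_chain",
    "is_bound_conformation",
    "load_structure",
    "write_pdb",
    "DEFAULT_ATOM_PARAMS",
]


class SingularStructureError(ValueError):
    """Coincident atoms make a pairwise energy diverge."""


class UndefinedDihedralError(ValueError):
    """Dihedral angle undefined (collinear atoms)."""


#: Per-element defaults for toy structures: radius (A), volume (A^3),
#: LK reference and free solvation energies (kcal/mol), LK correlation
#: length (A), LJ well depth (kcal/mol) and rmin/2 (A).  Configurable
#: stand-in values in the style of gaussian-solvation parameter sets;
#: real applications supply their own table.
DEFAULT_ATOM_PARAMS: dict[str, dict[str, float]] = {
    "C": dict(radius=2.0, volume=14.7, lk_g_ref=-0.25, lk_g_free=-0.25,
              lk_lambda=3.5, lj_epsilon=0.11, lj_rmin_half=2.0),
    "N": dict(radius=1.75, volume=11.2, lk_g_ref=-5.0, lk_g_free=-5.0,
              lk_lambda=3.5, lj_epsilon=0.20, lj_rmin_half=1.85),
    "O": dict(radius=1.6, volume=10.8, lk_g_ref=-5.3, lk_g_free=-5.3,
              lk_lambda=3.5, lj_epsilon=0.12, lj_rmin_half=1.70),
    "S": dict(radius=1.9, volume=14.7, lk_g_ref=-3.2, lk_g_free=-3.2,
              lk_lambda=3.5, lj_epsilon=0.45, lj_rmin_half=2.0),
    "H": dict(radius=1.0, volume=0.0, lk_g_ref=0.0, lk_g_free=0.0,
              lk_lambda=3.5, lj_epsilon=0.02, lj_rmin_half=1.1),
}


@dataclass
class Atom:
    """One atom with coordinates and energetic parameters."""

    id: int
    element: str
    xyz: np.ndarray
    radius: float
    volume: float
    lk_g_ref: float
    lk_g_free: float
    lk_lambda: float
    lj_epsilon: float
    lj_rmin_half: float
    charge: float = 0.0  # carried for completeness; unused by these energies
    chain_tag: str = "protein"
    residue_index: int | None = None
    name: str = ""

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.radius <= 0 or self.lk_lambda <= 0:
            raise ValueError(f"atom {self.id}: radius and lambda must be > 0")
        if self.volume < 0:
            raise ValueError(f"atom {self.id}: negative volume")


@dataclass
class Structure:
    """Ordered collection of atoms with minimal backbone topology.

    ``residue_index`` (1-based, PDB convention) and atom ``name`` are enough
    to locate the N, CA, C backbone atoms needed for dihedrals.
    """

    atoms: list[Atom]

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms])

    def param_array(self, name: str) -> np.ndarray:
        return np.array([getattr(a, name) for a in self.atoms], dtype=float)

    def chain(self, tag: str) -> "Structure":
        return Structure([a for a in self.atoms if a.chain_tag == tag])

    def chain_tags(self) -> set[str]:
        return {a.chain_tag for a in self.atoms}

    def backbone_atom(self, residue_index: int, name: str) -> Atom | None:
        for a in self.atoms:
            if a.residue_index == residue_index and a.name == name:
                return a
        return None

    def residue_indices(self) -> list[int]:
        seen: list[int] = []
        for a in self.atoms:
            if a.residue_index is not None and a.residue_index not in seen:
                seen.append(a.residue_index)
        return seen

    def translated(self, shift) -> "Structure":
        shift = np.asarray(shift, dtype=float)
        out = []
        for a in self.atoms:
            b = Atom(**{**a.__dict__, "xyz": a.xyz + shift})
            out.append(b)
        return Structure(out)


# --------------------------------------------------------------------------
# Lazaridis-Karplus gaussian implicit solvation
# --------------------------------------------------------------------------

def lk_solvation(s: Structure) -> float:
    """Gaussian-density implicit solvation free energy (kcal/mol).

    Each atom i contributes its fully-solvated reference free energy,
    reduced by the solvent it loses to every other atom j:

        dG = sum_i G_i_ref - sum_i sum_{j != i} g_i(r_ij) * V_j

    with the gaussian exclusion density

        g_i(r) = G_i_free / (2 pi^{3/2} lambda_i r^2) * exp(-((r - R_i)/lambda_i)^2)

    G_i_free is parameterised so the total vanishes for a fully buried atom.
    """
    n = len(s)
    if n == 0:
        return 0.0
    xyz = s.coords
    g_ref = s.param_array("lk_g_ref")
    if n == 1:
        return float(g_ref.sum())
    g_free = s.param_array("lk_g_free")
    lam = s.param_array("lk_lambda")
    rad = s.param_array("radius")
    vol = s.param_array("volume")

    diff = xyz[:, None, :] - xyz[None, :, :]
    r = np.sqrt((diff**2).sum(axis=-1))
    off = ~np.eye(n, dtype=bool)
    if np.any(r[off] < 1e-9):
        raise SingularStructureError("coincident atoms: 1/r^2 density diverges")
    np.fill_diagonal(r, np.inf)
    dens = (
        g_free[:, None]
        / (2 * math.pi**1.5 * lam[:, None] * r**2)
        * np.exp(-(((r - rad[:, None]) / lam[:, None]) ** 2))
    )
    screening = (dens * vol[None, :]).sum()
    return float(g_ref.sum() - screening)


# --------------------------------------------------------------------------
# Solvent accessible surface area (Shrake-Rupley via biotite)
# --------------------------------------------------------------------------

def sasa(
    s: Structure,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> tuple[np.ndarray, float]:
    """Per-atom and total solvent-accessible surface area (Angstrom^2).

    Sphere-sampling (Shrake-Rupley) with the atoms' own radii and a water
    probe; ``n_points`` sets the quadrature density per atom.
    """
    import biotite.structure as struc

    if n_points < 32:
        raise ValueError("n_points must be >= 32")
    n = len(s)
    if n == 0:
        return np.zeros(0), 0.0
    arr = struc.AtomArray(n)
    arr.coord = s.coords.astype(np.float32)
    arr.element = np.array([a.element for a in s.atoms])
    arr.atom_name = np.array([a.name or a.element for a in s.atoms])
    arr.res_id = np.array(
        [a.residue_index if a.residue_index is not None else 1 for a in s.atoms]
    )
    arr.res_name = np.array(["UNK"] * n)
    arr.chain_id = np.array(["A"] * n)
    per_atom = struc.sasa(
        arr,
        probe_radius=probe_radius,
        point_number=n_points,
        vdw_radii=s.param_array("radius"),
        ignore_ions=False,
    )
    per_atom = np.nan_to_num(per_atom, nan=0.0)
    return per_atom, float(per_atom.sum())


def total_sasa(s: Structure, probe_radius: float = 1.4, n_points: int = 960) -> float:
    return sasa(s, probe_radius=probe_radius, n_points=n_points)[1]


# --------------------------------------------------------------------------
# Binding change under the single-trajectory convention
# --------------------------------------------------------------------------

def delta_binding(s: Structure, f: Callable[[Structure], float]) -> float:
    """Change of a per-structure scalar upon binding.

    Evaluates ``f`` on the complex and on each chain separately, *at the
    same coordinates* (the single-trajectory convention: partners are rigidly
    separated, not re-simulated), and returns complex minus parts.  For SASA
    this is the surface change dA, negative for contacting chains.
    """
    tags = s.chain_tags()
    if tags != {"protein", "peptide"}:
        raise ValueError(
            f"chain tags must partition atoms into protein and peptide, got {tags}"
        )
    return (
        f(s) - f(s.chain("protein")) - f(s.chain("peptide"))
    )


# --------------------------------------------------------------------------
# Lennard-Jones protein-peptide interaction
# --------------------------------------------------------------------------

def lj_interaction(s: Structure, cutoff: float | None = None) -> float:
    """12-6 interaction energy between protein and peptide atoms (kcal/mol).

    Lorentz-Berthelot combination: rmin_ij = rmin/2_i + rmin/2_j and
    eps_ij = sqrt(eps_i * eps_j); intra-chain pairs are excluded.  No cutoff
    by default (structures here are small); ``cutoff`` truncates pairs beyond
    the given distance for parity experiments.
    """
    prot = s.chain("protein")
    pep = s.chain("peptide")
    if len(prot) == 0 or len(pep) == 0:
        return 0.0
    diff = prot.coords[:, None, :] - pep.coords[None, :, :]
    r = np.sqrt((diff**2).sum(axis=-1))
    if np.any(r < 1e-6):
        raise SingularStructureError("coincident inter-chain atoms in LJ sum")
    eps = np.sqrt(
        prot.param_array("lj_epsilon")[:, None] * pep.param_array("lj_epsilon")[None, :]
    )
    rmin = (
        prot.param_array("lj_rmin_half")[:, None]
        + pep.param_array("lj_rmin_half")[None, :]
    )
    q = (rmin / r) ** 6
    e = eps * (q**2 - 2 * q)
    if cutoff is not None:
        e = np.where(r <= cutoff, e, 0.0)
    return float(e.sum())


# --------------------------------------------------------------------------
# Backbone dihedrals and beta-region classification
# --------------------------------------------------------------------------

def dihedral(p0, p1, p2, p3) -> float:
    """IUPAC-signed dihedral of four points, in degrees, in (-180, 180]."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    norm = np.linalg.norm
    if norm(n1) < 1e-10 or norm(n2) < 1e-10:
        raise UndefinedDihedralError("collinear atoms: dihedral undefined")
    m1 = np.cross(n1, b1 / norm(b1))
    x = float(n1 @ n2)
    y = float(m1 @ n2)
    ang = -math.degrees(math.atan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return ang


def phi_psi(s: Structure, residue_index: int) -> tuple[float, float]:
    """Backbone (phi, psi) of a residue in degrees.

    phi = C(i-1)-N(i)-CA(i)-C(i); psi = N(i)-CA(i)-C(i)-N(i+1).  A missing
    neighbour (chain terminus) yields NaN for the affected angle, with a
    warning; the caller decides how to treat it.
    """
    get = s.backbone_atom
    n, ca, c = (get(residue_index, x) for x in ("N", "CA", "C"))
    if n is None or ca is None or c is None:
        raise ValueError(f"residue {residue_index}: backbone atoms missing")
    c_prev = get(residue_index - 1, "C")
    n_next = get(residue_index + 1, "N")
    if c_prev is None:
        warnings.warn(f"residue {residue_index}: phi undefined (no preceding residue)")
        phi = math.nan
    else:
        phi = dihedral(c_prev.xyz, n.xyz, ca.xyz, c.xyz)
    if n_next is None:
        warnings.warn(f"residue {residue_index}: psi undefined (no following residue)")
        psi = math.nan
    else:
        psi = dihedral(n.xyz, ca.xyz, c.xyz, n_next.xyz)
    return phi, psi


def phi_psi_chain(s: Structure) -> dict[int, tuple[float, float]]:
    """(phi, psi) for every residue of the structure."""
    return {i: phi_psi(s, i) for i in s.residue_indices()}


def _in_beta_region(phi: float, psi: float) -> bool:
    return (psi >= 60.0 or psi <= -150.0) and phi <= -30.0


def is_bound_conformation(
    torsions: Sequence[tuple[float, float]],
) -> bool:
    """Beta-region test for the binding-competent peptide conformation.

    ``torsions`` are the (phi, psi) pairs of the five C-terminal peptide
    residues; the frame is classified as bound (extended) iff *every*
    residue satisfies (psi >= 60 or psi <= -150) and phi <= -30, bounds
    inclusive.  A missing (NaN) angle classifies the frame as unbound, with
    a warning.
    """
    if len(torsions) != 5:
        raise ValueError("exactly 5 residue (phi, psi) pairs expected")
    for phi, psi in torsions:
        if math.isnan(phi) or math.isnan(psi):
            warnings.warn("missing torsion angle: frame classified as unbound")
            return False
        if not _in_beta_region(phi, psi):
            return False
    return True


# --------------------------------------------------------------------------
# PDB-format input/output (Biopython)
# --------------------------------------------------------------------------

_CHAIN_TO_TAG = {"A": "protein", "B": "peptide"}
_TAG_TO_CHAIN = {v: k for k, v in _CHAIN_TO_TAG.items()}


def load_structure(
    path: str | Path,
    params: dict[str, dict[str, float]] | None = None,
) -> Structure:
    """Read a PDB-format file into a :class:`Structure`.

    Chain A is tagged ``protein``, chain B ``peptide``.  Atom parameters are
    taken from ``params`` (per-element mapping; defaults to
    :data:`DEFAULT_ATOM_PARAMS`).
    """
    from Bio.PDB import PDBParser

    params = params or DEFAULT_ATOM_PARAMS
    parser = PDBParser(QUIET=True)
    model = parser.get_structure("s", str(path))[0]
    atoms: list[Atom] = []
    i = 0
    for chain in model:
        tag = _CHAIN_TO_TAG.get(chain.id, "protein")
        for residue in chain:
            for atom in residue:
                elem = (atom.element or atom.get_name()[0]).upper()
                p = params.get(elem, params.get("C"))
                i += 1
                atoms.append(
                    Atom(
                        id=i,
                        element=elem,
                        xyz=np.array(atom.get_coord(), dtype=float),
                        chain_tag=tag,
                        residue_index=residue.id[1],
                        name=atom.get_name(),
                        **p,
                    )
                )
    return Structure(atoms)


def write_pdb(s: Structure, path: str | Path) -> None:
    """Write a :class:`Structure` as a PDB-format file (chains A/B)."""
    from Bio.PDB import PDBIO, StructureBuilder

    builder = StructureBuilder.StructureBuilder()
    builder.init_structure("s")
    builder.init_model(0)
    for tag in ("protein", "peptide"):
        chain = s.chain(tag)
        if len(chain) == 0:
            continue
        builder.init_chain(_TAG_TO_CHAIN[tag])
        builder.init_seg("    ")
        current_res = None
        for a in chain.atoms:
            res_id = a.residue_index if a.residue_index is not None else 1
            if res_id != current_res:
                builder.init_residue("UNK", " ", res_id, " ")
                current_res = res_id
            builder.init_atom(
                a.name or a.element,
                a.xyz.astype(np.float32),
                0.0,
                1.0,
                " ",
                (a.name or a.element).ljust(4),
                a.id,
                element=a.element,
            )
    io = PDBIO()
    io.set_structure(builder.get_structure())
    io.save(str(path))
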