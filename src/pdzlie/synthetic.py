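"""Synthetic inputs with known ground truth for every pipeline stage.

Generators emulate the statistical structure of the study's inputs so the
whole analysis is testable without simulations: component tables with a
known linear signal plus gaussian noise, two-state torsion trajectories
with a prescribed stationary folded fraction, toy atomic structures (sphere
pairs, ideal strands/helices built from exact target torsions, random
dimers), and Crooks-consistent gaussian work samples with a closed-form
free energy.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .datasets import ComplexRecord, Dataset
from .energetics import DEFAULT_ATOM_PARAMS, Atom, Structure, write_pdb
from .estimators import BOLTZMANN_KCAL, WorkSamples
from .lie import CAL_TO_KCAL, LIECoefficients

__all__ = [
    "SyntheticTableSpec",
    "gen_component_table",
    "gen_torsion_trajectory",
    "gen_structure",
    "gen_work_samples",
    "build_backbone",
]


# --------------------------------------------------------------------------
# Component tables
# --------------------------------------------------------------------------

#: Component distributions matched to the ranges of the study's fitting
#: table: PB electrostatics ~ N(2, 1.5^2) kcal/mol, van der Waals
#: ~ N(1.5, 2.5^2) kcal/mol, surface change ~ N(0, 40^2) A^2.
DEFAULT_COMPONENT_DISTRIBUTIONS = {
    "pb": (2.0, 1.5),
    "vdw": (1.5, 2.5),
    "sa": (0.0, 40.0),
}


@dataclass(frozen=True)
class SyntheticTableSpec:
    """Recipe for a synthetic component table.

    Defaults mirror the study conditions: 35 fitting records, the published
    coefficient values as ground truth, component spreads matched to the
    fitting table, experimental noise of 0.4 kcal/mol (the order of the
    model+measurement error), and 9/35 of the records scored against the
    secondary (caspr4) reference.
    """

    n_complexes: int = 35
    true_coeffs: LIECoefficients = LIECoefficients(0.020, 0.25, -4.0)
    component_distributions: dict = field(
        default_factory=lambda: dict(DEFAULT_COMPONENT_DISTRIBUTIONS)
    )
    noise_sd: float = 0.4
    caspr_fraction: float = 9.0 / 35.0
    caspr_ref_exp: float = -0.23
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_complexes < 4:
            raise ValueError("n_complexes must be >= 4")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.caspr_fraction <= 1.0:
            raise ValueError("caspr_fraction must be in [0, 1]")


def gen_component_table(
    spec: SyntheticTableSpec,
) -> tuple[Dataset, LIECoefficients]:
    """Draw a component table whose targets follow the LIE model exactly.

    Components are drawn per ``spec``; experimental values are the model
    predictions under ``spec.true_coeffs`` plus gaussian noise.  Reference
    rows (zero components) are appended for each reference group in use.
    Returns the dataset together with the ground-truth coefficients.
    """
    rng = np.random.default_rng(spec.seed)
    theta = np.array(
        [
            spec.true_coeffs.alpha,
            spec.true_coeffs.beta,
            spec.true_coeffs.gamma * CAL_TO_KCAL,
        ]
    )
    n = spec.n_complexes
    n_caspr = int(round(spec.caspr_fraction * n))
    dists = spec.component_distributions
    pb = rng.normal(*dists["pb"], size=n)
    vdw = rng.normal(*dists["vdw"], size=n)
    sa = rng.normal(*dists["sa"], size=n)
    noise = rng.normal(0.0, spec.noise_sd, size=n) if spec.noise_sd > 0 else np.zeros(n)

    records: list[ComplexRecord] = []
    for i in range(n):
        group = "caspr4" if i < n_caspr else "sdc1"
        # zero-component references: the correction offset reduces to the
        # reference experimental value
        model_value = float(
            np.array([vdw[i], pb[i], sa[i]]) @ theta
            + (spec.caspr_ref_exp if group == "caspr4" else 0.0)
        )
        records.append(
            ComplexRecord(
                complex_id=f"syn-{i + 1:03d}",
                reference_group=group,
                in_fit=True,
                exp_ddg=model_value + float(noise[i]),
                pb=float(pb[i]),
                vdw=float(vdw[i]),
                sa=float(sa[i]),
                restraint=0.0,
            )
        )
    records.append(
        ComplexRecord(complex_id="ref-sdc1", reference_group="sdc1", exp_ddg=0.0)
    )
    if n_caspr > 0:
        records.append(
            ComplexRecord(
                complex_id="ref-caspr4",
                reference_group="caspr4",
                exp_ddg=spec.caspr_ref_exp,
            )
        )
    ds = Dataset(tuple(records), provenance=f"synthetic(seed={spec.seed})")
    return ds, spec.true_coeffs


# --------------------------------------------------------------------------
# Torsion trajectories
# --------------------------------------------------------------------------

def _beta_torsions(rng: np.random.Generator, n_res: int = 5) -> np.ndarray:
    """Torsions with every residue inside the beta region."""
    phi = rng.uniform(-180.0, -30.0, size=n_res)
    # psi region: [60, 180] (length 120) union [-180, -150] (length 30)
    u = rng.uniform(0.0, 150.0, size=n_res)
    psi = np.where(u < 120.0, 60.0 + u, -180.0 + (u - 120.0))
    return np.stack([phi, psi], axis=1)


def gen_torsion_trajectory(
    p_folded: float,
    n_frames: int,
    persistence: float = 10.0,
    seed: int = 0,
    n_residues: int = 5,
) -> np.ndarray:
    """Two-state Markov torsion trajectory of an unbound peptide.

    Frames alternate between a *folded* state (all residues inside the beta
    region, so the frame classifies as binding-competent) and an *unfolded*
    state (one residue forced outside it).  The chain has stationary folded
    probability ``p_folded`` and mean folded dwell time ``persistence``
    frames; the initial state is drawn from the stationary distribution.

    Returns an array of shape ``(n_frames, n_residues, 2)`` of (phi, psi)
    in degrees.
    """
    if not 0.0 <= p_folded <= 1.0:
        raise ValueError("p_folded must be in [0, 1]")
    if persistence < 1.0:
        raise ValueError("persistence must be >= 1 frame")
    rng = np.random.default_rng(seed)
    leave_folded = 1.0 / persistence
    if p_folded in (0.0, 1.0):
        states = np.full(n_frames, bool(p_folded))
    else:
        leave_unfolded = p_folded * leave_folded / (1.0 - p_folded)
        if leave_unfolded > 1.0:
            raise ValueError(
                "persistence too short for the requested folded probability"
            )
        states = np.empty(n_frames, dtype=bool)
        state = rng.random() < p_folded
        for t in range(n_frames):
            states[t] = state
            if state:
                state = not (rng.random() < leave_folded)
            else:
                state = rng.random() < leave_unfolded

    frames = np.empty((n_frames, n_residues, 2))
    for t in range(n_frames):
        tors = _beta_torsions(rng, n_residues)
        if not states[t]:
            k = rng.integers(n_residues)
            # helix-like torsions: psi inside (-150, 60) violates both clauses
            tors[k, 0] = rng.uniform(-90.0, -30.0)
            tors[k, 1] = rng.uniform(-140.0, 50.0)
        frames[t] = tors
    return frames


# --------------------------------------------------------------------------
# Toy structures
# --------------------------------------------------------------------------

# idealised backbone internal coordinates (A, degrees)
_BOND_N_CA = 1.458
_BOND_CA_C = 1.525
_BOND_C_N = 1.329
_ANGLE_N_CA_C = 111.2
_ANGLE_CA_C_N = 116.2
_ANGLE_C_N_CA = 121.7
_OMEGA = 180.0


def _place_atom(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """Internal-coordinate (NeRF) placement of atom d.

    d is ``bond`` from c, with angle(b, c, d) = ``angle`` and dihedral
    (a, b, c, d) = ``torsion`` (degrees).
    """
    angle = math.radians(angle)
    torsion = math.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * math.cos(angle),
            bond * math.sin(angle) * math.cos(torsion),
            bond * math.sin(angle) * math.sin(torsion),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(
    torsions: list[tuple[float, float]],
    chain_tag: str = "peptide",
    params: dict | None = None,
) -> Structure:
    """Poly-backbone (N, CA, C per residue) with exact target torsions.

    ``torsions[i]`` is the (phi, psi) pair of residue i+1; phi of the first
    and psi of the last residue are geometrically undefined and ignored.
    Omega is fixed at 180 degrees (trans).
    """
    par = (params or DEFAULT_ATOM_PARAMS)
    elem = {"N": "N", "CA": "C", "C": "C"}
    coords: list[tuple[str, int, np.ndarray]] = []
    # seed triad for residue 1
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = n0 + np.array([_BOND_N_CA, 0.0, 0.0])
    ang = math.radians(_ANGLE_N_CA_C)
    c0 = ca0 + _BOND_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    coords += [("N", 1, n0), ("CA", 1, ca0), ("C", 1, c0)]
    for i, (phi, psi) in enumerate(torsions[1:], start=2):
        n_prev, ca_prev, c_prev = (coords[-3][2], coords[-2][2], coords[-1][2])
        psi_prev = torsions[i - 2][1]
        n_i = _place_atom(n_prev, ca_prev, c_prev, _BOND_C_N, _ANGLE_CA_C_N, psi_prev)
        ca_i = _place_atom(ca_prev, c_prev, n_i, _BOND_N_CA, _ANGLE_C_N_CA, _OMEGA)
        c_i = _place_atom(c_prev, n_i, ca_i, _BOND_CA_C, _ANGLE_N_CA_C, phi)
        coords += [("N", i, n_i), ("CA", i, ca_i), ("C", i, c_i)]
    atoms = [
        Atom(
            id=k + 1,
            element=elem[name],
            xyz=xyz,
            chain_tag=chain_tag,
            residue_index=res,
            name=name,
            **par[elem[name]],
        )
        for k, (name, res, xyz) in enumerate(coords)
    ]
    return Structure(atoms)


def _sphere_pair(separation: float, radius: float = 1.9, params=None) -> Structure:
    par = dict((params or DEFAULT_ATOM_PARAMS)["C"])
    par["radius"] = radius
    mk = lambda i, x, tag: Atom(
        id=i, element="C", xyz=np.array([x, 0.0, 0.0]), chain_tag=tag,
        residue_index=i, name="C", **par
    )
    return Structure([mk(1, 0.0, "protein"), mk(2, separation, "peptide")])


def _random_dimer(
    n_protein: int, n_peptide: int, separation: float, rng: np.random.Generator
) -> Structure:
    atoms = []
    i = 0
    for tag, n_atoms, center in (
        ("protein", n_protein, np.zeros(3)),
        ("peptide", n_peptide, np.array([separation, 0.0, 0.0])),
    ):
        for _ in range(n_atoms):
            i += 1
            elem = rng.choice(["C", "N", "O"])
            atoms.append(
                Atom(
                    id=i,
                    element=str(elem),
                    xyz=center + rng.normal(0.0, 2.5, size=3),
                    chain_tag=tag,
                    residue_index=i,
                    name=str(elem),
                    **DEFAULT_ATOM_PARAMS[str(elem)],
                )
            )
    return Structure(atoms)


def gen_structure(
    kind: str,
    seed: int = 0,
    pdb_path: str | Path | None = None,
    **params,
) -> Structure:
    """Deterministic toy structure of the requested kind.

    ``kind`` is one of ``sphere-pair`` (two tagged atoms, ``separation``,
    ``radius``), ``ideal-strand`` / ``ideal-helix`` (backbone with exact
    ``phi``/``psi``, ``n_residues``), or ``random-dimer`` (``n_protein``,
    ``n_peptide`` atoms in two blobs ``separation`` apart).  When
    ``pdb_path`` is given the structure is also written as a PDB-format
    file (chain A protein, chain B peptide).
    """
    rng = np.random.default_rng(seed)
    if kind == "sphere-pair":
        s = _sphere_pair(
            separation=float(params.get("separation", 10.0)),
            radius=float(params.get("radius", 1.9)),
        )
    elif kind in {"ideal-strand", "ideal-helix"}:
        phi = float(params.get("phi", -120.0 if kind == "ideal-strand" else -57.0))
        psi = float(params.get("psi", 130.0 if kind == "ideal-strand" else -47.0))
        n_res = int(params.get("n_residues", 5))
        s = build_backbone([(phi, psi)] * n_res,
                           chain_tag=params.get("chain_tag", "peptide"))
    elif kind == "random-dimer":
        s = _random_dimer(
            n_protein=int(params.get("n_protein", 20)),
            n_peptide=int(params.get("n_peptide", 20)),
            separation=float(params.get("separation", 8.0)),
            rng=rng,
        )
    else:
        raise ValueError(f"unknown structure kind {kind!r}")
    if pdb_path is not None:
        write_pdb(s, pdb_path)
    return s


# --------------------------------------------------------------------------
# Work samples
# --------------------------------------------------------------------------

def gen_work_samples(
    mu: float,
    sigma: float,
    n: int,
    temperature: float = 298.15,
    seed: int = 0,
) -> tuple[WorkSamples, float]:
    """Crooks-consistent gaussian forward/reverse work samples.

    Forward work ~ N(mu, sigma^2); reverse work ~ N(-mu + sigma^2 beta,
    sigma^2), which satisfies the Crooks fluctuation relation with the
    closed-form free energy dG = mu - sigma^2 beta / 2.  Returns the samples
    and that ground-truth value.
    """
    rng = np.random.default_rng(seed)
    beta = 1.0 / (BOLTZMANN_KCAL * temperature)
    forward = mu + sigma * rng.standard_normal(n)
    reverse = (-mu + sigma**2 * beta) + sigma * rng.standard_normal(n)
    true_dg = mu - sigma**2 * beta / 2.0
    return WorkSamples(forward, reverse, temperature=temperature), true_dg
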