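"""Deterministic synthetic fixtures for every pipeline stage.

Everything here is generated from an integer seed and writes the same
standard formats (PDB/FASTA/CSV) the rest of the package consumes, so
no external structure or sequence downloads are ever needed for
testing.  Ground truth (applied transforms, noise levels, designed
contact counts) is returned in structure/sidecar metadata rather than
re-derived in test code.

Generators
----------
make_helix
    ideal poly-alanine α-helix backbone (rise 1.5 Å, 100° twist per
    residue, CA radius 2.3 Å) — a stand-in protein scaffold whose CA–CA
    spacing (≈ 3.8 Å) matches real chains.
perturb
    rigid motion plus i.i.d. per-coordinate Gaussian noise of known σ;
    after optimal re-superposition the expected RMSD is σ√3.
make_sequence_pair
    a random sequence and a copy with an exact designed number of
    substitutions, for identity/similarity statistics of known truth.
make_calibration_table
    (similarity, RMSD) points scattered around a known line, for
    regression-recovery tests.
make_pocket_scene
    a point ligand inside a spherical-cap shell of carbon atoms whose
    designed occlusion equals ``coverage`` under the default probing
    parameters (the cap angle is shrunk by the blocker inflation angle
    so the probe-inflated shell blocks exactly the requested solid
    angle).
make_contact_scene
    a minimal receptor/ligand pair with exactly one designed hydrogen
    bond and one van der Waals contact.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .errormodel import CalibrationPoint
from .errors import ValidationError
from .pocket import DEFAULT_RADIUS, VDW_RADII, fibonacci_sphere
from .structures import Atom, SequenceRecord, Structure

_AA20 = "ACDEFGHIKLMNPQRSTVWY"

# helix geometry: cylindrical (radius, phase offset deg, z offset) per atom
_HELIX_RISE = 1.5
_HELIX_TWIST = 100.0  # degrees per residue
_HELIX_ATOMS = (
    ("N", "N", 1.60, -26.0, -0.90),
    ("CA", "C", 2.30, 0.0, 0.00),
    ("C", "C", 1.70, 27.0, 0.70),
    ("O", "O", 2.00, 40.0, 1.40),
)


def make_helix(n_residues: int, chain_id: str = "A", label: str = "helix") -> Structure:
    """Ideal α-helix backbone, N/CA/C/O per residue, poly-alanine."""
    if n_residues < 3:
        raise ValidationError(f"helix needs >= 3 residues, got {n_residues}")
    atoms = []
    for i in range(n_residues):
        base = math.radians(i * _HELIX_TWIST)
        z0 = i * _HELIX_RISE
        for name, element, radius, dphi, dz in _HELIX_ATOMS:
            phi = base + math.radians(dphi)
            atoms.append(
                Atom(
                    name=name,
                    element=element,
                    residue_name="ALA",
                    residue_number=i + 1,
                    chain_id=chain_id,
                    position=np.array(
                        [radius * math.cos(phi), radius * math.sin(phi), z0 + dz]
                    ),
                )
            )
    return Structure(atoms, label=label)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation matrix."""
    quat = rng.normal(size=4)
    return Rotation.from_quat(quat / np.linalg.norm(quat)).as_matrix()


def perturb(
    structure: Structure,
    sigma: float,
    rigid="random",
    seed: int = 0,
) -> Structure:
    """Apply a rigid motion then add Gaussian coordinate noise.

    ``rigid`` is ``"random"`` (seed-derived rotation plus a translation
    drawn uniformly from [-10, 10] Å per axis), ``None``/``"identity"``
    for no motion, or an explicit ``(rotation, translation)`` pair.
    The applied transform and σ are recorded in the output metadata
    under ``"rigid_rotation"``, ``"rigid_translation"`` and ``"sigma"``.
    """
    if sigma < 0:
        raise ValidationError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    if rigid == "random":
        R = random_rotation(rng)
        t = rng.uniform(-10.0, 10.0, size=3)
    elif rigid is None or rigid == "identity":
        R = np.eye(3)
        t = np.zeros(3)
    else:
        R = np.asarray(rigid[0], float)
        t = np.asarray(rigid[1], float)
    out = structure.transformed(R, t)
    if sigma > 0:
        noise = rng.normal(0.0, sigma, size=(len(out.atoms), 3))
        out = Structure(
            [
                Atom(
                    name=a.name,
                    element=a.element,
                    residue_name=a.residue_name,
                    residue_number=a.residue_number,
                    chain_id=a.chain_id,
                    position=a.position + noise[i],
                    is_hetero=a.is_hetero,
                    icode=a.icode,
                    occupancy=a.occupancy,
                    bfactor=a.bfactor,
                )
                for i, a in enumerate(out.atoms)
            ],
            label=out.label,
        )
    out.label = (structure.label + "_perturbed") if structure.label else "perturbed"
    out.metadata = {
        "sigma": sigma,
        "rigid_rotation": np.asarray(R).tolist(),
        "rigid_translation": np.asarray(t).tolist(),
        "seed": seed,
    }
    return out


def make_sequence_pair(
    length: int,
    target_identity_pct: float,
    seed: int = 0,
    ids: tuple[str, str] = ("synthA", "synthB"),
) -> tuple[SequenceRecord, SequenceRecord]:
    """A random sequence and a mutated copy of designed gapless identity.

    Exactly ``round(length * (1 - target/100))`` positions are
    substituted (never to the original residue), so the realized
    position-wise identity matches the target to within one position.
    """
    if length < 10:
        raise ValidationError("sequence pair length must be >= 10")
    if not 0 <= target_identity_pct <= 100:
        raise ValidationError("target identity must be in [0, 100]")
    rng = np.random.default_rng(seed)
    letters = np.array(list(_AA20))
    a = rng.choice(letters, size=length)
    b = a.copy()
    n_sub = round(length * (1.0 - target_identity_pct / 100.0))
    sites = rng.choice(length, size=n_sub, replace=False)
    for pos in sites:
        choices = [c for c in _AA20 if c != a[pos]]
        b[pos] = choices[rng.integers(len(choices))]
    return (
        SequenceRecord(ids[0], "".join(a)),
        SequenceRecord(ids[1], "".join(b)),
    )


def make_calibration_table(
    slope: float,
    intercept: float,
    similarities: Sequence[float],
    sigma: float = 0.0,
    seed: int = 0,
) -> tuple[list[CalibrationPoint], dict]:
    """Calibration points scattered around a known line.

    Each point's RMSD is ``max(0, intercept + slope*s + N(0, sigma))``.
    Returns ``(points, truth)`` where ``truth`` records the generating
    slope, intercept, sigma and seed.
    """
    sims = list(similarities)
    if len(set(sims)) != len(sims):
        raise ValidationError("similarities must be distinct")
    rng = np.random.default_rng(seed)
    points = []
    for k, s in enumerate(sims):
        y = intercept + slope * s + (rng.normal(0.0, sigma) if sigma > 0 else 0.0)
        points.append(CalibrationPoint(f"synth{k}", float(s), max(0.0, float(y))))
    truth = dict(slope=slope, intercept=intercept, sigma=sigma, seed=seed)
    return points, truth


def _cap_directions(n: int, cos_theta_max: float, seed: int) -> np.ndarray:
    """Quasi-uniform unit vectors on the cap z >= cos_theta_max (golden spiral)."""
    i = np.arange(n)
    rng = np.random.default_rng(seed)
    phase = rng.uniform(0.0, 2.0 * math.pi)
    z = 1.0 - (1.0 - cos_theta_max) * (i + 0.5) / n
    phi = i * math.pi * (3.0 - math.sqrt(5.0)) + phase
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def make_pocket_scene(
    coverage: float,
    n_shell_atoms: int = 600,
    shell_radius: float = 8.0,
    probe_radius: float = 1.4,
    seed: int = 0,
) -> tuple[Structure, Structure]:
    """Point ligand at the origin inside a spherical-cap carbon shell.

    ``coverage`` is the designed occlusion: the fraction of directions
    from the origin blocked by the probe-inflated shell.  Each shell
    carbon blocks a cone of half-angle ``asin((r_C + probe)/R)``, so the
    cap of atom centers is shrunk by that inflation angle to make the
    blocked solid-angle fraction equal ``coverage`` (under the default
    probing parameters recorded in the receptor metadata).
    """
    if not 0.0 <= coverage <= 1.0:
        raise ValidationError("coverage must be in [0, 1]")
    ligand = Structure(
        [
            Atom(
                name="C1",
                element="C",
                residue_name="LIG",
                residue_number=1,
                chain_id="L",
                position=np.zeros(3),
                is_hetero=True,
            )
        ],
        label="point_ligand",
    )
    alpha = math.asin(min(1.0, (VDW_RADII["C"] + probe_radius) / shell_radius))
    atoms = []
    if coverage > 0:
        theta_edge = math.acos(1.0 - 2.0 * coverage)  # cap angle incl. inflation
        theta_max = max(0.0, theta_edge - alpha)
        dirs = _cap_directions(n_shell_atoms, math.cos(theta_max), seed)
        for k, d in enumerate(dirs):
            atoms.append(
                Atom(
                    name="C1",
                    element="C",
                    residue_name="SPH",
                    residue_number=k + 1,
                    chain_id="A",
                    position=shell_radius * d,
                )
            )
    receptor = Structure(atoms, label="shell_receptor")
    receptor.metadata = dict(
        coverage=coverage,
        n_shell_atoms=n_shell_atoms,
        shell_radius=shell_radius,
        probe_radius=probe_radius,
        inflation_angle_rad=alpha,
        seed=seed,
    )
    return receptor, ligand


def make_contact_scene() -> tuple[Structure, Structure]:
    """Receptor/ligand pair with exactly 1 designed hbond and 1 vdW contact.

    Ligand: C1 at the origin with a carbonyl-like O1 at 1.23 Å.  A
    glutamate carboxylate oxygen sits 2.9 Å from O1 in line with its
    antecedents (hydrogen bond); a leucine side-chain carbon sits
    3.54 Å from C1 (van der Waals) but beyond the O1 threshold.
    """
    ligand = Structure(
        [
            Atom("C1", "C", "LIG", 1, "L", np.array([0.0, 0.0, 0.0]), is_hetero=True),
            Atom("O1", "O", "LIG", 1, "L", np.array([1.23, 0.0, 0.0]), is_hetero=True),
        ],
        label="mini_ligand",
    )
    receptor = Structure(
        [
            Atom("OE1", "O", "GLU", 1, "A", np.array([4.13, 0.0, 0.0])),
            Atom("CD", "C", "GLU", 1, "A", np.array([5.38, 0.0, 0.0])),
            Atom("CD1", "C", "LEU", 2, "A", np.array([-0.5, 3.5, 0.0])),
            Atom("CG", "C", "LEU", 2, "A", np.array([-0.5, 4.9, 0.0])),
        ],
        label="mini_receptor",
    )
    receptor.metadata = dict(designed_hbonds=1, designed_vdw=1)
    return receptor, ligand
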