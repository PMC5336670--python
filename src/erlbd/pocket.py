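"""Receptor–ligand binding-pocket characterization.

Three geometric operators over hydrogen-free heavy-atom structures:

* pocket residues — any receptor residue with a heavy atom within a
  distance cutoff (default 4.5 Å) of any ligand heavy atom;
* hydrogen bonds — polar (N/O) donor–acceptor pairs within 2.4–3.5 Å
  whose geometry, judged by a donor-antecedent angle proxy, is not
  grossly bent (default minimum 120°).  With no hydrogens in the model
  the donor/acceptor roles are not assigned; both polar partners must
  pass the angle test when a bonded neighbour is identifiable;
* van der Waals contacts — heavy-atom pairs closer than the sum of
  their Bondi radii plus a slack (default 0.5 Å), excluding pairs
  already classified as hydrogen bonds.

Occlusion of the pocket is scored by casting rays from the ligand
centroid along a deterministic Fibonacci-sphere direction set and
counting the fraction blocked by probe-inflated receptor atoms within
15 Å: 0 = fully solvent-exposed, 1 = fully enclosed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .errors import ValidationError
from .structures import Atom, AtomLabel, ResidueLabel, Structure

log = logging.getLogger(__name__)

#: Bondi-style van der Waals radii (Å), by element symbol.
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "Cl": 1.75,
    "Br": 1.85,
    "I": 1.98,
}
DEFAULT_RADIUS = 1.70

#: Elements accepted as hydrogen-bond donors/acceptors (heavy-atom criterion).
POLAR_ELEMENTS = ("N", "O")

#: Covalent-neighbour search radius used by the angle proxy (Å).
COVALENT_MAX = 1.8


def vdw_radius(element: str) -> float:
    el = element.capitalize()
    if el not in VDW_RADII:
        log.warning("unknown element %r; using default vdW radius %.2f Å",
                    element, DEFAULT_RADIUS)
        return DEFAULT_RADIUS
    return VDW_RADII[el]


@dataclass(frozen=True)
class Contact:
    """A classified receptor–ligand interaction."""

    receptor_atom: AtomLabel
    ligand_atom: AtomLabel
    distance: float
    kind: str  # "hbond" | "vdw"
    angle: float | None = None  # degrees; hbond angle proxy when available

    def __post_init__(self) -> None:
        if self.distance <= 0:
            raise ValidationError("contact distance must be positive")
        if self.kind not in ("hbond", "vdw"):
            raise ValidationError(f"unknown contact kind {self.kind!r}")


@dataclass
class ContactReport:
    """Pocket residues, classified contacts and the occlusion score."""

    pocket_residues: list[ResidueLabel]
    contacts: list[Contact]
    occlusion: float
    occlusion_origin: str = "centroid"
    parameters: dict = field(default_factory=dict)

    @property
    def hbonds(self) -> list[Contact]:
        return [c for c in self.contacts if c.kind == "hbond"]

    @property
    def vdw_contacts(self) -> list[Contact]:
        return [c for c in self.contacts if c.kind == "vdw"]


def _heavy(structure: Structure) -> list[Atom]:
    return [a for a in structure.atoms if a.element.upper() != "H"]


def _require_ligand(ligand: Structure) -> list[Atom]:
    atoms = _heavy(ligand)
    if not atoms:
        raise ValidationError("ligand contains no heavy atoms")
    return atoms


def find_pocket_residues(
    receptor: Structure, ligand: Structure, cutoff: float = 4.5
) -> list[ResidueLabel]:
    """Receptor residues with >= 1 heavy atom within ``cutoff`` of the ligand.

    Ordered by chain then residue number (then insertion code).
    """
    if cutoff <= 0:
        raise ValidationError("cutoff must be positive")
    lig_atoms = _require_ligand(ligand)
    rec_atoms = _heavy(receptor)
    if not rec_atoms:
        return []
    tree = cKDTree(np.stack([a.position for a in rec_atoms]))
    lig_xyz = np.stack([a.position for a in lig_atoms])
    hits: set[int] = set()
    for idxs in tree.query_ball_point(lig_xyz, cutoff):
        hits.update(idxs)
    labels = {
        ResidueLabel(a.chain_id, a.residue_number, a.icode, a.residue_name)
        for i, a in enumerate(rec_atoms)
        if i in hits
    }
    return sorted(labels, key=lambda r: (r.chain_id, r.residue_number, r.icode))


def _antecedent(atom: Atom, residue_atoms: Sequence[Atom]) -> Atom | None:
    """Nearest covalently-bonded heavy neighbour within the same residue."""
    best = None
    best_d = COVALENT_MAX
    for other in residue_atoms:
        if other is atom or other.element.upper() == "H":
            continue
        d = float(np.linalg.norm(other.position - atom.position))
        if 0.0 < d <= best_d:
            best, best_d = other, d
    return best


def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle at vertex b, in degrees."""
    u, v = a - b, c - b
    cosang = float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
    return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))


def _residue_atom_map(structure: Structure) -> dict[tuple, list[Atom]]:
    groups: dict[tuple, list[Atom]] = {}
    for a in structure.atoms:
        groups.setdefault(a.residue_key, []).append(a)
    return groups


def detect_hbonds(
    receptor: Structure,
    ligand: Structure,
    d_max: float = 3.5,
    angle_min: float = 120.0,
    d_min: float = 2.4,
) -> list[Contact]:
    """Heavy-atom hydrogen bonds between receptor and ligand polar atoms.

    A pair qualifies when both atoms are N or O, the distance lies in
    ``[d_min, d_max]``, and every identifiable antecedent angle
    (bonded-neighbour — polar atom — partner) is at least ``angle_min``.
    Pairs with no identifiable antecedent fall back to distance-only.
    """
    lig_atoms = [a for a in _require_ligand(ligand) if a.element.capitalize() in POLAR_ELEMENTS]
    rec_atoms = [a for a in _heavy(receptor) if a.element.capitalize() in POLAR_ELEMENTS]
    rec_res = _residue_atom_map(receptor)
    lig_res = _residue_atom_map(ligand)
    contacts: list[Contact] = []
    for ra in rec_atoms:
        for la in lig_atoms:
            d = float(np.linalg.norm(ra.position - la.position))
            if not (d_min <= d <= d_max):
                continue
            angles = []
            ra_ante = _antecedent(ra, rec_res[ra.residue_key])
            if ra_ante is not None:
                angles.append(_angle_deg(ra_ante.position, ra.position, la.position))
            la_ante = _antecedent(la, lig_res[la.residue_key])
            if la_ante is not None:
                angles.append(_angle_deg(la_ante.position, la.position, ra.position))
            if angles and min(angles) < angle_min:
                continue
            contacts.append(
                Contact(
                    receptor_atom=ra.label,
                    ligand_atom=la.label,
                    distance=d,
                    kind="hbond",
                    angle=min(angles) if angles else None,
                )
            )
    return contacts


def detect_vdw_contacts(
    receptor: Structure,
    ligand: Structure,
    slack: float = 0.5,
    hbonds: Sequence[Contact] | None = None,
) -> list[Contact]:
    """Heavy-atom pairs within the sum of vdW radii plus ``slack``.

    Pairs already classified as hydrogen bonds are excluded; pass the
    hbond list explicitly to control the exclusion, otherwise it is
    recomputed with default criteria.
    """
    if hbonds is None:
        hbonds = detect_hbonds(receptor, ligand)
    taken = {(c.receptor_atom, c.ligand_atom) for c in hbonds}
    lig_atoms = _require_ligand(ligand)
    rec_atoms = _heavy(receptor)
    contacts: list[Contact] = []
    for ra in rec_atoms:
        r_r = vdw_radius(ra.element)
        for la in lig_atoms:
            if (ra.label, la.label) in taken:
                continue
            threshold = r_r + vdw_radius(la.element) + slack
            d = float(np.linalg.norm(ra.position - la.position))
            if 0.0 < d <= threshold:
                contacts.append(
                    Contact(
                        receptor_atom=ra.label,
                        ligand_atom=la.label,
                        distance=d,
                        kind="vdw",
                    )
                )
    return contacts


def fibonacci_sphere(n: int) -> np.ndarray:
    """``n`` quasi-uniform unit vectors (golden-angle spiral)."""
    i = np.arange(n)
    z = 1.0 - 2.0 * (i + 0.5) / n
    phi = i * math.pi * (3.0 - math.sqrt(5.0))
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _blocked_fraction(
    origin: np.ndarray,
    atoms: Sequence[Atom],
    directions: np.ndarray,
    probe_radius: float,
    max_dist: float,
) -> float:
    centers = np.stack([a.position for a in atoms]) - origin
    radii = np.array([vdw_radius(a.element) + probe_radius for a in atoms])
    dist = np.linalg.norm(centers, axis=1)
    keep = dist <= max_dist
    if not np.any(keep):
        return 0.0
    centers, radii, dist = centers[keep], radii[keep], dist[keep]
    # ray r(t) = t*d blocked by sphere (c, r) iff the perpendicular
    # distance from c to the ray is <= r, with the foot at t > 0
    T = centers @ directions.T  # (m, k) projections
    perp2 = (dist**2)[:, None] - T**2
    blocked = (T > 0) & (perp2 <= (radii**2)[:, None])
    return float(np.mean(np.any(blocked, axis=0)))


def occlusion_score(
    receptor: Structure,
    ligand: Structure,
    probe_radius: float = 1.4,
    n_directions: int = 512,
    seed: int = 0,
    origin: str = "centroid",
    max_dist: float = 15.0,
) -> float:
    """Fraction of directions from the ligand blocked by the receptor.

    Rays are cast along a Fibonacci-sphere direction set (rotated as a
    whole by a seed-derived random rotation, so the set stays
    quasi-uniform but is not axis-aligned).  A ray is blocked when it
    intersects any receptor heavy atom within ``max_dist``, inflated by
    ``probe_radius``.  ``origin`` is ``"centroid"`` (ligand heavy-atom
    centroid) or ``"per_atom"`` (score averaged over ligand atoms).
    """
    lig_atoms = _require_ligand(ligand)
    rec_atoms = _heavy(receptor)
    if not rec_atoms:
        log.warning("occlusion_score: empty receptor; returning 0")
        return 0.0
    directions = fibonacci_sphere(n_directions)
    rng = np.random.default_rng(seed)
    quat = rng.normal(size=4)
    directions = directions @ Rotation.from_quat(quat / np.linalg.norm(quat)).as_matrix().T
    if origin == "centroid":
        origins = [np.mean([a.position for a in lig_atoms], axis=0)]
    elif origin == "per_atom":
        origins = [a.position for a in lig_atoms]
    else:
        raise ValidationError(f"unknown occlusion origin {origin!r}")
    scores = [
        _blocked_fraction(np.asarray(o, float), rec_atoms, directions, probe_radius, max_dist)
        for o in origins
    ]
    return float(np.mean(scores))


def analyze_pocket(
    receptor: Structure,
    ligand: Structure,
    cutoff: float = 4.5,
    hbond_d_max: float = 3.5,
    hbond_angle_min: float = 120.0,
    vdw_slack: float = 0.5,
    probe_radius: float = 1.4,
    n_directions: int = 512,
    seed: int = 0,
    occlusion_origin: str = "centroid",
) -> ContactReport:
    """Full pocket characterization: residues, contacts, occlusion."""
    pocket = find_pocket_residues(receptor, ligand, cutoff=cutoff)
    hbonds = detect_hbonds(receptor, ligand, d_max=hbond_d_max, angle_min=hbond_angle_min)
    vdws = detect_vdw_contacts(receptor, ligand, slack=vdw_slack, hbonds=hbonds)
    # pocket list must cover every contacting residue even past the cutoff
    known = set(pocket)
    rec_res = {
        a.label: ResidueLabel(a.chain_id, a.residue_number, a.icode, a.residue_name)
        for a in receptor.atoms
    }
    for c in hbonds + vdws:
        r = rec_res[c.receptor_atom]
        if r not in known:
            known.add(r)
            pocket.append(r)
    pocket = sorted(pocket, key=lambda r: (r.chain_id, r.residue_number, r.icode))
    occ = occlusion_score(
        receptor,
        ligand,
        probe_radius=probe_radius,
        n_directions=n_directions,
        seed=seed,
        origin=occlusion_origin,
    )
    return ContactReport(
        pocket_residues=pocket,
        contacts=hbonds + vdws,
        occlusion=occ,
        occlusion_origin=occlusion_origin,
        parameters=dict(
            cutoff=cutoff,
            hbond_d_max=hbond_d_max,
            hbond_angle_min=hbond_angle_min,
            vdw_slack=vdw_slack,
            probe_radius=probe_radius,
            n_directions=n_directions,
            seed=seed,
        ),
    )
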