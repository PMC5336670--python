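"""Optimal rigid-body superposition and RMSD of atomic positions.

The rotation is the Kabsch/SVD least-squares solution with the
determinant corrected to +1, so reflections are never returned.  Atom
correspondence between two structures is built from a global sequence
alignment (gap-free columns only), never from residue numbering.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .align import GAP, AlignmentResult
from .errors import DegeneracyError, InsufficientDataError, ValidationError
from .structures import AtomLabel, Structure, _selected_names


@dataclass(frozen=True)
class Superposition:
    """A proper rigid transform ``x -> R x + t`` with its post-fit RMSD."""

    rotation: np.ndarray  # (3, 3), det = +1
    translation: np.ndarray  # (3,)
    rmsd: float
    n_pairs: int

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, float)
        t = np.asarray(self.translation, float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValidationError("rotation must be 3x3 and translation length 3")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValidationError("rotation is not orthogonal")
        if abs(np.linalg.det(R) - 1.0) > 1e-8:
            raise ValidationError("rotation determinant is not +1")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, float)
        return coords @ self.rotation.T + self.translation

    def inverse(self) -> "Superposition":
        Rinv = self.rotation.T
        return Superposition(Rinv, -Rinv @ self.translation, self.rmsd, self.n_pairs)


class PairedCoordinates(NamedTuple):
    """Equal-length coordinate sets plus the per-pair atom labels."""

    x: np.ndarray  # model coordinates, (n, 3)
    y: np.ndarray  # reference coordinates, (n, 3)
    labels: list[tuple[AtomLabel, AtomLabel]]


def _check_pair_shapes(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.ndim != 2 or x.shape[1] != 3 or y.ndim != 2 or y.shape[1] != 3:
        raise ValidationError("coordinate sets must have shape (n, 3)")
    if x.shape[0] != y.shape[0]:
        raise ValidationError(
            f"coordinate sets differ in length ({x.shape[0]} vs {y.shape[0]})"
        )
    return x, y


def rmsd(x: np.ndarray, y: np.ndarray, transform: Superposition | None = None) -> float:
    """Root-mean-square deviation between paired coordinates, in Angstroms.

    When ``transform`` is given it is applied to ``x`` first; otherwise
    the coordinates are compared as-is (no fitting).
    """
    x, y = _check_pair_shapes(x, y)
    if x.shape[0] == 0:
        raise ValidationError("cannot compute RMSD of empty coordinate sets")
    if transform is not None:
        x = transform.apply(x)
    d = x - y
    return float(np.sqrt(np.mean(np.einsum("ij,ij->i", d, d))))


def superpose(x: np.ndarray, y: np.ndarray) -> Superposition:
    """Least-squares optimal rigid superposition of ``x`` onto ``y``.

    Kabsch construction: centroids removed, SVD of the covariance,
    smallest singular direction sign-flipped when needed so the rotation
    is proper.  Requires at least 3 non-collinear pairs.
    """
    x, y = _check_pair_shapes(x, y)
    n = x.shape[0]
    if n < 3:
        raise InsufficientDataError(f"superposition needs >= 3 pairs, got {n}")
    xc_mean = x.mean(axis=0)
    yc_mean = y.mean(axis=0)
    xc = x - xc_mean
    yc = y - yc_mean
    for name, c in (("x", xc), ("y", yc)):
        s = np.linalg.svd(c, compute_uv=False)
        if s[1] <= 1e-9 * max(s[0], 1.0):
            raise DegeneracyError(
                f"coordinate set {name} is degenerate (collinear or coincident points)"
            )
    H = xc.T @ yc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = yc_mean - R @ xc_mean
    fit = Superposition(R, t, 0.0, n)
    value = rmsd(x, y, fit)
    return Superposition(R, t, value, n)


def pair_atoms(
    model: Structure,
    reference: Structure,
    alignment: AlignmentResult,
    selection: str = "CA",
) -> PairedCoordinates:
    """Build paired coordinates from the gap-free columns of an alignment.

    ``alignment`` must relate the polymer sequences of ``model`` (first
    sequence) and ``reference`` (second).  For each gap-free column the
    selected atoms present in *both* residues are paired; residues
    missing a selected atom contribute nothing for that atom name.
    """
    seq_a, seq_b = alignment.degapped()
    res_m = model.polymer_residues()
    res_r = reference.polymer_residues()
    if seq_a != model.sequence():
        raise ValidationError(
            "alignment first sequence does not match the model structure sequence"
        )
    if seq_b != reference.sequence():
        raise ValidationError(
            "alignment second sequence does not match the reference structure sequence"
        )
    names = _selected_names(selection)
    xs: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    labels: list[tuple[AtomLabel, AtomLabel]] = []
    i = j = 0
    for ca, cb in alignment.columns():
        if ca != GAP and cb != GAP:
            rm, rr = res_m[i], res_r[j]
            if names is None:
                shared = [
                    a.name
                    for a in rm.heavy_atoms()
                    if rr.atom(a.name) is not None
                    and rr.atom(a.name).element.upper() != "H"
                ]
            else:
                shared = [
                    nm
                    for nm in names
                    if rm.atom(nm) is not None and rr.atom(nm) is not None
                ]
            for nm in shared:
                am, ar = rm.atom(nm), rr.atom(nm)
                xs.append(am.position)
                ys.append(ar.position)
                labels.append((am.label, ar.label))
        if ca != GAP:
            i += 1
        if cb != GAP:
            j += 1
    if len(xs) < 3:
        raise InsufficientDataError(
            f"alignment yields only {len(xs)} atom pairs; >= 3 required"
        )
    return PairedCoordinates(np.stack(xs), np.stack(ys), labels)


def superpose_structures(
    model: Structure,
    reference: Structure,
    alignment: AlignmentResult,
    selection: str = "CA",
) -> tuple[Superposition, PairedCoordinates]:
    """Convenience: pair atoms by alignment, then superpose model on reference."""
    pairs = pair_atoms(model, reference, alignment, selection=selection)
    return superpose(pairs.x, pairs.y), pairs
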