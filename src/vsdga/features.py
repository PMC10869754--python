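"""Structural collective variables for voltage-sensor analysis.

Computes, from coordinate frames: superposition-based helix translocation
(distance along a reference axis) and rotation (spin angle about a local
helical axis), the displacement charge coupling the charge distribution to
the transmembrane potential, salt-bridge distances between named atoms or
group centers of mass, and geometric hydrogen bonds.

Units: angstrom, degrees, elementary charge.  Angles are reported in
(-180, 180] everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StructureFrame",
    "HelixCV",
    "HBondCriteria",
    "kabsch_align",
    "distance_z",
    "spin_angle",
    "displacement_charge",
    "salt_bridge_distances",
    "hydrogen_bonds",
    "committor_distance_pairs",
]

# standard atomic masses for element inference from atom names
_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974,
           "S": 32.06, "F": 18.998}


def _mass_from_name(name: str) -> float:
    """Infer an atomic mass from a PDB-style atom name (first alphabetic
    character that is a known element; two-letter guesses are not needed
    for protein/lipid heavy atoms)."""
    for ch in name:
        if ch.isalpha():
            return _MASSES.get(ch.upper(), 12.011)
    return 12.011


@dataclass
class StructureFrame:
    """A single coordinate frame with identifiers and optional charges.

    ``unwrapped_z`` are z-coordinates without periodic wrapping, required
    for the displacement charge (wrapped coordinates would make the charge
    jump discontinuously as atoms cross the box boundary).
    """

    coords: np.ndarray                       # (n_atoms, 3), angstrom
    atom_names: list[str]
    residue_ids: np.ndarray                  # (n_atoms,) int
    residue_names: list[str] | None = None
    charges: np.ndarray | None = None        # (n_atoms,), e
    box_length_z: float | None = None        # angstrom
    unwrapped_z: np.ndarray | None = None    # (n_atoms,), angstrom
    masses: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords contain non-finite values")
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        if len(self.atom_names) != len(self.coords) or len(self.residue_ids) != len(self.coords):
            raise ValueError("atom_names/residue_ids must match coords length")
        if self.masses is None:
            self.masses = np.array([_mass_from_name(n) for n in self.atom_names])

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    def select(self, residue_id: int, atom_name: str) -> int:
        """Index of a single atom by (residue id, atom name)."""
        hits = np.flatnonzero(
            (self.residue_ids == residue_id)
            & np.array([n == atom_name for n in self.atom_names])
        )
        if hits.size != 1:
            candidates = sorted(
                {n for n, r in zip(self.atom_names, self.residue_ids) if r == residue_id}
            )
            raise KeyError(
                f"atom {atom_name!r} in residue {residue_id} resolved to "
                f"{hits.size} atoms; residue has atoms {candidates}"
            )
        return int(hits[0])

    def com(self, indices: np.ndarray) -> np.ndarray:
        """Mass-weighted center of an atom index set."""
        idx = np.asarray(indices, dtype=int)
        if idx.size == 0:
            raise ValueError("empty selection")
        m = self.masses[idx]
        return (self.coords[idx] * m[:, None]).sum(axis=0) / m.sum()


@dataclass
class HelixCV:
    """Helix translocation/rotation pair; theta in (-180, 180]."""

    translocation: float   # angstrom
    rotation: float        # degrees

    def __post_init__(self) -> None:
        self.rotation = float(-((-self.rotation + 180.0) % 360.0 - 180.0))


@dataclass
class HBondCriteria:
    """Geometric hydrogen-bond criteria: donor-acceptor heavy-atom distance
    cutoff and minimum donor-hydrogen-acceptor angle."""

    max_heavy_distance: float = 3.5   # angstrom
    min_angle: float = 120.0          # degrees

    def __post_init__(self) -> None:
        if self.max_heavy_distance <= 0:
            raise ValueError("distance cutoff must be positive")
        if not (0 < self.min_angle <= 180):
            raise ValueError("angle cutoff must be in (0, 180]")


def kabsch_align(
    mobile: StructureFrame,
    reference: StructureFrame,
    selection: np.ndarray,
) -> tuple[StructureFrame, np.ndarray, float]:
    """Rigid-body superposition minimizing the selection RMSD.

    Returns the aligned copy of ``mobile`` (all atoms transformed), the
    proper rotation matrix, and the post-alignment RMSD over the selection.
    """
    sel = np.asarray(selection, dtype=int)
    if sel.size < 3:
        raise ValueError("alignment selection needs at least 3 atoms")
    P = mobile.coords[sel]
    Q = reference.coords[sel]
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    # collinearity check: rank of the centered selection
    if np.linalg.matrix_rank(Pc, tol=1e-8) < 2 or np.linalg.matrix_rank(Qc, tol=1e-8) < 2:
        raise ValueError("alignment selection is collinear or degenerate")
    H = Pc.T @ Qc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    moved = (mobile.coords - P.mean(axis=0)) @ R.T + Q.mean(axis=0)
    rmsd = float(np.sqrt(np.mean(np.sum((moved[sel] - Q) ** 2, axis=1))))
    aligned = StructureFrame(
        coords=moved,
        atom_names=list(mobile.atom_names),
        residue_ids=mobile.residue_ids.copy(),
        residue_names=mobile.residue_names,
        charges=mobile.charges,
        box_length_z=mobile.box_length_z,
        unwrapped_z=mobile.unwrapped_z,
        masses=mobile.masses,
    )
    return aligned, R, rmsd


def distance_z(
    frame: StructureFrame,
    reference: StructureFrame,
    main_selection: np.ndarray,
    axis: np.ndarray | None = None,
) -> float:
    """Translocation: projection of the COM displacement of the selection
    (frame relative to reference) onto an axis.

    The axis defaults to the principal inertia axis of the reference
    selection; the caller is expected to have aligned the frame on a static
    selection first.
    """
    sel = np.asarray(main_selection, dtype=int)
    if sel.size == 0:
        raise ValueError("empty selection")
    if axis is None:
        axis = principal_axis(reference, sel)
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    return float((frame.com(sel) - reference.com(sel)) @ axis)


def principal_axis(frame: StructureFrame, selection: np.ndarray) -> np.ndarray:
    """Principal inertia axis (smallest moment, i.e. the long axis) of a
    selection, oriented to have a nonnegative z-component."""
    sel = np.asarray(selection, dtype=int)
    X = frame.coords[sel] - frame.com(sel)
    m = frame.masses[sel]
    r2 = (X**2).sum(axis=1)
    inertia = (m * r2).sum() * np.eye(3) - np.einsum("a,ai,aj->ij", m, X, X)
    I = inertia
    vals, vecs = np.linalg.eigh(I)
    ax = vecs[:, 0]  # smallest moment = long axis for a helix
    if ax[2] < 0:
        ax = -ax
    return ax


def spin_angle(
    frame: StructureFrame,
    reference: StructureFrame,
    selection: np.ndarray,
    axis: np.ndarray | None = None,
) -> float:
    """Rotation (degrees) about the axis through the selection COM that
    best superimposes the reference selection onto the frame selection.

    Closed form: theta = atan2(sum (r_ref_perp x r_perp) . e,
    sum r_ref_perp . r_perp) on axis-perpendicular components, which is the
    RMSD-minimizing angle.  Positive = right-handed about the axis.
    """
    sel = np.asarray(selection, dtype=int)
    if axis is None:
        axis = principal_axis(reference, sel)
    e = np.asarray(axis, dtype=float)
    e = e / np.linalg.norm(e)
    X = frame.coords[sel] - frame.com(sel)
    Y = reference.coords[sel] - reference.com(sel)
    # remove axis-parallel components
    Xp = X - np.outer(X @ e, e)
    Yp = Y - np.outer(Y @ e, e)
    if np.max(np.linalg.norm(Xp, axis=1)) < 1e-10 or np.max(np.linalg.norm(Yp, axis=1)) < 1e-10:
        raise ValueError("all atoms lie on the rotation axis; spin angle undefined")
    m = frame.masses[sel]
    num = float(np.sum(m * (np.cross(Yp, Xp) @ e)))
    den = float(np.sum(m * np.sum(Yp * Xp, axis=1)))
    return float(np.degrees(np.arctan2(num, den)))


def displacement_charge(frame: StructureFrame) -> float:
    """Displacement charge Q_d = sum_i q_i (z_i_unwrapped + Lz/2)/Lz (e).

    Requires partial charges, the box length along z, and unwrapped
    z-coordinates; silently substituting wrapped coordinates is forbidden
    because wrapping makes Q_d discontinuous.
    """
    if frame.charges is None:
        raise ValueError("displacement charge requires partial charges")
    if frame.box_length_z is None or frame.box_length_z <= 0:
        raise ValueError("displacement charge requires box_length_z > 0")
    if frame.unwrapped_z is None:
        raise ValueError(
            "displacement charge requires unwrapped z-coordinates; "
            "wrapped coordinates are not a valid substitute"
        )
    q = np.asarray(frame.charges, dtype=float)
    z = np.asarray(frame.unwrapped_z, dtype=float)
    Lz = frame.box_length_z
    return float(np.sum(q * (z + Lz / 2.0) / Lz))


def _resolve_target(frame: StructureFrame, target) -> np.ndarray:
    """A target is (resid, atom_name) for a single atom or a list of such
    tuples for a group (distance taken to the mass-weighted center)."""
    if isinstance(target, tuple) and len(target) == 2 and not isinstance(target[0], tuple):
        return np.array([frame.select(*target)])
    return np.array([frame.select(*t) for t in target])


def salt_bridge_distances(frame: StructureFrame, pairs: list) -> np.ndarray:
    """Euclidean distances for a list of (target, target) pairs, where each
    target is a single atom ``(resid, name)`` or a group of atoms whose
    mass-weighted center is used."""
    out = np.empty(len(pairs))
    for i, (a, b) in enumerate(pairs):
        pa = frame.com(_resolve_target(frame, a))
        pb = frame.com(_resolve_target(frame, b))
        out[i] = float(np.linalg.norm(pa - pb))
    return out


def hydrogen_bonds(
    frame: StructureFrame,
    donors: list[tuple[int, int]],
    acceptors: np.ndarray,
    criteria: HBondCriteria | None = None,
) -> list[tuple[int, int, int]]:
    """Geometric hydrogen bonds: (donor, hydrogen, acceptor) index triples
    with donor-acceptor distance <= cutoff and D-H-A angle >= cutoff."""
    crit = criteria or HBondCriteria()
    X = frame.coords
    out = []
    for d_idx, h_idx in donors:
        for a_idx in np.asarray(acceptors, dtype=int):
            if a_idx == d_idx:
                continue
            da = np.linalg.norm(X[a_idx] - X[d_idx])
            if da > crit.max_heavy_distance:
                continue
            v1 = X[d_idx] - X[h_idx]
            v2 = X[a_idx] - X[h_idx]
            cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            if ang >= crit.min_angle:
                out.append((int(d_idx), int(h_idx), int(a_idx)))
    return out


# default residue groups for the committor distance basis: the five sensing
# arginines of the S4 helix and six acidic countercharges
SENSING_ARGININES = (217, 223, 226, 229, 232)
ACIDIC_PARTNERS = ((129, "ASP"), (136, "ASP"), (151, "ASP"), (164, "ASP"),
                   (183, "GLU"), (186, "ASP"))


def committor_distance_pairs(
    arginines: tuple[int, ...] = SENSING_ARGININES,
    acidic: tuple[tuple[int, str], ...] = ACIDIC_PARTNERS,
) -> list:
    """Pair list for the committor distance basis.

    All intergroup CA-CA distances plus all distances between the arginine
    guanidinium CZ and the carboxylate carbon (CG for aspartate, CD for
    glutamate) of the acidic partners: len(arginines) * len(acidic) of each.
    """
    pairs = []
    for r in arginines:
        for resid, _ in acidic:
            pairs.append(((r, "CA"), (resid, "CA")))
    for r in arginines:
        for resid, resname in acidic:
            carbon = "CG" if resname.upper() in ("ASP", "D") else "CD"
            pairs.append(((r, "CZ"), (resid, carbon)))
    return pairs
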