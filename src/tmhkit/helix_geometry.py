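"""Helix construction and hinge geometry.

Builds ideal and perturbed α-helices from internal coordinates (NeRF chain
extension with canonical peptide bond lengths/angles), measures hinge ("kink")
geometry in the bend / wobble / face-shift convention, classifies χ1 rotamers,
and performs least-squares superposition.

Conventions
-----------
* Dihedrals are degrees in (−180, 180].  φ_i = C_{i−1}–N_i–CA_i–C_i,
  ψ_i = N_i–CA_i–C_i–N_{i+1}, ω_i = CA_{i−1}–C_{i−1}–N_i–CA_i (the peptide
  bond preceding residue i), χ1 = N–CA–CB–γ.
* Helix axes are total-least-squares line fits to Cα windows (≥ 4 residues),
  oriented N→C.
* The bend angle is the angle between the pre- and post-hinge axes.  The
  wobble angle is the azimuth of the post-hinge axis about the pre-hinge
  axis, measured right-handedly with zero at the projection of the hinge-Cα
  radial vector.  The face shift compares the helical phase of Cα about the
  axis on the two sides of the hinge after correcting for the ideal
  100°/residue phase advance.
* χ1 rotamers follow the convention in which gauche-minus is the *positive*
  interval: g− = [0°, 120°), g+ = (−120°, 0°), trans = |χ1| ≥ 120°.  The
  mirrored community convention is available via ``convention="mirror"``.
"""

from __future__ import annotations

import copy as _copy
import enum
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .structure_io import AtomRecord, StructureModel

__all__ = [
    "ONE_TO_THREE",
    "THREE_TO_ONE",
    "GAMMA_ATOM",
    "RotamerState",
    "HelixSegment",
    "KinkGeometry",
    "build_ideal_helix",
    "set_dihedral",
    "fit_helix_axis",
    "kink_geometry",
    "classify_chi1",
    "superpose",
    "aromatic_stack_metrics",
    "dihedral_angle",
    "wrap_angle",
]

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
THREE_TO_ONE = {v: k for k, v in ONE_TO_THREE.items()}

#: γ heavy atom reached by χ1, with (name, CB–γ bond length Å, CA–CB–γ angle °)
GAMMA_ATOM = {
    "ARG": ("CG", 1.52, 114.0), "ASN": ("CG", 1.51, 112.6), "ASP": ("CG", 1.51, 112.6),
    "CYS": ("SG", 1.81, 114.0), "GLN": ("CG", 1.52, 114.0), "GLU": ("CG", 1.52, 114.0),
    "HIS": ("CG", 1.50, 113.8), "ILE": ("CG1", 1.53, 110.4), "LEU": ("CG", 1.53, 116.3),
    "LYS": ("CG", 1.52, 114.0), "MET": ("CG", 1.52, 114.0), "PHE": ("CG", 1.50, 113.8),
    "PRO": ("CG", 1.50, 104.5), "SER": ("OG", 1.43, 109.5), "THR": ("OG1", 1.43, 109.5),
    "TRP": ("CG", 1.50, 113.8), "TYR": ("CG", 1.50, 113.8), "VAL": ("CG1", 1.53, 110.4),
}

# canonical peptide internal coordinates (Engh–Huber-like values)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_CA_CB = 1.529
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.5
ANGLE_C_CA_CB = 109.5
TORSION_N_C_CA_CB = 120.0  # L-amino-acid chirality improper
ANGLE_N_CA_CB = 110.5

IDEAL_PHASE_PER_RESIDUE = 100.0  # degrees of helical phase per residue


class SequenceError(ValueError):
    """Unknown residue letter or sequence too short."""


class FitError(ValueError):
    """Degenerate input to a geometric fit."""


class PairingError(ValueError):
    """Atom sets cannot be matched for superposition."""


def wrap_angle(a):
    """Wrap angle(s) in degrees into (−180, 180]."""
    a = np.asarray(a, dtype=float)
    out = (-a + 180.0) % 360.0
    out = 180.0 - out
    return float(out) if out.ndim == 0 else out


def dihedral_angle(p0, p1, p2, p3):
    """Signed dihedral in degrees, (−180, 180]; broadcasts over leading axes."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    b1n = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    m1 = np.cross(n1, b1n)
    x = np.einsum("...i,...i", n1, n2)
    y = np.einsum("...i,...i", m1, n2)
    ang = -np.degrees(np.arctan2(y, x))  # IUPAC sign convention
    return wrap_angle(ang)


def _place_atom_f(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> tuple:
    """NeRF: position atom D bonded to C with angle B–C–D and torsion A–B–C–D.

    Pure-float inner kernel (hot path of the Monte-Carlo rebuild loop).
    """
    angle = math.radians(angle_deg)
    torsion = math.radians(torsion_deg)
    bcx, bcy, bcz = c[0] - b[0], c[1] - b[1], c[2] - b[2]
    r = math.sqrt(bcx * bcx + bcy * bcy + bcz * bcz)
    bcx, bcy, bcz = bcx / r, bcy / r, bcz / r
    abx, aby, abz = b[0] - a[0], b[1] - a[1], b[2] - a[2]
    nx = aby * bcz - abz * bcy
    ny = abz * bcx - abx * bcz
    nz = abx * bcy - aby * bcx
    r = math.sqrt(nx * nx + ny * ny + nz * nz)
    nx, ny, nz = nx / r, ny / r, nz / r
    mx = ny * bcz - nz * bcy
    my = nz * bcx - nx * bcz
    mz = nx * bcy - ny * bcx
    d0 = -bond * math.cos(angle)
    s = bond * math.sin(angle)
    d1 = s * math.cos(torsion)
    d2 = s * math.sin(torsion)
    return (c[0] + d0 * bcx + d1 * mx + d2 * nx,
            c[1] + d0 * bcy + d1 * my + d2 * ny,
            c[2] + d0 * bcz + d1 * mz + d2 * nz)


def _place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    return np.array(_place_atom_f(a, b, c, bond, angle_deg, torsion_deg))


class RotamerState(enum.Enum):
    g_plus = "g_plus"
    g_minus = "g_minus"
    trans = "trans"


def classify_chi1(chi1: float, convention: str = "paper") -> RotamerState:
    """Classify a χ1 dihedral into g+/g−/trans.

    Default convention: g− = [0°, 120°), g+ = (−120°, 0°), trans otherwise
    (boundaries: 0° → g−, ±120° and 180° → trans).  ``convention="mirror"``
    swaps the gauche labels (the convention in which g− is the negative
    interval).
    """
    chi = wrap_angle(chi1)
    if 0.0 <= chi < 120.0:
        state = RotamerState.g_minus
    elif -120.0 < chi < 0.0:
        state = RotamerState.g_plus
    else:
        state = RotamerState.trans
    if convention == "mirror" and state is not RotamerState.trans:
        state = RotamerState.g_plus if state is RotamerState.g_minus else RotamerState.g_minus
    elif convention not in ("paper", "mirror"):
        raise ValueError(f"unknown rotamer convention {convention!r}")
    return state


@dataclass
class _Residue:
    res_name: str
    res_seq: int
    bw: str | None = None
    # internal coordinates
    phi: float = -63.0
    psi: float = -42.0
    omega: float = 180.0
    chi1: float | None = None
    angle_n_ca_c: float = ANGLE_N_CA_C
    angle_ca_c_n: float = ANGLE_CA_C_N
    angle_c_n_ca: float = ANGLE_C_N_CA


class HelixSegment:
    """One transmembrane-helix segment held as internal coordinates.

    Cartesian coordinates are rebuilt deterministically from the stored
    internal coordinates after every mutation, so "set a dihedral" rotates
    all downstream atoms rigidly about the dihedral bond while leaving every
    other internal coordinate untouched.
    """

    def __init__(self, residues: list[_Residue]):
        self.residues = residues
        self._by_seq = {r.res_seq: r for r in residues}
        self._by_bw = {r.bw: r for r in residues if r.bw}
        self._atoms: dict[tuple[int, str], np.ndarray] = {}
        self._atom_order: list[tuple[int, str]] = []
        self.rebuild()

    # ------------------------------------------------------------------ build
    def rebuild(self) -> None:
        atoms: dict[tuple[int, str], tuple] = {}
        order: list[tuple[int, str]] = []
        prev = None
        n = ca = c = None
        for r in self.residues:
            if prev is None:
                n = (0.0, 0.0, 0.0)
                ca = (BOND_N_CA, 0.0, 0.0)
                ang = math.radians(r.angle_n_ca_c)
                c = (ca[0] - BOND_CA_C * math.cos(ang), BOND_CA_C * math.sin(ang), 0.0)
            else:
                pn, pca, pc = n, ca, c
                n = _place_atom_f(pn, pca, pc, BOND_C_N, prev.angle_ca_c_n, prev.psi)
                ca = _place_atom_f(pca, pc, n, BOND_N_CA, r.angle_c_n_ca, r.omega)
                c = _place_atom_f(pc, n, ca, BOND_CA_C, r.angle_n_ca_c, r.phi)
            atoms[(r.res_seq, "N")] = n
            atoms[(r.res_seq, "CA")] = ca
            atoms[(r.res_seq, "C")] = c
            order += [(r.res_seq, "N"), (r.res_seq, "CA"), (r.res_seq, "C")]
            # carbonyl O: anti-periplanar to the next N
            atoms[(r.res_seq, "O")] = _place_atom_f(n, ca, c, BOND_C_O, ANGLE_CA_C_O,
                                                    wrap_angle(r.psi + 180.0))
            order.append((r.res_seq, "O"))
            if r.res_name != "GLY":
                cb = _place_atom_f(n, c, ca, BOND_CA_CB, ANGLE_C_CA_CB, TORSION_N_C_CA_CB)
                atoms[(r.res_seq, "CB")] = cb
                order.append((r.res_seq, "CB"))
                if r.res_name in GAMMA_ATOM:
                    gname, gbond, gangle = GAMMA_ATOM[r.res_name]
                    chi = r.chi1 if r.chi1 is not None else -60.0
                    atoms[(r.res_seq, gname)] = _place_atom_f(n, ca, cb, gbond, gangle, chi)
                    order.append((r.res_seq, gname))
            prev = r
        self._atom_order = order
        pos = np.array([atoms[k] for k in order])
        self._atoms = {k: pos[i] for i, k in enumerate(order)}
        self._pos = pos

    # ----------------------------------------------------------------- access
    def resolve(self, residue) -> _Residue:
        """Resolve a residue by absolute number or BW label string."""
        if isinstance(residue, _Residue):
            return residue
        if isinstance(residue, (int, np.integer)):
            try:
                return self._by_seq[int(residue)]
            except KeyError:
                raise KeyError(f"residue {residue} not in segment") from None
        key = str(residue)
        if key in self._by_bw:
            return self._by_bw[key]
        raise KeyError(f"residue {residue!r} not in segment")

    def atom(self, residue, name: str) -> np.ndarray:
        r = self.resolve(residue)
        try:
            return self._atoms[(r.res_seq, name)]
        except KeyError:
            raise KeyError(f"atom {name} not present in residue {r.res_seq} ({r.res_name})") from None

    def ca_positions(self, residues=None) -> np.ndarray:
        res = self.residues if residues is None else [self.resolve(x) for x in residues]
        return np.array([self._atoms[(r.res_seq, "CA")] for r in res])

    @property
    def res_seqs(self) -> list[int]:
        return [r.res_seq for r in self.residues]

    def get_dihedral(self, residue, which: str) -> float:
        """Stored internal-coordinate value of φ/ψ/ω/χ1 for a residue."""
        r = self.resolve(residue)
        if which == "chi1":
            if r.chi1 is None and r.res_name in GAMMA_ATOM:
                return -60.0
            if r.res_name not in GAMMA_ATOM:
                raise KeyError(f"residue {r.res_seq} ({r.res_name}) has no chi1")
            return r.chi1
        return getattr(r, which)

    def measured_dihedral(self, residue, which: str) -> float:
        """Recompute φ/ψ/ω/χ1 from the Cartesian coordinates."""
        r = self.resolve(residue)
        i = self.residues.index(r)
        A = self._atoms
        s = r.res_seq
        if which == "phi":
            if i == 0:
                raise KeyError("phi undefined for the first residue")
            p = self.residues[i - 1].res_seq
            return dihedral_angle(A[(p, "C")], A[(s, "N")], A[(s, "CA")], A[(s, "C")])
        if which == "psi":
            if i == len(self.residues) - 1:
                raise KeyError("psi undefined for the last residue")
            nxt = self.residues[i + 1].res_seq
            return dihedral_angle(A[(s, "N")], A[(s, "CA")], A[(s, "C")], A[(nxt, "N")])
        if which == "omega":
            if i == 0:
                raise KeyError("omega undefined for the first residue")
            p = self.residues[i - 1].res_seq
            return dihedral_angle(A[(p, "CA")], A[(p, "C")], A[(s, "N")], A[(s, "CA")])
        if which == "chi1":
            if r.res_name not in GAMMA_ATOM:
                raise KeyError(f"residue {s} ({r.res_name}) has no chi1")
            g = GAMMA_ATOM[r.res_name][0]
            return dihedral_angle(A[(s, "N")], A[(s, "CA")], A[(s, "CB")], A[(s, g)])
        raise ValueError(f"unknown dihedral {which!r}")

    @property
    def atom_order(self) -> list[tuple[int, str]]:
        return list(self._atom_order)

    def positions(self) -> np.ndarray:
        """Atom positions stacked in atom order, shape (n_atoms, 3)."""
        return np.array([self._atoms[k] for k in self._atom_order])

    def _positions_view(self) -> np.ndarray:
        # fast path for energy evaluation; only valid until the next mutation
        return np.asarray([self._atoms[k] for k in self._atom_order]) \
            if self._pos is None else self._pos

    def copy(self) -> "HelixSegment":
        return HelixSegment([_copy.copy(r) for r in self.residues])

    def to_structure_model(self, chain: str = "A", model_id: int = 1) -> StructureModel:
        records = []
        for (seq, name) in self._atom_order:
            r = self._by_seq[seq]
            element = name[0] if name[0] in ("N", "C", "O", "S") else "C"
            records.append(AtomRecord(chain, seq, r.res_name, name, element,
                                      self._atoms[(seq, name)].copy()))
        return StructureModel(records, model_id=model_id)

    def apply_rigid(self, R: np.ndarray, t: np.ndarray) -> "HelixSegment":
        """Return a copy with every atom mapped x → R·x + t (breaks the
        internal-coordinate link; intended for read-only geometric tests)."""
        out = self.copy()
        for k in out._atoms:
            out._atoms[k] = R @ self._atoms[k] + np.asarray(t, dtype=float)
        out._pos = None
        return out


def build_ideal_helix(
    sequence: str,
    phi: float = -63.0,
    psi: float = -42.0,
    omega: float = 180.0,
    start_seq: int = 1,
    bw_labels: list[str | None] | None = None,
) -> HelixSegment:
    """Build a regular α-helix with uniform backbone dihedrals.

    Defaults are the canonical α-helix (φ=−63°, ψ=−42°, ω=180°).  Side chains
    are placed through the γ atom at χ1=−60° where one exists.
    """
    sequence = sequence.strip().upper()
    if len(sequence) < 8:
        raise SequenceError("helix sequence must have at least 8 residues")
    residues = []
    for k, letter in enumerate(sequence):
        if letter not in ONE_TO_THREE:
            raise SequenceError(f"unknown residue letter {letter!r} at position {k + 1}")
        residues.append(_Residue(
            res_name=ONE_TO_THREE[letter],
            res_seq=start_seq + k,
            bw=None if bw_labels is None else bw_labels[k],
            phi=phi, psi=psi, omega=omega,
            chi1=-60.0 if ONE_TO_THREE[letter] in GAMMA_ATOM else None,
        ))
    return HelixSegment(residues)


def set_dihedral(helix: HelixSegment, residue, which: str, value: float) -> HelixSegment:
    """Set one dihedral (in place) and rebuild coordinates; returns the helix.

    Requesting χ1 on Gly/Ala is a warned no-op.
    """
    value = wrap_angle(float(value))
    r = helix.resolve(residue)
    if which == "chi1":
        if r.res_name not in GAMMA_ATOM:
            warnings.warn(f"residue {r.res_seq} ({r.res_name}) has no chi1; ignoring")
            return helix
        r.chi1 = value
    elif which in ("phi", "psi", "omega"):
        setattr(r, which, value)
    else:
        raise ValueError(f"unknown dihedral {which!r}")
    helix.rebuild()
    return helix


def fit_helix_axis(ca_positions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Axis fit to ≥4 Cα positions; returns (unit axis, centroid), N→C oriented.

    For a helical trace the second differences of consecutive Cα positions
    point radially inward, i.e. they are exactly perpendicular to the helix
    axis; the axis is therefore taken as the null direction of the stacked
    second differences (smallest right singular vector).  This is exact for
    ideal helices of any window length, unlike a plain total-least-squares
    line fit, which tilts on windows covering a non-integer number of turns.
    Degenerate traces (near-collinear points, vanishing curvature) fall back
    to the total-least-squares line fit.
    """
    P = np.asarray(ca_positions, dtype=float)
    if P.ndim != 2 or P.shape[1] != 3 or P.shape[0] < 4:
        raise FitError("axis fit needs at least 4 Cα positions")
    centroid = P.mean(axis=0)
    X = P - centroid
    _, s_line, vt_line = np.linalg.svd(X, full_matrices=False)
    if s_line[0] < 1e-9:
        raise FitError("degenerate (coincident) points")
    D = P[2:] - 2.0 * P[1:-1] + P[:-2]
    _, s, vt = np.linalg.svd(D, full_matrices=False)
    if s[1] > 1e-8 * max(1.0, s[0]):
        axis = vt[2]
    else:  # straight or degenerate trace: line fit
        axis = vt_line[0]
    if np.dot(axis, P[-1] - P[0]) < 0:
        axis = -axis
    return axis, centroid


@dataclass
class KinkGeometry:
    """Hinge geometry: bend/wobble/face-shift at a named hinge residue."""

    bend_angle: float
    wobble_angle: float
    face_shift: float
    hinge_residue: str
    pre_window: tuple[int, int]
    post_window: tuple[int, int]

    def as_row(self) -> dict:
        return {
            "hinge": self.hinge_residue,
            "bend_deg": self.bend_angle,
            "wobble_deg": self.wobble_angle,
            "face_shift_deg": self.face_shift,
            "pre_window": f"{self.pre_window[0]}-{self.pre_window[1]}",
            "post_window": f"{self.post_window[0]}-{self.post_window[1]}",
        }


def _window_phase_at_hinge(P, seqs, axis, centroid, e1, e2, hinge_seq):
    """Circular-mean helical phase at the hinge position, assuming the ideal
    100°/residue advance, for one Cα window."""
    phases = []
    for p, s in zip(P, seqs):
        r = p - centroid
        r = r - np.dot(r, axis) * axis
        ph = math.degrees(math.atan2(np.dot(r, e2), np.dot(r, e1)))
        phases.append(ph - IDEAL_PHASE_PER_RESIDUE * (s - hinge_seq))
    ang = np.radians(phases)
    return math.degrees(math.atan2(np.mean(np.sin(ang)), np.mean(np.cos(ang))))


def kink_geometry(
    helix: HelixSegment,
    hinge,
    pre_window=None,
    post_window=None,
) -> KinkGeometry:
    """Bend, wobble and face shift across a hinge residue.

    ``pre_window``/``post_window`` are sequences of residue identifiers (or
    (first, last) tuples) strictly before/after the hinge, each ≥ 4 residues;
    defaults are everything before/after the hinge.
    """
    hinge_res = helix.resolve(hinge)
    seqs = helix.res_seqs

    def _window(w, default):
        if w is None:
            w = default
        elif isinstance(w, tuple) and len(w) == 2 and all(isinstance(x, (int, np.integer)) for x in w):
            w = list(range(w[0], w[1] + 1))
        return [helix.resolve(x).res_seq for x in w]

    pre = _window(pre_window, [s for s in seqs if s < hinge_res.res_seq])
    post = _window(post_window, [s for s in seqs if s > hinge_res.res_seq])
    if len(pre) < 4 or len(post) < 4:
        raise FitError("each window must contain at least 4 residues")
    if hinge_res.res_seq in pre or hinge_res.res_seq in post:
        raise ValueError("hinge residue must not be inside a window")
    if max(pre) >= hinge_res.res_seq or min(post) <= hinge_res.res_seq:
        raise ValueError("windows must lie on opposite sides of the hinge")

    P_pre = helix.ca_positions(pre)
    P_post = helix.ca_positions(post)
    a_pre, c_pre = fit_helix_axis(P_pre)
    a_post, c_post = fit_helix_axis(P_post)

    bend = math.degrees(math.acos(np.clip(np.dot(a_pre, a_post), -1.0, 1.0)))

    # wobble: azimuth of the post axis about the pre axis; zero at the
    # projection of the hinge-Cα radial vector
    ca_h = helix.atom(hinge_res.res_seq, "CA")
    r0 = ca_h - c_pre
    r0 = r0 - np.dot(r0, a_pre) * a_pre
    if np.linalg.norm(r0) < 1e-9:
        raise FitError("hinge Cα lies on the pre-hinge axis; wobble undefined")
    e1 = r0 / np.linalg.norm(r0)
    e2 = np.cross(a_pre, e1)
    perp = a_post - np.dot(a_post, a_pre) * a_pre
    if np.linalg.norm(perp) < 1e-12:
        wobble = 0.0
    else:
        wobble = math.degrees(math.atan2(np.dot(perp, e2), np.dot(perp, e1)))

    # face shift: phase of Cα about each window's axis, extrapolated to the
    # hinge with the ideal periodicity; the post frame is the pre frame
    # carried by the minimal rotation taking a_pre onto a_post
    phase_pre = _window_phase_at_hinge(P_pre, pre, a_pre, c_pre, e1, e2, hinge_res.res_seq)
    cross = np.cross(a_pre, a_post)
    if np.linalg.norm(cross) < 1e-12:
        R = np.eye(3)
    else:
        axis_r = cross / np.linalg.norm(cross)
        R = Rotation.from_rotvec(axis_r * math.radians(bend)).as_matrix()
    e1p, e2p = R @ e1, R @ e2
    phase_post = _window_phase_at_hinge(P_post, post, a_post, c_post, e1p, e2p, hinge_res.res_seq)
    face_shift = wrap_angle(phase_post - phase_pre)

    label = hinge_res.bw or str(hinge_res.res_seq)
    return KinkGeometry(
        bend_angle=bend, wobble_angle=wobble, face_shift=face_shift,
        hinge_residue=label, pre_window=(min(pre), max(pre)),
        post_window=(min(post), max(post)),
    )


@dataclass
class RigidTransform:
    R: np.ndarray
    t: np.ndarray

    def apply(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x, dtype=float) @ self.R.T + self.t


def _kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[float, RigidTransform]:
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    rot, rssd = Rotation.align_vectors(reference - rc, mobile - mc)
    R = rot.as_matrix()
    rmsd = rssd / math.sqrt(len(mobile))
    t = rc - mc @ R.T
    return float(rmsd), RigidTransform(R=R, t=t)


def superpose(
    mobile: HelixSegment | np.ndarray,
    reference: HelixSegment | np.ndarray,
    residues=None,
    atoms: tuple[str, ...] = ("N", "CA", "C", "O"),
) -> tuple[float, RigidTransform]:
    """Least-squares rigid superposition; returns (RMSD, transform).

    When HelixSegments are given, matched atom sets are collected over
    ``residues`` (default: all shared residue numbers) for the backbone
    ``atoms``.  Raw (n, 3) arrays are paired positionally.
    """
    if isinstance(mobile, np.ndarray) or isinstance(reference, np.ndarray):
        M = np.asarray(mobile, dtype=float)
        Rf = np.asarray(reference, dtype=float)
        if M.shape != Rf.shape or M.ndim != 2 or M.shape[1] != 3:
            raise PairingError("coordinate arrays must have identical (n, 3) shapes")
        return _kabsch(M, Rf)
    if residues is None:
        shared = [s for s in mobile.res_seqs if s in set(reference.res_seqs)]
    else:
        shared = [mobile.resolve(x).res_seq for x in residues]
    pts_m, pts_r = [], []
    for s in shared:
        for a in atoms:
            try:
                pm = mobile.atom(s, a)
                pr = reference.atom(s, a)
            except KeyError as exc:
                raise PairingError(f"atom {a} of residue {s} missing in one segment: {exc}") from None
            pts_m.append(pm)
            pts_r.append(pr)
    if len(pts_m) < 3:
        raise PairingError("need at least 3 matched atoms")
    return _kabsch(np.array(pts_m), np.array(pts_r))


def aromatic_stack_metrics(ring_a: np.ndarray, ring_b: np.ndarray) -> tuple[float, float]:
    """Centroid–centroid distance (Å) and interplanar angle (°, in [0, 90]).

    Ring planes are best-fit by SVD; ≥ 5 non-collinear atoms per ring.
    """
    def _plane(P):
        P = np.asarray(P, dtype=float)
        if P.ndim != 2 or P.shape[1] != 3 or P.shape[0] < 5:
            raise FitError("ring needs at least 5 atom positions")
        c = P.mean(axis=0)
        _, s, vt = np.linalg.svd(P - c)
        if s[1] < 1e-8:
            raise FitError("collinear ring atoms; plane undefined")
        return c, vt[2]

    ca, na = _plane(ring_a)
    cb, nb = _plane(ring_b)
    dist = float(np.linalg.norm(ca - cb))
    ang = math.degrees(math.acos(np.clip(abs(np.dot(na, nb)), 0.0, 1.0)))
    return dist, ang


# --------------------------------------------------------------------------
# External-structure benchmark helpers (delta opioid receptor template)
# --------------------------------------------------------------------------

def fetch_pdb(accession: str, dest: str, base_url: str = "https://files.rcsb.org/download") -> str:
    """Download a PDB entry to ``dest``; requires network access."""
    import urllib.request

    url = f"{base_url}/{accession.upper()}.pdb"
    urllib.request.urlretrieve(url, dest)
    return dest


def _read_ca_trace(path: str, chain: str, first: int, last: int) -> np.ndarray:
    """Lenient Cα extraction (first altloc, no insertion codes) from a PDB file."""
    rows: dict[int, np.ndarray] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("ATOM"):
                continue
            if line[12:16].strip() != "CA" or line[21] != chain:
                continue
            if line[16] not in (" ", "A"):  # keep first alternate location
                continue
            if line[26] != " ":
                continue
            seq = int(line[22:26])
            if first <= seq <= last and seq not in rows:
                rows[seq] = np.array([float(line[30:38]), float(line[38:46]), float(line[46:54])])
    if set(range(first, last + 1)) - set(rows):
        missing = sorted(set(range(first, last + 1)) - set(rows))
        raise FitError(f"missing Cα for residues {missing}")
    return np.array([rows[s] for s in range(first, last + 1)])


def tmh3_bend_benchmark(
    pdb_path: str,
    chain: str = "A",
    hinge_seq: int = 132,
    pre: tuple[int, int] = (120, 131),
    post: tuple[int, int] = (133, 146),
) -> float:
    """Bend angle (°) of a TMH3 Cα trace across position 3.36 of a class A
    receptor structure in author numbering (defaults: delta opioid receptor,
    where 3.50 = 146 and the 3.36 hinge = 132).

    Only Cα positions are used, so this works directly on a downloaded
    crystal structure file.
    """
    P_pre = _read_ca_trace(pdb_path, chain, *pre)
    P_post = _read_ca_trace(pdb_path, chain, *post)
    a_pre, _ = fit_helix_axis(P_pre)
    a_post, _ = fit_helix_axis(P_post)
    return math.degrees(math.acos(np.clip(np.dot(a_pre, a_post), -1.0, 1.0)))
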