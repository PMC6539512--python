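"""Per-frame trajectory metrics for GPCR activation micro-switches.

Implements the distance/angle series used to follow receptor activation in
a multi-model trajectory:

* ionic lock — minimum heteroatom distance R3.50{NE,NH1,NH2} ↔ S6.33{OG},
  hydrogen-bonded when ≤ 3.2 Å;
* arginine cage — R3.50{NE,NH1,NH2} ↔ D3.49{OD1,OD2}, salt-bridged when
  ≤ 4.0 Å;
* intracellular-end separation — distance between the unweighted Cα
  centroids of the last five cytoplasmic residues of TMH3 and TMH6;
* sodium pocket — distances from the sodium ion to the Cα of positions 3.39
  and 1.50;
* χ1 rotamer series for any side chain with a γ atom;
* generic pair distances, RMSD versus a reference, occupancy summaries.

Occupancy statistics are computed over frames at or after the equilibration
cut (default 100 ns); the plotted series always covers every frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .bw_numbering import LabelMap
from .helix_geometry import GAMMA_ATOM, RotamerState, classify_chi1, dihedral_angle
from .structure_io import AtomLookupError, StructureModel, Trajectory

__all__ = [
    "SwitchThresholds",
    "SwitchTimeSeries",
    "PairSpec",
    "pair_distance_series",
    "ionic_lock_series",
    "arginine_cage_series",
    "ic_end_separation",
    "sodium_pocket_distances",
    "chi1_series",
    "rmsd_series",
    "occupancy_summary",
    "state_report",
]

R350_ATOMS = ("NE", "NH1", "NH2")
D349_ATOMS = ("OD1", "OD2")


@dataclass
class SwitchThresholds:
    """Distance criteria and equilibration cut.

    ``hbond_heteroatom_max`` — maximum heteroatom–heteroatom distance for a
    hydrogen bond (3.2 Å); ``salt_bridge_max`` — maximum salt-bridge distance
    (4.0 Å); ``equilibration_cut`` — time (ns) before which frames are
    excluded from occupancy statistics (100 ns).
    """

    hbond_heteroatom_max: float = 3.2
    salt_bridge_max: float = 4.0
    equilibration_cut: float = 100.0

    def __post_init__(self) -> None:
        if min(self.hbond_heteroatom_max, self.salt_bridge_max) <= 0 or self.equilibration_cut < 0:
            raise ValueError("thresholds must be positive")
        if self.hbond_heteroatom_max >= self.salt_bridge_max:
            raise ValueError("hbond_heteroatom_max must be < salt_bridge_max")


@dataclass
class SwitchTimeSeries:
    """One named per-frame metric with optional threshold flags."""

    metric: str
    frame_times: np.ndarray
    values: np.ndarray
    bound_flags: np.ndarray | None = None
    threshold: float | None = None
    equilibration_cut: float = 100.0
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[0] != self.frame_times.shape[0]:
            raise ValueError("values length must equal frame count")
        if self.bound_flags is not None:
            self.bound_flags = np.asarray(self.bound_flags, dtype=bool)

    @property
    def post_cut(self) -> np.ndarray:
        return self.frame_times >= self.equilibration_cut

    @property
    def occupancy(self) -> float | None:
        """Fraction of post-equilibration frames with the flag set."""
        if self.bound_flags is None:
            return None
        sel = self.post_cut
        if not sel.any():
            return None
        return float(self.bound_flags[sel].mean())

    @property
    def occupancy_no_cut(self) -> float | None:
        if self.bound_flags is None:
            return None
        return float(self.bound_flags.mean())


@dataclass
class PairSpec:
    """Two residues (BW labels) with candidate atom sets; the per-frame value
    is the minimum distance over the atom-set cross product."""

    residue_a: str
    atoms_a: tuple[str, ...]
    residue_b: str
    atoms_b: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.atoms_a or not self.atoms_b:
            raise ValueError("atom sets must be non-empty")


def _resolve_atoms(traj: Trajectory, labels: LabelMap, residue: str,
                   atom_names, chain: str = "A") -> list[int]:
    try:
        res_seq = labels.bw_to_abs(residue)
    except (KeyError, ValueError):
        res_seq = int(residue)
    idx = []
    for name in atom_names:
        try:
            idx.append(traj.atom_index(chain, res_seq, name))
        except AtomLookupError:
            pass
    if not idx:
        raise AtomLookupError(
            f"none of atoms {tuple(atom_names)} of residue {residue} "
            f"(abs {res_seq}) resolvable in trajectory topology")
    return idx


def pair_distance_series(
    traj: Trajectory,
    labels: LabelMap,
    pair: PairSpec,
    threshold: float | None = None,
    equilibration_cut: float = 100.0,
    chain: str = "A",
    metric: str | None = None,
) -> SwitchTimeSeries:
    """Per-frame minimum heteroatom–heteroatom distance for a residue pair."""
    ia = _resolve_atoms(traj, labels, pair.residue_a, pair.atoms_a, chain)
    ib = _resolve_atoms(traj, labels, pair.residue_b, pair.atoms_b, chain)
    A = traj.coords[:, ia, :]          # (F, na, 3)
    B = traj.coords[:, ib, :]          # (F, nb, 3)
    d = np.linalg.norm(A[:, :, None, :] - B[:, None, :, :], axis=-1)
    values = d.reshape(d.shape[0], -1).min(axis=1)
    flags = values <= threshold if threshold is not None else None
    return SwitchTimeSeries(
        metric=metric or f"{pair.residue_a}-{pair.residue_b}",
        frame_times=traj.frame_times, values=values, bound_flags=flags,
        threshold=threshold, equilibration_cut=equilibration_cut,
    )


def ionic_lock_series(traj: Trajectory, labels: LabelMap,
                      thresholds: SwitchThresholds | None = None,
                      chain: str = "A") -> SwitchTimeSeries:
    """R3.50 ↔ S6.33 hydrogen-bond distance with the 3.2 Å criterion."""
    thresholds = thresholds or SwitchThresholds()
    pair = PairSpec("3.50", R350_ATOMS, "6.33", ("OG",))
    return pair_distance_series(
        traj, labels, pair, threshold=thresholds.hbond_heteroatom_max,
        equilibration_cut=thresholds.equilibration_cut, chain=chain,
        metric="ionic_lock")


def arginine_cage_series(traj: Trajectory, labels: LabelMap,
                         thresholds: SwitchThresholds | None = None,
                         chain: str = "A") -> SwitchTimeSeries:
    """R3.50 ↔ D3.49 intra-helical salt bridge with the 4.0 Å criterion."""
    thresholds = thresholds or SwitchThresholds()
    pair = PairSpec("3.50", R350_ATOMS, "3.49", D349_ATOMS)
    return pair_distance_series(
        traj, labels, pair, threshold=thresholds.salt_bridge_max,
        equilibration_cut=thresholds.equilibration_cut, chain=chain,
        metric="arginine_cage")


def ic_end_separation(
    traj: Trajectory,
    labels: LabelMap,
    tmh3_residues=None,
    tmh6_residues=None,
    equilibration_cut: float = 100.0,
    chain: str = "A",
) -> SwitchTimeSeries:
    """Distance between the unweighted Cα centroids of the last five
    cytoplasmic residues of TMH3 (3.51 … 3.51+4) and TMH6 (6.30 … 6.34)."""
    if tmh3_residues is None:
        start = labels.bw_to_abs("3.51")
        tmh3_residues = list(range(start, start + 5))
    if tmh6_residues is None:
        start = labels.bw_to_abs("6.30")
        tmh6_residues = list(range(start, start + 5))
    if len(tmh3_residues) != 5 or len(tmh6_residues) != 5:
        raise ValueError("each cytoplasmic-end set must contain exactly 5 residues")
    i3 = [traj.atom_index(chain, s, "CA") for s in tmh3_residues]
    i6 = [traj.atom_index(chain, s, "CA") for s in tmh6_residues]
    c3 = traj.coords[:, i3, :].mean(axis=1)
    c6 = traj.coords[:, i6, :].mean(axis=1)
    values = np.linalg.norm(c3 - c6, axis=1)
    return SwitchTimeSeries(metric="ic_end_separation", frame_times=traj.frame_times,
                            values=values, equilibration_cut=equilibration_cut)


def sodium_pocket_distances(
    traj: Trajectory,
    labels: LabelMap,
    ion_res_name: str = "NA",
    targets: tuple[str, ...] = ("3.39", "1.50"),
    equilibration_cut: float = 100.0,
    chain: str = "A",
) -> list[SwitchTimeSeries]:
    """Per-frame sodium-ion to Cα distances, one series per target position."""
    ion_idx = [i for i, a in enumerate(traj.topology)
               if a.res_name == ion_res_name and a.hetatm]
    if len(ion_idx) != 1:
        raise ValueError(f"expected exactly one {ion_res_name} ion, found {len(ion_idx)}")
    ion = traj.coords[:, ion_idx[0], :]
    out = []
    for target in targets:
        res_seq = labels.bw_to_abs(target)
        ica = traj.atom_index(chain, res_seq, "CA")
        values = np.linalg.norm(ion - traj.coords[:, ica, :], axis=1)
        out.append(SwitchTimeSeries(metric=f"na_ca_{target}", frame_times=traj.frame_times,
                                    values=values, equilibration_cut=equilibration_cut))
    return out


def _circular_mean(deg: np.ndarray) -> float:
    a = np.radians(deg)
    return float(np.degrees(np.arctan2(np.mean(np.sin(a)), np.mean(np.cos(a)))))


def chi1_series(
    traj: Trajectory,
    labels: LabelMap,
    residue: str,
    res_name: str | None = None,
    equilibration_cut: float = 100.0,
    chain: str = "A",
    convention: str = "paper",
) -> SwitchTimeSeries:
    """Per-frame χ1 (degrees) of one residue plus rotamer-state occupancies.

    ``extra`` carries the per-state occupancy over post-cut frames, the
    per-frame state labels and the circular mean of each contiguous state
    run.  The residue type is taken from the trajectory topology unless
    overridden.
    """
    try:
        res_seq = labels.bw_to_abs(residue)
    except (KeyError, ValueError):
        res_seq = int(residue)
    if res_name is None:
        res_name = next(a.res_name for a in traj.topology
                        if a.chain == chain and a.res_seq == res_seq)
    if res_name not in GAMMA_ATOM:
        raise ValueError(f"residue {residue} ({res_name}) has no chi1")
    gamma = GAMMA_ATOM[res_name][0]
    idx = [traj.atom_index(chain, res_seq, n) for n in ("N", "CA", "CB", gamma)]
    P = traj.coords[:, idx, :]
    values = dihedral_angle(P[:, 0], P[:, 1], P[:, 2], P[:, 3])
    values = np.atleast_1d(values)
    states = np.array([classify_chi1(v, convention).value for v in values])
    ts = SwitchTimeSeries(metric=f"chi1_{residue}", frame_times=traj.frame_times,
                          values=values, equilibration_cut=equilibration_cut)
    sel = ts.post_cut if ts.post_cut.any() else np.ones(len(values), bool)
    occ = {s.value: float((states[sel] == s.value).mean()) for s in RotamerState}
    runs = []
    start = 0
    for i in range(1, len(states) + 1):
        if i == len(states) or states[i] != states[start]:
            runs.append({
                "state": states[start],
                "start_frame": start, "end_frame": i - 1,
                "circular_mean_deg": _circular_mean(values[start:i]),
            })
            start = i
    ts.extra = {"rotamer_occupancy": occ, "states": states, "runs": runs,
                "dominant_state": max(occ, key=occ.get)}
    return ts


def rmsd_series(
    traj: Trajectory,
    reference: StructureModel,
    selection=None,
    equilibration_cut: float = 100.0,
) -> SwitchTimeSeries:
    """Per-frame best-fit (superposed) RMSD over a selection of atoms.

    ``selection`` is a predicate on AtomRecord (default: all Cα atoms).
    """
    if selection is None:
        def selection(a):  # noqa: E731 — default: Cα atoms
            return a.atom_name == "CA"
    ref_idx = [i for i, a in enumerate(reference.atoms) if selection(a)]
    ref_keys = [reference.atoms[i].key for i in ref_idx]
    try:
        traj_idx = [traj.atom_index(*k) for k in ref_keys]
    except AtomLookupError as exc:
        raise ValueError(f"selection mismatch between reference and trajectory: {exc}") from None
    if len(ref_idx) < 3:
        raise ValueError("selection must contain at least 3 atoms")
    ref = np.array([reference.atoms[i].position for i in ref_idx])
    ref0 = ref - ref.mean(axis=0)
    values = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        mob = traj.coords[f, traj_idx, :]
        mob0 = mob - mob.mean(axis=0)
        _, rssd = Rotation.align_vectors(ref0, mob0)
        values[f] = rssd / np.sqrt(len(ref_idx))
    return SwitchTimeSeries(metric="rmsd", frame_times=traj.frame_times,
                            values=values, equilibration_cut=equilibration_cut)


@dataclass
class OccupancySummary:
    metric: str
    occupancy: float | None
    occupancy_no_cut: float | None
    intervals: list[tuple[float, float, float]]  # (start ns, end ns, duration ns)
    n_formations: int
    n_breakages: int
    warning: str | None = None


def occupancy_summary(series: SwitchTimeSeries,
                      thresholds: SwitchThresholds | None = None) -> OccupancySummary:
    """Post-cut occupancy, bonded intervals and formation/breakage counts."""
    if series.bound_flags is None:
        raise ValueError("series carries no bound_flags")
    cut = thresholds.equilibration_cut if thresholds is not None else series.equilibration_cut
    sel = series.frame_times >= cut
    if not sel.any():
        return OccupancySummary(series.metric, None, series.occupancy_no_cut, [], 0, 0,
                                warning="series ends before the equilibration cut")
    flags = series.bound_flags
    times = series.frame_times
    intervals = []
    start_t = None
    for i in range(len(flags)):
        if flags[i] and start_t is None:
            start_t = times[i]
        elif not flags[i] and start_t is not None:
            intervals.append((start_t, times[i - 1], times[i - 1] - start_t))
            start_t = None
    if start_t is not None:
        intervals.append((start_t, times[-1], times[-1] - start_t))
    transitions = np.flatnonzero(np.diff(flags.astype(int)))
    n_form = int((np.diff(flags.astype(int)) > 0).sum())
    n_break = int((np.diff(flags.astype(int)) < 0).sum())
    del transitions
    occ = float(flags[sel].mean())
    return OccupancySummary(series.metric, occ, float(flags.mean()),
                            intervals, n_form, n_break)


@dataclass
class StateReport:
    classification: str
    lock: OccupancySummary
    cage: OccupancySummary
    series: dict[str, SwitchTimeSeries]

    def to_dict(self) -> dict:
        out = {"classification": self.classification,
               "lock_occupancy": self.lock.occupancy,
               "lock_occupancy_no_cut": self.lock.occupancy_no_cut,
               "cage_occupancy": self.cage.occupancy,
               "metrics": {}}
        for name, ts in self.series.items():
            entry = {"mean": float(np.mean(ts.values)),
                     "occupancy": ts.occupancy}
            if "rotamer_occupancy" in ts.extra:
                entry["rotamer_occupancy"] = ts.extra["rotamer_occupancy"]
                entry["dominant_state"] = ts.extra["dominant_state"]
            out["metrics"][name] = entry
        return out


#: occupancy bands for the lock classification (configurable)
LOCK_BANDS = {"stable": 0.8, "broken": 0.05}


def state_report(
    traj: Trajectory,
    labels: LabelMap,
    thresholds: SwitchThresholds | None = None,
    bands: dict | None = None,
    chain: str = "A",
    chi1_residue: str | None = "7.49",
    sodium: bool = True,
) -> StateReport:
    """Bundle all micro-switch metrics and classify the trajectory as
    lock-stable (occupancy ≥ 0.8), lock-intermittent (0.05–0.8) or
    lock-broken (< 0.05)."""
    thresholds = thresholds or SwitchThresholds()
    bands = bands or LOCK_BANDS
    series: dict[str, SwitchTimeSeries] = {}
    lock = ionic_lock_series(traj, labels, thresholds, chain)
    cage = arginine_cage_series(traj, labels, thresholds, chain)
    series["ionic_lock"] = lock
    series["arginine_cage"] = cage
    series["ic_end_separation"] = ic_end_separation(
        traj, labels, equilibration_cut=thresholds.equilibration_cut, chain=chain)
    if sodium:
        for ts in sodium_pocket_distances(
                traj, labels, equilibration_cut=thresholds.equilibration_cut, chain=chain):
            series[ts.metric] = ts
    if chi1_residue is not None:
        series[f"chi1_{chi1_residue}"] = chi1_series(
            traj, labels, chi1_residue,
            equilibration_cut=thresholds.equilibration_cut, chain=chain)
    occ = lock.occupancy
    if occ is None:
        classification = "undetermined"
    elif occ >= bands["stable"]:
        classification = "lock-stable"
    elif occ < bands["broken"]:
        classification = "lock-broken"
    else:
        classification = "lock-intermittent"
    return StateReport(classification=classification,
                       lock=occupancy_summary(lock, thresholds),
                       cage=occupancy_summary(cage, thresholds),
                       series=series)
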