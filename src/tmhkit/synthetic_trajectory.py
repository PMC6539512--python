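"""Synthetic trajectories with prescribed micro-switch dynamics.

This module generates, from explicit statistical specifications, multi-model
trajectories whose per-frame switch metrics are known exactly — the ground
truth the analysis stages are validated against.  Two ingredients:

* statistical samplers — a continuous-time two-state (bonded/broken) Markov
  process discretized per frame for hydrogen-bond/salt-bridge distances, and
  a discrete Markov chain over χ1 rotamer wells with von Mises emission;

* a coordinate realizer that turns sampled series into actual 3-D structures.

The realized bundle is **minimal proxy geometry**, not a receptor model: two
ideal helices stand in for TMH3/TMH6, short stubs for TMH1/TMH7, a handful of
side-chain proxy atoms (R3.50 guanidinium nitrogens, D3.49/D7.49
carboxylates, S6.33 OG, Q6.43 amide) are placed so that every target metric
matches its sampled series exactly, and one sodium ion moves along the
bundle axis.  Proxy side-chain atoms are placed by construction, not by
rotamer chemistry; nothing here approximates real receptor structure beyond
the measured metrics.

Named scenario presets emulate the wild-type-like receptor (ionic lock broken
throughout production, D7.49 χ1 in g−, sodium low in the pocket) and the
3.39-asparagine-mutant-like receptor (intermittent lock, χ1 g+, sodium
displaced ≈ 3 Å toward the extracellular side, intermittent 6.43–7.49
hydrogen bond).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .bw_numbering import LabelMap
from .helix_geometry import (
    HelixSegment,
    _place_atom,
    build_ideal_helix,
    fit_helix_axis,  # noqa: F401  (re-exported for kink fixtures)
    wrap_angle,
)
from .structure_io import AtomRecord, Trajectory

__all__ = [
    "TwoStateSpec",
    "RotamerHopSpec",
    "ScenarioSpec",
    "sample_two_state",
    "sample_rotamer_path",
    "realize_coordinates",
    "make_kinked_helix",
    "scenario_label_map",
    "DISTANCE_FLOOR",
]

DISTANCE_FLOOR = 1.5  # Å; distances are floored here to avoid unphysical overlap


class DiscretizationError(ValueError):
    """Transition rates too fast for the chosen frame interval."""


class RealizationError(ValueError):
    """A sampled series value cannot be realized geometrically."""


@dataclass
class TwoStateSpec:
    """Two-state (bonded/broken) distance dynamics.

    ``k_on``/``k_off`` are per-ns transition rates (broken→bonded and
    bonded→broken); the stationary bonded fraction is k_on/(k_on+k_off).
    """

    mu_bonded: float = 2.9
    mu_broken: float = 6.0
    sigma: float = 0.15
    k_on: float = 0.25
    k_off: float = 0.3
    n_frames: int = 7000
    dt: float = 0.1
    seed: int | None = None
    start_bonded: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.mu_bonded < self.mu_broken):
            raise ValueError("need 0 < mu_bonded < mu_broken")
        if self.k_on <= 0 or self.k_off <= 0:
            raise ValueError("rates must be positive")
        if self.sigma < 0 or self.n_frames < 1 or self.dt <= 0:
            raise ValueError("invalid sigma/n_frames/dt")

    @property
    def stationary_occupancy(self) -> float:
        return self.k_on / (self.k_on + self.k_off)


def sample_two_state(spec: TwoStateSpec,
                     rng: np.random.Generator | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Sample (state path, distance series); state 1 = bonded.

    The continuous-time chain is discretized with per-frame transition
    probabilities k·dt; rates giving a probability > 1 raise
    :class:`DiscretizationError`.  Distances are the state mean plus Gaussian
    noise, floored at 1.5 Å.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    p_on = spec.k_on * spec.dt
    p_off = spec.k_off * spec.dt
    if p_on > 1 or p_off > 1:
        raise DiscretizationError(
            f"per-frame transition probability exceeds 1 (p_on={p_on:.3g}, p_off={p_off:.3g}); "
            "decrease dt")
    states = np.empty(spec.n_frames, dtype=int)
    s = 1 if spec.start_bonded else 0
    u = rng.random(spec.n_frames)
    for i in range(spec.n_frames):
        states[i] = s
        if s == 1:
            if u[i] < p_off:
                s = 0
        else:
            if u[i] < p_on:
                s = 1
    means = np.where(states == 1, spec.mu_bonded, spec.mu_broken)
    dist = means + (spec.sigma * rng.standard_normal(spec.n_frames) if spec.sigma > 0 else 0.0)
    dist = np.maximum(dist, DISTANCE_FLOOR)
    return states, dist


@dataclass
class RotamerHopSpec:
    """Markov chain over χ1 wells with von Mises emission per well."""

    well_means: tuple[float, ...] = (55.0, -55.0, 180.0)   # g-, g+, trans
    kappas: tuple[float, ...] = (20.0, 20.0, 20.0)
    transition_matrix: np.ndarray | None = None  # rows sum to 1
    start_well: int = 0
    n_frames: int = 7000
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.transition_matrix is None:
            n = len(self.well_means)
            self.transition_matrix = np.full((n, n), 0.001)
            np.fill_diagonal(self.transition_matrix, 1.0 - 0.001 * (n - 1))
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        n = len(self.well_means)
        if self.transition_matrix.shape != (n, n):
            raise ValueError("transition matrix shape must match number of wells")
        rows = self.transition_matrix.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-8):
            raise ValueError("transition matrix rows must sum to 1")
        if np.any(self.transition_matrix < 0):
            raise ValueError("transition probabilities must be non-negative")
        means = np.sort(np.mod(self.well_means, 360.0))
        if np.any(np.diff(means) < 1e-6):
            raise ValueError("well means must be distinct modulo 360")


def sample_rotamer_path(spec: RotamerHopSpec,
                        rng: np.random.Generator | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Sample (well path, χ1 series in degrees, wrapped to (−180, 180])."""
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    n_wells = len(spec.well_means)
    path = np.empty(spec.n_frames, dtype=int)
    w = spec.start_well
    for i in range(spec.n_frames):
        path[i] = w
        w = int(rng.choice(n_wells, p=spec.transition_matrix[w]))
    chi = np.empty(spec.n_frames)
    for k in range(n_wells):
        sel = path == k
        if not sel.any():
            continue
        mu = math.radians(spec.well_means[k])
        kappa = spec.kappas[k]
        if np.isinf(kappa):
            chi[sel] = spec.well_means[k]
        else:
            chi[sel] = np.degrees(rng.vonmises(mu, kappa, size=int(sel.sum())))
    return path, wrap_angle(chi)


@dataclass
class GaussianSeriesSpec:
    """Plain Gaussian fluctuation around a mean (used for the IC-end and
    sodium displacement series)."""

    mean: float
    sigma: float


@dataclass
class ScenarioSpec:
    """A fully specified synthetic study condition."""

    name: str
    lock: TwoStateSpec
    cage: TwoStateSpec
    qd_hbond: TwoStateSpec          # 6.43–7.49 hydrogen bond
    chi1: RotamerHopSpec            # D7.49
    ic_separation: GaussianSeriesSpec
    na_displacement: GaussianSeriesSpec  # Å along the bundle axis toward EC
    n_frames: int = 7000
    dt: float = 0.1
    seed: int = 0

    @classmethod
    def preset(cls, name: str, n_frames: int = 7000, dt: float = 0.1,
               seed: int = 0) -> "ScenarioSpec":
        """``wt_like``: lock breaks immediately and stays broken, χ1 g−,
        sodium low.  ``mutant_like``: intermittent lock, χ1 g+, sodium
        displaced 3.0 Å toward the extracellular side, intermittent
        6.43–7.49 hydrogen bond."""
        common = dict(n_frames=n_frames, dt=dt)
        if name == "wt_like":
            lock = TwoStateSpec(k_on=0.002, k_off=1.0, start_bonded=True, **common)
            cage = TwoStateSpec(mu_bonded=3.5, mu_broken=6.5, k_on=0.05,
                                k_off=0.25, start_bonded=True, **common)
            qd = TwoStateSpec(k_on=0.004, k_off=0.8, start_bonded=True, **common)
            # toggles from g+ into g− early and stays
            T = np.array([[0.995, 0.0, 0.005],
                          [0.02, 0.98, 0.0],
                          [0.01, 0.0, 0.99]])
            chi1 = RotamerHopSpec(transition_matrix=T, start_well=1, n_frames=n_frames)
            ic = GaussianSeriesSpec(mean=13.0, sigma=0.4)
            na = GaussianSeriesSpec(mean=0.0, sigma=0.3)
        elif name == "mutant_like":
            lock = TwoStateSpec(k_on=0.25, k_off=0.3, start_bonded=False, **common)
            cage = TwoStateSpec(mu_bonded=3.5, mu_broken=6.5, k_on=0.6,
                                k_off=0.1, start_bonded=True, **common)
            qd = TwoStateSpec(k_on=0.3, k_off=0.3, start_bonded=True, **common)
            T = np.array([[0.98, 0.02, 0.0],
                          [0.0005, 0.9995, 0.0],
                          [0.0, 0.01, 0.99]])
            chi1 = RotamerHopSpec(transition_matrix=T, start_well=1, n_frames=n_frames)
            ic = GaussianSeriesSpec(mean=9.5, sigma=0.4)
            na = GaussianSeriesSpec(mean=3.0, sigma=0.3)  # pulled ~3 Å toward EC
        else:
            raise ValueError(f"unknown preset {name!r}")
        return cls(name=name, lock=lock, cage=cage, qd_hbond=qd, chi1=chi1,
                   ic_separation=ic, na_displacement=na,
                   n_frames=n_frames, dt=dt, seed=seed)


# ---------------------------------------------------------------------------
# proxy-bundle realization
# ---------------------------------------------------------------------------

# absolute residue numbers of the proxy bundle (consistent with the packaged
# GPR18 map where the positions overlap)
_T3_RANGE = (107, 125)   # 3.38 … 3.56
_T6_RANGE = (227, 247)   # 6.30 … 6.50
_T7_RANGE = (276, 284)   # 7.44 … 7.52
_T1_RANGE = (39, 46)     # 1.46 … 1.53


def scenario_label_map() -> LabelMap:
    """BW label map covering exactly the proxy bundle."""
    return LabelMap(
        anchors={1: 43, 3: 119, 6: 247, 7: 282},
        spans={1: _T1_RANGE, 3: _T3_RANGE, 6: _T6_RANGE, 7: _T7_RANGE},
        notes="synthetic proxy bundle map",
    )


def _proxy_sequence(rng_range: tuple[int, int], special: dict[int, str]) -> str:
    return "".join(special.get(i, "A") for i in range(rng_range[0], rng_range[1] + 1))


def _placed_helix(seq: str, start: int, offset: np.ndarray) -> tuple[HelixSegment, np.ndarray]:
    h = build_ideal_helix(seq, start_seq=start)
    model = h.to_structure_model()
    pos = model.coordinates() + offset
    return h, pos


def realize_coordinates(
    scenario: ScenarioSpec,
    labels: LabelMap | None = None,
) -> tuple[Trajectory, dict]:
    """Realize a scenario as a coordinate trajectory plus its ground truth.

    Returns ``(trajectory, truth)`` where ``truth`` maps metric names to the
    exact per-frame series the placed coordinates encode:
    ``ionic_lock``, ``arginine_cage``, ``ic_end_separation``, ``chi1_7.49``,
    ``qd_hbond``, ``na_ca_3.39``, ``na_ca_1.50`` plus the sampled state
    paths.  All series are reproducible from the scenario seed.
    """
    del labels  # the bundle defines its own numbering; see scenario_label_map()
    rng = np.random.default_rng(scenario.seed)
    n = scenario.n_frames
    times = np.arange(n) * scenario.dt

    lock_states, lock_d = sample_two_state(scenario.lock, rng)
    cage_states, cage_d = sample_two_state(scenario.cage, rng)
    qd_states, qd_d = sample_two_state(scenario.qd_hbond, rng)
    chi_path, chi_d = sample_rotamer_path(scenario.chi1, rng)
    ic_d = scenario.ic_separation.mean + scenario.ic_separation.sigma * rng.standard_normal(n)
    na_dz = scenario.na_displacement.mean + scenario.na_displacement.sigma * rng.standard_normal(n)
    if np.any(ic_d < DISTANCE_FLOOR):
        bad = int(np.argmax(ic_d < DISTANCE_FLOOR))
        raise RealizationError(f"IC separation below clash floor at frame {bad}")

    # --- static bundle ----------------------------------------------------
    t3, p3 = _placed_helix(_proxy_sequence(_T3_RANGE, {108: "A", 118: "D", 119: "R",
                                                       120: "Y", 125: "Q"}),
                           _T3_RANGE[0], np.zeros(3))
    t6, p6 = _placed_helix(_proxy_sequence(_T6_RANGE, {230: "S", 240: "Q"}),
                           _T6_RANGE[0], np.array([0.0, 12.0, 0.0]))
    t7, p7 = _placed_helix(_proxy_sequence(_T7_RANGE, {281: "D"}),
                           _T7_RANGE[0], np.array([0.0, 6.0, -10.0]))
    t1, p1 = _placed_helix(_proxy_sequence(_T1_RANGE, {43: "N"}),
                           _T1_RANGE[0], np.array([0.0, -9.0, -9.0]))

    topology: list[AtomRecord] = []
    blocks = []
    for seg, pos in ((t3, p3), (t6, p6), (t7, p7), (t1, p1)):
        model = seg.to_structure_model()
        start = len(topology)
        for a, p in zip(model.atoms, pos):
            topology.append(AtomRecord(a.chain, a.res_seq, a.res_name, a.atom_name,
                                       a.element, p))
        blocks.append((start, len(topology)))
    index = {a.key: i for i, a in enumerate(topology)}

    # R3.50 guanidinium proxies, placed so NE is always the closest N
    u_lock = np.array([0.0, 1.0, 0.0])
    u_cage = np.array([0.0, 0.0, 1.0])
    w = (u_lock + u_cage) / math.sqrt(2.0)
    perp = np.array([1.0, 0.0, 0.0])
    ne = topology[index[("A", 119, "CA")]].position + np.array([0.0, 2.2, 0.0])
    for name, pos in (("NE", ne), ("NH1", ne - w + perp), ("NH2", ne - w - perp)):
        topology.append(AtomRecord("A", 119, "ARG", name, "N", pos))
    index.update({("A", 119, n_): len(topology) - 3 + k
                  for k, n_ in enumerate(("NE", "NH1", "NH2"))})
    # D3.49 carboxylate, Q6.43 amide and D7.49 carboxylate proxies (per-frame)
    for seq, rname, names in ((118, "ASP", ("OD1", "OD2")),
                              (240, "GLN", ("NE2", "OE1")),
                              (281, "ASP", ("OD1", "OD2"))):
        for name in names:
            el = name[0]
            topology.append(AtomRecord("A", seq, rname, name, el, np.zeros(3)))
            index[("A", seq, name)] = len(topology) - 1
    # sodium ion: on the Cα(1.50)→Cα(3.39) line, below 3.39, so that a
    # displacement "up" toward the EC side lengthens the 1.50 distance and
    # shortens the 3.39 distance by exactly the displacement
    ca43 = topology[index[("A", 43, "CA")]].position
    ca108 = topology[index[("A", 108, "CA")]].position
    u_ec = (ca108 - ca43) / np.linalg.norm(ca108 - ca43)
    na_base = ca108 - 7.0 * u_ec  # 7 Å below the 3.39 Cα, on the pocket axis
    topology.append(AtomRecord("A", 500, "NA", "NA", "NA", na_base, hetatm=True))
    index[("A", 500, "NA")] = len(topology) - 1

    n_atoms = len(topology)
    base = np.array([a.position for a in topology])
    coords = np.tile(base, (n, 1, 1))

    # --- per-frame controls ----------------------------------------------
    # TMH6 rigid translation along the centroid line → exact IC separation
    i3_ca = [index[("A", s, "CA")] for s in range(120, 125)]
    i6_ca = [index[("A", s, "CA")] for s in range(227, 232)]
    c3 = base[i3_ca].mean(axis=0)
    c6 = base[i6_ca].mean(axis=0)
    u6 = (c6 - c3) / np.linalg.norm(c6 - c3)
    base_d = float(np.linalg.norm(c6 - c3))
    t6_lo, t6_hi = blocks[1]
    shift = (ic_d - base_d)[:, None] * u6[None, :]
    coords[:, t6_lo:t6_hi, :] += shift[:, None, :]

    # S6.33 OG at the exact lock distance from R3.50 NE
    coords[:, index[("A", 230, "OG")], :] = ne[None, :] + lock_d[:, None] * u_lock[None, :]
    # D3.49 carboxylate at the exact cage distance
    od1 = ne[None, :] + cage_d[:, None] * u_cage[None, :]
    coords[:, index[("A", 118, "OD1")], :] = od1
    coords[:, index[("A", 118, "OD2")], :] = od1 + 0.8 * u_cage[None, :]

    # D7.49 side chain rebuilt per frame at the sampled χ1
    n281 = base[index[("A", 281, "N")]]
    ca281 = base[index[("A", 281, "CA")]]
    cb281 = base[index[("A", 281, "CB")]]
    i_cg = index[("A", 281, "CG")]
    i_od1 = index[("A", 281, "OD1")]
    i_od2 = index[("A", 281, "OD2")]
    i_ne2 = index[("A", 240, "NE2")]
    i_oe1 = index[("A", 240, "OE1")]
    for f in range(n):
        cg = _place_atom(n281, ca281, cb281, 1.51, 112.6, chi_d[f])
        od1f = _place_atom(ca281, cb281, cg, 1.25, 118.4, -20.0)
        od2f = _place_atom(ca281, cb281, cg, 1.25, 118.4, 160.0)
        coords[f, i_cg] = cg
        coords[f, i_od1] = od1f
        coords[f, i_od2] = od2f
        # Q6.43 amide along the carboxylate bisector, pointing away from OD2,
        # so NE2–OD1 is the exact minimum heteroatom distance
        u_q = od1f - od2f
        u_q /= np.linalg.norm(u_q)
        ne2 = od1f + qd_d[f] * u_q
        coords[f, i_ne2] = ne2
        coords[f, i_oe1] = ne2 + 0.9 * u_q

    # sodium displaced along the pocket axis toward the EC side
    i_na = index[("A", 500, "NA")]
    coords[:, i_na, :] = na_base[None, :] + na_dz[:, None] * u_ec[None, :]

    traj = Trajectory(topology=topology, coords=coords, frame_times=times)
    truth = {
        "ionic_lock": lock_d, "ionic_lock_states": lock_states,
        "arginine_cage": cage_d, "arginine_cage_states": cage_states,
        "ic_end_separation": ic_d,
        "chi1_7.49": chi_d, "chi1_wells": chi_path,
        "qd_hbond": qd_d, "qd_states": qd_states,
        "na_ca_3.39": np.linalg.norm(coords[:, i_na, :]
                                     - base[index[("A", 108, "CA")]][None, :], axis=1),
        "na_ca_1.50": np.linalg.norm(coords[:, i_na, :]
                                     - base[index[("A", 43, "CA")]][None, :], axis=1),
        "frame_times": times,
    }
    return traj, truth


def make_kinked_helix(
    sequence: str,
    hinge: int,
    bend: float,
    wobble: float = 0.0,
    seed: int | None = None,
    noise: float = 0.0,
) -> HelixSegment:
    """Ideal helix with the post-hinge segment rigidly rotated to realize the
    requested bend and wobble exactly (under the package's conventions).

    ``hinge`` is the residue number (1-based within the built helix).  The
    rotation axis passes through the hinge Cα, perpendicular to the fitted
    pre-hinge axis, oriented so that the post-hinge axis tilts toward the
    azimuth ``wobble`` (zero at the hinge-Cα radial direction).  Optional
    Gaussian coordinate noise of ``noise`` Å is controlled by ``seed``.
    """
    if not 0.0 <= bend <= 90.0:
        raise ValueError("bend must be in [0, 90] degrees")
    helix = build_ideal_helix(sequence)
    seqs = helix.res_seqs
    if hinge - seqs[0] < 4 or seqs[-1] - hinge < 4:
        raise ValueError("hinge must have at least 4 residues on each side")
    pre = [s for s in seqs if s < hinge]
    a_pre, c_pre = fit_helix_axis(helix.ca_positions(pre))
    ca_h = helix.atom(hinge, "CA")
    r0 = ca_h - c_pre
    r0 = r0 - np.dot(r0, a_pre) * a_pre
    e1 = r0 / np.linalg.norm(r0)
    e2 = np.cross(a_pre, e1)
    m = math.cos(math.radians(wobble)) * e1 + math.sin(math.radians(wobble)) * e2
    k = np.cross(a_pre, m)
    k /= np.linalg.norm(k)
    R = Rotation.from_rotvec(k * math.radians(bend)).as_matrix()

    out = helix.copy()
    for (s, name) in out.atom_order:
        rotate = s > hinge or (s == hinge and name in ("C", "O"))
        if rotate:
            out._atoms[(s, name)] = ca_h + R @ (out._atoms[(s, name)] - ca_h)
    if noise > 0:
        rng = np.random.default_rng(seed)
        for key in out._atoms:
            out._atoms[key] = out._atoms[key] + noise * rng.standard_normal(3)
    out._pos = None
    return out
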