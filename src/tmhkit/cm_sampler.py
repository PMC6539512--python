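"""Two-phase "conformational memories" Monte-Carlo / simulated-annealing search.

The method maps the conformational space available to a transmembrane helix
around a hinge region in two phases:

1. *Exploratory phase* — simulated annealing from 3000 K to 310 K in 18
   temperature steps, 50 000 MC steps per temperature.  Each MC move perturbs
   exactly two randomly chosen dihedrals of the variable region (uniform
   draws within the per-dihedral allowed range) and one backbone bond angle
   (uniform within ±8° of its canonical value).  Accepted states at the final
   (310 K) temperature populate per-dihedral histograms ("memories").

2. *Biased phase* — annealing from 749.4 K to 310 K in nine steps, with
   dihedral proposals restricted to histogram bins that were highly populated
   in phase 1 (bins holding at least a configurable fraction, default 5 %, of
   the modal bin count).  Accepted 310 K states form the output ensemble.

The energy function is pluggable (any callable ``HelixSegment → kcal/mol``);
the default is a surrogate of Lennard-Jones + Coulomb with the
distance-dependent dielectric ε(r) = r plus a weak 3-fold backbone torsion
term.  It is a deliberately simplified potential: the sampler's algorithmic
behaviour, not force-field fidelity, is the tested content.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .helix_geometry import GAMMA_ATOM, HelixSegment, wrap_angle

logger = logging.getLogger(__name__)

__all__ = [
    "VariationSpec",
    "AnnealingSchedule",
    "EXPLORATORY_SCHEDULE",
    "BIASED_SCHEDULE",
    "PDB_DERIVED_RANGES",
    "Conformer",
    "ConformerEnsemble",
    "MemoryStore",
    "SurrogateEnergy",
    "ToyDihedralEnergy",
    "mc_move",
    "metropolis_accept",
    "run_exploratory",
    "build_allowed_regions",
    "run_biased",
    "select_conformers",
    "apply_conformer",
]

K_B = 0.0019872041  # kcal/(mol·K)

#: φ/ψ/ω variation limits for the proline hinge region, degrees
#: (statistics extracted from the Protein Data Bank)
PDB_DERIVED_RANGES: dict[str, tuple[float, float]] = {
    "phi": (-120.0, 40.0),
    "psi": (-70.0, 0.0),
    "omega": (-160.0, 160.0),
}


class ConfigError(ValueError):
    pass


class InitializationError(RuntimeError):
    pass


@dataclass
class VariationSpec:
    """The variable region: contiguous residues plus per-dihedral ranges."""

    residues: list
    dihedral_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(PDB_DERIVED_RANGES))
    bond_angle_jitter: float = 8.0

    def __post_init__(self) -> None:
        if not self.residues:
            raise ConfigError("variation region is empty")
        for name, (lo, hi) in self.dihedral_ranges.items():
            if name not in ("phi", "psi", "omega", "chi1"):
                raise ConfigError(f"unknown dihedral {name!r}")
            if not (-180.0 <= lo < hi <= 180.0):
                raise ConfigError(f"{name} range ({lo},{hi}) not a sub-interval of (-180,180]")
        if "omega" in self.dihedral_ranges:
            lo, hi = self.dihedral_ranges["omega"]
            if lo > -180.0 and hi < 180.0 and lo < 0 < hi:
                logger.warning(
                    "omega range (%g,%g) permits cis-like peptide values", lo, hi)

    def varied_dihedrals(self, helix: HelixSegment) -> list[tuple[int, str]]:
        """(res_seq, dihedral) pairs actually variable on this helix."""
        out = []
        seqs = [helix.resolve(r).res_seq for r in self.residues]
        if sorted(seqs) != list(range(min(seqs), max(seqs) + 1)):
            raise ConfigError("variation region must be contiguous in sequence")
        first_seq = helix.residues[0].res_seq
        last_seq = helix.residues[-1].res_seq
        for s in sorted(seqs):
            r = helix.resolve(s)
            for name in self.dihedral_ranges:
                if name == "chi1" and r.res_name not in GAMMA_ATOM:
                    continue
                if name in ("phi", "omega") and s == first_seq:
                    continue  # undefined at the N-terminus
                if name == "psi" and s == last_seq:
                    continue
                out.append((s, name))
        if not out:
            raise ConfigError("no variable dihedrals in region")
        return out

    def bond_angle_slots(self, helix: HelixSegment) -> list[tuple[int, str]]:
        seqs = sorted(helix.resolve(r).res_seq for r in self.residues)
        return [(s, name) for s in seqs
                for name in ("angle_n_ca_c", "angle_ca_c_n", "angle_c_n_ca")]


_CANONICAL_ANGLES = {"angle_n_ca_c": 111.2, "angle_ca_c_n": 116.2, "angle_c_n_ca": 121.7}


@dataclass
class AnnealingSchedule:
    """Geometric (default) cooling from t_start to t_end over n_steps."""

    t_start: float
    t_end: float
    n_steps: int
    mc_steps_per_temperature: int
    geometric: bool = True

    def __post_init__(self) -> None:
        if not (self.t_start > self.t_end > 0):
            raise ConfigError("need t_start > t_end > 0")
        if self.n_steps < 1 or self.mc_steps_per_temperature < 1:
            raise ConfigError("n_steps and mc_steps_per_temperature must be >= 1")

    def temperatures(self) -> np.ndarray:
        if self.n_steps == 1:
            return np.array([self.t_end])
        if self.geometric:
            return np.geomspace(self.t_start, self.t_end, self.n_steps)
        return np.linspace(self.t_start, self.t_end, self.n_steps)


EXPLORATORY_SCHEDULE = AnnealingSchedule(3000.0, 310.0, 18, 50_000)
BIASED_SCHEDULE = AnnealingSchedule(749.4, 310.0, 9, 50_000)


@dataclass
class Conformer:
    dihedrals: dict[tuple[int, str], float]
    energy: float
    phase: str  # "exploratory" | "biased"
    step_index: int


@dataclass
class ConformerEnsemble:
    template: HelixSegment
    conformers: list[Conformer]

    def __len__(self) -> int:
        return len(self.conformers)

    def energies(self) -> np.ndarray:
        return np.array([c.energy for c in self.conformers])

    def realize(self, i: int) -> HelixSegment:
        return apply_conformer(self.template, self.conformers[i])

    def to_trajectory(self, chain: str = "A"):
        from .structure_io import Trajectory

        frames = [self.realize(i).to_structure_model(chain, model_id=i + 1)
                  for i in range(len(self.conformers))]
        return Trajectory(frames)


def apply_conformer(template: HelixSegment, conformer: Conformer) -> HelixSegment:
    h = template.copy()
    for (seq, name), value in conformer.dihedrals.items():
        r = h.resolve(seq)
        if name == "chi1":
            r.chi1 = value
        elif name in _CANONICAL_ANGLES:
            setattr(r, name, value)
        else:
            setattr(r, name, value)
    h.rebuild()
    return h


class MemoryStore:
    """Per-dihedral histograms of accepted exploratory states."""

    def __init__(self, keys: list[tuple[int, str]],
                 ranges: dict[tuple[int, str], tuple[float, float]],
                 bin_width: float = 10.0):
        self.bin_width = bin_width
        self.edges: dict[tuple[int, str], np.ndarray] = {}
        self.counts: dict[tuple[int, str], np.ndarray] = {}
        self.mask: dict[tuple[int, str], np.ndarray] | None = None
        self.n_recorded = 0
        for k in keys:
            lo, hi = ranges[k]
            n_bins = max(1, math.ceil((hi - lo) / bin_width))
            edges = np.minimum(lo + bin_width * np.arange(n_bins + 1), hi)
            self.edges[k] = edges
            self.counts[k] = np.zeros(n_bins, dtype=int)

    def record(self, dihedrals: dict[tuple[int, str], float]) -> None:
        for k, edges in self.edges.items():
            v = dihedrals[k]
            i = int(np.clip(np.searchsorted(edges, v, side="right") - 1,
                            0, len(edges) - 2))
            self.counts[k][i] += 1
        self.n_recorded += 1

    def allowed_bins(self, key: tuple[int, str]) -> list[tuple[float, float]]:
        if self.mask is None:
            raise ConfigError("memories carry no mask; call build_allowed_regions first")
        e = self.edges[key]
        m = self.mask[key]
        return [(e[i], e[i + 1]) for i in np.flatnonzero(m)]

    def to_rows(self) -> list[dict]:
        rows = []
        for (seq, name), e in self.edges.items():
            cnt = self.counts[(seq, name)]
            msk = self.mask[(seq, name)] if self.mask is not None else [None] * len(cnt)
            for i in range(len(cnt)):
                rows.append({
                    "res_seq": seq, "dihedral": name,
                    "bin_low": float(e[i]), "bin_high": float(e[i + 1]),
                    "count": int(cnt[i]),
                    "allowed": None if msk[i] is None else bool(msk[i]),
                })
        return rows


def build_allowed_regions(memories: MemoryStore, population_cutoff: float = 0.05) -> MemoryStore:
    """Mark bins holding ≥ cutoff × (modal bin count) as allowed, per dihedral."""
    if not (0.0 < population_cutoff <= 1.0):
        raise ConfigError("population_cutoff must be in (0, 1]")
    mask = {}
    for k, cnt in memories.counts.items():
        if cnt.max() == 0:
            raise ConfigError(f"no recorded population for dihedral {k}")
        mask[k] = cnt >= population_cutoff * cnt.max()
    memories.mask = mask
    return memories


def metropolis_accept(delta_e: float, temperature: float, rng: np.random.Generator) -> bool:
    """Metropolis criterion: accept with probability min(1, exp(−ΔE/kT))."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if delta_e <= 0:
        return True
    return rng.random() < math.exp(-delta_e / (K_B * temperature))


def _draw_dihedral(key, spec: VariationSpec, memories: MemoryStore | None,
                   rng: np.random.Generator, weighted: bool) -> float:
    name = key[1]
    if memories is None:
        lo, hi = spec.dihedral_ranges[name]
        return float(rng.uniform(lo, hi))
    bins = memories.allowed_bins(key)
    if weighted:
        idx = np.flatnonzero(memories.mask[key])
        w = memories.counts[key][idx].astype(float)
        i = rng.choice(len(bins), p=w / w.sum())
    else:
        widths = np.array([b[1] - b[0] for b in bins])
        i = rng.choice(len(bins), p=widths / widths.sum())
    lo, hi = bins[i]
    return float(rng.uniform(lo, hi))


def mc_move(
    helix: HelixSegment,
    spec: VariationSpec,
    rng: np.random.Generator,
    memories: MemoryStore | None = None,
    weighted: bool = False,
) -> tuple[HelixSegment, dict]:
    """One CM proposal: perturb exactly two varied dihedrals and one backbone
    bond angle; returns (proposed helix copy, change record).

    Dihedral values are drawn uniformly within the spec range (or within the
    allowed memory bins when ``memories`` is given); the bond angle is drawn
    uniformly within ±jitter of its canonical value, so the proposal density
    is symmetric and every move is reversible.
    """
    varied = spec.varied_dihedrals(helix)
    n_pick = min(2, len(varied))
    picks = rng.choice(len(varied), size=n_pick, replace=False)
    proposal = helix.copy()
    changes: dict = {"dihedrals": {}, "bond_angle": None}
    for p in picks:
        key = varied[int(p)]
        value = _draw_dihedral(key, spec, memories, rng, weighted)
        r = proposal.resolve(key[0])
        if key[1] == "chi1":
            r.chi1 = value
        else:
            setattr(r, key[1], value)
        changes["dihedrals"][key] = value
    slots = spec.bond_angle_slots(helix)
    seq, aname = slots[int(rng.integers(len(slots)))]
    canonical = _CANONICAL_ANGLES[aname]
    new_angle = float(rng.uniform(canonical - spec.bond_angle_jitter,
                                  canonical + spec.bond_angle_jitter))
    setattr(proposal.resolve(seq), aname, new_angle)
    changes["bond_angle"] = ((seq, aname), new_angle)
    proposal.rebuild()
    return proposal, changes


def _state_of(helix: HelixSegment, varied, bond_slots) -> dict[tuple[int, str], float]:
    state = {}
    for seq, name in varied:
        r = helix.resolve(seq)
        state[(seq, name)] = r.chi1 if name == "chi1" else getattr(r, name)
    for seq, aname in bond_slots:
        state[(seq, aname)] = getattr(helix.resolve(seq), aname)
    return state


@dataclass
class RunLog:
    seed_state: str
    schedule: AnnealingSchedule
    acceptance_rates: list[float] = field(default_factory=list)


def _anneal(helix, spec, schedule, energy, rng, *, memories_in, weighted,
            phase: str, record_store: MemoryStore | None):
    varied = spec.varied_dihedrals(helix)
    bond_slots = spec.bond_angle_slots(helix)
    current = helix.copy()
    e_cur = float(energy(current))
    if not math.isfinite(e_cur):
        raise InitializationError("energy model returned a non-finite value at the start")
    temps = schedule.temperatures()
    final_t = temps[-1]
    samples: list[Conformer] = []
    log = RunLog(seed_state=str(rng.bit_generator.state["state"]), schedule=schedule)
    step_index = 0
    for t in temps:
        n_acc = 0
        for _ in range(schedule.mc_steps_per_temperature):
            proposal, _changes = mc_move(current, spec, rng,
                                         memories=memories_in, weighted=weighted)
            e_prop = float(energy(proposal))
            if math.isfinite(e_prop) and metropolis_accept(e_prop - e_cur, t, rng):
                current, e_cur = proposal, e_prop
                n_acc += 1
                if t == final_t:
                    state = _state_of(current, varied, bond_slots)
                    samples.append(Conformer(dihedrals=state, energy=e_cur,
                                             phase=phase, step_index=step_index))
                    if record_store is not None:
                        record_store.record(state)
            step_index += 1
        log.acceptance_rates.append(n_acc / schedule.mc_steps_per_temperature)
        logger.info("%s phase: T=%.1f K acceptance=%.3f", phase, t,
                    log.acceptance_rates[-1])
    return samples, log


def run_exploratory(
    helix: HelixSegment,
    spec: VariationSpec,
    schedule: AnnealingSchedule = EXPLORATORY_SCHEDULE,
    energy=None,
    rng: np.random.Generator | None = None,
) -> tuple[list[Conformer], MemoryStore, RunLog]:
    """Phase 1: anneal over the full ranges; accepted final-temperature states
    populate the memory histograms."""
    if energy is None:
        energy = SurrogateEnergy()
    rng = np.random.default_rng() if rng is None else rng
    varied = spec.varied_dihedrals(helix)
    ranges = {k: spec.dihedral_ranges[k[1]] for k in varied}
    store = MemoryStore(varied, ranges)
    samples, log = _anneal(helix, spec, schedule, energy, rng,
                           memories_in=None, weighted=False,
                           phase="exploratory", record_store=store)
    return samples, store, log


def run_biased(
    helix: HelixSegment,
    spec: VariationSpec,
    memories: MemoryStore,
    schedule: AnnealingSchedule = BIASED_SCHEDULE,
    energy=None,
    rng: np.random.Generator | None = None,
    weighted: bool = False,
) -> tuple[ConformerEnsemble, RunLog]:
    """Phase 2: proposals restricted to the allowed memory bins; accepted
    final-temperature states form the output ensemble."""
    if memories.mask is None:
        raise ConfigError("memories carry no mask; call build_allowed_regions first")
    if any(not m.any() for m in memories.mask.values()):
        raise ConfigError("empty allowed region for at least one dihedral")
    if energy is None:
        energy = SurrogateEnergy()
    rng = np.random.default_rng() if rng is None else rng
    samples, log = _anneal(helix, spec, schedule, energy, rng,
                           memories_in=memories, weighted=weighted,
                           phase="biased", record_store=None)
    return ConformerEnsemble(template=helix.copy(), conformers=samples), log


# ---------------------------------------------------------------------------
# clash filtering / ranking
# ---------------------------------------------------------------------------

VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "NA": 2.27, "X": 1.70}


def _radius(element: str) -> float:
    return VDW_RADII.get(element.upper(), VDW_RADII["X"])


def select_conformers(
    ensemble: ConformerEnsemble,
    bundle_context=None,
    max_clash_overlap: float = 0.6,
) -> list[Conformer]:
    """Rank conformers by energy; with a bundle context (StructureModel),
    drop conformers whose atoms overlap context atoms by more than
    ``max_clash_overlap`` Å relative to the sum of van der Waals radii."""
    if not ensemble.conformers:
        raise ConfigError("ensemble is empty")
    ranked = sorted(ensemble.conformers, key=lambda c: c.energy)
    if bundle_context is None:
        return ranked
    ctx_pos = bundle_context.coordinates()
    ctx_r = np.array([_radius(a.element) for a in bundle_context.atoms])
    kept: list[Conformer] = []
    worst: list[tuple[float, int]] = []
    for idx, conf in enumerate(ranked):
        h = apply_conformer(ensemble.template, conf)
        pos = h.positions()
        radii = np.array([_radius(n[1][0] if n[1][0] in "NOSC" else "C")
                          for n in h.atom_order])
        d = np.linalg.norm(pos[:, None, :] - ctx_pos[None, :, :], axis=-1)
        limit = radii[:, None] + ctx_r[None, :] - max_clash_overlap
        overlap = (limit - d).max()
        if (d < limit).any():
            worst.append((float(overlap), idx))
        else:
            kept.append(conf)
    if not kept:
        worst.sort(reverse=True)
        desc = ", ".join(f"conformer {i} (overlap {o:.2f} Å)" for o, i in worst[:5])
        logger.warning("all conformers clash with the bundle context; worst: %s", desc)
    return kept


# ---------------------------------------------------------------------------
# surrogate energy model
# ---------------------------------------------------------------------------

# element → (epsilon kcal/mol, Rmin/2 Å)
_LJ = {"C": (0.07, 2.00), "N": (0.17, 1.85), "O": (0.12, 1.70),
       "S": (0.45, 2.00), "NA": (0.047, 1.36), "X": (0.07, 2.00)}
# atom-name → partial charge (minimal, backbone-polar set)
_CHARGES = {"N": -0.47, "CA": 0.07, "C": 0.51, "O": -0.51,
            "OG": -0.66, "OG1": -0.66, "SG": -0.23}
COULOMB_K = 332.0636  # kcal·Å/(mol·e²)
SCALE_14 = 0.5        # 1-4 pairs scaled by this documented factor
CLASH_DISTANCE = 0.1  # Å; pairs closer than this are capped
CLASH_CAP = 1.0e4     # kcal/mol per capped pair
TORSION_K = 0.2       # kcal/mol, 3-fold backbone term


def lj_pair(eps: float, rmin: float, r):
    """12-6 Lennard-Jones: −eps at r = rmin (the pair minimum distance)."""
    x = rmin / np.asarray(r, dtype=float)
    return eps * (x**12 - 2.0 * x**6)


def coulomb_pair(q1: float, q2: float, r):
    """Coulomb with distance-dependent dielectric ε(r) = r → 1/r² falloff."""
    return COULOMB_K * q1 * q2 / np.asarray(r, dtype=float) ** 2


class SurrogateEnergy:
    """LJ + Coulomb (ε(r) = r distance-dependent dielectric) + 3-fold backbone
    torsions, with 1-2/1-3 exclusions and scaled 1-4 pairs.

    Translation/rotation invariant by construction.  Pairs closer than
    0.1 Å contribute a capped clash energy and are counted in
    ``last_clash_count``.
    """

    def __init__(self) -> None:
        self._cache_key = None
        self._pairs = None
        self.last_clash_count = 0

    # -- topology -----------------------------------------------------------
    @staticmethod
    def _bonds(helix: HelixSegment) -> list[tuple[int, int]]:
        order = helix.atom_order
        index = {k: i for i, k in enumerate(order)}
        bonds = []
        prev_c = None
        for r in helix.residues:
            s = r.res_seq
            n, ca, c, o = index[(s, "N")], index[(s, "CA")], index[(s, "C")], index[(s, "O")]
            bonds += [(n, ca), (ca, c), (c, o)]
            if prev_c is not None:
                bonds.append((prev_c, n))
            if (s, "CB") in index:
                cb = index[(s, "CB")]
                bonds.append((ca, cb))
                if r.res_name in GAMMA_ATOM:
                    g = GAMMA_ATOM[r.res_name][0]
                    if (s, g) in index:
                        bonds.append((cb, index[(s, g)]))
            prev_c = c
        return bonds

    def _build_pairs(self, helix: HelixSegment) -> None:
        order = helix.atom_order
        n = len(order)
        adj: list[set[int]] = [set() for _ in range(n)]
        for i, j in self._bonds(helix):
            adj[i].add(j)
            adj[j].add(i)
        excl: set[tuple[int, int]] = set()
        scale14: set[tuple[int, int]] = set()
        for i in range(n):
            for j in adj[i]:
                excl.add((min(i, j), max(i, j)))
                for k in adj[j]:
                    if k != i:
                        excl.add((min(i, k), max(i, k)))
                        for l in adj[k]:
                            if l not in (i, j):
                                scale14.add((min(i, l), max(i, l)))
        scale14 -= excl
        ii, jj, sc = [], [], []
        for i in range(n):
            for j in range(i + 1, n):
                if (i, j) in excl:
                    continue
                ii.append(i)
                jj.append(j)
                sc.append(SCALE_14 if (i, j) in scale14 else 1.0)
        eps = np.array([_LJ.get(name[1][0] if name[1][0] in "NOSC" else "X", _LJ["X"])[0]
                        for name in order])
        rmin2 = np.array([_LJ.get(name[1][0] if name[1][0] in "NOSC" else "X", _LJ["X"])[1]
                          for name in order])
        q = np.array([_CHARGES.get(name[1], 0.0) for name in order])
        ii = np.array(ii, dtype=int)
        jj = np.array(jj, dtype=int)
        sc = np.array(sc)
        self._pairs = {
            "i": ii, "j": jj, "scale": sc,
            "eps": np.sqrt(eps[ii] * eps[jj]),
            "rmin": rmin2[ii] + rmin2[jj],
            "qq": q[ii] * q[jj],
        }

    # -- evaluation ---------------------------------------------------------
    def __call__(self, helix: HelixSegment) -> float:
        key = tuple(helix.atom_order)
        if key != self._cache_key:
            self._build_pairs(helix)
            self._cache_key = key
        P = helix._positions_view()
        pr = self._pairs
        d = np.linalg.norm(P[pr["i"]] - P[pr["j"]], axis=1)
        clash = d < CLASH_DISTANCE
        self.last_clash_count = int(clash.sum())
        d = np.maximum(d, CLASH_DISTANCE)
        lj = lj_pair(pr["eps"], pr["rmin"], d)
        coul = COULOMB_K * pr["qq"] / d**2  # coulomb_pair with precombined charges
        e = float(np.sum(pr["scale"] * (lj + coul))) + CLASH_CAP * self.last_clash_count
        # weak 3-fold backbone torsion term
        tor = 0.0
        for r in helix.residues[1:-1]:
            tor += TORSION_K * (1.0 + math.cos(3.0 * math.radians(r.phi)))
            tor += TORSION_K * (1.0 + math.cos(3.0 * math.radians(r.psi)))
        return e + tor


class ToyDihedralEnergy:
    """Smooth benchmark landscape over two named dihedrals with known minima.

    ``E = k·(1−cos(d1−m1)) + k·(1−cos(d2−m2))`` — a single global minimum at
    (m1, m2), used to validate the sampler against a dense-grid oracle.  The
    default well depth k = 20 kcal/mol gives a 310 K angular spread of
    σ ≈ √(k_B·T/k) ≈ 10° per dihedral, so the equilibrium population
    concentrates within ±30° (≈3σ) of the minimum.
    """

    def __init__(self, key_a: tuple[int, str], key_b: tuple[int, str],
                 minimum: tuple[float, float], k: float = 20.0):
        self.key_a = key_a
        self.key_b = key_b
        self.minimum = minimum
        self.k = k

    def _get(self, helix: HelixSegment, key) -> float:
        r = helix.resolve(key[0])
        return r.chi1 if key[1] == "chi1" else getattr(r, key[1])

    def value(self, d1: float, d2: float) -> float:
        m1, m2 = self.minimum
        return (self.k * (1 - math.cos(math.radians(d1 - m1)))
                + self.k * (1 - math.cos(math.radians(d2 - m2))))

    def __call__(self, helix: HelixSegment) -> float:
        return self.value(self._get(helix, self.key_a), self._get(helix, self.key_b))

    def grid_minimum(self, ranges: dict[str, tuple[float, float]], step: float = 2.0):
        """Dense-grid oracle for the minimum inside the given ranges."""
        lo1, hi1 = ranges[self.key_a[1]]
        lo2, hi2 = ranges[self.key_b[1]]
        g1 = np.arange(lo1, hi1 + step / 2, step)
        g2 = np.arange(lo2, hi2 + step / 2, step)
        vals = np.array([[self.value(a, b) for b in g2] for a in g1])
        i, j = np.unravel_index(np.argmin(vals), vals.shape)
        return float(g1[i]), float(g2[j])
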