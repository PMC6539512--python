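# Methods

This note documents the models, conventions and numerical choices behind
`tmhkit`, and what the synthetic-data validation does and does not show.

## Helix construction

Helices are stored as internal coordinates (per-residue φ, ψ, ω, χ1 and the
three backbone bond angles) and rebuilt into Cartesian coordinates by NeRF
chain extension with canonical peptide geometry (N–CA 1.458 Å, CA–C 1.525 Å,
C–N 1.329 Å, C=O 1.231 Å; N–CA–C 111.2°, CA–C–N 116.2°, C–N–CA 121.7°).  The
ideal α-helix default is φ = −63°, ψ = −42°, ω = 180°, which yields a rise
of ≈1.5 Å/residue and ≈3.6 residues/turn.  Side chains are built through the
γ heavy atom only (the χ1 level; default χ1 = −60°), with L-chirality fixed
by the improper torsion N–C–CA–CB = +120° (the value in the chemical
component dictionary).  Setting a dihedral mutates one internal coordinate
and rebuilds, so downstream atoms rotate rigidly about the dihedral bond and
every other internal coordinate is untouched.

Dihedrals follow the IUPAC sign convention (cross-checked against
MDAnalysis and biotite in the test suite); ω of residue *i* refers to the
peptide bond preceding *i*.

## Hinge (kink) geometry

A hinge is described by three angles relative to Cα windows (each ≥ 4
residues) on either side of the hinge residue:

* **bend** — angle between the pre- and post-hinge helix axes, [0°, 180°];
* **wobble** — azimuth of the post-hinge axis about the pre-hinge axis,
  measured right-handedly, with zero at the projection of the hinge-Cα
  radial vector (sign conventions for wobble differ between programs; this
  package documents its own and does not claim sign agreement with others);
* **face shift** — difference in helical phase of Cα about the axis between
  the two windows, extrapolated to the hinge assuming the ideal 100°/residue
  phase advance.  The post-hinge phase frame is the pre-hinge frame carried
  by the minimal rotation between the axes.  Note that a *uniform* helix
  whose true periodicity differs from 100°/residue (the φ=−63°/ψ=−42°
  default advances ≈99.4°/residue) shows a constant face-shift baseline
  proportional to the window separation; face-shift values are therefore
  meaningful as differences between structures measured with identical
  windows.

**Axis estimator.**  The axis of a Cα window is the null direction of the
stacked second differences Cα(i−1) − 2Cα(i) + Cα(i+1), which for a helical
trace point exactly radially — this estimator is exact for ideal helices of
any window length.  A plain total-least-squares line fit (the obvious
alternative) tilts by ~1° on windows covering a non-integer number of
turns, which would exceed the 0.5° bend-recovery contract; it is retained
only as the fallback for degenerate (near-straight or noisy, curvature-free)
traces.  Axes are oriented N→C.

## χ1 rotamer convention

The package uses the convention in which **gauche-minus is the positive
interval**: g− = [0°, 120°), g+ = (−120°, 0°), trans = |χ1| ≥ 120°.  This is
the mirror of some community conventions; the mirrored labels are available
via `classify_chi1(..., convention="mirror")`.  Boundary assignment (0° to
g−, ±120° to trans) is a deterministic tie-break with measure-zero effect.
Circular statistics use vector means throughout; arithmetic means of angles
are never used.

## Conformational memories (CM)

Two-phase MC/simulated annealing over a contiguous variable region of a
helix:

* **Move set** — each MC step redraws exactly two randomly chosen varied
  dihedrals and one backbone bond angle.  Dihedrals are drawn uniformly
  within their allowed range (defaults for a proline hinge region:
  −120° < φ < 40°, −70° < ψ < 0°, −160° < ω < 160°; the ω interval admits
  cis-like values and a warning is logged); the bond angle is drawn
  uniformly within ±8° of its canonical value.  Proposals are independent
  of the current state, hence symmetric and reversible.
* **Schedules** — exploratory 3000 K → 310 K in 18 geometric steps, biased
  749.4 K → 310 K in 9 steps, 50 000 MC steps per temperature by default.
  Cooling is geometric (endpoints and counts are the protocol's content;
  the interpolation is this package's choice).  Tests and the acceptance
  script run reduced schedules (8–12 temperatures, 400–600 steps each) so a
  full two-phase run takes seconds; the schedule is an explicit parameter
  everywhere, so protocol-scale runs need only the default objects.
* **Memories** — accepted states at the final (310 K) exploratory
  temperature are histogrammed per dihedral (bin width 10°); the biased
  phase proposes only inside bins holding ≥ 5 % of the modal bin count
  (both configurable; population-weighted proposals are available behind a
  flag, uniform-over-allowed-bins is the default).  The recording
  temperature set (final temperature only) is this package's choice.
* **Acceptance** — Metropolis, k_B in kcal/(mol·K); validated against exact
  Boltzmann weights on discrete toy systems.

**Energy.**  The default is a documented surrogate, not a full force field:
12-6 Lennard-Jones with per-element parameters, Coulomb with the
distance-dependent dielectric ε(r) = r (so pair energies fall as 1/r²) over
a minimal backbone-polar charge set, and a weak 3-fold backbone torsion term
(k = 0.2 kcal/mol).  1-2/1-3 pairs are excluded, 1-4 pairs scaled by 0.5;
pairs closer than 0.1 Å contribute a capped clash energy (10⁴ kcal/mol) and
are counted.  The `EnergyModel` contract (any callable HelixSegment →
kcal/mol) admits a full force field.  Consequences: ensemble *sizes* and
*absolute* kink magnitudes depend on the energy model and are not
comparable to force-field results; the direction-level statement that a
proline hinge bends the helix (strictly positive, unimodal bend
distribution) is robust and is the tested claim.  The reference value of
16.8° for a TMH3 proline kink belongs to the original force-field
calculation, not to this surrogate.

**Toy benchmark landscape.**  `ToyDihedralEnergy` is a separable cosine
well over two dihedrals.  Its default depth k = 20 kcal/mol is fixed by the
closed-form 310 K spread σ = √(k_B·T/k) ≈ 10°, so ≥ 99 % of the equilibrium
population lies within ±30° of the minimum — the sampler is then required
to place ≥ 95 % of biased-phase conformers there, with the minimum located
independently by a dense grid search.

## Switch analysis

* "Heteroatom-to-heteroatom" distances are the **minimum over the
  donor/acceptor atom cross product** (R3.50: NE/NH1/NH2; carboxylates:
  both O; Ser: OG) — the permissive, convention-stable reading of a plotted
  single distance.
* Hydrogen bonds are distance-only (≤ 3.2 Å) by default; salt bridges use
  ≤ 4.0 Å.  An angle criterion is deliberately not applied, since analyzed
  trajectories may lack hydrogens.
* The TMH3/TMH6 intracellular-end separation is the distance between
  **unweighted Cα centroids** of the last five cytoplasmic residues on each
  side (3.51…3.55 and 6.30…6.34).
* Occupancies, bonded intervals and event counts are computed over frames
  at or after the equilibration cut (default 100 ns); the cut never
  truncates the series themselves, and the no-cut occupancy is also
  reported because the treatment of the equilibration window differs
  between analyses in the literature.
* The per-trajectory classification uses lock-occupancy bands
  ≥ 0.8 (lock-stable), 0.05–0.8 (lock-intermittent), < 0.05 (lock-broken);
  the bands are configurable.
* RMSD series superpose each frame onto the reference (Kabsch) over the
  selection (Cα by default) before measuring.

## Synthetic trajectories

The generator's role is to produce coordinates whose analysis output is
known exactly.

* **Two-state dynamics** — a continuous-time bonded/broken Markov process
  with per-ns rates k_on/k_off, discretized at dt (default 0.1 ns/frame;
  per-frame probabilities k·dt, rejected if > 1).  Distances are the state
  mean (defaults 2.9 Å bonded / 6.0 Å broken) plus Gaussian noise, floored
  at 1.5 Å.  Stationary occupancy is k_on/(k_on+k_off).
* **Rotamer hopping** — a discrete Markov chain over χ1 wells (+55°, −55°,
  180°) with von Mises emission (κ = 20 by default).
* **Coordinate realization** — a minimal proxy bundle: ideal-helix stand-ins
  for TMH3 (3.38–3.56) and TMH6 (6.30–6.50), stubs for TMH1 and TMH7, proxy
  side-chain heteroatoms placed *by construction* so that each target series
  is realized exactly (e.g. S6.33 OG on a fixed ray from R3.50 NE at the
  sampled lock distance, with NH1/NH2 positioned so NE is always the nearest
  nitrogen; the TMH6 backbone rigidly translated along the centroid line to
  the sampled IC separation; D7.49 rebuilt each frame at the sampled χ1; the
  sodium ion moved along the pocket axis so the Cα(1.50) and Cα(3.39)
  distances change by exactly the sampled displacement).  This geometry is
  **not** a receptor model: helices do not pack, proxy side chains are
  decoupled from their backbones where exactness requires it, and nothing
  beyond the measured metrics is physical.  Passing tests therefore
  demonstrate the correctness of the measurement pipeline, not realism of
  receptor structure or dynamics — real MD data adds noise sources
  (hydrogens, altlocs, periodic images, correlated motions) the proxies do
  not emulate.
* **Presets** — `wt_like` (lock breaks immediately and stays broken;
  stationary occupancy 0.002; D7.49 toggles into g− early; sodium low) and
  `mutant_like` (intermittent lock, stationary occupancy ≈ 0.45;
  D7.49 stays g+; sodium displaced 3.0 Å toward the extracellular side;
  intermittent 6.43–7.49 hydrogen bond).  Rates were chosen once to produce
  mean dwell times of a few ns at dt = 0.1 ns/frame — i.e. switching visible
  at the plotted timescale — and 700 ns default length (7000 frames)
  matching the study design; the acceptance checks use 10⁴ frames.
  All generator output is bit-reproducible from the scenario seed.

## Ballesteros–Weinstein numbering

Labels H.PP anchor the most conserved residue of helix H at H.50 and run
contiguously inside each helix span; loop residues carry absolute numbers
only.  The packaged GPR18 map fixes TMH3 by A3.39 = Ala(108) (hence
R3.50 = 119, D3.49 = 118, C3.25 = 94, Q3.56 = 125) and TMH6 by
K6.30 = Lys(227) (hence S6.33 = 230, Q6.43 = 240, F6.48 = 245).  The
documented loop spans (N-term 1–18, IC-1 51–55, EC-1 86–90, IC-2 126–133,
EC-2 159–184, IC-3 216–226, EC-3 259–264) determine the helix spans as
their complements; anchors for helices 1, 2, 4, 5, 7 and 8 are typical
class A placements and are marked approximate in the map's provenance
notes.  The source literature prints the mutation site both as 3.39(108)
and 3.93(102); the map adopts 3.39 = 108, the reading with a well-formed
label, and records the discrepancy.

## Degenerate inputs and tie-breaks

* PDB parsing is strict: insertion codes rejected, malformed fields raise
  with the line number, multi-model files must agree on atom identity and
  order.  Author numbering is never rewritten.
* Axis fits require ≥ 4 points; coincident points raise; near-zero
  curvature falls back to the line fit.  Wobble is undefined (raises) when
  the hinge Cα lies on the pre-hinge axis.
* classify_chi1 is total after normalization to (−180°, 180°].
* Bond-angle proposals are clamped by construction to ±8° of canonical.

## Known limitations

* The surrogate energy is qualitative; no solvent, lipid, hydrogens, CMAP
  or side-chain packing beyond χ1.
* The GPR18 map's non-TMH3/TMH6 anchors are approximate (see above).
* Only multi-model PDB is supported as a trajectory format; binary MD
  formats would need an adapter satisfying the same `Trajectory` contract.
* Face-shift values carry the 100°/residue baseline described above.
* The external crystal-structure benchmark (TMH3 bend of the delta opioid
  receptor, PDB 4N6H, reported ProKink bend 16.5°, tolerance ±3° for
  axis-convention differences) requires the downloaded structure and
  cannot run offline.
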