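# tmhkit

Transmembrane-helix geometry, conformational sampling and activation
micro-switch analysis for class A G-protein coupled receptors (GPCRs).

## The problem

Class A GPCRs switch between an inactive (R) and an active (R*) state.  A
handful of geometric "micro-switches" track that transition:

* the **ionic lock** between R3.50 (TMH3) and the intracellular end of TMH6 —
  in most receptors an R3.50–D/E6.30 salt bridge, in GPR18 a weaker
  R3.50–S6.33 hydrogen bond (distance criterion ≤ 3.2 Å);
* the **arginine cage**, the intra-helical R3.50–D3.49 salt bridge (≤ 4.0 Å);
* the separation of the cytoplasmic ends of TMH3 and TMH6, which opens to
  admit the G protein;
* the **sodium pocket** (N1.50/D2.50/3.39/7.45–7.49), whose ion position and
  the χ1 rotamer of position 7.49 couple to activation;
* χ1 **rotamer toggles** (g+/g−/trans) of aromatic toggle-switch residues.

Receptors with a weak ionic lock, such as GPR18, signal without an agonist
(constitutive activity); a single polar substitution at position 3.39 can
strengthen the lock and quench that activity.  Studying this computationally
takes three kinds of machinery, which this package provides as a tested
library with a thin CLI:

1. **Helix geometry** — build ideal/perturbed α-helices from internal
   coordinates, measure hinge geometry (bend / wobble / face shift),
   classify χ1 rotamers, superpose segments
   (`tmhkit.helix_geometry`);
2. **Conformational memories (CM)** — a two-phase Monte-Carlo/simulated-
   annealing search of a helix's hinge-region dihedrals: an exploratory
   phase (3000 K → 310 K, 18 steps, 50 000 MC steps/temperature) populates
   per-dihedral histograms, then a biased phase (749.4 K → 310 K, 9 steps)
   samples only the populated regions (`tmhkit.cm_sampler`);
3. **Switch analysis** — per-frame distance/rotamer series over multi-model
   PDB trajectories, with threshold flags, post-equilibration occupancies
   (100 ns cut) and a lock-stable / lock-intermittent / lock-broken
   classification (`tmhkit.switch_analysis`).

Because no public MD trajectories exist for this system, the package also
ships a **synthetic-trajectory generator** (`tmhkit.synthetic_trajectory`)
that realizes prescribed two-state bond dynamics, rotamer hopping and ion
displacement as actual 3-D coordinates, with the exact ground truth attached
— so the entire analysis stack is validated end-to-end.

## Worked example

```python
import numpy as np
from tmhkit import helix_geometry as hg, switch_analysis as sa, synthetic_trajectory as st

# 1. hinge geometry: build a helix kinked by construction, then measure it
helix = st.make_kinked_helix("A" * 21, hinge=11, bend=20.0, wobble=-16.2)
geom = hg.kink_geometry(helix, hinge=11)
print(f"bend = {geom.bend_angle:.1f} deg, wobble = {geom.wobble_angle:.1f} deg")

# 2. the two study scenarios, analyzed from coordinates
labels = st.scenario_label_map()
for name in ("wt_like", "mutant_like"):
    spec = st.ScenarioSpec.preset(name, n_frames=7000, seed=42)
    traj, truth = st.realize_coordinates(spec)
    report = sa.state_report(traj, labels)
    lock = report.series["ionic_lock"]
    chi = report.series["chi1_7.49"]
    print(f"{name}: {report.classification}, lock occupancy {lock.occupancy:.3f}, "
          f"D7.49 chi1 mostly {chi.extra['dominant_state']}")
```

prints

```
bend = 20.0 deg, wobble = -16.2 deg
wt_like: lock-broken, lock occupancy 0.000, D7.49 chi1 mostly g_minus
mutant_like: lock-intermittent, lock occupancy 0.437, D7.49 chi1 mostly g_plus
```

The hinge measurement recovers the constructed bend and wobble exactly.  The
wild-type-like scenario loses its ionic lock immediately and keeps the 7.49
side chain in the g− well (χ1 ≈ +55°); the 3.39-mutant-like scenario forms
an intermittent lock (occupancy ≈ 0.44 after the 100 ns equilibration cut)
with χ1 staying g+ (≈ −55°) and the sodium ion displaced 3.0 Å toward the
extracellular side — the qualitative wild-type vs. mutant contrast, by
construction.

The same pipeline from the shell:

```sh
tmhkit synth --scenario mutant_like --seed 42 --frames 7000 \
       --out traj.pdb --truth truth.csv
tmhkit switch-scan --traj traj.pdb --out metrics.csv --summary summary.json
tmhkit report --traj traj.pdb --out report.json
```

`tmhkit cm-sample --helix AAAAAAAAAAPAAAAAAAAAA --region 7:11 --seed 1
--out ensemble.pdb --stats memories.csv` runs the two-phase CM search on a
proline-hinge helix and writes the biased-phase ensemble as multi-model PDB.

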