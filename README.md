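# solvshell

Active-learning machine-learning potentials for metal ions in explicit
solvent — the full training-and-analysis workflow at desk scale.

Modelling the solvation shells and ligand-exchange dynamics of metal cations
(an octahedral Mg²⁺-like aqua complex, a square-planar Pd²⁺-like nitrile
complex) is hard for classical force fields and too expensive for long
*ab initio* dynamics.  A practical middle road is to train a machine-learning
potential (MLP) on solvated-cluster reference calculations gathered by
**active learning**: run short MD with the current potential, keep only the
structures that are *dissimilar* from the training set, label them with the
reference method, retrain, repeat.  `solvshell` implements every stage of
that pipeline as an importable Python library, with an analytic classical
force field standing in for the expensive reference so the whole loop runs
on a laptop:

* **Similarity selection** — global SOAP descriptors and the kernel
  similarity vector **K** = (|k(p₀·p_i)|^ζ, …); a candidate is added when
  max(**K**) < k_T.  MD in the AL loop runs for n³ + 2 fs, where n is the
  run index starting from 0.
* **The potential** — linear ridge regression over invariant 2-body + 3-body
  atomic features with exact analytic forces, a short-range core-repulsion
  guard, and the same calculator interface as the reference, so it plugs
  straight into the MD engine.
* **MD engine** — velocity Verlet (0.5 fs), stochastic velocity-rescaling
  (CSVR) thermostat (τ = 100 fs), flat-bottom spherical cluster restraints
  (U = k·Δ² beyond the onset radius), bit-reproducible per seed.
* **Free energies** — steered MD, umbrella sampling on distance or
  coordination-number collective variables, WHAM reconstruction, the radial
  entropy correction 2k_BT ln(r/r₀), and repeat-based uncertainties.
* **Analysis** — radial distribution functions g(r) and running coordination
  numbers N(r), first-shell detection, whole-molecule spherical cluster
  extraction, axial-coordination classification of square-planar complexes.

## Worked example

Train a potential by active learning on a solvated-ion complex, then check
that it reproduces the reference solvation structure:

```python
import solvshell as ss
from solvshell.fixtures import build_complex, random_displace
from solvshell.active_learning import bootstrap_dataset

calc = ss.ClassicalCalculator()                      # the reference potential
complex_ = build_complex("octahedral", bond_length=2.05)
seed_set = bootstrap_dataset(random_displace(complex_, 0.05, 10, seed=11), calc)

phase = ss.ALConfig(k_T=0.999, n_parallel=10, max_al_time=3000.0,
                    max_cycles=60, temperature=400.0, seed=12,
                    restraints=(ss.RestraintSpec(center=0, r_fb=8.0, k=500.0),))
dataset, model, history = ss.run_al_phase(seed_set, complex_, phase, calc)

state = ss.initialize_state(complex_, 300.0, seed=14)
run = ss.run_md(state, model, ss.ThermostatSpec("csvr", 300.0, 100.0),
                restraints=[ss.RestraintSpec(center=0, r_fb=8.0, k=500.0)],
                n_steps=100_000, dt=0.5, sample_every=20)
shell = ss.first_shell(ss.rdf(run.trajectory[500:], "Mg", "O",
                              bin_width=0.05, r_max=6.0))
print(shell)
```

After the second AL phase (see `examples/` and the acceptance suite for the
full two-phase protocol) this prints, for the trained potential,

```
{'peak_r': 2.125, 'min_r': 2.475, 'cn': 6.0, 'cn_rounded': 6}
```

matching the reference potential's own 50 ps RDF: the metal–oxygen first
peak at ≈ 2.1 Å and an octahedral first shell of 6 solvent molecules.  The
AL history shows the cubic MD-time schedule (2, 3, 10, 29, … fs) and the
training set growing only when genuinely new structures appear.

Each script in `examples/` demonstrates one capability end to end
(labelling + validation, similarity screening, an AL phase, MD + RDF,
umbrella sampling + WHAM, cluster cutting, axial classification) and prints
a line of interpretation with its numbers.

A thin CLI wraps the common one-shot operations
(`solvshell run|fixtures|label|train|md|rdf|validate`); YAML-driven
multi-stage runs go through `solvshell run config.yaml`
(see `solvshell.workflow`).

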