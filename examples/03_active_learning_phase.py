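"""One small active-learning phase on the solvated-ion complex.

Starts from 10 random-displacement structures, then iterates: MD with the
current model for n^3 + 2 fs, SOAP-similarity screening of the sampled
frames, reference labelling of accepted frames, retraining.  The printed
history shows the MD-time schedule and how the training set grows.
"""

import solvshell as ss
from solvshell.active_learning import bootstrap_dataset
from solvshell.fixtures import build_complex, random_displace

calc = ss.ClassicalCalculator()
complex_ = build_complex("octahedral", bond_length=2.05)
initial = bootstrap_dataset(random_displace(complex_, 0.05, 10, seed=7), calc)

config = ss.ALConfig(
    k_T=0.999,
    n_parallel=5,
    max_al_time=100.0,        # fs cap for this demo
    max_cycles=8,
    temperature=400.0,
    seed=8,
    restraints=(ss.RestraintSpec(center=0, r_fb=8.0, k=500.0),),
    phase="demo",
)
dataset, model, history = ss.run_al_phase(initial, complex_, config, calc)

print(history[["n", "md_time_fs", "candidates", "selected", "dataset_size"]]
      .to_string(index=False))
print(f"\nfinal dataset: {len(dataset)} structures "
      f"(each selected frame was dissimilar to the set at its acceptance)")
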