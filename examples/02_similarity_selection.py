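"""SOAP-kernel similarity screening — the decision rule of active learning.

A candidate structure enters the training set when the maximum of its
similarity vector K (kernel against every training structure) is below the
threshold k_T.  Here a mild distortion of a training structure is screened at
two thresholds; the printed max(K) shows how close it is to the training set.
"""

import solvshell as ss
from solvshell.fixtures import build_complex, random_displace
from solvshell.soap import SoapSpec, similarity_select

calc = ss.ClassicalCalculator()
complex_ = build_complex("octahedral", bond_length=2.05)
training = ss.label_dataset(random_displace(complex_, 0.05, 5, seed=3), calc)

spec = SoapSpec(species=("H", "O", "Mg"))
candidate = complex_.copy()
candidate.positions = candidate.positions.copy()
candidate.positions[4] += 0.15  # displace one oxygen by 0.15 Å

for k_T in (0.999, 0.99999):
    record = similarity_select(candidate, training, spec, k_T=k_T)
    print(f"k_T = {k_T}: max(K) = {record.max_similarity:.6f} "
          f"-> {'SELECT' if record.selected else 'skip'}")
print("(a looser threshold only admits structures far from everything seen;")
print(" a tighter one also admits near-duplicates — the per-phase thresholds")
print(" steer how aggressively the training set grows)")
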