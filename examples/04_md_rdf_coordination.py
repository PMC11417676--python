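"""Ion-in-water MD and solvation-shell analysis (short demo run).

Packs a periodic box with one +2 cation and 60 water-like molecules, runs a
few picoseconds of thermostatted MD with the classical surrogate, and
integrates the ion-oxygen radial distribution function to the first minimum
— the coordination number of the first solvation shell.  (The production
protocol uses >= 100 molecules and 50 ps; this demo is scaled down to run in
about a minute.)
"""

import solvshell as ss
from solvshell.fixtures import minimize, pack_solvent_box

calc = ss.ClassicalCalculator()
box = pack_solvent_box(60, density=0.997, seed=21, ion="Mg")
box = minimize(box, calc, n_steps=300)

state = ss.initialize_state(box, 300.0, seed=22)
thermo = ss.ThermostatSpec("csvr", temperature=300.0, tau=100.0)
result = ss.run_md(state, calc, thermo, n_steps=12_000, dt=0.5, sample_every=100)
print(result.log.tail(1).to_string(index=False))

rdf_result = ss.rdf(result.trajectory[40:], "Mg", "O", bin_width=0.05)
shell = ss.first_shell(rdf_result)
print(f"first peak at {shell['peak_r']:.2f} Å, first minimum at {shell['min_r']:.2f} Å")
print(f"coordination number N(r_min) = {shell['cn']:.2f} -> {shell['cn_rounded']}")
print("(a +2 magnesium-like cation coordinates 6 waters octahedrally;")
print(" the first peak near 2.0-2.1 Å is the metal-oxygen bond distance)")
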