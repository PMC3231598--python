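"""Forward response of the five-electrode array to a two-anion mixture.

Builds a single solution containing perchlorate and sulfide, converts the
concentrations to activities (Davies model) and evaluates each electrode's
Nikolsky-Eisenmann potential — the raw signal an electronic tongue sees.
"""

from dataclasses import replace

from etongue import SolutionState, electrode_potential, load_panel

panel = load_panel()
params = replace(panel.activity, fixed_background_ionic_strength=0.0)

clo4, s = panel.ion("ClO4"), panel.ion("S")
solution = SolutionState({clo4: 1.0e-4, s: 1.0e-4})

print(f"Solution: [ClO4-] = 1.0e-4 M, [S2-] = 1.0e-4 M")
print(f"Ionic strength: {solution.ionic_strength(params):.3e} M")
acts = solution.activities(params)
print(f"Activities:  a_ClO4 = {acts[clo4]:.3e}, a_S = {acts[s]:.3e}\n")

for sensor in panel.sensors:
    e = electrode_potential(sensor, solution, params)
    print(
        f"{sensor.id:>3}: {e:8.2f} mV   "
        f"(primary {sensor.primary_ion.name}, slope {sensor.slope} mV/decade)"
    )

print(
    "\nEach potential mixes both ions' contributions through the electrode's"
    "\nselectivity coefficients; no single reading determines either ion alone,"
    "\nwhich is why the array response must be inverted multivariately."
)
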