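"""Invert a rebinding curve into a maximum-entropy lifetime distribution.

Generates a noisy synthetic survival curve at each of two CO pressures and
shows that the slowest (bimolecular) kinetic phase moves tenfold slower
when the CO concentration drops tenfold, while the geminate phase stays
put — the classic signature used to assign kinetic phases.
"""

import numpy as np

from flashkin import GeneratorConfig, generate_two_concentration_set
from flashkin.mem import build_tau_grid, distribution_peaks, mem_invert

config = GeneratorConfig(regime="HE7Q", variant="HE7Q", seed=5,
                         points_per_decade=40)
hi, lo = generate_two_concentration_set(config, 293.15)

grid = build_tau_grid(1e-9, 1e2, 8)
for label, trace in (("1 atm CO", hi), ("0.1 atm CO", lo)):
    dist = mem_invert(trace, grid=grid, chi2_target=1.1)
    peaks = distribution_peaks(dist, 0.05)
    desc = ", ".join(f"tau = {tau:.2e} s (amp {amp:.2f})"
                     for tau, amp in peaks)
    print(f"{label:>10}: chi2/N = {dist.chi2_per_point:.3f}; peaks: {desc}")

# The fast peak (~1e-8 s) is geminate rebinding from the primary docking
# site: CO-concentration independent.  The slow peak is bimolecular
# rebinding from the solvent: its lifetime scales as 1/[CO], so diluting
# CO tenfold shifts it one decade slower.
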