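"""Recover microscopic rate constants by a global two-concentration fit.

Generates survival curves at 1 atm and 0.1 atm CO (1% noise) from the
preset rate constants, then fits both curves simultaneously with the rate
constants shared — the same strategy used to pin down the bimolecular
entry rate and the His binding/release rates — and compares the estimates
with the generating truth.
"""

import numpy as np

from flashkin import (FitSpec, GeneratorConfig, fit_global,
                      generate_two_concentration_set, goodness_of_fit,
                      preset_rates)

config = GeneratorConfig(regime="wt_solution", seed=42)
traces = generate_two_concentration_set(config, 293.15)
truth = preset_rates("wt_solution")

free_symbols = ("k_-1", "k_2", "k_c", "k_-2", "k_b", "k_-b")
free = {s: (np.log10(truth[s]) - 1.5, np.log10(truth[s]) + 1.5)
        for s in free_symbols}
fixed = {s: v for s, v in truth.values.items() if s not in free}

spec = FitSpec(model=config.model, datasets=traces, free=free, fixed=fixed)
result = fit_global(spec, truth, seed=42, n_starts=8)

print(f"global fit over {sum(len(t) for t in traces)} points, "
      f"chi2/N = {result.chi2_per_point:.3f}\n")
print(f"{'rate':>6} {'true':>10} {'fitted':>10} {'log10 err':>10}")
for s in free_symbols:
    err = np.log10(result.estimates[s] / truth[s])
    print(f"{s:>6} {truth[s]:10.3g} {result.estimates[s]:10.3g} {err:+10.3f}")

report = goodness_of_fit(result)
for i, d in enumerate(report["datasets"]):
    print(f"\ndataset {i}: chi2/N = {d['chi2_per_point']:.3f}, "
          f"runs-test p = {d['runs_test_p']:.2f}")
# log10 errors within a few hundredths mean every identifiable rate is
# recovered to better than ~10%; runs-test p-values away from 0 show the
# residuals carry no systematic structure.
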