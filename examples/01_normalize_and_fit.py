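"""Simulate a small plate screen, normalize it and fit potency exponents.

The generator plants known signed exponents; the printed table compares each
fitted beta with its ground truth. With 10% multiplicative noise the fits land
within a few hundredths of the planted values.
"""

import pandas as pd

from nanopotency import SimulationConfig, compute_fold_effect, fit_all, simulate_assay

betas = pd.DataFrame(
    {
        "particle": ["NP-A", "NP-A", "NP-A", "NP-B", "NP-B", "NP-B"],
        "cell_type": ["A549"] * 6,
        "endpoint": ["ATP", "CTB", "LDH"] * 2,
        "beta_signed": [-0.30, -0.20, 0.10, -1.20, -0.90, 0.25],
    }
)
config = SimulationConfig(betas=betas, noise_sigma=0.1)

raw = simulate_assay(config, seed=42)
print(f"simulated {len(raw)} wells "
      f"({raw['role'].value_counts().to_dict()})")

fe = compute_fold_effect(raw)  # blank-corrected, normalized per experiment
fitted = fit_all(fe).merge(betas, on=["particle", "cell_type", "endpoint"],
                           suffixes=("_fit", "_true"))
cols = ["particle", "endpoint", "beta_signed_true", "beta_signed_fit", "se_beta"]
print(fitted[cols].round(3).to_string(index=False))
print("\nEach row: fitted exponent of FE = (dose+1)^beta vs the planted truth;"
      "\nnegative = response declines with dose (viability), positive = rises (%LDH).")
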