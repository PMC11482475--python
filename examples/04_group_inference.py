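"""Treatment/dose inference on fold effects.

Runs the two-way ANOVA (treatment x dose, auto rank-transform) on simulated
fold effects and adjusts treatment-vs-control contrasts with the Holm-Sidak
stepdown.
"""

import pandas as pd

from nanopotency import (
    SimulationConfig,
    compute_fold_effect,
    pairwise_contrasts,
    simulate_assay,
    two_way_anova,
)

betas = pd.DataFrame(
    {
        "particle": ["potent", "potent", "inert", "inert"],
        "cell_type": ["A549"] * 4,
        "endpoint": ["ATP", "LDH", "ATP", "LDH"],
        "beta_signed": [-0.8, 0.3, 0.0, 0.0],
    }
)
fe = compute_fold_effect(simulate_assay(SimulationConfig(betas=betas), seed=5))

atp = fe[fe["endpoint"] == "ATP"]
res = two_way_anova(atp, factor_a="particle", factor_b="dose", transform="auto")
print(res.to_frame().round(4).to_string(index=False))
print("\nA large particle F and particle:dose interaction say the two particles'"
      "\ndose-response curves differ (one is cytotoxic, one inert);"
      f" transform = {res.transform}.")

top = atp[atp["dose"] == atp["dose"].max()]
groups = {p: g["fe"].to_numpy() for p, g in top.groupby("particle")}
groups["control"] = atp[atp["dose"] == 0]["fe"].to_numpy()
adj = pairwise_contrasts(groups, control="control")
print("\nHolm-Sidak adjusted treatment-vs-control contrasts at the top dose:")
print(adj.to_frame().round(5).to_string(index=False))
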