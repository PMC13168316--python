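"""Glycoform nomenclature, quality indices, and the hexosylation-bias fix.

Parses paired-glycan labels, computes the galactosylation and glycation
indices on hand-checkable inputs, and demonstrates that deconvolving the
glycation distribution restores the true galactosylation ladder.
"""

import numpy as np
import pandas as pd

from glycofeed import (
    GlycationProfile,
    correct_hexosylation_bias,
    forward_hexosylation_bias,
    galactosylation_index,
    glycation_index,
    normalize_abundances,
    parse_glycoform,
)

sp = parse_glycoform("G1F ⋅ G0F")
print(f"{sp.label}: {sp.g} galactoses on {sp.d} sites, "
      f"fucosylated arms: {sp.arm_a.fucosylated}, {sp.arm_b.fucosylated}")

table = normalize_abundances(pd.DataFrame(
    {"G0F ⋅ G0F": [50.0], "G1F ⋅ G1F": [50.0]}, index=["demo"]))
print(f"galactosylation index of a 50/50 G0F⋅G0F + G1F⋅G1F mix: "
      f"{galactosylation_index(table).iloc[0]:.4f} %")

profile = GlycationProfile(pd.DataFrame(
    [[50.0, 50.0, 0.0, 0.0]], index=["demo"],
    columns=["hexoses_0", "hexoses_1", "hexoses_2", "hexoses_3"]))
print(f"glycation index of f=(50,50,0,0)%: "
      f"{glycation_index(profile).iloc[0]:.4f} %")

# glycation hexoses are isobaric with galactose at the intact level; the
# correction deconvolves the independently measured glycation distribution
cols = ["G0F ⋅ G0F", "G0F ⋅ G1F", "G1F ⋅ G1F"]
truth = normalize_abundances(pd.DataFrame([[60.0, 30.0, 10.0]],
                                          index=["s"], columns=cols))
glyc = GlycationProfile(pd.DataFrame(
    [[80.0, 15.0, 4.0, 1.0]], index=["s"],
    columns=["hexoses_0", "hexoses_1", "hexoses_2", "hexoses_3"]))
biased = forward_hexosylation_bias(truth, glyc)
fixed = correct_hexosylation_bias(biased, glyc)
print()
print(f"true galactosylation index     : {galactosylation_index(truth).iloc[0]:.2f} %")
print(f"apparent (glycation-biased)    : {galactosylation_index(biased).iloc[0]:.2f} %")
print(f"after bias correction          : "
      f"{galactosylation_index(fixed).iloc[0]:.2f} %")
print()
print("Uncorrected intact-mass data overstates galactosylation whenever")
print("glycation is present; the correction recovers the true ladder.")
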