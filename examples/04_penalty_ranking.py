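"""The penalty scalarisation that ranks Pareto solutions: a weighted sum of
disease probabilities plus a positive-gap term discouraging lopsided
trade-offs (first-listed disease risk exceeding the second's)."""

import multicf as mc

config = mc.PenaltyConfig(
    disease_order=("heart_stroke", "diabetes"), weights=(1.0, 1.0), lambda_=1.0
)

pairs = [
    ("balanced, both tiny", (0.00001095, 0.00025517)),
    ("even smaller pair", (0.00000876, 0.00010403)),
    ("lopsided: stroke risk larger", (0.30, 0.10)),
    ("equal risks", (0.20, 0.20)),
]
for label, (p_hs, p_dm) in pairs:
    val = mc.penalty((p_hs, p_dm), config)
    print(f"{label:32s} P_HS={p_hs:<10g} P_DM={p_dm:<10g} -> L = {val:.8f}")

# When P_HS <= P_DM the gap term vanishes and L is just the sum; the
# lopsided pair pays an extra lambda * (0.30 - 0.10) = 0.20 on top of 0.40.
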