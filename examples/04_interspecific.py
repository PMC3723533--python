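"""Arm/spacer divergence and W<->S replacement analysis on a simulated triad.

Evolves human/chimp/gorilla sequences with a lower substitution rate in the
palindrome arm than the spacer (the signature of ancestral-state-biased
conversion) and an arm-restricted bias of substitution targets towards
strong bases, then recovers both signals.
"""

from palinconv import region_divergence, replacement_table
from palinconv.simulate import SimParams, simulate_triad

params = SimParams(seed=20, arm_length=60_000, spacer_length=30_000)
triad, mask, truth = simulate_triad(params)

div = region_divergence(triad.human, triad.chimp, mask)
print(div.to_string(index=False))
print(f"arm-vs-spacer Yates p = {div.attrs['arm_vs_spacer_p']:.2e}")
# Arm divergence ~1.4% vs spacer ~2.0%, as configured; the Yates chi-square
# confirms the contrast at this sequence length.

table = replacement_table(triad, mask, apply_dinucleotide_mask=True)
cols = ["lineage", "region", "total_replacements", "pct_ws", "pct_sw",
        "ratio_to_w_over_to_s"]
print(table[cols].round(3).to_string(index=False))
# The to-W/to-S ratio is higher in the spacer than the arm on both lineages:
# arms are enriched for weak->strong replacements relative to spacers.
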