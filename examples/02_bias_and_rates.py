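"""Directional/GC bias tests and per-generation rates from the survey counts.

Uses the bundled P6 survey tallies: 146 conversion events (86 to the
ancestral state, 60 to the derived; 59 fixing G/C vs 20 fixing A/T among the
79 GC-informative ones) over a phylogeny spanning 175,000-505,500
generations.
"""

from palinconv import datasets, gof_chisq, rate_range

c = datasets.CONVERSION_COUNTS

direction = gof_chisq(c["to_ancestral"], c["to_derived"])
print(f"ancestral-state bias: {c['to_ancestral']}:{c['to_derived']}, "
      f"chi2={direction.chi2:.2f}, p={direction.p:.4f}")

gc = gof_chisq(c["fixes_S"], c["fixes_W"])
print(f"GC fixation bias:     {c['fixes_S']}:{c['fixes_W']}, "
      f"chi2={gc.chi2:.2f}, p={gc.p:.2e}")

rates = rate_range(c["total"], datasets.GENERATION_BUDGET)
print(f"conversion rate: {rates.rate_lower:.2g} - {rates.rate_upper:.2g} "
      "events/generation")
# Both biases are significant (p ~ 0.031 and ~1.1e-5): conversion
# preferentially restores ancestral states and fixes strong (G/C) bases.
# The rate divides the event count by the generation budget bounds.
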