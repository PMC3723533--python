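"""Call gene-conversion events for one PSV on a toy haplogroup tree.

A PSV whose mutation arose in haplogroup F's founder (pseudoheterozygous
G/A) is observed fixed G/G in one descendant and fixed A/A in another:
maximum parsimony requires two conversion events, one per direction.
"""

import pandas as pd

from palinconv import GenotypeMatrix, HaplogroupTree, Psv, PseudoGenotype, enumerate_events

tree = HaplogroupTree.from_newick(
    "((A,B,C)F,OUT)ROOT;",
    {"sampleA": "A", "sampleB": "B", "sampleC": "C", "sampleOut": "OUT"},
)
psv = Psv("PSV1", 1000, "G", "A")  # G ancestral, A derived
matrix = GenotypeMatrix(
    pd.DataFrame(
        {"PSV1": [PseudoGenotype.HOM_ANC, PseudoGenotype.HOM_DER,
                  PseudoGenotype.HET, PseudoGenotype.HOM_ANC]},
        index=["sampleA", "sampleB", "sampleC", "sampleOut"],
    )
)

calls = enumerate_events(tree, matrix, [psv])
print(calls.events.to_string(index=False))
print(calls.summary())
# Two events below founder F: sampleA lost the derived allele (to_ancestral,
# fixing G = fixes_S) and sampleB lost the ancestral one (to_derived,
# fixing A = fixes_W).  The count is the minimum over all legal histories.
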