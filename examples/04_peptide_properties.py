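"""Profile peptide physicochemistry and contrast two phyla.

Aureocin A53-like core peptides are short, cationic and tryptophan
rich; the profile is length, GRAVY hydropathy, average molecular
weight, net charge at pH 7 and isoelectric point.  A Kruskal-Wallis
rank test asks whether a property differs between phyla, and the dose
converter turns an assay concentration into molarity.
"""

import numpy as np

from aureomine import (
    DEFAULT_SEED,
    dose_to_molar,
    molecular_weight,
    properties_table,
)
from aureomine.props import property_group_test
from aureomine.synthetic import SimConfig, generate_protein_db

records, truth = generate_protein_db(
    SimConfig(rng_seed=4, n_families=2, family_distances=(0.1, 0.3),
              members_per_family=8, n_decoys=0)
)
table = properties_table(records)
print(table.round(2).head(4).to_string(index=False))
print("...")

phylum = {k: v.phylum for k, v in truth.taxonomy.items()}
tests = property_group_test(table, phylum)
print("\nKruskal-Wallis by phylum (H, df, p per property):")
print(tests.round(4).to_string(index=False))
# small p: the property separates Actinomycetota from Bacillota peptides

mw = molecular_weight(DEFAULT_SEED.sequence)
dose = dose_to_molar(100.0, mw)
print(f"\n100 ug/mL of the {mw/1000:.1f} kDa seed peptide = {dose} uM")
print(f"100 ug/mL of a   6.3 kDa peptide                = "
      f"{dose_to_molar(100.0, 6300.0)} uM")
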