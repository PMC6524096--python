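"""Taxonomic profiles, the Firmicutes/Bacteroidetes trajectory, and the
pathway-presence filter.

Agglomeration conserves reads; the phylum ratio is the classic marker of
gut maturation (rises as fibre fermenters take over). The pathway filter
keeps pathways present in >= 1/3 of a taxon's genomes.
"""

import pandas as pd

from cecosucc import (StudyDesign, agglomerate, generate_study,
                      pathway_presence_filter, taxon_ratio)
from cecosucc.diversity import auto_depth, rarefy

table, _, _ = generate_study(StudyDesign(seed=42))
rt = rarefy(table, auto_depth(table), seed=0)

phyla = agglomerate(rt, "phylum")
rel = (phyla / phyla.sum(axis=0) * 100)
rel_age = rel.T.groupby(rt.sample_meta["age_days"]).mean()
print("mean phylum relative abundance (%) by age:")
print(rel_age.round(1).to_string())

res = taxon_ratio(phyla, "Firmicutes", "Bacteroidetes",
                  rt.sample_meta["age_days"])
print("\nFirmicutes/Bacteroidetes ratio by age (mean +/- sd):")
print(res.summary.round(2).to_string())

# toy pathway x genome completeness table for a genus of interest
pp = pd.DataFrame(
    {"genome1": [1.0, 1.0, 0.4, 0.0],
     "genome2": [1.0, 0.0, 0.5, 0.0],
     "genome3": [1.0, 1.0, 1.0, 0.2]},
    index=["fucose degradation", "xylose degradation",
           "sialic acid degradation", "cellulose degradation"])
kept = pathway_presence_filter(pp, min_presence=1 / 3)
print(f"\npathways kept at the 1/3-of-genomes rule: {kept}")
print("(a pathway counts as present in a genome when its completeness "
      "score reaches 1.0)")
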