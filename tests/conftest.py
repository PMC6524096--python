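import numpy as np
import pandas as pd
import pytest

from cecosucc import CountTable, StudyDesign, generate_study
from cecosucc.diversity import auto_depth, rarefy


@pytest.fixture
def tiny_table():
    """3 OTUs x 4 samples, two ages, with metadata and taxonomy."""
    counts = pd.DataFrame(
        [[5, 0, 2, 1],
         [3, 7, 0, 4],
         [2, 3, 8, 5]],
        index=["otuA", "otuB", "otuC"],
        columns=["s1", "s2", "s3", "s4"])
    meta = pd.DataFrame(
        {"age_days": [18, 18, 49, 49],
         "diet_group": ["LL", "HH", "LL", "HH"],
         "doe_id": ["d1", "d2", "d3", "d4"]},
        index=pd.Index(["s1", "s2", "s3", "s4"], name="sample_id"))
    tax = pd.DataFrame(
        {"kingdom": ["Bacteria"] * 3,
         "phylum": ["Firmicutes", "Firmicutes", "Bacteroidetes"],
         "class": [""] * 3, "order": [""] * 3,
         "family": ["Ruminococcaceae", "Lachnospiraceae", "Bacteroidaceae"],
         "genus": ["", "Blautia", "Bacteroides"]},
        index=pd.Index(["otuA", "otuB", "otuC"], name="otu_id"))
    return CountTable(counts, meta, tax)


@pytest.fixture(scope="session")
def default_study():
    """One default-design synthetic study, shared across the session."""
    design = StudyDesign(seed=7)
    table, tree, truth = generate_study(design)
    return design, table, tree, truth


@pytest.fixture(scope="session")
def rarefied_study(default_study):
    design, table, tree, truth = default_study
    rt = rarefy(table, auto_depth(table), seed=77)
    return design, rt, tree, truth
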