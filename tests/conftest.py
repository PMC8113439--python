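import numpy as np
import pandas as pd
import pytest

from gcea import CategorySpec, ExpressionAtlas, SyntheticAtlasSpec, make_synthetic_atlas

TOY_OBO = """format-version: 1.2
ontology: go

[Term]
id: GO:0000001
name: root
namespace: biological_process

[Term]
id: GO:0000002
name: mid1
namespace: biological_process
is_a: GO:0000001

[Term]
id: GO:0000003
name: mid2
namespace: biological_process
is_a: GO:0000001

[Term]
id: GO:0000004
name: leaf
namespace: biological_process
is_a: GO:0000002
is_a: GO:0000003

[Term]
id: GO:0000005
name: lonely molecular term
namespace: molecular_function

[Term]
id: GO:0000006
name: retired
namespace: biological_process
is_obsolete: true
"""


def gaf_line(gene, term, qualifier="", evidence="IDA"):
    return "\t".join([
        "MGI", gene, gene.upper(), qualifier, term, "PMID:1", evidence, "", "P",
        "", "", "protein", "taxon:10090", "20190417", "MGI", "", "",
    ])


@pytest.fixture
def toy_obo(tmp_path):
    p = tmp_path / "toy.obo"
    p.write_text(TOY_OBO)
    return p


@pytest.fixture
def toy_gaf(tmp_path):
    lines = [
        "!gaf-version: 2.1",
        gaf_line("geneA", "GO:0000004"),
        gaf_line("geneB", "GO:0000002"),
        gaf_line("geneC", "GO:0000004", qualifier="NOT"),
        gaf_line("geneD", "GO:0000003", evidence="ND"),
        gaf_line("geneE", "GO:0000005"),
    ]
    p = tmp_path / "toy.gaf"
    p.write_text("\n".join(lines) + "\n")
    return p


@pytest.fixture
def small_atlas():
    """Complete 40-region x 300-gene atlas with categories across w levels."""
    spec = SyntheticAtlasSpec(
        n_regions=40,
        n_genes=300,
        coordinate_box=10.0,
        categories=[CategorySpec(10, w) for w in (0.0, 0.5, 0.9) for _ in range(3)],
        seed=7,
    )
    return make_synthetic_atlas(spec)


@pytest.fixture
def tiny_expression():
    """Hand-sized 4x4 frame whose missingness makes the genes-first and
    regions-first filter orders disagree (worked out by hand):

    * genes first at 50%: g0 (observed 1/4) is dropped, then r0 and r1
      (observed 1/3 of the survivors) are dropped;
    * regions first at 50%: r0 and r1 (observed 1/4) are dropped, after
      which g0 is observed in 1/2 of the survivors and kept.
    """
    idx = [f"r{i}" for i in range(4)]
    cols = [f"g{i}" for i in range(4)]
    vals = np.arange(16, dtype=float).reshape(4, 4)
    df = pd.DataFrame(vals, index=idx, columns=cols)
    df.iloc[0, [0, 1, 2]] = np.nan
    df.iloc[1, [0, 1, 2]] = np.nan
    df.iloc[2, 0] = np.nan
    return df
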