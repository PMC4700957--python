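import pytest
from hypothesis import settings

from mitonuclear import load_table2_genotypes

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

# Published per-population genotype class counts (hom-1, het, hom-2) for the
# nine nonsynonymous substitutions in the six candidate genes, keyed by
# GENE_position (1-based in the human ortholog).  These are the independent
# oracle the shipped fixture must re-aggregate to.
PUBLISHED_COUNTS = {
    "POLRMT_1090": {"north": (16, 17, 2), "south": (2, 17, 16)},
    "POLRMT_1218": {"north": (4, 21, 10), "south": (0, 7, 28)},
    "ACO1_601": {"north": (7, 16, 11), "south": (0, 5, 30)},
    "NDUFA5_95": {"north": (30, 5, 0), "south": (12, 18, 5)},
    "LYRM4_51": {"north": (8, 20, 7), "south": (23, 9, 3)},
    "MARS2_298": {"north": (30, 4, 1), "south": (14, 13, 5)},
    "MARS2_345": {"north": (30, 4, 1), "south": (19, 12, 4)},
    "MARS2_498": {"north": (30, 4, 1), "south": (19, 12, 4)},
    "ACAD9_503": {"north": (29, 1, 0), "south": (21, 10, 0)},
}


@pytest.fixture(scope="session")
def chameleon_table():
    return load_table2_genotypes()


@pytest.fixture(scope="session")
def chameleon_counts(chameleon_table):
    return {c.locus: c for c in chameleon_table.all_counts()}
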