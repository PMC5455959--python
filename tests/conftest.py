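import numpy as np
import pandas as pd
import pytest

from castemk.phylostrat import Lineage
from castemk.variants import VariantSite


@pytest.fixture(scope="session")
def lineage():
    return Lineage.default()


@pytest.fixture
def small_counts():
    """Ten genes with hand-countable MK quadruples."""
    rng = np.random.default_rng(42)
    return pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(10)],
            "Pn": rng.integers(0, 6, 10),
            "Ps": rng.integers(1, 10, 10),
            "Dn": rng.integers(1, 10, 10),
            "Ds": rng.integers(1, 10, 10),
        }
    )


def make_site(ref="A", alts=("G",), quality=100.0, n_ingroup=22,
              n_missing=0, contig="ctg", position=5, outgroup_gt=(0, 0),
              ingroup_alt_carriers=0):
    """Construct a VariantSite with a simple genotype layout."""
    genotypes = {}
    for i in range(n_ingroup):
        if i < n_missing:
            genotypes[f"mph_{i:02d}"] = None
        elif i < n_missing + ingroup_alt_carriers:
            genotypes[f"mph_{i:02d}"] = (1, 1)
        else:
            genotypes[f"mph_{i:02d}"] = (0, 0)
    genotypes["outgroup"] = outgroup_gt
    return VariantSite(
        contig=contig, position=position, ref=ref, alts=tuple(alts),
        quality=quality, genotypes=genotypes,
    )
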