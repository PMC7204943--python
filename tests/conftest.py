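import numpy as np
import pytest

from ptmatlas.io_integration import ProteinRecord, PTMSiteRaw
from ptmatlas.ptm_catalog import PTMSite, build_catalog


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_proteome():
    """Three small proteins with known residues at key positions."""
    return {
        "P1": ProteinRecord("P1", "G1", "MKTAYKKLSSKQWKRKSKDCKKAYSTKNNTKKAYSTKLMM" * 5),
        "P2": ProteinRecord("P2", "", "MSSTTYYKKA" * 10),
        "P3": ProteinRecord("P3", "", "MKKKKKKKKK" * 3),
    }


def make_site(acc="P1", pos=10, types=("acetylation",), residue="K",
              sources=("dbPTM",)):
    return PTMSite(acc, pos, residue, set(types), set(sources))


@pytest.fixture
def small_catalog():
    """Hand-built catalog: P1 with a crosstalk site, P2 without."""
    raw = [
        PTMSiteRaw("P1", 6, "K", "N6-acetyllysine", "dbPTM"),
        PTMSiteRaw("P1", 6, "K", "Ubiquitination", "PSP"),
        PTMSiteRaw("P1", 11, "K", "N6-acetyllysine", "dbPTM"),
        PTMSiteRaw("P2", 5, "T", "Phosphothreonine", "neXtProt"),
    ]
    return build_catalog(raw)
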