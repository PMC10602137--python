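import pytest
from hypothesis import settings

from pitmatch.repertoire_io import Repertoire, TcrChainRecord

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from pitmatch.synthetic_data import load_mini_germline


@pytest.fixture(scope="session")
def germline():
    return load_mini_germline()


def make_record(junction_aa, record_id="r0", locus="TRA", v_gene=None,
                j_gene=None, cell_id="c0", donor_id="d0", **kw):
    return TcrChainRecord(
        record_id=record_id, locus=locus,
        v_gene=v_gene or f"{locus}V1-2", j_gene=j_gene or f"{locus}J8",
        junction_aa=junction_aa, cell_id=cell_id, donor_id=donor_id, **kw)


def make_repertoire(junctions, **kw):
    return Repertoire([
        make_record(j, record_id=f"r{i}", cell_id=f"c{i}")
        for i, j in enumerate(junctions)])


@pytest.fixture
def tiny_repertoire():
    return make_repertoire(["CAVRMNTGFQKLVF", "CAASNTGNQFYF", "CVVNDQAGTALIF"])
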