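import numpy as np
import pytest

from gutperm.records import CompoundRecord, QuantStatus, Source


def make_record(
    rid="r0",
    smiles="c1ccccc1",
    source=Source.HMDB_GUT,
    in_gut=True,
    in_serum=False,
    chem_class="Benzenoids",
    pka_acid=None,
    pka_base=None,
):
    return CompoundRecord(
        id=rid,
        smiles=smiles,
        source=source,
        in_gut=in_gut,
        in_serum=in_serum,
        pka_strongest_acidic=pka_acid,
        pka_strongest_basic=pka_base,
        chem_class=chem_class,
        quant_status=None if source is Source.DRUGBANK else QuantStatus.QUANTIFIED,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20231013)


@pytest.fixture(scope="session")
def small_benchmark():
    """Tiny labeled benchmark shared by pipeline/model smoke tests."""
    from gutperm.synthetic import BenchmarkSpec, generate_benchmark

    spec = BenchmarkSpec(n_fl=40, n_nofl=40, n_traverser=40, seed=11)
    return generate_benchmark(spec)
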