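import pytest

from kmernb import Database, KmerSpec
from kmernb.simulate import SimParams, synthetic_community


@pytest.fixture(scope="session")
def small_community(tmp_path_factory):
    """Six single-genome classes of 5 kb, plus a trained k=7 canonical db."""
    root = tmp_path_factory.mktemp("community")
    params = SimParams(
        genome_length=5000, n_reads=10, read_length=100,
        substitution_rate=0.0, seed=11,
    )
    records = synthetic_community(6, root, params)
    db = Database.create(root / "db", KmerSpec(7, True))
    for r in records:
        db.add_genome(r)
    return {"root": root, "records": records, "db": db, "params": params}
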