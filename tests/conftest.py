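import pytest

from splicefn.labels import build_catalogue
from splicefn.model import OrganismDataset, ProteinRecord, TranscriptionalUnit


def make_dataset(tu_specs, organism="test", scope="t", build=True):
    """Dataset from {tu_id: [keyword-set, ...]} specs; catalogue optional."""
    tus = []
    for tu_id, kw_sets in tu_specs.items():
        tu = TranscriptionalUnit(tu_id)
        for j, kws in enumerate(kw_sets, start=1):
            tu.proteins.append(
                ProteinRecord(f"{tu_id}_p{j}", tu_id, frozenset(kws))
            )
        tus.append(tu)
    ds = OrganismDataset(organism=organism, tus=tus)
    if build:
        build_catalogue(ds, scope)
    return ds


@pytest.fixture
def small_dataset():
    """Two polyform, one monoform, one unannotated TU."""
    return make_dataset(
        {
            "tu1": [{"A", "B"}, {"A"}, {"A", "B"}],
            "tu2": [{"C"}, {"D"}],
            "tu3": [{"A"}],
            "tu4": [set()],
        }
    )
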