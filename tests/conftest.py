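import pytest

from domainspot.catalog import ClassifiedMutation, MappedMutation
from domainspot.hotspots import HotspotTest
from domainspot.io import DomainInstance, MutationRecord, ProteinRecord


@pytest.fixture
def tiny_proteome():
    return {
        "P1": ProteinRecord("P1", "M" + "ACDEFGHIKL" * 12),  # length 121
        "P2": ProteinRecord("P2", "MKVLWAALLVTFLAGCQA" * 4),  # length 72
    }


def make_mutation(protein="P1", change="A2C", sample="S1"):
    return MutationRecord(sample, protein, change, "carcinoma")


def make_mapped(family="FAM", mclass="missense", protein="P1", column=1,
                position=10, start=1, end=100):
    """Minimal MappedMutation for count-level APIs."""
    record = MutationRecord("S1", protein, "A1C", "")
    mut = ClassifiedMutation(record, mclass, position, "A", "C")
    inst = DomainInstance(protein, family, start, end)
    return MappedMutation(mut, inst, position - start + 1, column)


def make_hotspot(family="FAM", column=1, mclass="missense", proteins=("P1",),
                 significant=True, k=5, n=50):
    return HotspotTest(family, column, mclass, n, k, 0.01, 1e-6, 1e-4,
                       significant, frozenset(proteins))


@pytest.fixture
def mapped_factory():
    return make_mapped


@pytest.fixture
def hotspot_factory():
    return make_hotspot
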