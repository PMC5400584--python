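import pytest
from hypothesis import given, settings, strategies as st

from domainspot.catalog import (
    aggregate_columns,
    classify_change,
    classify_mutation,
    map_to_domains,
    map_to_msa_column,
    validate_references,
)
from domainspot.io import (
    INDEL,
    MISSENSE,
    TRUNCATION,
    UNCLASSIFIED,
    DomainInstance,
    MutationRecord,
    ProteinRecord,
)
from conftest import make_mapped, make_mutation


class TestClassifyChange:
    @pytest.mark.parametrize("change,mclass,position,ref,alt", [
        ("V600E", MISSENSE, 600, "V", "E"),  # activating kinase substitution
        ("D816V", MISSENSE, 816, "D", "V"),
        ("E813*", TRUNCATION, 813, "E", "*"),  # stop gain
        ("Q1247fs*26", TRUNCATION, 1247, "Q", ""),  # frameshift
        ("D53fs*11", TRUNCATION, 53, "D", ""),
        ("K100fs", TRUNCATION, 100, "K", ""),
        ("E746_A750delELREA", INDEL, 746, "ELREA", ""),  # in-frame deletion
        ("F113del", INDEL, 113, "F", ""),
        ("T155insDSTPPPGT", INDEL, 155, "T", "DSTPPPGT"),
        ("A10_C12delinsKK", INDEL, 10, "A", "KK"),
    ])
    def test_grammar(self, change, mclass, position, ref, alt):
        assert classify_change(change) == (mclass, position, ref, alt)

    @pytest.mark.parametrize("change", [
        "V600V",       # synonymous: not a missense event
        "c.1799T>A",   # nucleotide-level notation
        "X600E",       # non-standard reference residue
        "600E",
        "?",
        "V600Efs",     # malformed hybrid
    ])
    def test_unparseable_is_unclassified(self, change):
        assert classify_change(change)[0] == UNCLASSIFIED

    def test_every_parse_lands_in_one_class(self):
        # the partition property on a grab-bag of strings
        changes = ["V600E", "E813*", "Q1247fs*26", "F113del", "junk", "A1C",
                   "G12insAA", "M1_K3delinsW", "V600V"]
        for change in changes:
            mclass = classify_change(change)[0]
            assert mclass in (MISSENSE, TRUNCATION, INDEL, UNCLASSIFIED)

    def test_classify_mutation_keeps_source(self):
        record = make_mutation(change="V600E")
        mut = classify_mutation(record)
        assert mut.source is record and mut.mclass == MISSENSE


@settings(derandomize=True, max_examples=200)
@given(st.text(min_size=1, max_size=15))
def test_classifier_never_raises(change):
    mclass, pos, _, _ = classify_change(change)
    assert mclass in (MISSENSE, TRUNCATION, INDEL, UNCLASSIFIED)
    assert pos >= 0


class TestValidateReferences:
    def test_stale_reference_dropped_not_errored(self, tiny_proteome):
        # P1 position 2 is "A": "A2C" is fresh, "W2C" stale
        fresh = classify_mutation(make_mutation(change="A2C"))
        stale = classify_mutation(make_mutation(change="W2C"))
        beyond = classify_mutation(make_mutation(change="A999C"))
        kept, dropped = validate_references([fresh, stale, beyond], tiny_proteome)
        assert kept == [fresh]
        assert set(dropped) == {stale, beyond}

    def test_multi_residue_deletion_checked(self, tiny_proteome):
        seq = tiny_proteome["P1"].sequence
        good = f"{seq[9]}10_{seq[11]}12del{seq[9:12]}"
        bad = f"{seq[9]}10_{seq[11]}12delWWW"
        muts = [classify_mutation(make_mutation(change=c)) for c in (good, bad)]
        kept, dropped = validate_references(muts, tiny_proteome)
        assert len(kept) == 1 and len(dropped) == 1


class TestMapToDomains:
    def test_local_position_arithmetic(self):
        mut = classify_mutation(make_mutation(change="V600E"))
        inst = DomainInstance("P1", "Pkinase", 457, 717)
        (mapped,) = map_to_domains(mut, [inst])
        assert mapped.local_pos == 144  # 600 - 457 + 1

    def test_outside_all_instances_is_empty(self):
        mut = classify_mutation(make_mutation(change="A5C"))
        assert map_to_domains(mut, [DomainInstance("P1", "F", 10, 60)]) == []

    def test_boundary_maps_to_local_one(self):
        mut = classify_mutation(make_mutation(change="A10C"))
        (mapped,) = map_to_domains(mut, [DomainInstance("P1", "F", 10, 60)])
        assert mapped.local_pos == 1

    def test_overlapping_families_both_map(self):
        mut = classify_mutation(make_mutation(change="A55C"))
        instances = [DomainInstance("P1", "F1", 10, 60),
                     DomainInstance("P1", "F2", 50, 90)]
        assert {m.family_id for m in map_to_domains(mut, instances)} == {"F1", "F2"}

    def test_foreign_protein_instance_rejected(self):
        mut = classify_mutation(make_mutation(protein="P1", change="A55C"))
        with pytest.raises(ValueError):
            map_to_domains(mut, [DomainInstance("P2", "F", 10, 60)])


class TestMapToMsaColumn:
    @pytest.mark.parametrize("row,local,column", [
        ("A-CD", 2, 3),
        ("ACD-", 3, 3),
        ("-ACD", 1, 2),
    ])
    def test_gap_skipping(self, row, local, column):
        mapped = make_mapped(position=local, start=1, end=10)
        assert map_to_msa_column(mapped, row).msa_column == column

    def test_inconsistent_row_is_hard_error(self):
        mapped = make_mapped(position=2, start=1, end=10)
        with pytest.raises(ValueError, match="exceeds"):
            map_to_msa_column(mapped, "--A")


class TestAggregateColumns:
    def test_counts_conserve_totals(self):
        mapped = ([make_mapped(column=7) for _ in range(3)]
                  + [make_mapped(column=9)])
        counts = aggregate_columns(mapped)
        assert {(c.msa_column, c.k) for c in counts} == {(7, 3), (9, 1)}
        assert sum(c.k for c in counts) == len(mapped)

    def test_classes_counted_separately(self):
        mapped = [make_mapped(column=7, mclass=MISSENSE),
                  make_mapped(column=7, mclass=TRUNCATION)]
        counts = aggregate_columns(mapped)
        assert len(counts) == 2 and all(c.k == 1 for c in counts)

    def test_empty_input(self):
        assert aggregate_columns([]) == []

    def test_mixed_families_rejected(self):
        with pytest.raises(ValueError):
            aggregate_columns([make_mapped(family="A"), make_mapped(family="B")])

    @settings(derandomize=True, max_examples=50)
    @given(st.permutations(list(range(8))))
    def test_order_independent(self, order):
        base = [make_mapped(column=1 + i % 3, protein=f"P{i % 2}")
                for i in range(8)]
        expected = aggregate_columns(base)
        assert aggregate_columns([base[i] for i in order]) == expected
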