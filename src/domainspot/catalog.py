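"""Protein-change parsing, mutation classification and domain/MSA mapping.

Mutations are sorted into three classes:

* ``missense`` — single-residue substitutions, e.g. ``V600E``;
* ``truncation`` — stop gains (``E813*``) and frameshifts
  (``Q1247fs*26``), pooled because both abolish the downstream product;
* ``indel`` — in-frame insertions, deletions and delins, e.g.
  ``E746_A750delELREA``.

Anything outside this grammar is kept as ``unclassified`` and excluded
downstream (with a log entry). A multi-residue indel is anchored at its
FIRST affected residue for all positional counting.
"""

from __future__ import annotations

import logging
import re
from collections import defaultdict
from dataclasses import dataclass, replace

from .io import (
    GAP_CHARS,
    INDEL,
    MISSENSE,
    STANDARD_AA,
    TRUNCATION,
    UNCLASSIFIED,
    DomainInstance,
    FamilyMSA,
    MutationRecord,
)

logger = logging.getLogger("domainspot")

_AA = re.escape(STANDARD_AA)
_MISSENSE_RE = re.compile(rf"^([{_AA}])(\d+)([{_AA}])$")
_NONSENSE_RE = re.compile(rf"^([{_AA}])(\d+)\*$")
_FRAMESHIFT_RE = re.compile(rf"^([{_AA}])(\d+)fs(?:\*\d+)?$")
# In-frame notation; the optional _Ref2Pos2 range covers multi-residue events.
_DELINS_RE = re.compile(rf"^([{_AA}])(\d+)(?:_([{_AA}])(\d+))?delins([{_AA}]+)$")
_DEL_RE = re.compile(rf"^([{_AA}])(\d+)(?:_([{_AA}])(\d+))?del([{_AA}]*)$")
_INS_RE = re.compile(rf"^([{_AA}])(\d+)(?:_([{_AA}])(\d+))?ins([{_AA}]+)$")


@dataclass(frozen=True)
class ClassifiedMutation:
    """A parsed mutation; class and position come from the change string alone."""

    source: MutationRecord
    mclass: str
    position: int  # 1-based index of the (first) affected residue; 0 if unparsed
    ref_aa: str  # reference residue(s); empty for pure insertions
    alt_aa: str  # replacement; "*" for stop, empty for deletions

    @property
    def protein_accession(self) -> str:
        return self.source.protein_accession


@dataclass(frozen=True)
class MappedMutation:
    """A classified mutation located on one domain instance (and MSA column)."""

    mutation: ClassifiedMutation
    domain: DomainInstance
    local_pos: int  # position - domain.start + 1
    msa_column: int | None = None  # 1-based; None until aligned

    @property
    def family_id(self) -> str:
        return self.domain.family_id

    @property
    def mclass(self) -> str:
        return self.mutation.mclass


@dataclass(frozen=True)
class ColumnCount:
    """Aggregated same-class mutation count at one MSA column of a family."""

    family_id: str
    msa_column: int
    mclass: str
    k: int
    contributing_proteins: frozenset

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("ColumnCount requires k >= 1")


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def classify_change(change: str) -> tuple:
    """Parse a protein-change string to ``(mclass, position, ref, alt)``.

    Returns ``(UNCLASSIFIED, 0, "", "")`` for anything outside the
    grammar, including synonymous substitutions (ref == alt).
    """
    m = _MISSENSE_RE.match(change)
    if m:
        ref, pos, alt = m.group(1), int(m.group(2)), m.group(3)
        if ref == alt:  # synonymous: not a missense event
            return UNCLASSIFIED, 0, "", ""
        return MISSENSE, pos, ref, alt
    m = _NONSENSE_RE.match(change)
    if m:
        return TRUNCATION, int(m.group(2)), m.group(1), "*"
    m = _FRAMESHIFT_RE.match(change)
    if m:
        return TRUNCATION, int(m.group(2)), m.group(1), ""
    m = _DELINS_RE.match(change)
    if m:
        return INDEL, int(m.group(2)), m.group(1), m.group(5)
    m = _DEL_RE.match(change)
    if m:
        ref = m.group(5) or m.group(1)
        return INDEL, int(m.group(2)), ref, ""
    m = _INS_RE.match(change)
    if m:
        return INDEL, int(m.group(2)), m.group(1), m.group(5)
    return UNCLASSIFIED, 0, "", ""


def classify_mutation(record: MutationRecord) -> ClassifiedMutation:
    """Classify one mutation record; unparseable strings are logged."""
    mclass, pos, ref, alt = classify_change(record.change)
    if mclass == UNCLASSIFIED:
        logger.debug("unclassified change %r on %s", record.change,
                     record.protein_accession)
    return ClassifiedMutation(record, mclass, pos, ref, alt)


def classify_all(records) -> tuple:
    """Classify a catalog; returns ``(classified, n_unclassified)``."""
    out = [classify_mutation(r) for r in records]
    n_un = sum(1 for c in out if c.mclass == UNCLASSIFIED)
    if n_un:
        logger.info("%d of %d mutation records were unclassified", n_un, len(out))
    return out, n_un


def validate_references(mutations, proteome) -> tuple:
    """Drop mutations whose stated reference residue contradicts the proteome.

    Bulk catalogs carry stale records; these are dropped and logged, never
    errored. A mutation on a protein absent from the proteome, or at a
    position beyond its length, is dropped the same way. Unclassified
    mutations pass through untouched (they are filtered later anyway).
    """
    kept, dropped = [], []
    for mut in mutations:
        if mut.mclass == UNCLASSIFIED:
            kept.append(mut)
            continue
        protein = proteome.get(mut.protein_accession)
        if protein is None:
            dropped.append(mut)
            continue
        ref = mut.ref_aa
        start = mut.position
        if not ref:  # pure insertion: check the anchor residue only
            ref = mut.source.change[0]
        if start < 1 or start + len(ref) - 1 > len(protein):
            dropped.append(mut)
            continue
        if protein.sequence[start - 1 : start - 1 + len(ref)] != ref:
            dropped.append(mut)
            continue
        kept.append(mut)
    if dropped:
        logger.info("dropped %d mutations with stale reference residues",
                    len(dropped))
    return kept, dropped


# ---------------------------------------------------------------------------
# Mapping
# ---------------------------------------------------------------------------

def map_to_domains(mutation: ClassifiedMutation, instances) -> list:
    """Map a mutation to every instance whose span contains its position.

    A mutation inside overlapping instances of different families maps to
    each family independently; outside all instances the result is empty
    (counted as unmapped by the caller).
    """
    mapped = []
    for inst in instances:
        if inst.protein_accession != mutation.protein_accession:
            raise ValueError(
                f"instance {inst.key} does not belong to protein "
                f"{mutation.protein_accession}"
            )
        if inst.start <= mutation.position <= inst.end:
            mapped.append(MappedMutation(mutation, inst,
                                         mutation.position - inst.start + 1))
    return mapped


def map_to_msa_column(mapped: MappedMutation, msa_row: str) -> MappedMutation:
    """Attach the MSA column: index of the local_pos-th non-gap character."""
    seen = 0
    for col, char in enumerate(msa_row, 1):
        if char not in GAP_CHARS:
            seen += 1
            if seen == mapped.local_pos:
                return replace(mapped, msa_column=col)
    raise ValueError(
        f"local position {mapped.local_pos} exceeds the {seen} residues of "
        f"MSA row {mapped.domain.key}: alignment and domain table disagree"
    )


def map_catalog(mutations, instances, msas) -> tuple:
    """Map a classified catalog onto domains and MSA columns.

    Returns ``(mapped, unmapped_counts)`` where ``unmapped_counts`` is a
    per-class dict; ``#mapped-mutations + #unmapped = #classified`` holds
    per class (one mutation in overlapping families yields several
    MappedMutations but still counts once here).
    """
    by_protein = defaultdict(list)
    for inst in instances:
        by_protein[inst.protein_accession].append(inst)
    mapped_all = []
    unmapped = defaultdict(int)
    for mut in mutations:
        if mut.mclass == UNCLASSIFIED:
            continue
        hits = map_to_domains(mut, by_protein.get(mut.protein_accession, []))
        if not hits:
            unmapped[mut.mclass] += 1
            continue
        for hit in hits:
            msa = msas[hit.family_id]
            mapped_all.append(map_to_msa_column(hit, msa.rows[hit.domain.key]))
    return mapped_all, dict(unmapped)


def aggregate_columns(mapped_for_family) -> list:
    """Aggregate one family's mapped mutations into per-(column, class) counts.

    The sum of counts over columns equals the number of mapped mutations
    of each class; input order is irrelevant.
    """
    families = {m.family_id for m in mapped_for_family}
    if len(families) > 1:
        raise ValueError(f"mixed families in aggregation: {sorted(families)}")
    counts = defaultdict(int)
    contributors = defaultdict(set)
    for m in mapped_for_family:
        if m.msa_column is None:
            raise ValueError("mutation not yet mapped to an MSA column")
        key = (m.msa_column, m.mclass)
        counts[key] += 1
        contributors[key].add(m.mutation.protein_accession)
    family_id = families.pop() if families else ""
    return [
        ColumnCount(family_id, col, mclass, counts[(col, mclass)],
                    frozenset(contributors[(col, mclass)]))
        for col, mclass in sorted(counts)
    ]


def mapped_by_family(mapped) -> dict:
    """Group mapped mutations by family id."""
    grouped = defaultdict(list)
    for m in mapped:
        grouped[m.family_id].append(m)
    return dict(grouped)
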