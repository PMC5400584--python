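"""Input/output for the domain-hotspot pipeline.

Reads the five external inputs (proteome FASTA, domain-instance TSV,
mutation TSV, gene-class labels, per-family MSAs in aligned FASTA or
Stockholm) and writes all result tables. Coordinates are 1-based
inclusive everywhere: protein residues, domain boundaries and MSA
columns, matching the protein-change notation ("V600E" is residue 600).

MSA rows are keyed "accession/start-end" so one protein can contribute
several instances of the same family.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, fields

import pandas as pd
from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.Align import MultipleSeqAlignment

logger = logging.getLogger("domainspot")

#: 20 standard amino acids; "X" is tolerated in sequences but never in
#: protein-change strings.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
VALID_SEQUENCE_CHARS = frozenset(STANDARD_AA + "X")
GAP_CHARS = frozenset("-.")

#: Mutation classes, plus the sink for strings the grammar cannot parse.
MISSENSE = "missense"
TRUNCATION = "truncation"
INDEL = "indel"
UNCLASSIFIED = "unclassified"
MUTATION_CLASSES = (MISSENSE, TRUNCATION, INDEL)

#: Dataset names for the three analysis strata.
DATASETS = ("TS", "OG", "genome")

#: Gene-class labels. "both" marks genes annotated as tumour suppressor
#: and oncogene simultaneously; they enter both the TS and OG strata.
GENE_CLASSES = ("TS", "OG", "other", "both")

#: Fixed float format for every result table; %.12e keeps 13 significant
#: digits so a write/read round trip is lossless to 12 digits.
FLOAT_FORMAT = "%.12e"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence with a unique accession."""

    accession: str
    sequence: str

    def __post_init__(self):
        if len(self.sequence) == 0:
            raise ValueError(f"empty sequence for protein {self.accession!r}")
        bad = set(self.sequence) - VALID_SEQUENCE_CHARS
        if bad:
            raise ValueError(
                f"protein {self.accession!r} contains invalid characters {sorted(bad)}"
            )

    def __len__(self):
        return len(self.sequence)


@dataclass(frozen=True)
class DomainInstance:
    """One occurrence of a domain family on a protein, 1-based inclusive."""

    protein_accession: str
    family_id: str
    start: int
    end: int

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"invalid boundaries {self.start}-{self.end} for "
                f"{self.protein_accession}/{self.family_id}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def key(self) -> str:
        """MSA row key: ``accession/start-end``."""
        return f"{self.protein_accession}/{self.start}-{self.end}"

    def subsequence(self, protein: ProteinRecord) -> str:
        return protein.sequence[self.start - 1 : self.end]


@dataclass(frozen=True)
class MutationRecord:
    """One reported protein alteration in one patient sample."""

    sample_id: str
    protein_accession: str
    change: str
    cancer_type: str = ""

    def __post_init__(self):
        if not self.change:
            raise ValueError("empty protein-change string")


@dataclass
class FamilyMSA:
    """A family multiple sequence alignment; rows keyed accession/start-end."""

    family_id: str
    rows: dict  # key -> gapped sequence, all equal length

    def __post_init__(self):
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError(
                f"ragged MSA for family {self.family_id!r}: row lengths {sorted(lengths)}"
            )

    @property
    def length(self) -> int:
        """Number of alignment columns."""
        if not self.rows:
            return 0
        return len(next(iter(self.rows.values())))

    @staticmethod
    def ungap(row: str) -> str:
        return "".join(c for c in row if c not in GAP_CHARS)


@dataclass
class RunConfig:
    """Run-wide knobs; every source of randomness flows from ``seed``."""

    alpha: float = 0.05
    min_hotspot_count: int = 2
    background_family_count: int = 450
    seed: int = 0
    correction: str = "global"  # "global" or "per-family" Bonferroni
    aligner: str = "builtin"  # "builtin" or "external"
    proteome_path: str = "proteome.fasta"
    domains_path: str = "domains.tsv"
    mutations_path: str = "mutations.tsv"
    labels_path: str = "labels.tsv"
    msa_dir: str = "msa"
    out_dir: str = "results"

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")
        if self.min_hotspot_count < 2:
            raise ValueError(
                f"min_hotspot_count must be >= 2, got {self.min_hotspot_count}"
            )
        if self.correction not in ("global", "per-family"):
            raise ValueError(f"unknown correction mode {self.correction!r}")


def read_config(path: str, **overrides) -> RunConfig:
    """Read a flat ``key = value`` config file; keyword overrides win."""
    values = {}
    ints = {"min_hotspot_count", "background_family_count", "seed"}
    floats = {"alpha"}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key in ints:
                values[key] = int(value)
            elif key in floats:
                values[key] = float(value)
            else:
                values[key] = value
    known = {f.name for f in fields(RunConfig)}
    unknown = set(values) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    values.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**values)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_proteome(path: str) -> dict:
    """Read a proteome FASTA into ``{accession: ProteinRecord}``.

    The accession is the first whitespace-delimited token of the header;
    sequences are upper-cased. Duplicate accessions and empty sequences
    are hard errors.
    """
    proteome: dict[str, ProteinRecord] = {}
    for record in SeqIO.parse(path, "fasta"):
        accession = record.id
        if accession in proteome:
            raise ValueError(f"duplicate accession {accession!r} in {path}")
        proteome[accession] = ProteinRecord(accession, str(record.seq).upper())
    if not proteome:
        logger.warning("proteome file %s contains no records", path)
    return proteome


def read_domain_table(path: str, proteome: dict) -> list:
    """Read the 4-column domain-instance TSV, validated against the proteome.

    Columns: protein accession, family id, start, end (1-based inclusive).
    Out-of-bounds rows and overlapping instances of the same family on one
    protein are hard errors naming the offending row.
    """
    instances: list[DomainInstance] = []
    seen: dict[tuple, list] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[:4] == ["protein", "family", "start", "end"]:
                continue
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
            accession, family_id = parts[0], parts[1]
            start, end = int(parts[2]), int(parts[3])
            if accession not in proteome:
                raise ValueError(f"{path}:{lineno}: unknown protein {accession!r}")
            if start > end:
                raise ValueError(f"{path}:{lineno}: start {start} > end {end}")
            if end > len(proteome[accession]):
                raise ValueError(
                    f"{path}:{lineno}: end {end} exceeds length of {accession} "
                    f"({len(proteome[accession])})"
                )
            inst = DomainInstance(accession, family_id, start, end)
            for other in seen.setdefault((accession, family_id), []):
                if inst.start <= other.end and other.start <= inst.end:
                    raise ValueError(
                        f"{path}:{lineno}: instance {inst.key} overlaps {other.key} "
                        f"within family {family_id!r}"
                    )
            seen[(accession, family_id)].append(inst)
            instances.append(inst)
    if not instances:
        logger.warning("domain table %s is empty", path)
    return instances


def read_mutation_table(path: str) -> list:
    """Read the mutation TSV: sample id, protein accession, change, cancer type."""
    records: list[MutationRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "sample" and parts[1:2] == ["protein"]:
                continue
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 columns")
            cancer_type = parts[3] if len(parts) > 3 else ""
            records.append(MutationRecord(parts[0], parts[1], parts[2], cancer_type))
    return records


def read_gene_labels(path: str) -> dict:
    """Read the gene-class TSV (gene, class in {TS, OG, other, both})."""
    labels: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "gene":
                continue
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            gene, cls = parts[0], parts[1]
            if cls not in GENE_CLASSES:
                raise ValueError(f"{path}:{lineno}: unknown gene class {cls!r}")
            if gene in labels and labels[gene] != cls:
                raise ValueError(f"{path}:{lineno}: conflicting labels for {gene!r}")
            labels[gene] = cls
    return labels


def _msa_format(path: str) -> str:
    return "stockholm" if path.endswith((".sto", ".stk", ".stockholm")) else "fasta"


def read_msa(path: str, family_id: str | None = None,
             proteome: dict | None = None,
             instances: list | None = None) -> FamilyMSA:
    """Read one family MSA (aligned FASTA or Stockholm).

    Rows must be equal length and keyed ``accession/start-end``. When a
    proteome is supplied, each ungapped row must reproduce the
    corresponding domain subsequence; a mismatching row is a hard error
    naming the row.
    """
    if family_id is None:
        family_id = os.path.splitext(os.path.basename(path))[0]
    try:
        alignment = AlignIO.read(path, _msa_format(path))
    except ValueError as exc:
        raise ValueError(f"{path}: not a valid alignment ({exc})") from exc
    rows = {}
    for record in alignment:
        if record.id in rows:
            raise ValueError(f"{path}: duplicate MSA row {record.id!r}")
        rows[record.id] = str(record.seq).upper()
    msa = FamilyMSA(family_id, rows)
    if proteome is not None:
        for key, gapped in rows.items():
            try:
                accession, span = key.rsplit("/", 1)
                start_s, end_s = span.split("-")
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}: row id {key!r} is not accession/start-end") from exc
            if accession not in proteome:
                raise ValueError(f"{path}: row {key!r} references unknown protein")
            expected = proteome[accession].sequence[start - 1 : end]
            ungapped = FamilyMSA.ungap(gapped)
            if ungapped != expected:
                raise ValueError(
                    f"{path}: row {key!r} ungaps to {ungapped!r} but the proteome "
                    f"slice is {expected!r}"
                )
    return msa


def read_msa_dir(msa_dir: str, proteome: dict | None = None) -> dict:
    """Read every ``<family>.afa`` / ``.sto`` under a directory."""
    msas = {}
    for name in sorted(os.listdir(msa_dir)):
        if not name.endswith((".afa", ".fasta", ".fa", ".sto", ".stk")):
            continue
        family_id = os.path.splitext(name)[0]
        msas[family_id] = read_msa(os.path.join(msa_dir, name), family_id, proteome)
    return msas


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_msa(msa: FamilyMSA, path: str) -> None:
    """Write an MSA as aligned FASTA with deterministic row order."""
    records = [
        SeqRecord(Seq(msa.rows[key]), id=key, description="")
        for key in sorted(msa.rows)
    ]
    AlignIO.write(MultipleSeqAlignment(records), path, "fasta")


def write_table(frame: pd.DataFrame, path: str) -> None:
    """Write a result table as TSV: fixed column order, scientific floats.

    Writing the same frame twice produces byte-identical files; an empty
    frame yields a header-only file.
    """
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    frame.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT,
                 lineterminator="\n")


def read_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
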