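"""Synthetic cohort generator with planted, recoverable signal.

Emulates the five pipeline inputs at desk scale: a proteome whose
proteins are random linkers carrying domain instances, per-family TRUE
alignments (each family is built by mutating a random ancestor, so the
alignment is known by construction rather than re-estimated), gene-class
labels, and a mutation catalog with

* uniform per-residue background mutations at class-specific rates,
* planted mutationally enriched families (rate multipliers),
* planted hotspot columns receiving a fixed excess fraction of their
  family's same-class mutations, optionally restricted to one gene class,
* class-specific spectra: tumour-suppressor genes carry mostly dispersed
  truncations and missense (62% missense), oncogenes mostly missense
  (85%), matching the reported cohort composition.

Every emitted protein-change string is generated in the exact grammar
the parser accepts, with reference residues read from the simulated
proteome (an optional fraction of stale references exercises the
drop-and-log path). All randomness flows from ``SimulationSpec.seed``;
the same seed yields byte-identical output files.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field, asdict

import numpy as np

from .io import (
    INDEL,
    MISSENSE,
    MUTATION_CLASSES,
    STANDARD_AA,
    TRUNCATION,
    DomainInstance,
    FamilyMSA,
    MutationRecord,
    ProteinRecord,
    write_msa,
)

logger = logging.getLogger("domainspot")

_CANCER_TYPES = ("carcinoma", "melanoma", "glioma", "leukaemia", "sarcoma")


@dataclass(frozen=True)
class PlantedHotspot:
    family_id: str
    column: int  # 1-based ancestor column (pre-insertion coordinate)
    mclass: str
    gene_class: str | None  # restrict to hosts of this class; None = any
    excess: float  # fraction of the family's class mutations sent here

    def __post_init__(self):
        if not 0.0 < self.excess <= 1.0:
            raise ValueError(f"excess fraction must be in (0,1], got {self.excess}")


@dataclass(frozen=True)
class PlantedEnrichment:
    family_id: str
    mclass: str
    multiplier: float

    def __post_init__(self):
        if self.multiplier <= 0:
            raise ValueError("rate multiplier must be positive")


def _default_class_weights() -> dict:
    # Mutation-class mixture per gene class; TS/OG missense shares follow
    # the reported cohort composition (TS 62%, OG 85% missense).
    return {
        "TS": {MISSENSE: 0.62, TRUNCATION: 0.33, INDEL: 0.05},
        "OG": {MISSENSE: 0.85, TRUNCATION: 0.10, INDEL: 0.05},
        "other": {MISSENSE: 0.80, TRUNCATION: 0.15, INDEL: 0.05},
    }


def _default_family_classes() -> dict:
    classes = {}
    for i in range(1, 5):
        classes[f"FAM_{i:02d}"] = "TS"
    for i in range(5, 9):
        classes[f"FAM_{i:02d}"] = "OG"
    for i in range(9, 12):
        classes[f"FAM_{i:02d}"] = "other"
    classes["FAM_12"] = "shared"  # instances alternate between TS and OG hosts
    return classes


def _default_hotspots() -> list:
    return [
        PlantedHotspot("FAM_01", 14, TRUNCATION, "TS", 0.25),
        PlantedHotspot("FAM_02", 10, TRUNCATION, "TS", 0.25),
        PlantedHotspot("FAM_05", 20, MISSENSE, "OG", 0.30),
        PlantedHotspot("FAM_06", 12, MISSENSE, "OG", 0.30),
        PlantedHotspot("FAM_07", 8, INDEL, "OG", 0.30),
        # co-planted column: same family, same column, both strata
        PlantedHotspot("FAM_12", 17, MISSENSE, "TS", 0.25),
        PlantedHotspot("FAM_12", 17, MISSENSE, "OG", 0.25),
    ]


def _default_enrichments() -> list:
    return [
        PlantedEnrichment("FAM_01", TRUNCATION, 25.0),
        PlantedEnrichment("FAM_02", TRUNCATION, 25.0),
        PlantedEnrichment("FAM_05", MISSENSE, 25.0),
        PlantedEnrichment("FAM_06", MISSENSE, 25.0),
        PlantedEnrichment("FAM_07", INDEL, 60.0),
        PlantedEnrichment("FAM_12", MISSENSE, 25.0),
        # enriched-but-not-hotspotted families
        PlantedEnrichment("FAM_03", TRUNCATION, 10.0),
        PlantedEnrichment("FAM_08", MISSENSE, 10.0),
        PlantedEnrichment("FAM_09", MISSENSE, 10.0),
    ]


@dataclass
class SimulationSpec:
    """Full description of one synthetic cohort."""

    n_families: int = 12
    instances_per_family: tuple = (3, 6)
    domain_length: tuple = (40, 80)
    n_background_families: int = 450
    background_instances: tuple = (2, 4)
    n_ts: int = 30
    n_og: int = 30
    n_other: int = 900
    n_samples: int = 150
    base_rate: float = 2e-4  # total per residue per sample, split by class weights
    class_weights: dict = field(default_factory=_default_class_weights)
    linker_length: tuple = (10, 30)
    p_sub: float = 0.30  # per-column substitution probability per instance
    p_del: float = 0.02  # per-column deletion probability
    p_ins: float = 0.01  # per-column insertion probability
    max_insert: int = 3
    family_classes: dict = field(default_factory=_default_family_classes)
    planted_hotspots: list = field(default_factory=_default_hotspots)
    planted_enrichments: list = field(default_factory=_default_enrichments)
    stale_ref_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.base_rate < 0 or self.stale_ref_fraction < 0:
            raise ValueError("rates must be non-negative")
        if len(self.family_classes) != self.n_families:
            raise ValueError(
                f"family_classes covers {len(self.family_classes)} families "
                f"but n_families={self.n_families}"
            )
        for h in self.planted_hotspots:
            if h.family_id not in self.family_classes:
                raise ValueError(f"planted hotspot on unknown family {h.family_id!r}")
        lo = min(self.domain_length)
        for h in self.planted_hotspots:
            if not 1 <= h.column <= lo:
                raise ValueError(
                    f"planted column {h.column} may exceed the shortest domain ({lo})"
                )


@dataclass
class SyntheticTruth:
    """Ground-truth record for recovery testing."""

    hotspots: list = field(default_factory=list)  # dicts: family, msa_column, ...
    enriched: list = field(default_factory=list)
    gene_classes: dict = field(default_factory=dict)
    ancestor_to_msa: dict = field(default_factory=dict)  # family -> {anc: final}

    def hotspot_keys(self, dataset: str | None = None) -> set:
        return {
            (h["family"], h["msa_column"], h["mclass"])
            for h in self.hotspots
            if dataset is None or h["dataset"] == dataset or h["dataset"] == "genome"
        }


@dataclass
class SyntheticData:
    """In-memory bundle of everything the generator produces."""

    spec: SimulationSpec
    proteome: dict = field(default_factory=dict)
    instances: list = field(default_factory=list)
    msas: dict = field(default_factory=dict)
    labels: dict = field(default_factory=dict)
    mutations: list = field(default_factory=list)
    truth: SyntheticTruth = field(default_factory=SyntheticTruth)

    @property
    def families(self) -> dict:
        fams: dict[str, list] = {}
        for inst in self.instances:
            fams.setdefault(inst.family_id, []).append(inst)
        return fams

    @property
    def signal_families(self) -> dict:
        sig = set(self.spec.family_classes)
        return {f: i for f, i in self.families.items() if f in sig}

    @property
    def background_families(self) -> dict:
        sig = set(self.spec.family_classes)
        return {f: i for f, i in self.families.items() if f not in sig}


# ---------------------------------------------------------------------------
# Proteome + true alignments
# ---------------------------------------------------------------------------

def _random_seq(rng, length: int) -> str:
    return "".join(rng.choice(list(STANDARD_AA), size=length))

def _evolve_family(rng, spec: SimulationSpec, ancestor: str, n_inst: int):
    """Mutate an ancestor per instance; returns (rows, anc->final column map).

    Deletions leave gaps, substitutions swap residues, insertions open new
    columns shared across the family (gap-filled in other rows), so the
    returned rows form the family's true MSA.
    """
    l_anc = len(ancestor)
    per_inst = []
    for _ in range(n_inst):
        chars, inserts = [], []
        for col in range(l_anc):
            if rng.random() < spec.p_del:
                chars.append("-")
            elif rng.random() < spec.p_sub:
                alt = ancestor[col]
                while alt == ancestor[col]:
                    alt = rng.choice(list(STANDARD_AA))
                chars.append(str(alt))
            else:
                chars.append(ancestor[col])
            if rng.random() < spec.p_ins:
                inserts.append(_random_seq(rng, int(rng.integers(1, spec.max_insert + 1))))
            else:
                inserts.append("")
        per_inst.append((chars, inserts))
    max_ins = [max(len(pi[1][c]) for pi in per_inst) for c in range(l_anc)]
    anc_to_final = {}
    rows = ["" for _ in range(n_inst)]
    final_col = 0
    for col in range(l_anc):
        final_col += 1
        anc_to_final[col + 1] = final_col
        for r, (chars, inserts) in enumerate(per_inst):
            rows[r] += chars[col]
        for slot in range(max_ins[col]):
            final_col += 1
            for r, (chars, inserts) in enumerate(per_inst):
                ins = inserts[col]
                rows[r] += ins[slot] if slot < len(ins) else "-"
    return rows, anc_to_final


class _HostCycle:
    """Deterministic round-robin over a shuffled gene pool."""

    def __init__(self, rng, names):
        self.names = list(names)
        rng.shuffle(self.names)
        self.pos = 0

    def take(self, k: int) -> list:
        if k > len(self.names):
            raise ValueError("family needs more hosts than the gene pool holds")
        out = []
        for _ in range(k):
            out.append(self.names[self.pos % len(self.names)])
            self.pos += 1
        if len(set(out)) < k:  # wrapped inside one family: restart cleanly
            self.pos -= k
            out = self.names[: k]
            self.pos = k
        return out


def simulate_proteome(spec: SimulationSpec, rng=None) -> SyntheticData:
    """Generate the proteome, domain instances, true MSAs and gene labels."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    data = SyntheticData(spec)
    pools = {
        "TS": _HostCycle(rng, [f"TS_{i:04d}" for i in range(1, spec.n_ts + 1)]),
        "OG": _HostCycle(rng, [f"OG_{i:04d}" for i in range(1, spec.n_og + 1)]),
        "other": _HostCycle(rng, [f"GEN_{i:04d}" for i in range(1, spec.n_other + 1)]),
    }
    family_ids = sorted(spec.family_classes) + [
        f"BG_{i:03d}" for i in range(1, spec.n_background_families + 1)
    ]
    # gene -> ordered list of (family, row_index, ungapped sequence)
    cargo: dict[str, list] = {}
    pending_rows: dict[str, list] = {}  # family -> gapped rows (key fixed later)
    host_of: dict[str, list] = {}  # family -> host gene per row
    for family_id in family_ids:
        gene_class = spec.family_classes.get(family_id, "other")
        if family_id.startswith("BG_"):
            lo, hi = spec.background_instances
        else:
            lo, hi = spec.instances_per_family
        n_inst = int(rng.integers(lo, hi + 1))
        length = int(rng.integers(spec.domain_length[0], spec.domain_length[1] + 1))
        ancestor = _random_seq(rng, length)
        rows, anc_map = _evolve_family(rng, spec, ancestor, n_inst)
        data.truth.ancestor_to_msa[family_id] = anc_map
        if gene_class == "shared":
            hosts = []
            for r in range(n_inst):
                hosts.extend(pools["TS" if r % 2 == 0 else "OG"].take(1))
        else:
            hosts = pools[gene_class].take(n_inst)
        pending_rows[family_id] = rows
        host_of[family_id] = hosts
        for r, host in enumerate(hosts):
            cargo.setdefault(host, []).append((family_id, r, FamilyMSA.ungap(rows[r])))
    # lay proteins out: linker + domain + linker + ...
    row_keys: dict[tuple, str] = {}
    for gene in sorted(cargo):
        pieces, pos = [], 0
        for family_id, r, seq in cargo[gene]:
            linker = _random_seq(rng, int(rng.integers(*spec.linker_length)))
            pieces.append(linker)
            pos += len(linker)
            start, end = pos + 1, pos + len(seq)
            pieces.append(seq)
            pos = end
            data.instances.append(DomainInstance(gene, family_id, start, end))
            row_keys[(family_id, r)] = f"{gene}/{start}-{end}"
        pieces.append(_random_seq(rng, int(rng.integers(*spec.linker_length))))
        data.proteome[gene] = ProteinRecord(gene, "".join(pieces))
    for family_id, rows in pending_rows.items():
        data.msas[family_id] = FamilyMSA(
            family_id, {row_keys[(family_id, r)]: row for r, row in enumerate(rows)}
        )
    for gene in sorted(data.proteome):
        data.labels[gene] = gene.split("_")[0] if gene.split("_")[0] in ("TS", "OG") else "other"
    data.truth.gene_classes = dict(data.labels)
    return data


# ---------------------------------------------------------------------------
# Mutations
# ---------------------------------------------------------------------------

def _make_change(rng, seq: str, pos: int, mclass: str, stale: bool) -> str:
    ref = seq[pos - 1]
    if stale:
        wrong = ref
        while wrong == ref:
            wrong = str(rng.choice(list(STANDARD_AA)))
        ref = wrong
    if mclass == MISSENSE:
        alt = ref
        while alt == seq[pos - 1] or alt == ref:
            alt = str(rng.choice(list(STANDARD_AA)))
        return f"{ref}{pos}{alt}"
    if mclass == TRUNCATION:
        if rng.random() < 0.5:
            return f"{ref}{pos}*"
        return f"{ref}{pos}fs*{int(rng.integers(1, 50))}"
    # in-frame indel, anchored at its first affected residue
    u = rng.random()
    if u < 0.55:  # deletion
        dlen = int(rng.integers(1, 4))
        end = min(pos + dlen - 1, len(seq))
        if end == pos:
            return f"{ref}{pos}del"
        return f"{ref}{pos}_{seq[end - 1]}{end}del{ref}{seq[pos:end]}"
    if u < 0.85:  # insertion after pos
        ins = _random_seq(rng, int(rng.integers(1, 4)))
        return f"{ref}{pos}ins{ins}"
    dlen = int(rng.integers(1, 4))  # delins
    end = min(pos + dlen - 1, len(seq))
    new = _random_seq(rng, int(rng.integers(1, 4)))
    if end == pos:
        return f"{ref}{pos}delins{new}"
    return f"{ref}{pos}_{seq[end - 1]}{end}delins{new}"


def _column_residue(row: str, column: int) -> int | None:
    """Local (1-based) residue index aligned to an MSA column; None if gap."""
    if row[column - 1] in "-.":
        return None
    return sum(1 for c in row[:column] if c not in "-.")


def simulate_mutations(spec: SimulationSpec, data: SyntheticData, rng=None) -> list:
    """Draw the mutation catalog; fills ``data.mutations`` and the truth table.

    Per instance and class the background count is Poisson with mean
    rate x multiplier x length x samples; each drawn mutation is diverted
    to a planted hotspot column with probability equal to the hotspot's
    excess fraction (when its instance is eligible), otherwise placed
    uniformly. Linker residues mutate at the plain background rate and
    become the unmapped fraction.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed + 1)
    multipliers = {
        (e.family_id, e.mclass): e.multiplier for e in spec.planted_enrichments
    }
    hotspots_by_family: dict[tuple, list] = {}
    for h in spec.planted_hotspots:
        hotspots_by_family.setdefault((h.family_id, h.mclass), []).append(h)
    mutations: list[MutationRecord] = []

    def emit(gene: str, pos: int, mclass: str) -> None:
        seq = data.proteome[gene].sequence
        stale = spec.stale_ref_fraction > 0 and rng.random() < spec.stale_ref_fraction
        change = _make_change(rng, seq, pos, mclass, stale)
        sample = f"S{int(rng.integers(1, spec.n_samples + 1)):05d}"
        cancer = str(rng.choice(_CANCER_TYPES))
        mutations.append(MutationRecord(sample, gene, change, cancer))

    families = data.families
    for family_id in sorted(families):
        insts = families[family_id]
        msa = data.msas[family_id]
        anc_map = data.truth.ancestor_to_msa[family_id]
        for mclass in MUTATION_CLASSES:
            mult = multipliers.get((family_id, mclass), 1.0)
            planted = hotspots_by_family.get((family_id, mclass), [])
            # eligibility and target residues per hotspot
            targets = []
            for h in planted:
                col = anc_map[h.column]
                eligible = {}
                for inst in insts:
                    if h.gene_class is not None and \
                            data.labels[inst.protein_accession] != h.gene_class:
                        continue
                    local = _column_residue(msa.rows[inst.key], col)
                    if local is not None:
                        eligible[inst.key] = local
                if not eligible:
                    raise ValueError(
                        f"planted hotspot {family_id}:{h.column} ({h.mclass}) "
                        "is aligned to gaps in all eligible instances"
                    )
                targets.append((h, col, eligible))
            for inst in insts:
                gclass = data.labels[inst.protein_accession]
                weight = spec.class_weights[gclass][mclass]
                lam = spec.base_rate * weight * mult * inst.length * spec.n_samples
                count = int(rng.poisson(lam)) if lam > 0 else 0
                for _ in range(count):
                    placed = False
                    for h, col, eligible in targets:
                        if inst.key in eligible and rng.random() < h.excess:
                            local = eligible[inst.key]
                            emit(inst.protein_accession,
                                 inst.start + local - 1, mclass)
                            placed = True
                            break
                    if not placed:
                        local = int(rng.integers(1, inst.length + 1))
                        emit(inst.protein_accession, inst.start + local - 1, mclass)
    # linker background: the unmapped fraction
    covered: dict[str, set] = {}
    for inst in data.instances:
        covered.setdefault(inst.protein_accession, set()).update(
            range(inst.start, inst.end + 1))
    for gene in sorted(data.proteome):
        linker = sorted(set(range(1, len(data.proteome[gene]) + 1))
                        - covered.get(gene, set()))
        if not linker:
            continue
        gclass = data.labels[gene]
        for mclass in MUTATION_CLASSES:
            lam = (spec.base_rate * spec.class_weights[gclass][mclass]
                   * len(linker) * spec.n_samples)
            count = int(rng.poisson(lam)) if lam > 0 else 0
            for _ in range(count):
                emit(gene, int(rng.choice(linker)), mclass)
    data.mutations = mutations
    data.truth.hotspots = [
        {"family": h.family_id,
         "msa_column": data.truth.ancestor_to_msa[h.family_id][h.column],
         "mclass": h.mclass,
         "dataset": h.gene_class if h.gene_class in ("TS", "OG") else "genome",
         "excess": h.excess}
        for h in spec.planted_hotspots
    ]
    data.truth.enriched = [
        {"family": e.family_id, "mclass": e.mclass, "multiplier": e.multiplier}
        for e in spec.planted_enrichments
    ]
    return mutations


def simulate(spec: SimulationSpec | None = None) -> SyntheticData:
    """Generate a complete synthetic cohort from one seed."""
    spec = spec if spec is not None else SimulationSpec()
    rng = np.random.default_rng(spec.seed)
    data = simulate_proteome(spec, rng)
    simulate_mutations(spec, data, rng)
    return data


# ---------------------------------------------------------------------------
# File emission
# ---------------------------------------------------------------------------

def write_synthetic(data: SyntheticData, out_dir: str) -> dict:
    """Write the five standard input files plus truth.json; returns paths."""
    os.makedirs(out_dir, exist_ok=True)
    msa_dir = os.path.join(out_dir, "msa")
    os.makedirs(msa_dir, exist_ok=True)
    paths = {
        "proteome": os.path.join(out_dir, "proteome.fasta"),
        "domains": os.path.join(out_dir, "domains.tsv"),
        "mutations": os.path.join(out_dir, "mutations.tsv"),
        "labels": os.path.join(out_dir, "labels.tsv"),
        "msa_dir": msa_dir,
        "truth": os.path.join(out_dir, "truth.json"),
    }
    with open(paths["proteome"], "w") as fh:
        for gene in sorted(data.proteome):
            seq = data.proteome[gene].sequence
            fh.write(f">{gene}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    with open(paths["domains"], "w") as fh:
        fh.write("protein\tfamily\tstart\tend\n")
        for inst in sorted(data.instances,
                           key=lambda i: (i.protein_accession, i.start)):
            fh.write(f"{inst.protein_accession}\t{inst.family_id}"
                     f"\t{inst.start}\t{inst.end}\n")
    with open(paths["mutations"], "w") as fh:
        fh.write("sample\tprotein\tchange\tcancer_type\n")
        for m in data.mutations:
            fh.write(f"{m.sample_id}\t{m.protein_accession}\t{m.change}"
                     f"\t{m.cancer_type}\n")
    with open(paths["labels"], "w") as fh:
        fh.write("gene\tclass\n")
        for gene in sorted(data.labels):
            fh.write(f"{gene}\t{data.labels[gene]}\n")
    for family_id in sorted(data.msas):
        write_msa(data.msas[family_id], os.path.join(msa_dir, f"{family_id}.afa"))
    with open(paths["truth"], "w") as fh:
        json.dump(
            {"hotspots": data.truth.hotspots,
             "enriched": data.truth.enriched,
             "gene_classes": data.truth.gene_classes,
             "ancestor_to_msa": data.truth.ancestor_to_msa},
            fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths
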