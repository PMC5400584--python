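"""MSA-column hotspot detection by a binomial tail test.

Under the null, each of a family's n same-class mutations lands on any
of the L alignment columns with equal probability p = 1/L, so the count
k at one column is Binomial(n, p) and a column's tail probability is

    P(X >= k) = sum_{i=k..n} C(n, i) p^i (1-p)^(n-i).

Only columns with at least ``min_hotspot_count`` (default 2) mutations
of one class are tested; the surviving tests are Bonferroni-corrected,
by default over all tested (family, column) pairs of the dataset-class
run ("global"), optionally per family. Tumour suppressors, oncogenes
and the whole gene set are analysed as separate datasets, and the three
mutation classes are always tested independently.

The module also carries a self-contained progressive aligner (pairwise
identity distances, average-linkage guide tree, BLOSUM62 profile-profile
merge) so families distributed as raw sequences can be aligned without
an external binary; precomputed MSAs bypass it entirely.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom
from Bio.Align import PairwiseAligner, substitution_matrices

from .catalog import ColumnCount, aggregate_columns, mapped_by_family
from .io import GAP_CHARS, MUTATION_CLASSES, STANDARD_AA, FamilyMSA

logger = logging.getLogger("domainspot")


@dataclass(frozen=True)
class HotspotTest:
    """One tested (family, MSA column, class) position."""

    family_id: str
    msa_column: int
    mclass: str
    n: int  # total same-class mutations mapped anywhere in the family
    k: int  # mutations at this column
    p: float  # per-column null probability, 1/L
    p_value: float
    p_corrected: float
    significant: bool
    contributing_proteins: frozenset = frozenset()

    @property
    def key(self) -> tuple:
        return (self.family_id, self.msa_column)


@dataclass
class HotspotAnalysis:
    """Results of one dataset-class run."""

    dataset: str
    mclass: str
    tests: list  # HotspotTest, one per tested column
    recorded_hotspots: int  # columns carrying >= min_hotspot_count mutations

    @property
    def significant(self) -> list:
        return [t for t in self.tests if t.significant]


# ---------------------------------------------------------------------------
# Binomial tail
# ---------------------------------------------------------------------------

def binomial_tail(n: int, k: int, p: float) -> float:
    """Upper-tail probability P(X >= k) for X ~ Binomial(n, p).

    Evaluated through the regularised survival function, which is stable
    for large n and tiny tails; k = 0 returns exactly 1.
    """
    if not 0 < p < 1:
        raise ValueError(f"p must be in (0,1), got {p}")
    if not 0 <= k <= n:
        raise ValueError(f"require 0 <= k <= n, got k={k}, n={n}")
    if k == 0:
        return 1.0
    return float(binom.sf(k - 1, n, p))


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------

def detect_hotspots(column_counts, msa_length: int, mclass: str, alpha: float,
                    m_total: int | None = None, min_count: int = 2) -> list:
    """Test one family's columns of one class.

    ``column_counts`` are all of the family's per-column counts for
    ``mclass`` (including singletons, which contribute to n but are never
    tested). ``m_total`` is the Bonferroni divisor of the surrounding
    dataset-class run; when None, the family's own number of tested
    columns is used (per-family correction).
    """
    if msa_length < 1:
        raise ValueError("MSA length must be >= 1")
    counts = [c for c in column_counts if c.mclass == mclass]
    if any(c.mclass != mclass for c in column_counts):
        raise ValueError("column_counts contain a foreign mutation class")
    n = sum(c.k for c in counts)
    tested = [c for c in counts if c.k >= min_count]
    if not tested:
        return []
    m = m_total if m_total is not None else len(tested)
    p_null = 1.0 / msa_length
    results = []
    for c in sorted(tested, key=lambda c: c.msa_column):
        if c.k > n:
            raise ValueError(f"column count {c.k} exceeds family total {n}")
        p_value = binomial_tail(n, c.k, p_null)
        p_corr = min(1.0, p_value * m)
        results.append(HotspotTest(
            c.family_id, c.msa_column, mclass, n, c.k, p_null, p_value,
            p_corr, significant=bool(p_corr < alpha),
            contributing_proteins=c.contributing_proteins,
        ))
    return results


def scan_hotspots(mapped, msa_lengths: dict, mclass: str, alpha: float = 0.05,
                  min_count: int = 2, correction: str = "global") -> list:
    """Hotspot tests over all families for one mutation class.

    Two passes: the >=min_count filter first fixes the set of tested
    positions, then Bonferroni m is either the global count of tested
    (family, column) pairs or, with ``correction="per-family"``, each
    family's own count.
    """
    per_family = {}
    for family_id, muts in mapped_by_family(mapped).items():
        counts = [c for c in aggregate_columns(muts) if c.mclass == mclass]
        if counts:
            per_family[family_id] = counts
    if correction == "global":
        m_total = sum(
            sum(1 for c in counts if c.k >= min_count)
            for counts in per_family.values()
        )
        if m_total == 0:
            return []
    elif correction == "per-family":
        m_total = None
    else:
        raise ValueError(f"unknown correction mode {correction!r}")
    tests = []
    for family_id in sorted(per_family):
        tests.extend(detect_hotspots(
            per_family[family_id], msa_lengths[family_id], mclass, alpha,
            m_total=m_total, min_count=min_count,
        ))
    return tests


def run_hotspot_analysis(mapped, msa_lengths: dict, gene_labels: dict,
                         mclass: str, alpha: float = 0.05, min_count: int = 2,
                         correction: str = "global") -> dict:
    """Run the three dataset strata (TS, OG, whole genome) for one class.

    The TS stratum keeps mutations on proteins labelled TS (or both),
    the OG stratum those labelled OG (or both); the whole-genome stratum
    ignores labels entirely.
    """
    def in_dataset(m, dataset):
        if dataset == "genome":
            return True
        label = gene_labels.get(m.mutation.protein_accession, "other")
        return label == dataset or label == "both"

    analyses = {}
    for dataset in ("TS", "OG", "genome"):
        subset = [m for m in mapped if m.mclass == mclass and in_dataset(m, dataset)]
        tests = scan_hotspots(subset, msa_lengths, mclass, alpha, min_count,
                              correction)
        analyses[dataset] = HotspotAnalysis(dataset, mclass, tests, len(tests))
    return analyses


def hotspot_frame(tests) -> pd.DataFrame:
    columns = ["family", "msa_column", "mclass", "n", "k", "p_null",
               "p_value", "p_corrected", "significant", "proteins"]
    rows = [
        [t.family_id, t.msa_column, t.mclass, t.n, t.k, t.p, t.p_value,
         t.p_corrected, t.significant, ";".join(sorted(t.contributing_proteins))]
        for t in sorted(tests, key=lambda t: (t.p_value, t.family_id, t.msa_column))
    ]
    return pd.DataFrame(rows, columns=columns)


def summary_frame(analyses_by_class: dict) -> pd.DataFrame:
    """Per-dataset, per-class recorded and significant hotspot counts."""
    rows = []
    for dataset in ("TS", "OG", "genome"):
        for mclass in MUTATION_CLASSES:
            analysis = analyses_by_class.get(mclass, {}).get(dataset)
            if analysis is None:
                rows.append([dataset, mclass, 0, 0])
            else:
                rows.append([dataset, mclass, analysis.recorded_hotspots,
                             len(analysis.significant)])
    return pd.DataFrame(rows, columns=["dataset", "mclass", "recorded_hotspots",
                                       "significant_hotspots"])


# ---------------------------------------------------------------------------
# Built-in progressive aligner
# ---------------------------------------------------------------------------

_ALPHABET = STANDARD_AA + "X-"
_GAP_INDEX = len(_ALPHABET) - 1
_GAP_SCORE = -4.0  # residue against gap inside a profile column
_GAP_OPEN = -6.0  # inserting an all-gap column during a profile merge


def _score_matrix() -> np.ndarray:
    blosum = substitution_matrices.load("BLOSUM62")
    m = np.zeros((len(_ALPHABET), len(_ALPHABET)))
    for i, a in enumerate(_ALPHABET):
        for j, b in enumerate(_ALPHABET):
            if a == "-" and b == "-":
                m[i, j] = 0.0
            elif a == "-" or b == "-":
                m[i, j] = _GAP_SCORE
            else:
                m[i, j] = blosum[a, b]
    return m


_M = _score_matrix()


def _profile_counts(rows) -> np.ndarray:
    """Column x alphabet count matrix of a gapped profile."""
    index = {c: i for i, c in enumerate(_ALPHABET)}
    length = len(rows[0])
    counts = np.zeros((length, len(_ALPHABET)))
    for row in rows:
        for col, char in enumerate(row):
            counts[col, index["-" if char in GAP_CHARS else char]] += 1
    return counts


def _profile_align(rows_a, rows_b) -> tuple:
    """Globally align two profiles; returns the two gapped row lists."""
    ca, cb = _profile_counts(rows_a), _profile_counts(rows_b)
    la, lb = ca.shape[0], cb.shape[0]
    norm = len(rows_a) * len(rows_b)
    score = (ca @ _M @ cb.T) / norm
    h = np.full((la + 1, lb + 1), -np.inf)
    back = np.zeros((la + 1, lb + 1), dtype=np.int8)  # 0 diag, 1 up, 2 left
    h[0, 0] = 0.0
    for i in range(1, la + 1):
        h[i, 0] = i * _GAP_OPEN
        back[i, 0] = 1
    for j in range(1, lb + 1):
        h[0, j] = j * _GAP_OPEN
        back[0, j] = 2
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            diag = h[i - 1, j - 1] + score[i - 1, j - 1]
            up = h[i - 1, j] + _GAP_OPEN
            left = h[i, j - 1] + _GAP_OPEN
            # deterministic tie-break: diagonal, then up, then left
            best, move = diag, 0
            if up > best:
                best, move = up, 1
            if left > best:
                best, move = left, 2
            h[i, j], back[i, j] = best, move
    # traceback
    path = []
    i, j = la, lb
    while i > 0 or j > 0:
        move = back[i, j]
        path.append(move)
        if move == 0:
            i, j = i - 1, j - 1
        elif move == 1:
            i -= 1
        else:
            j -= 1
    path.reverse()
    out_a = [[] for _ in rows_a]
    out_b = [[] for _ in rows_b]
    i = j = 0
    for move in path:
        if move in (0, 1):
            for r, row in enumerate(rows_a):
                out_a[r].append(row[i])
            i += 1
        else:
            for r in range(len(rows_a)):
                out_a[r].append("-")
        if move in (0, 2):
            for r, row in enumerate(rows_b):
                out_b[r].append(row[j])
            j += 1
        else:
            for r in range(len(rows_b)):
                out_b[r].append("-")
    return ["".join(r) for r in out_a], ["".join(r) for r in out_b]


def _identity_distance(seq_a: str, seq_b: str, aligner: PairwiseAligner) -> float:
    alignment = aligner.align(seq_a, seq_b)[0]
    a, b = str(alignment[0]), str(alignment[1])
    matches = sum(1 for x, y in zip(a, b) if x == y and x != "-")
    return 1.0 - matches / max(len(a), 1)


def align_family(sequences: dict, family_id: str = "") -> FamilyMSA:
    """Progressively align a family's domain sequences.

    Pairwise global alignments (BLOSUM62) give an identity distance
    matrix; an average-linkage guide tree orders the profile merges. A
    singleton family yields the trivial one-row alignment. The output is
    a valid MSA (equal row lengths, rows ungap to their inputs); column-
    level agreement with any particular external aligner is not promised.
    """
    if not sequences:
        raise ValueError("cannot align an empty family")
    keys = sorted(sequences)
    if len(keys) == 1:
        return FamilyMSA(family_id, {keys[0]: sequences[keys[0]]})
    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    aligner.mode = "global"
    n = len(keys)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = _identity_distance(sequences[keys[i]], sequences[keys[j]], aligner)
            dist[i, j] = dist[j, i] = d
    from scipy.cluster.hierarchy import linkage
    from scipy.spatial.distance import squareform
    merges = linkage(squareform(dist, checks=False), method="average")
    # clusters: id -> (row keys, gapped rows)
    clusters = {i: ([keys[i]], [sequences[keys[i]]]) for i in range(n)}
    next_id = n
    for a_id, b_id, _, _ in merges:
        keys_a, rows_a = clusters.pop(int(a_id))
        keys_b, rows_b = clusters.pop(int(b_id))
        merged_a, merged_b = _profile_align(rows_a, rows_b)
        clusters[next_id] = (keys_a + keys_b, merged_a + merged_b)
        next_id += 1
    (final_keys, final_rows), = clusters.values()
    return FamilyMSA(family_id, dict(zip(final_keys, final_rows)))
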