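"""Tumour-suppressor vs oncogene classification.

Two complementary routes:

* the 20:20 rule — within a cohort, a gene with >= 20% truncating
  mutations is called a tumour suppressor; a gene where >= 20% of its
  missense mutations recur at one protein position is called an
  oncogene (both can hold at once);
* a cross-validated classifier on domain composition — a gene x family
  matrix of domain-instance counts, stratified k-fold cross-validation
  with a pluggable binary scorer (default: a linear maximum-margin
  classifier), and ROC AUC pooled over held-out folds via the
  Mann-Whitney rank formulation (ties count 1/2).

Recurrence for the 20:20 rule is counted at protein positions, not MSA
columns, because the rule is defined on the gene's own sequence.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .io import MISSENSE, TRUNCATION, UNCLASSIFIED

logger = logging.getLogger("domainspot")


@dataclass(frozen=True)
class GeneMutationProfile:
    gene: str
    total_mutations: int
    truncation_fraction: float
    max_missense_fraction: float  # largest share of missense at one position

    def __post_init__(self):
        for f in (self.truncation_fraction, self.max_missense_fraction):
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"fraction out of [0,1]: {f}")


@dataclass
class ClassifierReport:
    fold_aucs: list
    pooled_auc: float
    scores: pd.DataFrame  # gene, label, raw_score, fold
    fold_assignment: dict  # gene -> fold index
    trap_auc: float = field(default=float("nan"))  # trapezoidal cross-check


# ---------------------------------------------------------------------------
# 20:20 rule
# ---------------------------------------------------------------------------

def gene_profiles(classified_mutations) -> list:
    """Build per-gene mutational profiles from a classified catalog."""
    totals = Counter()
    truncations = Counter()
    missense_positions = defaultdict(Counter)
    for mut in classified_mutations:
        if mut.mclass == UNCLASSIFIED:
            continue
        gene = mut.protein_accession
        totals[gene] += 1
        if mut.mclass == TRUNCATION:
            truncations[gene] += 1
        elif mut.mclass == MISSENSE:
            missense_positions[gene][mut.position] += 1
    profiles = []
    for gene in sorted(totals):
        n_missense = sum(missense_positions[gene].values())
        max_at_one = (max(missense_positions[gene].values()) / n_missense
                      if n_missense else 0.0)
        profiles.append(GeneMutationProfile(
            gene, totals[gene], truncations[gene] / totals[gene], max_at_one))
    return profiles


def twenty_twenty(profile: GeneMutationProfile, threshold: float = 0.20) -> str:
    """Apply the 20:20 rule: returns "TS", "OG", "both" or "neither"."""
    if profile.total_mutations < 1:
        logger.warning("gene %s has no mutations; 20:20 undefined", profile.gene)
        return "neither"
    is_ts = profile.truncation_fraction >= threshold
    is_og = profile.max_missense_fraction >= threshold
    if is_ts and is_og:
        return "both"
    if is_ts:
        return "TS"
    if is_og:
        return "OG"
    return "neither"


def twenty_twenty_frame(profiles, threshold: float = 0.20) -> pd.DataFrame:
    rows = [
        [p.gene, p.total_mutations, p.truncation_fraction,
         p.max_missense_fraction, twenty_twenty(p, threshold)]
        for p in profiles
    ]
    return pd.DataFrame(rows, columns=["gene", "total_mutations",
                                       "truncation_fraction",
                                       "max_missense_fraction", "call"])


# ---------------------------------------------------------------------------
# Domain-composition classifier
# ---------------------------------------------------------------------------

def build_feature_matrix(genes, domain_instances, binary: bool = False
                         ) -> pd.DataFrame:
    """Gene x family matrix of domain-instance counts.

    The column set is the union of families over the given genes; a gene
    with no domains keeps an all-zero row (logged). ``binary=True``
    switches cells to presence flags.
    """
    genes = sorted(genes)
    gene_set = set(genes)
    counts = defaultdict(Counter)
    families = set()
    for inst in domain_instances:
        if inst.protein_accession in gene_set:
            counts[inst.protein_accession][inst.family_id] += 1
            families.add(inst.family_id)
    families = sorted(families)
    matrix = pd.DataFrame(0, index=genes, columns=families, dtype=int)
    for gene, fam_counts in counts.items():
        for fam, k in fam_counts.items():
            matrix.loc[gene, fam] = k
    empty = [g for g in genes if g not in counts]
    if empty:
        logger.info("%d genes have no domain instances (zero feature rows)",
                    len(empty))
    if binary:
        matrix = (matrix > 0).astype(int)
    return matrix


def rank_auc(scores, labels) -> float:
    """ROC AUC by the Mann-Whitney rank statistic; tied scores count 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("AUC needs both classes present")
    wins = 0.0
    for s in pos:
        wins += np.sum(s > neg) + 0.5 * np.sum(s == neg)
    return float(wins / (len(pos) * len(neg)))


def default_learner():
    """Linear maximum-margin classifier (deterministic for fixed inputs)."""
    return SVC(kernel="linear", C=1.0)


def _score(model, X) -> np.ndarray:
    if hasattr(model, "decision_function"):
        return np.asarray(model.decision_function(X), dtype=float)
    if hasattr(model, "predict_proba"):
        return np.asarray(model.predict_proba(X)[:, 1], dtype=float)
    raise TypeError("learner exposes neither decision_function nor predict_proba")


def cross_validate(matrix: pd.DataFrame, labels: dict, k_folds: int = 10,
                   learner_factory=default_learner, seed: int = 0
                   ) -> ClassifierReport:
    """Stratified k-fold CV of TS-vs-OG on domain composition.

    ``labels`` maps gene -> "TS"/"OG"; genes labelled anything else
    (including "both") are excluded from training, mirroring the separate
    treatment of dual-annotated genes. Scores are oriented so higher
    means more TS-like. The pooled AUC uses the rank formulation; the
    trapezoidal ROC integral on the same scores is recorded as an
    internal consistency check.
    """
    genes = [g for g in matrix.index if labels.get(g) in ("TS", "OG")]
    y = np.array([1 if labels[g] == "TS" else 0 for g in genes])
    for cls, name in ((1, "TS"), (0, "OG")):
        if np.sum(y == cls) < k_folds:
            raise ValueError(
                f"need >= {k_folds} {name}-labelled genes, got {np.sum(y == cls)}"
            )
    X = matrix.loc[genes].to_numpy(dtype=float)
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    fold_aucs, records = [], []
    fold_assignment = {}
    from scipy.stats import rankdata
    for fold, (train_idx, test_idx) in enumerate(skf.split(X, y)):
        model = learner_factory()
        model.fit(X[train_idx], y[train_idx])
        raw = _score(model, X[test_idx])
        fold_aucs.append(rank_auc(raw, y[test_idx]))
        # raw decision values are not comparable across folds (each model
        # has its own scale), so pool within-fold mid-ranks instead
        norm = rankdata(raw, method="average") / (len(raw) + 1)
        for i, idx in enumerate(test_idx):
            fold_assignment[genes[idx]] = fold
            records.append([genes[idx], "TS" if y[idx] == 1 else "OG",
                            raw[i], norm[i], fold])
    scores = pd.DataFrame(records, columns=["gene", "label", "raw_score",
                                            "norm_score", "fold"])
    pooled = rank_auc(scores["norm_score"].to_numpy(),
                      (scores["label"] == "TS").to_numpy().astype(int))
    from sklearn.metrics import roc_auc_score
    trap = float(roc_auc_score((scores["label"] == "TS").astype(int),
                               scores["norm_score"]))
    return ClassifierReport(fold_aucs, pooled, scores, fold_assignment, trap)


def score_unlabelled(matrix: pd.DataFrame, labels: dict, unlabelled_genes,
                     learner_factory=default_learner, ts_cut: float = 0.78,
                     og_cut: float = 0.83) -> pd.DataFrame:
    """Score genes outside the training labels (e.g. dual-annotated genes).

    The scorer is trained on all TS/OG-labelled genes; raw scores of the
    unlabelled genes are calibrated to [0,1] by rank against the training
    scores (mid-rank for ties), higher = more TS-like. Decision labels:
    TS when the TS-probability exceeds ``ts_cut``, OG when it falls below
    ``1 - og_cut``, otherwise unresolved.
    """
    train_genes = [g for g in matrix.index if labels.get(g) in ("TS", "OG")]
    if not train_genes:
        raise ValueError("no labelled genes to train on")
    y = np.array([1 if labels[g] == "TS" else 0 for g in train_genes])
    X = matrix.loc[train_genes].to_numpy(dtype=float)
    model = learner_factory()
    model.fit(X, y)
    train_scores = np.sort(_score(model, X))
    rows = []
    unlabelled_genes = sorted(unlabelled_genes)
    if unlabelled_genes:
        raw = _score(model, matrix.loc[unlabelled_genes].to_numpy(dtype=float))
        n = len(train_scores)
        for gene, s in zip(unlabelled_genes, raw):
            below = np.searchsorted(train_scores, s, side="left")
            ties = np.searchsorted(train_scores, s, side="right") - below
            prob_ts = (below + 0.5 * ties) / n
            if prob_ts > ts_cut:
                call = "TS"
            elif prob_ts < 1.0 - og_cut:
                call = "OG"
            else:
                call = "unresolved"
            rows.append([gene, float(s), float(prob_ts), call])
    return pd.DataFrame(rows, columns=["gene", "raw_score", "prob_ts", "call"])
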