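"""Metrics and baselines for atom-wise regioselectivity prediction.

Metrics operate on atom-level decisions pooled over a test set: F-score,
atom accuracy (with recall reported separately), AUROC, and a per-reaction
top-1 accuracy. Baselines: condensed Fukui reactivity indices computed from
supplied atomic charges, and a random forest over atom-centered Morgan
fingerprints concatenated with the reaction-condition one-hot.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from rdkit.Chem import rdFingerprintGenerator
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score

from .datasets import ConditionVocabulary, ReactionRecord, encode_conditions
from .errors import (ChargeTableError, EmptyPredictionError, TrainingError,
                     UndefinedMetricError)
from .molgraph import MolecularGraph

ELECTROPHILIC_RADICALS = frozenset({"electrophilic_radical"})
NUCLEOPHILIC_RADICALS = frozenset({"nucleophilic_radical"})


@dataclass
class MetricCounts:
    """Confusion counts over atom-level decisions."""

    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("negative count")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @classmethod
    def from_predictions(cls, predicted: np.ndarray,
                         truth: np.ndarray) -> "MetricCounts":
        predicted = np.asarray(predicted).astype(bool)
        truth = np.asarray(truth).astype(bool)
        return cls(tp=int(np.sum(predicted & truth)),
                   fp=int(np.sum(predicted & ~truth)),
                   fn=int(np.sum(~predicted & truth)),
                   tn=int(np.sum(~predicted & ~truth)))


def f_score(c: MetricCounts) -> float:
    """F1 = 2 TP / (2 TP + FP + FN); 1.0 if no positives exist anywhere."""
    denom = 2 * c.tp + c.fp + c.fn
    if denom == 0:
        warnings.warn("no positive predictions or labels; F-score "
                      "degenerate, returning 1.0")
        return 1.0
    return 2 * c.tp / denom


def atom_accuracy(c: MetricCounts) -> float:
    """Fraction of all atoms classified correctly."""
    if c.total == 0:
        raise UndefinedMetricError("no atoms evaluated")
    return (c.tp + c.tn) / c.total


def recall(c: MetricCounts) -> float:
    """TP / (TP + FN): the fraction of true reactive sites recovered."""
    if c.tp + c.fn == 0:
        raise UndefinedMetricError("no positive labels")
    return c.tp / (c.tp + c.fn)


def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Probability a random positive outscores a random negative (ties 1/2).

    Raises
    ------
    UndefinedMetricError
        If labels are all one class.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise UndefinedMetricError("AUROC needs both classes present")
    return float(roc_auc_score(labels, np.asarray(scores)))


def eligible_sites(g: MolecularGraph) -> list[int]:
    """Carbons bearing at least one hydrogen (mono-addition C-H framing)."""
    return [i for i, el in enumerate(g.elements)
            if el == "C" and g.h_counts[i] >= 1]


def top1_accuracy(reactions: list[tuple[np.ndarray, set[int], list[int]]]
                  ) -> float:
    """Fraction of reactions whose top-ranked eligible site truly reacted.

    Each entry is (per-atom probabilities, true reactive-site set, eligible
    atom indices). A reaction scores 1 iff the highest-probability eligible
    atom is in the true set; ties break toward the lowest atom index.
    Negative records (empty true set) are excluded; reactions with no
    eligible atoms are skipped with a warning.
    """
    hits, n = 0, 0
    for probs, true_sites, eligible in reactions:
        if not true_sites:
            continue
        if not eligible:
            warnings.warn("reaction with no eligible C-H site skipped")
            continue
        eligible = sorted(eligible)
        probs = np.asarray(probs)
        best = eligible[int(np.argmax(probs[eligible]))]
        hits += int(best in true_sites)
        n += 1
    if n == 0:
        raise UndefinedMetricError("no scorable reactions")
    return hits / n


# ---------------------------------------------------------------------------
# Fukui-index baseline
# ---------------------------------------------------------------------------

@dataclass
class ChargeTable:
    """Per-atom charges for the N-1, N, N+1 electron states."""

    q_minus: np.ndarray       # q_i(N-1), one electron removed
    q_neutral: np.ndarray     # q_i(N)
    q_plus: np.ndarray        # q_i(N+1), one electron added
    total_minus: float = 1.0
    total_neutral: float = 0.0
    total_plus: float = -1.0

    def __post_init__(self):
        self.q_minus = np.asarray(self.q_minus, dtype=np.float64)
        self.q_neutral = np.asarray(self.q_neutral, dtype=np.float64)
        self.q_plus = np.asarray(self.q_plus, dtype=np.float64)
        for q, total, name in ((self.q_minus, self.total_minus, "N-1"),
                               (self.q_neutral, self.total_neutral, "N"),
                               (self.q_plus, self.total_plus, "N+1")):
            if abs(q.sum() - total) > 1e-3:
                raise ChargeTableError(
                    f"{name}-state charges sum to {q.sum():.6f}, "
                    f"expected {total}")


@dataclass
class FukuiIndices:
    """Condensed Fukui indices per atom.

    f_plus  F(+) = q(N) - q(N+1)   : susceptibility to nucleophilic charge
                                     gain, tracks electrophilic-radical
                                     attack sites
    f_minus F(-) = q(N-1) - q(N)
    f_zero  F(0) = (F(+) + F(-))/2 : radical index, tracks
                                     nucleophilic-radical attack sites
    """

    f_plus: np.ndarray
    f_minus: np.ndarray
    f_zero: np.ndarray


def fukui_indices(t: ChargeTable) -> FukuiIndices:
    """Compute F(+), F(-), F(0) from the three-state charge table.

    Each column telescopes to the unit change in molecular charge, so with
    exact charge sums every index column sums to 1.
    """
    f_plus = t.q_neutral - t.q_plus
    f_minus = t.q_minus - t.q_neutral
    return FukuiIndices(f_plus=f_plus, f_minus=f_minus,
                        f_zero=0.5 * (f_plus + f_minus))


def _top_k_with_ties(values: np.ndarray, candidates: list[int],
                     k: int, tie_tol: float = 1e-9) -> set[int]:
    ranked = sorted(candidates, key=lambda i: (-values[i], i))
    cut = ranked[:k]
    threshold = values[cut[-1]]
    return {i for i in candidates if values[i] >= threshold - tie_tol}


def fukui_predict(idx: FukuiIndices, reagent_class: str,
                  eligible: list[int], k: int = 1,
                  true_sites: set[int] | None = None
                  ) -> tuple[set[int], str]:
    """Predict reactive sites from Fukui indices.

    Electrophilic radicals (e.g. CF3) attack where F(+) is largest;
    nucleophilic radicals (CF2H, cyclobutyl) where F(0) is largest. For a
    reagent of unknown character both indices are scored against
    ``true_sites`` and the better-fitting one is reported (a best-fit
    protocol; the returned column name carries a "best_fit:" flag).
    Returns the top-k eligible carbons, expanding k over exact ties, and
    the name of the index column used.

    Raises
    ------
    EmptyPredictionError
        If there is no eligible carbon.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not eligible:
        raise EmptyPredictionError("no eligible C-H carbon")
    if reagent_class in ELECTROPHILIC_RADICALS:
        return _top_k_with_ties(idx.f_plus, eligible, k), "f_plus"
    if reagent_class in NUCLEOPHILIC_RADICALS:
        return _top_k_with_ties(idx.f_zero, eligible, k), "f_zero"
    if reagent_class != "unknown":
        raise ValueError(f"unknown reagent class {reagent_class!r}")
    if true_sites is None:
        raise ValueError("best-fit protocol for an unknown radical "
                         "requires the observed sites")
    best_set, best_name, best_f = set(), "", -1.0
    for name, col in (("f_plus", idx.f_plus), ("f_zero", idx.f_zero)):
        pred = _top_k_with_ties(col, eligible, k)
        c = MetricCounts(
            tp=len(pred & true_sites), fp=len(pred - true_sites),
            fn=len(true_sites - pred),
            tn=len(set(eligible) - pred - true_sites))
        score = f_score(c)
        if score > best_f:
            best_set, best_name, best_f = pred, name, score
    return best_set, f"best_fit:{best_name}"


# ---------------------------------------------------------------------------
# Random-forest baseline
# ---------------------------------------------------------------------------

def atom_morgan_fingerprints(g: MolecularGraph, radius: int = 2,
                             n_bits: int = 2048) -> np.ndarray:
    """One atom-centered circular fingerprint row per atom."""
    mol = g.to_rdkit()
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius,
                                                    fpSize=n_bits)
    rows = np.zeros((g.n_atoms, n_bits), dtype=np.float64)
    for i in range(g.n_atoms):
        fp = gen.GetFingerprint(mol, fromAtoms=[i])
        rows[i, list(fp.GetOnBits())] = 1.0
    return rows


def _rf_design_matrix(records: list[ReactionRecord],
                      vocab: ConditionVocabulary, radius: int,
                      n_bits: int) -> tuple[np.ndarray, np.ndarray]:
    xs, ys = [], []
    for rec in records:
        fp = atom_morgan_fingerprints(rec.sm, radius, n_bits)
        cond = encode_conditions(rec.conditions, vocab)
        xs.append(np.hstack([fp, np.tile(cond, (rec.sm.n_atoms, 1))]))
        ys.append(np.asarray(rec.labels.labels, dtype=np.float64))
    return np.vstack(xs), np.concatenate(ys)


@dataclass
class RFBaselineResult:
    classifier: RandomForestClassifier
    probabilities: np.ndarray     # per test atom
    labels: np.ndarray            # per test atom truth
    metrics: dict


def rf_baseline(train: list[ReactionRecord], test: list[ReactionRecord],
                vocab: ConditionVocabulary, radius: int = 2,
                n_bits: int = 2048, n_estimators: int = 200,
                seed: int = 0, tau: float = 0.5) -> RFBaselineResult:
    """Atom-wise Morgan-fingerprint random-forest classifier.

    Each training row is one atom: its atom-centered fingerprint
    concatenated with the reaction-condition one-hot; the target is the
    atom's reactive label.

    Raises
    ------
    TrainingError
        If the training labels contain a single class.
    """
    x_train, y_train = _rf_design_matrix(train, vocab, radius, n_bits)
    if len(np.unique(y_train)) < 2:
        raise TrainingError("training labels are single-class")
    clf = RandomForestClassifier(n_estimators=n_estimators,
                                 random_state=seed, n_jobs=1)
    clf.fit(x_train, y_train)
    x_test, y_test = _rf_design_matrix(test, vocab, radius, n_bits)
    probs = clf.predict_proba(x_test)[:, list(clf.classes_).index(1.0)]
    counts = MetricCounts.from_predictions(probs > tau, y_test)
    metrics = {"f_score": f_score(counts),
               "accuracy": atom_accuracy(counts)}
    try:
        metrics["auroc"] = auroc(probs, y_test)
    except UndefinedMetricError:
        metrics["auroc"] = float("nan")
    return RFBaselineResult(classifier=clf, probabilities=probs,
                            labels=y_test, metrics=metrics)


def evaluate_predictions(records: list[ReactionRecord],
                         probabilities: list[np.ndarray],
                         tau: float = 0.5) -> dict:
    """Pooled atom-level metric suite plus per-reaction top-1 accuracy."""
    all_p = np.concatenate(probabilities)
    all_y = np.concatenate([np.asarray(r.labels.labels, dtype=float)
                            for r in records])
    counts = MetricCounts.from_predictions(all_p > tau, all_y)
    out = {"f_score": f_score(counts),
           "accuracy": atom_accuracy(counts),
           "tp": counts.tp, "fp": counts.fp,
           "fn": counts.fn, "tn": counts.tn}
    try:
        out["recall"] = recall(counts)
    except UndefinedMetricError:
        out["recall"] = float("nan")
    try:
        out["auroc"] = auroc(all_p, all_y)
    except UndefinedMetricError:
        out["auroc"] = float("nan")
    try:
        out["top1_accuracy"] = top1_accuracy(
            [(p, set(r.labels.reactive_set), eligible_sites(r.sm))
             for p, r in zip(probabilities, records)])
    except UndefinedMetricError:
        out["top1_accuracy"] = float("nan")
    return out
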