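"""Levenshtein K-nearest-neighbor baseline for binding prediction.

A deliberately simple, non-parametric reference model: the distance between
two (epitope, TCR) pairs is the sum of the length-normalized edit distances
of the epitopes and of the receptors,

    D(e_i, t_i, e_j, t_j) = Lev(e_i, e_j) / |e_j| + Lev(t_i, t_j) / |t_j|,

normalizing by the *query* pair's lengths exactly as printed — the metric is
therefore mildly asymmetric. The prediction for a query is the mean label of
its k nearest training records; with odd k the 0.5 decision threshold never
ties. k is swept over the odd values 1..25 and chosen by cross-validated
ROC-AUC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd

from .records import BindingRecord, ConfigurationError

__all__ = ["levenshtein", "pair_distance", "KnnBindingModel", "KnnResults",
           "select_best_k", "DEFAULT_K_SWEEP"]

DEFAULT_K_SWEEP = tuple(range(1, 26, 2))


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance (insertions, deletions, substitutions)."""
    if not a or not b:
        return max(len(a), len(b))
    return edlib.align(a, b, task="distance")["editDistance"]


def pair_distance(e_train: str, t_train: str, e_query: str, t_query: str) -> float:
    """Distance of a training pair from a query pair (query-length normalized)."""
    if not e_query or not t_query:
        raise ValueError("query sequences must be non-empty (they normalize)")
    return (levenshtein(e_train, e_query) / len(e_query)
            + levenshtein(t_train, t_query) / len(t_query))


class _DistanceCache:
    """Memoized Levenshtein lookups; binding data repeats epitopes heavily."""

    def __init__(self):
        self._cache: dict = {}

    def __call__(self, a: str, b: str) -> int:
        key = (a, b)
        d = self._cache.get(key)
        if d is None:
            d = levenshtein(a, b)
            self._cache[key] = d
        return d


@dataclass
class KnnBindingModel:
    """K-NN binding classifier over a training set of BindingRecords.

    statsmodels-style usage::

        results = KnnBindingModel(train_records, k=13).fit()
        scores = results.predict(test_records)
        print(results.summary())
    """

    training_records: list
    k: int = 13
    symmetric: bool = False  # normalize by both lengths' mean instead

    def __post_init__(self):
        if self.k < 1 or self.k % 2 == 0:
            raise ConfigurationError(f"k must be odd and positive, got {self.k}")
        if self.k > len(self.training_records):
            raise ConfigurationError(
                f"k={self.k} exceeds training size {len(self.training_records)}")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, k: int = 13, **kwargs):
        recs = [BindingRecord(r.epitope, r.tcr, int(r.label))
                for r in df.itertuples(index=False)]
        return cls(recs, k=k, **kwargs)

    def fit(self) -> "KnnResults":
        """No parameters to estimate; returns a Results view of the data."""
        return KnnResults(self)

    # -- scoring machinery -------------------------------------------------

    def _neighbor_labels(self, e: str, t: str, n_neighbors: int,
                         cache: _DistanceCache | None = None) -> np.ndarray:
        """Labels of the n nearest training records, stable-sorted by
        (distance, training index)."""
        cache = cache or _DistanceCache()
        dists = np.empty(len(self.training_records))
        for i, r in enumerate(self.training_records):
            de = cache(r.epitope_seq, e)
            dt = cache(r.tcr_seq, t)
            if self.symmetric:
                dists[i] = (de / (0.5 * (len(r.epitope_seq) + len(e)))
                            + dt / (0.5 * (len(r.tcr_seq) + len(t))))
            else:
                dists[i] = de / len(e) + dt / len(t)
        order = np.argsort(dists, kind="stable")[:n_neighbors]
        return np.array([self.training_records[i].label for i in order])

    def predict_one(self, e: str, t: str) -> float:
        """Score one query pair: mean label of the k nearest neighbors."""
        return float(self._neighbor_labels(e, t, self.k).mean())


@dataclass
class KnnResults:
    """Fitted view of a KnnBindingModel: scoring and summary."""

    model: KnnBindingModel
    _cache: _DistanceCache = field(default_factory=_DistanceCache, repr=False)

    def predict(self, records: list) -> np.ndarray:
        """Scores in [0, 1] for a list of BindingRecords (labels ignored)."""
        return np.array([
            self.model._neighbor_labels(r.epitope_seq, r.tcr_seq,
                                        self.model.k, self._cache).mean()
            for r in records])

    def neighbor_label_matrix(self, records: list, max_k: int) -> np.ndarray:
        """(n_queries, max_k) matrix of nearest-neighbor labels, enabling a
        whole k-sweep from a single distance pass."""
        return np.stack([
            self.model._neighbor_labels(r.epitope_seq, r.tcr_seq, max_k,
                                        self._cache)
            for r in records])

    def summary(self) -> str:
        recs = self.model.training_records
        pos = sum(r.label for r in recs)
        lines = [
            "Levenshtein K-NN binding model",
            "=" * 38,
            f"training records      {len(recs):>8d}",
            f"  positives           {pos:>8d}",
            f"  epitopes            {len({r.epitope_seq for r in recs}):>8d}",
            f"k (odd)               {self.model.k:>8d}",
            f"distance              {'symmetric' if self.model.symmetric else 'query-normalized'}",
        ]
        return "\n".join(lines)


def select_best_k(records: list, folds, k_values=DEFAULT_K_SWEEP):
    """Sweep k by cross-validated ROC-AUC; return (k*, per-k table).

    For each fold, records outside the fold form the training set and the
    fold itself is scored; one neighbor pass at max(k) serves every k. Ties
    in the per-k mean AUC resolve to the smaller k.
    """
    from sklearn.metrics import roc_auc_score

    k_values = sorted(k_values)
    max_k = k_values[-1]
    per_fold_aucs: dict[int, list] = {k: [] for k in k_values}
    for f in range(folds.n_folds):
        test_idx = folds.indices(f)
        train = [records[i] for i in range(len(records))
                 if i in folds.fold_of and folds.fold_of[i] != f]
        test = [records[i] for i in test_idx]
        labels = np.array([r.label for r in test])
        if len(train) < max_k or len(set(labels)) < 2:
            continue
        res = KnnBindingModel(train, k=1).fit()
        nl = res.neighbor_label_matrix(test, max_k)
        for k in k_values:
            scores = nl[:, :k].mean(axis=1)
            per_fold_aucs[k].append(roc_auc_score(labels, scores))
    table = pd.DataFrame({
        "k": k_values,
        "mean_roc_auc": [float(np.mean(per_fold_aucs[k])) if per_fold_aucs[k]
                         else np.nan for k in k_values],
        "n_folds": [len(per_fold_aucs[k]) for k in k_values],
    })
    best = table.loc[table["mean_roc_auc"].idxmax(), "k"]
    return int(best), table
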