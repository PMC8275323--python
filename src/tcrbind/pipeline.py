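"""Dataset curation, negative sampling and cross-validation splitting.

Public binding databases list positives only and are heavily imbalanced:
a handful of immunodominant epitopes carry thousands of receptors while
most carry a few. The pipeline here mirrors the standard treatment —
drop epitopes with too few receptors, cap the rest, synthesize negatives
by reshuffling the observed pairing, and build receptor- or
epitope-disjoint cross-validation folds.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np

from .records import BindingRecord, ConfigurationError, DataError

logger = logging.getLogger(__name__)

__all__ = ["CurationConfig", "FoldAssignment", "curate_dataset",
           "generate_negatives", "make_folds", "preprocess_cpi"]


@dataclass
class CurationConfig:
    """Per-epitope receptor-count bounds applied before model training.

    Defaults follow common practice for repertoire binding data: epitopes
    with fewer than 15 distinct receptors are uninformative for training and
    are removed; abundant epitopes are capped at 400 receptors so a few
    immunodominant peptides cannot dominate the loss.
    """

    min_tcrs_per_epitope: int = 15
    max_tcrs_per_epitope: int = 400
    rng_seed: int = 0

    def __post_init__(self):
        if self.min_tcrs_per_epitope <= 0 or self.max_tcrs_per_epitope <= 0:
            raise ConfigurationError("TCR-per-epitope bounds must be positive")
        if self.min_tcrs_per_epitope > self.max_tcrs_per_epitope:
            raise ConfigurationError("min_tcrs_per_epitope > max_tcrs_per_epitope")


@dataclass
class FoldAssignment:
    """Record-index -> fold mapping with disjointness guarantees.

    ``tcr_split`` keeps every receptor inside a single fold (epitopes may be
    shared across folds); ``strict_split`` additionally keeps every epitope
    inside a single fold, so validation folds contain only unseen epitopes.
    """

    n_folds: int
    fold_of: dict = field(default_factory=dict)
    mode: str = "tcr_split"

    def indices(self, fold: int) -> list[int]:
        return [i for i, f in self.fold_of.items() if f == fold]

    def __len__(self):
        return len(self.fold_of)


def curate_dataset(records: list[BindingRecord],
                   config: CurationConfig) -> list[BindingRecord]:
    """Apply per-epitope receptor bounds to a positives-only dataset.

    Receptors are first deduplicated per epitope by ``tcr_id``; epitopes
    below the minimum are removed entirely and epitopes above the maximum
    are downsampled uniformly at random (seeded). Output order is
    deterministic given the seed. Idempotent: a curated dataset passes
    through unchanged under the same bounds.
    """
    if any(r.label != 1 for r in records):
        raise ConfigurationError("curate_dataset expects positives only")
    by_epitope: dict[str, list[BindingRecord]] = defaultdict(list)
    for r in records:
        by_epitope[r.epitope_seq].append(r)

    rng = np.random.default_rng(config.rng_seed)
    out: list[BindingRecord] = []
    census = {}
    for epi in sorted(by_epitope):
        seen, unique = set(), []
        for r in by_epitope[epi]:
            if r.tcr_id not in seen:
                seen.add(r.tcr_id)
                unique.append(r)
        census[epi] = len(unique)
        if len(unique) < config.min_tcrs_per_epitope:
            continue
        if len(unique) > config.max_tcrs_per_epitope:
            keep = rng.choice(len(unique), size=config.max_tcrs_per_epitope,
                              replace=False)
            unique = [unique[i] for i in sorted(keep)]
        out.extend(unique)
    if not out:
        raise DataError(f"curation removed every epitope; census: {census}")
    return out


def generate_negatives(records: list[BindingRecord],
                       scope: FoldAssignment | None = None,
                       rng_seed: int = 0,
                       max_retries: int = 100) -> list[BindingRecord]:
    """Balance a positives-only dataset by shuffling epitope-TCR pairings.

    Every receptor gains exactly as many negatives as it has positives, each
    negative pairing it with an epitope it is not recorded to bind. When a
    fold assignment is given, shuffling stays within each fold so fold
    disjointness is preserved. Returns positives + negatives (exact 50/50).
    """
    if any(r.label != 1 for r in records):
        raise ConfigurationError("generate_negatives expects positives only")
    rng = np.random.default_rng(rng_seed)
    positive_pairs = {(r.epitope_seq, r.tcr_seq) for r in records}

    if scope is None:
        groups = [list(range(len(records)))]
    else:
        groups = [scope.indices(f) for f in range(scope.n_folds)]

    negatives: list[tuple[int, BindingRecord]] = []
    dropped = 0
    for group in groups:
        epitopes = sorted({records[i].epitope_seq for i in group})
        by_tcr: dict[str, list[int]] = defaultdict(list)
        for i in group:
            by_tcr[records[i].tcr_seq].append(i)
        for tcr in sorted(by_tcr):
            own = {records[i].epitope_seq for i in by_tcr[tcr]}
            candidates = [e for e in epitopes if e not in own]
            for i in by_tcr[tcr]:
                drawn = None
                if candidates:
                    for _ in range(max_retries):
                        e = candidates[rng.integers(len(candidates))]
                        if (e, tcr) not in positive_pairs:
                            drawn = e
                            break
                    else:  # exhaustive fallback over remaining candidates
                        pool = [e for e in candidates
                                if (e, tcr) not in positive_pairs]
                        if pool:
                            drawn = pool[rng.integers(len(pool))]
                if drawn is None:
                    dropped += 1
                    continue
                negatives.append(
                    (i, BindingRecord(drawn, tcr, 0, records[i].tcr_id)))
    if dropped:
        logger.warning("no valid negative epitope for %d positive records; "
                       "those negatives were dropped", dropped)
    out = list(records)
    if scope is not None:
        for i, neg in negatives:
            scope.fold_of[len(out)] = scope.fold_of[i]
            out.append(neg)
    else:
        out.extend(neg for _, neg in negatives)
    return out


def make_folds(records: list[BindingRecord], n_folds: int,
               mode: str = "tcr_split", rng_seed: int = 0) -> FoldAssignment:
    """Assign records to cross-validation folds.

    ``tcr_split``: receptors are shuffled into folds; all records of a
    receptor follow it, so no receptor spans folds. ``strict_split``:
    epitopes are assigned greedily (largest first into the currently
    smallest fold) so folds balance in size, all records of an epitope
    follow it, and any receptor left spanning several folds is kept only in
    the fold where it has most records (ties to the lowest fold index).
    """
    if mode not in ("tcr_split", "strict_split"):
        raise ConfigurationError(f"unknown split mode {mode!r}")
    rng = np.random.default_rng(rng_seed)
    fa = FoldAssignment(n_folds=n_folds, mode=mode)

    if mode == "tcr_split":
        tcrs = sorted({r.tcr_id for r in records})
        order = rng.permutation(len(tcrs))
        fold_of_tcr = {tcrs[j]: int(f) for f, j in
                       ((i % n_folds, order[i]) for i in range(len(tcrs)))}
        for i, r in enumerate(records):
            fa.fold_of[i] = fold_of_tcr[r.tcr_id]
        return fa

    # strict split
    counts = Counter(r.epitope_seq for r in records)
    if n_folds > len(counts):
        raise ConfigurationError(
            f"strict split needs at least {n_folds} epitopes, have {len(counts)}")
    # shuffle before the greedy pass so equal-sized epitopes land randomly
    epitopes = sorted(counts)
    rng.shuffle(epitopes)
    epitopes.sort(key=lambda e: -counts[e])
    fold_sizes = [0] * n_folds
    fold_of_epi = {}
    for e in epitopes:
        f = int(np.argmin(fold_sizes))
        fold_of_epi[e] = f
        fold_sizes[f] += counts[e]

    # receptors appearing with epitopes of several folds stay where they
    # have most records
    tcr_fold_counts: dict[str, Counter] = defaultdict(Counter)
    for r in records:
        tcr_fold_counts[r.tcr_id][fold_of_epi[r.epitope_seq]] += 1
    home_fold = {}
    conflicts = 0
    for tcr, cnt in tcr_fold_counts.items():
        if len(cnt) > 1:
            conflicts += 1
        best = max(cnt.items(), key=lambda kv: (kv[1], -kv[0]))
        home_fold[tcr] = best[0]
    if conflicts:
        logger.info("strict split: %d receptors spanned folds; kept each in "
                    "its majority fold", conflicts)

    for i, r in enumerate(records):
        f = fold_of_epi[r.epitope_seq]
        if home_fold[r.tcr_id] == f:
            fa.fold_of[i] = f
    dropped = len(records) - len(fa.fold_of)
    if dropped:
        logger.info("strict split: dropped %d records of fold-spanning "
                    "receptors", dropped)
    return fa


def preprocess_cpi(pairs: list[tuple[str, str]],
                   max_smiles_tokens: int = 250,
                   max_protein_len: int = 1028,
                   train_fraction: float = 0.9,
                   rng_seed: int = 0):
    """Prepare compound-protein interaction data for pretraining.

    Every listed (SMILES ligand, protein) pair is taken as binding (label 1);
    an equal number of negatives is made by randomly re-assigning ligands to
    proteins, avoiding listed pairs. Ligands longer than ``max_smiles_tokens``
    SMILES tokens and proteins longer than ``max_protein_len`` residues are
    discarded before balancing. Returns (train, validation) lists of
    (smiles, protein, label), split 90/10 by default.
    """
    from .smiles import split_smiles_tokens

    if not pairs:
        raise DataError("empty CPI input")
    rng = np.random.default_rng(rng_seed)
    kept = [(s, p) for s, p in pairs
            if len(split_smiles_tokens(s)) <= max_smiles_tokens
            and len(p) <= max_protein_len]
    if not kept:
        raise DataError("all CPI pairs removed by length filters")
    positive_set = set(kept)
    ligands = sorted({s for s, _ in kept})
    proteins = sorted({p for _, p in kept})

    labeled = [(s, p, 1) for s, p in kept]
    n_neg, attempts = 0, 0
    max_attempts = 1000 * len(kept)
    while n_neg < len(kept):
        attempts += 1
        if attempts > max_attempts:
            raise DataError("could not sample enough non-binding CPI pairs")
        s = ligands[rng.integers(len(ligands))]
        p = proteins[rng.integers(len(proteins))]
        if (s, p) in positive_set:
            continue
        labeled.append((s, p, 0))
        n_neg += 1

    order = rng.permutation(len(labeled))
    n_train = int(round(train_fraction * len(labeled)))
    train = [labeled[i] for i in order[:n_train]]
    val = [labeled[i] for i in order[n_train:]]
    return train, val
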