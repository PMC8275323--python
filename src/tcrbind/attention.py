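"""Attention extraction and interpretability statistics.

The context-attention layers expose which sequence positions the network
weighs for a given binding partner. Three analyses are provided:

* heatmap extraction — one attention row per (receptor, epitope) pair per
  stream, averaged over the convolution channels;
* variance statistics — how much attention varies across different
  reference sequences (inter-group) and, for a fixed reference, across
  binding partners (intra-group). Near-zero epitope-side variances are the
  signature of a model that attends to fixed epitope positions regardless
  of sequence — treating epitopes as mere class labels;
* epitope compression — reducing each epitope to its residues with
  attention above a threshold (0.1 by default). If the compressed strings
  remain unique across epitopes, the attended positions suffice to identify
  the epitope, i.e. the model can act as an implicit epitope classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .records import ConfigurationError

__all__ = ["AttentionMatrix", "extract_attention", "attention_variances",
           "compress_epitopes"]


@dataclass
class AttentionMatrix:
    """Rows = samples, columns = token positions, values = attention."""

    values: np.ndarray
    reference_ids: list = field(default_factory=list)
    context_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        sums = self.values.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("attention rows must each sum to 1")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values)
        df.insert(0, "reference", self.reference_ids)
        df.insert(1, "context", self.context_ids)
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def plot(self, path=None, ax=None):
        """Heatmap of attention rows (samples x positions)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 0.3 * len(self.values) + 1.5))
        im = ax.imshow(self.values, aspect="auto", cmap="viridis")
        ax.set_xlabel("token position")
        ax.set_ylabel("sample")
        ax.figure.colorbar(im, ax=ax, label="attention")
        if path is not None:
            ax.figure.savefig(path, dpi=120, bbox_inches="tight")
            plt.close(ax.figure)
        return ax


def extract_attention(results, pairs: list[tuple]):
    """Attention heatmaps for (tcr, epitope) sequence pairs.

    ``results`` is a fitted TCRBindingResults (or a TCRBindingModel; its
    current parameters are used). Per stream, the four channels' attention
    maps are averaged into a single per-token row. Returns
    (tcr AttentionMatrix, epitope AttentionMatrix).
    """
    model = getattr(results, "model", results)
    encoder, network = model.encoder, model.network
    tcr_rows, epi_rows = [], []
    refs_t, ctx_t, refs_e, ctx_e = [], [], [], []
    for tcr, epi in pairs:
        t_idx = encoder.encode_tcr(tcr)[None, :]
        e_idx = encoder.encode_epitope(epi)[None, :]
        out = network.forward(t_idx, e_idx, return_attention=True)
        att = out["attention"]
        tcr_rows.append(np.mean([a[0] for a in att["tcr"]], axis=0))
        epi_rows.append(np.mean([a[0] for a in att["epi"]], axis=0))
        refs_t.append(tcr); ctx_t.append(epi)
        refs_e.append(epi); ctx_e.append(tcr)
    return (AttentionMatrix(np.stack(tcr_rows), refs_t, ctx_t),
            AttentionMatrix(np.stack(epi_rows), refs_e, ctx_e))


def attention_variances(matrix: AttentionMatrix, group_by: str = "reference",
                        ddof: int = 0) -> dict:
    """Inter- and intra-group attention variances, averaged over tokens.

    Groups are the distinct reference sequences (``group_by="reference"``)
    or contexts. *Inter*: per-token variance of the group-mean attention
    across groups, then averaged over tokens. *Intra*: per-token variance
    across the rows within a group, averaged over tokens, then averaged
    over groups (groups with a single row contribute nothing). The variance
    estimator is population (ddof=0) by default.
    """
    if group_by == "reference":
        keys = matrix.reference_ids
    elif group_by == "context":
        keys = matrix.context_ids
    else:
        raise ConfigurationError(f"unknown group_by {group_by!r}")
    groups: dict = {}
    for key, row in zip(keys, matrix.values):
        groups.setdefault(key, []).append(row)
    if len(groups) < 2:
        raise ConfigurationError("need at least two groups for variances")

    group_means = np.stack([np.mean(rows, axis=0) for rows in groups.values()])
    inter = float(group_means.var(axis=0, ddof=ddof).mean())

    intra_terms = [np.stack(rows).var(axis=0, ddof=ddof).mean()
                   for rows in groups.values() if len(rows) > 1]
    intra = float(np.mean(intra_terms)) if intra_terms else float("nan")
    return {"inter": inter, "intra": intra, "n_groups": len(groups)}


def compress_epitopes(epitopes: list[str], attention_rows: np.ndarray,
                      threshold: float = 0.1):
    """Reduce epitopes to their residues with attention above `threshold`.

    ``attention_rows[i]`` must align with the residues of ``epitopes[i]``
    (flank and padding columns already excluded). Residues with attention
    strictly above the threshold are kept in order. Returns
    (compressed strings, n_unique, fraction_unique) where uniqueness counts
    epitopes whose compressed form occurs exactly once in the set.
    """
    attention_rows = np.atleast_2d(np.asarray(attention_rows, dtype=float))
    if len(epitopes) != len(attention_rows):
        raise ValueError("one attention row per epitope required")
    compressed = []
    for seq, row in zip(epitopes, attention_rows):
        if len(seq) > len(row):
            raise ValueError(f"attention row shorter than epitope {seq!r}")
        compressed.append("".join(c for c, a in zip(seq, row) if a > threshold))
    counts = pd.Series(compressed).value_counts()
    n_unique = int(sum(counts[c] == 1 for c in compressed))
    return compressed, n_unique, n_unique / len(epitopes)
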