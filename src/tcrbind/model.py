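"""Model/Results interface for the bimodal attention binding predictor.

Follows the familiar two-object pattern: ``TCRBindingModel`` holds the data,
the architecture configuration and the encoders; ``fit()`` trains the
network and returns a ``TCRBindingResults`` carrying the trained parameters,
the loss trace and evaluation/attention utilities::

    model = TCRBindingModel(train_records, config=ModelConfig.reduced())
    results = model.fit(TrainConfig(max_epochs=30, batch_size=64))
    scores = results.predict(test_records)
    print(results.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .encoding import tokenize_protein
from .network import BimodalAttentionNetwork, ModelConfig
from .records import BindingRecord
from .smiles import SmilesVocabulary, augment_smiles, peptide_to_smiles, tokenize_smiles
from .training import TrainConfig, evaluate, train_model

__all__ = ["DatasetEncoder", "TCRBindingModel", "TCRBindingResults"]


class DatasetEncoder:
    """Turn BindingRecords into padded token-index arrays for the network.

    The receptor stream is always amino-acid encoded; the epitope stream is
    amino-acid or SMILES encoded depending on the configuration. SMILES
    tokenization uses a vocabulary built from the training epitopes
    (canonical forms plus a few randomized variants, so augmented strings
    tokenize without unknowns).
    """

    def __init__(self, config: ModelConfig, stereo: bool = True):
        self.config = config
        self.stereo = stereo
        self.smiles_mode = config.epitope_scheme == "smiles"
        self.vocab = SmilesVocabulary() if self.smiles_mode else None
        self._tcr_cache: dict[str, np.ndarray] = {}
        self._epi_cache: dict[str, np.ndarray] = {}
        self._smiles_of: dict[str, str] = {}

    def fit(self, records: list[BindingRecord]) -> "DatasetEncoder":
        if self.smiles_mode:
            for epi in sorted({r.epitope_seq for r in records}):
                smi = peptide_to_smiles(epi, stereo=self.stereo)
                self._smiles_of[epi] = smi.text
                self.vocab.add_corpus([smi])
                for s in range(3):  # close the vocabulary over augmentations
                    self.vocab.add_corpus([augment_smiles(smi, rng_seed=s)])
            self.config.smiles_vocab_size = max(
                self.config.smiles_vocab_size, len(self.vocab) + 8)
        return self

    def encode_tcr(self, seq: str) -> np.ndarray:
        arr = self._tcr_cache.get(seq)
        if arr is None:
            arr = tokenize_protein(seq, self.config.tcr_len).array
            self._tcr_cache[seq] = arr
        return arr

    def encode_epitope(self, seq: str, augment_seed: int | None = None) -> np.ndarray:
        if not self.smiles_mode:
            arr = self._epi_cache.get(seq)
            if arr is None:
                arr = tokenize_protein(seq, self.config.epitope_len).array
                self._epi_cache[seq] = arr
            return arr
        smi = self._smiles_of.get(seq)
        if smi is None:
            smi = peptide_to_smiles(seq, stereo=self.stereo).text
            self._smiles_of[seq] = smi
        if augment_seed is not None:
            smi = augment_smiles(smi, rng_seed=augment_seed).text
            return tokenize_smiles(smi, self.vocab, self.config.epitope_len).array
        arr = self._epi_cache.get(seq)
        if arr is None:
            arr = tokenize_smiles(smi, self.vocab, self.config.epitope_len).array
            self._epi_cache[seq] = arr
        return arr

    def encode_records(self, records: list[BindingRecord],
                       augment_rng: np.random.Generator | None = None):
        """(tcr_idx, epi_idx, labels) arrays; a generator enables on-the-fly
        SMILES augmentation (fresh random form per record per call)."""
        tcr = np.stack([self.encode_tcr(r.tcr_seq) for r in records])
        if augment_rng is not None and self.smiles_mode:
            epi = np.stack([
                self.encode_epitope(r.epitope_seq,
                                    int(augment_rng.integers(2 ** 31)))
                for r in records])
        else:
            epi = np.stack([self.encode_epitope(r.epitope_seq) for r in records])
        labels = np.array([r.label for r in records], dtype=float)
        return tcr, epi, labels


class TCRBindingModel:
    """Binding-prediction model bound to a training dataset.

    Parameters
    ----------
    records : list of BindingRecord
        Labeled training data (balanced by the dataset pipeline).
    config : ModelConfig, optional
        Architecture; defaults to the desk-scale reduced configuration.
    rng_seed : int
        Seeds parameter initialization.
    """

    def __init__(self, records: list[BindingRecord],
                 config: ModelConfig | None = None, rng_seed: int = 0,
                 stereo: bool = True):
        self.records = list(records)
        self.config = config or ModelConfig.reduced()
        self.rng_seed = rng_seed
        self.encoder = DatasetEncoder(self.config, stereo=stereo).fit(self.records)
        self.network = BimodalAttentionNetwork(self.config, rng_seed=rng_seed)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "TCRBindingModel":
        recs = [BindingRecord(r.epitope, r.tcr, int(r.label))
                for r in df.itertuples(index=False)]
        return cls(recs, **kwargs)

    def fit(self, train_config: TrainConfig | None = None,
            scopes: str = "all",
            validation: list[BindingRecord] | None = None) -> "TCRBindingResults":
        """Train and return a Results object.

        When a validation set is given, per-epoch validation ROC-AUC is
        tracked and the best-epoch parameters are restored at the end.
        """
        cfg = train_config or TrainConfig()
        trace = train_model(self.network, self.encoder, self.records, cfg,
                            validation=validation, scopes=scopes)
        return TCRBindingResults(model=self, train_config=cfg, trace=trace)


@dataclass
class TCRBindingResults:
    """Results of fitting a TCRBindingModel: trained parameters, loss trace
    and prediction/evaluation helpers."""

    model: TCRBindingModel
    train_config: TrainConfig
    trace: dict = field(default_factory=dict)

    @property
    def network(self) -> BimodalAttentionNetwork:
        return self.model.network

    @property
    def loss_trace(self) -> list:
        return self.trace.get("loss", [])

    def predict(self, records: list[BindingRecord]) -> np.ndarray:
        """Evaluation-mode binding probabilities for a list of records."""
        tcr, epi, _ = self.model.encoder.encode_records(records)
        return self.network.predict_proba(tcr, epi)

    def evaluate(self, records: list[BindingRecord]):
        labels = np.array([r.label for r in records])
        return evaluate(self.predict(records), labels)

    def attention_maps(self, pairs: list[tuple]):
        """Per-token attention for (tcr, epitope) pairs; see
        :func:`tcrbind.attention.extract_attention`."""
        from .attention import extract_attention

        return extract_attention(self, pairs)

    def summary(self) -> str:
        cfg = self.model.config
        n = len(self.model.records)
        pos = sum(r.label for r in self.model.records)
        lines = [
            "Bimodal context-attention binding model",
            "=" * 46,
            f"training records          {n:>10d}  (positives {pos})",
            f"epitopes                  {len({r.epitope_seq for r in self.model.records}):>10d}",
            f"parameters                {self.network.parameter_count:>10d}",
            f"epitope encoding          {cfg.epitope_scheme:>10s}",
            f"receptor encoding         {cfg.tcr_scheme:>10s}",
            f"attention space A         {cfg.attention_dim:>10d}",
            f"conv channels             {len(cfg.kernel_sizes_tcr):>10d}",
            f"trainable scope           {self.network.mode:>10s}",
            f"epochs trained            {len(self.loss_trace):>10d}",
        ]
        if self.loss_trace:
            lines.append(f"final training loss       {self.loss_trace[-1]:>10.4f}")
        if self.trace.get("val_auc"):
            best = int(np.argmax(self.trace["val_auc"]))
            lines.append(f"best val ROC-AUC          "
                         f"{self.trace['val_auc'][best]:>10.4f}  (epoch {best + 1})")
        return "\n".join(lines)
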