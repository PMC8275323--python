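"""Amino-acid tokenization and numeric embeddings.

Sequences of both input streams are flanked with a shared start/stop token,
padded to a fixed length and mapped to integer indices (0 = padding,
1 = start/stop, residues from 2). Three embedding schemes are provided:

* ``blosum62`` — each residue is the 26-dimensional row of the BLOSUM62
  substitution matrix over the extended alphabet (20 standard residues plus
  B, Z, X, U, O and ``*``; symbols absent from the published matrix get zero
  rows). Evolutionary similarity between residues thus becomes geometric
  proximity, a fixed representation that needs no training.
* ``biophysical`` — seven physicochemical descriptors per residue
  (molecular weight, residue weight, pKa, pKb, pKx, pI, hydrophobicity at
  pH 2), min-max scaled to [0, 1] by default.
* ``learned`` — a trainable table (32-dimensional by default) initialized
  from a seeded standard normal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["AA_ALPHABET", "PAD_INDEX", "FLANK_INDEX", "TOKEN_OF", "VOCAB_SIZE",
           "TokenSequence", "EmbeddingSpec", "tokenize_protein", "embed_tokens",
           "read_fasta_sequences", "AlphabetError", "LengthError"]

# 20 standard residues, then ambiguity/extended codes. Order fixes both token
# indices and the column order of the 26-dim BLOSUM62 rows.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWYBZXUO*"
PAD_INDEX = 0
FLANK_INDEX = 1  # shared start/stop token
TOKEN_OF = {aa: i + 2 for i, aa in enumerate(AA_ALPHABET)}
VOCAB_SIZE = len(AA_ALPHABET) + 2


class AlphabetError(ValueError):
    pass


class LengthError(ValueError):
    pass


@dataclass(frozen=True)
class TokenSequence:
    """A fixed-length, flanked, padded token-index sequence.

    Layout: ``[start] r1 ... rn [stop] pad ... pad`` with total length
    ``max_len``; ``content_length`` counts the real residue/atom tokens.
    """

    tokens: tuple
    content_length: int

    def __post_init__(self):
        if self.content_length + 2 > len(self.tokens):
            raise LengthError("content does not fit the padded length")

    def __len__(self):
        return len(self.tokens)

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.tokens, dtype=np.int64)


def tokenize_protein(seq: str, max_len: int = 500) -> TokenSequence:
    """Tokenize an amino-acid string into a flanked, padded TokenSequence."""
    if not seq:
        raise AlphabetError("empty sequence")
    seq = seq.upper()
    if len(seq) > max_len - 2:
        raise LengthError(
            f"sequence of length {len(seq)} exceeds max_len-2 = {max_len - 2}")
    toks = [FLANK_INDEX]
    for c in seq:
        if c not in TOKEN_OF:
            raise AlphabetError(f"illegal character {c!r} in sequence")
        toks.append(TOKEN_OF[c])
    toks.append(FLANK_INDEX)
    toks.extend([PAD_INDEX] * (max_len - len(toks)))
    return TokenSequence(tokens=tuple(toks), content_length=len(seq))


def _blosum62_table() -> np.ndarray:
    """(VOCAB_SIZE, 26) table of BLOSUM62 rows over the extended alphabet."""
    from Bio.Align import substitution_matrices

    mat = substitution_matrices.load("BLOSUM62")
    symbols = str(mat.alphabet)
    table = np.zeros((VOCAB_SIZE, len(AA_ALPHABET)))
    for aa, tok in TOKEN_OF.items():
        if aa not in symbols:
            continue  # U, O: zero rows
        for j, bb in enumerate(AA_ALPHABET):
            if bb in symbols:
                table[tok, j] = mat[aa, bb]
    return table


# Residue-level physicochemical constants (standard reference values):
# molecular weight (g/mol), pKa (alpha-COOH), pKb (alpha-NH3+),
# pKx (side chain; 7.0 where the side chain is not ionizable), pI,
# hydrophobicity at pH 2 (%, Monera scale). Residue weight = MW - 18.02.
_BIOPHYS = {
    "A": (89.10, 2.34, 9.69, 7.00, 6.00, 47.0),
    "R": (174.20, 2.17, 9.04, 12.48, 10.76, -26.0),
    "N": (132.12, 2.02, 8.80, 7.00, 5.41, -41.0),
    "D": (133.10, 1.88, 9.60, 3.65, 2.77, -18.0),
    "C": (121.16, 1.96, 10.28, 8.18, 5.07, 52.0),
    "E": (147.13, 2.19, 9.67, 4.25, 3.22, 8.0),
    "Q": (146.15, 2.17, 9.13, 7.00, 5.65, -18.0),
    "G": (75.07, 2.34, 9.60, 7.00, 5.97, 0.0),
    "H": (155.16, 1.82, 9.17, 6.00, 7.59, -42.0),
    "I": (131.18, 2.36, 9.60, 7.00, 6.02, 100.0),
    "L": (131.18, 2.36, 9.60, 7.00, 5.98, 100.0),
    "K": (146.19, 2.18, 8.95, 10.53, 9.74, -37.0),
    "M": (149.21, 2.28, 9.21, 7.00, 5.74, 74.0),
    "F": (165.19, 1.83, 9.13, 7.00, 5.48, 92.0),
    "P": (115.13, 1.99, 10.60, 7.00, 6.30, -46.0),
    "S": (105.09, 2.21, 9.15, 7.00, 5.68, -7.0),
    "T": (119.12, 2.09, 9.10, 7.00, 5.60, 13.0),
    "W": (204.23, 2.83, 9.39, 7.00, 5.89, 84.0),
    "Y": (181.19, 2.20, 9.11, 10.07, 5.66, 49.0),
    "V": (117.15, 2.32, 9.62, 7.00, 5.96, 79.0),
}


def _biophysical_table(normalize: bool = True) -> np.ndarray:
    table = np.zeros((VOCAB_SIZE, 7))
    for aa, (mw, pka, pkb, pkx, pi, hphob) in _BIOPHYS.items():
        table[TOKEN_OF[aa]] = [mw, mw - 18.02, pka, pkb, pkx, pi, hphob]
    if normalize:
        rows = [TOKEN_OF[aa] for aa in _BIOPHYS]
        sub = table[rows]
        lo, hi = sub.min(axis=0), sub.max(axis=0)
        table[rows] = (sub - lo) / (hi - lo)
    return table


@dataclass
class EmbeddingSpec:
    """Token-index -> vector table for one input stream.

    The padding row is all-zero in every scheme; the start/stop token gets a
    zero row under the fixed schemes and a trainable row under ``learned``.
    """

    scheme: str = "blosum62"
    dim: int = field(default=0)
    vocab_size: int = VOCAB_SIZE
    rng_seed: int = 0
    normalize: bool = True
    table: np.ndarray = field(default=None, repr=False)
    trainable: bool = field(default=False)

    _DIMS = {"blosum62": 26, "biophysical": 7, "learned": 32}

    def __post_init__(self):
        if self.scheme not in self._DIMS:
            raise ValueError(f"unknown embedding scheme {self.scheme!r}")
        if not self.dim:
            self.dim = self._DIMS[self.scheme]
        if self.table is None:
            self.table = self._build()
        if self.table.shape != (self.vocab_size, self.dim):
            raise ValueError(f"embedding table shape {self.table.shape} != "
                             f"({self.vocab_size}, {self.dim})")
        self.trainable = self.scheme == "learned"

    def _build(self) -> np.ndarray:
        if self.scheme == "blosum62":
            return _blosum62_table()
        if self.scheme == "biophysical":
            return _biophysical_table(self.normalize)
        rng = np.random.default_rng(self.rng_seed)
        table = rng.standard_normal((self.vocab_size, self.dim)) * 0.1
        table[PAD_INDEX] = 0.0
        return table

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.table).to_csv(path, sep="\t", header=False)


def embed_tokens(ts: TokenSequence, spec: EmbeddingSpec) -> np.ndarray:
    """Embed one TokenSequence as an (L, dim) matrix; pad rows are zero."""
    arr = ts.array
    if arr.max() >= spec.vocab_size:
        raise KeyError(f"token index {arr.max()} outside embedding table")
    return spec.table[arr]


def read_fasta_sequences(path) -> list[str]:
    """Read plain sequences from a FASTA file (IDs discarded)."""
    from Bio import SeqIO

    return [str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")]
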