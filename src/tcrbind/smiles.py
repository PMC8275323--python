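"""Peptide-to-SMILES conversion, randomized augmentation and tokenization.

Short antigenic peptides are small molecules, so the epitope stream can be
encoded at atom level: the peptide is condensed residue-by-residue into a
linear molecule (free N-terminus, free C-terminal acid, L-stereocenters) and
written as SMILES. Because SMILES strings are not unique per molecule,
re-serializing from a random atom ordering yields fresh but semantically
identical strings — free data augmentation at training time.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit import RDLogger

from .encoding import FLANK_INDEX, PAD_INDEX, LengthError, TokenSequence

RDLogger.DisableLog("rdApp.*")
logger = logging.getLogger(__name__)

__all__ = ["SmilesString", "SmilesVocabulary", "peptide_to_smiles",
           "canonicalize", "augment_smiles", "split_smiles_tokens",
           "tokenize_smiles", "ConversionError"]

_STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

# atom-level SMILES tokenization: bracket atoms, two-letter halogens,
# two-digit ring closures, then single characters
_TOKEN_RE = re.compile(
    r"(\[[^\]]+\]|Br|Cl|%\d{2}|[A-Za-z]|[0-9]|\(|\)|=|#|\+|-|/|\\|\.|@|:|~|\*|\$)"
)


class ConversionError(ValueError):
    pass


@dataclass(frozen=True)
class SmilesString:
    text: str
    is_canonical: bool = False

    def __str__(self):
        return self.text


def peptide_to_smiles(seq: str, stereo: bool = True) -> SmilesString:
    """Convert a peptide (1-50 standard residues) to canonical SMILES.

    The molecule is the N-to-C condensation of the residues: one amide bond
    per junction, free termini, alpha-carbon stereochemistry included unless
    ``stereo=False``.
    """
    seq = seq.upper()
    if not 1 <= len(seq) <= 50:
        raise ConversionError(f"peptide length {len(seq)} outside 1-50")
    bad = set(seq) - _STANDARD_AA
    if bad:
        raise ConversionError(f"non-standard residues {sorted(bad)}")
    mol = Chem.MolFromSequence(seq)
    if mol is None:
        raise ConversionError(f"could not build molecule for {seq!r}")
    if not stereo:
        Chem.RemoveStereochemistry(mol)
    return SmilesString(Chem.MolToSmiles(mol), is_canonical=True)


def canonicalize(s: SmilesString | str) -> SmilesString:
    text = s.text if isinstance(s, SmilesString) else s
    mol = Chem.MolFromSmiles(text)
    if mol is None:
        raise ConversionError(f"invalid SMILES {text!r}")
    return SmilesString(Chem.MolToSmiles(mol), is_canonical=True)


def augment_smiles(s: SmilesString | str, rng_seed: int = 0) -> SmilesString:
    """Emit a randomized but semantically identical SMILES string.

    Atoms are renumbered by a seeded permutation and the molecule is
    re-serialized without canonical ordering; canonicalization of the output
    always recovers ``canonicalize(s)``. Falls back to the input on any
    serialization hiccup.
    """
    text = s.text if isinstance(s, SmilesString) else s
    mol = Chem.MolFromSmiles(text)
    if mol is None:
        return SmilesString(text)
    n = mol.GetNumAtoms()
    if n < 2:
        return SmilesString(text)
    rng = np.random.default_rng(rng_seed)
    perm = [int(i) for i in rng.permutation(n)]
    try:
        shuffled = Chem.RenumberAtoms(mol, perm)
        out = Chem.MolToSmiles(shuffled, canonical=False)
    except Exception:  # pragma: no cover - rdkit edge cases
        return SmilesString(text)
    return SmilesString(out)


def split_smiles_tokens(text: str) -> list[str]:
    """Split a SMILES string into atom-level tokens."""
    tokens = _TOKEN_RE.findall(text)
    if "".join(tokens) != text:
        leftover = re.sub(_TOKEN_RE, "", text)
        raise ConversionError(f"untokenizable SMILES characters {leftover!r}")
    return tokens


@dataclass
class SmilesVocabulary:
    """Stable token -> index mapping with reserved pad/flank/unknown slots."""

    token_to_index: dict = field(default_factory=dict)
    UNK_INDEX = 2
    _RESERVED = 3  # 0 pad, 1 start/stop, 2 unknown

    def __len__(self):
        return len(self.token_to_index) + self._RESERVED

    def add_corpus(self, smiles_list) -> "SmilesVocabulary":
        for s in smiles_list:
            text = s.text if isinstance(s, SmilesString) else s
            for tok in split_smiles_tokens(text):
                if tok not in self.token_to_index:
                    self.token_to_index[tok] = self._RESERVED + len(self.token_to_index)
        return self

    def index_of(self, token: str, strict: bool = False) -> int:
        idx = self.token_to_index.get(token)
        if idx is None:
            if strict:
                raise KeyError(f"token {token!r} not in vocabulary")
            logger.warning("SMILES token %r not in vocabulary; using <UNK>", token)
            return self.UNK_INDEX
        return idx

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.token_to_index, fh, indent=0, sort_keys=False)

    @classmethod
    def load(cls, path) -> "SmilesVocabulary":
        with open(path) as fh:
            return cls(token_to_index=json.load(fh))


def tokenize_smiles(s: SmilesString | str, vocab: SmilesVocabulary,
                    max_len: int = 500, build: bool = False) -> TokenSequence:
    """Tokenize a SMILES string into a flanked, padded TokenSequence.

    In ``build`` mode unseen tokens are added to the vocabulary; otherwise
    they map to the unknown index with a warning.
    """
    text = s.text if isinstance(s, SmilesString) else s
    tokens = split_smiles_tokens(text)
    if len(tokens) > max_len - 2:
        raise LengthError(
            f"{len(tokens)} SMILES tokens exceed max_len-2 = {max_len - 2}")
    if build:
        vocab.add_corpus([text])
    idx = [FLANK_INDEX] + [vocab.index_of(t) for t in tokens] + [FLANK_INDEX]
    idx.extend([PAD_INDEX] * (max_len - len(idx)))
    return TokenSequence(tokens=tuple(idx), content_length=len(tokens))
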