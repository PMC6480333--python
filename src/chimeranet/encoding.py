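"""One-hot encoding of fusion proteins into fixed-size tensors.

Each protein string is mapped to an ``N x 1 x C`` binary tensor: ``N`` sequence
positions (default 5000, shorter sequences padded with a dedicated pad symbol),
width 1, and ``C = 22`` channels — the 20 standard amino acids plus two
non-amino-acid symbols for the stop codon and the padding.  The channel axis
carries the residue identity so that no artificial ordering among amino acids
is imposed on the classifier, unlike an ordinal code.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import MalformedTensorError, UnknownSymbolError

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
STOP_SYMBOL = "*"
PAD_SYMBOL = "_"
DEFAULT_SEQ_LEN = 5000


@dataclass(frozen=True)
class Alphabet:
    """Ordered 22-symbol channel alphabet: amino acids, then stop, then pad."""

    symbols: str = AMINO_ACIDS + STOP_SYMBOL + PAD_SYMBOL

    def __post_init__(self) -> None:
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("alphabet symbols must be unique")
        if len(self.symbols) != 22:
            raise ValueError(f"expected 22 symbols, got {len(self.symbols)}")

    @property
    def index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.symbols)}

    @property
    def stop_index(self) -> int:
        return self.symbols.index(STOP_SYMBOL)

    @property
    def pad_index(self) -> int:
        return self.symbols.index(PAD_SYMBOL)

    def __len__(self) -> int:
        return len(self.symbols)


DEFAULT_ALPHABET = Alphabet()


@dataclass(frozen=True)
class EncodingSpec:
    """Tensor geometry: N positions x M width x C channels."""

    n: int = DEFAULT_SEQ_LEN
    m: int = 1
    c: int = 22

    def __post_init__(self) -> None:
        if self.n <= 0 or self.m <= 0 or self.c <= 0:
            raise ValueError("all dimensions must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.n, self.m, self.c)


@dataclass
class EncodedSequence:
    """One one-hot encoded protein; every position has exactly one active channel."""

    tensor: np.ndarray
    source_id: str = ""
    original_length: int = 0
    truncated: bool = False


def _symbol_indices(aa_seq: str, ab: Alphabet, lenient: bool) -> np.ndarray:
    idx = ab.index
    out = np.empty(len(aa_seq), dtype=np.int64)
    for i, s in enumerate(aa_seq):
        j = idx.get(s)
        if j is None:
            if lenient:
                j = ab.pad_index
            else:
                raise UnknownSymbolError(
                    f"symbol {s!r} at position {i} is not in the 22-letter alphabet "
                    "(ambiguity codes such as X/B/Z/U are rejected; use lenient mode to map them to pad)"
                )
        out[i] = j
    return out


def encode_onehot(
    aa_seq: str,
    spec: EncodingSpec = EncodingSpec(),
    ab: Alphabet = DEFAULT_ALPHABET,
    source_id: str = "",
    lenient: bool = False,
) -> EncodedSequence:
    """Encode a protein string into an ``(N, 1, C)`` one-hot tensor.

    Position ``i`` activates the channel of ``aa_seq[i]``; positions beyond the
    sequence end activate the pad channel.  Sequences longer than ``spec.n``
    are truncated with a logged warning.  A retained stop symbol occupies its
    own channel; unterminated sequences are padded directly after the last
    residue.
    """
    original = len(aa_seq)
    truncated = original > spec.n
    if truncated:
        logger.warning(
            "sequence %s has %d symbols; truncating to %d", source_id or "<anon>", original, spec.n
        )
        aa_seq = aa_seq[: spec.n]
    codes = _symbol_indices(aa_seq, ab, lenient)
    tensor = np.zeros(spec.shape, dtype=np.uint8)
    tensor[np.arange(len(codes)), 0, codes] = 1
    tensor[len(codes) :, 0, ab.pad_index] = 1
    return EncodedSequence(
        tensor=tensor, source_id=source_id, original_length=original, truncated=truncated
    )


def decode_onehot(es: EncodedSequence | np.ndarray, ab: Alphabet = DEFAULT_ALPHABET) -> str:
    """Invert :func:`encode_onehot`, stripping trailing pad symbols.

    Raises
    ------
    MalformedTensorError
        If any position's channel vector is not exactly one-hot.
    """
    tensor = es.tensor if isinstance(es, EncodedSequence) else es
    flat = np.asarray(tensor).reshape(tensor.shape[0], -1)
    sums = flat.sum(axis=1)
    if not np.all(sums == 1):
        bad = int(np.flatnonzero(sums != 1)[0])
        raise MalformedTensorError(f"position {bad} has channel sum {int(sums[bad])}, expected 1")
    codes = flat.argmax(axis=1)
    chars = [ab.symbols[c] for c in codes]
    out = "".join(chars).rstrip(PAD_SYMBOL)
    return out


class OneHotProteinEncoder(TransformerMixin, BaseEstimator):
    """Transform an iterable of protein strings into a stacked one-hot tensor.

    Parameters
    ----------
    seq_len : int, default=5000
        Number of encoded positions N; shorter proteins are padded, longer
        ones truncated.
    lenient : bool, default=False
        Map symbols outside the 22-letter alphabet to the pad channel instead
        of raising.

    The transform output has shape ``(n_sequences, seq_len, 1, 22)`` with
    dtype uint8, matching the classifier's expected input layout.
    """

    def __init__(self, seq_len: int = DEFAULT_SEQ_LEN, lenient: bool = False):
        self.seq_len = seq_len
        self.lenient = lenient

    def fit(self, X, y=None):
        self.alphabet_ = DEFAULT_ALPHABET
        self.spec_ = EncodingSpec(n=self.seq_len)
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "spec_"):
            self.fit(X)
        seqs = list(X)
        out = np.zeros((len(seqs), self.spec_.n, 1, len(self.alphabet_)), dtype=np.uint8)
        for i, s in enumerate(seqs):
            out[i] = encode_onehot(
                s, self.spec_, self.alphabet_, source_id=str(i), lenient=self.lenient
            ).tensor
        return out

    def inverse_transform(self, X: np.ndarray) -> list[str]:
        return [decode_onehot(X[i], self.alphabet_) for i in range(X.shape[0])]


def encode_fasta(
    fasta_path,
    tensor_path,
    index_path,
    seq_len: int = DEFAULT_SEQ_LEN,
    lenient: bool = False,
) -> int:
    """Batch-encode a protein FASTA into an ``.npz`` container plus an index TSV.

    The index lists id, original length and a truncation flag per record.
    Returns the number of sequences encoded.
    """
    import pandas as pd
    from Bio import SeqIO

    spec = EncodingSpec(n=seq_len)
    ids, lengths, trunc, tensors = [], [], [], []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        es = encode_onehot(str(rec.seq), spec, source_id=rec.id, lenient=lenient)
        ids.append(rec.id)
        lengths.append(es.original_length)
        trunc.append(es.truncated)
        tensors.append(es.tensor)
    stacked = (
        np.stack(tensors) if tensors else np.zeros((0, spec.n, 1, spec.c), dtype=np.uint8)
    )
    np.savez_compressed(tensor_path, tensors=stacked, ids=np.array(ids, dtype=object))
    pd.DataFrame({"id": ids, "original_length": lengths, "truncated": trunc}).to_csv(
        index_path, sep="\t", index=False
    )
    return len(ids)
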