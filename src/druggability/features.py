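"""Protein feature construction.

Three feature families:

* the binary GO vector ``GOpr`` — position i is 1 iff the protein is
  annotated with the i-th term of a vocabulary fitted on training data only
  (all three sub-ontologies pooled, no ancestor propagation);
* the concatenated representation ``Rpr = [Fpr | GOpr]`` with the embedding
  block first, so selection-mask indices are portable;
* the amino-acid composition (AAC) baseline — the 20-vector of standard
  residue frequencies.

``GOVectorizer`` is the estimator form of the vocabulary + encoding pair,
usable inside sklearn pipelines; ``fit_go_vocabulary``/``encode_go`` are
the functional form.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .embedding import PooledEmbedding
from .records import ProteinRecord, STANDARD_AMINO_ACIDS


@dataclass(frozen=True)
class GOVocabulary:
    """An ordered, duplicate-free universe of GO term ids."""

    terms: tuple[str, ...]

    @property
    def size(self) -> int:
        return len(self.terms)

    @property
    def index(self) -> dict[str, int]:
        return {t: i for i, t in enumerate(self.terms)}

    @classmethod
    def fit(cls, training_records: Iterable[ProteinRecord]) -> "GOVocabulary":
        """Sorted union of GO ids over *training* records only (leak-free)."""
        union: set[str] = set()
        for rec in training_records:
            union |= rec.go_terms
        return cls(terms=tuple(sorted(union)))


@dataclass
class GOBinaryVector:
    protein_id: str
    GOpr: np.ndarray

    def __post_init__(self) -> None:
        self.GOpr = np.asarray(self.GOpr, dtype=np.float64).ravel()
        if not np.all(np.isin(self.GOpr, (0.0, 1.0))):
            raise ValueError("GO vector entries must be binary")


@dataclass
class ProteinRepresentation:
    """Concatenated representation Rpr = [embedding block | GO block]."""

    protein_id: str
    Rpr: np.ndarray
    embed_dim: int

    @property
    def embedding_block(self) -> np.ndarray:
        return self.Rpr[: self.embed_dim]

    @property
    def go_block(self) -> np.ndarray:
        return self.Rpr[self.embed_dim :]


def fit_go_vocabulary(training_records: Iterable[ProteinRecord]) -> GOVocabulary:
    return GOVocabulary.fit(training_records)


def encode_go(record: ProteinRecord, vocab: GOVocabulary) -> GOBinaryVector:
    """Binary membership vector over the vocabulary; unseen terms ignored.

    An unannotated protein encodes to all zeros, so prediction still works
    when GO terms are unavailable.
    """
    vec = np.zeros(vocab.size)
    index = vocab.index
    for term in record.go_terms:
        pos = index.get(term)
        if pos is not None:
            vec[pos] = 1.0
    return GOBinaryVector(protein_id=record.id, GOpr=vec)


class GOVectorizer(BaseEstimator, TransformerMixin):
    """sklearn-style transformer from GO term sets to binary matrices."""

    def fit(self, X: Sequence[set[str] | ProteinRecord], y=None) -> "GOVectorizer":
        records = [x if isinstance(x, ProteinRecord) else _as_record(i, x) for i, x in enumerate(X)]
        self.vocabulary_ = GOVocabulary.fit(records)
        return self

    def transform(self, X: Sequence[set[str] | ProteinRecord]) -> np.ndarray:
        if not hasattr(self, "vocabulary_"):
            raise ValueError("GOVectorizer is not fitted")
        rows = []
        for i, x in enumerate(X):
            rec = x if isinstance(x, ProteinRecord) else _as_record(i, x)
            rows.append(encode_go(rec, self.vocabulary_).GOpr)
        return np.array(rows).reshape(len(rows), self.vocabulary_.size)

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.asarray(self.vocabulary_.terms, dtype=object)


def _as_record(i: int, terms: set[str]) -> ProteinRecord:
    return ProteinRecord(id=f"_{i}", sequence="X", go_terms=set(terms))


def concat_representation(
    Fpr: PooledEmbedding, GOpr: GOBinaryVector
) -> ProteinRepresentation:
    """Rpr = CONCAT(Fpr, GOpr) with the embedding block first."""
    if Fpr.protein_id != GOpr.protein_id:
        raise ValueError(
            f"protein id mismatch: embedding {Fpr.protein_id!r} vs GO {GOpr.protein_id!r}"
        )
    return ProteinRepresentation(
        protein_id=Fpr.protein_id,
        Rpr=np.concatenate([Fpr.Fpr, GOpr.GOpr]),
        embed_dim=Fpr.Fpr.size,
    )


def build_feature_matrix(
    records: Sequence[ProteinRecord],
    embeddings: Mapping[str, np.ndarray],
    vocab: GOVocabulary,
) -> np.ndarray:
    """Stack concatenated representations for a batch of records."""
    rows = []
    for rec in records:
        if rec.id not in embeddings:
            raise KeyError(f"no embedding for protein {rec.id!r}")
        emb = np.asarray(embeddings[rec.id], dtype=float).ravel()
        rows.append(np.concatenate([emb, encode_go(rec, vocab).GOpr]))
    return np.array(rows)


@dataclass
class AACVector:
    """Amino-acid composition over the 20 standard residues."""

    protein_id: str
    frequencies: np.ndarray  # ordered as STANDARD_AMINO_ACIDS

    def as_dict(self) -> dict[str, float]:
        return dict(zip(STANDARD_AMINO_ACIDS, self.frequencies))


def compute_aac(sequence: str, protein_id: str = "") -> AACVector:
    """Residue frequencies among the standard residues of the sequence.

    Extended letters are excluded from both numerator and denominator.
    """
    if len(sequence) < 1:
        raise ValueError("sequence must be non-empty")
    counts = np.array([sequence.count(aa) for aa in STANDARD_AMINO_ACIDS], dtype=float)
    total = counts.sum()
    if total == 0:
        raise ValueError("sequence contains no standard residues")
    return AACVector(protein_id=protein_id, frequencies=counts / total)
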