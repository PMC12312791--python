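"""Core record types shared across the pipeline.

A :class:`ProteinRecord` couples a sequence with its Gene Ontology
annotations and an optional binary druggability label (1 = drug target,
0 = non-drug target).  A :class:`StructureRecord` holds the CA trace of a
curated monomer.  A :class:`DatasetManifest` is an ordered, id-unique
collection of protein records with optional split tags.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

#: The 20 standard amino-acid one-letter codes, alphabetical.
STANDARD_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Extended/ambiguity letters tolerated in input sequences but flagged.
EXTENDED_AMINO_ACIDS = "BJOUXZ"


@dataclass
class ProteinRecord:
    """One protein: id, sequence, GO term set and optional binary label."""

    id: str
    sequence: str
    go_terms: set[str] = field(default_factory=set)
    label: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"protein {self.id!r}: sequence must be non-empty")
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(
                f"protein {self.id!r}: label must be 0, 1 or None, got {self.label!r}"
            )
        self.go_terms = set(self.go_terms)


@dataclass
class StructureRecord:
    """A curated single-chain CA trace with coordinates in Å."""

    id: str
    chain_id: str
    ca_coords: np.ndarray
    resolution: float | None = None

    def __post_init__(self) -> None:
        self.ca_coords = np.asarray(self.ca_coords, dtype=float).reshape(-1, 3)
        if not np.all(np.isfinite(self.ca_coords)):
            raise ValueError(f"structure {self.id!r}: non-finite CA coordinate")

    @property
    def n_residues(self) -> int:
        return self.ca_coords.shape[0]


@dataclass
class DatasetManifest:
    """An ordered collection of protein records with unique ids."""

    records: list[ProteinRecord]
    split_tags: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise ValueError(f"duplicate protein id in manifest: {rec.id!r}")
            seen.add(rec.id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def ids(self) -> list[str]:
        return [rec.id for rec in self.records]

    def labels(self) -> np.ndarray:
        """Label vector; raises if any record is unlabeled."""
        missing = [rec.id for rec in self.records if rec.label is None]
        if missing:
            raise ValueError(f"unlabeled records in manifest: {missing[:5]}")
        return np.array([rec.label for rec in self.records], dtype=int)

    def class_counts(self) -> tuple[int, int]:
        y = self.labels()
        return int(np.sum(y == 0)), int(np.sum(y == 1))

    def subset(self, indices: Iterable[int]) -> "DatasetManifest":
        recs = [self.records[i] for i in indices]
        tags = {r.id: self.split_tags[r.id] for r in recs if r.id in self.split_tags}
        return DatasetManifest(records=recs, split_tags=tags)

    def attach_go(self, annotations: Mapping[str, set[str]]) -> None:
        """Attach GO annotations in place; ids absent from the map get none."""
        for rec in self.records:
            if rec.id in annotations:
                rec.go_terms = set(annotations[rec.id])
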