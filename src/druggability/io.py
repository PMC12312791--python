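"""Readers and writers for the standard formats the pipeline touches.

FASTA parsing is delegated to Bio.SeqIO; PDB parsing to Bio.PDB.  On top of
the PDB parser this module applies the monomer-curation rules used to build
a clean CA trace: a single protein chain, no HETATM records (waters, ions,
ligands), one CA per residue with alternate locations resolved by highest
occupancy (ties broken by file order).

GO annotations are accepted either as GAF 2.x (17-column, '!' comments) or
as a two-column TSV ``protein_id<TAB>GO_id``.
"""

from __future__ import annotations

import csv
import re
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import SeqIO
from Bio.PDB import PDBParser
from Bio.PDB.Atom import DisorderedAtom

from .records import (
    DatasetManifest,
    EXTENDED_AMINO_ACIDS,
    ProteinRecord,
    STANDARD_AMINO_ACIDS,
    StructureRecord,
)

_GO_ID_RE = re.compile(r"^GO:\d{7}$")
_VALID_RESIDUES = set(STANDARD_AMINO_ACIDS) | set(EXTENDED_AMINO_ACIDS)


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a multi-record FASTA file into :class:`ProteinRecord` objects.

    The header token before the first whitespace becomes the id; sequences
    are upper-cased.  Extended letters (B, J, O, U, X, Z) are tolerated and
    flagged in ``meta["nonstandard_residues"]``; anything else (gaps, stop
    codons, digits) is rejected with its 1-based position.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        pid = entry.id
        if pid in seen:
            raise FormatError(f"duplicate FASTA id: {pid!r}")
        seen.add(pid)
        seq = str(entry.seq).upper()
        nonstandard = []
        for pos, ch in enumerate(seq, start=1):
            if ch not in _VALID_RESIDUES:
                raise FormatError(
                    f"invalid residue {ch!r} at position {pos} in record {pid!r}"
                )
            if ch in EXTENDED_AMINO_ACIDS:
                nonstandard.append(pos)
        meta = {"description": entry.description}
        if nonstandard:
            meta["nonstandard_residues"] = nonstandard
        records.append(ProteinRecord(id=pid, sequence=seq, meta=meta))
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Sequence[ProteinRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GO annotations
# ---------------------------------------------------------------------------

def _check_go_id(go_id: str, lineno: int) -> None:
    if not _GO_ID_RE.match(go_id):
        raise FormatError(f"malformed GO id {go_id!r} on line {lineno}")


def read_go_annotations(path: str | Path, format: str = "tsv") -> dict[str, set[str]]:
    """Read per-protein GO annotations as a map ``id -> set of GO ids``.

    ``format="tsv"`` expects two tab-separated columns (protein id, GO id).
    ``format="gaf"`` parses GAF 2.x: '!'-prefixed comment lines are skipped,
    the protein id is column 2 (DB Object ID), the GO id column 5, and rows
    whose qualifier (column 4) contains ``NOT`` are dropped.

    Rows for proteins absent from any particular dataset are retained; the
    caller filters downstream.
    """
    if format not in ("tsv", "gaf"):
        raise ValueError(f"unknown annotation format {format!r}")
    out: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if format == "gaf":
                if line.startswith("!"):
                    continue
                cols = line.split("\t")
                if len(cols) < 5:
                    raise FormatError(f"GAF line {lineno} has {len(cols)} columns, expected >= 5")
                pid, qualifier, go_id = cols[1], cols[3], cols[4]
                if "NOT" in qualifier.split("|"):
                    continue
            else:
                cols = line.split("\t")
                if len(cols) < 2:
                    raise FormatError(f"TSV line {lineno} has {len(cols)} columns, expected 2")
                pid, go_id = cols[0], cols[1]
            _check_go_id(go_id, lineno)
            out.setdefault(pid, set()).add(go_id)
    return out


# ---------------------------------------------------------------------------
# PDB monomer curation
# ---------------------------------------------------------------------------

def _resolve_altloc(atom) -> object:
    """Pick one coordinate for a possibly-disordered atom.

    Highest occupancy wins; ties keep the variant that appears first in the
    file (the child list preserves file order).
    """
    if not isinstance(atom, DisorderedAtom):
        return atom
    best = None
    best_occ = -np.inf
    for child in atom.disordered_get_list():
        occ = child.get_occupancy()
        occ = -np.inf if occ is None else occ
        if occ > best_occ:  # strict: ties keep the earlier variant
            best, best_occ = child, occ
    return best


def read_pdb_monomer(path: str | Path, chain: str | None = None) -> StructureRecord:
    """Extract the CA trace of a single protein chain from a legacy PDB file.

    All HETATM records (waters, ions, ligands, other heteroatoms) are
    dropped.  By default the first chain in file order containing at least
    one standard (ATOM) residue is used; residues without a resolved CA are
    skipped.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        parser = PDBParser(QUIET=True)
        structure = parser.get_structure(Path(path).stem, str(path))
    model = next(structure.get_models())

    protein_chains = []
    for ch in model:
        if any(res.id[0] == " " for res in ch):
            protein_chains.append(ch.id)
    if not protein_chains:
        raise FormatError(f"no protein chain found in {path}")
    if chain is None:
        chain = protein_chains[0]
    elif chain not in protein_chains:
        raise FormatError(
            f"chain {chain!r} not found in {path}; available protein chains: {protein_chains}"
        )

    coords = []
    for res in model[chain]:
        if res.id[0] != " ":  # HETATM (waters, ions, ligands)
            continue
        if "CA" not in res:
            continue
        atom = _resolve_altloc(res["CA"])
        coords.append(atom.get_coord())
    if not coords:
        raise FormatError(f"chain {chain!r} in {path} has no CA atoms")

    resolution = structure.header.get("resolution") if structure.header else None
    return StructureRecord(
        id=Path(path).stem,
        chain_id=chain,
        ca_coords=np.asarray(coords, dtype=float),
        resolution=resolution,
    )


def select_best_structure(
    candidates: Sequence[tuple[float, int]], full_length: int
) -> int:
    """Pick the index of the best structure candidate.

    Each candidate is ``(resolution_angstrom, covered_length)``.  Candidates
    covering less than half of ``full_length`` are removed; among survivors
    the lowest resolution value wins, ties go to the longest coverage, and
    remaining ties to the earliest index.
    """
    if full_length < 1:
        raise ValueError("full_length must be >= 1")
    survivors = [
        (res, cov, i)
        for i, (res, cov) in enumerate(candidates)
        if cov / full_length >= 0.5
    ]
    if not survivors:
        raise ValueError("no structure covers half the sequence")
    survivors.sort(key=lambda t: (t[0], -t[1], t[2]))
    return survivors[0][2]


# ---------------------------------------------------------------------------
# Dataset manifest (CSV: id,label,split)
# ---------------------------------------------------------------------------

def read_manifest(path: str | Path, sequences: dict[str, str] | None = None) -> DatasetManifest:
    """Read a dataset manifest CSV with columns ``id,label[,split]``.

    If ``sequences`` is given (id -> sequence, e.g. from :func:`read_fasta`),
    records get real sequences; otherwise a one-residue placeholder is used
    so label-only workflows still round-trip.
    """
    records: list[ProteinRecord] = []
    split_tags: dict[str, str] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "id" not in reader.fieldnames:
            raise FormatError(f"manifest {path} must have an 'id' column")
        for row in reader:
            pid = row["id"]
            label_s = (row.get("label") or "").strip()
            label = int(label_s) if label_s else None
            seq = sequences.get(pid, "X") if sequences else "X"
            records.append(ProteinRecord(id=pid, sequence=seq, label=label))
            split = (row.get("split") or "").strip()
            if split:
                split_tags[pid] = split
    return DatasetManifest(records=records, split_tags=split_tags)


def write_manifest(manifest: DatasetManifest, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "label", "split"])
        for rec in manifest.records:
            label = "" if rec.label is None else rec.label
            writer.writerow([rec.id, label, manifest.split_tags.get(rec.id, "")])
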