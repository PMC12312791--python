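"""Synthetic labeled datasets with the statistical structure the pipeline
assumes.

The generator emulates a two-class protein set in which the signal lives
exactly where the real pipeline expects it:

* a class-dependent mean shift of ``effect_size`` (in units of the
  across-protein SD of each dimension) on ``n_informative`` designated
  embedding dimensions, injected into the pooled-embedding cache so that
  downstream stages are agnostic to its origin;
* class-enriched GO terms, present with probability ``go_prob_pos`` in
  positives and ``go_prob_neg`` in negatives, all other terms at a common
  background rate;
* uniform random sequences (optionally with a composition bias in the
  positive class, for AAC-baseline experiments);
* toy CA-trace structures: self-avoiding random walks with the idealized
  3.8 Å consecutive CA–CA spacing, written as valid single-chain PDB files.

Each artifact draws from its own named random stream, so components are
independently reproducible from the single master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .embedding import EmbedderConfig, SyntheticEmbedder, write_embedding_cache
from .io import write_fasta, write_manifest
from .records import DatasetManifest, ProteinRecord, STANDARD_AMINO_ACIDS, StructureRecord


@dataclass
class SimConfig:
    """Study conditions of the synthetic two-class protein set."""

    n_pos: int = 300
    n_neg: int = 300
    seq_length_range: tuple[int, int] = (50, 400)
    embed_dim: int = 64
    n_informative: int = 10
    effect_size: float = 3.0  # SD units of mean shift on informative dims
    n_go_terms: int = 100
    n_enriched_go: int = 10
    go_prob_pos: float = 0.8
    go_prob_neg: float = 0.2
    background_go_prob: float = 0.05
    composition_bias: float = 0.0  # tilt of positive-class residue frequencies
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("n_pos and n_neg must be >= 1")
        if not (0 <= self.n_informative <= self.embed_dim):
            raise ValueError("n_informative must be in [0, embed_dim]")
        for name in ("go_prob_pos", "go_prob_neg", "background_go_prob"):
            p = getattr(self, name)
            if not (0 <= p <= 1):
                raise ValueError(f"{name} must be a probability, got {p}")
        lo, hi = self.seq_length_range
        if lo < 1 or hi < lo:
            raise ValueError("invalid seq_length_range")


@dataclass
class SimulatedDataset:
    """In-memory bundle of everything the pipeline ingests."""

    manifest: DatasetManifest
    embeddings: dict[str, np.ndarray]
    annotations: dict[str, set[str]]
    informative_dims: np.ndarray
    enriched_terms: tuple[str, ...]
    embedder_config: EmbedderConfig
    config: SimConfig = field(repr=False, default=None)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write FASTA, TSV annotations, CSV manifest and HDF5 cache."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "proteins.fasta",
            "annotations": outdir / "annotations.tsv",
            "manifest": outdir / "manifest.csv",
            "cache": outdir / "embeddings.h5",
        }
        write_fasta(self.manifest.records, paths["fasta"])
        with open(paths["annotations"], "w", encoding="utf-8") as fh:
            for pid in self.manifest.ids:
                for term in sorted(self.annotations.get(pid, ())):
                    fh.write(f"{pid}\t{term}\n")
        write_manifest(self.manifest, paths["manifest"])
        write_embedding_cache(paths["cache"], self.embeddings, self.embedder_config)
        return paths


def _random_sequence(rng: np.random.Generator, length: int, bias: float) -> str:
    probs = np.full(20, 1 / 20)
    if bias > 0:
        # tilt the first half of the alphabet up, second half down
        probs = probs + bias * np.where(np.arange(20) < 10, 1 / 20, -1 / 20)
        probs = probs / probs.sum()
    letters = rng.choice(list(STANDARD_AMINO_ACIDS), size=length, p=probs)
    return "".join(letters)


def generate_dataset(config: SimConfig) -> SimulatedDataset:
    """Generate a labeled two-class dataset, reproducible from the seed."""
    streams = np.random.SeedSequence(config.seed).spawn(3)
    seq_rng = np.random.default_rng(streams[0])
    go_rng = np.random.default_rng(streams[1])
    embed_seed = int(np.random.default_rng(streams[2]).integers(2**31))

    n = config.n_pos + config.n_neg
    labels = np.array([1] * config.n_pos + [0] * config.n_neg)
    width = len(str(n))
    ids = [f"SIM{i:0{width}d}" for i in range(n)]

    lo, hi = config.seq_length_range
    lengths = seq_rng.integers(lo, hi + 1, size=n)
    sequences = {}
    for pid, lab, length in zip(ids, labels, lengths):
        bias = config.composition_bias if lab == 1 else 0.0
        sequences[pid] = _random_sequence(seq_rng, int(length), bias)

    # pooled embeddings from the synthetic backend, then a class-dependent
    # mean shift (in across-protein SD units) on the designated dimensions
    embedder_config = EmbedderConfig(
        backend="synthetic", dim=config.embed_dim, seed=embed_seed
    )
    embedder = SyntheticEmbedder(dim=config.embed_dim, seed=embed_seed)
    X = np.array([embedder.embed(sequences[pid]).mean(axis=0) for pid in ids])
    informative = np.arange(config.n_informative)
    if config.n_informative > 0 and config.effect_size != 0:
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X[np.ix_(labels == 1, informative)] += config.effect_size * sd[informative]
    embeddings = {pid: X[i].copy() for i, pid in enumerate(ids)}

    # GO annotations: enriched terms are class-dependent, the rest background
    terms = tuple(f"GO:{i + 1:07d}" for i in range(config.n_go_terms))
    enriched = terms[: config.n_enriched_go]
    annotations: dict[str, set[str]] = {}
    for pid, lab in zip(ids, labels):
        p_enriched = config.go_prob_pos if lab == 1 else config.go_prob_neg
        held = set()
        for j, term in enumerate(terms):
            p = p_enriched if j < config.n_enriched_go else config.background_go_prob
            if go_rng.random() < p:
                held.add(term)
        annotations[pid] = held

    records = [
        ProteinRecord(
            id=pid,
            sequence=sequences[pid],
            go_terms=set(annotations[pid]),
            label=int(lab),
        )
        for pid, lab in zip(ids, labels)
    ]
    return SimulatedDataset(
        manifest=DatasetManifest(records=records),
        embeddings=embeddings,
        annotations=annotations,
        informative_dims=informative,
        enriched_terms=enriched,
        embedder_config=embedder_config,
        config=config,
    )


# ---------------------------------------------------------------------------
# Toy CA-trace structures
# ---------------------------------------------------------------------------

_CA_STEP = 3.8  # idealized consecutive CA–CA spacing, Å
_MIN_SEPARATION = 4.0  # enforced between non-consecutive residues, Å


def generate_toy_structure(
    n_residues: int,
    seed: int = 0,
    path: str | Path | None = None,
    max_tries: int = 200,
    max_restarts: int = 50,
) -> StructureRecord:
    """Self-avoiding random CA walk; optionally written as a PDB file.

    Consecutive CA–CA distances are exactly 3.8 Å; non-consecutive pairs
    are kept at least 4.0 Å apart by rejection sampling.
    """
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    rng = np.random.default_rng(seed)
    for _ in range(max_restarts):
        coords = [np.zeros(3)]
        failed = False
        while len(coords) < n_residues:
            placed = False
            for _ in range(max_tries):
                direction = rng.standard_normal(3)
                direction /= np.linalg.norm(direction)
                candidate = coords[-1] + _CA_STEP * direction
                prior = np.asarray(coords[:-1])
                if prior.size and np.min(
                    np.linalg.norm(prior - candidate, axis=1)
                ) < _MIN_SEPARATION:
                    continue
                coords.append(candidate)
                placed = True
                break
            if not placed:
                failed = True
                break
        if not failed:
            record = StructureRecord(
                id=f"TOY{seed}", chain_id="A", ca_coords=np.asarray(coords)
            )
            if path is not None:
                write_ca_pdb(record, path)
            return record
    raise RuntimeError(
        f"could not place {n_residues} residues within the rejection budget; "
        "try a smaller n_residues"
    )


def write_ca_pdb(record: StructureRecord, path: str | Path) -> None:
    """Write a CA-only single-chain structure as a legacy PDB file."""
    lines = []
    for i, (x, y, z) in enumerate(record.ca_coords, start=1):
        lines.append(
            f"ATOM  {i:>5d}  CA  ALA {record.chain_id:1s}{i:>4d}    "
            f"{x:>8.3f}{y:>8.3f}{z:>8.3f}{1.00:>6.2f}{0.00:>6.2f}           C"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
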