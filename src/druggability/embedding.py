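"""Per-residue embeddings and mean pooling.

A protein of length L is mapped to a matrix ``F`` of shape (L', D) with
``L' = min(L, max_tokens)`` (sequences are truncated to their N-terminal
prefix), and the per-protein representation is the unweighted arithmetic
mean of the rows of ``F``.

Two backends satisfy the same contract (one D-vector per residue of the
truncated sequence):

* ``pretrained`` — a large pretrained protein language model; the default
  configuration names a 33-layer, 1280-dimensional checkpoint.  The adapter
  is config-gated and requires the optional model runtime to be installed;
  it is never needed for offline work.
* ``synthetic`` — a deterministic seeded-hash embedder: residue i's vector
  is a hash expansion of the residue identity plus its k-mer neighborhood,
  drawn from a standard-normal stream keyed by (seed, dim, context), which
  has zero mean and unit variance per dimension over the context alphabet
  in distribution.  Same (sequence, seed, dim, window) => bit-identical
  output.  All tests and offline workflows use this backend.

Pooled embeddings are cached in HDF5, one dataset per protein id, with the
backend configuration recorded as file attributes.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np

_PAD = "^"  # boundary placeholder for k-mer contexts


@dataclass
class EmbedderConfig:
    """Configuration of the residue-embedding backend."""

    backend: str = "synthetic"
    checkpoint_id: str = "esm2_t33_650M_UR50D"
    layer_index: int = 33
    dim: int = 1280
    max_tokens: int = 1024
    seed: int = 0
    kmer_window: int = 3

    def __post_init__(self) -> None:
        if self.backend not in ("pretrained", "synthetic"):
            raise ValueError(f"unknown embedder backend {self.backend!r}")
        if self.dim < 1:
            raise ValueError("dim must be >= 1")
        if self.max_tokens < 1:
            raise ValueError("max_tokens must be >= 1")
        if self.layer_index < 0:
            raise ValueError("layer_index must be >= 0")
        if self.kmer_window < 1 or self.kmer_window % 2 == 0:
            raise ValueError("kmer_window must be a positive odd integer")

    def fingerprint(self) -> str:
        """Short stable identifier of the backend configuration."""
        key = f"{self.backend}|{self.checkpoint_id}|{self.layer_index}|{self.dim}|{self.seed}|{self.kmer_window}"
        return hashlib.sha256(key.encode()).hexdigest()[:16]


@dataclass
class ResidueEmbeddingMatrix:
    """Per-residue embedding matrix F of shape (L', D)."""

    protein_id: str
    F: np.ndarray

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        if self.F.ndim != 2 or self.F.shape[0] < 1:
            raise ValueError("F must be a non-empty 2-D matrix")
        if not np.all(np.isfinite(self.F)):
            raise ValueError(f"non-finite embedding entries for {self.protein_id!r}")


@dataclass
class PooledEmbedding:
    """Per-protein embedding: the row mean of a residue matrix."""

    protein_id: str
    Fpr: np.ndarray

    def __post_init__(self) -> None:
        self.Fpr = np.asarray(self.Fpr, dtype=float).ravel()
        if not np.all(np.isfinite(self.Fpr)):
            raise ValueError(f"non-finite pooled embedding for {self.protein_id!r}")


class EmbedderUnavailableError(RuntimeError):
    """The requested backend cannot run in this environment."""


def truncate_sequence(sequence: str, max_tokens: int) -> str:
    """Keep the N-terminal prefix of at most ``max_tokens`` residues."""
    if max_tokens < 1:
        raise ValueError("max_tokens must be >= 1")
    if len(sequence) < 1:
        raise ValueError("sequence must be non-empty")
    return sequence[:max_tokens]


def _context_vector(context: str, seed: int, dim: int) -> np.ndarray:
    digest = hashlib.blake2b(
        f"{seed}|{dim}|{context}".encode(), digest_size=8
    ).digest()
    sub = int.from_bytes(digest, "little") % (2**63)
    return np.random.default_rng(sub).standard_normal(dim)


class SyntheticEmbedder:
    """Deterministic hash-based residue embedder (offline stand-in backend).

    Each residue's vector depends only on its k-mer context, the seed and
    the dimension, so identical configurations give bit-identical matrices.
    """

    def __init__(self, dim: int = 64, seed: int = 0, kmer_window: int = 3) -> None:
        self.dim = dim
        self.seed = seed
        self.kmer_window = kmer_window
        self._cache: dict[str, np.ndarray] = {}

    def embed(self, sequence: str) -> np.ndarray:
        half = self.kmer_window // 2
        padded = _PAD * half + sequence + _PAD * half
        rows = np.empty((len(sequence), self.dim))
        for i in range(len(sequence)):
            context = padded[i : i + self.kmer_window]
            vec = self._cache.get(context)
            if vec is None:
                vec = _context_vector(context, self.seed, self.dim)
                self._cache[context] = vec
            rows[i] = vec
        return rows


def _pretrained_embed(sequence: str, config: EmbedderConfig) -> np.ndarray:
    try:
        import esm  # type: ignore
        import torch  # type: ignore
    except ImportError as exc:  # pragma: no cover - requires the model runtime
        raise EmbedderUnavailableError(
            f"pretrained checkpoint {config.checkpoint_id!r} requires the "
            "fair-esm/torch runtime, which is not installed; use "
            "backend='synthetic' for offline work"
        ) from exc
    # pragma: no cover - exercised only where the runtime is installed
    model, alphabet = esm.pretrained.load_model_and_alphabet(config.checkpoint_id)
    model.eval()
    batch_converter = alphabet.get_batch_converter()
    _, _, tokens = batch_converter([("query", sequence)])
    with torch.no_grad():
        out = model(tokens, repr_layers=[config.layer_index])
    rep = out["representations"][config.layer_index][0]
    # strip begin/end special tokens so only residue positions are pooled
    return rep[1 : len(sequence) + 1].numpy().astype(float)


def embed_residues(
    sequence: str, config: EmbedderConfig, protein_id: str = ""
) -> ResidueEmbeddingMatrix:
    """Embed a sequence into a per-residue matrix, truncating internally."""
    seq = truncate_sequence(sequence, config.max_tokens)
    if config.backend == "synthetic":
        embedder = SyntheticEmbedder(
            dim=config.dim, seed=config.seed, kmer_window=config.kmer_window
        )
        F = embedder.embed(seq)
    else:
        F = _pretrained_embed(seq, config)
    return ResidueEmbeddingMatrix(protein_id=protein_id, F=F)


def mean_pool(F: ResidueEmbeddingMatrix | np.ndarray, protein_id: str | None = None) -> PooledEmbedding:
    """Average the residue vectors: ``Fpr[d] = (1/L') sum_i F[i, d]``."""
    if isinstance(F, ResidueEmbeddingMatrix):
        matrix, pid = F.F, F.protein_id
    else:
        matrix, pid = np.asarray(F, dtype=float), protein_id or ""
    if matrix.ndim != 2 or matrix.shape[0] < 1:
        raise ValueError("cannot pool an empty embedding matrix")
    return PooledEmbedding(protein_id=pid, Fpr=matrix.mean(axis=0))


# ---------------------------------------------------------------------------
# HDF5 cache of pooled embeddings
# ---------------------------------------------------------------------------

def write_embedding_cache(
    path: str | Path, pooled: dict[str, np.ndarray], config: EmbedderConfig
) -> None:
    """Write pooled embeddings to HDF5, one dataset per protein id."""
    with h5py.File(path, "w") as fh:
        fh.attrs["backend"] = config.backend
        fh.attrs["checkpoint_id"] = config.checkpoint_id
        fh.attrs["layer_index"] = config.layer_index
        fh.attrs["dim"] = config.dim
        fh.attrs["fingerprint"] = config.fingerprint()
        for pid in sorted(pooled):
            # track_times=False keeps identical runs byte-identical on disk
            fh.create_dataset(
                pid, data=np.asarray(pooled[pid], dtype=np.float64), track_times=False
            )


def read_embedding_cache(path: str | Path) -> tuple[dict[str, np.ndarray], dict]:
    """Read a pooled-embedding cache; returns (id -> vector, attributes)."""
    with h5py.File(path, "r") as fh:
        attrs = {k: fh.attrs[k] for k in fh.attrs}
        pooled = {pid: np.asarray(fh[pid], dtype=float) for pid in fh}
    return pooled, attrs


def pool_sequences(
    sequences: dict[str, str], config: EmbedderConfig
) -> dict[str, np.ndarray]:
    """Embed and mean-pool a batch of sequences."""
    return {
        pid: mean_pool(embed_residues(seq, config, protein_id=pid)).Fpr
        for pid, seq in sequences.items()
    }
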