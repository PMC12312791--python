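"""End-to-end druggability model: GO vocabulary + selection + neural head.

:class:`DruggabilityPipeline` owns every data-dependent fitting step, so
that restricting ``fit`` to a training fold automatically makes nested
cross-validation leak-free: the GO vocabulary, the feature standardizer,
the selection mask and the network are all (re)fitted inside ``fit`` and
nothing in the prediction path reads labels.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .embedding import EmbedderConfig
from .features import GOVocabulary, build_feature_matrix
from .network import DNNConfig, DruggabilityNet
from .records import ProteinRecord
from .selection import SVMFeatureSelector


class DruggabilityPipeline(BaseEstimator, ClassifierMixin):
    """Fit on labeled protein records plus a pooled-embedding lookup.

    Parameters
    ----------
    k : number of features kept by the margin-weight selector.
    C : regularization constant of the selection SVM.
    net_config : hyperparameters of the neural head (defaults used if None).
    random_state : master seed; the head's seed is derived from it.
    """

    def __init__(
        self,
        k: int = 4000,
        C: float = 1.0,
        net_config: DNNConfig | None = None,
        random_state: int = 0,
    ) -> None:
        self.k = k
        self.C = C
        self.net_config = net_config
        self.random_state = random_state

    def _net(self) -> DruggabilityNet:
        cfg = self.net_config if self.net_config is not None else DNNConfig()
        net = DruggabilityNet.from_config(cfg)
        net.set_params(random_state=int(self.random_state) % (2**31))
        return net

    def fit(
        self,
        records: Sequence[ProteinRecord],
        embeddings: Mapping[str, np.ndarray],
        y: np.ndarray | None = None,
    ) -> "DruggabilityPipeline":
        if y is None:
            if any(rec.label is None for rec in records):
                raise ValueError("all training records must be labeled")
            y = np.array([rec.label for rec in records], dtype=int)
        y = np.asarray(y, dtype=int)
        self.vocab_ = GOVocabulary.fit(records)
        X = build_feature_matrix(records, embeddings, self.vocab_)
        self.embed_dim_ = X.shape[1] - self.vocab_.size
        self.selector_ = SVMFeatureSelector(
            k=self.k, C=self.C, random_state=int(self.random_state) % (2**31)
        ).fit(X, y)
        Xk = self.selector_.transform(X)
        self.net_ = self._net().fit(Xk, y)
        self.classes_ = np.array([0, 1])
        return self

    def _features(
        self, records: Sequence[ProteinRecord], embeddings: Mapping[str, np.ndarray]
    ) -> np.ndarray:
        X = build_feature_matrix(records, embeddings, self.vocab_)
        return self.selector_.transform(X)

    def predict_scores(
        self, records: Sequence[ProteinRecord], embeddings: Mapping[str, np.ndarray]
    ) -> np.ndarray:
        """Druggability scores in [0, 1], one per record."""
        if not hasattr(self, "net_"):
            raise ValueError("pipeline is not fitted")
        return self.net_.predict_scores(self._features(records, embeddings))

    def predict(
        self, records: Sequence[ProteinRecord], embeddings: Mapping[str, np.ndarray]
    ) -> np.ndarray:
        return (self.predict_scores(records, embeddings) >= 0.5).astype(int)

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path, embedder_config: EmbedderConfig | None = None) -> None:
        """Write a model bundle: network weights + mask + vocabulary."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.net_.save(path)
        self.selector_.mask_.to_json(path / "mask.json")
        vocab_terms = list(self.vocab_.terms)
        vocab_hash = hashlib.sha256("\n".join(vocab_terms).encode()).hexdigest()[:16]
        bundle = {
            "k": self.k,
            "C": self.C,
            "random_state": self.random_state,
            "embed_dim": self.embed_dim_,
            "vocabulary": vocab_terms,
            "vocabulary_hash": vocab_hash,
            "embedder_fingerprint": embedder_config.fingerprint() if embedder_config else None,
        }
        (path / "pipeline.json").write_text(json.dumps(bundle, indent=2), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "DruggabilityPipeline":
        from .selection import SelectionMask

        path = Path(path)
        bundle = json.loads((path / "pipeline.json").read_text(encoding="utf-8"))
        pipe = cls(k=bundle["k"], C=bundle["C"], random_state=bundle["random_state"])
        pipe.vocab_ = GOVocabulary(terms=tuple(bundle["vocabulary"]))
        pipe.embed_dim_ = bundle["embed_dim"]
        selector = SVMFeatureSelector(k=bundle["k"], C=bundle["C"])
        selector.mask_ = SelectionMask.from_json(path / "mask.json")
        selector.n_features_in_ = selector.mask_.source_dim
        pipe.selector_ = selector
        pipe.net_ = DruggabilityNet.load(path)
        pipe.classes_ = np.array([0, 1])
        return pipe
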