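"""End-to-end predictor: encode -> one-vs-one SVM -> consensus filter.

:class:`SecondaryStructurePredictor` bundles the window encoder (with its
training-set conformation table), the profile normalization spec, the
three binary SVMs and the filter configuration, so a saved model predicts
on a fresh FASTA + PSSM pair with no other state.
"""

from __future__ import annotations

from pathlib import Path

import joblib
import numpy as np
from sklearn.base import BaseEstimator

from .features import WindowEncoder
from .metrics import SovReport, evaluate
from .pssm import DEFAULT_NORMALIZATION, NormalizationSpec, PssmProfile, normalize_profile
from .sequences import ProteinChain, StructureString
from .smoothing import DEFAULT_FILTER, FilterConfig, apply_filter
from .svm import OneVsOneStructureSVM

_FORMAT_VERSION = 1


class SecondaryStructurePredictor(BaseEstimator):
    """Three-state secondary-structure predictor.

    Parameters
    ----------
    window_size : odd int in [7, 19], default 13
    C, gamma : RBF-SVM hyper-parameters, default 2**1 and 2**-4 (the values
        selected by grid search at window size 13)
    normalization : how raw PSSM log-odds reach [0, 1]; baked into the model
    filter_config : Case H / Case E consensus-rule settings
    """

    def __init__(
        self,
        window_size: int = 13,
        C: float = 2.0,
        gamma: float = 2.0**-4,
        normalization: NormalizationSpec = DEFAULT_NORMALIZATION,
        filter_config: FilterConfig = DEFAULT_FILTER,
    ):
        self.window_size = window_size
        self.C = C
        self.gamma = gamma
        self.normalization = normalization
        self.filter_config = filter_config

    def _normalize(self, profiles: dict[str, PssmProfile]) -> dict[str, PssmProfile]:
        return {
            cid: p if p.normalized else normalize_profile(p, self.normalization)
            for cid, p in profiles.items()
        }

    def fit(
        self,
        chains: list[ProteinChain],
        structures: list[StructureString],
        profiles: dict[str, PssmProfile],
    ) -> "SecondaryStructurePredictor":
        if len(chains) != len(structures):
            raise ValueError("need one structure string per chain")
        pairs = list(zip(chains, structures))
        self.encoder_ = WindowEncoder(window_size=self.window_size).fit(pairs)
        X = self.encoder_.transform(chains, self._normalize(profiles))
        y = np.array([s for ss in structures for s in ss.states])
        self.svm_ = OneVsOneStructureSVM(C=self.C, gamma=self.gamma).fit(X, y)
        return self

    def predict(
        self,
        chains: list[ProteinChain],
        profiles: dict[str, PssmProfile],
        filtered: bool = True,
    ) -> dict[str, StructureString]:
        """Per-chain predicted 3-state strings (filter applied by default)."""
        if not hasattr(self, "svm_"):
            raise RuntimeError("predictor is not fitted")
        normalized = self._normalize(profiles)
        out = {}
        for chain in chains:
            X = self.encoder_.transform([chain], normalized)
            raw = StructureString("".join(self.svm_.predict(X)))
            out[chain.id] = apply_filter(raw, self.filter_config) if filtered else raw
        return out

    def score_report(
        self,
        chains: list[ProteinChain],
        structures: list[StructureString],
        profiles: dict[str, PssmProfile],
        filtered: bool = True,
    ) -> SovReport:
        preds = self.predict(chains, profiles, filtered=filtered)
        return evaluate(
            [ss.states for ss in structures],
            [preds[c.id].states for c in chains],
        )

    def save(self, path: str | Path) -> None:
        """Persist the full bundle (encoder, normalization, SVMs, filter)."""
        joblib.dump({"format_version": _FORMAT_VERSION, "model": self}, path)

    @classmethod
    def load(cls, path: str | Path) -> "SecondaryStructurePredictor":
        blob = joblib.load(path)
        if blob.get("format_version") != _FORMAT_VERSION:
            raise ValueError(f"unsupported model file version in {path}")
        return blob["model"]
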