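"""Mechanism-level burden profiles: one sparse autoencoder per mechanism.

The transformer turns a patients × SNPs dosage matrix into a patients ×
mechanisms matrix of burden scores in [0, 1] (a valid NMF input), and keeps
per-SNP contribution weights for interpretation. SNP columns are sorted
lexicographically by id inside each mechanism before training, so scores do
not depend on genotype column order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .autoencoder import SparseAutoencoder
from .catalog import SnpGrouping
from .io import GenotypeMatrix

__all__ = [
    "EncoderSpec",
    "BurdenEncoder",
    "BurdenProfile",
    "compute_burden_scores",
    "apply_encoders",
    "snp_contributions",
]


@dataclass
class EncoderSpec:
    """Training controls shared by all per-mechanism autoencoders."""

    bottleneck_dim: int = 1
    sparsity_weight: float = 1e-3
    ridge: float = 1e-3
    learning_rate: float = 0.05
    max_epochs: int = 800
    tol: float = 1e-6
    standardize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bottleneck_dim < 1:
            raise ValueError("bottleneck_dim must be >= 1")
        if self.sparsity_weight < 0:
            raise ValueError("sparsity_weight must be >= 0")


@dataclass
class BurdenProfile:
    """Patients × mechanisms burden scores plus per-SNP contribution weights."""

    scores: pd.DataFrame  # entries in [0, 1]
    contributions: dict[str, pd.Series]  # mechanism -> SNP weight, sums to 1
    encoder: "BurdenEncoder"

    @property
    def mechanism_names(self) -> list[str]:
        return list(self.scores.columns)

    def values(self) -> np.ndarray:
        return self.scores.to_numpy(dtype=float)


def _as_frame(genotypes) -> pd.DataFrame:
    if isinstance(genotypes, GenotypeMatrix):
        return genotypes.dosages
    if isinstance(genotypes, pd.DataFrame):
        return genotypes
    raise TypeError("genotypes must be a GenotypeMatrix or DataFrame")


class BurdenEncoder(BaseEstimator, TransformerMixin):
    """Per-mechanism sparse-autoencoder burden scoring as one transformer.

    Parameters mirror :class:`EncoderSpec`; ``grouping`` maps mechanism names
    to SNP id lists. ``fit`` trains one autoencoder per mechanism (seeded
    deterministically per mechanism from ``random_state``); ``transform``
    emits the patients × mechanisms score matrix.
    """

    def __init__(
        self,
        grouping: SnpGrouping | dict | None = None,
        bottleneck_dim: int = 1,
        sparsity_weight: float = 1e-3,
        ridge: float = 1e-3,
        learning_rate: float = 0.05,
        max_epochs: int = 800,
        tol: float = 1e-6,
        standardize: bool = True,
        random_state: int = 0,
    ):
        self.grouping = grouping
        self.bottleneck_dim = bottleneck_dim
        self.sparsity_weight = sparsity_weight
        self.ridge = ridge
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.tol = tol
        self.standardize = standardize
        self.random_state = random_state

    def _groups(self) -> dict[str, list[str]]:
        if self.grouping is None:
            raise ValueError("grouping must be provided")
        groups = self.grouping.groups if isinstance(self.grouping, SnpGrouping) else dict(self.grouping)
        if not groups:
            raise ValueError("empty grouping")
        # canonical within-group order: lexicographic by SNP id
        return {name: sorted(snps) for name, snps in groups.items()}

    def fit(self, X, y=None):
        frame = _as_frame(X)
        groups = self._groups()
        missing = {s for snps in groups.values() for s in snps} - set(frame.columns)
        if missing:
            raise ValueError(f"grouped SNPs absent from genotype matrix: {sorted(missing)[:5]}")
        self.groups_ = groups
        self.encoders_ = {}
        for idx, (name, snps) in enumerate(groups.items()):
            enc = SparseAutoencoder(
                bottleneck_dim=self.bottleneck_dim,
                sparsity_weight=self.sparsity_weight,
                ridge=self.ridge,
                learning_rate=self.learning_rate,
                max_epochs=self.max_epochs,
                tol=self.tol,
                standardize=self.standardize,
                random_state=(int(self.random_state) + 7 * idx) % (2**31 - 1),
            )
            enc.fit(frame[snps].to_numpy(dtype=float))
            self.encoders_[name] = enc
        return self

    def transform(self, X) -> pd.DataFrame:
        check_is_fitted(self, "encoders_")
        frame = _as_frame(X)
        cols = {}
        for name, snps in self.groups_.items():
            missing = set(snps) - set(frame.columns)
            if missing:
                raise ValueError(f"mechanism {name!r}: SNPs missing from input")
            cols[name] = self.encoders_[name].transform(frame[snps].to_numpy(dtype=float))
        return pd.DataFrame(cols, index=frame.index)

    def contributions(self) -> dict[str, pd.Series]:
        check_is_fitted(self, "encoders_")
        return {
            name: pd.Series(self.encoders_[name].contributions_, index=snps)
            for name, snps in self.groups_.items()
        }

    # -- persistence -------------------------------------------------------
    def save(self, path: str | Path) -> None:
        check_is_fitted(self, "encoders_")
        payload = {
            "groups": self.groups_,
            "encoders": {name: enc.to_dict() for name, enc in self.encoders_.items()},
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "BurdenEncoder":
        payload = json.loads(Path(path).read_text())
        obj = cls(grouping=payload["groups"])
        obj.groups_ = {k: list(v) for k, v in payload["groups"].items()}
        obj.encoders_ = {
            name: SparseAutoencoder.from_dict(d) for name, d in payload["encoders"].items()
        }
        return obj


def compute_burden_scores(
    genotypes: GenotypeMatrix | pd.DataFrame,
    grouping: SnpGrouping | dict,
    spec: EncoderSpec | None = None,
) -> BurdenProfile:
    """Train per-mechanism encoders and score the cohort (patients × mechanisms)."""
    spec = spec or EncoderSpec()
    enc = BurdenEncoder(
        grouping=grouping,
        bottleneck_dim=spec.bottleneck_dim,
        sparsity_weight=spec.sparsity_weight,
        ridge=spec.ridge,
        learning_rate=spec.learning_rate,
        max_epochs=spec.max_epochs,
        tol=spec.tol,
        standardize=spec.standardize,
        random_state=spec.seed,
    )
    enc.fit(genotypes)
    return BurdenProfile(
        scores=enc.transform(genotypes),
        contributions=enc.contributions(),
        encoder=enc,
    )


def apply_encoders(
    encoder: BurdenEncoder, genotypes: GenotypeMatrix | pd.DataFrame
) -> BurdenProfile:
    """Score new patients (e.g. a validation cohort) with discovery-trained encoders."""
    return BurdenProfile(
        scores=encoder.transform(genotypes),
        contributions=encoder.contributions(),
        encoder=encoder,
    )


def snp_contributions(encoder: SparseAutoencoder) -> np.ndarray:
    """Normalized |weight| vector of one fitted mechanism encoder (sums to 1)."""
    return encoder.contributions_
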