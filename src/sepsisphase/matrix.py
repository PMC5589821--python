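"""The patients x features container exchanged between pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass
class FeatureMatrix:
    """Numeric feature matrix plus labels for one cohort.

    ``X`` is patients x features (no non-finite entries), ``y`` the binary
    early-to-peak label, ``categories`` the raw 11-way adjudication label,
    and ``target`` an optional continuous regression target (log-SOFA).
    ``blocks`` names feature subsets ("biomarkers", "emr"); ``block("all")``
    returns the full matrix.
    """

    X: pd.DataFrame
    y: pd.Series | None = None
    categories: pd.Series | None = None
    target: pd.Series | None = None
    blocks: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.X.to_numpy(dtype=float))):
            bad = self.X.columns[self.X.isna().any() | ~np.isfinite(self.X).all()]
            raise ValueError(f"non-finite entries in feature columns {list(bad)}")
        for name, series in (("y", self.y), ("categories", self.categories),
                             ("target", self.target)):
            if series is not None and not series.index.equals(self.X.index):
                raise ValueError(f"{name} index does not match X")
        for block, cols in self.blocks.items():
            missing = set(cols) - set(self.X.columns)
            if missing:
                raise ValueError(f"block {block!r} references unknown columns {sorted(missing)}")

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)

    @property
    def n(self) -> int:
        return len(self.X)

    def subset(self, features: Sequence[str]) -> "FeatureMatrix":
        """Restrict to the given feature columns (order preserved)."""
        missing = [f for f in features if f not in self.X.columns]
        if missing:
            raise KeyError(f"unknown features {missing}")
        blocks = {k: [c for c in v if c in features] for k, v in self.blocks.items()}
        return replace(self, X=self.X[list(features)], blocks=blocks)

    def block(self, name: str) -> "FeatureMatrix":
        """Named feature subset; "all" returns the full matrix."""
        if name == "all":
            return self
        if name not in self.blocks:
            raise KeyError(f"unknown block {name!r}; available: {['all', *self.blocks]}")
        return self.subset(self.blocks[name])
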