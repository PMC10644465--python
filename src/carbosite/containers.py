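"""Shared in-memory containers.

The common currency of every stage is a :class:`FeatureMatrix`: a plain
samples x features float array with a binary label vector. Resamplers,
the GAN and the SVM all consume and produce it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["FeatureMatrix"]


@dataclass
class FeatureMatrix:
    """Numeric samples x features table with binary labels.

    Parameters
    ----------
    X : ndarray of shape (n_samples, n_features)
    y : ndarray of shape (n_samples,)
        Binary labels; 1 marks the positive (carbonylation-site) class.
    feature_names : list of str, optional
    scaling_state : {"raw", "minmax"}
    """

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str] | None = None
    scaling_state: str = "raw"

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        if self.y.shape != (self.X.shape[0],):
            raise ValueError(
                f"label vector length {self.y.shape} does not match "
                f"{self.X.shape[0]} rows of X"
            )
        if self.feature_names is not None and len(self.feature_names) != self.X.shape[1]:
            raise ValueError("feature_names length does not match number of columns")
        if self.scaling_state not in ("raw", "minmax"):
            raise ValueError(f"unknown scaling_state {self.scaling_state!r}")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def positives(self) -> np.ndarray:
        """Rows of the positive class."""
        return self.X[self.y == 1]

    def negatives(self) -> np.ndarray:
        return self.X[self.y == 0]

    def subset(self, idx) -> "FeatureMatrix":
        idx = np.asarray(idx)
        return replace(self, X=self.X[idx], y=self.y[idx])

    @staticmethod
    def concat(parts: list["FeatureMatrix"]) -> "FeatureMatrix":
        if not parts:
            raise ValueError("nothing to concatenate")
        d = {p.n_features for p in parts}
        if len(d) != 1:
            raise ValueError(f"feature dimension mismatch: {sorted(d)}")
        return FeatureMatrix(
            X=np.vstack([p.X for p in parts]),
            y=np.concatenate([p.y for p in parts]),
            feature_names=parts[0].feature_names,
            scaling_state=parts[0].scaling_state,
        )

    def to_frame(self) -> pd.DataFrame:
        names = self.feature_names or [f"f{i}" for i in range(self.n_features)]
        df = pd.DataFrame(self.X, columns=names)
        df["label"] = self.y
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FeatureMatrix":
        df = pd.read_csv(path)
        if "label" not in df.columns:
            raise ValueError(f"{path}: expected a final 'label' column")
        y = df.pop("label").to_numpy()
        return cls(X=df.to_numpy(dtype=float), y=y, feature_names=list(df.columns))
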