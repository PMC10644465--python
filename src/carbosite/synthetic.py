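"""Seeded synthetic datasets with the structure the method assumes.

Two generators:

* ``make_feature_dataset`` — an imbalanced two-class point cloud in
  feature space: negatives from a mixture of Gaussian clusters (so
  attention undersampling has non-trivial structure to exploit),
  positives from a single offset Gaussian, everything squashed into
  [0, 1] by a logistic transform (clipping would pile mass on the
  boundary and distort cosine similarities).

* ``make_peptide_dataset`` — synthetic peptide windows with the stated
  centre residue; positives carry signature residues at fixed offsets
  with probability background + motif_bias, negatives are pure uniform
  background. This emulates a compositional motif, not real
  carbonylation biology.

The default imbalance grid of interest is M = 1000 negatives versus
m in {200, 100, 10, 3} positives (imbalance ratios 5, 10, 100, 333).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import yaml

from .containers import FeatureMatrix
from .seq_features import ALPHABET, PeptideWindow

__all__ = ["SyntheticSpec", "make_feature_dataset", "make_peptide_dataset", "MOTIF_OFFSETS"]

# Signature (offset from centre -> enriched residue) used for positive windows.
MOTIF_OFFSETS = {-5: "D", -3: "E", -1: "P", 2: "G", 4: "S"}


@dataclass
class SyntheticSpec:
    n_neg: int = 1000
    n_pos: int = 100
    d: int = 10
    class_separation: float = 2.0  # distance between class means, in within-class sd
    n_neg_clusters: int = 3
    noise_sd: float = 1.0
    motif_bias: float = 0.5  # excess signature-residue probability in positives
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.n_neg >= self.n_pos >= 1:
            raise ValueError(f"need n_neg >= n_pos >= 1, got {self.n_neg}, {self.n_pos}")
        if self.d < 1:
            raise ValueError("d must be >= 1")
        if self.n_neg_clusters < 1:
            raise ValueError("n_neg_clusters must be >= 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0 <= self.motif_bias <= 1:
            raise ValueError("motif_bias must be in [0, 1]")

    @property
    def imbalance_ratio(self) -> float:
        return self.n_neg / self.n_pos

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)


def make_feature_dataset(spec: SyntheticSpec) -> FeatureMatrix:
    """Imbalanced Gaussian clouds squashed into [0, 1]^d; negatives first."""
    rng = np.random.default_rng(spec.seed)
    sd = spec.noise_sd
    centers = rng.normal(0.0, 2.0 * sd, size=(spec.n_neg_clusters, spec.d))
    assign = rng.integers(0, spec.n_neg_clusters, size=spec.n_neg)
    Xn = centers[assign] + rng.normal(0.0, sd, size=(spec.n_neg, spec.d))

    direction = rng.normal(size=spec.d)
    direction /= np.linalg.norm(direction)
    pos_mean = centers.mean(axis=0) + spec.class_separation * sd * direction
    Xp = pos_mean + rng.normal(0.0, sd, size=(spec.n_pos, spec.d))

    X = np.vstack([Xn, Xp])
    X = 1.0 / (1.0 + np.exp(-X / (2.0 * sd)))  # logistic squash into (0, 1)
    y = np.concatenate([np.zeros(spec.n_neg, dtype=int), np.ones(spec.n_pos, dtype=int)])
    return FeatureMatrix(X=X, y=y, scaling_state="minmax")


def make_peptide_dataset(
    spec: SyntheticSpec, window_len: int = 21, centre_residue: str = "K"
) -> list[PeptideWindow]:
    """Synthetic windows; positives carry a compositional motif."""
    if window_len % 2 == 0:
        raise ValueError(f"window_len must be odd, got {window_len}")
    if centre_residue not in "KRTP":
        raise ValueError(f"centre residue must be one of K/R/T/P, got {centre_residue!r}")
    rng = np.random.default_rng(spec.seed)
    half = window_len // 2
    aas = np.array(list(ALPHABET))
    background = 1.0 / len(ALPHABET)

    def _window(is_pos: bool) -> PeptideWindow:
        chars = aas[rng.integers(0, len(aas), size=window_len)]
        chars[half] = centre_residue
        if is_pos:
            # Exact categorical draw: P(signature) = background + motif_bias,
            # the other 19 residues uniform — so bias 0 matches negatives.
            for off, res in MOTIF_OFFSETS.items():
                p = half + off
                if 0 <= p < window_len and p != half:
                    if rng.uniform() < min(background + spec.motif_bias, 1.0):
                        chars[p] = res
                    else:
                        others = [a for a in ALPHABET if a != res]
                        chars[p] = others[rng.integers(0, len(others))]
        return PeptideWindow("".join(chars), int(is_pos))

    windows = [_window(False) for _ in range(spec.n_neg)]
    windows += [_window(True) for _ in range(spec.n_pos)]
    return windows
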