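"""Peptide windows and distance-based residue (DR) features.

Candidate carbonylation sites are K/R/T/P residues. Each site is cut
into a fixed-length window (default 21 residues, site at the centre;
termini padded with 'X') and encoded as DR features: the 20 single
residue counts plus, for every pair distance k = 1..d_max, the 400
counts of ordered residue pairs occurring at positions (p, p + k).
The vector length is therefore 20 + 400 * d_max. Padding 'X' never
contributes to any counter.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from Bio import SeqIO

from .containers import FeatureMatrix

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"  # the 20 standard residues, alphabetical
PAD = "X"
CENTRE_RESIDUES = frozenset("KRTP")

_AA_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}
_N = len(ALPHABET)

__all__ = [
    "ALPHABET",
    "PAD",
    "CENTRE_RESIDUES",
    "PeptideWindow",
    "DrFeatureVector",
    "read_sites",
    "read_windows",
    "write_windows",
    "dr_features",
    "dr_feature_names",
    "windows_to_features",
    "minmax_scale",
]


@dataclass(frozen=True)
class PeptideWindow:
    """A fixed-length amino-acid window centred on a candidate K/R/T/P site."""

    sequence: str
    label: int
    source_id: str = ""
    centre_position: int = 0  # 1-based position in the source protein

    def __post_init__(self) -> None:
        L = len(self.sequence)
        if L % 2 == 0:
            raise ValueError(f"window length must be odd, got {L}")
        bad = set(self.sequence) - set(ALPHABET) - {PAD}
        if bad:
            raise ValueError(f"invalid residue(s) {sorted(bad)} in window {self.sequence!r}")
        if self.centre_residue not in CENTRE_RESIDUES:
            raise ValueError(
                f"centre residue {self.centre_residue!r} not one of K/R/T/P "
                f"in window {self.sequence!r}"
            )
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")

    @property
    def centre_residue(self) -> str:
        return self.sequence[len(self.sequence) // 2]


@dataclass
class DrFeatureVector:
    """Raw (integer-count) DR encoding of one window."""

    values: np.ndarray
    d_max: int
    window_ref: PeptideWindow | None = None


def read_sites(fasta_path, sites_path, window_len: int = 21) -> list[PeptideWindow]:
    """Cut annotated sites out of proteins into fixed-length windows.

    ``sites_path`` is a TSV with header ``record_id  position  residue
    label``; positions are 1-based. Windows overhanging a terminus are
    padded with 'X'.
    """
    if window_len % 2 == 0:
        raise ValueError(f"window_len must be odd, got {window_len}")
    records = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    sites = pd.read_csv(sites_path, sep="\t", dtype={"record_id": str, "residue": str})
    required = {"record_id", "position", "residue", "label"}
    if missing := required - set(sites.columns):
        raise ValueError(f"{sites_path}: missing column(s) {sorted(missing)}")

    half = window_len // 2
    windows = []
    for row in sites.itertuples(index=False):
        seq = records.get(row.record_id)
        if seq is None:
            raise ValueError(f"record id {row.record_id!r} not present in {fasta_path}")
        pos = int(row.position)
        if not 1 <= pos <= len(seq):
            raise ValueError(
                f"position {pos} outside record {row.record_id!r} (length {len(seq)})"
            )
        actual = seq[pos - 1]
        if actual != row.residue:
            raise ValueError(
                f"record {row.record_id!r} position {pos}: site file says "
                f"{row.residue!r} but sequence has {actual!r}"
            )
        lo, hi = pos - 1 - half, pos - 1 + half  # 0-based inclusive span
        chunk = seq[max(lo, 0) : min(hi, len(seq) - 1) + 1]
        window = PAD * max(-lo, 0) + chunk + PAD * max(hi - (len(seq) - 1), 0)
        windows.append(
            PeptideWindow(window, int(row.label), source_id=row.record_id, centre_position=pos)
        )
    return windows


def read_windows(path) -> list[PeptideWindow]:
    """Read a plain-text windows file: one ``window label`` pair per line."""
    windows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            seq, label = line.split()
            windows.append(PeptideWindow(seq.upper(), int(label)))
    return windows


def write_windows(windows: list[PeptideWindow], path) -> None:
    with open(path, "w") as fh:
        for w in windows:
            fh.write(f"{w.sequence}\t{w.label}\n")


def dr_features(window: PeptideWindow | str, d_max: int = 3) -> DrFeatureVector:
    """Encode one window as a DR count vector of length 20 + 400 * d_max.

    Block 0 holds single-residue counts in alphabetical order; the k-th
    pair block holds counts of ordered pairs (i, j) at distance exactly
    k, pairs ordered AA, AC, ..., YY. 'X' positions count nowhere.
    """
    seq = window.sequence if isinstance(window, PeptideWindow) else window
    L = len(seq)
    if not 1 <= d_max < L:
        raise ValueError(f"d_max must be in [1, {L - 1}), got {d_max}")
    codes = np.empty(L, dtype=int)
    for p, aa in enumerate(seq):
        if aa == PAD:
            codes[p] = -1
        elif aa in _AA_INDEX:
            codes[p] = _AA_INDEX[aa]
        else:
            raise ValueError(f"invalid residue {aa!r} in window {seq!r}")

    values = np.zeros(_N + _N * _N * d_max, dtype=int)
    for c in codes:
        if c >= 0:
            values[c] += 1
    for k in range(1, d_max + 1):
        offset = _N + (k - 1) * _N * _N
        a, b = codes[: L - k], codes[k:]
        ok = (a >= 0) & (b >= 0)
        np.add.at(values, offset + a[ok] * _N + b[ok], 1)
    ref = window if isinstance(window, PeptideWindow) else None
    return DrFeatureVector(values=values, d_max=d_max, window_ref=ref)


def dr_feature_names(d_max: int) -> list[str]:
    names = list(ALPHABET)
    for k in range(1, d_max + 1):
        names += [f"{i}{j}@{k}" for i in ALPHABET for j in ALPHABET]
    return names


def windows_to_features(windows: list[PeptideWindow], d_max: int = 3) -> FeatureMatrix:
    """Vectorise a list of windows into a raw FeatureMatrix."""
    X = np.stack([dr_features(w, d_max).values for w in windows]).astype(float)
    y = np.array([w.label for w in windows])
    return FeatureMatrix(X=X, y=y, feature_names=dr_feature_names(d_max))


def minmax_scale(
    train: FeatureMatrix, others: list[FeatureMatrix] | None = None
) -> tuple[FeatureMatrix, list[FeatureMatrix]]:
    """Per-column min-max scaling fitted on ``train`` only.

    Constant columns map to 0; out-of-range values in ``others`` are not
    clipped, so test features may fall outside [0, 1].
    """
    if train.scaling_state != "raw":
        raise ValueError("train matrix is already scaled")
    others = others or []
    for o in others:
        if o.n_features != train.n_features:
            raise ValueError(
                f"column count mismatch: train has {train.n_features}, "
                f"other has {o.n_features}"
            )
    lo = train.X.min(axis=0)
    span = train.X.max(axis=0) - lo
    safe = np.where(span == 0, 1.0, span)

    def _apply(fm: FeatureMatrix) -> FeatureMatrix:
        return replace(fm, X=(fm.X - lo) / safe, scaling_state="minmax")

    return _apply(train), [_apply(o) for o in others]
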