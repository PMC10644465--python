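"""End-to-end orchestration: features -> rebalance -> train -> evaluate.

Strategies
----------
none
    Train on the data as-is.
random_under
    Balance by randomly downsampling negatives to the positive count m.
smote
    Balance by SMOTE-oversampling positives up to the negative count M.
attention_gan
    The two-way strategy: both classes meet at s = round(sqrt(m * M)) —
    attention-selected negatives, real + GAN-generated positives. The
    rebalanced training set is exactly balanced (s vs s).
random_gan / attention_smote
    Ablation arms of the two-way strategy: same scale s, with the
    negative selection replaced by a uniform draw, or the GAN replaced
    by SMOTE interpolation, respectively.

Evaluation is either stratified CV on one dataset or train/test with an
external test set (the imbalance-ratio sweep uses the latter, training
at each IR and scoring on a balanced held-out set).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classify import CvResult, EvalReport, cross_validate, evaluate, train_svm
from .containers import FeatureMatrix
from .gan import GanConfig, gan_oversample
from .rebalance import (
    RebalancePlan,
    attention_undersample,
    optimal_scale,
    random_undersample,
    smote_oversample,
)
from .seq_features import minmax_scale, read_sites, read_windows, windows_to_features
from .synthetic import SyntheticSpec, make_peptide_dataset

log = logging.getLogger("carbosite")

STRATEGIES = (
    "none", "random_under", "smote", "attention_gan", "random_gan", "attention_smote",
)

__all__ = [
    "RunConfig", "STRATEGIES", "rebalance_training_set", "make_rebalancer",
    "fit_and_score", "run_pipeline", "run_ir_sweep", "run_scale_sweep",
]


@dataclass
class RunConfig:
    """Everything needed to reproduce one run."""

    out_dir: str = "runs"
    fasta: str | None = None
    sites: str | None = None
    windows: str | None = None
    features: str | None = None  # pre-computed FeatureMatrix CSV
    residue_type: str = "K"
    d_max: int = 3
    strategy: str = "attention_gan"
    gan: GanConfig = field(default_factory=GanConfig)
    C: float = 1.0
    sigma: float | None = None
    n_folds: int = 10
    n_repeats: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}; choose from {STRATEGIES}")
        if self.residue_type not in "KRTP":
            raise ValueError("residue_type must be one of K/R/T/P")
        if isinstance(self.gan, dict):
            self.gan = GanConfig(**self.gan)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["gan"]["hidden_sizes"] = list(self.gan.hidden_sizes)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def rebalance_training_set(
    train: FeatureMatrix,
    strategy: str,
    gan_config: GanConfig | None = None,
    seed: int = 0,
    scale: int | None = None,
) -> tuple[FeatureMatrix, RebalancePlan | None]:
    """Apply one strategy to a (scaled) training set; returns (set, plan).

    ``scale`` overrides the optimal s for attention_gan (used by the
    sampling-scale sweep); it must lie in [1, M].
    """
    Xp, Xn = train.positives(), train.negatives()
    m, M = Xp.shape[0], Xn.shape[0]
    names, state = train.feature_names, train.scaling_state

    def _fm(X, y):
        return FeatureMatrix(X=X, y=y, feature_names=names, scaling_state=state)

    if strategy == "none":
        return train, None
    if strategy == "random_under":
        keep = random_undersample(Xn, min(m, M), seed)
        X = np.vstack([Xn[keep], Xp])
        y = np.r_[np.zeros(keep.size, int), np.ones(m, int)]
        return _fm(X, y), None
    if strategy == "smote":
        k = min(5, m - 1)
        synth = smote_oversample(Xp, max(0, M - m), k_neighbors=k, seed=seed)
        X = np.vstack([Xn, Xp, synth])
        y = np.r_[np.zeros(M, int), np.ones(m + synth.shape[0], int)]
        return _fm(X, y), None
    if strategy in ("attention_gan", "random_gan", "attention_smote"):
        s = optimal_scale(m, M) if scale is None else int(scale)
        plan = None
        if strategy == "random_gan":
            keep = random_undersample(Xn, s, seed)
        else:
            plan = attention_undersample(Xn, Xp, s)
            keep = np.asarray(plan.final_keep)
        n_synth = max(0, s - m)
        if n_synth == 0:  # s <= m: downsample positives to s for exact balance
            keep_p = random_undersample(Xp, s, seed) if s < m else np.arange(m)
            Xp_all = Xp[keep_p]
        elif strategy == "attention_smote":
            synth = smote_oversample(Xp, n_synth, k_neighbors=min(5, m - 1), seed=seed)
            Xp_all = np.vstack([Xp, synth])
        else:
            cfg = replace(gan_config or GanConfig(), seed=seed)
            Xp_all = gan_oversample(_fm(Xp, np.ones(m, int)), n_synth, cfg).X
        X = np.vstack([Xn[keep], Xp_all])
        y = np.r_[np.zeros(s, int), np.ones(Xp_all.shape[0], int)]
        return _fm(X, y), plan
    raise ValueError(f"unknown strategy {strategy!r}")


def make_rebalancer(strategy: str, gan_config: GanConfig | None = None):
    """Adapt a strategy name to the callable cross_validate expects."""
    if strategy == "none":
        return None

    def _reb(train: FeatureMatrix, seed: int) -> FeatureMatrix:
        return rebalance_training_set(train, strategy, gan_config, seed)[0]

    return _reb


def fit_and_score(
    train: FeatureMatrix,
    test: FeatureMatrix,
    strategy: str,
    C: float = 1.0,
    sigma: float | None = None,
    gan_config: GanConfig | None = None,
    seed: int = 0,
    n_repeats: int = 1,
    scale: int | None = None,
) -> EvalReport:
    """Train-at-IR / test-external evaluation (the Discussion-style design).

    Scaling is fitted on the raw training set only; over n_repeats
    rebalance+train cycles the model with the best training AUC is kept
    and scored once on the held-out test set.
    """
    if train.scaling_state == "raw":
        train_s, (test_s,) = minmax_scale(train, [test])
    else:  # inputs already live in [0, 1]
        train_s, test_s = train, test
    best = None
    for r in range(n_repeats):
        sub_seed = (seed + 131 * r) % (2**31)
        fit_set, _ = rebalance_training_set(train_s, strategy, gan_config, sub_seed, scale)
        model = train_svm(fit_set, C=C, sigma=sigma)
        tr_auc = evaluate(np.where(train_s.y > 0, 1, -1),
                          model.decision_scores(train_s.X)).auc
        if best is None or tr_auc > best[0]:
            best = (tr_auc, model)
    model = best[1]
    return evaluate(np.where(test_s.y > 0, 1, -1), model.decision_scores(test_s.X))


def _load_windows(config: RunConfig):
    if config.windows:
        return read_windows(config.windows)
    if config.fasta and config.sites:
        return read_sites(config.fasta, config.sites)
    raise ValueError("config must provide either windows or fasta+sites or features")


def run_pipeline(config: RunConfig) -> CvResult:
    """Full CV run from sequence (or feature) inputs; artifacts persisted."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    run_id = config.config_hash()
    log.info("run %s: strategy=%s seed=%d", run_id, config.strategy, config.seed)

    if config.features:
        fm = FeatureMatrix.from_csv(config.features)
    else:
        windows = _load_windows(config)
        fm = windows_to_features(windows, config.d_max)
        fm.to_csv(out / f"features_{run_id}.csv")

    m = int((fm.y == 1).sum())
    M = int((fm.y == 0).sum())
    if config.strategy == "attention_gan":
        s = optimal_scale(m, M)
        train_scaled, _ = minmax_scale(fm) if fm.scaling_state == "raw" else (fm, [])
        plan = attention_undersample(train_scaled.negatives(), train_scaled.positives(), s)
        plan.to_json(out / f"plan_{run_id}.json")

    result = cross_validate(
        fm,
        rebalancer=make_rebalancer(config.strategy, config.gan),
        C=config.C,
        sigma=config.sigma,
        n_folds=config.n_folds,
        n_repeats=config.n_repeats,
        seed=config.seed,
    )
    report = {"run_id": run_id, "seed": config.seed, "config": config.to_dict(),
              **result.to_dict()}
    with open(out / f"report_{run_id}.json", "w") as fh:
        json.dump(report, fh, indent=1)
    config.to_yaml(out / f"config_{run_id}.yaml")
    return result


def _ir_datasets(base_spec: SyntheticSpec, ir: int, d_max: int,
                 test_n: int = 500, window_len: int = 21, residue: str = "K"):
    """Train set at the requested imbalance ratio plus a balanced test set."""
    n_pos = base_spec.n_neg // ir
    if n_pos < 1:
        raise ValueError(f"IR={ir} needs n_pos >= 1 with n_neg={base_spec.n_neg}")
    tr_spec = replace(base_spec, n_pos=n_pos)
    te_spec = replace(base_spec, n_neg=test_n, n_pos=test_n, seed=base_spec.seed + 7919)
    train = windows_to_features(make_peptide_dataset(tr_spec, window_len, residue), d_max)
    test = windows_to_features(make_peptide_dataset(te_spec, window_len, residue), d_max)
    return train, test


def run_ir_sweep(
    base_config: RunConfig,
    irs: list[int],
    strategies: list[str],
    base_spec: SyntheticSpec | None = None,
    test_n: int = 500,
) -> pd.DataFrame:
    """One evaluation row per (IR, strategy) on synthetic peptide data.

    Emulates the constructed-imbalance experiment: M fixed negatives,
    m = M / IR positives, scored on a balanced external test set.
    """
    spec = base_spec or SyntheticSpec(seed=base_config.seed)
    rows = []
    for ir in irs:
        train, test = _ir_datasets(spec, ir, base_config.d_max,
                                   test_n=test_n, residue=base_config.residue_type)
        m = int((train.y == 1).sum())
        M = int((train.y == 0).sum())
        for strat in strategies:
            rep = fit_and_score(
                train, test, strat, C=base_config.C, sigma=base_config.sigma,
                gan_config=base_config.gan, seed=base_config.seed,
                n_repeats=base_config.n_repeats,
            )
            rows.append({"method": strat, "residue": base_config.residue_type,
                         "IR": ir, "s": optimal_scale(m, M),
                         "sen": rep.sen, "spe": rep.spe, "auc": rep.auc})
            log.info("IR=%d %s: sen=%.3f spe=%.3f auc=%.3f",
                     ir, strat, rep.sen, rep.spe, rep.auc)
    df = pd.DataFrame(rows, columns=["method", "residue", "IR", "s", "sen", "spe", "auc"])
    out = Path(base_config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df.to_csv(out / f"ir_sweep_{base_config.config_hash()}.csv", index=False)
    return df


def run_scale_sweep(
    train: FeatureMatrix,
    test: FeatureMatrix,
    scales: list[int],
    config: RunConfig,
) -> pd.DataFrame:
    """AUC of the two-way strategy as the sampling scale varies around s."""
    rows = []
    for s in scales:
        rep = fit_and_score(
            train, test, "attention_gan", C=config.C, sigma=config.sigma,
            gan_config=config.gan, seed=config.seed,
            n_repeats=config.n_repeats, scale=s,
        )
        rows.append({"s": s, "sen": rep.sen, "spe": rep.spe, "auc": rep.auc})
        log.info("scale s=%d: auc=%.3f", s, rep.auc)
    return pd.DataFrame(rows)


def plot_scale_sweep(df: pd.DataFrame, s_opt: int, path) -> None:
    """Save the sampling-scale/AUC curve with the predicted optimum marked."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(df["s"], df["auc"], "o-")
    ax.axvline(s_opt, color="crimson", ls="--", label=f"s = {s_opt}")
    ax.set_xlabel("sampling scale s")
    ax.set_ylabel("AUC")
    ax.set_xscale("log")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
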