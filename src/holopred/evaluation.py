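"""Cross-validated prediction accuracy and model comparison.

Implements the accuracy protocol used throughout holo-omics prediction work:
samples are randomly partitioned into k folds (a "foldid" vector); each fold
in turn is masked and predicted from a model trained on the rest; accuracy is
the squared Pearson correlation r² between predictions and the observed
phenotypes of the validation fold. The whole k-fold pass is repeated R times
with fresh random partitions, the per-repeat mean r² being the accuracy
criterion. Models are compared by one-way ANOVA on the per-repeat r² values
with Tukey HSD multiple comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import model as _model
from .kernels import Kernel
from .model import McmcSettings, PhenotypeTable

__all__ = [
    "FoldAssignment",
    "CVResult",
    "ComparisonResult",
    "make_folds",
    "r_squared",
    "cross_validate",
    "compare_models",
    "plot_accuracy",
]


@dataclass
class FoldAssignment:
    """One repeat's fold labels: ``fold_ids[i]`` in 1..k for each sample."""

    repeat_index: int
    fold_ids: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        self.fold_ids = np.asarray(self.fold_ids, dtype=int)
        k = self.fold_ids.max(initial=0)
        sizes = np.bincount(self.fold_ids, minlength=k + 1)[1:]
        if (sizes == 0).any():
            raise ValueError("every fold must be non-empty")
        if sizes.max() - sizes.min() > 1:
            raise ValueError("fold sizes must differ by at most 1")

    @property
    def k(self) -> int:
        return int(self.fold_ids.max())


@dataclass
class CVResult:
    """Per-fold and per-repeat squared-correlation accuracies for one model."""

    model_label: str
    per_fold_r2: np.ndarray  # k x R
    settings_fingerprint: str = ""

    def __post_init__(self) -> None:
        self.per_fold_r2 = np.atleast_2d(np.asarray(self.per_fold_r2, dtype=float))

    @property
    def per_repeat_r2(self) -> np.ndarray:
        return self.per_fold_r2.mean(axis=0)

    @property
    def mean_r2(self) -> float:
        return float(self.per_repeat_r2.mean())

    @property
    def sd_r2(self) -> float:
        v = self.per_repeat_r2
        return float(v.std(ddof=1)) if len(v) > 1 else 0.0

    @property
    def se_r2(self) -> float:
        return self.sd_r2 / np.sqrt(len(self.per_repeat_r2))

    def to_frame(self) -> pd.DataFrame:
        k, R = self.per_fold_r2.shape
        rows = [
            {"model_label": self.model_label, "repeat": r + 1,
             "fold": f + 1, "r2": self.per_fold_r2[f, r]}
            for r in range(R) for f in range(k)
        ]
        return pd.DataFrame(rows)


@dataclass
class ComparisonResult:
    """One-way ANOVA across models plus Tukey HSD pairwise table."""

    F_statistic: float
    p_value: float
    pairwise: pd.DataFrame  # columns: pair, diff, p_adj, significant
    alpha: float


def make_folds(n: int, k: int, repeats: int, seed: int) -> list[FoldAssignment]:
    """Balanced random partitions into k folds, one per repeat.

    Deterministic given the seed; different repeats get different partitions.
    """
    if k > n:
        raise ValueError(f"cannot split {n} samples into {k} folds")
    if k < 2:
        raise ValueError("need at least 2 folds")
    rng = np.random.default_rng(seed)
    out = []
    base = np.arange(n) % k + 1  # balanced label pool
    for r in range(repeats):
        labels = rng.permutation(base)
        out.append(FoldAssignment(repeat_index=r + 1, fold_ids=labels, seed=seed))
    return out


def r_squared(obs: np.ndarray, pred: np.ndarray) -> float:
    """Squared Pearson correlation between observed and predicted values."""
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise ValueError("obs and pred must be 1-D vectors of equal length")
    if len(obs) < 3:
        raise ValueError("need at least 3 pairs to compute r2")
    if np.var(obs) == 0 or np.var(pred) == 0:
        raise ValueError("r2 undefined: a vector has zero variance")
    r = float(np.corrcoef(obs, pred)[0, 1])
    return r * r


def cross_validate(
    spec_label: str,
    pheno: PhenotypeTable,
    kernels: Mapping[str, Kernel],
    settings: McmcSettings,
    folds: Sequence[FoldAssignment],
) -> CVResult:
    """Repeated k-fold CV: refit with each fold masked, score its predictions.

    Every (repeat, fold) fit gets its own derived MCMC seed so repeats differ
    while the whole procedure stays deterministic.
    """
    n = pheno.n_samples
    y = pheno.y
    if not np.isfinite(y).all():
        raise ValueError("cross-validation requires fully observed phenotypes")
    for fa in folds:
        if len(fa.fold_ids) != n:
            raise ValueError("fold assignment length does not match the data")
        sizes = np.bincount(fa.fold_ids)[1:]
        if sizes.min() < 3:
            raise ValueError(
                f"repeat {fa.repeat_index}: smallest fold has {sizes.min()} "
                "validation samples; need >= 3 for a defined r2"
            )
    k = folds[0].k
    R = len(folds)
    per_fold = np.zeros((k, R))
    for ri, fa in enumerate(folds):
        for f in range(1, k + 1):
            mask = fa.fold_ids == f
            masked = pheno.with_masked(mask)
            spec = _model.build_model(spec_label, kernels, masked)
            fit_settings = McmcSettings(
                **{**settings.__dict__,
                   "seed": (settings.seed * 100_003 + ri * 101 + f) % (2**31 - 1)}
            )
            post = _model.fit(spec, masked, fit_settings)
            pred = _model.predict(post, masked)
            pred = pred.reindex([s for s, m in zip(pheno.sample_ids, mask) if m])
            per_fold[f - 1, ri] = r_squared(y[mask], pred.to_numpy())
    fingerprint = f"{spec_label}|k={k}|R={R}|mcmc_seed={settings.seed}"
    return CVResult(spec_label, per_fold, fingerprint)


def compare_models(results: Sequence[CVResult], alpha: float = 0.05) -> ComparisonResult:
    """One-way ANOVA + Tukey HSD on the per-repeat r2 values across models."""
    if len(results) < 2:
        raise ValueError("need at least two models to compare")
    lengths = {len(r.per_repeat_r2) for r in results}
    if len(lengths) != 1:
        raise ValueError(f"models have unequal repeat counts: {sorted(lengths)}")
    groups = [r.per_repeat_r2 for r in results]
    labels = [r.model_label for r in results]
    n_per = len(groups[0])
    values = np.concatenate(groups)
    group_idx = np.repeat(np.arange(len(groups)), n_per)

    grand = values.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = len(values) - len(groups)

    pairs = [(i, j) for i in range(len(groups)) for j in range(i + 1, len(groups))]
    if ss_between <= 1e-300 * max(ss_within, 1.0):
        F, p = 0.0, 1.0
        pairwise = pd.DataFrame({
            "pair": [f"{labels[i]} vs {labels[j]}" for i, j in pairs],
            "diff": [groups[j].mean() - groups[i].mean() for i, j in pairs],
            "p_adj": 1.0,
            "significant": False,
        })
    else:
        F = (ss_between / df_b) / (ss_within / df_w) if ss_within > 0 else np.inf
        p = float(stats.f.sf(F, df_b, df_w)) if np.isfinite(F) else 0.0
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        tk = pairwise_tukeyhsd(values, np.array(labels)[group_idx], alpha=alpha)
        tk_df = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
        pairwise = pd.DataFrame({
            "pair": tk_df["group1"].astype(str) + " vs " + tk_df["group2"].astype(str),
            "diff": tk_df["meandiff"].astype(float),
            "p_adj": tk_df["p-adj"].astype(float),
            "significant": tk_df["reject"].astype(bool),
        })
    return ComparisonResult(float(F), float(p), pairwise, alpha)


def plot_accuracy(results: Sequence[CVResult], ax=None, use_se: bool = False):
    """Grouped bar chart of mean r2 per model with SD (or SE) error bars."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    labels = [r.model_label for r in results]
    means = [r.mean_r2 for r in results]
    errs = [r.se_r2 if use_se else r.sd_r2 for r in results]
    ax.bar(labels, means, yerr=errs, capsize=4, color="#4878a8")
    ax.set_ylabel("prediction accuracy ($r^2$)")
    ax.set_xlabel("model")
    return ax
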