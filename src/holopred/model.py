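"""Bayesian linear mixed models for holo-omics prediction, fitted by Gibbs
sampling.

The model is

    y = X beta + sum_b W_b alpha_b + sum_k u_k + e

with flat-prior fixed effects ``beta`` (intercept, continuous covariates,
dummy-coded categorical fixed effects), BayesB blocks ``alpha_b`` (dummy-coded
class effects such as diet, slaughter day or pen, each column under a
point-mass/Gaussian mixture prior with its own scaled-inverse-chi-square
variance), and RKHS kernel random effects ``u_k ~ N(0, K_k sigma_k^2)`` for
any number of sample x sample kernels (GRM, MRM, Hadamard, CORE). Residuals
are iid Gaussian; phenotypes recorded as NaN are excluded from the likelihood
and predicted from the posterior linear predictor.

Each kernel effect is sampled in the eigenbasis of the kernel restricted to
the observed samples: with ``K_oo = U D U'`` (eigenvalues below 1e-8 x max
truncated) and ``u_obs = U D^{1/2} t``, the coefficients ``t_j ~ N(0,
sigma_k^2)`` have a diagonal full conditional because U is orthonormal, so a
sweep is a handful of matrix-vector products. Masked samples are predicted by
kernel regression, ``u_miss = K[miss,obs] K[obs,obs]^+ u_obs``, which has the
same posterior mean as carrying the masked rows through the sampler with zero
likelihood weight.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .kernels import Kernel, normalise_kernel

logger = logging.getLogger(__name__)

__all__ = [
    "PhenotypeTable",
    "ModelSpec",
    "McmcSettings",
    "PosteriorSummary",
    "MODEL_LABELS",
    "build_model",
    "fit",
    "predict",
]

#: kernel kinds each model label requires, in fitting order
MODEL_LABELS: dict[str, tuple[str, ...]] = {
    "genomic": ("GRM",),
    "microbial": ("MRM",),
    "direct": ("GRM", "MRM"),
    "core": ("GRM", "MRM", "CORE"),
    "hadamard": ("GRM", "MRM", "HADAMARD"),
}

_EIG_TOL = 1e-8


@dataclass
class PhenotypeTable:
    """Phenotype vector plus covariates, aligned on sample order.

    ``y`` may contain NaN for samples whose phenotype is to be predicted.
    ``fixed_covariates`` columns enter as fixed effects (categoricals are
    dummy-coded, first level dropped); ``class_effects`` columns are
    categorical blocks fitted with the BayesB mixture prior.
    """

    y: np.ndarray
    sample_ids: list[str]
    fixed_covariates: pd.DataFrame | None = None
    class_effects: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        n = len(self.sample_ids)
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample IDs in phenotype table")
        if self.y.shape != (n,):
            raise ValueError(f"y has shape {self.y.shape}, expected ({n},)")
        if np.isfinite(self.y).sum() < 1:
            raise ValueError("phenotype table has no non-missing phenotypes")
        for df, what in ((self.fixed_covariates, "fixed_covariates"),
                         (self.class_effects, "class_effects")):
            if df is not None and len(df) != n:
                raise ValueError(f"{what} has {len(df)} rows, expected {n}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def observed_mask(self) -> np.ndarray:
        return np.isfinite(self.y)

    def with_masked(self, mask: np.ndarray) -> "PhenotypeTable":
        """Copy with ``y`` set to NaN where ``mask`` is True (CV masking)."""
        y = self.y.copy()
        y[np.asarray(mask, dtype=bool)] = np.nan
        return PhenotypeTable(y, list(self.sample_ids),
                              self.fixed_covariates, self.class_effects)


@dataclass
class ModelSpec:
    """A validated model: which covariates and kernels enter the fit."""

    model_label: str
    fixed_terms: list[str]
    bayesb_terms: list[str]
    kernel_terms: list[Kernel]

    def __post_init__(self) -> None:
        if self.model_label not in MODEL_LABELS:
            raise ValueError(
                f"unknown model label {self.model_label!r}; "
                f"valid labels: {sorted(MODEL_LABELS)}"
            )
        kinds = tuple(k.kind for k in self.kernel_terms)
        if kinds != MODEL_LABELS[self.model_label]:
            raise ValueError(
                f"model {self.model_label!r} requires kernels "
                f"{MODEL_LABELS[self.model_label]}, got {kinds}"
            )


@dataclass
class McmcSettings:
    """Gibbs chain settings and prior hyperparameters.

    Defaults follow common Bayesian-alphabet practice: 12,000 iterations with
    2,000 burn-in, thinning 5; mixture probability pi = 0.5 (prior probability
    an effect is exactly zero); 5 prior degrees of freedom for every variance.
    Scales default to the expected-proportion-of-variance rule: the prior mean
    of each variance equals ``r2_total * var(y)`` split equally over the random
    terms (``None`` means "derive from the data").

    ``fixed_variances`` maps term names (kernel kinds or ``"residual"``) to
    known variances, bypassing their updates — used for BLUP-equivalence
    checks. ``class_effects_as`` switches the class-effect blocks between the
    BayesB mixture prior ("bayesb") and plain Gaussian ridge ("gaussian",
    i.e. pi = 0).
    """

    n_iter: int = 12_000
    burn_in: int = 2_000
    thin: int = 5
    seed: int = 0
    bayesb_pi: float = 0.5
    bayesb_df: float = 5.0
    bayesb_scale: float | None = None
    vc_df: float = 5.0
    vc_scale: float | None = None
    resid_df: float = 5.0
    resid_scale: float | None = None
    r2_total: float = 0.5
    fixed_variances: Mapping[str, float] | None = None
    class_effects_as: str = "bayesb"
    check_residuals: bool = False

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iter:
            raise ValueError(
                f"burn_in ({self.burn_in}) must be < n_iter ({self.n_iter})"
            )
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if not 0.0 <= self.bayesb_pi < 1.0:
            raise ValueError("bayesb_pi must be in [0, 1)")
        if self.class_effects_as not in ("bayesb", "gaussian"):
            raise ValueError("class_effects_as must be 'bayesb' or 'gaussian'")


@dataclass
class PosteriorSummary:
    """Posterior means/SDs from a Gibbs run, plus per-sample predictions."""

    model_label: str
    sample_ids: list[str]
    var_components: dict[str, tuple[float, float]]  # term -> (mean, sd)
    fixed_effect_means: dict[str, float]
    linear_predictor: np.ndarray  # posterior-mean E[y] for every sample
    predicted_mask: np.ndarray  # True where y was NaN (predictions)
    n_kept: int
    seed: int

    def variance_fractions(self) -> dict[str, float]:
        total = sum(m for m, _ in self.var_components.values())
        return {k: m / total for k, (m, _) in self.var_components.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"term": k, "post_mean": m, "post_sd": s}
            for k, (m, s) in self.var_components.items()
        ]
        return pd.DataFrame(rows)


def build_model(
    spec_label: str,
    kernels: Mapping[str, Kernel] | Sequence[Kernel],
    pheno: PhenotypeTable,
) -> ModelSpec:
    """Assemble and validate a ModelSpec for one of the five model labels.

    ``kernels`` holds the available kernels keyed (or identified) by kind.
    All covariate columns the phenotype table provides are attached: the
    fixed-covariate columns as fixed effects, the class-effect columns as
    BayesB blocks.
    """
    if spec_label not in MODEL_LABELS:
        raise ValueError(
            f"unknown model label {spec_label!r}; valid labels: "
            f"{sorted(MODEL_LABELS)}"
        )
    if not isinstance(kernels, Mapping):
        kernels = {k.kind: k for k in kernels}
    terms = []
    for kind in MODEL_LABELS[spec_label]:
        if kind not in kernels:
            raise ValueError(
                f"model {spec_label!r} requires a {kind} kernel but none "
                "was provided"
            )
        k = kernels[kind]
        if k.sample_ids != pheno.sample_ids:
            raise ValueError(
                f"{kind} kernel sample IDs do not match the phenotype table"
            )
        terms.append(normalise_kernel(k))
    fixed = list(pheno.fixed_covariates.columns) if pheno.fixed_covariates is not None else []
    classes = list(pheno.class_effects.columns) if pheno.class_effects is not None else []
    return ModelSpec(spec_label, fixed, classes, terms)


# ---------------------------------------------------------------------------
# design-matrix helpers
# ---------------------------------------------------------------------------

def _fixed_design(pheno: PhenotypeTable, terms: list[str]) -> tuple[np.ndarray, list[str]]:
    """Intercept + covariates; categorical columns dummy-coded, drop-first."""
    n = pheno.n_samples
    cols: list[np.ndarray] = [np.ones(n)]
    names = ["intercept"]
    if terms:
        df = pheno.fixed_covariates[terms]
        for name in terms:
            col = df[name]
            if pd.api.types.is_numeric_dtype(col):
                cols.append(col.to_numpy(dtype=float))
                names.append(name)
            else:
                dummies = pd.get_dummies(col.astype("category"), drop_first=True)
                for lev in dummies.columns:
                    cols.append(dummies[lev].to_numpy(dtype=float))
                    names.append(f"{name}[{lev}]")
    return np.column_stack(cols), names


def _class_design(pheno: PhenotypeTable, terms: list[str]) -> list[tuple[str, np.ndarray]]:
    """Full (no level dropped) dummy coding per class-effect block."""
    blocks = []
    for name in terms:
        dummies = pd.get_dummies(pheno.class_effects[name].astype("category"))
        blocks.append((name, dummies.to_numpy(dtype=float)))
    return blocks


def _scaled_inv_chi2(rng: np.random.Generator, df: float, scale: float) -> float:
    return df * scale / rng.chisquare(df)


def _kernel_basis(K: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Eigenbasis of K with small/negative eigenvalues truncated.

    Returns (U, d, n_truncated); columns of U are orthonormal, d > 0.
    """
    d, U = np.linalg.eigh(K)
    if not np.isfinite(d).all():
        raise ValueError("kernel eigendecomposition produced non-finite values")
    tol = _EIG_TOL * max(d[-1], 0.0)
    keep = d > tol
    n_trunc = int((~keep).sum())
    if not keep.any():
        raise ValueError("kernel has no positive eigenvalues")
    return U[:, keep], d[keep], n_trunc


# ---------------------------------------------------------------------------
# the Gibbs sampler
# ---------------------------------------------------------------------------

def fit(spec: ModelSpec, pheno: PhenotypeTable, settings: McmcSettings) -> PosteriorSummary:
    """Fit the mixed model by Gibbs sampling; deterministic given the seed.

    Requires at least 20 non-missing phenotypes. Returns posterior means/SDs
    of the variance components, fixed effects, and the per-sample posterior
    linear predictor (which is the prediction for NaN phenotypes).
    """
    obs = pheno.observed_mask()
    n_obs = int(obs.sum())
    if n_obs < 20:
        raise ValueError(f"need >= 20 non-missing phenotypes, have {n_obs}")
    n = pheno.n_samples
    miss = ~obs
    y_obs = pheno.y[obs]
    vy = float(np.var(y_obs, ddof=1)) if n_obs > 1 else 1.0
    if vy <= 0:
        vy = 1.0
    rng = np.random.default_rng(settings.seed)

    fixed_vars = dict(settings.fixed_variances or {})

    # --- fixed effects ---
    X_full, x_names = _fixed_design(pheno, spec.fixed_terms)
    X = X_full[obs]
    xtx = np.einsum("ij,ij->j", X, X)
    active_x = xtx > 0  # all-zero dummy columns (level absent in training set)

    # --- BayesB class-effect blocks ---
    blocks = _class_design(pheno, spec.bayesb_terms)
    n_rand_terms = max(len(spec.kernel_terms) + len(blocks), 1)
    r2_term = settings.r2_total / n_rand_terms
    pi = settings.bayesb_pi if settings.class_effects_as == "bayesb" else 0.0

    bb = []  # per block: dict of working arrays
    for name, W_full in blocks:
        W = W_full[obs]
        wtw = np.einsum("ij,ij->j", W, W)
        col_var = W.var(axis=0)
        sum_var = float(col_var.sum())
        if settings.bayesb_scale is not None:
            S = settings.bayesb_scale
        else:
            target = r2_term * vy / max((1.0 - pi) * max(sum_var, 1e-12), 1e-12)
            S = target * max(settings.bayesb_df - 2.0, 0.5) / settings.bayesb_df
        bb.append({
            "name": name,
            "W": W, "W_full": W_full, "wtw": wtw,
            "alpha": np.zeros(W.shape[1]),
            "sigma2": np.full(W.shape[1], S * settings.bayesb_df /
                              max(settings.bayesb_df - 2.0, 0.5)),
            "scale": S,
        })

    # --- kernel terms: eigenbasis on observed block, predictor for the rest ---
    kt = []
    for K in spec.kernel_terms:
        K_oo = K.matrix[np.ix_(obs, obs)]
        try:
            U, d, n_trunc = _kernel_basis(K_oo)
        except ValueError as e:
            raise ValueError(f"degenerate {K.kind} kernel: {e}") from e
        if n_trunc:
            logger.info("fit: %s kernel, truncated %d eigenvalue(s)", K.kind, n_trunc)
        sqrt_d = np.sqrt(d)
        P = (K.matrix[np.ix_(miss, obs)] @ U) / sqrt_d if miss.any() else None
        if settings.vc_scale is not None:
            S = settings.vc_scale
        else:
            S = r2_term * vy * max(settings.vc_df - 2.0, 0.5) / settings.vc_df
        kt.append({
            "name": K.kind, "U": U, "d": d, "sqrt_d": sqrt_d, "P": P,
            "t": np.zeros(len(d)),
            "sigma2": fixed_vars.get(K.kind, S * settings.vc_df /
                                     max(settings.vc_df - 2.0, 0.5)),
            "scale": S,
            "fixed": K.kind in fixed_vars,
        })

    # --- residual variance prior ---
    if settings.resid_scale is not None:
        Se = settings.resid_scale
    else:
        Se = (1.0 - settings.r2_total) * vy * \
            max(settings.resid_df - 2.0, 0.5) / settings.resid_df
    sigma2_e = fixed_vars.get("residual", (1.0 - settings.r2_total) * vy)
    resid_fixed = "residual" in fixed_vars

    # --- state ---
    beta = np.zeros(X.shape[1])
    beta[0] = float(y_obs.mean())
    r = y_obs - X @ beta  # running residual on observed samples

    keep_iters = range(settings.burn_in, settings.n_iter, settings.thin)
    n_kept = len(keep_iters)
    keep_set = set(keep_iters)

    sum_lp = np.zeros(n)
    sum_beta = np.zeros(X.shape[1])
    vc_names = [k["name"] for k in kt] + ["residual"]
    vc_sum = dict.fromkeys(vc_names, 0.0)
    vc_sumsq = dict.fromkeys(vc_names, 0.0)

    for it in range(settings.n_iter):
        # fixed effects: single-site updates, flat prior
        for j in range(X.shape[1]):
            if not active_x[j]:
                continue
            xj = X[:, j]
            r += xj * beta[j]
            rhs = xj @ r
            mean = rhs / xtx[j]
            beta[j] = rng.normal(mean, np.sqrt(sigma2_e / xtx[j]))
            r -= xj * beta[j]

        # BayesB blocks
        for blk in bb:
            W, wtw, alpha, s2 = blk["W"], blk["wtw"], blk["alpha"], blk["sigma2"]
            df_b, S_b = settings.bayesb_df, blk["scale"]
            for j in range(W.shape[1]):
                wj = W[:, j]
                if alpha[j] != 0.0:
                    r += wj * alpha[j]
                if wtw[j] <= 0:
                    alpha[j] = 0.0
                    continue
                # per-column variance
                if alpha[j] != 0.0:
                    s2[j] = (df_b * S_b + alpha[j] ** 2) / rng.chisquare(df_b + 1)
                else:
                    s2[j] = _scaled_inv_chi2(rng, df_b, S_b)
                rhs = wj @ r
                C = wtw[j] / sigma2_e + 1.0 / s2[j]
                if pi > 0.0:
                    log_odds = (
                        np.log((1.0 - pi) / pi)
                        - 0.5 * np.log(s2[j] * C)
                        + 0.5 * rhs ** 2 / (sigma2_e ** 2 * C)
                    )
                    p_in = 1.0 / (1.0 + np.exp(-np.clip(log_odds, -700, 700)))
                    include = rng.random() < p_in
                else:
                    include = True
                if include:
                    mean = rhs / sigma2_e / C
                    alpha[j] = rng.normal(mean, np.sqrt(1.0 / C))
                    r -= wj * alpha[j]
                else:
                    alpha[j] = 0.0

        # kernel effects in the (orthonormal) eigenbasis: vectorised update
        for k in kt:
            U, sqrt_d, t = k["U"], k["sqrt_d"], k["t"]
            r += U @ (sqrt_d * t)
            v = U.T @ r
            prec = k["d"] / sigma2_e + 1.0 / k["sigma2"]
            mean = (sqrt_d * v / sigma2_e) / prec
            t[:] = mean + rng.standard_normal(len(t)) / np.sqrt(prec)
            r -= U @ (sqrt_d * t)
            if not k["fixed"]:
                m = len(t)
                ssq = float(t @ t)
                k["sigma2"] = (settings.vc_df * k["scale"] + ssq) / \
                    rng.chisquare(settings.vc_df + m)

        # residual variance
        if not resid_fixed:
            sse = float(r @ r)
            sigma2_e = (settings.resid_df * Se + sse) / \
                rng.chisquare(settings.resid_df + n_obs)
        if not np.isfinite(sigma2_e) or sigma2_e <= 0:
            raise ValueError("residual variance became non-finite; degenerate model")

        if settings.check_residuals:
            fitted = X @ beta
            for blk in bb:
                fitted = fitted + blk["W"] @ blk["alpha"]
            for k in kt:
                fitted = fitted + k["U"] @ (k["sqrt_d"] * k["t"])
            if np.abs(y_obs - fitted - r).max() > 1e-8:
                raise AssertionError("residual bookkeeping drifted beyond 1e-8")

        if it in keep_set:
            lp = X_full @ beta
            for blk in bb:
                lp = lp + blk["W_full"] @ blk["alpha"]
            for k in kt:
                u_obs = k["U"] @ (k["sqrt_d"] * k["t"])
                contrib = np.zeros(n)
                contrib[obs] = u_obs
                if k["P"] is not None:
                    contrib[miss] = k["P"] @ k["t"]
                lp = lp + contrib
            sum_lp += lp
            sum_beta += beta
            for k in kt:
                vc_sum[k["name"]] += k["sigma2"]
                vc_sumsq[k["name"]] += k["sigma2"] ** 2
            vc_sum["residual"] += sigma2_e
            vc_sumsq["residual"] += sigma2_e ** 2

    var_components = {}
    for name in vc_names:
        mean = vc_sum[name] / n_kept
        var = max(vc_sumsq[name] / n_kept - mean ** 2, 0.0)
        var_components[name] = (mean, float(np.sqrt(var)))

    return PosteriorSummary(
        model_label=spec.model_label,
        sample_ids=list(pheno.sample_ids),
        var_components=var_components,
        fixed_effect_means=dict(zip(x_names, sum_beta / n_kept)),
        linear_predictor=sum_lp / n_kept,
        predicted_mask=miss,
        n_kept=n_kept,
        seed=settings.seed,
    )


def predict(post: PosteriorSummary, pheno: PhenotypeTable) -> pd.Series:
    """Posterior-mean predictions for the NaN phenotypes, in input order.

    ``pheno`` must cover only samples present in the fit.
    """
    index = {s: i for i, s in enumerate(post.sample_ids)}
    missing = [s for s in pheno.sample_ids if s not in index]
    if missing:
        raise ValueError(
            f"samples not present in the fitted model: {missing[:5]}"
        )
    out_ids = [s for s, yv in zip(pheno.sample_ids, pheno.y) if not np.isfinite(yv)]
    vals = [post.linear_predictor[index[s]] for s in out_ids]
    return pd.Series(vals, index=pd.Index(out_ids, name="sample_id"), name="y_hat")
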