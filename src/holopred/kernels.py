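"""Sample-by-sample covariance kernels for holo-omics prediction.

Builds the four kernels that enter the mixed models:

* ``GRM`` — VanRaden genomic relationship matrix from SNP dosages,
  ``G = (Z - 2Q)(Z - 2Q)' / sum_m 2 p_m (1 - p_m)``.
* ``MRM`` — microbial relationship matrix from log-transformed, standardised
  OTU relative abundances, ``M = R R' / q``.
* ``HADAMARD`` — entry-wise product ``G ∘ M`` (PSD by the Schur product
  theorem when both inputs are PSD).
* ``CORE`` — symmetrised cross-product of Cholesky factors,
  ``K = (L_G L_M' + L_M L_G') / 2``, the covariance structure used to model
  the covariance between the genomic and microbial random effects. May be
  indefinite.

Also hosts the upstream marker/OTU filters (minor-allele frequency and
prevalence) and kernel normalisation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

_SYM_TOL = 1e-10

__all__ = [
    "GenotypeMatrix",
    "OTUTable",
    "Kernel",
    "filter_snps_maf",
    "filter_otus_prevalence",
    "compute_grm",
    "compute_mrm",
    "hadamard_kernel",
    "core_greml_kernel",
    "normalise_kernel",
]


def _check_ids(ids, what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate {what} IDs")
    return ids


@dataclass
class GenotypeMatrix:
    """SNP dosage matrix (samples x SNPs), values in {0, 1, 2, NaN}.

    Allele frequencies are recomputed from the non-missing dosages on
    construction; they refer to the counted (ALT) allele.
    """

    dosages: np.ndarray
    sample_ids: list[str]
    snp_ids: list[str]
    allele_freqs: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D samples x SNPs matrix")
        self.sample_ids = _check_ids(self.sample_ids, "sample")
        self.snp_ids = _check_ids(self.snp_ids, "SNP")
        n, p = self.dosages.shape
        if len(self.sample_ids) != n or len(self.snp_ids) != p:
            raise ValueError(
                f"ID lengths ({len(self.sample_ids)}, {len(self.snp_ids)}) "
                f"do not match dosage shape {self.dosages.shape}"
            )
        finite = self.dosages[np.isfinite(self.dosages)]
        if not np.isin(finite, (0.0, 1.0, 2.0)).all():
            bad = finite[~np.isin(finite, (0.0, 1.0, 2.0))][0]
            raise ValueError(f"dosage values must be 0, 1, 2 or NA; found {bad!r}")
        with np.errstate(invalid="ignore"):
            self.allele_freqs = np.nanmean(self.dosages, axis=0) / 2.0

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def minor_allele_freqs(self) -> np.ndarray:
        p = self.allele_freqs
        return np.minimum(p, 1.0 - p)


@dataclass
class OTUTable:
    """OTU abundance table (samples x OTUs): raw counts or relative abundances."""

    counts: np.ndarray
    sample_ids: list[str]
    otu_ids: list[str]
    is_relative: bool = False

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D samples x OTUs matrix")
        self.sample_ids = _check_ids(self.sample_ids, "sample")
        self.otu_ids = _check_ids(self.otu_ids, "OTU")
        n, q = self.counts.shape
        if len(self.sample_ids) != n or len(self.otu_ids) != q:
            raise ValueError("ID lengths do not match count matrix shape")
        if (self.counts < 0).any():
            raise ValueError("OTU abundances must be non-negative")
        if self.is_relative:
            sums = self.counts.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-8):
                raise ValueError("relative-abundance rows must sum to 1 within 1e-8")

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_otus(self) -> int:
        return self.counts.shape[1]

    def relative_abundances(self) -> np.ndarray:
        """Per-sample relative abundances (rows summing to 1)."""
        if self.is_relative:
            return self.counts.copy()
        totals = self.counts.sum(axis=1, keepdims=True)
        if (totals == 0).any():
            i = int(np.argmin(totals))
            raise ValueError(f"sample {self.sample_ids[i]!r} has zero total count")
        return self.counts / totals


@dataclass
class Kernel:
    """Named symmetric sample x sample similarity matrix."""

    matrix: np.ndarray
    sample_ids: list[str]
    kind: str  # GRM | MRM | HADAMARD | CORE

    VALID_KINDS = ("GRM", "MRM", "HADAMARD", "CORE")

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.sample_ids = _check_ids(self.sample_ids, "sample")
        n = len(self.sample_ids)
        if self.matrix.shape != (n, n):
            raise ValueError(f"kernel shape {self.matrix.shape} != ({n}, {n})")
        if not np.isfinite(self.matrix).all():
            raise ValueError(f"{self.kind} kernel contains non-finite entries")
        asym = np.abs(self.matrix - self.matrix.T).max() if n else 0.0
        if asym > _SYM_TOL:
            raise ValueError(f"{self.kind} kernel asymmetric by {asym:.3e}")
        if self.kind not in self.VALID_KINDS:
            raise ValueError(f"unknown kernel kind {self.kind!r}")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def diag_mean(self) -> float:
        return float(np.diag(self.matrix).mean())

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.matrix)[0])


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def filter_snps_maf(g: GenotypeMatrix, threshold: float) -> GenotypeMatrix:
    """Keep SNPs with minor-allele frequency >= ``threshold``.

    Frequencies are computed from non-missing dosages; SNP order preserved.
    """
    if not 0.0 <= threshold <= 0.5:
        raise ValueError(f"MAF threshold must be in [0, 0.5], got {threshold}")
    keep = g.minor_allele_freqs() >= threshold
    if not keep.any():
        raise ValueError(
            f"MAF filter at {threshold} removed all {g.n_snps} SNPs"
        )
    return GenotypeMatrix(
        g.dosages[:, keep],
        g.sample_ids,
        [s for s, k in zip(g.snp_ids, keep) if k],
    )


def filter_otus_prevalence(t: OTUTable, min_fraction: float) -> OTUTable:
    """Keep OTUs with a nonzero abundance in >= ``min_fraction`` of samples."""
    if not 0.0 <= min_fraction <= 1.0:
        raise ValueError(f"prevalence fraction must be in [0, 1], got {min_fraction}")
    prevalence = (t.counts > 0).mean(axis=0)
    keep = prevalence >= min_fraction
    if not keep.any():
        raise ValueError(
            f"prevalence filter at {min_fraction} removed all {t.n_otus} OTUs"
        )
    sub = t.counts[:, keep]
    if t.is_relative:
        # re-close the composition so rows still sum to 1
        sub = sub / sub.sum(axis=1, keepdims=True)
    return OTUTable(
        sub,
        t.sample_ids,
        [o for o, k in zip(t.otu_ids, keep) if k],
        is_relative=t.is_relative,
    )


# ---------------------------------------------------------------------------
# kernel constructors
# ---------------------------------------------------------------------------

def compute_grm(g: GenotypeMatrix, impute_missing: bool = True) -> Kernel:
    """VanRaden genomic relationship matrix.

    ``G = (Z - 2Q)(Z - 2Q)' / sum_m 2 p_m (1 - p_m)`` where column m of 2Q is
    the constant 2 p_m.  Missing dosages are mean-imputed to 2 p_m (the
    VanRaden-compatible choice) unless ``impute_missing`` is False, in which
    case any NA raises.
    """
    p = g.allele_freqs
    mono = (p <= 0.0) | (p >= 1.0)
    if mono.any():
        bad = g.snp_ids[int(np.argmax(mono))]
        raise ValueError(
            f"monomorphic SNP {bad!r} (allele frequency 0 or 1); "
            "apply filter_snps_maf first"
        )
    Z = g.dosages
    if np.isnan(Z).any():
        if not impute_missing:
            raise ValueError("missing dosages present and imputation disabled")
        Z = np.where(np.isnan(Z), 2.0 * p, Z)
    Zc = Z - 2.0 * p
    denom = float(np.sum(2.0 * p * (1.0 - p)))
    G = (Zc @ Zc.T) / denom
    G = 0.5 * (G + G.T)  # kill rounding asymmetry
    return Kernel(G, g.sample_ids, "GRM")


def _log_relative_abundances(t: OTUTable) -> np.ndarray:
    """Relative abundances with zeros replaced by half the smallest nonzero
    relative abundance in the whole table, then natural log."""
    rel = t.relative_abundances()
    nz = rel[rel > 0]
    if nz.size == 0:
        raise ValueError("OTU table is all zeros")
    pseudo = 0.5 * nz.min()
    return np.log(np.where(rel > 0, rel, pseudo))


def compute_mrm(t: OTUTable) -> Kernel:
    """Microbial relationship matrix ``M = R R' / q``.

    R holds log-transformed relative abundances, each OTU column centred and
    scaled to unit variance; q is the number of OTU columns retained.
    Zero-variance columns (after the log transform) are dropped with a
    warning.
    """
    R = _log_relative_abundances(t)
    mean = R.mean(axis=0)
    sd = R.std(axis=0, ddof=1) if R.shape[0] > 1 else np.zeros(R.shape[1])
    keep = sd > 0
    dropped = int((~keep).sum())
    if dropped:
        logger.warning(
            "compute_mrm: dropped %d zero-variance OTU column(s)", dropped
        )
    if not keep.any():
        raise ValueError("all OTU columns have zero variance after log transform")
    R = (R[:, keep] - mean[keep]) / sd[keep]
    q = R.shape[1]
    M = (R @ R.T) / q
    M = 0.5 * (M + M.T)
    return Kernel(M, t.sample_ids, "MRM")


def _require_aligned(a: Kernel, b: Kernel) -> None:
    if a.matrix.shape != b.matrix.shape:
        raise ValueError(
            f"kernel shape mismatch: {a.matrix.shape} vs {b.matrix.shape}"
        )
    for i, (x, y) in enumerate(zip(a.sample_ids, b.sample_ids)):
        if x != y:
            raise ValueError(
                f"sample ID mismatch at position {i}: {x!r} vs {y!r}"
            )


def hadamard_kernel(g: Kernel, m: Kernel) -> Kernel:
    """Entry-wise (Hadamard) product kernel ``K[i,j] = G[i,j] * M[i,j]``."""
    _require_aligned(g, m)
    return Kernel(g.matrix * m.matrix, g.sample_ids, "HADAMARD")


def _cholesky_with_ridge(K: Kernel, max_ridge: float = 1e-6) -> np.ndarray:
    """Lower Cholesky factor; on failure, add eps*I growing from 1e-10 by x10."""
    eps = 0.0
    while True:
        try:
            return np.linalg.cholesky(K.matrix + eps * np.eye(K.n_samples))
        except np.linalg.LinAlgError:
            if eps >= max_ridge:
                raise ValueError(
                    f"Cholesky of {K.kind} kernel failed even with ridge "
                    f"{max_ridge:g}; smallest eigenvalue {K.min_eigenvalue():.3e}"
                ) from None
            eps = 1e-10 if eps == 0.0 else eps * 10.0
            logger.info("core_greml_kernel: retrying Cholesky with ridge %g", eps)


def core_greml_kernel(g: Kernel, m: Kernel) -> Kernel:
    """Covariance-between-random-effects kernel from Cholesky factors.

    ``K = (L_G L_M' + L_M L_G') / 2`` with L the lower Cholesky factors of the
    (PSD, possibly ridge-stabilised) inputs. Symmetric by construction but may
    be indefinite; the smallest eigenvalue is logged.
    """
    _require_aligned(g, m)
    L_g = _cholesky_with_ridge(g)
    L_m = _cholesky_with_ridge(m)
    cross = L_g @ L_m.T
    K = Kernel(0.5 * (cross + cross.T), g.sample_ids, "CORE")
    logger.info(
        "core_greml_kernel: smallest eigenvalue %.3e", K.min_eigenvalue()
    )
    return K


def normalise_kernel(k: Kernel) -> Kernel:
    """Scale the kernel so its mean diagonal equals 1.

    Puts kernels on a comparable scale before variance-component estimation;
    idempotent.
    """
    d = k.diag_mean
    if abs(d) < 1e-300:
        raise ValueError(f"{k.kind} kernel has zero mean diagonal")
    return replace(k, matrix=k.matrix / d)
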