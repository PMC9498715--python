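"""Synthetic holo-omics datasets with a known variance decomposition.

Emulates the structure of livestock holo-omics studies — dense biallelic SNP
genotypes, compositional 16S OTU count tables, a farm-style fixed effect and a
diet-style class effect. Samples belong to herd/family-like groups: group
allele frequencies follow a Balding-Nichols model around the global
frequencies, and each group has its own microbiome base composition. This
gives the GRM and MRM the block relatedness real animal data carry; without
it the interaction kernel G ∘ M degenerates towards the identity and the
interaction variance cannot be separated from noise.

The phenotype is composed as

    y = fixed + g + m + gm + e

where the random components are zero-mean Gaussian vectors with covariances
``G var_g``, ``M var_m`` and ``(G ∘ M) var_gm`` built from the simulated data
itself (kernels normalised to mean diagonal 1 first), and ``e`` is iid noise.
The realised component vectors and target fractions are stored so parameter
recovery and model ranking can be checked against ground truth.

The interaction component is generated under the Hadamard kernel; an optional
``gm_correlation`` mixes a shared latent vector into g and m to exercise
covariance-between-effects (CORE) modelling. Neither choice asserts anything
about real biology — they define testable conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .kernels import (
    GenotypeMatrix,
    Kernel,
    OTUTable,
    compute_grm,
    compute_mrm,
    core_greml_kernel,
    hadamard_kernel,
    normalise_kernel,
)
from .model import PhenotypeTable

__all__ = ["SimulationParams", "SyntheticDataset", "simulate_holoomics", "write_dataset"]

_MIN_MAF = 0.01  # SNPs whose realised MAF falls below this are redrawn


@dataclass
class SimulationParams:
    """Generative settings for one synthetic holo-omics dataset.

    Variance fractions must sum to 1 (phenotypes are on the unit-variance
    scale). ``n_groups`` and ``fst`` control herd/family structure: samples
    in the same group share Balding-Nichols allele frequencies (Var[p_g] =
    Fst p (1-p)) and a group microbiome base composition whose spread around
    the global base is set by ``otu_group_concentration`` (smaller = more
    between-group variation). ``otu_concentration`` is the per-sample
    Dirichlet concentration around the group base — small values give
    sparse, overdispersed tables so the prevalence filter has bite.
    """

    n_samples: int = 400
    n_snps: int = 1000
    n_otus: int = 200
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_groups: int = 25
    fst: float = 0.1
    otu_concentration: float = 0.3
    otu_group_concentration: float = 3.0
    sequencing_depth: int = 10_000
    var_g: float = 0.3
    var_m: float = 0.3
    var_gm: float = 0.1
    var_e: float = 0.3
    fixed_effect_levels: int = 3
    class_effect_levels: int = 4
    gm_correlation: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        total = self.var_g + self.var_m + self.var_gm + self.var_e
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                "variance fractions must sum to 1: "
                f"var_g={self.var_g}, var_m={self.var_m}, "
                f"var_gm={self.var_gm}, var_e={self.var_e} (sum {total})"
            )
        if min(self.var_g, self.var_m, self.var_gm, self.var_e) < 0:
            raise ValueError("variance fractions must be non-negative")
        for name in ("n_samples", "n_snps", "n_otus", "sequencing_depth",
                     "fixed_effect_levels", "class_effect_levels"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie within (0, 0.5], got {self.maf_range}")
        if self.n_groups < 1:
            raise ValueError("n_groups must be >= 1")
        if not 0.0 <= self.fst < 1.0:
            raise ValueError("fst must be in [0, 1)")
        if not 0.0 <= self.gm_correlation <= 1.0:
            raise ValueError("gm_correlation must be in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")


@dataclass
class SyntheticDataset:
    """A simulated dataset plus the ground truth that generated it."""

    params: SimulationParams
    genotypes: GenotypeMatrix
    otus: OTUTable
    phenotypes: PhenotypeTable
    kernels: dict[str, Kernel]
    true_components: dict[str, np.ndarray]  # fixed, g, m, gm, e
    true_variances: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = self.params.n_samples
        for name, v in self.true_components.items():
            if v.shape != (n,):
                raise ValueError(f"component {name!r} has wrong length")
        total = sum(self.true_components[c] for c in ("fixed", "g", "m", "gm", "e"))
        if np.abs(self.phenotypes.y - total).max() > 1e-10:
            raise AssertionError("phenotype does not equal the sum of its components")


def _draw_gaussian_effect(rng: np.random.Generator, K: Kernel, variance: float) -> np.ndarray:
    """Zero-mean Gaussian vector with covariance K * variance (PSD square root)."""
    n = K.n_samples
    if variance == 0.0:
        return np.zeros(n)
    d, U = np.linalg.eigh(K.matrix)
    d = np.clip(d, 0.0, None)
    z = rng.standard_normal(n)
    return (U * np.sqrt(d)) @ z * np.sqrt(variance)


def _correlated_effects(
    rng: np.random.Generator,
    G: Kernel,
    M: Kernel,
    var_g: float,
    var_m: float,
    rho: float,
) -> tuple[np.ndarray, np.ndarray]:
    """g and m with optional correlation via a shared latent sample vector.

    With ``rho = 0`` (the default) the effects are independent, each with its
    own kernel covariance. With ``rho > 0`` a shared latent vector drawn on
    the blended kernel ``(G + M)/2`` is mixed into both effects, so that
    corr(g_i, m_i) ~ rho while each marginal stays a unit-diagonal kernel
    blend. This is a stand-in mechanism to exercise covariance-between-effects
    (CORE) modelling, not a claim about biology.
    """
    n = G.n_samples
    if rho == 0.0:
        return (_draw_gaussian_effect(rng, G, var_g),
                _draw_gaussian_effect(rng, M, var_m))
    shared_kernel = Kernel(0.5 * (G.matrix + M.matrix), G.sample_ids, "GRM")
    s = _draw_gaussian_effect(rng, normalise_kernel(shared_kernel), 1.0)
    g0 = _draw_gaussian_effect(rng, G, 1.0)
    m0 = _draw_gaussian_effect(rng, M, 1.0)
    g = np.sqrt(var_g) * (np.sqrt(1.0 - rho) * g0 + np.sqrt(rho) * s)
    m = np.sqrt(var_m) * (np.sqrt(1.0 - rho) * m0 + np.sqrt(rho) * s)
    return g, m


def _group_labels(rng: np.random.Generator, n: int, n_groups: int) -> np.ndarray:
    """Balanced random assignment of samples to herd-like groups."""
    return rng.permutation(np.arange(n) % n_groups)


def _group_freqs(rng: np.random.Generator, p_global: np.ndarray,
                 n_groups: int, fst: float) -> np.ndarray:
    """Balding-Nichols group allele frequencies around the global ones.

    Per group g and SNP m, p_gm ~ Beta(p (1-F)/F, (1-p)(1-F)/F) so that
    E[p_gm] = p and Var[p_gm] = F p (1-p). F = 0 collapses to a single
    undifferentiated population.
    """
    if fst == 0.0 or n_groups == 1:
        return np.tile(p_global, (n_groups, 1))
    a = p_global * (1.0 - fst) / fst
    b = (1.0 - p_global) * (1.0 - fst) / fst
    return np.clip(rng.beta(a, b, size=(n_groups, len(p_global))), 1e-4, 1 - 1e-4)


def _simulate_genotypes(rng: np.random.Generator, params: SimulationParams,
                        groups: np.ndarray) -> GenotypeMatrix:
    n, p = params.n_samples, params.n_snps
    lo, hi = params.maf_range
    freqs = rng.uniform(lo, hi, size=p)
    gfreq = _group_freqs(rng, freqs, params.n_groups, params.fst)
    Z = rng.binomial(2, gfreq[groups]).astype(float)
    # redraw SNPs whose realised MAF dropped below the hard floor
    for _ in range(100):
        realised = Z.mean(axis=0) / 2.0
        bad = np.minimum(realised, 1.0 - realised) < _MIN_MAF
        if not bad.any():
            break
        nb = int(bad.sum())
        freqs[bad] = rng.uniform(lo, hi, size=nb)
        gf = _group_freqs(rng, freqs[bad], params.n_groups, params.fst)
        Z[:, bad] = rng.binomial(2, gf[groups])
    if params.missing_rate > 0:
        mask = rng.random(Z.shape) < params.missing_rate
        Z[mask] = np.nan
    ids = [f"S{i + 1:04d}" for i in range(n)]
    snps = [f"snp{j + 1:05d}" for j in range(p)]
    return GenotypeMatrix(Z, ids, snps)


def _simulate_otus(rng: np.random.Generator, params: SimulationParams,
                   sample_ids: list[str], groups: np.ndarray) -> OTUTable:
    n, q = params.n_samples, params.n_otus
    base = rng.dirichlet(np.ones(q))
    # herd-level community compositions cluster around the global base
    group_base = np.vstack([
        rng.dirichlet(base * q * params.otu_group_concentration + 1e-3)
        for _ in range(params.n_groups)
    ])
    counts = np.empty((n, q), dtype=float)
    for i in range(n):
        alpha = group_base[groups[i]] * q * params.otu_concentration + 1e-6
        p_i = rng.dirichlet(alpha)
        counts[i] = rng.multinomial(params.sequencing_depth, p_i)
    otus = [f"OTU{j + 1:04d}" for j in range(q)]
    return OTUTable(counts, sample_ids, otus, is_relative=False)


def simulate_holoomics(params: SimulationParams) -> SyntheticDataset:
    """Generate genotypes, OTU counts, covariates and a decomposed phenotype.

    Same parameters (including seed) produce byte-identical output.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_samples

    groups = _group_labels(rng, n, params.n_groups)
    geno = _simulate_genotypes(rng, params, groups)
    otus = _simulate_otus(rng, params, geno.sample_ids, groups)

    G = normalise_kernel(compute_grm(geno))
    M = normalise_kernel(compute_mrm(otus))
    K_h = normalise_kernel(hadamard_kernel(G, M))
    K_c = normalise_kernel(core_greml_kernel(G, M))
    kernels = {"GRM": G, "MRM": M, "HADAMARD": K_h, "CORE": K_c}

    g, m = _correlated_effects(rng, G, M, params.var_g, params.var_m,
                               params.gm_correlation)
    gm = _draw_gaussian_effect(rng, K_h, params.var_gm)
    e = rng.standard_normal(n) * np.sqrt(params.var_e)

    farm = rng.integers(params.fixed_effect_levels, size=n)
    diet = rng.integers(params.class_effect_levels, size=n)
    farm_eff = rng.normal(0.0, 0.3, size=params.fixed_effect_levels)
    farm_eff -= farm_eff.mean()  # a single level is exactly "no effect"
    diet_eff = rng.normal(0.0, 0.2, size=params.class_effect_levels)
    diet_eff -= diet_eff.mean()
    fixed = farm_eff[farm] + diet_eff[diet]

    y = fixed + g + m + gm + e
    pheno = PhenotypeTable(
        y,
        geno.sample_ids,
        fixed_covariates=pd.DataFrame(
            {"farm": [f"farm{v + 1}" for v in farm]}, index=geno.sample_ids
        ),
        class_effects=pd.DataFrame(
            {"diet": [f"diet{v + 1}" for v in diet]}, index=geno.sample_ids
        ),
    )
    return SyntheticDataset(
        params=params,
        genotypes=geno,
        otus=otus,
        phenotypes=pheno,
        kernels=kernels,
        true_components={"fixed": fixed, "g": g, "m": m, "gm": gm, "e": e},
        true_variances={
            "g": params.var_g, "m": params.var_m,
            "gm": params.var_gm, "e": params.var_e,
        },
    )


def write_dataset(ds: SyntheticDataset, directory: str | Path) -> dict[str, Path]:
    """Write genotype TSV, OTU TSV and phenotype CSV; returns the file paths.

    Formats match the readers in :mod:`holopred.io`; a read round-trip
    reproduces the matrices exactly. The directory is created on demand.
    """
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
    except OSError as e:
        raise OSError(f"cannot create output directory {directory}: {e}") from e

    paths = {
        "genotypes": directory / "genotypes.tsv",
        "otus": directory / "otu_table.tsv",
        "phenotypes": directory / "phenotypes.csv",
    }
    geno_df = pd.DataFrame(ds.genotypes.dosages,
                           index=ds.genotypes.sample_ids,
                           columns=ds.genotypes.snp_ids)
    # integer dosages with NA for missing
    geno_df = geno_df.astype("Int64")
    geno_df.index.name = "sample_id"
    geno_df.to_csv(paths["genotypes"], sep="\t", na_rep="NA")

    otu_df = pd.DataFrame(ds.otus.counts.astype(int),
                          index=ds.otus.sample_ids,
                          columns=ds.otus.otu_ids)
    otu_df.index.name = "sample_id"
    otu_df.to_csv(paths["otus"], sep="\t")

    ph = ds.phenotypes
    pheno_df = pd.DataFrame({"y": ph.y}, index=ph.sample_ids)
    if ph.fixed_covariates is not None:
        for c in ph.fixed_covariates.columns:
            pheno_df[c] = ph.fixed_covariates[c].to_numpy()
    if ph.class_effects is not None:
        for c in ph.class_effects.columns:
            pheno_df[c] = ph.class_effects[c].to_numpy()
    pheno_df.index.name = "sample_id"
    pheno_df.to_csv(paths["phenotypes"])
    return paths
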