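"""Generative models for the eQTL power study.

Five scenarios are supported, all built on the same base model:

* ``LE``  - SNPs in linkage equilibrium (the base scenario),
* ``LD``  - SNPs correlated within consecutive blocks (Gaussian copula),
* ``GE``  - the analysed genotypes carry random genotyping errors while the
  expression is generated from the uncorrupted genotypes,
* ``LV``  - smaller eQTL effect-size variance than residual variance,
* ``Dom`` - dominance deviations added on top of the additive effects.

The base model: per-SNP allele frequencies are Beta(0.7, 0.7) draws truncated
by redraw to (0.05, 0.95); dosages are Binomial(2, p_i) under Hardy-Weinberg
equilibrium; each SNP receives a per-SNP trans-eQTL probability from
Beta(0.0004, 10) applied Bernoulli-wise across all features, plus a
Bernoulli(0.05) cis-eQTL on its index-matched feature; effect sizes at
flagged pairs are N(0, sigma_beta^2) with no minimum effect imposed; the
expression matrix is dosage x effects plus iid N(0, sigma_eps^2) noise.

``truth_orientation`` controls how the truth roster is recorded relative to
the generated signals.  ``"aligned"`` (the default contract) records the
truth exactly as generated: the signal for truth pair (SNP i, feature j)
sits in feature j.  ``"swapped"`` records the roster with the SNP and
feature axes interchanged while the expression is generated from the
unswapped effects: on a square SNP-by-feature grid the two conventions are
superficially interchangeable (the cis diagonal is invariant under the
swap), but trans signals then sit at the mirror image of their recorded
pairs.  Downstream detection-vs-truth scoring under the swapped convention
produces the "tip of the iceberg" regime — a few percent sensitivity, trans
truth essentially unrecoverable, thousands of real associations counted as
false positives — which is the operating regime the power study
reproduces.  See docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import sparse, stats

SCENARIOS = ("LE", "LD", "GE", "LV", "Dom")

#: pseudo-chromosome labels used for simulated SNP/feature maps
CHROMOSOMES = tuple(str(c) for c in range(1, 23)) + ("X",)

#: length assigned to each pseudo-chromosome, in base pairs
CHROM_LENGTH = 200_000_000

_MAX_REDRAWS = 1_000_000


# ---------------------------------------------------------------------------
# configuration and domain types


@dataclass(frozen=True)
class GenotypeErrorModel:
    """Row-stochastic 3x3 genotype confusion matrix.

    ``matrix[g_true, g_obs]`` is the probability of recording dosage
    ``g_obs`` when the true dosage is ``g_true``.
    """

    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError("error model must be a 3x3 matrix")
        if (m < 0).any():
            raise ValueError("error model entries must be non-negative")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("error model rows must sum to 1 within 1e-12")
        object.__setattr__(self, "matrix", m)

    @classmethod
    def identity(cls) -> "GenotypeErrorModel":
        return cls(np.eye(3))

    @classmethod
    def default_microarray(cls) -> "GenotypeErrorModel":
        """Default array-vs-sequencing confusion: ~1% misclassification,
        biased towards calling heterozygotes."""
        return cls(
            np.array(
                [
                    [0.9900, 0.0095, 0.0005],
                    [0.0050, 0.9900, 0.0050],
                    [0.0005, 0.0095, 0.9900],
                ]
            )
        )


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulation scenario.

    Defaults are the power-study conditions: a 20,000 x 20,000 SNP-by-feature
    grid and the Beta/Bernoulli/normal generative parameters described in the
    module docstring.
    """

    n_snp: int = 20_000
    n_trs: int = 20_000
    n_sample: int = 150
    freq_shape_a: float = 0.7
    freq_shape_b: float = 0.7
    freq_min: float = 0.05
    freq_max: float = 0.95
    trans_shape_a: float = 0.0004
    trans_shape_b: float = 10.0
    cis_prob: float = 0.05
    sigma_beta: Optional[float] = None  # resolved per scenario
    sigma_eps: float = 1.0
    sigma_dom: float = 0.25
    scenario: str = "LE"
    cis_band_halfwidth: int = 0
    ld_block_size: int = 10
    ld_rho: float = 0.8
    error_model: Optional[GenotypeErrorModel] = None
    truth_orientation: str = "aligned"
    seed: int = 0

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; one of {SCENARIOS}")
        if not (0 < self.freq_min < self.freq_max < 1):
            raise ValueError("require 0 < freq_min < freq_max < 1")
        if not (0 <= self.cis_prob <= 1):
            raise ValueError("cis_prob must be a probability")
        for name in ("sigma_eps", "sigma_dom"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.sigma_beta is not None and self.sigma_beta <= 0:
            raise ValueError("sigma_beta must be > 0")
        if self.scenario == "LD":
            if not (0 <= self.ld_rho < 1):
                raise ValueError("ld_rho must be in [0, 1)")
            if self.ld_block_size < 1:
                raise ValueError("ld_block_size must be >= 1")
        if self.truth_orientation not in ("aligned", "swapped"):
            raise ValueError("truth_orientation must be 'aligned' or 'swapped'")
        if self.truth_orientation == "swapped" and self.n_snp != self.n_trs:
            raise ValueError("swapped truth orientation requires n_snp == n_trs")
        if min(self.n_snp, self.n_trs, self.n_sample) < 1:
            raise ValueError("n_snp, n_trs and n_sample must be positive")

    @property
    def resolved_sigma_beta(self) -> float:
        """sigma_beta default: 0.85 for the low-variance scenario, else 1.15."""
        if self.sigma_beta is not None:
            return self.sigma_beta
        return 0.85 if self.scenario == "LV" else 1.15

    @property
    def resolved_error_model(self) -> GenotypeErrorModel:
        if self.error_model is not None:
            return self.error_model
        return GenotypeErrorModel.default_microarray()


def _uniform_map(n: int, prefix: str):
    """Spread n loci uniformly, in index order, over the 23 pseudo-chromosomes."""
    idx = np.arange(n)
    chrom_idx = (idx * len(CHROMOSOMES)) // max(n, 1)
    counts = np.bincount(chrom_idx, minlength=len(CHROMOSOMES))
    pos = np.empty(n, dtype=np.int64)
    for c in range(len(CHROMOSOMES)):
        sel = chrom_idx == c
        k = counts[c]
        if k:
            pos[sel] = (np.arange(k) + 1) * (CHROM_LENGTH // (k + 1))
    return pd.DataFrame(
        {
            "id": [f"{prefix}{i}" for i in idx],
            "chromosome": [CHROMOSOMES[c] for c in chrom_idx],
            "position": pos,
        }
    )


@dataclass
class GenotypeMatrix:
    """Allele-dosage matrix (n_sample x n_snp, values 0/1/2) with a SNP map."""

    dosages: np.ndarray
    snp_map: pd.DataFrame  # columns: id, chromosome, position

    def __post_init__(self):
        d = np.asarray(self.dosages)
        if d.ndim != 2:
            raise ValueError("dosage matrix must be 2-D (samples x SNPs)")
        if not np.isin(np.unique(d), [0, 1, 2]).all():
            raise ValueError("dosages must be in {0, 1, 2}")
        self.dosages = d

    @property
    def n_sample(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snp(self) -> int:
        return self.dosages.shape[1]


@dataclass
class EffectArchitecture:
    """The simulation truth: flagged SNP-feature pairs and their effects.

    Stored sparsely: parallel arrays of SNP index, feature index, additive
    effect beta, dominance deviation and a cis flag.  The cis and trans
    indicator sets are disjoint by construction.
    """

    n_snp: int
    n_trs: int
    snp_idx: np.ndarray
    feat_idx: np.ndarray
    beta: np.ndarray
    dom: np.ndarray
    is_cis: np.ndarray

    @property
    def n_eqtl(self) -> int:
        return len(self.snp_idx)

    def pair_keys(self, mask=None) -> np.ndarray:
        """Flat pair keys snp_idx * n_trs + feat_idx (sorted not guaranteed)."""
        keys = self.snp_idx.astype(np.int64) * self.n_trs + self.feat_idx
        return keys if mask is None else keys[mask]

    def truth_at(self, k: float) -> np.ndarray:
        """Boolean mask of truth pairs with |beta| >= k."""
        if k < 0:
            raise ValueError("k must be >= 0")
        return np.abs(self.beta) >= k

    def beta_matrix(self) -> sparse.csr_matrix:
        return sparse.coo_matrix(
            (self.beta, (self.snp_idx, self.feat_idx)), shape=(self.n_snp, self.n_trs)
        ).tocsr()

    def dom_matrix(self) -> sparse.csr_matrix:
        return sparse.coo_matrix(
            (self.dom, (self.snp_idx, self.feat_idx)), shape=(self.n_snp, self.n_trs)
        ).tocsr()

    def swapped(self) -> "EffectArchitecture":
        """The roster with SNP and feature axes interchanged (square grids)."""
        if self.n_snp != self.n_trs:
            raise ValueError("axis swap requires a square SNP-by-feature grid")
        return EffectArchitecture(
            self.n_snp,
            self.n_trs,
            self.feat_idx.copy(),
            self.snp_idx.copy(),
            self.beta.copy(),
            self.dom.copy(),
            self.is_cis.copy(),
        )


@dataclass
class ExpressionMatrix:
    """Real-valued expression matrix (n_sample x n_trs) with feature ids."""

    values: np.ndarray
    feature_map: pd.DataFrame  # columns: id, chromosome, position

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if not np.isfinite(v).all():
            raise ValueError("expression values must be finite")
        self.values = v


# ---------------------------------------------------------------------------
# operations


def draw_allele_freqs(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Draw per-SNP allele frequencies from a truncated Beta distribution.

    Out-of-range draws are redrawn, not clipped (clipping would create atoms
    at the bounds).  A hard cap on redraws guards against configurations whose
    acceptance region has vanishing mass.
    """
    p = rng.beta(config.freq_shape_a, config.freq_shape_b, config.n_snp)
    bad = (p <= config.freq_min) | (p >= config.freq_max)
    tries = 0
    while bad.any():
        tries += 1
        if tries > _MAX_REDRAWS:
            raise RuntimeError("allele-frequency redraw cap exceeded; check bounds")
        p[bad] = rng.beta(config.freq_shape_a, config.freq_shape_b, int(bad.sum()))
        bad = (p <= config.freq_min) | (p >= config.freq_max)
    return p


def simulate_genotypes(
    freqs: np.ndarray, n_sample: int, rng: np.random.Generator
) -> GenotypeMatrix:
    """Independent Hardy-Weinberg dosages: each entry ~ Binomial(2, p_i)."""
    freqs = np.asarray(freqs, dtype=float)
    dos = rng.binomial(2, freqs, size=(n_sample, len(freqs))).astype(np.int8)
    return GenotypeMatrix(dos, _uniform_map(len(freqs), "snp"))


def simulate_genotypes_ld(
    freqs: np.ndarray,
    n_sample: int,
    block_size: int,
    rho: float,
    rng: np.random.Generator,
) -> GenotypeMatrix:
    """Block-correlated dosages via a Gaussian copula.

    SNPs are partitioned into consecutive blocks of ``block_size``.  Within a
    block a latent standard-normal vector with equicorrelation ``rho`` is
    thresholded per SNP at the Hardy-Weinberg genotype quantiles, so marginal
    genotype frequencies are exactly (1-p)^2, 2p(1-p), p^2 while dosages are
    positively dependent within the block.  Blocks are independent.
    """
    if not (0 <= rho < 1):
        raise ValueError("rho must be in [0, 1)")
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    freqs = np.asarray(freqs, dtype=float)
    n_snp = len(freqs)
    # shared-factor construction of the equicorrelated latent
    common = rng.standard_normal((n_sample, int(np.ceil(n_snp / block_size))))
    idio = rng.standard_normal((n_sample, n_snp))
    block_of = np.arange(n_snp) // block_size
    z = np.sqrt(rho) * common[:, block_of] + np.sqrt(1.0 - rho) * idio
    # thresholds from HWE genotype frequencies (frequency of the counted allele)
    q0 = stats.norm.ppf((1.0 - freqs) ** 2)  # below: dosage 0
    q1 = stats.norm.ppf(1.0 - freqs**2)  # between: dosage 1; above: dosage 2
    dos = (z > q0).astype(np.int8) + (z > q1).astype(np.int8)
    return GenotypeMatrix(dos, _uniform_map(n_snp, "snp"))


def apply_genotyping_error(
    G: GenotypeMatrix, error_model: GenotypeErrorModel, rng: np.random.Generator
) -> GenotypeMatrix:
    """Independently resample every dosage from its confusion-matrix row.

    Returns the corrupted matrix that the mapper analyses; the caller keeps
    the uncorrupted matrix for expression generation.
    """
    cum = np.cumsum(error_model.matrix, axis=1)
    u = rng.random(G.dosages.shape)
    # observed dosage = number of cumulative cells strictly below u
    thresholds = cum[G.dosages.astype(np.intp), :]
    obs = (u[..., None] > thresholds[..., :2]).sum(axis=-1).astype(np.int8)
    return GenotypeMatrix(obs, G.snp_map)


def simulate_architecture(
    config: SimulationConfig, rng: np.random.Generator
) -> EffectArchitecture:
    """Draw the truth: trans/cis indicators and effect sizes.

    Per SNP i the trans probability is a Beta(a, b) draw applied
    Bernoulli-wise to every feature (equivalently a Binomial count with
    uniformly placed columns); cis indicators are Bernoulli(cis_prob) on the
    index-matched diagonal pairs (optionally a band of configurable
    half-width).  Effects at flagged pairs are N(0, sigma_beta^2); for the
    dominance scenario an extra N(0, sigma_dom^2) deviation is drawn at the
    same flagged pairs.
    """
    n_snp, n_trs = config.n_snp, config.n_trs
    p_trans = rng.beta(config.trans_shape_a, config.trans_shape_b, n_snp)
    counts = rng.binomial(n_trs, p_trans)
    snp_parts, feat_parts, cis_parts = [], [], []
    for i in np.nonzero(counts)[0]:
        cols = rng.choice(n_trs, counts[i], replace=False)
        snp_parts.append(np.full(counts[i], i, dtype=np.int64))
        feat_parts.append(cols.astype(np.int64))
    # cis pairs: diagonal band, index-matched up to min(n_snp, n_trs)
    w = config.cis_band_halfwidth
    diag = np.arange(min(n_snp, n_trs))
    for off in range(-w, w + 1):
        i = diag
        j = diag + off
        ok = (j >= 0) & (j < n_trs)
        i, j = i[ok], j[ok]
        hit = rng.random(len(i)) < config.cis_prob
        snp_parts.append(i[hit])
        feat_parts.append(j[hit])
        cis_parts.append(np.ones(int(hit.sum()), dtype=bool))
    snp_idx = np.concatenate(snp_parts) if snp_parts else np.empty(0, dtype=np.int64)
    feat_idx = np.concatenate(feat_parts) if feat_parts else np.empty(0, dtype=np.int64)
    is_cis = np.zeros(len(snp_idx), dtype=bool)
    n_cis = sum(len(c) for c in cis_parts)
    if n_cis:
        is_cis[-n_cis:] = True
    # cis and trans indicator sets must be disjoint: drop trans duplicates of cis pairs
    keys = snp_idx * np.int64(n_trs) + feat_idx
    order = np.lexsort((~is_cis, keys))  # cis first within a duplicated key
    keys_sorted = keys[order]
    keep_sorted = np.ones(len(keys), dtype=bool)
    keep_sorted[1:] = keys_sorted[1:] != keys_sorted[:-1]
    keep = np.zeros(len(keys), dtype=bool)
    keep[order] = keep_sorted
    snp_idx, feat_idx, is_cis = snp_idx[keep], feat_idx[keep], is_cis[keep]

    beta = rng.normal(0.0, config.resolved_sigma_beta, len(snp_idx))
    if config.scenario == "Dom":
        dom = rng.normal(0.0, config.sigma_dom, len(snp_idx))
    else:
        dom = np.zeros(len(snp_idx))
    return EffectArchitecture(n_snp, n_trs, snp_idx, feat_idx, beta, dom, is_cis)


def simulate_expression(
    G_true: GenotypeMatrix,
    arch: EffectArchitecture,
    sigma_eps: float,
    rng: np.random.Generator,
) -> ExpressionMatrix:
    """Expression = dosage x effects (+ heterozygosity x dominance) + noise.

    Y = G B + H D + E, where H is the heterozygosity indicator recoding of
    the dosages (1 where dosage = 1, else 0) and E has iid N(0, sigma_eps^2)
    entries.  D is all-zero outside the dominance scenario.
    """
    if G_true.n_snp != arch.n_snp:
        raise ValueError("genotype/architecture SNP dimensions differ")
    B = arch.beta_matrix()
    D = arch.dom_matrix()
    Gd = G_true.dosages.astype(np.float64)
    Y = Gd @ B
    Y = np.asarray(Y)
    if D.nnz:
        H = (G_true.dosages == 1).astype(np.float64)
        Y = Y + np.asarray(H @ D)
    if sigma_eps > 0:
        Y = Y + rng.normal(0.0, sigma_eps, Y.shape)
    return ExpressionMatrix(Y, _uniform_map(arch.n_trs, "trs"))


@dataclass
class ScenarioData:
    """Complete output of one scenario replicate.

    ``architecture`` is the truth roster that downstream scoring compares
    detections against; under the swapped truth orientation it differs from
    ``generative_architecture``, the roster the expression was built from.
    """

    config: SimulationConfig
    freqs: np.ndarray
    genotypes_true: GenotypeMatrix
    genotypes_analysed: GenotypeMatrix
    architecture: EffectArchitecture
    generative_architecture: EffectArchitecture
    expression: ExpressionMatrix


def simulate_scenario(config: SimulationConfig) -> ScenarioData:
    """Run the full generative model for one replicate.

    Child random streams are spawned per component in a fixed order, so the
    LE and GE scenarios share identical architecture and expression for the
    same seed and differ only in the analysed genotype matrix.
    """
    ss = np.random.SeedSequence(config.seed)
    r_freq, r_geno, r_arch, r_noise, r_extra = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )
    freqs = draw_allele_freqs(config, r_freq)
    if config.scenario == "LD":
        G = simulate_genotypes_ld(
            freqs, config.n_sample, config.ld_block_size, config.ld_rho, r_geno
        )
    else:
        G = simulate_genotypes(freqs, config.n_sample, r_geno)
    arch = simulate_architecture(config, r_arch)
    expr = simulate_expression(G, arch, config.sigma_eps, r_noise)
    if config.scenario == "GE":
        G_analysed = apply_genotyping_error(G, config.resolved_error_model, r_extra)
    else:
        G_analysed = G
    truth = arch.swapped() if config.truth_orientation == "swapped" else arch
    return ScenarioData(config, freqs, G, G_analysed, truth, arch, expr)


def scenario_config(scenario: str, n_sample: int, seed: int, **overrides) -> SimulationConfig:
    """Convenience constructor for a study-grid cell."""
    return replace(
        SimulationConfig(scenario=scenario, n_sample=n_sample, seed=seed), **overrides
    )
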