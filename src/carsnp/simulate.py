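"""Synthetic mini-exome GWAS generator.

Emulates the structure of unrelated-sample exome association panels used to
benchmark SNP selection: a few hundred samples, thousands of SNPs grouped
into genes, substantial within-gene linkage, a minor-allele-frequency
spectrum with a large rare-variant component (MAF < 0.01), a sparse causal
set, and a phenotype whose in-sample heritability is fixed by design.

Genotypes come from a Gaussian copula: per gene a latent multivariate normal
with exchangeable correlation rho_g, each coordinate thresholded into
{0, 1, 2} so the marginal matches Binomial(2, maf).  Genes are mutually
independent, so linkage exists only within genes.  Causal effect sizes follow
the empirical pattern that rarer causal variants carry larger effects:
beta ∝ (2 maf (1 - maf))^(-gamma/2) with gamma = 0.5 by default, random sign.

Phenotypes are y = X_std beta + noise with the noise variance chosen so the
realized in-sample Var(g)/Var(y) equals the design heritability exactly.

``gaw17_like_presets`` provides three ready-made designs mirroring published
benchmark phenotypes: Q1-like (n=697, 39 causal SNPs in 9 genes, h2=0.44),
Q2-like (n=697, 72 causal in 13 genes, h2=0.29, rarer causal variants) and
Q4-like (no genetic component), each with B=200 replicates by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MafSpectrum",
    "GeneBlock",
    "SimulationDesign",
    "SimulationTruth",
    "simulate_genotypes",
    "simulate_phenotype",
    "gaw17_like_presets",
]


@dataclass(frozen=True)
class MafSpectrum:
    """Mixture of rare and common minor-allele frequencies.

    rare variants are drawn log-uniformly on (rare_low, rare_high) and common
    ones log-uniformly on (common_low, common_high); ``rare_fraction`` sets
    the mixture weight of the rare component.
    """

    rare_fraction: float = 0.5
    rare_low: float = 0.001
    rare_high: float = 0.01
    common_low: float = 0.01
    common_high: float = 0.5

    def sample(self, size: int, rng: np.random.Generator) -> np.ndarray:
        rare = rng.random(size) < self.rare_fraction
        out = np.empty(size)
        lo = np.where(rare, self.rare_low, self.common_low)
        hi = np.where(rare, self.rare_high, self.common_high)
        out = np.exp(rng.uniform(np.log(lo), np.log(hi)))
        return out


@dataclass(frozen=True)
class GeneBlock:
    gene_id: str
    snp_count: int
    rho: float  # exchangeable within-gene latent correlation, 0 <= rho < 1

    def __post_init__(self) -> None:
        if not (0.0 <= self.rho < 1.0):
            raise ValueError(f"gene {self.gene_id}: rho must lie in [0, 1)")
        if self.snp_count < 1:
            raise ValueError(f"gene {self.gene_id}: need at least one SNP")


@dataclass
class SimulationDesign:
    """Complete recipe for one synthetic study."""

    n: int
    genes: list[GeneBlock]
    maf_distribution: MafSpectrum = field(default_factory=MafSpectrum)
    causal: list[tuple[str, float]] = field(default_factory=list)
    heritability: float = 0.0
    replicates: int = 200
    seed: int = 0
    synonymous_fraction: float = 0.3
    #: optional pre-drawn per-SNP MAFs (aligned with snp_ids); sampled from
    #: maf_distribution at genotype time when absent
    maf_values: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.heritability < 1.0):
            raise ValueError("heritability must lie in [0, 1)")
        ids = set(self.snp_ids)
        for snp, _ in self.causal:
            if snp not in ids:
                raise ValueError(f"causal SNP {snp} not present in the design")

    @property
    def d(self) -> int:
        return sum(g.snp_count for g in self.genes)

    @property
    def snp_ids(self) -> np.ndarray:
        ids = []
        for g in self.genes:
            ids.extend(f"{g.gene_id}_s{k + 1:03d}" for k in range(g.snp_count))
        return np.array(ids)


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth attached to one simulated phenotype replicate."""

    causal_ids: np.ndarray
    betas: np.ndarray
    mafs: np.ndarray  # realized sample MAFs of the causal SNPs
    heritability: float  # realized in-sample Var(g)/Var(y)
    replicate: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"snp_id": self.causal_ids, "beta": self.betas, "maf": self.mafs}
        )


def _threshold_genotypes(z: np.ndarray, maf: float) -> np.ndarray:
    """Map standard-normal latents to {0,1,2} with Binomial(2, maf) marginals."""
    p0 = (1.0 - maf) ** 2
    p1 = 2.0 * maf * (1.0 - maf)
    t0 = stats.norm.ppf(p0)
    t1 = stats.norm.ppf(p0 + p1)
    return (z > t0).astype(np.int8) + (z > t1).astype(np.int8)


def simulate_genotypes(
    design: SimulationDesign, seed: int | None = None
) -> tuple[np.ndarray, pd.DataFrame]:
    """Draw the genotype matrix and its annotation table for a design.

    Within a gene the latent normals share an exchangeable correlation rho_g
    (one common factor); genes are independent.  A column that comes out
    monomorphic is redrawn up to 10 times before erroring.  Deterministic
    given (design, seed); ``seed`` defaults to ``design.seed``.
    """
    if seed is None:
        seed = design.seed
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0)))
    snp_ids = design.snp_ids
    if design.maf_values is not None:
        mafs = np.asarray(design.maf_values, dtype=np.float64)
        if mafs.size != design.d:
            raise ValueError("maf_values length does not match design dimension")
    else:
        mafs = design.maf_distribution.sample(design.d, rng)
    x = np.empty((design.n, design.d), dtype=np.int8)
    genes = np.empty(design.d, dtype=object)
    col = 0
    for g in design.genes:
        shared = rng.standard_normal((design.n, 1))
        for _ in range(g.snp_count):
            maf = mafs[col]
            for attempt in range(11):
                eps = rng.standard_normal(design.n)
                z = np.sqrt(g.rho) * shared[:, 0] + np.sqrt(1.0 - g.rho) * eps
                geno = _threshold_genotypes(z, maf)
                if geno.min() != geno.max():
                    break
            else:
                raise ValueError(
                    f"SNP {snp_ids[col]} (maf={maf:.2e}) monomorphic after 10 resamples; "
                    "increase n or the MAF floor"
                )
            x[:, col] = geno
            genes[col] = g.gene_id
            col += 1
    synonymous = rng.random(design.d) < design.synonymous_fraction
    causal_map = dict(design.causal)
    # causal SNPs are by definition functional
    is_causal = np.array([s in causal_map for s in snp_ids])
    synonymous[is_causal] = False
    annotation = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "gene_id": genes,
            "synonymous": synonymous,
            "is_causal": is_causal,
            "maf": x.mean(axis=0) / 2.0,
            "beta": [causal_map.get(s, 0.0) for s in snp_ids],
        }
    )
    return x, annotation


def simulate_phenotype(
    x: np.ndarray,
    design: SimulationDesign,
    replicate_index: int = 0,
    covariates: bool = False,
) -> tuple["PhenotypeVector", SimulationTruth]:
    """Draw one phenotype replicate on a fixed genotype matrix.

    The genetic component is g = X_std beta over the causal set, standardized
    per column; noise is Gaussian and scaled so that the in-sample
    Var(g)/Var(y) equals the design heritability exactly.  Each replicate
    uses a fresh noise stream derived from ``design.seed XOR replicate_index``
    (tagged so it never collides with the genotype stream).
    """
    from .preprocess import PhenotypeVector  # local import to avoid a cycle

    x = np.asarray(x)
    if x.shape != (design.n, design.d):
        raise ValueError("genotype matrix does not match the design dimensions")
    h2 = design.heritability
    if h2 > 0.0 and not design.causal:
        raise ValueError("positive heritability requires a non-empty causal set")
    rng = np.random.default_rng(
        np.random.SeedSequence((design.seed ^ replicate_index, 1, replicate_index))
    )
    snp_ids = design.snp_ids
    eps = rng.standard_normal(design.n)
    if design.causal and h2 > 0.0:
        idx = {s: j for j, s in enumerate(snp_ids)}
        cols = np.array([idx[s] for s, _ in design.causal])
        betas = np.array([b for _, b in design.causal])
        xc = x[:, cols].astype(np.float64)
        sd = xc.std(axis=0, ddof=1)
        if np.any(sd == 0):
            bad = snp_ids[cols[sd == 0]]
            raise ValueError(f"causal SNP(s) monomorphic in sample: {', '.join(bad)}")
        g = ((xc - xc.mean(axis=0)) / sd) @ betas
        # project the noise off g in-sample so Var(y) = Var(g) + Var(eps)
        # exactly, making the realized heritability equal h2 by construction
        eps = eps - eps.mean()
        eps = eps - g * (eps @ g) / (g @ g)
        eps *= g.std(ddof=1) / eps.std(ddof=1) * np.sqrt((1.0 - h2) / h2)
        y = g + eps
        realized = float(g.var(ddof=1) / y.var(ddof=1))
    else:
        cols = np.array([], dtype=int)
        betas = np.array([])
        y = eps
        realized = 0.0
    cov = None
    if covariates:
        # generic sex/age/smoking-like covariates, additive on y
        sex = rng.integers(0, 2, design.n).astype(float)
        age = rng.normal(50.0, 10.0, design.n)
        smoke = rng.integers(0, 2, design.n).astype(float)
        cov = np.column_stack([sex, age, smoke])
        y = y + 0.5 * sex + 0.02 * (age - 50.0) + 0.3 * smoke
    truth = SimulationTruth(
        causal_ids=snp_ids[cols] if cols.size else np.array([], dtype=object),
        betas=betas,
        mafs=x[:, cols].mean(axis=0) / 2.0 if cols.size else np.array([]),
        heritability=realized,
        replicate=replicate_index,
    )
    return PhenotypeVector(y, covariates=cov, id=f"rep{replicate_index}"), truth


def _build_preset(
    name: str,
    n: int,
    d: int,
    n_causal: int,
    n_causal_genes: int,
    h2: float,
    rare_fraction: float,
    causal_rare_tilt: float,
    replicates: int,
    seed: int,
    gamma: float = 0.5,
) -> SimulationDesign:
    rng = np.random.default_rng(np.random.SeedSequence((seed, 17)))
    # partition d SNPs into genes of realistic, varying size (~20 SNPs/gene,
    # smaller when d is too small to host the required causal genes)
    mean_size = 20
    if n_causal_genes:
        mean_size = int(np.clip(d // (2 * n_causal_genes), 3, 20))
    sizes: list[int] = []
    remaining = d
    while remaining > 0:
        s = int(min(remaining, max(3, rng.poisson(mean_size))))
        sizes.append(s)
        remaining -= s
    rhos = rng.uniform(0.05, 0.6, len(sizes))
    genes = [
        GeneBlock(f"G{k + 1:04d}", sz, float(r))
        for k, (sz, r) in enumerate(zip(sizes, rhos))
    ]
    design = SimulationDesign(
        n=n,
        genes=genes,
        maf_distribution=MafSpectrum(rare_fraction=rare_fraction),
        heritability=h2,
        replicates=replicates,
        seed=seed,
    )
    mafs = design.maf_distribution.sample(design.d, rng)
    causal: list[tuple[str, float]] = []
    if n_causal > 0:
        snp_ids = design.snp_ids
        gene_of = np.repeat(np.arange(len(genes)), [g.snp_count for g in genes])
        eligible = [k for k, g in enumerate(genes) if g.snp_count >= 3]
        causal_genes = rng.choice(eligible, size=n_causal_genes, replace=False)
        # split the causal count across the chosen genes
        counts = np.full(n_causal_genes, n_causal // n_causal_genes)
        counts[: n_causal % n_causal_genes] += 1
        chosen: list[int] = []
        for gk, ck in zip(causal_genes, counts):
            members = np.flatnonzero(gene_of == gk)
            ck = min(int(ck), members.size)
            chosen.extend(rng.choice(members, size=ck, replace=False))
        # spill over if some genes were too small to host their share
        while len(chosen) < n_causal:
            extra = int(rng.integers(0, design.d))
            if extra not in chosen:
                chosen.append(extra)
        for j in chosen:
            # tilt causal variants toward the rare end of the spectrum
            if rng.random() < causal_rare_tilt:
                mafs[j] = float(
                    np.exp(rng.uniform(np.log(0.001), np.log(0.01)))
                )
            het = 2.0 * mafs[j] * (1.0 - mafs[j])
            beta = het ** (-gamma / 2.0) * rng.choice([-1.0, 1.0])
            causal.append((snp_ids[j], float(beta)))
    design.causal = causal
    design.maf_values = mafs
    design.__post_init__()  # re-validate with the causal set attached
    return design


def gaw17_like_presets(
    d: int = 2000, replicates: int = 200, seed: int = 0
) -> dict[str, SimulationDesign]:
    """Benchmark-style designs with known causal structure.

    Q1like: 39 causal SNPs in 9 genes, h2 = 0.44 (strong, moderate-MAF
    signals); Q2like: 72 causal SNPs in 13 genes, h2 = 0.29 with rarer causal
    variants; Q4like: heritability 0 with an empty causal set.  All use
    n = 697 samples; ``d`` defaults to a desk-scale 2,000 SNPs (set 8020 to
    mirror the benchmark's dimension).
    """
    return {
        "Q1like": _build_preset(
            "Q1like", n=697, d=d, n_causal=39, n_causal_genes=9, h2=0.44,
            rare_fraction=0.5, causal_rare_tilt=0.4, replicates=replicates,
            seed=seed,
        ),
        "Q2like": _build_preset(
            "Q2like", n=697, d=d, n_causal=72, n_causal_genes=13, h2=0.29,
            rare_fraction=0.6, causal_rare_tilt=0.7, replicates=replicates,
            seed=seed + 1,
        ),
        "Q4like": _build_preset(
            "Q4like", n=697, d=d, n_causal=0, n_causal_genes=0, h2=0.0,
            rare_fraction=0.5, causal_rare_tilt=0.0, replicates=replicates,
            seed=seed + 2,
        ),
    }
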