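"""Forward-in-time synthetic data generator.

The generator emulates the statistical structure the downstream association
analysis assumes: a random-mating population with a small target effective
size, a genome of equally spaced biallelic SNP, equal-effect QTNs placed at
SNP positions, and a single phenotypic record per individual.

Two stages:

1. ``build_founders`` — a Wright–Fisher burn-in at constant size ``Ne``
   (recommended length ``≥ 4·Ne`` generations) that takes an initially
   linkage-equilibrium pool to drift–recombination quasi-equilibrium, so the
   founder LD tracks the Sved curve ``E(r²) = 1/(4cNe + 1)``.  A small
   recurrent per-locus mutation rate keeps loci from all fixing.
2. ``gene_drop`` — an explicit-pedigree expansion: a base generation sampled
   from the founder pool followed by discrete generations of random mating
   with a fixed number of sires and dams, two progeny of alternating sex per
   mating, recombination but no mutation.

Meiosis draws a Poisson number of crossovers per chromosome (mean = map
length in Morgan), uniform positions, no interference.

Genotypes are additive 0/1/2 codes; "genotyped" individuals are those in the
last three generations, mirroring a livestock evaluation where genomic data
exist only for recent cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenomeSpec",
    "MatingDesign",
    "FounderPool",
    "Population",
    "TraitArchitecture",
    "build_founders",
    "gene_drop",
    "assign_qtn",
    "simulate_phenotypes",
    "empirical_r2",
    "minor_allele_frequencies",
]


@dataclass(frozen=True)
class GenomeSpec:
    """Coordinate system: equally spaced SNP on equal-length chromosomes.

    Positions are Morgans internally; the first SNP of each chromosome sits
    at 0 and adjacent SNP are ``1/(100·snps_per_cm)`` Morgan apart.
    """

    n_chrom: int = 10
    chrom_length: float = 1.0  # Morgan per chromosome
    snps_per_cm: int = 50

    def __post_init__(self):
        if self.n_chrom < 1:
            raise ValueError("n_chrom must be >= 1")
        if self.chrom_length <= 0:
            raise ValueError("chrom_length (Morgan) must be > 0")
        if self.snps_per_cm < 1:
            raise ValueError("snps_per_cm must be >= 1")

    @property
    def snps_per_chrom(self) -> int:
        return int(round(self.chrom_length * 100.0 * self.snps_per_cm))

    @property
    def n_snp(self) -> int:
        return self.n_chrom * self.snps_per_chrom

    @property
    def spacing(self) -> float:
        """Distance between adjacent SNP, Morgan."""
        return 1.0 / (100.0 * self.snps_per_cm)

    def positions_within_chrom(self) -> np.ndarray:
        """Within-chromosome SNP positions in Morgan (identical per chromosome)."""
        return np.arange(self.snps_per_chrom) * self.spacing

    def chrom_slice(self, k: int) -> slice:
        if not 0 <= k < self.n_chrom:
            raise IndexError(f"chromosome {k} out of range")
        m = self.snps_per_chrom
        return slice(k * m, (k + 1) * m)

    def chrom_of_snp(self) -> np.ndarray:
        """0-based chromosome index for every SNP."""
        return np.repeat(np.arange(self.n_chrom), self.snps_per_chrom)

    def map_table(self) -> pd.DataFrame:
        """Tidy SNP map: 0-based snp_index, 1-based chrom, position in cM."""
        pos_cm = np.tile(self.positions_within_chrom() * 100.0, self.n_chrom)
        return pd.DataFrame(
            {
                "snp_index": np.arange(self.n_snp),
                "chrom": self.chrom_of_snp() + 1,
                "pos_cm": pos_cm,
            }
        )


@dataclass(frozen=True)
class MatingDesign:
    """Discrete-generation random-mating design.

    Each generation, ``n_sires`` males and ``n_dams`` females are sampled
    from the previous generation; every dam is mated once to a random
    selected sire and produces two progeny of opposite sex, so the
    generation size is ``2·n_dams``.  The implied effective size is
    ``4·s·d/(s + d)``.
    """

    n_sires: int
    n_dams: int
    base_size: int
    n_generations: int = 9  # post-base

    def __post_init__(self):
        if min(self.n_sires, self.n_dams, self.base_size) < 1:
            raise ValueError("n_sires, n_dams and base_size must be >= 1")
        if self.n_generations < 1:
            raise ValueError("n_generations must be >= 1")
        if self.n_sires > self.generation_size // 2 or self.n_dams > self.generation_size // 2:
            raise ValueError(
                "selected parents per sex cannot exceed the per-sex generation size"
            )
        if self.n_sires > self.base_size // 2 or self.n_dams > self.base_size // 2:
            raise ValueError("base population too small for the requested parents")

    @property
    def generation_size(self) -> int:
        return 2 * self.n_dams

    @property
    def implied_ne(self) -> float:
        s, d = self.n_sires, self.n_dams
        return 4.0 * s * d / (s + d)

    @property
    def total_size(self) -> int:
        return self.base_size + self.n_generations * self.generation_size


@dataclass
class FounderPool:
    """Burn-in output: a pool of haplotypes near drift–recombination balance."""

    spec: GenomeSpec
    haplotypes: np.ndarray  # (2*ne, n_snp) uint8
    ne: int
    burn_in: int

    @property
    def n_individuals(self) -> int:
        return self.haplotypes.shape[0] // 2

    @property
    def genotypes(self) -> np.ndarray:
        return (self.haplotypes[0::2] + self.haplotypes[1::2]).astype(np.int8)

    @property
    def polymorphic_mask(self) -> np.ndarray:
        freq = self.haplotypes.mean(axis=0)
        return (freq > 0.0) & (freq < 1.0)


@dataclass
class Population:
    """Gene-drop output: explicit pedigree plus per-individual haplotypes."""

    spec: GenomeSpec
    design: MatingDesign
    pedigree: pd.DataFrame  # id, sire, dam, sex, generation (ids 1-based, 0 = unknown)
    haplotypes: np.ndarray  # (2*n, n_snp) uint8, rows 2i/2i+1 belong to individual i
    n_genotyped_generations: int = 3
    _genotypes: np.ndarray | None = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return len(self.pedigree)

    @property
    def generation(self) -> np.ndarray:
        return self.pedigree["generation"].to_numpy()

    @property
    def genotyped_mask(self) -> np.ndarray:
        last = self.generation.max()
        return self.generation > last - self.n_genotyped_generations

    @property
    def genotyped_idx(self) -> np.ndarray:
        return np.flatnonzero(self.genotyped_mask)

    @property
    def genotypes(self) -> np.ndarray:
        """Additive 0/1/2 codes for every individual, (n, n_snp) int8."""
        if self._genotypes is None:
            self._genotypes = (self.haplotypes[0::2] + self.haplotypes[1::2]).astype(np.int8)
        return self._genotypes


@dataclass
class TraitArchitecture:
    """Truth for profiling: QTN positions and the common additive effect.

    ``effect`` is filled in by :func:`simulate_phenotypes`, which rescales
    the common allele-substitution effect so the base-generation additive
    variance equals ``sigma2_u`` exactly.
    """

    qtn_indices: np.ndarray
    sigma2_u: float = 1.0
    sigma2_e: float = 1.0
    effect: float | None = None

    def __post_init__(self):
        self.qtn_indices = np.asarray(self.qtn_indices, dtype=int)
        if self.sigma2_u <= 0 or self.sigma2_e < 0:
            raise ValueError("sigma2_u must be > 0 and sigma2_e >= 0")

    @property
    def h2(self) -> float:
        return self.sigma2_u / (self.sigma2_u + self.sigma2_e)


# ---------------------------------------------------------------------------
# meiosis


def _gametes(hap0: np.ndarray, hap1: np.ndarray, spec: GenomeSpec,
             rng: np.random.Generator) -> np.ndarray:
    """Batch of recombinant gametes, one per row of the parent pair arrays.

    Per chromosome and meiosis: Poisson(L) crossovers, uniform positions, no
    interference, random starting phase.  ``hap0``/``hap1`` are the (K,
    n_snp) maternal/paternal haplotypes of the K parents.
    """
    k_batch = hap0.shape[0]
    out = np.empty_like(hap0)
    m = spec.snps_per_chrom
    pos = spec.positions_within_chrom()
    for k in range(spec.n_chrom):
        sl = slice(k * m, (k + 1) * m)
        n_x = rng.poisson(spec.chrom_length, size=k_batch)
        cuts = rng.uniform(0.0, spec.chrom_length, n_x.sum())
        row = np.repeat(np.arange(k_batch), n_x)
        col = np.searchsorted(pos, cuts, side="left")
        switch = np.zeros((k_batch, m + 1), dtype=np.int32)
        np.add.at(switch, (row, col), 1)
        phase = (np.cumsum(switch[:, :m], axis=1)
                 + rng.integers(0, 2, size=(k_batch, 1))) & 1
        out[:, sl] = np.where(phase == 0, hap0[:, sl], hap1[:, sl])
    return out


def _gamete(hap0: np.ndarray, hap1: np.ndarray, spec: GenomeSpec,
            rng: np.random.Generator) -> np.ndarray:
    """Single recombinant gamete (batch of one)."""
    return _gametes(hap0[None, :], hap1[None, :], spec, rng)[0]


def _mutate_batch(gam: np.ndarray, mutation_rate: float,
                  rng: np.random.Generator) -> None:
    """Recurrent symmetric mutation: flip alleles at rate µ per locus per
    gamete (Poissonised count over the batch)."""
    if mutation_rate <= 0.0:
        return
    n_mut = rng.poisson(mutation_rate * gam.size)
    if n_mut:
        rows = rng.integers(0, gam.shape[0], size=n_mut)
        cols = rng.integers(0, gam.shape[1], size=n_mut)
        gam[rows, cols] ^= 1


def _distinct_pairs(n: int, k: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """k pairs of distinct uniform indices in [0, n)."""
    first = rng.integers(0, n, size=k)
    second = (first + 1 + rng.integers(0, n - 1, size=k)) % n
    return first, second


def _wright_fisher_generation(hap: np.ndarray, n_offspring: int,
                              spec: GenomeSpec, rng: np.random.Generator,
                              mutation_rate: float) -> np.ndarray:
    """One generation of random mating (distinct parents) at a given size."""
    n_cur = hap.shape[0] // 2
    nxt = np.empty((2 * n_offspring, spec.n_snp), dtype=np.uint8)
    sires, dams = _distinct_pairs(n_cur, n_offspring, rng)
    for j, parents in enumerate((sires, dams)):
        gam = _gametes(hap[2 * parents], hap[2 * parents + 1], spec, rng)
        _mutate_batch(gam, mutation_rate, rng)
        nxt[j::2] = gam
    return nxt


# ---------------------------------------------------------------------------
# founders


def build_founders(spec: GenomeSpec, ne: int, burn_in: int | None = None,
                   mutation_rate: float = 1e-4, seed=None,
                   init_freq_range: tuple[float, float] = (0.2, 0.8),
                   ancestral_ne: int | None = None,
                   decline_generations: int | None = None) -> FounderPool:
    """Wright–Fisher burn-in that builds the founder LD structure.

    Two modes:

    * constant size (``ancestral_ne=None``): ``burn_in`` generations
      (default ``4·ne``) at size ``ne``, from a linkage-equilibrium start
      with per-locus allele frequencies drawn uniformly from
      ``init_freq_range``.  Approaches drift–recombination equilibrium, so
      the binned r² tracks ``1/(4cNe+1)``; diversity erodes on the same
      time scale.  ``burn_in = 0`` returns the equilibrium-free start.
    * declining size (``ancestral_ne`` set): a geometric size decline from
      ``ancestral_ne`` to ``ne`` over ``decline_generations`` (default
      ``3·ne``) followed by ``burn_in`` (default ``ne``) generations held
      at ``ne``.  This emulates a population whose effective size shrank
      from a large ancestral value: deep coalescence keeps heterozygosity
      high while the recent small-``ne`` epoch builds the short-range LD.

    The default mutation rate is small enough (``8·Ne·µ ≪ 4·Ne·c`` at the
    SNP spacings of interest) not to perturb the Sved decay, while
    re-seeding variation lost to drift over long burn-ins.
    """
    if ne < 2:
        raise ValueError("ne must be >= 2")
    if burn_in is None:
        burn_in = ne if ancestral_ne is not None else 4 * ne
    if burn_in < 0:
        raise ValueError("burn_in must be >= 0")
    if mutation_rate < 0:
        raise ValueError("mutation_rate must be >= 0")
    rng = np.random.default_rng(seed)

    sizes = np.full(burn_in, ne, dtype=int)
    n_start = ne
    if ancestral_ne is not None:
        if ancestral_ne < ne:
            raise ValueError("ancestral_ne must be >= ne")
        if decline_generations is None:
            decline_generations = 3 * ne
        if decline_generations < 1:
            raise ValueError("decline_generations must be >= 1")
        t = np.arange(1, decline_generations + 1)
        decline = np.round(
            ancestral_ne * (ne / ancestral_ne) ** (t / decline_generations)
        ).astype(int)
        sizes = np.concatenate([decline, sizes])
        n_start = ancestral_ne

    lo, hi = init_freq_range
    freqs = rng.uniform(lo, hi, size=spec.n_snp)
    hap = (rng.random((2 * n_start, spec.n_snp)) < freqs).astype(np.uint8)
    for n_next in sizes:
        hap = _wright_fisher_generation(hap, int(n_next), spec, rng, mutation_rate)

    pool = FounderPool(spec=spec, haplotypes=hap, ne=ne, burn_in=int(len(sizes)))
    if not pool.polymorphic_mask.any():
        raise RuntimeError(
            "burn-in produced an all-monomorphic pool; increase mutation_rate "
            "or shorten burn_in"
        )
    return pool


# ---------------------------------------------------------------------------
# gene drop

_SEX_M, _SEX_F = 0, 1


def gene_drop(founders: FounderPool, design: MatingDesign,
              seed=None, n_genotyped_generations: int = 3) -> Population:
    """Drop founder haplotypes through an explicit random-mating pedigree.

    The base generation (generation 0, unknown parents) consists of
    ``design.base_size`` offspring of random pairs from the founder pool,
    so base individuals already carry equilibrium LD.  Generations 1..G are
    produced by the mating design; recombination only, no mutation.
    """
    spec = founders.spec
    rng = np.random.default_rng(seed)
    n_total = design.total_size

    hap = np.empty((2 * n_total, spec.n_snp), dtype=np.uint8)
    sire = np.zeros(n_total, dtype=np.int64)   # 1-based ids, 0 unknown
    dam = np.zeros(n_total, dtype=np.int64)
    sex = np.empty(n_total, dtype=np.int8)
    gen = np.empty(n_total, dtype=np.int16)

    pool_hap = founders.haplotypes
    n_pool = founders.n_individuals

    nb = design.base_size
    a_idx, b_idx = _distinct_pairs(n_pool, nb, rng)
    hap[0:2 * nb:2] = _gametes(pool_hap[2 * a_idx], pool_hap[2 * a_idx + 1], spec, rng)
    hap[1:2 * nb:2] = _gametes(pool_hap[2 * b_idx], pool_hap[2 * b_idx + 1], spec, rng)
    sex[:nb] = np.arange(nb) % 2
    gen[:nb] = 0

    prev = np.arange(nb)
    row = nb
    for g in range(1, design.n_generations + 1):
        males = prev[sex[prev] == _SEX_M]
        females = prev[sex[prev] == _SEX_F]
        sires = rng.choice(males, size=design.n_sires, replace=False)
        dams = rng.choice(females, size=design.n_dams, replace=False)
        # each dam mated once to a random selected sire, two progeny each
        mate_sire = sires[rng.integers(0, design.n_sires, size=design.n_dams)]
        s_rep = np.repeat(mate_sire, 2)
        d_rep = np.repeat(dams, 2)
        cur = np.arange(row, row + 2 * design.n_dams)
        hap[2 * cur] = _gametes(hap[2 * s_rep], hap[2 * s_rep + 1], spec, rng)
        hap[2 * cur + 1] = _gametes(hap[2 * d_rep], hap[2 * d_rep + 1], spec, rng)
        sire[cur] = s_rep + 1
        dam[cur] = d_rep + 1
        sex[cur] = np.tile([_SEX_M, _SEX_F], design.n_dams)
        gen[cur] = g
        prev = cur
        row += cur.size

    pedigree = pd.DataFrame(
        {
            "id": np.arange(1, n_total + 1),
            "sire": sire,
            "dam": dam,
            "sex": sex,
            "generation": gen,
        }
    )
    return Population(
        spec=spec,
        design=design,
        pedigree=pedigree,
        haplotypes=hap,
        n_genotyped_generations=n_genotyped_generations,
    )


# ---------------------------------------------------------------------------
# trait


def assign_qtn(spec: GenomeSpec, per_chrom: int = 10, min_sep: int = 500,
               scheme: str = "equal", seed=None) -> np.ndarray:
    """Place ``per_chrom`` QTNs at SNP positions, identically on every
    chromosome, with within-chromosome separation ``>= min_sep`` SNP.

    ``scheme="equal"`` (default) spaces them deterministically;
    ``scheme="random"`` draws a seeded random pattern with the same gap
    guarantee.  Returns global (genome-wide) SNP indices.
    """
    m = spec.snps_per_chrom
    if per_chrom < 1 or min_sep < 1:
        raise ValueError("per_chrom and min_sep must be >= 1")
    if (per_chrom - 1) * min_sep > m - 1:
        raise ValueError(
            f"cannot place {per_chrom} QTN with separation {min_sep} on a "
            f"{m}-SNP chromosome"
        )
    if scheme == "equal":
        gap = m // per_chrom
        if gap < min_sep:
            raise ValueError(
                f"equal spacing {gap} SNP is below the required separation {min_sep}"
            )
        within = gap // 2 + gap * np.arange(per_chrom)
    elif scheme == "random":
        rng = np.random.default_rng(seed)
        slack = m - (per_chrom - 1) * min_sep
        base_pts = np.sort(rng.choice(slack, size=per_chrom, replace=False))
        within = base_pts + min_sep * np.arange(per_chrom)
    else:
        raise ValueError(f"unknown QTN placement scheme {scheme!r}")
    return (within[None, :] + m * np.arange(spec.n_chrom)[:, None]).ravel()


def simulate_phenotypes(pop: Population, arch: TraitArchitecture,
                        seed=None) -> pd.DataFrame:
    """Single phenotypic record per individual: ``y = g + e``.

    The true breeding value is ``g_i = a · Σ_q (x_iq − mean_base_q)`` over
    QTN genotype codes centred on the base-generation mean; the common
    effect ``a`` is rescaled so that the base-generation variance of ``g``
    equals ``sigma2_u`` exactly, and is stored on ``arch.effect``.
    Residuals are ``N(0, sigma2_e)``.
    """
    rng = np.random.default_rng(seed)
    x = pop.genotypes[:, arch.qtn_indices].astype(float)
    base = pop.generation == 0
    x -= x[base].mean(axis=0)
    g_raw = x.sum(axis=1)
    v = g_raw[base].var()
    if v <= 0.0:
        raise RuntimeError("all QTNs are monomorphic in the base generation")
    a = float(np.sqrt(arch.sigma2_u / v))
    arch.effect = a
    tbv = a * g_raw
    e = rng.normal(0.0, np.sqrt(arch.sigma2_e), size=pop.n) if arch.sigma2_e > 0 else 0.0
    return pd.DataFrame(
        {"id": pop.pedigree["id"], "phenotype": tbv + e, "tbv": tbv}
    )


# ---------------------------------------------------------------------------
# validation summaries


def empirical_r2(genotypes: np.ndarray, spec: GenomeSpec,
                 bin_edges: np.ndarray, maf_min: float = 0.0) -> pd.DataFrame:
    """Binned mean squared genotype correlation between within-chromosome
    SNP pairs, for validating simulated LD against the Sved curve.

    ``bin_edges`` are distances in Morgan.  Monomorphic SNP (and SNP below
    ``maf_min``) are excluded.  Returns one row per bin with the midpoint,
    mean r² and pair count.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges must be an increasing 1-D array")
    n_bins = edges.size - 1
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    pos = spec.positions_within_chrom()
    g = np.asarray(genotypes, dtype=float)
    n_ind = g.shape[0]
    if n_ind < 2:
        raise ValueError("need at least two individuals")

    for k in range(spec.n_chrom):
        sub = g[:, spec.chrom_slice(k)]
        p = sub.mean(axis=0) / 2.0
        maf = np.minimum(p, 1.0 - p)
        keep = maf > max(maf_min, 0.0)
        if keep.sum() < 2:
            continue
        sub = sub[:, keep]
        pk = pos[keep]
        z = sub - sub.mean(axis=0)
        z /= z.std(axis=0)
        corr = (z.T @ z) / n_ind
        r2 = corr**2
        iu, ju = np.triu_indices(len(pk), k=1)
        dist = pk[ju] - pk[iu]
        which = np.digitize(dist, edges) - 1
        ok = (which >= 0) & (which < n_bins)
        np.add.at(sums, which[ok], r2[iu[ok], ju[ok]])
        np.add.at(counts, which[ok], 1)

    with np.errstate(invalid="ignore"):
        mean_r2 = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame(
        {
            "dist_lo_morgan": edges[:-1],
            "dist_hi_morgan": edges[1:],
            "dist_mid_morgan": 0.5 * (edges[:-1] + edges[1:]),
            "mean_r2": mean_r2,
            "n_pairs": counts,
        }
    )


def minor_allele_frequencies(genotypes: np.ndarray) -> np.ndarray:
    """Per-SNP minor allele frequency from 0/1/2 codes; in [0, 0.5]."""
    p = np.asarray(genotypes, dtype=float).mean(axis=0) / 2.0
    return np.minimum(p, 1.0 - p)
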