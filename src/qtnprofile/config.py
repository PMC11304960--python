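"""Scenario configuration and presets.

A :class:`ScenarioConfig` bundles everything one run needs: genome geometry,
mating design, burn-in settings, trait architecture and analysis knobs.
Presets come in two tiers:

* full-scale scenarios ``NE60``, ``NE60_3x``, ``NE600`` — the reference
  study design (10 chromosomes × 100 cM × 50 SNP/cM, base 6,000, nine
  generations of 2,000 or 6,000, genotypes for the last three generations).
  These take hours on one core and exist for completeness and provenance.
* desk-scale scenarios ``desk_ne60``, ``desk_ne200``, ``desk_ne60_1x`` /
  ``desk_ne60_3x`` and the intermediate ``mid_ne60`` — the same structure
  with the genome and population shrunk so a run takes seconds to a couple
  of minutes, preserving the design ratios (two progeny per mating, last
  three generations genotyped, QTN separation ≈ 10 cM).

Configs round-trip through YAML.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

from .sim import GenomeSpec, MatingDesign

__all__ = ["ScenarioConfig", "PRESETS", "get_preset"]


@dataclass
class ScenarioConfig:
    name: str = "custom"
    # genome
    n_chrom: int = 10
    chrom_length: float = 1.0
    snps_per_cm: int = 50
    # founders / burn-in
    ne: int = 60                      # target (recent) effective size
    founder_history: str = "decline"  # "decline" (large ancestral Ne) or "constant"
    ancestral_ne: int | None = None   # decline start size; default 10*ne
    decline_generations: int | None = None  # decline length; default 3*ne
    burn_in: int | None = None        # held at ne; default ne (decline) / 4*ne (constant)
    mutation_rate: float = 1e-4
    # mating design
    n_sires: int = 15
    n_dams: int = 1000
    base_size: int = 6000
    n_generations: int = 9
    n_genotyped_generations: int = 3
    # trait
    qtn_per_chrom: int = 10
    qtn_min_sep: int = 500
    qtn_scheme: str = "equal"
    sigma2_u: float = 1.0
    sigma2_e: float = 1.0
    # analysis
    blend_alpha: float = 0.95
    tune_include_diagonal: bool = True
    sig_threshold: float = 1e-6
    profile_flank: int = 50
    fit_window_segments: float = 2.0
    window_snp: int | None = None     # moving-window size; default ≈ 8 Stam segments
    # bookkeeping
    seed: int = 0

    def __post_init__(self):
        self.validate()

    # -- derived objects ---------------------------------------------------
    @property
    def genome(self) -> GenomeSpec:
        return GenomeSpec(self.n_chrom, self.chrom_length, self.snps_per_cm)

    @property
    def design(self) -> MatingDesign:
        return MatingDesign(self.n_sires, self.n_dams, self.base_size,
                            self.n_generations)

    @property
    def h2(self) -> float:
        return self.sigma2_u / (self.sigma2_u + self.sigma2_e)

    def validate(self) -> None:
        if self.sigma2_u <= 0 or self.sigma2_e < 0:
            raise ValueError("sigma2_u must be > 0 and sigma2_e >= 0")
        if not 0.0 < self.h2 <= 1.0:
            raise ValueError(f"h2 = {self.h2} out of (0, 1]")
        if not 0.0 < self.blend_alpha <= 1.0:
            raise ValueError("blend_alpha must be in (0, 1]")
        if not 0.0 < self.sig_threshold < 1.0:
            raise ValueError("sig_threshold must be in (0, 1)")
        if self.ne < 2:
            raise ValueError("ne must be >= 2")
        if self.profile_flank < 1:
            raise ValueError("profile_flank must be >= 1")
        if self.founder_history not in ("decline", "constant"):
            raise ValueError("founder_history must be 'decline' or 'constant'")
        # these raise on inconsistency:
        self.genome
        self.design

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


def _preset(**kw) -> ScenarioConfig:
    return ScenarioConfig(**kw)


#: Named scenarios.  Implied Ne (4sd/(s+d)): NE60 ≈ 59.1, NE600 ≈ 595.7,
#: desk_ne60 ≈ 61.0, desk_ne200 = 200, desk_ne60_1x ≈ 59.2,
#: desk_ne60_3x ≈ 61.1, mid_ne60 ≈ 59.3.
PRESETS: dict[str, dict] = {
    # full-scale reference designs
    "NE60": dict(name="NE60", ne=60, n_sires=15, n_dams=1000, base_size=6000),
    "NE60_3x": dict(name="NE60_3x", ne=60, n_sires=15, n_dams=3000,
                    base_size=6000),
    "NE600": dict(name="NE600", ne=600, n_sires=175, n_dams=1000,
                  base_size=6000),
    # desk-scale: 2 chromosomes x 1 Morgan x 20 SNP/cM (4,000 SNP)
    "desk_ne60": dict(
        name="desk_ne60", n_chrom=2, snps_per_cm=20, ne=60,
        n_sires=18, n_dams=100, base_size=600,
        qtn_min_sep=200, profile_flank=20,
    ),
    "desk_ne200": dict(
        name="desk_ne200", n_chrom=2, snps_per_cm=20, ne=200,
        n_sires=100, n_dams=100, base_size=600,
        qtn_min_sep=200, profile_flank=20,
    ),
    # matched pair for the data-size contrast (same Ne, 3x the records)
    "desk_ne60_1x": dict(
        name="desk_ne60_1x", n_chrom=2, snps_per_cm=20, ne=60,
        n_sires=21, n_dams=50, base_size=300,
        qtn_min_sep=200, profile_flank=20,
    ),
    "desk_ne60_3x": dict(
        name="desk_ne60_3x", n_chrom=2, snps_per_cm=20, ne=60,
        n_sires=17, n_dams=150, base_size=900,
        qtn_min_sep=200, profile_flank=20,
    ),
    # intermediate scale: half the chromosomes at full SNP density
    "mid_ne60": dict(
        name="mid_ne60", n_chrom=5, snps_per_cm=50, ne=60,
        n_sires=16, n_dams=200, base_size=1200,
        qtn_min_sep=500, profile_flank=50,
    ),
    # full genome at full SNP density, population reduced ~2.5x
    "big_ne60": dict(
        name="big_ne60", n_chrom=10, snps_per_cm=50, ne=60,
        n_sires=16, n_dams=400, base_size=2400,
        qtn_min_sep=500, profile_flank=50,
    ),
}


def get_preset(name: str) -> ScenarioConfig:
    try:
        return _preset(**PRESETS[name])
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(sorted(PRESETS))}"
        ) from None
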