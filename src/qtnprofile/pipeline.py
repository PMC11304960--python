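"""Scenario orchestration: simulate → relate → solve → scan → profile.

``run_pipeline`` executes the whole chain for a :class:`ScenarioConfig` and
returns a :class:`PipelineResult` holding every intermediate artifact; with
an output directory it also writes the standard TSV/CSV files plus a JSON
run manifest (config, per-stage seeds, sizes, timings, content hashes of
the key outputs), enough to replay any stage alone.

Randomness: one master seed; independent named streams (founders, gene
drop, QTN placement, residuals) derived via ``numpy`` seed sequences, so a
stage can be re-run in isolation without disturbing the others.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as qio
from .config import ScenarioConfig
from .gwas import SnpScan, manhattan_table, snp_scan
from .mme import SsgblupFit, fit_ssgblup
from .profiles import (PldFit, QtnProfile, fit_pld_curve, pool_profile,
                       profile_width, window_variance)
from .relmat import (a_inverse, blend_and_tune, h_inverse,
                     numerator_relationship, vanraden_g)
from .sim import (Population, TraitArchitecture, assign_qtn, build_founders,
                  gene_drop, minor_allele_frequencies, simulate_phenotypes)
from .theory import decay_table, stam_segment_size

__all__ = ["PipelineResult", "run_pipeline", "make_fixtures"]

_STREAMS = ("founders", "gene_drop", "qtn", "residuals")


def _stage_seeds(master_seed: int) -> dict[str, int]:
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(len(_STREAMS))
    return {
        name: int(child.generate_state(1, dtype=np.uint32)[0])
        for name, child in zip(_STREAMS, children)
    }


@dataclass
class PipelineResult:
    config: ScenarioConfig
    seed: int
    population: Population
    arch: TraitArchitecture
    phenotypes: pd.DataFrame
    fit: SsgblupFit
    scan: SnpScan
    manhattan: pd.DataFrame
    profile: QtnProfile
    pld_fit: PldFit
    windows: pd.DataFrame
    width: dict
    rho: float
    delta: float
    p_freq: np.ndarray
    timings: dict = field(default_factory=dict)

    @property
    def implied_ne(self) -> float:
        return self.config.design.implied_ne


def run_pipeline(config: ScenarioConfig, seed: int | None = None,
                 outdir=None, compute_pev: bool = True,
                 free_haplotypes: bool = False) -> PipelineResult:
    """Run the full chain for one scenario.

    ``seed`` overrides ``config.seed``.  Identical (config, seed) pairs give
    identical outputs.  ``free_haplotypes`` drops the per-individual
    haplotype matrix once genotypes are formed, roughly halving the memory
    footprint of genome-scale runs.
    """
    seed = config.seed if seed is None else int(seed)
    seeds = _stage_seeds(seed)
    spec = config.genome
    design = config.design
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    if config.founder_history == "decline":
        ancestral = config.ancestral_ne or 10 * config.ne
        founders = build_founders(
            spec, config.ne, burn_in=config.burn_in,
            mutation_rate=config.mutation_rate, seed=seeds["founders"],
            ancestral_ne=ancestral,
            decline_generations=config.decline_generations)
    else:
        founders = build_founders(spec, config.ne, burn_in=config.burn_in,
                                  mutation_rate=config.mutation_rate,
                                  seed=seeds["founders"])
    timings["founders"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    pop = gene_drop(founders, design, seed=seeds["gene_drop"],
                    n_genotyped_generations=config.n_genotyped_generations)
    timings["gene_drop"] = time.perf_counter() - t0

    qtn = assign_qtn(spec, per_chrom=config.qtn_per_chrom,
                     min_sep=config.qtn_min_sep, scheme=config.qtn_scheme,
                     seed=seeds["qtn"])
    arch = TraitArchitecture(qtn_indices=qtn, sigma2_u=config.sigma2_u,
                             sigma2_e=config.sigma2_e)
    phen = simulate_phenotypes(pop, arch, seed=seeds["residuals"])
    geno = pop.genotypes[pop.genotyped_idx].astype(float)
    if free_haplotypes:
        pop.haplotypes = None

    # relationships
    t0 = time.perf_counter()
    g_idx = pop.genotyped_idx
    a = numerator_relationship(pop.pedigree)
    f = np.diag(a) - 1.0
    a22 = a[np.ix_(g_idx, g_idx)].copy()
    del a
    ainv = a_inverse(pop.pedigree, f=f)
    g_mat, p_freq = vanraden_g(geno)
    gb, rho, delta = blend_and_tune(g_mat, a22, alpha=config.blend_alpha,
                                    include_diagonal=config.tune_include_diagonal)
    hinv = h_inverse(ainv, a22, gb, g_idx)
    del ainv
    timings["relmat"] = time.perf_counter() - t0

    # mixed model
    t0 = time.perf_counter()
    fit = fit_ssgblup(phen["phenotype"].to_numpy(), np.arange(pop.n), hinv,
                      g_idx, sigma2_u=config.sigma2_u,
                      sigma2_e=config.sigma2_e, compute_pev=compute_pev)
    del hinv
    timings["solve"] = time.perf_counter() - t0

    # scan
    t0 = time.perf_counter()
    z = geno - 2.0 * p_freq
    scan = snp_scan(fit.u_hat[g_idx], z, gb, fit.c_u2u2, p_freq,
                    alpha=config.blend_alpha, delta=delta,
                    sigma2_u=config.sigma2_u, threshold=config.sig_threshold)
    man = manhattan_table(scan, spec.map_table())
    timings["scan"] = time.perf_counter() - t0

    # profile
    ne_prof = design.implied_ne
    profile = pool_profile(scan.a_hat, qtn, spec, flank=config.profile_flank)
    pld = fit_pld_curve(profile, ne_prof,
                        window_segments=config.fit_window_segments)
    width = profile_width(profile, a_hat=scan.a_hat, qtn_indices=qtn)
    w_snp = config.window_snp
    if w_snp is None:
        w_snp = max(int(round(8 * stam_segment_size(ne_prof) / spec.spacing)), 1)
    windows = window_variance(scan.a_hat, p_freq, spec, window_snp=w_snp)

    result = PipelineResult(
        config=config, seed=seed, population=pop, arch=arch, phenotypes=phen,
        fit=fit, scan=scan, manhattan=man, profile=profile, pld_fit=pld,
        windows=windows, width=width, rho=rho, delta=delta, p_freq=p_freq,
        timings=timings,
    )
    if outdir is not None:
        _write_outputs(result, outdir, seeds)
    return result


def _sha256(data: bytes) -> str:
    return hashlib.sha256(data).hexdigest()


def _write_outputs(res: PipelineResult, outdir, seeds: dict[str, int]) -> None:
    out = qio.ensure_dir(outdir)
    pop, spec = res.population, res.config.genome
    qio.write_pedigree(pop.pedigree, out / "pedigree.csv")
    qio.write_map(spec.map_table(), out / "snp_map.tsv")
    g_idx = pop.genotyped_idx
    qio.write_genotypes(pop.genotypes[g_idx], pop.pedigree["id"].to_numpy()[g_idx],
                        out / "genotypes.tsv")
    qio.write_phenotypes(res.phenotypes, out / "phenotypes.csv")
    res.manhattan.to_csv(out / "snp_scan.tsv", sep="\t", index=False)
    res.profile.to_frame().to_csv(out / "qtn_profile.tsv", sep="\t", index=False)
    pd.DataFrame([{
        "amplitude": res.pld_fit.amplitude,
        "intercept": res.pld_fit.intercept,
        "r_squared": res.pld_fit.r_squared,
        "window_segments": res.pld_fit.window_segments,
        "n_points": res.pld_fit.n_points,
    }]).to_csv(out / "pld_fit.tsv", sep="\t", index=False)
    res.windows.to_csv(out / "window_variance.tsv", sep="\t", index=False)
    decay_table(res.implied_ne).to_csv(out / "theory.tsv", sep="\t", index=False)

    sol = pd.DataFrame({
        "id": pop.pedigree["id"],
        "u_hat": res.fit.u_hat,
    })
    if res.fit.c_u2u2 is not None:
        pev = np.full(pop.n, np.nan)
        pev[g_idx] = res.fit.pev
        sol["pev"] = pev
    sol.to_csv(out / "solutions.tsv", sep="\t", index=False)

    manifest = {
        "scenario": res.config.name,
        "master_seed": res.seed,
        "stage_seeds": seeds,
        "config": res.config.to_dict(),
        "implied_ne": res.implied_ne,
        "n_individuals": int(pop.n),
        "n_genotyped": int(g_idx.size),
        "n_snp": int(spec.n_snp),
        "n_qtn": int(res.arch.qtn_indices.size),
        "realized_qtn_effect": res.arch.effect,
        "rho": res.rho,
        "delta": res.delta,
        "mu_hat": res.fit.mu_hat,
        "n_significant": res.scan.n_significant,
        "pld_fit_r2": res.pld_fit.r_squared,
        "profile_width_snp": res.width["width_snp"],
        "timings_s": {k: round(v, 3) for k, v in res.timings.items()},
        "hashes": {
            "pedigree": _sha256(pop.pedigree.to_csv(index=False).encode()),
            "a_hat": _sha256(res.scan.a_hat.tobytes()),
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)


def make_fixtures(seed: int = 0) -> dict:
    """Small deterministic datasets for unit tests and worked examples.

    Returns a dict with a hand-checkable trio pedigree, a toy genotype
    matrix with a known-frequency SNP set, and a 3-QTN effect vector whose
    pooled profile can be verified by hand.
    """
    rng = np.random.default_rng(seed)
    trio = pd.DataFrame(
        {"id": [1, 2, 3], "sire": [0, 0, 1], "dam": [0, 0, 2],
         "sex": [0, 1, 0], "generation": [0, 0, 1]}
    )
    toy_genotypes = rng.integers(0, 3, size=(8, 12)).astype(np.int8)
    effects = rng.normal(0.0, 0.01, size=33)
    qtn = np.array([5, 16, 27])
    effects[qtn] = 0.2
    return {"trio_pedigree": trio, "toy_genotypes": toy_genotypes,
            "effect_vector": effects, "qtn_indices": qtn}
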