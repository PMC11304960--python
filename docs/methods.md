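# Methods

This note documents the models, numerical choices and known limitations of
the package. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Segment and LD theory

Two closed forms drive everything. For a randomly mating population of
constant effective size Ne, the genome-wide expected number of founder
segments on *L* Morgan is 4·Ne·L, so the mean segment ("Stam segment") is
s = 1/(4·Ne) Morgan. The expected squared correlation between two loci at
genetic distance *c* Morgan is the Sved curve E(r²) = 1/(4cNe + 1). In
segment units the curve is universal: at k segments, E(r²) = 1/(k+1).

The variance-fraction relation treats the Sved curve as the expected shape
of a QTN's profile: a symmetric interval of total width *w* centred on the
QTN captures f = 1 − E(r²)(w/2) = w/(w+2) of the QTN's additive variance
(w in segments). This closed relation reproduces the standard
50% / 66.7% / 80% figures for 2 / 4 / 8-segment intervals and the
"80% within ±1/Ne Morgan" statement exactly. We present it as numerically
consistent with those figures, not as a first-principles derivation — the
profile-as-PLD assumption is a hypothesis that the simulation part of the
package exists to probe. Physical window sizes convert s to base pairs at
the genome-average bp/Morgan ratio; both conversions are linear, so the
printed species examples (2 Mb at Ne 100, 5 Mb at Ne 40, 20 kb at
Ne 10,000, on a 30-Morgan / 3-Gb genome) are exact.

Units: Morgans everywhere internally; cM only in files and tables.
Rounding for printed comparisons is round-half-even at the printed
precision. One wrinkle: the 4-segment fraction is exactly 2/3, which some
sources print truncated as 66%; the package reports 66.67.

## Synthetic-data generator

The generator emulates the statistical structure a single-step association
analysis sees, not any particular species' genome.

**Genome.** `n_chrom` equal chromosomes, equally spaced biallelic SNP
(default 10 × 100 cM × 50 SNP/cM = 50,000 SNP). Positions start at 0 per
chromosome with spacing 1/(100·snps_per_cm) Morgan.

**Meiosis.** Poisson(L) crossovers per chromosome per meiosis, uniform
positions, no interference, random starting phase; no mutation after the
founder stage. Implemented batch-wise (a whole generation of gametes per
call) with a cumulative-phase trick, so genome-scale gene drops run in
seconds.

**Founder LD.** Two burn-in modes.

* *Constant size* (default of `build_founders`): Ne diploids for ≥ 4·Ne
  generations from a linkage-equilibrium start (per-locus frequencies
  uniform on 0.2–0.8), with recurrent symmetric mutation at 10⁻⁴ per locus
  per gamete. This approaches drift–recombination equilibrium and the
  binned r² tracks the Sved curve within ±30% over 0.5–8 segment distances
  (verified in the suite over 5 seeds), but heterozygosity erodes on the
  same 2·Ne time scale.
* *Declining size* (default of the scenario presets): a geometric decline
  from an ancestral size of 10·Ne over 3·Ne generations, then Ne held for
  Ne generations. This mimics populations whose effective size shrank from
  a large ancestral value — deep coalescence keeps diversity high (mean
  2pq ≈ 0.16 at Ne = 60, so ~100 equal-effect QTNs rescale to a common
  effect of ≈ 0.24 trait units) while the recent small-Ne epoch builds the
  short-range LD the QTN profile lives on.

The decline parameters were fixed by two calibrations: the binned r² decay
against 1/(4cNe+1) (the check the theory itself supplies) and the
heterozygosity level implied by realistic rescaled QTN effects. Even so,
realized r² at sub-segment distances stays ~20–30% below the Sved value —
with a finite simulated history, very tight linkage reflects deep (large-Ne)
coalescence. Real coalescent machinery (e.g. msprime) would sharpen this,
at the cost of a second stochastic machinery to validate; the forward
burn-in keeps every base of the simulator under the same unit tests.

**Pedigree stage.** A base generation of `base_size` offspring of random
founder-pool pairs (unknown parents, generation 0), then discrete
generations: `n_sires` males and `n_dams` females sampled from the previous
generation, each dam mated once to a random selected sire, two progeny of
opposite sex per mating. Implied Ne = 4sd/(s+d). Genotypes are recorded
for the last three generations. Reference designs: 15/1,000 (Ne ≈ 59),
175/1,000 (Ne ≈ 596), 15/3,000 (Ne ≈ 59 with 3× records).

**Trait.** 10 QTNs per chromosome at SNP positions, identical pattern
across chromosomes, separation ≥ 500 SNP (≈ 10 cM at full density);
deterministic equal spacing by default, seeded random placement optional.
All QTNs share one additive effect, rescaled after the gene drop so the
base-generation variance of the true breeding values is exactly
σ²ᵤ = 1.00; residuals N(0, σ²ₑ = 1.00), h² = 0.5, one record per
individual. QTNs that drift to (near-)fixation are kept, not resampled —
they are part of the phenomenon (profiles vanish when only near-fixed QTNs
are pooled).

## Single-step machinery

A is built by the tabular method and A⁻¹ directly from Mendelian-sampling
variances with inbreeding (both dense; the package targets up to a few
thousand genotyped and a few tens of thousands of total animals). G uses
current-genotyped-population allele frequencies; monomorphic SNP contribute
zero while keeping their column so SNP coordinates never shift. Because
own-frequency centring makes G singular by construction (null vector 1),
G is blended, Gb = 0.95·G + 0.05·A22, before inversion. ρ averages all n²
elements of G − A22 (an off-diagonal-only switch exists), δ = 1 − ρ/2.
H⁻¹ adds Gb⁻¹ − A22⁻¹ into the genotyped block of A⁻¹ and is validated
against direct inversion of the joint (Legarra-form) H on small problems.

The mixed model y = 1μ + Wu + e is solved with variance components fixed
at the simulation truth (ratio λ = σ²ₑ/σ²ᵤ = 1, configurable). One dense
Cholesky factorization serves both the solution and the prediction-error
block C^{u2,u2} = σ²ₑ·[C⁻¹] over genotyped animal equations (solved
against unit columns rather than forming the full inverse).

SNP effects are back-solved as â = λ_SNP·αδ·DZ′Gb⁻¹û with D = I and
λ_SNP = 1/(2Σp(1−p)), the value consistent with the VanRaden scaling; it is
exposed in the configuration because it is a modelling choice, not an
estimate. With α = 1, D = I and everybody genotyped, the back-solved
effects equal a direct ridge-regression (SNP-BLUP) fit to machine
precision — the suite asserts correlation ≥ 0.9999 and agreement to 1e-9.
Per-SNP variances follow the quadratic form
λαδ·z′Gb⁻¹(Gbσ²ᵤ − C^{u2,u2})Gb⁻¹z·δαλ; negatives within −1e-10 are
clipped to zero, anything larger aborts. Note the direction of this
quantity: it is the variance of the *estimator*, which grows toward its
ceiling as data accumulate (it is exactly zero when C = Gbσ²ᵤ, i.e. no
information). p-values are 2(1 − Φ(|â/sd|)), threshold 10⁻⁶, SNP with zero
sd flagged and assigned p = 1.

## Profiles, fits, windows

Pooling averages |â| at each signed offset within ±flank SNP of every QTN
(signed averaging available; magnitudes are the default because profiles
are magnitude patterns and the pooled signed mean of flanking effects is
near zero). An optional filter keeps the k highest-MAF QTNs.

The PLD fit regresses the pooled profile on E(r²)(|offset|·spacing) over
offsets within ±2 Stam segments, excluding offset 0 (the QTN's own point is
direct signal, not linkage), with two free parameters: amplitude and an
intercept absorbing the noise floor. An amplitude-only mode exists; the
intercept is on by default because pooled |noise| has a folded-normal mean
that would otherwise bias the amplitude. R² = 1 − SSres/SStot over the
fitted points; a constant profile reports R² = 0 by convention (SStot = 0).
The fit is invariant to uniform rescaling of the profile.

Profile width is the contiguous span around offset 0 exceeding
mean + 1 SD of |â| over all non-QTN SNP (so the peak cannot inflate its own
threshold); a `capped` flag marks profiles exceeding the threshold
everywhere. Window variance assigns each SNP 2p(1−p)â² and reports disjoint
or sliding windows as percentages of the genome-wide total; disjoint
percentages sum to 100 exactly. The default window is ≈ 8 Stam segments,
the interval expected to hold 80% of a QTN's variance.

## Scenario presets and problem sizes

Full-scale presets (`NE60`, `NE60_3x`, `NE600`) carry the reference design
constants (50,000 SNP; 24,000 or 60,000 individuals; 6,000 or 18,000
genotyped) and are provided for completeness — at these sizes the dense
MME needs more than 8 GB and tens of minutes, so the routinely exercised
presets are reductions that preserve the design ratios:

| preset | genome | animals (genotyped) | implied Ne | runtime* |
|---|---|---|---|---|
| `desk_ne60` | 2 × 1 M × 20/cM (4,000 SNP) | 2,400 (600) | 61.0 | ~4 s |
| `desk_ne200` | same | 2,400 (600) | 200 | ~45 s |
| `desk_ne60_1x` / `_3x` | same | 1,200 (300) / 3,600 (900) | ~60 | ~3 / ~8 s |
| `mid_ne60` | 5 × 1 M × 50/cM (25,000 SNP) | 4,800 (1,200) | 59.3 | ~30 s |
| `big_ne60` | 10 × 1 M × 50/cM (50,000 SNP) | 9,600 (2,400) | 61.5 | ~100 s |

*one core; the large-Ne presets spend most time in the longer burn-in.

The acceptance script measures the profile-fit R² on `big_ne60` (the full
genome and QTN count, population reduced 2.5×), averaged over two seeds.
The pooled-profile R² is noise-limited: it scales with the number of QTNs
pooled and genotyped animals (measured here: ≈ 0.28 at desk scale,
≈ 0.5 at `big_ne60`), so values from reduced designs sit below what the
full design yields.

## Design notes and limitations

- Scenario orchestration is a library-first design; the CLI is a thin
  wrapper (`theory`, `run`, `presets`) because the granular stages are most
  useful as Python calls. Test fixtures are generated programmatically
  (`make_fixtures`, conftest) rather than shipped as files.
- Random numbers: one master seed per run, split into independent named
  streams (founders, gene drop, QTN placement, residuals) via seed
  sequences, recorded in the run manifest so any stage can be replayed.
- Dense linear algebra throughout; no sparse/iterative solvers, no APY
  approximation, no metafounders or unknown-parent groups, no
  variance-component estimation (components are the simulation truth), no
  multi-trait models, no selection or overlapping generations, no
  genotyping error or ascertainment-bias modelling.
- What passing tests show — and don't: the simulator reproduces the
  *statistical* structure assumed by the theory (Mendelian transmission,
  Poisson recombination, Sved-curve LD within tolerance, exact base-
  generation variance). It does not emulate sequence-level mutation
  processes, realistic allele-frequency ascertainment, or per-bp
  recombination maps, so absolute significance counts and profile widths
  from reduced designs should be read as qualitative.
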