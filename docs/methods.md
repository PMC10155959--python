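# Methods

## Model structure

The simulator couples three compartments through a shared daily loop.

**Tumor.** A tumor is a collection of lineages under common logistic growth
with lineage-specific death, `dN_i/dt = k_g N_i (1 − N/K)(1 − k_d,i)`. All
lineages share the birth rate `k_g` and carrying capacity `K`; they differ
only in their immunopeptidome (per-neoantigen expression flags × per-allele
MHC intactness flags) and hence in `k_d,i`. Mice start from a single lineage
of 4.77e7 cells (a 200 mm³ sphere at 4.19e-9 cm³/cell); humans from a single
founder cell whose clonal neoantigen count is a rounded Gamma(1.14, 56.24)
draw and which loses one of its three MHC alleles with probability 0.14.

**Neoantigens.** Each neoantigen carries a feature vector (MHC binding
affinity, binding stability, agretopicity, transcript abundance,
foreignness). Affinity/stability/agretopicity are coupled by a Gaussian
copula on log scale with correlations (−0.3495, −0.930, 0.2041); transcript
abundance is exponential with rate 6.6625 (rate parameterization — the
source does not state rate vs mean; rate is configurable); foreignness is a
zero- and one-inflated beta: exactly 0 with probability 0.7603, emitted as
1.0 with probability 0.0685, otherwise Beta(0.0597, 1.4404). A neoantigen
passing all four filter thresholds (affinity < 34 nM, stability > 1.4 h,
agretopicity > 0.1, foreignness < 1e−16; all strict) receives an intrinsic
immunogenicity `R` from an exponential density `∝ exp(−6x)` truncated to
[0,1] (exact inverse-CDF sampling); otherwise `R = 0`. Transcript abundance
is sampled but not assessed (it is conflated with clonality, which the
simulator resolves mechanistically). The printed foreignness direction
(pass-if-below) is implemented as printed and exposed as a flag, since the
criterion's upstream source treats *high* foreignness as immunogenic.

**Immune system.** One CTL clone per registered neoantigen, founded at
`2^n` cells with `n ~ Poisson(4)` (divisions before thymic efflux). Clones
expand on `ICB · S_k · T_a · C` where `S_k` is the immunogenicity-weighted
presented-cell count, and all CTLs contract or expand homeostatically at
`T_d (C − 1)`. The shared stimulus `C` is replenished at `k_in`, consumed
by non-CTLs (`f_out` fraction) and by CTLs in proportion to total CTL
numbers relative to `ICB · CTL_ss`. Killing of lineage `i` saturates in the
reactive fraction φ via `k_d,i = f_die + (k_mag + 1 − f_die)(φ k_kill)/(1 +
(φ k_kill)²)`. Under the defaults, `k_d = 1` at φ ≈ 0.751: tumor-reactive
CTLs must outnumber tumor-ignorant CTLs about 3:1 before any lineage
shrinks, and `k_d,max ≈ 1.099`.

### Equation parses fixed here

The source renderings of the clone-dynamics and killing equations are
typographically ambiguous. This package fixes: (i) clone antigen drive is
per-capita `S_k T_a C / CTL_k` times `CTL_k` (so the total drive is
`S_k T_a C`, independent of clone size — antigen is divided among the
clone's cells); alternatives are not implemented because they are either
dimensionally absurd or dynamically inert. (ii) The killing form above is
the only candidate that simultaneously lets `k_d` exceed 1 with `k_mag = 1`,
keeps `k_d ≤ 1` with `k_mag = 0`, and reproduces the ~3:1 outnumbering
requirement; Hill variants `x/(1+x)` and `x²/(1+x²)` are selectable via
`killing_form` for sensitivity checks. (iii) `S_k` follows its verbal
definition (an immunogenicity-weighted *cell count*), not the flag-only
product in the displayed formula. (iv) ICB multiplies both the antigen
sensitivity and the `CTL_ss` denominator with the same scalar.

## Parameters

Defaults (human / mouse), per day unless noted:

| symbol | meaning | human | mouse |
|---|---|---|---|
| kg | crude birth rate | 0.02 | 0.2 (MC38 presets: 0.3) |
| fdie | non-immune death fraction | 0.3 | 0.3 |
| cellVol | cell volume (cm³) | 4.19e-9 | 4.19e-9 |
| K | carrying capacity (cells) | 5e11 | 7e8 |
| nG | neoantigen gain rate (/cell/day) | 2.5e-9 | 0 |
| nGS, nGSt | gain-rate log-sd (tumor, daily) | 2.303 | 0 |
| nL, hlaL | loss / MHC-loss rate (/cell/day) | 1.68e-9 | 0 |
| hlaL0 | founder clonal MHC-loss prob. | 0.14 | 0 |
| g1, g2 | founder burden gamma shape, scale | 1.14, 56.24 | — |
| kin | stimulus turnover | 0.01 | 0.4 |
| fout | non-CTL stimulus consumption | 0.3 | 0.3 |
| CTL_ss, TCR_other | steady-state / ignorant T cells | 1e11 | 1e8 |
| T_d | T-cell turnover | 0.05 | 0.0333 |
| mu | Poisson divisions before efflux | 4 | 4 |
| T_a | antigen-stimulus scaling | 3e-2 | 3e-3 |
| k_kill, k_mag | killing shape, magnitude | 0.7, 1 | 0.7, 1 |

The printed gain rate ("2.5e9/day") is stored as 2.5e-9 per cell per day:
the printed exponent sign is inconsistent with the companion loss rate
1.68e-9 derived from the ~33% expressed fraction. The nonspecific pool is
initialized from `TCR_other` (the parameter table's value) rather than the
equation annotation that disagrees with it; both are configurable.

Presets: `rcc_like` halves `kg` and multiplies `nG`, `nL`, `hlaL` by 0.1;
`msi_like` doubles `kg` and triples `g2` (founder burden is the only
mechanism for "200% higher clonal burden"); MC38 presets raise mouse `kg`
by 50%. Mouse presets disable stochastic events (immunopeptidomes held
constant over the five-week horizon).

### Choices the source leaves open

**Gain-rate log-normal convention.** Both the per-tumor base rate and the
day-to-day jitter are *mean*-preserving by default (median-preserving is a
config option). With log-sd 2.303 at both levels, a median-preserving
convention would make the realized average gain rate ~200× the nominal nG
and produce tens of thousands of neoantigens per 5 cm tumor, while the
published virtual cohorts treat >600 neoantigens as a 1-in-100 outlier;
mean preservation reproduces that scale and keeps nG interpretable as the
average gain rate.

**Copula marginals.** The marginal distributions of affinity, stability and
agretopicity were originally fitted to a 146-peptide candidate panel and are
not published. Candidate neoantigen pipelines prefilter for strong predicted
binders, so the defaults are log-normals centered on binder-like scales:
affinity median 100 nM (log-sd 1.5), stability median 0.75 h (log-sd 1.0),
agretopicity median 1.0 (log-sd 1.5). Jointly with the copula and the
foreignness mixture these give a ~7.7% filter pass rate, i.e. ~5 putatively
immunogenic neoantigens for a median founder burden of 64 — of which the
large majority have small R (truncated-exp mean 0.16), consistent with the
observation that generally fewer than four candidates per patient validate
as immunogenic ex vivo. All refitting-based acceptance quantities depend
only on the printed copula/inflation/gamma/exponential parameters, not on
these marginals.

**Response basis.** Maximal tumor shrinkage is measured on the cell count
(equivalently volume), not the diameter, and a responder is a tumor whose
count drops ≥30% below its treatment-start baseline. Rationale: with
`k_d,max ≈ 1.099` and `k_g = 0.02`, the fastest attainable kill rate is
`k_g(k_d,max − 1) ≈ 0.002/day`, so a 30% *diameter* reduction (65% of
cells) would need >500 days of fully saturated killing and is unattainable
within a one-year treatment; the volume basis discriminates as the
published response rates require. The strict diameter basis remains
available (`max_shrinkage(..., on="diameter_cm")`).

**Clonality counting.** `clonal_subclonal_burden` implements both the
literal lineage-membership rule (clonal = presented by every living
lineage) and a cell-fraction rule (clonal = presented by ≥95% of living
cells). Cohort biomarkers use the cell-fraction rule: under lineage
branching every event spawns a 1-cell child, so the literal rule degrades
to zero clonal neoantigens in any grown tumor, which contradicts how clonal
calls are made in the sequencing cohorts the model is calibrated to
(cancer-cell-fraction thresholds).

**TCR entropy.** Shannon entropy `−Σ p ln p` on clone frequencies. The
original analysis used a wavelet-toolbox "entropy" routine whose convention
(`−Σ x² ln x²`, unnormalized and scale-dependent) is almost certainly not
intended for abundance vectors; it is provided as `mode="wentropy"` for
auditability.

**Rank-1 tie-break.** Most immunogenic neoantigen; ties resolve to higher
clonality, then lower id. Biomarker thresholds for sensitivity/specificity
maximize Youden's J over observed values (the original rule is unstated).
Immunoediting fold change (presented cells of the pre-treatment rank-1
neoantigen, last/first treatment day) reports 0/0 as missing, not 1.

## Numerics

Within each day the coupled system (lineages, clones, ignorant pool, shared
stimulus) is integrated with adaptive RK45 (rtol 1e-6; atol 1e-3 cells,
1e-9 for C), falling back to LSODA and then to recursive half-day splitting
on failure; populations are floored at 0 and `C` clamped at 0 after each
day. Stochastic events use tau-leaping at dt = 1 day: per lineage, Poisson
counts with mean rate·N·dt for gain (that day's jittered rate), loss (over
expressed neoantigens) and MHC loss (over intact alleles), applied in the
fixed order losses → MHC losses → gains with uniform target choice; each
event moves exactly one cell into the child lineage. Lineages below 0.5
cells are pruned from the dynamics (threshold configurable) but retained in
the event log. Gains register a new neoantigen and immediately found its
cognate CTL clone.

Two exact reductions keep large cohorts tractable without changing the
model: (i) children created from the same parent by the same modification
carry identical immunopeptidomes and are aggregated into one lineage;
(ii) clones whose cognate neoantigen has `R = 0` (never any antigen
stimulus) share the homeostatic dynamics exactly and are integrated as one
aggregate state — their contribution to the reactive fraction (bounded by
~1e-5 of the ignorant pool) is the one approximation, far below integrator
tolerance in all tested regimes.

Reproducibility: a run is fully determined by (preset, seed); cohorts give
each tumor an independent, order-independent substream via seed-sequence
spawning, and immune-controlled tumors are redrawn (logged) only when a
treatment schedule conditions the cohort on reaching treatment size.

## Synthetic data

`generate_fixture("bbn963")` emulates a 34-neoantigen murine panel on two
MHC alleles with ELISpot-like scores: three strongly positive entries
(uniform 50–200 spots) over a mostly-zero background with ~30% weak
positives (exponential, scale 5) — so that after min–max scaling to [0,1] a
handful of neoantigens carry high immunogenicity, as in ex vivo screens.
`generate_fixture("mc38")` resamples 489 R values from that scaled
empirical distribution. The generator reproduces panel *sizes and the
skewed immunogenicity shape* only; it does not emulate assay noise,
peptide identities, or allele-specific binding structure, so green tests
establish pipeline correctness on realistic shapes, not biological fidelity
of any particular panel.

## Known limitations

- One lumped, spatially unstructured tumor; no metastasis-specific
  immunopeptidomes, no intratumoral vs peripheral T-cell compartments, no
  exhaustion state, no TCR cross-reactivity.
- Neoantigen re-expression and MHC recovery are impossible by construction.
- At `N = K` the logistic factor freezes the tumor regardless of killing;
  irrelevant at simulated sizes (`N ≤ 0.03K` at treatment start) but a
  formal fixed point nonetheless.
- The one-year ICB response race is sensitive to the unpublished feature
  marginals (via the count and strength of clonal immunogenic neoantigens);
  distribution-level quantities are not.
- Treatment is a constant multiplier — no pharmacokinetics, scheduling, or
  resistance mechanisms beyond the modeled immunoediting.
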