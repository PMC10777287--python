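# Methods

## The estimation problem

Umbrella sampling holds a system near successive values ξᵢ of a reaction
coordinate with a harmonic restraint, so that the whole coordinate range —
here the separation distance between two oligonucleotide strands — is
sampled even across free-energy barriers of tens of kcal/mol. The analysis
problem is to undo the known biases and recover the unbiased potential of
mean force PMF(ξ) = −RT ln p(ξ), from which the duplex-formation
thermodynamics follow.

`whamtherm` implements the weighted histogram analysis method (WHAM). With
per-window bin counts nᵢ(b), in-grid totals Nᵢ, and bias energies wᵢ(ξ_b)
evaluated at bin centers, the coupled equations

    p(b) = Σᵢ nᵢ(b) / Σᵢ Nᵢ exp[(fᵢ − wᵢ(ξ_b))/RT]
    fᵢ   = −RT ln Σ_b p(b) exp[−wᵢ(ξ_b)/RT]

are iterated plainly until the largest per-iteration change in any window
shift fᵢ falls below a tolerance (default 10⁻⁶ kcal/mol). The fixed point
is the maximizer of the multinomial likelihood of the observed histograms;
the test suite exploits this by cross-checking the iteration against an
independent convex-minimization solution of the same likelihood.

Assumptions inherited from the method: samples within a window are treated
as independent draws from the window's stationary biased distribution
(optional stride subsampling and a burn-in fraction are provided, both off
by default); the coordinate is one-dimensional and aperiodic; the bias is
harmonic and known exactly.

## Units and conventions

Energies kcal/mol, distances Å, temperatures K throughout;
R = 1.987204×10⁻³ kcal/(mol·K). Reports use the conventional units of
duplex thermodynamics tables: ΔS° in cal/(mol·K) and Tm in °C.

The bias convention is **wᵢ(ξ) = ½K(ξ−ξᵢ)²** by default, the convention of
the widely used WHAM command-line program whose metadata dialect the io
module mirrors (one window per line: `path center spring_const
[temperature]`). A `half_factor=False` switch selects the AMBER restraint
convention K(ξ−ξᵢ)² for data restrained directly by AMBER's `rk2` values.
The ½ convention is also required for the standard window layout to make
physical sense as a design: with K = 10 kcal/(mol·Å²), a window's
histogram on a locally flat stretch of the PMF has width
σ = √(RT/K) ≈ 0.25 Å, which at the standard 0.5 Å spacing gives adjacent
histogram overlaps of ≈ 0.28–0.31 — comfortably above the 20 % floor that
WHAM needs to connect windows. Under the no-½ convention the same layout
would peak at ≈ 0.15 overlap and could never meet the criterion.

## Protocol defaults

| parameter | default | meaning |
|---|---|---|
| window centers | 0–45 Å, step 0.5 Å (91 windows) | strand-separation range sufficient for short duplexes; longer duplexes need 60 Å |
| K | 10 kcal/(mol·Å²) | harmonic bias constant |
| temperatures | 273–333 K, step 10 K | bounded below by water freezing, above by short-duplex denaturation |
| M (bins) | 150 | within the ≥100-bin plateau of the extracted ΔG |
| tolerance | 10⁻⁶ kcal/mol on max\|Δfᵢ\| | convergence of the self-consistent iteration |
| max_iter | 10⁵ | plain iteration, no acceleration (determinism over speed) |
| burn-in | 0 | no equilibration discard; configurable fraction |
| Ct | 10 μM | total strand concentration for Tm |
| molecularity m | 4 | non-self-complementary duplex (two distinct strands); m = 1 if self-complementary |
| grid | [0, ξ_max_center + 3σ_bias] | covers essentially all samples of the outermost window |

## From PMF to thermodynamics

ΔG°(T) is the PMF value at its global finite minimum (the duplex well,
near 6 Å) minus the value at the global finite maximum restricted to
ξ > ξ_min (the dissociation barrier). The restriction matters: the profile
also rises steeply at near-contact distances, and that repulsive wall must
never be mistaken for the barrier. A profile still rising at the end of
the grid raises an error advising a longer coordinate range.

ΔH° and ΔS° come from ordinary least squares of ΔG° on T
(ΔG°(T) = ΔH° − T·ΔS°); R² is the squared Pearson correlation. ΔG°37 is
the fitted line at 310.15 K — deliberately not a single-temperature PMF
value, since 310.15 K is not on the simulated grid. Tm uses the two-state
bimolecular form Tm(K) = 1000·ΔH°/(ΔS° + R·ln(Ct/m)); the molecularity
divisor is configurable because published statements of the formula vary
in whether Ct, Ct/2 or Ct/4 appears.

Linear calibration fits experimental = a·computed + b independently for
ΔH° and ΔS° (≥3 matched duplexes), then re-derives ΔG°37 and Tm from the
corrected parameters; correcting ΔG°37 or Tm directly would break the
thermodynamic identity ΔG°37 = ΔH° − 310.15·ΔS°/1000, which the
`ThermoParams` container enforces to 10⁻⁹ kcal/mol.

A caution on Tm sensitivities: at fixed ΔG°37 the melting temperature is
*not* monotonically increasing in |ΔH°| in general; dTm/dΔH° carries the
sign of (−ΔG°37/T₃₇ + R·ln(Ct/m)/1000), so at 10 μM strongly bound
duplexes (ΔG°37 below ≈ −8 kcal/mol) have Tm pulled *down* toward 37 °C
as |ΔH°| grows.

## The synthetic-data generator

The generator exists so every pipeline stage can be validated by parameter
recovery. The model PMF is a sum of compactly supported closed-form
pieces — cubic repulsive wall on [0, 3 Å], sextic-bump well centered at
6 Å with 3 Å half-width, smoothstep rise to a 2 kcal/mol barrier crest at
30 Å, linear decline of −0.02 kcal/mol/Å beyond — whose supports do not
overlap, so the well-to-barrier difference equals the configured
ΔG_true(T) = ΔH_true − T·ΔS_true/1000 *identically*, with all shape
parameters except the well depth held fixed across temperature. The
default truth (ΔH_true = −60 kcal/mol, ΔS_true = −160 cal/(mol·K),
ΔH/ΔS ≈ 375 K) is in the physically typical range for an 8-mer DNA duplex;
it is synthetic and corresponds to no measured sequence.

Window sampling is direct inverse-CDF transform from the tabulated biased
density p(ξ) ∝ exp(−[G(ξ)+w(ξ)]/RT) (10⁴-point grid per window, linear
interpolation) rather than integrated dynamics: exact marginal sampling
makes recovery tests sharp, because any residual error is attributable to
the estimator, not the data. An AR(1) mode pushes a correlated Gaussian
chain through the Gaussian copula onto the same marginal, to exercise
uncertainty estimation under serial correlation.

What the generator does **not** emulate — and therefore what passing tests
do not show about real MD data: serial correlation within windows (beyond
the optional AR(1) toy), slow orthogonal degrees of freedom that make a
window's sampled distribution depend on its starting structure, force-field
error, and any mismatch between the nominal and effective bias. Recovery
accuracy on synthetic data is an upper bound on what the same settings
achieve on trajectories.

## Numerical choices

- **Reference/gauge.** The PMF is shifted so the outer 5 % of (finite) bins
  — the dissociated plateau — average zero. Purely cosmetic: ΔG extraction
  is invariant under any additive shift, and the tests assert it.
- **Empty bins** carry probability 0 and PMF +∞; they are excluded from
  min/max searches.
- **Ties** in the min/max search resolve to the smallest coordinate
  (`argmin`/`argmax` first-hit), which only matters on flat stretches.
- **Overflow/underflow.** The iteration runs on exp(−w/RT) matrices;
  far-from-center weights underflow harmlessly to zero. A populated bin
  whose weight underflows in *every* window is reported as unreachable.
- **Bootstrap** resamples each window's in-grid samples with replacement
  (same size), re-solves warm-started from the central shifts, aligns
  replicates by the common plateau-zero rule, and reports per-bin standard
  deviations; replicates that fail are dropped, with >10 % failures an
  error.
- **Known edge artifact.** Because the bias is evaluated at bin centers,
  the outermost bin — beyond the last window center, sampled only by one
  window's steep one-sided tail — acquires a systematic offset of
  ~0.1–0.2 kcal/mol. It is far from both the well and the barrier crest
  and does not touch ΔG; the flat-surface null in the test suite bounds
  the whole profile, edge included, at 0.2 kcal/mol.

## Problem sizes used in validation

The test suite and `scripts/acceptance.py` run the full default layout
(91 windows × 10⁴ samples × 7 temperatures) for recovery checks; the
solver cross-check uses 31 windows × 5×10³ samples; the bootstrap
calibration compares bootstrap SEs on one dataset (40 replicates) against
the empirical SE over 20 regenerated datasets at 31 windows × 3×10³
samples, a scale at which both estimates are stable enough to demand
agreement within a factor of two.

## Known limitations

- No heat-capacity (ΔCp) modeling: a temperature-independent ΔH°/ΔS° is
  assumed over 273–333 K, as the van't Hoff fit requires.
- No MBAR, no two-dimensional or periodic coordinates.
- Statistical inefficiency is not estimated; correlated inputs will make
  bootstrap errors optimistic unless subsampled.
- The melting model is strictly two-state and bimolecular; hairpins and
  intermediates are out of scope.
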