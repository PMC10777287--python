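# whamtherm

Hybridization thermodynamics of oligonucleotide duplexes from
umbrella-sampling simulations.

`whamtherm` is for computational chemists and nucleic-acid researchers who
run umbrella-sampling molecular dynamics along a strand-separation
coordinate (typically the distance *r* between the centers of mass of the
two strands' C4′ atoms) and want duplex-formation thermodynamics out of the
raw biased time series. It implements the complete analysis chain:

1. **WHAM** — the weighted histogram analysis method combines the biased
   per-window histograms into one unbiased distribution by solving the
   self-consistent equations

   ```
   p(b) = Σᵢ nᵢ(b) / Σᵢ Nᵢ exp[(fᵢ − wᵢ(ξ_b))/RT]
   fᵢ   = −RT ln Σ_b p(b) exp[−wᵢ(ξ_b)/RT]
   ```

   with harmonic biases wᵢ(ξ) = ½K(ξ−ξᵢ)², giving the potential of mean
   force PMF(ξ) = −RT ln p(ξ). Per-bin uncertainties come from a
   Monte-Carlo bootstrap over each window's samples.
2. **ΔG° extraction** — the hybridization free energy at each temperature is
   ΔG°(T) = PMF(ξ_min) − PMF(ξ_max), the depth of the duplex well below the
   dissociation barrier.
3. **van't Hoff decomposition** — an ordinary least-squares fit of
   ΔG°(T) = ΔH° − T·ΔS° over the simulated temperature grid yields ΔH°
   (intercept) and ΔS° (−slope), plus ΔG°37 at 310.15 K.
4. **Melting temperature** — the two-state bimolecular model
   `Tm(K) = 1000·ΔH° / (ΔS° + R·ln(Ct/m))` at total strand concentration
   Ct (default 10 μM; m = 4 for non-self-complementary duplexes).
5. **Linear calibration** — computed ΔH°/ΔS° can be regressed against
   experimental values and corrected; ΔG°37 and Tm are re-derived from the
   corrected parameters.

Because deposited umbrella-sampling datasets for this protocol do not
exist, the package ships a first-class synthetic-data generator: an
analytic model PMF with the canonical strand-separation shape (repulsive
wall, single well near 6 Å, barrier, gently declining plateau) whose
well-to-barrier depth equals ΔH_true − T·ΔS_true/1000 exactly, sampled by
exact inverse-CDF draws from each window's biased density. Every stage of
the pipeline is therefore testable by parameter recovery against known
ground truth.

The estimators follow scikit-learn conventions (`fit`, fitted attributes
with trailing underscores, `get_params`/`set_params`): `WHAM`,
`VantHoffModel`, and `LinearCorrection` compose with sklearn tooling, and
thin module-level functions (`solve_wham`, `fit_gibbs_temperature`,
`calibrate_linear_correction`, …) wrap them.

## Worked example

Simulate a synthetic 8-mer-like duplex (ΔH_true = −60 kcal/mol,
ΔS_true = −160 cal/(mol·K)) at the default protocol — 91 umbrella windows
every 0.5 Å from 0 to 45 Å, K = 10 kcal/(mol·Å²), seven temperatures from
273 to 333 K, 10⁴ samples per window — and recover its thermodynamics:

```python
import numpy as np
import whamtherm as wt

truth = wt.GroundTruth()                      # ΔH −60, ΔS −160
plan = wt.SimulationPlan(n_per_window=10_000, seed=1)

temps, dgs = [], []
for T in plan.temperatures:
    windows = wt.simulate_windows(plan, truth, T)
    est = wt.WHAM(n_bins=150, tol=1e-6).fit(windows)
    dg, xi_min, xi_max = wt.extract_delta_g(est.profile_)
    temps.append(T); dgs.append(dg)
    print(f"T={T:.0f} K  dG={dg:7.3f} kcal/mol  well at {xi_min:.2f} A")

series = wt.ThermoSeries("demo", np.array(temps), np.array(dgs))
p = wt.fit_gibbs_temperature(series)          # Ct = 10 uM by default
print(f"dH={p.dh:.2f} kcal/mol  dS={p.ds:.1f} cal/(mol K)  "
      f"dG37={p.dg37:.2f} kcal/mol  Tm={p.tm:.1f} C  R2={p.r2:.4f}")
```

Output:

```
T=273 K  dG=-16.335 kcal/mol  well at 5.94 A
T=283 K  dG=-14.795 kcal/mol  well at 5.94 A
T=293 K  dG=-13.095 kcal/mol  well at 5.94 A
T=303 K  dG=-11.448 kcal/mol  well at 5.95 A
T=313 K  dG= -9.959 kcal/mol  well at 5.95 A
T=323 K  dG= -8.357 kcal/mol  well at 5.95 A
T=333 K  dG= -6.832 kcal/mol  well at 5.95 A
dH=-59.72 kcal/mol  dS=-159.0 cal/(mol K)  dG37=-10.41 kcal/mol  Tm=50.3 C  R2=0.9997
```

The per-temperature ΔG values track the true line −60 + 0.160·T within
~0.1 kcal/mol; the fitted enthalpy and entropy land within 1 % of the
ground truth, and the melting temperature of 50.3 °C is what a duplex with
these parameters melts at when 10 μM of strands are present.

The same run is available from the shell:

```sh
whamtherm simulate --dh -60 --ds -160 --n 10000 --seed 1 --out data/
whamtherm wham --meta data/meta_313K.txt --bins 150 --boot 100 --seed 1 --out pmf_313K.tsv
whamtherm pipeline --config run.yaml
```

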