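# organoidgrowth

Growth-law analysis for patient-derived tumor organoid (PDTO) tracking
data. Given per-organoid time series of 2-D projected areas exported by a
live-cell imaging/tracking step, the package:

1. **converts** areas to live-cell estimates — assuming an ellipsoidal
   organoid, V = (4/(3√π))·A^{3/2}, then n = V/ρ with calibration
   ρ = 7208 μm³/cell (re-estimable from paired volume/count data);
2. **filters** tracked objects (dead objects, debris below 300 μm²,
   non-growing tracks, optional segmentation-artifact heuristic), with
   exact per-stage accounting;
3. **fits** nine classical growth laws per organoid — exponential, power
   law (γ = 1/2, 2/3, 3/4), Gompertz, logistic, von Bertalanffy
   (γ = 1/2, 2/3, 3/4) — by multi-start bounded least squares, each
   organoid growing from a single cell at Day −τ with a free dormancy
   time τ ∈ [0, τ_max]:

       minimize  φ²(θ, τ) = Σᵢ (nᵢ − N(τ + tᵢ; θ))²

4. **ranks** the laws by BIC,
   BIC = k(1 + log 2π) + k log(φ²/k) + (p+1) log k, and by the normalized
   fitting error φ² / mean(nᵢ);
5. **summarizes heterogeneity** of the Gompertz parameters: lognormality
   of the initial rate a (KS test), the fraction of "exponential
   organoids" (decay rate b at its 10⁻⁴ floor), the a–b correlation,
   carrying-capacity categories (K = e^{a/b}), dormancy-time histograms,
   Day-0/Day-5 rates a·e^{−bτ} and a·e^{−b(τ+5)}, kernel-smoothed size
   CDFs, and well-position regressions;
6. **projects** cohort growth to Day 20 by resampling fitted (a, b, τ)
   triplets (100,000 samples) with median and 5th/95th-percentile bands,
   and converts in-vitro durations to patient-equivalent years via a
   doubling-time ratio.

A bundled synthetic-cohort generator reproduces the statistical structure
of such datasets (lognormal rates, correlated decay, exponential
subpopulation, dormancy-time shapes, measurement noise, contamination
objects), so the full pipeline is testable without experimental data.
See `docs/methods.md` for the model details and design choices.

## Worked example

Simulate a 150-organoid cohort on the 4-timepoint grid (Days 0, 1, 3, 6;
τ ≤ 7) with 2% multiplicative noise and some contamination, then run the
whole chain:

```python
from organoidgrowth import CohortConfig, invitro_to_patient_time
from organoidgrowth.io import run_pipeline

cfg = CohortConfig(n_organoids=150, day_grid=(0.0, 1.0, 3.0, 6.0),
                   tau_max=7.0, noise_level=0.02,
                   rate_dead=0.1, rate_debris=0.05, seed=42)
art = run_pipeline(config=cfg, n_starts=50, seed=42,
                   projection_samples=20000)
print(art["filter_report"].as_dict())
print(art["ranking"].table.round(4))
```

which prints

```
filter report: {'input': 173, 'removed_dead': 15, 'removed_small': 8,
                'removed_nonmonotone': 2, 'removed_artifact': 0, 'retained': 148}

                     mean_bic  mean_norm_error  rel_error_to_gompertz
model
exponential           18.4056           7.7034              3213.3309
gompertz              -9.2369           0.0024                 1.0000
logistic              -0.6046           0.0196                 8.1789
power_law 1/2         21.2124         121.0833             50507.6815
power_law 2/3         17.8978           4.7709              1990.1056
power_law 3/4         18.0664           3.0461              1270.6203
von_bertalanffy 1/2   14.7352         120.3228             50190.4448
von_bertalanffy 2/3    7.0359           3.1184              1300.7854
von_bertalanffy 3/4    3.0897           0.8133               339.2605
best model: gompertz
```

The filter report accounts for every removed object (15 dead objects, 8
sub-300 μm² objects, 2 non-growing tracks; removals sum with the 148
retained organoids to the 173 tracked objects). The ranking table is the
Gompertz-truth analog of a dataset-level model comparison: the
sigmoidal laws out-rank the unconstrained ones, and the generating
Gompertz model attains both the lowest mean BIC (−9.24) and the smallest
mean normalized error (0.0024; other models shown relative to it). The
heterogeneity report and projection for the same run give

```
exponential fraction: 0.081   corr(a,b) log10: 0.59   KS p: 0.913
Day-20 median 208 cells (5th-95th percentile: 14 - 1104920)
20 in-vitro days ~ 4.4 patient-equivalent years
```

— the fitted log10(a) sample is consistent with a normal distribution
(KS p = 0.91), 8% of organoids grew indistinguishably from pure
exponentials, and the Day-20 Monte-Carlo projection spans nearly five
orders of magnitude, reflecting genuine growth heterogeneity rather than
measurement noise. The final line applies the doubling-time scaling
(211-day clinical vs 2.6-day in-vitro): 20 days of organoid growth
correspond to about 4.4 years of patient-scale tumor growth.

The same pipeline is scriptable from a shell:

```sh
organoidgrowth simulate --preset uk-like --n 300 --seed 1 --out tracks.csv
organoidgrowth filter --input tracks.csv --out filtered.csv
organoidgrowth convert --input filtered.csv --out cells.csv
organoidgrowth fit --input cells.csv --n-starts 1000 --seed 1 --out fits.csv
organoidgrowth rank --input cells.csv --fits fits.csv --out ranking.csv
organoidgrowth project --fits fits.csv --n 100000 --seed 1 --out projection.csv
```

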