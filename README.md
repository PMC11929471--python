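# cotspred

Cryptic predation pressure on juvenile crown-of-thorns sea stars (CoTS,
*Acanthaster* spp.), estimated by linking three lines of evidence:

1. **Transect surveys** of rubble-dwelling decapod predators (*Schizophrys
   aspera* and portunid, xanthid and epialtid crabs) across reef regions with
   contrasting CoTS outbreak histories, analysed with zero-inflated count
   models (region fixed effect, site random intercept, log-area offset) and
   Tukey-adjusted pairwise contrasts.
2. **A Bayesian linear path model (SEM)** over standardized survey variables
   — spatial drivers → benthic cover → rubble microhabitat → predators →
   adult CoTS — fitted by Gibbs sampling with N(0, 1) priors, correlated
   residual blocks for compositional cover, rank-normalized split R-hat
   diagnostics, and posterior-predictive checking.
3. **ddPCR gut-content eDNA screening** of wild-caught predators: a specimen
   is positive when any replicate has ≥ 1 positive droplet; copy numbers
   follow Poisson occupancy, λ = −ln(1 − k/N) copies per droplet; detection
   probability decays logistically with hours post-ingestion.

The stages combine into two regional predation estimators (individuals per
100 m² per day):

- **Potential predation** = Σ_taxa density × per-capita consumption rate
  (5.8 ind d⁻¹ for *S. aspera*, 0.4 ind d⁻¹ for the crab families).
- **Realized predation** `RP = D × pDNA / d`, where `D` is predator density,
  `pDNA` the proportion of screened specimens carrying CoTS DNA (with exact
  Clopper–Pearson uncertainty), and `d` the assumed digestion window in days
  (1 or 2, matching the 24–48 h DNA detectability window).

Every stage runs on synthetic tables from a seeded generator that emulates
the study's sampling design (survey hierarchy and transect areas, the
1/3/9/12/48 h feeding-trial design, and the 2/12 southern vs 7/63 northern
screening outcomes), so the full pipeline is testable without any downloads.

## Worked example

```python
from cotspred import simulate, edna, predation

screen = simulate.generate_specimen_screen(seed=1, exact_counts=True)
south = edna.positivity_rate(screen, "south")
print(f"south pDNA: {south.k}/{south.n} = {100*south.proportion:.1f}% "
      f"(95% CI {100*south.ci95[0]:.1f}-{100*south.ci95[1]:.1f}%)")

est = predation.realized_predation(D=3.6, k=south.k, n=south.n, d_days=1.0)
print(f"realized predation: {est.rp:.2f} ind / 100 m^2 / day "
      f"(95% CI {est.ci95[0]:.2f}-{est.ci95[1]:.2f})")

trials = simulate.generate_feeding_trials(seed=1, exact=True)
decay = edna.fit_detection_decay(trials)
print(f"detection at 12 h: {decay.predict(12.0):.2f}; at 48 h: {decay.predict(48.0):.2f}")
```

prints

```
south pDNA: 2/12 = 16.7% (95% CI 2.1-48.4%)
realized predation: 0.60 ind / 100 m^2 / day (95% CI 0.08-1.74)
detection at 12 h: 0.94; at 48 h: 0.38
```

Two of twelve screened southern specimens carried CoTS DNA; at a community
density of 3.6 predators per 100 m² and a one-day digestion window that
implies 0.6 juveniles consumed per 100 m² per day, with the wide exact
interval reflecting the small screening sample.  The fitted decay curve
keeps detection above 90% through 12 h and drops it to roughly a third by
48 h.

A full run (simulation → counts → SEM → eDNA → predation → report):

```sh
cotspred all --seed 1 --outdir out --reduced
```

writes per-stage tables (`transects.csv`, `sem_summary.tsv`,
`edna_report.tsv`, `potential_predation.tsv`, ...) plus a machine-readable
`summary.json` and a `provenance.json` recording the seed.  Individual
stages are available as `cotspred simulate|counts|sem|edna|predation|report`.

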