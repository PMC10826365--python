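# heatlimits

Analysis pipeline for **critical environmental limits** from progressive
heat-stress ramp trials: given per-trial time series of core
(gastrointestinal) temperature, chamber dry-bulb temperature and ambient
water vapor pressure, it detects the core-temperature inflection point,
derives the per-trial critical temperature/humidity limit, builds
survival-style *compensability curves* with a Gehan-Breslow-Wilcoxon
group test, and fits quadratic psychrometric limit curves (mean and
lower-95%-CI) per study group.  A protocol-faithful synthetic-data
generator makes the whole pipeline testable with known ground truth.

## Modules

| module | what it does |
| --- | --- |
| `heatlimits.psychro` | saturation vapor pressure (Antoine/Buck), relative humidity, chart helpers — all limits live in (T_db °C, P_a mmHg) coordinates |
| `heatlimits.calorimetry` | DuBois body surface area, net metabolic heat production from V̇O2/RER, METs, sweat rate and % body-mass loss |
| `heatlimits.inflection` | exhaustive least-squares hinge (two-segment) breakpoint detection on T_gi, critical env value (2-min pre-inflection mean), below/above slopes |
| `heatlimits.trials` | ramp schedules (30-min equilibration, +1 unit / 5 min), per-trial orchestration, heat-balance estimation of censored 34 °C humid-limb trials |
| `heatlimits.compensability` | product-limit compensability curves over a stress axis, Gehan-Breslow-Wilcoxon test (from first principles) and an exact/Monte-Carlo permutation oracle |
| `heatlimits.limits` | condition-level loci with t-based 95% CIs, quadratic psychrometric limit fits, within-condition permutation group comparison |
| `heatlimits.synthdata` | seeded synthetic traces (AR(1) capsule noise, plateau + hinge rise) and full study cohorts with truth tables |
| `heatlimits.reference` | published condition-level summaries used as generator defaults |
| `heatlimits.io_cli` | trace/manifest CSV formats, validated run config, `heatlimits` CLI |

## CLI

```bash
# write a seeded synthetic study (traces + manifest + truth table)
heatlimits simulate --outdir study/ --seed 7 --n-per-cell 8

# per-trial critical limits
heatlimits analyze --indir study/ --outdir out/

# compensability curves + group tests, and limit curves + chart
heatlimits curves --results out/results.csv --outdir out/
heatlimits limits --results out/results.csv --outdir out/

# everything in one go, with a JSON summary
heatlimits report --outdir report/ --seed 7
```

All outputs are CSV/JSON with fixed float formatting and provenance
columns (config hash, seed, package version); identical config + seed
give byte-identical results.  Exit codes: 0 success, 2 config error,
3 data error.

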