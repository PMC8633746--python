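# respirotraits

Pipeline from raw intermittent-flow respirometry oxygen traces to individual
metabolic traits and mixed-model treatment inference, with a synthetic-data
generator for validation by parameter recovery.

Stages:

1. **simulate** — generate raw per-chamber dissolved-oxygen traces for a
   multi-batch experiment (7-min flush/measure cycles, ~45 h trials, blank
   background blocks at both ends, circadian / shelter / trial-day modulation
   of a latent uptake rate, activity bursts, a chase-elicited maximum-rate
   event, and 3-week growth under two group sizes), with known ground truth.
2. **mo2** — segment measurement cycles (first 30 s excluded), fit OLS
   oxygen-decline slopes, subtract linearly interpolated blank-chamber
   background, scale by effective chamber volume (chamber minus fish volume
   at 1 kg/L) and body mass, and apply the R² > 0.95 quality filter.
3. **traits** — windowed minimum metabolic rates (0.2 quantile of cycle
   estimates per day/night window), SMR (lowest valid windowed minimum), MMR
   (steepest 3-min rolling regression in the post-chase cycle), aerobic scope,
   allometric mass adjustment to a 1.95 g reference, and specific growth rate.
4. **stats** — Gaussian LMMs with nested (fish-in-batch) or fish-only random
   intercepts, likelihood-ratio (or Wald) per-term χ² tests, backward term
   reduction respecting marginality, marginal/conditional R², and percentage
   effect sizes from back-transformed equally weighted marginal means; plus
   the OLS growth-vs-group-size regression.

## CLI

```bash
respirotraits simulate --out sim/ --seed 1              # synthetic experiment
respirotraits mo2 --raw raw.csv --schedule sim/schedule.csv \
    --meta sim/metadata.csv --out mo2/ --r2-min 0.95 --exclude-initial-s 30
respirotraits traits --mo2 mo2/mo2_estimates.csv --schedule sim/schedule.csv \
    --meta sim/metadata.csv --raw raw.csv --out traits/ --q 0.2 --mmr-window-s 180
respirotraits stats --traits traits/traits.csv \
    --mo2min-long traits/mo2min_long.csv --family night_mo2min --out stats/
respirotraits run --config run.yaml                     # whole pipeline
```

`simulate` writes one raw CSV per trial; the analysis stages take a single
raw table — concatenate the trials with a `trial` column
(`initial`/`final`), as `respirotraits run` does internally.

### File schemas

- raw traces: `time_s, clock_time, chamber_id, phase{flush|measure|blank},
  cycle_index, o2_mg_per_l, temp_c` (+ optional `trial`)
- schedule: `chamber_id, fish_id, trial, shelter_first{0|1}, fish_in_s,
  condition_change_s, chase_s, fish_out_s, lights_on, lights_off, start_clock`
  (times in seconds on the trace clock)
- metadata: `fish_id, batch, chamber_id, tank_id, group_size,
  shelter_available, mass_initial_g, mass_final_g`
- outputs: `mo2_estimates.csv`, `qc_rejections.csv`, `traits.csv`,
  `mo2min_long.csv`, `model_table.csv`, `effects.csv`, `report.json`

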