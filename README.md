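# camphen

Canopy-greenness phenology products from repeat digital camera imagery.

Fixed cameras pointed at vegetation record images every 15–30 minutes from
sunrise to sunset. The seasonal trajectory of canopy color in those images —
spring green-up, autumn senescence — carries the phenology of the ecosystem.
`camphen` implements the processing chain that turns such an image archive
into analysis-ready data products, plus a ground-truthed synthetic camera
simulator so the whole chain can be exercised and validated without any
real imagery.

## What it computes

The core index is the **green chromatic coordinate** over a user-drawn
region of interest (ROI):

```
Gcc = G_DN / (R_DN + G_DN + B_DN)
```

where `R_DN`, `G_DN`, `B_DN` are mean 8-bit digital numbers per channel
across the ROI (`Rcc`, `Bcc` analogous). The chain is:

1. **process** — per-image channel statistics, chromatic coordinates, and
   whole-image screening statistics for every exposure (the `_roistats.csv`
   product). The **deviation from grey**
   `Δ = ‖(Rcc, Gcc, Bcc) − (⅓, ⅓, ⅓)‖₂`, computed from *whole-image* means,
   detects cameras stuck on "grey world" automatic white balance (AWB):
   such cameras hold the whole-image mean color grey, so Δ stays near zero.
   Images with Δ < 0.02 for more than 30 consecutive days are flagged as
   AWB suspects. A 0–100 % haze degree (brightness/contrast composite)
   annotates foggy frames (> 40 %), without removing them.
2. **summarize** — after darkness screening and LOESS-based outlier
   flagging, per-image Gcc is aggregated to the **90th percentile** within
   1-day and 3-day windows (`_1day.csv` / `_3day.csv`), then smoothed by
   locally weighted regression with a residual-resampling bootstrap
   confidence band.
3. **transitions** — the smoothed curve is segmented into rising and
   falling seasonal cycles; for each cycle the dates at which it crosses
   10 %, 25 % and 50 % of the cycle's amplitude are extracted with
   uncertainty intervals (`_transition_dates.csv`).
4. **compare** — agreement metrics between two transition-date sets
   (R², median absolute error, RMSD, fraction differing by > 20 days).

## Worked example

Simulate a compressed synthetic season (green-up centered on day of year
50, senescence on day 110), then run the full chain:

```sh
cat > scene.yaml <<EOF
site: demo
start_date: 2018-01-01
end_date: 2018-05-30
images_per_day: 1
image_size: [32, 48]
green_up_mid: 50.0
green_down_mid: 110.0
slope_up: 4.0
slope_down: 5.0
noise_sd: 0.002
seed: 3
EOF
camphen simulate  --out sim --config scene.yaml
camphen process   --images sim/images --roi sim/demo_DB_1000_roi.csv --out out
camphen summarize --roistats out/demo_DB_1000_roistats.csv --out out \
                  --interval 1 --n-boot 50 --seed 1
camphen transitions --summary out/demo_DB_1000_1day.csv --out out
```

`out/demo_DB_1000_1day_transition_dates.csv` then contains:

```
cycle_id,direction,threshold_percent,transition_date,ci_low_date,ci_high_date,gcc_at_threshold
0,rising,10,2018-02-09,2018-02-08,2018-02-09,0.33820
0,rising,25,2018-02-14,2018-02-13,2018-02-14,0.35362
0,rising,50,2018-02-19,2018-02-19,2018-02-19,0.37934
1,falling,10,2018-05-01,2018-05-01,2018-05-02,0.33858
1,falling,25,2018-04-26,2018-04-26,2018-04-26,0.35395
1,falling,50,2018-04-20,2018-04-20,2018-04-20,0.37955
```

Each row is one threshold crossing: e.g. the smoothed greenness first
reached 50 % of the spring cycle's amplitude (Gcc ≈ 0.379) on 2018-02-19.
The simulator's analytic truth table (`sim/demo_truth.csv`) puts the true
rising 10/25/50 % crossings at days of year 41.2 / 45.6 / 50.0
(2018-02-10 / 02-15 / 02-19): the pipeline recovers every date within one
day of truth on this noisy (σ = 0.002 Gcc) scene.

## Layout

| module        | role |
| ------------- | ---- |
| `imageio`     | images, TIFF ROI masks, ROI list CSVs, data-record CSV round-trip |
| `colorstats`  | channel means, chromatic coordinates, deviation from grey |
| `quality`     | AWB-suspect runs, haze degree, darkness screen, LOESS outliers |
| `summaries`   | 1-day/3-day 90th-percentile products, smoothing + bootstrap band |
| `transitions` | cycle segmentation, threshold dates, set intercomparison |
| `synthetic`   | seeded scene generator with analytic ground truth |
| `cli`         | `camphen` command-line front end |

See `docs/methods.md` for the model, parameter defaults and limitations.
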