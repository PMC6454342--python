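# screenuse

Daily smartphone-use parameters from raw screen-event logs, and how stable
they are over time.

Passive smartphone sensing ("digital phenotyping") turns timestamped
`screen_on` / `screen_off` / `notification` events into behavioural
measurements. Before such measurements can anchor longitudinal studies of
problematic smartphone use, two reliability questions need answers: how
many weeks of recording represent a person's typical use, and how far
apart two recordings can be before they no longer measure the same
behavioural regime. `screenuse` is a pipeline for both questions, aimed at
researchers who have event-level logs (or need realistic simulated ones).

## What it computes

For each user-day, seven parameters:

| symbol | meaning |
|---|---|
| F, D | total use frequency (episodes/day) and duration (s/day) |
| PF, PD | the proactive subset: episodes with no notification in the 60 s before screen-on |
| RMSSD | √( Σ (A_{i+1} − A_i)² / (n−1) ) over the day's alternating use/nonuse durations A_i |
| SI | mean \|X_i − Y_j\| of each nonuse gap X_i vs its 3 following uses Y_i, Y_{i+1}, Y_{i+2} |
| CI | mean \|X_i − (Y_i + Y_{i+1} + Y_{i+2})\| over the same gaps |

RMSSD/SI/CI quantify use–nonuse reciprocity (low = even, rhythmic use);
sleep time is excluded from nonuse first. Over a multi-week cohort the
package then runs two across-user Pearson-correlation analyses:

* **fundamental time unit** — each 1/2/4-week block mean vs the 2-month
  mean (is a short block representative? criterion r ≥ .75);
* **independent cycle** — two non-overlapping blocks separated by TI
  weeks, averaged per TI (when does the correlation decay enough that the
  periods belong to different use cycles?);

plus correlations of the 2-month parameter means with the SPAI-5
smartphone-addiction questionnaire total.

Because event-level datasets are private, a calibrated synthetic cohort
generator (33 users × 8 weeks by default: ~57 episodes and 5.74 h of
screen time per day, 40% of episodes / 23% of duration proactive, per-user
sleep windows, weekend effect, slow weekly drift, and a latent addiction
trait read out through SPAI-5) stands in for real data and makes every
stage testable end to end.

## Worked example

```sh
python analysis/01_simulate_cohort.py  --seed 1 --out-dir results
python analysis/02_extract_episodes.py --events results/events.csv --out results/episodes.csv
python analysis/03_daily_parameters.py --episodes results/episodes.csv --out results/daily_params.csv
python analysis/04_stability_analysis.py --daily results/daily_params.csv --spai5 results/spai5.csv --out-dir results
```

prints, stage by stage:

```
simulated 33 users x 8 weeks: 262034 events, 100452 use episodes (39.1% proactive)
1782 user-days -> 195432 episodes (96825 use); 0 stream anomalies (see episodes_qc.json)
1782 user-days: mean F 54.3/day, D 4.92 h/day, proactive 39% of episodes and 23% of duration
1-week units: mean r 0.957; 100% of cells at r>=0.75
2-week units: mean r 0.969; 100% of cells at r>=0.75
4-week units: mean r 0.983; 100% of cells at r>=0.75
1-week independent cycles, mean r by TI: TI0=0.955, TI1=0.924, TI2=0.899,
TI3=0.886, TI4=0.852, TI5=0.826, TI6=0.815
r(PD, SPAI-5) = 0.439 (p = 0.011)
```

Reading it: this seed's 33 users average 54 use episodes and 4.9 h of
screen time per day (sampling noise around the calibrated 57.3 and 5.74);
every 1/2/4-week block correlates ≥ .75 with the 2-month mean, so even one
week is a usable time unit for this low-drift cohort; the independent-cycle
curve decays smoothly with the gap between periods (drift at work); and
proactive use duration correlates r ≈ .44 with the questionnaire total —
the generator's latent addiction trait, recovered through the full event
pipeline. The same library surface is importable directly
(`screenuse.events_to_daily_parameters`, `screenuse.run_stability_suite`,
…) for use on your own tidy event logs
(`user_id,timestamp,event_type` CSV or JSON-lines).

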