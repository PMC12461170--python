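# shadowzone

Spatial shadow-zone analytics for indoor real-time location system (RTLS)
trajectories of mobile nursing workstations.

Hospital falls are rare, serious and strongly tied to caregiver visibility.
When nursing carts (satellite workstations) carry ultrawideband tags, their
position streams reveal where care is — and, just as importantly, where it
has not been for a long time. `shadowzone` turns raw tag emissions into a
minute-by-minute **percentage of spatial shadow zone**: the share of a care
unit's floor area that has sat outside every workstation's coverage area for
a sustained period, and links that statistic to clinical events.

## The statistic

The unit is partitioned into a grid of 1 m × 1 m cells. A workstation at
cell *c* covers the Chebyshev ball of radius *d* cells around *c* — the
(2d+1)×(2d+1) block reached in all cardinal and diagonal directions, with
*d* = 2 m approximating a caregiver's visual/functional range. A cell is in
*spatial shadow* at minute *t* if it has been outside every workstation's
coverage for at least *T* = 60 consecutive minutes ending at *t*. Writing
S_t for the set of shadow cells and A for the unit area,

    percent_shadow(t) = 100 · |S_t| · cell_area / A ,

evaluated every minute. The association analysis compares shadow percentage
between event-exposed and unexposed minutes (Welch t test) and fits
minute-level logistic regressions of fall / ICU-transfer exposure on shadow
percentage, adjusted for day of week and the shift's patient-to-nurse
ratio, reporting odds ratios per percentage point with Wald 95% CIs.
Sensitivity analyses sweep *d* over 1–4 m and *T* over 15–90 min.

## What's in the package

| module | role |
| --- | --- |
| `shadowzone.rtls_io` | position/event/schedule I/O, isolated-outlier noise filter (>2.5 m from both neighbours), noise and missing-rate metrics |
| `shadowzone.grid_coverage` | unit grid, per-minute resampling with staleness-limited carry-forward, Chebyshev-dilated coverage rasters |
| `shadowzone.shadow_zone` | incremental uncovered-minute counters, per-minute shadow series, (d, T) sensitivity surface |
| `shadowzone.validation` | positional error vs a ground-truth route: per-point distances, CDF table/plot, summary statistics |
| `shadowzone.association` | minute labelling, Welch comparisons, adjusted logistic models, sensitivity grid, split-half, fall rates |
| `shadowzone.synthetic_data` | seeded generator of workstation trajectories, data artifacts and shadow-linked events |

See `docs/methods.md` for the model conventions, generator design and known
limitations.

## Worked example

Two results need no data at all. Eight falls in a 40-bed unit over 210 days:

```python
>>> from shadowzone import fall_rate, compute_noise_rate
>>> fall_rate(8, 40, 210)
1.0
```

— 1.0 falls per 1000 patient-days. And 106,564 noise points among
47,230,357 emissions:

```python
>>> compute_noise_rate(47_230_357, 106_564)
(0.0022562607350183695, 443)
```

— a 0.226% noise rate, one flagged point in every 443.

The full pipeline runs on synthetic data from the command line. Simulate a
30-day study in the default 400 m² unit (4 workstations, 40 beds, injected
jump noise and missingness, events whose log-odds follow the true shadow
series):

```console
$ shadowzone simulate --seed 11 --days 30 --out demo
wrote demo/: 186041 positions, 21 events, mean shadow 74.3%

$ shadowzone quality --positions demo/positions.csv --out demo/quality.json
noise rate 0.238% (1 in 420)

$ shadowzone shadow --positions demo/positions.csv --boundary 20,20 --out demo/shadow.csv
wrote demo/shadow.csv (43200 minutes, mean shadow 74.3%)

$ shadowzone associate --series demo/shadow.csv --events demo/events.csv --out-prefix demo/assoc
{
  "fall_flag": 1.0371601087866538,
  "icu_flag": 0.9956661030951949
}
```

Reading the output: the recovered noise rate (0.238%) sits at the injection
probability; the unit spends ~74% of its area in shadow on average; and the
adjusted odds ratios per shadow percentage point come out above 1 for falls
(1.037 — more unvisited area, higher fall odds) and below 1 for ICU
transfers (0.996 — intensified bedside presence precedes transfers). With
only two falls in 30 simulated days the fall estimate is noisy; the signs
stabilize at full scale. `demo/assoc.json` holds the group comparisons and
CIs; `shadowzone sensitivity` and `shadowzone validate` cover the (d, T)
grid and the positional-accuracy procedure.

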