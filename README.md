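# nbhfsocial

Social click-train analysis for narrow-band high-frequency (NBHF) passive
acoustic monitoring data.

Harbour porpoises (*Phocoena phocoena*) echolocate with NBHF clicks
(~105–140 kHz). Most click trains are foraging/navigation: a slow
'searching' phase (long inter-click intervals, rates below 200 clicks/s),
an 'approach' with rising rate, and a terminal feeding buzz ('upsweep').
A minority are **social calls**: short, discrete bursts at 200–1,000
clicks/s, repeated within seconds, with no search phase and no buzz. This
package turns the visual criteria an analyst applies to click-detector
(e.g. F-POD) exports into an automated, reproducible pipeline for anyone
quantifying porpoise social acoustic behaviour:

1. **Filter** — keep trains with mean rate ≥ 100 c/s and mean frequency in
   105–140 kHz, and only scan 15-s frames holding ≥ 256 clicks.
2. **Classify** — mark a train social iff it (a) shows no searching phase
   and no terminal buzz, (b) is discrete (silence on both sides), (c) has
   its rate-profile pattern repeated at least twice within the same 15-s
   frame, and (d) has a mean rate of 200–1,000 c/s. Social trains are
   labelled "mushroom" (one rise–fall peak) or "wiggle" (oscillating).
3. **Aggregate** — detection-positive minutes (DPM) per hour: a minute is
   social-positive if any social train clicks in it; totals use union
   semantics so a minute never counts twice.
4. **Model** — proportions of social DPM (Shapiro–Wilk, Kruskal–Wallis,
   Dunn/Bonferroni) and negative-binomial GAMs of hourly DPM with cyclic
   smooths of hour (period 24) and month (period 12), a year factor,
   VIF and lag-1 ACF screens, and an AR1 working-correlation refit when
   residual autocorrelation exceeds 0.2:

   log E[DPM_t] = β₀ + f_hour(h_t) + f_month(m_t) + β_year,
   DPM_t ~ NB(μ_t, k),

   with f cyclic cubic regression splines penalized by their integrated
   squared second derivative.

Because click-level field recordings of this kind are not publicly
deposited, the package ships a first-class synthetic-data generator
(`nbhfsocial.synth`) that emulates the assumed structure — three-phase
foraging trains, repeated mushroom/wiggle social bursts, darkness-peaked
diel and spring/fall-peaked seasonal encounter intensity, NB-overdispersed
hourly counts — with per-train ground truth, so every stage is validated
against a known answer.

## Worked example

```python
import nbhfsocial as nh

cfg = nh.easy_scenario(seed=42, duration_days=5)
trains, truth = nh.generate_deployment(cfg)
classified = nh.classify_deployment(trains, cfg.duration_days * 86400.0,
                                    nh.FilterConfig(), nh.SocialCriteria())
n_social = sum(r.decision == "social" for r in classified)
print(f"trains: {len(trains)}, marked social: {n_social}")

span = nh.RecordSpan(cfg.site, cfg.start, cfg.duration_days * 86400.0)
rows = nh.aggregate_dpm(classified, span)
total = sum(r.dpm_total for r in rows)
social = sum(r.dpm_social for r in rows)
print(f"DPM: {social} social / {total} total = {nh.pct_social(social, total)}%")
```

prints

```
trains: 53, marked social: 31
DPM: 9 social / 34 total = 26.5%
```

— 53 synthetic trains over 5 days, of which 31 bursts satisfy all four
social criteria; they occupy 9 of the 34 detection-positive minutes
(26.5%; this well-separated scenario is social-rich by design). The same
proportion operation applied to a published dataset-wide tally of 2,619
social DPM out of 49,811 gives 5.3%, and the decline operation applied to
annual totals 15,006 → 6,948 gives −53.7%.

Longer records and the temporal models run the same way:

```python
df = nh.dpm_frame(rows)                      # tidy hourly DPM
fit = nh.fit_nb_gam(df, nh.GamSpec(response="dpm_social",
                                   terms=("hour", "month")))
fit.smooth_peak("hour")                      # diel peak of the fitted smooth
```

## Command line

```bash
nbhfsocial simulate config.yaml   # write clicks.csv + truth.csv
nbhfsocial classify config.yaml   # criteria (a)-(d) -> classified.csv
nbhfsocial aggregate config.yaml  # hourly DPM -> dpm.csv
nbhfsocial model config.yaml      # NB-GAMs -> model.json
nbhfsocial report config.yaml     # report.md
nbhfsocial all config.yaml        # end to end
```

The YAML config holds the scenario, filter, social-criteria and model
settings; every run writes its resolved config next to its outputs. Exit
codes: 0 success, 2 config error, 3 data error.

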