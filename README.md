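# thermolag

Weekly temperature–count anomaly analysis and distributed lag nonlinear
modelling (DLNM) for daily event series.

Given a daily table of maximum/minimum temperatures and non-negative event
counts, the package:

1. builds day-of-year climatologies and daily anomalies (`thermolag.anomaly`);
2. aggregates anomalies over trailing 7-day windows (count sums, temperature
   means) and classifies high-end / low-end event weeks at the 95th / 5th
   percentile (`thermolag.events`);
3. profiles monthly temperature anomalies by event class, selects the months
   with the largest high-vs-low differences, cuts weekly temperature
   anomalies into share-calibrated cool / normal / warm categories (including
   a signed "greatest departure" of the max/min anomalies) and crosses the
   labels into a 3×3 contingency table with column percentages;
4. fits a from-scratch DLNM — natural cubic spline exposure basis × polynomial
   lag basis cross-basis, Poisson log-link IRLS with a natural-spline time
   term and day-of-week contrasts — and predicts cumulative relative risk
   against the median exposure, with an AIC sensitivity grid over lag length
   (3–6), lag polynomial df (2–4) and exposure spline df (3–8)
   (`thermolag.dlnm`);
5. provides a synthetic generator (`thermolag.simulate`) with seasonal
   AR(1) temperatures and Poisson counts carrying a known, recoverable
   lag-distributed temperature effect, plus `toronto_like` / `jackson_like`
   presets.

## CLI

```sh
thermolag simulate --preset toronto_like --seed 1 --out daily.csv
thermolag climatology --counts daily.csv --var tmax --out clim.csv
thermolag events --counts daily.csv --months Jan,Jul,Aug,Sep \
    --cool-share 0.14 --warm-share 0.10 --variable greatest_departure \
    --outdir events_out
thermolag dlnm --counts daily.csv --var tmax --scale annual \
    --lag 6 --lag-df 2 --temp-df 4 --aic-grid --out fit
thermolag run-all --seed 1 --outdir run_out        # full pipeline
```

`run-all` accepts `--config FILE` (JSON or YAML) mirroring
`thermolag.pipeline.PipelineConfig`; every run writes a `run_log.txt` with
the seed and a config hash, and identical seeds give byte-identical numeric
outputs.

The daily CSV format is `date,tmax,tmin,count` with ISO-8601 dates, a
contiguous calendar, empty fields for missing temperatures, and integer
counts.

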