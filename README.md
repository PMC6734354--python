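# richrv

Heart-rate-variability (HRV) analysis for remote ischemic conditioning
(RIC) protocols.  RIC — repeated cuff inflation/deflation on a limb, here
four cycles of 5-min occlusion / 5-min reperfusion bracketed by a 10-min
baseline and a 5-min post-rest — is studied as a trigger of autonomic
responses, and HRV is the standard non-invasive window onto those
responses.  `richrv` provides the full chain a physiologist needs for such
a protocol:

* **synthetic cohorts** — seeded RR/ECG generators with known spectral
  structure, age-dependent baseline variability, an optional post-RIC rise
  in long-term variability, and ground-truth beat times and ectopic
  positions (no public recordings of this protocol exist);
* **R-peak detection** — the Pan-Tompkins algorithm (band-pass, derivative,
  squaring, moving-window integration, dual adaptive thresholds,
  refractory, T-wave rejection, search-back), zero-phase throughout;
* **segmentation** — the protocol timeline as labelled 5-min phases, with
  interval-to-phase assignment by terminating beat;
* **HRV features** per segment —
  time domain (mean/median RR, SDRR, SDSD, rMSSD, NN50, pNN50),
  frequency domain (ectopic correction, 10-Hz cubic-spline tachogram,
  Welch PSD with 256-sample Hann windows, VLF/LF/HF powers, nuLF, nuHF,
  LF/HF), and the Poincaré descriptors

      SD1² = ½ Var(RRₙ − RRₙ₊₁) = ½ SDSD²,   SD2² = 2 SDRR² − ½ SDSD²;

* **statistics** — exact paired Wilcoxon signed-rank tests (pre vs post
  RIC, occlusion vs non-occlusion), young/senior stratification at the
  strict >60-years cutoff, and Spearman correlations between per-subject
  feature changes.

## Worked example

Simulate a 17-subject cohort (9 young, 8 senior) in which the slow
(VLF+LF) RR modulation is amplified 1.5× after the last occlusion, extract
features, and run the paired pre/post comparison:

```python
from richrv import (CohortSpec, build_timeline, generate_ric_cohort,
                    cohort_feature_table, compare_pre_post, correlate_deltas)
from richrv.stats import results_frame

tl = build_timeline()                      # 11 phases, 0..3300 s
cohort = generate_ric_cohort(CohortSpec(9, 8, tl, post_effect_multiplier=1.5, seed=1))
table = cohort_feature_table(cohort, tl)   # one row per (subject, phase)
print(results_frame(compare_pre_post(table))[
    ["feature", "n_pairs", "W", "p_value", "direction", "significant"]])
c = correlate_deltas(table, "sd2_ms", "rmssd_ms")
print(f"delta SD2 ~ delta rMSSD: rho={c.rho:.3f} p={c.p_value:.4g} n={c.n}")
```

Output:

```
     feature  n_pairs    W  p_value  direction  significant
  mean_rr_ms       17 11.0 0.000839         -1         True
median_rr_ms       17 26.0 0.014999         -1         True
       pnn50       10  0.0 0.001953          1         True
    rmssd_ms       17  0.0 0.000015          1         True
       nu_lf       17  0.0 0.000015          1         True
       nu_hf       17  0.0 0.000015         -1         True
       lf_hf       17  0.0 0.000015          1         True
      sd1_ms       17  0.0 0.000015          1         True
      sd2_ms       17  0.0 0.000015          1         True
     sd1_sd2       17  0.0 0.000015         -1         True
delta SD2 ~ delta rMSSD: rho=0.799 p=0.0001194 n=17
```

The injected effect is detected as an SD2 increase (direction +1,
p = 2·2⁻¹⁷ ≈ 1.5e-5, the smallest two-sided p an exact signed-rank test
with 17 concordant pairs can produce), and the SD2 change correlates
positively with the rMSSD change across subjects.  Because every subject
shares the deterministic modulation frequencies, even tiny consistent
shifts in other features reach significance in this synthetic null-noise
setting — the paired design is that sensitive; with
`post_effect_multiplier=1.0` the cohort is exchangeable and rejections
occur at the nominal 5% rate (verified below).  `W` is the smaller of the
two signed-rank sums; `pnn50` shows `n_pairs = 10` because subjects with
identical pre and post values contribute zero differences, which the test
drops.

The same pipeline runs from the shell:

```sh
richrv simulate --n-young 9 --n-senior 8 --effect 1.5 --seed 1 --out-dir cohort/
richrv run --manifest cohort/manifest.yaml --out-dir results/
richrv report --features results/features.tsv --out results/figures/
```

`richrv detect / segment / features / analyze` expose the individual
stages; all file formats are plain tab-separated text plus YAML sidecars.

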