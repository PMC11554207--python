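# floodcontam

Quantifying the long-term "contamination" of native freshwater fish
assemblages by non-native species, for community ecologists working with
long-term ecological research (LTER) survey tables.

The package targets the situation of a floodplain monitoring programme:
nine localities (six lakes, three river channels) sampled quarterly by
gillnetting (fixed 368 m² of effort) and beach seining (lakes only), with
every catch identified to species and weighed, and every species classified
as native or non-native. From such tables it computes area-standardized
biomass, five contamination indices, Kempton's interquartile diversity,
biomass–richness correlations, and smooth temporal trends with
autocorrelated residuals. Because raw LTER data are rarely redistributable,
it also ships a seeded synthetic-survey generator with the same statistical
structure, so the entire pipeline is testable end to end and the trend
detector's power and size can be measured against a known truth.

## The statistics

For sampling unit *s* (one gillnetting or seining event) and species *j*,
biomass density is `B_j = Σ_i ω_ij / A` (summed individual weights over the
sampled area, g·m⁻²). Splitting species by origin gives richnesses
`R_n, R_nn` and summed densities `B_n, B_nn`, and the five indices:

    CI_r  = R_nn / (R_nn + R_n)
    CI_b  = B_nn / (B_nn + B_n)
    CI_e  = R_nn·B_nn / (R_nn·B_nn + R_n·B_n)
    CI_a  = (CI_b + CI_r) / 2
    CI_sq = sqrt(CI_b · CI_r)

Each lies in [0, 1]; an index with a vanishing denominator is *undefined*
and excluded from group means, never coerced to 0 or 1. Kempton's
diversity for a per-species biomass vector with richness *R* is
`Q = (R/2) / ln(B_4/B_2)` with `B_4`, `B_2` the 75th/25th percentiles
(linear interpolation), averaged across localities per campaign.
Temporal trends are penalized cubic-spline smooths of time with locality
random intercepts and AR(1) residual correlation (phi), reporting edf,
reference df, an approximate F test, adjusted R², and a slope summary
*beta* (OLS slope of the fitted values, response units per year).

## Worked example

```python
import floodcontam as fc

survey, truth = fc.simulate_survey(fc.default_config(seed=1))
prof = fc.contamination_indices(fc.summarize_unit(survey, "lgar-2000Q1-gill"))
print(f"CI_r={prof.ci_r:.3f} CI_b={prof.ci_b:.3f} CI_e={prof.ci_e:.3f}")

per = fc.unit_profile_table(survey)
g = per[per.gear == "gillnet"].dropna(subset=["CIr"])
import pandas as pd
d = pd.to_datetime(g["campaign_date"])
t = ((d - d.min()).dt.days / 365.25).to_numpy()
fit = fc.fit_smooth_trend(t, g["CIr"].to_numpy(), locality=g["locality"].to_numpy())
print(f"beta={fit.beta:.4f}/yr edf={fit.edf:.2f} p={fit.p:.2g} phi={fit.phi:.2f}")
print(fc.recovery_report(truth, g, [fit]))
```

prints (seed 1):

```
CI_r=0.045 CI_b=0.107 CI_e=0.006
beta=0.0180/yr edf=2.40 p=2.5e-108 phi=0.43
{'n_units': 612, 'bias': -0.009292233032801916, 'rmse': 0.04309936741390764,
 'true_slope': 0.018962317728550518, 'sign_agreement': 1.0}
```

The first unit (lake Garças, 2000 Q1) is still almost entirely native —
under 5% of observed species and ~11% of biomass are non-native; over the
18-year simulated series the gillnet richness-contamination index climbs by
~0.018 per year — a strongly supported smooth trend with moderate residual
autocorrelation — and the per-unit estimates track the true resident
non-native fraction with negligible bias (|bias| < 0.01, RMSE 0.043).

The same pipeline runs from the shell:

```bash
floodcontam simulate --seed 1 --out out/
floodcontam metrics --in out/ --out out/
floodcontam trends  --in out/ --out out/
floodcontam report  --out out/
```

producing the survey CSVs, Table-style metric and trend reports (two
decimals, undefined cells left empty), Wilcoxon comparisons of the
biomass–richness correlations of native vs non-native assemblages, and a
summary figure.

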