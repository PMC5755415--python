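# cariesmap

Small-area surveillance of early-childhood dental caries: Bayesian disease
mapping of parish-level relative risks, a regional caries *polarization
index* with outlier sensitivity analysis, and a risk-based capitation
algorithm that re-allocates a fixed dental-care budget toward high-need
parishes.  Written for dental public-health units and epidemiologists who
monitor socio-economic inequality in caries from routine examination
registries, and who want the full registry-to-report workflow to be
reproducible on synthetic data.

## The model

A child is a caries case when dmfs > 0 (decayed/missing/filled primary
surfaces).  For parish *i*, observed cases *O<sub>i</sub>* are compared
with internally standardized expected counts
*E<sub>i</sub> = Σ<sub>s</sub> n<sub>is</sub> r<sub>s</sub>* (region-wide
sex-specific rates *r<sub>s</sub>*), so Σ*E* = Σ*O* and
*O<sub>i</sub>/E<sub>i</sub>* is the raw SMR.  Smoothed relative risks come
from the BYM convolution model

&nbsp;&nbsp;&nbsp;&nbsp;*O<sub>i</sub>* ~ Poisson(*E<sub>i</sub>θ<sub>i</sub>*),&nbsp;&nbsp;
log *θ<sub>i</sub>* = *α* + *u<sub>i</sub>* + *v<sub>i</sub>*,

with *u* an intrinsic CAR (ICAR) spatially structured effect on the parish
adjacency graph and *v* iid normal heterogeneity.  The package reports the
posterior median SmRR, 90/95% credible intervals, the exceedance
probability Pr(RR > 1 | data), and the three-color certainty rule
(red: Pr > 0.95; green: Pr(RR < 1 | data) > 0.95; yellow otherwise).  The
polarization index is max(SmRR)/min(SmRR), recomputed after excluding
box-plot (Tukey-fence) outliers.  Capitation: each parish gets component
need scores in {1,2,3} (education, foreign background, low purchasing
power, caries risk) and a weighted total
0.2·edu + 0.2·foreign + 0.2·purchasing + 0.4·risk ∈ [1.0, 3.0] that scales
its per-child share of a fixed budget.

The MCMC sampler (adaptive Metropolis-within-Gibbs with graph-coloring
block updates and joint effect/scale rescaling moves) is built in; fits of
a 58-parish region take a few seconds.  See `docs/methods.md` for priors,
identifiability handling and numerical choices.

## Worked example

```python
import cariesmap as cm

truth = cm.simulate_region(cm.SimConfig(seed=3))     # 58-parish synthetic region
kids = cm.simulate_cohort(truth, 2010)               # child-level records
dom = cm.filter_cohort(kids, age_min=3, age_max=6, birth_class="domestic")
counts = cm.expected_counts(dom)                     # O, E, SMR per parish

mapper = cm.BYMMapper(seed=7).fit(counts, truth.graph)
res = cm.analyze_polarization(mapper.summary_["smrr"],
                              ids=mapper.summary_["parish_id"])
print(f"prevalence {cm.prevalence(dom).percent}%")
print(f"polarization index {res.index}, outlier-excluded {res.sensitivity_index}")
print(mapper.summary_["category"].value_counts().to_dict())
```

prints

```
prevalence 11.9%
polarization index 6.6, outlier-excluded 6.6
{'uncertain': 26, 'lowered': 19, 'elevated': 13}
```

i.e. a cohort prevalence of 11.9% (dmfs > 0), a 6.6-fold gap between the
highest- and lowest-risk parish after smoothing (no parish is a box-plot
outlier for this realization, so the sensitivity value is unchanged), and
13 parishes with strong evidence of elevated risk (red) versus 19 with
lowered risk (green).

The same workflow runs from the shell over YAML configuration:

```sh
cariesmap config init --out run.yaml    # prints every default
cariesmap run --config run.yaml         # simulate -> map -> polarize -> allocate -> report
```

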