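# commflux

Personalised community metabolic modelling of the gut microbiome, for
researchers asking how a community's *composition* constrains what it can
metabolically do — which metabolites it can take up from the diet, which
it can secrete into the faecal compartment, and which member strains are
responsible — and how that potential differs between healthy, IBD
non-dysbiotic and IBD dysbiotic microbiomes.

## The model

For each sample, the member strains' genome-scale reconstructions are
joined into one steady-state model `S v = 0, lb ≤ v ≤ ub`: one
compartment per strain, a shared lumen, diet exchanges flowing in
(`0 ≤ v ≤ diet`), faecal exchanges flowing out (`v ≥ 0`), and a community
biomass reaction consuming each strain k's biomass metabolite with
coefficient a_k (its relative abundance), which forces

    v_bio,k = a_k · v_community   for every feasible flux vector,

i.e. growth at the measured ratios.  Community biomass is bounded to
[0.4, 1] mmol/person/day and coupling constraints |v| ≤ 400·v_bio,k + 0.01
tie each strain's reactions to its growth.  The metabolic profile is then
computed by flux variability: for every dietary, faecal and strain-level
exchange reaction, two LPs give its minimal and maximal flux.  Secretion
potential = max faecal flux; uptake potential = max diet flux; a strain's
contribution to a metabolite = max flux of its strain → lumen transporter.

On top of the profiles sit the cohort statistics: Wilcoxon + FDR screens
of secretion fluxes, Fisher tests on binary secretion (collapsed to
independent features), OLS of secretion diversity on group with a
fractional-polynomial strain-count term, counting of independently
secreted sulfur species, logistic/AUC classification, Sobel–Goodman
mediation of the group effect by glycan-degrader presence (1000 bootstrap
replications), random-forest stratification (5000 trees), and agreement
of in-silico directions with a metabolomic reference table.

Because real strain reconstructions and metagenomes are not shipped, a
first-class synthetic-data module generates a pan-reactome with subsystem
structure (fermentation, amino-acid and B-vitamin biosynthesis, sulfur
metabolism, host-glycan degradation), taxonomically structured strains,
and three-group cohorts in which dysbiosis means reduced richness,
Proteobacteria enrichment, Bacteroidetes depletion and depleted
glycan degraders.  See `docs/methods.md` for the full model description.

## Worked example

```python
import warnings
from commflux import synthetic_data as sd
from commflux.community_builder import build_community_model, apply_diet
from commflux.flux_profiler import (
    compute_exchange_flux_ranges, compute_metabolite_profile)

pan = sd.generate_pan_reactome()
strain_a, strain_b, target, diet = sd.cross_feeding_pair(pan)

model = build_community_model(
    {"XF_A": strain_a, "XF_B": strain_b}, {"XF_A": 0.5, "XF_B": 0.5})
with warnings.catch_warnings():
    warnings.simplefilter("ignore")          # diet metabolites not in lumen
    model = apply_diet(model, diet)

ranges = compute_exchange_flux_ranges(model)
profile = compute_metabolite_profile(model, ranges)
print(profile.table.loc[["h2s", "so4", "cspg"]])
```

prints

```
               secretion_potential  uptake_potential    origin_class
metabolite_id
h2s                           3.75               0.0  microbial_only
so4                          20.00               0.0  microbial_only
cspg                         10.00              10.0            both
```

Strain A (a Bacteroidetes glycan degrader) releases sulfate from the
host glycans chondroitin and heparan sulfate (10 + 10 allowed units, so
up to 20 sulfate); strain B (a Proteobacteria sulfate reducer) reduces
it to hydrogen sulfide — 3.75 mmol/person/day at most, limited by the
protons the reduction chain consumes.  Neither strain alone can secrete
any H2S, which is the emergent cross-feeding the community formulation
exists to capture.  Sulfate and H2S are of microbial origin (absent from
the diet); chondroitin sulfate is both supplied and passed through.

The full analysis is a sequence of drivers:

```sh
python analysis/01_generate_cohort.py      # synthetic cohort + inputs
python analysis/02_profile_communities.py  # models, FVA, contributions
python analysis/03_network_metrics.py      # presence, correlations, sulfur, PCoA
python analysis/04_cohort_statistics.py    # screens, regression, mediation, RF
```

writing all tables under `results/run/`.

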