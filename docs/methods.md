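# Methods

`commflux` models the metabolic potential of personalised gut-microbiome
communities and the statistics that compare that potential across a
three-group cohort (healthy, non-dysbiotic IBD, dysbiotic IBD).  This note
records the model, its assumptions, the synthetic study conditions, the
numerical choices, and what the tests do and do not establish about real
data.

## Community model

Each sample's community model joins the member strains' genome-scale
reconstructions into one steady-state stoichiometric model:

* every strain keeps its own compartment; its exchange reactions become
  strain ↔ lumen transporters with the strain's original bounds;
* a shared lumen connects strains to the boundary: diet exchanges flow
  *into* the lumen with flux in `[0, diet amount]` and faecal exchanges
  flow *out* with flux in `[0, ∞)`.  This sign convention keeps uptake and
  secretion on separate non-negative axes (the SBML export keeps the same
  convention rather than the COBRA negative-uptake one);
* a community biomass reaction consumes each strain k's biomass metabolite
  with stoichiometric coefficient a_k, the strain's relative abundance.
  Since that metabolite is produced only by strain k's biomass reaction
  and consumed only by the community biomass reaction, every feasible flux
  vector satisfies v_bio,k = a_k · v_community exactly: all strains grow
  at the measured ratios by construction, not by an added constraint;
* community biomass flux is bounded to [0.4, 1] mmol/person/day,
  corresponding to faecal emptying between once every three days and once
  a day;
* optional coupling constraints |v| ≤ c·v_bio,k + ε (defaults c = 400,
  ε = 0.01) tie every strain-owned reaction, transporters included, to its
  strain's growth, so no strain can carry flux without growing.  They are
  on by default and can be disabled to study their effect.

Assumptions worth stating: there is no host compartment and no dynamics —
the model describes a flux *capability* polytope, not a time course.  The
diet is an upper bound on uptake, not a measured intake.  Strain exchange
bounds from the reconstructions are kept inside the community (results can
be sensitive to this; opening them admits more cross-feeding).

One structural consequence of the single shared lumen: any dietary
metabolite can pass diet → lumen → faeces without touching a strain, so
every dietary metabolite has positive secretion potential and classifies
as `both`.  The `dietary_only` origin class is therefore reachable only
for inputs whose faecal route is absent — in practice it does not occur in
pipeline runs, and the cohort-level secreted counts carry a constant
dietary offset that cancels in all group comparisons.  Raw secretion and
uptake potentials are reported; any netting of one against the other is
left to downstream analyses.

## Flux profiling

For every dietary, faecal and strain-level exchange reaction, two LPs
minimise and maximise that reaction's flux under all model constraints.
The solver is GLPK (via swiglpk) with a warm-started simplex across
objectives; results are reported at 1e-9 resolution — below LP tolerance —
so they are independent of solve order and worker count.  Per-reaction
LPs are independent tasks; the optional process pool partitions them and
yields identical results to a serial run.  Unbounded maxima (possible in
toy models, not in diet-bounded ones) are capped at 1e4 and flagged.
An infeasible sample raises a single report naming the binding constraint
class: "biomass bounds" if relaxing the community-biomass lower bound
restores feasibility, otherwise "diet".

Derived quantities, per sample: secretion potential (max faecal flux) and
uptake potential (max diet flux) per metabolite with a qualitative origin
class at tolerance τ = 1e-6; and a strain's contribution to a metabolite,
the maximal flux of its strain → lumen transporter (clipped at zero).
These satisfy, provably, the additivity bound
faecal max ≤ diet bound + Σ_k contribution_k, which the tests check.

## Synthetic study conditions

The generator emulates the statistical structure the analysis needs,
not any real reaction content.

* **Pan-reactome** (default 64 metabolites, 140 reactions): a curated
  backbone — glycolysis and biomass, 7 fermentation products, 18
  sulfur-free amino acids, a 14-species sulfur family, host glycans
  (chondroitin and heparan sulfate) with degradation reactions releasing
  sulfate plus a fermentable sugar, 6 B-vitamins (thiamine and biotin
  draw on cysteine so sulfur balances) — plus generic filler to the
  requested size.  Every non-exchange, non-biomass reaction conserves
  sulfur atoms exactly; full elemental balancing of the toy reactions is
  deliberately not enforced, since the sulfur ledger is the property the
  downstream argument uses.
* **Sulfur gating**: the default diet contains organic sulfur (cysteine,
  methionine) but no inorganic sulfate, so sulfate and its derivatives
  (sulfite, thiosulfate, isethionate) can enter a community only through
  host-glycan degradation.  Glycan-degrader presence therefore causally
  gates part of the sulfur secretion repertoire — the structure the
  mediation analysis is designed to detect.  Hydrogen sulfide,
  methanethiol and the amino-acid-derived sulfur species remain reachable
  from the diet, mirroring compounds secreted by essentially all
  communities.
* **Strains** (default 40): core reactions plus a repertoire sampled with
  phylum-level trait profiles — Bacteroidetes carry glycan degradation,
  Proteobacteria are amino-acid- and sulfate-reduction-heavy, Firmicutes
  ferment, Actinobacteria make B-vitamins.  Each strain's growth is
  verified by LP with open exchanges.
* **Cohort** (default 25 / 63 / 20 — healthy / non-dysbiotic / dysbiotic):
  per sample, richness is Poisson around the group mean (16 / 12 / 6
  strains), strains are drawn with phylum-biased weights (dysbiosis:
  Proteobacteria ×4, Bacteroidetes ×0.25), abundances are Dirichlet(1),
  and glycan-degrader membership is forced or suppressed to match the
  group prevalence (0.90 / 0.60 / 0.15).  The group sizes mirror the
  modelled study; richness and prevalence values are the package's choice
  of a realistic desk-scale gradient and are fixed once in the defaults.
* **Metabolomic reference**: an external direction table is emulated by
  flipping the in-silico directions independently with probability 0.3,
  so the expected agreement is 70%.

What the synthetic data does *not* emulate: real reaction content or
naming beyond style, genuine abundance spectra (real communities are far
more uneven), strain-level bound heterogeneity, and any host metabolism.
One visible consequence: because most products have several capable
producers and secretion maxima are capped by the shared substrate budget,
flux–species Spearman correlations above 0.75 are rare-to-absent in the
default cohort — the correlation machinery is exercised on constructed
monotone data in the tests instead.
Passing tests therefore show that the machinery detects effects whose
causal structure is known and planted; they do not validate biological
conclusions about real cohorts.

## Statistics

* Rank-sum screens use the exact Mann–Whitney distribution where tie-free
  and small, the normal approximation otherwise; all-tied features are
  emitted with p = 1.  FDR control is Benjamini–Hochberg throughout; all
  tests are two-sided.
* Binary secretion screens first collapse perfectly coupled features
  (identical binary columns cohort-wide — the most literal reading of
  "independent" secretions), then apply Fisher's exact test (2 groups) or
  a Freeman–Halton enumeration (3 groups).
* Secretion-diversity regression is OLS of the secreted-metabolite count
  on group plus an FP1 fractional-polynomial term in the strain count
  (powers −2, −1, −0.5, 0 = log, 0.5, 1, 2, 3), the power chosen by
  minimal deviance with a χ²(1) deviance-difference test against the
  linear form.  Degrees of freedom come from this design, not any
  external one.
* Classification AUC is the concordance of the raw score with the
  positive class — exactly U/(n₁n₂) — with the univariate logistic
  coefficient reported alongside.
* Mediation uses the Sobel–Goodman product-of-coefficients decomposition
  over OLS fits (total = direct + indirect exactly), with percentile
  bootstrap CIs over 1000 replications, deterministic given the seed.
* Random forests: 5000 trees, out-of-bag error, permutation-based mean
  decrease in accuracy for the feature ranking (computed on the full
  data, not OOB-restricted).
* Direction agreement counts metabolites significant in both tables and
  reports a binomial test against 0.5 as the headline number, with a
  Fisher test of the observed split against an even split labelled
  alongside (the 2×2 construction is not canonical, so both are emitted).

## Numerical choices and degenerate inputs

τ = 1e-6 separates "can secrete/take up" from numerical zero; abundances
below 1e-6 are dropped and rows renormalised (noise-level abundances make
near-singular biomass coefficients); flux results are rounded to 1e-9;
LP warm starts fall back to a fresh advanced basis if a solve goes
numerically stale.  Ties in the FP1 power search break toward the power
closest to linear.  Formula parsing gives two-letter element symbols
precedence, so selenium ("Se") and tin ("Sn") never count as sulfur.

## Problem sizes

Defaults profile 108 samples with roughly 500–1300 exchange LPs each
(~120k LPs per cohort run, a few minutes on one CPU).  The unit-test
fixtures use an 18-sample cohort over the same strain universe and
reduced bootstrap/tree counts; the acceptance checks run the full default
cohort.

## Known limitations

Single-objective FVA extremes only (no sampling of alternate optima); no
host compartment; diet conversion to mmol/person/day is exposed as an
explicit `diet_scale` multiplier rather than hard-coded; the Freeman–
Halton enumeration is exponential in group count and intended for 2–3
groups; SBML export of community models uses finite stand-ins for
infinite bounds.
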