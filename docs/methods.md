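# Methods

## Scores

**Inconsistency (GIMME LP).**  Given a stoichiometric model (matrix S,
flux bounds in mmol·gDW⁻¹·h⁻¹), an objective reaction and a per-sample
presence pattern, we first compute the FBA maximum v_max of the objective
(LP over S·v = 0 and the bounds), then solve

    min  Σ_{i absent} w_i (v_i⁺ + v_i⁻)
    s.t. S·v = 0,  bounds,  v_obj ≥ l·v_max,

where every reversible reaction is split into non-negative forward and
backward variables so |v| is linear.  The optimum is the inconsistency I;
the absent reactions with flux above ε_flux form the inconsistency vector
("reinserted" reactions).  Penalty weights default to the reaction-level
expression deficit w_i = max(0, t − x_i); a uniform mode (w_i = 1, the
literal sum-of-fluxes reading) is a switch, since published descriptions
admit both readings — the deficit-weighted score is primary.  The level
constraint is an inequality (v_obj ≥ l·v_max), not an equality: the level
parameter enforces a minimum achievement of the objective, and the
penalty already pushes v_obj down to it whenever I > 0.  Both LPs run on
HiGHS with 1e-9 primal/dual tolerances and deterministic settings.
For random-media comparisons I is normalised by the achieved objective
flux, which makes values comparable across media of very different
capacity; elsewhere raw I is used.

Reaction-level expression comes from evaluating each reaction's
gene-protein-reaction rule with AND→min, OR→max over log-signal
intensities.  Reactions without a GPR are conservatively treated as
expressed (present, deficit 0) — penalising them would punish knowledge
gaps, not data.  Model genes missing from a profile are imputed with the
profile median (a neutral choice: it neither forces absence nor presence;
logged per sample).  Thresholding uses ≥ t for presence so boundary ties
resolve deterministically.

**Metabolic coherence (MC).**  The model is projected to an undirected
gene network: reactions are adjacent when they share a metabolite that
survives currency removal, genes are adjacent when they occur in the same
or in adjacent reactions (one reaction step; a directed product→substrate
variant is available behind a flag for sensitivity analysis).  Currency
metabolites are the top ceil(4% · n) metabolites by reaction-degree per
compartment, degree ties broken by metabolite id so the cut is
reproducible; artificial drains do not count toward degree.  For a
sample, the genes at or above t that appear in the network induce a
subgraph; the coherence ratio is the fraction of induced nodes with at
least one induced neighbour.  MC is the z-score of that ratio against N
uniformly drawn node subsets of the same size (population 1/N standard
deviation, matching the null definition; N defaults to 1000 and is
config-exposed).  σ = 0 (point-mass null, e.g. subset = all nodes) yields
MC = 0 with a degenerate flag; an empty intersection is undefined and the
sample is excluded from correlations.  In cohort scoring each sample's
null uses an independent seed derived from the base seed and the sample
index: sharing one null estimate across samples of equal subset size
would give those samples literally identical MC values and make rank
statistics depend on hair-thin Monte-Carlo differences between blocks.
`exact_null` enumerates all subsets and is used as the sampling oracle on
small graphs.

## Cohort analysis

Case samples are labelled LIG (below) or HIG (at/above) relative to the
control group's mean inconsistency; the tie goes to HIG by convention.
Contribution strength of a reaction in a group is the fraction of that
group's inconsistency vectors containing it; usage frequency is the
fraction of samples where it carries flux above ε_flux.  A contributor is
*unspecific* when its strength is ≥ 0.9 in every group and *specific*
when the largest pairwise group difference is ≥ 0.5 — published analyses
make this separation by visual sorting, so these two thresholds are
operational choices, config-exposed, not empirical constants.

Topological markers are independent predicates on a directed reaction
graph (edge when one reaction produces a non-currency metabolite the
other consumes; reversible reactions act both ways):

* **JBT** — absent in ≥ 95% of samples and median reaction expression
  within 0.5 log-units below t (a rigid-threshold artifact);
* **CD** — absent while at least one upstream and one downstream
  neighbour are present, in ≥ 50% of samples;
* **CIL / COL** — within 2 reaction steps of an uptake-enabled exchange /
  of the objective reaction (signatures of a wrong medium / wrong
  objective);
* **IP** — ≥ 50% of non-exchange neighbours (radius 1) lack a GPR
  (invisible paths are never penalised);
* **BN** — forcing the reaction to zero drops the FBA maximum below
  l·v_max, with the same l as the scoring run.

All marker thresholds live in `MarkerConfig`.  A reaction may carry
several markers.

**Correlations.**  Pearson r with the one-tailed p of
t = r·sqrt((n−2)/(1−r²)) under Student-t with n−2 df, lower tail — the
working hypothesis is anticorrelation of MC and I.  Spearman ρ uses
average ranks for ties.  Zero-variance input yields an undefined marker
(NaN).  Sweeps: threshold grid 0.5–4.0 in steps of 0.1, levels
{0.5, 0.8, 0.9, 0.95}; grid points where all samples are degenerate are
reported as undefined with the exclusion count.

**Media.**  The reference medium enables uptake only for the configured
nutrient exchanges (defaults −10 for carbon sources, −1 for minor
nutrients; config-exposed since published media rarely print bounds) and
leaves oxygen unconstrained.  Random media select a fraction
f ~ U(0.04, 1) of all exchanges (at least one), give each selected
exchange lb ~ U(−20, 0) and ub ~ U(0, 20), and force the always-available
set (oxygen, protons, phosphate, water, sulfate) to unconstrained uptake
in every draw.  Media for which the objective is blocked are skipped,
logged and resampled up to a retry cap.  Unbounded fluxes are encoded as
±1000 throughout so every LP is finite.

## Synthetic study conditions

The generator builds a deterministic two-compartment model (cytosol,
mitochondrion; 68 reactions, 45 genes at defaults) containing, by
construction, every structure the analysis probes: two carbon uptakes
feeding a main biosynthetic chain through the mitochondrion to a terminal
product drain (the objective); an ATP/ADP cycle closed by an
oxygen-consuming regeneration reaction; a capacity-limited (2 flux units)
alternative route with GPR-less steps; water hubs in both compartments
plus cytosolic protons touching ~39% of reactions (these are exactly what
the 4% currency cut removes); a dead-end side branch; ten silent two-step
side chains; and three isolated "housekeeping" reactions whose genes have
no network neighbours.

Expression is drawn per gene and sample in log-signal units: present
genes ~ N(3.0, 0.4), absent genes ~ N(1.0, 0.4) — a bimodal histogram
whose modes sit 5 noise-SD apart around the default threshold t = 2, so
the default analysis settings (t = 2, l = 0.8) apply unchanged.  The
three states are planted as: control — main chain present, everything
else silent, with an always-absent chain disruptor (N(1.0, 0.1)), a
just-below-threshold reaction (N(1.7, 0.05)) and a borderline energy gene
(N(1.6, 0.2)); LIG-like — control plus the energy gene elevated to
N(3.0, 0.3) and the scattered housekeeping genes silent (a focused,
coherent program: lower I, higher MC); HIG-like — each main-chain gene
independently pushed below threshold with probability 0.6 (higher I, a
fragmented active subnetwork, lower MC).  Cohort sizes default to
20/20/20.  The planted marker reactions (one per marker class) and the
planted unspecific/specific contributors are recorded in a ground-truth
JSON for assertion-based tests.

What the generator does *not* emulate: genome scale (tens of reactions,
not thousands), isozyme-rich GPRs, probe-level noise and normalisation
artifacts, cross-sample batch effects, and biological heterogeneity
within a state.  Passing the recovery tests therefore shows the pipeline
is correct and sensitive under its own assumptions — not that real
tumour cohorts will separate this cleanly.

## Numerical choices and edge cases

* ε_flux = 1e-6 flux units decides "carries flux" / "reinserted";
  solver-noise floor, config-exposed.
* v_max ≤ ε_flux raises a degenerate-objective error: the level
  constraint is meaningless for a blocked objective.
* Artificial (`ART_`) reactions never enter penalties, contribution
  tables, degree counts or the gene network; they have no GPR and are
  expressed by convention.
* The objective-flux normalisation of I returns NaN when the achieved
  objective flux is zero (only possible at I = 0 with l·v_max = 0, which
  the degenerate check already rejects).
* Homogeneity: scaling all exchange bounds by c > 0 scales I and v_obj
  by c exactly when no internal capacity bound binds; the default
  synthetic model deliberately contains a binding internal cap (the
  alternative-route bottleneck), so the homogeneity tests use unbounded
  chain/branch fixtures.
* SBML: written as Level 3 + fbc v2 (bounds as shared parameters, GPRs
  as gene-product associations); the reader additionally accepts the
  legacy Level 2 COBRA notes encoding.  Model construction is
  deterministic, so a given spec always writes byte-identical SBML.

## Known limitations

The GIMME solution is generally non-unique; the reported flux
distribution and hence usage frequencies are one deterministic optimum
(HiGHS), not an enumeration of alternative optima.  The inconsistency
vector, by contrast, is stable in practice because penalised flux is
minimised.  MC is a Monte-Carlo estimate; its sampling error
(≈ σ/√N on μ) is visible when comparing samples with nearly equal
ratios.  The marker predicates operationalise qualitative topological
descriptions; their thresholds are defaults to be tuned per model, and
the BN test is a single-reaction knockout, not a full essentiality
analysis.
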