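# metcoherence

Tools for asking whether a transcriptome "agrees" with a metabolic network,
two different ways, and for comparing the answers.

Constraint-based integration methods such as GIMME reconcile expression
data with a metabolic objective: they keep flux through the objective at a
fraction *l* of its FBA maximum while minimising (deficit-weighted) flux
through reactions whose expression falls below a threshold *t*.  The
optimum of that LP,

    I = min Σ_{i absent} w_i |v_i|    s.t.  S·v = 0,  lb ≤ v ≤ ub,
                                            v_obj ≥ l · v_max,
    w_i = max(0, t − x_i),

is the **inconsistency** — the price, in penalised flux, of forcing the
objective despite the data.  A purely topological alternative projects the
model onto a gene network (reactions adjacent when they share a
non-currency metabolite; genes adjacent when their reactions coincide or
are adjacent), takes the subgraph induced by the genes above threshold,
and scores the fraction of induced nodes with at least one induced
neighbour against a null of random equal-size node subsets:

    MC = (|C(G_sub)|/|g_sub| − μ) / σ,

the **metabolic coherence** z-score.  The package computes both per
sample, correlates them across a cohort (Pearson with a one-tailed t
p-value for the anticorrelation hypothesis, and Spearman), sweeps the
threshold *t*, the level *l* and random growth media, splits case samples
into low/high-inconsistency groups (LIG/HIG) against the control mean,
decomposes *I* into per-reaction contributions, and classifies the
contributors by specificity and by topological markers — bottleneck (BN),
chain disruptor (CD), invisible path (IP), close to input/output layer
(CIL/COL), just below threshold (JBT).

It is aimed at systems-biology users who have an SBML model with GPR
rules, per-sample expression tables, and a medium definition — plus a
fully synthetic generator (`metcoherence.synthetic_data`) that builds a
two-compartment toy model and a seeded cohort with planted control /
LIG-like / HIG-like states, so the entire pipeline is testable without any
external data.

## Worked example

```sh
metcoherence simulate --out fx --seed 1
metcoherence run-all --model fx/model.xml --expression fx/expression.tsv \
    --medium fx/medium.json --truth fx/truth.json \
    --media-config fx/media_config.json --out results --seed 0
```

or, in Python:

```python
from metcoherence import (SyntheticSpec, generate_toy_model, generate_cohort,
                          reference_medium, CohortAnalysis,
                          pearson_one_tailed, spearman_rho)
from metcoherence.synthetic_data import default_media_config

spec = SyntheticSpec(seed=1)                 # 20 control + 20 LIG + 20 HIG
model = generate_toy_model(spec)             # 68 reactions, 45 genes, c/m
profiles, truth = generate_cohort(model, spec)
medium = reference_medium(model, default_media_config(model))
analysis = CohortAnalysis(model, profiles, medium)
frame = analysis.scores(t=2.0, level=0.8, seed=1)   # per-sample I and MC
r, p = pearson_one_tailed(frame["mc"], frame["inconsistency"])
print(r, p, spearman_rho(frame["mc"], frame["inconsistency"]))
```

On this seed the cohort shows the planted two-state structure: mean
inconsistency 10.9 (LIG) < 17.1 (control) < 118.4 (HIG), and the two
scores anticorrelate strongly across the 60 samples (r = −0.83,
p ≈ 1.3×10⁻¹⁶, ρ = −0.89).  The threshold sweep is most negative at
t = 2.1, right at the planted presence/absence boundary (t = 2), and 100
random growth media leave the Pearson correlation in a narrow all-negative
band (−0.83 to −0.60).  The contribution table surfaces exactly the two
planted unspecific contributors (the always-absent chain disruptor and the
just-below-threshold reaction, strength 1.0 in every group) and marks the
energy-cycle reaction specific (strength ≈ 1 in control/HIG, 0 in LIG).

`run-all` writes `scores.tsv`, `groups.tsv`, `inconsistency_vectors.tsv`,
`contributions.tsv` (strengths, usage frequencies, specificity, markers),
`threshold_sweep.tsv`, `level_sweep.tsv`, `media_sweep.tsv` and a
`manifest.json` with parameters, seeds and per-stage wall time.

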