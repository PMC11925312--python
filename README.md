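# pcgem — proteome-constrained genome-scale metabolic modeling

`pcgem` builds **proteome-constrained models** from a genome-scale
metabolic model (GEM) plus protein and complex tables, fits measured
proteomes to them by quadratic programming, derives relaxed
**context-specific models** per sample, classifies reactions by how
strongly their attainable flux depends on enzyme abundance, and
computes metabolite/gene **network-connectivity** statistics.  It is
aimed at systems biologists working with cells whose metabolism is
enzyme-limited rather than uptake-limited — the motivating case is the
mature red blood cell, whose proteome is dominated by hemoglobin
(≥90% of protein mass) and cannot be renewed, so the low-abundance
enzyme complement decides which fluxes are attainable.

## The model

A GEM is the linear program `max c'v  s.t.  S v = 0, v_lb ≤ v ≤ v_ub`
with fluxes `v` in mmol/gDW/hr.  `pcgem` augments it with a protein
layer in the style of enzyme-constrained (OVERLAY-type) formulations:

- protein abundances `p_j ≥ 0` (nmol/gDW) with molar masses `w_j`
  (mg/nmol, computed from amino-acid sequence), drawing on a
  partitioned proteome budget

  `P_total = P_HB + P_LA ≤ 1000 mg/gDW`, with the hemoglobin pool
  `P_HB ≥ 900` and the low-abundance pool `P_LA ≤ 100`;

- complex abundances `x_l` assembled from subunits, `C x ≤ p`;

- per-reaction *enzyme entities* `e_i = e_i^fwd + e_i^rev = Σ_l B_il r_l x_l`
  with rate-constant ratios `r_l = k_l / k_avg`, where
  `k_l = k_avg (M_l / M̄)^{3/4}` scales with complex molar mass
  (solvent-accessible surface area) around `k_avg = 65 s⁻¹ = 2.34e5 hr⁻¹`;

- capacity coupling `−k^rev e_i^rev ≤ v_i ≤ k^fwd e_i^fwd`.

A measured proteome `p^data` (budget-scaled so hemoglobin carries
950 mg/gDW and the rest 50 mg/gDW) is fitted by the convex QP

`min Σ_j c_j (p_j − p_j^data)²` subject to all model constraints, with
weights `c_j = 1/p_j^data` (measured > 0), `1` (measured 0), `0`
(missing).  The best-fit vector `p′` defines a context-specific model
with a slack `s` and a *relaxation budget*
`P_R ≤ P_R,ub = s Σ_j p′_j w_j` of unspecified protein mass:
measured proteins are bounded in `[(1−s) p′_j, p′_j + s P_R,ub / w_j]`,
unmeasured ones in `[0, s P_R,ub / w_j]`, and
`P_total = P_HB + P_LA + P_R`.  Proteome-constrained FVA with an
objective reaction held at 0/50/90/99% of its optimum yields effective
flux envelopes per reaction; the Spearman correlation ρ between a
reaction's maximum flux and its enzyme-entity abundance across samples
classifies it as abundance-dependent (ρ ≥ 0.8),
abundance-correlated (0.5 ≤ ρ < 0.8) or abundance-independent
(ρ < 0.5; spontaneous and blocked reactions always independent).

## Worked example

```python
from pcgem.synthetic_data import (make_toy_gem, make_protein_tables,
                                  sample_donor_proteomes, SyntheticSpec,
                                  OBJECTIVE_REACTION)
from pcgem.pc_build import build_pc_model
from pcgem.proteome_fit import prepare_samples, normalize_to_budget, build_context_model
from pcgem.pc_analysis import analyze_samples

model = make_toy_gem(seed=1)                      # 16-reaction toy RBC-like network
proteins, complexes = make_protein_tables(model, seed=1)
pcm = build_pc_model(model, proteins, complexes)  # the Model object
print(pcm.construction_summary())

spec = SyntheticSpec(n_donors=10, seed=1)         # 10 donors x 3 storage days
raw, hb_table, metadata, truth = sample_donor_proteomes(proteins, spec)
samples = prepare_samples(raw, hb_table)

fit = pcm.fit(normalize_to_budget(samples[0], pcm))   # Results object
print(fit.summary())
ctx = build_context_model(pcm, fit)
print(f"pump max flux: {ctx.optimize(OBJECTIVE_REACTION).objective_value:.3f} mmol/gDW/hr")

res = analyze_samples(pcm, samples, OBJECTIVE_REACTION, fractions=(0.0,))
print(res.classification.loc[["NAKPUMP", "LACT", "FAS", "ATPM"]])
```

prints

```
{'n_proteins': 12, 'n_complexes': 10, 'n_enzyme_entities': 9, 'n_nonzero_rate_constants': 11}
Proteome fit
========================================
status:            optimal
objective (wSSE):  1.08533e-15
proteins:          12
measured:          10
missing:           2
...
pump max flux: 1.752 mmol/gDW/hr
                  rho         classification          category         flag
reaction_id
NAKPUMP      1.000000    abundance-dependent         Transport
LACT         0.590997   abundance-correlated         Transport
FAS               NaN  abundance-independent  Lipid metabolism      blocked
ATPM              NaN  abundance-independent             Other  spontaneous
```

The fit objective near zero says the budget-scaled data were feasible
and reproduced essentially exactly.  The sodium/potassium pump's
maximum flux (1.752 mmol/gDW/hr) is set by its enzyme capacity, not by
substrate supply — and across donors it tracks the pump subunit's
abundance perfectly (ρ = 1.0, abundance-dependent), while the
structurally blocked fatty-acid branch and the spontaneous ATP drain
are abundance-independent by rule.

The same pipeline is scriptable from the shell:

```sh
pcgem simulate --n-donors 10 --seed 1 --out-dir study
pcgem build --model study/toy_gem.xml --proteins study/proteins.tsv \
            --complexes study/complexes.tsv --out pc.xml
pcgem classify --pc-model pc.xml --proteome study/abundance.csv \
               --hb study/hb.csv --objective NAKPUMP --out-dir out
```

Other subcommands: `pcgem model validate|fva|blocked|balance`,
`pcgem connectivity`, `pcgem fit`, `pcgem metadata-corr`.

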