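# Methods

This note documents the model `pcgem` implements, the parameters that
matter, the synthetic study generator, and the numerical choices, so
that results can be interpreted within the assumptions they rest on.

## The proteome-constrained formulation

The base object is a genome-scale metabolic model at steady state:
`S v = 0`, `v_lb ≤ v ≤ v_ub`, fluxes in mmol/gDW/hr, with "infinite"
bounds encoded as ±1000 (configurable).  On top of it, four groups of
variables are added, all realized as pseudo-metabolites and
pseudo-reactions so the augmented model remains an ordinary SBML/LP
object (identifier prefixes `prot_`, `cplx_`/`CPLXFM_`,
`enz_`/`ENZFM_`/`ENZRM_`, `pcpool_`/`PCPOOL_*`, `PROTDL_`/`PROTRL_`):

1. **Proteins.**  Each gene product `j` has abundance `p_j ≥ 0`
   (nmol/gDW) — the flux of its dilution reaction — and molar mass
   `w_j` (mg/nmol) computed from its amino-acid sequence
   (average-isotope residue masses plus one water; Biopython).  The
   dilution reaction consumes `w_j` mg of a budget pool per nmol.
2. **Budgets.**  Mass pools partition the proteome: a total pool
   capped at 1000 mg/gDW (100% of dry weight), a hemoglobin pool with
   default bounds [900, 1000] and a low-abundance pool with [0, 100].
   Pool fluxes *are* the budget variables, so
   `P_HB + P_LA (+ P_R) = Σ_j p_j w_j` holds as an exact metabolite
   balance, not as a numerically-enforced side constraint.
3. **Complexes.**  `x_l ≥ 0` (nmol/gDW) consume their subunits
   according to integer copy numbers (`C x ≤ p`; the inequality comes
   from a free sink on each protein species).  Complexes derive from
   the reaction's gene-protein-reaction rule — each OR-branch is an
   isozyme complex, AND-conjuncts are subunits with default copy
   number 1 — unless a curated complex table overrides them.
4. **Enzyme entities and capacity.**  Every catalyzed reaction `i`
   has `e_i = e_i^fwd + e_i^rev = Σ_l r_l x_l` over its member
   complexes, and its flux obeys
   `−k_i^rev e_i^rev ≤ v_i ≤ k_i^fwd e_i^fwd`.
   Enzyme-level constants are uniform at `k_avg`; complex-level
   constants are estimated from complex molar mass,
   `k_l = k_avg (M_l/M̄)^{3/4}` with `M̄` the mean complex mass, so
   `r_l = (M_l/M̄)^{3/4}`.  The ¾ exponent reflects the scaling of
   solvent-accessible surface area with mass; its sign and value are
   configurable (`BudgetConfig.sasa_exponent`).  Reverse constants
   are zero for irreversible reactions (`v_lb ≥ 0`).

**Units.**  Amounts are nmol/gDW and fluxes mmol/gDW/hr, so the
capacity coupling carries an explicit factor 1e−6 mmol/nmol
(`pc_build.NMOL_TO_MMOL`).  With `k_avg = 65 s⁻¹ = 2.34e5 hr⁻¹`, one
nmol/gDW of enzyme supports up to 0.234 mmol/gDW/hr of flux.

Assumptions inherited from the formulation: the metabolic proteome
cannot exceed a fixed mass fraction of dry weight; one gene ↔ one
protein with sequence-derived mass; a complex keeps one rate constant
regardless of which reaction it catalyzes; enzyme abundance caps flux
but never forces it; all protein species live in a single model
compartment.  A complex catalyzing several reactions contributes its
*full* abundance to each of their enzyme entities — capacities are
upper bounds, so no partitioning is imposed.

## Proteome fitting

A measured sample is first put through the *total protein approach*:
intensities are scaled by the donor's hemoglobin concentration
(missing concentrations imputed with the donor mean; donors lacking
any of the three storage days are dropped).  Mapped onto model
proteins, hemoglobin entries are rescaled so their mass equals the
hemoglobin cap and the remaining measured proteins so their mass
equals the low-abundance cap; during fitting those caps are 950 and
50 mg/gDW, which makes the scaled data itself satisfy the budget
constraints and puts data and model variables on the same scale.
Missing values stay missing (NaN); zeros are data.

The fit minimizes `Σ_j c_j (p_j − p_j^data)²` over *all* model
variables subject to every model constraint, with inverse-abundance
weights (`1/p^data` for positive measurements, 1 for zeros — which
penalizes expressing unobserved proteins — and 0 for missing values).
No metabolic flux objective is imposed during fitting: the printed
problem contains none, and adding one would bias `p′` toward the
chosen objective.  The QP is convex and sparse and is solved with
OSQP directly on the matrices extracted from the model.

## Context-specific models and the slack

From `p′`, a context model replaces the per-protein bounds with the
slack formulation (slack `s`, default 0.03):

- relaxation budget `P_R` with `0 ≤ P_R ≤ P_R,ub = s Σ_j p′_j w_j`,
  entering the total-mass balance (`P_total = P_HB + P_LA + P_R`);
- measured proteins: `(1−s) p′_j ≤ p_j ≤ p′_j + s P_R,ub / w_j`;
- unmeasured proteins: `0 ≤ p_j ≤ s P_R,ub / w_j`.

Structurally, the part of an abundance above the group-pool dilution
flows through a per-protein relaxation dilution (`PROTRL_`) fed by the
`PCPOOL_R` pool, so "relaxation budget actually used" is simply the
flux of `PCPOOL_R` — which is what the calibration minimizes.  The
relaxation pool models real uncertainty: absence of a low-abundance
protein from a proteomic run is often technical, so unmeasured
proteins get a small mass allowance instead of a hard zero.

**Calibration.**  For representative (mean/median) fits and an
increasing slack grid, each context model is solved
lexicographically — maximize the target reaction's flux (e.g. the
Na⁺/K⁺-ATPase), then minimize utilized `P_R` with the optimum fixed
to within 1e−9.  The chosen slack is the smallest grid value at which
every calibration model reaches ≥99% of its objective at the largest
slack ("plateau"; the fraction is configurable).  If the objective is
zero everywhere the largest slack is returned with a warning.  On
strongly capacity-limited models the objective may rise across the
whole grid; the rule then returns the largest grid value, which the
diagnostic table makes visible.

## PC-FVA, classification, representative model

Proteome-constrained FVA constrains the objective reaction to
fractions {0, 0.5, 0.9, 0.99} of its maximum and records per-reaction
(min, max) at each fraction; the *effective* envelope is the union
(so the effective maximum equals the fraction-0 maximum — running
classification with `fractions=(0,)` is an exact shortcut).  Enzyme
abundance ranges optimize `e^fwd + e^rev` per reaction.  Across
samples, Spearman ρ between maximum flux and maximum attainable
enzyme abundance classifies reactions with thresholds 0.8/0.5;
spontaneous (no gene rule) and blocked reactions are
abundance-independent by definition, and undefined correlations
(constant vectors, <2 complete pairs) fall back to independent with a
flag.  Metadata columns are Spearman-correlated against the same
per-sample quantities and ordered by agglomerative clustering
(Euclidean distance on correlation vectors, average linkage —
the linkage is configurable since the choice is conventional).
A representative model folds many contexts into one by taking
componentwise (min of effective minima, max of effective maxima) for
reaction bounds and likewise for protein abundance ranges.

## The synthetic study generator

`synthetic_data` emulates the statistical shape of a stored-blood
donor proteomics study, scaled to desk size:

- a 16-reaction, mass- and charge-balanced toy network (glucose →
  lactate backbone with a lumped glycolysis, a glycogen branch, an
  ATP-coupled Na⁺/K⁺ pump as objective, leaks, a spontaneous ATP
  drain, and a fatty-acid branch with no precursor producer — a
  structurally blocked pathway);
- one hemoglobin-flagged pool protein carrying ~95% of protein mass
  (per-donor fraction jittered with σ = 0.003), log-normal donor
  variation on the low-abundance proteins (σ = 0.35), a mild
  per-day storage drift on one enzyme, 15% missing-at-random entries
  (never hemoglobin or the planted enzyme), 15 decoy proteins not in
  the model, and donors × {10, 23, 42} days;
- a **planted limiting enzyme**: the pump's large α-subunit is given
  a baseline of 0.3% of low-abundance mass, placing the pump's
  catalytic capacity strictly below (a) the flux the metabolic
  network alone would allow and (b) the slack-relaxation floor of any
  co-essential enzyme.  That last point is the delicate part of the
  design: the relaxation grants every unmeasured protein the same
  *mass* (`s·P_R,ub`), so its capacity floor scales as
  `M_l^{3/4}/(w_j·copies)` — a heavy, multi-copy subunit has a *low*
  floor relative to light monomeric enzymes, which is why the planted
  subunit is a 1800-residue protein while the co-essential enzymes
  are ~400–500 residues and ~10× more abundant.  Network fluxes are
  kept small (glucose uptake 2 mmol/gDW/hr) so a missing co-enzyme's
  relaxation floor still exceeds the pump's needs;
- metadata columns generated as sign·(donor log-abundance of a linked
  enzyme) + Gaussian noise (σ = 0.25), plus an unlinked column.

What passing recovery tests shows — and what it does not: the
pipeline provably recovers a planted, genuinely binding enzyme and
planted monotone metadata links under log-normal variation and random
missingness.  It does not show robustness to peptide-level
mass-spectrometry effects, batch drift, abundance-dependent
missingness (a mode exists for such robustness tests), isozyme load
ambiguity, or errors in the rate-constant scaling — on real data the
`k_l` estimates are the dominant unknown.

## Numerical choices

- LP: GLPK through COBRApy/optlang (deterministic; single process).
  Blocked-reaction tolerance 1e−6 mmol/gDW/hr.
- QP: OSQP with `eps_abs = eps_rel = 1e−12`, polishing on, and
  **heuristic scaling disabled** — the problem is already in
  consistent units and OSQP's Ruiz scaling can stall on the
  pool/dilution structure; a fallback ladder (1e−9 unscaled, then
  1e−7 scaled) guards rare non-convergence, and infinite bounds are
  boxed at ±1e9 to preclude spurious unboundedness certificates.
  Feasible targets are reproduced with objective ≲1e−14.
- Mass balance: elemental residual tolerance 1e−9; generic R-groups
  are an inert pseudo-element, and reactions whose only residual is
  in R (lipid pooling) are excluded from balance percentages, as are
  boundary pseudo-reactions.
- Reference-line comparison for connectivity distributions is done in
  (rank, log10 degree) space, because degree distributions are
  heavy-tailed; points within 1e−12 of the line count as "on" it.
- Ties in Spearman ranks use average ranks (scipy); the dependent
  class boundary is ρ ≥ 0.8 — the half-open reading consistent with
  the adjacent correlated interval [0.5, 0.8).
- Problem sizes: tests and the acceptance script use the toy network
  (16 reactions, ~75 variables augmented) with 50-donor × 3-day
  panels and five replicate studies — sizes chosen so the whole
  acceptance pipeline is a desk-scale computation (~1 minute) while
  keeping ≥150 QP fits and several thousand LP solves per study.

## Known limitations

- Rate constants are mass-scaled estimates around one `k_avg`; no
  reconciliation against measured kinetics is attempted.
- Complexes shared between reactions are not load-partitioned
  (upper-bound semantics), so summed capacities can exceed what the
  shared complex could sustain simultaneously.
- The QP fixes no flux objective; if a context's biology implies an
  active demand during fitting, that knowledge is not used.
- Gene-level protein pooling means splice variants and
  compartment-specific forms are indistinguishable.
- `read_pc_model` reconstructs the base model by stripping prefixed
  pseudo-objects; models whose native identifiers collide with the
  reserved prefixes are not supported.
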