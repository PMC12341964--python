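# Methods

This note documents the models and procedures implemented in `cytodyn`, the
parameters that matter, the numerical choices made where the method leaves
room, and what the synthetic test bed does and does not establish.

## Data model

The universal input is a long-format table with one record per (subject,
condition, tissue, mediator): concentration ≥ 0, pg/mg protein in solid
tissue, pg/mL in plasma (the unit is a function of the tissue). Conditions
are `baseline` (no surgery, 0 h), `sham` / `vagotomy` (sacrifice 168 h = 7 d
post surgery) and `sham_lps` / `vagotomy_lps` (LPS at 168 h, sacrifice at
171 h). Encoding the timepoint in hours lets both velocity denominators —
7 days and 3 hours — derive from one field. The panel is the 20-mediator
cytokine/chemokine set (GM-CSF, IFNγ, IL-1α/β, IL-2/4/5/6/10/12p40/12p70/13/
17A, IP-10, KC, MCP-1, MIP-1α, MIG, VEGF, TNF).

## Outlier filtering

Within each (tissue, mediator, condition) group, mean and SD are computed
once on the original group and every value with |x − mean| > k·SD (default
k = 2) is removed in a single pass — no re-computation after removal.
Choices the rule itself leaves open:

* **Sample SD** (n−1 denominator): standard for small-n biological groups.
* **Strict inequality**: a value exactly at the cut is kept.
* **Groups with < 3 values pass through** — their SD is too unstable to
  support any outlier decision.
* Grouping is per condition (not pooled across arms); the grouping keys are
  an argument of the implementation, so pooled filtering is one call away.

## Group statistics

One-way ANOVA with Tukey's HSD (α = 0.05) compares a mediator across
conditions within a tissue; statsmodels' `pairwise_tukeyhsd` supplies the
studentized-range adjustment. The network gate is a **two-sided Welch**
t-test of each arm against baseline at p < 0.05: Welch rather than pooled
because the design is strongly unbalanced (baseline n = 5 vs surgery arms
n ≈ 28) with no reason to assume equal variances; two-sided because the
direction of change is not known a priori. When both groups have zero
variance and equal means, p is reported as 1 (no evidence of change) rather
than NaN. No multiplicity correction is applied across the mediator × tissue
grid — the Tukey adjustment acts only within one comparison family.

## DyNA

Per tissue and condition, nodes are the gated mediators and Pearson r is
computed for every pair on **pairwise-complete** subjects (outlier removal
deletes different subjects per mediator), requiring ≥ 3 complete pairs. An
edge exists when |r| > 0.90 (strict); |r| ≥ 0.95 is flagged `strong`. Both
thresholds are per-run parameters — the LPS arms are conventionally analysed
at |r| > 0.95. Negative correlations are retained as signed edges (the
qualification uses |r|): positive edges are read as propagation, negative as
concerted downregulation. Fewer than two gated mediators gives a valid empty
network.

**Complexity** is edge density as a percentage, 100·2E/(N(N−1)) for N ≥ 2
and 0 otherwise. The score is only ever used comparatively, and any metric
strictly monotone in E at fixed N preserves every such comparison; the
callable is pluggable for sensitivity analyses.

## Velocities and ranked profiles

υ_A = (median_to − median_from)/Δt on the outlier-filtered table, with the
sample median (even n → mean of the central pair). The 7-day contrasts are
baseline → sham and baseline → vagotomy (per day); the LPS contrasts use the
**matching surgery arm** as reference — sham → sham+LPS and vagotomy →
vagotomy+LPS over 3 hours (per hour).

Ranking one mediator's velocities across tissues ascending (ties broken
alphabetically by tissue) yields a profile that is typically sigmoidal. The
visually described "threshold" is operationalised two ways, and both are
reported without privileging either:

* **zero-crossing index** — position of the first non-negative velocity
  (None if all negative, 0 if all non-negative);
* **logistic midpoint** — a least-squares 4-parameter logistic
  `lower + (upper−lower)/(1+exp(−slope·(rank−midpoint)))` over rank index,
  fitted with `scipy.optimize.curve_fit`, requiring ≥ 4 tissues; flat
  profiles and non-convergent fits return None rather than a degenerate
  parameter set.

## DyHyp

Per tissue, mediators with positive velocity form one pool and mediators
with negative velocity another; a mediator qualifies as a **positive edge**
when its velocity > mean + 1·SD of the positive pool, and as a **negative
edge** when it is < mean − 1·SD of the negative pool. Numerical choices:

* Sample SD, consistent with the outlier filter (population SD available via
  `sd_mode="population"`).
* Strict inequalities; zero-velocity mediators belong to neither pool (the
  increasing/decreasing partition excludes "unchanged").
* A pool with < 2 members yields no edges of that sign — one value has no SD.
* Pooling is **per tissue** (selection is independent per tissue); the
  mean/SD are never shared across tissues. The text of the rule could also be
  read as one global pool; per-tissue is the default because selection is
  explicitly tissue-independent, and the alternative is a one-line change at
  the call site for sensitivity analysis.

One hyperedge per (mediator, sign) then covers every tissue where it
qualified — including singletons, since a hyperedge may surround one node.
The per-node **edge distribution** (membership counts split by sign) is the
hypergraph's complexity readout; no density normalisation is applied because
the node (tissue) count is fixed by the design. The sum of negative counts
is the pro-resolution complexity. DyNA networks are attached to hypergraph
nodes as insets in the combined export.

## Chemokine switch

A deterministic discrete model over nodes IFNγ, IP-10, MCP-1, IL-6 (and MIG
in the full variant) with levels {0, 1, 2} = absent / non-zero / elevated
and a constant binary injury input. A **ternary** alphabet is required
because the rules distinguish "non-zero expression" from "elevated" —
binary cannot express both. Each node has a {0, 2} target given the current
state:

* IFNγ → 2 iff injury = 0 **and** MCP-1 = 0 (the conjunctive parse of
  "in the absence of severe injury or MCP-1"; the disjunctive reading is a
  config switch);
* IP-10 → 0 if a suppressor is active, else 2 if IFNγ > 0 or IP-10 > 0
  (induction + self-feedback), else 0;
* MCP-1 → 2 iff MCP-1 > 0 and IP-10 < 2 (self-sustaining until elevated
  IP-10 shuts it down);
* IL-6 → 0 if IL-6 = 2 and IP-10 = 2 (elevated IP-10 suppresses elevated
  IL-6), else 2 if an inducer is active, else 0.

In the **full** variant the suppressor/inducer sets are {MCP-1, MIG}; MIG
itself is driven by IFNγ (MIG is "monokine induced by gamma interferon" —
but this input rule is a reconstruction, isolated in one constant, with no
claim of fidelity to the original trauma model). In the **MIG-KO** variant
(the in-silico vagotomy) MIG and every rule term reading it are removed, so
both sets reduce to {MCP-1}. Suppression dominates induction wherever a rule
states both. Injury defaults to 0, matching the 7-day post-surgical setting.

The update is synchronous and **gradual**: each node moves one level toward
its target per step, giving graded multi-step trajectories; an instant-jump
mode is available. Stochasticity enters only through uniform random initial
levels; ensembles (default 1,000 runs × 10 steps) report per-node mean and
variance per step, and `exact_expectation` averages over all 3^n initial
states (81 KO / 243 full) as the exact reference. The transition diagram
maps each state to its unique successor (out-degree 1); its state count,
transition count and fixed points quantify structural complexity, and the
KO diagram is a strict reduction of the full one.

With these rules the full variant drives IP-10 to 0 from every initial state
(MIG or MCP-1 is eventually active on every path) while the KO variant
retains a high-IP-10 attractor and a large oscillatory IP-10 variance. The
sign of the sham-vs-KO IP-10 difference therefore depends on the
reconstructed MIG input rule; the package reports it but deliberately
asserts nothing about its direction — the robust, asserted findings are the
structural reduction and the variance contrast.

## Synthetic cohorts

The generator emulates the study's statistical shape: baseline n = 5,
surgery arms n = 28, LPS arms n = 10; 20 mediators; 7 compartments plus both
brain halves in the LPS arms; log-normal concentrations (cytokine panels are
right-skewed and non-negative) with log-scale SD σ = 0.2 by default; planted
median shifts between arms (ground-truth velocities follow exactly from the
configured medians, because the log-normal median is exp(μ)); correlation
planted through one latent factor per block, giving pairwise log-scale
correlation ρ² between block members; outliers injected multiplicatively
(default rate 1%, scale 8×). The default fold changes plant the hallmark
structure: most mediators rising ~2× after surgery, MIG falling after
vagotomy everywhere, spleen IP-10/MIG rising after sham but falling after
vagotomy, and a few mediators declining in kidney/gut/lung so both hyperedge
sign classes are populated.

What it does **not** emulate: mechanistic inflammation biology, between-
mediator correlation induced by shared regulation (beyond the planted
blocks), heavy-tailed assay noise, censoring at detection limits, or
plate/batch effects. Passing the recovery tests therefore shows the pipeline
correctly extracts the structure it is defined to extract — not that the
biology of any real cohort will satisfy the thresholds.

## Validation strategy and problem sizes

Every stage is checked against an independent route: a brute-force
mean ± k·SD scan for the outlier filter (1,000 random groups), an all-pairs
Pearson scan for DyNA (200 fixtures), a direct re-statement of the one-SD
rule for DyHyp (500 velocity tables), textbook sums-of-squares /
Welch–Satterthwaite / studentized-range formulas for the statistics (100
fixtures, agreement to 1e-8), and exact enumeration for the Boolean
ensembles (3 SE at 1,000 runs). Planted-structure recovery uses 100 seeds
per scenario with cohorts trimmed to the tissues and mediators the scenario
needs; the full study-shaped cohort (~12,000 records) is exercised by the
pipeline tests and the acceptance script. These sizes keep the whole suite
around a minute on one CPU while leaving the Monte-Carlo margins (≥ 90/100
recovery; 3 SE) comfortably wide.

## Known limitations

* Pearson r on concentrations is sensitive to residual outliers; the filter
  runs first, but a rank correlation variant is not implemented.
* The logistic threshold read-out fits over rank index, not a physical axis;
  its midpoint is comparable between profiles only at equal tissue counts.
* The Boolean model is a single abstracted compartment; multi-compartment
  extension is out of scope.
* Hyperedge counts carry no statistical inference (no null model for "one SD
  beyond the pool mean" under resampling).
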