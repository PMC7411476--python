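# Methods

This note documents the models, rules and numerical choices behind
`cytonet`, and what its synthetic benchmarks do and do not demonstrate.

## Data model

A panel is an animal × cytokine matrix of concentrations (pg/mL) with a
group ∈ {control, CFA, CFA+MA} and timepoint ∈ {day1, day7, day15} label
per animal. The default roster is the 24-analyte rat panel (23 multiplex
analytes + CRP), classed as chemokines (MCP-1, CXCL1, MIP-1α, MIP-3α,
RANTES), innate cytokines (IL-1α, IL-1β, IL-6, TNF-α, IL-7, IL-18, CRP),
adaptive cytokines (IL-2, IL-4, IL-5, IL-10, IL-12, IL-13, IL-17, IFN-γ)
and growth factors (GM-CSF, G-CSF, M-CSF, VEGF). Names are normalised
through a fixed alias table (IL-1β ≡ IL-1b ≡ IL-1beta; the bare "MIP-3"
maps to MIP-3α) because mixed spellings are endemic in vendor sheets.

Concentrations must be finite and ≥ 0; values below the kit detection
floor (default 0.01 pg/mL, configurable) are stored at the floor rather
than as missing, which keeps correlations and fold changes total at the
cost of a small attenuation when censoring is heavy. Every stratum used
by an analysis must contain ≥ 3 animals.

The cell–cytokine map (secretors and targets per cytokine over a fixed
roster) is an *input artifact*, not a hard-coded table. The shipped
default covers the 24 cytokines over a 28-cell roster (8 innate immune,
11 adaptive immune, 9 body cell types) and was compiled editorially from
standard immunology references; it is a defensible but not unique
curation, and users with their own curation should override it. Pairs
absent from the map contribute zero to communication scores.

## Statistics track

Per cytokine × timepoint, three groups are compared:

1. **Normality**: Shapiro–Wilk per group at α = 0.05 (a standard small-n
   choice; groups of zero range cannot be tested and pass). If any group
   rejects, a single natural-log transform is attempted and normality
   re-checked; if a group still rejects, the nonparametric branch is
   used. One documented, deterministic transform attempt was preferred
   over an open-ended menu of "commonly accepted" transforms.
2. **Homogeneity** (parametric branch): median-centred Levene at
   α = 0.05, a robust default. Homogeneous → one-way ANOVA with Fisher
   LSD pairwise t-tests on the pooled mean-square error (df = N − k).
   Heterogeneous → Welch ANOVA (via pingouin) with Dunnett T3 pairwise
   comparisons: Welch t statistics with Satterthwaite df, referenced to
   the studentized maximum modulus through the independence
   approximation p = 1 − (2F_t(|t|; ν) − 1)^m, m = 3 comparisons. Exact
   SMM quantiles are not available in the installed stack; the
   approximation is slightly conservative, which only matters in the
   ~5% of null cases that reach this branch.
3. **Nonparametric branch**: Kruskal–Wallis omnibus + pairwise
   Mann–Whitney U, the conventional analogue of ANOVA + LSD.

Pairwise p-values are reported unconditionally (not gated on the
omnibus), matching conventional SPSS-style post-hoc output. The key rule
is a single contrast — treated vs model (CFA+MA vs CFA) — at
per-cytokine α = 0.05 with no multiplicity correction by default;
Benjamini–Hochberg within timepoint is available behind `bh_correct`.
Identical groups give F = 0/0; this is reported as p = 1 (no evidence
against the null). Every verdict (normality per branch, homogeneity p,
test used) is recorded in `method_trail`.

A caveat verified by the tests: evidence monotonicity (a larger fold on
the treated group ⇒ smaller contrast p) holds *within* a test branch;
scaling a group also scales its variance, so the Levene verdict can
switch the post-hoc family between folds, and p-values are only
comparable branch-wise.

## Correlation-network track

Pearson r is computed on raw concentrations (the conventional choice for
this procedure; a log-scale option exists behind `log_scale_corr`).
Zero-variance cytokines yield *undefined* correlations, excluded from
the network rather than treated as r = 0, because a constant series
carries no association evidence. The filter keeps pairs with
|r| ∈ [threshold, 1], threshold 0.8, closed boundary. `network_str` sums
|r| over retained edges, each unordered pair once.

Node metrics on the thresholded graph: degree; strength = Σ|r| over
incident edges (so strength ≤ degree); unweighted local clustering
2T_v/(k_v(k_v−1)), zero when degree < 2 (computed with networkx, and
cross-checked in the tests against an independent adjacency-matrix
oracle using diag(A³)). Clustering is deliberately computed on edge
presence only — a weighted variant is not part of the procedure being
implemented.

Rankings: degree descending, strength descending, clustering
**ascending**. The ascending direction is intentional: in this screening
tradition a low clustering coefficient marks a node whose neighbours are
otherwise unconnected, i.e. a bridge the network depends on. Degree-0
nodes are excluded from all rankings. Top-3 sets are tie-extended (every
node tying the third value is included; extensions are logged) — the
deterministic, conservative resolution of an otherwise unspecified
boundary. Key set = nodes in ≥ 2 top-3 sets; with fewer than three
connected nodes, all connected nodes are reported as candidates with a
logged warning.

## CCC track

The contrast statistic is p′ᵢ = (mean_cond(i) − mean_ref(i)) /
max(mean_ref(i), floor): the signed relative mean change of cytokine i
between the condition and reference strata (floor 0.01 pg/mL guards
near-zero references). This operationalisation reproduces the structural
properties the aggregates rely on — Ecc can be negative, cell_sd takes
absolute values, and the score grows with stronger stimulation — and is
pluggable (`mode="difference"` uses the raw mean difference instead).
Default contrasts are model-vs-control (CFA vs control) and
treated-vs-model (CFA+MA vs CFA) at each timepoint; arbitrary stratum
pairs are accepted.

E is filled over all ordered roster pairs, vectorised as
E = S·diag(p′)·Fᵀ with S, F the 0/1 membership matrices. Autocrine
(diagonal) terms are included by default — a secretor that is also a
target communicates with itself — with `include_diagonal=False`
available for sensitivity analysis. By construction
Σ row sums = Σ column sums = network_sd exactly; the test suite asserts
this to 1e−9 on random instances. Key cells are argmaxes of the signed
secretory and target densities and of cell_sd; ties are logged and
broken by roster order.

## Synthetic generator

Strata are drawn from a multivariate log-normal: log-scale covariance
σ²R with σ² = ln(1 + cv²) (default cv 0.3, typical of multiplex panel
replicates) and R block-diagonal with user-specified within-block
correlations (|r| ≤ 0.99); the per-cytokine *median* is
baseline_mean × fold. Log-normal marginals keep concentrations strictly
positive and right-skewed, as immunoassay data are; correlation targets
live on the log scale, where the dependence is linear (the implied
raw-scale Pearson r is slightly attenuated, e.g. ≈ 0.896 for a 0.9
log-scale target at cv 0.3 — still comfortably above the 0.8 filter).
Baseline means are order-of-magnitude plausible for rat tissue
homogenates; absolute magnitudes carry no information in any track that
matters here (statistics and correlations are scale-free; p′ is
relative).

If user blocks assemble into a non-PSD matrix, eigenvalues are clipped
at 1e−8 and the matrix rescaled to unit diagonal (nearest-PSD repair).
One master seed drives everything; each stratum uses a substream keyed
by (seed, group index, timepoint index), so adding a stratum never
perturbs the others and identical configs give byte-identical tables.

The study-like default configuration plants the reported *directions*:
MCP-1 (×3), CXCL1 (×2.5), IL-1β (×2.5), IL-6 (×3) elevated and GM-CSF
halved in the treated condition at day 1; MCP-1, CXCL1, MIP-3α, IL-1β,
IL-6 elevated (×2–2.5) at day 15; no day-7 effects; and two co-regulation
blocks (chemokine MCP-1/CXCL1/MIP-3α and innate IL-1β/IL-6/TNF-α) at
r = 0.85. Fold sizes are the generator's own choices within the 2–4×
range such treatment effects typically span. The generator does not
model timepoint-specific variance inflation (real day-7 data were
reportedly noisier), inter-animal covariance beyond the blocks, assay
censoring patterns, or plate/batch effects — so passing benchmarks show
the *procedure* behaves as specified on data satisfying its assumptions,
not that any particular biological dataset does.

## Benchmarks and their problem sizes

The acceptance suite and `scripts/acceptance.py` compute, at sizes
chosen to give tight Monte-Carlo error at desk scale: null calibration
over 1000 three-group experiments (key rate 0.05 ± 0.02 at α = 0.05;
binomial SE ≈ 0.007); power against a planted 3-fold IL-6 elevation at
n = 7 per group over 100 seeds (≥ 0.90); recovery of a planted
3-cytokine r = 0.9 block as exactly the top-3 degree nodes at n = 50
over 200 seeds (≥ 0.95); the macrophage key-secretory rate under the
study-like configuration over 100 seeds (≥ 0.90, mirroring the pattern
this procedure reports on real data without asserting unpublished
numbers); threshold monotonicity of network_str; and brute-force oracle
agreement (independent textbook Pearson formula; adjacency-matrix node
metrics including every non-isomorphic graph on ≤ 7 nodes; double-loop
CCC enumeration) to 1e−9.

## Known limitations

- The per-cytokine α with no multiplicity correction reproduces the
  screening convention faithfully but inflates family-wise error
  (expect ≈ 1.2 false keys per 24-cytokine timepoint under the null);
  `bh_correct` exists for users who want control.
- Dunnett T3 p-values use the SMM independence approximation (above).
- The shipped cell–cytokine map is one defensible curation; key-cell
  calls can change under a different curation, which is why the map is
  an input.
- Pearson r on raw concentrations at n = 6–7 is fragile to outliers;
  the |r| ≥ 0.8 filter partly compensates, and the log-scale flag is
  the robust alternative.
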