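# Methods

## The comparative model

All statistics assume host traits evolve on a known rooted phylogeny with
branch lengths in (arbitrary-scale) time. Under Brownian motion a
continuous trait across the n tips is multivariate normal with covariance
σ²V, where V[i, j] is the root-to-MRCA path length shared by tips i and j
and V[i, i] is the depth of tip i. This V is the error covariance of every
regression in the package.

**PGLS.** The GLS estimator β̂ = (XᵀV⁻¹X)⁻¹XᵀV⁻¹y is computed via the
Cholesky factor of V (never an explicit inverse; the whitened-space
formulation is algebraically identical to the naive inverse and the test
suite holds the PIC equivalence to 1e-8). The log-likelihood profiles σ²
out as σ̂² = eᵀV⁻¹e/n (ML). Standard errors and t-tests use the unbiased
residual variance eᵀV⁻¹e/(n − p) with n − p degrees of freedom, the usual
GLS practice; the ML σ̂² enters only the likelihood and hence AICc. R² is
1 − RSS/RSS₀ computed in the whitened space against the intercept-only GLS
fit under the same V, so it is comparable across transforms.

**Pagel transforms.** Three one-parameter relaxations of Brownian motion:

| parameter | action | bounds | value 1 |
|---|---|---|---|
| λ | multiplies off-diagonal entries of V (phylogenetic signal) | [0, 1] | identity |
| δ | raises node depths (equivalently all entries of V) to a power, rescaled to preserve total depth (time-dependent rates) | (0, 3] | identity |
| κ | raises each branch length to a power (κ = 0 is the punctuational limit: every branch counts 1) | [0, 3] | identity |

Because every entry of V is a node depth, the δ transform is implemented
elementwise on V (power then rescale by T^(1−δ) with T the maximum depth);
this is exact for any tree, not only ultrametric ones. κ genuinely needs
the branch decomposition, so V is rebuilt as Σ_e l_e^κ m_e m_eᵀ from
precomputed per-edge tip masks. Exactly one parameter is free per model;
it is estimated by maximizing the profile likelihood on a 64-point grid
followed by bounded scalar refinement (xatol 1e-6) — robust to the
multimodality that plagues pure local optimizers near λ boundaries.

**Model selection.** The four candidates (no transform, +λ, +δ, +κ)
compete by AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1), k = regression
coefficients + σ² + any free transform. Ties break toward fewer
parameters, then the fixed model. Fits with n ≤ k + 1 are valid but carry
no AICc; selecting among them raises an error rather than silently
comparing undefined scores. FDR control is Benjamini–Hochberg within an
explicit analysis family (e.g., all alpha-diversity × compartment tests
against disease form one family).

**Contrasts and ancestral states.** Felsenstein's pruning recursion gives
n − 1 standardized contrasts on a bifurcating tree (polytomies are first
resolved with zero-length branches; PGLS needs no resolution since V
handles polytomies natively). ML ancestral states under Brownian motion
minimize Σ_edges (x_child − x_parent)²/l — a weighted tree-Laplacian
solve whose root component equals the precision-weighted (GLS) mean of the
tips; per-node variances scale the inverse precision by the tip-data ML
σ̂². Zero-length branches are floored at 1e-9 to keep the system
nonsingular.

## Path analysis

For a candidate DAG over the trait set, the d-separation basis takes each
non-adjacent pair, ordered by a fixed lexicographic topological sort, and
emits the claim X ⟂ Y | pa(X) ∪ pa(Y); the later variable is the
regression response and the claim's p-value is the t-test on the X
coefficient under the chosen evolutionary model (Brownian: fixed V;
Pagel's λ: profile-ML). Fisher's C = −2 Σ ln pᵢ is χ²(2k) under the model;
zero p-values are floored at machine epsilon with a warning. Models are
ranked by CICc = C + 2qn/(n − 1 − q) with q = #edges + #nodes (one
coefficient per edge plus one intercept per node — the package's stated
convention, since published analyses differ on counting intercepts).
Traits are z-scored (sample SD) across genera before fitting so edge
coefficients are standardized; complete cases are taken over the union of
DAG nodes so n is identical for every candidate. Averaging over models
within ΔCICc ≤ 2 (configurable) is conditional by default — an edge is
averaged only over the top models that contain it — with full averaging
(absent edge = 0) behind a flag.

The default candidate set is all 25 DAGs on the three labeled nodes. A
curated 14-model preset is also shipped — the six fully-connected triads,
the four two-edge models with the focal microbe adjacent to both host
traits, and the four mediation chains with the focal microbe at an
endpoint — an approximation to "all biologically plausible pathways"
around a focal symbiont, in which the focal node is never isolated.

## Trait construction choices

- Dominance/abundance summaries are means of per-sample proportions, not
  pooled counts, matching the "most abundant on average across samples"
  definition; ties break lexicographically for determinism.
- Rarefied richness is the analytic hypergeometric expectation
  E[S] = Σᵢ[1 − C(N−Nᵢ, d)/C(N, d)] — deterministic and seed-free; samples
  shallower than the depth are excluded and reported. Gini is computed
  over nonzero abundances by default; a zero-padding flag reproduces the
  convention in which absent taxa count as members.
- Weighted UniFrac is the normalized form
  Σ_b l_b|p_A − p_B| / Σ_b l_b(p_A + p_B); beta traits are sample-level
  PCoA scores (classical MDS; negative-eigenvalue axes excluded) averaged
  within host genus × compartment. The aggregation order (ordinate, then
  average) is a design choice; averaging distances first would be equally
  defensible.
- Disease: one colony with ≥ 1 disease counts once as diseased; disease
  categories are assumed to partition diseased colonies. The ≥ 100-colony
  filter is strict ("fewer than 100" drops n = 99, keeps n = 100).
  Prevalence enters models untransformed by default; a logit option (with
  Haldane–Anscombe correction) is available.
- Genus names are harmonized (case-fold, trim) before joins; unmatched
  genera are reported, never silently dropped. Missing data are handled
  complete-case per test, with n reported per fit.

## The synthetic generator

`make_mini_gcmp` emulates the statistical structure of a multi-genus coral
microbiome survey. Defaults (the study conditions for all recovery tests):
40 host genera, 3 species per genus on a unit-height Yule tree with one
random representative retained per genus; latent traits E (symbiont load),
D (disease liability), G (growth potential) generated by standardized
structural equations E→D (β = 0.8), E→G (β = 0.6) with Brownian noise
(SDs 1.0/0.6/0.8); 8 samples per genus × compartment (about the per-group
replication of a ~1400-sample, 40-genus, 3-compartment survey) with
Dirichlet-multinomial counts (concentration 40, 150 background ASVs + 4
focal ASVs, log-normal library sizes, median ≈ 4900 reads); the focal
relative-abundance target is logistic(−2.5 + 0.9·E) ≈ 8% mean in tissue,
attenuated ×0.5 in mucus and ×0.25 in skeleton; disease prevalence is
logistic(−2.2 + 0.8·D) ≈ 10% mean, surveyed by 2 binomial sources with
log-normal sizes (median ≈ 665 colonies each, wide enough that a minority
of genera fail the 100-colony filter); growth records number 3–10 per
genus (so some genera fail the ≥ 5-replicate rule) at 10 ± 4 mm/yr between
genera, 1.5 mm/yr within. A single master seed fans out to independent,
CRC-derived streams per component, so tree, traits, counts, and surveys
are individually reproducible.

What the generator does *not* emulate: sequence-level noise (chimeras,
contamination), environmental covariates, spatial survey structure,
uneven genus representation, or real taxonomies. Passing recovery tests
therefore demonstrates the statistical machinery under the assumed
generative model — not robustness to the messiness of field data.

Measurement noise makes the observed traits (estimated abundances,
finite-survey prevalences) imperfect proxies of the latent traits, so
conditional-independence claims hold only approximately end to end; the
planted DAG is expected within ΔCICc ≤ 2 of the best model in roughly
three-quarters of studies at these settings, and the planted association
is essentially always detected.

## Problem sizes and numerical conventions

Calibration checks run at: 500 replicates (slope-CI coverage, 64 tips),
1000 (null p uniformity), 200 per λ value (recovery bias), 500 (Fisher's C
type-I), 50 end-to-end synthetic studies, 100 random trees (PIC/PGLS
equivalence) — sizes chosen so the full battery completes in about two
minutes while keeping Monte-Carlo error well inside the tested bands.
Newick serialization writes 12 significant digits; round-trips preserve
branch lengths to 1e-9 relative. All-zero count vectors are rejected as
undefined rather than returning a conventional value. Degenerate contrasts
(sister branches both zero-length) return contrast 0 with equal weights.

## Known limitations

- Ornstein–Uhlenbeck and multi-rate models are out of scope; λ/δ/κ are
  the only deviations from Brownian motion.
- The d-separation basis is the pairwise union-conditioning form, which is
  a valid basis for DAGs of this size but is not the minimal basis for
  every larger graph.
- CICc's parameter count q includes intercepts; comparisons against
  conventions that count only edges will differ by a constant within a
  fixed node set (and so rarely change rankings).
- PCoA axes are sign-indeterminate; only gaps and magnitudes are
  meaningful.
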