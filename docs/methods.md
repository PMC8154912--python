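# Methods

## Distortion as expected mutational cost

For a taxon with sense-codon usage P(c_i), the expected distortion on one
amino-acid property scale is

    D = Σ_{i,j} P(c_i) · q(c_i, c_j) · d(aa_i, aa_j),

the codon-usage-weighted mean physicochemical cost per translated symbol of
one round of background mutation.  The three ingredients and the choices
behind them:

**Distortion matrix d.**  d(aa_i, aa_j) = (v_i − v_j)² on a property scale
v, and 0 whenever aa_i = aa_j (synonymous changes are free).  The squared
form is the default because it matches the cost matrices classically used in
genetic-code error-minimization work; an absolute-difference form is
available (`d_form="absolute"`).  Four scales ship as TSV fixtures with
provenance headers: Woese's polar requirement, Kyte–Doolittle hydropathy,
Grantham's molecular volume, and the free-amino-acid isoelectric point.  D
is therefore in squared scale-native units, which is why the four responses
live on very different numeric scales (D_vol ~ 10³, D_pol ~ 10⁰) — the PGLS
stage reports standardized coefficients for cross-response comparison.
Users can supply any 2-column (amino acid, value) TSV as a custom scale.

**Mutation kernel q.**  A two-parameter model over codons in the spirit of
Kimura's 2-parameter nucleotide model: only single-nucleotide codon changes
have positive probability; conditional on an event the transition class has
probability κ/(1+κ) and the transversion class 1/(1+κ); within a class the
event is uniform over the codon's 3 transition neighbors (1/3 each) or 6
transversion neighbors (1/6 each); the diagonal is q(c,c) = 1 − μ.  The
uniform within-class distribution is the minimal assumption — no positional
or context bias — and reproduces the identity "transition share of mutation
mass = κ/(1+κ)", i.e. ≈ 71 % at the default κ = 2.5.  Every row sums to 1
exactly (checked to 1e-12 in tests).

**μ convention.**  D is linear in μ off the diagonal, so for between-taxon
comparison μ is a pure scale factor; the default μ = 1 reports distortion
per mutation event.  μ stays configurable for anyone wanting an absolute
per-replication scale.

**Stop codons.**  Stops carry no property value, so P(c_i) is defined over
the 61 sense codons (stop counts are retained in profiles for diagnostics
but renormalized away).  Mutations *into* stops default to cost 0
(`stop_policy="exclude"`), the common convention in this literature; a
worst-case nonsense penalty (`stop_policy="max_penalty"`, charging the
maximum entry of the distortion matrix) is available, and the policy is
recorded in all output metadata.

**Numerics.**  The whole panel is one matrix product: a per-codon expected
cost vector per scale (61 × 4 matrix), left-multiplied by usage rows.  The
vectorized path is tested against a deliberately naive triple-loop oracle
(independent codon table from Biopython, per-pair kernel entries recomputed
from neighbor enumeration) at 1e-12 *relative* tolerance — relative rather
than absolute because D_vol has magnitude ~10³, where float64 carries only
~4e-13 of absolute precision per operation.

## Codon usage extraction

CDS records are read in frame from position 1 (no ORF detection); records
whose length is not a multiple of 3 are skipped whole and counted; codons
containing ambiguous symbols are dropped individually; U maps to T on read.
GC-content is (G+C)/(A+C+G+T) over the retained coding sequence — coding
region, not whole genome, since codon usage is the object of study.

## PGLS stage

Brownian covariance: V_ij is the depth of the most recent common ancestor
of tips i and j (V_ii = root-to-tip distance), computed by one postorder
traversal; polytomies are handled naturally and the root edge is not
counted.  The fit whitens by the Cholesky factor of V and solves the normal
equations; reported statistics are

- σ̂² = eᵀV⁻¹e / (n − k) (k = predictors + intercept),
- SE from σ̂²(XᵀV⁻¹X)⁻¹, t = β̂/SE, two-sided Student-t p-values on n − k df,
- R² = 1 − eᵀV⁻¹e / (y − μ̂₀1)ᵀV⁻¹(y − μ̂₀1) with μ̂₀ the GLS intercept-only
  mean — the generalized R² convention of the comparative-methods packages,
  which differs from the whitened-centered-TSS R² some GLS implementations
  report,
- F = (R²/df1)/((1−R²)/df2), df1 = 4 predictors, df2 = n − 5.

Standardized coefficients come from refitting after an unweighted Z-transform
of response and predictors; they are invariant to affine rescaling of any
variable (°C vs tenths of °C) and share the raw coefficients' signs.

Only the plain Brownian correlation is implemented; branch-length transforms
(e.g. Pagel's λ) are a deliberate extension point, not implemented, since
the plain Brownian model is the analysis baseline.  If V is singular
(duplicate tips, zero-length cherries) one round of diagonal jitter
1e-10·trace(V)/n is added; anything still singular is treated as a data
error.  p-values carry no multiple-testing correction — the four responses
are modelled separately by design.  Collinearity is detected by rank of the
whitened design.

## Synthetic data generator

The generator exists to make every stage — and the end-to-end chain —
testable with known ground truth.  What it emulates, and what it does not:

- **Tree**: pure-birth (Yule) growth at rate 1 to n tips, plus one final
  exponential waiting time so all pendant edges are positive.  It emulates a
  clade sampled at the present (ultrametric), not the heterogeneous,
  non-clock 16S trees of real studies.
- **Environment and GC**: Brownian motion from the baseline
  [GC = 0.5, T = 30 °C, NaCl = 2.5 w/V %, pH = 7] with rates chosen to give
  tip spreads of roughly ±15 °C, ±2 w/V %, ±0.8 pH and ±0.08 GC on a 64-tip
  tree — mesophile-to-moderate-extremophile ranges.  Values are clamped to
  [0, 110] °C, [0, 30] w/V %, [4, 10] pH and [0.25, 0.75] GC (clamping is
  logged); real trait evolution is of course neither Brownian nor unbounded.
- **Codon usage**: base distribution = product of per-position nucleotide
  probabilities with P(G) = P(C) = gc/2, making GC a genuine causal driver;
  a log-linear tilt along per-scale "local distortion" axes (standardized
  vector of each sense codon's expected mutational cost at κ = 2.5) plants
  environmental effects of controllable size and known sign; Dirichlet-
  multinomial sampling (concentration 5000, 60 000 codons/taxon by default:
  200 genes × 300 codons) mimics gene-to-gene heterogeneity.  Default effect
  sizes put model R² near 0.5–0.65 at n = 64 — moderate, detectable signal —
  and planted-sign recovery near 97 %.  Real codon usage additionally
  reflects tRNA pools, expression weighting, amino-acid composition
  constraints and horizontal transfer, none of which are modelled; passing
  tests therefore validate the *pipeline's statistics*, not any biological
  claim.

One scenario seed expands into independent substreams (tree, traits,
per-taxon usage, FASTA emission), so each stage is reproducible on its own
and everything is byte-identical per seed.

## Validation design

- Exact oracles: kernel entries and D against naive dict-based
  recomputation; GLS against Cholesky-whitened OLS and against
  `statsmodels.GLS` (β/SE/t/p) on random trees; OLS equivalence on star
  phylogenies at 1e-10.
- Distribution-level checks: Brownian tip variance/covariance against
  rate × (shared) depth over 500 replicates; type-I error of each PGLS
  coefficient within a 99.9 % binomial band around 5 % over 200 null
  replicates with correctly specified Brownian responses.
- Study-level checks: planted-effect sign recovery ≥ 90 % over 100
  64-taxon replicates; sign stability of significant coefficients across
  κ ∈ {2.5, 5, 7.5, 10}.  Replicate counts (200/100/5) keep the default
  suite under a minute while leaving the binomial assertions well-powered.

## Known limitations

- Per-taxon distortion values have no published reference table to compare
  against, so correctness rests on the oracle/property tests above.
- The generator's planted axes are computed at κ = 2.5; at very different κ
  the planted effects attenuate (they remain directionally stable across
  the tested 2.5–10 range).
- Expression-weighted usage, core-gene filtering and non-standard genetic
  codes are out of scope (the `GeneticCode` container is pluggable).
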