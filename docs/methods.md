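# Methods

## The question the package operationalises

Machine-learning scoring functions (SFs) for protein–ligand binding
affinity are sometimes dismissed on the grounds that their test-set
accuracy comes entirely from training complexes whose proteins are highly
similar to the test proteins. The canonical way to probe this is a
similarity-cutoff benchmark: starting from a fixed, diverse test set and a
train × test protein-similarity matrix, one builds *nested* training sets
— at cutoff `c`, a training complex is kept only if **no** test protein is
more similar than `c` to it — and tracks each SF's test-set Pearson
correlation (Rp) against the number of training samples. A classical
linear SF that saturates early and a flexible regressor that keeps
climbing produce very different curves under this design.

`sfbench` implements that pipeline end to end: descriptor extraction from
3D structures, nested-set construction, repeated stochastic training,
learning-curve assembly, and a synthetic-complex generator so the whole
analysis runs at desk scale without any external structure database.

## Scoring functions and descriptors

Four SFs form the default roster, differing only in feature set and
regressor:

| name        | features                 | regressor |
|-------------|--------------------------|-----------|
| X-Score     | 4 energy-like terms      | MLR       |
| RF::X-Score | same 4 terms             | RF        |
| RF-Score    | 36 contact counts        | RF        |
| RF-Score-v3 | 36 counts + 6 Vina terms | RF        |

- **Contact counts (`rf_v1`, 36 features).** For each ordered pair of a
  ligand element in {C, N, O, F, P, S, Cl, Br, I} and a protein element in
  {C, N, O, S}: the number of intermolecular heavy-atom pairs with centre
  distance ≤ 12 Å (closed boundary; ties count). Feature order is
  ligand-major: (C,C), (C,N), (C,O), (C,S), (N,C), …
- **Empirical terms (`vina6`, 6 features).** Evaluated on the surface
  distance `d = r − R_i − R_j` (van der Waals radii: C 1.9, N 1.8, O 1.7,
  S 2.0, P 2.1, F 1.5, Cl 1.8, Br 2.0, I 2.2, default 1.8 Å) for every
  pair with `r ≤ 8 Å`: `gauss1 = exp(−(d/0.5)²)`,
  `gauss2 = exp(−((d−3)/2)²)`, `repulsion = d²·1[d<0]`, a hydrophobic
  ramp 1→0 on `d ∈ [0.5, 1.5]` restricted to C–C pairs, a hydrogen-bond
  ramp 1→0 on `d ∈ [−0.7, 0]` restricted to N/O–N/O pairs, and the ligand
  rotatable-bond count `Nrot`. "Hydrophobic atom" is simplified to
  "carbon"; no polar-neighbour refinement.
- **Classical surrogate (`xscore4`, 4 features).** An 8-4 potential
  `(d0/r)^8 − 2(d0/r)^4` (per-pair clamp [−1, 10], `d0 = R_i + R_j`,
  pairs within 8 Å), an N/O–N/O contact count at 3.5 Å, a C–C contact
  count at 4.5 Å, and `Nrot`. This is an explicitly approximate stand-in
  with the *shape* of a classical empirical SF; it reproduces no published
  parametrisation, and no claim is made that its absolute Rp matches any
  published scoring function.
- **Rotatable bonds.** Acyclic (bridge) single bonds whose endpoints both
  have ≥ 2 heavy-atom neighbours. No amide or conjugation perception —
  the SDF bond order field is taken at face value — so the count is an
  approximation of docking-style torsion counts.

Hydrogens are stripped on read everywhere (all schemes are heavy-atom
based); waters are always excluded; non-water HETATM cofactors are
excluded unless requested, and metals outside {C,N,O,S} contribute only to
the radius-based terms (with the default radius when unknown), never to
the contact counts, whose element sets are closed.

## Regressors and the repeat protocol

- **MLR**: ordinary least squares with intercept via SVD (numpy lstsq).
  Deterministic to the bit; minimum-norm with a warning on rank-deficient
  designs (the 4-feature scheme is occasionally collinear on tiny nested
  sets).
- **RF**: random forest regression (scikit-learn), 500 trees, ⌈p/3⌉
  candidate features per split, unlimited depth, bootstrap samples of size
  n — the common RF-regression defaults; no tuning, matching how the
  original contact-count SFs were trained.
- **Repeats**: each (SF, cutoff) cell is trained `n_repeats = 10` times;
  repeat `r` uses seed `base_seed + r`. MLR is fitted once and replicated
  (all repeats are provably identical). The curve table stores all
  per-repeat Rp values plus mean, median, min, max and range; plots
  default to the mean, and both mean and median are emitted because both
  central tendencies are in common use.

Cells whose nested set retains < 2 complexes are flagged untrainable and
reported with null Rp rather than dropped or errored, so schedules may
safely extend below the smallest informative cutoff.

## The synthetic benchmark

The generator produces, from one master seed, everything the analysis
consumes, with the statistical couplings the design relies on. Defaults
mirror the canonical benchmark's shape: 65 protein families each
contributing 3 test representatives (195 test complexes) and 1105 training
complexes spread over those families plus 15 train-only families with a
Zipf-like size skew.

- **Geometry** is schematic: ligands are self-avoiding chains (1.5 Å
  steps, ≥ 1.2 Å clearance, 8–26 atoms), pocket atoms sit on a 3.5–11 Å
  shell around the ligand centroid (30–70 atoms, ≥ 2 Å clearance). This
  guarantees nonzero contact counts but is not a physical conformation:
  no torsional preferences, no secondary structure, no packing. Element
  compositions are family-biased (Dirichlet draws around C-dominant
  priors), which is what makes family identity visible to the contact
  descriptors.
- **Similarity**: same-family train–test entries are uniform on
  [0.75, 0.98]; different-family entries are uniform on [0.05, u_i] with a
  per-training-complex ceiling u_i = 0.05 + 0.40·Beta(4, 1). The ceiling
  is essential: with ~200 independent test columns, iid between-family
  draws would put every row maximum at the top of the range and all small
  cutoffs would retain nothing, whereas real row maxima vary because each
  training protein has its own distance to the test set. A cutoff of 0.5
  (between the two ranges) retains exactly the train-only-family
  complexes, which the tests exploit as a bookkeeping oracle.
- **Affinities** are computed from each complex's own 42 descriptors,
  standardized over the cohort (`z`; `z'` additionally shifted to be
  nonnegative). The linear rule is `y = b + Σ w_k z_k + offset + ε`; the
  nonlinear rule is

      y = b + Σ_counts w_k·log(1+z'_k)          (36 contact counts)
            + Σ_terms  w_k·z_k                  (6 empirical terms)
            + 1.2·z'₁z'₂/(1+z'₂)                (count interaction)
            + 0.45·((z_g1² − 1) + (z_g2² − 1))  (steric quadratics)
            + 0.5·z_g1·z_rep                    (steric cross term)
            + offset + tilt·log(1+z'_counts) + ε

  with intercept b = 6.2 pKd and noise ε ~ N(0, 0.8²) pKd. Count-block
  weights are drawn once per benchmark (sd 0.22); the term-block weights
  are *fixed*, physically signed constants (0.45 × [1.2, 0.6, −0.9, 0.9,
  1.0, −0.7] for gauss1, gauss2, repulsion, hydrophobic, hbond, Nrot) —
  favorable contact terms, unfavorable repulsion, a torsion penalty — so
  the classical scoring function always has a stable linear component to
  capture, rather than one whose magnitude rides on a 6-dimensional
  random draw. The non-monotone part (quadratics and cross term) sits
  deliberately on the composition-blind *steric* terms, whose
  distributions every protein family samples alike: it is globally
  learnable by a flexible regressor through the 4-term features but
  inexpressible by a linear fit, which is what separates the forest from
  MLR on identical features without breaking MLR's plateau.

  Each family adds an offset N(0, 0.7²) **and** a slope perturbation
  ("tilt", sd 0.15) on the count-block weights. The tilt models
  target-specific structure–activity relationships: families differ in
  *how* contacts translate into affinity, not just by a constant, which
  is why same-family training data is genuinely more valuable than an
  equal amount of dissimilar data — the mechanism the cutoff analysis
  probes. Family size preferences are confined to the central band of
  the size ranges with wide within-family jitter, so the steric features
  are properties of individual complexes rather than of families; this
  keeps the realized test-set signal variance stable across master seeds
  (65 family-level draws would otherwise dominate it) and keeps the
  steric nonlinearity family-neutral.
- **Determinism**: all draws flow through named substreams
  (families, offsets, allocation, geometry, similarity, weights, noise) of
  one `SeedSequence`, so the benchmark is a pure function of
  (config, master seed) and components can be regenerated independently.
  Coordinates are quantised to 0.001 Å through their printed decimal so a
  PDB/SDF export re-read is bit-lossless; an exported benchmark rerun in
  files mode reproduces the synthetic-mode outputs byte for byte.

Constants were fixed once while shaping the generator at a ~450-complex
pilot scale, aiming for full-data forest Rp in a realistic 0.70–0.85 band
and a classical plateau well below it; they are configuration, not fitted
quantities.

### What passing tests do and do not show

The generator reproduces the *statistical couplings* of the real
benchmark — family-clustered similarity, family-visible descriptors,
partially nonlinear descriptor→affinity mapping, small stochastic repeat
variability — so qualitative conclusions (forests keep learning, the
linear model saturates, same features + better regressor = better SF)
transfer. It does not reproduce physical binding, real descriptor
distributions, or any published Rp value; absolute numbers from synthetic
runs characterise the generator, not any real dataset.

## Numerical and design choices

- Closed boundary everywhere a threshold appears (`≤ cutoff`): a tie
  convention must be fixed, and "within" reads as closed. A training
  complex tied exactly at the similarity cutoff is retained.
- Pair terms are computed vectorised but arithmetic-identical to the
  brute-force double loop (same squared-distance comparison, same
  summation order); the oracle tests assert equality at counts exactly
  and at 1e−12 on real terms.
- Pearson Rp on a constant vector raises rather than returning 0; a
  degenerate prediction is a result the caller must see.
- `pandas.read_csv` runs with `float_precision="round_trip"` on every
  numeric ingest path; the default parser is not exactly rounding and
  broke byte-level mode equivalence.
- Rp is reported to 3 decimals; partition percentages to 1 decimal.
- Learning-curve plots put `n_train`, never the cutoff, on the x axis —
  the scientifically meaningful axis for a learning curve.
- Seeds: repeat seeds are `base_seed + r`; sklearn forests receive the
  seed modulo 2³¹.

## Problem sizes used by the checks

The acceptance-style checks run the complete default benchmark
(1105/195, 13 cutoffs, 4 SFs, 10 repeats — about 400 forest fits), which
dominates the suite's runtime; unit and property tests use compact
benchmarks (90–450 complexes) with the same structure. The
linear-generator ceiling check uses 2000 training and 500 test complexes
so that both the least-squares estimation bias (which scales like p/n
with 42 collinear features) and the sampling error of Rp (~(1−r²)/√n)
sit comfortably inside its 0.02 tolerance.

## Known limitations

- The X-Score-like extractor is a surrogate; comparisons against
  published X-Score term values are out of scope by design.
- Rotatable-bond counting has no amide/conjugation perception.
- The Vina-term constants follow the published functional forms but the
  implementation is not pose-differentiable and ignores intramolecular
  terms; it is a descriptor extractor, not a docking score.
- Whether the sixth appended empirical term should be `Nrot` or a
  seventh pair term is ambiguous in the literature lineage; here `Nrot`
  is the sixth feature, which matters when comparing against externally
  computed descriptor files.
- The similarity matrix is an opaque input: the package never computes
  protein sequence or structural similarity from structures.
- No statistical significance testing: the repeat-range/gap-ratio
  comparison is the intended inference device, and the deterministic
  comparator has no stochastic scale to test against.
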