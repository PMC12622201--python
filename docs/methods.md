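# Methods

## Facet persistence

Given points in R³ and a metric, the Vietoris–Rips filtration includes a
simplex when all pairwise distances among its vertices are finite and at
most the filtration parameter; we use the **edge-length (diameter)
convention**, so a simplex's filtration value is its largest pairwise
distance and vertices enter at 0. Every reference barcode event in the
package (hexagon edges at 2, cuboid diagonals at √2) reads directly in
edge lengths under this convention, which is why it was chosen over the
radius scale; alpha filtration values are converted from the common
squared-circumradius convention to radii (Å) so the two complexes share
one filtration axis.

For each simplex σ, the facet bar is [filt(σ), min over cofacets τ ⊃ σ,
|τ| = |σ|+1, of filt(τ)). Bars with persistence ≤ 1e-9·f_max are
dropped — the robust floating-point form of excluding zero-length bars.
Bars with no cofacet by the ceiling are reported with death = f_max and
an `open_ended` flag, matching the convention of drawing such bars to
the plot limit. Bars are sorted by (dim, birth, death, vertices) so
serialization is deterministic.

Scoring dim-d deaths requires (d+1)-simplices to exist in the built
complex or be provably absent. The complex records a
`structural_max_dim` when higher dimensions cannot occur at any
threshold: n points cap the dimension at n−1, and a two-group modified
metric forbids triangles outright (any three vertices contain a
same-group pair at infinite distance). Requesting bars in a dimension
that is neither built one level above nor structurally capped raises an
error naming the needed dimension, rather than silently reporting
censored deaths.

## Alpha complexes and degeneracy

The alpha complex is the Delaunay triangulation filtered by smallest
empty circumscribing ball: a face whose circumball contains no other
input point (Gabriel) enters at its own circumradius; every other face
enters with its first Delaunay cofacet. We compute Gabriel-ness exactly
by testing all input points against each face's circumsphere (with a
1e-9 relative tolerance for on-sphere ties); at the neighborhood sizes
this package targets (tens to a few hundred atoms per element pair) the
quadratic check is cheap and removes the ordering subtleties of
propagation-based algorithms. Degenerate inputs reduce dimension instead
of failing: exact duplicates are collapsed with a warning, coplanar
input is triangulated in its plane, collinear input becomes a path of
consecutive segments (each entering at half its length), and a single
point is a lone vertex. Qhull failures are retried with joggling and
only then reported as an explicit error.

## Mutation featurization

- **Atom sets.** Heavy atoms of standard residues only; hydrogens,
  waters and heteroatoms excluded; alternate locations resolved to the
  highest-occupancy conformer. Mutation-site atoms are the residue at
  (chain, position); neighborhood atoms are all atoms of other residues
  within r = 16 Å of any site atom. A missing site residue is an
  explicit error (not a silent skip); an empty neighborhood is a
  warning. Elements outside {C, N, O} (S, Se) are excluded from the
  element-specific subsets.
- **Grid.** The nominal 1–12 Å range with a 0.4 Å step does not land on
  12; the grid is fixed at 28 points 1.0–11.8 Å with the ceiling at
  12 Å, making vectors reproducible bit-for-bit.
- **Per-grid facet statistic** = number of bars alive at t (birth ≤ t <
  death, open-ended bars alive through the ceiling). Counting alive bars
  rather than cumulative births/deaths keeps the statistic equal to the
  number of facet ideals present in the complex at that filtration
  value, which is the quantity the decomposition defines.
- **Alpha atom set per element pair** = the union of the pair's SITE and
  NEIGHBORHOOD atoms under the standard metric — the union preserves
  pair specificity while giving the alpha complex a full point set. The
  nine pairs are treated as ordered (site element, neighborhood element)
  for both complex kinds.
- **DIFF = WT − MT** by convention. Empty element-pair subclouds produce
  zero blocks so vector length is constant across samples. Auxiliary
  rows (SASA, secondary structure, transformer embeddings) are consumed
  precomputed and appended verbatim; the package does not compute them.
- Mutant structures are inputs; the package does not build rotamers.

## Learners

CATree fits `repetitions` scikit-learn gradient-boosted tree models with
consecutive seeds and averages predictions (class probabilities for
classification). Defaults: 20000 estimators, depth 7, min split 3,
learning rate 0.05, sqrt feature sampling, 0.4 subsample, 10
repetitions. CANet is a plain fully connected scikit-learn MLP — six
hidden layers of 15000 neurons, Adam, learning rate 1e-3, 200 epochs,
batch 32 for regression and 50 for the three-class solubility task; no
dropout or normalization layers. `test_scale()` constructors shrink only
capacity knobs (200 estimators / 3 repetitions; width 32) and leave the
per-tree and optimizer settings at the defaults — these are the configs
the test suite uses, chosen so the full suite runs in well under a
minute of training time.

Metrics: binary → MCC, AUC, F1, balanced accuracy (AUC omitted with a
warning when y_true has one class); regression → Pearson correlation
and RMSE; three-class → normalized accuracy implemented as
macro-averaged recall (robust to the strong class imbalance of
solubility data) and the generalized squared correlation GC² = χ²(confusion
matrix) / (N·(K−1)), which is 1 for a perfect diagonal and 0 for a
constant predictor. The GC² normalization is provisional: several χ²
normalizations exist and the macro-recall + χ²/(N·(K−1)) pair was chosen
for interpretability at the boundary cases. Class encodings:
pathogenic = 1 / benign = 0; solubility decrease/increase/unchanged =
0/1/2; ΔΔG signs are taken as provided by the dataset.

## Synthetic data

The generators produce every input the tests need. The hexagon (side 2)
and the 1 × 1 × 1.5 cuboid are the two reference configurations whose
barcode events are known in closed form; the hexagon is the unique
highly symmetric six-point configuration consistent with all of them
(dim-0 deaths at 2, triangles by 2√3 ≈ 3.46 < 3.5), and its manifest
records that reconstruction. Toy wild-type/mutant PDB pairs place
residues on an extended backbone (Cα spacing 3.8 Å) with idealized
offsets and seeded side-chain growth; heavy-atom composition per residue
matches the standard amino-acid tables, and the two files differ only in
the site-residue records. These fixtures are geometric stand-ins — no
rotamer realism, no energy minimization — so passing tests establish the
pipeline's combinatorial and geometric correctness and its invariances
(atom order, rigid motion), not predictive performance on real proteins.

The planted-signal check labels 500 points of a 40-dim Gaussian feature
cloud by the sign-majority of three planted coordinates, flips 10% of
the *training* labels, and scores held-out balanced accuracy against the
clean rule, averaged over 5 fixed seeds. The sign-majority form is
axis-aligned with balanced classes — the kind of structure a tree
ensemble is expected to recover — so the check isolates "does the
pipeline learn planted structure" from the orthogonal question of
approximating oblique decision boundaries.

## Numerical choices

- Filtration ties within 1e-9 relative tolerance are simultaneous; the
  same tolerance defines the zero-persistence cutoff (×f_max) and the
  on-sphere test in the Gabriel check.
- Vertex indices are 0-based internally; residue numbers stay 1-based
  as in PDB files.
- Facet deaths are found via cofacet lookup on sorted vertex tuples,
  never by materializing facet lists per filtration step, so cost is
  linear in the number of simplices.
- Problem sizes in the suite (clouds of n ≤ 10 for oracle comparisons at
  50 seeds, 6–9 residue toy proteins, test-scale learners) were chosen
  so every property is exercised end-to-end while the whole suite stays
  interactive; the brute-force oracle is exponential in n by design and
  is the reason for the n ≤ 10 cap.

## Known limitations

- Facet barcodes on large complexes (hundreds of points at 12 Å) are
  combinatorially heavy; use f-vector curves there, as the library's own
  CLI does with `--format fvector`.
- Persistent graded Betti numbers and homology are out of scope.
- Weighted alpha complexes, periodic boundaries and Čech complexes are
  not implemented.
- Benchmark figures on curated real mutation datasets require
  external structures, licensed mutant-building software, transformer
  embeddings and full-scale training, and are not reproduced here; the
  property suite plus the reference-configuration barcodes are the
  supported validation surface.
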