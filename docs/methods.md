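# Methods

## Scope and model

complexkit implements the computational layer that surrounds a protein
complex structure predictor built from monomer-trained networks: input
feature assembly from unpaired alignments, interface-aware confidence
scoring of predicted models, interface clash detection, and the statistics
of protein–protein interaction screening. Network inference, MSA generation
from sequence databases, template search and model relaxation are outside
the package; it starts from the files those steps produce.

## Complex feature assembly

Given monomer MSAs with lengths L_i, depths D_i and stoichiometries S_i,
the complex MSA is a gap-initialized matrix of Σ L_i·S_i columns and
Σ D_i·S_i rows. Blocks are laid out monomers-outer, copies-inner; each copy
of each monomer fills its own row-block × column-block with the monomer
alignment. Homo-oligomer copies are treated as if they were distinct
sequences and receive duplicated blocks. The consequences are deliberate:
no alignment row spans two chains, so no species pairing or orthology
mapping is ever needed, and pre-computed monomer features can be reused
across every complex that contains the monomer.

Two details were genuinely open and are resolved as follows:

* **Concatenated query row.** The literal block layout produces no single
  row spelling the full complex query. `make_complex_msa` emits the literal
  layout by default (its shape invariants are stated in those terms), while
  the pipeline-level `assemble_complex_features` prepends a concatenated
  query row by default (`include_query_row`), because downstream feature
  pipelines conventionally require row 0 to be the query. Either behaviour
  is one flag away.
* **Residue-index semantics.** The offset b·(p−1) (default b = 200, hard
  floor b > 32, the relative positional-encoding reach) is applied to the
  *running concatenated* index, so chains stay internally consecutive and
  only the inter-chain gap matters. Applying it to restarted per-chain
  indices would be equally valid for the network; the running form was
  chosen because indices are sequentially increased and it keeps the vector
  strictly increasing. b ≤ 32 warns and refuses rather than silently
  producing features a network would misread.

Monomer templates are re-indexed by adding the owning copy's column start;
one re-indexed template is emitted per copy. Cross-chain templates are
never constructed. All network-specific payloads (coordinates, one-hot
tensors, deletion matrices) pass through opaquely; only positions are
transformed. Domain cropping slices match columns of the full-length
monomer features (ranges half-open, ascending, non-overlapping); insertion
records are discarded at that point since complex features are defined over
match columns.

## Interface detection and the clash indicator

A residue–residue contact exists when any heavy atom of a residue on one
chain is within 4.5 Å — inclusive — of any heavy atom of a residue on
another chain. This single contact rule feeds everything downstream: the
interface set 𝓘 of the confidence metrics and the counts N_iRes, N_iCnt of
the clash indicator χ = N_iRes/N_iCnt. One definition, one source of truth.
Contacts are counted once per residue pair, not per atom pair. Waters and
hetero residues are excluded by default (flag to include). Detection uses a
k-d tree over all heavy atoms; the tests require bit-exact agreement with a
quadratic all-pairs scan, plus invariance under rigid motion and chain
reordering, and monotonicity in the cutoff.

χ is bounded in (0, 2]: each contact introduces at most two new interface
residues (the bound is attained by any matching-style interface — e.g. one
contact between two residues), and interpenetrating interfaces drive it
toward 0 (m residues per chain all mutually in contact give χ = 2/m). With
no contacts χ is undefined and reported NA — and `flag_clashing` then
returns False, since there is no interface to judge. χ uses only distances,
so it applies to un-relaxed models and serves as a cheap pre-filter;
thresholds near 0.6 (the low end of the typical experimental range
0.6–1.2) are sensible.

## Confidence metrics

piTM restricts a TM-score-style confidence to the interface residues,
substituting the predicted aligned error ⟨e_ij⟩ for real distances and the
max over interface reference frames i for the optimal superposition. The
PAE is read row = reference frame, column = assessed residue, and is
allowed to be asymmetric. The diagonal term j = i is included in the inner
sum (e_ii ≈ 0 in practice); the choice is isolated behind one line.

The interface-score S computes a piTM-like term per chain p and sums over
chains, with chain p's reference frame restricted to interface residues
*not* on p. A chain with no interface residues contributes 0; so does a
chain whose complement is empty (guarded, though unreachable when contacts
span two chains). The normalization d0(I) uses the *global* interface size
I in every chain term, exactly as the defining formula is printed; a
per-chain I_p normalization would be a different metric. d0 is piecewise —
1.24·(I−15)^(1/3) − 1.8 for I ≥ 22, else 0.02·I — and intentionally
discontinuous at I = 22 (0.42 vs ≈ 0.5720); both branch values are pinned
in tests. Empty interface ⇒ piTM = S = 0 by convention: no interface, no
confidence to report.

Sums are evaluated with numpy's pairwise-summation reductions; at interface
sizes up to a few thousand residues this is comfortably within the 1e−9
equality tolerance the tests use, and exhaustive brute-force enumeration
must agree to 1e−12 on interfaces of ≤ 12 residues.

Ranking of candidate models is by interface-score descending, ties broken
by piTM then model id, giving a total deterministic order. The
interface-score threshold 0.45 is exposed as the confident-interaction
preset; 0.55/0.45 are recorded as reference operating points
(high-precision / high-recall) from all-against-all screening, purely as
documentation.

## Screening evaluation

Predicted-positive is score ≥ threshold (boundary included). Precision and
MCC are reported NA — never 0 — when their denominators vanish. ROC/PR
curves sweep the distinct score values descending with ties grouped;
AUC_0.1 step-integrates TPR dFPR on [0, 0.1] using the left endpoint of
each segment (no trapezoids) and divides by 0.1, so a random classifier
scores ≈ 0.05 and a perfect one 1.0. The C-filter computes monomer
appearance counts on the full positive set, then keeps pairs whose monomers
each appear ≤ C times; C unset (∞) disables filtering. The filtered subset
is monotone in C by construction.

## Synthetic fixtures: what they emulate and what they do not

The fixture module generates every input the pipeline needs, with ground
truth derived from the construction itself rather than from the code under
test:

* **Toy complexes** — ladder (k isolated rungs: k contacts, 2k residues,
  χ = 2), interpenetrating (m×m all-pairs contacts: χ = 2/m), separated
  (empty interface), helix-pair (ideal α-helix backbones; expected contacts
  from the generator's own all-pairs scan) and perturbed-ladder (Gaussian
  jitter, same scan). Residues are poly-glycine with a single heavy atom
  unless the geometry needs a backbone, so distances are trivially
  controlled. Nothing about side-chain packing, secondary-structure realism
  or atom chemistry is emulated: passing tests demonstrate the counting,
  geometry and scoring machinery, not predictive accuracy on real models.
* **PAE surfaces** — zero, constant, two-block (intra/inter chain) and
  noisy (independent |N(μ, σ)| entries, hence asymmetric), clipped at
  31.75 Å to mirror the value ceiling of typical network PAE output (a
  realism constant, configurable). Real PAE matrices are smooth and
  structured; these are not, which is irrelevant for metric correctness.
* **MSAs** — uniform random queries over the 20-letter alphabet with
  per-column mutation (10%) and gap (5%) rates in homolog rows: enough to
  exercise shapes and block placement, with no phylogenetic structure.
* **Screening tables** — positives N(separation, 1) vs negatives N(0, 1),
  at the roughly 1:10 positive:negative ratios screening studies use
  (17:544, 701:6849 layouts); separation 0 is the random-classifier null
  used to verify the AUC_0.1 = 0.05 floor.

Everything is deterministic given its seed.

## Numerical and degenerate-input choices

Inclusive comparisons at boundaries (contact cutoff, score threshold);
alternate locations resolved to highest occupancy, ties first-seen;
PAE-to-model residue matching positional (file order), not author
numbering; both common PAE JSON dialects (bare matrix, object keyed
`predicted_aligned_error`) accepted and bitwise-equivalent; single-chain
models score piTM = S = 0 with χ = NA rather than erroring. Equality
tolerances: 1e−12 against enumeration oracles, 1e−9 elsewhere.

## Problem sizes

Test and acceptance runs use desk-scale inputs: toy complexes up to a few
hundred atoms, interfaces up to ~30 residues, 200 randomized MSA specs, 500
fixtures in the clash-indicator sweep, screening tables up to ~2×10⁴ pairs.
These sizes make every property checkable by exhaustive or quadratic
oracles; all algorithms scale beyond them (the k-d-tree contact search is
near-linear, scoring is vectorized).

## Known limitations

No atom-level van-der-Waals clash detection (χ is a residue-level summary);
no symmetry-aware chain remapping for homo-oligomer scoring; no MSA pairing
(by design); no mmCIF writing; nucleic-acid chains unsupported; the
fixture geometries are not physical proteins.
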