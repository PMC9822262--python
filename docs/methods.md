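# Methods

## Model and sign conventions

The package evaluates the pairwise Potts Hamiltonian
`H(S) = Σ_{i<j} J_ij(s_i,s_j) + Σ_i h_i(s_i) + offset` over fixed-width
alignments with a 21-state alphabet (20 amino acids + gap).  The Boltzmann
convention is `P(S) ∝ exp(−H(S))`: lower H is more probable, so a positive
threading penalty ΔE disfavors the inactive conformation.  Model inference
is out of scope — parameters arrive in an HDF5 container (`h`: L×q, `J`:
P×q×q in lexicographic i<j order, attributes L, q, alphabet, offset) or,
for small models, a plain-text TSV.

Before threading, couplings are put in the zero-sum gauge: every
`J_ij(·,β)` and `J_ij(α,·)` sums to zero, with the removed single-site
parts pushed into the fields, fields centered, and the constant absorbed
into `offset` so that H is preserved exactly for every sequence (and energy
*gaps* are preserved even without the offset).  The transform is idempotent;
the zero-sum check uses a 1e-10 absolute tolerance — double precision with
headroom.  The gauge matters because the threading sum samples individual
coupling cells: the zero-sum gauge is the convention in which those cells
are comparable across pairs.

## Sequence handling

- MSA columns are 1-based everywhere a user sees them.
- Nonstandard residue codes (X, B, Z, U, O, J) and `.` map to the gap state
  by default (`unknown_policy="error"` rejects them instead); the threading
  sum must index a q=21 coupling table, and gap is the least-committal
  state for an ambiguous residue.
- TK/STK classification reads three diagnostic columns (canonically
  126 = HRD+2, 128 = HRD+4, 165 = APE−2): TK iff (Ala|Arg, Arg, Trp), STK
  iff (Lys, ¬Arg, ·); a gap at any diagnostic column yields "other" rather
  than an error.  The column triple is a `ClassificationRule` field so that
  scaled-down synthetic alignments (L < 165) can carry the same predicate
  structure at shifted columns.
- Gatekeeper size: membership in the two canonical volume sets
  (small < 110 Å³: G, A, S, P, T, C, V).  Asp appears in neither canonical
  set; the default volume table assigns it 111 Å³ (large), adjacent to Asn
  which is canonically large.  The table and threshold are arguments.
- The gap filter retains sequences with ≤ 31 gaps (removes 32 or more).
- Phylogenetic weights: `w(s) = 1/n(s)` with `n(s)` the number of
  same-class sequences (including s itself, so weights never exceed 1)
  within the identity neighborhood.  "Within 40% identity" is ambiguous
  between identity ≥ 40% and divergence ≤ 40%; the default is divergence
  ≤ 40% (identity ≥ 60%), with the threshold exposed.  Identity is exact
  Hamming identity over all L columns with gap as an ordinary symbol,
  computed all-pairs — deterministic and oracle-checkable at the desk
  scales this package targets (~10³–10⁴ sequences); no clustering
  heuristic is used.

## Contacts and ensembles

A contact is assigned when the nearest side-chain heavy atoms of two
mapped residues lie strictly within 6 Å and their MSA columns differ by
more than 4.  "Side chain" means Cβ and beyond; glycine contributes its Cα
as a proxy side-chain atom (configurable, default on) so it can form
contacts at all.  Multi-model files use model 1; alternate locations keep
the highest-occupancy conformer per atom name.  Structures are mapped to
MSA columns by a user-supplied column map; the package does not align
structures itself.

Ensemble frequencies down-weight PDB redundancy with `w_n = 1/u_n`, where
`u_n` counts chains sharing the UniProt ID across the *combined*
active+inactive cluster pair, so duplicating every chain k times (with
weights recomputed) leaves every `c_ij` unchanged.  Unresolved residues
are missing data, not non-contacts: by default both numerator and
denominator of `c_ij` run only over structures resolving both columns
(per-pair normalization).  A global-denominator mode is provided for
comparison, since the alternative reading — zeroed numerator over a global
denominator — cannot be excluded.  Pairs with no resolved support are
flagged undefined, carried as c = 0 downstream, and warned about.

## Threading and decomposition

`ΔE(S) = −Σ J_ij(s_i,s_j)·Δc_ij(X)` uses class-specific Δc maps (each
class threaded on its own ensembles); a shared-map mode exists for
ablation.  Gap handling at threaded pairs is `gap_mode="model"` by default
(the gap state carries whatever couplings the model defines, appropriate
when the model was trained with gaps as a 21st state); `gap_mode="zero"`
silences gap-containing pairs for models without meaningful gap
parameters.  Both the per-sequence route and the bivariate-marginal route
use the same effective couplings and the same weights, which is what makes
`Σ_ij ΔΔE_ij = ΔΔE` an identity rather than an approximation; the test
suite asserts agreement below 1e-8 and against a quadruple-loop oracle
below 1e-10.  The ranked pair report orders by descending ΔΔE_ij with ties
broken by ascending (i, j).

## Statistics

- `ΔG_exp = k_B·T·ln(K_d/1 M)` with T = 298.15 K and
  k_B = 0.0019872041 kcal/(mol·K), both configurable; IC50 values are
  treated like K_d (a documented simplification).
- The weighted Welch test uses effective counts `N_eff = Σw`, weighted
  variance `s² = Σw(x−x̄_w)²/(N_eff−1)` and standard error `s/√N_eff`; the
  reference literature does not pin down the weighted standard error, so
  the estimator is isolated in one function.  Degrees of freedom follow
  the standard Welch–Satterthwaite form
  `ν = (se_X²+se_Y²)²/(se_X⁴/ν_X + se_Y⁴/ν_Y)` with `ν_i = N_eff,i − 1`.
  With unit weights the test reduces exactly to the textbook Welch test.
  One-tailed p-values below 1e-15 are reported as "< 1e-15".
- The energy-scale calibration regresses benchmark ΔG_reorg on the Potts
  penalty.  The through-origin slope `Σxy/Σx²` is the headline scale
  (≈1.3 kcal/mol per Potts unit on the packaged ten-kinase benchmark,
  r² ≈ 0.75); the unconstrained OLS fit is emitted alongside because the
  choice of constraint is genuinely open.
- Per-kinase ΔG_reorg is the intercept of a slope-one regression of
  ΔG_exp on ΔG_bind, i.e. `mean(ΔG_exp − ΔG_bind)`, with the standard
  error of the differences as its uncertainty (0 for a single complex).
- Hit rate counts ligands with K_d ≤ 10 μM, boundary inclusive; missing
  affinities are excluded and logged.

## Synthetic data

The generator produces the statistical structure the analysis assumes, not
kinase biology: no real phylogeny, contact topology, or 259-column
geometry is imitated, so passing tests demonstrate correctness of the
machinery, not biological conclusions.  Ground truth is planted as
follows: background couplings are N(0, 0.05); each planted pair (|i−j| > 4,
avoiding diagnostic columns) has its (STK-state, STK-state) cell lowered
by the contrast and its (TK-state, TK-state) cell raised by it, so the
STK-like class anchors favorably in the active ensemble and pays a
positive penalty when the contact is lost.  Structural ensembles are
generated directly as contact maps (the 6 Å geometry operator is tested
separately on handcrafted coordinate fixtures); active maps carry the
planted contacts, inactive maps toggle them, so Δc = ±1 exactly at planted
pairs and 0 elsewhere.  Pseudo-UniProt redundancy and random missing
residues exercise the weighting and per-pair normalization rules.  Class
marginals are separated by overwriting planted columns with the class's
favored state at a configurable rate (default 0.8) on top of Gibbs samples
from the ground-truth model.

Sampling is single-chain sequential-scan heat-bath (not random-scan, not
Metropolis) with all uniforms pre-drawn from one generator, so identical
(seed, parameters) give identical output; the numba-compiled kernel makes
desk-scale sampling essentially free.  Scenario generation routes one
master seed through named substreams (model, sequences, structures,
masks), making regeneration byte-identical and components independently
regenerable.

Default study conditions are desk-scale: L = 60 columns, q = 6 states
(alphabet chosen so the diagnostic letters A/R/W/K exist), 500 sequences
per class, 6 planted pairs at contrast 3.0, 8 structures per ensemble with
2-fold redundancy and 5% missing residues.  The 50-replicate sign-recovery
check runs at 120 sequences per class per replicate — the sign of ΔΔE is a
class-mean property that saturates well below 500 sequences, and this
keeps the whole acceptance run in seconds.  The null-calibration property
test (no contrast, no shift) checks that one-tailed p-values are uniform
or conservative by a one-sided Kolmogorov–Smirnov test at α = 0.01 over
200 replicates.

## Degenerate inputs and tie-breaks

Hard errors: ragged or empty alignments (naming the offending record),
width mismatches between model/sequences/map, empty structure lists or
classes, overlapping classes, zero-variance samples, nonpositive K_d,
missing decoupling legs (named).  Soft paths: residues with no side-chain
heavy atoms form no contacts; missing UniProt IDs are treated as unique
with a warning (or rejected by policy); undefined Δc pairs contribute
zero.  Threading a model that is not in the zero gauge warns and applies
the transform rather than failing.

## Known limitations

- The headline biological quantities (kinome-scale ΔΔE, the hit-rate
  correlation) require the externally inferred Potts model, the full
  Pfam-derived alignment and curated PDB ensembles; nothing in the test
  suite stands in for those inputs.
- All-pairs identity weighting is O(N²L) and intended for up to ~10⁴
  sequences; larger alignments need chunked or approximate weighting.
- The Welch test assumes approximately normal class means; with highly
  skewed ΔE distributions and tiny N_eff the one-tailed p is only
  indicative.
- IC50 ≈ K_d ignores assay-dependent offsets, which shifts ΔG_exp (and so
  ΔG_reorg) by a per-assay constant.
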