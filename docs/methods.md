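# Methods

## Model and procedure

The package treats an analog series' cellular activity as one bulk effect
plus sparse modification effects:

    pEC50_i = beta0 + beta_bulk * bulk_i + sum_k gamma_k * count_k(i) + eps_i

The tandem analysis never fits this model jointly. Stage 1 asks which
single descriptor best stands in for `bulk` by screening every pool
descriptor in a one-predictor least-squares fit, repeated over
property-ordered subsamples so that dominance — not one lucky fit — is the
criterion. Stage 2 conditions on that filter descriptor and screens every
E-state descriptor one at a time in a two-predictor context equation,
ranked by R². The working assumptions are that (i) the bulk effect is
well captured by a single charge-distribution descriptor (Jurs_RNCG),
(ii) modification effects are approximately additive in the count of the
modified feature, and (iii) distinct key modifications are carried by
distinct E-state atom types. "Prioritized by correlation coefficient" is
implemented as ranking by fit R² — the only reading consistent across the
one- and two-predictor stages (for stage 1 it equals the squared Pearson
correlation; an identity asserted in the tests).

## Descriptor engine

E-state atom types are bond-pattern symbols: one prefix letter per bond to
a heavy neighbor (s single, d double, t triple, a aromatic), ordered
t, d, a, s to match the canonical published names (dssC, aasC, tsC), then
the element, then an H suffix only when hydrogens are attached. Intrinsic
states use I = ((2/N)²·δᵛ + 1)/δ with δᵛ = valence electrons − attached H,
adjusted by −(formal charge); perturbation uses r = topological distance
+ 1 over **all** heavy-atom pairs (no cutoff), so bonded neighbors sit at
r = 2 and ΣS ≡ ΣI by antisymmetry — the identity is used as a cheap
integrity check throughout. Raw (possibly negative) S values enter the
ES_Sum descriptors untruncated. Aromaticity is RDKit's default perception
model, stamped implicitly by the parser choice; all downstream typing
(aaO vs ssO etc.) inherits it. Single-heavy-atom molecules have no
defined E-state (δ = 0) and are excluded from descriptor matrices with a
logged reason.

Partial charges are Gasteiger–Marsili (RDKit), with hydrogen charges
folded onto their heavy atoms; the charge model name is stamped into every
report. RNCG needs only a charge-coherent ordering, and its qualitative
behaviour as a bulk filter is robust to the specific charge model; no
surface-weighted CPSA descriptors are computed because RNCG is the only
Jurs-type quantity the method consumes. Compounds with no negative atom
(RNCG undefined) are excluded with a logged warning.

The stage-1 pool adds four simple bulk competitors (heavy-atom count,
molecular weight, ring-bond count, polar-atom fraction) so dominance is
contested by the descriptor families that compete on real data (size,
rings, polarity); the pool is configuration, not a hard-coded list.

## Numerical choices

- Least squares is QR-based (`numpy.linalg.lstsq`) with an explicit
  pivoted-QR rank check that names the collinear columns; a constant
  response raises rather than returning R² = 0/0.
- Ranking ties (identical R²) break lexicographically by descriptor name,
  so reports are reproducible byte for byte.
- Subset picking sorts by the ordering property descending (configurable
  to ascending) with a stable sort, so tied property values keep input
  order.
- ES columns constant in the data, or collinear with the filter
  (|r| ≥ 1 − 1e−9), are excluded from stage 2 with a logged reason.
- "Near dominant" means focal rank ≤ 4 (configurable).
- In the dependency diagnostics the deliberately combined fit uses the
  minimum-norm solution when the joint design is singular, so coefficient
  signs remain reportable; singularity itself is reported as dependency
  evidence. Rare-moiety ("analog outlier") descriptors are those with
  nonzero values in ≤ 3 compounds by default.
- Indeterminate activities — missing, non-positive, or flagged uncertain —
  are dropped at ingestion with a logged count.

## Synthetic analog series

The generator emulates the structure of a glitazone-type agonist series: a
constant thiazolidinedione–benzyl–ether core and a variable tail carrying
ether units (ssO, each −1.5 log units), methylene elongation (ssCH2, no
planted effect), an optional tertiary amine (sssN, +1.0), and an oxazole
(aaO, +2.0) in exactly two compounds — the rare, strongly active "analog
outlier" situation. Defaults: n = 150, noise σ = 0.3 on the log scale
(Gaussian noise on pEC50 is what makes least squares the natural
estimator). The bulk term uses the series' **own** computed Jurs_RNCG with
β_bulk = 20 and β₀ = 6, chosen so the bulk contribution spans roughly
1–2 log units (measured RNCG spread in such a series is ≈ 0.07 sd) and
simulated pEC50 values fall in the realistic 5–9 range; with those
magnitudes the bulk term is the dominant single effect, which is the
premise the stage-1 screen is meant to verify, not assume per subset.

Every emitted molecule is re-typed by the E-state engine and the declared
signature of each context-free moiety (ssO, sssN, aaO) is verified; a
mismatch aborts generation, so the planted truth cannot silently drift
from the typing rules. Linker carbons (ssCH2) are contributed by several
fragments at once and are intentionally not gated.

What the generator does **not** emulate: real charge physics beyond
Gasteiger, conformation-dependent descriptors, curation noise in
literature EC50 values, scaffold–tail interactions, and activity cliffs
that are not expressible as counts of one atom type. Passing recovery
tests therefore show that the two-stage screen isolates additive,
type-linked effects behind a dominant bulk signal — not that it would
rank modifications correctly in any real series.

## Validation experiments and problem sizes

`tandemro.experiments` fixes the study conditions used by the test-suite
and the acceptance script: recovery over 100 independently seeded default
series (criterion: an ssO descriptor rank 1 with sign −, an sssN
descriptor in the top 12 with sign +, each in ≥ 95/100 seeds); dominance
with activity regenerated as β₀ + β_bulk·RNCG + N(0, 0.2²) over the size
grid 10, 20, …, n; E-state exactness on 1,000 random typed trees of ≤ 12
heavy atoms against a naive all-ordered-pairs oracle; 100 random OLS
fixtures against the normal equations. These sizes keep the full
validation under a minute while leaving the statistical criteria
well-resolved.

## Structural contacts

PDB complexes are read with gemmi. Alternate conformers resolve to the
highest-occupancy copy unless an altloc is requested. Ligand bond orders —
absent from PDB — come from RDKit proximity bonding, overridden by a
user-supplied SMILES template whenever aromaticity or multiple bonds
matter for typing. Distances are heavy-atom Euclidean, reported to
0.01 Å; ambiguous residue selections (homodimers) either raise, accept a
chain qualifier (`A/CYS285:SG`), or resolve to the copy nearest the ligand
centroid when asked. The test fixture complex is synthetic (exact
constructed coordinates); the crystallographic worked-example test runs
against the real rosiglitazone complex (PDB 2PRG) and fails when that
entry cannot be obtained, since it cannot be redistributed with the
package.

## Known limitations

- Discovery-grade descriptor catalogues (hundreds of descriptors) are out
  of scope; the pool is small and extensible, which changes the absolute
  dominance denominators but not the method.
- E-state typing depends on the aromaticity model; other perception
  schemes can relabel borderline heteroaromatics (aaO ↔ ssO).
- Gasteiger charges are a topology-level model; RNCG values are not
  comparable across charge models.
- The detector reports association under a single-filter adjustment, not
  causal effect sizes; strongly correlated moieties (e.g. oxazole's aaO,
  aaN, aaCH) are flagged as dependent rather than disentangled.
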