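# Methods

## Model

`ppiscore` implements an empirical (knowledge-based) pair potential for
protein–protein interfaces. The underlying assumption is the standard one
for statistical potentials: residue pairs that occur across interfaces
more often than expected from interface composition alone are
energetically favourable, and the log of the observed/expected ratio is
an additive pseudo-energy. Three separate 20×20 matrices are kept per
distance threshold, one per interaction mode — main-chain–main-chain
(MM), main-chain–side-chain (MS), side-chain–side-chain (SS) — because
the same residue pair can have very different preferences depending on
which parts of the residues touch.

### Contact definition

Two residues on different chains interact when at least one heavy-atom
pair between them is within the threshold *d* (inclusive, `≤ d`).
Allowed thresholds are 4, 6 and 8 Å with 4 Å the default; the longer
thresholds act as a proxy for longer-range (e.g. water-mediated)
interactions. Each unordered residue pair is reported once per
chain-pair interface, with per-mode tallies `n_MM, n_MS, n_SS` counting
every qualifying atom pair, the minimum distance, and the number of
clashing atom pairs (strictly below the clash cutoff, default 2.5 Å).
Only inter-chain contacts are ever counted. The main-chain atom set is
{N, CA, C, O, OXT}; everything else, including CB and any nonstandard
atom name, is side chain, so glycine contributes only main-chain atoms.
Hydrogens, waters and non-polymer HETATM records (ions, cofactors such
as haem) are excluded; MSE is scored as MET; alternate locations resolve
to the highest-occupancy conformer (first on ties) and only the first
MODEL of a multi-model file is read. Neighbour search uses a k-d tree
per chain; results are defined to equal the brute-force all-pairs
computation exactly, and the test suite enforces this.

### Potential derivation

Over a training corpus, every interacting residue pair contributes one
count to mode m if it has at least one atom contact in that mode. With
pseudocount α (default 1):

    f_obs(a,b,m) = (C(a,b,m) + α) / Σ_{a'≤b'} (C(a',b',m) + α)
    f_exp(a,b)   = p_a · p_b · (2 − δ_ab)
    w(a,b,m)     = −ln( f_obs(a,b,m) / f_exp(a,b) )

The composition p is the corpus interface composition (each interface
residue counted once), smoothed with the same α
(`p_a = (n_a + α)/(N + 20α)`) so f_exp is strictly positive even when a
residue type is absent from a small corpus. Favourable (enriched) pairs
get negative weights. A mode with no contacts at all yields an all-zero
matrix and a warning rather than an error, because single-geometry
synthetic corpora legitimately populate only some modes.

Atomic propensities are tallied per (a, b, m): the distribution of the
per-pair atom-contact count n, binned 1–10 with 11+ pooled, normalised
so the modal count maps to a factor of 1.0. Scoring multiplies the pair
weight by this factor, so pairs interacting through their typical number
of atoms keep full weight; counts never seen in training fall back to a
floor (default 0.1). The multiplicative combination of pair weight and
propensity, the binning, and the floor are this package's declared
conventions — reasonable defaults, all overridable.

### Scoring and classification

A clash-free pair scores `Σ_m w(a,b,m)·g(a,b,m,n_m)` over the modes in
which it touches; a pair with any clash instead contributes `κ·n_clash`
with κ positive (default 1.0), i.e. clashes wipe out the pair's
favourable contribution and add a destabilising penalty. The raw score S
sums over all pairs (so the whole-complex score is exactly the sum of
its chain-pair interface scores) and the normalised raw score is S/N.

The null model for "non-native interfaces" is residue-label shuffling:
each interface residue's amino-acid identity is redrawn independently
from a background composition (default: the interface's own
composition), while the contact topology, per-mode atom counts and clash
counts stay fixed. Each shuffle is rescored, giving μ and σ over
`n_samples` draws (default 10,000, seedable). Because pair counts are
fixed under the shuffle, standardising the raw or the normalised score
gives the identical Z. With the energy convention (favourable =
negative),

    Z = (μ − S) / σ

so natives scoring below their shuffled background get positive Z, and a
complex is called a Binder when Z ≥ τ, with τ = 1.5 at 4 Å (boundary
inclusive). The cutoffs at 6 and 8 Å default to the same 1.5 but have
not been calibrated here and are flagged as such. A single-type
background composition makes σ = 0; this is reported as a degenerate
background rather than a Z score.

Implementation note: the shuffle is vectorised by precomputing, per
clash-free pair, the 20×20 table of scores as a function of the two
redrawn labels (the atom counts, hence the propensity factors, are
label-independent under the shuffle only through the (a,b) lookup);
clashing pairs contribute a label-independent constant. This makes
10,000 shuffles of a hundred-pair interface essentially instant, and Z
is exactly invariant under rescaling all weights w → c·w (c > 0).

### Evaluation metrics

For decoy ranking, rank = 1 + number of decoys scoring strictly better
than the native, and percentile = 100 × (decoys strictly worse)/(number
of decoys); ties never outrank the native (the optimistic tie rule,
stated explicitly because published percentile conventions vary).
Rate-based classifier metrics take TPR and TNR directly:
FPR = 1 − TNR, FNR = 1 − TPR, accuracy = prev·TPR + (1−prev)·TNR,
balanced accuracy = (TPR + TNR)/2, and MCC in its rate form
(TPR·TNR − FPR·FNR)/√((TPR+FPR)(TPR+FNR)(TNR+FPR)(TNR+FNR)) — the
appropriate variant at strong class imbalance; the default prevalence
1/101 corresponds to one native per hundred decoys. A zero denominator
factor reports MCC = 0 with a warning.

## Synthetic fixtures

The generator builds "ladder" complexes: extended chains whose residues
sit on rungs 6 Å apart, each with a planar four-atom backbone and 1–3
side-chain pseudo-atoms (count depending on residue size class)
extending perpendicular to the backbone plane with the tip always 3 Å
out. In the default `ss` geometry, adjacent chains face each other
side-chain-to-side-chain and the closest atoms of each rung are the two
tips, exactly `inter_chain_gap` apart — so at 4 Å each rung contributes
exactly one SS contact and the minimum inter-chain distance is the gap
by construction. The `mixed` geometry places backbone planes at the gap
with side chains swept aside, populating MM (and at longer thresholds MS
and SS) contacts. A `clique` layout drops short chains onto a small
circle so every chain pair touches, for interface-enumeration tests.
Steric clashes are planted as dedicated atom pairs 0.8 Å apart,
positioned so they add exactly one clashing pair each and perturb
nothing else. Optional coordinate jitter randomises geometry for
oracle-comparison tests (the gap contract then holds only to the jitter
width).

Rung residue types are drawn from an unordered pair-type distribution.
A planted enrichment "(a, b, m) at fold f" means the pair's frequency is
f times the frequency expected from the realised residue composition.
Multiplying the base distribution by f would inflate the marginals of a
and b and undershoot the realised ratio, so the observed/expected ratio
matrix is planted directly: enriched cells are fixed at f and all other
cells carry a multiplicative compensation s_a·s_b fitted iteratively so
every ratio row averages to 1 under the composition. The resulting joint
has marginals exactly equal to the composition and the planted ratio
exactly f, which is what makes the derived −ln f weight recoverable;
folds too large for the composition to compensate are rejected as
infeasible. Because glycine has no side-chain heavy atoms, `ss`-geometry
fixtures default to a glycine-free composition (a glycine rung would
simply fail to touch, biasing realised frequencies).

What the fixtures do **not** emulate: real backbone geometry and rotamer
packing, heterogeneous contact richness (most ladder pairs interact
through one atom pair at 4 Å, so propensity tables are nearly trivial in
`ss` fixtures), cofactors, crystallographic artefacts, and realistic
interface sizes. Passing tests therefore demonstrate the correctness of
the counting, derivation, scoring and classification machinery and the
recoverability of planted signal — not predictive performance on real
complexes, which depends on training data this package does not ship.

## Problem sizes and numerical choices

The test suite and the acceptance script use fixtures of 2–4 chains with
6–24 residues per chain; oracle comparisons run 100 fixtures per
threshold; potential-recovery corpora use 120–200 complexes (~4,800
interface pairs), where the pseudocount bias on a 5× planted enrichment
is ~2% and multinomial noise dominates; backgrounds use 10,000 shuffles.
These sizes make the whole suite run in well under a minute while
keeping every statistical tolerance at 3+ standard errors.

Other numerical conventions: distances compare inclusively at the
threshold and strictly at the clash cutoff; matrix serialisation is
tab-separated plain text at 4 decimal places (propensities at 6), and
reading validates dimensions, row/column order and symmetry (tolerance
1e-4); ties in altloc occupancy keep the first conformer; a background
σ below 1e-12 (relative) is snapped to exactly 0 and reported as
degenerate; per-interface backgrounds derive their seeds as
`seed + 1 + k` over the sorted chain-pair list so whole-complex and
per-interface results are independently reproducible.

## Known limitations

* The published scoring matrices are not redistributed; bundled demo
  matrices come from synthetic fixtures and are for smoke tests only, so
  absolute scores of real PDB complexes are not comparable to published
  case-study values unless a user supplies trained matrices.
* The Z cutoffs at 6 and 8 Å are uncalibrated defaults.
* The background model (independent residue redraw, topology fixed) is
  one operational definition of "non-native interfaces"; alternatives
  (joint pair redraw, composition from a reference database) would shift
  μ and σ.
* Mutational Δ-scoring, decoy generation, and solvent/SASA-based
  interface definitions are out of scope.
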