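# Methods

## The partitioning model

The sampler treats a superfamily MSA as a mixture over the leaves of a
subgroup tree.  A non-root node `v` is characterized by its *pattern*: a
set of alignment columns, each with a residue set of one to three amino
acids, differentially conserved in the node's foreground (the sequences of
`v`'s subtree) relative to its background (the rest of the parent's
subtree).

**Contrast statistic.**  For one column with `fg_matches / fg_total`
foreground and `bg_matches / bg_total` background residues in the set, the
score is

    score = −log10 P(X ≥ fg_matches),
    X ~ Hypergeometric(N = fg_total + bg_total + 1,
                       K = fg_matches + bg_matches + 1,
                       draws = fg_total)

i.e. the upper tail of a ball-in-urn draw after a +1 pseudocount on the
background (which keeps perfectly clean columns finite and makes the
zero-match case exactly score 0).  Tails are computed by an exact
log-space summation using the pmf ratio recurrence (`_hyper.py`); this is
the same finite sum an exhaustive enumeration performs, and the test suite
verifies agreement with an integer-arithmetic enumeration oracle to 1e-10
relative for all populations up to 25.

**Pattern selection.**  Per column, the residue set grows greedily from
the modal foreground residue, adding residues while the score increases,
to at most 3.  Columns with more than 50% foreground gaps are ineligible;
only columns scoring above the per-position penalty are kept (best score
first, ties by ascending column, at most `max_pattern_positions`).

**Objective.**  The hierarchy score is the sum over non-root nodes of
(pattern score sum − penalty × number of positions).  The default penalty
is **6.0 score units per position**.  This was set by a null-calibration
experiment: because selection maximizes over ~20 starting residues and up
to two greedy additions per column, exchangeable (structure-free) data
reaches column scores of ≈4–5 at the scales this package targets
(100–400 sequences per side, 60–120 columns); a penalty of 6 keeps null
patterns empty or nearly so while planted or biologically conserved
columns (scores in the tens to hundreds) are unaffected.

**Optimization.**  `PatternHierarchyClusterer.fit` runs restarts of:

1. *Divisive initialization* — each node's members are split among its
   children by a 2-means seed on one-hot encodings followed by a short
   local EM (pattern selection between siblings, reassignment by
   pattern-match log-odds), recursively from the root.  This is much more
   robust than joint random initialization, which tends to lock into
   mixed-family local optima.
2. *Sweeps* — alternating per-node pattern re-selection and a root-to-leaf
   rerouting of every sequence.  Sequences choose between staying at a
   node and descending to a child by the child's pattern-match log-odds
   (Laplace-smoothed Bernoulli per position; gaps contribute 0), sampled
   through a Gumbel-softmax at a temperature annealed linearly to zero
   over the first 75% of sweeps.
3. *Split/prune proposals* (tree search mode) — a candidate child is one
   group of the EM bisection of a node's direct members.  Because the
   greedy pattern search overfits exchangeable rows by tens of score
   units, a fixed objective threshold cannot control false splits;
   instead, a split is accepted only when its gain exceeds the gain the
   identical procedure achieves on *column-shuffled* data (which preserves
   per-column composition but destroys sequence grouping) by
   `split_margin` (default 10).  Pruning applies the same calibrated
   criterion in reverse.  On exchangeable sequences this accepts a split
   in ≲5% of runs; point estimates (the best-objective hierarchy over
   restarts), not posteriors, are returned.

The two-level reference analysis fixes the tree topology to the
generator's 2×2 shape and infers membership and patterns from random
initialization; topology search is exercised separately on smaller
fixtures.  This keeps the reference experiment focused on assignment and
pattern recovery rather than on model selection.

## Initial-cluster statistics

Given a chain ordering and a marked subset (the pattern residues), the
scan computes, for every prefix of size k, the hypergeometric tail
P(X ≥ marks in prefix) with population = chain length and marked = total
marks, and takes the minimum over k.  The reported best prefix ends at a
marked residue — the minimum over all prefixes is always attained at one,
since appending an unmarked residue can only raise the tail — with the
smallest such prefix on ties.

The selected minimum is not a p-value; the family-wise **adjusted p** is
the add-one permutation estimator `(1 + #{permuted orderings with
raw_min_p ≤ observed}) / (n_perm + 1)` under uniform permutation of the
mark positions.  This is exact under exchangeability of residue positions;
its floor is `1/(n_perm + 1)`.

Two orderings are provided:

- **Interface mode** — chain-a residues sorted by ascending minimum
  any-atom distance to the partner chain (ties by author number).  The
  original method's ordering rule is not published; this distance ordering
  is this package's definition.
- **Core mode** — a single-linkage growth ordering from *every* seed
  residue (repeatedly append the Cα-nearest residue to any member, ties
  by author number); the statistic is the best raw p over all seeds, and
  the permutation null repeats the full best-over-seeds scan so that the
  seed-selection multiplicity is calibrated away.  The test suite verifies
  the null rejection rate at nominal 0.05 stays within [0.02, 0.08].

## Structure handling

PDB input is parsed with Biopython (first model, HETATM skipped, altLocs
resolved to the highest-occupancy conformer, insertion codes appended to
author numbers).  Author numbering is used in all user-facing reports.
Interface membership uses minimum any-atom distances with an inclusive
5.0 Å default cutoff (for Cα-only synthetic structures this reduces to
Cα–Cα distances; an 8.0 Å cutoff is the sensible choice there and both are
config-exposed).  The published analyses' actual contact threshold is not
stated, so results on real structures can shift with this cutoff.
Sequence-to-structure maps come from global alignment (match +1, mismatch
−1, gap −2); maps under 30% identity are returned with a warning flag.
Superposition is the Kabsch SVD solution constrained to proper rotations,
cross-checked in the tests against an independent quaternion (Horn)
implementation.

## Binding model

The printed assay equation "A = Amax/1 + Kd/(L)" is read as the standard
one-site law `A = Amax/(1 + Kd/L)`; the Hill generalization
`A = Amax·Lʰ/(Kdʰ + Lʰ)` reduces to it at h = 1 and matches the assay
software's "one site-specific binding with Hill slope" family.
Fitting is unweighted nonlinear least squares (plate-reader practice;
weights are config-exposed through the curve container) with
initialization Amax₀ = max(A), Kd₀ = L nearest half-saturation, h₀ = 1,
positivity bounds, and 1e-10 relative parameter tolerance; standard errors
come from the Gauss–Newton covariance.  Non-convergence is flagged on the
result, not raised.  Concentrations are handled in nM; `ug_ml_to_nM`
converts the mass concentrations plates are prepared in (e.g. 1 μg/mL of
a 66 kDa protein ≈ 15.2 nM).  Per-curve fits are reported; replicate
curves are not pooled.

## Synthetic data: what it emulates and what it does not

- **Hierarchical MSA** — sequences drawn i.i.d. per column from a
  background distribution (uniform by default; a Robinson–Robinson
  frequency preset is included), with each node on a sequence's lineage
  emitting its pattern residue at its columns with probability
  `pattern_strength`.  Reference conditions: 2 families × 2 subfamilies,
  200 sequences per leaf, 5 disjoint pattern columns per node, strength
  0.95, 120 columns.  No indels, no phylogenetic correlation within
  subgroups, no overlapping patterns: passing recovery tests shows the
  sampler finds differential conservation of this planted form, not that
  it resolves real phylogenetic confounding.
- **Toy complex** — two 60-residue pseudo-Cα chains from self-avoiding
  3.8 Å random walks pulled toward their centroid, separated so the
  closest approach is ≈8 Å, with 8 planted residues relocated into a 5 Å
  sphere at the interface midpoint.  Geometry is Cα-level only; real
  side-chain packing, secondary structure and B-factors are absent.
- **Binding curves** — 12-point two-fold dilution series (0.25–512 nM by
  default) with homoscedastic Gaussian OD noise, the simplest model
  consistent with an ELISA readout.

All generators are bit-reproducible given their seed.

## Numerical and degenerate-input choices

Ties in pattern ranking break by ascending column; sequence sweep order is
input order; all randomness flows from one seeded generator per fit, and
pipeline stages draw child seeds from the single global seed.  Empty MSAs
are representable (filters may remove everything) but cannot be
partitioned; the scan requires at least one mark; superposition requires
three non-collinear pairs; fits require four distinct concentrations.
Problem sizes in the test suite (800×120 MSAs, 60+60-residue complexes,
199–999 permutations, 100–500 null replicates) were chosen so the full
planted-recovery and calibration experiments are routine desk-scale runs.

## Known limitations

The published real-data results this package's pipeline parallels (the
Sema-domain hierarchy shape and the interface-clustering p-values on the
Sema4D–Plexin B1 complex) depend on a particular sequence-database
snapshot and unstated contact thresholds and are not reproduced here; the
pipeline accepts any MSA/structure and reports what it computes.  The
sampler returns a point estimate, not posterior uncertainty over trees.
mmCIF input, docking/energetics, and profile-based homolog search are out
of scope.
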