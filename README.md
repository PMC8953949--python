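# fdrscope

Identifies **function-determining residues** in protein-domain
superfamilies, and provides the downstream analyses used to characterize
them experimentally.  The package is aimed at structural/computational
biologists studying receptor–ligand specificity (the motivating system is
the semaphorin Sema domain family and its Plexin B1 receptor), and covers
the full computational route:

1. **Alignment filtering** — fragment removal (rows with >25% deletions)
   and greedy redundancy collapse (pairs at ≥98% identity) of a superfamily
   MSA.
2. **Hierarchical subgroup partitioning** — an annealed sampler splits the
   MSA into a tree of subgroups, each defined by *pattern residues*:
   columns whose residue set is differentially conserved in the subgroup's
   foreground relative to its background.  The per-column contrast
   statistic is a hypergeometric ("ball-in-urn") upper tail, reported as
   −log₁₀ P(X ≥ x) with a +1 background pseudocount.
3. **Initial-cluster statistics on structures** — given a chain ordering
   (by distance to a partner chain, or by single-linkage growth from every
   seed residue) and a set of marked pattern residues, the minimum
   hypergeometric tail over initial segments measures clustering, and a
   mark-permutation null converts it into a family-wise adjusted p-value.
4. **Homology transfer and superposition** — pattern residues are carried
   between subfamily sequences via shared alignment columns, mapped onto
   structures by global alignment, and complexes are superimposed with a
   Kabsch least-squares fit.
5. **Saturation-binding analysis** — one-site binding
   `A(L) = Amax·Lʰ/(Kdʰ + Lʰ)` (h = 1 gives `A = Amax/(1 + Kd/L)`) fitted
   by nonlinear least squares, with Scatchard transforms (slope −1/Kd) and
   percent-inhibition summaries for competition assays.

Planted-truth generators (hierarchical MSAs, toy two-chain Cα complexes
with an interface cluster, noisy binding curves) make every stage testable
without external data.

## Worked example

Recover a planted two-level hierarchy (2 families × 2 subfamilies,
200 sequences per leaf, pattern strength 0.95) and test a planted
interface cluster:

```python
import fdrscope as f
from sklearn.metrics import adjusted_rand_score

msa, truth = f.gen_hierarchical_msa(f.default_two_level_spec(seed=0))
est = f.PatternHierarchyClusterer(
    fixed_shape=f.two_level_shape(), n_sweeps=10, n_restarts=2, random_state=0,
).fit(msa)
print(adjusted_rand_score([truth.assignment[i] for i in msa.ids], est.labels_))
# 0.9983340248832879

s, ctruth = f.gen_complex_structure(f.PlantedComplexSpec(seed=1))
r = f.interface_sipris(s, "A", "B", ctruth.planted_labels, n_perm=999, seed=3)
print(r.k_star, r.x_star, r.raw_p, r.adjusted_p)
# 8 8 3.91e-10 0.001
```

The adjusted Rand index of 0.998 means the 800 sequences were assigned to
the four planted leaves essentially perfectly; the interface test found
all 8 planted residues in the 8 structurally closest positions to the
partner chain (k\*=8, x\*=8), with the permutation-calibrated p at its floor
of 1/(999+1).

Fitting a simulated noisy ELISA curve from the shell:

```sh
$ fdrscope simulate binding --kd 20 --noise 0.02 --seed 3 --out curve.tsv
$ fdrscope fit curve.tsv
{
 "Amax": 1.0242274006040468,
 "Kd_nM": 22.241846101746752,
 ...
 "converged": true
}
```

The fitted Kd of 22.2 ± 2.0 nM brackets the simulated truth of 20 nM at
the 2% OD noise level.  Other subcommands: `filter`, `partition`,
`render`, `sipris`, `simulate msa|complex`, and `run` (full pipeline from
a YAML config).

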