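"""Initial-cluster statistics for pattern residues on structures.

Given an ordered list of a chain's residues with a subset *marked* (the
pattern residues), the initial-cluster scan computes, for every prefix of
the ordering, the hypergeometric upper-tail probability of the number of
marks inside that prefix, and takes the minimum over prefixes.  Because the
minimum is itself selected, its nominal value is not a p-value; a
family-wise p-value is obtained by permuting the mark positions uniformly
and applying the add-one permutation estimator.

Two orderings are provided: by ascending distance to a partner chain (is a
mark set clustered *at an interface*?) and by single-linkage growth from
every possible seed residue (is it clustered *anywhere in the chain*?  the
best-over-seeds selection is included inside the permutation null, so the
extra multiplicity is calibrated away).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from ._hyper import log_hypergeom_sf
from .errors import DomainError
from .structure import Structure, min_interchain_distances


def hypergeom_tail(x: int, K: int, n: int, N: int) -> float:
    """P(X >= x) for X ~ Hypergeometric(N population, K marked, n drawn)."""
    if not (0 <= K <= N and 0 <= n <= N and 0 <= x <= min(K, n)):
        raise DomainError(f"inconsistent counts x={x}, K={K}, n={n}, N={N}")
    return float(np.exp(log_hypergeom_sf(x, N, K, n)))


def _sf_table(N: int, K: int) -> np.ndarray:
    """table[x, k] = P(X >= x) for draws of size k; shape (K+1, N+1)."""
    x = np.arange(K + 1)[:, None]
    k = np.arange(N + 1)[None, :]
    # entries with x > min(K, k) are impossible prefixes; they lookup as 0
    return np.exp(log_hypergeom_sf(x, N, K, k))


@dataclass
class OrderedResidueList:
    """A chain's residues in a defined order, with pattern marks."""

    chain: str
    residues: list[str]  # author-number labels in order
    marks: np.ndarray  # bool per residue

    def __post_init__(self):
        self.marks = np.asarray(self.marks, dtype=bool)
        if len(self.residues) != self.marks.shape[0]:
            raise DomainError("one mark flag per residue")
        if len(self.residues) == 0:
            raise DomainError("empty residue list")


@dataclass
class ClusterResult:
    """Outcome of an initial-cluster significance test."""

    k_star: int  # best prefix size
    x_star: int  # marks inside the best prefix
    raw_p: float  # min over prefixes of the hypergeometric tail
    adjusted_p: float  # permutation-calibrated family-wise p
    n_permutations: int
    seed: int
    ordering: list[str] = field(default_factory=list)
    marks: list[bool] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "k_star": self.k_star,
            "x_star": self.x_star,
            "raw_p": self.raw_p,
            "adjusted_p": self.adjusted_p,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "ordering": self.ordering,
            "marks": [bool(m) for m in self.marks],
        }


def _scan_prefix_ps(marks: np.ndarray, table: np.ndarray) -> np.ndarray:
    """Prefix tail probabilities p_k, k = 1..N, via the precomputed table."""
    x = np.cumsum(marks)
    k = np.arange(1, marks.shape[0] + 1)
    return table[x, k]


def _best_prefix(marks: np.ndarray, ps: np.ndarray) -> int:
    """Index (1-based k*) of the best prefix.

    The minimum over all prefixes is always attained at a prefix ending in a
    marked residue (appending an unmarked residue can only raise the tail),
    so k* is reported among those, smallest k on ties.
    """
    masked = np.where(marks, ps, np.inf)
    return int(np.argmin(masked)) + 1


def ica_scan(orl: OrderedResidueList) -> tuple[int, int, float]:
    """Minimum-hypergeometric scan over initial segments.

    Returns ``(k_star, x_star, raw_min_p)``; the best prefix ends at a marked
    residue, with the smallest such prefix on ties.  Requires >= 1 mark.
    """
    marks = orl.marks
    K = int(marks.sum())
    if K == 0:
        raise DomainError("the scan needs at least one marked residue")
    N = marks.shape[0]
    ps = _scan_prefix_ps(marks, _sf_table(N, K))
    k_star = _best_prefix(marks, ps)
    return k_star, int(marks[:k_star].sum()), float(ps[k_star - 1])


def ica_pvalue(orl: OrderedResidueList, n_perm: int = 999, seed: int = 0) -> ClusterResult:
    """Permutation-calibrated initial-cluster p-value.

    Mark positions are permuted uniformly; the adjusted p is the add-one
    estimator ``(1 + #{permutations with raw_min_p <= observed}) /
    (n_perm + 1)``, exact under exchangeability of residue positions.
    """
    if n_perm < 99:
        raise DomainError("use at least 99 permutations")
    marks = orl.marks
    K = int(marks.sum())
    if K == 0:
        raise DomainError("the scan needs at least one marked residue")
    N = marks.shape[0]
    table = _sf_table(N, K)
    obs_ps = _scan_prefix_ps(marks, table)
    k_star = _best_prefix(marks, obs_ps)
    obs = float(obs_ps[k_star - 1])
    rng = np.random.default_rng(seed)
    perm = np.tile(marks, (n_perm, 1))
    perm = rng.permuted(perm, axis=1)
    x = np.cumsum(perm, axis=1)
    k = np.arange(1, N + 1)[None, :]
    perm_min = table[x, k].min(axis=1)
    count = int((perm_min <= obs + 1e-15).sum())
    return ClusterResult(
        k_star=k_star,
        x_star=int(marks[:k_star].sum()),
        raw_p=obs,
        adjusted_p=(1 + count) / (n_perm + 1),
        n_permutations=n_perm,
        seed=seed,
        ordering=list(orl.residues),
        marks=list(marks),
    )


def _chain_labels(s: Structure, chain: str) -> list[str]:
    return [r.label for r in s.chain(chain)]


def _marks_for(labels: list[str], pattern_residues) -> np.ndarray:
    wanted = {str(p) for p in pattern_residues}
    missing = wanted - set(labels)
    if missing:
        raise DomainError(f"pattern residues not in chain: {sorted(missing)}")
    return np.array([lab in wanted for lab in labels], dtype=bool)


def interface_sipris(
    s: Structure,
    a: str,
    b: str,
    pattern_residues,
    n_perm: int = 999,
    seed: int = 0,
) -> ClusterResult:
    """Are the pattern residues of chain `a` clustered at the `b` interface?

    Chain-`a` residues are ordered by ascending minimum any-atom distance to
    chain `b` (ties by author number), pattern residues are marked, and the
    permutation-calibrated initial-cluster p-value is computed.
    """
    labels = _chain_labels(s, a)
    dists = min_interchain_distances(s, a, b)
    numbers = np.array([r.number for r in s.chain(a)], dtype=float)
    order = np.lexsort((numbers, dists))
    ordered_labels = [labels[i] for i in order]
    marks = _marks_for(labels, pattern_residues)[order]
    orl = OrderedResidueList(chain=a, residues=ordered_labels, marks=marks)
    return ica_pvalue(orl, n_perm=n_perm, seed=seed)


def _growth_orderings(D: np.ndarray, numbers: np.ndarray) -> np.ndarray:
    """Single-linkage growth ordering from every seed residue.

    Row i is the ordering seeded at residue i: repeatedly append the residue
    nearest (C-alpha) to any current member, ties by author number.
    """
    n = D.shape[0]
    orderings = np.empty((n, n), dtype=int)
    for s0 in range(n):
        in_cluster = np.zeros(n, dtype=bool)
        dist_to_cluster = D[s0].copy()
        in_cluster[s0] = True
        orderings[s0, 0] = s0
        for step in range(1, n):
            cand = np.where(in_cluster, np.inf, dist_to_cluster)
            best = np.lexsort((numbers, cand))[0]
            orderings[s0, step] = best
            in_cluster[best] = True
            dist_to_cluster = np.minimum(dist_to_cluster, D[best])
    return orderings


def core_clustering(
    s: Structure,
    chain: str,
    pattern_residues,
    n_perm: int = 999,
    seed: int = 0,
) -> ClusterResult:
    """Is a mark set clustered within a chain, with no interface knowledge?

    Growth orderings are built from every seed residue; the observed
    statistic is the best (smallest) min-hypergeometric raw p over all
    orderings.  The permutation null shuffles the marks and repeats the full
    best-over-seeds scan, so the seed-selection multiplicity is calibrated
    into the adjusted p-value.
    """
    if n_perm < 99:
        raise DomainError("use at least 99 permutations")
    residues = s.chain(chain)
    if len(residues) < 3:
        raise DomainError("core clustering needs at least 3 residues")
    labels = [r.label for r in residues]
    marks = _marks_for(labels, pattern_residues)
    K = int(marks.sum())
    if K == 0:
        raise DomainError("the scan needs at least one marked residue")
    coords = s.ca_coords(chain)
    D = cdist(coords, coords)
    numbers = np.array([r.number for r in residues], dtype=float)
    orderings = _growth_orderings(D, numbers)  # (n_seeds, N)
    N = len(residues)
    table = _sf_table(N, K)
    k = np.arange(1, N + 1)[None, :]

    def best_over_seeds(m: np.ndarray) -> tuple[float, int, int]:
        ordered = m[orderings]
        x = np.cumsum(ordered, axis=1)
        ps = table[x, k]
        # report the best prefix among those ending at a mark (same minimum)
        flat = int(np.argmin(np.where(ordered, ps, np.inf)))
        si, kk = divmod(flat, N)
        return float(ps[si, kk]), si, kk + 1

    obs_p, best_seed, k_star = best_over_seeds(marks)
    best_order = orderings[best_seed]
    x_star = int(marks[best_order[:k_star]].sum())
    rng = np.random.default_rng(seed)
    perm = rng.permuted(np.tile(marks, (n_perm, 1)), axis=1)
    # vectorized best-over-seeds for all permutations
    x_all = np.cumsum(perm[:, orderings], axis=2)  # (n_perm, n_seeds, N)
    perm_best = table[x_all, k[None, :, :]].min(axis=(1, 2))
    count = int((perm_best <= obs_p + 1e-15).sum())
    return ClusterResult(
        k_star=k_star,
        x_star=x_star,
        raw_p=obs_p,
        adjusted_p=(1 + count) / (n_perm + 1),
        n_permutations=n_perm,
        seed=seed,
        ordering=[labels[i] for i in best_order],
        marks=list(marks[best_order]),
    )
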