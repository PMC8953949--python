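"""Hierarchical subgroup partitioning of an MSA by pattern selection.

The sampler splits a superfamily alignment into a tree of subgroups, each
non-root node characterized by *pattern positions*: alignment columns whose
residue set is differentially conserved in the node's foreground (its
subtree) relative to its background (the rest of the parent's subtree).

The contrast statistic for one column is the upper tail of a hypergeometric
("ball in urn") draw: pooling foreground and background residues at that
column, the probability of drawing at least the observed number of
foreground matches.  A +1 pseudocount on the background keeps perfectly
clean columns finite.  Scores are reported as -log10 of that tail.

Optimization alternates (a) greedy/annealed reassignment of sequences along
the tree by pattern-match log-odds, (b) per-node pattern re-selection, and
(c) split/prune proposals accepted on objective improvement, where the
objective is the summed pattern score minus a per-position penalty.  Point
estimates, not posteriors, are returned.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans

from ._hyper import log_hypergeom_sf

from .errors import AlignmentError, DomainError, SpecError
from .msa import AMINO_ACIDS, GAP_CODE, UNKNOWN_CODE, MSA, AlignedSequence, encode_residues

_LN10 = math.log(10.0)


# ---------------------------------------------------------------------------
# contrast statistic
# ---------------------------------------------------------------------------

def _contrast_scores(fg_m, fg_t, bg_m, bg_t):
    """Vectorized -log10 hypergeometric upper tail with +1 background pseudocount."""
    fg_m = np.asarray(fg_m, dtype=np.int64)
    fg_t = np.asarray(fg_t, dtype=np.int64)
    bg_m = np.asarray(bg_m, dtype=np.int64) + 1
    bg_t = np.asarray(bg_t, dtype=np.int64) + 1
    K = fg_m + bg_m  # marked in the urn
    N = fg_t + bg_t  # urn size
    # P(X >= fg_m) with X ~ Hypergeom(N, K, draws=fg_t)
    logp = log_hypergeom_sf(fg_m, N, K, fg_t)
    return np.maximum(0.0, -logp / _LN10) + 0.0


def contrast_score(fg_matches: int, fg_total: int, bg_matches: int, bg_total: int) -> float:
    """Enrichment of a residue set in the foreground over the background.

    Returns -log10 P(X >= fg_matches) for a hypergeometric draw of
    ``fg_total`` balls from the pooled urn, after adding a +1 pseudocount to
    the background counts.  Zero when there is no enrichment.
    """
    if fg_total <= 0 or bg_total <= 0:
        raise DomainError("fg_total and bg_total must be positive")
    if not (0 <= fg_matches <= fg_total) or not (0 <= bg_matches <= bg_total):
        raise DomainError("matches must lie within their totals")
    return float(_contrast_scores(fg_matches, fg_total, bg_matches, bg_total))


# ---------------------------------------------------------------------------
# pattern data model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PatternPosition:
    """One subgroup-distinguishing alignment column."""

    column: int  # 1-based MSA column
    residue_set: str  # 1-3 amino-acid letters, sorted
    fg_matches: int
    fg_total: int
    bg_matches: int
    bg_total: int
    score: float  # -log10 contrast tail


@dataclass
class HierarchyNode:
    node_id: int
    parent_id: int | None
    member_ids: set[str] = field(default_factory=set)
    pattern: list[PatternPosition] = field(default_factory=list)


class Hierarchy:
    """Tree of subgroups over an MSA.

    ``foreground(v)`` is the union of member sets over v's subtree;
    ``background(v)`` is ``foreground(parent(v))`` minus ``foreground(v)``.
    Direct member sets partition the sequence ids.
    """

    def __init__(self, nodes: list[HierarchyNode]):
        self.nodes: dict[int, HierarchyNode] = {n.node_id: n for n in nodes}
        if len(self.nodes) != len(nodes):
            raise DomainError("duplicate node ids")
        roots = [n.node_id for n in nodes if n.parent_id is None]
        if len(roots) != 1:
            raise DomainError("hierarchy must have exactly one root")
        self.root_id = roots[0]
        self._children: dict[int, list[int]] = {n.node_id: [] for n in nodes}
        for n in nodes:
            if n.parent_id is not None:
                if n.parent_id not in self.nodes:
                    raise DomainError(f"dangling parent {n.parent_id}")
                self._children[n.parent_id].append(n.node_id)
        # connected & acyclic: every node reachable from the root
        seen: set[int] = set()
        stack = [self.root_id]
        while stack:
            v = stack.pop()
            if v in seen:
                raise DomainError("cycle in hierarchy")
            seen.add(v)
            stack.extend(self._children[v])
        if seen != set(self.nodes):
            raise DomainError("hierarchy is not connected")
        # disjoint direct membership
        all_ids: set[str] = set()
        for n in nodes:
            if n.member_ids & all_ids:
                raise DomainError("node member sets are not disjoint")
            all_ids |= n.member_ids
        if self.nodes[self.root_id].pattern:
            raise DomainError("the root carries no pattern")

    def children(self, node_id: int) -> list[int]:
        return list(self._children[node_id])

    def subtree(self, node_id: int) -> list[int]:
        out, stack = [], [node_id]
        while stack:
            v = stack.pop()
            out.append(v)
            stack.extend(self._children[v])
        return out

    def foreground(self, node_id: int) -> set[str]:
        out: set[str] = set()
        for v in self.subtree(node_id):
            out |= self.nodes[v].member_ids
        return out

    def background(self, node_id: int) -> set[str]:
        parent = self.nodes[node_id].parent_id
        if parent is None:
            return set()
        return self.foreground(parent) - self.foreground(node_id)

    def all_member_ids(self) -> set[str]:
        return self.foreground(self.root_id)

    def depth(self, node_id: int) -> int:
        d, v = 0, node_id
        while self.nodes[v].parent_id is not None:
            v = self.nodes[v].parent_id
            d += 1
        return d

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        payload = []
        for nid in sorted(self.nodes):
            n = self.nodes[nid]
            payload.append(
                {
                    "node_id": n.node_id,
                    "parent_id": n.parent_id,
                    "member_ids": sorted(n.member_ids),
                    "pattern": [asdict(p) for p in n.pattern],
                }
            )
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "Hierarchy":
        nodes = []
        for item in json.loads(text):
            nodes.append(
                HierarchyNode(
                    node_id=item["node_id"],
                    parent_id=item["parent_id"],
                    member_ids=set(item["member_ids"]),
                    pattern=[PatternPosition(**p) for p in item["pattern"]],
                )
            )
        return cls(nodes)

    def to_newick(self) -> str:
        def rec(v: int) -> str:
            kids = self._children[v]
            label = f"n{v}_{len(self.nodes[v].member_ids)}"
            if not kids:
                return label
            return "(" + ",".join(rec(k) for k in sorted(kids)) + ")" + label

        return rec(self.root_id) + ";"


def patterns_to_tsv(h: Hierarchy) -> str:
    """Pattern table: node_id, column, residue_set, score and counts."""
    lines = ["node_id\tcolumn\tresidue_set\tscore\tfg_matches\tfg_total\tbg_matches\tbg_total"]
    for nid in sorted(h.nodes):
        for p in h.nodes[nid].pattern:
            lines.append(
                f"{nid}\t{p.column}\t{p.residue_set}\t{p.score:.4f}\t"
                f"{p.fg_matches}\t{p.fg_total}\t{p.bg_matches}\t{p.bg_total}"
            )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# sampler configuration
# ---------------------------------------------------------------------------

@dataclass
class SamplerConfig:
    """Knobs of the hierarchy sampler.

    ``fixed_shape`` is a nested tuple of child shapes (``()`` is a leaf;
    ``((), ())`` a root with two leaf children); when None the tree is
    searched by split/prune proposals bounded by ``max_depth`` and
    ``max_children``.  ``pattern_penalty`` is the score cost per pattern
    position; ``split_margin`` the minimum objective gain to accept a split.
    """

    fixed_shape: tuple | None = None
    max_depth: int = 2
    max_children: int = 3
    min_node_size: int = 10
    max_pattern_positions: int = 20
    pattern_penalty: float = 6.0
    n_sweeps: int = 20
    n_restarts: int = 4
    split_margin: float = 10.0
    t0: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.max_depth < 0 or self.max_children < 1 or self.min_node_size < 1:
            raise SpecError("tree-shape bounds must be positive")
        if self.n_sweeps < 1 or self.n_restarts < 1:
            raise SpecError("n_sweeps and n_restarts must be >= 1")
        if self.pattern_penalty < 0 or self.max_pattern_positions < 1:
            raise SpecError("penalty must be >= 0 and max positions >= 1")


def two_level_shape() -> tuple:
    """Fixed 2 x 2 topology matching the default planted hierarchy."""
    return (((), ()), ((), ()))


# ---------------------------------------------------------------------------
# column counts and pattern selection
# ---------------------------------------------------------------------------

def _column_counts(mat: np.ndarray) -> np.ndarray:
    """(m, L) coded rows -> (L, 22) per-column residue counts."""
    m, L = mat.shape
    if m == 0:
        return np.zeros((L, 22), dtype=np.int64)
    idx = mat.astype(np.int64) + 22 * np.arange(L)[None, :]
    return np.bincount(idx.ravel(), minlength=22 * L).reshape(L, 22)


def _select_pattern_from_counts(
    counts_fg: np.ndarray,
    counts_bg: np.ndarray,
    n_fg: int,
    cfg: SamplerConfig,
) -> list[PatternPosition]:
    """Greedy residue-set growth per column, then top columns by score."""
    L = counts_fg.shape[0]
    aa_fg = counts_fg[:, :20]
    aa_bg = counts_bg[:, :20]
    tot_fg = counts_fg[:, :20].sum(1) + counts_fg[:, UNKNOWN_CODE]
    tot_bg = counts_bg[:, :20].sum(1) + counts_bg[:, UNKNOWN_CODE]
    gap_frac_fg = counts_fg[:, GAP_CODE] / max(n_fg, 1)
    eligible = (tot_fg > 0) & (tot_bg > 0) & (gap_frac_fg <= 0.5)
    if not eligible.any():
        return []

    in_set = np.zeros((L, 20), dtype=bool)
    modal = aa_fg.argmax(axis=1)
    rows = np.arange(L)
    in_set[rows, modal] = True
    cur_fg = aa_fg[rows, modal]
    cur_bg = aa_bg[rows, modal]
    safe_tot_fg = np.maximum(tot_fg, 1)
    safe_tot_bg = np.maximum(tot_bg, 1)
    score = _contrast_scores(cur_fg, safe_tot_fg, cur_bg, safe_tot_bg)
    for _ in range(2):  # grow sets to at most 3 residues
        cand_fg = cur_fg[:, None] + aa_fg
        cand_bg = cur_bg[:, None] + aa_bg
        allowed = (~in_set) & (aa_fg > 0)
        cand_scores = np.where(
            allowed,
            _contrast_scores(cand_fg, safe_tot_fg[:, None], cand_bg, safe_tot_bg[:, None]),
            -np.inf,
        )
        best = cand_scores.argmax(axis=1)
        best_score = cand_scores[rows, best]
        improve = best_score > score + 1e-9
        if not improve.any():
            break
        in_set[rows[improve], best[improve]] = True
        cur_fg = np.where(improve, cand_fg[rows, best], cur_fg)
        cur_bg = np.where(improve, cand_bg[rows, best], cur_bg)
        score = np.where(improve, best_score, score)

    score = np.where(eligible, score, 0.0)
    keep = np.flatnonzero(score > cfg.pattern_penalty)
    if keep.size == 0:
        return []
    # descending score, ties by ascending column
    order = keep[np.lexsort((keep, -score[keep]))][: cfg.max_pattern_positions]
    out = []
    for c in order:
        residues = "".join(sorted(AMINO_ACIDS[i] for i in np.flatnonzero(in_set[c])))
        out.append(
            PatternPosition(
                column=int(c) + 1,
                residue_set=residues,
                fg_matches=int(cur_fg[c]),
                fg_total=int(tot_fg[c]),
                bg_matches=int(cur_bg[c]),
                bg_total=int(tot_bg[c]),
                score=float(score[c]),
            )
        )
    return out


def select_pattern(msa: MSA, fg: set[str], bg: set[str],
                   cfg: SamplerConfig = SamplerConfig()) -> list[PatternPosition]:
    """Pattern positions distinguishing foreground from background sequences.

    Residue sets grow greedily from the modal foreground residue while the
    contrast score increases (at most 3 residues); columns with more than
    50% foreground gaps are ineligible; only columns scoring above the
    per-position penalty are returned, best first.
    """
    if not fg or not bg:
        raise DomainError("foreground and background must both be non-empty")
    if fg & bg:
        raise DomainError("foreground and background must be disjoint")
    mat = msa.to_matrix()
    fg_rows = np.array([msa.index_of(i) for i in sorted(fg)])
    bg_rows = np.array([msa.index_of(i) for i in sorted(bg)])
    return _select_pattern_from_counts(
        _column_counts(mat[fg_rows]), _column_counts(mat[bg_rows]), len(fg_rows), cfg
    )


def _pattern_weights(pattern: list[PatternPosition]):
    """Per-position Bernoulli log-odds (Laplace-smoothed) for assignment.

    Returns (columns0, match_lo, miss_lo): a sequence scores ``match_lo[j]``
    when its residue at column j is in the set, ``miss_lo[j]`` for any other
    amino acid, and 0 for gaps/unknowns.
    """
    cols = np.array([p.column - 1 for p in pattern], dtype=int)
    pf = np.array([(p.fg_matches + 1) / (p.fg_total + 2) for p in pattern])
    pb = np.array([(p.bg_matches + 1) / (p.bg_total + 2) for p in pattern])
    match_lo = np.log(pf / pb)
    miss_lo = np.log((1 - pf) / (1 - pb))
    sets = [frozenset(p.residue_set) for p in pattern]
    return cols, match_lo, miss_lo, sets


def _pattern_scores_for_rows(mat: np.ndarray, pattern: list[PatternPosition]) -> np.ndarray:
    """Total pattern-match log-odds of each row of `mat` against `pattern`."""
    if not pattern:
        return np.zeros(mat.shape[0])
    cols, match_lo, miss_lo, sets = _pattern_weights(pattern)
    total = np.zeros(mat.shape[0])
    for j, (c, s) in enumerate(zip(cols, sets)):
        codes = mat[:, c]
        set_codes = np.array([AMINO_ACIDS.index(r) for r in s])
        is_match = np.isin(codes, set_codes)
        is_aa = codes < GAP_CODE
        total += np.where(is_match, match_lo[j], np.where(is_aa, miss_lo[j], 0.0))
    return total


# ---------------------------------------------------------------------------
# objective and classification
# ---------------------------------------------------------------------------

def objective(msa: MSA, h: Hierarchy, pattern_penalty: float = 6.0) -> float:
    """Summed pattern score minus per-position penalty, over non-root nodes."""
    if h.all_member_ids() != set(msa.ids):
        raise DomainError("hierarchy membership does not match the MSA")
    total = 0.0
    for nid, node in h.nodes.items():
        if nid == h.root_id:
            continue
        total += sum(p.score for p in node.pattern) - pattern_penalty * len(node.pattern)
    return total


def classify(h: Hierarchy, msa: MSA, seq: AlignedSequence) -> list[int]:
    """Greedy root-to-node descent of one aligned sequence.

    At each node, moves to the child whose pattern log-odds is highest and
    positive; stops otherwise.  Returns the visited node-id path.
    """
    if len(seq.residues) != msa.n_columns:
        raise AlignmentError("sequence is not aligned to the MSA columns")
    row = encode_residues(seq.residues)[None, :]
    path = [h.root_id]
    while True:
        kids = h.children(path[-1])
        if not kids:
            return path
        scores = [float(_pattern_scores_for_rows(row, h.nodes[k].pattern)[0]) for k in kids]
        best = int(np.argmax(scores))
        if scores[best] <= 0:
            return path
        path.append(kids[best])


# ---------------------------------------------------------------------------
# the sampler
# ---------------------------------------------------------------------------

class PatternHierarchyClusterer(BaseEstimator):
    """Estimator interface to the hierarchy sampler.

    ``fit(msa)`` runs annealed restarts and keeps the best-objective
    hierarchy.  Fitted attributes: ``hierarchy_``, ``labels_`` (terminal
    node id per sequence, in MSA order), ``objective_``.
    """

    def __init__(
        self,
        fixed_shape: tuple | None = None,
        max_depth: int = 2,
        max_children: int = 3,
        min_node_size: int = 10,
        max_pattern_positions: int = 20,
        pattern_penalty: float = 6.0,
        n_sweeps: int = 20,
        n_restarts: int = 4,
        split_margin: float = 10.0,
        t0: float = 1.0,
        random_state: int = 0,
    ):
        self.fixed_shape = fixed_shape
        self.max_depth = max_depth
        self.max_children = max_children
        self.min_node_size = min_node_size
        self.max_pattern_positions = max_pattern_positions
        self.pattern_penalty = pattern_penalty
        self.n_sweeps = n_sweeps
        self.n_restarts = n_restarts
        self.split_margin = split_margin
        self.t0 = t0
        self.random_state = random_state

    def _config(self) -> SamplerConfig:
        return SamplerConfig(
            fixed_shape=self.fixed_shape,
            max_depth=self.max_depth,
            max_children=self.max_children,
            min_node_size=self.min_node_size,
            max_pattern_positions=self.max_pattern_positions,
            pattern_penalty=self.pattern_penalty,
            n_sweeps=self.n_sweeps,
            n_restarts=self.n_restarts,
            split_margin=self.split_margin,
            t0=self.t0,
            seed=self.random_state,
        )

    # -- tree bookkeeping (plain dicts during sampling) ---------------------

    @staticmethod
    def _build_shape(shape: tuple) -> tuple[dict[int, list[int]], dict[int, int]]:
        children: dict[int, list[int]] = {0: []}
        parent: dict[int, int] = {}
        next_id = 1

        def rec(node: int, sub: tuple):
            nonlocal next_id
            for child_shape in sub:
                cid = next_id
                next_id += 1
                children[cid] = []
                children[node].append(cid)
                parent[cid] = node
                rec(cid, child_shape)

        rec(0, shape)
        return children, parent

    @staticmethod
    def _subtree(children: dict[int, list[int]], v: int) -> list[int]:
        out, stack = [], [v]
        while stack:
            u = stack.pop()
            out.append(u)
            stack.extend(children[u])
        return out

    def _node_patterns(self, mat, assign, children, parent, cfg):
        """Re-select every non-root node's pattern from current assignments."""
        direct = {
            v: _column_counts(mat[assign == v]) for v in children
        }
        sub_counts = {}

        def agg(v: int):
            c = direct[v].copy()
            for k in children[v]:
                c += agg(k)
            sub_counts[v] = c
            return c

        agg(0)
        n_direct = {v: int((assign == v).sum()) for v in children}
        n_sub = {v: sum(n_direct[u] for u in self._subtree(children, v)) for v in children}
        patterns: dict[int, list[PatternPosition]] = {0: []}
        for v in children:
            if v == 0:
                continue
            p = parent[v]
            counts_bg = sub_counts[p] - sub_counts[v]
            n_fg = n_sub[v]
            n_bg = n_sub[p] - n_fg
            if n_fg == 0 or n_bg == 0:
                patterns[v] = []
            else:
                patterns[v] = _select_pattern_from_counts(
                    sub_counts[v], counts_bg, n_fg, cfg
                )
        return patterns

    def _reassign(self, mat, assign, children, patterns, temperature, rng):
        """Route every sequence from the root down by pattern log-odds."""
        n = mat.shape[0]
        new_assign = np.zeros(n, dtype=int)
        frontier = {0: np.arange(n)}
        order = self._subtree(children, 0)
        node_scores = {
            v: _pattern_scores_for_rows(mat, patterns.get(v, [])) for v in order if v != 0
        }
        for v in order:
            idx = frontier.get(v)
            if idx is None or idx.size == 0:
                continue
            kids = children[v]
            if not kids:
                new_assign[idx] = v
                continue
            opts = np.zeros((idx.size, 1 + len(kids)))
            for j, k in enumerate(kids):
                opts[:, 1 + j] = node_scores[k][idx]
            if temperature > 1e-9:
                gumbel = rng.gumbel(size=opts.shape)
                choice = (opts / temperature + gumbel).argmax(axis=1)
            else:
                choice = opts.argmax(axis=1)
            stay = choice == 0
            new_assign[idx[stay]] = v
            for j, k in enumerate(kids):
                sel = idx[choice == 1 + j]
                if sel.size:
                    frontier[k] = np.concatenate([frontier.get(k, np.empty(0, int)), sel])
        return new_assign

    @staticmethod
    def _objective_from_patterns(patterns, cfg) -> float:
        return sum(
            sum(p.score for p in pat) - cfg.pattern_penalty * len(pat)
            for v, pat in patterns.items()
            if v != 0
        )

    def _local_split(self, mat, rows, k, cfg, rng, n_iter=8):
        """Partition `rows` into k groups: k-means seed + pattern-EM refinement."""
        onehot = np.eye(22, dtype=np.float32)[mat[rows]].reshape(rows.size, -1)
        km = KMeans(n_clusters=k, n_init=2,
                    random_state=int(rng.integers(2**31 - 1))).fit(onehot)
        labels = km.labels_.copy()
        sub = mat[rows]
        for _ in range(n_iter):
            scores = np.zeros((rows.size, k))
            for g in range(k):
                fg = np.flatnonzero(labels == g)
                bg = np.flatnonzero(labels != g)
                if fg.size == 0 or bg.size == 0:
                    continue
                pat = _select_pattern_from_counts(
                    _column_counts(sub[fg]), _column_counts(sub[bg]), fg.size, cfg
                )
                scores[:, g] = _pattern_scores_for_rows(sub, pat)
            new_labels = scores.argmax(axis=1)
            # keep every group populated
            for g in range(k):
                if not (new_labels == g).any():
                    new_labels[int(rng.integers(rows.size))] = g
            if (new_labels == labels).all():
                break
            labels = new_labels
        return labels

    def _divisive_init(self, mat, children, cfg, rng):
        """Top-down construction: split each node's members among its children."""
        n = mat.shape[0]
        assign = np.zeros(n, dtype=int)
        stack = [(0, np.arange(n))]
        while stack:
            v, rows = stack.pop()
            kids = children[v]
            assign[rows] = v
            if not kids or rows.size < len(kids):
                continue
            labels = self._local_split(mat, rows, len(kids), cfg, rng)
            for g, kid in enumerate(kids):
                stack.append((kid, rows[labels == g]))
        return assign

    def _node_contribution(self, mat, fg_rows, bg_rows, cfg) -> tuple[float, list]:
        if fg_rows.size == 0 or bg_rows.size == 0:
            return 0.0, []
        pat = _select_pattern_from_counts(
            _column_counts(mat[fg_rows]), _column_counts(mat[bg_rows]), fg_rows.size, cfg
        )
        return sum(p.score for p in pat) - cfg.pattern_penalty * len(pat), pat

    def _split_gain(self, mat_rows, cfg, rng):
        """Best one-group-vs-rest objective gain of an EM bisection of `mat_rows`."""
        m = mat_rows.shape[0]
        labels = self._local_split(mat_rows, np.arange(m), 2, cfg, rng, n_iter=4)
        best_gain, best_grp = -np.inf, None
        for lab in (0, 1):
            grp = np.flatnonzero(labels == lab)
            rest = np.flatnonzero(labels != lab)
            if grp.size < cfg.min_node_size or rest.size == 0:
                continue
            gain, _ = self._node_contribution(mat_rows, grp, rest, cfg)
            if gain > best_gain:
                best_gain, best_grp = gain, grp
        return best_gain, best_grp

    @staticmethod
    def _column_shuffle(mat_rows, rng):
        """Permute each column independently: destroys any row grouping while
        preserving per-column residue composition."""
        idx = np.argsort(rng.random(mat_rows.shape), axis=0)
        return mat_rows[idx, np.arange(mat_rows.shape[1])[None, :]]

    def _null_gain(self, mat_rows, cfg, rng, n_shuffles: int = 2) -> float:
        """Gain the bisection achieves on structure-free data: the greedy
        pattern search overfits exchangeable rows, so split acceptance is
        judged against this empirical null rather than zero."""
        best = 0.0
        for _ in range(n_shuffles):
            gain, _ = self._split_gain(self._column_shuffle(mat_rows, rng), cfg, rng)
            best = max(best, gain)
        return best

    def _propose_splits(self, mat, assign, children, parent, next_id, cfg, rng):
        """Add a child holding one EM-bisection group of a node's direct members.

        A split is accepted only when its objective gain beats the gain the
        same procedure achieves on column-shuffled (group-free) data by at
        least ``split_margin``.
        """
        for v in list(children):
            depth = 0
            u = v
            while u in parent:
                u = parent[u]
                depth += 1
            if depth >= cfg.max_depth or len(children[v]) >= cfg.max_children:
                continue
            direct = np.flatnonzero(assign == v)
            if direct.size < 2 * cfg.min_node_size:
                continue
            labels = self._local_split(mat[direct], np.arange(direct.size), 2, cfg, rng, n_iter=4)
            threshold = None
            for lab in (0, 1):
                if len(children[v]) >= cfg.max_children:
                    break
                grp_local = np.flatnonzero(labels == lab)
                rest_local = np.flatnonzero(labels != lab)
                if grp_local.size < cfg.min_node_size or rest_local.size == 0:
                    continue
                gain, _ = self._node_contribution(
                    mat[direct], grp_local, rest_local, cfg
                )
                if threshold is None:
                    threshold = self._null_gain(mat[direct], cfg, rng) + cfg.split_margin
                if gain > threshold:
                    cid = next_id
                    next_id += 1
                    children[cid] = []
                    children[v].append(cid)
                    parent[cid] = v
                    assign[direct[grp_local]] = cid
        return next_id

    def _prune(self, mat, assign, children, parent, cfg, rng):
        """Remove empty leaves and leaves whose contribution does not beat the
        column-shuffle null of their parent's subtree."""
        changed = True
        while changed:
            changed = False
            for v in list(children):
                if v == 0 or children[v]:
                    continue
                fg = np.flatnonzero(assign == v)
                p = parent[v]
                if fg.size == 0:
                    children[p].remove(v)
                    del children[v], parent[v]
                    changed = True
                    continue
                sub_rows = np.flatnonzero(np.isin(assign, self._subtree(children, p)))
                bg = np.setdiff1d(sub_rows, fg)
                gain, _ = self._node_contribution(mat, fg, bg, cfg)
                threshold = self._null_gain(mat[sub_rows], cfg, rng) + cfg.split_margin
                if gain <= threshold:
                    assign[fg] = p
                    children[p].remove(v)
                    del children[v], parent[v]
                    changed = True

    # -- main loop ----------------------------------------------------------

    def fit(self, msa: MSA, y=None):
        cfg = self._config()
        mat = msa.to_matrix()
        n = len(msa)
        if n == 0:
            raise DomainError("cannot partition an empty MSA")
        master = np.random.default_rng(cfg.seed)
        best = None  # (objective, assign, children, parent, patterns)
        adaptive = cfg.fixed_shape is None
        for _restart in range(cfg.n_restarts):
            rng = np.random.default_rng(master.integers(2**31 - 1))
            if adaptive:
                children, parent = {0: []}, {}
                assign = np.zeros(n, dtype=int)
                next_id = 1
            else:
                children, parent = self._build_shape(cfg.fixed_shape)
                next_id = max(children) + 1
                assign = self._divisive_init(mat, children, cfg, rng)
            for sweep in range(cfg.n_sweeps):
                frac = sweep / max(1, cfg.n_sweeps - 1)
                temperature = cfg.t0 * max(0.0, 1.0 - frac / 0.75)
                patterns = self._node_patterns(mat, assign, children, parent, cfg)
                assign = self._reassign(mat, assign, children, patterns, temperature, rng)
                if adaptive and sweep >= 1 and sweep % 2 == 1:
                    next_id = self._propose_splits(
                        mat, assign, children, parent, next_id, cfg, rng
                    )
            if adaptive:
                self._prune(mat, assign, children, parent, cfg, rng)
            # final greedy polish at zero temperature
            patterns = self._node_patterns(mat, assign, children, parent, cfg)
            assign = self._reassign(mat, assign, children, patterns, 0.0, rng)
            patterns = self._node_patterns(mat, assign, children, parent, cfg)
            obj = self._objective_from_patterns(patterns, cfg)
            if best is None or obj > best[0]:
                best = (obj, assign.copy(), dict(children), dict(parent), patterns)

        obj, assign, children, parent, patterns = best
        ids = msa.ids
        nodes = []
        for v in children:
            nodes.append(
                HierarchyNode(
                    node_id=v,
                    parent_id=parent.get(v),
                    member_ids={ids[i] for i in np.flatnonzero(assign == v)},
                    pattern=patterns.get(v, []) if v != 0 else [],
                )
            )
        self.hierarchy_ = Hierarchy(nodes)
        self.labels_ = assign
        self.objective_ = float(obj)
        return self

    def predict(self, msa_or_seqs) -> np.ndarray:
        """Terminal node of the greedy descent for each sequence."""
        h = self.hierarchy_
        if isinstance(msa_or_seqs, MSA):
            seqs = list(msa_or_seqs)
            ref = msa_or_seqs
        else:
            seqs = list(msa_or_seqs)
            ref = None
        out = []
        for s in seqs:
            row = encode_residues(s.residues)[None, :]
            path = [h.root_id]
            while True:
                kids = h.children(path[-1])
                if not kids:
                    break
                scores = [
                    float(_pattern_scores_for_rows(row, h.nodes[k].pattern)[0])
                    for k in kids
                ]
                b = int(np.argmax(scores))
                if scores[b] <= 0:
                    break
                path.append(kids[b])
            out.append(path[-1])
        return np.array(out)


def sample_hierarchy(msa: MSA, cfg: SamplerConfig = SamplerConfig()) -> Hierarchy:
    """Functional wrapper over :class:`PatternHierarchyClusterer`."""
    est = PatternHierarchyClusterer(
        fixed_shape=cfg.fixed_shape,
        max_depth=cfg.max_depth,
        max_children=cfg.max_children,
        min_node_size=cfg.min_node_size,
        max_pattern_positions=cfg.max_pattern_positions,
        pattern_penalty=cfg.pattern_penalty,
        n_sweeps=cfg.n_sweeps,
        n_restarts=cfg.n_restarts,
        split_margin=cfg.split_margin,
        t0=cfg.t0,
        random_state=cfg.seed,
    )
    return est.fit(msa).hierarchy_
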