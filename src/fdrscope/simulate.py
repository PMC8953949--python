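"""Planted-truth generators: hierarchical MSAs, toy complexes, binding curves.

Each generator is deterministic given its seed and returns both the data and
the planted truth, so every downstream stage of the pipeline can be tested
against a known answer without any external downloads.

The defaults define the package's reference study conditions: a two-level
subgroup hierarchy (2 families x 2 subfamilies, 200 sequences per leaf, five
pattern columns per node conserved with probability 0.95), a 60+60-residue
two-chain pseudo-C-alpha complex with an 8-residue cluster planted at the
interface (5 A radius, 8 A chain separation), and 12-point two-fold
saturation series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import SpecError
from .msa import AMINO_ACIDS, AlignedSequence, MSA
from .structure import Atom, Residue, Structure

#: Robinson & Robinson amino-acid background frequencies (order ACDEFGHIKLMNPQRSTVWY)
ROBINSON_FREQUENCIES = np.array(
    [
        0.07805, 0.01925, 0.05364, 0.06295, 0.03856, 0.07377, 0.02199,
        0.05142, 0.05744, 0.09019, 0.02243, 0.04487, 0.05203, 0.04264,
        0.05129, 0.07120, 0.05841, 0.06441, 0.01330, 0.03216,
    ]
)
ROBINSON_FREQUENCIES = ROBINSON_FREQUENCIES / ROBINSON_FREQUENCIES.sum()


# ---------------------------------------------------------------------------
# hierarchical MSA with planted subgroup patterns
# ---------------------------------------------------------------------------

@dataclass
class PlantedHierarchySpec:
    """A subgroup tree with per-node planted pattern columns.

    ``children`` maps node id -> list of child ids (node 0 is the root).
    ``pattern_columns`` / ``pattern_residues`` give, per node, the 1-based
    alignment columns and the single conserved letter planted at each; a
    foreground sequence carries the letter with probability
    ``pattern_strength`` (else background).  Pattern columns of a node must
    be disjoint from those of its ancestors.
    """

    children: dict[int, list[int]]
    n_sequences: dict[int, int]
    pattern_columns: dict[int, list[int]]
    pattern_residues: dict[int, str]
    pattern_strength: float = 0.95
    sequence_length: int = 120
    background_frequencies: np.ndarray = field(
        default_factory=lambda: np.full(20, 1.0 / 20.0)
    )
    seed: int = 0

    def __post_init__(self):
        if 0 not in self.node_ids():
            raise SpecError("the tree must contain a root node 0")
        if not (0.0 <= self.pattern_strength <= 1.0):
            raise SpecError("pattern_strength must be in [0, 1]")
        freqs = np.asarray(self.background_frequencies, dtype=float)
        if freqs.shape != (20,) or not np.isclose(freqs.sum(), 1.0) or (freqs < 0).any():
            raise SpecError("background_frequencies must be a 20-vector summing to 1")
        self.background_frequencies = freqs
        for node, n in self.n_sequences.items():
            if n < 0:
                raise SpecError(f"negative sequence count at node {node}")
        for node, cols in self.pattern_columns.items():
            residues = self.pattern_residues.get(node, "")
            if len(residues) != len(cols):
                raise SpecError(f"node {node}: one pattern residue per pattern column")
            for c in cols:
                if not (1 <= c <= self.sequence_length):
                    raise SpecError(f"node {node}: column {c} outside the alignment")
            for r in residues:
                if r not in AMINO_ACIDS:
                    raise SpecError(f"node {node}: illegal pattern residue '{r}'")
        # pattern columns disjoint along every root-to-node lineage
        parent = self.parent_map()
        for node in self.node_ids():
            seen: set[int] = set()
            cur: int | None = node
            while cur is not None:
                cols = set(self.pattern_columns.get(cur, []))
                if cols & seen:
                    raise SpecError(
                        f"pattern columns of node {cur} overlap a descendant's on the "
                        f"lineage of node {node}"
                    )
                seen |= cols
                cur = parent.get(cur)

    def node_ids(self) -> set[int]:
        ids = set(self.children)
        for kids in self.children.values():
            ids.update(kids)
        return ids

    def parent_map(self) -> dict[int, int]:
        return {kid: node for node, kids in self.children.items() for kid in kids}

    def lineage(self, node: int) -> list[int]:
        """Root-to-node path."""
        parent = self.parent_map()
        path = [node]
        while path[-1] in parent:
            path.append(parent[path[-1]])
        return path[::-1]

    def leaves(self) -> list[int]:
        return sorted(n for n in self.node_ids() if not self.children.get(n))


@dataclass
class HierarchyTruth:
    """Planted truth for a generated MSA."""

    assignment: dict[str, int]  # sequence id -> generating node
    pattern_columns: dict[int, list[int]]
    pattern_residues: dict[int, str]
    spec: PlantedHierarchySpec


def default_two_level_spec(seed: int = 0, pattern_strength: float = 0.95,
                           n_per_leaf: int = 200) -> PlantedHierarchySpec:
    """Reference conditions: 2 families x 2 subfamilies, 5 columns per node."""
    return PlantedHierarchySpec(
        children={0: [1, 2], 1: [3, 4], 2: [5, 6]},
        n_sequences={3: n_per_leaf, 4: n_per_leaf, 5: n_per_leaf, 6: n_per_leaf},
        pattern_columns={
            1: [5, 15, 25, 35, 45],
            2: [10, 20, 30, 40, 50],
            3: [55, 65, 75, 85, 95],
            4: [60, 70, 80, 90, 100],
            5: [56, 66, 76, 86, 96],
            6: [61, 71, 81, 91, 101],
        },
        pattern_residues={
            1: "WWWWW", 2: "CCCCC", 3: "HHHHH", 4: "MMMMM", 5: "YYYYY", 6: "FFFFF",
        },
        pattern_strength=pattern_strength,
        sequence_length=120,
        seed=seed,
    )


def gen_hierarchical_msa(spec: PlantedHierarchySpec) -> tuple[MSA, HierarchyTruth]:
    """Draw sequences column-wise from the background, planting node patterns.

    Every sequence generated at a node carries, at each pattern column of
    every node on its root-to-node lineage, that node's letter with
    probability ``pattern_strength``.
    """
    rng = np.random.default_rng(spec.seed)
    letters = np.array(list(AMINO_ACIDS))
    seqs: list[AlignedSequence] = []
    assignment: dict[str, int] = {}
    for node in sorted(spec.n_sequences):
        n = spec.n_sequences[node]
        if n == 0:
            continue
        lineage = spec.lineage(node)
        block = rng.choice(20, size=(n, spec.sequence_length),
                           p=spec.background_frequencies)
        for anc in lineage:
            cols = spec.pattern_columns.get(anc, [])
            res = spec.pattern_residues.get(anc, "")
            for col, letter in zip(cols, res):
                hit = rng.random(n) < spec.pattern_strength
                block[hit, col - 1] = AMINO_ACIDS.index(letter)
        for i in range(n):
            sid = f"n{node}_s{i}"
            seqs.append(AlignedSequence(sid, "".join(letters[block[i]])))
            assignment[sid] = node
    if not seqs:
        raise SpecError("spec generates no sequences")
    truth = HierarchyTruth(
        assignment=assignment,
        pattern_columns=dict(spec.pattern_columns),
        pattern_residues=dict(spec.pattern_residues),
        spec=spec,
    )
    return MSA(seqs), truth


# ---------------------------------------------------------------------------
# toy two-chain complex with a planted interface cluster
# ---------------------------------------------------------------------------

@dataclass
class PlantedComplexSpec:
    """A two-chain pseudo-C-alpha complex with a planted residue cluster.

    Chain residues are laid down by a self-avoiding 3.8-A random walk pulled
    toward its centroid (a compact globule); the chains are then separated
    along x so their closest approach is about ``interface_offset``; finally
    the planted residues of chain A are relocated into a sphere of
    ``cluster_radius`` centred on the interface midpoint.
    """

    n_residues_a: int = 60
    n_residues_b: int = 60
    planted_cluster: tuple[int, ...] = (3, 10, 17, 24, 31, 38, 45, 52)
    cluster_radius: float = 5.0
    interface_offset: float = 8.0
    seed: int = 0

    def __post_init__(self):
        if self.n_residues_a < 3 or self.n_residues_b < 3:
            raise SpecError("each chain needs at least 3 residues")
        if self.cluster_radius <= 0 or self.interface_offset <= 0:
            raise SpecError("radius and offset must be positive")
        if len(self.planted_cluster) > self.n_residues_a:
            raise SpecError("planted cluster larger than chain A")
        for i in self.planted_cluster:
            if not (1 <= i <= self.n_residues_a):
                raise SpecError(f"planted residue {i} outside chain A (1-based)")


@dataclass
class ComplexTruth:
    planted_labels: list[str]  # author-number labels on chain A
    interface_midpoint: np.ndarray
    spec: PlantedComplexSpec


_STEP = 3.8  # C-alpha virtual bond length, Angstroms
_MIN_SEP = 3.4  # self-avoidance distance


def _globule_walk(n: int, rng: np.random.Generator) -> np.ndarray:
    """Self-avoiding random walk with a centroid pull; 3.8-A steps."""
    pts = [np.zeros(3)]
    for _ in range(1, n):
        placed = False
        for _attempt in range(200):
            direction = rng.normal(size=3)
            # pull toward the running centroid to keep the chain compact
            centroid = np.mean(pts, axis=0)
            pull = centroid - pts[-1]
            norm = np.linalg.norm(pull)
            if norm > 1e-9:
                direction = direction + 0.6 * pull / norm * np.linalg.norm(direction)
            direction = direction / np.linalg.norm(direction)
            cand = pts[-1] + _STEP * direction
            d = np.linalg.norm(np.array(pts) - cand, axis=1)
            if (d >= _MIN_SEP).all():
                pts.append(cand)
                placed = True
                break
        if not placed:  # pragma: no cover - extremely unlikely
            pts.append(pts[-1] + _STEP * direction)
    return np.array(pts)


def gen_complex_structure(spec: PlantedComplexSpec) -> tuple[Structure, ComplexTruth]:
    rng = np.random.default_rng(spec.seed)
    a = _globule_walk(spec.n_residues_a, rng)
    b = _globule_walk(spec.n_residues_b, rng)
    # separate chain B along +x so the closest approach ~ interface_offset
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    span = a[:, 0].max() - b[:, 0].min()
    b = b + np.array([span + spec.interface_offset, 0.0, 0.0])
    # tighten: shift until the true closest approach equals the offset
    from scipy.spatial.distance import cdist

    gap = cdist(a, b).min()
    b[:, 0] -= gap - spec.interface_offset
    d = cdist(a, b)
    i, j = np.unravel_index(np.argmin(d), d.shape)
    midpoint = (a[i] + b[j]) / 2.0
    # relocate planted residues into the interface sphere (self-avoiding,
    # and keeping clear of chain B)
    planted0 = [i - 1 for i in spec.planted_cluster]
    for idx in planted0:
        for _attempt in range(500):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            r = spec.cluster_radius * rng.random() ** (1.0 / 3.0)
            cand = midpoint + r * u
            others = np.delete(a, idx, axis=0)
            if (np.linalg.norm(others - cand, axis=1) >= 2.0).all() and (
                np.linalg.norm(b - cand, axis=1) >= 3.0
            ).all():
                a[idx] = cand
                break
        else:  # pragma: no cover - fallback: accept the last candidate
            a[idx] = cand

    def _chain(coords: np.ndarray) -> list[Residue]:
        return [
            Residue(number=k + 1, name="ALA", atoms=[Atom("CA", coords[k].copy())])
            for k in range(len(coords))
        ]

    structure = Structure({"A": _chain(a), "B": _chain(b)})
    truth = ComplexTruth(
        planted_labels=[str(i) for i in spec.planted_cluster],
        interface_midpoint=midpoint,
        spec=spec,
    )
    return structure, truth


# ---------------------------------------------------------------------------
# saturation-binding curves
# ---------------------------------------------------------------------------

@dataclass
class BindingSimSpec:
    """One-site saturation binding with optional Hill slope and Gaussian noise.

    A(L) = Amax * L^h / (Kd^h + L^h) + eps,  eps ~ N(0, noise_sd).
    Concentrations in nM, absorbance in OD units.
    """

    Amax: float = 1.0
    Kd: float = 20.0
    hill_h: float = 1.0
    concentrations: tuple[float, ...] = ()
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.Kd <= 0 or self.Amax <= 0:
            raise SpecError("Kd and Amax must be positive")
        if self.hill_h < 0:
            raise SpecError("hill_h must be >= 0")
        if self.noise_sd < 0:
            raise SpecError("noise_sd must be >= 0")
        if not self.concentrations:
            self.concentrations = tuple(twofold_series())
        if any(c <= 0 for c in self.concentrations):
            raise SpecError("concentrations must be positive")


def twofold_series(start: float = 0.25, n: int = 12) -> list[float]:
    """Two-fold dilution series in nM, ascending (default 0.25 ... 512 nM)."""
    return [start * 2.0 ** k for k in range(n)]


def gen_binding_curve(spec: BindingSimSpec):
    from .binding import BindingCurve, model_one_site

    rng = np.random.default_rng(spec.seed)
    L = np.asarray(spec.concentrations, dtype=float)
    A = model_one_site(L, spec.Amax, spec.Kd, spec.hill_h)
    if spec.noise_sd > 0:
        A = A + rng.normal(0.0, spec.noise_sd, size=L.shape)
    return BindingCurve(L=L, A=A)
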