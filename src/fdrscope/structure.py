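"""Structure I/O, interface geometry, sequence-structure mapping, superposition.

Structures are lightweight: chains of residues, each residue carrying one or
more atoms with coordinates in Angstroms and the author residue numbering of
the source file.  All-atom PDB input is accepted; the synthetic complexes
generated elsewhere in the package carry a single C-alpha point per residue.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import Align
from Bio.PDB import PDBParser
from Bio.SeqUtils import seq1
from scipy.spatial.distance import cdist

from .errors import (
    AlignmentError,
    DegenerateGeometryError,
    DomainError,
    EmptyStructureError,
)


@dataclass
class Atom:
    name: str
    coord: np.ndarray  # shape (3,), Angstroms
    occupancy: float = 1.0


@dataclass
class Residue:
    number: int  # author residue number as deposited
    name: str = "ALA"
    icode: str = ""  # insertion code, appended to the author number in labels
    atoms: list[Atom] = field(default_factory=list)

    @property
    def label(self) -> str:
        return f"{self.number}{self.icode}"

    @property
    def ca(self) -> Atom:
        for a in self.atoms:
            if a.name == "CA":
                return a
        return self.atoms[0]

    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms], dtype=float)

    @property
    def one_letter(self) -> str:
        code = seq1(self.name.capitalize())
        return code if code and code != " " else "X"


class Structure:
    """Chains of residues; author numbers are unique within a chain."""

    def __init__(self, chains: dict[str, list[Residue]]):
        for cid, residues in chains.items():
            if not residues:
                raise EmptyStructureError(f"chain {cid} has no residues")
            labels = [r.label for r in residues]
            if len(set(labels)) != len(labels):
                raise DomainError(f"duplicate author numbers in chain {cid}")
            for r in residues:
                if not r.atoms:
                    raise DomainError(f"residue {r.label} in chain {cid} has no atoms")
        self.chains = chains

    def chain(self, chain_id: str) -> list[Residue]:
        if chain_id not in self.chains:
            raise KeyError(f"chain '{chain_id}' not in structure")
        return self.chains[chain_id]

    def chain_sequence(self, chain_id: str) -> str:
        return "".join(r.one_letter for r in self.chain(chain_id))

    def ca_coords(self, chain_id: str) -> np.ndarray:
        return np.array([r.ca.coord for r in self.chain(chain_id)], dtype=float)


def read_structure(path: str | Path) -> Structure:
    """Parse the first model of a PDB file.

    HETATM records are skipped; for alternate locations the highest-occupancy
    conformer is kept; insertion codes are appended to author numbers.
    """
    parser = PDBParser(QUIET=True)
    model = next(parser.get_structure("s", str(path)).get_models(), None)
    if model is None:
        raise EmptyStructureError(f"no models in {path}")
    chains: dict[str, list[Residue]] = {}
    for bio_chain in model:
        residues: list[Residue] = []
        for bio_res in bio_chain:
            hetflag, resseq, icode = bio_res.id
            if hetflag.strip():
                continue  # HETATM / water
            atoms: list[Atom] = []
            for bio_atom in bio_res:
                if bio_atom.is_disordered():
                    alts = bio_atom.disordered_get_list()
                    chosen = max(alts, key=lambda a: (a.get_occupancy() or 0.0))
                else:
                    chosen = bio_atom
                atoms.append(
                    Atom(
                        name=chosen.get_name(),
                        coord=np.asarray(chosen.get_coord(), dtype=float),
                        occupancy=float(chosen.get_occupancy() or 1.0),
                    )
                )
            if atoms:
                residues.append(
                    Residue(
                        number=int(resseq),
                        name=bio_res.get_resname(),
                        icode=icode.strip(),
                        atoms=atoms,
                    )
                )
        if residues:
            chains[bio_chain.id] = residues
    if not chains:
        raise EmptyStructureError(f"no ATOM records in {path}")
    return Structure(chains)


def write_structure(s: Structure, path: str | Path) -> None:
    """Write ATOM records (PDB format, single model)."""
    lines = []
    serial = 1
    for cid in s.chains:
        for res in s.chains[cid]:
            for atom in res.atoms:
                name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
                x, y, z = atom.coord
                lines.append(
                    f"ATOM  {serial:5d} {name:<4s} {res.name:<3s} {cid}{res.number:4d}"
                    f"{res.icode or ' '}   {x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}"
                    f"{0.0:6.2f}          {atom.name[0]:>2s}"
                )
            serial += len(res.atoms)
        lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class InterfaceSet:
    """Residues of one chain near a partner chain, with contact distances."""

    chain: str
    partner: str
    cutoff: float
    labels: list[str]  # all residues of `chain`, file order
    distances: np.ndarray  # per-residue min inter-chain atom distance
    members: list[str]  # labels with distance <= cutoff


def _residue_atom_blocks(residues: list[Residue]) -> tuple[np.ndarray, np.ndarray]:
    coords = np.concatenate([r.coords() for r in residues], axis=0)
    owner = np.concatenate(
        [np.full(len(r.atoms), i) for i, r in enumerate(residues)]
    )
    return coords, owner


def min_interchain_distances(s: Structure, a: str, b: str) -> np.ndarray:
    """Minimum any-atom distance from each residue of chain `a` to chain `b`."""
    res_a = s.chain(a)
    coords_a, owner_a = _residue_atom_blocks(res_a)
    coords_b, _ = _residue_atom_blocks(s.chain(b))
    d = cdist(coords_a, coords_b).min(axis=1)
    out = np.full(len(res_a), np.inf)
    np.minimum.at(out, owner_a, d)
    return out


def interface_residues(s: Structure, a: str, b: str, cutoff: float = 5.0) -> InterfaceSet:
    """Chain-`a` residues with any atom within `cutoff` A of chain `b` (inclusive)."""
    dists = min_interchain_distances(s, a, b)
    res_a = s.chain(a)
    members = [r.label for r, d in zip(res_a, dists) if d <= cutoff]
    return InterfaceSet(
        chain=a,
        partner=b,
        cutoff=cutoff,
        labels=[r.label for r in res_a],
        distances=dists,
        members=members,
    )


@dataclass
class ResidueMap:
    """Colinear correspondence between sequence positions and author numbers."""

    pairs: list[tuple[int, str]]  # (1-based sequence position, residue label)
    coverage: float  # mapped fraction of the query sequence
    identity: float  # identity over aligned positions
    low_identity: bool  # set when identity < 0.30

    def to_structure(self, pos: int) -> str | None:
        for p, lab in self.pairs:
            if p == pos:
                return lab
        return None


def map_seq_to_structure(seq: str, s: Structure, chain: str) -> ResidueMap:
    """Map an ungapped sequence onto a chain by global alignment.

    Needleman-Wunsch with match +1, mismatch -1, gap -2; every aligned
    (non-gap vs non-gap) column becomes a map pair, substitutions included.
    A map with <30% identity is returned with ``low_identity`` set.
    """
    seq = seq.upper().replace("-", "")
    if not seq:
        raise AlignmentError("empty query sequence")
    chain_res = s.chain(chain)
    chain_seq = s.chain_sequence(chain)
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    aln = aligner.align(seq, chain_seq)[0]
    pairs: list[tuple[int, str]] = []
    matches = 0
    for (qs, qe), (ts, te) in zip(*aln.aligned):
        for k in range(qe - qs):
            qpos, tpos = qs + k, ts + k
            pairs.append((qpos + 1, chain_res[tpos].label))
            if seq[qpos] == chain_seq[tpos]:
                matches += 1
    identity = matches / len(pairs) if pairs else 0.0
    return ResidueMap(
        pairs=pairs,
        coverage=len(pairs) / len(seq),
        identity=identity,
        low_identity=identity < 0.30,
    )


def transfer_residues(msa, src_id: str, dst_id: str, positions: list[int]):
    """Carry ungapped positions of one MSA row to another via shared columns.

    For each 1-based ungapped position of `src_id`, finds its alignment
    column and reads the `dst_id` row there.  Returns a list of
    ``(dst_position_or_None, dst_letter_or_None)``; a gap in the destination
    yields ``(None, None)``.
    """
    src = msa[src_id].residues
    dst = msa[dst_id].residues
    # ungapped position -> column, per row
    src_cols = [c for c, ch in enumerate(src) if ch != "-"]
    dst_pos_at_col: dict[int, int] = {}
    p = 0
    for c, ch in enumerate(dst):
        if ch != "-":
            p += 1
            dst_pos_at_col[c] = p
    out: list[tuple[int | None, str | None]] = []
    for pos in positions:
        if not (1 <= pos <= len(src_cols)):
            raise DomainError(f"position {pos} out of range for '{src_id}'")
        col = src_cols[pos - 1]
        ch = dst[col]
        if ch == "-":
            out.append((None, None))
        else:
            out.append((dst_pos_at_col[col], ch))
    return out


@dataclass
class SuperpositionResult:
    rotation: np.ndarray  # (3, 3), proper rotation (det = +1)
    translation: np.ndarray  # (3,)
    rmsd: float

    def apply(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation.T + self.translation


def superpose(mobile: np.ndarray, target: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid superposition (Kabsch) of paired point sets.

    Finds the proper rotation R and translation t minimizing
    ``sum_i || R m_i + t - q_i ||^2`` and reports the post-fit RMSD.
    Requires at least three non-collinear pairs.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(target, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise DegenerateGeometryError("point sets must be matching (n, 3) arrays")
    if P.shape[0] < 3:
        raise DegenerateGeometryError("need at least 3 correspondence pairs")
    cm, cq = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - cm, Q - cq
    if np.linalg.matrix_rank(P0, tol=1e-8) < 2:
        raise DegenerateGeometryError("mobile points are collinear")
    H = P0.T @ Q0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cm
    moved = P @ R.T + t
    rmsd = float(np.sqrt(((moved - Q) ** 2).sum(axis=1).mean()))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd)
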