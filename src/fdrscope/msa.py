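"""Alignment containers, FASTA/Stockholm I/O, and sequence-level filters.

An :class:`MSA` is a rectangular block of aligned amino-acid sequences over
the 20-letter alphabet plus ``-`` (gap) and ``X`` (unknown).  Two filters are
provided: a fragment filter that drops rows whose gap fraction exceeds a
threshold, and a greedy redundancy filter that keeps one representative of
every group of near-identical sequences.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlignmentError, EmptyInputError, SpecError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
UNKNOWN = "X"
#: integer codes: 0..19 amino acids, 20 gap, 21 unknown
GAP_CODE = 20
UNKNOWN_CODE = 21
_CODE = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
_CODE[GAP] = GAP_CODE
_CODE[UNKNOWN] = UNKNOWN_CODE
_LETTER = np.array(list(AMINO_ACIDS + GAP + UNKNOWN))

_ENCODE_TABLE = np.full(128, -1, dtype=np.int8)
for _ch, _c in _CODE.items():
    _ENCODE_TABLE[ord(_ch)] = _c


@dataclass(frozen=True)
class AlignedSequence:
    """One row of an alignment."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self):
        if not self.id:
            raise AlignmentError("sequence id must be non-empty")
        bad = set(self.residues) - set(AMINO_ACIDS + GAP + UNKNOWN)
        if bad:
            raise AlignmentError(f"illegal characters in '{self.id}': {sorted(bad)}")

    @property
    def gap_fraction(self) -> float:
        if not self.residues:
            return 0.0
        return self.residues.count(GAP) / len(self.residues)

    def ungapped(self) -> str:
        return self.residues.replace(GAP, "")


class MSA:
    """A multiple sequence alignment: equal-length rows with unique ids."""

    def __init__(self, sequences: Iterable[AlignedSequence]):
        seqs = list(sequences)
        # empty alignments are representable (filters may remove everything)
        n = len(seqs[0].residues) if seqs else 0
        for s in seqs:
            if len(s.residues) != n:
                raise AlignmentError(
                    f"ragged alignment: '{s.id}' has length {len(s.residues)}, expected {n}"
                )
        ids = [s.id for s in seqs]
        if len(set(ids)) != len(ids):
            raise AlignmentError("duplicate sequence ids in MSA")
        self.sequences: list[AlignedSequence] = seqs
        self.n_columns: int = n
        self._index = {s.id: i for i, s in enumerate(seqs)}
        self._matrix: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self) -> Iterator[AlignedSequence]:
        return iter(self.sequences)

    def __getitem__(self, key) -> AlignedSequence:
        if isinstance(key, str):
            return self.sequences[self._index[key]]
        return self.sequences[key]

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self._index

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.sequences]

    def index_of(self, seq_id: str) -> int:
        return self._index[seq_id]

    def to_matrix(self) -> np.ndarray:
        """Integer-coded (n_sequences, n_columns) view; cached."""
        if self._matrix is None:
            flat = np.frombuffer(
                "".join(s.residues for s in self.sequences).encode("ascii"),
                dtype=np.uint8,
            )
            codes = _ENCODE_TABLE[flat]
            self._matrix = codes.reshape(len(self.sequences), self.n_columns).astype(np.int8)
        return self._matrix

    def subset(self, seq_ids: Iterable[str]) -> "MSA":
        return MSA([self[i] for i in seq_ids])


def encode_residues(residues: str) -> np.ndarray:
    """Integer-code a single row (same code table as :meth:`MSA.to_matrix`)."""
    flat = np.frombuffer(residues.encode("ascii"), dtype=np.uint8)
    codes = _ENCODE_TABLE[flat]
    if (codes < 0).any():
        raise AlignmentError("illegal characters in sequence")
    return codes.astype(np.int8)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for the fragment and redundancy filters.

    ``max_deletion_fraction``: rows with a gap fraction strictly above this
    are removed.  ``identity_threshold``: pairs at or above this identity are
    collapsed to the first-seen representative.
    """

    max_deletion_fraction: float = 0.25
    identity_threshold: float = 0.98

    def __post_init__(self):
        for name in ("max_deletion_fraction", "identity_threshold"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise SpecError(f"{name} must be in [0, 1], got {v}")


def _normalize(seq: str) -> str:
    return seq.upper().replace(".", GAP)


def read_msa(path: str | Path, format: str = "fasta") -> MSA:
    """Read an alignment from FASTA or Stockholm.

    ``.`` and ``-`` gaps are both accepted and normalized to ``-``.
    """
    if format not in ("fasta", "stockholm"):
        raise ValueError(f"unsupported format '{format}'")
    try:
        records = list(SeqIO.parse(str(path), format))
    except ValueError as exc:
        raise AlignmentError(f"cannot parse {path} as {format}: {exc}") from exc
    if not records:
        raise EmptyInputError(f"no sequences found in {path}")
    seqs = [
        AlignedSequence(r.id, _normalize(str(r.seq)), r.description if r.description != r.id else "")
        for r in records
    ]
    return MSA(seqs)


def write_msa(msa: MSA, path: str | Path, format: str = "fasta") -> None:
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description=s.description) for s in msa
    ]
    SeqIO.write(records, str(path), format)


def msa_from_strings(rows: dict[str, str]) -> MSA:
    """Convenience constructor from an ``{id: residues}`` mapping."""
    return MSA([AlignedSequence(k, _normalize(v)) for k, v in rows.items()])


def filter_fragments(msa: MSA, cfg: FilterConfig = FilterConfig()) -> MSA:
    """Drop sequence fragments: rows with gap fraction > ``max_deletion_fraction``.

    A row with a gap fraction exactly at the threshold is retained; the
    result may be empty.  Row order is preserved.
    """
    return MSA([s for s in msa if s.gap_fraction <= cfg.max_deletion_fraction])


def pairwise_identity(a: AlignedSequence, b: AlignedSequence) -> float:
    """Fraction of mutually non-gap columns at which the two rows agree.

    Returns 0.0 when the rows share no non-gap columns.
    """
    if len(a.residues) != len(b.residues):
        raise AlignmentError("pairwise identity needs equal-length rows")
    ca = encode_residues(a.residues)
    cb = encode_residues(b.residues)
    both = (ca != GAP_CODE) & (cb != GAP_CODE)
    denom = int(both.sum())
    if denom == 0:
        return 0.0
    return float((ca[both] == cb[both]).sum()) / denom


def dedupe(msa: MSA, cfg: FilterConfig = FilterConfig()) -> MSA:
    """Greedy first-wins redundancy filter.

    Scans rows in input order; a row is dropped when its identity with any
    already-retained row is >= ``identity_threshold`` (the boundary is
    inclusive: a pair at exactly the threshold is collapsed).
    """
    mat = msa.to_matrix()
    nongap = mat != GAP_CODE
    kept_idx: list[int] = []
    for i in range(len(msa)):
        redundant = False
        for j in kept_idx:
            both = nongap[i] & nongap[j]
            denom = int(both.sum())
            ident = 0.0 if denom == 0 else float((mat[i, both] == mat[j, both]).sum()) / denom
            if ident >= cfg.identity_threshold:
                redundant = True
                break
        if not redundant:
            kept_idx.append(i)
    return MSA([msa.sequences[i] for i in kept_idx])
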