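"""Reading and writing multiple sequence alignments (A3M / aligned FASTA).

The internal :class:`MSA` representation follows the AlphaFold feature
convention: aligned rows over a fixed 22-letter alphabet (20 amino acids,
``X`` for unknown, ``-`` for gaps), a per-position deletion-count matrix
recording lowercase A3M insertions, optional per-row species labels parsed
from headers, and per-chain lengths for multimer alignments.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

#: Canonical residue-class order used for every profile/bias matrix downstream.
ALPHABET = "ARNDCQEGHILKMFPSTWYVX-"
N_CLASSES = len(ALPHABET)  # 22
GAP = "-"
AA_TO_INDEX = {c: i for i, c in enumerate(ALPHABET)}

# Ambiguity / rare codes collapse to the unknown class.
_AMBIGUOUS = str.maketrans({"B": "X", "Z": "X", "J": "X", "U": "X", "O": "X"})

_SPECIES_RE = re.compile(r"(?:OX|TaxID)=(\S+)")


class MSAFormatError(ValueError):
    """Raised when alignment text violates the A3M/FASTA format contract."""


@dataclass
class MSA:
    """An aligned set of sequences with deletion counts and species labels.

    ``rows`` are equal-length strings over :data:`ALPHABET`; ``deletions[r, c]``
    counts the lowercase insertions that immediately preceded match column
    ``c`` in row ``r`` of the source A3M. Row ``query_index`` (0 for any
    parsed alignment) is the query. ``chain_lengths`` partitions the columns
    for multimers; a block-diagonal fragment produced by featurization may
    carry ``query_index=None`` because it holds no query row.
    """

    rows: list[str]
    deletions: np.ndarray
    species: list[str | None]
    headers: list[str] = field(default_factory=list)
    chain_lengths: list[int] | None = None
    query_index: int | None = 0

    def __post_init__(self) -> None:
        if not self.rows:
            raise MSAFormatError("MSA must contain at least one row")
        L = len(self.rows[0])
        if L < 1:
            raise MSAFormatError("alignment length must be >= 1")
        if any(len(r) != L for r in self.rows):
            raise MSAFormatError("all rows must have identical length")
        self.deletions = np.asarray(self.deletions, dtype=np.int64)
        if self.deletions.shape != (len(self.rows), L):
            raise MSAFormatError(
                f"deletion matrix shape {self.deletions.shape} does not match "
                f"({len(self.rows)}, {L})"
            )
        if (self.deletions < 0).any():
            raise MSAFormatError("deletion counts must be non-negative")
        if len(self.species) != len(self.rows):
            raise MSAFormatError("one species entry (possibly None) per row required")
        if not self.headers:
            self.headers = [f"row{i}" for i in range(len(self.rows))]
        if self.chain_lengths is None:
            self.chain_lengths = [L]
        if sum(self.chain_lengths) != L:
            raise MSAFormatError("chain lengths must sum to alignment length")
        bad = set("".join(self.rows)) - set(ALPHABET)
        if bad:
            raise MSAFormatError(f"characters outside alphabet: {sorted(bad)}")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def L(self) -> int:
        return len(self.rows[0])

    @property
    def query(self) -> str:
        if self.query_index is None:
            raise ValueError("this MSA fragment has no query row")
        return self.rows[self.query_index]


def _records(text: str) -> list[tuple[str, str]]:
    if not text.strip():
        raise MSAFormatError("empty alignment input")
    recs = [
        (r.description, str(r.seq))
        for r in SeqIO.parse(io.StringIO(text), "fasta")
    ]
    if not recs:
        raise MSAFormatError("no FASTA records found")
    return recs


def _normalize_match(char: str) -> str:
    c = char.upper().translate(_AMBIGUOUS)
    if c not in AA_TO_INDEX:
        raise MSAFormatError(f"invalid alignment character {char!r}")
    return c


def _species_from_header(header: str) -> str | None:
    m = _SPECIES_RE.search(header)
    return m.group(1) if m else None


def parse_a3m(text: str) -> MSA:
    """Parse A3M text into an :class:`MSA`.

    Lowercase letters are insertions relative to the query: they are removed
    from the row and accumulated into the deletion count of the *following*
    match column. ``*`` terminators and ``.`` placeholders are stripped.
    Species labels are taken from an ``OX=`` or ``TaxID=`` header token when
    present.
    """
    recs = _records(text)
    rows: list[str] = []
    dels: list[list[int]] = []
    for header, seq in recs:
        matched: list[str] = []
        counts: list[int] = []
        pending = 0
        for ch in seq:
            if ch in "*.":
                continue
            if ch.islower():
                pending += 1
                continue
            matched.append(_normalize_match(ch))
            counts.append(pending)
            pending = 0
        # trailing insertions have no following match column and are dropped
        rows.append("".join(matched))
        dels.append(counts)
    L = len(rows[0])
    if L == 0:
        raise MSAFormatError("query row has no match columns")
    if any(len(r) != L for r in rows):
        raise MSAFormatError("rows have unequal match-column length")
    return MSA(
        rows=rows,
        deletions=np.array(dels, dtype=np.int64),
        species=[_species_from_header(h) for h, _ in recs],
        headers=[h for h, _ in recs],
    )


def parse_fasta_aligned(text: str) -> MSA:
    """Parse an already-aligned FASTA file (no lowercase insertion states)."""
    recs = _records(text)
    rows = []
    for header, seq in recs:
        cleaned = seq.replace("*", "")
        rows.append("".join(_normalize_match(c) for c in cleaned))
    L = len(rows[0])
    if any(len(r) != L for r in rows):
        raise MSAFormatError("aligned FASTA records have unequal lengths")
    return MSA(
        rows=rows,
        deletions=np.zeros((len(rows), L), dtype=np.int64),
        species=[_species_from_header(h) for h, _ in recs],
        headers=[h for h, _ in recs],
    )


def write_a3m(msa: MSA) -> str:
    """Serialize an :class:`MSA` back to A3M text.

    The original inserted residues are not stored, so insertion runs are
    emitted as runs of lowercase ``x``; deletion counts, match columns,
    headers and species therefore survive a parse → write → parse round trip
    unchanged.
    """
    out: list[str] = []
    for r, (header, row) in enumerate(zip(msa.headers, msa.rows)):
        out.append(f">{header}")
        chars = []
        for c in range(msa.L):
            chars.append("x" * int(msa.deletions[r, c]))
            chars.append(row[c])
        out.append("".join(chars))
    return "\n".join(out) + "\n"


def sequence_identity(row: str, query: str) -> float:
    """Fraction of non-gap query positions where ``row`` matches ``query``."""
    if len(row) != len(query):
        raise ValueError("row and query must have equal aligned length")
    positions = [i for i, q in enumerate(query) if q != GAP]
    if not positions:
        return 0.0
    matches = sum(1 for i in positions if row[i] == query[i])
    return matches / len(positions)


def encode_rows(msa: MSA, rows: list[int] | None = None) -> np.ndarray:
    """Integer-encode selected rows as indices into :data:`ALPHABET`."""
    idx = range(msa.n_rows) if rows is None else rows
    return np.array(
        [[AA_TO_INDEX[c] for c in msa.rows[r]] for r in idx], dtype=np.int64
    )
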