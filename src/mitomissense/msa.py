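"""Ortholog multiple sequence alignments and per-position residue profiles.

An alignment is consumed as aligned FASTA (MAFFT dialect) with one designated
human reference row.  All downstream features are expressed in reference
residue coordinates, so the central object here is the column map: reference
position k (1-based) -> alignment column, built by scanning the reference row
and skipping its gap columns.

Symbols outside the 20 standard residues and the gap characters ('-' and '.')
— X, B, Z, J, U, O and anything else — are pooled into an "unknown" bin that
counts toward the number of rows but never toward any amino acid, so odd
RefSeq entries can never inflate conservation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
from Bio import SeqIO

from .seqcore import STANDARD_AAS

GAP = "-"
UNKNOWN = "?"

#: profile symbol order: 20 amino acids, then gap, then pooled unknowns
SYMBOLS = tuple(STANDARD_AAS) + (GAP, UNKNOWN)
SYMBOL_INDEX = {s: i for i, s in enumerate(SYMBOLS)}
N_SYMBOLS = len(SYMBOLS)  # 22
GAP_CODE = SYMBOL_INDEX[GAP]
UNKNOWN_CODE = SYMBOL_INDEX[UNKNOWN]

_ENCODE = np.full(256, UNKNOWN_CODE, dtype=np.int8)
for _s, _i in SYMBOL_INDEX.items():
    _ENCODE[ord(_s)] = _i
    _ENCODE[ord(_s.lower())] = _i
_ENCODE[ord(".")] = GAP_CODE


class AlignmentFormatError(ValueError):
    """Ragged rows or otherwise malformed aligned FASTA."""


class MissingReferenceError(KeyError):
    """The designated reference row is absent from the alignment."""


@dataclass
class ColumnProfile:
    """Residue counts of one alignment column in reference coordinates."""

    position: int
    counts: dict[str, int]
    n_rows: int

    def count(self, symbol: str) -> int:
        return self.counts.get(symbol, 0)

    def rel_freq(self, symbol: str) -> float:
        """Relative frequency of a symbol over all rows (gaps and unknowns in the denominator)."""
        if self.n_rows == 0:
            raise ZeroDivisionError("empty alignment")
        return self.count(symbol) / self.n_rows


class OrthologAlignment:
    """Aligned ortholog rows with a designated human reference row.

    Rows are stored as an (n_rows, n_columns) int8 matrix over the 22-symbol
    alphabet (20 residues, gap, unknown).  ``column_map[k]`` gives the 0-based
    alignment column of reference residue k+1; the reference row is never a
    gap at a mapped column.
    """

    def __init__(self, polypeptide_id: str, ids: list[str], rows: list[str],
                 reference_row_id: str):
        if len(set(len(r) for r in rows)) > 1:
            raise AlignmentFormatError("alignment rows have unequal lengths")
        if reference_row_id not in ids:
            raise MissingReferenceError(
                f"reference row {reference_row_id!r} not in alignment"
            )
        self.polypeptide_id = polypeptide_id
        self.ids = list(ids)
        self.reference_row_id = reference_row_id
        self.matrix = np.vstack([
            _ENCODE[np.frombuffer(r.encode("ascii"), dtype=np.uint8)] for r in rows
        ])
        ref = self.matrix[ids.index(reference_row_id)]
        self.column_map = np.flatnonzero(ref != GAP_CODE)
        if (ref[self.column_map] == UNKNOWN_CODE).any():
            raise AlignmentFormatError("reference row contains non-residue symbols")
        self.reference_protein = "".join(SYMBOLS[c] for c in ref[self.column_map])

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]

    @property
    def reference_length(self) -> int:
        return len(self.column_map)

    def reference_residue(self, position: int) -> str:
        self._check_position(position)
        return self.reference_protein[position - 1]

    def column(self, position: int) -> np.ndarray:
        """Encoded symbols of the alignment column mapped to a reference position."""
        self._check_position(position)
        return self.matrix[:, self.column_map[position - 1]]

    def column_profile(self, position: int) -> ColumnProfile:
        """Symbol counts at a reference position, over all rows including gaps."""
        col = self.column(position)
        tallies = np.bincount(col, minlength=N_SYMBOLS)
        counts = {SYMBOLS[i]: int(tallies[i]) for i in range(N_SYMBOLS) if tallies[i]}
        return ColumnProfile(position, counts, self.n_rows)

    def profiles(self) -> list[ColumnProfile]:
        return [self.column_profile(k) for k in range(1, self.reference_length + 1)]

    def _check_position(self, position: int) -> None:
        if not 1 <= position <= self.reference_length:
            raise IndexError(
                f"position {position} outside reference length {self.reference_length}"
            )


def read_alignment(path, reference_row_id: str | None = None,
                   ref_regex: str | None = None,
                   polypeptide_id: str | None = None) -> OrthologAlignment:
    """Read an aligned FASTA and locate the reference row.

    The reference is selected either by exact record id or by the first id
    matching ``ref_regex``.  Case is folded and both '-' and '.' read as gaps.
    """
    ids, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        rows.append(str(rec.seq))
    if not ids:
        raise AlignmentFormatError(f"no sequences in {path}")
    if reference_row_id is None:
        if ref_regex is None:
            raise ValueError("either reference_row_id or ref_regex is required")
        pat = re.compile(ref_regex)
        matches = [i for i in ids if pat.search(i)]
        if not matches:
            raise MissingReferenceError(f"no id matches {ref_regex!r}")
        reference_row_id = matches[0]
    if polypeptide_id is None:
        polypeptide_id = reference_row_id
    return OrthologAlignment(polypeptide_id, ids, rows, reference_row_id)
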