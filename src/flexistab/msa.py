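"""Homolog-alignment consensus: column profiles and query-to-column mapping.

The consensus approach to protein stabilization replaces a residue with the
most frequent residue at the homologous alignment position, on the premise
that the consensus choice of a homolog family is, on average, stabilizing.
This module computes per-column plurality consensus, conservation (plurality
frequency and Shannon entropy) and gap fractions from an existing alignment,
and maps the structure's own sequence to alignment columns so that residue
numbers from the B-factor analysis and columns from the alignment can be
intersected downstream.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd
from Bio import AlignIO

__all__ = [
    "AA_ALPHABET",
    "Alignment",
    "ColumnProfile",
    "QueryColumnMap",
    "read_alignment",
    "column_profiles",
    "map_query_to_columns",
    "write_consensus_csv",
]

#: the 20 amino acids in the fixed tie-break order (alphabetical one-letter)
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_VALID = set(AA_ALPHABET) | {"-", "X"}


@dataclass
class Alignment:
    """Ordered (id, aligned sequence) pairs, all of length ``n_cols``."""

    entries: list[tuple[str, str]]
    n_cols: int

    def __post_init__(self) -> None:
        ids = [i for i, _ in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sequence ids in alignment")
        for sid, seq in self.entries:
            if len(seq) != self.n_cols:
                raise ValueError(f"not an alignment: {sid!r} has length {len(seq)}")
            bad = set(seq) - _VALID
            if bad:
                raise ValueError(f"invalid characters {sorted(bad)} in {sid!r}")

    @property
    def n_sequences(self) -> int:
        return len(self.entries)

    def sequence(self, seq_id: str) -> str:
        for sid, seq in self.entries:
            if sid == seq_id:
                return seq
        raise KeyError(f"query not in alignment: {seq_id!r}")


@dataclass(frozen=True)
class ColumnProfile:
    """Residue counts and consensus for one alignment column (1-based).

    ``consensus_freq`` is the plurality count over the non-gap count;
    ``entropy_bits`` is the Shannon entropy of the non-gap residue
    distribution (0 for a perfectly conserved column).  An all-gap column is
    ``degenerate`` with consensus ``'X'`` and frequency 0.
    """

    col: int
    counts: dict[str, int]
    consensus_aa: str
    consensus_freq: float
    gap_frac: float
    entropy_bits: float
    degenerate: bool = False


@dataclass
class QueryColumnMap:
    """Bijection between non-gap query positions and alignment columns.

    ``pairs`` holds (1-based query residue position, 1-based column); adding
    ``offset`` to a query position gives the structure residue number.
    """

    query_id: str
    pairs: list[tuple[int, int]]
    offset: int = 0

    def __post_init__(self) -> None:
        self._by_resnum = {qpos + self.offset: col for qpos, col in self.pairs}

    def column_for_residue(self, res_seq: int) -> int | None:
        """Alignment column for a structure residue number, or None if gapped."""
        return self._by_resnum.get(res_seq)


def read_alignment(
    source: str | Path | io.TextIOBase,
    fmt: str = "fasta",
) -> Alignment:
    """Read an aligned-FASTA (``fmt="fasta"``) or Clustal (``fmt="clustal"``) file.

    Sequences are upper-cased and '.' gaps are converted to '-'.
    """
    if fmt not in ("fasta", "clustal"):
        raise ValueError(f"unsupported alignment format {fmt!r}")
    try:
        msa = AlignIO.read(source, fmt)
    except ValueError as exc:
        msg = str(exc).lower()
        if "no records" in msg or "empty" in msg:
            raise ValueError("no sequences in alignment source") from exc
        raise ValueError(f"not an alignment: {exc}") from exc
    entries = [(rec.id, str(rec.seq).upper().replace(".", "-")) for rec in msa]
    if not entries:
        raise ValueError("no sequences in alignment source")
    return Alignment(entries=entries, n_cols=msa.get_alignment_length())


def column_profiles(alignment: Alignment) -> list[ColumnProfile]:
    """Per-column counts, plurality consensus and conservation.

    Plurality ties are broken by the fixed alphabet order A < C < D < ... < Y.
    """
    if alignment.n_sequences == 0:
        raise ValueError("no sequences in alignment")
    profiles: list[ColumnProfile] = []
    seqs = [seq for _, seq in alignment.entries]
    n = alignment.n_sequences
    for c in range(alignment.n_cols):
        column = [s[c] for s in seqs]
        counts: dict[str, int] = {}
        for ch in column:
            counts[ch] = counts.get(ch, 0) + 1
        n_gap = counts.get("-", 0)
        n_res = n - n_gap
        if n_res == 0:
            profiles.append(
                ColumnProfile(col=c + 1, counts=counts, consensus_aa="X",
                              consensus_freq=0.0, gap_frac=1.0,
                              entropy_bits=0.0, degenerate=True)
            )
            continue
        # plurality over non-gap residues; ties -> first in alphabet order
        top = max(counts[aa] for aa in counts if aa != "-")
        tied = sorted(aa for aa, k in counts.items() if aa != "-" and k == top)
        best = tied[0]
        entropy = -sum(
            (k / n_res) * math.log2(k / n_res)
            for aa, k in counts.items()
            if aa != "-" and k > 0
        )
        profiles.append(
            ColumnProfile(
                col=c + 1,
                counts=counts,
                consensus_aa=best,
                consensus_freq=top / n_res,
                gap_frac=n_gap / n,
                entropy_bits=entropy,
            )
        )
    return profiles


def consensus_string(profiles: Sequence[ColumnProfile]) -> str:
    """Concatenated per-column consensus residues (degenerate columns as 'X')."""
    return "".join(p.consensus_aa for p in profiles)


def map_query_to_columns(
    alignment: Alignment,
    query_id: str,
    offset: int = 0,
) -> QueryColumnMap:
    """Map the k-th non-gap query character to its column; res number = k + offset."""
    row = alignment.sequence(query_id)
    pairs: list[tuple[int, int]] = []
    qpos = 0
    for col, ch in enumerate(row, start=1):
        if ch != "-":
            qpos += 1
            pairs.append((qpos, col))
    return QueryColumnMap(query_id=query_id, pairs=pairs, offset=offset)


def write_consensus_csv(profiles: Sequence[ColumnProfile], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "col": [p.col for p in profiles],
            "consensus_aa": [p.consensus_aa for p in profiles],
            "consensus_freq": [round(p.consensus_freq, 4) for p in profiles],
            "gap_frac": [round(p.gap_frac, 4) for p in profiles],
            "entropy_bits": [round(p.entropy_bits, 4) for p in profiles],
        }
    )
    df.to_csv(path, index=False)
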