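"""Per-residue Calpha B-factor extraction, normalization and flexible-region detection.

Crystallographic B-factors (temperature factors) are proportional to the
mean-square displacement of an atom about its equilibrium position, so the
Calpha B-factor profile of a chain is a cheap per-residue flexibility read-out.
To compare chains on a common scale the raw values are z-scored::

    B'_i = (B_i - <B>) / sigma(B)

giving a dimensionless profile with zero mean and unit variance.  Contiguous
runs of residues with B' above a threshold are reported as candidate
high-flexibility regions for stabilizing mutagenesis.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser

__all__ = [
    "ResidueRecord",
    "BFactorProfile",
    "FlexibleRegion",
    "read_pdb_calpha",
    "normalize_bfactors",
    "detect_flexible_regions",
    "write_profile_csv",
    "read_profile_csv",
    "write_regions_csv",
]

#: standard 20 amino acids, three-letter -> one-letter
AA3_TO_1 = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}

_WATER_NAMES = {"HOH", "WAT", "DOD"}


@dataclass(frozen=True)
class ResidueRecord:
    """One residue's Calpha entry: identity plus raw B-factor (A^2)."""

    chain_id: str
    res_seq: int
    icode: str
    aa3: str
    aa1: str
    b_raw: float
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        if self.b_raw < 0:
            raise ValueError(f"negative B-factor at {self.chain_id}{self.res_seq}")


@dataclass
class BFactorProfile:
    """Ordered Calpha B-factor profile of one chain with its z-scores.

    ``sd_convention`` records whether ``sd_b`` is the population (divide by N,
    the default) or sample (divide by N-1) standard deviation.
    """

    residues: list[ResidueRecord]
    b_norm: np.ndarray
    mean_b: float
    sd_b: float
    sd_convention: str = "population"

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def b_raw(self) -> np.ndarray:
        return np.array([r.b_raw for r in self.residues], dtype=float)

    @property
    def positions(self) -> np.ndarray:
        return np.array([r.res_seq for r in self.residues], dtype=int)

    def bnorm_at(self, res_seq: int, chain_id: str | None = None) -> float:
        """B' of the residue numbered ``res_seq`` (first match wins)."""
        for rec, b in zip(self.residues, self.b_norm):
            if rec.res_seq == res_seq and (chain_id is None or rec.chain_id == chain_id):
                return float(b)
        raise KeyError(f"residue {res_seq} not in profile")


@dataclass(frozen=True)
class FlexibleRegion:
    """Maximal run of consecutive residues whose B' meets the threshold."""

    start: int
    end: int
    peak_bnorm: float
    member_positions: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("region start > end")

    def __contains__(self, res_seq: int) -> bool:
        return res_seq in self.member_positions


def _pick_altloc(atoms) -> object:
    """Highest-occupancy altloc; ties broken by altloc id, alphabetically."""
    return sorted(atoms, key=lambda a: (-(a.get_occupancy() or 0.0), a.get_altloc()))[0]


def read_pdb_calpha(
    pdb_source: str | Path | io.TextIOBase,
    chain: str | None = None,
) -> list[ResidueRecord]:
    """Extract one Calpha :class:`ResidueRecord` per residue from a PDB file.

    Parameters
    ----------
    pdb_source:
        Path to a PDB file, or an open text handle.
    chain:
        Chain identifier; ``None`` selects the first chain in the file.

    Notes
    -----
    Waters and Calpha-less heteroatoms are excluded.  For alternate locations
    the highest-occupancy CA wins (ties: first altloc alphabetically).
    Nonstandard amino acids that do carry a CA (e.g. MSE) are kept with
    one-letter code ``'X'`` and a warning.  Residues without a CA are skipped
    with a warning.  Author residue numbering is preserved.
    """
    parser = PDBParser(QUIET=True)
    handle = pdb_source if isinstance(pdb_source, io.TextIOBase) else open(pdb_source)
    try:
        structure = parser.get_structure("s", handle)
    finally:
        if handle is not pdb_source:
            handle.close()

    model = next(structure.get_models(), None)
    if model is None or len(model) == 0:
        raise ValueError("empty structure: no ATOM records found")

    chains = {c.id: c for c in model}
    if chain is None:
        target = next(iter(model))
    elif chain in chains:
        target = chains[chain]
    else:
        raise ValueError(f"unknown chain {chain!r}; file has {sorted(chains)}")

    records: list[ResidueRecord] = []
    for residue in target:
        hetflag, res_seq, icode = residue.id
        resname = residue.get_resname().strip()
        if resname in _WATER_NAMES or hetflag == "W":
            continue
        if "CA" not in residue:
            if hetflag == " ":
                warnings.warn(
                    f"residue {resname} {target.id}{res_seq}{icode.strip()} has no CA; skipped",
                    stacklevel=2,
                )
            continue
        ca = residue["CA"]
        if ca.is_disordered():
            ca = _pick_altloc(ca.disordered_get_list())
        if resname in AA3_TO_1:
            aa1 = AA3_TO_1[resname]
        else:
            aa1 = "X"
            warnings.warn(f"nonstandard residue {resname} {res_seq}: one-letter code 'X'",
                          stacklevel=2)
        records.append(
            ResidueRecord(
                chain_id=target.id,
                res_seq=res_seq,
                icode=icode.strip(),
                aa3=resname,
                aa1=aa1,
                b_raw=float(ca.get_bfactor()),
                occupancy=float(ca.get_occupancy() if ca.get_occupancy() is not None else 1.0),
            )
        )
    if not records:
        raise ValueError("empty structure: selected chain has no CA atoms")
    return records


def normalize_bfactors(
    records: Sequence[ResidueRecord],
    sd_convention: str = "population",
) -> BFactorProfile:
    """z-score the raw B-factors: B' = (B - <B>) / sigma(B).

    ``sd_convention`` is ``"population"`` (divide by N, default) or
    ``"sample"`` (divide by N-1).
    """
    if len(records) < 2:
        raise ValueError("degenerate profile: need at least 2 residues")
    if sd_convention not in ("population", "sample"):
        raise ValueError(f"unknown sd convention {sd_convention!r}")
    b = np.array([r.b_raw for r in records], dtype=float)
    mean = float(b.mean())
    sd = float(b.std(ddof=0 if sd_convention == "population" else 1))
    if sd == 0.0:
        raise ValueError("constant B-factors: zero variance, cannot normalize")
    return BFactorProfile(
        residues=list(records),
        b_norm=(b - mean) / sd,
        mean_b=mean,
        sd_b=sd,
        sd_convention=sd_convention,
    )


def detect_flexible_regions(
    profile: BFactorProfile,
    threshold: float = 1.0,
    min_run: int = 1,
) -> list[FlexibleRegion]:
    """Maximal runs of >= ``min_run`` consecutive residues with B' >= threshold.

    Residues count as consecutive when adjacent in the profile, on the same
    chain, and their author numbers differ by at most one (insertion-coded
    residues share a number).  Returned regions are non-overlapping and
    sorted by start.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    if min_run < 1:
        raise ValueError("min_run must be >= 1")

    regions: list[FlexibleRegion] = []
    run: list[tuple[ResidueRecord, float]] = []

    def flush() -> None:
        if len(run) >= min_run:
            positions = tuple(rec.res_seq for rec, _ in run)
            regions.append(
                FlexibleRegion(
                    start=positions[0],
                    end=positions[-1],
                    peak_bnorm=float(max(b for _, b in run)),
                    member_positions=positions,
                )
            )
        run.clear()

    prev: ResidueRecord | None = None
    for rec, b in zip(profile.residues, profile.b_norm):
        contiguous = (
            prev is not None
            and rec.chain_id == prev.chain_id
            and 0 <= rec.res_seq - prev.res_seq <= 1
        )
        if b >= threshold:
            if run and not contiguous:
                flush()
            run.append((rec, float(b)))
        else:
            flush()
        prev = rec
    flush()
    return regions


# ---------------------------------------------------------------------------
# CSV I/O (fixed 4-decimal convention so profiles round-trip as formatted)

def write_profile_csv(profile: BFactorProfile, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "chain": [r.chain_id for r in profile.residues],
            "res_seq": [r.res_seq for r in profile.residues],
            "icode": [r.icode for r in profile.residues],
            "aa1": [r.aa1 for r in profile.residues],
            "b_raw": [f"{r.b_raw:.4f}" for r in profile.residues],
            "b_norm": [f"{b:.4f}" for b in profile.b_norm],
        }
    )
    df.to_csv(path, index=False)


def read_profile_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"chain": str, "icode": str}, keep_default_na=False)
    df["b_raw"] = df["b_raw"].astype(float)
    df["b_norm"] = df["b_norm"].astype(float)
    return df


def write_regions_csv(regions: Iterable[FlexibleRegion], path: str | Path) -> None:
    regions = list(regions)
    df = pd.DataFrame(
        {
            "start": [r.start for r in regions],
            "end": [r.end for r in regions],
            "peak_bnorm": [f"{r.peak_bnorm:.4f}" for r in regions],
        }
    )
    df.to_csv(path, index=False)
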