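"""Conformational-ensemble post-processing: superposition, RMSF, H-bond occupancy.

An ensemble is a stack of frames over the same atoms (for example the MODEL
blocks of a multi-MODEL PDB, or snapshots saved from a molecular-dynamics
trajectory).  Three standard read-outs are implemented from scratch:

* rigid-body **superposition** of every frame onto a reference frame by the
  closed-form least-squares (Kabsch/SVD) rotation, with the determinant guard
  that forbids improper rotations;
* per-residue **RMSF**, the root-mean-square fluctuation of the selected atom
  about its ensemble-average position,
  RMSF_i = sqrt(<|r_i(t) - <r_i>|^2>_t;
* geometric **hydrogen-bond occupancy**, the percentage of frames in which a
  donor/acceptor heavy-atom pair is within a distance cutoff (default
  0.35 nm) and, when hydrogens are present and an angle cutoff is set, the
  D-H...A angle is at least the cutoff (default 120 deg).

Coordinates are handled in nm internally; PDB files (Angstrom) are converted
on input.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.structure.io import pdb as biotite_pdb

__all__ = [
    "ConformationalEnsemble",
    "HBondSpec",
    "HBondOccupancy",
    "read_ensemble_pdb",
    "superpose",
    "compute_rmsf",
    "hbond_occupancy",
]

ANGSTROM_PER_NM = 10.0


@dataclass
class ConformationalEnsemble:
    """Frames x atoms x 3 coordinates (nm) with per-atom metadata.

    ``atoms`` is a DataFrame with columns chain, res_seq, res_name, atom_name,
    element, one row per atom, identical across frames.
    """

    atoms: pd.DataFrame
    frames: np.ndarray
    frame_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (F, A, 3)")
        if self.frames.shape[1] != len(self.atoms):
            raise ValueError("frame atom count does not match metadata")
        if self.frames.shape[0] < 1:
            raise ValueError("need at least one frame")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("non-finite coordinates")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    def select(self, selection: str | Sequence[bool] | Sequence[int] = "CA") -> np.ndarray:
        """Atom indices for a selection: an atom-name string, mask, or index list."""
        if isinstance(selection, str):
            mask = (self.atoms["atom_name"] == selection).to_numpy()
            return np.flatnonzero(mask)
        arr = np.asarray(selection)
        if arr.dtype == bool:
            return np.flatnonzero(arr)
        return arr.astype(int)

    def atom_index(self, chain: str, res_seq: int, atom_name: str) -> int:
        hit = self.atoms[
            (self.atoms["chain"] == chain)
            & (self.atoms["res_seq"] == res_seq)
            & (self.atoms["atom_name"] == atom_name)
        ]
        if hit.empty:
            raise KeyError(f"atom not found: {chain}:{res_seq}:{atom_name}")
        return int(hit.index[0])


@dataclass(frozen=True)
class HBondSpec:
    """Geometric hydrogen-bond criterion between two named atoms.

    Atom identifiers are "chain:res_seq:atom_name" strings naming the donor
    and acceptor heavy atoms; ``hydrogen`` optionally names the donor
    hydrogen for the angle test.
    """

    donor_atom: str
    acceptor_atom: str
    dist_cutoff_nm: float = 0.35
    angle_cutoff_deg: float | None = None
    hydrogen: str | None = None

    def __post_init__(self) -> None:
        if self.dist_cutoff_nm <= 0:
            raise ValueError("distance cutoff must be positive")


@dataclass(frozen=True)
class HBondOccupancy:
    spec: HBondSpec
    occupancy_pct: float
    n_frames: int
    n_hits: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.occupancy_pct <= 100.0:
            raise ValueError("occupancy must be a percentage")


def _parse_atom_id(ident: str) -> tuple[str, int, str]:
    parts = ident.split(":")
    if len(parts) != 3:
        raise ValueError(f"atom identifier must be chain:res_seq:atom_name, got {ident!r}")
    return parts[0], int(parts[1]), parts[2]


def read_ensemble_pdb(path: str | Path) -> ConformationalEnsemble:
    """Read a multi-MODEL PDB as an ensemble (each MODEL = one frame), nm units."""
    pdb_file = biotite_pdb.PDBFile.read(str(path))
    stack = pdb_file.get_structure(model=None)
    if isinstance(stack, struc.AtomArray):  # single model
        stack = struc.stack([stack])
    atoms = pd.DataFrame(
        {
            "chain": stack.chain_id,
            "res_seq": stack.res_id.astype(int),
            "res_name": stack.res_name,
            "atom_name": stack.atom_name,
            "element": stack.element,
        }
    )
    return ConformationalEnsemble(atoms=atoms, frames=stack.coord / ANGSTROM_PER_NM)


def _kabsch_rotation(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Proper rotation R minimizing ||P @ R.T - Q|| for centered point sets."""
    H = P.T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    return Vt.T @ D @ U.T


def superpose(
    ensemble: ConformationalEnsemble,
    reference_frame: int = 0,
    selection: str | Sequence[bool] | Sequence[int] = "CA",
) -> tuple[ConformationalEnsemble, np.ndarray]:
    """Rigidly fit every frame onto the reference frame over the selection.

    Returns the superposed ensemble (all atoms transformed) and the
    per-frame RMSD (nm) of the selection after fitting.
    """
    idx = ensemble.select(selection)
    if idx.size < 3:
        raise ValueError("underdetermined superposition: need >= 3 selected atoms")
    ref = ensemble.frames[reference_frame, idx]
    ref_center = ref.mean(axis=0)
    ref_c = ref - ref_center
    # collinearity check: centered reference must span a plane
    if np.linalg.matrix_rank(ref_c, tol=1e-10) < 2:
        raise ValueError("underdetermined superposition: collinear selection")

    out = np.empty_like(ensemble.frames)
    rmsd = np.empty(ensemble.n_frames)
    for f in range(ensemble.n_frames):
        mob = ensemble.frames[f, idx]
        mob_center = mob.mean(axis=0)
        R = _kabsch_rotation(mob - mob_center, ref_c)
        out[f] = (ensemble.frames[f] - mob_center) @ R.T + ref_center
        diff = out[f, idx] - ref
        rmsd[f] = np.sqrt((diff**2).sum(axis=1).mean())
    return replace(ensemble, frames=out), rmsd


def compute_rmsf(
    ensemble: ConformationalEnsemble,
    selection: str | Sequence[bool] | Sequence[int] = "CA",
) -> pd.DataFrame:
    """Per-residue RMSF (nm) of the selected atoms about their mean positions.

    The caller is responsible for superposing first (or deliberately opting
    out for ensembles that carry no global motion).
    """
    if ensemble.n_frames < 2:
        raise ValueError("insufficient frames: need >= 2 for RMSF")
    idx = ensemble.select(selection)
    coords = ensemble.frames[:, idx]          # F x a x 3
    mean = coords.mean(axis=0)                # a x 3
    msf = ((coords - mean) ** 2).sum(axis=2).mean(axis=0)
    return pd.DataFrame(
        {
            "res_seq": ensemble.atoms["res_seq"].to_numpy()[idx],
            "rmsf_nm": np.sqrt(msf),
        }
    )


def hbond_occupancy(
    ensemble: ConformationalEnsemble,
    spec: HBondSpec,
) -> HBondOccupancy:
    """Percentage of frames in which the donor/acceptor pair is hydrogen bonded.

    A frame counts when the donor-acceptor heavy-atom distance is within
    ``dist_cutoff_nm`` and, if ``spec.hydrogen`` and ``spec.angle_cutoff_deg``
    are both set, the D-H...A angle is at least the cutoff.
    """
    d_idx = ensemble.atom_index(*_parse_atom_id(spec.donor_atom))
    a_idx = ensemble.atom_index(*_parse_atom_id(spec.acceptor_atom))
    d = ensemble.frames[:, d_idx]
    a = ensemble.frames[:, a_idx]
    dist = np.linalg.norm(d - a, axis=1)
    hit = dist <= spec.dist_cutoff_nm

    if spec.hydrogen is not None and spec.angle_cutoff_deg is not None:
        h_idx = ensemble.atom_index(*_parse_atom_id(spec.hydrogen))
        h = ensemble.frames[:, h_idx]
        v1 = d - h
        v2 = a - h
        cosang = (v1 * v2).sum(axis=1) / (
            np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)
        )
        angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        hit &= angle >= spec.angle_cutoff_deg

    n_hits = int(hit.sum())
    return HBondOccupancy(
        spec=spec,
        occupancy_pct=100.0 * n_hits / ensemble.n_frames,
        n_frames=ensemble.n_frames,
        n_hits=n_hits,
    )
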