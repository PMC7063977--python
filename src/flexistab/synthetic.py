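"""Seeded synthetic inputs with known ground truth for every pipeline stage.

Each generator takes an explicit integer seed, uses one private
``numpy.random.Generator`` (no global state), and returns the payload
together with a machine-readable truth manifest recording everything that
was planted.  Identical arguments give byte-identical output, so the
generators double as reproducible fixtures.

What the generators emulate, and what they do not:

* :func:`gen_pdb` — a single-chain Calpha trace whose B-factor column carries
  a planted high-flexibility bump (default residues 63-68) on top of a
  baseline of plateau values with scattered low "rigid-core" dips.  The dip
  mass keeps every baseline z-score safely below the detection threshold so
  the planted bump is provably the only flexible region.  The geometry is a
  straight line: B-factor analysis never looks at coordinates, and the trace
  must not be mistaken for a fold.
* :func:`gen_msa` — a homolog alignment (default 92 sequences, the size of a
  typical curated thermophile family) with a planted per-column consensus at
  a chosen plurality frequency and gap rate; the query row (default carrying
  63-TKWDCK-68 against a planted consensus 63-TNITCT-68) is gap-free so
  alignment columns equal residue positions.  Columns are independent; real
  alignments have phylogenetic correlation, which nothing here models.
* :func:`gen_kinetics` / :func:`gen_decay` — Michaelis–Menten initial rates
  on a doubling-dilution substrate series (10 down to 0.078125 mM) and
  first-order residual-activity decays on the standard 50 or 60 deg C
  sampling grids, each with multiplicative Gaussian noise of a stated CV.
* :func:`gen_ensemble` — a helical Calpha trace perturbed per frame by
  per-residue isotropic Gaussian displacement (so true RMSF = sigma*sqrt(3)),
  optionally wrapped in random per-frame rigid transforms to exercise
  superposition, and optionally carrying a planted donor/acceptor pair whose
  distance is inside the H-bond cutoff in an exact fraction of frames.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.structure.io import pdb as biotite_pdb

from flexistab.msa import AA_ALPHABET

__all__ = [
    "gen_pdb",
    "gen_msa",
    "gen_kinetics",
    "gen_decay",
    "gen_ensemble",
    "simulate",
    "SUBSTRATE_DOUBLING_SERIES_MM",
    "TIME_GRID_50C_MIN",
    "TIME_GRID_60C_MIN",
]

#: doubling dilutions from 10 mM down to 0.078125 mM (8 concentrations)
SUBSTRATE_DOUBLING_SERIES_MM = tuple(10.0 / 2**i for i in range(8))
#: standard sampling grids for residual activity at 50 and 60 deg C (min)
TIME_GRID_50C_MIN = (5, 10, 15, 20, 30, 40, 50, 65, 80, 100, 120)
TIME_GRID_60C_MIN = (1, 3, 6, 10, 15, 20, 25, 30, 35, 45, 60, 75, 90)

_LN2 = math.log(2.0)


def _pdb_text_from_atoms(
    coords_A: np.ndarray,
    res_ids: np.ndarray,
    atom_names: list[str],
    elements: list[str],
    b_factors: np.ndarray | None = None,
    chain: str = "A",
) -> str:
    """Render atoms (single frame (A,3) or stack (F,A,3), Angstrom) as PDB text."""
    multi = coords_A.ndim == 3
    n = coords_A.shape[-2]
    if multi:
        arr = struc.AtomArrayStack(coords_A.shape[0], n)
    else:
        arr = struc.AtomArray(n)
    arr.coord = coords_A
    arr.chain_id[:] = chain
    arr.res_id = np.asarray(res_ids, dtype=int)
    arr.res_name[:] = "ALA"
    arr.atom_name = np.asarray(atom_names)
    arr.element = np.asarray(elements)
    arr.hetero[:] = False
    arr.set_annotation("occupancy", np.ones(n))
    if b_factors is not None:
        arr.set_annotation("b_factor", np.round(np.asarray(b_factors, dtype=float), 2))
    pdb_file = biotite_pdb.PDBFile()
    pdb_file.set_structure(arr)
    return "\n".join(pdb_file.lines) + "\n"


def gen_pdb(
    seed: int,
    n_res: int = 150,
    bump_start: int = 63,
    bump_end: int = 68,
    bump_height: float = 4.0,
    chain: str = "A",
    dip_prob: float = 0.2,
) -> tuple[str, dict]:
    """Calpha-trace PDB with a planted B-factor bump; returns (pdb_text, truth).

    The baseline mixes a narrow plateau (``u`` in 0.3-0.7 baseline units) with
    scattered deep dips (``u`` near -2), which inflates the overall variance so
    that no plateau residue can reach z = 1 while the bump (``u`` near
    ``bump_height``, default 4) lands far above it.  ``bump_height = 0``
    disables the bump.  Raw B-factors are 25 + 8 u (A^2).
    """
    if not (1 <= bump_start <= bump_end <= n_res):
        raise ValueError("invalid spec: bump outside chain")
    rng = np.random.default_rng(seed)
    plateau = rng.uniform(0.3, 0.7, n_res)
    dips = rng.uniform(-2.2, -1.8, n_res)
    u = np.where(rng.random(n_res) < dip_prob, dips, plateau)
    width = bump_end - bump_start + 1
    if bump_height > 0:
        u[bump_start - 1 : bump_end] = bump_height + rng.uniform(-0.05, 0.05, width)
    b_raw = 25.0 + 8.0 * u
    b_written = np.round(b_raw, 2)  # PDB B column carries 2 decimals

    # truth: z-scores of the values as written, population sd
    z = (b_written - b_written.mean()) / b_written.std(ddof=0)
    above = z >= 1.0
    expected_region = None
    if bump_height > 0 and bool(above[bump_start - 1 : bump_end].all()):
        # the planted window must also be maximal for the truth to be a region
        lo_ok = bump_start == 1 or not above[bump_start - 2]
        hi_ok = bump_end == n_res or not above[bump_end]
        if lo_ok and hi_ok:
            expected_region = [bump_start, bump_end]

    x = np.arange(n_res, dtype=float) * 3.8
    coords = np.stack([x, np.zeros(n_res), np.zeros(n_res)], axis=1)
    text = _pdb_text_from_atoms(
        coords,
        res_ids=np.arange(1, n_res + 1),
        atom_names=["CA"] * n_res,
        elements=["C"] * n_res,
        b_factors=b_written,
        chain=chain,
    )
    truth = {
        "kind": "pdb_profile",
        "seed": seed,
        "n_res": n_res,
        "chain": chain,
        "bump_start": bump_start,
        "bump_end": bump_end,
        "bump_height": bump_height,
        "b_raw": [float(v) for v in b_written],
        "expected_region": expected_region,
        "expected_region_threshold": 1.0,
    }
    return text, truth


def gen_msa(
    seed: int,
    n_seqs: int = 92,
    n_cols: int = 120,
    query_id: str = "query",
    region_start: int = 63,
    query_region: str = "TKWDCK",
    consensus_region: str = "TNITCT",
    consensus_freq: float = 0.7,
    gap_frac: float = 0.1,
) -> tuple[str, dict]:
    """Aligned-FASTA with planted consensus; returns (fasta_text, truth).

    The gap-free query row makes column c correspond to residue position c
    (offset 0).  Outside the planted window the consensus equals the query,
    so the window is the only place design candidates can arise.
    """
    if len(query_region) != len(consensus_region):
        raise ValueError("invalid spec: query and consensus regions differ in length")
    region_end = region_start + len(query_region) - 1
    if not (1 <= region_start <= region_end <= n_cols):
        raise ValueError("invalid spec: planted region outside alignment")
    if consensus_freq <= 1.0 / len(AA_ALPHABET):
        raise ValueError("invalid spec: plurality frequency too low")
    if consensus_freq + gap_frac > 1.0:
        raise ValueError("invalid spec: frequency + gap rate exceed 1")
    rng = np.random.default_rng(seed)
    alphabet = np.array(list(AA_ALPHABET))

    query = rng.choice(alphabet, size=n_cols)
    query[region_start - 1 : region_end] = list(query_region)
    consensus = query.copy()
    consensus[region_start - 1 : region_end] = list(consensus_region)

    rows = [(query_id, "".join(query))]
    others = np.empty((n_seqs - 1, n_cols), dtype="<U1")
    for c in range(n_cols):
        pool = alphabet[alphabet != consensus[c]]
        draw = rng.random(n_seqs - 1)
        col = np.where(
            draw < gap_frac,
            "-",
            np.where(
                draw < gap_frac + (1 - gap_frac) * consensus_freq,
                consensus[c],
                rng.choice(pool, size=n_seqs - 1),
            ),
        )
        others[:, c] = col
    for i in range(n_seqs - 1):
        rows.append((f"homolog_{i + 1:03d}", "".join(others[i])))

    fasta = "".join(f">{sid}\n{seq}\n" for sid, seq in rows)
    expected_labels = [
        f"{q}{region_start + i}{c}"
        for i, (q, c) in enumerate(zip(query_region, consensus_region))
        if q != c
    ]
    truth = {
        "kind": "msa",
        "seed": seed,
        "n_seqs": n_seqs,
        "n_cols": n_cols,
        "query_id": query_id,
        "query_sequence": "".join(query),
        "consensus_string": "".join(consensus),
        "consensus_freq": consensus_freq,
        "gap_frac": gap_frac,
        "offset": 0,
        "region_start": region_start,
        "region_end": region_end,
        "expected_labels": expected_labels,
    }
    return fasta, truth


def gen_kinetics(
    seed: int,
    enzyme_id: str = "enzyme",
    vmax_U_per_mg: float = 714.29,
    km_mM: float = 0.36,
    noise_cv: float = 0.02,
    substrate_mM: tuple[float, ...] = SUBSTRATE_DOUBLING_SERIES_MM,
) -> tuple[pd.DataFrame, dict]:
    """Michaelis–Menten rate table with multiplicative noise; (df, truth)."""
    if vmax_U_per_mg <= 0 or km_mM <= 0:
        raise ValueError("invalid spec: parameters must be positive")
    if noise_cv < 0:
        raise ValueError("invalid spec: negative noise CV")
    rng = np.random.default_rng(seed)
    s = np.asarray(substrate_mM, dtype=float)
    v = vmax_U_per_mg * s / (km_mM + s)
    v = v * (1.0 + noise_cv * rng.standard_normal(s.size))
    df = pd.DataFrame(
        {"enzyme_id": enzyme_id, "substrate_mM": s, "rate_U_per_mg": v}
    )
    truth = {
        "kind": "kinetics",
        "seed": seed,
        "enzyme_id": enzyme_id,
        "vmax_U_per_mg": vmax_U_per_mg,
        "km_mM": km_mM,
        "noise_cv": noise_cv,
        "substrate_mM": [float(x) for x in s],
    }
    return df, truth


def gen_decay(
    seed: int,
    enzyme_id: str = "enzyme",
    temperature_C: float = 50.0,
    k_per_min: float = _LN2 / 65.0,
    noise_cv: float = 0.02,
    time_min: tuple[float, ...] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """First-order residual-activity decay table with noise; (df, truth).

    The default grid follows the temperature: the 50 deg C grid up to 120 min
    for ``temperature_C < 55``, else the finer 60 deg C grid up to 90 min.
    """
    if k_per_min <= 0:
        raise ValueError("invalid spec: decay constant must be positive")
    if noise_cv < 0:
        raise ValueError("invalid spec: negative noise CV")
    if time_min is None:
        time_min = TIME_GRID_50C_MIN if temperature_C < 55 else TIME_GRID_60C_MIN
    rng = np.random.default_rng(seed)
    t = np.asarray(time_min, dtype=float)
    r = 100.0 * np.exp(-k_per_min * t)
    r = r * (1.0 + noise_cv * rng.standard_normal(t.size))
    df = pd.DataFrame(
        {
            "enzyme_id": enzyme_id,
            "temperature_C": temperature_C,
            "time_min": t,
            "residual_pct": r,
        }
    )
    truth = {
        "kind": "decay",
        "seed": seed,
        "enzyme_id": enzyme_id,
        "temperature_C": temperature_C,
        "k_per_min": k_per_min,
        "t_half_min": _LN2 / k_per_min,
        "noise_cv": noise_cv,
        "time_min": [float(x) for x in t],
    }
    return df, truth


def _helix_trace(n_res: int) -> np.ndarray:
    """Non-collinear Calpha trace (nm): ideal-helix radius/rise/twist."""
    i = np.arange(n_res, dtype=float)
    theta = np.deg2rad(100.0) * i
    return np.stack(
        [0.23 * np.cos(theta), 0.23 * np.sin(theta), 0.15 * i], axis=1
    )


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation via QR of a Gaussian matrix."""
    A = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(A)
    Q *= np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def gen_ensemble(
    seed: int,
    n_res: int = 20,
    n_frames: int = 100,
    sigma_nm: float | np.ndarray = 0.05,
    rigid_transforms: bool = False,
    hbond_occupancy_pct: float | None = None,
    hbond_dist_in_nm: float = 0.30,
    hbond_dist_out_nm: float = 0.60,
    chain: str = "A",
) -> tuple[str, dict]:
    """Multi-MODEL PDB ensemble with planted fluctuations; (pdb_text, truth).

    Per-residue isotropic Gaussian displacement of each Calpha gives a true
    RMSF of sigma*sqrt(3).  With ``rigid_transforms`` every frame is also
    rotated/translated at random, which superposition must undo.  With
    ``hbond_occupancy_pct`` a donor N (residue 1) and acceptor O (residue
    ``n_res``) are appended whose mutual distance is ``hbond_dist_in_nm`` in
    an exact round(p/100 * F) frames and ``hbond_dist_out_nm`` otherwise.
    """
    if n_frames < 2:
        raise ValueError("invalid spec: need at least 2 frames")
    sigma = np.broadcast_to(np.asarray(sigma_nm, dtype=float), (n_res,)).copy()
    if np.any(sigma < 0):
        raise ValueError("invalid spec: negative sigma")
    rng = np.random.default_rng(seed)

    base = _helix_trace(n_res)
    frames = base[None] + sigma[None, :, None] * rng.standard_normal((n_frames, n_res, 3))

    res_ids = list(range(1, n_res + 1))
    atom_names = ["CA"] * n_res
    elements = ["C"] * n_res

    n_on = None
    if hbond_occupancy_pct is not None:
        if not 0 <= hbond_occupancy_pct <= 100:
            raise ValueError("invalid spec: occupancy must be a percentage")
        n_on = int(round(hbond_occupancy_pct / 100.0 * n_frames))
        on = np.zeros(n_frames, dtype=bool)
        on[rng.permutation(n_frames)[:n_on]] = True
        donor = base[0] + np.array([0.0, 0.0, -0.3])
        dist = np.where(on, hbond_dist_in_nm, hbond_dist_out_nm)
        acceptor = donor[None] + dist[:, None] * np.array([0.0, 0.0, -1.0])[None]
        extra = np.stack(
            [np.broadcast_to(donor, (n_frames, 3)), acceptor], axis=1
        )
        frames = np.concatenate([frames, extra], axis=1)
        res_ids += [1, n_res]
        atom_names += ["N", "O"]
        elements += ["N", "O"]

    if rigid_transforms:
        for f in range(n_frames):
            R = _random_rotation(rng)
            tvec = rng.uniform(-1.0, 1.0, 3)
            frames[f] = frames[f] @ R.T + tvec

    text = _pdb_text_from_atoms(
        frames * 10.0,  # nm -> Angstrom
        res_ids=np.array(res_ids),
        atom_names=atom_names,
        elements=elements,
        chain=chain,
    )
    truth = {
        "kind": "ensemble",
        "seed": seed,
        "n_res": n_res,
        "n_frames": n_frames,
        "sigma_nm": [float(s) for s in sigma],
        "expected_rmsf_nm": [float(s * math.sqrt(3.0)) for s in sigma],
        "rigid_transforms": rigid_transforms,
        "hbond_occupancy_pct": (
            100.0 * n_on / n_frames if n_on is not None else None
        ),
        "hbond_donor": f"{chain}:1:N" if n_on is not None else None,
        "hbond_acceptor": f"{chain}:{n_res}:O" if n_on is not None else None,
        "hbond_dist_in_nm": hbond_dist_in_nm if n_on is not None else None,
        "hbond_dist_out_nm": hbond_dist_out_nm if n_on is not None else None,
    }
    return text, truth


_GENERATORS = {
    "pdb_profile": (gen_pdb, "structure.pdb"),
    "msa": (gen_msa, "alignment.fasta"),
    "kinetics": (gen_kinetics, "kinetics.csv"),
    "decay": (gen_decay, "inactivation.csv"),
    "ensemble": (gen_ensemble, "ensemble.pdb"),
}


def simulate(kind: str, seed: int, out_dir: str | Path, **params) -> dict:
    """Generate one input kind into ``out_dir`` plus a ``truth.json`` manifest.

    Returns ``{"data": <path>, "truth": <path>}``.
    """
    if kind not in _GENERATORS:
        raise ValueError(f"unknown generator kind {kind!r}; choose from {sorted(_GENERATORS)}")
    gen, filename = _GENERATORS[kind]
    payload, truth = gen(seed, **params)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    data_path = out / filename
    if isinstance(payload, pd.DataFrame):
        payload.to_csv(data_path, index=False)
    else:
        data_path.write_text(payload)
    truth_path = out / "truth.json"
    truth_path.write_text(json.dumps(truth, indent=2) + "\n")
    return {"data": str(data_path), "truth": str(truth_path)}
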