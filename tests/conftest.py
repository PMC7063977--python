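"""Shared fixtures: tiny in-line PDB texts and the worked-example scenario."""

import io

import pytest

from flexistab import (
    detect_flexible_regions,
    map_query_to_columns,
    normalize_bfactors,
    read_alignment,
    read_pdb_calpha,
)
from flexistab import synthetic as syn


def pdb_line(serial, name, resname, chain, resseq, x, y, z, occ=1.00, b=0.00,
             altloc=" ", icode=" ", element=None):
    element = element or name[0]
    return (
        f"ATOM  {serial:>5d} {name:>4s}{altloc}{resname:>3s} {chain}{resseq:>4d}{icode}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {element:>2s}"
    )


@pytest.fixture
def three_residue_pdb():
    """Minimal 3-residue chain with known B-factors 10.00 / 20.00 / 30.00."""
    lines = [
        pdb_line(1, "  CA", "ALA", "A", 1, 0.0, 0.0, 0.0, b=10.00),
        pdb_line(2, "  CA", "GLY", "A", 2, 3.8, 0.0, 0.0, b=20.00),
        pdb_line(3, "  CA", "SER", "A", 3, 7.6, 0.0, 0.0, b=30.00),
        "END",
    ]
    return "\n".join(lines) + "\n"


@pytest.fixture
def worked_example():
    """Full planted scenario: bump at 63-68, query TKWDCK vs consensus TNITCT."""
    pdb_text, pdb_truth = syn.gen_pdb(seed=11)
    fasta, msa_truth = syn.gen_msa(seed=12)
    records = read_pdb_calpha(io.StringIO(pdb_text))
    profile = normalize_bfactors(records)
    regions = detect_flexible_regions(profile, threshold=1.0, min_run=3)
    alignment = read_alignment(io.StringIO(fasta))
    qmap = map_query_to_columns(alignment, msa_truth["query_id"],
                                offset=msa_truth["offset"])
    return {
        "profile": profile,
        "regions": regions,
        "alignment": alignment,
        "qmap": qmap,
        "pdb_truth": pdb_truth,
        "msa_truth": msa_truth,
    }
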