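"""Candidate stabilizing substitutions: flexible regions x MSA consensus.

A position is proposed for mutation when (i) it lies inside a detected
high-flexibility region of the normalized B-factor profile and (ii) the
consensus residue of the homolog alignment at the mapped column differs from
the wild-type residue and is supported by enough non-gap sequences.  The
emitted candidate is "mutate wild type to consensus", labelled in the usual
point-mutant style (e.g. ``K64N``).  A score combining flexibility and
conservation orders the list; it is a tie-ordering aid, never a filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from flexistab.msa import Alignment, QueryColumnMap, column_profiles
from flexistab.structure import BFactorProfile, FlexibleRegion

__all__ = [
    "MutationCandidate",
    "DesignParams",
    "score_candidate",
    "propose_mutations",
    "design_report",
    "write_candidates_csv",
]


@dataclass(frozen=True)
class MutationCandidate:
    """A proposed point substitution with its supporting evidence."""

    position: int
    wt_aa: str
    proposed_aa: str
    b_norm: float
    consensus_freq: float
    score: float
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.wt_aa == self.proposed_aa:
            raise ValueError("candidate must change the residue")

    @property
    def label(self) -> str:
        return f"{self.wt_aa}{self.position}{self.proposed_aa}"


@dataclass
class DesignParams:
    """Filters and ranking weights for mutation proposal.

    ``min_consensus_freq`` — minimum plurality frequency of the consensus
    residue (non-gap).  ``max_gap_frac`` — columns gappier than this are not
    trusted.  ``weights`` — (flexibility, conservation) score weights, must be
    non-negative and sum to 1.  ``b_cap`` — B' value treated as maximal
    flexibility in the score.
    """

    min_consensus_freq: float = 0.5
    max_gap_frac: float = 0.5
    weights: tuple[float, float] = (0.5, 0.5)
    b_cap: float = 3.0

    def __post_init__(self) -> None:
        if min(self.weights) < 0:
            raise ValueError("invalid weights: must be non-negative")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("invalid weights: must sum to 1")


def score_candidate(
    b_norm: float,
    consensus_freq: float,
    weights: tuple[float, float] = (0.5, 0.5),
    b_cap: float = 3.0,
) -> float:
    """Ranking score w1 * min(B'/b_cap, 1) + w2 * consensus_freq.

    The flexibility term is clipped to [0, 1] (B' above ``b_cap`` counts as
    maximally flexible; negative B' contributes nothing).
    """
    if min(weights) < 0:
        raise ValueError("invalid weights: must be non-negative")
    flex = min(max(b_norm, 0.0) / b_cap, 1.0)
    return weights[0] * flex + weights[1] * consensus_freq


def propose_mutations(
    bprofile: BFactorProfile,
    regions: Sequence[FlexibleRegion],
    alignment: Alignment,
    qmap: QueryColumnMap,
    params: DesignParams | None = None,
) -> list[MutationCandidate]:
    """Emit one candidate per flexible position whose consensus differs from WT.

    Positions where the consensus equals the wild-type residue, where the
    mapped column fails the frequency/gap filters, or where the query is
    gapped (skipped with a warning) emit nothing.  Candidates are sorted by
    score descending, ties by position ascending.
    """
    params = params or DesignParams()
    profiles = {p.col: p for p in column_profiles(alignment)}
    query_row = alignment.sequence(qmap.query_id)

    candidates: list[MutationCandidate] = []
    for region in regions:
        for pos in region.member_positions:
            col = qmap.column_for_residue(pos)
            if col is None:
                warnings.warn(f"flexible position {pos} not mapped (query gap); skipped",
                              stacklevel=2)
                continue
            wt = query_row[col - 1]
            prof = profiles[col]
            if prof.degenerate or prof.consensus_aa == wt:
                continue
            if prof.consensus_freq < params.min_consensus_freq:
                continue
            if prof.gap_frac > params.max_gap_frac:
                continue
            bn = bprofile.bnorm_at(pos)
            flags: list[str] = []
            if prof.consensus_aa == "C":
                flags.append("introduces-cysteine")
            candidates.append(
                MutationCandidate(
                    position=pos,
                    wt_aa=wt,
                    proposed_aa=prof.consensus_aa,
                    b_norm=bn,
                    consensus_freq=prof.consensus_freq,
                    score=score_candidate(bn, prof.consensus_freq,
                                          params.weights, params.b_cap),
                    flags=tuple(flags),
                )
            )
    candidates.sort(key=lambda c: (-c.score, c.position))
    return candidates


def design_report(
    candidates: Sequence[MutationCandidate],
    metadata: dict | None = None,
) -> str:
    """Human-readable report listing candidates with evidence and provenance."""
    metadata = metadata or {}
    lines = ["# flexistab mutation design report"]
    for key, value in metadata.items():
        lines.append(f"# {key}: {value}")
    lines.append("")
    if not candidates:
        lines.append("No candidate substitutions passed the filters.")
    else:
        lines.append(f"{len(candidates)} candidate substitution(s), ranked:")
        lines.append("")
        lines.append(f"{'label':<8} {'B_norm':>8} {'cons_freq':>10} {'score':>8}  flags")
        for c in candidates:
            lines.append(
                f"{c.label:<8} {c.b_norm:>8.3f} {c.consensus_freq:>10.3f} "
                f"{c.score:>8.3f}  {','.join(c.flags)}"
            )
    return "\n".join(lines) + "\n"


def write_candidates_csv(
    candidates: Sequence[MutationCandidate], path: str | Path
) -> None:
    df = pd.DataFrame(
        {
            "label": [c.label for c in candidates],
            "position": [c.position for c in candidates],
            "wt_aa": [c.wt_aa for c in candidates],
            "proposed_aa": [c.proposed_aa for c in candidates],
            "b_norm": [round(c.b_norm, 4) for c in candidates],
            "consensus_freq": [round(c.consensus_freq, 4) for c in candidates],
            "score": [round(c.score, 4) for c in candidates],
            "flags": [";".join(c.flags) for c in candidates],
        }
    )
    df.to_csv(path, index=False)
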