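"""Candidate-ligand re-ranking: density fit combined with interaction energy.

When several chemical identities are plausible for one density cluster, each
candidate carries a real-space correlation coefficient (RSCC, higher is
better) and a normalized interaction energy (kcal/mol per heavy atom, lower
is better).  The combined score is a nonparametric average: each metric is
converted to its within-list rank (ties share the mean rank) and the two
ranks are averaged.  Being rank-based, the score is invariant to any
order-preserving rescaling of either metric — RSCC values near 1 and
energies spanning orders of magnitude need no calibration against each
other.  A high-RSCC candidate that clashes with the protein (positive
normalized energy) is thereby demoted below a slightly worse-fitting but
energetically sound alternative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd
from scipy.stats import rankdata

from .scoring import _categorize

__all__ = ["Candidate", "combined_rank", "rank_report"]


@dataclass
class Candidate:
    ligand_id: str
    rscc: float
    e_normalized: float
    combined: float
    rank: int


def combined_rank(candidates: Sequence[tuple[str, Optional[float], float]],
                  method: str = "rank") -> list[Candidate]:
    """Score and order candidate ligand identities.

    ``candidates`` is a sequence of ``(ligand_id, rscc, e_normalized)``.
    With ``method="rank"`` (the default) the combined score is the mean of
    the within-list ranks of RSCC (descending) and normalized energy
    (ascending); ``method="minmax"`` instead averages min-max-rescaled
    values (provided as a sensitivity alternative — it is *not*
    scale-free).  Output is sorted by combined score; ties break by better
    normalized energy, then lexicographic id.  A missing RSCC raises
    ``ValueError``.
    """
    if not candidates:
        raise ValueError("need at least one candidate")
    ids = [c[0] for c in candidates]
    rsccs = [c[1] for c in candidates]
    energies = [float(c[2]) for c in candidates]
    if any(r is None for r in rsccs):
        missing = [i for i, r in zip(ids, rsccs) if r is None]
        raise ValueError(f"missing RSCC for candidate(s): {missing}")
    rsccs = [float(r) for r in rsccs]  # type: ignore[arg-type]

    if method == "rank":
        # rank 1 = best: highest RSCC, lowest energy
        r_rscc = rankdata([-r for r in rsccs], method="average")
        r_en = rankdata(energies, method="average")
        combined = [(a + b) / 2.0 for a, b in zip(r_rscc, r_en)]
    elif method == "minmax":
        def rescale(vals: list[float], low_is_good: bool) -> list[float]:
            lo, hi = min(vals), max(vals)
            if hi == lo:
                return [0.5] * len(vals)
            scaled = [(v - lo) / (hi - lo) for v in vals]
            return scaled if low_is_good else [1.0 - s for s in scaled]
        combined = [(a + b) / 2.0
                    for a, b in zip(rescale(rsccs, False), rescale(energies, True))]
    else:
        raise ValueError(f"unknown method {method!r}")

    order = sorted(range(len(ids)),
                   key=lambda i: (combined[i], energies[i], ids[i]))
    out = []
    for pos, i in enumerate(order, start=1):
        out.append(Candidate(ligand_id=ids[i], rscc=rsccs[i],
                             e_normalized=energies[i], combined=combined[i],
                             rank=pos))
    return out


def rank_report(candidates: Sequence[Candidate]) -> pd.DataFrame:
    """Tidy table of the ranked candidates (one row per candidate)."""
    return pd.DataFrame(
        [{
            "ligand_id": c.ligand_id,
            "rscc": c.rscc,
            "e_normalized": c.e_normalized,
            "combined": c.combined,
            "rank": c.rank,
            "category": _categorize(c.e_normalized),
        } for c in candidates],
        columns=["ligand_id", "rscc", "e_normalized", "combined", "rank",
                 "category"],
    )
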