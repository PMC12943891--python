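"""Selection of top-scoring peptide candidates from MM-GBSA results.

Scores arrive as one record per (peptide, terminal variant, conformer,
replicate).  Within each variant family a peptide's rank key is its best
(minimum) mean binding free energy over replicates/conformers — the
"lowest dG from one of the replicates" convention — and the k peptides
with the smallest keys are selected.  A mean-over-replicates key is
available as an alternative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = ["CandidateScore", "select_top", "best_replicate"]


@dataclass(frozen=True)
class CandidateScore:
    """One MM-GBSA estimate for a peptide run."""

    peptide_id: str
    variant: str  # "free" | "capped"
    dg_mean: float  # kcal/mol
    dg_sem: float = 0.0  # kcal/mol
    conformer_id: str = "c0"
    replicate_id: int = 0

    def __post_init__(self) -> None:
        if self.dg_sem < 0:
            raise ValueError("dg_sem must be >= 0")
        if self.variant not in ("free", "capped"):
            raise ValueError(f"unknown variant {self.variant!r}")


def best_replicate(scores: Sequence[CandidateScore]) -> CandidateScore:
    """The record with minimum dg_mean; ties resolved by lowest replicate id."""
    if not scores:
        raise ValueError("no score records")
    return min(scores, key=lambda s: (s.dg_mean, s.replicate_id, s.conformer_id))


def select_top(
    scores: Iterable[CandidateScore],
    k: int = 3,
    key: str = "min",
) -> dict[str, list[str]]:
    """Top-k peptide ids per variant group, lowest binding free energy first.

    ``key="min"`` ranks each peptide by its best replicate/conformer;
    ``key="mean"`` ranks by the mean over its records.  Exact ties are
    broken by lexicographic peptide id.  If a group has fewer than k
    distinct peptides, all are returned with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if key not in ("min", "mean"):
        raise ValueError(f"unknown rank key {key!r}")
    groups: dict[str, dict[str, list[CandidateScore]]] = {}
    for s in scores:
        groups.setdefault(s.variant, {}).setdefault(s.peptide_id, []).append(s)
    selected: dict[str, list[str]] = {}
    for variant in sorted(groups):
        peptides = groups[variant]
        if len(peptides) < k:
            warnings.warn(
                f"variant {variant!r}: only {len(peptides)} peptides for k={k}",
                stacklevel=2,
            )
        ranked = []
        for pid, records in peptides.items():
            if key == "min":
                rank_dg = min(r.dg_mean for r in records)
            else:
                rank_dg = sum(r.dg_mean for r in records) / len(records)
            ranked.append((rank_dg, pid))
        ranked.sort()  # (dg, id): numeric first, lexicographic id on ties
        selected[variant] = [pid for _, pid in ranked[:k]]
    return selected
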