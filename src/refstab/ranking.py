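"""Stepwise-elimination stability ranking.

M-values are recomputed after removing the least stable (highest-M) gene at
each step, until two genes remain.  Those two cannot be discriminated — with
only one pairwise ratio left their M-values are identical by construction —
so the final pair is reported as tied at the top of the ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from refstab.quantify import RQMatrix
from refstab.stability import m_values

__all__ = ["RankingStep", "RankingTrace", "rank_genes", "rank_genes_by_condition"]


@dataclass(frozen=True)
class RankingStep:
    """One elimination round: the M-values seen and the gene removed."""

    eliminated_gene: str
    m_values_at_step: pd.Series
    tied: bool = False


@dataclass
class RankingTrace:
    """Full record of the stepwise elimination.

    ``full_order`` lists genes from most to least stable: the tied final pair
    first (sorted alphabetically for determinism), then the eliminated genes
    in reverse elimination order.
    """

    steps: list[RankingStep]
    final_pair: tuple[str, str]
    final_m: float
    full_order: list[str] = field(init=False)

    def __post_init__(self) -> None:
        eliminated = [s.eliminated_gene for s in self.steps]
        self.full_order = list(self.final_pair) + eliminated[::-1]

    @property
    def eliminated(self) -> list[str]:
        return [s.eliminated_gene for s in self.steps]

    def display_order(self, cv: pd.Series) -> list[str]:
        """``full_order`` with the tied final pair sorted by CV — a display
        convenience only; it never affects the trace or downstream NF order."""
        pair = sorted(self.final_pair, key=lambda g: float(cv[g]))
        return pair + self.eliminated[::-1]

    def to_frame(self) -> pd.DataFrame:
        """step, eliminated_gene, then one M column per gene (empty once gone)."""
        genes = self.full_order
        rows = []
        for i, step in enumerate(self.steps, start=1):
            row = {"step": i, "eliminated_gene": step.eliminated_gene}
            for g in genes:
                row[g] = step.m_values_at_step.get(g, None)
            rows.append(row)
        final = {"step": len(self.steps) + 1, "eliminated_gene": ""}
        for g in genes:
            final[g] = self.final_m if g in self.final_pair else None
        rows.append(final)
        return pd.DataFrame(rows, columns=["step", "eliminated_gene", *genes])

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def rank_genes(rq: RQMatrix | pd.DataFrame) -> RankingTrace:
    """Rank candidate genes by iterative worst-gene elimination.

    Requires >= 3 genes.  Ties in the maximal M are broken by eliminating the
    lexicographically last gene label; the tie is flagged in the trace.
    """
    frame = rq.values if isinstance(rq, RQMatrix) else pd.DataFrame(rq).astype(float)
    if frame.shape[0] < 3:
        raise ValueError("ranking needs >= 3 genes")

    remaining = frame.copy()
    steps: list[RankingStep] = []
    while remaining.shape[0] > 2:
        m = m_values(remaining)
        worst_m = m.max()
        at_max = sorted(m.index[m == worst_m])
        victim = at_max[-1]
        steps.append(RankingStep(victim, m, tied=len(at_max) > 1))
        remaining = remaining.drop(index=victim)

    final_m = float(m_values(remaining).iloc[0])
    pair = tuple(sorted(remaining.index))
    return RankingTrace(steps=steps, final_pair=pair, final_m=final_m)


def rank_genes_by_condition(rq: RQMatrix) -> dict[str, RankingTrace]:
    """One ranking trace per condition group (exploratory; needs >= 2 samples
    per condition for the SDs to exist)."""
    if rq.conditions is None:
        raise ValueError("RQ matrix carries no condition labels")
    traces: dict[str, RankingTrace] = {}
    for cond, samples in rq.conditions.groupby(rq.conditions):
        cols = [s for s in samples.index if s in rq.values.columns]
        if len(cols) < 2:
            continue
        traces[str(cond)] = rank_genes(rq.values[cols])
    return traces
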