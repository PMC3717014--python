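"""Normalization factors and the V(n, n+1) minimal-gene criterion.

The normalization factor NF_n of a sample is the geometric mean of the n most
stable reference genes' relative quantities.  To decide how many reference
genes are needed, the pairwise variation V(n, n+1) — the sample standard
deviation across samples of log2(NF_n / NF_{n+1}) — is computed for
increasing n, adding genes in stability-ranking order.  Once V drops below a
threshold (0.15 by convention) the added gene contributes no meaningful
information and n genes suffice; if already V(2,3) is below the threshold,
two reference genes are enough.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from refstab.quantify import RQMatrix
from refstab.ranking import RankingTrace
from refstab.stability import _as_frame, m_values

__all__ = [
    "VSeries",
    "normalization_factor",
    "pairwise_variation_series",
    "worst_pair_check",
]

DEFAULT_V_THRESHOLD = 0.15


@dataclass
class VSeries:
    """Pairwise variations V(n, n+1) for n = 2 .. G-1.

    ``recommended_n`` is the smallest n whose V falls below the threshold, or
    the total gene count if none does.
    """

    entries: list[tuple[int, float]]
    gene_order: list[str]
    threshold: float
    recommended_n: int

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.entries, columns=["n", "v"])
        frame["below_threshold"] = frame["v"] < self.threshold
        return frame

    def write(self, path: str | Path) -> None:
        path = Path(path)
        with path.open("w", encoding="utf-8") as fh:
            fh.write(f"# recommended_n={self.recommended_n} threshold={self.threshold:g} "
                     f"gene_order={','.join(self.gene_order)}\n")
            self.to_frame().to_csv(fh, index=False)


def normalization_factor(rq: RQMatrix | pd.DataFrame, genes: Sequence[str]) -> pd.Series:
    """Per-sample geometric mean of the given genes' relative quantities."""
    frame = _as_frame(rq)
    genes = list(genes)
    if not genes:
        raise ValueError("normalization factor needs a nonempty gene subset")
    missing = [g for g in genes if g not in frame.index]
    if missing:
        raise KeyError(f"genes not in matrix: {missing}")
    nf = np.exp2(np.log2(frame.loc[genes].values).mean(axis=0))
    return pd.Series(nf, index=frame.columns, name=f"NF_{len(genes)}")


def _v_between(nf_a: pd.Series, nf_b: pd.Series, ddof: int = 1) -> float:
    return float(np.std(np.log2(nf_a.values / nf_b.values), ddof=ddof))


def pairwise_variation_series(
    rq: RQMatrix | pd.DataFrame,
    ranking: RankingTrace | Sequence[str],
    threshold: float = DEFAULT_V_THRESHOLD,
) -> VSeries:
    """Compute V(n, n+1) for n = 2 .. G-1 along a stability ranking.

    ``ranking`` is a RankingTrace (its ``full_order`` is used: tied final
    pair first, then reverse elimination order) or an explicit most-stable-
    first gene list covering the matrix.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    frame = _as_frame(rq)
    order = list(ranking.full_order) if isinstance(ranking, RankingTrace) else list(ranking)
    if sorted(order) != sorted(frame.index):
        raise ValueError("ranking must cover exactly the matrix's genes")
    g = len(order)
    if g < 3:
        raise ValueError("V series needs >= 3 genes")

    entries: list[tuple[int, float]] = []
    for n in range(2, g):
        nf_n = normalization_factor(frame, order[:n])
        nf_n1 = normalization_factor(frame, order[: n + 1])
        entries.append((n, _v_between(nf_n, nf_n1)))

    below = [n for n, v in entries if v < threshold]
    recommended = min(below) if below else g
    return VSeries(entries=entries, gene_order=order, threshold=threshold,
                   recommended_n=recommended)


def worst_pair_check(
    rq: RQMatrix | pd.DataFrame,
    validated_genes: Sequence[str],
    threshold: float = DEFAULT_V_THRESHOLD,
) -> tuple[float, bool]:
    """Stress-test the V criterion with the LEAST stable validated genes.

    Orders the validated genes by M-value (computed on the validated subset),
    forms the normalization factor of the two worst, adds the third worst,
    and reports the V-style variation between the two factors plus whether it
    stays below the threshold.  If even the worst validated pair passes, any
    validated pair is a safe normalizer.
    """
    frame = _as_frame(rq)
    validated = list(validated_genes)
    if len(validated) < 2:
        raise ValueError("worst-pair check needs >= 2 validated genes")
    if len(validated) == 2:
        raise ValueError(
            "worst-pair check needs a third validated gene to add to the pair"
        )
    missing = [g for g in validated if g not in frame.index]
    if missing:
        raise KeyError(f"genes not in matrix: {missing}")

    m = m_values(frame.loc[validated]).sort_values(kind="stable")
    worst_first = list(m.index[::-1])  # least stable first
    pair = worst_first[:2]
    trio = worst_first[:3]
    v = _v_between(normalization_factor(frame, pair), normalization_factor(frame, trio))
    return v, v < threshold
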