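"""Efficiency-corrected relative quantification of Cq values.

Each gene's Cq values are rescaled to that gene's lowest observed Cq (the
internal control), then converted to linear relative quantities

    RQ = (1 + E)^(Cq_anchor - Cq_well)

with the gene-specific amplification efficiency E, and technical replicates
are averaged arithmetically on the linear scale.  The anchor cancels from
every downstream ratio statistic (M, CV, V), so it only fixes the reported
RQ magnitudes: the maximum RQ of a gene is attained at its lowest-Cq well.

Amplification efficiencies are estimated from serial-dilution calibration
curves by ordinary least squares of Cq against log10 of the relative
template amount: E = 10^(-1/slope) - 1, with slope in cycles per decade
(slope -3.32 corresponds to perfect doubling, E = 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from refstab.cq_io import CqTable, DilutionSeries, EfficiencyTable, drop_incomplete_samples

__all__ = ["RQMatrix", "EfficiencyFit", "to_relative_quantities", "estimate_efficiency"]

logger = logging.getLogger(__name__)


@dataclass
class RQMatrix:
    """Gene x sample matrix of relative quantities.

    ``values`` has genes as rows and samples as columns, all entries > 0.
    ``anchors`` holds the per-gene internal-control Cq used for rescaling and
    ``efficiencies`` the per-gene amplification efficiency; both are carried
    for reporting only.  ``conditions`` maps sample -> group label.
    """

    values: pd.DataFrame
    anchors: pd.Series | None = None
    efficiencies: pd.Series | None = None
    conditions: pd.Series | None = None

    def __post_init__(self) -> None:
        v = self.values.astype(float)
        if (v.values <= 0).any() or not np.isfinite(v.values).all():
            raise ValueError("relative quantities must be finite and > 0")
        self.values = v

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def subset(self, genes: Sequence[str]) -> "RQMatrix":
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise KeyError(f"genes not in matrix: {missing}")
        sel = list(genes)
        return RQMatrix(
            self.values.loc[sel],
            self.anchors.loc[sel] if self.anchors is not None else None,
            self.efficiencies.loc[sel] if self.efficiencies is not None else None,
            self.conditions,
        )

    def write(self, path: str | Path, sidecar: str | Path | None = None) -> None:
        """Write the matrix (genes as rows); optional sidecar of anchors/efficiencies."""
        self.values.rename_axis("gene").to_csv(path)
        if sidecar is not None:
            side = pd.DataFrame({
                "anchor_cq": self.anchors if self.anchors is not None else np.nan,
                "efficiency": self.efficiencies if self.efficiencies is not None else np.nan,
            })
            side.rename_axis("gene").to_csv(sidecar)


class EfficiencyFit(NamedTuple):
    """Dilution-series fit: efficiency (fraction), slope (cycles/decade), R^2."""

    efficiency: float
    slope: float
    r_squared: float


def to_relative_quantities(
    table: CqTable,
    eff: EfficiencyTable,
    replicate_average: str = "rq",
    on_incomplete: str = "warn",
) -> RQMatrix:
    """Convert a QC'd Cq table into an efficiency-corrected RQ matrix.

    Per gene g the anchor A_g is the minimum Cq over all wells of g; each
    well's RQ is (1+E_g)^(A_g - Cq); per (sample, gene) the replicate RQs are
    averaged arithmetically (``replicate_average='cq'`` instead averages Cq
    first, i.e. geometric-mean behaviour on the linear scale).  Samples
    missing any gene are dropped with a warning (complete-case requirement).
    """
    if replicate_average not in ("rq", "cq"):
        raise ValueError("replicate_average must be 'rq' or 'cq'")
    missing = [g for g in table.genes if g not in eff]
    if missing:
        raise KeyError(f"no amplification efficiency for gene(s): {missing}")

    table, dropped = drop_incomplete_samples(table, on_incomplete=on_incomplete)
    if dropped:
        logger.warning("dropped incomplete samples (missing genes after QC): %s", dropped)

    frame = table.frame
    anchors = frame.groupby("gene")["cq"].min()
    effs = pd.Series({g: eff[g] for g in anchors.index})

    if replicate_average == "rq":
        rq_well = (1.0 + effs.loc[frame["gene"]].values) ** (
            anchors.loc[frame["gene"]].values - frame["cq"].values
        )
        per = frame.assign(rq=rq_well).groupby(["gene", "sample"])["rq"].mean()
    else:
        mean_cq = frame.groupby(["gene", "sample"])["cq"].mean()
        g_idx = mean_cq.index.get_level_values("gene")
        per = (1.0 + effs.loc[g_idx].values) ** (anchors.loc[g_idx].values - mean_cq.values)
        per = pd.Series(per, index=mean_cq.index)

    values = per.unstack("sample").loc[sorted(anchors.index), sorted(table.samples)]
    return RQMatrix(values, anchors=anchors.loc[values.index],
                    efficiencies=effs.loc[values.index], conditions=table.conditions())


def estimate_efficiency(series: DilutionSeries) -> EfficiencyFit:
    """Estimate amplification efficiency from a serial-dilution curve.

    Fits Cq ~ log10(relative template amount) by OLS, where the relative
    amount at dilution factor d is 1/d.  Requires >= 3 distinct dilutions and
    a negative slope (Cq must rise with dilution).
    """
    log_amount = -np.log10(series.dilutions)
    fit = stats.linregress(log_amount, series.cqs)
    if fit.slope >= 0:
        raise ValueError(
            f"dilution-series slope must be negative (Cq increases with dilution), "
            f"got {fit.slope:.4g} for {series.gene}"
        )
    efficiency = 10.0 ** (-1.0 / fit.slope) - 1.0
    return EfficiencyFit(float(efficiency), float(fit.slope), float(fit.rvalue**2))
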