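"""Expression-stability statistics: pairwise variation, M-values, CV.

The geNorm stability measure rests on the idea that the expression ratio of
two ideal reference genes is constant across samples.  For genes j and k the
pairwise variation V(j,k) is the sample standard deviation (n-1 denominator)
across samples of log2(RQ_j / RQ_k); a gene's M-value is the mean of its
pairwise variations with every other candidate.  Lower M = more stable.
The coefficient of variation CV = sigma/mu of a gene's relative quantities
is an independent, gene-specific dispersion gate: a gene can hold a good
M-value by co-varying with the panel yet still swing too much on its own.

Cut-offs follow the heterogeneous-panel convention (M < 1.0, CV < 50%); for
homogeneous experimental conditions the stricter M < 0.5, CV < 25% applies.
Comparisons are strict, and both gates must pass for a gene to be validated.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from refstab.quantify import RQMatrix

__all__ = [
    "CutoffPolicy",
    "pairwise_variation_matrix",
    "m_values",
    "coefficient_of_variation",
    "classify",
    "write_stability_report",
]


def _as_frame(rq: RQMatrix | pd.DataFrame) -> pd.DataFrame:
    frame = rq.values if isinstance(rq, RQMatrix) else pd.DataFrame(rq).astype(float)
    if (frame.values <= 0).any() or not np.isfinite(frame.values).all():
        raise ValueError("relative quantities must be finite and > 0")
    return frame


@dataclass(frozen=True)
class CutoffPolicy:
    """Validation thresholds for M and CV.

    ``heterogeneous`` panels (samples spanning conditions, as in a
    timepoint study) use m_cutoff 1.0 / cv_cutoff 0.50; ``homogeneous``
    panels use 0.5 / 0.25.
    """

    m_cutoff: float = 1.0
    cv_cutoff: float = 0.50
    panel: str = "heterogeneous"

    @classmethod
    def heterogeneous(cls) -> "CutoffPolicy":
        return cls(1.0, 0.50, "heterogeneous")

    @classmethod
    def homogeneous(cls) -> "CutoffPolicy":
        return cls(0.5, 0.25, "homogeneous")


def pairwise_variation_matrix(rq: RQMatrix | pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Symmetric gene x gene matrix of SD(log2 RQ_j/RQ_k) across samples."""
    frame = _as_frame(rq)
    if frame.shape[0] < 2:
        raise ValueError("need >= 2 genes")
    if frame.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    log2 = np.log2(frame.values)
    # V[j,k] = std over samples of (log2 rq_j - log2 rq_k)
    diffs = log2[:, None, :] - log2[None, :, :]
    v = diffs.std(axis=2, ddof=ddof)
    np.fill_diagonal(v, 0.0)
    return pd.DataFrame(v, index=frame.index, columns=frame.index)


def m_values(rq: RQMatrix | pd.DataFrame, ddof: int = 1) -> pd.Series:
    """Per-gene geNorm M: mean pairwise variation with all other genes.

    With exactly two genes both M equal their single pairwise variation.
    """
    v = pairwise_variation_matrix(rq, ddof=ddof)
    n = v.shape[0]
    m = v.sum(axis=1) / (n - 1)
    return m.rename("m_value")


def coefficient_of_variation(
    rq: RQMatrix | pd.DataFrame,
    ddof: int = 1,
    normalize_to: list[str] | None = None,
) -> pd.Series:
    """Per-gene CV = SD/mean of the gene's relative quantities across samples.

    By default the CV is taken on raw relative quantities.  ``normalize_to``
    switches to the normalized-RQ convention: each sample's RQs are first
    divided by the geometric mean of the listed reference genes' RQs.
    """
    frame = _as_frame(rq)
    if frame.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    if normalize_to is not None:
        missing = [g for g in normalize_to if g not in frame.index]
        if missing:
            raise KeyError(f"genes not in matrix: {missing}")
        nf = np.exp2(np.log2(frame.loc[list(normalize_to)].values).mean(axis=0))
        frame = frame / nf
    cv = frame.std(axis=1, ddof=ddof) / frame.mean(axis=1)
    return cv.rename("cv")


def classify(
    m: pd.Series, cv: pd.Series, policy: CutoffPolicy | None = None
) -> pd.DataFrame:
    """Apply the M and CV gates; a gene is validated iff both pass (strict <)."""
    policy = policy or CutoffPolicy.heterogeneous()
    genes = m.index
    report = pd.DataFrame({
        "m_value": m.astype(float),
        "cv": cv.reindex(genes).astype(float),
    })
    report["passes_m"] = report["m_value"] < policy.m_cutoff
    report["passes_cv"] = report["cv"] < policy.cv_cutoff
    report["validated"] = report["passes_m"] & report["passes_cv"]
    return report.rename_axis("gene")


def write_stability_report(
    report: pd.DataFrame, path: str | Path, policy: CutoffPolicy | None = None
) -> None:
    policy = policy or CutoffPolicy.heterogeneous()
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"# m_cutoff={policy.m_cutoff:g} cv_cutoff={policy.cv_cutoff:g} "
                 f"panel={policy.panel}\n")
        report.to_csv(fh)
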