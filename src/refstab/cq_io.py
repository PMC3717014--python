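"""Cq table I/O, validation and quality filtering.

The shared data model for the pipeline lives here: well-level quantification
cycle (Cq) observations, per-gene amplification efficiencies, and serial
dilution series.  Files are plain delimited text (comma or tab, sniffed).

Long format columns: ``sample,gene,replicate,cq,condition`` (``replicate``,
``condition`` and ``tissue`` optional).  Wide format: leading columns
``sample`` (then optionally ``replicate`` and ``condition``), followed by one
column per gene.
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CqMeasurement",
    "CqTable",
    "EfficiencyTable",
    "DilutionSeries",
    "QCLog",
    "CqValidationError",
    "CqParseError",
    "read_cq_table",
    "write_cq_table",
    "read_efficiencies",
    "write_efficiencies",
    "qc_filter",
    "drop_incomplete_samples",
]

#: canonical long-format column order
LONG_COLUMNS = ("sample", "gene", "replicate", "cq", "condition", "tissue")
#: wide-format leading (non-gene) columns, in the order they may appear
WIDE_ID_COLUMNS = ("sample", "replicate", "condition", "tissue")


class CqParseError(ValueError):
    """A file could not be parsed into the expected table shape."""


class CqValidationError(ValueError):
    """A parsed table violates a data-model invariant."""


@dataclass(frozen=True)
class CqMeasurement:
    """One well: a single technical replicate of one gene in one sample."""

    sample_id: str
    gene: str
    replicate_index: int
    cq: float
    condition: str | None = None
    tissue: str | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.cq) or self.cq <= 0:
            raise CqValidationError(
                f"cq must be finite and > 0, got {self.cq!r} for "
                f"({self.sample_id}, {self.gene}, {self.replicate_index})"
            )
        if self.replicate_index < 1:
            raise CqValidationError("replicate_index must be a positive integer")


class CqTable:
    """A validated collection of Cq measurements.

    Internally a pandas DataFrame with columns ``sample, gene, replicate, cq,
    condition, tissue``; ``metadata`` is a free-form dict (instrument, plate
    layout, notes).  Construction validates finiteness/positivity of every Cq
    and uniqueness of ``(sample, gene, replicate)``.
    """

    def __init__(self, frame: pd.DataFrame, metadata: dict | None = None):
        frame = frame.copy()
        for col in ("condition", "tissue"):
            if col not in frame.columns:
                frame[col] = None
        missing = {"sample", "gene", "replicate", "cq"} - set(frame.columns)
        if missing:
            raise CqParseError(f"missing mandatory columns: {sorted(missing)}")
        frame = frame.loc[:, list(LONG_COLUMNS)].reset_index(drop=True)
        frame["sample"] = frame["sample"].astype(str)
        frame["gene"] = frame["gene"].astype(str)
        frame["replicate"] = frame["replicate"].astype(int)
        frame["cq"] = frame["cq"].astype(float)
        self._validate(frame)
        self.frame = frame
        self.metadata: dict = dict(metadata or {})

    @staticmethod
    def _validate(frame: pd.DataFrame) -> None:
        bad = frame[~np.isfinite(frame["cq"]) | (frame["cq"] <= 0)]
        if len(bad):
            rows = bad.index[:5].tolist()
            raise CqValidationError(
                f"cq must be finite and > 0; offending rows (0-based): {rows}"
            )
        if (frame["replicate"] < 1).any():
            raise CqValidationError("replicate indices must be positive integers")
        dup = frame.duplicated(subset=["sample", "gene", "replicate"], keep=False)
        if dup.any():
            first = frame.loc[dup, ["sample", "gene", "replicate"]].iloc[0]
            raise CqValidationError(
                "duplicate (sample, gene, replicate) entry: "
                f"({first['sample']}, {first['gene']}, {first['replicate']})"
            )

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_measurements(
        cls, measurements: Iterable[CqMeasurement], metadata: dict | None = None
    ) -> "CqTable":
        rows = [
            (m.sample_id, m.gene, m.replicate_index, m.cq, m.condition, m.tissue)
            for m in measurements
        ]
        frame = pd.DataFrame(rows, columns=list(LONG_COLUMNS))
        return cls(frame, metadata)

    # -- views --------------------------------------------------------------

    @property
    def genes(self) -> list[str]:
        return sorted(self.frame["gene"].unique())

    @property
    def samples(self) -> list[str]:
        return sorted(self.frame["sample"].unique())

    @property
    def n_measurements(self) -> int:
        return len(self.frame)

    def measurements(self) -> list[CqMeasurement]:
        return [
            CqMeasurement(r.sample, r.gene, int(r.replicate), float(r.cq),
                          None if pd.isna(r.condition) else r.condition,
                          None if pd.isna(r.tissue) else r.tissue)
            for r in self.frame.itertuples(index=False)
        ]

    def conditions(self) -> pd.Series:
        """condition label per sample (first seen wins)."""
        return self.frame.groupby("sample", sort=True)["condition"].first()

    def is_complete(self) -> bool:
        """True if every sample carries every gene (full gene x sample grid)."""
        counts = self.frame.groupby("sample")["gene"].nunique()
        return bool((counts == len(self.genes)).all())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CqTable):
            return NotImplemented
        a = self.frame.sort_values(["sample", "gene", "replicate"]).reset_index(drop=True)
        b = other.frame.sort_values(["sample", "gene", "replicate"]).reset_index(drop=True)
        return a.equals(b)

    def __repr__(self) -> str:
        return (
            f"CqTable({self.n_measurements} measurements, "
            f"{len(self.genes)} genes, {len(self.samples)} samples)"
        )


@dataclass
class EfficiencyTable:
    """Per-gene amplification efficiency as a fraction in (0, 1.1].

    E = 1 means perfect per-cycle doubling.  Values marginally above 1 are
    tolerated (regression noise on dilution-series fits); anything outside
    (0, 1.1] raises.  ``source`` records whether values were supplied by the
    user or estimated from dilution series.
    """

    efficiencies: pd.Series
    source: str = "provided"

    def __post_init__(self) -> None:
        s = pd.Series(self.efficiencies, dtype=float)
        s.index = s.index.astype(str)
        if self.source not in ("provided", "estimated"):
            raise ValueError(f"source must be 'provided' or 'estimated', got {self.source!r}")
        bad = s[(s <= 0) | (s > 1.1) | ~np.isfinite(s)]
        if len(bad):
            g, v = bad.index[0], bad.iloc[0]
            raise ValueError(f"efficiency out of range (0, 1.1] for {g}: {v}")
        object.__setattr__(self, "efficiencies", s)

    def __getitem__(self, gene: str) -> float:
        if gene not in self.efficiencies.index:
            raise KeyError(f"no efficiency for gene {gene!r}")
        return float(self.efficiencies[gene])

    def __contains__(self, gene: str) -> bool:
        return gene in self.efficiencies.index

    @property
    def genes(self) -> list[str]:
        return list(self.efficiencies.index)


@dataclass(frozen=True)
class DilutionSeries:
    """Serial-dilution calibration points for one primer pair.

    ``points`` holds (dilution_factor, cq) pairs; dilution_factor d means the
    template was diluted d-fold relative to the most concentrated point, so
    relative template amount is 1/d.
    """

    gene: str
    points: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        pts = tuple((float(d), float(c)) for d, c in self.points)
        if any(d <= 0 for d, _ in pts):
            raise ValueError("dilution factors must be strictly positive")
        if len({d for d, _ in pts}) < 3:
            raise ValueError("a dilution series needs >= 3 distinct dilution factors")
        object.__setattr__(self, "points", pts)

    @property
    def dilutions(self) -> np.ndarray:
        return np.array([d for d, _ in self.points])

    @property
    def cqs(self) -> np.ndarray:
        return np.array([c for _, c in self.points])


@dataclass
class QCLog:
    """Record of measurements removed (or samples dropped) during QC."""

    removals: list[dict] = field(default_factory=list)

    def record(self, sample: str, gene: str, replicate: int, cq: float, reason: str) -> None:
        self.removals.append(
            {"sample": sample, "gene": gene, "replicate": replicate, "cq": cq, "reason": reason}
        )

    def to_frame(self) -> pd.DataFrame:
        cols = ["sample", "gene", "replicate", "cq", "reason"]
        if not self.removals:
            return pd.DataFrame(columns=cols)
        return pd.DataFrame(self.removals, columns=cols)

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def __len__(self) -> int:
        return len(self.removals)


# ---------------------------------------------------------------------------
# readers / writers


def _sniff_sep(text: str) -> str:
    try:
        return csv.Sniffer().sniff(text.splitlines()[0], delimiters=",\t;").delimiter
    except csv.Error:
        return ","


def read_cq_table(path: str | Path, format_hint: str = "auto") -> CqTable:
    """Read a delimited Cq table, long or wide.

    ``format_hint`` is one of ``long``, ``wide`` or ``auto`` (detected from
    the header: a ``cq`` column means long format).  Non-numeric Cq cells are
    reported with their row numbers.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text(encoding="utf-8")
    sep = _sniff_sep(text)
    raw = pd.read_csv(io.StringIO(text), sep=sep, dtype=str, skip_blank_lines=True)
    # normalize known header names only; wide-format gene columns keep their case
    known = set(LONG_COLUMNS)
    raw.columns = [c.strip().lower() if c.strip().lower() in known else c.strip()
                   for c in raw.columns]

    if format_hint == "auto":
        format_hint = "long" if "cq" in raw.columns else "wide"
    if format_hint == "long":
        frame = _parse_long(raw)
    elif format_hint == "wide":
        frame = _parse_wide(raw)
    else:
        raise ValueError(f"format_hint must be long|wide|auto, got {format_hint!r}")
    return CqTable(frame, metadata={"source_file": str(path), "format": format_hint})


def _coerce_cq(values: pd.Series, context: str) -> pd.Series:
    # float() rather than pd.to_numeric: the latter is not bit-exact on
    # 17-digit decimals, which would break write/read round-tripping
    def _parse(x):
        try:
            return float(x)
        except (TypeError, ValueError):
            return None

    out = values.map(_parse)
    bad = out[values.notna() & out.isna()]
    if len(bad):
        rows = (bad.index + 2).tolist()[:10]  # header is line 1
        raise CqParseError(f"non-numeric cq values in {context}; file lines {rows}")
    return out.astype(float)


def _parse_long(raw: pd.DataFrame) -> pd.DataFrame:
    missing = {"sample", "gene", "cq"} - set(raw.columns)
    if missing:
        raise CqParseError(f"long format is missing mandatory columns: {sorted(missing)}")
    frame = pd.DataFrame({
        "sample": raw["sample"].astype(str).str.strip(),
        "gene": raw["gene"].astype(str).str.strip(),
        "replicate": pd.to_numeric(raw["replicate"], errors="raise").astype(int)
        if "replicate" in raw.columns else 1,
        "cq": _coerce_cq(raw["cq"], "column 'cq'"),
        "condition": raw["condition"].astype(str).str.strip() if "condition" in raw.columns else None,
        "tissue": raw["tissue"].astype(str).str.strip() if "tissue" in raw.columns else None,
    })
    return frame


def _parse_wide(raw: pd.DataFrame) -> pd.DataFrame:
    if "sample" not in raw.columns:
        raise CqParseError("wide format is missing mandatory column: ['sample']")
    id_cols = [c for c in WIDE_ID_COLUMNS if c in raw.columns]
    gene_cols = [c for c in raw.columns if c not in id_cols]
    if not gene_cols:
        raise CqParseError("wide format has no gene columns")
    long = raw.melt(id_vars=id_cols, value_vars=gene_cols, var_name="gene", value_name="cq")
    long["cq"] = _coerce_cq(long["cq"], "gene columns")
    if "replicate" not in long.columns:
        long["replicate"] = 1
    long["replicate"] = pd.to_numeric(long["replicate"], errors="raise").astype(int)
    return long


def write_cq_table(table: CqTable, path: str | Path, format: str = "long", sep: str = ",") -> None:
    """Serialize a CqTable; ``format='long'`` round-trips field-by-field."""
    frame = table.frame.sort_values(["sample", "gene", "replicate"])
    if format == "long":
        out = frame.rename(columns={"sample": "sample"})
        drop = [c for c in ("condition", "tissue") if out[c].isna().all()]
        out.drop(columns=drop).to_csv(path, index=False, sep=sep)
    elif format == "wide":
        id_cols = ["sample", "replicate"]
        for extra in ("condition", "tissue"):
            if frame[extra].notna().any():
                id_cols.append(extra)
        wide = frame.pivot_table(index=id_cols, columns="gene", values="cq").reset_index()
        wide.to_csv(path, index=False, sep=sep)
    else:
        raise ValueError("format must be 'long' or 'wide'")


def read_efficiencies(path: str | Path, scale: str = "auto") -> EfficiencyTable:
    """Read a two-column ``gene,efficiency`` file.

    ``scale='percent'`` divides by 100, ``'fraction'`` takes values as-is,
    ``'auto'`` treats values > 1.5 as percent (no plausible fractional
    efficiency exceeds 1.1, no plausible percent efficiency is below 50).
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    raw = pd.read_csv(io.StringIO(text), sep=_sniff_sep(text))
    raw.columns = [c.strip().lower() for c in raw.columns]
    if not {"gene", "efficiency"} <= set(raw.columns):
        raise CqParseError("efficiency file needs columns gene,efficiency")
    values = pd.to_numeric(raw["efficiency"], errors="raise").astype(float)
    if scale == "percent":
        values = values / 100.0
    elif scale == "auto":
        values = values.where(values <= 1.5, values / 100.0)
    elif scale != "fraction":
        raise ValueError("scale must be fraction|percent|auto")
    series = pd.Series(values.values, index=raw["gene"].astype(str).str.strip())
    return EfficiencyTable(series, source="provided")


def write_efficiencies(eff: EfficiencyTable, path: str | Path) -> None:
    eff.efficiencies.rename("efficiency").rename_axis("gene").to_csv(path)


# ---------------------------------------------------------------------------
# quality filtering


def qc_filter(
    table: CqTable,
    max_cq: float = 30.0,
    max_replicate_spread: float = 0.5,
) -> tuple[CqTable, QCLog]:
    """Remove late-crossing wells and outlying technical replicates.

    Wells with Cq above ``max_cq`` (default 30 cycles, the assay's trusted
    range) are dropped.  Within each (sample, gene) replicate group whose
    range exceeds ``max_replicate_spread`` cycles, the replicate farthest from
    the group median is removed, iteratively, until the range is within
    tolerance or a single replicate remains.  Every removal is logged.

    Raises if any (sample, gene) group loses all its replicates — a group can
    only be emptied by the Cq ceiling, never by the spread rule.
    """
    if max_cq <= 0 or max_replicate_spread <= 0:
        raise ValueError("max_cq and max_replicate_spread must be > 0")
    log = QCLog()
    frame = table.frame.copy()

    too_late = frame["cq"] > max_cq
    for r in frame[too_late].itertuples(index=False):
        log.record(r.sample, r.gene, int(r.replicate), float(r.cq), f"cq > {max_cq:g}")
    frame = frame[~too_late]

    emptied = set(map(tuple, table.frame[["sample", "gene"]].values)) - set(
        map(tuple, frame[["sample", "gene"]].values)
    )
    if emptied:
        s, g = sorted(emptied)[0]
        raise CqValidationError(
            f"QC removed every replicate of ({s}, {g}); {len(emptied)} group(s) emptied"
        )

    keep_idx: list[int] = []
    for (sample, gene), grp in frame.groupby(["sample", "gene"], sort=False):
        grp = grp.sort_values("replicate")
        while len(grp) > 1 and grp["cq"].max() - grp["cq"].min() > max_replicate_spread:
            dist = (grp["cq"] - grp["cq"].median()).abs()
            # farthest from median; on a tie, drop the higher Cq (weaker signal)
            worst = grp.loc[dist == dist.max()].sort_values("cq").index[-1]
            row = grp.loc[worst]
            log.record(sample, gene, int(row["replicate"]), float(row["cq"]),
                       f"replicate spread > {max_replicate_spread:g}")
            grp = grp.drop(index=worst)
        keep_idx.extend(grp.index)

    filtered = CqTable(frame.loc[sorted(keep_idx)], metadata=dict(table.metadata))
    return filtered, log


def drop_incomplete_samples(
    table: CqTable, on_incomplete: str = "warn"
) -> tuple[CqTable, list[str]]:
    """Enforce the complete-case requirement of pairwise statistics.

    Samples missing any gene (after QC) are dropped and returned; geNorm-style
    ratios need a full gene x sample grid.  ``on_incomplete='error'`` raises
    instead of dropping.
    """
    if on_incomplete not in ("warn", "error"):
        raise ValueError("on_incomplete must be 'warn' or 'error'")
    genes = set(table.genes)
    per_sample = table.frame.groupby("sample")["gene"].agg(set)
    incomplete = sorted(per_sample.index[per_sample.apply(lambda g: g != genes)])
    if not incomplete:
        return table, []
    if on_incomplete == "error":
        raise CqValidationError(f"samples missing genes: {incomplete}")
    kept = table.frame[~table.frame["sample"].isin(incomplete)]
    return CqTable(kept, metadata=dict(table.metadata)), incomplete
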