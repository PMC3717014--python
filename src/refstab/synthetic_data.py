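"""Seeded Cq-data simulator with controlled stability structure.

The generator emulates a longitudinal nerve-injury RT-qPCR validation study:
seven candidate reference genes measured in seven condition groups (naive
plus days 2, 4, 7, 10, 14 and 21 after surgery) of three subjects each, in
triplicate wells, with gene-specific amplification efficiencies in the
0.63-0.89 range typical of validated primer pairs.

Noise is additive on the Cq (log-expression) scale, the standard qPCR error
model:

    Cq(subject, gene, well) = baseline_g + S_j + effect_g(condition)
                              + Normal(0, biological_sd_g) + Normal(0, technical_sd)

where S_j ~ Normal(0, sample_content_sd) is a subject-wide template-content
shift common to all genes (it cancels from M-values but inflates CVs), and
effect_g(condition) is a deterministic per-condition expression shift — the
instability being hunted.  A gene is truly "stable" iff all its condition
effects are zero.  Baselines default to the 15-25 cycle range so stable
genes stay below the 30-cycle QC ceiling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from refstab.cq_io import CqTable, DilutionSeries, EfficiencyTable

__all__ = [
    "GeneSpec",
    "SimulationConfig",
    "default_study_config",
    "simulate",
    "simulate_dilution_series",
    "write_truth",
]

#: condition labels of the emulated study: naive + post-surgery days
STUDY_CONDITIONS = ("naive", "d2", "d4", "d7", "d10", "d14", "d21")

#: (label, baseline_cq, efficiency) of the seven candidates; efficiencies are
#: the dorsal-horn values of the emulated assay panel, baselines reflect
#: typical transcript abundance (rRNA lowest Cq, low-abundance enzymes highest)
STUDY_GENES = (
    ("18S", 15.0, 0.78),
    ("Actb", 20.0, 0.85),
    ("GAPDH", 19.0, 0.89),
    ("HMBS", 25.0, 0.78),
    ("HPRT1", 24.0, 0.70),
    ("RPL13a", 21.0, 0.88),
    ("RPL29", 21.5, 0.81),
)


@dataclass(frozen=True)
class GeneSpec:
    """Ground-truth generative parameters of one candidate gene."""

    label: str
    baseline_cq: float
    efficiency: float
    biological_noise_sd: float = 0.2
    condition_effects: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.efficiency <= 1.1:
            raise ValueError(f"efficiency must be in (0, 1.1], got {self.efficiency}")
        if self.biological_noise_sd < 0:
            raise ValueError("biological_noise_sd must be >= 0")

    @property
    def is_stable(self) -> bool:
        return all(v == 0 for v in self.condition_effects.values())

    @property
    def max_effect(self) -> float:
        return max((abs(v) for v in self.condition_effects.values()), default=0.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Full study design: genes, condition groups, replication and noise."""

    genes: tuple[GeneSpec, ...]
    conditions: tuple[tuple[str, int], ...]
    technical_replicates: int = 3
    technical_noise_sd: float = 0.1
    sample_content_sd: float = 0.15
    seed: int = 0
    tissue: str | None = None

    def __post_init__(self) -> None:
        if self.technical_replicates < 1:
            raise ValueError("technical_replicates must be >= 1")
        if self.technical_noise_sd < 0 or self.sample_content_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if any(n < 1 for _, n in self.conditions):
            raise ValueError("every condition needs n_subjects >= 1")
        labels = [g.label for g in self.genes]
        if len(set(labels)) != len(labels):
            raise ValueError("gene labels must be unique")


def default_study_config(
    seed: int = 0,
    unstable_gene: str | None = None,
    max_effect: float = 1.5,
    n_subjects: int = 3,
    biological_noise_sd: float = 0.2,
    technical_noise_sd: float = 0.1,
    sample_content_sd: float = 0.15,
    tissue: str = "DH",
) -> SimulationConfig:
    """The study-shaped design: 7 genes x 7 conditions x ``n_subjects``.

    If ``unstable_gene`` is given, that gene receives condition effects
    ramping linearly from 0 (naive) to ``max_effect`` cycles at the last
    post-surgery day; all other genes are truly stable.
    """
    post = STUDY_CONDITIONS[1:]
    genes = []
    for label, baseline, eff in STUDY_GENES:
        effects: dict[str, float] = {}
        if label == unstable_gene:
            effects = {c: max_effect * (i + 1) / len(post) for i, c in enumerate(post)}
        genes.append(GeneSpec(label, baseline, eff, biological_noise_sd, effects))
    if unstable_gene is not None and unstable_gene not in {g.label for g in genes}:
        raise ValueError(f"unknown gene {unstable_gene!r}")
    return SimulationConfig(
        genes=tuple(genes),
        conditions=tuple((c, n_subjects) for c in STUDY_CONDITIONS),
        technical_noise_sd=technical_noise_sd,
        sample_content_sd=sample_content_sd,
        seed=seed,
        tissue=tissue,
    )


def simulate(config: SimulationConfig) -> tuple[CqTable, EfficiencyTable, pd.DataFrame]:
    """Draw a full Cq dataset plus its efficiency table and truth labels.

    Identical configs (including seed) produce identical output.  The truth
    frame has columns ``gene, is_stable, max_effect_cycles``.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    for cond, n_subj in config.conditions:
        for j in range(1, n_subj + 1):
            sample = f"{cond}_r{j}"
            content_shift = rng.normal(0.0, config.sample_content_sd)
            for gene in config.genes:
                true_cq = (
                    gene.baseline_cq
                    + content_shift
                    + gene.condition_effects.get(cond, 0.0)
                    + rng.normal(0.0, gene.biological_noise_sd)
                )
                for rep in range(1, config.technical_replicates + 1):
                    cq = true_cq + rng.normal(0.0, config.technical_noise_sd)
                    rows.append((sample, gene.label, rep, cq, cond, config.tissue))

    frame = pd.DataFrame(
        rows, columns=["sample", "gene", "replicate", "cq", "condition", "tissue"]
    )
    if (frame["cq"] > 30).any():
        warnings.warn(
            "simulated Cq values exceed 30 cycles; the QC ceiling will remove them",
            stacklevel=2,
        )
    table = CqTable(frame, metadata={"simulated": True, "seed": config.seed})
    eff = EfficiencyTable(
        pd.Series({g.label: g.efficiency for g in config.genes}), source="provided"
    )
    truth = pd.DataFrame(
        {
            "gene": [g.label for g in config.genes],
            "is_stable": [g.is_stable for g in config.genes],
            "max_effect_cycles": [g.max_effect for g in config.genes],
        }
    )
    return table, eff, truth


def simulate_dilution_series(
    efficiency: float,
    anchor_cq: float = 15.0,
    dilutions: Sequence[float] = (1.0, 10.0, 100.0, 1000.0),
    noise_sd: float = 0.0,
    seed: int = 0,
    gene: str = "simulated",
) -> DilutionSeries:
    """Simulate a serial-dilution calibration curve.

    Cq at dilution factor d is ``anchor_cq + log(d)/log(1+efficiency)`` (each
    d-fold dilution delays threshold crossing by log_{1+E}(d) cycles) plus
    optional Gaussian noise.
    """
    if not 0 < efficiency <= 1.1:
        raise ValueError(f"efficiency must be in (0, 1.1], got {efficiency}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    points = []
    for d in dilutions:
        cq = anchor_cq + np.log(d) / np.log1p(efficiency) + rng.normal(0.0, noise_sd)
        points.append((float(d), float(cq)))
    return DilutionSeries(gene=gene, points=tuple(points))


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, index=False)
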