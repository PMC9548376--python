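"""Core domain types shared across the pipeline.

The FUCCI reporter pair (red mKO2-Cdt1_30-120, green mAG-Geminin_1-110)
marks G1 nuclei in red and S/G2/M nuclei in green, with a possible window
of co-expression around the G1/S transition and a dark window of several
frames right after mitosis, when neither reporter has accumulated.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "CellCycleModel",
    "ImagingConfig",
    "ReporterParams",
    "TruthCell",
    "TruthLineage",
    "FucciMovie",
    "logsd_from_median_sd",
    "NPC_WT",
    "NPC_MUT",
    "HESC_WT",
    "HESC_MUT",
]


def logsd_from_median_sd(median: float, sd: float) -> float:
    """Log-scale sd of a lognormal with the given median and standard deviation.

    For X ~ Lognormal(mu, sigma), median = e^mu and
    sd/median = e^(sigma^2/2) * sqrt(e^(sigma^2) - 1).  Solving the quadratic
    in u = e^(sigma^2) gives u = (1 + sqrt(1 + 4 r^2)) / 2 with r = sd/median.
    """
    if median <= 0 or sd < 0:
        raise ValueError("median must be > 0 and sd >= 0")
    if sd == 0:
        return 0.0
    r = sd / median
    u = (1.0 + math.sqrt(1.0 + 4.0 * r * r)) / 2.0
    return math.sqrt(math.log(u))


@dataclass(frozen=True)
class CellCycleModel:
    """Per-genotype cell-cycle duration model.

    G1 and S/G2/M durations are independent lognormals parameterized by their
    median (minutes) and log-scale sd.  ``overlap_min`` is the duration of
    red+green co-expression at the G1/S transition (red persists that long
    after green onset); ``dark_gap_frames`` is the number of post-mitosis
    frames during which both reporters are below detection.
    """

    g1_median_min: float
    g1_logsd: float
    sg2m_median_min: float
    sg2m_logsd: float
    overlap_min: float = 0.0
    dark_gap_frames: int = 3
    genotype_label: str = ""

    def __post_init__(self) -> None:
        if self.g1_median_min <= 0 or self.sg2m_median_min <= 0:
            raise ValueError("phase duration medians must be positive")
        if self.g1_logsd < 0 or self.sg2m_logsd < 0:
            raise ValueError("log-scale sds must be nonnegative")
        if self.dark_gap_frames < 0:
            raise ValueError("dark_gap_frames must be nonnegative")
        if self.overlap_min < 0 or self.overlap_min >= self.g1_median_min:
            raise ValueError("overlap_min must be in [0, g1_median_min)")


# Cohort presets calibrated to the printed median +/- sd phase durations
# (G1: NPC 1408+/-982 wt vs 517+/-410 mutant; hESC 198+/-78 vs 153+/-61).
# S/G2/M medians are not printed; 720 min (NPC) and 600 min (hESC) are
# typical values, identical across genotypes (no reported genotype effect).
NPC_WT = CellCycleModel(1408.0, logsd_from_median_sd(1408.0, 982.0),
                        720.0, 0.25, overlap_min=60.0, genotype_label="CHD8+/+")
NPC_MUT = CellCycleModel(517.0, logsd_from_median_sd(517.0, 410.0),
                         720.0, 0.25, overlap_min=60.0, genotype_label="CHD8+/-")
HESC_WT = CellCycleModel(198.0, logsd_from_median_sd(198.0, 78.0),
                         600.0, 0.25, overlap_min=0.0, genotype_label="CHD8+/+")
HESC_MUT = CellCycleModel(153.0, logsd_from_median_sd(153.0, 61.0),
                          600.0, 0.25, overlap_min=0.0, genotype_label="CHD8+/-")


@dataclass(frozen=True)
class ImagingConfig:
    """Acquisition geometry, timing and noise for the synthetic microscope."""

    n_frames: int
    frame_interval_min: float = 15.0
    height: int = 256
    width: int = 256
    nucleus_radius_px: float = 6.0
    psf_sigma_px: float = 1.5
    background_level: float = 20.0
    photon_gain: float = 1.0
    read_noise_sd: float = 2.0
    bit_depth: int = 16
    poisson_noise: bool = True
    motion_step_px: float = 1.0
    motion_persistence: float = 0.8
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_interval_min <= 0:
            raise ValueError("frame_interval_min must be > 0")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")

    @property
    def total_min(self) -> float:
        return self.n_frames * self.frame_interval_min

    @property
    def max_value(self) -> int:
        return 2 ** self.bit_depth - 1


@dataclass(frozen=True)
class ReporterParams:
    """Reporter accumulation kinetics (linear ramps, saturating).

    Red rises over ``red_rise_min`` from birth, holds through G1, and decays
    to zero over the model's overlap window after green onset.  Green rises
    over ``green_rise_min`` from the G1/S transition, holds, and collapses at
    cytokinesis.  ``min_decay_min`` bounds the red decay below so that a zero
    overlap still yields a finite (sub-frame) decay.
    """

    red_max: float = 400.0
    green_max: float = 400.0
    red_rise_min: float = 120.0
    green_rise_min: float = 60.0
    min_decay_min: float = 10.0
    ellipse_aspect: float = 0.8
    bend: float = 0.0  # curvature of the nucleus ("boomerang") in 1/px


@dataclass
class TruthCell:
    """Ground-truth record for one simulated cell."""

    cell_id: int
    parent_id: Optional[int]
    birth_time_min: float
    g1_end_time_min: float
    division_time_min: Optional[float]  # None if censored by movie end
    censored_start: bool
    censored_end: bool
    children: list = field(default_factory=list)


@dataclass
class TruthLineage:
    """Simulated lineage forest with exact phase-transition times.

    ``frames`` is filled in by the renderer: one row per (cell, frame) with
    the nucleus centroid, visibility and pre-noise reporter amplitudes.
    """

    cells: dict  # cell_id -> TruthCell
    model: CellCycleModel
    t_total_min: float
    seed: int
    frames: Optional[pd.DataFrame] = None

    @property
    def founders(self) -> list:
        return [c for c in self.cells.values() if c.parent_id is None]

    @property
    def leaves(self) -> list:
        return [c for c in self.cells.values() if not c.children]

    def validate(self) -> list:
        """Check structural invariants; return list of violation strings."""
        problems = []
        for c in self.cells.values():
            if c.parent_id is not None:
                parent = self.cells.get(c.parent_id)
                if parent is None:
                    problems.append(f"cell {c.cell_id}: unknown parent {c.parent_id}")
                    continue
                if parent.division_time_min is None:
                    problems.append(f"cell {c.cell_id}: parent {c.parent_id} never divides")
                elif c.birth_time_min != parent.division_time_min:
                    problems.append(f"cell {c.cell_id}: birth != parent division")
            if c.division_time_min is not None:
                if not (c.birth_time_min < c.g1_end_time_min < c.division_time_min):
                    problems.append(f"cell {c.cell_id}: phase times out of order")
            n_kids = len(c.children)
            if n_kids not in (0, 2):
                problems.append(f"cell {c.cell_id}: {n_kids} daughters")
        return problems


@dataclass
class FucciMovie:
    """Two-channel time-lapse stack (uint arrays of shape (T, H, W))."""

    red: np.ndarray    # mKO2-Cdt1_30-120, G1 reporter
    green: np.ndarray  # mAG-Geminin_1-110, S/G2/M reporter
    frame_interval_min: float

    def __post_init__(self) -> None:
        if self.red.shape != self.green.shape:
            raise ValueError("red and green stacks must have the same shape")
        if self.red.ndim != 3:
            raise ValueError("channel stacks must be (T, H, W)")

    @property
    def n_frames(self) -> int:
        return self.red.shape[0]

    @property
    def shape(self) -> tuple:
        return self.red.shape
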