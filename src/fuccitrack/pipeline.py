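"""End-to-end orchestration: movie -> binary stack -> lineage -> durations.

``measure_cohort`` runs the whole chain on simulated movies with oracle
click scripts and pools the resulting duration tables — the in-silico
analog of one genotype's imaging arm.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .models import CellCycleModel, FucciMovie, ImagingConfig, ReporterParams
from .phase_timing import (detect_onsets, estimate_background, extract_trace,
                           phase_durations, segment_phases)
from .segmentation import SegmentationParams, binarize_movie
from .synthetic.lineage import sample_lineages
from .synthetic.movie import RenderResult, oracle_clicks, render_movie
from .tracking import GapPolicy, run_click_script

__all__ = ["AnalysisResult", "analyze_movie", "simulate_cohort_movie",
           "measure_cohort"]


@dataclass
class AnalysisResult:
    tree: object
    traces: dict
    onsets: dict
    segments: dict
    durations: pd.DataFrame  # complete phases (statistical table)
    audit: pd.DataFrame      # censored spans


def analyze_movie(movie: FucciMovie, clicks: pd.DataFrame,
                  seg_params: SegmentationParams | None = None,
                  gap_policy: GapPolicy | None = None,
                  k_onset: float = 5.0, min_run: int = 2,
                  genotype: str = "", on_error: str = "warn") -> AnalysisResult:
    """Run segmentation, click-script tracking and phase timing on a movie."""
    stack = binarize_movie(movie, seg_params)
    tree = run_click_script(stack, clicks, gap_policy, on_error=on_error)
    bg = estimate_background(movie)
    bg_mean = (bg["red"][0], bg["green"][0])
    bg_sd = (bg["red"][1], bg["green"][1])
    traces, onsets = {}, {}
    for cid in tree.cells:
        tr = extract_trace(movie, tree, cid)
        traces[cid] = tr
        onsets[cid] = detect_onsets(tr, bg_mean, bg_sd, k_onset, min_run)
    segments = segment_phases(tree, traces, onsets)
    durations, audit = phase_durations(segments, movie.frame_interval_min,
                                       genotype=genotype)
    return AnalysisResult(tree, traces, onsets, segments, durations, audit)


def simulate_cohort_movie(model: CellCycleModel, imaging: ImagingConfig,
                          n_founders: int, seed: int,
                          reporter: ReporterParams | None = None
                          ) -> tuple[RenderResult, pd.DataFrame]:
    """One simulated movie plus its oracle click script."""
    truth = sample_lineages(model, n_founders, imaging.total_min, seed)
    result = render_movie(truth, replace(imaging, rng_seed=seed + 1), reporter)
    return result, oracle_clicks(result)


def measure_cohort(model: CellCycleModel, imaging: ImagingConfig,
                   n_movies: int, n_founders: int, seed: int,
                   genotype: str = "",
                   reporter: ReporterParams | None = None,
                   seg_params: SegmentationParams | None = None,
                   gap_policy: GapPolicy | None = None) -> tuple:
    """Pool phase durations over replicate simulated movies.

    Returns ``(durations, audit)``: complete phase durations and censored
    spans, both in the duration-table schema.
    """
    ss = np.random.SeedSequence(seed)
    movie_seeds = [int(s.generate_state(1)[0] % (2 ** 31 - 1))
                   for s in ss.spawn(n_movies)]
    stats_parts, audit_parts = [], []
    for i, mseed in enumerate(movie_seeds):
        result, clicks = simulate_cohort_movie(model, imaging, n_founders,
                                               mseed, reporter)
        res = analyze_movie(result.movie, clicks, seg_params, gap_policy,
                            genotype=genotype or model.genotype_label)
        for df, parts in ((res.durations, stats_parts), (res.audit, audit_parts)):
            df = df.copy()
            df["movie"] = i
            parts.append(df)
    durations = pd.concat(stats_parts, ignore_index=True)
    audit = pd.concat(audit_parts, ignore_index=True)
    return durations, audit
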