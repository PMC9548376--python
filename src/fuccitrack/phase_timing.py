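"""From tracked regions to G1 and S/G2/M durations.

Mean red/green intensity is recorded over each cell's tracked region per
frame.  Green onset (first sustained threshold crossing of the smoothed
trace) marks the G1/S transition; the green collapse at the mother's last
tracked frame marks cytokinesis.  Phases without an observed bounding event
are censored: excluded from the statistical table but kept in an audit
table with the observed span as a duration lower bound.

Conventions: a daughter's G1 starts the frame after its mother's division
(the post-mitosis dark gap counts toward G1).  A founder whose track starts
at frame 0 was already mid-phase when acquisition began and is start-
censored; a founder that emerges from darkness later has an observed birth.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .models import FucciMovie
from .tracking import LineageTree

__all__ = [
    "IntensityTrace",
    "OnsetEvents",
    "PhaseSegments",
    "estimate_background",
    "extract_trace",
    "detect_onsets",
    "segment_phases",
    "phase_durations",
]

log = logging.getLogger(__name__)

DURATION_COLUMNS = ["cell_id", "genotype", "phase", "duration_min", "censored",
                    "censor_type"]


@dataclass
class IntensityTrace:
    """Per-frame mean channel intensities over one cell's tracked regions."""

    cell_id: str
    frames: np.ndarray  # int, sorted; includes recorded dark frames
    red: np.ndarray     # NaN on dark frames
    green: np.ndarray
    area: np.ndarray
    dark: np.ndarray    # bool


@dataclass(frozen=True)
class OnsetEvents:
    red_onset: Optional[int]
    red_offset: Optional[int]
    green_onset: Optional[int]
    green_offset: Optional[int]


@dataclass
class PhaseSegments:
    """Frame-interval phase segmentation for one cell.

    Intervals are half-open ``[start, end)`` in frame indices.  ``None``
    bounds mean the event was not observed (censored on that side).
    """

    cell_id: str
    g1_start: Optional[int]
    g1_end: Optional[int]
    sg2m_start: Optional[int]
    sg2m_end: Optional[int]
    g1_censored_start: bool = False
    g1_censored_end: bool = False
    sg2m_censored_start: bool = False
    sg2m_censored_end: bool = False
    last_observed_frame: Optional[int] = None
    unresolvable: bool = False


def estimate_background(movie: FucciMovie, subsample: int = 4) -> dict:
    """Robust per-channel background mean and sd (median / scaled MAD).

    Nuclei are sparse, so the median over all pixels sits on the background.
    The sd floor of one grey level keeps thresholds meaningful for
    noiseless, quantized renders.
    """
    out = {}
    for name, stack in (("red", movie.red), ("green", movie.green)):
        sample = stack[::subsample].ravel().astype(np.float64)
        med = float(np.median(sample))
        mad = float(np.median(np.abs(sample - med)))
        out[name] = (med, max(1.4826 * mad, 1.0))
    return out


def extract_trace(movie: FucciMovie, tree: LineageTree, cell_id: str) -> IntensityTrace:
    """Mean red/green intensity per tracked frame for ``cell_id``."""
    if cell_id not in tree.cells:
        raise KeyError(f"unknown cell_id {cell_id!r}")
    if tree.stack is None:
        raise ValueError("lineage tree carries no binary stack; regions "
                         "are unavailable for intensity extraction")
    track = tree.cells[cell_id]
    recs = []
    for p in track.points:
        ys, xs = tree.stack.region_pixels(p.frame, p.label)
        recs.append((p.frame,
                     float(movie.red[p.frame][ys, xs].mean()),
                     float(movie.green[p.frame][ys, xs].mean()),
                     len(ys), False))
    for f in track.dark_frames:
        recs.append((f, np.nan, np.nan, 0, True))
    recs.sort()
    if not recs:
        return IntensityTrace(cell_id, np.array([], int), np.array([]),
                              np.array([]), np.array([], int), np.array([], bool))
    frames, red, green, area, dark = map(np.array, zip(*recs))
    return IntensityTrace(cell_id, frames.astype(int), red.astype(float),
                          green.astype(float), area.astype(int),
                          dark.astype(bool))


def _smooth(x: np.ndarray) -> np.ndarray:
    # 3-frame centered rolling median, NaN-tolerant
    return (pd.Series(x).rolling(3, center=True, min_periods=1)
            .median().to_numpy())


def _first_run(above: np.ndarray, min_run: int, start: int = 0) -> Optional[int]:
    n = len(above)
    run = 0
    for i in range(start, n):
        run = run + 1 if above[i] else 0
        if run >= min_run:
            return i - min_run + 1
    return None


def detect_onsets(trace: IntensityTrace, bg_mean, bg_sd,
                  k_onset: float = 5.0, min_run: int = 2) -> OnsetEvents:
    """Sustained threshold crossings of the smoothed red/green traces.

    ``bg_mean``/``bg_sd`` may be scalars (shared) or ``(red, green)`` pairs.
    An onset is the first frame where the 3-frame median-smoothed trace
    exceeds ``bg_mean + k_onset * bg_sd`` for at least ``min_run``
    consecutive frames; offsets fall symmetrically below.  Frames are
    reported in absolute movie indices.
    """
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    if len(trace.frames) < min_run:
        log.warning("cell %s: trace shorter than min_run; no events",
                    trace.cell_id)
        return OnsetEvents(None, None, None, None)
    means = np.broadcast_to(np.asarray(bg_mean, dtype=float), (2,))
    sds = np.broadcast_to(np.asarray(bg_sd, dtype=float), (2,))
    events = {}
    for i, (name, y) in enumerate((("red", trace.red), ("green", trace.green))):
        thresh = means[i] + k_onset * sds[i]
        sm = _smooth(y)
        above = np.where(np.isnan(sm), False, sm > thresh)
        onset_i = _first_run(above, min_run)
        onset = int(trace.frames[onset_i]) if onset_i is not None else None
        offset = None
        if onset_i is not None:
            off_i = _first_run(~above, min_run, start=onset_i + 1)
            if off_i is not None:
                offset = int(trace.frames[off_i])
        events[name] = (onset, offset)
    return OnsetEvents(events["red"][0], events["red"][1],
                       events["green"][0], events["green"][1])


def segment_phases(tree: LineageTree, traces: dict, onsets: dict,
                   max_birth_gap_frames: int = 8) -> dict:
    """Assign G1 and S/G2/M frame intervals per cell.

    ``traces`` and ``onsets`` map cell_id to :class:`IntensityTrace` and
    :class:`OnsetEvents` and must cover every cell of the tree.  Red/green
    co-expression is assigned to G1 up to the green onset (the G1/S
    transition marker); the dark gap after mitosis belongs to the daughter's
    G1.  A daughter's birth frame is her mother's last tracked frame + 1,
    but only when the mother was followed to within
    ``max_birth_gap_frames`` of the daughter's appearance — a mother lost
    long before that leaves the division time, hence the birth, unobserved
    (G1 start-censored).
    """
    missing = [c for c in tree.cells if c not in traces or c not in onsets]
    if missing:
        raise ValueError(f"traces/onsets missing for cells: {missing}")
    segments: dict[str, PhaseSegments] = {}
    for cid, track in tree.cells.items():
        ev = onsets[cid]
        first, last = track.first_frame, track.last_frame
        seg = PhaseSegments(cid, None, None, None, None,
                            last_observed_frame=last)
        green_on = ev.green_onset
        if track.parent_id is not None and track.parent_id not in tree.cells:
            # mother's track was lost: the birth frame is unknown
            seg.g1_start = first
            seg.g1_censored_start = True
        elif track.parent_id is not None:
            mother_last = tree.cells[track.parent_id].last_frame
            if first - mother_last - 1 > max_birth_gap_frames:
                seg.g1_start = first
                seg.g1_censored_start = True
            else:
                seg.g1_start = mother_last + 1
        else:
            # founder: birth observed only if it emerged from darkness
            seg.g1_start = first
            if track.censored_start:
                seg.g1_censored_start = True
            if green_on is not None and green_on <= first:
                # already in S/G2/M when first seen: no G1 to measure
                seg.g1_start = None
                seg.g1_censored_start = True
                seg.sg2m_censored_start = True
        if seg.g1_start is not None and green_on is not None \
                and green_on < seg.g1_start:
            log.info("cell %s: green onset precedes birth; unresolvable", cid)
            seg.unresolvable = True
            segments[cid] = seg
            continue
        if seg.g1_start is not None:
            if green_on is not None:
                seg.g1_end = green_on
            else:
                # still red at the last observed frame: right-censored there
                seg.g1_end = last
                seg.g1_censored_end = True
        if green_on is not None:
            seg.sg2m_start = max(green_on, first)
            if track.censored_end or len(track.children) != 2:
                seg.sg2m_end = last
                seg.sg2m_censored_end = True
            else:
                seg.sg2m_end = last + 1  # green collapse at division
        segments[cid] = seg
    return segments


def phase_durations(segments: dict, frame_interval_min: float,
                    genotype: str = "") -> tuple:
    """Convert phase segments to duration tables.

    Returns ``(stats, audit)`` DataFrames with columns
    ``cell_id, genotype, phase, duration_min, censored, censor_type``:
    ``stats`` holds complete (uncensored) durations, ``audit`` holds
    censored spans and is excluded from statistics.  ``censor_type`` is
    ``start``, ``end`` or ``both``; an end-censored span is a right-
    censored lower bound of the true duration (usable by survival
    estimators), a start-censored one has an unobserved birth.
    """
    if frame_interval_min <= 0:
        raise ValueError("frame_interval_min must be > 0")
    stats_rows, audit_rows = [], []

    def ctype(start_c: bool, end_c: bool) -> str:
        if start_c and end_c:
            return "both"
        return "start" if start_c else ("end" if end_c else "")

    for cid, seg in segments.items():
        if seg.unresolvable:
            continue
        if seg.g1_start is not None and seg.g1_end is not None:
            dur = (seg.g1_end - seg.g1_start) * frame_interval_min
            censored = seg.g1_censored_start or seg.g1_censored_end
            row = (cid, genotype, "G1", dur, censored,
                   ctype(seg.g1_censored_start, seg.g1_censored_end))
            if dur > 0:
                (audit_rows if censored else stats_rows).append(row)
        if seg.sg2m_start is not None and seg.sg2m_end is not None:
            dur = (seg.sg2m_end - seg.sg2m_start) * frame_interval_min
            censored = seg.sg2m_censored_start or seg.sg2m_censored_end
            row = (cid, genotype, "SG2M", dur, censored,
                   ctype(seg.sg2m_censored_start, seg.sg2m_censored_end))
            if dur > 0:
                (audit_rows if censored else stats_rows).append(row)
    stats = pd.DataFrame(stats_rows, columns=DURATION_COLUMNS)
    audit = pd.DataFrame(audit_rows, columns=DURATION_COLUMNS)
    return stats, audit
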