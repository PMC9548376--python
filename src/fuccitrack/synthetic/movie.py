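"""Render ground-truth lineages into two-channel FUCCI movies.

The renderer stamps each nucleus as an (optionally bent) ellipse whose
per-channel amplitude follows piecewise-linear reporter kinetics, convolves
each frame with a Gaussian point-spread function, then applies Poisson photon
noise followed by Gaussian read noise.  Alongside the pixel data it exports a
per-(cell, frame) truth table and the frame indices of every phase
transition, which downstream tests use as the oracle.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from ..models import (CellCycleModel, FucciMovie, ImagingConfig,
                      ReporterParams, TruthLineage)

__all__ = ["render_movie", "RenderResult", "oracle_clicks"]


@dataclass
class RenderResult:
    movie: FucciMovie
    truth: TruthLineage          # with .frames filled in
    transitions: pd.DataFrame    # per cell: birth/G1S/division frame indices


def _reporter_amplitudes(t: float, cell, model: CellCycleModel,
                         rep: ReporterParams, frame_interval: float) -> tuple:
    """Pre-noise peak amplitude of each reporter at absolute time ``t``."""
    birth = cell.birth_time_min
    g1_end = cell.g1_end_time_min
    division = cell.division_time_min
    if t < birth or (division is not None and t >= division):
        return 0.0, 0.0, False
    # post-mitosis dark window (daughters only: founders ramp from zero)
    if cell.parent_id is not None and t < birth + model.dark_gap_frames * frame_interval:
        return 0.0, 0.0, True
    decay = max(model.overlap_min, rep.min_decay_min)
    if t <= g1_end:
        red = rep.red_max * min(1.0, (t - birth) / rep.red_rise_min)
    else:
        at_end = rep.red_max * min(1.0, (g1_end - birth) / rep.red_rise_min)
        red = at_end * max(0.0, 1.0 - (t - g1_end) / decay)
    green = 0.0
    if t >= g1_end:
        green = rep.green_max * min(1.0, (t - g1_end) / rep.green_rise_min)
    return red, green, False


def _stamp_ellipse(canvas: np.ndarray, x: float, y: float, a: float, b: float,
                   theta: float, bend: float, amplitude: float) -> None:
    """Add ``amplitude`` over a (possibly bent) ellipse footprint in place."""
    if amplitude <= 0:
        return
    h, w = canvas.shape
    half = int(np.ceil(a + abs(bend) * a * a + 2))
    x0, x1 = int(np.floor(x)) - half, int(np.floor(x)) + half + 1
    y0, y1 = int(np.floor(y)) - half, int(np.floor(y)) + half + 1
    x0c, x1c = max(x0, 0), min(x1, w)
    y0c, y1c = max(y0, 0), min(y1, h)
    if x0c >= x1c or y0c >= y1c:
        return
    yy, xx = np.mgrid[y0c:y1c, x0c:x1c]
    dx = xx - x
    dy = yy - y
    c, s = np.cos(theta), np.sin(theta)
    u = dx * c + dy * s
    v = -dx * s + dy * c
    v = v - bend * u * u  # curve the minor axis: "boomerang" nucleus
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    canvas[y0c:y1c, x0c:x1c][inside] += amplitude


def _simulate_positions(truth: TruthLineage, imaging: ImagingConfig,
                        rng: np.random.Generator) -> dict:
    """Persistent-random-walk centroid per cell per alive frame.

    All alive cells advance together frame by frame; overlapping nuclei are
    pushed apart (nuclei exclude each other, as in a monolayer), daughters
    start on opposite sides of the mother's final position, and walks
    reflect at a two-radius margin from the field border so no cell exits.
    Returns cell_id -> dict(frame -> (x, y)).
    """
    dt = imaging.frame_interval_min
    r = imaging.nucleus_radius_px
    margin = 2 * r  # keep nuclei clear of border-reflection artifacts
    lo = np.array([margin, margin])
    hi = np.array([imaging.width - 1 - margin, imaging.height - 1 - margin])
    d_min = 2.3 * r

    def reflect(p: np.ndarray) -> np.ndarray:
        span = hi - lo
        q = (p - lo) % (2 * span)
        return lo + (span - np.abs(q - span))

    cells = truth.cells
    f_start, f_end = {}, {}
    for cid, cell in cells.items():
        f_start[cid] = int(np.ceil(cell.birth_time_min / dt - 1e-9))
        end_t = cell.division_time_min
        f_end[cid] = (int(np.floor((end_t - 1e-9) / dt)) if end_t is not None
                      else imaging.n_frames - 1)
        f_end[cid] = min(f_end[cid], imaging.n_frames - 1)

    founders = sorted(cid for cid in cells if cells[cid].parent_id is None)
    grid = int(np.ceil(np.sqrt(max(len(founders), 1))))
    gx = np.linspace(lo[0] + 4, hi[0] - 4, max(grid, 1))
    gy = np.linspace(lo[1] + 4, hi[1] - 4, max(grid, 1))
    start_pos: dict[int, np.ndarray] = {}
    for i, cid in enumerate(founders):
        gi, gj = divmod(i, grid)
        start_pos[cid] = np.array([gx[gj % len(gx)] + rng.uniform(-3, 3),
                                   gy[gi % len(gy)] + rng.uniform(-3, 3)])

    positions: dict[int, dict[int, tuple]] = {cid: {} for cid in cells}
    last_pos: dict[int, np.ndarray] = {}
    births: dict[int, list] = {}
    for cid in cells:
        births.setdefault(f_start[cid], []).append(cid)

    persistence = imaging.motion_persistence
    step = imaging.motion_step_px * np.sqrt(max(0.0, 1 - persistence ** 2))
    alive: list[int] = []
    pos = np.zeros((0, 2))
    vel = np.zeros((0, 2))
    for f in range(imaging.n_frames):
        for cid in sorted(births.get(f, [])):
            cell = cells[cid]
            if f > f_end[cid]:
                continue
            if cell.parent_id is None:
                p0 = start_pos[cid]
            else:
                mother = cells[cell.parent_id]
                mpos = last_pos.get(cell.parent_id, start_pos.get(cell.parent_id))
                # deterministic per-mother axis; daughters go to opposite
                # sides so sibling nuclei resolve as separate components
                ang = (cell.parent_id * 2.399963) % (2 * np.pi)
                sign = 1.0 if cid == mother.children[0] else -1.0
                p0 = mpos + sign * 1.3 * r * np.array([np.cos(ang), np.sin(ang)])
            alive.append(cid)
            pos = np.vstack([pos, reflect(p0)])
            vel = np.vstack([vel, np.zeros(2)])
        # resolve overlaps, then record this frame's centroids
        for _ in range(3):
            if len(alive) < 2:
                break
            diff = pos[:, None, :] - pos[None, :, :]
            dist = np.maximum(np.hypot(diff[..., 0], diff[..., 1]), 1e-3)
            np.fill_diagonal(dist, 1e9)
            close = dist < d_min
            if not close.any():
                break
            scale = np.where(close, (d_min - dist) / dist / 2, 0.0)
            push = diff * scale[..., None]
            pos = reflect(pos + push.sum(axis=1))
        for i, cid in enumerate(alive):
            positions[cid][f] = (float(pos[i, 0]), float(pos[i, 1]))
            last_pos[cid] = pos[i].copy()
        # advance walks and retire divided cells
        vel = persistence * vel + step * rng.standard_normal(vel.shape)
        pos = reflect(pos + vel)
        keep = [i for i, cid in enumerate(alive) if f + 1 <= f_end[cid]]
        alive = [alive[i] for i in keep]
        pos = pos[keep]
        vel = vel[keep]
    return positions


def render_movie(truth: TruthLineage, imaging: ImagingConfig,
                 reporter: ReporterParams | None = None) -> RenderResult:
    """Render a lineage forest into a two-channel movie plus truth tables."""
    rep = reporter or ReporterParams()
    if truth.t_total_min > imaging.total_min + 1e-6:
        raise ValueError(
            f"lineage spans {truth.t_total_min} min but the movie only covers "
            f"{imaging.total_min} min")
    model = truth.model
    dt = imaging.frame_interval_min
    rng = np.random.default_rng(imaging.rng_seed)
    positions = _simulate_positions(truth, imaging, rng)
    shape = (imaging.n_frames, imaging.height, imaging.width)
    red = np.zeros(shape, dtype=np.float64)
    green = np.zeros(shape, dtype=np.float64)

    # fixed per-cell nucleus geometry
    geom = {}
    for cid in truth.cells:
        geom[cid] = (rng.uniform(0, np.pi),
                     imaging.nucleus_radius_px * rng.uniform(0.9, 1.1))

    rows = []
    for cid, per_frame in positions.items():
        cell = truth.cells[cid]
        theta, a = geom[cid]
        b = a * rep.ellipse_aspect
        for f, (x, y) in per_frame.items():
            r_amp, g_amp, dark = _reporter_amplitudes(
                f * dt, cell, model, rep, dt)
            if r_amp > 0:
                _stamp_ellipse(red[f], x, y, a, b, theta, rep.bend, r_amp)
            if g_amp > 0:
                _stamp_ellipse(green[f], x, y, a, b, theta, rep.bend, g_amp)
            rows.append((cid, f, x, y, dark, r_amp, g_amp))

    frames = pd.DataFrame(
        rows, columns=["cell_id", "frame", "x", "y", "dark", "red_amp", "green_amp"])
    frames = frames.sort_values(["cell_id", "frame"]).reset_index(drop=True)
    truth.frames = frames

    def finish(stack: np.ndarray) -> np.ndarray:
        for f in range(stack.shape[0]):
            if imaging.psf_sigma_px > 0:
                stack[f] = gaussian_filter(stack[f], imaging.psf_sigma_px)
        stack += imaging.background_level
        if imaging.poisson_noise:
            gain = imaging.photon_gain
            stack = rng.poisson(np.clip(stack * gain, 0, None)).astype(np.float64) / gain
        if imaging.read_noise_sd > 0:
            stack = stack + rng.normal(0, imaging.read_noise_sd, stack.shape)
        stack = np.clip(np.rint(stack), 0, imaging.max_value)
        return stack.astype(np.uint8 if imaging.bit_depth == 8 else np.uint16)

    movie = FucciMovie(red=finish(red), green=finish(green),
                       frame_interval_min=dt)

    trows = []
    for cid, cell in truth.cells.items():
        per_frame = positions.get(cid, {})
        birth_frame = min(per_frame) if per_frame else None
        g1s_frame = int(np.ceil(cell.g1_end_time_min / dt - 1e-9))
        if g1s_frame >= imaging.n_frames or not per_frame:
            g1s_frame = None
        div_frame = max(per_frame) if (per_frame and cell.division_time_min
                                       is not None) else None
        trows.append((cid, birth_frame, g1s_frame, div_frame,
                      cell.parent_id, cell.censored_end))
    transitions = pd.DataFrame(
        trows, columns=["cell_id", "birth_frame", "g1s_frame",
                        "division_frame", "parent_id", "censored_end"])
    return RenderResult(movie=movie, truth=truth, transitions=transitions)


def oracle_clicks(result: RenderResult, min_amplitude: float = 25.0,
                  every: int = 1) -> pd.DataFrame:
    """Build a perfect click script from render ground truth.

    One click per cell per ``every``-th frame where the nucleus carries
    detectable reporter signal (plus always its first such frame), mirroring
    the per-frame clicking of the original interactive workflow.  Returns a
    DataFrame with columns ``frame,x,y,cell_id,parent_id``.
    """
    frames = result.truth.frames
    if frames is None:
        raise ValueError("render result carries no truth frame table")
    vis = frames[(~frames["dark"])
                 & (frames["red_amp"] + frames["green_amp"] >= min_amplitude)]
    rows = []
    for cid, grp in vis.groupby("cell_id"):
        grp = grp.sort_values("frame")
        cell = result.truth.cells[cid]
        parent = "" if cell.parent_id is None else f"c{cell.parent_id}"
        kept = grp.iloc[::every]
        if grp.index[0] not in kept.index:
            kept = pd.concat([grp.iloc[[0]], kept])
        for _, r in kept.iterrows():
            rows.append((int(r["frame"]), float(r["x"]), float(r["y"]),
                         f"c{cid}", parent))
    clicks = pd.DataFrame(rows, columns=["frame", "x", "y", "cell_id", "parent_id"])
    # cells must be introduced after their parents: order by first frame
    first = clicks.groupby("cell_id")["frame"].transform("min")
    clicks = (clicks.assign(_first=first)
              .sort_values(["_first", "cell_id", "frame"])
              .drop(columns="_first").reset_index(drop=True))
    return clicks
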