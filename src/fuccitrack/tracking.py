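"""Lineage tracking driven by scripted seed points ("clicks").

A click script is the headless stand-in for the interactive point-and-click
workflow: ordered ``(frame, x, y, cell_id, parent_id)`` records that name a
cell and its progeny through the time series.  Between clicks the tracker
propagates by nearest-centroid matching; the multi-frame dark window after
mitosis (both reporters off) is bridged by tolerating up to
``max_dark_frames`` consecutive frames without a matched region.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .segmentation import BinaryStack

__all__ = [
    "GapPolicy",
    "ClickError",
    "TrackPoint",
    "Track",
    "LineageTree",
    "validate_click_script",
    "run_click_script",
    "auto_propagate",
    "validate_lineage",
]

log = logging.getLogger(__name__)

CLICK_COLUMNS = ["frame", "x", "y", "cell_id", "parent_id"]


@dataclass(frozen=True)
class GapPolicy:
    """Matching radius and dark-gap tolerance for track propagation."""

    search_radius_px: float = 18.0
    max_dark_frames: int = 5


class ClickError(ValueError):
    """A click could not be resolved to a foreground region."""

    def __init__(self, cell_id, frame, x, y, reason):
        self.cell_id, self.frame, self.x, self.y = cell_id, frame, x, y
        super().__init__(
            f"cell {cell_id}: click at frame {frame}, ({x:.1f}, {y:.1f}) {reason}")


@dataclass(frozen=True)
class TrackPoint:
    frame: int
    x: float
    y: float
    area: int
    label: int  # component label within its frame


@dataclass
class Track:
    cell_id: str
    parent_id: Optional[str]
    points: list = field(default_factory=list)       # ordered TrackPoints
    dark_frames: list = field(default_factory=list)  # frames with no region
    children: list = field(default_factory=list)
    censored_start: bool = False
    censored_end: bool = False
    halt_reason: Optional[str] = None

    @property
    def first_frame(self) -> Optional[int]:
        return self.points[0].frame if self.points else None

    @property
    def last_frame(self) -> Optional[int]:
        return self.points[-1].frame if self.points else None

    @property
    def frames(self) -> list:
        return [p.frame for p in self.points]


@dataclass
class LineageTree:
    """Reconstructed tracks plus division edges.

    ``stack`` is kept so that per-region pixels remain addressable for
    intensity extraction; a tree loaded from JSON has ``stack=None`` and
    carries centroids/areas only.
    """

    cells: dict = field(default_factory=dict)  # cell_id -> Track
    stack: Optional[BinaryStack] = None
    warnings: list = field(default_factory=list)

    @property
    def division_edges(self) -> list:
        """(mother, (d1, d2), division_frame) for every observed division."""
        out = []
        for cid, tr in self.cells.items():
            if len(tr.children) == 2:
                out.append((cid, tuple(tr.children), tr.last_frame))
        return out


def validate_click_script(clicks: pd.DataFrame) -> pd.DataFrame:
    """Normalize and structurally validate a click script."""
    missing = [c for c in CLICK_COLUMNS if c not in clicks.columns]
    if missing:
        raise ValueError(f"click script missing columns: {missing}")
    df = clicks.copy()
    df["frame"] = df["frame"].astype(int)
    df["cell_id"] = df["cell_id"].astype(str)
    df["parent_id"] = df["parent_id"].fillna("").astype(str)
    seen: list = []
    kids: dict = {}
    for cid, grp in df.groupby("cell_id", sort=False):
        if not grp["frame"].is_monotonic_increasing:
            raise ValueError(f"cell {cid}: click frames not nondecreasing")
    order = (df.groupby("cell_id")["frame"].min().sort_values().index.tolist())
    first = df.groupby("cell_id")["frame"].min()
    for cid in order:
        parent = df.loc[df["cell_id"] == cid, "parent_id"].iloc[0]
        if parent:
            if parent not in seen:
                raise ValueError(f"cell {cid}: parent {parent} not introduced first")
            kids.setdefault(parent, []).append(cid)
            if len(kids[parent]) > 2:
                raise ValueError(f"cell {parent}: more than 2 daughters")
            if first[cid] <= first[parent]:
                raise ValueError(f"cell {cid}: starts before parent {parent}")
        seen.append(cid)
    return df


def _match_component(stack: BinaryStack, frame: int, x: float, y: float,
                     radius: float, claimed: set) -> Optional[int]:
    """Unclaimed component at/near (x, y), or None.

    Preference: the component containing the pixel, else the one with the
    nearest centroid within ``radius``; ties broken by larger area then
    lower label (logged).
    """
    labels = stack.labels(frame)
    h, w = labels.shape
    xi, yi = int(round(x)), int(round(y))
    if 0 <= xi < w and 0 <= yi < h:
        lab = int(labels[yi, xi])
        if lab > 0 and (frame, lab) not in claimed:
            return lab
    comps = stack.components(frame)
    best = None
    best_key = None
    tie = False
    for lab, (cx, cy, area) in comps.items():
        if (frame, lab) in claimed:
            continue
        d = math.hypot(cx - x, cy - y)
        if d > radius:
            continue
        key = (round(d, 6), -area, lab)
        if best_key is None or key < best_key:
            tie = best_key is not None and key[0] == best_key[0]
            best, best_key = lab, key
    if tie:
        log.info("frame %d: ambiguous match near (%.1f, %.1f); "
                 "tie broken by larger area", frame, x, y)
    return best


def run_click_script(stack: BinaryStack, clicks: pd.DataFrame,
                     gap_policy: GapPolicy | None = None,
                     on_error: str = "raise") -> LineageTree:
    """Reconstruct a lineage tree from a binary stack and a click script.

    Each cell is tracked from its first click to the frame before its first
    daughter's click (or the movie end).  Clicked frames use the click
    position; other frames use the previous centroid.  Up to
    ``max_dark_frames`` consecutive unmatched frames are recorded as dark;
    beyond that the track halts (``on_error='raise'`` raises
    :class:`ClickError` if unconsumed clicks remain, ``'warn'`` logs).
    A region is never assigned to two different cells in one frame.
    """
    policy = gap_policy or GapPolicy()
    if on_error not in ("raise", "warn"):
        raise ValueError("on_error must be 'raise' or 'warn'")
    tree = LineageTree(stack=stack)
    if clicks.empty:
        return tree
    df = validate_click_script(clicks)
    order = df.groupby("cell_id")["frame"].min().sort_values(
        kind="stable").index.tolist()
    first_click = df.groupby("cell_id")["frame"].min()
    children_of: dict = {}
    cell_clicks: dict = {}
    parent_of: dict = {}
    for cid in order:
        sub = df[df["cell_id"] == cid]
        parent_of[cid] = sub["parent_id"].iloc[0] or None
        if parent_of[cid]:
            children_of.setdefault(parent_of[cid], []).append(cid)
        cc = {}
        for _, r in sub.iterrows():
            cc.setdefault(int(r["frame"]), (float(r["x"]), float(r["y"])))
        cell_clicks[cid] = cc

    class _State:
        __slots__ = ("track", "f_end", "last_pos", "consec_dark", "started",
                     "done")

    states: dict = {}
    for cid in order:
        st = _State()
        kids = children_of.get(cid, [])
        st.track = Track(cell_id=cid, parent_id=parent_of[cid], children=kids)
        st.f_end = (min(int(first_click[k]) for k in kids) - 1 if kids
                    else stack.n_frames - 1)
        st.last_pos = cell_clicks[cid][min(cell_clicks[cid])]
        st.consec_dark = 0
        st.started = False
        st.done = False
        states[cid] = st

    def _fail(cid, st, frame, pos, reason):
        err = ClickError(cid, frame, pos[0], pos[1], reason)
        if on_error == "raise":
            raise err
        tree.warnings.append(str(err))

    claimed: set = set()
    # frame-major sweep: explicit clicks bind identity first, then the
    # remaining active cells propagate from their previous centroid
    for f in range(int(first_click.min()), stack.n_frames):
        for phase_clicked in (True, False):
            for cid in order:
                st = states[cid]
                if st.done or f < int(first_click[cid]) or f > st.f_end:
                    continue
                has_click = f in cell_clicks[cid]
                if has_click != phase_clicked:
                    continue
                pos = cell_clicks[cid][f] if has_click else st.last_pos
                lab = _match_component(stack, f, pos[0], pos[1],
                                       policy.search_radius_px, claimed)
                if lab is None:
                    st.consec_dark += 1
                    if st.consec_dark > policy.max_dark_frames:
                        st.done = True
                        later = sorted(cf for cf in cell_clicks[cid] if cf > f)
                        if not st.started:
                            _fail(cid, st, int(first_click[cid]),
                                  cell_clicks[cid][int(first_click[cid])],
                                  "found no region within the dark-gap "
                                  "tolerance")
                        elif later:
                            _fail(cid, st, later[0], cell_clicks[cid][later[0]],
                                  "lands on background beyond the dark-gap "
                                  "tolerance")
                        st.track.halt_reason = "lost"
                    elif st.started:
                        st.track.dark_frames.append(f)
                    continue
                claimed.add((f, lab))
                cx, cy, area = stack.components(f)[lab]
                st.track.points.append(TrackPoint(f, cx, cy, int(area), lab))
                st.last_pos = (cx, cy)
                st.consec_dark = 0
                st.started = True

    for cid in order:
        st = states[cid]
        track = st.track
        if not track.points:
            if on_error == "raise":
                f0 = int(first_click[cid])
                raise ClickError(cid, f0, *cell_clicks[cid][f0],
                                 "found no region within the dark-gap tolerance")
            tree.warnings.append(f"cell {cid}: never matched a region; dropped")
            continue
        # trailing dark frames carry no information; trim them
        track.dark_frames = [f for f in track.dark_frames if f < track.last_frame]
        track.censored_start = track.first_frame == 0
        track.censored_end = not track.children  # division not observed
        if track.halt_reason == "lost":
            track.censored_end = True
        tree.cells[cid] = track
    return tree


def auto_propagate(stack: BinaryStack, seed: tuple, search_radius_px: float = 18.0,
                   max_dark_frames: int = 5) -> tuple:
    """Forward-track a single cell from ``seed = (frame, x, y)``.

    Returns ``(track, halt_reason, candidates)`` where ``halt_reason`` is
    ``"split"`` (two candidate regions appeared — likely a division;
    ``candidates`` holds two daughter seed points), ``"lost"`` (no region
    for more than ``max_dark_frames``) or ``"end"`` (movie end reached).
    """
    frame, x, y = int(seed[0]), float(seed[1]), float(seed[2])
    lab0 = _match_component(stack, frame, x, y, 0.0, set())
    if lab0 is None:
        raise ClickError("auto", frame, x, y, "lands on background")
    track = Track(cell_id="auto", parent_id=None)
    cx, cy, area = stack.components(frame)[lab0]
    track.points.append(TrackPoint(frame, cx, cy, int(area), lab0))
    last = (cx, cy)
    consec_dark = 0
    for f in range(frame + 1, stack.n_frames):
        comps = stack.components(f)
        cands = sorted(
            (lab for lab, (px, py, a) in comps.items()
             if math.hypot(px - last[0], py - last[1]) <= search_radius_px),
            key=lambda lab: (-comps[lab][2], lab))
        if len(cands) >= 2:
            seeds = [(f, comps[lab][0], comps[lab][1]) for lab in cands[:2]]
            return track, "split", seeds
        if not cands:
            consec_dark += 1
            if consec_dark > max_dark_frames:
                return track, "lost", []
            track.dark_frames.append(f)
            continue
        lab = cands[0]
        cx, cy, area = comps[lab]
        track.points.append(TrackPoint(f, cx, cy, int(area), lab))
        last = (cx, cy)
        consec_dark = 0
    track.dark_frames = [f for f in track.dark_frames if f < track.last_frame]
    return track, "end", []


def validate_lineage(tree: LineageTree) -> list:
    """Check LineageTree invariants; return a list of violation strings."""
    problems = []
    for cid, tr in tree.cells.items():
        if tr.parent_id is not None and tr.parent_id not in tree.cells:
            problems.append(f"structure: cell {cid} has unknown parent {tr.parent_id}")
        n = len(tr.children)
        if n not in (0, 2):
            problems.append(f"arity: cell {cid} has {n} daughters")
        for kid in tr.children:
            if kid in tree.cells:
                ks = tree.cells[kid].first_frame
                if (tr.last_frame is not None and ks is not None
                        and ks <= tr.last_frame):
                    problems.append(
                        f"temporal order: daughter {kid} starts at frame {ks}, "
                        f"mother {cid} ends at frame {tr.last_frame}")
        frames = tr.frames
        covered = set(frames) | set(tr.dark_frames)
        if frames and covered != set(range(min(frames), max(frames) + 1)):
            problems.append(f"interval: cell {cid} track frames are not an "
                            "interval minus dark frames")
    seen_regions: dict = {}
    for cid, tr in tree.cells.items():
        for p in tr.points:
            key = (p.frame, p.label)
            if key in seen_regions and seen_regions[key] != cid:
                problems.append(
                    f"region reuse: frame {p.frame} label {p.label} assigned "
                    f"to {seen_regions[key]} and {cid}")
            seen_regions[key] = cid
    return problems
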