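"""Sample ground-truth lineage forests from a cell-cycle duration model."""
from __future__ import annotations

from collections import deque

import numpy as np

from ..models import CellCycleModel, TruthCell, TruthLineage

__all__ = ["sample_lineages"]


def _draw_duration(rng: np.random.Generator, median: float, logsd: float) -> float:
    return float(median * np.exp(logsd * rng.standard_normal()))


def sample_lineages(model: CellCycleModel, n_founders: int, t_total_min: float,
                    seed: int) -> TruthLineage:
    """Simulate a forest of dividing cells over ``t_total_min`` minutes.

    Founders are born at t=0 (newly divided at acquisition start).  Each
    cell draws independent lognormal G1 and S/G2/M durations; a cell whose
    division time falls within the movie produces exactly two daughters born
    at that instant.  Cells still alive at ``t_total_min`` are flagged
    ``censored_end``.  Deterministic given ``seed``.
    """
    if n_founders < 1:
        raise ValueError("n_founders must be >= 1")
    if t_total_min < 0:
        raise ValueError("t_total_min must be nonnegative")

    rng = np.random.default_rng(seed)
    cells: dict[int, TruthCell] = {}
    next_id = 0
    queue: deque[tuple[int | None, float]] = deque(
        (None, 0.0) for _ in range(n_founders))

    while queue:
        parent_id, birth = queue.popleft()
        g1 = _draw_duration(rng, model.g1_median_min, model.g1_logsd)
        sg2m = _draw_duration(rng, model.sg2m_median_min, model.sg2m_logsd)
        g1_end = birth + g1
        division = g1_end + sg2m
        divides = division <= t_total_min
        cell = TruthCell(
            cell_id=next_id,
            parent_id=parent_id,
            birth_time_min=birth,
            g1_end_time_min=g1_end,
            division_time_min=division if divides else None,
            censored_start=False,
            censored_end=not divides,
        )
        # All truth births are exact (founders are born at movie start);
        # censoring of the *measured* phases is decided downstream from what
        # the rendered movie shows, not here.
        cells[next_id] = cell
        next_id += 1
        if divides:
            queue.append((cell.cell_id, division))
            queue.append((cell.cell_id, division))

    # children lists (two consecutive queue entries share a parent)
    for c in cells.values():
        if c.parent_id is not None:
            cells[c.parent_id].children.append(c.cell_id)

    return TruthLineage(cells=cells, model=model, t_total_min=t_total_min,
                        seed=seed)
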