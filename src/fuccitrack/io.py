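"""File formats: TIFF stacks with JSON sidecars, CSV tables, lineage JSON,
FASTA allele sets."""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import FucciMovie
from .tracking import CLICK_COLUMNS, LineageTree, Track, TrackPoint

__all__ = [
    "save_movie", "load_movie", "save_mask_stack", "load_mask_stack",
    "read_click_script", "write_click_script",
    "lineage_to_dict", "save_lineage", "load_lineage",
    "write_fasta", "read_fasta",
]


def save_movie(movie: FucciMovie, stem) -> tuple:
    """Write one multi-page TIFF per channel plus a JSON sidecar with the
    frame interval.  Returns the two TIFF paths."""
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    red_path = stem.with_name(stem.name + "_red.tif")
    green_path = stem.with_name(stem.name + "_green.tif")
    tifffile.imwrite(red_path, movie.red, photometric="minisblack")
    tifffile.imwrite(green_path, movie.green, photometric="minisblack")
    sidecar = stem.with_suffix(".json")
    sidecar.write_text(json.dumps(
        {"frame_interval_min": movie.frame_interval_min,
         "n_frames": movie.n_frames}))
    return red_path, green_path


def load_movie(stem=None, red_path=None, green_path=None,
               frame_interval_min=None) -> FucciMovie:
    """Load a movie either from a ``stem`` (with sidecar) or explicit paths."""
    if stem is not None:
        stem = Path(stem)
        red_path = stem.with_name(stem.name + "_red.tif")
        green_path = stem.with_name(stem.name + "_green.tif")
        sidecar = stem.with_suffix(".json")
        if frame_interval_min is None and sidecar.exists():
            frame_interval_min = json.loads(sidecar.read_text())["frame_interval_min"]
    if frame_interval_min is None:
        raise ValueError("frame_interval_min unknown: no sidecar found")
    return FucciMovie(red=tifffile.imread(red_path),
                      green=tifffile.imread(green_path),
                      frame_interval_min=float(frame_interval_min))


def save_mask_stack(masks: np.ndarray, path) -> None:
    tifffile.imwrite(Path(path), np.asarray(masks, bool) * np.uint8(255),
                     photometric="minisblack")


def load_mask_stack(path) -> np.ndarray:
    return tifffile.imread(Path(path)) > 0


def read_click_script(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"cell_id": str, "parent_id": str})
    missing = [c for c in CLICK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"click script {path} missing columns {missing}")
    return df


def write_click_script(clicks: pd.DataFrame, path) -> None:
    clicks.to_csv(path, index=False)


def lineage_to_dict(tree: LineageTree) -> dict:
    cells = {}
    for cid, tr in tree.cells.items():
        cells[cid] = {
            "parent_id": tr.parent_id,
            "children": list(tr.children),
            "points": [[p.frame, p.x, p.y, p.area, p.label] for p in tr.points],
            "dark_frames": list(tr.dark_frames),
            "censored_start": tr.censored_start,
            "censored_end": tr.censored_end,
            "halt_reason": tr.halt_reason,
        }
    return {"cells": cells, "warnings": list(tree.warnings)}


def save_lineage(tree: LineageTree, path) -> None:
    Path(path).write_text(json.dumps(lineage_to_dict(tree), indent=1))


def load_lineage(path) -> LineageTree:
    """Rebuild a tree from JSON.  Region pixel sets are not serialized, so
    the loaded tree carries centroids/areas only (``stack=None``)."""
    data = json.loads(Path(path).read_text())
    tree = LineageTree(stack=None, warnings=list(data.get("warnings", [])))
    for cid, c in data["cells"].items():
        tree.cells[cid] = Track(
            cell_id=cid, parent_id=c["parent_id"], children=list(c["children"]),
            points=[TrackPoint(int(f), float(x), float(y), int(a), int(l))
                    for f, x, y, a, l in c["points"]],
            dark_frames=[int(f) for f in c["dark_frames"]],
            censored_start=bool(c["censored_start"]),
            censored_end=bool(c["censored_end"]),
            halt_reason=c.get("halt_reason"))
    return tree


def write_fasta(alleles, path) -> None:
    """``alleles`` is an iterable of (id, sequence) pairs."""
    records = [SeqRecord(Seq(s), id=str(i), description="") for i, s in alleles]
    SeqIO.write(records, Path(path), "fasta")


def read_fasta(path) -> list:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(Path(path), "fasta")]
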