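"""Synthetic fixtures for the ancillary assays.

Each generator reproduces the statistical structure its analysis
counterpart assumes — a 2N/4N propidium-iodide mixture, replicated Ct
tables, two-group nuclei fields, and wt/indel allele sets — with exact
ground truth, so every assay is testable round-trip without any download.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "simulate_pi_events",
    "simulate_ct_table",
    "simulate_nuclei_field",
    "NucleiField",
    "VariantSpec",
    "simulate_alleles",
]

REFERENCE_GENE = "POLR2a"


def simulate_pi_events(fractions: Sequence[float], cv: float, n_events: int,
                       seed: int, mode_intensity: float = 200.0,
                       sample: str = "wt") -> pd.DataFrame:
    """Propidium-iodide intensity events for a G0-G1 / S / G2-M mixture.

    ``fractions`` are (f_g0g1, f_s, f_g2m) and must sum to 1.  G0-G1 events
    are Normal(mu, cv*mu) around ``mode_intensity``; G2-M events are
    Normal(2mu, 2*cv*mu); S events are uniform between the two modes with
    Gaussian-smoothed edges.  Returns a DataFrame with columns
    ``intensity, sample, phase`` (``phase`` is the generating truth).
    """
    fr = np.asarray(fractions, dtype=float)
    if fr.size != 3 or (fr < 0).any() or abs(fr.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must be 3 nonnegative values summing to 1")
    if not (0 <= cv < 0.3):
        raise ValueError("cv must be in [0, 0.3)")
    if n_events == 0:
        return pd.DataFrame(columns=["intensity", "sample", "phase"])
    rng = np.random.default_rng(seed)
    mu = mode_intensity
    counts = rng.multinomial(n_events, fr)
    parts = []
    g1 = mu + cv * mu * rng.standard_normal(counts[0])
    parts.append(pd.DataFrame({"intensity": g1, "phase": "G0-G1"}))
    s = rng.uniform(mu, 2 * mu, counts[1]) + cv * mu * rng.standard_normal(counts[1])
    parts.append(pd.DataFrame({"intensity": s, "phase": "S"}))
    g2 = 2 * mu + 2 * cv * mu * rng.standard_normal(counts[2])
    parts.append(pd.DataFrame({"intensity": g2, "phase": "G2-M"}))
    events = pd.concat(parts, ignore_index=True)
    events["intensity"] = events["intensity"].clip(lower=1e-6)
    events["sample"] = sample
    return events.sample(frac=1.0, random_state=int(rng.integers(2 ** 31))
                         ).reset_index(drop=True)


def simulate_ct_table(true_fold_changes: dict, ct_ref: float, replicates: int,
                      noise_sd: float, seed: int,
                      n_experiments: int = 3) -> pd.DataFrame:
    """Replicated two-sample TaqMan Ct table with known fold changes.

    For each gene, the mutant target Ct is shifted by -log2(fold) relative
    to the wild-type target (both measured against the reference gene
    POLR2a, included for every sample and experiment).  A per-(sample,
    experiment) baseline offset emulates loading differences; it cancels in
    the reference subtraction.  Columns: ``sample, gene, experiment,
    replicate, ct``.
    """
    if replicates < 2:
        raise ValueError("replicates must be >= 2")
    for gene, fold in true_fold_changes.items():
        if fold <= 0:
            raise ValueError(f"fold change for {gene} must be > 0")
    rng = np.random.default_rng(seed)
    rows = []
    base_ct = {gene: ct_ref + 1.0 + i for i, gene in
               enumerate(true_fold_changes)}
    for exp in range(1, n_experiments + 1):
        for sample in ("wt", "mut"):
            offset = rng.normal(0, 0.3)
            genes = {REFERENCE_GENE: ct_ref}
            for gene, fold in true_fold_changes.items():
                shift = -np.log2(fold) if sample == "mut" else 0.0
                genes[gene] = base_ct[gene] + shift
            for gene, ct0 in genes.items():
                for rep in range(1, replicates + 1):
                    ct = ct0 + offset + rng.normal(0, noise_sd)
                    rows.append((sample, gene, exp, rep, ct))
    return pd.DataFrame(rows, columns=["sample", "gene", "experiment",
                                       "replicate", "ct"])


@dataclass
class NucleiField:
    """Synthetic immunofluorescence field: one image+mask per group."""

    images: dict   # group -> float image
    labels: dict   # group -> int32 label mask
    truth: pd.DataFrame  # group, label, true_mean


def simulate_nuclei_field(group_means: Sequence[float],
                          n_cells: Sequence[int], noise_sd: float, seed: int,
                          groups: Sequence[str] = ("wt", "mut"),
                          nucleus_radius_px: float = 8.0,
                          background: float = 5.0,
                          pixel_noise_sd: float = 2.0) -> NucleiField:
    """Non-overlapping elliptical nuclei with per-cell means around each
    group mean (between-cell sd ``noise_sd``), plus mild pixel noise."""
    if len(group_means) != len(n_cells) or len(group_means) != len(groups):
        raise ValueError("group_means, n_cells and groups must align")
    if any(m <= 0 for m in group_means):
        raise ValueError("group means must be positive")
    if any(n <= 0 for n in n_cells):
        raise ValueError("each group needs at least one cell")
    rng = np.random.default_rng(seed)
    r = nucleus_radius_px
    pitch = int(np.ceil(2.6 * r))
    images, labels = {}, {}
    truth_rows = []
    for g_i, (group, mean, n) in enumerate(zip(groups, group_means, n_cells)):
        cols = int(np.ceil(np.sqrt(n)))
        rows_n = int(np.ceil(n / cols))
        h = rows_n * pitch + pitch
        w = cols * pitch + pitch
        img = np.full((h, w), background, dtype=np.float64)
        lab = np.zeros((h, w), dtype=np.int32)
        yy, xx = np.mgrid[0:h, 0:w]
        for idx in range(n):
            ri, ci = divmod(idx, cols)
            cy = pitch * (ri + 1) + rng.uniform(-2, 2)
            cx = pitch * (ci + 1) + rng.uniform(-2, 2)
            theta = rng.uniform(0, np.pi)
            a, b = r, 0.8 * r
            c, s = np.cos(theta), np.sin(theta)
            u = (xx - cx) * c + (yy - cy) * s
            v = -(xx - cx) * s + (yy - cy) * c
            inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
            cell_mean = max(rng.normal(mean, noise_sd), 1e-3)
            img[inside] += cell_mean
            lab[inside] = idx + 1
            truth_rows.append((group, idx + 1, cell_mean))
        img += rng.normal(0, pixel_noise_sd, img.shape)
        images[group] = np.clip(img, 0, None)
        labels[group] = lab
    truth = pd.DataFrame(truth_rows, columns=["group", "label", "true_mean"])
    return NucleiField(images=images, labels=labels, truth=truth)


@dataclass(frozen=True)
class VariantSpec:
    """A single indel: ``op`` is 'ins' or 'del', applied at ``pos`` (0-based
    offset in the reference).  Insertions insert ``seq`` before ``pos``;
    deletions remove ``length`` bases starting at ``pos``."""

    op: str
    pos: int
    seq: str = ""
    length: int = 0

    def apply(self, ref: str) -> str:
        if self.op == "ins":
            if not self.seq:
                raise ValueError("insertion needs seq")
            return ref[:self.pos] + self.seq + ref[self.pos:]
        if self.op == "del":
            if self.length < 1:
                raise ValueError("deletion needs length >= 1")
            return ref[:self.pos] + ref[self.pos + self.length:]
        raise ValueError(f"unknown op {self.op!r}")


def simulate_alleles(ref_seq: str, variant: VariantSpec, n_wt: int,
                     n_mut: int, seed: int = 0) -> list:
    """Single-allele amplicon set: n_wt reference copies and n_mut edited
    copies, shuffled deterministically.  Returns ``(allele_id, sequence)``
    pairs."""
    if n_wt < 0 or n_mut < 0 or n_wt + n_mut == 0:
        raise ValueError("need at least one allele")
    mut_seq = variant.apply(ref_seq)
    alleles = [("wt", ref_seq)] * n_wt + [("mut", mut_seq)] * n_mut
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(alleles))
    return [(f"allele_{i + 1:02d}", alleles[j][1]) for i, j in enumerate(order)]


def random_dna(length: int, seed: int, forbid_stops_in_frame: Optional[int] = None) -> str:
    """Random DNA; optionally free of in-frame stop codons for a given
    frame offset (useful for building premature-stop fixtures)."""
    rng = np.random.default_rng(seed)
    bases = "ACGT"
    stops = {"TAA", "TAG", "TGA"}
    while True:
        seq = "".join(bases[i] for i in rng.integers(0, 4, length))
        if forbid_stops_in_frame is None:
            return seq
        f = forbid_stops_in_frame
        codons = {seq[i:i + 3] for i in range(f, length - 2, 3)}
        if not (codons & stops):
            return seq
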