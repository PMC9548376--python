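"""Ancillary quantitative assays.

DNA-content gating of propidium-iodide histograms, relative expression by
the 2^-ddCt method, and ROI intensity quantification (group means,
nucleus/cytoplasm ratio, percent change).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d, labeled_comprehension
from scipy.signal import find_peaks

__all__ = [
    "PhaseFractions",
    "FoldChangeReport",
    "gate_dna_content",
    "ddct_fold_change",
    "quantify_rois",
    "nc_ratio",
    "percent_change",
]

log = logging.getLogger(__name__)

REFERENCE_GENE = "POLR2a"
MIN_PI_EVENTS = 500


@dataclass
class PhaseFractions:
    """Cell-cycle phase fractions gated from a PI histogram.

    Fractions are over all gated events (debris and far outliers excluded,
    so they may sum to slightly less than 1 before the S-plateau
    correction redistributes gate overlap).
    """

    f_g0g1: float
    f_s: float
    f_g2m: float
    g2m_over_g0g1: float
    mu_g0g1: float
    mu_g2m: Optional[float]
    n_gated: int
    n_events: int
    warnings: list = field(default_factory=list)


def _peak_positions(intensities: np.ndarray, bins: int = 256,
                    smooth_bins: float = 2.0) -> tuple:
    """(mu_g0g1, mu_g2m or None) from a kernel-smoothed histogram."""
    hist, edges = np.histogram(intensities, bins=bins)
    centers = (edges[:-1] + edges[1:]) / 2
    sm = gaussian_filter1d(hist.astype(float), smooth_bins)
    peaks, props = find_peaks(sm, prominence=0.02 * sm.max())
    if len(peaks) == 0:
        return float(centers[np.argmax(sm)]), None
    prom = props["prominences"]
    main = peaks[np.argmax(prom)]
    mu = centers[main]
    # if a comparable peak sits at half the position, that one is the 2N mode
    for p, pr in zip(peaks, prom):
        if 0.4 * mu <= centers[p] <= 0.6 * mu and pr >= 0.2 * prom.max():
            return float(centers[p]), float(mu)
    # otherwise find the 4N mode nearest twice the 2N position
    cands = [(abs(centers[p] - 2 * mu), float(centers[p]))
             for p in peaks if 1.6 * mu <= centers[p] <= 2.4 * mu]
    mu2 = min(cands)[1] if cands else None
    return float(mu), mu2


def _local_sd(intensities: np.ndarray, mu: float,
              init_halfwidth: float) -> float:
    """Peak sd from events near ``mu``, corrected for window truncation.

    The empirical sd of a normal restricted to +/-2 sigma is 0.8796 sigma;
    iterating window <- +/-2 sigma_est with that correction converges to
    the untruncated sd regardless of the starting window.
    """
    trunc_corr = 0.8796
    sigma = init_halfwidth * mu / 2.0
    for _ in range(15):
        sel = intensities[np.abs(intensities - mu) <= 2.0 * sigma]
        if sel.size < 10:
            return max(sigma, 0.01 * mu)
        new = float(np.std(sel)) / trunc_corr
        if abs(new - sigma) < 1e-3 * mu:
            sigma = new
            break
        sigma = new
    return sigma


def gate_dna_content(events, n_sigma: float = 3.0,
                     manual_gates: Optional[dict] = None,
                     debris_cut: float = 0.5) -> PhaseFractions:
    """Gate a PI event list into G0-G1, S and G2-M fractions.

    The G0-G1 (2N) mode is the dominant low-intensity peak of a smoothed
    histogram and the G2-M (4N) mode the peak nearest twice that position.
    Peak gates span ``n_sigma`` estimated peak sds; S is everything
    strictly between them.  Because S-phase events also lie underneath the
    peak gates, the S density estimated from the inter-gate plateau is
    added back to S and subtracted from the peak counts (event totals are
    conserved).  ``manual_gates`` ({'g0g1': (lo, hi), 'g2m': (lo, hi)})
    overrides peak detection and skips the correction, mirroring manual
    gating.  Events below ``debris_cut`` times the 2N mode are discarded
    as debris first.
    """
    if isinstance(events, pd.DataFrame):
        intensities = events["intensity"].to_numpy(dtype=float)
    else:
        intensities = np.asarray(events, dtype=float)
    if intensities.size < MIN_PI_EVENTS:
        raise ValueError(f"need at least {MIN_PI_EVENTS} events, "
                         f"got {intensities.size}")
    warnings: list = []

    if manual_gates is not None:
        lo1, hi1 = manual_gates["g0g1"]
        lo2, hi2 = manual_gates["g2m"]
        n_g1 = int(((intensities >= lo1) & (intensities <= hi1)).sum())
        n_g2 = int(((intensities >= lo2) & (intensities <= hi2)).sum())
        n_s = int(((intensities > hi1) & (intensities < lo2)).sum())
        total = n_g1 + n_s + n_g2
        f1, fs, f2 = (np.array([n_g1, n_s, n_g2]) / total if total else
                      (0.0, 0.0, 0.0))
        return PhaseFractions(f1, fs, f2, f2 / f1 if f1 else float("nan"),
                              (lo1 + hi1) / 2, (lo2 + hi2) / 2,
                              total, intensities.size, warnings)

    mu1_guess, _ = _peak_positions(intensities)
    kept = intensities[intensities >= debris_cut * mu1_guess]
    mu1, mu2 = _peak_positions(kept)
    sd1 = _local_sd(kept, mu1, 0.15)
    g1_lo, g1_hi = mu1 - n_sigma * sd1, mu1 + n_sigma * sd1
    if mu2 is None:
        warnings.append("no 4N peak found; f_g2m set to 0")
        log.warning("gate_dna_content: %s", warnings[-1])
        n_g1 = int(((kept >= g1_lo) & (kept <= g1_hi)).sum())
        return PhaseFractions(1.0 if n_g1 else 0.0, 0.0, 0.0,
                              0.0, mu1, None, n_g1, intensities.size, warnings)
    sd2 = _local_sd(kept, mu2, 0.10)
    g2_lo, g2_hi = mu2 - n_sigma * sd2, mu2 + n_sigma * sd2

    n_g1 = float(((kept >= g1_lo) & (kept <= g1_hi)).sum())
    n_g2 = float(((kept >= g2_lo) & (kept <= g2_hi)).sum())
    n_s = float(((kept > g1_hi) & (kept < g2_lo)).sum())

    # S-plateau correction: S events hidden under the peak gates
    between = g2_lo - g1_hi
    if between > 0 and n_s > 0:
        h = n_s / between  # events per intensity unit on the plateau
        under_g1 = min(h * (g1_hi - mu1), n_g1)
        under_g2 = min(h * (mu2 - g2_lo), n_g2)
        n_g1 -= under_g1
        n_g2 -= under_g2
        n_s += under_g1 + under_g2
    total = n_g1 + n_s + n_g2
    if total == 0:
        raise ValueError("no events fell inside the gates")
    f1, fs, f2 = n_g1 / total, n_s / total, n_g2 / total
    return PhaseFractions(f1, fs, f2, f2 / f1 if f1 else float("nan"),
                          mu1, mu2, int(round(total)), intensities.size,
                          warnings)


@dataclass
class FoldChangeReport:
    """2^-ddCt relative expression of one probe (mut vs wt)."""

    target: str
    reference: str
    per_experiment: pd.DataFrame  # experiment, dct_wt, dct_mut, ddct, fold
    mean_fold: float
    sd_fold: float


def ddct_fold_change(ct: pd.DataFrame, target_probe: str,
                     reference_gene: str = REFERENCE_GENE) -> FoldChangeReport:
    """Fold change of ``target_probe`` in mut vs wt by the 2^-ddCt method.

    Replicates are averaged at the Ct level per (sample, gene, experiment);
    dCt = Ct_target - Ct_reference, ddCt = dCt_mut - dCt_wt, fold =
    2^-ddCt per experiment, then mean +/- sd across experiments.
    """
    required = {"sample", "gene", "experiment", "replicate", "ct"}
    if not required.issubset(ct.columns):
        raise ValueError(f"Ct table must have columns {sorted(required)}")
    means = (ct.groupby(["experiment", "sample", "gene"])["ct"]
             .mean().rename("ct").reset_index())
    rows = []
    for exp, grp in means.groupby("experiment"):
        pivot = grp.pivot(index="gene", columns="sample", values="ct")
        for sample in ("wt", "mut"):
            if sample not in pivot.columns or \
                    reference_gene not in pivot.index or \
                    pd.isna(pivot.loc[reference_gene].get(sample, np.nan)):
                raise ValueError(
                    f"experiment {exp}: missing {reference_gene} rows for "
                    f"sample {sample!r}")
            if target_probe not in pivot.index or \
                    pd.isna(pivot.loc[target_probe].get(sample, np.nan)):
                raise ValueError(
                    f"experiment {exp}: missing {target_probe} rows for "
                    f"sample {sample!r}")
        dct_wt = pivot.loc[target_probe, "wt"] - pivot.loc[reference_gene, "wt"]
        dct_mut = pivot.loc[target_probe, "mut"] - pivot.loc[reference_gene, "mut"]
        ddct = dct_mut - dct_wt
        rows.append((exp, dct_wt, dct_mut, ddct, 2.0 ** (-ddct)))
    per_exp = pd.DataFrame(rows, columns=["experiment", "dct_wt", "dct_mut",
                                          "ddct", "fold"])
    folds = per_exp["fold"].to_numpy()
    sd = float(np.std(folds, ddof=1)) if len(folds) > 1 else 0.0
    return FoldChangeReport(target_probe, reference_gene, per_exp,
                            float(folds.mean()), sd)


def quantify_rois(image: np.ndarray, label_mask: np.ndarray,
                  group_label: str = "",
                  compartment: str = "nucleus") -> pd.DataFrame:
    """Mean intensity per labeled ROI.

    Returns columns ``roi_id, compartment, mean_intensity, area, group``;
    labels absent from the mask simply yield no row.
    """
    if image.shape != label_mask.shape:
        raise ValueError("image and label mask shapes differ")
    labs = np.unique(label_mask)
    labs = labs[labs > 0]
    if labs.size == 0:
        log.warning("quantify_rois: empty label mask")
        return pd.DataFrame(columns=["roi_id", "compartment",
                                     "mean_intensity", "area", "group"])
    means = labeled_comprehension(image, label_mask, labs, np.mean, float, np.nan)
    areas = labeled_comprehension(image, label_mask, labs, len, int, 0)
    return pd.DataFrame({"roi_id": labs.astype(int), "compartment": compartment,
                         "mean_intensity": means, "area": areas,
                         "group": group_label})


def nc_ratio(roi_table: pd.DataFrame, pairing: pd.DataFrame) -> pd.DataFrame:
    """Nucleus/cytoplasm mean-intensity ratio per cell.

    ``pairing`` has columns ``cell_id, nucleus_id, cytoplasm_id`` referring
    to ``roi_id`` values.  Cells whose cytoplasm mean is 0 are flagged
    ``excluded`` with a NaN ratio.
    """
    means = roi_table.set_index("roi_id")["mean_intensity"]
    rows = []
    for _, r in pairing.iterrows():
        try:
            nuc = float(means.loc[r["nucleus_id"]])
            cyt = float(means.loc[r["cytoplasm_id"]])
        except KeyError as e:
            raise ValueError(f"cell {r['cell_id']}: unknown ROI {e}") from e
        if cyt == 0:
            log.warning("cell %s: zero cytoplasm mean; excluded", r["cell_id"])
            rows.append((r["cell_id"], nuc, cyt, np.nan, True))
        else:
            rows.append((r["cell_id"], nuc, cyt, nuc / cyt, False))
    return pd.DataFrame(rows, columns=["cell_id", "nucleus_mean",
                                       "cytoplasm_mean", "ratio", "excluded"])


def percent_change(group_a_means: Sequence[float],
                   group_b_means: Sequence[float]) -> tuple:
    """Percent decrease of group b relative to group a, with sd.

    Returns ``(percent_decrease, sd)`` where the decrease is
    100*(1 - mean_b/mean_a) and the sd is that of the per-cell percent
    values of group b taken relative to the group-a mean.
    """
    a = np.asarray(list(group_a_means), dtype=float)
    b = np.asarray(list(group_b_means), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    mean_a = a.mean()
    if mean_a <= 0:
        raise ValueError("group a mean must be positive")
    per_cell = 100.0 * (1.0 - b / mean_a)
    sd = float(np.std(per_cell, ddof=1)) if b.size > 1 else 0.0
    return float(100.0 * (1.0 - b.mean() / mean_a)), sd
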