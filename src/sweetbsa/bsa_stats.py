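"""Per-locus bulk-segregant statistics and smoothed genome-wide tracks.

Two complementary statistics quantify allele-frequency divergence between
the high- and low-phenotype bulks at each biallelic locus:

* **ED / ED4** — the Euclidean distance between the bulks' allele-frequency
  vectors, ED = sqrt((f_H - f_L)^2 + ((1-f_H) - (1-f_L))^2)
  = sqrt(2)*|f_H - f_L| for a biallelic locus, raised to the fourth power to
  suppress background noise before window averaging.
* **G / G'** — the 2x2 log-likelihood-ratio (G-test) statistic on the
  ref/alt read counts of the two bulks, G = 2*sum n_i*ln(n_i/e_i) with
  expected counts e_i from the table margins under independence; G' is the
  tricube-kernel local average of G over a physical window.

ED4 is smoothed with an unweighted mean over 1 Mb windows stepped every
50 kb; G with a tricube kernel of 1 Mb total width.  The association
threshold is the genome-wide empirical quantile (default 99.5%, linear
interpolation) of the smoothed per-locus track.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import xlogy

log = logging.getLogger(__name__)


def allele_frequencies(ref: np.ndarray, alt: np.ndarray) -> np.ndarray:
    """Alt-allele read frequency alt/(ref+alt); NaN where depth is zero."""
    ref = np.asarray(ref, dtype=float)
    alt = np.asarray(alt, dtype=float)
    depth = ref + alt
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(depth > 0, alt / depth, np.nan)


def ed_statistic(f_high: np.ndarray, f_low: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Euclidean distance between bulk allele-frequency vectors, and its
    fourth power."""
    d = np.asarray(f_high, dtype=float) - np.asarray(f_low, dtype=float)
    ed = np.sqrt(d * d + d * d)
    return ed, ed ** 4


def g_statistic(ref_high, alt_high, ref_low, alt_low) -> np.ndarray:
    """G-test statistic of the 2x2 (ref,alt) x (high,low) read-count table.

    0*ln(0) is treated as 0.  Returns NaN where all four counts are zero
    (the statistic is undefined there); callers drop and log such loci.
    """
    n = np.stack([np.asarray(x, dtype=float)
                  for x in (ref_high, alt_high, ref_low, alt_low)])
    total = n.sum(axis=0)
    row_ref = n[0] + n[2]
    row_alt = n[1] + n[3]
    col_high = n[0] + n[1]
    col_low = n[2] + n[3]
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.stack([row_ref * col_high, row_alt * col_high,
                      row_ref * col_low, row_alt * col_low]) / total
    g = 2.0 * (xlogy(n, n) - xlogy(n, e)).sum(axis=0)
    return np.where(total > 0, g, np.nan)


# ---------------------------------------------------------------------------
# smoothing


def smooth_ed4(pos: np.ndarray, ed4: np.ndarray, window: int = 1_000_000,
               step: int = 50_000) -> tuple[np.ndarray, pd.DataFrame]:
    """Sliding-window mean of ED4 along one chromosome.

    Windows [a, a+window) are anchored every ``step`` bp from 0; empty
    windows emit no value.  Each locus's smoothed value is taken from the
    containing window whose centre is nearest the locus.  Returns the
    per-locus smoothed values and the per-window track (start, end, n, mean).
    """
    pos = np.asarray(pos)
    ed4 = np.asarray(ed4, dtype=float)
    n_anchor = int(pos.max() // step) + 1
    anchors = np.arange(n_anchor) * step
    left = np.searchsorted(pos, anchors, side="left")
    right = np.searchsorted(pos, anchors + window, side="left")
    csum = np.r_[0.0, np.cumsum(ed4)]
    counts = right - left
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, (csum[right] - csum[left]) / counts, np.nan)

    # containing window with the nearest centre: anchor closest to pos-window/2
    k = np.rint((pos - window / 2) / step).astype(int)
    kmax = pos // step                       # largest anchor with a <= pos
    kmin = np.maximum(0, (pos - window) // step + 1)  # smallest with pos < a+window
    k = np.clip(k, kmin, np.minimum(kmax, n_anchor - 1)).astype(int)
    smoothed = means[k]

    windows = pd.DataFrame({"start": anchors + 1, "end": anchors + window,
                            "n_loci": counts, "mean_ed4": means})
    return smoothed, windows.loc[counts > 0].reset_index(drop=True)


def smooth_gprime(pos: np.ndarray, g: np.ndarray, window: int = 1_000_000) -> np.ndarray:
    """Tricube-weighted local average of G along one chromosome.

    For each locus, loci within window/2 bp on either side contribute with
    weight (1 - (d/(window/2))^3)^3, normalised to sum to one.
    """
    pos = np.asarray(pos, dtype=float)
    g = np.asarray(g, dtype=float)
    half = window / 2.0
    out = np.empty_like(g)
    lo = np.searchsorted(pos, pos - half, side="left")
    hi = np.searchsorted(pos, pos + half, side="right")
    for i in range(len(pos)):
        d = np.abs(pos[lo[i]:hi[i]] - pos[i]) / half
        w = (1.0 - d ** 3) ** 3
        out[i] = np.dot(w, g[lo[i]:hi[i]]) / w.sum()
    return out


def scan_threshold(track: np.ndarray, quantile: float = 0.995) -> float:
    """Empirical genome-wide quantile of a smoothed track (linear
    interpolation between order statistics)."""
    track = np.asarray(track, dtype=float)
    if track.size == 0:
        raise ValueError("empty track")
    return float(np.quantile(track, quantile, method="linear"))


# ---------------------------------------------------------------------------
# scan driver


@dataclasses.dataclass
class GenomeScan:
    """One genome-wide association scan.

    ``loci`` has columns chrom, pos, raw_stat, smoothed_stat,
    above_threshold.  ``windows`` carries the per-window ED4 means (None for
    the G' method, whose kernel is locus-centred).
    """

    method: str                       # "ED4" or "Gprime"
    window: int
    step: int | None
    threshold_quantile: float
    threshold: float
    loci: pd.DataFrame
    windows: pd.DataFrame | None = None

    def write_track(self, path: str | Path) -> Path:
        path = Path(path)
        self.loci.to_csv(path, sep="\t", index=False, float_format="%.6g")
        return path


def genome_scan(table: pd.DataFrame, method: str = "ED4",
                window: int = 1_000_000, step: int = 50_000,
                quantile: float = 0.995) -> GenomeScan:
    """Compute a smoothed, thresholded genome scan from a filtered
    allele-depth table.

    Loci with zero read depth in either bulk are excluded up front (logged);
    for the G' method, loci where all four counts are zero would be dropped
    the same way.
    """
    if method not in ("ED4", "Gprime"):
        raise ValueError(f"unknown scan method {method!r}")
    depth_h = table["high_ref"] + table["high_alt"]
    depth_l = table["low_ref"] + table["low_alt"]
    usable = (depth_h > 0) & (depth_l > 0)
    if (~usable).any():
        log.info("%s scan: excluded %d loci with zero depth in a bulk",
                 method, int((~usable).sum()))
    table = table.loc[usable]

    if method == "ED4":
        f_high = allele_frequencies(table["high_ref"], table["high_alt"])
        f_low = allele_frequencies(table["low_ref"], table["low_alt"])
        _, raw = ed_statistic(f_high, f_low)
    else:
        raw = g_statistic(table["high_ref"], table["high_alt"],
                          table["low_ref"], table["low_alt"])

    loci = pd.DataFrame({"chrom": table["chrom"].to_numpy(),
                         "pos": table["pos"].to_numpy(),
                         "raw_stat": raw})
    smoothed = np.empty(len(loci))
    window_frames = []
    for chrom, sub in loci.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        if method == "ED4":
            sm, win = smooth_ed4(sub["pos"].to_numpy(), sub["raw_stat"].to_numpy(),
                                 window, step)
            win.insert(0, "chrom", chrom)
            window_frames.append(win)
        else:
            sm = smooth_gprime(sub["pos"].to_numpy(), sub["raw_stat"].to_numpy(), window)
        smoothed[idx] = sm
    loci["smoothed_stat"] = smoothed

    threshold = scan_threshold(loci["smoothed_stat"].to_numpy(), quantile)
    loci["above_threshold"] = loci["smoothed_stat"] > threshold
    windows = pd.concat(window_frames, ignore_index=True) if window_frames else None
    return GenomeScan(method=method, window=window,
                      step=step if method == "ED4" else None,
                      threshold_quantile=quantile, threshold=threshold,
                      loci=loci, windows=windows)
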