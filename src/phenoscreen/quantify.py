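"""Intensity quantification of plate-screen images.

Per experimental condition (probe x line x concentration x channel x time),
all images of that condition — typically 2 sites x 2 replicates = 4 — are
pooled into one pixel multiset, Otsu's threshold is computed on a 256-bin
histogram of the pooled pixels, and the mean intensity over the
threshold-positive (foreground) area is reported.  Thresholding the pooled
set, rather than each image, mirrors the combine-then-threshold processing
order of the original batch analysis; "positive" is read as strictly
greater than the threshold.
"""
from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import tifffile

from .synth import ImageRecord

logger = logging.getLogger("phenoscreen")

#: condition key shared by all images pooled together
CONDITION_KEY = ["probe_id", "line_id", "concentration_nM", "channel", "time_h"]

INTENSITY_COLUMNS = CONDITION_KEY + ["mean_fg", "n_fg_pixels", "threshold", "flag"]

N_BINS = 256


def pool_condition_images(images: Sequence[ImageRecord]) -> np.ndarray:
    """Concatenate pixels of all images of one condition into a flat array.

    Images must share the condition key (site/replicate may differ) and the
    bit depth.  Downstream statistics are order-invariant.
    """
    if not images:
        raise ValueError("need at least one image to pool")
    first = images[0]
    key0 = (first.condition.probe_id, first.condition.line_id,
            first.condition.concentration_nM, first.condition.channel,
            first.condition.time_h)
    for rec in images[1:]:
        c = rec.condition
        if (c.probe_id, c.line_id, c.concentration_nM, c.channel, c.time_h) != key0:
            raise ValueError("mismatched condition keys in pooled images")
        if rec.bit_depth != first.bit_depth:
            raise ValueError("mixed bit depths in pooled images")
    return np.concatenate([rec.pixels.ravel() for rec in images])


def otsu_threshold(counts: np.ndarray) -> int:
    """Otsu's threshold on a histogram: the bin index ``t`` maximizing the
    between-class variance of the split (bins <= t) vs (bins > t).

    Ties are broken toward the smallest ``t``.  A histogram whose mass sits
    in a single bin admits no two-class split and raises ``ValueError``.
    """
    counts = np.asarray(counts, dtype=np.float64)
    if counts.ndim != 1 or counts.size < 1 or counts.min() < 0:
        raise ValueError("counts must be a 1-D non-negative histogram")
    if np.count_nonzero(counts) < 2:
        raise ValueError("degenerate histogram: all mass in one bin")
    idx = np.arange(counts.size)
    total = counts.sum()
    w0 = np.cumsum(counts)[:-1]           # mass of class <= t, t = 0..B-2
    w1 = total - w0
    m0 = np.cumsum(counts * idx)[:-1]
    mu0 = np.divide(m0, w0, out=np.zeros_like(w0), where=w0 > 0)
    mu1 = np.divide(counts @ idx - m0, w1, out=np.zeros_like(w1), where=w1 > 0)
    sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b[(w0 == 0) | (w1 == 0)] = 0.0
    return int(np.argmax(sigma_b))        # argmax returns the first maximum


def otsu_threshold_value(pixels: np.ndarray, n_bins: int = N_BINS) -> int:
    """Integer threshold value for integer pixel data.

    Builds ``n_bins`` equal-width bins over the observed range (the classic
    ``graythresh`` route rescales to 8 bits; 256 bins keeps comparability),
    picks the Otsu bin, and converts it to the largest integer intensity in
    the lower class, so that ``pixel > threshold`` reproduces the histogram
    split exactly.
    """
    pixels = np.asarray(pixels)
    lo, hi = int(pixels.min()), int(pixels.max())
    if lo == hi:
        raise ValueError("degenerate histogram: constant image")
    edges = np.linspace(lo, hi, n_bins + 1)
    counts, _ = np.histogram(pixels, bins=edges)
    t = otsu_threshold(counts)
    return int(math.ceil(edges[t + 1])) - 1


def mean_foreground_intensity(pixels: np.ndarray,
                              threshold: float) -> tuple[float, int]:
    """Mean of pixels strictly greater than ``threshold`` and their count.

    An empty foreground is an error, never a silent (0, 0).
    """
    pixels = np.asarray(pixels)
    fg = pixels[pixels > threshold]
    if fg.size == 0:
        raise ValueError("empty foreground: no pixel above threshold")
    return float(fg.mean()), int(fg.size)


def _default_reader(path: Path) -> np.ndarray:
    return tifffile.imread(path)


def quantify_screen(manifest: pd.DataFrame, root: str | Path | None = None,
                    reader: Callable[[Path], np.ndarray] | None = None,
                    n_bins: int = N_BINS) -> pd.DataFrame:
    """Quantify every condition of a screen manifest.

    Returns one row per (probe, line, concentration, channel, time) with the
    pooled-foreground mean, foreground pixel count and threshold.  Rows whose
    images are missing or whose pooled histogram is degenerate are flagged
    (``flag`` = "missing" / "degenerate") rather than dropped; healthy rows
    carry ``flag`` = "ok".  Extra manifest annotation columns (family,
    origin) are carried through when present.
    """
    reader = reader or _default_reader
    root = Path(root) if root is not None else None
    carry = [c for c in ("family", "origin") if c in manifest.columns]

    rows = []
    n_missing = n_degenerate = 0
    for key, group in manifest.groupby(CONDITION_KEY, sort=True):
        extras = {c: group.iloc[0][c] for c in carry}
        pixel_parts: list[np.ndarray] = []
        missing = False
        for path in group["path"]:
            full = Path(path) if root is None else root / path
            try:
                pixel_parts.append(np.asarray(reader(full)).ravel())
            except (OSError, ValueError) as exc:
                logger.warning("missing image for condition %s: %s", key, exc)
                missing = True
        if missing or not pixel_parts:
            n_missing += 1
            rows.append({**dict(zip(CONDITION_KEY, key)), **extras,
                         "mean_fg": np.nan, "n_fg_pixels": 0,
                         "threshold": -1, "flag": "missing"})
            continue
        pooled = np.concatenate(pixel_parts)
        try:
            thr = otsu_threshold_value(pooled, n_bins=n_bins)
            mean_fg, n_fg = mean_foreground_intensity(pooled, thr)
        except ValueError as exc:
            logger.warning("degenerate condition %s: %s", key, exc)
            n_degenerate += 1
            rows.append({**dict(zip(CONDITION_KEY, key)), **extras,
                         "mean_fg": np.nan, "n_fg_pixels": 0,
                         "threshold": -1, "flag": "degenerate"})
            continue
        rows.append({**dict(zip(CONDITION_KEY, key)), **extras,
                     "mean_fg": mean_fg, "n_fg_pixels": n_fg,
                     "threshold": thr, "flag": "ok"})

    table = pd.DataFrame(rows)
    logger.info("quantified %d conditions (%d missing, %d degenerate)",
                len(table), n_missing, n_degenerate)
    return table[[c for c in INTENSITY_COLUMNS[:5]] + carry
                 + INTENSITY_COLUMNS[5:]]
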