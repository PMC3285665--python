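"""Kinetic fold-change features and probe selectivity summaries.

The phenotype feature is the kinetic fold change
``fold = mean foreground intensity at the endpoint (48 h) /
         mean foreground intensity at baseline (1 h)``
per probe x line x concentration x channel.  Because a plate-constant
multiplicative batch factor applied at both time points cancels in the
ratio, the fold is robust to batch-to-batch intensity drift — the reason
kinetic ratios, not absolute intensities, are profiled.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("phenoscreen")

COLLAPSE_POLICIES = ("per_condition", "brightest_channel")


def fold_change(intensity_baseline: float, intensity_end: float,
                baseline_floor: float = 1.0) -> float:
    """Endpoint/baseline intensity ratio, guarded against unstable baselines.

    Raises ``ValueError`` when the baseline sits below ``baseline_floor``
    (callers flag the record instead of producing a wild ratio).
    """
    if intensity_baseline < 0 or intensity_end < 0:
        raise ValueError("intensities must be >= 0")
    if intensity_baseline < baseline_floor:
        raise ValueError(
            f"baseline below floor ({intensity_baseline} < {baseline_floor})")
    return float(intensity_end) / float(intensity_baseline)


@dataclass
class FeatureMatrix:
    """Cell lines x probe-features matrix of kinetic fold changes."""

    values: pd.DataFrame          # index line_id, columns feature ids, > 0
    origins: pd.Series            # line_id -> origin label
    policy: str

    def log2(self) -> pd.DataFrame:
        """log2-transformed folds — the scale used for clustering and LDA."""
        return np.log2(self.values)

    def to_csv(self, path: str | Path, origins_path: str | Path) -> None:
        self.values.rename_axis("line_id").to_csv(path)
        self.origins.rename_axis("line_id").rename("origin").to_csv(origins_path)

    @classmethod
    def from_csv(cls, path: str | Path, origins_path: str | Path,
                 policy: str = "per_condition") -> "FeatureMatrix":
        values = pd.read_csv(path, index_col="line_id")
        origins = pd.read_csv(origins_path, index_col="line_id")["origin"]
        return cls(values, origins.loc[values.index], policy)


def _feature_id(probe: str, conc: float, channel: str) -> str:
    return f"{probe}@{conc:g}nM:{channel}"


def build_feature_matrix(intensity: pd.DataFrame,
                         origins: Mapping[str, str] | pd.Series | None = None,
                         collapse_policy: str = "per_condition",
                         baseline_floor: float = 1.0,
                         baseline_h: float | None = None,
                         endpoint_h: float | None = None) -> FeatureMatrix:
    """Pivot an intensity table into a lines x features fold-change matrix.

    Policies
    --------
    ``per_condition``
        one feature per (probe, concentration, channel) — lossless.
    ``brightest_channel``
        one feature per probe: at the highest concentration, the channel
        with the larger mean baseline intensity across lines.

    Features containing any flagged, missing, or below-floor cell are
    dropped (and counted in the log); a line absent from the table entirely
    is an error.
    """
    if collapse_policy not in COLLAPSE_POLICIES:
        raise ValueError(f"unknown collapse policy {collapse_policy!r}")
    tab = intensity.copy()
    times = sorted(tab["time_h"].unique())
    if len(times) < 2:
        raise ValueError("need both baseline and endpoint time points")
    t0 = baseline_h if baseline_h is not None else times[0]
    t1 = endpoint_h if endpoint_h is not None else times[-1]

    if origins is None:
        if "origin" not in tab.columns:
            raise ValueError("no origin labels: pass `origins` or include an "
                             "'origin' column")
        origins = tab.drop_duplicates("line_id").set_index("line_id")["origin"]
    origins = pd.Series(dict(origins) if not isinstance(origins, pd.Series)
                        else origins)
    lines = sorted(origins.index)
    missing_lines = set(lines) - set(tab["line_id"])
    if missing_lines:
        raise ValueError(f"lines absent from intensity table: "
                         f"{sorted(missing_lines)}")

    if collapse_policy == "brightest_channel":
        top_conc = tab["concentration_nM"].max()
        base = tab[(tab["time_h"] == t0) & (tab["concentration_nM"] == top_conc)
                   & (tab["flag"] == "ok")]
        chan_mean = base.groupby(["probe_id", "channel"])["mean_fg"].mean()
        keep = []
        for probe, sub in chan_mean.groupby(level="probe_id"):
            best = sub.idxmax()               # (probe, channel), ties -> first
            keep.append((probe, top_conc, best[1], probe))
    else:
        combos = tab[["probe_id", "concentration_nM", "channel"]].drop_duplicates()
        keep = [(p, c, ch, _feature_id(p, c, ch))
                for p, c, ch in combos.itertuples(index=False)]

    by_key = {(r.probe_id, r.concentration_nM, r.channel, r.time_h, r.line_id): r
              for r in tab.itertuples()}
    columns: dict[str, pd.Series] = {}
    n_dropped = 0
    for probe, conc, channel, fid in keep:
        col = {}
        ok = True
        for line in lines:
            r0 = by_key.get((probe, conc, channel, t0, line))
            r1 = by_key.get((probe, conc, channel, t1, line))
            if (r0 is None or r1 is None or r0.flag != "ok" or r1.flag != "ok"):
                ok = False
                break
            try:
                col[line] = fold_change(r0.mean_fg, r1.mean_fg, baseline_floor)
            except ValueError:
                ok = False
                break
        if ok:
            columns[fid] = pd.Series(col)
        else:
            n_dropped += 1
    if n_dropped:
        logger.info("dropped %d features with flagged/missing cells", n_dropped)
    if not columns:
        raise ValueError("no complete features left after the missing-data rule")
    values = pd.DataFrame(columns).loc[lines]
    return FeatureMatrix(values, origins.loc[lines], collapse_policy)


def selectivity_index(values) -> np.ndarray:
    """Per-line selectivity: each line's value over the mean of all others.

    A probe that turns on in exactly one line with fold ``f`` against a
    neutral background scores ~``f`` for that line and < 1 elsewhere.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need a 1-D column over >= 2 lines")
    if np.any(x <= 0):
        raise ValueError("selectivity requires strictly positive values")
    total = x.sum()
    loo_mean = (total - x) / (x.size - 1)
    return x / loo_mean


def feature_families(feature_ids, probe_families: Mapping[str, str]) -> pd.Series:
    """Map feature ids back to their probe's scaffold family."""
    fams = {}
    for fid in feature_ids:
        probe = fid.split("@")[0]
        if probe not in probe_families:
            raise ValueError(f"family label missing for probe {probe!r}")
        fams[fid] = probe_families[probe]
    return pd.Series(fams)
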