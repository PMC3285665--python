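"""Synthetic plate-screen generator.

Emulates a diversity-oriented fluorescence library (DOFL) screen against the
NCI-60 cancer cell-line panel: two fluorophore scaffold families (rosamine
"RS", 240 members; BODIPY "BD", 317 members) applied to 60 cell lines from
9 tissues of origin, imaged at two concentrations, two channels, two sites
per well, three time points and two replicates.  The generator produces
16-bit grayscale TIFF images with a known ground-truth effect structure so
the downstream quantification, feature-extraction and classification stages
can be validated end to end without any external data.

The intensity model is multiplicative: a per-(probe, line) baseline mean at
the first time point, a fluorescence turn-on fold effect reached at the last
time point (geometric interpolation in between), an optional plate-level
batch factor, and lognormal per-pixel noise.  Cells are rendered as random
ellipse blobs over a dim background; only intensity statistics are meant to
be realistic, not morphology.
"""
from __future__ import annotations

import itertools
import logging
import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger("phenoscreen")

# ---------------------------------------------------------------------------
# panel / library definitions
# ---------------------------------------------------------------------------

#: The NCI-60 panel: 9 tissues of origin, 60 lines, one 2-member class
#: (prostate).  Identifiers are filename-safe variants of the usual names.
NCI60_PANEL: dict[str, tuple[str, ...]] = {
    "leukemia": ("CCRF-CEM", "HL-60", "K-562", "MOLT-4", "RPMI-8226", "SR"),
    "lung": ("A549", "EKVX", "HOP-62", "HOP-92", "NCI-H226", "NCI-H23",
             "NCI-H322M", "NCI-H460", "NCI-H522"),
    "colon": ("COLO205", "HCC-2998", "HCT-116", "HCT-15", "HT29", "KM12",
              "SW-620"),
    "cns": ("SF-268", "SF-295", "SF-539", "SNB-19", "SNB-75", "U251"),
    "melanoma": ("LOXIMVI", "MALME-3M", "M14", "MDA-MB-435", "SK-MEL-2",
                 "SK-MEL-28", "SK-MEL-5", "UACC-257", "UACC-62"),
    "ovarian": ("IGROV1", "OVCAR-3", "OVCAR-4", "OVCAR-5", "OVCAR-8",
                "NCI-ADR-RES", "SK-OV-3"),
    "renal": ("786-0", "A498", "ACHN", "CAKI-1", "RXF393", "SN12C", "TK-10",
              "UO-31"),
    "prostate": ("PC-3", "DU-145"),
    "breast": ("MCF7", "MDA-MB-231", "HS578T", "BT-549", "T-47D",
               "MDA-MB-468"),
}

ORIGINS: tuple[str, ...] = tuple(NCI60_PANEL)

#: Family sizes of the two-scaffold probe library (RS + BD = 557).
FAMILY_SIZES: dict[str, int] = {"RS": 240, "BD": 317}

_SERIES_TAGS = "ABCDEFGHK"


@dataclass(frozen=True)
class Probe:
    probe_id: str
    family: str            # "RS" | "BD"
    series: str = ""       # sub-scaffold tag; may equal probe_id for singletons


@dataclass(frozen=True)
class CellLine:
    line_id: str
    origin: str


class Condition(NamedTuple):
    """One cell of the factorial screen design (one image to acquire)."""

    probe_id: str
    family: str
    series: str
    line_id: str
    origin: str
    concentration_nM: float
    channel: str
    site: int
    time_h: float
    replicate: int


def nci60_lines(n: int = 60) -> list[CellLine]:
    """First ``n`` panel lines, drawn round-robin across origins so every
    origin is represented as early as possible."""
    pools = {o: list(v) for o, v in NCI60_PANEL.items()}
    out: list[CellLine] = []
    while len(out) < n:
        added = False
        for origin in ORIGINS:
            if pools[origin]:
                out.append(CellLine(pools[origin].pop(0), origin))
                added = True
                if len(out) == n:
                    break
        if not added:
            raise ValueError(f"panel has only 60 lines, requested {n}")
    return out


def probe_library(n_rs: int = 240, n_bd: int = 317) -> list[Probe]:
    """Two-family probe library with cyclic sub-series tags."""
    probes = []
    for fam, count in (("RS", n_rs), ("BD", n_bd)):
        for i in range(count):
            tag = f"{fam}-{_SERIES_TAGS[i % len(_SERIES_TAGS)]}"
            probes.append(Probe(f"{fam}-{i + 1}", fam, tag))
    return probes


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------

@dataclass
class ScreenDesign:
    """Factorial layout of the screen.

    ``time_points_h`` must be strictly increasing; its first and last entries
    are the baseline and endpoint hours used for the kinetic fold change.
    """

    probes: Sequence[Probe]
    cell_lines: Sequence[CellLine]
    concentrations_nM: Sequence[float]
    channels: Sequence[str]
    sites: int
    time_points_h: Sequence[float]
    replicates: int
    image_shape: tuple[int, int] = (128, 128)
    bit_depth: int = 16

    def validate(self) -> None:
        if (not self.probes or not self.cell_lines or not self.concentrations_nM
                or not self.channels or not self.time_points_h):
            raise ValueError("degenerate design: empty factor list")
        if self.sites < 1 or self.replicates < 1:
            raise ValueError("degenerate design: counts must be >= 1")
        t = list(self.time_points_h)
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("time_points_h must be strictly increasing")
        pids = [p.probe_id for p in self.probes]
        lids = [c.line_id for c in self.cell_lines]
        if len(set(pids)) != len(pids):
            raise ValueError("probe_ids must be unique")
        if len(set(lids)) != len(lids):
            raise ValueError("line_ids must be unique")
        if any(d <= 0 for d in self.image_shape) or self.bit_depth < 1:
            raise ValueError("invalid image geometry")

    @property
    def n_records(self) -> int:
        return (len(self.probes) * len(self.cell_lines)
                * len(self.concentrations_nM) * len(self.channels)
                * self.sites * len(self.time_points_h) * self.replicates)

    @property
    def time_span(self) -> tuple[float, float]:
        return float(self.time_points_h[0]), float(self.time_points_h[-1])


def paper_design() -> ScreenDesign:
    """The full published layout: 557 probes x 60 lines x 2 concentrations x
    2 channels x 2 sites x 3 time points x 2 replicates = 1,604,160 images."""
    return ScreenDesign(
        probes=probe_library(),
        cell_lines=nci60_lines(60),
        concentrations_nM=[250.0, 500.0],
        channels=["FITC", "TRITC"],
        sites=2,
        time_points_h=[1.0, 24.0, 48.0],
        replicates=2,
    )


def enumerate_design(design: ScreenDesign) -> list[Condition]:
    """One :class:`Condition` per factorial cell, replicate innermost.

    The record count equals the product of factor cardinalities.
    """
    design.validate()
    return [
        Condition(p.probe_id, p.family, p.series, c.line_id, c.origin,
                  float(conc), ch, s, float(t), r)
        for p, c, conc, ch, s, t, r in itertools.product(
            design.probes, design.cell_lines, design.concentrations_nM,
            design.channels, range(1, design.sites + 1),
            design.time_points_h, range(1, design.replicates + 1))
    ]


# ---------------------------------------------------------------------------
# effect model
# ---------------------------------------------------------------------------

@dataclass
class EffectModel:
    """Ground-truth intensity model.

    Expected fold for (probe, line) is the product of the turn-on effect for
    the probe's series (falling back to its family) at the line's origin, and
    any line-specific effect; neutral effects are 1.0.  ``batch_sd`` is the
    log-scale sd of a multiplicative plate factor; with ``batch_aligned``
    (default) the factor is constant across time points of a plate so the
    kinetic fold change cancels it, otherwise it is redrawn per time point.
    """

    baseline_log_mean: float = math.log(2000.0)
    baseline_log_sd: float = 0.2
    turnon_effects: dict[tuple[str, str], float] = field(default_factory=dict)
    line_specific_effects: dict[tuple[str, str], float] = field(default_factory=dict)
    batch_sd: float = 0.0
    batch_aligned: bool = True
    pixel_noise_sigma: float = 0.0
    background_level: float = 150.0
    background_noise_sd: float = 0.0
    area_fraction: float = 0.7
    channel_gain: dict[str, float] = field(default_factory=dict)
    concentration_gain: dict[float, float] = field(default_factory=dict)

    def validate(self) -> None:
        if not 0.0 < self.area_fraction < 1.0:
            raise ValueError("area_fraction must lie in (0, 1)")
        for eff in itertools.chain(self.turnon_effects.values(),
                                   self.line_specific_effects.values()):
            if eff <= 0:
                raise ValueError("multiplicative effects must be > 0")
        if self.batch_sd < 0 or self.pixel_noise_sigma < 0:
            raise ValueError("noise scales must be >= 0")

    def expected_fold(self, probe: Probe | Condition, line_id: str | None = None,
                      origin: str | None = None) -> float:
        """Ground-truth endpoint/baseline fold for a (probe, line) pair."""
        if isinstance(probe, Condition):
            series, family = probe.series, probe.family
            line_id, origin = probe.line_id, probe.origin
            pid = probe.probe_id
        else:
            series, family, pid = probe.series, probe.family, probe.probe_id
        turnon = self.turnon_effects.get(
            (series, origin), self.turnon_effects.get((family, origin), 1.0))
        return turnon * self.line_specific_effects.get((pid, line_id), 1.0)

    def baseline_mean(self, probe_id: str, line_id: str, seed: int) -> float:
        """Deterministic per-(probe, line) baseline foreground mean (1 h)."""
        if self.baseline_log_sd == 0:
            return math.exp(self.baseline_log_mean)
        rng = _stream(seed, "baseline", probe_id, line_id)
        return math.exp(self.baseline_log_mean
                        + self.baseline_log_sd * rng.standard_normal())


def _stream(seed: int, *key) -> np.random.Generator:
    """Deterministic RNG keyed by (seed, semantic key) — independent of call
    order, so any condition can be re-rendered in isolation."""
    h = zlib.crc32("|".join(map(str, key)).encode())
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, h]))


def plate_id(cond: Condition) -> str:
    """Plate grouping: one physical plate per (probe, concentration).

    Duplicate wells and both imaging sites share the plate, so every image
    pooled into one quantification shares one batch factor — the layout
    under which aligned batches cancel exactly in the kinetic fold change.
    """
    return f"{cond.probe_id}_{cond.concentration_nM:g}nM"


def well_id(design: ScreenDesign, cond: Condition) -> str:
    """384-well position for a line; the first and last two columns of the
    plate are left unused (edge wells suffer evaporation artifacts)."""
    idx = next(i for i, c in enumerate(design.cell_lines)
               if c.line_id == cond.line_id)
    row, col = divmod(idx, 20)          # usable columns 3..22
    return f"{chr(ord('A') + row)}{col + 3:02d}"


def batch_factor(cond: Condition, model: EffectModel, seed: int) -> float:
    if model.batch_sd == 0:
        return 1.0
    key = ("batch", plate_id(cond))
    if not model.batch_aligned:
        key = key + (cond.time_h,)
    rng = _stream(seed, *key)
    return math.exp(model.batch_sd * rng.standard_normal())


# ---------------------------------------------------------------------------
# image rendering
# ---------------------------------------------------------------------------

@dataclass
class ImageRecord:
    """One grayscale image plus its condition metadata."""

    pixels: np.ndarray
    bit_depth: int
    condition: Condition

    def validate(self) -> None:
        if self.pixels.size == 0 or self.pixels.ndim != 2:
            raise ValueError("pixels must be a non-empty 2-D array")
        if self.pixels.min() < 0 or self.pixels.max() > 2 ** self.bit_depth - 1:
            raise ValueError("pixel values outside bit-depth range")


def _blob_mask(shape: tuple[int, int], area_fraction: float,
               rng: np.random.Generator) -> np.ndarray:
    """Union of random ellipses until the target area fraction is covered."""
    if not 0.0 < area_fraction < 1.0:
        raise ValueError("area_fraction must lie in (0, 1)")
    h, w = shape
    yy = np.arange(h, dtype=np.float64)[:, None]
    xx = np.arange(w, dtype=np.float64)[None, :]
    mask = np.zeros(shape, dtype=bool)
    target = area_fraction * mask.size
    for _ in range(10_000):
        if mask.sum() >= target:
            break
        r = rng.uniform(0.06, 0.14) * min(h, w)
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        a, b = r * rng.uniform(0.7, 1.3), r * rng.uniform(0.7, 1.3)
        mask |= ((yy - cy) / a) ** 2 + ((xx - cx) / b) ** 2 <= 1.0
    return mask


def foreground_mean_at(cond: Condition, model: EffectModel, seed: int,
                       time_span: tuple[float, float]) -> float:
    """Noise-free expected foreground mean at the condition's time point."""
    base = model.baseline_mean(cond.probe_id, cond.line_id, seed)
    base *= model.channel_gain.get(cond.channel, 1.0)
    base *= model.concentration_gain.get(cond.concentration_nM, 1.0)
    t0, t1 = time_span
    frac = 0.0 if t1 == t0 else (cond.time_h - t0) / (t1 - t0)
    return base * model.expected_fold(cond) ** frac


def render_image(cond: Condition, model: EffectModel, seed: int, *,
                 image_shape: tuple[int, int] = (128, 128),
                 bit_depth: int = 16,
                 time_span: tuple[float, float] = (1.0, 48.0)) -> ImageRecord:
    """Render one synthetic field of view, deterministic given ``seed``."""
    model.validate()
    rng = _stream(seed, "image", *cond)
    mask = _blob_mask(image_shape, model.area_fraction, rng)
    mean_fg = foreground_mean_at(cond, model, seed, time_span)

    img = np.full(image_shape, float(model.background_level))
    if model.background_noise_sd > 0:
        img += model.background_noise_sd * rng.standard_normal(image_shape)
    if model.pixel_noise_sigma > 0:
        s = model.pixel_noise_sigma
        # mean-corrected lognormal: E[pixel] equals the model mean
        fg = mean_fg * np.exp(s * rng.standard_normal(int(mask.sum())) - s * s / 2)
    else:
        fg = mean_fg
    img[mask] = fg
    img *= batch_factor(cond, model, seed)

    top = 2 ** bit_depth - 1
    np.clip(np.rint(img), 0, top, out=img)
    dtype = np.uint16 if bit_depth > 8 else np.uint8
    rec = ImageRecord(img.astype(dtype), bit_depth, cond)
    rec.validate()
    return rec


# ---------------------------------------------------------------------------
# screen generation
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = ["probe_id", "family", "line_id", "origin",
                    "concentration_nM", "channel", "site", "time_h",
                    "replicate", "plate", "well", "path"]


@dataclass
class ScreenOutputs:
    root: Path
    manifest: pd.DataFrame
    ground_truth: pd.DataFrame
    origins: pd.DataFrame
    probes: pd.DataFrame


def ground_truth_table(design: ScreenDesign, model: EffectModel) -> pd.DataFrame:
    """True expected endpoint/baseline fold per (probe, line, conc, channel)."""
    rows = []
    for p in design.probes:
        for c in design.cell_lines:
            fold = model.expected_fold(p, c.line_id, c.origin)
            for conc in design.concentrations_nM:
                for ch in design.channels:
                    rows.append((p.probe_id, c.line_id, float(conc), ch, fold))
    return pd.DataFrame(rows, columns=["probe_id", "line_id",
                                       "concentration_nM", "channel",
                                       "expected_fold"])


def _probe_info(design: ScreenDesign, model: EffectModel) -> pd.DataFrame:
    line_origin = {c.line_id: c.origin for c in design.cell_lines}
    rows = []
    for p in design.probes:
        origins = {o for (key, o), eff in model.turnon_effects.items()
                   if key in (p.series, p.family) and eff != 1.0}
        origins |= {line_origin[l] for (pid, l), eff
                    in model.line_specific_effects.items()
                    if pid == p.probe_id and eff != 1.0 and l in line_origin}
        rows.append((p.probe_id, p.family, p.series,
                     ";".join(sorted(origins))))
    return pd.DataFrame(rows, columns=["probe_id", "family", "series",
                                       "informative_origins"])


def image_filename(cond: Condition) -> str:
    return (f"{cond.probe_id}_{cond.line_id}_{cond.concentration_nM:g}_"
            f"{cond.channel}_{cond.site}_{cond.time_h:g}_{cond.replicate}.tif")


def generate_screen(design: ScreenDesign, model: EffectModel, seed: int,
                    outdir: str | Path) -> ScreenOutputs:
    """Write one TIFF per condition plus manifest and ground-truth tables.

    Re-running with the same (design, model, seed) reproduces identical files.
    """
    design.validate()
    model.validate()
    root = Path(outdir)
    imgdir = root / "images"
    imgdir.mkdir(parents=True, exist_ok=True)

    records = enumerate_design(design)
    rows = []
    for cond in records:
        fname = image_filename(cond)
        rec = render_image(cond, model, seed, image_shape=design.image_shape,
                           bit_depth=design.bit_depth,
                           time_span=design.time_span)
        try:
            tifffile.imwrite(imgdir / fname, rec.pixels)
        except OSError as exc:                     # pragma: no cover
            raise OSError(f"failed writing image for condition {cond}: {exc}")
        rows.append((cond.probe_id, cond.family, cond.line_id, cond.origin,
                     cond.concentration_nM, cond.channel, cond.site,
                     cond.time_h, cond.replicate, plate_id(cond),
                     well_id(design, cond), str(Path("images") / fname)))

    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    gt = ground_truth_table(design, model)
    origins = pd.DataFrame(
        [(c.line_id, c.origin) for c in design.cell_lines],
        columns=["line_id", "origin"])
    probes = _probe_info(design, model)

    manifest.to_csv(root / "manifest.csv", index=False)
    gt.to_csv(root / "ground_truth.csv", index=False)
    origins.to_csv(root / "origins.csv", index=False)
    probes.to_csv(root / "probes.csv", index=False)
    logger.info("generated screen: %d images under %s", len(manifest), root)
    return ScreenOutputs(root, manifest, gt, origins, probes)


# ---------------------------------------------------------------------------
# ready-made recipes
# ---------------------------------------------------------------------------

def demo_recipe(seed: int = 7, *, n_probes: int = 100, n_lines: int = 60,
                n_informative: int = 30,
                primary_fold: tuple[float, float] = (2.0, 4.0),
                secondary_fold: tuple[float, float] = (1.5, 2.5),
                line_scatter_sd: float = 0.12,
                pixel_noise_sigma: float = 0.15,
                batch_sd: float = 0.10, batch_aligned: bool = True,
                concentrations: Sequence[float] = (500.0,),
                channels: Sequence[str] = ("TRITC",),
                sites: int = 1, replicates: int = 2,
                time_points_h: Sequence[float] = (1.0, 48.0),
                image_shape: tuple[int, int] = (128, 128),
                ) -> tuple[ScreenDesign, EffectModel]:
    """Desk-scale screen with known class structure.

    Probes split between the two families in the library's 240:317 ratio.
    Informative probes are divided evenly between families; RS informative
    probes target the first six origins, BD informative probes the last six,
    so the two families carry complementary origin signals and every origin
    is covered by both at the overlap.  Each informative probe turns on for
    a primary origin (fold drawn from ``primary_fold``) and one secondary
    origin (``secondary_fold``).  Every (probe, line) pair also carries
    lognormal line-to-line scatter of log-sd ``line_scatter_sd`` (~12% CV by
    default), recorded in the ground truth as a line-specific effect.
    """
    rng = _stream(seed, "recipe")
    n_rs = int(round(n_probes * FAMILY_SIZES["RS"] / sum(FAMILY_SIZES.values())))
    probes: list[Probe] = []
    for fam, count in (("RS", n_rs), ("BD", n_probes - n_rs)):
        for i in range(count):
            pid = f"{fam}-{i + 1}"
            probes.append(Probe(pid, fam, pid))   # one series per probe
    lines = nci60_lines(n_lines)

    n_inf_rs = n_informative // 2
    rs_targets = ORIGINS[:6]
    bd_targets = ORIGINS[3:]
    turnon: dict[tuple[str, str], float] = {}
    informative = (list(probes[:n_inf_rs])
                   + list(probes[n_rs:n_rs + (n_informative - n_inf_rs)]))
    for k, p in enumerate(informative):
        targets = rs_targets if p.family == "RS" else bd_targets
        primary = targets[k % len(targets)]
        turnon[(p.series, primary)] = float(rng.uniform(*primary_fold))
        others = [o for o in targets if o != primary]
        secondary = others[int(rng.integers(len(others)))]
        turnon[(p.series, secondary)] = float(rng.uniform(*secondary_fold))

    line_eff: dict[tuple[str, str], float] = {}
    if line_scatter_sd > 0:
        for p in probes:
            for c in lines:
                line_eff[(p.probe_id, c.line_id)] = float(
                    math.exp(line_scatter_sd * rng.standard_normal()))

    design = ScreenDesign(probes, lines, list(concentrations), list(channels),
                          sites, list(time_points_h), replicates,
                          image_shape=image_shape)
    model = EffectModel(turnon_effects=turnon, line_specific_effects=line_eff,
                        batch_sd=batch_sd, batch_aligned=batch_aligned,
                        pixel_noise_sigma=pixel_noise_sigma,
                        background_noise_sd=15.0)
    return design, model


def spikein_recipe(seed: int = 11, *, n_probes: int = 20, n_lines: int = 60,
                   spike_probe: str = "RS-3", spike_line: str = "KM12",
                   spike_fold: float = 5.64,
                   pixel_noise_sigma: float = 0.10,
                   background_scatter_sd: float = 0.05,
                   image_shape: tuple[int, int] = (128, 128),
                   ) -> tuple[ScreenDesign, EffectModel]:
    """One probe given a single-line turn-on effect, all else near neutral.

    The canonical spike-in magnitude is the 5.64-fold single-line turn-on
    (the RS-C3 / KM12 signature); all other probes get only mild line
    scatter so the spiked probe should rank first by maximum selectivity.
    """
    rng = _stream(seed, "spikein")
    probes = [Probe(f"RS-{i + 1}", "RS", f"RS-{i + 1}") for i in range(n_probes)]
    lines = nci60_lines(n_lines)
    if spike_line not in {c.line_id for c in lines}:
        raise ValueError(f"spike line {spike_line!r} not in the panel subset")
    line_eff: dict[tuple[str, str], float] = {
        (spike_probe, spike_line): spike_fold}
    if background_scatter_sd > 0:
        for p in probes:
            for c in lines:
                if (p.probe_id, c.line_id) in line_eff:
                    continue
                line_eff[(p.probe_id, c.line_id)] = float(
                    math.exp(background_scatter_sd * rng.standard_normal()))
    design = ScreenDesign(probes, lines, [500.0], ["TRITC"], 1,
                          [1.0, 48.0], 2, image_shape=image_shape)
    model = EffectModel(line_specific_effects=line_eff,
                        pixel_noise_sigma=pixel_noise_sigma,
                        background_noise_sd=15.0)
    return design, model
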