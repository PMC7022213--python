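"""Synthetic multiplexed fluorescence scenes with known ground truth.

Generates 2D multichannel images that statistically emulate confocal
RNAscope fields of the nucleus accumbens: elliptical DAPI-stained nuclei on
a noisy, unevenly illuminated background, a designated endothelial subset
carrying CD31 puncta, and per-cell target-transcript puncta whose counts
follow a group-dependent Poisson law.  Every scene comes with a full truth
table (nucleus geometry, region label, endothelial flag, punctum centers and
owners), so detection and quantification can be scored against ground truth.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

CHANNELS = ("DAPI", "CD31", "TARGET1", "TARGET2")
GROUPS = ("CTRL", "SS", "RES")

U16_MAX = 65535


class SceneCrowdingError(RuntimeError):
    """Rejection sampling could not place all objects without overlap."""


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of one synthetic scene.

    Defaults describe the study conditions emulated throughout: a 512x512
    field (~63x confocal view) holding 30 well-separated nuclei, 30% of them
    endothelial, with Poisson-distributed puncta per cell and an uneven
    background that makes local (rather than global) thresholding necessary.
    """

    image_height: int = 512
    image_width: int = 512
    n_nuclei: int = 30
    nucleus_axis_range: tuple[float, float] = (20.0, 27.0)  # semi-axes, px
    nucleus_max_ecc: float = 0.8
    nucleus_amplitude: float = 500.0  # DAPI fill above background
    endothelial_fraction: float = 0.3
    group_label: str = "CTRL"
    # Poisson mean puncta per cell; CD31 applies to endothelial cells only.
    puncta_mean_per_cell: dict[str, float] = field(
        default_factory=lambda: {"CD31": 5.0, "TARGET1": 4.0}
    )
    punctum_sigma: float = 1.6  # Gaussian blob SD, px
    punctum_amplitude: float = 300.0  # peak above background
    punctum_min_separation: float = 12.0  # px, per channel (resolvable clusters)
    cd31_dilation: float = 2.0  # px added to nucleus semi-axes for CD31 centers
    background_level: float = 200.0
    background_gradient_amplitude: float = 60.0
    noise_sd: float = 20.0
    region_split: float = 0.5  # fraction of width labeled "shell"
    seed: int = 0
    max_place_attempts: int = 2000  # per object, rejection-sampling budget

    def validate(self) -> None:
        if self.image_height <= 0 or self.image_width <= 0:
            raise ValueError("image dimensions must be positive")
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be nonnegative")
        lo, hi = self.nucleus_axis_range
        if not (0 < lo <= hi):
            raise ValueError("nucleus_axis_range must satisfy 0 < min <= max")
        if not 0 <= self.nucleus_max_ecc < 1:
            raise ValueError("nucleus_max_ecc must be in [0, 1)")
        if not 0 <= self.endothelial_fraction <= 1:
            raise ValueError("endothelial_fraction must be in [0, 1]")
        if self.group_label not in GROUPS:
            raise ValueError(f"group_label must be one of {GROUPS}")
        for ch, mu in self.puncta_mean_per_cell.items():
            if ch not in CHANNELS or ch == "DAPI":
                raise ValueError(f"unknown puncta channel {ch!r}")
            if mu < 0:
                raise ValueError("puncta means must be nonnegative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not 0 <= self.region_split <= 1:
            raise ValueError("region_split must be in [0, 1]")


@dataclass(frozen=True)
class Nucleus:
    cell_id: int
    cx: float  # column
    cy: float  # row
    a: float  # major semi-axis, px
    b: float  # minor semi-axis, px
    theta: float  # orientation, radians
    ecc: float
    region: str  # shell | core
    is_endothelial: bool


@dataclass(frozen=True)
class Punctum:
    channel: str
    x: float  # column
    y: float  # row
    cell_id: int | None


@dataclass
class SceneTruth:
    nuclei: list[Nucleus]
    puncta: list[Punctum]

    def nuclei_frame(self) -> pd.DataFrame:
        cols = ["cell_id", "cx", "cy", "a", "b", "theta", "ecc", "region",
                "is_endothelial"]
        rows = [dataclasses.asdict(n) for n in self.nuclei]
        df = pd.DataFrame(rows, columns=cols)
        df["cell_id"] = df["cell_id"].astype(int)
        df["is_endothelial"] = df["is_endothelial"].astype(bool)
        return df

    def puncta_frame(self) -> pd.DataFrame:
        cols = ["channel", "x", "y", "cell_id"]
        rows = [dataclasses.asdict(p) for p in self.puncta]
        df = pd.DataFrame(rows, columns=cols)
        df["cell_id"] = df["cell_id"].astype("Int64")
        return df

    def counts_by_cell(self, channel: str) -> dict[int, int]:
        counts = {n.cell_id: 0 for n in self.nuclei}
        for p in self.puncta:
            if p.channel == channel and p.cell_id is not None:
                counts[p.cell_id] += 1
        return counts


@dataclass
class ChannelImage:
    """A single-channel 2D intensity raster."""

    pixels: np.ndarray
    channel: str
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("ChannelImage requires a 2D raster")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("ChannelImage intensities must be finite")
        if np.any(self.pixels < 0):
            raise ValueError("ChannelImage intensities must be nonnegative")


def _ellipse_mask(shape: tuple[int, int], cx: float, cy: float, a: float,
                  b: float, theta: float) -> tuple[np.ndarray, np.ndarray]:
    """Pixel (row, col) indices inside the rotated ellipse."""
    h, w = shape
    r0 = max(int(math.floor(cy - a)) - 1, 0)
    r1 = min(int(math.ceil(cy + a)) + 2, h)
    c0 = max(int(math.floor(cx - a)) - 1, 0)
    c1 = min(int(math.ceil(cx + a)) + 2, w)
    if r0 >= r1 or c0 >= c1:
        return np.empty(0, int), np.empty(0, int)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    dx = cc - cx
    dy = rr - cy
    ct, st = math.cos(theta), math.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return rr[inside], cc[inside]


def _sample_in_ellipse(rng: np.random.Generator, cx: float, cy: float,
                       a: float, b: float, theta: float) -> tuple[float, float]:
    r = math.sqrt(rng.uniform())
    phi = rng.uniform(0.0, 2.0 * math.pi)
    u = r * math.cos(phi) * a
    v = r * math.sin(phi) * b
    ct, st = math.cos(theta), math.sin(theta)
    return cx + u * ct - v * st, cy + u * st + v * ct


def _place_nuclei(cfg: SceneConfig, rng: np.random.Generator) -> list[Nucleus]:
    lo, hi = cfg.nucleus_axis_range
    h, w = cfg.image_height, cfg.image_width
    split_col = cfg.region_split * w
    placed: list[tuple[float, float, float]] = []  # (cx, cy, a)
    nuclei: list[Nucleus] = []
    for cid in range(1, cfg.n_nuclei + 1):
        ok = False
        for _ in range(cfg.max_place_attempts):
            a = rng.uniform(lo, hi)
            b_min = max(lo, a * math.sqrt(1.0 - cfg.nucleus_max_ecc ** 2))
            b = rng.uniform(min(b_min, a), a)
            theta = rng.uniform(0.0, math.pi)
            margin = a + 1.0
            if 2 * margin >= min(h, w):
                raise SceneCrowdingError(
                    "nucleus axes exceed the field; enlarge the image or "
                    "shrink nucleus_axis_range")
            cx = rng.uniform(margin, w - margin)
            cy = rng.uniform(margin, h - margin)
            # conservative disjointness: bounding circles must not touch
            if all((cx - px) ** 2 + (cy - py) ** 2 > (a + pa + 2.0) ** 2
                   for px, py, pa in placed):
                ok = True
                break
        if not ok:
            raise SceneCrowdingError(
                f"could not place nucleus {cid}/{cfg.n_nuclei} without overlap "
                f"after {cfg.max_place_attempts} attempts; the scene is too "
                "crowded (reduce n_nuclei or nucleus size, or enlarge the image)")
        ecc = math.sqrt(1.0 - (b / a) ** 2)
        region = "shell" if cx < split_col else "core"
        nuclei.append(Nucleus(cid, cx, cy, a, b, theta, ecc, region, False))
        placed.append((cx, cy, a))
    return nuclei


def _mark_endothelial(nuclei: list[Nucleus], fraction: float,
                      rng: np.random.Generator) -> list[Nucleus]:
    n_endo = int(round(fraction * len(nuclei)))
    if n_endo == 0:
        return nuclei
    ids = rng.choice(len(nuclei), size=n_endo, replace=False)
    chosen = set(int(i) for i in ids)
    return [dataclasses.replace(n, is_endothelial=(i in chosen))
            for i, n in enumerate(nuclei)]


def _sample_puncta(cfg: SceneConfig, nuclei: list[Nucleus],
                   rng: np.random.Generator) -> list[Punctum]:
    """Poisson counts per cell, centers placed with a minimum pairwise
    separation per channel so each planted cluster is individually
    resolvable (clusters closer than the detection scale would merge into a
    single object and have no well-defined ground-truth count)."""
    puncta: list[Punctum] = []
    min_sep2 = cfg.punctum_min_separation ** 2
    for channel in sorted(cfg.puncta_mean_per_cell):
        mu = cfg.puncta_mean_per_cell[channel]
        taken: list[tuple[float, float]] = []
        for nuc in nuclei:
            if channel == "CD31" and not nuc.is_endothelial:
                continue
            count = int(rng.poisson(mu))
            if channel == "CD31":
                aa, bb = nuc.a + cfg.cd31_dilation, nuc.b + cfg.cd31_dilation
            else:
                aa, bb = nuc.a, nuc.b
            for _ in range(count):
                # best-effort separation: keep the Poisson count exact and,
                # if the budget runs out, take the best-separated candidate
                best: tuple[float, float] | None = None
                best_d2 = -1.0
                for _ in range(cfg.max_place_attempts):
                    x, y = _sample_in_ellipse(rng, nuc.cx, nuc.cy, aa, bb,
                                              nuc.theta)
                    d2 = min(((x - tx) ** 2 + (y - ty) ** 2
                              for tx, ty in taken), default=math.inf)
                    if d2 > min_sep2:
                        best = (x, y)
                        break
                    if d2 > best_d2:
                        best_d2 = d2
                        best = (x, y)
                assert best is not None
                taken.append(best)
                puncta.append(Punctum(channel, best[0], best[1],
                                      nuc.cell_id))
    return puncta


def _background(cfg: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    h, w = cfg.image_height, cfg.image_width
    img = np.full((h, w), float(cfg.background_level))
    if cfg.background_gradient_amplitude > 0:
        fy = rng.uniform(0.5, 1.5)
        fx = rng.uniform(0.5, 1.5)
        py = rng.uniform(0.0, 2.0 * math.pi)
        px = rng.uniform(0.0, 2.0 * math.pi)
        yy = np.linspace(0.0, 1.0, h)[:, None]
        xx = np.linspace(0.0, 1.0, w)[None, :]
        img += cfg.background_gradient_amplitude * 0.5 * (
            np.sin(2.0 * math.pi * fy * yy + py)
            + np.sin(2.0 * math.pi * fx * xx + px))
    if cfg.noise_sd > 0:
        img += rng.normal(0.0, cfg.noise_sd, size=(h, w))
    return img


def _render_blob(img: np.ndarray, x: float, y: float, amplitude: float,
                 sigma: float) -> None:
    h, w = img.shape
    rad = int(math.ceil(4.0 * sigma))
    r0 = max(int(round(y)) - rad, 0)
    r1 = min(int(round(y)) + rad + 1, h)
    c0 = max(int(round(x)) - rad, 0)
    c1 = min(int(round(x)) + rad + 1, w)
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc = np.mgrid[r0:r1, c0:c1]
    d2 = (rr - y) ** 2 + (cc - x) ** 2
    img[r0:r1, c0:c1] += amplitude * np.exp(-d2 / (2.0 * sigma ** 2))


def generate_scene(
    cfg: SceneConfig,
) -> tuple[SceneTruth, dict[str, ChannelImage], np.ndarray]:
    """Generate one scene: truth tables, per-channel images, region mask.

    Deterministic: the same config (including seed) yields bit-identical
    outputs.  Images are floating point; quantize with :func:`quantize_u16`
    or write with :func:`write_scene` to obtain the 16-bit rasters that the
    detection stage consumes.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    nuclei = _place_nuclei(cfg, rng)
    nuclei = _mark_endothelial(nuclei, cfg.endothelial_fraction, rng)
    puncta = _sample_puncta(cfg, nuclei, rng)
    truth = SceneTruth(nuclei=nuclei, puncta=puncta)

    channels = ["DAPI"] + sorted(cfg.puncta_mean_per_cell)
    images: dict[str, ChannelImage] = {}
    for channel in channels:
        img = _background(cfg, rng)
        if channel == "DAPI":
            for nuc in nuclei:
                rr, cc = _ellipse_mask(img.shape, nuc.cx, nuc.cy, nuc.a,
                                       nuc.b, nuc.theta)
                img[rr, cc] += cfg.nucleus_amplitude
        else:
            for p in puncta:
                if p.channel == channel:
                    _render_blob(img, p.x, p.y, cfg.punctum_amplitude,
                                 cfg.punctum_sigma)
        np.clip(img, 0.0, None, out=img)
        images[channel] = ChannelImage(pixels=img, channel=channel)

    split_col = int(round(cfg.region_split * cfg.image_width))
    mask = np.full((cfg.image_height, cfg.image_width), 2, dtype=np.uint8)
    mask[:, :split_col] = 1
    return truth, images, mask


def quantize_u16(image: ChannelImage) -> ChannelImage:
    """Round to 16-bit integer range, clipping with a warning on overflow."""
    px = np.rint(image.pixels)
    if px.max(initial=0.0) > U16_MAX:
        warnings.warn(
            f"channel {image.channel}: intensities exceed 16-bit range; "
            "clipping to 65535", stacklevel=2)
        px = np.clip(px, 0, U16_MAX)
    return ChannelImage(pixels=px.astype(np.uint16), channel=image.channel,
                        pixel_size=image.pixel_size)


def write_scene(truth: SceneTruth, images: dict[str, ChannelImage],
                region_mask: np.ndarray, out_dir: str | Path,
                config: SceneConfig | None = None) -> list[Path]:
    """Write one TIFF per channel (16-bit), the labeled region mask, truth
    CSVs, and a JSON config echo.  Returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for channel, img in images.items():
        q = quantize_u16(img) if img.pixels.dtype != np.uint16 else img
        p = out / f"{channel}.tif"
        tifffile.imwrite(p, q.pixels)
        written.append(p)
    p = out / "region_mask.tif"
    tifffile.imwrite(p, np.asarray(region_mask, dtype=np.uint8))
    written.append(p)
    p = out / "nuclei.csv"
    truth.nuclei_frame().to_csv(p, index=False)
    written.append(p)
    p = out / "puncta.csv"
    truth.puncta_frame().to_csv(p, index=False)
    written.append(p)
    p = out / "scene_config.json"
    echo = dataclasses.asdict(config) if config is not None else {}
    echo["channels"] = sorted(images)
    with open(p, "w") as fh:
        json.dump(echo, fh, indent=2, default=str)
    written.append(p)
    return written


def read_scene(
    in_dir: str | Path,
) -> tuple[SceneTruth, dict[str, ChannelImage], np.ndarray]:
    """Read back a scene written by :func:`write_scene`."""
    src = Path(in_dir)
    with open(src / "scene_config.json") as fh:
        echo = json.load(fh)
    images = {}
    for channel in echo["channels"]:
        px = tifffile.imread(src / f"{channel}.tif")
        images[channel] = ChannelImage(pixels=px, channel=channel)
    mask = tifffile.imread(src / "region_mask.tif")
    ndf = pd.read_csv(src / "nuclei.csv")
    nuclei = [Nucleus(int(r.cell_id), float(r.cx), float(r.cy), float(r.a),
                      float(r.b), float(r.theta), float(r.ecc), str(r.region),
                      bool(r.is_endothelial))
              for r in ndf.itertuples()]
    pdf = pd.read_csv(src / "puncta.csv")
    puncta = [Punctum(str(r.channel), float(r.x), float(r.y),
                      None if pd.isna(r.cell_id) else int(r.cell_id))
              for r in pdf.itertuples()]
    return SceneTruth(nuclei=nuclei, puncta=puncta), images, mask
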