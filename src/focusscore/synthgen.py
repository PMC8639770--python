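"""Synthetic Giemsa-like focus-candidate images with known labels.

The Bhas 42 cell transformation assay scores colonies ("foci") growing on a
confluent monolayer.  Experts call a focus *transformed* (positive) when it
meets six morphological criteria: basophilic (dark Giemsa staining), spindle
cell shape, multilayered growth, random cell orientation, invasive borders,
and at least 100 cells.  This module generates labelled micrograph-like
images that encode those criteria as generative parameters, so that the
segmentation, feature-extraction and classifier stages can be tested with
known ground truth.

Positive phenotypes are dark, dense, large clusters of elongated cells in
random orientation with irregular (invasive) borders; negative phenotypes
are lighter, sparser, smoother-edged clusters that additionally violate one
randomly chosen criterion outright (the violation is recorded per sample).
A ``contrast`` dial interpolates the two class distributions toward a common
midpoint: at 1 the classes are maximally separated, at 0 they are identical
and the label carries no image information — useful for null experiments.

Every operation is a pure function of its arguments including the seed.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import gaussian_filter
from skimage.draw import ellipse as draw_ellipse

__all__ = [
    "FocusPhenotype",
    "FocusImage",
    "DatasetManifest",
    "STYLES",
    "sample_phenotype",
    "render_image",
    "render_image_with_mask",
    "generate_dataset",
    "load_manifest",
]

#: Reference canvas edge (pixels) at which cluster_radius is expressed.
REFERENCE_CANVAS = 512

#: Minimum canvas edge accepted by the renderer (network input size).
MIN_CANVAS = 224

CRITERIA = ("cell_count", "stain", "border", "elongation", "density", "orientation")


class UnknownStyleError(ValueError):
    """Raised when a chemical-style tag is not registered."""


@dataclass(frozen=True)
class FocusPhenotype:
    """Generative parameters of one focus candidate.

    Fields mirror the assay's morphological criteria: ``stain_intensity``
    (0-1, basophilic darkness), ``elongation`` (cell aspect ratio, spindle
    when high), ``orientation_dispersion`` (degrees; random orientation when
    high), ``density`` (cell-area coverage per unit cluster area; multilayer
    proxy), ``border_irregularity`` (0-1, invasive edge roughness),
    ``cell_count`` and ``cluster_radius`` (pixels on a 512-px reference
    canvas).  ``violated`` records which criteria this sample fails.
    """

    label: int
    cell_count: int
    elongation: float
    orientation_dispersion: float
    stain_intensity: float
    density: float
    border_irregularity: float
    cluster_radius: float
    style: str = "TPA-like"
    violated: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")
        if not (self.elongation >= 1.0):
            raise ValueError("elongation must be >= 1")
        for name in ("stain_intensity", "border_irregularity"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.cell_count < 1 or self.cluster_radius <= 0 or self.density <= 0:
            raise ValueError("cell_count, cluster_radius, density must be positive")


@dataclass(frozen=True)
class FocusImage:
    """One labelled RGB focus-candidate image (uint8, row-major, origin top-left)."""

    pixels: np.ndarray
    label: int
    chemical: str = "TPA-like"
    source: str = "synthetic"
    id: str = ""

    def __post_init__(self) -> None:
        px = self.pixels
        if px.ndim != 3 or px.shape[2] != 3 or px.dtype != np.uint8:
            raise ValueError("pixels must be an HxWx3 uint8 array")
        if px.shape[0] < MIN_CANVAS or px.shape[1] < MIN_CANVAS:
            raise ValueError(f"image must be at least {MIN_CANVAS}x{MIN_CANVAS}")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")


@dataclass
class DatasetManifest:
    """Tabular index of a labelled image set.

    ``records`` has columns ``id, path, label, chemical, split`` (split may be
    empty until a splitter assigns one).
    """

    records: pd.DataFrame

    COLUMNS = ("id", "path", "label", "chemical", "split")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.records.columns)
        if missing:
            raise ValueError(f"manifest missing columns: {sorted(missing)}")
        bad = set(self.records["label"].unique()) - {0, 1}
        if bad:
            raise ValueError(f"labels must be 0/1, got {sorted(bad)}")

    @property
    def class_counts(self) -> dict[int, int]:
        vc = self.records["label"].value_counts()
        return {0: int(vc.get(0, 0)), 1: int(vc.get(1, 0))}

    def __len__(self) -> int:
        return len(self.records)

    def to_csv(self, path: str | Path) -> None:
        self.records.to_csv(path, index=False)


def load_manifest(path: str | Path) -> DatasetManifest:
    df = pd.read_csv(path, dtype={"id": str, "path": str, "chemical": str}, keep_default_na=False)
    if "split" not in df.columns:
        df["split"] = ""
    df["label"] = df["label"].astype(int)
    return DatasetManifest(df[list(DatasetManifest.COLUMNS)].copy())


# ---------------------------------------------------------------------------
# Style registry

@dataclass(frozen=True)
class StyleParams:
    """Per-chemical-style parameter ranges (lo, hi) for each class.

    ``pos``/``neg`` map phenotype field -> uniform range.  Micro-focus styles
    shrink ``cluster_radius``; intensity distributions may also differ.
    """

    pos: dict[str, tuple[float, float]]
    neg: dict[str, tuple[float, float]]


_TPA_POS = {
    "cell_count": (140, 320),
    "elongation": (2.5, 4.0),
    "orientation_dispersion": (40.0, 90.0),
    "stain_intensity": (0.60, 0.95),
    "density": (1.4, 2.4),
    "border_irregularity": (0.45, 0.85),
    "cluster_radius": (110.0, 170.0),
}
_TPA_NEG = {
    "cell_count": (30, 90),
    "elongation": (1.1, 1.7),
    "orientation_dispersion": (4.0, 20.0),
    "stain_intensity": (0.28, 0.48),
    "density": (0.35, 0.75),
    "border_irregularity": (0.03, 0.25),
    "cluster_radius": (60.0, 110.0),
}

def _scaled(base: dict, **overrides) -> dict:
    d = dict(base)
    d.update(overrides)
    return d


#: Registered chemical styles.  "TPA-like": large clear foci (the typical
#: potent-promoter morphology); "micro-focus": the small dense foci seen with
#: 1-nitropyrene; "LCA-like": mainly large and dark foci.
STYLES: dict[str, StyleParams] = {
    "TPA-like": StyleParams(pos=_TPA_POS, neg=_TPA_NEG),
    "micro-focus": StyleParams(
        pos=_scaled(_TPA_POS, cluster_radius=(55.0, 85.0), cell_count=(100, 170),
                    density=(1.8, 2.8)),
        neg=_scaled(_TPA_NEG, cluster_radius=(35.0, 65.0), cell_count=(20, 60)),
    ),
    "LCA-like": StyleParams(
        pos=_scaled(_TPA_POS, cluster_radius=(130.0, 190.0),
                    stain_intensity=(0.70, 0.98)),
        neg=_TPA_NEG,
    ),
}

#: Negative-class hard violations: the chosen criterion is pushed to an
#: unambiguous failure of the corresponding assay criterion.
_VIOLATION_RANGES = {
    "cell_count": (20, 80),
    "stain": (0.12, 0.32),          # stain_intensity: not basophilic
    "border": (0.0, 0.10),          # border_irregularity: smooth, not invasive
    "elongation": (1.02, 1.35),     # round, not spindle
    "density": (0.25, 0.55),        # monolayer, not multilayered
    "orientation": (1.0, 10.0),     # aligned, not random
}
_VIOLATION_FIELD = {
    "cell_count": "cell_count",
    "stain": "stain_intensity",
    "border": "border_irregularity",
    "elongation": "elongation",
    "density": "density",
    "orientation": "orientation_dispersion",
}


def _mix(lo_hi_class: tuple[float, float], lo_hi_other: tuple[float, float],
         contrast: float) -> tuple[float, float]:
    """Interpolate a class range toward the midpoint of the two class means."""
    mid = 0.5 * (0.5 * (lo_hi_class[0] + lo_hi_class[1])
                 + 0.5 * (lo_hi_other[0] + lo_hi_other[1]))
    lo = mid + contrast * (lo_hi_class[0] - mid)
    hi = mid + contrast * (lo_hi_class[1] - mid)
    return lo, hi


def sample_phenotype(label: int, style: str = "TPA-like", rng_seed: int = 0,
                     contrast: float = 1.0) -> FocusPhenotype:
    """Draw a phenotype from the style's class-conditional distributions.

    Deterministic given ``(label, style, rng_seed, contrast)``.  At the
    default ``contrast=1`` positives satisfy the >=100-cell criterion and
    negatives record at least one violated criterion; lowering ``contrast``
    pulls both class distributions toward their common midpoint.
    """
    if style not in STYLES:
        raise UnknownStyleError(
            f"unknown style {style!r}; registered styles: {sorted(STYLES)}")
    if label not in (0, 1):
        raise ValueError("label must be 0 or 1")
    if not (0.0 <= contrast <= 1.0):
        raise ValueError("contrast must be in [0, 1]")
    sp = STYLES[style]
    own, other = (sp.pos, sp.neg) if label == 1 else (sp.neg, sp.pos)
    rng = np.random.default_rng(np.random.SeedSequence([int(rng_seed), label, _style_key(style)]))
    draw = {}
    for name in ("cell_count", "elongation", "orientation_dispersion",
                 "stain_intensity", "density", "border_irregularity",
                 "cluster_radius"):
        lo, hi = _mix(own[name], other[name], contrast)
        draw[name] = rng.uniform(lo, hi)

    violated: list[str] = []
    if label == 0:
        # one criterion is pushed to a hard violation (recorded); the push is
        # scaled by contrast so the dial stays continuous down to zero.
        crit = CRITERIA[int(rng.integers(len(CRITERIA)))]
        lo, hi = _VIOLATION_RANGES[crit]
        fieldname = _VIOLATION_FIELD[crit]
        hard = rng.uniform(lo, hi)
        draw[fieldname] = (1 - contrast) * draw[fieldname] + contrast * hard
    else:
        # positives always meet the 100-cell criterion
        draw["cell_count"] = max(100.0, draw["cell_count"])

    draw["cell_count"] = int(round(draw["cell_count"]))
    draw["elongation"] = max(1.0, draw["elongation"])
    draw["stain_intensity"] = float(np.clip(draw["stain_intensity"], 0, 1))
    draw["border_irregularity"] = float(np.clip(draw["border_irregularity"], 0, 1))
    violated = _violations_of(draw)
    return FocusPhenotype(label=label, style=style, violated=tuple(violated), **draw)


def _violations_of(draw: dict) -> list[str]:
    """Which assay criteria does this parameter draw actually fail?"""
    out = []
    if draw["cell_count"] < 100:
        out.append("cell_count")
    if draw["stain_intensity"] < 0.5:
        out.append("stain")
    if draw["border_irregularity"] < 0.3:
        out.append("border")
    if draw["elongation"] < 2.0:
        out.append("elongation")
    if draw["density"] < 1.0:
        out.append("density")
    if draw["orientation_dispersion"] < 25.0:
        out.append("orientation")
    return out


def _style_key(style: str) -> int:
    # stable small integer per style for seed mixing
    return sorted(STYLES).index(style) if style in STYLES else 0


# ---------------------------------------------------------------------------
# Rendering

# Giemsa renders dense cell regions blue-purple; background monolayer is a
# pale, nearly unsaturated lavender-grey.  Linear RGB in [0, 1].
_BG_COLOR = np.array([0.936, 0.922, 0.945])
_CELL_LIGHT = np.array([0.80, 0.74, 0.88])
_CELL_DARK = np.array([0.22, 0.13, 0.38])


def _boundary_radius(theta: np.ndarray, R: float, irregularity: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Smooth periodic boundary r(theta) for the cluster support region.

    A low-order random Fourier perturbation; amplitude scales with
    ``irregularity`` so 0 gives an exact circle.
    """
    pert = np.zeros_like(theta)
    if irregularity > 0:
        ks = np.arange(2, 8)
        amps = rng.normal(size=ks.size) / ks
        phases = rng.uniform(0, 2 * np.pi, size=ks.size)
        for k, a, p in zip(ks, amps, phases):
            pert += a * np.cos(k * theta + p)
        m = np.max(np.abs(pert))
        if m > 0:
            pert = pert / m
    return R * (1.0 + 0.35 * irregularity * pert)


def _support_mask(shape: tuple[int, int], center: tuple[float, float], R: float,
                  irregularity: float, rng: np.random.Generator) -> np.ndarray:
    H, W = shape
    yy, xx = np.mgrid[0:H, 0:W]
    dy = yy - center[0]
    dx = xx - center[1]
    rad = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    # evaluate the boundary on a dense angular grid, then look up per pixel
    grid = np.linspace(-np.pi, np.pi, 1024, endpoint=False)
    rb = _boundary_radius(grid, R, irregularity, rng)
    idx = np.clip(((theta + np.pi) / (2 * np.pi) * 1024).astype(int), 0, 1023)
    return rad <= rb[idx]


def render_image_with_mask(phenotype: FocusPhenotype, canvas: tuple[int, int] = (512, 512),
                           rng_seed: int = 0) -> tuple[FocusImage, np.ndarray]:
    """Render a phenotype and also return the ground-truth cluster mask.

    The mask is the cluster support region (the deformed disk the cells are
    confined to), which is what the segmentation stage should recover.
    """
    H, W = canvas
    if H < MIN_CANVAS or W < MIN_CANVAS:
        raise ValueError(f"canvas must be at least {MIN_CANVAS}x{MIN_CANVAS}")
    rng = np.random.default_rng(np.random.SeedSequence([int(rng_seed), 7, phenotype.label]))
    scale = min(H, W) / REFERENCE_CANVAS
    R = phenotype.cluster_radius * scale

    # --- background: pale monolayer with smooth low-amplitude texture
    tex = gaussian_filter(rng.uniform(-1, 1, size=(H, W)), sigma=8 * max(scale, 0.5))
    tex = tex / (np.abs(tex).max() + 1e-12)
    img = _BG_COLOR[None, None, :] + 0.025 * tex[:, :, None]

    # --- cluster support (ground truth)
    center = (H / 2 + rng.uniform(-4, 4) * scale, W / 2 + rng.uniform(-4, 4) * scale)
    support = _support_mask((H, W), center, R, phenotype.border_irregularity, rng)

    # --- cells: elliptical, spindle when elongation is high; size chosen so
    # total cell area ~= density * support area (multilayer when density > 1)
    n = phenotype.cell_count
    area_support = math.pi * R * R
    ab = phenotype.density * area_support / max(n, 1) / math.pi
    b = math.sqrt(max(ab, 1.0) / phenotype.elongation)
    a = b * phenotype.elongation
    base_col = _CELL_LIGHT + phenotype.stain_intensity * (_CELL_DARK - _CELL_LIGHT)
    alpha = float(np.clip(0.18 + 0.16 * phenotype.density, 0.20, 0.62))
    mean_angle = rng.uniform(0, 180.0)

    # continuous cell bed: a focus is a contiguous mass of cells, so the whole
    # support region carries a stain wash under the individually drawn cells
    bed_alpha = float(np.clip(0.38 + 0.14 * phenotype.density, 0.40, 0.72))
    img[support] = img[support] * (1 - bed_alpha) + base_col[None, :] * bed_alpha

    placed = 0
    attempts = 0
    while placed < n and attempts < 40 * n:
        attempts += 1
        # uniform over the enclosing disk, accept if inside support
        rr = R * math.sqrt(rng.uniform())
        th = rng.uniform(0, 2 * math.pi)
        cy = center[0] + rr * math.sin(th)
        cx = center[1] + rr * math.cos(th)
        iy, ix = int(round(cy)), int(round(cx))
        if not (0 <= iy < H and 0 <= ix < W) or not support[iy, ix]:
            continue
        ang = math.radians(mean_angle + rng.normal(0.0, phenotype.orientation_dispersion))
        ys, xs = draw_ellipse(cy, cx, a, b, shape=(H, W), rotation=ang)
        if ys.size == 0:
            continue
        keep = support[ys, xs]
        ys, xs = ys[keep], xs[keep]
        if ys.size == 0:
            continue
        col = np.clip(base_col * (1.0 + rng.normal(0.0, 0.05, size=3)), 0, 1)
        img[ys, xs] = img[ys, xs] * (1 - alpha) + col[None, :] * alpha
        placed += 1

    # light smoothing stands in for optical blur / anti-aliasing
    for c in range(3):
        img[:, :, c] = gaussian_filter(img[:, :, c], sigma=0.6)
    img += rng.normal(0.0, 0.004, size=img.shape)
    pixels = (np.clip(img, 0, 1) * 255).round().astype(np.uint8)
    fi = FocusImage(pixels=pixels, label=phenotype.label, chemical=phenotype.style,
                    source="synthetic")
    return fi, support


def render_image(phenotype: FocusPhenotype, canvas: tuple[int, int] = (512, 512),
                 rng_seed: int = 0) -> FocusImage:
    """Render a phenotype to an RGB image (see :func:`render_image_with_mask`)."""
    return render_image_with_mask(phenotype, canvas, rng_seed)[0]


# ---------------------------------------------------------------------------
# Dataset generation

def generate_dataset(n_pos: int, n_neg: int, style_mix: dict[str, float] | None = None,
                     rng_seed: int = 0, out_dir: str | Path | None = None,
                     canvas: tuple[int, int] = (512, 512), contrast: float = 1.0,
                     image_format: str = "png") -> DatasetManifest:
    """Generate a labelled dataset and (optionally) write it to disk.

    With ``out_dir=None`` images are kept in memory and the manifest's
    ``path`` column is empty; :func:`images_for` retrieves them by re-rendering
    (generation is deterministic).  Class ratio defaults in the assay are
    heavily positive-skewed (roughly 78% positives among suspected foci);
    callers choose ``n_pos``/``n_neg`` explicitly.
    """
    if n_pos < 0 or n_neg < 0:
        raise ValueError("n_pos and n_neg must be >= 0")
    style_mix = style_mix or {"TPA-like": 1.0}
    styles = sorted(style_mix)
    weights = np.array([style_mix[s] for s in styles], dtype=float)
    if (weights < 0).any() or weights.sum() <= 0:
        raise ValueError("style weights must be nonnegative and not all zero")
    for s in styles:
        if s not in STYLES:
            raise UnknownStyleError(
                f"unknown style {s!r}; registered styles: {sorted(STYLES)}")
    weights = weights / weights.sum()

    out_path = None
    if out_dir is not None:
        out_path = Path(out_dir)
        out_path.mkdir(parents=True, exist_ok=True)

    rows = []
    labels = [1] * n_pos + [0] * n_neg
    master = np.random.default_rng(np.random.SeedSequence([int(rng_seed), 11]))
    style_draws = master.choice(len(styles), size=len(labels), p=weights)
    for i, (lab, si) in enumerate(zip(labels, style_draws)):
        style = styles[si]
        img_id = f"syn{rng_seed}_{i:05d}"
        sub_seed = int(rng_seed) * 1_000_003 + i
        path = ""
        if out_path is not None:
            img = _render_record(lab, style, sub_seed, canvas, contrast)
            fname = f"{img_id}.{image_format}"
            Image.fromarray(img.pixels).save(out_path / fname)
            path = str(out_path / fname)
        rows.append({"id": img_id, "path": path, "label": lab,
                     "chemical": style, "split": "", "_seed": sub_seed,
                     "_contrast": contrast, "_canvas": min(canvas)})
    df = pd.DataFrame(rows, columns=["id", "path", "label", "chemical", "split",
                                     "_seed", "_contrast", "_canvas"])
    manifest = DatasetManifest(df)
    if out_path is not None:
        manifest.records[list(DatasetManifest.COLUMNS)].to_csv(
            out_path / "manifest.csv", index=False)
    return manifest


def _render_record(label: int, style: str, sub_seed: int, canvas, contrast) -> FocusImage:
    ph = sample_phenotype(label, style, rng_seed=sub_seed, contrast=contrast)
    return render_image(ph, canvas=canvas, rng_seed=sub_seed)


def images_for(manifest: DatasetManifest, rows: pd.DataFrame | None = None) -> list[FocusImage]:
    """Materialise images for manifest rows, from disk or by re-rendering."""
    df = manifest.records if rows is None else rows
    out = []
    for _, r in df.iterrows():
        if r.get("path", ""):
            px = np.asarray(Image.open(r["path"]).convert("RGB"))
            out.append(FocusImage(pixels=px, label=int(r["label"]),
                                  chemical=str(r["chemical"]), source="file",
                                  id=str(r["id"])))
        else:
            canvas = int(r.get("_canvas", 512))
            img = _render_record(int(r["label"]), str(r["chemical"]),
                                 int(r["_seed"]), (canvas, canvas),
                                 float(r.get("_contrast", 1.0)))
            out.append(dataclasses.replace(img, id=str(r["id"])))
    return out
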