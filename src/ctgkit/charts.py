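"""Chart-image pipeline: render CTG strips as scanned-style page images,
degrade, crop, annotate with Pascal VOC boxes, split and augment.

The time↔pixel mapping is an exact affine transform carried on each page, so
boxes generated from event times remain traceable back to signal time even
after cropping or horizontal flips.  VOC coordinates are 1-based inclusive
(classic Pascal VOC dialect).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import skimage.draw
import skimage.filters
import skimage.transform
from lxml import etree

from .signal import CTGRecord, EventKind, CTGFormatError

WHITE = 255
GRID_GRAY = 205
INK = 0


class ChartDetectionError(ValueError):
    """Raised when the plot region of a page image cannot be located."""


@dataclass
class ChartStyle:
    """Strip-chart geometry (US-standard CTG conventions, configurable)."""

    paper_speed_cm_min: float = 3.0
    fhr_bpm_per_cm: float = 30.0
    px_per_cm: int = 47               # ~120 dpi
    page_duration_min: float = 10.0
    fhr_range: tuple = (30.0, 240.0)
    uc_range: tuple = (0.0, 100.0)
    uc_units_per_cm: float = 25.0
    header_px: int = 60
    footer_px: int = 40
    panel_gap_px: int = 14

    def __post_init__(self):
        for name in ("paper_speed_cm_min", "fhr_bpm_per_cm", "px_per_cm",
                     "page_duration_min", "uc_units_per_cm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def px_per_s(self) -> float:
        return self.paper_speed_cm_min * self.px_per_cm / 60.0

    @property
    def page_width(self) -> int:
        return int(round(self.paper_speed_cm_min * self.page_duration_min * self.px_per_cm))

    @property
    def fhr_panel_height(self) -> int:
        lo, hi = self.fhr_range
        return int(round((hi - lo) / self.fhr_bpm_per_cm * self.px_per_cm))

    @property
    def uc_panel_height(self) -> int:
        lo, hi = self.uc_range
        return int(round((hi - lo) / self.uc_units_per_cm * self.px_per_cm))

    @property
    def page_height(self) -> int:
        return (self.header_px + self.fhr_panel_height + self.panel_gap_px
                + self.uc_panel_height + self.footer_px)


@dataclass
class PageImage:
    """One rendered page with its time↔pixel mapping.

    ``origin_x`` is the 1-based pixel column of time ``t0``; ``fhr_top_y`` /
    ``uc_top_y`` are the 1-based rows of the panel tops.  Cropping shifts
    these so the mapping stays exact.
    """

    pixels: np.ndarray
    page_index: int
    t0: float
    style: ChartStyle
    origin_x: int = 1
    fhr_top_y: int = 1
    uc_top_y: int = 1

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def height(self) -> int:
        return self.pixels.shape[0]


@dataclass
class BoundingBox:
    """Pascal VOC box: 1-based inclusive pixel coordinates."""

    label: str
    xmin: int
    ymin: int
    xmax: int
    ymax: int
    score: float | None = None

    def __post_init__(self):
        self.xmin, self.ymin = int(self.xmin), int(self.ymin)
        self.xmax, self.ymax = int(self.xmax), int(self.ymax)
        if not (self.xmin < self.xmax and self.ymin < self.ymax):
            raise ValueError("box must satisfy xmin < xmax and ymin < ymax")
        if self.xmin < 1 or self.ymin < 1:
            raise ValueError("VOC coordinates are 1-based")


# ---------------------------------------------------------------------------
# Mapping
# ---------------------------------------------------------------------------

def time_to_pixel(t: float, value: float, page: PageImage,
                  channel: str = "fhr") -> tuple:
    """Map (time s, value) to fractional (x, y) pixel coordinates (1-based)."""
    style = page.style
    if not page.t0 - 1e-9 <= t < page.t0 + style.page_duration_min * 60 + 1e-9:
        raise ValueError(f"t={t} outside page {page.page_index} span")
    x = page.origin_x + (t - page.t0) * style.px_per_s
    if channel == "fhr":
        top = page.fhr_top_y
        y = top + (style.fhr_range[1] - value) * style.px_per_cm / style.fhr_bpm_per_cm
    else:
        top = page.uc_top_y
        y = top + (style.uc_range[1] - value) * style.px_per_cm / style.uc_units_per_cm
    return x, y


def pixel_to_time(x: float, y: float, page: PageImage,
                  channel: str = "fhr") -> tuple:
    """Inverse of :func:`time_to_pixel` (exact affine inverse)."""
    style = page.style
    t = page.t0 + (x - page.origin_x) / style.px_per_s
    if channel == "fhr":
        value = style.fhr_range[1] - (y - page.fhr_top_y) * style.fhr_bpm_per_cm / style.px_per_cm
    else:
        value = style.uc_range[1] - (y - page.uc_top_y) * style.uc_units_per_cm / style.px_per_cm
    return t, value


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _draw_grid(img, top, height, width, px_per_cm):
    xs = list(range(0, width, px_per_cm)) + [width - 1]
    for x in xs:
        img[top:top + height, x] = np.minimum(img[top:top + height, x], GRID_GRAY)
    ys = [y for y in range(0, height, px_per_cm)] + [height - 1]
    for y in ys:
        img[top + y, :width] = np.minimum(img[top + y, :width], GRID_GRAY)


def _draw_trace(img, cols, rows, valid):
    h, w = img.shape
    rows = np.clip(np.round(rows).astype(int), 0, h - 1)
    cols = np.clip(np.round(cols).astype(int), 0, w - 1)
    for i in range(len(cols) - 1):
        if not (valid[i] and valid[i + 1]):
            continue
        rr, cc = skimage.draw.line(rows[i], cols[i], rows[i + 1], cols[i + 1])
        img[rr, cc] = INK


def _draw_header_marks(img, style, page_index):
    # sparse pseudo-text: short dashes standing in for header text, kept
    # clear of the plot band so auto-cropping has something to remove
    y = style.header_px // 2
    for k in range(6):
        x0 = 40 + 90 * k + (page_index * 7) % 20
        img[y:y + 2, x0:x0 + 14] = INK


def render_pages(record: CTGRecord, style: ChartStyle | None = None) -> list:
    """Rasterize a record into page images (FHR top panel, UC bottom).

    Deterministic: the same record and style always give identical pixels.
    """
    style = style or ChartStyle()
    if record.duration <= 0:
        return []
    page_s = style.page_duration_min * 60.0
    n_pages = int(math.ceil(record.duration / page_s - 1e-9))
    W, H = style.page_width, style.page_height
    fhr_top = style.header_px
    uc_top = fhr_top + style.fhr_panel_height + style.panel_gap_px

    pages = []
    for pi in range(n_pages):
        img = np.full((H, W), WHITE, dtype=np.uint8)
        _draw_grid(img, fhr_top, style.fhr_panel_height, W, style.px_per_cm)
        _draw_grid(img, uc_top, style.uc_panel_height, W, style.px_per_cm)
        _draw_header_marks(img, style, pi)

        t0 = pi * page_s
        page = PageImage(pixels=img, page_index=pi, t0=t0, style=style,
                         origin_x=1, fhr_top_y=fhr_top + 1, uc_top_y=uc_top + 1)

        for channel, series in (("fhr", record.fhr), ("uc", record.uc)):
            t = series.times()
            sel = (t >= t0) & (t < t0 + page_s)
            if not sel.any():
                continue
            ts = t[sel]
            vals = series.values[sel]
            lo, hi = (style.fhr_range if channel == "fhr" else style.uc_range)
            vals = np.clip(vals, lo, hi)
            xs = np.array([time_to_pixel(tt, vv, page, channel)[0]
                           for tt, vv in zip(ts[:1], vals[:1])])
            # vectorized affine (the helper validates; do the bulk inline)
            xs = page.origin_x + (ts - t0) * style.px_per_s
            if channel == "fhr":
                ys = page.fhr_top_y + (style.fhr_range[1] - vals) * style.px_per_cm / style.fhr_bpm_per_cm
                valid = series.quality[sel]
            else:
                ys = page.uc_top_y + (style.uc_range[1] - vals) * style.px_per_cm / style.uc_units_per_cm
                valid = np.ones(len(ts), dtype=bool)
            # convert 1-based fractional coords to 0-based array indices
            _draw_trace(img, xs - 1, ys - 1, valid)
        pages.append(page)
    return pages


# ---------------------------------------------------------------------------
# Degradation
# ---------------------------------------------------------------------------

def degrade(page: PageImage, level: float, seed: int = 0) -> PageImage:
    """Emulate photocopy/scan/fax damage: blur, contrast loss, speckle, and a
    slight rotation (≤1°), all scaled by *level* in [0, 1].  ``level=0`` is
    the identity; fixed seed gives identical output."""
    if not 0 <= level <= 1:
        raise ValueError("level must lie in [0, 1]")
    if level == 0:
        return replace(page, pixels=page.pixels.copy())
    rng = np.random.default_rng([int(seed) % (2 ** 31), 7])
    img = page.pixels.astype(float)

    img = skimage.filters.gaussian(img, sigma=1.5 * level, preserve_range=True)
    mean = 210.0
    img = mean + (img - mean) * (1 - 0.5 * level)

    frac = 0.04 * level
    mask = rng.random(img.shape) < frac
    salt = rng.random(img.shape) < 0.5
    img[mask & salt] = 255
    img[mask & ~salt] = 0

    angle = float(rng.uniform(-1.0, 1.0)) * level
    img = skimage.transform.rotate(img, angle, mode="edge", preserve_range=True)
    return replace(page, pixels=np.clip(img, 0, 255).astype(np.uint8))


# ---------------------------------------------------------------------------
# Cropping
# ---------------------------------------------------------------------------

def crop_chart_region(page: PageImage) -> PageImage:
    """Crop to the graphical plot band, dropping headers/footers/margins.

    Detection: grid columns are pixel columns inked over a large fraction of
    the image height; the plot band is the row range over which at least
    half of those columns are inked.  The page's pixel mapping is updated so
    :func:`time_to_pixel` remains correct on the cropped image.
    """
    ink = page.pixels < 240
    col_ink = ink.sum(axis=0)
    grid_cols = np.flatnonzero(col_ink >= 0.3 * page.height)
    if grid_cols.size < 3:
        raise ChartDetectionError("no chart grid detected")
    row_hits = ink[:, grid_cols].sum(axis=1)
    band = np.flatnonzero(row_hits >= 0.5 * grid_cols.size)
    if band.size == 0:
        raise ChartDetectionError("no plot band detected")
    r0, r1 = int(band[0]), int(band[-1])
    c0, c1 = int(grid_cols[0]), int(grid_cols[-1])
    cropped = page.pixels[r0:r1 + 1, c0:c1 + 1].copy()
    return replace(
        page,
        pixels=cropped,
        origin_x=page.origin_x - c0,
        fhr_top_y=page.fhr_top_y - r0,
        uc_top_y=page.uc_top_y - r0,
    )


# ---------------------------------------------------------------------------
# Boxes
# ---------------------------------------------------------------------------

def events_to_boxes(events, pages, pad_s: float = 30.0) -> dict:
    """Project event labels onto per-page full-panel-height bounding boxes.

    Each event spans ``[t_start − pad, t_end + pad]`` horizontally and the
    full FHR panel vertically; events crossing page borders are split into
    one box per page.  Returns ``{page_index: [BoundingBox, ...]}``.
    """
    out = {p.page_index: [] for p in pages}
    for p in pages:
        style = p.style
        page_s = style.page_duration_min * 60.0
        t_lo, t_hi = p.t0, p.t0 + page_s
        panel_h = style.fhr_panel_height
        for ev in events:
            a = max(ev.t_start - pad_s, t_lo)
            b = min(ev.t_end + pad_s, t_hi)
            if b - a <= 0:
                continue
            x0 = p.origin_x + (a - p.t0) * style.px_per_s
            x1 = p.origin_x + (b - p.t0) * style.px_per_s
            xmin = max(1, int(math.floor(x0)))
            xmax = min(p.width, int(math.ceil(x1)))
            if xmax <= xmin:
                continue
            kind = ev.kind.value if isinstance(ev.kind, EventKind) else str(ev.kind)
            out[p.page_index].append(BoundingBox(
                label=kind, xmin=xmin, ymin=p.fhr_top_y,
                xmax=xmax, ymax=min(p.height, p.fhr_top_y + panel_h - 1),
            ))
    return out


# ---------------------------------------------------------------------------
# Pascal VOC XML
# ---------------------------------------------------------------------------

def write_voc(boxes, image_meta: dict, path) -> None:
    """Write boxes for one image in Pascal VOC XML.

    *image_meta* needs ``filename``, ``width``, ``height`` (and optionally
    ``folder``, ``depth``).
    """
    root = etree.Element("annotation")
    etree.SubElement(root, "folder").text = str(image_meta.get("folder", "images"))
    etree.SubElement(root, "filename").text = str(image_meta["filename"])
    size = etree.SubElement(root, "size")
    etree.SubElement(size, "width").text = str(int(image_meta["width"]))
    etree.SubElement(size, "height").text = str(int(image_meta["height"]))
    etree.SubElement(size, "depth").text = str(int(image_meta.get("depth", 1)))
    for b in boxes:
        obj = etree.SubElement(root, "object")
        etree.SubElement(obj, "name").text = b.label
        etree.SubElement(obj, "pose").text = "Unspecified"
        etree.SubElement(obj, "truncated").text = "0"
        etree.SubElement(obj, "difficult").text = "0"
        if b.score is not None:
            etree.SubElement(obj, "score").text = repr(float(b.score))
        bnd = etree.SubElement(obj, "bndbox")
        for name, val in (("xmin", b.xmin), ("ymin", b.ymin),
                          ("xmax", b.xmax), ("ymax", b.ymax)):
            etree.SubElement(bnd, name).text = str(int(val))
    etree.ElementTree(root).write(str(path), pretty_print=True,
                                  xml_declaration=False, encoding="utf-8")


def read_voc(path):
    """Read a VOC XML file back into (boxes, image_meta)."""
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise CTGFormatError(f"malformed VOC XML: {path}") from exc
    root = tree.getroot()
    size = root.find("size")
    meta = {
        "folder": root.findtext("folder", "images"),
        "filename": root.findtext("filename", ""),
        "width": int(size.findtext("width")) if size is not None else 0,
        "height": int(size.findtext("height")) if size is not None else 0,
        "depth": int(size.findtext("depth", "1")) if size is not None else 1,
    }
    boxes = []
    for obj in root.findall("object"):
        bnd = obj.find("bndbox")
        if bnd is None:
            raise CTGFormatError(f"object without bndbox in {path}")
        score_text = obj.findtext("score")
        boxes.append(BoundingBox(
            label=obj.findtext("name", ""),
            xmin=int(bnd.findtext("xmin")), ymin=int(bnd.findtext("ymin")),
            xmax=int(bnd.findtext("xmax")), ymax=int(bnd.findtext("ymax")),
            score=float(score_text) if score_text is not None else None,
        ))
    return boxes, meta


# ---------------------------------------------------------------------------
# Split and augmentation
# ---------------------------------------------------------------------------

def split_train_test(items, train_fraction: float = 0.8, seed: int = 0,
                     holdout_fraction_of_test: float = 0.5) -> dict:
    """Deterministic random train/test split with a validation holdout.

    ``round(train_fraction·n)`` items go to train; the validation set is
    drawn out of the remaining test items (``round(holdout·|test|)``), so the
    three partitions are disjoint and exhaustive.  For 252 items at the
    defaults this gives 202 train and 50 held-out items, 25 of which form
    the validation set.
    """
    items = list(items)
    n = len(items)
    if n < 3:
        raise ValueError("need at least 3 items to split")
    rng = np.random.default_rng(int(seed) % (2 ** 31))
    order = rng.permutation(n)
    n_train = int(round(train_fraction * n))
    train = [items[i] for i in order[:n_train]]
    test_all = [items[i] for i in order[n_train:]]
    n_val = int(round(holdout_fraction_of_test * len(test_all)))
    validation = test_all[:n_val]
    test = test_all[n_val:]
    return {"train": train, "test": test, "validation": validation}


def flip_horizontal(image: np.ndarray, boxes):
    """Mirror an image left↔right and remap its boxes (an involution).

    With 1-based inclusive coordinates the flip maps column ``x`` to
    ``W − x + 1``, so a box [xmin, xmax] becomes [W−xmax+1, W−xmin+1].
    """
    W = image.shape[1]
    flipped = image[:, ::-1].copy()
    new_boxes = [replace(b, xmin=W - b.xmax + 1, xmax=W - b.xmin + 1) for b in boxes]
    return flipped, new_boxes


def _reduce_resolution(image: np.ndarray) -> np.ndarray:
    h, w = image.shape[:2]
    small = skimage.transform.resize(image, (h // 2, w // 2), order=1,
                                     anti_aliasing=True, preserve_range=True)
    back = skimage.transform.resize(small, (h, w), order=1, preserve_range=True)
    return np.clip(back, 0, 255).astype(np.uint8)


def _sharpen(image: np.ndarray) -> np.ndarray:
    out = skimage.filters.unsharp_mask(image.astype(float) / 255.0,
                                       radius=1.5, amount=1.0)
    return np.clip(out * 255.0, 0, 255).astype(np.uint8)


def augment(items):
    """Quadruple a dataset of (image, boxes) pairs.

    Each input yields exactly four variants — {identity, horizontal flip} ×
    {resolution-reduced, sharpened}.  Never a vertical flip: upside-down
    heart-rate excursions have no physiological counterpart.  Resolution
    treatments leave box geometry unchanged; the flip remaps x coordinates.
    Returns a list of (image, boxes, variant_tag).
    """
    out = []
    for image, boxes in items:
        fl_img, fl_boxes = flip_horizontal(image, boxes)
        for orient_tag, img, bxs in (("orig", image, boxes), ("flip", fl_img, fl_boxes)):
            out.append((_reduce_resolution(img), list(bxs), f"{orient_tag}-reduced"))
            out.append((_sharpen(img), list(bxs), f"{orient_tag}-sharpened"))
    return out
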