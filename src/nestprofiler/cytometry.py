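"""Image cytometry: cell detection, marker quantification, lineage gating
and region-stratified density metrics.

Cells are detected on the nuclear (hematoxylin) channel by Otsu
thresholding and a distance-transform watershed, quantified as per-marker
mean intensity over the cell footprint, gated into leukocyte lineages by a
first-match-wins walk of conjunction rules (flow-cytometry-style), and
assigned to tumor cell nest or intratumoral stroma by centroid containment.

The gating hierarchy mirrors the marker panel's lineage definitions:
CD8 T (CD45+CD3+CD8+), TREG (CD45+CD3+CD8-Foxp3+), helper T
(CD45+CD3+CD8-Foxp3-) with TH1/TH2 sub-labels by Tbet/GATA3, B cells
(CD45+CD3-CD20+), NK (CD56+), CD66b+ granulocytes, mast cells (Tryptase+),
and TAM (CD68+CSF1R+) split by CD163. PD-1 positivity is a flag orthogonal
to lineage. A validation-panel variant identifies helper T as CD3+CD4+
rather than CD3+CD8-.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import regionprops
from skimage.segmentation import watershed

from .segmentation import BinaryMask, GrayImage, SegmentationResult
from .simulate import MarkerImageStack

__all__ = [
    "GatingConfig",
    "discovery_rules",
    "validation_rules",
    "CellDetection",
    "detect_cells",
    "quantify_markers",
    "classify_cells",
    "assign_region",
    "RegionStats",
    "compute_region_stats",
    "Th1Th2Ratio",
    "th1_th2_ratio",
    "polarization_class",
    "region_validation",
    "load_cell_table",
]

REGIONS = ("nest", "stroma")

# immune lineages counted against the CD45+ denominator in composition stats
CD45_LINEAGES = (
    "helper_t", "cd8_t", "treg", "b_cell", "nk", "granulocyte", "mast",
    "tam_cd163_pos", "tam_cd163_neg",
)

PD1_GATED_LINEAGES = ("helper_t", "treg", "cd8_t")


def discovery_rules() -> list[tuple[str, dict[str, bool]]]:
    """First-match-wins gating hierarchy of the 12-marker discovery panel."""
    return [
        ("cd8_t", {"CD45": True, "CD3": True, "CD8": True}),
        ("treg", {"CD45": True, "CD3": True, "CD8": False, "Foxp3": True}),
        ("helper_t", {"CD45": True, "CD3": True, "CD8": False, "Foxp3": False}),
        ("b_cell", {"CD45": True, "CD3": False, "CD20": True}),
        ("nk", {"CD45": True, "CD3": False, "CD20": False, "CD56": True}),
        (
            "granulocyte",
            {"CD45": True, "CD3": False, "CD20": False, "CD56": False,
             "CD66b": True},
        ),
        (
            "mast",
            {"CD45": True, "CD3": False, "CD20": False, "CD56": False,
             "CD66b": False, "Tryptase": True},
        ),
        (
            "tam_cd163_pos",
            {"CD45": True, "CD3": False, "CD20": False, "CD56": False,
             "CD66b": False, "Tryptase": False, "CD68": True, "CSF1R": True,
             "CD163": True},
        ),
        (
            "tam_cd163_neg",
            {"CD45": True, "CD3": False, "CD20": False, "CD56": False,
             "CD66b": False, "Tryptase": False, "CD68": True, "CSF1R": True,
             "CD163": False},
        ),
        ("tumor", {"CD45": False, "TumorMarker": True}),
    ]


def validation_rules() -> list[tuple[str, dict[str, bool]]]:
    """Validation-panel variant: helper T cells gated as CD3+CD4+."""
    return [
        ("cd8_t", {"CD3": True, "CD8": True}),
        ("treg", {"CD3": True, "CD4": True, "Foxp3": True}),
        ("helper_t", {"CD3": True, "CD4": True, "Foxp3": False}),
        ("tumor", {"CD3": False, "TumorMarker": True}),
    ]


@dataclass
class GatingConfig:
    """Per-marker positivity thresholds plus an ordered gating rule list.

    A cell is positive for a marker when its mean intensity is >= the
    marker's threshold (default 127, the 8-bit midpoint). Rule order
    resolves overlaps: the first matching conjunction wins, unmatched cells
    are labeled ``other``.
    """

    thresholds: dict[str, float] = field(default_factory=dict)
    rules: list[tuple[str, dict[str, bool]]] | None = None
    panel_variant: str = "discovery"
    default_threshold: float = 127.0
    pd1_marker: str = "PD1"

    def __post_init__(self) -> None:
        if self.rules is None:
            if self.panel_variant == "discovery":
                self.rules = discovery_rules()
            elif self.panel_variant == "validation":
                self.rules = validation_rules()
            else:
                raise ValueError(f"unknown panel_variant {self.panel_variant!r}")

    def threshold(self, marker: str) -> float:
        return float(self.thresholds.get(marker, self.default_threshold))

    def required_markers(self) -> set[str]:
        out: set[str] = {self.pd1_marker}
        for _, conj in self.rules:
            out.update(conj)
        return out


@dataclass(frozen=True)
class CellDetection:
    """Detected cells (table: cell_id, x, y, area_px) plus the label image."""

    table: pd.DataFrame
    labels: np.ndarray
    pixel_size_um: float


def detect_cells(
    hematoxylin: GrayImage,
    roi: BinaryMask,
    min_area_px: int = 5,
    max_area_px: int = 2000,
    min_distance_px: int = 5,
) -> CellDetection:
    """Detect nuclei inside the ROI by Otsu + distance-transform watershed.

    The nuclear channel is thresholded (Otsu over ROI pixels), touching
    nuclei are split by a watershed seeded at peaks of the smoothed distance
    transform, and components with area outside [min_area_px, max_area_px]
    are dropped. Fully deterministic.
    """
    if hematoxylin.shape != roi.shape:
        raise ValueError("image and roi must share one shape")
    if not roi.pixels.any():
        raise ValueError("empty ROI: no cells detectable")
    values = hematoxylin.pixels[roi.pixels]
    if values.min() == values.max():
        return CellDetection(
            pd.DataFrame(columns=["cell_id", "x", "y", "area_px"]),
            np.zeros(roi.shape, dtype=np.int32),
            roi.pixel_size_um,
        )
    t = threshold_otsu(values)
    foreground = (hematoxylin.pixels > t) & roi.pixels
    distance = ndi.distance_transform_edt(foreground)
    smooth = gaussian(distance, sigma=1.0)
    peaks = peak_local_max(
        smooth, min_distance=min_distance_px, labels=foreground,
        exclude_border=False,
    )
    markers = np.zeros(foreground.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = watershed(-smooth, markers, mask=foreground)

    rows = []
    keep = np.zeros(labels.max() + 1, dtype=bool)
    for prop in regionprops(labels):
        if min_area_px <= prop.area <= max_area_px:
            keep[prop.label] = True
            cy, cx = prop.centroid
            rows.append((prop.label, float(cx), float(cy), int(prop.area)))
    labels = np.where(keep[labels], labels, 0).astype(np.int32)
    table = pd.DataFrame(rows, columns=["cell_id", "x", "y", "area_px"])
    return CellDetection(table, labels, roi.pixel_size_um)


def quantify_markers(
    cells: CellDetection | pd.DataFrame,
    stack: MarkerImageStack,
    footprint_radius_px: int | None = None,
) -> pd.DataFrame:
    """Per-cell mean intensity of every marker channel.

    ``cells`` is either a :class:`CellDetection` (means over the watershed
    footprints) or a table with x/y centroids, in which case means are taken
    over a disk of ``footprint_radius_px`` around each rounded centroid.
    """
    if isinstance(cells, CellDetection):
        table = cells.table.copy()
        if table.empty:
            for name in stack.markers:
                table[name] = np.empty(0)
            return table
        index = table["cell_id"].to_numpy()
        for name in stack.markers:
            table[name] = ndi.mean(
                stack.channels[name].astype(float), labels=cells.labels, index=index
            )
        table["cell_id"] = np.arange(len(table))
        return table

    if footprint_radius_px is None:
        raise ValueError("footprint_radius_px required for centroid tables")
    table = cells.copy().reset_index(drop=True)
    h, w = stack.shape
    r = footprint_radius_px
    dy, dx = np.ogrid[-r : r + 1, -r : r + 1]
    disk = dy**2 + dx**2 <= r**2
    channels = {name: stack.channels[name].astype(float) for name in stack.markers}
    means = {name: np.empty(len(table)) for name in stack.markers}
    xs = np.rint(table["x"].to_numpy()).astype(int)
    ys = np.rint(table["y"].to_numpy()).astype(int)
    for i in range(len(table)):
        cy, cx = ys[i], xs[i]
        if not (0 <= cx < w and 0 <= cy < h):
            raise ValueError(f"cell {i} centroid outside image bounds")
        y0, y1 = max(0, cy - r), min(h, cy + r + 1)
        x0, x1 = max(0, cx - r), min(w, cx + r + 1)
        local = disk[y0 - (cy - r) : y1 - (cy - r), x0 - (cx - r) : x1 - (cx - r)]
        for name in stack.markers:
            means[name][i] = channels[name][y0:y1, x0:x1][local].mean()
    for name in stack.markers:
        table[name] = means[name]
    if "cell_id" not in table.columns:
        table.insert(0, "cell_id", np.arange(len(table)))
    return table


def classify_cells(table: pd.DataFrame, config: GatingConfig) -> pd.DataFrame:
    """Gate cells into lineages by a first-match-wins walk of the rule list.

    Adds ``lineage`` (``other`` when no rule matches), ``th_subset``
    (``th1``/``th2``/``none``; Tbet wins over GATA3 for helper T cells) and
    the orthogonal boolean ``pd1`` flag.
    """
    missing = config.required_markers() - set(table.columns)
    if missing:
        raise ValueError(f"cell table lacks panel markers: {sorted(missing)}")
    out = table.copy()
    positive = {
        m: table[m].to_numpy(float) >= config.threshold(m)
        for m in config.required_markers()
    }
    n = len(table)
    lineage = np.full(n, "other", dtype=object)
    unassigned = np.ones(n, dtype=bool)
    for name, conjunction in config.rules:
        match = unassigned.copy()
        for marker, wanted in conjunction.items():
            match &= positive[marker] if wanted else ~positive[marker]
        lineage[match] = name
        unassigned &= ~match

    th_subset = np.full(n, "none", dtype=object)
    if "Tbet" in table.columns and "GATA3" in table.columns:
        helper = lineage == "helper_t"
        tbet = table["Tbet"].to_numpy(float) >= config.threshold("Tbet")
        gata3 = table["GATA3"].to_numpy(float) >= config.threshold("GATA3")
        th_subset[helper & tbet] = "th1"
        th_subset[helper & ~tbet & gata3] = "th2"

    out["lineage"] = lineage
    out["th_subset"] = th_subset
    out["pd1"] = positive[config.pd1_marker]
    return out


def assign_region(table: pd.DataFrame, seg: SegmentationResult) -> pd.DataFrame:
    """Label each cell nest / stroma / outside by rounded-centroid containment."""
    out = table.copy()
    h, w = seg.roi.shape
    xs = np.clip(np.rint(out["x"].to_numpy()).astype(int), 0, w - 1)
    ys = np.clip(np.rint(out["y"].to_numpy()).astype(int), 0, h - 1)
    region = np.full(len(out), "outside", dtype=object)
    region[seg.stroma.pixels[ys, xs]] = "stroma"
    region[seg.nest.pixels[ys, xs]] = "nest"
    out["region"] = region
    return out


@dataclass(frozen=True)
class RegionStats:
    """Per-region, per-lineage counts, areas and densities for one specimen.

    ``per_lineage`` columns: region, lineage, count, area_mm2, density
    (cells/mm^2, NaN for a zero-area region where density is undefined);
    ``pd1_per_lineage`` holds the PD-1+ sub-densities for helper T, TREG
    and CD8 T cells; ``percent_of_cd45`` is each immune lineage's share of
    CD45+ cells per region; ``th_counts`` holds TH1/TH2 counts per region.
    """

    per_lineage: pd.DataFrame
    pd1_per_lineage: pd.DataFrame
    percent_of_cd45: pd.DataFrame
    th_counts: pd.DataFrame
    areas_mm2: dict[str, float]

    def _lookup(self, frame: pd.DataFrame, region: str, lineage: str, col: str):
        sel = frame[(frame["region"] == region) & (frame["lineage"] == lineage)]
        return float(sel[col].iloc[0]) if len(sel) else 0.0

    def count(self, region: str, lineage: str) -> int:
        return int(self._lookup(self.per_lineage, region, lineage, "count"))

    def density(self, region: str, lineage: str) -> float:
        return self._lookup(self.per_lineage, region, lineage, "density")

    def pd1_density(self, region: str, lineage: str) -> float:
        return self._lookup(self.pd1_per_lineage, region, lineage, "density")


def compute_region_stats(
    table: pd.DataFrame,
    seg: SegmentationResult,
    lineages: tuple[str, ...] | None = None,
) -> RegionStats:
    """Region-stratified counts, densities and composition percentages.

    ``table`` must carry ``lineage``, ``th_subset``, ``pd1`` and ``region``
    columns (see :func:`classify_cells` / :func:`assign_region`). Cells
    labeled ``outside`` are ignored. A zero-area region reports counts with
    NaN density.
    """
    for col in ("lineage", "region", "pd1", "th_subset"):
        if col not in table.columns:
            raise ValueError(f"cell table lacks column {col!r}")
    if lineages is None:
        observed = set(map(str, table["lineage"].unique()))
        lineages = tuple(
            sorted(observed | set(CD45_LINEAGES) | {"tumor", "other"})
        )
    areas = {"nest": seg.nest.area_mm2, "stroma": seg.stroma.area_mm2}

    rows, pd1_rows, pct_rows, th_rows = [], [], [], []
    for region in REGIONS:
        area = areas[region]
        sub = table[table["region"] == region]
        counts = sub["lineage"].value_counts()
        cd45_total = int(sum(counts.get(l, 0) for l in CD45_LINEAGES))
        for lin in lineages:
            c = int(counts.get(lin, 0))
            dens = c / area if area > 0 else float("nan")
            rows.append((region, lin, c, area, dens))
            if lin in CD45_LINEAGES:
                pct = 100.0 * c / cd45_total if cd45_total else float("nan")
                pct_rows.append((region, lin, pct))
        for lin in PD1_GATED_LINEAGES:
            c = int(((sub["lineage"] == lin) & sub["pd1"]).sum())
            dens = c / area if area > 0 else float("nan")
            pd1_rows.append((region, lin, c, dens))
        th_rows.append(
            (
                region,
                int((sub["th_subset"] == "th1").sum()),
                int((sub["th_subset"] == "th2").sum()),
            )
        )

    return RegionStats(
        per_lineage=pd.DataFrame(
            rows, columns=["region", "lineage", "count", "area_mm2", "density"]
        ),
        pd1_per_lineage=pd.DataFrame(
            pd1_rows, columns=["region", "lineage", "count", "density"]
        ),
        percent_of_cd45=pd.DataFrame(
            pct_rows, columns=["region", "lineage", "percent"]
        ),
        th_counts=pd.DataFrame(th_rows, columns=["region", "th1", "th2"]),
        areas_mm2=areas,
    )


@dataclass(frozen=True)
class Th1Th2Ratio:
    """TH1/TH2 count ratio for one region; ``excluded`` when TH2 is absent."""

    ratio: float | None
    excluded: bool


def th1_th2_ratio(stats: RegionStats, region: str) -> Th1Th2Ratio:
    """TH1 count / TH2 count in a region; the specimen is excluded from this
    metric when it has no TH2 cells there."""
    row = stats.th_counts[stats.th_counts["region"] == region]
    if not len(row):
        raise ValueError(f"unknown region {region!r}")
    th1, th2 = int(row["th1"].iloc[0]), int(row["th2"].iloc[0])
    if th2 == 0:
        return Th1Th2Ratio(None, True)
    return Th1Th2Ratio(th1 / th2, False)


def polarization_class(density_nest: float, density_stroma: float) -> str:
    """Polarization status from the nest/stroma density ratio.

    Ratio > 2.0 -> ``nest_polarized``; < 0.5 -> ``stroma_polarized``;
    otherwise ``balanced`` (the boundaries 0.5 and 2.0 are balanced).
    Zero stroma density with positive nest density is nest-polarized by
    convention; two zero densities are ``undefined``.
    """
    if density_nest < 0 or density_stroma < 0:
        raise ValueError("densities must be non-negative")
    if density_stroma == 0:
        return "nest_polarized" if density_nest > 0 else "undefined"
    r = density_nest / density_stroma
    if r > 2.0:
        return "nest_polarized"
    if r < 0.5:
        return "stroma_polarized"
    return "balanced"


def region_validation(
    table: pd.DataFrame, seg: SegmentationResult, config: GatingConfig | None = None
) -> pd.DataFrame:
    """Per-region percentages of CD45+, double-negative and tumor-marker+
    cells (three mutually exclusive classes summing to 100), the check that
    tumor cells concentrate in nest regions.

    Classes are assigned from raw marker positivity: CD45+ first, else
    tumor-marker+, else CD45- tumor-marker-.
    """
    config = config or GatingConfig()
    for marker in ("CD45", "TumorMarker"):
        if marker not in table.columns:
            raise ValueError(f"cell table lacks marker {marker!r}")
    if "region" not in table.columns:
        raise ValueError("cell table lacks region labels")
    cd45 = table["CD45"].to_numpy(float) >= config.threshold("CD45")
    tumor = table["TumorMarker"].to_numpy(float) >= config.threshold("TumorMarker")
    rows = []
    for region in REGIONS:
        in_region = (table["region"] == region).to_numpy()
        n = int(in_region.sum())
        if n == 0:
            rows.append((region, float("nan"), float("nan"), float("nan")))
            continue
        n_cd45 = int((in_region & cd45).sum())
        n_tumor = int((in_region & ~cd45 & tumor).sum())
        n_double_neg = n - n_cd45 - n_tumor
        rows.append(
            (
                region,
                100.0 * n_cd45 / n,
                100.0 * n_double_neg / n,
                100.0 * n_tumor / n,
            )
        )
    return pd.DataFrame(
        rows, columns=["region", "cd45_pos_pct", "double_neg_pct", "tumor_pos_pct"]
    )


def load_cell_table(path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read an externally produced per-cell CSV (e.g. a CellProfiler export),
    optionally renaming columns via ``column_map`` (external -> canonical)."""
    table = pd.read_csv(path)
    if column_map:
        table = table.rename(columns=column_map)
    for col in ("x", "y"):
        if col not in table.columns:
            raise ValueError(f"cell table lacks required column {col!r}")
    return table
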