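"""Culture metrics from segmentation outputs.

Turns detected nuclei, microcarriers and cell-body segmentations into the
quantities used to monitor microcarrier expansion: per-microcarrier cell
counts, the cells-per-microcarrier (CPM) distribution with aggregate
handling, total and mean single-cell volume, and single-cell morphology
(sphericity, nuclear-to-cytoplasmic ratio).

CPM conventions follow the assay: non-populated microcarriers are omitted
(the distribution is zero-truncated by construction) and microcarriers that
belong to touching clusters (aggregates) can be excluded so the histogram is
not weighted against single carriers.  Aggregates are defined geometrically:
two carriers are in contact when their centre distance is below
contact_factor × (r_i + r_j), default 1.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .segment import LabeledSegmentation, MicrocarrierSet, SpotSet

__all__ = [
    "CellAssignment",
    "CPMDistribution",
    "SampleQuantification",
    "assign_cells",
    "carrier_clusters",
    "cpm_distribution",
    "summarize",
    "morphology",
]

UNASSIGNED = -1


@dataclass
class CellAssignment:
    """Nucleus-to-microcarrier mapping.

    One row per nucleus spot: the assigned microcarrier id (or -1) and the
    signed distance from the nucleus centroid to that carrier's surface
    (negative = inside the sphere).
    """

    table: pd.DataFrame  # spot_id, carrier_id, surface_distance_um
    max_distance_um: float

    def counts_per_carrier(self, n_carriers: int) -> np.ndarray:
        assigned = self.table[self.table.carrier_id >= 0]
        return np.bincount(
            assigned.carrier_id.to_numpy(dtype=np.int64), minlength=n_carriers
        )

    @property
    def n_assigned(self) -> int:
        return int((self.table.carrier_id >= 0).sum())


def assign_cells(
    spots: SpotSet, carriers: MicrocarrierSet, max_distance: float = 15.0
) -> CellAssignment:
    """Assign each nucleus to the microcarrier with the nearest surface.

    The signed surface distance is |centroid - centre| - radius; a nucleus is
    assigned when that distance does not exceed ``max_distance`` (the height
    a nucleus can sit above the surface within a spread cell).  Exact ties
    break toward the lower carrier id.
    """
    if max_distance <= 0:
        raise ValueError("max_distance must be > 0")
    n = len(spots)
    if n == 0 or len(carriers) == 0:
        table = pd.DataFrame(
            {"spot_id": spots.spots.id if n else [], "carrier_id": UNASSIGNED,
             "surface_distance_um": np.nan}
        )
        return CellAssignment(table, max_distance)

    pts = spots.centroids()[:, None, :]  # (n, 1, 3)
    centers = carriers.centers()[None, :, :]  # (1, m, 3)
    sdist = np.linalg.norm(pts - centers, axis=2) - carriers.radii()[None, :]
    best = np.argmin(sdist, axis=1)  # argmin takes the first (lowest id) on ties
    best_d = sdist[np.arange(n), best]
    carrier_ids = carriers.carriers.id.to_numpy()
    assigned = np.where(best_d <= max_distance, carrier_ids[best], UNASSIGNED)
    table = pd.DataFrame(
        {
            "spot_id": spots.spots.id.to_numpy(),
            "carrier_id": assigned,
            "surface_distance_um": np.where(assigned >= 0, best_d, np.nan),
        }
    )
    return CellAssignment(table, max_distance)


def carrier_clusters(
    carriers: MicrocarrierSet, contact_factor: float = 1.05
) -> np.ndarray:
    """Connected-cluster label per carrier under the contact criterion."""
    m = len(carriers)
    if m == 0:
        return np.zeros(0, dtype=np.int64)
    centers = carriers.centers()
    radii = carriers.radii()
    d = np.linalg.norm(centers[:, None, :] - centers[None, :, :], axis=2)
    touch = d < contact_factor * (radii[:, None] + radii[None, :])
    np.fill_diagonal(touch, False)
    _, labels = connected_components(csr_matrix(touch), directed=False)
    return labels


@dataclass
class CPMDistribution:
    """Cells-per-microcarrier histogram over populated microcarriers.

    ``histogram`` maps k >= 1 to the number of microcarriers carrying k
    cells; zero-truncated by construction because unpopulated carriers are
    never included.
    """

    histogram: dict  # {k >= 1: count}
    n: int  # populated microcarriers included
    aggregates_excluded: bool
    cluster_sizes: dict = field(default_factory=dict)  # cluster size -> n clusters

    def counts(self) -> np.ndarray:
        """Expand the histogram back into one CPM value per microcarrier."""
        if not self.histogram:
            return np.zeros(0, dtype=np.int64)
        ks = np.fromiter(self.histogram.keys(), dtype=np.int64)
        ns = np.fromiter(self.histogram.values(), dtype=np.int64)
        return np.repeat(ks, ns)

    @property
    def mean(self) -> float:
        c = self.counts()
        return float(c.mean()) if c.size else float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cells_per_microcarrier": sorted(self.histogram),
             "n_microcarriers": [self.histogram[k] for k in sorted(self.histogram)]}
        )


def cpm_distribution(
    assignment: CellAssignment,
    carriers: MicrocarrierSet,
    exclude_aggregates: bool = True,
    contact_factor: float = 1.05,
) -> CPMDistribution:
    """CPM histogram over populated microcarriers.

    Carriers are first grouped into touching clusters; with
    ``exclude_aggregates`` only single (cluster-size-1) carriers contribute,
    so the histogram is not weighted against single microcarriers.  Carriers
    with zero assigned cells are always omitted (zero truncation).  Cluster
    size strata are reported alongside for aggregate bookkeeping.
    """
    m = len(carriers)
    counts = assignment.counts_per_carrier(m)
    clusters = carrier_clusters(carriers, contact_factor)
    cluster_sizes_per_carrier = (
        np.bincount(clusters)[clusters] if m else np.zeros(0, dtype=np.int64)
    )
    include = np.ones(m, dtype=bool)
    if exclude_aggregates:
        include &= cluster_sizes_per_carrier == 1
    include &= counts >= 1

    kept = counts[include]
    hist_k, hist_n = np.unique(kept, return_counts=True)
    size_hist_k, size_hist_n = (
        np.unique(np.bincount(clusters), return_counts=True) if m else ([], [])
    )
    size_hist = {
        int(s): int(c) for s, c in zip(size_hist_k, size_hist_n) if s > 0
    }
    return CPMDistribution(
        histogram={int(k): int(c) for k, c in zip(hist_k, hist_n)},
        n=int(kept.size),
        aggregates_excluded=exclude_aggregates,
        cluster_sizes=size_hist,
    )


@dataclass
class SampleQuantification:
    """Whole-sample culture metrics."""

    total_cell_count: int
    total_microcarrier_count: int
    populated_microcarrier_count: int
    average_cpm: float  # assigned cells / populated carriers
    total_cell_volume_um3: float
    mean_cell_volume_um3: float
    sd_cell_volume_um3: float
    volume_estimator: str  # "per_object" or "volume_per_nucleus"
    n_cell_objects: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def summarize(
    assignment: Optional[CellAssignment],
    carriers: Optional[MicrocarrierSet],
    cells: Optional[LabeledSegmentation],
) -> SampleQuantification:
    """Sample-level totals and means.

    Mean single-cell volume uses the per-object mean when each cell is its
    own segmented object; once cells merge into confluent networks (fewer
    objects than nuclei) it falls back to total volume / nucleus count, and
    ``volume_estimator`` records which estimator was used.  Zero populated
    microcarriers yields a defined empty summary, not an exception.
    """
    n_spots = len(assignment.table) if assignment is not None else 0
    m = len(carriers) if carriers is not None else 0
    if assignment is not None and m:
        counts = assignment.counts_per_carrier(m)
        populated = int((counts >= 1).sum())
        assigned = int(counts.sum())
        avg_cpm = assigned / populated if populated else float("nan")
    else:
        populated, avg_cpm = 0, float("nan")

    if cells is not None and cells.n_objects:
        total_vol = cells.total_volume_um3
        vols = cells.objects.volume_um3.to_numpy()
        if n_spots and cells.n_objects < n_spots:
            est = "volume_per_nucleus"
            mean_vol = total_vol / n_spots
            sd_vol = float("nan")
        else:
            est = "per_object"
            mean_vol = float(vols.mean())
            sd_vol = float(vols.std(ddof=1)) if vols.size > 1 else 0.0
    else:
        total_vol, mean_vol, sd_vol, est = 0.0, float("nan"), float("nan"), "per_object"

    return SampleQuantification(
        total_cell_count=n_spots,
        total_microcarrier_count=m,
        populated_microcarrier_count=populated,
        average_cpm=avg_cpm,
        total_cell_volume_um3=float(total_vol),
        mean_cell_volume_um3=float(mean_vol),
        sd_cell_volume_um3=sd_vol,
        volume_estimator=est,
        n_cell_objects=cells.n_objects if cells is not None else 0,
    )


def morphology(
    cells: LabeledSegmentation,
    nuclei_seg: Optional[LabeledSegmentation] = None,
) -> pd.DataFrame:
    """Per-cell morphology: volume, surface area, sphericity, N:C ratio.

    Sphericity = pi^(1/3) (6V)^(2/3) / A, with A from the marching-cubes mesh
    already measured on each object (1 for a perfect sphere).  When a nucleus
    segmentation is given, nuclei are matched to cells by containment of the
    nucleus centroid and the nuclear-to-cytoplasmic volume ratio is
    V_nuc / (V_cell - V_nuc); unmatched cells carry NaN.

    Meaningful at low confluency where cells do not overlap; merged networks
    yield one row per network, not per cell.
    """
    if cells.n_objects == 0:
        return pd.DataFrame(
            columns=["label", "volume_um3", "surface_area_um2", "sphericity",
                     "nc_ratio"]
        )
    df = cells.objects[["label", "volume_um3", "surface_area_um2"]].copy()
    v = df.volume_um3.to_numpy()
    a = df.surface_area_um2.to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        df["sphericity"] = np.pi ** (1 / 3) * (6.0 * v) ** (2 / 3) / a

    nc = np.full(len(df), np.nan)
    if nuclei_seg is not None and nuclei_seg.n_objects:
        pitch = np.array(cells.geometry.pitch_zyx)
        label_of = {lab: i for i, lab in enumerate(df.label)}
        nuc_vol_in_cell = dict.fromkeys(df.label, 0.0)
        for r in nuclei_seg.objects.itertuples():
            vox = np.floor(np.array([r.z_um, r.y_um, r.x_um]) / pitch).astype(int)
            vox = np.clip(vox, 0, np.array(cells.labels.shape) - 1)
            host = int(cells.labels[tuple(vox)])
            if host > 0:
                nuc_vol_in_cell[host] += float(r.volume_um3)
        for lab, vn in nuc_vol_in_cell.items():
            if vn > 0:
                i = label_of[lab]
                denom = v[i] - vn
                nc[i] = vn / denom if denom > 0 else np.nan
    df["nc_ratio"] = nc
    return df
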