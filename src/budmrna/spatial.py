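"""Single-molecule spot statistics: compartment assignment, mRNA-protein
colocalization and transcription-site quantification.

Spot tables are pandas DataFrames with columns ``x_um, y_um, z_um,
intensity, channel, cell_id, is_ts`` (coordinates in micrometres).  Cells
are modelled as a mother and an optional bud ellipsoid fitted from 2-D
outline measurements: the short in-plane axis doubles as the z semi-axis,
and the z origin is aligned to the imaging stack by maximizing how many
detected spots fall inside the ellipsoid union.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

SPOT_COLUMNS = ["x_um", "y_um", "z_um", "intensity", "channel", "cell_id", "is_ts"]


@dataclass(frozen=True)
class Ellipsoid:
    center: tuple[float, float, float]  # um
    semi_axes: tuple[float, float, float]  # um

    def __post_init__(self) -> None:
        if min(self.semi_axes) <= 0:
            raise ValueError("semi-axes must be positive")

    def contains(self, xyz: np.ndarray) -> np.ndarray:
        """Standard normalized quadratic form <= 1 (vectorised)."""
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        q = ((xyz - np.array(self.center)) / np.array(self.semi_axes)) ** 2
        return q.sum(axis=1) <= 1.0


@dataclass(frozen=True)
class CellModel:
    mother: Ellipsoid
    bud: Ellipsoid | None = None
    z_origin: float = 0.0


def build_cell_model(
    mother_center_xy: tuple[float, float],
    mother_axes_xy: tuple[float, float],
    bud_center_xy: tuple[float, float] | None = None,
    bud_axes_xy: tuple[float, float] | None = None,
    spots: pd.DataFrame | None = None,
    z_range: tuple[float, float] = (0.0, 8.0),
    z_step: float = 0.05,
) -> CellModel:
    """Build mother/bud ellipsoids from 2-D axis measurements.

    ``*_axes_xy`` are full axis lengths (as measured on the outline); the z
    semi-axis is set to the shorter in-plane semi-axis.  The shared z origin
    is found by a grid search (default step 50 nm) maximizing the number of
    spots inside the ellipsoid union; without spots it defaults to the stack
    mid-plane.
    """

    def make(center_xy, axes_xy, z0):
        ax, ay = axes_xy[0] / 2.0, axes_xy[1] / 2.0
        az = min(ax, ay)
        return Ellipsoid((center_xy[0], center_xy[1], z0), (ax, ay, az))

    if (bud_center_xy is None) != (bud_axes_xy is None):
        raise ValueError("bud centre and axes must be given together")

    if spots is None or len(spots) == 0:
        z0 = 0.5 * (z_range[0] + z_range[1])
        mother = make(mother_center_xy, mother_axes_xy, z0)
        bud = make(bud_center_xy, bud_axes_xy, z0) if bud_center_xy is not None else None
        return CellModel(mother, bud, z0)

    xyz = spots[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
    z_mean = float(xyz[:, 2].mean())
    best = None
    for z0 in np.arange(z_range[0], z_range[1] + 0.5 * z_step, z_step):
        mother = make(mother_center_xy, mother_axes_xy, z0)
        inside = mother.contains(xyz)
        if bud_center_xy is not None:
            inside = inside | make(bud_center_xy, bud_axes_xy, z0).contains(xyz)
        n = int(inside.sum())
        # the inclusion count plateaus once every spot fits; break plateau
        # ties toward the spot centroid so the model stays centred
        score = (n, -abs(z0 - z_mean))
        if best is None or score > best[0]:
            best = (score, z0)
    z0 = best[1]
    mother = make(mother_center_xy, mother_axes_xy, z0)
    bud = make(bud_center_xy, bud_axes_xy, z0) if bud_center_xy is not None else None
    return CellModel(mother, bud, z0)


def assign_compartment(spots: pd.DataFrame, model: CellModel) -> np.ndarray:
    """Label each spot 'bud', 'mother' or 'outside'.

    A spot inside both ellipsoids (neck region) is assigned to the bud.
    """
    xyz = spots[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
    labels = np.full(len(spots), "outside", dtype=object)
    if len(spots) == 0:
        return labels
    in_mother = model.mother.contains(xyz)
    labels[in_mother] = "mother"
    if model.bud is not None:
        labels[model.bud.contains(xyz)] = "bud"
    return labels


@dataclass(frozen=True)
class ColocResult:
    pairs: list[tuple[int, int, float]]  # (mRNA row, protein row, distance nm)
    complexes: list[int]  # mRNA rows with >= 1 protein within radius
    n_mrna: int
    n_protein: int
    fraction_mrna_in_complex: float
    per_compartment: dict | None = None


def colocalize(
    mrna: pd.DataFrame,
    protein: pd.DataFrame,
    radius_nm: float = 250.0,
    labels: np.ndarray | None = None,
    project_2d: bool = False,
) -> ColocResult:
    """All-pairs 3-D Euclidean colocalization within ``radius_nm``.

    Several protein molecules within the radius of one mRNA still count as a
    single translation complex.  ``project_2d`` drops the z coordinate
    (maximal-projection variant).  ``labels`` (per-mRNA compartment labels)
    adds a per-compartment breakdown.
    """
    cols = ["x_um", "y_um"] if project_2d else ["x_um", "y_um", "z_um"]
    if len(mrna) == 0 or len(protein) == 0:
        return ColocResult([], [], len(mrna), len(protein), 0.0)
    a = mrna[cols].to_numpy(dtype=float) * 1000.0  # um -> nm, exact
    b = protein[cols].to_numpy(dtype=float) * 1000.0
    tree = cKDTree(b)
    pairs = []
    complexes = []
    for i, neighbours in enumerate(tree.query_ball_point(a, r=radius_nm)):
        if neighbours:
            complexes.append(i)
        for j in sorted(neighbours):
            d = float(np.linalg.norm(a[i] - b[j]))
            pairs.append((i, j, d))
    frac = len(complexes) / len(mrna)
    per_comp = None
    if labels is not None:
        labels = np.asarray(labels)
        per_comp = {}
        for comp in ("bud", "mother", "outside"):
            idx = np.flatnonzero(labels == comp)
            n_cplx = sum(1 for i in complexes if labels[i] == comp)
            per_comp[comp] = {
                "n_mrna": int(idx.size),
                "n_complex": n_cplx,
                "fraction": n_cplx / idx.size if idx.size else np.nan,
            }
    return ColocResult(pairs, complexes, len(mrna), len(protein), frac, per_comp)


def nascent_count(ts_intensity: float, single_molecule_intensities) -> float:
    """Nascent transcripts at a transcription site: TS intensity divided by
    the mean single-molecule intensity."""
    ref = np.asarray(list(single_molecule_intensities), dtype=float)
    if ref.size == 0:
        raise ValueError("need at least one single-molecule intensity")
    mean = ref.mean()
    if mean <= 0:
        raise ValueError("mean single-molecule intensity must be positive")
    return float(ts_intensity / mean)


def localization_summary(
    spots: pd.DataFrame,
    labels: np.ndarray,
    phases: dict | None = None,
) -> pd.DataFrame:
    """Per-cell totals, bud fractions and nascent counts, averaged per phase.

    Only expressing cells (>= 1 cytoplasmic mRNA) enter the means.  ``phases``
    maps cell_id -> phase label; without it all cells share one phase.
    """
    spots = spots.copy()
    spots["label"] = np.asarray(labels)
    rows = []
    for cell_id, grp in spots.groupby("cell_id", sort=True):
        cyto = grp[~grp["is_ts"].astype(bool)]
        n = len(cyto)
        if n == 0:
            continue
        bud_frac = float((cyto["label"] == "bud").sum() / n)
        ts = grp[grp["is_ts"].astype(bool)]
        nascent = (
            nascent_count(float(ts["intensity"].sum()), cyto["intensity"])
            if len(ts) and len(cyto)
            else 0.0
        )
        phase = phases.get(cell_id, "all") if phases else "all"
        rows.append(dict(cell_id=cell_id, phase=phase, n_mrna=n, bud_fraction=bud_frac, nascent=nascent))
    per_cell = pd.DataFrame(rows, columns=["cell_id", "phase", "n_mrna", "bud_fraction", "nascent"])
    if per_cell.empty:
        return pd.DataFrame(
            columns=["phase", "n_cells", "mean_mrna", "sd_mrna", "mean_bud_fraction", "sd_bud_fraction", "mean_nascent"]
        )
    agg = per_cell.groupby("phase", sort=True).agg(
        n_cells=("cell_id", "size"),
        mean_mrna=("n_mrna", "mean"),
        sd_mrna=("n_mrna", "std"),
        mean_bud_fraction=("bud_fraction", "mean"),
        sd_bud_fraction=("bud_fraction", "std"),
        mean_nascent=("nascent", "mean"),
    )
    return agg.reset_index()
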