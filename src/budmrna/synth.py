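"""Seeded synthetic data with the statistical structure the analyses assume.

Defaults follow the study conditions: G2 cells express a Poisson-distributed
~10.2 mature mRNAs (with ~2.9 nascent transcripts at the transcription
site), a fraction p = 0.6 of cytoplasmic mRNAs sit in the bud, a fraction
q = 0.25 of bud mRNAs have a protein focus within 250 nm, and budded-phase
durations are normal with means 48.2 min (wild type) and 53.5 min (zipcode
mutant) at ~600 cells per group.  Every generator is a pure function of its
arguments and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lineage import Detection
from .spatial import SPOT_COLUMNS, CellModel, Ellipsoid
from .transcript import Transcript

#: the minimal bud-localization (zipcode) element of the CLB2 mRNA
MINIMAL_ZIP = "AGCAGATGACTACGATATACAGTCTCGAACTCTTGCC"


# ---------------------------------------------------------------------------
# sequences


def gen_transcript(
    seed: int,
    background_length: int = 2000,
    gc_content: float = 0.40,
    implant: str | None = MINIMAL_ZIP,
    implant_pos: int = 1001,
) -> tuple[Transcript, tuple[int, int] | None]:
    """Random background sequence with the zipcode implanted at a known spot.

    The background is i.i.d. with the requested GC content; ``implant``
    overwrites the bases starting at 1-based ``implant_pos``.  CDS bounds are
    chosen so the implant is in frame.  Returns the transcript and the
    ground-truth implant interval (1-based, inclusive).
    """
    rng = np.random.default_rng(seed)
    if implant and background_length == 0:
        seq = implant.upper()
        implant_pos = 1
    else:
        p_gc = gc_content / 2.0
        p_at = (1.0 - gc_content) / 2.0
        seq = "".join(rng.choice(list("ACGT"), size=background_length, p=[p_at, p_gc, p_gc, p_at]))
        if implant:
            if implant_pos < 1 or implant_pos + len(implant) - 1 > background_length:
                raise ValueError("implant does not fit within the background")
            seq = seq[: implant_pos - 1] + implant.upper() + seq[implant_pos - 1 + len(implant) :]
    interval = (implant_pos, implant_pos + len(implant) - 1) if implant else None
    # put the implant in frame: cds_start congruent to implant_pos mod 3
    cds_start = (implant_pos - 1) % 3 + 1
    n_codons = (len(seq) - cds_start + 1) // 3
    cds_end = cds_start + 3 * n_codons - 1
    t = Transcript(id=f"synthetic_seed{seed}", seq=seq, cds_start=cds_start, cds_end=cds_end)
    return t, interval


# ---------------------------------------------------------------------------
# spot clouds


@dataclass(frozen=True)
class CellGeometry:
    """Mother/bud ellipsoids used for all synthetic cells (um)."""

    mother_center: tuple[float, float, float] = (0.0, 0.0, 4.0)
    mother_axes: tuple[float, float, float] = (2.0, 1.75, 1.75)  # semi-axes
    bud_center: tuple[float, float, float] = (3.0, 0.0, 4.0)
    bud_axes: tuple[float, float, float] = (1.2, 1.1, 1.1)

    def model(self) -> CellModel:
        return CellModel(
            mother=Ellipsoid(self.mother_center, self.mother_axes),
            bud=Ellipsoid(self.bud_center, self.bud_axes),
            z_origin=self.mother_center[2],
        )


def _uniform_in_ellipsoid(rng: np.random.Generator, ell: Ellipsoid, n: int) -> np.ndarray:
    """Rejection sampling of uniform points inside an ellipsoid."""
    out = np.empty((n, 3))
    got = 0
    axes = np.array(ell.semi_axes)
    center = np.array(ell.center)
    while got < n:
        cand = rng.uniform(-1.0, 1.0, size=(2 * (n - got) + 8, 3))
        keep = cand[(cand ** 2).sum(axis=1) <= 1.0]
        take = keep[: n - got]
        out[got : got + take.shape[0]] = center + take * axes
        got += take.shape[0]
    return out


def gen_cell_spots(
    seed: int,
    n_cells: int = 500,
    bud_fraction: float = 0.6,
    coloc_fraction: float = 0.25,
    mrna_mean: float = 10.2,
    nascent_mean: float = 2.9,
    protein_background: int = 10,
    jitter_sd_nm: float = 80.0,
    radius_nm: float = 250.0,
    geometry: CellGeometry | None = None,
) -> tuple[pd.DataFrame, CellModel, dict]:
    """Synthetic smFISH/IF spot tables for a population of budded cells.

    Each cell draws a Poisson number of mature mRNAs, placed uniformly in
    the bud with probability ``bud_fraction`` else in the mother; a fraction
    ``coloc_fraction`` of mRNAs receive a protein focus offset by
    |Normal(0, jitter)| <= radius in a random direction; the remaining
    protein spots are uniform in the cell.  Transcription-site spots carry
    Poisson nascent counts encoded in their intensity (single-molecule
    intensity 100).  Returns (spot table, cell model, ground truth).
    """
    if not (0 <= bud_fraction <= 1 and 0 <= coloc_fraction <= 1):
        raise ValueError("fractions must be in [0, 1]")
    geometry = geometry or CellGeometry()
    model = geometry.model()
    rng = np.random.default_rng(seed)
    single_intensity = 100.0
    rows = []
    for ci in range(n_cells):
        cell = f"cell{ci:05d}"
        n_mrna = rng.poisson(mrna_mean)
        in_bud = rng.random(n_mrna) < bud_fraction
        for k in range(n_mrna):
            ell = model.bud if in_bud[k] else model.mother
            xyz = _uniform_in_ellipsoid(rng, ell, 1)[0]
            inten = single_intensity * math.exp(rng.normal(0.0, 0.1))
            rows.append([*xyz, inten, "mRNA", cell, False])
            if rng.random() < coloc_fraction:
                while True:  # truncate |N(0, jitter)| at the pairing radius
                    d = abs(rng.normal(0.0, jitter_sd_nm)) / 1000.0
                    if d > radius_nm / 1000.0:
                        continue
                    direction = rng.normal(size=3)
                    direction /= np.linalg.norm(direction)
                    pos = xyz + d * direction
                    # keep the focus inside the cell (offsets near the wall
                    # would otherwise step outside)
                    if model.mother.contains(pos)[0] or model.bud.contains(pos)[0]:
                        break
                rows.append([*pos, single_intensity, "protein", cell, False])
        for xyz in _uniform_in_ellipsoid(rng, model.mother, protein_background):
            rows.append([*xyz, single_intensity, "protein", cell, False])
        # one nuclear transcription site per expressing cell
        if n_mrna > 0:
            ts_xyz = np.array(model.mother.center)
            nascent = rng.poisson(nascent_mean)
            rows.append([*ts_xyz, nascent * single_intensity, "mRNA", cell, True])
    spots = pd.DataFrame(rows, columns=SPOT_COLUMNS)
    truth = dict(
        bud_fraction=bud_fraction,
        coloc_fraction=coloc_fraction,
        mrna_mean=mrna_mean,
        nascent_mean=nascent_mean,
        seed=seed,
        n_cells=n_cells,
    )
    return spots, model, truth


# ---------------------------------------------------------------------------
# time-lapse detection streams


@dataclass(frozen=True)
class TimelapseSpec:
    groups: dict = field(
        default_factory=lambda: {"WT": (48.2, 8.0, 602), "ZIP": (53.5, 8.0, 694)}
    )  # name -> (mean min, sd min, n)
    frame_interval: float = 1.0  # minutes
    jitter_px: float = 2.0
    grid_spacing_px: float = 600.0  # >> matching threshold
    nucleus_prob: float = 0.9
    parent_area: float = 400.0
    bud_area: float = 150.0


def gen_timelapse(seed: int, spec: TimelapseSpec | None = None) -> dict:
    """Detection streams per group with known neck-track durations.

    Objects sit on a sparse grid and random-walk with per-frame jitter; a
    neck detection exists for exactly the drawn duration (truncated-normal
    minutes rounded to >= 1 frame); each neck carries a parent cell (larger,
    nucleus with probability ``nucleus_prob``) and a bud cell overlapping
    it.  Returns per-group detections and ground truth.
    """
    spec = spec or TimelapseSpec()
    rng = np.random.default_rng(seed)
    out = {}
    for gname, (mean, sd, n) in spec.groups.items():
        durations = []
        while len(durations) < n:
            d = rng.normal(mean, sd)
            if d > 0:
                durations.append(d)
        durations = np.array(durations)
        n_frames = np.maximum(1, np.round(durations / spec.frame_interval).astype(int))
        side = int(np.ceil(np.sqrt(n)))
        detections: list[Detection] = []
        truth = []
        for i in range(n):
            gx = (i % side) * spec.grid_spacing_px
            gy = (i // side) * spec.grid_spacing_px
            start = int(rng.integers(0, 5))
            x, y = gx, gy
            for f in range(start, start + int(n_frames[i])):
                x += rng.normal(0.0, spec.jitter_px)
                y += rng.normal(0.0, spec.jitter_px)
                detections.append(Detection(frame=f, id=i, centroid=(x, y), kind="neck"))
            truth.append(
                dict(
                    object=i,
                    start_frame=start,
                    n_frames=int(n_frames[i]),
                    duration_min=float(n_frames[i] * spec.frame_interval),
                    parent_nucleus=bool(rng.random() < spec.nucleus_prob),
                )
            )
        out[gname] = dict(detections=detections, truth=truth, mean=mean, sd=sd, n=n)
    out["seed"] = seed
    out["frame_interval"] = spec.frame_interval
    return out


# ---------------------------------------------------------------------------
# counts


def gen_counts(
    seed: int,
    n_cells: int = 1000,
    mature_mean: float = 10.2,
    nascent_mean: float = 2.9,
) -> dict:
    """Poisson per-cell mature counts and per-TS nascent counts."""
    if mature_mean <= 0 or nascent_mean <= 0:
        raise ValueError("means must be positive")
    rng = np.random.default_rng(seed)
    return dict(
        mature=rng.poisson(mature_mean, size=n_cells),
        nascent=rng.poisson(nascent_mean, size=n_cells),
        seed=seed,
    )
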