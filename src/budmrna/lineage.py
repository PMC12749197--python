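"""Time-lapse analytics: detection linking, budded-phase durations,
Bayesian parent-bud assignment and duration-distribution comparison.

The budded phase of a cell is read out as the lifetime of its septin-neck
signal: neck detections are linked into tracks across consecutive frames by
minimum-total-distance bipartite matching (edges only between detections
less than ``max_dist`` pixels apart), and the track length times the frame
interval is the phase duration.  When several cells overlap a neck, the
parent/bud ordering is resolved by a posterior built from independent
factors: relative area a_p/(a_p + a_b), a symmetric overlap weight
(o_i + o_j)/sum_k o_k, a factor 2 for a candidate with a fluorescent
nucleus, and zero probability for self-pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import linear_sum_assignment

_BIG = 1e12


@dataclass(frozen=True)
class Detection:
    frame: int
    id: int
    centroid: tuple[float, float]  # px
    area: float = 1.0  # px^2
    nucleus_flag: bool = False
    kind: str = "cell"  # or "neck"

    def __post_init__(self) -> None:
        if self.frame < 0:
            raise ValueError("frame must be >= 0")
        if self.kind == "cell" and self.area <= 0:
            raise ValueError("cell area must be positive")


@dataclass
class Track:
    detections: list[Detection] = field(default_factory=list)

    @property
    def frames(self) -> list[int]:
        return [d.frame for d in self.detections]

    @property
    def kind(self) -> str:
        return self.detections[0].kind if self.detections else "cell"

    def __len__(self) -> int:
        return len(self.detections)


def _match_frame_pair(prev: list[Detection], nxt: list[Detection], max_dist: float):
    """Minimum-total-distance bipartite matching with births/deaths.

    Dummy nodes absorb unmatched detections; edges of length >= max_dist are
    forbidden.  Returns list of (prev_index, next_index).
    """
    n, m = len(prev), len(nxt)
    if n == 0 or m == 0:
        return []
    C = np.full((n + m, n + m), 0.0)
    dist = np.array(
        [[np.hypot(p.centroid[0] - q.centroid[0], p.centroid[1] - q.centroid[1]) for q in nxt] for p in prev]
    )
    real = np.where(dist < max_dist, dist, _BIG)
    C[:n, :m] = real
    C[:n, m:] = _BIG
    C[n:, :m] = _BIG
    np.fill_diagonal(C[:n, m:], max_dist)  # death of prev detection
    np.fill_diagonal(C[n:, :m], max_dist)  # birth of next detection
    rows, cols = linear_sum_assignment(C)
    out = []
    for r, c in zip(rows, cols):
        if r < n and c < m and dist[r, c] < max_dist:
            out.append((r, c))
    return out


def link_detections(detections: list[Detection], max_dist: float = 200.0) -> list[Track]:
    """Link detections into tracks frame by frame.

    Detections are grouped by frame; each consecutive frame pair is matched
    by minimum-total-distance assignment restricted to edges shorter than
    ``max_dist`` px.  Unmatched detections terminate or start tracks.
    Deterministic: detections are processed in (frame, id) order.
    """
    if max_dist <= 0:
        raise ValueError("max_dist must be positive")
    by_frame: dict[int, list[Detection]] = {}
    for det in detections:
        by_frame.setdefault(det.frame, []).append(det)
    for dets in by_frame.values():
        dets.sort(key=lambda d: d.id)

    tracks: list[Track] = []
    active: dict[int, Track] = {}  # index into current frame's detections -> track
    prev_frame = None
    for frame in sorted(by_frame):
        dets = by_frame[frame]
        new_active: dict[int, Track] = {}
        if prev_frame is not None and frame == prev_frame + 1 and active:
            prev_dets = by_frame[prev_frame]
            matches = _match_frame_pair(prev_dets, dets, max_dist)
            matched_next = set()
            for (r, c) in matches:
                if r in active:
                    active[r].detections.append(dets[c])
                    new_active[c] = active[r]
                    matched_next.add(c)
            for c, det in enumerate(dets):
                if c not in matched_next:
                    t = Track([det])
                    tracks.append(t)
                    new_active[c] = t
        else:
            for c, det in enumerate(dets):
                t = Track([det])
                tracks.append(t)
                new_active[c] = t
        active = new_active
        prev_frame = frame
    return tracks


@dataclass(frozen=True)
class BuddedPhase:
    track: Track
    budding_frame: int
    n_frames: int
    duration_min: float


def budded_phases(
    neck_tracks: list[Track],
    frame_interval: float = 1.0,
    budding_overrides: dict[int, int] | None = None,
) -> list[BuddedPhase]:
    """Budded-phase durations from neck tracks.

    Duration is the number of frames in the track times the frame interval
    (minutes).  ``budding_overrides`` maps track index -> manually corrected
    budding frame (bud emergence seen in bright-field before the neck
    signal); the duration then runs from that frame to the track end.
    """
    out = []
    overrides = budding_overrides or {}
    for i, track in enumerate(neck_tracks):
        if len(track) == 0:
            warnings.warn(f"neck track {i} is empty; excluded")
            continue
        first, last = track.frames[0], track.frames[-1]
        budding = overrides.get(i, first)
        n = last - budding + 1
        if n <= 0:
            warnings.warn(f"neck track {i}: override after track end; excluded")
            continue
        out.append(BuddedPhase(track, budding, n, n * frame_interval))
    return out


@dataclass(frozen=True)
class ParentCandidate:
    id: int
    area: float  # px^2
    overlap: float  # px overlap with the neck
    nucleus_flag: bool = False

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise ValueError("area must be positive")
        if self.overlap < 0:
            raise ValueError("overlap must be >= 0")


def parent_bud_posterior(candidates: list[ParentCandidate]) -> dict[tuple[int, int], float]:
    """Normalized posterior over ordered (parent, bud) id pairs."""
    if len(candidates) < 2:
        raise ValueError("need at least two candidates")
    total_overlap = sum(c.overlap for c in candidates)
    raw = {}
    for p in candidates:
        for q in candidates:
            if p.id == q.id:
                continue  # self-matches have probability zero
            w = p.area / (p.area + q.area)
            if total_overlap > 0:
                w *= (p.overlap + q.overlap) / total_overlap
            if p.nucleus_flag:
                w *= 2.0
            raw[(p.id, q.id)] = w
    z = sum(raw.values())
    if z <= 0:
        raise ValueError("no valid parent-bud pair (all-zero posterior)")
    return {k: v / z for k, v in raw.items()}


def assign_parent_bud(candidates: list[ParentCandidate]):
    """Most probable ordered (parent_id, bud_id) pair and its posterior.

    Ties are broken toward the larger-area parent, then lowest ids.
    """
    post = parent_bud_posterior(candidates)
    area = {c.id: c.area for c in candidates}
    best = max(post.items(), key=lambda kv: (kv[1], area[kv[0][0]], -kv[0][0], -kv[0][1]))
    (parent, bud), prob = best
    return parent, bud, prob, post


def bootstrap_means(
    durations,
    n_boot: int = 10000,
    sample_size: int = 250,
    seed: int | None = None,
) -> np.ndarray:
    """Means of ``n_boot`` with-replacement samples of size ``sample_size``."""
    durations = np.asarray(list(durations), dtype=float)
    if durations.size == 0:
        raise ValueError("durations must be non-empty")
    if sample_size <= 0:
        raise ValueError("sample_size must be positive")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, durations.size, size=(n_boot, sample_size))
    return durations[idx].mean(axis=1)


@dataclass(frozen=True)
class DurationComparison:
    mean_a: float
    mean_b: float
    difference: float
    t: float
    p: float


def compare_durations(group_a, group_b, equal_var: bool = False) -> DurationComparison:
    """Two-sided two-sample t-test on budded-phase durations (Welch by
    default; pooled variance with ``equal_var=True``)."""
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return DurationComparison(a.mean(), b.mean(), 0.0, 0.0, 1.0)
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return DurationComparison(
        float(a.mean()), float(b.mean()), float(b.mean() - a.mean()), float(t), float(p)
    )
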