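"""Systematic-uniform-random sampling hierarchy and the unbiased counting frame.

The hierarchy mirrors routine EM stereology practice: a serial series of
ultrathin sections is subsampled as an arithmetic progression with a uniformly
random start (SUR), fields are placed along a sampling line with a random
phase inside each cortical layer band, and profiles are counted inside an
unbiased counting frame: two adjacent *exclusion* edges (left + bottom) whose
touch forbids counting, two *inclusion* edges (right + top) whose touch does
not.  Ties at corners follow the exclusion edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .tissue import PROFILE_COLUMNS

__all__ = [
    "SamplingPlan",
    "CountingFrame",
    "FrameSample",
    "select_sections",
    "place_frames",
    "count_in_frame",
    "frames_to_table",
    "FRAME_SIDE_UM",
]

#: counting-frame side used throughout the study design (area 14.9769 um^2,
#: the exact product, not the rounded ~15 um^2)
FRAME_SIDE_UM = 3.87


@dataclass(frozen=True)
class SamplingPlan:
    """Design constants of the sampling hierarchy."""

    bregma_range_mm: tuple[float, float] = (3.2, 2.2)
    vibratome_thickness_um: float = 80.0
    ultrathin_thickness_nm: float = 60.0
    ultrathin_period: int = 5  # every k-th ultrathin section collected
    sections_per_animal: int = 10
    fields_per_layer_per_section: int = 10
    frame_side_um: float = FRAME_SIDE_UM

    def __post_init__(self) -> None:
        if self.ultrathin_period < 1:
            raise ValueError("ultrathin_period must be >= 1")
        if self.sections_per_animal < 1 or self.fields_per_layer_per_section < 1:
            raise ValueError("section and field counts must be >= 1")


@dataclass(frozen=True)
class CountingFrame:
    """Axis-aligned unbiased counting frame."""

    origin: tuple[float, float]  # (x, y) um, lower-left corner
    width: float = FRAME_SIDE_UM
    height: float = FRAME_SIDE_UM

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("frame sides must be positive")

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        x0, y0 = self.origin
        return x0, y0, x0 + self.width, y0 + self.height


@dataclass
class FrameSample:
    """Counts and measured lengths observed in one counting frame."""

    frame: CountingFrame
    layer: str
    n_asym: int = 0
    n_sym: int = 0
    n_axon: int = 0
    excluded_count: int = 0
    n_terminals: int | None = None
    counted: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def n_synapses(self) -> int:
        return self.n_asym + self.n_sym


def select_sections(
    series_length: int, plan: SamplingPlan, seed: int | np.random.Generator = 0
) -> list[int]:
    """SUR selection of ultrathin sections: arithmetic progression of period
    ``plan.ultrathin_period`` with a uniformly random start in [0, period)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    k, n = plan.ultrathin_period, plan.sections_per_animal
    required = (n - 1) * k + k  # start may be as large as k-1
    if series_length < required:
        raise ValueError(
            f"serial series of {series_length} sections is too short: "
            f"need at least {required} for {n} sections at period {k}"
        )
    start = int(rng.integers(0, k))
    return [start + i * k for i in range(n)]


def place_frames(
    section_width: float,
    band: tuple[float, float],
    plan: SamplingPlan,
    seed: int | np.random.Generator = 0,
    n_frames: int | None = None,
) -> list[CountingFrame]:
    """Place non-overlapping frames on a sampling line inside a layer band.

    Frames sit on one horizontal line at a random height within the band and
    are spread along x with equal pitch and a random phase; when the band
    fits exactly the requested number, this degenerates to a tiling with
    random phase.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    w = plan.frame_side_um
    f = plan.fields_per_layer_per_section if n_frames is None else n_frames
    y0, y1 = band
    if y1 - y0 < w:
        raise ValueError(
            f"layer band of height {y1 - y0:.2f} um cannot hold a {w:.2f} um frame"
        )
    pitch = section_width / f
    if pitch < w:
        max_f = int(section_width // w)
        raise ValueError(
            f"section width {section_width:.2f} um fits at most {max_f} "
            f"non-overlapping frames of side {w:.2f}; requested {f} — request fewer frames"
        )
    phase = float(rng.uniform(0.0, pitch - w)) if pitch > w else 0.0
    y = float(rng.uniform(y0, y1 - w)) if y1 - y0 > w else y0
    return [CountingFrame(origin=(phase + i * pitch, y), width=w, height=w) for i in range(f)]


# ---------------------------------------------------------------------------
# counting rule
# ---------------------------------------------------------------------------


def _segments_hit_rect(x1, y1, x2, y2, b):
    """Closed segment vs closed axis-aligned rectangle intersection (Liang–Barsky)."""
    x0, y0, xr, yt = b
    dx, dy = x2 - x1, y2 - y1
    t0 = np.zeros_like(x1)
    t1 = np.ones_like(x1)
    ok = np.ones(x1.shape, dtype=bool)
    for p, q in (
        (-dx, x1 - x0),
        (dx, xr - x1),
        (-dy, y1 - y0),
        (dy, yt - y1),
    ):
        zero = p == 0
        ok &= ~(zero & (q < 0))  # parallel and outside this half-plane
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(zero, 0.0, q / np.where(zero, 1.0, p))
        t0 = np.where(~zero & (p < 0), np.maximum(t0, r), t0)
        t1 = np.where(~zero & (p > 0), np.minimum(t1, r), t1)
    return ok & (t0 <= t1)


def _segments_hit_vline(x1, y1, x2, y2, xe, ya, yb):
    """Closed segment vs closed vertical edge segment x=xe, y in [ya, yb]."""
    dx = x2 - x1
    vertical = dx == 0
    out = np.zeros(x1.shape, dtype=bool)
    # non-vertical: parameter t where segment crosses x = xe
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(vertical, 0.0, (xe - x1) / np.where(vertical, 1.0, dx))
    yc = y1 + t * (y2 - y1)
    out |= (~vertical) & (t >= 0) & (t <= 1) & (yc >= ya) & (yc <= yb)
    # collinear vertical segments on the edge line: overlap in y
    ylo = np.minimum(y1, y2)
    yhi = np.maximum(y1, y2)
    out |= vertical & (x1 == xe) & (yhi >= ya) & (ylo <= yb)
    return out


def _segments_hit_hline(x1, y1, x2, y2, ye, xa, xb):
    return _segments_hit_vline(y1, x1, y2, x2, ye, xa, xb)


def _point_seg_dist(px, py, ax, ay, bx, by):
    """Distance from points to a segment (vectorised over points)."""
    abx, aby = bx - ax, by - ay
    denom = abx * abx + aby * aby
    t = np.clip(((px - ax) * abx + (py - ay) * aby) / denom, 0.0, 1.0) if denom > 0 else 0.0
    cx, cy = ax + t * abx, ay + t * aby
    return np.hypot(px - cx, py - cy)


def count_in_frame(
    profiles: pd.DataFrame | Sequence, frame: CountingFrame, layer: str | None = None
) -> FrameSample:
    """Apply the unbiased counting-frame rule to a profile table.

    A profile is counted iff its trace (segment for synapses, circle for
    axon profiles) meets the closed frame and does not touch the left or
    bottom (exclusion) edge.  ``excluded_count`` tallies traces that met the
    frame but touched an exclusion edge.
    """
    df = _as_profile_frame(profiles)
    x0, y0, xr, yt = frame.bounds
    if len(df) == 0:
        return FrameSample(frame=frame, layer=layer or "", counted=df)

    is_axon = (df["type"] == "axon").to_numpy()
    x1 = df["x1_um"].to_numpy(float)
    y1 = df["y1_um"].to_numpy(float)
    x2 = df["x2_um"].to_numpy(float)
    y2 = df["y2_um"].to_numpy(float)
    r = df["radius_um"].to_numpy(float)
    px = df["x_um"].to_numpy(float)
    py = df["y_um"].to_numpy(float)

    hit = np.zeros(len(df), dtype=bool)
    excl = np.zeros(len(df), dtype=bool)

    seg = ~is_axon
    if seg.any():
        hit_s = _segments_hit_rect(x1[seg], y1[seg], x2[seg], y2[seg], frame.bounds)
        left = _segments_hit_vline(x1[seg], y1[seg], x2[seg], y2[seg], x0, y0, yt)
        bottom = _segments_hit_hline(x1[seg], y1[seg], x2[seg], y2[seg], y0, x0, xr)
        hit[seg] = hit_s
        excl[seg] = left | bottom
    if is_axon.any():
        cxp, cyp, rr = px[is_axon], py[is_axon], r[is_axon]
        # circle meets closed rectangle iff centre within rect dilated by r
        qx = np.clip(cxp, x0, xr)
        qy = np.clip(cyp, y0, yt)
        hit_c = np.hypot(cxp - qx, cyp - qy) <= rr
        left = _point_seg_dist(cxp, cyp, x0, y0, x0, yt) <= rr
        bottom = _point_seg_dist(cxp, cyp, x0, y0, xr, y0) <= rr
        hit[is_axon] = hit_c
        excl[is_axon] = left | bottom

    counted_mask = hit & ~excl
    counted = df.loc[counted_mask]
    types = counted["type"]
    return FrameSample(
        frame=frame,
        layer=layer if layer is not None else _dominant_layer(counted),
        n_asym=int((types == "asymmetric").sum()),
        n_sym=int((types == "symmetric").sum()),
        n_axon=int((types == "axon").sum()),
        excluded_count=int((hit & excl).sum()),
        counted=counted.reset_index(drop=True),
    )


def _dominant_layer(df: pd.DataFrame) -> str:
    if len(df) == 0:
        return ""
    return df["layer"].mode().iloc[0]


def _as_profile_frame(profiles) -> pd.DataFrame:
    if isinstance(profiles, pd.DataFrame):
        return profiles
    # sequence of Profile dataclasses: build degenerate point-segment rows
    rows = []
    for p in profiles:
        half = p.junction_length / 2000.0
        rows.append(
            {
                "object_id": p.object_id,
                "type": p.type,
                "layer": p.layer,
                "x_um": p.position[0],
                "y_um": p.position[1],
                "x1_um": p.position[0] - half,
                "y1_um": p.position[1],
                "x2_um": p.position[0] + half,
                "y2_um": p.position[1],
                "junction_length_nm": p.junction_length,
                "terminal_membrane_length_nm": p.terminal_membrane_length,
                "radius_um": 0.0,
                "perforated": p.perforated,
            }
        )
    if not rows:
        return pd.DataFrame(columns=PROFILE_COLUMNS)
    return pd.DataFrame(rows)[PROFILE_COLUMNS]


def frames_to_table(
    samples: Sequence[FrameSample],
    animal_id: str = "",
    group: str = "",
    section: int = 0,
) -> pd.DataFrame:
    """Flatten FrameSamples to the frame-level CSV schema."""
    return pd.DataFrame(
        {
            "animal_id": animal_id,
            "group": group,
            "section": section,
            "layer": [s.layer for s in samples],
            "frame_index": range(len(samples)),
            "n_asym": [s.n_asym for s in samples],
            "n_sym": [s.n_sym for s in samples],
            "n_axon": [s.n_axon for s in samples],
            "n_terminals": [(-1 if s.n_terminals is None else s.n_terminals) for s in samples],
            "excluded": [s.excluded_count for s in samples],
            "frame_area_um2": [s.frame.area for s in samples],
        }
    )
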