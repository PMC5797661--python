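"""Density, volume and total-number estimators.

* **size-frequency**: N_V = N_A / d̄, profile areal density divided by the
  mean profile size.  For synapses d̄ is the mean junction trace; for
  myelinated axons it is the mean profile diameter.  d̄ is pooled per animal
  across sections and layers (per-layer pooling available via filtering the
  input frame samples).
* **physical disector**: N_V = Q⁻ / (A·h), tops counted between a reference
  and a look-up section — retained as the independent cross-check of the
  size-frequency estimate.
* **Cavalieri**: V = Σ areas × section thickness × sampling period, the
  classical unbiased volume estimate from a systematically sampled series.
* **total number** = density × volume (with exact unit conversion
  1 mm³ = 10⁹ μm³).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .sampling import CountingFrame, FrameSample, count_in_frame
from .tissue import UM3_PER_MM3

__all__ = [
    "DensityEstimate",
    "VolumeEstimate",
    "size_frequency_density",
    "disector_density",
    "cavalieri_volume",
    "total_number",
]

ProfileType = Literal["asymmetric", "symmetric", "axon", "all"]


@dataclass(frozen=True)
class DensityEstimate:
    type: ProfileType
    N_A: float  # profiles / um^2
    d_bar: float | None  # mean profile length, um (None when no profiles seen)
    N_V: float  # objects / um^3
    n_frames: int
    total_area: float  # um^2


@dataclass(frozen=True)
class VolumeEstimate:
    layer_bin: str
    areas: tuple[float, ...]  # um^2 per measured section
    section_thickness: float  # um
    period: int
    volume: float  # mm^3


def _counts_and_lengths(samples: Sequence[FrameSample], type_: str):
    """Pooled count and per-profile sizes (um) for one profile type.

    Perforated profiles contribute to counts but not to the type-specific
    length mean.
    """
    count = 0
    lengths: list[np.ndarray] = []
    all_lengths: list[np.ndarray] = []
    for s in samples:
        if type_ == "asymmetric":
            count += s.n_asym
        elif type_ == "symmetric":
            count += s.n_sym
        else:
            count += s.n_axon
        if len(s.counted):
            sub = s.counted[s.counted["type"] == type_]
            if type_ != "axon":
                vals_all = sub["junction_length_nm"].to_numpy(float) / 1000.0
                vals = (
                    sub.loc[~sub["perforated"].astype(bool), "junction_length_nm"]
                    .to_numpy(float) / 1000.0
                )
            else:
                vals_all = vals = 2.0 * sub["radius_um"].to_numpy(float)
            if len(vals):
                lengths.append(vals)
            if len(vals_all):
                all_lengths.append(vals_all)
    pooled = np.concatenate(lengths) if lengths else np.empty(0)
    if len(pooled) == 0 and all_lengths:
        # every counted profile was perforated: use them for the size term
        pooled = np.concatenate(all_lengths)
    return count, pooled


def size_frequency_density(
    samples: Sequence[FrameSample], type_: ProfileType = "asymmetric"
) -> DensityEstimate:
    """Size-frequency numerical density from counting-frame samples.

    ``type_="all"`` is defined as the sum of the asymmetric and symmetric
    estimates so that the additivity identity density(all) =
    density(asym) + density(sym) holds exactly.
    """
    if not samples:
        raise ValueError("at least one frame sample is required")
    total_area = sum(s.frame.area for s in samples)
    if total_area <= 0:
        raise ValueError("total sampled frame area is zero")

    if type_ == "all":
        a = size_frequency_density(samples, "asymmetric")
        s_ = size_frequency_density(samples, "symmetric")
        d_bars = [d for d in (a.d_bar, s_.d_bar) if d is not None]
        return DensityEstimate(
            type="all",
            N_A=a.N_A + s_.N_A,
            d_bar=float(np.mean(d_bars)) if d_bars else None,
            N_V=a.N_V + s_.N_V,
            n_frames=len(samples),
            total_area=total_area,
        )

    count, lengths = _counts_and_lengths(samples, type_)
    N_A = count / total_area
    if count == 0:
        return DensityEstimate(type_, 0.0, None, 0.0, len(samples), total_area)
    if len(lengths) == 0:
        raise ValueError(f"no measurable profile lengths for type {type_!r}")
    d_bar = float(lengths.mean())
    return DensityEstimate(type_, N_A, d_bar, N_A / d_bar, len(samples), total_area)


def disector_density(
    reference: pd.DataFrame,
    lookup: pd.DataFrame,
    frame: CountingFrame,
    h: float,
    type_: ProfileType = "asymmetric",
) -> DensityEstimate:
    """Physical-disector density from a registered section pair.

    Q⁻ counts objects whose profile is counted in the reference frame and
    that yield no profile at all in the look-up section; h is the mid-plane
    separation in micrometres.
    """
    if h <= 0:
        raise ValueError("disector height h must be > 0")
    ref = reference if type_ == "all" else reference[reference["type"] == type_]
    sample = count_in_frame(ref, frame)
    present = set(lookup["object_id"].tolist())
    if len(sample.counted):
        q_minus = int((~sample.counted["object_id"].isin(present)).sum())
    else:
        q_minus = 0
    N_V = q_minus / (frame.area * h)
    return DensityEstimate(
        type=type_,
        N_A=len(sample.counted) / frame.area,
        d_bar=None,
        N_V=N_V,
        n_frames=1,
        total_area=frame.area,
    )


def cavalieri_volume(
    areas: Sequence[float],
    thickness: float,
    period: int,
    layer_bin: str = "total",
) -> VolumeEstimate:
    """Cavalieri volume from a systematically sampled area series (result in mm³)."""
    areas = tuple(float(a) for a in areas)
    if len(areas) == 0:
        raise ValueError("area series is empty")
    if any(a < 0 for a in areas):
        raise ValueError("areas must be non-negative")
    if thickness <= 0 or period <= 0:
        raise ValueError("thickness and period must be positive")
    vol_um3 = sum(areas) * thickness * period
    return VolumeEstimate(
        layer_bin=layer_bin,
        areas=areas,
        section_thickness=thickness,
        period=int(period),
        volume=vol_um3 / UM3_PER_MM3,
    )


def total_number(density: float, volume_mm3: float) -> float:
    """Total object count = density (n/μm³) × volume (mm³) × 10⁹."""
    if density < 0 or volume_mm3 < 0:
        raise ValueError("density and volume must be non-negative")
    return density * volume_mm3 * UM3_PER_MM3
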