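"""Germ-grain simulation of layered cortical neuropil and virtual ultrathin sectioning.

The tissue block is a rectangular box (x, y, z in micrometres).  The y axis is
cortical depth and is partitioned into layer bands (agranular cortex: layers
I, II, III, V, VI).  The z axis is the sectioning axis, mimicking the serial
ultramicrotome cut.  Three object populations are laid down as independent
Poisson processes within each layer band:

* **synaptic junction disks** (asymmetric / Type I and symmetric / Type II):
  flat circular disks with isotropic (or partially axis-aligned) normals.
  A section plane that hits a disk produces a line-segment trace whose length
  is the chord of the disk at the plane — the "synaptic junction length"
  an electron microscopist would measure.
* **axon terminal bodies**: not simulated as explicit geometry; each synapse
  object carries a terminal extent, and a sectioned profile's terminal
  membrane trace is the chord of a virtual disk of that extent at a uniform
  random offset (mean trace = π/4 × extent).
* **myelinated axons**: z-aligned cylinders whose segment height equals their
  diameter, so the sectional profile is a circle and the caliper height along
  z equals the diameter (the size term used by the size-frequency method).

All randomness flows through :class:`numpy.random.Generator` seeded
explicitly; identical seed and configuration give bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterator, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LayerSpec",
    "DistributionSpec",
    "TissueModel",
    "SynapticObject",
    "UltrathinSection",
    "Profile",
    "ObjectPopulation",
    "SectionPlan",
    "simulate_block",
    "cut_sections",
    "disk_chord",
    "disk_mean_diameter_for_trace",
    "default_tissue_model",
    "compact_tissue_model",
    "PROFILE_COLUMNS",
]

LAYER_NAMES = ("I", "II", "III", "V", "VI")

#: micrometres per millimetre cubed conversion: 1 mm^3 = 1e9 um^3
UM3_PER_MM3 = 1.0e9


@dataclass(frozen=True)
class LayerSpec:
    """One cortical layer band: its share of block depth and object intensities."""

    name: str
    depth_fraction: float
    density_asym: float  # objects / um^3
    density_sym: float
    density_axon: float

    def __post_init__(self) -> None:
        if self.depth_fraction <= 0:
            raise ValueError(f"layer {self.name}: depth_fraction must be > 0")
        for attr in ("density_asym", "density_sym", "density_axon"):
            if getattr(self, attr) < 0:
                raise ValueError(f"layer {self.name}: {attr} must be >= 0")


@dataclass(frozen=True)
class DistributionSpec:
    """Positive size distribution given by family, mean (nm) and coefficient of variation."""

    family: Literal["lognormal", "normal", "constant"] = "lognormal"
    mean: float = 250.0  # nm
    cv: float = 0.2

    def __post_init__(self) -> None:
        if self.mean <= 0:
            raise ValueError("distribution mean must be > 0")
        if self.cv < 0:
            raise ValueError("distribution CV must be >= 0")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.family == "constant" or self.cv == 0:
            return np.full(n, self.mean)
        if self.family == "lognormal":
            sigma2 = math.log(1.0 + self.cv**2)
            mu = math.log(self.mean) - sigma2 / 2.0
            return rng.lognormal(mu, math.sqrt(sigma2), n)
        if self.family == "normal":
            out = rng.normal(self.mean, self.cv * self.mean, n)
            # sizes are physical lengths; reflect the (rare) negative tail
            return np.abs(out)
        raise ValueError(f"unknown distribution family {self.family!r}")


@dataclass(frozen=True)
class TissueModel:
    """Full configuration of the synthetic block (the ground truth estimators must recover)."""

    layers: tuple[LayerSpec, ...]
    block_dims: tuple[float, float, float]  # (x, y, z) um
    disk_diameter_dist: DistributionSpec
    terminal_size_dist: DistributionSpec
    axon_diameter_dist: DistributionSpec
    orientation: float = 0.0  # weight of z-aligned disk normals; 0 = isotropic
    perforated_rate: float = 0.075
    #: germs are laid down in a domain dilated by this margin so that the
    #: observed block sees the stationary profile intensity right up to its
    #: faces (no edge deficit from truncating the point process)
    edge_padding_um: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.block_dims):
            raise ValueError("block_dims must be strictly positive")
        total = sum(l.depth_fraction for l in self.layers)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"layer depth fractions must sum to 1 (got {total})")
        if not 0.0 <= self.orientation <= 1.0:
            raise ValueError("orientation weight must lie in [0, 1]")
        if not 0.0 <= self.perforated_rate <= 1.0:
            raise ValueError("perforated_rate must lie in [0, 1]")

    # -- layer geometry helpers -------------------------------------------------
    def layer_bands(self) -> dict[str, tuple[float, float]]:
        """y interval (um) occupied by each layer, ordered from y=0 downward."""
        bands: dict[str, tuple[float, float]] = {}
        y0 = 0.0
        for layer in self.layers:
            y1 = y0 + layer.depth_fraction * self.block_dims[1]
            bands[layer.name] = (y0, y1)
            y0 = y1
        return bands

    def layer_of_y(self, y: np.ndarray) -> np.ndarray:
        """Layer name for each y coordinate."""
        edges = np.cumsum([l.depth_fraction for l in self.layers]) * self.block_dims[1]
        idx = np.searchsorted(edges, y, side="right")
        idx = np.clip(idx, 0, len(self.layers) - 1)
        names = np.array([l.name for l in self.layers])
        return names[idx]

    def mean_density(self, kind: str) -> float:
        """Volume-weighted whole-block density for 'asym', 'sym' or 'axon'."""
        return sum(l.depth_fraction * getattr(l, f"density_{kind}") for l in self.layers)


@dataclass(frozen=True)
class SynapticObject:
    """A single germ: disk (synapse) or cylinder segment (axon)."""

    center: tuple[float, float, float]  # um
    diameter: float  # nm
    normal: tuple[float, float, float]
    type: Literal["asymmetric", "symmetric", "axon"]
    perforated: bool = False
    terminal_extent: float = 0.0  # nm


@dataclass(frozen=True)
class UltrathinSection:
    """One virtual ultrathin section (a z-slab)."""

    index: int  # position in the full serial series
    z_position: float  # um, lower face of the slab
    thickness: float = 60.0  # nm
    parent_vibratome_section: int = 0

    @property
    def z_mid(self) -> float:
        return self.z_position + self.thickness / 2000.0  # um


@dataclass(frozen=True)
class Profile:
    """A sectioned 2D trace as it would be measured on an electron micrograph."""

    type: Literal["asymmetric", "symmetric", "axon"]
    position: tuple[float, float]  # um in the section plane
    layer: str
    junction_length: float = 0.0  # nm, synapse types only
    terminal_membrane_length: float = 0.0  # nm, synapse types only
    perforated: bool = False
    object_id: int = -1


#: canonical column set of a profile table (one row per sectioned trace)
PROFILE_COLUMNS = [
    "object_id",
    "type",
    "layer",
    "x_um",
    "y_um",
    "x1_um",
    "y1_um",
    "x2_um",
    "y2_um",
    "junction_length_nm",
    "terminal_membrane_length_nm",
    "radius_um",
    "perforated",
]


class ObjectPopulation(Sequence):
    """Array-backed sequence of :class:`SynapticObject` (fast bulk operations,
    object views on demand)."""

    _TYPES = np.array(["asymmetric", "symmetric", "axon"])

    def __init__(
        self,
        centers: np.ndarray,
        diameters_nm: np.ndarray,
        normals: np.ndarray,
        type_codes: np.ndarray,
        perforated: np.ndarray,
        terminal_extents_nm: np.ndarray,
        model: TissueModel,
    ) -> None:
        self.centers = centers
        self.diameters_nm = diameters_nm
        self.normals = normals
        self.type_codes = type_codes
        self.perforated = perforated
        self.terminal_extents_nm = terminal_extents_nm
        self.model = model

    def __len__(self) -> int:
        return len(self.diameters_nm)

    def __getitem__(self, i):
        if isinstance(i, slice):
            return [self[j] for j in range(*i.indices(len(self)))]
        return SynapticObject(
            center=tuple(self.centers[i]),
            diameter=float(self.diameters_nm[i]),
            normal=tuple(self.normals[i]),
            type=str(self._TYPES[self.type_codes[i]]),
            perforated=bool(self.perforated[i]),
            terminal_extent=float(self.terminal_extents_nm[i]),
        )

    def __iter__(self) -> Iterator[SynapticObject]:
        for i in range(len(self)):
            yield self[i]

    def counts_by_type(self) -> dict[str, int]:
        return {t: int(np.sum(self.type_codes == c)) for c, t in enumerate(self._TYPES)}


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


def _isotropic_normals(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit vectors uniform on the sphere (z-component uniform on [-1, 1])."""
    nz = rng.uniform(-1.0, 1.0, n)
    phi = rng.uniform(0.0, 2.0 * math.pi, n)
    s = np.sqrt(1.0 - nz**2)
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), nz])


def simulate_block(model: TissueModel, seed: int | None = None) -> ObjectPopulation:
    """Lay down the Poisson object populations layer by layer.

    Counts per layer are Poisson with mean ``density x layer volume``;
    positions are uniform in the layer band; synapse type is fixed by which
    intensity generated the point.
    """
    if seed is None:
        seed = model.seed
    rng = np.random.default_rng(seed)
    x_dim, y_dim, z_dim = model.block_dims
    if x_dim * y_dim * z_dim <= 0:
        raise ValueError("block volume must be positive")

    centers, diam, normals, codes, perf, text = [], [], [], [], [], []
    bands = model.layer_bands()
    pad = model.edge_padding_um
    first, last = model.layers[0].name, model.layers[-1].name
    for layer in model.layers:
        y0, y1 = bands[layer.name]
        # dilate the outer faces only; internal layer boundaries stay sharp
        ylo = y0 - pad if layer.name == first else y0
        yhi = y1 + pad if layer.name == last else y1
        vol = (x_dim + 2 * pad) * (yhi - ylo) * (z_dim + 2 * pad)
        for code, (dens, size_dist) in enumerate(
            [
                (layer.density_asym, model.disk_diameter_dist),
                (layer.density_sym, model.disk_diameter_dist),
                (layer.density_axon, model.axon_diameter_dist),
            ]
        ):
            n = int(rng.poisson(dens * vol))
            if n == 0:
                continue
            c = np.column_stack(
                [
                    rng.uniform(-pad, x_dim + pad, n),
                    rng.uniform(ylo, yhi, n),
                    rng.uniform(-pad, z_dim + pad, n),
                ]
            )
            d = size_dist.sample(n, rng)
            if code == 2:  # axon: z-aligned cylinder
                nv = np.tile([0.0, 0.0, 1.0], (n, 1))
                p = np.zeros(n, dtype=bool)
                te = np.zeros(n)
            else:
                nv = _isotropic_normals(n, rng)
                if model.orientation > 0:
                    aligned = rng.random(n) < model.orientation
                    nv[aligned] = [0.0, 0.0, 1.0]
                p = (
                    (rng.random(n) < model.perforated_rate)
                    if code == 0
                    else np.zeros(n, dtype=bool)
                )
                te = model.terminal_size_dist.sample(n, rng)
            centers.append(c)
            diam.append(d)
            normals.append(nv)
            codes.append(np.full(n, code, dtype=np.int8))
            perf.append(p)
            text.append(te)

    if not centers:
        empty3 = np.empty((0, 3))
        return ObjectPopulation(
            empty3, np.empty(0), empty3, np.empty(0, dtype=np.int8),
            np.empty(0, dtype=bool), np.empty(0), model,
        )
    return ObjectPopulation(
        np.concatenate(centers),
        np.concatenate(diam),
        np.concatenate(normals),
        np.concatenate(codes),
        np.concatenate(perf),
        np.concatenate(text),
        model,
    )


# ---------------------------------------------------------------------------
# sectioning
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SectionPlan:
    """Which ultrathin sections of the serial series are examined.

    ``indices`` are positions in the full series of consecutive 60-nm cuts
    (index i occupies z in [i*t, (i+1)*t]).  ``vibratome_thickness`` is only
    used to label the parent thick section.
    """

    indices: tuple[int, ...]
    thickness_nm: float = 60.0
    vibratome_thickness_um: float = 80.0
    section_model: Literal["midplane", "slab"] = "midplane"

    def __post_init__(self) -> None:
        if self.thickness_nm <= 0:
            raise ValueError("section thickness must be > 0")
        if len(set(self.indices)) != len(self.indices):
            raise ValueError("section indices must be distinct (non-overlapping slabs)")
        if list(self.indices) != sorted(self.indices):
            raise ValueError("section indices must be ordered")

    def sections(self) -> list[UltrathinSection]:
        t_um = self.thickness_nm / 1000.0
        per_vib = max(1, int(round(self.vibratome_thickness_um / t_um)))
        return [
            UltrathinSection(
                index=i,
                z_position=i * t_um,
                thickness=self.thickness_nm,
                parent_vibratome_section=i // per_vib,
            )
            for i in self.indices
        ]


def disk_chord(diameter: float, offset: float) -> float:
    """Chord length of a circle of the given diameter at a centre offset.

    Zero when the offset reaches or exceeds the radius.
    """
    r = diameter / 2.0
    if abs(offset) >= r:
        return 0.0
    return 2.0 * math.sqrt(r * r - offset * offset)


def disk_mean_diameter_for_trace(mean_trace_nm: float, cv: float) -> float:
    """Disk diameter mean that yields a given mean sectional trace length.

    For isotropic disks hit by a plane, hit probability is proportional to
    D·sin(alpha) and the conditional mean chord is πD/4, so the pooled trace
    mean is (π/4)·E[D²]/E[D] = (π/4)·μ_D·(1+CV²); invert for μ_D.
    """
    return mean_trace_nm * 4.0 / math.pi / (1.0 + cv**2)


def _section_profiles(
    pop: ObjectPopulation,
    section: UltrathinSection,
    rng: np.random.Generator,
    section_model: str,
) -> pd.DataFrame:
    """Vectorised intersection of the whole population with one slab."""
    z_mid = section.z_mid
    t_um = section.thickness / 1000.0
    z_lo, z_hi = section.z_position, section.z_position + t_um

    cx, cy, cz = pop.centers.T if len(pop) else (np.empty(0),) * 3
    rows: list[pd.DataFrame] = []

    # ---- synaptic disks -----------------------------------------------------
    syn = pop.type_codes < 2
    if syn.any():
        nx, ny, nz = pop.normals[syn].T
        D_um = pop.diameters_nm[syn] / 1000.0
        R = D_um / 2.0
        scx, scy, scz = cx[syn], cy[syn], cz[syn]
        s = np.sqrt(np.maximum(1.0 - nz**2, 0.0))
        ok = s > 1e-12

        if section_model == "midplane":
            plane_z = np.full(len(R), z_mid)
        else:  # slab: any overlap; chord taken at the in-slab plane nearest centre
            half = R * s
            overlap = (scz + half >= z_lo) & (scz - half <= z_hi)
            plane_z = np.clip(scz, z_lo, z_hi)
            ok &= overlap
        d_plane = np.where(ok, np.abs(scz - plane_z) / np.where(ok, s, 1.0), np.inf)
        hit = ok & (d_plane < R)
        if hit.any():
            idx = np.flatnonzero(syn)[hit]
            chord_um = 2.0 * np.sqrt(R[hit] ** 2 - d_plane[hit] ** 2)
            sh, dh = s[hit], (plane_z[hit] - scz[hit])
            # chord mid-point: walk from the disk centre within the disk plane
            px = scx[hit] - nz[hit] * dh / sh**2 * nx[hit]
            py = scy[hit] - nz[hit] * dh / sh**2 * ny[hit]
            # chord direction = n x z-hat, normalised (horizontal by construction)
            vx, vy = ny[hit] / sh, -nx[hit] / sh
            half_c = chord_um / 2.0
            # terminal membrane trace: chord of a virtual disk of the terminal
            # extent at a uniform random offset (mean = pi/4 * extent)
            u = rng.random(hit.sum())
            term = pop.terminal_extents_nm[syn][hit] * np.sqrt(1.0 - u**2)
            rows.append(
                pd.DataFrame(
                    {
                        "object_id": idx,
                        "type": np.where(
                            pop.type_codes[idx] == 0, "asymmetric", "symmetric"
                        ),
                        "layer": pop.model.layer_of_y(py),
                        "x_um": px,
                        "y_um": py,
                        "x1_um": px - half_c * vx,
                        "y1_um": py - half_c * vy,
                        "x2_um": px + half_c * vx,
                        "y2_um": py + half_c * vy,
                        "junction_length_nm": chord_um * 1000.0,
                        "terminal_membrane_length_nm": term,
                        "radius_um": 0.0,
                        "perforated": pop.perforated[idx],
                    }
                )
            )

    # ---- myelinated axons ---------------------------------------------------
    ax = pop.type_codes == 2
    if ax.any():
        D_um = pop.diameters_nm[ax] / 1000.0
        half_h = D_um / 2.0  # segment height equals diameter
        acz = cz[ax]
        if section_model == "midplane":
            hit = np.abs(acz - z_mid) <= half_h
        else:
            hit = (acz + half_h >= z_lo) & (acz - half_h <= z_hi)
        if hit.any():
            idx = np.flatnonzero(ax)[hit]
            axx, ayy = cx[ax][hit], cy[ax][hit]
            rows.append(
                pd.DataFrame(
                    {
                        "object_id": idx,
                        "type": "axon",
                        "layer": pop.model.layer_of_y(ayy),
                        "x_um": axx,
                        "y_um": ayy,
                        "x1_um": axx,
                        "y1_um": ayy,
                        "x2_um": axx,
                        "y2_um": ayy,
                        "junction_length_nm": pop.diameters_nm[idx],
                        "terminal_membrane_length_nm": 0.0,
                        "radius_um": D_um[hit] / 2.0,
                        "perforated": False,
                    }
                )
            )

    if not rows:
        return pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
            PROFILE_COLUMNS,
            [int, str, str, float, float, float, float, float, float, float, float, float, bool],
        )})
    out = pd.concat(rows, ignore_index=True)
    return out[PROFILE_COLUMNS]


def cut_sections(
    objects: ObjectPopulation | Sequence[SynapticObject],
    plan: SectionPlan,
    seed: int = 0,
    model: TissueModel | None = None,
) -> list[tuple[UltrathinSection, pd.DataFrame]]:
    """Section the block at the planned slabs and emit per-section profile tables.

    Returns ``[(UltrathinSection, profiles DataFrame), ...]`` with the columns
    of :data:`PROFILE_COLUMNS`.  An empty object list yields empty tables.
    The seed drives only the terminal-membrane trace draws.
    """
    if not isinstance(objects, ObjectPopulation):
        objects = _population_from_objects(list(objects), model)
    rng = np.random.default_rng(seed)
    return [(sec, _section_profiles(objects, sec, rng, plan.section_model))
            for sec in plan.sections()]


def _population_from_objects(
    objs: list[SynapticObject], model: TissueModel | None
) -> ObjectPopulation:
    if model is None:
        model = compact_tissue_model()
    code = {"asymmetric": 0, "symmetric": 1, "axon": 2}
    n = len(objs)
    return ObjectPopulation(
        np.array([o.center for o in objs]).reshape(n, 3),
        np.array([o.diameter for o in objs]),
        np.array([o.normal for o in objs]).reshape(n, 3),
        np.array([code[o.type] for o in objs], dtype=np.int8),
        np.array([o.perforated for o in objs], dtype=bool),
        np.array([o.terminal_extent for o in objs]),
        model,
    )


# ---------------------------------------------------------------------------
# stock configurations
# ---------------------------------------------------------------------------

#: pooled trace-length targets (nm) behind the stock models
MEAN_JUNCTION_TRACE_NM = 207.0
MEAN_TERMINAL_TRACE_NM = 489.0
DISK_DIAMETER_CV = 0.20


def _stock_dists(junction_trace_nm: float = MEAN_JUNCTION_TRACE_NM):
    disk = DistributionSpec(
        "lognormal",
        disk_mean_diameter_for_trace(junction_trace_nm, DISK_DIAMETER_CV),
        DISK_DIAMETER_CV,
    )
    # terminal trace is an unweighted chord, mean = pi/4 * extent
    terminal = DistributionSpec("lognormal", MEAN_TERMINAL_TRACE_NM * 4.0 / math.pi, 0.35)
    axon = DistributionSpec("lognormal", 800.0, DISK_DIAMETER_CV)
    return disk, terminal, axon


def default_tissue_model(
    density_asym: float = 5.5,
    density_sym: float = 0.5,
    density_axon: float = 0.47,
    block_dims: tuple[float, float, float] = (42.0, 45.0, 3.2),
    junction_trace_nm: float = MEAN_JUNCTION_TRACE_NM,
    seed: int = 0,
) -> TissueModel:
    """Five-layer block with the study's whole-cortex mean densities.

    Asymmetric synapses are denser in the superficial layers, symmetric
    synapses uniform, myelinated axons concentrated in the deep layers; the
    depth-weighted means equal the requested whole-block densities exactly.
    """
    fracs = {"I": 0.10, "II": 0.15, "III": 0.25, "V": 0.25, "VI": 0.25}
    # relative per-layer weights, depth-weighted mean = 1 by construction
    asym_w = {"I": 6.3 / 5.5, "II": 6.3 / 5.5, "III": 5.9 / 5.5, "V": 5.1 / 5.5, "VI": 4.7 / 5.5}
    axon_w = {"I": 0.05 / 0.47, "II": 0.10 / 0.47, "III": 0.30 / 0.47,
              "V": 0.55 / 0.47, "VI": 0.95 / 0.47}
    disk, terminal, axon = _stock_dists(junction_trace_nm)
    layers = tuple(
        LayerSpec(
            name=n,
            depth_fraction=fracs[n],
            density_asym=density_asym * asym_w[n],
            density_sym=density_sym,
            density_axon=density_axon * axon_w[n],
        )
        for n in LAYER_NAMES
    )
    return TissueModel(
        layers=layers,
        block_dims=block_dims,
        disk_diameter_dist=disk,
        terminal_size_dist=terminal,
        axon_diameter_dist=axon,
        seed=seed,
    )


def compact_tissue_model(
    density_asym: float = 5.5,
    density_sym: float = 0.5,
    density_axon: float = 0.47,
    block_dims: tuple[float, float, float] = (16.0, 4.5, 2.1),
    seed: int = 0,
) -> TissueModel:
    """Single-band block for estimator-recovery experiments (uniform densities)."""
    disk, terminal, axon = _stock_dists()
    layers = (
        LayerSpec("III", 1.0, density_asym, density_sym, density_axon),
    )
    return TissueModel(
        layers=layers,
        block_dims=block_dims,
        disk_diameter_dist=disk,
        terminal_size_dist=terminal,
        axon_diameter_dist=axon,
        seed=seed,
    )


def scale_stress_model(model: TissueModel, junction_scale: float = 1.0,
                       density_scale: float = 1.0) -> TissueModel:
    """Variant model for the stressed group (longer junction traces, optional
    density change); geometry unchanged."""
    disk = replace(model.disk_diameter_dist, mean=model.disk_diameter_dist.mean * junction_scale)
    layers = tuple(
        replace(
            l,
            density_asym=l.density_asym * density_scale,
            density_sym=l.density_sym * density_scale,
            density_axon=l.density_axon * density_scale,
        )
        for l in model.layers
    )
    return replace(model, layers=layers, disk_diameter_dist=disk)
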