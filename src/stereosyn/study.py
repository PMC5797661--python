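"""End-to-end study orchestration: simulate a two-group cohort, section and
sample each animal's block, estimate densities and volumes, build the
individual/group summary tables, and run the group statistics.

The default configuration is "paper-like": 4 control and 4 stressed animals,
control ground truth of 5.5 asymmetric and 0.5 symmetric synapses/μm³ and
0.47 myelinated axons/μm³, control infralimbic volume 0.211 mm³ with the
stress effect expressed as a deep-layer (III–VI) volume reduction bringing
the total to ≈0.184 mm³ while densities stay unchanged — the dissociation
in which totals, not densities, carry the group difference.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .behavior import simulate_sucrose_intake
from .estimators import (
    DensityEstimate,
    VolumeEstimate,
    cavalieri_volume,
    size_frequency_density,
)
from .morphometry import (
    TABLE1_COLUMNS,
    AnimalSummary,
    assign_terminal_census,
    summarize_animal,
    summarize_group,
)
from .sampling import FrameSample, SamplingPlan, count_in_frame, place_frames, select_sections
from .stats import StatResult, anova_two_way, render_p, sucrose_analysis, ttest_unpaired
from .tissue import (
    SectionPlan,
    TissueModel,
    compact_tissue_model,
    cut_sections,
    default_tissue_model,
    scale_stress_model,
    simulate_block,
)

__all__ = [
    "RunConfig",
    "StudyResult",
    "run_study",
    "sample_animal",
    "animal_density",
    "simulate_area_series",
    "ingest_table1",
    "table1_group_tests",
    "replicate_size_frequency",
]

#: cross-sectional share of each Cavalieri layer bin (deep layers ~65%)
VOLUME_BIN_FRACTIONS = {"I": 0.20, "II": 0.15, "III-VI": 0.65}


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one reproducible study run."""

    seed: int
    n_per_group: int = 4
    tissue: TissueModel = field(default_factory=default_tissue_model)
    plan: SamplingPlan = field(default_factory=SamplingPlan)
    control_volume_mm3: float = 0.211
    deep_volume_reduction: float = 0.186  # fractional loss of bin III–VI under stress
    superficial_volume_reduction: float = 0.02
    stress_density_scale: float = 1.0  # 1.0 = densities unchanged by stress
    stress_junction_scale: float = 1.024  # slightly longer junction traces
    cavalieri_sections: int = 6
    cavalieri_thickness_um: float = 80.0
    cavalieri_period: int = 3
    out_dir: str | None = None
    write_profiles: bool = False

    def __post_init__(self) -> None:
        for eff in (self.deep_volume_reduction, self.superficial_volume_reduction):
            if not -1.0 <= eff <= 1.0:
                raise ValueError("effect sizes must lie in [-1, 1]")
        if self.n_per_group < 2:
            raise ValueError("need at least 2 animals per group")

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output plumbing excluded)."""
        payload = _as_jsonable(self)
        payload.pop("out_dir", None)
        payload.pop("write_profiles", None)
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _as_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _as_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _as_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_jsonable(v) for v in obj]
    return obj


# ---------------------------------------------------------------------------
# per-animal pipeline
# ---------------------------------------------------------------------------


def sample_animal(
    model: TissueModel,
    plan: SamplingPlan,
    seed: int,
    n_frames: int | None = None,
):
    """simulate → section → SUR-sample → count for one animal.

    Returns ``(sections, samples)`` where ``sections`` is the cut
    ``(UltrathinSection, profiles)`` list and ``samples`` the flat list of
    :class:`FrameSample` over all sections and layer bands.
    """
    rng = np.random.default_rng(seed)
    pop = simulate_block(model, seed=int(rng.integers(0, 2**31 - 1)))
    series_length = int(model.block_dims[2] / (plan.ultrathin_thickness_nm / 1000.0))
    indices = select_sections(series_length, plan, rng)
    splan = SectionPlan(
        indices=tuple(indices),
        thickness_nm=plan.ultrathin_thickness_nm,
        vibratome_thickness_um=plan.vibratome_thickness_um,
    )
    sections = cut_sections(pop, splan, seed=int(rng.integers(0, 2**31 - 1)))

    bands = model.layer_bands()
    samples: list[FrameSample] = []
    for sec, profiles in sections:
        for layer in model.layers:
            frames = place_frames(
                model.block_dims[0], bands[layer.name], plan, rng, n_frames=n_frames
            )
            for fr in frames:
                samples.append(count_in_frame(profiles, fr, layer=layer.name))
    return sections, samples


def animal_density(
    samples: Sequence[FrameSample],
    model: TissueModel,
    type_: str,
) -> DensityEstimate:
    """Depth-weighted whole-block density: per-layer size-frequency estimates
    combined with the layer depth fractions (the design-correct pooling when
    every layer contributes the same number of frames regardless of its
    thickness)."""
    by_layer = {}
    for s in samples:
        by_layer.setdefault(s.layer, []).append(s)
    nv = 0.0
    na = 0.0
    d_bars = []
    total_area = 0.0
    for layer in model.layers:
        sub = by_layer.get(layer.name)
        if not sub:
            continue
        est = size_frequency_density(sub, type_)
        nv += layer.depth_fraction * est.N_V
        na += layer.depth_fraction * est.N_A
        total_area += est.total_area
        if est.d_bar is not None:
            d_bars.append(est.d_bar)
    return DensityEstimate(
        type=type_,
        N_A=na,
        d_bar=float(np.mean(d_bars)) if d_bars else None,
        N_V=nv,
        n_frames=len(samples),
        total_area=total_area,
    )


def simulate_area_series(
    total_volume_mm3: float,
    n_sections: int,
    thickness_um: float,
    period: int,
    rng: np.random.Generator,
    bin_fractions: dict[str, float] = VOLUME_BIN_FRACTIONS,
    noise_cv: float = 0.01,
) -> pd.DataFrame:
    """Per-section cross-sectional areas per layer bin for the Cavalieri stage.

    Section areas follow a smooth dome along the rostro-caudal axis; the
    expected Cavalieri sum equals ``total_volume_mm3`` exactly before the
    small per-animal multiplicative noise.
    """
    k = np.arange(n_sections)
    shape = 1.0 - 0.5 * ((k - (n_sections - 1) / 2) / ((n_sections - 1) / 2 + 0.5)) ** 2
    shape /= shape.sum()
    rows = []
    for bin_name, frac in bin_fractions.items():
        target_um3 = total_volume_mm3 * 1e9 * frac
        base = target_um3 / (thickness_um * period) * shape
        noise = rng.lognormal(-0.5 * np.log(1 + noise_cv**2), np.sqrt(np.log(1 + noise_cv**2)))
        for i, a in enumerate(base * noise):
            rows.append(
                {"section_index": i, "layer_bin": bin_name, "area_um2": float(a)}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cohort run
# ---------------------------------------------------------------------------


@dataclass
class StudyResult:
    config: RunConfig
    summaries: list[AnimalSummary]
    table1: pd.DataFrame
    table2: pd.DataFrame
    layer_densities: pd.DataFrame
    layer_volumes: pd.DataFrame
    volumes: pd.DataFrame
    sucrose: pd.DataFrame
    stats: dict[str, StatResult]
    report_text: str
    manifest: dict


def run_study(config: RunConfig) -> StudyResult:
    """Run the full two-group study and (optionally) write the report bundle."""
    root = np.random.SeedSequence(config.seed)
    animal_seeds = root.spawn(2 * config.n_per_group)
    aux = np.random.default_rng(root.spawn(1)[0])

    stress_model = scale_stress_model(
        config.tissue,
        junction_scale=config.stress_junction_scale,
        density_scale=config.stress_density_scale,
    )

    summaries: list[AnimalSummary] = []
    layer_density_rows = []
    layer_volume_rows = []
    volume_rows = []
    profile_tables = {}

    idx = 0
    for group, model in (("control", config.tissue), ("stress", stress_model)):
        for a in range(config.n_per_group):
            animal_id = f"{group}_{a + 1}"
            seed = int(animal_seeds[idx].generate_state(1)[0] % (2**31 - 1))
            idx += 1
            arng = np.random.default_rng(seed)

            sections, samples = sample_animal(model, config.plan, seed)
            assign_terminal_census(samples, arng)

            # Cavalieri volumes per layer bin
            if group == "stress":
                bin_scale = {
                    "I": 1.0 - config.superficial_volume_reduction,
                    "II": 1.0 - config.superficial_volume_reduction,
                    "III-VI": 1.0 - config.deep_volume_reduction,
                }
            else:
                bin_scale = {b: 1.0 for b in VOLUME_BIN_FRACTIONS}
            fractions = {
                b: f * bin_scale[b] for b, f in VOLUME_BIN_FRACTIONS.items()
            }
            total_target = config.control_volume_mm3 * sum(fractions.values())
            areas = simulate_area_series(
                config.control_volume_mm3,
                config.cavalieri_sections,
                config.cavalieri_thickness_um,
                config.cavalieri_period,
                arng,
                bin_fractions=fractions,
            )
            bin_estimates = {}
            for b in fractions:
                sub = areas[areas["layer_bin"] == b]
                bin_estimates[b] = cavalieri_volume(
                    sub["area_um2"],
                    config.cavalieri_thickness_um,
                    config.cavalieri_period,
                    layer_bin=b,
                )
                layer_volume_rows.append(
                    {
                        "animal_id": animal_id,
                        "group": group,
                        "layer_bin": b,
                        "volume_mm3": bin_estimates[b].volume,
                    }
                )
            total_volume = VolumeEstimate(
                layer_bin="total",
                areas=tuple(areas.groupby("section_index")["area_um2"].sum()),
                section_thickness=config.cavalieri_thickness_um,
                period=config.cavalieri_period,
                volume=sum(v.volume for v in bin_estimates.values()),
            )
            volume_rows.append(
                {
                    "animal_id": animal_id,
                    "group": group,
                    "volume_mm3": total_volume.volume,
                    "target_mm3": total_target,
                }
            )

            densities = {
                t: animal_density(samples, model, t)
                for t in ("asymmetric", "symmetric", "axon")
            }
            summaries.append(
                summarize_animal(samples, total_volume, densities, animal_id, group)
            )

            # per-layer densities for the laminar ANOVA
            by_layer = {}
            for s in samples:
                by_layer.setdefault(s.layer, []).append(s)
            for layer, sub in by_layer.items():
                row = {"animal_id": animal_id, "group": group, "layer": layer}
                for t, col in (
                    ("asymmetric", "density_asym"),
                    ("symmetric", "density_sym"),
                    ("axon", "density_axon"),
                ):
                    row[col] = size_frequency_density(sub, t).N_V
                row["density_all"] = row["density_asym"] + row["density_sym"]
                layer_density_rows.append(row)

            if config.write_profiles:
                profile_tables[animal_id] = pd.concat(
                    [
                        p.assign(ultrathin_section=sec.index,
                                 vibratome_section=sec.parent_vibratome_section,
                                 animal_id=animal_id, group=group)
                        for sec, p in sections
                    ],
                    ignore_index=True,
                )

    table1 = pd.DataFrame([s.to_row() for s in summaries])[TABLE1_COLUMNS]
    ctrl = [s for s in summaries if s.group == "control"]
    strs = [s for s in summaries if s.group == "stress"]
    table2 = pd.concat([summarize_group(ctrl), summarize_group(strs)], ignore_index=True)
    layer_densities = pd.DataFrame(layer_density_rows)
    layer_volumes = pd.DataFrame(layer_volume_rows)
    volumes = pd.DataFrame(volume_rows)

    sucrose = simulate_sucrose_intake(
        n_per_group=config.n_per_group,
        seed=int(aux.integers(0, 2**31 - 1)),
    )

    stats = _study_statistics(summaries, volumes, layer_densities, layer_volumes, sucrose)
    report = _render_report(table2, volumes, stats)

    manifest = {
        "package": "stereosyn",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_animals": len(summaries),
        "n_frames": int(table1["n_sample_areas"].sum()),
    }
    result = StudyResult(
        config=config,
        summaries=summaries,
        table1=table1,
        table2=table2,
        layer_densities=layer_densities,
        layer_volumes=layer_volumes,
        volumes=volumes,
        sucrose=sucrose,
        stats=stats,
        report_text=report,
        manifest=manifest,
    )
    if config.out_dir is not None:
        _write_bundle(result, Path(config.out_dir), profile_tables)
    return result


def _study_statistics(summaries, volumes, layer_densities, layer_volumes, sucrose):
    ctrl = {f: [getattr(s, f) for s in summaries if s.group == "control"]
            for f in ("total_asym", "total_sym", "total_axon")}
    strs = {f: [getattr(s, f) for s in summaries if s.group == "stress"]
            for f in ("total_asym", "total_sym", "total_axon")}
    vols_c = volumes.loc[volumes["group"] == "control", "volume_mm3"]
    vols_s = volumes.loc[volumes["group"] == "stress", "volume_mm3"]
    out: dict[str, StatResult] = {
        "total_asym_t": ttest_unpaired(ctrl["total_asym"], strs["total_asym"], tail="one"),
        "total_sym_t": ttest_unpaired(ctrl["total_sym"], strs["total_sym"], tail="one"),
        "total_axon_t": ttest_unpaired(ctrl["total_axon"], strs["total_axon"], tail="two"),
        "volume_t": ttest_unpaired(vols_c, vols_s, tail="one"),
        "density_asym_layer_anova": anova_two_way(
            layer_densities.rename(columns={"density_asym": "response"}),
            factor_a="group", factor_b="layer", posthoc="sidak",
        ),
        "density_all_layer_anova": anova_two_way(
            layer_densities.rename(columns={"density_all": "response"}),
            factor_a="group", factor_b="layer", posthoc="sidak",
        ),
        "volume_layer_anova": anova_two_way(
            layer_volumes.rename(columns={"volume_mm3": "response"}),
            factor_a="group", factor_b="layer_bin", posthoc="sidak",
        ),
        "sucrose": sucrose_analysis(sucrose),
    }
    return out


def _render_report(table2, volumes, stats) -> str:
    def g(group, field_):
        sub = table2[(table2["group"] == group) & (table2["field"] == field_)]
        return float(sub["mean"].iloc[0]), float(sub["sem"].iloc[0])

    lines = ["Quantitative stereology report", "=" * 32]
    for label, field_, scale in [
        ("Density of asymmetric synapses (n/um^3)", "density_asym", 1.0),
        ("Density of symmetric synapses (n/um^3)", "density_sym", 1.0),
        ("Total asymmetric synapses (x10^9)", "total_asym", 1e-9),
        ("Total symmetric synapses (x10^8)", "total_sym", 1e-8),
        ("Total myelinated axons (x10^8)", "total_axon", 1e-8),
        ("Synapse membrane length (nm)", "synapse_length_mean", 1.0),
        ("Terminal membrane length (nm)", "terminal_length_mean", 1.0),
    ]:
        mc, sc = g("control", field_)
        ms, ss = g("stress", field_)
        lines.append(
            f"{label}: control {mc * scale:.2f} +/- {sc * scale:.2f}, "
            f"stress {ms * scale:.2f} +/- {ss * scale:.2f}"
        )
    vc = volumes.loc[volumes["group"] == "control", "volume_mm3"]
    vs = volumes.loc[volumes["group"] == "stress", "volume_mm3"]
    lines.append(
        f"IL volume (mm^3): control {vc.mean():.3f} +/- {vc.sem():.3f}, "
        f"stress {vs.mean():.3f} +/- {vs.sem():.3f}"
    )
    for key, label in [
        ("total_asym_t", "t-test, total asymmetric synapses"),
        ("total_sym_t", "t-test, total symmetric synapses"),
        ("total_axon_t", "t-test, total myelinated axons"),
        ("volume_t", "t-test, IL volume"),
    ]:
        r = stats[key]
        lines.append(f"{label}: t = {r.statistic:.2f}, {render_p(r.p_value)}")
    sr = stats["sucrose"]
    first = sr.effects.get("first_significant_week")
    lines.append(
        f"sucrose ANOVA stress effect: F{sr.df} = {sr.statistic:.2f}, "
        f"{render_p(sr.p_value)}; first significant week: {first}"
    )
    return "\n".join(lines) + "\n"


def _write_bundle(result: StudyResult, out: Path, profile_tables: dict) -> None:
    out.mkdir(parents=True, exist_ok=True)
    fmt = "%.6g"
    result.table1.to_csv(out / "table1_individual.csv", index=False, float_format=fmt)
    result.table2.to_csv(out / "table2_group.csv", index=False, float_format=fmt)
    result.layer_densities.to_csv(out / "layer_densities.csv", index=False, float_format=fmt)
    result.layer_volumes.to_csv(out / "layer_volumes.csv", index=False, float_format=fmt)
    result.volumes.to_csv(out / "volumes.csv", index=False, float_format=fmt)
    result.sucrose.to_csv(out / "sucrose_intake.csv", index=False, float_format=fmt)
    stats_rows = []
    for name, r in result.stats.items():
        stats_rows.append(
            {
                "name": name,
                "test": r.test,
                "statistic": r.statistic,
                "df": str(r.df),
                "p_value": r.p_value,
                "tail": r.tail,
            }
        )
    pd.DataFrame(stats_rows).to_csv(out / "stats_report.csv", index=False, float_format=fmt)
    (out / "report.txt").write_text(result.report_text)
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=2, sort_keys=True))
    for animal_id, table in profile_tables.items():
        table.to_csv(out / f"profiles_{animal_id}.csv", index=False, float_format=fmt)


# ---------------------------------------------------------------------------
# printed-table ingestion and statistics
# ---------------------------------------------------------------------------

_TABLE1_NUMERIC = [c for c in TABLE1_COLUMNS if c not in
                   ("animal_id", "group", "synapse_per_terminal_pct",
                    "synapses_per_100_terminals")]


def ingest_table1(path: str | Path | None = None) -> list[AnimalSummary]:
    """Load a per-animal summary CSV (defaults to the packaged transcription
    of the study's individual-values table) into typed summaries.

    Warns (via ``warnings``) when the additivity identity
    density_all = density_asym + density_sym fails beyond printed rounding.
    """
    import warnings

    if path is None:
        path = resources.files("stereosyn") / "data" / "table1.csv"
    df = pd.read_csv(str(path))
    if df.empty:
        raise ValueError("per-animal summary table is empty")
    missing = [c for c in _TABLE1_NUMERIC if c not in df.columns]
    if missing:
        raise ValueError(f"per-animal summary table missing columns: {missing}")
    out = []
    for _, row in df.iterrows():
        s = AnimalSummary(
            animal_id=str(row["animal_id"]),
            group=str(row["group"]),
            n_sample_areas=int(row["n_sample_areas"]),
            n_terminals=int(row["n_terminals"]),
            density_all=float(row["density_all"]),
            density_asym=float(row["density_asym"]),
            density_sym=float(row["density_sym"]),
            density_axon=float(row["density_axon"]),
            total_asym=float(row["total_asym"]),
            total_sym=float(row["total_sym"]),
            total_axon=float(row["total_axon"]),
            terminal_length_mean=float(row["terminal_length_mean"]),
            terminal_length_sem=float(row["terminal_length_sem"]),
            synapse_length_mean=float(row["synapse_length_mean"]),
            synapse_length_sem=float(row["synapse_length_sem"]),
            synapse_per_terminal_pct=float(row.get("synapse_per_terminal_pct", np.nan)),
            synapses_per_100_terminals=float(row.get("synapses_per_100_terminals", np.nan)),
        )
        if not s.validate_additivity():
            warnings.warn(
                f"{s.animal_id}: density_all != density_asym + density_sym "
                f"beyond printed rounding", stacklevel=2,
            )
        out.append(s)
    return out


def table1_group_tests(summaries: Sequence[AnimalSummary]) -> dict[str, StatResult]:
    """The three recomputable group comparisons on per-animal totals:
    one-tailed t for synapse totals (hypothesis: stress < control),
    two-tailed t for myelinated-axon totals."""
    c = [s for s in summaries if s.group == "control"]
    s_ = [s for s in summaries if s.group == "stress"]

    def vals(group, f):
        return [getattr(x, f) for x in group]

    return {
        "total_asym_t": ttest_unpaired(vals(c, "total_asym"), vals(s_, "total_asym"), tail="one"),
        "total_sym_t": ttest_unpaired(vals(c, "total_sym"), vals(s_, "total_sym"), tail="one"),
        "total_axon_t": ttest_unpaired(vals(c, "total_axon"), vals(s_, "total_axon"), tail="two"),
    }


# ---------------------------------------------------------------------------
# recovery experiments
# ---------------------------------------------------------------------------


def replicate_size_frequency(
    n_replicates: int = 200,
    seed: int = 0,
    type_: str = "asymmetric",
    model: TissueModel | None = None,
    plan: SamplingPlan | None = None,
    n_frames: int | None = None,
) -> np.ndarray:
    """Size-frequency density estimates over seeded pipeline replicates.

    Each replicate runs the full simulate → section → SUR-sample → count →
    estimate chain on an independent block and returns the depth-weighted
    whole-block density estimate.
    """
    if model is None:
        model = compact_tissue_model()
        if plan is None:
            plan = SamplingPlan(sections_per_animal=6, fields_per_layer_per_section=4)
    if plan is None:
        plan = SamplingPlan()
    seeds = np.random.SeedSequence(seed).spawn(n_replicates)
    out = np.empty(n_replicates)
    for i, ss in enumerate(seeds):
        rep_seed = int(ss.generate_state(1)[0] % (2**31 - 1))
        _, samples = sample_animal(model, plan, rep_seed, n_frames=n_frames)
        out[i] = animal_density(samples, model, type_).N_V
    return out
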