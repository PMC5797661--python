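"""Per-animal and per-group morphometric summaries (the individual/group
quantitative-EM table schema).

Each animal's summary pools its counting-frame samples: densities from the
size-frequency estimator, totals as density × Cavalieri volume, trace-length
means ± SEM over all measured profiles, and the terminal-census ratios
(fraction of axon terminals bearing a synapse; synapse profiles per 100
terminal profiles).  SEM throughout is sample SD (n−1 denominator) / √n.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .estimators import DensityEstimate, VolumeEstimate, total_number
from .sampling import FrameSample

__all__ = [
    "AnimalSummary",
    "assign_terminal_census",
    "summarize_animal",
    "summarize_group",
    "sem",
    "TABLE1_COLUMNS",
]

#: tidy per-animal table schema (one row per animal)
TABLE1_COLUMNS = [
    "animal_id",
    "group",
    "n_sample_areas",
    "n_terminals",
    "density_all",
    "total_asym",
    "density_asym",
    "total_sym",
    "density_sym",
    "terminal_length_mean",
    "terminal_length_sem",
    "synapse_length_mean",
    "synapse_length_sem",
    "total_axon",
    "density_axon",
    "synapse_per_terminal_pct",
    "synapses_per_100_terminals",
]

#: terminal-census calibration: fraction of terminal profiles bearing >=1
#: synapse, and mean synapse profiles per bearing terminal (chosen so the
#: pooled census reproduces a ~52.7% synapse/terminal ratio and ~116 synapse
#: profiles per 100 terminals)
BEARING_FRACTION = 0.527
SYNAPSES_PER_BEARING = 116.3 / 52.7  # ~2.207


def sem(values: Sequence[float]) -> float:
    """Standard error of the mean with the n−1 denominator SD."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        return 0.0
    return float(v.std(ddof=1) / math.sqrt(len(v)))


@dataclass
class AnimalSummary:
    animal_id: str
    group: str
    n_sample_areas: int
    n_terminals: int
    density_all: float
    density_asym: float
    density_sym: float
    density_axon: float
    total_asym: float
    total_sym: float
    total_axon: float
    terminal_length_mean: float
    terminal_length_sem: float
    synapse_length_mean: float
    synapse_length_sem: float
    synapse_per_terminal_pct: float
    synapses_per_100_terminals: float

    def to_row(self) -> dict:
        return {c: getattr(self, c) for c in TABLE1_COLUMNS}

    def validate_additivity(self, tol: float = 0.005) -> bool:
        return abs(self.density_all - (self.density_asym + self.density_sym)) <= tol


def assign_terminal_census(
    samples: Sequence[FrameSample], seed: int | np.random.Generator = 0
) -> None:
    """Overlay a terminal census on counted synapse profiles (in place).

    Each frame's terminal-profile tally is drawn as Poisson with mean
    ``n_synapses × 100 / synapses-per-100-terminals``, which makes the pooled
    synapses-per-100-terminals statistic unbiased for its calibration value.
    This is a statistical decoration, not sectioned geometry: it supplies the
    per-frame terminal tallies that the ratio statistics need.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    per_terminal = (BEARING_FRACTION / 100.0) * SYNAPSES_PER_BEARING * 100.0  # 1.163
    for s in samples:
        s.n_terminals = int(rng.poisson(s.n_synapses / per_terminal)) if s.n_synapses else 0


def summarize_animal(
    samples: Sequence[FrameSample],
    volume: VolumeEstimate,
    densities: dict[str, DensityEstimate],
    animal_id: str = "",
    group: str = "control",
) -> AnimalSummary:
    """Fill the per-animal summary row from frames, volume and density estimates."""
    if volume is None:
        raise ValueError(f"missing volume estimate for animal {animal_id!r}")
    for key in ("asymmetric", "symmetric", "axon"):
        if key not in densities:
            raise ValueError(f"missing {key} density estimate for animal {animal_id!r}")

    d_asym = densities["asymmetric"].N_V
    d_sym = densities["symmetric"].N_V
    d_axon = densities["axon"].N_V

    syn_lengths: list[np.ndarray] = []
    term_lengths: list[np.ndarray] = []
    n_terminals = 0
    have_census = False
    n_bearing_est = 0
    for s in samples:
        if s.n_terminals is not None:
            n_terminals += s.n_terminals
            have_census = True
        if len(s.counted):
            syn = s.counted[s.counted["type"] != "axon"]
            if len(syn):
                keep = ~syn["perforated"].astype(bool)
                syn_lengths.append(syn.loc[keep, "junction_length_nm"].to_numpy(float))
                term_lengths.append(
                    syn["terminal_membrane_length_nm"].to_numpy(float)
                )
    syn_pool = np.concatenate(syn_lengths) if syn_lengths else np.empty(0)
    term_pool = np.concatenate(term_lengths) if term_lengths else np.empty(0)
    n_synapses = sum(s.n_synapses for s in samples)

    if have_census and n_terminals > 0:
        per100 = 100.0 * n_synapses / n_terminals
        # bearing terminals from the census partition model
        bearing = min(n_terminals, int(round(n_synapses / SYNAPSES_PER_BEARING)))
        pct = 100.0 * bearing / n_terminals
    else:
        per100 = float("nan")
        pct = float("nan")

    return AnimalSummary(
        animal_id=animal_id,
        group=group,
        n_sample_areas=len(samples),
        n_terminals=n_terminals,
        density_all=d_asym + d_sym,
        density_asym=d_asym,
        density_sym=d_sym,
        density_axon=d_axon,
        total_asym=total_number(d_asym, volume.volume),
        total_sym=total_number(d_sym, volume.volume),
        total_axon=total_number(d_axon, volume.volume),
        terminal_length_mean=float(term_pool.mean()) if len(term_pool) else float("nan"),
        terminal_length_sem=sem(term_pool),
        synapse_length_mean=float(syn_pool.mean()) if len(syn_pool) else float("nan"),
        synapse_length_sem=sem(syn_pool),
        synapse_per_terminal_pct=pct,
        synapses_per_100_terminals=per100,
    )


#: fields aggregated as mean ± SEM in the group table; count fields are summed
_GROUP_MEAN_FIELDS = [
    "density_all",
    "total_asym",
    "density_asym",
    "total_sym",
    "density_sym",
    "terminal_length_mean",
    "synapse_length_mean",
    "total_axon",
    "density_axon",
    "synapse_per_terminal_pct",
    "synapses_per_100_terminals",
]
_GROUP_SUM_FIELDS = ["n_sample_areas", "n_terminals"]


def summarize_group(summaries: Sequence[AnimalSummary]) -> pd.DataFrame:
    """Group table: mean ± SEM across animals per field; tallies are summed.

    All summaries must come from one group (mixing groups silently averages
    away the contrast, so it raises).
    """
    if len(summaries) < 2:
        raise ValueError("need at least 2 animals per group")
    groups = {s.group for s in summaries}
    if len(groups) != 1:
        raise ValueError(f"summaries mix groups {sorted(groups)}; call once per group")
    rows = []
    for f in _GROUP_SUM_FIELDS:
        vals = [getattr(s, f) for s in summaries]
        rows.append({"field": f, "mean": float(np.sum(vals)), "sem": 0.0, "n": len(vals)})
    for f in _GROUP_MEAN_FIELDS:
        vals = [getattr(s, f) for s in summaries]
        rows.append(
            {"field": f, "mean": float(np.mean(vals)), "sem": sem(vals), "n": len(vals)}
        )
    out = pd.DataFrame(rows)
    out.insert(0, "group", summaries[0].group)
    return out


# ---------------------------------------------------------------------------
# report-precision formatting (densities 2 dp, lengths 1–2 dp, totals 3 s.f.)
# ---------------------------------------------------------------------------


def format_total(x: float) -> str:
    """Scientific notation at 3 significant digits, e.g. ``1.15 x 10^9``."""
    if x == 0:
        return "0"
    exp = int(math.floor(math.log10(abs(x))))
    mant = x / 10**exp
    return f"{mant:.2f} x 10^{exp}"


def format_density(x: float) -> str:
    return f"{x:.2f}"
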