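"""Synthetic sucrose-consumption trajectories for the anhedonia read-out.

Chronic-mild-stress protocols read out anhedonia as a progressive drop in
weekly 1-h sucrose intake relative to undisturbed controls.  The generator
emulates the study design: a pre-stress baseline (week 0), nine stress weeks,
control intake drifting slowly upward, and stressed intake declining from a
configurable onset week so that the Bonferroni-adjusted group comparison
first reaches significance around week 4.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["simulate_sucrose_intake"]


def simulate_sucrose_intake(
    n_per_group: int = 4,
    n_weeks: int = 9,
    baseline_mean: float = 11.0,
    control_slope: float = 0.4,
    stress_onset_week: int = 2,
    stress_decline: float = 1.5,
    sd: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Tidy weekly intake table (animal_id, group, week, intake_g).

    Week 0 is the baseline.  Control mean rises by ``control_slope`` g/week;
    the stressed mean follows the control trajectory until
    ``stress_onset_week`` and then loses ``stress_decline`` g/week relative
    to it.  Intakes are normal with common SD and floored at zero.
    """
    if n_per_group < 2:
        raise ValueError("need at least 2 animals per group")
    rng = np.random.default_rng(seed)
    rows = []
    for g, gname in enumerate(["control", "stress"]):
        for a in range(n_per_group):
            for week in range(0, n_weeks + 1):
                mean = baseline_mean + control_slope * week
                if gname == "stress" and week > stress_onset_week:
                    mean -= stress_decline * (week - stress_onset_week)
                rows.append(
                    {
                        "animal_id": f"{gname}_{a + 1}",
                        "group": gname,
                        "week": week,
                        "intake_g": max(0.0, float(rng.normal(mean, sd))),
                    }
                )
    return pd.DataFrame(rows)
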