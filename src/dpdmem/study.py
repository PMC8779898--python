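"""Scaled-down study protocols: morphology corners and reversible toggling.

The full-size membrane/protein systems (40 x 40 x 48 box, ~230,000 beads,
millions of steps) are far beyond a desk run, so the package defines a
scaled-down analogue that preserves the study's composition ratios: minority
lipid fraction 16/96 = 0.167, all minority in the upper leaflet, telechelic
B6 proteins at a bulk concentration comparable to the larger systems, and
the same force field.  The default scale (8 x 8 x 14 box, 96 lipids, 16
proteins, 30,000 steps) resolves all four corner morphologies of the
(eps_EE, eps_EM) attraction plane in about a minute per run.

``min_size`` for the condensation metric is 6 at this scale (proportionate
to 10 out of ~400 proteins at full size: a "droplet" must hold more than a
third of the proteins here).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import analysis
from .builder import SystemRecipe, build_system
from .engine import ReferenceEngine, RunParams, Schedule, ScheduleEvent, SimulationBox
from .model import A_WE, EpsilonSpec, epsilon_to_a

__all__ = [
    "StudyScale",
    "CORNERS",
    "corner_recipe",
    "run_corner",
    "corner_labels",
    "majority_label",
    "run_toggling",
    "toggling_times",
]

#: the four corner points of the attraction plane and their expected states
CORNERS: dict[tuple[float, float], str] = {
    (0.0, 0.0): analysis.MIXED_DISPERSED,
    (0.68, 0.0): analysis.MIXED_DROPLET,
    (0.0, 0.8): analysis.WETTING_DOMAIN,
    (0.8, 0.8): analysis.ADSORBED_DROPLET_DOMAIN,
}


@dataclass(frozen=True)
class StudyScale:
    """Problem size of the scaled-down study."""

    box: tuple[float, float, float] = (8.0, 8.0, 14.0)
    n_major: int = 80
    n_minor: int = 16
    n_idp: int = 16
    idp_backbone: int = 6
    steps: int = 30_000
    observe_every: int = 1000
    tail_fraction: float = 0.2
    min_size: int = 6


DEFAULT_SCALE = StudyScale()


def corner_recipe(
    eps_ee: float, eps_em: float, seed: int, scale: StudyScale = DEFAULT_SCALE
) -> SystemRecipe:
    return SystemRecipe(
        box=SimulationBox(scale.box),
        n_major=scale.n_major,
        n_minor=scale.n_minor,
        n_idp=scale.n_idp,
        idp_backbone=scale.idp_backbone,
        seed=seed,
        eps=EpsilonSpec(eps_ee=eps_ee, eps_em=eps_em),
    )


def run_corner(
    eps_ee: float,
    eps_em: float,
    seed: int,
    scale: StudyScale = DEFAULT_SCALE,
    schedule: Schedule | None = None,
) -> analysis.MorphologyReport:
    """Build, run and classify one point of the attraction plane.

    Metrics are averaged over the final ``tail_fraction`` of the run and the
    label assigned from the averages.
    """
    recipe = corner_recipe(eps_ee, eps_em, seed, scale)
    state = build_system(recipe)
    engine = ReferenceEngine(
        state, recipe.eps.make_table(), RunParams(seed=seed), schedule=schedule
    )
    reports: list[analysis.MorphologyReport] = []
    tail_start = int((1.0 - scale.tail_fraction) * scale.steps)

    def observer(s):
        if s.step >= tail_start:
            reports.append(analysis.analyze_state(s, min_size=scale.min_size))

    engine.run(scale.steps, observer=observer, observe_every=scale.observe_every)
    return analysis.average_reports(reports)


def corner_labels(
    eps_ee: float, eps_em: float, seeds, scale: StudyScale = DEFAULT_SCALE
) -> list[str]:
    return [run_corner(eps_ee, eps_em, s, scale).label for s in seeds]


def majority_label(labels: list[str]) -> str:
    vals, counts = np.unique(labels, return_counts=True)
    return str(vals[np.argmax(counts)])


# ---------------------------------------------------------------------------
# reversible wetting (interaction toggling)


def run_toggling(
    seed: int,
    scale: StudyScale = DEFAULT_SCALE,
    t_max: int = 40_000,
    on_frac: float = 0.2,
    off_frac: float = 0.85,
    eps_ee: float = 0.68,
    eps_em_on: float = 0.8,
    observe_every: int = 500,
) -> pd.DataFrame:
    """Droplet -> wetting -> droplet protocol driven by toggling eps_EM.

    Proteins start self-attracting (eps_EE) but neutral to the membrane; at
    ``on_frac * t_max`` a strong endcap/minority-headgroup attraction turns
    on, and it is removed again at ``off_frac * t_max``.  Returns the time
    series of the adsorbed and condensed fractions.
    """
    on_step = int(on_frac * t_max)
    off_step = int(off_frac * t_max)
    schedule = Schedule(
        [
            ScheduleEvent(on_step, ("E", "H_B"), epsilon_to_a(eps_em_on, A_WE)),
            ScheduleEvent(off_step, ("E", "H_B"), epsilon_to_a(0.0, A_WE)),
        ]
    )
    recipe = corner_recipe(eps_ee, 0.0, seed, scale)
    state = build_system(recipe)
    engine = ReferenceEngine(
        state, recipe.eps.make_table(), RunParams(seed=seed), schedule=schedule
    )
    rows = []

    def observer(s):
        rows.append(
            {
                "step": s.step,
                "adsorbed": analysis.idp_adsorbed_fraction(s),
                "condensed": analysis.idp_condensed_fraction(s, min_size=scale.min_size),
            }
        )

    engine.run(t_max, observer=observer, observe_every=observe_every)
    df = pd.DataFrame(rows)
    df.attrs["on_step"] = on_step
    df.attrs["off_step"] = off_step
    return df


def toggling_times(df: pd.DataFrame, theta: float = 0.5) -> dict:
    """Wetting and recovery times from a toggling time series.

    Wetting time: steps from the on-event until the adsorbed fraction first
    reaches ``theta``.  Recovery time: steps from the off-event until it
    first falls back below ``1 - theta`` of its pre-off plateau.  Also
    reports the mean adsorbed fraction before the on-event, between the
    events, and at the end.
    """
    on_step = df.attrs["on_step"]
    off_step = df.attrs["off_step"]
    before = df[df.step <= on_step]
    between = df[(df.step > on_step) & (df.step <= off_step)]
    after = df[df.step > off_step]
    wet = between[between.adsorbed >= theta]
    wetting_time = int(wet.step.iloc[0] - on_step) if len(wet) else None
    plateau = float(between.adsorbed.tail(max(1, len(between) // 5)).mean())
    rec = after[after.adsorbed <= (1 - theta) * plateau]
    recovery_time = int(rec.step.iloc[0] - off_step) if len(rec) else None
    return {
        "ads_before_on": float(before.adsorbed.mean()) if len(before) else float("nan"),
        "ads_plateau": plateau,
        "ads_end": float(after.adsorbed.tail(3).mean()) if len(after) else float("nan"),
        "wetting_time": wetting_time,
        "recovery_time": recovery_time,
    }
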