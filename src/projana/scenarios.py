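"""Canonical simulated designs for projection analysis of ancient samples.

Two model families, each in five variants and run in both sampling
directions:

* **OPM** (one-population model): the ancient sample is directly ancestral
  to the present-day population.
* **TPM** (two-population model): the ancient sample sits on a sister
  lineage that diverged from the present-day population 2000 generations
  ago.

Variants (all sizes diploid; baseline N = 5000):

* **A** — constant size, no gene flow;
* **B** — as A plus a 5% admixture pulse 750 generations ago into the
  present-day population (from an unsampled sister in the OPM, from the
  sampled sister in the TPM);
* **C** — size expansion 500 → 5000 in the present-day population 750
  generations ago;
* **D** — size decline 5000 → 500 at 750 generations ago;
* **E** — bottleneck: size 500 between 500 and 1000 generations ago, 5000
  outside.

Sampling times are {0, 500, 1000, 2000, 3000, 4000} generations ago.  In the
``ancient_test`` direction the 200-chromosome reference panel is sampled at
present and the single test lineage at the chosen time; ``ancient_panel``
swaps the roles.  A diverging population keeps the size its ancestor had at
the divergence time.

Year-valued inputs convert at 25 years per generation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .coalescent import simulate_projection
from .demography import Deme, DemographicModel, PopulationSplit, PulseAdmixture, SampleGroup
from .projection import ProjectionCurve

__all__ = [
    "ScenarioSpec",
    "build_scenario",
    "run_scenario_grid",
    "grid_to_frame",
    "years_to_generations",
    "HUMAN_MODEL_PARAMETERS",
]

FAMILIES = ("OPM", "TPM")
VARIANTS = ("A", "B", "C", "D", "E")
SAMPLING_TIMES = (0, 500, 1000, 2000, 3000, 4000)
DIRECTIONS = ("ancient_test", "ancient_panel")

N_BASELINE = 5000.0
N_REDUCED = 500.0
DIVERGENCE_TIME = 2000.0
PULSE_TIME = 750.0
PULSE_FRACTION = 0.05
BOTTLENECK_INTERVAL = (500.0, 1000.0)
PANEL_LINEAGES = 200
GENERATION_YEARS = 25.0

#: Fitted free parameters of the published eight-population human model
#: (times in years): Neanderthal admixture time and fraction into ancestral
#: non-Africans, Neanderthal divergence time, and recent European-to-Yoruba
#: admixture.  The remaining model parameters are not bundled here and must
#: come from a user-supplied demography configuration.
HUMAN_MODEL_PARAMETERS = {
    "T_8": 38950.0,
    "T_15": 610175.0,
    "f_NEA-ANC1": 0.018,
    "f_FRE-YOR": 0.02,
}


def years_to_generations(years: float, generation_years: float = GENERATION_YEARS) -> float:
    """Convert years to generations (rounded to the nearest generation)."""
    return float(round(years / generation_years))


@dataclass(frozen=True)
class ScenarioSpec:
    family: str
    variant: str
    sampling_time: float
    direction: str = "ancient_test"

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}, got {self.family!r}")
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}, got {self.variant!r}")
        if self.direction not in DIRECTIONS:
            raise ValueError(
                f"direction must be one of {DIRECTIONS}, got {self.direction!r}"
            )
        if self.sampling_time < 0:
            raise ValueError("sampling_time must be non-negative")

    def label(self) -> str:
        return f"{self.family}:{self.variant}:t={self.sampling_time:g}:{self.direction}"


def _focal_epochs(variant: str) -> tuple:
    """Size history of the present-day (reference) population, backward in time."""
    if variant in ("A", "B"):
        return ((0.0, N_BASELINE),)
    if variant == "C":  # forward-time expansion at 750 ga: small before, big after
        return ((0.0, N_BASELINE), (PULSE_TIME, N_REDUCED))
    if variant == "D":  # forward-time decline at 750 ga
        return ((0.0, N_REDUCED), (PULSE_TIME, N_BASELINE))
    if variant == "E":
        lo, hi = BOTTLENECK_INTERVAL
        return ((0.0, N_BASELINE), (lo, N_REDUCED), (hi, N_BASELINE))
    raise ValueError(variant)


def _size_at(epochs: tuple, t: float) -> float:
    n = epochs[0][1]
    for start, size in epochs:
        if start <= t:
            n = size
    return n


def build_scenario(spec: ScenarioSpec, panel_lineages: int = PANEL_LINEAGES) -> DemographicModel:
    """Materialise a scenario as a concrete :class:`DemographicModel`."""
    focal = Deme("focal", _focal_epochs(spec.variant))
    demes = [focal]
    events = []

    needs_sister = spec.family == "TPM" or spec.variant == "B"
    if needs_sister:
        # the diverging population keeps the ancestral size at divergence
        sister_n = _size_at(focal.size_epochs, DIVERGENCE_TIME)
        demes.append(Deme("sister", ((0.0, sister_n),)))
        events.append(PopulationSplit(DIVERGENCE_TIME, "sister", "focal"))
    if spec.variant == "B":
        events.append(
            PulseAdmixture(PULSE_TIME, source="sister", recipient="focal",
                           fraction=PULSE_FRACTION)
        )

    # the ancient lineage lives on the sister branch only in the TPM and only
    # until the divergence time; older samples sit in the common ancestor
    if spec.family == "TPM" and spec.sampling_time <= DIVERGENCE_TIME:
        ancient_deme = "sister"
    else:
        ancient_deme = "focal"

    if spec.direction == "ancient_test":
        samples = (
            SampleGroup("focal", 0.0, panel_lineages, "panel"),
            SampleGroup(ancient_deme, float(spec.sampling_time), 1, "test"),
        )
    else:
        samples = (
            SampleGroup(ancient_deme, float(spec.sampling_time), panel_lineages, "panel"),
            SampleGroup("focal", 0.0, 1, "test"),
        )

    model = DemographicModel(tuple(demes), tuple(events), samples)
    model.validate()
    return model


def run_scenario_grid(
    specs: Sequence[ScenarioSpec],
    num_sites: int,
    seed: int,
    expected: bool = False,
) -> dict:
    """Simulate and project every scenario with independently derived seeds.

    Returns ``{spec: ProjectionCurve}``; see :func:`grid_to_frame` for the
    tidy long-format table.
    """
    seeds = derive_seeds(seed, len(specs))
    out = {}
    for spec, s in zip(specs, seeds):
        model = build_scenario(spec)
        out[spec] = simulate_projection(model, num_sites, s, expected=expected)
    return out


def derive_seeds(seed: int, count: int) -> list:
    """Independent child seeds (each < 2^31) from one root seed."""
    ss = np.random.SeedSequence(int(seed))
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(count)]


def grid_to_frame(curves: dict) -> pd.DataFrame:
    """Long-format table of a scenario grid, one row per (scenario, x)."""
    rows = []
    for spec, curve in curves.items():
        df = curve.to_frame()
        df.insert(0, "family", spec.family)
        df.insert(1, "variant", spec.variant)
        df.insert(2, "sampling_time", spec.sampling_time)
        df.insert(3, "direction", spec.direction)
        rows.append(df)
    return pd.concat(rows, ignore_index=True)
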