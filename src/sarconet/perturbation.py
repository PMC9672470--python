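"""Frequency-based perturbation schedules and correlation sweeps.

A binary model cannot express "70 % active", but a periodic forcing
pattern can: *set-activity* with frequency p drives an element ON at
evenly spread steps (ON at every k-th step, k = 1/p; e.g. p = 0.25 gives
[1-0-0-0-1-0-0-0-...]), while *inhibition* with frequency p forces it OFF
at the analogous steps and leaves it free otherwise.  Non-integer 1/p is
handled with a Bresenham-style ceiling accumulator: step i (1-based) is ON
iff ceil((i-1)*p) < ceil(i*p), which spreads exactly ceil(n*p) ON steps
over any n-step window.

Nutrition states are periodic block patterns on the food-intake element:
undernourished 5 ON / 25 OFF, well-nourished 5 ON / 10 OFF, overnourished
5 ON / 2 OFF steps.

A correlation sweep varies the forcing frequency of a source element over
a grid (default 0..1 in 1 % increments), runs an independent simulation
per level from the initial state, measures every element's activity over
the final n observed steps (n = 100 by default), and reports per-target
Pearson r with a two-sided p-value across levels.  Constant activity
series yield an undefined correlation, flagged rather than zeroed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import stats

from .boolean_engine import (
    BooleanModel,
    measure_activity,
    phenotype_scores,
    simulate,
)
from .network_core import NetworkError

__all__ = [
    "PerturbationSchedule",
    "NutritionState",
    "NUTRITION_PRESETS",
    "CompositeSchedule",
    "CorrelationResult",
    "TargetCorrelation",
    "DEFAULT_OBSERVATION_WINDOW",
    "DEFAULT_GRID",
    "set_activity_sequence",
    "inhibition_sequence",
    "nutrition_schedule",
    "correlation_sweep",
    "disease_severity_sweep",
    "rank_transmitters",
]

DEFAULT_OBSERVATION_WINDOW = 100

#: activity grid 0..100 % in 1 % increments (101 levels)
DEFAULT_GRID = tuple(i / 100 for i in range(101))


def _as_fraction(p: float) -> Fraction:
    if not 0 <= p <= 1:
        raise NetworkError(f"frequency p={p} outside [0, 1]")
    return Fraction(p).limit_denominator(10**6)


def _accumulator_marks(p: float, n: int) -> list[bool]:
    if n < 1:
        raise NetworkError("sequence length n must be >= 1")
    q = _as_fraction(p)
    return [math.ceil((i - 1) * q) < math.ceil(i * q) for i in range(1, n + 1)]


def set_activity_sequence(p: float, n: int) -> list[int]:
    """Binary forcing sequence of length n with ON-frequency p.

    ON steps are spread evenly: for p = 1/k the element is ON at steps
    1, k+1, 2k+1, ...; over any n-step window there are exactly
    ceil(n*p) ON steps.
    """
    return [int(b) for b in _accumulator_marks(p, n)]


def inhibition_sequence(p: float, n: int) -> list[int]:
    """Forced-OFF mask of length n: 1 marks steps where the element is
    clamped OFF; at unmarked steps it behaves normally."""
    return [int(b) for b in _accumulator_marks(p, n)]


@dataclass(frozen=True)
class PerturbationSchedule:
    """Periodic forcing of one element.

    Modes: ``set_activity`` clamps to the ON/OFF pattern every step;
    ``inhibit`` clamps OFF at marked steps only; ``clamp_on``/``clamp_off``
    are the constant limit cases.
    """

    element: str
    mode: str
    p: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in {"set_activity", "inhibit", "clamp_on", "clamp_off"}:
            raise NetworkError(f"unknown perturbation mode {self.mode!r}")
        _as_fraction(self.p)

    @property
    def period(self) -> int:
        if self.mode in ("clamp_on", "clamp_off"):
            return 1
        q = _as_fraction(self.p)
        return 1 if q == 0 else q.denominator

    def clamps(self, t: int) -> dict[str, bool]:
        """Clamp dict for 1-based step t."""
        if self.mode == "clamp_on":
            return {self.element: True}
        if self.mode == "clamp_off":
            return {self.element: False}
        q = _as_fraction(self.p)
        mark = math.ceil((t - 1) * q) < math.ceil(t * q)
        if self.mode == "set_activity":
            return {self.element: mark}
        return {self.element: False} if mark else {}

    __call__ = clamps


@dataclass(frozen=True)
class NutritionState:
    """Periodic block feeding pattern on the food-intake element."""

    name: str
    on_steps: int
    off_steps: int
    element: str = "food_intake"

    def __post_init__(self) -> None:
        if self.on_steps < 1 or self.off_steps < 0:
            raise NetworkError("nutrition pattern needs on_steps >= 1, off_steps >= 0")

    @property
    def period(self) -> int:
        return self.on_steps + self.off_steps

    def pattern(self, n: int) -> list[int]:
        return [1 if ((t - 1) % self.period) < self.on_steps else 0
                for t in range(1, n + 1)]

    def clamps(self, t: int) -> dict[str, bool]:
        return {self.element: ((t - 1) % self.period) < self.on_steps}

    __call__ = clamps


NUTRITION_PRESETS = {
    "undernourished": NutritionState("undernourished", 5, 25),
    "well_nourished": NutritionState("well_nourished", 5, 10),
    "overnourished": NutritionState("overnourished", 5, 2),
}


def nutrition_schedule(name: str, element: str = "food_intake") -> NutritionState:
    try:
        preset = NUTRITION_PRESETS[name]
    except KeyError:
        raise NetworkError(
            f"unknown nutrition state {name!r}; valid: {sorted(NUTRITION_PRESETS)}"
        ) from None
    return NutritionState(preset.name, preset.on_steps, preset.off_steps, element)


class CompositeSchedule:
    """Stacked clamp sources applied in order; later entries win.

    Order of application: nutrition schedule, then the source
    perturbation, then user clamps.  (Disease precedence is enforced
    inside the Boolean engine, not here.)
    """

    def __init__(self, *parts):
        self.parts = [p for p in parts if p is not None]

    @property
    def period(self) -> int:
        period = 1
        for p in self.parts:
            period = math.lcm(period, getattr(p, "period", 1))
        return period

    def __call__(self, t: int) -> dict[str, bool]:
        clamps: dict[str, bool] = {}
        for p in self.parts:
            clamps.update(p.clamps(t) if hasattr(p, "clamps") else p(t))
        return clamps


@dataclass(frozen=True)
class TargetCorrelation:
    target: str
    r: float | None  # None when the activity series is constant
    p_value: float | None
    activities: tuple[float, ...]  # one per grid level

    @property
    def defined(self) -> bool:
        return self.r is not None


@dataclass(frozen=True)
class CorrelationResult:
    source: str
    mode: str
    nutrition: str | None
    grid: tuple[float, ...]
    per_target: dict[str, TargetCorrelation]
    source_activities: tuple[float, ...]

    def __getitem__(self, target: str) -> TargetCorrelation:
        return self.per_target[target]

    def to_tsv(self) -> str:
        lines = ["target\tr\tp_value\tflag"]
        for tgt in sorted(self.per_target):
            tc = self.per_target[tgt]
            if tc.defined:
                lines.append(f"{tgt}\t{tc.r:.6g}\t{tc.p_value:.6g}\t")
            else:
                lines.append(f"{tgt}\tNA\tNA\tconstant")
        return "\n".join(lines) + "\n"

    def curves_tsv(self) -> str:
        header = "level\t" + "\t".join(sorted(self.per_target))
        lines = [header]
        for i, level in enumerate(self.grid):
            vals = "\t".join(
                f"{self.per_target[t].activities[i]:.6g}"
                for t in sorted(self.per_target)
            )
            lines.append(f"{level:.6g}\t{vals}")
        return "\n".join(lines) + "\n"


def _pearson(levels_activity, target_activity):
    x = np.asarray(levels_activity, dtype=float)
    y = np.asarray(target_activity, dtype=float)
    if np.ptp(y) == 0 or np.ptp(x) == 0:
        return None, None
    r, pval = stats.pearsonr(x, y)
    return float(r), float(pval)


def correlation_sweep(
    model: BooleanModel,
    source: str,
    mode: str = "set_activity",
    nutrition: NutritionState | str | None = None,
    targets=None,
    grid=DEFAULT_GRID,
    n: int = DEFAULT_OBSERVATION_WINDOW,
    extra_clamps=None,
) -> CorrelationResult:
    """Sweep the forcing frequency of ``source`` and correlate activities.

    Each grid level restarts from the model's initial state (independent
    simulations).  ``targets=None`` measures every element, which the
    transmitter ranking needs.
    """
    if source not in model:
        raise NetworkError(f"sweep source {source!r} not in model")
    if n < 2:
        raise NetworkError("observation window n must be >= 2")
    if isinstance(nutrition, str):
        nutrition = nutrition_schedule(nutrition)
    if targets is None:
        targets = sorted(model.rules)
    grid = tuple(grid)

    activities: dict[str, list[float]] = {t: [] for t in targets}
    source_act: list[float] = []
    for level in grid:
        pert = PerturbationSchedule(source, mode, level)
        schedule = CompositeSchedule(nutrition, pert, extra_clamps)
        trace = simulate(model, n, schedule=schedule)
        act = measure_activity(trace, set(targets) | {source}, n)
        for t in targets:
            activities[t].append(act[t])
        source_act.append(act[source])

    # x-variable is the imposed forcing level: it equals the realized
    # source activity for set_activity mode and the imposed deficiency for
    # inhibit mode (where the measured activity runs opposite to it)
    per_target = {}
    for t in targets:
        r, pval = _pearson(grid, activities[t])
        per_target[t] = TargetCorrelation(t, r, pval, tuple(activities[t]))
    return CorrelationResult(
        source=source,
        mode=mode,
        nutrition=nutrition.name if nutrition is not None else None,
        grid=grid,
        per_target=per_target,
        source_activities=tuple(source_act),
    )


def disease_severity_sweep(
    model: BooleanModel,
    disease_id: str,
    nutrition: NutritionState | str | None = None,
    n: int = DEFAULT_OBSERVATION_WINDOW,
    grid=DEFAULT_GRID,
):
    """Set-activity sweep of a disease element, scored on muscle phenotypes.

    Severity is the forcing frequency of the disease node.  Returns the
    CorrelationResult plus per-level composite phenotype scores and their
    Pearson correlation with severity.
    """
    el = model.network.elements.get(disease_id)
    if el is None or el.element_class != "disease":
        raise NetworkError(f"{disease_id!r} is not a disease-class element")
    result = correlation_sweep(
        model, disease_id, mode="set_activity", nutrition=nutrition, grid=grid, n=n
    )
    scores = {"catabolism": [], "anabolism": [], "sarcopenia": []}
    for i in range(len(result.grid)):
        act = {t: tc.activities[i] for t, tc in result.per_target.items()}
        sc = phenotype_scores(act)
        for k in scores:
            scores[k].append(sc[k])
    score_corr = {}
    for k, series in scores.items():
        r, pval = _pearson(result.grid, series)
        score_corr[k] = TargetCorrelation(k, r, pval, tuple(series))
    return result, score_corr


def rank_transmitters(result: CorrelationResult, source: str, target: str):
    """Rank elements by how strongly they track both source and target.

    For a candidate e the score is |r(e, source)| * |r(e, target)| computed
    across the sweep's activity curves; the sign pair classifies the
    transmission mode (e.g. (+, -): activated by the source, inhibits the
    target).  Candidates with undefined correlations are excluded, as are
    the endpoints themselves.
    """
    if target not in result.per_target:
        raise NetworkError(f"target {target!r} missing from sweep output")
    src_curve = result.source_activities
    tgt_curve = result.per_target[target].activities
    rows = []
    for eid, tc in result.per_target.items():
        if eid in (source, target):
            continue
        r_s, _ = _pearson(src_curve, tc.activities)
        r_t, _ = _pearson(tgt_curve, tc.activities)
        if r_s is None or r_t is None:
            continue
        rows.append(
            {
                "element": eid,
                "score": abs(r_s) * abs(r_t),
                "r_source": r_s,
                "r_target": r_t,
                "sign_pair": (int(math.copysign(1, r_s)), int(math.copysign(1, r_t))),
            }
        )
    rows.sort(key=lambda row: (-row["score"], row["element"]))
    return rows
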