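"""Synthetic endotoxemia study data.

Emulates the study design the downstream analyses expect: two age groups,
an LPS bolus (or saline) at t = 0, plasma sampled at 0, 60, 90, 240, 720
and 1440 minutes with 4 animals per time point, analytes IL-6, TNF-alpha,
IL-10 and NO2-/NO3-. Replicates are model truth multiplied by i.i.d.
lognormal noise (median 1) with a configured coefficient of variation;
values under a detection floor are recorded as 0, mimicking assay limits.

The generator records the generating parameters and overlay, so recovery
experiments can compare fitted fold changes against a known truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError, SimulationError, UnknownParameterError
from .model import DoseProtocol, resting_state, simulate, STATE_ORDER
from .params import PARAM_ORDER, ModelParameters

#: analyte column label -> model state variable.
ANALYTE_STATES = {
    "IL-6": "IL6",
    "TNF-a": "TNF",
    "IL-10": "IL10",
    "NO2-/NO3-": "NO",
}
ANALYTES = tuple(ANALYTE_STATES)

#: reference middle-aged overlay: fitted fold changes (vs the young
#: baseline) reported for the best-fitting middle-aged model variant.
MIDDLE_AGED_BEST_OVERLAY: Mapping[str, float] = {
    "h10cp": 1.0 / 8.0,
    "hn10": 1.0 / 5.0,
    "kmd": 1.0 / 3.0,
    "kmpe": 9.0,
    "kn": 16.0,
    "knpe": 5.0,
    "xcp6": 11.0,
}

DATASET_COLUMNS = ("age", "treatment", "analyte", "time_min", "replicate", "value")
SUMMARY_COLUMNS = ("age", "treatment", "analyte", "mean", "sem", "n")


def make_middle_aged_params(
    young: ModelParameters,
    overlay: Mapping[str, float],
    label: str = "middle-aged",
) -> ModelParameters:
    """Apply multiplicative fold changes to a subset of parameters.

    ``overlay`` maps parameter names to positive fold factors; all other
    parameters are untouched. Unknown names are rejected listing the valid
    vocabulary.
    """
    unknown = sorted(set(overlay) - set(PARAM_ORDER))
    if unknown:
        raise UnknownParameterError(
            f"unknown overlay parameter(s): {', '.join(unknown)}; "
            f"valid names: {', '.join(PARAM_ORDER)}"
        )
    for name, fold in overlay.items():
        if not (fold > 0 and math.isfinite(fold)):
            raise InvalidInputError(f"fold for {name!r} must be positive, got {fold!r}")
    updates = {name: young[name] * fold for name, fold in overlay.items()}
    return young.replace(label=label, **updates)


@dataclass(frozen=True)
class GroupSpec:
    """One study arm: an age label, its parameters, and a treatment."""

    age: str
    params: ModelParameters
    treatment: str  # "saline" | "LPS"

    def __post_init__(self):
        if self.treatment not in ("saline", "LPS"):
            raise InvalidInputError("treatment must be 'saline' or 'LPS'")


@dataclass(frozen=True)
class StudyDesign:
    """Design grid for one synthetic endotoxemia experiment."""

    groups: Sequence[GroupSpec]
    obs_times_min: Sequence[float] = (0.0, 60.0, 90.0, 240.0, 720.0, 1440.0)
    n_per_timepoint: int = 4
    noise_cv: float = 0.3
    detection_floor: float = 1.0
    seed: int = 0
    dose: float = 1.0

    def __post_init__(self):
        times = list(self.obs_times_min)
        if times != sorted(set(times)) or times[0] != 0:
            raise InvalidInputError("obs_times_min must strictly increase from 0")
        if self.n_per_timepoint < 2:
            raise InvalidInputError("need n_per_timepoint >= 2")
        if not 0 < self.noise_cv < 2:
            raise InvalidInputError("noise_cv must be in (0, 2)")


@dataclass
class TimeCourseDataset:
    """Replicate-level analyte measurements for every study arm.

    ``records`` is a long DataFrame with columns
    (age, treatment, analyte, time_min, replicate, value); ``truth``
    optionally records the generating parameter sets and overlays.
    """

    records: pd.DataFrame
    truth: dict = field(default_factory=dict)

    def __post_init__(self):
        missing = set(DATASET_COLUMNS) - set(self.records.columns)
        if missing:
            raise InvalidInputError(f"dataset missing column(s): {sorted(missing)}")
        if (self.records["value"] < 0).any():
            raise InvalidInputError("dataset contains negative values")

    def subset(self, age=None, treatment=None, analytes=None) -> "TimeCourseDataset":
        df = self.records
        if age is not None:
            df = df[df["age"] == age]
        if treatment is not None:
            df = df[df["treatment"] == treatment]
        if analytes is not None:
            df = df[df["analyte"].isin(analytes)]
        return TimeCourseDataset(df.reset_index(drop=True), truth=self.truth)

    def group_means(self) -> pd.DataFrame:
        """Mean value per (age, treatment, analyte, time_min)."""
        return (
            self.records.groupby(["age", "treatment", "analyte", "time_min"])
            ["value"].mean().reset_index()
        )

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TimeCourseDataset":
        df = pd.read_csv(path)
        return cls(df)


def _lognormal_sigma(cv: float) -> float:
    """Lognormal shape parameter matching a coefficient of variation."""
    return math.sqrt(math.log(1.0 + cv * cv))


def generate_timecourse(design: StudyDesign) -> TimeCourseDataset:
    """Simulate every study arm and add replicate-level measurement noise.

    Each arm is integrated from its own resting state (dose 1.0 for LPS,
    0 for saline); the model truth at the design time points is multiplied
    by i.i.d. lognormal noise with median 1 and the configured CV, per
    animal; values below ``detection_floor`` are stored as 0.
    """
    rng = np.random.default_rng(design.seed)
    sigma = _lognormal_sigma(design.noise_cv)
    times = np.asarray(design.obs_times_min, dtype=float)

    rows = []
    truth = {"overlays": {}, "labels": {}, "design": {
        "noise_cv": design.noise_cv, "seed": design.seed,
        "n_per_timepoint": design.n_per_timepoint,
        "detection_floor": design.detection_floor,
    }, "curves": {}}
    for spec in design.groups:
        dose = design.dose if spec.treatment == "LPS" else 0.0
        protocol = DoseProtocol(dose=dose, horizon=max(1440.0, times[-1]))
        try:
            rest = resting_state(spec.params)
            res = simulate(spec.params, protocol, init=rest, obs_times=times)
        except SimulationError as exc:
            raise SimulationError(
                f"simulation failed for group ({spec.age}, {spec.treatment}): {exc}",
                diagnostics=getattr(exc, "diagnostics", {}),
            ) from exc
        truth["labels"][(spec.age, spec.treatment)] = spec.params.label
        truth["curves"][(spec.age, spec.treatment)] = {
            analyte: res.get(state).copy() for analyte, state in ANALYTE_STATES.items()
        }
        for analyte, state in ANALYTE_STATES.items():
            curve = res.get(state)
            for t, mu in zip(times, curve):
                noise = np.exp(sigma * rng.standard_normal(design.n_per_timepoint))
                values = mu * noise
                values[values < design.detection_floor] = 0.0
                for rep, v in enumerate(values, start=1):
                    rows.append((spec.age, spec.treatment, analyte, t, rep, v))

    df = pd.DataFrame(rows, columns=list(DATASET_COLUMNS))
    return TimeCourseDataset(df, truth=truth)


@dataclass
class GroupSummary:
    """(mean, SEM, n) records per age x treatment x analyte."""

    records: pd.DataFrame

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "GroupSummary":
        return cls(pd.read_csv(path))


def summarize(dataset: TimeCourseDataset, at_time: float) -> GroupSummary:
    """Group summaries (mean, SEM = sd/sqrt(n), n) at one time point.

    Singleton groups get a missing SEM (NaN) with a warning, mirroring how
    a summary table would flag an undefined standard error.
    """
    df = dataset.records
    sel = df[df["time_min"] == at_time]
    if sel.empty:
        raise InvalidInputError(f"time {at_time} min not present in the dataset")
    out = []
    for (age, trt, analyte), grp in sel.groupby(["age", "treatment", "analyte"]):
        vals = grp["value"].to_numpy(dtype=float)
        n = len(vals)
        mean = float(vals.mean())
        if n >= 2:
            sem = float(vals.std(ddof=1) / math.sqrt(n))
        else:
            import warnings

            warnings.warn(
                f"SEM undefined for ({age}, {trt}, {analyte}): n < 2", stacklevel=2
            )
            sem = float("nan")
        out.append((age, trt, analyte, mean, sem, n))
    return GroupSummary(pd.DataFrame(out, columns=list(SUMMARY_COLUMNS)))


def default_two_arm_design(
    young: ModelParameters,
    overlay: Mapping[str, float] = MIDDLE_AGED_BEST_OVERLAY,
    seed: int = 0,
    noise_cv: float = 0.3,
    n_per_timepoint: int = 4,
    with_saline: bool = True,
) -> StudyDesign:
    """Young vs middle-aged LPS study (optionally with saline arms)."""
    middle = make_middle_aged_params(young, overlay)
    groups = [
        GroupSpec("young", young, "LPS"),
        GroupSpec("middle-aged", middle, "LPS"),
    ]
    if with_saline:
        groups += [
            GroupSpec("young", young, "saline"),
            GroupSpec("middle-aged", middle, "saline"),
        ]
    design = StudyDesign(
        groups=groups, seed=seed, noise_cv=noise_cv,
        n_per_timepoint=n_per_timepoint,
    )
    return design
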