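"""Ordinal classification of xenograft tumor-volume responses.

Implements the six-class preclinical response scale used by large xenograft
screening consortia: progressive disease without/with growth delay (PD1, PD2),
stable disease (SD), partial response (PR, >=50% regression), complete
response (CR, tumor below the measurable threshold at some point), and
maintained complete response (MCR, still below threshold at study end).
Classes carry integer scores 0..10 (PD1=0, MCR=10, even spacing between);
a treatment group's score is the median of its individual scores.

The decision table, given relative tumor volume RTV(t) = V(t)/V(0) over the
study window:

    CR-event  := any post-baseline volume < ``measurable_mm3``
    MCR       := CR-event and final volume < measurable_mm3
    CR        := CR-event and final volume >= measurable_mm3
    PR        := no CR-event and min RTV <= 0.5
    SD        := min RTV > 0.5 and final RTV < 1.25
    PD        := min RTV > 0.5 and final RTV >= 1.25
                 -> PD2 if a control median EFS is supplied and the animal's
                    EFS exceeds 1.5x that median, else PD1

All thresholds are parameters; the defaults (42-day window, 100 mm3
measurable threshold, RTV >= 4 event) follow common solid-tumor protocol.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ResponseClass",
    "VolumeSeries",
    "GroupResponse",
    "EfsResult",
    "relative_tumor_volume",
    "event_free_survival",
    "classify_individual",
    "group_response",
    "objective_response_rate",
    "heatmap_matrix",
    "write_heatmap",
    "read_heatmap",
    "binarize_outcome",
]


class ResponseClass(enum.Enum):
    """Ordinal response class; ``value`` is the integer heat-map score."""

    PD1 = 0
    PD2 = 2
    SD = 4
    PR = 6
    CR = 8
    MCR = 10

    @property
    def score(self) -> int:
        return self.value

    @property
    def is_objective(self) -> bool:
        """Objective responses are regressions: PR, CR, MCR."""
        return self.value >= ResponseClass.PR.value

    def __lt__(self, other: "ResponseClass") -> bool:
        return self.value < other.value

    def __le__(self, other: "ResponseClass") -> bool:
        return self.value <= other.value


#: map score -> class, for median/tie resolution
_SCORE_TO_CLASS = {c.value: c for c in ResponseClass}


@dataclass
class VolumeSeries:
    """One animal's tumor-volume trajectory (mm^3 against study day)."""

    model_id: str
    arm: str  # "control" | "treated"
    animal_id: str
    days: np.ndarray
    volumes: np.ndarray

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        self.volumes = np.asarray(self.volumes, dtype=float)
        if self.arm not in ("control", "treated"):
            raise ValueError(f"arm must be 'control' or 'treated', got {self.arm!r}")
        if self.days.shape != self.volumes.shape or self.days.ndim != 1:
            raise ValueError("days and volumes must be 1-d arrays of equal length")
        if len(self.days) == 0:
            raise ValueError("empty volume series")
        order = np.argsort(self.days)
        self.days = self.days[order]
        self.volumes = self.volumes[order]
        if np.any(np.diff(self.days) <= 0):
            raise ValueError(
                f"duplicate measurement days for animal {self.animal_id!r}"
            )
        if self.days[0] != 0:
            raise ValueError(
                f"animal {self.animal_id!r} lacks a day-0 baseline measurement"
            )
        if np.any(self.volumes < 0):
            raise ValueError(f"negative volume for animal {self.animal_id!r}")

    def __len__(self) -> int:
        return len(self.days)


@dataclass
class EfsResult:
    """Event-free survival: days to the RTV event, or censoring at last day."""

    time: float
    event: bool  # False -> censored at `time` (= last observation day)

    @property
    def comparison_time(self) -> float:
        """Event time for growth-delay comparisons; +inf when censored."""
        return self.time if self.event else math.inf


@dataclass
class GroupResponse:
    """Median response of a treatment group for one (agent, model) pair."""

    model_id: str
    agent: str
    individual_classes: list[ResponseClass]
    group_score: float = field(init=False)
    group_class: ResponseClass = field(init=False)

    def __post_init__(self) -> None:
        if not self.individual_classes:
            raise ValueError("group_response requires a non-empty class list")
        scores = sorted(c.score for c in self.individual_classes)
        n = len(scores)
        if n % 2 == 1:
            med = float(scores[n // 2])
        else:
            med = (scores[n // 2 - 1] + scores[n // 2]) / 2.0
        self.group_score = med
        # A half-way median maps to the class at the lower adjacent even
        # score (conservative: never upgrades activity).
        self.group_class = _SCORE_TO_CLASS[int(med // 2) * 2]


def relative_tumor_volume(series: VolumeSeries) -> np.ndarray:
    """RTV(t) = V(t)/V(0), dimensionless; RTV(0) = 1."""
    v0 = series.volumes[0]
    if v0 <= 0:
        raise ValueError(
            f"animal {series.animal_id!r}: baseline volume is 0, RTV undefined"
        )
    return series.volumes / v0


def event_free_survival(series: VolumeSeries, event_rtv: float = 4.0) -> EfsResult:
    """Days until RTV first reaches ``event_rtv``, linearly interpolated.

    The crossing time is interpolated between the bracketing measurements;
    if the threshold is never reached the result is censored at the last
    observation day.
    """
    rtv = relative_tumor_volume(series)
    above = np.nonzero(rtv >= event_rtv)[0]
    if len(above) == 0:
        return EfsResult(time=float(series.days[-1]), event=False)
    i = above[0]
    if i == 0:  # impossible for valid series (RTV(0)=1 < 4) but kept total
        return EfsResult(time=float(series.days[0]), event=True)
    t0, t1 = series.days[i - 1], series.days[i]
    r0, r1 = rtv[i - 1], rtv[i]
    if r1 == r0:
        t = t1
    else:
        t = t0 + (event_rtv - r0) / (r1 - r0) * (t1 - t0)
    return EfsResult(time=float(t), event=True)


def classify_individual(
    series: VolumeSeries,
    study_end: float = 42.0,
    measurable_mm3: float = 100.0,
    control_median_efs: Optional[float] = None,
    event_rtv: float = 4.0,
) -> ResponseClass:
    """Classify a single treated animal's trajectory.

    The series must be observed through ``study_end`` unless the RTV event
    occurred earlier (the animal leaves the study as progressive disease).
    Measurements beyond the study window are ignored.
    """
    efs = event_free_survival(series, event_rtv=event_rtv)
    observed_through = series.days[-1] >= study_end
    if not observed_through and not efs.event:
        raise ValueError(
            f"animal {series.animal_id!r} observed only to day {series.days[-1]:g} "
            f"< study end {study_end:g} with no progression event"
        )
    in_window = series.days <= study_end
    rtv = relative_tumor_volume(series)[in_window]
    vols = series.volumes[in_window]
    min_rtv = float(np.min(rtv))
    final_rtv = float(rtv[-1])
    final_vol = float(vols[-1])
    cr_event = bool(np.any(vols[1:] < measurable_mm3))

    if cr_event:
        if final_vol < measurable_mm3:
            return ResponseClass.MCR
        return ResponseClass.CR
    if min_rtv <= 0.5:
        return ResponseClass.PR
    if final_rtv < 1.25:
        return ResponseClass.SD
    # progressive disease; split on growth delay relative to controls
    if control_median_efs is not None and efs.comparison_time > 1.5 * control_median_efs:
        return ResponseClass.PD2
    return ResponseClass.PD1


def group_response(
    classes: Sequence[ResponseClass], model_id: str = "", agent: str = ""
) -> GroupResponse:
    """Aggregate individual classes to the group median score/class."""
    return GroupResponse(model_id=model_id, agent=agent, individual_classes=list(classes))


def _round_half_up(x: float, decimals: int = 1) -> float:
    factor = 10.0**decimals
    return math.floor(x * factor + 0.5) / factor


def objective_response_rate(
    group_classes: Iterable[ResponseClass],
) -> tuple[float, float]:
    """Objective response rate: fraction (and percent, 1 decimal) of groups
    achieving PR or better."""
    classes = list(group_classes)
    if not classes:
        raise ValueError("objective_response_rate requires a non-empty list")
    n_obj = sum(1 for c in classes if c.is_objective)
    frac = n_obj / len(classes)
    return frac, _round_half_up(100.0 * frac, 1)


def heatmap_matrix(group_responses: Sequence[GroupResponse]) -> pd.DataFrame:
    """Agent x model matrix of group scores; untested pairs are NaN (never 0:
    missing is not PD1). Row/column order follows first appearance."""
    seen: set[tuple[str, str]] = set()
    agents: list[str] = []
    models: list[str] = []
    for gr in group_responses:
        key = (gr.agent, gr.model_id)
        if key in seen:
            raise ValueError(f"duplicate (agent, model) pair {key}")
        seen.add(key)
        if gr.agent not in agents:
            agents.append(gr.agent)
        if gr.model_id not in models:
            models.append(gr.model_id)
    mat = pd.DataFrame(np.nan, index=agents, columns=models, dtype=float)
    for gr in group_responses:
        mat.loc[gr.agent, gr.model_id] = gr.group_score
    mat.index.name = "agent"
    return mat


def write_heatmap(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", na_rep="NA")


def read_heatmap(path) -> pd.DataFrame:
    mat = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"], comment="#")
    mat.index.name = "agent"
    return mat


def binarize_outcome(cls: ResponseClass) -> str:
    """Collapse the ordinal scale to the in vivo validation endpoint:
    PD1/PD2 -> "progression"; SD/PR/CR/MCR -> "progression_free"."""
    return "progression" if cls.score < ResponseClass.SD.score else "progression_free"
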