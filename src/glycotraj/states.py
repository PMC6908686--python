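"""Binding-state classification, event detection and occupancy statistics.

The classifier turns subsite RMSD profiles into a three-state label per frame:

* ``specific``    — minimum subsite RMSD at or below ``specific_max``
                    (default 0.5 nm): the ligand occupies the reference pose;
* ``unbound``     — minimum RMSD at or above ``unbound_min`` (default 4 nm):
                    the ligand is fully detached;
* ``nonspecific`` — in between (the 1-2 nm surface-adhesion band).

Hysteresis keeps a state until the RMSD crosses its boundary by at least the
hysteresis width, which suppresses chatter exactly at a threshold.  A
transition into ``specific`` is a binding event; out of it, an unbinding
event.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .profiles import RMSDProfile

STATE_LABELS = ("specific", "nonspecific", "unbound")


@dataclass(frozen=True)
class StateThresholds:
    specific_max: float = 0.5
    unbound_min: float = 4.0
    hysteresis: float = 0.1
    min_dwell: float = 10.0

    def __post_init__(self) -> None:
        if not 0 < self.specific_max < self.unbound_min:
            raise ValueError("require 0 < specific_max < unbound_min")
        if self.hysteresis < 0 or self.min_dwell < 0:
            raise ValueError("hysteresis and min_dwell must be >= 0")


@dataclass
class BindingStateSeries:
    times: np.ndarray
    state: np.ndarray  # unicode labels from STATE_LABELS
    best_subsite: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.state = np.asarray(self.state)
        self.best_subsite = np.asarray(self.best_subsite)
        n = len(self.times)
        if len(self.state) != n or len(self.best_subsite) != n:
            raise ValueError("times, state and best_subsite must have equal length")
        unknown = set(np.unique(self.state)) - set(STATE_LABELS)
        if unknown:
            raise ValueError(f"unknown state labels {unknown}")

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class BindingEvent:
    kind: str  # "binding" | "unbinding"
    time: float
    from_state: str
    to_state: str

    def __post_init__(self) -> None:
        if self.kind not in ("binding", "unbinding"):
            raise ValueError(f"invalid event kind {self.kind!r}")


def _raw_label(m: float, thresholds: StateThresholds) -> str:
    if m <= thresholds.specific_max:
        return "specific"
    if m >= thresholds.unbound_min:
        return "unbound"
    return "nonspecific"


def classify_frames(
    profiles: dict[str, RMSDProfile], thresholds: StateThresholds = StateThresholds()
) -> BindingStateSeries:
    """Classify frames from a subsite -> RMSD-profile map.

    Per frame the minimum RMSD over subsites decides the state; hysteresis is
    applied at both the specific and the unbound boundary: the current state
    is only left once the minimum crosses the relevant boundary by at least
    the hysteresis width.
    """
    if not profiles:
        raise ValueError("profiles must be non-empty")
    labels = list(profiles)
    values = np.stack([profiles[k].values for k in labels])
    times = profiles[labels[0]].times
    for k in labels[1:]:
        if not np.array_equal(profiles[k].times, times):
            raise ValueError("all profiles must share identical times")
    best = np.argmin(values, axis=0)
    m = values[best, np.arange(values.shape[1])]
    h = thresholds.hysteresis
    state = np.empty(len(times), dtype=object)
    current = _raw_label(m[0], thresholds)
    state[0] = current
    for i in range(1, len(times)):
        mi = m[i]
        if current == "specific":
            if mi > thresholds.specific_max + h:
                current = "unbound" if mi >= thresholds.unbound_min else "nonspecific"
        elif current == "unbound":
            if mi < thresholds.unbound_min - h:
                current = "specific" if mi <= thresholds.specific_max else "nonspecific"
        else:  # nonspecific
            if mi <= thresholds.specific_max:
                current = "specific"
            elif mi >= thresholds.unbound_min:
                current = "unbound"
        state[i] = current
    return BindingStateSeries(
        times=times,
        state=state.astype(str),
        best_subsite=np.array(labels, dtype=object)[best].astype(str),
    )


def min_profile(profile_maps: list[dict[str, RMSDProfile]]) -> dict[str, RMSDProfile]:
    """Ligand-level subsite profiles: per subsite, minimum over moieties.

    The ligand state is driven by the moiety/subsite pair of minimal RMSD, so
    taking the per-subsite minimum over per-moiety maps before classification
    yields the ligand-level series.
    """
    if not profile_maps:
        raise ValueError("need at least one moiety profile map")
    labels = list(profile_maps[0])
    out: dict[str, RMSDProfile] = {}
    for label in labels:
        stack = np.stack([pm[label].values for pm in profile_maps])
        out[label] = RMSDProfile(
            times=profile_maps[0][label].times,
            values=stack.min(axis=0),
            key=("ligand", label),
        )
    return out


# ---------------------------------------------------------------------------
# Events


def _runs(state: np.ndarray) -> list[list[int]]:
    """[state-start-index, end-index-exclusive] runs of constant label."""
    boundaries = np.flatnonzero(state[1:] != state[:-1]) + 1
    edges = np.concatenate(([0], boundaries, [len(state)]))
    return [[int(edges[i]), int(edges[i + 1])] for i in range(len(edges) - 1)]


def _run_duration(times: np.ndarray, start: int, end: int) -> float:
    """Duration of a frame run, crediting each frame one frame interval."""
    if len(times) < 2:
        return 0.0
    dt = float(np.median(np.diff(times)))
    return times[end - 1] - times[start] + dt


def merge_short_runs(
    times: np.ndarray, state: np.ndarray, min_dwell: float
) -> np.ndarray:
    """Absorb state runs shorter than min_dwell into their flanking runs.

    The shortest offending run is processed first (ties: earliest).  It is
    absorbed into the shorter of its two neighbours (ties: the earlier one);
    a run at either edge of the series has only one neighbour.
    """
    state = np.array(state, dtype=object)
    if min_dwell <= 0:
        return state.astype(str)
    while True:
        runs = _runs(state)
        if len(runs) == 1:
            break
        durations = [_run_duration(times, s, e) for s, e in runs]
        short = [i for i, d in enumerate(durations) if d < min_dwell]
        if not short:
            break
        i = min(short, key=lambda k: (durations[k], k))
        s, e = runs[i]
        if i == 0:
            absorber = 1
        elif i == len(runs) - 1:
            absorber = i - 1
        else:
            absorber = i - 1 if durations[i - 1] <= durations[i + 1] else i + 1
        state[s:e] = state[runs[absorber][0]]
    return state.astype(str)


def detect_events(series: BindingStateSeries, min_dwell: float = 10.0) -> list[BindingEvent]:
    """Binding/unbinding events after dwell filtering.

    Runs shorter than ``min_dwell`` (ns) are merged away first; an event is
    then emitted at every boundary where the state enters (binding) or leaves
    (unbinding) the specific state.  The event time is the time of the first
    frame of the new run.
    """
    if len(series) == 0:
        raise ValueError("series must be non-empty")
    state = merge_short_runs(series.times, series.state, min_dwell)
    events: list[BindingEvent] = []
    runs = _runs(state)
    for prev, cur in zip(runs, runs[1:]):
        from_state = str(state[prev[0]])
        to_state = str(state[cur[0]])
        t = float(series.times[cur[0]])
        if to_state == "specific":
            events.append(BindingEvent("binding", t, from_state, to_state))
        elif from_state == "specific":
            events.append(BindingEvent("unbinding", t, from_state, to_state))
    return events


# ---------------------------------------------------------------------------
# Occupancy


def _frame_weights(times: np.ndarray) -> np.ndarray:
    """Per-frame time weights (midpoint widths; uniform sampling -> equal)."""
    if len(times) == 1:
        return np.ones(1)
    dt = np.diff(times)
    w = np.empty(len(times))
    w[0] = dt[0]
    w[-1] = dt[-1]
    if len(times) > 2:
        w[1:-1] = 0.5 * (dt[:-1] + dt[1:])
    return w


def bound_fraction(
    series: BindingStateSeries, bound_states: frozenset[str] | set[str] = frozenset({"specific"})
) -> float:
    """Time-weighted fraction of the trajectory spent in ``bound_states``."""
    if len(series) == 0:
        raise ValueError("series must be non-empty")
    w = _frame_weights(series.times)
    mask = np.isin(series.state, list(bound_states))
    return float(w[mask].sum() / w.sum())


def pooled_bound_fraction(
    series_list: list[BindingStateSeries],
    bound_states: frozenset[str] | set[str] = frozenset({"specific"}),
) -> float:
    """Time-weighted bound fraction pooled over replicas."""
    if not series_list:
        raise ValueError("need at least one series")
    num = 0.0
    den = 0.0
    for series in series_list:
        w = _frame_weights(series.times)
        mask = np.isin(series.state, list(bound_states))
        num += w[mask].sum()
        den += w.sum()
    return float(num / den)


def pre_binding_conformation_fraction(
    residue_profile: RMSDProfile,
    events: list[BindingEvent],
    window: float = 50.0,
    cutoff: float = 0.25,
) -> list[float]:
    """Conformational-selection statistic per binding event.

    For each binding event at time t, the fraction of frames in [t - window, t)
    whose binding-residue RMSD is at or below ``cutoff`` (nm).  Values near 1
    mean the binding site already sat in its binding-competent conformation
    before the ligand arrived — the conformational-selection picture; this is
    a descriptive report, not a hypothesis test.
    """
    binding = [e for e in events if e.kind == "binding"]
    if not binding:
        warnings.warn("no binding events; pre-binding fractions empty", stacklevel=2)
        return []
    out = []
    for event in binding:
        mask = (residue_profile.times >= event.time - window) & (
            residue_profile.times < event.time
        )
        if not mask.any():
            out.append(float("nan"))
            continue
        out.append(float(np.mean(residue_profile.values[mask] <= cutoff)))
    return out
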