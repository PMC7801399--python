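"""Light/dark-box behavior phenotyping.

A tracked mouse is summarized per frame by the fraction of its body visible
in the light compartment (``area_fraction``) plus its centroid in mm.  This
module thresholds that series into a LIGHT / PARTIAL / DARK state sequence,
counts whole-body and partial-body transitions with an explicit state
machine, and extracts the seven anxiety-related phenotypes:

* total distance travelled in the light area (mm)
* number of full (whole-body) light->dark transitions
* total time spent in the light area (s)
* number of partial-body dark->light->dark excursions
* average speed in the light area (mm/s)
* average time in light per visit (s)
* latency to the first full transition into the dark (s)

Only the light compartment is observed (the camera covers the light box),
so kinematics are computed over fully-in-light frames only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LIGHT",
    "PARTIAL",
    "DARK",
    "TrackingProfile",
    "StateSequence",
    "PhenotypeVector",
    "compute_states",
    "count_transitions",
    "compute_phenotypes",
    "extract_phenotypes",
    "PHENOTYPE_NAMES",
]

DARK = 0
PARTIAL = 1
LIGHT = 2

_STATE_NAMES = {DARK: "DARK", PARTIAL: "PARTIAL", LIGHT: "LIGHT"}

#: Column order used whenever phenotypes are tabulated.
PHENOTYPE_NAMES = (
    "distance_light",
    "n_full_transitions",
    "time_light",
    "n_partial_transitions",
    "avg_speed",
    "avg_time_light",
    "latency_first_transition",
)


@dataclass
class TrackingProfile:
    """Per-frame tracking series for one mouse over one assay.

    Parameters
    ----------
    t : array of float
        Time stamps in seconds on a uniform grid starting at 0.
    area_fraction : array of float
        Fraction of the mouse body visible in the light compartment,
        in [0, 1].
    x, y : array of float
        Centroid in mm within the light compartment; NaN when the mouse
        is not visible (fully in the dark).
    frame_rate : float
        Frames per second.
    """

    t: np.ndarray
    area_fraction: np.ndarray
    x: np.ndarray
    y: np.ndarray
    frame_rate: float
    mouse_id: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.area_fraction = np.asarray(self.area_fraction, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        n = self.t.size
        if not (self.area_fraction.size == self.x.size == self.y.size == n):
            raise ValueError("t, area_fraction, x, y must have equal length")
        if n >= 2:
            dt = np.diff(self.t)
            if not np.allclose(dt, 1.0 / self.frame_rate, rtol=0, atol=1e-6):
                raise ValueError("t must be a uniform grid with step 1/frame_rate")
        finite = self.area_fraction[np.isfinite(self.area_fraction)]
        if finite.size and (finite.min() < -1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError("area_fraction must lie in [0, 1]")

    @property
    def n_frames(self) -> int:
        return self.t.size

    @property
    def duration(self) -> float:
        """Assay duration in seconds (number of frames / frame rate)."""
        return self.n_frames / self.frame_rate


@dataclass
class StateSequence:
    """Per-frame LIGHT/PARTIAL/DARK states with the thresholds that made them."""

    states: np.ndarray
    theta_hi: float
    theta_lo: float
    min_dwell: int = 1

    def runs(self) -> list[tuple[int, int, int]]:
        """Maximal runs as ``(state, start, length)`` triples."""
        return _runs(self.states)


@dataclass
class PhenotypeVector:
    """The seven light/dark-box phenotypes for one mouse."""

    distance_light: float  # mm
    n_full_transitions: int
    time_light: float  # s
    n_partial_transitions: int
    avg_speed: float  # mm/s
    avg_time_light: float  # s
    latency_first_transition: float  # s
    mouse_id: str = ""

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in PHENOTYPE_NAMES], dtype=float)


def _runs(states: np.ndarray) -> list[tuple[int, int, int]]:
    if states.size == 0:
        return []
    change = np.flatnonzero(np.diff(states)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [states.size]))
    return [(int(states[s]), int(s), int(e - s)) for s, e in zip(starts, ends)]


def compute_states(
    profile: TrackingProfile,
    theta_hi: float = 0.95,
    theta_lo: float = 0.05,
    min_dwell: int = 3,
) -> StateSequence:
    """Threshold the area-fraction series into LIGHT/PARTIAL/DARK states.

    A frame is LIGHT when ``area_fraction >= theta_hi`` (whole body in the
    light), DARK when ``<= theta_lo`` and PARTIAL in between.  Runs shorter
    than ``min_dwell`` frames are merged into the preceding state
    (segmentation-flicker debounce); the opening run is reported as given,
    since there is nothing before t=0 to absorb it into.

    Raises
    ------
    ValueError
        If thresholds are inconsistent or any frame has NaN area.
    """
    if not theta_lo < theta_hi:
        raise ValueError(f"need theta_lo < theta_hi, got {theta_lo} >= {theta_hi}")
    if min_dwell < 1:
        raise ValueError("min_dwell must be >= 1")
    area = profile.area_fraction
    bad = np.flatnonzero(~np.isfinite(area))
    if bad.size:
        raise ValueError(f"NaN/inf area_fraction at frame {bad[0]}")

    states = np.full(area.shape, PARTIAL, dtype=np.int8)
    states[area >= theta_hi] = LIGHT
    states[area <= theta_lo] = DARK

    if min_dwell > 1:
        states = _debounce(states, min_dwell)
    return StateSequence(states=states, theta_hi=theta_hi, theta_lo=theta_lo, min_dwell=min_dwell)


def _debounce(states: np.ndarray, min_dwell: int) -> np.ndarray:
    """Merge runs shorter than ``min_dwell`` into the preceding run's state.

    The first run is exempt: its state is taken at face value.  Merging is
    repeated until every non-initial run reaches the dwell requirement.
    """
    out = states.copy()
    while True:
        runs = _runs(out)
        short = [
            (st, s, ln) for st, s, ln in runs[1:] if ln < min_dwell
        ]
        if not short:
            return out
        st, s, ln = short[0]
        prev_state = out[s - 1]
        out[s : s + ln] = prev_state


def count_transitions(states: StateSequence | np.ndarray) -> tuple[int, int]:
    """Count full and partial transitions from a state sequence.

    A *full* transition is counted each time the mouse reaches DARK after
    having been in LIGHT more recently than in DARK, i.e. a whole-body
    light->dark excursion (possibly passing through PARTIAL).  A *partial*
    transition is a DARK -> PARTIAL -> ... -> DARK excursion that never
    reaches LIGHT: the mouse pokes part of its body into the light and
    withdraws.
    """
    seq = states.states if isinstance(states, StateSequence) else np.asarray(states)
    n_full = 0
    n_partial = 0
    last_major = None  # most recent LIGHT or DARK state seen
    in_partial_excursion = False  # currently in a PARTIAL run that started from DARK
    for st, _, _ in _runs(seq):
        if st == LIGHT:
            last_major = LIGHT
            in_partial_excursion = False
        elif st == DARK:
            if last_major == LIGHT:
                n_full += 1
            elif in_partial_excursion:
                n_partial += 1
            last_major = DARK
            in_partial_excursion = False
        else:  # PARTIAL
            in_partial_excursion = last_major == DARK
    return n_full, n_partial


def compute_phenotypes(
    profile: TrackingProfile, states: StateSequence
) -> PhenotypeVector:
    """Extract the seven phenotypes from a profile and its state sequence.

    Time in light counts frames where the majority of the body
    (``area_fraction >= 0.5``) is in the light compartment, so PARTIAL
    frames near the opening split sensibly between the compartments.
    Distance and speed are computed over frame pairs whose endpoints are
    both fully in light (state LIGHT), the only frames with reliable
    centroids.  Latency is the time of the first entry into DARK and equals
    the assay duration for mice that never leave the light.
    """
    seq = states.states
    if seq.size != profile.n_frames:
        raise ValueError("states were not derived from this profile")
    fr = profile.frame_rate

    time_light = float(np.count_nonzero(profile.area_fraction >= 0.5)) / fr

    light = seq == LIGHT
    pair = light[:-1] & light[1:]
    dx = np.diff(profile.x)
    dy = np.diff(profile.y)
    step = np.hypot(dx, dy)
    valid = pair & np.isfinite(step)
    distance_light = float(step[valid].sum())

    time_in_light_state = float(np.count_nonzero(light)) / fr
    if time_in_light_state == 0.0:
        if distance_light > 0:
            raise RuntimeError("internal inconsistency: distance without light time")
        avg_speed = 0.0
    else:
        avg_speed = distance_light / time_in_light_state

    n_full, n_partial = count_transitions(states)

    runs = _runs(seq)
    dark_starts = [s for st, s, _ in runs if st == DARK]
    latency = dark_starts[0] / fr if dark_starts else profile.duration

    n_visits = sum(1 for st, _, _ in runs if st == LIGHT)
    avg_time_light = time_light / n_visits if n_visits > 0 else 0.0

    return PhenotypeVector(
        distance_light=distance_light,
        n_full_transitions=n_full,
        time_light=time_light,
        n_partial_transitions=n_partial,
        avg_speed=avg_speed,
        avg_time_light=avg_time_light,
        latency_first_transition=latency,
        mouse_id=profile.mouse_id,
    )


def extract_phenotypes(
    profile: TrackingProfile,
    theta_hi: float = 0.95,
    theta_lo: float = 0.05,
    min_dwell: int = 3,
) -> PhenotypeVector:
    """Convenience wrapper: states + phenotypes in one call."""
    states = compute_states(profile, theta_hi=theta_hi, theta_lo=theta_lo, min_dwell=min_dwell)
    return compute_phenotypes(profile, states)
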