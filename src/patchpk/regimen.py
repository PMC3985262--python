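"""Patch-wear timelines as ordered event lists.

A regimen is a sequence of patch events — application, scheduled
replacement, (partial) detachment, reattachment, removal — over a
simulation horizon.  Between events the wearer's state is constant:
either no patch, or one patch with a fixed attached-area fraction and a
known application time (its "age origin").  The absorption model needs
exactly that state, so regimens compile to a list of constant segments.

The release rate resets when a patch is replaced or a new one applied;
reattaching the *same* patch after a partial detachment does not reset
it — the patch has kept aging on (or off) the skin.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterator, Optional

__all__ = ["EventKind", "PatchEvent", "Regimen", "Segment", "RegimenError"]


class RegimenError(ValueError):
    """Raised for invalid or physically impossible event timelines."""


class EventKind(str, Enum):
    APPLY_NEW = "apply_new"
    REPLACE = "replace"
    DETACH = "detach"
    REATTACH = "reattach"
    REMOVE = "remove"


@dataclass(frozen=True)
class PatchEvent:
    """One timeline event.

    ``area_fraction`` is the fraction of the patch contact area attached
    *after* the event: 1 for apply/replace/reattach, 0 for removal or
    total detachment, anything in (0, 1) for partial detachment.
    """

    time: float
    kind: EventKind
    area_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.time < 0:
            raise RegimenError(f"event time must be non-negative, got {self.time}")
        if not 0.0 <= self.area_fraction <= 1.0:
            raise RegimenError(
                f"area_fraction must lie in [0, 1], got {self.area_fraction}"
            )
        if self.kind in (EventKind.APPLY_NEW, EventKind.REPLACE, EventKind.REATTACH):
            if self.area_fraction != 1.0:
                raise RegimenError(f"{self.kind.value} must have area_fraction = 1")
        if self.kind is EventKind.REMOVE and self.area_fraction != 0.0:
            raise RegimenError("remove must have area_fraction = 0")


@dataclass(frozen=True)
class Segment:
    """Constant wear state on [t_start, t_end).

    ``age_origin`` is the time the currently worn patch was applied
    (None when no patch is worn); patch age at time t within the segment
    is ``t - age_origin``.
    """

    t_start: float
    t_end: float
    area_fraction: float
    age_origin: Optional[float]


@dataclass(frozen=True)
class Regimen:
    """Validated, time-ordered patch event list with a horizon (hours)."""

    events: tuple[PatchEvent, ...]
    horizon: float

    def __init__(self, events, horizon: float):
        events = tuple(sorted(events, key=lambda e: e.time))
        object.__setattr__(self, "events", events)
        object.__setattr__(self, "horizon", float(horizon))
        self._validate()

    def _validate(self) -> None:
        if self.horizon <= 0:
            raise RegimenError("horizon must be positive")
        if not self.events:
            raise RegimenError("a regimen needs at least one event")
        first = self.events[0]
        if first.kind is not EventKind.APPLY_NEW or first.area_fraction != 1.0:
            raise RegimenError("first event must be apply_new with full area")
        for ev in self.events:
            if ev.time >= self.horizon:
                raise RegimenError(
                    f"event at {ev.time} h is not before horizon {self.horizon} h"
                )
        # replay the state machine once so invalid sequences fail at build time
        list(self.segments())

    def segments(self) -> list[Segment]:
        """Compile the timeline into constant-state segments covering [0, horizon]."""
        segs: list[Segment] = []
        area = 0.0
        origin: Optional[float] = None
        worn = False  # a patch is assigned (possibly detached, area 0)
        t_prev = 0.0

        def push(t_next: float) -> None:
            if t_next > t_prev:
                segs.append(Segment(t_prev, t_next, area if worn else 0.0,
                                    origin if worn else None))

        for ev in self.events:
            push(ev.time)
            k = ev.kind
            if k is EventKind.APPLY_NEW:
                if worn and area >= 1.0 and ev.time > 0:
                    raise RegimenError(
                        f"apply_new at {ev.time} h overlaps a fully attached patch; "
                        "use replace to swap patches"
                    )
                worn, area, origin = True, 1.0, ev.time
            elif k is EventKind.REPLACE:
                if not worn:
                    raise RegimenError(f"replace at {ev.time} h with no patch worn")
                area, origin = 1.0, ev.time
            elif k is EventKind.DETACH:
                if not worn or area == 0.0:
                    raise RegimenError(f"detach at {ev.time} h with no attached patch")
                area = ev.area_fraction
                if area >= 1.0:
                    raise RegimenError("detach must reduce the attached area below 1")
            elif k is EventKind.REATTACH:
                if not worn:
                    raise RegimenError(f"reattach at {ev.time} h with no patch assigned")
                area = 1.0  # age origin unchanged: same patch
            elif k is EventKind.REMOVE:
                if not worn:
                    raise RegimenError(f"remove at {ev.time} h with no patch worn")
                worn, area, origin = False, 0.0, None
            t_prev = ev.time
        push(self.horizon)
        return segs

    def state_at(self, t: float) -> tuple[float, Optional[float]]:
        """Return (attached area fraction, patch age) at time ``t``."""
        for seg in self.segments():
            if seg.t_start <= t < seg.t_end or (t == self.horizon and seg.t_end == t):
                age = None if seg.age_origin is None else t - seg.age_origin
                return seg.area_fraction, age
        raise ValueError(f"time {t} outside [0, {self.horizon}]")

    def final_removal_time(self) -> Optional[float]:
        """Time of the last removal event, if any."""
        times = [e.time for e in self.events if e.kind is EventKind.REMOVE]
        return max(times) if times else None

    def __iter__(self) -> Iterator[PatchEvent]:
        return iter(self.events)
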