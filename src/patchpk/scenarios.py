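"""Regimen constructors for compliant and non-compliant patch use.

The prescribed cycle is one patch per week for three weeks (application
at 0 h, replacements at 168 h and 336 h, removal at 504 h) followed by a
patch-free week.  Non-compliance is expressed as modified event
timelines: a replacement delayed by whole days, or a partial/total
detachment of given duration, after which the wearer either presses the
same patch back (its age, and hence its depleted release rate, carries
on) or applies a fresh one (release rate resets).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

from .regimen import EventKind, PatchEvent, Regimen, RegimenError

__all__ = [
    "ScenarioSpec",
    "standard_cycle",
    "delayed_replacement",
    "detachment",
    "build_regimen",
    "WEEK_H",
    "CYCLE_H",
    "DECAY_TAIL_H",
]

WEEK_H = 168.0
CYCLE_H = 3 * WEEK_H  # 504 h of patch wear
#: horizon extension past final removal, exposing the elimination phase
DECAY_TAIL_H = 96.0

_KINDS = ("standard_cycle", "delayed_replacement", "missed_replacement", "detachment")


@dataclass(frozen=True)
class ScenarioSpec:
    """Declarative scenario: a kind plus kind-specific parameters.

    Recognised kinds and their parameters:

    - ``standard_cycle`` — none
    - ``delayed_replacement`` / ``missed_replacement`` — ``delay_days``
      (and optionally ``boundary_h``, default 336)
    - ``detachment`` — ``detach_time``, ``area_fraction``, ``duration``,
      ``reattach_vs_new`` ("reattach" or "new")
    """

    kind: str
    parameters: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown scenario kind {self.kind!r}; one of {_KINDS}")
        p = dict(self.parameters)
        if self.kind in ("delayed_replacement", "missed_replacement"):
            if p.get("delay_days", 0) < 0:
                raise ValueError("delay_days must be non-negative")
        if self.kind == "detachment":
            af = p.get("area_fraction", 0.0)
            if not 0.0 <= af < 1.0:
                raise ValueError("area_fraction during detachment must lie in [0, 1)")
            if p.get("duration", 0.0) < 0:
                raise ValueError("duration must be non-negative")


def standard_cycle() -> Regimen:
    """The prescribed three-week cycle, plus a 96 h post-removal tail."""
    events = [
        PatchEvent(0.0, EventKind.APPLY_NEW, 1.0),
        PatchEvent(WEEK_H, EventKind.REPLACE, 1.0),
        PatchEvent(2 * WEEK_H, EventKind.REPLACE, 1.0),
        PatchEvent(CYCLE_H, EventKind.REMOVE, 0.0),
    ]
    return Regimen(events, horizon=CYCLE_H + DECAY_TAIL_H)


def delayed_replacement(delay_days: float, boundary_h: float = 2 * WEEK_H) -> Regimen:
    """Replacement at ``boundary_h`` forgotten for ``delay_days`` days.

    The old patch stays on (its release rate keeps attenuating) until the
    delayed replacement; the fresh patch is then worn for a full week, so
    the whole cycle shifts by the delay.
    """
    if delay_days < 0:
        raise ValueError("delay_days must be non-negative")
    if boundary_h not in (WEEK_H, 2 * WEEK_H):
        raise ValueError("boundary_h must be a scheduled replacement time (168 or 336)")
    delay_h = 24.0 * delay_days
    events = [PatchEvent(0.0, EventKind.APPLY_NEW, 1.0)]
    t = WEEK_H
    while t < CYCLE_H:
        actual = t + delay_h if t == boundary_h else t + (delay_h if t > boundary_h else 0.0)
        events.append(PatchEvent(actual, EventKind.REPLACE, 1.0))
        t += WEEK_H
    events.append(PatchEvent(CYCLE_H + delay_h, EventKind.REMOVE, 0.0))
    return Regimen(events, horizon=CYCLE_H + delay_h + DECAY_TAIL_H)


def detachment(detach_time: float, area_fraction: float, duration: float,
               reattach_vs_new: str = "reattach") -> Regimen:
    """Standard cycle with a detachment inserted at ``detach_time``.

    ``area_fraction`` is the fraction *remaining attached* (0 = total
    detachment).  After ``duration`` hours the patch is either reattached
    (same patch: age keeps running) or a new one applied (age resets).
    A no-op detachment (``duration`` 0 or full area) returns the standard
    cycle unchanged.
    """
    if not 0.0 <= area_fraction <= 1.0:
        raise ValueError("area_fraction must lie in [0, 1]")
    if duration < 0:
        raise ValueError("duration must be non-negative")
    if reattach_vs_new not in ("reattach", "new"):
        raise ValueError("reattach_vs_new must be 'reattach' or 'new'")
    if duration == 0.0 or area_fraction == 1.0:
        return standard_cycle()
    if not 0.0 <= detach_time < CYCLE_H:
        raise RegimenError("detachment must occur while a patch is worn (0–504 h)")
    t_back = detach_time + duration
    boundaries = [WEEK_H, 2 * WEEK_H, CYCLE_H]
    if any(detach_time < b < t_back or detach_time < b == t_back for b in boundaries):
        raise RegimenError(
            "detachment interval crosses a scheduled replacement/removal; "
            "build such regimens from events directly"
        )
    back_kind = EventKind.REATTACH if reattach_vs_new == "reattach" else EventKind.APPLY_NEW
    events = [
        PatchEvent(0.0, EventKind.APPLY_NEW, 1.0),
        PatchEvent(WEEK_H, EventKind.REPLACE, 1.0),
        PatchEvent(2 * WEEK_H, EventKind.REPLACE, 1.0),
        PatchEvent(detach_time, EventKind.DETACH, area_fraction),
        PatchEvent(t_back, back_kind, 1.0),
        PatchEvent(CYCLE_H, EventKind.REMOVE, 0.0),
    ]
    return Regimen(events, horizon=CYCLE_H + DECAY_TAIL_H)


def build_regimen(spec: ScenarioSpec) -> Regimen:
    """Construct the regimen a :class:`ScenarioSpec` describes."""
    p = spec.parameters
    if spec.kind == "standard_cycle":
        return standard_cycle()
    if spec.kind in ("delayed_replacement", "missed_replacement"):
        return delayed_replacement(p.get("delay_days", 0),
                                   p.get("boundary_h", 2 * WEEK_H))
    return detachment(
        p["detach_time"], p.get("area_fraction", 0.0),
        p.get("duration", 24.0), p.get("reattach_vs_new", "reattach"),
    )
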