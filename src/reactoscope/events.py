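"""Event engine: triggers, effects, and the main acquisition loop.

An experiment is a backbone of timed image acquisitions plus a registry of
events. An event pairs a *trigger* (a predicate over the experiment state)
with an *effect* (an action on the state / hardware handle) and a recurrence
policy. After each frame's acquisitions and analysis hooks, all active
triggers are evaluated on the updated state and the effects of true triggers
are applied in registration order. Effects may register new events, which
become visible from the next frame's evaluation pass. Execution is
sequential-equivalent: effects never interleave within a frame.

A raising effect is logged and isolated — the remaining effects of the frame
still run and the experiment continues.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

from .logbook import ExperimentLog

__all__ = ["Event", "one_shot", "every_frame", "until_frame",
           "ExperimentState", "register_event", "evaluate_frame"]


@dataclass
class Event:
    """A trigger predicate plus an effect action with a recurrence policy.

    recurrence: "one-shot" (deactivated after first firing), "every-frame",
    or "until-frame" with ``until_frame`` set (active while
    frame_index <= until_frame).
    """

    id: str
    trigger: Callable  # (ExperimentState) -> bool
    effect: Callable  # (ExperimentState, hardware) -> None
    recurrence: str = "one-shot"
    until_frame: int | None = None
    created_at_frame: int = 0
    active: bool = True

    def __post_init__(self) -> None:
        if self.recurrence not in ("one-shot", "every-frame", "until-frame"):
            raise ValueError(f"unknown recurrence {self.recurrence!r}")
        if self.recurrence == "until-frame" and self.until_frame is None:
            raise ValueError("until-frame recurrence needs until_frame")


def one_shot(id: str, trigger, effect, created_at_frame: int = 0) -> Event:
    return Event(id, trigger, effect, "one-shot", created_at_frame=created_at_frame)


def every_frame(id: str, trigger, effect, created_at_frame: int = 0) -> Event:
    return Event(id, trigger, effect, "every-frame", created_at_frame=created_at_frame)


def until_frame(id: str, trigger, effect, n: int, created_at_frame: int = 0) -> Event:
    return Event(id, trigger, effect, "until-frame", until_frame=n,
                 created_at_frame=created_at_frame)


@dataclass
class ExperimentState:
    """Mutable state threaded through the acquisition loop."""

    frame_index: int = 0
    brightfield_period_min: float = 3.0
    positions: list = field(default_factory=lambda: [0])
    latest_images: dict = field(default_factory=dict)  # (position, channel) -> image
    tracked_cells: dict = field(default_factory=dict)  # position -> list[TrackedCell]
    channel_exposures: dict = field(default_factory=dict)
    event_registry: list = field(default_factory=list)
    log: ExperimentLog = field(default_factory=ExperimentLog)
    extras: dict = field(default_factory=dict)  # scenario scratch space

    @property
    def clock_min(self) -> float:
        return self.frame_index * self.brightfield_period_min


def register_event(state: ExperimentState, event: Event) -> bool:
    """Add an event to the registry; duplicate ids are rejected (logged)."""
    if any(e.id == event.id for e in state.event_registry):
        state.log.error("core", "duplicate event id rejected", event_id=event.id)
        return False
    event.created_at_frame = state.frame_index
    state.event_registry.append(event)
    state.log.info("core", "event registered", event_id=event.id,
                   recurrence=event.recurrence)
    return True


def _event_due(event: Event, frame: int) -> bool:
    if not event.active:
        return False
    if event.created_at_frame > frame:
        return False
    if event.recurrence == "until-frame" and frame > event.until_frame:
        return False
    return True


def evaluate_frame(
    state: ExperimentState,
    hardware,
    acquisition=None,
    analysis_hooks: tuple = (),
) -> ExperimentState:
    """Run one frame: acquire -> analyze -> evaluate triggers -> apply effects.

    ``acquisition(state, hardware)`` acquires whatever channels are due this
    frame; ``analysis_hooks`` run afterwards (segmentation, tracking,
    quantification, controllers...). Triggers are evaluated only after all
    hooks complete, on a snapshot of the registry, so events registered by an
    effect are first evaluated on the next frame. A raising effect is logged
    as an error and does not abort the frame.
    """
    log = state.log
    log.frame_index = state.frame_index
    log.info("core", "frame start", frame=state.frame_index,
             clock_min=state.clock_min)
    if acquisition is not None:
        acquisition(state, hardware)
    for hook in analysis_hooks:
        hook(state, hardware)
    snapshot = list(state.event_registry)
    for event in snapshot:
        if not _event_due(event, state.frame_index):
            continue
        try:
            fired = bool(event.trigger(state))
        except Exception as exc:  # noqa: BLE001 - fault isolation
            log.error("core", "trigger raised", event_id=event.id, error=repr(exc))
            continue
        if not fired:
            continue
        log.info("core", "effect applied", event_id=event.id,
                 frame=state.frame_index)
        try:
            event.effect(state, hardware)
        except Exception as exc:  # noqa: BLE001 - fault isolation
            log.error("core", "effect raised", event_id=event.id, error=repr(exc))
        if event.recurrence == "one-shot":
            event.active = False
    state.frame_index += 1
    return state
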