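"""Activity / motion-state hierarchies and their many-to-many correspondence.

Coarse-to-fine recognition rests on a two-level label structure: a set of
``n`` activities ``A`` (what the wearer is doing: eating, reading, walking
outside, ...) and a much smaller set of ``m`` motion states ``M`` (the
kinematic regime the trunk is in: lying, sedentary, standing, walking).
When every activity occurs in exactly one motion state the structure is a
plain many-to-one mapping ``phi: A -> M`` whose preimages partition ``A``
into ``m`` disjoint groups. Real activities are messier — reading happens
seated or standing, phone calls while lying, seated or walking — so the
mapping generalizes to a many-to-many *correspondence*: an activity is a
member of every group it can occur in, and group sizes then sum to more
than ``n``.

This module represents those objects, validates them (an activity outside
every group could never be emitted by the hierarchical recognizer, so
coverage failures are hard errors), and ships the published hierarchies as
declarative YAML fixtures: the 15-activity / 4-state chest-camera hierarchy
(``"ebutton"``) and the four 20-activity groupings ``"M5"``–``"M8"`` used
for the grouping-granularity sweep.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import yaml

__all__ = [
    "ActivitySet",
    "MotionStateSet",
    "Correspondence",
    "build_correspondence",
    "load_hierarchy_file",
    "load_fixture",
    "FIXTURE_NAMES",
]


class HierarchyError(ValueError):
    """Raised for structurally invalid hierarchies (coverage, unknown labels)."""


def _check_unique(labels: tuple[str, ...], what: str) -> None:
    if len(labels) == 0:
        raise HierarchyError(f"{what} must contain at least one label")
    seen = set()
    for lab in labels:
        if lab in seen:
            raise HierarchyError(f"duplicate {what} label: {lab!r}")
        seen.add(lab)


@dataclass(frozen=True)
class ActivitySet:
    """Ordered set of activity labels; order defines the global activity index."""

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(self.labels))
        _check_unique(self.labels, "activity")

    @property
    def n(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown activity: {label!r}") from None

    def __contains__(self, label: object) -> bool:
        return label in self.labels

    def __iter__(self):
        return iter(self.labels)

    def __len__(self) -> int:
        return self.n


@dataclass(frozen=True)
class MotionStateSet:
    """Ordered set of motion-state labels (the coarse layer)."""

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(self.labels))
        _check_unique(self.labels, "motion state")

    @property
    def m(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown motion state: {label!r}") from None

    def __contains__(self, label: object) -> bool:
        return label in self.labels

    def __iter__(self):
        return iter(self.labels)

    def __len__(self) -> int:
        return self.m


@dataclass(frozen=True)
class Correspondence:
    """Many-to-many relation between activities and motion states.

    Stores the link set ``pairs`` together with both ordered label sets.
    Construction validates coverage in both directions: every activity must
    belong to at least one group and every state must own at least one
    activity. When every activity has exactly one state the relation is a
    function and the groups partition the activity set.
    """

    activity_set: ActivitySet
    state_set: MotionStateSet
    pairs: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        object.__setattr__(self, "pairs", frozenset(self.pairs))
        for act, st in self.pairs:
            if act not in self.activity_set:
                raise KeyError(f"unknown activity in pair: {act!r}")
            if st not in self.state_set:
                raise KeyError(f"unknown motion state in pair: {st!r}")
        linked_acts = {a for a, _ in self.pairs}
        missing = [a for a in self.activity_set if a not in linked_acts]
        if missing:
            raise HierarchyError(
                "activities not covered by any motion-state group: "
                + ", ".join(repr(a) for a in missing)
            )
        linked_states = {s for _, s in self.pairs}
        empty = [s for s in self.state_set if s not in linked_states]
        if empty:
            raise HierarchyError(
                "motion states with empty groups: " + ", ".join(repr(s) for s in empty)
            )

    # -- set algebra ------------------------------------------------------

    def invert(self, state: str) -> tuple[str, ...]:
        """Group of the given state: all its activities in canonical A order."""
        if state not in self.state_set:
            raise KeyError(f"unknown motion state: {state!r}")
        members = {a for a, s in self.pairs if s == state}
        return tuple(a for a in self.activity_set if a in members)

    def states_of(self, activity: str) -> tuple[str, ...]:
        """All motion states the activity can occur in, in canonical M order."""
        if activity not in self.activity_set:
            raise KeyError(f"unknown activity: {activity!r}")
        states = {s for a, s in self.pairs if a == activity}
        return tuple(s for s in self.state_set if s in states)

    def group_sizes(self) -> tuple[tuple[int, ...], int]:
        """Per-state group sizes ``n_i`` (in M order) and their total.

        The total equals ``n`` exactly when the relation is a function of
        activities; any multi-state activity pushes it above ``n``.
        """
        sizes = tuple(len(self.invert(s)) for s in self.state_set)
        return sizes, sum(sizes)

    def singleton_groups(self) -> tuple[str, ...]:
        """States whose group holds a single activity.

        Samples routed to these states are recognized by the motion sensor
        alone; no image classifier is consulted.
        """
        return tuple(s for s in self.state_set if len(self.invert(s)) == 1)

    def is_function(self) -> bool:
        """True iff every activity maps to exactly one state (the phi case)."""
        return all(len(self.states_of(a)) == 1 for a in self.activity_set)

    def fingerprint(self) -> str:
        """Stable hex digest identifying this hierarchy across artifacts."""
        import hashlib

        payload = repr(
            (self.activity_set.labels, self.state_set.labels, sorted(self.pairs))
        ).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def build_correspondence(
    activities: ActivitySet | list[str],
    states: MotionStateSet | list[str],
    pairs: list[tuple[str, str]] | set[tuple[str, str]],
) -> Correspondence:
    """Build and validate a Correspondence from explicit (activity, state) links.

    Raises :class:`KeyError` for labels outside the declared sets and
    :class:`HierarchyError` if any activity is left uncovered or any state's
    group is empty.
    """
    if not isinstance(activities, ActivitySet):
        activities = ActivitySet(tuple(activities))
    if not isinstance(states, MotionStateSet):
        states = MotionStateSet(tuple(states))
    return Correspondence(activities, states, frozenset(pairs))


def identity_correspondence(activities: list[str] | ActivitySet) -> Correspondence:
    """Degenerate phi where each activity is its own motion state (m = n)."""
    if isinstance(activities, ActivitySet):
        activities = list(activities.labels)
    return build_correspondence(
        activities, list(activities), [(a, a) for a in activities]
    )


# -- fixture loading ------------------------------------------------------

FIXTURE_NAMES = ("eButton", "M5", "M6", "M7", "M8")

_FIXTURE_FILES = {
    "ebutton": "ebutton.yaml",
    "m5": "m5.yaml",
    "m6": "m6.yaml",
    "m7": "m7.yaml",
    "m8": "m8.yaml",
}


def hierarchy_from_mapping(cfg: dict) -> Correspondence:
    """Build a Correspondence from the declarative config mapping.

    Expected keys: ``activities`` (ordered list), ``motion_states`` (ordered
    list), ``correspondence`` (state -> activity-list map).
    """
    try:
        acts = list(cfg["activities"])
        states = list(cfg["motion_states"])
        corr = dict(cfg["correspondence"])
    except KeyError as exc:
        raise HierarchyError(f"hierarchy config missing section: {exc}") from None
    pairs = [(a, s) for s, members in corr.items() for a in members]
    return build_correspondence(acts, states, pairs)


def load_hierarchy_file(path) -> Correspondence:
    """Load a hierarchy from a YAML config file on disk."""
    with open(path, "r", encoding="utf-8") as fh:
        return hierarchy_from_mapping(yaml.safe_load(fh))


def load_fixture(name: str) -> Correspondence:
    """Load a packaged hierarchy by name: ``eButton`` or ``M5``..``M8``."""
    key = name.lower().replace("-", "").replace("ℳ", "m")
    if key not in _FIXTURE_FILES:
        raise KeyError(
            f"unknown hierarchy fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
        )
    ref = importlib.resources.files("hierfusion.fixtures") / _FIXTURE_FILES[key]
    return hierarchy_from_mapping(yaml.safe_load(ref.read_text(encoding="utf-8")))
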