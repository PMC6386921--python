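"""Hierarchical recognition and the direct-fusion / flat baselines.

Hierarchical recognition is a two-stage hard cascade: the motion-state
classifier routes the sensor segment to the group ``j`` with the highest
state posterior; if that group holds a single activity the activity is
emitted directly (the motion sensor alone resolves it), otherwise the
group's image classifier — single-frame head for low-frame-rate photo
streams (``Ips = L``), frame-sequence network for high-rate streams
(``Ips = H``) — picks the activity inside the group. The emitted activity
is therefore always a member of the routed group.

The direct-fusion baseline instead runs two flat classifiers over the full
activity set (one per modality) and pools their softmax outputs
elementwise, by average or by maximum. Average pooling preserves the
simplex; maximum pooling is renormalized for reporting (the argmax is
unaffected). All argmax ties break toward the lowest canonical index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment import AlignedSample, FramePayload
from .classifiers import (
    GroupFrameClassifier,
    GroupSequenceClassifier,
    MotionStateClassifier,
)
from .hierarchy import Correspondence

__all__ = [
    "RecognizerBundle",
    "ActivityPrediction",
    "hierarchical_recognize",
    "hierarchical_recognize_batch",
    "direct_fuse",
    "flat_recognize",
]


@dataclass(frozen=True)
class ActivityPrediction:
    """Outcome of one recognition: final activity plus the route taken.

    ``index`` is the 0-based position of the activity in the canonical
    activity order. ``group_posterior`` is None when the routed group was a
    singleton (no image classifier consulted) or for flat recognizers
    (``group`` is then also None).
    """

    activity: str
    index: int
    group: str | None
    motion_posterior: np.ndarray | None
    group_posterior: np.ndarray | None


@dataclass
class RecognizerBundle:
    """Everything the hierarchical recognizer needs at inference time."""

    correspondence: Correspondence
    motion_model: MotionStateClassifier | None
    group_models: dict[str, GroupFrameClassifier | GroupSequenceClassifier]
    ips: str  # "L" (single frame per window) or "H" (frame sequence)

    def __post_init__(self) -> None:
        if self.ips not in ("L", "H"):
            raise ValueError("ips must be 'L' or 'H'")
        C = self.correspondence
        if self.motion_model is None:
            # degenerate m = 1 hierarchy: routing is trivial, no motion net
            if C.state_set.m != 1:
                raise ValueError("motion model required when m > 1")
        elif tuple(self.motion_model.classes) != C.state_set.labels:
            raise ValueError("motion model classes must equal the motion-state set")
        want = GroupFrameClassifier if self.ips == "L" else GroupSequenceClassifier
        for s in C.state_set:
            group = C.invert(s)
            if len(group) == 1:
                continue
            model = self.group_models.get(s)
            if model is None:
                raise ValueError(f"multi-activity group {s!r} has no image classifier")
            if not isinstance(model, want):
                raise TypeError(
                    f"group {s!r}: expected {want.__name__} for Ips={self.ips}"
                )
            if tuple(model.group) != group:
                raise ValueError(f"group model for {s!r} covers the wrong activities")


def _predict_group(model, payload: FramePayload, ips: str) -> np.ndarray:
    if ips == "L":
        return model.predict_proba(payload)
    return model.predict_proba(payload)


def hierarchical_recognize(bundle: RecognizerBundle, sample: AlignedSample) -> ActivityPrediction:
    """Run the two-stage cascade on one aligned sample."""
    C = bundle.correspondence
    if bundle.motion_model is None:
        motion_post = np.ones(1)
    else:
        motion_post = bundle.motion_model.predict_proba(sample.segment)
    j = int(np.argmax(motion_post))
    state = C.state_set.labels[j]
    group = C.invert(state)
    if len(group) == 1:
        activity = group[0]
        group_post = None
    else:
        model = bundle.group_models[state]
        group_post = _predict_group(model, sample.payload, bundle.ips)
        activity = group[int(np.argmax(group_post))]
    return ActivityPrediction(
        activity=activity,
        index=C.activity_set.index(activity),
        group=state,
        motion_posterior=motion_post,
        group_posterior=group_post,
    )


def hierarchical_recognize_batch(
    bundle: RecognizerBundle, samples: list[AlignedSample]
) -> list[ActivityPrediction]:
    """Vectorized cascade over many samples (same outputs as the scalar op).

    Motion posteriors are computed in one batch; samples are then bucketed
    by routed group (and frame count, for sequences) so the image networks
    also run batched.
    """
    C = bundle.correspondence
    if bundle.motion_model is None:
        motion = np.ones((len(samples), 1))
    else:
        X = np.stack([s.segment.samples for s in samples])
        motion = bundle.motion_model.predict_proba_batch(X)
    routed = np.argmax(motion, axis=1)
    preds: list[ActivityPrediction | None] = [None] * len(samples)

    buckets: dict[tuple, list[int]] = {}
    feat_cache: dict[int, np.ndarray] = {}
    for i, s in enumerate(samples):
        state = C.state_set.labels[routed[i]]
        group = C.invert(state)
        if len(group) == 1:
            preds[i] = ActivityPrediction(
                activity=group[0], index=C.activity_set.index(group[0]),
                group=state, motion_posterior=motion[i], group_posterior=None,
            )
            continue
        model = bundle.group_models[state]
        if bundle.ips == "H":
            feats = model._features(s.payload, strided=True)
        else:
            feats = model._features(s.payload)
        key = (state, feats.shape[0] if feats.ndim == 2 else -1)
        buckets.setdefault(key, []).append(i)
        feat_cache[i] = feats

    for (state, _), idxs in buckets.items():
        model = bundle.group_models[state]
        group = C.invert(state)
        F = np.stack([feat_cache[i] for i in idxs])
        probs = model.predict_proba_batch(F)
        for row, i in enumerate(idxs):
            gi = int(np.argmax(probs[row]))
            preds[i] = ActivityPrediction(
                activity=group[gi], index=C.activity_set.index(group[gi]),
                group=state, motion_posterior=motion[i],
                group_posterior=probs[row],
            )
    return preds  # type: ignore[return-value]


def direct_fuse(posteriors, mode: str = "avg") -> np.ndarray:
    """Pool per-modality softmax outputs over the full activity set.

    ``avg``: elementwise mean (still a simplex). ``max``: elementwise
    maximum, renormalized to sum 1 so the result reports as a posterior;
    the argmax is identical with or without renormalization.
    """
    if mode not in ("avg", "max"):
        raise ValueError("mode must be 'avg' or 'max'")
    arrs = [np.asarray(p, dtype=float) for p in posteriors]
    if not arrs:
        raise ValueError("no posteriors to fuse")
    n = arrs[0].shape[-1]
    for a in arrs:
        if a.shape[-1] != n:
            raise ValueError("posterior length mismatch")
    stack = np.stack(arrs)
    if mode == "avg":
        return stack.mean(axis=0)
    mx = stack.max(axis=0)
    return mx / mx.sum(axis=-1, keepdims=True)


def flat_recognize(model, sample: AlignedSample, activities=None) -> ActivityPrediction:
    """Single-modality flat recognition over the full activity set.

    ``model`` is either a sensor-segment classifier (its classes must be
    activities) or an image classifier whose group is the full activity set.
    """
    if isinstance(model, MotionStateClassifier):
        probs = model.predict_proba(sample.segment)
        labels = model.classes
    else:
        probs = model.predict_proba(sample.payload)
        labels = model.group
    if activities is not None and tuple(labels) != tuple(activities):
        raise ValueError("flat model does not cover the requested activity set")
    k = int(np.argmax(probs))
    return ActivityPrediction(
        activity=labels[k], index=k, group=None,
        motion_posterior=None, group_posterior=probs,
    )
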