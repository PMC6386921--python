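"""The three classifier contracts of the hierarchical recognition framework.

* Motion-state classifier: an LSTM over the (L, 6) sensor segment followed
  by a fully connected softmax head over the motion states,
  ``y = softmax(FC(LSTM(x)))``. Its argmax is the routing decision of the
  hierarchical recognizer.
* Group frame classifier (low-frame-rate photo streams): a frozen feature
  extractor, global average pooling of the spatial feature maps, and a
  fine-tuned fully connected softmax head over the group's activities,
  ``y = softmax(FC(GAP(conv(I))))``.
* Group frame-sequence classifier (high-frame-rate photo streams): per-frame
  GAP features fed through an LSTM, a fully connected layer with dropout,
  and a softmax head, ``y = softmax(FC(LSTM({f_1..f_K})))``.

The published training hyperparameters are the defaults (Adam, learning
rate 0.001, moment decays 0.9 / 0.99; 150 epochs batch 30 for the motion
net, 50 epochs batch 8 for image heads; sequence LSTM 512 hidden + 512 FC
with dropout 0.7). Reduced desk-scale profiles ship alongside; all training
is bit-reproducible given the config seed on one thread configuration.

The feature extractor is an injectable contract: a pass-through for
precomputed feature vectors (the default for synthetic data), or a small
fixed seeded convolutional stack for raster images. Head training always
freezes the extractor — only heads (and the sequence LSTM) learn — so the
extractor's parameters are verifiably unchanged by training.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict, replace

import numpy as np

from ._nn import LSTM, Adam, Dense, Dropout, softmax, softmax_xent
from .alignment import FramePayload, SensorSegment

__all__ = [
    "TrainConfig",
    "gap",
    "FeatureExtractor",
    "PassthroughExtractor",
    "ConvExtractor",
    "MotionStateClassifier",
    "GroupFrameClassifier",
    "GroupSequenceClassifier",
    "train_motion_classifier",
    "train_group_frame_classifier",
    "train_group_sequence_classifier",
]


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters; published values are the role defaults.

    ``stride`` subsamples the segment time axis before the recurrent layer
    (1 = every sample); the reduced profiles use it to cut sequence length
    at desk scale.
    """

    lr: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.99
    epochs: int = 50
    batch_size: int = 8
    hidden: int = 128
    fc_width: int = 512
    dropout: float = 0.0
    stride: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.lr, self.epochs, self.batch_size, self.hidden, self.stride) <= 0:
            raise ValueError("training hyperparameters must be positive")

    # role defaults -------------------------------------------------------

    @classmethod
    def motion_default(cls, seed: int = 0) -> "TrainConfig":
        return cls(epochs=150, batch_size=30, hidden=128, seed=seed)

    @classmethod
    def frame_head_default(cls, seed: int = 0) -> "TrainConfig":
        return cls(epochs=50, batch_size=8, seed=seed)

    @classmethod
    def sequence_default(cls, seed: int = 0) -> "TrainConfig":
        return cls(epochs=50, batch_size=8, hidden=512, fc_width=512,
                   dropout=0.7, seed=seed)

    # reduced desk-scale profiles ----------------------------------------

    @classmethod
    def motion_reduced(cls, seed: int = 0) -> "TrainConfig":
        return cls(epochs=8, batch_size=64, hidden=32, stride=3, lr=3e-3, seed=seed)

    @classmethod
    def frame_head_reduced(cls, seed: int = 0) -> "TrainConfig":
        return cls(epochs=30, batch_size=32, lr=3e-3, seed=seed)

    @classmethod
    def sequence_reduced(cls, seed: int = 0) -> "TrainConfig":
        return cls(epochs=12, batch_size=32, hidden=48, fc_width=48,
                   dropout=0.3, stride=3, lr=3e-3, seed=seed)

    def to_dict(self) -> dict:
        return asdict(self)


def gap(feature_maps) -> np.ndarray:
    """Global average pooling: one scalar (the spatial mean) per feature map.

    Accepts an array of shape (C, H, W) or a list of equally sized 2-D maps;
    returns the length-C channel vector. 1x1 maps make this the identity on
    the channel vector.
    """
    maps = np.asarray(feature_maps, dtype=float)
    if maps.size == 0:
        raise ValueError("empty feature-map set")
    if maps.ndim == 1:  # already a channel vector
        return maps
    if maps.ndim != 3:
        raise ValueError(f"expected (C, H, W) maps, got shape {maps.shape}")
    return maps.mean(axis=(1, 2))


# -- feature extractors ----------------------------------------------------


class FeatureExtractor:
    """Contract: image or vector -> stack of spatial feature maps (C, H, W)."""

    n_channels: int

    def extract(self, frame: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def checksum(self) -> str:
        """Digest of all parameters; used to assert the frozen contract."""
        h = hashlib.sha256()
        for arr in self._param_arrays():
            h.update(np.ascontiguousarray(arr).tobytes())
        return h.hexdigest()

    def _param_arrays(self) -> list[np.ndarray]:
        return []


class PassthroughExtractor(FeatureExtractor):
    """Identity on precomputed feature vectors, viewed as d maps of size 1x1."""

    def __init__(self, dim: int):
        self.n_channels = int(dim)

    def extract(self, frame: np.ndarray) -> np.ndarray:
        v = np.asarray(frame, dtype=float).ravel()
        if v.shape[0] != self.n_channels:
            raise ValueError(f"expected {self.n_channels}-dim vector, got {v.shape}")
        return v.reshape(self.n_channels, 1, 1)


def _conv2d(x: np.ndarray, filters: np.ndarray, stride: int) -> np.ndarray:
    """Valid convolution of (H, W, Cin) with (Cout, k, k, Cin) via im2col."""
    H, W, Cin = x.shape
    Cout, k, _, _ = filters.shape
    Ho = (H - k) // stride + 1
    Wo = (W - k) // stride + 1
    cols = np.empty((Ho * Wo, k * k * Cin))
    r = 0
    for i in range(Ho):
        for j in range(Wo):
            patch = x[i * stride:i * stride + k, j * stride:j * stride + k, :]
            cols[r] = patch.ravel()
            r += 1
    out = cols @ filters.reshape(Cout, -1).T
    return out.reshape(Ho, Wo, Cout).transpose(2, 0, 1)


class ConvExtractor(FeatureExtractor):
    """Small fixed convolutional stack with seeded random filters.

    Two 3x3 stride-2 convolution + ReLU stages mapping (H, W, C) rasters to
    ``n_channels`` spatial maps. Filters are drawn once from the seed and
    never trained: every training routine in this framework fine-tunes heads
    on top of a frozen extractor, so the stack acts as a deterministic
    random-projection feature bank. Parameters can be replaced wholesale
    (e.g. by an externally pretrained backbone adapter) but no gradient path
    exists into them.
    """

    def __init__(self, in_channels: int = 3, n_channels: int = 16, seed: int = 0):
        rng = np.random.default_rng(seed)
        c_mid = max(8, n_channels // 2)
        scale1 = np.sqrt(2.0 / (9 * in_channels))
        scale2 = np.sqrt(2.0 / (9 * c_mid))
        self.filters1 = rng.standard_normal((c_mid, 3, 3, in_channels)) * scale1
        self.filters2 = rng.standard_normal((n_channels, 3, 3, c_mid)) * scale2
        self.n_channels = n_channels

    def extract(self, frame: np.ndarray) -> np.ndarray:
        x = np.asarray(frame, dtype=float)
        if x.ndim == 2:
            x = x[:, :, None]
        maps = _conv2d(x, self.filters1, stride=2)
        maps = np.maximum(maps, 0.0)
        maps = _conv2d(maps.transpose(1, 2, 0), self.filters2, stride=2)
        return np.maximum(maps, 0.0)

    def _param_arrays(self) -> list[np.ndarray]:
        return [self.filters1, self.filters2]


def _payload_features(payload: FramePayload, extractor: FeatureExtractor) -> np.ndarray:
    """GAP feature vector(s) of a payload: (d,) for a frame, (K, d) for a sequence."""
    if payload.features is not None:
        data = payload.features
        if data.ndim == 1:
            return gap(extractor.extract(data))
        return np.stack([gap(extractor.extract(f)) for f in data])
    imgs = payload.images
    if imgs.ndim == 3:
        return gap(extractor.extract(imgs))
    return np.stack([gap(extractor.extract(img)) for img in imgs])


# -- shared training utilities --------------------------------------------


def _check_simplex_head(classes) -> tuple[str, ...]:
    classes = tuple(classes)
    if len(classes) < 2:
        raise ValueError("classifier needs at least 2 classes")
    return classes


def _class_targets(labels, classes) -> np.ndarray:
    index = {c: i for i, c in enumerate(classes)}
    try:
        return np.array([index[lab] for lab in labels], dtype=int)
    except KeyError as exc:
        raise ValueError(f"label {exc} outside the class list") from None


def _minibatches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start:start + batch_size]


# -- motion-state classifier ----------------------------------------------


class MotionStateClassifier:
    """LSTM + softmax head over fixed-length (L, 6) sensor segments.

    Generic over its ``classes`` tuple: normally the motion states, but the
    flat sensor-only baseline instantiates it over the full activity set.
    Segments are standardized per channel with training-set statistics.
    """

    def __init__(self, classes, config: TrainConfig):
        self.classes = _check_simplex_head(classes)
        self.config = config
        rng = np.random.default_rng([config.seed, 0])
        self.lstm = LSTM(6, config.hidden, rng)
        self.head = Dense(config.hidden, len(self.classes), zero_init=True)
        self.norm_mean = np.zeros(6)
        self.norm_sd = np.ones(6)
        self.input_length: int | None = None
        self.loss_history: list[float] = []
        self.metadata: dict = {"seed": config.seed}

    # prediction ----------------------------------------------------------

    def _prep(self, X: np.ndarray) -> np.ndarray:
        X = (X - self.norm_mean) / self.norm_sd
        return X[:, ::self.config.stride, :]

    def predict_proba_batch(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.input_length is not None and X.shape[1] != self.input_length:
            raise ValueError(
                f"segment length {X.shape[1]} != training length {self.input_length}"
            )
        logits = self.head.forward(self.lstm.forward(self._prep(X)))
        return softmax(logits)

    def predict_proba(self, segment: SensorSegment | np.ndarray) -> np.ndarray:
        x = segment.samples if isinstance(segment, SensorSegment) else np.asarray(segment)
        return self.predict_proba_batch(x[None])[0]

    def predict(self, segment) -> str:
        probs = self.predict_proba(segment)
        return self.classes[int(np.argmax(probs))]


def _segments_array(segments) -> np.ndarray:
    if isinstance(segments, np.ndarray):
        X = segments.astype(float)
    else:
        X = np.stack([
            s.samples if isinstance(s, SensorSegment) else np.asarray(s, float)
            for s in segments
        ])
    if X.ndim != 3 or X.shape[2] != 6:
        raise ValueError(f"expected (N, L, 6) segments, got {X.shape}")
    lengths = {X.shape[1]}
    if len(lengths) != 1:
        raise ValueError("segments must share a fixed length")
    return X


def train_motion_classifier(
    segments, labels, classes, config: TrainConfig | None = None
) -> MotionStateClassifier:
    """Train the sensor-segment classifier; deterministic given config.seed.

    ``segments`` is a list of SensorSegments or an (N, L, 6) array;
    ``labels`` the per-segment class labels; ``classes`` the ordered label
    set (motion states, or activities for the flat baseline).
    """
    config = config or TrainConfig.motion_default()
    X = _segments_array(segments)
    classes = tuple(getattr(classes, "labels", classes))
    y = _class_targets(labels, classes)
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single class")

    model = MotionStateClassifier(classes, config)
    model.input_length = X.shape[1]
    model.norm_mean = X.mean(axis=(0, 1))
    model.norm_sd = X.std(axis=(0, 1)) + 1e-8
    Xp = model._prep(X)

    opt = Adam([model.lstm, model.head], lr=config.lr,
               beta1=config.beta1, beta2=config.beta2)
    rng = np.random.default_rng([config.seed, 1])
    for _ in range(config.epochs):
        epoch_loss = 0.0
        n_batches = 0
        for idx in _minibatches(len(y), config.batch_size, rng):
            opt.zero_grad()
            h = model.lstm.forward(Xp[idx], train=True)
            logits = model.head.forward(h, train=True)
            loss, dlogits = softmax_xent(logits, y[idx])
            model.lstm.backward(model.head.backward(dlogits))
            opt.step()
            epoch_loss += loss
            n_batches += 1
        model.loss_history.append(epoch_loss / n_batches)
    return model


def predict_state(model: MotionStateClassifier, segment) -> np.ndarray:
    """Probability vector over the model's classes for one segment."""
    return model.predict_proba(segment)


# -- group frame classifier -----------------------------------------------


class GroupFrameClassifier:
    """Frozen extractor + GAP + fine-tuned softmax head over a group's activities."""

    def __init__(self, group, extractor: FeatureExtractor, config: TrainConfig):
        self.group = _check_simplex_head(group)
        self.extractor = extractor
        self.config = config
        self.head = Dense(extractor.n_channels, len(self.group), zero_init=True)
        self.norm_mean = np.zeros(extractor.n_channels)
        self.norm_sd = np.ones(extractor.n_channels)
        self.loss_history: list[float] = []
        self.metadata: dict = {"seed": config.seed}

    def _features(self, payload: FramePayload) -> np.ndarray:
        if payload.is_sequence:
            raise TypeError("frame classifier got a sequence payload")
        return _payload_features(payload, self.extractor)

    def predict_proba(self, payload: FramePayload) -> np.ndarray:
        f = (self._features(payload) - self.norm_mean) / self.norm_sd
        return softmax(self.head.forward(f[None]))[0]

    def predict_proba_batch(self, feats: np.ndarray) -> np.ndarray:
        f = (feats - self.norm_mean) / self.norm_sd
        return softmax(self.head.forward(f))

    def predict(self, payload: FramePayload) -> str:
        return self.group[int(np.argmax(self.predict_proba(payload)))]


def train_group_frame_classifier(
    group, payloads, labels, extractor: FeatureExtractor,
    config: TrainConfig | None = None,
) -> GroupFrameClassifier:
    """Fine-tune a softmax head for one group on frozen GAP features.

    Rejects singleton groups (they bypass the image path entirely) and any
    sample labeled outside the group. The extractor is read-only throughout.
    """
    config = config or TrainConfig.frame_head_default()
    group = tuple(group)
    if len(group) < 2:
        raise ValueError(
            "singleton group needs no image classifier; it is recognized "
            "directly from the motion state"
        )
    model = GroupFrameClassifier(group, extractor, config)
    y = _class_targets(labels, group)
    feats = np.stack([model._features(p) for p in payloads])
    model.norm_mean = feats.mean(axis=0)
    model.norm_sd = feats.std(axis=0) + 1e-8
    F = (feats - model.norm_mean) / model.norm_sd

    opt = Adam([model.head], lr=config.lr, beta1=config.beta1, beta2=config.beta2)
    rng = np.random.default_rng([config.seed, 1])
    for _ in range(config.epochs):
        epoch_loss = 0.0
        n_batches = 0
        for idx in _minibatches(len(y), config.batch_size, rng):
            opt.zero_grad()
            logits = model.head.forward(F[idx], train=True)
            loss, dlogits = softmax_xent(logits, y[idx])
            model.head.backward(dlogits)
            opt.step()
            epoch_loss += loss
            n_batches += 1
        model.loss_history.append(epoch_loss / n_batches)
    return model


def predict_frame(model: GroupFrameClassifier, payload: FramePayload) -> np.ndarray:
    """Probability vector over the group's activities for a single frame."""
    return model.predict_proba(payload)


# -- group frame-sequence classifier --------------------------------------


class GroupSequenceClassifier:
    """Per-frame GAP features -> LSTM -> FC(+dropout) -> softmax over the group."""

    def __init__(self, group, extractor: FeatureExtractor, config: TrainConfig):
        self.group = _check_simplex_head(group)
        self.extractor = extractor
        self.config = config
        rng = np.random.default_rng([config.seed, 0])
        self.lstm = LSTM(extractor.n_channels, config.hidden, rng)
        self.fc = Dense(config.hidden, config.fc_width, rng=rng)
        self.drop1 = Dropout(config.dropout)
        self.drop2 = Dropout(config.dropout)
        self.head = Dense(config.fc_width, len(self.group), zero_init=True)
        self.norm_mean = np.zeros(extractor.n_channels)
        self.norm_sd = np.ones(extractor.n_channels)
        self.loss_history: list[float] = []
        self.metadata: dict = {"seed": config.seed}

    def _features(self, payload: FramePayload, strided: bool = False) -> np.ndarray:
        f = _payload_features(payload, self.extractor)
        if f.ndim == 1:  # K = 1 degenerates to a single recurrent step
            f = f[None]
        if strided:
            f = f[:: self.config.stride]
        return f

    def _forward(self, F: np.ndarray, train: bool = False,
                 rng: np.random.Generator | None = None) -> np.ndarray:
        h = self.lstm.forward(F, train=train)
        h = self.drop1.forward(h, train=train, rng=rng)
        z = np.maximum(self.fc.forward(h, train=train), 0.0)
        self._relu_mask = z > 0
        z = self.drop2.forward(z, train=train, rng=rng)
        return self.head.forward(z, train=train)

    def _backward(self, dlogits: np.ndarray) -> None:
        dz = self.head.backward(dlogits)
        dz = self.drop2.backward(dz)
        dh = self.fc.backward(dz * self._relu_mask)
        dh = self.drop1.backward(dh)
        self.lstm.backward(dh)

    def predict_proba(self, payload: FramePayload) -> np.ndarray:
        F = (self._features(payload, strided=True) - self.norm_mean) / self.norm_sd
        return softmax(self._forward(F[None]))[0]

    def predict_proba_batch(self, feats: np.ndarray) -> np.ndarray:
        F = (feats - self.norm_mean) / self.norm_sd
        return softmax(self._forward(F))

    def predict(self, payload: FramePayload) -> str:
        return self.group[int(np.argmax(self.predict_proba(payload)))]


def train_group_sequence_classifier(
    group, payloads, labels, extractor: FeatureExtractor,
    config: TrainConfig | None = None,
) -> GroupSequenceClassifier:
    """Train the frame-sequence classifier of one group (extractor frozen).

    All payloads must share the same frame count K >= 1; the time axis may
    additionally be subsampled by ``config.stride``.
    """
    config = config or TrainConfig.sequence_default()
    group = tuple(group)
    if len(group) < 2:
        raise ValueError("singleton group needs no image classifier")
    model = GroupSequenceClassifier(group, extractor, config)
    y = _class_targets(labels, group)
    feats = np.stack([model._features(p) for p in payloads])
    if feats.shape[1] < 1:
        raise ValueError("empty frame sequence")
    feats = feats[:, ::config.stride, :]
    model.norm_mean = feats.mean(axis=(0, 1))
    model.norm_sd = feats.std(axis=(0, 1)) + 1e-8
    F = (feats - model.norm_mean) / model.norm_sd

    opt = Adam([model.lstm, model.fc, model.head], lr=config.lr,
               beta1=config.beta1, beta2=config.beta2)
    rng = np.random.default_rng([config.seed, 1])
    for _ in range(config.epochs):
        epoch_loss = 0.0
        n_batches = 0
        for idx in _minibatches(len(y), config.batch_size, rng):
            opt.zero_grad()
            logits = model._forward(F[idx], train=True, rng=rng)
            loss, dlogits = softmax_xent(logits, y[idx])
            model._backward(dlogits)
            opt.step()
            epoch_loss += loss
            n_batches += 1
        model.loss_history.append(epoch_loss / n_batches)
    return model


def predict_sequence(model: GroupSequenceClassifier, payload: FramePayload) -> np.ndarray:
    """Probability vector over the group's activities for a K-frame sequence."""
    return model.predict_proba(payload)
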