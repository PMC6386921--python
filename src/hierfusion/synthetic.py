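"""Seeded generator of multimodal wearable datasets with the structure the
hierarchical framework assumes.

The generative model encodes the framework's two premises directly:

* Motion states are separable from the IMU alone. Each motion state owns a
  6-channel signal model — a gravity orientation offset on the
  accelerometer axes, per-channel Gaussian noise, and for ambulatory states
  a sinusoidal gait oscillation with a random phase — and states are placed
  at distinct orientations/frequencies.
* Activities within one motion-state group are *not* separable from the
  IMU: all activities sharing a state draw their segments from that state's
  model, identically. What distinguishes activities is the photo stream,
  modeled as Gaussian feature clusters in a d-dimensional space (one
  cluster mean per activity, within-cluster SD 1, cluster-mean scale
  ``separation``). High-frame-rate payloads are AR(1)-correlated feature
  sequences with per-frame marginal equal to the activity's cluster.

Because all densities are known, :func:`bayes_oracle` evaluates the exact
posterior under the model, which upper-bounds what any trained classifier
can achieve and anchors the accuracy assertions in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import logsumexp

from .alignment import (
    AlignedSample,
    FramePayload,
    SensorSegment,
    SensorStream,
    TimeWindow,
    segment_length,
)
from .hierarchy import Correspondence, load_fixture

__all__ = [
    "StateSignalModel",
    "GeneratorSpec",
    "generate_dataset",
    "generate_sequence_dataset",
    "bayes_oracle",
    "preset",
    "make_state_models",
]

_PHASE_GRID = 24  # quadrature points for the phase-marginalized likelihood


@dataclass(frozen=True)
class StateSignalModel:
    """6-channel signal statistics of one motion state.

    Accelerometer rows are ``gravity + osc_amp * sin(2 pi f t + phi) * u +
    noise`` with ``u`` the unit gravity direction and ``phi`` uniform per
    segment; gyroscope rows are ``gyro_osc_amp * cos(...)`` on the first
    gyro axis plus noise. Static states simply have zero amplitudes.
    """

    gravity: tuple[float, float, float]
    noise_sd: float = 0.3
    gyro_noise_sd: float = 0.1
    osc_amp: float = 0.0
    osc_freq: float = 0.0
    gyro_osc_amp: float = 0.0

    def mean_matrix(self, t: np.ndarray, phase: float) -> np.ndarray:
        """(L, 6) mean of the segment given the oscillation phase."""
        g = np.asarray(self.gravity, dtype=float)
        L = len(t)
        mu = np.zeros((L, 6))
        mu[:, :3] = g
        if self.osc_amp > 0:
            u = g / (np.linalg.norm(g) + 1e-12)
            wave = np.sin(2 * np.pi * self.osc_freq * t + phase)
            mu[:, :3] += self.osc_amp * wave[:, None] * u
            mu[:, 3] += self.gyro_osc_amp * np.cos(2 * np.pi * self.osc_freq * t + phase)
        return mu

    @property
    def channel_sd(self) -> np.ndarray:
        return np.array([self.noise_sd] * 3 + [self.gyro_noise_sd] * 3)


def make_state_models(
    states, ambulatory: set[str] | None = None,
    noise_sd: float = 0.3, osc_amp: float = 3.0, base_freq: float = 1.6,
) -> dict[str, StateSignalModel]:
    """Assign each state a distinct gravity orientation, ambulatory ones a gait.

    Orientations are spread on a cone around vertical (unit vectors
    ``(0.6 cos a_i, 0.6 sin a_i, 0.8)`` at equally spaced angles), which
    guarantees pairwise-separated channel means; ambulatory states get a
    sinusoidal oscillation whose frequency steps by 0.4 Hz per state so that
    even same-orientation dynamics stay distinguishable.
    """
    states = list(states)
    ambulatory = ambulatory or set()
    models = {}
    amb_rank = 0
    for i, s in enumerate(states):
        angle = 2.0 * np.pi * i / max(len(states), 1)
        u = np.array([0.6 * np.cos(angle), 0.6 * np.sin(angle), 0.8])
        if s in ambulatory:
            models[s] = StateSignalModel(
                gravity=tuple(9.81 * u), noise_sd=noise_sd,
                osc_amp=osc_amp, osc_freq=base_freq + 0.4 * amb_rank,
                gyro_osc_amp=1.0,
            )
            amb_rank += 1
        else:
            models[s] = StateSignalModel(gravity=tuple(9.81 * u), noise_sd=noise_sd)
    return models


@dataclass(frozen=True)
class GeneratorSpec:
    """Full description of a synthetic study condition.

    ``world_seed`` fixes the activity feature-cluster means (the "world");
    ``seed`` drives sample draws, so train/test sets from the same world use
    different draw seeds. ``separation`` scales the cluster-mean cloud:
    within-group image separability grows monotonically with it.
    """

    correspondence: Correspondence
    state_models: dict[str, StateSignalModel]
    feature_dim: int = 8
    separation: float = 1.0
    cluster_sd: float = 1.0
    cluster_means: np.ndarray | None = None
    fs: float = 90.0
    t_w: float = 3.0
    regime: str = "low"  # "low": 1 frame/window; "high": K-frame AR(1) sequence
    K: int = 90
    rho: float = 0.95
    frame_spacing: float = 4.0
    proportions: np.ndarray | None = None
    world_seed: int = 20190546
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regime not in ("low", "high"):
            raise ValueError("regime must be 'low' or 'high'")
        if self.separation <= 0:
            raise ValueError("separation must be positive")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must be in [0, 1)")
        if self.K < 1:
            raise ValueError("K must be >= 1")
        for s in self.correspondence.state_set:
            if s not in self.state_models:
                raise ValueError(f"no signal model for motion state {s!r}")

    @property
    def activities(self) -> tuple[str, ...]:
        return self.correspondence.activity_set.labels

    def means(self) -> np.ndarray:
        """(n, d) activity feature-cluster means, fixed by world_seed."""
        if self.cluster_means is not None:
            return np.asarray(self.cluster_means, dtype=float)
        rng = np.random.default_rng(self.world_seed)
        n = len(self.activities)
        return self.separation * rng.standard_normal((n, self.feature_dim))

    def activity_proportions(self) -> np.ndarray:
        n = len(self.activities)
        if self.proportions is None:
            return np.full(n, 1.0 / n)
        p = np.asarray(self.proportions, dtype=float)
        if p.shape != (n,) or not np.isclose(p.sum(), 1.0):
            raise ValueError("proportions must be a length-n simplex")
        return p


def _draw_segment(
    spec: GeneratorSpec, model: StateSignalModel, t_c: float,
    rng: np.random.Generator,
) -> SensorSegment:
    L = segment_length(spec.fs, spec.t_w)
    t = np.arange(L) / spec.fs
    phase = rng.uniform(0.0, 2.0 * np.pi)
    mu = model.mean_matrix(t, phase)
    samples = mu + rng.standard_normal((L, 6)) * model.channel_sd
    return SensorSegment(samples, TimeWindow(t_c, spec.t_w), np.zeros(L, dtype=bool))


def _draw_feature_sequence(
    mean: np.ndarray, sd: float, K: int, rho: float, rng: np.random.Generator
) -> np.ndarray:
    """Stationary AR(1) sequence with marginal N(mean, sd^2 I)."""
    d = mean.shape[0]
    out = np.empty((K, d))
    e = rng.standard_normal((K, d)) * sd
    out[0] = mean + e[0]
    c = np.sqrt(1.0 - rho ** 2)
    for k in range(1, K):
        out[k] = mean + rho * (out[k - 1] - mean) + c * e[k]
    return out


def generate_dataset(
    spec: GeneratorSpec, n_samples: int, seed: int | None = None
) -> list[AlignedSample]:
    """Draw ``n_samples`` aligned (segment, payload) pairs with ground truth.

    Per sample: activity ~ class proportions; motion state ~ uniform over the
    activity's states; sensor segment ~ the state's signal model; payload ~
    the activity's feature cluster (one vector in the low-rate regime, a
    K-frame AR(1) sequence in the high-rate regime). Bitwise reproducible
    from the seed.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    C = spec.correspondence
    acts = spec.activities
    means = spec.means()
    props = spec.activity_proportions()
    samples = []
    for i in range(n_samples):
        ai = int(rng.choice(len(acts), p=props))
        activity = acts[ai]
        states = C.states_of(activity)
        state = states[int(rng.integers(len(states)))]
        t_c = i * spec.frame_spacing + spec.t_w / 2.0
        segment = _draw_segment(spec, spec.state_models[state], t_c, rng)
        if spec.regime == "low":
            payload = FramePayload(
                timestamps=[t_c],
                features=means[ai] + rng.standard_normal(spec.feature_dim) * spec.cluster_sd,
            )
        else:
            feats = _draw_feature_sequence(means[ai], spec.cluster_sd, spec.K, spec.rho, rng)
            ts = t_c - spec.t_w / 2.0 + np.arange(spec.K) * (spec.t_w / spec.K)
            payload = FramePayload(timestamps=ts, features=feats)
        samples.append(
            AlignedSample(segment=segment, payload=payload, activity=activity,
                          state=state, sample_id=i)
        )
    return samples


def generate_sequence_dataset(
    spec: GeneratorSpec, n_sequences: int, duration: float = 15.0,
    dc: float = 1.0, fps: float = 30.0, seed: int | None = None,
) -> tuple[list[AlignedSample], list[int]]:
    """High-rate regime at the recording level: whole sequences, then windows.

    Each sequence is one activity performed for ``duration`` seconds: a
    continuous 6-channel stream from the state's signal model plus an
    ``fps``-rate AR(1) feature stream. The stream is cut into overlapping
    windows with centers every ``dc`` s (so ``floor(duration/dc)`` aligned
    samples per sequence), each carrying the frames inside its window.
    Returns the flat sample list and the per-sample sequence id, for
    sequence-level cross-validation splits. Activities cycle round-robin so
    counts are balanced across activities.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    C = spec.correspondence
    acts = spec.activities
    means = spec.means()
    samples: list[AlignedSample] = []
    seq_ids: list[int] = []
    n_windows = int(np.floor(duration / dc + 1e-9))
    L = segment_length(spec.fs, spec.t_w)
    n_frames_total = int(round(duration * fps))
    for sid in range(n_sequences):
        ai = sid % len(acts)
        activity = acts[ai]
        states = C.states_of(activity)
        state = states[int(rng.integers(len(states)))]
        model = spec.state_models[state]
        # continuous sensor stream
        n_samp = int(round(duration * spec.fs))
        t = np.arange(n_samp) / spec.fs
        phase = rng.uniform(0.0, 2.0 * np.pi)
        stream_vals = model.mean_matrix(t, phase) + \
            rng.standard_normal((n_samp, 6)) * model.channel_sd
        stream = SensorStream(t0=0.0, fs=spec.fs, values=stream_vals)
        # continuous feature stream at the camera rate
        frame_t = np.arange(n_frames_total) / fps
        frames = _draw_feature_sequence(means[ai], spec.cluster_sd,
                                        n_frames_total, spec.rho, rng)
        for k in range(n_windows):
            center = (k + 0.5) * dc
            w = TimeWindow(center, spec.t_w)
            first = int(round((w.start - stream.t0) * spec.fs))
            idx = np.clip(first + np.arange(L), 0, n_samp - 1)
            pad = (first + np.arange(L) < 0) | (first + np.arange(L) >= n_samp)
            segment = SensorSegment(stream_vals[idx], w, pad)
            in_w = (frame_t >= w.start) & (frame_t < w.end)
            payload = FramePayload(timestamps=frame_t[in_w], features=frames[in_w])
            samples.append(AlignedSample(segment=segment, payload=payload,
                                         activity=activity, state=state,
                                         sample_id=len(samples)))
            seq_ids.append(sid)
    return samples, seq_ids


# -- exact posterior under the generative model ---------------------------


def _segment_loglik(spec: GeneratorSpec, model: StateSignalModel,
                    x: np.ndarray) -> float:
    """log p(segment | state), marginalizing the oscillation phase on a grid."""
    L = x.shape[0]
    t = np.arange(L) / spec.fs
    sd = model.channel_sd
    const = -0.5 * L * np.sum(np.log(2 * np.pi * sd ** 2))
    if model.osc_amp == 0.0:
        mu = model.mean_matrix(t, 0.0)
        return const - 0.5 * float(np.sum(((x - mu) / sd) ** 2))
    lls = np.empty(_PHASE_GRID)
    for i, phase in enumerate(np.linspace(0, 2 * np.pi, _PHASE_GRID, endpoint=False)):
        mu = model.mean_matrix(t, phase)
        lls[i] = const - 0.5 * float(np.sum(((x - mu) / sd) ** 2))
    return float(logsumexp(lls) - np.log(_PHASE_GRID))


def _payload_loglik(spec: GeneratorSpec, mean: np.ndarray, f: np.ndarray) -> float:
    """log p(payload | activity) under the (possibly AR(1)) feature model."""
    sd = spec.cluster_sd
    if f.ndim == 1:
        return float(-0.5 * np.sum(((f - mean) / sd) ** 2)
                     - 0.5 * f.shape[0] * np.log(2 * np.pi * sd ** 2))
    K, d = f.shape
    ll = -0.5 * np.sum(((f[0] - mean) / sd) ** 2) - 0.5 * d * np.log(2 * np.pi * sd ** 2)
    if K > 1:
        c2 = 1.0 - spec.rho ** 2
        resid = f[1:] - mean - spec.rho * (f[:-1] - mean)
        ll += -0.5 * np.sum(resid ** 2) / (sd ** 2 * c2) \
              - 0.5 * (K - 1) * d * np.log(2 * np.pi * sd ** 2 * c2)
    return float(ll)


def bayes_oracle(
    spec: GeneratorSpec, sample: AlignedSample,
    modality: str = "both", group: tuple[str, ...] | None = None,
) -> np.ndarray:
    """Exact activity posterior of a sample under the generative model.

    ``modality`` restricts the evidence ("sensor", "image", or "both");
    ``group`` restricts the candidate set (posterior over that group only,
    e.g. the within-group image oracle). Upper-bounds any trained
    classifier's accuracy on generator data.
    """
    if modality not in ("both", "image", "sensor"):
        raise ValueError("modality must be 'both', 'image' or 'sensor'")
    C = spec.correspondence
    acts = list(group) if group is not None else list(spec.activities)
    means = spec.means()
    props = spec.activity_proportions()
    act_index = {a: i for i, a in enumerate(spec.activities)}

    state_ll: dict[str, float] = {}
    if modality in ("both", "sensor"):
        for s in C.state_set:
            state_ll[s] = _segment_loglik(spec, spec.state_models[s],
                                          sample.segment.samples)
    logpost = np.empty(len(acts))
    for j, a in enumerate(acts):
        ai = act_index[a]
        lp = np.log(props[ai])
        if modality in ("both", "sensor"):
            states = C.states_of(a)
            lp += logsumexp([state_ll[s] for s in states]) - np.log(len(states))
        if modality in ("both", "image"):
            f = sample.payload.features
            lp += _payload_loglik(spec, means[ai], f)
        logpost[j] = lp
    logpost -= logsumexp(logpost)
    return np.exp(logpost)


# -- presets ---------------------------------------------------------------


def preset(name: str, seed: int = 0) -> GeneratorSpec:
    """Packaged study conditions.

    ``"ebutton-like"``: 15 activities, 4 states, low-frame-rate regime
    (one frame per window, frames 4 s apart, disjoint windows), 90 Hz,
    t_w = 3 s. Image separability is moderate (separation 1.0 in 8-d) while
    state separability is strong — the asymmetric-sensor-difference regime.

    ``"multimodal-like"`` (aliases ``"multimodal-m5"``..``"-m8"`` select the
    grouping): 20 activities, high-frame-rate regime (K = 90 correlated
    frames per 3 s window, centers 1 s apart over 15 s sequences).
    """
    key = name.lower()
    if key == "ebutton-like":
        C = load_fixture("eButton")
        models = make_state_models(C.state_set.labels, ambulatory={"WK"})
        return GeneratorSpec(correspondence=C, state_models=models,
                             regime="low", frame_spacing=4.0, seed=seed)
    if key == "multimodal-like":
        key = "multimodal-m6"
    if key.startswith("multimodal-m"):
        fixture = key.removeprefix("multimodal-").upper()
        C = load_fixture(fixture)
        ambulatory = {s for s in C.state_set.labels
                      if any(tag in s for tag in ("WK", "RN", "DPU", "DSU", "CY"))
                      and "SD" not in s}
        models = make_state_models(C.state_set.labels, ambulatory=ambulatory)
        return GeneratorSpec(correspondence=C, state_models=models,
                             regime="high", K=90, rho=0.95,
                             frame_spacing=1.0, seed=seed)
    raise KeyError(f"unknown preset: {name!r}")
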