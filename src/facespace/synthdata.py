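"""Synthetic data with planted ground truth.

Everything downstream — HFA extraction, contact screening, decoding, the
layer-profile analyses and the model-unit search — is exercised on data from
this module, where the true face-space geometry, the true category gains and
the true exemplar tuning of every synthetic contact are known.

The generative story: a latent face space assigns each face exemplar a
k-dimensional embedding. Synthetic contacts respond to stimuli with a
stimulus-locked high-gamma burst whose envelope amplitude follows a softplus
link of the contact's tuning weights dotted with the exemplar's embedding,
riding on 1/f² background noise, a shared common-mode component and 60 Hz
line noise. Synthetic network layers embed the same latent geometry at a
controllable fidelity α per layer: α = 1 is an isometric embedding (layer
distances reproduce latent distances exactly), α = 0 is independent noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve, firwin
from scipy.stats import gamma as gamma_dist

from ._rng import derive_seed, rng_for
from .convnet import ToyConvNetSpec, build_toy_convnet  # noqa: F401  (re-export)
from .images import generate_face_images  # noqa: F401  (re-export)
from .protocols import (  # noqa: F401  (re-export)
    SET_CATEGORIES,
    TaskProtocol,
    generate_protocol,
    validate_protocol,
)
from .signal import Recording

DEFAULT_N_LAYERS = 22


@dataclass
class LatentFaceSpace:
    """Ground-truth geometry: one k-dimensional embedding per face exemplar."""

    embeddings: dict  # exemplar id -> 1-D vector
    k: int
    seed: int

    def __post_init__(self):
        for v in self.embeddings.values():
            if not np.isfinite(v).all():
                raise ValueError("non-finite embedding")

    @property
    def exemplar_ids(self) -> list:
        return list(self.embeddings)

    @property
    def matrix(self) -> np.ndarray:
        return np.stack([self.embeddings[e] for e in self.embeddings])

    @classmethod
    def random(cls, exemplar_ids, k: int = 4, seed: int = 0) -> "LatentFaceSpace":
        rng = rng_for(seed, "latent")
        Z = rng.standard_normal((len(exemplar_ids), k))
        return cls({e: Z[i] for i, e in enumerate(exemplar_ids)}, k, seed)


@dataclass
class SyntheticLayerStack:
    """Per-layer activation matrices whose geometry tracks the latent space."""

    layer_names: list
    activations: dict  # layer name -> (n_exemplars x dim) matrix
    exemplar_ids: list
    match_profile: dict  # layer name -> α in [0, 1]
    noise_seed: int

    @property
    def n_layers(self) -> int:
        return len(self.layer_names)

    def layers(self) -> list:
        return [(name, self.activations[name]) for name in self.layer_names]


def _default_layer_names(n: int) -> list:
    if n == DEFAULT_N_LAYERS:
        from .network_spec import default_architecture, enumerate_layers

        return enumerate_layers(default_architecture())
    return [f"layer_{i + 1:02d}" for i in range(n)]


def simulate_layer_stack(
    latent: LatentFaceSpace,
    match_profile,
    dims: int = 64,
    seed: int = 0,
    layer_names=None,
) -> SyntheticLayerStack:
    """Build a stack of layer activations with planted geometric fidelity.

    Each layer's activation for exemplar i is a random linear isometric
    embedding of ``α·z_i + (1−α)·ε_i`` with ε Gaussian noise scaled to the
    latent embeddings' spread; projections and noise are independent across
    layers. ``match_profile`` is a dict layer->α, or a sequence of α values.
    """
    if layer_names is None:
        n = len(match_profile)
        layer_names = list(match_profile) if isinstance(match_profile, dict) else _default_layer_names(n)
    if isinstance(match_profile, dict):
        alphas = [match_profile[name] for name in layer_names]
    else:
        alphas = list(match_profile)
    if len(alphas) != len(layer_names):
        raise ValueError("match_profile must define α for every layer")
    for a in alphas:
        if not 0 <= a <= 1:
            raise ValueError(f"α = {a} outside [0, 1]")
    if dims < latent.k:
        raise ValueError("dims must be at least the latent dimension")

    Z = latent.matrix
    scale = Z.std()
    acts = {}
    for name, alpha in zip(layer_names, alphas):
        rng = rng_for(seed, "layer_stack", name)
        eps = rng.standard_normal(Z.shape) * scale
        mixed = alpha * Z + (1 - alpha) * eps
        q, _ = np.linalg.qr(rng.standard_normal((dims, latent.k)))
        acts[name] = mixed @ q.T  # isometric k -> dims embedding
    return SyntheticLayerStack(
        list(layer_names), acts, latent.exemplar_ids, dict(zip(layer_names, alphas)), seed
    )


def planted_match_profile(
    planted_layer: str | int = 12,
    alpha_planted: float = 0.95,
    alpha_other: float = 0.2,
    n_layers: int = DEFAULT_N_LAYERS,
) -> dict:
    """α profile with one high-fidelity layer and a low floor elsewhere."""
    names = _default_layer_names(n_layers)
    if isinstance(planted_layer, int):
        planted_layer = names[planted_layer]
    if planted_layer not in names:
        raise ValueError(f"unknown layer {planted_layer!r}")
    return {name: (alpha_planted if name == planted_layer else alpha_other) for name in names}


# ---------------------------------------------------------------------------
# forward model: continuous recordings
# ---------------------------------------------------------------------------

def default_contacts_config(
    n_contacts: int,
    latent: LatentFaceSpace,
    n_face: int | None = None,
    face_gain: float = 3.0,
    visual_gain: float = 1.0,
    tuning_strength: float = 1.0,
    noise_level: float = 10.0,
    line_amp: float = 2.0,
    common_amp: float = 3.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-channel forward-model parameters.

    The first ``n_face`` channels (default: half) are face selective with
    exemplar tuning drawn on the unit sphere in latent space; the rest are
    merely visually responsive. ``face_gain=0`` and ``visual_gain=0`` give a
    pure-noise (null) recording.
    """
    rng = rng_for(seed, "contacts_config")
    if n_face is None:
        n_face = n_contacts // 2
    rows = []
    for i in range(n_contacts):
        is_face = i < n_face
        w = rng.standard_normal(latent.k)
        w *= tuning_strength / max(np.linalg.norm(w), 1e-12)
        rows.append(
            {
                "channel": f"ch{i + 1:03d}",
                "face_gain": face_gain if is_face else 0.0,
                "visual_gain": visual_gain,
                "tuning": w if is_face else np.zeros(latent.k),
                "noise_level": noise_level,
                "line_amp": line_amp,
                "common_amp": common_amp,
            }
        )
    return pd.DataFrame(rows)


def _softplus(x):
    return np.log1p(np.exp(-np.abs(x))) + np.maximum(x, 0)


def burst_envelope(fs: float, rise_ms: float = 50.0, peak_ms: float = 200.0) -> np.ndarray:
    """Gamma-shaped burst envelope: onset at ``rise_ms``, peak at ``peak_ms``."""
    t = np.arange(0, 0.6, 1 / fs) * 1000.0  # ms, 600 ms support
    shape = 3.0
    scale = (peak_ms - rise_ms) / (shape - 1)
    env = gamma_dist.pdf(t - rise_ms, a=shape, scale=scale)
    env[t < rise_ms] = 0.0
    return env / env.max()


def simulate_recording(
    protocol: TaskProtocol,
    contacts_config: pd.DataFrame,
    latent: LatentFaceSpace,
    seed: int = 0,
    fs: float = 500.0,
) -> tuple[Recording, pd.DataFrame]:
    """Forward-model a continuous recording for one protocol.

    Per channel: 1/f² (Brownian) background plus a broadband floor, a shared
    common-mode component, 60 Hz line noise, and a stimulus-locked 70–150 Hz
    burst whose envelope amplitude is ``visual_gain`` for any stimulus plus
    ``face_gain · softplus(tuning · embedding)`` for face exemplars.

    Returns the recording and a ground-truth table (one row per channel).
    """
    known = set(latent.exemplar_ids)
    face_trials = protocol.trials[protocol.trials["category"] == "faces"]
    missing = set(face_trials["stimulus_id"]) - known
    if missing:
        raise ValueError(f"protocol face stimuli missing from latent space: {sorted(missing)}")

    n_samples = int(np.ceil((protocol.trials["onset_ms"].max() + 2000) / 1000 * fs))
    env = burst_envelope(fs)
    n_env = len(env)
    onset_samples = np.round(protocol.trials["onset_ms"].values / 1000 * fs).astype(int)
    bp = firwin(129, [70, 150], fs=fs, pass_zero=False)

    rng = rng_for(seed, "recording", protocol.set_id)
    common = np.cumsum(rng.standard_normal(n_samples))
    common /= max(common.std(), 1e-12)
    line_phase = rng.uniform(0, 2 * np.pi)
    line = np.sin(2 * np.pi * 60.0 * np.arange(n_samples) / fs + line_phase)

    data = np.empty((len(contacts_config), n_samples))
    truth_rows = []
    for ci, row in contacts_config.reset_index(drop=True).iterrows():
        crng = rng_for(seed, "recording", protocol.set_id, row["channel"])
        brown = np.cumsum(crng.standard_normal(n_samples))
        brown /= max(brown.std(), 1e-12)
        floor = crng.standard_normal(n_samples)
        carrier = fftconvolve(crng.standard_normal(n_samples), bp, mode="same")
        carrier /= max(carrier.std(), 1e-12)

        amp = np.zeros(n_samples)
        w = np.asarray(row["tuning"], dtype=float)
        for onset, (_, tr) in zip(onset_samples, protocol.trials.iterrows()):
            a = row["visual_gain"]
            if tr["category"] == "faces":
                a = a + row["face_gain"] * _softplus(w @ latent.embeddings[tr["stimulus_id"]])
            stop = min(onset + n_env, n_samples)
            amp[onset:stop] += a * env[: stop - onset]
        data[ci] = (
            row["noise_level"] * brown
            + 0.3 * row["noise_level"] * floor
            + row["common_amp"] * common
            + row["line_amp"] * line
            + amp * carrier
        )
        truth_rows.append(
            {
                "channel": row["channel"],
                "face_gain": row["face_gain"],
                "visual_gain": row["visual_gain"],
                "tuning_norm": float(np.linalg.norm(w)),
                "noise_level": row["noise_level"],
            }
        )
    rec = Recording(data, fs, list(contacts_config["channel"]))
    return rec, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# direct response-matrix generator (fast path for repeated-seed suites)
# ---------------------------------------------------------------------------

def simulate_response_matrix(
    latent: LatentFaceSpace,
    n_contacts: int = 40,
    n_trials: int = 5,
    n_timepoints: int = 225,
    fs: float = 500.0,
    tuning_strength: float = 1.5,
    noise_sd: float = 0.5,
    seed: int = 0,
):
    """Draw a grand response matrix G directly from the latent space.

    Skips the continuous forward model: each contact's mean response to an
    exemplar is ``softplus(tuning · embedding)`` shaped by the burst envelope,
    plus i.i.d. Gaussian trial noise. Returns a :class:`~facespace.contacts.
    ResponseMatrix`-compatible object via :func:`facespace.contacts.
    ResponseMatrix` (exemplars x contacts x trials x time) together with the
    contacts' true tuning matrix.
    """
    from .contacts import ResponseMatrix

    rng = rng_for(seed, "response_matrix")
    Z = latent.matrix
    n_ex = len(latent.exemplar_ids)
    W = rng.standard_normal((n_contacts, latent.k))
    W *= tuning_strength / np.linalg.norm(W, axis=1, keepdims=True)
    mean_amp = _softplus(W @ Z.T)  # contacts x exemplars
    kernel = burst_envelope(fs)[25 : 25 + n_timepoints]  # [50, 500) ms of the burst
    G = (
        mean_amp.T[:, :, None, None] * kernel[None, None, None, :]
        + noise_sd * rng.standard_normal((n_ex, n_contacts, n_trials, n_timepoints))
    )
    contact_ids = [f"ch{i + 1:03d}" for i in range(n_contacts)]
    times = 50 + np.arange(n_timepoints) * 1000.0 / fs
    rm = ResponseMatrix(G, list(latent.exemplar_ids), contact_ids, times_ms=times, set_id=0)
    return rm, W
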