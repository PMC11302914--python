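"""Gradient-descent learning of an additive bias to the MSA cluster profile.

The optimization loop treats a frozen fold-confidence predictor (the
*backend*) as a differentiable black box. A zero-initialized, unconstrained
L x 22 bias matrix is added to the cluster profile, the biased features are
pushed through the backend to obtain iptm/ptm, and the bias is updated by
Adam to minimize ``1/confidence`` where confidence = 0.8*iptm + 0.2*ptm.
Per-iteration stochasticity (fresh cluster resampling plus backend-internal
noise, standing in for MSA resampling and dropout) makes the learned bias
robust across samples; gradients are taken only at the backend's final pass,
never across recycles. The bias is specific to one complex and never shared.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol

import numpy as np
import pandas as pd

from .featurize import Profile, compute_profile, sample_clusters
from .evaluate import ranking_confidence
from .msa_io import MSA, N_CLASSES


@dataclass
class Prediction:
    """One backend forward pass: confidence components plus an accuracy proxy
    (for the surrogate backend, the negated distance to the planted profile;
    a real structural backend would report an external accuracy score)."""

    iptm: float
    ptm: float
    accuracy_proxy: float | None = None

    @property
    def confidence(self) -> float:
        return ranking_confidence(self.iptm, self.ptm)


class FoldConfidenceBackend(Protocol):
    """Contract a predictor must satisfy to be optimized against.

    Both methods must be pure given (features, rng seed); ``gradient``
    returns d(confidence)/d(features) evaluated at the final internal pass
    only. ``stochastic`` enables backend-internal noise (the dropout /
    subsampling stand-in).
    """

    def forward(
        self, features: np.ndarray, n_recycles: int, rng: np.random.Generator, stochastic: bool
    ) -> Prediction: ...

    def gradient(
        self, features: np.ndarray, n_recycles: int, rng: np.random.Generator, stochastic: bool
    ) -> np.ndarray: ...


@dataclass
class OptConfig:
    """Optimizer settings. Defaults: Adam, lr 1e-4, 100 steps, 20 recycles,
    stochastic resampling on."""

    learning_rate: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-8
    max_iters: int = 100
    n_recycles: int = 20
    stochastic: bool = True
    master_seed: int = 0
    n_clusters: int = 128

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not (0 <= self.beta1 < 1 and 0 <= self.beta2 < 1):
            raise ValueError("beta1/beta2 must lie in [0, 1)")
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")
        if self.n_recycles < 0:
            raise ValueError("n_recycles must be >= 0")


@dataclass
class ProfileBias:
    """Unconstrained additive residual to the cluster profile (zeros at init)."""

    matrix: np.ndarray
    complex_id: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2:
            raise ValueError("bias must be a 2-D matrix")

    @property
    def l2(self) -> float:
        return float(np.linalg.norm(self.matrix))


@dataclass
class AdamState:
    m: np.ndarray
    v: np.ndarray
    t: int = 0

    @classmethod
    def zeros(cls, shape) -> "AdamState":
        return cls(m=np.zeros(shape), v=np.zeros(shape), t=0)


@dataclass
class TrajectoryRecord:
    iteration: int
    iptm: float
    ptm: float
    confidence: float
    loss: float
    bias_l2: float
    accuracy_proxy: float | None = None


@dataclass
class Trajectory:
    records: list[TrajectoryRecord]
    config: OptConfig
    best_index: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.records])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.12g")

    def confidences(self) -> np.ndarray:
        return np.array([r.confidence for r in self.records])


class BackendError(RuntimeError):
    """Backend failure or non-finite gradient; carries the partial trajectory."""

    def __init__(self, message: str, trajectory: Trajectory):
        super().__init__(message)
        self.trajectory = trajectory


def init_bias(L: int, A: int = N_CLASSES, complex_id: str = "") -> ProfileBias:
    """All-zero bias with the same shape as the profile."""
    if L < 1 or A < 1:
        raise ValueError("bias dimensions must be positive")
    return ProfileBias(np.zeros((L, A)), complex_id=complex_id)


def apply_bias(profile: Profile, bias: ProfileBias) -> np.ndarray:
    """Elementwise profile + bias, fed to the backend as-is.

    No clamping and no renormalization: the backend consumes possibly
    non-simplex features, exactly as an additive perturbation to a raw
    feature tensor would.
    """
    if profile.matrix.shape != bias.matrix.shape:
        raise ValueError(
            f"profile shape {profile.matrix.shape} != bias shape {bias.matrix.shape}"
        )
    return profile.matrix + bias.matrix


def confidence_loss(confidence: float) -> float:
    """The optimization objective: 1/confidence (minimized)."""
    if confidence <= 0:
        raise ValueError("confidence must be positive; degenerate backend output")
    return 1.0 / confidence


def adam_update(
    bias: ProfileBias, grad: np.ndarray, state: AdamState, config: OptConfig
) -> tuple[ProfileBias, AdamState]:
    """One Adam step with bias-corrected moment estimates."""
    grad = np.asarray(grad, dtype=np.float64)
    if grad.shape != bias.matrix.shape:
        raise ValueError("gradient shape does not match bias shape")
    t = state.t + 1
    m = config.beta1 * state.m + (1 - config.beta1) * grad
    v = config.beta2 * state.v + (1 - config.beta2) * grad**2
    m_hat = m / (1 - config.beta1**t)
    v_hat = v / (1 - config.beta2**t)
    new = bias.matrix - config.learning_rate * m_hat / (np.sqrt(v_hat) + config.epsilon)
    return ProfileBias(new, complex_id=bias.complex_id), AdamState(m=m, v=v, t=t)


def iteration_rng(master_seed: int, iteration: int, stream: int) -> np.random.Generator:
    """Independent, reproducible generator for (run, iteration, purpose)."""
    return np.random.default_rng([master_seed & 0x7FFFFFFF, iteration, stream])


_STREAM_CLUSTERS = 1
_STREAM_BACKEND = 2


def optimize(
    backend: FoldConfidenceBackend,
    msa: MSA,
    config: OptConfig,
    complex_id: str = "",
) -> tuple[Trajectory, ProfileBias]:
    """Run the full bias-learning loop on one complex.

    Per iteration: derive an iteration seed from the master seed; with
    ``stochastic`` on, resample cluster rows and rebuild the profile
    (otherwise a fixed profile is reused); add the bias; run the backend
    forward with ``n_recycles`` internal recycles; take the confidence
    gradient at the final pass; convert via the chain rule
    d(loss)/d(bias) = -confidence^-2 * d(confidence)/d(bias); Adam-update.
    The recorded confidence at each iteration is evaluated at the
    pre-update bias. Backend failure or a non-finite gradient aborts with
    the partial trajectory attached.
    """
    bias = init_bias(msa.L, complex_id=complex_id)
    state = AdamState.zeros(bias.matrix.shape)
    records: list[TrajectoryRecord] = []

    fixed_profile: Profile | None = None
    if not config.stochastic:
        rows = sample_clusters(msa, config.n_clusters, iteration_rng(config.master_seed, 0, _STREAM_CLUSTERS))
        fixed_profile = compute_profile(msa, rows)

    for i in range(config.max_iters):
        if config.stochastic:
            rows = sample_clusters(
                msa, config.n_clusters, iteration_rng(config.master_seed, i, _STREAM_CLUSTERS)
            )
            profile = compute_profile(msa, rows)
        else:
            profile = fixed_profile
        features = apply_bias(profile, bias)
        # forward and gradient replay the same backend-noise stream so the
        # gradient is taken at exactly the final pass the forward evaluated
        try:
            pred = backend.forward(
                features, config.n_recycles,
                iteration_rng(config.master_seed, i, _STREAM_BACKEND), config.stochastic,
            )
            grad_conf = backend.gradient(
                features, config.n_recycles,
                iteration_rng(config.master_seed, i, _STREAM_BACKEND), config.stochastic,
            )
        except Exception as exc:  # noqa: BLE001 - surfaced with partial trajectory
            raise BackendError(
                f"backend failed at iteration {i}: {exc}",
                _finish(records, config),
            ) from exc
        conf = pred.confidence
        loss = confidence_loss(conf)
        grad_loss = -(conf**-2) * np.asarray(grad_conf, dtype=np.float64)
        if not np.all(np.isfinite(grad_loss)):
            raise BackendError(
                f"non-finite gradient at iteration {i}", _finish(records, config)
            )
        records.append(
            TrajectoryRecord(
                iteration=i,
                iptm=pred.iptm,
                ptm=pred.ptm,
                confidence=conf,
                loss=loss,
                bias_l2=bias.l2,
                accuracy_proxy=pred.accuracy_proxy,
            )
        )
        bias, state = adam_update(bias, grad_loss, state, config)

    return _finish(records, config), bias


def _finish(records: list[TrajectoryRecord], config: OptConfig) -> Trajectory:
    best = int(np.argmax([r.confidence for r in records])) if records else 0
    return Trajectory(records=records, config=config, best_index=best)


def select_best(trajectory: Trajectory) -> TrajectoryRecord:
    """Highest-confidence record; ties broken by the earliest iteration."""
    if not trajectory.records:
        raise ValueError("cannot select from an empty trajectory")
    idx = int(np.argmax([r.confidence for r in trajectory.records]))
    return trajectory.records[idx]
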