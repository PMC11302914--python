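"""Synthetic differentiable fold-confidence backend with a planted optimum.

A surrogate problem plants a sharp "true" per-column profile P*, blurs it
with Gaussian noise projected back onto the simplex, and samples synthetic
MSA rows from the blurred profile. The surrogate confidence is a smooth,
convex-in-features function of the mean squared column distance d between
the input features and P*:

    iptm = exp(-k_i * d),   ptm = exp(-k_p * d),
    confidence = 0.8*iptm + 0.2*ptm,

maximized exactly when features (profile + bias) equal P*. With stochastic
noise on, each internal pass evaluates a random 80% column subset, and
``n_recycles`` extra averaging passes shrink the subset-sampling variance;
the gradient is defined only at the final pass. No claim of fidelity to a
real structure-prediction confidence landscape is made — the surrogate
exists so the optimization machinery, selection logic and statistics are
testable against known ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .bias_opt import Prediction
from .featurize import Profile
from .msa_io import ALPHABET, MSA, N_CLASSES, write_a3m

DEFAULT_K_IPTM = 5.0
DEFAULT_K_PTM = 3.0
_SUBSET_FRACTION = 0.8
_N_AA = 20  # planted residues are drawn from the 20 standard amino acids


@dataclass
class SurrogateProblem:
    """A planted instance: true profile P*, blurred profile, sampled MSA."""

    planted_profile: Profile
    blurred_profile: Profile
    observed_msa: MSA
    noise_sigma: float
    sharpness_iptm: float = DEFAULT_K_IPTM
    sharpness_ptm: float = DEFAULT_K_PTM
    seed: int = 0

    @property
    def L(self) -> int:
        return self.planted_profile.L


def project_simplex(v: np.ndarray) -> np.ndarray:
    """Euclidean projection of each row of ``v`` onto the probability simplex."""
    v = np.asarray(v, dtype=np.float64)
    u = np.sort(v, axis=-1)[..., ::-1]
    cssv = np.cumsum(u, axis=-1) - 1.0
    ind = np.arange(1, v.shape[-1] + 1)
    cond = u - cssv / ind > 0
    rho = cond.sum(axis=-1)
    tau = cssv[np.arange(v.shape[0]), rho - 1] / rho
    return np.maximum(v - tau[:, None], 0.0)


def make_problem(
    L: int,
    n_rows: int,
    noise_sigma: float,
    seed: int,
    k_iptm: float = DEFAULT_K_IPTM,
    k_ptm: float = DEFAULT_K_PTM,
) -> SurrogateProblem:
    """Build a planted problem, deterministically from ``seed``.

    P* columns are Dirichlet draws concentrated on one standard amino acid
    per column; the observed MSA's non-query rows are i.i.d. per-column
    draws from the blurred profile; the query row is the planted consensus.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    if n_rows < 2:
        raise ValueError("n_rows must be >= 2 (query plus at least one sample)")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    if k_iptm <= 0 or k_ptm <= 0:
        raise ValueError("sharpness parameters must be positive")
    rng = np.random.default_rng(seed)

    planted = np.empty((L, N_CLASSES))
    consensus_idx = rng.integers(0, _N_AA, size=L)
    for l in range(L):
        alpha = np.full(N_CLASSES, 0.1)
        alpha[consensus_idx[l]] += 9.9
        planted[l] = rng.dirichlet(alpha)

    blurred = project_simplex(planted + rng.normal(0.0, noise_sigma, size=planted.shape))
    # a projected column can degenerate numerically; keep it a distribution
    blurred /= blurred.sum(axis=1, keepdims=True)

    query = "".join(ALPHABET[i] for i in np.argmax(planted[:, :_N_AA], axis=1))
    rows = [query]
    cdf = np.cumsum(blurred, axis=1)
    for _ in range(n_rows - 1):
        u = rng.random(L)
        idx = np.array([np.searchsorted(cdf[l], u[l], side="right") for l in range(L)])
        idx = np.minimum(idx, N_CLASSES - 1)
        rows.append("".join(ALPHABET[i] for i in idx))

    msa = MSA(
        rows=rows,
        deletions=np.zeros((n_rows, L), dtype=np.int64),
        species=[None] * n_rows,
        headers=["query_planted"] + [f"sample{i}" for i in range(1, n_rows)],
    )
    return SurrogateProblem(
        planted_profile=Profile(planted),
        blurred_profile=Profile(blurred),
        observed_msa=msa,
        noise_sigma=noise_sigma,
        sharpness_iptm=k_iptm,
        sharpness_ptm=k_ptm,
        seed=seed,
    )


def _column_subsets(
    L: int, n_evals: int, rng: np.random.Generator, stochastic: bool
) -> list[np.ndarray]:
    if not stochastic:
        return [np.arange(L)] * n_evals
    m = max(1, int(round(_SUBSET_FRACTION * L)))
    return [np.sort(rng.choice(L, size=m, replace=False)) for _ in range(n_evals)]


def _check_shape(problem: SurrogateProblem, features: np.ndarray) -> np.ndarray:
    features = np.asarray(features, dtype=np.float64)
    if features.shape != problem.planted_profile.matrix.shape:
        raise ValueError(
            f"feature shape {features.shape} != planted profile shape "
            f"{problem.planted_profile.matrix.shape}"
        )
    return features


def surrogate_forward(
    problem: SurrogateProblem,
    features: np.ndarray,
    n_recycles: int,
    rng: np.random.Generator,
    stochastic: bool,
) -> Prediction:
    """Evaluate the surrogate confidence at the given features.

    d is the mean over evaluated columns of the squared Euclidean distance
    between the feature column and the planted column, averaged over
    ``n_recycles + 1`` passes (each pass drawing its own column subset when
    stochastic). The accuracy proxy is -d over ALL columns, the surrogate's
    stand-in for an external structural accuracy score.
    """
    features = _check_shape(problem, features)
    col_sq = ((features - problem.planted_profile.matrix) ** 2).sum(axis=1)
    subsets = _column_subsets(problem.L, n_recycles + 1, rng, stochastic)
    d = float(np.mean([col_sq[s].mean() for s in subsets]))
    return Prediction(
        iptm=float(np.exp(-problem.sharpness_iptm * d)),
        ptm=float(np.exp(-problem.sharpness_ptm * d)),
        accuracy_proxy=float(-col_sq.mean()),
    )


def surrogate_gradient(
    problem: SurrogateProblem,
    features: np.ndarray,
    n_recycles: int,
    rng: np.random.Generator,
    stochastic: bool,
) -> np.ndarray:
    """d(confidence)/d(features), evaluated at the FINAL pass only.

    On the final pass's evaluated columns S (|S| = L'):
        dC/df = (0.8*k_i*iptm + 0.2*k_p*ptm) * (-2/L') * (f - P*),
    and zero on unevaluated columns. The rng must replay the same stream the
    matching forward call consumed so the final subset is identical.
    """
    features = _check_shape(problem, features)
    diff = features - problem.planted_profile.matrix
    col_sq = (diff**2).sum(axis=1)
    subsets = _column_subsets(problem.L, n_recycles + 1, rng, stochastic)
    d = float(np.mean([col_sq[s].mean() for s in subsets]))
    iptm = np.exp(-problem.sharpness_iptm * d)
    ptm = np.exp(-problem.sharpness_ptm * d)
    final = subsets[-1]
    prefac = 0.8 * problem.sharpness_iptm * iptm + 0.2 * problem.sharpness_ptm * ptm
    grad = np.zeros_like(features)
    grad[final] = prefac * (-2.0 / final.size) * diff[final]
    return grad


class SurrogateBackend:
    """Adapter exposing a planted problem through the backend contract."""

    name = "surrogate"

    def __init__(self, problem: SurrogateProblem):
        self.problem = problem

    def forward(self, features, n_recycles, rng, stochastic) -> Prediction:
        return surrogate_forward(self.problem, features, n_recycles, rng, stochastic)

    def gradient(self, features, n_recycles, rng, stochastic) -> np.ndarray:
        return surrogate_gradient(self.problem, features, n_recycles, rng, stochastic)


class StubBackend:
    """Documents the adapter surface for a real structure-prediction backend.

    A production adapter would wrap the frozen network, return its iptm/ptm
    head outputs from ``forward`` and the input-feature confidence gradient
    from ``gradient``. This stub raises on use.
    """

    name = "stub"

    def forward(self, features, n_recycles, rng, stochastic) -> Prediction:
        raise NotImplementedError(
            "the stub backend documents the adapter surface only; "
            "use the surrogate backend for runnable optimization"
        )

    gradient = forward


PROBLEM_FILES = {
    "msa": "observed.a3m",
    "planted": "planted_profile.tsv",
    "blurred": "blurred_profile.tsv",
    "params": "params.json",
}


def write_problem(problem: SurrogateProblem, out_dir) -> None:
    """Write a problem as plain text: A3M MSA, profile TSVs, JSON params."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / PROBLEM_FILES["msa"]).write_text(write_a3m(problem.observed_msa))
    problem.planted_profile.to_tsv(out / PROBLEM_FILES["planted"])
    problem.blurred_profile.to_tsv(out / PROBLEM_FILES["blurred"])
    params = {
        "L": problem.L,
        "n_rows": problem.observed_msa.n_rows,
        "noise_sigma": problem.noise_sigma,
        "k_iptm": problem.sharpness_iptm,
        "k_ptm": problem.sharpness_ptm,
        "seed": problem.seed,
    }
    (out / PROBLEM_FILES["params"]).write_text(json.dumps(params, indent=2) + "\n")


def load_problem(in_dir) -> SurrogateProblem:
    """Load a problem written by :func:`write_problem` (regenerated from its
    recorded seed, so it is bit-identical to the original)."""
    p = Path(in_dir)
    params = json.loads((p / PROBLEM_FILES["params"]).read_text())
    return make_problem(
        L=params["L"],
        n_rows=params["n_rows"],
        noise_sigma=params["noise_sigma"],
        seed=params["seed"],
        k_iptm=params["k_iptm"],
        k_ptm=params["k_ptm"],
    )
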