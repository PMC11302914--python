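"""AlphaFold-style input featurization from an MSA.

The central object is the cluster profile: the per-column frequency
distribution over the 22 residue classes computed from a sampled subset of
MSA rows. The profile is the feature the bias optimizer perturbs; everything
else (deletion means, pairing structure) is pass-through context. Multimer
construction mirrors the AlphaFold-multimer recipe at reduced fidelity:
rows paired across chains by species, plus block-diagonalized per-chain rows
that keep intra-chain covariation without asserting inter-chain pairing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .msa_io import ALPHABET, GAP, MSA, N_CLASSES, encode_rows, sequence_identity

_PROFILE_ATOL = 1e-9


@dataclass
class Profile:
    """L x 22 column-wise categorical frequency matrix (rows sum to 1)."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != N_CLASSES:
            raise ValueError(f"profile must be L x {N_CLASSES}")
        if (self.matrix < -_PROFILE_ATOL).any() or (self.matrix > 1 + _PROFILE_ATOL).any():
            raise ValueError("profile entries must lie in [0, 1]")
        sums = self.matrix.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=_PROFILE_ATOL, rtol=0):
            raise ValueError("profile columns must sum to 1")

    @property
    def L(self) -> int:
        return self.matrix.shape[0]

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.matrix, columns=list(ALPHABET))
        df.to_csv(path, sep="\t", index=False, float_format="%.12g")

    @classmethod
    def from_tsv(cls, path) -> "Profile":
        df = pd.read_csv(path, sep="\t")
        if list(df.columns) != list(ALPHABET):
            raise ValueError("profile TSV header must be the residue alphabet")
        return cls(df.to_numpy(dtype=np.float64))

    def to_json(self, path) -> None:
        payload = {
            "shape": list(self.matrix.shape),
            "alphabet": ALPHABET,
            "matrix": [[float(f"{v:.12g}") for v in row] for row in self.matrix],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "Profile":
        with open(path) as fh:
            payload = json.load(fh)
        m = np.array(payload["matrix"], dtype=np.float64)
        if list(m.shape) != payload["shape"]:
            raise ValueError("profile JSON shape metadata mismatch")
        return cls(m)


@dataclass
class FeatureBundle:
    """Profile plus the sampling context it was computed from.

    ``deletion_mean`` (mean deletion count per column over the cluster rows)
    is carried for backend use but is never biased.
    """

    profile: Profile
    cluster_rows: list[int]
    msa_ref: MSA
    deletion_mean: np.ndarray | None = None
    bias_applied: bool = False

    def __post_init__(self) -> None:
        if not self.cluster_rows:
            raise ValueError("cluster_rows must be non-empty")
        if self.cluster_rows[0] != 0:
            raise ValueError("the query (row 0) must be the first cluster center")
        if len(set(self.cluster_rows)) != len(self.cluster_rows):
            raise ValueError("cluster_rows must be unique")
        if max(self.cluster_rows) >= self.msa_ref.n_rows:
            raise ValueError("cluster row index out of range")


def compute_profile(msa: MSA, rows: list[int] | None = None) -> Profile:
    """Column-wise residue-class frequencies over the selected rows."""
    if rows is not None and len(rows) == 0:
        raise ValueError("row selection must be non-empty")
    enc = encode_rows(msa, rows)
    counts = np.zeros((msa.L, N_CLASSES), dtype=np.float64)
    for col in range(msa.L):
        counts[col] = np.bincount(enc[:, col], minlength=N_CLASSES)
    return Profile(counts / enc.shape[0])


def sample_clusters(msa: MSA, n_clusters: int, rng: np.random.Generator) -> list[int]:
    """Sample cluster-center rows: the query first, the rest uniform without
    replacement. Capped silently at the row count."""
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    k = min(n_clusters, msa.n_rows)
    others = np.arange(1, msa.n_rows)
    picked = rng.choice(others, size=k - 1, replace=False) if k > 1 else []
    return [0] + [int(i) for i in picked]


def make_features(
    msa: MSA, n_clusters: int, rng: np.random.Generator
) -> FeatureBundle:
    """Sample clusters and build the profile + deletion-mean bundle."""
    rows = sample_clusters(msa, n_clusters, rng)
    profile = compute_profile(msa, rows)
    deletion_mean = msa.deletions[rows].mean(axis=0)
    return FeatureBundle(profile, rows, msa, deletion_mean=deletion_mean)


def pair_by_species(chain_msas: list[MSA]) -> MSA:
    """Pair rows across chains by shared species label.

    For every species present in all chains, the highest-identity row per
    chain (ties to the lowest row index) is concatenated into one paired row.
    Row 0 is the concatenated query. Rows without a parsable species are
    unpairable and ignored here.
    """
    if len(chain_msas) < 2:
        raise ValueError("pairing requires at least two chains")
    for m in chain_msas:
        if m.n_rows < 1:
            raise ValueError("empty chain MSA")
        if GAP in m.query:
            raise ValueError("chain query rows must be gap-free for pairing")

    per_chain_best: list[dict[str, int]] = []
    for m in chain_msas:
        best: dict[str, int] = {}
        for r in range(1, m.n_rows):
            sp = m.species[r]
            if sp is None:
                continue
            if sp not in best or sequence_identity(m.rows[r], m.query) > sequence_identity(
                m.rows[best[sp]], m.query
            ):
                best[sp] = r
        per_chain_best.append(best)

    shared = set(per_chain_best[0])
    for best in per_chain_best[1:]:
        shared &= set(best)

    chain_lengths = [m.L for m in chain_msas]
    rows = ["".join(m.query for m in chain_msas)]
    deletions = [np.concatenate([m.deletions[m.query_index] for m in chain_msas])]
    species: list[str | None] = [None]
    headers = ["query_paired"]
    for sp in sorted(shared):
        parts, dparts = [], []
        for m, best in zip(chain_msas, per_chain_best):
            r = best[sp]
            parts.append(m.rows[r])
            dparts.append(m.deletions[r])
        rows.append("".join(parts))
        deletions.append(np.concatenate(dparts))
        species.append(sp)
        headers.append(f"paired OX={sp}")
    return MSA(
        rows=rows,
        deletions=np.stack(deletions),
        species=species,
        headers=headers,
        chain_lengths=chain_lengths,
        query_index=0,
    )


def block_diagonalize(chain_msas: list[MSA]) -> MSA:
    """Place each chain's non-query rows in their own column span, gaps elsewhere.

    Returns an MSA *fragment* (``query_index=None``): one output row per
    non-query input row, length = total multimer length. Stack it under a
    paired/query alignment via :func:`build_multimer_msa`.
    """
    if not chain_msas:
        raise ValueError("at least one chain required")
    chain_lengths = [m.L for m in chain_msas]
    total = sum(chain_lengths)
    offsets = np.concatenate([[0], np.cumsum(chain_lengths)])
    rows, dels, species, headers = [], [], [], []
    for c, m in enumerate(chain_msas):
        left, right = int(offsets[c]), int(offsets[c + 1])
        for r in range(m.n_rows):
            if r == m.query_index:
                continue
            rows.append(GAP * left + m.rows[r] + GAP * (total - right))
            d = np.zeros(total, dtype=np.int64)
            d[left:right] = m.deletions[r]
            dels.append(d)
            species.append(m.species[r])
            headers.append(m.headers[r])
    if not rows:
        raise ValueError("no non-query rows to block-diagonalize")
    return MSA(
        rows=rows,
        deletions=np.stack(dels),
        species=species,
        headers=headers,
        chain_lengths=chain_lengths,
        query_index=None,
    )


def build_multimer_msa(chain_msas: list[MSA]) -> MSA:
    """Full multimer MSA: concatenated query, species-paired rows, then
    block-diagonalized per-chain rows. For one chain, the input is returned."""
    if len(chain_msas) == 1:
        return chain_msas[0]
    paired = pair_by_species(chain_msas)
    has_block = any(m.n_rows > 1 for m in chain_msas)
    if not has_block:
        return paired
    block = block_diagonalize(chain_msas)
    return MSA(
        rows=paired.rows + block.rows,
        deletions=np.vstack([paired.deletions, block.deletions]),
        species=paired.species + block.species,
        headers=paired.headers + block.headers,
        chain_lengths=paired.chain_lengths,
        query_index=0,
    )


def randomize_profile(profile: Profile, rng: np.random.Generator) -> Profile:
    """Replace every column with a uniform draw from the 22-class simplex.

    Feeding such a corrupted profile to a fold-confidence backend is the
    negative control: with all positional information destroyed, confidence
    collapses.
    """
    return Profile(rng.dirichlet(np.ones(N_CLASSES), size=profile.L))
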