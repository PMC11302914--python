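"""Batch orchestration: configuration, seeding, per-target runs, fixtures.

One master seed flows into everything; per-target and per-iteration seeds
are derived from it, so a batch re-run with the same configuration
reproduces identical outputs byte for byte. A failing target is recorded
under ``failures`` and never aborts the rest of the batch.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import featurize, msa_io, surrogate
from .bias_opt import BackendError, OptConfig, optimize, select_best
from .evaluate import ranking_confidence
from .featurize import build_multimer_msa

logger = logging.getLogger("afprofile")

TRAJECTORY_FILE = "trajectory.tsv"
BIAS_FILE = "bias.tsv"
META_FILE = "meta.json"


@dataclass
class TargetSpec:
    """One complex to optimize: its MSA file(s) and, for the surrogate
    backend, the directory holding the planted problem."""

    target_id: str
    msa_paths: list[str] = field(default_factory=list)
    problem_dir: str | None = None


@dataclass
class RunConfig:
    opt: OptConfig
    backend_name: str
    targets: list[TargetSpec]
    output_dir: str
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not self.targets:
            raise ValueError("at least one target required")
        if self.backend_name not in BACKENDS:
            raise ValueError(
                f"unknown backend {self.backend_name!r}; registered: {sorted(BACKENDS)}"
            )

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        raw = yaml.safe_load(text)
        return cls(
            opt=OptConfig(**raw.get("opt", {})),
            backend_name=raw["backend_name"],
            targets=[TargetSpec(**t) for t in raw["targets"]],
            output_dir=raw["output_dir"],
            log_level=raw.get("log_level", "INFO"),
        )


def _build_surrogate(spec: TargetSpec, _msa):
    if spec.problem_dir is None:
        raise ValueError(f"target {spec.target_id}: surrogate backend needs problem_dir")
    return surrogate.SurrogateBackend(surrogate.load_problem(spec.problem_dir))


def _build_stub(_spec, _msa):
    return surrogate.StubBackend()

BACKENDS = {"surrogate": _build_surrogate, "stub": _build_stub}


def load_target_msa(spec: TargetSpec) -> msa_io.MSA:
    """Read one A3M per chain and assemble the (multimer) MSA."""
    if spec.msa_paths:
        chains = [msa_io.parse_a3m(Path(p).read_text()) for p in spec.msa_paths]
        return build_multimer_msa(chains)
    if spec.problem_dir is not None:
        path = Path(spec.problem_dir) / surrogate.PROBLEM_FILES["msa"]
        return msa_io.parse_a3m(path.read_text())
    raise ValueError(f"target {spec.target_id}: no MSA source given")


def run_target(spec: TargetSpec, config: RunConfig, target_seed: int, out_dir: Path) -> dict:
    """Optimize one complex and write trajectory.tsv / bias.tsv / meta.json."""
    msa = load_target_msa(spec)
    backend = BACKENDS[config.backend_name](spec, msa)
    opt = OptConfig(**{**vars(config.opt), "master_seed": target_seed})
    trajectory, bias = optimize(backend, msa, opt, complex_id=spec.target_id)
    best = select_best(trajectory)

    out_dir.mkdir(parents=True, exist_ok=True)
    trajectory.to_tsv(out_dir / TRAJECTORY_FILE)
    pd.DataFrame(bias.matrix, columns=list(msa_io.ALPHABET)).to_csv(
        out_dir / BIAS_FILE, sep="\t", index=False, float_format="%.12g"
    )
    meta = {
        "target_id": spec.target_id,
        "backend": config.backend_name,
        "target_seed": target_seed,
        "config": vars(opt),
        "n_records": len(trajectory.records),
        "best_iteration": best.iteration,
        "best_confidence": best.confidence,
    }
    (out_dir / META_FILE).write_text(json.dumps(meta, indent=2) + "\n")
    return meta


def run_batch(config: RunConfig) -> dict:
    """Run every target, isolate failures, and write a batch report.

    The report's ``total_records`` is the sum of completed iterations over
    all successful targets; failed targets are listed with their error.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out_root = Path(config.output_dir)
    out_root.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "master_seed": config.opt.master_seed,
        "backend": config.backend_name,
        "targets": {},
        "failures": {},
        "total_records": 0,
    }
    for k, spec in enumerate(config.targets):
        target_seed = int(
            np.random.SeedSequence([config.opt.master_seed & 0x7FFFFFFF, k]).generate_state(1)[0]
            % 2**31
        )
        try:
            meta = run_target(spec, config, target_seed, out_root / spec.target_id)
        except (OSError, ValueError, BackendError, msa_io.MSAFormatError) as exc:
            logger.warning("target %s failed: %s", spec.target_id, exc)
            report["failures"][spec.target_id] = str(exc)
            continue
        report["targets"][spec.target_id] = {
            "n_records": meta["n_records"],
            "best_confidence": meta["best_confidence"],
            "best_iteration": meta["best_iteration"],
        }
        report["total_records"] += meta["n_records"]
    (out_root / "batch_report.json").write_text(json.dumps(report, indent=2) + "\n")
    return report


def make_fixtures(seed: int, out) -> dict:
    """Write the deterministic desk-scale fixture suite.

    Contents: three planted surrogate problems (L = 10, 50, 200), a
    two-chain species-pairing A3M pair with overlapping taxa, a clean /
    corrupted profile pair, and a synthetic per-target score table for the
    evaluation statistics. Everything is derived from ``seed``.
    """
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": seed, "problems": {}, "files": []}

    for L in (10, 50, 200):
        sub = out / f"surrogate_L{L}"
        problem = surrogate.make_problem(
            L=L, n_rows=200, noise_sigma=0.1,
            seed=int(np.random.SeedSequence([seed & 0x7FFFFFFF, L]).generate_state(1)[0] % 2**31),
        )
        surrogate.write_problem(problem, sub)
        manifest["problems"][f"surrogate_L{L}"] = sub.name

    rng = np.random.default_rng([seed & 0x7FFFFFFF, 997])

    chain_a = (
        ">queryA\nMKVLA\n"
        ">a1 OX=9606\nMKVLA\n"
        ">a2 OX=9606\nMKILA\n"
        ">a3 OX=10090\nMRVLA\n"
        ">a4 OX=7227\nMKV-A\n"
    )
    chain_b = (
        ">queryB\nGHWTE\n"
        ">b1 OX=9606\nGHWSE\n"
        ">b2 OX=10090\nGHFTE\n"
        ">b3 OX=4932\nGYWTE\n"
    )
    (out / "chainA.a3m").write_text(chain_a)
    (out / "chainB.a3m").write_text(chain_b)
    manifest["files"] += ["chainA.a3m", "chainB.a3m"]

    clean = surrogate.load_problem(out / "surrogate_L10").blurred_profile
    clean.to_tsv(out / "profile_clean.tsv")
    featurize.randomize_profile(clean, rng).to_tsv(out / "profile_corrupted.tsv")
    manifest["files"] += ["profile_clean.tsv", "profile_corrupted.tsv"]

    n = 40
    mm_initial = np.round(rng.uniform(0.2, 0.7, size=n), 3)
    delta = np.round(rng.normal(0.1, 0.15, size=n), 3)
    mm_final = np.clip(mm_initial + delta, 0.0, 1.0)
    iptm = np.clip(np.round(mm_final + rng.normal(0.05, 0.1, size=n), 3), 0.0, 1.0)
    ptm = np.clip(np.round(iptm + rng.normal(0.05, 0.05, size=n), 3), 0.0, 1.0)
    scores = pd.DataFrame(
        {
            "target_id": [f"T{i:04d}" for i in range(n)],
            "mmscore_initial": mm_initial,
            "mmscore_final": mm_final,
            "iptm": iptm,
            "ptm": ptm,
            "ranking_confidence": [ranking_confidence(i, p) for i, p in zip(iptm, ptm)],
            "msa_depth": rng.integers(10, 5000, size=n),
        }
    )
    scores.to_csv(out / "scores.tsv", sep="\t", index=False, float_format="%.6g")
    manifest["files"].append("scores.tsv")

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
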