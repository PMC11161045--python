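"""Batch orchestration: prior sampling, simulation batches, fixtures.

An :class:`ExperimentConfig` bundles the metacommunity spec, per-parameter
priors (uniform / log-uniform / choice, per the parameter table convention),
coalescent settings, and the master seed.  :func:`run_batch` runs
assembly -> popgen -> sumstats for every draw and returns the labeled
summary-statistics table that the inference module trains on.  Every
stochastic stage derives its seed deterministically from the master seed
and the (model, run index) pair, so batches are reproducible and resumable.

Three built-in configurations:

- ``default_config``: the wide prior ranges used for full-scale batches
  (J 500-2000, m log-uniform 1e-4..1e-2, s_E log-uniform 0.001..1, ...).
- ``desk_config``: the reproduction scale used by the test-suite and the
  acceptance script (500 sims/model, J 500-1000, m log-uniform 1e-3..1e-2,
  2500-generation cap); see docs/methods.md.
- ``fixture_config``: a tiny deterministic bundle (5 models x 20 sims at
  J=200) for tests and docs.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ecoassembly.assembly import MODELS, SimulationParams, run
from ecoassembly.metacommunity import MetacommunitySpec, generate_metacommunity
from ecoassembly.popgen import PopgenConfig, community_pi_vector
from ecoassembly.sumstats import summarize

__all__ = [
    "PriorSpec",
    "ExperimentConfig",
    "default_config",
    "desk_config",
    "fixture_config",
    "sample_priors",
    "run_batch",
    "make_fixtures",
]

_PARAM_COLUMNS = [
    "model",
    "run_index",
    "J",
    "m",
    "nu",
    "s_E",
    "beta_intra",
    "beta_inter",
    "alpha",
    "lambda_target",
    "seed",
]


@dataclass(frozen=True)
class PriorSpec:
    """One parameter's prior: uniform / loguniform / choice / fixed.

    ``zero_prob`` mixes in a point mass at zero (used for the speciation
    rate: a fraction of draws are strictly ``nu = 0``).
    """

    dist: str
    lo: float | None = None
    hi: float | None = None
    choices: tuple | None = None
    value: float | None = None
    integer: bool = False
    zero_prob: float = 0.0

    def sample(self, rng: np.random.Generator):
        if self.zero_prob > 0 and rng.random() < self.zero_prob:
            return 0.0
        if self.dist == "fixed":
            return self.value
        if self.dist == "choice":
            return self.choices[int(rng.integers(len(self.choices)))]
        if self.dist == "uniform":
            v = rng.uniform(self.lo, self.hi)
        elif self.dist == "loguniform":
            v = float(np.exp(rng.uniform(np.log(self.lo), np.log(self.hi))))
        else:
            raise ValueError(f"unknown prior distribution {self.dist!r}")
        return int(round(v)) if self.integer else v


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one simulation batch."""

    metacommunity: MetacommunitySpec = field(
        default_factory=lambda: MetacommunitySpec(n_species=200)
    )
    priors: dict = field(default_factory=dict)
    popgen: PopgenConfig = field(default_factory=PopgenConfig)
    models: tuple = MODELS
    n_per_model: int = 100
    max_generations: int = 3000
    snapshot_every: int = 1
    seed: int = 0
    outdir: str | None = None

    def to_yaml(self, path) -> None:
        def enc(obj):
            if dataclasses.is_dataclass(obj):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, dict):
                return {k: enc(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [enc(v) for v in obj]
            return obj

        with open(path, "w") as fh:
            yaml.safe_dump(enc(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["metacommunity"] = MetacommunitySpec(**raw["metacommunity"])
        raw["popgen"] = PopgenConfig(**raw["popgen"])
        raw["priors"] = {
            k: PriorSpec(**{**v, "choices": tuple(v["choices"]) if v.get("choices") else None})
            for k, v in raw["priors"].items()
        }
        raw["models"] = tuple(raw["models"])
        return cls(**raw)


def _standard_priors(J_lo, J_hi, m_lo, m_hi) -> dict:
    return {
        "J": PriorSpec("uniform", lo=J_lo, hi=J_hi, integer=True),
        "m": PriorSpec("loguniform", lo=m_lo, hi=m_hi),
        "nu": PriorSpec("loguniform", lo=1e-4, hi=5e-3, zero_prob=0.25),
        "s_E": PriorSpec("loguniform", lo=0.001, hi=1.0),
        "beta_ratio": PriorSpec("loguniform", lo=1.0, hi=30.0),
        "alpha": PriorSpec("loguniform", lo=100.0, hi=5000.0),
        "lambda_target": PriorSpec("choice", choices=(0.25, 0.5, 0.75, 1.0)),
    }


def default_config(seed: int = 0, n_per_model: int = 10000) -> ExperimentConfig:
    """Full-scale batch configuration (wide prior ranges)."""
    return ExperimentConfig(
        metacommunity=MetacommunitySpec(n_species=200, seed=seed),
        priors=_standard_priors(500, 2000, 1e-4, 1e-2),
        n_per_model=n_per_model,
        max_generations=10000,
        seed=seed,
    )


def desk_config(seed: int = 0, n_per_model: int = 500) -> ExperimentConfig:
    """Desk-scale reproduction configuration (see docs/methods.md)."""
    return ExperimentConfig(
        metacommunity=MetacommunitySpec(n_species=200, seed=seed),
        priors=_standard_priors(500, 1000, 1e-3, 1e-2),
        n_per_model=n_per_model,
        max_generations=2500,
        seed=seed,
    )


def fixture_config(seed: int = 0, n_per_model: int = 20) -> ExperimentConfig:
    """Tiny deterministic bundle for tests and documentation examples."""
    cfg = ExperimentConfig(
        metacommunity=MetacommunitySpec(n_species=100, seed=seed),
        priors=_standard_priors(200, 200, 2e-3, 2e-2),
        n_per_model=n_per_model,
        max_generations=800,
        seed=seed,
    )
    return cfg


def _run_seed(master: int, tag: str, model: str, index: int) -> int:
    """Deterministic per-stage seed from the master seed and run identity."""
    tag_key = zlib.crc32(tag.encode())
    ss = np.random.SeedSequence(
        entropy=master, spawn_key=(tag_key, MODELS.index(model), index)
    )
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def params_from_draw(config: ExperimentConfig, model: str, index: int) -> SimulationParams:
    """Materialize one prior draw into SimulationParams (deterministic)."""
    rng = np.random.default_rng(_run_seed(config.seed, "prior", model, index))
    p = {k: spec.sample(rng) for k, spec in config.priors.items()}
    ratio = p.pop("beta_ratio", 1.0)
    return SimulationParams(
        J=int(p["J"]),
        m=float(p["m"]),
        nu=float(p["nu"]),
        s_E=float(p["s_E"]),
        beta_intra=float(ratio) if model == "beta" else 1.0,
        beta_inter=1.0,
        model=model,
        alpha=float(p.get("alpha", 1000.0)),
        lambda_target=float(p["lambda_target"]),
        max_generations=config.max_generations,
        snapshot_every=config.snapshot_every,
        seed=_run_seed(config.seed, "assembly", model, index),
    )


def sample_priors(
    config: ExperimentConfig, n: int | None = None, models=None
) -> pd.DataFrame:
    """The full draw table for a batch (one row per planned run)."""
    models = models or config.models
    n = n if n is not None else config.n_per_model
    rows = []
    for model in models:
        for i in range(n):
            sp = params_from_draw(config, model, i)
            rows.append(
                {
                    "model": model,
                    "run_index": i,
                    "J": sp.J,
                    "m": sp.m,
                    "nu": sp.nu,
                    "s_E": sp.s_E,
                    "beta_intra": sp.beta_intra,
                    "beta_inter": sp.beta_inter,
                    "alpha": sp.alpha,
                    "lambda_target": sp.lambda_target,
                    "seed": sp.seed,
                }
            )
    return pd.DataFrame(rows, columns=_PARAM_COLUMNS)


def run_one(config: ExperimentConfig, meta, model: str, index: int) -> pd.Series:
    """assembly -> popgen -> sumstats for a single draw; returns one row."""
    sp = params_from_draw(config, model, index)
    traj = run(sp, meta)
    pi_table = community_pi_vector(
        traj,
        sp,
        config.popgen,
        seed=_run_seed(config.seed, "popgen", model, index),
    )
    row = summarize(traj.final, pi_table, meta, lam=traj.final_lambda)
    row["model"] = model
    row["run_index"] = index
    for k in ("J", "m", "nu", "s_E", "beta_intra", "beta_inter", "alpha",
              "lambda_target", "seed"):
        row[f"param_{k}"] = getattr(sp, k)
    row["truncated"] = traj.truncated
    return row


def run_batch(
    config: ExperimentConfig,
    models=None,
    progress: bool = False,
) -> pd.DataFrame:
    """Run the whole batch and return the labeled summary-statistics table.

    With ``config.outdir`` set, per-run manifests (JSON) and rows (CSV) are
    persisted and completed runs are skipped on re-invocation (resumable).
    Individual run failures are logged and skipped; the batch raises only
    if more than 1% of runs fail.
    """
    models = models or config.models
    meta = generate_metacommunity(config.metacommunity)
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        (outdir / "runs").mkdir(parents=True, exist_ok=True)
        config.to_yaml(outdir / "config.yaml")

    rows, failures, total = [], [], 0
    iterator = [(mdl, i) for mdl in models for i in range(config.n_per_model)]
    if progress:
        from tqdm import tqdm

        iterator = tqdm(iterator)
    for model, i in iterator:
        total += 1
        manifest = outdir / "runs" / f"{model}_{i:05d}.json" if outdir else None
        if manifest is not None and manifest.exists():
            rows.append(pd.read_json(manifest, typ="series"))
            continue
        try:
            row = run_one(config, meta, model, i)
        except Exception as exc:  # noqa: BLE001 - batch isolation by design
            failures.append((model, i, repr(exc)))
            warnings.warn(f"run {model}/{i} failed: {exc!r}", RuntimeWarning,
                          stacklevel=2)
            continue
        rows.append(row)
        if manifest is not None:
            manifest.write_text(json.dumps(row.to_dict()))
    if total and len(failures) > 0.01 * total:
        raise RuntimeError(f"{len(failures)}/{total} runs failed: {failures[:5]}")
    table = pd.DataFrame(rows).reset_index(drop=True)
    if outdir:
        table.to_csv(outdir / "sumstats.tsv", sep="\t", index=False)
    return table


def make_fixtures(seed: int = 0, out: str | None = None, n_per_model: int = 20) -> pd.DataFrame:
    """Small deterministic dataset (5 models x ``n_per_model`` sims, J=200)."""
    cfg = fixture_config(seed=seed, n_per_model=n_per_model)
    cfg.outdir = out
    return run_batch(cfg)
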