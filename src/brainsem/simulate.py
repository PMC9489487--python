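"""Synthetic species-level data for the brain-size / body-size / third-trait system.

Two causal settings are generated, matching the two DAGs under study:

* **Case I** — absolute brain size is the *response*: body size and a third
  trait ``z`` both cause brain size.  A variant (``case1_confounded``) adds a
  direct path from body size to ``z``, so body size confounds the z -> brain
  relationship.
* **Case II** — *relative* brain size is a *predictor*: body size and relative
  brain size both cause ``z``, and absolute brain size is their (noise-free)
  sum — a collider between body size and relative brain size.

All variables live on a standardized log scale (mean 0, SD 1 for the
exogenous variables), so effect sizes are directly comparable across
scenarios.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "SimScenario",
    "Dataset",
    "simulate_case1",
    "simulate_case1_confounded",
    "simulate_case2",
    "make_replicates",
    "write_dataset",
    "read_dataset",
    "CASE_IDS",
]

CASE_IDS = ("case1", "case1_confounded", "case2")


class ScenarioError(ValueError):
    """Raised when a simulation scenario is internally inconsistent."""


@dataclass(frozen=True)
class SimScenario:
    """Complete generative specification of one simulation condition.

    Parameters
    ----------
    case_id
        One of ``case1`` (brain size as response), ``case1_confounded``
        (same, plus a body -> z path) or ``case2`` (relative brain size as
        predictor; brain size is a collider).
    n_species
        Species per replicate dataset.  Must be >= 3 so a regression with
        two predictors is estimable.
    n_replicates
        Number of independent replicate datasets.
    beta_body
        Allometric slope of brain size on body size.  In Case I it is the
        body-size coefficient of the brain-size mean; in Case II it scales
        the body-size component of the deterministic brain-size sum.
    beta_z
        Effect of ``z`` on brain size (Case I only).
    gamma_body
        Direct effect of body size on ``z`` (Case II, and the added
        confounding path in ``case1_confounded``).
    gamma_brain
        Effect of relative brain size on ``z`` (Case II only).
    sigma_brain
        Residual SD of brain size around its mean (Case I only; Case II
        brain size is an exact sum).
    sigma_z
        Residual SD of ``z`` (Case II and ``case1_confounded``).
    base_seed
        Root seed; every replicate derives its own independent stream from
        ``(base_seed, replicate_index)``.
    """

    case_id: str
    n_species: int = 100
    n_replicates: int = 20
    beta_body: float = 1.0
    beta_z: float = 1.0
    gamma_body: float = 1.0
    gamma_brain: float = 1.0
    sigma_brain: float = 1.0
    sigma_z: float = 1.0
    base_seed: int = 2022

    def __post_init__(self) -> None:
        if self.case_id not in CASE_IDS:
            raise ScenarioError(
                f"unknown case_id {self.case_id!r}; expected one of {CASE_IDS}"
            )
        if self.n_species < 3:
            raise ScenarioError("n_species must be >= 3 for a two-predictor regression")
        if self.n_replicates < 1:
            raise ScenarioError("n_replicates must be >= 1")
        if not self.sigma_brain > 0:
            raise ScenarioError("sigma_brain must be strictly positive")
        if not self.sigma_z > 0:
            raise ScenarioError("sigma_z must be strictly positive")

    def with_seed(self, base_seed: int) -> "SimScenario":
        return replace(self, base_seed=base_seed)


@dataclass
class Dataset:
    """One species table: log body size, log brain size and a third trait z.

    For simulated data, ``truth`` maps every parameter the evaluation layer
    scores to its generating value, and (Case II only) ``rel_true`` holds the
    latent relative brain size used in the construction.
    """

    body: np.ndarray
    brain: np.ndarray
    z: np.ndarray
    case_id: str
    replicate_index: int
    seed_used: int
    rel_true: Optional[np.ndarray] = None
    truth: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.body)
        if not (len(self.brain) == n and len(self.z) == n):
            raise ValueError("body, brain and z must have identical length")
        if self.rel_true is not None and len(self.rel_true) != n:
            raise ValueError("rel_true must match the trait vectors in length")

    @property
    def n(self) -> int:
        return len(self.body)

    def to_frame(self) -> pd.DataFrame:
        cols = {
            "species_index": np.arange(self.n),
            "body": self.body,
            "brain": self.brain,
            "z": self.z,
        }
        if self.rel_true is not None:
            cols["rel_true"] = self.rel_true
        return pd.DataFrame(cols)

    def column(self, name: str) -> np.ndarray:
        try:
            vec = getattr(self, name)
        except AttributeError:
            raise KeyError(f"dataset has no column {name!r}") from None
        if vec is None:
            raise KeyError(f"dataset has no column {name!r}")
        return np.asarray(vec)


def _replicate_rng(base_seed: int, replicate_index: int) -> tuple[np.random.Generator, int]:
    """Independent, reproducible stream for one replicate.

    Uses ``SeedSequence([base_seed, replicate_index])`` so streams never
    overlap across replicates and are stable across processes.
    """
    ss = np.random.SeedSequence([int(base_seed) & 0x7FFFFFFF, int(replicate_index)])
    seed_used = int(ss.generate_state(1)[0])
    return np.random.default_rng(ss), seed_used


def _check(scenario: SimScenario, expected_case: str, replicate_index: int) -> None:
    if scenario.case_id != expected_case:
        raise ScenarioError(
            f"scenario.case_id is {scenario.case_id!r}; this generator requires "
            f"{expected_case!r}"
        )
    if not 0 <= replicate_index < scenario.n_replicates:
        raise ScenarioError(
            f"replicate_index {replicate_index} outside [0, {scenario.n_replicates})"
        )


def simulate_case1(scenario: SimScenario, replicate_index: int = 0) -> Dataset:
    """Brain size as response: body ~ N(0,1), z ~ N(0,1) independent, and
    brain ~ N(beta_body*body + beta_z*z, sigma_brain)."""
    _check(scenario, "case1", replicate_index)
    rng, seed_used = _replicate_rng(scenario.base_seed, replicate_index)
    n = scenario.n_species
    body = rng.standard_normal(n)
    eps_z = rng.standard_normal(n)
    eps_brain = rng.standard_normal(n)
    z = eps_z
    brain = scenario.beta_body * body + scenario.beta_z * z + scenario.sigma_brain * eps_brain
    return Dataset(
        body=body,
        brain=brain,
        z=z,
        case_id="case1",
        replicate_index=replicate_index,
        seed_used=seed_used,
        truth={"beta_body": scenario.beta_body, "beta_z": scenario.beta_z},
    )


def simulate_case1_confounded(scenario: SimScenario, replicate_index: int = 0) -> Dataset:
    """Case I with an extra body -> z path: z ~ N(gamma_body*body, sigma_z).

    At gamma_body = 0 and sigma_z = 1 this reduces exactly to
    :func:`simulate_case1` (the noise draws occupy the same stream
    positions).
    """
    _check(scenario, "case1_confounded", replicate_index)
    rng, seed_used = _replicate_rng(scenario.base_seed, replicate_index)
    n = scenario.n_species
    body = rng.standard_normal(n)
    eps_z = rng.standard_normal(n)
    eps_brain = rng.standard_normal(n)
    z = scenario.gamma_body * body + scenario.sigma_z * eps_z
    brain = scenario.beta_body * body + scenario.beta_z * z + scenario.sigma_brain * eps_brain
    return Dataset(
        body=body,
        brain=brain,
        z=z,
        case_id="case1_confounded",
        replicate_index=replicate_index,
        seed_used=seed_used,
        truth={
            "beta_body": scenario.beta_body,
            "beta_z": scenario.beta_z,
            "gamma_body": scenario.gamma_body,
        },
    )


def simulate_case2(scenario: SimScenario, replicate_index: int = 0) -> Dataset:
    """Relative brain size as predictor; absolute brain size is a collider.

    body ~ N(0,1) and rel ~ N(0,1) are independent; brain is the exact sum
    beta_body*body + rel (no residual noise — absolute brain size is fully
    determined by allometry plus the extra brain tissue); and
    z ~ N(gamma_body*body + gamma_brain*rel, sigma_z).
    """
    _check(scenario, "case2", replicate_index)
    rng, seed_used = _replicate_rng(scenario.base_seed, replicate_index)
    n = scenario.n_species
    body = rng.standard_normal(n)
    rel = rng.standard_normal(n)
    eps_z = rng.standard_normal(n)
    brain = scenario.beta_body * body + rel
    # re-derive rel from the sum so the construction identity
    # brain - beta_body*body - rel == 0 holds exactly in float arithmetic
    rel = brain - scenario.beta_body * body
    z = scenario.gamma_body * body + scenario.gamma_brain * rel + scenario.sigma_z * eps_z
    return Dataset(
        body=body,
        brain=brain,
        z=z,
        case_id="case2",
        replicate_index=replicate_index,
        seed_used=seed_used,
        rel_true=rel,
        truth={
            "beta_body": scenario.beta_body,
            "gamma_body": scenario.gamma_body,
            "gamma_brain": scenario.gamma_brain,
        },
    )


_GENERATORS = {
    "case1": simulate_case1,
    "case1_confounded": simulate_case1_confounded,
    "case2": simulate_case2,
}


def simulate(scenario: SimScenario, replicate_index: int = 0) -> Dataset:
    """Dispatch to the generator matching ``scenario.case_id``."""
    return _GENERATORS[scenario.case_id](scenario, replicate_index)


def make_replicates(scenario: SimScenario) -> list[Dataset]:
    """All ``n_replicates`` datasets of a scenario, on mutually independent
    streams derived deterministically from ``(base_seed, replicate_index)``."""
    return [simulate(scenario, r) for r in range(scenario.n_replicates)]


def write_dataset(dataset: Dataset, directory: str | Path, stem: Optional[str] = None) -> Path:
    """Persist a dataset as CSV plus a JSON sidecar with truth and seed."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if stem is None:
        stem = f"{dataset.case_id}_rep{dataset.replicate_index:03d}"
    csv_path = directory / f"{stem}.csv"
    dataset.to_frame().to_csv(csv_path, index=False)
    meta = {
        "case_id": dataset.case_id,
        "replicate_index": dataset.replicate_index,
        "seed_used": dataset.seed_used,
        "truth": dataset.truth,
    }
    (directory / f"{stem}.meta.json").write_text(json.dumps(meta, indent=2))
    return csv_path


def read_dataset(csv_path: str | Path) -> Dataset:
    """Load a dataset written by :func:`write_dataset` (or any user table
    with ``body``, ``brain`` and ``z`` columns)."""
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    for col in ("body", "brain", "z"):
        if col not in df.columns:
            raise ValueError(f"{csv_path} is missing required column {col!r}")
    meta_path = csv_path.parent / (csv_path.stem + ".meta.json")
    meta = {}
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
    return Dataset(
        body=df["body"].to_numpy(float),
        brain=df["brain"].to_numpy(float),
        z=df["z"].to_numpy(float),
        rel_true=df["rel_true"].to_numpy(float) if "rel_true" in df.columns else None,
        case_id=meta.get("case_id", "user"),
        replicate_index=int(meta.get("replicate_index", 0)),
        seed_used=int(meta.get("seed_used", -1)),
        truth={k: float(v) for k, v in meta.get("truth", {}).items()},
    )
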