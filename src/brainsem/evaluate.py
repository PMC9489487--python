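"""Monte-Carlo evaluation: bias and coverage of each model over replicates.

For every replicate dataset the requested models are fitted and, for each
scored effect, the point estimate and its uncertainty are recorded:

* ``linear`` — OLS estimate and classical SE,
* ``bayes_linear`` — posterior mean and posterior SD of the slope,
* ``sem`` — posterior mean and posterior SD of the structural effect.

Bias is ``truth - estimate`` (the sign convention that makes the collider
scenario's body-size bias positive: an estimate of ~0 with a true effect of
1 is reported as bias ~ +1).  Coverage is the fraction of replicates where
the truth falls within the point estimate +/- 2 SE (frequentist) or +/- 2
posterior SD (Bayesian).

Scored effects per case:

* Case I (and the confounded variant): the ``body`` and ``z`` coefficients
  of the brain-size regression.
* Case II: the ``body`` and ``brain`` effects on ``z`` — for the linear
  models these are the slopes of body and absolute brain size; for the SEM
  they are ``gamma_body`` and ``gamma_brain``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import bayes, ols
from .simulate import Dataset, SimScenario, make_replicates

__all__ = [
    "ReplicateResult",
    "bias",
    "covered",
    "run_experiment",
    "summarize",
    "correlation_summary",
    "get_preset",
    "PRESETS",
    "MODELS_BY_CASE",
    "SCORED_PARAMETERS",
]

MODELS_BY_CASE = {
    "case1": ("linear", "bayes_linear"),
    "case1_confounded": ("linear", "bayes_linear"),
    "case2": ("linear", "bayes_linear", "sem"),
}

#: per case: (response, predictors, {scored label: (design column, truth key)})
_CASE_DESIGN = {
    "case1": ("brain", ("body", "z"), {"body": ("body", "beta_body"), "z": ("z", "beta_z")}),
    "case1_confounded": (
        "brain",
        ("body", "z"),
        {"body": ("body", "beta_body"), "z": ("z", "beta_z")},
    ),
    "case2": (
        "z",
        ("body", "brain"),
        {"body": ("body", "gamma_body"), "brain": ("brain", "gamma_brain")},
    ),
}

#: scored label -> SEM parameter name (Case II only)
_SEM_COLUMNS = {"body": "gamma_body", "brain": "gamma_brain"}

#: human-readable case labels used in summary tables
CASE_LABELS = {"case1": "Response", "case1_confounded": "Response", "case2": "Predictor"}

#: scored label -> posterior-draw column, per model (used by the report module)
SCORED_PARAMETERS = {
    ("case1", "bayes_linear"): {"body": "body", "z": "z"},
    ("case1_confounded", "bayes_linear"): {"body": "body", "z": "z"},
    ("case2", "bayes_linear"): {"body": "body", "brain": "brain"},
    ("case2", "sem"): {"body": "gamma_body", "brain": "gamma_brain"},
}


@dataclass
class ReplicateResult:
    """One scored effect from one model fit on one replicate."""

    case_id: str
    replicate_index: int
    model: str
    parameter: str
    point_estimate: float
    uncertainty: float
    truth: float
    diagnostics_ok: bool = True


def bias(point_estimate: float, truth: float) -> float:
    """Signed bias, ``truth - point_estimate``."""
    return truth - point_estimate


def covered(point_estimate: float, uncertainty: float, truth: float) -> bool:
    """Whether truth lies within the symmetric 2-SE/2-SD interval."""
    if not uncertainty > 0:
        raise ValueError("uncertainty must be strictly positive")
    return abs(truth - point_estimate) <= 2.0 * uncertainty


def correlation_summary(datasets: Sequence[Dataset]) -> float:
    """Mean over datasets of the sample Pearson correlation of body and
    absolute brain size."""
    if not datasets:
        raise ValueError("need at least one dataset")
    rs = []
    for ds in datasets:
        body, brain = np.asarray(ds.body), np.asarray(ds.brain)
        if body.std() == 0 or brain.std() == 0:
            raise ValueError("correlation undefined for zero-variance input")
        rs.append(float(np.corrcoef(body, brain)[0, 1]))
    return float(np.mean(rs))


def _fit_one(
    model: str,
    ds: Dataset,
    response: str,
    predictors: tuple[str, ...],
    scored: dict[str, tuple[str, str]],
    priors: bayes.PriorSpec,
    sampler: bayes.SamplerConfig,
) -> tuple[list[ReplicateResult], Optional[bayes.PosteriorFit]]:
    """Fit one model to one replicate and score the case-relevant effects."""
    results: list[ReplicateResult] = []
    fit_obj: Optional[bayes.PosteriorFit] = None
    # each replicate/model pair gets its own sampler stream
    rep_sampler = bayes.SamplerConfig(
        n_chains=sampler.n_chains,
        n_warmup=sampler.n_warmup,
        n_sampling=sampler.n_sampling,
        target_acceptance=sampler.target_acceptance,
        base_seed=int(
            np.random.SeedSequence(
                [sampler.base_seed & 0x7FFFFFFF, ds.replicate_index,
                 {"bayes_linear": 1, "sem": 2}.get(model, 0)]
            ).generate_state(1)[0]
            & 0x7FFFFFFF
        ),
    )
    if model == "linear":
        fit = ols.fit_linear(ds.column(response), {p: ds.column(p) for p in predictors})
        for label, (col, truth_key) in scored.items():
            results.append(
                ReplicateResult(
                    case_id=ds.case_id,
                    replicate_index=ds.replicate_index,
                    model=model,
                    parameter=label,
                    point_estimate=fit.estimate(col),
                    uncertainty=fit.se(col),
                    truth=ds.truth[truth_key],
                )
            )
    elif model == "bayes_linear":
        fit_obj = bayes.fit_bayes_linear(
            ds, response=response, predictors=predictors,
            priors=priors, sampler=rep_sampler,
        )
        for label, (col, truth_key) in scored.items():
            results.append(
                ReplicateResult(
                    case_id=ds.case_id,
                    replicate_index=ds.replicate_index,
                    model=model,
                    parameter=label,
                    point_estimate=fit_obj.mean(col),
                    uncertainty=fit_obj.sd(col),
                    truth=ds.truth[truth_key],
                    diagnostics_ok=fit_obj.diagnostics.ok,
                )
            )
    elif model == "sem":
        fit_obj = bayes.fit_sem(ds, priors=priors, sampler=rep_sampler)
        for label, (_, truth_key) in scored.items():
            name = _SEM_COLUMNS[label]
            results.append(
                ReplicateResult(
                    case_id=ds.case_id,
                    replicate_index=ds.replicate_index,
                    model=model,
                    parameter=label,
                    point_estimate=fit_obj.mean(name),
                    uncertainty=fit_obj.sd(name),
                    truth=ds.truth[truth_key],
                    diagnostics_ok=fit_obj.diagnostics.ok,
                )
            )
    else:
        raise ValueError(f"unknown model {model!r}")
    return results, fit_obj


def run_experiment(
    scenario: SimScenario,
    models: Optional[Sequence[str]] = None,
    priors: Optional[bayes.PriorSpec] = None,
    sampler: Optional[bayes.SamplerConfig] = None,
    out_dir: Optional[str | Path] = None,
    log_name: str = "run_log.txt",
) -> tuple[list[ReplicateResult], pd.DataFrame]:
    """Fit every requested model to every replicate of a scenario and
    aggregate bias/coverage per (case, parameter, model).

    A model that fails outright on a replicate is logged and excluded from
    that model's summary (the per-row replicate count ``n_replicates``
    reflects the exclusion); it is never silently imputed.
    """
    priors = priors or bayes.PriorSpec.default()
    sampler = sampler or bayes.SamplerConfig()
    if models is None:
        models = MODELS_BY_CASE[scenario.case_id]
    response, predictors, scored = _CASE_DESIGN[scenario.case_id]
    datasets = make_replicates(scenario)

    results: list[ReplicateResult] = []
    log_lines: list[str] = []
    draw_frames: dict[tuple[str, str, int], pd.DataFrame] = {}
    for ds in datasets:
        for model in models:
            try:
                rows, fit_obj = _fit_one(
                    model, ds, response, predictors, scored, priors, sampler
                )
            except Exception as exc:  # noqa: BLE001 - recorded, never imputed
                log_lines.append(
                    f"FAILED case={ds.case_id} rep={ds.replicate_index} "
                    f"model={model}: {exc!r}"
                )
                continue
            results.extend(rows)
            if fit_obj is not None:
                d = fit_obj.diagnostics
                log_lines.append(
                    f"case={ds.case_id} rep={ds.replicate_index} model={model} "
                    f"max_rhat={d.max_rhat:.4f} min_ess={d.min_ess:.0f} "
                    f"divergent={sum(d.n_divergent)} retried={d.retried} "
                    f"converged={d.converged}"
                )
                if not d.ok:
                    log_lines.append(
                        f"DIAGNOSTIC ISSUE case={ds.case_id} rep={ds.replicate_index} "
                        f"model={model}: {'; '.join(d.messages) or 'see diagnostics'}"
                    )
                if out_dir is not None:
                    draw_frames[(ds.case_id, model, ds.replicate_index)] = pd.DataFrame(
                        fit_obj.draws, columns=list(fit_obj.parameter_names)
                    )

    summary = summarize(results)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        replicates_to_frame(results).to_csv(out / "replicates.csv", index=False)
        summary.to_csv(out / "summary.csv", index=False)
        (out / log_name).write_text("\n".join(log_lines) + "\n")
        draws_dir = out / "draws"
        draws_dir.mkdir(exist_ok=True)
        for (case_id, model, rep), frame in draw_frames.items():
            frame.to_csv(draws_dir / f"{case_id}_{model}_rep{rep:03d}.csv", index=False)
    return results, summary


def replicates_to_frame(results: Sequence[ReplicateResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "case_id": [r.case_id for r in results],
            "replicate_index": [r.replicate_index for r in results],
            "model": [r.model for r in results],
            "parameter": [r.parameter for r in results],
            "point_estimate": [r.point_estimate for r in results],
            "uncertainty": [r.uncertainty for r in results],
            "truth": [r.truth for r in results],
            "diagnostics_ok": [r.diagnostics_ok for r in results],
        }
    )


def summarize(results: Sequence[ReplicateResult] | pd.DataFrame) -> pd.DataFrame:
    """Table-1-shaped summary: mean bias, SD of bias and coverage per
    (case, parameter, model).  A pure function of the replicate rows —
    recomputing it from the persisted CSV reproduces it exactly."""
    df = results if isinstance(results, pd.DataFrame) else replicates_to_frame(results)
    if df.empty:
        return pd.DataFrame(
            columns=["case", "parameter", "model", "mean_bias", "sd_bias",
                     "coverage", "n_replicates"]
        )
    df = df.assign(
        bias=df["truth"] - df["point_estimate"],
        covered=(np.abs(df["truth"] - df["point_estimate"]) <= 2.0 * df["uncertainty"]),
    )
    rows = []
    model_order = {"linear": 0, "bayes_linear": 1, "sem": 2}
    for (case_id, parameter, model), grp in df.groupby(
        ["case_id", "parameter", "model"], sort=False
    ):
        rows.append(
            {
                "case": CASE_LABELS.get(case_id, case_id),
                "case_id": case_id,
                "parameter": parameter,
                "model": model,
                "mean_bias": float(grp["bias"].mean()),
                "sd_bias": float(grp["bias"].std(ddof=1)) if len(grp) > 1 else 0.0,
                "coverage": float(grp["covered"].mean()),
                "n_replicates": int(len(grp)),
            }
        )
    rows.sort(
        key=lambda r: (r["case_id"], r["parameter"], model_order.get(r["model"], 9))
    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# named experiment presets (main grid + sensitivity analyses)


def _table1(seed: int):
    return [
        (SimScenario("case1", base_seed=seed), bayes.PriorSpec.default()),
        (SimScenario("case2", base_seed=seed), bayes.PriorSpec.default()),
    ]


def _appendix_n(n: int):
    def build(seed: int):
        return [
            (SimScenario("case1", n_species=n, base_seed=seed), bayes.PriorSpec.default()),
            (SimScenario("case2", n_species=n, base_seed=seed), bayes.PriorSpec.default()),
        ]

    return build


PRESETS = {
    "table1": _table1,
    "appendix-n20": _appendix_n(20),
    "appendix-n1000": _appendix_n(1000),
    "appendix-vague": lambda seed: [
        (SimScenario("case2", base_seed=seed), bayes.PriorSpec.vague())
    ],
    "appendix-informative": lambda seed: [
        (SimScenario("case2", base_seed=seed), bayes.PriorSpec.informative(1.0))
    ],
    "appendix-strong-body": lambda seed: [
        (
            SimScenario("case2", gamma_body=2.0, gamma_brain=0.5, base_seed=seed),
            bayes.PriorSpec.default(),
        )
    ],
    "appendix-strong-brain": lambda seed: [
        (
            SimScenario("case2", gamma_body=0.5, gamma_brain=2.0, base_seed=seed),
            bayes.PriorSpec.default(),
        )
    ],
    "appendix-case1-confounded": lambda seed: [
        (SimScenario("case1_confounded", base_seed=seed), bayes.PriorSpec.default())
    ],
}


def get_preset(name: str, seed: int = 2022) -> list[tuple[SimScenario, bayes.PriorSpec]]:
    """Scenario/prior jobs for a named experiment preset."""
    try:
        builder = PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; available: {', '.join(sorted(PRESETS))}"
        ) from None
    return builder(seed)


def run_preset(
    name: str,
    seed: int = 2022,
    sampler: Optional[bayes.SamplerConfig] = None,
    out_dir: Optional[str | Path] = None,
) -> tuple[list[ReplicateResult], pd.DataFrame]:
    """Run every job of a preset and concatenate results and summaries."""
    sampler = sampler or bayes.SamplerConfig(base_seed=seed)
    all_results: list[ReplicateResult] = []
    log_names: list[str] = []
    for scenario, priors in get_preset(name, seed):
        log_names.append(f"run_log_{scenario.case_id}.txt")
        res, _ = run_experiment(
            scenario, priors=priors, sampler=sampler, out_dir=out_dir,
            log_name=log_names[-1],
        )
        all_results.extend(res)
    summary = summarize(all_results)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        replicates_to_frame(all_results).to_csv(out / "replicates.csv", index=False)
        summary.to_csv(out / "summary.csv", index=False)
        parts = []
        for ln in log_names:
            part = out / ln
            if part.exists():
                parts.append(part.read_text())
                part.unlink()
        (out / "run_log.txt").write_text("".join(parts))
    return all_results, summary
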