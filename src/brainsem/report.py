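"""Density-strip figures comparing per-replicate estimates across models.

One panel per scored effect.  Within a panel, every replicate contributes
one density per fitted model: the frequentist fit is drawn as a
Normal(estimate, SE) curve; Bayesian fits are kernel density estimates of
their posterior draws.  A dashed vertical line marks the true value, so the
collider bias of the linear models in the predictor case is visible as a
cloud of densities away from the line.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy import stats

from .evaluate import SCORED_PARAMETERS

__all__ = ["FigureSpec", "render_estimates_figure"]

_MODEL_STYLE = {
    "linear": ("tab:orange", "Linear"),
    "bayes_linear": ("tab:purple", "Bayesian linear"),
    "sem": ("tab:green", "SEM"),
}


@dataclass
class FigureSpec:
    """What to draw and from where.

    ``experiment_dir`` must contain ``replicates.csv`` and, for Bayesian
    models, a ``draws/`` directory with one CSV of posterior draws per
    replicate (as written by ``run_experiment(..., out_dir=...)``).
    """

    experiment_dir: Path
    parameters_to_show: Optional[Sequence[str]] = None
    output_format: str = "png"
    case_id: Optional[str] = None  # restrict to one case when a dir holds several
    grid_points: int = 301

    def __post_init__(self) -> None:
        self.experiment_dir = Path(self.experiment_dir)
        if self.output_format not in ("png", "pdf", "svg"):
            raise ValueError("output_format must be png, pdf or svg")


def _posterior_draws(
    spec: FigureSpec, case_id: str, model: str, replicate: int, column: str
) -> np.ndarray:
    path = spec.experiment_dir / "draws" / f"{case_id}_{model}_rep{replicate:03d}.csv"
    if not path.exists():
        raise FileNotFoundError(
            f"posterior draws for model {model!r}, replicate {replicate} not found: {path}"
        )
    frame = pd.read_csv(path)
    return frame[column].to_numpy()


def render_estimates_figure(spec: FigureSpec, out_path: str | Path) -> Path:
    """Render the per-replicate estimate densities to ``out_path``.

    Deterministic given the files on disk.  Raises if the experiment
    directory is empty or posterior draw files are missing.
    """
    rep_path = spec.experiment_dir / "replicates.csv"
    if not rep_path.exists():
        raise FileNotFoundError(f"no replicates.csv in {spec.experiment_dir}")
    df = pd.read_csv(rep_path)
    if df.empty:
        raise ValueError(f"{rep_path} holds no replicate results; nothing to draw")
    if spec.case_id is not None:
        df = df[df["case_id"] == spec.case_id]
        if df.empty:
            raise ValueError(f"no rows for case {spec.case_id!r} in {rep_path}")

    params = list(spec.parameters_to_show or sorted(df["parameter"].unique()))
    fig, axes = plt.subplots(
        1, len(params), figsize=(4.5 * len(params), 3.5), squeeze=False
    )
    for ax, param in zip(axes[0], params):
        sub = df[df["parameter"] == param]
        if sub.empty:
            raise ValueError(f"parameter {param!r} not present in {rep_path}")
        lo = float((sub["point_estimate"] - 4 * sub["uncertainty"]).min())
        hi = float((sub["point_estimate"] + 4 * sub["uncertainty"]).max())
        truth = float(sub["truth"].iloc[0])
        lo, hi = min(lo, truth - 0.5), max(hi, truth + 0.5)
        grid = np.linspace(lo, hi, spec.grid_points)
        for row in sub.itertuples():
            color, _ = _MODEL_STYLE.get(row.model, ("gray", row.model))
            if row.model == "linear":
                dens = stats.norm.pdf(grid, row.point_estimate, row.uncertainty)
            else:
                column = SCORED_PARAMETERS[(row.case_id, row.model)][param]
                draws = _posterior_draws(
                    spec, row.case_id, row.model, row.replicate_index, column
                )
                dens = stats.gaussian_kde(draws)(grid)
            ax.plot(grid, dens, color=color, alpha=0.35, linewidth=0.9)
        ax.axvline(truth, color="gray", linestyle="--", linewidth=1.2)
        ax.set_xlabel(f"{param} effect")
        ax.set_ylabel("density")
        ax.set_title(param)
    handles = [
        plt.Line2D([], [], color=c, label=lab)
        for m, (c, lab) in _MODEL_STYLE.items()
        if m in set(df["model"])
    ]
    if handles:
        axes[0][-1].legend(handles=handles, frameon=False, fontsize=8)
    fig.tight_layout()
    out_path = Path(out_path).with_suffix(f".{spec.output_format}")
    out_path.parent.mkdir(parents=True, exist_ok=True)
    save_kwargs: dict = {"format": spec.output_format, "dpi": 150}
    if spec.output_format == "svg":
        # fixed hash salt + no timestamp -> byte-stable vector output
        matplotlib.rcParams["svg.hashsalt"] = "brainsem"
        save_kwargs["metadata"] = {"Date": None}
    fig.savefig(out_path, **save_kwargs)
    plt.close(fig)
    return out_path
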