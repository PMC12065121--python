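"""Figures and machine-readable reports for completed experiments."""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import seaborn as sns

from .errors import ValidationError
from .parsimony import classification_summary, records_to_frame
from .prediction import SweepResult, aggregate_importances


def plot_accuracy_sweep(result: SweepResult, path) -> dict:
    """Accuracy-vs-perturbation scatter with the fitted OLS line.

    A companion JSON with the regression summary is written next to the
    figure.  With a single level the line is omitted and a warning logged.
    """
    frame = result.runs_frame()
    fig, ax = plt.subplots(figsize=(7, 4.5))
    sns.scatterplot(
        data=frame, x="level", y="accuracy", ax=ax, s=14, alpha=0.55,
        edgecolor="none", color="#2b6cb0",
    )
    payload = {"regression": result.regression,
               "n_runs": len(result.runs),
               "levels": result.levels,
               "replicates": result.replicates}
    if result.regression:
        xs = np.linspace(min(result.levels), max(result.levels), 50)
        reg = result.regression
        ax.plot(xs, reg["intercept"] + reg["slope"] * xs, color="#c53030",
                lw=1.5)
        ax.set_title(
            f"Accuracy vs. label perturbation "
            f"(R² = {reg['r_squared']:.3f}, slope = {reg['slope']:.3f})"
        )
    else:
        warnings.warn("single-level sweep: no regression line drawn",
                      stacklevel=2)
        ax.set_title("Accuracy vs. label perturbation")
    ax.set_xlabel("perturbation level p")
    ax.set_ylabel("validation accuracy")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    json_path = Path(path).with_suffix(".json")
    with open(json_path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")
    return {"figure": str(path), "json": str(json_path)}


def plot_importances(
    result: SweepResult, level: float, path, top_n: int = 15
) -> dict:
    """Horizontal bars of the top mean importances at one level."""
    table = aggregate_importances(result, level, top_n=top_n)
    fig, ax = plt.subplots(figsize=(7, 0.35 * len(table) + 1.2))
    ax.barh(table["column"][::-1], table["mean_importance"][::-1],
            color="#2f855a")
    ax.set_xlabel("mean impurity-based importance")
    ax.set_title(f"Top attributes at perturbation level {level:.0%}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    json_path = Path(path).with_suffix(".json")
    table.to_json(json_path, orient="records", indent=1)
    return {"figure": str(path), "json": str(json_path)}


def render_report(
    result: SweepResult,
    out_dir,
    records=None,
    comparison: tuple[int, int, int] | None = None,
    importance_levels=(0.0, 0.5, 1.0),
    top_n: int = 15,
) -> dict:
    """Full report bundle: figures, JSON summaries and tables.

    ``records`` (transformation records) and ``comparison`` (shared,
    only_a, only_b clade counts) are optional; when given they are
    summarized alongside the sweep outputs.  Zero counts are reported
    explicitly, never omitted.
    """
    if not result.runs:
        raise ValidationError("cannot report an empty sweep")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts = {
        "accuracy": plot_accuracy_sweep(result, out / "accuracy_sweep.png")
    }
    available = {round(lv, 2) for lv in result.levels}
    for level in importance_levels:
        if round(level, 2) not in available:
            continue
        artifacts[f"importances_p{int(round(level * 100))}"] = (
            plot_importances(
                result, level,
                out / f"importances_p{int(round(level * 100))}.png",
                top_n=top_n,
            )
        )
    if records is not None:
        records = list(records)
        records_to_frame(records).to_csv(
            out / "transformations.csv", index=False
        )
        with open(out / "transformation_summary.json", "w",
                  encoding="utf-8") as fh:
            json.dump(classification_summary(records), fh, indent=1)
            fh.write("\n")
        artifacts["transformations"] = str(out / "transformations.csv")
    if comparison is not None:
        shared, only_a, only_b = comparison
        with open(out / "tree_comparison.json", "w", encoding="utf-8") as fh:
            json.dump(
                {"shared": shared, "only_a": only_a, "only_b": only_b},
                fh, indent=1,
            )
            fh.write("\n")
        artifacts["comparison"] = str(out / "tree_comparison.json")
    return artifacts
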