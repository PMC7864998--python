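"""Result surfaces: heatmap tables, boxplots, MDS plots, the per-scan
"neural recording" heatmap, and the end-to-end pipeline driver.

Every figure has a value-identical CSV twin; the CSVs (and the summary
JSON) are the contract, figures are decoration.  Re-running with the
same inputs and seed produces byte-identical CSV/JSON output.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .embedding import Embedding2D, mds_embed
from .exceptions import ValidationError
from .labelmaps import GradingEnsemble
from .metrics import (
    COMPARTMENT_SCOPES,
    DistanceTable,
    MeanDistanceMatrix,
    Scope,
    build_distance_table,
    fraction_model_closer,
    mean_distance_matrix,
)
from .stats import (
    BoxplotSummary,
    PermutationResult,
    assemble_groups,
    boxplot_summary,
    mc_permutation_test,
)

__all__ = ["ReportBundle", "heatmap_table", "neural_recording", "run_trex"]

logger = logging.getLogger("trex")

ALL_SCOPES = (Scope.ALL, *COMPARTMENT_SCOPES)


@dataclass
class ReportBundle:
    """All computed result surfaces of one pipeline run."""

    table: DistanceTable
    heatmap_tables: dict[Scope, MeanDistanceMatrix]
    neural_recording: pd.DataFrame
    boxplot_stats: dict[tuple[tuple[str, str], Scope], BoxplotSummary]
    embeddings: dict[Scope, Embedding2D]
    permutation_results: dict[Scope, PermutationResult] = field(default_factory=dict)
    summary: dict = field(default_factory=dict)


def heatmap_table(
    table: DistanceTable, scopes: Sequence[Scope] = ALL_SCOPES
) -> dict[Scope, MeanDistanceMatrix]:
    """Mean-distance matrices for every scope (the Hamming heatmap table)."""
    return {scope: mean_distance_matrix(table, scope) for scope in scopes}


def _ordered_pairs(
    table: DistanceTable, model_id: str | None
) -> list[tuple[str, str]]:
    """Inter-grader pairs first, then grader-model pairs, stable order."""
    pairs = table.pairs
    if model_id is None:
        return pairs
    inter = [p for p in pairs if model_id not in p]
    versus = [p for p in pairs if model_id in p]
    return inter + versus


def neural_recording(
    table: DistanceTable,
    scan_order: Sequence[str] | None = None,
    eye_of_scan: Mapping[str, str] | None = None,
    model_id: str | None = None,
) -> pd.DataFrame:
    """The per-scan recording grid: one row per grading pair (inter-grader
    rows above grader-model rows), one column per scan in stated order."""
    pairs = _ordered_pairs(table, model_id)
    if scan_order is None:
        scan_order = table.scan_ids
    if eye_of_scan is not None:
        # stable grouping by eye, preserving within-eye order
        order: dict[str, list[str]] = {}
        for s in scan_order:
            order.setdefault(str(eye_of_scan.get(s, "")), []).append(s)
        scan_order = [s for scans in order.values() for s in scans]
    rows = {}
    for pair in pairs:
        series = table.select(Scope.ALL, pair).set_index("scan_id")["distance"]
        missing = [s for s in scan_order if s not in series.index]
        if missing:
            raise ValidationError(
                f"missing scope-all records for pair {pair}, scans {missing[:5]}"
            )
        rows["-".join(pair)] = [float(series[s]) for s in scan_order]
    return pd.DataFrame(rows, index=list(scan_order)).T


def _percent_formatted(matrix: MeanDistanceMatrix) -> pd.DataFrame:
    return matrix.to_frame(percent=True).round(2)


def _write_heatmap_figure(
    matrices: dict[Scope, MeanDistanceMatrix], path: Path
) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(matrices), figsize=(4 * len(matrices), 3.6))
    axes = np.atleast_1d(axes)
    for ax, (scope, matrix) in zip(axes, matrices.items()):
        pct = matrix.as_percent()
        vmax = max(np.percentile(pct, 99), 1e-9)
        im = ax.imshow(pct, cmap="RdYlGn_r", vmin=0.0, vmax=vmax)
        ax.set_xticks(range(len(matrix.ids)), matrix.ids)
        ax.set_yticks(range(len(matrix.ids)), matrix.ids)
        ax.set_title(scope.value)
        for i in range(len(matrix.ids)):
            for j in range(len(matrix.ids)):
                ax.text(j, i, f"{pct[i, j]:.2f}", ha="center", va="center", fontsize=7)
        fig.colorbar(im, ax=ax, shrink=0.8)
    fig.suptitle("Mean Hamming distance (%)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _write_recording_figure(
    grid: pd.DataFrame,
    path: Path,
    n_inter_pairs: int,
    eye_of_scan: Mapping[str, str] | None,
) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    values = grid.to_numpy()
    vmax = max(np.percentile(values, 99), 1e-9)
    fig, ax = plt.subplots(figsize=(max(6, values.shape[1] / 12), 3.2))
    im = ax.imshow(values, aspect="auto", cmap="RdYlGn_r", vmin=0.0, vmax=vmax)
    ax.set_yticks(range(len(grid.index)), grid.index)
    ax.set_xlabel("scan")
    if 0 < n_inter_pairs < values.shape[0]:
        ax.axhline(n_inter_pairs - 0.5, color="black", linewidth=1.5)
    if eye_of_scan is not None:
        eyes = [str(eye_of_scan.get(s, "")) for s in grid.columns]
        for idx in range(1, len(eyes)):
            if eyes[idx] != eyes[idx - 1]:
                ax.axvline(idx - 0.5, color="black", linewidth=0.8)
    fig.colorbar(im, ax=ax, label="Hamming distance")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _write_boxplot_figure(
    table: DistanceTable, pairs: list[tuple[str, str]], path: Path
) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(ALL_SCOPES), figsize=(3.2 * len(ALL_SCOPES), 3.4))
    for ax, scope in zip(np.atleast_1d(axes), ALL_SCOPES):
        data = [
            table.select(scope, pair)["distance"].to_numpy() * 100 for pair in pairs
        ]
        ax.boxplot(data, tick_labels=["-".join(p) for p in pairs], whis=1.5,
                   showmeans=True)
        ax.set_title(scope.value)
        ax.set_ylabel("Hamming distance (%)")
        ax.tick_params(axis="x", rotation=60, labelsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _write_embedding_figure(embeddings: dict[Scope, Embedding2D], path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(embeddings), figsize=(3.4 * len(embeddings), 3.4))
    for ax, (scope, emb) in zip(np.atleast_1d(axes), embeddings.items()):
        ax.scatter(emb.coords[:, 0], emb.coords[:, 1])
        for gid, (x, y) in zip(emb.ids, emb.coords):
            ax.annotate(gid, (x, y), textcoords="offset points", xytext=(4, 4))
        ax.set_title(f"{scope.value} (stress {emb.stress:.3g})")
        ax.set_aspect("equal")
    fig.suptitle("Metric MDS of mean Hamming distances (axes unitless)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_trex(
    ensemble: GradingEnsemble,
    out_dir: str | Path | None = None,
    n_resamples: int = 99_999,
    seed: int = 0,
    eye_of_scan: Mapping[str, str] | None = None,
    figures: bool = True,
) -> ReportBundle:
    """Run the full pipeline on a grading ensemble.

    Stages: pairwise distance table (all scopes) → heatmap tables →
    per-scan recording → boxplot summaries → MDS embeddings → permutation
    tests (inter-grader vs grader-model; skipped with a notice when the
    ensemble has no model or fewer than two graders).  Writes CSV/JSON
    artifacts (and figures) into ``out_dir`` when given.
    """
    ensemble.require_complete()
    if ensemble.any_empty_compartment():
        warnings.warn(
            "some label maps lack one of the four compartments; the study's "
            "inclusion criteria require all four to be visible",
            stacklevel=2,
        )
    model_id = ensemble.model_id
    grader_ids = ensemble.grader_ids if model_id is None else ensemble.grader_ids

    logger.info("stage distances: %d scans, gradings %s", len(ensemble.scan_ids),
                ensemble.grading_ids)
    table = build_distance_table(ensemble)
    matrices = heatmap_table(table)
    grid = neural_recording(table, eye_of_scan=eye_of_scan, model_id=model_id)
    pairs = _ordered_pairs(table, model_id)
    box = {
        (pair, scope): boxplot_summary(table.select(scope, pair)["distance"])
        for pair in pairs
        for scope in ALL_SCOPES
    }
    logger.info("stage embedding")
    embeddings = {scope: mds_embed(matrices[scope], seed=seed) for scope in ALL_SCOPES}

    perm: dict[Scope, PermutationResult] = {}
    frac = None
    notice = None
    if model_id is not None and len(grader_ids) >= 2:
        logger.info("stage permutation: %d resamples", n_resamples)
        for scope in ALL_SCOPES:
            groups = assemble_groups(table, grader_ids, model_id, scope)
            perm[scope] = mc_permutation_test(groups, n_resamples=n_resamples, seed=seed)
        if len(grader_ids) >= 2:
            frac = fraction_model_closer(table, grader_ids, model_id)
    else:
        notice = (
            "permutation stage skipped: needs a model grading and at least "
            "two graders"
        )
        logger.info(notice)

    inter_pairs = [p for p in pairs if model_id is None or model_id not in p]
    versus_pairs = [p for p in pairs if model_id is not None and model_id in p]
    summary: dict = {
        "n_scans": len(ensemble.scan_ids),
        "grader_ids": list(grader_ids),
        "model_id": model_id,
        "seed": seed,
        "overall_mean_intergrader_pct": _pooled_mean_pct(table, inter_pairs),
        "overall_mean_grader_model_pct": _pooled_mean_pct(table, versus_pairs),
        "per_compartment_mean_pct": {
            scope.value: _pooled_mean_pct(table, inter_pairs, scope)
            for scope in COMPARTMENT_SCOPES
        },
        "fraction_model_closer": frac,
        "p_two_sided": {s.value: r.p_two_sided for s, r in perm.items()} or None,
    }
    if notice:
        summary["notice"] = notice

    bundle = ReportBundle(
        table=table,
        heatmap_tables=matrices,
        neural_recording=grid,
        boxplot_stats=box,
        embeddings=embeddings,
        permutation_results=perm,
        summary=summary,
    )
    if out_dir is not None:
        write_bundle(bundle, Path(out_dir), eye_of_scan=eye_of_scan, figures=figures)
    return bundle


def _pooled_mean_pct(
    table: DistanceTable,
    pairs: list[tuple[str, str]],
    scope: Scope = Scope.ALL,
) -> float | None:
    if not pairs:
        return None
    values = np.concatenate(
        [table.select(scope, pair)["distance"].to_numpy() for pair in pairs]
    )
    return float(values.mean() * 100.0)


def write_bundle(
    bundle: ReportBundle,
    out_dir: Path,
    eye_of_scan: Mapping[str, str] | None = None,
    figures: bool = True,
) -> None:
    """Write all bundle components as CSV/JSON (and optional figures)."""
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle.table.to_csv(out_dir / "distances.csv")
    for scope, matrix in bundle.heatmap_tables.items():
        _percent_formatted(matrix).to_csv(
            out_dir / f"mean_distance_{scope.value}_pct.csv", index_label="grading_id"
        )
    bundle.neural_recording.to_csv(out_dir / "neural_recording.csv", index_label="pair")
    box_rows = [
        {
            "pair": "-".join(pair),
            "scope": scope.value,
            "q1": s.q1,
            "median": s.median,
            "q3": s.q3,
            "mean": s.mean,
            "lower_whisker": s.lower_whisker,
            "upper_whisker": s.upper_whisker,
            "n_outliers": len(s.outliers),
        }
        for (pair, scope), s in bundle.boxplot_stats.items()
    ]
    pd.DataFrame(box_rows).to_csv(out_dir / "boxplot_stats.csv", index=False)
    for scope, emb in bundle.embeddings.items():
        emb.to_csv(out_dir / f"mds_{scope.value}.csv")
    if bundle.permutation_results:
        payload = {s.value: r.to_dict() for s, r in bundle.permutation_results.items()}
        (out_dir / "permutation.json").write_text(
            json.dumps(payload, indent=2, sort_keys=True) + "\n"
        )
    (out_dir / "summary.json").write_text(
        json.dumps(bundle.summary, indent=2, sort_keys=True) + "\n"
    )
    if figures:
        model_id = bundle.summary.get("model_id")
        pairs = _ordered_pairs(bundle.table, model_id)
        n_inter = len([p for p in pairs if model_id is None or model_id not in p])
        _write_heatmap_figure(bundle.heatmap_tables, out_dir / "heatmap_table.png")
        _write_recording_figure(
            bundle.neural_recording, out_dir / "neural_recording.png", n_inter,
            eye_of_scan,
        )
        _write_boxplot_figure(bundle.table, pairs, out_dir / "boxplots.png")
        _write_embedding_figure(bundle.embeddings, out_dir / "mds.png")
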