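"""End-to-end evaluation runs: config, report bundle, curves, plots.

`run_evaluation` ties the readers, similarity, SALI curve and metric layers
into one reproducible run: it writes a model-comparison table (metrics as
rows, models as columns), per-model curve CSVs, a SALI histogram and a
manifest capturing every option and seed, then ranks the models by SCI with
S(0)/S(1) tie-breakers. Reruns with the same config are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import SaliCurve, sali_curve, sali_histogram, sali_matrix
from .errors import ConfigurationError, SaliError, ValidationError
from .io import (
    ActivityTable,
    read_activity_table,
    read_similarity_matrix,
    read_structures,
)
from .metrics import STATISTICS, ModelEvaluation, evaluate_model
from .similarity import FingerprintParams, SimilarityMatrix, similarity_from_structures

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything needed to reproduce one evaluation run."""

    activities: str
    similarity: str  # "matrix:<path>" or a structures file for fingerprints
    out_dir: str = "sali_run"
    models: list[str] | None = None  # None = all prediction columns
    transform: str = "none"  # none | log10
    method: str = "exact"
    step: float = 0.01
    reference_max: float | None = None
    n_bins: int = 20
    seed: int = 0
    fingerprint: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "activities" not in raw or "similarity" not in raw:
            raise ConfigurationError("config must set 'activities' and 'similarity'")
        return cls(**raw)


@dataclass
class ReportBundle:
    evaluations: list[ModelEvaluation]
    curves: dict[str, SaliCurve]
    ranking: list[str]
    out_dir: Path


def _load_similarity(config: RunConfig, ids: list[str]) -> tuple[SimilarityMatrix, list[str]]:
    """Return the similarity matrix restricted to ids, plus the usable ids."""
    src = config.similarity
    if src.startswith("matrix:"):
        sim = read_similarity_matrix(src[len("matrix:"):])
    else:
        records = read_structures(src)
        params = FingerprintParams(**config.fingerprint) if config.fingerprint else FingerprintParams()
        sim = similarity_from_structures(records, params)
    usable = [c for c in ids if c in set(sim.ids)]
    dropped = len(ids) - len(usable)
    if dropped:
        logger.warning("%d compound(s) without similarity information dropped", dropped)
    if len(usable) < 2:
        raise ValidationError("fewer than 2 compounds shared between activities and similarity")
    return sim.reindex(usable), usable


def _apply_transform(table: ActivityTable, transform: str) -> ActivityTable:
    if transform == "none":
        return table
    if transform == "log10":
        cols = [table.observed, *table.predictions.values()]
        if any(np.any(c <= 0) for c in cols):
            raise ValidationError("log10 transform requires strictly positive activities")
        return table.transform_observed(np.log10)
    raise ConfigurationError(f"unknown transform {transform!r}")


def rank_models(evals: list[ModelEvaluation]) -> list[str]:
    """Model names sorted by SCI, with S(0) then S(1) breaking ties."""
    return [e.model for e in sorted(evals, key=lambda e: (-e.sci, -e.s0, -e.s1, e.model))]


def report_frame(evals: list[ModelEvaluation]) -> pd.DataFrame:
    """Comparison table: one row per statistic, one column per model."""
    frame = pd.DataFrame(
        {e.model: [getattr(e, s) for s in STATISTICS] for e in evals},
        index=list(STATISTICS),
    )
    frame.index.name = "statistic"
    return frame


def run_evaluation(config: RunConfig) -> ReportBundle:
    """Execute one full evaluation run and write its report bundle.

    Any failure names the stage it occurred in and removes partial outputs.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _write(path: Path, writer) -> None:
        writer(path)
        written.append(path)

    stage = "configuration"
    try:
        stage = "reading activities"
        table = read_activity_table(config.activities)
        stage = "activity transform"
        table = _apply_transform(table, config.transform)
        stage = "similarity"
        sim, usable = _load_similarity(config, table.ids)
        table = table.subset(usable)
        models = config.models if config.models else table.models
        missing = [m for m in models if m not in table.predictions]
        if missing:
            raise ConfigurationError(f"models not present in activity table: {missing}")
        if not models:
            raise ConfigurationError("activity table has no prediction columns")

        stage = "SALI evaluation"
        evals: list[ModelEvaluation] = []
        curves: dict[str, SaliCurve] = {}
        for m in models:
            curve = sali_curve(
                table.observed,
                table.predictions[m],
                sim,
                method=config.method,
                step=config.step,
                reference_max=config.reference_max,
            )
            curves[m] = curve
            evals.append(
                evaluate_model(
                    table.observed,
                    table.predictions[m],
                    sim,
                    model=m,
                    method=config.method,
                    step=config.step,
                    reference_max=config.reference_max,
                )
            )
        ranking = rank_models(evals)

        stage = "writing reports"
        _write(out_dir / "report.csv", lambda p: report_frame(evals).to_csv(p))
        _write(
            out_dir / "report.json",
            lambda p: p.write_text(
                json.dumps(
                    {"ranking": ranking, "evaluations": [e.as_dict() for e in evals]},
                    indent=2,
                    sort_keys=True,
                )
                + "\n"
            ),
        )
        for m in models:
            xs, ys = curves[m].sample(config.step)
            _write(
                out_dir / f"curve_{m}.csv",
                lambda p, xs=xs, ys=ys: pd.DataFrame({"X": xs, "S": ys}).to_csv(p, index=False),
            )
        hist = sali_histogram(sali_matrix(table.observed, sim), config.n_bins)
        _write(
            out_dir / "histogram.csv",
            lambda p: pd.DataFrame(
                {
                    "bin_low": hist.bin_edges[:-1],
                    "bin_high": hist.bin_edges[1:],
                    "count": hist.counts,
                }
            ).to_csv(p, index=False),
        )
        manifest = {
            "config": asdict(config),
            "n_compounds": table.n,
            "models": models,
            "ranking": ranking,
            "salicurves_version": __version__,
        }
        _write(
            out_dir / "manifest.json",
            lambda p: p.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n"),
        )
        return ReportBundle(evals, curves, ranking, out_dir)
    except SaliError as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise type(exc)(f"[stage: {stage}] {exc}") from exc


def plot_curves(curves: list[SaliCurve], labels: list[str], path) -> None:
    """Render SALI curves as step functions on [0, 1] x [-1, 1]."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not curves:
        raise ValidationError("no curves to plot")
    if len(labels) != len(curves):
        raise ValidationError("labels do not match curves")
    fig, ax = plt.subplots(figsize=(6, 4))
    for curve, label in zip(curves, labels):
        xs, ys = curve.sample(0.002)
        ax.step(xs, ys, where="post", label=label)
    ax.axhline(0.0, color="grey", lw=0.8, ls="--")
    ax.set_xlim(0, 1)
    ax.set_ylim(-1.05, 1.05)
    ax.set_xlabel("X (normalized SALI threshold)")
    ax.set_ylabel("S(X)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def monitor(
    evaluation: ModelEvaluation, thresholds: dict[str, float]
) -> dict[str, bool]:
    """Flag statistics that fell below user-set alert thresholds.

    Supports the model-maintenance loop: recompute SCI/S(0)/S(1) as new
    measured data accumulate and flag when the model needs retraining.
    Threshold keys must be statistic names (e.g. {"sci": 0.5, "s0": 0.4}).
    """
    unknown = set(thresholds) - set(STATISTICS)
    if unknown:
        raise ConfigurationError(f"unknown statistics in thresholds: {sorted(unknown)}")
    flags = {}
    for stat, limit in thresholds.items():
        value = getattr(evaluation, stat)
        below = value > limit if stat == "mae" else value < limit
        flags[stat] = bool(below)
    return flags
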