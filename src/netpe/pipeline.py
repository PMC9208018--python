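"""End-to-end orchestration: cohort -> band features -> group statistics.

For each subject, every analysis band is brick-wall filtered per epoch and
three features are estimated per epoch and averaged per subject: local PE
per ROI, the JPE_inv connectivity profile per ROI (mean over all other
ROIs), and relative band power per ROI (reference band 0.5-45 Hz).  Group
differences are then tested per band and per feature with the permutation
test + BH-FDR across ROIs, and the global (ROI-averaged) theta features
feed three single-feature logistic classifiers plus a one-way ANCOVA of
theta JPE_inv on group controlling for relative theta power.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import Cohort, generate_cohort
from .io import (
    PipelineConfig,
    provenance_lines,
    read_manifest,
    read_recording,
    write_feature_table,
)
from .ordinal import OrdinalConfig, connectivity_matrix, permutation_entropy
from .spectral import (
    BROADBAND,
    bandpass,
    extract_epochs,
    per_subject_aggregate,
    relative_power,
    tau_from_band,
)
from .stats import ancova_oneway, logistic_auc, permutation_test

logger = logging.getLogger(__name__)

MEASURES = ("pe", "jpe_inv", "rel_power")


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""


@dataclass
class PipelineResult:
    """Everything the pipeline computed, plus where it was written."""

    config: PipelineConfig
    features: dict  # (band, measure) -> DataFrame(subject, group, ROI...)
    comparisons: dict  # (band, measure) -> GroupComparison
    result_tables: dict  # (band, measure) -> per-ROI DataFrame
    classification: dict  # measure -> ClassificationReport
    ancova: object | None
    output_dir: Path | None


def band_ordinal_config(config: PipelineConfig, band) -> OrdinalConfig:
    """Ordinal config for one band under the configured tau rule."""
    if config.tau_rule == "band":
        return OrdinalConfig(config.ordinal.n, tau_from_band(config.fs, band))
    return config.ordinal


def subject_features(rec, config: PipelineConfig) -> dict:
    """Per-band, per-ROI features of one subject (epoch means).

    Returns ``{band_name: {"pe": (n_ch,), "jpe_inv": (n_ch,),
    "rel_power": (n_ch,), "connectivity": (n_ch, n_ch)}}``.
    """
    out = {}
    for band in config.bands:
        oc = band_ordinal_config(config, band)
        filt = bandpass(rec.data, rec.fs, band)
        pe = np.array(
            [
                [permutation_entropy(filt[c, e], oc) for c in range(rec.n_channels)]
                for e in range(rec.n_epochs)
            ]
        )
        mats = np.array(
            [
                connectivity_matrix(filt[:, e, :], oc, band=band.name).matrix
                for e in range(rec.n_epochs)
            ]
        )
        rel = np.array(
            [relative_power(rec.data[:, e, :], rec.fs, band, BROADBAND) for e in range(rec.n_epochs)]
        )
        mean_mat = per_subject_aggregate(mats)
        profile = (mean_mat.sum(axis=1) - np.diag(mean_mat)) / (rec.n_channels - 1)
        out[band.name] = {
            "pe": per_subject_aggregate(pe),
            "jpe_inv": profile,
            "rel_power": per_subject_aggregate(rel),
            "connectivity": mean_mat,
        }
    return out


def _load_cohort(config: PipelineConfig):
    """Recordings + labels + ids, either simulated or read from a manifest."""
    if config.input_manifest:
        subjects = read_manifest(config.input_manifest)
        recordings, labels, ids = [], [], []
        for entry in subjects:
            raw, ch_labels = read_recording(entry["path"], config.expected_channels)
            rec = extract_epochs(
                raw, config.fs, config.n_epochs, config.epoch_len, ch_labels
            )
            recordings.append(rec)
            labels.append(str(entry["group"]))
            ids.append(str(entry["id"]))
        return recordings, labels, ids
    cohort_spec = config.cohort
    if cohort_spec is None:
        from .cohort import default_cohort_spec

        cohort_spec = default_cohort_spec(seed=config.seed)
    cohort: Cohort = generate_cohort(cohort_spec)
    return list(cohort.recordings), list(cohort.labels), list(cohort.subject_ids)


def compute_features(recordings, labels, subject_ids, config: PipelineConfig) -> dict:
    """Feature tables for all subjects: ``(band, measure) -> DataFrame``
    with columns ``subject, group, <ROI labels...>``."""
    per_subject = []
    for sid, rec in zip(subject_ids, recordings):
        t0 = time.perf_counter()
        per_subject.append(subject_features(rec, config))
        logger.info("features %s computed in %.2f s", sid, time.perf_counter() - t0)
    roi_labels = recordings[0].channel_labels
    tables = {}
    for band in config.bands:
        for measure in MEASURES:
            rows = [feats[band.name][measure] for feats in per_subject]
            df = pd.DataFrame(np.asarray(rows), columns=list(roi_labels))
            df.insert(0, "group", labels)
            df.insert(0, "subject", subject_ids)
            tables[(band.name, measure)] = df
    return tables


def _group_split(df: pd.DataFrame):
    groups = sorted(df["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, got {groups}")
    roi_cols = [c for c in df.columns if c not in ("subject", "group")]
    a = df.loc[df["group"] == groups[0], roi_cols].to_numpy(dtype=float)
    b = df.loc[df["group"] == groups[1], roi_cols].to_numpy(dtype=float)
    return groups, roi_cols, a, b


def compare_groups(tables: dict, config: PipelineConfig, seed: int | None = None):
    """Permutation test + FDR per (band, measure); returns the
    GroupComparison objects and tidy per-ROI result tables."""
    seed = config.seed if seed is None else seed
    comparisons, result_tables = {}, {}
    for key, df in tables.items():
        groups, roi_cols, a, b = _group_split(df)
        comp = permutation_test(
            a, b, n_perm=config.n_perm, seed=seed, alpha_q=config.alpha_q
        )
        comparisons[key] = comp
        result_tables[key] = pd.DataFrame(
            {
                "roi": roi_cols,
                f"mean_{groups[0]}": a.mean(axis=0),
                f"mean_{groups[1]}": b.mean(axis=0),
                "stat": comp.per_roi_stat,
                "p": comp.p,
                "q": comp.q,
                "significant": comp.significant,
            }
        )
    return comparisons, result_tables


def classify_global_theta(tables: dict, config: PipelineConfig, band_name: str = "theta"):
    """Global-mean theta features -> one logistic ROC per measure, plus the
    ANCOVA of theta JPE_inv on group controlling for relative theta power."""
    if (band_name, "pe") not in tables:
        raise ValueError(f"band {band_name!r} not among computed features")
    reports, global_means = {}, {}
    labels = None
    for measure in MEASURES:
        df = tables[(band_name, measure)]
        groups, roi_cols, _, _ = _group_split(df)
        feature = df[roi_cols].mean(axis=1).to_numpy()
        labels = (df["group"] == groups[1]).astype(int).to_numpy()
        global_means[measure] = feature
        reports[measure] = logistic_auc(feature, labels)
    ancova = ancova_oneway(global_means["jpe_inv"], labels, global_means["rel_power"])
    return reports, ancova


def _write_outputs(result: PipelineResult, seed: int) -> None:
    outdir = result.output_dir
    assert outdir is not None
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = result.config
    for (band, measure), df in result.features.items():
        write_feature_table(outdir / f"features_{band}_{measure}.tsv", df, cfg, seed)
    for (band, measure), df in result.result_tables.items():
        write_feature_table(outdir / f"results_{band}_{measure}.tsv", df, cfg, seed)
    lines = list(provenance_lines(cfg, seed))
    lines.append("")
    lines.append("Classification of the two groups from global theta features")
    lines.append("(in-sample logistic regression; AUC with DeLong 95% CI):")
    for measure, rep in result.classification.items():
        lines.append(
            f"  theta {measure}: AUC = {rep.auc:.3f} "
            f"[{rep.ci_low:.3f}-{rep.ci_high:.3f}]"
            + ("  (perfect separation)" if rep.perfect_separation else "")
        )
        roc = pd.DataFrame(rep.roc_points, columns=["fpr", "tpr"])
        write_feature_table(outdir / f"roc_theta_{measure}.tsv", roc, cfg, seed)
    if result.ancova is not None:
        a = result.ancova
        lines.append(
            f"ANCOVA (theta jpe_inv ~ group + rel_power): "
            f"F({a.df[0]}, {a.df[1]}) = {a.F:.2f}, p = {a.p:.4f}, eta_sq = {a.eta_sq:.2f}"
        )
    lines.append("")
    lines.append("Significant ROIs (q < %g) per band and measure:" % cfg.alpha_q)
    for (band, measure), comp in result.comparisons.items():
        lines.append(f"  {band} {measure}: {int(comp.significant.sum())}")
    (outdir / "summary.txt").write_text("\n".join(lines) + "\n")


def run_pipeline(
    config: PipelineConfig,
    seed: int | None = None,
    output_dir=None,
    classify_band: str = "theta",
) -> PipelineResult:
    """Run the full pipeline; deterministic given config and seed.

    Stages: load-or-simulate cohort -> per-subject band features ->
    per-ROI group comparison -> global-theta classification.  Any stage
    failure raises :class:`PipelineStageError` naming the stage.
    """
    seed = config.seed if seed is None else seed
    if seed != config.seed:
        import dataclasses

        config = dataclasses.replace(config, seed=seed)
    stages = {}

    def run_stage(name, fn):
        t0 = time.perf_counter()
        try:
            out = fn()
        except Exception as exc:
            raise PipelineStageError(f"stage {name!r} failed: {exc}") from exc
        stages[name] = time.perf_counter() - t0
        logger.info("stage %s done in %.2f s (seed=%d)", name, stages[name], seed)
        return out

    recordings, labels, ids = run_stage("cohort", lambda: _load_cohort(config))
    tables = run_stage(
        "features", lambda: compute_features(recordings, labels, ids, config)
    )
    comparisons, result_tables = run_stage(
        "compare", lambda: compare_groups(tables, config, seed)
    )
    band_names = [b.name for b in config.bands]
    if classify_band in band_names:
        classification, ancova = run_stage(
            "classify", lambda: classify_global_theta(tables, config, classify_band)
        )
    else:
        classification, ancova = {}, None

    outdir = Path(output_dir) if output_dir else (
        Path(config.output_dir) if config.output_dir else None
    )
    result = PipelineResult(
        config=config,
        features=tables,
        comparisons=comparisons,
        result_tables=result_tables,
        classification=classification,
        ancova=ancova,
        output_dir=outdir,
    )
    if outdir is not None:
        run_stage("write", lambda: _write_outputs(result, seed))
    return result
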