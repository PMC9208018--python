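"""Readers and writers for ASCII recordings, feature/result tables, and the
pipeline configuration.

The canonical recording format is a delimited text matrix, one row per
sample and one column per channel, with an optional first header line of
channel labels.  Whitespace- and comma-delimited files are auto-detected.
The sampling rate is configuration, not file content.  Every results file
starts with ``#``-prefixed provenance lines carrying the package version,
the resolved configuration and the seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import Cohort, CohortSpec, SubjectSpec, mci_like, scd_like
from .ordinal import OrdinalConfig
from .spectral import BandDefinition, DEFAULT_BANDS, EpochedRecording, default_labels

__all__ = [
    "PipelineConfig",
    "read_recording",
    "write_recording",
    "write_cohort",
    "read_manifest",
    "read_feature_table",
    "write_feature_table",
    "provenance_lines",
]

_FLOAT_FMT = "{:.12g}"


def _detect_delimiter(first_line: str) -> str | None:
    return "," if "," in first_line else None  # None = any whitespace


def _is_numeric_row(tokens: list[str]) -> bool:
    try:
        for t in tokens:
            float(t)
    except ValueError:
        return False
    return True


def read_recording(path, expected_channels: int | None = None):
    """Read a delimited ASCII recording (samples x channels, optional header).

    Returns ``(data, labels)`` with ``data`` as a ``channels x samples``
    float array.  Header-less files get auto-generated labels
    ``ROI_001, ...``.  Raises ``ValueError`` on ragged rows, non-numeric
    cells or a channel-count mismatch with ``expected_channels``.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if not first.strip():
        raise ValueError(f"{path}: empty file")
    sep = _detect_delimiter(first)
    tokens = first.strip().split(sep)
    has_header = not _is_numeric_row(tokens)
    try:
        df = pd.read_csv(
            path,
            sep=sep if sep is not None else r"\s+",
            header=0 if has_header else None,
            dtype=float,
            comment="#",
        )
    except ValueError as exc:
        raise ValueError(f"{path}: could not parse as a numeric matrix: {exc}") from exc
    if df.isna().any().any():
        raise ValueError(f"{path}: ragged rows or non-numeric cells detected")
    labels = tuple(str(c) for c in df.columns) if has_header else default_labels(df.shape[1])
    if expected_channels is not None and df.shape[1] != expected_channels:
        raise ValueError(
            f"{path}: expected {expected_channels} channels, file has {df.shape[1]}"
        )
    return df.to_numpy().T.copy(), labels


def write_recording(path, data, channel_labels=None) -> None:
    """Write a ``channels x samples`` array (or an :class:`EpochedRecording`,
    whose epochs are re-concatenated) as samples x channels text with a
    header line of labels."""
    if isinstance(data, EpochedRecording):
        channel_labels = data.channel_labels
        data = data.data.reshape(data.n_channels, -1)
    data = np.asarray(data, dtype=float)
    labels = channel_labels if channel_labels is not None else default_labels(data.shape[0])
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("\t".join(labels) + "\n")
        for row in data.T:
            fh.write("\t".join(_FLOAT_FMT.format(v) for v in row) + "\n")


def write_cohort(cohort: Cohort, outdir) -> Path:
    """Write one recording file per subject plus a YAML manifest
    (subject ID, group, seed, generator parameters, file path).

    Returns the manifest path.  Files round-trip through
    :func:`read_recording`, the same reader used for real recordings.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for sid, group, rec, spec in zip(
        cohort.subject_ids, cohort.labels, cohort.recordings, cohort.specs
    ):
        fname = f"{sid}.txt"
        write_recording(outdir / fname, rec)
        entries.append(
            {
                "id": sid,
                "group": group,
                "path": fname,
                "seed": int(spec.seed),
                "params": {
                    k: (float(v) if isinstance(v, (int, float)) and k != "seed" else v)
                    for k, v in dataclasses.asdict(spec).items()
                    if k != "seed"
                },
            }
        )
    manifest = {
        "netpe_version": __version__,
        "fs": float(cohort.recordings[0].fs),
        "master_seed": int(cohort.spec.seed),
        "subjects": entries,
    }
    mpath = outdir / "manifest.yaml"
    with open(mpath, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return mpath


def read_manifest(path):
    """Read a cohort manifest; returns a list of dicts with resolved paths."""
    path = Path(path)
    with open(path) as fh:
        manifest = yaml.safe_load(fh)
    if not isinstance(manifest, dict) or "subjects" not in manifest:
        raise ValueError(f"{path}: not a cohort manifest (missing 'subjects')")
    subjects = []
    for entry in manifest["subjects"]:
        e = dict(entry)
        e["path"] = path.parent / e["path"]
        subjects.append(e)
    return subjects


# --------------------------------------------------------------------------
# configuration


_KNOWN_KEYS = {
    "fs", "bands", "ordinal", "tau_rule", "epochs", "stats", "seed",
    "channels", "paths", "cohort",
}


@dataclass(frozen=True)
class PipelineConfig:
    """Resolved pipeline configuration with the canonical defaults.

    ``tau_rule`` is either ``"fixed"`` (use ``ordinal.tau`` in every band)
    or ``"band"`` (per-band ``tau = round(fs / (3 * f_high))``).
    """

    fs: float = 1250.0
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS
    ordinal: OrdinalConfig = field(default_factory=OrdinalConfig)
    tau_rule: str = "fixed"
    n_epochs: int = 20
    epoch_len: int = 4096
    n_perm: int = 10_000
    alpha_q: float = 0.05
    seed: int = 0
    expected_channels: int | None = None
    input_manifest: str | None = None
    output_dir: str | None = None
    cohort: CohortSpec | None = None

    def __post_init__(self) -> None:
        if self.tau_rule not in ("fixed", "band"):
            raise ValueError(f"tau_rule must be 'fixed' or 'band', got {self.tau_rule!r}")
        for b in self.bands:
            b.validate_for(self.fs)
        if len({b.name for b in self.bands}) != len(self.bands):
            raise ValueError("band names must be unique")
        # reliable pattern statistics: n! <= epoch_len / 10
        if self.ordinal.n_patterns > self.epoch_len / 10:
            raise ValueError(
                f"n={self.ordinal.n} gives {self.ordinal.n_patterns} patterns; "
                f"epochs of {self.epoch_len} samples require n! <= epoch_len/10"
            )
        if self.n_perm < 1 or not 0 < self.alpha_q < 1:
            raise ValueError("invalid stats settings")

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kw: dict = {}
        if "fs" in raw:
            kw["fs"] = float(raw["fs"])
        if "bands" in raw:
            kw["bands"] = tuple(
                BandDefinition(b["name"], float(b["f_low"]), float(b["f_high"]))
                for b in raw["bands"]
            )
        if "ordinal" in raw:
            extra = set(raw["ordinal"]) - {"n", "tau"}
            if extra:
                raise ValueError(f"unknown ordinal keys: {sorted(extra)}")
            kw["ordinal"] = OrdinalConfig(**{k: int(v) for k, v in raw["ordinal"].items()})
        if "tau_rule" in raw:
            kw["tau_rule"] = raw["tau_rule"]
        if "epochs" in raw:
            extra = set(raw["epochs"]) - {"n_epochs", "epoch_len"}
            if extra:
                raise ValueError(f"unknown epochs keys: {sorted(extra)}")
            kw.update({k: int(v) for k, v in raw["epochs"].items()})
        if "stats" in raw:
            extra = set(raw["stats"]) - {"n_perm", "alpha_q"}
            if extra:
                raise ValueError(f"unknown stats keys: {sorted(extra)}")
            if "n_perm" in raw["stats"]:
                kw["n_perm"] = int(raw["stats"]["n_perm"])
            if "alpha_q" in raw["stats"]:
                kw["alpha_q"] = float(raw["stats"]["alpha_q"])
        if "seed" in raw:
            kw["seed"] = int(raw["seed"])
        if "channels" in raw and raw["channels"] is not None:
            kw["expected_channels"] = int(raw["channels"])
        if "paths" in raw:
            extra = set(raw["paths"]) - {"input_manifest", "output_dir"}
            if extra:
                raise ValueError(f"unknown paths keys: {sorted(extra)}")
            kw["input_manifest"] = raw["paths"].get("input_manifest")
            kw["output_dir"] = raw["paths"].get("output_dir")
        if "cohort" in raw and raw["cohort"] is not None:
            kw["cohort"] = _cohort_spec_from_dict(raw["cohort"])
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        d = {
            "fs": self.fs,
            "bands": [dataclasses.asdict(b) for b in self.bands],
            "ordinal": {"n": self.ordinal.n, "tau": self.ordinal.tau},
            "tau_rule": self.tau_rule,
            "epochs": {"n_epochs": self.n_epochs, "epoch_len": self.epoch_len},
            "stats": {"n_perm": self.n_perm, "alpha_q": self.alpha_q},
            "seed": self.seed,
        }
        if self.expected_channels is not None:
            d["channels"] = self.expected_channels
        if self.input_manifest or self.output_dir:
            d["paths"] = {"input_manifest": self.input_manifest, "output_dir": self.output_dir}
        if self.cohort is not None:
            d["cohort"] = _cohort_spec_to_dict(self.cohort)
        return d


def _cohort_spec_from_dict(raw: dict) -> CohortSpec:
    known = {"n_subjects_a", "n_subjects_b", "label_a", "label_b", "seed",
             "jitter", "group_a", "group_b"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown cohort keys: {sorted(unknown)}")
    kw = {k: raw[k] for k in raw if k not in ("group_a", "group_b")}
    spec_fields = {f.name for f in dataclasses.fields(SubjectSpec)}
    for key, template in (("group_a", scd_like), ("group_b", mci_like)):
        overrides = dict(raw.get(key) or {})
        extra = set(overrides) - spec_fields
        if extra:
            raise ValueError(f"unknown {key} keys: {sorted(extra)}")
        kw[key] = template(**overrides)
    return CohortSpec(**kw)


def _cohort_spec_to_dict(spec: CohortSpec) -> dict:
    d = dataclasses.asdict(spec)
    return d


# --------------------------------------------------------------------------
# tabular features / results


def provenance_lines(config: PipelineConfig, seed: int | None = None) -> list[str]:
    """``#``-prefixed header lines embedding version, config and seed."""
    return [
        f"# netpe {__version__}",
        f"# config: {json.dumps(config.to_dict(), sort_keys=True)}",
        f"# seed: {config.seed if seed is None else seed}",
    ]


def write_feature_table(path, table: pd.DataFrame, config: PipelineConfig,
                        seed: int | None = None) -> None:
    """Write a per-subject feature table (columns: subject, group, features)
    as TSV with provenance header lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in provenance_lines(config, seed):
            fh.write(line + "\n")
        table.to_csv(fh, sep="\t", index=False, float_format="%.12g")


def read_feature_table(path) -> pd.DataFrame:
    """Read a feature/results TSV written by :func:`write_feature_table`."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if "subject" in df.columns and df["subject"].duplicated().any():
        raise ValueError(f"{path}: duplicate subject IDs")
    return df
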