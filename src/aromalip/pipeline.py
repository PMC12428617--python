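"""End-to-end pipeline: screening → ROAV → classification → correlation.

``run_pipeline`` chains the stages on a replicate peak table (plus
optional lipid and amino-acid blocks), writes tidy CSV exports, and
records a JSON run manifest (package version, configuration, SHA-256
input hashes, seed) so a run is reproducible from a single artifact.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import amino as _amino
from . import correlation as _corr
from . import lipids as _lip
from . import roav as _roav
from . import screening as _scr
from .datasets import load_threshold_db
from .io import read_feature_table
from .names import canonicalize

logger = logging.getLogger("aromalip")


@dataclass
class PipelineConfig:
    """Tunable constants of the screening/scoring pipeline.

    Defaults are the published screening rules: detection rate strictly
    above 0.5, CV strictly below 0.30, ROAV bands at 1.0/0.1.
    """

    min_detection_rate: float = 0.5
    max_cv: float = 0.30
    inclusive: bool = False
    roav_characteristic_cutoff: float = 1.0
    roav_modifier_cutoff: float = 0.1
    threshold_db_path: str | None = None
    registry_path: str | None = None
    adjust_method: str = "bh"
    key_lipid_top_n: int = 14
    amino_key_cutoff: float = 40.0
    export_decimals: int | None = None
    seed: int | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0 <= self.min_detection_rate < 1:
            raise ValueError("min_detection_rate must be in [0, 1)")
        if self.max_cv <= 0:
            raise ValueError("max_cv must be positive")
        if not (0 < self.roav_modifier_cutoff
                < self.roav_characteristic_cutoff):
            raise ValueError("ROAV cutoffs must be positive and ordered")
        if self.adjust_method not in ("bh", "none"):
            raise ValueError("adjust_method must be 'bh' or 'none'")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Load a flat key:value YAML config mirroring the field names."""
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class RunResult:
    """Outputs of one pipeline run, stage by stage."""

    screened: pd.DataFrame
    detection_report: pd.DataFrame
    cv_report: pd.DataFrame
    annotated: pd.DataFrame
    dropped_no_threshold: list[str]
    standard: str
    roav: pd.DataFrame
    class_summary: pd.DataFrame
    lipid_shares: pd.DataFrame | None = None
    key_lipids: pd.DataFrame | None = None
    lipid_correlations: pd.DataFrame | None = None
    amino_records: pd.DataFrame | None = None
    amino_correlations: pd.DataFrame | None = None
    manifest: dict = field(default_factory=dict)


def _hash_table(df: pd.DataFrame) -> str:
    return hashlib.sha256(df.to_csv().encode("utf-8")).hexdigest()


def _maybe_read(source, kind):
    if source is None or isinstance(source, pd.DataFrame):
        return source
    return read_feature_table(source, kind)


def _correlate_block(block: pd.DataFrame, volatiles: pd.DataFrame,
                     config: PipelineConfig, label: str):
    shared = set(block.columns) & set(volatiles.columns)
    if len(shared) < 3:
        logger.warning(
            "%s block shares only %d samples with the peak table; "
            "skipping correlation", label, len(shared),
        )
        return None
    return _corr.block_correlate(block, volatiles,
                                 adjust=config.adjust_method)


def run_pipeline(
    peaks, config: PipelineConfig | None = None, threshold_db=None,
    lipid_table=None, amino_table=None, outdir=None,
) -> RunResult:
    """Run screening → ROAV → classification (→ correlations) end to end.

    ``peaks``/``lipid_table``/``amino_table`` are DataFrames or CSV/TSV
    paths; ``threshold_db`` defaults to the packaged ham panel.  When
    ``outdir`` is given, all stage outputs plus ``manifest.json`` are
    written there.
    """
    config = config or PipelineConfig()
    logging.getLogger("aromalip").setLevel(config.log_level)
    peaks = _maybe_read(peaks, "peaks")
    peaks = peaks.copy()
    peaks.index = [canonicalize(c) for c in peaks.index]
    lipid_table = _maybe_read(lipid_table, "lipids")
    amino_table = _maybe_read(amino_table, "amino_acids")
    if threshold_db is None:
        threshold_db = load_threshold_db()
    elif not isinstance(threshold_db, pd.DataFrame):
        threshold_db = _scr.read_threshold_db(threshold_db)

    try:
        stage = "detection_rate_filter"
        kept, det_report = _scr.detection_rate_filter(
            peaks, config.min_detection_rate, inclusive=config.inclusive)
        stage = "cv_filter"
        kept, cv_report = _scr.cv_filter(
            kept, config.max_cv, inclusive=config.inclusive)
        stage = "relative_content"
        screened = _scr.relative_content(kept)
        stage = "join_thresholds"
        annotated, dropped = _scr.join_thresholds(screened, threshold_db)
        stage = "roav"
        standard = _roav.select_standard(annotated)
        scored = _roav.compute_roav(annotated, standard)
        scored = _roav.classify_contribution(
            scored, config.roav_characteristic_cutoff,
            config.roav_modifier_cutoff)
        stage = "class_composition"
        class_summary = _roav.class_composition(scored)
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    result = RunResult(
        screened=screened, detection_report=det_report,
        cv_report=cv_report, annotated=annotated,
        dropped_no_threshold=dropped, standard=standard, roav=scored,
        class_summary=class_summary,
    )

    characteristic = scored.loc[
        scored["category"] == "characteristic", "compound"]
    volatile_block = peaks.loc[peaks.index.isin(set(characteristic))]

    if lipid_table is not None:
        result.lipid_shares = _lip.class_shares(lipid_table, "class_code")
        result.key_lipids = _lip.select_key_lipids(
            lipid_table, top_n=config.key_lipid_top_n)
        key_block = lipid_table.loc[result.key_lipids["lipid"]]
        result.lipid_correlations = _correlate_block(
            key_block, volatile_block, config, "lipid")
    if amino_table is not None:
        records = _amino.annotate_taste(amino_table)
        result.amino_records = _amino.select_key(
            records, config.amino_key_cutoff)
        result.amino_correlations = _correlate_block(
            amino_table, volatile_block, config, "amino-acid")

    manifest = {
        "package": "aromalip",
        "version": __version__,
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "inputs": {
            "peaks": _hash_table(peaks),
            "threshold_db": _hash_table(threshold_db),
            "lipids": None if lipid_table is None
            else _hash_table(lipid_table),
            "amino_acids": None if amino_table is None
            else _hash_table(amino_table),
        },
        "standard_compound": standard,
        "n_screened": int(len(screened)),
        "n_annotated": int(len(annotated)),
        "n_characteristic": int((scored["category"] == "characteristic").sum()),
    }
    result.manifest = manifest

    if outdir is not None:
        _write_outputs(result, Path(outdir), config)
    return result


def _write_outputs(result: RunResult, outdir: Path,
                   config: PipelineConfig) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    dec = config.export_decimals

    def _csv(df: pd.DataFrame, name: str) -> None:
        out = df.round(dec) if dec is not None else df
        out.to_csv(outdir / name, index=False)

    _csv(result.screened, "screened_compounds.csv")
    _csv(result.roav, "roav_results.csv")
    _csv(result.class_summary, "class_summary.csv")
    report = {
        "n_input": int(len(result.detection_report)),
        "n_after_detection_filter":
            int(result.detection_report["retained"].sum()),
        "n_after_cv_filter": int(result.cv_report["retained"].sum()),
        "dropped_no_threshold": result.dropped_no_threshold,
        "standard_compound": result.standard,
    }
    (outdir / "screening_report.json").write_text(
        json.dumps(report, indent=2) + "\n", encoding="utf-8")
    for attr, name in (
        ("lipid_shares", "lipid_shares.csv"),
        ("key_lipids", "key_lipids.csv"),
        ("lipid_correlations", "lipid_volatile_correlations.csv"),
        ("amino_records", "amino_acids_annotated.csv"),
        ("amino_correlations", "amino_volatile_correlations.csv"),
    ):
        df = getattr(result, attr)
        if df is not None:
            _csv(df, name)
    (outdir / "manifest.json").write_text(
        json.dumps(result.manifest, indent=2, sort_keys=True) + "\n",
        encoding="utf-8")
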