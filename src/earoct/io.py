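"""Configuration, file I/O and pipeline orchestration.

Ties the stages together the way the acquisition device does: load an
M-mode image, gate it on image quality (SNR and axial resolution), extract
per-A-scan features, classify, apply the real-time window, and report both
line-classification readouts plus a verdict. The pipeline fails closed: a
scan that does not pass the quality gate gets no verdict, only the gate
report.

All tunables live in :class:`RunConfig`, which loads from YAML or JSON and
rejects unknown keys. Reports serialize to JSON deterministically (sorted
keys, no timestamps), so a fixed config and fixed inputs give a
byte-identical report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from . import __version__
from .classify import (
    DEFAULT_WINDOW,
    ClassifierModel,
    MModeClassification,
    classify_mmode,
)
from .features import FeatureConfig, QualityReport, QualityThresholds, measure_snr, quality_check
from .labels import ABNORMAL_CLASSES, PRIMARY_CLASSES, ClassLabel
from .phantom import SCHEMA_VERSION, AScan, MModeImage, ScanMode

logger = logging.getLogger("earoct")


class PipelineError(Exception):
    """Base class for pipeline failures."""


class GateFailure(PipelineError):
    """The acquisition did not meet the quality gate (exit code 2)."""


class FormatError(PipelineError):
    """Unreadable or malformed input file (exit code 3)."""


class ConfigError(PipelineError):
    """Invalid run configuration (exit code 4)."""


@dataclass(frozen=True)
class RunConfig:
    """Every tunable of the pipeline, with its documented default."""

    schema_version: str = SCHEMA_VERSION
    seed: int = 0
    #: real-time readout length in A-scans
    window: int = DEFAULT_WINDOW
    #: a scan is called ABNORMAL when the windowed abnormal percentage
    #: exceeds this cutoff
    verdict_threshold_pct: float = 50.0
    #: flag verdicts whose leading subtypes are separated by less than this
    margin_pct: float = 10.0
    refractive_index: float = 1.44
    # quality gate
    min_snr_db: float = 80.0
    max_axial_resolution_um: float = 19.2
    #: axial resolution of the acquiring system (um in air)
    axial_resolution_um: float = 4.9
    # feature extraction
    min_prominence_rel: float = 0.1
    min_separation_um: float = 9.8
    noise_fraction: float = 0.1
    signal_threshold_mult: float = 6.0
    noise_floor_mult: float = 5.0
    min_fit_px: int = 10
    #: depth pixel pitch assumed when a file carries no sidecar metadata
    pixel_um_default: float = 2900.0 / 1024.0

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        try:
            return cls(**d)
        except TypeError as exc:  # pragma: no cover - defensive
            raise ConfigError(str(exc)) from exc

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        import yaml

        path = Path(path)
        try:
            data = yaml.safe_load(path.read_text())
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse config {path}: {exc}") from exc
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ConfigError(f"config {path} must be a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def feature_config(self) -> FeatureConfig:
        return FeatureConfig(
            min_prominence_rel=self.min_prominence_rel,
            min_separation_um=self.min_separation_um,
            refractive_index=self.refractive_index,
            noise_fraction=self.noise_fraction,
            signal_threshold_mult=self.signal_threshold_mult,
            noise_floor_mult=self.noise_floor_mult,
            axial_resolution_um=self.axial_resolution_um,
            min_fit_px=self.min_fit_px,
        )

    def quality_thresholds(self) -> QualityThresholds:
        return QualityThresholds(
            min_snr_db=self.min_snr_db,
            max_axial_resolution_um=self.max_axial_resolution_um,
        )


# ---------------------------------------------------------------------------
# M-mode file I/O
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def read_mmode(path: str | Path, config: RunConfig = RunConfig()) -> MModeImage:
    """Read a single-channel M-mode image (TIFF/PNG) with optional sidecar.

    Rows are depth (row 0 = zero delay), columns time. A JSON sidecar with
    the same basename supplies ``pixel_um``, ``trigger_index`` and the
    acquisition-mode tags; without one, defaults are applied and a warning
    is logged.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"input file not found: {path}")
    try:
        if path.suffix.lower() in {".tif", ".tiff"}:
            import tifffile

            arr = tifffile.imread(path)
        else:
            import imageio.v3 as iio

            arr = iio.imread(path)
    except (OSError, ValueError) as exc:
        raise FormatError(f"cannot read image {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim != 2:
        raise FormatError(
            f"{path} is not a single-channel 2-D image (shape {arr.shape})"
        )
    if not np.issubdtype(arr.dtype, np.number):
        raise FormatError(f"{path} holds non-numeric data ({arr.dtype})")
    arr = arr.astype(np.float64)
    if arr.min() < 0:
        arr = arr - arr.min()  # magnitude images are non-negative

    pixel_um = config.pixel_um_default
    trigger_index = None
    a_scan_rate = 20_000.0
    modes: list[str] | None = None
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        try:
            meta = json.loads(sidecar.read_text())
        except json.JSONDecodeError as exc:
            raise FormatError(f"corrupted sidecar JSON {sidecar}: {exc}") from exc
        pixel_um = float(meta.get("pixel_um", pixel_um))
        trigger_index = meta.get("trigger_index")
        a_scan_rate = float(meta.get("a_scan_rate_hz", a_scan_rate))
        modes = meta.get("modes")
    else:
        logger.warning(
            "%s has no sidecar; assuming pixel_um=%.3f and no trigger",
            path,
            pixel_um,
        )
    ascans = []
    for k in range(arr.shape[1]):
        mode = ScanMode(modes[k]) if modes else (
            ScanMode.POST_TRIGGER
            if trigger_index is not None and k >= trigger_index
            else ScanMode.FREE_RUN
        )
        ascans.append(AScan(intensity=arr[:, k], pixel_um=pixel_um, mode=mode))
    return MModeImage(
        ascans=ascans, trigger_index=trigger_index, a_scan_rate_hz=a_scan_rate
    )


# ---------------------------------------------------------------------------
# classification report
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassificationReport:
    """Full, serializable record of one pipeline run."""

    input_path: str
    input_sha256: str
    tool_version: str
    config: dict[str, Any]
    gate: dict[str, Any]
    labels: tuple[str, ...]
    windowed: dict[str, Any]
    full_scan: dict[str, Any]
    shortfall: bool
    verdict: str | None
    subtype: str | None
    low_margin: bool

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ClassificationReport":
        d = json.loads(text)
        d["labels"] = tuple(d["labels"])
        return cls(**d)


def _gate_snr_db(mmode: MModeImage, config: RunConfig) -> float:
    """Achieved SNR of the acquisition: the best per-column peak SNR.

    The gate asks whether the acquisition *reached* sufficient SNR; columns
    degraded by motion are expected and handled by per-A-scan exclusion, so
    the brightest stabilized column is the fair measure.
    """
    best = -np.inf
    for a in mmode.ascans:
        if float(a.intensity.max()) == 0.0:
            continue
        best = max(best, measure_snr(a))
    return best


def run_pipeline(
    config: RunConfig,
    input_path: str | Path,
    model_path: str | Path,
) -> ClassificationReport:
    """Quality gate -> features -> classification -> window -> verdict.

    Fails closed: when the gate fails, the report carries the gate outcome
    and no verdict (the CLI maps this to exit code 2). Exclusion counts
    reconcile: n_total = n_valid + n_excluded on the full-scan readout.
    """
    input_path = Path(input_path)
    mmode = read_mmode(input_path, config)
    try:
        model = ClassifierModel.load(model_path)
    except (OSError, json.JSONDecodeError, KeyError, ValueError) as exc:
        raise FormatError(f"cannot load model bundle {model_path}: {exc}") from exc

    digest = hashlib.sha256(input_path.read_bytes()).hexdigest()
    gate = quality_check(
        _gate_snr_db(mmode, config),
        config.axial_resolution_um,
        config.quality_thresholds(),
    )
    gate_dict = {
        "passed": gate.passed,
        "snr_db": gate.snr_db,
        "axial_resolution_um": gate.axial_resolution_um,
        "failures": list(gate.failures),
    }
    if not gate.passed:
        empty = {
            "percent": {c.value: None for c in PRIMARY_CLASSES},
            "abnormal_percent": None,
            "n_valid": 0,
            "n_excluded": 0,
            "empty": True,
        }
        return ClassificationReport(
            input_path=str(input_path),
            input_sha256=digest,
            tool_version=__version__,
            config=config.to_dict(),
            gate=gate_dict,
            labels=(),
            windowed=empty,
            full_scan=empty,
            shortfall=False,
            verdict=None,
            subtype=None,
            low_margin=False,
        )

    result: MModeClassification = classify_mmode(
        mmode, model, config.feature_config(), window=config.window
    )
    verdict, subtype, low_margin = _verdict(result, config)
    return ClassificationReport(
        input_path=str(input_path),
        input_sha256=digest,
        tool_version=__version__,
        config=config.to_dict(),
        gate=gate_dict,
        labels=tuple(lab.value for lab in result.labels),
        windowed=_jsonify_lc(result.windowed.to_dict()),
        full_scan=_jsonify_lc(result.full_scan.to_dict()),
        shortfall=result.shortfall,
        verdict=verdict,
        subtype=subtype,
        low_margin=low_margin,
    )


def _jsonify_lc(d: dict[str, Any]) -> dict[str, Any]:
    """NaN percentages (empty readouts) become JSON nulls."""
    pct = {
        k: (None if v != v else v) for k, v in d["percent"].items()
    }
    ab = d["abnormal_percent"]
    return {**d, "percent": pct, "abnormal_percent": None if ab != ab else ab}


def _verdict(
    result: MModeClassification, config: RunConfig
) -> tuple[str | None, str | None, bool]:
    lc = result.windowed
    if lc.empty:
        return None, None, False
    abnormal = lc.abnormal_percent
    if abnormal > config.verdict_threshold_pct:
        sub = max(
            ABNORMAL_CLASSES,
            key=lambda c: (lc.percent[c], -PRIMARY_CLASSES.index(c)),
        )
        others = sorted((lc.percent[c] for c in ABNORMAL_CLASSES), reverse=True)
        margin = others[0] - others[1] if len(others) > 1 else others[0]
        return "ABNORMAL", sub.value, margin < config.margin_pct
    return "NORMAL", None, False
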