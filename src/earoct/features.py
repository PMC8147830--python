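"""Per-A-scan feature extraction for middle-ear OCT classification.

Each reconstructed A-scan yields the three diagnostic features the
classifier consumes -- the tympanic-membrane (TM) thickness measured between
the two predominant reflectivity peaks, the total number of scattering peaks,
and an estimated optical attenuation coefficient of the content behind the
TM -- plus a per-A-scan SNR and a has-signal validity flag used to exclude
empty free-run A-scans from every percentage readout.

Conventions
-----------
* Depth pixel 0 is the zero optical delay; depths are micrometres of optical
  path unless a name says ``physical``.
* Physical thickness = optical thickness / refractive index (1.44 for the TM).
* SNR (dB) = 20 log10(peak magnitude / noise-floor standard deviation), with
  the noise floor measured over the deepest 10% of the A-scan by default.
* Attenuation follows the single-scattering round-trip model
  I(z) ~ exp(-2 mu z): mu is minus half the least-squares slope of
  ln(intensity) against depth (mm) over the fit window behind the TM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks, peak_prominences

from .phantom import AScan

DEFAULT_REFRACTIVE_INDEX = 1.44


@dataclass(frozen=True)
class Peak:
    """One detected reflectivity peak."""

    index_px: int
    depth_um: float
    height: float
    prominence: float


@dataclass(frozen=True)
class QualityThresholds:
    """Minimum image quality for which the classifier is trusted.

    The classifier generalises across OCT systems provided the acquisition
    reaches roughly 80 dB SNR and an axial resolution of 19.2 um or better;
    both bounds are inclusive.
    """

    min_snr_db: float = 80.0
    max_axial_resolution_um: float = 19.2

    def __post_init__(self) -> None:
        if self.min_snr_db <= 0 or self.max_axial_resolution_um <= 0:
            raise ValueError("quality thresholds must be strictly positive")


@dataclass(frozen=True)
class QualityReport:
    passed: bool
    snr_db: float
    axial_resolution_um: float
    failures: tuple[str, ...] = ()


@dataclass(frozen=True)
class FeatureVector:
    """The classifier's view of one A-scan.

    Invalid A-scans (no optical signal, or fewer than two detectable peaks)
    keep ``valid=False`` and carry NaN / None in every feature field; they
    are never guessed by the classifier.
    """

    tm_thickness_optical_um: float = math.nan
    tm_thickness_physical_um: float = math.nan
    peak_count: int | None = None
    attenuation_mm1: float = math.nan
    snr_db: float = math.nan
    valid: bool = False


@dataclass(frozen=True)
class FeatureConfig:
    """Tunables of the feature extractor (defaults match the briefcase system)."""

    min_prominence_rel: float = 0.1
    #: minimum peak separation; default 2x the 4.9 um axial resolution
    min_separation_um: float = 9.8
    refractive_index: float = DEFAULT_REFRACTIVE_INDEX
    #: fraction of the deepest pixels treated as the noise floor
    noise_fraction: float = 0.1
    #: a peak must exceed this multiple of the noise deviation to count as signal
    signal_threshold_mult: float = 6.0
    #: the attenuation fit window ends where the smoothed profile falls below
    #: noise mean + noise_floor_mult * SE of the smoothed noise
    noise_floor_mult: float = 5.0
    #: peaks within this optical distance behind the TM inner surface are
    #: treated as part of the adherent layer complex (TM + biofilm); the
    #: attenuation window starts behind the deepest of them
    layer_complex_um: float = 150.0
    #: axial resolution of the system; the fit window starts one resolution
    #: width behind the deeper of the two predominant TM peaks
    axial_resolution_um: float = 4.9
    min_fit_px: int = 10


def _noise_slice(n: int, noise_fraction: float) -> slice:
    start = min(n - 1, int(math.floor(n * (1.0 - noise_fraction))))
    return slice(start, n)


def noise_stats(
    ascan: AScan, noise_region: slice | None = None, noise_fraction: float = 0.1
) -> tuple[float, float]:
    """(mean, standard deviation) of the noise floor."""
    region = noise_region or _noise_slice(len(ascan), noise_fraction)
    noise = ascan.intensity[region]
    if noise.size == 0:
        raise ValueError("noise region is empty")
    return float(noise.mean()), float(noise.std())


def measure_snr(ascan: AScan, noise_region: slice | None = None) -> float:
    """Peak SNR in dB: 20 log10(max intensity / noise-floor deviation).

    The noise region (default: deepest 10% of the A-scan) must not contain
    structural signal. Returns ``inf`` when the noise deviation is zero;
    raises on an all-zero A-scan.
    """
    peak = float(ascan.intensity.max())
    if peak == 0.0:
        raise ValueError("all-zero A-scan: SNR undefined")
    _, sd = noise_stats(ascan, noise_region)
    if sd == 0.0:
        return math.inf
    return 20.0 * math.log10(peak / sd)


def has_signal(
    ascan: AScan,
    *,
    threshold_mult: float = 6.0,
    noise_region: slice | None = None,
) -> bool:
    """True iff the strongest peak rises ``threshold_mult`` noise deviations
    above the noise-floor mean.

    Mirrors the rule that free-run A-scans without any optical signal are
    excluded from line-classification percentages. Degenerate inputs
    (all-zero profile) are simply not signal.
    """
    peak = float(ascan.intensity.max())
    if peak == 0.0:
        return False
    mean, sd = noise_stats(ascan, noise_region)
    if sd == 0.0:
        return peak > mean
    return peak - mean > threshold_mult * sd


def detect_peaks(
    ascan: AScan,
    min_prominence_rel: float = 0.1,
    min_separation_um: float = 9.8,
) -> list[Peak]:
    """Detect scattering peaks, sorted by depth.

    Rules, applied in order: (1) candidate peaks are interior local maxima,
    a flat plateau counting once at its first (shallowest) sample;
    (2) candidates whose prominence falls below ``min_prominence_rel`` x the
    global maximum are dropped; (3) of any two survivors closer than
    ``min_separation_um`` the taller wins (equal heights: the shallower).
    """
    if not (0.0 < min_prominence_rel <= 1.0):
        raise ValueError("min_prominence_rel must be in (0, 1]")
    if min_separation_um < ascan.pixel_um:
        raise ValueError("min_separation_um must be at least one pixel")
    x = ascan.intensity
    gmax = float(x.max())
    if gmax <= 0.0:
        return []
    idx, props = find_peaks(x, plateau_size=(1, None))
    if idx.size == 0:
        return []
    lefts = props["left_edges"]
    proms = peak_prominences(x, idx)[0]
    ok = proms >= min_prominence_rel * gmax
    idx, lefts, proms = idx[ok], lefts[ok], proms[ok]

    # greedy separation: taller first, equal heights shallower first
    order = sorted(range(idx.size), key=lambda k: (-x[idx[k]], lefts[k]))
    keep = np.ones(idx.size, dtype=bool)
    min_sep_px = min_separation_um / ascan.pixel_um
    for k in order:
        if not keep[k]:
            continue
        suppress = np.abs(lefts - lefts[k]) < min_sep_px
        suppress[k] = False
        keep[suppress] = False
    peaks = []
    for mid, left, prom in zip(idx[keep], lefts[keep], proms[keep]):
        peaks.append(
            Peak(
                index_px=int(left),
                depth_um=float(left * ascan.pixel_um),
                height=float(x[mid]),
                prominence=float(prom),
            )
        )
    return peaks


def predominant_pair(peaks: list[Peak]) -> tuple[Peak, Peak] | None:
    """The two tallest peaks (height ties break toward the shallower one),
    returned in depth order; ``None`` if fewer than two peaks exist."""
    if len(peaks) < 2:
        return None
    ranked = sorted(peaks, key=lambda p: (-p.height, p.index_px))
    a, b = ranked[0], ranked[1]
    return (a, b) if a.index_px <= b.index_px else (b, a)


def tm_thickness(
    ascan: AScan,
    peaks: list[Peak],
    refractive_index: float = DEFAULT_REFRACTIVE_INDEX,
) -> tuple[float, float] | None:
    """TM thickness from the two predominant peaks.

    The two tallest detected peaks are taken as the TM's outer and inner
    surfaces; the optical thickness is their depth separation and the
    physical thickness divides out the refractive index. Returns
    ``(optical_um, physical_um)``, or ``None`` when fewer than two peaks are
    available (the feature vector is then marked invalid).
    """
    if refractive_index <= 0:
        raise ValueError("refractive_index must be positive")
    pair = predominant_pair(peaks)
    if pair is None:
        return None
    optical = abs(pair[1].depth_um - pair[0].depth_um)
    return optical, optical / refractive_index


def estimate_attenuation(
    ascan: AScan,
    fit_region: slice | None = None,
    *,
    peaks: list[Peak] | None = None,
    config: FeatureConfig = FeatureConfig(),
) -> float:
    """Attenuation coefficient mu (1/mm) from a log-linear fit.

    Under the single-scattering model the backscattered intensity decays as
    ``I(z) ~ exp(-2 mu z)``, so mu is minus half the least-squares slope of
    ``ln I`` against depth in mm over ``fit_region``.

    When ``fit_region`` is None it is derived from the detected peaks: the
    window starts two axial-resolution widths behind the adherent layer
    complex -- the deepest peak lying within ``config.layer_complex_um`` of
    the deeper predominant TM peak, so an adherent biofilm's own reflections
    never contaminate the cavity fit -- and ends at the last depth where the
    5-px smoothed
    profile still exceeds the noise floor, trimmed by two resolution widths
    to keep the high-leverage tail clear of boundary roll-off; the mean
    noise floor is subtracted before taking the logarithm so deep,
    noise-dominated samples do not flatten the slope. An explicit
    ``fit_region`` is fitted exactly as given on the raw intensities.
    Returns NaN when no window of at least ``config.min_fit_px`` strictly
    positive samples exists.
    """
    x = ascan.intensity
    n = x.size
    if fit_region is None:
        if peaks is None:
            peaks = detect_peaks(
                ascan, config.min_prominence_rel, config.min_separation_um
            )
        pair = predominant_pair(peaks)
        if pair is None:
            return math.nan
        anchor = pair[1]
        for p in peaks:  # deepest peak of the adherent layer complex
            if anchor.depth_um < p.depth_um <= pair[1].depth_um + config.layer_complex_um:
                anchor = p
        res_px = int(math.ceil(config.axial_resolution_um / ascan.pixel_um))
        start = anchor.index_px + 2 * res_px
        if start >= n:
            return math.nan
        mean_n, sd_n = noise_stats(ascan, noise_fraction=config.noise_fraction)
        w = 5
        smooth = uniform_filter1d(x, size=w, mode="nearest")
        floor = mean_n + config.noise_floor_mult * sd_n / math.sqrt(w)
        above = np.nonzero(smooth[start:] > floor)[0]
        if above.size == 0:
            return math.nan
        fit_region = slice(start, start + int(above[-1]) + 1 - 2 * res_px)
        x = x - mean_n
    seg = x[fit_region]
    z_mm = ascan.depth_um[fit_region] / 1000.0
    pos = seg > 0
    if pos.sum() < config.min_fit_px:
        return math.nan
    slope = np.polyfit(z_mm[pos], np.log(seg[pos]), 1)[0]
    return float(-slope / 2.0)


def extract_features(
    ascan: AScan, config: FeatureConfig = FeatureConfig()
) -> FeatureVector:
    """Compose the full per-A-scan feature vector.

    Never raises on degenerate input: any failure (no signal, fewer than two
    peaks) is encoded as ``valid=False`` with missing feature fields. A
    failed attenuation fit on an otherwise valid A-scan leaves
    ``attenuation_mm1`` as NaN (interpreted downstream as "no measurable
    decay behind the TM").
    """
    if float(ascan.intensity.max()) == 0.0:
        return FeatureVector()
    snr = measure_snr(ascan)
    if not has_signal(
        ascan,
        threshold_mult=config.signal_threshold_mult,
        noise_region=_noise_slice(len(ascan), config.noise_fraction),
    ):
        return FeatureVector(snr_db=snr)
    peaks = detect_peaks(ascan, config.min_prominence_rel, config.min_separation_um)
    thick = tm_thickness(ascan, peaks, config.refractive_index)
    if thick is None:
        return FeatureVector(snr_db=snr)
    mu = estimate_attenuation(ascan, peaks=peaks, config=config)
    return FeatureVector(
        tm_thickness_optical_um=thick[0],
        tm_thickness_physical_um=thick[1],
        peak_count=len(peaks),
        attenuation_mm1=mu,
        snr_db=snr,
        valid=True,
    )


def quality_check(
    snr_db: float,
    axial_resolution_um: float,
    thresholds: QualityThresholds = QualityThresholds(),
) -> QualityReport:
    """Gate an acquisition on SNR and axial resolution (both bounds inclusive)."""
    failures = []
    if not snr_db >= thresholds.min_snr_db:
        failures.append(
            f"SNR {snr_db:.1f} dB below required {thresholds.min_snr_db:.1f} dB"
        )
    if not axial_resolution_um <= thresholds.max_axial_resolution_um:
        failures.append(
            f"axial resolution {axial_resolution_um:.1f} um coarser than "
            f"{thresholds.max_axial_resolution_um:.1f} um"
        )
    return QualityReport(
        passed=not failures,
        snr_db=snr_db,
        axial_resolution_um=axial_resolution_um,
        failures=tuple(failures),
    )


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------

FEATURE_TABLE_COLUMNS = (
    "source",
    "column",
    "mode",
    "ear_id",
    "label",
    "valid",
    "snr_db",
    "peak_count",
    "tm_thickness_optical_um",
    "tm_thickness_physical_um",
    "attenuation_mm1",
)


def features_to_frame(
    rows: list[tuple[str, int, str, str, str, FeatureVector]]
):
    """Build the fixed-header feature table.

    ``rows`` are (source, column, mode, ear_id, label, FeatureVector);
    missing values become empty CSV fields via NaN / None.
    """
    import pandas as pd

    records = []
    for source, col, mode, ear_id, label, fv in rows:
        records.append(
            {
                "source": source,
                "column": col,
                "mode": mode,
                "ear_id": ear_id,
                "label": label,
                "valid": fv.valid,
                "snr_db": fv.snr_db,
                "peak_count": fv.peak_count,
                "tm_thickness_optical_um": fv.tm_thickness_optical_um,
                "tm_thickness_physical_um": fv.tm_thickness_physical_um,
                "attenuation_mm1": fv.attenuation_mm1,
            }
        )
    return pd.DataFrame.from_records(records, columns=list(FEATURE_TABLE_COLUMNS))
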