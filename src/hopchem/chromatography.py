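"""Chromatogram handling: peaks, integration, calibration, quantitation.

The quantitation chain mirrors routine UPLC-DAD practice: detect peaks on a
single-wavelength trace, integrate the area above a local baseline, convert
area to solution concentration through a linear calibration curve (or, for
the bitter acids, through response factors derived from the ICE-3 reference
extract of defined w/w composition), then convert to percent of sample dry
weight using the extraction bookkeeping (mass extracted, pooled volume,
dilution).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import signal, stats

from .catalog import BITTER_ACIDS, CompoundCatalogEntry
from .errors import (
    CurveError,
    DegenerateDesignError,
    InputError,
    RangeError,
    StandardMixtureError,
)

__all__ = [
    "Chromatogram",
    "Peak",
    "CalibrationCurve",
    "ExtractionRecord",
    "Ice3Composition",
    "QuantResult",
    "detect_peaks",
    "assign_compounds",
    "integrate_peak",
    "fit_calibration",
    "quantify",
    "quantify_bitter_acids",
    "CONE_EXTRACTION",
    "LEAF_EXTRACTION",
]

FLAG_BELOW_LOWEST = "below lowest calibrant"
FLAG_COELUTING = "coeluting"


@dataclass
class Chromatogram:
    """Single-channel DAD trace: time (min) vs absorbance (mAU)."""

    channel_nm: float
    time_min: np.ndarray
    absorbance_mau: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.absorbance_mau = np.asarray(self.absorbance_mau, dtype=float)
        if self.time_min.ndim != 1 or self.time_min.size < 2:
            raise InputError("chromatogram needs at least 2 samples")
        if self.time_min.shape != self.absorbance_mau.shape:
            raise InputError("time and absorbance lengths differ")
        if not np.all(np.diff(self.time_min) > 0):
            raise InputError("time axis must be strictly increasing")
        if not np.all(np.isfinite(self.absorbance_mau)):
            raise InputError("non-finite absorbance values")

    def to_file(self, path: str | Path) -> None:
        """Plain two-column text with '# key: value' metadata header lines."""
        path = Path(path)
        lines = [f"# channel_nm: {self.channel_nm:g}"]
        for key, value in sorted(self.metadata.items()):
            lines.append(f"# {key}: {value}")
        lines.append("time_min\tabsorbance_mAU")
        for t, a in zip(self.time_min, self.absorbance_mau):
            lines.append(f"{t:.6f}\t{a:.6f}")
        path.write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "Chromatogram":
        meta: dict[str, str] = {}
        times: list[float] = []
        values: list[float] = []
        for raw in Path(path).read_text().splitlines():
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line[1:].partition(":")
                meta[key.strip()] = value.strip()
            elif not line[0].isalpha():  # skip the column-header line
                t, a = line.split()
                times.append(float(t))
                values.append(float(a))
        channel = float(meta.pop("channel_nm", "nan"))
        return cls(channel, np.array(times), np.array(values), metadata=meta)


@dataclass
class Peak:
    """Integrated chromatographic peak."""

    apex_time: float
    window: tuple[float, float]
    area: float  # mAU*min
    height: float  # mAU above local baseline
    compound_id: Optional[str] = None
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        lo, hi = self.window
        if not (lo <= self.apex_time <= hi):
            raise InputError("peak window must contain the apex")
        if self.area < 0 or self.height < 0:
            raise InputError("peak area/height must be non-negative")


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear detector response y = slope*c + intercept, c in mg/ml."""

    compound_id: str
    slope: float
    intercept: float
    r_squared: float
    valid_range: tuple[float, float]

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise InputError("r_squared outside [0, 1]")
        if self.valid_range[0] >= self.valid_range[1]:
            raise InputError("valid_range low must be < high")


@dataclass(frozen=True)
class ExtractionRecord:
    """Sample-prep bookkeeping for area -> percent dry weight conversion."""

    sample_mass_mg: float
    extract_volume_ml: float
    dilution_factor: float = 1.0

    def __post_init__(self) -> None:
        if min(self.sample_mass_mg, self.extract_volume_ml, self.dilution_factor) <= 0:
            raise InputError("extraction parameters must be strictly positive")


# 0.5 g cone powder pooled into 2 x 25 ml; ~200 mg leaf into 2 x 5 ml.
CONE_EXTRACTION = ExtractionRecord(sample_mass_mg=500.0, extract_volume_ml=50.0)
LEAF_EXTRACTION = ExtractionRecord(sample_mass_mg=200.0, extract_volume_ml=10.0)


@dataclass(frozen=True)
class Ice3Composition:
    """ICE-3 reference extract: defined mass fractions (w/w) of the four
    bitter-acid analytes, prepared at a known total concentration."""

    fractions: dict = None  # compound_id -> w/w fraction
    total_concentration_mg_ml: float = 1.0

    def __post_init__(self) -> None:
        if self.fractions is None:
            object.__setattr__(
                self,
                "fractions",
                {"COH": 0.1388, "nADH": 0.3076, "COL": 0.1344, "nADL": 0.1084},
            )
        for cid, frac in self.fractions.items():
            if not 0.0 < frac < 1.0:
                raise InputError(f"ICE-3 fraction for {cid} outside (0, 1)")
        if self.total_concentration_mg_ml <= 0:
            raise InputError("ICE-3 total concentration must be positive")

    def analyte_concentration(self, compound_id: str) -> float:
        return self.fractions[compound_id] * self.total_concentration_mg_ml


@dataclass(frozen=True)
class QuantResult:
    """Quantified analyte amount with provenance flags."""

    compound_id: str
    area: float
    concentration_mg_ml: float
    percent_dw: float
    flags: tuple[str, ...] = ()


def detect_peaks(
    chrom: Chromatogram,
    min_height: float = 3.0,
    min_prominence: float = 2.0,
    min_separation_min: float = 0.05,
) -> list[Peak]:
    """Find local maxima rising above the trace floor.

    Height is measured above the trace's robust floor (median absorbance,
    appropriate for traces that are baseline most of the time).  Maxima
    closer than ``min_separation_min`` collapse to the taller one, so a
    near-isochronous pair reports a single (joint) peak rather than an
    arbitrary noise-driven split.  Each peak's window is delimited by the
    flanking minima or by the return to baseline, whichever comes first;
    the baseline-return threshold adapts to the trace's noise level
    (MAD-based estimate), so windows hug the peaks instead of spanning
    long flat stretches.  Windows of neighbouring peaks stay disjoint.
    """
    if chrom.time_min.size < 3:
        raise InputError("peak detection needs at least 3 samples")
    y = chrom.absorbance_mau
    floor = float(np.median(y))
    noise_sd = 1.4826 * float(np.median(np.abs(y - floor)))
    eps = max(3.0 * noise_sd, 1e-9 * max(float(np.max(y)) - floor, 1.0))
    dt = float(np.median(np.diff(chrom.time_min)))
    distance = max(int(round(min_separation_min / dt)), 1)
    idx, _ = signal.find_peaks(
        y, height=floor + min_height, prominence=min_prominence, distance=distance
    )
    if idx.size == 0:
        return []

    valleys = [0]
    for left, right in zip(idx[:-1], idx[1:]):
        valleys.append(left + int(np.argmin(y[left:right + 1])))
    valleys.append(y.size - 1)

    peaks = []
    for k, apex in enumerate(idx):
        lo = apex
        while lo > valleys[k] and y[lo] > floor + eps:
            lo -= 1
        hi = apex
        while hi < valleys[k + 1] and y[hi] > floor + eps:
            hi += 1
        lo, hi = max(lo, valleys[k]), min(hi, valleys[k + 1])
        if hi - lo < 2:  # guard: degenerate window around a spike
            lo, hi = max(apex - 1, 0), min(apex + 1, y.size - 1)
        window = (float(chrom.time_min[lo]), float(chrom.time_min[hi]))
        area = integrate_peak(chrom, window, baseline="linear_endpoints")
        peaks.append(
            Peak(
                apex_time=float(chrom.time_min[apex]),
                window=window,
                area=area,
                height=max(float(y[apex] - floor), 0.0),
            )
        )
    return peaks


def assign_compounds(
    peaks: Sequence[Peak],
    entries: Sequence[CompoundCatalogEntry],
    tolerance_min: float = 0.05,
) -> list[Peak]:
    """Assign detected peaks to catalogue analytes by retention time.

    Each catalogue entry claims the nearest detected apex within the
    tolerance.  When several entries claim the same peak (co-elution, e.g.
    near-isochronous flavonols 0.02 min apart), the peak is duplicated per
    analyte and flagged ``coeluting``; downstream consumers must treat those
    areas as a joint measurement.  Unassigned peaks are returned unchanged.
    """
    claimed: dict[int, list[CompoundCatalogEntry]] = {}
    for entry in entries:
        best, best_dt = None, tolerance_min
        for i, peak in enumerate(peaks):
            dt = abs(peak.apex_time - entry.rt_min)
            if dt <= best_dt:
                best, best_dt = i, dt
        if best is not None:
            claimed.setdefault(best, []).append(entry)

    out: list[Peak] = []
    for i, peak in enumerate(peaks):
        entries_here = claimed.get(i, [])
        if not entries_here:
            out.append(peak)
        elif len(entries_here) == 1:
            out.append(replace(peak, compound_id=entries_here[0].compound_id))
        else:
            for entry in entries_here:
                out.append(
                    replace(
                        peak,
                        compound_id=entry.compound_id,
                        flags=peak.flags + (FLAG_COELUTING,),
                    )
                )
    return out


def integrate_peak(
    chrom: Chromatogram,
    window: tuple[float, float],
    baseline: str = "linear_endpoints",
) -> float:
    """Trapezoidal area (mAU*min) of signal minus baseline over a window.

    ``baseline='zero'`` integrates the raw signal; ``'linear_endpoints'``
    subtracts the straight line joining the signal values at the window
    edges (robust to constant offsets).  Negative net areas clip to 0.
    """
    lo, hi = window
    if not (lo < hi):
        raise InputError("empty integration window")
    if lo < chrom.time_min[0] - 1e-9 or hi > chrom.time_min[-1] + 1e-9:
        raise InputError("window outside chromatogram time range")
    mask = (chrom.time_min >= lo) & (chrom.time_min <= hi)
    t = chrom.time_min[mask]
    y = chrom.absorbance_mau[mask]
    if t.size < 2:
        raise InputError("window contains fewer than 2 samples")
    if baseline == "zero":
        base = np.zeros_like(y)
    elif baseline == "linear_endpoints":
        base = np.interp(t, [t[0], t[-1]], [y[0], y[-1]])
    else:
        raise InputError(f"unknown baseline mode: {baseline!r}")
    return max(float(np.trapezoid(y - base, t)), 0.0)


def fit_calibration(
    points: Iterable[tuple[float, float]],
    compound_id: str,
) -> CalibrationCurve:
    """Unweighted OLS of area on concentration (y = mx + b)."""
    pts = list(points)
    conc = np.array([c for c, _ in pts], dtype=float)
    area = np.array([a for _, a in pts], dtype=float)
    if conc.size < 2 or np.unique(conc).size < 2:
        raise DegenerateDesignError(
            f"{compound_id}: calibration needs >= 2 distinct concentrations"
        )
    fit = stats.linregress(conc, area)
    # Guard against tiny negative round-off on exact lines.
    r2 = min(max(float(fit.rvalue) ** 2, 0.0), 1.0)
    return CalibrationCurve(
        compound_id=compound_id,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=r2,
        valid_range=(float(conc.min()), float(conc.max())),
    )


def quantify(
    area: float,
    curve: CalibrationCurve,
    extraction: ExtractionRecord,
) -> QuantResult:
    """Convert one peak area to percent dry weight via a calibration curve.

    Responses below the lowest calibrant are reported as-is and flagged
    (relevant for trace marker compounds); responses above the calibrated
    range raise :class:`RangeError` advising dilution.
    """
    if curve.slope <= 0:
        raise CurveError(f"{curve.compound_id}: non-positive calibration slope")
    conc = (area - curve.intercept) / curve.slope
    low, high = curve.valid_range
    if conc > high * (1 + 1e-9):
        raise RangeError(
            f"{curve.compound_id}: response implies {conc:.4g} mg/ml above the "
            f"calibrated range (max {high:g} mg/ml); dilute and re-run"
        )
    flags: tuple[str, ...] = ()
    if conc < low:
        flags = (FLAG_BELOW_LOWEST,)
    conc = max(conc, 0.0) * extraction.dilution_factor
    pct = 100.0 * conc * extraction.extract_volume_ml / extraction.sample_mass_mg
    return QuantResult(curve.compound_id, float(area), float(conc), float(pct), flags)


def quantify_bitter_acids(
    areas: dict[str, float],
    ice3: Ice3Composition,
    ice3_areas: dict[str, float],
    extraction: ExtractionRecord,
) -> dict[str, QuantResult]:
    """Quantify the four bitter-acid analytes against the ICE-3 standard.

    The standard's known w/w composition fixes a per-analyte response
    factor ``area / concentration``; sample areas divide through it.
    """
    missing = [cid for cid in BITTER_ACIDS if cid not in ice3_areas]
    if missing:
        raise StandardMixtureError(f"ICE-3 standard areas missing: {missing}")
    out: dict[str, QuantResult] = {}
    for cid in BITTER_ACIDS:
        std_conc = ice3.analyte_concentration(cid)
        rf = ice3_areas[cid] / std_conc
        if rf <= 0:
            raise StandardMixtureError(f"{cid}: non-positive ICE-3 response factor")
        area = float(areas.get(cid, 0.0))
        conc = max(area / rf, 0.0) * extraction.dilution_factor
        pct = 100.0 * conc * extraction.extract_volume_ml / extraction.sample_mass_mg
        out[cid] = QuantResult(cid, area, conc, pct)
    return out
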