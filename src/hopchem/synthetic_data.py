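"""Seeded synthetic germplasm panels and forward-simulated DAD traces.

The generator emulates the study conditions of a two-subspecies wild-hop
panel: 19 native *lupuloides* and 11 feral *lupulus* accessions, with the
cone marker structure (xanthogalenol and 4'-O-methyl xanthohumol present in
every lupuloides cone, absent in every lupulus cone) and a bimodal leaf
malonyl-flavonol proportion (class means ~0.034 vs ~0.391).  Per-class
trait values are drawn from truncated normal distributions whose means and
truncation bounds follow the published class summaries and column ranges,
so empirical class means converge to the published ones while values never
leave the observed ranges.

Chromatograms are a sum of Gaussian peaks (apex at the catalogue retention
time, area = response_factor x solution concentration) on a constant
baseline with optional white noise — enough structure to exercise the whole
detection/integration/calibration chain, with no tailing, drift, or
gradient modelling.

Every random draw comes from a stream derived from (seed, accession,
tissue/purpose), so panels are reproducible element-by-element and safe to
generate in parallel.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from . import catalog as cat
from .catalog import (
    CompoundCatalogEntry,
    catalog_index,
    default_catalog,
    entries_for,
)
from .chromatography import (
    CONE_EXTRACTION,
    LEAF_EXTRACTION,
    Chromatogram,
    ExtractionRecord,
)
from .errors import CatalogueError, ConfigurationError

__all__ = [
    "TraitDistribution",
    "PanelConfig",
    "SyntheticTruth",
    "default_trait_params",
    "generate_panel",
    "realize_replicate",
    "simulate_trace",
    "simulate_chromatogram",
    "generate_calibration_series",
    "method_duration_min",
]

LUPULOIDES = "lupuloides"
LUPULUS = "lupulus"

# DAD scan rate (20 Hz) expressed per minute of retention time.
POINTS_PER_MIN = 1200
DEFAULT_PEAK_WIDTH_MIN = 0.01  # Gaussian sigma; ~1.4 s FWHM, sub-2-um UPLC
DEFAULT_BASELINE_MAU = 1.0
DEFAULT_NOISE_SD_MAU = 0.2

# Fixed composition of the non-malonylated leaf flavonol pool.
_NONMALONYL_SPLIT = {cat.Q_RUT: 0.35, cat.Q_GLC: 0.25, cat.K_RUT: 0.15, cat.K_GLC: 0.25}
# Xanthohumol dominates the prenylchalcone remainder, desmethylxanthohumol second.
_XHU_SHARE_OF_REMAINDER = 0.72


@dataclass(frozen=True)
class TraitDistribution:
    """Truncated normal: mean/sd with hard truncation at the observed range."""

    mean: float
    sd: float
    low: float
    high: float

    def __post_init__(self) -> None:
        vals = (self.mean, self.sd, self.low, self.high)
        if not all(np.isfinite(vals)):
            raise ConfigurationError(f"non-finite trait parameters: {vals}")
        if self.sd < 0:
            raise ConfigurationError("trait spread must be >= 0")
        if not (self.low <= self.mean <= self.high):
            raise ConfigurationError(
                f"trait range [{self.low}, {self.high}] must contain mean {self.mean}"
            )

    def sample(self, rng: np.random.Generator) -> float:
        if self.sd == 0 or self.low == self.high:
            return self.mean
        loc = _recentred_loc(self.mean, self.sd, self.low, self.high)
        a = (self.low - loc) / self.sd
        b = (self.high - loc) / self.sd
        return float(stats.truncnorm.rvs(a, b, loc=loc, scale=self.sd,
                                         random_state=rng))


from functools import lru_cache


@lru_cache(maxsize=256)
def _recentred_loc(mean: float, sd: float, low: float, high: float) -> float:
    """Location parameter whose *truncated* normal mean equals ``mean``.

    Asymmetric truncation shifts the mean of a truncated normal away from
    its location parameter; recentring keeps empirical class means
    converging to the configured class means.
    """
    from scipy.optimize import brentq

    def mean_error(loc: float) -> float:
        a, b = (low - loc) / sd, (high - loc) / sd
        return stats.truncnorm.mean(a, b, loc=loc, scale=sd) - mean

    lo, hi = low - 5 * sd, high + 5 * sd
    return float(brentq(mean_error, lo, hi, xtol=1e-12))


def default_trait_params() -> dict[str, dict[str, TraitDistribution]]:
    """Per-class trait distributions from the published class summaries.

    Means are the published class averages; truncation bounds are the
    printed per-class column minima/maxima; spreads are set to a quarter of
    the truncated range so draws use the whole observed range without
    piling onto the bounds.
    """
    t = TraitDistribution
    return {
        LUPULOIDES: {
            "total_prenylchalcones": t(0.67, 0.17, 0.47, 1.15),
            "xga": t(0.050, 0.020, 0.0295, 0.111),
            "mxh": t(0.044, 0.015, 0.0254, 0.0868),
            "total_alpha": t(6.65, 1.70, 2.53, 9.38),
            "prop_coh": t(0.41, 0.025, 0.36, 0.47),
            "total_beta": t(6.27, 2.00, 3.97, 12.0),
            "malonyl_proportion": t(0.034, 0.011, 0.021, 0.063),
            "total_flavonols": t(1.20, 0.62, 0.28, 2.77),
        },
        LUPULUS: {
            "total_prenylchalcones": t(0.51, 0.090, 0.29, 0.65),
            "xga": t(0.0, 0.0, 0.0, 0.0),
            "mxh": t(0.0, 0.0, 0.0, 0.0),
            "total_alpha": t(4.58, 1.65, 1.70, 8.31),
            "prop_coh": t(0.26, 0.070, 0.17, 0.36),
            "total_beta": t(4.36, 1.10, 2.12, 6.55),
            "malonyl_proportion": t(0.391, 0.079, 0.221, 0.536),
            "total_flavonols": t(1.20, 0.62, 0.28, 2.77),
        },
    }


@dataclass
class PanelConfig:
    """Panel composition and noise model for a synthetic germplasm study."""

    n_lupuloides: int = 19
    n_lupulus: int = 11
    replicates: int = 3
    replicate_noise_cv: float = 0.05
    kaempferol_to_quercetin_malonyl_ratio: float = 5.0
    seed: int = 0
    trait_params: dict[str, dict[str, TraitDistribution]] = field(
        default_factory=default_trait_params
    )

    def __post_init__(self) -> None:
        if self.n_lupuloides < 0 or self.n_lupulus < 0 or self.replicates < 1:
            raise ConfigurationError("panel counts must be non-negative, replicates >= 1")
        if not np.isfinite(self.replicate_noise_cv) or self.replicate_noise_cv < 0:
            raise ConfigurationError("replicate_noise_cv must be finite and >= 0")
        if self.kaempferol_to_quercetin_malonyl_ratio <= 0:
            raise ConfigurationError("kaempferol:quercetin malonyl ratio must be > 0")


@dataclass
class SyntheticTruth:
    """Ground-truth composition of one synthetic accession."""

    accession_id: str
    subspecies_label: str
    cone_concentrations: dict[str, float]  # compound_id -> % dw
    leaf_abundances: dict[str, float]  # compound_id -> % dw (equivalents scale)
    replicate_noise_cv: float
    seed: int

    def concentrations(self, tissue: str) -> dict[str, float]:
        if tissue == "cone":
            return self.cone_concentrations
        if tissue == "leaf":
            return self.leaf_abundances
        raise ConfigurationError(f"unknown tissue: {tissue!r}")


def _stream(seed: int, *keys: str) -> np.random.Generator:
    """One independent RNG stream per (seed, string-keys) combination."""
    entropy = [int(seed)] + [zlib.crc32(k.encode()) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def _cone_composition(traits: dict[str, float]) -> dict[str, float]:
    xga, mxh = traits["xga"], traits["mxh"]
    remainder = max(traits["total_prenylchalcones"] - xga - mxh, 0.0)
    alpha, beta = traits["total_alpha"], traits["total_beta"]
    p_coh = traits["prop_coh"]
    return {
        cat.XHU: _XHU_SHARE_OF_REMAINDER * remainder,
        cat.DXH: (1 - _XHU_SHARE_OF_REMAINDER) * remainder,
        cat.XGA: xga,
        cat.MXH: mxh,
        cat.COH: p_coh * alpha,
        cat.NADH: (1 - p_coh) * alpha,
        # the co-analogue share of the beta acids tracks the alpha-acid one
        cat.COL: p_coh * beta,
        cat.NADL: (1 - p_coh) * beta,
    }


def _leaf_composition(traits: dict[str, float], kq_ratio: float) -> dict[str, float]:
    total = traits["total_flavonols"]
    p = traits["malonyl_proportion"]
    malonyl = p * total
    k_mal = malonyl * kq_ratio / (1.0 + kq_ratio)
    q_mal = malonyl / (1.0 + kq_ratio)
    rest = (1.0 - p) * total
    out = {cid: frac * rest for cid, frac in _NONMALONYL_SPLIT.items()}
    out[cat.K_MAL] = k_mal
    out[cat.Q_MAL] = q_mal
    return out


def generate_panel(config: PanelConfig) -> list[SyntheticTruth]:
    """Draw a full panel of ground-truth accessions (deterministic per seed)."""
    truths: list[SyntheticTruth] = []
    plan = [(LUPULOIDES, "SYN-LO", config.n_lupuloides),
            (LUPULUS, "SYN-LU", config.n_lupulus)]
    for label, prefix, count in plan:
        params = config.trait_params[label]
        for i in range(1, count + 1):
            accession_id = f"{prefix}-{i:02d}"
            rng = _stream(config.seed, accession_id, "truth")
            traits = {name: dist.sample(rng) for name, dist in sorted(params.items())}
            truths.append(
                SyntheticTruth(
                    accession_id=accession_id,
                    subspecies_label=label,
                    cone_concentrations=_cone_composition(traits),
                    leaf_abundances=_leaf_composition(
                        traits, config.kaempferol_to_quercetin_malonyl_ratio
                    ),
                    replicate_noise_cv=config.replicate_noise_cv,
                    seed=config.seed,
                )
            )
    return truths


def realize_replicate(
    truth: SyntheticTruth, tissue: str, replicate: int
) -> dict[str, float]:
    """One replicate's realized concentrations.

    Replicate scatter is multiplicative log-normal with the configured
    coefficient of variation (unit mean), matching the few-percent standard
    errors typical of triplicate measurements.
    """
    conc = truth.concentrations(tissue)
    cv = truth.replicate_noise_cv
    if cv == 0:
        return dict(conc)
    rng = _stream(truth.seed, truth.accession_id, tissue, f"rep{replicate}")
    sigma = float(np.sqrt(np.log1p(cv**2)))
    factors = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=len(conc))
    return {cid: c * f for (cid, c), f in zip(sorted(conc.items()), factors)}


def method_duration_min(tissue: str) -> float:
    """Gradient length: 8 min for the non-polar cone methods, 10 min polar."""
    return 8.0 if tissue == "cone" else 10.0


def _pct_dw_to_mg_ml(pct: float, extraction: ExtractionRecord) -> float:
    return pct * extraction.sample_mass_mg / (100.0 * extraction.extract_volume_ml)


def simulate_trace(
    concentrations_mg_ml: dict[str, float],
    entries: Sequence[CompoundCatalogEntry],
    duration_min: float,
    noise_sd: float = DEFAULT_NOISE_SD_MAU,
    rng: Optional[np.random.Generator] = None,
    peak_width_min: float = DEFAULT_PEAK_WIDTH_MIN,
    baseline_mau: float = DEFAULT_BASELINE_MAU,
    channel_nm: float = float("nan"),
    metadata: Optional[dict] = None,
) -> Chromatogram:
    """Sum-of-Gaussians forward model over an evenly sampled time axis.

    Each listed analyte contributes a Gaussian apexed at its catalogue
    retention time whose *analytic* area equals response_factor times its
    solution concentration (mg/ml).
    """
    index = {e.compound_id: e for e in entries}
    rts = [e.rt_min for e in entries if concentrations_mg_ml.get(e.compound_id, 0) > 0]
    if rts and max(rts) + 6 * peak_width_min > duration_min:
        duration_min = max(rts) + 6 * peak_width_min
    n = int(round(duration_min * POINTS_PER_MIN)) + 1
    t = np.linspace(0.0, duration_min, n)
    y = np.full(n, baseline_mau, dtype=float)
    for cid, conc in sorted(concentrations_mg_ml.items()):
        if conc <= 0:
            continue
        if cid not in index:
            raise CatalogueError(f"no catalogue entry for nonzero compound {cid!r}")
        entry = index[cid]
        area = entry.response_factor * conc
        amp = area / (peak_width_min * np.sqrt(2.0 * np.pi))
        y += amp * np.exp(-0.5 * ((t - entry.rt_min) / peak_width_min) ** 2)
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        y += rng.normal(0.0, noise_sd, size=n)
    return Chromatogram(channel_nm, t, y, metadata=dict(metadata or {}))


def simulate_chromatogram(
    truth: SyntheticTruth,
    tissue: str,
    channel_nm: int,
    catalog: Optional[Sequence[CompoundCatalogEntry]] = None,
    noise_sd: float = DEFAULT_NOISE_SD_MAU,
    seed: Optional[int] = None,
    replicate: int = 1,
    peak_width_min: float = DEFAULT_PEAK_WIDTH_MIN,
    baseline_mau: float = DEFAULT_BASELINE_MAU,
    extraction: Optional[ExtractionRecord] = None,
    concentrations: Optional[dict[str, float]] = None,
) -> Chromatogram:
    """Simulate one accession/tissue/channel DAD trace.

    Percent-dry-weight truths convert to injected solution concentrations
    through the tissue's extraction record before entering the forward
    model, so the full quantitation chain can be run in reverse on the
    result.  ``concentrations`` overrides the truth map (e.g. with a
    replicate realization from :func:`realize_replicate`).
    """
    catalog = list(catalog) if catalog is not None else default_catalog()
    if extraction is None:
        extraction = CONE_EXTRACTION if tissue == "cone" else LEAF_EXTRACTION
    pct = concentrations if concentrations is not None else truth.concentrations(tissue)
    index = catalog_index(catalog)
    for cid, value in pct.items():
        if value > 0 and cid not in index:
            raise CatalogueError(f"no catalogue entry for nonzero compound {cid!r}")
    entries = entries_for(catalog, tissue, channel_nm)
    visible = {e.compound_id for e in entries}
    mg_ml = {
        cid: _pct_dw_to_mg_ml(value, extraction)
        for cid, value in pct.items()
        if cid in visible
    }
    rng = _stream(
        truth.seed if seed is None else seed,
        truth.accession_id, tissue, f"chrom-{channel_nm}-{replicate}",
    )
    return simulate_trace(
        mg_ml,
        entries,
        duration_min=method_duration_min(tissue),
        noise_sd=noise_sd,
        rng=rng,
        peak_width_min=peak_width_min,
        baseline_mau=baseline_mau,
        channel_nm=channel_nm,
        metadata={
            "accession_id": truth.accession_id,
            "tissue": tissue,
            "replicate": str(replicate),
        },
    )


def generate_calibration_series(
    compound_id: str,
    n_levels: int = 7,
    low: float = 0.001,
    high: float = 0.5,
    n_series: int = 3,
    seed: int = 0,
    noise_cv: float = 0.005,
    response_factor: Optional[float] = None,
) -> list[tuple[float, float]]:
    """Simulated calibration points: geometric levels, replicate dilutions.

    Defaults reproduce the study's calibration design: 7 levels spanning
    0.001-0.5 mg/ml (about 2.5 orders of magnitude) in three independent
    serial dilutions.  Areas carry multiplicative injection noise with a
    sub-percent CV, consistent with fits achieving r^2 > 0.999.
    """
    if not 0 < low < high:
        raise ConfigurationError("calibration range requires 0 < low < high")
    if n_levels < 2 or n_series < 1:
        raise ConfigurationError("need >= 2 levels and >= 1 series")
    if response_factor is None:
        entry = catalog_index(default_catalog()).get(compound_id)
        if entry is None:
            raise CatalogueError(f"unknown compound {compound_id!r}")
        response_factor = entry.response_factor
    levels = low * (high / low) ** (np.arange(n_levels) / (n_levels - 1))
    points: list[tuple[float, float]] = []
    for series in range(n_series):
        rng = _stream(seed, compound_id, f"calibration-{series}")
        for conc in levels:
            area = response_factor * conc
            if noise_cv > 0:
                area *= 1.0 + rng.normal(0.0, noise_cv)
            points.append((float(conc), float(area)))
    return points
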