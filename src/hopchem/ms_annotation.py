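"""Theoretical masses and ESI ion series for flavonol glycoside candidates.

Candidates are built from monoisotopic building blocks: a flavonol
aglycone (kaempferol or quercetin), a glycoside (single hexose or the
disaccharide rutinose), and an optional malonyl ester on the sugar.  In
positive electrospray the quasimolecular ion [M+H]+ dominates, with the
protonated aglycone appearing as an in-source glycoside-loss fragment for
non-acylated candidates.  In negative mode [M-H]- and the proton-bound
dimer [2M-H]- are observed, and malonylated candidates additionally lose
neutral CO2 from the terminal carboxy group, giving the diagnostic
[M-H-CO2]- fragment (written [M-CO2]- in unit-resolution ion tables).

Annotation scores an observed ion list against each candidate's predicted
series by m/z presence alone (relative abundances are tune-dependent and
not scored), with UV lambda-max and retention-time proximity as
tie-breakers: kaempferol glycosides absorb near 347-348 nm, quercetin
glycosides near 354 nm.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .errors import ConfigurationError, InputError

__all__ = [
    "AGLYCONE_MASSES", "SUGAR_INCREMENTS", "ACYL_INCREMENTS",
    "PROTON_MASS", "CO2_MASS",
    "GlycosideCandidate", "IonPrediction", "MatchResult",
    "theoretical_mass", "predict_ions", "annotate_spectrum",
    "default_candidates",
]

# Monoisotopic constants (Da)
AGLYCONE_MASSES = {"kaempferol": 286.0477, "quercetin": 302.0427}
SUGAR_INCREMENTS = {"glucoside": 162.0528, "rutinoside": 308.1107}
ACYL_INCREMENTS = {"none": 0.0, "malonyl": 86.0004}
PROTON_MASS = 1.00728
CO2_MASS = 43.9898

# Typical UV absorbance maxima (nm) of the two aglycone families.
AGLYCONE_LAMBDA_MAX = {"kaempferol": 347.5, "quercetin": 354.0}

POSITIVE = "positive"
NEGATIVE = "negative"


@dataclass(frozen=True)
class GlycosideCandidate:
    """A flavonol glycoside hypothesis: aglycone + sugar + optional acyl."""

    aglycone: str  # kaempferol | quercetin
    sugar: str  # glucoside | rutinoside
    acyl: str = "none"  # none | malonyl
    name: Optional[str] = None
    rt_min: Optional[float] = None

    def __post_init__(self) -> None:
        if self.aglycone not in AGLYCONE_MASSES:
            raise ConfigurationError(f"unknown aglycone {self.aglycone!r}")
        if self.sugar not in SUGAR_INCREMENTS:
            raise ConfigurationError(f"unknown sugar {self.sugar!r}")
        if self.acyl not in ACYL_INCREMENTS:
            raise ConfigurationError(f"unknown acyl group {self.acyl!r}")

    @property
    def monoisotopic_mass(self) -> float:
        return (AGLYCONE_MASSES[self.aglycone]
                + SUGAR_INCREMENTS[self.sugar]
                + ACYL_INCREMENTS[self.acyl])

    @property
    def lambda_max_nm(self) -> float:
        return AGLYCONE_LAMBDA_MAX[self.aglycone]

    @property
    def label(self) -> str:
        if self.name:
            return self.name
        acyl = "(6''-O-malonyl)-" if self.acyl == "malonyl" else ""
        return f"{self.aglycone}-3-O-{acyl}{self.sugar}"


@dataclass(frozen=True)
class IonPrediction:
    species: str  # M+H | aglycone+H | M-H | 2M-H | M-CO2-H
    mz: float
    mode: str  # positive | negative


@dataclass(frozen=True)
class MatchResult:
    candidate: GlycosideCandidate
    score: float  # fraction of predicted ions matched within tolerance
    matched: tuple[tuple[str, float], ...]  # (species, observed mz)


def theoretical_mass(candidate: GlycosideCandidate) -> float:
    """Monoisotopic neutral mass (Da), a sum of building-block constants."""
    return candidate.monoisotopic_mass


def predict_ions(candidate: GlycosideCandidate, mode: str) -> list[IonPrediction]:
    """Singly-charged ion series expected for one candidate in one ESI mode."""
    m = candidate.monoisotopic_mass
    if mode == POSITIVE:
        ions = [IonPrediction("M+H", m + PROTON_MASS, POSITIVE)]
        if candidate.acyl == "none":
            # in-source loss of the glycoside leaves the protonated aglycone
            ions.append(IonPrediction(
                "aglycone+H", AGLYCONE_MASSES[candidate.aglycone] + PROTON_MASS,
                POSITIVE,
            ))
        return ions
    if mode == NEGATIVE:
        ions = [
            IonPrediction("M-H", m - PROTON_MASS, NEGATIVE),
            IonPrediction("2M-H", 2 * m - PROTON_MASS, NEGATIVE),
        ]
        if candidate.acyl == "malonyl":
            ions.append(IonPrediction("M-CO2-H", m - PROTON_MASS - CO2_MASS, NEGATIVE))
        return ions
    raise ConfigurationError(f"unknown ESI mode {mode!r}")


def default_candidates() -> list[GlycosideCandidate]:
    """The six leaf flavonol glycosides observed in hops, with their RTs."""
    c = GlycosideCandidate
    return [
        c("quercetin", "rutinoside", "none", rt_min=3.83),
        c("quercetin", "glucoside", "none", rt_min=3.96),
        c("kaempferol", "rutinoside", "none", rt_min=4.18),
        c("quercetin", "glucoside", "malonyl", rt_min=4.20),
        c("kaempferol", "glucoside", "none", rt_min=4.30),
        c("kaempferol", "glucoside", "malonyl", rt_min=4.60),
    ]


def _score_candidate(
    candidate: GlycosideCandidate,
    observed_by_mode: dict[str, list[tuple[float, float]]],
    tolerance: float,
) -> tuple[float, tuple[tuple[str, float], ...]]:
    predictions = [
        ion for mode in observed_by_mode for ion in predict_ions(candidate, mode)
    ]
    matched = []
    for ion in predictions:
        hits = [mz for mz, _ in observed_by_mode[ion.mode]
                if abs(mz - ion.mz) <= tolerance]
        if hits:
            matched.append((ion.species, min(hits, key=lambda mz: abs(mz - ion.mz))))
    score = len(matched) / len(predictions) if predictions else 0.0
    return score, tuple(matched)


def annotate_spectrum(
    observed: Sequence[tuple[float, float]] | dict[str, Sequence[tuple[float, float]]],
    mode: str = NEGATIVE,
    rt: Optional[float] = None,
    lambda_max: Optional[float] = None,
    catalog: Optional[Sequence[GlycosideCandidate]] = None,
    tolerance: float = 0.5,
) -> list[MatchResult]:
    """Rank glycoside candidates against an observed ion list.

    ``observed`` is either a list of (m/z, relative abundance) pairs for a
    single ESI ``mode``, or a dict mapping mode -> pair list when both
    polarities were recorded for the same peak.  Score is the fraction of
    the candidate's predicted ions matched within ``tolerance`` (Da;
    default 0.5 for unit-resolution instruments); zero-match candidates
    are dropped.  Ties break on lambda-max proximity, then retention-time
    proximity, then candidate name, so the ranking is deterministic.
    """
    if tolerance <= 0:
        raise ConfigurationError("tolerance must be positive")
    if catalog is None:
        catalog = default_candidates()
    if not catalog:
        raise ConfigurationError("empty candidate catalogue")
    if isinstance(observed, dict):
        observed_by_mode = {m: list(v) for m, v in observed.items()}
    else:
        observed_by_mode = {mode: list(observed)}
    if not any(observed_by_mode.values()):
        raise InputError("no observed ions to annotate")
    for m in observed_by_mode:
        if m not in (POSITIVE, NEGATIVE):
            raise ConfigurationError(f"unknown ESI mode {m!r}")

    results = []
    for candidate in catalog:
        score, matched = _score_candidate(candidate, observed_by_mode, tolerance)
        if score > 0:
            results.append(MatchResult(candidate, score, matched))

    def sort_key(res: MatchResult):
        lam_dist = (abs(res.candidate.lambda_max_nm - lambda_max)
                    if lambda_max is not None else 0.0)
        rt_dist = (abs(res.candidate.rt_min - rt)
                   if rt is not None and res.candidate.rt_min is not None else 0.0)
        return (-res.score, lam_dist, rt_dist, res.candidate.label)

    return sorted(results, key=sort_key)
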