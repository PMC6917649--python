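"""Subspecies chemotype rules and their cross-tissue concordance.

Two independent rules identify wild North American (*lupuloides*) versus
feral European (*lupulus*) hops:

* Cone rule — the methylated prenylchalcones xanthogalenol (XGA) and
  4'-O-methyl xanthohumol (MXH) occur only in North American lineages.
  Both present above a trace threshold -> lupuloides; both absent ->
  lupulus.  A single marker on its own matches neither published
  chemotype and is called "atypical" rather than forced into a class.

* Leaf rule — the proportion of malonylated kaempferol/quercetin
  glucosides among total leaf flavonol glycosides is bimodal: below 0.10
  in lupuloides, above 0.20 in lupulus.  Values inside the (0.10, 0.20)
  gap — never observed in the study material — are "indeterminate".

Concordance measures how often the two rules agree where both give a
definite answer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import math

from .chemometrics import ConeProfile, LeafProfile
from .errors import ConfigurationError, InputError

__all__ = [
    "CONE_LUPULOIDES", "CONE_LUPULUS", "CONE_ATYPICAL", "UNAVAILABLE",
    "LEAF_LUPULOIDES", "LEAF_LUPULUS", "LEAF_INDETERMINATE",
    "DEFAULT_PRESENCE_THRESHOLD", "DEFAULT_LEAF_LOW", "DEFAULT_LEAF_HIGH",
    "ChemotypeCall", "classify_cone", "classify_cone_markers",
    "classify_leaf", "classify_leaf_proportion", "make_call",
    "concordance", "subspecies_fractions",
]

CONE_LUPULOIDES = "lupuloides"
CONE_LUPULUS = "lupulus"
CONE_ATYPICAL = "atypical"
UNAVAILABLE = "unavailable"

LEAF_LUPULOIDES = "lupuloides_type"
LEAF_LUPULUS = "lupulus_type"
LEAF_INDETERMINATE = "indeterminate"

# Marker presence floor = lowest calibration level expressed as % dw is of
# the same order; a 0.001 % dw floor keeps noise-driven trace signals from
# flipping calls while leaving every observed marker level (>= 0.025 % dw)
# far above it.
DEFAULT_PRESENCE_THRESHOLD = 0.001
DEFAULT_LEAF_LOW = 0.10
DEFAULT_LEAF_HIGH = 0.20

_CONCORDANT_PAIRS = {
    (CONE_LUPULOIDES, LEAF_LUPULOIDES),
    (CONE_LUPULUS, LEAF_LUPULUS),
}


@dataclass(frozen=True)
class ChemotypeCall:
    """Joint cone/leaf chemotype decision for one accession."""

    site_code: str
    cone_call: str
    leaf_call: str
    concordant: Optional[bool]  # None when either call is not definite


def classify_cone_markers(
    xga: float, mxh: float,
    presence_threshold: float = DEFAULT_PRESENCE_THRESHOLD,
) -> str:
    """Cone chemotype from the two marker concentrations (% dw)."""
    has_xga = xga > presence_threshold
    has_mxh = mxh > presence_threshold
    if has_xga and has_mxh:
        return CONE_LUPULOIDES
    if not has_xga and not has_mxh:
        return CONE_LUPULUS
    return CONE_ATYPICAL


def classify_cone(
    profile: ConeProfile,
    presence_threshold: float = DEFAULT_PRESENCE_THRESHOLD,
) -> str:
    return classify_cone_markers(
        profile.compounds["XGA"], profile.compounds["MXH"], presence_threshold
    )


def classify_leaf_proportion(
    malonyl_proportion: float,
    low: float = DEFAULT_LEAF_LOW,
    high: float = DEFAULT_LEAF_HIGH,
) -> str:
    """Leaf chemotype from the malonyl-flavonol proportion."""
    if not (0.0 <= low < high <= 1.0):
        raise ConfigurationError("need 0 <= low < high <= 1")
    if math.isnan(malonyl_proportion):
        return UNAVAILABLE
    if malonyl_proportion < low:
        return LEAF_LUPULOIDES
    if malonyl_proportion > high:
        return LEAF_LUPULUS
    return LEAF_INDETERMINATE


def classify_leaf(
    profile: LeafProfile,
    low: float = DEFAULT_LEAF_LOW,
    high: float = DEFAULT_LEAF_HIGH,
) -> str:
    return classify_leaf_proportion(profile.malonyl_proportion, low, high)


def make_call(site_code: str, cone_call: str, leaf_call: str) -> ChemotypeCall:
    """Combine the two rules; concordance defined only for definite calls."""
    concordant: Optional[bool] = None
    if cone_call in (CONE_LUPULOIDES, CONE_LUPULUS) and leaf_call in (
        LEAF_LUPULOIDES, LEAF_LUPULUS
    ):
        concordant = (cone_call, leaf_call) in _CONCORDANT_PAIRS
    return ChemotypeCall(site_code, cone_call, leaf_call, concordant)


def concordance(
    calls: Sequence[ChemotypeCall],
) -> tuple[Optional[float], int]:
    """Fraction of evaluable accessions where cone and leaf rules agree.

    Accessions with atypical/indeterminate/unavailable calls are excluded
    from the denominator; with zero evaluable calls the fraction is None.
    """
    if not calls:
        raise InputError("concordance of an empty call list")
    evaluable = [c for c in calls if c.concordant is not None]
    if not evaluable:
        return None, 0
    agree = sum(1 for c in evaluable if c.concordant)
    return agree / len(evaluable), len(evaluable)


def subspecies_fractions(calls: Sequence[ChemotypeCall]) -> dict[str, float]:
    """Proportion of each cone-call category over all calls (sums to 1)."""
    if not calls:
        raise InputError("fractions of an empty call list")
    counts: dict[str, int] = {}
    for call in calls:
        counts[call.cone_call] = counts.get(call.cone_call, 0) + 1
    return {k: v / len(calls) for k, v in sorted(counts.items())}
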