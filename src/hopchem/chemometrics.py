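"""Per-accession trait statistics and group summaries.

Traits follow hop-chemistry conventions: total prenylchalcones (sum of
XHU, DXH, XGA, MXH), total alpha and beta acids, the cohumulone proportion
COH/(total alpha), the alpha ratio P_alpha = alpha/(alpha+beta), and the
leaf malonyl-flavonol proportion (malonylated kaempferol + quercetin
glucosides over total flavonol glycosides).  Ratios with a zero denominator
are reported as NaN rather than raising, since a cone with no bitter acids
is a data problem, not a programming one.

Group summaries are unweighted means over per-accession values — the
convention that reproduces published collection averages from a table of
per-accession means — with the standard error taken across accessions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from . import catalog as cat
from .errors import InputError, SummaryError

__all__ = [
    "ConeProfile",
    "LeafProfile",
    "AccessionRecord",
    "GroupSummary",
    "cone_profile",
    "leaf_profile",
    "aggregate_replicates",
    "group_summary",
    "summarize_trait_table",
    "ENTIRE_COLLECTION",
]

ENTIRE_COLLECTION = "entire collection"


def _check_non_negative(quantified: dict[str, float], required: Sequence[str]) -> None:
    missing = [cid for cid in required if cid not in quantified]
    if missing:
        raise InputError(f"missing compounds: {missing}")
    negative = [cid for cid in required if quantified[cid] < 0]
    if negative:
        raise InputError(f"negative concentrations for: {negative}")


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


@dataclass(frozen=True)
class ConeProfile:
    """Quantified cone composition (% dw) with derived bitter-acid ratios."""

    compounds: dict  # the eight cone analytes, % dw
    total_prenylchalcones: float
    total_alpha: float
    total_beta: float
    coh_proportion: float  # COH / total alpha; NaN when alpha is 0
    alpha_ratio: float  # P_alpha = alpha / (alpha + beta); NaN when both 0


@dataclass(frozen=True)
class LeafProfile:
    """Quantified leaf flavonol glycosides (% dw, equivalents scale)."""

    compounds: dict  # the six flavonol glycosides
    total_flavonols: float
    malonyl_proportion: float  # NaN when total is 0


def cone_profile(quantified: dict[str, float]) -> ConeProfile:
    """Derive cone trait statistics from per-compound % dry weight."""
    _check_non_negative(quantified, cat.CONE_COMPOUNDS)
    comp = {cid: float(quantified[cid]) for cid in cat.CONE_COMPOUNDS}
    alpha = comp[cat.COH] + comp[cat.NADH]
    beta = comp[cat.COL] + comp[cat.NADL]
    return ConeProfile(
        compounds=comp,
        total_prenylchalcones=sum(comp[c] for c in cat.PRENYLCHALCONES),
        total_alpha=alpha,
        total_beta=beta,
        coh_proportion=_ratio(comp[cat.COH], alpha),
        alpha_ratio=_ratio(alpha, alpha + beta),
    )


def leaf_profile(quantified: dict[str, float]) -> LeafProfile:
    """Derive the leaf flavonol trait statistics, incl. malonyl proportion."""
    _check_non_negative(quantified, cat.FLAVONOLS)
    comp = {cid: float(quantified[cid]) for cid in cat.FLAVONOLS}
    total = sum(comp.values())
    malonyl = sum(comp[c] for c in cat.MALONYL_FLAVONOLS)
    return LeafProfile(
        compounds=comp,
        total_flavonols=total,
        malonyl_proportion=_ratio(malonyl, total),
    )


def aggregate_replicates(values: Iterable[float]) -> tuple[float, Optional[float]]:
    """Mean and standard error of replicate measurements.

    SE uses the sample standard deviation (n-1 denominator) over sqrt(n)
    and is None for a single replicate, where it is undefined.
    """
    vals = [float(v) for v in values]
    if not vals:
        raise InputError("cannot aggregate an empty replicate list")
    mean = sum(vals) / len(vals)
    if len(vals) == 1:
        return mean, None
    sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / (len(vals) - 1))
    return mean, sd / math.sqrt(len(vals))


@dataclass
class AccessionRecord:
    """One accession's aggregated trait means (and SEs) over replicates."""

    site_code: str
    habitat: str = ""
    trait_means: dict = field(default_factory=dict)  # trait -> mean
    trait_ses: dict = field(default_factory=dict)  # trait -> SE or None

    @classmethod
    def from_replicates(
        cls,
        site_code: str,
        cone_profiles: Sequence[ConeProfile] = (),
        leaf_profiles: Sequence[LeafProfile] = (),
        habitat: str = "",
    ) -> "AccessionRecord":
        record = cls(site_code=site_code, habitat=habitat)
        cone_traits = {
            "total_prenylchalcones": lambda p: p.total_prenylchalcones,
            "xga": lambda p: p.compounds[cat.XGA],
            "mxh": lambda p: p.compounds[cat.MXH],
            "total_alpha": lambda p: p.total_alpha,
            "prop_coh": lambda p: p.coh_proportion,
            "total_beta": lambda p: p.total_beta,
            "alpha_ratio": lambda p: p.alpha_ratio,
        }
        leaf_traits = {
            "total_flavonols": lambda p: p.total_flavonols,
            "malonyl_proportion": lambda p: p.malonyl_proportion,
        }
        for traits, profiles in ((cone_traits, cone_profiles),
                                 (leaf_traits, leaf_profiles)):
            if not profiles:
                continue
            for name, getter in traits.items():
                mean, se = aggregate_replicates([getter(p) for p in profiles])
                record.trait_means[name] = mean
                record.trait_ses[name] = se
        return record


@dataclass(frozen=True)
class GroupSummary:
    group_label: str
    n: int
    trait_means: dict  # trait -> unweighted mean over accessions
    trait_ses: dict  # trait -> SE over accessions (None for n = 1)


def group_summary(
    records: Sequence[AccessionRecord],
    labels: dict[str, str],
    include_entire_collection: bool = True,
) -> list[GroupSummary]:
    """Unweighted per-group means/SEs of accession-level trait means."""
    unlabelled = [r.site_code for r in records if r.site_code not in labels]
    if unlabelled:
        raise SummaryError(f"records without a group label: {unlabelled}")
    groups: dict[str, list[AccessionRecord]] = {}
    for rec in records:
        groups.setdefault(labels[rec.site_code], []).append(rec)
    if include_entire_collection and records:
        groups[ENTIRE_COLLECTION] = list(records)
    out = []
    for label in groups:
        members = groups[label]
        if not members:
            raise SummaryError(f"empty group: {label!r}")
        traits = sorted({t for rec in members for t in rec.trait_means})
        means, ses = {}, {}
        for trait in traits:
            values = [rec.trait_means[trait] for rec in members
                      if trait in rec.trait_means]
            means[trait], ses[trait] = aggregate_replicates(values)
        out.append(GroupSummary(label, len(members), means, ses))
    return out


def summarize_trait_table(
    table: pd.DataFrame,
    trait_cols: Sequence[str],
    group_col: str = "subspecies",
    include_entire_collection: bool = True,
) -> pd.DataFrame:
    """Group mean/SE table from a tidy per-accession trait DataFrame.

    This is the tabular twin of :func:`group_summary`, convenient for
    trait tables loaded straight from file (one row per accession).
    """
    frames = []
    groups = [(g, df) for g, df in table.groupby(group_col, sort=True)]
    if include_entire_collection:
        groups.append((ENTIRE_COLLECTION, table))
    for label, df in groups:
        row: dict[str, object] = {group_col: label, "n": len(df)}
        for col in trait_cols:
            mean, se = aggregate_replicates(df[col].astype(float))
            row[f"{col}_mean"] = mean
            row[f"{col}_se"] = se
        frames.append(row)
    return pd.DataFrame(frames)
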