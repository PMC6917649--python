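"""Analyte catalogue: identities, retention times, channels, response factors.

The catalogue drives both the forward simulator (where does each analyte
elute, how strongly does it absorb) and peak-to-compound assignment during
quantitation.  Cone analytes are measured on the short non-polar gradient
(8 min) with prenylchalcones quantified at 370 nm and the bitter acids at
320 nm; leaf flavonol glycosides run on the polar gradient (10 min) at
350 nm.

Retention times for the leaf flavonols are the published values; the cone
analytes' times are catalogue defaults that respect the observed elution
order on the 8-minute gradient (DXH < XGA < XHU < MXH, and COH < n+ADH <
COL < n+ADL).

Response factors are integrated-area responses in mAU*min per (mg/ml).
Analytes quantified "as equivalents" of a reference compound (all
prenylchalcones as xanthohumol; all flavonols as quercetin-3-O-rutinoside)
share that reference's response factor, so equivalent-scale amounts and
true amounts coincide in the forward model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

# Quantitation channels (nm)
CHANNEL_BITTER_ACIDS = 320
CHANNEL_PRENYLCHALCONES = 370
CHANNEL_FLAVONOLS = 350

# Compound ids
XHU = "XHU"  # xanthohumol
DXH = "DXH"  # desmethylxanthohumol
XGA = "XGA"  # xanthogalenol (marker)
MXH = "MXH"  # 4'-O-methyl xanthohumol (marker)
COH = "COH"  # cohumulone
NADH = "nADH"  # humulone + adhumulone (one peak)
COL = "COL"  # colupulone
NADL = "nADL"  # lupulone + adlupulone (one peak)

Q_RUT = "quercetin-3-O-rutinoside"
Q_GLC = "quercetin-3-O-glucoside"
K_RUT = "kaempferol-3-O-rutinoside"
Q_MAL = "quercetin-3-O-(6''-O-malonyl)-glucoside"
K_GLC = "kaempferol-3-O-glucoside"
K_MAL = "kaempferol-3-O-(6''-O-malonyl)-glucoside"

PRENYLCHALCONES = (XHU, DXH, XGA, MXH)
ALPHA_ACIDS = (COH, NADH)
BETA_ACIDS = (COL, NADL)
BITTER_ACIDS = ALPHA_ACIDS + BETA_ACIDS
CONE_COMPOUNDS = PRENYLCHALCONES + BITTER_ACIDS
FLAVONOLS = (Q_RUT, Q_GLC, K_RUT, Q_MAL, K_GLC, K_MAL)
MALONYL_FLAVONOLS = (Q_MAL, K_MAL)
MARKER_COMPOUNDS = (XGA, MXH)


@dataclass(frozen=True)
class CompoundCatalogEntry:
    """One analyte: identity, chromatographic behaviour, detector response."""

    compound_id: str
    compound_class: str  # prenylchalcone | alpha_acid | beta_acid | flavonol
    tissue: str  # cone | leaf
    rt_min: float
    quant_channel_nm: int
    response_factor: float  # mAU*min per (mg/ml)
    lambda_max_nm: Optional[float] = None
    monoisotopic_mass: Optional[float] = None


# Reference response factors (equivalents convention, see module docstring).
_RF_XHU = 2400.0
_RF_QRUT = 3000.0


def default_catalog() -> list[CompoundCatalogEntry]:
    """The 14-analyte catalogue used throughout the synthetic study."""
    e = CompoundCatalogEntry
    return [
        # cone prenylchalcones, 370 nm, 8-min gradient
        e(DXH, "prenylchalcone", "cone", 2.90, CHANNEL_PRENYLCHALCONES, _RF_XHU,
          monoisotopic_mass=340.1311),
        e(XGA, "prenylchalcone", "cone", 3.40, CHANNEL_PRENYLCHALCONES, _RF_XHU,
          monoisotopic_mass=354.1467),
        e(XHU, "prenylchalcone", "cone", 3.90, CHANNEL_PRENYLCHALCONES, _RF_XHU,
          monoisotopic_mass=354.1467),
        e(MXH, "prenylchalcone", "cone", 4.40, CHANNEL_PRENYLCHALCONES, _RF_XHU,
          monoisotopic_mass=368.1624),
        # cone bitter acids, 320 nm; n+ad isomers co-report as one peak
        e(COH, "alpha_acid", "cone", 1.70, CHANNEL_BITTER_ACIDS, 250.0,
          monoisotopic_mass=348.1937),
        e(NADH, "alpha_acid", "cone", 2.10, CHANNEL_BITTER_ACIDS, 250.0,
          monoisotopic_mass=362.2093),
        e(COL, "beta_acid", "cone", 5.00, CHANNEL_BITTER_ACIDS, 200.0,
          monoisotopic_mass=400.2614),
        e(NADL, "beta_acid", "cone", 5.60, CHANNEL_BITTER_ACIDS, 200.0,
          monoisotopic_mass=414.2770),
        # leaf flavonol glycosides, 350 nm, 10-min polar gradient
        e(Q_RUT, "flavonol", "leaf", 3.83, CHANNEL_FLAVONOLS, _RF_QRUT,
          lambda_max_nm=354.0, monoisotopic_mass=610.1534),
        e(Q_GLC, "flavonol", "leaf", 3.96, CHANNEL_FLAVONOLS, _RF_QRUT,
          lambda_max_nm=354.0, monoisotopic_mass=464.0955),
        e(K_RUT, "flavonol", "leaf", 4.18, CHANNEL_FLAVONOLS, _RF_QRUT,
          lambda_max_nm=347.0, monoisotopic_mass=594.1584),
        e(Q_MAL, "flavonol", "leaf", 4.20, CHANNEL_FLAVONOLS, _RF_QRUT,
          lambda_max_nm=354.0, monoisotopic_mass=550.0959),
        e(K_GLC, "flavonol", "leaf", 4.30, CHANNEL_FLAVONOLS, _RF_QRUT,
          lambda_max_nm=348.0, monoisotopic_mass=448.1005),
        e(K_MAL, "flavonol", "leaf", 4.60, CHANNEL_FLAVONOLS, _RF_QRUT,
          lambda_max_nm=348.0, monoisotopic_mass=534.1009),
    ]


def catalog_index(catalog: list[CompoundCatalogEntry]) -> dict[str, CompoundCatalogEntry]:
    return {entry.compound_id: entry for entry in catalog}


def entries_for(catalog: list[CompoundCatalogEntry], tissue: str,
                channel_nm: int) -> list[CompoundCatalogEntry]:
    """Catalogue entries visible on one tissue/channel, in elution order."""
    sel = [c for c in catalog if c.tissue == tissue and c.quant_channel_nm == channel_nm]
    return sorted(sel, key=lambda c: c.rt_min)
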