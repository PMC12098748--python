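"""Marker gene panels for TAM classification and polarization labeling.

Panels follow the field's convention: microglia-derived TAMs (Mg-TAM) and
monocyte-derived TAMs (Mo-TAM) are scored from fixed ontogeny marker lists,
while inflammatory polarization uses pro- and anti-inflammatory marker sets.
Symbols are human-style (upper case); :func:`to_mouse_symbols` converts to the
mouse title-case convention.  TGFBI legitimately appears in both the
anti-inflammatory and the Mo-TAM panel.
"""

from __future__ import annotations

MG_TAM_PANEL = ["P2RY12", "CX3CR1", "NAV3", "SIGLEC8", "SLC1A3"]
MO_TAM_PANEL = ["TGFBI", "ITGA4", "IFITM2", "FPR3", "S100A11", "KYNU"]
PRO_INFLAMMATORY_PANEL = ["CCL3", "CD83", "IL1B", "TNF"]
ANTI_INFLAMMATORY_PANEL = ["CD163", "LGALS1", "LGALS3", "LYZ", "RNASE1", "TGFBI", "VIM"]

AMPAR_GENES = ["Gria1", "Gria2", "Gria3", "Gria4"]

TSP1_HUMAN = "THBS1"
TSP1_MOUSE = "Thbs1"

DEFAULT_PANELS: dict[str, list[str]] = {
    "pro": list(PRO_INFLAMMATORY_PANEL),
    "anti": list(ANTI_INFLAMMATORY_PANEL),
    "mg": list(MG_TAM_PANEL),
    "mo": list(MO_TAM_PANEL),
}


def to_mouse_symbol(symbol: str) -> str:
    """Human SYMBOL -> mouse Symbol (first letter upper, rest lower)."""
    return symbol[:1].upper() + symbol[1:].lower()


def to_mouse_symbols(symbols: list[str]) -> list[str]:
    return [to_mouse_symbol(s) for s in symbols]
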