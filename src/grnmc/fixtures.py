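"""The packaged A. thaliana root stem-cell-niche models.

The nine-gene network couples the auxin pathway (AUXINS -| IAA -| ARF ->
PLT) to the SHR/SCR module with its JKD/MGP/WOX5 feedbacks. Three
variants ship as data files:

* ``root_scn.eq`` — the nine equations; every rule deterministic;
* ``root_scn_scr_star.tables`` — SCR as a truth table over SHR, SCR, JKD,
  MGP with one indeterminate row (SHR=1, SCR=1, JKD=0, MGP=1 -> ``*``),
  the unresolved jkd-background behavior;
* ``root_scn_fas0.tables`` — the fas mutant: every SCR row indeterminate.

``TABLE2_PROFILES`` holds the four expected expression profiles of the
niche cell types (quiescent center, vascular, cortex/endodermis and
epidermis/root-cap initials); under asynchronous updates they are exactly
the Auxin-active stable steady states of the equation model.
"""

from __future__ import annotations

from importlib import resources

from .network import GRN, parse_equations, parse_tables
from .statespace import encode

__all__ = [
    "root_scn",
    "root_scn_scr_star",
    "root_scn_scr_star_resolved",
    "root_scn_fas0",
    "fixture_text",
    "TABLE2_PROFILES",
    "profile_index",
]

TABLE2_PROFILES: dict[str, dict[str, int]] = {
    "QC": dict(PLT=1, AUXINS=1, ARF=1, IAA=0, SHR=1, SCR=1, JKD=1, MGP=0, WOX=1),
    "Vascular": dict(PLT=1, AUXINS=1, ARF=1, IAA=0, SHR=1, SCR=0, JKD=0, MGP=0, WOX=0),
    "CEI": dict(PLT=1, AUXINS=1, ARF=1, IAA=0, SHR=1, SCR=1, JKD=1, MGP=1, WOX=0),
    "CEpI": dict(PLT=1, AUXINS=1, ARF=1, IAA=0, SHR=0, SCR=0, JKD=0, MGP=0, WOX=0),
}


def fixture_text(name: str) -> str:
    return (resources.files("grnmc") / "data" / name).read_text()


def root_scn() -> GRN:
    """The equation model (star-free; all rules deterministic)."""
    return parse_equations(fixture_text("root_scn.eq"))


def root_scn_scr_star() -> GRN:
    """Table model with the single indeterminate SCR row kept."""
    return parse_tables(fixture_text("root_scn_scr_star.tables"))


def root_scn_scr_star_resolved(value: int) -> GRN:
    """The star row resolved to 0 or 1. The 0-resolution is pointwise equal
    to the equation model; the 1-resolution is the variant in which SCR
    stays expressed in a jkd background."""
    if value not in (0, 1):
        raise ValueError("value must be 0 or 1")
    text = fixture_text("root_scn_scr_star.tables").replace(": *", f": {value}")
    return parse_tables(text)


def root_scn_fas0() -> GRN:
    """The fas mutant: SCR fully indeterminate."""
    return parse_tables(fixture_text("root_scn_fas0.tables"))


def profile_index(grn: GRN, profile: dict[str, int]) -> int:
    """State index of a gene->value profile in ``grn``'s numbering."""
    return encode([profile[name] for name in grn.names])
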