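"""Enzyme models for chromatin digestion.

Each enzyme is described by a per-base cutting hazard modifier set: an
overall rate (scaled linearly by concentration ``units``), a preference for
linker over nucleosome-protected DNA, an optional sequence bias, and
enzyme-specific end chemistry (nicking for DNase I, exonucleolytic end
trimming for MNase, asymmetric 3'-overhang cleavage for S1).

``g_bias`` is specified on the observable scale: it is the realized
fold-enrichment of guanine at the first base of a digestion fragment
relative to the genomic background.  The per-site hazard multiplier that
produces this enrichment is derived internally from the genome's G
frequency (see :func:`nucleocut.simulate.digest.digest`).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["EnzymeModel", "s1", "mnase", "dnase_i", "restriction"]


@dataclass
class EnzymeModel:
    """Parameters of a chromatin-digesting nuclease.

    Attributes
    ----------
    name
        Enzyme family (``S1``, ``MNase``, ``DNaseI``, or a restriction
        enzyme name).
    units
        Concentration in arbitrary units; hazard scales linearly with it.
    cut_rate
        Expected cuts per kb of fully accessible DNA per unit.
    linker_preference
        Extra hazard multiplier in linker vs. nucleosome-protected DNA
        (steric footprint protection itself is a chromatin property of the
        genome model, not of the enzyme).
    g_bias
        Target fold-enrichment of G at the +1 position of cut sites.
    nick_fraction
        Fraction of cut events that are single-strand nicks (DNase I);
        nicks do not delimit fragments, they flag the nearest fragment end.
    exo_trim
        Mean bp trimmed from free fragment ends toward the nearest
        protected footprint (MNase exonuclease activity).
    overhang_3p
        Length of the 3'-sticky end left by asymmetric cleavage (S1); the
        blunted fragment end is recessed by this many bp.
    recognition_site
        If set, the enzyme cuts only at occurrences of this motif
        (restriction model); ``cut_rate`` is then the per-site cut
        probability per unit.
    """

    name: str
    units: float
    cut_rate: float
    linker_preference: float = 1.0
    g_bias: float = 1.0
    nick_fraction: float = 0.0
    exo_trim: float = 0.0
    overhang_3p: int = 0
    recognition_site: str | None = None

    def __post_init__(self) -> None:
        if self.units < 0 or self.cut_rate < 0 or self.exo_trim < 0:
            raise ValueError("rates must be >= 0")
        if self.linker_preference < 1:
            raise ValueError("linker_preference must be >= 1")
        if not 0 <= self.nick_fraction <= 1:
            raise ValueError("nick_fraction must be in [0, 1]")
        if self.g_bias <= 0:
            raise ValueError("g_bias must be > 0")


def s1(units: float = 1000.0) -> EnzymeModel:
    """S1 nuclease: sequence-agnostic, slight G preference at +1,
    asymmetric cleavage leaving 3'-sticky ends, no nicking, no
    exonuclease trimming."""
    return EnzymeModel(
        name="S1", units=units, cut_rate=0.05, linker_preference=3.0,
        g_bias=2.0, nick_fraction=0.0, exo_trim=0.0, overhang_3p=2,
    )


def mnase(units: float = 1000.0) -> EnzymeModel:
    """MNase: strong linker preference and concentration-scaled
    exonucleolytic trimming toward the nucleosome footprint."""
    return EnzymeModel(
        name="MNase", units=units, cut_rate=0.002, linker_preference=50.0,
        g_bias=1.0, nick_fraction=0.0, exo_trim=0.15 * units, overhang_3p=0,
    )


def dnase_i(units: float = 500.0) -> EnzymeModel:
    """DNase I: sequence-agnostic with a high single-strand nicking
    fraction (the source of dangling ends in DNase I proximity-ligation
    libraries)."""
    return EnzymeModel(
        name="DNaseI", units=units, cut_rate=0.03, linker_preference=4.0,
        g_bias=1.0, nick_fraction=0.4, exo_trim=0.0, overhang_3p=0,
    )


def restriction(site: str = "GATC", units: float = 1000.0) -> EnzymeModel:
    """Restriction-enzyme model (DpnII/MboI-like): cuts only at motif
    occurrences, with per-site cut probability ``units * cut_rate``."""
    return EnzymeModel(
        name=f"RE[{site}]", units=units, cut_rate=5e-4,
        linker_preference=1.0, g_bias=1.0, recognition_site=site,
    )
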