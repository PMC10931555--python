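"""Sample-composition arithmetic for drug-in-surfactant mixtures.

Drug loading is reported in weight percent with respect to the surfactant
mass; the corresponding lipid-per-drug mole ratio uses the surfactant's
average relative molar mass (762 g/mol for the porcine extract studied
here) and the drug molar mass (budesonide, 430.53 g/mol).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["SampleComposition", "molar_ratio", "ratio_label",
           "BUDESONIDE_MW", "SURFACTANT_MW"]

#: Budesonide molar mass, g/mol.
BUDESONIDE_MW = 430.53
#: Average relative molar mass used for the surfactant lipid mixture, g/mol.
SURFACTANT_MW = 762.0


@dataclass
class SampleComposition:
    """Drug loading of a surfactant sample.

    ``bud_wt_pct`` is grams of drug per 100 g of surfactant; ``ca_mmol``
    the Ca2+ concentration of the hydration medium in mmol/L (metadata
    only).
    """

    bud_wt_pct: float = 0.0
    M_bud: float = BUDESONIDE_MW
    M_lipid: float = SURFACTANT_MW
    ca_mmol: float = 0.0

    def __post_init__(self):
        if self.bud_wt_pct < 0:
            raise ValueError("bud_wt_pct must be >= 0")
        if self.M_bud <= 0 or self.M_lipid <= 0:
            raise ValueError("molar masses must be > 0")


def molar_ratio(comp: SampleComposition) -> float:
    """Moles of surfactant lipid per mole of drug.

    For w wt% of drug per 100 g surfactant:
    r = (100 / M_lipid) / (w / M_bud). Raises for w = 0 (no finite ratio).
    """
    if comp.bud_wt_pct == 0:
        raise ValueError("bud_wt_pct = 0: lipid-per-drug ratio is not finite")
    return (100.0 / comp.M_lipid) / (comp.bud_wt_pct / comp.M_bud)


def ratio_label(r: float) -> str:
    """Human-readable "1:N" form, rounded to the nearest integer."""
    return f"1:{round(r):d}"
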