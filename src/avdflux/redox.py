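"""NADPH supply accounting and the GapN/GAPDH deconvolution.

The four NADPH-forming routes of the producer strains differ in the
carbon they burn: the oxidative PP pathway yields 2 NADPH per CO2
released, isocitrate dehydrogenase 1 NADPH per 2 CO2 (a full TCA turn),
malic enzyme 1 NADPH per CO2, and GapN 1 NADPH with no CO2 at all.
From a fitted flux vector this module tallies per-pathway NADPH and CO2
fluxes (percent of glucose uptake), splits the total
glyceraldehyde-3-phosphate dehydrogenase flux into its NAD+ and NADP+
dependent components by closing the NADPH balance at a stated total
demand, and reports the carbon economy (NADPH formed per CO2 released).

13C labeling cannot separate GAPDH from GapN — both transfer the same
three carbons — which is exactly why the NADPH balance is needed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .network import FluxVector

__all__ = [
    "RedoxStoichiometry",
    "RedoxLedger",
    "GapNSplit",
    "nadph_supply",
    "deconvolve_gapn",
    "carbon_economy",
    "NADPH_DEMAND_AVD",
]

#: Total NADPH demand of the 5-AVD producers, % of glucose uptake.  The
#: value is the summed NADPH-forming flux of the GapN-free reference
#: strain (oxPPP + ICD + malic enzyme), carried over to the GapN strain
#: under the assumption of equal growth and product formation.
NADPH_DEMAND_AVD = 250.0


@dataclass(frozen=True)
class RedoxStoichiometry:
    """(NADPH, CO2) formed per unit pathway flux.

    Keys are pathway names; defaults encode oxPPP (2, 1), GapN (1, 0),
    TCA/ICD (1, 2) and malic enzyme (1, 1).
    """

    coefficients: dict = field(
        default_factory=lambda: {
            "oxPPP": (2.0, 1.0),
            "GapN": (1.0, 0.0),
            "TCA_ICD": (1.0, 2.0),
            "malic_enzyme": (1.0, 1.0),
        }
    )

    def __post_init__(self) -> None:
        for name, (nadph, co2) in self.coefficients.items():
            if nadph < 0 or co2 < 0:
                raise ValueError(f"negative stoichiometry for {name}")


#: Mapping from ledger pathway names to reaction ids of the shipped network.
DEFAULT_PATHWAY_REACTIONS = {
    "oxPPP": "oxppp",
    "GapN": "gapn",
    "TCA_ICD": "cs_icd",
    "malic_enzyme": "mae",
}


@dataclass
class RedoxLedger:
    """Per-pathway NADPH/CO2 fluxes (% of glucose uptake) and totals."""

    nadph: dict
    co2: dict
    total_nadph: float
    total_co2: float
    nadph_per_co2: float
    contributions_percent: dict

    def to_dict(self) -> dict:
        return {
            "nadph_flux_percent": self.nadph,
            "co2_flux_percent": self.co2,
            "total_nadph_percent": self.total_nadph,
            "total_co2_percent": self.total_co2,
            "nadph_per_co2": self.nadph_per_co2,
            "contributions_percent": self.contributions_percent,
        }


def nadph_supply(
    v: FluxVector | dict,
    stoich: RedoxStoichiometry | None = None,
    pathway_reactions: dict | None = None,
) -> RedoxLedger:
    """Tally the NADPH supply of a flux vector.

    ``v`` may be a FluxVector or a plain mapping of pathway name ->
    flux; ``pathway_reactions`` maps pathway names to reaction ids when
    a FluxVector is given.  Pathways absent from the mapping default to
    zero flux only if explicitly mapped to None; a mapped reaction
    missing from the vector is an error naming it.
    """
    stoich = stoich or RedoxStoichiometry()
    mapping = pathway_reactions or DEFAULT_PATHWAY_REACTIONS
    fluxes: dict[str, float] = {}
    for pathway in stoich.coefficients:
        if isinstance(v, FluxVector):
            rid = mapping.get(pathway)
            if rid is None:
                fluxes[pathway] = 0.0
                continue
            if rid not in v.net:
                raise KeyError(f"flux vector lacks reaction {rid!r} for pathway {pathway}")
            fluxes[pathway] = max(v.net[rid], 0.0)
        else:
            if pathway not in v:
                raise KeyError(f"flux mapping lacks pathway {pathway!r}")
            fluxes[pathway] = max(float(v[pathway]), 0.0)
    nadph = {}
    co2 = {}
    for pathway, flux in fluxes.items():
        cn, cc = stoich.coefficients[pathway]
        nadph[pathway] = cn * flux
        co2[pathway] = cc * flux
    total_n = sum(nadph.values())
    total_c = sum(co2.values())
    ratio = total_n / total_c if total_c > 0 else math.inf
    contrib = (
        {p: 100.0 * x / total_n for p, x in nadph.items()}
        if total_n > 0
        else {p: 0.0 for p in nadph}
    )
    return RedoxLedger(
        nadph=nadph, co2=co2, total_nadph=total_n, total_co2=total_c,
        nadph_per_co2=ratio, contributions_percent=contrib,
    )


@dataclass
class GapNSplit:
    """Result of the NADPH-balance deconvolution of the GAP node."""

    gapn_flux: float
    gapdh_flux: float
    gapn_fraction_percent: float


def deconvolve_gapn(
    v_partial: FluxVector | dict,
    total_gap_flux: float,
    nadph_demand_total: float = NADPH_DEMAND_AVD,
    stoich: RedoxStoichiometry | None = None,
    pathway_reactions: dict | None = None,
) -> GapNSplit:
    """Split the total GAP-dehydrogenase flux into GapN and GAPDH.

    The measurable NADPH-forming fluxes (oxPPP, ICD, malic enzyme) are
    summed from ``v_partial``; the remaining difference to the stated
    total NADPH demand is assigned to GapN, and the NAD+-dependent
    GAPDH carries the rest of the GAP node.
    """
    stoich = stoich or RedoxStoichiometry()
    partial_stoich = RedoxStoichiometry(
        {p: c for p, c in stoich.coefficients.items() if p != "GapN"}
    )
    ledger = nadph_supply(v_partial, partial_stoich, pathway_reactions)
    measurable = ledger.total_nadph
    gapn = nadph_demand_total - measurable
    if gapn < -1e-9:
        raise ValueError(
            f"NADPH demand {nadph_demand_total}% already exceeded by measurable "
            f"sources ({measurable}%)"
        )
    gapn = max(gapn, 0.0)
    if gapn > total_gap_flux + 1e-9:
        raise ValueError(
            f"inferred GapN flux {gapn}% exceeds the total GAP node flux {total_gap_flux}%"
        )
    gapdh = total_gap_flux - gapn
    fraction = 100.0 * gapn / total_gap_flux if total_gap_flux > 0 else 0.0
    return GapNSplit(gapn_flux=gapn, gapdh_flux=gapdh, gapn_fraction_percent=fraction)


def carbon_economy(ledger: RedoxLedger) -> float:
    """NADPH formed per CO2 released across the NADPH-forming pathways.

    Returns +inf (tagged sentinel, not an exception) when no
    decarboxylating NADPH source carries flux, so pipelines can report
    a carbon-free NADPH supply.
    """
    if ledger.total_co2 <= 0:
        return math.inf
    return ledger.total_nadph / ledger.total_co2
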