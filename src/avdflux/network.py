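"""Atom-mapped metabolic network representation.

A network is a list of reactions with carbon atom transitions written as
letter strings (``abcdef -> abc + def``), the convention of 13C-MFA
model files.  Metabolites whose name ends in ``.ext`` are external
(substrate feeds, secreted products, vented CO2); everything else is
balanced at steady state.  Anabolic precursor drains are attached from a
separate table and become sink reactions with fixed fluxes, expressed as
percent of the glucose uptake rate.

Only carbon is atom-mapped; hydrogen, oxygen and nitrogen enter through
per-reaction signed cofactor counts (NADPH, NADH, ATP, O2, NH4), which
feed the redox accounting and the cofactor demand queries.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import linprog

__all__ = [
    "AtomMapVariant",
    "Reaction",
    "NetworkModel",
    "FluxVector",
    "NetworkValidationError",
    "load_network",
    "serialize_network",
    "load_drains",
    "flux_balance_residual",
    "cofactor_demand",
]


class NetworkValidationError(ValueError):
    """A structural defect in a network definition."""


@dataclass(frozen=True)
class AtomMapVariant:
    """One carbon-transition variant of a reaction.

    ``substrate_atoms``/``product_atoms`` hold one letter string per
    metabolite occurrence; equal-weight variants encode the scrambling
    of symmetric intermediates (succinate/fumarate, meso-DAP).
    """

    substrate_atoms: tuple[str, ...]
    product_atoms: tuple[str, ...]
    weight: float = 1.0

    def source_of(self, prod_occ: int, atom_pos: int) -> tuple[int, int]:
        """(substrate occurrence, 0-based atom position) feeding a product atom."""
        letter = self.product_atoms[prod_occ][atom_pos]
        for occ, letters in enumerate(self.substrate_atoms):
            pos = letters.find(letter)
            if pos >= 0:
                return occ, pos
        raise KeyError(f"letter {letter!r} not on substrate side")


@dataclass
class Reaction:
    id: str
    substrates: list[str]
    products: list[str]
    atom_maps: list[AtomMapVariant] = field(default_factory=list)
    reversible: bool = False
    cofactors: dict[str, float] = field(default_factory=dict)

    @property
    def is_mapped(self) -> bool:
        return bool(self.atom_maps)

    def validate(self, carbon_counts: dict[str, int]) -> None:
        for var in self.atom_maps:
            if len(var.substrate_atoms) != len(self.substrates):
                raise NetworkValidationError(
                    f"reaction {self.id}: atom map has {len(var.substrate_atoms)} "
                    f"substrate strings for {len(self.substrates)} substrates"
                )
            if len(var.product_atoms) != len(self.products):
                raise NetworkValidationError(
                    f"reaction {self.id}: atom map has {len(var.product_atoms)} "
                    f"product strings for {len(self.products)} products"
                )
            sub_letters = "".join(var.substrate_atoms)
            prod_letters = "".join(var.product_atoms)
            if len(set(sub_letters)) != len(sub_letters):
                raise NetworkValidationError(
                    f"reaction {self.id}: duplicate atom letter on substrate side"
                )
            if len(set(prod_letters)) != len(prod_letters):
                raise NetworkValidationError(
                    f"reaction {self.id}: duplicate atom letter on product side"
                )
            if self.products and len(sub_letters) != len(prod_letters):
                raise NetworkValidationError(
                    f"reaction {self.id}: carbon imbalance in atom map "
                    f"({len(sub_letters)} substrate atoms vs {len(prod_letters)} product atoms)"
                )
            if not set(prod_letters) <= set(sub_letters):
                raise NetworkValidationError(
                    f"reaction {self.id}: product atom letters not drawn from substrate side"
                )
            for met, letters in zip(
                self.substrates + self.products,
                var.substrate_atoms + var.product_atoms,
            ):
                known = carbon_counts.setdefault(met, len(letters))
                if known != len(letters):
                    raise NetworkValidationError(
                        f"reaction {self.id}: {met} mapped with {len(letters)} carbons, "
                        f"elsewhere {known}"
                    )
        weights = sum(v.weight for v in self.atom_maps)
        if self.atom_maps and abs(weights - 1.0) > 1e-9:
            raise NetworkValidationError(
                f"reaction {self.id}: atom map variant weights sum to {weights}, expected 1"
            )


def _is_external(met: str) -> bool:
    return met.endswith(".ext")


@dataclass
class NetworkModel:
    """Validated atom-mapped network with optional anabolic drains."""

    reactions: list[Reaction]
    drain_fluxes: dict[str, float] = field(default_factory=dict)
    carbon_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.reactions]
        if len(set(ids)) != len(ids):
            raise NetworkValidationError("duplicate reaction ids")
        self.carbon_counts = dict(self.carbon_counts)
        for rxn in self.reactions:
            rxn.validate(self.carbon_counts)
        self._check_orphans()

    # -- structure ---------------------------------------------------------

    @property
    def metabolites(self) -> set[str]:
        mets: set[str] = set()
        for r in self.reactions:
            mets.update(r.substrates)
            mets.update(r.products)
        return mets

    @property
    def external_metabolites(self) -> set[str]:
        return {m for m in self.metabolites if _is_external(m)}

    @property
    def balanced_metabolites(self) -> list[str]:
        return sorted(m for m in self.metabolites if not _is_external(m))

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def reaction(self, rxn_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == rxn_id:
                return r
        raise KeyError(f"no reaction {rxn_id!r}")

    def _check_orphans(self) -> None:
        produced: set[str] = set()
        consumed: set[str] = set()
        for r in self.reactions:
            consumed.update(r.substrates)
            produced.update(r.products)
            if r.reversible:
                produced.update(r.substrates)
                consumed.update(r.products)
        for met in self.balanced_metabolites:
            if met not in produced or met not in consumed:
                raise NetworkValidationError(
                    f"balanced metabolite {met} is not both produced and consumed"
                )

    def stoich_matrix(self) -> pd.DataFrame:
        """S over balanced metabolites x reactions (net directions)."""
        mets = self.balanced_metabolites
        S = pd.DataFrame(0.0, index=mets, columns=self.reaction_ids)
        for r in self.reactions:
            for met in r.substrates:
                if met in S.index:
                    S.loc[met, r.id] -= 1.0
            for met in r.products:
                if met in S.index:
                    S.loc[met, r.id] += 1.0
        return S

    def attach_drains(self, drains: dict[str, float]) -> None:
        """Add fixed-flux anabolic sink reactions (percent of uptake)."""
        for met, flux in drains.items():
            if flux < 0:
                raise NetworkValidationError(f"drain flux for {met} is negative")
            if met not in self.metabolites:
                raise NetworkValidationError(f"drain precursor {met} not in network")
            rid = f"drain_{met}"
            if rid not in self.reaction_ids:
                self.reactions.append(
                    Reaction(id=rid, substrates=[met], products=[], atom_maps=[])
                )
            self.drain_fluxes[rid] = float(flux)

    @property
    def drain_reaction_ids(self) -> list[str]:
        return sorted(self.drain_fluxes)


@dataclass
class FluxVector:
    """Net fluxes (% of glucose uptake = 100) and exchange fluxes (>= 0)."""

    net: dict[str, float]
    exchange: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for rid, x in self.exchange.items():
            if x < 0:
                raise ValueError(f"exchange flux of {rid} is negative")

    def scaled(self, factor: float) -> "FluxVector":
        return FluxVector(
            net={k: v * factor for k, v in self.net.items()},
            exchange={k: v * factor for k, v in self.exchange.items()},
        )

    def as_series(self) -> pd.Series:
        return pd.Series(self.net, dtype=float)


# -- file dialect ----------------------------------------------------------


def _parse_side(side: str) -> list[str]:
    side = side.strip()
    if not side:
        return []
    return [tok.strip() for tok in side.split("+")]


def _parse_transitions(text, n_sub: int, n_prod: int) -> list[AtomMapVariant]:
    if text is None or (isinstance(text, float) and np.isnan(text)):
        text = ""
    text = str(text).strip()
    if not text:
        return []
    variants = [v.strip() for v in text.split(";") if v.strip()]
    maps = []
    for var in variants:
        if "->" in var:
            left, right = var.split("->")
        else:
            left, right = var, ""
        maps.append(
            AtomMapVariant(
                substrate_atoms=tuple(_parse_side(left)),
                product_atoms=tuple(_parse_side(right)),
                weight=1.0 / len(variants),
            )
        )
    return maps


def _parse_cofactors(text) -> dict[str, float]:
    if text is None or (isinstance(text, float) and np.isnan(text)):
        text = ""
    text = str(text).strip()
    if not text:
        return {}
    out: dict[str, float] = {}
    for tok in text.split():
        name, val = tok.split(":")
        out[name] = float(val)
    return out


def load_network(path: str | Path, drains: str | Path | dict[str, float] | None = None) -> NetworkModel:
    """Load a network CSV (``rxn_id, equation, atom_transitions, reversible, cofactors``).

    Raises :class:`NetworkValidationError` naming the offending reaction
    on carbon imbalance or malformed atom maps.  ``drains`` optionally
    attaches anabolic sink fluxes from a CSV (``precursor, flux_percent``)
    or a dict.
    """
    df = pd.read_csv(path, comment="#", skipinitialspace=True, dtype=str)
    required = {"rxn_id", "equation", "atom_transitions", "reversible"}
    if not required <= set(df.columns):
        raise NetworkValidationError(f"network file missing columns {required - set(df.columns)}")
    reactions = []
    for _, row in df.iterrows():
        eq = row["equation"]
        if "->" not in eq:
            raise NetworkValidationError(f"reaction {row['rxn_id']}: equation lacks '->'")
        left, right = eq.split("->")
        subs, prods = _parse_side(left), _parse_side(right)
        reactions.append(
            Reaction(
                id=row["rxn_id"].strip(),
                substrates=subs,
                products=prods,
                atom_maps=_parse_transitions(row.get("atom_transitions", ""), len(subs), len(prods)),
                reversible=str(row["reversible"]).strip() in ("1", "True", "true"),
                cofactors=_parse_cofactors(row.get("cofactors", "")),
            )
        )
    model = NetworkModel(reactions=reactions)
    if drains is not None:
        model.attach_drains(drains if isinstance(drains, dict) else load_drains(drains))
    return model


def load_drains(path: str | Path) -> dict[str, float]:
    """Read a drain CSV ``precursor, flux_percent`` into a dict."""
    df = pd.read_csv(path, comment="#", skipinitialspace=True)
    return dict(zip(df["precursor"].astype(str).str.strip(), df["flux_percent"].astype(float)))


def serialize_network(model: NetworkModel, path: str | Path | None = None) -> str:
    """Write the network back to the CSV dialect (drains excluded)."""
    rows = []
    for r in model.reactions:
        if r.id in model.drain_fluxes:
            continue
        eq = " + ".join(r.substrates) + " -> " + " + ".join(r.products)
        trans = "; ".join(
            " + ".join(v.substrate_atoms) + " -> " + " + ".join(v.product_atoms)
            for v in r.atom_maps
        )
        cof = " ".join(f"{k}:{v:g}" for k, v in r.cofactors.items())
        rows.append(
            {"rxn_id": r.id, "equation": eq, "atom_transitions": trans,
             "reversible": int(r.reversible), "cofactors": cof}
        )
    buf = io.StringIO()
    pd.DataFrame(rows).to_csv(buf, index=False)
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text)
    return text


# -- balance and cofactor queries ------------------------------------------


def flux_balance_residual(model: NetworkModel, v: FluxVector) -> float:
    """max |S.v| over balanced metabolites (drain fluxes filled in)."""
    S = model.stoich_matrix()
    full = dict(model.drain_fluxes)
    full.update(v.net)
    missing = set(S.columns) - set(full)
    if missing:
        raise ValueError(f"flux vector missing reactions: {sorted(missing)}")
    vec = np.array([full[c] for c in S.columns])
    return float(np.max(np.abs(S.to_numpy() @ vec))) if len(S) else 0.0


def cofactor_demand(model: NetworkModel, target: str, cofactor: str = "NADPH") -> float:
    """Net mol of a cofactor consumed per mol of target synthesized.

    Solves a minimal-total-flux route (linear program: S.v = e_target with
    biomass drains zeroed, v >= 0 after splitting reversible reactions)
    and sums the signed cofactor counts along it.  A vanishing secondary
    cost on cofactor-producing reactions breaks the tie between the
    canonical route and cofactor-regenerating bypasses (GAPDH vs GapN),
    so the query reports the pathway's intrinsic requirement.
    """
    if target not in model.metabolites or _is_external(target):
        raise ValueError(f"target {target!r} is not a balanced metabolite")
    cols: list[tuple[str, int]] = []  # (rxn_id, direction)
    for r in model.reactions:
        if r.id in model.drain_fluxes:
            continue  # biomass drains zeroed
        cols.append((r.id, +1))
        if r.reversible:
            cols.append((r.id, -1))
    mets = model.balanced_metabolites
    midx = {m: i for i, m in enumerate(mets)}
    A = np.zeros((len(mets), len(cols)))
    c = np.ones(len(cols))
    eps = 1e-3
    for j, (rid, sign) in enumerate(cols):
        r = model.reaction(rid)
        for met in r.substrates:
            if met in midx:
                A[midx[met], j] -= sign
        for met in r.products:
            if met in midx:
                A[midx[met], j] += sign
        produced = sign * r.cofactors.get(cofactor, 0.0)
        if produced > 0:
            c[j] += eps * produced
    b = np.zeros(len(mets))
    b[midx[target]] = 1.0
    res = linprog(c, A_eq=A, b_eq=b, bounds=(0, None), method="highs")
    if not res.success:
        raise ValueError(f"no biosynthetic route to {target!r} found")
    demand = 0.0
    for j, (rid, sign) in enumerate(cols):
        demand -= res.x[j] * sign * model.reaction(rid).cofactors.get(cofactor, 0.0)
    return float(demand)
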