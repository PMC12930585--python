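"""Elementary metabolite unit (EMU) simulation of 13C labeling.

Given an atom-mapped network, a steady-state flux vector and a tracer
mixture, this module predicts the mass isotopomer distribution (MID) of
any fragment.  The EMU decomposition finds the minimal set of atom
subsets whose labeling must be balanced to predict the targets; the
resulting balances are linear per EMU size, so the full nonlinear
isotopomer system collapses into a cascade of small dense solves
(size 1, then 2, ... up to the substrate carbon number).  Condensation
reactions couple levels through convolutions of smaller EMU MIDs.

Reversible reactions are simulated as forward/backward pairs derived
from (net, exchange) fluxes; symmetric-intermediate scrambling enters
through equal-weight atom-map variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .isotopes import NATURAL_13C
from .network import FluxVector, NetworkModel

__all__ = [
    "TracerSpec",
    "EMUNode",
    "substrate_mid",
    "EMUSimulator",
    "decompose_emu",
    "simulate_mids",
    "natural_glucose",
    "glucose_1_13c",
    "glucose_u13c_mix",
]


@dataclass(frozen=True)
class TracerSpec:
    """An isotopic tracer mixture for one substrate feed.

    ``components`` is a list of (positional pattern, molar fraction);
    patterns are strings of 0/1 per carbon ('1' = nominally 13C) or 'U'
    for uniform labeling.  Each nominally labeled position is 13C with
    probability ``purity``; unlabeled positions carry natural abundance.
    """

    substrate: str
    components: tuple[tuple[str, float], ...]
    purity: float = 0.99

    def __post_init__(self) -> None:
        total = sum(f for _, f in self.components)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"tracer fractions sum to {total}, expected 1")
        if not 0.0 < self.purity <= 1.0:
            raise ValueError("purity must be in (0, 1]")

    def expanded_patterns(self, n_carbon: int) -> list[tuple[str, float]]:
        out = []
        for pattern, frac in self.components:
            if pattern.upper() == "U":
                pattern = "1" * n_carbon
            if len(pattern) != n_carbon or set(pattern) - {"0", "1"}:
                raise ValueError(
                    f"pattern {pattern!r} invalid for {n_carbon}-carbon substrate"
                )
            out.append((pattern, frac))
        return out


@dataclass(frozen=True)
class EMUNode:
    """A metabolite together with a subset of its carbon atoms (1-based)."""

    metabolite: str
    atoms: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "atoms", tuple(sorted(self.atoms)))
        if len(set(self.atoms)) != len(self.atoms) or any(a < 1 for a in self.atoms):
            raise ValueError("EMU atoms must be unique 1-based indices")

    @property
    def size(self) -> int:
        return len(self.atoms)


def substrate_mid(tracer: TracerSpec, atoms: tuple[int, ...], n_carbon: int) -> np.ndarray:
    """Exact MID of a substrate EMU under the tracer mixture.

    Convex combination over tracer components of the per-atom label
    distributions restricted to the EMU's atom positions.
    """
    atoms = tuple(sorted(atoms))
    if any(a < 1 or a > n_carbon for a in atoms):
        raise ValueError(f"atoms {atoms} outside 1..{n_carbon}")
    mid = np.zeros(len(atoms) + 1)
    labeled = np.array([1.0 - tracer.purity, tracer.purity])
    natural = np.array([1.0 - NATURAL_13C, NATURAL_13C])
    for pattern, frac in tracer.expanded_patterns(n_carbon):
        comp = np.array([1.0])
        for a in atoms:
            comp = np.convolve(comp, labeled if pattern[a - 1] == "1" else natural)
        mid += frac * comp
    return mid


# -- internal expanded-reaction form --------------------------------------


@dataclass
class _SimpleReaction:
    """A unidirectional mapped reaction (reversibles expanded to pairs)."""

    orig_id: str
    direction: int  # +1 forward, -1 backward
    substrates: list[str]
    products: list[str]
    variants: list  # AtomMapVariant


def _expand_reactions(model: NetworkModel) -> list[_SimpleReaction]:
    simple: list[_SimpleReaction] = []
    for r in model.reactions:
        simple.append(
            _SimpleReaction(r.id, +1, list(r.substrates), list(r.products), list(r.atom_maps))
        )
        if r.reversible:
            from .network import AtomMapVariant

            inv = [
                AtomMapVariant(
                    substrate_atoms=v.product_atoms,
                    product_atoms=v.substrate_atoms,
                    weight=v.weight,
                )
                for v in r.atom_maps
            ]
            simple.append(_SimpleReaction(r.id, -1, list(r.products), list(r.substrates), inv))
    return simple


def _expand_fluxes(
    model: NetworkModel, simple: list[_SimpleReaction], v: FluxVector, strict: bool = True
) -> np.ndarray:
    net = dict(model.drain_fluxes)
    net.update(v.net)
    out = np.zeros(len(simple))
    for i, sr in enumerate(simple):
        if sr.orig_id not in net:
            raise ValueError(f"flux vector missing reaction {sr.orig_id!r}")
        n = net[sr.orig_id]
        x = v.exchange.get(sr.orig_id, 0.0)
        if model.reaction(sr.orig_id).reversible:
            out[i] = x + max(n, 0.0) if sr.direction > 0 else x + max(-n, 0.0)
        else:
            if strict and n < -1e-9:
                raise ValueError(f"irreversible reaction {sr.orig_id} has negative flux {n}")
            out[i] = max(n, 0.0) if sr.direction > 0 else 0.0
    return out


# -- decomposition ---------------------------------------------------------

_INPUT = "input"
_INTERNAL = "internal"
_CONV = "conv"


@dataclass
class _Level:
    """All precomputed index structure for one EMU size."""

    size: int
    unknowns: list[EMUNode]
    knowns: list[tuple]  # ('input', node) or ('conv', tuple of source keys)
    diag: list[tuple[int, int, float]] = field(default_factory=list)  # (i, rxn, count)
    internal_terms: list[tuple[int, int, int, float]] = field(default_factory=list)
    known_terms: list[tuple[int, int, int, float]] = field(default_factory=list)


class EMUSimulator:
    """Decomposed EMU network for a fixed set of target fragments.

    Build once per (model, targets); :meth:`simulate` is then a cheap
    cascade of dense linear solves for any flux vector and tracer.
    """

    def __init__(self, model: NetworkModel, targets: list[tuple[str, tuple[int, ...]]]):
        self.model = model
        self.targets = [EMUNode(met, tuple(atoms)) for met, atoms in targets]
        self.simple = _expand_reactions(model)
        self._decompose()

    # decomposition ........................................................

    def _producers(self, met: str):
        for ridx, sr in enumerate(self.simple):
            for pocc, pmet in enumerate(sr.products):
                if pmet == met:
                    yield ridx, sr, pocc

    def _consumption_counts(self, met: str) -> list[tuple[int, int]]:
        out = []
        for ridx, sr in enumerate(self.simple):
            cnt = sr.substrates.count(met)
            if cnt:
                out.append((ridx, cnt))
        return out

    def _decompose(self) -> None:
        external = self.model.external_metabolites
        terms: dict[EMUNode, list] = {}
        stack = [t for t in self.targets if t.metabolite not in external]
        seen: set[EMUNode] = set()
        while stack:
            node = stack.pop()
            if node in seen:
                continue
            seen.add(node)
            node_terms = []
            producers = list(self._producers(node.metabolite))
            if not producers:
                raise ValueError(
                    f"metabolite {node.metabolite} is not produced by any reaction; "
                    f"EMU {node} unreachable from substrates"
                )
            for ridx, sr, pocc in producers:
                for var in sr.variants:
                    groups: dict[int, list[int]] = {}
                    for a in node.atoms:
                        socc, spos = var.source_of(pocc, a - 1)
                        groups.setdefault(socc, []).append(spos + 1)
                    sources = []
                    for socc in sorted(groups):
                        smet = sr.substrates[socc]
                        snode = EMUNode(smet, tuple(groups[socc]))
                        if smet in external:
                            sources.append((_INPUT, snode))
                        else:
                            sources.append((_INTERNAL, snode))
                            stack.append(snode)
                    node_terms.append((ridx, var.weight, tuple(sources)))
            terms[node] = node_terms
        self._build_levels(terms)

    def _build_levels(self, terms: dict[EMUNode, list]) -> None:
        sizes = sorted({n.size for n in terms})
        self.levels: list[_Level] = []
        self._solution_index: dict[EMUNode, tuple[int, int]] = {}  # node -> (level idx, row)
        for size in sizes:
            unknowns = sorted(
                (n for n in terms if n.size == size),
                key=lambda n: (n.metabolite, n.atoms),
            )
            lvl = _Level(size=size, unknowns=unknowns, knowns=[])
            uidx = {n: i for i, n in enumerate(unknowns)}
            kidx: dict[tuple, int] = {}

            def known_index(key: tuple) -> int:
                if key not in kidx:
                    kidx[key] = len(lvl.knowns)
                    lvl.knowns.append(key)
                return kidx[key]

            for node in unknowns:
                i = uidx[node]
                for ridx, cnt in self._consumption_counts(node.metabolite):
                    lvl.diag.append((i, ridx, float(cnt)))
                for ridx, weight, sources in terms[node]:
                    if len(sources) == 1:
                        kind, snode = sources[0]
                        if kind == _INTERNAL:
                            lvl.internal_terms.append((i, uidx[snode], ridx, weight))
                        else:
                            k = known_index((_INPUT, snode))
                            lvl.known_terms.append((i, k, ridx, weight))
                    else:
                        k = known_index((_CONV, sources))
                        lvl.known_terms.append((i, k, ridx, weight))
            for li, node in enumerate(unknowns):
                self._solution_index[node] = (len(self.levels), li)
            self.levels.append(lvl)

    # simulation ...........................................................

    def _input_mid(self, node: EMUNode, tracer: TracerSpec) -> np.ndarray:
        n_carbon = self.model.carbon_counts.get(node.metabolite)
        if n_carbon is None:
            raise ValueError(f"unknown carbon count for {node.metabolite}")
        if node.metabolite != tracer.substrate:
            # non-tracer external feed: natural abundance
            unlabeled = TracerSpec(node.metabolite, (("0" * n_carbon, 1.0),))
            return substrate_mid(unlabeled, node.atoms, n_carbon)
        return substrate_mid(tracer, node.atoms, n_carbon)

    def simulate(
        self, v: FluxVector, tracer: TracerSpec, strict: bool = True
    ) -> dict[EMUNode, np.ndarray]:
        """Steady-state MIDs of all target EMUs for one flux vector.

        With ``strict=False`` small stoichiometric violations (clipped
        negative fluxes during optimization) are tolerated and the MIDs
        renormalized instead of raising.
        """
        fluxes = _expand_fluxes(self.model, self.simple, v, strict=strict)
        solved: dict[EMUNode, np.ndarray] = {}

        def mid_of(kind: str, node: EMUNode) -> np.ndarray:
            if kind == _INPUT:
                return self._input_mid(node, tracer)
            return solved[node]

        for lvl in self.levels:
            n = len(lvl.unknowns)
            width = lvl.size + 1
            A = np.zeros((n, n))
            for i, ridx, cnt in lvl.diag:
                A[i, i] -= cnt * fluxes[ridx]
            for i, j, ridx, w in lvl.internal_terms:
                A[i, j] += w * fluxes[ridx]
            if np.any(np.abs(np.diag(A)) < 1e-12):
                dead = [lvl.unknowns[i].metabolite for i in range(n) if abs(A[i, i]) < 1e-12]
                raise ValueError(
                    f"zero throughput at EMU size {lvl.size} for metabolite(s) {sorted(set(dead))}"
                )
            Y = np.zeros((len(lvl.knowns), width))
            for k, key in enumerate(lvl.knowns):
                if key[0] == _INPUT:
                    Y[k] = mid_of(*key)
                else:
                    conv = np.array([1.0])
                    for kind, snode in key[1]:
                        conv = np.convolve(conv, mid_of(kind, snode))
                    Y[k] = conv
            B = np.zeros((n, len(lvl.knowns)))
            for i, k, ridx, w in lvl.known_terms:
                B[i, k] += w * fluxes[ridx]
            X = np.linalg.solve(A, -B @ Y) if len(lvl.knowns) else np.linalg.solve(A, np.zeros((n, width)))
            tol = 1e-6 if strict else 0.5
            for i, node in enumerate(lvl.unknowns):
                mid = X[i]
                total = mid.sum()
                if not np.isfinite(total) or abs(total - 1.0) > tol or total <= 0:
                    raise ValueError(
                        f"EMU balance for {node} failed to normalize (sum={total}); "
                        "check that the flux vector is stoichiometrically balanced"
                    )
                solved[node] = mid / total
        out = {}
        for t in self.targets:
            if t.metabolite in self.model.external_metabolites:
                out[t] = self._input_mid(t, tracer)
            else:
                out[t] = solved[t]
        return out


def decompose_emu(
    model: NetworkModel, targets: list[tuple[str, tuple[int, ...]]]
) -> list[EMUNode]:
    """EMU decomposition for target fragments; returns nodes ordered by size."""
    sim = EMUSimulator(model, targets)
    nodes = [n for lvl in sim.levels for n in lvl.unknowns]
    return nodes


def simulate_mids(
    model: NetworkModel,
    v: FluxVector,
    tracer: TracerSpec,
    fragments: dict[str, tuple[str, tuple[int, ...]]],
) -> dict[str, np.ndarray]:
    """Simulate fragment MIDs: ``fragments`` maps id -> (metabolite, atoms)."""
    sim = EMUSimulator(model, list(fragments.values()))
    res = sim.simulate(v, tracer)
    return {fid: res[EMUNode(met, tuple(atoms))] for fid, (met, atoms) in fragments.items()}


# -- tracers used in the study ---------------------------------------------


def natural_glucose() -> TracerSpec:
    """Naturally labeled glucose."""
    return TracerSpec("GLC.ext", (("000000", 1.0),))


def glucose_1_13c(purity: float = 0.99) -> TracerSpec:
    """[1-13C] glucose."""
    return TracerSpec("GLC.ext", (("100000", 1.0),), purity=purity)


def glucose_u13c_mix(purity: float = 0.99) -> TracerSpec:
    """1:1 mixture of naturally labeled and [U-13C6] glucose."""
    return TracerSpec("GLC.ext", (("000000", 0.5), ("U", 0.5)), purity=purity)
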