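"""Brute-force isotopomer oracle, independent of the EMU code path.

Tracks the full joint isotopomer distribution of every balanced
metabolite (a (2,)*n tensor over its carbon labeling states) and
iterates the steady-state balance to a fixed point.  Cleavage is
marginalization of the substrate tensor; condensation is the outer
product of independent well-mixed pools — the same steady-state
assumptions as the analytical simulator, realized by exhaustive
enumeration instead of EMU decomposition.
"""

from __future__ import annotations

import numpy as np

NATURAL_13C = 0.0107


def _expand(model):
    """Unidirectional (substrates, products, variants, orig_id, direction)."""
    out = []
    for r in model.reactions:
        out.append((list(r.substrates), list(r.products), list(r.atom_maps), r.id, +1))
        if r.reversible:
            inv = [
                type(v)(
                    substrate_atoms=v.product_atoms,
                    product_atoms=v.substrate_atoms,
                    weight=v.weight,
                )
                for v in r.atom_maps
            ]
            out.append((list(r.products), list(r.substrates), inv, r.id, -1))
    return out


def _fluxes(model, fv, simple):
    net = dict(model.drain_fluxes)
    net.update(fv.net)
    vals = []
    for subs, prods, variants, rid, direction in simple:
        n = net[rid]
        x = fv.exchange.get(rid, 0.0)
        if model.reaction(rid).reversible:
            vals.append(x + max(n, 0.0) if direction > 0 else x + max(-n, 0.0))
        else:
            vals.append(max(n, 0.0) if direction > 0 else 0.0)
    return np.array(vals)


def _tracer_tensor(tracer, n_carbon):
    """Joint labeling tensor of the tracer substrate (independent atoms per component)."""
    total = np.zeros((2,) * n_carbon)
    for pattern, frac in tracer.components:
        if pattern.upper() == "U":
            pattern = "1" * n_carbon
        t = np.array(1.0)
        for ch in pattern:
            p = tracer.purity if ch == "1" else NATURAL_13C
            t = np.multiply.outer(t, np.array([1.0 - p, p]))
        total += frac * t
    return total


def _produced_tensor(subs, variant, pocc, dists, n_carbons):
    """Joint labeling tensor of one product occurrence."""
    prod_met_atoms = len(variant.product_atoms[pocc])
    # group product atoms by source substrate occurrence
    groups: dict[int, list[tuple[int, int]]] = {}
    for i in range(prod_met_atoms):
        socc, spos = variant.source_of(pocc, i)
        groups.setdefault(socc, []).append((i, spos))
    tensor = np.array(1.0)
    axis_to_prod_atom: list[int] = []
    for socc in sorted(groups):
        pairs = groups[socc]
        sub_met = subs[socc]
        dist = dists[sub_met]
        keep = sorted(p[1] for p in pairs)
        drop = tuple(ax for ax in range(n_carbons[sub_met]) if ax not in keep)
        marg = dist.sum(axis=drop) if drop else dist
        # axes of marg follow ascending substrate positions `keep`
        spos_to_prod = {spos: i for i, spos in pairs}
        tensor = np.multiply.outer(tensor, marg)
        axis_to_prod_atom.extend(spos_to_prod[s] for s in keep)
    order = np.argsort(axis_to_prod_atom)
    return np.transpose(tensor, axes=order)


def isotopomer_mids(model, fv, tracer, targets, n_iter=5000, tol=1e-13):
    """MIDs of target (metabolite, atoms) pairs by isotopomer fixed point."""
    simple = _expand(model)
    flux = _fluxes(model, fv, simple)
    external = model.external_metabolites
    internal = [m for m in model.balanced_metabolites]
    nc = dict(model.carbon_counts)

    inputs = {}
    for m in external:
        if m == tracer.substrate:
            inputs[m] = _tracer_tensor(tracer, nc[m])
        elif m in nc:
            nat = np.array(1.0)
            for _ in range(nc[m]):
                nat = np.multiply.outer(nat, np.array([1.0 - NATURAL_13C, NATURAL_13C]))
            inputs[m] = nat

    consumption = {m: 0.0 for m in internal}
    for (subs, prods, variants, rid, d), f in zip(simple, flux):
        for s in subs:
            if s in consumption:
                consumption[s] += f

    dists = {}
    for m in internal:
        nat = np.array(1.0)
        for _ in range(nc[m]):
            nat = np.multiply.outer(nat, np.array([1.0 - NATURAL_13C, NATURAL_13C]))
        dists[m] = nat

    def lookup(met):
        return inputs[met] if met in inputs else dists[met]

    for _ in range(n_iter):
        new = {m: np.zeros_like(dists[m]) for m in internal}
        for (subs, prods, variants, rid, d), f in zip(simple, flux):
            if f == 0.0:
                continue
            for variant in variants:
                for pocc, pmet in enumerate(prods):
                    if pmet in new:
                        src = {s: lookup(s) for s in subs}
                        new[pmet] += f * variant.weight * _produced_tensor(
                            subs, variant, pocc, src, nc
                        )
        delta = 0.0
        for m in internal:
            if consumption[m] <= 0:
                raise ValueError(f"metabolite {m} has zero consumption")
            new[m] /= consumption[m]
            delta = max(delta, np.max(np.abs(new[m] - dists[m])))
        dists = new
        if delta < tol:
            break
    else:
        raise RuntimeError("isotopomer fixed point did not converge")

    out = {}
    for met, atoms in targets:
        dist = inputs[met] if met in inputs else dists[met]
        atoms0 = sorted(a - 1 for a in atoms)
        drop = tuple(ax for ax in range(nc[met]) if ax not in atoms0)
        marg = dist.sum(axis=drop) if drop else dist
        k = len(atoms0)
        mid = np.zeros(k + 1)
        for idx in np.ndindex(*marg.shape):
            mid[sum(idx)] += marg[idx]
        out[(met, tuple(sorted(atoms)))] = mid / mid.sum()
    return out
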