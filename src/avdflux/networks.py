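"""Shipped network models.

``central_network()`` loads the reconstructed C. glutamicum central
metabolism (EMP, PP pathway, TCA with anaplerosis and malic enzyme,
lysine/5-AVD branch, GapN) from the package data files; the file is
editable and swappable for a laboratory's own atom-transition table.
The toy networks are small fully-enumerable models used to validate the
EMU simulator against brute-force isotopomer accounting.
"""

from __future__ import annotations

from importlib import resources

from .network import AtomMapVariant, NetworkModel, Reaction, load_network

__all__ = [
    "central_network",
    "toy_linear",
    "toy_cleave",
    "toy_split_recombine",
    "toy_networks",
]


def _data_path(name: str) -> str:
    return str(resources.files("avdflux.data").joinpath(name))


def central_network(with_drains: bool = True) -> NetworkModel:
    """The shipped central-metabolism model of the 5-AVD producers."""
    drains = _data_path("drains_avd.csv") if with_drains else None
    return load_network(_data_path("central_network.csv"), drains=drains)


def _rxn(rid, subs, prods, maps, reversible=False, cofactors=None):
    variants = [
        AtomMapVariant(
            substrate_atoms=tuple(s), product_atoms=tuple(p), weight=1.0 / len(maps)
        )
        for s, p in maps
    ]
    return Reaction(
        id=rid, substrates=subs, products=prods, atom_maps=variants,
        reversible=reversible, cofactors=cofactors or {},
    )


def toy_linear() -> NetworkModel:
    """Five-reaction linear chain of 2-carbon metabolites."""
    return NetworkModel(
        reactions=[
            _rxn("upt", ["S.ext"], ["A"], [(["ab"], ["ab"])]),
            _rxn("r1", ["A"], ["B"], [(["ab"], ["ab"])]),
            _rxn("r2", ["B"], ["C"], [(["ab"], ["ba"])]),
            _rxn("r3", ["C"], ["D"], [(["ab"], ["ab"])]),
            _rxn("out", ["D"], ["D.ext"], [(["ab"], ["ab"])]),
        ]
    )


def toy_cleave() -> NetworkModel:
    """Cleavage/condensation cycle with a reversible split.

    A 4-carbon substrate is cleaved into two 2-carbon halves which
    recombine in swapped order; a bypass keeps the molecule intact.
    Exercises convolution terms and exchange fluxes.
    """
    return NetworkModel(
        reactions=[
            _rxn("upt", ["S.ext"], ["S"], [(["abcd"], ["abcd"])]),
            _rxn("cleave", ["S"], ["P", "Q"], [(["abcd"], ["ab", "cd"])], reversible=True),
            _rxn("cond", ["P", "Q"], ["R"], [(["ab", "cd"], ["cdab"])]),
            _rxn("bypass", ["S"], ["R"], [(["abcd"], ["abcd"])]),
            _rxn("out", ["R"], ["R.ext"], [(["abcd"], ["abcd"])]),
        ]
    )


def toy_split_recombine() -> NetworkModel:
    """Branch point with a carbon-scrambling route.

    Route 1 transfers the intact 2-carbon unit; route 2 cleaves it to
    single carbons that recombine from well-mixed pools.  Under a 1:1
    [U-13C]/unlabeled feed the product M+1 fraction is linear in the
    route-1 share — an analytically solvable branch-ratio sensor.
    """
    return NetworkModel(
        reactions=[
            _rxn("upt", ["S.ext"], ["S"], [(["ab"], ["ab"])]),
            _rxn("intact", ["S"], ["P"], [(["ab"], ["ab"])]),
            _rxn("cleave", ["S"], ["X", "Y"], [(["ab"], ["a", "b"])]),
            _rxn("recomb", ["X", "Y"], ["P"], [(["a", "b"], ["ab"])]),
            _rxn("out", ["P"], ["P.ext"], [(["ab"], ["ab"])]),
        ]
    )


def toy_networks() -> dict[str, NetworkModel]:
    """All shipped toy networks, by name."""
    return {
        "linear": toy_linear(),
        "cleave": toy_cleave(),
        "split_recombine": toy_split_recombine(),
    }
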