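"""Natural-isotope handling for GC-MS mass isotopomer distributions.

GC-MS fragments of TBDMS-derivatized analytes (the [M-57]+ cluster
retains the full carbon backbone) carry natural-abundance isotope
contributions from the derivatization group (C, H, Si, O, N) and the
analyte heteroatoms.  Before flux fitting these must be deconvolved so
the corrected MID reflects only the labeling state of the backbone
carbons.  This module builds natural isotope patterns for arbitrary
elemental compositions, corrects raw MIDs by constrained least squares,
and diagnoses nitrogen counts from 15N tracer mass shifts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml
from scipy.optimize import nnls

from .compounds import CompoundSpec, get_compound

__all__ = [
    "ISOTOPE_ABUNDANCES",
    "NATURAL_13C",
    "natural_mid",
    "natural_carbon_mid",
    "convolve_mid",
    "FragmentSpec",
    "load_fragments",
    "correct_mid",
    "tracer_mass_shift",
]


def _load_abundances() -> dict[str, np.ndarray]:
    text = resources.files("avdflux.data").joinpath("isotope_abundances.yaml").read_text()
    raw = yaml.safe_load(text)
    return {el: np.asarray(v, dtype=float) for el, v in raw.items()}


#: Per-element mass-shift distributions, loaded from shipped data.
ISOTOPE_ABUNDANCES = _load_abundances()

#: Natural 13C abundance used throughout the tracer model.
NATURAL_13C = float(ISOTOPE_ABUNDANCES["C"][1])


def natural_mid(formula: dict[str, int], length: int | None = None) -> np.ndarray:
    """Natural isotope pattern of an elemental composition.

    Convolves the per-element single-atom mass-shift distributions and
    truncates/renormalizes to ``length`` channels (M+0 ... M+length-1).
    An empty formula gives the delta pattern [1, 0, ...].
    """
    pattern = np.array([1.0])
    for el, n in formula.items():
        if n < 0:
            raise ValueError(f"negative count for element {el!r}")
        try:
            single = ISOTOPE_ABUNDANCES[el]
        except KeyError:
            raise KeyError(f"no isotope data for element {el!r}") from None
        for _ in range(n):
            pattern = np.convolve(pattern, single)
    if length is not None:
        if length < 1:
            raise ValueError("length must be >= 1")
        if len(pattern) < length:
            pattern = np.pad(pattern, (0, length - len(pattern)))
        pattern = pattern[:length]
        pattern = pattern / pattern.sum()
    return pattern


def natural_carbon_mid(n_carbon: int) -> np.ndarray:
    """Binomial natural-abundance MID of an n-carbon unit."""
    return natural_mid({"C": n_carbon})


def convolve_mid(mid: np.ndarray, pattern: np.ndarray, length: int | None = None) -> np.ndarray:
    """Convolve a backbone MID with a natural isotope pattern.

    This is the forward model of a raw GC-MS measurement: the observed
    cluster is the labeling MID smeared by the natural isotopes of all
    non-backbone atoms.  Truncated to ``length`` and renormalized.
    """
    out = np.convolve(np.asarray(mid, float), np.asarray(pattern, float))
    if length is not None:
        if len(out) < length:
            out = np.pad(out, (0, length - len(out)))
        out = out[:length]
    return out / out.sum()


@dataclass
class FragmentSpec:
    """A measured GC-MS fragment of a derivatized analyte.

    ``metabolite``/``atoms`` place the fragment on the network (which
    carbon atoms of which metabolite the backbone represents);
    ``correction_formula`` is the elemental composition of everything in
    the ion except the backbone carbons (derivatization C/H/N/O/Si plus
    analyte heteroatoms), used for natural-isotope correction.
    """

    fragment_id: str
    metabolite: str
    atoms: tuple[int, ...]
    correction_formula: dict[str, int] = field(default_factory=dict)
    ion: str = "[M-57]+"

    def __post_init__(self) -> None:
        self.atoms = tuple(int(a) for a in self.atoms)
        if any(a < 1 for a in self.atoms):
            raise ValueError("atom indices are 1-based and must be >= 1")
        if any(n < 0 for n in self.correction_formula.values()):
            raise ValueError("correction formula counts must be >= 0")

    @property
    def backbone_carbons(self) -> int:
        return len(self.atoms)


def load_fragments(path: str | Path | None = None) -> dict[str, FragmentSpec]:
    """Load fragment specs from YAML (the shipped set by default)."""
    if path is None:
        text = resources.files("avdflux.data").joinpath("fragments.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    frags: dict[str, FragmentSpec] = {}
    for entry in raw:
        spec = FragmentSpec(
            fragment_id=entry["fragment_id"],
            metabolite=entry["metabolite"],
            atoms=tuple(entry["atoms"]),
            correction_formula=dict(entry.get("correction_formula", {})),
            ion=entry.get("ion", "[M-57]+"),
        )
        frags[spec.fragment_id] = spec
    return frags


def correct_mid(raw: np.ndarray, frag: FragmentSpec, correct_backbone: bool = False) -> np.ndarray:
    """Correct a raw fragment MID for naturally occurring isotopes.

    Solves ``raw ~ P @ corrected`` where column j of P is the natural
    pattern of the correction formula shifted by j channels, by
    non-negative least squares (avoids the negative fractions a plain
    matrix inversion produces at low signal), then renormalizes.
    Returns the backbone MID of length ``backbone_carbons + 1``.

    By default only non-backbone atoms are deconvolved, so the corrected
    MID retains the natural 13C of unlabeled backbone positions — the
    convention matching a labeling simulator that models substrate
    natural abundance explicitly.  With ``correct_backbone=True`` the
    backbone carbons' natural 13C is removed as well, so a fully
    unlabeled analyte corrects to [1, 0, ...].
    """
    raw = np.asarray(raw, dtype=float)
    k = frag.backbone_carbons
    if len(raw) < k + 1:
        raise ValueError(
            f"raw MID of {frag.fragment_id} has {len(raw)} channels, need >= {k + 1}"
        )
    formula = dict(frag.correction_formula)
    if correct_backbone:
        formula["C"] = formula.get("C", 0) + k
    if not formula:
        out = raw[: k + 1].copy()
        return out / out.sum()
    pattern = natural_mid(formula)
    n = len(raw)
    P = np.zeros((n, k + 1))
    for j in range(k + 1):
        seg = pattern[: n - j]
        P[j : j + len(seg), j] = seg
    if np.linalg.cond(P.T @ P) > 1e12:
        raise np.linalg.LinAlgError(
            f"ill-conditioned correction matrix for {frag.fragment_id}"
        )
    x, _ = nnls(P, raw)
    total = x.sum()
    if total <= 0:
        raise ValueError(f"correction of {frag.fragment_id} produced an empty MID")
    return x / total


def correction_sd(frag: FragmentSpec, raw_sd: np.ndarray | float, n_channels: int) -> np.ndarray:
    """First-order SDs of a corrected MID given raw per-channel SDs.

    The least-squares deconvolution amplifies measurement noise; the
    propagated SD per corrected channel is the row-norm of the
    pseudo-inverse of the correction matrix weighted by the raw SDs.
    Used to weight corrected MIDs consistently in the flux fit.
    """
    k = frag.backbone_carbons
    if np.isscalar(raw_sd):
        raw_sd = np.full(n_channels, float(raw_sd))
    raw_sd = np.asarray(raw_sd, dtype=float)
    if not frag.correction_formula:
        return raw_sd[: k + 1].copy()
    pattern = natural_mid(frag.correction_formula)
    P = np.zeros((n_channels, k + 1))
    for j in range(k + 1):
        seg = pattern[: n_channels - j]
        P[j : j + len(seg), j] = seg
    pinv = np.linalg.pinv(P)
    return np.sqrt((pinv**2) @ (raw_sd**2))


def tracer_mass_shift(
    analyte: CompoundSpec | str, tracer_element: str, enrichment: float = 0.99
) -> tuple[int, float]:
    """Nominal and expected mass shift (Da) under an isotopic tracer.

    Growing a culture on a fully labeled nitrogen (or carbon) source
    shifts each fragment cluster by one mass unit per atom of the
    tracer element in the analyte — the +2 Da shift of 5-AVD on 15N
    ammonium sulfate identified its two nitrogens.  Returns
    ``(nominal_shift, expected_fractional_shift)`` where the nominal
    shift assumes full enrichment and the fractional one scales with the
    tracer enrichment.  An element absent from the formula gives 0.
    """
    if isinstance(analyte, str):
        analyte = get_compound(analyte)
    if not 0.0 < enrichment <= 1.0:
        raise ValueError(f"enrichment must be in (0, 1], got {enrichment}")
    count = analyte.formula.get(tracer_element, 0)
    return count, count * enrichment
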