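"""Fermentation kinetics and stoichiometry.

Growth rate (mu), biomass-specific substrate/product rates (q), molar
yields (Y), product selectivity, space-time yield and specific enzyme
activity — the quantities tabulated for batch and fed-batch cultures of
the 5-AVD producer strains.

Cell density enters as OD660 and is converted to cell dry weight (CDW)
with a configurable correlation factor.  The factor shipped here
(0.32 g_CDW/L per OD660 unit) is a documented stand-in for the
laboratory calibration, which is strain- and instrument-specific; every
computation lets the caller override it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .compounds import get_compound

__all__ = [
    "DEFAULT_CDW_FACTOR",
    "CultureTimeCourse",
    "RatesAndYields",
    "fit_growth_rate",
    "find_exponential_window",
    "compute_specific_rates",
    "compute_molar_yield",
    "compute_selectivity",
    "space_time_yield",
    "specific_enzyme_activity",
]

#: Stand-in OD660 -> g_CDW/L correlation factor (configurable everywhere).
DEFAULT_CDW_FACTOR = 0.32


@dataclass
class CultureTimeCourse:
    """A batch/fed-batch culture: times (h), OD660 and concentrations (g/L).

    ``concentrations`` maps compound name -> array of g/L per time point.
    ``phase_labels`` optionally annotates each sample (e.g. batch/feed).
    """

    times: np.ndarray
    od660: np.ndarray
    concentrations: dict[str, np.ndarray] = field(default_factory=dict)
    cdw_factor: float = DEFAULT_CDW_FACTOR
    phase_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od660 = np.asarray(self.od660, dtype=float)
        if self.times.ndim != 1 or len(self.times) != len(self.od660):
            raise ValueError("times and od660 must be 1-D arrays of equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.od660 < 0):
            raise ValueError("od660 must be >= 0")
        if self.cdw_factor <= 0:
            raise ValueError("cdw_factor must be > 0")
        for name, conc in self.concentrations.items():
            conc = np.asarray(conc, dtype=float)
            if len(conc) != len(self.times):
                raise ValueError(f"concentration series {name!r} length mismatch")
            if np.any(conc < -1e-12):
                raise ValueError(f"concentration series {name!r} has negative values")
            self.concentrations[name] = conc

    @property
    def cdw(self) -> np.ndarray:
        """Cell dry weight, g/L."""
        return self.od660 * self.cdw_factor

    def to_frame(self) -> pd.DataFrame:
        data = {"time_h": self.times, "od660": self.od660}
        for name, conc in self.concentrations.items():
            data[f"{name}_gL"] = conc
        df = pd.DataFrame(data)
        if self.phase_labels is not None:
            df["phase"] = self.phase_labels
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, cdw_factor: float = DEFAULT_CDW_FACTOR) -> "CultureTimeCourse":
        """Read a time-course CSV with columns ``time_h, od660, <compound>_gL...``."""
        df = pd.read_csv(path)
        conc = {
            col[: -len("_gL")]: df[col].to_numpy(float)
            for col in df.columns
            if col.endswith("_gL")
        }
        phases = df["phase"].astype(str).tolist() if "phase" in df.columns else None
        return cls(
            times=df["time_h"].to_numpy(float),
            od660=df["od660"].to_numpy(float),
            concentrations=conc,
            cdw_factor=cdw_factor,
            phase_labels=phases,
        )


@dataclass
class RatesAndYields:
    """Specific rates and yields of one culture, with standard errors."""

    mu: float
    mu_se: float
    q_substrate: float
    q_substrate_se: float
    q_products: dict[str, float]
    q_products_se: dict[str, float]
    yields_molar: dict[str, float]
    yields_molar_se: dict[str, float]
    yield_biomass: float
    yield_biomass_se: float
    substrate: str = "glucose"

    def to_dict(self) -> dict:
        return {
            "mu_per_h": self.mu,
            "mu_se": self.mu_se,
            "substrate": self.substrate,
            "q_substrate_mmol_g_h": self.q_substrate,
            "q_substrate_se": self.q_substrate_se,
            "q_products_mmol_g_h": self.q_products,
            "q_products_se": self.q_products_se,
            "yields_mmol_mol": self.yields_molar,
            "yields_mmol_mol_se": self.yields_molar_se,
            "yield_biomass_g_mol": self.yield_biomass,
            "yield_biomass_se": self.yield_biomass_se,
        }


def _window_mask(times: np.ndarray, window: tuple[float, float] | None) -> np.ndarray:
    if window is None:
        return np.ones_like(times, dtype=bool)
    lo, hi = window
    return (times >= lo) & (times <= hi)


def fit_growth_rate(tc: CultureTimeCourse, window: tuple[float, float] | None = None) -> tuple[float, float]:
    """Specific growth rate mu (1/h) as the slope of ln(CDW) vs time.

    Returns ``(mu, standard_error)``.  Exact on noiseless exponential
    data; requires >= 3 points with positive OD inside the window.
    """
    mask = _window_mask(tc.times, window)
    t = tc.times[mask]
    x = tc.cdw[mask]
    if len(t) < 3:
        raise ValueError(f"need >= 3 points in window, got {len(t)}")
    if np.any(x <= 0):
        raise ValueError("nonpositive OD660/CDW inside the fit window")
    res = stats.linregress(t, np.log(x))
    mu = float(res.slope)
    se = float(res.stderr) if np.isfinite(res.stderr) else 0.0
    return mu, se


def find_exponential_window(tc: CultureTimeCourse, min_points: int = 4) -> tuple[float, float]:
    """Pick the contiguous run of samples maximizing R^2 of ln(CDW) vs t.

    Windows with fewer than ``min_points`` samples or nonpositive OD are
    skipped.  Among near-ties (R^2 within 1e-9) the longest run wins.
    """
    t, x = tc.times, tc.cdw
    n = len(t)
    best: tuple[float, int, tuple[float, float]] | None = None
    for i in range(n):
        for j in range(i + min_points, n + 1):
            xi = x[i:j]
            if np.any(xi <= 0):
                continue
            res = stats.linregress(t[i:j], np.log(xi))
            if res.slope <= 0:
                continue
            r2 = res.rvalue**2
            key = (round(r2, 9), j - i)
            if best is None or key > best[:2]:
                best = (key[0], key[1], (float(t[i]), float(t[j - 1])))
    if best is None:
        raise ValueError("no exponential window with positive growth found")
    return best[2]


def compute_specific_rates(
    tc: CultureTimeCourse,
    substrate: str = "glucose",
    products: list[str] | None = None,
    window: tuple[float, float] | None = None,
    mu: tuple[float, float] | None = None,
) -> RatesAndYields:
    """Biomass-specific rates q (mmol/g/h) and molar yields from a culture.

    During exponential growth concentration is linear in CDW with slope
    dC/dX = q*M/(1000*mu) (M the molar mass, g/mol), so
    q_i = mu * slope_i * 1000 / M_i.  Substrate consumption is reported
    positive.  Yields follow as Y_i = 1000 * q_i / q_S (mmol/mol) and the
    biomass yield as Y_X = 1000 * mu / q_S (g/mol).
    """
    if window is None:
        window = find_exponential_window(tc)
    if mu is None:
        mu_val, mu_se = fit_growth_rate(tc, window)
    else:
        mu_val, mu_se = mu
    if mu_val <= 0:
        raise ValueError("growth rate must be positive to derive specific rates")
    if products is None:
        products = [c for c in tc.concentrations if c != substrate]
    if substrate not in tc.concentrations:
        raise KeyError(f"substrate {substrate!r} not in time course")

    mask = _window_mask(tc.times, window)
    cdw = tc.cdw[mask]

    def _q(compound: str) -> tuple[float, float]:
        conc = tc.concentrations[compound][mask]
        res = stats.linregress(cdw, conc)
        mw = get_compound(compound).molar_mass
        q = mu_val * res.slope * 1000.0 / mw
        slope_se = res.stderr if np.isfinite(res.stderr) else 0.0
        # first-order propagation: q = mu * slope * const
        rel = np.hypot(
            mu_se / mu_val if mu_val else 0.0,
            slope_se / res.slope if res.slope else 0.0,
        )
        return float(q), float(abs(q) * rel)

    q_s, q_s_se = _q(substrate)
    q_s, q_s_se = -q_s, q_s_se  # consumption positive
    if q_s <= 0:
        raise ValueError(f"substrate {substrate!r} is not consumed in the window")

    q_p: dict[str, float] = {}
    q_p_se: dict[str, float] = {}
    yields: dict[str, float] = {}
    yields_se: dict[str, float] = {}
    for prod in products:
        q, se = _q(prod)
        q_p[prod] = q
        q_p_se[prod] = se
        yields[prod] = compute_molar_yield(q, q_s)
        yields_se[prod] = (
            yields[prod] * np.hypot(se / q if q else 0.0, q_s_se / q_s)
            if q
            else 0.0
        )

    y_x = 1000.0 * mu_val / q_s
    y_x_se = y_x * np.hypot(mu_se / mu_val, q_s_se / q_s)
    return RatesAndYields(
        mu=mu_val,
        mu_se=mu_se,
        q_substrate=q_s,
        q_substrate_se=q_s_se,
        q_products=q_p,
        q_products_se=q_p_se,
        yields_molar=yields,
        yields_molar_se=yields_se,
        yield_biomass=float(y_x),
        yield_biomass_se=float(y_x_se),
        substrate=substrate,
    )


def compute_molar_yield(q_product: float, q_substrate: float) -> float:
    """Molar product yield Y = 1000 * q_P / q_S in mmol/mol."""
    if q_substrate <= 0:
        raise ValueError(f"substrate rate must be > 0, got {q_substrate}")
    return 1000.0 * q_product / q_substrate


def compute_selectivity(
    product_titers: dict[str, float],
    main: str,
    baseline_correction: dict[str, float] | None = None,
    basis: str = "molar",
) -> float:
    """Fraction (%) of the main product among all secreted products.

    Molar basis by default; titers are g/L and converted with the
    registered molar masses.  ``baseline_correction`` subtracts amounts
    already present at inoculation (e.g. lysine carried in with complex
    medium) before computing the fraction.
    """
    if main not in product_titers:
        raise KeyError(f"main product {main!r} not among titers")
    if basis not in ("molar", "mass"):
        raise ValueError("basis must be 'molar' or 'mass'")
    baseline = baseline_correction or {}
    amounts: dict[str, float] = {}
    for name, titer in product_titers.items():
        if titer < 0:
            raise ValueError(f"titer of {name!r} is negative")
        net = max(titer - baseline.get(name, 0.0), 0.0)
        if basis == "molar":
            net /= get_compound(name).molar_mass
        amounts[name] = net
    total = sum(amounts.values())
    if total <= 0:
        raise ValueError("all product titers are zero after baseline correction")
    return 100.0 * amounts[main] / total


def space_time_yield(
    tc: CultureTimeCourse,
    compound: str,
    phase: str | tuple[float, float] | None = None,
) -> tuple[float, float]:
    """Volumetric productivity of a compound, g/L/h.

    Returns ``(overall, maximum)``: the overall delta-titer over
    delta-time across the phase, and the maximum slope over consecutive
    sampling intervals (the "maximum space-time yield").  ``phase`` is a
    label matching ``phase_labels`` or an explicit (t_start, t_end).
    """
    conc = tc.concentrations[compound]
    if phase is None:
        mask = np.ones_like(tc.times, dtype=bool)
    elif isinstance(phase, str):
        if tc.phase_labels is None:
            raise ValueError("time course has no phase labels")
        mask = np.array([p == phase for p in tc.phase_labels])
    else:
        mask = _window_mask(tc.times, phase)
    t = tc.times[mask]
    c = conc[mask]
    if len(t) < 2:
        raise ValueError("phase contains fewer than 2 samples")
    overall = (c[-1] - c[0]) / (t[-1] - t[0])
    slopes = np.diff(c) / np.diff(t)
    return float(overall), float(np.max(slopes))


def specific_enzyme_activity(
    times_min: np.ndarray,
    substrate_mM: np.ndarray,
    protein_mg_per_ml: float,
    volume_ml: float = 1.0,
    n_initial: int | None = None,
) -> tuple[float, bool]:
    """Specific activity in mU/mg from substrate depletion.

    The initial-rate slope of the substrate time course (mM/min, i.e.
    nmol/uL/min) divided by the protein concentration gives
    nmol/min/mg = mU/mg.  1 mU converts 1 nmol substrate per minute.
    ``volume_ml`` is accepted for assays quoting total protein per
    reaction volume; it cancels when protein is given per mL.

    Returns ``(activity, assay_valid)`` where the flag marks a flat
    (no-conversion) course, the expected outcome of the no-enzyme and
    no-substrate negative controls.
    """
    if protein_mg_per_ml <= 0:
        raise ValueError(f"protein concentration must be > 0, got {protein_mg_per_ml}")
    t = np.asarray(times_min, dtype=float)
    s = np.asarray(substrate_mM, dtype=float)
    if len(t) < 2:
        raise ValueError("need >= 2 time points")
    if n_initial is not None:
        t, s = t[:n_initial], s[:n_initial]
    slope = stats.linregress(t, s).slope  # mM/min
    rate_nmol_min_ml = -slope * 1000.0  # nmol/min per mL, consumption positive
    activity = max(rate_nmol_min_ml, 0.0) / protein_mg_per_ml
    flat = bool(abs(slope) < 1e-12)
    return float(activity), flat
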