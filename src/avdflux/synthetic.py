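"""Synthetic culture and labeling data with known ground truth.

The generators emulate the two kinds of raw data the analysis consumes:
exponential batch time courses with product secretion at stated
specific rates, and GC-MS mass isotopomer measurements of fragments
under the study's two tracer setups ([1-13C] glucose; 1:1 unlabeled /
[U-13C6] glucose).  Every scenario carries its full ground truth, so
each downstream operation — growth-rate fitting, rate/yield
computation, isotope correction, flux estimation, GapN deconvolution —
can be validated by parameter recovery.

The shipped producer scenarios mirror the published physiology of the
strains (Table-2-level rates: the GapN strain at mu = 0.12 1/h,
q_GLC = 3.45, q_5-AVD = 1.09 mmol/g/h) and carry flux vectors whose
redox ledgers reproduce the stated NADPH structure: 250% total NADPH
demand, a 53.8% GapN share of the GAP node in the GapN strain, and
NADPH/CO2 carbon economies of 1.27 and 1.0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .compounds import get_compound
from .emu import EMUSimulator, EMUNode, TracerSpec, glucose_1_13c, glucose_u13c_mix
from .fitting import DEFAULT_MID_SD, FitProblem
from .isotopes import (
    FragmentSpec,
    convolve_mid,
    correct_mid,
    correction_sd,
    load_fragments,
    natural_mid,
)
from .network import FluxVector, NetworkModel
from .networks import central_network, toy_cleave
from .physiology import DEFAULT_CDW_FACTOR, CultureTimeCourse

__all__ = [
    "SyntheticScenario",
    "avd11_scenario",
    "avd3_scenario",
    "toy_cleave_scenario",
    "gen_timecourse",
    "gen_mid_dataset",
    "MIDDataset",
    "corrected_measurements",
    "make_fit_problem",
    "write_problem_dir",
]


@dataclass
class SyntheticScenario:
    """Ground truth for one simulated strain/experiment."""

    name: str
    model: NetworkModel
    true_fluxes: FluxVector
    tracers: dict[str, TracerSpec]
    fragments: dict[str, FragmentSpec]
    fixed: dict[str, float]
    free_reactions: list[str]
    rate_measurements: dict[str, tuple[float, float]] = field(default_factory=dict)
    mid_noise_sd: float = DEFAULT_MID_SD
    # physiology ground truth
    mu: float = 0.12
    q_substrate: float = 3.45  # mmol/g/h glucose
    q_products: dict[str, float] = field(default_factory=dict)
    substrate: str = "glucose"
    s0_gL: float = 10.0
    od0: float = 0.15
    cdw_factor: float = DEFAULT_CDW_FACTOR
    conc_noise_rel: float = 0.02
    master_seed: int = 0

    def simulator(self) -> EMUSimulator:
        return EMUSimulator(self.model, [(f.metabolite, f.atoms) for f in self.fragments.values()])


def _avd_fluxes(model: NetworkModel, free_vals: dict[str, float], fixed: dict[str, float],
                exchange: dict[str, float]) -> FluxVector:
    from .fitting import FluxParameterization

    par = FluxParameterization(model, fixed, free_reactions=list(free_vals))
    net = par.net_fluxes(np.array(list(free_vals.values())))
    return FluxVector(net=net, exchange=exchange)


def avd11_scenario() -> SyntheticScenario:
    """GapN-expressing producer: high EMP flux, low oxPPP, GapN at the GAP node.

    Free fluxes calibrated so the ledger shows 250% NADPH supply, a
    53.8% GapN share of the GAP node and 1.27 NADPH per CO2; physiology
    mirrors the published strain (mu = 0.12, q_GLC = 3.45, yield
    316 mmol/mol -> 5-AVD export 31.6% of glucose uptake).
    """
    model = central_network()
    fixed = {"upt": 100.0, "lys_out": 0.0, "avd_out": 31.60}
    fv = _avd_fluxes(
        model,
        {"oxppp": 35.7707, "gapn": 96.4453, "mae": 2.9468},
        fixed,
        exchange={"pgi": 50.0, "tkt1": 10.0, "tal": 10.0, "tkt2": 10.0},
    )
    return SyntheticScenario(
        name="AVD-11-like",
        model=model,
        true_fluxes=fv,
        tracers={"1-13C": glucose_1_13c(), "U-13C-mix": glucose_u13c_mix()},
        fragments=load_fragments(),
        fixed={"upt": 100.0, "lys_out": 0.0, "gapn": 0.0},
        free_reactions=["oxppp", "mae", "avd_out"],
        rate_measurements={"avd_out": (31.60, 1.0)},
        mu=0.12,
        q_substrate=3.45,
        q_products={"5-AVD": 1.09},
    )


def avd3_scenario() -> SyntheticScenario:
    """GapN-free reference producer: oxPPP/TCA-dominated NADPH supply.

    Ledger: 250% NADPH supply entirely from decarboxylating sources,
    hence 1.0 NADPH per CO2; yield 235.6 mmol/mol (export 23.56%).
    """
    model = central_network()
    fixed = {"upt": 100.0, "lys_out": 0.0, "avd_out": 23.56}
    fv = _avd_fluxes(
        model,
        {"oxppp": 80.3025, "gapn": 0.0, "mae": 9.0925},
        fixed,
        exchange={"pgi": 40.0, "tkt1": 10.0, "tal": 10.0, "tkt2": 10.0},
    )
    return SyntheticScenario(
        name="AVD-3-like",
        model=model,
        true_fluxes=fv,
        tracers={"1-13C": glucose_1_13c(), "U-13C-mix": glucose_u13c_mix()},
        fragments=load_fragments(),
        fixed={"upt": 100.0, "lys_out": 0.0, "gapn": 0.0},
        free_reactions=["oxppp", "mae", "avd_out"],
        rate_measurements={"avd_out": (23.56, 1.0)},
        mu=0.11,
        q_substrate=3.35,
        q_products={"5-AVD": 0.79},
    )


def toy_cleave_scenario() -> SyntheticScenario:
    """Small fully identifiable problem on the cleavage/condensation toy.

    Used for fast parameter-recovery and confidence-interval coverage
    studies: one free net flux (the bypass) plus the cleavage exchange.
    """
    model = toy_cleave()
    fv = FluxVector(
        net={"upt": 100.0, "cleave": 60.0, "cond": 60.0, "bypass": 40.0, "out": 100.0},
        exchange={"cleave": 30.0},
    )
    tracer = TracerSpec("S.ext", (("1000", 0.5), ("U", 0.5)), purity=0.99)
    fragments = {
        "R_full": FragmentSpec("R_full", "R", (1, 2, 3, 4)),
        "R_12": FragmentSpec("R_12", "R", (1, 2)),
        "P_12": FragmentSpec("P_12", "P", (1, 2)),
    }
    return SyntheticScenario(
        name="toy-cleave",
        model=model,
        true_fluxes=fv,
        tracers={"mix": tracer},
        fragments=fragments,
        fixed={"upt": 100.0},
        free_reactions=["bypass"],
        mid_noise_sd=DEFAULT_MID_SD,
    )


# -- culture time courses --------------------------------------------------


def gen_timecourse(
    scenario: SyntheticScenario,
    times: np.ndarray | None = None,
    noise_rel: float | None = None,
    seed: int | None = None,
) -> CultureTimeCourse:
    """Exponential batch culture with product secretion at the true rates.

    Integrates dX/dt = mu X, dS/dt = -q_S M_S X / 1000,
    dP/dt = q_P M_P X / 1000 analytically, truncates at substrate
    exhaustion, and applies multiplicative Gaussian noise to OD and
    concentrations.  Deterministic for a fixed seed.
    """
    if scenario.mu <= 0:
        raise ValueError("scenario growth rate must be > 0")
    noise = scenario.conc_noise_rel if noise_rel is None else noise_rel
    if times is None:
        times = np.arange(0.0, 32.0, 2.0)
    times = np.asarray(times, dtype=float)
    mu = scenario.mu
    x0 = scenario.od0 * scenario.cdw_factor
    growth = np.exp(mu * times)
    consumed = x0 * (growth - 1.0) / mu  # integral of X dt, g/L * h basis
    mw_s = get_compound(scenario.substrate).molar_mass
    s = scenario.s0_gL - scenario.q_substrate * mw_s / 1000.0 * consumed
    alive = s > 0
    if alive.sum() < 2:
        raise ValueError("substrate exhausted before the second sample")
    times = times[alive]
    growth = growth[alive]
    consumed = consumed[alive]
    s = s[alive]
    conc = {scenario.substrate: s}
    for prod, q in scenario.q_products.items():
        mw = get_compound(prod).molar_mass
        conc[prod] = q * mw / 1000.0 * consumed
    od = scenario.od0 * growth
    if noise > 0:
        rng = np.random.default_rng(scenario.master_seed if seed is None else seed)
        od = od * (1.0 + rng.normal(0.0, noise, size=od.shape))
        conc = {
            k: np.clip(v * (1.0 + rng.normal(0.0, noise, size=v.shape)), 0.0, None)
            for k, v in conc.items()
        }
    return CultureTimeCourse(
        times=times, od660=np.clip(od, 1e-9, None), concentrations=conc,
        cdw_factor=scenario.cdw_factor,
    )


# -- MID datasets ----------------------------------------------------------


@dataclass
class MIDDataset:
    """Raw (derivatized, noisy) MIDs plus the generating ground truth."""

    raw: pd.DataFrame  # experiment, fragment_id, m0.., sd0..
    ground_truth: dict

    def to_csv(self, path: str | Path) -> None:
        self.raw.to_csv(path, index=False)


def gen_mid_dataset(scenario: SyntheticScenario, seed: int | None = None) -> MIDDataset:
    """Simulate raw fragment measurements for every tracer experiment.

    Backbone MIDs from the EMU model are convolved with the natural
    isotope pattern of each fragment's correction formula (the forward
    model of the derivatized ion cluster), perturbed with additive
    Gaussian noise per channel and renormalized.
    """
    sim = scenario.simulator()
    rng = np.random.default_rng(scenario.master_seed if seed is None else seed)
    rows = []
    truth_mids: dict[str, dict[str, list[float]]] = {}
    n_extra = 3  # channels recorded beyond the backbone
    for exp, tracer in scenario.tracers.items():
        mids = sim.simulate(scenario.true_fluxes, tracer)
        truth_mids[exp] = {}
        for fid, frag in scenario.fragments.items():
            backbone = mids[EMUNode(frag.metabolite, frag.atoms)]
            truth_mids[exp][fid] = backbone.tolist()
            length = len(backbone) + n_extra
            if frag.correction_formula:
                pattern = natural_mid(frag.correction_formula)
                raw = convolve_mid(backbone, pattern, length=length)
            else:
                raw = np.pad(backbone, (0, n_extra))
            if scenario.mid_noise_sd > 0:
                raw = raw + rng.normal(0.0, scenario.mid_noise_sd, size=raw.shape)
                raw = np.clip(raw, 0.0, None)
                raw = raw / raw.sum()
            row = {"experiment": exp, "fragment_id": fid}
            for ch, val in enumerate(raw):
                row[f"m{ch}"] = val
            for ch in range(len(raw)):
                row[f"sd{ch}"] = scenario.mid_noise_sd
            rows.append(row)
    ground_truth = {
        "scenario": scenario.name,
        "net_fluxes": scenario.true_fluxes.net,
        "exchange_fluxes": scenario.true_fluxes.exchange,
        "backbone_mids": truth_mids,
        "mid_noise_sd": scenario.mid_noise_sd,
    }
    return MIDDataset(raw=pd.DataFrame(rows), ground_truth=ground_truth)


def corrected_measurements(
    dataset: MIDDataset | pd.DataFrame,
    fragments: dict[str, FragmentSpec],
    sd: float = DEFAULT_MID_SD,
) -> dict[str, dict[str, tuple[np.ndarray, np.ndarray]]]:
    """Natural-isotope-correct a raw dataset into fit-ready measurements."""
    df = dataset.raw if isinstance(dataset, MIDDataset) else dataset
    out: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
    mcols = sorted(
        (c for c in df.columns if c.startswith("m") and c[1:].isdigit()),
        key=lambda c: int(c[1:]),
    )
    for _, row in df.iterrows():
        frag = fragments[row["fragment_id"]]
        raw = row[mcols].to_numpy(dtype=float)
        raw = raw[~np.isnan(raw)]
        corrected = correct_mid(raw, frag)
        # deconvolution amplifies noise: propagate raw SDs through the
        # correction matrix so the fit weights channels consistently
        prop_sd = correction_sd(frag, sd, len(raw))
        exp = row["experiment"]
        out.setdefault(exp, {})[frag.fragment_id] = (
            corrected,
            np.clip(prop_sd, sd, None),
        )
    return out


def make_fit_problem(
    scenario: SyntheticScenario,
    dataset: MIDDataset,
    rate_seed: int | None = None,
) -> FitProblem:
    """Bundle a generated dataset into the estimator's problem form.

    Measured extracellular rates are resampled around their true values
    at the stated SDs (seeded); MIDs are isotope-corrected first.
    """
    sd_floor = scenario.mid_noise_sd if scenario.mid_noise_sd > 0 else 1e-6
    measurements = corrected_measurements(dataset, scenario.fragments, sd_floor)
    rng = np.random.default_rng(scenario.master_seed if rate_seed is None else rate_seed)
    rates = {
        rid: (val + (rng.normal(0.0, sd) if scenario.mid_noise_sd > 0 else 0.0), sd)
        for rid, (val, sd) in scenario.rate_measurements.items()
    }
    fragments = {fid: (f.metabolite, f.atoms) for fid, f in scenario.fragments.items()}
    return FitProblem(
        model=scenario.model,
        tracers=scenario.tracers,
        fragments=fragments,
        measurements=measurements,
        rates=rates,
        fixed=scenario.fixed,
        free_reactions=scenario.free_reactions,
    )


def write_problem_dir(scenario: SyntheticScenario, outdir: str | Path, seed: int = 0) -> dict:
    """Write a complete fit-problem directory plus ground truth JSON.

    Layout: network.csv, drains.csv, tracers.yaml, fragments.yaml,
    mids.csv, rates.csv, ground_truth.json.  Returns the manifest dict.
    """
    import yaml

    from .network import serialize_network

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    serialize_network(scenario.model, outdir / "network.csv")
    pd.DataFrame(
        [
            {"precursor": rid.removeprefix("drain_"), "flux_percent": v}
            for rid, v in sorted(scenario.model.drain_fluxes.items())
        ],
        columns=["precursor", "flux_percent"],
    ).to_csv(outdir / "drains.csv", index=False)
    tracers = {
        exp: {
            "substrate": t.substrate,
            "components": [[p, f] for p, f in t.components],
            "purity": t.purity,
        }
        for exp, t in scenario.tracers.items()
    }
    (outdir / "tracers.yaml").write_text(yaml.safe_dump(tracers, sort_keys=True))
    frags = [
        {
            "fragment_id": f.fragment_id,
            "metabolite": f.metabolite,
            "atoms": list(f.atoms),
            "ion": f.ion,
            "correction_formula": f.correction_formula,
        }
        for f in scenario.fragments.values()
    ]
    (outdir / "fragments.yaml").write_text(yaml.safe_dump(frags, sort_keys=True))
    dataset = gen_mid_dataset(scenario, seed=seed)
    dataset.to_csv(outdir / "mids.csv")
    pd.DataFrame(
        [
            {"rxn_id": rid, "value_percent": val, "sd": sd}
            for rid, (val, sd) in scenario.rate_measurements.items()
        ],
        columns=["rxn_id", "value_percent", "sd"],
    ).to_csv(outdir / "rates.csv", index=False)
    (outdir / "ground_truth.json").write_text(json.dumps(dataset.ground_truth, indent=1))
    manifest = {
        "scenario": scenario.name,
        "seed": seed,
        "files": sorted(p.name for p in outdir.iterdir()),
        "fixed": scenario.fixed,
        "free_reactions": scenario.free_reactions,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
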