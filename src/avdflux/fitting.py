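"""Weighted least-squares 13C flux estimation.

The estimator minimizes the variance-weighted squared deviation between
simulated and measured fragment MIDs (both tracer experiments jointly)
plus measured extracellular rates, over the network's free degrees of
freedom.  Stoichiometry is enforced exactly: net fluxes are
parameterized on the null space of the balance matrix after removing
the fixed constraints (glucose uptake = 100, anabolic drains, any
clamped reactions), with the fluxes of a chosen set of free reactions
as the coordinates.  Exchange fluxes of reversible reactions are
parameterized on [0, 1) through beta * x / (1 - x) to keep the search
bounded.

The nonlinear MID model can in principle trap a local optimizer, so the
fit runs from many random starting points and reports whether all
restarts converged to the same solution; confidence intervals come from
Monte-Carlo resampling of the measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import null_space, qr
from scipy.optimize import least_squares

from .emu import EMUSimulator, TracerSpec
from .network import FluxVector, NetworkModel

__all__ = [
    "FluxParameterization",
    "FitProblem",
    "FitResult",
    "ConfidenceIntervals",
    "fit_fluxes",
    "monte_carlo_ci",
    "normalize_to_glucose",
    "DEFAULT_MID_SD",
]

#: Default per-channel MID standard deviation (mole fraction), a common
#: GC-MS measurement floor of 0.4 mol%.
DEFAULT_MID_SD = 0.004


class FluxParameterization:
    """Net fluxes as a function of free-reaction coordinates.

    Solves ``S v = 0`` with equality constraints ``v_r = c_r`` for the
    fixed reactions; the remaining freedom is spanned by a null-space
    basis re-expressed so that the coordinates are the fluxes of the
    ``free_reactions`` themselves (interpretable, boundable quantities).
    """

    def __init__(
        self,
        model: NetworkModel,
        fixed: dict[str, float],
        free_reactions: list[str] | None = None,
    ):
        self.model = model
        self.rxn_ids = model.reaction_ids
        idx = {r: i for i, r in enumerate(self.rxn_ids)}
        S = model.stoich_matrix().to_numpy()
        n = len(self.rxn_ids)
        fixed = dict(model.drain_fluxes) | dict(fixed)
        rows = [S]
        rhs = [np.zeros(S.shape[0])]
        for rid, val in fixed.items():
            e = np.zeros(n)
            e[idx[rid]] = 1.0
            rows.append(e[None, :])
            rhs.append(np.array([val]))
        A = np.vstack(rows)
        b = np.concatenate(rhs)
        v0, res, rank, _ = np.linalg.lstsq(A, b, rcond=None)
        if np.max(np.abs(A @ v0 - b)) > 1e-8:
            raise ValueError("fixed fluxes are inconsistent with the stoichiometry")
        N = null_space(A)
        self.v0 = v0
        self.N = N
        self.n_free = N.shape[1]
        if free_reactions is None:
            free_reactions = self._auto_select_free()
        if len(free_reactions) != self.n_free:
            raise ValueError(
                f"network has {self.n_free} free degrees of freedom, "
                f"got {len(free_reactions)} free reactions"
            )
        F = np.array([idx[r] for r in free_reactions], dtype=int)
        NF = N[F, :]
        if np.linalg.matrix_rank(NF) < self.n_free:
            raise ValueError("chosen free reactions do not span the null space")
        self.free_reactions = list(free_reactions)
        self._M = N @ np.linalg.inv(NF)
        self._v0_free = v0[F]
        self.fixed = fixed

    def _auto_select_free(self) -> list[str]:
        # QR with column pivoting on N^T picks maximally independent rows
        _, _, piv = qr(self.N.T, pivoting=True)
        chosen = sorted(piv[: self.n_free])
        return [self.rxn_ids[i] for i in chosen]

    def net_fluxes(self, free_values: np.ndarray) -> dict[str, float]:
        v = self.v0 + self._M @ (np.asarray(free_values, float) - self._v0_free)
        return dict(zip(self.rxn_ids, v))

    def irreversible_ids(self) -> list[str]:
        return [r.id for r in self.model.reactions if not r.reversible]


@dataclass
class FitProblem:
    """Everything the estimator needs for one strain.

    ``measurements`` maps experiment id -> fragment id -> (MID, SD)
    arrays on the corrected (backbone) scale; ``tracers`` maps the same
    experiment ids to their tracer mixtures.  ``rates`` holds measured
    net fluxes in percent of glucose uptake with their SDs.
    """

    model: NetworkModel
    tracers: dict[str, TracerSpec]
    fragments: dict[str, tuple[str, tuple[int, ...]]]
    measurements: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]]
    rates: dict[str, tuple[float, float]] = field(default_factory=dict)
    fixed: dict[str, float] = field(default_factory=dict)
    free_reactions: list[str] | None = None
    exchange_scale: float = 100.0
    net_bounds: tuple[float, float] = (0.0, 400.0)
    exchange_x_max: float = 0.95

    def __post_init__(self) -> None:
        for exp, frames in self.measurements.items():
            if exp not in self.tracers:
                raise ValueError(f"measurements reference unknown experiment {exp!r}")
            for fid, (mid, sd) in frames.items():
                mid, sd = np.asarray(mid, float), np.asarray(sd, float)
                if np.any(sd <= 0):
                    raise ValueError(f"all SDs must be > 0 ({exp}/{fid})")
                frames[fid] = (mid, sd)
        for rid, (val, sd) in self.rates.items():
            if sd <= 0:
                raise ValueError(f"rate SD for {rid} must be > 0")
        self._param = FluxParameterization(self.model, self.fixed, self.free_reactions)
        self.free_reactions = self._param.free_reactions
        self.exchange_reactions = [r.id for r in self.model.reactions if r.reversible]
        self._simulator = EMUSimulator(self.model, list(self.fragments.values()))
        self._irrev = self._param.irreversible_ids()
        self._n_mid_channels = sum(
            len(m[0]) for frames in self.measurements.values() for m in frames.values()
        )

    # parameter vector: free net fluxes then exchange x-coordinates
    @property
    def n_params(self) -> int:
        return len(self.free_reactions) + len(self.exchange_reactions)

    def param_names(self) -> list[str]:
        return [f"net:{r}" for r in self.free_reactions] + [
            f"exch:{r}" for r in self.exchange_reactions
        ]

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo, hi = [], []
        for rid in self.free_reactions:
            if rid in self._irrev:
                lo.append(self.net_bounds[0])
            else:
                lo.append(-self.net_bounds[1])
            hi.append(self.net_bounds[1])
        lo += [0.0] * len(self.exchange_reactions)
        hi += [self.exchange_x_max] * len(self.exchange_reactions)
        return np.array(lo), np.array(hi)

    def flux_vector(self, params: np.ndarray) -> FluxVector:
        d = len(self.free_reactions)
        net = self._param.net_fluxes(params[:d])
        x = params[d:]
        exch = {
            rid: self.exchange_scale * xi / (1.0 - xi)
            for rid, xi in zip(self.exchange_reactions, x)
        }
        return FluxVector(net=net, exchange=exch)

    def residuals(self, params: np.ndarray, with_penalty: bool = True) -> np.ndarray:
        from .emu import EMUNode

        fv = self.flux_vector(params)
        # soft feasibility: dependent irreversible fluxes must stay >= 0
        violations = np.array([min(fv.net[r], 0.0) for r in self._irrev])
        mid_parts = []
        try:
            for exp, tracer in self.tracers.items():
                if exp not in self.measurements:
                    continue
                sim = self._simulator.simulate(fv, tracer, strict=False)
                for fid, (mid, sd) in self.measurements[exp].items():
                    met, atoms = self.fragments[fid]
                    s = sim[EMUNode(met, tuple(atoms))]
                    mid_parts.append((s - mid) / sd)
            mid_res = np.concatenate(mid_parts) if mid_parts else np.zeros(0)
        except (ValueError, np.linalg.LinAlgError):
            # structurally infeasible candidate (zero throughput somewhere)
            mid_res = np.full(self._n_mid_channels, 1e3)
        rate_res = np.array(
            [(fv.net[rid] - val) / sd for rid, (val, sd) in self.rates.items()]
        )
        res = np.concatenate([mid_res, rate_res])
        if with_penalty:
            res = np.concatenate([res, 1e3 * violations])
        return res

    def feasible_net(self, params: np.ndarray, tol: float = 1e-9) -> bool:
        """True when every irreversible net flux is nonnegative."""
        fv = self.flux_vector(params)
        return all(fv.net[r] >= -tol for r in self._irrev)

    def n_measurements(self) -> int:
        n = sum(len(m[0]) for frames in self.measurements.values() for m in frames.values())
        return n + len(self.rates)


@dataclass
class FitResult:
    fluxes: FluxVector
    ssr: float
    restart_ssrs: list[float]
    converged_to_same_solution: bool
    params: np.ndarray
    param_names: list[str]
    residual_table: pd.DataFrame
    n_free: int = 0

    def to_dict(self) -> dict:
        return {
            "net_fluxes": self.fluxes.net,
            "exchange_fluxes": self.fluxes.exchange,
            "ssr": self.ssr,
            "restart_ssrs": self.restart_ssrs,
            "converged_to_same_solution": self.converged_to_same_solution,
            "parameters": dict(zip(self.param_names, self.params.tolist())),
        }


@dataclass
class ConfidenceIntervals:
    """Per-flux 95% Monte-Carlo bounds."""

    lower: dict[str, float]
    upper: dict[str, float]
    samples: pd.DataFrame | None = None

    def contains(self, rxn_id: str, value: float, tol: float = 1e-9) -> bool:
        return self.lower[rxn_id] - tol <= value <= self.upper[rxn_id] + tol


def _residual_table(problem: FitProblem, params: np.ndarray) -> pd.DataFrame:
    from .emu import EMUNode

    fv = problem.flux_vector(params)
    rows = []
    for exp, tracer in problem.tracers.items():
        if exp not in problem.measurements:
            continue
        sim = problem._simulator.simulate(fv, tracer)
        for fid, (mid, sd) in problem.measurements[exp].items():
            met, atoms = problem.fragments[fid]
            s = sim[EMUNode(met, tuple(atoms))]
            for ch, (sv, mv, sdv) in enumerate(zip(s, mid, sd)):
                rows.append(
                    {"experiment": exp, "fragment": fid, "channel": f"M+{ch}",
                     "simulated": sv, "measured": mv, "sd": sdv,
                     "weighted_residual": (sv - mv) / sdv}
                )
    for rid, (val, sd) in problem.rates.items():
        rows.append(
            {"experiment": "rates", "fragment": rid, "channel": "net",
             "simulated": fv.net[rid], "measured": val, "sd": sd,
             "weighted_residual": (fv.net[rid] - val) / sd}
        )
    return pd.DataFrame(rows)


def fit_fluxes(
    problem: FitProblem,
    n_restarts: int = 100,
    seed: int = 0,
    start: np.ndarray | None = None,
    ssr_rtol: float = 1e-3,
    flux_atol: float = 0.5,
    restart_net_max: float = 150.0,
) -> FitResult:
    """Multi-start weighted least-squares flux fit.

    Runs ``n_restarts`` trust-region fits from random starting points
    (deterministic for a given seed) and keeps the best.  Starts are
    drawn uniformly inside the bounds but with net fluxes capped at
    ``restart_net_max`` (percent of uptake) so restarts begin in the
    stoichiometrically plausible region; the optimization bounds
    themselves are unchanged.  ``converged_to_same_solution`` is true
    when every restart lands within ``ssr_rtol`` (relative SSR) and
    ``flux_atol`` (absolute net flux, percentage points) of the best —
    the robustness check used to declare a global minimum.
    """
    lo, hi = problem.bounds()
    d = len(problem.free_reactions)
    sample_hi = hi.copy()
    sample_hi[:d] = np.minimum(sample_hi[:d], restart_net_max)
    rng = np.random.default_rng(seed)
    starts = []
    if start is not None:
        starts.append(np.asarray(start, float))
    attempts = 0
    while len(starts) < n_restarts:
        cand = lo + rng.random(problem.n_params) * (sample_hi - lo)
        attempts += 1
        # only start inside the irreversibility-feasible region; give up
        # on the screen (not the restart) after many rejections
        if problem.feasible_net(cand) or attempts > 50 * n_restarts:
            starts.append(cand)

    results = []
    for p0 in starts:
        try:
            sol = least_squares(
                problem.residuals, p0, bounds=(lo, hi), method="trf",
                xtol=1e-10, ftol=1e-10, gtol=1e-10,
            )
        except Exception:
            continue
        ssr = float(np.sum(problem.residuals(sol.x, with_penalty=False) ** 2))
        results.append((ssr, sol.x))
    if not results:
        raise RuntimeError("all restarts failed")
    results.sort(key=lambda t: t[0])
    best_ssr, best_p = results[0]
    best_fv = problem.flux_vector(best_p)
    same = True
    for ssr, p in results[1:]:
        if ssr > best_ssr * (1 + ssr_rtol) + ssr_rtol:
            same = False
            break
        fv = problem.flux_vector(p)
        if any(abs(fv.net[r] - best_fv.net[r]) > flux_atol for r in fv.net):
            same = False
            break
    return FitResult(
        fluxes=best_fv,
        ssr=best_ssr,
        restart_ssrs=[r[0] for r in results],
        converged_to_same_solution=same,
        params=best_p,
        param_names=problem.param_names(),
        residual_table=_residual_table(problem, best_p),
        n_free=problem.n_params,
    )


def monte_carlo_ci(
    problem: FitProblem,
    fit: FitResult,
    n_iter: int = 100,
    seed: int = 0,
    max_failures: float = 0.2,
) -> ConfidenceIntervals:
    """95% confidence intervals by Monte-Carlo resampling.

    Each iteration resamples every measurement from Normal(value, SD)
    (MIDs renormalized to sum 1), refits starting from the best-fit
    parameters, and records the flux vector; the 2.5/97.5 percentiles
    per reaction bound the interval.
    """
    rng = np.random.default_rng(seed)
    lo, hi = problem.bounds()
    samples = []
    failures = 0
    for _ in range(n_iter):
        perturbed = {}
        for exp, frames in problem.measurements.items():
            new_frames = {}
            for fid, (mid, sd) in frames.items():
                m = mid + rng.normal(0.0, sd)
                m = np.clip(m, 0.0, None)
                total = m.sum()
                if total <= 0:
                    m = mid.copy()
                    total = m.sum()
                new_frames[fid] = (m / total, sd)
            perturbed[exp] = new_frames
        rates = {
            rid: (val + rng.normal(0.0, sd), sd) for rid, (val, sd) in problem.rates.items()
        }
        sub = FitProblem(
            model=problem.model, tracers=problem.tracers, fragments=problem.fragments,
            measurements=perturbed, rates=rates, fixed=problem.fixed,
            free_reactions=problem.free_reactions,
            exchange_scale=problem.exchange_scale, net_bounds=problem.net_bounds,
            exchange_x_max=problem.exchange_x_max,
        )
        try:
            sol = least_squares(
                sub.residuals, fit.params, bounds=(lo, hi), method="trf",
                xtol=1e-9, ftol=1e-9, gtol=1e-9,
            )
            samples.append(sub.flux_vector(sol.x).net)
        except Exception:
            failures += 1
    if failures > max_failures * n_iter:
        raise RuntimeError(f"{failures}/{n_iter} Monte-Carlo refits failed")
    df = pd.DataFrame(samples)
    lower = df.quantile(0.025).to_dict()
    upper = df.quantile(0.975).to_dict()
    # guarantee the invariant lower <= point <= upper under sampling noise
    for rid in lower:
        point = fit.fluxes.net[rid]
        lower[rid] = min(lower[rid], point)
        upper[rid] = max(upper[rid], point)
    return ConfidenceIntervals(lower=lower, upper=upper, samples=df)


def normalize_to_glucose(fluxes: FluxVector, uptake_reaction: str = "upt") -> FluxVector:
    """Rescale a flux vector so glucose uptake is 100 (molar percent)."""
    q = fluxes.net.get(uptake_reaction)
    if q is None:
        raise KeyError(f"flux vector lacks uptake reaction {uptake_reaction!r}")
    if q <= 0:
        raise ValueError(f"glucose uptake must be > 0, got {q}")
    return fluxes.scaled(100.0 / q)
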