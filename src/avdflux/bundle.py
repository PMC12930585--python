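"""Reading fit-problem directories.

A problem bundle is a directory with ``network.csv``, ``drains.csv``,
``tracers.yaml``, ``fragments.yaml``, ``mids.csv`` and ``rates.csv`` —
the on-disk form written by the synthetic generator and editable by
hand for real datasets.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .emu import TracerSpec
from .fitting import DEFAULT_MID_SD, FitProblem
from .isotopes import load_fragments
from .network import load_network

__all__ = ["load_problem_dir"]


def load_problem_dir(
    path: str | Path,
    fixed: dict[str, float] | None = None,
    free_reactions: list[str] | None = None,
    mid_sd: float = DEFAULT_MID_SD,
) -> FitProblem:
    """Assemble a :class:`FitProblem` from a bundle directory.

    ``fixed``/``free_reactions`` default to the values recorded in the
    bundle's ``manifest.json`` when present.
    """
    from .synthetic import corrected_measurements

    path = Path(path)
    for name in ("network.csv", "tracers.yaml", "fragments.yaml", "mids.csv"):
        if not (path / name).exists():
            raise FileNotFoundError(f"problem bundle is missing {path / name}")
    drains = path / "drains.csv"
    model = load_network(path / "network.csv", drains=drains if drains.exists() else None)
    tracers_raw = yaml.safe_load((path / "tracers.yaml").read_text())
    tracers = {
        exp: TracerSpec(
            substrate=spec["substrate"],
            components=tuple((p, float(f)) for p, f in spec["components"]),
            purity=float(spec.get("purity", 0.99)),
        )
        for exp, spec in tracers_raw.items()
    }
    fragments = load_fragments(path / "fragments.yaml")
    raw = pd.read_csv(path / "mids.csv")
    measurements = corrected_measurements(raw, fragments, sd=mid_sd)
    rates = {}
    rates_file = path / "rates.csv"
    if rates_file.exists():
        for _, row in pd.read_csv(rates_file).iterrows():
            rates[str(row["rxn_id"])] = (float(row["value_percent"]), float(row["sd"]))
    manifest_file = path / "manifest.json"
    if manifest_file.exists():
        manifest = json.loads(manifest_file.read_text())
        fixed = fixed if fixed is not None else manifest.get("fixed")
        free_reactions = (
            free_reactions if free_reactions is not None else manifest.get("free_reactions")
        )
    return FitProblem(
        model=model,
        tracers=tracers,
        fragments={fid: (f.metabolite, f.atoms) for fid, f in fragments.items()},
        measurements=measurements,
        rates=rates,
        fixed=fixed or {},
        free_reactions=free_reactions,
    )
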