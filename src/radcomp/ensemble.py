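"""Monte Carlo propagation of parameter uncertainty to CR distributions.

Spatial and temporal variation of the compartment model's parameters is
represented by probability distribution functions attached to individual
config parameters.  Each draw perturbs a deep copy of the configuration,
re-solves the steady tracer system for every radionuclide, and records
the resulting CR table; the ensemble is then summarized per
(radionuclide x group) by the median, geometric mean and 5th/95th
percentiles (linear interpolation between order statistics).

The interval is reported as ``p5``/``p95`` -- explicitly percentiles, not
a confidence interval -- covering the central 90% of the distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .config import ConfigError, ModelConfig, ParameterPDF, validate
from .foodweb import build_fluxes
from .cr import cr_from_state
from .solvers import solve_steady
from .tracer import assemble

_MAX_REJECTION = 1000


class EnsembleError(RuntimeError):
    """Raised when too many draws fail to produce a solvable system."""


@dataclass
class EnsembleSummary:
    """Summary statistics of the CR ensemble."""

    table: pd.DataFrame  # per (radionuclide, group): n, median, gm, p5, p95
    seed: int
    n_requested: int
    n_failed: int
    failures: list[str] = field(default_factory=list)

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False, float_format="%.10e")


def _draw(pdf: ParameterPDF, rng: np.random.Generator) -> float:
    p = pdf.parameters
    for _ in range(_MAX_REJECTION):
        if pdf.distribution == "lognormal":
            sigma = np.log(p["gsd"])
            x = p["median"] * np.exp(rng.normal(0.0, sigma))
        elif pdf.distribution == "normal":
            x = rng.normal(p["mean"], p["sd"])
        elif pdf.distribution == "uniform":
            x = rng.uniform(p["low"], p["high"])
        elif pdf.distribution == "triangular":
            x = rng.triangular(p["left"], p["mode"], p["right"])
        elif pdf.distribution == "fixed":
            x = p["value"]
        else:
            raise ConfigError(f"unknown distribution {pdf.distribution!r}")
        if pdf.bounds is None:
            return float(x)
        lo, hi = pdf.bounds
        if lo <= x <= hi:
            return float(x)
        if pdf.distribution == "fixed":
            raise ConfigError(
                f"pdf {pdf.target}: fixed value {x} outside bounds {pdf.bounds}"
            )
    raise ConfigError(
        f"pdf {pdf.target}: rejection sampling exhausted within bounds {pdf.bounds}"
    )


def _resolve_parent(config: ModelConfig, target: str):
    parts = target.split(".")
    obj = config
    for part in parts[:-1]:
        if isinstance(obj, list):
            matches = [item for item in obj if getattr(item, "name", None) == part]
            if not matches:
                raise ConfigError(f"pdf target {target!r}: no element named {part!r}")
            obj = matches[0]
        elif hasattr(obj, part):
            obj = getattr(obj, part)
        else:
            raise ConfigError(f"pdf target {target!r}: no field {part!r}")
    leaf = parts[-1]
    if isinstance(obj, list):
        raise ConfigError(f"pdf target {target!r}: cannot end on a list")
    if not hasattr(obj, leaf):
        raise ConfigError(f"pdf target {target!r}: no field {leaf!r}")
    return obj, leaf


def apply_draw(config: ModelConfig, values: dict[str, float]) -> ModelConfig:
    """Return a deep copy with the drawn parameter values applied."""
    out = config.copy()
    for target, value in values.items():
        parent, leaf = _resolve_parent(out, target)
        setattr(parent, leaf, value)
    for b in out.basins:  # keep the derived volume consistent
        b.volume = b.surface_area * b.mean_depth
    return out


def sample_configs(
    config: ModelConfig, n: int, seed: int
) -> list[ModelConfig]:
    """``n`` perturbed configurations, deterministic for a given seed.

    Parameters without a PDF are untouched; draws respect truncation
    bounds by rejection sampling.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    for pdf in config.pdfs:
        _resolve_parent(config, pdf.target)  # fail fast on bad paths
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        values = {pdf.target: _draw(pdf, rng) for pdf in config.pdfs}
        out.append(apply_draw(config, values))
    return out


def run_ensemble(
    config: ModelConfig,
    n: int,
    seed: int,
    mode: str | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Steady-state CR tables for ``n`` parameter draws.

    Returns the concatenated per-draw tables (with a ``draw`` column) and
    the diagnostics of failed draws, which are excluded.  More than 10%
    failures raise :class:`EnsembleError`.
    """
    draws = sample_configs(config, n, seed)
    # the carbon web only changes when a PDF perturbs it; otherwise build once
    web_targets = ("groups", "basins", "diet")
    static_web = not any(
        p.target.split(".")[0] in web_targets for p in config.pdfs
    )
    shared_fluxes = build_fluxes(config) if static_web else None
    tables = []
    failures: list[str] = []
    for i, drawn in enumerate(draws):
        violations = validate(drawn)
        if violations:
            failures.append(f"draw {i}: " + "; ".join(violations))
            continue
        try:
            frames = []
            for rn in drawn.radionuclides:
                system = assemble(drawn, rn, mode=mode, fluxes=shared_fluxes)
                state = solve_steady(system)
                frames.append(cr_from_state(system, state))
            table = pd.concat(frames, ignore_index=True)
            table.insert(0, "draw", i)
            tables.append(table)
        except Exception as exc:  # noqa: BLE001 - recorded as diagnostics
            failures.append(f"draw {i}: {type(exc).__name__}: {exc}")
    if len(failures) > 0.10 * n:
        raise EnsembleError(
            f"{len(failures)}/{n} draws failed; first: {failures[0]}"
        )
    if not tables:
        raise EnsembleError("no successful draws")
    return pd.concat(tables, ignore_index=True), failures


def summarize(
    per_draw: pd.DataFrame,
    seed: int = 0,
    n_requested: int | None = None,
    failures: Sequence[str] = (),
) -> EnsembleSummary:
    """Median, geometric mean and 5/95 percentiles per (radionuclide, group).

    The geometric mean is exp(mean(log x)) and is reported as NaN with a
    warning column when any sample is non-positive.
    """
    if per_draw.empty:
        raise ValueError("no draws to summarize")
    rows = []
    for (rn, group), sub in per_draw.groupby(["radionuclide", "group"], sort=True):
        x = sub["cr"].to_numpy(dtype=float)
        positive = bool(np.all(x > 0))
        rows.append(
            {
                "radionuclide": rn,
                "group": group,
                "n": len(x),
                "median": float(np.percentile(x, 50)),
                "gm": float(np.exp(np.mean(np.log(x)))) if positive else float("nan"),
                "p5": float(np.percentile(x, 5)),
                "p95": float(np.percentile(x, 95)),
                "gm_defined": positive,
            }
        )
    table = pd.DataFrame(rows)
    n_req = n_requested if n_requested is not None else per_draw["draw"].nunique()
    return EnsembleSummary(
        table=table,
        seed=seed,
        n_requested=int(n_req),
        n_failed=len(failures),
        failures=list(failures),
    )


def load_measured_cr() -> pd.DataFrame:
    """Field-measured concentration ratios (m^3 kgC^-1) for the Forsmark
    coastal area: geometric means with 95% interval bounds for Ni-59,
    Cs-135 and Th-230 in phytoplankton, zooplankton and fish, compiled
    from published site surveys.  For overlay comparison only -- the toy
    parameterization makes no claim of reproducing them.
    """
    path = Path(__file__).parent / "data" / "forsmark_measured_cr.csv"
    return pd.read_csv(path)
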