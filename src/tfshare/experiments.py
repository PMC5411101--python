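"""Figure-level experiments: parameter sweeps, collapse checks, modality scans.

Every experiment returns a tidy table (one row per swept value) together
with provenance (the spec template, the simulation settings and the master
seed), and is deterministic for a fixed seed.  The CME engine computes
exact moments; the SSA engine attaches bootstrap standard errors.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .analytics import ModeReport, count_modes, fano, fold_change, master_curve_variance
from .exact import cme_steady_state
from .model import ModelSpec, ValidationError, validate_model
from .ssa import sample_population

__all__ = [
    "SimSettings",
    "SweepTable",
    "CollapseReport",
    "sweep_tf",
    "sweep_competitors",
    "collapse_residuals",
    "load_config",
]

SUMMARY_COLUMNS = [
    "N_TF",
    "N_P",
    "N_C",
    "mode",
    "mean",
    "variance",
    "fano",
    "fold_change",
    "se_mean",
    "se_variance",
    "n_cells",
    "seed",
]


@dataclass
class SimSettings:
    """Engine-independent simulation/solver settings with figure-run defaults."""

    engine: str = "cme"
    n_cells: int = 10_000
    burn_in: float | None = None
    t_end: float | None = None
    m_max: int | None = None
    tol: float = 1e-8
    bootstrap: int = 1000
    smoothing_window: int = 5
    prominence: float = 0.05

    def __post_init__(self) -> None:
        if self.engine not in ("cme", "ssa"):
            raise ValidationError(f"engine must be 'cme' or 'ssa', got {self.engine!r}")


_SETTINGS_FIELDS = {
    "engine",
    "n_cells",
    "burn_in",
    "t_end",
    "m_max",
    "tol",
    "bootstrap",
    "smoothing_window",
    "prominence",
    "seed",
}


@dataclass
class SweepTable:
    """Summary statistics versus one swept parameter, with provenance."""

    table: pd.DataFrame
    swept: str
    provenance: dict

    def to_csv(self, path) -> None:
        path = Path(path)
        self.table.to_csv(path, index=False)
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(self.provenance, indent=2))

    def argmax(self, column: str) -> int:
        """Swept value maximizing ``column`` (ties toward the smaller value)."""
        vals = self.table[column].to_numpy()
        return int(self.table[self.swept].iloc[int(np.argmax(vals))])


def _point_seed(seed: int, index: int) -> int:
    return int(np.random.SeedSequence(entropy=seed, spawn_key=(index,)).generate_state(1)[0] % (2**31))


def _summarize_point(spec: ModelSpec, settings: SimSettings, seed: int, index: int):
    """One summary row; returns (row dict, m-marginal pmf)."""
    if settings.engine == "cme":
        dist = cme_steady_state(spec, m_max=settings.m_max, tol=settings.tol)
        mean, var = dist.mean_m(), dist.var_m()
        pmf = dist.m_marginal()
        se_mean = se_var = float("nan")
        n_cells: float = float("nan")
        pt_seed: float = float("nan")
    else:
        pt_seed = _point_seed(seed, index)
        sample = sample_population(
            spec, settings.n_cells, seed=pt_seed, burn_in=settings.burn_in
        )
        mean, var, se_mean, se_var = sample.moment_summary(
            bootstrap=settings.bootstrap, seed=pt_seed
        )
        pmf = sample.m_pmf()
        n_cells = settings.n_cells
    row = {
        "N_TF": spec.n_tf,
        "N_P": spec.n_promoters,
        "N_C": spec.n_competitors,
        "mode": spec.mode.value,
        "mean": mean,
        "variance": var,
        "fano": fano(mean, var),
        "fold_change": fold_change(mean, spec),
        "se_mean": se_mean,
        "se_variance": se_var,
        "n_cells": n_cells,
        "seed": pt_seed,
    }
    return row, pmf


def _check_sweep_values(values, name: str) -> list[int]:
    values = [int(v) for v in values]
    if not values:
        raise ValueError(f"{name} must be non-empty")
    if any(v < 0 for v in values):
        raise ValueError(f"{name} must be non-negative")
    if any(b <= a for a, b in zip(values, values[1:])):
        raise ValueError(f"{name} must be strictly increasing")
    return values


def _provenance(spec: ModelSpec, settings: SimSettings, seed: int, swept, values) -> dict:
    from . import __version__

    return {
        "spec_template": spec.to_dict(),
        "settings": asdict(settings),
        "seed": seed,
        "swept": swept,
        "values": list(values),
        "package_version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }


def sweep_tf(spec_template, ntf_values: Sequence[int], engine: str | None = None,
             settings: SimSettings | None = None, seed: int = 0) -> SweepTable:
    """Summary statistics versus TF copy number.

    With the CME engine the variance of the mRNA distribution peaks when
    the TF number is at (activators) or near (repressors' Fano factor,
    slightly above) the promoter copy number.
    """
    spec_template = validate_model(spec_template)
    settings = settings or SimSettings()
    if engine is not None:
        settings = SimSettings(**{**asdict(settings), "engine": engine})
    ntf_values = _check_sweep_values(ntf_values, "ntf_values")
    rows = []
    for i, ntf in enumerate(ntf_values):
        row, _ = _summarize_point(spec_template.replace(n_tf=ntf), settings, seed, i)
        rows.append(row)
    table = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    return SweepTable(table, "N_TF", _provenance(spec_template, settings, seed, "N_TF", ntf_values))


def sweep_competitors(spec_template, nc_values: Sequence[int], engine: str | None = None,
                      settings: SimSettings | None = None, seed: int = 0):
    """Summary statistics and full mRNA pmfs versus competitor-site number.

    Returns ``(SweepTable, pmfs)`` where ``pmfs`` maps each N_C to a pair
    ``(m_marginal pmf, ModeReport)``.  Raising the number of competitor
    sites at fixed TF number can transform a unimodal mRNA distribution
    into a multimodal one.
    """
    spec_template = validate_model(spec_template)
    settings = settings or SimSettings()
    if engine is not None:
        settings = SimSettings(**{**asdict(settings), "engine": engine})
    nc_values = _check_sweep_values(nc_values, "nc_values")
    rows = []
    pmfs: dict[int, tuple[np.ndarray, ModeReport]] = {}
    for i, nc in enumerate(nc_values):
        spec = spec_template.replace(n_competitors=nc)
        row, pmf = _summarize_point(spec, settings, seed, i)
        rows.append(row)
        report = count_modes(
            pmf / pmf.sum(), settings.smoothing_window, settings.prominence
        )
        pmfs[nc] = (pmf, report)
    table = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    return (
        SweepTable(table, "N_C", _provenance(spec_template, settings, seed, "N_C", nc_values)),
        pmfs,
    )


@dataclass
class CollapseReport:
    """Residuals of (mean, variance) points against the master curve."""

    points: pd.DataFrame  # columns: N_P, mean_per_promoter, var_per_promoter, predicted, residual
    max_residual: float
    rates: dict
    mode: str

    def to_json(self, path) -> None:
        payload = {
            "rates": self.rates,
            "mode": self.mode,
            "max_residual": self.max_residual,
            "points": self.points.to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def collapse_residuals(points, rates: Mapping, mode, eps: float = 1e-12) -> CollapseReport:
    """Relative residuals of per-promoter (mean, variance) points against the
    single-promoter master curve.

    ``points`` is a sequence of ``(n_promoters, mean, variance)`` triples
    (aggregate moments; they are divided by N_P internally).  The residual
    of a point is |var/N_P - curve(mean/N_P)| / max(curve(mean/N_P), eps).
    """
    points = list(points)
    if not points:
        raise ValueError("points must be non-empty")
    recs = []
    for np_, mean, var in points:
        m = mean / np_
        v = var / np_
        pred = master_curve_variance(rates, mode, m)
        resid = abs(v - pred) / max(pred, eps)
        recs.append(
            {
                "N_P": int(np_),
                "mean_per_promoter": m,
                "var_per_promoter": v,
                "predicted": pred,
                "residual": resid,
            }
        )
    df = pd.DataFrame(recs)
    return CollapseReport(
        points=df,
        max_residual=float(df["residual"].max()),
        rates={k: float(rates[k]) for k in ("r", "gamma", "k_off")},
        mode=str(getattr(mode, "value", mode)),
    )


def load_config(path) -> tuple[ModelSpec, SimSettings, int]:
    """Read a JSON config into (ModelSpec, SimSettings, seed).

    The flat object mixes model fields with settings fields; unknown keys
    are rejected with the offending names.
    """
    path = Path(path)
    try:
        raw = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise ValidationError(f"config {path} is not valid JSON: {e}") from e
    if not isinstance(raw, dict):
        raise ValidationError("config must be a JSON object")
    from .model import _SPEC_FIELDS  # shared source of truth for field names

    model_raw = {k: v for k, v in raw.items() if k in _SPEC_FIELDS}
    settings_raw = {k: v for k, v in raw.items() if k in _SETTINGS_FIELDS}
    unknown = set(raw) - _SPEC_FIELDS - _SETTINGS_FIELDS
    if unknown:
        raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
    spec = validate_model(model_raw)
    seed = int(settings_raw.pop("seed", 0))
    settings = SimSettings(**settings_raw)
    return spec, settings, seed
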