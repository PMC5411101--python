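"""Exact stochastic simulation (Gillespie direct method) of TF sharing.

The simulator draws statistically exact sample paths of the continuous-time
Markov chain whose propensities are defined in :mod:`tfshare.model`.
Identical promoter copies are tracked individually — each mRNA molecule is
attributed to the promoter that produced it — which leaves the aggregate
dynamics of (n, c, m) unchanged but makes per-promoter correlation
measurements possible.

Steady-state "isogenic population" snapshots are taken from independent
replicates, each run from the all-free initial condition for a burn-in of
ten times the slowest relaxation time of the system (the mRNA lifetime
1/gamma or the promoter/competitor binding timescale, whichever is longer)
by default.  Replicate random streams are spawned from a single
master seed with a counter-based scheme, so any replicate is reproducible
in isolation and every result is bit-reproducible for a fixed
(spec, settings, seed).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .model import (
    InconsistentStateError,
    ModelSpec,
    RegulationMode,
    SystemState,
    validate_model,
)

__all__ = [
    "Trajectory",
    "PopulationSample",
    "simulate_trajectory",
    "sample_population",
    "replicate_rng",
]

DEFAULT_BURN_IN_RELAXATION_TIMES = 10.0


def relaxation_time(spec: ModelSpec) -> float:
    """Slowest relaxation timescale of the coupled binding/mRNA system.

    The mRNA pool relaxes at gamma but the promoter occupancy chain relaxes
    at order k_on + k_off (and the competitor sites at k_on_c + k_off_c),
    which for slow TF kinetics is the bottleneck; the burn-in must cover the
    slowest of these or steady-state samples stay biased toward the initial
    condition.
    """
    times = [1.0 / spec.gamma]
    if spec.k_on + spec.k_off > 0 and spec.n_tf > 0:
        times.append(1.0 / (spec.k_on + spec.k_off))
    if spec.n_competitors > 0 and spec.k_on_c + spec.k_off_c > 0 and spec.n_tf > 0:
        times.append(1.0 / (spec.k_on_c + spec.k_off_c))
    return max(times)


def replicate_rng(seed: int, replicate: int) -> np.random.Generator:
    """Independent, individually reproducible stream for one replicate."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(replicate,)))


@dataclass
class Trajectory:
    """One simulated sample path.

    ``recording='events'`` stores the state after every reaction (plus the
    initial state); ``recording='grid'`` stores snapshots on a fixed time
    grid of spacing ``dt``.
    """

    spec: ModelSpec
    seed: int
    recording: str
    times: np.ndarray
    occupancy: np.ndarray  # (T, N_P) int8
    bound_competitors: np.ndarray  # (T,)
    mrna: np.ndarray  # (T, N_P)

    @property
    def n(self) -> np.ndarray:
        return self.occupancy.sum(axis=1)

    @property
    def c(self) -> np.ndarray:
        return self.bound_competitors

    @property
    def m(self) -> np.ndarray:
        return self.mrna.sum(axis=1)

    def to_tsv(self, path, per_promoter: bool = True) -> None:
        """Write the trajectory as TSV with a JSON provenance sidecar."""
        path = Path(path)
        np_ = self.spec.n_promoters
        cols = ["time", "n", "c", "m"]
        data = [self.times, self.n, self.c, self.m]
        if per_promoter:
            for i in range(np_):
                cols.append(f"s_{i + 1}")
                data.append(self.occupancy[:, i])
            for i in range(np_):
                cols.append(f"m_{i + 1}")
                data.append(self.mrna[:, i])
        with open(path, "w") as fh:
            fh.write("\t".join(cols) + "\n")
            for row in zip(*data):
                fh.write("\t".join(_fmt(v) for v in row) + "\n")
        sidecar = {"spec": self.spec.to_dict(), "seed": self.seed, "recording": self.recording}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


@dataclass
class PopulationSample:
    """Steady-state snapshot across independent replicates ("cells")."""

    spec: ModelSpec
    n_cells: int
    burn_in: float
    seed: int
    occupancy: np.ndarray  # (n_cells, N_P)
    bound_competitors: np.ndarray  # (n_cells,)
    mrna: np.ndarray  # (n_cells, N_P)

    @property
    def n(self) -> np.ndarray:
        return self.occupancy.sum(axis=1)

    @property
    def c(self) -> np.ndarray:
        return self.bound_competitors

    @property
    def m(self) -> np.ndarray:
        return self.mrna.sum(axis=1)

    def m_pmf(self, m_max: int | None = None) -> np.ndarray:
        """Empirical pmf of the total mRNA count."""
        m = self.m
        if m_max is None:
            m_max = int(m.max(initial=0))
        return np.bincount(m, minlength=m_max + 1)[: m_max + 1] / max(len(m), 1)

    def moment_summary(self, bootstrap: int = 1000, seed: int = 0):
        """(mean, variance, se_mean, se_variance) of the total mRNA count."""
        m = self.m.astype(float)
        mean = float(m.mean())
        var = float(m.var(ddof=1)) if len(m) > 1 else float("nan")
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0xB00, 0)))
        if bootstrap and len(m) > 1:
            idx = rng.integers(0, len(m), size=(bootstrap, len(m)))
            res = m[idx]
            se_mean = float(res.mean(axis=1).std(ddof=1))
            se_var = float(res.var(axis=1, ddof=1).std(ddof=1))
        else:
            se_mean = se_var = float("nan")
        return mean, var, se_mean, se_var

    def to_csv(self, path) -> None:
        path = Path(path)
        np_ = self.spec.n_promoters
        cols = ["replicate", "n", "c", "m"] + [f"m_{i + 1}" for i in range(np_)]
        with open(path, "w") as fh:
            fh.write(",".join(cols) + "\n")
            n, c, m = self.n, self.c, self.m
            for k in range(self.n_cells):
                row = [k, n[k], c[k], m[k], *self.mrna[k]]
                fh.write(",".join(str(int(v)) for v in row) + "\n")
        sidecar = {
            "spec": self.spec.to_dict(),
            "seed": self.seed,
            "n_cells": self.n_cells,
            "burn_in": self.burn_in,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def _fmt(v) -> str:
    if isinstance(v, (float, np.floating)):
        return format(float(v), ".10g")
    return str(int(v))


def _gillespie(
    spec: ModelSpec,
    s: list,
    mrna: list,
    c: int,
    t: float,
    t_stop: float,
    rng: np.random.Generator,
    on_event=None,
    check: bool = False,
):
    """Advance one cell to ``t_stop``; returns (s, mrna, c).

    The channel layout is fixed (promoter binding, unbinding, competitor
    binding/unbinding, transcription, decay) and promoter selection within
    an aggregate channel is by a second uniform draw, which is equivalent in
    law to the per-promoter direct method.
    """
    kon, koff = spec.k_on, spec.k_off
    konc, koffc = spec.k_on_c, spec.k_off_c
    r, rb, gamma = spec.r, spec.r_basal, spec.gamma
    ntf, np_, nc = spec.n_tf, spec.n_promoters, spec.n_competitors
    activator = spec.mode is RegulationMode.ACTIVATOR
    n = sum(s)
    m_tot = sum(mrna)
    random = rng.random
    while True:
        free = ntf - n - c
        a_bind = kon * free * (np_ - n)
        a_unbind = koff * n
        a_cbind = konc * free * (nc - c)
        a_cunbind = koffc * c
        if activator:
            a_tx = r * n + rb * (np_ - n)
        else:
            a_tx = r * (np_ - n)
        a_deg = gamma * m_tot
        a0 = a_bind + a_unbind + a_cbind + a_cunbind + a_tx + a_deg
        if a0 <= 0.0:
            break  # absorbing state: nothing can happen any more
        u = random()
        while u <= 0.0:
            u = random()
        t_next = t - math.log(u) / a0
        if t_next > t_stop:
            break
        t = t_next
        x = random() * a0
        if x < a_bind:
            j = int(random() * (np_ - n))  # uniform among free promoters
            for i in range(np_):
                if not s[i]:
                    if j == 0:
                        s[i] = 1
                        break
                    j -= 1
            n += 1
        elif x < a_bind + a_unbind:
            j = int(random() * n)
            for i in range(np_):
                if s[i]:
                    if j == 0:
                        s[i] = 0
                        break
                    j -= 1
            n -= 1
        elif x < a_bind + a_unbind + a_cbind:
            c += 1
        elif x < a_bind + a_unbind + a_cbind + a_cunbind:
            c -= 1
        elif x < a_bind + a_unbind + a_cbind + a_cunbind + a_tx:
            if activator and rb > 0.0:
                y = random() * a_tx  # weighted: r for bound, rb for free
                for i in range(np_):
                    y -= r if s[i] else rb
                    if y < 0.0:
                        mrna[i] += 1
                        break
                else:
                    mrna[np_ - 1] += 1
            else:
                # uniform among transcribing promoters
                k = n if activator else np_ - n
                j = int(random() * k)
                want = 1 if activator else 0
                for i in range(np_):
                    if s[i] == want:
                        if j == 0:
                            mrna[i] += 1
                            break
                        j -= 1
            m_tot += 1
        else:
            j = int(random() * m_tot)
            for i in range(np_):
                if j < mrna[i]:
                    mrna[i] -= 1
                    break
                j -= mrna[i]
            m_tot -= 1
        if check:
            assert 0 <= n <= np_ and 0 <= c <= nc and n + c <= ntf and m_tot >= 0
        if on_event is not None:
            on_event(t, s, c, mrna)
    return s, mrna, c


def simulate_trajectory(
    spec,
    t_end: float,
    seed: int,
    recording: str = "events",
    dt: float | None = None,
    initial_state: SystemState | None = None,
    check_invariants: bool = False,
) -> Trajectory:
    """Simulate one exact sample path up to ``t_end`` seconds.

    Parameters
    ----------
    recording
        ``'events'`` records every reaction; ``'grid'`` records snapshots at
        multiples of ``dt`` (required for grid mode).
    check_invariants
        Assert TF conservation and non-negativity after every event.
    """
    spec = validate_model(spec)
    if t_end < 0:
        raise ValueError(f"t_end must be >= 0, got {t_end}")
    if recording not in ("events", "grid"):
        raise ValueError(f"recording must be 'events' or 'grid', got {recording!r}")
    if recording == "grid":
        if dt is None or dt <= 0:
            raise ValueError("grid recording requires dt > 0")
    state0 = SystemState.initial(spec) if initial_state is None else initial_state
    state0.check(spec)
    rng = replicate_rng(seed, 0)
    s = [int(v) for v in state0.occupancy]
    mrna = [int(v) for v in state0.mrna_per_promoter]
    c = state0.c

    times = [0.0]
    occ = [list(s)]
    cs = [c]
    ms = [list(mrna)]

    if recording == "events":

        def on_event(t, s_, c_, mrna_):
            times.append(t)
            occ.append(list(s_))
            cs.append(c_)
            ms.append(list(mrna_))

        _gillespie(spec, s, mrna, c, 0.0, t_end, rng, on_event, check_invariants)
    else:
        grid = np.arange(0.0, t_end + 0.5 * dt, dt)
        cursor = [1]  # grid[0] already recorded

        def on_event(t, s_, c_, mrna_):
            # snapshot value at a grid point is the state just before it
            while cursor[0] < len(grid) and grid[cursor[0]] < t:
                times.append(float(grid[cursor[0]]))
                occ.append(prev[0])
                cs.append(prev[1])
                ms.append(prev[2])
                cursor[0] += 1
            prev[0], prev[1], prev[2] = list(s_), c_, list(mrna_)

        prev = [list(s), c, list(mrna)]
        _gillespie(spec, s, mrna, c, 0.0, t_end, rng, on_event, check_invariants)
        while cursor[0] < len(grid):
            times.append(float(grid[cursor[0]]))
            occ.append(prev[0])
            cs.append(prev[1])
            ms.append(prev[2])
            cursor[0] += 1

    return Trajectory(
        spec=spec,
        seed=seed,
        recording=recording,
        times=np.asarray(times, dtype=float),
        occupancy=np.asarray(occ, dtype=np.int8),
        bound_competitors=np.asarray(cs, dtype=np.int64),
        mrna=np.asarray(ms, dtype=np.int64),
    )


def sample_population(
    spec,
    n_cells: int,
    seed: int,
    burn_in: float | None = None,
    initial_state: SystemState | None = None,
    method: str = "replicates",
    spacing: float | None = None,
    check_invariants: bool = False,
) -> PopulationSample:
    """Steady-state mRNA/occupancy snapshot across an isogenic population.

    ``method='replicates'`` (default) runs ``n_cells`` independent cells for
    ``burn_in`` seconds each.  ``method='time_average'`` runs a single long
    trajectory and records ``n_cells`` snapshots separated by ``spacing``
    (default five relaxation times) after the burn-in; by ergodicity both sample the same
    stationary law, which is cross-checked in the test suite.
    """
    spec = validate_model(spec)
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    default_burn = DEFAULT_BURN_IN_RELAXATION_TIMES * relaxation_time(spec)
    if burn_in is None:
        burn_in = default_burn
    elif burn_in < default_burn:
        warnings.warn(
            f"burn_in={burn_in:g}s is below the default {default_burn:g}s "
            "(10 times the slowest relaxation time); the sample may not be stationary",
            stacklevel=2,
        )
    if initial_state is not None:
        initial_state.check(spec)

    np_ = spec.n_promoters
    occ = np.zeros((n_cells, np_), dtype=np.int8)
    cs = np.zeros(n_cells, dtype=np.int64)
    ms = np.zeros((n_cells, np_), dtype=np.int64)

    if method == "replicates":
        for k in range(n_cells):
            st = SystemState.initial(spec) if initial_state is None else initial_state
            s = [int(v) for v in st.occupancy]
            mrna = [int(v) for v in st.mrna_per_promoter]
            rng = replicate_rng(seed, k)
            s, mrna, c = _gillespie(
                spec, s, mrna, st.c, 0.0, burn_in, rng, check=check_invariants
            )
            occ[k] = s
            cs[k] = c
            ms[k] = mrna
    elif method == "time_average":
        if spacing is None:
            spacing = 5.0 * relaxation_time(spec)
        st = SystemState.initial(spec) if initial_state is None else initial_state
        s = [int(v) for v in st.occupancy]
        mrna = [int(v) for v in st.mrna_per_promoter]
        c = st.c
        rng = replicate_rng(seed, 0)
        t = 0.0
        s, mrna, c = _gillespie(spec, s, mrna, c, t, burn_in, rng, check=check_invariants)
        t = burn_in
        for k in range(n_cells):
            s, mrna, c = _gillespie(
                spec, s, mrna, c, t, t + spacing, rng, check=check_invariants
            )
            t += spacing
            occ[k] = s
            cs[k] = c
            ms[k] = mrna
    else:
        raise ValueError(f"method must be 'replicates' or 'time_average', got {method!r}")

    return PopulationSample(
        spec=spec,
        n_cells=n_cells,
        burn_in=float(burn_in),
        seed=seed,
        occupancy=occ,
        bound_competitors=cs,
        mrna=ms,
    )
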