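"""Domain model of transcription under transcription-factor (TF) resource sharing.

A fixed pool of ``n_tf`` TF molecules is shared between ``n_promoters``
identical promoter copies (one TF binding site each) and ``n_competitors``
competitor ("decoy") sites that bind TFs without driving the target gene.
A promoter bound by an activator transcribes at rate ``r`` (rate ``r_basal``
when free); a promoter bound by a repressor is silent and transcribes at
rate ``r`` when free.  mRNA decays at rate ``gamma`` per molecule.

All rates are in s^-1 and all copy numbers are exact non-negative integers;
there is no concentration (mass-action volume) approximation.  TF copy
number is conserved: at all times ``n + c <= n_tf`` where ``n`` is the
number of TF-promoter complexes and ``c`` the number of TF-bound competitor
sites.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field, fields
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "RegulationMode",
    "ModelSpec",
    "SystemState",
    "ReactionKind",
    "ReactionChannel",
    "ValidationError",
    "InconsistentStateError",
    "validate_model",
    "free_tf_count",
    "propensity_vector",
    "transcription_rates",
]


class ValidationError(ValueError):
    """A parameter set violates the model's invariants."""


class InconsistentStateError(ValueError):
    """A microstate is incompatible with its parameter set."""


class RegulationMode(str, enum.Enum):
    """Whether the TF promotes or blocks transcription of the target gene."""

    ACTIVATOR = "activator"
    REPRESSOR = "repressor"


def _as_count(value, name: str) -> int:
    if isinstance(value, bool) or value is None:
        raise ValidationError(f"{name} must be a non-negative integer, got {value!r}")
    if isinstance(value, float):
        if not value.is_integer():
            raise ValidationError(f"{name} must be an integer, got {value!r}")
        value = int(value)
    if not isinstance(value, (int, np.integer)):
        raise ValidationError(f"{name} must be an integer, got {value!r}")
    if value < 0:
        raise ValidationError(f"{name} must be >= 0, got {value}")
    return int(value)


def _as_rate(value, name: str) -> float:
    try:
        value = float(value)
    except (TypeError, ValueError):
        raise ValidationError(f"{name} must be a number, got {value!r}") from None
    if not math.isfinite(value) or value < 0:
        raise ValidationError(f"{name} must be a finite rate >= 0 s^-1, got {value}")
    return value


@dataclass(frozen=True)
class ModelSpec:
    """Full parameterization of one TF-competition scenario.

    Parameters
    ----------
    n_tf
        TF copy number (conserved; no TF production or degradation).
    k_on, k_off
        TF binding rate per free TF per free promoter and unbinding rate per
        TF-promoter complex, s^-1.
    r
        Transcription rate per transcribing promoter, s^-1.
    gamma
        mRNA decay rate per molecule, s^-1 (must be > 0).
    mode
        Regulatory role of the TF.
    n_promoters, n_competitors
        Copy numbers of identical target promoters and of competitor sites.
    k_on_c, k_off_c
        TF binding/unbinding rates at competitor sites; default to the
        promoter rates when left unspecified.
    r_basal
        Basal transcription rate of an activator-free promoter
        (activator mode only; default 0).
    """

    n_tf: int
    k_on: float
    k_off: float
    r: float
    gamma: float
    mode: RegulationMode
    n_promoters: int = 1
    n_competitors: int = 0
    k_on_c: float | None = None
    k_off_c: float | None = None
    r_basal: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "n_tf", _as_count(self.n_tf, "n_tf"))
        object.__setattr__(self, "n_promoters", _as_count(self.n_promoters, "n_promoters"))
        object.__setattr__(self, "n_competitors", _as_count(self.n_competitors, "n_competitors"))
        if self.n_promoters < 1:
            raise ValidationError("n_promoters must be >= 1")
        try:
            object.__setattr__(self, "mode", RegulationMode(self.mode))
        except ValueError:
            raise ValidationError(
                f"mode must be 'activator' or 'repressor', got {self.mode!r}"
            ) from None
        for name in ("k_on", "k_off", "r", "gamma", "r_basal"):
            object.__setattr__(self, name, _as_rate(getattr(self, name), name))
        # competitor rates inherit the promoter rates unless overridden
        kc = self.k_on if self.k_on_c is None else _as_rate(self.k_on_c, "k_on_c")
        kcu = self.k_off if self.k_off_c is None else _as_rate(self.k_off_c, "k_off_c")
        object.__setattr__(self, "k_on_c", kc)
        object.__setattr__(self, "k_off_c", kcu)
        if self.gamma <= 0:
            raise ValidationError(f"gamma must be > 0, got {self.gamma}")
        if self.r <= 0:
            raise ValidationError(f"r must be > 0, got {self.r}")
        if self.r_basal > 0 and self.mode is not RegulationMode.ACTIVATOR:
            raise ValidationError("r_basal > 0 is only meaningful in activator mode")

    # -- derived quantities -------------------------------------------------

    @property
    def max_promoter_occupancy(self) -> int:
        return min(self.n_promoters, self.n_tf)

    def max_competitor_occupancy(self, n_bound_promoters: int = 0) -> int:
        return min(self.n_competitors, self.n_tf - n_bound_promoters)

    def saturated_mean(self) -> float:
        """Maximum mean expression N_P * r / gamma."""
        return self.n_promoters * self.r / self.gamma

    def replace(self, **changes) -> "ModelSpec":
        data = self.to_dict()
        data.update(changes)
        return validate_model(data)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "n_tf": self.n_tf,
            "n_promoters": self.n_promoters,
            "n_competitors": self.n_competitors,
            "k_on": self.k_on,
            "k_off": self.k_off,
            "k_on_c": self.k_on_c,
            "k_off_c": self.k_off_c,
            "r": self.r,
            "r_basal": self.r_basal,
            "gamma": self.gamma,
            "mode": self.mode.value,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_json(cls, text: str) -> "ModelSpec":
        return validate_model(json.loads(text))


_SPEC_FIELDS = {f.name for f in fields(ModelSpec)}
_REQUIRED_FIELDS = ("n_tf", "k_on", "k_off", "r", "gamma", "mode")


def validate_model(raw: Mapping) -> ModelSpec:
    """Build a :class:`ModelSpec` from a flat mapping, rejecting unknown keys.

    Missing competitor rates default to the promoter rates; every invariant
    violation raises :class:`ValidationError` naming the offending field.
    """
    if isinstance(raw, ModelSpec):
        return raw
    unknown = set(raw) - _SPEC_FIELDS
    if unknown:
        raise ValidationError(f"unknown parameter(s): {sorted(unknown)}")
    missing = [k for k in _REQUIRED_FIELDS if k not in raw]
    if missing:
        raise ValidationError(f"missing required parameter(s): {missing}")
    return ModelSpec(**dict(raw))


@dataclass
class SystemState:
    """Instantaneous microstate of one cell.

    Occupancy and mRNA are tracked per promoter copy: ``occupancy[i]`` is 1
    when promoter *i* is TF-bound and ``mrna_per_promoter[i]`` counts the
    transcripts it produced that have not yet decayed.  Aggregates ``n``,
    ``c`` and ``m`` are derived views.
    """

    occupancy: np.ndarray
    bound_competitors: int
    mrna_per_promoter: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.occupancy = np.asarray(self.occupancy, dtype=np.int8)
        self.mrna_per_promoter = np.asarray(self.mrna_per_promoter, dtype=np.int64)
        self.bound_competitors = int(self.bound_competitors)

    @classmethod
    def initial(cls, spec: ModelSpec) -> "SystemState":
        """All promoters and competitor sites free, no mRNA, t = 0."""
        np_ = spec.n_promoters
        return cls(np.zeros(np_, dtype=np.int8), 0, np.zeros(np_, dtype=np.int64), 0.0)

    @property
    def n(self) -> int:
        return int(self.occupancy.sum())

    @property
    def c(self) -> int:
        return self.bound_competitors

    @property
    def m(self) -> int:
        return int(self.mrna_per_promoter.sum())

    def check(self, spec: ModelSpec) -> None:
        """Raise :class:`InconsistentStateError` if any invariant fails."""
        if self.occupancy.shape != (spec.n_promoters,):
            raise InconsistentStateError(
                f"occupancy has shape {self.occupancy.shape}, expected ({spec.n_promoters},)"
            )
        if self.mrna_per_promoter.shape != (spec.n_promoters,):
            raise InconsistentStateError("mrna_per_promoter length != n_promoters")
        if not np.isin(self.occupancy, (0, 1)).all():
            raise InconsistentStateError("occupancy entries must be 0 or 1")
        if (self.mrna_per_promoter < 0).any():
            raise InconsistentStateError("negative mRNA count")
        if not 0 <= self.c <= spec.n_competitors:
            raise InconsistentStateError(
                f"bound_competitors={self.c} outside [0, {spec.n_competitors}]"
            )
        if self.n + self.c > spec.n_tf:
            raise InconsistentStateError(
                f"TF conservation violated: n={self.n} + c={self.c} > n_tf={spec.n_tf}"
            )


def free_tf_count(state: SystemState, spec: ModelSpec) -> int:
    """Number of unbound TFs, ``n_tf - n - c`` (>= 0 by conservation)."""
    state.check(spec)
    return spec.n_tf - state.n - state.c


class ReactionKind(str, enum.Enum):
    BIND_PROMOTER = "bind_promoter"
    UNBIND_PROMOTER = "unbind_promoter"
    BIND_COMPETITOR = "bind_competitor"
    UNBIND_COMPETITOR = "unbind_competitor"
    TRANSCRIBE = "transcribe"
    DEGRADE = "degrade"


@dataclass(frozen=True)
class ReactionChannel:
    """One elementary stochastic transition and its current propensity.

    ``index`` identifies the promoter copy for per-promoter channels and is
    ``None`` for the competitor channels.
    """

    kind: ReactionKind
    index: int | None
    propensity: float

    def __post_init__(self) -> None:
        if self.propensity < 0:
            raise ValueError("propensity must be >= 0")


def transcription_rates(occupancy: np.ndarray, spec: ModelSpec) -> np.ndarray:
    """Per-promoter transcription propensities given the occupancy pattern."""
    s = np.asarray(occupancy, dtype=float)
    if spec.mode is RegulationMode.ACTIVATOR:
        return spec.r * s + spec.r_basal * (1.0 - s)
    return spec.r * (1.0 - s)


def propensity_vector(state: SystemState, spec: ModelSpec) -> list[ReactionChannel]:
    """All reaction channels of the model in a fixed deterministic order.

    Zero-propensity channels are included (with propensity 0) so the layout
    depends only on ``n_promoters``, never on the state.  The per-promoter
    binding propensities sum to ``k_on * F * (N_P - n)`` with
    ``F = n_tf - n - c`` free TFs, so the aggregate rates of the
    master-equation generator are recovered exactly.
    """
    free = free_tf_count(state, spec)  # also validates the state
    s = state.occupancy
    channels: list[ReactionChannel] = []
    for i in range(spec.n_promoters):
        channels.append(
            ReactionChannel(ReactionKind.BIND_PROMOTER, i, spec.k_on * free * (1 - int(s[i])))
        )
    for i in range(spec.n_promoters):
        channels.append(ReactionChannel(ReactionKind.UNBIND_PROMOTER, i, spec.k_off * int(s[i])))
    channels.append(
        ReactionChannel(
            ReactionKind.BIND_COMPETITOR,
            None,
            spec.k_on_c * free * (spec.n_competitors - state.c),
        )
    )
    channels.append(
        ReactionChannel(ReactionKind.UNBIND_COMPETITOR, None, spec.k_off_c * state.c)
    )
    tx = transcription_rates(s, spec)
    for i in range(spec.n_promoters):
        channels.append(ReactionChannel(ReactionKind.TRANSCRIBE, i, float(tx[i])))
    for i in range(spec.n_promoters):
        channels.append(
            ReactionChannel(ReactionKind.DEGRADE, i, spec.gamma * int(state.mrna_per_promoter[i]))
        )
    return channels
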