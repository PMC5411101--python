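"""Closed-form noise results and distribution summaries.

For a single promoter without competitor sites the stationary mean and
variance of the mRNA count are known exactly (the model reduces to the
telegraph/ON-OFF promoter):

    activator:  <m> = (r/g) k_on N_TF / (k_on N_TF + k_off)
                Fano = 1 + k_off r / ((k_on N_TF + k_off)(g + k_on N_TF + k_off))
    repressor:  <m> = (r/g) k_off / (k_on N_TF + k_off)
                Fano = 1 + k_on N_TF r / ((k_on N_TF + k_off)(g + k_on N_TF + k_off))

Eliminating the effective binding rate k_on N_TF between mean and variance
yields the master curve var(<m>) that depends only on (r, gamma, k_off) —
the relation that single-promoter competition scenarios collapse onto.

For multiple promoter copies the moment hierarchy does not close (the
binding propensity is quadratic in the complex number); a second-order
moment-closure approximation is provided that neglects third-order joint
cumulants of the promoter occupancy indicators and reduces exactly to the
closed form above at N_P = 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import root
from scipy.signal import find_peaks

from .model import ModelSpec, RegulationMode, validate_model

__all__ = [
    "Moments",
    "ModeReport",
    "analytic_moments_single",
    "master_curve_variance",
    "fold_change",
    "fano",
    "moment_closure_moments",
    "count_modes",
    "promoter_correlation",
]


@dataclass(frozen=True)
class Moments:
    """First two moments of a steady-state mRNA distribution."""

    mean: float
    variance: float
    fano: float
    fold_change: float


def fano(mean: float, variance: float) -> float:
    """Fano factor variance/mean; NaN when the mean vanishes."""
    if variance < 0:
        raise ValueError("variance must be >= 0")
    if mean == 0:
        return float("nan")
    return variance / mean


def fold_change(mean: float, spec) -> float:
    """Mean expression relative to its saturated value N_P * r / gamma."""
    spec = validate_model(spec)
    if mean < 0:
        raise ValueError("mean must be >= 0")
    return mean / spec.saturated_mean()


def analytic_moments_single(spec) -> Moments:
    """Exact telegraph-model moments; valid only for N_P=1, N_C=0, r_basal=0."""
    spec = validate_model(spec)
    if spec.n_promoters != 1 or spec.n_competitors != 0 or spec.r_basal != 0:
        raise ValueError(
            "closed-form moments hold only for a single promoter without "
            "competitor sites and zero basal rate"
        )
    keff = spec.k_on * spec.n_tf
    ksum = keff + spec.k_off
    burst = spec.r / spec.gamma
    if spec.mode is RegulationMode.ACTIVATOR:
        mean = burst * keff / ksum
        f = 1.0 + spec.k_off * spec.r / (ksum * (spec.gamma + ksum))
    else:
        mean = burst * spec.k_off / ksum
        f = 1.0 + keff * spec.r / (ksum * (spec.gamma + ksum))
    var = mean * f
    return Moments(mean=mean, variance=var, fano=fano(mean, var), fold_change=fold_change(mean, spec))


def master_curve_variance(rates, mode, mean: float) -> float:
    """Variance predicted by the single-promoter master curve at a given mean.

    ``rates`` is a mapping with keys ``r``, ``gamma``, ``k_off``.  The curve
    is independent of k_on, N_TF and the competitor sites by construction:

        activator: var = m + m ((r/g) - m)^2 g / (g ((r/g) - m) + (r/g) k_off)
        repressor: var = m + m^2 ((r/g) - m) g / (g m + (r/g) k_off)
    """
    r, gamma, k_off = float(rates["r"]), float(rates["gamma"]), float(rates["k_off"])
    mode = RegulationMode(mode)
    cap = r / gamma
    if not 0.0 <= mean <= cap * (1.0 + 1e-12):
        raise ValueError(f"mean must lie in [0, r/gamma = {cap:g}], got {mean}")
    mean = min(mean, cap)
    gap = cap - mean
    if mode is RegulationMode.ACTIVATOR:
        denom = gamma * gap + cap * k_off
        extra = mean * gap * gap * gamma / denom if denom > 0 else 0.0
    else:
        denom = gamma * mean + cap * k_off
        extra = mean * mean * gap * gamma / denom if denom > 0 else 0.0
    return mean + extra


def _closure_equations(v, spec: ModelSpec, alpha: float, beta: float):
    """Steady-state residuals of the second-order indicator-moment system.

    Unknowns: p = <s_i>, q = <s_i s_j> (i != j), mu = <m>, w = <s_i m>,
    M2 = <m^2>.  Third-order joint cumulants of (s_i, s_j, s_k) and
    (s_i, s_j, m) are set to zero.
    """
    p, q, mu, w, M2 = v
    kon, koff, gamma = spec.k_on, spec.k_off, spec.gamma
    A, NP = spec.n_tf, spec.n_promoters
    t3 = 3.0 * p * q - 2.0 * p**3
    u = 2.0 * p * w + q * mu - 2.0 * p * p * mu
    eq_p = kon * (A * (1 - p) - NP * p + p + (NP - 1) * q) - koff * p
    eq_q = 2.0 * kon * (A * (p - q) - p + (3 - NP) * q + (NP - 2) * t3) - 2.0 * koff * q
    eq_mu = NP * (alpha + beta * p) - gamma * mu
    eq_w = (
        kon * (A * (mu - w) - NP * w + w + (NP - 1) * u)
        - koff * w
        + NP * alpha * p
        + beta * (p + (NP - 1) * q)
        - gamma * w
    )
    eq_M2 = 2.0 * NP * (alpha * mu + beta * w) + NP * (alpha + beta * p) - 2.0 * gamma * M2 + gamma * mu
    return [eq_p, eq_q, eq_mu, eq_w, eq_M2]


def moment_closure_moments(spec) -> Moments:
    """Approximate mean and variance from second-order moment closure.

    Scope: no competitor sites.  Exact for N_P = 1 (two-state occupancy);
    for N_P > 1 a systematic deviation from the neglected higher-order
    cumulants is expected, typically within ~10% near TF/promoter parity.
    """
    spec = validate_model(spec)
    if spec.n_competitors != 0:
        raise ValueError("moment closure is implemented for n_competitors == 0")
    if spec.mode is RegulationMode.ACTIVATOR:
        alpha, beta = spec.r_basal, spec.r - spec.r_basal
    else:
        alpha, beta = spec.r, -spec.r
    keff = spec.k_on * spec.n_tf
    p0 = keff / (keff + spec.k_off) if keff + spec.k_off > 0 else 0.0
    mu0 = spec.n_promoters * (alpha + beta * p0) / spec.gamma
    guess = [p0, p0 * p0, mu0, p0 * mu0, mu0 * mu0 + mu0]
    sol = root(_closure_equations, guess, args=(spec, alpha, beta), method="hybr", tol=1e-12)
    if not sol.success:
        raise RuntimeError(f"moment closure failed to converge: {sol.message}")
    p, q, mu, w, M2 = sol.x
    var = M2 - mu * mu
    mu = max(mu, 0.0)
    var = max(var, 0.0)
    return Moments(mean=mu, variance=var, fano=fano(mu, var), fold_change=fold_change(mu, spec))


@dataclass(frozen=True)
class ModeReport:
    """Modes (local maxima) of an integer-support mRNA pmf."""

    n_modes: int
    mode_locations: tuple[int, ...]
    mode_heights: tuple[float, ...]
    smoothing_window: int
    prominence_threshold: float

    def to_dict(self) -> dict:
        return {
            "n_modes": self.n_modes,
            "mode_locations": list(self.mode_locations),
            "mode_heights": list(self.mode_heights),
            "smoothing_window": self.smoothing_window,
            "prominence_threshold": self.prominence_threshold,
        }


def count_modes(pmf, smoothing_window: int = 5, prominence: float = 0.05) -> ModeReport:
    """Count the modes of an mRNA pmf after moving-average smoothing.

    The pmf on integer support is smoothed with a centered moving average
    (edge windows renormalized so boundary modes are not damped), then local
    maxima with prominence >= ``prominence`` times the smoothed maximum are
    reported.  Plateaus are merged to a single mode at their leftmost index;
    boundary maxima (e.g. a pile-up at m = 0) count as modes.
    """
    p = np.asarray(pmf, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("pmf must be a non-empty 1-D array")
    if (p < 0).any():
        raise ValueError("pmf entries must be >= 0")
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError(f"pmf must be normalized (sum = {p.sum():.6g})")
    if smoothing_window < 1:
        raise ValueError("smoothing_window must be >= 1")
    w = int(smoothing_window)
    kernel = np.ones(w)
    smooth = np.convolve(p, kernel, mode="same") / np.convolve(np.ones_like(p), kernel, mode="same")
    # pad below the minimum so boundary maxima are detectable as peaks
    pad = smooth.min() - 1.0
    padded = np.concatenate(([pad], smooth, [pad]))
    threshold = prominence * smooth.max()
    peaks, props = find_peaks(padded, prominence=max(threshold, 0.0) or None, plateau_size=1)
    locations = [int(e) - 1 for e in props["left_edges"]]  # leftmost index of plateaus
    heights = [float(smooth[i]) for i in locations]
    order = np.argsort(locations)
    locations = [locations[i] for i in order]
    heights = [heights[i] for i in order]
    return ModeReport(
        n_modes=len(locations),
        mode_locations=tuple(locations),
        mode_heights=tuple(heights),
        smoothing_window=w,
        prominence_threshold=float(prominence),
    )


def promoter_correlation(sample) -> float:
    """Pearson correlation of the two promoters' mRNA counts in a population.

    ``sample`` is a :class:`tfshare.ssa.PopulationSample` from a
    two-promoter model.  Returns NaN when either coordinate has zero
    variance (correlation undefined).
    """
    if sample.spec.n_promoters != 2:
        raise ValueError("promoter correlation requires n_promoters == 2")
    if sample.n_cells < 2:
        raise ValueError("need at least two replicates")
    m1 = sample.mrna[:, 0].astype(float)
    m2 = sample.mrna[:, 1].astype(float)
    v1, v2 = m1.var(), m2.var()
    if v1 == 0 or v2 == 0:
        return float("nan")
    return float(np.corrcoef(m1, m2)[0, 1])
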