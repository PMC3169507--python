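"""Degree-distribution analysis: cumulative tails, family fits, and the
generating-function prediction for projected degree distributions.

The empirical claim being probed is that complexome networks have
*exponential* degree distributions p(k) ~ exp(-k/k0) — whose cumulative
P(k) = Σ_{k'≥k} p(k') is again exponential — rather than the power-law
form familiar from binary protein-interaction networks. Fits are least
squares on log-cumulative values, the simplest criterion matching the
straight-line test on semi-log (exponential) or log-log (power law)
axes.

For an uncorrelated bipartite graph, the degree distribution of the
one-mode projection follows from composing generating functions: if
G_p(x) generates the protein membership-count distribution and E(x) the
*excess* size distribution of a complex reached along a random edge
(size-biased, minus the arriving protein), the projected protein degree
is generated by G_p(E(x)).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class FitResult:
    family: str  # "exponential" or "power_law"
    parameter: float  # scale k0 (exponential) or exponent (power law)
    goodness: float  # SSR on log-transformed cumulative values
    intercept: float
    ks: np.ndarray
    fitted: np.ndarray  # fitted cumulative values at ks

    @property
    def scale(self) -> float:
        if self.family != "exponential":
            raise AttributeError("scale is defined for exponential fits only")
        return self.parameter

    @property
    def exponent(self) -> float:
        if self.family != "power_law":
            raise AttributeError("exponent is defined for power-law fits only")
        return self.parameter


def cumulative(data) -> dict[int, float]:
    """Cumulative distribution P(k) = Σ_{k'≥k} p(k') on observed support.

    ``data`` is either a sequence of observed degrees or a mapping
    k → p(k). P is non-increasing and P at the minimum observed degree
    is 1.
    """
    if isinstance(data, dict):
        ks = sorted(data)
        p = np.array([data[k] for k in ks], dtype=float)
        total = p.sum()
        if total <= 0:
            raise ValueError("pmf has zero total mass")
        p = p / total
    else:
        values = np.asarray(list(data))
        if values.size == 0:
            raise ValueError("empty degree sequence")
        ks, counts = np.unique(values, return_counts=True)
        ks = [int(k) for k in ks]
        p = counts / counts.sum()
    tail = np.cumsum(p[::-1])[::-1]
    return {int(k): float(t) for k, t in zip(ks, tail)}


def fit_family(
    cum: dict[int, float], family: str, tail_cut: int | None = None
) -> FitResult:
    """Least-squares fit of log P(k) against k (exponential) or log k
    (power law).

    ``tail_cut`` drops points with k above it — the finite-size "tail"
    of an empirical distribution. Requires ≥ 3 distinct usable degrees.
    """
    if family not in ("exponential", "power_law"):
        raise ValueError(f"unknown family {family!r}")
    pts = [(k, P) for k, P in sorted(cum.items()) if P > 0]
    if tail_cut is not None:
        pts = [(k, P) for k, P in pts if k <= tail_cut]
    if family == "power_law":
        pts = [(k, P) for k, P in pts if k > 0]
    if len(pts) < 3:
        raise ValueError(f"need >= 3 distinct degree values, got {len(pts)}")
    ks = np.array([k for k, _ in pts], dtype=float)
    logP = np.log(np.array([P for _, P in pts]))
    x = ks if family == "exponential" else np.log(ks)
    slope, intercept = np.polyfit(x, logP, 1)
    resid = logP - (slope * x + intercept)
    goodness = float(np.sum(resid**2))
    if family == "exponential":
        parameter = -1.0 / slope if slope < 0 else np.inf
        fitted = np.exp(intercept + slope * ks)
    else:
        parameter = -slope
        fitted = np.exp(intercept) * ks**slope
    return FitResult(
        family=family,
        parameter=float(parameter),
        goodness=goodness,
        intercept=float(intercept),
        ks=ks,
        fitted=fitted,
    )


def compare_families(
    cum: dict[int, float], tail_cut: int | None = None
) -> tuple[str, FitResult, FitResult]:
    """Fit both families; return (winner, exponential fit, power-law fit).

    The winner is the family with the lower sum of squared residuals on
    log-cumulative values.
    """
    exp_fit = fit_family(cum, "exponential", tail_cut)
    pow_fit = fit_family(cum, "power_law", tail_cut)
    winner = "exponential" if exp_fit.goodness <= pow_fit.goodness else "power_law"
    return winner, exp_fit, pow_fit


def tail_cut_for(cum: dict[int, float], fraction: float = 0.01) -> int:
    """Degree cutoff excluding the largest ``fraction`` of the support."""
    ks = sorted(cum)
    n_drop = int(np.ceil(len(ks) * fraction))
    return ks[max(0, len(ks) - 1 - n_drop)]


def normalize_pmf(p, tol: float = 1e-9) -> np.ndarray:
    """Validate and renormalize a pmf vector indexed by degree 0..k_max."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValueError("pmf has negative entries")
    total = p.sum()
    if total <= 0:
        raise ValueError("pmf has zero total mass")
    if abs(total - 1.0) > tol:
        p = p / total
    else:
        p = p / total  # exact normalization either way
    return p


def project_pmf_via_generating_functions(
    p_protein, p_complex, k_max: int = 512
) -> np.ndarray:
    """Projected protein-network degree pmf for an uncorrelated bipartite
    graph.

    ``p_protein[d]`` is the probability a protein belongs to d complexes;
    ``p_complex[s]`` the probability a complex has s member proteins. A
    protein of membership d reaches, through each of its d complexes, an
    independent excess-size draw s−1 from the size-biased complex
    distribution; its projected degree is the sum. In series form the
    result is G_p(E(x)) with E(x) = G_q'(x)/G_q'(1), evaluated by
    polynomial convolution truncated at ``k_max`` and renormalized.

    Emits a warning with a mass report if the truncation loses more than
    1e-6 of probability mass.
    """
    p = normalize_pmf(p_protein)
    q = normalize_pmf(p_complex)
    s = np.arange(len(q), dtype=float)
    mean_size = float((s * q).sum())
    if mean_size <= 0:
        raise ValueError("complex size pmf has zero mean")
    # excess pmf over s-1: e[s-1] ∝ s * q[s]
    excess = (s * q)[1:] / mean_size  # index t = s-1, t >= 0
    out = np.zeros(k_max + 1)
    power = np.zeros(k_max + 1)
    power[0] = 1.0  # e^{*0} = delta at 0
    lost = 0.0
    for d, pd in enumerate(p):
        if d > 0:
            full = np.convolve(power, excess)
            power = full[: k_max + 1]
        if pd > 0:
            out += pd * power
    total = out.sum()
    lost = 1.0 - total
    if lost > 1e-6:
        warnings.warn(
            f"k_max={k_max} truncation lost {lost:.3e} of probability mass",
            stacklevel=2,
        )
    return out / total
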