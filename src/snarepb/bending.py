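"""Helfrich-theory estimate of electrostatically induced membrane bending.

A vesicle of resting radius R that locally bends its lower hemisphere to a
smaller radius r pays the harmonic (mean-curvature) elastic penalty

    dF(r) = 4 pi kappa R^2 (1/r - 1/R)^2

i.e. the lower-hemisphere area 2 pi R^2 times the energy-density increase
2 kappa (1/r - 1/R)^2, with the bending rigidity kappa in kT.  By the
Gauss-Bonnet theorem the Gaussian-curvature term is a topological constant
for an intact vesicle and never enters any computed number; ``kappa_bar`` is
carried for bookkeeping only.

Bending is electrostatically sustainable down to the smallest local radius
r* at which the penalty is still offset by the reduction in protein/membrane
repulsion read off an interaction-energy "standard curve" over radius:

    dF(r) <= N * (dG_v(R) - dG_v(r))

where N is the number of complexes acting in synergy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._constants import DEFAULT_TEMPERATURE, kT_kJ_per_mol
from .energetics import EnergyCurve, curve_interpolator
from .errors import ConfigurationError, InterpolationError


@dataclass
class BendingModel:
    """Helfrich parameters: kappa and kappa_bar in kT, spontaneous curvature
    c0 in 1/Å, resting vesicle radius R in Å.  Only the lower hemisphere is
    assumed to bend (screening limits the repulsion's reach to ~1 nm)."""

    kappa: float = 20.0          # kT; typical fluid bilayer rigidity
    kappa_bar: float = 0.0       # kT; bookkeeping only (Gauss-Bonnet)
    c0: float = 0.0              # 1/Å; resting radius stands in for 1/c0
    R: float = 200.0             # Å (40 nm vesicle diameter)
    region: str = "lower_hemisphere"
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self):
        if self.kappa <= 0 or self.R <= 0:
            raise ConfigurationError("kappa and R must be positive")
        if self.region != "lower_hemisphere":
            raise ConfigurationError("only the lower-hemisphere region is supported")


@dataclass
class BendingEstimate:
    """Result of solve_bending: minimal admissible local radius r_star (Å),
    the penalty/compensation balance there, and the diameter reduction."""

    r_star: float
    N: int
    penalty_at_r: float          # kJ/mol
    compensation_at_r: float     # kJ/mol
    diameter_reduction: float    # 1 - r_star/R
    kappa: float                 # kT, echoed so reports carry the rigidity used
    no_bending: bool = False


def bending_penalty(model: BendingModel, r: float) -> float:
    """Elastic penalty dF(r) in kJ/mol for bending the lower hemisphere from
    the resting radius R to local radius r."""
    if r <= 0:
        raise ConfigurationError("local radius must be positive")
    dF_kt = 4.0 * np.pi * model.kappa * model.R**2 * (1.0 / r - 1.0 / model.R) ** 2
    return float(dF_kt * kT_kJ_per_mol(model.temperature))


def compensation_delta(curve: EnergyCurve, R1: float, R2: float) -> float:
    """dG_v(R1) - dG_v(R2) from the interpolated standard curve (exact at
    curve knots)."""
    f = curve_interpolator(curve, "dG_v")
    try:
        return float(f(R1) - f(R2))
    except InterpolationError as exc:
        raise InterpolationError(f"radius outside curve range: {exc}") from exc


def solve_bending(curve: EnergyCurve, model: BendingModel, N: int,
                  tol: float = 0.1) -> BendingEstimate:
    """Smallest local radius r* in the curve's range with
    dF(r*) <= N * (dG_v(R) - dG_v(r*)), located by coarse scan plus
    bisection to ``tol`` Å.

    Returns r* = R with ``no_bending`` set when no admissible radius below R
    exists (or N = 0).
    """
    if N < 0:
        raise ConfigurationError("N must be >= 0")
    R = model.R
    f = curve_interpolator(curve, "dG_v")
    finite = curve.x[np.isfinite(curve.x)]
    r_min = float(finite.min())
    if not (r_min <= R <= (np.inf if np.isinf(curve.x).any() else finite.max())):
        raise InterpolationError("model.R outside the curve's radius range")
    dG_R = float(f(R))

    def slack(r):
        # negative or zero when bending to r is admissible
        return bending_penalty(model, r) - N * (dG_R - float(f(r)))

    if N == 0:
        return BendingEstimate(R, N, 0.0, 0.0, 0.0, model.kappa, True)

    rs = np.linspace(r_min, R, max(32, int((R - r_min) / 1.0) + 1))
    vals = np.array([slack(r) for r in rs])
    admissible = np.where(vals <= 1e-9)[0]
    # drop the trivial r = R root (slack(R) = 0 by construction)
    admissible = admissible[rs[admissible] < R - 1e-9]
    if admissible.size == 0:
        return BendingEstimate(R, N, 0.0, 0.0, 0.0, model.kappa, True)
    i = admissible[0]
    lo = rs[i]
    if i == 0:
        r_star = lo
    else:
        hi = rs[i]
        lo = rs[i - 1]  # slack(lo) > 0, slack(hi) <= 0
        while hi - lo > tol:
            mid = 0.5 * (lo + hi)
            if slack(mid) <= 1e-9:
                hi = mid
            else:
                lo = mid
        r_star = hi
    pen = bending_penalty(model, r_star)
    comp = N * (dG_R - float(f(r_star)))
    return BendingEstimate(float(r_star), N, pen, comp,
                           1.0 - r_star / R, model.kappa, False)
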