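"""Noncompartmental pharmacokinetic fitting for serum enzyme-activity profiles.

IV profiles of the PEGylated enzyme decline mono-exponentially, so the fit
is ordinary least squares of ln(concentration) on time over all
positive-concentration samples:

    lambda_z = -slope        t_half = ln 2 / lambda_z
    c0 = exp(intercept)      Vd = dose / c0        CL = lambda_z * Vd

Subcutaneous profiles are absorption-confounded early on; only the terminal
log-linear tail (post-peak points) is regressed and only the half-life is
reported.  A biphasic profile — the failure mode of hyper-PEGylated
comparators — trips a lack-of-fit warning via an r² threshold.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["PKProfile", "PKFit", "fit_iv_monophasic", "fit_sc_terminal"]


@dataclass
class PKProfile:
    times: np.ndarray        # hours post dose
    conc: np.ndarray         # active-enzyme serum concentration (e.g. µg/mL)
    dose: float              # per kg, same mass unit as conc * volume (e.g. mg/kg with µg/mL)
    route: str               # "IV" or "SC"
    subject_id: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.conc = np.asarray(self.conc, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.conc < 0):
            raise ValueError("concentrations must be non-negative")
        if self.dose <= 0:
            raise ValueError("dose must be positive")
        if self.route not in ("IV", "SC"):
            raise ValueError(f"route must be IV or SC, got {self.route!r}")


@dataclass
class PKFit:
    lambda_z: float          # 1/hr
    half_life: float         # hr
    r_squared: float
    n_points_used: int
    c0: float | None = None  # back-extrapolated, IV only
    vd: float | None = None  # L/kg, IV only
    cl: float | None = None  # L/hr/kg, IV only


def _loglinear(times: np.ndarray, conc: np.ndarray) -> tuple[float, float, float]:
    """OLS of ln(conc) on time -> (slope, intercept, r_squared)."""
    y = np.log(conc)
    slope, intercept = np.polyfit(times, y, 1)
    fitted = slope * times + intercept
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return float(slope), float(intercept), r2


def fit_iv_monophasic(
    profile: PKProfile,
    conc_per_dose_unit: float = 1000.0,
    r2_warn: float = 0.95,
) -> PKFit:
    """Mono-exponential fit of an IV profile over all positive samples.

    ``conc_per_dose_unit`` converts the dose mass unit into the
    concentration mass unit (default 1000 for mg/kg dose with µg/mL
    concentrations), so Vd comes out in L/kg.  Profiles whose log-linear r²
    falls below ``r2_warn`` — e.g. an atypical fast initial elimination
    phase — raise a lack-of-fit warning.
    """
    if profile.route != "IV":
        raise ValueError("fit_iv_monophasic requires an IV profile")
    mask = profile.conc > 0
    if mask.sum() < 3:
        raise ValueError("need at least 3 positive-concentration samples")
    t, c = profile.times[mask], profile.conc[mask]
    slope, intercept, r2 = _loglinear(t, c)
    if slope >= 0:
        raise ValueError("no elimination phase: concentrations do not decline")
    if r2 < r2_warn:
        warnings.warn(
            f"log-linear r²={r2:.3f} < {r2_warn}: profile may not be monophasic", stacklevel=2
        )
    lambda_z = -slope
    c0 = math.exp(intercept)
    vd = profile.dose * conc_per_dose_unit / c0 / 1000.0  # µg/kg over µg/mL -> mL/kg -> L/kg
    cl = lambda_z * vd
    return PKFit(
        lambda_z=lambda_z,
        half_life=math.log(2) / lambda_z,
        r_squared=r2,
        n_points_used=int(mask.sum()),
        c0=c0,
        vd=vd,
        cl=cl,
    )


def fit_sc_terminal(profile: PKProfile, terminal_points: int = 3) -> PKFit:
    """Terminal half-life of an SC (absorption-then-elimination) profile.

    Locates the observed peak, regresses ln(conc) on the last
    ``terminal_points`` post-peak positive samples, and reports the
    half-life only — volume and clearance are absorption-confounded for an
    extravascular dose and are deliberately omitted.
    """
    if profile.route != "SC":
        raise ValueError("fit_sc_terminal requires an SC profile")
    if terminal_points < 3:
        raise ValueError("terminal_points must be >= 3")
    i_peak = int(np.argmax(profile.conc))
    post = np.arange(len(profile.times)) > i_peak
    post &= profile.conc > 0
    if post.sum() < terminal_points:
        raise ValueError(
            f"no usable terminal phase: {int(post.sum())} post-peak points, need {terminal_points}"
        )
    idx = np.where(post)[0][-terminal_points:]
    t, c = profile.times[idx], profile.conc[idx]
    slope, _, r2 = _loglinear(t, c)
    if slope >= 0:
        raise ValueError("no post-peak decline: terminal slope is non-negative")
    lambda_z = -slope
    return PKFit(
        lambda_z=lambda_z,
        half_life=math.log(2) / lambda_z,
        r_squared=r2,
        n_points_used=len(idx),
    )
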