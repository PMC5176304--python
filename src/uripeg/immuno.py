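"""Stimulation-index statistics for PBMC T-cell proliferation assays.

Each donor's plate carries replicate wells (typically n = 8) of proliferating
CD3+CD4+ T-cell counts per condition.  Per donor, condition means are
estimated by an ordinary-least-squares linear model with condition as the
only factor — which reduces in closed form to the group means with a pooled
residual variance — and the stimulation index (SI) is the contrast

    SI = mean(treated) / mean(reference)

with a delta-method standard error, a two-sided t-test of H0: SI = 1, and a
95% confidence interval.  A donor is called a responder when SI >= 2 AND
p < 0.05; the SI gate is a pre-set assay convention, the p-value a
supporting statistical screen.  No multiple-testing correction is applied
across donors: responder calling is a per-donor decision by design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "DonorWellCounts",
    "SIResult",
    "donor_si",
    "call_responder",
    "population_summary",
]

CONDITIONS = ("blank", "buffer", "test", "positive")


@dataclass
class DonorWellCounts:
    donor_id: str
    condition: str
    counts: np.ndarray  # proliferating cells per well, one entry per replicate

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}, got {self.condition!r}")
        self.counts = np.asarray(self.counts)
        if self.counts.size < 2:
            raise ValueError("need at least 2 replicates per condition")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")


@dataclass
class SIResult:
    donor_id: str
    si: float
    ci95: tuple[float, float]
    p_value: float
    responder: bool
    se: float = float("nan")


def donor_si(
    treated: DonorWellCounts,
    reference: DonorWellCounts,
    si_threshold: float = 2.0,
    alpha: float = 0.05,
) -> SIResult:
    """Stimulation index of one donor with delta-method inference.

    OLS with a two-level condition factor gives group means m_t, m_r and a
    pooled residual variance s² on (n_t + n_r - 2) degrees of freedom; the
    ratio R = m_t / m_r then has delta-method variance

        Var(R) ≈ R² (s²/n_t/m_t² + s²/n_r/m_r²)

    and H0: R = 1 is tested two-sided against a t distribution on the
    pooled df.  Degenerate zero-variance plates collapse to exact answers
    (p = 1 for identical means, p = 0 otherwise).
    """
    if treated.donor_id != reference.donor_id:
        raise ValueError("treated and reference wells must come from the same donor")
    xt = treated.counts.astype(float)
    xr = reference.counts.astype(float)
    mt, mr = xt.mean(), xr.mean()
    if mr <= 0:
        raise ValueError(f"reference mean is {mr}; stimulation index undefined")
    nt, nr = xt.size, xr.size
    df = nt + nr - 2
    pooled_var = (np.sum((xt - mt) ** 2) + np.sum((xr - mr) ** 2)) / df

    ratio = mt / mr
    var_ratio = ratio**2 * (pooled_var / nt / mt**2 + pooled_var / nr / mr**2) if mt > 0 else (
        pooled_var / nr / mr**2
    )
    se = float(np.sqrt(var_ratio))

    if se == 0.0:
        p = 1.0 if ratio == 1.0 else 0.0
        ci = (ratio, ratio)
    else:
        tstat = (ratio - 1.0) / se
        p = float(2.0 * stats.t.sf(abs(tstat), df))
        tcrit = float(stats.t.ppf(0.975, df))
        ci = (ratio - tcrit * se, ratio + tcrit * se)

    result = SIResult(donor_id=treated.donor_id, si=float(ratio), ci95=ci, p_value=p, responder=False, se=se)
    result.responder = call_responder(result, si_threshold=si_threshold, alpha=alpha)
    return result


def call_responder(result: SIResult, si_threshold: float = 2.0, alpha: float = 0.05) -> bool:
    """Responder rule: SI >= threshold AND p < alpha."""
    return bool(result.si >= si_threshold and result.p_value < alpha)


def population_summary(results: list[SIResult]) -> dict:
    """Responder count / fraction and arithmetic-mean SI over a donor panel."""
    if not results:
        raise ValueError("no donor results to summarize")
    n = len(results)
    responders = sum(1 for r in results if r.responder)
    return {
        "n_donors": n,
        "n_responders": responders,
        "responder_fraction": responders / n,
        "mean_si": float(np.mean([r.si for r in results])),
    }
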