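"""Chou-Talalay median-effect fitting and combination-index (CI) evaluation.

The median-effect model relates dose D to fraction affected fa through

    fa / fu = (D / Dm)^m,     fu = 1 - fa,

so log10(fa/fu) is linear in log10(D) with slope m (the sigmoidicity) and
the median dose Dm = 10^(-intercept/m) gives 50% effect (IC50 for an
inhibitor).  Inverting gives the dose for any effect level,

    Dx = Dm * (fa / (1 - fa))^(1/m),

and for a combination observed at doses (D_A, D_B) reaching fraction
affected fa, the combination index is

    CI = D_A / (D_A)_x + D_B / (D_B)_x,

where (D_A)_x and (D_B)_x are the single-agent doses producing the same fa.
CI < 1 is synergy, CI = 1 additivity (Loewe), CI > 1 antagonism.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import FormatError

logger = logging.getLogger("synergyscreen")

#: fraction-affected observations are clipped into [FA_EPS, 1 - FA_EPS]
#: before the log transform (log(fa/fu) is undefined at 0 and 1).
FA_EPS = 0.005

#: |CI - 1| below this counts as additive.
ADDITIVE_TOL = 1e-9

VERDICTS = ("synergistic", "additive", "antagonistic")


@dataclass
class DoseResponse:
    """Single-agent dose-response observations (dose in umol/L, fa in [0,1])."""

    agent_id: str
    doses: np.ndarray
    fa: np.ndarray

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.fa = np.asarray(self.fa, dtype=float)
        if self.doses.shape != self.fa.shape:
            raise ValueError("doses and fa must have equal length")
        if (self.doses < 0).any():
            raise ValueError("doses must be non-negative")
        if ((self.fa < 0) | (self.fa > 1)).any():
            raise ValueError("fa must lie in [0, 1]")


@dataclass
class MedianEffectFit:
    """Fitted median-effect parameters for one agent."""

    agent_id: str
    m: float        # slope of the median-effect plot
    dm: float       # median dose, umol/L
    r2: float       # squared correlation of the linear fit
    n_points: int
    n_clipped: int = 0
    degenerate: bool = False  # non-positive slope or all points clipped

    def __post_init__(self) -> None:
        if self.dm <= 0:
            raise ValueError("dm must be positive")


@dataclass
class CIResult:
    """Combination index for one combination observation (one dose pair)."""

    agent_a: str
    agent_b: str
    dose_a: float
    dose_b: float
    fa_combo: float
    ci: float
    verdict: str

    def __post_init__(self) -> None:
        if self.verdict not in VERDICTS:
            raise ValueError(f"unknown verdict {self.verdict!r}")


def fit_median_effect(dr: DoseResponse) -> MedianEffectFit:
    """Least-squares median-effect fit on the log-log plot.

    Zero-dose rows are excluded; replicate wells at one dose are averaged
    before fitting; fa values outside (FA_EPS, 1-FA_EPS) are clipped and
    logged.  Requires >= 3 distinct usable doses.  A non-positive slope is
    returned flagged, not raised.
    """
    mask = dr.doses > 0
    doses, fa = dr.doses[mask], dr.fa[mask]
    if len(doses) == 0:
        raise ValueError(f"{dr.agent_id}: no non-zero doses")
    frame = pd.DataFrame({"dose": doses, "fa": fa}).groupby("dose", as_index=False).mean()
    doses = frame["dose"].to_numpy()
    fa = frame["fa"].to_numpy()
    n_clipped = int(((fa < FA_EPS) | (fa > 1 - FA_EPS)).sum())
    if n_clipped:
        logger.info("fit_median_effect[%s]: clipped %d fa value(s) to [%g, %g]",
                    dr.agent_id, n_clipped, FA_EPS, 1 - FA_EPS)
    fa = np.clip(fa, FA_EPS, 1 - FA_EPS)
    if len(doses) < 3:
        raise ValueError(f"{dr.agent_id}: need >= 3 distinct non-zero doses, "
                         f"have {len(doses)}")
    x = np.log10(doses)
    y = np.log10(fa / (1.0 - fa))
    fit = stats.linregress(x, y)
    m = float(fit.slope)
    degenerate = m <= 0 or n_clipped == len(doses)
    if degenerate:
        logger.warning("fit_median_effect[%s]: degenerate fit (m=%.4g, "
                       "%d/%d clipped)", dr.agent_id, m, n_clipped, len(doses))
        m_safe = m if m > 0 else np.finfo(float).tiny
        dm = float(10 ** (-fit.intercept / m_safe)) if m > 0 else float("inf")
        dm = dm if np.isfinite(dm) and dm > 0 else 1.0
    else:
        dm = float(10 ** (-fit.intercept / m))
    return MedianEffectFit(agent_id=dr.agent_id, m=m, dm=dm,
                           r2=float(fit.rvalue ** 2), n_points=len(doses),
                           n_clipped=n_clipped, degenerate=degenerate)


def dose_for_effect(fit: MedianEffectFit, fa: float) -> float:
    """Dx = Dm * (fa/(1-fa))^(1/m), the dose producing fraction affected fa."""
    if not 0.0 < fa < 1.0:
        raise ValueError("fa must lie strictly inside (0, 1)")
    if fit.degenerate:
        raise ValueError(f"{fit.agent_id}: degenerate fit cannot be inverted")
    return fit.dm * (fa / (1.0 - fa)) ** (1.0 / fit.m)


def ic50_of(fit: MedianEffectFit) -> float:
    """IC50 equals the median dose Dm under the median-effect model."""
    if fit.degenerate:
        raise ValueError(f"{fit.agent_id}: degenerate fit has no IC50")
    return fit.dm


def ic50_label(fit: MedianEffectFit, max_dose: float | None = None) -> str:
    """IC50 for reports: '> max_dose' when Dm exceeds the tested range."""
    dm = ic50_of(fit)
    if max_dose is not None and dm > max_dose:
        return f"> {max_dose:g}"
    return f"{dm:.4g}"


def classify_ci(ci: float, tol: float = ADDITIVE_TOL) -> str:
    if abs(ci - 1.0) <= tol:
        return "additive"
    return "synergistic" if ci < 1.0 else "antagonistic"


def combination_index(fit_a: MedianEffectFit, fit_b: MedianEffectFit,
                      d_a: float, d_b: float, fa_combo: float) -> CIResult:
    """CI = d_a/(D_A)_x + d_b/(D_B)_x at the observed combination effect."""
    if not 0.0 < fa_combo < 1.0:
        raise ValueError("fa_combo must lie strictly inside (0, 1)")
    if d_a < 0 or d_b < 0:
        raise ValueError("doses must be non-negative")
    dax = dose_for_effect(fit_a, fa_combo)
    dbx = dose_for_effect(fit_b, fa_combo)
    ci = d_a / dax + d_b / dbx
    return CIResult(agent_a=fit_a.agent_id, agent_b=fit_b.agent_id,
                    dose_a=d_a, dose_b=d_b, fa_combo=fa_combo,
                    ci=ci, verdict=classify_ci(ci))


# ---------------------------------------------------------------------------
# table-level drivers (the `synergy` stage)
# ---------------------------------------------------------------------------

def fit_all_agents(single_agent: pd.DataFrame) -> dict[str, MedianEffectFit]:
    """Median-effect fits per agent from a long-format dose-response table."""
    fits: dict[str, MedianEffectFit] = {}
    for agent, grp in single_agent.groupby("agent_id", sort=True):
        fits[agent] = fit_median_effect(DoseResponse(
            agent_id=str(agent), doses=grp["dose"].to_numpy(),
            fa=grp["fa"].to_numpy()))
    return fits


def ci_table(fits: dict[str, MedianEffectFit], combos: pd.DataFrame) -> pd.DataFrame:
    """Per-row CI for a combination table (agent_a, agent_b, dose_a, dose_b, fa).

    Adds the per-pair minimum CI as ``pair_min_ci`` on every row of a pair.
    """
    rows = []
    for row in combos.itertuples(index=False):
        if row.agent_a not in fits or row.agent_b not in fits:
            raise FormatError(f"no single-agent fit for pair "
                              f"({row.agent_a}, {row.agent_b})")
        res = combination_index(fits[row.agent_a], fits[row.agent_b],
                                float(row.dose_a), float(row.dose_b), float(row.fa))
        rows.append({"agent_a": res.agent_a, "agent_b": res.agent_b,
                     "dose_a": res.dose_a, "dose_b": res.dose_b,
                     "fa": res.fa_combo, "ci": res.ci, "verdict": res.verdict})
    out = pd.DataFrame(rows)
    if len(out):
        out["pair_min_ci"] = out.groupby(["agent_a", "agent_b"])["ci"].transform("min")
    return out


def fits_table(fits: dict[str, MedianEffectFit],
               max_dose: float | None = None) -> pd.DataFrame:
    rows = []
    for agent, fit in fits.items():
        rows.append({"agent": agent, "m": fit.m, "dm": fit.dm, "r2": fit.r2,
                     "ic50": ic50_label(fit, max_dose) if not fit.degenerate
                     else "degenerate"})
    return pd.DataFrame(rows)
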