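"""Trial-averaged evoked-response characterisation.

Profiles the trial-averaged dF/F aligned to US onset: peak time within
5 s, amplitude relative to the pre-peak minimum, full width at half
maximum (total, possibly non-contiguous, time above half-amplitude), and
trapezoidal area under the curve over the 5 s post-onset window.  Also
computes the population response latency (first 2-SD excursion above the
10 s baseline) and compares profile metrics across PRF and cell type with
a two-factor GLM tested against an intercept-only model by deviance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy.stats import chi2, f as f_dist

__all__ = [
    "ResponseProfile",
    "response_profile",
    "population_latency",
    "GLMComparison",
    "glm_compare",
]

RESPONSE_WINDOW_S = 5.0


@dataclass(frozen=True)
class ResponseProfile:
    """Evoked-response metrics of one neuron (or one neuron x PRF).

    ``valid`` is false when the post-onset maximum falls after the 5 s
    window, in which case the neuron is excluded from profile statistics.
    """

    peak_time_s: float
    amplitude: float
    fwhm_s: float
    auc: float
    valid: bool
    neuron: int = -1
    prf: float = np.nan


def _time_above(y: np.ndarray, thr: float, dt: float) -> float:
    """Lebesgue measure of {t : y(t) > thr} for the piecewise-linear trace."""
    total = 0.0
    above = y > thr
    for k in range(y.size - 1):
        y0, y1 = y[k], y[k + 1]
        if above[k] and above[k + 1]:
            total += dt
        elif above[k] != above[k + 1] and y1 != y0:
            frac = abs((y0 - thr) / (y1 - y0)) if above[k] else abs((thr - y0) / (y1 - y0))
            total += dt * (frac if above[k] else 1.0 - frac)
    return total


def response_profile(
    mean_dff: np.ndarray,
    fs: float = 20.0,
    neuron: int = -1,
    prf: float = np.nan,
) -> ResponseProfile:
    """Profile a trial-averaged trace whose first sample is US onset.

    The trace must cover at least the 5 s post-onset window; any samples
    beyond it are used only to decide whether the true post-onset maximum
    lies outside the window (which invalidates the profile).
    """
    y = np.asarray(mean_dff, dtype=float).ravel()
    if np.all(np.isnan(y)):
        raise ValueError("all-NaN response window")
    n_win = int(round(RESPONSE_WINDOW_S * fs))
    if y.size < n_win + 1:
        raise ValueError("trace must cover 5 s after onset")
    peak_global = 1 + int(np.nanargmax(y[1:]))
    if peak_global > n_win:
        return ResponseProfile(
            peak_time_s=peak_global / fs, amplitude=np.nan, fwhm_s=np.nan,
            auc=np.nan, valid=False, neuron=neuron, prf=prf,
        )
    pk = peak_global
    pre_min = float(np.nanmin(y[: pk + 1]))
    amplitude = float(y[pk]) - pre_min
    thr = pre_min + 0.5 * amplitude
    win = y[: n_win + 1]
    fwhm = _time_above(win, thr, 1.0 / fs) if amplitude > 0 else 0.0
    auc = float(np.trapezoid(win, dx=1.0 / fs))
    return ResponseProfile(
        peak_time_s=pk / fs, amplitude=amplitude, fwhm_s=fwhm, auc=auc,
        valid=True, neuron=neuron, prf=prf,
    )


def population_latency(
    mean_dff: np.ndarray, fs: float = 20.0, pre_s: float = 10.0
) -> float | None:
    """Population response latency in seconds.

    ``mean_dff`` is the population-average trace starting ``pre_s`` before
    US onset.  Returns the first post-onset time at which the trace exceeds
    the baseline mean by two baseline SDs, or ``None`` if never crossed.
    """
    y = np.asarray(mean_dff, dtype=float).ravel()
    nb = int(round(pre_s * fs))
    if y.size <= nb:
        raise ValueError("trace must extend past the baseline window")
    base = y[:nb]
    sd = float(np.std(base))
    if sd == 0:
        raise ValueError("zero baseline SD")
    thr = float(np.mean(base)) + 2.0 * sd
    post = y[nb:]
    above = np.nonzero(post > thr)[0]
    return float(above[0] / fs) if above.size else None


@dataclass
class GLMComparison:
    """Deviance test of ``Y ~ PRF * cell type`` against intercept-only."""

    deviance_full: float
    deviance_null: float
    df_model: int
    p_deviance: float
    significant: bool
    coefficients: pd.DataFrame
    coefficients_reported: bool  # convention: analysed only when the
    #                              omnibus deviance test is significant


def glm_compare(
    profiles: pd.DataFrame,
    value: str,
    prf: str = "prf",
    cell_type: str = "cell_type",
    family: str = "gaussian",
    alpha: float = 0.05,
) -> GLMComparison:
    """Fit ``value ~ 1 + PRF + cell_type + PRF x cell_type`` and compare to
    the intercept-only model with a deviance test.

    Gaussian/identity by default; for the Gaussian family the deviance test
    is the exact F-test on the deviance difference.  Per-coefficient tests
    are reported only when the omnibus deviance test is significant.
    """
    df = profiles.dropna(subset=[value, prf, cell_type])
    for col in (prf, cell_type):
        if df[col].nunique() < 2:
            raise ValueError(f"factor {col!r} needs at least two levels")
    fam = {"gaussian": sm.families.Gaussian()}.get(family)
    if fam is None:
        raise ValueError(f"unsupported family {family!r}")
    formula = f"{value} ~ C({prf}) * C({cell_type})"
    full = smf.glm(formula, data=df, family=fam)
    if np.linalg.matrix_rank(full.exog) < full.exog.shape[1]:
        raise ValueError(
            "rank-deficient design: some PRF x cell-type cells are empty "
            f"(counts: {df.groupby([prf, cell_type]).size().to_dict()})"
        )
    full_res = full.fit()
    null_res = smf.glm(f"{value} ~ 1", data=df, family=fam).fit()
    df_model = int(full_res.df_model)
    d1, d0 = full_res.deviance, null_res.deviance
    if family == "gaussian":
        fstat = ((d0 - d1) / df_model) / (d1 / full_res.df_resid)
        p = float(f_dist.sf(fstat, df_model, full_res.df_resid))
    else:
        p = float(chi2.sf(d0 - d1, df_model))
    sig = p < alpha
    coefs = pd.DataFrame({
        "coef": full_res.params,
        "se": full_res.bse,
        "p": full_res.pvalues,
    })
    return GLMComparison(
        deviance_full=float(d1), deviance_null=float(d0), df_model=df_model,
        p_deviance=p, significant=sig, coefficients=coefs,
        coefficients_reported=sig,
    )
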