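"""Model-fit criteria for the two-level CFA: chi-square test, CFI, RMSEA,
level-specific SRMRs, per-item ICC(1), and cut-off decisions.

Conventions (each the mainstream multilevel-SEM default, stated explicitly
because the indices depend on them):

- the chi-square is the deviance difference against the numerically/closed-
  form fitted saturated model on the same moments, on 18 df for six items;
- the CFI baseline is the independence (diagonal) model at *both* levels
  with free means;
- the RMSEA sample size is the total number of observation rows ``n * t``
  (switchable to the cluster count);
- SRMR-b standardizes residuals of the unbiased between estimator
  ``(S_B - S_PW) / c``, not of ``S_B`` itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datagen import ILDDataset
from .twolevel_cfa import (FitResult, TwoLevelMoments, compute_moments,
                           model_df)

__all__ = [
    "FitIndices",
    "CutoffReport",
    "MomentsMismatchError",
    "DegenerateDataError",
    "chi_square_test",
    "compute_cfi",
    "compute_rmsea",
    "between_sample_cov",
    "compute_srmr",
    "icc1",
    "evaluate_cutoffs",
    "fit_indices",
    "CFI_CUTOFFS",
    "RMSEA_CUTOFFS",
    "SRMR_CUTOFFS",
]

CFI_CUTOFFS = (0.99, 0.95, 0.90)
RMSEA_CUTOFFS = (0.06, 0.08, 0.10)
SRMR_CUTOFFS = (0.08, 0.11)
ALPHA = 0.05


class MomentsMismatchError(ValueError):
    """Fit results being compared were not computed on the same moments."""


class DegenerateDataError(ValueError):
    """Data carry no variance where the statistic requires some."""


@dataclass(frozen=True)
class FitIndices:
    chi2: float
    df: int
    p_value: float
    cfi: float
    rmsea: float
    srmr_w: float
    srmr_b: float

    def to_dict(self) -> dict:
        return {
            "chi2": self.chi2, "df": self.df, "p_value": self.p_value,
            "cfi": self.cfi, "rmsea": self.rmsea,
            "srmr_w": self.srmr_w, "srmr_b": self.srmr_b,
        }


@dataclass(frozen=True)
class CutoffReport:
    """Boolean pass/fail decisions at the printed cut-offs.

    ``chi2_significant`` is True when p < 0.05 (misfit flagged); the index
    fields are True when the index *passes* (good fit): CFI >= cut-off,
    RMSEA < cut-off, SRMR < cut-off, strict comparisons exactly as printed.
    """

    chi2_significant: bool
    cfi: dict  # cutoff -> passed
    rmsea: dict
    srmr_w: dict
    srmr_b: dict

    def to_dict(self) -> dict:
        d = {"chi2_p<0.05": self.chi2_significant}
        d.update({f"cfi>={k}": v for k, v in self.cfi.items()})
        d.update({f"rmsea<{k}": v for k, v in self.rmsea.items()})
        d.update({f"srmr_w<{k}": v for k, v in self.srmr_w.items()})
        d.update({f"srmr_b<{k}": v for k, v in self.srmr_b.items()})
        return d


def _same_moments(a: TwoLevelMoments, b: TwoLevelMoments) -> bool:
    return (a is b) or (
        a.G == b.G and a.c == b.c
        and np.array_equal(a.ybar, b.ybar)
        and np.array_equal(a.s_pw, b.s_pw)
        and np.array_equal(a.s_b, b.s_b))


def chi_square_test(fit_h0: FitResult, fit_sat: FitResult):
    """Deviance-difference chi-square of the hypothesized model.

    Returns ``(chi2, df, p)``; the statistic is clamped at zero.
    """
    if not _same_moments(fit_h0.moments, fit_sat.moments):
        raise MomentsMismatchError("fits were computed on different moments")
    chi2 = max(fit_h0.minus2ll - fit_sat.minus2ll, 0.0)
    df = model_df(fit_h0.model) - model_df(fit_sat.model)
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    return chi2, df, p


def compute_cfi(chi2: float, df: int, chi2_base: float, df_base: int) -> float:
    """Comparative fit index against an independence baseline."""
    num = max(chi2 - df, 0.0)
    den = max(chi2_base - df_base, chi2 - df, 0.0)
    if den == 0.0:
        return 1.0
    return float(np.clip(1.0 - num / den, 0.0, 1.0))


def compute_rmsea(chi2: float, df: int, N: int) -> float:
    """Root mean square error of approximation, ``N`` = observation rows."""
    if df <= 0:
        raise ValueError("RMSEA requires df > 0")
    if N <= 1:
        raise ValueError("RMSEA requires N > 1")
    return float(np.sqrt(max(chi2 - df, 0.0) / (df * N)))


def between_sample_cov(m: TwoLevelMoments) -> np.ndarray:
    """Unbiased between-level covariance estimate ``(S_B - S_PW) / c``.

    May be indefinite or have negative diagonal entries in small samples;
    returned as-is (SRMR only standardizes and differences).
    """
    if m.c < 2:
        raise ValueError("between estimator requires cluster size >= 2")
    return (m.s_b - m.s_pw) / m.c


def compute_srmr(sample: np.ndarray, implied: np.ndarray) -> float:
    """Standardized root mean square residual over unique elements.

    Negative sample variances (possible for the between estimator) enter the
    standardizer by absolute value; a zero sample variance is an error.
    """
    sample = np.asarray(sample, float)
    implied = np.asarray(implied, float)
    if sample.shape != implied.shape:
        raise ValueError("sample/implied dimension mismatch")
    d = np.abs(np.diag(sample))
    if np.any(d == 0.0):
        raise DegenerateDataError("zero sample variance in SRMR standardizer")
    denom = np.sqrt(np.outer(d, d))
    resid = (sample - implied) / denom
    iu = np.triu_indices(sample.shape[0])
    return float(np.sqrt(np.mean(resid[iu] ** 2)))


def icc1(data) -> np.ndarray:
    """One-way ANOVA ICC(1) per item: ``(MSB - MSW) / (MSB + (c-1) MSW)``.

    Accepts an :class:`ILDDataset` or precomputed :class:`TwoLevelMoments`.
    Negative estimates are reported unclamped.
    """
    m = data if isinstance(data, TwoLevelMoments) else compute_moments(data)
    msb = np.diag(m.s_b)  # c * var of cluster means, divisor G - 1
    msw = np.diag(m.s_pw)
    denom = msb + (m.c - 1) * msw
    if np.any(denom == 0.0):
        raise DegenerateDataError("item with zero total variance")
    return (msb - msw) / denom


def evaluate_cutoffs(fi: FitIndices) -> CutoffReport:
    """Apply the printed cut-offs with strict comparisons."""
    return CutoffReport(
        chi2_significant=fi.p_value < ALPHA,
        cfi={c: fi.cfi >= c for c in CFI_CUTOFFS},
        rmsea={c: fi.rmsea < c for c in RMSEA_CUTOFFS},
        srmr_w={c: fi.srmr_w < c for c in SRMR_CUTOFFS},
        srmr_b={c: fi.srmr_b < c for c in SRMR_CUTOFFS},
    )


def fit_indices(fit_h0: FitResult, fit_sat: FitResult, fit_base: FitResult,
                rmsea_n: str = "n_rows") -> FitIndices:
    """All five fit criteria from the three fitted models.

    ``rmsea_n`` selects the RMSEA sample-size convention: total observation
    rows (``"n_rows"``, default) or cluster count (``"n_clusters"``).
    """
    chi2, df, p = chi_square_test(fit_h0, fit_sat)
    chi2_b, df_b, _ = chi_square_test(fit_base, fit_sat)
    cfi = compute_cfi(chi2, df, chi2_b, df_b)
    m = fit_h0.moments
    n_eff = m.N if rmsea_n == "n_rows" else m.G
    rmsea = compute_rmsea(chi2, df, n_eff)
    srmr_w = compute_srmr(m.s_pw, fit_h0.sigma_w)
    srmr_b = compute_srmr(between_sample_cov(m), fit_h0.sigma_b)
    return FitIndices(chi2, df, p, cfi, rmsea, srmr_w, srmr_b)
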