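"""Evaluation metrics: standardized genetic gain, genomic relationships,
inbreeding and replicate-level significance tests.

Gain is expressed in baseline genetic standard deviations: the cohort
entering the first genomic-selection cycle is the yardstick, and later
cycles report (mean TBV - baseline mean) / baseline SD per trait.
Inbreeding is tracked through the genomic relationship matrix (GRM,
VanRaden method 1) computed against the *frozen* baseline allele
frequencies: F = mean(diag(G)) - 1, and the per-cycle rate
dF = (F_c - F_{c-1}) / (1 - F_{c-1}).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .basepop import ConfigError

__all__ = [
    "BaselineFreqs",
    "delta_sigma_g",
    "grm_vanraden",
    "inbreeding_F",
    "delta_F",
    "compare_scenarios",
    "TTestResult",
]


@dataclass(frozen=True)
class BaselineFreqs:
    """Frozen counted-allele frequencies of the baseline cohort."""

    freqs: np.ndarray

    def __post_init__(self) -> None:
        f = self.freqs
        if np.any((f < 0) | (f > 1)):
            raise ConfigError("frequencies must lie in [0, 1]")


def delta_sigma_g(tbv_ci: np.ndarray, tbv_c5: np.ndarray) -> float:
    """Standardized gain: (mean(ci) - mean(c5)) / sd(c5)."""
    tbv_ci = np.asarray(tbv_ci, dtype=float)
    tbv_c5 = np.asarray(tbv_c5, dtype=float)
    sd = tbv_c5.std(ddof=1)
    if sd == 0.0:
        raise ConfigError("baseline TBV standard deviation is zero")
    return float((tbv_ci.mean() - tbv_c5.mean()) / sd)


def grm_vanraden(dosages: np.ndarray, base: BaselineFreqs) -> np.ndarray:
    """VanRaden method-1 GRM: G = W W' / (2 sum p (1 - p)).

    ``dosages`` (n x m) count the same allele as the baseline
    frequencies; columns are centered by 2p with p frozen at baseline.
    SNPs monomorphic at baseline contribute zero to W and are retained.
    """
    Z = np.asarray(dosages, dtype=float)
    p = np.asarray(base.freqs, dtype=float)
    if Z.ndim != 2 or Z.shape[1] != p.shape[0]:
        raise ConfigError("dosage columns do not match baseline frequencies")
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom == 0.0:
        raise ConfigError("all SNPs monomorphic at baseline")
    W = Z - 2.0 * p
    return (W @ W.T) / denom


def inbreeding_F(G: np.ndarray) -> float:
    """Mean population inbreeding: average GRM diagonal minus one."""
    G = np.asarray(G, dtype=float)
    if G.ndim != 2 or G.shape[0] != G.shape[1]:
        raise ConfigError("G must be square")
    return float(np.mean(np.diag(G)) - 1.0)


def delta_F(f_c: float, f_prev: float) -> float:
    """Rate of inbreeding between neighbouring cycles."""
    if f_prev >= 1.0:
        raise ConfigError("previous-cycle F must be < 1")
    return (f_c - f_prev) / (1.0 - f_prev)


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    pvalue: float
    significant: bool
    degenerate: bool = False


def compare_scenarios(values_a, values_b, alpha: float = 0.01,
                      welch: bool = False) -> TTestResult:
    """Two-sample Student's t-test between replicate-level values.

    Pooled-variance (classic Student) by default; Welch available by
    flag.  Significance is declared at p < ``alpha`` (study convention
    0.01).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ConfigError("need at least two replicates per arm")
    if np.var(a, ddof=1) == 0.0 and np.var(b, ddof=1) == 0.0:
        same = float(a.mean() == b.mean())
        return TTestResult(statistic=0.0 if same else np.inf,
                           pvalue=1.0 if same else 0.0,
                           significant=not same, degenerate=True)
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return TTestResult(statistic=float(res.statistic),
                       pvalue=float(res.pvalue),
                       significant=bool(res.pvalue < alpha))
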