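"""Genomic prediction: masked SNP panel, pooled plot genotypes, Bayesian
ridge regression and GEBV accuracy.

The prediction machinery mirrors practice in forage-grass genomic
selection: causal loci are masked (the SNP panel excludes every QTL),
reference observations are *plot pools* (per-SNP dosage = 2 x allele
frequency among 20 plants sampled from the plot), and per-trait SNP
effects come from Bayesian ridge regression (BRR) -- a Gaussian prior
with one common effect variance and scaled-inverse-chi-square
hyperpriors on both variances.  A closed-form ridge path with the
variance ratio fixed gives the same posterior mean and is the default
for reduced-scale runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .basepop import ConfigError, Population

__all__ = [
    "SNPPanel",
    "BRRSettings",
    "TraitModel",
    "PredictionModel",
    "ReferencePopulation",
    "build_snp_panel",
    "panel_dosages",
    "pool_plot_genotype",
    "fit_brr",
    "predict_gebv",
    "gebv_accuracy",
]


# ---------------------------------------------------------------------------
# panel
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SNPPanel:
    """Genotyping panel: flat locus indices plus a fixed allele coding.

    The counted allele is the base-population minor allele; the coding
    is persisted with the panel so models trained in different cycles
    stay comparable even when loci later drift to fixation.
    """

    loci: np.ndarray
    count_allele_is_one: np.ndarray  # bool per SNP
    base_freqs: np.ndarray           # counted-allele frequency at creation

    @property
    def size(self) -> int:
        return self.loci.size


def build_snp_panel(base_pop: Population, qtl, size: int,
                    rng: np.random.Generator,
                    maf_min: float = 0.05) -> SNPPanel:
    """Random SNP draw with base MAF > ``maf_min``, excluding all QTL."""
    freqs = base_pop.allele_freqs()
    maf = np.minimum(freqs, 1 - freqs)
    eligible = np.flatnonzero(maf > maf_min)
    if qtl is not None:
        eligible = np.setdiff1d(eligible, qtl.all_loci(),
                                assume_unique=False)
    if eligible.size < size:
        raise ConfigError(f"only {eligible.size} eligible loci for a "
                          f"panel of {size}")
    loci = np.sort(rng.choice(eligible, size=size, replace=False))
    count_one = freqs[loci] <= 0.5
    base = np.where(count_one, freqs[loci], 1 - freqs[loci])
    return SNPPanel(loci=loci, count_allele_is_one=count_one,
                    base_freqs=base)


def panel_dosages(pop: Population, panel: SNPPanel) -> np.ndarray:
    """Integer dosages (0/1/2) of the counted allele, shape (n, m)."""
    d = pop.dosages(panel.loci)
    return np.where(panel.count_allele_is_one, d, 2 - d).astype(np.int8)


def pool_plot_genotype(plot_pop: Population, panel: SNPPanel,
                       rng: np.random.Generator,
                       n_sample: int = 20) -> np.ndarray:
    """Pooled plot dosage row: 2 x counted-allele frequency in a sample.

    Twenty random plants per plot are genotyped; with fewer plants than
    that, the whole plot is pooled (flagged with a warning).
    """
    n = plot_pop.n_individuals
    if n < n_sample:
        warnings.warn(f"plot has only {n} plants; pooling all of them")
        rows = np.arange(n)
    else:
        rows = rng.choice(n, size=n_sample, replace=False)
    d = panel_dosages(plot_pop.subset(rows), panel)
    return d.mean(axis=0)  # mean dosage == 2 * allele frequency


# ---------------------------------------------------------------------------
# reference population
# ---------------------------------------------------------------------------

class ReferencePopulation:
    """Growing training set of pooled plot genotypes and phenotypes."""

    def __init__(self, n_markers: int, trait_names: tuple[str, ...]):
        self.n_markers = n_markers
        self.trait_names = trait_names
        self._Z: list[np.ndarray] = []
        self._y: list[np.ndarray] = []
        self._prov: list[tuple] = []

    def add_plot(self, z_row: np.ndarray, phenos: np.ndarray,
                 cycle: int, stage: str) -> None:
        if z_row.shape != (self.n_markers,):
            raise ConfigError("pooled genotype row does not match the panel")
        self._Z.append(np.asarray(z_row, dtype=np.float32))
        self._y.append(np.asarray(phenos, dtype=float))
        self._prov.append((cycle, stage))

    @property
    def n_rows(self) -> int:
        return len(self._Z)

    def Z(self) -> np.ndarray:
        return np.vstack(self._Z)

    def y(self, trait: str) -> np.ndarray:
        j = self.trait_names.index(trait)
        return np.array([row[j] for row in self._y])

    def provenance(self) -> pd.DataFrame:
        return pd.DataFrame(self._prov, columns=["cycle", "stage"])


# ---------------------------------------------------------------------------
# Bayesian ridge regression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BRRSettings:
    """Sampler / solver settings.

    ``method='gibbs'`` runs the full sampler (study settings: 50,000
    iterations, 10,000 burn-in); ``method='ridge'`` solves the
    equivalent ridge system with the variance ratio fixed at its prior
    value -- the fast path for reduced-scale runs and the oracle used
    in tests.
    """

    method: str = "gibbs"
    iterations: int = 50_000
    burn_in: int = 10_000
    df_beta: float = 5.0
    df_e: float = 5.0
    h2_prior: float = 0.5
    fix_variances: bool = False


@dataclass
class TraitModel:
    intercept: float
    beta: np.ndarray
    var_beta: float
    var_e: float
    degenerate: bool = False


@dataclass
class PredictionModel:
    """Per-trait SNP-effect estimates sharing one panel."""

    panel: SNPPanel
    traits: dict[str, TraitModel] = field(default_factory=dict)

    def beta_matrix(self, trait_names) -> np.ndarray:
        return np.column_stack([self.traits[t].beta for t in trait_names])

    def dump(self, pop: Population) -> pd.DataFrame:
        """Delimited-text-ready effect table (one row per SNP)."""
        L = pop.loci_per_chromosome
        c_idx, l_idx = np.divmod(self.panel.loci, L)
        cm = pop.positions_cm()
        out = pd.DataFrame({"snp": [f"L{g}" for g in self.panel.loci],
                            "chromosome": c_idx + 1,
                            "position_cM": cm[l_idx]})
        for t, m in self.traits.items():
            out[f"beta_{t}"] = m.beta
        return out


def _prior_variances(Z: np.ndarray, y: np.ndarray,
                     h2_prior: float) -> tuple[float, float]:
    var_y = float(np.var(y, ddof=1)) if y.size > 1 else 0.0
    zc = Z - Z.mean(axis=0)
    sum_zz = float((zc ** 2).sum() / max(len(y), 1))
    var_b = max(var_y * h2_prior, 1e-12) / max(sum_zz, 1e-12)
    var_e = max(var_y * (1.0 - h2_prior), 1e-12)
    return var_b, var_e


def _ridge_solution(Z: np.ndarray, y: np.ndarray,
                    lam: float) -> tuple[float, np.ndarray]:
    """Posterior mean of the fixed-variance model: (Z'Z + lam I)^-1 Z'y
    on centered data; intercept = mean(y)."""
    mu = float(y.mean())
    zbar = Z.mean(axis=0)
    Zc = Z - zbar
    yc = y - mu
    n, m = Zc.shape
    if m <= n:
        beta = np.linalg.solve(Zc.T @ Zc + lam * np.eye(m), Zc.T @ yc)
    else:  # dual form for wide marker matrices
        alpha = np.linalg.solve(Zc @ Zc.T + lam * np.eye(n), yc)
        beta = Zc.T @ alpha
    return mu - float(zbar @ beta), beta


def _gibbs_brr(Z: np.ndarray, y: np.ndarray, settings: BRRSettings,
               rng: np.random.Generator) -> TraitModel:
    n, m = Z.shape
    var_b, var_e = _prior_variances(Z, y, settings.h2_prior)
    S_b = var_b * (settings.df_beta + 2) / settings.df_beta
    S_e = var_e * (settings.df_e + 2) / settings.df_e
    beta = np.zeros(m)
    mu = float(y.mean())
    zz = (Z ** 2).sum(axis=0)
    resid = y - mu
    keep = settings.iterations - settings.burn_in
    sum_beta = np.zeros(m)
    sum_mu = 0.0
    sum_vb = 0.0
    sum_ve = 0.0
    cond_beta = np.zeros(m)  # Rao-Blackwellized accumulator
    for it in range(settings.iterations):
        # intercept
        resid += mu
        cond_mu = resid.mean()
        mu = rng.normal(cond_mu, np.sqrt(var_e / n))
        resid -= mu
        # SNP effects, sequential with residual updates
        lam = var_e / var_b
        for j in range(m):
            bj = beta[j]
            zj = Z[:, j]
            if zz[j] == 0.0:
                beta[j] = rng.normal(0.0, np.sqrt(var_b))
                cond_beta[j] = 0.0
                continue
            resid += zj * bj
            c = zz[j] + lam
            mean_j = (zj @ resid) / c
            bj = rng.normal(mean_j, np.sqrt(var_e / c))
            beta[j] = bj
            cond_beta[j] = mean_j
            resid -= zj * bj
        if not settings.fix_variances:
            df_b = settings.df_beta + m
            var_b = (beta @ beta + settings.df_beta * S_b) \
                / rng.chisquare(df_b)
            df_e = settings.df_e + n
            var_e = (resid @ resid + settings.df_e * S_e) \
                / rng.chisquare(df_e)
        if it >= settings.burn_in:
            # averaging the full-conditional means (Rao-Blackwell) cuts
            # the Monte-Carlo error of the posterior-mean estimate
            sum_beta += cond_beta
            sum_mu += cond_mu
            sum_vb += var_b
            sum_ve += var_e
    return TraitModel(intercept=sum_mu / keep, beta=sum_beta / keep,
                      var_beta=sum_vb / keep, var_e=sum_ve / keep)


def fit_brr(Z: np.ndarray, y: np.ndarray,
            settings: BRRSettings | None = None,
            rng: np.random.Generator | None = None) -> TraitModel:
    """Fit one trait's SNP effects on the reference population.

    Returns posterior-mean estimates.  A constant phenotype vector
    yields an intercept-only model (with a warning).
    """
    Z = np.asarray(Z, dtype=float)
    y = np.asarray(y, dtype=float)
    if Z.ndim != 2 or len(y) != Z.shape[0]:
        raise ConfigError("Z must be (n_rows, n_markers) matching y")
    if len(y) < 2:
        raise ConfigError("need at least two reference rows")
    settings = BRRSettings() if settings is None else settings
    if float(np.var(y)) == 0.0:
        warnings.warn("constant phenotype vector; returning an "
                      "intercept-only model")
        return TraitModel(intercept=float(y[0]),
                          beta=np.zeros(Z.shape[1]), var_beta=0.0,
                          var_e=0.0, degenerate=True)
    if settings.method == "ridge":
        var_b, var_e = _prior_variances(Z, y, settings.h2_prior)
        intercept, beta = _ridge_solution(Z, y, var_e / var_b)
        return TraitModel(intercept=intercept, beta=beta,
                          var_beta=var_b, var_e=var_e)
    if settings.method != "gibbs":
        raise ConfigError(f"unknown BRR method {settings.method!r}")
    rng = np.random.default_rng() if rng is None else rng
    return _gibbs_brr(Z, y, settings, rng)


def predict_gebv(model: TraitModel, Z: np.ndarray) -> np.ndarray:
    """GEBV = Z beta-hat (+ intercept; irrelevant for ranking)."""
    Z = np.asarray(Z, dtype=float)
    if Z.shape[1] != model.beta.shape[0]:
        raise ConfigError("candidate dosage columns do not match the model")
    return Z @ model.beta + model.intercept


def gebv_accuracy(gebv: np.ndarray, tbv: np.ndarray) -> float:
    """Pearson correlation between GEBVs and TBVs (NaN if degenerate)."""
    gebv = np.asarray(gebv, dtype=float)
    tbv = np.asarray(tbv, dtype=float)
    if gebv.shape != tbv.shape or gebv.size < 3:
        raise ConfigError("need equal-length vectors with >= 3 entries")
    if np.std(gebv) == 0.0 or np.std(tbv) == 0.0:
        return float("nan")
    return float(stats.pearsonr(gebv, tbv).statistic)
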