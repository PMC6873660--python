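"""Trait architectures: QTL sampling, correlated mixed-distribution effects,
true breeding values and phenotypes.

Five traits are modelled after a forage-grass improvement program:
heading date (HD, h2 = 0.7), forage yield (FY, 0.3), seed yield
(SY, 0.4), quality (Q, 0.3) and persistency (Per, 0.1).  FY, SY and Per
effects are standard normal; HD and Q mix a few large-effect QTL (drawn
with an inflated variance m) into a polygenic background so the large
class explains a set fraction e of the trait's genetic variance.

Genetic correlations (FY--SY 0.2, FY--HD 0.3) arise from a block of QTL
shared by FY, SY and HD whose effects are correlated across traits.
Because mixture columns do not have identity covariance, the usual
"multiply by the Cholesky factor of C" recipe does not apply directly;
the method here first whitens the raw effect matrix with the inverse
Cholesky factor of its own (second-moment) covariance and then colours
it with the Cholesky factor of the target correlation matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .basepop import ConfigError, Population

__all__ = [
    "TRAIT_ORDER",
    "TraitSpec",
    "CorrelationTargets",
    "QTLSet",
    "TraitState",
    "default_trait_specs",
    "default_correlation_targets",
    "scaled_variance_m",
    "sample_raw_effects",
    "correlate_effects",
    "assign_qtl",
    "true_breeding_value",
    "phenotype",
    "qtl_table",
]

TRAIT_ORDER = ("FY", "HD", "SY", "Q", "Per")


@dataclass(frozen=True)
class TraitSpec:
    """Architecture of one trait.

    ``n_large`` QTL carry effects from N(0, m) with m chosen so they
    explain a fraction ``var_fraction_large`` of the trait's effect
    variance; the remaining effects are N(0, 1).  ``index_weight`` is
    the weight of the trait's standardized GEBV in the SpeedGS
    selection index.
    """

    name: str
    h2: float
    n_qtl: int = 1_000
    n_large: int = 0
    var_fraction_large: float = 0.0
    index_weight: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.h2 <= 1.0):
            raise ConfigError(f"{self.name}: h2 must be in (0, 1]")
        if not (0 <= self.n_large <= self.n_qtl):
            raise ConfigError(f"{self.name}: need 0 <= n_large <= n_qtl")
        if not (0.0 <= self.var_fraction_large < 1.0):
            raise ConfigError(f"{self.name}: var fraction must be in [0, 1)")


def default_trait_specs(n_qtl: int = 1_000) -> tuple[TraitSpec, ...]:
    """The five study traits, large-QTL counts scaled with ``n_qtl``."""
    scale = n_qtl / 1_000
    hd_l = max(1, int(round(20 * scale)))
    q_l = max(1, int(round(100 * scale)))
    return (
        TraitSpec("FY", h2=0.3, n_qtl=n_qtl, index_weight=0.25),
        TraitSpec("HD", h2=0.7, n_qtl=n_qtl, n_large=hd_l,
                  var_fraction_large=0.5, index_weight=0.10),
        TraitSpec("SY", h2=0.4, n_qtl=n_qtl, index_weight=0.15),
        TraitSpec("Q", h2=0.3, n_qtl=n_qtl, n_large=q_l,
                  var_fraction_large=0.5, index_weight=0.15),
        TraitSpec("Per", h2=0.1, n_qtl=n_qtl, index_weight=0.35),
    )


def default_correlation_targets(n_shared: int = 500) -> "CorrelationTargets":
    """Table-of-study targets: FY--SY 0.2, FY--HD 0.3, 500 shared QTL."""
    return CorrelationTargets(n_shared=n_shared)


@dataclass(frozen=True)
class CorrelationTargets:
    """Target genetic correlations and the pleiotropic QTL block size."""

    trait_corr: Mapping[frozenset, float] = field(
        default_factory=lambda: {frozenset(("FY", "SY")): 0.2,
                                 frozenset(("FY", "HD")): 0.3})
    shared_traits: tuple[str, ...] = ("FY", "HD", "SY")
    n_shared: int = 500

    def corr(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self.trait_corr.get(frozenset((a, b)), 0.0)

    def matrix(self, names: Iterable[str]) -> np.ndarray:
        names = list(names)
        return np.array([[self.corr(a, b) for b in names] for a in names])


# ---------------------------------------------------------------------------
# effect simulation
# ---------------------------------------------------------------------------

def scaled_variance_m(e: float, n: int, l: int) -> float:
    """Variance multiplier m for the large-effect QTL class.

    With l large QTL of effect variance m and (n - l) small QTL of unit
    variance, the large class explains l*m / (l*m + n - l) of the
    effect variance; solving for a share of e gives
    m = e (n - l) / (l (1 - e)).
    """
    if l == 0:
        raise ConfigError("m is undefined with no large-effect QTL")
    if not (0 <= e < 1) or not (0 < l < n):
        raise ConfigError("require 0 <= e < 1 and 0 < l < n")
    return e * (n - l) / (l * (1.0 - e))


def sample_raw_effects(specs: Iterable[TraitSpec],
                       rng: np.random.Generator) -> np.ndarray:
    """Raw effect matrix R (n_qtl x p), one mixture column per trait.

    The first ``n_large`` rows of a mixture trait's column hold the
    large-effect draws (callers decide where those land in the genome).
    """
    specs = list(specs)
    n = specs[0].n_qtl
    if any(s.n_qtl != n for s in specs):
        raise ConfigError("all traits must have the same QTL count")
    R = rng.standard_normal((n, len(specs)))
    for j, s in enumerate(specs):
        if s.n_large and s.var_fraction_large > 0:
            m = scaled_variance_m(s.var_fraction_large, s.n_qtl, s.n_large)
            R[:s.n_large, j] = rng.normal(0.0, np.sqrt(m), size=s.n_large)
    return R


def correlate_effects(R: np.ndarray, C: np.ndarray,
                      preserve_scale: bool = True) -> np.ndarray:
    """Impose a target column correlation C on a raw effect matrix R.

    The empirical second-moment covariance of R (about zero -- effects
    are zero-mean by construction) is factored as S = L L'.  Whitening
    RS = R (L')^-1 gives exactly identity covariance even when columns
    come from different mixture distributions; colouring F = RS D' with
    C = D D' then gives F'F/n = C exactly.  The first column is only
    rescaled, never mixed, so a mixture structure placed there survives
    the transform; order columns accordingly.

    With ``preserve_scale`` each output column is scaled back to its
    input root-mean-square so marginal effect-variance structure (and
    any large-effect variance share) is kept.
    """
    R = np.asarray(R, dtype=float)
    C = np.asarray(C, dtype=float)
    n, p = R.shape
    if C.shape != (p, p):
        raise ConfigError("C must be p x p for R with p columns")
    if not np.allclose(C, C.T) or not np.allclose(np.diag(C), 1.0):
        raise ConfigError("C must be symmetric with unit diagonal")
    S = R.T @ R / n
    try:
        L = np.linalg.cholesky(S)
        D = np.linalg.cholesky(C)
    except np.linalg.LinAlgError as err:
        raise ConfigError(
            "covariance of R (or C) is not positive definite; "
            "increase the number of QTL") from err
    dl = np.diag(L)
    if np.any(dl < 1e-6 * dl.max()):
        raise ConfigError("covariance of R is numerically rank-deficient; "
                          "increase the number of QTL")
    RS = R @ np.linalg.inv(L).T          # cov(RS) = I exactly
    F = RS @ D.T                         # cov(F) = C exactly
    if preserve_scale:
        F = F * np.sqrt(np.diag(S))
    return F


# ---------------------------------------------------------------------------
# QTL placement
# ---------------------------------------------------------------------------

@dataclass
class QTLSet:
    """Per-trait QTL positions and effects on a fixed genome map."""

    specs: tuple[TraitSpec, ...]
    loci: dict[str, np.ndarray]
    effects: dict[str, np.ndarray]
    is_large: dict[str, np.ndarray]
    shared_loci: np.ndarray

    @property
    def trait_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.specs)

    def all_loci(self) -> np.ndarray:
        return np.unique(np.concatenate(list(self.loci.values())))

    def spec(self, name: str) -> TraitSpec:
        return next(s for s in self.specs if s.name == name)


def _shared_variance_share(spec: TraitSpec, n_shared: int) -> float:
    """Fraction of a trait's effect variance carried by the shared block.

    Large-effect QTL (variance m) are placed inside the shared block;
    small QTL have unit variance.
    """
    n, l = spec.n_qtl, spec.n_large
    if l:
        m = scaled_variance_m(spec.var_fraction_large, n, l)
        total = (n - l) + l * m
        shared = (n_shared - l) + l * m
    else:
        total, shared = float(n), float(n_shared)
    return shared / total


def assign_qtl(base_pop: Population, specs: Iterable[TraitSpec],
               targets: CorrelationTargets, rng: np.random.Generator,
               maf_min: float = 0.05) -> QTLSet:
    """Sample QTL positions and build correlated effect vectors.

    QTL are drawn from loci with base-population MAF > ``maf_min``.
    One block of ``targets.n_shared`` loci is pleiotropic for FY, HD
    and SY; the remaining QTL of those traits, and all QTL of Q and
    Per, are disjoint draws.  Effects on the shared block are
    correlated across the three traits with a within-block correlation
    inflated by the inverse of each trait's shared-block variance
    share, so the genome-wide genetic correlation hits the target.
    HD's large-effect QTL live inside the shared block and its column
    is ordered first in the Cholesky transform, which preserves the
    large/small mixture exactly.
    """
    specs = tuple(specs)
    by_name = {s.name: s for s in specs}
    n_qtl = specs[0].n_qtl
    n_shared = targets.n_shared
    if n_shared > n_qtl:
        raise ConfigError("shared block larger than per-trait QTL count")
    freqs = base_pop.allele_freqs()
    eligible = np.flatnonzero(np.minimum(freqs, 1 - freqs) > maf_min)
    shared_ts = [t for t in targets.shared_traits if t in by_name]
    solo_ts = [s.name for s in specs if s.name not in shared_ts]
    need = n_shared + len(shared_ts) * (n_qtl - n_shared) \
        + len(solo_ts) * n_qtl
    if eligible.size < need:
        raise ConfigError(
            f"only {eligible.size} loci with MAF > {maf_min}; "
            f"{need} distinct QTL required")
    draw = rng.choice(eligible, size=need, replace=False)
    pos = 0

    def take(k: int) -> np.ndarray:
        nonlocal pos
        out = draw[pos:pos + k]
        pos += k
        return out

    shared = take(n_shared)
    loci: dict[str, np.ndarray] = {}
    effects: dict[str, np.ndarray] = {}
    is_large: dict[str, np.ndarray] = {}
    private = {t: take(n_qtl - n_shared) for t in shared_ts}
    for t in solo_ts:
        loci[t] = take(n_qtl)

    # --- correlated shared block -----------------------------------------
    # order mixture traits first so whitening/colouring never mixes into
    # their columns (upper-triangular transform structure)
    block_order = sorted(shared_ts,
                         key=lambda t: -by_name[t].n_large)
    w = {t: _shared_variance_share(by_name[t], n_shared)
         for t in shared_ts}
    p = len(block_order)
    C_block = np.eye(p)
    for i in range(p):
        for j in range(i + 1, p):
            a, b = block_order[i], block_order[j]
            C_block[i, j] = C_block[j, i] = \
                targets.corr(a, b) / np.sqrt(w[a] * w[b])
    if np.any(np.abs(C_block) > 1.0):
        raise ConfigError("target correlation unreachable for the given "
                          "shared-block variance shares")
    R_block = np.empty((n_shared, p))
    large_in_shared: dict[str, int] = {}
    for j, t in enumerate(block_order):
        s = by_name[t]
        col = rng.standard_normal(n_shared)
        if s.n_large:
            if s.n_large > n_shared:
                raise ConfigError(f"{t}: large-effect QTL exceed the "
                                  "shared block")
            m = scaled_variance_m(s.var_fraction_large, s.n_qtl, s.n_large)
            col[:s.n_large] = rng.normal(0.0, np.sqrt(m), size=s.n_large)
            large_in_shared[t] = s.n_large
        R_block[:, j] = col
    F_block = correlate_effects(R_block, C_block, preserve_scale=True)

    for j, t in enumerate(block_order):
        s = by_name[t]
        priv_eff = rng.standard_normal(n_qtl - n_shared)
        loci[t] = np.concatenate([shared, private[t]])
        effects[t] = np.concatenate([F_block[:, j], priv_eff])
        flags = np.zeros(n_qtl, dtype=bool)
        flags[:large_in_shared.get(t, 0)] = True
        is_large[t] = flags

    # --- disjoint traits (Q, Per) -----------------------------------------
    for t in solo_ts:
        s = by_name[t]
        eff = rng.standard_normal(n_qtl)
        flags = np.zeros(n_qtl, dtype=bool)
        if s.n_large:
            m = scaled_variance_m(s.var_fraction_large, s.n_qtl, s.n_large)
            eff[:s.n_large] = rng.normal(0.0, np.sqrt(m), size=s.n_large)
            flags[:s.n_large] = True
        effects[t] = eff
        is_large[t] = flags

    return QTLSet(specs=specs, loci=loci, effects=effects,
                  is_large=is_large, shared_loci=shared)


# ---------------------------------------------------------------------------
# breeding values and phenotypes
# ---------------------------------------------------------------------------

def true_breeding_value(dosages: np.ndarray,
                        effects: np.ndarray) -> np.ndarray:
    """TBV = sum of QTL effects times allelic dosage (0/1/2)."""
    return np.asarray(dosages, dtype=float) @ np.asarray(effects, dtype=float)


def tbv_matrix(pop: Population, qtl: QTLSet) -> np.ndarray:
    """TBVs for every individual and trait, shape (n, p)."""
    out = np.empty((pop.n_individuals, len(qtl.specs)))
    for j, t in enumerate(qtl.trait_names):
        out[:, j] = true_breeding_value(pop.dosages(qtl.loci[t]),
                                        qtl.effects[t])
    return out


@dataclass
class TraitState:
    """Per-cycle environmental error variances keeping h2 constant.

    ``refresh`` recomputes sigma_e^2 = Var(TBV) (1 - h2) / h2 per trait
    from the current cycle's cohort, so realized heritability stays at
    its nominal value as genetic variance erodes under selection.
    """

    specs: tuple[TraitSpec, ...]
    error_variances: np.ndarray | None = None

    def refresh(self, tbv: np.ndarray) -> None:
        var_g = tbv.var(axis=0, ddof=1)
        h2 = np.array([s.h2 for s in self.specs])
        self.error_variances = var_g * (1.0 - h2) / h2

    def error_sd(self) -> np.ndarray:
        if self.error_variances is None:
            raise ConfigError("TraitState.refresh was never called")
        return np.sqrt(self.error_variances)


def phenotype(tbv: np.ndarray, state: TraitState,
              rng: np.random.Generator,
              error_scale: float = 1.0) -> np.ndarray:
    """Phenotype = TBV + independent normal error per trait.

    ``error_scale`` multiplies the error *variance* (used for plot
    means, whose error variance is set at the plot level).
    """
    sd = state.error_sd() * np.sqrt(error_scale)
    return tbv + rng.standard_normal(tbv.shape) * sd


def qtl_table(qtl: QTLSet, pop: Population) -> pd.DataFrame:
    """Tidy QTL export: trait, chromosome, position_cM, effect, flags."""
    cm = pop.positions_cm()
    L = pop.loci_per_chromosome
    shared = set(qtl.shared_loci.tolist())
    rows = []
    for t in qtl.trait_names:
        c_idx, l_idx = np.divmod(qtl.loci[t], L)
        for g, c, l, e, big in zip(qtl.loci[t], c_idx, l_idx,
                                   qtl.effects[t], qtl.is_large[t]):
            rows.append((t, int(c) + 1, float(cm[l]), float(e),
                         bool(big), int(g) in shared))
    return pd.DataFrame(rows, columns=["trait", "chromosome", "position_cM",
                                       "effect", "is_large", "is_shared"])
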