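"""Zero handling: turn a sparse count table into a strictly positive matrix.

Three strategies: a pseudo-count (default 0.5 added to every count),
library-size-proportional imputation of zeros, or an adaptive rule that
picks imputation only when the library size is associated with the covariate
of interest (slope t-test of log library size on the covariate, p < 0.1).
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .tables import CountTable, SampleFrame

KINDS = ("pseudo", "imputation", "adaptive")


@dataclass
class ZeroStrategy:
    kind: str = "adaptive"
    pseudo_count: float = 0.5
    adaptive_alpha: float = 0.1
    chosen: str | None = None
    association_p: float | None = None

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"zero strategy must be one of {KINDS}, got {self.kind!r}")
        if self.pseudo_count <= 0:
            raise ValueError("pseudo_count must be > 0")
        if not 0 < self.adaptive_alpha < 1:
            raise ValueError("adaptive_alpha must be in (0, 1)")

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "pseudo_count": self.pseudo_count,
            "adaptive_alpha": self.adaptive_alpha,
            "chosen": self.chosen,
            "association_p": self.association_p,
        }


def add_pseudocount(ct: CountTable, pc: float = 0.5) -> np.ndarray:
    """Return ``Y + pc`` as a strictly positive float matrix."""
    if pc <= 0:
        raise ValueError("pseudo-count must be > 0")
    return ct.counts.astype(float) + pc


def impute_zeros(ct: CountTable) -> np.ndarray:
    """Impute zeros proportionally to library size.

    A zero for taxon *i* in sample *s* becomes ``N_s / max_k{N_k : Y[i,k]=0}``
    so the zero sample with the largest library receives exactly 1 and all
    imputed values within a taxon are proportional to library size.  Nonzero
    entries and zero-free taxa are unchanged.
    """
    out = ct.counts.astype(float)
    libs = ct.library_sizes.astype(float)
    zero = out == 0
    has_zero = zero.any(axis=1)
    # per-taxon max library size among its zero samples
    nmax = np.where(zero, libs[None, :], -np.inf).max(axis=1)
    for i in np.flatnonzero(has_zero):
        out[i, zero[i]] = libs[zero[i]] / nmax[i]
    return out


def _choose(p: float, alpha: float) -> str:
    # strict inequality: p exactly at the threshold keeps the pseudo-count
    return "imputation" if p < alpha else "pseudo"


def resolve_strategy(ct: CountTable, sf: SampleFrame, strategy: ZeroStrategy) -> ZeroStrategy:
    """Resolve an adaptive strategy to a concrete one.

    The adaptive rule regresses log library size on the covariate of
    interest by OLS and uses the two-sided slope t-test p-value: below
    ``adaptive_alpha`` the (conservative) imputation path is chosen,
    otherwise the pseudo-count path.
    """
    if strategy.kind != "adaptive":
        return replace(strategy, chosen=strategy.kind)
    u = sf.u
    if np.ptp(u) == 0:
        raise ValueError("covariate of interest is constant; cannot test library-size association")
    libs = ct.library_sizes.astype(float)
    if (libs <= 0).any():
        raise ValueError("zero library size; filter samples before zero handling")
    res = stats.linregress(u, np.log(libs))
    p = float(res.pvalue)
    return replace(strategy, chosen=_choose(p, strategy.adaptive_alpha), association_p=p)


def positive_matrix(ct: CountTable, strategy: ZeroStrategy) -> np.ndarray:
    """Apply a resolved strategy; zero-free tables pass through unchanged.

    Skipping zero handling on zero-free input keeps the downstream CLR
    analysis exactly invariant to per-sample count rescaling.
    """
    chosen = strategy.chosen or strategy.kind
    if chosen == "adaptive":
        raise ValueError("strategy must be resolved before use (call resolve_strategy)")
    if (ct.counts > 0).all():
        return ct.counts.astype(float)
    if chosen == "pseudo":
        return add_pseudocount(ct, strategy.pseudo_count)
    return impute_zeros(ct)
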