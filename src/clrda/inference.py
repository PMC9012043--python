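"""Bias-corrected testing, BH adjustment, and the fixed-effects pipeline.

The per-taxon statistic is ``T_i = sqrt(n) * alpha_hat_i /
sqrt(rho_hat * sigma2_hat_i)`` with two-sided p-values from the
t-distribution on ``n - d - 2`` degrees of freedom, followed by
Benjamini-Hochberg adjustment at the target FDR level ``q``.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .modebias import BiasEstimate, debias
from .regression import DesignInfo, OlsFit, build_design, clr_transform, fit_all_taxa
from .tables import CountTable, FilterReport, SampleFrame, filter_table, winsorize
from .zeros import ZeroStrategy, positive_matrix, resolve_strategy


@dataclass
class RunConfig:
    """Pipeline configuration; ``fdr_level`` enters only the reject flag."""

    fdr_level: float = 0.05
    zero: ZeroStrategy | str = "adaptive"
    winsor: bool = False
    winsor_q: float = 0.97
    min_lib: int = 1000
    min_prev: float = 0.10
    bandwidth: float | None = None

    def __post_init__(self):
        if not 0 < self.fdr_level < 1:
            raise ValueError("fdr_level must be in (0, 1)")
        if isinstance(self.zero, str):
            self.zero = ZeroStrategy(kind=self.zero)


def test_statistics(alpha_hat, sigma2_hat, di: DesignInfo):
    """Studentized statistics ``T = alpha_hat / sqrt(rho * sigma2 / n)``."""
    alpha_hat = np.asarray(alpha_hat, dtype=float)
    sigma2 = np.asarray(sigma2_hat, dtype=float)
    se = np.sqrt(di.rho_hat * sigma2 / di.n)
    degenerate = sigma2 == 0
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} taxa have zero residual variance; "
                      "their statistics are infinite (perfect fit)")
    with np.errstate(divide="ignore", invalid="ignore"):
        T = np.where(degenerate, np.sign(alpha_hat) * np.inf, alpha_hat / se)
    T = np.where(degenerate & (alpha_hat == 0), 0.0, T)
    return T, di.df


def p_values(T, df: int) -> np.ndarray:
    """Two-sided p-values ``2 * F_df(-|T|)`` from the t-distribution."""
    if df < 1:
        raise ValueError("degrees of freedom must be >= 1")
    T = np.asarray(T, dtype=float)
    p = 2.0 * stats.t.cdf(-np.abs(T), df)
    return np.where(np.isinf(T), 0.0, p)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class RunResult:
    """Full output of a pipeline run."""

    table: pd.DataFrame
    bias: BiasEstimate
    strategy: ZeroStrategy
    filter_report: FilterReport
    design: DesignInfo
    fit: OlsFit | object = None

    def log(self) -> dict:
        return {
            "bias": self.bias.bias,
            "mode_value": self.bias.mode_value,
            "bandwidth": self.bias.h,
            "kernel": self.bias.kernel,
            "zero_strategy": self.strategy.to_dict(),
            "filter": self.filter_report.to_dict(),
            "n": self.design.n,
            "d": self.design.d,
            "rho_hat": self.design.rho_hat,
        }


def _assemble_table(
    taxon_ids, alpha_tilde, alpha_hat, se, T, df, p, padj, q, all_taxa, extra=None
) -> pd.DataFrame:
    tested = pd.DataFrame({
        "taxon": taxon_ids,
        "alpha_raw": alpha_tilde,
        "alpha_debiased": alpha_hat,
        "log2fc": np.asarray(alpha_hat) / np.log(2),
        "se": se,
        "stat": T,
        "df": df,
        "pvalue": p,
        "padj": padj,
        "reject": padj <= q,
        "status": "tested",
    })
    if extra is not None:
        for k, v in extra.items():
            tested[k] = v
    dropped = [t for t in all_taxa if t not in set(taxon_ids)]
    if dropped:
        na = pd.DataFrame({"taxon": dropped})
        for col in tested.columns:
            if col not in ("taxon", "status", "reject"):
                na[col] = np.nan
        na["reject"] = False
        na["status"] = "low_prevalence"
        tested = pd.concat([tested, na[tested.columns]], ignore_index=True)
    out = tested.sort_values(["pvalue", "taxon"], na_position="last", kind="mergesort")
    return out.reset_index(drop=True)


def run_fixed(ct: CountTable, sf: SampleFrame, cfg: RunConfig | None = None) -> RunResult:
    """End-to-end fixed-effects analysis.

    Stages: sample/taxon filtering, optional winsorization, zero-handling
    resolution, CLR transform, shared-design OLS, mode-based bias
    correction, t-tests, BH adjustment.  Taxa dropped by the prevalence
    filter appear in the output with NA statistics and status
    ``low_prevalence``.  Deterministic for fixed inputs.
    """
    cfg = cfg or RunConfig()
    all_taxa = list(ct.taxon_ids)
    sub, report = filter_table(ct, cfg.min_lib, cfg.min_prev)
    if cfg.winsor:
        sub = winsorize(sub, cfg.winsor_q)
    sfa = sf.reindex(sub.sample_ids)
    strategy = resolve_strategy(sub, sfa, cfg.zero)
    P = positive_matrix(sub, strategy)
    W = clr_transform(P)
    di = build_design(sfa)
    fit = fit_all_taxa(W, di)
    alpha_hat, bias = debias(fit, di, h=cfg.bandwidth)
    T, df = test_statistics(alpha_hat, fit.sigma2_hat, di)
    p = p_values(T, df)
    padj = bh_adjust(p)
    table = _assemble_table(
        sub.taxon_ids, fit.alpha_tilde, alpha_hat, fit.se_tilde,
        T, df, p, padj, cfg.fdr_level, all_taxa,
    )
    return RunResult(table=table, bias=bias, strategy=strategy,
                     filter_report=report, design=di, fit=fit)


def export_plot_data(result: RunResult) -> pd.DataFrame:
    """Per-taxon table behind effect-size and volcano plots.

    Carries both the raw (biased) and debiased effects; their difference is
    the same constant for every taxon.
    """
    t = result.table
    out = t.loc[t["status"] == "tested",
                ["taxon", "alpha_raw", "alpha_debiased", "log2fc", "pvalue", "padj"]].copy()
    out["neg_log10_p"] = -np.log10(np.clip(out["pvalue"], 1e-300, None))
    out["significant"] = t.loc[t["status"] == "tested", "reject"].to_numpy()
    return out.reset_index(drop=True)
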