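"""Empirical FDR / TPR scoring against simulated truth.

Per run, the false discovery proportion uses the ``1 v R`` denominator
convention (``FDP = FP / max(R, 1)``) and the true positive rate divides by
the number of truly differential taxa realized in that dataset.  Replicate
runs are aggregated as means with normal-approximation 95% confidence
intervals.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .inference import RunConfig, RunResult, run_fixed
from .mixed import run_lmm
from .simulate import SimScenario, simulate


@dataclass
class RunMetrics:
    n_rejected: int
    n_true_pos: int
    n_false_pos: int
    fdp: float
    tpr: float


@dataclass
class AggregateMetrics:
    fdr: float
    tpr: float
    fdr_ci: float  # 95% CI half-width
    tpr_ci: float
    runs: int

    def to_dict(self) -> dict:
        return {"fdr": self.fdr, "tpr": self.tpr,
                "fdr_ci_halfwidth": self.fdr_ci, "tpr_ci_halfwidth": self.tpr_ci,
                "runs": self.runs}


def score_run(results: pd.DataFrame, truth: pd.DataFrame, q: float) -> RunMetrics:
    """Score one analysis against ground truth (aligned on taxon ID).

    Taxa absent from the results (or untested) count as not rejected; the
    TPR denominator is every truly differential taxon in the dataset.
    """
    merged = truth.merge(results[["taxon", "padj"]], on="taxon", how="left")
    if len(merged) != len(truth):
        raise ValueError("taxon IDs in results and truth do not align")
    rejected = (merged["padj"] <= q).fillna(False).to_numpy()
    diff = merged["is_differential"].to_numpy(dtype=bool)
    R = int(rejected.sum())
    TP = int((rejected & diff).sum())
    FP = R - TP
    n_diff = int(diff.sum())
    return RunMetrics(
        n_rejected=R, n_true_pos=TP, n_false_pos=FP,
        fdp=FP / max(R, 1), tpr=TP / max(n_diff, 1),
    )


def aggregate(runs: list[RunMetrics]) -> AggregateMetrics:
    """Means over runs with 95% normal-approximation CIs (mean +/- 1.96 SE)."""
    if not runs:
        raise ValueError("need at least one run")
    fdp = np.array([r.fdp for r in runs], dtype=float)
    tpr = np.array([r.tpr for r in runs], dtype=float)
    k = len(runs)
    se = lambda x: float(np.std(x, ddof=1) / np.sqrt(k)) if k > 1 else 0.0
    return AggregateMetrics(
        fdr=float(fdp.mean()), tpr=float(tpr.mean()),
        fdr_ci=1.96 * se(fdp), tpr_ci=1.96 * se(tpr), runs=k,
    )


def evaluate_scenario(
    sc: SimScenario,
    runs: int = 100,
    cfg: RunConfig | None = None,
    seed_base: int = 1,
    mixed: bool = False,
) -> tuple[pd.DataFrame, AggregateMetrics]:
    """Simulate ``runs`` datasets and score the pipeline on each.

    Run *k* uses seed ``seed_base + k``; the mixed-effects path is used when
    ``mixed`` is set (or automatically for the S8 settings).
    """
    cfg = cfg or RunConfig()
    mixed = mixed or sc.setting.startswith("S8")
    metrics = []
    for k in range(runs):
        ds = simulate(replace(sc, seed=seed_base + k))
        res: RunResult = (run_lmm if mixed else run_fixed)(ds.counts, ds.samples, cfg)
        metrics.append(score_run(res.table, ds.truth, cfg.fdr_level))
    per_run = pd.DataFrame([vars(r) for r in metrics])
    per_run.insert(0, "run", np.arange(runs))
    return per_run, aggregate(metrics)
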