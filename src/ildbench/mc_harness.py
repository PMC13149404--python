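"""Monte-Carlo harness: factorial grid construction, per-condition
replication loops, and aggregation into the study's table layouts.

The default grid crosses n in {50, 100, 200}, t in {10, 20, 30, 50, 80},
trait SD in {1, 2, 3}, bias conditions {none, 1, 2, 3, 4} and bias strengths
{low, high}; the no-bias condition is emitted once per (n, t, SD) regardless
of strength, giving 3*5*3*(1 + 4*2) = 405 distinct conditions (the full
bookkeeping crossing counts 450 cells, the 45 no-bias cells twice).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .datagen import (GRID_N, GRID_SD_B, GRID_T, ILDDataset, MeasurementDesign,
                      SimCondition, condition_seed, default_design,
                      simulate_dataset)
from .fit_evaluation import (CFI_CUTOFFS, RMSEA_CUTOFFS, SRMR_CUTOFFS,
                             FitIndices, evaluate_cutoffs, fit_indices, icc1)
from .twolevel_cfa import BASELINE, HYPOTHESIZED, SATURATED, compute_moments, fit_model

__all__ = [
    "GridConfig",
    "ConditionSummary",
    "ReplicationRecord",
    "build_grid",
    "evaluate_dataset",
    "run_condition",
    "run_grid",
    "aggregate",
    "recommendation_table",
    "POWER_THRESHOLD",
    "INDEX_COLUMNS",
]

POWER_THRESHOLD = 0.80

#: column order mirroring the result tables: chi-square rejection count,
#: then CFI, RMSEA, SRMR-b, SRMR-w pass proportions at their cut-offs
INDEX_COLUMNS = (
    ["chi2_p<0.05"]
    + [f"cfi>={c}" for c in CFI_CUTOFFS]
    + [f"rmsea<{c}" for c in RMSEA_CUTOFFS]
    + [f"srmr_b<{c}" for c in SRMR_CUTOFFS]
    + [f"srmr_w<{c}" for c in SRMR_CUTOFFS]
)


@dataclass(frozen=True)
class GridConfig:
    """Factor lists and bookkeeping for a Monte-Carlo run."""

    n: tuple = GRID_N
    t: tuple = GRID_T
    sd_b: tuple = GRID_SD_B
    bias: tuple = ("none", 1, 2, 3, 4)
    strength: tuple = ("low", "high")
    replications: int = 1000
    root_seed: int = 0
    design: MeasurementDesign = field(default_factory=default_design)
    n_jobs: int = 1

    def __post_init__(self) -> None:
        for name in ("n", "t", "sd_b", "bias", "strength"):
            if len(getattr(self, name)) == 0:
                raise ValueError(f"empty factor list: {name}")
        if self.replications < 1:
            raise ValueError("need at least one replication")


def build_grid(cfg: GridConfig) -> list[SimCondition]:
    """Deterministically ordered list of conditions with stable seeds.

    ``bias="none"`` appears once per (n, t, sd_b) cell; each condition's
    seed is a stable hash of the root seed and the condition key, so subsets
    of the grid reproduce the same per-condition streams.
    """
    conditions = []
    seen = set()
    for n, t, sd, bias, strength in itertools.product(
            cfg.n, cfg.t, cfg.sd_b, cfg.bias, cfg.strength):
        if bias == "none":
            strength = "low"  # strength is irrelevant without bias
        key = (n, t, sd, bias, strength if bias != "none" else "-")
        if key in seen:
            continue
        seen.add(key)
        seed = condition_seed(cfg.root_seed, key)
        conditions.append(SimCondition(n, t, sd, bias, strength, seed))
    return conditions


@dataclass(frozen=True)
class ReplicationRecord:
    """Per-replication outcome inside a condition."""

    replication: int
    converged: bool
    indices: FitIndices | None
    cutoffs: dict | None
    iccs: np.ndarray | None


@dataclass
class ConditionSummary:
    """Aggregated results of one condition over its replications."""

    condition: SimCondition
    replications: int
    converged: int
    pass_counts: dict           # cutoff label -> count over converged reps
    index_mean: dict            # index name -> mean over converged reps
    index_sd: dict
    mean_icc: np.ndarray        # per item
    mean_icc_overall: float

    @property
    def chi2_rejections(self) -> int:
        return self.pass_counts["chi2_p<0.05"]

    def rejection_rate(self, label: str) -> float:
        """Fraction of converged replications flagging misfit at a cut-off.

        For the chi-square label this is the significance rate itself; for
        index labels it is one minus the pass rate.
        """
        if self.converged == 0:
            return float("nan")
        count = self.pass_counts[label]
        if label == "chi2_p<0.05":
            return count / self.converged
        return 1.0 - count / self.converged

    def row(self, proportions: bool = False) -> dict:
        chi2 = self.pass_counts["chi2_p<0.05"]
        out = {
            "bias": self.condition.bias,
            "strength": "-" if self.condition.bias == "none"
                        else self.condition.strength,
            "sd_b": self.condition.sd_b,
            "n": self.condition.n,
            "t": self.condition.t,
            "replications": self.replications,
            "converged": self.converged,
            "chi2_p<0.05": chi2 / self.converged if proportions else chi2,
        }
        for label in INDEX_COLUMNS[1:]:
            out[label] = (self.pass_counts[label] / self.converged
                          if self.converged else float("nan"))
        for name, v in self.index_mean.items():
            out[f"mean_{name}"] = v
        for name, v in self.index_sd.items():
            out[f"sd_{name}"] = v
        out["mean_icc"] = self.mean_icc_overall
        return out


def evaluate_dataset(data: ILDDataset, rmsea_n: str = "n_rows"):
    """Fit the three models to one dataset and score it.

    Returns ``(indices, cutoffs, iccs, converged)``; ``indices`` is None
    when the hypothesized fit did not converge.
    """
    m = compute_moments(data)
    iccs = icc1(m)
    fit_h = fit_model(m, HYPOTHESIZED)
    fit_s = fit_model(m, SATURATED)
    fit_b = fit_model(m, BASELINE)
    converged = fit_h.converged and fit_s.converged and fit_b.converged
    if not converged:
        return None, None, iccs, False
    fi = fit_indices(fit_h, fit_s, fit_b, rmsea_n=rmsea_n)
    cutoffs = evaluate_cutoffs(fi).to_dict()
    return fi, cutoffs, iccs, True


def _run_replication(cond: SimCondition, r: int,
                     design: MeasurementDesign) -> ReplicationRecord:
    rep_cond = replace(cond, seed=(cond.seed + r) % 2 ** 31)
    data = simulate_dataset(rep_cond, design)
    fi, cuts, iccs, ok = evaluate_dataset(data)
    return ReplicationRecord(r, ok, fi, cuts, iccs)


def run_condition(cond: SimCondition, reps: int,
                  design: MeasurementDesign | None = None,
                  n_jobs: int = 1) -> ConditionSummary:
    """Simulate, fit and score ``reps`` replications of one condition.

    Replication ``r`` uses seed ``cond.seed + r`` so scheduling cannot
    change results.  Non-converged replications are counted and excluded
    from index means and cut-off counts; failures are recorded, not raised.
    """
    design = design or default_design()
    if n_jobs != 1:
        from joblib import Parallel, delayed
        records = Parallel(n_jobs=n_jobs)(
            delayed(_run_replication)(cond, r, design) for r in range(reps))
    else:
        records = [_run_replication(cond, r, design) for r in range(reps)]

    converged = [rec for rec in records if rec.converged]
    pass_counts = {label: 0 for label in INDEX_COLUMNS}
    values: dict[str, list] = {k: [] for k in
                               ("chi2", "p_value", "cfi", "rmsea",
                                "srmr_w", "srmr_b")}
    for rec in converged:
        for label in INDEX_COLUMNS:
            pass_counts[label] += bool(rec.cutoffs[label])
        d = rec.indices.to_dict()
        for k in values:
            values[k].append(d[k])
    index_mean = {k: float(np.mean(v)) if v else float("nan")
                  for k, v in values.items()}
    index_sd = {k: float(np.std(v, ddof=1)) if len(v) > 1 else float("nan")
                for k, v in values.items()}
    iccs = np.array([rec.iccs for rec in records if rec.iccs is not None])
    mean_icc = iccs.mean(axis=0) if iccs.size else np.full(6, np.nan)
    return ConditionSummary(cond, reps, len(converged), pass_counts,
                            index_mean, index_sd, mean_icc,
                            float(np.mean(mean_icc)))


def run_grid(cfg: GridConfig,
             conditions: Sequence[SimCondition] | None = None
             ) -> list[ConditionSummary]:
    """Run every condition of a grid config (or an explicit subset)."""
    if conditions is None:
        conditions = build_grid(cfg)
    return [run_condition(c, cfg.replications, cfg.design, cfg.n_jobs)
            for c in conditions]


def aggregate(summaries: Iterable[ConditionSummary],
              proportions: bool = False) -> dict[str, pd.DataFrame]:
    """Long- and wide-format result tables plus the recommendation matrix.

    ``wide`` mirrors the study tables: one row per condition, the chi-square
    column as a rejection count (or a proportion with ``proportions=True``)
    and the index columns as pass proportions at each cut-off.  ``long`` has
    one row per condition and statistic.
    """
    summaries = list(summaries)
    rows = [s.row(proportions) for s in summaries]
    id_cols = ["bias", "strength", "sd_b", "n", "t"]
    wide_cols = id_cols + ["replications", "converged"] + INDEX_COLUMNS
    wide = pd.DataFrame(rows, columns=wide_cols + [
        c for c in (rows[0] if rows else {}) if c not in wide_cols])
    if rows:
        wide = wide.sort_values(id_cols, key=lambda s: s.astype(str),
                                kind="stable").reset_index(drop=True)
    long = wide.melt(id_vars=id_cols, var_name="statistic",
                     value_name="value") if rows else pd.DataFrame(
        columns=id_cols + ["statistic", "value"])
    return {
        "long": long,
        "wide": wide,
        "recommendations": recommendation_table(summaries),
    }


def recommendation_table(summaries: Iterable[ConditionSummary]) -> pd.DataFrame:
    """Adequate-power verdicts: one row per biased condition and criterion.

    A cell is ``adequate`` when the rejection rate at that criterion reaches
    the 80% power threshold, else ``underpowered``; no-bias conditions are
    excluded (power is undefined there).
    """
    rows = []
    for s in summaries:
        if s.condition.bias == "none":
            continue
        for label in INDEX_COLUMNS:
            rate = s.rejection_rate(label)
            rows.append({
                "bias": s.condition.bias,
                "strength": s.condition.strength,
                "sd_b": s.condition.sd_b,
                "n": s.condition.n,
                "t": s.condition.t,
                "criterion": label,
                "power": rate,
                "verdict": "adequate" if rate >= POWER_THRESHOLD
                           else "underpowered",
            })
    return pd.DataFrame(rows, columns=["bias", "strength", "sd_b", "n", "t",
                                       "criterion", "power", "verdict"])
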