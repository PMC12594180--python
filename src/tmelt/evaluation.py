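"""Stratified evaluation: pooled vs. per-species metrics and paired tests.

Pooled (cross-species) Spearman rho conflates two signals: the ordering of
species means and the ordering of proteins within a species. When species
means spread much wider than proteins within a species, a model that only
ranks species correctly still achieves a high pooled rho — a Simpson's-
paradox effect that makes pooled rank correlation an overly optimistic
metric for variant-level prediction. This module therefore reports every
metric both pooled and per species: Spearman rho (with the unweighted mean
over species), RMSE (°C), MRAE (percent), nonparametric bootstrap standard
errors over test proteins, and two-sided paired t-tests on per-protein
absolute errors between training regimes.
"""

from __future__ import annotations

import logging
from collections.abc import Callable, Sequence
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .experiment import PredictionRecord, records_to_frame

logger = logging.getLogger(__name__)

__all__ = [
    "rmse",
    "mrae",
    "spearman_global",
    "spearman_per_species",
    "bootstrap_se",
    "paired_regime_test",
    "PairedTestResult",
    "ScenarioMetrics",
    "EvaluationReport",
    "build_report",
    "scatter_frame",
]


def _arrays(records: Sequence[PredictionRecord]) -> tuple[np.ndarray, np.ndarray]:
    return (
        np.array([r.y_true for r in records], dtype=float),
        np.array([r.y_pred for r in records], dtype=float),
    )


def rmse(records: Sequence[PredictionRecord]) -> float:
    if len(records) == 0:
        raise ValueError("rmse of an empty record set is undefined")
    y, yhat = _arrays(records)
    return float(np.sqrt(np.mean((yhat - y) ** 2)))


def mrae(records: Sequence[PredictionRecord]) -> float:
    """Mean relative absolute error in percent: 100 * mean(|err| / |truth|)."""
    if len(records) == 0:
        raise ValueError("mrae of an empty record set is undefined")
    y, yhat = _arrays(records)
    if np.any(y == 0):
        raise ValueError("MRAE undefined for zero ground-truth Tm")
    return float(100.0 * np.mean(np.abs(yhat - y) / np.abs(y)))


def spearman_global(records: Sequence[PredictionRecord]) -> float:
    """Spearman rank correlation over all pooled records (NaN when a vector
    is constant, in which case the correlation is undefined)."""
    if len(records) < 2:
        raise ValueError("Spearman rho needs at least 2 records")
    y, yhat = _arrays(records)
    if np.ptp(y) == 0 or np.ptp(yhat) == 0:
        logger.warning("constant vector: pooled Spearman rho undefined")
        return float("nan")
    rho, _ = stats.spearmanr(y, yhat)
    return float(rho)


def spearman_per_species(
    records: Sequence[PredictionRecord],
) -> tuple[dict[str, float], float]:
    """Spearman rho within each species plus the unweighted average.

    Species with fewer than 2 test records or a constant vector are
    excluded from both the map and the average (and logged).
    """
    by_species: dict[str, list[PredictionRecord]] = {}
    for r in records:
        by_species.setdefault(r.species, []).append(r)
    rhos: dict[str, float] = {}
    for sp, rs in by_species.items():
        if len(rs) < 2:
            logger.info("species %s excluded from per-species rho (n=%d)", sp, len(rs))
            continue
        y, yhat = _arrays(rs)
        if np.ptp(y) == 0 or np.ptp(yhat) == 0:
            logger.info("species %s excluded from per-species rho (zero variance)", sp)
            continue
        rho, _ = stats.spearmanr(y, yhat)
        rhos[sp] = float(rho)
    mean = float(np.mean(list(rhos.values()))) if rhos else float("nan")
    return rhos, mean


def bootstrap_se(
    records: Sequence[PredictionRecord],
    metric: Callable[[Sequence[PredictionRecord]], float],
    n_boot: int = 1000,
    seed: int = 0,
) -> float:
    """SD of ``metric`` over nonparametric resamples of the records
    (proteins resampled with replacement); seed-deterministic."""
    if len(records) < 2:
        raise ValueError("bootstrap needs at least 2 records")
    rng = np.random.default_rng(seed)
    n = len(records)
    values = np.empty(n_boot)
    recs = list(records)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        values[b] = metric([recs[i] for i in idx])
    return float(values.std(ddof=1))


class PairedTestResult(NamedTuple):
    t: float
    p: float
    n: int
    degenerate: bool


def paired_regime_test(
    records_a: Sequence[PredictionRecord], records_b: Sequence[PredictionRecord]
) -> PairedTestResult:
    """Two-sided paired t-test on per-protein absolute errors.

    Pairing is by protein id; both record sets must cover the same
    proteins. A zero-variance difference vector is degenerate: the test
    statistic is reported as 0 (p = 1) when all differences vanish and
    flagged otherwise.
    """
    a = {r.protein_id: abs(r.y_pred - r.y_true) for r in records_a}
    b = {r.protein_id: abs(r.y_pred - r.y_true) for r in records_b}
    if set(a) != set(b):
        only_a = sorted(set(a) - set(b))[:3]
        only_b = sorted(set(b) - set(a))[:3]
        raise ValueError(f"record sets differ (e.g. only in a: {only_a}, only in b: {only_b})")
    ids = sorted(a)
    if len(ids) < 2:
        raise ValueError("paired test needs at least 2 shared proteins")
    d = np.array([a[i] - b[i] for i in ids])
    if d.std(ddof=1) == 0:
        if np.all(d == 0):
            return PairedTestResult(t=0.0, p=1.0, n=len(ids), degenerate=True)
        logger.warning("constant non-zero error differences: paired t undefined")
        return PairedTestResult(t=float("nan"), p=float("nan"), n=len(ids), degenerate=True)
    t, p = stats.ttest_rel([a[i] for i in ids], [b[i] for i in ids])
    return PairedTestResult(t=float(t), p=float(p), n=len(ids), degenerate=False)


@dataclass
class ScenarioMetrics:
    """All metrics of one (approach, regime) cell."""

    approach: str
    regime: str
    n: int
    global_spearman: float
    per_species_spearman: dict[str, float]
    mean_species_spearman: float
    global_rmse: float
    global_rmse_se: float
    per_species_rmse: dict[str, float]
    mean_species_rmse: float
    mrae: float
    mrae_se: float
    n_per_species: dict[str, int]


@dataclass
class EvaluationReport:
    """Per-scenario metrics plus pairwise regime comparisons per approach."""

    scenarios: list[ScenarioMetrics] = field(default_factory=list)
    pairwise_tests: dict[tuple[str, str, str], PairedTestResult] = field(default_factory=dict)

    def scenario(self, approach: str, regime: str) -> ScenarioMetrics:
        for s in self.scenarios:
            if (s.approach, s.regime) == (approach, regime):
                return s
        raise KeyError(f"no scenario ({approach}, {regime}) in report")

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format table: approach, regime, species ('' = pooled),
        metric, value, se."""
        rows = []
        for s in self.scenarios:
            rows.append((s.approach, s.regime, "", "spearman", s.global_spearman, np.nan))
            rows.append((s.approach, s.regime, "", "rmse", s.global_rmse, s.global_rmse_se))
            rows.append((s.approach, s.regime, "", "mrae", s.mrae, s.mrae_se))
            rows.append((s.approach, s.regime, "", "mean_species_spearman", s.mean_species_spearman, np.nan))
            rows.append((s.approach, s.regime, "", "mean_species_rmse", s.mean_species_rmse, np.nan))
            for sp, v in s.per_species_spearman.items():
                rows.append((s.approach, s.regime, sp, "spearman", v, np.nan))
            for sp, v in s.per_species_rmse.items():
                rows.append((s.approach, s.regime, sp, "rmse", v, np.nan))
        return pd.DataFrame(rows, columns=["approach", "regime", "species", "metric", "value", "se"])

    def to_summary_frame(self) -> pd.DataFrame:
        """Wide summary (one row per approach): RMSE and MRAE per regime plus
        the G-vs-S paired test."""
        rows = []
        for approach in sorted({s.approach for s in self.scenarios}):
            row: dict = {"approach": approach}
            for s in self.scenarios:
                if s.approach != approach:
                    continue
                row[f"rmse_{s.regime}"] = s.global_rmse
                row[f"rmse_se_{s.regime}"] = s.global_rmse_se
                row[f"mrae_{s.regime}"] = s.mrae
                row[f"mrae_se_{s.regime}"] = s.mrae_se
            test = self.pairwise_tests.get((approach, "G", "S"))
            if test is not None:
                row["t_G_vs_S"] = test.t
                row["p_G_vs_S"] = test.p
            rows.append(row)
        return pd.DataFrame(rows)

    def to_json_dict(self) -> dict:
        return {
            "scenarios": [
                {
                    "approach": s.approach,
                    "regime": s.regime,
                    "n": s.n,
                    "global_spearman": s.global_spearman,
                    "mean_species_spearman": s.mean_species_spearman,
                    "global_rmse": s.global_rmse,
                    "global_rmse_se": s.global_rmse_se,
                    "mean_species_rmse": s.mean_species_rmse,
                    "mrae": s.mrae,
                    "mrae_se": s.mrae_se,
                    "per_species_spearman": s.per_species_spearman,
                    "per_species_rmse": s.per_species_rmse,
                    "n_per_species": s.n_per_species,
                }
                for s in self.scenarios
            ],
            "pairwise_tests": {
                f"{a}:{ra}_vs_{rb}": {"t": r.t, "p": r.p, "n": r.n, "degenerate": r.degenerate}
                for (a, ra, rb), r in self.pairwise_tests.items()
            },
        }


def scatter_frame(records: Sequence[PredictionRecord]) -> pd.DataFrame:
    """Scatter data (y_true, y_pred, species) for pooled-prediction plots."""
    df = records_to_frame(records)
    return df[["y_true", "y_pred", "species", "approach", "regime"]]


def build_report(
    records: Sequence[PredictionRecord], n_boot: int = 1000, seed: int = 0
) -> EvaluationReport:
    """Aggregate prediction records into the full evaluation report.

    Species with a single test protein stay in the RMSE aggregates but are
    excluded (and logged) from per-species rank correlations. Paired tests
    compare regimes of the same approach on the intersection of protein ids
    (regimes may skip species)."""
    groups: dict[tuple[str, str], list[PredictionRecord]] = {}
    for r in records:
        groups.setdefault((r.approach, r.regime), []).append(r)
    report = EvaluationReport()
    for gi, ((approach, regime), rs) in enumerate(groups.items()):
        by_species: dict[str, list[PredictionRecord]] = {}
        for r in rs:
            by_species.setdefault(r.species, []).append(r)
        per_rmse = {sp: rmse(v) for sp, v in by_species.items()}
        rhos, mean_rho = spearman_per_species(rs)
        report.scenarios.append(
            ScenarioMetrics(
                approach=approach,
                regime=regime,
                n=len(rs),
                global_spearman=spearman_global(rs) if len(rs) >= 2 else float("nan"),
                per_species_spearman=rhos,
                mean_species_spearman=mean_rho,
                global_rmse=rmse(rs),
                global_rmse_se=bootstrap_se(rs, rmse, n_boot, seed + gi) if len(rs) >= 2 else float("nan"),
                per_species_rmse=per_rmse,
                mean_species_rmse=float(np.mean(list(per_rmse.values()))),
                mrae=mrae(rs),
                mrae_se=bootstrap_se(rs, mrae, n_boot, seed + gi) if len(rs) >= 2 else float("nan"),
                n_per_species={sp: len(v) for sp, v in by_species.items()},
            )
        )
    approaches = sorted({a for a, _ in groups})
    for approach in approaches:
        regimes = sorted({r for a, r in groups if a == approach})
        for i, ra in enumerate(regimes):
            for rb in regimes[i + 1 :]:
                ra_recs = groups[(approach, ra)]
                rb_recs = groups[(approach, rb)]
                ids = {r.protein_id for r in ra_recs} & {r.protein_id for r in rb_recs}
                if len(ids) < 2:
                    continue
                dropped = (len(ra_recs) - len(ids)) + (len(rb_recs) - len(ids))
                if dropped:
                    logger.info(
                        "paired test %s %s-vs-%s restricted to %d shared proteins", approach, ra, rb, len(ids)
                    )
                test = paired_regime_test(
                    [r for r in ra_recs if r.protein_id in ids],
                    [r for r in rb_recs if r.protein_id in ids],
                )
                report.pairwise_tests[(approach, ra, rb)] = test
    return report
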