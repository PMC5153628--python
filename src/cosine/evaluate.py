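"""Benchmark protocols and accuracy metrics.

Protocols mirror the standard virtual-screening evaluations: chemical-wise
k-fold cross-validation scored by AUC/AUPR, leave-one-drug-out retrieval
scored by the Top-1 hit rate, and cold-start evaluation scored by the true
positive rate among the top r% of ranked targets, stratified by
ligands-per-target and by maximum chemical similarity.

Rank ties use the worst-rank (pessimistic) convention everywhere, so no
reported metric ever benefits from a tie.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import average_precision_score

from cosine.cold_start import ColdStartConfig, apply_cold_start
from cosine.data_io import InteractionDataset, SimilarityMatrix
from cosine.factor_model import predict_probability
from cosine.optimizer import FitResult, ModelConfig, OptimizerConfig, fit_cosine
from cosine.reweight import ReweightConfig
from cosine.synthetic import ColdStartFixture


class UndefinedMetricError(ValueError):
    """Metric undefined for the given labels (e.g. single-class input)."""


# ---------------------------------------------------------------- metrics


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """ROC AUC as the normalized Mann-Whitney U statistic; ties count 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUC needs at least one positive and one negative")
    ranks = stats.rankdata(scores)  # average ranks give the 1/2 tie convention
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def aupr(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the precision-recall curve by step-wise integration."""
    labels = np.asarray(labels)
    if (labels == 1).sum() == 0:
        raise UndefinedMetricError("AUPR needs at least one positive")
    return float(average_precision_score(labels, np.asarray(scores, dtype=float)))


def worst_ranks(scores: np.ndarray) -> np.ndarray:
    """1-based rank of each score, descending; tied scores all get the worst rank."""
    scores = np.asarray(scores, dtype=float)
    return np.array([int((scores >= s).sum()) for s in scores])


def cutoff_rank(n_targets: int, r_percent: float) -> int:
    """Top-r% cutoff rank: round(n_targets * r / 100), half away from zero.

    With 3,500 targets the top r% comprises ranks up to 35 * r.
    """
    return int(math.floor(n_targets * r_percent / 100.0 + 0.5))


def tpr_at_top_percent(
    scores: np.ndarray, true_targets: Sequence[int], r_percent: float
) -> float:
    """Fraction of a chemical's true targets ranked within the top r%."""
    if not (0.0 < r_percent <= 100.0):
        raise ValueError("r_percent must lie in (0, 100]")
    true_targets = list(true_targets)
    if not true_targets:
        raise ValueError("need at least one true target")
    ranks = worst_ranks(scores)
    cut = cutoff_rank(len(scores), r_percent)
    return float(np.mean([ranks[t] <= cut for t in true_targets]))


@dataclass
class TTestResult:
    statistic: float
    p_value: float
    significant: bool
    degenerate: bool


def fold_significance(per_fold_a: Sequence[float], per_fold_b: Sequence[float], alpha: float = 0.05) -> TTestResult:
    """Paired t-test across folds; zero-variance differences are flagged, not a crash."""
    a = np.asarray(per_fold_a, dtype=float)
    b = np.asarray(per_fold_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need equal-length fold lists with at least 2 folds")
    diff = a - b
    if np.allclose(diff.std(ddof=1), 0.0):
        if np.allclose(diff.mean(), 0.0):
            # identical fold metrics: no evidence either way
            return TTestResult(statistic=float("nan"), p_value=float("nan"),
                               significant=False, degenerate=True)
        # constant nonzero shift: infinitely strong paired evidence
        return TTestResult(statistic=float(np.sign(diff.mean()) * np.inf), p_value=0.0,
                           significant=True, degenerate=True)
    t_stat, p = stats.ttest_rel(a, b)
    return TTestResult(statistic=float(t_stat), p_value=float(p), significant=bool(p < alpha), degenerate=False)


# ---------------------------------------------------------------- splits


def chemical_cv_split(
    n_chemicals: int, k: int, rounds: int = 1, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Chemical-wise k-fold splits, repeated ``rounds`` times.

    Returns k * rounds (train_indices, test_indices) pairs; within each round
    the test folds partition the chemicals with sizes differing by at most 1.
    """
    if k > n_chemicals:
        raise ValueError(f"cannot make {k} folds from {n_chemicals} chemicals")
    rng = np.random.default_rng(seed)
    folds: list[tuple[np.ndarray, np.ndarray]] = []
    for _ in range(rounds):
        perm = rng.permutation(n_chemicals)
        for part in np.array_split(perm, k):
            test = np.sort(part)
            train = np.sort(np.setdiff1d(np.arange(n_chemicals), test))
            folds.append((train, test))
    return folds


def mask_chemicals(data: InteractionDataset, chemicals: Sequence[int]) -> InteractionDataset:
    """Zero the interaction columns of the given chemicals (weights then revert
    to the baseline automatically, since initial weights derive from R)."""
    masked = data.copy()
    masked.R[:, list(chemicals)] = 0.0
    return masked


# ---------------------------------------------------------------- protocols


@dataclass
class EvalReport:
    """Per-fold metrics and their aggregate for one protocol run."""

    protocol: str
    fold_metrics: list[dict]
    seeds: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    def aggregate(self, key: str) -> tuple[float, float]:
        values = np.array([fm[key] for fm in self.fold_metrics if key in fm and fm[key] is not None])
        return float(values.mean()), float(values.std(ddof=1)) if values.size > 1 else 0.0


def cv_evaluate(
    data: InteractionDataset,
    M: SimilarityMatrix,
    N: SimilarityMatrix,
    k: int = 5,
    rounds: int = 1,
    seed: int = 0,
    model_cfg: ModelConfig = ModelConfig(),
    opt_cfg: OptimizerConfig = OptimizerConfig(),
    reweight_cfg: ReweightConfig = ReweightConfig(),
    cold_cfg: ColdStartConfig = ColdStartConfig(),
) -> EvalReport:
    """Chemical-wise cross-validation: hide each test fold's columns, fit the
    two-pass model, cold-start the test chemicals, and score AUC/AUPR over all
    (test chemical, target) pairs; metrics are averaged across folds."""
    folds = chemical_cv_split(data.n_chemicals, k, rounds, seed)
    fold_metrics = []
    for fold_id, (train, test) in enumerate(folds):
        masked = mask_chemicals(data, test)
        fit = fit_cosine(masked, M, N, model_cfg, opt_cfg, reweight_cfg)
        model = apply_cold_start(fit.model, masked, M, N, cold_cfg, new_chemicals=test)
        P = predict_probability(model)
        scores = P[:, test].ravel()
        labels = data.R[:, test].ravel()
        try:
            fold_auc = auc(scores, labels)
            fold_aupr = aupr(scores, labels)
        except UndefinedMetricError:
            fold_auc = fold_aupr = None
        fold_metrics.append({"fold": fold_id, "auc": fold_auc, "aupr": fold_aupr, "n_test": len(test)})
    return EvalReport(
        protocol=f"cv{k}" + (f"x{rounds}" if rounds > 1 else ""),
        fold_metrics=fold_metrics,
        seeds={"split_seed": seed, "opt_seed": opt_cfg.seed},
        config={"k": k, "rounds": rounds},
    )


def loocv_top1(
    data: InteractionDataset,
    M: SimilarityMatrix,
    N: SimilarityMatrix,
    model_cfg: ModelConfig = ModelConfig(),
    opt_cfg: OptimizerConfig = OptimizerConfig(),
    reweight_cfg: ReweightConfig = ReweightConfig(),
    cold_cfg: ColdStartConfig = ColdStartConfig(),
    mode: str = "full",
    drugs: Optional[Sequence[int]] = None,
) -> EvalReport:
    """Leave-one-drug-out Top-1 retrieval.

    For each drug with at least one known interaction: hide its column,
    obtain its latent row (``mode="full"`` retrains the whole model, the
    reference semantics; ``mode="fast"`` freezes F, G from one fit on the
    full data and only recomputes the drug's cold-start row — cheaper but
    its trained row saw the hidden column, so use fast mode only with v=0),
    rank all targets, and count a hit when the top-ranked target (worst-rank
    tie convention: it must be the strict maximum) is a hidden true target.
    Reported as a percentage of evaluated drugs.
    """
    if mode not in ("full", "fast"):
        raise ValueError(f"unknown mode {mode!r}")
    eligible = [j for j in range(data.n_chemicals) if data.R[:, j].sum() >= 1]
    if drugs is not None:
        eligible = [j for j in eligible if j in set(drugs)]
    base_fit = None
    if mode == "fast":
        base_fit = fit_cosine(data, M, N, model_cfg, opt_cfg, reweight_cfg)
    fold_metrics = []
    for j in eligible:
        masked = mask_chemicals(data, [j])
        if mode == "full":
            fit = fit_cosine(masked, M, N, model_cfg, opt_cfg, reweight_cfg)
            model = fit.model
        else:
            model = base_fit.model
        model = apply_cold_start(model, masked, M, N, cold_cfg, new_chemicals=[j])
        column = predict_probability(model)[:, j]
        ranks = worst_ranks(column)
        true_targets = np.flatnonzero(data.R[:, j] == 1)
        hit = bool((ranks[true_targets] == 1).any())
        fold_metrics.append({"fold": int(j), "top1": float(hit)})
    report = EvalReport(
        protocol="loocv_top1",
        fold_metrics=fold_metrics,
        seeds={"opt_seed": opt_cfg.seed},
        config={"mode": mode, "J": cold_cfg.J, "v": cold_cfg.v},
    )
    return report


LT_BINS = [(1, 5, "1-5"), (6, 10, "6-10"), (11, 15, "11-15"), (16, 20, "16-20"), (21, None, ">20")]


def lt_bin_label(count: int) -> str:
    """Ligands-per-target bin; counts below 1 fall in the lowest bin."""
    for lo, hi, label in LT_BINS:
        if hi is None or count <= hi:
            return label
    raise AssertionError("unreachable")


def mcs_bin_label(sim: float) -> str:
    """Max-chemical-similarity bin of width 0.1; 1.0 joins the top bin."""
    idx = min(int(sim / 0.1), 9)
    return f"{idx / 10:.1f}-{(idx + 1) / 10:.1f}"


@dataclass
class Stratum:
    kind: str  # "ligands_per_target" or "max_chemical_similarity"
    label: str
    chemicals: list[int]
    test_half: list[int]
    train_half: list[int]


def coldstart_stratify(fixture: ColdStartFixture, seed: int = 0) -> list[Stratum]:
    """Assign each single-target cold-start chemical to one bin per criterion
    and halve each stratum into test/train subsets."""
    rng = np.random.default_rng(seed)
    strata: list[Stratum] = []
    groups: dict[tuple[str, str], list[int]] = {}
    for j in fixture.cold_chemicals:
        groups.setdefault(
            ("ligands_per_target", lt_bin_label(fixture.ligands_per_target[j])), []
        ).append(j)
        groups.setdefault(
            ("max_chemical_similarity", mcs_bin_label(fixture.max_chemical_similarity[j])), []
        ).append(j)
    for (kind, label), chems in sorted(groups.items()):
        perm = rng.permutation(len(chems))
        half = (len(chems) + 1) // 2
        test = sorted(chems[i] for i in perm[:half])
        train = sorted(chems[i] for i in perm[half:])
        strata.append(Stratum(kind, label, sorted(chems), test, train))
    return strata


def coldstart_tpr(
    fixture: ColdStartFixture,
    r_percents: Sequence[float] = (1.0, 5.0, 10.0),
    model_cfg: ModelConfig = ModelConfig(),
    opt_cfg: OptimizerConfig = OptimizerConfig(),
    reweight_cfg: ReweightConfig = ReweightConfig(),
    cold_cfg: ColdStartConfig = ColdStartConfig(),
    stratify_seed: int = 0,
) -> EvalReport:
    """Cold-start evaluation: fit on the fixture (cold columns zeroed), apply
    the weighted profile to cold chemicals, and report mean TPR@r% per stratum."""
    fit = fit_cosine(fixture.data, fixture.M, fixture.N, model_cfg, opt_cfg, reweight_cfg)
    model = apply_cold_start(
        fit.model, fixture.data, fixture.M, fixture.N, cold_cfg,
        new_chemicals=fixture.cold_chemicals,
    )
    P = predict_probability(model)
    tpr_by_chem = {
        j: {r: tpr_at_top_percent(P[:, j], [fixture.hidden_targets[j]], r) for r in r_percents}
        for j in fixture.cold_chemicals
    }
    fold_metrics = []
    for stratum in coldstart_stratify(fixture, stratify_seed):
        for r in r_percents:
            chems = stratum.test_half
            if not chems:
                continue
            fold_metrics.append(
                {
                    "fold": f"{stratum.kind}:{stratum.label}:r={r}",
                    "kind": stratum.kind,
                    "label": stratum.label,
                    "r_percent": r,
                    "tpr": float(np.mean([tpr_by_chem[j][r] for j in chems])),
                    "n_chemicals": len(chems),
                }
            )
    return EvalReport(
        protocol="coldstart_tpr",
        fold_metrics=fold_metrics,
        seeds={"opt_seed": opt_cfg.seed, "stratify_seed": stratify_seed},
        config={"r_percents": list(r_percents), "J": cold_cfg.J, "v": cold_cfg.v},
    )
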