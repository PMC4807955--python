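"""Exhaustive-search oracle, confusion/power metrics, and replicate harness.

The exhaustive scan scores every one of the C(N,2) pairs under both criteria
and serves as the ground-truth ranking against which the harmony search is
validated.  The replicate harness reruns the full two-stage pipeline on many
simulated datasets with known causal pairs and aggregates:

* screening power  — fraction of datasets whose true pair entered the
  candidate set (HM1 ∪ HM2);
* testing power    — fraction whose true pair additionally passed the
  Bonferroni-corrected G-test;
* TP/FP/TN/FN      — counted over the *screened* candidates relative to the
  known truth (a statistical-precision measure of the testing stage, not a
  genome-wide per-pair matrix): TP = true pairs passing the test, FN = true
  pairs screened but rejected, FP/TN the same for non-causal screened pairs;
* mean model evaluations (MEs) consumed per dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import GenotypeDataset
from .gtest import DEFAULT_EPSILON, SignificancePolicy, gtest_pairs
from .scoring import gini_from_counts, k2_neglog_from_counts
from .search import SearchConfig, fhsa_run
from .simulate import PenetranceModel, simulate_dataset

__all__ = [
    "ExhaustiveResult",
    "MetricsReport",
    "exhaustive_search",
    "confusion_metrics",
    "run_power_experiment",
]


@dataclass
class ExhaustiveResult:
    """Both scores for every pair, with per-criterion rankings."""

    pairs: list[tuple[int, int]]
    k2_neglog: np.ndarray
    gini: np.ndarray

    @property
    def n_evaluations(self) -> int:
        return len(self.pairs)

    @property
    def best_k2_pair(self) -> tuple[int, int]:
        return self.pairs[int(np.argmin(self.k2_neglog))]

    @property
    def best_gini_pair(self) -> tuple[int, int]:
        return self.pairs[int(np.argmin(self.gini))]

    def ranking(self, criterion: str) -> list[tuple[int, int]]:
        """All pairs sorted best-first under one criterion."""
        scores = {"k2": self.k2_neglog, "gini": self.gini}[criterion]
        return [self.pairs[i] for i in np.argsort(scores, kind="stable")]


def exhaustive_search(ds: GenotypeDataset) -> ExhaustiveResult:
    """Score all C(N,2) pairs under both criteria (the brute-force oracle)."""
    n = ds.n_snps
    if n < 2:
        raise ValueError("need at least two SNPs")
    geno = ds.genotypes.astype(np.int64)
    pheno = ds.phenotype.astype(np.int64)
    pairs = [(a, b) for a in range(n - 1) for b in range(a + 1, n)]
    counts = np.empty((len(pairs), 9, 2), dtype=np.int64)
    for idx, (a, b) in enumerate(pairs):
        combo = 3 * geno[:, a] + geno[:, b]
        counts[idx] = np.bincount(combo * 2 + pheno, minlength=18).reshape(9, 2)
    return ExhaustiveResult(
        pairs=pairs,
        k2_neglog=k2_neglog_from_counts(counts),
        gini=gini_from_counts(counts),
    )


def confusion_metrics(tp: int, fp: int, tn: int, fn: int) -> dict[str, float | None]:
    """Sensitivity, specificity, precision and accuracy from a 2x2 confusion.

    ``tpr = TP/(TP+FN)``, ``spc = TN/(FP+TN)``, ``ppv = TP/(TP+FP)``,
    ``acc = (TP+TN)/(TP+TN+FN+FP)``.  A ratio with a zero denominator is
    ``None`` (undefined), never silently 0.
    """
    for name, v in (("tp", tp), ("fp", fp), ("tn", tn), ("fn", fn)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0, got {v}")

    def ratio(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    return {
        "tpr": ratio(tp, tp + fn),
        "spc": ratio(tn, fp + tn),
        "ppv": ratio(tp, tp + fp),
        "acc": ratio(tp + tn, tp + tn + fn + fp),
    }


@dataclass
class MetricsReport:
    """Aggregate outcome of a replicate power experiment."""

    tp: int
    fp: int
    tn: int
    fn: int
    tpr: float | None
    spc: float | None
    ppv: float | None
    acc: float | None
    power_screen: float
    power_test: float
    mean_mes: float
    n_datasets: int
    replicate_seeds: list[int] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "tpr": self.tpr,
            "spc": self.spc,
            "ppv": self.ppv,
            "acc": self.acc,
            "power_screen": self.power_screen,
            "power_test": self.power_test,
            "mean_mes": self.mean_mes,
            "n_datasets": self.n_datasets,
            "replicate_seeds": self.replicate_seeds,
        }


def replicate_seeds(master_seed: int, n: int) -> list[int]:
    """Per-replicate seeds derived deterministically from a master seed.

    Each is below 2**31 and recorded in the report so any single replicate
    can be rerun in isolation.
    """
    ss = np.random.SeedSequence(master_seed)
    return [int(s) for s in ss.generate_state(n) % (2**31)]


def run_power_experiment(
    model: PenetranceModel,
    n_datasets: int,
    cfg: SearchConfig,
    seed: int,
    n_cases: int = 400,
    n_controls: int = 400,
    n_snps: int = 100,
    epsilon: int = DEFAULT_EPSILON,
    early_stop: bool = True,
) -> MetricsReport:
    """Replicate the simulation-study protocol at a configurable scale.

    Simulates ``n_datasets`` datasets from ``model`` (distinct derived
    seeds), runs screening then testing on each, and aggregates the
    confusion counts, both powers, and the mean evaluation count.
    ``early_stop`` terminates each screening run once the known causal pair
    is in memory, the convention used when collecting evaluation-count
    statistics against a known truth.
    """
    if n_datasets < 1:
        raise ValueError("need at least one dataset")
    seeds = replicate_seeds(seed, 2 * n_datasets)
    policy = SignificancePolicy(alpha0=cfg.alpha0, n_snps=n_snps, k=2)

    tp = fp = tn = fn = 0
    screen_hits = 0
    test_hits = 0
    mes_values = []
    for t in range(n_datasets):
        ds, truth = simulate_dataset(
            model, n_cases, n_controls, n_snps, seed=seeds[2 * t]
        )
        result = fhsa_run(
            ds,
            cfg.with_seed(seeds[2 * t + 1]),
            truth_pair=truth,
            early_stop=early_stop,
        )
        mes_values.append(result.mes)
        candidates = result.candidate_pairs()
        screened_truth = truth in candidates
        screen_hits += screened_truth
        for pair, res in gtest_pairs(ds, candidates, epsilon):
            passed = res.p_value < policy.alpha
            if pair == truth:
                if passed:
                    tp += 1
                    test_hits += 1
                else:
                    fn += 1
            else:
                if passed:
                    fp += 1
                else:
                    tn += 1

    ratios = confusion_metrics(tp, fp, tn, fn)
    return MetricsReport(
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        tpr=ratios["tpr"],
        spc=ratios["spc"],
        ppv=ratios["ppv"],
        acc=ratios["acc"],
        power_screen=screen_hits / n_datasets,
        power_test=test_hits / n_datasets,
        mean_mes=float(np.mean(mes_values)),
        n_datasets=n_datasets,
        replicate_seeds=seeds,
    )
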