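"""Resampling test of signature generality, with a permuted-label null.

Each repetition draws a training set of whole case pairs, re-selects a
signature by paired t-test on the training samples only, then clusters the
held-out samples on that signature and counts how many land in a cluster
dominated by the opposite tissue class.  Selection happens strictly inside
the resampling loop, so the held-out error is an honest estimate of how the
signature generalizes.  Re-running with class labels randomly permuted
(swapping normal/malignant within random cases, which keeps the paired test
well defined) provides the chance baseline.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cluster import average_linkage, cut_tree, distance_matrix, score_assignment
from .de import Signature, paired_t, select_signature
from .io import complete_pairs

__all__ = [
    "CVConfig",
    "RepeatResult",
    "CVReport",
    "run_cv",
    "run_permutation_null",
    "summarize_misclassification",
    "selection_frequency",
]


@dataclass(frozen=True)
class CVConfig:
    """Settings for the cross-validation generalization test."""

    n_repeats: int = 15
    n_train_pairs: int = 14
    alpha: float = 1e-4
    k_clusters: int = 3
    seed: int = 0
    permute_labels: bool = False
    permutation_scheme: str = "within_case"  # or "free"

    def validate(self, n_pairs: int) -> None:
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if not 1 <= self.n_train_pairs < n_pairs:
            raise ValueError(
                f"n_train_pairs must be in [1, {n_pairs - 1}] for {n_pairs} pairs"
            )
        if self.permutation_scheme not in ("within_case", "free"):
            raise ValueError("permutation_scheme must be 'within_case' or 'free'")


@dataclass
class RepeatResult:
    index: int
    seed: int
    train_cases: list[str]
    held_out: list[str]
    signature: Signature
    misplaced: int | None
    failed: bool = False
    reason: str = ""


@dataclass
class CVReport:
    config: CVConfig
    repeats: list[RepeatResult] = field(default_factory=list)
    held_out_size: int = 0

    @property
    def successful(self) -> list[RepeatResult]:
        return [r for r in self.repeats if not r.failed]

    @property
    def misplaced_counts(self) -> list[int]:
        return [r.misplaced for r in self.successful]

    def histogram(self) -> dict[int, int]:
        return dict(sorted(Counter(self.misplaced_counts).items()))

    def average_error_rate(self) -> float:
        """Mean held-out error over successful repeats, as a percentage."""
        counts = self.misplaced_counts
        if not counts:
            return float("nan")
        return 100.0 * sum(counts) / (len(counts) * self.held_out_size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "repeat": [r.index for r in self.repeats],
                "n_selected": [len(r.signature) for r in self.repeats],
                "misplaced": [r.misplaced for r in self.repeats],
                "failed": [r.failed for r in self.repeats],
                "reason": [r.reason for r in self.repeats],
                "held_out": [";".join(r.held_out) for r in self.repeats],
            }
        ).set_index("repeat")


def _permute_annotation(a: pd.DataFrame, rng: np.random.Generator, scheme: str) -> pd.DataFrame:
    out = a.copy()
    if scheme == "within_case":
        for case, grp in a.groupby("case_id", sort=False):
            if rng.random() < 0.5:
                out.loc[grp.index, "tissue_class"] = (
                    grp["tissue_class"].map({"normal": "malignant", "malignant": "normal"}).values
                )
    else:  # free: unrestricted shuffle of labels over samples
        labels = a["tissue_class"].to_numpy().copy()
        rng.shuffle(labels)
        out["tissue_class"] = labels
    return out


def run_cv(m: pd.DataFrame, a: pd.DataFrame, cfg: CVConfig) -> CVReport:
    """Run the repeated select-then-cluster generalization test.

    Per repeat: (1) sample ``n_train_pairs`` case IDs without replacement;
    (2) paired t-test on the training samples; (3) signature at
    ``cfg.alpha``; (4) UPGMA clustering of only the held-out samples on the
    signature, cut at ``k_clusters``; (5) majority-vote scoring.  A repeat
    whose signature is empty is recorded as failed and excluded from the
    average.  Everything is driven by per-repeat seeds spawned from
    ``cfg.seed`` so any repeat is reproducible in isolation.
    """
    pairs = complete_pairs(a)
    cfg.validate(len(pairs))
    rng = np.random.default_rng(cfg.seed)
    repeat_seeds = rng.integers(0, 2**31 - 1, size=cfg.n_repeats)
    held_out_size = 2 * (len(pairs) - cfg.n_train_pairs)
    report = CVReport(cfg, held_out_size=held_out_size)

    case_ids = [c for c, _, _ in pairs]
    by_case = {c: (n, t) for c, n, t in pairs}

    for r in range(cfg.n_repeats):
        rep_rng = np.random.default_rng(int(repeat_seeds[r]))
        annot = a
        if cfg.permute_labels:
            annot = _permute_annotation(a, rep_rng, cfg.permutation_scheme)
        train_cases = sorted(
            rep_rng.choice(case_ids, size=cfg.n_train_pairs, replace=False).tolist()
        )
        test_cases = [c for c in case_ids if c not in train_cases]
        train_samples = [s for c in train_cases for s in by_case[c]]
        test_samples = [s for c in test_cases for s in by_case[c]]

        de = paired_t(m[train_samples], annot.loc[train_samples])
        sig = select_signature(de, cfg.alpha)
        if len(sig) == 0:
            report.repeats.append(
                RepeatResult(r, int(repeat_seeds[r]), train_cases, test_samples, sig,
                             None, failed=True, reason="empty signature")
            )
            continue
        try:
            d = distance_matrix(m[test_samples], sig.feature_ids)
        except ValueError as exc:  # tiny signature + missing wells: unusable
            report.repeats.append(
                RepeatResult(r, int(repeat_seeds[r]), train_cases, test_samples, sig,
                             None, failed=True, reason=f"unusable signature: {exc}")
            )
            continue
        tree = average_linkage(d)
        assign = cut_tree(tree, min(cfg.k_clusters, len(test_samples)))
        misplaced, _, _ = score_assignment(assign, annot)
        report.repeats.append(
            RepeatResult(r, int(repeat_seeds[r]), train_cases, test_samples, sig, misplaced)
        )
    return report


def run_permutation_null(m: pd.DataFrame, a: pd.DataFrame, cfg: CVConfig) -> CVReport:
    """The same procedure with tissue-class labels permuted before each repeat."""
    return run_cv(m, a, replace(cfg, permute_labels=True))


def summarize_misclassification(
    counts, held_out_size: int
) -> tuple[dict[int, int], float]:
    """Histogram and average error rate (%) of per-repeat misplaced counts.

    The average error rate is ``mean(count / held_out_size)`` expressed as a
    percentage; e.g. fifteen 10-sample repetitions with misplaced counts
    0,0,0,0,1,1,1,1,2,2,2,3,3,3,4 give 23/150 = 15.33%.
    """
    counts = list(counts)
    for c in counts:
        if not 0 <= c <= held_out_size:
            raise ValueError(f"misplaced count {c} outside [0, {held_out_size}]")
    hist = dict(sorted(Counter(counts).items()))
    rate = 100.0 * sum(counts) / (len(counts) * held_out_size) if counts else float("nan")
    return hist, rate


def selection_frequency(report: CVReport) -> pd.DataFrame:
    """How often each feature entered the per-repeat signatures.

    Counts are over all repeats (an empty signature contributes nothing);
    frequency = count / n_repeats.
    """
    if not report.successful:
        raise ValueError("no successful repeats in report")
    counter: Counter[str] = Counter()
    for r in report.repeats:
        counter.update(r.signature.feature_ids)
    n = len(report.repeats)
    rows = sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(
        {
            "feature_id": [f for f, _ in rows],
            "n_selected": [c for _, c in rows],
            "frequency": [c / n for _, c in rows],
        }
    ).set_index("feature_id")
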