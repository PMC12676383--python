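"""Session-wise cross-validation and the method-comparison statistics.

Evaluation is leave-one-session-out: each recording session serves once as
the test fold while the remaining sessions train the model, which measures
cross-session generalization rather than within-session fit.  Accuracies
are percentages of correctly labeled test trials; per-subject summaries
are the unweighted mean ± SD over folds.

Method comparison follows the non-parametric battery standard for
classifier benchmarks: a Friedman test on the subjects x methods accuracy
table (mid-ranks with tie correction), Kendall's coefficient of
concordance W = chi2 / (n (k - 1)) as the effect size, and post-hoc
pairwise Wilcoxon signed-rank tests at a Bonferroni-adjusted alpha of
family_alpha / C(k, 2).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .synth import EpochSet

__all__ = [
    "CVReport",
    "MethodComparison",
    "session_cv",
    "friedman_test",
    "pairwise_wilcoxon",
    "accuracy_table",
]


@dataclass
class CVReport:
    """Per-fold accuracies (%) of one method on one subject's sessions."""

    method: str
    subject: int
    fold_sessions: list[int]
    fold_accuracy: list[float]

    @property
    def mean(self) -> float:
        return float(np.mean(self.fold_accuracy))

    @property
    def sd(self) -> float:
        return float(np.std(self.fold_accuracy, ddof=0))

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "subject": self.subject,
            "fold_sessions": self.fold_sessions,
            "fold_accuracy": self.fold_accuracy,
            "mean": self.mean,
            "sd": self.sd,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


@dataclass
class MethodComparison:
    """Friedman + Kendall W + pairwise Wilcoxon over a subjects x methods table."""

    methods: list[str]
    chi2: float
    df: int
    p_value: float
    kendall_w: float
    average_ranks: dict[str, float]
    pairwise_p: dict[str, float | None]
    degenerate_pairs: list[str]
    adjusted_alpha: float
    significant: dict[str, bool]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1, default=str))


def session_cv(
    dataset: EpochSet,
    pipeline_factory: Callable[[], object],
    method: str = "method",
    subject: int = 1,
) -> CVReport:
    """Leave-one-session-out CV.

    ``pipeline_factory`` returns a fresh object with ``fit(train: EpochSet)``
    and ``predict(test: EpochSet) -> labels`` for each fold, so no state
    leaks between folds.  A session missing some class triggers a warning
    but the fold still runs.
    """
    sessions = np.unique(dataset.session_id)
    if sessions.size < 2:
        raise ValueError("need >= 2 sessions for session-wise CV")
    all_classes = np.unique(dataset.labels)
    fold_acc, fold_sessions = [], []
    for s in sessions:
        test_mask = dataset.session_id == s
        train, test = dataset.select(~test_mask), dataset.select(test_mask)
        if np.unique(train.labels).size < all_classes.size:
            warnings.warn(f"training folds for session {s} miss some class")
        pipe = pipeline_factory()
        pipe.fit(train)
        pred = np.asarray(pipe.predict(test))
        fold_acc.append(100.0 * float(np.mean(pred == test.labels)))
        fold_sessions.append(int(s))
    return CVReport(
        method=method, subject=subject,
        fold_sessions=fold_sessions, fold_accuracy=fold_acc,
    )


def _mid_ranks(row: np.ndarray) -> np.ndarray:
    return stats.rankdata(row, method="average")


def friedman_test(
    acc: np.ndarray, methods: Sequence[str] | None = None
) -> tuple[float, int, float, np.ndarray, float]:
    """Friedman test with mid-ranks and tie correction; returns Kendall W.

    ``acc`` is a subjects x methods table.  Returns
    (chi2, df, p, average ranks, W) with W = chi2 / (n (k - 1)).
    """
    acc = np.asarray(acc, dtype=np.float64)
    n, k = acc.shape
    if n < 2 or k < 2:
        raise ValueError("need >= 2 subjects and >= 2 methods")
    ranks = np.apply_along_axis(_mid_ranks, 1, acc)
    if np.allclose(ranks.var(axis=1), 0):
        raise ValueError("all methods tie within every subject; W undefined")
    Rj = ranks.sum(axis=0)
    # tie correction: sum over rows of sum(t^3 - t) for each tie group
    T = 0.0
    for row in acc:
        _, counts = np.unique(row, return_counts=True)
        T += float(np.sum(counts**3 - counts))
    denom = n**2 * k * (k**2 - 1) - n * T
    W = (12.0 * np.sum(Rj**2) - 3.0 * n**2 * k * (k + 1) ** 2) / denom
    chi2 = n * (k - 1) * W
    df = k - 1
    p = float(stats.chi2.sf(chi2, df))
    avg_ranks = Rj / n
    return float(chi2), df, p, avg_ranks, float(W)


def pairwise_wilcoxon(
    acc: np.ndarray,
    methods: Sequence[str] | None = None,
    family_alpha: float = 0.05,
) -> MethodComparison:
    """Friedman + post-hoc pairwise Wilcoxon with Bonferroni correction.

    The signed-rank test drops zero differences (Wilcoxon convention) and
    uses the exact null distribution for n <= 25, the normal approximation
    beyond.  Pairs whose accuracies are identical for every subject carry
    no information and are flagged degenerate instead of given a p-value.
    """
    acc = np.asarray(acc, dtype=np.float64)
    n, k = acc.shape
    if methods is None:
        methods = [f"method_{i}" for i in range(k)]
    chi2, df, p, avg_ranks, W = friedman_test(acc)
    n_pairs = k * (k - 1) // 2
    adj_alpha = family_alpha / n_pairs
    pairwise_p: dict[str, float | None] = {}
    degenerate: list[str] = []
    significant: dict[str, bool] = {}
    for i, j in combinations(range(k), 2):
        key = f"{methods[i]} vs {methods[j]}"
        diff = acc[:, i] - acc[:, j]
        if np.all(diff == 0):
            pairwise_p[key] = None
            degenerate.append(key)
            continue
        nz = diff[diff != 0]
        mode = "exact" if nz.size <= 25 else "approx"
        res = stats.wilcoxon(acc[:, i], acc[:, j], zero_method="wilcox", mode=mode)
        pairwise_p[key] = float(res.pvalue)
        significant[key] = bool(res.pvalue < adj_alpha)
    return MethodComparison(
        methods=list(methods),
        chi2=chi2, df=df, p_value=p, kendall_w=W,
        average_ranks={m: float(r) for m, r in zip(methods, avg_ranks)},
        pairwise_p=pairwise_p,
        degenerate_pairs=degenerate,
        adjusted_alpha=adj_alpha,
        significant=significant,
    )


def accuracy_table(reports: Sequence[CVReport]) -> pd.DataFrame:
    """Subjects x methods table of "mean ± SD" strings with summary rows."""
    methods = sorted({r.method for r in reports})
    subjects = sorted({r.subject for r in reports})
    cells: dict[str, dict[int, str]] = {m: {} for m in methods}
    means: dict[str, dict[int, float]] = {m: {} for m in methods}
    for r in reports:
        cells[r.method][r.subject] = f"{r.mean:.2f} ± {r.sd:.2f}"
        means[r.method][r.subject] = r.mean
    rows = []
    for s in subjects:
        rows.append({"subject": str(s), **{
            m: cells[m].get(s, "") for m in methods
        }})
    mean_row: dict[str, str] = {"subject": "Mean"}
    sd_row: dict[str, str] = {"subject": "SD"}
    for m in methods:
        vals = [means[m][s] for s in subjects if s in means[m]]
        if vals:
            mean_row[m] = f"{np.mean(vals):.2f}"
            sd_row[m] = f"{np.std(vals, ddof=0):.2f}"
        else:
            mean_row[m] = ""
            sd_row[m] = ""
    rows.extend([mean_row, sd_row])
    return pd.DataFrame(rows).set_index("subject")
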