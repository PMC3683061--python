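"""Subject matching, balanced cross-validation protocol and ROC metrics.

The screening task is heavily imbalanced (disease prevalence of a few
percent), so the evaluation protocol trains on balanced subsets: in each
of ``n_tests`` independent tests the cohort is split into stratified
halves A and B; round 1 trains on all A-positives plus an equal-size
random draw of A-negatives and scores ALL of B, round 2 swaps the halves.
Every method (modality subset) in a given (test, round) sees the identical
split and negative draw, making paired method comparisons valid.  With the
default 10 tests this yields 20 result groups per method.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    EmptyIntersectionError,
    ProtocolError,
    SingleClassError,
)
from .mkl import decision_function, linear_gram, train_mkl, train_svm
from .types import CohortBundle, FeatureView, as_labels

__all__ = [
    "MethodSpec",
    "all_methods",
    "EvalResult",
    "match_subjects",
    "run_protocol",
    "roc_and_auc",
    "sensitivity_at_specificity",
    "balanced_accuracy",
    "compare_methods",
    "paired_auc_test",
]

log = logging.getLogger(__name__)

MODALITY_ORDER = ("D", "G", "I")


@dataclass(frozen=True)
class MethodSpec:
    """A non-empty modality subset defining one method of the comparison."""

    modalities: tuple

    def __post_init__(self):
        mods = tuple(m for m in MODALITY_ORDER if m in self.modalities)
        if not mods or set(mods) != set(self.modalities):
            raise ValueError(f"bad modality subset: {self.modalities}")
        object.__setattr__(self, "modalities", mods)

    @property
    def key(self) -> str:
        return "+".join(self.modalities)

    @property
    def combination_type(self) -> str:
        return {1: "Single", 2: "Two", 3: "Multiple"}[len(self.modalities)]


def all_methods(available=MODALITY_ORDER) -> list:
    """The 7 modality subsets: D, G, I, D+G, D+I, G+I, D+G+I."""
    out = []
    for size in (1, 2, 3):
        for combo in combinations([m for m in MODALITY_ORDER if m in available], size):
            out.append(MethodSpec(combo))
    return out


def match_subjects(labels: pd.Series, views: dict, provenance=None) -> CohortBundle:
    """Merge modality views by subject id.

    ``labels`` is a +1/-1 series indexed by subject id; ``views`` maps
    modality tags to :class:`FeatureView` objects.  The bundle keeps the
    intersection of subject ids across all provided sources, in sorted-id
    order.
    """
    common = set(labels.index)
    log.info("subject matching: labels %d", len(common))
    for tag, view in views.items():
        log.info("subject matching: view %s %d", tag, view.n_subjects)
        common &= set(view.subject_ids)
    if not common:
        raise EmptyIntersectionError("no subject appears in every source")
    ids = sorted(common)
    log.info("subject matching: intersection %d", len(ids))
    matched = {}
    for tag, view in views.items():
        pos = {s: i for i, s in enumerate(view.subject_ids)}
        matched[tag] = view.subset([pos[s] for s in ids])
    return CohortBundle(
        subject_ids=ids,
        labels=labels.loc[ids].to_numpy(),
        views=matched,
        provenance=provenance or {},
    )


@dataclass
class EvalResult:
    """Per-(test, round, method) ROC results plus protocol provenance."""

    records: list = field(default_factory=list)
    methods: list = field(default_factory=list)
    n_tests: int = 0
    seed: int = 0
    setpoint: float = 0.85

    def frame(self) -> pd.DataFrame:
        """Scalar columns of the records as a DataFrame."""
        cols = ["test", "round", "method", "auc", "sensitivity",
                "n_train", "n_test"]
        return pd.DataFrame([{k: r[k] for k in cols} for r in self.records])

    def aucs(self, method_key: str) -> np.ndarray:
        """The matched AUC values of one method, ordered by (test, round)."""
        rows = sorted(
            (r for r in self.records if r["method"] == method_key),
            key=lambda r: (r["test"], r["round"]),
        )
        return np.array([r["auc"] for r in rows])


def _stratified_halves(y: np.ndarray, rng) -> tuple[np.ndarray, np.ndarray]:
    """Random disjoint halves preserving class proportions; when a class
    has an odd count the extra subject goes to half A."""
    a_parts, b_parts = [], []
    for cls in (1, -1):
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        n_a = (len(idx) + 1) // 2
        a_parts.append(idx[:n_a])
        b_parts.append(idx[n_a:])
    return np.sort(np.concatenate(a_parts)), np.sort(np.concatenate(b_parts))


def run_protocol(
    bundle: CohortBundle,
    methods: list | None = None,
    n_tests: int = 10,
    seed: int = 0,
    C: float = 1.0,
    setpoint: float = 0.85,
) -> EvalResult:
    """Run the balanced stratified cross-validation comparison.

    Returns 2 * ``n_tests`` result groups per method.  RNG streams for the
    half-split and each round's negative draw are derived from ``seed``
    with fixed offsets, so adding or removing methods never perturbs the
    splits.
    """
    if methods is None:
        methods = all_methods(sorted(bundle.views))
    y = bundle.labels
    for spec in methods:
        for tag in spec.modalities:
            if tag not in bundle.views:
                raise ProtocolError(f"method {spec.key} needs missing view {tag!r}")

    result = EvalResult(
        methods=[m.key for m in methods],
        n_tests=n_tests,
        seed=seed,
        setpoint=setpoint,
    )
    for t in range(n_tests):
        split_rng = np.random.default_rng([seed, 1000 + t])
        half_a, half_b = _stratified_halves(y, split_rng)
        for r, (train_half, test_half) in enumerate(
            [(half_a, half_b), (half_b, half_a)]
        ):
            pos = train_half[y[train_half] == 1]
            neg = train_half[y[train_half] == -1]
            if len(pos) < 1 or int(np.sum(y[test_half] == 1)) < 1:
                raise ProtocolError(f"test {t}: a half has no positive subject")
            if len(neg) < len(pos):
                raise ProtocolError(f"test {t}: fewer negatives than positives")
            neg_rng = np.random.default_rng([seed, 1000 + t, r])
            drawn = np.sort(neg_rng.choice(neg, size=len(pos), replace=False))
            train_idx = np.concatenate([pos, drawn])
            y_train, y_test = y[train_idx], y[test_half]

            # per-modality scaling fitted on this balanced training set
            scaled = {}
            for tag, view in bundle.views.items():
                view.fit_scaling(train_idx)
                tr = FeatureView(tag, [bundle.subject_ids[i] for i in train_idx],
                                 view.scaled(train_idx))
                te = FeatureView(tag, [bundle.subject_ids[i] for i in test_half],
                                 view.scaled(test_half))
                scaled[tag] = (tr, te)

            train_ids = tuple(bundle.subject_ids[i] for i in train_idx)
            for spec in methods:
                trains = [scaled[m][0] for m in spec.modalities]
                tests = [scaled[m][1] for m in spec.modalities]
                if len(spec.modalities) == 1:
                    model = train_svm(linear_gram(trains[0]), y_train, C=C)
                    scores = model.decision_values(
                        tests[0].matrix @ trains[0].matrix.T
                    )
                    weights = [1.0]
                else:
                    mkl = train_mkl(trains, y_train, C=C)
                    scores = decision_function(mkl, trains, tests)
                    weights = mkl.kernel_weights.tolist()
                roc, auc = roc_and_auc(scores, y_test)
                result.records.append(
                    {
                        "test": t,
                        "round": r,
                        "method": spec.key,
                        "auc": auc,
                        "sensitivity": sensitivity_at_specificity(roc, setpoint),
                        "n_train": len(train_idx),
                        "n_test": len(test_half),
                        "kernel_weights": weights,
                        "roc": roc,
                        "train_ids": train_ids,
                    }
                )
    return result


def roc_and_auc(scores, labels) -> tuple[np.ndarray, float]:
    """ROC vertices and trapezoidal AUC.

    Thresholds sweep the sorted unique scores (scores >= threshold predict
    positive) with a (0, 0) sentinel; the trapezoidal area equals the
    tie-corrected Mann-Whitney statistic.  Returns (vertices, auc) where
    vertices has columns (fpr, tpr).
    """
    scores = np.asarray(scores, dtype=float)
    y = as_labels(labels)
    order = np.argsort(-scores, kind="mergesort")
    y_sorted = y[order]
    s_sorted = scores[order]
    tps = np.cumsum(y_sorted == 1)
    fps = np.cumsum(y_sorted == -1)
    # keep the last index of every tie group
    last = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    tps, fps = tps[last], fps[last]
    P, N = tps[-1], fps[-1]
    tpr = np.r_[0.0, tps / P]
    fpr = np.r_[0.0, fps / N]
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


def sensitivity_at_specificity(roc: np.ndarray, setpoint: float = 0.85) -> float:
    """Sensitivity of the ROC at a fixed specificity.

    Linear interpolation between the two vertices bracketing
    ``specificity = setpoint``; if the setpoint is attained exactly, the
    best (highest-sensitivity) vertex there is returned.
    """
    fpr, tpr = roc[:, 0], roc[:, 1]
    spec = 1.0 - fpr  # decreasing along the curve
    exact = spec == setpoint
    if exact.any():
        return float(tpr[exact].max())
    k = int(np.searchsorted(-spec, -setpoint) )
    if k == 0:
        return float(tpr[0])
    x0, x1 = spec[k - 1], spec[k]
    y0, y1 = tpr[k - 1], tpr[k]
    return float(y0 + (y1 - y0) * (x0 - setpoint) / (x0 - x1))


def balanced_accuracy(tp: int, fp: int, tn: int, fn: int):
    """(sensitivity, specificity, balanced accuracy) from confusion counts."""
    if tp + fn < 1 or tn + fp < 1:
        raise SingleClassError("confusion counts lack a class")
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    return sens, spec, 0.5 * (sens + spec)


def paired_auc_test(result: EvalResult, method_a: str, method_b: str):
    """Paired t-test on the matched per-group AUCs of two methods."""
    a, b = result.aucs(method_a), result.aucs(method_b)
    if len(a) != len(b) or len(a) < 2:
        raise ProtocolError("methods lack matched result groups")
    d = a - b
    if np.allclose(d, 0.0):
        return 0.0, 1.0
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


def _check_provenance(result: EvalResult) -> None:
    by_group: dict = {}
    for r in result.records:
        key = (r["test"], r["round"])
        prev = by_group.setdefault(key, r["train_ids"])
        if prev != r["train_ids"]:
            raise ProtocolError(
                f"methods trained on different splits in group {key}"
            )


def compare_methods(result: EvalResult, alpha: float = 0.05):
    """Method comparison table plus paired significance tests.

    Returns ``(summary, pairs)``: a per-method table of mean sensitivity at
    the specificity setpoint and AUC mean/SD over the result groups, and a
    table of paired t-test p-values for every method pair, flagged at
    ``alpha``.  Raises if the methods were not evaluated on identical
    splits.
    """
    if len(result.methods) < 1:
        raise ProtocolError("empty result")
    _check_provenance(result)
    frame = result.frame()
    rows = []
    for key in result.methods:
        sub = frame[frame["method"] == key]
        rows.append(
            {
                "method": key,
                "combination_type": {1: "Single", 2: "Two"}.get(
                    len(key.split("+")), "Multiple"
                ),
                "sensitivity_at_setpoint": sub["sensitivity"].mean(),
                "auc_mean": sub["auc"].mean(),
                "auc_sd": sub["auc"].std(ddof=1),
                "n_groups": len(sub),
            }
        )
    summary = pd.DataFrame(rows)

    pair_rows = []
    for a, b in combinations(result.methods, 2):
        tstat, p = paired_auc_test(result, a, b)
        pair_rows.append(
            {
                "method_a": a,
                "method_b": b,
                "delta_auc": float(np.mean(result.aucs(a) - result.aucs(b))),
                "t_statistic": tstat,
                "p_value": p,
                "significant": p < alpha,
            }
        )
    return summary, pd.DataFrame(pair_rows)
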