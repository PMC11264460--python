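"""Agreement battery for predicted versus assessor-rated ordinal scores.

Implements the full evaluation used to judge a score-predicting model
against clinician ratings on the 0-4 ICF qualifiers scale:

* exact-match accuracy (percent) and mean square error;
* the tally of absolute score differences (the data behind difference
  histograms);
* quadratic weighted Cohen's kappa with a standard error (seeded bootstrap
  by default, the large-sample asymptotic formula on request);
* a one-sample t-test on prediction - reference differences (does the model
  over- or under-predict?) with Cohen's d;
* a one-way ANOVA comparing difference scores across model variants;
* binarisation to impaired (score >= 2) / unimpaired (score <= 1) and the
  contingency metrics recall, precision, accuracy and F1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

SCORE_CATEGORIES = tuple(range(5))
IMPAIRMENT_THRESHOLD = 2  # score >= 2 -> impaired


class AgreementError(ValueError):
    pass


def _pair(pred, ref) -> Tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred)
    ref = np.asarray(ref)
    if pred.shape != ref.shape or pred.ndim != 1:
        raise AgreementError(
            f"prediction and reference must be equal-length 1-D, got "
            f"{pred.shape} vs {ref.shape}")
    if pred.size == 0:
        raise AgreementError("empty score vectors")
    return pred, ref


def score_accuracy(pred: Sequence[int], ref: Sequence[int]) -> float:
    """Percent of exactly matching scores: 100 * (#equal) / n."""
    pred, ref = _pair(pred, ref)
    return 100.0 * float(np.mean(pred == ref))


def score_mse(pred: Sequence[int], ref: Sequence[int]) -> float:
    """Mean square error between predicted and observed scores."""
    pred, ref = _pair(pred, ref)
    return float(np.mean((np.asarray(ref, float) - np.asarray(pred, float)) ** 2))


def diff_tally(pred: Sequence[int], ref: Sequence[int]) -> Dict[int, int]:
    """Histogram of absolute score differences |pred - ref| over 0..4."""
    pred, ref = _pair(pred, ref)
    absdiff = np.abs(np.asarray(pred, int) - np.asarray(ref, int))
    return {d: int(np.sum(absdiff == d)) for d in range(5)}


def quadratic_weights(k: int) -> np.ndarray:
    """Agreement weight matrix w_ij = 1 - (i - j)^2 / (k - 1)^2."""
    i, j = np.meshgrid(np.arange(k), np.arange(k), indexing="ij")
    return 1.0 - (i - j) ** 2 / (k - 1) ** 2


def _confusion(r1: np.ndarray, r2: np.ndarray, k: int) -> np.ndarray:
    O = np.zeros((k, k))
    for a, b in zip(r1, r2):
        O[a, b] += 1
    return O


def _weighted_kappa_from_confusion(O: np.ndarray) -> float:
    k = O.shape[0]
    n = O.sum()
    w = quadratic_weights(k)
    po = (w * O).sum() / n
    p_row = O.sum(axis=1) / n
    p_col = O.sum(axis=0) / n
    pe = (w * np.outer(p_row, p_col)).sum()
    if pe == 1.0:
        return float("nan")
    return float((po - pe) / (1.0 - pe))


def _asymptotic_se(O: np.ndarray, kappa: float) -> float:
    # large-sample variance of weighted kappa (Fleiss, Cohen & Everitt form)
    k = O.shape[0]
    n = O.sum()
    w = quadratic_weights(k)
    P = O / n
    p_row = P.sum(axis=1)
    p_col = P.sum(axis=0)
    pe = (w * np.outer(p_row, p_col)).sum()
    wbar_row = w @ p_col          # \bar w_i.
    wbar_col = p_row @ w          # \bar w_.j
    term = (w - np.add.outer(wbar_row, wbar_col) * (1 - kappa)) ** 2
    var = ((P * term).sum() - (kappa - pe * (1 - kappa)) ** 2) / (n * (1 - pe) ** 2)
    return float(np.sqrt(max(var, 0.0)))


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    se: float
    n: int
    undefined: bool = False


def quadratic_weighted_kappa(
    r1: Sequence[int], r2: Sequence[int],
    categories: Sequence[int] = SCORE_CATEGORIES,
    se_method: str = "bootstrap",
    n_bootstrap: int = 2000,
    seed: int = 0,
) -> KappaResult:
    """Quadratic weighted Cohen's kappa between two raters.

    Uses agreement weights w_ij = 1 - (i - j)^2 / (k - 1)^2 over the full
    category grid (0..4 by default) so that categories unused by either
    rater still shape the weighting.  The standard error comes from a
    seeded nonparametric bootstrap over rated items (default 2000
    resamples) or, with ``se_method="asymptotic"``, the large-sample
    formula.  If both raters use a single category throughout, kappa is
    undefined and flagged.
    """
    r1, r2 = _pair(r1, r2)
    if r1.size < 2:
        raise AgreementError("kappa needs at least 2 rated items")
    cats = np.asarray(sorted(categories))
    k = len(cats)
    lut = {c: i for i, c in enumerate(cats.tolist())}
    for v in np.concatenate([r1, r2]):
        if int(v) not in lut:
            raise AgreementError(f"score {v} outside categories {cats.tolist()}")
    a = np.array([lut[int(v)] for v in r1])
    b = np.array([lut[int(v)] for v in r2])

    if len(np.unique(np.concatenate([a, b]))) < 2:
        return KappaResult(float("nan"), float("nan"), r1.size, undefined=True)

    O = _confusion(a, b, k)
    kappa = _weighted_kappa_from_confusion(O)
    if se_method == "asymptotic":
        se = _asymptotic_se(O, kappa)
    elif se_method == "bootstrap":
        rng = np.random.default_rng(seed)
        n = r1.size
        boots = []
        for _ in range(n_bootstrap):
            idx = rng.integers(0, n, n)
            kb = _weighted_kappa_from_confusion(_confusion(a[idx], b[idx], k))
            if np.isfinite(kb):
                boots.append(kb)
        se = float(np.std(boots, ddof=1)) if len(boots) > 1 else float("nan")
    else:
        raise AgreementError(f"unknown se_method {se_method!r}")
    return KappaResult(kappa, se, r1.size)


@dataclass(frozen=True)
class BiasTest:
    t_stat: float
    p_value: float
    cohens_d: float
    mean_diff: float
    degenerate: bool = False  # sd of differences was 0


def bias_test(pred: Sequence[int], ref: Sequence[int]) -> BiasTest:
    """One-sample t-test of (pred - ref) against zero.

    A negative mean difference means the model under-predicts relative to
    the reference.  Cohen's d = mean(diff) / sd(diff); when the differences
    have zero variance the test is degenerate and t, d are reported as 0
    with p = 1 and a flag.
    """
    pred, ref = _pair(pred, ref)
    if pred.size < 2:
        raise AgreementError("bias test needs n >= 2")
    diff = np.asarray(pred, float) - np.asarray(ref, float)
    sd = float(np.std(diff, ddof=1))
    if sd == 0.0:
        return BiasTest(0.0, 1.0, 0.0, float(diff.mean()), degenerate=True)
    t, p = stats.ttest_1samp(diff, 0.0)
    return BiasTest(float(t), float(p), float(diff.mean() / sd), float(diff.mean()))


def networks_anova(groups: Sequence[Sequence[float]]) -> Tuple[float, float]:
    """One-way ANOVA on difference scores across model variants -> (F, p)."""
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise AgreementError("ANOVA needs >= 2 groups with n >= 2 each")
    if all(np.allclose(g, groups[0]) and g.size == groups[0].size for g in groups):
        return 0.0, 1.0
    F, p = stats.f_oneway(*groups)
    return float(F), float(p)


def binarize(scores: Sequence[int]) -> np.ndarray:
    """Map 0-4 scores to impairment: True where score >= 2 (moderate or
    higher), False for 0-1 (minimal to none)."""
    scores = np.asarray(scores, int)
    if scores.size and (scores.min() < 0 or scores.max() > 4):
        raise AgreementError("scores must lie in 0..4")
    return scores >= IMPAIRMENT_THRESHOLD


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts of predicted vs reference impairment ('positive' = impaired)."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise AgreementError("contingency counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @classmethod
    def from_scores(cls, pred: Sequence[int], ref: Sequence[int]) -> "ContingencyTable":
        p = binarize(pred)
        r = binarize(ref)
        return cls(tp=int(np.sum(p & r)), fp=int(np.sum(p & ~r)),
                   fn=int(np.sum(~p & r)), tn=int(np.sum(~p & ~r)))


@dataclass(frozen=True)
class ContingencyMetrics:
    recall: float
    precision: float
    accuracy: float
    f1: float
    undefined: Tuple[str, ...] = ()


def contingency_metrics(ct: ContingencyTable) -> ContingencyMetrics:
    """Recall TP/(TP+FN), precision TP/(TP+FP), accuracy (TP+TN)/total and
    F1 = 2PR/(P+R).  Zero-denominator cases are NaN and named in
    ``undefined``."""
    if ct.total == 0:
        raise AgreementError("empty contingency table")
    flags = []

    def ratio(num, den, name):
        if den == 0:
            flags.append(name)
            return float("nan")
        return num / den

    recall = ratio(ct.tp, ct.tp + ct.fn, "recall")
    precision = ratio(ct.tp, ct.tp + ct.fp, "precision")
    accuracy = (ct.tp + ct.tn) / ct.total
    if np.isnan(recall) or np.isnan(precision) or (precision + recall) == 0:
        flags.append("f1")
        f1 = float("nan")
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return ContingencyMetrics(recall, precision, accuracy, f1, tuple(flags))


@dataclass
class AgreementReport:
    """Everything computed for one prediction-vs-reference comparison."""

    n: int
    accuracy_pct: float
    mse: float
    diff_tally: Dict[int, int]
    kappa: KappaResult
    bias: BiasTest
    contingency: ContingencyTable
    metrics: ContingencyMetrics
    anova_F: Optional[float] = None
    anova_p: Optional[float] = None

    def to_dict(self) -> dict:
        d = {
            "n": self.n,
            "accuracy_pct": round(self.accuracy_pct, 1),
            "mse": round(self.mse, 2),
            "diff_tally": self.diff_tally,
            "kappa": round(self.kappa.kappa, 2) if np.isfinite(self.kappa.kappa) else None,
            "kappa_se": round(self.kappa.se, 2) if np.isfinite(self.kappa.se) else None,
            "t_stat": round(self.bias.t_stat, 3),
            "p_value": round(self.bias.p_value, 4),
            "cohens_d": round(self.bias.cohens_d, 3),
            "contingency": {"TP": self.contingency.tp, "FP": self.contingency.fp,
                            "FN": self.contingency.fn, "TN": self.contingency.tn},
            "recall": None if np.isnan(self.metrics.recall) else round(self.metrics.recall, 2),
            "precision": None if np.isnan(self.metrics.precision) else round(self.metrics.precision, 2),
            "binary_accuracy": round(self.metrics.accuracy, 2),
            "f1": None if np.isnan(self.metrics.f1) else round(self.metrics.f1, 2),
        }
        if self.anova_F is not None:
            d["anova_F"] = round(self.anova_F, 3)
            d["anova_p"] = round(self.anova_p, 4)
        return d


def evaluate_agreement(
    pred: Sequence[int], ref: Sequence[int],
    kappa_se_method: str = "bootstrap",
    n_bootstrap: int = 2000,
    seed: int = 0,
) -> AgreementReport:
    """Run the full battery for one predicted-vs-reference score pairing."""
    pred, ref = _pair(pred, ref)
    kap = quadratic_weighted_kappa(pred, ref, se_method=kappa_se_method,
                                   n_bootstrap=n_bootstrap, seed=seed)
    ct = ContingencyTable.from_scores(pred, ref)
    return AgreementReport(
        n=pred.size,
        accuracy_pct=score_accuracy(pred, ref),
        mse=score_mse(pred, ref),
        diff_tally=diff_tally(pred, ref),
        kappa=kap,
        bias=bias_test(pred, ref),
        contingency=ct,
        metrics=contingency_metrics(ct),
    )
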