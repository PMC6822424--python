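"""Agreement statistics between predicted and reference hypnograms.

Per-night Cohen's kappa, pooled confusion matrices (row percentages =
class sensitivities; for the two-class wake/sleep problem the diagonal
reads specificity then sensitivity, sleep being the positive class),
Deming regression and Pearson correlation for sleep measures, and
Bland-Altman bias with limits of agreement and an exact paired
sign-flip permutation test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io import STAGES, WAKE_SLEEP, Hypnogram
from .sleep_measures import MEASURE_NAMES, compute_measures, to_sleep_wake

logger = logging.getLogger(__name__)


@dataclass
class ConfusionMatrix:
    """KxK agreement counts, truth in rows, prediction in columns."""

    counts: np.ndarray
    class_order: tuple[str, ...]

    @property
    def percents(self) -> np.ndarray:
        """Row-normalized percentages (NaN rows where a class is absent)."""
        totals = self.counts.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(totals > 0, 100.0 * self.counts / totals, np.nan)

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if self.class_order != other.class_order:
            raise ValueError("cannot pool confusion matrices over different classes")
        return ConfusionMatrix(self.counts + other.counts, self.class_order)


@dataclass(frozen=True)
class DemingFit:
    """Errors-in-both-variables straight-line fit."""

    slope: float
    intercept: float
    pearson_r: float
    lam: float = 1.0


@dataclass(frozen=True)
class BlandAltmanResult:
    """Bias and limits of agreement for paired measurements.

    Differences are truth minus estimate, so a positive mean difference
    means the estimator underestimates the measure.
    """

    mean_diff: float
    sd_diff: float
    limits: tuple[float, float]
    p_value: float
    n: int


def _canonical_order(labels: set[str]) -> tuple[str, ...]:
    for canon in (STAGES, WAKE_SLEEP):
        if labels <= set(canon):
            return tuple(c for c in canon if c in labels) if labels != set(canon) else canon
    return tuple(sorted(labels))


def confusion(
    truth: Sequence[str],
    pred: Sequence[str],
    classes: Sequence[str] | None = None,
) -> ConfusionMatrix:
    """Agreement counts between two equal-length label sequences."""
    truth = list(truth.stages) if isinstance(truth, Hypnogram) else list(truth)
    pred = list(pred.stages) if isinstance(pred, Hypnogram) else list(pred)
    if len(truth) != len(pred):
        raise ValueError(
            f"length mismatch: truth has {len(truth)} epochs, "
            f"prediction has {len(pred)}"
        )
    if classes is None:
        classes = _canonical_order(set(truth) | set(pred))
    classes = tuple(classes)
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(truth, pred):
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts=counts, class_order=classes)


def kappa_from_confusion(cm: ConfusionMatrix) -> float:
    """Cohen's kappa from agreement counts."""
    n = cm.counts.sum()
    if n == 0:
        raise ValueError("empty confusion matrix")
    po = np.trace(cm.counts) / n
    pe = float(cm.counts.sum(axis=1) @ cm.counts.sum(axis=0)) / n**2
    if pe >= 1.0 - 1e-15:
        logger.warning(
            "both raters constant and identical (p_e = 1); kappa defined as 1"
        )
        return 1.0
    return float((po - pe) / (1.0 - pe))


def cohens_kappa(a: Sequence[str], b: Sequence[str]) -> float:
    """Chance-corrected agreement kappa = (p_o - p_e) / (1 - p_e)."""
    return kappa_from_confusion(confusion(a, b))


def two_class_sensitivity_specificity(cm: ConfusionMatrix) -> tuple[float, float]:
    """(sensitivity, specificity) in percent, sleep as the positive class.

    An empty truth row leaves the corresponding quantity NaN.
    """
    if cm.class_order != WAKE_SLEEP:
        raise ValueError(f"expected class order {WAKE_SLEEP}, got {cm.class_order}")
    pct = cm.percents
    return float(pct[1, 1]), float(pct[0, 0])


def deming_fit(
    x: Sequence[float], y: Sequence[float], lam: float = 1.0
) -> DemingFit:
    """Deming (errors-in-variables) regression of y on x.

    ``lam`` is the ratio of the y- to x-error variances; lam = 1 gives
    orthogonal regression, for which swapping x and y inverts the slope.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must be paired")
    if len(x) < 3:
        raise ValueError(f"need at least 3 points, got {len(x)}")
    sxx = float(np.var(x))
    syy = float(np.var(y))
    sxy = float(np.mean((x - x.mean()) * (y - y.mean())))
    if sxx == 0.0 and syy == 0.0:
        raise ValueError("zero variance in both variables")
    if sxy == 0.0:
        slope = math.sqrt(syy / (lam * sxx)) if sxx > 0 else math.inf
    else:
        d = syy - lam * sxx
        slope = (d + math.sqrt(d * d + 4.0 * lam * sxy * sxy)) / (2.0 * sxy)
    intercept = float(y.mean() - slope * x.mean())
    if sxx > 0 and syy > 0:
        r = float(np.corrcoef(x, y)[0, 1])
    else:
        r = math.nan
    return DemingFit(slope=float(slope), intercept=intercept, pearson_r=r, lam=lam)


def exact_permutation_test(
    d: Sequence[float],
    two_sided: bool = True,
    max_exact_n: int = 20,
    n_mc: int = 20_000,
    seed: int = 0,
) -> float:
    """Paired sign-flip permutation p-value for mean(d) = 0.

    All 2^n sign assignments are enumerated (n <= ``max_exact_n``);
    the p-value is the fraction of assignments whose |mean| is at least
    the observed |mean|, hence an exact multiple of 2^-n. Larger n
    falls back to seeded Monte-Carlo sign flips.
    """
    d = np.asarray(d, dtype=float)
    n = len(d)
    if n == 0:
        raise ValueError("empty difference vector")
    obs = abs(float(d.sum()))  # |mean| comparison via |sum|
    tol = 1e-9 * max(np.abs(d).sum(), 1.0)
    if n <= max_exact_n:
        sums = np.zeros(1)
        for di in d:
            sums = np.concatenate([sums + di, sums - di])
        if two_sided:
            hits = np.abs(sums) >= obs - tol
        else:
            hits = sums >= obs - tol
        return float(hits.mean())
    rng = np.random.default_rng(seed)
    n_hits = 0
    chunk = max(1, min(n_mc, 10_000_000 // max(n, 1)))
    done = 0
    while done < n_mc:
        m = min(chunk, n_mc - done)
        sums = rng.choice([-1.0, 1.0], size=(m, n)) @ d
        if two_sided:
            n_hits += int((np.abs(sums) >= obs - tol).sum())
        else:
            n_hits += int((sums >= obs - tol).sum())
        done += m
    # add-one correction keeps Monte-Carlo p-values strictly positive
    return float((n_hits + 1) / (n_mc + 1))


def bland_altman(
    x: Sequence[float], y: Sequence[float], loa_scale: str = "sd_diff"
) -> BlandAltmanResult:
    """Bland-Altman agreement between truth ``x`` and estimate ``y``.

    Differences d = x - y; limits of agreement are the mean difference
    plus/minus 1.96 x SD(d) (``loa_scale='sem'`` substitutes the
    standard error of the mean); the p-value comes from the exact
    paired permutation test.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must be paired")
    if len(x) < 2:
        raise ValueError(f"need at least 2 pairs, got {len(x)}")
    d = x - y
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    scale = sd / math.sqrt(len(d)) if loa_scale == "sem" else sd
    p = exact_permutation_test(d)
    return BlandAltmanResult(
        mean_diff=mean,
        sd_diff=sd,
        limits=(mean - 1.96 * scale, mean + 1.96 * scale),
        p_value=p,
        n=len(d),
    )


def paired_kappa_test(
    kappas_a: Sequence[float], kappas_b: Sequence[float]
) -> float:
    """Exact paired permutation test on per-night kappa differences."""
    a = np.asarray(kappas_a, dtype=float)
    b = np.asarray(kappas_b, dtype=float)
    if len(a) != len(b):
        raise ValueError("kappa vectors must be paired by night")
    return exact_permutation_test(a - b)


# ---------------------------------------------------------------------------
# Study-level report
# ---------------------------------------------------------------------------


@dataclass
class AgreementReport:
    """All agreement statistics for one prediction method over a study."""

    kappa5: dict[str, float]
    kappa2: dict[str, float]
    confusion5: ConfusionMatrix
    confusion2: ConfusionMatrix
    sensitivity: float
    specificity: float
    measures: dict[str, dict[str, float]]

    def to_dict(self) -> dict:
        return {
            "kappa5": self.kappa5,
            "kappa5_mean": float(np.mean(list(self.kappa5.values()))),
            "kappa2": self.kappa2,
            "kappa2_mean": float(np.mean(list(self.kappa2.values()))),
            "confusion5_counts": self.confusion5.counts.tolist(),
            "confusion5_percents": np.round(self.confusion5.percents, 2).tolist(),
            "confusion2_counts": self.confusion2.counts.tolist(),
            "class_order5": list(self.confusion5.class_order),
            "class_order2": list(self.confusion2.class_order),
            "sensitivity_pct": self.sensitivity,
            "specificity_pct": self.specificity,
            "measures": self.measures,
        }


def evaluate_study(
    truth: Mapping[str, Hypnogram],
    pred: Mapping[str, Hypnogram],
    tats_min: Mapping[str, float] | None = None,
) -> AgreementReport:
    """Compare predicted hypnograms against references night by night.

    Computes per-night 5- and 2-class kappas, confusion matrices pooled
    over nights (a population average weighted by epoch count), and per
    sleep measure a Deming fit, Pearson r and Bland-Altman analysis.
    Nights where a measure is undefined on either side (e.g. REM
    latency without REM) are dropped pairwise with a logged count.
    """
    nights = sorted(truth)
    if sorted(pred) != nights:
        raise ValueError("truth and prediction cover different nights")
    kappa5, kappa2 = {}, {}
    cm5 = ConfusionMatrix(np.zeros((5, 5), dtype=int), STAGES)
    cm2 = ConfusionMatrix(np.zeros((2, 2), dtype=int), WAKE_SLEEP)
    truth_measures = {m: [] for m in MEASURE_NAMES}
    pred_measures = {m: [] for m in MEASURE_NAMES}
    for night in nights:
        t, p = truth[night], pred[night]
        kappa5[night] = cohens_kappa(t.stages, p.stages)
        tw, pw = to_sleep_wake(t), to_sleep_wake(p)
        kappa2[night] = cohens_kappa(tw.states, pw.states)
        cm5 = cm5 + confusion(t.stages, p.stages, classes=STAGES)
        cm2 = cm2 + confusion(tw.states, pw.states, classes=WAKE_SLEEP)
        tats = tats_min.get(night) if tats_min else None
        mt = compute_measures(t, tats_min=tats).as_dict()
        mp = compute_measures(p, tats_min=tats).as_dict()
        for m in MEASURE_NAMES:
            truth_measures[m].append(mt[m])
            pred_measures[m].append(mp[m])
    sens, spec = two_class_sensitivity_specificity(cm2)
    measures: dict[str, dict[str, float]] = {}
    for m in MEASURE_NAMES:
        xt = np.asarray(truth_measures[m])
        yp = np.asarray(pred_measures[m])
        ok = np.isfinite(xt) & np.isfinite(yp)
        dropped = int(len(xt) - ok.sum())
        if dropped:
            logger.info("measure %s: dropped %d night(s) with missing values", m, dropped)
        block: dict[str, float] = {"n": int(ok.sum()), "n_dropped": dropped}
        if ok.sum() >= 3 and (np.var(xt[ok]) > 0 or np.var(yp[ok]) > 0):
            fit = deming_fit(xt[ok], yp[ok])
            block.update(
                deming_slope=fit.slope,
                deming_intercept=fit.intercept,
                pearson_r=fit.pearson_r,
            )
        if ok.sum() >= 2:
            ba = bland_altman(xt[ok], yp[ok])
            block.update(
                bias=ba.mean_diff,
                sd_diff=ba.sd_diff,
                loa_low=ba.limits[0],
                loa_high=ba.limits[1],
                p_value=ba.p_value,
            )
        measures[m] = block
    return AgreementReport(
        kappa5=kappa5,
        kappa2=kappa2,
        confusion5=cm5,
        confusion2=cm2,
        sensitivity=sens,
        specificity=spec,
        measures=measures,
    )
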