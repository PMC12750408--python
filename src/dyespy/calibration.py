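"""Similarity statistics and threshold calibration.

Three ingredients support the confidence gating of color assignment:

* cosine similarity, the scale-free shape metric used throughout;
* a one-tailed Welch's t-test (unequal variances) used to test whether
  nonoxidative dye spectra are more additive than oxidative ones;
* a label-shuffling null: every sample is deliberately paired with a wrong
  mixture identity (a derangement), the cosine similarities of true and
  false pairings are pooled, and the similarity threshold maximizing
  Youden's J = TPR - FPR becomes the decision boundary between genuine
  matches and spectral impostors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .exceptions import CalibrationError, DataError, UsageError


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """dot(a, b) / (||a|| ||b||); undefined for zero vectors."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise DataError("cosine_similarity requires equal-length vectors")
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise DataError("cosine similarity undefined for a zero vector")
    return float(a @ b / (na * nb))


@dataclass
class WelchResult:
    """Welch's t-test outcome (one-tailed)."""

    t: float
    df: float
    p_one_tailed: float
    direction: str


def welch_one_tailed(x, y, direction: str = "greater") -> WelchResult:
    """Welch's unequal-variance t-test of mean(x) vs mean(y), one-tailed.

    ``direction='greater'`` tests H1: mean(x) > mean(y) (right-sided);
    ``'less'`` tests the opposite side.  The statistic is

        t = (mx - my) / sqrt(sx^2/nx + sy^2/ny)

    with Welch-Satterthwaite degrees of freedom and the p-value from the
    t survival function on the stated side.
    """
    if direction not in ("greater", "less"):
        raise UsageError(f"direction must be 'greater' or 'less', got {direction!r}")
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size < 2 or y.size < 2:
        raise UsageError("welch_one_tailed needs >= 2 observations per sample")
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    if vx == 0.0 and vy == 0.0 and x.mean() == y.mean():
        # Degenerate but well-defined: identical constants, no evidence.
        return WelchResult(t=0.0, df=float(x.size + y.size - 2),
                           p_one_tailed=0.5, direction=direction)
    if vx == 0.0 and vy == 0.0:
        raise UsageError("both samples have zero variance")
    se2 = vx / x.size + vy / y.size
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2**2 / (
        (vx / x.size) ** 2 / (x.size - 1) + (vy / y.size) ** 2 / (y.size - 1)
    )
    if direction == "greater":
        p = float(stats.t.sf(t, df))
    else:
        p = float(stats.t.cdf(t, df))
    return WelchResult(t=float(t), df=float(df), p_one_tailed=p, direction=direction)


def shuffle_mixture_ids(mixture_ids, seed: int) -> list:
    """Derange mixture identities across samples.

    Returns a reassignment of ``mixture_ids`` in which no position keeps a
    value equal to its original one, i.e. every sample receives a *wrong*
    mixture identity — the construction the shuffled-similarity null
    requires.  Deterministic given ``seed`` (permutations are redrawn until
    one with no fixed value is found).
    """
    ids = list(mixture_ids)
    n = len(ids)
    distinct = set(ids)
    if n < 2 or len(distinct) < 2:
        raise CalibrationError(
            "cannot derange fewer than two samples or all-identical mixture ids"
        )
    rng = np.random.default_rng(seed)
    for _ in range(10_000):
        perm = rng.permutation(n)
        shuffled = [ids[j] for j in perm]
        if all(a != b for a, b in zip(shuffled, ids)):
            return shuffled
    # Value-level derangements can be infeasible for skewed multisets
    # (e.g. one id holds more than half the positions).
    raise CalibrationError("no derangement found; mixture ids too unbalanced")


@dataclass
class ThresholdCalibration:
    """Youden's-J optimal similarity threshold and its operating point."""

    threshold: float
    j: float
    accuracy: float
    fpr: float
    fnr: float
    true_scores: np.ndarray = field(repr=False)
    false_scores: np.ndarray = field(repr=False)
    #: a score s is declared a match iff s >= threshold
    match_rule: str = "score >= threshold"


def youden_threshold(true_scores, false_scores) -> ThresholdCalibration:
    """Threshold maximizing J(theta) = TPR(theta) - FPR(theta).

    Candidate thresholds are the midpoints of adjacent sorted unique scores
    plus guards below the minimum and above the maximum; a score counts as
    a declared match when ``score >= theta``.  Ties in J resolve to the
    smallest threshold.
    """
    ts = np.asarray(true_scores, dtype=float).ravel()
    fs = np.asarray(false_scores, dtype=float).ravel()
    if ts.size == 0 or fs.size == 0:
        raise CalibrationError("both score sets must be non-empty")
    pooled = np.unique(np.concatenate([ts, fs]))
    mids = (pooled[:-1] + pooled[1:]) / 2.0 if pooled.size > 1 else np.array([])
    span = max(pooled[-1] - pooled[0], 1.0)
    candidates = np.concatenate(
        [[pooled[0] - 0.01 * span], mids, [pooled[-1] + 0.01 * span]]
    )
    best = None
    for theta in candidates:
        tpr = float(np.mean(ts >= theta))
        fpr = float(np.mean(fs >= theta))
        j = tpr - fpr
        if best is None or j > best[0] + 1e-15:
            best = (j, theta, tpr, fpr)
    j, theta, tpr, fpr = best
    n = ts.size + fs.size
    accuracy = (tpr * ts.size + (1.0 - fpr) * fs.size) / n
    return ThresholdCalibration(
        threshold=float(theta),
        j=float(j),
        accuracy=float(accuracy),
        fpr=float(fpr),
        fnr=float(1.0 - tpr),
        true_scores=ts,
        false_scores=fs,
    )
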