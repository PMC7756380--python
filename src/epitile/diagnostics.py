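"""Serological and diagnostic statistics.

Covers the semiquantitative EAST class mapping of EUROLINE immunoblot
intensities, sIgE/sIgG4 ratios, sensitivity/specificity of binary
classification rules (titre cut-offs, ratio cut-offs, epitope-based
rules), non-parametric group comparison (Mann-Whitney U, exact for small
cohorts) and PCA variable contributions.

Rates are reported to 2 decimals and recognition fractions as whole
percentages, matching standard presentation. No multiple-testing
correction is applied.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .epitopes import EpitopeCall

logger = logging.getLogger(__name__)

#: Discriminative ovomucoid (Gal d 1) epitope regions, mature coordinates.
DEFAULT_DISCRIMINATIVE_REGIONS = ((30, 41), (39, 50), (84, 95))

#: EAST class thresholds: class k for integer RU in [lo, hi].
_EAST_BINS = (
    (0, 0, 2),
    (1, 3, 6),
    (2, 7, 15),
    (3, 16, 30),
    (4, 31, 50),
    (5, 51, 100),
)


def el_to_east_class(el_intensity: float) -> int:
    """EAST class (0-6) from a EUROLINE intensity in response units.

    Mapping: <3 -> 0, 3-6 -> 1, 7-15 -> 2, 16-30 -> 3, 31-50 -> 4,
    51-100 -> 5, >100 -> 6. Non-integer inputs are rounded (half up) to
    the nearest integer first, so the step function is total on RU >= 0.
    """
    if el_intensity < 0:
        raise ValueError(f"EL intensity must be >= 0, got {el_intensity}")
    r = math.floor(el_intensity + 0.5)
    for cls, lo, hi in _EAST_BINS:
        if lo <= r <= hi:
            return cls
    return 6


@dataclass(frozen=True)
class RatioRecord:
    """sIgE/sIgG4 ratio of one patient and component.

    ``ratio`` is None (flagged undefined) when the IgG4 intensity is zero;
    undefined ratios are excluded from medians.
    """

    patient_id: str
    component: str
    ige_ru: float
    igg4_ru: float
    ratio: float | None
    log_ratio: float | None


def ige_igg4_ratio(
    ige_ru: float, igg4_ru: float, patient_id: str = "", component: str = ""
) -> RatioRecord:
    if ige_ru < 0 or igg4_ru < 0:
        raise ValueError("EL intensities must be >= 0")
    if igg4_ru == 0:
        return RatioRecord(patient_id, component, ige_ru, igg4_ru, None, None)
    ratio = ige_ru / igg4_ru
    log_ratio = math.log10(ratio) if ratio > 0 else -math.inf
    return RatioRecord(patient_id, component, ige_ru, igg4_ru, ratio, log_ratio)


def ratio_median(records: Sequence[RatioRecord]) -> float:
    """Median sIgE/sIgG4 ratio over patients with a defined ratio."""
    defined = [r.ratio for r in records if r.ratio is not None]
    if not defined:
        raise ValueError("no defined ratios")
    return float(np.median(defined))


@dataclass(frozen=True)
class DiagnosticCounts:
    """2x2 contingency of a binary rule against allergic/tolerant truth."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)

    def summary(self) -> dict[str, float | int]:
        """Rates rounded to 2 decimals, percentages to whole numbers."""
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "sensitivity": round(self.sensitivity, 2),
            "specificity": round(self.specificity, 2),
            "sensitivity_pct": round(100 * self.sensitivity),
            "specificity_pct": round(100 * self.specificity),
        }


def diagnostic_performance(
    predictions: Mapping[str, bool], truth: Mapping[str, str]
) -> DiagnosticCounts:
    """Count TP/FP/TN/FN of per-patient predictions against group labels.

    ``truth`` maps patient_id to "allergic" (positive class) or
    "tolerant"; both maps must cover the same patients.
    """
    if not truth:
        raise ValueError("empty cohort")
    if set(predictions) != set(truth):
        raise ValueError("predictions and truth cover different patients")
    tp = fp = tn = fn = 0
    for pid, group in truth.items():
        pos = bool(predictions[pid])
        if group == "allergic":
            tp, fn = tp + pos, fn + (not pos)
        elif group == "tolerant":
            fp, tn = fp + pos, tn + (not pos)
        else:
            raise ValueError(f"{pid}: unknown group {group!r}")
    return DiagnosticCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def threshold_classifier(
    titres: Mapping[str, float], cutoff: float
) -> dict[str, bool]:
    """Positive iff titre >= cutoff (inclusive boundary)."""
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    return {pid: t >= cutoff for pid, t in titres.items()}


def ratio_classifier(
    ratios: Mapping[str, float | None],
    cutoff: float = 1.0,
    inclusive: bool = True,
) -> dict[str, bool]:
    """Positive iff the sIgE/sIgG4 ratio passes the cutoff.

    Undefined ratios (None) classify negative. The strict/inclusive
    boundary convention is exposed because reported cut-off conventions
    vary.
    """
    out = {}
    for pid, r in ratios.items():
        if r is None:
            out[pid] = False
        else:
            out[pid] = (r >= cutoff) if inclusive else (r > cutoff)
    return out


def epitope_classifier(
    calls: Sequence[EpitopeCall],
    patient_ids: Sequence[str],
    regions: Sequence[tuple[int, int]] = DEFAULT_DISCRIMINATIVE_REGIONS,
    channel: str = "IgE",
    antigen_id: str | None = None,
) -> dict[str, bool]:
    """Positive iff the patient has >=1 call overlapping a listed region.

    Overlap means at least one shared residue; the default regions are the
    discriminative ovomucoid epitopes aa30-41, aa39-50, aa84-95.
    """
    out = {pid: False for pid in patient_ids}
    for c in calls:
        if c.channel != channel or c.patient_id not in out:
            continue
        if antigen_id is not None and c.antigen_id != antigen_id:
            continue
        if any(c.overlaps(s, e) for s, e in regions):
            out[c.patient_id] = True
    return out


def recognition_fraction(k: int, n: int) -> int:
    """Recognition fraction as a whole percentage (e.g. 5/13 -> 38)."""
    if n <= 0 or not 0 <= k <= n:
        raise ValueError(f"invalid fraction {k}/{n}")
    return round(100 * k / n)


EXACT_LIMIT = 25  # combined sample size up to which the exact p is used


def compare_groups(
    values_a: Sequence[float], values_b: Sequence[float]
) -> tuple[float, float]:
    """Mann-Whitney U test, two-sided.

    Returns (U of group a, p). For combined n <= 25 the p-value is the
    exact permutation p (tie-aware, computed from the full rank-sum
    distribution over all group assignments); larger cohorts use the
    normal approximation with tie correction.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    n1, n = len(a), len(a) + len(b)
    ranks = stats.rankdata(np.concatenate([a, b]))
    r1 = float(ranks[:n1].sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0
    if n <= EXACT_LIMIT:
        p = _exact_ranksum_p(ranks, n1, r1)
    else:
        _, p = stats.mannwhitneyu(a, b, alternative="two-sided",
                                  method="asymptotic")
        p = float(p)
    return u1, p


def _exact_ranksum_p(ranks: np.ndarray, n1: int, r1_obs: float) -> float:
    """Exact two-sided permutation p of the rank sum, ties included.

    Midranks are doubled to integers and the number of size-``n1``
    subsets attaining each rank sum is counted by dynamic programming —
    equivalent to full enumeration of all C(n, n1) assignments.
    """
    w = np.rint(2 * ranks).astype(np.int64)
    total = int(w.sum())
    # dp[k, s] = number of subsets of size k with doubled-rank sum s
    dp = np.zeros((n1 + 1, total + 1), dtype=float)
    dp[0, 0] = 1.0
    for wi in w:
        for k in range(n1, 0, -1):  # descending k: each item used once
            dp[k, wi:] += dp[k - 1, : total + 1 - wi]
    dist = dp[n1]
    n_subsets = dist.sum()
    obs = int(round(2 * r1_obs))
    p_low = dist[: obs + 1].sum() / n_subsets
    p_high = dist[obs:].sum() / n_subsets
    return float(min(1.0, 2.0 * min(p_low, p_high)))


@dataclass
class PCAResult:
    """Deterministic PCA with variable contribution percentages.

    ``contributions`` (features x components) holds squared unit-norm
    loadings as percentages, summing to 100 per component;
    ``coordinates`` are patient scores. Sign convention: per component,
    the largest-magnitude loading is positive.
    """

    contributions: pd.DataFrame
    coordinates: pd.DataFrame
    explained_variance_ratio: pd.Series
    dropped_features: list[str]


def pca_contributions(
    matrix: pd.DataFrame, n_components: int | None = None, scale: bool = False
) -> PCAResult:
    """PCA of a patients x features matrix (centering only by default).

    Constant features are dropped with a warning; an all-constant matrix
    is an error. With ``scale=True`` features are standardized to unit
    variance first (correlation PCA).
    """
    X = matrix.astype(float)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 patients and 2 features")
    var = X.var(axis=0, ddof=0)
    dropped = list(X.columns[var == 0])
    if dropped:
        logger.warning("dropping constant feature(s): %s", dropped)
        X = X.drop(columns=dropped)
    if X.shape[1] == 0:
        raise ValueError("matrix has zero variance everywhere")
    if scale:
        X = (X - X.mean()) / X.std(ddof=0)
    k = n_components or min(X.shape[0] - 1, X.shape[1])
    k = min(k, X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=k, svd_solver="full")
    coords = pca.fit_transform(X.to_numpy())
    loadings = pca.components_  # (k, n_features), unit rows
    # deterministic sign: largest-magnitude loading positive per component
    for j in range(k):
        lead = np.argmax(np.abs(loadings[j]))
        if loadings[j, lead] < 0:
            loadings[j] *= -1
            coords[:, j] *= -1
    names = [f"PC{j + 1}" for j in range(k)]
    contrib = pd.DataFrame(
        100.0 * loadings.T**2, index=X.columns, columns=names
    )
    return PCAResult(
        contributions=contrib,
        coordinates=pd.DataFrame(coords, index=X.index, columns=names),
        explained_variance_ratio=pd.Series(
            pca.explained_variance_ratio_, index=names
        ),
        dropped_features=dropped,
    )
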