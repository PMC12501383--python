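"""Rater-agreement statistics for perceptual image quality assessment.

Scans are rated on an ordinal 1..4 quality scale (bad, medium, good,
perfect) by multiple raters, optionally twice (repeat sessions).  This
module provides:

* mean opinion scores (MOS) with two-stage repeat averaging,
* MOS-difference analysis (paired differences, substantial-difference
  fractions, histograms with the boundary-to-the-left convention),
* significance tests on MOS differences (two-sample t-test, Wilcoxon
  signed-rank, bootstrap CI of the median difference),
* the generalized weighted Fleiss' kappa with linear disagreement
  weights, image-sampling (closed-form linearization) and rater-sampling
  (jackknife) variances, intra-rater kappa, group-of-3 aggregation with
  the delete-two jackknife, and agreement-gain tests.

Kappa formulation
-----------------
With disagreement weights ``w`` (``w_ij = |v_i - v_j| / (v_max - v_min)``),

    kappa = 1 - D_o / D_e

where ``D_o`` is the mean within-scan pairwise disagreement (all ordered
pairs of distinct raters) and ``D_e = sum_jk pi_j pi_k w_jk`` the expected
disagreement under the pooled marginal category distribution ``pi``.  This
is the disagreement-ratio form of the agreement-weight generalized Fleiss
kappa (the two are identical because agreement weights are ``1 - w``).
``D_e = 0`` (all ratings in one category) defines ``kappa = 1``.

The image-sampling variance ``v_im`` is the delta-method (influence
function) variance of ``1 - D_o/D_e`` over scans:

    IF_i = -(d_i - D_o)/D_e + (D_o/D_e^2) * (e_i - 2*D_e) * (n_i/n_bar)
    v_im = 1/(N(N-1)) * sum_i (IF_i - mean(IF))^2

with ``d_i`` scan i's mean pairwise disagreement, ``e_i = 2 sum_jk p_ij
pi_k w_jk`` the linearized contribution of scan i's category profile
``p_ij`` to ``D_e``, and ``n_i/n_bar`` the scan's share of ratings.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats as sps

from .tiling import quantile

__all__ = [
    "RatingTable",
    "WeightMatrix",
    "KappaResult",
    "GainResult",
    "HistogramResult",
    "mos",
    "mos_differences",
    "histogram_mos",
    "histogram_diff",
    "mean_diff_test",
    "median_diff_test",
    "linear_weights",
    "weighted_fleiss_kappa",
    "jackknife_rater_variance",
    "intra_kappa",
    "enumerate_group_pairs",
    "group3_kappa",
    "kappa_gain",
    "kappa_compare",
    "interpret_kappa",
]

NATIVE_LEVELS = (1.0, 2.0, 3.0, 4.0)


# ---------------------------------------------------------------------------
# data container

@dataclass
class RatingTable:
    """Scan x rater ordinal ratings with optional repeat sessions.

    ``ratings`` and ``repeats`` are (n_scans, n_raters) float arrays with
    NaN marking missing entries; repeats may only exist where a first
    rating exists.
    """

    scan_ids: List
    rater_ids: List
    ratings: np.ndarray
    repeats: Optional[np.ndarray] = None
    method: str = ""

    def __post_init__(self) -> None:
        self.ratings = np.asarray(self.ratings, dtype=np.float64)
        if self.ratings.shape != (len(self.scan_ids), len(self.rater_ids)):
            raise ValueError("ratings shape does not match scan/rater ids")
        self._check_values(self.ratings, "ratings")
        if self.repeats is not None:
            self.repeats = np.asarray(self.repeats, dtype=np.float64)
            if self.repeats.shape != self.ratings.shape:
                raise ValueError("repeats shape differs from ratings")
            self._check_values(self.repeats, "repeats")
            orphan = np.isnan(self.ratings) & ~np.isnan(self.repeats)
            if np.any(orphan):
                raise ValueError("repeat entries exist where no first rating does")

    @staticmethod
    def _check_values(arr: np.ndarray, name: str) -> None:
        vals = arr[~np.isnan(arr)]
        if vals.size and (not np.all(np.isin(vals, NATIVE_LEVELS))):
            raise ValueError(f"{name} must be integers in 1..4 (or missing)")

    @property
    def n_scans(self) -> int:
        return len(self.scan_ids)

    @property
    def n_raters(self) -> int:
        return len(self.rater_ids)

    @classmethod
    def from_csv(
        cls, path: Union[str, Path, pd.DataFrame], method: Optional[str] = None
    ) -> "RatingTable":
        """Build from a long-format CSV: scan_id, rater_id, method, session, rating."""
        df = path if isinstance(path, pd.DataFrame) else pd.read_csv(path)
        required = {"scan_id", "rater_id", "method", "rating"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"ratings CSV missing columns: {sorted(missing)}")
        if "session" not in df.columns:
            df = df.assign(session=1)
        if method is not None:
            df = df[df["method"] == method]
            if df.empty:
                raise ValueError(f"no rows with method {method!r}")
        scans = sorted(df["scan_id"].unique().tolist())
        raters = sorted(df["rater_id"].unique().tolist())
        si = {s: i for i, s in enumerate(scans)}
        ri = {r: j for j, r in enumerate(raters)}
        first = np.full((len(scans), len(raters)), np.nan)
        second = np.full((len(scans), len(raters)), np.nan)
        bad_rows: List[int] = []
        for row in df.itertuples():
            try:
                rating = float(row.rating)
                session = int(row.session)
            except (TypeError, ValueError):
                bad_rows.append(row.Index)
                continue
            if rating not in NATIVE_LEVELS or session not in (1, 2):
                bad_rows.append(row.Index)
                continue
            target = first if session == 1 else second
            target[si[row.scan_id], ri[row.rater_id]] = rating
        if bad_rows:
            raise ValueError(f"malformed rating rows at indices: {bad_rows[:20]}")
        repeats = second if np.any(~np.isnan(second)) else None
        return cls(
            scan_ids=scans,
            rater_ids=raters,
            ratings=first,
            repeats=repeats,
            method=method or "",
        )

    def effective_scores(self) -> np.ndarray:
        """Per-rater scores with repeats averaged in (two-stage averaging)."""
        if self.repeats is None:
            return self.ratings.copy()
        out = self.ratings.copy()
        has_rep = ~np.isnan(self.repeats)
        out[has_rep] = 0.5 * (self.ratings[has_rep] + self.repeats[has_rep])
        return out


# ---------------------------------------------------------------------------
# MOS and differences

def mos(table: RatingTable) -> pd.Series:
    """Per-scan mean opinion score (repeat ratings averaged per rater first).

    Scans without any rating are excluded (logged via a warning).
    """
    scores = table.effective_scores()
    counts = (~np.isnan(scores)).sum(axis=1)
    empty = counts == 0
    if np.any(empty):
        dropped = [table.scan_ids[i] for i in np.nonzero(empty)[0]]
        warnings.warn(f"scans without ratings excluded from MOS: {dropped}", RuntimeWarning)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        values = np.nanmean(scores, axis=1)
    keep = ~empty
    return pd.Series(
        values[keep], index=[s for s, k in zip(table.scan_ids, keep) if k], name="MOS"
    )


def mos_differences(
    emip: RatingTable, mip: RatingTable, substantial: float = 0.5
) -> Tuple[pd.Series, Dict[str, float]]:
    """Paired MOS differences d_i = MOS(eMIP) - MOS(MIP) plus summaries."""
    mos_e, mos_m = mos(emip), mos(mip)
    if list(mos_e.index) != list(mos_m.index):
        only_e = sorted(set(mos_e.index) - set(mos_m.index))
        only_m = sorted(set(mos_m.index) - set(mos_e.index))
        raise ValueError(
            f"scan sets differ between methods (eMIP-only: {only_e[:10]}, "
            f"MIP-only: {only_m[:10]})"
        )
    d = (mos_e - mos_m).rename("d")
    n = len(d)
    summary = {
        "mean": float(d.mean()),
        "median": float(d.median()),
        "frac_substantial_positive": float(((d >= substantial)).sum() / n),
        "frac_substantial_negative": float(((d <= -substantial)).sum() / n),
    }
    return d, summary


# ---------------------------------------------------------------------------
# histograms

@dataclass
class HistogramResult:
    edges: np.ndarray
    counts: np.ndarray
    percent: np.ndarray


def _left_closed_histogram(values: np.ndarray, anchor: float, width: float) -> HistogramResult:
    """Bins (anchor + (j-1)w, anchor + jw]; boundary values go to the left bin."""
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise ValueError("no values to bin")
    if not np.all(np.isfinite(values)):
        raise ValueError("histogram requires finite values")
    eps = width * 1e-9
    j_lo = int(np.floor((values.min() - anchor) / width - eps))
    j_hi = int(np.ceil((values.max() - anchor) / width + eps))
    edges = anchor + width * np.arange(j_lo, j_hi + 1)
    if edges[0] >= values.min():
        edges = np.concatenate([[edges[0] - width], edges])
    idx = np.digitize(values, edges, right=True) - 1
    counts = np.bincount(idx, minlength=edges.size - 1)
    return HistogramResult(
        edges=edges, counts=counts, percent=100.0 * counts / values.size
    )


def histogram_mos(values, width: float = 0.125) -> HistogramResult:
    """MOS histogram; edges anchored at the scale minimum 1.0."""
    return _left_closed_histogram(np.asarray(values), anchor=1.0, width=width)


def histogram_diff(values, width: float = 1.0 / 3.0) -> HistogramResult:
    """MOS-difference histogram with a bin centered on zero."""
    return _left_closed_histogram(np.asarray(values), anchor=-width / 2.0, width=width)


# ---------------------------------------------------------------------------
# significance tests on MOS differences

def mean_diff_test(
    sample_a,
    sample_b,
    alpha: float = 1e-4,
    alternative: str = "two-sided",
) -> Dict[str, float]:
    """Two-sample t-test on MOS samples plus the (1-alpha) CI of the mean difference."""
    a = np.asarray(sample_a, dtype=np.float64)
    b = np.asarray(sample_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per sample")
    res = sps.ttest_ind(a, b, alternative=alternative)
    n1, n2 = a.size, b.size
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / df
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    diff = float(a.mean() - b.mean())
    degenerate = se == 0.0
    if degenerate:
        ci = (diff, diff)
        warnings.warn("zero pooled variance; t-test degenerate", RuntimeWarning)
    else:
        tcrit = sps.t.ppf(1.0 - alpha / 2.0, df)
        ci = (diff - tcrit * se, diff + tcrit * se)
    return {
        "t": float(res.statistic),
        "p": float(res.pvalue),
        "mean_difference": diff,
        "ci_low": float(ci[0]),
        "ci_high": float(ci[1]),
        "alpha": alpha,
        "alternative": alternative,
        "degenerate": bool(degenerate),
    }


def median_diff_test(
    d,
    n_boot: int = 2000,
    seed: int = 0,
    ci_level: float = 0.95,
    alternative: str = "two-sided",
) -> Dict[str, float]:
    """Wilcoxon signed-rank test on paired differences + bootstrap CI of the median."""
    d = np.asarray(d, dtype=np.float64)
    if d.size < 2:
        raise ValueError("need at least 2 paired differences")
    if np.all(d == 0):
        warnings.warn("all differences are zero; Wilcoxon test undefined", RuntimeWarning)
        w_stat, w_p = float("nan"), float("nan")
    else:
        res = sps.wilcoxon(d, alternative=alternative)
        w_stat, w_p = float(res.statistic), float(res.pvalue)
    rng = np.random.default_rng(seed)
    meds = np.median(
        d[rng.integers(0, d.size, size=(n_boot, d.size))], axis=1
    )
    lo = float(quantile(meds, (1.0 - ci_level) / 2.0))
    hi = float(quantile(meds, 1.0 - (1.0 - ci_level) / 2.0))
    return {
        "wilcoxon_statistic": w_stat,
        "p": w_p,
        "median_difference": float(np.median(d)),
        "ci_low": lo,
        "ci_high": hi,
        "ci_level": ci_level,
        "alternative": alternative,
    }


# ---------------------------------------------------------------------------
# weighted Fleiss' kappa

@dataclass
class WeightMatrix:
    """Ordinal disagreement weights over an ordered level set."""

    levels: np.ndarray
    w: np.ndarray

    def level_index(self, values: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.levels, values)
        idx = np.clip(idx, 0, self.levels.size - 1)
        if not np.allclose(self.levels[idx], values):
            raise ValueError("rating values not on the weight matrix's level set")
        return idx


def linear_weights(levels: Sequence[float] = NATIVE_LEVELS) -> WeightMatrix:
    """Linear disagreement weights w_ij = |v_i - v_j| / (v_max - v_min)."""
    lv = np.asarray(sorted(set(float(v) for v in levels)), dtype=np.float64)
    if lv.size < 2:
        raise ValueError("need at least 2 distinct levels")
    span = lv[-1] - lv[0]
    w = np.abs(lv[:, None] - lv[None, :]) / span
    return WeightMatrix(levels=lv, w=w)


@dataclass
class KappaResult:
    """Agreement coefficient with its variance decomposition."""

    kappa: float
    v_im: float = 0.0
    v_r: float = 0.0

    @property
    def variance(self) -> float:
        return self.v_im + self.v_r

    @property
    def se(self) -> float:
        return float(np.sqrt(self.variance))

    @property
    def ci(self) -> Tuple[float, float]:
        return (self.kappa - 1.96 * self.se, self.kappa + 1.96 * self.se)


def _kappa_core(
    scores: np.ndarray, weights: WeightMatrix
) -> Tuple[float, float, np.ndarray, np.ndarray, np.ndarray]:
    """Return (D_o, D_e, d_i, p_profiles, n_i) for a scans x raters score matrix."""
    L = weights.levels.size
    valid = ~np.isnan(scores)
    n_i = valid.sum(axis=1)
    usable = n_i >= 2
    if not np.any(usable):
        raise ValueError("no scan has >= 2 ratings")
    if np.any(~usable):
        warnings.warn(
            f"{int((~usable).sum())} scan(s) with < 2 ratings dropped from kappa",
            RuntimeWarning,
        )
    scores = scores[usable]
    valid = valid[usable]
    n_i = n_i[usable]
    N = scores.shape[0]

    counts = np.zeros((N, L))
    idx_flat = weights.level_index(scores[valid])
    rows = np.repeat(np.arange(N), valid.sum(axis=1))
    np.add.at(counts, (rows, idx_flat), 1.0)

    # mean pairwise disagreement per scan over ordered pairs of distinct raters
    pairweight = counts @ weights.w  # (N, L): sum_d n_id * w_cd
    d_i = (counts * pairweight).sum(axis=1) / (n_i * (n_i - 1.0))
    D_o = float(d_i.mean())

    pi = counts.sum(axis=0) / counts.sum()  # pooled marginal distribution
    D_e = float(pi @ weights.w @ pi)
    p_profiles = counts / n_i[:, None]
    return D_o, D_e, d_i, p_profiles, n_i.astype(np.float64), pi


def weighted_fleiss_kappa(
    scores: Union[RatingTable, np.ndarray],
    weights: Optional[WeightMatrix] = None,
) -> KappaResult:
    """Generalized weighted Fleiss' kappa for multiple raters (v_r unset).

    ``scores`` may be a :class:`RatingTable` (first-session ratings) or a
    (scans x raters) float matrix with NaN for missing.  Scans need at
    least two ratings; scans below that are dropped.  Perfect single-
    category tables (D_e = 0) define kappa = 1.
    """
    if isinstance(scores, RatingTable):
        scores = scores.ratings
    scores = np.asarray(scores, dtype=np.float64)
    if scores.ndim != 2 or scores.shape[0] < 2:
        raise ValueError("need a 2D score matrix with >= 2 scans")
    weights = weights or linear_weights(NATIVE_LEVELS)
    D_o, D_e, d_i, p_profiles, n_i, pi = _kappa_core(scores, weights)
    if D_e == 0.0:
        return KappaResult(kappa=1.0, v_im=0.0)
    kappa = 1.0 - D_o / D_e
    # influence-function variance over scans (see module docstring)
    N = d_i.size
    share = n_i / n_i.mean()  # scan's share of the pooled ratings
    e_i = 2.0 * share * (p_profiles @ (weights.w @ pi))
    IF = -(d_i - D_o) / D_e + (D_o / D_e**2) * (e_i - 2.0 * D_e)
    IF = IF - IF.mean()
    v_im = float(np.sum(IF**2) / (N * (N - 1.0))) if N > 1 else 0.0
    return KappaResult(kappa=float(kappa), v_im=v_im)


def jackknife_rater_variance(
    scores: Union[RatingTable, np.ndarray],
    weights: Optional[WeightMatrix] = None,
    kappa_fn: Optional[Callable[[np.ndarray], float]] = None,
) -> float:
    """Delete-one jackknife variance of kappa over raters.

    ``v_r = ((R-1)/R) * sum_l (kappa_(-l) - mean)^2``.
    """
    if isinstance(scores, RatingTable):
        scores = scores.ratings
    scores = np.asarray(scores, dtype=np.float64)
    R = scores.shape[1]
    if R < 3:
        raise ValueError("rater jackknife needs >= 3 raters")
    weights = weights or linear_weights(NATIVE_LEVELS)
    if kappa_fn is None:
        kappa_fn = lambda m: weighted_fleiss_kappa(m, weights).kappa
    loo = np.array(
        [kappa_fn(np.delete(scores, l, axis=1)) for l in range(R)], dtype=np.float64
    )
    return float((R - 1.0) / R * np.sum((loo - loo.mean()) ** 2))


def intra_kappa(
    table: RatingTable, weights: Optional[WeightMatrix] = None
) -> KappaResult:
    """Intra-rater agreement from repeat sessions.

    Per rater, the two sessions of the repeated scans form a 2-rater
    table; the mean of the per-rater kappas is reported.  ``v_r`` is the
    unbiased variance of the per-rater kappas divided by the rater count;
    ``v_im`` the mean per-rater image-sampling variance divided by the
    rater count.
    """
    if table.repeats is None:
        raise ValueError("intra-rater agreement requires repeat sessions")
    weights = weights or linear_weights(NATIVE_LEVELS)
    kappas: List[float] = []
    v_ims: List[float] = []
    for j in range(table.n_raters):
        both = ~np.isnan(table.ratings[:, j]) & ~np.isnan(table.repeats[:, j])
        if both.sum() < 2:
            raise ValueError(
                f"rater {table.rater_ids[j]!r} has < 2 repeated scans"
            )
        two = np.column_stack([table.ratings[both, j], table.repeats[both, j]])
        res = weighted_fleiss_kappa(two, weights)
        kappas.append(res.kappa)
        v_ims.append(res.v_im)
    R = len(kappas)
    arr = np.asarray(kappas)
    v_r = float(arr.var(ddof=1) / R) if R > 1 else 0.0
    v_im = float(np.mean(v_ims) / R)
    return KappaResult(kappa=float(arr.mean()), v_im=v_im, v_r=v_r)


# ---------------------------------------------------------------------------
# group-of-3 aggregation

def enumerate_group_pairs(
    n_raters: int, group_size: int
) -> Tuple[List[Tuple[Tuple[int, ...], Tuple[int, ...]]], int]:
    """All pairs of disjoint rater groups, built by exclusion then split.

    Choose the ``n_raters - 2*group_size`` excluded raters, then every
    ``group_size``-subset of the remainder forms the first group, its
    complement within the remainder the second.  The count is
    ``C(n, n-2g) * C(2g, g)``.
    """
    n, g = n_raters, group_size
    if 2 * g > n or g < 1:
        raise ValueError(f"cannot form two disjoint groups of {g} from {n} raters")
    pairs: List[Tuple[Tuple[int, ...], Tuple[int, ...]]] = []
    all_raters = set(range(n))
    for excluded in itertools.combinations(range(n), n - 2 * g):
        rest = sorted(all_raters - set(excluded))
        for group_a in itertools.combinations(rest, g):
            group_b = tuple(sorted(set(rest) - set(group_a)))
            pairs.append((group_a, group_b))
    return pairs, len(pairs)


def group3_kappa(
    table: Union[RatingTable, np.ndarray],
    weights: Optional[WeightMatrix] = None,
    group_size: int = 3,
) -> Tuple[KappaResult, Dict[str, object]]:
    """Agreement of group-averaged scores over all disjoint group pairs.

    Each group's per-scan MOS lives on the attainable-average scale (10
    levels for triples of 1..4 ratings); a 2-"rater" weighted kappa is
    computed per pair of disjoint groups and averaged.  ``v_im`` is the
    sum of per-pair image-sampling variances (as defined, without
    normalization by the pair count — noted in the report);  ``v_r`` is
    the delete-two jackknife over excluded rater pairs.

    Scans with any missing first-session rating are dropped.
    """
    scores = table.ratings if isinstance(table, RatingTable) else np.asarray(table)
    scores = np.asarray(scores, dtype=np.float64)
    complete = ~np.isnan(scores).any(axis=1)
    if not np.all(complete):
        warnings.warn(
            f"{int((~complete).sum())} scan(s) with missing ratings dropped from "
            "group aggregation",
            RuntimeWarning,
        )
    scores = scores[complete]
    N, R = scores.shape
    if N < 2:
        raise ValueError("need >= 2 complete scans")

    # attainable averages of `group_size` native ratings
    sums = range(group_size * 1, group_size * 4 + 1)
    levels = sorted({s / group_size for s in sums})
    gw = weights if weights is not None and weights.levels.size == len(levels) else (
        linear_weights(levels)
    )

    pairs, P = enumerate_group_pairs(R, group_size)
    cache: Dict[frozenset, KappaResult] = {}

    def pair_result(a: Tuple[int, ...], b: Tuple[int, ...]) -> KappaResult:
        key = frozenset((a, b))
        if key not in cache:
            mos_a = scores[:, a].mean(axis=1)
            mos_b = scores[:, b].mean(axis=1)
            cache[key] = weighted_fleiss_kappa(np.column_stack([mos_a, mos_b]), gw)
        return cache[key]

    per_pair = [pair_result(a, b) for a, b in pairs]
    kappas = np.array([r.kappa for r in per_pair])
    kappa_g3 = float(kappas.mean())
    v_im_g3 = float(np.sum([r.v_im for r in per_pair]))  # as defined; no /P

    # delete-two jackknife over excluded rater pairs
    subset_kappas: List[float] = []
    for excluded in itertools.combinations(range(R), 2):
        rest = sorted(set(range(R)) - set(excluded))
        ks = []
        for group_a in itertools.combinations(rest, group_size):
            group_b = tuple(sorted(set(rest) - set(group_a)))
            ks.append(pair_result(group_a, group_b).kappa)
        subset_kappas.append(float(np.mean(ks)))
    Q = len(subset_kappas)
    v_r_g3 = float(
        (R - 2.0) / (2.0 * R) * np.sum((np.asarray(subset_kappas) - kappa_g3) ** 2)
    )
    result = KappaResult(kappa=kappa_g3, v_im=v_im_g3, v_r=v_r_g3)
    extras = {
        "n_pairs": P,
        "n_subsets": Q,
        "subset_kappas": subset_kappas,
        "levels": levels,
        "note": "v_im is the plain sum of per-pair image-sampling variances",
    }
    return result, extras


# ---------------------------------------------------------------------------
# gains and comparisons

@dataclass
class GainResult:
    gain: float
    variance: float
    p_value: float


def kappa_gain(
    result_emip: KappaResult, result_mip: KappaResult, v_r_gain: float
) -> GainResult:
    """Agreement gain eMIP - MIP with one-sided normal-approximation p-value.

    ``variance = v_r_gain + v_im(MIP) + v_im(eMIP)``; ``v_r_gain`` comes
    from jackknifing the paired kappa difference over raters (delete-one
    for inter-rater, per-rater paired differences for intra, delete-two
    for group-of-3).  ``p = 1 - Phi(gain / sqrt(variance))``; a zero gain
    with zero variance yields p = 0.5 by continuity.
    """
    gain = result_emip.kappa - result_mip.kappa
    variance = float(v_r_gain + result_emip.v_im + result_mip.v_im)
    if variance < 0:
        raise ValueError("negative gain variance")
    if variance == 0.0:
        if gain == 0.0:
            warnings.warn("zero variance with zero gain; p = 0.5", RuntimeWarning)
            p = 0.5
        else:
            p = 0.0 if gain > 0 else 1.0
    else:
        p = float(1.0 - sps.norm.cdf(gain / np.sqrt(variance)))
    return GainResult(gain=float(gain), variance=variance, p_value=p)


def inter_gain_rater_variance(
    table_emip: Union[RatingTable, np.ndarray],
    table_mip: Union[RatingTable, np.ndarray],
    weights: Optional[WeightMatrix] = None,
) -> float:
    """Delete-one jackknife variance of the paired inter-rater kappa difference."""
    a = table_emip.ratings if isinstance(table_emip, RatingTable) else np.asarray(table_emip)
    b = table_mip.ratings if isinstance(table_mip, RatingTable) else np.asarray(table_mip)
    if a.shape[1] != b.shape[1]:
        raise ValueError("methods must share the rater set")
    weights = weights or linear_weights(NATIVE_LEVELS)
    R = a.shape[1]
    if R < 3:
        raise ValueError("rater jackknife needs >= 3 raters")
    diffs = np.array(
        [
            weighted_fleiss_kappa(np.delete(a, l, axis=1), weights).kappa
            - weighted_fleiss_kappa(np.delete(b, l, axis=1), weights).kappa
            for l in range(R)
        ]
    )
    return float((R - 1.0) / R * np.sum((diffs - diffs.mean()) ** 2))


def kappa_compare(result_a: KappaResult, result_b: KappaResult) -> GainResult:
    """Two-sample one-sided comparison p = 1 - Phi((ka - kb)/sqrt(va + vb))."""
    diff = result_a.kappa - result_b.kappa
    variance = result_a.variance + result_b.variance
    if variance == 0.0:
        p = 0.5 if diff == 0.0 else (0.0 if diff > 0 else 1.0)
    else:
        p = float(1.0 - sps.norm.cdf(diff / np.sqrt(variance)))
    return GainResult(gain=float(diff), variance=float(variance), p_value=p)


_KAPPA_BANDS = [
    (0.0, "Poor agreement"),
    (0.20, "Slight agreement"),
    (0.40, "Fair agreement"),
    (0.60, "Moderate agreement"),
    (0.80, "Substantial agreement"),
    (1.00, "Almost perfect agreement"),
]


def interpret_kappa(kappa: float) -> str:
    """Interpretation band of a kappa value (Landis-Koch benchmark)."""
    if not (-1.0 <= kappa <= 1.0):
        raise ValueError("kappa must lie in [-1, 1]")
    for upper, label in _KAPPA_BANDS:
        if kappa <= upper:
            return label
    return _KAPPA_BANDS[-1][1]
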