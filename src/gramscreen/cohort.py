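"""Library-level statistics linking bilayer potency to cytotoxicity.

Given a per-drug table (descriptors, measured NormRate, HepG2 CC20),
this module bins drugs by potency, cytotoxicity, or descriptor
quadrants; builds 2×2 contingency tables and odds ratios with Woolf
(log-OR normal) confidence intervals; computes probability-vs-bin
curves such as P(CC20 < 50 µM | NormRate bin); and provides the group
comparison and summary primitives used throughout the screen analysis:
two-sided Mann–Whitney tests with Bonferroni correction, 1.5·IQR box
summaries, squared Pearson correlation, and silhouette cluster scores.

Drugs with missing CC20 are excluded from cytotoxicity statistics and
never imputed; they remain in potency-only statistics.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import stats
from scipy.spatial.distance import cdist

__all__ = [
    "DrugRecord",
    "ContingencyTable",
    "OddsRatioResult",
    "BoxSummary",
    "SilhouetteResult",
    "MannWhitneyResult",
    "NORMRATE_EDGES",
    "CC20_EDGES",
    "ALOGP_THRESHOLD",
    "PSA_THRESHOLD",
    "bin_drugs",
    "quadrant_groups",
    "quadrant_table",
    "collapse_to_alogp",
    "odds_ratio",
    "probability_curve",
    "mann_whitney",
    "bonferroni",
    "box_summary",
    "silhouette",
    "r_squared",
    "supplementary_checks",
]

NORMRATE_EDGES = (1.25, 1.5)
CC20_EDGES = (10.0, 50.0)       # µM: toxic < 10, moderate [10, 50), nontoxic >= 50
ALOGP_THRESHOLD = 3.0
PSA_THRESHOLD = 75.0            # Å²
QED_THRESHOLD = 0.5
PSCORE_EDGES = (100.0, 300.0)


@dataclass(frozen=True)
class DrugRecord:
    """One library entry as consumed by the cohort statistics."""

    id: str
    alogp: float
    psa: float
    qed: float
    pscore: float
    normrate: float
    cc20: float | None = None        # µM in (0, 80], or None
    fu_mouse: float | None = None
    fu_mic: float | None = None
    normrate_disp: float = 0.0
    disp_kind: str = "half_range"

    def __post_init__(self) -> None:
        if self.normrate <= 0:
            raise ValueError("normrate must be > 0")


@dataclass(frozen=True)
class ContingencyTable:
    """2×2 counts: (a, b) exposed +/-, (c, d) unexposed +/-."""

    a: int
    b: int
    c: int
    d: int
    exposure_label: str = "exposed"
    event_label: str = "event"

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.total == 0:
            raise ValueError("table must contain at least one observation")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class OddsRatioResult:
    odds_exposed: float
    odds_unexposed: float
    oratio: float
    ci_low: float
    ci_high: float
    level: float
    flags: tuple[str, ...] = field(default=())


@dataclass(frozen=True)
class BoxSummary:
    """Quartiles, 1.5·IQR fences, data-snapped whisker ends, outliers."""

    q1: float
    median: float
    q3: float
    whisker_low: float
    whisker_high: float
    fence_low: float
    fence_high: float
    outliers: tuple[float, ...]


@dataclass(frozen=True)
class SilhouetteResult:
    scores: np.ndarray
    cluster_means: dict
    overall: float


@dataclass(frozen=True)
class MannWhitneyResult:
    statistic: float              # U of the first sample
    pvalue: float
    method: str                   # 'exact' or 'asymptotic'


# --- binning --------------------------------------------------------------

def _interval_label(lo: float, hi: float) -> str:
    lo_s = "-inf" if math.isinf(lo) else f"{lo:g}"
    hi_s = "inf" if math.isinf(hi) else f"{hi:g}"
    return f"[{lo_s}, {hi_s})"

_DEFAULT_EDGES = {
    "normrate": NORMRATE_EDGES,
    "cc20": CC20_EDGES,
    "qed": (QED_THRESHOLD,),
    "pscore": PSCORE_EDGES,
}


def bin_drugs(
    records: Sequence[DrugRecord],
    axis: str,
    edges: Sequence[float] | None = None,
) -> tuple[dict[str, list[DrugRecord]], list[DrugRecord]]:
    """Group drugs into half-open bins [e_i, e_{i+1}) along one axis.

    Values below the first edge fall in the leftmost bin, values at an
    edge in the bin to its right (so NormRate = 1.25 is 'moderate' and
    CC20 = 50 µM is non-toxic).  Returns ``(groups, excluded)`` where
    ``excluded`` holds drugs without a value on the axis (missing CC20);
    the quadrant axis is handled by `quadrant_groups`.
    """
    if axis == "alogp_psa_quadrant":
        return quadrant_groups(records), []
    if axis not in _DEFAULT_EDGES:
        raise ValueError(f"unknown binning axis {axis!r}")
    edges = tuple(_DEFAULT_EDGES[axis]) if edges is None else tuple(edges)
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("edges must be strictly increasing")
    bounds = (-math.inf, *edges, math.inf)
    labels = [_interval_label(lo, hi) for lo, hi in zip(bounds, bounds[1:])]
    groups: dict[str, list[DrugRecord]] = {lab: [] for lab in labels}
    excluded: list[DrugRecord] = []
    for rec in records:
        value = getattr(rec, axis)
        if value is None:
            excluded.append(rec)
            continue
        idx = int(np.searchsorted(edges, value, side="right"))
        groups[labels[idx]].append(rec)
    return groups, excluded


def quadrant_groups(
    records: Sequence[DrugRecord],
    alogp_threshold: float = ALOGP_THRESHOLD,
    psa_threshold: float = PSA_THRESHOLD,
) -> dict[str, list[DrugRecord]]:
    """Split drugs into the four ALogP/PSA quadrants (thresholds inclusive low)."""
    groups = {
        "low_alogp_low_psa": [],
        "low_alogp_high_psa": [],
        "high_alogp_low_psa": [],
        "high_alogp_high_psa": [],
    }
    for rec in records:
        a = "low" if rec.alogp <= alogp_threshold else "high"
        p = "low" if rec.psa <= psa_threshold else "high"
        groups[f"{a}_alogp_{p}_psa"].append(rec)
    return groups


def quadrant_table(
    records: Sequence[DrugRecord],
    event: Callable[[DrugRecord], bool],
    event_label: str = "event",
) -> ContingencyTable:
    """2×2 table comparing the high/high vs low/low ALogP-PSA quadrants.

    Exposed = ALogP > 3 and PSA > 75 Å²; unexposed = ALogP <= 3 and
    PSA <= 75 Å².  Drugs for which the event is undefined (missing CC20
    in a CC20 event) are excluded.
    """
    q = quadrant_groups(records)
    counts = {}
    for name in ("high_alogp_high_psa", "low_alogp_low_psa"):
        pos = neg = 0
        for rec in q[name]:
            try:
                hit = event(rec)
            except TypeError:      # event undefined (e.g. missing cc20)
                continue
            if hit is None:
                continue
            pos, neg = (pos + 1, neg) if hit else (pos, neg + 1)
        counts[name] = (pos, neg)
    a, b = counts["high_alogp_high_psa"]
    c, d = counts["low_alogp_low_psa"]
    return ContingencyTable(a, b, c, d, "ALogP>3 & PSA>75", event_label)


def collapse_to_alogp(tables: dict[str, tuple[int, int]]) -> ContingencyTable:
    """Collapse per-quadrant (event, non-event) counts over the PSA axis.

    Input keys are the four quadrant names; output compares ALogP > 3
    (exposed) with ALogP <= 3 (unexposed), summing the PSA columns.
    """
    a = tables["high_alogp_low_psa"][0] + tables["high_alogp_high_psa"][0]
    b = tables["high_alogp_low_psa"][1] + tables["high_alogp_high_psa"][1]
    c = tables["low_alogp_low_psa"][0] + tables["low_alogp_high_psa"][0]
    d = tables["low_alogp_low_psa"][1] + tables["low_alogp_high_psa"][1]
    return ContingencyTable(a, b, c, d, "ALogP>3", "event")


# --- inference ------------------------------------------------------------

def odds_ratio(t: ContingencyTable, level: float = 0.95) -> OddsRatioResult:
    """Odds ratio (a·d)/(b·c) with a Woolf confidence interval.

    The Woolf CI is exp(ln OR ± z·sqrt(1/a + 1/b + 1/c + 1/d)), with no
    continuity correction.  A zero in b or c makes the OR infinite and
    any zero cell leaves the CI undefined; both are flagged rather than
    silently corrected.
    """
    flags: list[str] = []
    odds_exp = t.a / t.b if t.b else math.inf
    odds_unexp = t.c / t.d if t.d else math.inf
    if t.b * t.c == 0:
        flags.append("infinite_or")
        oratio = math.inf if t.a * t.d > 0 else math.nan
    else:
        oratio = (t.a * t.d) / (t.b * t.c)
    if min(t.a, t.b, t.c, t.d) == 0:
        flags.append("ci_undefined")
        ci_low = ci_high = math.nan
    else:
        z = stats.norm.ppf(0.5 + level / 2.0)
        se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
        log_or = math.log(oratio)
        ci_low, ci_high = math.exp(log_or - z * se), math.exp(log_or + z * se)
    return OddsRatioResult(odds_exp, odds_unexp, oratio, ci_low, ci_high,
                           level, tuple(flags))


def probability_curve(
    groups: dict[str, Sequence[DrugRecord]],
    event: Callable[[DrugRecord], bool],
) -> tuple[dict[str, float | None], float]:
    """Per-bin event probabilities and the overall event fraction.

    Records for which the event is undefined are dropped from both the
    bin and overall fractions; empty bins are reported as None.
    """
    per_bin: dict[str, float | None] = {}
    total_hits = total_n = 0
    for label, recs in groups.items():
        hits = n = 0
        for rec in recs:
            try:
                outcome = event(rec)
            except TypeError:
                continue
            if outcome is None:
                continue
            n += 1
            hits += bool(outcome)
        per_bin[label] = hits / n if n else None
        total_hits += hits
        total_n += n
    overall = total_hits / total_n if total_n else math.nan
    return per_bin, overall


def _u_statistic(ranks_x: np.ndarray, n_x: int) -> float:
    return float(ranks_x.sum() - n_x * (n_x + 1) / 2.0)


def mann_whitney(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two-sided",
    exact_max_n: int = 12,
) -> MannWhitneyResult:
    """Two-sided Mann–Whitney U test with midranks for ties.

    For small samples (n_x + n_y <= ``exact_max_n``) the null
    distribution of U is enumerated exactly over all group assignments
    of the pooled midranks; the two-sided P is twice the smaller tail,
    capped at 1.  Larger samples use the tie-corrected normal
    approximation (no continuity correction).
    """
    if alternative != "two-sided":
        raise ValueError("only the two-sided alternative is implemented")
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)      # midranks
    n_x, n = x.size, pooled.size
    u_obs = _u_statistic(ranks[:n_x], n_x)

    if n <= exact_max_n:
        us = np.array([
            _u_statistic(ranks[list(idx)], n_x)
            for idx in itertools.combinations(range(n), n_x)
        ])
        tol = 1e-9
        p_low = np.mean(us <= u_obs + tol)
        p_high = np.mean(us >= u_obs - tol)
        p = min(1.0, 2.0 * min(p_low, p_high))
        return MannWhitneyResult(u_obs, float(p), "exact")

    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method="asymptotic", use_continuity=False)
    return MannWhitneyResult(float(res.statistic), float(res.pvalue), "asymptotic")


def bonferroni(pvals: Iterable[float], m: int | None = None) -> list[float]:
    """Bonferroni-adjusted p-values, multiplied by m and capped at 1."""
    pvals = list(pvals)
    m = len(pvals) if m is None else m
    return [min(1.0, p * m) for p in pvals]


def box_summary(values: Sequence[float]) -> BoxSummary:
    """Box-plot summary with the 1.5·IQR whisker rule.

    Quartiles use linear interpolation between order statistics; the
    fences sit at q1 - 1.5·IQR and q3 + 1.5·IQR, whisker ends snap to
    the most extreme observations inside the fences, and values outside
    are reported as outliers.
    """
    v = np.asarray(values, float)
    if v.size == 0:
        raise ValueError("need at least one value")
    q1, med, q3 = np.percentile(v, [25, 50, 75], method="linear")
    iqr = q3 - q1
    fence_low, fence_high = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= fence_low) & (v <= fence_high)]
    outliers = tuple(sorted(v[(v < fence_low) | (v > fence_high)].tolist()))
    return BoxSummary(
        q1=float(q1), median=float(med), q3=float(q3),
        whisker_low=float(inside.min()), whisker_high=float(inside.max()),
        fence_low=float(fence_low), fence_high=float(fence_high),
        outliers=outliers,
    )


def silhouette(
    points: np.ndarray,
    labels: Sequence,
    standardize: bool = True,
) -> SilhouetteResult:
    """Silhouette scores on (optionally standardized) Euclidean distances.

    s(i) = (b(i) - a(i)) / max(a(i), b(i)), where a(i) is the mean
    distance to the other members of i's cluster and b(i) the smallest
    mean distance to any other cluster.  Members of singleton clusters
    score 0.  Requires at least two clusters.
    """
    pts = np.asarray(points, float)
    if pts.ndim == 1:
        pts = pts[:, None]
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("silhouette needs at least 2 clusters")
    if standardize:
        sd = pts.std(axis=0)
        sd[sd == 0] = 1.0
        pts = (pts - pts.mean(axis=0)) / sd
    dist = cdist(pts, pts)
    scores = np.zeros(pts.shape[0])
    members = {lab: np.nonzero(labels == lab)[0] for lab in uniq}
    for i in range(pts.shape[0]):
        own = members[labels[i]]
        if own.size == 1:
            scores[i] = 0.0
            continue
        a = dist[i, own[own != i]].mean()
        b = min(
            dist[i, members[lab]].mean() for lab in uniq if lab != labels[i]
        )
        denom = max(a, b)
        scores[i] = 0.0 if denom == 0 else (b - a) / denom
    cluster_means = {lab: float(scores[members[lab]].mean()) for lab in uniq}
    return SilhouetteResult(scores, cluster_means, float(scores.mean()))


def r_squared(x: Sequence[float], y: Sequence[float]) -> float:
    """Squared Pearson correlation; NaN (with a warning) if degenerate."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples of size >= 3")
    if x.std() == 0 or y.std() == 0:
        warnings.warn("zero variance: r^2 undefined", stacklevel=2)
        return math.nan
    r, _ = stats.pearsonr(x, y)
    return float(r**2)


def supplementary_checks(records: Sequence[DrugRecord]) -> dict[str, float]:
    """Headline conditional probabilities of likely cytotoxicity.

    Returns the percentage of drugs with CC20 < 50 µM among (i) drugs
    with NormRate >= 1.5 and (ii) drugs with NormRate >= 1.25 and
    QED < 0.5, computed over drugs with a defined CC20.
    """
    def pct(pred) -> float:
        sel = [r for r in records if r.cc20 is not None and pred(r)]
        if not sel:
            return math.nan
        return 100.0 * sum(r.cc20 < 50.0 for r in sel) / len(sel)

    return {
        "pct_cc20_lt50_high_potency": pct(lambda r: r.normrate >= 1.5),
        "pct_cc20_lt50_potent_low_qed": pct(
            lambda r: r.normrate >= 1.25 and r.qed < QED_THRESHOLD
        ),
    }
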