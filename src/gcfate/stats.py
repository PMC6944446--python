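"""Correlation, binning and distribution machinery.

Rank statistics throughout: Spearman correlation (with pairwise complete-case
deletion), rank-based partial correlation (rank-transform then residualize,
equivalent to the precision-matrix route), the Meng-Rosenthal-Rubin z test
for comparing two dependent overlapping correlations, and the two-sided
Mann-Whitney U test.  Binning utilities implement the GC / length class
schemes, fixed-width GC histograms, equal-count tendency curves and
stratified boxplot-style summaries (quartiles by linear interpolation,
type-7).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

P_FLOOR = 1e-300


@dataclass
class CorrelationResult:
    rs: float
    p_value: float
    n: int
    controls: list[str] = field(default_factory=list)


def _complete(*cols: np.ndarray) -> list[np.ndarray]:
    arrs = [np.asarray(c, dtype=float) for c in cols]
    mask = np.logical_and.reduce([~np.isnan(a) for a in arrs])
    return [a[mask] for a in arrs]


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation with pairwise complete-case deletion."""
    xc, yc = _complete(x, y)
    n = len(xc)
    if n < 3:
        raise ValueError(f"need >= 3 complete cases, got {n}")
    if np.all(xc == xc[0]) or np.all(yc == yc[0]):
        warnings.warn("constant vector; Spearman undefined")
        return CorrelationResult(math.nan, math.nan, n)
    rs, p = sps.spearmanr(xc, yc)
    return CorrelationResult(float(rs), max(float(p), P_FLOOR), n)


def partial_spearman(x, y, controls: Mapping[str, Sequence[float]]
                     ) -> CorrelationResult:
    """Rank-based partial correlation of x and y given one or more controls.

    All variables are rank-transformed (average ranks); x and y are then
    residualized on the controls and the partial correlation is the Pearson
    correlation of the residuals (equivalent to the inverse-correlation-matrix
    route when it is defined).  A variable fully explained by the controls
    yields 0 with a warning; collinear controls raise.  An empty control set
    reduces exactly to plain Spearman.
    """
    names = list(controls)
    if not names:
        return spearman(x, y)
    arrs = _complete(x, y, *[controls[k] for k in names])
    n = len(arrs[0])
    if n < len(names) + 3:
        raise ValueError(f"need >= {len(names) + 3} complete cases, got {n}")
    ranks = [sps.rankdata(a) for a in arrs]
    design = np.column_stack([np.ones(n), *ranks[2:]])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError(f"singular rank-correlation matrix: collinear "
                         f"control variables among {names}")
    rx = ranks[0] - design @ np.linalg.lstsq(design, ranks[0], rcond=None)[0]
    ry = ranks[1] - design @ np.linalg.lstsq(design, ranks[1], rcond=None)[0]
    vx, vy = float(rx @ rx), float(ry @ ry)
    scale = float(np.var(ranks[0]) * n)
    if vx < 1e-10 * scale or vy < 1e-10 * scale:
        warnings.warn("variable fully explained by controls; partial "
                      "correlation set to 0")
        rs = 0.0
    else:
        rs = float(rx @ ry / math.sqrt(vx * vy))
    df = n - 2 - len(names)
    if abs(rs) >= 1.0:
        p = P_FLOOR
    else:
        t = rs * math.sqrt(df / (1 - rs ** 2))
        p = max(2 * sps.t.sf(abs(t), df), P_FLOOR)
    return CorrelationResult(float(rs), float(p), n, controls=names)


def compare_dependent_correlations(r_xy: float, r_xz: float, r_yz: float,
                                   n: int) -> tuple[float, float]:
    """Meng-Rosenthal-Rubin z test for two overlapping dependent correlations.

    Tests whether corr(x,y) differs from corr(x,z) when y and z are
    themselves correlated (r_yz), using Fisher-transformed coefficients.
    Returns (z, two-sided p).
    """
    if n <= 3:
        raise ValueError("need n > 3")
    for r in (r_xy, r_xz, r_yz):
        if not -1 < r < 1:
            raise ValueError(f"degenerate correlation {r}")
    z1, z2 = math.atanh(r_xy), math.atanh(r_xz)
    rbar2 = (r_xy ** 2 + r_xz ** 2) / 2
    f = min((1 - r_yz) / (2 * (1 - rbar2)), 1.0)
    h = (1 - f * rbar2) / (1 - rbar2)
    z = (z1 - z2) * math.sqrt((n - 3) / (2 * (1 - r_yz) * h))
    p = max(2 * sps.norm.sf(abs(z)), P_FLOOR)
    return z, p


def mann_whitney(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    U is reported for the first sample (number of (a, b) pairs with a > b,
    ties counting 1/2).  Exact p for small tie-free samples, normal
    approximation with tie correction otherwise (scipy's default policy).
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be nonempty")
    res = sps.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


# --- class schemes and binning ---------------------------------------------

@dataclass
class ClassScheme:
    """Ordered breakpoints partitioning the real line into labeled classes.

    Classes are left-closed: value v falls in [b_i, b_{i+1}).  The first
    class is (-inf, b_0) and the last [b_last, +inf).
    """

    name: str
    breakpoints: tuple[float, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if list(self.breakpoints) != sorted(set(self.breakpoints)):
            raise ValueError("breakpoints must be strictly increasing")
        if len(self.labels) != len(self.breakpoints) + 1:
            raise ValueError("need one label per class (breakpoints + 1)")


def _interval_labels(breaks: Sequence[float], fmt, unit: str
                     ) -> tuple[str, ...]:
    labs = [f"<{fmt(breaks[0])}{unit}"]
    labs += [f"{fmt(a)}-{fmt(b)}{unit}" for a, b in zip(breaks, breaks[1:])]
    labs.append(f">{fmt(breaks[-1])}{unit}")
    return tuple(labs)


def gc_classes(breaks: Sequence[float] = (0.40, 0.45, 0.50, 0.55, 0.60),
               name: str = "gc") -> ClassScheme:
    """The six GC classes, <40% to >60% in 5-point steps (fractions)."""
    return ClassScheme(name, tuple(breaks),
                       _interval_labels(breaks, lambda b: f"{b * 100:g}", "%"))


def length_classes(breaks_kb: Sequence[float] = (1.5, 2.5, 4.0, 6.0, 10.0),
                   name: str = "length") -> ClassScheme:
    """Six transcript-length classes, <1.5 kb to >10 kb (breakpoints in nt).

    Interior edges are a configurable convention; only the outer bounds are
    canonical.
    """
    breaks = tuple(b * 1000 for b in breaks_kb)
    return ClassScheme(name, breaks,
                       _interval_labels(breaks, lambda b: f"{b / 1000:g}", "kb"))


def gc3_classes(breaks: Sequence[float] = (0.40, 0.45, 0.50, 0.55, 0.60,
                                           0.65, 0.70),
                name: str = "gc3") -> ClassScheme:
    """Eight GC3 classes, <40% to >70%."""
    return ClassScheme(name, tuple(breaks),
                       _interval_labels(breaks, lambda b: f"{b * 100:g}", "%"))


def utr3_gc_classes(breaks: Sequence[float] = (0.40, 0.43, 0.46, 0.49, 0.55),
                    name: str = "gc_utr3") -> ClassScheme:
    """Six 3'UTR GC classes, <40% to >55% (interior edges a convention)."""
    return ClassScheme(name, tuple(breaks),
                       _interval_labels(breaks, lambda b: f"{b * 100:g}", "%"))


def utr5_extended_gc_classes(
        breaks: Sequence[float] = (0.40, 0.45, 0.50, 0.55, 0.60, 0.65, 0.70),
        name: str = "gc_utr5") -> ClassScheme:
    """GC classes with the >60% tail subdivided, for the GC-richer 5'UTRs."""
    return ClassScheme(name, tuple(breaks),
                       _interval_labels(breaks, lambda b: f"{b * 100:g}", "%"))


def assign_classes(values, scheme: ClassScheme) -> pd.Series:
    """Map each non-missing value to exactly one class label."""
    values = pd.Series(values, dtype=float)
    idx = np.digitize(values.to_numpy(), scheme.breakpoints, right=False)
    labels = pd.Series(
        pd.Categorical.from_codes(idx, categories=list(scheme.labels),
                                  ordered=True),
        index=values.index)
    labels[values.isna()] = np.nan
    return labels


def fixed_width_histogram(values, width: float = 0.007,
                          groups: pd.Series | None = None) -> pd.DataFrame:
    """Contiguous fixed-width bins over the observed range, with group counts.

    Returns one row per bin with the bin edges, the total count, per-group
    counts if ``groups`` is given, and attaches per-group medians in
    ``DataFrame.attrs["medians"]``.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    values = pd.Series(values, dtype=float).dropna()
    lo = math.floor(values.min() / width) * width
    nbins = int(math.ceil((values.max() - lo) / width)) or 1
    edges = lo + width * np.arange(nbins + 1)
    idx = np.clip(np.digitize(values, edges) - 1, 0, nbins - 1)
    out = pd.DataFrame({
        "bin_left": edges[:-1], "bin_right": edges[1:],
        "count": np.bincount(idx, minlength=nbins)})
    medians = {"all": float(values.median())}
    if groups is not None:
        groups = groups.reindex(values.index)
        for g in groups.dropna().unique():
            sel = values[groups == g]
            gi = np.clip(np.digitize(sel, edges) - 1, 0, nbins - 1)
            out[f"count_{g}"] = np.bincount(gi, minlength=nbins)
            medians[str(g)] = float(sel.median())
    out.attrs["medians"] = medians
    return out


def equal_count_tendency(x, y, bin_size: int = 500) -> pd.DataFrame:
    """Median-vs-median tendency curve over equal-count bins of x.

    Complete cases are sorted by x and cut into consecutive blocks of
    ``bin_size``; a trailing block smaller than ``bin_size``/2 is merged into
    the previous one.  Returns per-block medians of x and y with block sizes.
    """
    xc, yc = _complete(x, y)
    n = len(xc)
    if n < bin_size:
        warnings.warn(f"n={n} < bin_size={bin_size}; single bin")
        bin_size = max(n, 1)
    order = np.argsort(xc, kind="mergesort")
    xs, ys = xc[order], yc[order]
    bounds = list(range(0, n, bin_size)) + [n]
    if len(bounds) > 2 and bounds[-1] - bounds[-2] < bin_size / 2:
        del bounds[-2]
    rows = [{"x_median": float(np.median(xs[a:b])),
             "y_median": float(np.median(ys[a:b])), "n": b - a}
            for a, b in zip(bounds, bounds[1:])]
    return pd.DataFrame(rows)


def stratified_distribution(df: pd.DataFrame, stratify_by: str,
                            scheme: ClassScheme, response: str,
                            group: str | None = None) -> pd.DataFrame:
    """Boxplot-style summaries of ``response`` per stratum (and group).

    Strata come from ``scheme`` applied to column ``stratify_by``; summaries
    are n, the 10/25/50/75/90 percentiles (linear interpolation, type-7).
    Empty strata are reported with n=0.
    """
    strata = assign_classes(df[stratify_by], scheme)
    qs = [0.10, 0.25, 0.50, 0.75, 0.90]
    rows = []
    group_values = ([None] if group is None
                    else list(pd.unique(df[group].dropna())))
    for label in scheme.labels:
        for g in group_values:
            sel = df[response][(strata == label)
                               & (df[group] == g if g is not None else True)]
            sel = sel.dropna()
            row = {"stratum": label, "group": g, "n": len(sel)}
            for q in qs:
                row[f"p{int(q * 100)}"] = (
                    float(np.quantile(sel, q, method="linear"))
                    if len(sel) else math.nan)
            rows.append(row)
    return pd.DataFrame(rows)


def correlation_matrix(df: pd.DataFrame,
                       columns: Sequence[str] | None = None) -> pd.DataFrame:
    """Pairwise Spearman matrix with pairwise complete-case deletion."""
    cols = list(columns) if columns is not None else list(df.columns)
    out = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            try:
                r = spearman(df[a], df[b]).rs
            except ValueError:
                r = math.nan
            out.loc[a, b] = out.loc[b, a] = r
    return out
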