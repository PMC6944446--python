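"""Regulator target-set summaries.

Target sets (RBP / miRNA targets, motif-defined lists) are consumed as plain
gene-id lists with provenance tags.  Summaries are per-dataset medians over
members, assembled into GC-ordered heatmap matrices; transcripts/datasets can
be clustered hierarchically with 1 - Kendall tau distance and average
linkage (tau-b, i.e. tie-corrected); miRNA GC is correlated with median
target GC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import kendalltau

from .stats import CorrelationResult, spearman
from .seqfeatures import gc_fraction


@dataclass(frozen=True)
class TargetSet:
    """A named gene set with provenance (CLIP, RIP, motif, miRTarBase)."""

    name: str
    members: frozenset[str]
    source: str = "unknown"
    regulator_sequence: str | None = None  # e.g. the miRNA; U mapped to T

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"target set {self.name!r} is empty")
        if self.regulator_sequence is not None:
            object.__setattr__(self, "regulator_sequence",
                               self.regulator_sequence.upper().replace("U", "T"))


def load_target_set(path: str | Path, name: str, source: str = "unknown",
                    regulator_sequence: str | None = None) -> TargetSet:
    """Load a one-column gene-id TSV (header ``gene_id``) into a TargetSet."""
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns:
        raise ValueError(f"{path}: needs a gene_id column")
    return TargetSet(name=name, members=frozenset(df["gene_id"].astype(str)),
                     source=source, regulator_sequence=regulator_sequence)


def set_summary(ts: TargetSet, data: pd.DataFrame,
                columns: Sequence[str] | None = None) -> pd.Series:
    """Median of each data column over set members, with counts.

    ``data`` is indexed by gene_id (fate table joined with composition
    features).  Unresolved member ids are counted, not silently dropped;
    background (whole-universe) medians are attached in ``attrs``.
    """
    cols = list(columns) if columns is not None else [
        c for c in data.columns if pd.api.types.is_numeric_dtype(data[c])]
    resolved = data.index.intersection(list(ts.members))
    if len(resolved) == 0:
        raise ValueError(f"no member of {ts.name!r} resolves in the universe")
    med = data.loc[resolved, cols].median()
    med["n"] = len(resolved)
    med["n_unresolved"] = len(ts.members) - len(resolved)
    med.name = ts.name
    med.attrs = {"background": data[cols].median()}
    return med


def heatmap_matrix(sets: Iterable[TargetSet], data: pd.DataFrame,
                   columns: Sequence[str], order_by: str = "gc_mrna"
                   ) -> pd.DataFrame:
    """Set-by-dataset matrix of medians, rows ordered by increasing GC.

    ``order_by`` names the composition column whose set median defines the
    row order; columns keep the caller's (dataset) order.
    """
    sets = list(sets)
    if len(sets) < 2:
        raise ValueError("need >= 2 target sets")
    cols = list(dict.fromkeys([*columns, order_by]))
    rows = [set_summary(ts, data, cols) for ts in sets]
    mat = pd.DataFrame(rows)
    mat = mat.sort_values(order_by, kind="mergesort")
    return mat[[*columns, "n", "n_unresolved"]]


def cluster_matrix(matrix: pd.DataFrame, linkage_method: str = "average"
                   ) -> tuple[list, list, np.ndarray, np.ndarray]:
    """Hierarchical clustering with 1 - Kendall tau distance, average linkage.

    Rows with any missing value are deleted (count reported via warning);
    constant rows, for which tau is undefined, are dropped with a warning.
    Returns (row leaf order, column leaf order, row linkage, column linkage);
    leaf orders are index/column labels.
    """
    mat = matrix.dropna(axis=0)
    if len(mat) < len(matrix):
        warnings.warn(f"dropped {len(matrix) - len(mat)} incomplete rows")
    const = mat.apply(lambda r: np.all(r.to_numpy() == r.to_numpy()[0]), axis=1)
    if const.any():
        warnings.warn(f"dropped {int(const.sum())} constant rows "
                      "(Kendall tau undefined)")
        mat = mat[~const]
    if len(mat) < 3:
        raise ValueError("need >= 3 complete, non-constant rows")
    row_link = _kendall_linkage(mat.to_numpy(), linkage_method)
    col_link = _kendall_linkage(mat.to_numpy().T, linkage_method)
    row_order = [mat.index[i] for i in hierarchy.leaves_list(row_link)]
    col_order = [mat.columns[i] for i in hierarchy.leaves_list(col_link)]
    return row_order, col_order, row_link, col_link


def kendall_distance_matrix(rows: np.ndarray) -> np.ndarray:
    """Pairwise 1 - Kendall tau-b distances between observation vectors."""
    n = len(rows)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            tau = kendalltau(rows[i], rows[j]).statistic
            dist[i, j] = dist[j, i] = 1.0 - tau
    return dist


def _kendall_linkage(rows: np.ndarray, method: str) -> np.ndarray:
    return hierarchy.linkage(squareform(kendall_distance_matrix(rows),
                                        checks=False), method=method)


def mirna_gc_correlation(mirnas: Sequence[TargetSet],
                         data: pd.DataFrame, gc_column: str = "gc_mrna"
                         ) -> CorrelationResult:
    """Spearman between miRNA sequence GC and the median GC of its targets."""
    usable = [m for m in mirnas if m.regulator_sequence]
    if len(usable) < 5:
        raise ValueError("need >= 5 miRNAs with sequences and targets")
    mirna_gc, target_gc = [], []
    for m in usable:
        resolved = data.index.intersection(list(m.members))
        if len(resolved) == 0:
            warnings.warn(f"{m.name}: no resolvable targets; skipped")
            continue
        mirna_gc.append(gc_fraction(m.regulator_sequence))
        target_gc.append(float(data.loc[resolved, gc_column].median()))
    return spearman(np.array(mirna_gc), np.array(target_gc))
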