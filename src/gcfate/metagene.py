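"""5'->3' metagene read-coverage profiling.

Each transcript is subdivided into 20 near-equal contiguous bins from its 5'
to 3' end and the proportion of reads per bin computed; group profiles are
unweighted means over transcripts so each gene counts equally regardless of
expression level.  Coverage is consumed as per-transcript per-base depth
(transcript coordinates); alignment is out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

N_BINS_DEFAULT = 20


@dataclass
class CoverageProfile:
    transcript_id: str
    bins: np.ndarray          # length n_bins; proportions (sum 1) or NaN
    total_reads: float

    @property
    def valid(self) -> bool:
        return self.total_reads > 0


def bin_edges(length: int, n_bins: int = N_BINS_DEFAULT) -> np.ndarray:
    """Base offsets partitioning [0, length) into n_bins near-equal segments.

    Edge i is floor(i * length / n_bins); segment sizes differ by at most one
    base (largest-remainder allocation of the leftover bases).
    """
    return (np.arange(n_bins + 1) * length) // n_bins


def bin_coverage(transcript_id: str, depth: Sequence[float],
                 n_bins: int = N_BINS_DEFAULT) -> CoverageProfile:
    """Per-bin read proportions from a per-base depth vector."""
    depth = np.asarray(depth, dtype=float)
    if len(depth) < n_bins:
        raise ValueError(
            f"{transcript_id}: length {len(depth)} < {n_bins} bins")
    edges = bin_edges(len(depth), n_bins)
    sums = np.add.reduceat(depth, edges[:-1])
    total = float(depth.sum())
    if total == 0:
        return CoverageProfile(transcript_id, np.full(n_bins, np.nan), 0.0)
    return CoverageProfile(transcript_id, sums / total, total)


def group_profile(profiles: Iterable[CoverageProfile]
                  ) -> tuple[np.ndarray, np.ndarray, int]:
    """Equal-gene-weight mean profile with per-bin standard deviation.

    Transcripts with zero reads are excluded.  Returns (mean, sd, n).
    """
    mat = np.array([p.bins for p in profiles if p.valid])
    if mat.size == 0:
        raise ValueError("no profiles with reads")
    return mat.mean(axis=0), mat.std(axis=0, ddof=0), mat.shape[0]


def five_prime_summary(bins: np.ndarray, k: int = 2) -> float:
    """Proportion of reads in the first k bins (the 5' window)."""
    return float(np.asarray(bins)[:k].sum())


def contrast_profiles(target_ids: Sequence[str],
                      control: Mapping[str, CoverageProfile],
                      silenced: Mapping[str, CoverageProfile]
                      ) -> pd.DataFrame:
    """Target-set vs all-mRNA group profiles in control and silenced conditions.

    Returns a tidy frame of four 20-bin curves (targets/all x
    control/silenced) plus the per-bin control-vs-silenced difference for the
    target set.
    """
    resolvable = [t for t in target_ids if t in control and t in silenced]
    if len(resolvable) < 10:
        warnings.warn(f"only {len(resolvable)} resolvable targets")
    curves = {
        ("targets", "control"): group_profile(
            [control[t] for t in resolvable])[0],
        ("targets", "silenced"): group_profile(
            [silenced[t] for t in resolvable])[0],
        ("all", "control"): group_profile(control.values())[0],
        ("all", "silenced"): group_profile(silenced.values())[0],
    }
    n_bins = len(next(iter(curves.values())))
    rows = []
    for (subset, condition), prof in curves.items():
        for b in range(n_bins):
            rows.append({"subset": subset, "condition": condition,
                         "bin": b + 1, "proportion": prof[b]})
    df = pd.DataFrame(rows)
    df.attrs["target_difference"] = (curves[("targets", "silenced")]
                                     - curves[("targets", "control")])
    df.attrs["n_targets"] = len(resolvable)
    return df


def read_coverage_table(path: str | Path,
                        lengths: Mapping[str, int]) -> dict[str, np.ndarray]:
    """Load a depth TSV (transcript_id, pos [1-based], depth) into arrays.

    Positions absent from the file have depth 0; transcript lengths come from
    the annotation.
    """
    df = pd.read_csv(path, sep="\t")
    need = {"transcript_id", "pos", "depth"}
    if not need <= set(df.columns):
        raise ValueError(f"coverage table needs columns {sorted(need)}")
    out: dict[str, np.ndarray] = {}
    for tid, sub in df.groupby("transcript_id", sort=False):
        L = lengths.get(str(tid))
        if L is None:
            warnings.warn(f"coverage for unknown transcript {tid}; skipped")
            continue
        depth = np.zeros(L)
        pos = sub["pos"].to_numpy(int) - 1
        if (pos < 0).any() or (pos >= L).any():
            raise ValueError(f"{tid}: position outside [1, {L}]")
        depth[pos] = sub["depth"].to_numpy(float)
        out[str(tid)] = depth
    return out


def write_coverage_table(depths: Mapping[str, np.ndarray],
                         path: str | Path) -> None:
    """Write per-base depths as a sparse TSV (zero-depth bases omitted)."""
    with open(path, "w") as fh:
        fh.write("transcript_id\tpos\tdepth\n")
        for tid in sorted(depths):
            d = depths[tid]
            for p in np.nonzero(d)[0]:
                fh.write(f"{tid}\t{p + 1}\t{d[p]:g}\n")
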