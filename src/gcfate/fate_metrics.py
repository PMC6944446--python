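"""Per-gene mRNA fate measurements.

Assembles the fate table: P-body (PB) enrichment, silencing log2 fold-changes
(DDX6, XRN1, PAT1B), CLIP enrichment, translation rate (polysomal/total
ratio), protein yield, haplo-insufficiency scores and meiotic recombination
rates.  Differential-expression testing is consumed, never computed; the
simple normalized-ratio estimator here only makes the synthetic pipeline
self-contained.  Changes in total mRNA after silencing a decay factor are
interpreted as stabilization.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

AVOGADRO = 6.02214076e23


def log2_enrichment(counts_a: pd.Series, counts_b: pd.Series,
                    pseudocount: float = 1.0) -> pd.Series:
    """Library-size-normalized per-gene log2 ratio of two count vectors."""
    if set(counts_a.index) != set(counts_b.index):
        diff = set(counts_a.index) ^ set(counts_b.index)
        raise ValueError(f"gene universe mismatch: {len(diff)} ids differ")
    counts_b = counts_b.reindex(counts_a.index)
    tot_a, tot_b = counts_a.sum(), counts_b.sum()
    if tot_a <= 0 or tot_b <= 0:
        raise ValueError("library sizes must be positive")
    return np.log2(((counts_a + pseudocount) / tot_a)
                   / ((counts_b + pseudocount) / tot_b))


def translation_rate(fc_poly, fc_total):
    """Translation-rate log2 fold-change: polysomal minus total (log2 scale).

    The polysomal/total mRNA ratio proxies translation rate; differencing the
    two fold-changes isolates translational regulation from abundance change.
    Missing inputs propagate to missing output.
    """
    if np.isscalar(fc_poly):
        return fc_poly - fc_total
    return pd.Series(fc_poly) - pd.Series(fc_total)


def protein_yield(protein: float, mrna: float) -> float:
    """Protein abundance per unit mRNA abundance."""
    if mrna == 0:
        warnings.warn("mRNA abundance 0; yield undefined")
        return np.nan
    return protein / mrna


def weighted_crossover_rate(gene_interval: tuple[int, int],
                            genetic_map: pd.DataFrame) -> float:
    """Overlap-weighted mean crossover rate (cM/Mb) over a gene's span.

    ``genetic_map`` needs columns start, end (0-based half-open, sorted,
    non-overlapping) and cM_per_Mb.  NaN if the gene overlaps no map interval.
    """
    gs, ge = gene_interval
    ov = (np.minimum(genetic_map["end"], ge)
          - np.maximum(genetic_map["start"], gs)).clip(lower=0)
    total = ov.sum()
    if total == 0:
        return np.nan
    return float((genetic_map["cM_per_Mb"] * ov).sum() / total)


def classify_pb(pb_enrichment: pd.Series, significant: pd.Series,
                threshold: float = 1.0) -> pd.Series:
    """Assign "PB-in"/"PB-out" labels.

    Requires both |log2 enrichment| above ``threshold`` and a significance
    flag; everything else (including missing values) is unlabeled (NA).
    """
    sig = significant.reindex(pb_enrichment.index).fillna(False).astype(bool)
    labels = pd.Series(pd.NA, index=pb_enrichment.index, dtype="object")
    labels[sig & (pb_enrichment >= threshold)] = "PB-in"
    labels[sig & (pb_enrichment <= -threshold)] = "PB-out"
    return labels


def assemble_fate_table(tables: Mapping[str, pd.DataFrame],
                        pb_threshold: float = 1.0) -> pd.DataFrame:
    """Outer-join per-gene tables into one fate table.

    All inputs must be indexed by gene_id with disjoint (or consistent)
    columns; conflicting duplicate keys raise.  The derived
    ``translation_rate_fc`` (= fc_poly_ddx6 - fc_total_ddx6) and PB class
    labels are (re)computed wherever their inputs are present.
    """
    joined: pd.DataFrame | None = None
    for name, df in tables.items():
        if df.index.duplicated().any():
            raise ValueError(f"table {name!r}: duplicated gene_id keys")
        joined = df if joined is None else joined.join(df, how="outer")
    if joined is None:
        raise ValueError("no input tables")
    if {"fc_poly_ddx6", "fc_total_ddx6"} <= set(joined.columns):
        joined["translation_rate_fc"] = translation_rate(
            joined["fc_poly_ddx6"], joined["fc_total_ddx6"])
    if {"pb_enrichment", "pb_significant"} <= set(joined.columns):
        joined["pb_class"] = classify_pb(
            joined["pb_enrichment"], joined["pb_significant"],
            threshold=pb_threshold)
    return joined


# --- in vitro granule-reconstitution arithmetic -----------------------------

def molar_concentration_um(mass_ug: float, volume_ul: float,
                           mw_kda: float) -> float:
    """Molar concentration (µM) of a protein from mass, volume and size.

    Used for the cell-free P-body-like granule reconstitution assay, where
    the recombinant helicase concentration is compared with its concentration
    in cells and inside P-bodies.
    """
    mol = (mass_ug * 1e-6) / (mw_kda * 1e3)
    return mol / (volume_ul * 1e-6) * 1e6


def concentration_ratio(conc_a: float, conc_b: float) -> float:
    """Fold-difference between two concentrations (same units)."""
    if conc_b == 0:
        raise ValueError("reference concentration is zero")
    return conc_a / conc_b
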