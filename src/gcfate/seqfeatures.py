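"""Composition and codon-usage statistics.

GC content per region and at codon third positions (GC3), amino-acid
frequencies, relative synonymous codon usage (RSCU, the "normalized relative
usage": observed codon frequency divided by the expected frequency under
uniform use within its synonymous family), low-usage codon metrics, and a
tAI-style tRNA adaptation score.

N bases are excluded from both numerator and denominator of every GC
computation; codons containing N are skipped in codon-level statistics.
Missing values (empty region, no informative base) are returned as NaN, never
raised.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .transcript_io import TranscriptRecord

_STANDARD = CodonTable.unambiguous_dna_by_id[1]

#: codon -> amino acid (single letter; '*' for stop), DNA alphabet
CODON_TO_AA: dict[str, str] = dict(_STANDARD.forward_table)
CODON_TO_AA.update({c: "*" for c in _STANDARD.stop_codons})

#: amino acid -> synonymous codons (stops grouped as their own family '*')
SYN_FAMILIES: dict[str, list[str]] = {}
for _codon in sorted(CODON_TO_AA):
    SYN_FAMILIES.setdefault(CODON_TO_AA[_codon], []).append(_codon)

ALL_CODONS: list[str] = sorted(CODON_TO_AA)
SENSE_CODONS: list[str] = [c for c in ALL_CODONS if CODON_TO_AA[c] != "*"]
AMINO_ACIDS: list[str] = sorted(a for a in SYN_FAMILIES if a != "*")


def gc_fraction(seq: str) -> float:
    """(G+C)/(A+C+G+T); N excluded from the denominator; NaN if no informative base."""
    gc = sum(seq.count(b) for b in "GC")
    at = sum(seq.count(b) for b in "AT")
    if gc + at == 0:
        return math.nan
    return gc / (gc + at)


def region_gc(rec: TranscriptRecord) -> tuple[float, float, float, float]:
    """GC of the whole mRNA, 5'UTR, CDS and 3'UTR (NaN for empty regions)."""
    return (gc_fraction(rec.sequence), gc_fraction(rec.utr5),
            gc_fraction(rec.cds), gc_fraction(rec.utr3))


def codons_of(cds: str) -> list[str]:
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    return [cds[i:i + 3] for i in range(0, len(cds), 3)]


def gc3(cds: str) -> float:
    """GC fraction at codon third (wobble) positions, N excluded."""
    third = "".join(c[2] for c in codons_of(cds))
    return gc_fraction(third)


def amino_acid_frequencies(cds: str) -> pd.Series:
    """Frequencies of the 20 amino acids in the encoded protein.

    Stop codons are excluded from the denominator; codons containing N are
    skipped.  An internal stop is reported with a warning but frequencies are
    still computed over the sense codons.
    """
    counts = pd.Series(0.0, index=AMINO_ACIDS)
    cods = codons_of(cds)
    for i, codon in enumerate(cods):
        aa = CODON_TO_AA.get(codon)
        if aa is None:  # contains N
            continue
        if aa == "*":
            if i < len(cods) - 1:
                warnings.warn(f"internal stop codon at codon {i + 1}")
            continue
        counts[aa] += 1
    total = counts.sum()
    return counts / total if total > 0 else counts * math.nan


@dataclass
class CodonUsageTable:
    """Pooled codon counts with sense-codon frequencies and RSCU.

    ``rscu`` (normalized relative usage) is frequency x family size / family
    total, so within each synonymous family the mean over observed codons is
    1.  Stop codons form their own 3-codon family.
    """

    counts: pd.Series      # 64 codons
    frequency: pd.Series   # over sense codons only
    rscu: pd.Series        # 64 codons; NaN where the family is unobserved


def codon_usage(cds_collection: Iterable[str],
                pseudocount: float = 0.0) -> CodonUsageTable:
    """Pool codon counts over CDSs and compute frequencies and RSCU."""
    counts = pd.Series(0.0, index=ALL_CODONS)
    n_seqs = 0
    for cds in cds_collection:
        n_seqs += 1
        for codon in codons_of(cds):
            if codon in CODON_TO_AA:
                counts[codon] += 1
    if n_seqs == 0:
        raise ValueError("empty CDS collection")
    return usage_from_counts(counts, pseudocount=pseudocount)


def usage_from_counts(counts: pd.Series,
                      pseudocount: float = 0.0) -> CodonUsageTable:
    """Build a CodonUsageTable from raw per-codon counts."""
    counts = counts.reindex(ALL_CODONS).fillna(0.0).astype(float)
    work = counts + pseudocount
    sense_total = work[SENSE_CODONS].sum()
    frequency = work[SENSE_CODONS] / sense_total if sense_total > 0 else \
        work[SENSE_CODONS] * math.nan
    rscu = pd.Series(math.nan, index=ALL_CODONS)
    for aa, family in SYN_FAMILIES.items():
        fam_total = work[family].sum()
        if fam_total > 0:
            rscu[family] = work[family] * len(family) / fam_total
    return CodonUsageTable(counts=counts, frequency=frequency, rscu=rscu)


def load_reference_usage() -> CodonUsageTable:
    """The bundled human codon-usage reference table (counts per million)."""
    with resources.files("gcfate.data").joinpath("human_codon_usage.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", comment="#")
    counts = df.set_index("codon")["count"].astype(float)
    counts.index = counts.index.str.upper().str.replace("U", "T")
    return usage_from_counts(counts)


def load_trna_weights(path: str | None = None) -> dict[str, float]:
    """Per-codon tRNA weights (tAI convention, max 1) from a TSV.

    Defaults to the bundled *synthetic* weight set, a stand-in scaled from
    codon-usage frequencies that exercises the adaptation score; supply a
    measured table for biological use.
    """
    if path is None:
        fh = resources.files("gcfate.data").joinpath(
            "trna_weights_synthetic.tsv").open()
    else:
        fh = open(path)
    with fh:
        df = pd.read_csv(fh, sep="\t", comment="#")
    weights = df.set_index("codon")["weight"].astype(float)
    weights.index = weights.index.str.upper().str.replace("U", "T")
    if weights.max() <= 0:
        raise ValueError("tRNA weights must contain positive values")
    return (weights / weights.max()).to_dict()


def audit_low_usage_codons(
        table: CodonUsageTable) -> tuple[set[str], dict[str, str]]:
    """Identify biased codons in a transcriptome-scale usage table.

    Returns ``(low_set, lowest_per_aa)`` where ``low_set`` holds every
    synonymous sense codon with RSCU < 1 and ``lowest_per_aa`` maps each of
    the 18 amino acids with >= 2 synonymous codons to its single
    lowest-usage codon (ties broken by lexicographic codon order; amino acids
    entirely unobserved are excluded with a warning).
    """
    low_set: set[str] = set()
    lowest: dict[str, str] = {}
    for aa, family in SYN_FAMILIES.items():
        if aa == "*" or len(family) < 2:
            continue
        vals = table.rscu[family]
        if vals.isna().all() or table.counts[family].sum() == 0:
            warnings.warn(f"amino acid {aa} unobserved; excluded from audit")
            continue
        low_set.update(c for c in family if vals[c] < 1.0)
        lowest[aa] = min(family, key=lambda c: (vals[c], c))
    return low_set, lowest


def low_usage_stats(cds: str, low_codons: set[str]) -> tuple[float, int]:
    """(frequency, count) of low-usage codons among the sense codons of a CDS."""
    sense = [c for c in codons_of(cds) if CODON_TO_AA.get(c, "*") != "*"]
    count = sum(1 for c in sense if c in low_codons)
    return (count / len(sense) if sense else math.nan, count)


def usage_log_ratio(group_in: Iterable[str], group_out: Iterable[str],
                    pseudocount: float = 0.5) -> pd.Series:
    """Per-codon log2 ratio of normalized relative usage between two groups.

    The pseudocount is added to raw counts before normalization so the ratio
    is finite for codons absent from one group.  Stop codons are included as
    their own family.
    """
    t_in = codon_usage(group_in, pseudocount=pseudocount)
    t_out = codon_usage(group_out, pseudocount=pseudocount)
    return np.log2(t_in.rscu / t_out.rscu)


def usage_log_ratio_from_tables(t_in: CodonUsageTable,
                                t_out: CodonUsageTable,
                                pseudocount: float = 0.5) -> pd.Series:
    t_in = usage_from_counts(t_in.counts, pseudocount=pseudocount)
    t_out = usage_from_counts(t_out.counts, pseudocount=pseudocount)
    return np.log2(t_in.rscu / t_out.rscu)


def trna_adaptation(cds: str, weights: Mapping[str, float],
                    floor: float = 1e-4) -> float:
    """Geometric mean of per-codon tRNA weights over sense codons (tAI style).

    Weights follow the tAI convention (normalized to max 1).  A zero weight
    is replaced by ``floor`` with a warning.
    """
    logs = []
    for codon in codons_of(cds):
        if CODON_TO_AA.get(codon, "*") == "*":
            continue
        w = weights.get(codon, math.nan)
        if math.isnan(w):
            continue
        if w <= 0:
            warnings.warn(f"zero tRNA weight for {codon}; floored at {floor}")
            w = floor
        logs.append(math.log(w))
    return math.exp(sum(logs) / len(logs)) if logs else math.nan


@dataclass
class CompositionFeatures:
    """Per-transcript composition metrics keyed by gene."""

    gene_id: str
    transcript_id: str
    gc_mrna: float
    gc_utr5: float
    gc_cds: float
    gc_utr3: float
    gc3: float
    len_mrna: int
    len_utr5: int
    len_cds: int
    len_utr3: int
    low_usage_freq: float
    low_usage_count: int
    trna_adaptation: float


def compute_features(records: Iterable[TranscriptRecord],
                     low_codons: set[str] | None = None,
                     trna_weights: Mapping[str, float] | None = None
                     ) -> pd.DataFrame:
    """Composition feature table (one row per transcript, indexed by gene_id).

    Transcripts whose CDS is empty or out of frame get NaN codon metrics.
    ``low_codons`` defaults to the per-amino-acid lowest-usage set of the
    bundled human reference.
    """
    if low_codons is None:
        _, lowest = audit_low_usage_codons(load_reference_usage())
        low_codons = set(lowest.values())
    rows = []
    for rec in records:
        g_mrna, g_u5, g_cds, g_u3 = region_gc(rec)
        if rec.cds_frame_ok:
            g3 = gc3(rec.cds)
            lu_freq, lu_count = low_usage_stats(rec.cds, low_codons)
            tai = (trna_adaptation(rec.cds, trna_weights)
                   if trna_weights is not None else math.nan)
        else:
            g3, lu_freq, lu_count, tai = math.nan, math.nan, 0, math.nan
        feat = CompositionFeatures(
            gene_id=rec.gene_id, transcript_id=rec.transcript_id,
            gc_mrna=g_mrna, gc_utr5=g_u5, gc_cds=g_cds, gc_utr3=g_u3, gc3=g3,
            len_mrna=len(rec.sequence),
            len_utr5=rec.utr5_span[1] - rec.utr5_span[0],
            len_cds=rec.cds_span[1] - rec.cds_span[0],
            len_utr3=rec.utr3_span[1] - rec.utr3_span[0],
            low_usage_freq=lu_freq, low_usage_count=lu_count,
            trna_adaptation=tai)
        row = vars(feat).copy()
        aa = (amino_acid_frequencies(rec.cds) if rec.cds_frame_ok
              else pd.Series(math.nan, index=AMINO_ACIDS))
        for a in AMINO_ACIDS:
            row[f"aa_{a}"] = aa[a]
        rows.append(row)
    df = pd.DataFrame(rows)
    return df.set_index("gene_id")
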