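"""Synthetic transcriptomes, fate tables, coverage and target sets.

Generators emulate the statistical structure the analysis assumes, with
known ground truth, so every pipeline stage is testable without downloads:

* transcriptomes with controllable region-wise GC composition (CDS GC is
  steered through third-position base probabilities over a fixed human-like
  amino-acid background, mirroring the GC3-centric analyses) and log-normal
  region lengths;
* fate measurements drawn from a Gaussian copula with specified pairwise
  Spearman structure against GC (Pearson parameters use the
  2*sin(pi*rho_s/6) adjustment so rank-correlation targets are hit);
* per-base coverage with an optional 5' skew in a designated gene set;
* GC-biased target sets sampled with exponentially tilted weights calibrated
  so the realized median-GC offset matches the request.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

from .seqfeatures import SYN_FAMILIES, gc_fraction
from .targets import TargetSet
from .transcript_io import AnnotationSet, TranscriptModel, TranscriptRecord

#: human-like amino-acid background frequencies (percent, normalized below)
AA_BACKGROUND = {
    "A": 7.0, "R": 5.6, "N": 3.6, "D": 4.7, "C": 2.3, "Q": 4.8, "E": 7.1,
    "G": 6.6, "H": 2.6, "I": 4.3, "L": 10.0, "K": 5.7, "M": 2.1, "F": 3.7,
    "P": 6.3, "S": 8.3, "T": 5.4, "V": 6.0, "W": 1.2, "Y": 2.7,
}

#: default pairwise Spearman targets of each fate variable against GC,
#: matching the magnitudes the analysis is designed to detect
DEFAULT_SPEARMAN_TARGETS = {
    "pb_enrichment": -0.64,
    "fc_total_ddx6": 0.45,
    "fc_translation_ddx6": -0.53,
    "fc_total_ddx6_k562": 0.59,
    "fc_xrn1": 0.41,
    "fc_pat1b": -0.50,
    "clip_enrichment": 0.41,
    "protein_yield": 0.40,
    "hi_score": -0.20,
    "recomb_rate": 0.15,
}


@dataclass
class SynthSpec:
    """Parameters of the synthetic study.

    GC targets are drawn from a two-component normal mixture emulating the
    wide, mildly bimodal human mRNA GC distribution; region lengths are
    log-normal.  The copula correlation matrix uses a single GC factor:
    corr(i, j) = rho_i * rho_j for fate variables i != j, which is positive
    semi-definite by construction.
    """

    seed: int = 0
    n_genes: int = 500
    # GC mixture (weights, means, sds) and feasibility clip
    gc_weights: tuple[float, float] = (0.55, 0.45)
    gc_means: tuple[float, float] = (0.42, 0.55)
    gc_sds: tuple[float, float] = (0.05, 0.06)
    gc_clip: tuple[float, float] = (0.30, 0.72)
    # log-normal length parameters (log-scale mean, sigma)
    utr5_len: tuple[float, float] = (math.log(150), 0.5)
    cds_codons: tuple[float, float] = (math.log(430), 0.45)
    utr3_len: tuple[float, float] = (math.log(800), 0.6)
    min_codons: int = 20
    gc_tolerance: float = 0.02
    spearman_targets: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SPEARMAN_TARGETS))
    mean_reads: float = 200.0
    skew_fraction: float = 0.05
    #: optional explicit Pearson copula matrix over (gc, *spearman_targets);
    #: overrides the GC-factor construction when given
    copula_matrix: np.ndarray | None = None


def _rng(spec: SynthSpec, tag: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed, tag])


# --- transcriptome ----------------------------------------------------------

def _family_split() -> dict[str, tuple[list[str], list[str]]]:
    """Per amino acid: (AT-ending codons, GC-ending codons)."""
    out = {}
    for aa, fam in SYN_FAMILIES.items():
        if aa == "*":
            continue
        at = [c for c in fam if c[2] in "AT"]
        gc = [c for c in fam if c[2] in "GC"]
        out[aa] = (at, gc)
    return out


_SPLIT = _family_split()
_GC_COUNT = {c: sum(b in "GC" for b in c)
             for fam in SYN_FAMILIES.values() for c in fam}


def _expected_gc(aa_probs: Mapping[str, float], p3: float) -> float:
    """Expected per-codon G+C count under third-base GC probability p3."""
    e = 0.0
    for aa, p in aa_probs.items():
        at, gc = _SPLIT[aa]
        m_at = np.mean([_GC_COUNT[c] for c in at]) if at else None
        m_gc = np.mean([_GC_COUNT[c] for c in gc]) if gc else None
        if m_at is None:
            e += p * m_gc
        elif m_gc is None:
            e += p * m_at
        else:
            e += p * (p3 * m_gc + (1 - p3) * m_at)
    return e


def _solve_p3(aa_probs: Mapping[str, float], target_gc: float) -> float:
    e0, e1 = _expected_gc(aa_probs, 0.0), _expected_gc(aa_probs, 1.0)
    p3 = (3 * target_gc - e0) / (e1 - e0)
    return float(np.clip(p3, 0.02, 0.98))


def _sample_cds(rng: np.random.Generator, n_codons: int, target_gc: float,
                aa_names: list[str], aa_probs: np.ndarray, p3: float) -> str:
    interior = rng.choice(len(aa_names), size=n_codons - 2, p=aa_probs)
    use_gc = rng.random(n_codons - 2) < p3
    within = rng.random(n_codons - 2)
    codons = ["ATG"]
    for idx, g, u in zip(interior, use_gc, within):
        at, gc = _SPLIT[aa_names[idx]]
        pool = (gc if (g and gc) else at) or gc
        codons.append(pool[int(u * len(pool))])
    codons.append("TAA")
    return "".join(codons)


def _sample_utr(rng: np.random.Generator, length: int, gc: float) -> str:
    if length <= 0:
        return ""
    bases = rng.choice(np.array(list("GCAT")), size=length,
                       p=[gc / 2, gc / 2, (1 - gc) / 2, (1 - gc) / 2])
    return "".join(bases)


def synth_transcriptome(spec: SynthSpec
                        ) -> tuple[list[TranscriptRecord], AnnotationSet,
                                   pd.DataFrame]:
    """Generate transcripts with controlled region GC plus ground truth.

    CDSs start with ATG, end with a single TAA and contain no internal stop
    (guaranteed by construction: codons are drawn per amino acid).  Realized
    CDS GC is rejected-and-resampled until within ``gc_tolerance`` of the
    gene's target.  Returns (records, annotation with a toy genomic layout,
    ground-truth table).
    """
    rng = _rng(spec, 1)
    lo, hi = spec.gc_clip
    if lo < 0.25 or hi > 0.85:
        raise ValueError(f"infeasible GC clip {spec.gc_clip}: "
                         "targets must lie in [0.25, 0.85]")
    aa_names = sorted(AA_BACKGROUND)
    aa_probs = np.array([AA_BACKGROUND[a] for a in aa_names])
    aa_probs = aa_probs / aa_probs.sum()
    aa_prob_map = dict(zip(aa_names, aa_probs))

    comp = rng.random(spec.n_genes) < spec.gc_weights[0]
    mu = np.where(comp, spec.gc_means[0], spec.gc_means[1])
    sd = np.where(comp, spec.gc_sds[0], spec.gc_sds[1])
    target_gc = np.clip(rng.normal(mu, sd), lo, hi)

    records, truth_rows = [], []
    ann = AnnotationSet()
    cursor = 1000  # genomic layout cursor on the toy chromosome
    for i in range(spec.n_genes):
        gid, tid = f"G{i:05d}", f"T{i:05d}"
        n_codons = max(spec.min_codons,
                       int(round(rng.lognormal(*spec.cds_codons))))
        len5 = int(round(rng.lognormal(*spec.utr5_len)))
        len3 = int(round(rng.lognormal(*spec.utr3_len)))
        g_cds = float(target_gc[i])
        g5 = float(np.clip(g_cds + 0.10 + rng.normal(0, 0.05), 0.2, 0.9))
        g3 = float(np.clip(g_cds + rng.normal(0, 0.04), 0.2, 0.9))

        p3 = _solve_p3(aa_prob_map, g_cds)
        best, best_err = None, math.inf
        for _ in range(60):
            cds = _sample_cds(rng, n_codons, g_cds, aa_names, aa_probs, p3)
            err = abs(gc_fraction(cds) - g_cds)
            if err < best_err:
                best, best_err = cds, err
            if err <= spec.gc_tolerance:
                break
        cds = best
        seq = _sample_utr(rng, len5, g5) + cds + _sample_utr(rng, len3, g3)
        L = len(seq)
        rec = TranscriptRecord(
            transcript_id=tid, gene_id=gid, sequence=seq,
            utr5_span=(0, len5), cds_span=(len5, len5 + len(cds)),
            utr3_span=(len5 + len(cds), L))
        records.append(rec)

        # toy genomic layout: 1-3 exons, random strand
        n_exons = int(rng.integers(1, 4))
        cuts = sorted(rng.choice(np.arange(1, L), size=n_exons - 1,
                                 replace=False)) if n_exons > 1 else []
        piece_lens = np.diff([0, *cuts, L])
        exons, pos = [], cursor
        for pl in piece_lens:
            exons.append((pos, pos + int(pl)))
            pos += int(pl) + int(rng.integers(50, 500))
        strand = "+" if rng.random() < 0.5 else "-"
        tx = TranscriptModel(transcript_id=tid, gene_id=gid, chrom="chrS",
                             strand=strand, exons=exons, cds_segments=[])
        tx.cds_segments = tx.genomic_segments(len5, len5 + len(cds))
        tx.resolve_spans()
        assert tx.cds_span == rec.cds_span
        ann.add(tx)
        cursor = pos + int(rng.integers(500, 2000))

        truth_rows.append({
            "gene_id": gid, "transcript_id": tid,
            "target_gc_cds": g_cds, "target_gc_utr5": g5, "target_gc_utr3": g3,
            "realized_gc_cds": gc_fraction(cds),
            "len_utr5": len5, "len_cds": len(cds), "len_utr3": len3})
    truth = pd.DataFrame(truth_rows).set_index("gene_id")
    return records, ann, truth


# --- fate table -------------------------------------------------------------

def spearman_to_pearson(rho_s: float) -> float:
    """Pearson parameter of a bivariate Gaussian with given Spearman rho."""
    return 2 * math.sin(math.pi * rho_s / 6)


def _copula_matrix(rhos: np.ndarray) -> np.ndarray:
    """Pearson copula matrix from GC-factor Spearman targets."""
    k = len(rhos) + 1
    s = np.eye(k)
    s[0, 1:] = s[1:, 0] = rhos
    s[1:, 1:] = np.outer(rhos, rhos)
    np.fill_diagonal(s, 1.0)
    p = 2 * np.sin(np.pi * s / 6)
    np.fill_diagonal(p, 1.0)
    return p


DEFAULT_MARGINS = {
    "pb_enrichment": lambda z: 1.5 * z,
    "protein_yield": lambda z: np.exp(0.8 * z),
    "hi_score": lambda z: sps.beta.ppf(sps.norm.cdf(z), 2, 5),
    "recomb_rate": lambda z: sps.gamma.ppf(sps.norm.cdf(z), 2, scale=0.8),
}


def synth_fate(spec: SynthSpec, gc: pd.Series) -> pd.DataFrame:
    """Fate table with specified pairwise Spearman structure against GC.

    The latent Gaussian copula couples the observed GC values (via their
    normal scores) with each fate variable; marginals are normal for log2
    fold-changes, beta for the haplo-insufficiency score, log-normal for
    protein yield and gamma for recombination rates (monotone transforms, so
    rank correlations are preserved).  Derived columns keep the pipeline
    invariants: fc_poly_ddx6 = fc_total_ddx6 + fc_translation_ddx6, and
    translation_rate_fc = fc_poly_ddx6 - fc_total_ddx6.
    """
    rng = _rng(spec, 2)
    names = list(spec.spearman_targets)
    rhos = np.array([spec.spearman_targets[v] for v in names])
    p = (np.asarray(spec.copula_matrix, dtype=float)
         if spec.copula_matrix is not None else _copula_matrix(rhos))
    if p.shape != (len(names) + 1, len(names) + 1):
        raise ValueError(f"copula matrix must be {len(names) + 1} square")
    eigmin = float(np.linalg.eigvalsh(p).min())
    if eigmin < -1e-8:
        raise ValueError(f"copula matrix not PSD (min eigenvalue {eigmin:.3g})")
    L = np.linalg.cholesky(p + 1e-10 * np.eye(len(p)))

    n = len(gc)
    u = (sps.rankdata(gc.to_numpy()) - 0.5) / n
    e = rng.standard_normal((n, len(p)))
    e[:, 0] = sps.norm.ppf(u)
    z = e @ L.T

    df = pd.DataFrame(index=gc.index)
    for j, v in enumerate(names, start=1):
        margin = DEFAULT_MARGINS.get(v, lambda x: 0.8 * x)
        df[v] = margin(z[:, j])
    if {"fc_total_ddx6", "fc_translation_ddx6"} <= set(df.columns):
        df["fc_poly_ddx6"] = df["fc_total_ddx6"] + df["fc_translation_ddx6"]
        df["translation_rate_fc"] = df["fc_translation_ddx6"]
    if "pb_enrichment" in df.columns:
        # proxy significance call on the enrichment magnitude
        df["pb_p"] = 2 * sps.norm.sf(np.abs(df["pb_enrichment"]) / 0.9)
        df["pb_significant"] = df["pb_p"] < 0.05
    return df


# --- coverage ---------------------------------------------------------------

def synth_coverage(spec: SynthSpec, lengths: Mapping[str, int],
                   skew_set: set[str] | None = None,
                   skew: float | None = None) -> dict[str, np.ndarray]:
    """Per-base read depth: uniform background plus optional 5' skew.

    Each transcript receives Poisson(mean_reads) reads placed uniformly;
    for transcripts in ``skew_set`` a Binomial(n, skew) subset is instead
    placed uniformly within the first 10% of positions.
    """
    skew = spec.skew_fraction if skew is None else skew
    if not 0 <= skew < 1:
        raise ValueError("skew must be in [0, 1)")
    skew_set = skew_set or set()
    rng = _rng(spec, 3)
    out: dict[str, np.ndarray] = {}
    for tid in sorted(lengths):
        L = int(lengths[tid])
        n = int(rng.poisson(spec.mean_reads))
        m = int(rng.binomial(n, skew)) if tid in skew_set and n > 0 else 0
        front = max(int(math.ceil(0.1 * L)), 1)
        pos = np.concatenate([rng.integers(0, front, size=m),
                              rng.integers(0, L, size=n - m)])
        out[tid] = np.bincount(pos, minlength=L).astype(float)
    return out


# --- target sets ------------------------------------------------------------

def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values, kind="mergesort")
    v, w = values[order], weights[order]
    cum = np.cumsum(w)
    return float(v[np.searchsorted(cum, 0.5 * cum[-1])])


def _tilt_beta(gc: np.ndarray, target_median: float) -> float:
    if not gc.min() < target_median < gc.max():
        raise ValueError(
            f"unattainable target median {target_median:.3f}; population "
            f"range [{gc.min():.3f}, {gc.max():.3f}]")
    center = np.median(gc)

    def f(beta: float) -> float:
        w = np.exp(np.clip(beta * (gc - center), -700, 700))
        return _weighted_median(gc, w) - target_median

    if abs(f(0.0)) < 1e-12:
        return 0.0
    return float(optimize.brentq(f, -400.0, 400.0, xtol=1e-3))


def synth_target_sets(spec: SynthSpec, gc: pd.Series,
                      set_specs: Sequence[tuple[str, int, float]]
                      ) -> tuple[list[TargetSet], pd.DataFrame]:
    """Sample GC-biased gene sets with requested median-GC offsets.

    ``set_specs`` holds (name, size, offset) with the offset in GC fraction
    relative to the universe median.  Sampling weights are exponential in GC
    with the tilt calibrated so the weighted population median hits the
    requested offset; sets are drawn without replacement (Gumbel top-k).
    Overlap between sets is not prevented.  Returns the sets and a table of
    requested vs realized offsets.
    """
    rng = _rng(spec, 4)
    values = gc.to_numpy(dtype=float)
    ids = gc.index.to_numpy()
    m0 = float(np.median(values))
    sets, rows = [], []
    for name, size, offset in set_specs:
        if size > len(values):
            raise ValueError(f"{name}: size {size} exceeds universe")
        beta = _tilt_beta(values, m0 + offset) if offset != 0 else 0.0
        logw = np.clip(beta * (values - m0), -700, 700)
        keys = logw + rng.gumbel(size=len(values))
        chosen = ids[np.argsort(keys)[::-1][:size]]
        ts = TargetSet(name=name, members=frozenset(map(str, chosen)),
                       source="synthetic")
        realized = float(np.median(gc.loc[list(ts.members)])) - m0
        sets.append(ts)
        rows.append({"name": name, "size": size, "offset_requested": offset,
                     "offset_realized": realized, "beta": beta})
    overlap_warned = False
    for i in range(len(sets)):
        for j in range(i + 1, len(sets)):
            inter = len(sets[i].members & sets[j].members)
            if inter and not overlap_warned:
                overlap_warned = True
    return sets, pd.DataFrame(rows).set_index("name")


def synth_mirnas(spec: SynthSpec, gc: pd.Series, n_mirnas: int = 22,
                 set_size: int = 150, coupling: float = 0.8
                 ) -> list[TargetSet]:
    """miRNAs whose target sets' median GC tracks the miRNA's own GC."""
    rng = _rng(spec, 5)
    m0 = float(gc.median())
    lo = float(gc.quantile(0.05))
    hi = float(gc.quantile(0.95))
    out = []
    for i in range(n_mirnas):
        mir_gc = float(rng.uniform(0.35, 0.65))
        k = int(round(22 * mir_gc))
        bases = np.array(list("G" * (k // 2 + k % 2) + "C" * (k // 2)
                              + "A" * ((22 - k) // 2 + (22 - k) % 2)
                              + "T" * ((22 - k) // 2)))
        rng.shuffle(bases)
        target_med = float(np.clip(m0 + coupling * (mir_gc - 0.5), lo, hi))
        sub_spec = SynthSpec(seed=spec.seed, n_genes=spec.n_genes)
        sub_spec.seed = spec.seed * 1000 + i + 7
        sets, _ = synth_target_sets(sub_spec, gc,
                                    [(f"miR-{i:02d}", set_size,
                                      target_med - m0)])
        out.append(TargetSet(name=f"miR-{i:02d}", members=sets[0].members,
                             source="synthetic-miRTarBase",
                             regulator_sequence="".join(bases)))
    return out
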