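"""Stage orchestration: simulate -> features -> correlate -> metagene -> targets.

Each stage is a plain function over a :class:`RunConfig`; the CLI and the
analysis drivers are thin wrappers.  Every run writes a manifest recording
the package version, seed and SHA-256 of each input and output file, so a
rerun with identical inputs reproduces the manifest byte-identically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import fate_metrics, metagene, seqfeatures, simulate, stats, targets
from . import transcript_io as tio

FLOAT_FMT = "%.6g"


@dataclass
class RunConfig:
    out_dir: Path
    seed: int = 0
    n_genes: int = 300
    fasta: Path | None = None
    annotation: Path | None = None
    annotation_dialect: str = "gtf"
    fate_table: Path | None = None
    coverage: Path | None = None
    min_length: int = 500
    pb_threshold: float = 1.0
    significance: float = 0.05
    histogram_width: float = 0.007
    tendency_bin: int = 500
    n_bins: int = 20

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        cfg = yaml.safe_load(Path(path).read_text()) or {}
        cfg.update(overrides)
        cfg["out_dir"] = Path(cfg["out_dir"])
        for key in ("fasta", "annotation", "fate_table", "coverage"):
            if cfg.get(key):
                cfg[key] = Path(cfg[key])
        return cls(**cfg)

    def validate(self) -> None:
        for key in ("fasta", "annotation", "fate_table", "coverage"):
            p = getattr(self, key)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{key}: {p} does not exist")
        if not 0 < self.histogram_width < 1:
            raise ValueError("histogram_width must be in (0, 1)")
        if self.tendency_bin < 2 or self.n_bins < 2:
            raise ValueError("bin sizes must be >= 2")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(out_dir: Path, seed: int, inputs: dict[str, Path],
                    outputs: dict[str, Path]) -> Path:
    manifest = {
        "tool": "gcfate", "version": __version__, "seed": seed,
        "inputs": {k: _sha256(Path(v)) for k, v in sorted(inputs.items())},
        "outputs": {k: _sha256(Path(v)) for k, v in sorted(outputs.items())},
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def _save(df: pd.DataFrame, path: Path, index: bool = True) -> Path:
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT, index=index)
    return path


def run_simulate(config: RunConfig) -> dict[str, Path]:
    """Generate a full synthetic study bundle in the ingestion formats."""
    out = Path(config.out_dir) / "synth"
    out.mkdir(parents=True, exist_ok=True)
    spec = simulate.SynthSpec(seed=config.seed, n_genes=config.n_genes)
    records, ann, truth = simulate.synth_transcriptome(spec)

    fasta = out / "transcripts.fa"
    tio.write_fasta(((r.transcript_id, r.sequence) for r in records), fasta)
    gtf = out / "annotation.gtf"
    tio.write_gtf(ann, gtf)

    gc = truth["realized_gc_cds"]
    fate = simulate.synth_fate(spec, gc)
    fate_path = _save(fate, out / "fate.tsv")

    lengths = {r.transcript_id: len(r.sequence) for r in records}
    gene_of = {r.transcript_id: r.gene_id for r in records}
    skew_genes = set(fate.sort_values("fc_pat1b").index[:max(config.n_genes // 5, 1)])
    skew_tids = {t for t, g in gene_of.items() if g in skew_genes}
    cov = simulate.synth_coverage(spec, lengths, skew_tids)
    cov_path = out / "coverage.tsv"
    metagene.write_coverage_table(cov, cov_path)

    sets, offsets = simulate.synth_target_sets(
        spec, gc, [("AU-set", max(config.n_genes // 5, 10), -0.04),
                   ("GC-set", max(config.n_genes // 5, 10), 0.04),
                   ("neutral-set", max(config.n_genes // 5, 10), 0.0)])
    sets_dir = out / "targets"
    sets_dir.mkdir(exist_ok=True)
    for ts in sets:
        pd.DataFrame({"gene_id": sorted(ts.members)}).to_csv(
            sets_dir / f"{ts.name}.tsv", sep="\t", index=False)
    _save(offsets, out / "target_truth.tsv")
    _save(truth, out / "transcript_truth.tsv")
    skew_path = out / "skew_genes.tsv"
    pd.DataFrame({"gene_id": sorted(skew_genes)}).to_csv(
        skew_path, sep="\t", index=False)
    return {"fasta": fasta, "annotation": gtf, "fate_table": fate_path,
            "coverage": cov_path, "targets_dir": sets_dir,
            "skew_genes": skew_path}


def _load_study(config: RunConfig):
    seqs = dict(tio.read_transcript_fasta(config.fasta))
    ann = tio.read_annotation(config.annotation, config.annotation_dialect)
    rep = tio.select_representative(ann, min_length=config.min_length)
    records = tio.build_records(rep, seqs)
    return records, rep


def run_features(config: RunConfig) -> Path:
    """Composition feature table for the representative transcripts."""
    config.validate()
    records, _ = _load_study(config)
    feats = seqfeatures.compute_features(
        records, trna_weights=seqfeatures.load_trna_weights())
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return _save(feats, out / "features.tsv")


def run_correlate(config: RunConfig) -> dict[str, Path]:
    """Correlation/binning battery over features joined with the fate table."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    feats = pd.read_csv(out / "features.tsv", sep="\t", index_col="gene_id")
    fate = pd.read_csv(config.fate_table, sep="\t", index_col="gene_id")
    df = fate_metrics.assemble_fate_table(
        {"features": feats, "fate": fate}, pb_threshold=config.pb_threshold)
    overlap = feats.index.intersection(fate.index)
    if len(overlap) < 50:
        import warnings
        warnings.warn(f"gene universe overlap is only {len(overlap)}")

    fate_cols = [c for c in ("pb_enrichment", "fc_total_ddx6", "fc_poly_ddx6",
                             "fc_xrn1", "fc_pat1b", "translation_rate_fc")
                 if c in df.columns]
    paths = {}
    rs = stats.correlation_matrix(df, ["gc_mrna", *fate_cols])
    paths["correlations"] = _save(rs, out / "spearman_matrix.tsv")

    rows = []
    for col in fate_cols:
        plain = stats.spearman(df["gc_mrna"], df[col])
        rows.append({"x": "gc_mrna", "y": col, "controls": "",
                     "rs": plain.rs, "p": plain.p_value, "n": plain.n})
        if "recomb_rate" in df.columns:
            part = stats.partial_spearman(
                df["gc_mrna"], df[col], {"recomb_rate": df["recomb_rate"]})
            rows.append({"x": "gc_mrna", "y": col, "controls": "recomb_rate",
                         "rs": part.rs, "p": part.p_value, "n": part.n})
    paths["partial"] = _save(pd.DataFrame(rows), out / "correlations.tsv",
                             index=False)

    scheme = stats.gc_classes()
    strat = stats.stratified_distribution(
        df.assign(group="all"), "gc_mrna", scheme,
        response=fate_cols[0] if fate_cols else "gc_cds", group="group")
    paths["gc_class_distribution"] = _save(
        strat, out / "gc_class_distribution.tsv", index=False)

    if "pb_class" in df.columns:
        hist = stats.fixed_width_histogram(
            df["gc_mrna"], width=config.histogram_width, groups=df["pb_class"])
        paths["gc_histogram"] = _save(hist, out / "gc_histogram.tsv",
                                      index=False)

    if fate_cols:
        bin_size = min(config.tendency_bin, max(len(df) // 2, 2))
        tend = stats.equal_count_tendency(df["gc_mrna"], df[fate_cols[0]],
                                          bin_size=bin_size)
        paths["tendency"] = _save(tend, out / "tendency.tsv", index=False)
    return paths


def run_metagene(config: RunConfig, target_genes: set[str] | None = None
                 ) -> dict[str, Path]:
    """20-bin coverage profiles and the target-vs-all 5' contrast."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records, _ = _load_study(config)
    lengths = {r.transcript_id: len(r.sequence) for r in records}
    gene_of = {r.transcript_id: r.gene_id for r in records}
    cov = metagene.read_coverage_table(config.coverage, lengths)
    profiles = {t: metagene.bin_coverage(t, d, config.n_bins)
                for t, d in cov.items()}
    prof_df = pd.DataFrame(
        {t: p.bins for t, p in profiles.items() if p.valid}).T
    prof_df.columns = [f"bin{b + 1}" for b in range(config.n_bins)]
    prof_df.index.name = "transcript_id"
    paths = {"profiles": _save(prof_df, out / "profiles.tsv")}
    mean, sd, n = metagene.group_profile(profiles.values())
    gp = pd.DataFrame({"bin": np.arange(1, config.n_bins + 1),
                       "mean": mean, "sd": sd, "n": n})
    paths["group_profile"] = _save(gp, out / "group_profile.tsv", index=False)
    if target_genes:
        tids = [t for t, g in gene_of.items() if g in target_genes]
        contrast = metagene.contrast_profiles(tids, profiles, profiles)
        paths["contrast"] = _save(contrast, out / "contrast.tsv", index=False)
    return paths


def run_targets(config: RunConfig, sets_dir: Path | None = None
                ) -> dict[str, Path]:
    """Target-set medians, GC-ordered heatmap matrix and clustering orders."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    feats = pd.read_csv(out / "features.tsv", sep="\t", index_col="gene_id")
    fate = pd.read_csv(config.fate_table, sep="\t", index_col="gene_id")
    df = fate_metrics.assemble_fate_table({"features": feats, "fate": fate})
    sets_dir = Path(sets_dir) if sets_dir else Path(config.out_dir) / "synth/targets"
    sets = [targets.load_target_set(p, p.stem, source="file")
            for p in sorted(sets_dir.glob("*.tsv"))]
    cols = [c for c in ("pb_enrichment", "fc_total_ddx6", "fc_xrn1",
                        "fc_pat1b", "translation_rate_fc") if c in df.columns]
    mat = targets.heatmap_matrix(sets, df, cols, order_by="gc_mrna")
    paths = {"heatmap": _save(mat, out / "target_heatmap.tsv")}
    cluster_input = df[["gc_mrna", *cols]].dropna()
    sub = cluster_input.sample(n=min(len(cluster_input), 150),
                               random_state=config.seed)
    row_order, col_order, _, _ = targets.cluster_matrix(sub)
    orders = pd.DataFrame({"row_order": pd.Series(row_order, dtype=object),
                           "col_order": pd.Series(col_order, dtype=object)})
    paths["cluster_orders"] = _save(orders, out / "cluster_orders.tsv",
                                    index=False)
    return paths


def run_all(config: RunConfig) -> Path:
    """simulate -> features -> correlate -> metagene -> targets + manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        inputs = run_simulate(config)
        config.fasta = inputs["fasta"]
        config.annotation = inputs["annotation"]
        config.fate_table = inputs["fate_table"]
        config.coverage = inputs["coverage"]
        stage = "features"
        feat_path = run_features(config)
        stage = "correlate"
        outputs = {"features": feat_path, **run_correlate(config)}
        stage = "metagene"
        skew = set(pd.read_csv(inputs["skew_genes"], sep="\t")["gene_id"])
        outputs.update(run_metagene(config, target_genes=skew))
        stage = "targets"
        outputs.update(run_targets(config, sets_dir=inputs["targets_dir"]))
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    file_inputs = {k: v for k, v in inputs.items() if Path(v).is_file()}
    return _write_manifest(out, config.seed, file_inputs, outputs)
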