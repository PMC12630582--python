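"""End-to-end orchestration: genome -> catalog -> libraries -> counts ->
markers -> scores, with a reproducibility manifest.

Every stage writes plain-text artifacts into the output directory and records
them (with SHA-256 digests and the seeds used) in ``manifest.json``.
Deterministic stages are byte-identical across reruns with the same config.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd
import yaml

from . import io as rio
from .markers import cpm_normalize, select_count_markers
from .read_processing import apply_filters, build_cut_site_index, count_fragments, qc_min_fragments
from .reference_catalog import GenomeSequence, Motif, build_catalog
from .scoring import (
    bootstrap_auc_ci,
    detected_marker_count,
    roc_auc,
    sensitivity_at_specificity,
    total_marker_cpm,
)
from .simulate import (
    GenomeSpec,
    LibraryParams,
    MethylomeSpec,
    SpikeInDesign,
    assign_methylation,
    generate_genome,
    simulate_spikein_cohort,
)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Single-file configuration for the full synthetic pipeline."""

    outdir: str = "recap_out"
    seed: int = 0
    fasta: Optional[str] = None  # use an existing reference instead of generating
    islands_bed: Optional[str] = None
    blacklist_bed: Optional[str] = None
    motif: str = "CGCG"
    min_insert: int = 50
    max_insert: int = 300
    genome: GenomeSpec = field(default_factory=GenomeSpec)
    methylome: MethylomeSpec = field(default_factory=MethylomeSpec)
    library: LibraryParams = field(default_factory=LibraryParams)
    spikein: SpikeInDesign = field(default_factory=SpikeInDesign)
    max_failures: int = 0
    qc_min_unique: int = 2000
    lfc_min: float = 5.0
    fdr_max: float = 0.01
    cpm_cutoff: float = 5.0
    n_boot: int = 1000
    spec_target: float = 0.95

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        for key, typ in (
            ("genome", GenomeSpec),
            ("methylome", MethylomeSpec),
            ("library", LibraryParams),
            ("spikein", SpikeInDesign),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                sub = dict(kwargs[key])
                if key == "spikein" and "fractions" in sub:
                    sub["fractions"] = tuple(sub["fractions"])
                kwargs[key] = typ(**sub)
        cfg = cls(**kwargs)
        # a single top-level seed threads through every stochastic stage
        cfg.genome = replace(cfg.genome, seed=cfg.seed)
        cfg.library = replace(cfg.library, seed=cfg.seed)
        cfg.spikein = replace(cfg.spikein, seed=cfg.seed)
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> Dict:
    """Execute all stages in dependency order; return the artifact manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: Dict = {"seed": config.seed, "stages": {}}
    manifest_path = out / "manifest.json"

    def record(stage: str, files: List[Path], **extra) -> None:
        manifest["stages"][stage] = {
            "outputs": {str(p.relative_to(out)): _sha256(p) for p in files},
            **extra,
        }
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    # --- reference stage -------------------------------------------------
    if config.fasta is not None:
        fasta = Path(config.fasta)
        if not fasta.exists():
            raise FileNotFoundError(f"reference stage: FASTA not found: {fasta}")
        genome = GenomeSequence.from_fasta(fasta)
        islands = rio.read_bed(config.islands_bed) if config.islands_bed else []
        from .simulate import GenomeIndex

        cpg_sites = GenomeIndex(genome).cpg_pos
        record("reference", [], source=str(fasta))
    else:
        genome, islands, cpg_sites = generate_genome(config.genome)
        fasta = out / "genome.fa"
        genome.to_fasta(fasta)
        islands_bed = out / "islands.bed"
        rio.write_bed(islands, islands_bed)
        record("reference", [fasta, islands_bed], seed=config.genome.seed)

    # --- catalog stage ---------------------------------------------------
    blacklist = rio.read_bed(config.blacklist_bed) if config.blacklist_bed else []
    catalog = build_catalog(
        genome,
        Motif.from_sequence(config.motif),
        min_insert=config.min_insert,
        max_insert=config.max_insert,
        blacklist=blacklist,
    )
    if not catalog:
        raise RuntimeError("catalog stage: no fragments retained")
    catalog_path = out / "catalog.tsv"
    rio.write_catalog(catalog, catalog_path)
    record("catalog", [catalog_path], n_fragments=len(catalog))

    # --- simulate stage --------------------------------------------------
    beta_n, markers_truth = assign_methylation(
        cpg_sites, islands, replace(config.methylome, class_label="normal"), config.seed
    )
    beta_t, _ = assign_methylation(
        cpg_sites, islands, replace(config.methylome, class_label="tumor"), config.seed
    )
    samples, truth = simulate_spikein_cohort(
        genome, beta_n, beta_t, config.spikein, config.library, catalog
    )
    truth_path = out / "truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    truth_bed = out / "marker_islands.bed"
    rio.write_bed(markers_truth, truth_bed)
    reads_dir = out / "reads"
    reads_dir.mkdir(exist_ok=True)
    read_files = []
    for sid, reads in samples.items():
        p = reads_dir / f"{sid}.reads.tsv"
        rio.write_reads_tsv(reads, p)
        read_files.append(p)
    record("simulate", [truth_path, truth_bed] + read_files, seed=config.spikein.seed)

    # --- process stage ---------------------------------------------------
    index = build_cut_site_index(catalog)
    filtered = {}
    acct_rows = []
    for sid, reads in samples.items():
        kept, acct = apply_filters(reads, index, config.max_failures)
        filtered[sid] = kept
        acct_rows.append({"sample_id": sid, "input_reads": len(reads), **acct})
    matrix = count_fragments(filtered, catalog)
    counts_path, sizes_path = out / "counts.tsv", out / "library_sizes.tsv"
    matrix.to_tsv(counts_path, sizes_path)
    qc = qc_min_fragments(matrix, config.qc_min_unique)
    qc_path = out / "qc.tsv"
    qc.rename("pass").rename_axis("sample_id").to_csv(qc_path, sep="\t")
    acct_path = out / "filter_accounting.tsv"
    pd.DataFrame(acct_rows).fillna(0).to_csv(acct_path, sep="\t", index=False)
    record("process", [counts_path, sizes_path, qc_path, acct_path])

    # --- markers stage ---------------------------------------------------
    fr = truth.set_index("sample_id")["fraction"]
    group1 = list(fr.index[fr == 0])
    group2 = list(fr.index[fr == fr.max()])
    if not group1 or not group2 or fr.max() == 0:
        raise RuntimeError("markers stage: need baseline (fraction 0) and spike-in samples")
    table = select_count_markers(
        matrix, group1, group2, lfc_min=config.lfc_min, fdr_max=config.fdr_max
    )
    markers_path = out / "markers.tsv"
    table.to_csv(markers_path, sep="\t", index=False)
    selected = table.loc[table["selected"], "fragment_id"].tolist()
    record("markers", [markers_path], n_selected=len(selected))

    # --- score stage -----------------------------------------------------
    cpm = cpm_normalize(matrix)
    scores = total_marker_cpm(cpm, selected)
    detected = detected_marker_count(cpm, selected, config.cpm_cutoff)
    labels = pd.Series(
        ["cancer" if fr[s] > 0 else "healthy" for s in scores.index], index=scores.index
    )
    score_table = pd.DataFrame(
        {"sample_id": scores.index, "total_cpm": scores.values,
         "detected_markers": detected.reindex(scores.index).values, "label": labels.values}
    )
    scores_path = out / "scores.tsv"
    score_table.to_csv(scores_path, sep="\t", index=False)
    metrics: Dict[str, float] = {}
    if labels.nunique() == 2 and selected:
        auc = roc_auc(scores.values, labels.values)
        lo, hi = bootstrap_auc_ci(
            scores.values, labels.values, n_boot=config.n_boot, seed=config.seed
        )
        sens = sensitivity_at_specificity(scores.values, labels.values, config.spec_target)
        metrics = {"auc": auc, "ci_low": lo, "ci_high": hi,
                   f"sens_at_spec_{config.spec_target:g}": sens}
    metrics_path = out / "metrics.tsv"
    pd.DataFrame([metrics]).to_csv(metrics_path, sep="\t", index=False)
    record("score", [scores_path, metrics_path], **metrics)

    return manifest
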