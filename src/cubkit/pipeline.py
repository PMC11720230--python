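"""End-to-end per-species and cross-species analysis.

``run_full_analysis`` drives the whole method in order: filter each
species' CDS FASTA, compute per-gene indices, RSCU, the ENC-GC3s /
PR2 / neutrality diagnostics, the index-correlation matrix,
correspondence analysis, and optimal codons; then pool species into
usage profiles, compute distance matrices, and cluster.  Every stage is
deterministic (no unseeded randomness), so reruns on identical inputs are
checksum-identical.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .codon_metrics import (
    compute_gene_indices,
    count_codons,
    pool_counts,
    rscu,
)
from .comparative_clustering import (
    euclidean_distance_matrix,
    hierarchical_clustering,
    species_profile,
)
from .genetic_code import CODON_TO_AA, STOP_CODONS, SYNONYMOUS_CODONS
from .multivariate import correspondence_analysis, gc_class_labels, rscu_matrix
from .optimal_codons import (
    delta_rscu,
    high_frequency_codons,
    split_expression_libraries,
)
from .selection_analyses import (
    bin_enc_deviations,
    enc_deviation,
    expected_enc,
    index_correlation_matrix,
    neutrality_regression,
    pr2_coordinates,
)
from .sequence_io import filter_cds, read_cds_fasta, write_filter_report

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_full_analysis"]

_FLOAT_FMT = "%.6g"


@dataclass
class RunConfig:
    """Parameters of one full analysis run."""

    species: dict[str, str]  # label -> FASTA path
    output_dir: str
    min_len: int = 300
    expression_fraction: float = 0.10
    delta_rscu_threshold: float = 0.08
    pr2_fourfold_only: bool = True
    linkage: str = "average"
    correlation_method: str = "pearson"
    ca_max_missing_families: int = 10
    subset_ids: dict[str, str] | None = None  # label -> gene-ID list file
    make_plots: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.species:
            raise ValueError("config must name at least one species")
        if self.min_len <= 0 or self.expression_fraction <= 0 or self.delta_rscu_threshold <= 0:
            raise ValueError("thresholds must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT)


def _analyze_species(label: str, fasta: Path, out: Path, cfg: RunConfig) -> tuple[dict, list]:
    out.mkdir(parents=True, exist_ok=True)
    records = read_cds_fasta(fasta)
    if cfg.subset_ids and label in cfg.subset_ids:
        with open(cfg.subset_ids[label]) as fh:
            wanted = {line.strip() for line in fh if line.strip()}
        records = [r for r in records if r[0] in wanted]
    kept, report = filter_cds(records, min_len=cfg.min_len)
    write_filter_report(report, [c.gene_id for c in kept], out / "filter_report.tsv")
    logger.info("%s: %d/%d CDS kept", label, report.kept_count, report.input_count)
    if not kept:
        raise ValueError(f"{label}: no sequences passed filtering")

    indices = compute_gene_indices(kept, reference_fraction=cfg.expression_fraction)
    _write(indices, out / "gene_indices.tsv")

    tables = {c.gene_id: count_codons(c) for c in kept}
    pooled = pool_counts(tables.values(), source=label)

    # pooled RSCU over 59 codons + pooled stop usage
    pooled_rscu = rscu(pooled, include_stops=True)
    rscu_rows = [
        {"codon": c, "amino_acid": CODON_TO_AA[c], "rscu": pooled_rscu[c]}
        for c in list(SYNONYMOUS_CODONS) + list(STOP_CODONS)
    ]
    _write(pd.DataFrame(rscu_rows), out / "rscu.tsv")
    _write(
        pd.DataFrame(
            [{"codon": c, "rscu": pooled_rscu[c]} for c in STOP_CODONS]
        ),
        out / "stop_codon_rscu.tsv",
    )

    # ENC-GC3s plot table and deviation bins
    enc_tbl = indices[["gene_id", "GC3s", "ENC"]].copy()
    enc_tbl["ENC_expected"] = [
        expected_enc(s) if not math.isnan(s) else math.nan for s in enc_tbl["GC3s"]
    ]
    enc_tbl["deviation"] = [
        enc_deviation(e, s) for e, s in zip(enc_tbl["ENC"], enc_tbl["GC3s"])
    ]
    _write(enc_tbl, out / "enc_gc3s.tsv")
    bins = bin_enc_deviations(enc_tbl["deviation"].to_numpy())
    _write(bins.to_frame(), out / "enc_deviation_bins.tsv")

    # PR2 per gene
    pr2_rows = []
    for gid, t in tables.items():
        at_bias, gc_bias = pr2_coordinates(t, fourfold_only=cfg.pr2_fourfold_only)
        pr2_rows.append({"gene_id": gid, "at_bias": at_bias, "gc_bias": gc_bias})
    _write(pd.DataFrame(pr2_rows), out / "pr2.tsv")

    # neutrality regression
    points = indices[["GC12", "GC3"]].to_numpy()
    reg = neutrality_regression(points)
    _write(pd.DataFrame([asdict(reg)]), out / "neutrality_stats.tsv")
    _write(indices[["gene_id", "GC12", "GC3"]], out / "neutrality.tsv")

    # index correlations
    r_mat, p_mat = index_correlation_matrix(indices, method=cfg.correlation_method)
    _write(r_mat, out / "correlation_r.tsv", index=True)
    _write(p_mat, out / "correlation_p.tsv", index=True)

    # correspondence analysis
    mat = rscu_matrix(list(tables.values()), max_missing_families=cfg.ca_max_missing_families)
    coa = correspondence_analysis(mat, n_axes=4)
    row_coords = coa.row_coordinates.copy()
    gc_by_gene = indices.set_index("gene_id")["GC"]
    row_coords["gc_class"] = gc_class_labels(
        gc_by_gene.reindex(row_coords.index).to_numpy())
    _write(row_coords, out / "ca_row_coordinates.tsv", index=True)
    _write(coa.column_coordinates, out / "ca_column_coordinates.tsv", index=True)
    inertia = pd.DataFrame({
        "axis": [f"axis{i+1}" for i in range(len(coa.inertia_fraction))],
        "inertia_fraction": coa.inertia_fraction,
        "cumulative_fraction": coa.cumulative_fraction,
    })
    _write(inertia, out / "ca_inertia.tsv")

    # optimal codons
    gene_enc = list(zip(indices["gene_id"], indices["ENC"]))
    libs = split_expression_libraries(gene_enc, fraction=cfg.expression_fraction)
    high_pool = pool_counts((tables[g] for g in libs.high_expression), "high")
    low_pool = pool_counts((tables[g] for g in libs.low_expression), "low")
    opt = delta_rscu(high_pool, low_pool, threshold=cfg.delta_rscu_threshold)
    _write(opt.reset_index(), out / "optimal_codons.tsv")
    top5 = high_frequency_codons({c: pooled_rscu[c] for c in SYNONYMOUS_CODONS})[:5]
    _write(
        pd.DataFrame(top5, columns=["codon", "rscu"]),
        out / "high_frequency_top5.tsv",
    )

    if cfg.make_plots:
        _species_plots(label, indices, enc_tbl, pd.DataFrame(pr2_rows), reg,
                       row_coords, out)

    summary = {
        "label": label,
        "input_count": report.input_count,
        "kept": report.kept_count,
        "optimal_codon_count": int(opt["optimal"].sum()),
        "neutrality_slope": reg.slope,
    }
    return summary, kept


def _species_plots(label, indices, enc_tbl, pr2_tbl, reg, row_coords, out: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    s = np.linspace(0.0, 1.0, 200)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(enc_tbl["GC3s"], enc_tbl["ENC"], s=4, alpha=0.4)
    ax.plot(s, [expected_enc(v) for v in s], color="purple")
    ax.set(xlabel="GC3s", ylabel="ENC", title=f"{label}: ENC-GC3s")
    fig.savefig(out / "enc_plot.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(pr2_tbl["gc_bias"], pr2_tbl["at_bias"], s=4, alpha=0.4)
    ax.axhline(0.5, color="grey", lw=0.8)
    ax.axvline(0.5, color="grey", lw=0.8)
    ax.set(xlabel="G3/(G3+C3)", ylabel="A3/(A3+T3)", title=f"{label}: PR2")
    fig.savefig(out / "pr2_plot.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(indices["GC3"], indices["GC12"], s=4, alpha=0.4)
    xs = np.linspace(indices["GC3"].min(), indices["GC3"].max(), 2)
    ax.plot(xs, reg.intercept + reg.slope * xs, color="purple")
    ax.set(xlabel="GC3", ylabel="GC12",
           title=f"{label}: neutrality (slope={reg.slope:.3f})")
    fig.savefig(out / "neutrality_plot.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 4))
    for cls, color in zip(("<45%", "45-60%", ">60%"), ("purple", "green", "red")):
        sub = row_coords[row_coords["gc_class"] == cls]
        ax.scatter(sub["axis1"], sub["axis2"], s=5, alpha=0.5, label=cls, color=color)
    ax.legend(title="GC class", fontsize=7)
    ax.set(xlabel="axis 1", ylabel="axis 2", title=f"{label}: CA of RSCU")
    fig.savefig(out / "ca_plot.png", dpi=120)
    plt.close(fig)


def run_full_analysis(config: RunConfig) -> Path:
    """Run the whole analysis; returns the report directory.

    Missing input files fail fast; a failure inside one species' analysis
    is logged and the remaining species continue.  Cross-species outputs
    are produced for the species that succeeded.
    """
    out_root = Path(config.output_dir)
    out_root.mkdir(parents=True, exist_ok=True)

    fasta_paths = {}
    for label, path in config.species.items():
        p = Path(path)
        if not p.exists():
            raise FileNotFoundError(f"input FASTA for {label!r} not found: {p}")
        fasta_paths[label] = p

    summaries = []
    kept_by_species = {}
    for label in sorted(fasta_paths):
        try:
            summary, kept = _analyze_species(
                label, fasta_paths[label], out_root / label, config)
            summaries.append(summary)
            kept_by_species[label] = kept
        except Exception:
            logger.exception("species %s failed; continuing", label)

    if len(kept_by_species) >= 2:
        profiles = [
            species_profile(genes, label)
            for label, genes in sorted(kept_by_species.items())
        ]
        summary_df = pd.DataFrame([
            {"species": p.label, "gene_count": p.gene_count,
             "mean_GC": p.mean_gc, "mean_GC3": p.mean_gc3,
             "mean_GC3s": p.mean_gc3s}
            for p in profiles
        ])
        _write(summary_df, out_root / "species_summary.tsv")
        for feature in ("rscu59", "gc3"):
            D = euclidean_distance_matrix(profiles, feature=feature)
            _write(D, out_root / f"distance_{feature}.tsv", index=True)
        tree = hierarchical_clustering(
            euclidean_distance_matrix(profiles, feature="rscu59"),
            linkage=config.linkage,
        )
        (out_root / "rscu_tree.nwk").write_text(tree.newick + "\n")

    manifest = {
        "cubkit_version": __version__,
        "parameters": {
            k: v for k, v in asdict(config).items() if k != "species"
        },
        "species": {
            label: {"path": str(p), "sha256": _sha256(p)}
            for label, p in fasta_paths.items()
        },
        "per_species_summary": summaries,
    }
    with open(out_root / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return out_root
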