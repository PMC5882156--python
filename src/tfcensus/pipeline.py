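"""End-to-end orchestration: hits -> census -> lifestyle -> promiscuity -> enrichment.

All stage outputs are tab-separated tables under the configured output
directory, each prefixed with ``#`` metadata lines carrying the config
hash, plus a JSON run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import abundance as ab
from . import enrichment as en
from . import lifestyle as ls
from . import promiscuity as pr
from . import refdata
from .io_model import (
    LIFESTYLES,
    DomainHit,
    FamilyCatalog,
    GenomeRecord,
    ProteinArchitecture,
    assemble_architectures,
    filter_hits,
    read_assignment_file,
    read_metadata,
    write_architectures_tsv,
)

logger = logging.getLogger(__name__)

_RESERVED_FILES = {"metadata.tsv", "catalog.tsv", "truth.tsv"}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    input_dir: str
    output_dir: str
    metadata_path: str | None = None       # default: <input_dir>/metadata.tsv
    catalog_path: str | None = None        # default: <input_dir>/catalog.tsv
    dbd_e_max: float = 1e-4
    dbd_min_cov: float = 0.60
    sf_e_max: float = 1e-3
    enrich_alpha: float = 1e-10
    enrich_threshold_on: str = "adjusted"
    adjacency_mode: str = pr.ADJACENCY_ADJACENT
    cv_strict: bool = False
    cv_include_absent: bool = True
    clustering_metric: str = "manhattan"
    cluster_normalize_rows: bool = True
    seed: int = 0
    figures: bool = False

    def __post_init__(self) -> None:
        for name in ("dbd_e_max", "sf_e_max", "enrich_alpha"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 <= self.dbd_min_cov <= 1.0:
            raise ValueError("dbd_min_cov must be in [0, 1]")
        if self.metadata_path is None:
            self.metadata_path = str(Path(self.input_dir) / "metadata.tsv")
        if self.catalog_path is None:
            self.catalog_path = str(Path(self.input_dir) / "catalog.tsv")

    @property
    def config_hash(self) -> str:
        """Hash of the analytic parameters only (paths excluded), so the
        same analysis rerun elsewhere produces identical output bytes."""
        params = asdict(self)
        for key in ("input_dir", "output_dir", "metadata_path", "catalog_path"):
            params.pop(key)
        payload = json.dumps(params, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with Path(path).open(encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        data.update(overrides)
        return cls(**data)


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def _hits_dir(config: PipelineConfig) -> Path:
    base = Path(config.input_dir)
    sub = base / "assignments"
    return sub if sub.is_dir() else base


def _hit_files(config: PipelineConfig) -> list[Path]:
    return sorted(
        p for p in _hits_dir(config).glob("*.tsv") if p.name not in _RESERVED_FILES
    )


def validate_inputs(config: PipelineConfig) -> ValidationReport:
    """Non-fatal input validation: presence, vocabulary, cross-references."""
    report = ValidationReport()
    meta_path = Path(config.metadata_path)
    if not meta_path.exists():
        report.errors.append(f"metadata file missing: {meta_path}")
        return report
    if not Path(config.catalog_path).exists():
        report.errors.append(f"catalog file missing: {config.catalog_path}")
        return report

    genomes: list[GenomeRecord] = []
    import csv

    with meta_path.open(encoding="utf-8") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#") or row[0] == "genome_id":
                continue
            if len(row) < 4:
                report.errors.append(f"metadata row too short: {row}")
                continue
            if row[3] not in LIFESTYLES:
                report.errors.append(
                    f"genome {row[0]}: lifestyle {row[3]!r} outside closed vocabulary"
                )
                continue
            try:
                genomes.append(GenomeRecord(row[0], row[1], int(row[2]), row[3]))
            except ValueError as exc:
                report.errors.append(str(exc))

    files = _hit_files(config)
    if not files:
        report.warnings.append(f"no assignment files found under {_hits_dir(config)}")
    meta_ids = {g.genome_id for g in genomes}
    file_ids = {p.stem for p in files}
    for gid in sorted(file_ids - meta_ids):
        report.warnings.append(f"assignment file {gid} has no metadata row")
    for gid in sorted(meta_ids - file_ids):
        report.warnings.append(f"genome {gid} has no assignment file")

    seen_proteins: set[tuple[str, str, str, int]] = set()
    for path in files:
        for hit in read_assignment_file(path):
            key = (hit.genome_id, hit.protein_id, hit.model_id, hit.start)
            if key in seen_proteins:
                report.warnings.append(
                    f"duplicate hit row {key} in {path.name}"
                )
            seen_proteins.add(key)
    return report


def load_inputs(
    config: PipelineConfig,
) -> tuple[list[GenomeRecord], list[DomainHit], FamilyCatalog]:
    genomes = read_metadata(config.metadata_path)
    catalog = FamilyCatalog.from_tsv(config.catalog_path)
    hits: list[DomainHit] = []
    for path in _hit_files(config):
        hits.extend(read_assignment_file(path, genome_id=path.stem))
    return genomes, hits, catalog


def _write_tsv(path: Path, df: pd.DataFrame, config: PipelineConfig, **to_csv_kwargs) -> None:
    with path.open("w", encoding="utf-8", newline="") as fh:
        fh.write(f"# tfcensus config_hash={config.config_hash}\n")
        df.to_csv(fh, sep="\t", **to_csv_kwargs)


def _cd_length_stats(
    architectures: Sequence[ProteinArchitecture], family: str
) -> tuple[float, float]:
    lengths = [
        seg.length
        for arch in architectures
        if family in arch.all_families and not arch.is_multi_family
        for seg in arch.segments
        if seg.family_id is None
    ]
    if not lengths:
        return float("nan"), float("nan")
    a = np.asarray(lengths, dtype=float)
    return float(a.mean()), float(a.std(ddof=1)) if a.size > 1 else 0.0


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the run manifest (also written to disk).

    Any stage failure raises :class:`PipelineError` naming the stage.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": asdict(config),
        "config_hash": config.config_hash,
        "stages": {},
    }

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - report stage + cause
                raise PipelineError(name, exc) from exc
        return deco

    @stage("io")
    def _io():
        genomes, raw_hits, catalog = load_inputs(config)
        hits = filter_hits(
            raw_hits, config.dbd_e_max, config.dbd_min_cov, config.sf_e_max
        )
        archs = assemble_architectures(hits, catalog)
        write_architectures_tsv(outdir / "architectures.tsv", archs)
        manifest["stages"]["io"] = {
            "n_genomes": len(genomes),
            "n_raw_hits": len(raw_hits),
            "n_filtered_hits": len(hits),
            "n_proteins": len(archs),
        }
        return genomes, hits, catalog, archs

    genomes, hits, catalog, archs = _io

    @stage("abundance")
    def _abundance():
        counts = ab.count_families(archs, catalog, genomes)
        _write_tsv(outdir / "abundance_matrix.tsv", counts, config, index_label="family")
        summary = ab.family_summary(counts, genomes)
        means = dict(summary["per_genome_mean"])
        try:
            groups = ab.abundance_groups(means, mode="fixed")
        except ValueError:
            groups = ab.abundance_groups(means, mode="rank")
        summary["abundance_group"] = [groups[f] for f in summary.index]
        _write_tsv(outdir / "family_summary.tsv", summary, config)
        manifest["stages"]["abundance"] = {
            "grand_total": int(counts.to_numpy().sum()),
            "family_totals": {f: int(t) for f, t in summary["total"].items()},
        }
        return counts, summary

    counts, summary = _abundance

    @stage("lifestyle")
    def _lifestyle():
        summaries = ls.tf_proportions(counts, genomes)
        rows = pd.DataFrame(
            [
                {
                    "lifestyle": s.lifestyle,
                    "n_genomes": s.n_genomes,
                    "median": s.median,
                    "min": s.minimum,
                    "max": s.maximum,
                    "n_outliers": len(s.outliers),
                }
                for s in summaries.values()
            ]
        ).set_index("lifestyle")
        _write_tsv(outdir / "lifestyle_summary.tsv", rows, config)
        groups = [s.proportions for s in summaries.values()]
        h_stat, p_value = ls.kruskal_wallis(groups) if len(groups) >= 2 else (float("nan"),) * 2
        rates = ls.family_lifestyle_rates(counts, genomes)
        _write_tsv(outdir / "family_lifestyle_rates.tsv", rates, config, index_label="family")
        if rates.shape[0] >= 2 and rates.shape[1] >= 1:
            clust = ls.cluster_families(
                rates,
                metric=config.clustering_metric,
                normalize_rows=config.cluster_normalize_rows,
            )
            (outdir / "family_dendrogram.nwk").write_text(
                clust.newick + "\n", encoding="utf-8"
            )
        manifest["stages"]["lifestyle"] = {
            "kruskal_H": h_stat,
            "kruskal_p": p_value,
            "n_lifestyles": len(summaries),
            "clustering_metric": config.clustering_metric,
            "rows_normalized": config.cluster_normalize_rows,
        }
        return summaries

    _lifestyle

    @stage("promiscuity")
    def _promiscuity():
        scores = pr.compute_scores(archs, genomes, catalog, mode=config.adjacency_mode)
        _write_tsv(outdir / "ws_scores.tsv", scores, config, index=False)
        # wide S2-style table: one row per organism, one WS column per family
        wide = scores.pivot_table(
            index="genome_id", values="WS", columns="family", fill_value=0.0
        )
        orgs = {g.genome_id: g.organism_name for g in genomes}
        wide.insert(0, "organism", [orgs.get(g, g) for g in wide.index])
        wide.insert(1, "total_tfs", counts.sum(axis=0).reindex(wide.index).astype(int))
        _write_tsv(outdir / "ws_scores_wide.tsv", wide, config)

        classes = []
        cd_rows = []
        extraction_by_family = {}
        for fam in catalog.families:
            extraction = pr.extract_cds(archs, fam, mode=config.adjacency_mode)
            extraction_by_family[fam] = extraction
            vec = pr.ws_vector(scores, fam, genomes, include_absent=config.cv_include_absent)
            if vec.size >= 2 and np.any(vec != 0):
                cls = pr.classify_promiscuity(
                    vec, family=fam, strict=config.cv_strict,
                    n_distinct_cds=len(extraction.global_cds),
                )
            else:
                cls = pr.PromiscuityClass(
                    fam, float("nan"), pr.CLASS_UNDEFINED, len(extraction.global_cds)
                )
            classes.append(cls)
            mean_len, sd_len = _cd_length_stats(archs, fam)
            cd_rows.append(
                {
                    "family": fam,
                    "n_distinct_cds": len(extraction.global_cds),
                    "cd_mean_length": mean_len,
                    "cd_length_sd": sd_len,
                }
            )
        class_df = pd.DataFrame(
            [
                {
                    "family": c.family,
                    "cv": c.cv,
                    "class": c.label,
                    "n_distinct_cds": c.n_distinct_cds,
                }
                for c in classes
            ]
        ).set_index("family")
        _write_tsv(outdir / "promiscuity_classes.tsv", class_df, config)
        cd_df = pd.DataFrame(cd_rows).set_index("family")
        _write_tsv(outdir / "cd_catalog.tsv", cd_df, config)

        tf_archs = [a for a in archs if a.dbd_family is not None]
        census = pr.architecture_census(tf_archs) if tf_archs else (float("nan"),) * 3
        all_cds = frozenset().union(
            *(e.global_cds for e in extraction_by_family.values())
        ) if extraction_by_family else frozenset()
        manifest["stages"]["promiscuity"] = {
            "census_monodomain": census[0],
            "census_two_domain": census[1],
            "census_multidomain": census[2],
            "n_distinct_cds_total": len(all_cds),
            "adjacency_mode": config.adjacency_mode,
        }
        sizes = [g.n_orfs for g in genomes]
        if len(set(sizes)) >= 2:
            scheme = pr.bin_genomes(sizes)
            manifest["stages"]["promiscuity"]["sturges_k"] = scheme.k
            manifest["stages"]["promiscuity"]["bin_width"] = scheme.c
        return scores, class_df, cd_df

    scores, class_df, cd_df = _promiscuity

    @stage("enrichment")
    def _enrichment():
        results = en.enrich_all(
            archs, catalog,
            alpha=config.enrich_alpha,
            threshold_on=config.enrich_threshold_on,
        )
        res_df = pd.DataFrame(
            [
                {
                    "family": r.family, "cd": r.cd_model,
                    "a": r.a, "b": r.b, "c": r.c, "d": r.d,
                    "p_raw": r.p_raw, "p_adj": r.p_adj,
                    "enriched": r.enriched, "unique": r.unique,
                }
                for r in results
            ],
            columns=["family", "cd", "a", "b", "c", "d", "p_raw", "p_adj",
                     "enriched", "unique"],
        )
        _write_tsv(outdir / "enrichment.tsv", res_df, config, index=False)
        sets = en.enriched_cd_sets(results, families=catalog.families)
        counts_df = pd.DataFrame(
            {"n_enriched_cds": {f: len(s) for f, s in sets.items()}}
        )
        counts_df.index.name = "family"
        _write_tsv(outdir / "enriched_counts_per_family.tsv", counts_df, config)
        sharing = pr.cd_sharing(sets)
        _write_tsv(outdir / "sharing_matrix.tsv", sharing, config, index_label="family")
        manifest["stages"]["enrichment"] = {
            "n_tests": len(results),
            "n_enriched": int(sum(r.enriched for r in results)),
            "alpha": config.enrich_alpha,
            "threshold_on": config.enrich_threshold_on,
        }
        return res_df, counts_df

    res_df, enriched_counts = _enrichment

    @stage("report")
    def _report():
        report = summary.copy()
        report["n_distinct_cds"] = cd_df["n_distinct_cds"]
        report["cd_mean_length"] = cd_df["cd_mean_length"]
        report["cd_length_sd"] = cd_df["cd_length_sd"]
        report["n_enriched_cds"] = enriched_counts["n_enriched_cds"]
        report["cv"] = class_df["cv"]
        report["promiscuity_class"] = class_df["class"]
        _write_tsv(outdir / "family_report.tsv", report, config)
        manifest["stages"]["report"] = {"n_families": int(report.shape[0])}
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )

    _report

    if config.figures:
        _make_figures(config, outdir, counts, genomes)
    return manifest


def _make_figures(config, outdir: Path, counts: pd.DataFrame, genomes) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    summaries = ls.tf_proportions(counts, genomes)
    fig, ax = plt.subplots(figsize=(6, 4))
    labels = list(summaries)
    ax.boxplot([summaries[l].proportions for l in labels], tick_labels=labels)
    ax.set_ylabel("TF proportion (TFs / ORFs)")
    fig.tight_layout()
    fig.savefig(outdir / "tf_proportions_boxplot.png", dpi=150)
    plt.close(fig)

    rates = ls.family_lifestyle_rates(counts, genomes)
    if rates.size:
        fig, ax = plt.subplots(figsize=(5, 7))
        norm = rates.div(rates.max(axis=1).replace(0, 1), axis=0)
        im = ax.imshow(norm.to_numpy(), aspect="auto", cmap="viridis")
        ax.set_xticks(range(rates.shape[1]), rates.columns, rotation=45, ha="right")
        ax.set_yticks(range(rates.shape[0]), rates.index)
        fig.colorbar(im, ax=ax, label="relative rate")
        fig.tight_layout()
        fig.savefig(outdir / "family_lifestyle_heatmap.png", dpi=150)
        plt.close(fig)


__all__ = [
    "PipelineConfig", "PipelineError", "ValidationReport",
    "validate_inputs", "load_inputs", "run_pipeline",
]
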