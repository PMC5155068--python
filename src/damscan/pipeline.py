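"""End-to-end orchestration: scan -> ingest -> transform -> detect ->
temporal -> patterns -> enrich, with a machine-readable run manifest.

Each stage is also exposed on its own through the library API and the CLI
subcommands; this module wires them together with one configuration object
and a fixed output layout.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .motifs import (
    BUILTIN_MOTIFS,
    GenomeSequence,
    MotifSite,
    count_long_gaps,
    gap_lengths,
    read_fasta,
    scan_motif,
    write_sites_bed,
)
from .ingest import (
    IpdObservationSet,
    SampleMetadata,
    clean_observations,
    read_ipd_table,
    read_metadata,
)
from .transform import TransformParams, boxcox_transform, optimize_params, write_params
from .detection import detect_methylation
from .temporal import select_significant, temporal_scan
from .patterns import build_ratio_matrix, cut_to_patterns, label_patterns, linkage_to_newick, ward_cluster
from .enrichment import enrich_terms, load_term_map, map_sites_to_genes, read_annotations

logger = logging.getLogger("damscan")

CONFIG_ERROR = 2
DATA_ERROR = 3


class PipelineError(RuntimeError):
    """Stage failure carrying the stage name and a machine-readable code."""

    def __init__(self, stage: str, code: int, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
        self.code = code


@dataclass
class PipelineConfig:
    genome_fasta: str = ""
    ipd_table: str = ""
    metadata: str = ""
    annotations: str | None = None
    term_map: str | None = None
    out_dir: str = "damscan_out"
    motif: str = "Dam_GATC"
    outlier_cutoff: float = 50_000.0
    min_coverage: int = 20
    detection_fdr: float = 0.05
    temporal_fdr: float = 0.05
    pattern_fdr: float = 0.3
    enrichment_alpha: float = 0.1
    upstream_window: int = 300
    gap_threshold: int = 1000
    k_clusters: int = 4
    transform: Any = "default"  # "default" | "optimize" | {"alpha":..., "lambda":...}
    n_resamples: int = 100
    equalize: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise PipelineError("config", CONFIG_ERROR, f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for name, lo, hi in (
            ("detection_fdr", 0, 1),
            ("temporal_fdr", 0, 1),
            ("pattern_fdr", 0, 1),
            ("enrichment_alpha", 0, 1),
        ):
            v = getattr(self, name)
            if not lo < v < hi:
                raise PipelineError("config", CONFIG_ERROR, f"{name} must be in ({lo}, {hi})")
        if self.outlier_cutoff <= 0 or self.min_coverage < 1 or self.k_clusters < 1:
            raise PipelineError("config", CONFIG_ERROR, "invalid threshold configuration")


def resolve_params(transform_spec: Any, datasets: Sequence[np.ndarray] = ()) -> TransformParams:
    if transform_spec == "default" or transform_spec is None:
        return TransformParams()
    if transform_spec == "optimize":
        if not len(datasets):
            raise PipelineError("transform", DATA_ERROR, "no data to optimize transform on")
        return optimize_params(datasets)
    if isinstance(transform_spec, Mapping):
        return TransformParams(
            alpha=float(transform_spec["alpha"]), lambda_=float(transform_spec["lambda"])
        )
    raise PipelineError("config", CONFIG_ERROR, f"bad transform spec {transform_spec!r}")


def assemble_site_maps(
    sets: Mapping[tuple[int, str, str], IpdObservationSet],
    params: TransformParams,
) -> tuple[
    dict[tuple[int, str], dict[str, np.ndarray]],
    dict[tuple[int, str], dict[str, np.ndarray]],
    dict[str, float],
]:
    """Raw and centered-transformed per-(site, sample) value maps.

    The centering offset of a sample is the grand mean of its transformed
    values over *all* observed reference positions — motif sites and
    unmethylated background positions alike — mirroring the genome-wide
    centering that keeps the per-site methylation signal intact.
    """
    transformed: dict[tuple[int, str, str], np.ndarray] = {}
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for key, obs in sets.items():
        if obs.excluded:
            continue
        y = boxcox_transform(obs.kept_values, params)
        transformed[key] = y
        sums[obs.sample_id] = sums.get(obs.sample_id, 0.0) + float(y.sum())
        counts[obs.sample_id] = counts.get(obs.sample_id, 0) + y.size
    offsets = {sid: sums[sid] / counts[sid] for sid in sums}

    raw_map: dict[tuple[int, str], dict[str, np.ndarray]] = {}
    cen_map: dict[tuple[int, str], dict[str, np.ndarray]] = {}
    for (pos, strand, sid), y in transformed.items():
        site = (pos, strand)
        raw_map.setdefault(site, {})[sid] = sets[(pos, strand, sid)].kept_values
        cen_map.setdefault(site, {})[sid] = y - offsets[sid]
    return raw_map, cen_map, offsets


def _restrict(site_map, keys):
    return {k: site_map[k] for k in keys if k in site_map}


def _md5(path: str | Path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage in order; returns the output directory.

    Outputs: sites BED, gap summary, detection and temporal TSVs,
    significant-site BEDs, ratio matrix, pattern assignments, dendrogram,
    enrichment TSV (when annotations are configured) and a JSON manifest.
    Reruns with the same config and inputs are identical given the seed.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "damscan_version": __version__,
        "config": {k: v for k, v in asdict(config).items()},
        "stages": {},
        "inputs": {},
    }

    # --- scan ---------------------------------------------------------
    stage = "scan"
    try:
        genome = read_fasta(config.genome_fasta)[0]
        manifest["inputs"][config.genome_fasta] = _md5(config.genome_fasta)
        pattern, offset = BUILTIN_MOTIFS.get(config.motif, (config.motif, 1))
        sites = scan_motif(genome, pattern, offset, motif_name=config.motif)
        write_sites_bed(sites, out / "sites.bed")
        gaps = gap_lengths(sites, genome)
        gap_summary = {
            "n_stranded_sites": len(sites),
            "n_duplex_sites": len(sites) // 2,
            "n_gaps": len(gaps),
            f"n_gaps_gt_{config.gap_threshold}": count_long_gaps(gaps, config.gap_threshold),
        }
        (out / "gap_summary.json").write_text(json.dumps(gap_summary, indent=2))
        manifest["stages"][stage] = gap_summary
        logger.info("scan: %d stranded sites", len(sites))
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError(stage, DATA_ERROR, str(e)) from e

    # --- ingest -------------------------------------------------------
    stage = "ingest"
    try:
        metadata = read_metadata(config.metadata)
        manifest["inputs"][config.metadata] = _md5(config.metadata)
        records, parse_report = read_ipd_table(
            config.ipd_table, metadata, genome_length=len(genome)
        )
        manifest["inputs"][config.ipd_table] = _md5(config.ipd_table)
        sets, clean_report = clean_observations(
            records, outlier_cutoff=config.outlier_cutoff, min_coverage=config.min_coverage
        )
        manifest["stages"][stage] = {
            "rows": parse_report.n_rows,
            "rejected_rows": parse_report.n_rejected,
            "outliers_removed": clean_report.outliers_removed,
            "sites_excluded": clean_report.sites_excluded,
        }
        dam_ids = [m.sample_id for m in metadata if m.role == "dam_control"]
        if len(dam_ids) != 1:
            raise PipelineError(
                "detect", DATA_ERROR, f"exactly one dam_control required, found {len(dam_ids)}"
            )
        dam_id = dam_ids[0]
        timepoint_samples = sorted(
            [(m.time_h, m.sample_id) for m in metadata if m.role == "timepoint"]
        )
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError(stage, DATA_ERROR, str(e)) from e

    # --- transform ----------------------------------------------------
    stage = "transform"
    try:
        pooled = [obs.kept_values for obs in sets.values() if not obs.excluded]
        params = resolve_params(config.transform, pooled)
        write_params(params, out / "transform_params.txt")
        raw_map, cen_map, offsets = assemble_site_maps(sets, params)
        manifest["stages"][stage] = {
            "alpha": params.alpha,
            "lambda": params.lambda_,
            "offsets": offsets,
        }
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError(stage, DATA_ERROR, str(e)) from e

    site_keys = [s.key for s in sites]
    raw_sites = _restrict(raw_map, site_keys)
    cen_sites = _restrict(cen_map, site_keys)

    # --- detect -------------------------------------------------------
    stage = "detect"
    try:
        det, det_summary = detect_methylation(
            raw_sites,
            cen_sites,
            dam_sample_id=dam_id,
            fdr=config.detection_fdr,
            equalize=config.equalize,
            n_resamples=config.n_resamples,
            seed=config.seed,
        )
        det.to_csv(out / "detection.tsv", sep="\t", index=False)
        det_summary.to_csv(out / "detection_summary.tsv", sep="\t", index=False)
        manifest["stages"][stage] = {
            "n_rows": len(det),
            "fdr": config.detection_fdr,
            "fdr_scope": "per sample cohort",
        }
    except PipelineError:
        raise
    except ValueError as e:
        raise PipelineError(stage, DATA_ERROR, str(e)) from e

    # --- temporal -----------------------------------------------------
    stage = "temporal"
    try:
        tp_ids = [sid for _, sid in timepoint_samples]
        raw_groups = {
            key: [per[sid] for sid in tp_ids if sid in per]
            for key, per in raw_sites.items()
        }
        cen_groups = {
            key: [per[sid] for sid in tp_ids if sid in per]
            for key, per in cen_sites.items()
        }
        temporal, excluded_sites = temporal_scan(raw_groups, cen_groups, len(tp_ids))
        temporal.to_csv(out / "temporal.tsv", sep="\t", index=False)
        pd.DataFrame(excluded_sites, columns=["position", "strand"]).to_csv(
            out / "temporal_exclusions.tsv", sep="\t", index=False
        )
        sig_strict = select_significant(temporal, config.temporal_fdr) if len(temporal) else temporal
        sig_loose = select_significant(temporal, config.pattern_fdr) if len(temporal) else temporal
        for name, sig in (("strict", sig_strict), ("pattern", sig_loose)):
            bed_sites = [
                MotifSite(genome.id, int(r.position), r.strand, config.motif)
                for r in sig.itertuples()
            ]
            write_sites_bed(bed_sites, out / f"significant_{name}.bed")
        manifest["stages"][stage] = {
            "n_tested": len(temporal),
            "n_excluded": len(excluded_sites),
            "n_significant_strict": len(sig_strict),
            "n_significant_pattern": len(sig_loose),
        }
    except PipelineError:
        raise
    except ValueError as e:
        raise PipelineError(stage, DATA_ERROR, str(e)) from e

    # --- patterns -----------------------------------------------------
    stage = "patterns"
    try:
        sig_keys = [(int(r.position), r.strand) for r in sig_loose.itertuples()]
        if len(sig_keys) >= max(2, config.k_clusters):
            matrix, dropped = build_ratio_matrix(raw_sites, sig_keys, timepoint_samples, dam_id)
            link = ward_cluster(matrix)
            labels = cut_to_patterns(link, config.k_clusters)
            pattern_df = label_patterns(labels, matrix, link)
            pattern_df.to_csv(out / "patterns.tsv", sep="\t", index=False)
            matrix.to_frame().to_csv(out / "ratio_matrix.tsv", sep="\t", index=False)
            leaf = [f"{p}{s}" for p, s in matrix.sites]
            (out / "dendrogram.nwk").write_text(linkage_to_newick(link, leaf) + "\n")
            manifest["stages"][stage] = {
                "n_clustered": len(matrix.sites),
                "n_dropped": len(dropped),
                "q_threshold": config.pattern_fdr,
            }
        else:
            manifest["stages"][stage] = {
                "skipped": f"only {len(sig_keys)} significant site(s); need >= {config.k_clusters}"
            }
    except PipelineError:
        raise
    except ValueError as e:
        raise PipelineError(stage, DATA_ERROR, str(e)) from e

    # --- enrich -------------------------------------------------------
    stage = "enrich"
    if config.annotations and config.term_map:
        try:
            annotations = read_annotations(config.annotations)
            term_map = load_term_map(config.term_map)
            duplex = sorted({p for p, s in sig_keys})
            gene_set, mapping, unmapped = map_sites_to_genes(
                duplex, annotations, upstream_window=config.upstream_window
            )
            universe = {a.gene_id for a in annotations}
            enr = enrich_terms(gene_set, universe, term_map, alpha=config.enrichment_alpha)
            enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)
            mapping.to_csv(out / "site_gene_map.tsv", sep="\t", index=False)
            manifest["stages"][stage] = {
                "n_genes": len(gene_set),
                "n_unmapped_sites": len(unmapped),
                "n_terms_tested": len(enr),
                "universe": "all annotated genes",
            }
        except PipelineError:
            raise
        except ValueError as e:
            raise PipelineError(stage, DATA_ERROR, str(e)) from e
    else:
        manifest["stages"][stage] = {"skipped": "no annotations/term map configured"}

    manifest["seed"] = config.seed
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out
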