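"""End-to-end orchestration: simulate -> enrich -> array DE -> qPCR.

`run_pipeline` wires the stages together on synthetic inputs (or existing
files), writes every intermediate and final table under one output
directory, and finishes with a manifest recording the seed, the resolved
configuration and the SHA-256 of every artifact.  Reruns with the same seed
and configuration produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Dict, Optional

import pandas as pd

from . import arraydiff, enrichment, io, qpcr
from .ontology import propagate_annotations
from .synthdata import (
    ArraySimConfig,
    ContigSimConfig,
    QpcrSimConfig,
    simulate_contig_experiment,
    simulate_microarray,
    simulate_ontology,
    simulate_qpcr,
)

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class RunConfig:
    """Umbrella configuration for a full synthetic run.

    ``profile`` selects the generator scale: 'full' (study-scale defaults)
    or 'tiny' (fast test profile).  Stage parameters mirror the per-module
    configs; unknown keys in a config file are rejected.
    """

    seed: int = 0
    out_dir: str = "gutenrich_run"
    profile: str = "tiny"
    alpha: float = 0.05
    scale: float = 1000.0
    min_contigs: int = 2
    score_threshold: Optional[float] = 100.0
    propagate: bool = True
    n_spiked: int = 4
    spike_fold: float = 5.0
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path, **overrides) -> "RunConfig":
        """Parse a plain-text ``key = value`` config file."""
        known = {f.name: f.type for f in dataclasses.fields(cls)}
        values: Dict[str, object] = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}: line {lineno}: expected 'key = value'")
            key, _, value = (s.strip() for s in line.partition("="))
            if key not in known:
                raise ValueError(f"{path}: line {lineno}: unknown key {key!r}")
            values[key] = value
        config = cls(**{**_coerce(values), **overrides})
        return config


def _coerce(values: Dict[str, object]) -> Dict[str, object]:
    out: Dict[str, object] = {}
    for key, value in values.items():
        if key in ("seed", "min_contigs", "n_spiked"):
            out[key] = int(value)
        elif key in ("alpha", "scale", "spike_fold"):
            out[key] = float(value)
        elif key == "score_threshold":
            out[key] = None if str(value).lower() in ("none", "off") else float(value)
        elif key == "propagate":
            out[key] = str(value).lower() in ("1", "true", "yes", "on")
        else:
            out[key] = value
    return out


def run_pipeline(config: RunConfig) -> Dict[str, Path]:
    """Execute the full synthetic workflow; returns the artifact paths.

    Stages: contig simulation + both enrichment modes; microarray simulation,
    per-time pairwise DE, ANOVA, Venn overlaps, PCA and sample clustering;
    qPCR simulation and ddCt folds.  Any stage failure propagates with a
    stage-named message.
    """
    logging.basicConfig(level=config.log_level)
    logger.info("run config: %s", dataclasses.asdict(config))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: Dict[str, Path] = {}

    def path(name: str) -> Path:
        p = out / name
        artifacts[name] = p
        return p

    # --- contig / enrichment stage ---------------------------------------
    try:
        if config.profile == "tiny":
            sim = ContigSimConfig.tiny(seed=config.seed, n_spiked=config.n_spiked,
                                       spike_fold=config.spike_fold)
        elif config.profile == "full":
            sim = ContigSimConfig(seed=config.seed, n_spiked=config.n_spiked,
                                  spike_fold=config.spike_fold)
        else:
            raise ValueError(f"unknown profile {config.profile!r}")
        ontology = simulate_ontology(sim.n_terms, seed=config.seed)
        contigs, direct, truth = simulate_contig_experiment(sim, ontology)
        io.write_obo(ontology, path("ontology.obo"))
        io.write_contig_table(contigs, path("contigs.tsv"))
        io.write_annotations(direct, path("annotations.tsv"))
        io.write_frame(truth, path("truth_contigs.tsv"))

        annotations = propagate_annotations(direct, ontology)
        e_config = enrichment.EnrichmentConfig(
            alpha=config.alpha, scale=config.scale, min_contigs=config.min_contigs,
            score_threshold=config.score_threshold, propagate=config.propagate,
        )
        quantitative = enrichment.run_quantitative_enrichment(
            contigs, annotations, ontology, e_config)
        io.write_frame(enrichment.results_to_frame(quantitative),
                       path("enrichment_quantitative.tsv"))
        qualitative = enrichment.run_qualitative_enrichment(
            contigs, annotations, ontology,
            dataclasses.replace(e_config, mode="qualitative"))
        io.write_frame(enrichment.results_to_frame(qualitative),
                       path("enrichment_qualitative.tsv"))
        io.write_frame(enrichment.term_read_summary(contigs, annotations,
                                                    ontology=ontology),
                       path("term_read_summary.tsv"))
    except Exception as exc:
        raise RuntimeError(f"enrichment stage failed: {exc}") from exc

    # --- microarray stage -------------------------------------------------
    try:
        a_sim = (ArraySimConfig.tiny(seed=config.seed) if config.profile == "tiny"
                 else ArraySimConfig(seed=config.seed))
        matrix, array_truth = simulate_microarray(a_sim)
        io.write_expression(matrix, path("array_intensities.tsv"), path("array_samples.tsv"))
        io.write_frame(array_truth, path("array_truth.tsv"))
        normalized = arraydiff.normalize(matrix)
        results_by_time: Dict[int, pd.DataFrame] = {}
        for time_h in normalized.times:
            de = arraydiff.pairwise_de(normalized, time_h)
            results_by_time[time_h] = de
            io.write_frame(de.reset_index(), path(f"de_{time_h}h.tsv"))
        io.write_frame(arraydiff.anova_de(normalized).reset_index(), path("anova.tsv"))
        for direction in ("induced", "repressed"):
            sets = arraydiff.significant_sets(results_by_time, direction,
                                              alpha=config.alpha)
            counts = arraydiff.venn_counts(sets)
            frame = pd.DataFrame(
                [{"region": "&".join(k), "count": v} for k, v in sorted(counts.items())],
                columns=["region", "count"],
            )
            io.write_frame(frame, path(f"venn_{direction}.tsv"))
        scores, explained, _ = arraydiff.pca(normalized)
        scores = scores.copy()
        scores.index.name = "sample_id"
        io.write_frame(scores.reset_index(), path("pca_scores.tsv"))
        io.write_frame(pd.DataFrame({"component": range(1, len(explained) + 1),
                                     "explained_variance": explained}),
                       path("pca_variance.tsv"))
        z, labels = arraydiff.hcluster_manhattan_average(normalized)
        path("dendrogram.nwk").write_text(
            arraydiff.linkage_to_newick(z, labels) + "\n", encoding="utf-8")
    except Exception as exc:
        raise RuntimeError(f"microarray stage failed: {exc}") from exc

    # --- qPCR stage --------------------------------------------------------
    try:
        q_sim = QpcrSimConfig(seed=config.seed)
        records, q_truth = simulate_qpcr(q_sim)
        io.write_ct_table(records, path("qpcr_ct.tsv"))
        io.write_frame(q_truth, path("qpcr_truth.tsv"))
        targets = [gene for gene, _ in q_sim.true_folds]
        folds = qpcr.fold_table(records, targets, q_sim.reference)
        io.write_frame(folds, path("qpcr_folds.tsv"))
    except Exception as exc:
        raise RuntimeError(f"qPCR stage failed: {exc}") from exc

    checksums = {name: io.sha256_of(p) for name, p in sorted(artifacts.items())}
    io.write_manifest(out / "manifest.json", seed=config.seed, inputs={},
                      outputs=checksums, config=dataclasses.asdict(config))
    artifacts["manifest.json"] = out / "manifest.json"
    return artifacts
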