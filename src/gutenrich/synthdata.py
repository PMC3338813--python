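"""Synthetic data generators mirroring the study design the analyses expect.

The real experiment profiled the gut transcriptome of beetle larvae fed a
control diet or one laced with a Cry3Aa protoxin dose: two 454 read sets
(~134k control / ~124k treated reads, mean read length ~249 bp) assembled
separately into ~1.3k and ~1.1k contigs, GO annotation of the contigs, a
two-condition x {6, 12, 24} h dye-swapped two-colour microarray, and ddCt
qPCR normalised to a ribosomal-protein reference gene.  The raw data are not
bundled here; these generators emit synthetic datasets with the same
statistical structure plus ground-truth tables, so every pipeline stage is
testable end to end.

Design notes
------------
* Reads are allocated multinomially with probability proportional to contig
  length, so the reads-per-kilobase weight used by the quantitative
  enrichment test is flat across terms under the null and a spiked term's
  fold multiplier is the estimand of the test.
* Scaled-down profiles (``tiny``, ``benchmark``) keep the per-contig read
  depth of the full-scale default (~50-100 reads per contig) by shrinking
  the mean contig length along with the read totals; this preserves the
  reads-per-kilobase scale on which the enrichment score threshold operates.
* All generators are pure functions of their config (including its seed):
  the same config yields byte-identical outputs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from .arraydiff import ExpressionMatrix
from .enrichment import ContigRecord
from .ontology import NAMESPACES, Ontology, propagate_annotations

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# ontology

def simulate_ontology(n_terms: int, seed: int) -> Ontology:
    """Random rooted ``is_a`` DAG with synthetic GO-style term ids.

    Term 0 is the root; the next (up to three) terms are namespace heads for
    biological_process / cellular_component / molecular_function; every later
    term attaches to 1-2 parents among the earlier non-root terms and
    inherits the namespace of its first parent.  Acyclic by construction.
    """
    if n_terms < 3:
        raise ValueError("need at least 3 terms")
    rng = np.random.default_rng(seed)
    graph = nx.DiGraph()
    ids = [f"GO:{i + 1:07d}" for i in range(n_terms)]
    graph.add_node(ids[0], name="root", namespace=NAMESPACES[0])
    n_heads = min(3, n_terms - 1)
    for i in range(1, n_heads + 1):
        ns = NAMESPACES[(i - 1) % 3]
        graph.add_node(ids[i], name=f"{ns} head", namespace=ns)
        graph.add_edge(ids[i], ids[0])
    for i in range(n_heads + 1, n_terms):
        n_parents = int(rng.integers(1, 3))
        parents = rng.choice(i - 1, size=min(n_parents, i - 1), replace=False) + 1
        ns = graph.nodes[ids[int(parents[0])]]["namespace"]
        graph.add_node(ids[i], name=f"term {i:04d}", namespace=ns)
        for p in parents:
            graph.add_edge(ids[i], ids[int(p)])
    ontology = Ontology(graph)
    ontology.validate()
    return ontology


# ---------------------------------------------------------------------------
# contig experiment

@dataclass(frozen=True)
class ContigSimConfig:
    """Conditions for the synthetic two-group contig experiment.

    Defaults mirror the full-scale study: 1,318 control / 1,140 treated
    contigs carrying 134,090 / 124,287 reads, contig lengths log-normal with
    mean ~780 bp.  ``terms_per_contig`` is the mean number of direct GO
    annotations per contig (Poisson, at least one); with ancestor propagation
    over a ~300-term DAG this yields per-contig annotation totals in the
    15-20 range typical of Blast2GO output at this scale.
    """

    seed: int = 0
    n_terms: int = 300
    n_contigs_control: int = 1318
    n_contigs_treated: int = 1140
    reads_control: int = 134090
    reads_treated: int = 124287
    length_meanlog: float = math.log(650.0)
    length_sdlog: float = 0.6
    min_length: int = 100
    terms_per_contig: float = 3.0
    n_spiked: int = 0
    spike_fold: float = 5.0
    spiked: Optional[Tuple[Tuple[str, float, str], ...]] = None

    def __post_init__(self):
        for name in ("n_terms", "n_contigs_control", "n_contigs_treated",
                     "reads_control", "reads_treated", "min_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.spike_fold <= 0:
            raise ValueError("spike_fold must be positive")

    @classmethod
    def tiny(cls, seed: int = 0, **overrides) -> "ContigSimConfig":
        """Fast test profile: 100 contigs and 5,000 reads per group, 40 terms,
        mean contig length ~370 bp (same per-contig depth as the default)."""
        base = dict(seed=seed, n_terms=40, n_contigs_control=100,
                    n_contigs_treated=100, reads_control=5000,
                    reads_treated=5000, length_meanlog=math.log(310.0))
        base.update(overrides)
        return cls(**base)

    @classmethod
    def benchmark(cls, seed: int = 0, **overrides) -> "ContigSimConfig":
        """Calibration profile: 1,000 contigs and 50,000 reads per group over
        200 terms, mean contig length ~370 bp."""
        base = dict(seed=seed, n_terms=200, n_contigs_control=1000,
                    n_contigs_treated=1000, reads_control=50000,
                    reads_treated=50000, length_meanlog=math.log(310.0))
        base.update(overrides)
        return cls(**base)


def _pick_spiked(
    config: ContigSimConfig, ontology: Ontology, rng: np.random.Generator
) -> List[Tuple[str, float, str]]:
    """Resolve the spiked-term list: explicit list, or ``n_spiked`` leaves.

    Leaves are pairwise non-ancestral by construction, so spikes never sit on
    a common ancestor path; directions alternate enriched/repressed so that
    up- and down-spikes roughly balance the read reallocation.
    """
    if config.spiked is not None:
        return [tuple(s) for s in config.spiked]
    if config.n_spiked == 0:
        return []
    leaves = sorted(ontology.leaves())
    if config.n_spiked > len(leaves):
        raise ValueError(f"cannot spike {config.n_spiked} terms: only {len(leaves)} leaves")
    chosen = rng.choice(len(leaves), size=config.n_spiked, replace=False)
    out = []
    for j, idx in enumerate(sorted(int(i) for i in chosen)):
        direction = "enriched" if j % 2 == 0 else "repressed"
        out.append((leaves[idx], config.spike_fold, direction))
    return out


def simulate_contig_experiment(
    config: ContigSimConfig, ontology: Ontology
) -> Tuple[List[ContigRecord], Dict[str, frozenset], pd.DataFrame]:
    """Two contig populations with annotations and spiked-term ground truth.

    Returns (contig records, direct annotation map, truth table).  Read
    totals match the config exactly; in the treated group the allocation
    probability of a contig annotated (after propagation) to a spiked term
    is multiplied by the spike fold (or its reciprocal for repressed spikes)
    and renormalised.  A spiked term with no annotated contig in a group has
    the term injected into one random contig of that group (logged).

    Contigs that draw a spiked term keep only that spiked term as their
    direct annotation.  Reads are a per-contig resource shared by all of a
    contig's labels, so without this restriction a spike would genuinely
    perturb every term co-annotated on its contigs and the truth table would
    no longer delimit the set of changed terms; confining spiked contigs to
    a single label keeps the spiked fold the estimand of the enrichment
    statistic (the perturbed ancestors that remain are handled by
    child-term pruning).
    """
    rng = np.random.default_rng(config.seed)
    terms = sorted(ontology.terms)
    if config.n_terms != len(terms):
        raise ValueError("ontology size does not match config.n_terms")
    spiked = _pick_spiked(config, ontology, rng)

    groups = {
        "control": ("Cont", config.n_contigs_control, config.reads_control),
        "treated": ("Bt", config.n_contigs_treated, config.reads_treated),
    }
    lengths: Dict[str, np.ndarray] = {}
    ids: Dict[str, List[str]] = {}
    direct: Dict[str, frozenset] = {}
    for group, (prefix, n_contigs, _) in groups.items():
        raw = rng.lognormal(config.length_meanlog, config.length_sdlog, size=n_contigs)
        lengths[group] = np.maximum(np.rint(raw).astype(int), config.min_length)
        ids[group] = [f"{prefix}-{i + 1:05d}" for i in range(n_contigs)]
        n_annot = np.maximum(rng.poisson(config.terms_per_contig, size=n_contigs), 1)
        n_annot = np.minimum(n_annot, len(terms))
        spiked_terms = {t for t, _, _ in spiked}
        for cid, k in zip(ids[group], n_annot):
            picks = rng.choice(len(terms), size=int(k), replace=False)
            chosen = frozenset(terms[int(i)] for i in picks)
            hit = chosen & spiked_terms
            if hit:
                chosen = frozenset([sorted(hit)[0]])  # spiked contigs are single-label
            direct[cid] = chosen

    # every spiked term must be annotated in both groups
    for term, _, _ in spiked:
        for group in groups:
            if not any(term in direct[cid] for cid in ids[group]):
                cid = ids[group][int(rng.integers(len(ids[group])))]
                logger.info("spiked term %s absent from %s; injected into %s", term, group, cid)
                direct[cid] = direct[cid] | {term}

    annotations = propagate_annotations(direct, ontology)

    contigs: List[ContigRecord] = []
    for group, (_, n_contigs, total_reads) in groups.items():
        weight = lengths[group].astype(float).copy()
        if group == "treated":
            for i, cid in enumerate(ids[group]):
                factor = 1.0
                for term, fold, direction in spiked:
                    if term in annotations.propagated[cid]:
                        factor *= fold if direction == "enriched" else 1.0 / fold
                weight[i] *= factor
        prob = weight / weight.sum()
        reads = rng.multinomial(total_reads, prob)
        for cid, length, r in zip(ids[group], lengths[group], reads):
            contigs.append(ContigRecord(id=cid, group=group, length=int(length), reads=int(r)))

    truth = pd.DataFrame(
        [{"term": t, "fold": f, "direction": d} for t, f, d in spiked],
        columns=["term", "fold", "direction"],
    )
    return contigs, direct, truth


# ---------------------------------------------------------------------------
# microarray

@dataclass(frozen=True)
class ArraySimConfig:
    """Conditions for the synthetic two-colour time-course microarray.

    Defaults mirror the real chip: 23,671 probes, conditions control/treated
    at 6, 12 and 24 h, two biological replicates per cell with the dye
    swapped between them.  Probe baselines are N(baseline_mean, baseline_sd)
    on the log2 scale; each differential probe is shifted by ``effect`` log2
    units (sign per truth direction) in the treated cells of its affected
    times; replicate noise is N(0, noise_sd); intensities are 2**log2.
    """

    seed: int = 0
    n_probes: int = 23671
    n_de_probes: int = 200
    effect: float = 2.0
    noise_sd: float = 0.2
    baseline_mean: float = 10.0
    baseline_sd: float = 1.0
    replicates: int = 2
    times: Tuple[int, ...] = (6, 12, 24)
    dye_swap: bool = True
    de_all_times: bool = True  # False: each DE probe affects a random nonempty time subset

    def __post_init__(self):
        if self.n_de_probes > self.n_probes:
            raise ValueError("n_de_probes cannot exceed n_probes")
        if self.replicates < 2:
            raise ValueError("need >=2 replicates per (condition, time) cell")

    @classmethod
    def tiny(cls, seed: int = 0, **overrides) -> "ArraySimConfig":
        base = dict(seed=seed, n_probes=500, n_de_probes=20)
        base.update(overrides)
        return cls(**base)


def simulate_microarray(config: ArraySimConfig) -> Tuple[ExpressionMatrix, pd.DataFrame]:
    """Synthetic intensity matrix plus per-probe ground truth.

    Truth columns: probe, fold (2**effect), direction, times (';'-joined
    hours at which the probe is shifted).

    Differential probes are drawn in induced/repressed pairs whose baselines
    differ by exactly the effect size and that share the same affected
    times, so the treated columns carry the same value multiset as the
    control columns.  Differential content then cannot shift a column's
    mean intensity, and the mean-scaling normalisation stays neutral — in
    particular the noise-free limit leaves every null probe untouched.
    (With an odd number of differential probes the last induced probe is
    unpaired and neutrality is only approximate.)
    """
    rng = np.random.default_rng(config.seed)
    probes = [f"probe_{i + 1:05d}" for i in range(config.n_probes)]
    de_idx = rng.choice(config.n_probes, size=config.n_de_probes, replace=False)
    de_idx = np.sort(de_idx)
    signs = np.where(np.arange(config.n_de_probes) % 2 == 0, 1.0, -1.0)
    if config.de_all_times:
        affected = [tuple(config.times)] * config.n_de_probes
    else:
        affected = []
        for pair in range((config.n_de_probes + 1) // 2):
            mask = rng.integers(0, 2, size=len(config.times)).astype(bool)
            if not mask.any():
                mask[int(rng.integers(len(config.times)))] = True
            times = tuple(t for t, m in zip(config.times, mask) if m)
            affected.extend([times, times])
        affected = affected[: config.n_de_probes]

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=config.n_probes)
    # balanced pairs: the repressed probe starts `effect` log2 units above
    # its induced partner, making their treated values a positional swap
    for k in range(1, config.n_de_probes, 2):
        baseline[de_idx[k]] = baseline[de_idx[k - 1]] + config.effect
    shift = {p: (s, set(t)) for p, s, t in zip(de_idx, signs, affected)}

    columns = {}
    meta_rows = []
    for time_h in config.times:
        for condition, tag in (("control", "ctl"), ("treated", "bt")):
            for rep in range(1, config.replicates + 1):
                sample = f"{tag}_{time_h}h_r{rep}"
                log2 = baseline.copy()
                if condition == "treated":
                    for p, (sign, times_p) in shift.items():
                        if time_h in times_p:
                            log2[p] += sign * config.effect
                if config.noise_sd > 0:
                    log2 = log2 + rng.normal(0.0, config.noise_sd, size=config.n_probes)
                columns[sample] = 2.0 ** log2
                if config.dye_swap:
                    dye = ("Cy3" if rep % 2 == 1 else "Cy5") if condition == "control" \
                        else ("Cy5" if rep % 2 == 1 else "Cy3")
                else:
                    dye = "Cy3" if condition == "control" else "Cy5"
                meta_rows.append({"sample_id": sample, "condition": condition,
                                  "time_h": time_h, "dye": dye, "replicate": rep})

    values = pd.DataFrame(columns, index=probes)
    samples = pd.DataFrame(meta_rows).set_index("sample_id")
    matrix = ExpressionMatrix(values=values, samples=samples, log2=False)
    truth = pd.DataFrame(
        [{"probe": probes[p], "fold": 2.0 ** config.effect,
          "direction": "induced" if shift[p][0] > 0 else "repressed",
          "times": ";".join(str(t) for t in sorted(shift[p][1]))}
         for p in de_idx],
        columns=["probe", "fold", "direction", "times"],
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# qPCR

@dataclass(frozen=True)
class QpcrSimConfig:
    """Conditions for the synthetic qPCR run.

    ``true_folds`` maps target gene -> signed true fold (negative means
    repressed); defaults mirror the two chitin-binding-domain transcripts
    assayed in the study (37.9-fold induced, 7.2-fold repressed) against a
    constant ribosomal-protein L24 reference.  Two biological x three
    technical replicates; Ct noise is N(0, ct_sd) cycles.
    """

    seed: int = 0
    reference: str = "RpL24"
    true_folds: Tuple[Tuple[str, float], ...] = (
        ("Contig_12590", 37.9),
        ("Contig_16411", -7.2),
    )
    reference_ct: float = 18.0
    target_ct_mean: float = 22.0
    target_ct_sd: float = 1.0
    n_biological: int = 2
    n_technical: int = 3
    ct_sd: float = 0.2


def simulate_qpcr(config: QpcrSimConfig) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic Ct table plus per-gene ground truth.

    The reference gene has a condition-independent Ct; each target's treated
    Ct is shifted by -log2(raw fold) relative to its control Ct.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    genes = [(config.reference, 1.0)] + [
        (g, (f if f >= 1 else -1.0 / f)) for g, f in config.true_folds
    ]
    for gene, raw_fold in genes:
        base = config.reference_ct if gene == config.reference else float(
            rng.normal(config.target_ct_mean, config.target_ct_sd)
        )
        for condition in ("control", "treated"):
            ct_center = base if condition == "control" else base - math.log2(raw_fold)
            for bio in range(1, config.n_biological + 1):
                for tech in range(1, config.n_technical + 1):
                    noise = float(rng.normal(0.0, config.ct_sd)) if config.ct_sd > 0 else 0.0
                    rows.append({
                        "sample_id": f"{condition}_b{bio}",
                        "condition": condition,
                        "gene": gene,
                        "replicate": tech,
                        "ct": ct_center + noise,
                    })
    records = pd.DataFrame(rows, columns=["sample_id", "condition", "gene", "replicate", "ct"])
    truth = pd.DataFrame(
        [{"gene": g, "fold": f, "direction": "induced" if f >= 1 else "repressed"}
         for g, f in config.true_folds],
        columns=["gene", "fold", "direction"],
    )
    return records, truth
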