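"""Functional enrichment of assembled contigs between two sequencing groups.

Two modes are provided:

* **qualitative** — the classical Blast2GO-style Fisher's exact test on
  contig presence: for each term, a 2x2 table of annotated / not-annotated
  contig counts in the treated vs control group.

* **quantitative** — a read-abundance- and contig-length-weighted variant.
  For each term *t* and group *g* the reads falling in contigs annotated to
  the term are normalised by the summed length of those contigs, giving a
  reads-per-kilobase weight ``W_t,g = scale * R_t,g / L_t,g``.  The rounded
  weights of the term and of its complement (contigs not annotated to the
  term) form the 2x2 table tested with Fisher's exact test.  This rewards
  deeply sequenced functions rather than merely widely annotated ones.

Both modes share the same downstream cascade: Benjamini-Hochberg FDR over the
family of annotated terms, a fold-change filter (quantitative mode), a
minimum-contig filter, pruning of terms with significant descendants (only
the most specific significant terms are reported), and an optional
"score > threshold" filter on the maximum group weight that restricts output
to the strongest signals.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .ontology import AnnotationSet, Ontology

logger = logging.getLogger(__name__)

GROUPS = ("control", "treated")

# filter flags
FOLD_FILTERED = "fold_filtered"
MIN_CONTIG_FILTERED = "min_contig_filtered"
CHILD_PRUNED = "child_pruned"
SCORE_FILTERED = "score_filtered"


@dataclass(frozen=True)
class ContigRecord:
    """One assembled contig: identifier, group label, length (bp) and read count."""

    id: str
    group: str
    length: int
    reads: int

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"contig {self.id!r}: group must be one of {GROUPS}")
        if self.length < 1:
            raise ValueError(f"contig {self.id!r}: length must be >= 1")
        if self.reads < 0:
            raise ValueError(f"contig {self.id!r}: reads must be >= 0")


@dataclass(frozen=True)
class TermGroupStats:
    """Per-term, per-group read/length totals and normalised weight.

    ``weight = scale * reads_sum / length_sum`` (reads per ``scale`` bases;
    reads per kilobase at the default scale of 1000), or 0 for an empty set.
    """

    term: str
    group: str
    n_contigs: int
    reads_sum: int
    length_sum: int
    weight: float


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table; rows are groups (treated, control), columns are
    function-annotated / function-not-annotated."""

    a: int  # treated, annotated
    b: int  # treated, not annotated
    c: int  # control, annotated
    d: int  # control, not annotated

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)

    @property
    def degenerate(self) -> bool:
        """True when a row or column margin is zero (Fisher p is 1 by convention)."""
        return (
            self.a + self.b == 0
            or self.c + self.d == 0
            or self.a + self.c == 0
            or self.b + self.d == 0
        )


@dataclass(frozen=True)
class EnrichmentConfig:
    """Tunable parameters of the enrichment cascade.

    alpha            FDR cut-off for reporting (default 0.05).
    scale            weight unit: reads per `scale` bases (default 1000).
    min_contigs      minimum contigs annotated to a term across both groups.
    score_threshold  report only terms whose max group weight exceeds this;
                     None disables.  Applied in quantitative mode by default.
    mode             'quantitative' or 'qualitative'.
    propagate        apply the true-path rule before counting.
    two_sided        two-sided Fisher test (direction assigned post hoc).
    complement       construction of the "not annotated" cell in quantitative
                     mode: 'unannotated' uses the weight of the complementary
                     contig set; 'dataset_total' uses the whole-group weight
                     minus the term weight (clamped at zero).
    """

    alpha: float = 0.05
    scale: float = 1000.0
    min_contigs: int = 2
    score_threshold: Optional[float] = 100.0
    mode: str = "quantitative"
    propagate: bool = True
    two_sided: bool = True
    complement: str = "unannotated"
    apply_fold_filter: Optional[bool] = None  # None -> quantitative only
    apply_score_filter: Optional[bool] = None  # None -> quantitative only

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if self.mode not in ("quantitative", "qualitative"):
            raise ValueError("mode must be 'quantitative' or 'qualitative'")
        if self.complement not in ("unannotated", "dataset_total"):
            raise ValueError("complement must be 'unannotated' or 'dataset_total'")

    @property
    def fold_filter_on(self) -> bool:
        if self.apply_fold_filter is None:
            return self.mode == "quantitative"
        return self.apply_fold_filter

    @property
    def score_filter_on(self) -> bool:
        if self.apply_score_filter is None:
            return self.mode == "quantitative"
        return self.apply_score_filter


@dataclass
class EnrichmentResult:
    """Outcome of the cascade for one term."""

    term: str
    name: str
    namespace: str
    stats_control: TermGroupStats
    stats_treated: TermGroupStats
    table: ContingencyTable
    p: float
    q: float = float("nan")
    fold: float = float("nan")
    direction: str = ""
    score: float = float("nan")
    flags: set = field(default_factory=set)

    def reported(self, alpha: float) -> bool:
        """A term is reported iff it passes the FDR cut-off and no filter flag is set."""
        return self.q <= alpha and not self.flags


def term_stats(
    contigs: Sequence[ContigRecord],
    annotations: AnnotationSet,
    term: str,
    group: str,
    scale: float = 1000.0,
    propagated: bool = True,
) -> TermGroupStats:
    """Read/length totals and weight for one (term, group) cell.

    Sums run over contigs of ``group`` whose (propagated or direct) annotation
    set contains ``term``; an empty set yields all-zero stats.
    """
    source = annotations.propagated if propagated else annotations.direct
    n = r = ell = 0
    for contig in contigs:
        if contig.group == group and term in source.get(contig.id, ()):
            n += 1
            r += contig.reads
            ell += contig.length
    weight = scale * r / ell if ell > 0 else 0.0
    return TermGroupStats(term=term, group=group, n_contigs=n, reads_sum=r,
                          length_sum=ell, weight=weight)


def group_totals(
    contigs: Sequence[ContigRecord], group: str, scale: float = 1000.0
) -> TermGroupStats:
    """Whole-group read/length totals and weight (the dataset weight T_g)."""
    n = r = ell = 0
    for contig in contigs:
        if contig.group == group:
            n += 1
            r += contig.reads
            ell += contig.length
    weight = scale * r / ell if ell > 0 else 0.0
    return TermGroupStats(term="*", group=group, n_contigs=n, reads_sum=r,
                          length_sum=ell, weight=weight)


def build_contingency(
    stats_treated: TermGroupStats,
    stats_control: TermGroupStats,
    total_treated: float,
    total_control: float,
) -> ContingencyTable:
    """Dataset-total contingency construction.

    ``a = round(W_t,treated)``, ``b = round(T_treated) - a`` and likewise for
    the control row.  Rounding is round-half-even; negative complements
    (a term hotter than the dataset average) are clamped to zero with a
    logged warning.
    """
    if total_treated <= 0 or total_control <= 0:
        raise ValueError("group totals must be positive")
    a = round(stats_treated.weight)
    c = round(stats_control.weight)
    b = round(total_treated) - a
    d = round(total_control) - c
    if b < 0 or d < 0:
        logger.warning(
            "term %s: complement cell negative (b=%d, d=%d); clamped to 0",
            stats_treated.term, b, d,
        )
        b = max(b, 0)
        d = max(d, 0)
    return ContingencyTable(a=a, b=b, c=c, d=d)


def fisher_exact_two_sided(table: ContingencyTable) -> float:
    """Two-sided Fisher's exact p for a 2x2 table.

    The p-value sums the hypergeometric probabilities of every table with the
    observed margins whose probability does not exceed that of the observed
    table.  Degenerate tables (a zero margin) return p = 1.
    """
    if table.degenerate:
        return 1.0
    _, p = sps.fisher_exact(table.as_array(), alternative="two-sided")
    return float(min(p, 1.0))


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, clipped at 1, in input order."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fold_and_direction(
    stats_treated: TermGroupStats,
    stats_control: TermGroupStats,
    total_treated: float,
    total_control: float,
) -> Tuple[float, str]:
    """Ratio of within-group proportions and its direction.

    fold = (W_t,treated / T_treated) / (W_t,control / T_control); a zero
    control proportion with nonzero treated proportion yields +inf (and the
    mirror case 0.0); both proportions zero yields NaN — the caller drops
    such terms.  Direction is 'enriched' when the treated proportion is the
    larger one, 'repressed' otherwise.
    """
    if total_treated <= 0 or total_control <= 0:
        raise ValueError("group totals must be positive")
    pt = stats_treated.weight / total_treated
    pc = stats_control.weight / total_control
    if pt == 0.0 and pc == 0.0:
        return float("nan"), ""
    if pc == 0.0:
        return float("inf"), "enriched"
    fold = pt / pc
    return fold, ("enriched" if pt > pc else "repressed")


def prune_by_children(
    results: List[EnrichmentResult], ontology: Ontology, alpha: float
) -> List[EnrichmentResult]:
    """Flag significant terms that have a significant ``is_a`` descendant.

    After pruning, the reported set contains no ancestor-descendant pair of
    significant terms (it is an antichain).  "Child" is read as any
    transitive descendant, which is stricter than direct children and
    independent of evaluation order.  Terms absent from the ontology are
    kept unpruned with a warning.
    """
    significant = {r.term for r in results if r.q <= alpha}
    for result in results:
        if result.q > alpha:
            continue
        if result.term not in ontology:
            logger.warning("term %r absent from ontology; kept unpruned", result.term)
            continue
        if ontology.descendants(result.term) & significant:
            result.flags.add(CHILD_PRUNED)
    return results


def _index_contigs(
    contigs: Sequence[ContigRecord],
    annotations: AnnotationSet,
    propagated: bool,
) -> Tuple[Dict[str, Dict[str, np.ndarray]], Dict[str, TermGroupStats], FrozenSet[str]]:
    """Invert annotations into per-term, per-group (n, R, L) sums.

    Returns (per-term sums, whole-group totals keyed by group, family of
    annotated terms).  One pass over contigs; avoids the quadratic cost of
    calling :func:`term_stats` per term.
    """
    source = annotations.propagated if propagated else annotations.direct
    sums: Dict[str, Dict[str, List[int]]] = {}
    totals = {g: [0, 0, 0] for g in GROUPS}  # n, reads, length
    for contig in contigs:
        tot = totals[contig.group]
        tot[0] += 1
        tot[1] += contig.reads
        tot[2] += contig.length
        for term in source.get(contig.id, ()):
            cell = sums.setdefault(term, {g: [0, 0, 0] for g in GROUPS})[contig.group]
            cell[0] += 1
            cell[1] += contig.reads
            cell[2] += contig.length
    return sums, totals, frozenset(sums)


def _stats_from_sums(term: str, group: str, cell: List[int], scale: float) -> TermGroupStats:
    n, r, ell = cell
    weight = scale * r / ell if ell > 0 else 0.0
    return TermGroupStats(term=term, group=group, n_contigs=n, reads_sum=r,
                          length_sum=ell, weight=weight)


def _run_enrichment(
    contigs: Sequence[ContigRecord],
    annotations: AnnotationSet,
    ontology: Ontology,
    config: EnrichmentConfig,
) -> List[EnrichmentResult]:
    groups_present = {c.group for c in contigs}
    if groups_present != set(GROUPS):
        raise ValueError(f"both groups {GROUPS} must be present; found {sorted(groups_present)}")
    sums, totals, family = _index_contigs(contigs, annotations, config.propagate)
    if not family:
        raise ValueError("no annotated contigs: the test family is empty")
    tot_t = _stats_from_sums("*", "treated", totals["treated"], config.scale)
    tot_c = _stats_from_sums("*", "control", totals["control"], config.scale)

    results: List[EnrichmentResult] = []
    for term in sorted(family):
        st = _stats_from_sums(term, "treated", sums[term]["treated"], config.scale)
        sc = _stats_from_sums(term, "control", sums[term]["control"], config.scale)
        if config.mode == "qualitative":
            table = ContingencyTable(
                a=st.n_contigs, b=tot_t.n_contigs - st.n_contigs,
                c=sc.n_contigs, d=tot_c.n_contigs - sc.n_contigs,
            )
            pt = st.n_contigs / tot_t.n_contigs
            pc = sc.n_contigs / tot_c.n_contigs
            if pt == 0.0 and pc == 0.0:
                fold, direction = float("nan"), ""
            elif pc == 0.0:
                fold, direction = float("inf"), "enriched"
            else:
                fold = pt / pc
                direction = "enriched" if pt > pc else "repressed"
        else:
            if config.complement == "unannotated":
                comp_t = _stats_from_sums(
                    term, "treated",
                    [tot_t.n_contigs - st.n_contigs, tot_t.reads_sum - st.reads_sum,
                     tot_t.length_sum - st.length_sum],
                    config.scale,
                )
                comp_c = _stats_from_sums(
                    term, "control",
                    [tot_c.n_contigs - sc.n_contigs, tot_c.reads_sum - sc.reads_sum,
                     tot_c.length_sum - sc.length_sum],
                    config.scale,
                )
                table = ContingencyTable(
                    a=round(st.weight), b=round(comp_t.weight),
                    c=round(sc.weight), d=round(comp_c.weight),
                )
            else:
                table = build_contingency(st, sc, tot_t.weight, tot_c.weight)
            fold, direction = fold_and_direction(st, sc, tot_t.weight, tot_c.weight)
        p = fisher_exact_two_sided(table)
        name = ontology.name(term) if term in ontology else term
        namespace = ontology.namespace(term) if term in ontology else ""
        result = EnrichmentResult(
            term=term, name=name, namespace=namespace,
            stats_control=sc, stats_treated=st, table=table, p=p,
            fold=fold, direction=direction,
            score=max(st.weight, sc.weight),
        )
        results.append(result)

    qvals = bh_adjust([r.p for r in results])
    for result, q in zip(results, qvals):
        result.q = float(q)

    for result in results:
        n_total = result.stats_treated.n_contigs + result.stats_control.n_contigs
        if n_total < config.min_contigs:
            result.flags.add(MIN_CONTIG_FILTERED)
        if config.fold_filter_on:
            # "fold change > 1": boundary fold of exactly 1, or an undefined
            # fold (both proportions zero), fails the filter
            if math.isnan(result.fold) or result.fold == 1.0:
                result.flags.add(FOLD_FILTERED)
        elif math.isnan(result.fold):
            result.flags.add(FOLD_FILTERED)
        if config.score_filter_on and config.score_threshold is not None:
            if not result.score > config.score_threshold:
                result.flags.add(SCORE_FILTERED)

    prune_by_children(results, ontology, config.alpha)
    return results


def run_quantitative_enrichment(
    contigs: Sequence[ContigRecord],
    annotations: AnnotationSet,
    ontology: Ontology,
    config: EnrichmentConfig = EnrichmentConfig(),
) -> List[EnrichmentResult]:
    """Read/length-weighted enrichment of treated vs control contigs.

    One result per term annotated to at least one contig (in either group);
    deterministic given its inputs.
    """
    if config.mode != "quantitative":
        config = replace(config, mode="quantitative")
    return _run_enrichment(contigs, annotations, ontology, config)


def run_qualitative_enrichment(
    contigs: Sequence[ContigRecord],
    annotations: AnnotationSet,
    ontology: Ontology,
    config: EnrichmentConfig = EnrichmentConfig(mode="qualitative"),
) -> List[EnrichmentResult]:
    """Contig-presence Fisher enrichment (read counts ignored).

    Contingency cells are annotated / not-annotated contig counts per group.
    The fold and score filters are off by default in this mode.
    """
    if config.mode != "qualitative":
        config = replace(config, mode="qualitative")
    return _run_enrichment(contigs, annotations, ontology, config)


def term_read_summary(
    contigs: Sequence[ContigRecord],
    annotations: AnnotationSet,
    terms: Optional[Iterable[str]] = None,
    keyword: Optional[str] = None,
    ontology: Optional[Ontology] = None,
    propagated: bool = False,
) -> pd.DataFrame:
    """Per-term, per-group read counts with no statistical test.

    Select terms explicitly or by case-insensitive substring match on term
    names (requires ``ontology``).  Useful for side-by-side read-abundance
    comparisons of chosen functions (e.g. putative toxin receptors).
    """
    if keyword is not None:
        if ontology is None:
            raise ValueError("keyword selection requires an ontology")
        terms = [t for t in ontology.terms if keyword.lower() in ontology.name(t).lower()]
    elif terms is None:
        terms = sorted(annotations.terms(propagated=propagated))
    rows = []
    for term in terms:
        sc = term_stats(contigs, annotations, term, "control", propagated=propagated)
        st = term_stats(contigs, annotations, term, "treated", propagated=propagated)
        rows.append({
            "term": term,
            "name": ontology.name(term) if ontology is not None and term in ontology else term,
            "n_contigs_control": sc.n_contigs,
            "n_contigs_treated": st.n_contigs,
            "reads_control": sc.reads_sum,
            "reads_treated": st.reads_sum,
        })
    columns = ["term", "name", "n_contigs_control", "n_contigs_treated",
               "reads_control", "reads_treated"]
    return pd.DataFrame(rows, columns=columns)


def results_to_frame(results: List[EnrichmentResult]) -> pd.DataFrame:
    """Tabular view of enrichment results, one row per tested term."""
    rows = []
    for r in results:
        rows.append({
            "term": r.term, "name": r.name, "namespace": r.namespace,
            "n_contigs_control": r.stats_control.n_contigs,
            "n_contigs_treated": r.stats_treated.n_contigs,
            "reads_control": r.stats_control.reads_sum,
            "reads_treated": r.stats_treated.reads_sum,
            "length_control": r.stats_control.length_sum,
            "length_treated": r.stats_treated.length_sum,
            "weight_control": r.stats_control.weight,
            "weight_treated": r.stats_treated.weight,
            "fold": r.fold, "direction": r.direction,
            "p": r.p, "q": r.q, "score": r.score,
            "flags": ";".join(sorted(r.flags)),
        })
    columns = ["term", "name", "namespace", "n_contigs_control", "n_contigs_treated",
               "reads_control", "reads_treated", "length_control", "length_treated",
               "weight_control", "weight_treated", "fold", "direction", "p", "q",
               "score", "flags"]
    return pd.DataFrame(rows, columns=columns)
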