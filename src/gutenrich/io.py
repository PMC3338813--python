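"""Readers and writers for the plain-text formats the pipeline exchanges.

Everything is TSV (GO term names contain commas), UTF-8, with ``#`` comment
lines allowed; the ontology travels as an OBO 1.2 subset and dendrograms as
Newick.  Every writer's output is parseable by its paired reader.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Dict, FrozenSet, List, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .arraydiff import ExpressionMatrix
from .enrichment import ContigRecord
from .ontology import Ontology

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.10g"

CONTIG_COLUMNS = ["contig_id", "group", "length_bp", "reads"]
SAMPLE_COLUMNS = ["sample_id", "condition", "time_h", "dye", "replicate"]
CT_COLUMNS = ["sample_id", "condition", "gene", "replicate", "ct"]


class FormatError(ValueError):
    """Raised for malformed input files, naming the offending line."""


def _read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str, **kwargs)


# ---------------------------------------------------------------------------
# contig tables

def read_contig_table(path) -> List[ContigRecord]:
    """Read a ``contig_id group length_bp reads`` TSV into validated records."""
    frame = _read_tsv(path)
    missing = [c for c in CONTIG_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    records: List[ContigRecord] = []
    seen: set[tuple[str, str]] = set()
    for i, row in enumerate(frame.itertuples(index=False), start=2):
        try:
            record = ContigRecord(
                id=row.contig_id, group=row.group,
                length=int(row.length_bp), reads=int(row.reads),
            )
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}: line {i}: {exc}") from exc
        key = (record.group, record.id)
        if key in seen:
            raise FormatError(f"{path}: line {i}: duplicate contig id {record.id!r} "
                              f"in group {record.group!r}")
        seen.add(key)
        records.append(record)
    return records


def write_contig_table(records: Sequence[ContigRecord], path) -> None:
    frame = pd.DataFrame(
        [(r.id, r.group, r.length, r.reads) for r in records],
        columns=CONTIG_COLUMNS,
    )
    frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# annotations

def read_annotations(path) -> Dict[str, FrozenSet[str]]:
    """Read a two-column ``contig_id term_id`` TSV into a direct-annotation map."""
    frame = _read_tsv(path)
    expected = ["contig_id", "term_id"]
    if list(frame.columns) != expected:
        raise FormatError(f"{path}: expected columns {expected}, found {list(frame.columns)}")
    out: Dict[str, set] = {}
    for row in frame.itertuples(index=False):
        out.setdefault(row.contig_id, set()).add(row.term_id)
    return {c: frozenset(t) for c, t in out.items()}


def write_annotations(direct: Mapping[str, FrozenSet[str]], path) -> None:
    rows = [(c, t) for c in sorted(direct) for t in sorted(direct[c])]
    pd.DataFrame(rows, columns=["contig_id", "term_id"]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# ontology

def write_obo(ontology: Ontology, path) -> None:
    """Serialise an ontology as a minimal OBO 1.2 file (id/name/namespace/is_a)."""
    lines = ["format-version: 1.2", "ontology: gutenrich-synthetic", ""]
    graph = ontology.graph
    for term in sorted(graph.nodes):
        lines.append("[Term]")
        lines.append(f"id: {term}")
        lines.append(f"name: {graph.nodes[term].get('name', term)}")
        lines.append(f"namespace: {graph.nodes[term].get('namespace', '')}")
        for parent in sorted(graph.successors(term)):
            lines.append(f"is_a: {parent}")
        lines.append("")
    Path(path).write_text("\n".join(lines), encoding="utf-8")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta_ids(path) -> List[str]:
    """Record ids (first whitespace-delimited header token) in file order.

    Used only to cross-check contig tables; duplicate ids draw a warning and
    an empty file is an error.
    """
    ids = [record.id for record in SeqIO.parse(str(path), "fasta")]
    if not ids:
        raise FormatError(f"{path}: no FASTA records found")
    if len(set(ids)) != len(ids):
        logger.warning("%s: duplicate FASTA headers", path)
    return ids


# ---------------------------------------------------------------------------
# expression matrices

def read_expression(values_path, samples_path) -> ExpressionMatrix:
    """Read a ``probe_id`` + sample-columns intensity TSV and its metadata TSV."""
    values = pd.read_csv(values_path, sep="\t", comment="#", index_col="probe_id")
    samples = pd.read_csv(samples_path, sep="\t", comment="#")
    missing = [c for c in SAMPLE_COLUMNS if c not in samples.columns]
    if missing:
        raise FormatError(f"{samples_path}: missing columns {missing}")
    samples["time_h"] = samples["time_h"].astype(int)
    samples = samples.set_index("sample_id")
    return ExpressionMatrix(values=values, samples=samples, log2=False)


def write_expression(matrix: ExpressionMatrix, values_path, samples_path) -> None:
    frame = matrix.values.copy()
    frame.index.name = "probe_id"
    frame.to_csv(values_path, sep="\t", float_format=FLOAT_FORMAT)
    matrix.samples.reset_index().to_csv(samples_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# qPCR

def read_ct_table(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in CT_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    if (frame["ct"] <= 0).any():
        line = int(frame.index[frame["ct"] <= 0][0]) + 2
        raise FormatError(f"{path}: line {line}: Ct values must be positive")
    return frame


def write_ct_table(records: pd.DataFrame, path) -> None:
    records.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# generic frame + manifest helpers

def write_frame(frame: pd.DataFrame, path, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


def sha256_of(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(path, *, seed, inputs: Mapping[str, str], outputs: Mapping[str, str],
                   config: Mapping) -> None:
    """Record the resolved run: seed, config, and input/output checksums."""
    from . import __version__

    manifest = {
        "version": __version__,
        "seed": seed,
        "config": dict(config),
        "inputs": dict(inputs),
        "outputs": dict(outputs),
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n",
                          encoding="utf-8")
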