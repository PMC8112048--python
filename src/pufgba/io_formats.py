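"""Readers and writers for the pipeline's external formats.

Tables are tab-separated UTF-8 with a single header row and ``#``
comment lines; the Newick reader tolerates unlabeled internal nodes and
internal support values (parsed and discarded, as produced by FastTree
and OrthoFinder), and branch lengths default to 1.0 when absent.  Gene
and protein identifiers are opaque strings — no accession normalization
is attempted.  Malformed rows are rejected with their row number rather
than silently coerced.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import networkx as nx
import numpy as np
import obonet
import pandas as pd

from .trees import NewickFormatError, SpeciesTree, TreeValidationError

__all__ = [
    "FileDialect",
    "OrthogroupMembership",
    "read_newick",
    "write_newick",
    "read_orthogroup_table",
    "read_peptide_table",
    "read_obo",
    "read_annotation_map",
    "read_operon_table",
    "write_evidence_table",
    "read_evidence_table",
]


@dataclass
class FileDialect:
    delimiter: str = "\t"
    comment_prefix: str = "#"
    missing_token: str = "NA"
    encoding: str = "utf-8"

    def __post_init__(self) -> None:
        if len(self.delimiter) != 1:
            raise ValueError("delimiter must be a single character")
        if not self.missing_token:
            raise ValueError("missing_token must be non-empty")


DEFAULT_DIALECT = FileDialect()


def _rows(path, dialect: FileDialect):
    """Yield (row_number, fields) skipping comments and blank lines."""
    with open(path, encoding=dialect.encoding, newline="") as fh:
        for i, fields in enumerate(csv.reader(fh, delimiter=dialect.delimiter), 1):
            if not fields or (fields[0].startswith(dialect.comment_prefix)
                              and len(fields) == 1):
                continue
            yield i, fields


def read_newick(source) -> SpeciesTree:
    """Parse Newick text or a file into a rooted :class:`SpeciesTree`.

    Missing branch lengths become 1.0 (count recorded on the tree);
    duplicate leaf labels and negative branch lengths are rejected.
    """
    if isinstance(source, (str, Path)) and Path(str(source)).exists():
        text = Path(source).read_text()
    else:
        text = str(source)
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick",
            suppress_internal_node_taxa=True,
            terminating_semicolon_required=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        if "Duplicate taxon labels" in str(exc):
            raise TreeValidationError(f"duplicate leaf labels: {exc}") from exc
        raise NewickFormatError(f"Newick parse failure: {exc}") from exc
    return SpeciesTree.from_dendropy(tree)


def write_newick(tree: SpeciesTree, path=None) -> str:
    text = tree.to_newick()
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


@dataclass
class OrthogroupMembership:
    """Orthogroup -> species -> gene list, plus the full species set."""

    species: list[str]
    members: dict[str, dict[str, list[str]]] = field(default_factory=dict)

    @property
    def orthogroups(self) -> list[str]:
        return list(self.members)

    def genes(self, orthogroup: str, species: str) -> list[str]:
        return self.members.get(orthogroup, {}).get(species, [])

    def all_genes(self, orthogroup: str) -> list[str]:
        return [g for sp in self.species for g in self.genes(orthogroup, sp)]


def read_orthogroup_table(path, dialect: FileDialect = DEFAULT_DIALECT) -> OrthogroupMembership:
    """Read an Orthogroups.tsv-style table (first column = orthogroup id).

    Cells hold comma-separated gene lists or are empty; ragged rows are
    rejected with their row number.
    """
    it = _rows(path, dialect)
    try:
        _, header = next(it)
    except StopIteration:
        raise ValueError("empty orthogroup table (no header)")
    species = header[1:]
    membership = OrthogroupMembership(species=species)
    for rownum, fields in it:
        if len(fields) != len(header):
            raise ValueError(
                f"row {rownum}: expected {len(header)} columns, got {len(fields)}")
        og = fields[0]
        per_species = {}
        for sp, cell in zip(species, fields[1:]):
            cell = cell.strip()
            if cell and cell != dialect.missing_token:
                per_species[sp] = [g.strip() for g in cell.split(",") if g.strip()]
        membership.members[og] = per_species
    return membership


def read_peptide_table(path, dialect: FileDialect = DEFAULT_DIALECT) -> pd.DataFrame:
    """Read a long-format peptide intensity table.

    Columns: peptide, protein, sample, intensity, psm_count.  The
    dialect's missing token yields a missing intensity (with PSM count
    forced to be 0), never zero.
    """
    from .proteoquant import validate_peptide_table

    df = pd.read_csv(path, sep=dialect.delimiter, comment=dialect.comment_prefix,
                     na_values=[dialect.missing_token], keep_default_na=False,
                     encoding=dialect.encoding)
    required = ["peptide", "protein", "sample", "intensity", "psm_count"]
    missing = set(required) - set(df.columns)
    if missing:
        raise ValueError(f"peptide table missing columns: {sorted(missing)}")
    psm = pd.to_numeric(df["psm_count"], errors="coerce")
    if psm.isna().any():
        bad = df.index[psm.isna()][0] + 2  # header + 1-based
        raise ValueError(f"row {bad}: psm_count is not numeric")
    if not np.allclose(psm, np.round(psm)):
        bad = df.index[~np.isclose(psm, np.round(psm))][0] + 2
        raise ValueError(f"row {bad}: psm_count must be an integer")
    df["psm_count"] = psm.astype(int)
    df["intensity"] = pd.to_numeric(df["intensity"], errors="raise")
    return validate_peptide_table(df)


def read_obo(path) -> nx.MultiDiGraph:
    """Read an OBO 1.2 ontology into a child->parent MultiDiGraph.

    Keeps ``is_a`` and ``part_of`` edges, excludes obsolete terms,
    verifies that every edge endpoint is a declared term and that the
    graph is acyclic (one offending cycle is reported otherwise).
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dag = obonet.read_obo(path)
    keep = {"is_a", "part_of"}
    drop = [(u, v, k) for u, v, k in dag.edges(keys=True) if k not in keep]
    dag.remove_edges_from(drop)
    undeclared = [n for n in dag.nodes if "name" not in dag.nodes[n]]
    if undeclared:
        raise ValueError(f"edges reference undeclared terms: {sorted(undeclared)}")
    if not nx.is_directed_acyclic_graph(dag):
        cycle = nx.find_cycle(dag)
        raise ValueError(f"ontology contains a cycle: {cycle}")
    return dag


def read_annotation_map(path, dialect: FileDialect = DEFAULT_DIALECT) -> dict[str, set[str]]:
    """Read a GAF-lite map: ``gene<TAB>term;term;...`` per row."""
    annotation: dict[str, set[str]] = {}
    for rownum, fields in _rows(path, dialect):
        if len(fields) != 2:
            raise ValueError(f"row {rownum}: expected 2 columns, got {len(fields)}")
        gene, terms = fields
        if terms == dialect.missing_token or not terms.strip():
            annotation.setdefault(gene, set())
            continue
        annotation.setdefault(gene, set()).update(
            t.strip() for t in terms.split(";") if t.strip())
    return annotation


def read_operon_table(path, dialect: FileDialect = DEFAULT_DIALECT,
                      known_genes: set[str] | None = None) -> pd.DataFrame:
    """Read a DOOR-like operon table.

    Columns: ``operon_id``, ``genes`` (comma-separated, ordered) and
    ``annotations`` (semicolon-separated, aligned with the genes).
    Operons referencing genes outside ``known_genes`` are retained, with
    a warning listing the unknown identifiers.
    """
    rows = []
    unknown: list[str] = []
    it = _rows(path, dialect)
    _, header = next(it)
    if header[:3] != ["operon_id", "genes", "annotations"]:
        raise ValueError(f"unexpected operon header: {header}")
    for rownum, fields in it:
        if len(fields) != 3:
            raise ValueError(f"row {rownum}: expected 3 columns, got {len(fields)}")
        op, genes_s, ann_s = fields
        genes = [g.strip() for g in genes_s.split(",") if g.strip()]
        anns = ([a.strip() for a in ann_s.split(";")]
                if ann_s and ann_s != dialect.missing_token else [""] * len(genes))
        if len(anns) != len(genes):
            raise ValueError(f"row {rownum}: {len(genes)} genes but {len(anns)} annotations")
        if known_genes is not None:
            unknown.extend(g for g in genes if g not in known_genes)
        rows.append({"operon_id": op, "genes": genes, "annotations": anns})
    if unknown:
        warnings.warn(f"operons reference genes absent from the study: {sorted(set(unknown))}")
    return pd.DataFrame(rows, columns=["operon_id", "genes", "annotations"])


def write_operon_table(operons: pd.DataFrame, path,
                       dialect: FileDialect = DEFAULT_DIALECT) -> None:
    with open(path, "w", encoding=dialect.encoding) as fh:
        fh.write(dialect.delimiter.join(["operon_id", "genes", "annotations"]) + "\n")
        for _, row in operons.iterrows():
            fh.write(dialect.delimiter.join([
                row["operon_id"], ",".join(row["genes"]),
                ";".join(row["annotations"]),
            ]) + "\n")


def write_evidence_table(records: pd.DataFrame, path,
                         dialect: FileDialect = DEFAULT_DIALECT) -> None:
    """Serialize the per-PUF evidence table (stable column order).

    Absent evidence is written as the dialect's missing token, never an
    empty string.
    """
    df = records.copy()
    df = df.where(~df.isna(), dialect.missing_token)
    df = df.replace("", dialect.missing_token)
    df.to_csv(path, sep=dialect.delimiter, index=False,
              encoding=dialect.encoding)


def read_evidence_table(path, dialect: FileDialect = DEFAULT_DIALECT) -> pd.DataFrame:
    return pd.read_csv(path, sep=dialect.delimiter,
                       na_values=[dialect.missing_token], keep_default_na=False,
                       encoding=dialect.encoding)
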