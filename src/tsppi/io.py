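"""Readers and writers for the tab-delimited formats the tool exchanges.

Formats covered:

* interaction dataset files — 2 columns (unweighted) or 3 columns
  (weighted, last column in [0, 1]);
* expression matrices — first row tissue/tumor names, first column gene
  symbols, cells non-negative expression values;
* TS-PPI network files — one record per (edge, tissue):
  ``gene_a  gene_b  tissue  expr_a  expr_b  weight``;
* homology files — ``node_a  network_a  node_b  network_b  score``;
* alignment reports — one plain-text file per alignment plus a
  machine-readable TSV index.

All readers skip blank lines and lines starting with ``#``, canonicalize
gene symbols to stripped upper case, and raise :class:`ParseError` naming
the offending line.  Numbers are parsed locale-independently (decimal
point only).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import networkx as nx

from .homology import HomologyTable
from .networks import TSPPINetwork

if TYPE_CHECKING:  # pragma: no cover
    from .align import Alignment

__all__ = [
    "ParseError",
    "InteractionRecord",
    "TSPPIRecord",
    "read_interaction_file",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_tsppi_network",
    "write_tsppi_network",
    "read_homology_file",
    "write_alignment_report",
    "write_global_network",
]

log = logging.getLogger(__name__)

LABEL_SEPARATOR = ";"


class ParseError(ValueError):
    """Malformed input file; the message names the file and line number."""


@dataclass(frozen=True)
class InteractionRecord:
    gene_a: str
    gene_b: str
    weight: float | None = None


@dataclass(frozen=True)
class TSPPIRecord:
    gene_a: str
    gene_b: str
    tissue: str
    expr_a: float
    expr_b: float
    weight: float


def _data_lines(path: Path) -> Iterable[tuple[int, str]]:
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


def _parse_float(token: str, path: Path, lineno: int, what: str) -> float:
    try:
        value = float(token)
    except ValueError:
        raise ParseError(f"{path}:{lineno}: non-numeric {what} {token!r}") from None
    if value != value:  # NaN
        raise ParseError(f"{path}:{lineno}: {what} is NaN")
    return value


def _gene(token: str) -> str:
    return token.strip().upper()


def read_interaction_file(path: str | Path, weighted: bool) -> list[InteractionRecord]:
    """Parse an interaction dataset file into records.

    ``weighted`` files carry a third column in [0, 1]; unweighted files
    have exactly two columns.  Self-loops are *not* rejected here — they
    are dropped when datasets are merged.
    """
    path = Path(path)
    expected = 3 if weighted else 2
    records: list[InteractionRecord] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) != expected:
            raise ParseError(
                f"{path}:{lineno}: expected {expected} columns, found {len(fields)}"
            )
        a, b = _gene(fields[0]), _gene(fields[1])
        if not a or not b:
            raise ParseError(f"{path}:{lineno}: empty gene symbol")
        weight = None
        if weighted:
            weight = _parse_float(fields[2], path, lineno, "weight")
            if not 0.0 <= weight <= 1.0:
                raise ParseError(f"{path}:{lineno}: weight {weight} outside [0, 1]")
        records.append(InteractionRecord(a, b, weight))
    return records


def read_expression_matrix(path: str | Path):
    """Read a tissue-by-gene expression matrix.

    Returns a :class:`pandas.DataFrame` with gene symbols as index and
    condition names as columns.  Cell (0, 0) of the file is ignored;
    duplicate gene rows are merged by arithmetic mean.
    """
    import pandas as pd

    path = Path(path)
    lines = list(_data_lines(path))
    if not lines:
        raise ParseError(f"{path}: empty expression matrix")
    header_lineno, header = lines[0]
    header_fields = header.split("\t")
    conditions = [c.strip() for c in header_fields[1:]]
    if not conditions or any(not c for c in conditions):
        raise ParseError(f"{path}:{header_lineno}: empty condition name in header")
    if len(set(conditions)) != len(conditions):
        raise ParseError(f"{path}:{header_lineno}: duplicate condition names")
    genes: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in lines[1:]:
        fields = line.split("\t")
        if len(fields) != len(conditions) + 1:
            raise ParseError(
                f"{path}:{lineno}: row has {len(fields) - 1} values, "
                f"header declares {len(conditions)} conditions"
            )
        gene = _gene(fields[0])
        if not gene:
            raise ParseError(f"{path}:{lineno}: empty gene symbol")
        values = []
        for col, token in enumerate(fields[1:], start=1):
            v = _parse_float(token, path, lineno, f"cell (row {gene}, column {conditions[col - 1]})")
            values.append(v)
        genes.append(gene)
        rows.append(values)
    if not genes:
        raise ParseError(f"{path}: expression matrix has no gene rows")
    frame = pd.DataFrame(rows, index=genes, columns=conditions, dtype=float)
    if frame.index.has_duplicates:
        frame = frame.groupby(level=0, sort=False).mean()
    return frame


def write_expression_matrix(frame, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("gene\t" + "\t".join(str(c) for c in frame.columns) + "\n")
        for gene, row in frame.iterrows():
            handle.write(str(gene) + "\t" + "\t".join(_fmt(v) for v in row) + "\n")


def _fmt(value: float) -> str:
    return format(float(value), ".6g")


def read_tsppi_records(path: str | Path) -> list[TSPPIRecord]:
    path = Path(path)
    records: list[TSPPIRecord] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) != 6:
            raise ParseError(f"{path}:{lineno}: expected 6 columns, found {len(fields)}")
        a, b = _gene(fields[0]), _gene(fields[1])
        tissue = fields[2].strip()
        if not a or not b or not tissue:
            raise ParseError(f"{path}:{lineno}: empty gene symbol or tissue")
        expr_a = _parse_float(fields[3], path, lineno, "expression")
        expr_b = _parse_float(fields[4], path, lineno, "expression")
        if expr_a <= 0 or expr_b <= 0:
            raise ParseError(f"{path}:{lineno}: non-positive expression score")
        weight = _parse_float(fields[5], path, lineno, "weight")
        if not 0.0 <= weight <= 1.0:
            raise ParseError(f"{path}:{lineno}: weight {weight} outside [0, 1]")
        records.append(TSPPIRecord(a, b, tissue, expr_a, expr_b, weight))
    if not records:
        raise ParseError(f"{path}: empty TS-PPI network file")
    return records


def read_tsppi_network(path: str | Path, name: str | None = None) -> TSPPINetwork:
    """Load a TS-PPI network file as a simple undirected graph.

    Multi-edges (several records for the same unordered gene pair, e.g.
    from different tissues) collapse to a single edge whose weight is the
    mean of the record weights and whose label concatenates the record
    tissues with ``;``.  A gene mentioned with inconsistent expression
    values gets the mean, with a logged warning.  Self-loops are dropped
    with a logged warning; a file that is empty after the drop is an
    error.
    """
    path = Path(path)
    records = read_tsppi_records(path)
    graph = nx.Graph()
    node_values: dict[str, list[float]] = {}
    edge_weights: dict[tuple[str, str], list[float]] = {}
    edge_labels: dict[tuple[str, str], list[str]] = {}
    conditions: list[str] = []
    for rec in records:
        if rec.tissue not in conditions:
            conditions.append(rec.tissue)
        if rec.gene_a == rec.gene_b:
            log.warning("%s: dropping self-loop on %s", path, rec.gene_a)
            continue
        node_values.setdefault(rec.gene_a, []).append(rec.expr_a)
        node_values.setdefault(rec.gene_b, []).append(rec.expr_b)
        key = (rec.gene_a, rec.gene_b) if rec.gene_a <= rec.gene_b else (rec.gene_b, rec.gene_a)
        edge_weights.setdefault(key, []).append(rec.weight)
        labels = edge_labels.setdefault(key, [])
        if rec.tissue not in labels:
            labels.append(rec.tissue)
    if not edge_weights:
        raise ParseError(f"{path}: network is empty after dropping self-loops")
    for gene, values in node_values.items():
        if max(values) - min(values) > 1e-9:
            log.warning(
                "%s: inconsistent expression values for %s (%s); using their mean",
                path, gene, values,
            )
        graph.add_node(gene, weight=sum(values) / len(values))
    for (a, b), weights in edge_weights.items():
        graph.add_edge(
            a, b,
            weight=sum(weights) / len(weights),
            label=LABEL_SEPARATOR.join(edge_labels[(a, b)]),
        )
    return TSPPINetwork(name=name or path.stem, conditions=tuple(conditions), graph=graph)


def write_tsppi_network(network: TSPPINetwork, path: str | Path) -> None:
    """Write a TS-PPI network in the 6-column record format.

    One record per edge; the tissue field carries the (possibly
    ``;``-joined) edge label, and the expression fields carry the node
    weights — so ``read_tsppi_network`` round-trips the graph.
    """
    path = Path(path)
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("# gene_a\tgene_b\ttissue\texpr_a\texpr_b\tweight\n")
        for a, b in sorted(map(sorted, network.graph.edges())):
            data = network.graph.edges[a, b]
            handle.write(
                "\t".join([
                    a, b,
                    data.get("label", LABEL_SEPARATOR.join(network.conditions) or "na"),
                    repr(float(network.node_weight(a))),
                    repr(float(network.node_weight(b))),
                    repr(float(data["weight"])),
                ]) + "\n"
            )


def read_homology_file(
    path: str | Path, network_names: Sequence[str]
) -> HomologyTable:
    """Load a 5-column homology file (node, network, node, network, score).

    Scores must be positive; the two networks of a pair must differ and
    be among ``network_names``.  The returned table is symmetric.
    """
    path = Path(path)
    known = set(network_names)
    table = HomologyTable({})
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) != 5:
            raise ParseError(
                f"{path}:{lineno}: expected 5 columns "
                "(node_a, network_a, node_b, network_b, score)"
            )
        node_a, net_a = _gene(fields[0]), fields[1].strip()
        node_b, net_b = _gene(fields[2]), fields[3].strip()
        for net in (net_a, net_b):
            if net not in known:
                raise ParseError(f"{path}:{lineno}: unknown network name {net!r}")
        if net_a == net_b:
            raise ParseError(f"{path}:{lineno}: homology pair within one network")
        score = _parse_float(fields[4], path, lineno, "homology score")
        if score <= 0:
            raise ParseError(f"{path}:{lineno}: homology score must be positive")
        table.add((node_a, net_a), (node_b, net_b), score)
    if len(table) == 0:
        raise ParseError(f"{path}: homology file contains no pairs")
    return table


def write_global_network(network, path: str | Path) -> None:
    """Write a global gene-interaction network as a TSV edge table
    (gene_a, gene_b, avg_weight, coverage, reporting datasets)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("# gene_a\tgene_b\tavg_weight\tcoverage\tdatasets\n")
        for a, b in sorted(map(sorted, network.graph.edges())):
            data = network.graph.edges[a, b]
            reporting = ";".join(
                name if data["per_dataset"][name] is None
                else f"{name}={_fmt(data['per_dataset'][name])}"
                for name in sorted(data["per_dataset"])
            )
            handle.write(
                f"{a}\t{b}\t{repr(float(data['avg_weight']))}\t"
                f"{repr(float(data['coverage']))}\t{reporting}\n"
            )


def write_alignment_report(
    alignments: "Sequence[Alignment]", path: str | Path
) -> list[Path]:
    """Write one text file per alignment plus a TSV index.

    Each alignment file lists, per network, the aligned nodes with their
    weights and the induced edges with weights and labels, followed by
    the node mapping matrix in which each column holds nodes of one
    network and each row is one set of mapped genes.  The index file
    ``index.tsv`` carries rank, size, average MaxLogFold and ISC.
    """
    if not alignments:
        raise ValueError("no alignments to write")
    outdir = Path(path)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    index_path = outdir / "index.tsv"
    with open(index_path, "w", encoding="utf-8") as index:
        index.write("rank\tfile\tsize\tavg_max_logfold\tisc\n")
        for rank, alignment in enumerate(alignments, start=1):
            fname = f"alignment_{rank:03d}.txt"
            index.write(
                f"{rank}\t{fname}\t{alignment.size}\t"
                f"{alignment.avg_max_logfold:.6f}\t{alignment.isc:.6f}\n"
            )
            target = outdir / fname
            with open(target, "w", encoding="utf-8") as handle:
                handle.write(f"# local alignment {rank}\n")
                handle.write(f"size\t{alignment.size}\n")
                handle.write(f"avg_max_logfold\t{alignment.avg_max_logfold:.6f}\n")
                handle.write(f"isc\t{alignment.isc:.6f}\n")
                handle.write("networks\t" + "\t".join(alignment.network_names) + "\n")
                for i, net_name in enumerate(alignment.network_names):
                    sub = alignment.subgraphs[net_name]
                    handle.write(f"\n[nodes {net_name}]\n")
                    for node in (col.members[i] for col in alignment.columns):
                        handle.write(f"{node}\t{_fmt(sub.nodes[node]['weight'])}\n")
                    handle.write(f"[edges {net_name}]\n")
                    for a, b in sorted(map(sorted, sub.edges())):
                        data = sub.edges[a, b]
                        handle.write(
                            f"{a}\t{b}\t{_fmt(data.get('weight', 1.0))}\t"
                            f"{data.get('label', 'na')}\n"
                        )
                handle.write("\n[mapping]\n")
                handle.write("\t".join(alignment.network_names) + "\tmax_logfold\n")
                for col in alignment.columns:
                    handle.write(
                        "\t".join(col.members) + f"\t{col.max_logfold:.6f}\n"
                    )
            written.append(target)
    return written
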