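"""Readers and writers for every external format the pipeline touches.

Tabular inputs are delimiter-explicit TSV/CSV; gene sets use the Broad GMT
standard; networks are exported as a SIF edge file (Cytoscape-compatible)
paired with a node-attribute TSV so a write/read round trip reproduces the
network exactly. Gene symbols are normalized (trim + uppercase) at every
ingest point; component identifiers keep their own namespace and case.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .adme import ComponentRecord
from .enrichment import GeneSetCollection
from .networks import DiseaseGene, TypedNetwork, normalize_symbol


class ParseError(ValueError):
    """Malformed input row; the message names the file and line number."""


@dataclass(frozen=True)
class TableDialect:
    """How a tabular text file is laid out."""

    delimiter: str = "\t"
    header: bool = False
    comment_prefix: str = "#"

    def __post_init__(self) -> None:
        if len(self.delimiter) != 1:
            raise ValueError("delimiter must be a single character")


DEFAULT_DIALECT = TableDialect()


def _data_rows(path: Path, dialect: TableDialect):
    """Yield (line_number, fields) for non-comment, non-blank rows."""
    seen_header = not dialect.header
    with open(path, newline="") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.rstrip("\n").rstrip("\r")
            if not stripped.strip():
                continue
            if dialect.comment_prefix and stripped.startswith(dialect.comment_prefix):
                continue
            if not seen_header:
                seen_header = True
                continue
            yield lineno, stripped.split(dialect.delimiter)


def read_edge_list(
    path: str | Path, dialect: TableDialect = DEFAULT_DIALECT
) -> list[tuple[str, str]]:
    """Read symbol pairs exactly as listed: no dedup, order preserved,
    symbols trimmed and uppercased. An empty file yields an empty list."""
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    for lineno, fields in _data_rows(path, dialect):
        if len(fields) < 2:
            raise ParseError(
                f"{path}:{lineno}: edge row needs >= 2 columns, got {len(fields)}"
            )
        a, b = normalize_symbol(fields[0]), normalize_symbol(fields[1])
        if not a or not b:
            raise ParseError(f"{path}:{lineno}: empty symbol in edge row")
        pairs.append((a, b))
    return pairs


def write_edge_list(
    pairs: Iterable[tuple[str, str]], path: str | Path,
    dialect: TableDialect = DEFAULT_DIALECT,
) -> None:
    with open(path, "w", newline="") as fh:
        for a, b in pairs:
            fh.write(f"{a}{dialect.delimiter}{b}\n")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a Broad-standard GMT file: term <TAB> description <TAB> genes...

    Duplicate genes within a set collapse; a duplicate term id, a row with
    fewer than three fields, or an empty gene list is an error.
    """
    path = Path(path)
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, newline="") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.rstrip("\n").rstrip("\r")
            if not stripped.strip():
                continue
            fields = stripped.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT row needs term, description and "
                    f">= 1 gene, got {len(fields)} fields"
                )
            term = fields[0].strip()
            if term in sets:
                raise ParseError(f"{path}:{lineno}: duplicate term id {term!r}")
            genes = [normalize_symbol(g) for g in fields[2:] if g.strip()]
            if not genes:
                raise ParseError(f"{path}:{lineno}: empty gene list for {term!r}")
            sets[term] = genes
            descriptions[term] = fields[1].strip()
    return GeneSetCollection.from_sets(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        for term, (desc, genes) in collection.sets.items():
            fh.write("\t".join([term, desc, *sorted(genes)]) + "\n")


# -- network SIF + node attributes ------------------------------------

_SIF_SUFFIX = ".sif"
_ATTR_SUFFIX = ".nodes.tsv"


def write_network(net: TypedNetwork, prefix: str | Path) -> tuple[Path, Path]:
    """Write ``<prefix>.sif`` (one row per undirected edge, endpoints in
    lexicographic order so diffs are deterministic) and ``<prefix>.nodes.tsv``
    (id, role, weight per node). Returns the two paths."""
    prefix = Path(prefix)
    sif_path = prefix.with_name(prefix.name + _SIF_SUFFIX)
    attr_path = prefix.with_name(prefix.name + _ATTR_SUFFIX)
    edges = sorted(
        (min(u, v), d["relation"], max(u, v))
        for u, v, d in net.graph.edges(data=True)
    )
    with open(sif_path, "w", newline="") as fh:
        for a, rel, b in edges:
            fh.write(f"{a}\t{rel}\t{b}\n")
    with open(attr_path, "w", newline="") as fh:
        fh.write("id\trole\tweight\n")
        for n in sorted(net.graph.nodes):
            w = net.weight(n)
            fh.write(f"{n}\t{net.role(n)}\t{'' if w is None else repr(w)}\n")
    return sif_path, attr_path


def read_network(prefix: str | Path) -> TypedNetwork:
    """Rebuild a network written by :func:`write_network`."""
    prefix = Path(prefix)
    sif_path = prefix.with_name(prefix.name + _SIF_SUFFIX)
    attr_path = prefix.with_name(prefix.name + _ATTR_SUFFIX)
    net = TypedNetwork()
    with open(attr_path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            weight = float(row["weight"]) if row["weight"] else None
            net.add_node(row["id"], row["role"], weight)
    with open(sif_path, newline="") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 3:
                raise ParseError(f"{sif_path}:{lineno}: SIF row needs 3 fields")
            a, rel, b = fields
            net.add_edge(a, b, rel)
    net.validate()
    return net


# -- domain tables -----------------------------------------------------


def read_disease_genes(
    path: str | Path, dialect: TableDialect = DEFAULT_DIALECT
) -> list[DiseaseGene]:
    """TSV of (gene symbol, relevance score) rows."""
    path = Path(path)
    out = []
    for lineno, fields in _data_rows(path, dialect):
        if len(fields) < 2:
            raise ParseError(f"{path}:{lineno}: need symbol and score columns")
        try:
            score = float(fields[1])
        except ValueError as exc:
            raise ParseError(
                f"{path}:{lineno}: bad relevance score {fields[1]!r}"
            ) from exc
        out.append(DiseaseGene(symbol=normalize_symbol(fields[0]), relevance_score=score))
    return out


def write_disease_genes(genes: Sequence[DiseaseGene], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("# symbol\trelevance_score\n")
        for g in genes:
            fh.write(f"{g.symbol}\t{g.relevance_score!r}\n")


_COMPONENT_COLS = ("id", "name", "herbs", "mw", "ob", "caco2", "dl", "include_listed")


def read_components(
    path: str | Path, dialect: TableDialect = TableDialect(header=True)
) -> list[ComponentRecord]:
    """Component property table: id, name, herbs (comma-joined), MW, OB,
    Caco-2, DL, include_listed (0/1). Empty property cells become missing."""
    path = Path(path)
    out = []
    for lineno, fields in _data_rows(path, dialect):
        if len(fields) < len(_COMPONENT_COLS):
            raise ParseError(
                f"{path}:{lineno}: need {len(_COMPONENT_COLS)} columns"
            )
        cid, name, herbs_raw, mw, ob, caco2, dl, listed = fields[:8]

        def num(cell: str, what: str) -> float | None:
            cell = cell.strip()
            if not cell:
                return None
            try:
                return float(cell)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad {what} {cell!r}") from exc

        out.append(
            ComponentRecord(
                id=cid.strip(),
                name=name.strip(),
                herbs=frozenset(
                    h.strip() for h in herbs_raw.split(",") if h.strip()
                ),
                mw=num(mw, "MW"),
                ob=num(ob, "OB"),
                caco2=num(caco2, "Caco-2"),
                dl=num(dl, "DL"),
                include_listed=listed.strip() in ("1", "true", "True"),
            )
        )
    return out


def write_components(records: Sequence[ComponentRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("\t".join(_COMPONENT_COLS) + "\n")
        for r in records:
            cells = [
                r.id,
                r.name,
                ",".join(sorted(r.herbs)),
                *("" if v is None else repr(v) for v in (r.mw, r.ob, r.caco2, r.dl)),
                "1" if r.include_listed else "0",
            ]
            fh.write("\t".join(cells) + "\n")


def read_associations(
    path: str | Path, dialect: TableDialect = DEFAULT_DIALECT
) -> list[tuple[str, str]]:
    """Component-target association rows: (component id, target symbol).
    Component ids are kept verbatim; target symbols are normalized."""
    path = Path(path)
    out = []
    for lineno, fields in _data_rows(path, dialect):
        if len(fields) < 2:
            raise ParseError(f"{path}:{lineno}: need component and target columns")
        out.append((fields[0].strip(), normalize_symbol(fields[1])))
    return out


def write_associations(
    associations: Sequence[tuple[str, str]], path: str | Path
) -> None:
    with open(path, "w", newline="") as fh:
        for c, t in associations:
            fh.write(f"{c}\t{t}\n")


def read_gene_list(path: str | Path) -> list[str]:
    """One gene symbol per line; blank lines and # comments skipped."""
    out = []
    with open(path, newline="") as fh:
        for line in fh:
            s = line.strip()
            if s and not s.startswith("#"):
                out.append(normalize_symbol(s))
    return out


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        for g in sorted(genes):
            fh.write(g + "\n")


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
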