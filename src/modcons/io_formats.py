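"""Readers and writers for every external format the pipeline touches.

All tabular inputs and outputs are plain TSV; ontologies arrive as OBO plus
GAF annotation files.  Gene identifiers are opaque, case-sensitive strings —
no symbol/ORF aliasing is attempted.  Output tables carry a commented header
line with provenance (tool version and the parameters used to produce them).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx
import obonet
import pandas as pd
from Bio.UniProt.GOA import gafiterator

logger = logging.getLogger(__name__)

EVIDENCE_TYPES = ("coexpression", "ppi", "gi_positive", "gi_negative", "sequence", "go")
RAW_EDGE_TYPES = ("ppi", "gi_positive", "gi_negative", "curated_ortholog", "blast_hit")
#: evidence types whose edge lists are undirected and deduplicated on read
UNDIRECTED_EDGE_TYPES = ("ppi", "gi_positive", "gi_negative", "curated_ortholog")

_NAMESPACE_ASPECT = {
    "biological_process": "P",
    "molecular_function": "F",
    "cellular_component": "C",
}


class FormatError(ValueError):
    """Malformed or invalid input file."""


@dataclass
class ExpressionMatrix:
    """Gene x array table of log-ratio measurements for one experiment set."""

    species: str
    values: pd.DataFrame  # index = genes, columns = arrays; NaN permitted
    experiment_id: str = "exp"

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise FormatError("duplicate gene identifiers")
        if self.values.columns.has_duplicates:
            raise FormatError("duplicate array identifiers")
        if self.values.shape[1] < 2:
            raise FormatError("expression matrix needs at least 2 arrays")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def arrays(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class RawEdgeList:
    """Unscored edge records of one species and evidence type.

    Undirected types are stored with ``gene_a < gene_b`` and deduplicated;
    ``blast_hit`` records are directed (query, subject, E-value).
    """

    species: str
    data_type: str
    records: list[tuple[str, str, float | None]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.data_type not in RAW_EDGE_TYPES:
            raise FormatError(f"unknown edge-list type {self.data_type!r}")
        cleaned: list[tuple[str, str, float | None]] = []
        seen: set[tuple[str, str]] = set()
        for a, b, score in self.records:
            if a == b:
                continue
            if self.data_type in UNDIRECTED_EDGE_TYPES:
                a, b = (a, b) if a < b else (b, a)
                if (a, b) in seen:
                    continue
                seen.add((a, b))
            cleaned.append((a, b, score))
        self.records = cleaned

    def pairs(self) -> list[tuple[str, str]]:
        return [(a, b) for a, b, _ in self.records]


def _provenance_line(**params) -> str:
    from . import __version__

    items = " ".join(f"{k}={v}" for k, v in params.items())
    return f"# modcons {__version__} {items}".rstrip()


# ---------------------------------------------------------------------------
# expression matrices


def read_expression(
    path: str | Path, species: str = "", experiment_id: str | None = None
) -> ExpressionMatrix:
    """Read a TSV expression matrix (header = array ids, first column = genes).

    Duplicate gene rows (multiple probes) are collapsed by the per-array
    median.  Cells that cannot be parsed as numbers raise with the offending
    row and column named; empty cells are missing values.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expression matrix needs at least 2 arrays")
    numeric = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna() & (df[col].str.strip() != "")
        if bad.any():
            gene = df.index[bad.to_numpy().nonzero()[0][0]]
            raise FormatError(f"{path}: malformed numeric cell at row {gene!r}, column {col!r}")
        numeric[col] = parsed
    if numeric.index.has_duplicates:
        n_before = len(numeric)
        numeric = numeric.groupby(level=0, sort=False).median()
        logger.info(
            "%s: collapsed %d probe rows into %d genes by median",
            path,
            n_before,
            len(numeric),
        )
    numeric.index = numeric.index.astype(str)
    return ExpressionMatrix(
        species=species,
        values=numeric,
        experiment_id=experiment_id or path.stem,
    )


def write_expression(expr: ExpressionMatrix, path: str | Path, **provenance) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(
            _provenance_line(
                species=expr.species, experiment=expr.experiment_id, **provenance
            )
            + "\n"
        )
        expr.values.to_csv(fh, sep="\t", index_label="gene")


# ---------------------------------------------------------------------------
# edge lists


def read_edge_list(
    path: str | Path, data_type: str, species: str = ""
) -> RawEdgeList:
    """Read a two-column TSV edge list (plus E-value for ``blast_hit``).

    ``blast_hit`` accepts BLAST tabular (outfmt 6) files: columns 1, 2 and 11
    (query, subject, E-value) are used and the rest ignored.
    """
    path = Path(path)
    records: list[tuple[str, str, float | None]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected at least 2 columns")
            a, b = fields[0], fields[1]
            score: float | None = None
            if data_type == "blast_hit":
                if len(fields) >= 11:
                    raw = fields[10]
                elif len(fields) >= 3:
                    raw = fields[2]
                else:
                    raise FormatError(f"{path}:{lineno}: blast_hit requires an E-value column")
                try:
                    score = float(raw)
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: bad E-value {raw!r}") from exc
            elif len(fields) >= 3 and fields[2] != "":
                try:
                    score = float(fields[2])
                except ValueError:
                    score = None
            records.append((a, b, score))
    out = RawEdgeList(species=species, data_type=data_type, records=records)
    if not out.records:
        logger.warning("%s: empty %s edge list", path, data_type)
    else:
        logger.info("%s: %d %s records", path, len(out.records), data_type)
    return out


def write_edge_list(raw: RawEdgeList, path: str | Path, **provenance) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(
            _provenance_line(species=raw.species, data_type=raw.data_type, **provenance)
            + "\n"
        )
        for a, b, score in raw.records:
            if score is None:
                fh.write(f"{a}\t{b}\n")
            else:
                fh.write(f"{a}\t{b}\t{score:g}\n")


# ---------------------------------------------------------------------------
# ontology and annotations


def read_ontology(
    obo_path: str | Path,
    gaf_path: str | Path,
    namespace: str = "biological_process",
    evidence_filter: set[str] | str = "all",
    species: str = "",
):
    """Read an OBO ontology plus GAF 2.x annotations.

    Obsolete terms are dropped; annotations are restricted to the requested
    namespace and evidence codes and stored unpropagated (ancestor closure is
    computed where an operation needs it).  Rows referencing terms absent
    from the ontology are skipped with a warning.
    """
    from .go_semantics import AnnotationSet, OntologyDAG

    multigraph = obonet.read_obo(str(obo_path))  # skips obsolete terms
    g = nx.DiGraph()
    for term, data in multigraph.nodes(data=True):
        if data.get("namespace", namespace) != namespace:
            continue
        g.add_node(term, name=data.get("name", ""))
    for child, parent, relation in multigraph.edges(keys=True):
        if relation not in ("is_a", "part_of"):
            continue
        if child in g and parent in g:
            # prefer is_a when both relation types link the same pair
            if g.has_edge(child, parent) and g.edges[child, parent]["relation"] == "is_a":
                continue
            g.add_edge(child, parent, relation=relation)
    if not nx.is_directed_acyclic_graph(g):
        raise FormatError(f"{obo_path}: cyclic is_a/part_of graph")
    dag = OntologyDAG(graph=g, namespace=namespace)

    aspect = _NAMESPACE_ASPECT[namespace]
    annotations: dict[str, set[str]] = {}
    evidence: dict[tuple[str, str], set[str]] = {}
    n_skipped = 0
    with open(gaf_path) as fh:
        for rec in gafiterator(fh):
            if rec["Aspect"] != aspect:
                continue
            if any(q.startswith("NOT") for q in rec.get("Qualifier", []) if q):
                continue
            code = rec["Evidence"]
            if evidence_filter != "all" and code not in evidence_filter:
                continue
            term = rec["GO_ID"]
            gene = rec["DB_Object_ID"]
            if term not in dag:
                n_skipped += 1
                continue
            annotations.setdefault(gene, set()).add(term)
            evidence.setdefault((gene, term), set()).add(code)
    if n_skipped:
        logger.warning(
            "%s: skipped %d annotation rows with obsolete/unknown terms",
            gaf_path,
            n_skipped,
        )
    ann = AnnotationSet(species=species, annotations=annotations, evidence=evidence)
    ann.validate_against(dag)
    return dag, ann


# ---------------------------------------------------------------------------
# networks, partitions, orthology maps, reports


def write_scored_network(net, path: str | Path, **provenance) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(
            _provenance_line(species=net.species, data_type=net.data_type, **provenance)
            + "\n"
        )
        fh.write("gene_a\tgene_b\tweight\n")
        for a, b, w in sorted(net.edges()):
            fh.write(f"{a}\t{b}\t{w:.10g}\n")


def read_scored_network(path: str | Path, species: str = "", data_type: str = "ppi"):
    from .edge_scoring import ScoredNetwork

    net = ScoredNetwork(species=species, data_type=data_type)
    for a, b, w in _read_weighted_rows(path):
        net.add_edge(a, b, w)
    return net


def write_integrated_network(net, path: str | Path, **provenance) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_provenance_line(species=net.species, **provenance) + "\n")
        fh.write("gene_a\tgene_b\tweight\tprovenance\n")
        for a, b, w, prov in sorted(net.edges()):
            fh.write(f"{a}\t{b}\t{w:.10g}\t{','.join(sorted(prov))}\n")


def read_integrated_network(path: str | Path, species: str = ""):
    from .integration import IntegratedNetwork

    net = IntegratedNetwork(species=species)
    path = Path(path)
    with path.open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("gene_a\t"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}: expected 4 columns")
            net.add_edge(fields[0], fields[1], float(fields[2]), frozenset(fields[3].split(",")))
    return net


def _read_weighted_rows(path: str | Path) -> Iterable[tuple[str, str, float]]:
    path = Path(path)
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("gene_a\t"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns")
            yield fields[0], fields[1], float(fields[2])


def write_partition(part, path: str | Path, **provenance) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_provenance_line(species=part.species, **provenance) + "\n")
        fh.write("gene\tmodule_id\n")
        for mid in sorted(part.modules):
            for gene in sorted(part.modules[mid]):
                fh.write(f"{gene}\t{mid}\n")
        for gene in sorted(part.unassigned):
            fh.write(f"{gene}\tunassigned\n")


def read_partition(path: str | Path, species: str = ""):
    from .clustering import ModulePartition

    modules: dict[int, set[str]] = {}
    unassigned: set[str] = set()
    path = Path(path)
    with path.open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("gene\t"):
                continue
            gene, mid = line.split("\t")[:2]
            if mid == "unassigned":
                unassigned.add(gene)
            else:
                modules.setdefault(int(mid), set()).add(gene)
    return ModulePartition(
        species=species,
        modules={k: frozenset(v) for k, v in modules.items()},
        unassigned=unassigned,
        parameters={},
    )


def write_orthology(omap, path: str | Path, **provenance) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(
            _provenance_line(
                species_a=omap.species_a, species_b=omap.species_b, mode=omap.mode, **provenance
            )
            + "\n"
        )
        fh.write("gene_a\tgene_b\tprovenance\n")
        for a, b in sorted(omap.pairs):
            fh.write(f"{a}\t{b}\t{omap.provenance.get((a, b), 'imported')}\n")


def read_orthology(
    path: str | Path, species_a: str = "", species_b: str = "", mode: str = "one_to_one"
):
    from .orthology import OrthologyMap

    pairs: set[tuple[str, str]] = set()
    provenance: dict[tuple[str, str], str] = {}
    path = Path(path)
    with path.open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("gene_a\t"):
                continue
            fields = line.split("\t")
            a, b = fields[0], fields[1]
            pairs.add((a, b))
            provenance[(a, b)] = fields[2] if len(fields) > 2 else "imported"
    return OrthologyMap(
        species_a=species_a,
        species_b=species_b,
        pairs=pairs,
        mode=mode,
        provenance=provenance,
    )


def write_json_report(obj, path: str | Path) -> None:
    path = Path(path)
    data = obj.to_dict() if hasattr(obj, "to_dict") else obj
    with path.open("w") as fh:
        json.dump(data, fh, indent=2, sort_keys=True)
        fh.write("\n")
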