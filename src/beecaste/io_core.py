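"""Readers and writers for the external formats the pipeline touches.

Formats handled here: CGmap (the 8-column per-cytosine methylation call
table emitted by BS-Seeker2/CGmapTools), plain TSV differential-expression
tables, OrthoFinder ``Orthogroups.tsv``, a minimal OBO 1.2 subset (via
obonet), and FASTA (via Biopython). Coordinates are 1-based throughout,
matching the upstream methylation caller. Gzip input is sniffed from magic
bytes, never from the file extension.
"""

from __future__ import annotations

import dataclasses
import gzip
import io
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import networkx as nx
import obonet
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger("beecaste")
if not logger.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)


class ParseError(ValueError):
    """A malformed input line or stanza; message names the offending line."""


class SchemaError(ValueError):
    """An input table is missing a required column."""


class ValidationError(ValueError):
    """Structurally parseable input that violates a data-model invariant."""


_CONTEXT3 = {"CG", "CHG", "CHH"}
_DINUC = {"CA", "CC", "CG", "CT"}


@dataclass(frozen=True)
class CGmapRecord:
    """One cytosine site from a CGmap file.

    ``nucleotide`` is 'C' for a plus-strand cytosine and 'G' for a cytosine
    on the minus strand. ``level`` is the methylated-read fraction as
    printed by the caller (rounded); ``mc_count``/``coverage`` are exact.
    """

    seq_id: str
    nucleotide: str
    position: int  # 1-based
    context3: str  # CG / CHG / CHH
    dinucleotide: str  # CA / CC / CG / CT
    level: float
    mc_count: int
    coverage: int

    def validate(self) -> None:
        if self.nucleotide not in ("C", "G"):
            raise ValidationError(f"nucleotide must be C or G, got {self.nucleotide!r}")
        if self.context3 not in _CONTEXT3:
            raise ValidationError(f"unknown 3-letter context {self.context3!r}")
        if self.dinucleotide not in _DINUC:
            raise ValidationError(f"unknown dinucleotide {self.dinucleotide!r}")
        if (self.dinucleotide == "CG") != (self.context3 == "CG"):
            raise ValidationError(
                f"dinucleotide {self.dinucleotide} inconsistent with context {self.context3}"
            )
        if not 0 <= self.mc_count <= self.coverage:
            raise ValidationError(
                f"mc_count {self.mc_count} outside [0, coverage={self.coverage}]"
            )
        if (self.coverage > 0
                and abs(self.level - self.mc_count / self.coverage) > 0.005 + 1e-9):
            raise ValidationError(
                f"level {self.level} inconsistent with {self.mc_count}/{self.coverage}"
            )


@dataclass(frozen=True)
class DeRecord:
    """One differentially expressed superTranscript.

    ``log_fc`` follows the declared orientation (default: positive means
    forager-biased); ``bias`` is stored explicitly so downstream code never
    re-infers sign conventions. ``norm_count`` is the normalized read count
    when the table carries one (used for methylation-expression coupling).
    """

    gene_id: str
    log_fc: float
    p_value: float
    bias: str  # "nurse" | "forager"
    annotation: str = ""
    norm_count: float | None = None


@dataclass
class DeTable:
    species: str
    records: list[DeRecord]
    orientation: str = "forager-positive"

    def __iter__(self) -> Iterator[DeRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def subset(self, bias: str) -> "DeTable":
        return DeTable(self.species, [r for r in self.records if r.bias == bias],
                       self.orientation)

    @property
    def annotations(self) -> list[str]:
        return [r.annotation for r in self.records]


@dataclass
class OrthogroupMatrix:
    """Orthogroup x dataset gene counts plus per-dataset unassigned genes."""

    orthogroup_ids: list[str]
    dataset_ids: list[str]
    counts: pd.DataFrame  # index = orthogroup_ids, columns = dataset_ids
    genes: dict[str, dict[str, list[str]]] = field(default_factory=dict)
    unassigned: dict[str, list[str]] = field(default_factory=dict)

    def presence(self, orthogroup: str) -> dict[str, bool]:
        row = self.counts.loc[orthogroup]
        return {d: bool(row[d] > 0) for d in self.dataset_ids}

    def orthogroups_of(self, dataset: str, genes: Iterable[str]) -> set[str]:
        """Orthogroups containing any of `genes` in the given dataset column."""
        wanted = set(genes)
        hits = set()
        for og, per_ds in self.genes.items():
            if wanted.intersection(per_ds.get(dataset, ())):
                hits.add(og)
        return hits


@dataclass
class OntologyDag:
    """Minimal is_a ontology: terms, parent links, roots. Acyclic by construction."""

    terms: dict[str, tuple[str, str]]  # id -> (name, namespace)
    is_a: dict[str, set[str]]  # child -> parents
    root_ids: set[str]

    def parents(self, term: str) -> set[str]:
        return self.is_a.get(term, set())

    def ancestors(self, term: str) -> set[str]:
        out: set[str] = set()
        stack = [term]
        while stack:
            for p in self.is_a.get(stack.pop(), ()):
                if p not in out:
                    out.add(p)
                    stack.append(p)
        return out

    def children_map(self) -> dict[str, set[str]]:
        kids: dict[str, set[str]] = {t: set() for t in self.terms}
        for c, ps in self.is_a.items():
            for p in ps:
                kids[p].add(c)
        return kids


@dataclass
class RunConfig:
    """Run-level knobs; defaults encode the analysis constants (10x coverage
    filter, alpha = 0.01 significance, 10,000 resampling draws)."""

    seed: int = 0
    resample_reps: int = 10_000
    min_coverage: int = 10
    alpha: float = 0.01
    clade_config_path: str | None = None
    category_rules_path: str | None = None

    def __post_init__(self) -> None:
        if self.resample_reps < 1:
            raise ValidationError("resample_reps must be >= 1")
        if self.min_coverage < 1:
            raise ValidationError("min_coverage must be >= 1")


def _open_text(path: str | Path):
    """Open possibly-gzipped text, sniffing the gzip magic bytes."""
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, "r", encoding="utf-8")


# ---------------------------------------------------------------- CGmap

def read_cgmap(path: str | Path) -> list[CGmapRecord]:
    """Parse an (optionally gzipped) 8-column CGmap file.

    Raises ParseError naming the line for a wrong column count or unparsable
    field; ValidationError for records violating the data model
    (e.g. mc_count > coverage).
    """
    records: list[CGmapRecord] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 8:
                raise ParseError(
                    f"{path}: line {lineno}: expected 8 tab-separated columns, got {len(fields)}"
                )
            try:
                rec = CGmapRecord(
                    seq_id=fields[0],
                    nucleotide=fields[1],
                    position=int(fields[2]),
                    context3=fields[3],
                    dinucleotide=fields[4],
                    level=float(fields[5]),
                    mc_count=int(fields[6]),
                    coverage=int(fields[7]),
                )
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            try:
                rec.validate()
            except ValidationError as exc:
                raise ValidationError(f"{path}: line {lineno}: {exc}") from exc
            records.append(rec)
    return records


def write_cgmap(records: Iterable[CGmapRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for r in records:
            fh.write(
                f"{r.seq_id}\t{r.nucleotide}\t{r.position}\t{r.context3}\t"
                f"{r.dinucleotide}\t{r.level:g}\t{r.mc_count}\t{r.coverage}\n"
            )


# ---------------------------------------------------------------- DE tables

_DE_COLUMN_ALIASES = {
    "id": {"id", "gene_id", "gene", "supertranscript"},
    "logFC": {"logfc", "log_fc", "log2foldchange", "log2fc"},
    "p_value": {"p_value", "pvalue", "p-value", "pval", "padj"},
    "annotation": {"annotation", "description", "blast_hit"},
    "norm_count": {"norm_count", "normalized_count", "basemean", "mean_count"},
}


def _resolve_columns(columns: Sequence[str]) -> dict[str, str]:
    lower = {c.lower(): c for c in columns}
    resolved: dict[str, str] = {}
    for canonical, aliases in _DE_COLUMN_ALIASES.items():
        for alias in aliases:
            if alias in lower:
                resolved[canonical] = lower[alias]
                break
    return resolved


def read_de_table(path: str | Path, species: str = "",
                  orientation: str = "forager-positive") -> DeTable:
    """Read a per-gene DE table (TSV with id, logFC, p-value, annotation).

    ``orientation`` declares which subcaste a positive logFC favors:
    "forager-positive" (default) or "nurse-positive". Bias is derived from
    the logFC sign once, here, and stored on every record.
    """
    if orientation not in ("forager-positive", "nurse-positive"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = _resolve_columns(df.columns)
    missing = [c for c in ("id", "logFC", "p_value") if c not in cols]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
    pos_bias = "forager" if orientation == "forager-positive" else "nurse"
    neg_bias = "nurse" if pos_bias == "forager" else "forager"
    records = []
    for _, row in df.iterrows():
        lfc = float(row[cols["logFC"]])
        annot = ""
        if "annotation" in cols and pd.notna(row[cols["annotation"]]):
            annot = str(row[cols["annotation"]])
        nc = None
        if "norm_count" in cols and pd.notna(row[cols["norm_count"]]):
            nc = float(row[cols["norm_count"]])
        records.append(
            DeRecord(
                gene_id=str(row[cols["id"]]),
                log_fc=lfc,
                p_value=float(row[cols["p_value"]]),
                bias=pos_bias if lfc >= 0 else neg_bias,
                annotation=annot,
                norm_count=nc,
            )
        )
    return DeTable(species=species or str(path), records=records, orientation=orientation)


def write_de_table(table: DeTable, path: str | Path) -> None:
    rows = [
        {
            "id": r.gene_id,
            "logFC": r.log_fc,
            "p_value": r.p_value,
            "annotation": r.annotation,
            "norm_count": "" if r.norm_count is None else r.norm_count,
        }
        for r in table.records
    ]
    pd.DataFrame(rows, columns=["id", "logFC", "p_value", "annotation", "norm_count"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------- Orthogroups.tsv

def read_orthogroups(path: str | Path) -> OrthogroupMatrix:
    """Parse an OrthoFinder-style Orthogroups.tsv.

    First column is the orthogroup id; each further column is one dataset;
    cells are comma-separated gene ids (possibly empty). Duplicate
    orthogroup ids raise ValidationError.
    """
    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise ParseError(f"{path}: empty file")
        cols = header.split("\t")
        dataset_ids = cols[1:]
        if len(set(dataset_ids)) != len(dataset_ids):
            raise ValidationError(f"{path}: duplicate dataset column names")
        og_ids: list[str] = []
        counts_rows: list[list[int]] = []
        genes: dict[str, dict[str, list[str]]] = {}
        seen: set[str] = set()
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(cols):
                raise ParseError(
                    f"{path}: line {lineno}: expected {len(cols)} columns, got {len(fields)}"
                )
            og = fields[0]
            if og in seen:
                raise ValidationError(f"{path}: line {lineno}: duplicate orthogroup id {og!r}")
            seen.add(og)
            og_ids.append(og)
            per_ds: dict[str, list[str]] = {}
            row_counts = []
            for ds, cell in zip(dataset_ids, fields[1:]):
                ids = [g.strip() for g in cell.split(",") if g.strip()] if cell.strip() else []
                per_ds[ds] = ids
                row_counts.append(len(ids))
            genes[og] = per_ds
            counts_rows.append(row_counts)
    counts = pd.DataFrame(counts_rows, index=og_ids, columns=dataset_ids, dtype=int)
    return OrthogroupMatrix(orthogroup_ids=og_ids, dataset_ids=dataset_ids,
                            counts=counts, genes=genes)


def write_orthogroups(matrix: OrthogroupMatrix, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("Orthogroup\t" + "\t".join(matrix.dataset_ids) + "\n")
        for og in matrix.orthogroup_ids:
            cells = [", ".join(matrix.genes.get(og, {}).get(d, [])) for d in matrix.dataset_ids]
            fh.write(og + "\t" + "\t".join(cells) + "\n")


def read_unassigned(path: str | Path) -> dict[str, list[str]]:
    """Read an Orthogroups_UnassignedGenes-style TSV (same dialect, one gene
    per row under its dataset column)."""
    mat = read_orthogroups(path)
    out: dict[str, list[str]] = {d: [] for d in mat.dataset_ids}
    for og in mat.orthogroup_ids:
        for d, ids in mat.genes[og].items():
            out[d].extend(ids)
    return out


# ---------------------------------------------------------------- OBO

def read_obo_min(path: str | Path) -> OntologyDag:
    """Read a minimal OBO 1.2 ontology (id/name/namespace/is_a; obsolete
    terms dropped). Verifies acyclicity, naming a cycle member on failure."""
    graph = obonet.read_obo(str(path))  # obonet drops obsolete stanzas
    terms: dict[str, tuple[str, str]] = {}
    is_a: dict[str, set[str]] = {}
    for node, data in graph.nodes(data=True):
        terms[node] = (data.get("name", node), data.get("namespace", ""))
    for child, parent, key in graph.edges(keys=True):
        if key != "is_a":
            continue
        is_a.setdefault(child, set()).add(parent)
    # restrict to is_a reachability for cycle check
    g = nx.DiGraph()
    g.add_nodes_from(terms)
    for c, ps in is_a.items():
        for p in ps:
            g.add_edge(c, p)
    if not nx.is_directed_acyclic_graph(g):
        member = next(iter(nx.find_cycle(g)))[0]
        raise ValidationError(f"{path}: is_a cycle detected involving term {member!r}")
    roots = {t for t in terms if not is_a.get(t)}
    return OntologyDag(terms=terms, is_a={k: set(v) for k, v in is_a.items()}, root_ids=roots)


# ---------------------------------------------------------------- FASTA

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA as (id, uppercase sequence) pairs; id is the first
    whitespace token of the header. A sequence line before any header is a
    ParseError; empty records are retained with a warning."""
    with _open_text(path) as fh:
        first = fh.readline()
        while first and not first.strip():
            first = fh.readline()
        if first and not first.startswith(">"):
            raise ParseError(f"{path}: sequence line before any FASTA header")
    out: list[tuple[str, str]] = []
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            seq = str(rec.seq).upper()
            if not seq:
                logger.warning("FASTA record %s has empty sequence", rec.id)
            out.append((rec.id, seq))
    return out


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sid, seq in records:
            fh.write(f">{sid}\n")
            for i in range(0, max(len(seq), 1), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------- config

def read_config(path: str | Path) -> RunConfig:
    """Read a declarative key=value config file into a RunConfig."""
    kv: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ParseError(f"{path}: expected key=value, got {line!r}")
            k, v = line.split("=", 1)
            kv[k.strip()] = v.strip()
    cfg = RunConfig(
        seed=int(kv.get("seed", 0)),
        resample_reps=int(kv.get("resample_reps", 10_000)),
        min_coverage=int(kv.get("min_coverage", 10)),
        alpha=float(kv.get("alpha", 0.01)),
        clade_config_path=kv.get("clade_config_path"),
        category_rules_path=kv.get("category_rules_path"),
    )
    logger.info("run config loaded: seed=%d reps=%d min_coverage=%d alpha=%g",
                cfg.seed, cfg.resample_reps, cfg.min_coverage, cfg.alpha)
    return cfg


def config_to_dict(cfg: RunConfig) -> dict:
    return dataclasses.asdict(cfg)
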