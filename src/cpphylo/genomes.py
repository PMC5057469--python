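"""Plastid genome content and size comparison tables.

Genome summaries mirror a published-style statistics table: one row per
taxon with genome length, GC content, and feature counts.  Values prefixed
``>=`` (or the typographic ``≥``) mark draft genomes: those counts are
lower bounds and the record is flagged incomplete, excluding it from
min/max genome-size comparisons.  A packaged fixture transcribes the
Nemaliales + outgroup table; gene-content records (per-gene copy counts,
pseudogene status) can be attached for presence/absence matrices.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import pandas as pd

_COUNT_COLS = ("protein_genes", "orfs", "trna", "tmrna", "rrna", "ncrna", "introns")


@dataclass
class GenomeRecord:
    taxon: str
    family: str
    group: str  # ingroup | outgroup
    genome_length: int
    complete: bool
    gc_percent: float | None = None
    counts: dict = field(default_factory=dict)
    accession: str = ""
    genes: dict = field(default_factory=dict)  # gene name -> copy count
    pseudogenes: set = field(default_factory=set)

    def __post_init__(self):
        if self.genome_length <= 0:
            raise ValueError(f"{self.taxon}: genome length must be positive")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError(f"{self.taxon}: negative feature count")


def _parse_value(raw: str, taxon: str, column: str):
    """Parse a possibly '>='-prefixed integer; returns (value, is_bound)."""
    s = str(raw).strip().replace("≥", ">=").replace(",", "").replace(" ", "")
    bound = s.startswith(">=")
    if bound:
        s = s[2:]
    try:
        return int(s), bound
    except ValueError as exc:
        raise ValueError(f"malformed count {raw!r} for {taxon!r}, column {column!r}") from exc


def packaged_genome_table():
    """Path to the packaged genome-statistics fixture (TSV)."""
    return importlib.resources.files("cpphylo").joinpath("data/genome_table.tsv")


def read_genome_table(path=None) -> list[GenomeRecord]:
    """Read a genome-statistics TSV into records (packaged fixture by default)."""
    if path is None:
        path = packaged_genome_table()
    df = pd.read_csv(path, sep="\t", dtype=str)
    records = []
    for _, row in df.iterrows():
        taxon = row["species"]
        length, incomplete = _parse_value(row["genome_length"], taxon, "genome_length")
        counts = {}
        for col in _COUNT_COLS:
            if col in df.columns and str(row[col]).strip() not in ("", "-", "nan"):
                counts[col], b = _parse_value(row[col], taxon, col)
                incomplete = incomplete or b
        gc = None
        if str(row.get("gc_percent", "-")).strip() not in ("", "-", "nan"):
            gc = float(row["gc_percent"])
        records.append(
            GenomeRecord(
                taxon=taxon,
                family=row["family"],
                group=row.get("group", "ingroup"),
                genome_length=length,
                complete=not incomplete,
                gc_percent=gc,
                counts=counts,
                accession=row.get("accession", ""),
            )
        )
    return records


def write_genome_table(records, path) -> None:
    """Write records back to TSV, preserving lower-bound markers."""
    rows = []
    for r in records:
        prefix = "" if r.complete else ">="
        row = {
            "family": r.family,
            "species": r.taxon,
            "accession": r.accession,
            "group": r.group,
            "genome_length": f"{prefix}{r.genome_length}",
            "gc_percent": "-" if r.gc_percent is None else f"{r.gc_percent}",
        }
        for col in _COUNT_COLS:
            row[col] = f"{prefix}{r.counts[col]}" if col in r.counts else "-"
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def attach_gene_content(records, table) -> list:
    """Attach per-taxon gene copy counts from a long-form table.

    ``table`` is a DataFrame or TSV path with columns taxon, gene, count
    and an optional status column ({present, absent, pseudogene}).
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table, sep="\t")
    by_taxon = {r.taxon: r for r in records}
    for _, row in table.iterrows():
        rec = by_taxon.get(row["taxon"])
        if rec is None:
            raise ValueError(f"gene content for unknown taxon {row['taxon']!r}")
        rec.genes[row["gene"]] = int(row.get("count", 1))
        if str(row.get("status", "present")) == "pseudogene":
            rec.pseudogenes.add(row["gene"])
    return records


def presence_absence_matrix(records, gene_set) -> pd.DataFrame:
    """Taxon x gene copy-count matrix from attached gene content.

    Pseudogenes count as absent (0) here; they remain listed in each
    record's ``pseudogenes`` set for separate reporting.
    """
    gene_set = list(gene_set)
    data = {
        r.taxon: [
            0 if g in r.pseudogenes else int(r.genes.get(g, 0)) for g in gene_set
        ]
        for r in records
    }
    return pd.DataFrame.from_dict(data, orient="index", columns=gene_set)


def absence_summary(matrix: pd.DataFrame) -> dict:
    """Genes absent from at least one taxon, with the taxa lacking them."""
    out = {}
    for gene in matrix.columns:
        lacking = sorted(matrix.index[matrix[gene] == 0])
        if lacking:
            out[gene] = lacking
    return out


def size_summary(records):
    """(shortest record, longest record, difference in bp) over complete
    ingroup genomes only."""
    usable = [r for r in records if r.complete and r.group == "ingroup"]
    if len(usable) < 2:
        raise ValueError("need at least 2 complete ingroup genomes")
    lo = min(usable, key=lambda r: (r.genome_length, r.taxon))
    hi = max(usable, key=lambda r: (r.genome_length, r.taxon))
    return lo, hi, hi.genome_length - lo.genome_length
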