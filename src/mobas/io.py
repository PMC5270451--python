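"""Readers and writers for the four input file kinds and the module report.

The file contracts are deliberately minimal and PLINK-friendly:

* ``.assoc`` — whitespace-delimited table with a header; required columns
  ``SNP`` and ``P`` (case-insensitive), optional ``CHR`` and ``BP``.
* SNP–gene map — tab-delimited ``snp_id<TAB>gene_id`` rows, no header.
* PPI edge list — ``gene_a  gene_b  [weight]`` rows; a missing weight means an
  unweighted interaction and defaults to 1.0.
* Module report — tab-delimited table of ranked subnetworks with their
  significance columns and a comma-joined gene list.
"""

from __future__ import annotations

import logging
import math
from collections import OrderedDict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FileFormatError",
    "SnpRecord",
    "SnpGeneMap",
    "ModuleReport",
    "read_assoc",
    "read_snp_gene_map",
    "read_ppi",
    "write_modules",
    "read_modules",
]


class FileFormatError(ValueError):
    """An input file does not follow the expected layout."""


@dataclass(frozen=True)
class SnpRecord:
    """One assayed locus: identifier, optional coordinates and QC statistics.

    ``p_value`` lives in the open-closed interval (0, 1]; a p-value of exactly
    zero is rejected because gene scores are ``-log(p)``.
    """

    snp_id: str
    p_value: float | None = None
    chromosome: str | None = None
    position: int | None = None
    missing_rate: float | None = None
    maf: float | None = None

    def __post_init__(self) -> None:
        if not self.snp_id:
            raise ValueError("snp_id must be non-empty")
        if self.p_value is not None and not (0.0 < self.p_value <= 1.0):
            raise ValueError(
                f"p-value for {self.snp_id} must be in (0, 1], got {self.p_value!r}"
            )


class SnpGeneMap:
    """Many-to-many SNP→gene assignment with a per-gene inverse view."""

    def __init__(self, pairs: Iterable[tuple[str, str]]):
        seen: set[tuple[str, str]] = set()
        self._pairs: list[tuple[str, str]] = []
        self._snps_of: dict[str, set[str]] = {}
        self._genes_of: dict[str, set[str]] = {}
        for snp, gene in pairs:
            pair = (str(snp), str(gene))
            if pair in seen:
                continue
            seen.add(pair)
            self._pairs.append(pair)
            self._snps_of.setdefault(pair[1], set()).add(pair[0])
            self._genes_of.setdefault(pair[0], set()).add(pair[1])

    @property
    def pairs(self) -> list[tuple[str, str]]:
        return list(self._pairs)

    @property
    def genes(self) -> set[str]:
        return set(self._snps_of)

    @property
    def snps(self) -> set[str]:
        return set(self._genes_of)

    def snps_of(self, gene: str) -> frozenset[str]:
        return frozenset(self._snps_of.get(gene, ()))

    def genes_of(self, snp: str) -> frozenset[str]:
        return frozenset(self._genes_of.get(snp, ()))

    def restrict_to_snps(self, snp_ids: Iterable[str]) -> "SnpGeneMap":
        """Drop pairs whose SNP is not in ``snp_ids`` (e.g. after QC filters)."""
        keep = set(snp_ids)
        return SnpGeneMap(p for p in self._pairs if p[0] in keep)

    def __len__(self) -> int:
        return len(self._pairs)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self._pairs)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SnpGeneMap):
            return NotImplemented
        return set(self._pairs) == set(other._pairs)


@dataclass
class ModuleReport:
    """One ranked subnetwork as written to the results table."""

    rank: int
    size: int
    score: float
    genes: list[str]
    scheme: str | None = None
    q_pheno: float | None = None
    q_net: float | None = None
    q_combined: float | None = None

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ValueError("rank must be a positive integer")
        if self.size != len(self.genes):
            raise ValueError("size must equal the number of genes")


def read_assoc(path: str | Path) -> list[SnpRecord]:
    """Parse a PLINK-style ``.assoc`` association table.

    Raises :class:`FileFormatError` when the header lacks the SNP or P column
    and :class:`ValueError` (with the offending row number) for unparsable or
    out-of-range p-values or duplicate SNP ids.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=r"\s+", dtype=str)
    cols = {c.upper(): c for c in df.columns}
    for required in ("SNP", "P"):
        if required not in cols:
            raise FileFormatError(f"{path}: missing required column {required!r}")
    snp_col, p_col = cols["SNP"], cols["P"]
    chr_col = cols.get("CHR")
    bp_col = cols.get("BP")

    records: list[SnpRecord] = []
    seen: set[str] = set()
    for row_number, (_, row) in enumerate(df.iterrows(), start=2):
        snp_id = str(row[snp_col])
        if snp_id in seen:
            raise ValueError(f"{path}: duplicate SNP id {snp_id!r} at row {row_number}")
        seen.add(snp_id)
        raw_p = row[p_col]
        try:
            p = float(raw_p)
        except (TypeError, ValueError):
            raise ValueError(
                f"{path}: unparsable p-value {raw_p!r} at row {row_number}"
            ) from None
        if not (0.0 < p <= 1.0) or math.isnan(p):
            raise ValueError(
                f"{path}: p-value {p!r} out of (0, 1] at row {row_number}"
            )
        position = None
        if bp_col is not None and not pd.isna(row[bp_col]):
            position = int(float(row[bp_col]))
        chromosome = None
        if chr_col is not None and not pd.isna(row[chr_col]):
            chromosome = str(row[chr_col])
        records.append(
            SnpRecord(snp_id=snp_id, p_value=p, chromosome=chromosome, position=position)
        )
    return records


def read_snp_gene_map(path: str | Path) -> SnpGeneMap:
    """Read a tab-delimited SNP→gene map (no header); duplicates collapse."""
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        for line_number, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2 or not fields[0].strip() or not fields[1].strip():
                raise FileFormatError(
                    f"{path}: malformed SNP-gene row at line {line_number}: {line!r}"
                )
            pairs.append((fields[0].strip(), fields[1].strip()))
    return SnpGeneMap(pairs)


def read_ppi(path: str | Path) -> nx.Graph:
    """Read a weighted undirected PPI edge list into a simple graph.

    Missing weights default to 1.0 (unweighted networks), self-loops are
    dropped, and duplicate edges keep the maximum weight so that re-reading a
    row-permuted file yields an identical graph.
    """
    path = Path(path)
    graph = nx.Graph()
    n_self_loops = 0
    with open(path) as fh:
        for line_number, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) < 2:
                raise FileFormatError(
                    f"{path}: expected at least 2 columns at line {line_number}"
                )
            u, v = fields[0], fields[1]
            weight = 1.0
            if len(fields) >= 3:
                try:
                    weight = float(fields[2])
                except ValueError:
                    raise FileFormatError(
                        f"{path}: unparsable weight at line {line_number}"
                    ) from None
                if not (0.0 < weight <= 1.0):
                    raise ValueError(
                        f"{path}: weight {weight} outside (0, 1] at line {line_number}"
                    )
            if u == v:
                n_self_loops += 1
                continue
            if graph.has_edge(u, v):
                graph[u][v]["weight"] = max(graph[u][v]["weight"], weight)
            else:
                graph.add_edge(u, v, weight=weight)
    if n_self_loops:
        logger.info("read_ppi: dropped %d self-loop rows from %s", n_self_loops, path)
    return graph


_REPORT_COLUMNS = ("rank", "size", "score", "q_pheno", "q_net", "q_combined", "genes")


def _format_q(q: float | None, rank: int, m_null: int | None) -> str:
    if q is None:
        return "NA"
    if q == 0.0 and m_null:
        # Mirror the "< 1/(M*i)" convention for empirical q-values that beat
        # every pooled null score.
        return "<" + format(1.0 / (m_null * rank), ".6g")
    return format(q, ".6g")


def write_modules(
    reports: Sequence[ModuleReport], path: str | Path, m_null: int | None = None
) -> None:
    """Write ranked subnetworks as a tab-delimited table (6 significant digits)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t".join(_REPORT_COLUMNS) + "\n")
        for rep in reports:
            fh.write(
                "\t".join(
                    [
                        str(rep.rank),
                        str(rep.size),
                        format(rep.score, ".6g"),
                        _format_q(rep.q_pheno, rep.rank, m_null),
                        _format_q(rep.q_net, rep.rank, m_null),
                        _format_q(rep.q_combined, rep.rank, m_null),
                        ",".join(rep.genes),
                    ]
                )
                + "\n"
            )


def _parse_q(token: str) -> float | None:
    if token == "NA":
        return None
    if token.startswith("<"):
        return 0.0
    return float(token)


def read_modules(path: str | Path, scheme: str | None = None) -> list[ModuleReport]:
    """Parse a module report written by :func:`write_modules`."""
    path = Path(path)
    reports: list[ModuleReport] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != _REPORT_COLUMNS:
            raise FileFormatError(f"{path}: unexpected report header {header!r}")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(_REPORT_COLUMNS):
                raise FileFormatError(f"{path}: malformed report row {line!r}")
            reports.append(
                ModuleReport(
                    rank=int(fields[0]),
                    size=int(fields[1]),
                    score=float(fields[2]),
                    q_pheno=_parse_q(fields[3]),
                    q_net=_parse_q(fields[4]),
                    q_combined=_parse_q(fields[5]),
                    genes=fields[6].split(",") if fields[6] else [],
                    scheme=scheme,
                )
            )
    return reports
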