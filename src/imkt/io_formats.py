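"""Readers and writers for every external representation the toolkit touches.

Formats
-------
DAF table
    Tab-delimited with header ``daf<TAB>Pn<TAB>Ps`` (one row per frequency
    class). Alternative column names are absorbed by a user-supplied
    ``dialect`` mapping of {"daf", "pn", "ps"} to the file's header names.
Divergence file
    One tab-delimited row with header ``mn<TAB>Dn<TAB>ms<TAB>Ds``; the site
    totals ``mn``/``ms`` may be omitted or left blank ("NA").
Alignment
    Multi-record aligned FASTA; the outgroup record is named by id.
Gene dataset
    JSON-lines, one record per gene with the DAF bins inline; a long-format
    TSV importer (gene_id, daf, pn, ps) is provided for convenience.

All text I/O is UTF-8 with '.' as the decimal separator.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Iterable, Mapping

from Bio import SeqIO

from .types import (
    Alignment,
    DafBin,
    DafTable,
    DivergenceSummary,
    GeneRecord,
    ValidationError,
)


class ParseError(ValueError):
    """Raised on malformed input files; message names the offending line."""


_DAF_COLUMNS = {"daf": "daf", "pn": "Pn", "ps": "Ps"}
_DIV_COLUMNS = {"mn": "mn", "dn": "Dn", "ms": "ms", "ds": "Ds"}


def _resolve_columns(
    header: list[str], wanted: Mapping[str, str], dialect: Mapping[str, str] | None
) -> dict[str, int]:
    """Map canonical field names to column indices, honouring a dialect."""
    names = {k: (dialect or {}).get(k, v) for k, v in wanted.items()}
    lower = [h.strip().lower() for h in header]
    out = {}
    for field, col in names.items():
        try:
            out[field] = lower.index(col.lower())
        except ValueError:
            out[field] = -1
    return out


def read_daf_table(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    n_sample: int | None = None,
) -> DafTable:
    """Read a tab-delimited DAF spectrum.

    Rows with zero counts are preserved; rows are sorted ascending by
    frequency. ``n_sample`` defaults to 1 + the number of rows, the depth
    implied by a complete grid of frequencies i/n for i=1..n-1.
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    rows = [(i + 1, ln) for i, ln in enumerate(lines) if ln.strip()]
    if not rows:
        raise ParseError(f"{path}: empty file")
    header = rows[0][1].split("\t")
    cols = _resolve_columns(header, _DAF_COLUMNS, dialect)
    missing = [f for f, idx in cols.items() if idx < 0]
    if missing:
        raise ParseError(f"{path}: header missing column(s) {missing}: {header}")
    bins = []
    for lineno, ln in rows[1:]:
        parts = ln.split("\t")
        try:
            daf = float(parts[cols["daf"]])
            pn = int(parts[cols["pn"]])
            ps = int(parts[cols["ps"]])
        except (ValueError, IndexError) as exc:
            raise ParseError(f"{path}: malformed row at line {lineno}: {ln!r}") from exc
        bins.append(DafBin(daf, pn, ps))
    bins.sort(key=lambda b: b.daf)
    if n_sample is None:
        n_sample = len(bins) + 1
    try:
        return DafTable(n_sample=n_sample, bins=bins)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_daf_table(table: DafTable, path: str | Path) -> None:
    path = Path(path)
    lines = ["daf\tPn\tPs"]
    for b in table.bins:
        lines.append(f"{b.daf!r}\t{b.pn}\t{b.ps}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_divergence(
    path: str | Path, dialect: Mapping[str, str] | None = None
) -> DivergenceSummary:
    """Read a one-row divergence-counts file; absent mn/ms become None."""
    path = Path(path)
    lines = [ln for ln in path.read_text(encoding="utf-8").splitlines() if ln.strip()]
    if len(lines) < 2:
        raise ParseError(f"{path}: expected a header and one data row")
    header = lines[0].split("\t")
    cols = _resolve_columns(header, _DIV_COLUMNS, dialect)
    if cols["dn"] < 0 or cols["ds"] < 0:
        raise ParseError(f"{path}: header must name Dn and Ds columns: {header}")
    parts = lines[1].split("\t")

    def _get(field: str, cast: type) -> Any:
        idx = cols[field]
        if idx < 0 or idx >= len(parts):
            return None
        raw = parts[idx].strip()
        if raw in ("", "NA", "na", "None"):
            return None
        try:
            return cast(raw)
        except ValueError as exc:
            raise ParseError(f"{path}: bad {field} value {raw!r} at line 2") from exc

    dn = _get("dn", int)
    ds = _get("ds", int)
    if dn is None or ds is None:
        raise ParseError(f"{path}: Dn and Ds are required")
    return DivergenceSummary(dn=dn, ds=ds, m_n=_get("mn", float), m_s=_get("ms", float))


def write_divergence(div: DivergenceSummary, path: str | Path) -> None:
    path = Path(path)
    mn = "NA" if div.m_n is None else repr(div.m_n)
    ms = "NA" if div.m_s is None else repr(div.m_s)
    path.write_text(
        "mn\tDn\tms\tDs\n" + f"{mn}\t{div.dn}\t{ms}\t{div.ds}\n", encoding="utf-8"
    )


def read_fasta_alignment(path: str | Path, outgroup_id: str) -> Alignment:
    """Read an aligned multi-FASTA and split off the named outgroup record."""
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) < 3:
        raise ValidationError(
            f"{path}: need >= 3 records (2 ingroup + 1 outgroup), got {len(records)}"
        )
    ids = [r.id for r in records]
    dup = {i for i in ids if ids.count(i) > 1}
    if dup:
        raise ValidationError(f"{path}: duplicate record id(s): {sorted(dup)}")
    outgroup = None
    ingroup = []
    for r in records:
        pair = (r.id, str(r.seq))
        if r.id == outgroup_id:
            outgroup = pair
        else:
            ingroup.append(pair)
    if outgroup is None:
        raise ValidationError(f"{path}: outgroup id {outgroup_id!r} not found")
    return Alignment(ingroup=ingroup, outgroup=outgroup)


def write_fasta_alignment(aln: Alignment, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for rid, seq in list(aln.ingroup) + [aln.outgroup]:
            fh.write(f">{rid}\n{seq}\n")


def _gene_to_json(gene: GeneRecord) -> dict[str, Any]:
    return {
        "gene_id": gene.gene_id,
        "n_sample": gene.daf.n_sample,
        "daf": [[b.daf, b.pn, b.ps] for b in gene.daf.bins],
        "dn": gene.div.dn,
        "ds": gene.div.ds,
        "m_n": gene.div.m_n,
        "m_s": gene.div.m_s,
        "metadata": gene.metadata,
    }


def _gene_from_json(obj: Mapping[str, Any]) -> GeneRecord:
    daf = DafTable(
        n_sample=obj["n_sample"],
        bins=[DafBin(float(d), int(pn), int(ps)) for d, pn, ps in obj["daf"]],
    )
    div = DivergenceSummary(
        dn=int(obj["dn"]),
        ds=int(obj["ds"]),
        m_n=obj.get("m_n"),
        m_s=obj.get("m_s"),
    )
    return GeneRecord(
        gene_id=obj["gene_id"], daf=daf, div=div, metadata=dict(obj.get("metadata", {}))
    )


def read_gene_dataset(path: str | Path) -> list[GeneRecord]:
    """Read a JSON-lines gene dataset (one object per gene, DAF bins inline)."""
    path = Path(path)
    genes: list[GeneRecord] = []
    seen: set[str] = set()
    for lineno, ln in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        if not ln.strip():
            continue
        try:
            obj = json.loads(ln)
            gene = _gene_from_json(obj)
        except (json.JSONDecodeError, KeyError, TypeError) as exc:
            raise ParseError(f"{path}: malformed record at line {lineno}") from exc
        if gene.gene_id in seen:
            raise ValidationError(f"{path}: duplicated gene_id {gene.gene_id!r}")
        seen.add(gene.gene_id)
        genes.append(gene)
    if not genes:
        raise ParseError(f"{path}: no gene records")
    return genes


def write_gene_dataset(genes: Iterable[GeneRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for gene in genes:
            fh.write(json.dumps(_gene_to_json(gene), sort_keys=True) + "\n")


def import_gene_daf_tsv(path: str | Path, n_sample: int) -> dict[str, DafTable]:
    """Import long-format TSV (gene_id, daf, pn, ps) into per-gene DAF tables."""
    path = Path(path)
    lines = [ln for ln in path.read_text(encoding="utf-8").splitlines() if ln.strip()]
    header = [h.strip().lower() for h in lines[0].split("\t")]
    try:
        gi, di, pi, si = (header.index(c) for c in ("gene_id", "daf", "pn", "ps"))
    except ValueError as exc:
        raise ParseError(f"{path}: header must name gene_id, daf, pn, ps") from exc
    acc: dict[str, list[DafBin]] = {}
    for lineno, ln in enumerate(lines[1:], 2):
        parts = ln.split("\t")
        try:
            acc.setdefault(parts[gi], []).append(
                DafBin(float(parts[di]), int(parts[pi]), int(parts[si]))
            )
        except (ValueError, IndexError) as exc:
            raise ParseError(f"{path}: malformed row at line {lineno}") from exc
    return {
        g: DafTable(n_sample=n_sample, bins=sorted(b, key=lambda x: x.daf))
        for g, b in acc.items()
    }


def write_results_json(results: Mapping[str, Any], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(results, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
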