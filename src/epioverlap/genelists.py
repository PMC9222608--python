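"""Gene lists and how they are built.

Everything downstream of this module consumes :class:`GeneList` objects.
They are constructed in three ways, mirroring how comparative-methylation
studies assemble their inputs:

* intersecting differentially methylated regions (DMRs, plus a flanking
  window, 5000 bp by default) with a genome annotation
  (:func:`map_dmrs_to_genes`);
* converting identifiers between namespaces with a local two-column table
  (:func:`convert_ids`);
* taking the union of lists from independent studies
  (:func:`union_lists`).

Coordinates are 1-based inclusive throughout (the GTF convention); BED
input (0-based half-open) is converted at read time.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from intervaltree import IntervalTree

from .errors import InputError

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "GeneList",
    "IdMap",
    "read_gtf",
    "read_dmr_table",
    "read_id_map",
    "read_gene_list",
    "write_gene_list",
    "map_dmrs_to_genes",
    "convert_ids",
    "union_lists",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A 1-based inclusive interval on a named sequence.

    ``payload`` carries free-form attributes such as a methylation
    difference in percentage points or a tissue label.
    """

    seq_name: str
    start: int
    end: int
    payload: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.seq_name:
            raise InputError("interval seq_name must be non-empty")
        if self.start < 1:
            raise InputError(f"interval start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise InputError(
                f"interval end {self.end} < start {self.start} on {self.seq_name}"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class GeneModel:
    """A gene extent with a stable identifier. Strand is '+', '-' or 'unknown'."""

    gene_id: str
    seq_name: str
    start: int
    end: int
    strand: str = "unknown"

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise InputError("gene_id must be non-empty")
        if self.start > self.end:
            raise InputError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-", "unknown"):
            object.__setattr__(self, "strand", "unknown")


def _normalize_ids(genes: Iterable[str]) -> tuple[str, ...]:
    """Trim whitespace, reject empties, deduplicate keeping first occurrence.

    Identifier case is preserved (Ensembl IDs are case-sensitive by
    convention).
    """
    seen: dict[str, None] = {}
    for g in genes:
        g = g.strip()
        if not g:
            raise InputError("empty gene identifier in list")
        seen.setdefault(g, None)
    return tuple(seen)


class GeneList:
    """A named, deduplicated, ordered collection of gene identifiers."""

    __slots__ = ("name", "genes", "provenance")

    def __init__(self, name: str, genes: Iterable[str], provenance: str = "") -> None:
        self.name = name
        self.genes = _normalize_ids(genes)
        self.provenance = provenance

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[str]:
        return iter(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneList):
            return NotImplemented
        return self.name == other.name and self.genes == other.genes

    def __repr__(self) -> str:
        return f"GeneList({self.name!r}, n={len(self.genes)})"

    def as_set(self) -> frozenset[str]:
        return frozenset(self.genes)


@dataclass(frozen=True)
class IdMap:
    """Mapping from source identifiers to zero-or-more target identifiers."""

    pairs: Mapping[str, tuple[str, ...]]

    def targets(self, source: str) -> tuple[str, ...]:
        return self.pairs.get(source, ())


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_GENE_ID_RE = re.compile(r'gene_id\s+"?([^";]+)"?')


def read_gtf(path: str | Path) -> list[GeneModel]:
    """Read gene models from a GTF file.

    Gene extents come from ``gene`` feature rows where present; for
    gene_ids that have no ``gene`` row the extent is the min start / max
    end over that gene's features (exons, CDS, ...). Strand conflicts
    across features collapse to ``unknown``.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"GTF file not found: {path}")

    # per gene_id: [seq, start, end, strand, from_gene_feature]
    extents: dict[str, list] = {}
    n_lines = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            n_lines += 1
            fields = line.split("\t")
            if len(fields) != 9:
                raise InputError(
                    f"{path}:{lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            seq, _source, feature, start_s, end_s, _score, strand, _frame, attrs = fields
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise InputError(
                    f"{path}:{lineno}: non-integer coordinates "
                    f"({start_s!r}, {end_s!r})"
                ) from None
            m = _GENE_ID_RE.search(attrs)
            if m is None:
                raise InputError(f"{path}:{lineno}: missing gene_id attribute")
            gene_id = m.group(1)
            strand = strand if strand in ("+", "-") else "unknown"
            is_gene = feature == "gene"
            rec = extents.get(gene_id)
            if rec is None:
                extents[gene_id] = [seq, start, end, strand, is_gene]
            elif is_gene and not rec[4]:
                extents[gene_id] = [seq, start, end, strand, True]
            elif rec[4] and not is_gene:
                pass  # a gene row already fixed the extent
            else:
                if rec[0] != seq:
                    raise InputError(
                        f"{path}:{lineno}: gene {gene_id} spans multiple "
                        f"sequences ({rec[0]}, {seq})"
                    )
                rec[1] = min(rec[1], start)
                rec[2] = max(rec[2], end)
                if rec[3] != strand:
                    rec[3] = "unknown"

    if n_lines == 0:
        logger.warning("GTF %s contains no feature lines", path)
    models = [
        GeneModel(gene_id=g, seq_name=r[0], start=r[1], end=r[2], strand=r[3])
        for g, r in extents.items()
    ]
    logger.info("read %d gene models from %s (%d feature lines)",
                len(models), path, n_lines)
    return models


def read_dmr_table(path: str | Path) -> list[GenomicInterval]:
    """Read a DMR table.

    Two dialects are auto-detected:

    * TSV with a header containing ``chrom``, ``start``, ``end`` (1-based
      inclusive), plus optional ``meth_diff`` / ``tissue`` columns that are
      stored in the interval payload;
    * headerless 3+-column BED (0-based half-open), converted to 1-based
      inclusive on read.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"DMR table not found: {path}")
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        logger.warning("DMR table %s is empty", path)
        return []

    header = lines[0].split("\t")
    has_header = {"chrom", "start", "end"} <= {h.lower() for h in header}
    out: list[GenomicInterval] = []
    if has_header:
        cols = {h.lower(): i for i, h in enumerate(header)}
        extra = [h for h in header if h.lower() not in ("chrom", "start", "end")]
        for lineno, line in enumerate(lines[1:], start=2):
            f = line.split("\t")
            if len(f) < len(header):
                raise InputError(f"{path}:{lineno}: expected {len(header)} fields")
            try:
                start, end = int(f[cols["start"]]), int(f[cols["end"]])
            except ValueError:
                raise InputError(f"{path}:{lineno}: non-integer coordinates") from None
            payload = {}
            for h in extra:
                v = f[header.index(h)]
                if h.lower() == "meth_diff":
                    try:
                        v = float(v)
                    except ValueError:
                        raise InputError(
                            f"{path}:{lineno}: meth_diff is not numeric: {v!r}"
                        ) from None
                payload[h] = v
            out.append(GenomicInterval(f[cols["chrom"]], start, end, payload))
    else:
        for lineno, line in enumerate(lines, start=1):
            f = line.split("\t")
            if len(f) < 3:
                raise InputError(f"{path}:{lineno}: BED line needs >= 3 fields")
            try:
                start0, end0 = int(f[1]), int(f[2])
            except ValueError:
                raise InputError(f"{path}:{lineno}: non-integer coordinates") from None
            out.append(GenomicInterval(f[0], start0 + 1, end0))
    logger.info("read %d DMRs from %s", len(out), path)
    return out


def read_id_map(path: str | Path) -> IdMap:
    """Read a two-column (source, target) TSV into an :class:`IdMap`."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"ID map not found: {path}")
    pairs: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 2:
                raise InputError(f"{path}:{lineno}: expected 2 tab-separated columns")
            src, tgt = f[0].strip(), f[1].strip()
            if not src or not tgt:
                raise InputError(f"{path}:{lineno}: empty identifier")
            bucket = pairs.setdefault(src, [])
            if tgt not in bucket:
                bucket.append(tgt)
    return IdMap({k: tuple(v) for k, v in pairs.items()})


def read_gene_list(path: str | Path, name: str | None = None) -> GeneList:
    """Read a gene list: one identifier per line ('#' comments ignored)."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"gene list not found: {path}")
    with open(path) as fh:
        ids = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    return GeneList(name or path.stem, ids, provenance=f"read from {path.name}")


def write_gene_list(gene_list: GeneList, path: str | Path,
                    with_provenance: bool = False) -> None:
    """Write one identifier per line; with ``with_provenance``, a TSV with
    list name and provenance columns instead."""
    path = Path(path)
    with open(path, "w") as fh:
        if with_provenance:
            fh.write("gene_id\tlist_name\tprovenance\n")
            for g in gene_list:
                fh.write(f"{g}\t{gene_list.name}\t{gene_list.provenance}\n")
        else:
            for g in gene_list:
                fh.write(g + "\n")


# ---------------------------------------------------------------------------
# core operations
# ---------------------------------------------------------------------------

def map_dmrs_to_genes(
    dmrs: Iterable[GenomicInterval],
    genes: Iterable[GeneModel],
    flank: int = 5000,
    name: str = "dmr_genes",
) -> GeneList:
    """Assign genes to DMRs: a gene is hit when its body shares >= 1 bp with
    a DMR extended by ``flank`` bp on both sides (clipped at position 1).

    Strand is ignored. A gene hit by several DMRs (e.g. in different
    tissues) counts once. DMRs on sequences absent from the annotation
    match nothing and trigger a warning only.
    """
    if flank < 0:
        raise InputError(f"flank must be >= 0, got {flank}")
    genes = list(genes)
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        # interval tree is half-open; store [start-1, end)
        trees.setdefault(g.seq_name, IntervalTree()).addi(g.start - 1, g.end, g)

    hits: dict[str, None] = {}
    missing_seqs: set[str] = set()
    dmr_list = list(dmrs)
    for dmr in dmr_list:
        tree = trees.get(dmr.seq_name)
        if tree is None:
            missing_seqs.add(dmr.seq_name)
            continue
        lo = max(1, dmr.start - flank) - 1
        hi = dmr.end + flank
        found = sorted(tree[lo:hi], key=lambda iv: (iv.begin, iv.data.gene_id))
        for iv in found:
            hits.setdefault(iv.data.gene_id, None)
    if missing_seqs:
        logger.warning(
            "%d DMR sequence name(s) absent from the annotation: %s",
            len(missing_seqs), ", ".join(sorted(missing_seqs)),
        )
    logger.info("mapped %d DMRs to %d unique genes (flank=%d bp)",
                len(dmr_list), len(hits), flank)
    return GeneList(
        name,
        hits,
        provenance=f"{len(dmr_list)} DMRs vs {len(genes)} genes, flank={flank} bp",
    )


def convert_ids(gene_list: GeneList, id_map: IdMap,
                drop_unmapped: bool = True) -> GeneList:
    """Translate every identifier through ``id_map``.

    Each source ID is replaced by all of its targets (one-to-many
    expansion); the result is deduplicated. IDs absent from the map are
    dropped (and counted) when ``drop_unmapped``, else retained verbatim.
    """
    out: list[str] = []
    n_unmapped = 0
    for g in gene_list:
        targets = id_map.targets(g)
        if targets:
            out.extend(targets)
        elif drop_unmapped:
            n_unmapped += 1
        else:
            out.append(g)
    if n_unmapped:
        logger.info("convert_ids(%s): dropped %d unmapped identifiers",
                    gene_list.name, n_unmapped)
    prov = (f"{gene_list.provenance}; id-converted from {len(gene_list)} IDs, "
            f"{n_unmapped} unmapped " +
            ("dropped" if drop_unmapped else "retained"))
    return GeneList(gene_list.name, out, provenance=prov)


def union_lists(lists: Iterable[GeneList], name: str) -> GeneList:
    """Set union of several gene lists, deduplicated, order-stable.

    Provenance records each source list's name and size.
    """
    lists = list(lists)
    if not lists:
        raise InputError("union_lists requires at least one list")
    merged: list[str] = []
    for lst in lists:
        merged.extend(lst)
    prov = "union of " + ", ".join(f"{l.name}(n={len(l)})" for l in lists)
    return GeneList(name, merged, provenance=prov)
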