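"""Cross-species list translation via orthologue and paralogue tables.

Comparative gene-list studies translate human lists into a target genome
two ways: orthologues only, or the "homologue" variant where the human
list is first widened by its within-genome paralogues (one hop, no
transitive closure) and the widened list is then translated through the
orthologue table. Both drop genes with no counterpart, counting them in
provenance — which is how a list of 588 human genes can translate into
589 targets when one-to-many orthology expands more than the drops
remove.

Tables are local BioMart-export-style TSVs; no live queries.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

from .errors import InputError
from .genelists import GeneList

logger = logging.getLogger(__name__)

__all__ = [
    "HomologyMap",
    "read_homology_table",
    "orthologues_of",
    "expand_with_paralogues",
]

RELATIONS = ("orthologue", "paralogue")


@dataclass(frozen=True)
class HomologyMap:
    """Many-to-many directed gene mapping tagged with its relation."""

    relation: str
    source_universe: str
    target_universe: str
    pairs: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        if self.relation not in RELATIONS:
            raise InputError(
                f"relation must be one of {RELATIONS}, got {self.relation!r}"
            )
        for src, targets in self.pairs.items():
            if not targets:
                raise InputError(f"homology map entry {src!r} has no targets")
            if self.relation == "paralogue" and src in targets:
                raise InputError(f"self-pair {src!r} in paralogue map")

    def targets(self, source: str) -> tuple[str, ...]:
        return self.pairs.get(source, ())

    @property
    def n_pairs(self) -> int:
        return sum(len(t) for t in self.pairs.values())


def read_homology_table(
    path: str | Path,
    relation: str,
    source_universe: str = "source",
    target_universe: str = "target",
) -> HomologyMap:
    """Read a 2+-column TSV (source gene, target gene[, homology_type]).

    When a third column is present only rows whose homology type contains
    ``relation`` (e.g. BioMart's ``ortholog_one2many``) are kept. Gzipped
    files are read transparently. Duplicate pairs are collapsed and
    logged.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"homology table not found: {path}")
    opener = gzip.open if path.suffix == ".gz" else open
    pairs: dict[str, list[str]] = {}
    n_rows = n_dup = 0
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 2 or not f[0].strip() or not f[1].strip():
                raise InputError(
                    f"{path}:{lineno}: expected >= 2 non-empty tab-separated columns"
                )
            if lineno == 1 and f[0].strip().lower() in (
                "source_gene_id", "gene_stable_id", "source"
            ):
                continue  # header row
            if len(f) >= 3 and f[2].strip():
                # map BioMart vocabulary ("ortholog_one2one", "within_species_paralog")
                # onto the relation tags
                htype = f[2].strip().lower()
                key = relation.replace("ue", "")[:8]  # ortholog / paralog
                if key not in htype:
                    continue
            src, tgt = f[0].strip(), f[1].strip()
            n_rows += 1
            bucket = pairs.setdefault(src, [])
            if tgt in bucket:
                n_dup += 1
            else:
                bucket.append(tgt)
    if not pairs:
        logger.warning("homology table %s yielded no %s pairs", path, relation)
    if n_dup:
        logger.info("homology table %s: %d duplicate rows collapsed", path, n_dup)
    logger.info("read %d %s pairs (%d source genes) from %s",
                n_rows - n_dup, relation, len(pairs), path)
    return HomologyMap(
        relation=relation,
        source_universe=source_universe,
        target_universe=target_universe,
        pairs={k: tuple(v) for k, v in pairs.items()},
    )


def orthologues_of(gene_list: GeneList, orthologue_map: HomologyMap) -> GeneList:
    """Translate a list through an orthologue map.

    Returns the deduplicated union of targets over all list members found
    in the map; members without an orthologue are dropped and counted in
    provenance.
    """
    if orthologue_map.relation != "orthologue":
        raise InputError(
            f"orthologues_of needs an orthologue map, got {orthologue_map.relation}"
        )
    out: list[str] = []
    n_unmapped = 0
    for g in gene_list:
        targets = orthologue_map.targets(g)
        if targets:
            out.extend(targets)
        else:
            n_unmapped += 1
    if n_unmapped == len(gene_list) and len(gene_list) > 0:
        logger.warning("orthologues_of(%s): no list member has an orthologue",
                       gene_list.name)
    prov = (f"{gene_list.provenance}; orthologues "
            f"{orthologue_map.source_universe}->{orthologue_map.target_universe}, "
            f"{n_unmapped}/{len(gene_list)} without orthologue dropped")
    return GeneList(f"{gene_list.name}_orthologues", out, provenance=prov)


def expand_with_paralogues(
    gene_list: GeneList,
    paralogue_map: HomologyMap,
    orthologue_map: HomologyMap,
) -> GeneList:
    """Build the "homologue" list: orthologues of (list ∪ its paralogues).

    Paralogue expansion is a single hop within the source universe; the
    widened list is then translated like :func:`orthologues_of`. The
    result is always a superset of ``orthologues_of(gene_list, ...)`` for
    the same orthologue map.
    """
    if paralogue_map.relation != "paralogue":
        raise InputError(
            f"expand_with_paralogues needs a paralogue map, got "
            f"{paralogue_map.relation}"
        )
    widened: list[str] = list(gene_list)
    for g in gene_list:
        widened.extend(paralogue_map.targets(g))
    n_added = len(dict.fromkeys(widened)) - len(gene_list)
    widened_list = GeneList(
        gene_list.name, widened,
        provenance=f"{gene_list.provenance}; +{n_added} paralogues (one hop)",
    )
    out = orthologues_of(widened_list, orthologue_map)
    return GeneList(f"{gene_list.name}_homologues", out.genes,
                    provenance=out.provenance)
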