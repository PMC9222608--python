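"""Synthetic inputs with the statistical structure the pipeline assumes.

Real runs of this pipeline consume a genome annotation, DMR coordinate
tables, homology tables exported from a data-mining service, and GMT
gene-set libraries. This module fabricates all of them, seeded and
byte-reproducible, so that every stage is testable without downloads:

* :func:`generate_annotation` — non-overlapping gene models on one or
  more chromosomes, written as GTF;
* :func:`generate_dmrs` — one DMR placed on each target gene plus decoys
  far from every gene, so the DMR->gene mapper provably recovers the
  planted list;
* :func:`generate_homology` — orthologue and paralogue maps with
  one-to-many orthology and small paralogue families;
* :func:`generate_overlapping_lists` — two gene lists whose overlap is
  drawn from Fisher's noncentral hypergeometric distribution with odds
  parameter ω, putting the planted effect on the same scale as the
  sample odds ratio the pipeline estimates (ω = 1 is exactly the
  permutation null);
* :func:`generate_gmt` — a term library with an optional planted term
  guaranteed to top the enrichment ranking;
* :func:`simulate_fixture` — a directory of files in the exact dialects
  the readers consume, plus a manifest of every parameter and seed.

Defaults mirror the study conditions this pipeline is built around: a
23,382-gene background, list sizes 1181/589/506/532/367 and a 5000 bp
flank.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from .errors import InfeasibleError, InputError
from .genelists import GeneList, GeneModel, GenomicInterval, map_dmrs_to_genes
from .homology import HomologyMap
from .enrichment import GeneSetLibrary

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "generate_annotation",
    "generate_dmrs",
    "generate_homology",
    "generate_overlapping_lists",
    "generate_gmt",
    "simulate_fixture",
]

TISSUES = ("brain", "muscle", "liver", "testis")


@dataclass
class SimulationConfig:
    """Parameters of a full synthetic fixture.

    The defaults are the study-scale conditions (23,382-gene background,
    list sizes 1181 and 589, ω the planted enrichment odds, 5000 bp
    flank); tests use much smaller instances of the same structure.
    """

    background_size: int = 23_382
    list_size_a: int = 1_181
    list_size_b: int = 589
    planted_odds: float = 1.0
    flank: int = 5_000
    n_chromosomes: int = 4
    genes_per_chromosome: int = 50
    chromosome_length: int = 3_000_000
    gene_length_range: tuple[int, int] = (1_000, 15_000)
    n_decoy_dmrs: int = 20
    orthology_rate: float = 0.8
    one_to_many_rate: float = 0.1
    n_paralogue_families: int = 20
    paralogue_family_sizes: tuple[int, int] = (2, 5)
    n_terms: int = 200
    term_size_range: tuple[int, int] = (10, 200)
    n_perm: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.planted_odds <= 0:
            raise InputError(f"planted_odds must be > 0, got {self.planted_odds}")
        if max(self.list_size_a, self.list_size_b) > self.background_size:
            raise InfeasibleError("list sizes exceed the background")
        if not 0 <= self.orthology_rate <= 1:
            raise InputError("orthology_rate must be a probability")


def _gene_label(i: int) -> str:
    return f"SIMG{i + 1:06d}"


def generate_annotation(
    n_genes: int,
    n_chromosomes: int = 1,
    chromosome_length: int = 3_000_000,
    gene_length_range: tuple[int, int] = (1_000, 15_000),
    min_gap: int | None = None,
    flank: int = 5_000,
    seed: int = 0,
) -> tuple[str, list[GeneModel]]:
    """Place non-overlapping genes of random length and return (GTF text,
    gene models).

    Genes are separated by at least ``min_gap`` bp (default 2*flank + 200)
    so that a DMR inside one gene body can never fall within ``flank`` of
    a neighbour — the guarantee :func:`generate_dmrs` relies on. Raises
    :class:`InfeasibleError` when the requested genes cannot be packed.
    """
    if n_genes < 0 or n_chromosomes < 1:
        raise InputError("need n_genes >= 0 and n_chromosomes >= 1")
    if min_gap is None:
        min_gap = 2 * flank + 200
    rng = np.random.default_rng(seed)
    lo, hi = gene_length_range
    per_chrom = [n_genes // n_chromosomes] * n_chromosomes
    for i in range(n_genes % n_chromosomes):
        per_chrom[i] += 1

    models: list[GeneModel] = []
    lines: list[str] = []
    idx = 0
    for c in range(n_chromosomes):
        chrom = f"chr{c + 1}"
        pos = 1
        for _ in range(per_chrom[c]):
            gap = int(rng.integers(min_gap, min_gap + max(min_gap // 2, 1)))
            length = int(rng.integers(lo, hi + 1))
            start = pos + gap
            end = start + length - 1
            if end > chromosome_length:
                raise InfeasibleError(
                    f"cannot pack {per_chrom[c]} genes of {lo}-{hi} bp with "
                    f"gaps >= {min_gap} bp on a {chromosome_length} bp chromosome"
                )
            strand = "+" if rng.random() < 0.5 else "-"
            gene_id = _gene_label(idx)
            models.append(GeneModel(gene_id, chrom, start, end, strand))
            lines.append(
                f"{chrom}\tepioverlap_sim\tgene\t{start}\t{end}\t.\t{strand}\t.\t"
                f'gene_id "{gene_id}"; gene_biotype "protein_coding";'
            )
            pos = end
            idx += 1
    gtf_text = "\n".join(lines) + ("\n" if lines else "")
    return gtf_text, models


def generate_dmrs(
    models: list[GeneModel],
    target_genes: GeneList,
    decoy_count: int = 0,
    flank: int = 5_000,
    seed: int = 0,
    dmr_length_range: tuple[int, int] = (100, 1_000),
) -> list[GenomicInterval]:
    """Place one DMR on each target gene and ``decoy_count`` DMRs at least
    ``flank`` + 1 bp from every gene.

    Mapping the output through :func:`map_dmrs_to_genes` with the same
    flank recovers exactly ``target_genes``. DMRs carry a synthetic
    methylation difference (percentage points) and tissue label in their
    payload.
    """
    rng = np.random.default_rng(seed)
    by_id = {m.gene_id: m for m in models}
    unknown = [g for g in target_genes if g not in by_id]
    if unknown:
        raise InputError(f"target genes absent from annotation: {unknown[:5]}")
    lo, hi = dmr_length_range
    dmrs: list[GenomicInterval] = []
    for g in target_genes:
        m = by_id[g]
        length = int(rng.integers(lo, min(hi, m.end - m.start + 1) + 1))
        offset = int(rng.integers(0, m.end - m.start + 2 - length))
        start = m.start + offset
        dmrs.append(GenomicInterval(
            m.seq_name, start, start + length - 1,
            payload={
                "meth_diff": round(float(rng.uniform(10, 60))
                                   * (1 if rng.random() < 0.5 else -1), 2),
                "tissue": TISSUES[int(rng.integers(len(TISSUES)))],
            },
        ))

    if decoy_count:
        # candidate slots: gaps between consecutive genes with >= flank+1 bp
        # clearance on both sides
        slots: list[tuple[str, int, int]] = []
        by_chrom: dict[str, list[GeneModel]] = {}
        for m in models:
            by_chrom.setdefault(m.seq_name, []).append(m)
        for chrom, ms in by_chrom.items():
            ms = sorted(ms, key=lambda m: m.start)
            bounds = [(1, ms[0].start - flank - 1)] if ms else []
            for prev, nxt in zip(ms, ms[1:]):
                bounds.append((prev.end + flank + 1, nxt.start - flank - 1))
            for s, e in bounds:
                if e - s + 1 >= lo:
                    slots.append((chrom, s, e))
        if not slots:
            raise InfeasibleError(
                "no intergenic space for decoy DMRs at this flank"
            )
        for _ in range(decoy_count):
            chrom, s, e = slots[int(rng.integers(len(slots)))]
            length = int(rng.integers(lo, min(hi, e - s + 1) + 1))
            start = s + int(rng.integers(0, e - s + 2 - length))
            dmrs.append(GenomicInterval(
                chrom, start, start + length - 1,
                payload={"meth_diff": round(float(rng.uniform(-60, 60)), 2),
                         "tissue": TISSUES[int(rng.integers(len(TISSUES)))]},
            ))

    recovered = map_dmrs_to_genes(dmrs, models, flank=flank)
    if recovered.as_set() != target_genes.as_set():
        raise InfeasibleError(
            "DMR placement does not recover the target list exactly; "
            "the annotation is too dense for this flank"
        )
    return dmrs


def generate_homology(
    source_size: int,
    target_size: int,
    orthology_rate: float = 0.8,
    one_to_many_rate: float = 0.1,
    n_paralogue_families: int = 0,
    family_size_range: tuple[int, int] = (2, 5),
    seed: int = 0,
    source_universe: str = "human",
    target_universe: str = "fish",
    source_labels: list[str] | None = None,
    target_labels: list[str] | None = None,
) -> tuple[HomologyMap, HomologyMap]:
    """Random orthologue and paralogue maps.

    Each source gene receives an orthologue with probability
    ``orthology_rate``; a mapped gene gets a second target with
    probability ``one_to_many_rate``. Paralogue families partition a
    random subset of source genes; within a family every gene lists the
    other members (no self-pairs, one hop). Explicit ``source_labels`` /
    ``target_labels`` override the default HS/FS naming so the maps can
    be tied to an existing annotation.
    """
    rng = np.random.default_rng(seed)
    sources = source_labels or [f"HS{i + 1:05d}" for i in range(source_size)]
    targets = target_labels or [f"FS{i + 1:05d}" for i in range(target_size)]
    source_size, target_size = len(sources), len(targets)

    orth: dict[str, tuple[str, ...]] = {}
    for s in sources:
        if rng.random() < orthology_rate:
            picks = [targets[int(rng.integers(target_size))]]
            if rng.random() < one_to_many_rate:
                extra = targets[int(rng.integers(target_size))]
                if extra not in picks:
                    picks.append(extra)
            orth[s] = tuple(picks)

    para: dict[str, tuple[str, ...]] = {}
    if n_paralogue_families:
        pool = list(rng.permutation(sources))
        lo, hi = family_size_range
        for _ in range(n_paralogue_families):
            size = int(rng.integers(lo, hi + 1))
            if len(pool) < size:
                break
            family = [pool.pop() for _ in range(size)]
            for g in family:
                others = tuple(x for x in family if x != g)
                if others:
                    para[g] = others

    return (
        HomologyMap("orthologue", source_universe, target_universe, orth),
        HomologyMap("paralogue", source_universe, source_universe, para),
    )


def generate_overlapping_lists(
    background_size: int,
    size_a: int,
    size_b: int,
    odds: float = 1.0,
    seed: int = 0,
    name_a: str = "listA",
    name_b: str = "listB",
) -> tuple[GeneList, GeneList, int]:
    """Two lists over a labelled universe with a planted overlap.

    The shared count k is drawn from Fisher's noncentral hypergeometric
    distribution with parameters (N, size_a, size_b, odds); at odds = 1
    this is the ordinary hypergeometric, i.e. the permutation null
    itself. Returns (list A, list B, realized k).
    """
    n = background_size
    if max(size_a, size_b) > n:
        raise InfeasibleError("list sizes exceed the background")
    if odds <= 0:
        raise InputError(f"odds must be > 0, got {odds}")
    rng = np.random.default_rng(seed)
    if size_a == 0 or size_b == 0:
        k = 0
    else:
        k = int(stats.nchypergeom_fisher.rvs(n, size_a, size_b, odds,
                                             random_state=rng))
    picks = rng.choice(n, size_a + size_b - k, replace=False)
    shared = picks[:k]
    only_a = picks[k:size_a]
    only_b = picks[size_a:]
    genes_a = [_gene_label(i) for i in np.concatenate([shared, only_a]).astype(int)]
    genes_b = [_gene_label(i) for i in np.concatenate([shared, only_b]).astype(int)]
    prov = f"planted odds={odds}, N={n}, realized overlap={k}"
    return (GeneList(name_a, genes_a, provenance=prov),
            GeneList(name_b, genes_b, provenance=prov),
            k)


def generate_gmt(
    universe: list[str],
    n_terms: int,
    term_size_range: tuple[int, int] = (10, 200),
    seed: int = 0,
    planted: tuple[str, list[str]] | None = None,
    name: str = "sim_library",
) -> GeneSetLibrary:
    """A library of terms drawn uniformly from the universe; ``planted``
    adds a term equal to a supplied gene set (guaranteeing it tops the
    enrichment ranking of that same query)."""
    if n_terms < 0:
        raise InputError("n_terms must be >= 0")
    lo, hi = term_size_range
    if n_terms and (lo < 1 or hi > len(universe)):
        raise InfeasibleError(
            f"term sizes {lo}-{hi} infeasible for a universe of {len(universe)}"
        )
    rng = np.random.default_rng(seed)
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    for i in range(n_terms):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(len(universe), size, replace=False)
        terms[f"SIMT{i + 1:04d}"] = (
            f"simulated term {i + 1}",
            frozenset(universe[j] for j in members),
        )
    if planted is not None:
        term_id, genes = planted
        if not genes:
            raise InputError("planted term needs a non-empty gene set")
        terms[term_id] = ("planted term", frozenset(genes))
    return GeneSetLibrary(name, terms)


def simulate_fixture(config: SimulationConfig, outdir: str | Path) -> dict:
    """Materialize a full input bundle and manifest under ``outdir``.

    Writes annotation.gtf, dmrs.tsv, homology_orthologues.tsv,
    homology_paralogues.tsv, library.gmt, the planted gene lists, and
    manifest.json recording every parameter, derived seed, and planted
    truth. All randomness derives from ``config.seed``, so reusing the
    manifest's seed reproduces the bundle byte for byte.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = config
    seeds = np.random.SeedSequence(cfg.seed).spawn(5)
    sub = [int(s.generate_state(1)[0] % (2**31)) for s in seeds]

    n_genes = cfg.n_chromosomes * cfg.genes_per_chromosome
    gtf_text, models = generate_annotation(
        n_genes, cfg.n_chromosomes, cfg.chromosome_length,
        cfg.gene_length_range, flank=cfg.flank, seed=sub[0],
    )
    (outdir / "annotation.gtf").write_text(gtf_text)

    universe = [m.gene_id for m in models]
    size_a = min(cfg.list_size_a, n_genes)
    size_b = min(cfg.list_size_b, n_genes)
    list_a, list_b, k = generate_overlapping_lists(
        n_genes, size_a, size_b, cfg.planted_odds, seed=sub[1],
        name_a="FED_sim", name_b="COMP_sim",
    )
    dmrs = generate_dmrs(models, list_a, cfg.n_decoy_dmrs, cfg.flank,
                         seed=sub[2])
    with open(outdir / "dmrs.tsv", "w") as fh:
        fh.write("chrom\tstart\tend\tmeth_diff\ttissue\n")
        for d in dmrs:
            fh.write(f"{d.seq_name}\t{d.start}\t{d.end}\t"
                     f"{d.payload['meth_diff']}\t{d.payload['tissue']}\n")

    orth, para = generate_homology(
        source_size=n_genes, target_size=n_genes,
        source_labels=universe,
        orthology_rate=cfg.orthology_rate,
        one_to_many_rate=cfg.one_to_many_rate,
        n_paralogue_families=min(cfg.n_paralogue_families,
                                 n_genes // max(cfg.paralogue_family_sizes)),
        family_size_range=cfg.paralogue_family_sizes,
        seed=sub[3],
    )
    for m, fname in ((orth, "homology_orthologues.tsv"),
                     (para, "homology_paralogues.tsv")):
        with open(outdir / fname, "w") as fh:
            fh.write("source_gene_id\ttarget_gene_id\thomology_type\n")
            htype = ("ortholog_one2one" if m.relation == "orthologue"
                     else "within_species_paralog")
            for src in m.pairs:
                for tgt in m.pairs[src]:
                    fh.write(f"{src}\t{tgt}\t{htype}\n")

    term_sizes = (min(cfg.term_size_range[0], max(1, n_genes // 4)),
                  min(cfg.term_size_range[1], n_genes))
    library = generate_gmt(
        universe, cfg.n_terms, term_sizes, seed=sub[4],
        planted=("SIMT_PLANTED", sorted(list_a.as_set() & list_b.as_set())
                 or list(list_a)[: max(2, size_a // 10)]),
    )
    from .enrichment import write_gmt
    write_gmt(library, outdir / "library.gmt")

    from .genelists import write_gene_list
    write_gene_list(list_a, outdir / "list_a.txt")
    write_gene_list(list_b, outdir / "list_b.txt")

    manifest = {
        "config": dataclasses.asdict(cfg),
        "derived_seeds": sub,
        "n_genes": n_genes,
        "planted": {
            "list_a": list(list_a), "list_b": list(list_b),
            "overlap": k, "planted_term": "SIMT_PLANTED",
        },
        "files": ["annotation.gtf", "dmrs.tsv", "homology_orthologues.tsv",
                  "homology_paralogues.tsv", "library.gmt",
                  "list_a.txt", "list_b.txt"],
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    logger.info("fixture written to %s (%d genes, planted overlap %d)",
                outdir, n_genes, k)
    return manifest
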