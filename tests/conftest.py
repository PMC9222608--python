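import numpy as np
import pytest

from epioverlap import GeneList, GeneModel, GenomicInterval


@pytest.fixture
def small_models() -> list[GeneModel]:
    return [
        GeneModel("g1", "1", 15_100, 16_000, "+"),
        GeneModel("g2", "1", 40_000, 45_000, "-"),
        GeneModel("g3", "2", 1_000, 2_000, "+"),
    ]


@pytest.fixture
def gtf_file(tmp_path, small_models):
    lines = [
        f'{m.seq_name}\ttest\tgene\t{m.start}\t{m.end}\t.\t{m.strand}\t.\t'
        f'gene_id "{m.gene_id}";'
        for m in small_models
    ]
    path = tmp_path / "genes.gtf"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_gene_list(rng, universe_size: int, size: int, name: str) -> GeneList:
    idx = rng.choice(universe_size, size, replace=False)
    return GeneList(name, [f"u{i}" for i in idx])


def brute_force_dmr_scan(dmrs: list[GenomicInterval],
                         genes: list[GeneModel], flank: int) -> set[str]:
    """All-pairs interval overlap oracle (1-based inclusive coordinates)."""
    hits = set()
    for d in dmrs:
        lo, hi = max(1, d.start - flank), d.end + flank
        for g in genes:
            if g.seq_name == d.seq_name and g.start <= hi and lo <= g.end:
                hits.add(g.gene_id)
    return hits
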