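import numpy as np
import pytest

from zgakit.genomic import GenomicInterval, PeakSet, SignalTrack
from zgakit.simulate import SyntheticConfig, simulate_multiome


@pytest.fixture(scope="session")
def small_multiome():
    """A small but structured multiome: 3 cell types x 100 cells, 20 genes."""
    cfg = SyntheticConfig(
        n_cell_types=3, cells_per_type=100, n_genes=20, enhancer_effect=2.0, seed=42
    )
    return simulate_multiome(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_intervals(rng, n, chroms=("chrA", "chrB"), span=1000, max_w=60):
    """Small random intervals for brute-force comparisons."""
    out = []
    for i in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        start = int(rng.integers(0, span - max_w))
        width = int(rng.integers(1, max_w))
        out.append(GenomicInterval(chrom, start, start + width, id=f"iv{i}"))
    return PeakSet(out)


def per_bp_union(peaks, span=1200):
    """Brute-force oracle: union-find of intervals that share a base.

    Components of the overlap graph, per chromosome.  Book-ended
    intervals share no base and stay separate, unlike a plain per-bp
    occupancy union.
    """
    comps = []
    for chrom, ivs in peaks.by_chrom().items():
        parent = list(range(len(ivs)))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        covering = [[] for _ in range(span)]
        for k, iv in enumerate(ivs):
            for bp in range(iv.start, iv.end):
                covering[bp].append(k)
        for members in covering:
            for a, b in zip(members, members[1:]):
                parent[find(a)] = find(b)
        groups = {}
        for k, iv in enumerate(ivs):
            groups.setdefault(find(k), []).append(iv)
        for members in groups.values():
            comps.append(
                (chrom, min(m.start for m in members), max(m.end for m in members))
            )
    return sorted(comps)
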