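import itertools

import numpy as np
import pandas as pd
import pytest

from apakit.synthetic import SyntheticUsage, gen_usage, jak1_like_dataset


@pytest.fixture(scope="session")
def jak1_dataset():
    return jak1_like_dataset()


@pytest.fixture(scope="session")
def small_synth() -> SyntheticUsage:
    """A small two-group usage matrix with 30% shortened features."""
    return gen_usage(n_features=40, n_per_group=12, frac_affected=0.3,
                     delta=-0.3, noise_sd=0.1, seed=7)


def mannwhitney_exact_p(a, b) -> float:
    """Exhaustive-permutation two-sided Mann-Whitney p (no-tie oracle).

    Enumerates every assignment of the pooled values to the two groups and
    counts assignments whose U statistic is at least as far from its null
    mean as the observed one.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    pooled = np.concatenate([a, b])
    n1, n2 = len(a), len(b)
    mu = n1 * n2 / 2

    def u_stat(x, y):
        return sum(1 for xi in x for yi in y if xi > yi)

    obs = abs(u_stat(a, b) - mu)
    idx = range(len(pooled))
    count = total = 0
    for comb in itertools.combinations(idx, n1):
        mask = np.zeros(len(pooled), bool)
        mask[list(comb)] = True
        u = u_stat(pooled[mask], pooled[~mask])
        count += abs(u - mu) >= obs - 1e-12
        total += 1
    return count / total


def brute_force_overlaps(regions, track, stranded=False):
    """O(n*m) interval-overlap oracle (half-open, optional strand match)."""
    out = []
    for chrom, start, end, strand in regions:
        names = []
        for f in track:
            if f.chrom != chrom:
                continue
            if stranded and f.strand != strand:
                continue
            if max(start, f.start) < min(end, f.end):
                names.append(f.name)
        out.append(sorted(names))
    return out


def brute_force_motifs(seq, window, motifs):
    """All-substring motif-scan oracle."""
    seq = seq.upper()
    L = len(seq)
    hits = []
    for i in range(L):
        for m in motifs:
            if seq[i:i + len(m)] == m and (L - i) <= window:
                hits.append((m, L - i))
    return sorted(hits, key=lambda h: (h[1], h[0]))
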