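"""Independent brute-force oracles used by the tests.

Everything here is coded directly from first principles (scalar loops,
exhaustive enumeration) and never calls the library paths it checks.
"""

from __future__ import annotations


def wc_fst_brute(g1, g2):
    """Two-population diploid Weir-Cockerham theta via the a, b, c variance
    components, coded scalar-by-scalar from the 1984 definitions.

    ``g1``/``g2`` are per-individual allele-A copy counts with -1 missing.
    Returns None where the estimate is undefined (fewer than two usable
    individuals in a population, or zero denominator).
    """
    def summarize(g):
        usable = [x for x in g if x >= 0]
        n = len(usable)
        if n == 0:
            return 0, 0.0, 0.0
        p = sum(usable) / (2.0 * n)
        h = sum(1 for x in usable if x == 1) / n
        return n, p, h

    n1, p1, h1 = summarize(g1)
    n2, p2, h2 = summarize(g2)
    if n1 < 2 or n2 < 2:
        return None
    r = 2.0
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1 * n1 + n2 * n2) / (r * nbar)) / (r - 1.0)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1.0 - pbar) - ((r - 1.0) / r) * s2 - hbar / 4.0)
        / (nbar - 1.0))
    b = (nbar / (nbar - 1.0)) * (
        pbar * (1.0 - pbar) - ((r - 1.0) / r) * s2
        - ((2.0 * nbar - 1.0) / (4.0 * nbar)) * hbar)
    c = hbar / 2.0
    denom = a + b + c
    if denom == 0.0:
        return None
    return a / denom


def exact_overlap_probability(chrom_length, region_length, genes):
    """Exact probability that one region placed uniformly on a single
    chromosome overlaps at least one gene, by exhaustive enumeration of all
    valid start positions (1-based inclusive coordinates)."""
    n_starts = chrom_length - region_length + 1
    assert n_starts >= 1
    hits = 0
    for start in range(1, n_starts + 1):
        end = start + region_length - 1
        if any(start <= ge and end >= gs for gs, ge in genes):
            hits += 1
    return hits / n_starts


def ccr_components_brute(fst_regions, het_regions):
    """Expected CCR spans via explicit pairwise overlap + union-find.

    ``fst_regions`` and ``het_regions`` are lists of (chrom, start, end)
    tuples (het list may mix methods).  Returns a sorted list of
    (chrom, start, end) CCR envelopes.
    """
    nodes = [("F", t) for t in fst_regions] + [("H", t) for t in het_regions]
    parent = list(range(len(nodes)))

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    for i, (ki, (ci, si, ei)) in enumerate(nodes):
        for j, (kj, (cj, sj, ej)) in enumerate(nodes):
            if ki == "F" and kj == "H" and ci == cj \
                    and si <= ej and sj <= ei:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)

    comps = {}
    for i in range(len(nodes)):
        comps.setdefault(find(i), []).append(i)
    out = []
    for members in comps.values():
        kinds = {nodes[i][0] for i in members}
        if kinds != {"F", "H"}:
            continue
        ivs = [nodes[i][1] for i in members]
        out.append((ivs[0][0], min(s for _, s, _ in ivs),
                    max(e for _, _, e in ivs)))
    return sorted(out)
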