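"""Candidate regions, multi-breed consensus, and convergence regions (CCR).

The calling rules, in order:

1. *merge*: for one breed (or breed pair) and one method, flagged windows
   or grid positions whose centers lie within ``gap`` (default 2 Mb,
   inclusive) of each other chain into one candidate region spanning the
   first to the last member window.
2. *consensus*: candidate regions from different breeds/pairs within 2 Mb
   of each other (interval gap; overlap counts as 0) group by single
   linkage.  A group survives if it is supported by at least two distinct
   dairy breeds (heterozygosity methods) or by at least two breed pairs
   sharing no common breed (F_ST) — pairs like MilkLacaune~APM plus
   Comisana~APM do not qualify.  Non-dairy breeds never count toward
   heterozygosity support but are kept as annotations.
3. *CCR*: a convergence candidate region is a maximal group in which an
   F_ST consensus region strictly overlaps (>= 1 bp — proximity is not
   enough) at least one heterozygosity-based consensus region; its span is
   the envelope of the contributing intervals.

Breed pairs are labeled ``"A~B"`` with the two names sorted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import chrom_sort_key

__all__ = ["CandidateRegion", "ConsensusRegion", "CCR", "pair_label",
           "pair_breeds", "merge_flags", "consensus", "intersect_ccr"]

PAIR_SEP = "~"

HET_METHODS = frozenset({"OBSHTZ", "REGRESSION"})


def pair_label(breed_a: str, breed_b: str) -> str:
    """Canonical unordered label for a breed pair."""
    for b in (breed_a, breed_b):
        if PAIR_SEP in b:
            raise ValueError(f"breed name may not contain {PAIR_SEP!r}: {b!r}")
    return PAIR_SEP.join(sorted((breed_a, breed_b)))


def pair_breeds(label: str) -> frozenset[str]:
    """Breed set of a pair label; raises on malformed labels."""
    parts = label.split(PAIR_SEP)
    if len(parts) != 2 or not all(parts):
        raise ValueError(f"malformed breed-pair label {label!r}")
    return frozenset(parts)


@dataclass(frozen=True)
class CandidateRegion:
    """Run of extreme flags for one method and one breed or breed pair."""

    chrom: str
    start: int
    end: int
    method: str
    label: str
    n_flags: int = 1

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError("region start > end")

    @property
    def support(self) -> tuple:
        return ((self.label, self.start, self.end),)


@dataclass(frozen=True)
class ConsensusRegion:
    """Candidate region supported by enough independent breeds or pairs."""

    chrom: str
    start: int
    end: int
    method: str
    supports: tuple = ()        # (label, start, end) of qualifying members
    annotations: tuple = ()     # (label, start, end) of co-signals (non-dairy)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(lbl for lbl, _, _ in self.supports))


@dataclass(frozen=True)
class CCR:
    """Convergence candidate region: F_ST plus >= 1 heterozygosity method."""

    chrom: str
    start: int
    end: int
    methods: frozenset = field(default_factory=frozenset)
    components: tuple = ()      # (method, start, end) of contributing regions

    def __post_init__(self):
        if "FST" not in self.methods or not (self.methods & HET_METHODS):
            raise ValueError("CCR needs FST and a heterozygosity method")


def _sorted_regions(regions):
    return sorted(regions, key=lambda r: (chrom_sort_key(r.chrom),
                                          int(r.start), int(r.end)))


def merge_flags(flags: pd.DataFrame, gap: float = 2e6, method: str = "",
                label: str = "") -> list[CandidateRegion]:
    """Single-linkage merge of flagged windows/positions into regions.

    ``flags`` needs columns chrom, center_pos, start, end (for grid
    positions start = end = center_pos).  Consecutive flags on one
    chromosome whose centers are <= ``gap`` apart (inclusive) join one
    region; the region spans the minimum start to the maximum end of its
    members.
    """
    out: list[CandidateRegion] = []
    if len(flags) == 0:
        return out
    for chrom, grp in flags.groupby("chrom", sort=False):
        grp = grp.sort_values("center_pos", kind="mergesort")
        centers = grp["center_pos"].to_numpy(dtype=np.int64)
        starts = grp["start"].to_numpy(dtype=np.int64)
        ends = grp["end"].to_numpy(dtype=np.int64)
        run_start = 0
        for i in range(1, len(grp) + 1):
            if i == len(grp) or centers[i] - centers[i - 1] > gap:
                out.append(CandidateRegion(
                    chrom=str(chrom),
                    start=int(starts[run_start:i].min()),
                    end=int(ends[run_start:i].max()),
                    method=method, label=label, n_flags=i - run_start))
                run_start = i
    return _sorted_regions(out)


def _interval_gap(a_start, a_end, b_start, b_end) -> int:
    """Distance between closest endpoints of two intervals; 0 on overlap.

    Matches the flag-merge convention: points 10.0 and 12.0 Mb are gap
    2.0 Mb apart, which the inclusive 2-Mb rule still joins.
    """
    return max(0, max(a_start, b_start) - min(a_end, b_end))


def _group_single_linkage(regions, gap: float):
    """Chain regions of one chromosome whose interval gap is <= gap."""
    groups = []
    for chrom in dict.fromkeys(r.chrom for r in regions):
        on_chrom = sorted((r for r in regions if r.chrom == chrom),
                          key=lambda r: (int(r.start), int(r.end)))
        cur = [on_chrom[0]]
        cur_end = on_chrom[0].end
        for r in on_chrom[1:]:
            if r.start - cur_end <= gap:
                cur.append(r)
                cur_end = max(cur_end, r.end)
            else:
                groups.append(cur)
                cur = [r]
                cur_end = r.end
        groups.append(cur)
    return groups


def consensus(regions, mode: str, dairy_breeds=(), min_support: int = 2,
              gap: float = 2e6) -> list[ConsensusRegion]:
    """Multi-breed (or multi-pair) consensus over candidate regions.

    Parameters
    ----------
    regions
        :class:`CandidateRegion` objects, each labeled with its breed
        (heterozygosity methods) or breed pair (``"A~B"``, F_ST).
    mode
        ``"FST"``: a group survives when at least two supporting pairs have
        disjoint breed sets.  ``"HET"``: a group survives when supported by
        at least ``min_support`` distinct dairy breeds; regions from
        non-dairy breeds are excluded from grouping and attached to
        surviving groups as annotations.
    gap
        Maximum interval gap (bp, inclusive) for grouping regions across
        breeds/pairs; overlapping intervals have gap 0.

    The surviving group's span is the envelope of its qualifying members.
    Output order is independent of input order.
    """
    if mode not in ("FST", "HET"):
        raise ValueError("mode must be 'FST' or 'HET'")
    regions = _sorted_regions(regions)
    if mode == "HET":
        dairy = set(dairy_breeds)
        eligible = [r for r in regions if r.label in dairy]
        extras = [r for r in regions if r.label not in dairy]
    else:
        eligible = regions
        extras = []
        for r in eligible:
            pair_breeds(r.label)  # validates label shape

    out: list[ConsensusRegion] = []
    if not eligible:
        return out
    for group in _group_single_linkage(eligible, gap):
        labels = list(dict.fromkeys(r.label for r in group))
        if mode == "FST":
            sets = [pair_breeds(lbl) for lbl in labels]
            ok = any(sets[i].isdisjoint(sets[j])
                     for i in range(len(sets)) for j in range(i + 1, len(sets)))
        else:
            ok = len(labels) >= min_support
        if not ok:
            continue
        chrom = group[0].chrom
        start = min(r.start for r in group)
        end = max(r.end for r in group)
        ann = tuple(sorted((e.label, e.start, e.end) for e in extras
                           if e.chrom == chrom
                           and _interval_gap(start, end, e.start, e.end) <= gap))
        out.append(ConsensusRegion(
            chrom=chrom, start=int(start), end=int(end),
            method=group[0].method,
            supports=tuple((r.label, r.start, r.end) for r in group),
            annotations=ann))
    return _sorted_regions(out)


def intersect_ccr(fst_regions, obshtz_regions=(), regression_regions=()
                  ) -> list[CCR]:
    """Intersect per-method consensus regions into CCRs.

    A CCR is emitted for each maximal group in which an F_ST region
    strictly overlaps (>= 1 bp) at least one heterozygosity-based region;
    regions merely near each other (the 2-Mb proximity rule) do not
    qualify.  Heterozygosity regions link into the same CCR only through a
    shared F_ST region.  The CCR span is the envelope of all contributing
    intervals.
    """
    nodes = ([("FST", r) for r in fst_regions]
             + [("OBSHTZ", r) for r in obshtz_regions]
             + [("REGRESSION", r) for r in regression_regions])
    nodes = sorted(enumerate(nodes),
                   key=lambda kv: (chrom_sort_key(kv[1][1].chrom),
                                   int(kv[1][1].start), kv[1][0]))
    nodes = [nv for _, nv in nodes]
    parent = list(range(len(nodes)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    for i, (mi, ri) in enumerate(nodes):
        if mi != "FST":
            continue
        for j, (mj, rj) in enumerate(nodes):
            if mj == "FST":
                continue
            if ri.chrom == rj.chrom and ri.start <= rj.end and rj.start <= ri.end:
                union(i, j)

    comps: dict[int, list[int]] = {}
    for i in range(len(nodes)):
        comps.setdefault(find(i), []).append(i)

    out: list[CCR] = []
    for members in comps.values():
        methods = frozenset(nodes[i][0] for i in members)
        if "FST" not in methods or not (methods & HET_METHODS):
            continue
        regs = [nodes[i] for i in members]
        out.append(CCR(
            chrom=regs[0][1].chrom,
            start=int(min(r.start for _, r in regs)),
            end=int(max(r.end for _, r in regs)),
            methods=methods,
            components=tuple(sorted((m, int(r.start), int(r.end))
                                    for m, r in regs))))
    return _sorted_regions(out)
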