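"""Genotype, map, breed-table and interval file handling.

File dialects
-------------
* PLINK text genotypes: ``.ped`` (six leading columns, then two allele
  columns per SNP, alleles coded ``A``/``B``, ``0`` = missing) and
  ``.map`` (chromosome, snp-id, genetic position placeholder, bp).
* Breed assignment: TSV with header ``individual_id  breed  dairy``.
* Interval sets (genes, QTL, regions): TSV with header or BED.

All coordinates are 1-based inclusive internally.  BED output converts to
0-based half-open at the boundary and nowhere else.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: chromosome labels treated as unmapped/unplaced; SNPs on them are dropped
#: on read (comparison is case-insensitive)
UNMAPPED_CHROMS = frozenset({"0", "un", "chrun", "unknown", "na", "none"})

#: stable float formatting for every TSV the package writes, so that a rerun
#: with identical inputs is byte-identical
FLOAT_FORMAT = "%.10g"

MISSING = -1  # genotype code for a missing call


def chrom_sort_key(label: str):
    """Sort key placing numeric chromosome labels in numeric order.

    Labels are opaque strings internally; this is used only when writing
    reports.
    """
    s = str(label)
    return (0, int(s), "") if s.isdigit() else (1, 0, s)


class SnpMap:
    """Ordered SNP map: chromosome label, snp-id and 1-based bp position.

    Within each chromosome positions must be strictly increasing, each
    chromosome must form one contiguous block, and snp-ids must be unique.
    """

    def __init__(self, chrom: Sequence[str], snp_id: Sequence[str],
                 pos: Sequence[int], validate: bool = True):
        self.chrom = np.asarray(chrom, dtype=object)
        self.snp_id = np.asarray(snp_id, dtype=object)
        self.pos = np.asarray(pos, dtype=np.int64)
        if not (len(self.chrom) == len(self.snp_id) == len(self.pos)):
            raise ValueError("map columns differ in length")
        self._slices: dict[str, slice] = {}
        start = 0
        for i in range(1, len(self.chrom) + 1):
            if i == len(self.chrom) or self.chrom[i] != self.chrom[start]:
                c = str(self.chrom[start])
                if c in self._slices:
                    raise ValueError(
                        f"chromosome {c!r} appears in more than one block; "
                        "map must be grouped by chromosome")
                self._slices[c] = slice(start, i)
                start = i
        if validate:
            self._validate()

    def _validate(self) -> None:
        ids, counts = np.unique(self.snp_id.astype(str), return_counts=True)
        if (counts > 1).any():
            dup = ids[counts > 1][0]
            raise ValueError(f"duplicate snp-id {dup!r} in map")
        for c, sl in self._slices.items():
            p = self.pos[sl]
            if len(p) and p[0] < 1:
                raise ValueError(f"non-positive position on chromosome {c!r}")
            bad = np.nonzero(np.diff(p) <= 0)[0]
            if bad.size:
                offender = self.snp_id[sl][bad[0] + 1]
                raise ValueError(
                    f"positions not strictly increasing on chromosome {c!r} "
                    f"at snp {offender!r}")

    # -- basic interface ---------------------------------------------------
    def __len__(self) -> int:
        return len(self.pos)

    @property
    def n_snps(self) -> int:
        return len(self.pos)

    @property
    def chromosomes(self) -> tuple[str, ...]:
        return tuple(self._slices)

    def chrom_slice(self, chrom: str) -> slice:
        return self._slices[str(chrom)]

    def positions(self, chrom: str) -> np.ndarray:
        return self.pos[self.chrom_slice(chrom)]

    def subset(self, mask: np.ndarray) -> "SnpMap":
        return SnpMap(self.chrom[mask], self.snp_id[mask], self.pos[mask])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"chrom": self.chrom.astype(str),
                             "snp_id": self.snp_id.astype(str),
                             "pos": self.pos})


@dataclass
class GenotypeMatrix:
    """Diploid calls for one breed: individuals x SNPs, allele-A copy counts.

    ``calls`` is int8 with values {0, 1, 2} and :data:`MISSING` (-1) for a
    missing call; columns follow ``snp_map`` order.
    """

    calls: np.ndarray
    individuals: list[str]
    snp_map: SnpMap

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValueError("calls must be 2-D (individuals x SNPs)")
        if self.calls.shape[0] != len(self.individuals):
            raise ValueError("row count != number of individuals")
        if self.calls.shape[1] != self.snp_map.n_snps:
            raise ValueError("column count != number of mapped SNPs")
        valid = (self.calls >= MISSING) & (self.calls <= 2)
        if not valid.all():
            raise ValueError("genotype calls outside {missing,0,1,2}")

    @property
    def n_individuals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_snps(self) -> int:
        return self.calls.shape[1]


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def read_map(map_path) -> tuple[SnpMap, np.ndarray]:
    """Read a PLINK .map file, dropping SNPs on unmapped chromosomes.

    Returns the filtered map and the boolean keep-mask over the file's rows
    (needed to subset the .ped allele columns consistently).
    """
    df = pd.read_csv(map_path, sep=r"\s+", header=None,
                     names=["chrom", "snp_id", "cm", "pos"],
                     dtype={"chrom": str, "snp_id": str})
    keep = ~df["chrom"].str.lower().isin(UNMAPPED_CHROMS)
    kept = df[keep]
    snp_map = SnpMap(kept["chrom"].to_numpy(), kept["snp_id"].to_numpy(),
                     kept["pos"].to_numpy())
    return snp_map, keep.to_numpy()


def read_breed_table(breeds_path) -> pd.DataFrame:
    """Read the individual->breed assignment TSV (columns
    ``individual_id``, ``breed``, ``dairy``)."""
    df = pd.read_csv(breeds_path, sep="\t", dtype={"individual_id": str,
                                                   "breed": str})
    required = {"individual_id", "breed", "dairy"}
    if not required.issubset(df.columns):
        raise ValueError(f"breed table must have columns {sorted(required)}")
    dup = df["individual_id"].duplicated()
    if dup.any():
        raise ValueError("duplicate individual id in breed table: "
                         f"{df['individual_id'][dup].iloc[0]!r}")
    df["dairy"] = df["dairy"].astype(bool)
    return df


_ALLELE_COUNT = {"A": 1, "B": 0}


def read_genotypes(ped_path, map_path, breeds_path
                   ) -> tuple[dict[str, GenotypeMatrix], SnpMap, dict[str, bool]]:
    """Read .ped/.map genotypes plus breed assignments.

    Returns per-breed genotype matrices sharing one :class:`SnpMap`, and a
    ``breed -> is_dairy`` mapping.  SNPs assigned to unmapped chromosomes
    are excluded.  Duplicate individual ids, individuals absent from the
    breed table, and non-monotone maps are hard errors naming the offender.
    """
    snp_map, keep = read_map(map_path)
    breed_df = read_breed_table(breeds_path)
    breed_of = dict(zip(breed_df["individual_id"], breed_df["breed"]))
    dairy = {b: bool(g["dairy"].iloc[0])
             for b, g in breed_df.groupby("breed", sort=False)}

    ids: list[str] = []
    rows: list[np.ndarray] = []
    n_file_snps = keep.size
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * n_file_snps:
                raise ValueError(
                    f"{ped_path}: line {lineno} has {len(fields)} fields, "
                    f"expected {6 + 2 * n_file_snps}")
            iid = fields[1]
            if iid in ids:
                raise ValueError(f"duplicate individual id {iid!r} in ped")
            if iid not in breed_of:
                raise ValueError(f"individual {iid!r} missing from breed table")
            alleles = fields[6:]
            row = np.empty(n_file_snps, dtype=np.int8)
            for j in range(n_file_snps):
                a1, a2 = alleles[2 * j], alleles[2 * j + 1]
                if a1 == "0" or a2 == "0":
                    row[j] = MISSING
                    continue
                try:
                    row[j] = _ALLELE_COUNT[a1] + _ALLELE_COUNT[a2]
                except KeyError:
                    raise ValueError(
                        f"{ped_path}: line {lineno}: allele {a1!r}/{a2!r} "
                        "not in dialect {A,B,0}") from None
            ids.append(iid)
            rows.append(row[keep])

    calls = (np.vstack(rows) if rows
             else np.empty((0, snp_map.n_snps), dtype=np.int8))
    genotypes: dict[str, GenotypeMatrix] = {}
    ids_arr = np.asarray(ids, dtype=object)
    breeds_arr = np.asarray([breed_of[i] for i in ids], dtype=object)
    for breed in dict.fromkeys(breeds_arr):  # preserve first-seen order
        sel = breeds_arr == breed
        genotypes[str(breed)] = GenotypeMatrix(
            calls[sel], list(ids_arr[sel]), snp_map)
    return genotypes, snp_map, dairy


def read_intervals(path, dialect: str | None = None) -> pd.DataFrame:
    """Read an interval set (genes/QTL/regions) as TSV or BED.

    Returns a DataFrame with 1-based inclusive ``chrom, start, end, label``.
    ``dialect`` defaults to "bed" for a ``.bed`` suffix, else "tsv".
    """
    path = Path(path)
    if dialect is None:
        dialect = "bed" if path.suffix.lower() == ".bed" else "tsv"
    if dialect == "bed":
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         usecols=[0, 1, 2, 3],
                         names=["chrom", "start", "end", "label"],
                         dtype={"chrom": str, "label": str})
        df["start"] = df["start"].astype(np.int64) + 1  # to 1-based inclusive
        df["end"] = df["end"].astype(np.int64)
    else:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        if "label" not in df.columns:
            df["label"] = [f"iv{i}" for i in range(len(df))]
        df = df[["chrom", "start", "end", "label"]].astype(
            {"start": np.int64, "end": np.int64})
    if (df["start"] > df["end"]).any():
        raise ValueError(f"{path}: interval with start > end")
    return df


def read_chrom_lengths(path) -> dict[str, int]:
    """Read a two-column TSV ``chrom  length`` into a dict."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return dict(zip(df["chrom"], df["length"].astype(int)))


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path) -> None:
    """Write a TSV with the package-wide stable float format."""
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def write_genotypes(genotypes: Mapping[str, GenotypeMatrix],
                    dairy: Mapping[str, bool], prefix) -> None:
    """Write per-breed genotypes as ``<prefix>.ped/.map/.breeds.tsv``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    snp_map = next(iter(genotypes.values())).snp_map
    with open(f"{prefix}.map", "w") as fh:
        for c, s, p in zip(snp_map.chrom, snp_map.snp_id, snp_map.pos):
            fh.write(f"{c}\t{s}\t0\t{p}\n")
    pair = {2: "A A", 1: "A B", 0: "B B", MISSING: "0 0"}
    with open(f"{prefix}.ped", "w") as fh:
        for breed, gm in genotypes.items():
            for i, iid in enumerate(gm.individuals):
                geno = " ".join(pair[int(g)] for g in gm.calls[i])
                fh.write(f"{breed} {iid} 0 0 0 -9 {geno}\n")
    rows = []
    for breed, gm in genotypes.items():
        for iid in gm.individuals:
            rows.append((iid, breed, int(bool(dairy[breed]))))
    pd.DataFrame(rows, columns=["individual_id", "breed", "dairy"]).to_csv(
        f"{prefix}.breeds.tsv", sep="\t", index=False)


def write_chrom_lengths(lengths: Mapping[str, int], path) -> None:
    pd.DataFrame({"chrom": list(lengths), "length": list(lengths.values())}
                 ).to_csv(path, sep="\t", index=False)


def _region_row(region) -> dict:
    method = getattr(region, "method", None) or "|".join(
        sorted(getattr(region, "methods", ())))
    support = getattr(region, "supports", None)
    if support is None:
        support = getattr(region, "support", ())
    sup = ";".join(f"{lbl}:{s}-{e}" for lbl, s, e in support)
    comp = ";".join(f"{m}:{s}-{e}"
                    for m, s, e in getattr(region, "components", ()))
    return {"chrom": region.chrom, "start": int(region.start),
            "end": int(region.end), "method": method,
            "support": sup, "components": comp}


def write_regions(regions: Iterable, path, dialect: str = "tsv") -> None:
    """Write candidate/consensus/CCR intervals as TSV or BED.

    TSV preserves internal 1-based inclusive coordinates and provenance
    columns; BED converts ``[start, end]`` to 0-based half-open
    ``[start-1, end)``.  An empty region list yields a header-only TSV or an
    empty BED.
    """
    rows = [_region_row(r) for r in regions]
    if dialect == "tsv":
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "method",
                                         "support", "components"])
        write_table(df, path)
    elif dialect == "bed":
        with open(path, "w") as fh:
            for r in rows:
                name = r["method"] or "."
                fh.write(f"{r['chrom']}\t{r['start'] - 1}\t{r['end']}\t{name}\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
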