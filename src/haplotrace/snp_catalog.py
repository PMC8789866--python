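"""Strain-discriminating SNP catalog construction and amplicon selection.

Two inbred strains (labelled A and B, e.g. FVB and B6) are compared at every
position where both carry a confident homozygous SNP call; positions where the
two homozygous alleles differ become *informative sites*: a read carrying
``allele_A`` identifies a strain-A chromosome and vice versa. One
maximal-site-density amplicon window (1100–1500 bp by default, matching a
long-amplicon MiSeq design) is then selected per chromosome.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .io import DEFAULT_CHROMOSOMES, chrom_sort_key, read_strain_variants

STRAIN_A = "A"
STRAIN_B = "B"
STRAINS = (STRAIN_A, STRAIN_B)

DEFAULT_MIN_DEPTH = 10
DEFAULT_MIN_QUALITY = 30.0
AMPLICON_MIN_LEN = 1100
AMPLICON_MAX_LEN = 1500


def other_strain(strain: str) -> str:
    if strain == STRAIN_A:
        return STRAIN_B
    if strain == STRAIN_B:
        return STRAIN_A
    raise ValueError(f"unknown strain label: {strain!r}")


@dataclass(frozen=True)
class InformativeSite:
    """One strain-discriminating site: homozygous ``allele_A`` in strain A,
    homozygous ``allele_B`` (different base) in strain B."""

    chrom: str
    pos: int  # 1-based
    allele_A: str
    allele_B: str

    def __post_init__(self):
        if self.allele_A == self.allele_B:
            raise ValueError(f"non-discriminating site {self.chrom}:{self.pos}")


@dataclass(frozen=True)
class AmpliconRegion:
    """A candidate PCR amplicon; coordinates are 1-based inclusive."""

    chrom: str
    start: int
    end: int
    n_sites: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end


@dataclass
class SNPCatalog:
    """Per-chromosome ordered collections of informative sites.

    ``sites`` holds columns ``chrom, pos, allele_A, allele_B`` with unique
    (chrom, pos), sorted by chromosome then position. ``meta`` records
    provenance (input paths, filters).
    """

    sites: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        df = self.sites.copy()
        df["chrom"] = df["chrom"].astype(str)
        df["pos"] = df["pos"].astype(int)
        if df.duplicated(["chrom", "pos"]).any():
            raise ValueError("duplicate (chrom, pos) in catalog")
        if (df["allele_A"] == df["allele_B"]).any():
            raise ValueError("catalog contains non-discriminating sites")
        df = df.sort_values(
            ["chrom", "pos"], key=lambda s: s.map(chrom_sort_key) if s.name == "chrom" else s
        ).reset_index(drop=True)
        self.sites = df

    def __len__(self) -> int:
        return len(self.sites)

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self.sites["chrom"].unique(), key=chrom_sort_key)

    def sites_for(self, chrom: str) -> pd.DataFrame:
        return self.sites[self.sites["chrom"] == chrom].reset_index(drop=True)

    def positions(self, chrom: str) -> list[int]:
        return self.sites_for(chrom)["pos"].tolist()

    def n_sites(self, chrom: str) -> int:
        return int((self.sites["chrom"] == chrom).sum())

    def to_frame(self) -> pd.DataFrame:
        return self.sites.copy()

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, meta: Optional[dict] = None) -> "SNPCatalog":
        return cls(frame[["chrom", "pos", "allele_A", "allele_B"]].copy(), meta or {})

    def swap_strains(self) -> "SNPCatalog":
        df = self.sites.rename(columns={"allele_A": "allele_B", "allele_B": "allele_A"})
        return SNPCatalog.from_frame(df, dict(self.meta, strains_swapped=True))


def build_catalog(
    variants_A,
    variants_B,
    min_depth: int = DEFAULT_MIN_DEPTH,
    min_quality: float = DEFAULT_MIN_QUALITY,
) -> SNPCatalog:
    """Intersect two strains' homozygous SNP calls into an informative-site catalog.

    Parameters
    ----------
    variants_A, variants_B
        Either VCF paths or frames with columns ``chrom, pos, allele, depth,
        qual`` (one homozygous SNP call per row, as produced by
        :func:`haplotrace.io.read_strain_variants`).
    min_depth, min_quality
        Confidence filters applied to each strain's call independently; a call
        with missing depth/quality passes that filter (sites-only inputs).

    A site enters the catalog iff both strains carry a passing homozygous call
    there and the two alleles differ. Raises ``ValueError`` when the two inputs
    share no chromosome (different references / naming schemes).
    """
    a = _as_variant_frame(variants_A)
    b = _as_variant_frame(variants_B)

    if len(a) and len(b):
        if not (set(a["chrom"]) & set(b["chrom"])):
            raise ValueError(
                "variant sets share no chromosome — inputs appear to be called "
                "against different references"
            )

    a = _apply_filters(a, min_depth, min_quality)
    b = _apply_filters(b, min_depth, min_quality)

    merged = a.merge(b, on=["chrom", "pos"], suffixes=("_A", "_B"))
    merged = merged[merged["allele_A"] != merged["allele_B"]]
    sites = merged[["chrom", "pos", "allele_A", "allele_B"]].drop_duplicates(["chrom", "pos"])
    if sites.empty:
        import logging

        logging.getLogger("haplotrace").warning("empty catalog: no discriminating sites found")
    meta = {"min_depth": min_depth, "min_quality": min_quality}
    return SNPCatalog.from_frame(sites.reset_index(drop=True), meta)


def _as_variant_frame(variants) -> pd.DataFrame:
    if isinstance(variants, (str, Path)):
        return read_strain_variants(variants)
    df = pd.DataFrame(variants)
    for col in ("depth", "qual"):
        if col not in df.columns:
            df[col] = float("nan")
    if df.empty:
        return pd.DataFrame(columns=["chrom", "pos", "allele", "depth", "qual"])
    return df[["chrom", "pos", "allele", "depth", "qual"]].copy()


def _apply_filters(df: pd.DataFrame, min_depth: int, min_quality: float) -> pd.DataFrame:
    if df.empty:
        return df
    ok_depth = df["depth"].isna() | (df["depth"] >= min_depth)
    ok_qual = df["qual"].isna() | (df["qual"] >= min_quality)
    return df[ok_depth & ok_qual]


def select_amplicon(
    catalog: SNPCatalog,
    chrom: str,
    min_len: int = AMPLICON_MIN_LEN,
    max_len: int = AMPLICON_MAX_LEN,
) -> Optional[AmpliconRegion]:
    """Select the window of length in [min_len, max_len] containing the most
    catalog sites on ``chrom``.

    Candidate windows are anchored at site positions (a maximal-count window can
    always be slid left until its start coincides with a site). Ties are broken
    by smallest start, then smallest length; the window is trimmed to the last
    contained site but never below ``min_len``. Returns ``None`` when the
    chromosome has no catalog sites.
    """
    if not (1 <= min_len <= max_len):
        raise ValueError("window bounds must satisfy 1 <= min_len <= max_len")
    pos = catalog.positions(chrom)
    if not pos:
        return None
    best: tuple[int, int, int] | None = None  # (-count, start, length)
    for s in pos:
        hi = s + max_len - 1
        lo_i = bisect_left(pos, s)
        hi_i = bisect_right(pos, hi)
        count = hi_i - lo_i
        last_site = pos[hi_i - 1]
        end = max(last_site, s + min_len - 1)
        cand = (-count, s, end - s + 1)
        if best is None or cand < best:
            best = cand
    count, start, length = -best[0], best[1], best[2]
    return AmpliconRegion(chrom=chrom, start=start, end=start + length - 1, n_sites=count)


def select_all_amplicons(
    catalog: SNPCatalog,
    chromosomes: Iterable[str] = DEFAULT_CHROMOSOMES,
    min_len: int = AMPLICON_MIN_LEN,
    max_len: int = AMPLICON_MAX_LEN,
) -> dict[str, Optional[AmpliconRegion]]:
    return {c: select_amplicon(catalog, c, min_len, max_len) for c in chromosomes}
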