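"""Per-chromosome zygosity calling from allele read counts at catalog sites.

Site-level genotypes (HOM_A / HOM_B / HET / NO_COVER) are aggregated to one
call per sample x chromosome (HOM_A / HOM_B / HET / NO_AMP). Aggregation is
deliberately robust to whole-genome-amplification allelic dropout: a HET
chromosome whose sites individually drop one allele or the other still shows a
mix of discordant homozygous site calls, which the chromosome rule reads as
heterozygosity rather than letting a site majority flip it to HOM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

HOM_A = "HOM_A"
HOM_B = "HOM_B"
HET = "HET"
NO_COVER = "NO_COVER"
NO_AMP = "NO_AMP"

SITE_GENOTYPES = (HOM_A, HOM_B, HET, NO_COVER)
CHROMOSOME_CALLS = (HOM_A, HOM_B, HET, NO_AMP)


@dataclass(frozen=True)
class CallingParams:
    """Thresholds for site and chromosome calling.

    min_site_depth : reads required to call a site at all.
    hom_fraction : allele fraction at/above which a site is homozygous.
    min_sites_covered : covered sites required to call a chromosome (else NO_AMP).
    majority_fraction : fraction of covered sites one homozygous label needs.
    het_site_fraction : HET-site proportion at/above which the chromosome is HET.
    discordance_floor : if both HOM_A and HOM_B site calls each exceed this
        proportion of covered sites, the mixed signal is read as HET.
    """

    min_site_depth: int = 10
    hom_fraction: float = 0.9
    min_sites_covered: int = 3
    majority_fraction: float = 0.8
    het_site_fraction: float = 0.3
    discordance_floor: float = 0.1

    def __post_init__(self):
        for name in ("hom_fraction", "majority_fraction", "het_site_fraction", "discordance_floor"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0,1], got {v}")
        if self.min_site_depth < 1 or self.min_sites_covered < 1:
            raise ValueError("depth/coverage floors must be >= 1")


@dataclass
class ChromosomeCall:
    sample_id: str
    chrom: str
    call: str
    n_sites_covered: int
    n_sites_total: int
    mean_fraction_A: float  # NaN when nothing covered
    site_calls: list[str] = field(default_factory=list)


def call_site_genotype(
    reads_A: int,
    reads_B: int,
    min_site_depth: int = CallingParams.min_site_depth,
    hom_fraction: float = CallingParams.hom_fraction,
) -> str:
    """Call one site from its two strain-allele read counts."""
    if reads_A < 0 or reads_B < 0:
        raise ValueError("read counts must be non-negative")
    depth = reads_A + reads_B
    if depth < min_site_depth:
        return NO_COVER
    frac_a = reads_A / depth
    if frac_a >= hom_fraction:
        return HOM_A
    if frac_a <= 1.0 - hom_fraction:
        return HOM_B
    return HET


def _aggregate_sites(
    n_cov: int, n_het: int, n_hom_a: int, n_hom_b: int, params: CallingParams
) -> str:
    if n_cov < params.min_sites_covered:
        return NO_AMP
    if n_het / n_cov >= params.het_site_fraction:
        return HET
    floor = params.discordance_floor * n_cov
    if n_hom_a > floor and n_hom_b > floor:
        return HET
    if n_hom_a / n_cov >= params.majority_fraction:
        return HOM_A
    if n_hom_b / n_cov >= params.majority_fraction:
        return HOM_B
    return HET


def call_chromosome(
    counts: pd.DataFrame,
    catalog_positions,
    params: CallingParams = CallingParams(),
    sample_id: str | None = None,
    chrom: str | None = None,
) -> ChromosomeCall:
    """Aggregate one sample's site counts on one chromosome into a call.

    ``counts`` needs columns ``pos, reads_A, reads_B`` restricted to one
    (sample, chromosome); sites of the catalog absent from ``counts`` are
    treated as uncovered. ``catalog_positions`` is the chromosome's full site
    list and must be non-empty (a chromosome outside the catalog is an error).
    """
    catalog_positions = list(catalog_positions)
    if not catalog_positions:
        raise ValueError(f"chromosome {chrom!r} has no catalog sites")
    if sample_id is None:
        sample_id = str(counts["sample_id"].iloc[0]) if "sample_id" in counts and len(counts) else "?"
    if chrom is None:
        chrom = str(counts["chrom"].iloc[0]) if "chrom" in counts and len(counts) else "?"

    by_pos = {
        int(p): (int(a), int(b))
        for p, a, b in zip(counts["pos"], counts["reads_A"], counts["reads_B"])
    }
    site_calls = []
    fracs = []
    for p in catalog_positions:
        ra, rb = by_pos.get(int(p), (0, 0))
        g = call_site_genotype(ra, rb, params.min_site_depth, params.hom_fraction)
        site_calls.append(g)
        if g != NO_COVER:
            fracs.append(ra / (ra + rb))
    n_cov = len(fracs)
    n_het = site_calls.count(HET)
    n_a = site_calls.count(HOM_A)
    n_b = site_calls.count(HOM_B)
    call = _aggregate_sites(n_cov, n_het, n_a, n_b, params)
    return ChromosomeCall(
        sample_id=sample_id,
        chrom=chrom,
        call=call,
        n_sites_covered=n_cov,
        n_sites_total=len(catalog_positions),
        mean_fraction_A=float(np.mean(fracs)) if fracs else float("nan"),
        site_calls=site_calls,
    )


def call_table(
    counts: pd.DataFrame,
    catalog,
    params: CallingParams = CallingParams(),
) -> pd.DataFrame:
    """Vectorized chromosome calling for a whole allele-count table.

    Returns one row per (sample_id, chrom) with columns ``call,
    n_sites_covered, n_sites_total, mean_fraction_A, n_het, n_hom_a, n_hom_b``.
    Every chromosome present in the table must exist in the catalog; catalog
    chromosomes entirely absent for a sample are NOT invented (callers that
    need complete universes pass complete tables, as the simulator emits).
    """
    cat = catalog.to_frame() if hasattr(catalog, "to_frame") else catalog
    n_total = cat.groupby("chrom")["pos"].size()
    unknown = set(counts["chrom"].unique()) - set(n_total.index)
    if unknown:
        raise ValueError(f"chromosomes absent from catalog: {sorted(unknown)}")

    df = counts.copy()
    depth = df["reads_A"].to_numpy() + df["reads_B"].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        frac_a = np.where(depth > 0, df["reads_A"].to_numpy() / np.maximum(depth, 1), np.nan)
    covered = depth >= params.min_site_depth
    site_call = np.select(
        [
            ~covered,
            frac_a >= params.hom_fraction,
            frac_a <= 1.0 - params.hom_fraction,
        ],
        [NO_COVER, HOM_A, HOM_B],
        default=HET,
    )
    df["_covered"] = covered
    df["_het"] = site_call == HET
    df["_a"] = site_call == HOM_A
    df["_b"] = site_call == HOM_B
    df["_frac"] = np.where(covered, frac_a, np.nan)

    g = df.groupby(["sample_id", "chrom"], sort=False).agg(
        n_sites_covered=("_covered", "sum"),
        n_het=("_het", "sum"),
        n_hom_a=("_a", "sum"),
        n_hom_b=("_b", "sum"),
        mean_fraction_A=("_frac", "mean"),
    )
    g = g.reset_index()
    g["n_sites_total"] = g["chrom"].map(n_total).astype(int)

    n_cov = g["n_sites_covered"].to_numpy(dtype=float)
    n_het = g["n_het"].to_numpy(dtype=float)
    n_a = g["n_hom_a"].to_numpy(dtype=float)
    n_b = g["n_hom_b"].to_numpy(dtype=float)
    safe_cov = np.maximum(n_cov, 1.0)
    floor = params.discordance_floor * n_cov
    call = np.select(
        [
            n_cov < params.min_sites_covered,
            n_het / safe_cov >= params.het_site_fraction,
            (n_a > floor) & (n_b > floor),
            n_a / safe_cov >= params.majority_fraction,
            n_b / safe_cov >= params.majority_fraction,
        ],
        [NO_AMP, HET, HET, HOM_A, HOM_B],
        default=HET,
    )
    g["call"] = call
    cols = [
        "sample_id",
        "chrom",
        "call",
        "n_sites_covered",
        "n_sites_total",
        "mean_fraction_A",
        "n_het",
        "n_hom_a",
        "n_hom_b",
    ]
    return g[cols]
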