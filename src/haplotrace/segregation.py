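"""Reciprocal-segregation classification of PPB–embryo pairs.

After somatic-cell nuclear transfer into an enucleated MII oocyte and
fertilization, the diploid somatic chromosome set (2n/2c) can partition so
that one homolog of each pair is extruded into the pseudo-polar body (PPB)
while the other remains in the embryo alongside the sperm genome. With an
F1-hybrid donor (strains A and B) each homolog carries a strain signature, so
per-chromosome zygosity calls of the PPB and embryo reveal whether the pair
segregated reciprocally (PROPER) or nondisjoined into the PPB (both homologs
extruded, PPB heterozygous) or into the embryo (PPB empty).

The embryo genotype is always read *net of the known sperm strain*: an embryo
HOM call equal to the sperm strain means "somatic contribution not detected",
not somatic homozygosity. Donor cells are not perfectly heterozygous — pooled
fibroblasts carry recombined homozygous (LOH) tracts — so a same-strain signal
in both PPB and embryo is still accepted as proper segregation when the donor
itself is homozygous for that strain on the chromosome (the donor-homozygosity
relaxation). Evidence precedence: complementary-homozygosity > donor-LOH
relaxation > nondisjunction patterns > AMBIGUOUS.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .io import CHROM_X, DEFAULT_CHROMOSOMES, chrom_sort_key
from .snp_catalog import STRAIN_A, STRAIN_B, other_strain
from .zygosity import HET, HOM_A, HOM_B, NO_AMP, ChromosomeCall

PROPER = "PROPER"
NDJ_PPB = "NDJ_PPB"
NDJ_EMBRYO = "NDJ_EMBRYO"
AMBIGUOUS = "AMBIGUOUS"
CLASSES = (PROPER, NDJ_PPB, NDJ_EMBRYO, AMBIGUOUS)

MALE = "male"
FEMALE = "female"
UNDETERMINED = "undetermined"

X_SOMATIC = "somatic"
X_SPERM = "sperm"
X_BOTH = "both"

COMPLETE_SH = "complete_SH"
PARTIAL_SH = "partial_SH"
NO_SOMATIC = "no_somatic"

_HOM_OF = {STRAIN_A: HOM_A, STRAIN_B: HOM_B}
_STRAIN_OF = {HOM_A: STRAIN_A, HOM_B: STRAIN_B}


@dataclass
class DonorZygosityMap:
    """Donor zygosity at catalog sites: HET / HOM_A / HOM_B per (chrom, pos).

    ``donor_informative(chrom)`` is true when at least ``min_het_fraction`` of
    the chromosome's sites are heterozygous in the donor — below that the two
    homologs are barely distinguishable and pair classification abstains.
    """

    zygosity: pd.DataFrame  # columns: chrom, pos, donor_call
    min_het_fraction: float = 0.3

    def __post_init__(self):
        need = {"chrom", "pos", "donor_call"}
        if not need <= set(self.zygosity.columns):
            raise ValueError(f"donor zygosity needs columns {sorted(need)}")
        bad = set(self.zygosity["donor_call"]) - {HET, HOM_A, HOM_B}
        if bad:
            raise ValueError(f"invalid donor calls: {sorted(bad)}")
        stats = (
            self.zygosity.groupby("chrom")["donor_call"]
            .agg(
                n="size",
                n_het=lambda s: int((s == HET).sum()),
                n_hom_a=lambda s: int((s == HOM_A).sum()),
                n_hom_b=lambda s: int((s == HOM_B).sum()),
            )
            .to_dict(orient="index")
        )
        self._chrom_stats = stats

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self._chrom_stats, key=chrom_sort_key)

    def het_fraction(self, chrom: str) -> float:
        st = self._chrom_stats.get(chrom)
        if not st or st["n"] == 0:
            return float("nan")
        return st["n_het"] / st["n"]

    def donor_informative(self, chrom: str) -> bool:
        f = self.het_fraction(chrom)
        return bool(f == f and f >= self.min_het_fraction)

    def has_hom(self, chrom: str, strain: str) -> bool:
        """Does the donor carry homozygous strain-``strain`` sites on ``chrom``?"""
        st = self._chrom_stats.get(chrom)
        if not st:
            return False
        return (st["n_hom_a"] if strain == STRAIN_A else st["n_hom_b"]) > 0

    @classmethod
    def from_site_calls(
        cls, site_calls: pd.DataFrame, min_het_fraction: float = 0.3
    ) -> "DonorZygosityMap":
        """Build from per-site genotype calls of the donor sample
        (columns ``chrom, pos, site_call``; NO_COVER sites are dropped)."""
        df = site_calls.rename(columns={"site_call": "donor_call"})
        df = df[df["donor_call"].isin([HET, HOM_A, HOM_B])]
        return cls(df[["chrom", "pos", "donor_call"]].reset_index(drop=True), min_het_fraction)


@dataclass(frozen=True)
class ChromClassification:
    chrom: str
    class_: str
    retained_origin: Optional[str]  # strain retained in the embryo; PROPER only
    rationale: str
    embryo_call: Optional[str] = None
    ppb_call: Optional[str] = None


@dataclass
class PairClassification:
    pair_id: str
    sperm_strain: str
    chromosomes: dict[str, ChromClassification] = field(default_factory=dict)

    def n_with_class(self, cls: str) -> int:
        return sum(1 for c in self.chromosomes.values() if c.class_ == cls)

    @property
    def n_proper(self) -> int:
        return self.n_with_class(PROPER)

    @property
    def n_classified(self) -> int:
        return sum(1 for c in self.chromosomes.values() if c.class_ != AMBIGUOUS)


def _classify_one(
    embryo: Optional[str],
    ppb: Optional[str],
    donor_informative: bool,
    donor_hom_a: bool,
    donor_hom_b: bool,
    sperm: str,
    no_sperm_allele: bool,
) -> tuple[str, Optional[str], str]:
    """Classify one chromosome from its (embryo call, PPB call) and donor context.

    ``no_sperm_allele`` marks the X of a male embryo: the sperm contributed Y,
    so the embryo's X signal is purely somatic and no sperm subtraction applies.
    """
    if not donor_informative:
        return AMBIGUOUS, None, "donor_uninformative"
    if embryo is None or ppb is None:
        return AMBIGUOUS, None, "missing_chromosome"

    donor_hom = {STRAIN_A: donor_hom_a, STRAIN_B: donor_hom_b}

    if ppb == HET:
        # both somatic homologs extruded
        return NDJ_PPB, None, "ppb_heterozygous"

    if ppb in (HOM_A, HOM_B):
        p = _STRAIN_OF[ppb]  # strain extruded to the PPB
        comp = other_strain(p)  # homolog the embryo should retain
        if embryo == NO_AMP:
            return AMBIGUOUS, None, "embryo_no_amplification"
        if no_sperm_allele:
            if embryo == _HOM_OF[comp]:
                return PROPER, comp, "reciprocal"
            if embryo == _HOM_OF[p]:
                if donor_hom[p]:
                    return PROPER, p, "donor_loh_relaxation"
                return AMBIGUOUS, None, "same_strain_conflict"
            return AMBIGUOUS, None, "inconsistent_pattern"  # embryo HET vs PPB HOM
        o = other_strain(sperm)  # the strain only the somatic genome can supply
        somatic_o_detected = embryo in (HET, _HOM_OF[o])
        if somatic_o_detected:
            if p == sperm:
                return PROPER, o, "reciprocal"
            # same non-sperm strain on both sides
            if donor_hom[o]:
                return PROPER, o, "donor_loh_relaxation"
            return AMBIGUOUS, None, "same_strain_conflict"
        # embryo HOM_sperm: somatic contribution masked or absent
        if p == o:
            # PPB extruded the non-sperm homolog; the retained homolog must be
            # the sperm-strain one, invisible behind the sperm allele
            return PROPER, sperm, "complement_inferred"
        if donor_hom[sperm]:
            return PROPER, sperm, "donor_loh_relaxation"
        return AMBIGUOUS, None, "somatic_undetected"

    # ppb == NO_AMP: nothing amplified from the PPB
    if embryo == NO_AMP or embryo is None:
        return AMBIGUOUS, None, "no_amplification"
    somatic_signal = (
        embryo in (HET, HOM_A, HOM_B)
        if no_sperm_allele
        else embryo in (HET, _HOM_OF[other_strain(sperm)])
    )
    if somatic_signal:
        # empty PPB with somatic material in the embryo: pair retained in embryo
        return NDJ_EMBRYO, None, "ppb_empty_somatic_in_embryo"
    return AMBIGUOUS, None, "no_somatic_signal"


def _call_of(x) -> Optional[str]:
    if x is None:
        return None
    if isinstance(x, ChromosomeCall):
        return x.call
    return str(x)


def classify_pair(
    embryo_calls: Mapping[str, object],
    ppb_calls: Mapping[str, object],
    donor: DonorZygosityMap,
    sperm_strain: str,
    pair_id: str = "pair",
    embryo_is_male: bool = False,
    chromosomes: Optional[Sequence[str]] = None,
) -> PairClassification:
    """Classify every chromosome of one PPB–embryo pair.

    ``embryo_calls``/``ppb_calls`` map chromosome -> call (string or
    :class:`~haplotrace.zygosity.ChromosomeCall`). A chromosome missing from
    either sample is AMBIGUOUS with rationale, never silently dropped. The X of
    a male embryo is classified without sperm subtraction (sperm gave Y, the
    embryo X is of somatic origin).
    """
    if sperm_strain not in (STRAIN_A, STRAIN_B):
        raise ValueError(f"unknown sperm strain {sperm_strain!r}")
    if chromosomes is None:
        universe = set(embryo_calls) | set(ppb_calls) | set(donor.chromosomes)
        chromosomes = sorted(universe, key=chrom_sort_key)
    result = PairClassification(pair_id=pair_id, sperm_strain=sperm_strain)
    for chrom in chromosomes:
        e = _call_of(embryo_calls.get(chrom))
        p = _call_of(ppb_calls.get(chrom))
        cls, origin, rationale = _classify_one(
            e,
            p,
            donor.donor_informative(chrom),
            donor.has_hom(chrom, STRAIN_A),
            donor.has_hom(chrom, STRAIN_B),
            sperm_strain,
            no_sperm_allele=(chrom == CHROM_X and embryo_is_male),
        )
        result.chromosomes[chrom] = ChromClassification(
            chrom=chrom,
            class_=cls,
            retained_origin=origin,
            rationale=rationale,
            embryo_call=e,
            ppb_call=p,
        )
    return result


def classify_pairs_table(
    calls: pd.DataFrame,
    manifest: pd.DataFrame,
    donor_maps: Mapping[str, DonorZygosityMap],
    sexes: Optional[Mapping[str, str]] = None,
    chromosomes: Sequence[str] = DEFAULT_CHROMOSOMES,
) -> list[PairClassification]:
    """Classify every pair of a cohort from a chromosome-call table.

    ``calls`` is the frame produced by :func:`haplotrace.zygosity.call_table`;
    ``manifest`` maps pair_id -> embryo/ppb/donor sample ids and sperm strain;
    ``donor_maps`` maps donor_sample_id -> :class:`DonorZygosityMap`;
    ``sexes`` optionally maps pair_id -> "male"/"female" (default female).
    """
    by_sample: dict[str, dict[str, str]] = {}
    for sid, sub in calls.groupby("sample_id"):
        by_sample[str(sid)] = dict(zip(sub["chrom"], sub["call"]))
    out = []
    for row in manifest.itertuples(index=False):
        for col in ("embryo_sample_id", "ppb_sample_id"):
            if getattr(row, col) not in by_sample:
                raise ValueError(f"manifest sample {getattr(row, col)!r} absent from call table")
        donor = donor_maps[row.donor_sample_id]
        sex = (sexes or {}).get(row.pair_id, FEMALE)
        out.append(
            classify_pair(
                by_sample[row.embryo_sample_id],
                by_sample[row.ppb_sample_id],
                donor,
                row.sperm_strain,
                pair_id=row.pair_id,
                embryo_is_male=(sex == MALE),
                chromosomes=chromosomes,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Cohort aggregation
# ---------------------------------------------------------------------------


@dataclass
class SegregationSummary:
    """Cohort-level aggregates over pair classifications.

    Fractions over empty denominators are reported as ``None`` (absent), never
    coerced to 0.
    """

    n_pairs: int
    n_chromosomes_assayed: int
    n_proper_per_pair: dict[str, int]
    n_homozygous_ppb_per_pair: dict[str, int]
    percent_proper_mean: float
    ndj_in_ppb_fraction: Optional[float]
    retained_origin_a_fraction: Optional[float]
    proper_count_per_chromosome: dict[str, int]
    n_ndj_ppb: int
    n_ndj_embryo: int
    n_ambiguous: int
    total_proper: int
    total_classified: int
    sex_tally: Optional[dict[str, int]] = None
    n_complete_sh: Optional[int] = None

    def to_dict(self) -> dict:
        return {
            "n_pairs": self.n_pairs,
            "n_chromosomes_assayed": self.n_chromosomes_assayed,
            "n_proper_per_pair": self.n_proper_per_pair,
            "n_homozygous_ppb_per_pair": self.n_homozygous_ppb_per_pair,
            "percent_proper_mean": self.percent_proper_mean,
            "ndj_in_ppb_fraction": self.ndj_in_ppb_fraction,
            "retained_origin_a_fraction": self.retained_origin_a_fraction,
            "proper_count_per_chromosome": self.proper_count_per_chromosome,
            "n_ndj_ppb": self.n_ndj_ppb,
            "n_ndj_embryo": self.n_ndj_embryo,
            "n_ambiguous": self.n_ambiguous,
            "total_proper": self.total_proper,
            "total_classified": self.total_classified,
            "sex_tally": self.sex_tally,
            "n_complete_sh": self.n_complete_sh,
        }


def summarize(
    classifications: Iterable[PairClassification],
    n_chromosomes_assayed: Optional[int] = None,
    sexes: Optional[Mapping[str, str]] = None,
    n_complete_sh: Optional[int] = None,
) -> SegregationSummary:
    """Aggregate pair classifications into cohort statistics by direct counting."""
    classifications = list(classifications)
    if not classifications:
        raise ValueError("summarize requires at least one pair")
    if n_chromosomes_assayed is None:
        n_chromosomes_assayed = max(len(c.chromosomes) for c in classifications)

    n_proper_per_pair = {}
    n_hom_ppb = {}
    per_chrom_proper: dict[str, int] = {}
    n_ppb = n_emb = n_amb = 0
    retained_a = retained_total = 0
    for pc in classifications:
        n_proper_per_pair[pc.pair_id] = pc.n_proper
        n_hom_ppb[pc.pair_id] = sum(
            1 for c in pc.chromosomes.values() if c.ppb_call in (HOM_A, HOM_B)
        )
        for c in pc.chromosomes.values():
            if c.class_ == PROPER:
                per_chrom_proper[c.chrom] = per_chrom_proper.get(c.chrom, 0) + 1
                retained_total += 1
                if c.retained_origin == STRAIN_A:
                    retained_a += 1
            elif c.class_ == NDJ_PPB:
                n_ppb += 1
            elif c.class_ == NDJ_EMBRYO:
                n_emb += 1
            else:
                n_amb += 1

    total_proper = sum(n_proper_per_pair.values())
    total_classified = total_proper + n_ppb + n_emb
    percent_proper_mean = float(
        np.mean([n / n_chromosomes_assayed * 100.0 for n in n_proper_per_pair.values()])
    )
    ndj_total = n_ppb + n_emb
    sex_tally = None
    if sexes is not None:
        sex_tally = {MALE: 0, FEMALE: 0, UNDETERMINED: 0}
        for s in sexes.values():
            sex_tally[s if s in sex_tally else UNDETERMINED] += 1
    return SegregationSummary(
        n_pairs=len(classifications),
        n_chromosomes_assayed=n_chromosomes_assayed,
        n_proper_per_pair=n_proper_per_pair,
        n_homozygous_ppb_per_pair=n_hom_ppb,
        percent_proper_mean=percent_proper_mean,
        ndj_in_ppb_fraction=(n_ppb / ndj_total) if ndj_total else None,
        retained_origin_a_fraction=(retained_a / retained_total) if retained_total else None,
        proper_count_per_chromosome=dict(
            sorted(per_chrom_proper.items(), key=lambda kv: chrom_sort_key(kv[0]))
        ),
        n_ndj_ppb=n_ppb,
        n_ndj_embryo=n_emb,
        n_ambiguous=n_amb,
        total_proper=total_proper,
        total_classified=total_classified,
        sex_tally=sex_tally,
        n_complete_sh=n_complete_sh,
    )


# ---------------------------------------------------------------------------
# Sex / contribution calls
# ---------------------------------------------------------------------------


def call_sex(
    x_call: Optional[object],
    y_marker_present: Optional[bool],
    sperm_strain: str,
) -> tuple[str, str]:
    """Infer embryo sex and X-chromosome origin.

    A present Y marker (the PCR sex assay abstracted to presence/absence) means
    male, and the sperm contributed Y — so the embryo X must be of somatic
    origin. Without a Y marker the X zygosity decides: a heterozygous X carries
    both the somatic and the sperm X.
    """
    x = _call_of(x_call)
    if y_marker_present is True:
        return MALE, X_SOMATIC
    if y_marker_present is False:
        if x == HET:
            return FEMALE, X_BOTH
        if x == _HOM_OF[sperm_strain]:
            return FEMALE, X_SPERM
        if x in (HOM_A, HOM_B):  # non-sperm strain observed
            return FEMALE, X_SOMATIC
        return FEMALE, UNDETERMINED
    # Y-marker status unknown
    if x == HET:
        return FEMALE, X_BOTH
    return UNDETERMINED, UNDETERMINED


@dataclass(frozen=True)
class ContributionCall:
    category: str  # complete_SH / partial_SH / no_somatic
    somatic_positive: dict
    n_somatic_positive: int
    n_assayed: int


def classify_contribution(
    embryo_calls: Mapping[str, object],
    sperm_strain: str,
    embryo_is_male: bool = False,
    chromosomes: Sequence[str] = DEFAULT_CHROMOSOMES,
) -> ContributionCall:
    """Score somatic-genome contribution across all 20 chromosomes of an embryo.

    A chromosome is somatic-positive when the non-sperm strain allele is
    detected. ``complete_SH`` requires every chromosome to show both the
    somatic and the sperm contribution (heterozygous), except the X of a male
    embryo, where a purely somatic X (sperm gave Y) suffices. Chromosomes
    without data force a partial verdict.
    """
    o = other_strain(sperm_strain)
    somatic_pos: dict[str, bool] = {}
    complete = True
    for chrom in chromosomes:
        call = _call_of(embryo_calls.get(chrom))
        pos = call in (HET, _HOM_OF[o])
        somatic_pos[chrom] = bool(pos)
        if chrom == CHROM_X and embryo_is_male:
            ok = pos  # somatic X, sperm supplied Y
        else:
            ok = call == HET
        complete = complete and ok
    n_pos = sum(somatic_pos.values())
    if complete:
        category = COMPLETE_SH
    elif n_pos == 0:
        category = NO_SOMATIC
    else:
        category = PARTIAL_SH
    return ContributionCall(
        category=category,
        somatic_positive=somatic_pos,
        n_somatic_positive=n_pos,
        n_assayed=len(list(chromosomes)),
    )


# ---------------------------------------------------------------------------
# Outputs
# ---------------------------------------------------------------------------


def classifications_to_frame(classifications: Iterable[PairClassification]) -> pd.DataFrame:
    rows = []
    for pc in classifications:
        for c in pc.chromosomes.values():
            rows.append(
                {
                    "pair_id": pc.pair_id,
                    "chrom": c.chrom,
                    "class": c.class_,
                    "retained_origin": c.retained_origin or "",
                    "rationale": c.rationale,
                    "embryo_call": c.embryo_call or "",
                    "ppb_call": c.ppb_call or "",
                }
            )
    return pd.DataFrame(rows)


_MAP_SYMBOL = {HOM_A: "A", HOM_B: "B", HET: "AB", NO_AMP: "."}


def chromosome_map_text(classifications: Iterable[PairClassification]) -> str:
    """Render a per-pair text chromosome map: one row per chromosome showing
    the PPB and embryo strain states (A / B / AB heterozygous / . no amplicon)
    and the assigned segregation class."""
    lines = []
    for pc in classifications:
        lines.append(f"# pair {pc.pair_id} (sperm strain {pc.sperm_strain})")
        lines.append("chrom\tppb\tembryo\tclass\tretained_origin")
        for chrom in sorted(pc.chromosomes, key=chrom_sort_key):
            c = pc.chromosomes[chrom]
            lines.append(
                "\t".join(
                    [
                        chrom,
                        _MAP_SYMBOL.get(c.ppb_call, "?"),
                        _MAP_SYMBOL.get(c.embryo_call, "?"),
                        c.class_,
                        c.retained_origin or "-",
                    ]
                )
            )
        lines.append("")
    return "\n".join(lines)
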