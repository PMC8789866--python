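"""Chromosome-level copy-number profiling from per-chromosome read counts.

Normalization follows the two-step ratio used for exome-based embryo ploidy
screening: each chromosome's read count is divided by the sample's mean
autosomal count (giving r, whose autosomal mean is 1 by construction), then by
the same quantity of a reference male sample (giving R). Estimated copies are
R times the reference ploidy (autosomes 2, X 1 for a male reference), rounded
to the nearest integer within a confidence band.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .io import AUTOSOMES, CHROM_X, chrom_sort_key

MALE = "male"
FEMALE = "female"

#: estimated copies must be within this distance of an integer for a confident call
DEFAULT_ROUNDING_BAND = 0.25
MAX_PLOIDY_CALL = 3


def reference_ploidy(reference_sex: str = MALE, chromosomes: Iterable[str] = None) -> dict[str, int]:
    """Per-chromosome copy number of the reference sample (autosomes 2; X 1 if male)."""
    chroms = list(chromosomes) if chromosomes is not None else list(AUTOSOMES) + [CHROM_X]
    out = {}
    for c in chroms:
        if c == CHROM_X:
            out[c] = 1 if reference_sex == MALE else 2
        else:
            out[c] = 2
    return out


@dataclass
class CNVProfile:
    sample_id: str
    r: dict[str, float]  # count / mean autosomal count of the sample
    R: dict[str, float]  # r(sample) / r(reference); NaN where reference r == 0
    reference_sex: str = MALE
    undefined: list[str] = field(default_factory=list)  # chromosomes with undefined R

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self.r, key=chrom_sort_key)


@dataclass
class PloidyResult:
    sample_id: str
    estimated_copies: dict[str, float]
    calls: dict[str, Optional[int]]  # None where R undefined
    confident: dict[str, bool]
    euploid: bool


def _as_series(counts) -> pd.Series:
    if isinstance(counts, pd.Series):
        return counts.astype(float)
    if isinstance(counts, Mapping):
        return pd.Series(counts, dtype=float)
    raise TypeError("counts must be a mapping or Series of chrom -> count")


def normalize(
    sample_counts,
    reference_counts,
    sample_id: str = "sample",
    reference_sex: str = MALE,
    autosomes: Iterable[str] = AUTOSOMES,
) -> CNVProfile:
    """Compute r and R values for one sample against a reference sample.

    Both inputs map chromosome -> mapped-read count. Raises ``ValueError`` when
    either sample has zero mean autosomal count; chromosomes where the
    reference r is 0 get ``R = NaN`` and are listed in ``undefined``.
    """
    s = _as_series(sample_counts)
    ref = _as_series(reference_counts)
    autosomes = [a for a in autosomes if a in s.index]
    if not autosomes:
        raise ValueError("no autosomal counts in sample")
    s_mean = float(s.loc[autosomes].mean())
    ref_auto = [a for a in autosomes if a in ref.index]
    ref_mean = float(ref.loc[ref_auto].mean()) if ref_auto else 0.0
    if s_mean <= 0 or ref_mean <= 0:
        raise ValueError("mean autosomal read count must be positive in sample and reference")

    r = {c: float(s[c]) / s_mean for c in s.index}
    R: dict[str, float] = {}
    undefined = []
    for c in s.index:
        if c not in ref.index or ref[c] <= 0:
            R[c] = float("nan")
            undefined.append(c)
        else:
            R[c] = r[c] / (float(ref[c]) / ref_mean)
    return CNVProfile(sample_id=sample_id, r=r, R=R, reference_sex=reference_sex, undefined=undefined)


def call_ploidy(
    profile: CNVProfile,
    ref_ploidy: Optional[Mapping[str, int]] = None,
    rounding_band: float = DEFAULT_ROUNDING_BAND,
    autosomes: Iterable[str] = AUTOSOMES,
) -> PloidyResult:
    """Convert R values to integer per-chromosome copy calls and a euploidy flag.

    Estimated copies = R x reference ploidy. A call is confident when within
    ``rounding_band`` of its nearest integer (clipped to 0..3). Euploid means
    every autosome confidently calls 2 and the X (when profiled) confidently
    calls 1 or 2.
    """
    if ref_ploidy is None:
        ref_ploidy = reference_ploidy(profile.reference_sex, profile.chromosomes)
    est: dict[str, float] = {}
    calls: dict[str, Optional[int]] = {}
    conf: dict[str, bool] = {}
    for c in profile.chromosomes:
        Rv = profile.R.get(c, float("nan"))
        if not np.isfinite(Rv) or c not in ref_ploidy:
            est[c] = float("nan")
            calls[c] = None
            conf[c] = False
            continue
        e = Rv * ref_ploidy[c]
        k = int(np.clip(np.rint(e), 0, MAX_PLOIDY_CALL))
        est[c] = float(e)
        calls[c] = k
        conf[c] = bool(abs(e - k) <= rounding_band)

    autoset = set(autosomes)
    euploid = True
    for c in profile.chromosomes:
        if c in autoset:
            if not (calls[c] == 2 and conf[c]):
                euploid = False
        elif c == CHROM_X:
            if not (calls[c] in (1, 2) and conf[c]):
                euploid = False
    return PloidyResult(
        sample_id=profile.sample_id,
        estimated_copies=est,
        calls=calls,
        confident=conf,
        euploid=euploid,
    )


def euploidy_screen(
    profiles: Iterable[CNVProfile],
    ref_ploidy: Optional[Mapping[str, int]] = None,
    rounding_band: float = DEFAULT_ROUNDING_BAND,
) -> tuple[dict[str, bool], int]:
    """Per-sample euploidy verdicts and the cohort euploid count."""
    profiles = list(profiles)
    if not profiles:
        raise ValueError("euploidy_screen requires at least one profile")
    verdicts = {}
    for p in profiles:
        verdicts[p.sample_id] = call_ploidy(p, ref_ploidy, rounding_band).euploid
    return verdicts, sum(verdicts.values())


def profiles_to_frame(profiles: Iterable[CNVProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        for c in p.chromosomes:
            rows.append(
                {"sample_id": p.sample_id, "chrom": c, "r": p.r[c], "R": p.R[c]}
            )
    return pd.DataFrame(rows)
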