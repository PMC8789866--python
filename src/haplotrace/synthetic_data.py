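"""Ground-truthed synthetic somatic-haploidization experiments.

The generator emulates the genetic design end-to-end: an informative-SNP
catalog for two inbred strains, an F1-hybrid donor that is heterozygous except
for occasional homozygous (LOH-like) tracts, per-chromosome reciprocal
segregation of the two somatic homologs between embryo and pseudo-polar body
(with a configurable nondisjunction rate and PPB-destination bias), a
single-strain sperm genome (X or Y transmitted with equal probability),
WGA-style site-level allelic dropout plus chromosome-level amplification
failure, and Poisson/binomial read sampling at catalog sites. Chromosome-level
read counts for copy-number profiling are Poisson around copy-proportional
means.

Default parameters mirror the experimental regime the analysis is designed
for: 20 mouse chromosomes (19 autosomes + X), 15 PPB–embryo pairs, a 0.24
per-chromosome nondisjunction rate with 74% of nondisjoined pairs extruded to
the PPB, and B-strain (B6-like) sperm. Everything is deterministic in the
configuration seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .io import AUTOSOMES, CHROM_X
from .segregation import DonorZygosityMap, FEMALE, MALE
from .snp_catalog import STRAIN_A, STRAIN_B, SNPCatalog, other_strain
from .zygosity import HET, HOM_A, HOM_B

PROPER = "PROPER"
NDJ_PPB = "NDJ_PPB"
NDJ_EMBRYO = "NDJ_EMBRYO"
EVENTS = (PROPER, NDJ_PPB, NDJ_EMBRYO)

_BASES = np.array(list("ACGT"))
_CHROM_SPAN = 2_000_000  # synthetic coordinate span per chromosome


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters of one synthetic haploidization experiment."""

    n_autosomes: int = 19
    include_X: bool = True
    sites_per_chromosome: int = 20
    p_nondisjunction: float = 0.24
    p_ndj_to_ppb: float = 0.74
    p_site_dropout: float = 0.05
    p_chrom_amp_failure: float = 0.02
    mean_depth: float = 100.0
    donor_loh_fraction: float = 0.1
    n_pairs: int = 15
    sperm_strain: str = STRAIN_B
    seed: int = 0

    def __post_init__(self):
        probs = {
            "p_nondisjunction": self.p_nondisjunction,
            "p_ndj_to_ppb": self.p_ndj_to_ppb,
            "p_site_dropout": self.p_site_dropout,
            "p_chrom_amp_failure": self.p_chrom_amp_failure,
            "donor_loh_fraction": self.donor_loh_fraction,
        }
        for name, v in probs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0,1], got {v}")
        if self.n_autosomes < 1 or self.sites_per_chromosome < 1 or self.n_pairs < 1:
            raise ValueError("counts must be >= 1")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.sperm_strain not in (STRAIN_A, STRAIN_B):
            raise ValueError(f"unknown sperm strain {self.sperm_strain!r}")

    @property
    def chromosomes(self) -> list[str]:
        chroms = [str(i) for i in range(1, self.n_autosomes + 1)]
        if self.include_X:
            chroms.append(CHROM_X)
        return chroms

    @property
    def n_chromosomes(self) -> int:
        return self.n_autosomes + (1 if self.include_X else 0)


@dataclass
class SimTruth:
    """Ground truth of one simulated experiment.

    ``events`` has one row per (pair, chromosome): the segregation event, the
    homolog retained in the embryo (PROPER only), and the somatic copy counts
    on each side, which always sum to 2 (conservation of the 2n content).
    ``pairs`` records per-pair sperm transmission (X vs Y) and embryo sex.
    ``donor_tracts`` maps chromosome -> list of (start_idx, stop_idx, strain)
    half-open site-index ranges where the donor is homozygous.
    """

    config: SimConfig
    pairs: pd.DataFrame  # pair_id, sperm_transmits_y, embryo_sex, sperm_strain
    events: pd.DataFrame  # pair_id, chrom, event, retained_homolog, embryo_somatic_copies, ppb_copies
    donor_tracts: dict = field(default_factory=dict)

    def event_for(self, pair_id: str, chrom: str) -> str:
        sub = self.events[(self.events["pair_id"] == pair_id) & (self.events["chrom"] == chrom)]
        return str(sub["event"].iloc[0])

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config": asdict(self.config),
            "pairs": self.pairs.to_dict(orient="records"),
            "events": self.events.to_dict(orient="records"),
            "donor_tracts": {
                c: [[int(a), int(b), s] for a, b, s in tracts]
                for c, tracts in self.donor_tracts.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            config=SimConfig(**payload["config"]),
            pairs=pd.DataFrame(payload["pairs"]),
            events=pd.DataFrame(payload["events"]),
            donor_tracts={
                c: [(int(a), int(b), s) for a, b, s in tracts]
                for c, tracts in payload["donor_tracts"].items()
            },
        )


def _rng(config: SimConfig, stream: int, rng: Optional[np.random.Generator]) -> np.random.Generator:
    return rng if rng is not None else np.random.default_rng([config.seed, stream])


# ---------------------------------------------------------------------------
# Catalog and donor
# ---------------------------------------------------------------------------

def _place_loh_tracts(rng: np.random.Generator, n_sites: int, fraction: float):
    """Place non-overlapping contiguous homozygous tracts covering ~fraction of
    sites; returns half-open site-index ranges with one strain each."""
    target = int(round(fraction * n_sites))
    if target <= 0:
        return []
    covered = np.zeros(n_sites, dtype=bool)
    tracts: list[tuple[int, int, str]] = []
    mean_len = max(1, n_sites // 8)
    attempts = 0
    while covered.sum() < target and attempts < 200:
        remaining = target - int(covered.sum())
        length = int(min(remaining, max(1, rng.geometric(1.0 / mean_len))))
        start = int(rng.integers(0, n_sites - length + 1))
        if covered[start : start + length].any():
            attempts += 1
            continue
        strain = STRAIN_A if rng.random() < 0.5 else STRAIN_B
        tracts.append((start, start + length, strain))
        covered[start : start + length] = True
    # congested layouts: fill remaining free runs deterministically
    remaining = target - int(covered.sum())
    i = 0
    while remaining > 0 and i < n_sites:
        if not covered[i]:
            j = i
            while j < n_sites and not covered[j] and (j - i) < remaining:
                j += 1
            strain = STRAIN_A if rng.random() < 0.5 else STRAIN_B
            tracts.append((i, j, strain))
            covered[i:j] = True
            remaining -= j - i
            i = j
        else:
            i += 1
    return sorted(tracts)


def simulate_catalog_and_donor(
    config: SimConfig, rng: Optional[np.random.Generator] = None
) -> tuple[SNPCatalog, DonorZygosityMap, dict]:
    """Generate the informative-site catalog and the donor's zygosity map.

    The donor is heterozygous at every site except those inside LOH tracts,
    where both homologs carry the tract's strain allele. Returns the catalog,
    the donor map and the tract dictionary (the donor part of the truth).
    """
    rng = _rng(config, 1, rng)
    cat_rows = []
    donor_rows = []
    tracts_by_chrom: dict[str, list] = {}
    for chrom in config.chromosomes:
        n = config.sites_per_chromosome
        pos = np.sort(rng.choice(_CHROM_SPAN, size=n, replace=False)) + 1
        a_idx = rng.integers(0, 4, size=n)
        b_off = rng.integers(1, 4, size=n)
        allele_a = _BASES[a_idx]
        allele_b = _BASES[(a_idx + b_off) % 4]
        tracts = _place_loh_tracts(rng, n, config.donor_loh_fraction)
        tracts_by_chrom[chrom] = tracts
        donor_call = np.full(n, HET, dtype=object)
        for start, stop, strain in tracts:
            donor_call[start:stop] = HOM_A if strain == STRAIN_A else HOM_B
        for i in range(n):
            cat_rows.append((chrom, int(pos[i]), allele_a[i], allele_b[i]))
            donor_rows.append((chrom, int(pos[i]), donor_call[i]))
    catalog = SNPCatalog.from_frame(
        pd.DataFrame(cat_rows, columns=["chrom", "pos", "allele_A", "allele_B"]),
        meta={"synthetic": True, "seed": config.seed},
    )
    donor = DonorZygosityMap(
        pd.DataFrame(donor_rows, columns=["chrom", "pos", "donor_call"])
    )
    return catalog, donor, tracts_by_chrom


# ---------------------------------------------------------------------------
# Segregation truth
# ---------------------------------------------------------------------------

def simulate_haploidization(
    config: SimConfig,
    catalog: Optional[SNPCatalog] = None,
    donor: Optional[DonorZygosityMap] = None,
    donor_tracts: Optional[dict] = None,
    rng: Optional[np.random.Generator] = None,
) -> SimTruth:
    """Draw per-pair, per-chromosome segregation events.

    Each chromosome pair segregates reciprocally with probability
    1 - p_nondisjunction (the retained homolog uniform over A/B); a
    nondisjoined pair goes to the PPB with probability p_ndj_to_ppb, else both
    homologs stay in the embryo. Somatic copies in embryo + PPB always sum to 2.
    """
    rng = _rng(config, 2, rng)
    P = config.n_pairs
    chroms = config.chromosomes
    C = len(chroms)
    pair_ids = [f"pair{i:03d}" for i in range(P)]

    is_ndj = rng.random((P, C)) < config.p_nondisjunction
    to_ppb = rng.random((P, C)) < config.p_ndj_to_ppb
    retained = np.where(rng.random((P, C)) < 0.5, STRAIN_A, STRAIN_B)
    transmits_y = rng.random(P) < 0.5

    event = np.where(is_ndj, np.where(to_ppb, NDJ_PPB, NDJ_EMBRYO), PROPER)
    embryo_copies = np.select([event == PROPER, event == NDJ_EMBRYO], [1, 2], default=0)
    ppb_copies = 2 - embryo_copies
    retained_out = np.where(event == PROPER, retained, "")

    events = pd.DataFrame(
        {
            "pair_id": np.repeat(pair_ids, C),
            "chrom": np.tile(chroms, P),
            "event": event.ravel(),
            "retained_homolog": retained_out.ravel(),
            "embryo_somatic_copies": embryo_copies.ravel(),
            "ppb_copies": ppb_copies.ravel(),
        }
    )
    pairs = pd.DataFrame(
        {
            "pair_id": pair_ids,
            "sperm_transmits_y": transmits_y,
            "embryo_sex": np.where(transmits_y, MALE, FEMALE),
            "sperm_strain": config.sperm_strain,
        }
    )
    return SimTruth(config=config, pairs=pairs, events=events, donor_tracts=donor_tracts or {})


# ---------------------------------------------------------------------------
# Allele read counts
# ---------------------------------------------------------------------------

def _homolog_strain_alleles(n_sites: int, tracts) -> tuple[np.ndarray, np.ndarray]:
    """Strain allele carried by each homolog at each site ("A"/"B" labels):
    homolog A carries allele A (and B allele B) except inside an LOH tract,
    where both carry the tract strain."""
    hap_a = np.full(n_sites, STRAIN_A, dtype=object)
    hap_b = np.full(n_sites, STRAIN_B, dtype=object)
    for start, stop, strain in tracts or []:
        hap_a[start:stop] = strain
        hap_b[start:stop] = strain
    return hap_a, hap_b


def simulate_allele_counts(
    truth: SimTruth,
    catalog: SNPCatalog,
    config: Optional[SimConfig] = None,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Sample strain-allele read counts at every catalog site for every
    embryo, PPB and the donor sample.

    Per sample and chromosome the allele mixture follows the true chromosome
    content (the embryo includes the sperm allele; the PPB holds somatic
    content only). Each present allele class is independently lost with
    p_site_dropout, whole chromosomes fail to amplify with
    p_chrom_amp_failure, per-site depth is Poisson(mean_depth), and reads
    split binomially between the surviving alleles. The bulk donor sample is
    sequenced without WGA artifacts (no dropout, no chromosome failure).
    """
    config = config or truth.config
    rng = _rng(config, 3, rng)
    P = config.n_pairs
    pair_ids = truth.pairs["pair_id"].tolist()
    female = ~truth.pairs["sperm_transmits_y"].to_numpy()
    sperm = config.sperm_strain

    ev = truth.events.set_index(["pair_id", "chrom"])
    frames = []
    for chrom in config.chromosomes:
        sub = ev.xs(chrom, level="chrom").loc[pair_ids]
        event = sub["event"].to_numpy()
        retained = sub["retained_homolog"].to_numpy()

        sites = catalog.sites_for(chrom)
        S = len(sites)
        pos = sites["pos"].to_numpy()
        hap_a, hap_b = _homolog_strain_alleles(S, truth.donor_tracts.get(chrom))
        a_is_A = (hap_a == STRAIN_A).astype(np.int64)  # homolog A carries allele A here
        b_is_A = (hap_b == STRAIN_A).astype(np.int64)

        e_has_a = ((event == PROPER) & (retained == STRAIN_A)) | (event == NDJ_EMBRYO)
        e_has_b = ((event == PROPER) & (retained == STRAIN_B)) | (event == NDJ_EMBRYO)
        p_has_a = ((event == PROPER) & (retained == STRAIN_B)) | (event == NDJ_PPB)
        p_has_b = ((event == PROPER) & (retained == STRAIN_A)) | (event == NDJ_PPB)

        if chrom == CHROM_X:
            sperm_copy = female.astype(np.int64)
        else:
            sperm_copy = np.ones(P, dtype=np.int64)

        def allele_copies(has_a, has_b, with_sperm):
            ca = np.outer(has_a.astype(np.int64), a_is_A) + np.outer(
                has_b.astype(np.int64), b_is_A
            )
            cb = np.outer(has_a.astype(np.int64), 1 - a_is_A) + np.outer(
                has_b.astype(np.int64), 1 - b_is_A
            )
            if with_sperm:
                if sperm == STRAIN_A:
                    ca = ca + sperm_copy[:, None]
                else:
                    cb = cb + sperm_copy[:, None]
            return ca, cb

        for prefix, (ca, cb) in (
            ("embryo", allele_copies(e_has_a, e_has_b, with_sperm=True)),
            ("ppb", allele_copies(p_has_a, p_has_b, with_sperm=False)),
        ):
            drop_a = rng.random((P, S)) < config.p_site_dropout
            drop_b = rng.random((P, S)) < config.p_site_dropout
            sa = np.where(drop_a, 0, ca)
            sb = np.where(drop_b, 0, cb)
            fail = rng.random(P) < config.p_chrom_amp_failure
            depth = rng.poisson(config.mean_depth, size=(P, S))
            tot = sa + sb
            depth = np.where(fail[:, None] | (tot == 0), 0, depth)
            with np.errstate(invalid="ignore", divide="ignore"):
                frac_a = np.where(tot > 0, sa / np.maximum(tot, 1), 0.0)
            reads_a = rng.binomial(depth, frac_a)
            reads_b = depth - reads_a
            frames.append(
                pd.DataFrame(
                    {
                        "sample_id": np.repeat([f"{prefix}_{pid}" for pid in pair_ids], S),
                        "chrom": chrom,
                        "pos": np.tile(pos, P),
                        "reads_A": reads_a.ravel(),
                        "reads_B": reads_b.ravel(),
                    }
                )
            )

        # bulk donor: both homologs, no WGA artifacts
        dca = a_is_A + b_is_A
        dcb = (1 - a_is_A) + (1 - b_is_A)
        depth = rng.poisson(config.mean_depth, size=S)
        frac_a = dca / (dca + dcb)
        reads_a = rng.binomial(depth, frac_a)
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": "donor",
                    "chrom": chrom,
                    "pos": pos,
                    "reads_A": reads_a,
                    "reads_B": depth - reads_a,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    return out[["sample_id", "chrom", "pos", "reads_A", "reads_B"]]


# ---------------------------------------------------------------------------
# Chromosome-level read counts (CNV input)
# ---------------------------------------------------------------------------

def default_reference_profile(config: SimConfig, depth_per_chrom: float = 10_000.0) -> dict:
    """Expected diploid-male read counts per chromosome (X at half depth)."""
    return {
        c: (depth_per_chrom / 2.0 if c == CHROM_X else depth_per_chrom)
        for c in config.chromosomes
    }


def simulate_chrom_read_counts(
    truth: SimTruth,
    config: Optional[SimConfig] = None,
    reference_profile: Optional[Mapping[str, float]] = None,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Poisson per-chromosome read counts with mean proportional to the true
    copy number, scaled by a diploid-male reference profile."""
    config = config or truth.config
    rng = _rng(config, 4, rng)
    ref = dict(reference_profile or default_reference_profile(config))
    pair_ids = truth.pairs["pair_id"].tolist()
    female = dict(zip(pair_ids, ~truth.pairs["sperm_transmits_y"].to_numpy()))

    rows = []
    ev = truth.events
    for row in ev.itertuples(index=False):
        chrom = row.chrom
        ref_ploidy = 1 if chrom == CHROM_X else 2
        rate = ref[chrom] / ref_ploidy
        if chrom == CHROM_X:
            sperm_copy = 1 if female[row.pair_id] else 0
        else:
            sperm_copy = 1
        e_copy = row.embryo_somatic_copies + sperm_copy
        p_copy = row.ppb_copies
        rows.append((f"embryo_{row.pair_id}", chrom, e_copy * rate))
        rows.append((f"ppb_{row.pair_id}", chrom, p_copy * rate))
    df = pd.DataFrame(rows, columns=["sample_id", "chrom", "mean"])
    df["count"] = rng.poisson(df["mean"].to_numpy())
    return df[["sample_id", "chrom", "count"]]


def simulate_reference_counts(
    reference_profile: Mapping[str, float], rng: np.random.Generator
) -> dict[str, int]:
    """One Poisson realization of the diploid-male reference sample."""
    return {c: int(rng.poisson(lam)) for c, lam in reference_profile.items()}


# ---------------------------------------------------------------------------
# Bundles
# ---------------------------------------------------------------------------

def manifest_from_truth(truth: SimTruth) -> pd.DataFrame:
    """Pairing manifest (pair -> embryo/PPB/donor samples) plus the truth-level
    Y-marker flag that stands in for the PCR sex assay."""
    cfg = truth.config
    cross = f"{other_strain(cfg.sperm_strain)}/{cfg.sperm_strain}"
    return pd.DataFrame(
        {
            "pair_id": truth.pairs["pair_id"],
            "embryo_sample_id": "embryo_" + truth.pairs["pair_id"],
            "ppb_sample_id": "ppb_" + truth.pairs["pair_id"],
            "donor_sample_id": "donor",
            "sperm_strain": cfg.sperm_strain,
            "cross": cross,
            "y_marker_present": truth.pairs["sperm_transmits_y"],
        }
    )


def simulate_experiment(config: SimConfig):
    """Run the full generator: catalog + donor, truth, allele counts,
    chromosome counts, manifest. Returns a dict bundle."""
    catalog, donor, tracts = simulate_catalog_and_donor(config)
    truth = simulate_haploidization(config, catalog, donor, donor_tracts=tracts)
    counts = simulate_allele_counts(truth, catalog, config)
    ref_profile = default_reference_profile(config)
    chrom_counts = simulate_chrom_read_counts(truth, config, ref_profile)
    reference = simulate_reference_counts(ref_profile, _rng(config, 5, None))
    return {
        "config": config,
        "catalog": catalog,
        "donor": donor,
        "truth": truth,
        "allele_counts": counts,
        "chrom_counts": chrom_counts,
        "reference_profile": ref_profile,
        "reference_counts": reference,
        "manifest": manifest_from_truth(truth),
    }
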