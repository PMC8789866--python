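"""End-to-end pipeline: simulate (or load) -> genotype -> segregate -> cnv -> model."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .io import (
    DEFAULT_CHROMOSOMES,
    write_allele_counts_tsv,
    write_bed,
    write_calls_tsv,
    write_catalog_tsv,
    write_chrom_counts_tsv,
    write_manifest_tsv,
    write_report,
)
from .cnv import euploidy_screen, normalize, profiles_to_frame
from .model import estimate_ndj_rate, semicloning_probability
from .segregation import (
    DonorZygosityMap,
    MALE,
    chromosome_map_text,
    classifications_to_frame,
    classify_pairs_table,
    call_sex,
    classify_contribution,
    summarize,
    COMPLETE_SH,
)
from .snp_catalog import select_all_amplicons
from .synthetic_data import SimConfig, simulate_experiment
from .zygosity import CallingParams, call_table

logger = logging.getLogger("haplotrace")


@dataclass
class RunConfig:
    """Serializable configuration of one pipeline run."""

    sim: SimConfig = field(default_factory=SimConfig)
    calling: CallingParams = field(default_factory=CallingParams)
    donor_min_het_fraction: float = 0.3
    cnv_rounding_band: float = 0.25
    seed: int = 0
    out_dir: Optional[str] = None

    def to_dict(self) -> dict:
        return {
            "sim": asdict(self.sim),
            "calling": asdict(self.calling),
            "donor_min_het_fraction": self.donor_min_het_fraction,
            "cnv_rounding_band": self.cnv_rounding_band,
            "seed": self.seed,
            "out_dir": self.out_dir,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(
            sim=SimConfig(**d.get("sim", {})),
            calling=CallingParams(**d.get("calling", {})),
            donor_min_het_fraction=d.get("donor_min_het_fraction", 0.3),
            cnv_rounding_band=d.get("cnv_rounding_band", 0.25),
            seed=d.get("seed", 0),
            out_dir=d.get("out_dir"),
        )

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def donor_map_from_counts(
    counts: pd.DataFrame,
    donor_sample_id: str,
    params: CallingParams,
    min_het_fraction: float = 0.3,
) -> DonorZygosityMap:
    """Site-level donor zygosity from the donor sample's allele counts."""
    from .zygosity import call_site_genotype

    sub = counts[counts["sample_id"] == donor_sample_id]
    if sub.empty:
        raise ValueError(f"donor sample {donor_sample_id!r} absent from count table")
    site_calls = sub.apply(
        lambda r: call_site_genotype(
            int(r["reads_A"]), int(r["reads_B"]), params.min_site_depth, params.hom_fraction
        ),
        axis=1,
    )
    df = pd.DataFrame(
        {"chrom": sub["chrom"].values, "pos": sub["pos"].values, "site_call": site_calls.values}
    )
    return DonorZygosityMap.from_site_calls(df, min_het_fraction)


def filter_to_informative_sites(
    counts: pd.DataFrame,
    donor_map: DonorZygosityMap,
    donor_sample_ids: tuple[str, ...] = ("donor",),
) -> pd.DataFrame:
    """Restrict embryo/PPB allele counts to donor-heterozygous catalog sites.

    Only sites where the donor itself is heterozygous carry information about
    which homolog went where; sites inside donor LOH tracts show the tract
    strain on *both* homologs and would otherwise masquerade as discordant
    homozygous signal. Donor samples keep all their sites.
    """
    from .zygosity import HET as _HET

    het_sites = donor_map.zygosity.loc[
        donor_map.zygosity["donor_call"] == _HET, ["chrom", "pos"]
    ]
    keep_donor = counts["sample_id"].isin(donor_sample_ids)
    informative = counts.merge(het_sites, on=["chrom", "pos"], how="inner")
    return pd.concat([informative[~informative["sample_id"].isin(donor_sample_ids)],
                      counts[keep_donor]], ignore_index=True)


def run_pipeline(config: RunConfig, out_dir: Optional[str | Path] = None) -> dict:
    """Execute the simulated end-to-end analysis and return the report dict.

    When ``out_dir`` (or ``config.out_dir``) is given, all intermediate tables
    and the JSON report are written there. The run is fully determined by the
    configuration (single seed recorded in the report).
    """
    sim_cfg = config.sim
    bundle = simulate_experiment(sim_cfg)
    catalog = bundle["catalog"]
    counts = bundle["allele_counts"]
    manifest = bundle["manifest"]
    truth = bundle["truth"]

    # genotype: donor map first, then embryo/PPB calls at donor-HET sites only
    donor_map = donor_map_from_counts(
        counts, "donor", config.calling, config.donor_min_het_fraction
    )
    informative = filter_to_informative_sites(counts, donor_map)
    calls = call_table(informative, catalog, config.calling)

    # sex from the Y-marker flag, then pair classification
    by_sample = {
        sid: dict(zip(sub["chrom"], sub["call"])) for sid, sub in calls.groupby("sample_id")
    }
    sexes = {}
    for row in manifest.itertuples(index=False):
        x_call = by_sample.get(row.embryo_sample_id, {}).get("X")
        sex, _ = call_sex(x_call, bool(row.y_marker_present), row.sperm_strain)
        sexes[row.pair_id] = sex
    classifications = classify_pairs_table(
        calls,
        manifest,
        {"donor": donor_map},
        sexes=sexes,
        chromosomes=tuple(sim_cfg.chromosomes),
    )

    contributions = {}
    for row in manifest.itertuples(index=False):
        contributions[row.pair_id] = classify_contribution(
            by_sample.get(row.embryo_sample_id, {}),
            row.sperm_strain,
            embryo_is_male=(sexes[row.pair_id] == MALE),
            chromosomes=tuple(sim_cfg.chromosomes),
        )
    n_complete = sum(1 for c in contributions.values() if c.category == COMPLETE_SH)

    summary = summarize(
        classifications,
        n_chromosomes_assayed=sim_cfg.n_chromosomes,
        sexes=sexes,
        n_complete_sh=n_complete,
    )

    # CNV
    profiles = [
        normalize(
            dict(zip(sub["chrom"], sub["count"])),
            bundle["reference_counts"],
            sample_id=str(sid),
        )
        for sid, sub in bundle["chrom_counts"].groupby("sample_id")
        if str(sid).startswith("embryo_")
    ]
    verdicts, n_euploid = euploidy_screen(profiles, rounding_band=config.cnv_rounding_band)

    # analytic layer
    ndj = estimate_ndj_rate(summary)
    report = {
        "haplotrace_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "segregation_summary": summary.to_dict(),
        "ndj_rate_estimate": {
            "p_hat": ndj.p_hat,
            "ci_low": ndj.ci_low,
            "ci_high": ndj.ci_high,
            "n_proper": ndj.n_proper,
            "n_classified": ndj.n_classified,
        },
        "semicloning_probability_20_pairs": semicloning_probability(20),
        "cnv": {"euploid_verdicts": verdicts, "n_euploid": n_euploid},
        "contribution_categories": {k: v.category for k, v in contributions.items()},
        "truth_event_counts": truth.events["event"].value_counts().to_dict(),
    }

    out = Path(out_dir or config.out_dir) if (out_dir or config.out_dir) else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        write_catalog_tsv(catalog.to_frame(), out / "catalog.tsv")
        amplicons = [a for a in select_all_amplicons(catalog, catalog.chromosomes).values() if a]
        write_bed(amplicons, out / "amplicons.bed")
        write_allele_counts_tsv(counts, out / "allele_counts.tsv")
        write_chrom_counts_tsv(bundle["chrom_counts"], out / "chrom_counts.tsv")
        write_manifest_tsv(manifest, out / "manifest.tsv")
        write_calls_tsv(calls, out / "chromosome_calls.tsv")
        classifications_to_frame(classifications).to_csv(
            out / "classifications.tsv", sep="\t", index=False
        )
        (out / "chromosome_map.txt").write_text(chromosome_map_text(classifications))
        profiles_to_frame(profiles).to_csv(out / "cnv_profiles.tsv", sep="\t", index=False)
        truth.to_json(out / "truth.json")
        write_report(report, out / "report.json")
        logger.info("pipeline outputs written to %s", out)
    return report
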