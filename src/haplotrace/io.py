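"""File input/output for the haplotrace pipeline.

All tabular interchange is plain TSV; amplicon regions are exported as BED
(0-based, half-open); run reports and cohort summaries are JSON. VCF input is
parsed with pysam. Chromosome names are normalized to ``{"1".."19","X","Y"}``
with tolerant handling of ``chr`` prefixes.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import pysam

logger = logging.getLogger("haplotrace")

AUTOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 20))
CHROM_X = "X"
CHROM_Y = "Y"
#: the 20 chromosomes assayed in the cross design: 19 autosomes + X
DEFAULT_CHROMOSOMES: tuple[str, ...] = AUTOSOMES + (CHROM_X,)

ALLELE_COUNT_COLUMNS = ["sample_id", "chrom", "pos", "reads_A", "reads_B"]
CHROM_COUNT_COLUMNS = ["sample_id", "chrom", "count"]
MANIFEST_COLUMNS = [
    "pair_id",
    "embryo_sample_id",
    "ppb_sample_id",
    "donor_sample_id",
    "sperm_strain",
    "cross",
]

REPORT_SCHEMA_VERSION = "1.0"


def normalize_chrom(name: str) -> str:
    """Normalize a chromosome name ("chr1", "CHRX", "x" ...) to "1".."19"/"X"/"Y"."""
    s = str(name).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    if s.upper() in ("X", "Y"):
        return s.upper()
    return s


def chrom_sort_key(chrom: str) -> tuple[int, str]:
    try:
        return (int(chrom), "")
    except ValueError:
        return (100 + ord(chrom[0]), chrom)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_strain_variants(path: str | Path) -> pd.DataFrame:
    """Read homozygous SNP calls for one inbred strain from a VCF.

    Returns a frame with columns ``chrom, pos, allele, depth, qual`` holding one
    row per confidently parsable homozygous biallelic SNP record. Multiallelic
    records, indels and heterozygous/missing genotypes are skipped (counts
    logged). ``depth`` is taken from FORMAT/DP when present, else INFO/DP, else
    NaN; ``qual`` is the record QUAL (NaN if missing).

    Malformed records raise ``ValueError`` naming the offending position.
    """
    path = Path(path)
    rows = []
    n_multi = n_indel = n_nonhom = 0
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            alts = rec.alts or ()
            if len(alts) > 1:
                n_multi += 1
                continue
            alleles = (rec.ref,) + tuple(alts)
            if any(a is None or len(a) != 1 or a not in "ACGT" for a in alleles):
                n_indel += 1
                continue
            if samples:
                gt = rec.samples[samples[0]].get("GT")
                if gt is None or any(g is None for g in gt) or len(set(gt)) != 1:
                    n_nonhom += 1
                    continue
                allele = alleles[gt[0]]
                depth = rec.samples[samples[0]].get("DP")
            else:
                # sites-only VCF: treat the ALT (or REF if no ALT) as the call
                allele = alts[0] if alts else rec.ref
                depth = None
            if depth is None:
                depth = rec.info.get("DP")
            rows.append(
                (
                    normalize_chrom(rec.chrom),
                    int(rec.pos),
                    allele,
                    float(depth) if depth is not None else float("nan"),
                    float(rec.qual) if rec.qual is not None else float("nan"),
                )
            )
    if n_multi or n_indel or n_nonhom:
        logger.info(
            "%s: skipped %d multiallelic, %d indel/non-SNP, %d non-homozygous records",
            path.name,
            n_multi,
            n_indel,
            n_nonhom,
        )
    return pd.DataFrame(rows, columns=["chrom", "pos", "allele", "depth", "qual"])


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def write_catalog_tsv(catalog_frame: pd.DataFrame, path: str | Path) -> None:
    catalog_frame.to_csv(path, sep="\t", index=False)


def read_catalog_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    expected = {"chrom", "pos", "allele_A", "allele_B"}
    missing = expected - set(df.columns)
    if missing:
        raise ValueError(f"catalog TSV {path} lacks columns: {sorted(missing)}")
    df["chrom"] = df["chrom"].map(normalize_chrom)
    return df


def write_allele_counts_tsv(counts: pd.DataFrame, path: str | Path) -> None:
    counts.loc[:, ALLELE_COUNT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_allele_counts_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample_id": str})
    missing = set(ALLELE_COUNT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"allele-count TSV {path} lacks columns: {sorted(missing)}")
    df["chrom"] = df["chrom"].map(normalize_chrom)
    if (df[["reads_A", "reads_B"]] < 0).any().any():
        raise ValueError(f"negative read counts in {path}")
    return df


def write_chrom_counts_tsv(counts: pd.DataFrame, path: str | Path) -> None:
    counts.loc[:, CHROM_COUNT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_chrom_counts_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample_id": str})
    missing = set(CHROM_COUNT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"chromosome-count TSV {path} lacks columns: {sorted(missing)}")
    df["chrom"] = df["chrom"].map(normalize_chrom)
    return df


def write_calls_tsv(calls: pd.DataFrame, path: str | Path) -> None:
    calls.to_csv(path, sep="\t", index=False)


def read_calls_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample_id": str})
    missing = {"sample_id", "chrom", "call"} - set(df.columns)
    if missing:
        raise ValueError(f"calls TSV {path} lacks columns: {sorted(missing)}")
    df["chrom"] = df["chrom"].map(normalize_chrom)
    return df


def write_manifest_tsv(manifest: pd.DataFrame, path: str | Path) -> None:
    manifest.to_csv(path, sep="\t", index=False)


def read_manifest_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(MANIFEST_COLUMNS[:5]) - set(df.columns)
    if missing:
        raise ValueError(f"pairing manifest {path} lacks columns: {sorted(missing)}")
    if df["pair_id"].duplicated().any():
        dup = df.loc[df["pair_id"].duplicated(), "pair_id"].iloc[0]
        raise ValueError(f"duplicate pair_id in manifest: {dup}")
    return df


# ---------------------------------------------------------------------------
# BED / JSON
# ---------------------------------------------------------------------------

def write_bed(regions: Iterable, path: str | Path) -> None:
    """Write regions with 1-based inclusive ``start``/``end`` as 0-based half-open BED."""
    with open(path, "w") as fh:
        for reg in regions:
            name = f"amplicon_chr{reg.chrom}"
            fh.write(f"{reg.chrom}\t{reg.start - 1}\t{reg.end}\t{name}\t{reg.n_sites}\n")


def read_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start0", "end0", "name", "score"],
        dtype={"chrom": str},
    )
    df["start"] = df["start0"] + 1  # back to 1-based inclusive
    df["end"] = df["end0"]
    return df[["chrom", "start", "end", "name", "score"]]


def write_report(report: Mapping, path: str | Path) -> None:
    payload = {"schema_version": REPORT_SCHEMA_VERSION}
    payload.update(report)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def read_report(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _json_default(obj):
    import numpy as np

    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)!r}")
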