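from __future__ import annotations

from pathlib import Path

import pandas as pd
import pytest

from haplotrace import SimConfig, simulate_experiment


def write_vcf(path: Path, records, sample: str = "S1", contigs=("1", "2")):
    """Write a minimal single-sample VCF.

    ``records``: iterables of (chrom, pos, ref, alt, qual, gt, dp); ``alt`` may
    be a comma-joined string for multiallelic records.
    """
    header = "##fileformat=VCFv4.2\n"
    for c in contigs:
        header += f"##contig=<ID={c}>\n"
    header += (
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Depth">\n'
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n'
        f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n"
    )
    lines = [header]
    for chrom, pos, ref, alt, qual, gt, dp in records:
        lines.append(
            f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t{qual}\t.\t.\tGT:DP\t{gt}:{dp}\n"
        )
    path.write_text("".join(lines))
    return path


@pytest.fixture
def variant_frames():
    """Toy variant frames: 5 shared positions -> exactly 3 discriminating sites."""
    a = pd.DataFrame(
        {
            "chrom": ["1"] * 5,
            "pos": [100, 200, 300, 400, 500],
            "allele": ["A", "C", "G", "T", "A"],
            "depth": [50.0] * 5,
            "qual": [99.0] * 5,
        }
    )
    # pos 400: same allele in both strains; pos 500 missing from B
    b = pd.DataFrame(
        {
            "chrom": ["1"] * 4,
            "pos": [100, 200, 300, 400],
            "allele": ["G", "T", "A", "T"],
            "depth": [50.0] * 4,
            "qual": [99.0] * 4,
        }
    )
    return a, b


@pytest.fixture(scope="session")
def noiseless_config():
    return SimConfig(
        n_pairs=40,
        sites_per_chromosome=12,
        p_site_dropout=0.0,
        p_chrom_amp_failure=0.0,
        donor_loh_fraction=0.0,
        mean_depth=200.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def noiseless_bundle(noiseless_config):
    return simulate_experiment(noiseless_config)


@pytest.fixture(scope="session")
def small_bundle():
    """Small noisy bundle at the defaults' regime for smoke tests."""
    return simulate_experiment(SimConfig(n_pairs=6, sites_per_chromosome=10, seed=3))
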