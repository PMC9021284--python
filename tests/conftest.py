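from pathlib import Path

import pytest

from ffpeconcord.simulate import SimConfig, make_study_fixture, simulate_pair


@pytest.fixture(scope="session")
def small_pair():
    """One simulated patient pair at moderate size, shared across tests."""
    config = SimConfig(seed=11, n_true_variants=4000)
    return simulate_pair(config, "P1")


@pytest.fixture(scope="session")
def study_dir(tmp_path_factory) -> Path:
    """A small study-shaped fixture directory with VCFs and a sample sheet."""
    out = tmp_path_factory.mktemp("study")
    make_study_fixture(
        out, base_config=SimConfig(seed=7, n_true_variants=1200, n_patients=2)
    )
    return out


def write_vcf_text(path: Path, records: list[str], samples: list[str] = ["S1"]) -> Path:
    """Write a minimal VCF from raw record lines (tab-joined field strings)."""
    header = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=PL,Number=G,Type=Integer,Description="PL">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="GQ">',
        "##contig=<ID=chr1,length=1000000>",
        "##contig=<ID=chr2,length=1000000>",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    path.write_text("\n".join(header + records) + "\n")
    return path
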