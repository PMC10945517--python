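import numpy as np
import pandas as pd
import pytest

from seedling_qtl.filtering import SAMPLE_ROLES


def make_marker_table(n: int, seed: int = 0, chrom: str = "chr1",
                      depth: int = 100) -> pd.DataFrame:
    """Random biallelic marker table with segregating parents."""
    rng = np.random.default_rng(seed)
    alt_h = rng.binomial(depth, 0.5, n)
    alt_l = rng.binomial(depth, 0.5, n)
    df = pd.DataFrame({
        "chrom": chrom,
        "pos": np.arange(1, n + 1) * 1000,
        "ref": "A", "alt": "G", "multiallelic": False,
        "alt_bulk_high": alt_h, "ref_bulk_high": depth - alt_h,
        "alt_bulk_low": alt_l, "ref_bulk_low": depth - alt_l,
        "ref_parent_low": depth, "alt_parent_low": 0,
        "ref_parent_high": 0, "alt_parent_high": depth,
    })
    return df


def write_vcf_text(path, body_rows, samples=SAMPLE_ROLES, fmt="AD"):
    """Write a minimal VCF from raw body row strings (for parser edge cases)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="AD">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n')
        fh.write("##contig=<ID=chr1>\n##contig=<ID=chr2>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for row in body_rows:
            fh.write(row + "\n")
    return path


@pytest.fixture
def marker_table():
    return make_marker_table(200, seed=42)
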