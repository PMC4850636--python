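import numpy as np
import pytest

from strainmap.panel_io import GenotypeMatrix, StrainPanel

TSV_HEADER = "chrom\tpos\tid\tref\talt"


@pytest.fixture
def tiny_tsv(tmp_path):
    """3 strains x 2 sites, deliberately written out of order."""
    path = tmp_path / "geno.tsv"
    path.write_text(
        f"{TSV_HEADER}\tA\tB\tC\n"
        "chr1\t200\ts2\tA\tG\t1\t0\t.\n"
        "chr1\t100\ts1\tC\tT\t0\t1\t1\n"
    )
    return path


@pytest.fixture
def tiny_vcf(tmp_path):
    path = tmp_path / "geno.vcf"
    path.write_text(
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "##contig=<ID=chr1>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\tB\tC\n"
        "chr1\t100\ts1\tC\tT\t.\t.\t.\tGT\t0/0\t1/1\t1/1\n"
        "chr1\t200\ts2\tA\tG\t.\t.\t.\tGT\t1/1\t0/0\t./.\n"
    )
    return path


@pytest.fixture
def small_phenotypes_csv(tmp_path):
    strains = [f"S{i:03d}" for i in range(1, 24)]
    traits = ["t1", "t2", "t3", "t4", "t5", "t6"]
    rng = np.random.default_rng(7)
    lines = ["strain," + ",".join(traits)]
    for s in strains:
        lines.append(s + "," + ",".join(f"{v:.4f}" for v in rng.normal(size=6)))
    path = tmp_path / "pheno.csv"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def bed_file(tmp_path):
    path = tmp_path / "genes.bed"
    path.write_text("chr4\t100\t200\tMpdz\n")
    return path


def make_matrix(calls_by_strain, chrom="chr1", start_pos=100, spacing=100):
    """GenotypeMatrix from per-strain call strings like {'A': '010', ...}."""
    strains = tuple(calls_by_strain)
    n_sites = len(next(iter(calls_by_strain.values())))
    calls = np.array(
        [
            [(-1 if c == "." else int(c)) for c in calls_by_strain[s]]
            for s in strains
        ],
        dtype=np.int8,
    )
    pos = [start_pos + spacing * j for j in range(n_sites)]
    return GenotypeMatrix.from_arrays(
        StrainPanel(strains),
        [chrom] * n_sites,
        pos,
        [f"s{j}" for j in range(n_sites)],
        ["A"] * n_sites,
        ["G"] * n_sites,
        calls,
    )
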