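import pandas as pd
import pytest

from imprintseq import ModelParams, SnpRecord


@pytest.fixture
def params() -> ModelParams:
    return ModelParams()


@pytest.fixture
def snp() -> SnpRecord:
    return SnpRecord(
        rs_id="rs1", chrom="chr1", position=100, strand="+",
        allele_x="A", allele_y="G", freq_x=0.5,
    )


@pytest.fixture
def snp_table(tmp_path):
    """A small SNP reference TSV on disk."""
    path = tmp_path / "snps.tsv"
    rows = [
        "rs_id\tchrom\tposition\tstrand\tallele_x\tallele_y\tfreq_x",
        "rs1\tchr1\t100\t+\tA\tG\t0.5",
        "rs2\tchr1\t250\t-\tA\tG\t0.3",
        "rs3\tchr2\t75\t+\tC\tT\t0.9",
    ]
    path.write_text("\n".join(rows) + "\n")
    return path


def make_counts_frame(rows):
    """rows: iterable of (sample_id, rs_id, x, y, other)."""
    return pd.DataFrame(
        rows, columns=["sample_id", "rs_id", "count_x", "count_y", "count_other"]
    )
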