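import numpy as np
import pandas as pd
import pytest

from polyatails.io import POLYA_COLUMNS


def make_polya_file(path, rows):
    """Write a Nanopolish polya TSV from (readname, contig, polya_length, qc_tag) tuples."""
    lines = ["\t".join(POLYA_COLUMNS)]
    for readname, contig, length, qc in rows:
        lines.append(
            "\t".join(
                [readname, contig, "0", "10.0", "20.0", "30.0", "40.0", "80.0", str(length), qc]
            )
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def make_records(transcripts_and_tails, sample_id="s1", qc_tag="PASS"):
    """In-memory read-record frame from (transcript_id, tail) pairs."""
    rows = list(transcripts_and_tails)
    return pd.DataFrame(
        {
            "read_id": [f"r{i}" for i in range(len(rows))],
            "transcript_id": [t for t, _ in rows],
            "position": 0,
            "polya_length": [float(x) for _, x in rows],
            "qc_tag": qc_tag,
            "sample_id": sample_id,
        }
    )


def make_normalized(entries):
    """Normalized-summary frame from
    (transcript_id, norm_count, log2_abundance, mean_tail, bin, placeholder) tuples."""
    return pd.DataFrame(
        {
            "transcript_id": [e[0] for e in entries],
            "n_reads": 100,
            "raw_count": 100,
            "norm_count": [float(e[1]) for e in entries],
            "log2_abundance": [float(e[2]) for e in entries],
            "mean_tail": [float(e[3]) for e in entries],
            "bin": [e[4] for e in entries],
            "placeholder_flag": [bool(e[5]) for e in entries],
        }
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
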