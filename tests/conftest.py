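import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def write_stats(tmp_path):
    """Write a summary-stats TSV from a list of row dicts; returns the path."""

    def _write(rows, name="stats.tsv", header=("SNP", "CHR", "BP", "BETA", "P", "MAF")):
        path = tmp_path / name
        df = pd.DataFrame(rows)
        df.to_csv(path, sep="\t", index=False, columns=list(header))
        return path

    return _write


def make_stats_rows(n, seed=0, chrom="1"):
    rng = np.random.default_rng(seed)
    return [
        {
            "SNP": f"rs{i}",
            "CHR": chrom,
            "BP": 1000 * (i + 1),
            "BETA": round(float(rng.normal()), 4),
            "P": round(float(rng.uniform(1e-6, 1)), 6),
            "MAF": round(float(rng.uniform(0.01, 0.5)), 4),
        }
        for i in range(n)
    ]
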