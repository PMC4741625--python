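import numpy as np
import pandas as pd
import pytest

from mycnet.expression import ExpressionMatrix


@pytest.fixture
def toy_expression(tmp_path):
    """3-gene x 4-sample TSV trio on disk plus the expected in-memory matrix."""
    genes = ["gA", "gB", "gC"]
    samples = ["s1", "s2", "s3", "s4"]
    signals = pd.DataFrame(
        [[100.0, 110, 300, 310], [50, 55, 52, 51], [10, 12, 9, 11]],
        index=genes, columns=samples, dtype=float,
    )
    calls = pd.DataFrame([["P"] * 4] * 3, index=genes, columns=samples)
    groups = {"s1": "control", "s2": "control", "s3": "case", "s4": "case"}

    signals.to_csv(tmp_path / "signals.tsv", sep="\t")
    calls.to_csv(tmp_path / "calls.tsv", sep="\t")
    with open(tmp_path / "groups.tsv", "w") as fh:
        for s, g in groups.items():
            fh.write(f"{s}\t{g}\n")
    return tmp_path, ExpressionMatrix(signals=signals, detection_calls=calls, groups=groups)


def make_expression(signal_rows, groups_per_sample, gene_ids=None):
    """Build an ExpressionMatrix from raw rows (all calls Present)."""
    arr = np.asarray(signal_rows, dtype=float)
    genes = gene_ids or [f"g{i}" for i in range(arr.shape[0])]
    samples = [f"s{i}" for i in range(arr.shape[1])]
    signals = pd.DataFrame(arr, index=genes, columns=samples)
    calls = pd.DataFrame([["P"] * arr.shape[1]] * arr.shape[0], index=genes, columns=samples)
    groups = dict(zip(samples, groups_per_sample))
    return ExpressionMatrix(signals=signals, detection_calls=calls, groups=groups)
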