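import numpy as np
import pandas as pd
import pytest

from lncnet import simulate as sim


def make_pair_table(rows):
    """Build a ceRNA pair table from (lnc, tf, significant[, pcc]) tuples."""
    records = []
    for row in rows:
        lnc, tf, significant = row[:3]
        pcc = row[3] if len(row) > 3 else 0.8
        records.append((lnc, tf, 5, 0.001, pcc, 1e-6, 0.01, significant))
    return pd.DataFrame(records, columns=[
        "lnc_id", "tf_id", "r_shared", "hyper_p", "pcc", "pcc_p", "bh_q",
        "significant"])


@pytest.fixture
def planted_cerna_universe():
    """Small interaction + expression universe with three planted pairs."""
    rng = np.random.default_rng(42)
    lncs = [f"LNC{i + 1:03d}" for i in range(20)]
    tfs = [f"TF{i + 1:03d}" for i in range(10)]
    planted = [("LNC001", "TF001"), ("LNC002", "TF002"), ("LNC003", "TF003")]
    iset, _ = sim.simulate_interactions(
        n_mirna=300, n_lnc=20, n_tf=10, base_rate=0.02, overlap_boost=10,
        planted=planted, seed=7)
    expr, _ = sim.simulate_expression(
        lncs + tfs, [(l, t, 0.9) for l, t in planted], n_samples=300, seed=8)
    return iset, expr, planted
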