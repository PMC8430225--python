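"""lncRNA-m6A regulator co-expression network and immune-infiltration links.

m6A (N6-methyladenosine) writer/eraser/reader proteins can bind lncRNAs and
drive their expression, so strongly co-expressed lncRNA-regulator pairs are
candidate regulatory links.  The network keeps pairs whose Pearson
correlation passes a cutoff of 0.6 — by default in absolute value, so
strong negative co-expression also forms an edge; a signed mode keeps only
positive pairs.  "Key genes" are nodes of the resulting bipartite network
with degree above a threshold.

The immune readout correlates each lncRNA's expression with per-sample
immune cell infiltration estimation scores (one row per lncRNA x cell
type, with a Benjamini-Hochberg q over the whole grid), and can stratify
patients into cell-type-enriched vs other at the mean infiltration score to
feed the survival comparison.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cerna import validate_expression
from .errors import ValidationError
from .survival import stratify_by_mean
from .topology import add_typed_edge, add_typed_node, new_network

logger = logging.getLogger(__name__)

CORRELATION_MODES = ("signed", "absolute")
CORRELATION_METHODS = ("pearson", "spearman")


def validate_infiltration(infil: pd.DataFrame) -> pd.DataFrame:
    """Infiltration matrix: samples x cell types, no missing cells."""
    if infil.index.has_duplicates or infil.columns.has_duplicates:
        raise ValidationError("duplicate sample ids or cell types")
    if infil.isna().any().any():
        raise ValidationError("infiltration matrix contains missing cells")
    return infil


def correlation_network(expr_a: pd.DataFrame, expr_b: pd.DataFrame,
                        cutoff: float = 0.6, mode: str = "absolute",
                        type_a: str = "lncRNA", type_b: str = "m6A"):
    """Bipartite co-expression network between two gene sets.

    Both matrices must share identically ordered samples.  An edge joins
    (a, b) iff ``pcc > cutoff`` (signed mode) or ``|pcc| > cutoff``
    (absolute mode, the default); edges carry the correlation as ``pcc``.
    """
    if mode not in CORRELATION_MODES:
        raise ValidationError(f"mode must be one of {CORRELATION_MODES}")
    validate_expression(expr_a)
    validate_expression(expr_b)
    if list(expr_a.columns) != list(expr_b.columns):
        raise ValidationError("sample sets/order differ between the matrices")
    s = expr_a.shape[1]
    if s < 3:
        raise ValidationError("need >= 3 shared samples")
    az = expr_a.values - expr_a.values.mean(axis=1, keepdims=True)
    bz = expr_b.values - expr_b.values.mean(axis=1, keepdims=True)
    anorm = np.linalg.norm(az, axis=1, keepdims=True)
    bnorm = np.linalg.norm(bz, axis=1, keepdims=True)
    ok_a = anorm[:, 0] > 0
    ok_b = bnorm[:, 0] > 0
    if not ok_a.all() or not ok_b.all():
        logger.info("excluded %d constant genes from correlation network",
                    int((~ok_a).sum() + (~ok_b).sum()))
    az = np.divide(az, anorm, out=np.zeros_like(az), where=anorm > 0)
    bz = np.divide(bz, bnorm, out=np.zeros_like(bz), where=bnorm > 0)
    pcc = np.clip(az @ bz.T, -1.0, 1.0)
    g = new_network()
    a_ids = list(expr_a.index)
    b_ids = list(expr_b.index)
    for i, a in enumerate(a_ids):
        if not ok_a[i]:
            continue
        for j, b in enumerate(b_ids):
            if not ok_b[j]:
                continue
            r = float(pcc[i, j])
            passes = r > cutoff if mode == "signed" else abs(r) > cutoff
            if passes:
                add_typed_node(g, a, type_a)
                add_typed_node(g, b, type_b)
                add_typed_edge(g, a, b, "coexpr", pcc=r)
    return g


def key_genes(network, min_degree_exclusive: int = 2) -> list:
    """Genes with degree strictly greater than the threshold, sorted by
    degree descending then id."""
    if min_degree_exclusive < 0:
        raise ValidationError("min_degree_exclusive must be >= 0")
    ranked = [(node, deg) for node, deg in network.degree()
              if deg > min_degree_exclusive]
    ranked.sort(key=lambda nd: (-nd[1], str(nd[0])))
    return [node for node, _ in ranked]


def immune_correlation(lnc_expr: pd.DataFrame, infil: pd.DataFrame,
                       method: str = "pearson") -> pd.DataFrame:
    """Correlate each lncRNA with each immune cell type across samples.

    Returns one row per (lncRNA, cell type) with ``r``, ``p``, ``bh_q`` and
    an ``r_defined`` flag (False when either profile is constant, in which
    case ``r``/``p`` are NaN and the row is excluded from the BH grid).
    """
    if method not in CORRELATION_METHODS:
        raise ValidationError(f"method must be one of {CORRELATION_METHODS}")
    validate_expression(lnc_expr)
    validate_infiltration(infil)
    samples = [s for s in lnc_expr.columns if s in infil.index]
    if len(samples) < 3:
        raise ValidationError("fewer than 3 shared samples")
    expr = lnc_expr[samples]
    scores = infil.loc[samples]
    rows = []
    for lnc in expr.index:
        x = expr.loc[lnc].values.astype(float)
        for cell in scores.columns:
            y = scores[cell].values.astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                rows.append((lnc, cell, np.nan, np.nan, False))
                continue
            if method == "pearson":
                res = stats.pearsonr(x, y)
            else:
                res = stats.spearmanr(x, y)
            rows.append((lnc, cell, float(res.statistic), float(res.pvalue), True))
    table = pd.DataFrame(rows, columns=["lnc_id", "cell_type", "r", "p", "r_defined"])
    table["bh_q"] = np.nan
    defined = table["r_defined"].values
    if defined.any():
        table.loc[defined, "bh_q"] = multipletests(
            table.loc[defined, "p"].values, method="fdr_bh")[1]
    return table


def stratify_by_infiltration(infil: pd.DataFrame, cell_type: str) -> pd.Series:
    """Mean-split on one cell type's infiltration scores: "enriched" iff
    strictly above the mean, "other" otherwise."""
    validate_infiltration(infil)
    if cell_type not in infil.columns:
        raise ValidationError(f"cell type {cell_type!r} not in infiltration matrix")
    labels = stratify_by_mean(infil[cell_type])
    return labels.map({"high": "enriched", "low": "other"}).rename("group")
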