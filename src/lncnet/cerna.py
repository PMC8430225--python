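"""ceRNA pair inference: shared-miRNA hypergeometric test plus co-expression.

Long non-coding RNAs and transcription-factor mRNAs that are targeted by the
same miRNAs can act as competing endogenous RNAs (ceRNAs): sequestering a
shared miRNA pool couples their expression.  A candidate lncRNA-TF pair is
called significant when

* the overlap of their miRNA target sets is larger than expected by chance
  under a hypergeometric null (upper-tail p below ``hyper_p_cutoff``), and
* their expression profiles are positively correlated across tumour samples
  (signed Pearson r > ``pcc_cutoff`` with two-sided p < ``pcc_p_cutoff``).

With ``m`` miRNAs in the study, ``n`` of them targeting the lncRNA, ``t``
targeting the TF and ``r`` targeting both, the enrichment p-value is the
hypergeometric upper tail

    p = 1 - sum_{i=0}^{r-1} C(t, i) C(m-t, n-i) / C(m, n) = P(X >= r).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .config import RunConfig
from .errors import DegenerateDataError, ValidationError

logger = logging.getLogger(__name__)

GENE_CLASSES = ("lncRNA", "TF")

PAIR_TABLE_COLUMNS = [
    "lnc_id", "tf_id", "r_shared", "hyper_p", "pcc", "pcc_p", "bh_q", "significant",
]


@dataclass(frozen=True)
class CorrelationResult:
    """Sample Pearson correlation with its exact t-test p-value."""

    r: float
    p: float
    n_obs: int


@dataclass
class InteractionSet:
    """Bipartite miRNA -> target membership for lncRNAs and TFs.

    ``mirna_ids`` is the miRNA universe of the study (the ``m`` of the
    hypergeometric test); ``targets_of`` maps each gene to the subset of
    miRNAs predicted to target it; ``gene_class`` labels each gene as
    ``"lncRNA"`` or ``"TF"``.
    """

    mirna_ids: frozenset = field(default_factory=frozenset)
    targets_of: dict = field(default_factory=dict)
    gene_class: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for gene, mirnas in self.targets_of.items():
            extra = set(mirnas) - set(self.mirna_ids)
            if extra:
                raise ValidationError(
                    f"gene {gene!r} targets miRNAs outside the universe: "
                    f"{sorted(extra)[:5]}")
            if gene not in self.gene_class:
                raise ValidationError(f"gene {gene!r} has no class label")
        bad = {g: c for g, c in self.gene_class.items() if c not in GENE_CLASSES}
        if bad:
            raise ValidationError(f"unknown gene classes: {bad}")

    @property
    def m(self) -> int:
        """Size of the miRNA universe."""
        return len(self.mirna_ids)

    def genes_of_class(self, cls: str) -> list:
        return sorted(g for g, c in self.gene_class.items() if c == cls)

    @property
    def lncrnas(self) -> list:
        return self.genes_of_class("lncRNA")

    @property
    def tfs(self) -> list:
        return self.genes_of_class("TF")


def validate_expression(expr: pd.DataFrame) -> pd.DataFrame:
    """Check the expression-matrix invariants (genes x samples, unique ids,
    no missing cells) and return the frame unchanged."""
    if expr.index.has_duplicates:
        dupes = expr.index[expr.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate gene ids: {dupes[:5]}")
    if expr.columns.has_duplicates:
        dupes = expr.columns[expr.columns.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate sample ids: {dupes[:5]}")
    if expr.isna().any().any():
        raise ValidationError("expression matrix contains missing cells")
    return expr


def filter_expression(expr: pd.DataFrame, max_zero_fraction: float = 0.7) -> pd.DataFrame:
    """Drop genes whose fraction of zero values strictly exceeds the cutoff.

    A gene with exactly ``max_zero_fraction`` of zeros is retained ("more
    than" is a strict inequality).  Sample set and gene order are preserved.
    """
    if not 0.0 <= max_zero_fraction <= 1.0:
        raise ValidationError(f"max_zero_fraction={max_zero_fraction} outside [0, 1]")
    validate_expression(expr)
    zero_frac = (expr.values == 0).mean(axis=1)
    keep = zero_frac <= max_zero_fraction
    out = expr.loc[keep]
    dropped = int((~keep).sum())
    if dropped:
        logger.info("filter_expression removed %d/%d genes (> %.0f%% zeros)",
                    dropped, expr.shape[0], 100 * max_zero_fraction)
    if out.empty:
        logger.warning("filter_expression removed every gene")
    return out


def _log_comb(a: int, b: int) -> float:
    if b < 0 or b > a:
        return -math.inf
    return math.lgamma(a + 1) - math.lgamma(b + 1) - math.lgamma(a - b + 1)


def hypergeom_pvalue(m: int, n: int, t: int, r: int) -> float:
    """Upper-tail hypergeometric probability P(X >= r).

    ``m`` miRNAs in the study, ``n`` targeting the lncRNA, ``t`` targeting the
    TF, ``r`` targeting both.  Computed in log space so miRNA universes of
    1e5+ do not overflow; summing the upper tail directly keeps small
    p-values accurate (mathematically identical to ``1 - P(X <= r-1)``).
    """
    for name, v in (("m", m), ("n", n), ("t", t), ("r", r)):
        if v != int(v) or v < 0:
            raise ValidationError(f"{name}={v} must be a non-negative integer")
    m, n, t, r = int(m), int(n), int(t), int(r)
    if n > m or t > m:
        raise ValidationError(f"n={n} and t={t} must not exceed m={m}")
    if r > min(n, t):
        raise ValidationError(f"r={r} exceeds min(n, t)={min(n, t)}")
    if r == 0:
        return 1.0
    log_cmn = _log_comb(m, n)
    terms = []
    for i in range(r, min(n, t) + 1):
        lg = _log_comb(t, i) + _log_comb(m - t, n - i)
        if lg > -math.inf:
            terms.append(lg - log_cmn)
    if not terms:
        return 0.0
    p = float(np.exp(special.logsumexp(terms)))
    return min(p, 1.0)


def pearson_with_p(x, y) -> CorrelationResult:
    """Sample Pearson correlation with the exact two-sided t-test p-value
    (t = r * sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or x.shape != y.shape:
        raise ValidationError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 3:
        raise ValidationError(f"need >= 3 observations, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("zero-variance vector: correlation undefined")
    res = stats.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p=float(res.pvalue), n_obs=n)


def _membership_matrix(interactions: InteractionSet, genes: list, mirna_index: dict) -> np.ndarray:
    mat = np.zeros((len(genes), len(mirna_index)), dtype=bool)
    for i, g in enumerate(genes):
        for mir in interactions.targets_of.get(g, ()):
            mat[i, mirna_index[mir]] = True
    return mat


def call_cerna_pairs(interactions: InteractionSet, expr: pd.DataFrame,
                     config: RunConfig | None = None) -> pd.DataFrame:
    """Evaluate every lncRNA-TF pair and flag significant ceRNA pairs.

    For each pair the shared-miRNA count, hypergeometric upper-tail p,
    Pearson correlation across samples and its p-value are computed.  A pair
    is significant iff ``hyper_p < hyper_p_cutoff`` and ``pcc > pcc_cutoff``
    (signed: strong negative correlation does not qualify) and
    ``pcc_p < pcc_p_cutoff``.  A Benjamini-Hochberg q computed on the
    hypergeometric p-values is emitted for information only; it does not
    enter the significance call.

    Returns a table sorted by (hyper_p, pcc descending, lnc_id, tf_id) with
    columns ``lnc_id, tf_id, r_shared, hyper_p, pcc, pcc_p, bh_q, significant``.
    Pairs whose genes lack expression, or whose expression is constant, are
    skipped with a logged reason.
    """
    config = config or RunConfig()
    m = interactions.m
    if m == 0:
        raise ValidationError("empty miRNA universe")
    validate_expression(expr)

    def usable(genes: list) -> list:
        kept = []
        for g in genes:
            if g not in expr.index:
                logger.info("skipping %s: no expression profile", g)
            elif np.ptp(expr.loc[g].values) == 0:
                logger.info("skipping %s: constant expression", g)
            else:
                kept.append(g)
        return kept

    lncs = usable(interactions.lncrnas)
    tfs = usable(interactions.tfs)
    if not lncs or not tfs:
        return pd.DataFrame(columns=PAIR_TABLE_COLUMNS)

    mirna_index = {mir: i for i, mir in enumerate(sorted(interactions.mirna_ids))}
    lnc_mat = _membership_matrix(interactions, lncs, mirna_index)
    tf_mat = _membership_matrix(interactions, tfs, mirna_index)
    shared = lnc_mat.astype(np.int64) @ tf_mat.T.astype(np.int64)
    n_per_lnc = lnc_mat.sum(axis=1)
    t_per_tf = tf_mat.sum(axis=1)

    # correlations for all pairs at once: r = Z_l Z_t' with unit-norm rows
    s = expr.shape[1]
    if s < 3:
        raise ValidationError(f"need >= 3 samples, got {s}")
    lvals = expr.loc[lncs].values.astype(float)
    tvals = expr.loc[tfs].values.astype(float)
    lz = lvals - lvals.mean(axis=1, keepdims=True)
    tz = tvals - tvals.mean(axis=1, keepdims=True)
    lz /= np.linalg.norm(lz, axis=1, keepdims=True)
    tz /= np.linalg.norm(tz, axis=1, keepdims=True)
    pcc = np.clip(lz @ tz.T, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        tstat = pcc * np.sqrt((s - 2) / np.maximum(1.0 - pcc ** 2, 1e-300))
    pcc_p = 2.0 * stats.t.sf(np.abs(tstat), df=s - 2)

    hyper_cache: dict = {}
    rows = []
    for i, lnc in enumerate(lncs):
        for j, tf in enumerate(tfs):
            key = (int(n_per_lnc[i]), int(t_per_tf[j]), int(shared[i, j]))
            hp = hyper_cache.get(key)
            if hp is None:
                hp = hypergeom_pvalue(m, *key)
                hyper_cache[key] = hp
            rows.append((lnc, tf, int(shared[i, j]), hp,
                         float(pcc[i, j]), float(pcc_p[i, j])))

    table = pd.DataFrame(rows, columns=["lnc_id", "tf_id", "r_shared",
                                        "hyper_p", "pcc", "pcc_p"])
    table["bh_q"] = multipletests(table["hyper_p"].values, method="fdr_bh")[1]
    table["significant"] = (
        (table["hyper_p"] < config.hyper_p_cutoff)
        & (table["pcc"] > config.pcc_cutoff)
        & (table["pcc_p"] < config.pcc_p_cutoff)
    )
    table = table.sort_values(
        by=["hyper_p", "pcc", "lnc_id", "tf_id"],
        ascending=[True, False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return table[PAIR_TABLE_COLUMNS]
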