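"""PWM scanning of lncRNA promoters/enhancers and TF-lncRNA feedback loops.

A position weight matrix (PWM) scores a DNA window by summing per-column
log2 odds ``log2(freq[i][base] / background[base])`` (bits).  The p-value of
a score is the probability that a random background word of the motif width
scores at least as high; it is computed exactly by dynamic programming over
the per-column score distributions (merging equal partial sums), or on a
discretized lattice for very wide motifs.

A TF-lncRNA *positive feedback loop* is a pair that is both a significant
ceRNA pair (the lncRNA buffers the TF's miRNA repressors) and supported by a
motif hit of that TF inside a promoter (TSS +/- 2,000 bp) or assigned
enhancer of the lncRNA: the TF activates the lncRNA's transcription while
the lncRNA raises the TF's mRNA level.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}

REGION_ROLES = ("promoter", "enhancer")

# widths above this use the lattice DP (4**w exact states get too large)
_EXACT_WIDTH_LIMIT = 12
_DEFAULT_LATTICE_BINS = 1000


@dataclass(frozen=True)
class GenomicRegion:
    """A 0-based half-open interval owned by a lncRNA (promoter or enhancer)."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    role: str = "promoter"
    owner_gene: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"bad interval [{self.start}, {self.end}) on {self.chrom}")
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"bad strand {self.strand!r}")
        if self.role not in REGION_ROLES:
            raise ValidationError(f"bad region role {self.role!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class PWMModel:
    """Log-odds matrix (bits) with its frequency model and background."""

    tf_id: str
    freq: np.ndarray          # width x 4, rows sum to 1
    background: np.ndarray    # 4 probabilities summing to 1
    pseudocount: float = 0.1
    log_odds: np.ndarray = field(default=None)  # width x 4, bits

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.freq.ndim != 2 or self.freq.shape[1] != 4:
            raise ValidationError("freq must be a width x 4 matrix")
        if self.background.shape != (4,) or abs(self.background.sum() - 1) > 1e-9:
            raise ValidationError("background must be 4 probabilities summing to 1")
        if np.any(self.background <= 0):
            raise ValidationError("background probabilities must be positive")
        if np.any(np.abs(self.freq.sum(axis=1) - 1) > 1e-9):
            raise ValidationError("each freq row must sum to 1")
        if np.any(self.freq <= 0):
            raise ValidationError("freq must be strictly positive (apply a pseudocount)")
        if self.log_odds is None:
            self.log_odds = np.log2(self.freq / self.background[None, :])
        else:
            self.log_odds = np.asarray(self.log_odds, dtype=float)
            if not np.allclose(self.log_odds,
                               np.log2(self.freq / self.background[None, :]),
                               atol=1e-9):
                raise ValidationError("log_odds inconsistent with freq/background")

    @property
    def width(self) -> int:
        return int(self.freq.shape[0])

    @classmethod
    def from_counts(cls, tf_id: str, counts, background=None,
                    pseudocount: float = 0.1) -> "PWMModel":
        """Build from a width x 4 count matrix, adding ``pseudocount`` to
        every cell before normalising (the scanner's documented default is
        0.1).  Background defaults to uniform."""
        counts = np.asarray(counts, dtype=float)
        if counts.ndim != 2 or counts.shape[1] != 4:
            raise ValidationError("counts must be a width x 4 matrix")
        if np.any(counts < 0):
            raise ValidationError("counts must be non-negative")
        if pseudocount <= 0:
            raise ValidationError("pseudocount must be positive")
        if background is None:
            background = np.full(4, 0.25)
        background = np.asarray(background, dtype=float)
        padded = counts + pseudocount
        freq = padded / padded.sum(axis=1, keepdims=True)
        return cls(tf_id=tf_id, freq=freq, background=background,
                   pseudocount=float(pseudocount))

    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    def min_score(self) -> float:
        return float(self.log_odds.min(axis=1).sum())


@dataclass(frozen=True)
class MotifHit:
    """A scored PWM occurrence inside a region (offset is region-relative,
    leftmost base of the matched window on the + coordinate)."""

    tf_id: str
    region: GenomicRegion
    offset: int
    strand: str
    score: float
    p: float

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"bad hit strand {self.strand!r}")
        if not 0.0 < self.p <= 1.0:
            raise ValidationError(f"hit p={self.p} outside (0, 1]")


@dataclass
class FeedbackLoop:
    """A TF-lncRNA pair with both ceRNA and motif-binding evidence."""

    tf_id: str
    lnc_id: str
    cerna_evidence: dict
    binding_evidence: list
    region_roles: frozenset


def define_promoters(tss_table: pd.DataFrame, flank: int = 2000) -> list[GenomicRegion]:
    """Promoter = [TSS - flank, TSS + flank), clipped at zero.

    ``tss_table`` needs columns ``gene_id, chrom, tss`` (0-based) and
    optionally ``strand``.
    """
    if flank <= 0:
        raise ValidationError("flank must be positive")
    regions = []
    for row in tss_table.itertuples(index=False):
        tss = int(row.tss)
        if tss < 0:
            raise ValidationError(f"negative TSS for {row.gene_id}")
        strand = getattr(row, "strand", ".")
        regions.append(GenomicRegion(
            chrom=str(row.chrom), start=max(0, tss - flank), end=tss + flank,
            strand=str(strand), role="promoter", owner_gene=str(row.gene_id)))
    return regions


def assign_enhancers(enhancers: pd.DataFrame, tss_table: pd.DataFrame,
                     min_dist: int = 2000, max_dist: int = 100_000) -> list[GenomicRegion]:
    """Assign each enhancer to every lncRNA whose TSS lies more than
    ``min_dist`` and at most ``max_dist`` bp from the enhancer's nearest
    edge (distance 0 when the TSS falls inside the enhancer).  Enhancers may
    be assigned to several lncRNAs."""
    if max_dist <= min_dist:
        raise ValidationError("max_dist must exceed min_dist")
    regions = []
    for enh in enhancers.itertuples(index=False):
        for gene in tss_table.itertuples(index=False):
            if str(enh.chrom) != str(gene.chrom):
                continue
            tss = int(gene.tss)
            if tss < enh.start:
                dist = enh.start - tss
            elif tss >= enh.end:
                dist = tss - (enh.end - 1)
            else:
                dist = 0
            if min_dist < dist <= max_dist:
                regions.append(GenomicRegion(
                    chrom=str(enh.chrom), start=int(enh.start), end=int(enh.end),
                    strand=".", role="enhancer", owner_gene=str(gene.gene_id)))
    return regions


def _exact_distribution(pwm: PWMModel) -> tuple[np.ndarray, np.ndarray]:
    """All achievable window scores and P(score >= s) by merge-by-value DP.

    Returns (sorted unique scores ascending, tail probabilities) where
    ``tail[i] = P(score >= scores[i])`` under i.i.d. background bases.
    """
    sums = np.zeros(1)
    probs = np.ones(1)
    for col in range(pwm.width):
        sums = (sums[:, None] + pwm.log_odds[col][None, :]).ravel()
        probs = (probs[:, None] * pwm.background[None, :]).ravel()
        # merge bitwise-equal partial sums only: atoms stay exactly the
        # left-to-right column sums a scanner would compute
        uniq, inverse = np.unique(sums, return_inverse=True)
        probs = np.bincount(inverse, weights=probs)
        sums = uniq
    tail = np.cumsum(probs[::-1])[::-1]
    return sums, tail


def _lattice_distribution(pwm: PWMModel, granularity: float) -> tuple[np.ndarray, np.ndarray]:
    """Lattice DP: column scores floored to multiples of ``granularity``.
    Floored scores never exceed true scores, so the looked-up tail is an
    upper bound on the true p-value."""
    if granularity <= 0:
        raise ValidationError("granularity must be positive")
    ints = np.floor(pwm.log_odds / granularity).astype(np.int64)
    offset = ints.min(axis=1).sum()
    span = int((ints.max(axis=1) - ints.min(axis=1)).sum())
    dist = np.zeros(span + 1)
    dist[0] = 1.0
    pos = 0
    for col in range(pwm.width):
        shifted = ints[col] - ints[col].min()
        new = np.zeros(pos + shifted.max() + 1)
        for b in range(4):
            new[shifted[b]:shifted[b] + pos + 1] += pwm.background[b] * dist[:pos + 1]
        dist = new
        pos = len(new) - 1
    tail = np.cumsum(dist[::-1])[::-1]
    scores = (np.arange(len(dist)) + offset) * granularity
    return scores, tail


def score_distribution(pwm: PWMModel, granularity: float | None = None
                       ) -> tuple[np.ndarray, np.ndarray, float]:
    """Null score distribution as (scores ascending, tails, slack).

    ``tails[i] = P(score >= scores[i])``; a query score ``s`` maps to the
    first lattice point at or above ``s - slack``.  The distribution is
    exact (slack 0) when ``granularity`` is None and the width allows it
    (<= 12); wider motifs fall back to a lattice of 1/1000 of the score
    range, where floor-rounding each column by up to one lattice unit
    requires ``slack = width * granularity`` so the looked-up tail upper
    bounds the true p-value.
    """
    if granularity is None:
        if pwm.width <= _EXACT_WIDTH_LIMIT:
            scores, tail = _exact_distribution(pwm)
            return scores, tail, 0.0
        granularity = (pwm.max_score() - pwm.min_score()) / _DEFAULT_LATTICE_BINS
        logger.info("width %d PWM %s: using lattice DP with granularity %.3g",
                    pwm.width, pwm.tf_id, granularity)
    scores, tail = _lattice_distribution(pwm, granularity)
    return scores, tail, pwm.width * granularity


def _tail_lookup(scores: np.ndarray, tail: np.ndarray, slack: float,
                 score: float) -> float:
    idx = int(np.searchsorted(scores, score - slack - 1e-9, side="left"))
    if idx >= len(scores):
        return 0.0
    return float(min(tail[idx], 1.0))


def score_pvalue(pwm: PWMModel, score: float,
                 granularity: float | None = None) -> float:
    """P(random background window scores >= ``score``), exact by default.

    Scores below the minimum achievable return 1.0; scores above the
    maximum return 0.0 (no achievable word reaches them).
    """
    scores, tail, slack = score_distribution(pwm, granularity)
    return _tail_lookup(scores, tail, slack, score)


def _encode(seq: str) -> np.ndarray:
    # A/C/G/T -> 0..3, anything else (N, ...) -> 4, scored as log-odds 0
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = np.full(raw.size, 4, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        codes[raw == ord(base)] = idx
    return codes


def _window_scores(codes: np.ndarray, log_odds: np.ndarray) -> np.ndarray:
    w = log_odds.shape[0]
    lo5 = np.hstack([log_odds, np.zeros((w, 1))])
    windows = np.lib.stride_tricks.sliding_window_view(codes, w)
    return lo5[np.arange(w)[None, :], windows].sum(axis=1)


def reverse_complement_pwm(log_odds: np.ndarray) -> np.ndarray:
    """Scoring a window against the reverse-complement motif equals scoring
    the window's reverse complement against the motif; with alphabet ACGT
    that is a flip of both axes."""
    return log_odds[::-1, ::-1]


def scan_regions(pwm: PWMModel, sequences: dict, regions: list,
                 p_cutoff: float = 1e-4,
                 granularity: float | None = None) -> list[MotifHit]:
    """Score every window of every region on both strands; return hits with
    p < ``p_cutoff`` sorted by (region order, offset, strand).

    ``sequences`` maps chromosome/sequence id -> DNA string; a region whose
    sequence cannot be resolved is skipped with a warning.  Ambiguous bases
    score 0 bits (background).  Minus-strand windows score the reverse
    complement; the reported offset is the leftmost base of the window on
    the plus coordinate.
    """
    if not 0.0 < p_cutoff <= 1.0:
        raise ValidationError(f"p_cutoff={p_cutoff} outside (0, 1]")
    scores_axis, tail, slack = score_distribution(pwm, granularity)
    lo_fwd = pwm.log_odds
    lo_rev = reverse_complement_pwm(pwm.log_odds)
    hits = []
    for region in regions:
        seq = sequences.get(region.chrom)
        if seq is None:
            logger.warning("no sequence for region %s:%d-%d; skipped",
                           region.chrom, region.start, region.end)
            continue
        sub = str(seq)[region.start:region.end].upper()
        if len(sub) < pwm.width:
            continue
        codes = _encode(sub)
        for strand, lo in (("+", lo_fwd), ("-", lo_rev)):
            wscores = _window_scores(codes, lo)
            idx = np.searchsorted(scores_axis, wscores - slack - 1e-9, side="left")
            pvals = np.where(idx < len(scores_axis),
                             tail[np.minimum(idx, len(scores_axis) - 1)], 0.0)
            for offset in np.nonzero(pvals < p_cutoff)[0]:
                p = float(min(max(pvals[offset], np.nextafter(0, 1)), 1.0))
                hits.append(MotifHit(
                    tf_id=pwm.tf_id, region=region, offset=int(offset),
                    strand=strand, score=float(wscores[offset]), p=p))
    order = {id(region): i for i, region in enumerate(regions)}
    hits.sort(key=lambda h: (order[id(h.region)], h.offset, h.strand))
    return hits


def hits_table(hits: list) -> pd.DataFrame:
    """Flatten hits for TSV export."""
    rows = [(h.tf_id, h.region.owner_gene, h.region.role, h.region.chrom,
             h.region.start, h.region.end, h.offset, h.strand, h.score, h.p)
            for h in hits]
    return pd.DataFrame(rows, columns=[
        "tf_id", "owner_gene", "role", "chrom", "region_start", "region_end",
        "offset", "strand", "score_bits", "p"])


def find_feedback_loops(cerna_pairs: pd.DataFrame, hits: list) -> list[FeedbackLoop]:
    """Emit a loop for every significant ceRNA pair whose TF has >= 1 motif
    hit inside a promoter or enhancer owned by the pair's lncRNA.
    ``region_roles`` records which element types carried hits."""
    by_pair: dict = {}
    for h in hits:
        by_pair.setdefault((h.tf_id, h.region.owner_gene), []).append(h)
    loops = []
    if not len(cerna_pairs):
        return loops
    sig = cerna_pairs[cerna_pairs["significant"].astype(bool)]
    for row in sig.itertuples(index=False):
        evidence = by_pair.get((row.tf_id, row.lnc_id))
        if not evidence:
            continue
        loops.append(FeedbackLoop(
            tf_id=row.tf_id, lnc_id=row.lnc_id,
            cerna_evidence=row._asdict(),
            binding_evidence=list(evidence),
            region_roles=frozenset(h.region.role for h in evidence)))
    loops.sort(key=lambda lp: (lp.tf_id, lp.lnc_id))
    return loops


def loops_table(loops: list) -> pd.DataFrame:
    """One row per loop, with per-role hit counts (the motif-count readout)."""
    rows = []
    for lp in loops:
        n_prom = sum(1 for h in lp.binding_evidence if h.region.role == "promoter")
        n_enh = sum(1 for h in lp.binding_evidence if h.region.role == "enhancer")
        rows.append((lp.tf_id, lp.lnc_id, ",".join(sorted(lp.region_roles)),
                     n_prom, n_enh, lp.cerna_evidence.get("hyper_p"),
                     lp.cerna_evidence.get("pcc")))
    return pd.DataFrame(rows, columns=[
        "tf_id", "lnc_id", "region_roles", "n_promoter_hits", "n_enhancer_hits",
        "hyper_p", "pcc"])
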