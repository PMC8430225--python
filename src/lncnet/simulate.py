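"""Synthetic inputs with planted structure and machine-readable ground truth.

Each generator emulates one statistical feature the pipeline relies on:

* ``simulate_interactions`` — miRNA-target membership where planted
  lncRNA-TF pairs share a block of dedicated miRNAs on top of an i.i.d.
  background rate (the signal of the hypergeometric test);
* ``simulate_expression`` — Gaussian log-scale expression where each
  planted pair shares a latent factor so its population correlation equals
  the requested rho exactly;
* ``simulate_survival`` — exponential event times whose hazard is
  ``baseline_rate * exp(sum beta * expression)`` with independent
  exponential censoring;
* ``simulate_modular_graph`` — an Erdos-Renyi background with
  vertex-disjoint planted cliques, each tied in by one bridge edge (the
  module-detection fixture);
* ``simulate_sequences`` — i.i.d. background DNA with PWM-sampled motif
  sites planted at recorded offsets and strands.

All generators derive an independent named substream from one global seed,
so adding a generator never perturbs another, and each returns a
``SyntheticTruth`` describing exactly what was planted.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .cerna import InteractionSet
from .errors import ValidationError
from .motif import ALPHABET, GenomicRegion, PWMModel
from .topology import add_typed_edge, add_typed_node, new_network

NODE_CYCLE = ("lncRNA", "TF")

# Default study conditions for the end-to-end fixture generator.
DEFAULT_N_MIRNA = 386          # size of the miRNA universe
DEFAULT_N_LNC = 200
DEFAULT_N_TF = 50
DEFAULT_BASE_RATE = 0.02       # background miRNA-target probability
DEFAULT_OVERLAP_BOOST = 10     # dedicated shared miRNAs per planted pair
DEFAULT_N_PLANTED = 20
DEFAULT_RHO = 0.75             # planted co-expression
DEFAULT_N_SAMPLES = 300
DEFAULT_NOISE_SD = 1.0
DEFAULT_BASELINE_RATE = 0.1    # exponential baseline hazard
DEFAULT_CENSOR_RATE = 0.05
DEFAULT_BETA = 0.5             # planted log hazard ratio per expression unit


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, independent RNG substream derived from one global seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(name.encode())]))


@dataclass
class SyntheticTruth:
    """What was planted: the reference answer for every recovery test."""

    planted_cerna_pairs: list = field(default_factory=list)
    # entries: (lnc_id, tf_id, target_pcc or None, planted shared-miRNA count)
    planted_modules: list = field(default_factory=list)     # list of node-id sets
    planted_motif_sites: list = field(default_factory=list)  # (seq_id, offset, strand)
    planted_hazard_coefs: dict = field(default_factory=dict)  # gene -> beta
    planted_immune_pairs: list = field(default_factory=list)  # (lnc, cell, rho)

    def to_dict(self) -> dict:
        return {
            "planted_cerna_pairs": [list(t) for t in self.planted_cerna_pairs],
            "planted_modules": [sorted(m) for m in self.planted_modules],
            "planted_motif_sites": [list(t) for t in self.planted_motif_sites],
            "planted_hazard_coefs": dict(self.planted_hazard_coefs),
            "planted_immune_pairs": [list(t) for t in self.planted_immune_pairs],
        }


def _ids(prefix: str, n: int) -> list:
    width = max(3, len(str(n)))
    return [f"{prefix}{i + 1:0{width}d}" for i in range(n)]


def simulate_interactions(n_mirna: int = DEFAULT_N_MIRNA,
                          n_lnc: int = DEFAULT_N_LNC,
                          n_tf: int = DEFAULT_N_TF,
                          base_rate: float = DEFAULT_BASE_RATE,
                          overlap_boost: int = DEFAULT_OVERLAP_BOOST,
                          planted=None, seed: int = 0
                          ) -> tuple[InteractionSet, SyntheticTruth]:
    """miRNA-target membership with planted shared-target pairs.

    Every gene draws each miRNA independently at ``base_rate``; each planted
    (lncRNA, TF) pair then gains ``overlap_boost`` dedicated miRNAs, disjoint
    across pairs, added to both target sets.  Unplanted pairs therefore
    share ``Binomial(n_mirna, base_rate^2)`` miRNAs in expectation.
    """
    if not 0.0 <= base_rate < 1.0:
        raise ValidationError("base_rate must be in [0, 1)")
    if overlap_boost < 0 or overlap_boost > n_mirna:
        raise ValidationError("overlap_boost must be in [0, n_mirna]")
    planted = list(planted or [])
    if len(planted) * overlap_boost > n_mirna:
        raise ValidationError("not enough miRNAs for disjoint dedicated blocks")
    mirnas = _ids("miR-", n_mirna)
    lncs = _ids("LNC", n_lnc)
    tfs = _ids("TF", n_tf)
    lnc_set, tf_set = set(lncs), set(tfs)
    for lnc, tf in planted:
        if lnc not in lnc_set or tf not in tf_set:
            raise ValidationError(f"planted pair ({lnc!r}, {tf!r}) outside universe")
    rng = substream(seed, "interactions")
    membership = rng.random((n_lnc + n_tf, n_mirna)) < base_rate
    genes = lncs + tfs
    gene_index = {g: i for i, g in enumerate(genes)}
    block_order = rng.permutation(n_mirna)
    truth = SyntheticTruth()
    for k, (lnc, tf) in enumerate(planted):
        block = block_order[k * overlap_boost:(k + 1) * overlap_boost]
        membership[gene_index[lnc], block] = True
        membership[gene_index[tf], block] = True
        truth.planted_cerna_pairs.append((lnc, tf, None, int(overlap_boost)))
    targets_of = {}
    for g, row in zip(genes, membership):
        targets_of[g] = frozenset(mirnas[j] for j in np.nonzero(row)[0])
    gene_class = {g: "lncRNA" for g in lncs}
    gene_class.update({g: "TF" for g in tfs})
    iset = InteractionSet(mirna_ids=frozenset(mirnas), targets_of=targets_of,
                          gene_class=gene_class)
    return iset, truth


def simulate_expression(gene_ids: list, planted_pairs=None,
                        n_samples: int = DEFAULT_N_SAMPLES,
                        noise_sd: float = DEFAULT_NOISE_SD,
                        seed: int = 0) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Gaussian expression with exact planted pairwise correlations.

    For a planted pair with target correlation rho the two profiles are
    ``sqrt(|rho|) z + sqrt(1 - |rho|) eps`` built on a shared latent factor
    (the second gene's loading carries rho's sign), so the population
    correlation is exactly rho; all other genes are independent noise.  The
    whole matrix is scaled by ``noise_sd``.
    """
    if n_samples < 3:
        raise ValidationError("n_samples must be >= 3")
    if noise_sd <= 0:
        raise ValidationError("noise_sd must be positive")
    planted_pairs = list(planted_pairs or [])
    gene_ids = list(gene_ids)
    gene_set = set(gene_ids)
    if len(gene_set) != len(gene_ids):
        raise ValidationError("duplicate gene ids")
    used: set = set()
    for a, b, rho in planted_pairs:
        if not -1.0 < rho < 1.0:
            raise ValidationError(f"target correlation {rho} outside (-1, 1)")
        if a not in gene_set or b not in gene_set:
            raise ValidationError(f"planted pair ({a!r}, {b!r}) outside gene set")
        if a in used or b in used:
            raise ValidationError("a gene may appear in at most one planted pair")
        used |= {a, b}
    rng = substream(seed, "expression")
    values = rng.standard_normal((len(gene_ids), n_samples))
    index = {g: i for i, g in enumerate(gene_ids)}
    truth = SyntheticTruth()
    for a, b, rho in planted_pairs:
        z = rng.standard_normal(n_samples)
        r = abs(rho)
        values[index[a]] = np.sqrt(r) * z + np.sqrt(1 - r) * rng.standard_normal(n_samples)
        values[index[b]] = (np.sign(rho) * np.sqrt(r) * z
                            + np.sqrt(1 - r) * rng.standard_normal(n_samples))
        truth.planted_cerna_pairs.append((a, b, float(rho), None))
    expr = pd.DataFrame(values * noise_sd, index=gene_ids,
                        columns=_ids("S", n_samples))
    return expr, truth


def simulate_survival(expr: pd.DataFrame, coefs: dict,
                      baseline_rate: float = DEFAULT_BASELINE_RATE,
                      censor_rate: float = DEFAULT_CENSOR_RATE,
                      seed: int = 0) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Exponential survival under a proportional-hazards model.

    Event time ~ Exp(rate = baseline_rate * exp(sum_i beta_i Exp(i)));
    censoring time ~ Exp(censor_rate); observed time is the minimum and the
    event indicator marks which came first.
    """
    if baseline_rate <= 0 or censor_rate <= 0:
        raise ValidationError("rates must be positive")
    missing = [g for g in coefs if g not in expr.index]
    if missing:
        raise ValidationError(f"coefficient genes missing from expression: {missing}")
    rng = substream(seed, "survival")
    samples = list(expr.columns)
    lp = np.zeros(len(samples))
    for g, beta in coefs.items():
        if not np.isfinite(beta):
            raise ValidationError(f"non-finite beta for {g!r}")
        lp += float(beta) * expr.loc[g].values.astype(float)
    rate = baseline_rate * np.exp(lp)
    event_time = rng.exponential(1.0 / rate)
    censor_time = rng.exponential(1.0 / censor_rate, size=len(samples))
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    clinical = pd.DataFrame({"time": time, "event": event},
                            index=pd.Index(samples, name="sample_id"))
    truth = SyntheticTruth(planted_hazard_coefs={g: float(b) for g, b in coefs.items()})
    return clinical, truth


def simulate_modular_graph(n_background: int = 100,
                           p_background: float = 0.03,
                           clique_sizes=(5, 6), seed: int = 0
                           ) -> tuple[nx.Graph, SyntheticTruth]:
    """Erdos-Renyi background plus vertex-disjoint planted cliques, each
    attached to the background by exactly one bridge edge."""
    if n_background < 1:
        raise ValidationError("need at least one background node (bridge anchor)")
    if not 0.0 <= p_background <= 1.0:
        raise ValidationError("p_background must be a probability")
    clique_sizes = list(clique_sizes)
    if any(s < 3 for s in clique_sizes):
        raise ValidationError("clique sizes must be >= 3")
    rng = substream(seed, "modular_graph")
    g = new_network()
    background = _ids("BG", n_background)
    for i, node in enumerate(background):
        add_typed_node(g, node, NODE_CYCLE[i % 2])
    for i in range(n_background):
        for j in range(i + 1, n_background):
            if rng.random() < p_background:
                add_typed_edge(g, background[i], background[j], "coexpr")
    truth = SyntheticTruth()
    for k, size in enumerate(clique_sizes):
        members = _ids(f"MOD{k + 1}-", size)
        for i, node in enumerate(members):
            add_typed_node(g, node, NODE_CYCLE[i % 2])
        for i in range(size):
            for j in range(i + 1, size):
                add_typed_edge(g, members[i], members[j], "coexpr")
        anchor = background[int(rng.integers(n_background))]
        bridge = members[int(rng.integers(size))]
        add_typed_edge(g, bridge, anchor, "coexpr")
        truth.planted_modules.append(set(members))
    return g, truth


def simulate_sequences(pwm: PWMModel, n_seq: int = 200, seq_len: int = 2000,
                       planted_sites: int = 0, background=None, seed: int = 0
                       ) -> tuple[dict, list, SyntheticTruth]:
    """Background DNA with PWM-sampled sites planted at recorded positions.

    Returns (sequences dict id -> string, promoter regions spanning each
    sequence owned by synthetic lncRNA ids, truth).  Sites are sampled
    column-wise from the PWM frequency model; a site planted on the '-'
    strand is inserted as the reverse complement of the sampled word, at a
    recorded plus-coordinate offset.  Planted sites never overlap.
    """
    if n_seq < 1 or seq_len < pwm.width:
        raise ValidationError("need n_seq >= 1 and seq_len >= motif width")
    if planted_sites < 0 or planted_sites * 2 * pwm.width > seq_len:
        raise ValidationError("too many planted sites for the sequence length")
    background = np.full(4, 0.25) if background is None else np.asarray(background, float)
    if background.shape != (4,) or abs(background.sum() - 1) > 1e-9:
        raise ValidationError("background must be 4 probabilities summing to 1")
    rng = substream(seed, "sequences")
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    sequences = {}
    regions = []
    truth = SyntheticTruth()
    seq_ids = _ids("chrSyn", n_seq)
    owners = _ids("LNC", n_seq)
    for seq_id, owner in zip(seq_ids, owners):
        bases = rng.choice(list(ALPHABET), size=seq_len, p=background)
        taken: list = []
        for _ in range(planted_sites):
            for _attempt in range(1000):
                offset = int(rng.integers(0, seq_len - pwm.width + 1))
                if all(offset + pwm.width <= s or offset >= e for s, e in taken):
                    break
            else:
                raise ValidationError("could not place non-overlapping sites")
            taken.append((offset, offset + pwm.width))
            word = [ALPHABET[rng.choice(4, p=pwm.freq[i])] for i in range(pwm.width)]
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                word = [comp[b] for b in reversed(word)]
            bases[offset:offset + pwm.width] = word
            truth.planted_motif_sites.append((seq_id, offset, strand))
        sequences[seq_id] = "".join(bases)
        regions.append(GenomicRegion(chrom=seq_id, start=0, end=seq_len,
                                     strand="+", role="promoter",
                                     owner_gene=owner))
    return sequences, regions, truth
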