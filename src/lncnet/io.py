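"""Readers and writers for every external format of the pipeline.

Tabular files are TSV (tab-delimited, UTF-8, ``#`` comments ignored, '.'
decimal point).  Genomic intervals are 0-based half-open (BED-native); a
1-based source must be shifted by its loader before reaching this layer.
Every writer/reader pair is a lossless round trip on valid data.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from Bio import SeqIO, motifs as bio_motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .cerna import InteractionSet, validate_expression
from .errors import ParseError, ValidationError
from .motif import ALPHABET, PWMModel
from .survival import validate_clinical
from .topology import EDGE_TYPES, add_typed_edge, add_typed_node, new_network

logger = logging.getLogger(__name__)

NETWORK_FORMATS = ("edge_tsv", "graphml")

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def _read_tsv(path, **kwargs) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", comment="#", **kwargs)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty file") from exc


# -- expression ---------------------------------------------------------------

def read_expression(path) -> pd.DataFrame:
    """Expression TSV: header row of sample ids, first column gene ids."""
    df = _read_tsv(path, index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "gene_id"
    df.columns = df.columns.astype(str)
    if df.isna().any().any():
        bad = df.index[df.isna().any(axis=1)].tolist()
        raise ParseError(f"{path}: missing cells in rows {bad[:5]}")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric expression value ({exc})") from exc
    return validate_expression(df)


def write_expression(expr: pd.DataFrame, path) -> None:
    validate_expression(expr)
    expr.to_csv(path, sep="\t", index_label="gene_id")


# -- clinical -----------------------------------------------------------------

def read_clinical(path) -> pd.DataFrame:
    """Clinical TSV with columns sample_id, time, event."""
    df = _read_tsv(path)
    required = {"sample_id", "time", "event"}
    if not required <= set(df.columns):
        raise ParseError(f"{path}: needs columns {sorted(required)}")
    df = df.set_index("sample_id")
    df.index = df.index.astype(str)
    return validate_clinical(df[["time", "event"]].astype(float))


def write_clinical(clinical: pd.DataFrame, path) -> None:
    validate_clinical(clinical)
    out = clinical.copy()
    out["event"] = out["event"].astype(int)
    out.to_csv(path, sep="\t", index_label="sample_id")


# -- interactions -------------------------------------------------------------

def read_interactions(path) -> InteractionSet:
    """miRNA-target edge TSV: mirna_id, target_id, target_class.

    The miRNA universe is the set of miRNAs appearing in the file (a
    standing-in snapshot of the interaction resource defines its own
    universe)."""
    df = _read_tsv(path, dtype=str)
    required = {"mirna_id", "target_id", "target_class"}
    if not required <= set(df.columns):
        raise ParseError(f"{path}: needs columns {sorted(required)}")
    if df.isna().any().any():
        raise ParseError(f"{path}: missing cells")
    targets_of: dict = {}
    gene_class: dict = {}
    for row in df.itertuples(index=False):
        prev = gene_class.get(row.target_id)
        if prev is not None and prev != row.target_class:
            raise ValidationError(
                f"{row.target_id!r} labelled both {prev!r} and {row.target_class!r}")
        gene_class[row.target_id] = row.target_class
        targets_of.setdefault(row.target_id, set()).add(row.mirna_id)
    return InteractionSet(
        mirna_ids=frozenset(df["mirna_id"]),
        targets_of={g: frozenset(s) for g, s in targets_of.items()},
        gene_class=gene_class)


def write_interactions(interactions: InteractionSet, path) -> None:
    rows = [(mir, gene, interactions.gene_class[gene])
            for gene in sorted(interactions.targets_of)
            for mir in sorted(interactions.targets_of[gene])]
    pd.DataFrame(rows, columns=["mirna_id", "target_id", "target_class"]) \
        .to_csv(path, sep="\t", index=False)


# -- infiltration scores ------------------------------------------------------

def read_infiltration(path) -> pd.DataFrame:
    """Infiltration TSV: header row of cell types, first column sample ids."""
    df = _read_tsv(path, index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "sample_id"
    df.columns = df.columns.astype(str)
    if df.isna().any().any():
        raise ParseError(f"{path}: missing cells")
    return df.astype(float)


def write_infiltration(infil: pd.DataFrame, path) -> None:
    infil.to_csv(path, sep="\t", index_label="sample_id")


# -- PPI edges ----------------------------------------------------------------

def read_ppi(path) -> list:
    """TF-TF PPI edge TSV with columns tf_a, tf_b."""
    df = _read_tsv(path, dtype=str)
    if not {"tf_a", "tf_b"} <= set(df.columns):
        raise ParseError(f"{path}: needs columns ['tf_a', 'tf_b']")
    return [(row.tf_a, row.tf_b) for row in df.itertuples(index=False)]


def write_ppi(edges, path) -> None:
    pd.DataFrame(sorted(edges), columns=["tf_a", "tf_b"]) \
        .to_csv(path, sep="\t", index=False)


# -- BED ----------------------------------------------------------------------

def read_bed(path) -> pd.DataFrame:
    """BED6 (or BED3/4) as a frame with 0-based half-open coordinates."""
    df = _read_tsv(path, header=None, dtype=str)
    if df.shape[1] < 3:
        raise ParseError(f"{path}: BED needs >= 3 columns")
    df = df.iloc[:, :6]
    df.columns = BED6_COLUMNS[:df.shape[1]]
    for col in BED6_COLUMNS[df.shape[1]:]:
        df[col] = "." if col != "score" else "0"
    try:
        df["start"] = df["start"].astype(int)
        df["end"] = df["end"].astype(int)
    except ValueError as exc:
        raise ParseError(f"{path}: non-integer BED coordinate ({exc})") from exc
    if (df["start"] < 0).any() or (df["start"] >= df["end"]).any():
        raise ValidationError(f"{path}: invalid interval (start<0 or start>=end)")
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    out = df.copy()
    for col in BED6_COLUMNS[len(out.columns):]:
        out[col] = "." if col != "score" else "0"
    out[BED6_COLUMNS].to_csv(path, sep="\t", index=False, header=False)


def read_tss_table(path) -> pd.DataFrame:
    """TSS BED: one record per lncRNA, the TSS is the interval start (the
    name column carries the gene id)."""
    bed = read_bed(path)
    return pd.DataFrame({"gene_id": bed["name"], "chrom": bed["chrom"],
                         "tss": bed["start"], "strand": bed["strand"]})


# -- FASTA --------------------------------------------------------------------

def read_fasta(path) -> dict:
    """FASTA as a dict id -> uppercase sequence string."""
    seqs = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seqs:
            raise ValidationError(f"{path}: duplicate sequence id {record.id!r}")
        seqs[record.id] = str(record.seq).upper()
    return seqs


def write_fasta(sequences: dict, path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


# -- MEME minimal motifs ------------------------------------------------------

def read_meme(path, pseudocount: float = 0.1) -> list:
    """MEME minimal motif format -> PWMModels (counts = probabilities x
    nsites, re-normalised with the given pseudocount)."""
    with open(path) as handle:
        parsed = bio_motifs.parse(handle, "minimal")
    background = np.array([parsed.background[b] for b in ALPHABET], dtype=float)
    models = []
    for motif in parsed:
        counts = np.array([[motif.counts[b][i] for b in ALPHABET]
                           for i in range(motif.length)], dtype=float)
        models.append(PWMModel.from_counts(motif.name, counts,
                                           background=background,
                                           pseudocount=pseudocount))
    return models


def write_meme(pwms: list, path, nsites: int = 100) -> None:
    """Write count matrices in MEME minimal format (letter-probability
    rows; counts are encoded as probabilities over ``nsites`` sites)."""
    lines = ["MEME version 4", "", "ALPHABET= ACGT", "", "strands: + -", ""]
    bg = pwms[0].background if pwms else np.full(4, 0.25)
    lines += ["Background letter frequencies",
              " ".join(f"{b} {bg[i]:.5f}" for i, b in enumerate(ALPHABET)), ""]
    for pwm in pwms:
        lines.append(f"MOTIF {pwm.tf_id}")
        lines.append(f"letter-probability matrix: alength= 4 w= {pwm.width} "
                     f"nsites= {nsites} E= 0")
        for row in pwm.freq:
            lines.append(" ".join(f"{v:.6f}" for v in row))
        lines.append("")
    Path(path).write_text("\n".join(lines) + "\n")


# -- networks -----------------------------------------------------------------

def export_network(network: nx.Graph, path, fmt: str = "edge_tsv") -> None:
    """Edge TSV (source, target, edge_type) or GraphML with node_type /
    edge_type attributes."""
    if fmt not in NETWORK_FORMATS:
        raise ValidationError(f"format must be one of {NETWORK_FORMATS}")
    if fmt == "edge_tsv":
        rows = sorted((str(u), str(v), d.get("edge_type", ""))
                      if str(u) <= str(v) else (str(v), str(u), d.get("edge_type", ""))
                      for u, v, d in network.edges(data=True))
        pd.DataFrame(rows, columns=["source", "target", "edge_type"]) \
            .to_csv(path, sep="\t", index=False)
    else:
        nx.write_graphml(network, str(path), named_key_ids=True)


def import_network(path, fmt: str = "edge_tsv") -> nx.Graph:
    if fmt not in NETWORK_FORMATS:
        raise ValidationError(f"format must be one of {NETWORK_FORMATS}")
    if fmt == "edge_tsv":
        df = _read_tsv(path, dtype=str)
        if not {"source", "target", "edge_type"} <= set(df.columns):
            raise ParseError(f"{path}: needs columns source, target, edge_type")
        g = new_network()
        for row in df.itertuples(index=False):
            for label in str(row.edge_type).split(","):
                if label not in EDGE_TYPES:
                    raise ValidationError(f"{path}: unknown edge type {label!r}")
                add_typed_edge(g, row.source, row.target, label)
        return g
    g = nx.read_graphml(str(path))
    out = new_network()
    for node, data in g.nodes(data=True):
        if "node_type" in data:
            add_typed_node(out, node, data["node_type"])
        else:
            out.add_node(node)
    for u, v, data in g.edges(data=True):
        for label in str(data.get("edge_type", "coexpr")).split(","):
            attrs = {k: v2 for k, v2 in data.items() if k != "edge_type"}
            add_typed_edge(out, u, v, label, **attrs)
    return out


# -- stage summaries ----------------------------------------------------------

def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2, sort_keys=True,
                                     default=_json_default) + "\n")


def _jsonable(obj):
    # strict JSON: non-finite floats become null
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (float, np.floating)) and not np.isfinite(obj):
        return None
    return obj


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
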