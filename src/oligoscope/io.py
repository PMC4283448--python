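"""File formats: aligned FASTA per OTU, TSV tables, graph exports.

Read IDs follow ``<otu>|<site>|<serial>``.  Alignments round-trip
losslessly: writing an :class:`AlignedReadSet` and reading it back
reproduces the character matrix and labels exactly.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from oligoscope.oligotyping import AlignedReadSet, OligotypeTable

log = logging.getLogger("oligoscope")


class FormatError(ValueError):
    pass


def write_alignment(rs: AlignedReadSet, path: str | Path) -> None:
    """Write one OTU's alignment as gapped FASTA (IDs ``otu|site|serial``)."""
    records = [
        SeqRecord(Seq("".join(row)), id=str(rid), description="")
        for row, rid in zip(rs.reads, rs.read_ids)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_alignment(path: str | Path) -> AlignedReadSet:
    """Read one per-OTU aligned FASTA file back into an AlignedReadSet."""
    path = Path(path)
    seqs, sites, ids = [], [], []
    otu = None
    length = None
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.id.split("|")
        if len(parts) != 3:
            raise FormatError(
                f"{path.name}: read ID {rec.id!r} does not parse as otu|site|serial"
            )
        if otu is None:
            otu = parts[0]
        s = str(rec.seq).upper()
        if length is None:
            length = len(s)
        elif len(s) != length:
            raise FormatError(
                f"{path.name}: read {rec.id!r} has length {len(s)}, expected {length}"
            )
        seqs.append(list(s))
        sites.append(parts[1])
        ids.append(rec.id)
    if not seqs:
        raise FormatError(f"{path.name}: no FASTA records")
    return AlignedReadSet(
        otu_id=otu,
        reads=np.array(seqs, dtype="<U1"),
        site_of_read=np.array(sites),
        read_ids=np.array(ids),
    )


def read_alignments(directory: str | Path) -> list[AlignedReadSet]:
    """Read every ``*.fasta``/``*.fa`` alignment in a directory (sorted)."""
    directory = Path(directory)
    paths = sorted(
        p for p in directory.iterdir() if p.suffix.lower() in (".fasta", ".fa")
    )
    if not paths:
        log.warning("no alignment files found in %s", directory)
    return [read_alignment(p) for p in paths]


def write_alignments(read_sets: list[AlignedReadSet], directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for rs in read_sets:
        write_alignment(rs, directory / f"{rs.otu_id}.fasta")


def write_env_table(env: pd.DataFrame, path: str | Path) -> None:
    env.to_csv(path, sep="\t")


def read_env_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_oligotype_table(table: OligotypeTable, path: str | Path) -> None:
    """TSV with metadata columns first, then per-site counts."""
    merged = table.meta.join(table.counts)
    merged.index.name = "oligotype"
    merged.to_csv(path, sep="\t")


def read_oligotype_table(path: str | Path, meta_cols=None) -> OligotypeTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if meta_cols is None:
        meta_cols = [
            c for c in ("otu_id", "label", "positions", "phylum", "class", "order")
            if c in df.columns
        ]
    counts = df.drop(columns=meta_cols).astype(int)
    return OligotypeTable(counts, df[meta_cols])


def write_ground_truth(truth, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth.to_jsonable(), indent=1))


def write_graphml(g: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(g, str(path))


def write_sif(g: nx.Graph, path: str | Path) -> None:
    """Simple interaction format: ``node1 ia node2`` per edge."""
    with open(path, "w") as fh:
        isolated = [v for v in g.nodes() if g.degree(v) == 0]
        for a, b in g.edges():
            fh.write(f"{a}\tia\t{b}\n")
        for v in isolated:
            fh.write(f"{v}\n")


def write_edge_list(g: nx.Graph, path: str | Path) -> None:
    rows = [
        {
            "node1": a,
            "node2": b,
            "ia": d.get("ia", d.get("weight")),
            "p_adjusted": d.get("p_adjusted", float("nan")),
        }
        for a, b, d in g.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["node1", "node2", "ia", "p_adjusted"]).to_csv(
        path, sep="\t", index=False
    )
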