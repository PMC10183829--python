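"""File I/O: FASTA, newick, TSV tables and the profile text format."""

from __future__ import annotations

import os
from typing import Dict, Iterable, Mapping

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def read_fasta(path: str | os.PathLike) -> Dict[str, str]:
    """Read a FASTA file into an ordered {id: sequence} mapping."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        records[rec.id] = str(rec.seq)
    return records


def write_fasta(seqs: Mapping[str, str], path: str | os.PathLike, width: int = 60) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_tree(path: str | os.PathLike) -> dendropy.Tree:
    return dendropy.Tree.get(
        path=str(path),
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )


def write_tree(tree: dendropy.Tree, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(tree_to_newick(tree))
        fh.write("\n")


def tree_to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        suppress_internal_node_labels=False,
    ).strip()


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path: str | os.PathLike, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def write_profile(profile, path: str | os.PathLike) -> None:
    """Serialize a ProfileModel as a plain-text table.

    Header lines (``#``) carry metadata; then one row of 20 log-odds scores
    per profile column.
    """
    from .alphabet import AA

    with open(path, "w") as fh:
        fh.write(f"# phyloprof profile L={profile.length}\n")
        fh.write("# background\t" + "\t".join(f"{b:.9f}" for b in profile.background) + "\n")
        fh.write("col\t" + "\t".join(AA) + "\n")
        for i, row in enumerate(profile.log_odds, start=1):
            fh.write(f"{i}\t" + "\t".join(f"{x:.6f}" for x in row) + "\n")


def read_profile(path: str | os.PathLike):
    from .homology_search import ProfileModel

    background = None
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# background\t"):
                background = np.array([float(x) for x in line.split("\t")[1:]])
            elif line.startswith("#") or line.startswith("col\t") or not line:
                continue
            else:
                rows.append([float(x) for x in line.split("\t")[1:]])
    if background is None or not rows:
        raise ValueError(f"malformed profile file {path}")
    log_odds = np.array(rows)
    return ProfileModel(log_odds=log_odds, background=background)


def ensure_dir(path: str | os.PathLike) -> str:
    os.makedirs(path, exist_ok=True)
    return str(path)


def write_lines(lines: Iterable[str], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for line in lines:
            fh.write(line + "\n")
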