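"""Standard-format IO: FASTA, newick and TSV with round-trip guarantees.

FASTA reads are wrap-agnostic and writes are 60-column.  Newick goes through
dendropy and preserves quoted labels and bootstrap/support values.  TSV is
tab-delimited with a header row, UTF-8, '.' decimal; empty optional fields
survive a round trip as empty (never coerced to zero).
"""

from __future__ import annotations

import os
from typing import Iterable

import dendropy
import pandas as pd

FASTA_WIDTH = 60


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a FASTA file into an ordered id -> sequence mapping."""
    records: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    records[name] = "".join(chunks)
                name = line[1:].split()[0] if line[1:].split() else line[1:]
                if name in records:
                    raise ValueError(f"duplicate FASTA id: {name}")
                chunks = []
            elif line:
                chunks.append(line.strip())
    if name is not None:
        records[name] = "".join(chunks)
    return records


def write_fasta(records: dict[str, str] | Iterable[tuple[str, str]], path: str | os.PathLike) -> None:
    items = records.items() if isinstance(records, dict) else records
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), FASTA_WIDTH):
                fh.write(seq[i:i + FASTA_WIDTH] + "\n")


def read_newick(path: str | os.PathLike) -> dendropy.Tree:
    try:
        return dendropy.Tree.get(
            path=str(path),
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"malformed newick in {path}: {exc}") from exc


def parse_newick(text: str) -> dendropy.Tree:
    return dendropy.Tree.get(
        data=text,
        schema="newick",
        preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )


def write_newick(tree: dendropy.Tree, path: str | os.PathLike) -> None:
    tree.write(path=str(path), schema="newick", unquoted_underscores=True, suppress_rooting=True)


def read_tsv(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, na_values=[])


def write_tsv(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)
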