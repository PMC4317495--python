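"""Readers and writers for the plain-text formats the pipeline exchanges.

Counts, design and metadata tables are TSV; gene sets are GMT; interaction
edge lists are SIF ("A pp B") or two-column TSV; tracks and polygon
boundaries are CSV. The packaged +TIP registry (known microtubule plus-end
tracking proteins with their measured active/inactive fold enrichments) is
exposed through :func:`load_tip_registry`.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "read_counts",
    "read_design",
    "read_meta",
    "write_counts",
    "read_gmt",
    "write_gmt",
    "read_sif",
    "write_sif",
    "read_edge_tsv",
    "read_tracks",
    "write_tracks",
    "read_boundary",
    "write_boundary",
    "load_tip_registry",
]


def read_counts(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="accession")


def read_design(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"bio_rep": str, "tech_rep": str})


def read_meta(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_gmt(path) -> dict:
    """GMT gene sets: term, description, then member ids, tab-separated."""
    terms: dict[str, set] = {}
    for raw in Path(path).read_text().splitlines():
        if not raw.strip():
            continue
        fields = raw.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {raw!r}")
        terms[fields[0]] = set(fields[2:])
    return terms


def write_gmt(terms: dict, path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for term in sorted(terms):
            members = "\t".join(sorted(map(str, terms[term])))
            fh.write(f"{term}\t{description}\t{members}\n")


def read_sif(path) -> list[tuple]:
    """SIF edge list: 'A <relation> B [C ...]' per line."""
    edges = []
    for raw in Path(path).read_text().splitlines():
        fields = raw.split()
        if not fields:
            continue
        if len(fields) < 3:
            raise ValueError(f"malformed SIF line: {raw!r}")
        src = fields[0]
        for tgt in fields[2:]:
            edges.append((src, tgt))
    return edges


def write_sif(edges, path, relation: str = "pp") -> None:
    with open(path, "w") as fh:
        for u, v in edges:
            fh.write(f"{u} {relation} {v}\n")


def read_edge_tsv(path) -> list[tuple]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    return list(df.iloc[:, :2].itertuples(index=False, name=None))


def read_tracks(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_tracks(tracks: pd.DataFrame, path) -> None:
    tracks.to_csv(path, index=False)


def read_boundary(path):
    """Boundary polygon vertices, one 'x_um,y_um' pair per line."""
    import numpy as np

    return np.loadtxt(path, delimiter=",", ndmin=2)


def write_boundary(vertices, path) -> None:
    import numpy as np

    np.savetxt(path, np.asarray(vertices), delimiter=",", fmt="%.6g")


def load_tip_registry() -> pd.DataFrame:
    """Known +TIP registry with measured fold enrichments (active/inactive).

    Columns: gene, protein_name, alias, identified (0/1), fold_or_U ("U" for
    proteins detected only in active complexes; empty for +TIPs not
    identified by MS).
    """
    with resources.files("adhesiomics.data").joinpath("tip_registry.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", dtype={"fold_or_U": str})
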