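"""Readers and writers for every external artifact.

Expression matrices and result tables travel as delimited text (CSV or TSV,
autodetected from the file extension), gene sets as GMT, plain gene lists as
one symbol per line, and dendrograms as Newick.  Sample labels in matrix
headers encode the study design as ``Breed_Diet_Kill_Tissue`` (delimiter
configurable); replicate samples may repeat the same label.

Missing values are rejected rather than imputed: the matrices this package
consumes are complete, post-normalization log2 intensities, and a hole in
one is a symptom of an upstream problem worth surfacing.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LABEL_FIELDS = ("breed", "diet", "kill", "tissue")


class ParseError(ValueError):
    """Raised when an input file violates its declared format."""


def _sep_for(path: str) -> str:
    ext = os.path.splitext(str(path))[1].lower()
    return "\t" if ext in (".tsv", ".txt", ".tab") else ","


@dataclass
class ExpressionMatrix:
    """Log2 expression intensities, probes x samples, with design metadata.

    ``values`` is indexed by probe id with one column per sample (column
    names are unique internal sample ids); ``samples`` is indexed by those
    same ids and carries the breed/diet/kill/tissue tags parsed from the
    sample labels.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ParseError(f"duplicate probe ids: {list(dups)[:5]}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ParseError("expression values must all be finite")
        if list(self.values.columns) != list(self.samples.index):
            raise ValueError("values columns and samples index disagree")
        missing = [f for f in LABEL_FIELDS if f not in self.samples.columns]
        if missing:
            raise ValueError(f"samples table lacks fields {missing}")
        if (self.samples["tissue"].astype(str).str.len() == 0).any():
            raise ParseError("every sample must carry a tissue tag")

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def tissues(self) -> list[str]:
        return sorted(self.samples["tissue"].unique())

    def samples_for(self, tissue: str) -> list[str]:
        """Internal sample ids of every sample tagged with ``tissue``."""
        hit = self.samples.index[self.samples["tissue"] == tissue]
        return list(hit)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class GeneSetCollection:
    """Named gene sets over a symbol universe, upper-case normalized."""

    sets: dict[str, frozenset[str]]
    background: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        norm = {}
        for name, members in self.sets.items():
            members = frozenset(str(m).upper() for m in members)
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            norm[name] = members
        self.sets = norm
        self.background = frozenset(str(g).upper() for g in self.background)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def restrict(self, universe) -> "GeneSetCollection":
        """Intersect every set with ``universe``, dropping emptied sets."""
        uni = frozenset(str(g).upper() for g in universe)
        kept = {n: m & uni for n, m in self.sets.items() if m & uni}
        return GeneSetCollection(kept, background=uni)


def parse_sample_label(label: str, delimiter: str = "_") -> dict[str, str]:
    """Split ``Breed_Diet_Kill_Tissue`` into its four design fields."""
    parts = str(label).split(delimiter)
    if len(parts) != 4 or any(not p for p in parts):
        raise ParseError(
            f"sample label {label!r} does not parse as "
            f"Breed{delimiter}Diet{delimiter}Kill{delimiter}Tissue"
        )
    return dict(zip(LABEL_FIELDS, parts))


def format_sample_label(row, delimiter: str = "_") -> str:
    return delimiter.join(str(row[f]) for f in LABEL_FIELDS)


def read_expression_matrix(path, label_delimiter: str = "_") -> ExpressionMatrix:
    """Read a probes x samples log2 matrix from delimited text.

    The first column holds probe ids; the header row holds sample labels in
    ``Breed_Diet_Kill_Tissue`` form (labels may repeat across replicate
    samples and are assigned unique internal ids ``label#k``).  Any
    non-numeric cell is an error naming the offending probe and sample.
    """
    sep = _sep_for(path)
    raw = pd.read_csv(path, sep=sep, header=None, dtype=str)
    if raw.shape[0] < 2 or raw.shape[1] < 2:
        raise ParseError(f"{path}: need a header row, >=1 probe and >=1 sample")
    labels = [str(v) for v in raw.iloc[0, 1:]]
    meta = pd.DataFrame([parse_sample_label(lab, label_delimiter) for lab in labels])
    counts: dict[str, int] = {}
    ids = []
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1
        ids.append(f"{lab}#{counts[lab]}")
    meta.index = pd.Index(ids, name="sample")

    body = raw.iloc[1:]
    probes = body.iloc[:, 0].astype(str)
    cells = body.iloc[:, 1:]
    numeric = cells.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().to_numpy()
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ParseError(
            f"{path}: non-numeric cell {cells.iat[r, c]!r} at probe "
            f"{probes.iloc[r]!r}, sample {labels[c]!r}"
        )
    values = pd.DataFrame(
        numeric.to_numpy(dtype=float), index=pd.Index(probes, name="probe"), columns=ids
    )
    return ExpressionMatrix(values, meta)


def write_expression_matrix(
    matrix: ExpressionMatrix, path, label_delimiter: str = "_", float_format: str = "%.6f"
) -> None:
    """Write the matrix with sample labels rebuilt from the metadata."""
    sep = _sep_for(path)
    out = matrix.values.copy()
    out.columns = [
        format_sample_label(matrix.samples.loc[s], label_delimiter)
        for s in matrix.values.columns
    ]
    out.to_csv(path, sep=sep, float_format=float_format, index_label="probe")


def read_probe_map(path) -> pd.Series:
    """Read a two-column probe -> gene-symbol table.

    Returns a Series indexed by probe id with upper-cased symbols.  A probe
    appearing twice, or an empty symbol, is an error.
    """
    sep = _sep_for(path)
    df = pd.read_csv(path, sep=sep, header=0, dtype=str)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: probe map needs probe and symbol columns")
    probes = df.iloc[:, 0].astype(str)
    symbols = df.iloc[:, 1].astype(str).str.strip().str.upper()
    if probes.duplicated().any():
        dups = probes[probes.duplicated()].unique()
        raise ParseError(f"{path}: duplicate probes in map: {list(dups)[:5]}")
    if (symbols == "") .any() or symbols.isin(("NAN",)).any():
        raise ParseError(f"{path}: empty gene symbol in probe map")
    return pd.Series(symbols.to_numpy(), index=pd.Index(probes, name="probe"), name="gene")


def write_probe_map(probe_map: pd.Series, path) -> None:
    sep = _sep_for(path)
    probe_map.rename("gene").to_csv(path, sep=sep, index_label="probe")


def read_gene_sets(path) -> GeneSetCollection:
    """Read a GMT file: per line tab-separated name, description, members."""
    sets: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, need >=3"
                )
            name = fields[0]
            members = frozenset(m.strip().upper() for m in fields[2:] if m.strip())
            if not members:
                raise ParseError(f"{path}:{lineno}: set {name!r} has no members")
            sets[name] = members
    return GeneSetCollection(sets)


def write_gene_sets(collection: GeneSetCollection, path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            fh.write("\t".join([name, description, *sorted(members)]) + "\n")


def read_gene_list(path) -> list[str]:
    """Read a plain one-symbol-per-line gene list (upper-cased, deduplicated)."""
    seen: dict[str, None] = {}
    with open(path) as fh:
        for line in fh:
            sym = line.strip().upper()
            if sym:
                seen[sym] = None
    return list(seen)


def write_gene_list(genes, path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(str(g).upper() + "\n")


def write_newick(tree, path=None) -> str:
    """Serialize a merge tree to Newick with branch lengths.

    Branch lengths are differences of merge heights, so two leaves merged at
    height ``h`` serialize as ``(a:h,b:h);``.  A single leaf serializes as
    ``a;``.  Returns the Newick string; also writes it when ``path`` given.
    """
    from scipy.cluster import hierarchy

    labels = list(tree.labels)
    if len(labels) == 0:
        raise ValueError("cannot serialize an empty tree")
    if len(labels) == 1:
        text = f"{labels[0]};"
    else:
        root = hierarchy.to_tree(tree.linkage)

        def render(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{labels[node.id]}:{length:g}"
            inner = ",".join(render(c, node.dist) for c in (node.left, node.right))
            return f"({inner}):{length:g}"

        inner = ",".join(render(c, root.dist) for c in (root.left, root.right))
        text = f"({inner});"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text
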