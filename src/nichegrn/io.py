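"""Typed containers and delimited-text readers/writers.

The package moves four kinds of data around:

* expression matrices (features x samples, continuous, one platform each),
* sample sheets assigning each sample to a region and replicate,
* signed directed prior interaction networks (SIF-like, 4 columns),
* per-gene baseline (basal) expression references.

All on-disk formats are plain text, tab-separated by default. Readers
validate and refuse malformed records rather than silently coercing them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .errors import FormatError

logger = logging.getLogger("nichegrn.io")

TRANSCRIPTION = "transcription_regulation"
BINDING = "binding"
INTERACTION_TYPES = (TRANSCRIPTION, BINDING)

ACTIVATION = "activation"
INHIBITION = "inhibition"
UNASSIGNED = "unassigned"
SIGNS = (ACTIVATION, INHIBITION, UNASSIGNED)

#: canonical region labels of the two-niche, four-region design
REGIONS = ("stemA", "diffA", "stemB", "diffB")


@dataclass(frozen=True)
class Edge:
    """A signed directed interaction: ``source`` regulates ``target``."""

    source: str
    target: str
    interaction: str = TRANSCRIPTION
    sign: str = UNASSIGNED

    def __post_init__(self):
        if self.interaction not in INTERACTION_TYPES:
            raise FormatError(
                f"unknown interaction type {self.interaction!r}; "
                f"kept types are {INTERACTION_TYPES}"
            )
        if self.sign not in SIGNS:
            raise FormatError(f"unknown sign {self.sign!r}; expected one of {SIGNS}")

    @property
    def key(self) -> tuple:
        return (self.source, self.target, self.interaction)


def _collapse_edges(edges) -> tuple:
    """Collapse duplicate edges per (source, target, interaction).

    A fixed sign wins over ``unassigned``; two contradictory fixed signs for
    the same key are rejected.
    """
    by_key: dict = {}
    for e in edges:
        prev = by_key.get(e.key)
        if prev is None:
            by_key[e.key] = e
        elif prev.sign == e.sign or e.sign == UNASSIGNED:
            continue
        elif prev.sign == UNASSIGNED:
            by_key[e.key] = e
        else:
            raise FormatError(
                f"contradictory duplicate edge {e.key}: "
                f"{prev.sign!r} vs {e.sign!r}"
            )
    return tuple(sorted(by_key.values(), key=lambda e: (e.source, e.target, e.interaction)))


@dataclass(frozen=True)
class PriorNetwork:
    """Signed directed prior interaction network (the knowledge network)."""

    edges: tuple
    nodes: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        object.__setattr__(self, "edges", _collapse_edges(self.edges))
        nodes = set(self.nodes)
        for e in self.edges:
            nodes.add(e.source)
            nodes.add(e.target)
        object.__setattr__(self, "nodes", frozenset(nodes))

    @property
    def n_unassigned(self) -> int:
        return sum(1 for e in self.edges if e.sign == UNASSIGNED)

    def adjacent(self, g1: str, g2: str) -> bool:
        """True if a direct edge links g1 and g2 in either direction."""
        return any(
            (e.source == g1 and e.target == g2) or (e.source == g2 and e.target == g1)
            for e in self.edges
        )

    def to_digraph(self) -> "nx.DiGraph":
        g = nx.DiGraph()
        g.add_nodes_from(sorted(self.nodes))
        for e in self.edges:
            g.add_edge(e.source, e.target)
        return g


@dataclass
class ExpressionMatrix:
    """Continuous expression values, features (probes or genes) x samples."""

    feature_ids: list
    sample_ids: list
    values: np.ndarray
    platform_tag: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        nf, ns = len(self.feature_ids), len(self.sample_ids)
        if self.values.shape != (nf, ns):
            raise FormatError(
                f"matrix shape {self.values.shape} does not match "
                f"{nf} features x {ns} samples"
            )
        if len(set(self.sample_ids)) != ns:
            raise FormatError("duplicated sample ids")
        dups = pd.Index(self.feature_ids)[pd.Index(self.feature_ids).duplicated()]
        if len(dups):
            raise FormatError(f"duplicated feature ids: {sorted(set(dups))}")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise FormatError(
                f"non-finite value at feature {self.feature_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, platform_tag: str = "") -> "ExpressionMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float), platform_tag)


@dataclass
class SampleSheet:
    """Assignment of each sample id to a region and replicate index."""

    table: pd.DataFrame  # columns: sample_id, region, replicate

    def __post_init__(self):
        required = {"sample_id", "region", "replicate"}
        missing = required - set(self.table.columns)
        if missing:
            raise FormatError(f"sample sheet missing columns: {sorted(missing)}")
        if self.table["sample_id"].duplicated().any():
            dups = self.table.loc[self.table["sample_id"].duplicated(), "sample_id"]
            raise FormatError(f"sample assigned to more than one region: {sorted(set(dups))}")
        if (self.table["replicate"].astype(int) < 1).any():
            raise FormatError("replicate indices must be >= 1")

    @property
    def regions(self) -> list:
        return sorted(self.table["region"].unique())

    def samples(self, region: str) -> list:
        sel = self.table.loc[self.table["region"] == region, "sample_id"]
        if sel.empty:
            raise FormatError(f"region {region!r} has zero samples")
        return list(sel)

    def validate_against(self, matrix: ExpressionMatrix) -> None:
        missing = set(matrix.sample_ids) - set(self.table["sample_id"])
        if missing:
            raise FormatError(f"samples absent from sheet: {sorted(missing)}")


@dataclass
class ProbeMap:
    """Many-to-one feature -> gene mapping (probe summarization support)."""

    mapping: dict

    def genes(self) -> set:
        return set(self.mapping.values())

    def validate_against(self, matrix: ExpressionMatrix) -> None:
        missing = set(self.mapping) - set(matrix.feature_ids)
        if missing:
            raise FormatError(
                f"probe map refers to features absent from the matrix: {sorted(missing)[:10]}"
            )


@dataclass
class BaselineReference:
    """Per-gene basal expression (median over a reference panel)."""

    values: dict
    quartiles: dict | None = None

    def __post_init__(self):
        for g, v in self.values.items():
            if not np.isfinite(v):
                raise FormatError(f"non-finite baseline value for gene {g!r}")
        if self.quartiles is not None:
            bad = {g: q for g, q in self.quartiles.items() if not 1 <= int(q) <= 4}
            if bad:
                raise FormatError(f"baseline quartiles outside 1..4: {bad}")


# ---------------------------------------------------------------------------
# readers / writers


def _sep(delimiter: str) -> str:
    return {"\t": "\t", "tab": "\t", ",": ",", "comma": ","}.get(delimiter, delimiter)


def read_expression(
    path,
    orientation: str = "features-rows",
    delimiter: str = "\t",
    platform_tag: str = "",
) -> ExpressionMatrix:
    """Read a delimited expression table (header = sample ids, col 0 = feature id)."""
    raw = pd.read_csv(path, sep=_sep(delimiter), index_col=0, dtype=str,
                      keep_default_na=False)
    if orientation == "samples-rows":
        raw = raw.T
    elif orientation != "features-rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    if raw.shape[0] == 0:
        raise FormatError(f"no features in {path}")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() | ~np.isfinite(numeric.to_numpy(dtype=float))
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"non-numeric value {raw.iat[r, c]!r} at feature {raw.index[r]!r}, "
            f"sample {raw.columns[c]!r} in {path}"
        )
    m = ExpressionMatrix.from_frame(numeric, platform_tag=platform_tag)
    logger.info("read %d features x %d samples from %s",
                len(m.feature_ids), len(m.sample_ids), path)
    return m


def write_expression(matrix: ExpressionMatrix, path, delimiter: str = "\t") -> None:
    matrix.to_frame().to_csv(path, sep=_sep(delimiter), index_label="feature_id")


def read_sample_sheet(path, delimiter: str = "\t") -> SampleSheet:
    df = pd.read_csv(path, sep=_sep(delimiter), dtype={"sample_id": str, "region": str})
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path, delimiter: str = "\t") -> None:
    sheet.table.to_csv(path, sep=_sep(delimiter), index=False)


def read_probe_map(path, delimiter: str = "\t") -> ProbeMap:
    df = pd.read_csv(path, sep=_sep(delimiter), dtype=str)
    if not {"feature_id", "gene_id"} <= set(df.columns):
        raise FormatError("probe map needs columns feature_id, gene_id")
    return ProbeMap(dict(zip(df["feature_id"], df["gene_id"])))


def write_probe_map(probemap: ProbeMap, path, delimiter: str = "\t") -> None:
    pd.DataFrame(
        {"feature_id": list(probemap.mapping), "gene_id": list(probemap.mapping.values())}
    ).to_csv(path, sep=_sep(delimiter), index=False)


def read_baseline(path, delimiter: str = "\t") -> BaselineReference:
    df = pd.read_csv(path, sep=_sep(delimiter), dtype={"gene_id": str})
    if not {"gene_id", "value"} <= set(df.columns):
        raise FormatError("baseline needs columns gene_id, value")
    quart = None
    if "quartile" in df.columns:
        quart = dict(zip(df["gene_id"], df["quartile"].astype(int)))
    return BaselineReference(dict(zip(df["gene_id"], df["value"].astype(float))), quart)


def write_baseline(baseline: BaselineReference, path, delimiter: str = "\t") -> None:
    df = pd.DataFrame({"gene_id": list(baseline.values), "value": list(baseline.values.values())})
    if baseline.quartiles is not None:
        df["quartile"] = [baseline.quartiles[g] for g in baseline.values]
    df.to_csv(path, sep=_sep(delimiter), index=False)


def read_network(path) -> PriorNetwork:
    """Read a SIF-like 4-column edge list: source, interaction_type, sign, target.

    Unknown sign tokens map to ``unassigned``; unknown interaction types are
    rejected (only transcription regulation and binding are kept).
    """
    edges = []
    nodes: set = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) == 1:
                nodes.add(fields[0])  # isolated node
                continue
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 fields, got {len(fields)}")
            source, itype, sign, target = fields[:4]
            if itype not in INTERACTION_TYPES:
                raise FormatError(
                    f"{path}:{lineno}: interaction type {itype!r} not kept "
                    f"(expected one of {INTERACTION_TYPES})"
                )
            if sign not in SIGNS:
                logger.warning("%s:%d: unknown sign %r mapped to unassigned",
                               path, lineno, sign)
                sign = UNASSIGNED
            edges.append(Edge(source, target, itype, sign))
    if not edges and not nodes:
        raise FormatError(f"no edges in {path}")
    return PriorNetwork(tuple(edges), frozenset(nodes))


def write_network(net, path, dialect: str = "sif-signed") -> None:
    """Write a network as signed SIF or GraphML (for Cytoscape-style viewers).

    Round-trip guarantee (sif-signed): ``read_network(write_network(net))``
    reproduces node and edge sets exactly.
    """
    if dialect == "sif-signed":
        with open(path, "w") as fh:
            lonely = set(net.nodes)
            for e in net.edges:
                lonely.discard(e.source)
                lonely.discard(e.target)
                fh.write(f"{e.source}\t{e.interaction}\t{e.sign}\t{e.target}\n")
            for n in sorted(lonely):
                fh.write(f"{n}\n")
    elif dialect == "graphml":
        g = nx.DiGraph()
        g.add_nodes_from(sorted(net.nodes))
        for e in net.edges:
            g.add_edge(e.source, e.target, interaction=e.interaction, sign=e.sign)
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def write_table(df: pd.DataFrame, path, delimiter: str = "\t") -> None:
    df.to_csv(path, sep=_sep(delimiter), index=False)


def read_table(path, delimiter: str = "\t") -> pd.DataFrame:
    return pd.read_csv(path, sep=_sep(delimiter))
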