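"""Domain containers and on-disk formats.

All pipeline stages exchange four in-memory panels — aligned mtDNA control
region sequences, Y-STR repeat-count matrices, binary Y-marker call matrices
and a rooted marker-defined haplogroup tree — plus the reference table of
simulated summary statistics that drives ABC model choice.  Formats are
deliberately plain: FASTA for sequences, tab-separated tables with a header
row for everything sample-shaped, a one-node-per-line text format for trees,
and CSV with a two-line role header for reference tables, so that every
artifact remains greppable and tool-agnostic.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

MISSING_TOKEN = "NA"
#: Y-STR repeat value used for a missing call inside integer matrices.
MISSING_REPEAT = -1

SEQ_ALPHABET = frozenset("ACGTN-")
#: FASTA symbols treated as missing in all sequence statistics.
SEQ_MISSING = frozenset("N-")

#: The 17 Y-STR loci of the assembled paternal dataset, in canonical order.
DEFAULT_STR_LOCI = (
    "DYS19", "DYS388", "DYS389a", "DYS389b", "DYS390", "DYS391", "DYS392",
    "DYS393", "DYS426", "DYS434", "DYS435", "DYS436", "DYS437", "DYS439",
    "DYS460", "DYS461", "Y-GATA-A10",
)


class FormatError(ValueError):
    """A file violated its declared on-disk format."""


class AlignmentError(FormatError):
    """Sequences in a panel are not all the same length."""


class CrossRefError(FormatError):
    """A cross-reference (sample id, population label, node name) failed."""


class TreeError(FormatError):
    """A haplogroup tree file is not a valid single-rooted marker tree."""


# ---------------------------------------------------------------------------
# panels


@dataclass
class SequencePanel:
    """Aligned haploid sequences with one population label per sample."""

    sample_ids: list[str]
    populations: list[str]
    sequences: list[str]
    locus_length: int

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        if len(self.populations) != n or len(self.sequences) != n:
            raise FormatError("sample_ids, populations and sequences must align")
        if len(set(self.sample_ids)) != n:
            raise FormatError("duplicate sample ids in sequence panel")
        if n == 0:
            raise FormatError("empty sequence panel")
        for sid, seq in zip(self.sample_ids, self.sequences):
            if len(seq) != self.locus_length:
                raise AlignmentError(
                    f"sequence {sid!r} has length {len(seq)}, "
                    f"expected {self.locus_length}"
                )
            bad = set(seq) - SEQ_ALPHABET
            if bad:
                raise FormatError(f"sequence {sid!r} has symbols {sorted(bad)}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def population_order(self) -> list[str]:
        """Distinct population labels in first-appearance order."""
        return list(dict.fromkeys(self.populations))

    def by_population(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {p: [] for p in self.population_order()}
        for pop, seq in zip(self.populations, self.sequences):
            out[pop].append(seq)
        return out


@dataclass
class STRPanel:
    """Integer repeat counts at fully linked Y-STR loci.

    ``repeats`` is an ``n x L`` integer matrix; missing calls carry
    :data:`MISSING_REPEAT`.
    """

    sample_ids: list[str]
    populations: list[str]
    locus_names: list[str]
    repeats: np.ndarray

    def __post_init__(self) -> None:
        self.repeats = np.asarray(self.repeats, dtype=np.int64)
        n = len(self.sample_ids)
        if len(self.populations) != n:
            raise FormatError("populations must align with sample_ids")
        if len(set(self.locus_names)) != len(self.locus_names):
            raise FormatError("duplicate locus names")
        if self.repeats.shape != (n, len(self.locus_names)):
            raise FormatError(
                f"repeat matrix shape {self.repeats.shape} does not match "
                f"{n} samples x {len(self.locus_names)} loci"
            )
        observed = self.repeats[self.repeats != MISSING_REPEAT]
        if observed.size and observed.min() < 1:
            raise FormatError("repeat counts must be positive integers")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def population_order(self) -> list[str]:
        return list(dict.fromkeys(self.populations))

    def by_population(self) -> dict[str, np.ndarray]:
        pops = np.asarray(self.populations)
        return {p: self.repeats[pops == p] for p in self.population_order()}


ANCESTRAL, DERIVED, MISSING_CALL = 0, 1, -1
_CALL_TOKENS = {"A": ANCESTRAL, "D": DERIVED, MISSING_TOKEN: MISSING_CALL,
                "0": ANCESTRAL, "1": DERIVED,
                "ancestral": ANCESTRAL, "derived": DERIVED}


@dataclass
class MarkerPanel:
    """Binary (ancestral/derived/missing) Y-marker calls per sample."""

    sample_ids: list[str]
    populations: list[str]
    marker_names: list[str]
    calls: np.ndarray  # n x M over {ANCESTRAL, DERIVED, MISSING_CALL}

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        n = len(self.sample_ids)
        if len(self.populations) != n:
            raise FormatError("populations must align with sample_ids")
        if len(set(self.marker_names)) != len(self.marker_names):
            raise FormatError("duplicate marker names")
        if self.calls.shape != (n, len(self.marker_names)):
            raise FormatError("call matrix dimensions do not match panel")
        valid = np.isin(self.calls, (ANCESTRAL, DERIVED, MISSING_CALL))
        if not valid.all():
            raise FormatError("calls must be ancestral, derived or missing")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def profile(self, i: int) -> dict[str, int]:
        """Marker -> call mapping for sample ``i`` (missing calls omitted)."""
        row = self.calls[i]
        return {m: int(c) for m, c in zip(self.marker_names, row)
                if c != MISSING_CALL}


# ---------------------------------------------------------------------------
# haplogroup tree


@dataclass
class TreeNode:
    name: str
    parent: str | None
    markers: tuple[str, ...]


@dataclass
class HaplogroupTree:
    """Rooted tree whose branches are defined by binary markers.

    Each non-root node owns the markers of the branch joining it to its
    parent; a marker may appear on at most one branch.
    """

    nodes: dict[str, TreeNode]
    root: str

    def __post_init__(self) -> None:
        if self.root not in self.nodes:
            raise TreeError(f"root {self.root!r} is not a node")
        if self.nodes[self.root].parent is not None:
            raise TreeError("root must have no parent")
        roots = [n for n in self.nodes.values() if n.parent is None]
        if len(roots) != 1:
            raise TreeError(f"expected a single root, found {len(roots)}")
        seen_markers: dict[str, str] = {}
        for node in self.nodes.values():
            if node.parent is not None and node.parent not in self.nodes:
                raise TreeError(f"unknown parent {node.parent!r} of {node.name!r}")
            for m in node.markers:
                if m in seen_markers:
                    raise TreeError(
                        f"marker {m!r} defines both {seen_markers[m]!r} "
                        f"and {node.name!r}"
                    )
                seen_markers[m] = node.name
        # acyclicity: walking to the root must terminate for every node
        for name in self.nodes:
            seen = set()
            cur: str | None = name
            while cur is not None:
                if cur in seen:
                    raise TreeError(f"cycle through node {cur!r}")
                seen.add(cur)
                cur = self.nodes[cur].parent

    def path_to_root(self, name: str) -> list[str]:
        """Node names from the root down to ``name`` inclusive."""
        path = []
        cur: str | None = name
        while cur is not None:
            path.append(cur)
            cur = self.nodes[cur].parent
        return path[::-1]

    def depth(self, name: str) -> int:
        return len(self.path_to_root(name)) - 1

    def children(self, name: str) -> list[str]:
        return [n.name for n in self.nodes.values() if n.parent == name]

    def marker_to_node(self) -> dict[str, str]:
        return {m: node.name for node in self.nodes.values()
                for m in node.markers}

    def names_in_preorder(self) -> list[str]:
        order: list[str] = []

        def visit(name: str) -> None:
            order.append(name)
            for child in self.children(name):
                visit(child)

        visit(self.root)
        return order


# ---------------------------------------------------------------------------
# reference table


@dataclass
class ReferenceTable:
    """Simulated (model, parameters, summary statistics) rows for ABC.

    All rows share one statistic name order; rows whose statistics include
    undefined values are kept and marked in ``flags`` so the selection stage
    can impute rather than silently shrink the table.
    """

    model_ids: np.ndarray          # object array of model labels
    param_names: list[str]
    params: np.ndarray             # n x P float
    stat_names: list[str]
    stats: np.ndarray              # n x S float, NaN where undefined
    flags: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.model_ids = np.asarray(self.model_ids, dtype=object)
        self.params = np.atleast_2d(np.asarray(self.params, dtype=float))
        self.stats = np.atleast_2d(np.asarray(self.stats, dtype=float))
        n = len(self.model_ids)
        if n == 0:
            self.params = self.params.reshape(0, len(self.param_names))
            self.stats = self.stats.reshape(0, len(self.stat_names))
        if self.params.shape != (n, len(self.param_names)):
            raise FormatError("parameter matrix does not match names")
        if self.stats.shape != (n, len(self.stat_names)):
            raise FormatError("statistic matrix does not match names")
        if self.flags is None:
            self.flags = np.isnan(self.stats).any(axis=1)
        self.flags = np.asarray(self.flags, dtype=bool)

    @property
    def n_rows(self) -> int:
        return len(self.model_ids)

    @staticmethod
    def concatenate(tables: list["ReferenceTable"]) -> "ReferenceTable":
        first = tables[0]
        for t in tables[1:]:
            if t.stat_names != first.stat_names:
                raise FormatError("statistic name order differs between tables")
            if t.param_names != first.param_names:
                raise FormatError("parameter name order differs between tables")
        return ReferenceTable(
            model_ids=np.concatenate([t.model_ids for t in tables]),
            param_names=first.param_names,
            params=np.vstack([t.params for t in tables]),
            stat_names=first.stat_names,
            stats=np.vstack([t.stats for t in tables]),
            flags=np.concatenate([t.flags for t in tables]),
        )


# ---------------------------------------------------------------------------
# readers / writers


def read_sequence_panel(fasta_path, metadata_path) -> SequencePanel:
    """Read an aligned FASTA plus a sample_id/population TSV.

    Samples keep file order; every FASTA record id must appear in the
    metadata table.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise FormatError(f"no FASTA records in {fasta_path}")
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    for col in ("sample_id", "population"):
        if col not in meta.columns:
            raise FormatError(f"metadata lacks required column {col!r}")
    pop_of = dict(zip(meta["sample_id"], meta["population"]))
    sample_ids, populations, sequences = [], [], []
    for rec in records:
        if rec.id not in pop_of:
            raise CrossRefError(f"sample {rec.id!r} absent from metadata")
        sample_ids.append(rec.id)
        populations.append(pop_of[rec.id])
        sequences.append(str(rec.seq).upper())
    locus_length = len(sequences[0])
    return SequencePanel(sample_ids, populations, sequences, locus_length)


def write_sequence_panel(panel: SequencePanel, fasta_path, metadata_path) -> None:
    with open(fasta_path, "w") as fh:
        for sid, seq in zip(panel.sample_ids, panel.sequences):
            fh.write(f">{sid}\n{seq}\n")
    pd.DataFrame(
        {"sample_id": panel.sample_ids, "population": panel.populations}
    ).to_csv(metadata_path, sep="\t", index=False)


def read_str_panel(tsv_path) -> STRPanel:
    """Read a TSV of integer repeat counts (columns: sample_id, population,
    then one column per locus).  Intermediate (non-integer) alleles are
    rejected: the stepwise mutation model underlying every downstream use
    requires whole repeat counts."""
    df = pd.read_csv(tsv_path, sep="\t", dtype=str)
    for col in ("sample_id", "population"):
        if col not in df.columns:
            raise FormatError(f"STR table lacks required column {col!r}")
    locus_names = [c for c in df.columns if c not in ("sample_id", "population")]
    n = len(df)
    repeats = np.empty((n, len(locus_names)), dtype=np.int64)
    for j, locus in enumerate(locus_names):
        for i, raw in enumerate(df[locus]):
            raw = str(raw).strip()
            if raw == MISSING_TOKEN or raw == "nan":
                repeats[i, j] = MISSING_REPEAT
                continue
            try:
                repeats[i, j] = int(raw)
            except ValueError:
                raise FormatError(
                    f"non-integer allele {raw!r} at sample "
                    f"{df['sample_id'][i]!r}, locus {locus!r}"
                ) from None
    return STRPanel(list(df["sample_id"]), list(df["population"]),
                    locus_names, repeats)


def write_str_panel(panel: STRPanel, tsv_path) -> None:
    df = pd.DataFrame(panel.repeats, columns=panel.locus_names)
    df = df.astype(object).where(panel.repeats != MISSING_REPEAT, MISSING_TOKEN)
    df.insert(0, "population", panel.populations)
    df.insert(0, "sample_id", panel.sample_ids)
    df.to_csv(tsv_path, sep="\t", index=False)


def read_marker_panel(tsv_path) -> MarkerPanel:
    """Read binary marker calls; tokens A/D/0/1/ancestral/derived/NA."""
    df = pd.read_csv(tsv_path, sep="\t", dtype=str)
    for col in ("sample_id", "population"):
        if col not in df.columns:
            raise FormatError(f"marker table lacks required column {col!r}")
    marker_names = [c for c in df.columns if c not in ("sample_id", "population")]
    calls = np.empty((len(df), len(marker_names)), dtype=np.int8)
    for j, marker in enumerate(marker_names):
        for i, raw in enumerate(df[marker]):
            raw = str(raw).strip()
            if raw == "nan":
                raw = MISSING_TOKEN
            if raw not in _CALL_TOKENS:
                raise FormatError(
                    f"unknown call {raw!r} at sample {df['sample_id'][i]!r}, "
                    f"marker {marker!r}"
                )
            calls[i, j] = _CALL_TOKENS[raw]
    return MarkerPanel(list(df["sample_id"]), list(df["population"]),
                       marker_names, calls)


def write_marker_panel(panel: MarkerPanel, tsv_path) -> None:
    token = {ANCESTRAL: "A", DERIVED: "D", MISSING_CALL: MISSING_TOKEN}
    df = pd.DataFrame(
        [[token[int(c)] for c in row] for row in panel.calls],
        columns=panel.marker_names,
    )
    df.insert(0, "population", panel.populations)
    df.insert(0, "sample_id", panel.sample_ids)
    df.to_csv(tsv_path, sep="\t", index=False)


def read_haplogroup_tree(path) -> HaplogroupTree:
    """Parse a node-per-line tree file.

    Each non-comment line is ``name<TAB>parent<TAB>markers`` where parent is
    ``-`` for the root and markers is a comma-separated list (``-`` for
    none).  Validation (single root, acyclicity, unique markers) happens in
    :class:`HaplogroupTree`.
    """
    nodes: dict[str, TreeNode] = {}
    root = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise TreeError(f"{path}:{lineno}: expected 3 tab-separated fields")
            name, parent, markers_raw = (p.strip() for p in parts)
            if name in nodes:
                raise TreeError(f"{path}:{lineno}: duplicate node {name!r}")
            markers = tuple(
                m.strip() for m in markers_raw.split(",")
                if m.strip() and m.strip() != "-"
            )
            parent_name = None if parent == "-" else parent
            if parent_name is None:
                root = name
            nodes[name] = TreeNode(name, parent_name, markers)
    if root is None:
        raise TreeError(f"{path}: no root node (parent '-') found")
    return HaplogroupTree(nodes, root)


def write_haplogroup_tree(tree: HaplogroupTree, path) -> None:
    with open(path, "w") as fh:
        for name in tree.names_in_preorder():
            node = tree.nodes[name]
            parent = node.parent if node.parent is not None else "-"
            markers = ",".join(node.markers) if node.markers else "-"
            fh.write(f"{name}\t{parent}\t{markers}\n")


_REF_FLOAT_FMT = "%.17g"


def write_reference_table(table: ReferenceTable, path) -> None:
    """CSV with a two-line role header (statistic names, parameter names)
    ahead of the column header, so the statistic/parameter split survives
    tools that only see a flat CSV."""
    with open(path, "w") as fh:
        fh.write("#stats," + ",".join(table.stat_names) + "\n")
        fh.write("#params," + ",".join(table.param_names) + "\n")
        cols = ["model_id", "flagged", *table.param_names, *table.stat_names]
        fh.write(",".join(cols) + "\n")
        for i in range(table.n_rows):
            row = [str(table.model_ids[i]), "1" if table.flags[i] else "0"]
            row += [_REF_FLOAT_FMT % v for v in table.params[i]]
            row += [_REF_FLOAT_FMT % v for v in table.stats[i]]
            fh.write(",".join(row) + "\n")


def read_reference_table(path) -> ReferenceTable:
    with open(path) as fh:
        stats_line = fh.readline().strip()
        params_line = fh.readline().strip()
        if not stats_line.startswith("#stats,") and stats_line != "#stats":
            raise FormatError(f"{path}: missing #stats header line")
        if not params_line.startswith("#params,") and params_line != "#params":
            raise FormatError(f"{path}: missing #params header line")
        stat_names = [s for s in stats_line.split(",")[1:] if s]
        param_names = [s for s in params_line.split(",")[1:] if s]
        body = fh.read()
    expected_cols = ["model_id", "flagged", *param_names, *stat_names]
    df = pd.read_csv(io.StringIO(body), float_precision="round_trip") \
        if body.strip() else None
    if df is None:
        header = body.strip()
        return ReferenceTable(
            model_ids=np.empty(0, dtype=object), param_names=param_names,
            params=np.empty((0, len(param_names))), stat_names=stat_names,
            stats=np.empty((0, len(stat_names))),
            flags=np.empty(0, dtype=bool),
        )
    if list(df.columns) != expected_cols:
        raise FormatError(
            f"{path}: column header does not match the role header lines"
        )
    return ReferenceTable(
        model_ids=df["model_id"].to_numpy(dtype=object),
        param_names=param_names,
        params=df[param_names].to_numpy(dtype=float),
        stat_names=stat_names,
        stats=df[stat_names].to_numpy(dtype=float),
        flags=df["flagged"].to_numpy(dtype=bool),
    )
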