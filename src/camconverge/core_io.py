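"""Domain data model and readers/writers for every format the pipeline touches.

The pipeline compares diel (24-h light/dark cycle) transcript time-courses
across species and screens gene trees plus protein alignments for convergent
substitutions, so the data model covers replicate-resolved FPKM time-courses,
ortholog-group membership, multiple sequence alignments, species-labelled gene
trees, and gene-gene similarity graphs derived from BLASTp E-values.

All readers validate their inputs against the type invariants and raise
:class:`ValidationError` / :class:`FormatError` instead of silently coercing.
"""

from __future__ import annotations

import json
import math
import re
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import networkx as nx
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ValidationError",
    "FormatError",
    "CANONICAL_TIMES",
    "AMINO_ACIDS",
    "GAP",
    "DielProfile",
    "DielMatrix",
    "OrthologGroup",
    "TimeWindowScheme",
    "MSA",
    "GeneTree",
    "SimilarityGraph",
    "read_expression_table",
    "write_expression_table",
    "read_orthogroups",
    "write_orthogroups",
    "read_alignment_fasta",
    "write_alignment_fasta",
    "read_tree_newick",
    "write_tree_newick",
    "read_similarity_graph",
    "write_similarity_graph",
    "write_results",
    "read_results",
]


class ValidationError(ValueError):
    """Input violates a data-model invariant."""


class FormatError(ValueError):
    """Input file does not conform to the expected layout."""


#: Canonical diel sampling grid: hours after light onset, 2-h steps over 24 h.
CANONICAL_TIMES: tuple[float, ...] = tuple(float(h) for h in range(2, 25, 2))

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"

_LABEL_RE = re.compile(r"^(?P<species>[^|]+)\|(?P<gene>.+)$")


def split_label(label: str) -> tuple[str, str]:
    """Split a ``Species|gene_id`` leaf/record label into (species, gene_id)."""
    m = _LABEL_RE.match(label)
    if m is None:
        raise ValidationError(f"label {label!r} lacks a 'Species|gene_id' tag")
    return m.group("species"), m.group("gene")


# ---------------------------------------------------------------------------
# Expression time-courses
# ---------------------------------------------------------------------------


@dataclass
class DielProfile:
    """Replicate-resolved FPKM time-course of one gene on the circular 24-h clock.

    ``times`` are hours after light onset in (0, 24] (hour 24 is identified
    with hour 0 for circular arithmetic); ``values`` has shape
    (n_times, n_replicates) and holds non-negative FPKM.
    """

    gene_id: str
    species: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        if self.times.ndim != 1 or self.times.size == 0:
            raise ValidationError(f"{self.gene_id}: empty time grid")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError(f"{self.gene_id}: times must be strictly increasing")
        if np.any(self.times <= 0) or np.any(self.times > 24):
            raise ValidationError(f"{self.gene_id}: times must lie in (0, 24]")
        if self.values.shape[0] != self.times.size:
            raise ValidationError(
                f"{self.gene_id}: values rows ({self.values.shape[0]}) "
                f"!= number of times ({self.times.size})"
            )
        if self.values.shape[1] < 1:
            raise ValidationError(f"{self.gene_id}: at least one replicate required")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError(f"{self.gene_id}: non-finite abundance value")
        if np.any(self.values < 0):
            raise ValidationError(f"{self.gene_id}: negative abundance value")

    @property
    def n_replicates(self) -> int:
        return self.values.shape[1]

    def mean_series(self) -> np.ndarray:
        """Replicate-mean abundance at each time point."""
        return self.values.mean(axis=1)

    def on_canonical_grid(self) -> bool:
        return self.times.size == len(CANONICAL_TIMES) and np.allclose(
            self.times, CANONICAL_TIMES
        )

    def is_degenerate(self, atol: float = 0.0) -> bool:
        """True when the replicate-mean series has (near-)zero variance."""
        m = self.mean_series()
        return bool(np.ptp(m) <= atol)


@dataclass
class DielMatrix:
    """All diel profiles of one species, sharing a single sampling grid."""

    species: str
    profiles: dict[str, DielProfile] = field(default_factory=dict)
    light_hours: float = 12.0
    dark_hours: float = 12.0

    def __post_init__(self) -> None:
        grid = None
        for gid, prof in self.profiles.items():
            if gid != prof.gene_id:
                raise ValidationError(f"profile key {gid!r} != gene_id {prof.gene_id!r}")
            if grid is None:
                grid = prof.times
            elif prof.times.shape != grid.shape or not np.allclose(prof.times, grid):
                raise ValidationError(
                    f"{self.species}: profile {gid} is not on the shared grid"
                )

    def add(self, profile: DielProfile) -> None:
        if profile.gene_id in self.profiles:
            raise ValidationError(f"duplicate gene_id {profile.gene_id!r}")
        if self.profiles:
            grid = next(iter(self.profiles.values())).times
            if profile.times.shape != grid.shape or not np.allclose(profile.times, grid):
                raise ValidationError(
                    f"{self.species}: profile {profile.gene_id} is not on the shared grid"
                )
        self.profiles[profile.gene_id] = profile

    def __len__(self) -> int:
        return len(self.profiles)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.profiles

    def __getitem__(self, gene_id: str) -> DielProfile:
        return self.profiles[gene_id]

    @property
    def times(self) -> np.ndarray:
        if not self.profiles:
            return np.asarray(CANONICAL_TIMES)
        return next(iter(self.profiles.values())).times


@dataclass
class OrthologGroup:
    """Cross-species gene membership: mapping species tag -> list of gene ids."""

    group_id: str
    members: dict[str, list[str]]

    def __post_init__(self) -> None:
        if not any(len(v) > 0 for v in self.members.values()):
            raise ValidationError(f"{self.group_id}: no members")
        seen: set[str] = set()
        for genes in self.members.values():
            for g in genes:
                if g in seen:
                    raise ValidationError(f"{self.group_id}: duplicate gene {g!r}")
                seen.add(g)

    def genes(self, species: str) -> list[str]:
        return list(self.members.get(species, []))

    def all_genes(self) -> list[str]:
        return [g for genes in self.members.values() for g in genes]


@dataclass(frozen=True)
class TimeWindowScheme:
    """The four diel time windows and their opposite-window mapping.

    Defaults follow the canonical scheme: dawn = {22, 24, 2}, midday =
    {4, 6, 8}, dusk = {10, 12, 14}, midnight = {16, 18, 20}; dawn is opposite
    dusk and midday opposite midnight.
    """

    windows: Mapping[str, frozenset[float]] = field(
        default_factory=lambda: {
            "dawn": frozenset({22.0, 24.0, 2.0}),
            "midday": frozenset({4.0, 6.0, 8.0}),
            "dusk": frozenset({10.0, 12.0, 14.0}),
            "midnight": frozenset({16.0, 18.0, 20.0}),
        }
    )

    def __post_init__(self) -> None:
        pts: list[float] = []
        for w in self.windows.values():
            pts.extend(w)
        if sorted(pts) != sorted(CANONICAL_TIMES):
            raise ValidationError("windows must partition the canonical 2-h grid")

    def opposite(self, window: str) -> str:
        pairs = {"dawn": "dusk", "dusk": "dawn", "midday": "midnight", "midnight": "midday"}
        return pairs[window]

    @property
    def contrasts(self) -> tuple[tuple[str, str], ...]:
        return (("midday", "midnight"), ("dawn", "dusk"))

    def mask(self, window: str, times: np.ndarray) -> np.ndarray:
        pts = self.windows[window]
        return np.asarray([t in pts for t in times])


# ---------------------------------------------------------------------------
# Alignments, trees, similarity graphs
# ---------------------------------------------------------------------------


@dataclass
class MSA:
    """Protein multiple sequence alignment with species-labelled records.

    Records are ordered ``(seq_id, species, sequence)`` triples; ``seq_id`` is
    the full ``Species|gene_id`` label. Columns are addressed 1-based in all
    reported output.
    """

    records: list[tuple[str, str, str]]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValidationError("alignment has no sequences")
        lengths = {len(seq) for _, _, seq in self.records}
        if len(lengths) != 1:
            raise ValidationError("ragged alignment: sequences differ in length")
        ids = [sid for sid, _, _ in self.records]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate sequence ids in alignment")
        alphabet = set(AMINO_ACIDS + GAP + "X")
        for sid, sp, seq in self.records:
            if not sp:
                raise ValidationError(f"{sid}: missing species label")
            bad = set(seq) - alphabet
            if bad:
                raise ValidationError(f"{sid}: invalid residue(s) {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.records[0][2])

    @property
    def seq_ids(self) -> list[str]:
        return [sid for sid, _, _ in self.records]

    def sequence(self, seq_id: str) -> str:
        for sid, _, seq in self.records:
            if sid == seq_id:
                return seq
        raise KeyError(seq_id)

    def species_of(self, seq_id: str) -> str:
        for sid, sp, _ in self.records:
            if sid == seq_id:
                return sp
        raise KeyError(seq_id)

    def column(self, pos: int) -> dict[str, str]:
        """Residues at 1-based column ``pos``, keyed by seq_id."""
        if not 1 <= pos <= self.length:
            raise IndexError(f"column {pos} outside 1..{self.length}")
        return {sid: seq[pos - 1] for sid, _, seq in self.records}


class GeneTree:
    """Rooted gene tree whose leaves carry (gene_id, species).

    Thin wrapper over a :class:`dendropy.Tree`; leaf taxon labels are the
    ``Species|gene_id`` form shared with alignment records.
    """

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        leaves = self.leaf_labels()
        if len(leaves) < 2:
            raise ValidationError("tree needs at least 2 leaves")
        if len(set(leaves)) != len(leaves):
            raise ValidationError("duplicate leaf labels in tree")
        for lab in leaves:
            split_label(lab)  # validates Species|gene form

    @classmethod
    def from_newick(cls, newick: str) -> "GeneTree":
        tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
        return cls(tree)

    def to_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def leaf_species(self) -> set[str]:
        return {split_label(l)[0] for l in self.leaf_labels()}

    def is_binary_rooted(self) -> bool:
        return len(self.tree.seed_node.child_nodes()) == 2

    def ensure_rooted(self) -> None:
        """Midpoint-root a tree read with a basal polytomy.

        Clade membership is only defined on a rooted tree; trees arriving with
        a trifurcating base are midpoint-rooted (warning emitted). Without
        branch lengths midpoint rooting is impossible and an error instructs
        the caller to root first.
        """
        if self.is_binary_rooted():
            return
        lengths = [e.length for e in self.tree.preorder_edge_iter() if e.head_node.parent_node]
        if any(l is None for l in lengths):
            raise ValidationError(
                "tree is unrooted and lacks branch lengths; root it before screening"
            )
        warnings.warn("unrooted input tree: applying midpoint rooting", stacklevel=2)
        self.tree.reroot_at_midpoint(update_bipartitions=True)

    def bipartitions(self) -> set[frozenset[str]]:
        """Leaf-set bipartitions (smaller-side leaf sets), for topology equality."""
        all_leaves = frozenset(self.leaf_labels())
        out: set[frozenset[str]] = set()
        for node in self.tree.preorder_node_iter():
            if node.is_leaf() or node is self.tree.seed_node:
                continue
            side = frozenset(lf.taxon.label for lf in node.leaf_iter())
            other = all_leaves - side
            out.add(min(side, other, key=lambda s: (len(s), sorted(s))))
        return out


@dataclass
class SimilarityGraph:
    """Undirected gene-gene similarity graph with E-value edge annotations.

    Edge weights used by Markov clustering are ``-log10(max(E, 1e-180))``;
    self-loops are rejected on input (MCL adds its own).
    """

    graph: nx.Graph = field(default_factory=nx.Graph)

    def __post_init__(self) -> None:
        for u, v in self.graph.edges():
            if u == v:
                raise ValidationError(f"self-loop on {u!r}")
        for u, v, d in self.graph.edges(data=True):
            e = d.get("evalue")
            if e is None or e < 0:
                raise ValidationError(f"edge ({u},{v}) lacks a valid E-value")

    def add_edge(self, a: str, b: str, evalue: float) -> None:
        if a == b:
            raise ValidationError(f"self-loop on {a!r}")
        if evalue < 0:
            raise ValidationError("negative E-value")
        self.graph.add_edge(a, b, evalue=float(evalue))

    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes())

    @staticmethod
    def weight_from_evalue(evalue: float) -> float:
        return -math.log10(max(evalue, 1e-180))


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_COL_RE = re.compile(r"^t(?P<hour>\d+(?:\.\d+)?)_r(?P<rep>\d+)$")


def read_expression_table(path, species: str) -> DielMatrix:
    """Read a diel expression TSV (columns ``gene_id``, ``t<hour>_r<rep>``)."""
    df = pd.read_csv(path, sep="\t", dtype={0: str}, float_precision="round_trip")
    if df.columns[0] != "gene_id":
        raise FormatError(f"{path}: first column must be 'gene_id', got {df.columns[0]!r}")
    slots: list[tuple[float, int, str]] = []
    for col in df.columns[1:]:
        m = _COL_RE.match(col)
        if m is None:
            raise FormatError(f"{path}: unrecognized column {col!r} (expected t<hour>_r<rep>)")
        slots.append((float(m.group("hour")), int(m.group("rep")), col))
    if not slots:
        raise FormatError(f"{path}: no time/replicate columns")
    hours = sorted({h for h, _, _ in slots})
    reps = sorted({r for _, r, _ in slots})
    col_of = {(h, r): c for h, r, c in slots}
    missing = [(h, r) for h in hours for r in reps if (h, r) not in col_of]
    if missing:
        raise FormatError(f"{path}: incomplete time x replicate design, missing {missing[:3]}")

    matrix = DielMatrix(species=species)
    for _, row in df.iterrows():
        gid = row["gene_id"]
        vals = np.empty((len(hours), len(reps)))
        for i, h in enumerate(hours):
            for j, r in enumerate(reps):
                v = row[col_of[(h, r)]]
                try:
                    vals[i, j] = float(v)
                except (TypeError, ValueError) as exc:
                    raise ValidationError(f"{path}: unparseable value {v!r} for {gid}") from exc
        matrix.add(DielProfile(gene_id=gid, species=species, times=np.asarray(hours), values=vals))
    return matrix


def write_expression_table(matrix: DielMatrix, path) -> None:
    rows = []
    for gid in sorted(matrix.profiles):
        prof = matrix[gid]
        row: dict[str, object] = {"gene_id": gid}
        for i, h in enumerate(prof.times):
            for j in range(prof.n_replicates):
                row[f"t{h:g}_r{j + 1}"] = repr(float(prof.values[i, j]))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_orthogroups(path) -> list[OrthologGroup]:
    """Read an ortholog-group TSV (columns group_id, species, gene_id)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    expected = ["group_id", "species", "gene_id"]
    if list(df.columns[:3]) != expected:
        raise FormatError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    order: list[str] = []
    members: dict[str, dict[str, list[str]]] = {}
    gene_home: dict[str, str] = {}
    for _, row in df.iterrows():
        gid, sp, gene = row["group_id"], row["species"], row["gene_id"]
        if gene in gene_home and gene_home[gene] != gid:
            raise ValidationError(
                f"{path}: gene {gene!r} listed in groups {gene_home[gene]!r} and {gid!r}"
            )
        gene_home[gene] = gid
        if gid not in members:
            members[gid] = {}
            order.append(gid)
        members[gid].setdefault(sp, []).append(gene)
    return [OrthologGroup(group_id=g, members=members[g]) for g in order]


def write_orthogroups(groups: Sequence[OrthologGroup], path) -> None:
    rows = [
        {"group_id": g.group_id, "species": sp, "gene_id": gene}
        for g in groups
        for sp, genes in g.members.items()
        for gene in genes
    ]
    pd.DataFrame(rows, columns=["group_id", "species", "gene_id"]).to_csv(
        path, sep="\t", index=False
    )


def read_alignment_fasta(path) -> MSA:
    """Read a protein alignment whose headers are ``Species|gene_id``."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        sp, _ = split_label(rec.id)
        records.append((rec.id, sp, str(rec.seq).upper()))
    return MSA(records=records)


def write_alignment_fasta(msa: MSA, path) -> None:
    recs = [SeqRecord(Seq(seq), id=sid, description="") for sid, _, seq in msa.records]
    SeqIO.write(recs, str(path), "fasta")


def read_tree_newick(path) -> GeneTree:
    with open(path) as fh:
        return GeneTree.from_newick(fh.read())


def write_tree_newick(tree: GeneTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")


def read_similarity_graph(path) -> SimilarityGraph:
    """Read a similarity edge list TSV (columns gene_a, gene_b, evalue)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
    expected = ["gene_a", "gene_b", "evalue"]
    if list(df.columns[:3]) != expected:
        raise FormatError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    g = SimilarityGraph()
    for _, row in df.iterrows():
        g.add_edge(row["gene_a"], row["gene_b"], float(row["evalue"]))
    return g


def write_similarity_graph(graph: SimilarityGraph, path) -> None:
    rows = [
        {"gene_a": u, "gene_b": v, "evalue": _fmt(d["evalue"])}
        for u, v, d in sorted(graph.graph.edges(data=True))
    ]
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "evalue"]).to_csv(path, sep="\t", index=False)


def _fmt(x) -> object:
    """Serialize floats at 6 significant digits; pass everything else through."""
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    if isinstance(x, (float, np.floating)):
        if math.isnan(x):
            return float("nan")
        return float(f"{x:.6g}")
    if isinstance(x, (int, np.integer)):
        return int(x)
    return x


def write_results(calls: Sequence, path, format: str = "tsv") -> None:
    """Write screen calls (objects exposing ``to_record()``) to TSV or JSON.

    Column order follows the first record; floats are serialized at 6
    significant digits so that re-reading reproduces verdicts exactly.
    """
    records = [{k: _fmt(v) for k, v in c.to_record().items()} for c in calls]
    if format == "tsv":
        if records:
            df = pd.DataFrame(records, columns=list(records[0].keys()))
        else:
            df = pd.DataFrame(columns=["gene_id"])
        df.to_csv(path, sep="\t", index=False)
    elif format == "json":
        with open(path, "w") as fh:
            json.dump(records, fh, indent=1, allow_nan=True)
            fh.write("\n")
    else:
        raise ValueError(f"unknown results format {format!r}")


def read_results(path, format: str = "tsv") -> list[dict]:
    if format == "tsv":
        df = pd.read_csv(path, sep="\t")
        return df.to_dict(orient="records")
    if format == "json":
        with open(path) as fh:
            return json.load(fh)
    raise ValueError(f"unknown results format {format!r}")
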