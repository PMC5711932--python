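"""Sequence arm of the convergence screen.

Protein families ("tribes") are built by Markov clustering of a BLASTp-style
similarity graph; per-tribe gene trees are screened for CAM-convergence
clades (clades joining the eudicot CAM gene with at least one monocot CAM
gene and containing no C3/C4 genes); Fitch parsimony reconstructs ancestral
residues so that convergent versus divergent substitutions can be counted on
a pair of non-adjacent branches; and alignment columns at which all CAM
foreground sequences share a residue absent from the C3/C4 background are
reported as convergent sites (the classic case being an aspartate shared by
the CAM lineages where the background carries R/K/H).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core_io import (
    AMINO_ACIDS,
    GAP,
    GeneTree,
    MSA,
    SimilarityGraph,
    ValidationError,
    split_label,
)

__all__ = [
    "TribeSet",
    "CamCladeCall",
    "ConvergentSite",
    "ConvDivCount",
    "SequenceConvergenceCall",
    "mcl_cluster",
    "find_cam_clades",
    "shared_substitution_sites",
    "fitch_ancestral",
    "count_conv_div",
    "convergence_null_fraction",
    "screen_sequence_convergence",
]

logger = logging.getLogger(__name__)

CAM_ROLES = {"CAM_dicot", "CAM_monocot"}
BACKGROUND_ROLES = {"C3", "C4"}


# ---------------------------------------------------------------------------
# Tribes via Markov clustering
# ---------------------------------------------------------------------------


@dataclass
class TribeSet:
    """Partition of similarity-graph nodes into protein tribes."""

    tribes: list[frozenset[str]]
    inflation: float
    evalue_cutoff: float

    def partition(self) -> dict[str, int]:
        return {n: i for i, tribe in enumerate(self.tribes) for n in tribe}

    def __len__(self) -> int:
        return len(self.tribes)


def mcl_cluster(
    graph: SimilarityGraph,
    inflation: float = 5.0,
    evalue_cutoff: float = 1e-5,
    prune: float = 1e-8,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> TribeSet:
    """Markov clustering of the similarity graph into tribes.

    Edges with E-value above ``evalue_cutoff`` are discarded; surviving edges
    get weight -log10(max(E, 1e-180)). Self-loops are added with each node's
    maximum incident weight, columns are normalized to stochastic, and the
    expansion (matrix square) / inflation (elementwise power, renormalize)
    cycle runs with pruning threshold ``prune`` until the matrix changes by
    less than ``tol`` or ``max_iter`` iterations. Clusters are the connected
    components of the converged matrix's support.
    """
    nodes = sorted(graph.graph.nodes())
    if not nodes:
        return TribeSet(tribes=[], inflation=inflation, evalue_cutoff=evalue_cutoff)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    M = np.zeros((n, n))
    for u, v, d in graph.graph.edges(data=True):
        if d["evalue"] > evalue_cutoff:
            continue
        w = SimilarityGraph.weight_from_evalue(d["evalue"])
        if w <= 0:
            continue
        M[idx[u], idx[v]] = M[idx[v], idx[u]] = w
    # self-loops: each node's maximum incident weight (1 for isolated nodes)
    for i in range(n):
        inc = M[i].max()
        M[i, i] = inc if inc > 0 else 1.0
    M = M / M.sum(axis=0, keepdims=True)
    for _ in range(max_iter):
        prev = M
        M = M @ M  # expansion
        M = M**inflation  # inflation
        M[M < prune] = 0.0
        colsum = M.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        M = M / colsum
        if np.max(np.abs(M - prev)) < tol:
            break
    support = (M > prune) | (M.T > prune)
    np.fill_diagonal(support, True)
    # connected components of the support graph
    seen = np.zeros(n, dtype=bool)
    tribes: list[frozenset[str]] = []
    for start in range(n):
        if seen[start]:
            continue
        stack = [start]
        comp = []
        seen[start] = True
        while stack:
            i = stack.pop()
            comp.append(nodes[i])
            for j in np.nonzero(support[i])[0]:
                if not seen[j]:
                    seen[j] = True
                    stack.append(int(j))
        tribes.append(frozenset(comp))
    tribes.sort(key=lambda t: sorted(t)[0])
    return TribeSet(tribes=tribes, inflation=inflation, evalue_cutoff=evalue_cutoff)


# ---------------------------------------------------------------------------
# CAM-convergence clades
# ---------------------------------------------------------------------------


@dataclass
class CamCladeCall:
    """One maximal clade satisfying the CAM-convergence rule."""

    leaves: frozenset[str]
    contains_kf: bool
    monocot_cam_species: frozenset[str]
    verdict: bool

    def cam_members(self, roles: Mapping[str, str]) -> list[str]:
        return sorted(
            l for l in self.leaves if roles[split_label(l)[0]] in CAM_ROLES
        )


def _leaf_roles(leaves: Iterable[str], roles: Mapping[str, str]) -> list[tuple[str, str]]:
    out = []
    for lab in leaves:
        sp, _ = split_label(lab)
        if sp not in roles:
            raise ValidationError(f"species {sp!r} has no declared role")
        out.append((lab, roles[sp]))
    return out


def _clade_qualifies(leaves: Iterable[str], roles: Mapping[str, str]) -> CamCladeCall | None:
    pairs = _leaf_roles(leaves, roles)
    has_dicot = any(r == "CAM_dicot" for _, r in pairs)
    monocots = frozenset(split_label(l)[0] for l, r in pairs if r == "CAM_monocot")
    has_bg = any(r in BACKGROUND_ROLES for _, r in pairs)
    verdict = has_dicot and bool(monocots) and not has_bg
    if not verdict:
        return None
    return CamCladeCall(
        leaves=frozenset(l for l, _ in pairs),
        contains_kf=has_dicot,
        monocot_cam_species=monocots,
        verdict=True,
    )


def find_cam_clades(tree: GeneTree, roles: Mapping[str, str]) -> list[CamCladeCall]:
    """All maximal clades with >=1 CAM-dicot leaf, >=1 CAM-monocot leaf and no
    C3/C4 leaf ("other"-role leaves are permitted inside).

    Maximality: the parent clade violates the rule (the root, having no
    parent, is maximal if it qualifies). Requires a rooted tree; basal
    polytomies trigger midpoint rooting (see :meth:`GeneTree.ensure_rooted`).
    """
    tree.ensure_rooted()
    calls: list[CamCladeCall] = []
    for node in tree.tree.preorder_node_iter():
        if node.is_leaf():
            continue
        leaves = [lf.taxon.label for lf in node.leaf_iter()]
        call = _clade_qualifies(leaves, roles)
        if call is None:
            continue
        parent = node.parent_node
        if parent is not None:
            parent_leaves = [lf.taxon.label for lf in parent.leaf_iter()]
            if _clade_qualifies(parent_leaves, roles) is not None:
                continue  # not maximal
        calls.append(call)
    calls.sort(key=lambda c: sorted(c.leaves)[0])
    return calls


# ---------------------------------------------------------------------------
# Shared-substitution sites
# ---------------------------------------------------------------------------


@dataclass
class ConvergentSite:
    """Alignment column (1-based) where the CAM foreground shares a residue
    absent from the C3/C4 background."""

    column: int
    cam_residue: str
    background_residues: frozenset[str]
    n_gaps: int


def shared_substitution_sites(
    msa: MSA,
    foreground: Iterable[str],
    background: Iterable[str],
    max_fg_gap: int = 0,
    min_bg_coverage: float = 0.8,
) -> list[ConvergentSite]:
    """Columns at which every foreground sequence carries one identical
    residue that no background sequence carries.

    Background sequences may differ among themselves (e.g. R/K/H against a
    foreground D); columns where fewer than ``min_bg_coverage`` of the
    background is non-gap are skipped, as are columns with more than
    ``max_fg_gap`` foreground gaps.
    """
    fg = sorted(set(foreground))
    bg = sorted(set(background))
    if not fg:
        raise ValidationError("foreground set is empty")
    fg_seqs = [msa.sequence(s) for s in fg]
    bg_seqs = [msa.sequence(s) for s in bg]
    sites: list[ConvergentSite] = []
    for col in range(msa.length):
        fg_states = [s[col] for s in fg_seqs]
        n_fg_gaps = sum(1 for x in fg_states if x == GAP)
        if n_fg_gaps > max_fg_gap:
            continue
        residues = {x for x in fg_states if x != GAP}
        if len(residues) != 1:
            continue
        (cam_res,) = residues
        bg_states = [s[col] for s in bg_seqs]
        n_bg_gaps = sum(1 for x in bg_states if x == GAP)
        if bg_states and (len(bg_states) - n_bg_gaps) < min_bg_coverage * len(bg_states):
            continue
        bg_residues = {x for x in bg_states if x != GAP}
        if cam_res in bg_residues:
            continue
        if not bg_residues:
            continue  # no informative background at this column
        sites.append(
            ConvergentSite(
                column=col + 1,
                cam_residue=cam_res,
                background_residues=frozenset(bg_residues),
                n_gaps=n_fg_gaps + n_bg_gaps,
            )
        )
    return sites


# ---------------------------------------------------------------------------
# Fitch parsimony and convergent/divergent substitution counts
# ---------------------------------------------------------------------------


def fitch_ancestral(
    tree: GeneTree, leaf_states: Mapping[str, str | None]
) -> tuple[dict, int]:
    """One minimum-change Fitch labeling for a single character column.

    ``leaf_states`` maps leaf labels to residues; gaps/missing are given as
    None and excluded from state sets. Ties during the top-down pass prefer
    the parent's state, then the alphabetically first state. Returns
    (node -> state dict keyed by dendropy nodes, parsimony score). Polytomies
    are folded child-by-child (exact on binary trees).

    Raises when every leaf is missing (the column carries no signal).
    """
    tree.ensure_rooted()
    states: dict = {}
    sets: dict = {}
    score = 0
    for node in tree.tree.postorder_node_iter():
        if node.is_leaf():
            st = leaf_states.get(node.taxon.label)
            sets[node] = None if st is None or st == GAP else frozenset({st})
            continue
        cur: frozenset | None = None
        for child in node.child_nodes():
            s = sets[child]
            if s is None:
                continue
            if cur is None:
                cur = s
            elif cur & s:
                cur = cur & s
            else:
                cur = cur | s
                score += 1
        sets[node] = cur
    root = tree.tree.seed_node
    if sets[root] is None:
        raise ValidationError("all leaves missing at this column")
    for node in tree.tree.preorder_node_iter():
        s = sets[node]
        if s is None:
            states[node] = None
            continue
        parent = node.parent_node
        if parent is not None and states.get(parent) in s:
            states[node] = states[parent]
        else:
            states[node] = min(s)
    return states, score


@dataclass
class ConvDivCount:
    """Convergent vs divergent substitution counts on a branch pair."""

    branch_a: str
    branch_b: str
    n_convergent: int
    n_divergent: int
    null_expected_convergent_fraction: float
    convergent_columns: list[int] = field(default_factory=list)
    divergent_columns: list[int] = field(default_factory=list)


def _find_node(tree: GeneTree, leaf_label: str):
    for lf in tree.tree.leaf_node_iter():
        if lf.taxon.label == leaf_label:
            return lf
    raise KeyError(leaf_label)


def count_conv_div(
    tree: GeneTree, msa: MSA, branch_a: str, branch_b: str
) -> ConvDivCount:
    """Count columns where both branches substitute, split by whether they
    arrive at the same (convergent) or different (divergent) residue.

    Branches are named by the leaf (or any node's representative leaf) they
    lead to; the two branches must not share an endpoint, otherwise the
    convergent/divergent comparison is undefined.
    """
    tree.ensure_rooted()
    na, nb = _find_node(tree, branch_a), _find_node(tree, branch_b)
    pa, pb = na.parent_node, nb.parent_node
    if na is nb or na is pb or nb is pa or pa is pb:
        raise ValidationError(f"branches to {branch_a!r} and {branch_b!r} are adjacent")
    leaf_labels = tree.leaf_labels()
    n_conv = n_div = 0
    conv_cols: list[int] = []
    div_cols: list[int] = []
    for col in range(1, msa.length + 1):
        column = msa.column(col)
        leaf_states = {l: (None if column[l] == GAP else column[l]) for l in leaf_labels}
        if all(v is None for v in leaf_states.values()):
            continue
        states, _ = fitch_ancestral(tree, leaf_states)
        sa, spa = states[na], states[pa]
        sb, spb = states[nb], states[pb]
        if None in (sa, spa, sb, spb):
            continue
        if sa != spa and sb != spb:
            if sa == sb:
                n_conv += 1
                conv_cols.append(col)
            else:
                n_div += 1
                div_cols.append(col)
    return ConvDivCount(
        branch_a=branch_a,
        branch_b=branch_b,
        n_convergent=n_conv,
        n_divergent=n_div,
        null_expected_convergent_fraction=convergence_null_fraction(msa),
        convergent_columns=conv_cols,
        divergent_columns=div_cols,
    )


def convergence_null_fraction(msa: MSA) -> float:
    """Probability that two independent substitutions drawn from the
    alignment's amino-acid frequency vector land on the same residue.

    Computed as sum_a pi_a^2 over the gap-free residue frequencies; reported
    alongside convergent/divergent counts as the expected convergent fraction
    among double-substitution columns under independence.
    """
    counts = {a: 0 for a in AMINO_ACIDS}
    total = 0
    for _, _, seq in msa.records:
        for ch in seq:
            if ch in counts:
                counts[ch] += 1
                total += 1
    if total == 0:
        return 0.0
    pi = np.array([counts[a] / total for a in AMINO_ACIDS])
    return float(np.sum(pi**2))


# ---------------------------------------------------------------------------
# Full sequence screen
# ---------------------------------------------------------------------------


@dataclass
class SequenceConvergenceCall:
    """Evidence bundle for one focal (CAM-dicot) gene in one tribe."""

    kf_gene: str
    tribe_id: str
    in_cam_clade: bool = False
    clade_leaves: frozenset[str] = frozenset()
    n_convergent_subs: int = 0
    n_divergent_subs: int = 0
    null_convergent_fraction: float = float("nan")
    sites: list[ConvergentSite] = field(default_factory=list)
    criterion_clade: bool = False
    criterion_convergent_subs: bool = False
    criterion_shared_site: bool = False

    @property
    def convergent(self) -> bool:
        return (
            self.criterion_clade
            and self.criterion_convergent_subs
            and self.criterion_shared_site
        )

    def to_record(self) -> dict:
        return {
            "kf_gene": self.kf_gene,
            "tribe_id": self.tribe_id,
            "in_cam_clade": self.in_cam_clade,
            "clade_size": len(self.clade_leaves),
            "n_convergent_subs": self.n_convergent_subs,
            "n_divergent_subs": self.n_divergent_subs,
            "null_convergent_fraction": self.null_convergent_fraction,
            "site_columns": ";".join(str(s.column) for s in self.sites),
            "criterion_clade": self.criterion_clade,
            "criterion_convergent_subs": self.criterion_convergent_subs,
            "criterion_shared_site": self.criterion_shared_site,
            "convergent": self.convergent,
        }


def screen_sequence_convergence(
    tribes: Mapping[str, tuple[GeneTree, MSA]],
    roles: Mapping[str, str],
    required_species: Iterable[str] | None = None,
    min_bg_coverage: float = 0.8,
) -> list[SequenceConvergenceCall]:
    """Screen tribe trees and alignments for protein-sequence convergence.

    A focal (CAM-dicot) gene is called convergent iff (1) it sits in a
    CAM-convergence clade, (2) parsimony counts at least one convergent
    substitution between its branch and a monocot-CAM branch of the clade,
    and (3) the clade's CAM members share at least one residue absent from
    all C3/C4 background sequences.

    Tribes missing any species in ``required_species`` (default: every
    species with a declared role) are skipped with a log entry, mirroring the
    all-species tribe filter applied before tree building.
    """
    required = set(required_species) if required_species is not None else set(roles)
    calls: list[SequenceConvergenceCall] = []
    for tribe_id in sorted(tribes):
        tree, msa = tribes[tribe_id]
        tree_leaves = set(tree.leaf_labels())
        if tree_leaves != set(msa.seq_ids):
            logger.error("tribe %s: tree/alignment leaf sets differ; skipped", tribe_id)
            continue
        species_present = tree.leaf_species()
        if not required.issubset(species_present):
            logger.info(
                "tribe %s: species coverage failed (missing %s); skipped",
                tribe_id,
                sorted(required - species_present),
            )
            continue
        clades = find_cam_clades(tree, roles)
        background = sorted(
            l for l in tree_leaves if roles[split_label(l)[0]] in BACKGROUND_ROLES
        )
        kf_leaves = sorted(
            l for l in tree_leaves if roles[split_label(l)[0]] == "CAM_dicot"
        )
        for kf_leaf in kf_leaves:
            call = SequenceConvergenceCall(kf_gene=kf_leaf, tribe_id=tribe_id)
            clade = next((c for c in clades if kf_leaf in c.leaves), None)
            if clade is None:
                calls.append(call)
                continue
            call.in_cam_clade = True
            call.criterion_clade = True
            call.clade_leaves = clade.leaves
            monocot_leaves = sorted(
                l
                for l in clade.leaves
                if roles[split_label(l)[0]] == "CAM_monocot"
            )
            best_conv = 0
            best_div = 0
            for ml in monocot_leaves:
                try:
                    cd = count_conv_div(tree, msa, kf_leaf, ml)
                except ValidationError:
                    # adjacent branches: convergence on this pair is not
                    # countable by independent substitutions
                    continue
                call.null_convergent_fraction = cd.null_expected_convergent_fraction
                if cd.n_convergent > best_conv:
                    best_conv, best_div = cd.n_convergent, cd.n_divergent
            call.n_convergent_subs = best_conv
            call.n_divergent_subs = best_div
            call.criterion_convergent_subs = best_conv >= 1
            foreground = clade.cam_members(roles)
            if background:
                call.sites = shared_substitution_sites(
                    msa, foreground, background, min_bg_coverage=min_bg_coverage
                )
            call.criterion_shared_site = len(call.sites) > 0
            calls.append(call)
    return calls
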