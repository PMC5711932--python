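"""Synthetic-data generators for both arms of the convergence screen.

The expression generator emulates three-species ortholog groups with
log-normal (cosinor-mean) diel profiles: a eudicot CAM species and a monocot
CAM species share a peak phase (up to jitter) while the C3 species either
shares the phase too (non-convergent groups) or is displaced by a fixed
antiphase offset (convergent groups). The sequence generator evolves protein
alignments along species-labelled gene trees under a Poisson substitution
process and plants convergent residues on designated foreground lineages.
The similarity-graph generator plants tribes joined only by weak bridges.

All generators are pure functions of (params, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np

from .core_io import (
    AMINO_ACIDS,
    CANONICAL_TIMES,
    DielMatrix,
    DielProfile,
    GeneTree,
    MSA,
    OrthologGroup,
    SimilarityGraph,
    ValidationError,
)

__all__ = [
    "DielSimParams",
    "SeqSimParams",
    "SimTruth",
    "DEFAULT_ROLES",
    "EXPRESSION_SPECIES",
    "simulate_diel_dataset",
    "simulate_msa_with_convergence",
    "simulate_similarity_graph",
    "simulate_sequence_dataset",
    "species_tree_newick",
    "convergence_tree_newick",
]

#: Species tags of the three expression time-courses (focal CAM eudicot,
#: CAM monocot partner, C3 comparator).
EXPRESSION_SPECIES = ("Kf", "Ac", "At")

#: Thirteen-species preset for the sequence arm: one CAM eudicot (Kfe,
#: Kalanchoe-like), two CAM monocots (Aco pineapple-like, Peq orchid-like),
#: six C3 species, two C4 grasses, and two basal "other" species that are
#: neither CAM foreground nor C3/C4 background.
DEFAULT_ROLES: dict[str, str] = {
    "Kfe": "CAM_dicot",
    "Aco": "CAM_monocot",
    "Peq": "CAM_monocot",
    "Ath": "C3",
    "Sly": "C3",
    "Vvi": "C3",
    "Ppe": "C3",
    "Osa": "C3",
    "Bdi": "C3",
    "Sbi": "C4",
    "Zma": "C4",
    "Atr": "other",
    "Smo": "other",
}


@dataclass
class SimTruth:
    """Planted ground truth for recovery testing."""

    group_labels: dict[str, str] = field(default_factory=dict)
    phases: dict[tuple[str, str], float] = field(default_factory=dict)
    planted_genes: set[str] = field(default_factory=set)
    planted_columns: dict[str, list[int]] = field(default_factory=dict)
    planted_residues: dict[str, dict[int, str]] = field(default_factory=dict)
    tribe_partition: list[frozenset[str]] = field(default_factory=list)
    event_log: list[tuple[str, int, str, str]] = field(default_factory=list)

    def convergent_groups(self) -> set[str]:
        return {g for g, l in self.group_labels.items() if l == "convergent"}


# ---------------------------------------------------------------------------
# Diel expression generator
# ---------------------------------------------------------------------------


@dataclass
class DielSimParams:
    """Study conditions for the synthetic three-species diel dataset.

    Log-scale parameters are natural-log units: FPKM(t) =
    exp(B + A cos(2 pi (t - phase)/24) + eps), eps ~ N(0, noise_sd) drawn
    independently per time point and replicate.
    """

    n_groups: int = 500
    frac_convergent: float = 0.1
    frac_flat: float = 0.0
    baseline_log_fpkm: tuple[float, float] = (2.0, 1.0)  # mean, sd
    amplitude: tuple[float, float] = (1.5, 0.3)  # mean, sd (log scale)
    phase_jitter_cam: float = 0.5  # hours, sd
    phase_at_offset: float = 12.0  # hours
    noise_sd: float = 0.2
    n_reps: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.frac_convergent <= 1 or not 0 <= self.frac_flat <= 1:
            raise ValidationError("fractions must lie in [0, 1]")
        if self.frac_convergent + self.frac_flat > 1:
            raise ValidationError("frac_convergent + frac_flat exceeds 1")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.n_reps < 1:
            raise ValidationError("n_reps must be >= 1")


def simulate_diel_dataset(
    params: DielSimParams,
) -> tuple[dict[str, DielMatrix], list[OrthologGroup], SimTruth]:
    """Simulate three-species ortholog groups with controlled phase structure.

    Convergent groups: both CAM species peak at a shared phase (CAM jitter
    applied), the C3 ortholog at phase + phase_at_offset. Non-convergent
    groups: all three species share the phase (CAM jitter on every species).
    Null-flat groups have zero amplitude. One gene per species per group.
    """
    rng = np.random.default_rng(params.seed)
    times = np.asarray(CANONICAL_TIMES)
    n_conv = round(params.frac_convergent * params.n_groups)
    n_flat = round(params.frac_flat * params.n_groups)
    matrices = {sp: DielMatrix(species=sp) for sp in EXPRESSION_SPECIES}
    groups: list[OrthologGroup] = []
    truth = SimTruth()
    b_mean, b_sd = params.baseline_log_fpkm
    a_mean, a_sd = params.amplitude
    for i in range(params.n_groups):
        gid = f"OG{i:04d}"
        if i < n_conv:
            label = "convergent"
        elif i < n_conv + n_flat:
            label = "null-flat"
        else:
            label = "non-convergent"
        truth.group_labels[gid] = label
        phase = rng.uniform(0.0, 24.0)
        baseline = rng.normal(b_mean, b_sd)
        amp = 0.0 if label == "null-flat" else abs(rng.normal(a_mean, a_sd))
        members: dict[str, list[str]] = {}
        for sp in EXPRESSION_SPECIES:
            if label == "convergent" and sp == "At":
                sp_phase = phase + params.phase_at_offset
            else:
                sp_phase = phase + rng.normal(0.0, params.phase_jitter_cam)
            sp_phase = sp_phase % 24.0
            truth.phases[(gid, sp)] = sp_phase
            log_mean = baseline + amp * np.cos(2 * np.pi * (times - sp_phase) / 24.0)
            eps = rng.normal(0.0, params.noise_sd, size=(times.size, params.n_reps))
            values = np.exp(log_mean[:, None] + eps)
            gene = f"{sp}_g{i:04d}"
            members[sp] = [gene]
            matrices[sp].add(
                DielProfile(gene_id=gene, species=sp, times=times, values=values)
            )
        groups.append(OrthologGroup(group_id=gid, members=members))
    return matrices, groups, truth


# ---------------------------------------------------------------------------
# Protein alignment generator
# ---------------------------------------------------------------------------


@dataclass
class SeqSimParams:
    """Study conditions for one simulated tribe alignment."""

    tree_newick: str
    n_sites: int = 200
    n_planted_sites: int = 2
    foreground: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_planted_sites > self.n_sites:
            raise ValidationError("n_planted_sites exceeds n_sites")


def simulate_msa_with_convergence(
    params: SeqSimParams,
) -> tuple[MSA, GeneTree, SimTruth]:
    """Evolve a protein alignment along the tree and plant convergent sites.

    The root sequence is uniform over the 20 amino acids; on each branch every
    site receives Poisson(branch length) substitution events, each replacing
    the residue uniformly among the other 19 letters. Afterwards, at each of
    ``n_planted_sites`` distinct columns, every foreground leaf's residue is
    overwritten with one residue absent from all background leaves at that
    column (columns where no residue is free are resampled).
    """
    rng = np.random.default_rng(params.seed)
    tree = GeneTree.from_newick(params.tree_newick)
    truth = SimTruth()
    aa = np.array(list(AMINO_ACIDS))
    root_seq = rng.integers(0, 20, size=params.n_sites)
    seqs_idx: dict = {}
    for node in tree.tree.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            seqs_idx[node] = root_seq.copy()
            continue
        seq = seqs_idx[parent].copy()
        bl = node.edge.length if node.edge.length is not None else 0.0
        n_events = rng.poisson(bl, size=params.n_sites)
        label = node.taxon.label if node.is_leaf() else f"node{id(node)}"
        for site in np.nonzero(n_events)[0]:
            for _ in range(int(n_events[site])):
                old = seq[site]
                # uniform among the other 19 letters
                new = rng.integers(0, 19)
                if new >= old:
                    new += 1
                truth.event_log.append((label, int(site) + 1, AMINO_ACIDS[old], AMINO_ACIDS[new]))
                seq[site] = new
        seqs_idx[node] = seq
    leaf_seqs = {
        lf.taxon.label: seqs_idx[lf].copy() for lf in tree.tree.leaf_node_iter()
    }
    fg = list(params.foreground)
    for f in fg:
        if f not in leaf_seqs:
            raise ValidationError(f"foreground leaf {f!r} not in tree")
    bg = [l for l in leaf_seqs if l not in fg]
    planted: list[int] = []
    residues: dict[int, str] = {}
    if fg and params.n_planted_sites > 0:
        candidates = list(rng.permutation(params.n_sites))
        for site in candidates:
            if len(planted) == params.n_planted_sites:
                break
            bg_states = {int(leaf_seqs[l][site]) for l in bg}
            free = sorted(set(range(20)) - bg_states)
            if not free:
                continue  # resample: all 20 residues present in background
            choice = int(rng.choice(free))
            for l in fg:
                leaf_seqs[l][site] = choice
            planted.append(int(site) + 1)
            residues[int(site) + 1] = AMINO_ACIDS[choice]
        if len(planted) < params.n_planted_sites:
            raise ValidationError("could not place all planted columns")
    planted.sort()
    truth.planted_columns["msa"] = planted
    truth.planted_residues["msa"] = residues
    records = [
        (label, label.split("|")[0], "".join(aa[leaf_seqs[label]]))
        for label in sorted(leaf_seqs)
    ]
    return MSA(records=records), tree, truth


# ---------------------------------------------------------------------------
# Similarity graph generator
# ---------------------------------------------------------------------------


def simulate_similarity_graph(
    n_tribes: int,
    tribe_size: int,
    intra_evalue: float = 1e-50,
    inter_evalue: float = 1e-3,
    seed: int = 0,
) -> tuple[SimilarityGraph, SimTruth]:
    """Plant ``n_tribes`` cliques of strong edges joined by weak bridges.

    Within-tribe E-values jitter around ``intra_evalue`` (one decade either
    way); one bridge edge joins consecutive tribes at ``inter_evalue``. With
    the default bridge E-value above the tribe-building cutoff (1e-5) the
    filtered graph falls apart into exactly the planted tribes.
    """
    rng = np.random.default_rng(seed)
    graph = SimilarityGraph()
    truth = SimTruth()
    tribes: list[list[str]] = []
    for t in range(n_tribes):
        members = [f"T{t:02d}_g{i}" for i in range(tribe_size)]
        tribes.append(members)
        for i in range(tribe_size):
            graph.graph.add_node(members[i])
            for j in range(i + 1, tribe_size):
                e = intra_evalue * 10 ** rng.uniform(-1.0, 1.0)
                graph.add_edge(members[i], members[j], e)
    for t in range(n_tribes - 1):
        e = inter_evalue * 10 ** rng.uniform(-1.0, 1.0)
        graph.add_edge(tribes[t][0], tribes[t + 1][0], e)
    truth.tribe_partition = [frozenset(m) for m in tribes]
    return graph, truth


# ---------------------------------------------------------------------------
# Whole sequence-arm dataset (trees + alignments, with planted tribes)
# ---------------------------------------------------------------------------


def _leaf(species: str, tribe_id: str) -> str:
    return f"{species}|{tribe_id}_{species}"


def species_tree_newick(tribe_id: str, branch_length: float = 0.05) -> str:
    """Gene-tree topology following the species history: the CAM eudicot sits
    among the eudicot C3 species, the CAM monocots among the grasses."""
    b = branch_length
    l = lambda sp: f"{_leaf(sp, tribe_id)}:{b}"
    return (
        f"((({l('Kfe')},(({l('Ath')},{l('Sly')}):{b},({l('Vvi')},{l('Ppe')}):{b}):{b}):{b},"
        f"(({l('Osa')},{l('Bdi')}):{b},(({l('Sbi')},{l('Zma')}):{b},"
        f"({l('Aco')},{l('Peq')}):{b}):{b}):{b}):{b},({l('Atr')},{l('Smo')}):{b});"
    )


def convergence_tree_newick(tribe_id: str, branch_length: float = 0.05) -> str:
    """Gene-tree topology carrying a CAM-convergence clade: the CAM eudicot
    gene and the orchid-like CAM monocot gene group together, each in a
    cherry with an "other"-role species, with no C3/C4 gene inside.

    The clade-internal context branches (the "other" terminals, the two
    cherry stems and the clade stem) have zero length, so the clade's
    ancestral background is frozen and planted foreground residues are
    reconstructed as two independent substitutions on the (non-adjacent)
    CAM terminal branches rather than one ancestral change.
    """
    b = branch_length
    l = lambda sp: f"{_leaf(sp, tribe_id)}:{b}"
    l0 = lambda sp: f"{_leaf(sp, tribe_id)}:0.0"
    return (
        f"(((({l('Kfe')},{l0('Atr')}):0.0,({l('Peq')},{l0('Smo')}):0.0):0.0,"
        f"(({l('Ath')},{l('Sly')}):{b},({l('Vvi')},{l('Ppe')}):{b}):{b}):{b},"
        f"(({l('Osa')},{l('Bdi')}):{b},(({l('Sbi')},{l('Zma')}):{b},{l('Aco')}):{b}):{b});"
    )


def simulate_sequence_dataset(
    n_tribes: int = 50,
    n_convergent: int = 10,
    n_sites: int = 200,
    n_planted_sites: int = 3,
    branch_length: float = 0.05,
    seed: int = 0,
) -> tuple[dict[str, tuple[GeneTree, MSA]], SimTruth]:
    """Simulate a batch of 13-species tribes, the first ``n_convergent`` of
    which carry a planted CAM-convergence clade plus convergent columns.

    Planted tribes use :func:`convergence_tree_newick` with foreground = the
    CAM-eudicot and orchid-like leaves; the rest follow the species topology
    and receive no planted columns. Truth records the planted focal genes and
    columns per tribe.
    """
    if n_convergent > n_tribes:
        raise ValidationError("n_convergent exceeds n_tribes")
    rng = np.random.default_rng(seed)
    tribes: dict[str, tuple[GeneTree, MSA]] = {}
    truth = SimTruth()
    for t in range(n_tribes):
        tribe_id = f"TR{t:03d}"
        planted = t < n_convergent
        sub_seed = int(rng.integers(0, 2**31 - 1))
        if planted:
            nwk = convergence_tree_newick(tribe_id, branch_length)
            fg = (_leaf("Kfe", tribe_id), _leaf("Peq", tribe_id))
            params = SeqSimParams(
                tree_newick=nwk,
                n_sites=n_sites,
                n_planted_sites=n_planted_sites,
                foreground=fg,
                seed=sub_seed,
            )
        else:
            nwk = species_tree_newick(tribe_id, branch_length)
            params = SeqSimParams(
                tree_newick=nwk,
                n_sites=n_sites,
                n_planted_sites=0,
                foreground=(),
                seed=sub_seed,
            )
        msa, tree, tribe_truth = simulate_msa_with_convergence(params)
        tribes[tribe_id] = (tree, msa)
        if planted:
            truth.planted_genes.add(_leaf("Kfe", tribe_id))
            truth.planted_columns[tribe_id] = tribe_truth.planted_columns["msa"]
            truth.planted_residues[tribe_id] = tribe_truth.planted_residues["msa"]
    return tribes, truth
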