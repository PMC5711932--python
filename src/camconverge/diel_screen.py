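"""Expression arm of the convergence screen.

Compares diel transcript time-courses of a eudicot CAM species (focal, "Kf"),
a monocot CAM species ("Ac") and a C3 species ("At") across ortholog groups
and classifies focal genes as convergently re-scheduled when

1. the focal profile is highly Spearman-correlated (r > r_high) with at least
   one CAM-partner ortholog but not highly correlated (r < r_low) with any C3
   ortholog;
2. the focal gene shows a significant opposite-window abundance contrast
   (midday vs midnight or dawn vs dusk) at BH-FDR < fdr;
3. the circular time shift between the two CAM profiles is <= max_cam_shift
   hours while both CAM profiles are shifted >= min_c3_shift hours against
   the best-matched C3 ortholog.

Also provides the low-expression filter, the flat-line (time-structure)
polynomial-regression filter, Spearman-distance hierarchical clustering of
profiles, and the enrichment triangle-network construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.cluster import hierarchy
from scipy.interpolate import CubicSpline
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .core_io import (
    CANONICAL_TIMES,
    DielMatrix,
    DielProfile,
    OrthologGroup,
    TimeWindowScheme,
    ValidationError,
)

__all__ = [
    "ShiftEstimate",
    "WindowEnrichment",
    "ExpressionConvergenceCall",
    "TriangleEdge",
    "periodic_spline_resample",
    "interpolate_to_grid",
    "zscore",
    "diel_spearman",
    "estimate_time_shift",
    "expression_filter",
    "window_enrichment_test",
    "bh_fdr",
    "attach_qvalues",
    "classify_convergent_expression",
    "flatline_test",
    "cluster_profiles",
    "build_triangle_network",
]

PERIOD = 24.0


@dataclass
class ShiftEstimate:
    """Signed circular lag (hours) maximizing cross-correlation of two profiles.

    Positive shift means the second profile lags the first: b(t) ~ a(t - shift).
    """

    shift: float
    peak_correlation: float
    grid_step: float = 0.5


@dataclass
class WindowEnrichment:
    """Opposite-window abundance contrasts for one gene.

    ``pvalues`` / ``qvalues`` are keyed by contrast ("midday_vs_midnight",
    "dawn_vs_dusk"); ``larger_window`` records which window of each contrast
    has the larger mean. ``enriched_window`` is set after FDR adjustment to
    the larger-mean window of the most significant contrast with q below the
    threshold, else None.
    """

    gene_id: str
    species: str
    window_means: dict[str, float]
    pvalues: dict[str, float]
    larger_window: dict[str, str]
    qvalues: dict[str, float] = field(default_factory=dict)
    enriched_window: str | None = None


@dataclass
class ExpressionConvergenceCall:
    """Per focal-gene verdict on the three convergent-expression criteria."""

    kf_gene: str
    group_id: str
    evaluable: bool = True
    best_ac_gene: str | None = None
    best_at_gene: str | None = None
    r_kf_ac: float = float("nan")
    r_kf_at_max: float = float("nan")
    shift_kf_ac: float = float("nan")
    shift_kf_at: float = float("nan")
    shift_ac_at: float = float("nan")
    q_kf: float = float("nan")
    kf_enrichment: WindowEnrichment | None = None
    ac_enrichment: WindowEnrichment | None = None
    at_enrichment: WindowEnrichment | None = None
    criterion1: bool = False
    criterion2: bool = False
    criterion3: bool = False

    @property
    def convergent(self) -> bool:
        return self.criterion1 and self.criterion2 and self.criterion3

    def to_record(self) -> dict:
        return {
            "kf_gene": self.kf_gene,
            "group_id": self.group_id,
            "evaluable": self.evaluable,
            "best_ac_gene": self.best_ac_gene or "",
            "best_at_gene": self.best_at_gene or "",
            "r_kf_ac": self.r_kf_ac,
            "r_kf_at_max": self.r_kf_at_max,
            "shift_kf_ac": self.shift_kf_ac,
            "shift_kf_at": self.shift_kf_at,
            "shift_ac_at": self.shift_ac_at,
            "q_kf": self.q_kf,
            "kf_enriched_window": (self.kf_enrichment.enriched_window or "")
            if self.kf_enrichment
            else "",
            "ac_enriched_window": (self.ac_enrichment.enriched_window or "")
            if self.ac_enrichment
            else "",
            "at_enriched_window": (self.at_enrichment.enriched_window or "")
            if self.at_enrichment
            else "",
            "criterion1": self.criterion1,
            "criterion2": self.criterion2,
            "criterion3": self.criterion3,
            "convergent": self.convergent,
        }


@dataclass
class TriangleEdge:
    """One edge of an enrichment triangle (Kf-Ac, Kf-At or Ac-At)."""

    group_id: str
    gene_a: str
    gene_b: str
    species_a: str
    species_b: str
    shift: float

    def to_record(self) -> dict:
        return {
            "group_id": self.group_id,
            "gene_a": self.gene_a,
            "gene_b": self.gene_b,
            "species_a": self.species_a,
            "species_b": self.species_b,
            "shift": self.shift,
        }


# ---------------------------------------------------------------------------
# Interpolation and normalization
# ---------------------------------------------------------------------------


def periodic_spline_resample(
    times: np.ndarray, values: np.ndarray, query: np.ndarray, period: float = PERIOD
) -> np.ndarray:
    """Evaluate a periodic natural cubic spline through (times, values) at query.

    The curve is closed over one period (value at t equals value at
    t + period), so no endpoint artifacts arise on the circular 24-h clock.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    t_ext = np.concatenate([times, [times[0] + period]])
    y_ext = np.concatenate([values, [values[0]]])
    spline = CubicSpline(t_ext, y_ext, bc_type="periodic")
    q = times[0] + np.mod(np.asarray(query, dtype=float) - times[0], period)
    return spline(q)


def interpolate_to_grid(profile: DielProfile, target_step: float = 2.0) -> DielProfile:
    """Re-grid the replicate-mean series onto {step, 2*step, ..., 24} hours.

    Used to bring 4-h-interval C3 data onto the canonical 2-h grid before any
    cross-species comparison. Interpolation is a periodic cubic spline of the
    replicate mean; negative spline excursions are clipped at zero since FPKM
    is non-negative. The output carries a single (interpolated-mean) replicate.
    """
    if profile.times.size < 4:
        raise ValidationError(
            f"{profile.gene_id}: need >= 4 time points to interpolate, "
            f"have {profile.times.size}"
        )
    if PERIOD % target_step != 0:
        raise ValueError(f"target_step {target_step} must divide {PERIOD}")
    grid = np.arange(target_step, PERIOD + target_step / 2, target_step)
    if profile.times.size == grid.size and np.allclose(profile.times, grid):
        return DielProfile(
            gene_id=profile.gene_id,
            species=profile.species,
            times=grid,
            values=profile.mean_series()[:, None],
        )
    interp = periodic_spline_resample(profile.times, profile.mean_series(), grid)
    return DielProfile(
        gene_id=profile.gene_id,
        species=profile.species,
        times=grid,
        values=np.clip(interp, 0.0, None)[:, None],
    )


def zscore(profile: DielProfile) -> DielProfile:
    """Z-score transform of the replicate-mean series (mean 0, sd 1).

    Raises on a zero-variance (degenerate) profile; degenerate genes are
    excluded from correlation and shift estimation upstream.
    """
    m = profile.mean_series()
    sd = m.std()
    if sd == 0:
        raise ValidationError(f"{profile.gene_id}: zero-variance profile")
    z = (m - m.mean()) / sd
    prof = DielProfile.__new__(DielProfile)
    prof.gene_id = profile.gene_id
    prof.species = profile.species
    prof.times = profile.times.copy()
    prof.values = z[:, None]  # bypass FPKM >= 0 check: z-scores are signed
    return prof


# ---------------------------------------------------------------------------
# Correlation and circular time shift
# ---------------------------------------------------------------------------


def _check_same_canonical_grid(a: DielProfile, b: DielProfile) -> None:
    if a.times.shape != b.times.shape or not np.allclose(a.times, b.times):
        raise ValidationError(f"{a.gene_id} vs {b.gene_id}: mismatched time grids")


def diel_spearman(a: DielProfile, b: DielProfile) -> float:
    """Spearman rank correlation of two replicate-mean diel series."""
    _check_same_canonical_grid(a, b)
    if a.is_degenerate() or b.is_degenerate():
        raise ValidationError("degenerate profile in correlation")
    rho, _ = stats.spearmanr(a.mean_series(), b.mean_series())
    return float(rho)


def estimate_time_shift(
    a: DielProfile, b: DielProfile, grid_step: float = 0.5
) -> ShiftEstimate:
    """Signed circular lag in (-12, +12] maximizing Pearson correlation.

    Both profiles are z-scored and upsampled to ``grid_step`` by periodic
    cubic spline; the returned shift is the lag of b behind a. Ties are broken
    toward the smaller absolute lag, then toward the positive lag.
    """
    _check_same_canonical_grid(a, b)
    if a.is_degenerate() or b.is_degenerate():
        raise ValidationError("degenerate profile in shift estimation")
    fine = np.arange(grid_step, PERIOD + grid_step / 2, grid_step)
    za = periodic_spline_resample(a.times, zscore(a).mean_series(), fine)
    zb = periodic_spline_resample(b.times, zscore(b).mean_series(), fine)
    za = za - za.mean()
    zb = zb - zb.mean()
    denom = np.sqrt((za**2).sum() * (zb**2).sum())
    n = fine.size
    half = int(round(PERIOD / 2 / grid_step))  # lags -(half-1) .. +half
    best: tuple[float, float] | None = None
    for k in range(-(half - 1), half + 1):
        lag = k * grid_step
        # b evaluated at t + lag is a circular roll of the fine grid
        corr = float(np.dot(za, np.roll(zb, -k)) / denom)
        if best is None:
            best = (lag, corr)
            continue
        b_lag, b_corr = best
        if corr > b_corr + 1e-12:
            best = (lag, corr)
        elif abs(corr - b_corr) <= 1e-12:
            if (abs(lag), -np.sign(lag)) < (abs(b_lag), -np.sign(b_lag)):
                best = (lag, corr)
    assert best is not None and n == fine.size
    return ShiftEstimate(shift=best[0], peak_correlation=best[1], grid_step=grid_step)


# ---------------------------------------------------------------------------
# Filters and window tests
# ---------------------------------------------------------------------------


def expression_filter(
    matrix: DielMatrix, min_fpkm: float = 0.01, min_timepoints: int = 6
) -> set[str]:
    """Genes whose replicate-mean FPKM exceeds ``min_fpkm`` (strictly) at
    ``min_timepoints`` or more of the 12 canonical time points."""
    kept: set[str] = set()
    for gid, prof in matrix.profiles.items():
        n_above = int(np.sum(prof.mean_series() > min_fpkm))
        if n_above >= min_timepoints:
            kept.add(gid)
    return kept


def window_enrichment_test(
    profile: DielProfile, scheme: TimeWindowScheme | None = None
) -> WindowEnrichment:
    """Welch two-sided t-tests of the two opposite-window abundance contrasts.

    Observations are pooled per window: the per-replicate values at the
    window's 3 time points (3 x n_reps observations per side).
    """
    scheme = scheme or TimeWindowScheme()
    if not profile.on_canonical_grid():
        raise ValidationError(f"{profile.gene_id}: window test requires the canonical grid")
    means: dict[str, float] = {}
    obs: dict[str, np.ndarray] = {}
    for w in scheme.windows:
        mask = scheme.mask(w, profile.times)
        vals = profile.values[mask].ravel()
        if vals.size < 2:
            raise ValidationError(f"{profile.gene_id}: <2 observations in window {w}")
        obs[w] = vals
        means[w] = float(vals.mean())
    pvals: dict[str, float] = {}
    larger: dict[str, str] = {}
    for w1, w2 in scheme.contrasts:
        res = stats.ttest_ind(obs[w1], obs[w2], equal_var=False)
        p = float(res.pvalue)
        pvals[f"{w1}_vs_{w2}"] = 1.0 if np.isnan(p) else p
        larger[f"{w1}_vs_{w2}"] = w1 if means[w1] >= means[w2] else w2
    return WindowEnrichment(
        gene_id=profile.gene_id,
        species=profile.species,
        window_means=means,
        pvalues=pvals,
        larger_window=larger,
    )


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def attach_qvalues(
    enrichments: Sequence[WindowEnrichment], fdr_threshold: float = 0.01
) -> None:
    """BH-adjust all contrast p-values of one species jointly and set
    ``enriched_window`` per gene.

    The adjustment family is genome-wide within a species, pooling both
    opposite-window contrasts of every gene.
    """
    keys = [(i, c) for i, e in enumerate(enrichments) for c in e.pvalues]
    if not keys:
        return
    q = bh_fdr([enrichments[i].pvalues[c] for i, c in keys])
    for (i, c), qv in zip(keys, q):
        enrichments[i].qvalues[c] = float(qv)
    for e in enrichments:
        sig = [(e.qvalues[c], c) for c in e.qvalues if e.qvalues[c] < fdr_threshold]
        e.enriched_window = e.larger_window[min(sig)[1]] if sig else None


# ---------------------------------------------------------------------------
# The three-criterion classifier
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExpressionThresholds:
    r_high: float = 0.8
    r_low: float = 0.5
    fdr: float = 0.01
    max_cam_shift: float = 3.0
    min_c3_shift: float = 6.0
    shift_grid: float = 0.5


def classify_convergent_expression(
    group: OrthologGroup,
    profiles: Mapping[str, Mapping[str, DielProfile]],
    enrichments: Mapping[str, Mapping[str, WindowEnrichment]],
    kf_gene: str,
    thresholds: ExpressionThresholds = ExpressionThresholds(),
    species_kf: str = "Kf",
    species_ac: str = "Ac",
    species_at: str = "At",
) -> ExpressionConvergenceCall:
    """Apply the three convergent-expression criteria to one focal gene.

    ``profiles`` maps species -> gene -> canonical-grid profile (replicate
    mean, post-filter); ``enrichments`` maps species -> gene -> q-annotated
    window contrasts. Degenerate profiles can never be called convergent.
    """
    call = ExpressionConvergenceCall(kf_gene=kf_gene, group_id=group.group_id)
    ac_genes = [g for g in group.genes(species_ac) if g in profiles.get(species_ac, {})]
    at_genes = [g for g in group.genes(species_at) if g in profiles.get(species_at, {})]
    kf_prof = profiles.get(species_kf, {}).get(kf_gene)
    if kf_prof is None or not ac_genes or not at_genes:
        call.evaluable = False
        return call
    if kf_prof.is_degenerate():
        call.evaluable = True  # evaluable but never convergent
        return call

    ac_profiles = {g: profiles[species_ac][g] for g in ac_genes}
    at_profiles = {g: profiles[species_at][g] for g in at_genes}
    ac_ok = {g: p for g, p in ac_profiles.items() if not p.is_degenerate()}
    at_ok = {g: p for g, p in at_profiles.items() if not p.is_degenerate()}
    if not ac_ok or not at_ok:
        return call

    r_ac = {g: diel_spearman(kf_prof, p) for g, p in sorted(ac_ok.items())}
    r_at = {g: diel_spearman(kf_prof, p) for g, p in sorted(at_ok.items())}
    call.best_ac_gene = max(r_ac, key=lambda g: (r_ac[g], g))
    call.best_at_gene = max(r_at, key=lambda g: (r_at[g], g))
    call.r_kf_ac = r_ac[call.best_ac_gene]
    call.r_kf_at_max = r_at[call.best_at_gene]

    # Criterion 1: in phase with >=1 CAM-partner ortholog, out of phase with all C3.
    call.criterion1 = (call.r_kf_ac > thresholds.r_high) and (
        call.r_kf_at_max < thresholds.r_low
    )

    # Criterion 2: significant opposite-window contrast of the focal gene.
    kf_enr = enrichments.get(species_kf, {}).get(kf_gene)
    call.kf_enrichment = kf_enr
    call.ac_enrichment = enrichments.get(species_ac, {}).get(call.best_ac_gene)
    call.at_enrichment = enrichments.get(species_at, {}).get(call.best_at_gene)
    if kf_enr is not None and kf_enr.qvalues:
        call.q_kf = min(kf_enr.qvalues.values())
        call.criterion2 = call.q_kf < thresholds.fdr

    # Criterion 3: CAM-CAM shift small, both CAM-vs-C3 shifts large, against
    # the single best-matched C3 ortholog.
    best_ac = ac_ok[call.best_ac_gene]
    best_at = at_ok[call.best_at_gene]
    call.shift_kf_ac = estimate_time_shift(kf_prof, best_ac, thresholds.shift_grid).shift
    call.shift_kf_at = estimate_time_shift(kf_prof, best_at, thresholds.shift_grid).shift
    call.shift_ac_at = estimate_time_shift(best_ac, best_at, thresholds.shift_grid).shift
    call.criterion3 = (
        abs(call.shift_kf_ac) <= thresholds.max_cam_shift
        and abs(call.shift_kf_at) >= thresholds.min_c3_shift
        and abs(call.shift_ac_at) >= thresholds.min_c3_shift
    )
    return call


# ---------------------------------------------------------------------------
# Flat-line filter and clustering
# ---------------------------------------------------------------------------


def flatline_test(
    times: np.ndarray, counts: np.ndarray, degree: int = 3
) -> float:
    """F-test p-value of a degree-``degree`` polynomial time trend vs a flat line.

    The response is log2(count + 1) of the replicate-resolved values; the null
    model is an intercept. Genes with p < 0.05 are considered time-structured.
    A constant series (both residual sums zero) returns p = 1.
    """
    times = np.asarray(times, dtype=float)
    counts = np.asarray(counts, dtype=float)
    if counts.ndim == 1:
        counts = counts[:, None]
    if times.size < 3:
        raise ValidationError("flatline test needs >= 3 time points")
    if counts.shape[1] < 1:
        raise ValidationError("flatline test needs >= 1 replicate")
    t_long = np.repeat(times, counts.shape[1])
    y = np.log2(counts + 1.0).ravel()
    n = y.size
    X = np.vander(t_long, degree + 1, increasing=True)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss1 = float(np.sum((y - X @ beta) ** 2))
    rss0 = float(np.sum((y - y.mean()) ** 2))
    df1 = degree
    df2 = n - (degree + 1)
    if df2 <= 0:
        raise ValidationError("flatline test: not enough observations for the fit")
    if rss1 <= 1e-300:
        return 1.0 if rss0 <= 1e-300 else 0.0
    f_stat = ((rss0 - rss1) / df1) / (rss1 / df2)
    return float(stats.f.sf(f_stat, df1, df2))


def cluster_profiles(profiles: Sequence[DielProfile], k: int) -> dict[str, int]:
    """Average-linkage hierarchical clustering with distance 1 - Spearman rho.

    Profiles are ordered lexicographically by gene_id before linkage, so the
    result is deterministic in the input order. Returns gene_id -> cluster
    label (1..k).
    """
    profs = sorted(profiles, key=lambda p: p.gene_id)
    n = len(profs)
    if n < 2:
        raise ValidationError("clustering needs >= 2 profiles")
    if k > n:
        raise ValidationError(f"k={k} exceeds number of profiles ({n})")
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = 1.0 - diel_spearman(profs[i], profs[j])
    Z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    return {p.gene_id: int(l) for p, l in zip(profs, labels)}


def linkage_matrix(profiles: Sequence[DielProfile]) -> np.ndarray:
    """Average-linkage matrix on 1 - Spearman distances (for merge-order audits)."""
    profs = sorted(profiles, key=lambda p: p.gene_id)
    n = len(profs)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = 1.0 - diel_spearman(profs[i], profs[j])
    return hierarchy.linkage(squareform(dist, checks=False), method="average")


# ---------------------------------------------------------------------------
# Enrichment triangle networks
# ---------------------------------------------------------------------------


def build_triangle_network(
    calls: Sequence[ExpressionConvergenceCall],
    scheme: TimeWindowScheme | None = None,
    species_kf: str = "Kf",
    species_ac: str = "Ac",
    species_at: str = "At",
) -> list[TriangleEdge]:
    """Emit Kf-Ac-At triangles where both CAM genes are enriched in the same
    time window and the C3 ortholog in the opposite window.

    Each triangle contributes its three edges, annotated with the pairwise
    time shifts already recorded on the call.
    """
    scheme = scheme or TimeWindowScheme()
    edges: list[TriangleEdge] = []
    for call in calls:
        kf_e = call.kf_enrichment.enriched_window if call.kf_enrichment else None
        ac_e = call.ac_enrichment.enriched_window if call.ac_enrichment else None
        at_e = call.at_enrichment.enriched_window if call.at_enrichment else None
        if kf_e is None or ac_e is None or at_e is None:
            continue
        if kf_e != ac_e or at_e != scheme.opposite(kf_e):
            continue
        kf, ac, at = call.kf_gene, call.best_ac_gene, call.best_at_gene
        edges.append(
            TriangleEdge(call.group_id, kf, ac, species_kf, species_ac, call.shift_kf_ac)
        )
        edges.append(
            TriangleEdge(call.group_id, kf, at, species_kf, species_at, call.shift_kf_at)
        )
        edges.append(
            TriangleEdge(call.group_id, ac, at, species_ac, species_at, call.shift_ac_at)
        )
    return edges
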