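"""Weighted coexpression network construction, module detection and preservation.

The network is built from pairwise Pearson correlations raised to a soft
power (unsigned by default, ``A = |r|^beta``), converted to topological
overlap (TOM), and clustered by average linkage on ``1 - TOM``.  Clusters of
at least ``min_size`` genes become modules; each module is summarized by its
eigengene (first principal component of the gene-standardized submatrix) and
modules with near-identical eigengenes are merged.  Preservation of a module
between a reference and a test cohort is scored by permutation Z statistics
for intramodular density and connectivity pattern, averaged into Zsummary
(<2: no evidence of preservation; >10: strong evidence).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .containers import ExpressionMatrix, SampleAnnotation
from .preprocess import bh_fdr

__all__ = [
    "correlation_matrix",
    "pick_soft_threshold",
    "adjacency",
    "tom_similarity",
    "detect_modules",
    "module_eigengene",
    "module_membership",
    "module_trait_correlation",
    "hub_genes",
    "preservation_zsummary",
    "SoftThresholdReport",
    "ModuleAssignment",
    "EigengeneMatrix",
    "ModuleMembership",
    "PreservationResult",
    "NetworkError",
]

UNASSIGNED = "unassigned"


class NetworkError(ValueError):
    pass


def correlation_matrix(expr: ExpressionMatrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene-gene Pearson correlations with two-sided p-values (t-transform)."""
    X = expr.data.to_numpy(dtype=float)
    n = X.shape[1]
    if n < 3:
        raise NetworkError("correlation_matrix requires at least 3 samples")
    variances = X.var(axis=1)
    if (variances == 0).any():
        bad = [g for g, v in zip(expr.feature_ids, variances) if v == 0]
        raise NetworkError(f"zero-variance genes: {bad}")
    r = np.clip(np.corrcoef(X), -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[~np.isfinite(t)] = 0.0  # |r| == 1
    np.fill_diagonal(p, 0.0)
    idx = expr.data.index
    return pd.DataFrame(r, index=idx, columns=idx), pd.DataFrame(p, index=idx, columns=idx)


def adjacency(r: pd.DataFrame | np.ndarray, power: float, network_type: str = "unsigned"):
    """Soft-threshold a correlation matrix into network adjacency.

    unsigned: ``|r|^beta``; signed: ``((1+r)/2)^beta``.  The diagonal is set
    to zero so connectivity sums exclude self-edges.
    """
    if power < 1:
        raise NetworkError("power must be >= 1")
    R = np.asarray(r, dtype=float)
    if network_type == "unsigned":
        A = np.abs(R) ** power
    elif network_type == "signed":
        A = ((1.0 + R) / 2.0) ** power
    else:
        raise NetworkError(f"unknown network type {network_type!r}")
    np.fill_diagonal(A, 0.0)
    if isinstance(r, pd.DataFrame):
        return pd.DataFrame(A, index=r.index, columns=r.columns)
    return A


@dataclass
class SoftThresholdReport:
    powers: list[float]
    fits: list[float]                 # signed scale-free R^2 per power (nan if degenerate)
    mean_connectivity: list[float]
    chosen_power: float
    fit_target: float
    degenerate: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"power": self.powers, "fit": self.fits, "mean_k": self.mean_connectivity}
        )


def _scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of log10 frequency vs log10 binned connectivity."""
    k = k[k > 0]
    if k.size < 3 or np.allclose(k, k[0]):
        return np.nan
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    which = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    counts = np.bincount(which, minlength=n_bins)
    means = np.array([k[which == b].mean() if counts[b] else np.nan for b in range(n_bins)])
    mask = counts > 0
    if mask.sum() < 3:
        return np.nan
    x = np.log10(means[mask])
    y = np.log10(counts[mask] / counts.sum())
    slope, _i, rval, _p, _s = stats.linregress(x, y)
    r2 = rval**2
    return -r2 if slope > 0 else r2


def pick_soft_threshold(
    expr: ExpressionMatrix,
    powers=(1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 14, 16),
    fit_target: float = 0.8,
    network_type: str = "unsigned",
) -> SoftThresholdReport:
    """Scale-free topology criterion for the soft power.

    Chooses the smallest candidate whose signed scale-free fit reaches
    ``fit_target``; if none does, the power with maximal fit.
    """
    powers = list(powers)
    if not powers:
        raise NetworkError("empty power list")
    if expr.data.shape[0] < 3:
        raise NetworkError("need at least 3 genes")
    r, _p = correlation_matrix(expr)
    fits, mean_k = [], []
    for beta in powers:
        A = adjacency(r, beta, network_type=network_type).to_numpy()
        k = A.sum(axis=1)
        fits.append(_scale_free_fit(k))
        mean_k.append(float(k.mean()))
    fits_arr = np.asarray(fits, dtype=float)
    degenerate = bool(np.isnan(fits_arr).all())
    if degenerate:
        warnings.warn("scale-free fit undefined (degenerate connectivity); using first power",
                      stacklevel=2)
        chosen = powers[0]
    else:
        ok = [p for p, f in zip(powers, fits_arr) if not np.isnan(f) and f >= fit_target]
        chosen = ok[0] if ok else powers[int(np.nanargmax(fits_arr))]
    return SoftThresholdReport(powers, fits, mean_k, chosen, fit_target, degenerate)


def tom_similarity(A: pd.DataFrame | np.ndarray):
    """Topological overlap: shared-neighbor similarity of network nodes.

    ``TOM_ij = (sum_u A_iu A_uj + A_ij) / (min(k_i, k_j) + 1 - A_ij)`` with
    unit diagonal.
    """
    M = np.asarray(A, dtype=float)
    if M.shape[0] != M.shape[1] or not np.allclose(M, M.T):
        raise NetworkError("adjacency must be a symmetric square matrix")
    if (M < 0).any() or (M > 1).any():
        raise NetworkError("adjacency entries must lie in [0, 1]")
    M = M.copy()
    np.fill_diagonal(M, 0.0)
    k = M.sum(axis=1)
    numer = M @ M + M
    denom = np.minimum.outer(k, k) + 1.0 - M
    tom = numer / denom
    np.fill_diagonal(tom, 1.0)
    if isinstance(A, pd.DataFrame):
        return pd.DataFrame(tom, index=A.index, columns=A.columns)
    return tom


@dataclass
class ModuleAssignment:
    """Gene -> module label; genes in no module carry the ``unassigned`` label."""

    labels: pd.Series
    min_size: int

    @property
    def modules(self) -> list[str]:
        return [m for m in self.labels.unique() if m != UNASSIGNED]

    def genes_in(self, module: str) -> list[str]:
        return list(self.labels.index[self.labels == module])

    def sizes(self) -> pd.Series:
        return self.labels[self.labels != UNASSIGNED].value_counts()


def _relabel_by_size(labels: pd.Series) -> pd.Series:
    named = labels[labels != UNASSIGNED]
    # deterministic: by decreasing size, ties by first gene position
    order = sorted(
        named.unique(),
        key=lambda m: (-(named == m).sum(), int(np.argmax((labels == m).to_numpy()))),
    )
    mapping = {m: f"M{i + 1}" for i, m in enumerate(order)}
    mapping[UNASSIGNED] = UNASSIGNED
    return labels.map(mapping)


def detect_modules(
    tom: pd.DataFrame,
    expr: ExpressionMatrix,
    min_size: int = 30,
    merge_cut: float = 0.25,
    kme_rescue: float | None = 0.5,
) -> ModuleAssignment:
    """Cluster genes on 1 - TOM and call modules of at least ``min_size`` genes.

    Average-linkage hierarchical clustering; the tree is cut statically at
    the smallest height yielding the most clusters of size >= min_size.
    Modules whose eigengenes correlate above ``1 - merge_cut`` are merged
    iteratively; genes the cut left unassigned but with module membership
    above ``kme_rescue`` are then assigned to their best module (set
    ``kme_rescue=None`` to disable).  Labels are renumbered by decreasing
    module size (M1, M2, ...).
    """
    genes = list(tom.index)
    if min_size < 2:
        raise NetworkError("min_size must be >= 2")
    if len(genes) < min_size:
        warnings.warn("fewer genes than min_size; all genes unassigned", stacklevel=2)
        return ModuleAssignment(pd.Series(UNASSIGNED, index=genes), min_size)

    D = 1.0 - tom.to_numpy()
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method="average")

    # static cut: smallest height yielding the most clusters of >= min_size
    # genes (small heights give the purest clusters; fragments of one true
    # module are reunited by the eigengene merge below)
    heights = np.unique(Z[:, 2])
    best_height, best_count = None, 0
    for h in heights:
        flat = fcluster(Z, t=h, criterion="distance")
        sizes = np.bincount(flat)
        count = int((sizes[1:] >= min_size).sum())
        if count > best_count:
            best_count, best_height = count, h
    if best_count < 1:
        warnings.warn("no cluster reached min_size; all genes unassigned", stacklevel=2)
        return ModuleAssignment(pd.Series(UNASSIGNED, index=genes), min_size)

    flat = fcluster(Z, t=best_height, criterion="distance")
    labels = pd.Series([f"c{c}" for c in flat], index=genes)
    sizes = labels.value_counts()
    labels[labels.isin(sizes.index[sizes < min_size])] = UNASSIGNED

    labels = _merge_close_modules(labels, expr, merge_cut)
    if kme_rescue is not None:
        labels = _rescue_by_membership(labels, expr, kme_rescue)
    return ModuleAssignment(_relabel_by_size(labels), min_size)


def _rescue_by_membership(labels: pd.Series, expr: ExpressionMatrix, kme_cut: float) -> pd.Series:
    """Assign unassigned genes whose kME to some module exceeds ``kme_cut``.

    Genes left out by the static cut but clearly belonging to a module by
    module membership are reclaimed; genes uncorrelated with every module
    (background) remain unassigned.
    """
    unassigned = labels.index[labels == UNASSIGNED]
    modules = [m for m in labels.unique() if m != UNASSIGNED]
    if len(unassigned) == 0 or not modules:
        return labels
    eig = module_eigengene(expr, ModuleAssignment(labels, 2))
    mm = module_membership(expr.subset_features(unassigned), eig)
    best = mm.mm.max(axis=1)
    claimed = best.index[best > kme_cut]
    labels = labels.copy()
    labels[claimed] = mm.mm.loc[claimed].idxmax(axis=1)
    return labels


def _merge_close_modules(labels: pd.Series, expr: ExpressionMatrix, merge_cut: float) -> pd.Series:
    while True:
        modules = [m for m in labels.unique() if m != UNASSIGNED]
        if len(modules) < 2:
            return labels
        eig = module_eigengene(expr, ModuleAssignment(labels, 2))
        me = eig.eigengenes.loc[modules]
        corr = np.corrcoef(me.to_numpy())
        np.fill_diagonal(corr, -np.inf)
        i, j = np.unravel_index(np.argmax(corr), corr.shape)
        if 1.0 - corr[i, j] >= merge_cut:
            return labels
        keep, drop = sorted((modules[i], modules[j]))
        labels = labels.replace({drop: keep})


@dataclass
class EigengeneMatrix:
    """Module eigengenes: module x sample values plus variance explained.

    Each eigengene is the first right singular vector (unit norm over
    samples) of the gene-standardized module submatrix, with sign aligned to
    the module's mean standardized profile.
    """

    eigengenes: pd.DataFrame
    var_explained: pd.Series

    @property
    def modules(self) -> list[str]:
        return list(self.eigengenes.index)


def module_eigengene(expr: ExpressionMatrix, assignment: ModuleAssignment) -> EigengeneMatrix:
    rows, varex = {}, {}
    for module in assignment.modules:
        genes = assignment.genes_in(module)
        sub = expr.data.loc[genes].to_numpy(dtype=float)
        sd = sub.std(axis=1, ddof=0)
        if (sd == 0).any():
            dropped = [g for g, s in zip(genes, sd) if s == 0]
            warnings.warn(f"module {module}: dropping zero-variance genes {dropped}",
                          stacklevel=2)
            sub = sub[sd > 0]
            sd = sd[sd > 0]
        if sub.shape[0] == 0:
            raise NetworkError(f"module {module} has no genes with variance")
        Zs = (sub - sub.mean(axis=1, keepdims=True)) / sd[:, None]
        _u, s, vt = np.linalg.svd(Zs, full_matrices=False)
        v = vt[0]
        if np.corrcoef(v, Zs.mean(axis=0))[0, 1] < 0:
            v = -v
        rows[module] = v
        varex[module] = float(s[0] ** 2 / (s**2).sum())
    eig = pd.DataFrame(rows, index=expr.data.columns).T
    return EigengeneMatrix(eig, pd.Series(varex, name="var_explained"))


@dataclass
class ModuleMembership:
    """Gene x module table of kME values with p-values."""

    mm: pd.DataFrame
    pvalues: pd.DataFrame


def module_membership(expr: ExpressionMatrix, eigengenes: EigengeneMatrix) -> ModuleMembership:
    """kME: Pearson correlation of each gene with each module eigengene."""
    X = expr.data.to_numpy(dtype=float)
    n = X.shape[1]
    ME = eigengenes.eigengenes[expr.data.columns].to_numpy(dtype=float)
    sd = X.std(axis=1, ddof=0)
    flagged = sd == 0
    if flagged.any():
        warnings.warn(f"{int(flagged.sum())} zero-variance genes: MM undefined", stacklevel=2)
    Xz = np.zeros_like(X)
    Xz[~flagged] = (X[~flagged] - X[~flagged].mean(axis=1, keepdims=True)) / sd[~flagged, None]
    Mz = (ME - ME.mean(axis=1, keepdims=True)) / ME.std(axis=1, ddof=0)[:, None]
    r = np.clip(Xz @ Mz.T / n, -1.0, 1.0)
    r[flagged] = np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isinf(t)] = 0.0
    idx, cols = expr.data.index, eigengenes.eigengenes.index
    return ModuleMembership(
        pd.DataFrame(r, index=idx, columns=cols), pd.DataFrame(p, index=idx, columns=cols)
    )


def module_trait_correlation(
    eigengenes: EigengeneMatrix,
    annotation: SampleAnnotation,
    traits: list[str],
    fdr_cut: float = 0.05,
) -> pd.DataFrame:
    """Correlate module eigengenes with (numeric or 0/1-coded) traits.

    Returns a tidy table with r, p and BH q per module x trait cell; a
    module is flagged disease-associated when q < ``fdr_cut`` for the trait.
    """
    samples = eigengenes.eigengenes.columns
    rows = []
    for trait in traits:
        y = pd.to_numeric(annotation.table.loc[samples, trait])
        if y.nunique() < 2:
            raise NetworkError(f"trait {trait!r} is constant")
        for module in eigengenes.modules:
            x = eigengenes.eigengenes.loc[module, samples]
            r, p = stats.pearsonr(x.to_numpy(dtype=float), y.to_numpy(dtype=float))
            rows.append({"module": module, "trait": trait, "r": r, "pvalue": p})
    out = pd.DataFrame(rows)
    out["qvalue"] = bh_fdr(out["pvalue"].to_numpy())
    out["significant"] = out["qvalue"] < fdr_cut
    return out


def hub_genes(
    mm: ModuleMembership,
    de: pd.DataFrame,
    module: str,
    mm_cut: float = 0.5,
    p_cut: float = 0.05,
) -> list[str]:
    """Genes with MM > mm_cut and DE p < p_cut (both strict) in a module."""
    if module not in mm.mm.columns:
        raise NetworkError(f"module {module!r} not in membership table")
    shared = mm.mm.index.intersection(de.index)
    kme = mm.mm.loc[shared, module]
    p = de.loc[shared, "pvalue"]
    return list(shared[(kme > mm_cut) & (p < p_cut)])


@dataclass
class PreservationResult:
    """Per-module permutation Z statistics for cross-cohort preservation."""

    table: pd.DataFrame
    n_perm: int

    def zsummary(self, module: str) -> float:
        return float(self.table.loc[module, "z_summary"])


def _module_stats(
    idx: np.ndarray, A_ref: np.ndarray, A_test: np.ndarray
) -> tuple[float, float]:
    sub_test = A_test[np.ix_(idx, idx)]
    m = len(idx)
    density = sub_test.sum() / (m * (m - 1))
    k_ref = A_ref[np.ix_(idx, idx)].sum(axis=1)
    k_test = sub_test.sum(axis=1)
    if k_ref.std() == 0 or k_test.std() == 0:
        conn = 0.0
    else:
        conn = float(np.corrcoef(k_ref, k_test)[0, 1])
    return float(density), conn


def preservation_zsummary(
    ref_expr: ExpressionMatrix,
    test_expr: ExpressionMatrix,
    assignment: ModuleAssignment,
    n_perm: int = 200,
    seed: int = 0,
    power: float = 6,
    network_type: str = "unsigned",
) -> PreservationResult:
    """Permutation Zsummary for module preservation between two cohorts.

    Observed statistics in the test network: intramodular density (mean
    off-diagonal adjacency) and connectivity-pattern preservation (Pearson r
    of intramodular connectivity, reference vs test).  Nulls come from
    ``n_perm`` random same-size gene sets; ``Z = (obs - null mean)/null SD``
    and ``Zsummary = (Zdensity + Zconnectivity)/2``.
    """
    common = [g for g in ref_expr.feature_ids if g in set(test_expr.feature_ids)]
    modules = assignment.modules
    for module in modules:
        missing = [g for g in assignment.genes_in(module) if g not in set(common)]
        if missing:
            raise NetworkError(f"module {module}: genes absent from both cohorts: {missing}")
        if len(assignment.genes_in(module)) < 3:
            raise NetworkError(f"module {module} has fewer than 3 genes")

    ref = ref_expr.subset_features(common)
    test = test_expr.subset_features(common)
    r_ref, _ = correlation_matrix(ref)
    r_test, _ = correlation_matrix(test)
    A_ref = adjacency(r_ref, power, network_type).to_numpy()
    A_test = adjacency(r_test, power, network_type).to_numpy()
    pos = {g: i for i, g in enumerate(common)}
    rng = np.random.default_rng(seed)

    rows = {}
    for module in modules:
        idx = np.array([pos[g] for g in assignment.genes_in(module)])
        obs_d, obs_c = _module_stats(idx, A_ref, A_test)
        null_d = np.empty(n_perm)
        null_c = np.empty(n_perm)
        for b in range(n_perm):
            ridx = rng.choice(len(common), size=len(idx), replace=False)
            null_d[b], null_c[b] = _module_stats(ridx, A_ref, A_test)
        sd_d, sd_c = null_d.std(ddof=1), null_c.std(ddof=1)
        if sd_d == 0 or sd_c == 0:
            raise NetworkError(
                f"module {module}: null SD is zero; increase n_perm or the gene pool"
            )
        z_d = (obs_d - null_d.mean()) / sd_d
        z_c = (obs_c - null_c.mean()) / sd_c
        rows[module] = {
            "size": len(idx),
            "obs_density": obs_d,
            "obs_connectivity": obs_c,
            "null_density_mean": null_d.mean(),
            "null_density_sd": sd_d,
            "null_connectivity_mean": null_c.mean(),
            "null_connectivity_sd": sd_c,
            "z_density": z_d,
            "z_connectivity": z_c,
            "z_summary": (z_d + z_c) / 2.0,
        }
    table = pd.DataFrame(rows).T
    table.index.name = "module"
    return PreservationResult(table, n_perm)
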