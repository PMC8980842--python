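"""Two-step integrated mRNA-miRNA analysis.

Step 1 screens differentially expressed miRNAs against disease modules: the
mean Pearson correlation between a miRNA and all module genes is compared
with a permutation null built by shuffling the miRNA's sample order B times
(default 10,000); the empirical lower-tail p-value (with plus-one
correction) is FDR-adjusted across all miR-module pairs, and pairs with
p < 0.05 and q < 0.25 are selected.

Step 2 predicts targets for the selected miRNAs by canonical seed matching
in 3'UTRs (optionally combined with an external prediction table) and keeps
pairs whose expression is negatively correlated (r < 0, p < 0.05) in the
patient subset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix, NormalizedMatrix, SampleAnnotation
from .preprocess import bh_fdr
from .seeds import SITE_TYPES, SeedSite, find_seed_sites

__all__ = [
    "MirProfile",
    "mean_module_correlation",
    "permutation_pvalue",
    "screen_mirs",
    "predict_targets",
    "inverse_correlation_filter",
    "rank_mirs_by_target_count",
    "seed_enrichment",
    "PermutationResult",
    "IntegrationError",
]


class IntegrationError(ValueError):
    pass


@dataclass
class MirProfile:
    """A miRNA: identifier, mature sequence (5'->3') and expression profile."""

    mir_id: str
    sequence: str
    expression: pd.Series


def _standardize_rows(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=0)
    if (sd == 0).any():
        raise IntegrationError("zero-variance expression vector")
    return (X - mu) / sd[:, None]


def _align(mir_values: pd.Series, module_expr: ExpressionMatrix):
    samples = [s for s in module_expr.sample_ids if s in mir_values.index]
    if len(samples) < 3:
        raise IntegrationError("need at least 3 shared samples")
    x = mir_values[samples].to_numpy(dtype=float)
    if x.std() == 0:
        raise IntegrationError("miR expression vector is constant")
    G = module_expr.data[samples].to_numpy(dtype=float)
    return x, G


def mean_module_correlation(mir_values: pd.Series, module_expr: ExpressionMatrix) -> float:
    """Mean Pearson correlation between one miRNA and all module genes."""
    x, G = _align(mir_values, module_expr)
    n = len(x)
    z = (x - x.mean()) / x.std()
    Gz = _standardize_rows(G)
    return float((Gz @ z).mean() / n)


@dataclass
class PermutationResult:
    mir_id: str
    module: str
    actual_r: float
    n_perm: int
    bg_mean: float
    bg_sd: float
    bg_min: float
    bg_max: float
    pvalue: float
    qvalue: float = np.nan
    selected: bool = False


def permutation_pvalue(
    mir: MirProfile,
    module_expr: ExpressionMatrix,
    module: str = "",
    B: int = 10_000,
    seed: int = 0,
    alternative: str = "less",
) -> PermutationResult:
    """Empirical permutation p for the mean miR-module correlation.

    The miRNA's sample order is permuted against the fixed gene matrix B
    times; the background mean correlations define the null.  The default
    lower tail targets negative coupling:
    ``p = (1 + #{background <= actual}) / (B + 1)``.
    """
    if B < 1:
        raise IntegrationError("B must be >= 1")
    x, G = _align(mir.expression, module_expr)
    n = len(x)
    z = (x - x.mean()) / x.std()
    # mean over genes commutes with the dot product: one profile suffices
    u = _standardize_rows(G).mean(axis=0)
    actual = float(u @ z / n)

    # canonical sample frame: sampled permutations are applied after sorting
    # samples by (u, z), so the p-value is exactly invariant under any joint
    # relabeling of the inputs
    order = np.lexsort((z, u))
    u_c, z_c = u[order], z[order]
    rng = np.random.default_rng(seed)
    perms = np.argsort(rng.random((B, n)), axis=1)
    bg = (z_c[perms] @ u_c) / n

    if alternative == "less":
        hits = int((bg <= actual).sum())
    elif alternative == "two-sided":
        hits = int((np.abs(bg) >= abs(actual)).sum())
    else:
        raise IntegrationError(f"unknown alternative {alternative!r}")
    p = (1 + hits) / (B + 1)
    return PermutationResult(
        mir_id=mir.mir_id,
        module=module,
        actual_r=actual,
        n_perm=B,
        bg_mean=float(bg.mean()),
        bg_sd=float(bg.std(ddof=1)) if B > 1 else 0.0,
        bg_min=float(bg.min()),
        bg_max=float(bg.max()),
        pvalue=p,
    )


def screen_mirs(
    mir_ids,
    mir_matrix: NormalizedMatrix | ExpressionMatrix,
    module_exprs: dict[str, ExpressionMatrix],
    p_cut: float = 0.05,
    q_cut: float = 0.25,
    B: int = 10_000,
    seed: int = 0,
    alternative: str = "less",
) -> pd.DataFrame:
    """Permutation screen of (DE miR, disease module) pairs.

    ``mir_ids`` should already be restricted to the differentially expressed
    (typically down-regulated) miRNAs.  Returns one row per pair with
    empirical p, BH q over all pairs, and the selected flag
    (p < p_cut and q < q_cut).
    """
    mir_ids = list(mir_ids)
    if not mir_ids:
        return pd.DataFrame(
            columns=["mir_id", "module", "actual_r", "n_perm", "bg_mean", "bg_sd",
                     "bg_min", "bg_max", "pvalue", "qvalue", "selected"]
        )
    pairs = [(m, mod) for m in mir_ids for mod in sorted(module_exprs)]
    seeds = np.random.SeedSequence(seed).spawn(len(pairs))
    results = []
    for (mir_id, mod), child in zip(pairs, seeds):
        profile = MirProfile(mir_id, "", mir_matrix.data.loc[mir_id])
        res = permutation_pvalue(
            profile, module_exprs[mod], module=mod, B=B,
            seed=int(child.generate_state(1)[0] % (2**31)), alternative=alternative,
        )
        results.append(res)
    out = pd.DataFrame([r.__dict__ for r in results])
    out["qvalue"] = bh_fdr(out["pvalue"].to_numpy())
    out["selected"] = (out["pvalue"] < p_cut) & (out["qvalue"] < q_cut)
    return out


_SITE_RANK = {t: i for i, t in enumerate(SITE_TYPES)}


def predict_targets(
    mirs: list[MirProfile],
    utrs: dict[str, str] | None = None,
    external_table: pd.DataFrame | None = None,
    mode: str = "seed-only",
) -> pd.DataFrame:
    """miR -> gene target predictions from seed matches and/or an external table.

    Modes: ``seed-only`` (>=1 canonical site), ``external-only`` (table rows
    for the given miRs), ``union``, ``intersection``.  Returns one row per
    (mir, gene) pair with the evidence source, best site type and site count.
    """
    if mode not in ("seed-only", "external-only", "union", "intersection"):
        raise IntegrationError(f"unknown mode {mode!r}")
    if mode in ("union", "intersection") and external_table is None:
        raise IntegrationError(f"mode {mode!r} requires an external table")
    if mode in ("seed-only", "union", "intersection") and utrs is None:
        raise IntegrationError(f"mode {mode!r} requires UTR sequences")

    seed_hits: dict[tuple[str, str], list[SeedSite]] = {}
    if mode != "external-only":
        for mir in mirs:
            for gene, utr in utrs.items():
                sites = find_seed_sites(mir.sequence, utr)
                if sites:
                    seed_hits[(mir.mir_id, gene)] = sites

    ext_pairs: set[tuple[str, str]] = set()
    if external_table is not None:
        wanted = {m.mir_id for m in mirs}
        for row in external_table.itertuples():
            if row.mir_id in wanted:
                ext_pairs.add((row.mir_id, row.gene_id))

    if mode == "seed-only":
        pairs = set(seed_hits)
    elif mode == "external-only":
        pairs = ext_pairs
    elif mode == "union":
        pairs = set(seed_hits) | ext_pairs
    else:
        pairs = set(seed_hits) & ext_pairs

    rows = []
    for mir_id, gene in sorted(pairs):
        sites = seed_hits.get((mir_id, gene), [])
        if sites and (mir_id, gene) in ext_pairs:
            evidence = "both"
        elif sites:
            evidence = "seed-match"
        else:
            evidence = "external-table"
        best = min((s.site_type for s in sites), key=_SITE_RANK.get, default="")
        rows.append(
            {"mir_id": mir_id, "gene_id": gene, "evidence": evidence,
             "best_site_type": best, "n_sites": len(sites)}
        )
    return pd.DataFrame(rows, columns=["mir_id", "gene_id", "evidence", "best_site_type", "n_sites"])


def inverse_correlation_filter(
    predictions: pd.DataFrame,
    gene_expr: ExpressionMatrix,
    mir_matrix: NormalizedMatrix | ExpressionMatrix,
    annotation: SampleAnnotation,
    subset: str = "case",
    p_cut: float = 0.05,
) -> pd.DataFrame:
    """Keep predicted pairs with r < 0 and p < p_cut in the patient subset."""
    samples = [s for s in annotation.samples_in_group(subset) if s in gene_expr.sample_ids]
    if not samples:
        raise IntegrationError(f"no samples in subset {subset!r}")
    rows = []
    for row in predictions.itertuples():
        if row.gene_id not in gene_expr.data.index or row.mir_id not in mir_matrix.data.index:
            warnings.warn(f"pair ({row.mir_id}, {row.gene_id}) missing from matrices; skipped",
                          stacklevel=2)
            continue
        g = gene_expr.data.loc[row.gene_id, samples].to_numpy(dtype=float)
        m = mir_matrix.data.loc[row.mir_id, samples].to_numpy(dtype=float)
        if g.std() == 0 or m.std() == 0:
            warnings.warn(f"pair ({row.mir_id}, {row.gene_id}) constant in subset; skipped",
                          stacklevel=2)
            continue
        r, p = stats.pearsonr(m, g)
        if r < 0 and p < p_cut:
            rows.append(
                {"mir_id": row.mir_id, "gene_id": row.gene_id, "r": r, "pvalue": p,
                 "evidence": row.evidence}
            )
    return pd.DataFrame(rows, columns=["mir_id", "gene_id", "r", "pvalue", "evidence"])


def rank_mirs_by_target_count(integrated: pd.DataFrame) -> pd.DataFrame:
    """Rank miRNAs by their number of retained targets (ties: lexicographic)."""
    if integrated.empty:
        return pd.DataFrame(columns=["mir_id", "n_targets"])
    counts = integrated.groupby("mir_id").size().rename("n_targets").reset_index()
    counts = counts.sort_values(["n_targets", "mir_id"], ascending=[False, True])
    return counts.reset_index(drop=True)


def seed_enrichment(
    gene_set,
    background_genes,
    mir_sequence: str,
    utrs: dict[str, str],
) -> tuple[float, float]:
    """Fraction of a gene set with >=1 canonical site, and its enrichment p.

    The p-value is the one-sided hypergeometric tail for over-representation
    of site-bearing genes in the set relative to the background.
    """
    gene_set = list(gene_set)
    background = list(background_genes)
    if not gene_set:
        raise IntegrationError("empty gene set")
    extra = set(gene_set) - set(background)
    if extra:
        raise IntegrationError(f"gene set not contained in background: {sorted(extra)}")
    missing = [g for g in background if g not in utrs]
    if missing:
        raise IntegrationError(f"UTRs missing for genes: {missing[:5]}")

    has_site = {g: bool(find_seed_sites(mir_sequence, utrs[g])) for g in background}
    N = len(background)
    K = sum(has_site.values())
    n = len(gene_set)
    k = sum(has_site[g] for g in gene_set)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return k / n, p
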