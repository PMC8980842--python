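"""Self-contained simulation studies used by the analysis drivers.

Each function simulates its own inputs from a seed, runs the relevant part
of the pipeline, and returns summary numbers; the analysis scripts and the
reproduction script call these directly.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix
from .coexpression import (
    ModuleAssignment,
    UNASSIGNED,
    adjacency,
    correlation_matrix,
    detect_modules,
    preservation_zsummary,
    tom_similarity,
)
from .integration import (
    MirProfile,
    inverse_correlation_filter,
    predict_targets,
    rank_mirs_by_target_count,
    screen_mirs,
)
from .preprocess import cpm_normalize, differential_expression, filter_expressed, threshold_stability
from .simulate import SimulationConfig, generate_dataset

__all__ = [
    "preservation_study",
    "regulator_recovery_replicate",
    "threshold_stability_study",
    "REPLICATE_CONFIG",
]


def preservation_study(seed: int, n_perm: int = 200) -> dict[str, float]:
    """Module preservation between two replicate cohorts.

    Simulates two independent 50-sample cohorts sharing one 60-gene module
    specification (mean intra-module correlation about 0.5) over 400
    independent background genes, then scores (a) the planted module and
    (b) a 60-gene pseudo-module drawn from the reference background, in the
    test cohort with ``n_perm`` random same-size gene-set nulls.
    """
    base = dict(
        n_cases=25, n_controls=25, n_genes=460, module_sizes=(60,),
        disease_modules=(), factor_shift=0.0, loading_range=(0.7, 1.3),
        noise_sd=1.0, n_mirs=10, regulator_specs=((0, 0, -0.8),),
        targets_per_regulator=5, utr_length_range=(100, 200),
        gene_param_seed=seed,
    )
    ss = np.random.SeedSequence(seed).generate_state(4) % (2**31)
    ref = generate_dataset(SimulationConfig(**base, seed=int(ss[0])))
    test = generate_dataset(SimulationConfig(**base, seed=int(ss[1])))

    labels = ref.truth.gene_modules.replace({"background": UNASSIGNED})
    planted = preservation_zsummary(
        ref.genes, test.genes, ModuleAssignment(labels, 2), n_perm=n_perm, seed=int(ss[2])
    )

    rng = np.random.default_rng(int(ss[3]))
    background = [g for g, m in ref.truth.gene_modules.items() if m == "background"]
    pseudo = pd.Series(UNASSIGNED, index=labels.index)
    pseudo[rng.choice(background, 60, replace=False)] = "pseudo"
    random_set = preservation_zsummary(
        ref.genes, test.genes, ModuleAssignment(pseudo, 2), n_perm=n_perm, seed=int(ss[2])
    )
    return {
        "planted_zsummary": planted.zsummary("M1"),
        "pseudo_zsummary": random_set.zsummary("pseudo"),
    }


# study conditions for the planted-regulator recovery replicates: a 60-sample
# cohort with one 50-gene disease module, one regulator miRNA (coupling -0.8)
# with 20 planted targets, and 39 null miRNAs
REPLICATE_CONFIG = dict(
    n_cases=30, n_controls=30, n_genes=80, module_sizes=(50,),
    disease_modules=(0,), n_mirs=40, regulator_specs=((0, 0, -0.8),),
    targets_per_regulator=20, utr_length_range=(200, 400),
)


def regulator_recovery_replicate(seed: int, B: int = 10_000) -> dict:
    """One end-to-end replicate: simulate, screen, predict, filter, rank.

    Returns whether the planted regulator was selected by the permutation
    screen, its rank by integrated-target count, and the sensitivity /
    false-positive fraction of the retained target set.
    """
    cfg = SimulationConfig(**REPLICATE_CONFIG, seed=seed)
    ds = generate_dataset(cfg)

    r, _ = correlation_matrix(ds.genes)
    tom = tom_similarity(adjacency(r, 6))
    assignment = detect_modules(tom, ds.genes, min_size=30)

    log_cpm = cpm_normalize(ds.mirs, log=True)
    cpm = cpm_normalize(ds.mirs)
    expressed = filter_expressed(cpm, ds.annotation)
    mir_de = differential_expression(
        ExpressionMatrix(log_cpm.data.loc[expressed], kind="mir"), ds.annotation
    )
    down = list(mir_de[(mir_de["qvalue"] < 0.05) & (mir_de["log2fc"] < 0)].index)

    module_exprs = {m: ds.genes.subset_features(assignment.genes_in(m))
                    for m in assignment.modules}
    screen = screen_mirs(down, log_cpm, module_exprs, B=B, seed=seed)
    hits = screen.loc[screen["selected"], "mir_id"].unique() if not screen.empty else []

    profiles = [MirProfile(m, ds.truth.mir_sequences[m], log_cpm.data.loc[m]) for m in hits]
    predictions = predict_targets(profiles, utrs=ds.utrs)
    integrated = inverse_correlation_filter(predictions, ds.genes, log_cpm, ds.annotation)
    ranking = rank_mirs_by_target_count(integrated)

    regulator = next(iter(ds.truth.regulators))
    reg_module = ds.truth.regulators[regulator][0]
    # the regulator's planted module is the largest detected module (M1)
    selected = bool(
        not screen.empty
        and screen[(screen["mir_id"] == regulator) & screen["selected"]].shape[0] > 0
    )
    rank = (
        int(ranking.index[ranking["mir_id"] == regulator][0]) + 1
        if regulator in set(ranking["mir_id"])
        else np.inf
    )
    true_pairs = set(zip(ds.truth.true_targets["mir_id"], ds.truth.true_targets["gene_id"]))
    retained = set(zip(integrated["mir_id"], integrated["gene_id"])) if len(integrated) else set()
    sensitivity = len(retained & true_pairs) / len(true_pairs)
    fp_fraction = len(retained - true_pairs) / len(retained) if retained else 0.0
    return {
        "selected": selected,
        "rank": rank,
        "sensitivity": sensitivity,
        "fp_fraction": fp_fraction,
        "n_retained": len(retained),
        "regulator_module": reg_module,
    }


def threshold_stability_study(seed: int) -> dict:
    """The cpm-cutoff subsampling experiment on one ~10M-read library.

    Simulates one default cohort, takes its deepest miRNA library, and
    subsamples it to 0.6-5M reads in triplicate, counting expressed miRNAs
    at 1, 2 and 3 cpm and the log-cpm R^2 against the full library.
    """
    ds = generate_dataset(SimulationConfig(seed=seed))
    lib = ds.mirs.library_sizes
    sample = lib.idxmax()
    column = ds.mirs.data[sample]
    depths = [600_000, 1_000_000, 2_000_000, 3_000_000, 4_000_000, 5_000_000]
    report = threshold_stability(column, depths=depths, cutoffs=[1.0, 2.0, 3.0], seed=seed)
    spread = {
        cutoff: float(grp["n_expressed"].max() - grp["n_expressed"].min())
        for cutoff, grp in report.expressed.groupby("cutoff")
    }
    full = threshold_stability(column, depths=[int(column.sum())], cutoffs=[2.0], n_reps=1,
                               seed=seed)
    return {
        "library_size": int(column.sum()),
        "spread_by_cutoff": spread,
        "full_depth_r2": float(full.r_squared["r_squared"].iloc[0]),
        "report": report,
    }
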