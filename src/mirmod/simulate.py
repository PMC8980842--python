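"""Synthetic paired mRNA/miRNA cohorts with planted ground truth.

The generator emulates the structure of a case/control monocyte cohort
profiled on expression arrays (genes) and by small RNA-seq (miRNA counts):

* genes are organised in coexpression modules driven by latent per-sample
  factors (``x_gs = a_g * f_m(s) + noise``); disease modules have their
  factor mean shifted in cases;
* miRNA counts are negative binomial with library-size-proportional means;
  planted regulator miRNAs carry a negative log-linear coupling to their
  module's factor, so their normalized abundance anti-correlates with the
  module eigengene;
* every true target gene's 3'UTR carries exactly one canonical seed site
  for its regulator, while all other UTRs are guaranteed site-free for all
  regulators (rejection sampling);
* therapy-response labels follow a logistic model on the first disease
  module's factor (high module activity -> nonresponse).

All randomness flows from ``SimulationConfig.seed`` through four named
substreams (genes, mirs, utrs, response), in that order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CountMatrix, ExpressionMatrix, SampleAnnotation
from .seeds import SITE_TYPES, find_seed_sites, site_sequence

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SyntheticDataset",
    "ConfigurationError",
    "generate_dataset",
    "generate_mir_counts",
    "generate_utr_sequences",
]


class ConfigurationError(ValueError):
    """Raised when a SimulationConfig violates its invariants."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohort generator.

    Defaults reflect a monocyte IBD-vs-healthy style study: 46 cases and 20
    controls, three 50-gene modules in a 500-gene background, one disease
    module whose factor is shifted by 2 SD in cases, and one regulator miRNA
    coupled to it with strength -0.8 among 400 miRNAs sequenced to ~10M
    reads per library.
    """

    n_cases: int = 46
    n_controls: int = 20
    n_genes: int = 500
    module_sizes: tuple[int, ...] = (50, 50, 50)
    disease_modules: tuple[int, ...] = (0,)
    factor_shift: float = 2.0
    loading_range: tuple[float, float] = (0.7, 0.9)
    noise_sd: float = 0.6
    n_mirs: int = 400
    # (mir index, module index, coupling<0) per planted regulator
    regulator_specs: tuple[tuple[int, int, float], ...] = ((0, 0, -0.8),)
    mir_mean_cpm_range: tuple[float, float] = (0.05, 5000.0)
    regulator_mean_cpm_range: tuple[float, float] = (50.0, 500.0)
    mir_dispersion: float = 0.1
    library_size_range: tuple[int, int] = (8_500_000, 11_000_000)
    utr_length_range: tuple[int, int] = (300, 800)
    utr_gc: float = 0.45
    site_type_for_true_targets: str = "8mer"
    targets_per_regulator: int = 20
    response_beta: float = 2.0
    seed: int = 0
    # seed for gene-level parameters (module loadings); two cohorts sharing
    # this value but differing in `seed` are independent subject samples of
    # the same underlying network (replicate cohorts for preservation)
    gene_param_seed: int | None = None

    def validate(self) -> None:
        for name in ("n_cases", "n_controls", "n_genes", "n_mirs", "targets_per_regulator"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if any(s <= 0 for s in self.module_sizes):
            raise ConfigurationError("module_sizes must all be positive")
        if sum(self.module_sizes) > self.n_genes:
            raise ConfigurationError("module_sizes sum exceeds n_genes")
        n_modules = len(self.module_sizes)
        if any(m < 0 or m >= n_modules for m in self.disease_modules):
            raise ConfigurationError("disease_modules contains an invalid module index")
        for mir_idx, mod_idx, coupling in self.regulator_specs:
            if not (0 <= mir_idx < self.n_mirs):
                raise ConfigurationError(f"regulator_specs: invalid mir index {mir_idx}")
            if not (0 <= mod_idx < n_modules):
                raise ConfigurationError(f"regulator_specs: invalid module index {mod_idx}")
            if coupling >= 0:
                raise ConfigurationError("regulator_specs: coupling must be negative")
            if self.targets_per_regulator > self.module_sizes[mod_idx]:
                raise ConfigurationError(
                    "targets_per_regulator exceeds the regulator's module size"
                )
        if not (0.0 < self.utr_gc < 1.0):
            raise ConfigurationError("utr_gc must lie in (0, 1)")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")
        if self.mir_dispersion < 0:
            raise ConfigurationError("mir_dispersion must be non-negative")
        lo, hi = self.library_size_range
        if lo <= 0 or hi < lo:
            raise ConfigurationError("library_size_range must be a positive interval")
        lo, hi = self.utr_length_range
        if lo < 30 or hi < lo:
            raise ConfigurationError("utr_length_range must be an interval with lower bound >= 30")
        if self.site_type_for_true_targets not in SITE_TYPES:
            raise ConfigurationError(
                f"site_type_for_true_targets must be one of {SITE_TYPES}"
            )


@dataclass
class GroundTruth:
    """Planted structure of a synthetic dataset."""

    gene_modules: pd.Series            # gene id -> module label ("M1".. / "background")
    disease_modules: list[str]         # module labels with shifted case means
    regulators: dict[str, tuple[str, float]]  # mir id -> (module label, coupling)
    true_targets: pd.DataFrame         # mir_id, gene_id, site_type, start, end
    factors: pd.DataFrame              # module label x sample
    responders: pd.Series              # sample -> responder/nonresponder/NA (cases only)
    mir_sequences: dict[str, str]      # mir id -> mature RNA sequence 5'->3'

    def module_genes(self, module: str) -> list[str]:
        return list(self.gene_modules.index[self.gene_modules == module])


@dataclass
class SyntheticDataset:
    genes: ExpressionMatrix
    mirs: CountMatrix
    annotation: SampleAnnotation
    utrs: dict[str, str]
    truth: GroundTruth

    @property
    def sample_ids(self) -> list[str]:
        return self.genes.sample_ids


def _substreams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(4)
    names = ("genes", "mirs", "utrs", "response")
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _module_labels(config: SimulationConfig) -> list[str]:
    return [f"M{i + 1}" for i in range(len(config.module_sizes))]


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate a fully-specified synthetic cohort.

    Deterministic given ``config`` (including its seed).
    """
    config.validate()
    rngs = _substreams(config.seed)

    n = config.n_cases + config.n_controls
    samples = [f"S{i + 1:03d}" for i in range(n)]
    is_case = np.array([True] * config.n_cases + [False] * config.n_controls)
    labels = _module_labels(config)

    rng = rngs["genes"]
    factors = {}
    for m, label in enumerate(labels):
        f = rng.normal(size=n)
        if m in config.disease_modules:
            f = f + np.where(is_case, config.factor_shift, 0.0)
        factors[label] = f
    factor_df = pd.DataFrame(factors, index=samples).T

    gene_ids = [f"G{i + 1:04d}" for i in range(config.n_genes)]
    module_of = pd.Series("background", index=gene_ids, name="module")
    X = np.empty((config.n_genes, n))
    pos = 0
    lo, hi = config.loading_range
    param_seed = config.seed if config.gene_param_seed is None else config.gene_param_seed
    param_rng = np.random.default_rng(np.random.SeedSequence((param_seed, 1)))
    for m, (label, size) in enumerate(zip(labels, config.module_sizes)):
        loadings = param_rng.uniform(lo, hi, size=size)
        block = np.outer(loadings, factor_df.loc[label].to_numpy())
        block += rng.normal(scale=config.noise_sd, size=block.shape)
        X[pos:pos + size] = block
        module_of.iloc[pos:pos + size] = label
        pos += size
    n_bg = config.n_genes - pos
    if n_bg:
        X[pos:] = rng.normal(size=(n_bg, n))
    # array-like per-gene baselines (do not affect any correlation statistic)
    X += rng.normal(loc=8.0, scale=1.5, size=(config.n_genes, 1))
    genes = ExpressionMatrix(pd.DataFrame(X, index=gene_ids, columns=samples), kind="gene")

    mir_ids = [f"miR-{i + 1:04d}" for i in range(config.n_mirs)]
    mirs, mir_sequences = generate_mir_counts(
        config, factor_df, rng=rngs["mirs"], sample_ids=samples, mir_ids=mir_ids
    )

    regulators = {
        mir_ids[mi]: (labels[mo], coupling) for mi, mo, coupling in config.regulator_specs
    }

    # pick true targets inside each regulator's module
    target_rows = []
    utr_rng = rngs["utrs"]
    for mir_id, (mod_label, _c) in sorted(regulators.items()):
        members = list(module_of.index[module_of == mod_label])
        chosen = utr_rng.choice(len(members), size=config.targets_per_regulator, replace=False)
        for gi in sorted(chosen):
            target_rows.append((mir_id, members[gi]))

    truth = GroundTruth(
        gene_modules=module_of,
        disease_modules=[labels[m] for m in config.disease_modules],
        regulators=regulators,
        true_targets=pd.DataFrame(target_rows, columns=["mir_id", "gene_id"]),
        factors=factor_df,
        responders=pd.Series(pd.NA, index=samples, dtype="object"),
        mir_sequences=mir_sequences,
    )
    utrs = generate_utr_sequences(truth, config, rng=utr_rng)

    # therapy response: logistic on the first disease module's factor, cases only
    resp_rng = rngs["response"]
    response = pd.Series(pd.NA, index=samples, dtype="object")
    if config.disease_modules:
        f = factor_df.loc[labels[config.disease_modules[0]]].to_numpy()
        fc = f - f[is_case].mean() if is_case.any() else f
        p_nonresp = 1.0 / (1.0 + np.exp(-config.response_beta * fc))
        draw = resp_rng.uniform(size=n) < p_nonresp
        response[is_case] = np.where(draw[is_case], "nonresponder", "responder")
    truth.responders = response

    annotation = SampleAnnotation(
        pd.DataFrame(
            {
                "group": np.where(is_case, "case", "control"),
                "response": response,
            },
            index=pd.Index(samples, name="sample_id"),
        )
    )
    return SyntheticDataset(genes=genes, mirs=mirs, annotation=annotation, utrs=utrs, truth=truth)


def generate_mir_counts(
    config: SimulationConfig,
    factors: pd.DataFrame,
    rng: np.random.Generator | None = None,
    sample_ids: list[str] | None = None,
    mir_ids: list[str] | None = None,
) -> tuple[CountMatrix, dict[str, str]]:
    """Negative-binomial miRNA counts with library-size scaling.

    Per-miR mean is ``cpm_i / 1e6 * L_s`` with ``L_s`` the sample library
    size; planted regulators multiply the mean by ``exp(coupling * f_m(s))``
    so their normalized abundance falls as module activity rises.  Returns
    the count matrix and the random mature sequences (22 nt RNA) of all miRs.
    """
    if rng is None:
        rng = _substreams(config.seed)["mirs"]
    if sample_ids is None:
        sample_ids = list(factors.columns)
    missing = [s for s in sample_ids if s not in factors.columns]
    if missing:
        raise ConfigurationError(f"factor values missing for samples: {missing}")
    if mir_ids is None:
        mir_ids = [f"miR-{i + 1:04d}" for i in range(config.n_mirs)]

    n = len(sample_ids)
    labels = _module_labels(config)
    regulator_idx = {mi: (mo, c) for mi, mo, c in config.regulator_specs}

    lo, hi = config.mir_mean_cpm_range
    base_cpm = np.exp(rng.uniform(np.log(lo), np.log(hi), size=config.n_mirs))
    rlo, rhi = config.regulator_mean_cpm_range
    for mi in regulator_idx:
        base_cpm[mi] = np.exp(rng.uniform(np.log(rlo), np.log(rhi)))
    # treat the draws as relative abundances: rescale so the expected read
    # total per library matches the drawn library size (cpm sums to 1e6)
    base_cpm *= 1e6 / base_cpm.sum()

    lib_lo, lib_hi = config.library_size_range
    lib_sizes = rng.integers(lib_lo, lib_hi + 1, size=n)

    mu = np.outer(base_cpm / 1e6, lib_sizes).astype(float)
    for mi, (mo, coupling) in regulator_idx.items():
        f = factors.loc[labels[mo], sample_ids].to_numpy()
        mu[mi] *= np.exp(coupling * f)

    if config.mir_dispersion > 0:
        shape = 1.0 / config.mir_dispersion
        lam = rng.gamma(shape, mu / shape)
    else:
        lam = mu
    counts = rng.poisson(lam)

    seq = ["".join(rng.choice(list("ACGU"), size=22)) for _ in range(config.n_mirs)]
    mir_sequences = dict(zip(mir_ids, seq))
    matrix = CountMatrix(pd.DataFrame(counts, index=mir_ids, columns=sample_ids))
    return matrix, mir_sequences


_MAX_UTR_TRIES = 500


def _random_utr(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(list("ACGT"), size=length, p=p))


def _regulator_sites(utr: str, mir_seqs: dict[str, str], regulators) -> dict[str, list]:
    return {mir_id: find_seed_sites(mir_seqs[mir_id], utr) for mir_id in regulators}


def generate_utr_sequences(
    truth: GroundTruth,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> dict[str, str]:
    """Random DNA 3'UTRs with planted seed sites for true targets only.

    True-target UTRs contain exactly one canonical site (of the configured
    type) for their regulator and no site for any other regulator; all other
    UTRs are site-free for every regulator.  Enforced by rejection sampling.
    """
    if rng is None:
        rng = _substreams(config.seed)["utrs"]
    for mir_id in truth.regulators:
        if mir_id not in truth.mir_sequences:
            raise ConfigurationError(f"no mature sequence for regulator {mir_id}")

    target_of: dict[str, list[str]] = {}
    for row in truth.true_targets.itertuples():
        target_of.setdefault(row.gene_id, []).append(row.mir_id)

    lo, hi = config.utr_length_range
    regulator_ids = sorted(truth.regulators)
    utrs: dict[str, str] = {}
    site_records = []
    for gene in truth.gene_modules.index:
        mirs_here = target_of.get(gene, [])
        if len(mirs_here) > 1:
            raise ConfigurationError(f"gene {gene} assigned to multiple regulators")
        for attempt in range(_MAX_UTR_TRIES):
            length = int(rng.integers(lo, hi + 1))
            utr = _random_utr(rng, length, config.utr_gc)
            if mirs_here:
                mir_id = mirs_here[0]
                site = site_sequence(truth.mir_sequences[mir_id], config.site_type_for_true_targets)
                start = int(rng.integers(1, length - len(site)))
                utr = utr[:start] + site + utr[start + len(site):]
            sites = _regulator_sites(utr, truth.mir_sequences, regulator_ids)
            if mirs_here:
                own = sites.pop(mirs_here[0])
                ok = (
                    len(own) == 1
                    and own[0].site_type == config.site_type_for_true_targets
                    and all(len(s) == 0 for s in sites.values())
                )
                if ok:
                    utrs[gene] = utr
                    site_records.append(
                        (mirs_here[0], gene, own[0].site_type, own[0].start, own[0].end)
                    )
                    break
            else:
                if all(len(s) == 0 for s in sites.values()):
                    utrs[gene] = utr
                    break
        else:
            raise ConfigurationError(
                f"could not generate a valid UTR for gene {gene} in {_MAX_UTR_TRIES} tries; "
                "try longer UTRs or a different seed"
            )

    if site_records:
        planted = pd.DataFrame(
            site_records, columns=["mir_id", "gene_id", "site_type", "start", "end"]
        )
        truth.true_targets = planted.sort_values(["mir_id", "gene_id"]).reset_index(drop=True)
    return utrs
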