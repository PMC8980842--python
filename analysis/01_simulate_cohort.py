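#!/usr/bin/env python
"""Simulate the study cohort: 46 cases / 20 controls with planted structure.

Writes the gene expression matrix, miRNA count matrix, sample annotation,
3'UTR FASTA, miRNA mature-sequence FASTA and the ground-truth JSON under
results/data/.
"""

from pathlib import Path

from mirmod import SimulationConfig, generate_dataset
from mirmod.io import write_dataset

OUT = Path(__file__).resolve().parents[1] / "results" / "data"


def main() -> None:
    config = SimulationConfig(seed=20260101)
    dataset = generate_dataset(config)
    paths = write_dataset(dataset, OUT)

    truth = dataset.truth
    print(f"cohort: {config.n_cases} cases, {config.n_controls} controls")
    print(f"genes: {config.n_genes} ({len(config.module_sizes)} planted modules "
          f"of sizes {list(config.module_sizes)}; disease modules {truth.disease_modules})")
    print(f"miRNAs: {config.n_mirs}; planted regulators: {truth.regulators}")
    print(f"true targets: {len(truth.true_targets)} (site type "
          f"{config.site_type_for_true_targets})")
    print("written:")
    for name, path in paths.items():
        print(f"  {name}: {path}")


if __name__ == "__main__":
    main()
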