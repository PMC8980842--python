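#!/usr/bin/env python
"""Score the pipeline output of 02 against the planted ground truth of 01."""

import json
from pathlib import Path

import pandas as pd

from mirmod import recovery_metrics
from mirmod.io import read_ground_truth

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "results" / "data"
PIPE = ROOT / "results" / "pipeline"
OUT = ROOT / "results" / "recovery.json"


def main() -> None:
    truth = read_ground_truth(DATA / "ground_truth.json")
    assignment = pd.read_csv(PIPE / "module_assignment.tsv", sep="\t", index_col=0)["module"]
    screen = pd.read_csv(PIPE / "permutation_screen.tsv", sep="\t")
    integrated = pd.read_csv(PIPE / "integrated_targets.tsv", sep="\t")
    ranking = pd.read_csv(PIPE / "mir_ranking.tsv", sep="\t")

    report = recovery_metrics(assignment, screen, integrated, ranking, truth)
    OUT.write_text(json.dumps(report.to_dict(), indent=1))
    print(f"module recovery ARI: {report.module_ari:.3f}")
    print(f"regulator screen: sensitivity {report.screen_sensitivity:.2f}, "
          f"specificity {report.screen_specificity:.2f}")
    print(f"target filter: sensitivity {report.target_sensitivity:.2f}, "
          f"precision {report.target_precision:.2f}")
    print(f"planted regulator rank(s): {report.regulator_ranks}")
    print(f"written: {OUT}")


if __name__ == "__main__":
    main()
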