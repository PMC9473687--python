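#!/usr/bin/env python
"""Region-level peptide abundance analysis of the simulated LC-MS table.

Reads results/data/peptides.tsv, applies the 1.5e7 control-median
filter, normalizes to the constitutive region (exons 256-363), and
summarizes/tests the three proximal-Ig regions.  Expect ~+18% and ~+16%
knockout increases on exons 70-79 and 80-88 (the generator's ground
truth), with the Bonferroni-adjusted threshold 0.025 over the two
regions detected in both genotypes.
"""

import json
from pathlib import Path

import pandas as pd

from titinsplice.io import read_peptide_table
from titinsplice.pipeline import RunConfig, run_proteomics

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    groups = json.loads((ROOT / "data" / "groups.json").read_text())
    table = read_peptide_table(
        ROOT / "data" / "peptides.tsv",
        groups=groups,
        sequence_column="peptide_sequence",
        exon_column="exons",
    )
    report = run_proteomics(RunConfig(), table=table)

    out = ROOT / "analysis"
    out.mkdir(parents=True, exist_ok=True)
    (out / "proteomics_report.json").write_text(json.dumps(report, indent=1, default=str))
    rows = [
        {"region": name, **{k: v for k, v in r.items() if not isinstance(v, (dict, list))}}
        for name, r in report["regions"].items()
    ]
    pd.DataFrame(rows).to_csv(out / "region_summaries.tsv", sep="\t", index=False)

    print(f"peptides: {report['n_peptides_input']} read, "
          f"{report['n_peptides_retained']} past the 1.5e7 filter, "
          f"{report['n_exons_covered']} exons covered")
    for name, r in report["regions"].items():
        print(f"  exons {name}: {r['percent_difference']:+.1f}% (p={r['p_value']:.2e}, "
              f"adjusted alpha={r['alpha_adjusted']}, significant={r['significant']})")


if __name__ == "__main__":
    main()
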