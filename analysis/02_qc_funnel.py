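#!/usr/bin/env python
"""Apply the preprocessing funnel to the simulated cohort: keep mutations with
>= 10 DNA and >= 10 RNA reads, drop hypermutated samples (> 10 mutations/Mb),
and discard genes mutated more than once within a sample.

Writes the filtered table and a per-stage funnel report under results/.
"""

from pathlib import Path

import pandas as pd

from aimseq import filters, io

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    records = io.read_mutation_table(ROOT / "cohort" / "mutations.tsv")
    reports = []
    kept, rep = filters.filter_by_depth(records, 10, 10)
    reports.append(rep)
    kept, rep = filters.drop_hypermutated(kept, 10.0, 38.0)
    reports.append(rep)
    kept, rep = filters.drop_multimutant_genes(kept)
    reports.append(rep)

    io.write_mutation_table(kept, ROOT / "mutations_filtered.tsv")
    funnel = pd.DataFrame([
        {"stage": r.stage_name, "records_in": r.records_in,
         "records_out": r.records_out, "n_removed": len(r.removed_ids)}
        for r in reports
    ])
    funnel.to_csv(ROOT / "funnel.tsv", sep="\t", index=False)
    print(funnel.to_string(index=False))
    print(f"\nretained {len(kept)}/{len(records)} mutations "
          f"-> {ROOT / 'mutations_filtered.tsv'}")


if __name__ == "__main__":
    main()
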