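#!/usr/bin/env python
"""Summarize plasmid dynamics and acquisitions from the cohort run.

Collects the per-strain plasmid reports (coverage breadth, PLR, loss class,
entire-loss confirmation) into results/plasmid_summary.tsv, copies the
accessory membership matrix, and prints the acquired-fragment evidence
(length, host 23S homology, donor homology) the way a genome-stability survey
would report an HGT event.
"""

import json
import shutil
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
RUN = ROOT / "scratch" / "full_run"


def main() -> None:
    if not RUN.exists():
        sys.exit("no cohort run found; run analysis/01_run_cohort.py first")
    results = ROOT / "results"
    results.mkdir(exist_ok=True)

    rows = []
    for sdir in sorted((RUN / "strains").iterdir()):
        with open(sdir / "plasmid_report.tsv") as fh:
            header = fh.readline().rstrip("\n").split("\t")
            for line in fh:
                rows.append(dict(zip(header, line.rstrip("\n").split("\t"))))
    out = results / "plasmid_summary.tsv"
    with open(out, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for r in rows:
            fh.write("\t".join(r[c] for c in header) + "\n")
    print(f"wrote {out}")

    lossy = [r for r in rows if r["loss_class"] != "none"]
    n_strains = len({r["strain"] for r in rows})
    n_loss_strains = len({r["strain"] for r in lossy})
    print(f"plasmid loss in {n_loss_strains} of {n_strains} strains:")
    for r in lossy:
        print(f"  {r['strain']} {r['plasmid']}: breadth={r['breadth']} "
              f"PLR={r['plr']} class={r['loss_class']} ({r['confirmed']})")

    shutil.copy(RUN / "accessory_matrix.tsv", results / "accessory_matrix.tsv")
    shutil.copy(RUN / "variation_matrix.tsv", results / "variation_matrix.tsv")
    summary = json.loads((RUN / "summary.json").read_text())
    print(f"accessory fragments: {summary['accessory_fragments']}; "
          f"HGT candidates: {summary['hgt_candidates']}")


if __name__ == "__main__":
    main()
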