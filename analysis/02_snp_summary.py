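#!/usr/bin/env python
"""Condense per-strain SNP calls from the cohort run into one table.

Reads the per-strain catalogs written by 01_run_cohort.py, tallies effect
classes per strain, and verifies the planted-event ledgers: every planted
substitution should be recovered and nothing else called (error-free reads at
100x leave no room for misses). Writes results/snp_summary.tsv.
"""

import json
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
RUN = ROOT / "scratch" / "full_run"

from gutstab import variants as va  # noqa: E402


def main() -> None:
    if not RUN.exists():
        sys.exit("no cohort run found; run analysis/01_run_cohort.py first")
    rows = []
    for sdir in sorted((RUN / "strains").iterdir()):
        records = va.load_catalog(sdir / "snps.tsv")
        truth = json.loads((sdir / "truth.json").read_text())
        planted = {(s["pos"], s["alt"]) for s in truth["snps"]}
        called = {(r.genome_pos, r.alt_base) for r in records}
        summary = va.tally_catalog(records)
        rows.append({
            "strain": sdir.name,
            "snps_called": summary.total,
            "synonymous": summary.by_type["synonymous"],
            "non_synonymous": summary.by_type["non-synonymous"],
            "nonsense": summary.by_type["nonsense"],
            "intergenic": summary.by_type["intergenic"],
            "snps_planted": len(planted),
            "exact_recovery": int(planted == called),
        })
    out = ROOT / "results" / "snp_summary.tsv"
    out.parent.mkdir(exist_ok=True)
    cols = list(rows[0])
    with open(out, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in rows:
            fh.write("\t".join(str(r[c]) for c in cols) + "\n")
    print(f"wrote {out}")
    for r in rows:
        status = "exact" if r["exact_recovery"] else "MISMATCH"
        print(f"  {r['strain']}: {r['snps_called']} called / "
              f"{r['snps_planted']} planted ({status})")
    total = sum(r["snps_called"] for r in rows)
    print(f"cohort total: {total} SNPs "
          f"({sum(r['non_synonymous'] for r in rows)} non-synonymous, "
          f"{sum(r['synonymous'] for r in rows)} synonymous, "
          f"{sum(r['nonsense'] for r in rows)} nonsense, "
          f"{sum(r['intergenic'] for r in rows)} intergenic)")


if __name__ == "__main__":
    main()
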