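#!/usr/bin/env python
"""Simulate the desk-scale cohort and run every analysis stage.

Builds the synthetic reference (200-kb chromosome at 44.5% GC, seven plasmids
of which p2/p4/p7 carry chromosome-homologous segments, five 2923-bp 23S
copies), plants the six-strain event cohort (catalog substitutions, complete
and partial plasmid losses, one acquired 23S-like fragment), simulates 101-bp
pairs at 100x, and runs mapping, SNP calling, pan-genome delineation,
presence/PLR calling, HGT detection and manifest screening end to end.

Bulky per-strain outputs (FASTA, truth ledgers, depth-derived reports) land
under scratch/full_run/; the follow-up scripts condense them into results/.
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]

from gutstab.pipeline import PipelineConfig, run_all  # noqa: E402


def main() -> None:
    seed = int(sys.argv[1]) if len(sys.argv) > 1 else 42
    outdir = ROOT / "scratch" / "full_run"
    cfg = PipelineConfig(seed=seed)
    result = run_all(cfg, outdir, compute_strain_ani=True)

    print()
    print(f"cohort of {len(result.strains)} strains analyzed into {outdir}")
    for s in result.strains:
        losses = {r.plasmid_id: r.loss_class for r in s.plasmids
                  if r.loss_class != "none"}
        ani = f"{s.ani:.2f}" if s.ani is not None else "n/a"
        print(f"  {s.strain_id}: {len(s.snps)} SNPs, losses={losses or '{}'}, "
              f"ANI vs reference={ani}")
    print(f"accessory genome: {len(result.accessory)} non-redundant fragments, "
          f"{sum(f.length for f in result.accessory)} bp")
    print(f"HGT candidates: {len(result.acquisitions)}")
    print(f"manifest screening: {result.screen.n_retained} of "
          f"{result.screen.n_retained + result.screen.n_excluded} isolates retained")


if __name__ == "__main__":
    main()
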