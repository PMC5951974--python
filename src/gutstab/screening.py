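"""Cohort screening and evolutionary-rate arithmetic.

Isolates are accepted as descendants of the reference strain when their ANI
against the reference reaches the species cutoff (95%); anything below —
including isolates for which no ANI could be computed — is excluded with a
reason. The mutation-rate estimate is the study-style bound: the largest
per-strain SNP count divided by an explicit generation count (never inferred
silently), compared against the 0.0033 changes-per-generation spontaneous
benchmark.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

SPECIES_ANI_CUTOFF = 95.0
SPONTANEOUS_RATE_BENCHMARK = 0.0033  # changes per generation

MANIFEST_COLUMNS = ["isolate_id", "subject_id", "trial", "timepoint",
                    "genome_size", "gc_percent", "ani_vs_reference"]


@dataclass
class ScreenResult:
    retained: pd.DataFrame
    excluded: pd.DataFrame  # with an extra 'reason' column

    @property
    def n_retained(self) -> int:
        return len(self.retained)

    @property
    def n_excluded(self) -> int:
        return len(self.excluded)


def load_manifest(path=None) -> pd.DataFrame:
    """Load a cohort manifest TSV; defaults to the packaged synthetic manifest
    reproducing the study-scale bookkeeping (108 isolates across 3 trials)."""
    if path is None:
        path = resources.files("gutstab.data") / "cohort_manifest_synthetic.tsv"
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    if not df["trial"].isin([1, 2, 3]).all():
        raise ValueError("trial must be one of 1, 2, 3")
    return df


def screen_descendants(manifest: pd.DataFrame,
                       ani_cutoff: float = SPECIES_ANI_CUTOFF) -> ScreenResult:
    """Retain isolates with ANI >= cutoff; exclude the rest with reasons.

    Isolates whose ANI is undefined (no alignable fragments) are never
    retained.
    """
    df = manifest.copy()
    ani = pd.to_numeric(df["ani_vs_reference"], errors="coerce")
    keep = ani >= ani_cutoff
    retained = df[keep].copy()
    excluded = df[~keep].copy()
    reasons = []
    for _, row in excluded.iterrows():
        v = pd.to_numeric(pd.Series([row["ani_vs_reference"]]), errors="coerce")[0]
        if pd.isna(v):
            reasons.append("ANI undefined (no alignable fragments)")
        else:
            reasons.append(f"ANI {v:.1f} < {ani_cutoff:g} (different species)")
    excluded["reason"] = reasons
    retained["retained"] = True
    return ScreenResult(retained, excluded)


@dataclass
class MutationRateEstimate:
    rate: float  # changes per generation
    max_snps_per_strain: int
    generations: int
    benchmark: float = SPONTANEOUS_RATE_BENCHMARK

    @property
    def at_or_below_spontaneous(self) -> bool:
        return self.rate <= self.benchmark


def estimate_mutation_rate(max_snps_per_strain: int,
                           generations: int) -> MutationRateEstimate:
    """Upper-bound mutation rate: max per-strain SNP count / generations."""
    if generations <= 0:
        raise ValueError("generations must be positive")
    if max_snps_per_strain < 0:
        raise ValueError("SNP count cannot be negative")
    return MutationRateEstimate(
        rate=max_snps_per_strain / generations,
        max_snps_per_strain=max_snps_per_strain,
        generations=generations)


@dataclass
class AbundanceSeries:
    subject_id: str
    timepoints: list[float]  # days or weeks, strictly increasing
    log10_abundance: list[float]  # per gram of sample
    detection_limit: float  # same units as log10_abundance

    def __post_init__(self):
        if len(self.timepoints) != len(self.log10_abundance):
            raise ValueError("timepoints and abundances differ in length")
        if any(b <= a for a, b in zip(self.timepoints, self.timepoints[1:])):
            raise ValueError("timepoints must be strictly increasing")


@dataclass
class PersistenceSummary:
    subject_id: str
    last_detectable: float | None  # None when never above the detection limit
    peak_abundance: float | None
    peak_timepoint: float | None


def persistence_summary(series: AbundanceSeries) -> PersistenceSummary:
    """Last timepoint above the detection limit, and the abundance peak."""
    detectable = [(t, a) for t, a in zip(series.timepoints, series.log10_abundance)
                  if a > series.detection_limit]
    if not detectable:
        return PersistenceSummary(series.subject_id, None, None, None)
    last = max(t for t, _ in detectable)
    peak_t, peak_a = max(detectable, key=lambda ta: ta[1])
    return PersistenceSummary(series.subject_id, last, peak_a, peak_t)


def write_screen_report(result: ScreenResult, tsv_path, log_path=None) -> None:
    merged = pd.concat([
        result.retained.assign(reason=""),
        result.excluded.assign(retained=False),
    ])
    merged.to_csv(tsv_path, sep="\t", index=False)
    if log_path is not None:
        with open(log_path, "w") as fh:
            fh.write(f"isolates: {len(merged)}\n")
            fh.write(f"retained: {result.n_retained}\n")
            fh.write(f"excluded: {result.n_excluded}\n")
            for _, row in result.excluded.iterrows():
                fh.write(f"  {row['isolate_id']}: {row['reason']}\n")
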