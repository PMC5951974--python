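"""End-to-end orchestration: simulate a cohort, run every analysis stage, and
emit the consolidated per-strain variation report.

Stages run in a fixed order (simulate -> map -> snps -> pangenome ->
presence/PLR -> HGT -> screening -> report); every stage is deterministic
given the config seed, and the effective configuration (with every threshold)
is snapshotted into the run directory for auditability.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import pangenome as pg
from . import replicon_dynamics as rd
from . import screening as scr
from . import synthgenome as sg
from . import variants as va
from .homology import ReadMapper, compute_ani
from .seqs import write_fasta

log = logging.getLogger("gutstab")


@dataclass
class Thresholds:
    core_min_identity: float = 90.0
    core_max_evalue: float = 1e-5
    dedup_min_identity: float = 90.0
    dedup_length_fraction: float = 0.85
    presence_breadth: float = 0.8
    absence_breadth: float = 0.2
    snp_min_quality: float = 20.0
    snp_min_depth: int = 10
    ani_species_cutoff: float = 95.0
    repeat_min_identity: float = 95.0
    repeat_min_length: int = 100
    min_zero_run: int = 300

    def validate(self) -> None:
        if not (0 <= self.absence_breadth < self.presence_breadth <= 1):
            raise ValueError(
                "presence threshold must exceed absence threshold within [0, 1]")
        for name in ("core_min_identity", "dedup_min_identity",
                     "ani_species_cutoff", "repeat_min_identity"):
            v = getattr(self, name)
            if not (0 <= v <= 100):
                raise ValueError(f"{name} must be a percent in [0, 100]")
        if self.snp_min_depth < 0 or self.snp_min_quality < 0:
            raise ValueError("SNP filter thresholds must be non-negative")


@dataclass
class StrainPlan:
    """Declarative description of one simulated strain's planted events."""

    strain_id: str
    catalog_snps: bool = False  # plant the 7/9/2/1 effect-class mix
    complete_losses: list[str] = field(default_factory=list)
    partial_losses: dict[str, float] = field(default_factory=dict)  # plasmid -> PLR
    acquisition: bool = False


def default_cohort() -> list[StrainPlan]:
    """Six-strain desk cohort exercising every event type."""
    return [
        StrainPlan("S01"),
        StrainPlan("S02", catalog_snps=True),
        StrainPlan("S03", complete_losses=["p4"]),
        StrainPlan("S04", partial_losses={"p1": 0.75, "p2": 0.85}),
        StrainPlan("S05", partial_losses={"p1": 0.5}, complete_losses=["p7"]),
        StrainPlan("S06", acquisition=True, complete_losses=["p4"]),
    ]


@dataclass
class PipelineConfig:
    seed: int = 42
    genome: sg.GenomeConfig = field(default_factory=sg.GenomeConfig)
    cohort: list[StrainPlan] = field(default_factory=default_cohort)
    read_params: sg.ReadSimParams = field(default_factory=sg.ReadSimParams)
    thresholds: Thresholds = field(default_factory=Thresholds)
    contig_mean_length: int = 20_000

    def validate(self) -> None:
        self.thresholds.validate()
        self.read_params.validate()

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        if "seed" in raw:
            cfg.seed = int(raw["seed"])
        if "contig_mean_length" in raw:
            cfg.contig_mean_length = int(raw["contig_mean_length"])
        if "genome" in raw:
            g = dict(raw["genome"])
            plasmids = [sg.PlasmidSpec(**p) for p in g.pop("plasmids", [])]
            for key in ("gene_length_codons", "intergenic_gap"):
                if key in g:
                    g[key] = tuple(g[key])
            cfg.genome = sg.GenomeConfig(**g)
            if plasmids:
                cfg.genome.plasmids = plasmids
        if "read_params" in raw:
            cfg.read_params = sg.ReadSimParams(**raw["read_params"])
        if "thresholds" in raw:
            cfg.thresholds = Thresholds(**raw["thresholds"])
        if "cohort" in raw:
            cfg.cohort = [StrainPlan(**p) for p in raw["cohort"]]
        cfg.validate()
        return cfg


def small_config(seed: int = 42) -> PipelineConfig:
    """Reduced problem size for quick exploratory runs and unit tests."""
    genome = sg.GenomeConfig(
        chrom_length=60_000,
        plasmids=[
            sg.PlasmidSpec("p1", 8_000, 0.0, 2),
            sg.PlasmidSpec("p2", 6_000, 0.35, 2),
            sg.PlasmidSpec("p3", 5_000, 0.0, 1),
            sg.PlasmidSpec("p4", 7_000, 0.30, 2),
            sg.PlasmidSpec("p5", 4_000, 0.0, 1),
            sg.PlasmidSpec("p6", 5_500, 0.0, 1),
            sg.PlasmidSpec("p7", 4_500, 0.45, 1),
        ],
    )
    cfg = PipelineConfig(seed=seed, genome=genome, contig_mean_length=8_000)
    return cfg


def _derive_seed(seed: int, stage: str, index: int = 0) -> int:
    digest = hashlib.sha256(f"{seed}:{stage}:{index}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def plan_to_eventspec(plan: StrainPlan, reference: sg.ReferenceGenome,
                      seed: int) -> sg.EventSpec:
    snps = (sg.plan_catalog_snps(reference, _derive_seed(seed, "snps"))
            if plan.catalog_snps else [])
    losses = [sg.PlasmidLossSpec(pid, "complete") for pid in plan.complete_losses]
    losses += [sg.PlasmidLossSpec(pid, "partial", plr=plr)
               for pid, plr in sorted(plan.partial_losses.items())]
    acqs = [sg.AcquisitionSpec()] if plan.acquisition else []
    return sg.EventSpec(plan.strain_id, snps, losses, acqs)


@dataclass
class StrainResult:
    strain_id: str
    truth: sg.TruthRecord
    snps: list[va.SnpRecord]
    plasmids: list[rd.PlasmidLossReport]
    ani: float | None


@dataclass
class RunResult:
    reference: sg.ReferenceGenome
    strains: list[StrainResult]
    accessory: list[pg.AccessoryFragment]
    acquisitions: list[rd.HgtCandidate]
    screen: scr.ScreenResult
    outdir: Path


def run_all(config: PipelineConfig, outdir, compute_strain_ani: bool = False
            ) -> RunResult:
    """Execute the whole pipeline into ``outdir``; see module docstring."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir / "run.log")
    th = config.thresholds
    log.info("thresholds %s", json.dumps(dataclasses.asdict(th)))
    config.to_yaml(outdir / "effective_config.yaml")

    t0 = time.time()
    log.info("stage=simulate building reference (seed=%d)", config.seed)
    reference = sg.build_reference(config.genome, seed=config.seed)
    reference.save(outdir / "reference")
    repeat_mask = va.build_repeat_mask(
        reference, th.repeat_min_identity, th.repeat_min_length)
    mapper = ReadMapper(reference.sequences())

    strains: list[StrainResult] = []
    contigs_by_strain: dict[str, list[tuple[str, str]]] = {}
    donor_db: dict[str, str] = {}
    for i, plan in enumerate(config.cohort):
        sdir = outdir / "strains" / plan.strain_id
        sdir.mkdir(parents=True, exist_ok=True)
        spec = plan_to_eventspec(plan, reference, config.seed)
        strain = sg.plant_events(reference, spec,
                                 seed=_derive_seed(config.seed, "plant", i))
        strain.truth.to_json(sdir / "truth.json")
        write_fasta(sdir / "genome.fasta", sorted(strain.replicons.items()))

        forced: dict[str, list[int]] = {}
        for acq in strain.truth.acquisitions:
            forced.setdefault(acq.insert_replicon, []).extend(
                [acq.insert_pos, acq.insert_pos + acq.length])
            donor_db[f"donor_23S_{plan.strain_id}"] = acq.donor_gene
        contigs = sg.shear_contigs(
            strain.replicons, mean_length=config.contig_mean_length,
            seed=_derive_seed(config.seed, "shear", i), forced_breakpoints=forced)
        named = [(f"{plan.strain_id}_{c.name}", c.sequence) for c in contigs]
        contigs_by_strain[plan.strain_id] = named
        write_fasta(sdir / "contigs.fasta", named)

        rp = dataclasses.replace(config.read_params,
                                 seed=_derive_seed(config.seed, "reads", i))
        pairs = sg.simulate_reads(strain.replicons, rp)
        log.info("stage=map strain=%s pairs=%d", plan.strain_id, len(pairs))
        tracks = mapper.map_reads(pairs)

        log.info("stage=snps strain=%s", plan.strain_id)
        candidates = va.call_raw_snps(named, reference.sequences(),
                                      min_identity=th.core_min_identity,
                                      max_evalue=th.core_max_evalue)
        snps = va.filter_snps(candidates, tracks, repeat_mask, reference,
                              th.snp_min_quality, th.snp_min_depth)
        reports = rd.plasmid_report(plan.strain_id, tracks, reference,
                                    th.min_zero_run)
        rd.write_plasmid_report(reports, sdir / "plasmid_report.tsv")
        va.write_catalog(snps, sdir / "snps.tsv")
        ani = None
        if compute_strain_ani:
            res = compute_ani(strain.replicons, reference.sequences(),
                              species_cutoff=th.ani_species_cutoff)
            ani = res.ani
        strains.append(StrainResult(plan.strain_id, strain.truth, snps,
                                    reports, ani))

    log.info("stage=pangenome strains=%d", len(strains))
    core = pg.delineate_core(contigs_by_strain, reference,
                             th.core_min_identity, th.core_max_evalue)
    accessory = pg.build_accessory(core.strain_specific, th.dedup_min_identity,
                                   th.dedup_length_fraction)
    accessory = pg.assign_source(accessory, reference, th.dedup_min_identity,
                                 th.dedup_length_fraction)
    pg.write_core_bed(core.core_intervals, outdir / "core_intervals.bed")
    pg.write_accessory(accessory, [s.strain_id for s in strains],
                       outdir / "accessory.fasta", outdir / "accessory_matrix.tsv")

    log.info("stage=hgt novel-candidates")
    acquisitions = rd.detect_acquisitions(accessory, reference,
                                          donor_db or None)

    log.info("stage=screening packaged manifest")
    screen = scr.screen_descendants(scr.load_manifest(), th.ani_species_cutoff)
    scr.write_screen_report(screen, outdir / "screening.tsv",
                            outdir / "screening.log")

    carriers = {s for c in acquisitions for s in c.carrier_strains}
    render_variation_matrix(strains, reference, outdir / "variation_matrix.tsv",
                            hgt_carriers=carriers)
    summary = {
        "n_strains": len(strains),
        "snp_counts": {s.strain_id: len(s.snps) for s in strains},
        "plasmid_loss": {
            s.strain_id: {r.plasmid_id: r.loss_class for r in s.plasmids
                          if r.loss_class != rd.LOSS_NONE}
            for s in strains},
        "accessory_fragments": len(accessory),
        "hgt_candidates": len(acquisitions),
        "screen_retained": screen.n_retained,
        "elapsed_s": round(time.time() - t0, 1),
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    log.info("stage=report done in %.1fs", summary["elapsed_s"])
    return RunResult(reference, strains, accessory, acquisitions, screen, outdir)


def render_variation_matrix(strains: list[StrainResult],
                            reference: sg.ReferenceGenome, path,
                            hgt_carriers: set[str] | None = None) -> None:
    """Per-strain variation matrix: SNP presence, per-plasmid loss class, and
    acquisition flags (rows follow cohort/sampling order)."""
    snp_ids: list[str] = []
    for s in strains:
        for rec in s.snps:
            key = f"{rec.replicon}:{rec.genome_pos}:{rec.alt_base}"
            if key not in snp_ids:
                snp_ids.append(key)
    plasmid_ids = [p.id for p in reference.plasmids]
    with open(path, "w") as fh:
        cols = (["strain"] + snp_ids + [f"loss_{p}" for p in plasmid_ids]
                + ["acquisition"])
        fh.write("\t".join(cols) + "\n")
        for s in strains:
            have = {f"{r.replicon}:{r.genome_pos}:{r.alt_base}" for r in s.snps}
            row = [s.strain_id]
            row += ["1" if k in have else "" for k in snp_ids]
            loss = {r.plasmid_id: r.loss_class for r in s.plasmids}
            row += [loss.get(p, "") if loss.get(p) != rd.LOSS_NONE else ""
                    for p in plasmid_ids]
            row.append("1" if s.strain_id in (hgt_carriers or set()) else "")
            fh.write("\t".join(row) + "\n")


def _setup_logging(logfile) -> None:
    if not log.handlers:
        log.setLevel(logging.INFO)
        fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
        sh = logging.StreamHandler()
        sh.setFormatter(fmt)
        log.addHandler(sh)
    fh = logging.FileHandler(logfile, mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
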