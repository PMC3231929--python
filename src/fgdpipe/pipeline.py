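"""Stage orchestration: run the comparative-genomics pipeline from a config.

Each stage writes deterministic artifact files into the output
directory and records them (with SHA-256 checksums and timings) in
``manifest.json``.  The all-vs-all hit table is cached on disk so the
FGD, gene-set and region stages can rerun without repeating the search.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import fgd, genesets, regions as regmod
from .genome_io import GenomeRecord, extract_orfeome, genome_stats, read_genome, write_tsv
from .pairwise import HitTable, ScoringScheme, all_vs_all
from .simulate import SimConfig, simulate_pangenome, truth_report, write_pangenome

log = logging.getLogger("fgdpipe")


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    outdir: str
    #: inline simulation config; mutually exclusive with ``genomes``
    simulate: dict | None = None
    #: list of {id, path, format, gff3} entries for on-disk genomes
    genomes: list[dict] | None = None
    include_pseudo_in_orfeome: bool = True
    word_len: int = 4
    band: int = 40
    table_ceiling: float = 10.0
    fgd_ceiling: float = 1e-5
    core_cutoff: float = 1e-60
    shared_cutoff: float = 1e-10
    specific_cutoff: float = 1e-10
    min_region_len: int = 50
    nt_word_len: int = 16
    xdrop: int = 100
    min_overlap_frac: float = 0.5
    locus_gap_bp: int = 5000
    window_bp: int = 1000
    reference_genome: str | None = None
    rrna_gap_bp: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("table_ceiling", "fgd_ceiling", "core_cutoff",
                     "shared_cutoff", "specific_cutoff"):
            if not getattr(self, name) > 0:
                raise ConfigError(f"{name} must be > 0")
        if self.min_region_len <= 0 or self.locus_gap_bp <= 0:
            raise ConfigError("region parameters must be positive")
        if self.simulate is None and not self.genomes:
            raise ConfigError("config needs either 'simulate' or 'genomes'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        try:
            return cls(**data)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class Manifest:
    path: Path
    stages: dict = field(default_factory=dict)

    def record(self, stage: str, files: list[Path], seconds: float) -> None:
        self.stages[stage] = {
            "seconds": round(seconds, 3),
            "files": {str(f): _sha256(f) for f in sorted(files)},
        }
        self.path.write_text(json.dumps(self.stages, indent=2, sort_keys=True))


class Pipeline:
    def __init__(self, cfg: RunConfig) -> None:
        self.cfg = cfg
        self.outdir = Path(cfg.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest = Manifest(self.outdir / "manifest.json")
        self._genomes: list[GenomeRecord] | None = None
        self._table: HitTable | None = None

    # -- inputs -----------------------------------------------------------

    def load_genomes(self) -> list[GenomeRecord]:
        if self._genomes is not None:
            return self._genomes
        cfg = self.cfg
        if cfg.simulate is not None:
            sim = dict(cfg.simulate)
            sim.setdefault("seed", cfg.seed)
            genomes, proteomes, truth = simulate_pangenome(SimConfig(**sim))
            gdir = self.outdir / "genomes"
            t0 = time.time()
            write_pangenome(genomes, proteomes, gdir)
            truth_report(truth, self.outdir / "truth")
            self.manifest.record(
                "simulate",
                list(gdir.iterdir()) + list((self.outdir / "truth").iterdir()),
                time.time() - t0,
            )
            self._genomes = genomes
        else:
            recs = []
            for entry in self.cfg.genomes or []:
                recs.append(
                    read_genome(
                        entry["path"],
                        format=entry.get("format", "genbank"),
                        gff3=entry.get("gff3"),
                        genome_id=entry.get("id"),
                    )
                )
            self._genomes = recs
        return self._genomes

    def orfeomes(self) -> dict[str, list[tuple[str, str]]]:
        return {
            g.genome_id: extract_orfeome(g, self.cfg.include_pseudo_in_orfeome)
            for g in self.load_genomes()
        }

    # -- stages -----------------------------------------------------------

    def run_stats(self) -> Path:
        t0 = time.time()
        rows = []
        for g in self.load_genomes():
            s = genome_stats(g, rrna_gap_bp=self.cfg.rrna_gap_bp)
            rows.append({"genome": g.genome_id, "replicon": g.replicon_id,
                         **{k: (round(v, 2) if isinstance(v, float) else v)
                            for k, v in asdict(s).items()}})
        out = self.outdir / "genome_stats.tsv"
        write_tsv(rows, out)
        self.manifest.record("stats", [out], time.time() - t0)
        return out

    def run_search(self) -> HitTable:
        if self._table is not None:
            return self._table
        cache = self.outdir / "search"
        if (cache / "table.json").exists():
            log.info("reusing cached hit table at %s", cache)
            self._table = HitTable.load(cache)
            return self._table
        t0 = time.time()
        table = all_vs_all(
            self.orfeomes(),
            ScoringScheme.protein_default(),
            word_len=self.cfg.word_len,
            band=self.cfg.band,
            e_ceiling=self.cfg.table_ceiling,
        )
        table.save(cache)
        self.manifest.record(
            "search", [cache / "hits.tsv", cache / "table.json"], time.time() - t0
        )
        self._table = table
        return table

    def run_fgd(self) -> tuple[Path, Path]:
        t0 = time.time()
        table = self.run_search()
        matrix = fgd.build_matrix(table, e_ceiling=self.cfg.fgd_ceiling)
        tree = fgd.upgma(matrix)
        phylip = self.outdir / "fgd_matrix.phylip"
        tsv = self.outdir / "fgd_distances.tsv"
        nwk = self.outdir / "fgd_upgma.nwk"
        matrix.to_phylip(phylip)
        matrix.to_tsv(tsv)
        nwk.write_text(tree.newick() + "\n")
        self.manifest.record("fgd", [phylip, tsv, nwk], time.time() - t0)
        return phylip, nwk

    def run_genesets(self) -> list[Path]:
        t0 = time.time()
        table = self.run_search()
        ids = table.genome_ids
        files: list[Path] = []
        core = genesets.core_genes(table, ids, e_present=self.cfg.core_cutoff)
        p = self.outdir / "core_genes.tsv"
        core.to_tsv(p, ids)
        files.append(p)
        for g in ids:
            res = genesets.strain_specific(
                table, g, [x for x in ids if x != g], e_absent=self.cfg.specific_cutoff
            )
            p = self.outdir / f"specific_{g}.tsv"
            res.to_tsv(p, ids)
            files.append(p)
        rows = []
        for a in ids:
            for b in ids:
                if a != b:
                    rows.append({
                        "genome_a": a, "genome_b": b,
                        "shared_pct": round(genesets.shared_fraction(
                            table, [a], [b], self.cfg.shared_cutoff), 2),
                    })
        p = self.outdir / "shared_fractions.tsv"
        write_tsv(rows, p)
        files.append(p)
        self.manifest.record("genesets", files, time.time() - t0)
        return files

    def run_regions(self) -> list[Path]:
        t0 = time.time()
        cfg = self.cfg
        genomes = self.load_genomes()
        by_id = {g.genome_id: g for g in genomes}
        ref_id = cfg.reference_genome or sorted(by_id)[0]
        if ref_id not in by_id:
            raise ConfigError(f"reference genome {ref_id} not among inputs")
        ref = by_id[ref_id]
        files: list[Path] = []
        per_query: list[list[regmod.SpecificRegion]] = []
        acc_rows = []
        for qid in sorted(by_id):
            if qid == ref_id:
                continue
            blocks = regmod.nucleotide_align(
                ref, by_id[qid], word_len=cfg.nt_word_len, xdrop=cfg.xdrop
            )
            p = self.outdir / f"blocks_{ref_id}_vs_{qid}.tsv"
            regmod.blocks_to_tsv(blocks, p)
            files.append(p)
            regs = regmod.specific_regions(
                ref, blocks, cfg.min_region_len, query_id=qid
            )
            per_query.append(regs)
            p = self.outdir / f"specific_regions_{ref_id}_vs_{qid}.bed"
            regmod.regions_to_bed(regs, p)
            files.append(p)
            acc_rows.append({"query": qid, **regmod.coverage_accounting(
                ref, blocks, cfg.min_region_len)})
        inter = regmod.multi_query_specific(ref, per_query, cfg.min_region_len)
        inter = regmod.map_orfs_and_loci(
            inter, ref, cfg.min_overlap_frac, cfg.locus_gap_bp
        )
        inter = regmod.flag_transposase_flanks(inter, ref, cfg.window_bp)
        p = self.outdir / f"specific_regions_{ref_id}_all_queries.tsv"
        regmod.regions_to_tsv(inter, p)
        files.append(p)
        p = self.outdir / "coverage_accounting.tsv"
        write_tsv(acc_rows, p)
        files.append(p)
        self.manifest.record("regions", files, time.time() - t0)
        return files

    def run_all(self) -> None:
        self.run_stats()
        self.run_search()
        self.run_fgd()
        self.run_genesets()
        self.run_regions()
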