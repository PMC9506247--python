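"""End-to-end orchestration: annotated genomes in, all tables and reports out.

Stages are independent where the science allows: a failure in one stage is
recorded and the remaining stages still run; the bundle is deterministic
for a given config and seed (timestamps are confined to the log file).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .architecture import (compare_orders, find_tandem_repeats, gene_order,
                           longest_polyT, reference_order, spacers_overlaps)
from .codon_usage import (GeneticCode, count_codons, fold_class_profile,
                          pooled_counts, rscu)
from .composition import compose_by_class, composition_table, skew_scatter_table
from .divergence import gene_rates, sliding_pi
from .mito_io import Mitogenome, extract_gene, read_alignment, read_mitogenome
from .phylo_prep import (concatenate, jc_distance_matrix, nj_tree,
                         write_newick, write_partitions, write_supermatrix)

log = logging.getLogger("mitocomp")


@dataclass
class RunConfig:
    """Validated configuration of a full analysis run."""

    genomes: list[str] = field(default_factory=list)
    genome_format: str = "genbank"
    alignments: list[str] = field(default_factory=list)  # per-gene codon FASTAs
    genetic_code: int = 5
    window: int = 200
    step: int = 20
    repeat_unit_min: int = 5
    repeat_unit_max: int = 50
    repeat_min_copies: int = 3
    reference_order: str = "ancestral"
    outdir: str = "mitocomp_out"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.window <= 0 or self.step <= 0:
            raise ValueError("window and step must be positive")
        if self.repeat_unit_min < 1 or self.repeat_unit_max < self.repeat_unit_min:
            raise ValueError("bad repeat unit length range")
        if self.genetic_code not in (2, 4, 5, 9, 13, 14):
            raise ValueError(f"unsupported mitochondrial code table {self.genetic_code}")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


@dataclass
class RunResult:
    outdir: Path
    stages: dict[str, str]  # stage -> 'ok' | 'skipped: reason' | 'error: msg'

    @property
    def failed(self) -> bool:
        return any(s.startswith("error") for s in self.stages.values())


def _fmt(df: pd.DataFrame, ndp: dict[str, int]) -> pd.DataFrame:
    out = df.copy()
    for col, n in ndp.items():
        if col in out:
            out[col] = out[col].map(
                lambda x: "" if isinstance(x, float) and math.isnan(x)
                else f"{x:.{n}f}" if isinstance(x, float) else x)
    return out


def run_all(config: RunConfig,
            genomes: list[Mitogenome] | None = None) -> RunResult:
    """Run every applicable analysis stage and write the report bundle.

    ``genomes`` may be passed directly (e.g. synthetic ones); otherwise they
    are read from the configured paths.  Divergence and phylogeny stages
    need per-gene codon alignments with >= 2 taxa and are skipped, with a
    logged reason, when those are absent.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    log_handler = logging.FileHandler(outdir / "run.log")
    log_handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(log_handler)
    config.to_yaml(outdir / "config.yaml")
    code = GeneticCode(config.genetic_code)
    stages: dict[str, str] = {}

    if genomes is None:
        genomes = [read_mitogenome(p, config.genome_format) for p in config.genomes]
    genomes = sorted(genomes, key=lambda g: g.id)
    if not genomes:
        raise ValueError("no input genomes")

    def stage(name):
        def deco(fn):
            try:
                fn()
                stages[name] = "ok"
                log.info("stage %s: ok", name)
            except Exception as exc:  # record and continue with later stages
                stages[name] = f"error: {exc}"
                log.error("stage %s failed: %s", name, exc)
        return deco

    @stage("composition")
    def _composition():
        frames = []
        for g in genomes:
            t = composition_table(compose_by_class(g))
            t.insert(0, "taxon", g.id)
            frames.append(t)
        table = pd.concat(frames, ignore_index=True)
        _fmt(table, {"pctA": 1, "pctT": 1, "pctG": 1, "pctC": 1, "pctAT": 1,
                     "at_skew": 4, "gc_skew": 4}).to_csv(
            outdir / "composition.tsv", sep="\t", index=False)
        _fmt(skew_scatter_table(genomes),
             {"pctAT": 1, "pctGC": 1, "at_skew": 4, "gc_skew": 4}).to_csv(
            outdir / "skew_scatter.tsv", sep="\t", index=False)

    @stage("codon_usage")
    def _codon_usage():
        frames, ss_rows = [], []
        fold_sets: dict[str, dict[str, str]] = {}
        for g in genomes:
            results = []
            for f in g.features:
                if f.ftype != "PCG":
                    continue
                cds = extract_gene(g, f)
                r = count_codons(cds, code, f.name)
                results.append(r)
                ss = r.start_stop
                ss_rows.append({"taxon": g.id, "gene": f.name,
                                "start": ss.start_codon, "stop": ss.stop_codon,
                                "complete": ss.complete})
                fold_sets.setdefault(f.name, {})[g.id] = cds
            if not results:
                continue
            table = rscu(pooled_counts(results), code).to_frame()
            table.insert(0, "taxon", g.id)
            frames.append(table)
        if not frames:
            raise ValueError("no protein-coding genes annotated")
        _fmt(pd.concat(frames, ignore_index=True), {"count": 1, "rscu": 2}).to_csv(
            outdir / "codon_usage.tsv", sep="\t", index=False)
        pd.DataFrame(ss_rows).to_csv(outdir / "start_stop.tsv", sep="\t", index=False)
        prof = fold_class_profile(fold_sets, code)
        _fmt(prof.summary, {"mean_at_pct": 1, "sd_at_pct": 2}).to_csv(
            outdir / "fold_class_at.tsv", sep="\t", index=False)

    @stage("architecture")
    def _architecture():
        ref = reference_order(config.reference_order)
        report = {}
        boundary_frames = []
        for g in genomes:
            order = gene_order(g)
            rearr = compare_orders(order, ref)
            so = spacers_overlaps(g)
            entry = {
                "order": [f"{'-' if s == '-' else ''}{n}" + (f".{c}" if c > 1 else "")
                          for n, s, c in order.order],
                "breakpoints": rearr.breakpoints,
                "moved_genes": sorted(rearr.moved_genes),
                "duplicated": rearr.duplicated,
                "missing_genes": sorted(rearr.missing_genes),
                "extra_genes": sorted(rearr.extra_genes),
                "spacers": {"count": so.spacer_count, "bp": so.spacer_bp,
                            "longest": so.longest_spacer},
                "overlaps": {"count": so.overlap_count, "bp": so.overlap_bp},
                "cr_length": so.cr_length,
            }
            boundary_frames.append(pd.DataFrame(
                [{"taxon": g.id, "left": b.left, "right": b.right, "gap": b.gap}
                 for b in so.boundaries]))
            crs = [f for f in g.features if f.ftype == "control_region"]
            if crs:
                region = extract_gene(g, crs[0])
                reps = find_tandem_repeats(
                    region, (config.repeat_unit_min, config.repeat_unit_max),
                    config.repeat_min_copies)
                pt_len, pt_start = longest_polyT(region)
                entry["cr_repeats"] = [
                    {"unit": r.unit, "copies": r.copies, "span": list(r.span)}
                    for r in reps]
                entry["polyT"] = {"length": pt_len, "start": pt_start}
            report[g.id] = entry
        with open(outdir / "architecture.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        pd.concat(boundary_frames, ignore_index=True).to_csv(
            outdir / "boundaries.tsv", sep="\t", index=False)

    alns = []
    if config.alignments:
        alns = [read_alignment(p, codon_aligned=True)
                for p in sorted(config.alignments)]
    usable = [a for a in alns if len(a.taxa) >= 2]

    if not usable:
        reason = "skipped: no codon alignments with >= 2 taxa"
        stages["divergence"] = stages["phylogeny"] = reason
        log.info("divergence/phylogeny %s", reason)
    else:
        @stage("divergence")
        def _divergence():
            pi_frames = []
            for a in usable:
                win = min(config.window, a.length)
                prof = sliding_pi(a, win, config.step)
                t = prof.windows.copy()
                t.insert(0, "gene", a.gene)
                pi_frames.append(t)
            _fmt(pd.concat(pi_frames, ignore_index=True), {"pi": 5}).to_csv(
                outdir / "sliding_pi.tsv", sep="\t", index=False)
            rates = gene_rates({a.gene: a for a in usable}, code)
            _fmt(rates, {c: 5 for c in ("Ka", "Ks", "ka_ks", "JKa", "JKs", "jka_jks")}
                 ).to_csv(outdir / "gene_rates.tsv", sep="\t", index=False)

        @stage("phylogeny")
        def _phylogeny():
            sm = concatenate(usable, gap_fill=True)
            write_supermatrix(sm, outdir / "supermatrix.fasta")
            write_partitions(sm, outdir / "partitions.txt")
            if len(sm.taxa) >= 3:
                dm = jc_distance_matrix(sm.taxa, sm.rows)
                if dm.isna().any().any():
                    raise ValueError("JC-saturated pairs; cannot build NJ tree")
                write_newick(nj_tree(dm), outdir / "nj_tree.nwk")
            else:
                log.info("fewer than 3 taxa; NJ tree not built")

    summary = {"version": __version__,
               "config": dataclasses.asdict(config),
               "n_genomes": len(genomes),
               "genome_ids": [g.id for g in genomes],
               "stages": stages}
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    log.removeHandler(log_handler)
    log_handler.close()
    return RunResult(outdir, stages)
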