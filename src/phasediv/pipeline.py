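"""End-to-end orchestration: simulate -> compare -> hemizygosity ->
homologs -> de -> promoters -> qc, with a content-hash manifest.

Each stage records the hashes of the files it read and wrote; re-running
with an unchanged configuration skips stages whose inputs and outputs all
match the previous manifest, and re-runs anything downstream of a change.
A SyRI-style region TSV can be supplied to replace the internal comparison
stage, in which case downstream stages consume the ingested calls.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import pandas as pd

from . import formats
from .expression import (
    compare_hemi_vs_homo,
    compute_tpm,
    de_between_haplotypes,
    de_results_frame,
)
from .hemizygosity import call_hemizygous, categorize_hemizygous, summarize_categories
from .homologs import filter_identical, pair_homologs

from .qc import assembly_stats, map_concordance, telomere_scan
from .regulatory import compare_de_burden, count_promoter_variants, extract_promoters
from .simulate import SimulationConfig, simulate_diploid
from .synteny import chain_anchors, classify_regions, find_anchors, region_partition_check

log = logging.getLogger("phasediv")

STAGES = ("simulate", "compare", "hemizygosity", "homologs", "de", "promoters", "qc")


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class StageRecord:
    status: str = "pending"  # run | skipped | failed
    inputs: dict[str, str] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)


@dataclass
class RunManifest:
    config: dict
    seed: int
    stages: dict[str, StageRecord] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "seed": self.seed,
            "stages": {k: dataclasses.asdict(v) for k, v in self.stages.items()},
        }

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)


def _load_previous(path: str) -> dict | None:
    if not os.path.exists(path):
        return None
    try:
        with open(path) as fh:
            return json.load(fh)
    except (OSError, json.JSONDecodeError):
        return None


def _outputs_intact(prev_stage: dict | None, outdir: str) -> bool:
    if not prev_stage or prev_stage.get("status") not in ("run", "skipped"):
        return False
    for rel, digest in prev_stage.get("outputs", {}).items():
        p = os.path.join(outdir, rel)
        if not os.path.exists(p) or _sha256(p) != digest:
            return False
    return True


def _inputs_match(prev_stage: dict | None, inputs: dict[str, str]) -> bool:
    return bool(prev_stage) and prev_stage.get("inputs", {}) == inputs


class Pipeline:
    """Stateful runner holding in-memory products between stages."""

    def __init__(
        self,
        config: SimulationConfig,
        outdir: str,
        region_tsv: str | None = None,
        alpha: float = 0.05,
        force: bool = False,
    ):
        self.config = config
        self.outdir = outdir
        self.region_tsv = region_tsv
        self.alpha = alpha
        self.force = force
        os.makedirs(outdir, exist_ok=True)
        os.makedirs(os.path.join(outdir, "truth"), exist_ok=True)
        # JSON-normalized so tuple fields compare equal after a round trip
        self._config_dict = json.loads(json.dumps(dataclasses.asdict(config)))
        self.manifest = RunManifest(config=self._config_dict, seed=config.seed)
        self._prev = None if force else _load_previous(self._manifest_path)
        self._dirty = force  # once a stage runs, everything downstream runs
        # in-memory state
        self.hap1 = self.hap2 = None
        self.genes_h1 = self.genes_h2 = None
        self.expr_h1 = self.expr_h2 = None
        self.markers = None
        self.calls = None
        self.records_h1 = self.records_h2 = None
        self.pairs = None
        self.identical = None
        self.de = None

    @property
    def _manifest_path(self) -> str:
        return os.path.join(self.outdir, "manifest.json")

    def _path(self, rel: str) -> str:
        return os.path.join(self.outdir, rel)

    def _finish(self, name: str, rec: StageRecord, outputs: list[str]) -> None:
        for rel in outputs:
            rec.outputs[rel] = _sha256(self._path(rel))
        self.manifest.stages[name] = rec
        log.info("stage %s: %s (%s)", name, rec.status,
                 ", ".join(f"{k}={v}" for k, v in rec.counts.items()))

    def _should_skip(self, name: str, inputs: dict[str, str]) -> bool:
        if self._dirty or self.force:
            return False
        prev = (self._prev or {}).get("stages", {}).get(name)
        prev_cfg = (self._prev or {}).get("config")
        if prev_cfg != self._config_dict:
            return False
        return _inputs_match(prev, inputs) and _outputs_intact(prev, self.outdir)

    # ----- stages ---------------------------------------------------------

    def run_simulate(self) -> None:
        name = "simulate"
        outputs = [
            "hap1.fa", "hap2.fa", "hap1.gff3", "hap2.gff3",
            "counts_hap1.tsv", "counts_hap2.tsv", "genetic_map.tsv",
            "truth/regions.tsv", "truth/hemizygosity.tsv",
            "truth/identical_pairs.tsv", "truth/de_truth.tsv",
            "truth/promoter_variants.tsv",
        ]
        rec = StageRecord(inputs={"seed": str(self.config.seed)})
        skip = self._should_skip(name, rec.inputs)
        ds = simulate_diploid(self.config)
        self.hap1, self.hap2 = ds.hap1, ds.hap2
        self.genes_h1, self.genes_h2 = ds.genes_hap1, ds.genes_hap2
        self.expr_h1, self.expr_h2 = ds.expression_hap1, ds.expression_hap2
        self.markers = ds.markers
        self.truth = ds.truth
        if skip:
            rec.status = "skipped"
        else:
            self._dirty = True
            formats.write_genome(ds.hap1, self._path("hap1.fa"))
            formats.write_genome(ds.hap2, self._path("hap2.fa"))
            formats.write_annotation(ds.genes_hap1, self._path("hap1.gff3"))
            formats.write_annotation(ds.genes_hap2, self._path("hap2.gff3"))
            formats.write_counts(ds.expression_hap1, self._path("counts_hap1.tsv"))
            formats.write_counts(ds.expression_hap2, self._path("counts_hap2.tsv"))
            formats.write_genetic_map(ds.markers, self._path("genetic_map.tsv"))
            formats.write_region_calls(ds.truth.regions, self._path("truth/regions.tsv"))
            pd.DataFrame(
                [
                    {"haplotype": h, "gene_id": g, "category": v}
                    for (h, g), v in sorted(ds.truth.hemizygosity.items())
                ]
            ).to_csv(self._path("truth/hemizygosity.tsv"), sep="\t", index=False)
            pd.DataFrame(ds.truth.identical_pairs, columns=["gene_id_h1", "gene_id_h2"]).to_csv(
                self._path("truth/identical_pairs.tsv"), sep="\t", index=False
            )
            pd.DataFrame(
                [
                    {"gene_id_h1": a, "gene_id_h2": b, "tissue": t, "fold_h1_over_h2": f}
                    for (a, b), tf in sorted(ds.truth.de_truth.items())
                    for t, f in tf.items()
                ],
                columns=["gene_id_h1", "gene_id_h2", "tissue", "fold_h1_over_h2"],
            ).to_csv(self._path("truth/de_truth.tsv"), sep="\t", index=False)
            pd.DataFrame(
                sorted(ds.truth.promoter_variants.items()),
                columns=["gene_id", "planted_variants"],
            ).to_csv(self._path("truth/promoter_variants.tsv"), sep="\t", index=False)
            rec.status = "run"
        rec.counts = {
            "genes_hap1": len(ds.genes_hap1), "genes_hap2": len(ds.genes_hap2),
            "truth_regions": len(ds.truth.regions),
        }
        self._finish(name, rec, outputs)

    def run_compare(self) -> None:
        name = "compare"
        rec = StageRecord()
        if self.region_tsv is not None:
            # externally supplied SyRI-style calls: ingest and skip comparison
            rec.inputs["region_tsv"] = _sha256(self.region_tsv)
            self.calls = formats.read_region_calls(self.region_tsv)
            formats.write_region_calls(self.calls, self._path("regions.tsv"))
            rec.status = "ingested"
            self._dirty = True
            rec.counts = {"region_calls": len(self.calls)}
            self._finish(name, rec, ["regions.tsv"])
            return
        rec.inputs = {
            "hap1.fa": _sha256(self._path("hap1.fa")),
            "hap2.fa": _sha256(self._path("hap2.fa")),
        }
        outputs = ["regions.tsv", "variants.vcf"] + [
            f"regions_{t.lower()}.bed"
            for t in ("SYN", "INV", "TRANS", "INS", "DEL", "HDR", "NOTAL")
        ]
        if self._should_skip(name, rec.inputs):
            self.calls = formats.read_region_calls(self._path("regions.tsv"))
            rec.status = "skipped"
        else:
            self._dirty = True
            anchors = find_anchors(self.hap1, self.hap2)
            chains = chain_anchors(anchors)
            self.calls = classify_regions(chains, self.hap1, self.hap2)
            report = region_partition_check(self.calls, self.hap1, self.hap2)
            if not report.ok:
                log.warning("partition defects: %d uncovered / %d overlapped bases",
                            report.total_uncovered("hap1") + report.total_uncovered("hap2"),
                            report.total_overlapped("hap1") + report.total_overlapped("hap2"))
            formats.write_region_calls(self.calls, self._path("regions.tsv"))
            formats.write_vcf(self.calls, self.hap1, self.hap2, self._path("variants.vcf"))
            for rtype in ("SYN", "INV", "TRANS", "INS", "DEL", "HDR", "NOTAL"):
                rows = []
                for i, c in enumerate(self.calls):
                    if c.rtype != rtype:
                        continue
                    iv = c.interval("hap1") or c.interval("hap2")
                    if iv and iv[2] > iv[1]:
                        rows.append((iv[0], iv[1], iv[2], f"{rtype.lower()}{i}"))
                formats.write_bed(rows, self._path(f"regions_{rtype.lower()}.bed"))
            rec.status = "run"
        rec.counts = {"region_calls": len(self.calls)}
        self._finish(name, rec, outputs)

    def run_hemizygosity(self) -> None:
        name = "hemizygosity"
        rec = StageRecord(inputs={
            "regions.tsv": _sha256(self._path("regions.tsv")),
            "hap1.gff3": _sha256(self._path("hap1.gff3")),
            "hap2.gff3": _sha256(self._path("hap2.gff3")),
        })
        r1, r2 = call_hemizygous(self.genes_h1, self.genes_h2, self.calls)
        self.records_h1 = categorize_hemizygous(r1, self.genes_h1, self.calls)
        self.records_h2 = categorize_hemizygous(r2, self.genes_h2, self.calls)
        if self._should_skip(name, rec.inputs):
            rec.status = "skipped"
        else:
            self._dirty = True
            rows = [
                {
                    "gene_id": r.gene_id, "haplotype": r.haplotype, "status": r.status,
                    "category": r.category or "", "overlap_fraction": r.overlap_fraction,
                    "partner_id": r.partner_id or "",
                    "partner_identity": r.partner_identity
                    if r.partner_identity is not None else "",
                }
                for r in self.records_h1 + self.records_h2
            ]
            pd.DataFrame(rows).to_csv(self._path("hemizygosity.tsv"), sep="\t", index=False)
            summary = summarize_categories(self.records_h1 + self.records_h2)
            pd.DataFrame(summary).T.to_csv(self._path("hemizygosity_summary.tsv"), sep="\t")
            genes = {g.gene_id: g for g in self.genes_h1 + self.genes_h2}
            bed = [
                (genes[r.gene_id].chrom, genes[r.gene_id].start, genes[r.gene_id].end,
                 f"{r.gene_id}|{r.category}")
                for r in self.records_h1 + self.records_h2
                if r.status == "hemizygous"
            ]
            formats.write_bed(bed, self._path("hemizygous_genes.bed"))
            rec.status = "run"
        hemi1 = sum(r.status == "hemizygous" for r in self.records_h1)
        hemi2 = sum(r.status == "hemizygous" for r in self.records_h2)
        rec.counts = {"hemizygous_hap1": hemi1, "hemizygous_hap2": hemi2}
        self._finish(name, rec,
                     ["hemizygosity.tsv", "hemizygosity_summary.tsv", "hemizygous_genes.bed"])

    def run_homologs(self) -> None:
        name = "homologs"
        rec = StageRecord(inputs={
            "regions.tsv": _sha256(self._path("regions.tsv")),
            "hap1.gff3": _sha256(self._path("hap1.gff3")),
            "hap2.gff3": _sha256(self._path("hap2.gff3")),
        })
        self.pairs = pair_homologs(self.genes_h1, self.genes_h2, self.calls)
        self.identical = filter_identical(self.pairs)
        if self._should_skip(name, rec.inputs):
            rec.status = "skipped"
        else:
            self._dirty = True
            pd.DataFrame(
                [
                    {
                        "gene_id_h1": p.gene_id_h1, "gene_id_h2": p.gene_id_h2,
                        "cds_identity": p.cds_identity,
                        "identical": p.identical, "syntenic": p.syntenic,
                    }
                    for p in self.pairs
                ]
            ).to_csv(self._path("homolog_pairs.tsv"), sep="\t", index=False)
            rec.status = "run"
        rec.counts = {"pairs": len(self.pairs), "identical": len(self.identical)}
        self._finish(name, rec, ["homolog_pairs.tsv"])

    def run_de(self) -> None:
        name = "de"
        rec = StageRecord(inputs={
            "counts_hap1.tsv": _sha256(self._path("counts_hap1.tsv")),
            "counts_hap2.tsv": _sha256(self._path("counts_hap2.tsv")),
        })
        tpm1, tpm2 = compute_tpm(self.expr_h1), compute_tpm(self.expr_h2)
        self.tpm_h1, self.tpm_h2 = tpm1, tpm2
        self.de = de_between_haplotypes(tpm1, tpm2, self.identical, alpha=self.alpha)
        if self._should_skip(name, rec.inputs):
            rec.status = "skipped"
        else:
            self._dirty = True
            de_results_frame(self.de).to_csv(self._path("de_results.tsv"), sep="\t", index=False)
            hemi_cmp = compare_hemi_vs_homo(tpm1, self.records_h1)
            hemi_cmp.to_csv(self._path("hemi_vs_homo_hap1.tsv"), sep="\t", index=False)
            compare_hemi_vs_homo(tpm2, self.records_h2).to_csv(
                self._path("hemi_vs_homo_hap2.tsv"), sep="\t", index=False
            )
            rec.status = "run"
        rec.counts = {"tested_pairs": len(self.de.results), "de_pairs": len(self.de.de_pairs)}
        self._finish(name, rec,
                     ["de_results.tsv", "hemi_vs_homo_hap1.tsv", "hemi_vs_homo_hap2.tsv"])

    def run_promoters(self) -> None:
        name = "promoters"
        rec = StageRecord(inputs={
            "regions.tsv": _sha256(self._path("regions.tsv")),
            "de_pairs": ",".join(a for a, _ in self.de.de_pairs),
        })
        window = self.config.promoter_window
        ident_h1 = {p.gene_id_h1 for p in self.identical}
        ident_h2 = {p.gene_id_h2 for p in self.identical}
        prom1 = extract_promoters(
            [g for g in self.genes_h1 if g.gene_id in ident_h1], self.hap1, window
        )
        prom2 = extract_promoters(
            [g for g in self.genes_h2 if g.gene_id in ident_h2], self.hap2, window
        )
        self.burdens_h1 = count_promoter_variants(prom1, self.calls, "hap1")
        self.burdens_h2 = count_promoter_variants(prom2, self.calls, "hap2")
        self.burden_report = compare_de_burden(
            self.burdens_h1, self.burdens_h2, self.de.de_pairs, self.de.non_de_pairs
        )
        if self._should_skip(name, rec.inputs):
            rec.status = "skipped"
        else:
            self._dirty = True
            pd.DataFrame(
                [
                    {
                        "gene_id": b.gene_id, "haplotype": b.haplotype,
                        "chrom": b.chrom, "start": b.start + 1, "end": b.end,
                        "strand": b.strand, "snp_count": b.snp_count,
                        "sv_count": b.sv_count, "total": b.total_variant_count,
                    }
                    for b in self.burdens_h1 + self.burdens_h2
                ]
            ).to_csv(self._path("promoter_burden.tsv"), sep="\t", index=False)
            pd.DataFrame([self.burden_report]).to_csv(
                self._path("burden_comparison.tsv"), sep="\t", index=False
            )
            formats.write_bed(
                [(b.chrom, b.start, b.end, b.gene_id) for b in self.burdens_h1 + self.burdens_h2],
                self._path("promoters.bed"),
            )
            rec.status = "run"
        rec.counts = {"promoters": len(self.burdens_h1) + len(self.burdens_h2)}
        self._finish(name, rec,
                     ["promoter_burden.tsv", "burden_comparison.tsv", "promoters.bed"])

    def run_qc(self) -> None:
        name = "qc"
        rec = StageRecord(inputs={
            "hap1.fa": _sha256(self._path("hap1.fa")),
            "hap2.fa": _sha256(self._path("hap2.fa")),
            "genetic_map.tsv": _sha256(self._path("genetic_map.tsv")),
        })
        self.telomeres = {
            "hap1": telomere_scan(self.hap1), "hap2": telomere_scan(self.hap2)
        }
        self.map_report = map_concordance(self.markers)
        self.stats = {"hap1": assembly_stats(self.hap1), "hap2": assembly_stats(self.hap2)}
        if self._should_skip(name, rec.inputs):
            rec.status = "skipped"
        else:
            self._dirty = True
            rows = [
                {
                    "haplotype": hap, "chrom": p.chrom,
                    "total_copies": p.total_copies,
                    "left_positive": p.left_terminal_positive,
                    "right_positive": p.right_terminal_positive,
                }
                for hap, profs in self.telomeres.items()
                for p in profs
            ]
            pd.DataFrame(rows).to_csv(self._path("telomeres.tsv"), sep="\t", index=False)
            self.map_report.to_csv(self._path("map_concordance.tsv"), sep="\t", index=False)
            with open(self._path("assembly_stats.json"), "w") as fh:
                json.dump(self.stats, fh, indent=2)
            rec.status = "run"
        rec.counts = {"chromosomes": len(self.hap1.chromosomes)}
        self._finish(name, rec,
                     ["telomeres.tsv", "map_concordance.tsv", "assembly_stats.json"])

    def run_all(self) -> RunManifest:
        self.run_simulate()
        self.run_compare()
        self.run_hemizygosity()
        self.run_homologs()
        self.run_de()
        self.run_promoters()
        self.run_qc()
        self.manifest.save(self._manifest_path)
        return self.manifest


def run_all(
    config: SimulationConfig,
    outdir: str,
    region_tsv: str | None = None,
    alpha: float = 0.05,
    force: bool = False,
) -> RunManifest:
    """Run the full pipeline on a simulated dataset; see :class:`Pipeline`."""
    return Pipeline(config, outdir, region_tsv=region_tsv, alpha=alpha, force=force).run_all()
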