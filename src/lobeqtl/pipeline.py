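"""End-to-end orchestration: simulate -> genotype -> phenotype -> map.

Each stage reads its inputs from the output directory, writes text
artifacts, and records file hashes + parameters + seeds in a JSON run
manifest, so a rerun with the same config and master seed is verifiably
bit-identical and any stage can be resumed from disk.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as lio
from .config import (
    CallParams,
    CoverageModel,
    CrossDesign,
    GenomeConfig,
    Chromosome,
    QTLEffect,
    QTLSpec,
    SNPFilterParams,
    default_genome,
    default_qtl_spec,
)
from .genotyping import (
    build_marker_matrix,
    bin_window_counts,
    chr4_consensus,
    filter_individuals,
    filter_snps,
    genotype_clustering_qc,
    mask_markers,
)
from .morphometrics import TRAITS, phenotype_table, select_mapping_lobe, trait_summary_stats
from .qtl import (
    estimate_genetic_map,
    fit_multi_qtl,
    genotype_probabilities,
    lod_drop_interval,
    map_expansion,
    permutation_thresholds,
    regress_chr4,
    scan_one,
    significant_peaks,
)
from .rng import child_seed
from .simulate import simulate_ail_cohort, simulate_lobe_outlines, simulate_snp_reads, snp_panel

STAGES = ["simulate", "genotype", "phenotype", "map", "report"]


@dataclass
class PipelineConfig:
    genome: GenomeConfig = field(default_factory=default_genome)
    design: CrossDesign = field(default_factory=CrossDesign)
    coverage: CoverageModel = field(default_factory=CoverageModel)
    # half the recombinants are genotyped MSG-style by default, as in a
    # mixed-method panel
    msg_coverage: CoverageModel | None = field(
        default_factory=lambda: CoverageModel(regime="MSG", mean_depth=2.5)
    )
    msg_fraction_of_samples: float = 0.5
    qtl: QTLSpec = field(default_factory=default_qtl_spec)
    snp_filter: SNPFilterParams = field(default_factory=SNPFilterParams)
    caller: CallParams = field(default_factory=CallParams)
    scan_method: str = "hk"
    n_perm: int = 1000
    alpha: float = 0.05
    step_cm: float = 1.0
    hmm_error_rate: float = 0.01
    seed: int = 0

    def to_yaml(self, path):
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            if isinstance(obj, (list, tuple)):
                return [enc(v) for v in obj]
            return obj

        doc = {
            "genome": enc(self.genome),
            "design": enc(self.design),
            "coverage": enc(self.coverage),
            "msg_coverage": enc(self.msg_coverage) if self.msg_coverage else None,
            "msg_fraction_of_samples": self.msg_fraction_of_samples,
            "qtl": enc(self.qtl),
            "snp_filter": enc(self.snp_filter),
            "caller": enc(self.caller),
            "scan_method": self.scan_method,
            "n_perm": self.n_perm,
            "alpha": self.alpha,
            "step_cm": self.step_cm,
            "hmm_error_rate": self.hmm_error_rate,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        genome = default_genome()
        if "genome" in doc and doc["genome"]:
            g = doc["genome"]
            genome = GenomeConfig(
                chromosomes=[Chromosome(**c) for c in g["chromosomes"]],
                snp_density=g.get("snp_density", 2e-4),
                window_size=g.get("window_size", 250_000),
            )
        qtl = default_qtl_spec()
        if doc.get("qtl"):
            q = doc["qtl"]
            qtl = QTLSpec(
                qtl=[QTLEffect(**e) for e in q["qtl"]],
                noise_sd=tuple(q.get("noise_sd", (2.17e-3, 1.16e-3))),
                bilateral_rho=q.get("bilateral_rho", 0.75),
            )
        kw = {}
        for name, klass in (
            ("design", CrossDesign),
            ("coverage", CoverageModel),
            ("snp_filter", SNPFilterParams),
            ("caller", CallParams),
        ):
            if doc.get(name):
                d = dict(doc[name])
                if name == "caller" and "het_band" in d:
                    d["het_band"] = tuple(d["het_band"])
                kw[name] = klass(**d)
        msg = None
        if doc.get("msg_coverage"):
            msg = CoverageModel(**doc["msg_coverage"])
        return cls(
            genome=genome,
            qtl=qtl,
            msg_coverage=msg,
            msg_fraction_of_samples=doc.get("msg_fraction_of_samples", 0.5),
            scan_method=doc.get("scan_method", "hk"),
            n_perm=doc.get("n_perm", 1000),
            alpha=doc.get("alpha", 0.05),
            step_cm=doc.get("step_cm", 1.0),
            hmm_error_rate=doc.get("hmm_error_rate", 0.01),
            seed=doc.get("seed", 0),
            **kw,
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    path: Path

    def __post_init__(self):
        self.path = Path(self.path)
        self.data = {"stages": {}}
        if self.path.exists():
            self.data = json.loads(self.path.read_text())

    def record(self, stage: str, outputs: list, seed: int, params: dict | None = None):
        self.data["stages"][stage] = {
            "outputs": {str(p.name): _sha256(p) for p in map(Path, outputs)},
            "seed": seed,
            "params": params or {},
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }
        self.path.write_text(json.dumps(self.data, indent=2, sort_keys=True))

    def record_failure(self, stage: str, err: Exception):
        self.data["stages"][stage] = {"failed": repr(err)}
        self.path.write_text(json.dumps(self.data, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------
def stage_simulate(cfg: PipelineConfig, outdir: Path, manifest: RunManifest):
    outdir.mkdir(parents=True, exist_ok=True)
    seed = child_seed(cfg.seed, "simulate")
    cohort = simulate_ail_cohort(cfg.genome, cfg.design, seed=seed)
    panel = snp_panel(cfg.genome, seed=child_seed(seed, "panel"))
    regimes = None
    if cfg.msg_coverage is not None:
        ids = cohort.sample_ids
        k = int(round(len(ids) * cfg.msg_fraction_of_samples))
        regimes = {sid: cfg.msg_coverage for sid in ids[:k]}
    reads = simulate_snp_reads(cohort, panel, cfg.coverage, seed=child_seed(seed, "reads"), regimes=regimes)
    outlines, truth = simulate_lobe_outlines(cohort, cfg.qtl, seed=child_seed(seed, "lobes"))

    hap_path = outdir / "truth_haplotypes.tsv"
    lio.write_truth_haplotypes(hap_path, cohort)
    reads_path = outdir / "snp_read_counts.tsv"
    lio.write_snp_counts(reads_path, reads)
    truth_path = outdir / "truth_traits.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    odir = outdir / "outlines"
    odir.mkdir(exist_ok=True)
    opaths = []
    for i, o in enumerate(outlines):
        p = odir / f"{o.sample_id}_{o.side}.txt"
        lio.write_outline(p, o)
        opaths.append(p)
    method_path = outdir / "genotyping_method.tsv"
    method = pd.DataFrame(
        {
            "sample": cohort.sample_ids,
            "method": ["MSG" if regimes and s in regimes else "WGS" for s in cohort.sample_ids],
        }
    )
    method.to_csv(method_path, sep="\t", index=False)
    manifest.record("simulate", [hap_path, reads_path, truth_path, method_path], seed)
    return {"cohort": cohort, "reads": reads, "outlines": outlines, "truth": truth, "method": method}


def stage_genotype(cfg: PipelineConfig, outdir: Path, manifest: RunManifest, sim: dict):
    reads = sim["reads"]
    mask, rule_table = filter_snps(reads, cfg.snp_filter)
    wc = bin_window_counts(reads, mask, cfg.genome)
    mm = build_marker_matrix(wc, cfg.caller)
    mm = filter_individuals(mm, cfg.caller)
    consensus = chr4_consensus(mm) if (mm.markers["chrom"] == "4").any() else None
    mm_masked = mask_markers(mm, cfg.caller)
    # chromosome 4 carries no map; scans use the recombining arms only
    mm_map = mm_masked.subset_markers((mm_masked.markers["chrom"] != "4").to_numpy())

    wc_path = outdir / "window_counts.tsv"
    lio.write_window_counts(wc_path, wc)
    qc_lines = [
        f"SNPs retained: {int(mask.sum())} / {len(mask)}",
        f"samples retained: {len(mm.samples)} (of {len(wc.samples)})",
        f"markers retained for mapping: {len(mm_map.markers)}",
    ]
    method = sim.get("method")
    if method is not None and len(mm_map.recombinants().samples) >= 3:
        rec = mm_map.recombinants()
        labels = method.set_index("sample")["method"].reindex(rec.samples).to_numpy()
        qc = genotype_clustering_qc(rec, labels, seed=child_seed(cfg.seed, "qc"))
        qc_lines.append(
            f"method-mixing score: {qc['mixing_score']:.3f} (permutation p = {qc['p_value']:.3f})"
        )
    qc_path = outdir / "genotyping_qc.txt"
    qc_path.write_text("\n".join(qc_lines) + "\n")
    if consensus is not None:
        consensus.to_csv(outdir / "chr4_consensus.tsv", sep="\t", index=False)
    manifest.record("genotype", [wc_path, qc_path], child_seed(cfg.seed, "genotype"))
    return {"marker_matrix": mm_map, "consensus": consensus, "window_counts": wc}


def stage_phenotype(cfg: PipelineConfig, outdir: Path, manifest: RunManifest, sim: dict):
    seed = child_seed(cfg.seed, "phenotype")
    lobes = phenotype_table(sim["outlines"])
    primary, alternate = select_mapping_lobe(lobes, seed=seed)
    lobes_path = outdir / "lobe_traits.tsv"
    lobes.to_csv(lobes_path, sep="\t", index=False)
    prim_path = outdir / "phenotypes.tsv"
    primary.to_csv(prim_path, sep="\t", index=False)
    alt_path = outdir / "phenotypes_other_lobe.tsv"
    alternate.to_csv(alt_path, sep="\t", index=False)
    var_path = outdir / "pc_variance.tsv"
    pd.DataFrame(
        {"pc": [f"pc{i+1}" for i in range(len(lobes.attrs["pc_variance"]))],
         "variance_fraction": lobes.attrs["pc_variance"]}
    ).to_csv(var_path, sep="\t", index=False)
    welch, corr, pvals = trait_summary_stats(primary)
    welch.to_csv(outdir / "welch_tests.tsv", sep="\t", index=False)
    corr.to_csv(outdir / "trait_correlations.tsv", sep="\t")
    manifest.record("phenotype", [lobes_path, prim_path, alt_path, var_path], seed)
    return {"lobes": lobes, "primary": primary, "alternate": alternate}


def stage_map(cfg: PipelineConfig, outdir: Path, manifest: RunManifest, geno: dict, pheno: dict):
    seed = child_seed(cfg.seed, "map")
    mm = geno["marker_matrix"]
    gmap = estimate_genetic_map(mm)
    expansion = map_expansion(gmap, cfg.genome, cfg.design)
    grid = genotype_probabilities(mm, gmap, step=cfg.step_cm, error_rate=cfg.hmm_error_rate)

    primary = pheno["primary"]
    rec = primary[primary["group"] == "rec"].set_index("sample_id")
    traits = [t for t in TRAITS if t in rec.columns]
    scans, qtl_rows = {}, []
    thresholds = {}
    for tr in traits:
        y = rec[tr].reindex(grid.samples)
        scans[tr] = scan_one(grid, y, method=cfg.scan_method, seed=child_seed(seed, "scan", tr))
        thr = permutation_thresholds(
            grid, y, n_perm=cfg.n_perm, alpha=cfg.alpha, seed=child_seed(seed, "perm", tr)
        )
        thresholds[tr] = thr
        peaks = significant_peaks(scans[tr], thr)
        if len(peaks):
            fit = fit_multi_qtl(
                grid,
                [(r["chrom"], r["pos_cm"]) for _, r in peaks.iterrows()],
                y,
                conditional=False,
            )
            for qi, row in fit.table.iterrows():
                iv = lod_drop_interval(scans[tr], row["chrom"], row["pos_cm"])
                qtl_rows.append(
                    {
                        "trait": tr,
                        "chrom": row["chrom"],
                        "peak_cm": iv["peak_cm"],
                        "lod": iv["peak_lod"],
                        "var_explained_pct": row["var_explained"],
                        "additive": row["additive"],
                        "dominance": row["dominance"],
                        "interval_cm": f"{iv['cm_lo']:.1f}-{iv['cm_hi']:.1f}",
                        "interval_mb": f"{iv['bp_lo']/1e6:.2f}-{iv['bp_hi']/1e6:.2f}",
                        "model_var_explained_pct": fit.total_var_explained,
                    }
                )

    lio.write_cross_csv(outdir / "cross.csv", mm, gmap, primary)
    lod_path = outdir / "lod_table.tsv"
    lio.write_lod_table(lod_path, scans)
    exp_path = outdir / "map_expansion.tsv"
    expansion.table.to_csv(exp_path, sep="\t", index=False)
    thr_path = outdir / "thresholds.tsv"
    pd.DataFrame(
        [
            {
                "trait": tr,
                "autosome_lod": thresholds[tr].autosome,
                "x_lod": thresholds[tr].x,
                "alpha": thresholds[tr].alpha,
                "n_perm": thresholds[tr].n_perm,
            }
            for tr in traits
        ]
    ).to_csv(thr_path, sep="\t", index=False)
    qtl_cols = [
        "trait",
        "chrom",
        "peak_cm",
        "lod",
        "var_explained_pct",
        "additive",
        "dominance",
        "interval_cm",
        "interval_mb",
        "model_var_explained_pct",
    ]
    qtl_path = outdir / "qtl_report.tsv"
    pd.DataFrame(qtl_rows, columns=qtl_cols).to_csv(qtl_path, sep="\t", index=False)
    chr4_path = None
    if geno.get("consensus") is not None:
        chr4 = regress_chr4(geno["consensus"], primary)
        chr4_path = outdir / "chr4_regression.tsv"
        chr4.to_csv(chr4_path, sep="\t", index=False)
    outputs = [outdir / "cross.csv", lod_path, exp_path, thr_path, qtl_path]
    if chr4_path:
        outputs.append(chr4_path)
    manifest.record("map", outputs, seed)
    return {
        "gmap": gmap,
        "expansion": expansion,
        "scans": scans,
        "thresholds": thresholds,
        "qtl_table": pd.DataFrame(qtl_rows),
    }


def make_report(outdir: Path) -> str:
    """Plain-text run summary assembled from on-disk artifacts."""
    outdir = Path(outdir)
    lines = ["lobeqtl run report", "=" * 40]
    def table(path, title):
        p = outdir / path
        if not p.exists():
            lines.append(f"[missing artifact: {path}]")
            return None
        try:
            df = pd.read_csv(p, sep="\t")
        except pd.errors.EmptyDataError:
            df = pd.DataFrame()
        lines.append("")
        lines.append(title)
        lines.append("-" * len(title))
        lines.append(df.to_string(index=False))
        return df

    table("pc_variance.tsv", "Shape PC variance fractions")
    table("welch_tests.tsv", "Parental strain contrasts (Welch's t)")
    table("map_expansion.tsv", "Genetic map expansion")
    table("thresholds.tsv", "Permutation thresholds (5% genome-wide)")
    qtl = table("qtl_report.tsv", "Mapped QTL")
    if qtl is not None and qtl.empty:
        lines.append("no significant QTL at the genome-wide threshold")
    table("chr4_regression.tsv", "Chromosome 4 consensus regression")
    text = "\n".join(lines) + "\n"
    (outdir / "report.txt").write_text(text)
    return text


def run_pipeline(cfg: PipelineConfig, outdir, stages=None) -> RunManifest:
    """Execute the requested stages in order, recording a manifest.

    A stage failure aborts the run with the failure recorded; completed
    stages keep their artifacts and hashes.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(outdir / "config.yaml")
    manifest = RunManifest(outdir / "manifest.json")
    stages = stages or STAGES
    state = {}
    try:
        if "simulate" in stages:
            state["sim"] = stage_simulate(cfg, outdir, manifest)
        if "genotype" in stages:
            state["geno"] = stage_genotype(cfg, outdir, manifest, state["sim"])
        if "phenotype" in stages:
            state["pheno"] = stage_phenotype(cfg, outdir, manifest, state["sim"])
        if "map" in stages:
            state["map"] = stage_map(cfg, outdir, manifest, state["geno"], state["pheno"])
        if "report" in stages:
            make_report(outdir)
            manifest.record("report", [outdir / "report.txt"], cfg.seed)
    except Exception as err:  # noqa: BLE001 - manifest must record the failure
        stage = next((s for s in stages if s not in manifest.data["stages"]), "?")
        manifest.record_failure(stage, err)
        raise
    return manifest
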