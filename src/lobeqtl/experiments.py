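"""Reusable study-scale experiment drivers.

These functions wire the simulator to the mapping stack at the scales of
the original study design (an F13 advanced intercross of a few hundred
males, ~426 window markers on an ~822 cM expanded map) and are shared by
the test suite and the acceptance script.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .config import CrossDesign, GenomeConfig, QTLSpec, default_genome, default_qtl_spec
from .genotyping import MarkerMatrix
from .morphometrics import phenotype_table, select_mapping_lobe
from .qtl import (
    Thresholds,
    estimate_genetic_map,
    genotype_probabilities,
    lod_drop_interval,
    map_expansion,
    permutation_thresholds,
    scan_one,
)
from .rng import child_seed
from .simulate import Cohort, simulate_ail_cohort, simulate_lobe_outlines, truth_genotypes

# marker counts retained for mapping in the study design
STUDY_MARKER_COUNTS = {"X": 70, "2L": 86, "2R": 78, "3L": 87, "3R": 105}
STUDY_N_RECOMBINANTS = 181
# realized per-chromosome map expansion of the study panel (X, 2, 3); with
# the 276 cM reference these put the whole expanded map at ~822 cM
STUDY_EXPANSION = {"X": 2.8, "2L": 2.8, "2R": 2.8, "3L": 3.3, "3R": 3.3}


def evenly_spaced_markers(config: GenomeConfig, counts: dict) -> pd.DataFrame:
    """Window-midpoint-style marker positions, ``counts[chrom]`` per arm."""
    rows = []
    for chrom, k in counts.items():
        c = config.chrom(chrom)
        mids = np.linspace(0.5, k - 0.5, k) / k * c.length_bp
        w = c.length_bp / k
        for i, mid in enumerate(mids):
            rows.append(
                {
                    "name": f"Chr{chrom}.{i}",
                    "chrom": chrom,
                    "pos": int(mid),
                    "start": int(mid - w / 2),
                    "end": int(mid + w / 2),
                    "mid": int(mid),
                    "is_x": c.is_x,
                }
            )
    return pd.DataFrame(rows)


def dense_window_markers(config: GenomeConfig, spacing: int | None = None) -> pd.DataFrame:
    """One marker per genotyping window (window midpoints)."""
    w = config.windows()
    w = w[[c.recombining for c in map(config.chrom, w["chrom"])]]
    df = w.rename(columns={"mid": "pos"}).reset_index(drop=True)
    df["mid"] = df["pos"]
    return df[["name", "chrom", "pos", "start", "end", "mid", "is_x"]]


def truth_marker_matrix(cohort: Cohort, markers: pd.DataFrame) -> MarkerMatrix:
    """Error-free marker matrix straight from the truth haplotypes."""
    calls = truth_genotypes(cohort, markers.reset_index(drop=True))
    n = len(cohort.individuals)
    return MarkerMatrix(
        samples=cohort.sample_ids,
        roles=np.array(["rec"] * n),
        sex=np.array([ind.sex for ind in cohort.individuals]),
        calls=calls,
        markers=markers.reset_index(drop=True),
    )


# ---------------------------------------------------------------------------
# map expansion at study scale
# ---------------------------------------------------------------------------
def map_expansion_experiment(
    seed: int = 0,
    n_seeds: int = 5,
    n_males: int = 400,
    population: int = 300,
    generations: int = 13,
    config: GenomeConfig | None = None,
) -> pd.DataFrame:
    """Simulate F_t cohorts with dense error-free markers, estimate the
    map, and report autosomal and X expansion per replicate seed."""
    config = config or default_genome()
    design = CrossDesign(generations=generations, population_size=population, n_males=n_males)
    markers = dense_window_markers(config)
    rows = []
    for k in range(n_seeds):
        s = child_seed(seed, "expansion", k)
        cohort = simulate_ail_cohort(config, design, seed=s)
        mm = truth_marker_matrix(cohort, markers)
        gmap = estimate_genetic_map(mm)
        rep = map_expansion(gmap, config, design)
        rows.append(
            {
                "seed": s,
                "autosome_ratio": rep.autosome_ratio,
                "x_ratio": rep.x_ratio,
                "expected_autosome": rep.expected_autosome,
                "expected_x": rep.expected_x,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# permutation thresholds at study scale
# ---------------------------------------------------------------------------
def study_map_markers(config: GenomeConfig | None = None) -> pd.DataFrame:
    """The study's marker panel on its realized (expanded) genetic map.

    426 markers with the study's per-arm counts, evenly spaced along each
    arm, with expanded cM positions given by the per-chromosome expansion
    of the study panel applied to the standard female map.
    """
    config = config or default_genome()
    markers = evenly_spaced_markers(config, STUDY_MARKER_COUNTS)
    cms = []
    for _, row in markers.iterrows():
        ref_cm = config.cm_at(row["chrom"], row["mid"])
        cms.append(ref_cm * STUDY_EXPANSION[row["chrom"]])
    markers["cm"] = cms
    return markers


def simulate_chain_genotypes(markers: pd.DataFrame, n: int, seed: int = 0) -> np.ndarray:
    """Marker genotypes from the intercross Markov model on a given map.

    Each diploid sample is two independent parental-origin chains with
    Haldane transition probabilities between adjacent markers; males are
    hemizygous (one chain) on the X, coded 0/2.  This draws genotypes
    whose linkage structure follows the supplied expanded map exactly —
    the model under which the scan and its permutation thresholds are
    defined.
    """
    from .qtl import haldane_r
    from .rng import stream

    rng = stream(seed, "chain-genotypes")
    out = np.empty((n, len(markers)), dtype=np.int8)
    for chrom, grp in markers.groupby("chrom", sort=False):
        cols = grp.index.to_numpy()
        r = haldane_r(np.diff(grp["cm"].to_numpy()))
        n_gam = 1 if bool(grp["is_x"].iloc[0]) else 2
        geno = np.zeros((n, len(cols)), dtype=np.int8)
        for _ in range(n_gam):
            g = np.empty((n, len(cols)), dtype=np.int8)
            g[:, 0] = rng.random(n) < 0.5
            for j, rj in enumerate(r):
                flip = rng.random(n) < rj
                g[:, j + 1] = np.where(flip, 1 - g[:, j], g[:, j])
            geno += g
        if n_gam == 1:
            geno *= 2
        out[:, cols] = geno
    return out


def threshold_experiment(
    seed: int = 0,
    n_recombinants: int = STUDY_N_RECOMBINANTS,
    n_perm: int = 1000,
    alpha: float = 0.05,
    config: GenomeConfig | None = None,
) -> Thresholds:
    """Null-trait genome scan at the study design scale.

    Draws genotypes for the study's sample size at its 426 markers on the
    ~822 cM realized map, re-estimates the map from those genotypes,
    draws an independent Gaussian trait, and returns the permutation
    thresholds with the length-proportional X/autosome alpha split (the
    X permutation count scaled up by L/L_X).
    """
    config = config or default_genome()
    markers = study_map_markers(config)
    calls = simulate_chain_genotypes(markers, n_recombinants, seed=child_seed(seed, "thr-geno"))
    mm = MarkerMatrix(
        samples=[f"rec_{i:04d}" for i in range(n_recombinants)],
        roles=np.array(["rec"] * n_recombinants),
        sex=np.array(["M"] * n_recombinants),
        calls=calls,
        markers=markers.drop(columns=["cm"]).reset_index(drop=True),
    )
    gmap = estimate_genetic_map(mm)
    grid = genotype_probabilities(mm, gmap, step=1.0)
    rng = np.random.default_rng(child_seed(seed, "thr-trait"))
    y = rng.standard_normal(n_recombinants)
    thr = permutation_thresholds(grid, y, n_perm=n_perm, alpha=alpha, seed=child_seed(seed, "thr-perm"))
    thr.__dict__["map_cm"] = gmap.total_cm()
    return thr


# ---------------------------------------------------------------------------
# planted-QTL recovery at study scale
# ---------------------------------------------------------------------------
def planted_variance_fractions(qtl_spec: QTLSpec) -> pd.DataFrame:
    """Analytic per-locus variance fractions at 50:50 allele frequency.

    Autosomal HWE: var = a^2/2 + (d/2)^2; hemizygous X: var = a^2.  The
    denominator adds the residual variance of the locus's trait axis.
    """
    rows = []
    per_axis_vg = {}
    for q in qtl_spec.qtl:
        hemi = q.chrom == "X"
        v = q.additive**2 if hemi else q.additive**2 / 2 + (q.dominance / 2) ** 2
        per_axis_vg[q.trait_axis] = per_axis_vg.get(q.trait_axis, 0.0) + v
        rows.append({"chrom": q.chrom, "pos_cm": q.pos_cm, "axis": q.trait_axis, "vg": v})
    df = pd.DataFrame(rows)
    noise = list(qtl_spec.noise_sd)
    df["v_total"] = [
        per_axis_vg[a] + noise[min(a, len(noise) - 1)] ** 2 for a in df["axis"]
    ]
    df["ve_fraction"] = df["vg"] / df["v_total"]
    return df


def qtl_recovery_experiment(
    seed: int = 0,
    n_reps: int = 20,
    n_recombinants: int = STUDY_N_RECOMBINANTS,
    n_perm: int = 1000,
    qtl_spec: QTLSpec | None = None,
    config: GenomeConfig | None = None,
    window_cm: float = 15.0,
) -> pd.DataFrame:
    """Detection and 2-LOD-interval coverage of planted QTL.

    Each replicate simulates a study-scale cohort, generates bilateral
    outlines with the planted architecture, runs the full phenotype
    pipeline (standardize -> EFA -> PCA -> lobe selection), scans the
    leading PCs at 1 cM with per-replicate permutation thresholds, and
    records, for every planted locus, whether the LOD within
    ``window_cm`` (expanded map) of the true position clears the
    chromosome-type threshold and whether the chromosome peak's 2-LOD
    interval covers the truth.
    """
    config = config or default_genome()
    qtl_spec = qtl_spec or default_qtl_spec()
    design = CrossDesign(generations=13, population_size=300, n_males=n_recombinants)
    markers = evenly_spaced_markers(config, STUDY_MARKER_COUNTS)
    planted = planted_variance_fractions(qtl_spec)
    rows = []
    for rep in range(n_reps):
        s = child_seed(seed, "recovery", rep)
        cohort = simulate_ail_cohort(config, design, seed=s)
        mm = truth_marker_matrix(cohort, markers)
        gmap = estimate_genetic_map(mm)
        grid = genotype_probabilities(mm, gmap, step=1.0)
        outlines, _ = simulate_lobe_outlines(cohort, qtl_spec, seed=child_seed(s, "outl"))
        lobes = phenotype_table(outlines)
        primary, _ = select_mapping_lobe(lobes, seed=child_seed(s, "pick"))
        primary = primary[primary["group"] == "rec"].set_index("sample_id")
        for axis, trait in ((0, "pc1"), (1, "pc2")):
            y = primary[trait].reindex(cohort.sample_ids)
            scan = scan_one(grid, y, method="hk")
            thr = permutation_thresholds(grid, y, n_perm=n_perm, seed=child_seed(s, "perm", axis))
            for q in [q for q in qtl_spec.qtl if q.trait_axis == axis]:
                cmap = gmap.chrom(q.chrom)
                true_bp = config.bp_at(q.chrom, q.pos_cm)
                true_cm = float(np.interp(true_bp, cmap.bp, cmap.cm))
                sub = scan[scan["chrom"] == q.chrom]
                near = sub[(sub["pos_cm"] - true_cm).abs() <= window_cm]
                lim = thr.x if q.chrom == "X" else thr.autosome
                detected = bool(len(near) and near["lod"].max() >= lim)
                # support interval around the local peak nearest the truth
                # (a chromosome may carry two planted loci)
                local_peak = (
                    float(near.loc[near["lod"].idxmax(), "pos_cm"]) if len(near) else true_cm
                )
                iv = lod_drop_interval(scan, q.chrom, peak_cm=local_peak)
                covered = iv["cm_lo"] <= true_cm <= iv["cm_hi"]
                ve = float(
                    planted.loc[
                        (planted["chrom"] == q.chrom)
                        & (planted["pos_cm"] == q.pos_cm)
                        & (planted["axis"] == axis),
                        "ve_fraction",
                    ].iloc[0]
                )
                rows.append(
                    {
                        "rep": rep,
                        "axis": axis,
                        "chrom": q.chrom,
                        "pos_cm": q.pos_cm,
                        "planted_ve": ve,
                        "threshold": lim,
                        "max_lod_near": float(near["lod"].max()) if len(near) else 0.0,
                        "detected": detected,
                        "covered": bool(covered),
                    }
                )
    return pd.DataFrame(rows)
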