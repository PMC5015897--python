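"""Readers and writers for the pipeline's plain-text formats.

Formats: long tab-delimited SNP read counts; window count tables with
paired T7reads/SSreads columns; the intercross cross-file CSV dialect
(genotype codes A/H/B, empty = missing, with chromosome and cM header
rows under each marker); LOD tables (one row per test position); outline
coordinate files (x y pairs with a small header); truth haplotypes as
BED-like segment text.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .genotyping import CHAR_TO_CODE, CODE_TO_CHAR, NA, MarkerMatrix
from .morphometrics import RawOutline
from .qtl import GeneticMap


# ---------------------------------------------------------------------------
# haplotypes / read counts
# ---------------------------------------------------------------------------
def write_truth_haplotypes(path, cohort):
    rows = []
    for ind in cohort.individuals:
        for chrom, haps in ind.haplotypes.items():
            for hi, h in enumerate(haps):
                start = 0
                for end, par in zip(h.ends, h.parents):
                    rows.append(
                        {
                            "chrom": chrom,
                            "start": start,
                            "end": int(end),
                            "parent": "SS" if par == 1 else "T7",
                            "sample": ind.id,
                            "copy": hi,
                        }
                    )
                    start = int(end)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_snp_counts(path, reads):
    """Long format: sample, chrom, pos (1-based), t7_reads, ss_reads."""
    from .genotyping import infer_parental_alleles

    ss_allele, t7_allele = infer_parental_alleles(reads)
    cols = np.arange(reads.counts.shape[1])
    ss = reads.counts[:, cols, ss_allele]
    t7 = reads.counts[:, cols, t7_allele]
    frames = []
    for i, sid in enumerate(reads.samples):
        covered = (ss[i] + t7[i]) > 0
        frames.append(
            pd.DataFrame(
                {
                    "sample": sid,
                    "role": reads.roles[i],
                    "chrom": reads.snps["chrom"][covered],
                    "pos": reads.snps["pos"][covered] + 1,
                    "t7_reads": t7[i, covered],
                    "ss_reads": ss[i, covered],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def write_window_counts(path, wc):
    wc.to_paired_table().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# cross-file CSV
# ---------------------------------------------------------------------------
def write_cross_csv(path, m: MarkerMatrix, gmap: GeneticMap, pheno: pd.DataFrame | None = None):
    """Cross CSV: trait columns, then markers with chromosome and cM rows.

    Row 1 holds 'id', trait names and marker names; row 2 the chromosome
    of each marker (blank under id/traits); row 3 the cM position;
    genotypes are A/H/B with empty cells for missing.
    """
    mframe = gmap.to_frame().set_index("name")
    marker_names, chrom_row, cm_row = [], [], []
    order = []
    for cmap in gmap.chroms:
        for nm in cmap.marker_names:
            marker_names.append(nm)
            chrom_row.append(cmap.name)
            cm_row.append(f"{mframe.loc[nm, 'cm']:.6g}")
            order.append(list(m.markers["name"]).index(nm))
    traits = [c for c in (pheno.columns if pheno is not None else []) if c not in ("sample_id", "group", "side")]
    lines = []
    lines.append(",".join(["id"] + traits + marker_names))
    lines.append(",".join([""] * (1 + len(traits)) + chrom_row))
    lines.append(",".join([""] * (1 + len(traits)) + cm_row))
    ph = pheno.set_index("sample_id") if pheno is not None else None
    for i, sid in enumerate(m.samples):
        if m.roles[i] != "rec":
            continue
        vals = [sid]
        for tr in traits:
            v = ph[tr].get(sid, np.nan) if ph is not None else np.nan
            vals.append("" if pd.isna(v) else f"{v:.10g}")
        for j in order:
            vals.append(CODE_TO_CHAR[int(m.calls[i, j])])
        lines.append(",".join(vals))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_cross_csv(path):
    """Read the cross CSV back to (phenotype frame, MarkerMatrix)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(",")
        chrom_row = fh.readline().rstrip("\n").split(",")
        cm_row = fh.readline().rstrip("\n").split(",")
        body = [ln.rstrip("\n").split(",") for ln in fh if ln.strip()]
    n_meta = sum(1 for c in chrom_row if c == "")
    traits = header[1:n_meta]
    marker_names = header[n_meta:]
    chroms = chrom_row[n_meta:]
    cms = [float(v) for v in cm_row[n_meta:]]
    samples = [row[0] for row in body]
    pheno = pd.DataFrame(
        {
            "sample_id": samples,
            **{
                tr: [float(row[1 + k]) if row[1 + k] != "" else np.nan for row in body]
                for k, tr in enumerate(traits)
            },
        }
    )
    calls = np.array(
        [[CHAR_TO_CODE.get(v, NA) for v in row[n_meta:]] for row in body], dtype=np.int8
    )
    markers = pd.DataFrame(
        {
            "name": marker_names,
            "chrom": chroms,
            "cm": cms,
            "start": 0,
            "end": 0,
            "mid": np.arange(len(marker_names)),  # physical order proxy
            "is_x": [c == "X" for c in chroms],
        }
    )
    # preserve physical order within chromosomes via the cm order
    mm = MarkerMatrix(
        samples,
        np.array(["rec"] * len(samples)),
        np.array(["M"] * len(samples)),
        calls,
        markers,
    )
    return pheno, mm


# ---------------------------------------------------------------------------
# LOD tables / outlines
# ---------------------------------------------------------------------------
def write_lod_table(path, scans: dict):
    """One row per test position; one LOD column per trait.

    ``scans`` maps trait name -> scan frame (identical grids assumed).
    """
    first = next(iter(scans.values()))
    out = first[["name", "chrom", "pos_cm", "bp_lo", "bp_hi"]].copy()
    out.columns = ["Name", "Chr", "Position_cM", "Pos_Lower_bp", "Pos_Upper_bp"]
    for tr, sc in scans.items():
        out[f"{tr}.LOD"] = sc["lod"].to_numpy()
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_outline(path, o: RawOutline):
    with open(path, "w") as fh:
        fh.write(f"# sample={o.sample_id} side={o.side} group={o.group}\n")
        fh.write(f"# flip={int(o.flip)} baseline={o.baseline[0]},{o.baseline[1]} mm_per_px={o.mm_per_px:g}\n")
        for x, y in o.coords:
            fh.write(f"{x:.8g}\t{y:.8g}\n")


def read_outline(path) -> RawOutline:
    meta = {}
    coords = []
    with open(path) as fh:
        for ln in fh:
            if ln.startswith("#"):
                for tok in ln[1:].split():
                    if "=" in tok:
                        k, v = tok.split("=", 1)
                        meta[k] = v
            elif ln.strip():
                x, y = ln.split()
                coords.append((float(x), float(y)))
    b = tuple(int(v) for v in meta.get("baseline", "0,1").split(","))
    return RawOutline(
        coords=np.asarray(coords),
        flip=bool(int(meta.get("flip", "0"))),
        baseline=b,
        sample_id=meta.get("sample", ""),
        side=meta.get("side", "L"),
        group=meta.get("group", "rec"),
        mm_per_px=float(meta.get("mm_per_px", "1")),
    )
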