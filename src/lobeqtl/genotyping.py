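"""Window-based genotype calling for low-coverage two-parent crosses.

The pipeline consumes per-sample, per-SNP allele read counts (not reads or
VCFs).  SNPs pass six quality filters, surviving counts are summed into
non-overlapping 250 kb windows, and window genotypes are called from the
summed SS/T7 counts:

  filters: (1) at most two bases segregate in the panel; (2) both parents
  have reads; (3) each parent's top base has sample frequency >= 0.9;
  (4) the parents' top bases differ; (5) at least 48 recombinants yield a
  SNP-level genotype call; (6) the heterozygous-call fraction is <= 0.75.
  Per-sample calls backed by more than 500 reads are excluded from rule
  evaluation.

  window calls: (a) at least 20 reads for autosomal windows (10 on the X,
  reflecting male hemizygous dosage); (b) homozygote when one parental
  allele has at least 10x the reads of the other ("at least" — a tie at
  exactly 10x is homozygous); (c) heterozygote when the T7 allele
  frequency lies in the closed band [0.3, 0.7]; otherwise no call.
  Rules apply in the order a -> b -> c.

Samples with under 40% of windows called are dropped (parents never are);
windows called in under 90% of recombinants or with minor allele
frequency under 5% are masked.  On the male X, which is hemizygous, a
heterozygous call is biologically impossible and is forced to no-call.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .config import CallParams, GenomeConfig, SNPFilterParams

# genotype codes; A = T7 homozygote, B = SS homozygote (cross-file dialect)
A, H, B, NA = 0, 1, 2, -1
CODE_TO_CHAR = {A: "A", H: "H", B: "B", NA: ""}
CHAR_TO_CODE = {"A": A, "H": H, "B": B, "": NA, "NA": NA, "-": NA}


class InputError(ValueError):
    pass


# ---------------------------------------------------------------------------
# read tables
# ---------------------------------------------------------------------------
@dataclass
class SNPReadTable:
    """Per-sample per-SNP read counts split by base (A/C/G/T axis).

    ``roles`` flags each sample as 'SS', 'T7' (parental strains) or 'rec'
    (recombinant); ``snps`` carries chrom, 1-based-convention position
    (stored 0-based internally), and is_x.
    """

    samples: list
    roles: np.ndarray
    sex: np.ndarray
    snps: pd.DataFrame
    counts: np.ndarray  # (n_samples, n_snps, 4) int

    def __post_init__(self):
        if self.counts.shape != (len(self.samples), len(self.snps), 4):
            raise InputError("count array shape does not match samples x snps x 4")
        if (self.counts < 0).any():
            raise InputError("read counts must be non-negative")

    def parent_index(self, strain: str) -> int:
        idx = np.flatnonzero(self.roles == strain)
        if len(idx) != 1:
            raise InputError(f"expected exactly one {strain} parent sample")
        return int(idx[0])

    @property
    def recombinant_mask(self) -> np.ndarray:
        return self.roles == "rec"


def infer_parental_alleles(reads: SNPReadTable):
    """Most-frequent base per parent at every SNP (-1 where no reads)."""
    out = {}
    for strain in ("SS", "T7"):
        c = reads.counts[reads.parent_index(strain)]  # (n_snps, 4)
        top = c.argmax(axis=1)
        top[c.sum(axis=1) == 0] = -1
        out[strain] = top
    return out["SS"], out["T7"]


# ---------------------------------------------------------------------------
# SNP filters (rules 1-6)
# ---------------------------------------------------------------------------
def filter_snps(reads: SNPReadTable, p: SNPFilterParams | None = None):
    """Apply the six SNP quality rules; returns (mask, per-rule table).

    SNP-level genotype calls used by rules 5-6 are defined from counts: a
    recombinant yields a call when it has 1..max_reads_per_call reads on
    the parental bases, and the call is heterozygous when both parental
    bases are observed.
    """
    p = p or SNPFilterParams()
    iss, it7 = reads.parent_index("SS"), reads.parent_index("T7")
    counts = reads.counts
    n_snps = counts.shape[1]

    panel_base_present = counts.sum(axis=0) > 0  # (n_snps, 4)
    rule1 = panel_base_present.sum(axis=1) <= 2

    ss_tot = counts[iss].sum(axis=1)
    t7_tot = counts[it7].sum(axis=1)
    rule2 = (ss_tot > 0) & (t7_tot > 0)

    with np.errstate(invalid="ignore", divide="ignore"):
        ss_freq = counts[iss].max(axis=1) / np.where(ss_tot > 0, ss_tot, 1)
        t7_freq = counts[it7].max(axis=1) / np.where(t7_tot > 0, t7_tot, 1)
    rule3 = rule2 & (ss_freq >= p.parental_hom_freq) & (t7_freq >= p.parental_hom_freq)

    ss_allele = counts[iss].argmax(axis=1)
    t7_allele = counts[it7].argmax(axis=1)
    rule4 = rule2 & (ss_allele != t7_allele)

    rec = counts[reads.recombinant_mask]  # (n_rec, n_snps, 4)
    cols = np.arange(n_snps)
    n_ss = rec[:, cols, ss_allele]
    n_t7 = rec[:, cols, t7_allele]
    total_any = rec.sum(axis=2)
    eligible = (total_any <= p.max_reads_per_call) & ((n_ss + n_t7) > 0)
    het = eligible & (n_ss > 0) & (n_t7 > 0)
    n_calls = eligible.sum(axis=0)
    rule5 = n_calls >= p.min_recomb_calls
    with np.errstate(invalid="ignore", divide="ignore"):
        het_frac = het.sum(axis=0) / np.where(n_calls > 0, n_calls, 1)
    rule6 = (n_calls > 0) & (het_frac <= p.max_het_frac)

    table = pd.DataFrame(
        {
            "rule1_biallelic": rule1,
            "rule2_parent_reads": rule2,
            "rule3_parents_hom": rule3,
            "rule4_parents_differ": rule4,
            "rule5_min_calls": rule5,
            "rule6_het_frac": rule6,
        }
    )
    mask = table.all(axis=1).to_numpy()
    return mask, table


# ---------------------------------------------------------------------------
# window binning
# ---------------------------------------------------------------------------
@dataclass
class WindowCountTable:
    windows: pd.DataFrame  # name, chrom, index, start, end, mid, is_x
    ss: np.ndarray  # (n_samples, n_windows)
    t7: np.ndarray
    samples: list
    roles: np.ndarray
    sex: np.ndarray

    def to_paired_table(self) -> pd.DataFrame:
        """Paired-column layout: per window a T7reads and an SSreads column."""
        data = {"ID": self.samples, "Role": self.roles}
        for j, w in self.windows.iterrows():
            data[f"{w['name']}.T7reads"] = self.t7[:, j]
            data[f"{w['name']}.SSreads"] = self.ss[:, j]
        return pd.DataFrame(data)


def bin_window_counts(
    reads: SNPReadTable, retained: np.ndarray, config: GenomeConfig
) -> WindowCountTable:
    """Sum retained-SNP SS/T7 allele counts into 250 kb windows.

    Windows tile every configured chromosome; windows without retained
    SNPs are emitted with zero counts.  Order of SNPs in the input is
    irrelevant.
    """
    if retained.sum() == 0:
        raise InputError("no retained SNPs to bin")
    windows = config.windows()
    ss_allele, t7_allele = infer_parental_alleles(reads)
    n = len(reads.samples)
    ss = np.zeros((n, len(windows)), dtype=np.int64)
    t7 = np.zeros((n, len(windows)), dtype=np.int64)

    wkey = {(r["chrom"], r["index"]): j for j, r in windows.iterrows()}
    snps = reads.snps
    kept = np.flatnonzero(retained)
    cols = np.arange(reads.counts.shape[1])
    cnt_ss = reads.counts[:, cols, ss_allele]
    cnt_t7 = reads.counts[:, cols, t7_allele]
    wid = np.array(
        [
            wkey[(snps["chrom"].iat[k], int(snps["pos"].iat[k]) // config.window_size)]
            for k in kept
        ],
        dtype=np.int64,
    )
    np.add.at(ss.T, wid, cnt_ss[:, kept].T)
    np.add.at(t7.T, wid, cnt_t7[:, kept].T)
    return WindowCountTable(windows, ss, t7, list(reads.samples), reads.roles.copy(), reads.sex.copy())


# ---------------------------------------------------------------------------
# window genotype calls
# ---------------------------------------------------------------------------
def call_window_genotype(ss, t7, is_x, p: CallParams | None = None):
    """Call A/H/B/NA from summed window counts (vectorized).

    Precedence: depth gate, then the 10x homozygote ratio, then the closed
    heterozygote band on the T7 allele frequency, else no call.
    """
    p = p or CallParams()
    ss = np.asarray(ss, dtype=np.int64)
    t7 = np.asarray(t7, dtype=np.int64)
    is_x = np.broadcast_to(np.asarray(is_x, dtype=bool), ss.shape)
    total = ss + t7
    min_reads = np.where(is_x, p.min_reads_x, p.min_reads_aut)
    out = np.full(ss.shape, NA, dtype=np.int8)
    ok = total >= min_reads
    is_b = ok & (ss >= p.hom_ratio * t7)
    is_a = ok & (t7 >= p.hom_ratio * ss) & ~is_b
    with np.errstate(invalid="ignore", divide="ignore"):
        f_t7 = t7 / np.where(total > 0, total, 1)
    lo, hi = p.het_band
    is_h = ok & ~is_b & ~is_a & (f_t7 >= lo) & (f_t7 <= hi)
    out[is_b] = B
    out[is_a] = A
    out[is_h] = H
    if out.ndim == 0:
        return int(out)
    return out


# ---------------------------------------------------------------------------
# marker matrix
# ---------------------------------------------------------------------------
@dataclass
class MarkerMatrix:
    samples: list
    roles: np.ndarray  # 'SS' / 'T7' / 'rec'
    sex: np.ndarray
    calls: np.ndarray  # (n_samples, n_markers) int8 in {A,H,B,NA}
    markers: pd.DataFrame  # name, chrom, start, end, mid, is_x

    def __post_init__(self):
        if self.calls.shape != (len(self.samples), len(self.markers)):
            raise InputError("call matrix shape mismatch")

    @property
    def recombinant_mask(self):
        return self.roles == "rec"

    def recombinants(self) -> "MarkerMatrix":
        return self.subset_samples(self.recombinant_mask)

    def subset_samples(self, mask) -> "MarkerMatrix":
        mask = np.asarray(mask)
        return MarkerMatrix(
            [s for s, m in zip(self.samples, mask) if m],
            self.roles[mask],
            self.sex[mask],
            self.calls[mask],
            self.markers,
        )

    def subset_markers(self, mask) -> "MarkerMatrix":
        mask = np.asarray(mask)
        return MarkerMatrix(
            self.samples,
            self.roles,
            self.sex,
            self.calls[:, mask],
            self.markers.loc[mask].reset_index(drop=True),
        )

    def chrom_markers(self, chrom: str) -> np.ndarray:
        return (self.markers["chrom"] == chrom).to_numpy()

    def called_fraction_per_sample(self) -> np.ndarray:
        return (self.calls != NA).mean(axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        chars = np.vectorize(CODE_TO_CHAR.get)(self.calls)
        return pd.DataFrame(chars, index=self.samples, columns=self.markers["name"])


def build_marker_matrix(wc: WindowCountTable, p: CallParams | None = None) -> MarkerMatrix:
    """Elementwise window calls, with the male-X hemizygosity guard.

    A heterozygous call on the X of a male sample cannot be real (one X
    copy) and is recorded as no-call.  Idempotent: the matrix is a pure
    function of the count table and parameters.
    """
    p = p or CallParams()
    is_x = wc.windows["is_x"].to_numpy()
    calls = call_window_genotype(wc.ss, wc.t7, is_x[None, :], p)
    male = (wc.sex == "M")[:, None]
    calls[male & is_x[None, :] & (calls == H)] = NA
    return MarkerMatrix(list(wc.samples), wc.roles.copy(), wc.sex.copy(), calls, wc.windows.copy())


def filter_individuals(m: MarkerMatrix, p: CallParams | None = None) -> MarkerMatrix:
    """Drop recombinants with a called-marker fraction strictly below the
    threshold (default 40%); parental samples are always retained."""
    p = p or CallParams()
    frac = m.called_fraction_per_sample()
    keep = (frac >= p.min_ind_call_rate) | ~m.recombinant_mask
    if not (keep & m.recombinant_mask).any():
        raise InputError("all recombinant samples failed the call-rate filter")
    return m.subset_samples(keep)


def marker_maf(m: MarkerMatrix) -> np.ndarray:
    """Minor parental-allele frequency per marker over called recombinant
    genotypes, counting 2 alleles per autosomal genotype and 1 per male-X
    genotype (hemizygous calls are recorded as homozygous codes)."""
    rec = m.recombinant_mask
    calls = m.calls[rec]
    male = (m.sex[rec] == "M")[:, None]
    is_x = m.markers["is_x"].to_numpy()[None, :]
    hemi = male & is_x
    called = calls != NA
    # SS allele dosage per genotype: A=0, H=1, B=2 (diploid); hemi: A=0, B=1
    ss_dose = np.where(called, calls, 0).astype(float)
    ss_dose = np.where(hemi, ss_dose / 2.0, ss_dose)
    n_alleles = np.where(called, np.where(hemi, 1.0, 2.0), 0.0)
    tot = n_alleles.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        f_ss = ss_dose.sum(axis=0) / np.where(tot > 0, tot, 1)
    maf = np.minimum(f_ss, 1 - f_ss)
    maf[tot == 0] = 0.0
    return maf


def mask_markers(m: MarkerMatrix, p: CallParams | None = None) -> MarkerMatrix:
    """Remove windows called in too few recombinants or nearly monomorphic.

    A marker is masked when its recombinant called fraction is < 90% or
    its minor allele frequency is < 5%.  The MAF clause also removes
    regions fixed for one parent (e.g. a swept chromosome tip), where no
    mapping information remains.  Monotone: raising either threshold can
    only mask more markers.
    """
    p = p or CallParams()
    rec = m.recombinant_mask
    called_frac = (m.calls[rec] != NA).mean(axis=0)
    maf = marker_maf(m)
    keep = (called_frac >= p.min_window_called_frac) & (maf >= p.min_maf)
    return m.subset_markers(keep)


# ---------------------------------------------------------------------------
# chromosome 4 consensus
# ---------------------------------------------------------------------------
def chr4_consensus(m: MarkerMatrix, chrom: str = "4") -> pd.DataFrame:
    """Single consensus genotype per sample across chromosome-4 windows.

    The consensus is the unique non-missing call when all called windows
    agree; samples with conflicting calls are flagged discordant and get
    no consensus.
    """
    sel = m.chrom_markers(chrom)
    if not sel.any():
        raise InputError(f"no markers on chromosome {chrom}")
    sub = m.calls[:, sel]
    rows = []
    for i, sid in enumerate(m.samples):
        vals = sub[i][sub[i] != NA]
        uniq = np.unique(vals)
        if len(uniq) == 1:
            rows.append({"sample": sid, "consensus": int(uniq[0]), "discordant": False})
        elif len(uniq) == 0:
            rows.append({"sample": sid, "consensus": NA, "discordant": False})
        else:
            rows.append({"sample": sid, "consensus": NA, "discordant": True})
    df = pd.DataFrame(rows)
    df.attrs["n_called"] = int((df["consensus"] != NA).sum())
    return df


# ---------------------------------------------------------------------------
# method QC clustering
# ---------------------------------------------------------------------------
def genotype_mismatch_matrix(m: MarkerMatrix) -> np.ndarray:
    """Pairwise genotype mismatch counts over co-called markers."""
    calls = m.calls
    n = calls.shape[0]
    if n < 3:
        raise InputError("need at least 3 samples to cluster")
    ok = calls != NA
    d = np.zeros((n, n))
    for i in range(n):
        both = ok[i][None, :] & ok
        diff = (calls[i][None, :] != calls) & both
        d[i] = diff.sum(axis=1)
    np.fill_diagonal(d, 0.0)
    return d


def genotype_clustering_qc(
    m: MarkerMatrix, labels, n_null: int = 999, seed: int = 0
) -> dict:
    """Hierarchical clustering of recombinants + label-mixing statistic.

    Average-linkage clustering of the pairwise mismatch matrix, as one
    would do to check that genotyping batches (e.g. WGS vs MSG samples)
    do not cluster by method.  The mixing score is the fraction of
    samples whose nearest neighbour shares their label; its permutation
    null yields a p-value (high mixing beyond chance <=> batch structure).
    """
    from .rng import stream

    labels = np.asarray(labels)
    d = genotype_mismatch_matrix(m)
    Z = linkage(squareform(d, checks=False), method="average")

    dd = d + np.eye(len(d)) * (d.max() + 1)
    nn = dd.argmin(axis=1)

    def score(lab):
        return float((lab[nn] == lab).mean())

    obs = score(labels)
    rng = stream(seed, "cluster-qc")
    null = np.array([score(rng.permutation(labels)) for _ in range(n_null)])
    p = (1 + (null >= obs).sum()) / (n_null + 1)
    return {
        "distance": d,
        "linkage": Z,
        "mixing_score": obs,
        "null_scores": null,
        "p_value": float(p),
    }
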