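"""Genetic map estimation and QTL genome scans for an AIL intercross.

The advanced intercross is analysed as an F2-type intercross on its own
estimated (expanded) genetic map: adjacent-marker recombination fractions
are estimated by EM over intercross genotype pairs, converted to cM with
the Haldane map function, and single-QTL scans step through the genome in
1 cM increments using genotype-class probabilities from a hidden Markov
model (3 classes on autosomes, 2 on the hemizygous male X).

Scans come in two flavours: Haley-Knott regression on expected genotype
dosages ('hk', deterministic, the default) and multiple imputation
('imp'), which samples genotype realizations from the joint chain and
combines per-draw LODs as log10 of the mean of 10^LOD.  Genome-wide
significance uses trait permutations with separate X/autosome thresholds,
the overall alpha split in proportion to genetic length.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import ConfigError, CrossDesign, GenomeConfig
from .genotyping import A, B, H, NA, MarkerMatrix
from .rng import stream

MAX_R = 0.4999


def haldane_cm(r):
    """Map distance in cM from a recombination fraction (Haldane)."""
    r = np.clip(np.asarray(r, dtype=float), 0.0, MAX_R)
    return -50.0 * np.log(1.0 - 2.0 * r)


def haldane_r(d_cm):
    """Recombination fraction across d cM (Haldane, no interference)."""
    return 0.5 * (1.0 - np.exp(-np.asarray(d_cm, dtype=float) / 50.0))


# ---------------------------------------------------------------------------
# genetic map
# ---------------------------------------------------------------------------
@dataclass
class ChromosomeMap:
    name: str
    is_x: bool
    marker_names: list
    cm: np.ndarray  # cumulative positions, first marker at 0
    bp: np.ndarray  # physical anchor (window midpoint) per marker
    start: np.ndarray  # window bounds per marker
    end: np.ndarray
    r: np.ndarray  # adjacent recombination fractions (len n-1)
    informative: bool = True

    @property
    def length_cm(self) -> float:
        return float(self.cm[-1] - self.cm[0]) if len(self.cm) else 0.0

    def cm_to_bp(self, cm):
        return np.interp(cm, self.cm, self.bp)


@dataclass
class GeneticMap:
    chroms: list
    map_function: str = "haldane"

    def chrom(self, name: str) -> ChromosomeMap:
        for c in self.chroms:
            if c.name == name:
                return c
        raise ConfigError(f"chromosome {name!r} not in map")

    def total_cm(self, informative_only: bool = True) -> float:
        return float(
            sum(c.length_cm for c in self.chroms if c.informative or not informative_only)
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.chroms:
            for i, name in enumerate(c.marker_names):
                rows.append(
                    {"name": name, "chrom": c.name, "cm": c.cm[i], "bp_mid": c.bp[i]}
                )
        return pd.DataFrame(rows)


def _em_recomb_fraction(g1, g2, hemizygous: bool, tol=1e-10, max_iter=200):
    """Recombination fraction between two marker columns (codes 0/1/2).

    Pairs with a missing call at either marker are dropped.  For diploid
    intercross data the double-heterozygote class is phase-ambiguous
    (0 or 2 recombinant gametes) and is resolved by EM; two-class
    hemizygous data gives the direct mismatch fraction.
    """
    ok = (g1 != NA) & (g2 != NA)
    g1, g2 = g1[ok], g2[ok]
    n = len(g1)
    if n == 0:
        return np.nan, 0
    if hemizygous:
        return float(np.mean(g1 != g2)), n
    counts = np.bincount(g1.astype(int) * 3 + g2.astype(int), minlength=9).reshape(3, 3)
    # recombinant gametes per two-locus genotype class (double het ambiguous)
    base_k = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float)
    n_hh = counts[1, 1]
    counts_k = (counts * base_k).sum()
    r = 0.1
    for _ in range(max_iter):
        e_hh = 2 * r**2 / (r**2 + (1 - r) ** 2) if (r > 0) else 0.0
        r_new = (counts_k + n_hh * e_hh) / (2.0 * n)
        r_new = min(max(r_new, 1e-12), MAX_R)
        if abs(r_new - r) < tol:
            r = r_new
            break
        r = r_new
    return float(r), n


def _multipoint_em_r(
    calls: np.ndarray,
    hemi: bool,
    error_rate: float = 1e-4,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> np.ndarray:
    """Joint EM over a whole chromosome's marker chain (Baum-Welch).

    Missing calls are genuinely missing data, not dropped samples: a
    crossover hidden inside a no-call window is probabilistically
    reassigned to the flanking intervals, which a complete-case
    adjacent-pair estimate would censor.  ``error_rate`` is the assumed
    genotyping error in the emissions.
    """
    n, m = calls.shape
    if m < 2 or n == 0:
        return np.zeros(max(m - 1, 0))
    k = 2 if hemi else 3
    obs = calls.copy()
    if hemi:
        obs = np.where(obs == H, NA, obs)
    emis = np.stack([_emission(obs[:, j], k, error_rate) for j in range(m)])  # (m, n, k)
    prior = np.full(k, 0.5) if k == 2 else np.array([0.25, 0.5, 0.25])
    gametes = 1.0 if hemi else 2.0
    base_k = np.array([[0.0, 1.0], [1.0, 0.0]]) if hemi else np.array(
        [[0.0, 1.0, 2.0], [1.0, 0.0, 1.0], [2.0, 1.0, 0.0]]
    )

    # initialize from complete-case pairwise estimates
    r = np.empty(m - 1)
    for j in range(m - 1):
        rj, nn = _em_recomb_fraction(calls[:, j], calls[:, j + 1], hemi)
        r[j] = 0.01 if (np.isnan(rj) or nn == 0) else min(max(rj, 1e-6), MAX_R)

    for _ in range(max_iter):
        trans = [_transition(rj, k) for rj in r]
        alpha = np.empty((m, n, k))
        a = prior[None, :] * emis[0]
        a /= a.sum(axis=1, keepdims=True)
        alpha[0] = a
        for j in range(1, m):
            a = (a @ trans[j - 1]) * emis[j]
            a /= a.sum(axis=1, keepdims=True)
            alpha[j] = a
        beta = np.ones((n, k))
        r_new = np.empty_like(r)
        for j in range(m - 2, -1, -1):
            right = emis[j + 1] * beta  # (n, k)
            # posterior transition counts for interval j
            xi = alpha[j][:, :, None] * trans[j][None, :, :] * right[:, None, :]
            xi /= xi.sum(axis=(1, 2), keepdims=True)
            kk = base_k.copy()
            if not hemi:
                rr = r[j]
                kk[1, 1] = 2 * rr**2 / ((1 - rr) ** 2 + rr**2) if rr > 0 else 0.0
            r_new[j] = (xi.sum(axis=0) * kk).sum() / (gametes * n)
            beta = (right @ trans[j].T)
            beta /= beta.sum(axis=1, keepdims=True)
        r_new = np.clip(r_new, 0.0, MAX_R)
        delta = np.max(np.abs(r_new - r))
        r = r_new
        if delta < tol:
            break
    return r


def estimate_genetic_map(m: MarkerMatrix, error_rate: float = 1e-4) -> GeneticMap:
    """Estimate the realized (expanded) map from a recombinant panel.

    Uses recombinant samples only; markers are taken in physical order
    within each chromosome, adjacent recombination fractions estimated by
    multipoint EM (missing calls handled as missing data) and converted
    to cM via Haldane, positions cumulative from 0.  Chromosomes with
    fewer than 2 markers (or no data) are flagged uninformative and
    excluded from map totals.
    """
    rec = m.recombinants()
    chroms = []
    for chrom in rec.markers["chrom"].unique():
        sel = rec.markers["chrom"] == chrom
        sub = rec.markers[sel].sort_values("mid")
        order = sub.index.to_numpy()
        calls = rec.calls[:, order]
        is_x = bool(sub["is_x"].iloc[0])
        hemi = is_x and bool((rec.sex == "M").all())
        n_mark = len(order)
        informative = n_mark >= 2 and bool((calls != NA).any())
        if informative:
            rs = _multipoint_em_r(calls, hemi, error_rate=error_rate)
        else:
            rs = np.zeros(max(n_mark - 1, 0))
        cm = np.concatenate([[0.0], np.cumsum(haldane_cm(rs))]) if n_mark else np.array([])
        chroms.append(
            ChromosomeMap(
                name=chrom,
                is_x=is_x,
                marker_names=list(sub["name"]),
                cm=cm,
                bp=sub["mid"].to_numpy(dtype=float),
                start=sub["start"].to_numpy(),
                end=sub["end"].to_numpy(),
                r=rs,
                informative=informative,
            )
        )
    return GeneticMap(chroms)


# ---------------------------------------------------------------------------
# map expansion
# ---------------------------------------------------------------------------
@dataclass
class ExpansionReport:
    table: pd.DataFrame
    autosome_ratio: float
    x_ratio: float
    expected_autosome: float
    expected_x: float


def map_expansion(
    est: GeneticMap, config: GenomeConfig, design: CrossDesign
) -> ExpansionReport:
    """Observed/reference map-length ratios vs the AIL design expectation.

    The reference length for each chromosome is the standard female-map
    distance spanned by the same first/last marker anchors.  With
    recombination confined to females, s = t/2 effective generations, and
    the expected expansion is s/2 on autosomes and 2/3 of that on the X
    (the X spends two thirds of its history in females).
    """
    s = design.s
    exp_a, exp_x = s / 2.0, (2.0 / 3.0) * (s / 2.0)
    rows = []
    for c in est.chroms:
        if not c.informative:
            continue
        ref = config.cm_at(c.name, c.bp[-1]) - config.cm_at(c.name, c.bp[0])
        if ref <= 0:
            continue
        rows.append(
            {
                "chrom": c.name,
                "is_x": c.is_x,
                "observed_cm": c.length_cm,
                "reference_cm": ref,
                "ratio": c.length_cm / ref,
                "expected": exp_x if c.is_x else exp_a,
            }
        )
    if not rows:
        raise ConfigError("no informative chromosome spans a non-zero reference map")
    table = pd.DataFrame(rows)
    aut = table[~table["is_x"]]
    xr = table[table["is_x"]]
    autosome_ratio = float(aut["observed_cm"].sum() / aut["reference_cm"].sum()) if len(aut) else np.nan
    x_ratio = float(xr["observed_cm"].sum() / xr["reference_cm"].sum()) if len(xr) else np.nan
    return ExpansionReport(table, autosome_ratio, x_ratio, exp_a, exp_x)


# ---------------------------------------------------------------------------
# genotype probabilities (hidden Markov model)
# ---------------------------------------------------------------------------
@dataclass
class ChromosomeGrid:
    name: str
    is_x: bool
    n_states: int
    cm: np.ndarray
    bp: np.ndarray
    bp_lo: np.ndarray
    bp_hi: np.ndarray
    names: list
    is_marker: np.ndarray
    probs: np.ndarray  # (n_samples, n_pos, n_states) posterior
    filtered: np.ndarray  # forward-filtered probabilities, for path sampling
    step_r: np.ndarray  # recombination fraction between successive positions


@dataclass
class ProbGrid:
    samples: list
    chroms: list
    step: float
    error_rate: float

    def chrom(self, name: str) -> ChromosomeGrid:
        for c in self.chroms:
            if c.name == name:
                return c
        raise ConfigError(f"chromosome {name!r} not in grid")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def genetic_lengths(self):
        la = sum(float(c.cm[-1] - c.cm[0]) for c in self.chroms if not c.is_x)
        lx = sum(float(c.cm[-1] - c.cm[0]) for c in self.chroms if c.is_x)
        return la, lx


def _transition(r: float, n_states: int) -> np.ndarray:
    if n_states == 2:
        return np.array([[1 - r, r], [r, 1 - r]])
    return np.array(
        [
            [(1 - r) ** 2, 2 * r * (1 - r), r**2],
            [r * (1 - r), (1 - r) ** 2 + r**2, r * (1 - r)],
            [r**2, 2 * r * (1 - r), (1 - r) ** 2],
        ]
    )


def _emission(obs: np.ndarray, n_states: int, eps: float) -> np.ndarray:
    """(n_samples, n_states) emission weights for one marker column."""
    n = len(obs)
    e = np.ones((n, n_states))
    if n_states == 2:
        state_of = {A: 0, B: 1}
    else:
        state_of = {A: 0, H: 1, B: 2}
    for code, s in state_of.items():
        sel = obs == code
        e[sel] = eps / (n_states - 1)
        e[sel, s] = 1.0 - eps
    return e


def genotype_probabilities(
    m: MarkerMatrix, gmap: GeneticMap, step: float = 1.0, error_rate: float = 0.01
) -> ProbGrid:
    """Forward-backward genotype-class probabilities on a pseudomarker grid.

    Positions are the markers plus a 1 cM lattice (by default) spanning
    each chromosome; transitions follow Haldane on the estimated
    (expanded) map, emissions allow a symmetric genotyping error rate,
    and the chain has two states on the hemizygous male X.  Posterior
    probabilities sum to 1 at every position.
    """
    rec = m.recombinants()
    chroms = []
    for cmap in gmap.chroms:
        if not len(cmap.cm):
            continue
        sel = rec.markers["chrom"] == cmap.name
        sub = rec.markers[sel].sort_values("mid")
        calls = rec.calls[:, sub.index.to_numpy()]
        n_samp = calls.shape[0]
        hemi = cmap.is_x and bool((rec.sex == "M").all())
        k = 2 if hemi else 3
        if hemi:
            calls = np.where(calls == H, NA, calls)

        lattice = np.arange(0.0, cmap.cm[-1] + 1e-9, step) if cmap.cm[-1] > 0 else np.array([0.0])
        pos = np.unique(np.round(np.concatenate([cmap.cm, lattice]), 9))
        marker_idx = np.searchsorted(pos, np.round(cmap.cm, 9))
        is_marker = np.zeros(len(pos), dtype=bool)
        is_marker[marker_idx] = True
        obs_col = np.full(len(pos), -1, dtype=np.int64)
        obs_col[marker_idx] = np.arange(len(cmap.cm))

        names = []
        mi = {int(p): nm for p, nm in zip(marker_idx, cmap.marker_names)}
        for j, p in enumerate(pos):
            names.append(mi.get(j, f"c{cmap.name}.loc{p:g}"))

        bp = cmap.cm_to_bp(pos)
        bp_lo = np.interp(pos, cmap.cm, cmap.start.astype(float))
        bp_hi = np.interp(pos, cmap.cm, cmap.end.astype(float))

        step_r = haldane_r(np.diff(pos))
        prior = np.full(k, 1.0 / 2) if k == 2 else np.array([0.25, 0.5, 0.25])

        emis = np.ones((len(pos), n_samp, k))
        for j in np.flatnonzero(is_marker):
            emis[j] = _emission(calls[:, obs_col[j]], k, error_rate)

        # forward
        filtered = np.empty((n_samp, len(pos), k))
        alpha = prior[None, :] * emis[0]
        alpha /= alpha.sum(axis=1, keepdims=True)
        filtered[:, 0] = alpha
        trans = [_transition(r, k) for r in step_r]
        for j in range(1, len(pos)):
            alpha = (alpha @ trans[j - 1]) * emis[j]
            alpha /= alpha.sum(axis=1, keepdims=True)
            filtered[:, j] = alpha
        # backward
        post = np.empty_like(filtered)
        beta = np.ones((n_samp, k))
        post[:, -1] = filtered[:, -1]
        for j in range(len(pos) - 2, -1, -1):
            beta = (beta * emis[j + 1]) @ trans[j].T
            beta /= beta.sum(axis=1, keepdims=True)
            p = filtered[:, j] * beta
            post[:, j] = p / p.sum(axis=1, keepdims=True)

        chroms.append(
            ChromosomeGrid(
                name=cmap.name,
                is_x=cmap.is_x,
                n_states=k,
                cm=pos,
                bp=bp,
                bp_lo=bp_lo,
                bp_hi=bp_hi,
                names=names,
                is_marker=is_marker,
                probs=post,
                filtered=filtered,
                step_r=step_r,
            )
        )
    return ProbGrid(list(rec.samples), chroms, step, error_rate)


def sample_genotype_paths(cg: ChromosomeGrid, n_draws: int, rng) -> np.ndarray:
    """Joint genotype realizations (n_draws, n_samples, n_pos) drawn by
    forward-filter backward-sampling from the chain."""
    ns, npos, k = cg.filtered.shape
    trans = [_transition(r, k) for r in cg.step_r]
    out = np.empty((n_draws, ns, npos), dtype=np.int8)
    for d in range(n_draws):
        draw = np.empty((ns, npos), dtype=np.int8)
        p = cg.filtered[:, -1]
        u = rng.random(ns)
        draw[:, -1] = (p.cumsum(axis=1) < u[:, None]).sum(axis=1)
        for j in range(npos - 2, -1, -1):
            tcol = trans[j][:, draw[:, j + 1]].T  # (ns, k)
            p = cg.filtered[:, j] * tcol
            p /= p.sum(axis=1, keepdims=True)
            u = rng.random(ns)
            draw[:, j] = (p.cumsum(axis=1) < u[:, None]).sum(axis=1)
        out[d] = draw
    return out


# ---------------------------------------------------------------------------
# scans
# ---------------------------------------------------------------------------
def _dosage_columns(probs: np.ndarray, n_states: int):
    """Additive (and dominance) dosage columns from class probabilities."""
    if n_states == 2:
        return (probs[..., 1] - probs[..., 0])[..., None]
    add = probs[..., 2] - probs[..., 0]
    dom = probs[..., 1]
    return np.stack([add, dom], axis=-1)


def _indicator_columns(draws: np.ndarray, n_states: int):
    if n_states == 2:
        return (2.0 * draws - 1.0)[..., None]
    add = draws.astype(float) - 1.0
    dom = (draws == 1).astype(float)
    return np.stack([add, dom], axis=-1)


def _batched_rss(design: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Residual sums of squares of y on each (n, p) design in a batch.

    ``design`` is (n_pos, n, p) *including* the intercept column; uses
    pseudo-inverse-free normal equations with a ridge fallback for
    singular positions.
    """
    xtx = np.einsum("pni,pnj->pij", design, design)
    xty = np.einsum("pni,n->pi", design, y)
    yty = float(y @ y)
    p = design.shape[2]
    try:
        beta = np.linalg.solve(xtx, xty[..., None])[..., 0]
    except np.linalg.LinAlgError:
        beta = np.linalg.solve(xtx + 1e-10 * np.eye(p)[None], xty[..., None])[..., 0]
    rss = yty - np.einsum("pi,pi->p", beta, xty)
    return np.maximum(rss, 1e-300)


def _align_trait(grid: ProbGrid, trait) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(trait, pd.Series):
        y = trait.reindex(grid.samples).to_numpy(dtype=float)
    else:
        y = np.asarray(trait, dtype=float)
        if len(y) != grid.n_samples:
            raise ConfigError("trait length does not match grid samples")
    ok = np.isfinite(y)
    return y, ok


def scan_one(
    grid: ProbGrid,
    trait,
    method: str = "hk",
    n_draws: int = 64,
    seed: int = 0,
    covariates: np.ndarray | None = None,
) -> pd.DataFrame:
    """Single-QTL genome scan; LOD(position) = (n/2) log10(RSS0/RSS1).

    'hk' regresses the trait on expected additive/dominance dosages from
    the probability grid; 'imp' fits each of ``n_draws`` sampled genotype
    realizations and combines LODs as log10 of the mean of 10^LOD.
    Samples with a missing trait value are dropped; male-X positions use
    a one-degree-of-freedom hemizygous contrast.  ``covariates`` (n, k)
    enter both null and alternative models (used for conditional scans).
    """
    if method not in ("hk", "imp"):
        raise ConfigError(f"unknown scan method {method!r}")
    y, ok = _align_trait(grid, trait)
    y = y[ok]
    n = len(y)
    if n < 3 or np.var(y) == 0:
        raise ConfigError("trait must be non-constant with at least 3 observations")
    cov = None
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)[ok]
    base = np.ones((n, 1)) if cov is None else np.column_stack([np.ones(n), cov])
    rss0 = _batched_rss(base[None, :, :], y)[0]

    rng = stream(seed, "imp-scan")
    frames = []
    for cg in grid.chroms:
        npos = len(cg.cm)
        if method == "hk":
            dos = _dosage_columns(cg.probs[ok], cg.n_states)  # (n, npos, q)
            design = np.concatenate(
                [np.broadcast_to(base[:, None, :], (n, npos, base.shape[1])), dos], axis=2
            ).transpose(1, 0, 2)
            rss1 = _batched_rss(design, y)
            lod = (n / 2.0) * np.log10(rss0 / rss1)
        else:
            draws = sample_genotype_paths(cg, n_draws, rng)[:, ok, :]
            lods = np.empty((n_draws, npos))
            for d in range(n_draws):
                ind = _indicator_columns(draws[d], cg.n_states)  # (n, npos, q)
                design = np.concatenate(
                    [np.broadcast_to(base[:, None, :], (n, npos, base.shape[1])), ind], axis=2
                ).transpose(1, 0, 2)
                rss1 = _batched_rss(design, y)
                lods[d] = (n / 2.0) * np.log10(rss0 / rss1)
            # combine on the 10^LOD scale; subtract the max for stability
            mx = lods.max(axis=0)
            lod = mx + np.log10(np.mean(10.0 ** (lods - mx), axis=0))
        frames.append(
            pd.DataFrame(
                {
                    "name": cg.names,
                    "chrom": cg.name,
                    "pos_cm": cg.cm,
                    "bp_lo": cg.bp_lo,
                    "bp_hi": cg.bp_hi,
                    "is_x": cg.is_x,
                    "lod": np.maximum(lod, 0.0),
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    out.attrs["n"] = n
    out.attrs["method"] = method
    return out


# ---------------------------------------------------------------------------
# permutation thresholds
# ---------------------------------------------------------------------------
@dataclass
class Thresholds:
    alpha: float
    alpha_autosome: float
    alpha_x: float
    autosome: float
    x: float
    n_perm: int
    n_perm_x: int
    autosome_max: np.ndarray = field(repr=False, default=None)
    x_max: np.ndarray = field(repr=False, default=None)


def _orthonormal_bases(grid: ProbGrid, ok: np.ndarray, x_only: bool | None):
    """Per-position orthonormal bases of the centered dosage columns,
    stacked as one (total_cols, n) matrix with position offsets."""
    blocks, owners = [], []
    for cg in grid.chroms:
        if x_only is True and not cg.is_x:
            continue
        if x_only is False and cg.is_x:
            continue
        dos = _dosage_columns(cg.probs[ok], cg.n_states)  # (n, npos, q)
        dos = dos - dos.mean(axis=0, keepdims=True)
        n, npos, q = dos.shape
        qcols = np.zeros((npos, n, q))
        d1 = dos[:, :, 0].T  # (npos, n)
        nrm = np.linalg.norm(d1, axis=1, keepdims=True)
        good = nrm[:, 0] > 1e-12
        qcols[good, :, 0] = d1[good] / nrm[good]
        if q == 2:
            d2 = dos[:, :, 1].T
            proj = np.einsum("pn,pn->p", qcols[:, :, 0], d2)
            v = d2 - proj[:, None] * qcols[:, :, 0]
            nrm2 = np.linalg.norm(v, axis=1, keepdims=True)
            good2 = nrm2[:, 0] > 1e-12
            qcols[good2, :, 1] = v[good2] / nrm2[good2]
        blocks.append(qcols)
        owners.append(npos)
    return blocks


def _perm_max_lod(blocks, y_perm: np.ndarray, n: int) -> np.ndarray:
    """Genome-wide max LOD per permuted trait column."""
    tss = np.einsum("nb,nb->b", y_perm, y_perm)
    best = np.zeros(y_perm.shape[1])
    for qcols in blocks:
        npos, _, q = qcols.shape
        flat = qcols.transpose(0, 2, 1).reshape(npos * q, n)  # (npos*q, n)
        proj = flat @ y_perm  # (npos*q, B)
        ss = (proj**2).reshape(npos, q, -1).sum(axis=1)  # (npos, B)
        lod = (n / 2.0) * np.log10(tss[None, :] / np.maximum(tss[None, :] - ss, 1e-300))
        best = np.maximum(best, lod.max(axis=0))
    return best


def permutation_thresholds(
    grid: ProbGrid,
    trait,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> Thresholds:
    """Genome-wide LOD thresholds, X and autosomes estimated separately.

    The trait is permuted against the genotype rows; the genome-wide max
    LOD (hk scan) is recorded separately over autosomal and X positions.
    The overall alpha is split in proportion to genetic length,
    alpha_A = 1 - (1-alpha)^(L_A/L) and likewise for the X, and the X
    permutation count is scaled up by L/L_X to stabilize its more extreme
    quantile.  Thresholds are the (1 - alpha_A) and (1 - alpha_X)
    quantiles of the two max-LOD null distributions.
    """
    if n_perm < 100:
        raise ConfigError("use at least 100 permutations")
    y, ok = _align_trait(grid, trait)
    y = y[ok]
    n = len(y)
    yc = y - y.mean()

    la, lx = grid.genetic_lengths()
    total = la + lx
    if total > 0 and lx > 0:
        alpha_a = 1.0 - (1.0 - alpha) ** (la / total)
        alpha_x = 1.0 - (1.0 - alpha) ** (lx / total)
        n_perm_x = int(np.ceil(n_perm * total / lx))
    elif lx == 0:
        alpha_a, alpha_x, n_perm_x = alpha, alpha, 0
    else:
        alpha_a = alpha_x = alpha
        n_perm_x = n_perm

    rng = stream(seed, "perm")
    has_aut = any(not c.is_x for c in grid.chroms)
    has_x = any(c.is_x for c in grid.chroms)

    aut_max = x_max = None
    thr_a = thr_x = np.inf
    if has_aut:
        blocks = _orthonormal_bases(grid, ok, x_only=False)
        Y = np.empty((n, n_perm))
        for b in range(n_perm):
            Y[:, b] = rng.permutation(yc)
        aut_max = _perm_max_lod(blocks, Y, n)
        thr_a = float(np.quantile(aut_max, 1.0 - alpha_a)) if alpha_a > 0 else np.inf
    if has_x and n_perm_x > 0:
        blocks = _orthonormal_bases(grid, ok, x_only=True)
        x_max = np.empty(n_perm_x)
        chunk = 2000
        done = 0
        while done < n_perm_x:
            b = min(chunk, n_perm_x - done)
            Y = np.empty((n, b))
            for j in range(b):
                Y[:, j] = rng.permutation(yc)
            x_max[done : done + b] = _perm_max_lod(blocks, Y, n)
            done += b
        thr_x = float(np.quantile(x_max, 1.0 - alpha_x)) if alpha_x > 0 else np.inf
    return Thresholds(alpha, alpha_a, alpha_x, thr_a, thr_x, n_perm, n_perm_x, aut_max, x_max)


# ---------------------------------------------------------------------------
# peaks and support intervals
# ---------------------------------------------------------------------------
def significant_peaks(scan: pd.DataFrame, thr: Thresholds) -> pd.DataFrame:
    """One row per chromosome whose max LOD clears its threshold."""
    rows = []
    for chrom, sub in scan.groupby("chrom", sort=False):
        i = sub["lod"].idxmax()
        lim = thr.x if bool(sub["is_x"].iloc[0]) else thr.autosome
        if scan.loc[i, "lod"] >= lim:
            rows.append(scan.loc[i])
    return pd.DataFrame(rows).reset_index(drop=True) if rows else scan.iloc[:0].copy()


def lod_drop_interval(scan: pd.DataFrame, chrom: str, peak_cm: float | None = None, drop: float = 2.0) -> dict:
    """Support interval: widest contiguous run around the peak with
    LOD >= peak - drop, clipped at the chromosome ends; cM endpoints are
    mapped to bp by interpolation between flanking marker anchors."""
    sub = scan[scan["chrom"] == chrom].reset_index(drop=True)
    if sub.empty:
        raise ConfigError(f"no scan positions on chromosome {chrom}")
    if peak_cm is None:
        pi = int(sub["lod"].idxmax())
    else:
        pi = int((sub["pos_cm"] - peak_cm).abs().idxmin())
    lim = sub["lod"].iloc[pi] - drop
    lo = pi
    while lo > 0 and sub["lod"].iloc[lo - 1] >= lim:
        lo -= 1
    hi = pi
    while hi < len(sub) - 1 and sub["lod"].iloc[hi + 1] >= lim:
        hi += 1
    return {
        "chrom": chrom,
        "peak_cm": float(sub["pos_cm"].iloc[pi]),
        "peak_lod": float(sub["lod"].iloc[pi]),
        "cm_lo": float(sub["pos_cm"].iloc[lo]),
        "cm_hi": float(sub["pos_cm"].iloc[hi]),
        "bp_lo": float(sub["bp_lo"].iloc[lo]),
        "bp_hi": float(sub["bp_hi"].iloc[hi]),
    }


# ---------------------------------------------------------------------------
# multi-QTL model
# ---------------------------------------------------------------------------
@dataclass
class QTLModelFit:
    table: pd.DataFrame
    total_var_explained: float
    interactions: pd.DataFrame
    conditional_scan: pd.DataFrame | None = None


def _peak_design(grid: ProbGrid, peaks, ok):
    """Dosage columns at each peak + bookkeeping of column ownership."""
    cols, owner, kinds = [], [], []
    for qi, (chrom, cm) in enumerate(peaks):
        cg = grid.chrom(chrom)
        j = int(np.argmin(np.abs(cg.cm - cm)))
        dos = _dosage_columns(cg.probs[ok, j][:, None, :], cg.n_states)[:, 0, :]
        for c in range(dos.shape[1]):
            cols.append(dos[:, c])
            owner.append(qi)
            kinds.append("additive" if c == 0 else "dominance")
    return np.column_stack(cols), np.array(owner), np.array(kinds)


def fit_multi_qtl(
    grid: ProbGrid,
    peaks,
    trait,
    interactions: bool = True,
    conditional: bool = True,
    seed: int = 0,
) -> QTLModelFit:
    """Joint fit of all detected QTL with effect estimates.

    Regresses the trait on additive + dominance dosages at every peak
    (expected dosages from the probability grid, equivalent to averaging
    imputation draws).  Reports per-QTL drop-one LOD and variance
    explained, additive effects on the replace-T7-with-SS = +a convention
    and dominance deviations, pairwise interaction F-tests, and a
    conditional scan for further QTL with the fitted peaks as covariates.
    """
    if not peaks:
        raise ConfigError("need at least one peak to fit")
    y, ok = _align_trait(grid, trait)
    y = y[ok]
    n = len(y)
    X, owner, kinds = _peak_design(grid, peaks, ok)
    if np.linalg.matrix_rank(np.column_stack([np.ones(n), X])) < X.shape[1] + 1:
        warnings.warn("collinear peak dosages; effects estimated by least norm")
    full = np.column_stack([np.ones(n), X])
    beta, _, _, _ = np.linalg.lstsq(full, y, rcond=None)
    resid = y - full @ beta
    rss_full = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    total_ve = 100.0 * (1.0 - rss_full / tss)

    rows = []
    for qi, (chrom, cm) in enumerate(peaks):
        keep = owner != qi
        red = np.column_stack([np.ones(n), X[:, keep]])
        br, _, _, _ = np.linalg.lstsq(red, y, rcond=None)
        rr = y - red @ br
        rss_red = float(rr @ rr)
        lod = (n / 2.0) * np.log10(rss_red / rss_full)
        mine = np.flatnonzero(owner == qi)
        add = float(beta[1 + mine[0]])
        dom = float(beta[1 + mine[1]]) if len(mine) > 1 else np.nan
        rows.append(
            {
                "chrom": chrom,
                "pos_cm": cm,
                "lod": lod,
                "additive": add,
                "dominance": dom,
                "var_explained": 100.0 * (rss_red - rss_full) / tss,
            }
        )
    table = pd.DataFrame(rows)

    inter_rows = []
    if interactions and len(peaks) > 1:
        for i in range(len(peaks)):
            for j in range(i + 1, len(peaks)):
                ci = np.flatnonzero(owner == i)
                cj = np.flatnonzero(owner == j)
                prod = np.column_stack([X[:, a] * X[:, b] for a in ci for b in cj])
                aug = np.column_stack([full, prod])
                ba, _, _, _ = np.linalg.lstsq(aug, y, rcond=None)
                ra = y - aug @ ba
                rss_aug = float(ra @ ra)
                df1 = prod.shape[1]
                df2 = n - aug.shape[1]
                if rss_aug <= 0 or df2 <= 0:
                    f = np.nan
                    p = np.nan
                else:
                    f = ((rss_full - rss_aug) / df1) / (rss_aug / df2)
                    p = float(stats.f.sf(f, df1, df2))
                inter_rows.append(
                    {"q1": i, "q2": j, "F": float(f) if np.isfinite(f) else np.nan, "p": p}
                )
    inter = pd.DataFrame(inter_rows)

    cond = None
    if conditional:
        full_cov = np.full((grid.n_samples, X.shape[1]), np.nan)
        full_cov[ok] = X
        cond = scan_one(grid, trait, method="hk", covariates=full_cov, seed=seed)
    return QTLModelFit(table, total_ve, inter, cond)


# ---------------------------------------------------------------------------
# chromosome 4 regression
# ---------------------------------------------------------------------------
def regress_chr4(consensus: pd.DataFrame, pheno: pd.DataFrame, traits=None) -> pd.DataFrame:
    """Ordinary linear regressions of each trait on the consensus
    chromosome-4 genotype dosage; monomorphic consensus yields NA."""
    traits = traits or [c for c in pheno.columns if c not in ("sample_id", "group", "side")]
    merged = consensus.merge(pheno, left_on="sample", right_on="sample_id", how="inner")
    merged = merged[merged["consensus"] != NA]
    rows = []
    for tr in traits:
        sub = merged[["consensus", tr]].dropna()
        dose = sub["consensus"].to_numpy(dtype=float)
        if len(sub) < 3 or len(np.unique(dose)) < 2:
            rows.append({"trait": tr, "slope": np.nan, "p": np.nan, "n": len(sub)})
            continue
        res = stats.linregress(dose, sub[tr].to_numpy(dtype=float))
        rows.append({"trait": tr, "slope": res.slope, "p": res.pvalue, "n": len(sub)})
    return pd.DataFrame(rows)
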