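"""Ground-truthed advanced-intercross simulator.

Generates F_t male cohorts from two fully homozygous parental strains
("SS" and "T7"), with recombination restricted to the female germline
(as in flies), X/autosome inheritance, and a non-recombining chromosome 4.
Downstream stages are fed either truth genotypes directly, low-coverage
SNP read counts, or synthetic bilateral lobe outlines carrying planted
QTL effects.

Crossovers follow a Poisson (no-interference) process on the female
genetic map, consistent with the Haldane map function used by the
mapping module; within a chromosome the cM<->bp relation comes from the
genome config (linear by default).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ConfigError, CoverageModel, CrossDesign, GenomeConfig, QTLSpec
from .rng import stream

SS, T7 = 1, 0  # allele codes; genotype = sum of allele codes (0=T7/T7 .. 2=SS/SS)
STRAIN_ALLELE = {"SS": SS, "T7": T7}


# ---------------------------------------------------------------------------
# haplotypes and individuals
# ---------------------------------------------------------------------------
@dataclass
class Haplotype:
    """Mosaic of parental-origin segments tiling [0, L) on one chromosome.

    ``ends`` holds the exclusive bp end of each segment (last entry = L);
    ``parents`` the allele code (0=T7, 1=SS) of each segment.  Adjacent
    segments always carry different parents after merging.
    """

    chrom: str
    ends: np.ndarray
    parents: np.ndarray

    @property
    def length(self) -> int:
        return int(self.ends[-1])

    @property
    def n_crossovers(self) -> int:
        return len(self.ends) - 1

    def allele_at(self, pos):
        """Parental allele at bp position(s) (0-based, < L)."""
        idx = np.searchsorted(self.ends, np.asarray(pos), side="right")
        return self.parents[idx]

    def validate(self):
        if len(self.ends) != len(self.parents) or len(self.ends) == 0:
            raise ValueError("malformed haplotype")
        if np.any(np.diff(self.ends) <= 0) or self.ends[0] <= 0:
            raise ValueError("segment ends must be strictly increasing and positive")
        if np.any(self.parents[1:] == self.parents[:-1]):
            raise ValueError("adjacent segments share a parent (unmerged)")


def constant_haplotype(chrom: str, length: int, strain: str) -> Haplotype:
    return Haplotype(
        chrom,
        np.array([length], dtype=np.int64),
        np.array([STRAIN_ALLELE[strain]], dtype=np.int8),
    )


@dataclass
class Individual:
    id: str
    sex: str  # 'M' or 'F'
    generation: int
    haplotypes: dict = field(default_factory=dict)  # chrom -> tuple of Haplotype

    def genotype_at(self, chrom: str, pos):
        """Genotype code 0/1/2 (T7/T7, het, SS/SS); male X is scored
        hemizygously as 0 or 2."""
        haps = self.haplotypes[chrom]
        g = sum(int(h.allele_at(pos)) for h in haps)
        if len(haps) == 1:  # male X
            g *= 2
        return g


def founder(strain: str, config: GenomeConfig, sex: str, uid: str | None = None) -> Individual:
    """A fully homozygous parental-strain individual."""
    if sex not in ("M", "F"):
        raise ConfigError(f"invalid sex {sex!r}")
    haps = {}
    for c in config.chromosomes:
        n = 1 if (c.is_x and sex == "M") else 2
        haps[c.name] = tuple(constant_haplotype(c.name, c.length_bp, strain) for _ in range(n))
    return Individual(uid or f"{strain}_{sex}", sex, 0, haps)


# ---------------------------------------------------------------------------
# meiosis
# ---------------------------------------------------------------------------
def _pieces(h: Haplotype, lo: int, hi: int):
    """Segments of h restricted to [lo, hi) as (ends, parents) lists."""
    i = int(np.searchsorted(h.ends, lo, side="right"))
    ends, parents = [], []
    while i < len(h.ends):
        e = int(h.ends[i])
        ends.append(min(e, hi))
        parents.append(int(h.parents[i]))
        if e >= hi:
            break
        i += 1
    return ends, parents


def _recombine(h1: Haplotype, h2: Haplotype, xo_bp, first: int) -> Haplotype:
    """Join alternating stretches of h1/h2 at the crossover positions."""
    L = h1.length
    haps = (h1, h2)
    cur = first
    ends, parents = [], []
    prev = 0
    bounds = sorted(int(x) for x in xo_bp if 0 < int(x) < L)
    for b in bounds + [L]:
        if b > prev:
            e, p = _pieces(haps[cur], prev, b)
            # merge with running tail
            for ei, pi in zip(e, p):
                if parents and parents[-1] == pi:
                    ends[-1] = ei
                else:
                    ends.append(ei)
                    parents.append(pi)
            prev = b
        cur ^= 1
    return Haplotype(h1.chrom, np.array(ends, dtype=np.int64), np.array(parents, dtype=np.int8))


def simulate_gamete(
    parent: Individual, config: GenomeConfig, parent_sex: str, rng: np.random.Generator
) -> dict:
    """One gamete: chrom -> Haplotype.

    Males never recombine: each chromosome is transmitted verbatim (one of
    the two homologs, chosen independently per chromosome); a male's X
    entry is his single X, i.e. the X-bearing sperm — whether it is used
    depends on offspring sex.  Female crossover counts are
    Poisson(map length / 100) with breakpoints uniform on the genetic map;
    non-recombining chromosomes (e.g. 4) never cross over.
    """
    if parent_sex not in ("M", "F"):
        raise ConfigError(f"invalid parent sex {parent_sex!r}")
    gam = {}
    for c in config.chromosomes:
        haps = parent.haplotypes[c.name]
        if parent_sex == "M":
            gam[c.name] = haps[0] if len(haps) == 1 else haps[rng.integers(2)]
            continue
        h1, h2 = haps
        if c.recombining and c.female_cm > 0:
            k = rng.poisson(c.female_cm / 100.0)
        else:
            k = 0
        first = int(rng.integers(2))
        if k == 0:
            gam[c.name] = (h1, h2)[first]
        else:
            xo_cm = rng.uniform(0.0, c.female_cm, size=k)
            xo_bp = np.atleast_1d(config.bp_at(c.name, xo_cm))
            gam[c.name] = _recombine(h1, h2, xo_bp, first)
    return gam


def _mate(
    mother: Individual,
    father: Individual,
    config: GenomeConfig,
    child_sex: str,
    uid: str,
    gen: int,
    rng: np.random.Generator,
) -> Individual:
    mg = simulate_gamete(mother, config, "F", rng)
    fg = simulate_gamete(father, config, "M", rng)
    xname = config.x_name
    haps = {}
    for c in config.chromosomes:
        if c.name == xname:
            haps[c.name] = (mg[c.name],) if child_sex == "M" else (mg[c.name], fg[c.name])
        else:
            haps[c.name] = (mg[c.name], fg[c.name])
    return Individual(uid, child_sex, gen, haps)


# ---------------------------------------------------------------------------
# cohort breeding
# ---------------------------------------------------------------------------
@dataclass
class Cohort:
    individuals: list  # sampled F_t males
    parents: dict  # strain -> founder Individual (male, as dissected flies are)
    config: GenomeConfig
    design: CrossDesign
    seed: int

    @property
    def sample_ids(self):
        return [ind.id for ind in self.individuals]


def simulate_ail_cohort(
    config: GenomeConfig,
    design: CrossDesign,
    n_males: int | None = None,
    seed: int = 0,
) -> Cohort:
    """Breed an F_t advanced intercross and sample male recombinants.

    F1 comes from the two reciprocal parental crosses (SS father x T7
    mother and the reverse); F2 onwards is random mating within a finite
    population of ``design.population_size``; the final generation
    consists of ``n_males`` males.  Deterministic under ``seed``.
    """
    n_males = design.n_males if n_males is None else int(n_males)
    if n_males < 1:
        raise ConfigError("need at least one sampled male")
    rng = stream(seed, "cohort")
    t = design.generations
    N = design.population_size

    ss_m = founder("SS", config, "M")
    ss_f = founder("SS", config, "F")
    t7_m = founder("T7", config, "M")
    t7_f = founder("T7", config, "F")
    crosses = [(t7_f, ss_m)]  # (mother, father): cross A = SS male x T7 female
    if design.reciprocal_f1:
        crosses.append((ss_f, t7_m))

    def make_generation(mothers, fathers, gen, sexes):
        kids = []
        mi = rng.integers(len(mothers), size=len(sexes))
        fi = rng.integers(len(fathers), size=len(sexes))
        for j, sex in enumerate(sexes):
            kids.append(
                _mate(mothers[mi[j]], fathers[fi[j]], config, sex, f"F{gen}_{j}", gen, rng)
            )
        return kids

    def balanced_sexes(n):
        sexes = np.array(["M", "F"] * (n // 2 + 1))[:n]
        rng.shuffle(sexes)
        return sexes

    # F1: both reciprocal crosses contribute equally
    f1 = []
    sexes = balanced_sexes(N)
    for j, sex in enumerate(sexes):
        mother, father = crosses[j % len(crosses)]
        f1.append(_mate(mother, father, config, sex, f"F1_{j}", 1, rng))
    current = f1

    for gen in range(2, t):
        mothers = [i for i in current if i.sex == "F"]
        fathers = [i for i in current if i.sex == "M"]
        current = make_generation(mothers, fathers, gen, balanced_sexes(N))

    mothers = [i for i in current if i.sex == "F"]
    fathers = [i for i in current if i.sex == "M"]
    males = make_generation(mothers, fathers, t, ["M"] * n_males)
    for j, ind in enumerate(males):
        ind.id = f"rec_{j:04d}"
    return Cohort(males, {"SS": ss_m, "T7": t7_m}, config, design, seed)


def truth_genotypes(cohort: Cohort, markers: pd.DataFrame) -> np.ndarray:
    """Truth genotype codes (0/1/2; male X hemizygous 0/2) at marker
    positions.  ``markers`` needs columns chrom and pos (0-based bp)."""
    n, m = len(cohort.individuals), len(markers)
    out = np.empty((n, m), dtype=np.int8)
    for chrom, grp in markers.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        cols = grp.index.to_numpy()
        for i, ind in enumerate(cohort.individuals):
            haps = ind.haplotypes[chrom]
            g = np.zeros(len(pos), dtype=np.int8)
            for h in haps:
                g += h.allele_at(pos)
            if len(haps) == 1:
                g *= 2
            out[i, cols] = g
    return out


# ---------------------------------------------------------------------------
# SNP panel and read counts
# ---------------------------------------------------------------------------
BASES = np.array(list("ACGT"))


def snp_panel(config: GenomeConfig, seed: int = 0, density: float | None = None) -> pd.DataFrame:
    """Random biallelic SNP positions between the strains, with distinct
    parental bases, at ``density`` SNPs per bp (config default)."""
    rng = stream(seed, "panel")
    density = config.snp_density if density is None else density
    rows = []
    for c in config.chromosomes:
        n = max(2, int(round(c.length_bp * density)))
        pos = np.sort(rng.choice(c.length_bp, size=n, replace=False))
        b1 = rng.integers(0, 4, size=n)
        b2 = (b1 + rng.integers(1, 4, size=n)) % 4
        for p, t7b, ssb in zip(pos, b1, b2):
            rows.append({"chrom": c.name, "pos": int(p), "t7_base": int(t7b), "ss_base": int(ssb)})
    df = pd.DataFrame(rows)
    df["is_x"] = df["chrom"] == config.x_name
    return df


def _msg_covered(panel: pd.DataFrame, model: CoverageModel, rng) -> np.ndarray:
    """Sparse clustered coverage mask shared by all MSG samples: the genome
    is tiled with blocks of ``msg_cluster_bp`` and a random subset of
    blocks (the 'restriction-site clusters') carries all the reads."""
    block = panel["pos"].to_numpy() // model.msg_cluster_bp
    key = pd.factorize(panel["chrom"].astype(str) + ":" + block.astype(str))[0]
    n_blocks = key.max() + 1
    keep = rng.random(n_blocks) < model.msg_covered_fraction
    return keep[key]


def simulate_snp_reads(
    cohort: Cohort,
    panel: pd.DataFrame,
    model: CoverageModel,
    seed: int = 0,
    regimes: dict | None = None,
    include_parents: bool = True,
):
    """Per-sample x per-SNP base read counts under the coverage model.

    Each read supports the individual's true allele with probability
    1 - error_rate and the other parental allele otherwise; SS+T7 counts
    therefore sum to the drawn depth at every covered SNP.  ``regimes``
    optionally maps sample id -> CoverageModel to mix WGS- and MSG-style
    samples in one table (as when half a panel is genotyped each way).
    Returns a genotyping.SNPReadTable.
    """
    from .genotyping import SNPReadTable  # local import; genotyping is downstream

    rng = stream(seed, "reads")
    inds = list(cohort.individuals)
    roles = ["rec"] * len(inds)
    if include_parents:
        inds = [cohort.parents["SS"], cohort.parents["T7"]] + inds
        roles = ["SS", "T7"] + roles
    samples = [i.id for i in inds]
    sex = np.array([i.sex for i in inds])
    n, m = len(inds), len(panel)

    truth = np.empty((n, m), dtype=np.int8)
    mk = panel[["chrom", "pos"]].reset_index(drop=True)
    for chrom, grp in mk.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        cols = grp.index.to_numpy()
        for i, ind in enumerate(inds):
            haps = ind.haplotypes[chrom]
            g = np.zeros(len(pos), dtype=np.int8)
            for h in haps:
                g += h.allele_at(pos)
            if len(haps) == 1:
                g *= 2
            truth[i, cols] = g

    is_x = panel["is_x"].to_numpy()
    counts = np.zeros((n, m, 4), dtype=np.int32)
    msg_masks: dict[int, np.ndarray] = {}

    for i, sid in enumerate(samples):
        mdl = (regimes or {}).get(sid, model)
        is_parent = roles[i] != "rec"
        mean = np.full(m, mdl.parent_depth if is_parent else mdl.mean_depth)
        if inds[i].sex == "M":
            mean[is_x] *= mdl.x_male_depth_factor
        if mdl.regime == "MSG" and not is_parent:
            key = id(mdl)
            if key not in msg_masks:
                msg_masks[key] = _msg_covered(panel, mdl, stream(seed, "msg-sites", key))
            mean[~msg_masks[key]] = 0.0
        # per-SNP depth with optional gamma-Poisson overdispersion
        if mdl.overdispersion <= 0:
            depth = rng.poisson(mean)
        else:
            theta = mdl.overdispersion
            lam = rng.gamma(theta, mean / theta)
            depth = rng.poisson(lam)
        p_ss = truth[i] / 2.0
        p_ss = p_ss * (1 - mdl.error_rate) + (1 - p_ss) * mdl.error_rate
        n_ss = rng.binomial(depth, p_ss)
        n_t7 = depth - n_ss
        for b in range(4):
            sel = panel["ss_base"].to_numpy() == b
            counts[i, sel, b] += n_ss[sel].astype(np.int32)
            sel = panel["t7_base"].to_numpy() == b
            counts[i, sel, b] += n_t7[sel].astype(np.int32)

    return SNPReadTable(
        samples=samples,
        roles=np.array(roles),
        sex=sex,
        snps=panel.reset_index(drop=True),
        counts=counts,
    )


# ---------------------------------------------------------------------------
# bilateral lobe outlines with planted QTL effects
# ---------------------------------------------------------------------------
def base_lobe_outline(n_arc: int = 120, n_base: int = 30, width: float = 0.05, height: float = 0.06):
    """Smooth asymmetric lobe-like closed polygon above a flat baseline.

    Units are mm (a fly posterior lobe is ~0.05 mm across).  Returns the
    polygon (counterclockwise, not closed) and the indices of the two
    baseline endpoints.
    """
    th = np.linspace(0.0, np.pi, n_arc)
    x = (width / 2) * np.cos(th)
    y = height * np.sin(th) * (1 + 0.35 * np.sin(th) * np.cos(th))
    xb = np.linspace(-width / 2, width / 2, n_base + 2)[1:-1]
    coords = np.concatenate(
        [np.column_stack([x, y]), np.column_stack([xb, np.zeros_like(xb)])]
    )
    return coords, (0, n_arc - 1)


def _loading_vectors(n_harmonics: int = 25):
    """Two orthonormal deformation directions in coefficient space: a
    width-like stretch and a size-like dilation, derived from the base
    shape so the planted axes are geometrically meaningful."""
    from .morphometrics import efa_coefficients

    coords, _ = base_lobe_outline()
    base = efa_coefficients(coords, n_harmonics).flat_coefficients()
    wide = coords * np.array([1.1, 1.0])
    big = coords * 1.1
    l0 = efa_coefficients(wide, n_harmonics).flat_coefficients() - base
    l1 = efa_coefficients(big, n_harmonics).flat_coefficients() - base
    l0 /= np.linalg.norm(l0)
    l1 -= (l1 @ l0) * l0
    l1 /= np.linalg.norm(l1)
    return base, l0, l1


def genetic_values(individuals, qtl_spec: QTLSpec, config: GenomeConfig) -> np.ndarray:
    """Planted genetic value per individual per trait axis:
    sum over loci of a*x + d*z with x in {-1,0,+1} for {T7/T7, het, SS/SS}
    and z=1 for heterozygotes; hemizygous male-X loci contribute a*x with
    x in {-1,+1} and no dominance term."""
    qtl_spec.validate_positions(config)
    n_axes = qtl_spec.n_axes
    g = np.zeros((len(individuals), n_axes))
    for q in qtl_spec.qtl:
        bp = int(config.bp_at(q.chrom, q.pos_cm))
        for i, ind in enumerate(individuals):
            code = ind.genotype_at(q.chrom, bp)
            x = code - 1
            hemi = len(ind.haplotypes[q.chrom]) == 1
            z = 1.0 if (code == 1 and not hemi) else 0.0
            g[i, q.trait_axis] += q.additive * x + q.dominance * z
    return g


def simulate_lobe_outlines(
    cohort: Cohort,
    qtl_spec: QTLSpec,
    seed: int = 0,
    n_points: int = 150,
    p_both_sides: float = 0.58,
    n_parent_ss: int = 8,
    n_parent_t7: int = 21,
):
    """Left/right raw lobe outlines per individual plus a truth table.

    The latent shape value (genetic value + environmental deviation, with
    the left/right environmental deviations correlated so the total
    bilateral correlation approximates ``bilateral_rho``) displaces the
    base outline along fixed Fourier-coefficient loadings; each raw
    outline is then randomly rotated/translated, and right-side lobes are
    mirrored with the handedness flag set, so the standardization step is
    genuinely exercised.  Parental-strain males are included so the shape
    PCA can be oriented against the parents.
    """
    from .morphometrics import RawOutline, efa_reconstruct, EFADescriptor

    rng = stream(seed, "lobes")
    config = cohort.config
    n_harm = 25
    base, l0, l1 = _loading_vectors(n_harm)

    # reconstruct base once to locate baseline endpoints in the resampled outline
    base_desc = EFADescriptor.from_flat(base, period=1.0)
    base_pts = efa_reconstruct(base_desc, n_points)
    raw_base, (i1, i2) = base_lobe_outline()
    centered = raw_base - raw_base.mean(axis=0)
    b_idx = (
        int(np.argmin(np.linalg.norm(base_pts - centered[i1], axis=1))),
        int(np.argmin(np.linalg.norm(base_pts - centered[i2], axis=1))),
    )

    groups = (
        [("SS", cohort.parents["SS"])] * n_parent_ss
        + [("T7", cohort.parents["T7"])] * n_parent_t7
        + [("rec", ind) for ind in cohort.individuals]
    )
    inds = [ind for _, ind in groups]
    g = genetic_values(inds, qtl_spec, config)
    n_axes = g.shape[1]
    noise = np.array(qtl_spec.noise_sd[:n_axes])
    if len(noise) < n_axes:
        noise = np.pad(noise, (0, n_axes - len(noise)), constant_values=noise[-1])

    # environmental correlation needed to hit the target total bilateral
    # correlation, given the realized genetic variance on each axis
    rho = qtl_spec.bilateral_rho
    rec = np.array([grp == "rec" for grp, _ in groups])
    rho_e = np.zeros(n_axes)
    for a in range(n_axes):
        vg = np.var(g[rec, a]) if rec.sum() > 1 else 0.0
        ve = noise[a] ** 2
        rho_e[a] = np.clip((rho * (vg + ve) - vg) / ve, -1.0, 1.0) if ve > 0 else 0.0

    outlines, truth_rows = [], []
    for i, (grp, ind) in enumerate(groups):
        uid = ind.id if grp == "rec" else f"{grp}_{i}"
        both = rng.random() < p_both_sides
        sides = ["L", "R"] if both else [rng.choice(["L", "R"])]
        # correlated environmental deviations per axis
        e = np.zeros((2, n_axes))
        for a in range(n_axes):
            if noise[a] > 0:
                cov = noise[a] ** 2 * np.array([[1.0, rho_e[a]], [rho_e[a], 1.0]])
                e[:, a] = rng.multivariate_normal([0.0, 0.0], cov, method="cholesky")
        for side in sides:
            k = 0 if side == "L" else 1
            latent = g[i] + e[k]
            coeffs = base + latent[0] * l0
            if n_axes > 1:
                coeffs = coeffs + latent[1] * l1
            pts = efa_reconstruct(EFADescriptor.from_flat(coeffs, period=1.0), n_points)
            flip = side == "R"
            if flip:
                pts = pts * np.array([-1.0, 1.0])
            ang = rng.uniform(-np.pi, np.pi)
            R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
            pts = pts @ R.T + rng.uniform(-0.5, 0.5, size=2)
            outlines.append(
                RawOutline(
                    coords=pts,
                    flip=flip,
                    baseline=b_idx,
                    sample_id=uid,
                    side=side,
                    group=grp,
                )
            )
            row = {"sample_id": uid, "group": grp, "side": side}
            for a in range(n_axes):
                row[f"genetic{a}"] = g[i, a]
                row[f"latent{a}"] = latent[a]
            truth_rows.append(row)
    return outlines, pd.DataFrame(truth_rows)
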