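"""Cross, genome, coverage and caller configuration.

The default genome is the five major *D. melanogaster* chromosome arms
(X, 2L, 2R, 3L, 3R) plus the tiny non-recombining fourth chromosome, with
release-6 physical lengths and a 276 cM standard female genetic map.
Recombination in flies is confined to the female germline, so all map
lengths here are female-meiosis map lengths; males transmit chromosomes
intact.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd


class ConfigError(ValueError):
    """Raised for invalid cross/genome/caller configuration."""


@dataclass(frozen=True)
class Chromosome:
    name: str
    length_bp: int
    female_cm: float
    is_x: bool = False
    recombining: bool = True


@dataclass
class GenomeConfig:
    """Physical + genetic layout of the genome.

    ``map_anchors`` optionally carries per-chromosome piecewise-linear
    (bp, cM) anchor arrays; without anchors the cM<->bp relation is linear
    (uniform recombination density along the arm).
    """

    chromosomes: list
    snp_density: float = 2e-4  # SNPs per bp between the two parental strains
    window_size: int = 250_000
    map_anchors: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.chromosomes:
            raise ConfigError("genome needs at least one chromosome")
        n_x = sum(c.is_x for c in self.chromosomes)
        if n_x != 1:
            raise ConfigError(f"exactly one X chromosome required, got {n_x}")
        for c in self.chromosomes:
            if c.length_bp <= 0:
                raise ConfigError(f"chromosome {c.name} has non-positive length")
            if c.female_cm < 0:
                raise ConfigError(f"chromosome {c.name} has negative map length")
            if c.name == "4" and c.recombining:
                raise ConfigError("chromosome 4 must be non-recombining")
        if self.window_size <= 0:
            raise ConfigError("window size must be positive")

    # -- lookups ---------------------------------------------------------
    def chrom(self, name: str) -> Chromosome:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise ConfigError(f"unknown chromosome {name!r}")

    @property
    def names(self):
        return [c.name for c in self.chromosomes]

    @property
    def x_name(self) -> str:
        return next(c.name for c in self.chromosomes if c.is_x)

    def total_female_cm(self, recombining_only: bool = True) -> float:
        return float(
            sum(c.female_cm for c in self.chromosomes if c.recombining or not recombining_only)
        )

    # -- cM <-> bp -------------------------------------------------------
    def cm_at(self, name: str, bp):
        c = self.chrom(name)
        bp = np.asarray(bp, dtype=float)
        if name in self.map_anchors:
            abp, acm = self.map_anchors[name]
            out = np.interp(bp, abp, acm)
        else:
            out = c.female_cm * bp / c.length_bp
        return float(out) if out.ndim == 0 else out

    def bp_at(self, name: str, cm):
        c = self.chrom(name)
        cm = np.asarray(cm, dtype=float)
        if name in self.map_anchors:
            abp, acm = self.map_anchors[name]
            out = np.interp(cm, acm, abp)
        elif c.female_cm == 0:
            out = np.zeros_like(cm)
        else:
            out = c.length_bp * cm / c.female_cm
        out = np.clip(out, 0, c.length_bp - 1)
        return float(out) if out.ndim == 0 else out

    # -- windows ---------------------------------------------------------
    def windows(self) -> pd.DataFrame:
        """Non-overlapping genotyping windows tiling every chromosome.

        Coordinates are 0-based half-open [k*w, (k+1)*w); a 1-based SNP
        position p falls in window (p-1)//w.  The last window of each arm
        is truncated at the chromosome end.
        """
        rows = []
        for c in self.chromosomes:
            n = int(np.ceil(c.length_bp / self.window_size))
            for k in range(n):
                start = k * self.window_size
                end = min((k + 1) * self.window_size, c.length_bp)
                rows.append(
                    {
                        "name": f"Chr{c.name}.{k}",
                        "chrom": c.name,
                        "index": k,
                        "start": start,
                        "end": end,
                        "mid": (start + end) // 2,
                        "is_x": c.is_x,
                    }
                )
        return pd.DataFrame(rows)


def default_genome(**kw) -> GenomeConfig:
    """Major-arm D. melanogaster genome, release-6 lengths, 276 cM map."""
    chroms = [
        Chromosome("X", 23_542_271, 66.0, is_x=True),
        Chromosome("2L", 23_513_712, 55.0),
        Chromosome("2R", 25_286_936, 52.0),
        Chromosome("3L", 28_110_227, 46.0),
        Chromosome("3R", 32_079_331, 57.0),
        Chromosome("4", 1_348_131, 0.0, recombining=False),
    ]
    return GenomeConfig(chromosomes=chroms, **kw)


@dataclass
class CrossDesign:
    """Advanced-intercross breeding design.

    ``generations`` is t of F_t; the sampled cohort is the F_t generation.
    Because only females recombine, the effective number of recombining
    meioses per lineage is s = t/2, and the autosomal map expands by s/2.
    """

    generations: int = 13
    population_size: int = 300
    n_males: int = 192
    reciprocal_f1: bool = True

    def __post_init__(self):
        if self.generations < 2:
            raise ConfigError("an intercross needs at least 2 generations")
        if self.population_size < 2:
            raise ConfigError("population size must be at least 2")
        if self.n_males < 1:
            raise ConfigError("need at least one sampled male")

    @property
    def s(self) -> float:
        return self.generations / 2.0


@dataclass
class CoverageModel:
    """Sequencing-depth model for genotyping-by-sequencing read counts.

    regime 'WGS' covers every SNP; 'MSG' (reduced representation) restricts
    coverage to a sparse, spatially clustered subset of SNPs, emulating
    restriction-site-anchored reads.  ``overdispersion`` is the negative
    binomial shape (0 = pure Poisson).  Male X depth is halved by default
    (hemizygous dosage).  Parental strain samples are sequenced at
    ``parent_depth`` (uniform coverage), reflecting the deeper sequencing
    a two-strain panel gives its parents.
    """

    regime: str = "WGS"
    mean_depth: float = 5.0
    parent_depth: float = 10.0
    overdispersion: float = 0.0
    error_rate: float = 0.005
    x_male_depth_factor: float = 0.5
    msg_covered_fraction: float = 0.4
    msg_cluster_bp: int = 50_000

    def __post_init__(self):
        if self.regime not in ("WGS", "MSG"):
            raise ConfigError(f"unknown coverage regime {self.regime!r}")
        if self.mean_depth < 0:
            raise ConfigError("mean depth must be >= 0")
        if not (0 <= self.error_rate < 0.5):
            raise ConfigError("error rate must be in [0, 0.5)")
        if not (0 < self.msg_covered_fraction <= 1):
            raise ConfigError("MSG covered fraction must be in (0, 1]")


@dataclass(frozen=True)
class QTLEffect:
    """One planted locus: additive effect a (replacing a T7 allele with an
    SS allele adds +a to the trait) and dominance deviation d of the
    heterozygote.  Hemizygous male-X loci have no heterozygote, so d is
    ignored on the X."""

    chrom: str
    pos_cm: float
    additive: float
    dominance: float = 0.0
    trait_axis: int = 0


@dataclass
class QTLSpec:
    qtl: list
    noise_sd: tuple = (2.17e-3, 1.16e-3)
    bilateral_rho: float = 0.75

    def __post_init__(self):
        if abs(self.bilateral_rho) > 1:
            raise ConfigError("|bilateral correlation| must be <= 1")
        if np.isscalar(self.noise_sd):
            self.noise_sd = (float(self.noise_sd),)
        for q in self.qtl:
            if not np.isfinite([q.additive, q.dominance]).all():
                raise ConfigError("QTL effects must be finite")

    @property
    def n_axes(self) -> int:
        axes = [q.trait_axis for q in self.qtl] + [len(self.noise_sd) - 1, 0]
        return max(axes) + 1

    def validate_positions(self, genome: GenomeConfig):
        for q in self.qtl:
            c = genome.chrom(q.chrom)
            if not (0 <= q.pos_cm <= c.female_cm):
                raise ConfigError(
                    f"QTL position {q.pos_cm} cM outside {q.chrom} map (0-{c.female_cm})"
                )


def default_qtl_spec() -> QTLSpec:
    """Six-locus architecture mimicking a moderately polygenic shape trait.

    Trait axis 0 carries four loci of mixed sign, one hemizygous on the X
    and one overdominant; axis 1 carries two loci on one arm, one of them
    overdominant.  Effects are on the scale of EFA-PC scores in mm units
    (a few 1e-4 to 1e-3); the residual SDs put the per-locus variance
    fractions between ~2% and ~14% of each axis.
    """
    qtl = [
        QTLEffect("X", 46.2, 3.4e-4, 0.0, trait_axis=0),
        QTLEffect("2L", 11.3, 13.3e-4, -0.4e-4, trait_axis=0),
        QTLEffect("3L", 19.7, -10.9e-4, 1.7e-4, trait_axis=0),
        QTLEffect("3R", 40.3, 1.4e-4, -7.4e-4, trait_axis=0),
        QTLEffect("3L", 11.5, -6.5e-4, 1.4e-4, trait_axis=1),
        QTLEffect("3L", 32.6, 2.2e-4, -9.4e-4, trait_axis=1),
    ]
    return QTLSpec(qtl=qtl)


@dataclass
class SNPFilterParams:
    """SNP-level quality filters applied before window binning."""

    parental_hom_freq: float = 0.9
    min_recomb_calls: int = 48
    max_het_frac: float = 0.75
    max_reads_per_call: int = 500

    def __post_init__(self):
        if not (0 < self.parental_hom_freq <= 1):
            raise ConfigError("parental homozygosity frequency must be in (0,1]")
        if not (0 <= self.max_het_frac <= 1):
            raise ConfigError("max het fraction must be in [0,1]")
        if self.min_recomb_calls < 0 or self.max_reads_per_call <= 0:
            raise ConfigError("invalid SNP filter thresholds")


@dataclass
class CallParams:
    """Window genotype-call and masking thresholds."""

    min_reads_aut: int = 20
    min_reads_x: int = 10
    hom_ratio: float = 10.0
    het_band: tuple = (0.3, 0.7)
    min_ind_call_rate: float = 0.4
    min_window_called_frac: float = 0.9
    min_maf: float = 0.05

    def __post_init__(self):
        lo, hi = self.het_band
        if not (0 < lo <= hi < 1):
            raise ConfigError("het band must lie inside (0, 1)")
        if self.hom_ratio <= 1:
            raise ConfigError("homozygote ratio must exceed 1")
        for v in (self.min_ind_call_rate, self.min_window_called_frac, self.min_maf):
            if not (0 <= v <= 1):
                raise ConfigError("masking fractions must be in [0,1]")


def config_to_dict(obj) -> dict:
    return asdict(obj)
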