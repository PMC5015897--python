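"""Outline morphometrics: standardization, elliptic Fourier analysis, PCA.

A lobe is recorded as an ordered closed outline of Cartesian coordinates
whose two baseline endpoints mark the artificial segment closing the
outline where the structure joins the lateral plate.  Standardization
mirrors for handedness, rotates the baseline horizontal (structure above
it), translates the area centroid to the origin and fixes a clockwise
traversal.  Shape is then described by 25 elliptic Fourier harmonics
(100 coefficients; the DC terms vanish after centering and are excluded,
and no further size/rotation normalization is applied, so coefficients
keep their mm units), which enter a centered, unscaled PCA jointly over
parental and recombinant lobes.  Size metrics (area, height, width, H:W)
are computed on the standardized polygon.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .rng import stream


class OutlineError(ValueError):
    pass


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------
@dataclass
class RawOutline:
    coords: np.ndarray  # (n, 2), ordered, not necessarily closed
    flip: bool = False  # True when the image must be mirrored to the reference handedness
    baseline: tuple = (0, 1)  # indices of the two baseline endpoints
    sample_id: str = ""
    side: str = "L"
    group: str = "rec"
    mm_per_px: float = 1.0

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2 or len(self.coords) < 3:
            raise OutlineError("outline needs at least 3 (x, y) points")
        i, j = self.baseline
        if i == j:
            raise OutlineError("baseline endpoints must be distinct")


@dataclass
class StandardOutline:
    coords: np.ndarray  # closed polygon (first point not repeated), mm units
    sample_id: str = ""
    side: str = "L"
    group: str = "rec"


@dataclass
class EFADescriptor:
    """Elliptic Fourier coefficients (a_n, b_n, c_n, d_n), n = 1..N."""

    coefficients: np.ndarray  # (n_harmonics, 4)
    period: float  # total perimeter parameter T

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if not np.isfinite(self.coefficients).all():
            raise OutlineError("non-finite Fourier coefficients")

    @property
    def n_harmonics(self) -> int:
        return self.coefficients.shape[0]

    def flat_coefficients(self) -> np.ndarray:
        return self.coefficients.reshape(-1)

    @classmethod
    def from_flat(cls, flat, period: float = 1.0) -> "EFADescriptor":
        flat = np.asarray(flat, dtype=float)
        return cls(flat.reshape(-1, 4), period)


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------
def signed_area(coords: np.ndarray) -> float:
    x, y = coords[:, 0], coords[:, 1]
    x2, y2 = np.roll(x, -1), np.roll(y, -1)
    return 0.5 * float(np.sum(x * y2 - x2 * y))


def polygon_centroid(coords: np.ndarray) -> np.ndarray:
    """Area centroid of the closed polygon (robust to uneven vertex
    spacing, unlike the vertex mean)."""
    x, y = coords[:, 0], coords[:, 1]
    x2, y2 = np.roll(x, -1), np.roll(y, -1)
    cross = x * y2 - x2 * y
    a = 0.5 * cross.sum()
    if abs(a) < 1e-300:
        raise OutlineError("degenerate polygon (zero area)")
    cx = ((x + x2) * cross).sum() / (6 * a)
    cy = ((y + y2) * cross).sum() / (6 * a)
    return np.array([cx, cy])


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------
def standardize_outline(raw: RawOutline) -> StandardOutline:
    """Mirror/rotate/translate an outline into the standard configuration.

    Steps: mirror when the handedness flag is set; rotate about the
    baseline midpoint so the baseline is horizontal with the lobe body
    above it; fix a clockwise traversal; translate the area centroid to
    the origin.  Idempotent on already-standard outlines.
    """
    pts = raw.coords * raw.mm_per_px
    i, j = raw.baseline
    if raw.flip:
        pts = pts * np.array([-1.0, 1.0])
    p1, p2 = pts[i], pts[j]
    base_vec = p2 - p1
    blen = np.linalg.norm(base_vec)
    diam = np.linalg.norm(pts.max(axis=0) - pts.min(axis=0))
    if blen < 1e-9 * max(diam, 1e-12):
        raise OutlineError("zero-length baseline")
    mid = (p1 + p2) / 2
    ang = np.arctan2(base_vec[1], base_vec[0])
    c, s = np.cos(-ang), np.sin(-ang)
    R = np.array([[c, -s], [s, c]])
    pts = (pts - mid) @ R.T + mid
    # lobe body above the baseline
    cen = polygon_centroid(pts)
    if cen[1] < mid[1]:
        pts = mid + (mid - pts)  # rotate by pi about the midpoint
    # canonical clockwise traversal (negative signed area)
    if signed_area(pts) > 0:
        pts = pts[::-1]
    pts = pts - polygon_centroid(pts)
    return StandardOutline(pts, raw.sample_id, raw.side, raw.group)


# ---------------------------------------------------------------------------
# elliptic Fourier analysis
# ---------------------------------------------------------------------------
def efa_coefficients(outline, n_harmonics: int = 25) -> EFADescriptor:
    """Fourier coefficients of the outline's piecewise-linear traverse.

    The closed polygon is parameterized by cumulative chord length over
    period T and each coordinate expanded in N harmonics following the
    classical elliptic Fourier construction.  No size, rotation or
    phase normalization is applied, and the DC offsets are dropped.
    """
    pts = outline.coords if isinstance(outline, StandardOutline) else np.asarray(outline, float)
    if len(pts) < 3:
        raise OutlineError("need at least 3 points")
    if np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    d = np.diff(np.vstack([pts, pts[:1]]), axis=0)
    dt = np.hypot(d[:, 0], d[:, 1])
    keep = dt > 0
    d, dt = d[keep], dt[keep]
    if len(dt) < 3:
        raise OutlineError("degenerate outline (all points coincide)")
    t = np.concatenate([[0.0], np.cumsum(dt)])
    T = t[-1]
    n = np.arange(1, n_harmonics + 1)[:, None]
    phi = 2 * np.pi * n * t[None, :] / T  # (N, n_pts+1)
    dcos = np.cos(phi[:, 1:]) - np.cos(phi[:, :-1])
    dsin = np.sin(phi[:, 1:]) - np.sin(phi[:, :-1])
    k = T / (2 * (n.ravel() ** 2) * np.pi**2)
    dxdt = d[:, 0] / dt
    dydt = d[:, 1] / dt
    a = k * (dcos @ dxdt)
    b = k * (dsin @ dxdt)
    c = k * (dcos @ dydt)
    dd = k * (dsin @ dydt)
    return EFADescriptor(np.column_stack([a, b, c, dd]), T)


def efa_reconstruct(desc: EFADescriptor, n_points: int = 200) -> np.ndarray:
    """Harmonic-sum reconstruction at uniformly spaced parameter values,
    centered at the origin (DC terms excluded by construction)."""
    T = desc.period
    t = np.linspace(0.0, T, n_points, endpoint=False)
    n = np.arange(1, desc.n_harmonics + 1)[:, None]
    phi = 2 * np.pi * n * t[None, :] / T
    cosp, sinp = np.cos(phi), np.sin(phi)
    a, b, c, d = desc.coefficients.T
    x = a @ cosp + b @ sinp
    y = c @ cosp + d @ sinp
    return np.column_stack([x, y])


# ---------------------------------------------------------------------------
# size metrics
# ---------------------------------------------------------------------------
def _axis_crossings(pts: np.ndarray, axis: int, level: float) -> np.ndarray:
    """Coordinates (on the other axis) where the polygon boundary crosses
    the line {axis coordinate == level}."""
    v = pts[:, axis] - level
    w = pts[:, 1 - axis]
    v2 = np.roll(v, -1)
    w2 = np.roll(w, -1)
    cross = (v <= 0) != (v2 <= 0)
    denom = v2 - v
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(denom != 0, -v / denom, 0.0)
    return (w + frac * (w2 - w))[cross]


def size_metrics(o: StandardOutline) -> dict:
    """Area (shoelace), and height/width as the span of the vertical /
    horizontal chord through the centroid (outermost boundary
    intersections); H:W is their ratio."""
    pts = o.coords
    area = abs(signed_area(pts))
    cen = polygon_centroid(pts)
    ys = _axis_crossings(pts, 0, cen[0])
    xs = _axis_crossings(pts, 1, cen[1])
    if len(ys) < 2 or len(xs) < 2:
        raise OutlineError("centroid chord fails to cross the boundary twice")
    height = float(ys.max() - ys.min())
    width = float(xs.max() - xs.min())
    if width == 0:
        raise OutlineError("degenerate zero-width outline")
    return {"area": area, "height": height, "width": width, "hw_ratio": height / width}


# ---------------------------------------------------------------------------
# shape PCA
# ---------------------------------------------------------------------------
def shape_pca(coeff_matrix: np.ndarray, groups, n_components: int = 3):
    """Centered, unscaled PCA of the flat coefficient matrix.

    All lobes — both parental strains and recombinants — enter jointly.
    Sign convention: each PC is oriented so the mean SS parental score is
    at least the mean T7 score (fallback when a strain is absent: the
    largest-magnitude loading is positive), making scores comparable
    across runs.  Returns (scores, variance fractions, loadings).
    """
    X = np.asarray(coeff_matrix, dtype=float)
    groups = np.asarray(groups)
    if len(X) < 2:
        raise OutlineError("PCA needs at least two lobes")
    if np.allclose(X.var(axis=0), 0):
        raise OutlineError("constant coefficient matrix")
    n_components = min(n_components, len(X) - 1, X.shape[1])
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_.copy()
    ss, t7 = groups == "SS", groups == "T7"
    for k in range(n_components):
        if ss.any() and t7.any():
            flip = scores[ss, k].mean() < scores[t7, k].mean()
        else:
            flip = loadings[k, np.argmax(np.abs(loadings[k]))] < 0
        if flip:
            scores[:, k] *= -1
            loadings[k] *= -1
    return scores, pca.explained_variance_ratio_.copy(), loadings


# ---------------------------------------------------------------------------
# phenotype assembly
# ---------------------------------------------------------------------------
def phenotype_table(outlines, n_harmonics: int = 25, n_pcs: int = 3) -> pd.DataFrame:
    """Per-lobe trait table from raw outlines.

    Standardizes every outline, extracts Fourier descriptors, runs the
    joint shape PCA, and computes size metrics.  Returns one row per lobe
    with columns sample_id, group, side, area, height, width, hw_ratio,
    pc1..pck; PCA variance fractions live in ``df.attrs['pc_variance']``.
    """
    std = [standardize_outline(o) for o in outlines]
    desc = [efa_coefficients(s, n_harmonics) for s in std]
    X = np.array([d.flat_coefficients() for d in desc])
    groups = np.array([s.group for s in std])
    scores, var_frac, loadings = shape_pca(X, groups, n_pcs)
    rows = []
    for i, s in enumerate(std):
        row = {"sample_id": s.sample_id, "group": s.group, "side": s.side}
        row.update(size_metrics(s))
        for k in range(scores.shape[1]):
            row[f"pc{k+1}"] = scores[i, k]
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["pc_variance"] = var_frac
    df.attrs["pc_loadings"] = loadings
    return df


def select_mapping_lobe(lobe_table: pd.DataFrame, seed: int = 0):
    """One randomly chosen lobe per individual (plus the complement).

    Where both sides were measured, a seeded uniform choice picks the
    mapping lobe; the other side goes to the alternate table used for the
    bilateral replicate scan.  Individuals with a single lobe appear only
    in the primary table.
    """
    rng = stream(seed, "lobe-choice")
    primary, alternate = [], []
    for sid, grp in lobe_table.groupby("sample_id", sort=False):
        if len(grp) == 1:
            primary.append(grp.iloc[0])
        else:
            k = int(rng.integers(len(grp)))
            primary.append(grp.iloc[k])
            alternate.append(grp.iloc[1 - k])
    prim = pd.DataFrame(primary).reset_index(drop=True)
    alt = pd.DataFrame(alternate).reset_index(drop=True) if alternate else lobe_table.iloc[:0].copy()
    prim.attrs.update(lobe_table.attrs)
    alt.attrs.update(lobe_table.attrs)
    return prim, alt


TRAITS = ["area", "height", "width", "hw_ratio", "pc1", "pc2", "pc3"]


def trait_summary_stats(pheno: pd.DataFrame, group_col: str = "group"):
    """Welch's t-tests between the parental strains per trait, and the
    pairwise Pearson correlation matrix (with p-values) over one-lobe-
    per-individual recombinant data."""
    traits = [t for t in TRAITS if t in pheno.columns]
    ss = pheno[pheno[group_col] == "SS"]
    t7 = pheno[pheno[group_col] == "T7"]
    welch_rows = []
    for tr in traits:
        a, b = ss[tr].dropna(), t7[tr].dropna()
        if len(a) < 2 or len(b) < 2 or (a.var() == 0 and b.var() == 0):
            welch_rows.append({"trait": tr, "t": np.nan, "p": np.nan})
            continue
        t, p = stats.ttest_ind(a, b, equal_var=False)
        welch_rows.append({"trait": tr, "t": float(t), "p": float(p)})
    welch = pd.DataFrame(welch_rows)

    rec = pheno[pheno[group_col] == "rec"]
    k = len(traits)
    r = np.full((k, k), np.nan)
    pm = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i, k):
            x, y = rec[traits[i]], rec[traits[j]]
            if len(rec) < 3 or x.var() == 0 or y.var() == 0:
                continue
            rr, pp = stats.pearsonr(x, y)
            r[i, j] = r[j, i] = rr
            pm[i, j] = pm[j, i] = pp
    corr = pd.DataFrame(r, index=traits, columns=traits)
    pvals = pd.DataFrame(pm, index=traits, columns=traits)
    return welch, corr, pvals
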