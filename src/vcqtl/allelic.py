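"""Per-parent allelic substitution models, sex-linkage scans and epistasis.

These are the family-based fixed-effect companions to the variance-component
scan.  For one parent, the design column at a locus is the centred
probability z = p - 1/2 of having inherited that parent's haplotype 1, so the
coefficient q of z is the allelic substitution effect (average phenotype
difference between offspring inheriting haplotype 1 vs haplotype 2).  With
two or more mates a fixed mate effect enters, and the gene-by-parent
(epistasis) test compares the model with a common allelic effect against the
model with a mate-specific effect.  The gene-by-gene test adds a product
interaction of two locus contrasts inside a full-sib family.

Genome-wide significance of the interaction scans uses a conservative
max-statistic parametric resampling under the no-interaction null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .dataio import DatasetTable, FamilyStructure
from .gametic import InheritanceProbabilities

_EPS = 1e-9


def _z_column(inh: InheritanceProbabilities, parent: str, offspring: list[str],
              chrom: int, pos: float) -> np.ndarray:
    pidx = inh.pair_index
    col = inh.at(chrom, pos)
    return np.array([col[pidx[(o, parent)]] for o in offspring]) - 0.5


def _pheno_vector(table: DatasetTable, ids: list[str], phenotype: str
                  ) -> np.ndarray:
    s = table.df.set_index("id").loc[ids]
    if phenotype == "sex":
        return s["sex"].map({"F": 0.0, "M": 1.0}).to_numpy(dtype=float)
    return s[phenotype].to_numpy(dtype=float)


def _all_positions(inh: InheritanceProbabilities, grid: str = "markers"):
    out = []
    for chrom in inh.lmap.chromosomes:
        if grid == "markers":
            pos = inh.lmap.markers_on(chrom)["pos"].to_numpy()
        else:
            pos = inh.grid[chrom]
        out.extend((chrom, float(x)) for x in pos)
    return out


# ---------------------------------------------------------------------------
# Models 4-5: per-parent allelic substitution scan
# ---------------------------------------------------------------------------

def per_parent_scan(table: DatasetTable, structure: FamilyStructure,
                    inh: InheritanceProbabilities, parent: str,
                    phenotype: str = "weight",
                    positions=None) -> pd.DataFrame:
    """Least-squares allelic substitution effect of one parent per locus.

    Offspring of the parent with the phenotype recorded are regressed on the
    centred haplotype-1 probability; with two or more mates a fixed mate
    effect is added.  Loci where all offspring share one inherited haplotype
    are skipped as uninformative.
    """
    import statsmodels.api as sm

    offs = [o for o in structure.offspring_of(parent)]
    y_all = _pheno_vector(table, offs, phenotype)
    keep = ~np.isnan(y_all)
    offs = [o for o, k in zip(offs, keep) if k]
    y = y_all[keep]
    mates = np.array([
        structure.family_of(o).sire if structure.family_of(o).dam == parent
        else structure.family_of(o).dam
        for o in offs
    ])
    mate_levels = pd.unique(mates)
    dummies = np.column_stack([
        (mates == m).astype(float) for m in mate_levels[1:]
    ]) if len(mate_levels) > 1 else np.empty((len(offs), 0))
    positions = positions or _all_positions(inh)
    rows = []
    for chrom, pos in positions:
        z = _z_column(inh, parent, offs, chrom, pos)
        if np.var(z) < _EPS:
            continue
        X = np.column_stack([np.ones(len(offs)), dummies, z])
        fit = sm.OLS(y, X).fit()
        rows.append({
            "parent": parent, "chromosome": chrom, "pos": pos,
            "q": float(fit.params[-1]), "se": float(fit.bse[-1]),
            "pvalue": float(fit.pvalues[-1]), "n_offspring": len(offs),
            "n_mates": len(mate_levels),
        })
    return pd.DataFrame(rows, columns=["parent", "chromosome", "pos", "q",
                                       "se", "pvalue", "n_offspring",
                                       "n_mates"])


# ---------------------------------------------------------------------------
# Sex-linkage scan
# ---------------------------------------------------------------------------

@dataclass
class SexScanResult:
    dataset_scan: "object"               # ScanResult for sex as response
    per_family: pd.DataFrame | None      # chromosome, fraction, n_informative
    n_excluded_families: int = 0


def sex_linkage_scan(table: DatasetTable, structure: FamilyStructure,
                     inh: InheritanceProbabilities, per_family: bool = True,
                     min_sex_fraction: float = 0.2,
                     alpha: float = 0.05) -> SexScanResult:
    """Scan for loci associated with phenotypic sex (coded F=0, M=1).

    Dataset level: the variance-component scan run with sex as the response.
    Per-family mode: for each family segregating both sexes, the within-family
    allelic contrast is tested at every marker of each chromosome; a family
    counts toward a chromosome when its best nominal p-value beats ``alpha``.
    Single-sex families are excluded and counted.
    """
    from .scan import genome_scan

    sexed = table.offspring["sex"].isin(("F", "M"))
    if sexed.mean() < min_sex_fraction:
        raise ValueError(
            f"phenotypic sex recorded for {100 * sexed.mean():.0f}% of "
            f"offspring (< {100 * min_sex_fraction:.0f}%)")
    scan, _ = genome_scan(table, structure, inh, phenotype="sex",
                          covariates=("strain",))
    pf = None
    n_excl = 0
    if per_family:
        chroms = inh.lmap.chromosomes
        counts = {c: 0 for c in chroms}
        n_inf = 0
        for fam in structure.families.values():
            ids = [o for o in fam.offspring]
            sex = _pheno_vector(table, ids, "sex")
            ok = ~np.isnan(sex)
            ids = [i for i, k in zip(ids, ok) if k]
            sex = sex[ok]
            if len(ids) < 4 or len(np.unique(sex)) < 2:
                n_excl += 1
                continue
            n_inf += 1
            for chrom in chroms:
                best = 1.0
                m = 0
                for pos in inh.lmap.markers_on(chrom)["pos"]:
                    for par in (fam.dam, fam.sire):
                        z = _z_column(inh, par, ids, chrom, float(pos))
                        if np.var(z) < _EPS:
                            continue
                        m += 1
                        best = min(best, _simple_slope_pvalue(sex, z))
                # Sidak correction over the markers x parents tested
                if m and best < 1.0 - (1.0 - alpha) ** (1.0 / m):
                    counts[chrom] += 1
        pf = pd.DataFrame({
            "chromosome": chroms,
            "n_families": [counts[c] for c in chroms],
            "fraction": [counts[c] / n_inf if n_inf else np.nan for c in chroms],
        })
    return SexScanResult(scan, pf, n_excl)


def _simple_slope_pvalue(y: np.ndarray, z: np.ndarray) -> float:
    n = len(y)
    zc = z - z.mean()
    yc = y - y.mean()
    szz = float(zc @ zc)
    b = float(zc @ yc) / szz
    rss = float(yc @ yc) - b * b * szz
    if rss <= 0 or n <= 2:
        return 0.0
    se = np.sqrt(rss / (n - 2) / szz)
    from scipy.stats import t as tdist
    return float(2 * tdist.sf(abs(b / se), n - 2))


# ---------------------------------------------------------------------------
# Models 6-7: gene-by-gene interaction scan (within full-sib family)
# ---------------------------------------------------------------------------

@dataclass
class PairwiseScanResult:
    """All locus-pair interaction tests within one full-sib family."""

    family_id: str
    table: pd.DataFrame      # parent1,chrom1,pos1,parent2,chrom2,pos2,LR,p,pct
    n_offspring: int
    _y: np.ndarray = field(repr=False, default=None)
    _Z: np.ndarray = field(repr=False, default=None)
    _contrasts: list = field(repr=False, default=None)
    _pairs: np.ndarray = field(repr=False, default=None)

    @property
    def max_lr(self) -> float:
        return float(self.table["LR"].max()) if len(self.table) else 0.0


def _pair_lr_batch(y: np.ndarray, Z: np.ndarray, pairs: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Interaction LR (and %SS) for locus-contrast pairs, batched.

    ``y`` and the columns of ``Z`` are centred.  For each pair (i, j) the
    main-effects model [z_i, z_j] is compared with [z_i, z_j, z_i*z_j]
    (interaction column centred); LR = n * log(RSS0/RSS1).
    """
    n = len(y)
    G = Z.T @ Z
    Z2 = Z ** 2
    A21 = Z2.T @ Z                      # sum z_i^2 z_j
    A22 = Z2.T @ Z2                     # sum z_i^2 z_j^2
    Zy = Z.T @ y
    Ay = (Z * y[:, None]).T @ Z         # sum z_i y z_j
    i, j = pairs[:, 0], pairs[:, 1]
    m = G[i, j] / n                     # mean of interaction column
    # Gram of [z_i, z_j, w] with w = z_i z_j - m
    g11, g22, g12 = G[i, i], G[j, j], G[i, j]
    g1w = A21[i, j]                     # sum z_i^2 z_j (z cols centred)
    g2w = A21[j, i]
    gww = A22[i, j] - n * m ** 2
    b1, b2 = Zy[i], Zy[j]
    bw = Ay[i, j]                       # sum y z_i z_j (y centred)
    yy = float(y @ y)

    det = g11 * g22 - g12 ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        c1 = (g22 * b1 - g12 * b2) / det
        c2 = (-g12 * b1 + g11 * b2) / det
        rss0 = yy - (c1 * b1 + c2 * b2)
    Gm = np.empty((len(i), 3, 3))
    Gm[:, 0, 0], Gm[:, 0, 1], Gm[:, 0, 2] = g11, g12, g1w
    Gm[:, 1, 0], Gm[:, 1, 1], Gm[:, 1, 2] = g12, g22, g2w
    Gm[:, 2, 0], Gm[:, 2, 1], Gm[:, 2, 2] = g1w, g2w, gww
    rhs = np.stack([b1, b2, bw], axis=1)
    ok = (np.abs(np.linalg.det(Gm))
          > _EPS * np.maximum(1.0, g11 * g22 * np.abs(gww)))
    ok &= np.abs(det) > _EPS * np.maximum(1.0, g11 * g22)
    coef = np.full_like(rhs, np.nan)
    if ok.any():
        coef[ok] = np.linalg.solve(Gm[ok], rhs[ok][..., None])[..., 0]
    rss1 = yy - np.einsum("ij,ij->i", coef, rhs)
    with np.errstate(invalid="ignore", divide="ignore"):
        lr = n * np.log(rss0 / rss1)
    lr = np.where(ok & (rss1 > 0), np.maximum(lr, 0.0), np.nan)
    pct = np.where(ok, 100.0 * (rss0 - rss1) / yy, np.nan)
    return lr, pct


def gene_by_gene_scan(table: DatasetTable, structure: FamilyStructure,
                      inh: InheritanceProbabilities, family_id: str,
                      phenotype: str = "weight", positions=None,
                      min_cm_apart: float = 50.0) -> PairwiseScanResult:
    """Two-locus interaction tests for every locus pair in one family.

    Locus contrasts are the centred haplotype-1 probabilities of the dam and
    the sire; pairs on the same chromosome closer than ``min_cm_apart`` cM
    (including a locus with itself) are excluded to avoid confounding with a
    single segregating QTL.  Nominal p-values use chi-squared with 1 df;
    genome-wide significance via :func:`resampling_significance`.
    """
    fam = structure.families[family_id]
    ids = list(fam.offspring)
    y = _pheno_vector(table, ids, phenotype)
    ok = ~np.isnan(y)
    ids = [i for i, k in zip(ids, ok) if k]
    y = y[ok]
    y = y - y.mean()
    positions = positions or _all_positions(inh)
    contrasts = []       # (parent, chrom, pos)
    zcols = []
    for parent in (fam.dam, fam.sire):
        for chrom, pos in positions:
            z = _z_column(inh, parent, ids, chrom, pos)
            if np.var(z) < 1e-4:
                continue
            contrasts.append((parent, chrom, pos))
            zcols.append(z - z.mean())
    if not zcols:
        return PairwiseScanResult(family_id, pd.DataFrame(), len(ids))
    Z = np.column_stack(zcols)
    pairs = []
    for a in range(len(contrasts)):
        for b in range(a + 1, len(contrasts)):
            _, c1, p1 = contrasts[a]
            _, c2, p2 = contrasts[b]
            if c1 == c2 and abs(p1 - p2) < min_cm_apart:
                continue
            pairs.append((a, b))
    if not pairs:
        return PairwiseScanResult(family_id, pd.DataFrame(), len(ids))
    pairs = np.array(pairs)
    lr, pct = _pair_lr_batch(y, Z, pairs)
    skipped = int(np.isnan(lr).sum())
    if skipped:
        warnings.warn(f"family {family_id}: {skipped} rank-deficient "
                      f"locus pairs skipped")
    tab = pd.DataFrame({
        "family": family_id,
        "parent1": [contrasts[a][0] for a, _ in pairs],
        "chrom1": [contrasts[a][1] for a, _ in pairs],
        "pos1": [contrasts[a][2] for a, _ in pairs],
        "parent2": [contrasts[b][0] for _, b in pairs],
        "chrom2": [contrasts[b][1] for _, b in pairs],
        "pos2": [contrasts[b][2] for _, b in pairs],
        "LR": lr,
        "pvalue": chi2.sf(np.nan_to_num(lr), 1),
        "pct_family_variance": pct,
    }).dropna(subset=["LR"]).reset_index(drop=True)
    return PairwiseScanResult(family_id, tab, len(ids), _y=y, _Z=Z,
                              _contrasts=contrasts, _pairs=pairs)


# ---------------------------------------------------------------------------
# Models 5 vs 8: gene-by-parent interaction scan (half-sib group)
# ---------------------------------------------------------------------------

@dataclass
class GeneByParentResult:
    """Interaction of one shared parent's allelic effect with its mates."""

    parent: str
    mates: list[str]
    table: pd.DataFrame       # chrom,pos,LR,p,pct_within_family,q_<mate>...
    n_offspring: int
    dropped_mates: list[str] = field(default_factory=list)
    _y: np.ndarray = field(repr=False, default=None)
    _mate_idx: np.ndarray = field(repr=False, default=None)
    _Zs: dict = field(repr=False, default=None)

    @property
    def max_lr(self) -> float:
        return float(self.table["LR"].max()) if len(self.table) else 0.0


def _gxp_stats(y: np.ndarray, mate_idx: np.ndarray, z: np.ndarray,
               n_mates: int) -> tuple[float, np.ndarray, float]:
    """LR of mate-specific vs common allelic effect, per-mate slopes, %SS.

    Model 5: y ~ mate + z.  Model 8: y ~ mate + z:mate.  The %SS is the
    interaction sum of squares over the within-family-centred total SS.
    """
    n = len(y)
    D = np.zeros((n, n_mates))
    D[np.arange(n), mate_idx] = 1.0
    X5 = np.column_stack([D, z])
    X8 = np.column_stack([D, D * z[:, None]])
    b5, rss5 = _lstsq_rss(X5, y)
    b8, rss8 = _lstsq_rss(X8, y)
    counts = D.sum(axis=0)
    means = (D.T @ y) / counts
    ss_within = float(((y - means[mate_idx]) ** 2).sum())
    lr = n * np.log(rss5 / rss8) if rss8 > 0 else np.inf
    pct = 100.0 * max(rss5 - rss8, 0.0) / ss_within if ss_within > 0 else 0.0
    return max(lr, 0.0), b8[n_mates:], pct


def _lstsq_rss(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    b, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ b
    return b, float(r @ r)


def gene_by_parent_scan(table: DatasetTable, structure: FamilyStructure,
                        inh: InheritanceProbabilities, parent: str,
                        phenotype: str = "weight", positions=None,
                        min_offspring: int = 15) -> GeneByParentResult:
    """Test whether a shared parent's allelic effect depends on the mate.

    Requires the parent to have >= 2 mates each contributing at least
    ``min_offspring`` phenotyped offspring (smaller mates are dropped from
    the contrast and reported).  Per-mate allelic effects are returned so
    sign flips between half-sib families are visible; the interaction LR
    compares the common-effect with the mate-specific-effect model and the
    percentage is of the within-family phenotypic sum of squares.
    """
    if parent not in structure.half_sib_groups:
        raise ValueError(f"parent {parent!r} has fewer than 2 mates")
    fams = [structure.families[fid]
            for fid, _ in structure.half_sib_groups[parent]]
    ids, mates = [], []
    for fam in fams:
        mate = fam.sire if fam.dam == parent else fam.dam
        for o in fam.offspring:
            ids.append(o)
            mates.append(mate)
    y = _pheno_vector(table, ids, phenotype)
    ok = ~np.isnan(y)
    ids = [i for i, k in zip(ids, ok) if k]
    mates = [m for m, k in zip(mates, ok) if k]
    y = y[ok]
    counts = pd.Series(mates).value_counts()
    keep_mates = counts[counts >= min_offspring].index.tolist()
    dropped = [m for m in counts.index if m not in keep_mates]
    if len(keep_mates) < 2:
        return GeneByParentResult(parent, keep_mates, pd.DataFrame(), 0,
                                  dropped)
    sel = [k for k, m in enumerate(mates) if m in keep_mates]
    ids = [ids[k] for k in sel]
    y = y[sel]
    mate_arr = np.array([mates[k] for k in sel])
    mate_idx = np.searchsorted(np.sort(keep_mates),
                               mate_arr)  # deterministic mate order
    keep_sorted = sorted(keep_mates)
    positions = positions or _all_positions(inh)
    rows = []
    Zs = {}
    for chrom, pos in positions:
        z = _z_column(inh, parent, ids, chrom, pos)
        if np.var(z) < 1e-4:
            continue
        lr, slopes, pct = _gxp_stats(y, mate_idx, z, len(keep_sorted))
        Zs[(chrom, pos)] = z
        row = {"parent": parent, "chromosome": chrom, "pos": pos, "LR": lr,
               "pvalue": float(chi2.sf(lr, len(keep_sorted) - 1)),
               "pct_within_family": pct}
        for m, q in zip(keep_sorted, slopes):
            row[f"q[{m}]"] = float(q)
        rows.append(row)
    tab = pd.DataFrame(rows)
    return GeneByParentResult(parent, keep_sorted, tab, len(ids), dropped,
                              _y=y, _mate_idx=mate_idx, _Zs=Zs)


# ---------------------------------------------------------------------------
# Genome-wide significance by conservative resampling
# ---------------------------------------------------------------------------

@dataclass
class ResamplingResult:
    pvalue: float
    is_bound: bool               # True when observed beats every resample
    mc_se: float
    n_resamples: int
    null_maxima: np.ndarray


def resampling_significance(result, n_resamples: int = 200,
                            seed: int | None = 0,
                            scheme: str = "bootstrap") -> ResamplingResult:
    """Genome-wide p for the maximum interaction statistic of a scan.

    Data are resampled under the no-interaction null -- fitted values of the
    null model (family or mate means) plus Gaussian residuals for the
    parametric ``bootstrap`` scheme, or residual permutation for
    ``permutation`` -- and the maximum interaction LR over all tested
    pairs/loci is recomputed each time.  The genome-wide p-value is the
    fraction of null maxima at or above the observed maximum (with the +1
    correction); when no null maximum reaches it the value 1/(n+1) is
    reported as an upper bound.
    """
    if n_resamples < 100:
        raise ValueError("n_resamples must be >= 100")
    rng = np.random.default_rng(seed)
    obs = result.max_lr
    if isinstance(result, PairwiseScanResult):
        y, fitted = result._y, np.zeros_like(result._y)
        recompute = lambda ystar: np.nanmax(_pair_lr_batch(
            ystar - ystar.mean(), result._Z, result._pairs)[0])
    elif isinstance(result, GeneByParentResult):
        y = result._y
        n_m = len(result.mates)
        D = np.zeros((len(y), n_m))
        D[np.arange(len(y)), result._mate_idx] = 1.0
        fitted = (D.T @ y / D.sum(axis=0))[result._mate_idx]

        def recompute(ystar):
            best = 0.0
            for z in result._Zs.values():
                lr, _, _ = _gxp_stats(ystar, result._mate_idx, z, n_m)
                best = max(best, lr)
            return best
    else:
        raise TypeError(f"unsupported result type {type(result)!r}")
    resid = y - fitted
    sigma = float(np.std(resid, ddof=1))
    maxima = np.empty(n_resamples)
    for k in range(n_resamples):
        if scheme == "bootstrap":
            ystar = fitted + rng.normal(0.0, sigma, size=len(y))
        elif scheme == "permutation":
            ystar = fitted + rng.permutation(resid)
        else:
            raise ValueError(f"unknown scheme {scheme!r}")
        maxima[k] = recompute(ystar)
    n_ge = int((maxima >= obs).sum())
    p = (1 + n_ge) / (n_resamples + 1)
    return ResamplingResult(pvalue=p, is_bound=(n_ge == 0),
                            mc_se=float(np.sqrt(p * (1 - p) / n_resamples)),
                            n_resamples=n_resamples, null_maxima=maxima)
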