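"""Variance-component genome scan, permutation thresholds and QTL reports.

The scan compares, at every evaluation position, the mixed model with a
locus-specific random QTL effect (covariance Vq * IBD) against the no-QTL
polygenic model, using twice the restricted-likelihood difference as the
statistic.  Genome-wide significance comes from the permutation distribution
of the genome-wide maximum statistic (Churchill-Doerge), permuting phenotype
records within full-sib families by default so the family/polygenic structure
is preserved while within-family marker-phenotype linkage is destroyed.

For speed the scan statistic is computed in two stages: the polygenic and
residual variances are estimated once under the no-QTL model (exact
two-component REML), and at each position the covariance Vq*Q + s*V0 is
profiled over (Vq, s) after a one-off eigenrotation of Q against
V0 = Va0*K + Ve0*I.  The same statistic is used for observed and permuted
data.  Reported variance components (heritability, per-QTL Va/Vq with
standard deviations, joint multi-QTL models, parental contributions) come
from full multi-component AI-REML fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .dataio import DatasetTable, FamilyStructure, LinkageMap
from .gametic import InheritanceProbabilities, gametic_design, kinship_lowrank
from .reml import VarCompFit, VarComponent, reml_2comp, reml_fit

_LOG2PI = np.log(2.0 * np.pi)


# ---------------------------------------------------------------------------
# Fixed-effect design
# ---------------------------------------------------------------------------

def strain_labels(table: DatasetTable, structure: FamilyStructure) -> pd.Series:
    """Per-individual strain-cross label (dam strain x sire strain)."""
    lab = {}
    for fam in structure.families.values():
        ds = structure.parent_strain.get(fam.dam, "") or structure.parent_origin[fam.dam]
        ss = structure.parent_strain.get(fam.sire, "") or structure.parent_origin[fam.sire]
        lab[fam.family_id] = f"{ds}x{ss}"
    return table.df["family"].map(lambda f: lab.get(f, ""))


def design_matrix(table: DatasetTable, structure: FamilyStructure,
                  ids: list[str], covariates=("strain", "replicate")
                  ) -> tuple[np.ndarray, list[str]]:
    """Intercept plus treatment-coded covariate dummies for the given ids.

    Factor levels represented by fewer than two individuals are merged into
    the reference level with a warning.
    """
    df = table.df.set_index("id").loc[ids]
    cols = {"intercept": np.ones(len(ids))}
    for cov in covariates:
        if cov == "strain":
            vals = strain_labels(table, structure).set_axis(table.df["id"]).loc[ids]
        elif cov == "sex":
            vals = df["sex"]
        else:
            vals = df[cov].astype(str)
        vals = vals.astype(str)
        counts = vals.value_counts()
        small = counts[counts < 2].index.tolist()
        if small:
            warnings.warn(f"covariate {cov!r}: levels {small} have <2 "
                          f"individuals; merged into reference")
            vals = vals.where(~vals.isin(small), counts.idxmax())
        levels = sorted(vals.unique())
        for lev in levels[1:]:
            cols[f"{cov}[{lev}]"] = (vals == lev).to_numpy(dtype=float)
    X = np.column_stack(list(cols.values()))
    # drop collinear columns (e.g. replicate aliased with strain)
    keep = []
    names = list(cols.keys())
    for j in range(X.shape[1]):
        trial = keep + [j]
        if np.linalg.matrix_rank(X[:, trial]) == len(trial):
            keep.append(j)
    return X[:, keep], [names[j] for j in keep]


def phenotyped_ids(table: DatasetTable, structure: FamilyStructure,
                   phenotype: str, covariates=()) -> list[str]:
    """Offspring with the phenotype (and any requested covariates) recorded."""
    df = table.offspring
    ok = df["family"].isin(structure.families)
    if phenotype in ("weight", "length"):
        ok &= df[phenotype].notna()
    elif phenotype == "sex":
        ok &= df["sex"].isin(("F", "M"))
    if "sex" in covariates:
        ok &= df["sex"].isin(("F", "M"))
    return df["id"][ok].tolist()


# ---------------------------------------------------------------------------
# Scan context and fast profiled LR
# ---------------------------------------------------------------------------

@dataclass
class ScanContext:
    """Everything a genome scan, permutation run or QTL report needs."""

    table: DatasetTable
    structure: FamilyStructure
    inh: InheritanceProbabilities
    phenotype: str
    covariates: tuple
    ids: list[str]
    y: np.ndarray
    X: np.ndarray
    beta_names: list[str]
    K: np.ndarray                     # dense kinship over ids
    B: np.ndarray                     # kinship low-rank factor (K = BB' + 0.5 I)
    null_fit: VarCompFit
    L0: np.ndarray                    # chol of Va0*K + Ve0*I
    lmap: LinkageMap

    @property
    def families_of_ids(self) -> np.ndarray:
        fam = self.table.df.set_index("id").loc[self.ids, "family"]
        return fam.to_numpy()


def make_scan_context(table: DatasetTable, structure: FamilyStructure,
                      inh: InheritanceProbabilities, phenotype: str = "weight",
                      covariates=("strain", "replicate")) -> ScanContext:
    ids = phenotyped_ids(table, structure, phenotype, covariates)
    y = table.df.set_index("id").loc[ids, phenotype] if phenotype != "sex" \
        else table.df.set_index("id").loc[ids, "sex"].map({"F": 0.0, "M": 1.0})
    y = y.to_numpy(dtype=float)
    X, names = design_matrix(table, structure, ids, covariates)
    B, dk = kinship_lowrank(structure, ids)
    K = B @ B.T + dk * np.eye(len(ids))
    null = reml_2comp(y, X, K, beta_names=names)
    V0 = null["Va"] * K + null["Ve"] * np.eye(len(ids))
    L0 = linalg.cholesky(V0, lower=True)
    return ScanContext(table, structure, inh, phenotype, tuple(covariates),
                       ids, y, X, names, K, B, null, L0, inh.lmap)


_DELTAS = np.concatenate(([0.0], np.exp(np.linspace(-9.0, 9.0, 37))))


def _profile_ll_batch(lam: np.ndarray, Ystar: np.ndarray, Xstar: np.ndarray
                      ) -> np.ndarray:
    """REML loglik of cov = s*(delta*lam + 1), s profiled, for every delta
    on the fixed grid and every phenotype column; returns (G, P)."""
    n, p = Xstar.shape
    G = len(_DELTAS)
    out = np.empty((G, Ystar.shape[1]))
    for g, delta in enumerate(_DELTAS):
        w = delta * lam + 1.0
        Xw = Xstar / w[:, None]
        XtWX = Xstar.T @ Xw
        _, logdetX = np.linalg.slogdet(XtWX)
        Yw = Ystar / w[:, None]
        T = Xstar.T @ Yw
        sols = np.linalg.solve(XtWX, T)
        rss = np.einsum("ij,ij->j", Ystar, Yw) - np.einsum("ij,ij->j", T, sols)
        rss = np.maximum(rss, 1e-300)
        out[g] = -0.5 * (np.sum(np.log(w)) + logdetX
                         + (n - p) * (1.0 + np.log(rss / (n - p)) + _LOG2PI))
    return out


def _lr_from_profile(ll: np.ndarray) -> np.ndarray:
    """LR per column from the grid profile, with one parabolic refinement
    step in log-delta around the grid maximum (same statistic everywhere)."""
    G = ll.shape[0]
    j = np.argmax(ll, axis=0)
    best = ll[j, np.arange(ll.shape[1])]
    interior = (j > 1) & (j < G - 1)
    if interior.any():
        cols = np.flatnonzero(interior)
        y0 = ll[j[cols] - 1, cols]
        y1 = ll[j[cols], cols]
        y2 = ll[j[cols] + 1, cols]
        denom = y0 - 2 * y1 + y2
        with np.errstate(divide="ignore", invalid="ignore"):
            peak = y1 + np.where(denom < -1e-12,
                                 (y0 - y2) ** 2 / (-8 * denom), 0.0)
        best[cols] = np.maximum(best[cols], peak)
    return np.maximum(0.0, 2.0 * (best - ll[0]))


def _profile_lr(lam, ystar, Xstar) -> float:
    """LR statistic: 2*(max over delta >= 0 minus delta = 0)."""
    ll = _profile_ll_batch(lam, ystar[:, None], Xstar)
    return float(_lr_from_profile(ll)[0])


def _position_rotation(ctx: ScanContext, chrom: int, pos: float):
    """Eigenrotation of the IBD covariance against V0 at one position."""
    W, cols = gametic_design(ctx.inh, ctx.structure, chrom, pos, ctx.ids)
    Q = W @ W.T
    np.fill_diagonal(Q, 1.0)
    A = linalg.solve_triangular(ctx.L0, Q, lower=True, check_finite=False)
    Qt = linalg.solve_triangular(ctx.L0, A.T, lower=True, check_finite=False).T
    lam, U = np.linalg.eigh((Qt + Qt.T) / 2.0)
    lam = np.clip(lam, 0.0, None)
    return lam, U


def scan_positions(lmap: LinkageMap, inh: InheritanceProbabilities,
                   grid: str | float = "markers") -> list[tuple[int, float]]:
    """Evaluation positions: marker positions or a regular cM grid."""
    out = []
    for chrom in lmap.chromosomes:
        if grid == "markers":
            pos = lmap.markers_on(chrom)["pos"].to_numpy()
        elif grid == "all":
            pos = inh.grid[chrom]
        else:
            step = float(grid)
            gx = inh.grid[chrom]
            pos = [x for x in gx if (x / step) == int(x / step)]
        for x in pos:
            out.append((chrom, float(x)))
    return out


@dataclass
class ScanResult:
    """Per-position LR profile with genome-wide thresholds."""

    df: pd.DataFrame                  # chrom, pos, LR
    null_fit: VarCompFit
    phenotype: str
    covariates: tuple
    thresholds: dict[float, float] = field(default_factory=dict)

    @property
    def max_lr(self) -> float:
        return float(self.df["LR"].max())

    def significant_regions(self, level: float = 0.05) -> pd.DataFrame:
        """Per chromosome: span of grid points exceeding the threshold.

        The reported interval is the half-open span [first, last] of
        consecutive significant grid positions containing the chromosome
        maximum.
        """
        if level not in self.thresholds:
            raise ValueError(f"no threshold computed at level {level}")
        thr = self.thresholds[level]
        rows = []
        for chrom, grp in self.df.groupby("chromosome"):
            sig = grp[grp["LR"] >= thr]
            if sig.empty:
                continue
            peak = grp.loc[grp["LR"].idxmax()]
            rows.append({
                "chromosome": chrom,
                "pos_lo": float(sig["pos"].min()),
                "pos_hi": float(sig["pos"].max()),
                "peak_pos": float(peak["pos"]),
                "max_LR": float(peak["LR"]),
            })
        return pd.DataFrame(rows, columns=["chromosome", "pos_lo", "pos_hi",
                                           "peak_pos", "max_LR"])

    def to_table(self, path) -> None:
        out = self.df.copy()
        for lv, thr in sorted(self.thresholds.items()):
            out[f"sig{int(lv * 100)}"] = (out["LR"] >= thr).astype(int)
        out.to_csv(path, sep="\t", index=False, float_format="%.4f")


def genome_scan(table: DatasetTable, structure: FamilyStructure,
                inh: InheritanceProbabilities, phenotype: str = "weight",
                covariates=("strain", "replicate"), grid: str | float = "markers",
                ctx: ScanContext | None = None) -> tuple[ScanResult, ScanContext]:
    """Likelihood-ratio profile of the QTL model over the evaluation grid."""
    if ctx is None:
        ctx = make_scan_context(table, structure, inh, phenotype, covariates)
    positions = scan_positions(ctx.lmap, inh, grid)
    yt = linalg.solve_triangular(ctx.L0, ctx.y, lower=True, check_finite=False)
    Xt = linalg.solve_triangular(ctx.L0, ctx.X, lower=True, check_finite=False)
    rows = []
    for chrom, pos in positions:
        try:
            lam, U = _position_rotation(ctx, chrom, pos)
            lr = _profile_lr(lam, U.T @ yt, U.T @ Xt)
        except np.linalg.LinAlgError:
            lr = np.nan
        rows.append({"chromosome": chrom, "pos": pos, "LR": lr})
    res = ScanResult(pd.DataFrame(rows), ctx.null_fit, phenotype,
                     tuple(covariates))
    return res, ctx


# ---------------------------------------------------------------------------
# Permutation thresholds (Churchill-Doerge)
# ---------------------------------------------------------------------------

def _family_permutations(families: np.ndarray, n_perm: int,
                         rng: np.random.Generator,
                         scheme: str) -> np.ndarray:
    n = len(families)
    perms = np.empty((n_perm, n), dtype=int)
    if scheme == "across_family":
        for k in range(n_perm):
            perms[k] = rng.permutation(n)
        return perms
    groups = [np.flatnonzero(families == f) for f in pd.unique(families)]
    base = np.arange(n)
    for k in range(n_perm):
        p = base.copy()
        for g in groups:
            p[g] = g[rng.permutation(len(g))]
        perms[k] = p
    return perms


@dataclass
class PermutationResult:
    thresholds: dict[float, float]
    max_lrs: np.ndarray
    n_perm: int
    scheme: str


def permutation_thresholds(ctx: ScanContext, n_perm: int = 1000,
                           seed: int | None = 0,
                           grid: str | float = "markers",
                           scheme: str = "within_family",
                           levels=(0.05, 0.01)) -> PermutationResult:
    """Genome-wide max-LR null distribution from permuted phenotype records.

    Phenotype rows (with their covariate rows) are permuted across offspring
    within each full-sib family (default), keeping genotypes fixed; the
    95th/99th percentiles of the per-permutation genome-wide maximum give the
    5%/1% thresholds.  Reproducible given ``seed``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if ctx.structure.n_families < 20:
        warnings.warn("fewer than 20 families: exchangeability across "
                      "permutations is weak")
    rng = np.random.default_rng(seed)
    fams = ctx.families_of_ids
    perms = _family_permutations(fams, n_perm, rng, scheme)
    positions = scan_positions(ctx.lmap, ctx.inh, grid)
    n = len(ctx.ids)
    L0inv = linalg.solve_triangular(ctx.L0, np.eye(n), lower=True,
                                    check_finite=False)
    # covariate columns constant within families never change under the
    # within-family scheme
    Xp_all = None
    if scheme == "within_family":
        const = [j for j in range(ctx.X.shape[1])
                 if all(len(np.unique(ctx.X[fams == f, j])) == 1
                        for f in pd.unique(fams))]
        vary = [j for j in range(ctx.X.shape[1]) if j not in const]
    else:
        vary = list(range(ctx.X.shape[1]))
    lrs = np.zeros((len(positions), n_perm))
    Xt = linalg.solve_triangular(ctx.L0, ctx.X, lower=True, check_finite=False)
    Yperm = ctx.y[perms.T]                     # (n, n_perm)
    for ip, (chrom, pos) in enumerate(positions):
        lam, U = _position_rotation(ctx, chrom, pos)
        G = U.T @ L0inv
        Xstar0 = U.T @ Xt
        if not vary:
            # covariates invariant under the scheme: all permutations at once
            ll = _profile_ll_batch(lam, G @ Yperm, Xstar0)
            lrs[ip] = _lr_from_profile(ll)
        else:
            for k in range(n_perm):
                p = perms[k]
                Xstar = Xstar0.copy()
                Xstar[:, vary] = G @ ctx.X[np.ix_(p, vary)]
                lrs[ip, k] = _profile_lr(lam, G @ ctx.y[p], Xstar)
    max_lrs = lrs.max(axis=0)
    thr = {lv: float(np.quantile(max_lrs, 1.0 - lv)) for lv in levels}
    return PermutationResult(thr, max_lrs, n_perm, scheme)


def nominal_pvalue(lr: float) -> float:
    """Per-position p-value from the 50:50 chi2(0):chi2(1) boundary mixture."""
    from scipy.stats import chi2
    if lr <= 0:
        return 1.0
    return 0.5 * chi2.sf(lr, 1)


# ---------------------------------------------------------------------------
# Reported fits: heritability, per-QTL, joint model, parental contribution
# ---------------------------------------------------------------------------

def heritability(ctx: ScanContext) -> float:
    """H2 = Va/(Va+Ve) from the no-QTL model on the full dataset."""
    return ctx.null_fit.h2


def _qtl_component(ctx: ScanContext, chrom: int, pos: float,
                   name: str) -> VarComponent:
    W, _ = gametic_design(ctx.inh, ctx.structure, chrom, pos, ctx.ids)
    d = 1.0 - np.sum(W ** 2, axis=1)
    Q = W @ W.T
    np.fill_diagonal(Q, 1.0)
    return VarComponent(name, matrix=Q, factor=W, diag=d)


def single_qtl_fit(ctx: ScanContext, chrom: int, pos: float) -> VarCompFit:
    """Full AI-REML of the one-QTL model (Va, Vq, Ve with SDs)."""
    comps = [
        VarComponent("Va", matrix=ctx.K, factor=ctx.B, diag=0.5),
        _qtl_component(ctx, chrom, pos, "Vq"),
    ]
    return reml_fit(ctx.y, ctx.X, comps, beta_names=ctx.beta_names)


def joint_qtl_fit(ctx: ScanContext, positions: list[tuple[int, float]]
                  ) -> tuple[VarCompFit, dict[str, float]]:
    """All significant QTLs in one model; cumulative explained variance.

    Returns the fit and the cumulative percentage under both conventions:
    ``pct_phenotypic`` = 100*sum(Vq)/(Va+sum(Vq)+Ve) and
    ``pct_genetic`` = 100*sum(Vq)/(Va+sum(Vq)).
    """
    if not positions:
        raise ValueError("need at least one QTL position")
    comps = [VarComponent("Va", matrix=ctx.K, factor=ctx.B, diag=0.5)]
    for k, (chrom, pos) in enumerate(positions):
        comps.append(_qtl_component(ctx, chrom, pos, f"Vq{k + 1}"))
    fit = reml_fit(ctx.y, ctx.X, comps, beta_names=ctx.beta_names)
    vq = sum(v for nm, v in fit.varcomps.items() if nm.startswith("Vq"))
    va, ve = fit["Va"], fit["Ve"]
    pct = {
        "pct_phenotypic": 100.0 * vq / (va + vq + ve),
        "pct_genetic": 100.0 * vq / (va + vq) if va + vq > 0 else 0.0,
    }
    return fit, pct


def parental_contribution(ctx: ScanContext, chrom: int, pos: float
                          ) -> dict[str, float]:
    """Relative domesticated vs wild variance contribution at a QTL.

    The QTL random effect is split into two terms -- haplotypes transmitted
    by domesticated parents and by wild parents -- with separate variances;
    the contribution of each origin is its share of Vq_dom + Vq_wild.
    """
    W, cols = gametic_design(ctx.inh, ctx.structure, chrom, pos, ctx.ids)
    origin = ctx.structure.parent_origin
    dom = [k for k, (p, _) in enumerate(cols) if origin.get(p) == "domesticated"]
    wld = [k for k, (p, _) in enumerate(cols) if origin.get(p) == "wild"]
    comps = [
        VarComponent("Va", matrix=ctx.K, factor=ctx.B, diag=0.5),
        VarComponent("Vq_dom", factor=W[:, dom]),
        VarComponent("Vq_wild", factor=W[:, wld]),
    ]
    fit = reml_fit(ctx.y, ctx.X, comps, beta_names=ctx.beta_names)
    vd, vw = fit["Vq_dom"], fit["Vq_wild"]
    tot = vd + vw
    note = ""
    if tot <= 0:
        pct_dom = 50.0
        note = "no QTL variance in either origin class"
    else:
        pct_dom = 100.0 * vd / tot
        if "Vq_dom" in fit.boundary or "Vq_wild" in fit.boundary:
            note = "QTL variance at boundary in one origin class"
    return {"pct_domesticated": pct_dom, "pct_wild": 100.0 - pct_dom,
            "Vq_dom": vd, "Vq_wild": vw, "note": note, "fit": fit}


def qtl_report(ctx: ScanContext, scan: ScanResult, level: float = 0.05
               ) -> pd.DataFrame:
    """Per-QTL table: interval, variance components, parental contributions."""
    regions = scan.significant_regions(level)
    h2 = ctx.null_fit.h2
    rows = []
    for _, reg in regions.iterrows():
        chrom, peak = int(reg["chromosome"]), float(reg["peak_pos"])
        fit = single_qtl_fit(ctx, chrom, peak)
        va, vq, ve = fit["Va"], fit["Vq"], fit["Ve"]
        contrib = parental_contribution(ctx, chrom, peak)
        rows.append({
            "phenotype": ctx.phenotype, "H2": h2, "chromosome": chrom,
            "pos_lo": reg["pos_lo"], "pos_hi": reg["pos_hi"],
            "peak_pos": peak, "max_LR": reg["max_LR"],
            "Va": va, "Va_sd": fit.sds.get("Va", np.nan),
            "Vq": vq, "Vq_sd": fit.sds.get("Vq", np.nan),
            "pct_phenotypic": 100.0 * vq / (va + vq + ve),
            "pct_genetic": 100.0 * vq / (va + vq) if va + vq > 0 else 0.0,
            "pct_domesticated": contrib["pct_domesticated"],
            "pct_wild": contrib["pct_wild"],
        })
    return pd.DataFrame(rows)
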