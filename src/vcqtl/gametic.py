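"""Family-based phasing, gametic transmission probabilities and IBD matrices.

In a two-generation cross every offspring allele traces back to one of four
parental haplotypes (two maternal, two paternal).  This module reconstructs
parental phase from the offspring data, turns the observed transmissions into
multipoint probabilities of having inherited parental haplotype 1 at any map
position (the rows of the QTL design matrix Z), and assembles locus-specific
IBD matrices and the pedigree kinship matrix together with the factorizations
the mixed-model machinery consumes.

Phasing is per parent per chromosome.  Because the number of recombinations
implied by a phase configuration decomposes over adjacent informative-marker
pairs, choosing each phase link by majority vote among the offspring that are
informative at both markers is exactly the minimal-recombination
configuration; ties are broken toward the allele listed first (deterministic).
Links with no informative offspring (or tied votes) start a new phase block;
transmission probabilities never interpolate across block boundaries.

Recombination distances use the Haldane map function (no interference),
r = (1 - exp(-2d/100))/2 for d in cM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataio import (MISSING_GENO, DatasetTable, FamilyStructure, LinkageMap,
                     ValidationError)

PSD_EIG_FLOOR = 1e-8
# minimum net weighted phase-link evidence; below this the chain starts a
# new phase block instead of committing to an unreliable orientation
PHASE_LINK_MIN_VOTES = 3.0


def haldane(d_cm):
    """Haldane map function: cM distance -> recombination fraction."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm, dtype=float) / 100.0))


def haldane_inverse(r):
    """Recombination fraction -> cM (inverse Haldane)."""
    return -50.0 * np.log(1.0 - 2.0 * np.asarray(r, dtype=float))


# ---------------------------------------------------------------------------
# Phasing
# ---------------------------------------------------------------------------

@dataclass
class ParentPhase:
    """Phased haplotypes of one parent on one chromosome."""

    hap1: list[str]                # allele carried by haplotype 1, per marker
    hap2: list[str]
    confidence: np.ndarray         # in [0,1]; 0.5 = arbitrary/ambiguous
    block: np.ndarray              # phase-block id per marker (int)


@dataclass
class PhasedGenotypes:
    """Parental phases plus per-offspring transmission observations.

    ``pairs`` lists every (offspring, parent) pair in a fixed order;
    ``H[chrom]`` is a (n_pairs, n_markers) array with 1.0/0.0 where the
    transmitted parental haplotype is determined, NaN where the marker is
    uninformative (parent homozygous, genotype missing, or transmission
    ambiguous).  ``blocks[chrom]`` carries the parent phase-block id per
    (pair, marker).
    """

    lmap: LinkageMap
    pairs: list[tuple[str, str]]
    parent_phase: dict[tuple[str, int], ParentPhase]
    H: dict[int, np.ndarray]
    blocks: dict[int, np.ndarray]

    @property
    def pair_index(self) -> dict[tuple[str, str], int]:
        return {p: i for i, p in enumerate(self.pairs)}


def _transmitted_allele(off: str, par: str, mate: str) -> str | None:
    """Allele transmitted by ``par`` to ``off``, or None if undetermined."""
    if MISSING_GENO in (off, par):
        return None
    possible = set()
    for x, y in ((off[0], off[1]), (off[1], off[0])):
        if x in par and (mate == MISSING_GENO or y in mate):
            possible.add(x)
    if len(possible) == 1:
        return possible.pop()
    return None


def phase_families(table: DatasetTable, structure: FamilyStructure,
                   lmap: LinkageMap | None = None) -> PhasedGenotypes:
    """Phase every parent and label offspring alleles by parental haplotype.

    A parent mated into several families is phased once, pooling offspring
    across its families, so haplotype labels are consistent within each
    half-sib group (required by the gene-by-parent models).
    """
    lmap = lmap or table.lmap
    geno = table.genotypes
    row_of = {i: k for k, i in enumerate(table.df["id"])}
    g = geno.to_numpy()

    # offspring of each parent with the mate per offspring
    offspring_of: dict[str, list[tuple[str, str]]] = {}
    pairs: list[tuple[str, str]] = []
    for fam in structure.families.values():
        for off in fam.offspring:
            pairs.append((off, fam.dam))
            pairs.append((off, fam.sire))
            offspring_of.setdefault(fam.dam, []).append((off, fam.sire))
            offspring_of.setdefault(fam.sire, []).append((off, fam.dam))

    marker_idx = {m: k for k, m in enumerate(table.markers)}
    parent_phase: dict[tuple[str, int], ParentPhase] = {}
    H: dict[int, np.ndarray] = {}
    blocks: dict[int, np.ndarray] = {}
    pair_idx = {p: i for i, p in enumerate(pairs)}

    for chrom in lmap.chromosomes:
        cmarkers = [m for m in lmap.markers_on(chrom)["marker"] if m in marker_idx]
        M = len(cmarkers)
        Hc = np.full((len(pairs), M), np.nan)
        Bc = np.zeros((len(pairs), M), dtype=int)
        cols = [marker_idx[m] for m in cmarkers]

        for parent, offs in offspring_of.items():
            prow = row_of[parent]
            pg = [g[prow][c] for c in cols]
            # transmitted allele per offspring per marker
            trans: dict[str, list[str | None]] = {}
            for off, mate in offs:
                orow, mrow = row_of[off], row_of[mate]
                trans[off] = [
                    _transmitted_allele(g[orow][c], pg[j], g[mrow][c])
                    for j, c in enumerate(cols)
                ]
            het = [j for j in range(M)
                   if pg[j] != MISSING_GENO and pg[j][0] != pg[j][1]]
            hap1 = [""] * M
            hap2 = [""] * M
            conf = np.full(M, 0.5)
            blk = np.zeros(M, dtype=int)
            for j in range(M):
                if pg[j] == MISSING_GENO:
                    hap1[j] = hap2[j] = "?"
                else:
                    a, b = sorted(pg[j])
                    hap1[j], hap2[j] = a, b   # provisional; het links may flip
            # chain phase linkage over heterozygous markers: each offspring
            # votes through its nearest previous informative marker, with
            # weight 1-2r (the vote's expected correctness margin under the
            # Haldane model), so sparse double-informative overlap does not
            # starve the link
            cpos = lmap.markers_on(chrom)["pos"].to_numpy()
            cur_block = 0
            for k, j in enumerate(het):
                a, b = sorted(pg[j])
                if k == 0:
                    hap1[j], hap2[j] = a, b
                    conf[j] = 1.0
                    blk[j] = cur_block
                    continue
                votes = 0.0
                n_votes = 0
                for off, _ in offs:
                    tc = trans[off][j]
                    if tc is None:
                        continue
                    for jp in reversed(het[:k]):
                        tp = trans[off][jp]
                        if tp is None:
                            continue
                        w = 1.0 - 2.0 * float(haldane(cpos[j] - cpos[jp]))
                        same = (tp == hap1[jp]) == (tc == a)
                        votes += w if same else -w
                        n_votes += 1
                        break
                if n_votes == 0 or abs(votes) < PHASE_LINK_MIN_VOTES:
                    # weak or tied link: new phase block, listed-first order
                    cur_block += 1
                    hap1[j], hap2[j] = a, b
                    conf[j] = 0.5
                elif votes > 0:
                    hap1[j], hap2[j] = a, b
                    conf[j] = 1.0
                else:
                    hap1[j], hap2[j] = b, a
                    conf[j] = 1.0
                blk[j] = cur_block
            # refinement: re-orient each het marker against all others,
            # couplings summed over offspring and weighted by 1-2r;
            # deterministic sweeps from the chain initialization
            if len(het) > 2:
                S = np.zeros((len(offs), len(het)))
                first = {j: sorted(pg[j])[0] for j in het}
                for i, (off, _) in enumerate(offs):
                    for kk, j in enumerate(het):
                        t = trans[off][j]
                        if t is not None:
                            S[i, kk] = 1.0 if t == first[j] else -1.0
                hpos = np.array([lmap.markers_on(chrom)["pos"].to_numpy()[j]
                                 for j in het])
                Wd = 1.0 - 2.0 * haldane(np.abs(hpos[:, None] - hpos[None, :]))
                np.fill_diagonal(Wd, 0.0)
                same_block = (blk[het][:, None] == blk[het][None, :])
                J = (S.T @ S) * Wd * same_block
                o = np.array([1.0 if hap1[j] == first[j] else -1.0
                              for j in het])
                for _sweep in range(3):
                    changed = False
                    for kk in range(len(het)):
                        field = float(J[kk] @ o)
                        if field * o[kk] < -1e-12:
                            o[kk] = -o[kk]
                            changed = True
                    if not changed:
                        break
                for kk, j in enumerate(het):
                    a, b = sorted(pg[j])
                    hap1[j], hap2[j] = (a, b) if o[kk] > 0 else (b, a)
            # homozygous markers: both assignments equivalent
            for j in range(M):
                if j not in het and pg[j] != MISSING_GENO:
                    conf[j] = 0.5
            parent_phase[(parent, chrom)] = ParentPhase(hap1, hap2, conf, blk)

            # per-offspring haplotype observations at het markers
            for off, _ in offs:
                i = pair_idx[(off, parent)]
                Bc[i] = blk
                for j in het:
                    t = trans[off][j]
                    if t is None:
                        continue
                    Hc[i, j] = 1.0 if t == hap1[j] else 0.0
        H[chrom] = Hc
        blocks[chrom] = Bc

    return PhasedGenotypes(lmap, pairs, parent_phase, H, blocks)


# ---------------------------------------------------------------------------
# Multipoint transmission probabilities
# ---------------------------------------------------------------------------

@dataclass
class InheritanceProbabilities:
    """P(haplotype 1 inherited) per (offspring, parent) pair on a cM grid."""

    lmap: LinkageMap
    pairs: list[tuple[str, str]]
    grid: dict[int, np.ndarray]          # chrom -> positions (cM)
    P: dict[int, np.ndarray]             # chrom -> (n_pairs, n_grid)
    flagged: set[tuple[str, int]] = field(default_factory=set)
    # (parent, chrom) pairs with no informative marker anywhere

    @property
    def pair_index(self) -> dict[tuple[str, str], int]:
        return {p: i for i, p in enumerate(self.pairs)}

    def at(self, chrom: int, pos: float) -> np.ndarray:
        """Column of probabilities at a grid position (must be on the grid)."""
        gpos = self.grid[chrom]
        j = int(np.argmin(np.abs(gpos - pos)))
        if abs(gpos[j] - pos) > 1e-9:
            raise ValidationError(
                f"position {pos} cM not on the evaluation grid of chromosome {chrom}"
            )
        return self.P[chrom][:, j]


def _build_grid(positions: np.ndarray, step: float | None) -> np.ndarray:
    pts = set(np.round(positions, 6).tolist())
    if step:
        x = 0.0
        stop = float(positions.max())
        while x <= stop + 1e-9:
            pts.add(round(x, 6))
            x += step
    return np.array(sorted(pts))


def transmission_probabilities(phased: PhasedGenotypes,
                               lmap: LinkageMap | None = None,
                               grid_step: float | None = 5.0
                               ) -> InheritanceProbabilities:
    """Interpolate haplotype-1 probabilities between informative markers.

    At each grid position the probability is conditioned on the nearest
    informative flanking markers (Haldane map function); this equals the full
    multipoint conditional because transmission along a chromosome is Markov
    and intervening uninformative markers carry no information.  At an
    informative marker the probability is exactly the observation; with no
    informative flank it is 0.5.
    """
    lmap = lmap or phased.lmap
    n_pairs = len(phased.pairs)
    grid: dict[int, np.ndarray] = {}
    P: dict[int, np.ndarray] = {}
    flagged: set[tuple[str, int]] = set()

    for chrom in lmap.chromosomes:
        mpos = lmap.markers_on(chrom)["pos"].to_numpy()
        Hc = phased.H[chrom]
        Bc = phased.blocks[chrom]
        gx = _build_grid(mpos, grid_step)
        M = len(mpos)
        obs = ~np.isnan(Hc)
        # last informative marker index at or before j / first at or after j
        idx = np.where(obs, np.arange(M)[None, :], -1)
        left_at = np.maximum.accumulate(idx, axis=1)
        idx_r = np.where(obs, np.arange(M)[None, :], M)
        right_at = np.minimum.accumulate(idx_r[:, ::-1], axis=1)[:, ::-1]

        Pc = np.full((n_pairs, len(gx)), 0.5)
        for gj, x in enumerate(gx):
            jl = int(np.searchsorted(mpos, x + 1e-9) - 1)   # last marker <= x
            jr = int(np.searchsorted(mpos, x - 1e-9))       # first marker >= x
            L = left_at[:, jl] if jl >= 0 else np.full(n_pairs, -1)
            R = right_at[:, jr] if jr < M else np.full(n_pairs, M)
            has_l = L >= 0
            has_r = R < M
            Ls = np.where(has_l, L, 0)
            Rs = np.where(has_r, R, 0)
            # different phase blocks: keep only the nearer flank
            both = has_l & has_r
            cross = both & (np.take_along_axis(Bc, Ls[:, None], 1)[:, 0]
                            != np.take_along_axis(Bc, Rs[:, None], 1)[:, 0])
            dl = x - mpos[Ls]
            dr = mpos[Rs] - x
            drop_l = cross & (dl > dr)
            drop_r = cross & ~drop_l
            has_l = has_l & ~drop_l
            has_r = has_r & ~drop_r
            both = has_l & has_r
            hl = np.take_along_axis(Hc, Ls[:, None], 1)[:, 0]
            hr = np.take_along_axis(Hc, Rs[:, None], 1)[:, 0]
            rl = haldane(dl)
            rr = haldane(dr)
            p = np.full(n_pairs, 0.5)
            # single-flank conditioning
            only_l = has_l & ~has_r
            p[only_l] = hl[only_l] * (1 - rl[only_l]) + (1 - hl[only_l]) * rl[only_l]
            only_r = has_r & ~has_l
            p[only_r] = hr[only_r] * (1 - rr[only_r]) + (1 - hr[only_r]) * rr[only_r]
            # double-flank conditioning
            fl1 = np.where(hl == 1.0, 1 - rl, rl)    # P(left obs -> state 1)
            fl0 = np.where(hl == 1.0, rl, 1 - rl)
            fr1 = np.where(hr == 1.0, 1 - rr, rr)    # P(state 1 -> right obs)
            fr0 = np.where(hr == 1.0, rr, 1 - rr)
            num = fl1 * fr1
            den = num + fl0 * fr0
            with np.errstate(invalid="ignore"):
                pb = num / den
            p[both] = pb[both]
            Pc[:, gj] = p
        grid[chrom] = gx
        P[chrom] = Pc

        informative = obs.any(axis=1)
        for i, (off, parent) in enumerate(phased.pairs):
            if not informative[i]:
                flagged.add((parent, chrom))

    return InheritanceProbabilities(lmap, phased.pairs, grid, P, flagged)


# ---------------------------------------------------------------------------
# Gametic design matrix and IBD matrices
# ---------------------------------------------------------------------------

def gametic_design(inh: InheritanceProbabilities, structure: FamilyStructure,
                   chrom: int, pos: float, ids: list[str]
                   ) -> tuple[np.ndarray, list[tuple[str, int]]]:
    """Gametic design matrix W at a position for the given individuals.

    Columns are parental haplotypes (parent, 1|2); for an offspring the row
    holds p/sqrt(2) and (1-p)/sqrt(2) in its dam's and sire's column pairs;
    a parent scores 1/sqrt(2) on both of its own columns.  W @ W.T matches the
    pairwise IBD allele-sharing fractions off the diagonal.
    """
    parents = structure.parents
    cols = [(p, h) for p in parents for h in (1, 2)]
    col_idx = {c: k for k, c in enumerate(cols)}
    pcol = inh.at(chrom, pos)
    pidx = inh.pair_index
    W = np.zeros((len(ids), len(cols)))
    s = 1.0 / np.sqrt(2.0)
    parent_set = set(parents)
    for i, ind in enumerate(ids):
        if ind in parent_set:
            W[i, col_idx[(ind, 1)]] = s
            W[i, col_idx[(ind, 2)]] = s
        else:
            dam, sire = structure.parents_of(ind)
            for par in (dam, sire):
                p = pcol[pidx[(ind, par)]]
                W[i, col_idx[(par, 1)]] = p * s
                W[i, col_idx[(par, 2)]] = (1 - p) * s
    return W, cols


def psd_factor(mat: np.ndarray, floor: float = PSD_EIG_FLOOR) -> np.ndarray:
    """Symmetric PSD repair: clip eigenvalues below ``floor``, return factor F
    with F @ F.T reproducing the repaired matrix."""
    w, U = np.linalg.eigh((mat + mat.T) / 2.0)
    w = np.clip(w, floor, None)
    return U * np.sqrt(w)


@dataclass
class IBDMatrix:
    """Locus-specific IBD allele-sharing matrix with its factor."""

    ids: list[str]
    matrix: np.ndarray
    factor: np.ndarray
    chrom: int
    pos: float

    def to_text(self, path) -> None:
        import pandas as pd
        pd.DataFrame(self.matrix, index=self.ids, columns=self.ids).to_csv(
            path, sep="\t", float_format="%.6f")


def ibd_at_position(inh: InheritanceProbabilities, structure: FamilyStructure,
                    chrom: int, pos: float, ids: list[str] | None = None
                    ) -> IBDMatrix:
    """Pairwise expected IBD allele-sharing fractions at one map position.

    Scale: expected fraction of allele pairs shared identical by descent, in
    [0,1] -- full sibs average 0.5 at a random locus, half sibs 0.25,
    parent-offspring exactly 0.5, unrelated founders 0.  Diagonal set to 1
    (no inbreeding in a two-generation design); the matrix is PSD-repaired
    and returned with its factor.
    """
    if chrom not in inh.grid:
        raise ValidationError(f"chromosome {chrom} outside the map")
    if pos < inh.grid[chrom].min() - 1e-9 or pos > inh.grid[chrom].max() + 1e-9:
        raise ValidationError(f"position {pos} cM outside chromosome {chrom}")
    if ids is None:
        ids = structure.parents + [o for f in structure.families.values()
                                   for o in f.offspring]
    W, _ = gametic_design(inh, structure, chrom, pos, ids)
    M = W @ W.T
    np.fill_diagonal(M, 1.0)
    F = psd_factor(M)
    return IBDMatrix(ids, F @ F.T, F, chrom, pos)


# ---------------------------------------------------------------------------
# Pedigree kinship
# ---------------------------------------------------------------------------

@dataclass
class KinshipMatrix:
    """Additive relationship matrix (tabular method) with a PSD factor."""

    ids: list[str]
    matrix: np.ndarray
    factor: np.ndarray


def pedigree_kinship(structure: FamilyStructure,
                     ids: list[str] | None = None) -> KinshipMatrix:
    """Additive relationship matrix on the additive-relationship scale
    (parent-offspring 0.5, full sibs 0.5, half sibs 0.25, founders I)."""
    parents = structure.parents
    offspring = [o for f in structure.families.values() for o in f.offspring]
    order = parents + offspring
    if set(parents) & set(offspring):
        raise ValidationError("cyclic pedigree: an individual is its own ancestor")
    idx = {ind: k for k, ind in enumerate(order)}
    n = len(order)
    A = np.zeros((n, n))
    A[: len(parents), : len(parents)] = np.eye(len(parents))
    for fam in structure.families.values():
        for off in fam.offspring:
            i = idx[off]
            d, s = idx[fam.dam], idx[fam.sire]
            A[i, :i] = 0.5 * (A[d, :i] + A[s, :i])
            A[:i, i] = A[i, :i]
            A[i, i] = 1.0 + 0.5 * A[d, s]
    if ids is not None:
        sel = [idx[i] for i in ids]
        A = A[np.ix_(sel, sel)]
        order = list(ids)
    F = psd_factor(A)
    return KinshipMatrix(order, A, F)


def kinship_lowrank(structure: FamilyStructure, ids: list[str]
                    ) -> tuple[np.ndarray, float]:
    """Low-rank + diagonal form of the offspring kinship: A = B B' + 0.5 I.

    Valid for non-inbred offspring of a two-generation pedigree; ``B`` has a
    0.5 entry in the dam and sire column of each offspring.
    """
    parents = structure.parents
    pidx = {p: k for k, p in enumerate(parents)}
    B = np.zeros((len(ids), len(parents)))
    for i, ind in enumerate(ids):
        dam, sire = structure.parents_of(ind)
        B[i, pidx[dam]] = 0.5
        B[i, pidx[sire]] = 0.5
    return B, 0.5
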