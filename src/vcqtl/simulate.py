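"""Gene-drop simulator for two-generation wild x domesticated cross designs.

The generator reproduces the statistical structure of common-garden QTL
mapping experiments on the domesticated-wild interface: founder strains with
drifted allele frequencies, full/half-sib mating designs mixing pure and
F1-hybrid crosses, meiosis with Haldane-model crossovers on a sparse SNP
linkage map, and growth phenotypes built from strain means, additive QTLs,
a pedigree polygenic term, gene-by-parent (allelic effect x mate)
interactions, sex effects and Gaussian residuals.  The hidden truth channel
(true gametes, QTL genotype values, breeding values) is kept alongside the
public dataset so every downstream stage can be validated end to end.

Presets ``dataset1`` .. ``dataset4`` mirror the four study designs: family
counts per cross type, 107 wild + 73 domesticated distinct parents overall,
109 genome-wide SNPs at 30 cM spacing, per-dataset phenotype means and
heritabilities, cumulative QTL variance shares, and gene-by-parent
interaction loci with within-family variance shares between 2.5 and 16.4%.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dataio import (DatasetTable, FamilyStructure, LinkageMap,
                     build_family_structure, read_parent_metadata)

# chromosomes 1-22: 90 cM, 23-29: 60 cM; markers every 30 cM -> 109 markers
DEFAULT_CHROM_LENGTHS = {c: (90.0 if c <= 22 else 60.0) for c in range(1, 30)}
DEFAULT_MARKER_STEP = 30.0


@dataclass(frozen=True)
class FamilySpec:
    family_id: str
    dam: str
    sire: str
    n_offspring: int


@dataclass(frozen=True)
class QTLConfig:
    """Additive QTL: haplotype effects drawn per founder haplotype.

    ``var`` is the target offspring-level variance contribution;
    ``dom_share`` the share of it carried by domesticated-founder haplotypes
    (None = neutral, proportional to allelic contribution).
    """

    chrom: int
    pos: float
    var: float
    dom_share: float | None = None


@dataclass(frozen=True)
class GxPConfig:
    """Gene-by-parent interaction: a shared parent's allelic effect flips
    sign (alternating by mate) with magnitude set so the interaction term
    accounts for ``pct_within_family`` percent of the within-family variance.
    """

    chrom: int
    pos: float
    parent: str
    pct_within_family: float


@dataclass(frozen=True)
class TraitConfig:
    name: str
    mean: float
    va: float                       # polygenic variance
    ve: float                       # residual variance
    strain_offsets: dict[str, float] = field(default_factory=dict)
    qtls: tuple[QTLConfig, ...] = ()
    gxp: tuple[GxPConfig, ...] = ()
    sex_effect: float = 0.0         # added to males
    replicate_effect: float = 0.0


@dataclass(frozen=True)
class SimulationConfig:
    name: str
    families: tuple[FamilySpec, ...]
    parent_strain: dict[str, str]
    strain_origin: dict[str, str]          # strain -> wild|domesticated
    parent_sex: dict[str, str]
    traits: tuple[TraitConfig, ...]
    chrom_lengths: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_CHROM_LENGTHS))
    marker_step: float = DEFAULT_MARKER_STEP
    fst: float = 0.1                       # strain drift from ancestral freqs
    freq_floor: float = 0.2                # informativeness floor on freqs
    fixed_allele_freq: float | None = None  # override: one freq for all markers
    n_replicates: int = 2
    sex_recorded_fraction: float = 0.0
    sex_loci: tuple[tuple[int, float, float], ...] = ()   # chrom,pos,frac sires
    seed: int = 0

    def __post_init__(self):
        for tr in self.traits:
            if tr.va < 0 or tr.ve < 0:
                raise ValueError(f"negative variance in trait {tr.name!r}")
        for _, length in self.chrom_lengths.items():
            if length < 0:
                raise ValueError("chromosome lengths must be non-negative")

    # -- derived -----------------------------------------------------------
    def marker_map(self) -> LinkageMap:
        rows = []
        for chrom in sorted(self.chrom_lengths):
            length = self.chrom_lengths[chrom]
            pos = 0.0
            k = 1
            while pos <= length + 1e-9:
                rows.append({"marker": f"c{chrom:02d}m{k}",
                             "chromosome": chrom, "pos": round(pos, 6)})
                pos += self.marker_step
                k += 1
        return LinkageMap(pd.DataFrame(rows))

    @property
    def parents(self) -> list[str]:
        seen: list[str] = []
        for fam in self.families:
            for p in (fam.dam, fam.sire):
                if p not in seen:
                    seen.append(p)
        return seen

    def origin_of(self, parent: str) -> str:
        return self.strain_origin[self.parent_strain[parent]]


@dataclass
class SimTruth:
    """Hidden truth channel: never written into the public dataset file."""

    offspring: list[str]
    dams: list[str]
    sires: list[str]
    origin_dam: np.ndarray              # (n_off, n_markers) in {0,1}
    origin_sire: np.ndarray
    extra_origins: dict[tuple[int, float], np.ndarray]   # (n_off, 2)
    breeding_values: dict[str, np.ndarray]
    qtl_values: dict[str, np.ndarray]
    male: np.ndarray
    qtl_positions: dict[str, list[tuple[int, float]]]
    gxp_effects: dict[str, list[dict]]


@dataclass
class SimulatedDataset:
    table: DatasetTable
    parent_meta: pd.DataFrame
    truth: SimTruth
    config: SimulationConfig
    lmap: LinkageMap

    def structure(self) -> FamilyStructure:
        return build_family_structure(self.table, self.parent_meta)


# ---------------------------------------------------------------------------
# Founders
# ---------------------------------------------------------------------------

def simulate_founders(config: SimulationConfig, rng: np.random.Generator
                      ) -> dict[str, np.ndarray]:
    """Phased founder haplotypes: parent -> (2, n_markers) allele codes.

    Per-marker strain frequencies follow a Balding-Nichols drift model around
    a shared ancestral frequency (drift parameter ``fst``), clipped to
    ``freq_floor`` so the sparse panel stays informative within families --
    emulating the study's preference for markers heterozygous in the parents.
    """
    lmap = config.marker_map()
    M = len(lmap.markers)
    strains = sorted(set(config.parent_strain.values()))
    if not config.parents:
        raise ValueError("configuration defines no founders")
    anc = rng.uniform(0.25, 0.75, size=M)
    f = config.fst
    freqs = {}
    for s in strains:
        if config.fixed_allele_freq is not None:
            freqs[s] = np.full(M, float(config.fixed_allele_freq))
            continue
        if f <= 0:
            freqs[s] = anc.copy()
        else:
            a = anc * (1 - f) / f
            b = (1 - anc) * (1 - f) / f
            freqs[s] = rng.beta(a, b)
        freqs[s] = np.clip(freqs[s], config.freq_floor, 1 - config.freq_floor)
    haplos = {}
    for p in config.parents:
        fr = freqs[config.parent_strain[p]]
        haplos[p] = (rng.random((2, M)) < fr).astype(np.int8)
    return haplos


# ---------------------------------------------------------------------------
# Meiosis
# ---------------------------------------------------------------------------

def meiosis_origins(length: float, positions: np.ndarray, n_gametes: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Haplotype-of-origin (0/1) at the given positions for each gamete.

    Crossovers: Poisson count with mean length/100 Morgans, positions
    uniform (Haldane model, no interference); the starting haplotype is
    fair-coin.
    """
    counts = rng.poisson(max(length, 0.0) / 100.0, size=n_gametes)
    start = rng.integers(0, 2, size=n_gametes)
    m = counts.max() if n_gametes else 0
    if m == 0:
        return np.repeat(start[:, None], len(positions), axis=1).astype(np.int8)
    xo = rng.uniform(0.0, length, size=(n_gametes, m))
    mask = np.arange(m)[None, :] < counts[:, None]
    xo = np.where(mask, xo, np.inf)
    crosses = (xo[:, :, None] <= positions[None, None, :]).sum(axis=1)
    return ((start[:, None] + crosses) % 2).astype(np.int8)


def simulate_cross(haplos: dict[str, np.ndarray], config: SimulationConfig,
                   rng: np.random.Generator):
    """Drop gametes through the mating design.

    Returns offspring ids, dam/sire lists, per-offspring genotype codes
    (n_off, n_markers, 2) and the true origins at markers and at every extra
    locus needed by the phenotype model (QTL, gene-by-parent and sex loci).
    """
    lmap = config.marker_map()
    mtab = lmap.table
    chroms = sorted(config.chrom_lengths)
    extra: set[tuple[int, float]] = set()
    for tr in config.traits:
        extra.update((q.chrom, q.pos) for q in tr.qtls)
        extra.update((g.chrom, g.pos) for g in tr.gxp)
    extra.update((c, p) for c, p, _ in config.sex_loci)
    extra = sorted(extra)

    offspring, dams, sires = [], [], []
    for fam in config.families:
        for k in range(fam.n_offspring):
            offspring.append(f"{fam.family_id}o{k + 1}")
            dams.append(fam.dam)
            sires.append(fam.sire)
    n = len(offspring)
    M = len(lmap.markers)
    origin_d = np.zeros((n, M), dtype=np.int8)
    origin_s = np.zeros((n, M), dtype=np.int8)
    extra_origin = {xp: np.zeros((n, 2), dtype=np.int8) for xp in extra}

    for chrom in chroms:
        sel = mtab["chromosome"] == chrom
        mcols = np.flatnonzero(sel.to_numpy())
        mpos = mtab["pos"][sel].to_numpy()
        xp_here = [xp for xp in extra if xp[0] == chrom]
        allpos = np.concatenate([mpos, [p for _, p in xp_here]])
        length = config.chrom_lengths[chrom]
        for par_k, (origin_mat, par_list) in enumerate(
                ((origin_d, dams), (origin_s, sires))):
            og = meiosis_origins(length, allpos, n, rng)
            origin_mat[:, mcols] = og[:, : len(mpos)]
            for j, xp in enumerate(xp_here):
                extra_origin[xp][:, par_k] = og[:, len(mpos) + j]

    # genotype codes: allele from dam gamete and sire gamete at each marker
    dam_h = np.stack([haplos[d] for d in dams])       # (n, 2, M)
    sire_h = np.stack([haplos[s] for s in sires])
    ar = np.arange(M)
    geno = np.stack([
        dam_h[np.arange(n)[:, None], origin_d, ar[None, :]],
        sire_h[np.arange(n)[:, None], origin_s, ar[None, :]],
    ], axis=2)
    return offspring, dams, sires, geno, origin_d, origin_s, extra_origin


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def _haplotype_effects(config: SimulationConfig, qtl: QTLConfig,
                       dams: list[str], sires: list[str],
                       rng: np.random.Generator) -> dict[tuple[str, int], float]:
    """One effect per founder haplotype, scaled to the target variance."""
    parents = config.parents
    if qtl.dom_share is None:
        tau = {p: np.sqrt(qtl.var / 2.0) for p in parents}
    else:
        slots = [config.origin_of(p) == "domesticated"
                 for pair in zip(dams, sires) for p in pair]
        w_dom = float(np.mean(slots))
        w_dom = min(max(w_dom, 1e-6), 1 - 1e-6)
        tau_d = np.sqrt(qtl.var * qtl.dom_share / (2.0 * w_dom))
        tau_w = np.sqrt(qtl.var * (1 - qtl.dom_share) / (2.0 * (1 - w_dom)))
        tau = {p: (tau_d if config.origin_of(p) == "domesticated" else tau_w)
               for p in parents}
    return {(p, h): rng.normal(0.0, tau[p]) for p in parents for h in (0, 1)}


def simulate_phenotypes(config: SimulationConfig, offspring, dams, sires,
                        extra_origin, male: np.ndarray,
                        rng: np.random.Generator):
    """Assemble trait values; returns (values, truth components) per trait."""
    n = len(offspring)
    parents = config.parents
    values: dict[str, np.ndarray] = {}
    bvs: dict[str, np.ndarray] = {}
    qtl_vals: dict[str, np.ndarray] = {}
    gxp_info: dict[str, list[dict]] = {}
    rep = np.array([(i % config.n_replicates) + 1 for i in range(n)])

    for tr in config.traits:
        # polygenic: founder values + Mendelian sampling
        founder_bv = {p: rng.normal(0.0, np.sqrt(tr.va)) for p in parents}
        mend = rng.normal(0.0, np.sqrt(tr.va / 2.0), size=n) if tr.va > 0 \
            else np.zeros(n)
        bv = np.array([0.5 * (founder_bv[d] + founder_bv[s])
                       for d, s in zip(dams, sires)]) + mend
        # additive QTLs
        qv = np.zeros(n)
        for q in tr.qtls:
            eff = _haplotype_effects(config, q, dams, sires, rng)
            og = extra_origin[(q.chrom, q.pos)]
            qv += np.array([eff[(d, og[i, 0])] + eff[(s, og[i, 1])]
                            for i, (d, s) in enumerate(zip(dams, sires))])
        # gene-by-parent interactions
        gxp_terms = np.zeros(n)
        v0 = tr.ve + tr.va / 2.0 + sum(q.var for q in tr.qtls) / 2.0
        infos = []
        for g in tr.gxp:
            qfrac = g.pct_within_family / 100.0
            og = extra_origin[(g.chrom, g.pos)]
            mates = sorted({(s if d == g.parent else d)
                            for d, s in zip(dams, sires)
                            if g.parent in (d, s)})
            n_grp = sum(g.parent in (d, s) for d, s in zip(dams, sires))
            # the requested share is the *observed* SS ratio: its numerator
            # picks up (m-1) degrees of freedom of noise, so the first-order
            # correction keeps the expected measured share on target
            eps = (len(mates) - 1) * v0 / max(n_grp, 1)
            t = max(qfrac * v0 / (1.0 - qfrac) - eps, 0.0)
            a = 2.0 * np.sqrt(t)
            sign = {m: (1.0 if k % 2 == 0 else -1.0)
                    for k, m in enumerate(mates)}
            term = np.zeros(n)
            for i, (d, s) in enumerate(zip(dams, sires)):
                if d == g.parent:
                    term[i] = sign[s] * a * (og[i, 0] - 0.5)
                elif s == g.parent:
                    term[i] = sign[d] * a * (og[i, 1] - 0.5)
            gxp_terms += term
            infos.append({"chrom": g.chrom, "pos": g.pos, "parent": g.parent,
                          "mates": mates, "effect": a,
                          "target_pct": g.pct_within_family})
        fixed = np.array([
            0.5 * (tr.strain_offsets.get(config.parent_strain[d], 0.0)
                   + tr.strain_offsets.get(config.parent_strain[s], 0.0))
            for d, s in zip(dams, sires)
        ])
        fixed = fixed + tr.replicate_effect * (rep - (config.n_replicates + 1) / 2.0)
        fixed = fixed + tr.sex_effect * male
        resid = rng.normal(0.0, np.sqrt(tr.ve), size=n)
        y = tr.mean - fixed.mean() + fixed + bv + qv + gxp_terms + resid
        y = np.maximum(y, 0.02 * tr.mean)
        values[tr.name] = y
        bvs[tr.name] = bv
        qtl_vals[tr.name] = qv
        gxp_info[tr.name] = infos
    return values, bvs, qtl_vals, gxp_info, rep


# ---------------------------------------------------------------------------
# Full dataset
# ---------------------------------------------------------------------------

_ALLELE = np.array(["A", "B"])


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Run the full gene-drop simulation for one configuration."""
    rng = np.random.default_rng(config.seed)
    lmap = config.marker_map()
    haplos = simulate_founders(config, rng)
    # marker ascertainment: the study selected SNPs for maximal information
    # content within families (heterozygous parents prioritised).  At a
    # configured gene-by-parent locus the carrier parent is therefore made
    # heterozygous and its mates homozygous, so the carrier's transmissions
    # at that marker are fully observable.
    mt = lmap.table
    pair_sets = {}
    for fam in config.families:
        pair_sets.setdefault(fam.dam, set()).add(fam.sire)
        pair_sets.setdefault(fam.sire, set()).add(fam.dam)
    for tr in config.traits:
        for g in tr.gxp:
            on = mt[mt["chromosome"] == g.chrom]
            k = int(on.index[np.argmin(np.abs(on["pos"].to_numpy() - g.pos))])
            haplos[g.parent][0, k] = 0
            haplos[g.parent][1, k] = 1
            for mate in pair_sets.get(g.parent, ()):
                haplos[mate][:, k] = 0
    (offspring, dams, sires, geno, origin_d, origin_s,
     extra_origin) = simulate_cross(haplos, config, rng)
    n = len(offspring)

    # phenotypic sex: sire-transmitted determinant on configured chromosomes
    male = rng.integers(0, 2, size=n).astype(float)
    if config.sex_loci:
        sire_list = sorted(set(sires))
        fracs = np.array([f for _, _, f in config.sex_loci])
        fracs = fracs / fracs.sum()
        assign = rng.choice(len(config.sex_loci), size=len(sire_list), p=fracs)
        locus_of = {s: config.sex_loci[a][:2]
                    for s, a in zip(sire_list, assign)}
        for i, s in enumerate(sires):
            og = extra_origin[locus_of[s]]
            male[i] = float(og[i, 1] == 0)

    values, bvs, qtl_vals, gxp_info, rep = simulate_phenotypes(
        config, offspring, dams, sires, extra_origin, male, rng)

    # assemble the public table
    fam_of = []
    cross_of = []
    fam_by_pair = {}
    for fam in config.families:
        fam_by_pair[(fam.dam, fam.sire)] = fam.family_id
    for d, s in zip(dams, sires):
        fam_of.append(fam_by_pair[(d, s)])
        od = config.origin_of(d)
        os_ = config.origin_of(s)
        if od == os_ == "wild":
            cross_of.append("wild")
        elif od == os_ == "domesticated":
            cross_of.append("domesticated")
        elif od == "domesticated":
            cross_of.append("hybrid-DW")
        else:
            cross_of.append("hybrid-WD")

    recorded = np.zeros(n, dtype=bool)
    if config.sex_recorded_fraction > 0:
        recorded = rng.random(n) < config.sex_recorded_fraction
    sex_col = np.where(recorded, np.where(male == 1.0, "M", "F"), "")

    traits = {tr.name: values[tr.name] for tr in config.traits}
    weight = traits.get("weight", np.full(n, np.nan))
    length = traits.get("length", np.full(n, np.nan))

    geno_sorted = np.sort(geno, axis=2)
    geno_str = (_ALLELE[geno_sorted[:, :, 0]].astype(object)
                + _ALLELE[geno_sorted[:, :, 1]])
    parents = config.parents
    prow_geno = []
    for p in parents:
        h = np.sort(haplos[p], axis=0)
        prow_geno.append(_ALLELE[h[0]].astype(object) + _ALLELE[h[1]])

    df = pd.DataFrame({
        "id": parents + offspring,
        "dam": [""] * len(parents) + dams,
        "sire": [""] * len(parents) + sires,
        "family": [""] * len(parents) + fam_of,
        "cross": [""] * len(parents) + cross_of,
        "length": [np.nan] * len(parents) + list(length),
        "weight": [np.nan] * len(parents) + list(weight),
        "replicate": [""] * len(parents) + [f"r{r}" for r in rep],
        "sex": [config.parent_sex.get(p, "") for p in parents] + list(sex_col),
    })
    gmat = np.vstack([np.vstack(prow_geno), geno_str])
    gdf = pd.DataFrame(gmat, columns=lmap.markers)
    table = DatasetTable(df, gdf, lmap)

    parent_meta = pd.DataFrame({
        "parent": parents,
        "strain": [config.parent_strain[p] for p in parents],
        "origin": [config.origin_of(p) for p in parents],
        "sex": [config.parent_sex.get(p, "") for p in parents],
    })
    truth = SimTruth(
        offspring=offspring, dams=dams, sires=sires,
        origin_dam=origin_d, origin_sire=origin_s,
        extra_origins=extra_origin,
        breeding_values=bvs, qtl_values=qtl_vals, male=male,
        qtl_positions={tr.name: [(q.chrom, q.pos) for q in tr.qtls]
                       for tr in config.traits},
        gxp_effects=gxp_info,
    )
    return SimulatedDataset(table, parent_meta, truth, config, lmap)


def generate_dataset(config: SimulationConfig, outdir) -> dict[str, str]:
    """Simulate and write dataset, map, parent metadata and truth files."""
    import os

    from .dataio import write_dataset, write_linkage_map

    sim = simulate_dataset(config)
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "dataset": os.path.join(outdir, f"{config.name}.csv"),
        "map": os.path.join(outdir, f"{config.name}.map"),
        "parents": os.path.join(outdir, f"{config.name}.parents"),
        "truth": os.path.join(outdir, f"{config.name}.truth.tsv"),
    }
    write_dataset(sim.table, paths["dataset"])
    write_linkage_map(sim.lmap, paths["map"])
    sim.parent_meta.to_csv(paths["parents"], sep="\t", index=False)
    tr = sim.truth
    rows = {"id": tr.offspring, "dam": tr.dams, "sire": tr.sires,
            "male": tr.male.astype(int)}
    for name, bv in tr.breeding_values.items():
        rows[f"bv_{name}"] = bv
        rows[f"qtl_{name}"] = tr.qtl_values[name]
    origin_cols = {}
    for k, m in enumerate(sim.lmap.markers):
        origin_cols[f"od_{m}"] = tr.origin_dam[:, k]
        origin_cols[f"os_{m}"] = tr.origin_sire[:, k]
    truth_df = pd.concat([pd.DataFrame(rows), pd.DataFrame(origin_cols)],
                         axis=1)
    truth_df.to_csv(paths["truth"], sep="\t", index=False)
    return paths


# ---------------------------------------------------------------------------
# Small generic configurations (used throughout the test-suite)
# ---------------------------------------------------------------------------

def simple_config(n_families: int = 10, offspring_per_family: int = 20,
                  n_chrom: int = 3, chrom_length: float = 90.0,
                  marker_step: float = 30.0, va: float = 20.0,
                  ve: float = 80.0, mean: float = 50.0,
                  qtls: tuple[QTLConfig, ...] = (),
                  gxp_pct: float | None = None,
                  gxp_locus: tuple[int, float] = (1, 30.0),
                  half_sib: bool = True, seed: int = 0,
                  strain_gap: float = 10.0,
                  freq_floor: float = 0.2) -> SimulationConfig:
    """A compact wild x domesticated design for tests and calibration runs.

    Families alternate wild, domesticated and hybrid crosses; consecutive
    even/odd family pairs share a sire when ``half_sib`` so gene-by-parent
    contrasts are estimable.  When ``gxp_pct`` is set, the first shared sire
    carries a sign-flipping allelic effect at ``gxp_locus``.
    """
    strains = {"farm": "domesticated", "river": "wild"}
    fams = []
    parent_strain = {}
    parent_sex = {}
    kinds = ["wild", "domesticated", "hybrid"]
    n_sires = 0
    shared_sires = []
    for k in range(n_families):
        kind = kinds[k % 3]
        dam = f"d{k + 1}"
        if half_sib:
            if k % 2 == 0:
                n_sires += 1
                if k + 1 < n_families:
                    shared_sires.append(f"s{n_sires}")
            sire = f"s{n_sires}"
        else:
            sire = f"s{k + 1}"
        dstrain = "river" if kind == "wild" else "farm"
        sstrain = "farm" if kind == "domesticated" else "river"
        parent_strain[dam] = dstrain
        parent_strain.setdefault(sire, sstrain)
        parent_sex[dam] = "F"
        parent_sex[sire] = "M"
        fams.append(FamilySpec(f"f{k + 1:02d}", dam, sire,
                               offspring_per_family))
    gxp = ()
    if gxp_pct is not None:
        if not shared_sires:
            raise ValueError("gxp requires half_sib=True and >=2 families")
        gxp = (GxPConfig(gxp_locus[0], gxp_locus[1], shared_sires[0],
                         gxp_pct),)
    trait = TraitConfig("weight", mean=mean, va=va, ve=ve,
                        strain_offsets={"farm": strain_gap / 2.0,
                                        "river": -strain_gap / 2.0},
                        qtls=tuple(qtls), gxp=gxp)
    return SimulationConfig(
        name="simple", families=tuple(fams), parent_strain=parent_strain,
        strain_origin=strains, parent_sex=parent_sex, traits=(trait,),
        chrom_lengths={c: chrom_length for c in range(1, n_chrom + 1)},
        marker_step=marker_step, freq_floor=freq_floor, seed=seed)
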