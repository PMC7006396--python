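"""Reading, validation and writing of the cross dataset format.

The dataset file is a semicolon-separated text table with seven fixed leading
columns -- individual ID, dam ID, sire ID, family ID, cross type, length (cm),
weight (g) -- followed by one column per SNP marker.  Optional ``replicate``
and ``sex`` columns may appear between the fixed block and the genotype block.
Founders (the parental generation) appear as rows whose dam and sire fields
are missing.  Genotypes are diploid allele pairs written as two characters
(e.g. ``AB``); ``00``, ``--`` or an empty field denote a missing call.

A 3-column linkage map (marker, chromosome, female-map position in cM) and an
optional 4-column parent metadata table (parent, strain, origin, sex) complete
the inputs.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING_GENO = "00"
_MISSING_TOKENS = {"", "0", "00", "--", "NA", "nan", "None"}
_FIXED_COLS = ["id", "dam", "sire", "family", "cross", "length", "weight"]
_OPTIONAL_COLS = ["replicate", "sex"]


class ValidationError(ValueError):
    """Raised when a dataset, map or metadata file violates its contract."""


# ---------------------------------------------------------------------------
# Linkage map
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LinkageMap:
    """Marker order on the (female) recombination map.

    Attributes
    ----------
    table:
        DataFrame with columns ``marker``, ``chromosome`` (int) and ``pos``
        (cM from the chromosome start, 0-based), sorted by chromosome then
        position, strictly increasing within each chromosome.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        for col in ("marker", "chromosome", "pos"):
            if col not in t.columns:
                raise ValidationError(f"linkage map lacks column {col!r}")
        if t["marker"].duplicated().any():
            dups = t["marker"][t["marker"].duplicated()].tolist()
            raise ValidationError(f"duplicated markers in map: {dups}")
        for chrom, grp in t.groupby("chromosome"):
            d = np.diff(grp["pos"].to_numpy())
            if len(d) and (d <= 0).any():
                raise ValidationError(
                    f"map positions not strictly increasing on chromosome {chrom}"
                )

    @property
    def markers(self) -> list[str]:
        return self.table["marker"].tolist()

    @property
    def chromosomes(self) -> list[int]:
        return sorted(self.table["chromosome"].unique().tolist())

    def markers_on(self, chrom: int) -> pd.DataFrame:
        sub = self.table[self.table["chromosome"] == chrom]
        if sub.empty:
            raise ValidationError(f"chromosome {chrom} not in map")
        return sub

    def length_of(self, chrom: int) -> float:
        return float(self.markers_on(chrom)["pos"].max())

    def position_of(self, marker: str) -> tuple[int, float]:
        row = self.table[self.table["marker"] == marker]
        if row.empty:
            raise ValidationError(f"marker {marker!r} not in map")
        return int(row["chromosome"].iloc[0]), float(row["pos"].iloc[0])


def read_linkage_map(path) -> LinkageMap:
    """Read a 3-column (marker, chromosome, cM) whitespace/; separated map."""
    df = pd.read_csv(path, sep=None, engine="python", header=None,
                     names=["marker", "chromosome", "pos"], comment="#",
                     skip_blank_lines=True)
    # tolerate a header line
    if not str(df.iloc[0, 1]).lstrip("-").replace(".", "").isdigit():
        df = df.iloc[1:].reset_index(drop=True)
    df["marker"] = df["marker"].astype(str)
    df["chromosome"] = df["chromosome"].astype(int)
    df["pos"] = df["pos"].astype(float)
    df = df.sort_values(["chromosome", "pos"], kind="stable").reset_index(drop=True)
    return LinkageMap(df)


def write_linkage_map(lmap: LinkageMap, path) -> None:
    lmap.table.to_csv(path, sep="\t", index=False, header=False)


# ---------------------------------------------------------------------------
# Dataset table
# ---------------------------------------------------------------------------

@dataclass
class DatasetTable:
    """Validated two-generation dataset: pedigree, phenotypes, genotypes.

    ``df`` holds the fixed columns (id, dam, sire, family, cross, length,
    weight, replicate, sex) indexed 0..n-1; ``genotypes`` is a parallel
    DataFrame of two-character allele strings with :data:`MISSING_GENO` for
    missing calls, columns in map order.
    """

    df: pd.DataFrame
    genotypes: pd.DataFrame
    lmap: LinkageMap

    def __post_init__(self) -> None:
        self._validate()

    # -- core accessors ----------------------------------------------------
    @property
    def ids(self) -> list[str]:
        return self.df["id"].tolist()

    @property
    def markers(self) -> list[str]:
        return list(self.genotypes.columns)

    def is_founder(self) -> pd.Series:
        return (self.df["dam"] == "") & (self.df["sire"] == "")

    @property
    def offspring(self) -> pd.DataFrame:
        return self.df[~self.is_founder()]

    @property
    def founders(self) -> pd.DataFrame:
        return self.df[self.is_founder()]

    def genotype_of(self, ind: str, marker: str) -> str:
        row = self.df.index[self.df["id"] == ind]
        if len(row) == 0:
            raise KeyError(ind)
        return self.genotypes.at[row[0], marker]

    def alleles_at(self, marker: str) -> list[str]:
        col = self.genotypes[marker]
        alleles = set("".join(col[col != MISSING_GENO]))
        return sorted(alleles)

    # -- validation --------------------------------------------------------
    def _validate(self) -> None:
        df = self.df
        if df["id"].duplicated().any():
            dups = df["id"][df["id"].duplicated()].tolist()
            raise ValidationError(f"duplicated individual IDs: {dups}")
        known = set(df["id"])
        bad_rows = []
        for _, row in df.iterrows():
            for pcol in ("dam", "sire"):
                p = row[pcol]
                if p and p not in known:
                    bad_rows.append((row["id"], pcol, p))
        if bad_rows:
            msg = "; ".join(f"row {i!r}: {c} {p!r} not in file" for i, c, p in bad_rows)
            raise ValidationError(f"unresolvable parent references: {msg}")
        half = (df["dam"] == "") ^ (df["sire"] == "")
        if half.any():
            raise ValidationError(
                f"rows with exactly one parent recorded: {df['id'][half].tolist()}"
            )
        for col in ("length", "weight"):
            vals = df[col]
            bad = vals.notna() & (vals <= 0)
            if bad.any():
                raise ValidationError(
                    f"non-positive {col} for individuals {df['id'][bad].tolist()}"
                )
        mapped = set(self.lmap.markers)
        unmapped = [m for m in self.genotypes.columns if m not in mapped]
        if unmapped:
            raise ValidationError(f"genotype columns with no map entry: {unmapped}")
        # column order of SNPs follows the map
        order = [m for m in self.lmap.markers if m in self.genotypes.columns]
        self.genotypes = self.genotypes[order]

    # -- convenience -------------------------------------------------------
    def phenotype(self, name: str) -> pd.Series:
        if name not in ("weight", "length", "sex"):
            raise KeyError(name)
        if name == "sex":
            s = self.df["sex"].map({"F": 0.0, "M": 1.0})
            return s
        return self.df[name]

    def subset(self, ids) -> "DatasetTable":
        keep = self.df["id"].isin(set(ids))
        return DatasetTable(self.df[keep].reset_index(drop=True),
                            self.genotypes[keep.to_numpy()].reset_index(drop=True),
                            self.lmap)


def _norm_missing(tok: str) -> str:
    return "" if tok.strip() in _MISSING_TOKENS else tok.strip()


def _norm_geno(tok: str) -> str:
    tok = tok.strip().replace("/", "")
    if tok in _MISSING_TOKENS or len(tok) != 2:
        return MISSING_GENO
    return tok


def read_dataset(path, lmap: LinkageMap, sep: str = ";") -> DatasetTable:
    """Read and validate a dataset file.

    Parameters
    ----------
    path:
        Dataset file (or file-like) in the supplementary layout.
    lmap:
        Linkage map; every genotype column must match one of its markers.
    sep:
        Field separator; semicolon by default, pass ``"\\t"`` for tab files.
    """
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    cols = list(raw.columns)
    if len(cols) < 8:
        raise ValidationError("dataset file needs 7 fixed columns plus >=1 SNP column")
    rename = dict(zip(cols[:7], _FIXED_COLS))
    raw = raw.rename(columns=rename)
    rest = cols[7:]
    meta_cols = []
    while rest and rest[0].lower() in _OPTIONAL_COLS:
        meta_cols.append(rest.pop(0))
    mapped = set(lmap.markers)
    bad = [c for c in rest if c not in mapped]
    if bad:
        raise ValidationError(f"genotype columns with no map entry: {bad}")

    df = raw[_FIXED_COLS].copy()
    for c in ("id", "dam", "sire", "family", "cross"):
        df[c] = df[c].map(_norm_missing)
    for c in ("length", "weight"):
        df[c] = pd.to_numeric(df[c].map(_norm_missing), errors="coerce")
    df["replicate"] = ""
    df["sex"] = ""
    for c in meta_cols:
        lc = c.lower()
        df[lc] = raw[c].map(_norm_missing)
    df["sex"] = df["sex"].str.upper().map(lambda s: s if s in ("F", "M") else "")

    geno = raw[rest].copy()
    for c in rest:
        geno[c] = geno[c].map(_norm_geno)
    return DatasetTable(df.reset_index(drop=True), geno.reset_index(drop=True), lmap)


def write_dataset(table: DatasetTable, path, sep: str = ";") -> None:
    """Write a dataset back to disk (inverse of :func:`read_dataset`)."""
    df = table.df.copy()
    for c in ("length", "weight"):
        df[c] = df[c].map(lambda v: "" if pd.isna(v) else f"{v:g}")
    cols = _FIXED_COLS + [c for c in _OPTIONAL_COLS
                          if (df[c] != "").any()]
    out = pd.concat([df[cols], table.genotypes], axis=1)
    text = out.to_csv(sep=sep, index=False)
    if hasattr(path, "write"):
        path.write(text)
    else:
        with open(path, "w") as fh:
            fh.write(text)


# ---------------------------------------------------------------------------
# Family structure
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Family:
    family_id: str
    dam: str
    sire: str
    cross_type: str
    offspring: tuple[str, ...]


@dataclass
class FamilyStructure:
    """Full-sib families, half-sib groups, and parent origin labels."""

    families: dict[str, Family]
    parent_origin: dict[str, str]      # parent -> "wild" | "domesticated"
    parent_strain: dict[str, str]
    parent_sex: dict[str, str]         # "F" | "M" | ""
    half_sib_groups: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    # parent -> [(family_id, mate), ...] for parents with >=2 mates

    def __post_init__(self) -> None:
        if not self.half_sib_groups:
            mates: dict[str, list[tuple[str, str]]] = {}
            for fam in self.families.values():
                mates.setdefault(fam.dam, []).append((fam.family_id, fam.sire))
                mates.setdefault(fam.sire, []).append((fam.family_id, fam.dam))
            self.half_sib_groups = {p: v for p, v in mates.items() if len(v) >= 2}

    @property
    def parents(self) -> list[str]:
        seen = []
        for fam in self.families.values():
            for p in (fam.dam, fam.sire):
                if p not in seen:
                    seen.append(p)
        return seen

    @property
    def n_families(self) -> int:
        return len(self.families)

    def n_parents(self, origin: str | None = None) -> int:
        if origin is None:
            return len(self.parents)
        return sum(1 for p in self.parents if self.parent_origin.get(p) == origin)

    def parents_of(self, offspring_id: str) -> tuple[str, str]:
        for fam in self.families.values():
            if offspring_id in fam.offspring:
                return fam.dam, fam.sire
        raise KeyError(offspring_id)

    def family_of(self, offspring_id: str) -> Family:
        for fam in self.families.values():
            if offspring_id in fam.offspring:
                return fam
        raise KeyError(offspring_id)

    def offspring_of(self, parent: str) -> list[str]:
        out = []
        for fam in self.families.values():
            if parent in (fam.dam, fam.sire):
                out.extend(fam.offspring)
        return out

    def summary(self) -> dict:
        return {
            "n_families": self.n_families,
            "n_offspring": sum(len(f.offspring) for f in self.families.values()),
            "n_parents_wild": self.n_parents("wild"),
            "n_parents_domesticated": self.n_parents("domesticated"),
            "n_half_sib_groups": len(self.half_sib_groups),
        }


_CROSS_ORIGINS = {
    "wild": ("wild", "wild"),
    "domesticated": ("domesticated", "domesticated"),
    "hybrid-dw": ("domesticated", "wild"),   # dam domesticated x sire wild
    "hybrid-wd": ("wild", "domesticated"),
}


def _origins_from_cross(cross: str) -> tuple[str, str] | None:
    return _CROSS_ORIGINS.get(cross.strip().lower())


def read_parent_metadata(path) -> pd.DataFrame:
    """Read a 4-column (parent, strain, origin, sex) table."""
    df = pd.read_csv(path, sep=None, engine="python", dtype=str,
                     keep_default_na=False, comment="#")
    df.columns = ["parent", "strain", "origin", "sex"][: len(df.columns)]
    df["origin"] = df["origin"].str.lower()
    df["sex"] = df["sex"].str.upper()
    return df


def build_family_structure(table: DatasetTable,
                           parent_meta: pd.DataFrame | None = None) -> FamilyStructure:
    """Group offspring into full-sib families and derive half-sib groups.

    Parent origin is resolved from explicit metadata when given, otherwise
    parsed from the family cross-type labels (``wild``, ``domesticated``,
    ``hybrid-DW``, ``hybrid-WD``); inconsistent labels raise.
    """
    fams: dict[str, Family] = {}
    rows = table.offspring
    for fam_id, grp in rows.groupby("family", sort=False):
        dams = grp["dam"].unique()
        sires = grp["sire"].unique()
        if len(dams) != 1 or len(sires) != 1:
            raise ValidationError(
                f"family {fam_id!r} has multiple parent pairs "
                f"(dams {dams.tolist()}, sires {sires.tolist()})"
            )
        crosses = [c for c in grp["cross"].unique() if c]
        cross = crosses[0] if crosses else ""
        fams[fam_id] = Family(fam_id, dams[0], sires[0], cross,
                              tuple(grp["id"].tolist()))

    origin: dict[str, str] = {}
    strain: dict[str, str] = {}
    sex: dict[str, str] = {}
    if parent_meta is not None:
        for _, r in parent_meta.iterrows():
            origin[r["parent"]] = r["origin"]
            strain[r["parent"]] = r["strain"]
            sex[r["parent"]] = r["sex"]

    conflicts = []
    for fam in fams.values():
        parsed = _origins_from_cross(fam.cross_type)
        if parsed is None:
            continue
        for p, o in zip((fam.dam, fam.sire), parsed):
            if p in origin and origin[p] != o and parent_meta is None:
                conflicts.append((p, origin[p], o))
            origin.setdefault(p, o)
    if conflicts:
        msg = "; ".join(f"{p}: {a} vs {b}" for p, a, b in conflicts)
        raise ValidationError(f"inconsistent parent origin labels: {msg}")

    all_parents = {p for f in fams.values() for p in (f.dam, f.sire)}
    missing = sorted(all_parents - set(origin))
    if missing:
        raise ValidationError(
            f"origin unresolvable for parents {missing}: provide parent metadata "
            f"or cross-type labels (wild/domesticated/hybrid-DW/hybrid-WD)"
        )
    # dam/sire position implies sex when metadata silent
    for fam in fams.values():
        sex.setdefault(fam.dam, "F")
        sex.setdefault(fam.sire, "M")
    return FamilyStructure(fams, origin, strain, sex)


# ---------------------------------------------------------------------------
# Parentage exclusion check
# ---------------------------------------------------------------------------

def _compatible(off: str, dam: str, sire: str) -> bool:
    """Mendelian compatibility of one unphased trio genotype."""
    o1, o2 = off[0], off[1]
    return ((o1 in dam and o2 in sire) or (o2 in dam and o1 in sire))


@dataclass
class ParentageConflicts:
    """Per-offspring Mendelian conflicts against the assigned parent pair."""

    conflicts: dict[str, list[str]]     # offspring -> conflicting markers
    skipped: dict[str, int]             # offspring -> markers skipped (missing)

    def excluded(self, threshold: int = 3) -> list[str]:
        """Offspring whose conflict count reaches the exclusion threshold."""
        return [o for o, ms in self.conflicts.items() if len(ms) >= threshold]

    @property
    def n_conflicts(self) -> int:
        return sum(len(v) for v in self.conflicts.values())


def parentage_exclusion_check(table: DatasetTable,
                              structure: FamilyStructure | None = None
                              ) -> ParentageConflicts:
    """Re-check parentage assignment by genotype exclusion.

    For each offspring, lists the markers at which it carries no allele pair
    transmissible by its assigned dam and sire.  Missing genotypes (offspring
    or either parent) are skipped and counted.  An empty conflict list means
    the SNP data are consistent with the pedigree.
    """
    df = table.df
    geno = table.genotypes.to_numpy()
    idx = {i: k for k, i in enumerate(df["id"])}
    conflicts: dict[str, list[str]] = {}
    skipped: dict[str, int] = {}
    markers = table.markers
    for k, row in df.iterrows():
        if not row["dam"]:
            continue
        og = geno[k]
        dg = geno[idx[row["dam"]]]
        sg = geno[idx[row["sire"]]]
        bad, skip = [], 0
        for m, (o, d, s) in enumerate(zip(og, dg, sg)):
            if MISSING_GENO in (o, d, s):
                skip += 1
                continue
            if not _compatible(o, d, s):
                bad.append(markers[m])
        if bad:
            conflicts[row["id"]] = bad
        if skip:
            skipped[row["id"]] = skip
    return ParentageConflicts(conflicts, skipped)
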