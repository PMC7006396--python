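"""Shared fixtures: small simulated crosses and hand-built family tables."""

import numpy as np
import pandas as pd
import pytest

from vcqtl.dataio import DatasetTable, LinkageMap
from vcqtl.gametic import phase_families, transmission_probabilities
from vcqtl.simulate import QTLConfig, simple_config, simulate_dataset


@pytest.fixture(scope="session")
def small_sim():
    """12 half-sib families x 25 offspring, one 12% QTL on chr 2."""
    cfg = simple_config(n_families=12, offspring_per_family=25, n_chrom=3,
                        marker_step=15.0, freq_floor=0.35,
                        qtls=(QTLConfig(2, 30.0, 20.0),), va=20.0, ve=85.0,
                        seed=42)
    sim = simulate_dataset(cfg)
    structure = sim.structure()
    phased = phase_families(sim.table, structure)
    inh = transmission_probabilities(phased, grid_step=None)
    return sim, structure, phased, inh


def make_map(markers):
    """markers: list of (name, chrom, pos)."""
    return LinkageMap(pd.DataFrame(markers,
                                   columns=["marker", "chromosome", "pos"]))


def make_table(rows, markers, lmap=None):
    """Hand-built DatasetTable.

    rows: list of dicts with id/dam/sire/family/cross/length/weight and one
    key per marker name holding the genotype string.
    """
    lmap = lmap or make_map(markers)
    names = [m[0] for m in markers] if isinstance(markers[0], tuple) else markers
    df = pd.DataFrame([{**{
        "id": r["id"], "dam": r.get("dam", ""), "sire": r.get("sire", ""),
        "family": r.get("family", ""), "cross": r.get("cross", ""),
        "length": r.get("length", np.nan), "weight": r.get("weight", np.nan),
        "replicate": r.get("replicate", ""), "sex": r.get("sex", ""),
    }} for r in rows])
    geno = pd.DataFrame([{m: r.get(m, "00") for m in names} for r in rows])
    return DatasetTable(df, geno, lmap)


@pytest.fixture()
def trio_fixture():
    """One family, three markers on one chromosome, fully informative dam."""
    markers = [("m1", 1, 0.0), ("m2", 1, 30.0), ("m3", 1, 60.0)]
    rows = [
        {"id": "D", "sex": "F", "m1": "AB", "m2": "AB", "m3": "AB"},
        {"id": "S", "sex": "M", "m1": "AA", "m2": "AA", "m3": "AA"},
    ]
    # dam haplotype 1 = (A,A,A), haplotype 2 = (B,B,B); first six offspring
    # inherit hap1 uncut, next four hap2 uncut
    for k in range(10):
        hap = "A" if k < 6 else "B"
        g = "".join(sorted(hap + "A"))
        rows.append({"id": f"o{k}", "dam": "D", "sire": "S", "family": "f1",
                     "cross": "hybrid-DW", "weight": 10.0,
                     "m1": g, "m2": g, "m3": g})
    return make_table(rows, markers)
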