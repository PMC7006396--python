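"""Study-design presets for the four mapping populations.

Each preset reproduces the corresponding experiment's structure: number of
full-sib families per cross type, parent sharing across families (which is
what creates the half-sib groups and keeps the distinct parent counts at
107 wild and 73 domesticated over the four designs), offspring sample sizes,
strain composition, phenotype means, heritabilities, cumulative QTL variance
shares and gene-by-parent interaction loci.

Per-QTL variances are allocated proportionally to the reported per-QTL
variance estimates, scaled so that the QTLs jointly account for the target
share of the genetic variance; heritability fixes the polygenic/residual
split.  Gene-by-parent effect sizes are derived from the requested share of
within-family variance.
"""

from __future__ import annotations

import numpy as np

from .simulate import (FamilySpec, GxPConfig, QTLConfig, SimulationConfig,
                       TraitConfig)


def _sizes(total: int, n_fam: int) -> list[int]:
    base = total // n_fam
    extra = total - base * n_fam
    return [base + 1 if k < extra else base for k in range(n_fam)]


def _qtls(chroms, positions, weights, total_var) -> tuple[QTLConfig, ...]:
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    return tuple(QTLConfig(c, p, float(total_var * wk))
                 for c, p, wk in zip(chroms, positions, w))


class _Pools:
    """Deterministic parent-id pools (P1, P2, ...) per role."""

    def __init__(self):
        self.count = 0
        self.sex: dict[str, str] = {}
        self.strain: dict[str, str] = {}

    def make(self, n, sex, strains):
        out = []
        for k in range(n):
            self.count += 1
            pid = f"P{self.count}"
            self.sex[pid] = sex
            self.strain[pid] = strains[k % len(strains)]
            out.append(pid)
        return out


def _build(name, fam_pairs, sizes, pools, strain_origin, traits, **kw):
    fams = tuple(
        FamilySpec(f"F{k + 1:02d}", dam, sire, n)
        for k, ((dam, sire), n) in enumerate(zip(fam_pairs, sizes))
    )
    return SimulationConfig(
        name=name, families=fams, parent_strain=pools.strain,
        strain_origin=strain_origin, parent_sex=pools.sex,
        traits=traits, **kw)


_WILD = "wild"
_DOM = "domesticated"


def _dataset1(seed: int) -> SimulationConfig:
    # 10 domesticated, 10 hybrid (dom dam x wild sire), 9 wild families;
    # hybrid families share their dams with the domesticated families and
    # (mostly) their sires with the wild families.
    p = _Pools()
    DD = p.make(10, "F", ["Mowi"])
    DS = p.make(10, "M", ["Mowi"])
    WD = p.make(9, "F", ["Figgjo"])
    WS = p.make(11, "M", ["Figgjo"])
    pairs = [(DD[i], DS[i]) for i in range(10)]          # domesticated
    pairs += [(DD[i], WS[i]) for i in range(10)]         # hybrid-DW
    pairs += [(WD[i], WS[i]) for i in range(8)] + [(WD[8], WS[10])]
    weight = TraitConfig(
        "weight", mean=62.2, va=24.0, ve=100.1,
        strain_offsets={"Mowi": 31.0, "Figgjo": -31.0},
        qtls=_qtls([1, 2, 3, 7, 8, 9, 19], [60, 30, 90, 60, 30, 30, 30],
                   [17.4, 24.4, 6.0, 7.5, 29.1, 22.4, 12.7], 11.8),
        gxp=(GxPConfig(9, 30.0, WS[0], 3.0),
             GxPConfig(22, 30.0, DD[1], 3.1)),
        sex_effect=3.0, replicate_effect=1.0)
    length = TraitConfig(
        "length", mean=16.6, va=0.63, ve=5.22,
        strain_offsets={"Mowi": 2.6, "Figgjo": -2.6},
        qtls=_qtls([1, 7, 8, 9, 19, 20], [60, 60, 30, 30, 30, 30],
                   [13.0, 18.4, 10.4, 19.5, 11.6, 9.6], 0.188),
        gxp=(GxPConfig(17, 0.0, DD[0], 2.5),
             GxPConfig(22, 30.0, DD[1], 2.7)),
        sex_effect=0.3, replicate_effect=0.1)
    return _build("dataset1", pairs, _sizes(2000, 29), p,
                  {"Mowi": _DOM, "Figgjo": _WILD}, (weight, length),
                  sex_recorded_fraction=1170 / 2000,
                  sex_loci=((2, 10.0, 0.62), (3, 40.0, 0.19),
                            (6, 40.0, 0.19)),
                  seed=seed)


def _dataset2(seed: int) -> SimulationConfig:
    # 20 wild, 6 domesticated, 15 reciprocal hybrid families (8 wild-dam,
    # 7 dom-dam); the reciprocal hybrids share parents with the pure crosses.
    p = _Pools()
    WD = p.make(18, "F", ["Figgjo"] * 8 + ["Arna", "Vosso", "Figgjo",
                                           "Arna", "Vosso", "Figgjo",
                                           "Arna", "Vosso", "Figgjo", "Arna"])
    WS = p.make(17, "M", ["Figgjo"] * 10 + ["Arna", "Vosso", "Figgjo",
                                            "Arna", "Vosso", "Figgjo", "Arna"])
    DD = p.make(10, "F", ["Mowi"])
    DS = p.make(10, "M", ["Mowi"])
    pairs = [(WD[i], WS[i]) for i in range(17)]                       # wild
    pairs += [(WD[17], WS[0]), (WD[8], WS[1]), (WD[9], WS[2])]        # wild
    pairs += [(DD[i], DS[i]) for i in range(6)]                       # dom
    pairs += [(WD[i], DS[[6, 7, 8, 9, 0, 1, 2, 3][i]]) for i in range(8)]
    pairs += [(DD[[6, 7, 8, 9, 0, 1, 2][i]], WS[3 + i]) for i in range(7)]
    weight = TraitConfig(
        "weight", mean=103.1, va=32.9, ve=170.8,
        strain_offsets={"Mowi": 150.0, "Figgjo": -44.0, "Arna": -47.0,
                        "Vosso": -45.0},
        qtls=_qtls([3, 6, 7, 9, 10, 11, 12, 15, 20, 21, 22, 28],
                   [90, 30, 90, 60, 30, 30, 30, 60, 0, 30, 30, 0],
                   [37.0, 45.8, 38.4, 40.7, 48.3, 49.3, 32.3, 51.3, 27.3,
                    39.8, 64.8, 36.1], 18.7),
        gxp=(GxPConfig(9, 60.0, WD[0], 5.2),
             GxPConfig(28, 30.0, WD[0], 4.0)),
        sex_effect=5.0, replicate_effect=1.5)
    length = TraitConfig(
        "length", mean=19.4, va=1.53, ve=9.64,
        strain_offsets={"Mowi": 3.8, "Figgjo": -1.2, "Arna": -1.4,
                        "Vosso": -1.3},
        qtls=_qtls([2, 6, 9, 11, 15, 20, 22, 28],
                   [60, 30, 60, 30, 60, 0, 30, 30],
                   [19.4, 43.0, 21.7, 27.4, 14.9, 11.9, 24.7, 13.3], 0.757),
        gxp=(GxPConfig(9, 60.0, WD[0], 5.2),
             GxPConfig(28, 30.0, WD[0], 3.8)),
        sex_effect=0.4, replicate_effect=0.15)
    return _build("dataset2", pairs, _sizes(2400, 41), p,
                  {"Mowi": _DOM, "Figgjo": _WILD, "Arna": _WILD,
                   "Vosso": _WILD}, (weight, length),
                  sex_recorded_fraction=1564 / 2400,
                  sex_loci=((2, 10.0, 0.80), (6, 40.0, 0.20)),
                  seed=seed)


def _dataset3(seed: int) -> SimulationConfig:
    # 10 wild, 10 domesticated, 9 hybrid (dom dam x wild sire) families.
    p = _Pools()
    WD = p.make(10, "F", ["Etne"])
    WS = p.make(10, "M", ["Etne"])
    DD = p.make(10, "F", ["Mowi"])
    DS = p.make(10, "M", ["Mowi"])
    pairs = [(WD[i], WS[i]) for i in range(10)]
    pairs += [(DD[i], DS[i]) for i in range(10)]
    pairs += [(DD[i], WS[i]) for i in range(9)]
    weight = TraitConfig(
        "weight", mean=22.6, va=4.01, ve=56.4,
        strain_offsets={"Mowi": 9.0, "Etne": -9.0},
        qtls=_qtls([2, 17], [60, 30], [1.7, 2.1], 0.51),
        gxp=(GxPConfig(4, 60.0, WS[0], 6.2),
             GxPConfig(5, 60.0, DD[0], 4.9),
             GxPConfig(11, 60.0, DD[1], 9.1)),
        replicate_effect=0.5)
    length = TraitConfig(
        "length", mean=11.6, va=0.266, ve=3.26,
        strain_offsets={"Mowi": 1.7, "Etne": -1.7},
        qtls=_qtls([2, 17], [60, 30], [11.5, 10.6], 0.038),
        gxp=(GxPConfig(4, 60.0, WS[0], 6.5),
             GxPConfig(5, 60.0, DD[0], 4.6),
             GxPConfig(11, 60.0, DD[1], 9.5)),
        replicate_effect=0.05)
    return _build("dataset3", pairs, _sizes(1128, 29), p,
                  {"Mowi": _DOM, "Etne": _WILD}, (weight, length), seed=seed)


def _dataset4(seed: int) -> SimulationConfig:
    # 19 wild, 8 domesticated (two strains), 8 hybrid families (4 dom-dam,
    # 4 wild-dam); the chromosome-17 gene-by-parent interaction sits on a
    # wild sire shared between a hybrid and a wild family.
    p = _Pools()
    wild_cycle = ["Figgjo", "Arna", "Vosso", "Driva", "Skibotn"]
    WD = p.make(16, "F", wild_cycle)
    WS = p.make(16, "M", wild_cycle)
    DD = p.make(6, "F", ["Farm1", "Farm1", "Farm1", "Farm2", "Farm2",
                         "Farm2"])
    DS = p.make(7, "M", ["Farm1", "Farm1", "Farm1", "Farm2", "Farm2",
                         "Farm2", "Farm2"])
    p.strain[WS[3]] = "Vosso"
    p.strain[WS[0]] = "Skibotn"
    p.strain[WD[0]] = "Skibotn"
    p.strain[WD[1]] = "Skibotn"
    pairs = [(WD[i], WS[i]) for i in range(16)]                      # wild
    pairs += [(WD[0], WS[2]), (WD[1], WS[0]), (WD[2], WS[1])]        # wild
    pairs += [(DD[i], DS[i]) for i in range(6)]
    pairs += [(DD[0], DS[6]), (DD[1], DS[0])]                        # dom
    pairs += [(DD[2 + i], WS[3 + i]) for i in range(4)]              # hyb-DW
    pairs += [(WD[3 + i], DS[1 + i]) for i in range(4)]              # hyb-WD
    weight = TraitConfig(
        "weight", mean=32.4, va=15.5, ve=49.1,
        strain_offsets={"Farm1": 10.0, "Farm2": 11.0, "Figgjo": -10.0,
                        "Arna": -9.0, "Vosso": -8.0, "Driva": -7.0,
                        "Skibotn": -6.0},
        qtls=_qtls([2, 6, 10, 21, 23], [60, 30, 30, 60, 30],
                   [10.6, 9.1, 8.1, 3.2, 2.4], 11.74),
        gxp=(GxPConfig(17, 30.0, WS[3], 16.4),
             GxPConfig(2, 60.0, WS[0], 8.6)),
        replicate_effect=0.8)
    length = TraitConfig(
        "length", mean=13.5, va=0.355, ve=1.47,
        strain_offsets={"Farm1": 1.25, "Farm2": 1.35, "Figgjo": -1.2,
                        "Arna": -1.1, "Vosso": -1.0, "Driva": -0.9,
                        "Skibotn": -0.8},
        qtls=_qtls([2, 6, 10, 21, 23], [60, 30, 30, 60, 30],
                   [35.6, 39.6, 25.5, 20.7, 8.1], 0.243),
        gxp=(GxPConfig(17, 30.0, WS[3], 14.1),
             GxPConfig(2, 60.0, WS[0], 9.7)),
        replicate_effect=0.08)
    return _build("dataset4", pairs, _sizes(1400, 35), p,
                  {"Farm1": _DOM, "Farm2": _DOM, "Figgjo": _WILD,
                   "Arna": _WILD, "Vosso": _WILD, "Driva": _WILD,
                   "Skibotn": _WILD}, (weight, length), seed=seed)


_PRESETS = {"dataset1": _dataset1, "dataset2": _dataset2,
            "dataset3": _dataset3, "dataset4": _dataset4}


def preset(name: str, seed: int = 0) -> SimulationConfig:
    """Return the configuration for one of ``dataset1`` .. ``dataset4``."""
    if name not in _PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from "
                       f"{sorted(_PRESETS)}")
    return _PRESETS[name](seed)
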