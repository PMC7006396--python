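"""Phasing, transmission probabilities, IBD and kinship.

The multipoint machinery is checked against an independent exhaustive
gamete-path enumeration oracle: every haplotype-origin vector over the
marker positions is weighted by its Haldane transition probabilities and
conditioned on the observed transmissions, which gives exact marginal and
pairwise quantities for small families.
"""

from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vcqtl.dataio import ValidationError, build_family_structure
from vcqtl.gametic import (haldane, haldane_inverse, ibd_at_position,
                           kinship_lowrank, pedigree_kinship, phase_families,
                           psd_factor, transmission_probabilities)

from conftest import make_table


# ---------------------------------------------------------------------------
# independent oracle
# ---------------------------------------------------------------------------

def enum_marginal(obs, query_pos):
    """P(haplotype 1 at query | observations) by path enumeration.

    ``obs``: list of (position_cM, observed_hap in {0,1}).
    """
    pos = sorted({p for p, _ in obs} | {query_pos})
    want = dict(obs)
    num = den = 0.0
    for path in product([0, 1], repeat=len(pos)):
        pr = 0.5
        for a, b, (p1, p2) in zip(path, path[1:], zip(pos, pos[1:])):
            r = haldane(p2 - p1)
            pr *= r if a != b else 1.0 - r
        if any(path[pos.index(p)] != h for p, h in want.items()):
            continue
        den += pr
        if path[pos.index(query_pos)] == 1:
            num += pr
    return num / den


def test_haldane_closed_form():
    assert haldane(0.0) == 0.0
    assert haldane(1e9) == pytest.approx(0.5)
    assert haldane(10.0) == pytest.approx(0.5 * (1 - np.exp(-0.2)))
    assert haldane_inverse(haldane(23.0)) == pytest.approx(23.0)


@given(st.floats(0.1, 400.0), st.floats(0.1, 400.0))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_haldane_monotone_and_bounded(d1, d2):
    r1, r2 = haldane(d1), haldane(d2)
    assert 0 < r1 < 0.5 and 0 < r2 < 0.5
    if d1 < d2:
        assert r1 <= r2


class TestTransmission:
    def _inh(self, table, grid_step=None):
        st_ = build_family_structure(table)
        return transmission_probabilities(phase_families(table, st_),
                                          grid_step=grid_step)

    def test_exact_at_informative_marker(self, trio_fixture):
        inh = self._inh(trio_fixture)
        p = inh.at(1, 0.0)
        idx = inh.pair_index
        by_off = {o: p[idx[(o, "D")]] for o in
                  [f"o{k}" for k in range(10)]}
        # first six offspring inherited one haplotype, last four the other
        first = by_off["o0"]
        assert first in (0.0, 1.0)
        assert all(by_off[f"o{k}"] == first for k in range(6))
        assert all(by_off[f"o{k}"] == 1.0 - first for k in range(6, 10))

    def test_homozygous_parent_uninformative(self, trio_fixture):
        inh = self._inh(trio_fixture)
        p = inh.at(1, 30.0)
        # the sire is homozygous everywhere: probability 0.5 and flagged
        assert all(p[inh.pair_index[(f"o{k}", "S")]] == 0.5
                   for k in range(10))
        assert ("S", 1) in inh.flagged

    def test_midpoint_matches_enumeration(self, trio_fixture):
        inh = self._inh(trio_fixture, grid_step=15.0)
        p = inh.at(1, 15.0)
        got = p[inh.pair_index[("o0", "D")]]
        h = 1 if inh.at(1, 0.0)[inh.pair_index[("o0", "D")]] == 1.0 else 0
        want = enum_marginal([(0.0, h), (30.0, h), (60.0, h)], 15.0)
        assert got == pytest.approx(want, abs=1e-12)
        # two agreeing flanks 30 cM apart: (1-r)^2 / ((1-r)^2 + r^2)
        r = haldane(15.0)
        expect = (1 - r) ** 2 / ((1 - r) ** 2 + r ** 2)
        assert max(got, 1 - got) == pytest.approx(expect, abs=1e-12)

    def test_continuity_between_markers(self, trio_fixture):
        inh = self._inh(trio_fixture, grid_step=1.0)
        grid = inh.grid[1]
        P = inh.P[1]
        steps = np.abs(np.diff(P, axis=1)).max()
        assert steps < 0.05  # 1 cM steps move the probability smoothly

    def test_phase_flip_preserves_magnitude(self, trio_fixture):
        # flipping which haplotype is labelled "1" maps p to 1-p
        inh = self._inh(trio_fixture)
        p = inh.at(1, 0.0)
        idx = inh.pair_index
        vals = sorted(p[idx[(f"o{k}", "D")]] for k in range(10))
        assert vals == [0.0] * 4 + [1.0] * 6 or vals == [0.0] * 6 + [1.0] * 4


class TestPhasing:
    def test_forced_origin_single_marker(self):
        rows = [{"id": "D", "m1": "AB"}, {"id": "S", "m1": "BB"},
                {"id": "o1", "dam": "D", "sire": "S", "family": "f",
                 "cross": "wild", "m1": "AB"}]
        t = make_table(rows, [("m1", 1, 0.0)])
        st_ = build_family_structure(t)
        ph = phase_families(t, st_)
        h = ph.H[1][ph.pair_index[("o1", "D")], 0]
        assert h in (0.0, 1.0)   # the A allele is forced to come from the dam

    def test_homozygous_marker_confidence_half(self, trio_fixture):
        st_ = build_family_structure(trio_fixture)
        ph = phase_families(trio_fixture, st_)
        assert np.all(ph.parent_phase[("S", 1)].confidence == 0.5)
        assert np.all(ph.parent_phase[("D", 1)].confidence == 1.0)

    def test_fully_informative_family_origin_accuracy(self):
        # dam heterozygous everywhere, sire homozygous: every transmission
        # is observable, so >=99% of dam alleles must be origin-labelled
        # correctly (up to the global haplotype-label flip per chromosome)
        rng = np.random.default_rng(5)
        markers = [(f"m{k}", 1, 15.0 * k) for k in range(7)]
        hap = {0: "A", 1: "B"}
        rows = [{"id": "D", **{m[0]: "AB" for m in markers}},
                {"id": "S", **{m[0]: "AA" for m in markers}}]
        truth = {}
        for k in range(20):
            origin = [rng.integers(0, 2)]
            for j in range(1, 7):
                flip = rng.random() < haldane(15.0)
                origin.append(origin[-1] ^ flip)
            truth[f"o{k}"] = origin
            rows.append({"id": f"o{k}", "dam": "D", "sire": "S",
                         "family": "f", "cross": "wild",
                         **{m[0]: "".join(sorted(hap[o] + "A"))
                            for m, o in zip(markers, origin)}})
        t = make_table(rows, markers)
        st_ = build_family_structure(t)
        ph = phase_families(t, st_)
        H = ph.H[1]
        agree = []
        for k in range(20):
            h = H[ph.pair_index[(f"o{k}", "D")]]
            assert not np.isnan(h).any()
            agree.append(h == np.array(truth[f"o{k}"]))
        agree = np.vstack(agree)
        acc = max(agree.mean(), 1 - agree.mean())   # labels arbitrary
        assert acc >= 0.99


class TestIBD:
    def test_certain_full_sibs_share_everything(self, trio_fixture):
        # o0 and o1 both inherited the same dam haplotype with certainty and
        # the sire is homozygous (expected sharing from him is 1/2 a priori
        # -> probability of same sire haplotype 0.5)
        st_ = build_family_structure(trio_fixture)
        inh = transmission_probabilities(phase_families(trio_fixture, st_),
                                         grid_step=None)
        ibd = ibd_at_position(inh, st_, 1, 0.0)
        i, j = ibd.ids.index("o0"), ibd.ids.index("o1")
        assert ibd.matrix[i, j] == pytest.approx(0.75, abs=1e-9)
        k = ibd.ids.index("o6")  # inherited the other dam haplotype
        assert ibd.matrix[i, k] == pytest.approx(0.25, abs=1e-9)

    def test_unrelated_founders_zero_parent_offspring_half(self, trio_fixture):
        st_ = build_family_structure(trio_fixture)
        inh = transmission_probabilities(phase_families(trio_fixture, st_),
                                         grid_step=None)
        ibd = ibd_at_position(inh, st_, 1, 30.0)
        d, s, o = (ibd.ids.index(x) for x in ("D", "S", "o0"))
        assert ibd.matrix[d, s] == pytest.approx(0.0, abs=1e-9)
        assert ibd.matrix[d, o] == pytest.approx(0.5, abs=1e-9)

    def test_half_sib_uninformative_expectation(self):
        # two half sibs through a homozygous (uninformative) shared sire:
        # exhaustive enumeration over the 4 equiprobable gamete combinations
        # gives expected allele-sharing 0.25
        markers = [("m1", 1, 0.0)]
        rows = [{"id": "D1", "m1": "AA"}, {"id": "D2", "m1": "AA"},
                {"id": "S", "m1": "AA"},
                {"id": "x", "dam": "D1", "sire": "S", "family": "f1",
                 "cross": "wild", "m1": "AA"},
                {"id": "y", "dam": "D2", "sire": "S", "family": "f2",
                 "cross": "wild", "m1": "AA"}]
        t = make_table(rows, markers)
        st_ = build_family_structure(t)
        inh = transmission_probabilities(phase_families(t, st_),
                                         grid_step=None)
        ibd = ibd_at_position(inh, st_, 1, 0.0)
        i, j = ibd.ids.index("x"), ibd.ids.index("y")
        # oracle: mean over the 4 equiprobable sire-gamete pairs of the
        # shared-allele fraction (1/2 when same haplotype, 0 otherwise)
        oracle = np.mean([0.5 if a == b else 0.0
                          for a in (0, 1) for b in (0, 1)])
        assert oracle == 0.25
        assert ibd.matrix[i, j] == pytest.approx(oracle, abs=1e-9)

    def test_recursive_equals_path_enumeration(self, trio_fixture):
        # pairwise IBD from interpolated marginals equals the exhaustive
        # gamete-path computation exactly (meioses are independent and the
        # transmission chain is Markov)
        st_ = build_family_structure(trio_fixture)
        inh = transmission_probabilities(phase_families(trio_fixture, st_),
                                         grid_step=15.0)
        ph = phase_families(trio_fixture, st_)
        ibd = ibd_at_position(inh, st_, 1, 15.0)
        idx = ph.pair_index
        for a, b in (("o0", "o1"), ("o0", "o6"), ("o5", "o9")):
            pa = enum_marginal(
                [(p, int(h)) for p, h in
                 zip([0.0, 30.0, 60.0], ph.H[1][idx[(a, "D")]])], 15.0)
            pb = enum_marginal(
                [(p, int(h)) for p, h in
                 zip([0.0, 30.0, 60.0], ph.H[1][idx[(b, "D")]])], 15.0)
            same_dam = pa * pb + (1 - pa) * (1 - pb)
            want = 0.5 * same_dam + 0.5 * 0.5   # sire side uninformative
            got = ibd.matrix[ibd.ids.index(a), ibd.ids.index(b)]
            assert got == pytest.approx(want, abs=1e-12)

    def test_position_outside_map_raises(self, small_sim):
        sim, st_, _, inh = small_sim
        with pytest.raises(ValidationError):
            ibd_at_position(inh, st_, 1, 5000.0)

    def test_factor_reproduces_matrix(self, small_sim):
        sim, st_, _, inh = small_sim
        ibd = ibd_at_position(inh, st_, 2, 30.0)
        assert np.allclose(ibd.factor @ ibd.factor.T, ibd.matrix, atol=1e-10)
        w = np.linalg.eigvalsh(ibd.matrix)
        assert w.min() >= -1e-10


class TestKinship:
    def test_nuclear_family_entries(self, trio_fixture):
        st_ = build_family_structure(trio_fixture)
        kin = pedigree_kinship(st_)
        a = kin.matrix
        i = {x: k for k, x in enumerate(kin.ids)}
        assert a[i["o0"], i["o1"]] == pytest.approx(0.5)
        assert a[i["D"], i["o0"]] == pytest.approx(0.5)
        assert a[i["D"], i["S"]] == 0.0
        assert np.allclose(kin.factor @ kin.factor.T, a, atol=1e-10)

    def test_lowrank_form_matches_tabular(self, small_sim):
        sim, st_, _, _ = small_sim
        ids = [o for f in st_.families.values() for o in f.offspring]
        B, d = kinship_lowrank(st_, ids)
        dense = pedigree_kinship(st_, ids=ids).matrix
        assert np.allclose(B @ B.T + d * np.eye(len(ids)), dense, atol=1e-10)

    def test_against_gene_drop_oracle(self):
        # 3 families incl. a half-sib pair; expected allele sharing from
        # 100k gene drops must match the tabular additive relationship / 2
        rows = [{"id": p, "m1": "AB"} for p in ("D1", "D2", "S1", "S2")]
        fams = [("f1", "D1", "S1"), ("f2", "D2", "S1"), ("f3", "D2", "S2")]
        for fam, d, s in fams:
            for k in range(2):
                rows.append({"id": f"{fam}o{k}", "dam": d, "sire": s,
                             "family": fam, "cross": "wild", "m1": "AB"})
        t = make_table(rows, [("m1", 1, 0.0)])
        st_ = build_family_structure(t)
        kin = pedigree_kinship(st_)
        rng = np.random.default_rng(0)
        ids = kin.ids
        founders = ["D1", "D2", "S1", "S2"]
        n = 100_000
        # gene drop: founder alleles 2k, 2k+1; offspring sample one per parent
        alleles = {f: np.stack([np.full(n, 2 * k), np.full(n, 2 * k + 1)])
                   for k, f in enumerate(founders)}
        for fam, d, s in fams:
            for k in range(2):
                a = alleles[d][rng.integers(0, 2, n), np.arange(n)]
                b = alleles[s][rng.integers(0, 2, n), np.arange(n)]
                alleles[f"{fam}o{k}"] = np.stack([a, b])
        for a, b in (("f1o0", "f1o1"), ("f1o0", "f2o0"), ("f1o0", "f3o0"),
                     ("D1", "f1o0"), ("f2o0", "f3o1")):
            A, Bm = alleles[a], alleles[b]
            share = np.zeros(n)
            for i in range(2):
                for j in range(2):
                    share += (A[i] == Bm[j])
            # expected fraction of shared alleles equals the additive
            # relationship for non-inbred pairs
            mc = (share / 2.0).mean()
            assert kin.matrix[ids.index(a), ids.index(b)] == \
                pytest.approx(mc, abs=0.01)


def test_psd_factor_clips_negative_eigenvalues():
    m = np.array([[1.0, 0.999, 0.0], [0.999, 1.0, 0.999], [0.0, 0.999, 1.0]])
    f = psd_factor(m)
    w = np.linalg.eigvalsh(f @ f.T)
    assert w.min() >= 1e-9
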