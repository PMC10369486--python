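"""Discretized rotamer classification: bins, PRO pucker, census, groups."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rotamer_audit.geometry import ChiAngles
from rotamer_audit.rotamer_model import (GROUPS, OFF_LABEL, assign_group,
                                         circular_distance, classify,
                                         classify_pro, rotamer_census)


def chis_for(aa, values):
    return ChiAngles(aa=aa, values=list(values),
                     defined_mask=[True] * len(values))


class TestCircularDistance:
    @pytest.mark.parametrize("x, y, expected", [
        (10.0, -10.0, 20.0),
        (170.0, -170.0, 20.0),       # wrap-around
        (90.0, -90.0, 180.0),
        (0.0, 360.0, 0.0),
    ])
    def test_reference_values(self, x, y, expected):
        assert circular_distance(x, y) == pytest.approx(expected)

    @settings(max_examples=300, deadline=None)
    @given(st.floats(-720, 720, allow_nan=False),
           st.floats(-720, 720, allow_nan=False))
    def test_identities(self, x, y):
        d = circular_distance(x, y)
        assert 0.0 <= d <= 180.0
        assert d == pytest.approx(circular_distance(y, x))
        assert circular_distance(x, x) == pytest.approx(0.0)
        # congruence: zero iff x == y (mod 360)
        if d < 1e-9:
            assert abs((x - y) % 360.0) < 1e-6 \
                or abs((x - y) % 360.0 - 360.0) < 1e-6


class TestClassify:
    @pytest.mark.parametrize("aa, values, expected", [
        ("LEU", (-65.0, 180.0), "mt"),
        ("ASN", (-65.0, -20.0), "m-20°"),
        ("LEU", (0.0, 180.0), OFF_LABEL),     # chi1 outside every bin
        ("VAL", (65.0,), "p"),
        ("ARG", (-65.0, 180.0, 180.0, 180.0), "mtt180°"),
        ("LYS", (-65.0, 180.0, 180.0, 180.0), "mttt"),
        ("MET", (-70.0, 175.0, 70.0), "mtp"),
        # corrected terminal torsion near -90 still matches the p90 bin
        # (the symmetric branch is 180-degree periodic)
        ("PHE", (65.0, -85.0), "p90°"),
    ])
    def test_reference_assignments(self, aa, values, expected, fx):
        assert classify(aa, chis_for(aa, values), fx).label == expected

    def test_invariant_under_360_shift(self, fx):
        rng = np.random.default_rng(0)
        for _ in range(200):
            aa = rng.choice(["LEU", "ASN", "MET", "LYS"])
            n = len(fx.chi_definitions[aa])
            values = rng.uniform(-180, 180, size=n)
            shifted = values + rng.choice([-360, 0, 360], size=n)
            a = classify(aa, chis_for(aa, list(values)), fx)
            b = classify(aa, chis_for(aa, list(shifted)), fx)
            assert a.label == b.label

    def test_undefined_chi_refused(self, fx):
        chis = ChiAngles("LEU", [-65.0, float("nan")], [True, False])
        assert classify("LEU", chis, fx) is None

    def test_no_chi_residue_rejected(self, fx):
        with pytest.raises(ValueError):
            classify("ALA", ChiAngles("ALA"), fx)

    def test_group_i_generic_bins_partition_uniquely(self, fx):
        # for 1-chi residues the three generic bins never overlap: at most
        # one class qualifies at any angle
        for aa in GROUPS["I"]:
            modes = {c.label: c.modes[0] for c in fx.inventory[aa]}
            for angle in np.arange(-180.0, 180.0, 1.0):
                hits = [l for l, m in modes.items()
                        if circular_distance(angle, m) <= 30.0]
                assert len(hits) <= 1
                got = classify(aa, chis_for(aa, [angle]), fx).label
                assert got == (hits[0] if hits else OFF_LABEL)


class TestBruteForceEquivalence:
    """classify() must agree with an independent vectorized scan of the
    inventory: off iff no class qualifies, otherwise a qualifying class
    with minimal worst-angle deviation."""

    @staticmethod
    def _oracle_dev(aa, grid, modes, fx):
        # independent reimplementation: explicit wrap, no shared helpers
        dev = np.empty((len(grid), len(modes)))
        from rotamer_audit.nomenclature import SYMMETRIC_AAS, \
            symmetric_chi_index
        sym_idx = (symmetric_chi_index(aa) - 1
                   if aa in SYMMETRIC_AAS else None)
        for j, mode_vec in enumerate(modes):
            per_index = []
            for i, m in enumerate(mode_vec):
                diff = np.abs(grid[:, i] - m)
                period = 180.0 if i == sym_idx else 360.0
                diff = diff % period
                per_index.append(np.minimum(diff, period - diff))
            dev[:, j] = np.max(per_index, axis=0)
        return dev

    def _check_aa(self, aa, step, fx, rng=None, n_random=0):
        n_chi = 1 if aa == "PRO" else len(fx.chi_definitions[aa])
        axes = [np.arange(-177.5, 180.0, step)] * n_chi
        mesh = np.meshgrid(*axes, indexing="ij")
        grid = np.stack([m.ravel() for m in mesh], axis=1)
        if n_random:
            fine = np.arange(-177.5, 180.0, 5.0)
            grid = fine[rng.integers(0, len(fine),
                                     size=(n_random, n_chi))]
        modes = [c.modes for c in fx.inventory[aa]]
        dev = self._oracle_dev(aa, grid, modes, fx)
        qualifies = dev <= 30.0
        oracle_off = ~qualifies.any(axis=1)
        for k in range(len(grid)):
            values = list(grid[k])
            if aa == "PRO":
                got = classify_pro(chis_for(aa, values + [0.0]))
            else:
                got = classify(aa, chis_for(aa, values), fx)
            if oracle_off[k]:
                assert got.label == OFF_LABEL, (aa, values)
            else:
                assert got.label != OFF_LABEL, (aa, values)
                j = [c.label for c in fx.inventory[aa]].index(got.label)
                assert qualifies[k, j], (aa, values, got.label)
                assert dev[k, j] == pytest.approx(dev[k].min(), abs=1e-9)

    @pytest.mark.parametrize("aa", sorted(
        GROUPS["I"] + tuple(a for a in GROUPS["II"] if a != "PRO")))
    def test_exhaustive_5deg_grid_one_and_two_chi(self, aa, fx):
        self._check_aa(aa, 5.0, fx)

    def test_exhaustive_5deg_grid_pro(self, fx):
        self._check_aa("PRO", 5.0, fx)

    @pytest.mark.parametrize("aa", sorted(GROUPS["III"] + GROUPS["IV"]))
    def test_coarse_grid_plus_random_long_chains(self, aa, fx):
        # exhaustive grids get coarser with chi dimensionality (15 deg for
        # 3 chis, 30 deg for 4) and are complemented by a seeded random
        # sample of the 5-degree grid
        step = 15.0 if aa in GROUPS["III"] else 30.0
        self._check_aa(aa, step, fx)
        seed = sum(ord(c) for c in aa)
        self._check_aa(aa, 5.0, fx, rng=np.random.default_rng(seed),
                       n_random=2000)


class TestClassifyPro:
    @pytest.mark.parametrize("chi1, expected", [
        (30.0, "Cγ Endo"),
        (-30.0, "Cγ Exo"),
        (75.0, OFF_LABEL),
        (0.0, "Cγ Exo"),          # documented tie-break at the boundary
        (59.0, "Cγ Endo"),
        (-59.0, "Cγ Exo"),
    ])
    def test_pucker_assignment(self, chi1, expected):
        got = classify_pro(chis_for("PRO", [chi1, -1.2 * chi1]))
        assert got.label == expected

    def test_endo_center_matches_built_ring_pucker_sign(self, fx, make_structure):
        # a synthetically built Endo proline must classify as Endo
        st_, ledger = make_structure(n_residues=30, seed=51,
                                     aa_weights={"PRO": 1.0})
        from rotamer_audit.geometry import compute_chis
        for (_, res), row in zip(st_.iter_residues(), ledger.itertuples()):
            chis = compute_chis(res, fx.chi_definitions["PRO"])
            assert classify_pro(chis).label == row.true_label


class Rec:
    def __init__(self, aa, rotamer):
        self.aa = aa
        self.rotamer = rotamer


class RC:
    def __init__(self, label):
        self.label = label
        self.is_off = label == OFF_LABEL


class TestCensus:
    def test_counting_and_percentages(self):
        records = [Rec("ARG", RC(OFF_LABEL)) for _ in range(44)]
        records += [Rec("ARG", RC("mtt180°")) for _ in range(56)]
        records += [Rec("ALA", None) for _ in range(10)]
        df = rotamer_census(records)
        arg = df[df.aa == "ARG"].iloc[0]
        assert arg["off"] == 44 and arg["all"] == 100
        assert arg["pct_off"] == pytest.approx(44.0)
        ala = df[df.aa == "ALA"].iloc[0]
        assert ala["all"] == 10 and ala["canonical"] == 0

    def test_empty_input(self):
        assert len(rotamer_census([])) == 0

    def test_conservation(self):
        rng = np.random.default_rng(3)
        labels = ["mt", "tp", OFF_LABEL]
        records = [Rec("LEU", RC(rng.choice(labels))) for _ in range(500)]
        df = rotamer_census(records)
        for _, row in df.iterrows():
            assert row["canonical"] + row["off"] == row["all"]

    def test_known_mix_recovered_exactly(self):
        records = ([Rec("VAL", RC("t"))] * 90
                   + [Rec("VAL", RC(OFF_LABEL))] * 10)
        df = rotamer_census(records)
        row = df[df.aa == "VAL"].iloc[0]
        assert row["pct_off"] == pytest.approx(10.0)


class TestGroups:
    @pytest.mark.parametrize("aa, expected", [
        ("MET", "III"), ("ARG", "IV"), ("GLY", "none"), ("CYS", "I"),
        ("PRO", "II"), ("ALA", "none"), ("LYS", "IV"), ("THR", "I"),
    ])
    def test_membership(self, aa, expected):
        assert assign_group(aa) == expected

    def test_group_sizes_match_chi_counts(self, fx):
        expected_chis = {"I": 1, "II": 2, "III": 3, "IV": 4}
        for group, aas in GROUPS.items():
            for aa in aas:
                assert len(fx.chi_definitions[aa]) == expected_chis[group]

    def test_unknown_code_rejected(self):
        with pytest.raises(ValueError):
            assign_group("XXX")
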