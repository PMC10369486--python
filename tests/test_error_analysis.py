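"""Error decomposition, confidence, transitions and ACC statistics."""
import numpy as np
import pytest
from scipy import stats as sps

from rotamer_audit.error_analysis import (ComparisonRecord, ResidueRecord,
                                          adjust_p, anova_acc_by_class,
                                          contribution_by_aa,
                                          confidence_by_class,
                                          error_rate_by_aa,
                                          error_rate_by_acc, pair_structures,
                                          accuracy_by_stratum,
                                          top_transitions, tukey_hsd)
from rotamer_audit.rotamer_model import OFF_LABEL, RotamerClass


def comp(aa, orig, pred, tag="mock", acc=10.0, ss="H", group="I",
         devs=(), errs=()):
    return ComparisonRecord(
        key=("s", "A", 1, ""), aa=aa, original_label=orig,
        predicted_label=pred, chi_deviations=list(devs),
        chi_errors=list(errs), program_tag=tag, acc=acc, ss_code=ss,
        group=group)


def record(aa, label, acc, sid="s", seq=1):
    return ResidueRecord(structure_id=sid, chain="A", seq_id=seq, aa=aa,
                         rotamer=RotamerClass(aa, label), acc=acc)


class TestPairing:
    def _records(self, fx, seed=70, n=60, eps=0.3):
        from rotamer_audit.pipeline import RunConfig, build_residue_records
        from rotamer_audit.synthetic_data import GeneratorConfig, \
            make_paired_fixture
        cfg = RunConfig(acc_method="none", require_resolution=False)
        orig, pred, ledger = make_paired_fixture(
            GeneratorConfig(n_residues=n, seed=seed, off_fraction=0.1),
            epsilon0=eps, predictor_seed=seed + 1, fixtures=fx)
        o_recs, _ = build_residue_records(orig, fx, cfg)
        p_recs, _ = build_residue_records(pred, fx, cfg)
        return o_recs, p_recs, ledger

    def test_identical_structures_have_no_errors(self, fx):
        o_recs, _, _ = self._records(fx, eps=0.0)
        comps, unmatched = pair_structures(o_recs, o_recs, "self")
        assert not unmatched
        assert comps
        for c in comps:
            assert not c.class_error
            assert all(d == pytest.approx(0.0, abs=1e-9)
                       for d in c.chi_deviations)

    def test_error_flags_match_generator_ledger_exactly(self, fx):
        o_recs, p_recs, ledger = self._records(fx)
        comps, _ = pair_structures(o_recs, p_recs, "mock")
        truth = dict(zip(ledger["seq_id"], ledger["action"]))
        assert comps
        for c in comps:
            assert c.class_error == truth[c.key[2]].startswith("confused")

    def test_aa_mismatch_rejected(self):
        a = record("LEU", "mt", 5.0)
        b = record("VAL", "t", 5.0)
        a.chis = b.chis = None
        with pytest.raises(ValueError, match="mismatch"):
            pair_structures([a], [b])

    def test_unmatched_residues_reported_not_compared(self):
        a = record("LEU", "mt", 5.0, seq=1)
        b = record("LEU", "tp", 5.0, seq=2)
        comps, unmatched = pair_structures([a], [b])
        assert comps == [] and unmatched == [a.key]


class TestRates:
    def test_error_rate_arithmetic(self):
        comps = [comp("LYS", "mttt", "tttt")] * 4 \
            + [comp("LYS", "mttt", "mttt")] * 6
        df = error_rate_by_aa(comps)
        row = df[df.aa == "LYS"].iloc[0]
        assert row["pct_errors"] == pytest.approx(40.0)

    def test_all_correct_gives_zero(self):
        comps = [comp("LEU", "mt", "mt"), comp("VAL", "t", "t")]
        df = error_rate_by_aa(comps)
        assert (df["pct_errors"] == 0).all()

    def test_contribution_shares(self):
        comps = ([comp("LYS", "mttt", "tttt")] * 3
                 + [comp("ARG", "mtt180°", OFF_LABEL)]
                 + [comp("LYS", "mttt", "mttt")] * 10)
        df = contribution_by_aa(comps)
        assert df.set_index("aa").loc["LYS", "pct_contribution"] \
            == pytest.approx(75.0)
        assert df.set_index("aa").loc["ARG", "pct_contribution"] \
            == pytest.approx(25.0)
        assert df["pct_contribution"].sum() == pytest.approx(100.0)

    def test_single_aa_contribution_is_total(self):
        comps = [comp("GLN", "tt0°", "mt-30°")] * 5
        df = contribution_by_aa(comps)
        assert len(df) == 1
        assert df["pct_contribution"].iloc[0] == pytest.approx(100.0)

    def test_no_errors_yields_empty_contribution(self):
        df = contribution_by_aa([comp("LEU", "mt", "mt")])
        assert df.empty


class TestAccStrata:
    def test_concentrated_errors(self):
        comps = [comp("LYS", "mttt", "tttt", acc=105.0)] * 5 \
            + [comp("LYS", "mttt", "mttt", acc=15.0)] * 5
        by_bin, by_cat = error_rate_by_acc(comps)
        assert by_bin.set_index("acc_bin").loc["100", "pct_errors"] == 100.0
        assert by_bin.set_index("acc_bin").loc["0", "pct_errors"] == 0.0
        assert by_cat.set_index("acc_cat").loc["high", "pct_errors"] == 100.0

    def test_empty_bin_absent_not_zero(self):
        comps = [comp("LYS", "mttt", "tttt", acc=5.0)]
        by_bin, _ = error_rate_by_acc(comps)
        assert list(by_bin["acc_bin"]) == ["0"]

    def test_high_bins_flagged_low_n(self):
        comps = [comp("LYS", "mttt", "tttt", acc=250.0),
                 comp("LYS", "mttt", "mttt", acc=30.0)]
        by_bin, _ = error_rate_by_acc(comps)
        flags = dict(zip(by_bin["acc_bin"], by_bin["low_n_flag"]))
        assert flags["240"] and not flags["20"]

    def test_per_chi_rates(self):
        comps = [comp("LYS", "mttt", "tttt", acc=5.0,
                      devs=[120.0, 5.0, 5.0, 5.0],
                      errs=[True, False, False, False])] * 2
        by_bin, _ = error_rate_by_acc(comps, per_chi=True)
        chi1 = by_bin[(by_bin.chi_index == 1)]
        assert chi1["pct_errors"].iloc[0] == 100.0
        chi2 = by_bin[(by_bin.chi_index == 2)]
        assert chi2["pct_errors"].iloc[0] == 0.0


class TestStrata:
    def test_accuracy_complements_error_rate(self):
        comps = [comp("LEU", "mt", "tp", ss="H")] * 3 \
            + [comp("LEU", "mt", "mt", ss="H")] * 7
        acc_df = accuracy_by_stratum(comps, stratum="secondary_structure")
        assert acc_df["pct_correct"].iloc[0] == pytest.approx(70.0)

    def test_single_stratum(self):
        comps = [comp("LEU", "mt", "mt", group="II")]
        df = accuracy_by_stratum(comps, stratum="group")
        assert len(df) == 1

    def test_protein_size_binning(self):
        comps = [comp("LEU", "mt", "mt")]
        records = [record("LEU", "mt", 1.0, seq=i) for i in range(150)]
        df = accuracy_by_stratum(comps, records, stratum="protein_size")
        assert list(df["stratum"]) == [100]


class TestConfidence:
    def test_confidence_fraction(self):
        comps = [comp("LYS", "mttt", "mttt")] * 3 \
            + [comp("LYS", "mttt", "tttt")]
        df = confidence_by_class(comps)
        row = df[(df["class"] == "mttt") & (df.program_tag == "mock")]
        assert row["confidence"].iloc[0] == pytest.approx(75.0)

    def test_perfect_predictor_is_100(self):
        comps = [comp("LEU", "mt", "mt"), comp("LEU", "tp", "tp")]
        df = confidence_by_class(comps)
        assert (df["confidence"] == 100.0).all()

    def test_macro_average_across_programs(self):
        comps = [comp("LEU", "mt", "mt", tag="a"),
                 comp("LEU", "mt", "tp", tag="b")]
        df = confidence_by_class(comps)
        macro = df[df.program_tag == "macro_avg"]
        assert macro["confidence"].iloc[0] == pytest.approx(50.0)


class TestTransitions:
    def test_ranked_by_count(self):
        comps = [comp("VAL", "m", "t")] * 5 + [comp("VAL", "p", "t")] * 3
        assert top_transitions(comps, "VAL") == [("m to t", 5), ("p to t", 3)]

    def test_tie_broken_lexicographically(self):
        comps = [comp("VAL", "m", "t")] * 2 + [comp("VAL", "p", "t")] * 2 \
            + [comp("VAL", "m", "p")] * 2
        labels = [t[0] for t in top_transitions(comps, "VAL")]
        assert labels == sorted(labels)

    def test_no_errors_empty(self):
        assert top_transitions([comp("VAL", "m", "m")], "VAL") == []

    def test_top_n_cut(self):
        comps = [comp("VAL", "m", "t")] * 3 + [comp("VAL", "p", "t")] * 2 \
            + [comp("VAL", "t", "p")]
        assert len(top_transitions(comps, "VAL", n=2)) == 2


def brute_force_anova(groups):
    """Sum-of-squares one-way ANOVA, written out longhand."""
    all_values = np.concatenate(groups)
    grand = all_values.mean()
    ss_between = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ss_within = sum(((np.asarray(g) - np.mean(g)) ** 2).sum()
                    for g in groups)
    df_between = len(groups) - 1
    df_within = len(all_values) - len(groups)
    f = (ss_between / df_between) / (ss_within / df_within)
    p = sps.f.sf(f, df_between, df_within)
    return f, p


class TestAnova:
    def test_matches_sum_of_squares_oracle(self):
        rng = np.random.default_rng(17)
        groups = [rng.normal(loc, 1.0, size=n)
                  for loc, n in [(0.0, 12), (0.5, 9), (1.5, 20)]]
        records = []
        for label, g in zip(["mt", "tp", OFF_LABEL], groups):
            records += [record("LEU", label, float(v), seq=i)
                        for i, v in enumerate(g)]
        f_ours, p_ours = anova_acc_by_class(records, "LEU")
        f_ref, p_ref = brute_force_anova(groups)
        assert f_ours == pytest.approx(f_ref, rel=1e-8)
        assert p_ours == pytest.approx(p_ref, rel=1e-8)

    def test_separation_limit(self):
        records = [record("LEU", "mt", 1.0 + 1e-9 * i, seq=i)
                   for i in range(10)]
        records += [record("LEU", "tp", 100.0 + 1e-9 * i, seq=i + 10)
                    for i in range(10)]
        f, p = anova_acc_by_class(records, "LEU")
        assert f > 1e6 and p < 1e-12

    def test_degenerate_grouping_rejected(self):
        records = [record("LEU", "mt", 1.0)]
        with pytest.raises(ValueError):
            anova_acc_by_class(records, "LEU")

    def test_type_one_error_rate_calibrated(self):
        # 1000 null simulations, 3 groups x 8 from one normal distribution
        rng = np.random.default_rng(2024)
        data = rng.normal(size=(3, 8, 1000))
        _, p = sps.f_oneway(*data, axis=0)
        # cross-check a handful against the longhand oracle
        for k in range(5):
            _, p_ref = brute_force_anova([data[i, :, k] for i in range(3)])
            assert p[k] == pytest.approx(p_ref, rel=1e-8)
        rate = (p < 0.05).mean()
        assert rate == pytest.approx(0.05, abs=0.015)


class TestTukey:
    def _records(self):
        rng = np.random.default_rng(23)
        records = []
        seq = 0
        for label, loc, n in [("mt", 20.0, 30), ("tp", 25.0, 25),
                              (OFF_LABEL, 45.0, 20)]:
            for v in rng.normal(loc, 8.0, size=n):
                records.append(record("LEU", label, float(v), seq=seq))
                seq += 1
        return records

    def test_family_adjustment_is_exact_arithmetic(self):
        for p_raw in (1e-7, 1.67e-5, 1e-3, 0.5, 0.9):
            assert adjust_p(p_raw) == min(1.0, p_raw * 963)

    def test_printed_adjustment_example(self):
        # raw 1.67e-5 under the 963-fold family: adjusted ~ 1.61e-2
        assert adjust_p(1.67e-5) == pytest.approx(1.61e-2, rel=5e-3)

    def test_adjusted_alpha_threshold(self):
        # adjusted alpha = 0.05 / 963 = 0.000052
        assert round(0.05 / 963, 6) == 0.000052

    def test_results_consistent(self):
        results = tukey_hsd(self._records(), "LEU")
        assert len(results) == 3
        for r in results:
            assert r.ci_low <= r.difference <= r.ci_high
            assert r.p_adjusted >= r.p_raw
            assert r.significant == (r.p_adjusted < 0.05)
            assert r.p_adjusted == adjust_p(r.p_raw)

    def test_off_pairs_carry_correlation_sign(self):
        results = tukey_hsd(self._records(), "LEU")
        off_pairs = [r for r in results if "off" in r.pair]
        assert off_pairs
        # off was simulated with the highest mean ACC
        assert all(r.correlation_sign == "off_higher_acc" for r in off_pairs)
        non_off = [r for r in results if "off" not in r.pair]
        assert all(r.correlation_sign == "n/a" for r in non_off)

    def test_equal_mean_groups_ci_spans_zero(self):
        records = [record("LEU", "mt", float(v), seq=i)
                   for i, v in enumerate([10, 20, 30, 40])]
        records += [record("LEU", "tp", float(v), seq=i + 4)
                    for i, v in enumerate([10, 20, 30, 40])]
        res = tukey_hsd(records, "LEU")[0]
        assert res.difference == pytest.approx(0.0)
        assert res.ci_low < 0 < res.ci_high

    def test_singleton_class_dropped(self):
        records = self._records() + [record("LEU", "pp", 99.0, seq=999)]
        results = tukey_hsd(records, "LEU")
        assert not any("pp" in r.pair for r in results)

    def test_matches_statsmodels_reference(self):
        # independent oracle for the raw studentized-range p-values
        from statsmodels.stats.multicomp import pairwise_tukeyhsd
        records = self._records()
        values = np.array([r.acc for r in records])
        labels = np.array([r.rotamer.label for r in records])
        ref = pairwise_tukeyhsd(values, labels)
        ours = {r.pair: r for r in tukey_hsd(records, "LEU")}
        for (a, b), p_ref, diff_ref in zip(
                [(ref.groupsunique[i], ref.groupsunique[j])
                 for i, j in zip(*np.triu_indices(len(ref.groupsunique), 1))],
                ref.pvalues, ref.meandiffs):
            r = ours.get(f"{a}-{b}") or ours.get(f"{b}-{a}")
            assert r is not None
            assert r.p_raw == pytest.approx(p_ref, abs=1e-6)
            assert abs(r.difference) == pytest.approx(abs(diff_ref),
                                                      rel=1e-9)
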