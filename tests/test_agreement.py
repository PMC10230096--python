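"""Dichotomization, cross-tabulation, Cohen's kappa, and report building."""

import numpy as np
import pandas as pd
import pytest

from foodprofiler import (
    CrossTab2x2,
    HealthFlag,
    HealthFlags,
    KappaBand,
    build_report,
    cohen_kappa,
    crosstab_2x2,
    dichotomize,
    interpret_kappa,
    reference_counts,
    reference_crosstabs,
    restrict_to_complete,
    systems_met_distribution,
    upf_share_among_healthy,
)
from foodprofiler.agreement import SYSTEMS, report_from_crosstabs, round_half_up
from foodprofiler.nova import NovaClass
from foodprofiler.profiling import ClassificationResult, System

H, U, N = HealthFlag.HEALTHY, HealthFlag.UNHEALTHY, HealthFlag.NOT_CLASSIFIABLE


def _flags(pid, doh=H, who=H, hcl=H, nova=H):
    return HealthFlags(
        product_id=pid, flags={"DOH": doh, "WHO_SEA": who, "HCL": hcl, "NOVA": nova}
    )


def _result(system, label):
    return ClassificationResult(system=system, label=label)


class TestDichotomize:
    def test_all_healthy_combination(self):
        f = dichotomize(
            "p",
            _result(System.DOH, "GROUP_A"),
            _result(System.WHO_SEA, "PERMITTED"),
            _result(System.HCL, "ELIGIBLE"),
            NovaClass.MP,
        )
        assert all(v is H for v in f.flags.values())

    @pytest.mark.parametrize("doh_label", ["GROUP_B", "GROUP_C", "AUTO_PROHIBITED"])
    def test_non_group_a_is_unhealthy(self, doh_label):
        f = dichotomize(
            "p",
            _result(System.DOH, doh_label),
            _result(System.WHO_SEA, "PERMITTED"),
            _result(System.HCL, "ELIGIBLE"),
            NovaClass.MP,
        )
        assert f.flags["DOH"] is U

    @pytest.mark.parametrize("nova,expected", [
        (NovaClass.MP, H), (NovaClass.PCI, H), (NovaClass.P, H),
        (NovaClass.UPF, U), (NovaClass.NOT_CLASSIFIABLE, N),
    ])
    def test_nova_dichotomy_is_non_upf(self, nova, expected):
        f = dichotomize(
            "p",
            _result(System.DOH, "GROUP_A"),
            _result(System.WHO_SEA, "PERMITTED"),
            _result(System.HCL, "ELIGIBLE"),
            nova,
        )
        assert f.flags["NOVA"] is expected

    def test_not_classifiable_propagates(self):
        f = dichotomize(
            "p",
            _result(System.DOH, "NOT_CLASSIFIABLE"),
            _result(System.WHO_SEA, "PERMITTED"),
            _result(System.HCL, "ELIGIBLE"),
            NovaClass.MP,
        )
        assert f.flags["DOH"] is N and not f.complete


class TestRestrictAndCrosstab:
    def test_incomplete_products_dropped(self):
        flags = [_flags("a"), _flags("b", hcl=N), _flags("c", nova=N)]
        assert [f.product_id for f in restrict_to_complete(flags)] == ["a"]

    def test_restriction_matches_bruteforce_filter(self):
        rng = np.random.default_rng(3)
        opts = [H, U, N]
        flags = [
            _flags(f"p{i}", *(opts[int(k)] for k in rng.integers(0, 3, 4)))
            for i in range(500)
        ]
        kept = restrict_to_complete(flags)
        expected = [
            f for f in flags if all(v is not N for v in f.flags.values())
        ]
        assert kept == expected

    def test_all_both_unhealthy_lands_in_n11(self):
        flags = [_flags(f"p{i}", doh=U, who=U) for i in range(3)]
        tab = crosstab_2x2(flags, "DOH", "WHO_SEA")
        assert (tab.n11, tab.n12, tab.n21, tab.n22) == (3, 0, 0, 0)

    def test_cells_conserve_input_size(self):
        rng = np.random.default_rng(5)
        flags = [
            _flags(f"p{i}", *(H if rng.random() < 0.3 else U for _ in range(4)))
            for i in range(400)
        ]
        tab = crosstab_2x2(flags, "HCL", "NOVA")
        assert tab.n == 400

    def test_random_flags_match_per_product_tally(self):
        rng = np.random.default_rng(8)
        flags = [
            _flags(f"p{i}", *(H if rng.random() < 0.4 else U for _ in range(4)))
            for i in range(300)
        ]
        tab = crosstab_2x2(flags, "DOH", "NOVA")
        cells = {"UU": 0, "UH": 0, "HU": 0, "HH": 0}
        for f in flags:
            key = ("U" if f.flags["DOH"] is U else "H") + ("U" if f.flags["NOVA"] is U else "H")
            cells[key] += 1
        assert (tab.n11, tab.n12, tab.n21, tab.n22) == (
            cells["UU"], cells["UH"], cells["HU"], cells["HH"]
        )

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            crosstab_2x2([], "DOH", "HCL")


def _tab(n11, n12, n21, n22, labels=("A", "B")):
    return CrossTab2x2(labels=labels, n11=n11, n12=n12, n21=n21, n22=n22)


class TestKappa:
    def test_published_doh_whosea_table(self):
        res = cohen_kappa(_tab(8819, 625, 500, 542))
        assert res.kappa_3dp == 0.431
        assert round_half_up(res.percent_agreement, 2) == 89.27

    def test_perfect_agreement_diagonal(self):
        res = cohen_kappa(_tab(10, 0, 0, 10))
        assert res.kappa == pytest.approx(1.0)
        assert res.percent_agreement == pytest.approx(100.0)

    def test_random_tables_match_definition_and_sklearn(self):
        """Dual oracle: the po/pe definition and sklearn's implementation."""
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(12)
        for _ in range(200):
            n11, n12, n21, n22 = (int(x) for x in rng.integers(1, 200, 4))
            res = cohen_kappa(_tab(n11, n12, n21, n22))
            n = n11 + n12 + n21 + n22
            po = (n11 + n22) / n
            pe = ((n11 + n12) * (n11 + n21) + (n21 + n22) * (n12 + n22)) / n**2
            assert res.kappa == pytest.approx((po - pe) / (1 - pe))
            a = [0] * (n11 + n12) + [1] * (n21 + n22)
            b = [0] * n11 + [1] * n12 + [0] * n21 + [1] * n22
            assert res.kappa == pytest.approx(cohen_kappa_score(a, b))

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(14)
        for _ in range(50):
            n11, n12, n21, n22 = (int(x) for x in rng.integers(1, 100, 4))
            k1 = cohen_kappa(_tab(n11, n12, n21, n22)).kappa
            k2 = cohen_kappa(_tab(n22, n21, n12, n11)).kappa
            assert k1 == pytest.approx(k2)

    def test_kappa_one_iff_offdiagonal_zero(self):
        assert cohen_kappa(_tab(5, 0, 0, 7)).kappa == pytest.approx(1.0)
        assert cohen_kappa(_tab(5, 1, 0, 7)).kappa < 1.0

    def test_kappa_never_exceeds_observed_agreement(self):
        rng = np.random.default_rng(16)
        for _ in range(100):
            n11, n12, n21, n22 = (int(x) for x in rng.integers(0, 50, 4))
            if n11 + n12 + n21 + n22 == 0:
                continue
            res = cohen_kappa(_tab(n11, n12, n21, n22))
            assert res.kappa <= res.po + 1e-12

    def test_degenerate_marginals_return_one_with_note(self):
        res = cohen_kappa(_tab(9, 0, 0, 0))
        assert res.kappa == 1.0 and res.degenerate

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            cohen_kappa(_tab(0, 0, 0, 0))


class TestInterpretation:
    @pytest.mark.parametrize(
        "kappa,band",
        [
            (0.431, KappaBand.MODERATE),
            (0.094, KappaBand.NONE_TO_SLIGHT),  # rounds to 0.09
            (1.00, KappaBand.ALMOST_PERFECT),
            (0.205, KappaBand.FAIR),  # half-up to 0.21
            (0.20, KappaBand.NONE_TO_SLIGHT),
            (0.61, KappaBand.SUBSTANTIAL),
            (0.004, KappaBand.ZERO),
            (-0.3, KappaBand.NEGATIVE),
        ],
    )
    def test_bands(self, kappa, band):
        assert interpret_kappa(kappa) is band

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            interpret_kappa(1.5)


class TestDistributionsAndShares:
    def test_all_four_healthy_lands_in_bucket_four(self):
        dist = systems_met_distribution([_flags("p")])
        assert dist.counts[4] == 1

    def test_buckets_conserve_and_match_counting_oracle(self):
        rng = np.random.default_rng(19)
        flags = [
            _flags(f"p{i}", *(H if rng.random() < 0.35 else U for _ in range(4)))
            for i in range(600)
        ]
        dist = systems_met_distribution(flags)
        assert dist.n == 600
        expected = [0] * 5
        for f in flags:
            expected[sum(v is H for v in f.flags.values())] += 1
        assert list(dist.counts) == expected

    def test_upf_share_all_mp_is_zero(self):
        flags = [_flags(f"p{i}", doh=H, nova=H) for i in range(4)]
        assert upf_share_among_healthy(flags, "DOH") == 0.0

    def test_upf_share_half(self):
        flags = [
            _flags("a", doh=H, nova=U),
            _flags("b", doh=H, nova=U),
            _flags("c", doh=H, nova=H),
            _flags("d", doh=H, nova=H),
            _flags("e", doh=U, nova=U),
        ]
        assert upf_share_among_healthy(flags, "DOH") == pytest.approx(50.0)

    def test_upf_share_undefined_without_healthy(self):
        flags = [_flags("a", doh=U)]
        assert upf_share_among_healthy(flags, "DOH") is None

    def test_upf_share_matches_bruteforce_filter(self):
        rng = np.random.default_rng(23)
        flags = [
            _flags(f"p{i}", *(H if rng.random() < 0.5 else U for _ in range(4)))
            for i in range(400)
        ]
        for system in ("DOH", "WHO_SEA", "HCL"):
            healthy = [f for f in flags if f.flags[system] is H]
            expected = 100.0 * sum(f.flags["NOVA"] is U for f in healthy) / len(healthy)
            assert upf_share_among_healthy(flags, system) == pytest.approx(expected)


class TestReports:
    def test_report_on_published_tables_reproduces_six_kappas(self, tmp_path):
        paths = report_from_crosstabs(reference_crosstabs(), tmp_path)
        df = pd.read_csv(paths["pairwise_csv"])
        got = {
            (r.system_a, r.system_b): r.kappa for r in df.itertuples()
        }
        assert got[("DOH", "WHO_SEA")] == 0.431
        assert got[("DOH", "NOVA")] == 0.118
        assert got[("WHO_SEA", "NOVA")] == 0.167
        assert got[("HCL", "DOH")] == 0.210
        assert got[("HCL", "WHO_SEA")] == 0.212
        assert round(abs(got[("HCL", "NOVA")] - 0.094), 9) <= 0.001

    def test_csv_output_reparses_to_same_numbers(self, tmp_path):
        rng = np.random.default_rng(29)
        flags = [
            _flags(f"p{i}", *(H if rng.random() < 0.3 else U for _ in range(4)))
            for i in range(200)
        ]
        paths = build_report(flags, tmp_path)
        df = pd.read_csv(paths["pairwise_csv"])
        for row in df.itertuples():
            tab = crosstab_2x2(flags, row.system_a, row.system_b)
            res = cohen_kappa(tab)
            assert row.kappa == pytest.approx(res.kappa_3dp)
            assert row.n == tab.n
        dist_df = pd.read_csv(paths["distribution_csv"])
        assert dist_df["count"].sum() == 200

    def test_empty_statistics_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            build_report([], tmp_path)

    def test_nova_pair_percent_agreement_consistent_with_counts(self):
        """Count-derived percent agreement for the NOVA pairs (the printed
        values differ from their own counts by ~0.03 points)."""
        tabs = reference_crosstabs()
        expected = {
            ("WHO_SEA", "NOVA"): 79.82,
            ("DOH", "NOVA"): 79.33,
            ("HCL", "NOVA"): 78.21,
        }
        for pair, value in expected.items():
            res = cohen_kappa(tabs[pair])
            assert round_half_up(res.percent_agreement, 2) == pytest.approx(value, abs=0.05)


from hypothesis import given, settings
from hypothesis import strategies as st

cell = st.integers(min_value=0, max_value=2000)


@given(st.tuples(cell, cell, cell, cell).filter(lambda c: sum(c) > 0))
@settings(max_examples=200, deadline=None, derandomize=True)
def test_kappa_invariants_hold_on_arbitrary_tables(cells):
    n11, n12, n21, n22 = cells
    res = cohen_kappa(_tab(n11, n12, n21, n22))
    assert -1.0 <= res.kappa <= 1.0
    assert res.kappa <= res.po + 1e-12
    swapped = cohen_kappa(_tab(n22, n21, n12, n11))
    assert swapped.kappa == pytest.approx(res.kappa)
    if n12 == 0 and n21 == 0 and not res.degenerate:
        assert res.kappa == pytest.approx(1.0)


def test_reference_counts_fixture_is_consistent():
    ref = reference_counts()
    for cells in ref["pairwise_2x2"].values():
        assert sum(cells) == ref["n_complete_cases"]
    assert sum(ref["systems_met_counts"].values()) == ref["n_complete_cases"]
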