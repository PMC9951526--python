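"""Score parsing, statistics kernels vs brute-force oracles, HMM profiles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from indelkit.fixtures import SimConfig, simulate_scores, write_hmm_profile
from indelkit.scores_analysis import (
    HMMIndelProfile,
    StructureAnnotation,
    class_summaries,
    fisher_exact_two_sided,
    gly_correlation,
    indel_conservation_test,
    parse_variant_name,
    read_hmm_indel_profile,
    read_scores,
    structure_strata,
    wilcoxon_rank_sum,
)


class TestParsing:
    @pytest.mark.parametrize(
        "name,expected",
        [
            ("p.A12del", ("deletion", 12, "", 1)),
            ("p.A12_G14del", ("deletion", 12, "", 3)),
            ("p.K7_insGS", ("insertion", 7, "GS", 2)),
            ("p.L28A", ("missense", 28, "A", 0)),
            ("p.L28*", ("stop", 28, "*", 0)),
            ("p.A12=", ("synonymous", 12, "", 0)),
        ],
    )
    def test_hgvs_like_names_parse(self, name, expected):
        assert parse_variant_name(name) == expected

    def test_score_row_parses_deletion(self):
        st = read_scores(pd.DataFrame({"hgvs": ["p.A12del"], "score": [-1.3], "SE": [0.2]}))
        row = st.df.iloc[0]
        assert row["kind"] == "deletion" and row["position"] == 12
        assert row["score"] == pytest.approx(-1.3)

    def test_duplicate_identifier_is_an_error(self):
        df = pd.DataFrame({"hgvs": ["p.A12del", "p.A12del"], "score": [0, 1]})
        with pytest.raises(ValueError, match="p.A12del"):
            read_scores(df)

    def test_unparseable_rows_are_excluded_and_reported(self):
        df = pd.DataFrame({"hgvs": ["p.A12del", "_wt"], "score": [0.0, 0.1]})
        st = read_scores(df)
        assert st.skipped == ["_wt"] and st.df.shape[0] == 1

    def test_simulated_table_round_trips_through_disk(self, small_design, tmp_path):
        scores = simulate_scores(small_design, SimConfig(seed=20))
        path = tmp_path / "scores.tsv"
        scores.to_csv(path, sep="\t", index=False)
        st = read_scores(path)
        assert st.df.shape[0] == scores.shape[0]
        merged = st.df.set_index("name")["score"]
        for name, score in zip(scores["hgvs"], scores["score"]):
            assert merged[name] == pytest.approx(score)


class TestClassSummaries:
    def test_disruption_hierarchy_is_recovered(self, small_design):
        cfg = SimConfig(seed=21, position_sigma=0.2, score_noise_sigma=0.1)
        st = read_scores(simulate_scores(small_design, cfg))
        by_kind = class_summaries(st)["by_kind"]
        means = by_kind["mean"]
        assert (
            means["deletion"] < means["insertion"] < means["missense"] < means["synonymous"]
        )

    def test_single_variant_table_mean_is_that_score(self):
        st = read_scores(pd.DataFrame({"hgvs": ["p.A12del"], "score": [-1.5]}))
        assert class_summaries(st)["by_kind"].loc["deletion", "mean"] == pytest.approx(-1.5)

    def test_per_position_deletion_mean_is_arithmetic_mean(self):
        df = pd.DataFrame(
            {
                "hgvs": ["p.A5del", "p.A5_C6del", "p.A5_D7del"],
                "score": [-1.0, -2.0, -3.0],
            }
        )
        st = read_scores(df)
        per_pos = class_summaries(st)["per_position"]
        vals = per_pos.loc[5, "deletion"]
        assert vals.mean() == pytest.approx(-2.0)


class TestGlyCorrelation:
    def test_identical_insertion_and_substitution_scores_give_r_one(self):
        rows = []
        rng = np.random.default_rng(22)
        for pos in range(2, 42):
            s = float(rng.normal())
            rows.append({"hgvs": f"p.A{pos}_insG", "score": s})
            rows.append({"hgvs": f"p.A{pos}G", "score": s})
        n, r, _ = gly_correlation(read_scores(pd.DataFrame(rows)))
        assert n == 40 and r == pytest.approx(1.0)

    def test_configured_correlation_is_recovered(self):
        # shared position effect + independent noise: rho = 0.5 when the
        # variances match; recovery within sampling error at n=400
        rng = np.random.default_rng(23)
        rows = []
        for pos in range(1, 401):
            shared = rng.normal(0, 1.0)
            rows.append({"hgvs": f"p.A{pos}_insG", "score": shared + rng.normal(0, 1.0)})
            rows.append({"hgvs": f"p.A{pos}G", "score": shared + rng.normal(0, 1.0)})
        n, r, _ = gly_correlation(read_scores(pd.DataFrame(rows)))
        assert n == 400
        assert r == pytest.approx(0.5, abs=0.1)

    def test_too_few_pairs_is_an_error(self):
        df = pd.DataFrame({"hgvs": ["p.A2_insG", "p.A2G"], "score": [0.0, 0.1]})
        with pytest.raises(ValueError, match="positions"):
            gly_correlation(read_scores(df))

    def test_pearson_matches_direct_formula_on_small_input(self):
        rng = np.random.default_rng(24)
        x, y = rng.normal(size=8), rng.normal(size=8)
        r_scipy = sps.pearsonr(x, y)[0]
        xc, yc = x - x.mean(), y - y.mean()
        r_direct = float((xc * yc).sum() / math.sqrt((xc**2).sum() * (yc**2).sum()))
        assert r_scipy == pytest.approx(r_direct, abs=1e-12)


def _wilcoxon_exact_oracle(x, y):
    """Two-sided rank-sum p by enumerating all rank assignments (no ties)."""
    pooled = sorted(x) + sorted(y)
    m = len(x)
    u_obs = sum(1 for xi in x for yj in y if xi > yj)
    center = m * len(y) / 2
    total = 0
    extreme = 0
    idx = range(len(pooled))
    pooled_sorted = sorted(pooled)
    for combo in itertools.combinations(range(len(pooled)), m):
        xs = [pooled_sorted[i] for i in combo]
        ys = [pooled_sorted[i] for i in idx if i not in combo]
        u = sum(1 for xi in xs for yj in ys if xi > yj)
        total += 1
        if abs(u - center) >= abs(u_obs - center) - 1e-12:
            extreme += 1
    return extreme / total


class TestWilcoxon:
    def test_identical_distributions_give_p_one(self):
        x = np.arange(10.0)
        u, p = wilcoxon_rank_sum(x, x)
        assert p == pytest.approx(1.0)

    def test_large_shift_is_detected(self):
        rng = np.random.default_rng(25)
        a = rng.normal(-2, 1, size=200)
        b = rng.normal(0, 1, size=200)
        _, p = wilcoxon_rank_sum(a, b)
        assert p < 1e-10

    @pytest.mark.parametrize("seed", range(8))
    def test_small_sample_statistic_matches_rank_permutation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m, n = int(rng.integers(3, 6)), int(rng.integers(3, 6))
        x = rng.normal(size=m)
        y = rng.normal(size=n)
        _, p = wilcoxon_rank_sum(x, y)
        assert p == pytest.approx(_wilcoxon_exact_oracle(list(x), list(y)), abs=1e-12)


class TestStructureStrata:
    def _table(self, ann_len=40):
        rng = np.random.default_rng(26)
        rows = []
        for pos in range(1, ann_len + 1):
            shift = -2.0 if pos <= ann_len // 2 else 0.0
            rows.append({"hgvs": f"p.A{pos}del", "score": shift + rng.normal(0, 1)})
            rows.append({"hgvs": f"p.A{pos}_insG", "score": shift + rng.normal(0, 1)})
        return read_scores(pd.DataFrame(rows))

    def test_structured_vs_unstructured_shift_is_significant(self):
        ann = StructureAnnotation(("helix",) * 20 + ("unstructured",) * 20)
        out = structure_strata(self._table(), ann)
        row = out[(out["comparison"] == "structured_vs_unstructured") & (out["kinds"] == "all")]
        assert row["p"].iloc[0] < 1e-6
        assert row["median_a"].iloc[0] < row["median_b"].iloc[0]

    def test_helix_vs_sheet_comparison_present(self):
        ann = StructureAnnotation(("helix",) * 20 + ("sheet",) * 20)
        out = structure_strata(self._table(), ann)
        assert (out["comparison"] == "helix_vs_sheet").any()

    def test_annotation_validates_classes(self):
        with pytest.raises(ValueError, match="unknown structure"):
            StructureAnnotation(("coil",))

    def test_annotation_tsv_round_trip(self, tmp_path):
        path = tmp_path / "ann.tsv"
        path.write_text("1\thelix\n2\tsheet\n3\tunstructured\n")
        ann = StructureAnnotation.from_tsv(path)
        assert ann.classes == ("helix", "sheet", "unstructured")
        assert ann.structured(1) and not ann.structured(3)


def _fisher_oracle(table):
    """Two-sided Fisher p: sum of hypergeometric pmfs <= observed pmf."""
    a, b = table[0]
    c, d = table[1]
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    pmf = lambda k: (
        math.comb(r1, k) * math.comb(r2, c1 - k) / math.comb(n, c1)
    )
    p_obs = pmf(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    return sum(pmf(k) for k in range(lo, hi + 1) if pmf(k) <= p_obs * (1 + 1e-9))


class TestFisher:
    def test_flat_table_gives_p_one(self):
        assert fisher_exact_two_sided([[10, 10], [10, 10]]) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "table", [[[8, 2], [1, 9]], [[5, 0], [3, 7]], [[2, 13], [11, 4]], [[1, 1], [18, 2]]]
    )
    def test_matches_hypergeometric_enumeration(self, table):
        assert fisher_exact_two_sided(table) == pytest.approx(_fisher_oracle(table), abs=1e-12)

    def test_sweep_of_small_margins_matches_oracle(self):
        rng = np.random.default_rng(27)
        for _ in range(60):
            t = rng.integers(0, 11, size=(2, 2))
            if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
                continue
            p = fisher_exact_two_sided(t)
            assert p == pytest.approx(_fisher_oracle(t.tolist()), abs=1e-12)


class TestHMMProfile:
    def test_encoded_transition_probabilities_round_trip(self, tmp_path):
        cons = "MKLVNWAEQR"
        mi = [0.2, 0.02, 0.02, 0.3, 0.02, 0.02, 0.02, 0.15, 0.02, 0.02]
        md = [0.1, 0.02, 0.02, 0.02, 0.25, 0.02, 0.02, 0.02, 0.12, 0.0]
        path = write_hmm_profile(tmp_path / "toy.hmm", cons, mi, md)
        prof = read_hmm_indel_profile(path, cons)
        for k in range(1, 11):
            assert prof.ins_prob[k] == pytest.approx(mi[k - 1], abs=1e-9)
            assert prof.del_prob[k] == pytest.approx(md[k - 1], abs=1e-9)

    def test_exact_consensus_match_maps_identically(self, tmp_path):
        cons = "MKWLANDERVQHISTY"
        m = len(cons)
        path = write_hmm_profile(tmp_path / "t.hmm", cons, [0.05] * m, [0.05] * m)
        prof = read_hmm_indel_profile(path, cons)
        assert prof.positions == list(range(1, m + 1))

    def test_two_domain_profiles_map_to_disjoint_ranges(self, tmp_path):
        target = "MKWLANDERV" + "QHISTYCFGP" + "WKLMNEDAVR"
        p1 = write_hmm_profile(tmp_path / "a.hmm", target[:10], [0.2] * 10, [0.1] * 10, name="nterm")
        p2 = write_hmm_profile(tmp_path / "b.hmm", target[20:], [0.3] * 10, [0.05] * 10, name="cterm")
        prof = read_hmm_indel_profile([p1, p2], target)
        mapped = prof.positions
        assert set(mapped) <= set(range(1, 11)) | set(range(21, 31))
        assert len(mapped) == len(set(mapped))


class TestIndelConservation:
    def _profile(self, positions, ins_hot, del_hot):
        return HMMIndelProfile(
            ins_prob={p: (0.4 if p in ins_hot else 0.01) for p in positions},
            del_prob={p: (0.4 if p in del_hot else 0.01) for p in positions},
        )

    def test_flat_association_gives_p_one(self):
        rng = np.random.default_rng(28)
        rows = []
        for pos in range(1, 41):
            rows.append({"hgvs": f"p.A{pos}_insG", "score": float(rng.normal())})
            rows.append({"hgvs": f"p.A{pos}del", "score": float(rng.normal())})
        st = read_scores(pd.DataFrame(rows))
        prof = self._profile(range(1, 41), ins_hot=set(range(1, 41, 2)), del_hot=set(range(2, 41, 2)))
        out = indel_conservation_test(st, prof)
        assert out["insertion"]["p"] > 0.05  # independent layout: no signal

    def test_perfect_association_drives_p_to_zero(self):
        rows = []
        hot = set(range(1, 21))
        for pos in range(1, 41):
            score = 1.0 if pos in hot else -1.0
            rows.append({"hgvs": f"p.A{pos}_insG", "score": score})
            rows.append({"hgvs": f"p.A{pos}del", "score": score})
        st = read_scores(pd.DataFrame(rows))
        prof = self._profile(range(1, 41), ins_hot=hot, del_hot=hot)
        out = indel_conservation_test(st, prof)
        assert out["insertion"]["p"] < 1e-8
        assert out["deletion"]["p"] < 1e-8

    def test_degenerate_table_warns_and_returns_one(self):
        rows = [{"hgvs": f"p.A{pos}_insG", "score": 1.0} for pos in range(1, 11)]
        rows += [{"hgvs": f"p.A{pos}del", "score": 1.0} for pos in range(1, 11)]
        st = read_scores(pd.DataFrame(rows))
        prof = self._profile(range(1, 11), ins_hot=set(), del_hot=set())
        with pytest.warns(UserWarning, match="degenerate"):
            out = indel_conservation_test(st, prof)
        assert out["insertion"]["p"] == 1.0
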