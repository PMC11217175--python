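import itertools

import numpy as np
import pandas as pd
import pytest

from sclcnet import (
    EnrichmentMatrix,
    ExpressionMatrix,
    GeneSetCollection,
    SampleMetadata,
    compare_groups,
    composite_scores,
    ssgsea_score,
)
from sclcnet.scoring import _rank_sum_p


def expr(values: dict[str, list[float]], genes: list[str]) -> ExpressionMatrix:
    return ExpressionMatrix(pd.DataFrame(values, index=genes))


def brute_force_score(ranked_in_set: list[bool], alpha: float) -> float:
    """Position-by-position cumulative-sum oracle for one sample and set."""
    n = len(ranked_in_set)
    n_in = sum(ranked_in_set)
    weights = [(n - i + 1) ** alpha if m else 0.0
               for i, m in enumerate(ranked_in_set, start=1)]
    total_w = sum(weights)
    score, cin, cout = 0.0, 0.0, 0.0
    for i, m in enumerate(ranked_in_set):
        cin += weights[i] / total_w
        cout += (not m) / (n - n_in)
        score += cin - cout
    return score


class TestSsgsea:
    def test_single_top_gene_scores_plus_1_5(self):
        X = expr({"s": [3.0, 2.0, 1.0]}, ["A", "B", "C"])
        E = ssgsea_score(X, GeneSetCollection({"top": ("A",)}), alpha=0.25)
        assert E.data.loc["top", "s"] == pytest.approx(1.5)

    def test_single_bottom_gene_scores_minus_1_5(self):
        X = expr({"s": [3.0, 2.0, 1.0]}, ["A", "B", "C"])
        E = ssgsea_score(X, GeneSetCollection({"bot": ("C",)}), alpha=0.25)
        assert E.data.loc["bot", "s"] == pytest.approx(-1.5)

    def test_improving_in_set_rank_never_lowers_score(self, rng):
        genes = [f"g{i:02d}" for i in range(12)]
        vals = rng.normal(size=12)
        members = ("g03", "g07")
        base = ssgsea_score(
            expr({"s": vals.tolist()}, genes),
            GeneSetCollection({"S": members}),
        ).data.loc["S", "s"]
        boosted = vals.copy()
        boosted[3] = vals.max() + 1.0  # promote an in-set gene to rank 1
        up = ssgsea_score(
            expr({"s": boosted.tolist()}, genes),
            GeneSetCollection({"S": members}),
        ).data.loc["S", "s"]
        assert up >= base - 1e-12

    def test_monotone_transform_invariance(self, rng):
        genes = [f"g{i:02d}" for i in range(15)]
        vals = rng.normal(size=(15, 3))
        sets = GeneSetCollection({"S": ("g01", "g05", "g09")})
        a = ssgsea_score(
            ExpressionMatrix(pd.DataFrame(vals, index=genes, columns=list("xyz"))),
            sets,
        )
        b = ssgsea_score(
            ExpressionMatrix(
                pd.DataFrame(np.exp(vals) + 5, index=genes, columns=list("xyz"))
            ),
            sets,
        )
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_complement_antisymmetry_at_alpha_zero(self, rng):
        genes = [f"g{i:02d}" for i in range(10)]
        vals = rng.normal(size=10)
        members = ("g02", "g04", "g06")
        complement = tuple(g for g in genes if g not in members)
        X = expr({"s": vals.tolist()}, genes)
        E = ssgsea_score(
            X, GeneSetCollection({"S": members, "notS": complement}), alpha=0.0
        )
        assert E.data.loc["S", "s"] == pytest.approx(-E.data.loc["notS", "s"])

    def test_matches_brute_force_oracle(self, rng):
        genes = [f"g{i:02d}" for i in range(9)]
        vals = rng.normal(size=9)
        members = ("g00", "g03", "g08")
        E = ssgsea_score(
            expr({"s": vals.tolist()}, genes),
            GeneSetCollection({"S": members}),
            alpha=0.25,
        )
        order = np.argsort(-vals, kind="stable")
        ranked = [genes[i] in members for i in order]
        assert E.data.loc["S", "s"] == pytest.approx(
            brute_force_score(ranked, 0.25)
        )

    def test_no_overlap_and_full_universe_rejected(self):
        X = expr({"s": [1.0, 2.0]}, ["A", "B"])
        with pytest.raises(ValueError, match="'ghost'"):
            ssgsea_score(X, GeneSetCollection({"ghost": ("Z",)}))
        with pytest.raises(ValueError, match="'all'"):
            ssgsea_score(X, GeneSetCollection({"all": ("A", "B")}))

    def test_normalize_divides_by_score_range(self):
        X = expr({"s1": [3.0, 2.0, 1.0], "s2": [1.0, 2.0, 3.0]}, ["A", "B", "C"])
        sets = GeneSetCollection({"top": ("A",)})
        raw = ssgsea_score(X, sets, normalize=False).data
        norm = ssgsea_score(X, sets, normalize=True).data
        span = raw.to_numpy().max() - raw.to_numpy().min()
        assert np.allclose(norm, raw / span)


class TestCompositeScores:
    def test_arithmetic_by_definition(self):
        E = EnrichmentMatrix(
            pd.DataFrame({"s": [0.4, 0.2]}, index=["imm", "str"])
        )
        out = composite_scores(E, ["imm"], ["str"])
        assert out.loc["s", "immune_score"] == pytest.approx(0.4)
        assert out.loc["s", "stromal_score"] == pytest.approx(0.2)
        assert out.loc["s", "microenvironment_score"] == pytest.approx(0.6)

    def test_zero_signatures_give_zero_score(self):
        E = EnrichmentMatrix(
            pd.DataFrame({"s": [0.0, 0.1]}, index=["imm", "str"])
        )
        assert composite_scores(E, ["imm"], ["str"]).loc["s", "immune_score"] == 0.0

    def test_sample_permutation_equivariance(self, rng):
        E = EnrichmentMatrix(
            pd.DataFrame(rng.normal(size=(3, 5)),
                         index=["i1", "i2", "st"],
                         columns=[f"s{j}" for j in range(5)])
        )
        out = composite_scores(E, ["i1", "i2"], ["st"])
        perm = ["s3", "s0", "s4", "s1", "s2"]
        out_p = composite_scores(
            EnrichmentMatrix(E.data[perm]), ["i1", "i2"], ["st"]
        )
        pd.testing.assert_frame_equal(out_p, out.loc[perm])

    def test_empty_name_list_rejected(self):
        E = EnrichmentMatrix(pd.DataFrame({"s": [0.4]}, index=["imm"]))
        with pytest.raises(ValueError):
            composite_scores(E, [], ["imm"])


def exact_mw_p_by_enumeration(a, b) -> float:
    """Two-sided Mann-Whitney p by enumerating all label assignments."""
    pooled = np.asarray(list(a) + list(b), dtype=float)
    na = len(a)

    def u_stat(ids):
        av = pooled[list(ids)]
        bv = np.delete(pooled, list(ids))
        return sum((x > y) + 0.5 * (x == y) for x in av for y in bv)

    observed = u_stat(range(na))
    mean_u = na * len(b) / 2.0
    count = total = 0
    for ids in itertools.combinations(range(len(pooled)), na):
        total += 1
        if abs(u_stat(ids) - mean_u) >= abs(observed - mean_u) - 1e-12:
            count += 1
    return count / total


class TestCompareGroups:
    def test_two_vs_two_exact_p_one_third(self, meta_17):
        # arms {1,2} vs {3,4}: U = 0, 2 of 6 orderings as extreme
        a, b = np.array([1.0, 2.0]), np.array([3.0, 4.0])
        u, p = _rank_sum_p(a, b)
        assert p == pytest.approx(1 / 3)
        assert p == pytest.approx(exact_mw_p_by_enumeration(a, b))

    def test_exact_p_matches_enumeration_small_groups(self, rng):
        for na, nb in [(3, 4), (5, 5), (6, 6)]:
            a = rng.normal(size=na)
            b = rng.normal(size=nb) + 0.5
            _, p = _rank_sum_p(a, b)
            assert p == pytest.approx(exact_mw_p_by_enumeration(a, b))

    def _enrichment(self, meta, values_by_sample):
        return EnrichmentMatrix(
            pd.DataFrame({s: [values_by_sample[s]] for s in meta.sample_ids},
                         index=["S"])
        )

    def test_identical_distributions_give_p_one(self, meta_17):
        E = self._enrichment(meta_17, {s: 1.0 for s in meta_17.sample_ids})
        rec = compare_groups(
            E, meta_17, "unpaired", ("PR", "pre"), ("AR", "pre")
        ).iloc[0]
        assert rec["p_value"] == 1.0
        assert rec["direction"] == "equal"

    def test_swapping_arms_flips_direction_keeps_p(self, meta_17, rng):
        vals = {s: float(v) for s, v in
                zip(meta_17.sample_ids, rng.normal(size=34))}
        E = self._enrichment(meta_17, vals)
        ab = compare_groups(E, meta_17, "unpaired", ("PR", "pre"), ("AR", "pre")).iloc[0]
        ba = compare_groups(E, meta_17, "unpaired", ("AR", "pre"), ("PR", "pre")).iloc[0]
        assert ab["p_value"] == pytest.approx(ba["p_value"])
        if ab["direction"] != "equal":
            assert {ab["direction"], ba["direction"]} == {"up", "down"}

    def test_paired_all_zero_differences_flagged(self, meta_17):
        E = self._enrichment(meta_17, {s: 2.5 for s in meta_17.sample_ids})
        rec = compare_groups(
            E, meta_17, "paired", ("AR", "pre"), ("AR", "post")
        ).iloc[0]
        assert rec["p_value"] == 1.0
        assert bool(rec["degenerate"])

    def test_paired_detects_planted_shift(self, meta_17, rng):
        base = rng.normal(size=17)
        vals = {}
        for i, (_, row) in enumerate(meta_17.table.iterrows()):
            shift = 1.0 if row["timepoint"] == "post" else 0.0
            vals[row["sample_id"]] = float(
                base[i // 2] + shift + 0.05 * rng.normal()
            )
        E = self._enrichment(meta_17, vals)
        rec = compare_groups(
            E, meta_17, "paired", (None, "pre"), (None, "post")
        ).iloc[0]
        assert rec["p_value"] < 0.01
        assert rec["direction"] == "down"  # pre is arm a
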