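import numpy as np
import pandas as pd
import pytest

from methylarow import (
    MulticlassArowModel,
    annotate_counts,
    common_sites,
    extract_weight_table,
    high_weight_count_summary,
    per_class_counts,
    select_high_weight,
)
from methylarow.weights import HighWeightSelection


class TestExtractWeightTable:
    def test_two_classes_times_three_probes(self):
        model = MulticlassArowModel(["cg1", "cg2", "cg3"])
        table = extract_weight_table(model)
        assert len(table) == 6
        assert (table["weight"] == 0).all()

    def test_entries_match_model_mu_elementwise(self, rng):
        model = MulticlassArowModel([f"cg{i}" for i in range(10)])
        model.mu = rng.normal(size=model.mu.shape)
        table = extract_weight_table(model)
        for _, row in table.iterrows():
            c = model.classes.index(row["class"])
            j = model.feature_index[row["probe_id"]]
            assert row["weight"] == model.mu[c, j]


def _table(weights, classes=None, probes=None):
    n = len(weights)
    return pd.DataFrame(
        {
            "class": classes or ["ESC", "iPSC"] * (n // 2) + ["ESC"] * (n % 2),
            "probe_id": probes or [f"cg{i:04d}" for i in range(n)],
            "weight": weights,
        }
    )


class TestSelectHighWeight:
    def test_k_equal_table_size_takes_everything(self):
        table = _table(list(range(10)))
        sel = select_high_weight(table, k=10)
        assert len(sel.positive_set) == len(sel.negative_set) == 10

    def test_distinct_weights_match_ranks(self):
        table = _table(list(range(1, 21)))
        sel = select_high_weight(table, k=5)
        top_probes = {p for _, p in sel.positive_set}
        assert top_probes == {f"cg{i:04d}" for i in range(15, 20)}  # weights 16..20
        bottom = {p for _, p in sel.negative_set}
        assert bottom == {f"cg{i:04d}" for i in range(5)}  # weights 1..5

    def test_matches_full_sort_oracle_on_large_random_table(self, rng):
        n = 10_000
        table = _table(list(rng.normal(size=n)))
        k = 500
        sel = select_high_weight(table, k=k)
        order = np.argsort(-table["weight"].to_numpy(), kind="stable")
        top_oracle = set(zip(table["class"].iloc[order[:k]],
                             table["probe_id"].iloc[order[:k]]))
        bot_oracle = set(zip(table["class"].iloc[order[-k:]],
                             table["probe_id"].iloc[order[-k:]]))
        assert sel.positive_set == top_oracle
        assert sel.negative_set == bot_oracle

    def test_ties_at_cutoff_resolved_deterministically(self):
        # five entries tied exactly at the cutoff value
        weights = [5.0, 5.0, 5.0, 5.0, 5.0, 1.0, 9.0, 8.0]
        table = _table(weights)
        a = select_high_weight(table, k=4)
        b = select_high_weight(table.sample(frac=1, random_state=0), k=4)
        assert a.positive_set == b.positive_set
        assert a.negative_set == b.negative_set
        assert len(a.positive_set) == 4

    def test_k_too_large_errors(self):
        with pytest.raises(ValueError, match="exceeds"):
            select_high_weight(_table([1.0, 2.0]), k=3)


class TestPerClassCounts:
    def test_single_class_selection(self):
        sel = HighWeightSelection(
            series_id=1, k=2,
            positive_set=frozenset({("iPSC", "a"), ("iPSC", "b")}),
            negative_set=frozenset({("ESC", "c"), ("iPSC", "d")}),
        )
        counts = per_class_counts(sel)
        assert counts == {"iPSC_pos": 2, "ESC_neg": 1, "iPSC_neg": 1}

    def test_positive_counts_partition_k(self, rng):
        table = _table(list(rng.normal(size=200)))
        sel = select_high_weight(table, k=40)
        counts = per_class_counts(sel)
        assert counts.get("ESC_pos", 0) + counts.get("iPSC_pos", 0) == 40
        assert counts.get("ESC_neg", 0) + counts.get("iPSC_neg", 0) == 40

    def test_summary_mean_sem(self):
        sels = [
            HighWeightSelection(i, 2,
                                frozenset({("iPSC", "a"), ("iPSC", f"b{i}")}),
                                frozenset({("ESC", "c"), ("ESC", f"d{i}")}))
            for i in range(1, 5)
        ]
        summary = high_weight_count_summary(sels)
        assert summary.loc["iPSC_pos", "mean"] == 2.0
        assert summary.loc["iPSC_pos", "sem"] == 0.0
        assert summary.loc["ESC_pos", "mean"] == 0.0


def _selection(sid, pos, neg):
    return HighWeightSelection(sid, max(len(pos), len(neg)),
                               frozenset(pos), frozenset(neg))


class TestCommonSites:
    def test_identical_selections_idempotent(self):
        pos = {("ESC", "a"), ("iPSC", "b")}
        neg = {("ESC", "c"), ("iPSC", "d")}
        sig = common_sites([_selection(i, pos, neg) for i in range(1, 5)])
        assert sig.common_sites["ESC"]["pos"] == {"a"}
        assert sig.common_sites["iPSC"]["neg"] == {"d"}

    def test_disjoint_selections_empty(self):
        sels = [
            _selection(i, {("ESC", f"p{i}")}, {("iPSC", f"q{i}")}) for i in range(1, 5)
        ]
        sig = common_sites(sels)
        assert all(not s for cls in sig.common_sites.values() for s in cls.values())
        assert not sig.esc_pos_ipsc_neg and not sig.ipsc_pos_esc_neg

    def test_planted_core_recovered_and_order_invariant(self, rng):
        core_pos = {("iPSC", f"core{i}") for i in range(30)}
        core_neg = {("ESC", f"core{i}") for i in range(30)}
        sels = []
        for sid in range(1, 5):
            noise_p = {("iPSC", f"np{sid}{i}") for i in range(10)}
            noise_n = {("ESC", f"nn{sid}{i}") for i in range(10)}
            sels.append(_selection(sid, core_pos | noise_p, core_neg | noise_n))
        sig = common_sites(sels)
        assert sig.common_sites["iPSC"]["pos"] == {f"core{i}" for i in range(30)}
        assert sig.ipsc_pos_esc_neg == {f"core{i}" for i in range(30)}
        shuffled = common_sites(sels[::-1])
        assert shuffled.ipsc_pos_esc_neg == sig.ipsc_pos_esc_neg

    def test_cross_sets_disjoint_when_pos_neg_disjoint(self, rng):
        table = _table(list(rng.normal(size=400)))
        sels = [select_high_weight(table, k=50, series_id=i) for i in range(1, 5)]
        sig = common_sites(sels)
        assert not (sig.esc_pos_ipsc_neg & sig.ipsc_pos_esc_neg)


class TestAnnotateCounts:
    @pytest.fixture()
    def annotation(self):
        return pd.DataFrame(
            {
                "chromosome": ["8", "8", "8", "12"],
                "gene_feature_groups": [
                    frozenset({"TSS200", "Body"}),
                    frozenset({"Body"}),
                    frozenset({"intergenic"}),
                    frozenset({"TSS200"}),
                ],
                "cgi_relation": ["Island", "Island", "OpenSea", "N_Shore"],
            },
            index=pd.Index(["p1", "p2", "p3", "p4"], name="probe_id"),
        )

    def test_chromosome_facet_all_on_one(self, annotation):
        out = annotate_counts(["p1", "p2", "p3"], annotation, "chromosome")
        assert list(out["category"]) == ["8"]
        assert out["proportion"].iloc[0] == 1.0

    def test_multi_group_probe_counts_once_per_group(self, annotation):
        out = annotate_counts(["p1"], annotation, "gene_feature")
        assert dict(zip(out["category"], out["count"])) == {"Body": 1, "TSS200": 1}
        assert out["proportion"].sum() == pytest.approx(1.0)

    def test_tallies_match_hand_enumeration(self, annotation):
        out = annotate_counts(["p1", "p2", "p3", "p4"], annotation, "gene_feature")
        assert dict(zip(out["category"], out["count"])) == {
            "Body": 2, "TSS200": 2, "intergenic": 1,
        }
        cgi = annotate_counts(["p1", "p2", "p3", "p4"], annotation, "cgi_relation")
        assert dict(zip(cgi["category"], cgi["count"])) == {
            "Island": 2, "N_Shore": 1, "OpenSea": 1,
        }

    def test_unknown_facet_and_missing_probe(self, annotation):
        with pytest.raises(ValueError, match="facet"):
            annotate_counts(["p1"], annotation, "strand")
        with pytest.raises(KeyError):
            annotate_counts(["zz"], annotation, "chromosome")
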