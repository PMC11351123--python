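import itertools

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from pddlearn.disentangle import DSU
from pddlearn.patterns import count_patterns, grow_patterns
from pddlearn.sr_matrix import build_sr_matrix, indicator_matrix
from .conftest import make_dataset


def bruteforce_patterns(dsu, dataset, sr, min_support, max_order, threshold=1.96):
    """Independent oracle: enumerate every attribute-distinct AV subset of
    the DSU (orders 2..max_order) and apply the same support and
    connectivity tests directly."""
    label = dataset.label_attribute
    cand = sorted(i for i in dsu.members if sr.index.avs[i][0] != label)
    X = indicator_matrix(dataset.data, sr.index)
    sig = np.abs(sr.residuals) >= threshold
    sig[sr.structural_zero] = False
    found = []
    for order in range(2, max_order + 1):
        for combo in itertools.combinations(cand, order):
            attrs = [sr.index.avs[i][0] for i in combo]
            if len(set(attrs)) < len(attrs):
                continue
            support = X[:, list(combo)].all(axis=1).sum()
            if support < min_support:
                continue
            if all(any(sig[a, b] for b in combo if b != a) for a in combo):
                found.append(tuple(combo))
    return sorted(found)


def toy_world():
    """<= 15 records, <= 8 AVs, engineered so some subsets pass support
    but fail connectivity and vice versa."""
    rows = []
    for _ in range(6):
        rows.append({"a": "1", "b": "1", "c": "1", "d": "1", "class": "x"})
    for _ in range(5):
        rows.append({"a": "1", "b": "1", "c": "2", "d": "2", "class": "x"})
    for _ in range(4):
        rows.append({"a": "2", "b": "2", "c": "1", "d": "2", "class": "y"})
    ds = make_dataset(rows)
    sr = build_sr_matrix(ds, include_label=False)
    members = list(range(len(sr.index)))
    dsu = DSU(code=(1, 1, 1), members=members,
              summarized_pattern=[sr.index.avs[i] for i in members])
    return ds, sr, dsu


@pytest.mark.parametrize("min_support,max_order", [(2, 3), (3, 4), (5, 2)])
def test_growth_matches_bruteforce_oracle(min_support, max_order):
    ds, sr, dsu = toy_world()
    grown = grow_patterns(ds_dsu := dsu, ds, sr, min_support=min_support,
                          max_order=max_order)
    got = sorted(p.avs for p in grown)
    expected = bruteforce_patterns(dsu, ds, sr, min_support, max_order)
    assert got == expected
    assert len(expected) > 0  # the toy world is not vacuous


def test_smallest_case_single_pair():
    rows = [{"a": "1", "b": "1", "class": "x"} for _ in range(8)]
    rows += [{"a": "2", "b": "2", "class": "y"} for _ in range(8)]
    ds = make_dataset(rows)
    sr = build_sr_matrix(ds, include_label=False)
    members = [sr.index.position("a", "1"), sr.index.position("b", "1")]
    dsu = DSU(code=(1, 1, 1), members=members)
    grown = grow_patterns(dsu, ds, sr, min_support=5, max_order=5)
    assert len(grown) == 1
    assert grown[0].avs == tuple(sorted(members))
    assert len(grown[0].support) == 8


def test_min_support_validation():
    ds, sr, dsu = toy_world()
    with pytest.raises(ValueError, match="min_support"):
        grow_patterns(dsu, ds, sr, min_support=0)


def test_support_antimonotone():
    ds, sr, dsu = toy_world()
    grown = grow_patterns(dsu, ds, sr, min_support=2, max_order=4)
    by_avs = {p.avs: p.support for p in grown}
    for avs, support in by_avs.items():
        for sub in itertools.combinations(avs, len(avs) - 1):
            if sub in by_avs:
                assert support <= by_avs[sub]


def test_label_avs_never_enter_patterns(default_world, fitted_default):
    _, dataset, _ = default_world
    label = dataset.label_attribute
    for plist in fitted_default.knowledge_base_.pattern_space.values():
        for p in plist:
            assert all(a != label for a, _ in p.av_pairs)


class TestCounting:
    def test_full_pattern_record_possesses_everything(self):
        ds, sr, dsu = toy_world()
        grown = grow_patterns(dsu, ds, sr, min_support=2, max_order=4)
        counts = count_patterns({(1, 1, 1): grown}, ds, sr)
        total = counts.cp_totals[(1, 1, 1)]
        # records of the first row-type contain AVs a=1,b=1,c=1,d=1
        full = [p for p in grown
                if all(ds.data.loc["r0", a] == c for a, c in p.av_pairs)]
        assert counts.count("r0", (1, 1, 1)) == len(full)

    def test_empty_pattern_list_counts_zero(self):
        ds, sr, _ = toy_world()
        counts = count_patterns({(9, 9, 9): []}, ds, sr)
        assert counts.cp_totals[(9, 9, 9)] == 0
        assert (counts.record_counts["9.9.9"] == 0).all()

    def test_counts_match_double_loop(self):
        ds, sr, dsu = toy_world()
        grown = grow_patterns(dsu, ds, sr, min_support=2, max_order=3)
        counts = count_patterns({(1, 1, 1): grown}, ds, sr)
        for rid in ds.record_ids:
            row = ds.data.loc[rid]
            brute = sum(
                1 for p in grown
                if all(row[a] == c for a, c in p.av_pairs)
            )
            assert counts.count(rid, (1, 1, 1)) == brute
            assert 0 <= brute <= counts.cp_totals[(1, 1, 1)]

    def test_counting_invariant_to_pattern_order(self):
        ds, sr, dsu = toy_world()
        grown = grow_patterns(dsu, ds, sr, min_support=2, max_order=3)
        fwd = count_patterns({(1, 1, 1): grown}, ds, sr)
        rev = count_patterns({(1, 1, 1): grown[::-1]}, ds, sr)
        assert fwd.record_counts.equals(rev.record_counts)


def test_class_records_possess_more_own_class_patterns(default_world, fitted_default):
    """Records of class c carry more patterns in c-associated DSUs than
    records of the other class (rank-sum check on the planted world)."""
    _, dataset, truth = default_world
    kb = fitted_default.knowledge_base_
    counts = kb.data_space.record_counts
    clean = truth.table[truth.table.planted_status == "clean"]
    for cls in ("sepsis", "other"):
        codes = [d.code_str for d in kb.knowledge_space
                 if d.class_assoc == cls
                 and kb.data_space.cp_totals[tuple(d.code)] >= 100]
        assert codes, f"no substantial {cls} DSUs discovered"
        own = counts.loc[clean.index[clean.true_class == cls], codes].sum(axis=1)
        other = counts.loc[clean.index[clean.true_class != cls], codes].sum(axis=1)
        stat = mannwhitneyu(own, other, alternative="greater")
        assert stat.pvalue < 1e-6
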