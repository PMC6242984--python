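import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

import facegaze as fg


def oneway_oracle(groups):
    """Explicit-loop sum-of-squares decomposition."""
    alln = [v for g in groups.values() for v in g]
    grand = sum(alln) / len(alln)
    ss_b = 0.0
    ss_w = 0.0
    for g in groups.values():
        m = sum(g) / len(g)
        ss_b += len(g) * (m - grand) ** 2
        for v in g:
            ss_w += (v - m) ** 2
    df_b = len(groups) - 1
    df_w = len(alln) - len(groups)
    f = (ss_b / df_b) / (ss_w / df_w)
    eta = ss_b / (ss_b + ss_w)
    return f, eta


class TestOnewayAnova:
    def test_identical_groups_give_zero_f(self):
        res = fg.oneway_anova({"a": [1, 2, 3], "b": [1, 2, 3], "c": [1, 2, 3]})
        assert res.F == 0.0
        assert res.partial_eta_sq == 0.0

    def test_two_groups_f_is_t_squared(self):
        a = [4.1, 5.2, 3.9, 4.8, 5.5]
        b = [6.0, 6.3, 5.7, 7.1]
        res = fg.oneway_anova({"a": a, "b": b})
        t, _ = sps.ttest_ind(a, b)
        assert res.F == pytest.approx(t ** 2, rel=1e-12)

    def test_matches_ss_oracle_and_scipy(self):
        rng = np.random.default_rng(11)
        groups = {k: rng.normal(i, 1.0, 5).tolist()
                  for i, k in enumerate("abc")}
        res = fg.oneway_anova(groups)
        f, eta = oneway_oracle(groups)
        assert res.F == pytest.approx(f, abs=1e-9)
        assert res.partial_eta_sq == pytest.approx(eta, abs=1e-9)
        f_sp, p_sp = sps.f_oneway(*groups.values())
        assert res.F == pytest.approx(f_sp, rel=1e-12)
        assert res.p == pytest.approx(p_sp, rel=1e-9)

    def test_constant_shift_invariance(self):
        rng = np.random.default_rng(2)
        groups = {k: rng.normal(0, 1, 6) for k in "ab"}
        shifted = {k: v + 100.0 for k, v in groups.items()}
        assert fg.oneway_anova(groups).F == pytest.approx(
            fg.oneway_anova(shifted).F, rel=1e-9)

    def test_rejects_degenerate_designs(self):
        with pytest.raises(ValueError):
            fg.oneway_anova({"a": [1, 2]})
        with pytest.raises(ValueError):
            fg.oneway_anova({"a": [1, 2], "b": [3]})


def mixed_oracle(df, dv, between, within, subject):
    """Split-plot decomposition by explicit loops over cells."""
    subs = sorted(df[subject].unique())
    bl = sorted(df[between].unique())
    wl = sorted(df[within].unique())
    val = {(r[subject], r[within]): r[dv] for _, r in df.iterrows()}
    grp = {r[subject]: r[between] for _, r in df.iterrows()}
    a, b, n = len(bl), len(wl), len(subs)
    grand = sum(val.values()) / len(val)
    sub_mean = {s: sum(val[(s, w)] for w in wl) / b for s in subs}
    grp_mean = {g: np.mean([sub_mean[s] for s in subs if grp[s] == g]) for g in bl}
    n_g = {g: sum(grp[s] == g for s in subs) for g in bl}
    w_mean = {w: sum(val[(s, w)] for s in subs) / n for w in wl}
    cell = {(g, w): np.mean([val[(s, w)] for s in subs if grp[s] == g])
            for g in bl for w in wl}
    ss_subj = b * sum((sub_mean[s] - grand) ** 2 for s in subs)
    ss_A = b * sum(n_g[g] * (grp_mean[g] - grand) ** 2 for g in bl)
    ss_errA = ss_subj - ss_A
    ss_tot = sum((v - grand) ** 2 for v in val.values())
    ss_B = n * sum((w_mean[w] - grand) ** 2 for w in wl)
    ss_cells = sum(n_g[g] * (cell[(g, w)] - grand) ** 2 for g in bl for w in wl)
    ss_AB = ss_cells - ss_A - ss_B
    ss_errB = ss_tot - ss_subj - ss_B - ss_AB
    def f_eta(ss_e, df_e, ss_r, df_r):
        return (ss_e / df_e) / (ss_r / df_r), ss_e / (ss_e + ss_r)
    return {
        "between": f_eta(ss_A, a - 1, ss_errA, n - a),
        "within": f_eta(ss_B, b - 1, ss_errB, (n - a) * (b - 1)),
        "interaction": f_eta(ss_AB, (a - 1) * (b - 1), ss_errB, (n - a) * (b - 1)),
    }


def _toy_mixed(seed=5, groups=("g1", "g2"), n_per=3, within=("r1", "r2")):
    rng = np.random.default_rng(seed)
    rows = []
    for gi, g in enumerate(groups):
        for s in range(n_per):
            sid = f"{g}_{s}"
            base = rng.normal(gi, 1.0)
            for wi, w in enumerate(within):
                rows.append((sid, g, w, base + 0.5 * wi + rng.normal(0, 0.3)))
    return pd.DataFrame(rows, columns=["item", "grp", "reg", "val"])


class TestMixedAnova:
    def test_all_equal_gives_zero_f(self):
        df = _toy_mixed()
        df["val"] = 3.0
        res = fg.mixed_anova(df, "val", "grp", "reg", "item")
        assert all(r.F == 0.0 for r in res)

    def test_pure_within_effect(self):
        # constant offset per within level, no between differences
        rows = []
        for g in ("g1", "g2"):
            for s in range(4):
                for w, off in (("r1", 0.0), ("r2", 5.0), ("r3", 10.0)):
                    rows.append((f"{g}{s}", g, w, off))
        df = pd.DataFrame(rows, columns=["item", "grp", "reg", "val"])
        res = {r.effect: r for r in fg.mixed_anova(df, "val", "grp", "reg", "item")}
        assert res["grp"].F == 0.0
        assert res["reg"].F == np.inf or res["reg"].F > 1e6
        assert res["reg"].partial_eta_sq == pytest.approx(1.0)

    def test_matches_explicit_ss_oracle(self):
        df = _toy_mixed()
        res = fg.mixed_anova(df, "val", "grp", "reg", "item")
        oracle = mixed_oracle(df, "val", "grp", "reg", "item")
        for r, key in zip(res, ("between", "within", "interaction")):
            f, eta = oracle[key]
            assert r.F == pytest.approx(f, abs=1e-9)
            assert r.partial_eta_sq == pytest.approx(eta, abs=1e-9)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        df = _toy_mixed(seed=9, groups=("a", "b", "c"), n_per=5,
                        within=("w1", "w2", "w3"))
        res = fg.mixed_anova(df, "val", "grp", "reg", "item")
        ref = pg.mixed_anova(df, dv="val", within="reg", between="grp",
                             subject="item")
        for r, (_, row) in zip(res, ref.iterrows()):
            assert r.F == pytest.approx(row["F"], rel=1e-9)
            assert r.partial_eta_sq == pytest.approx(row["np2"], rel=1e-9)

    def test_oneway_equals_between_effect_with_single_within_level(self):
        rng = np.random.default_rng(4)
        groups = {k: rng.normal(i, 1, 6) for i, k in enumerate("ab")}
        rows = [(f"{g}{i}", g, "only", v)
                for g, vs in groups.items() for i, v in enumerate(vs)]
        df = pd.DataFrame(rows, columns=["item", "grp", "reg", "val"])
        between = fg.mixed_anova(df, "val", "grp", "reg", "item")[0]
        ow = fg.oneway_anova(groups)
        assert between.F == pytest.approx(ow.F, rel=1e-9)

    def test_incomplete_design_rejected(self):
        df = _toy_mixed().iloc[:-1]
        with pytest.raises(ValueError):
            fg.mixed_anova(df, "val", "grp", "reg", "item")


class TestBonferroni:
    def test_adjustment_examples(self):
        rng = np.random.default_rng(0)
        groups = {k: rng.normal(i, 1, 10) for i, k in enumerate("abcdef")}
        c = fg.bonferroni_pairwise(groups)
        m = 15
        assert np.allclose(c.p_adjusted[np.triu_indices(6, 1)],
                           np.minimum(c.p_raw[np.triu_indices(6, 1)] * m, 1.0))

    def test_single_pair_identity(self):
        rng = np.random.default_rng(1)
        groups = {"a": rng.normal(0, 1, 8), "b": rng.normal(1, 1, 8)}
        c = fg.bonferroni_pairwise(groups)
        assert c.p_adjusted[0, 1] == pytest.approx(c.p_raw[0, 1])

    @given(st.floats(1e-6, 1.0), st.floats(1e-6, 1.0))
    def test_monotone_and_capped(self, p1, p2):
        m = 15
        a1, a2 = min(p1 * m, 1.0), min(p2 * m, 1.0)
        assert (p1 <= p2) == (a1 <= a2) or a1 == a2 == 1.0
        assert a1 >= p1 and a1 <= 1.0

    def test_symmetric_matrices(self):
        rng = np.random.default_rng(2)
        groups = {k: rng.normal(i, 1, 6) for i, k in enumerate("abc")}
        c = fg.bonferroni_pairwise(groups)
        assert np.allclose(c.p_adjusted, c.p_adjusted.T)
        assert np.all(c.p_adjusted + 1e-12 >= c.p_raw)


def letters_consistent(letters, contrasts):
    """Verify the sharing-iff-non-significant property exhaustively."""
    for a, b in itertools.combinations(letters, 2):
        share = bool(set(letters[a]) & set(letters[b]))
        if share == contrasts.significant(a, b):
            return False
    return True


def contrasts_from_flags(labels, sig_pairs, alpha=0.05):
    k = len(labels)
    p = np.ones((k, k))
    for a, b in sig_pairs:
        i, j = labels.index(a), labels.index(b)
        p[i, j] = p[j, i] = 0.0
    return fg.PairwiseContrasts(tuple(labels), np.zeros((k, k)),
                                p.copy(), p, alpha)


class TestCompactLetterDisplay:
    def test_all_distinct(self):
        labels = ["a_grp", "b_grp", "c_grp"]
        c = contrasts_from_flags(labels, [("a_grp", "b_grp"),
                                          ("a_grp", "c_grp"),
                                          ("b_grp", "c_grp")])
        means = {"a_grp": 3.0, "b_grp": 2.0, "c_grp": 1.0}
        letters = fg.compact_letter_display(c, means)
        assert letters == {"a_grp": "a", "b_grp": "b", "c_grp": "c"}

    def test_none_significant_single_letter(self):
        labels = ["x", "y", "z"]
        c = contrasts_from_flags(labels, [])
        letters = fg.compact_letter_display(c, {"x": 1, "y": 2, "z": 3})
        assert set(letters.values()) == {"a"}

    def test_chain_pattern(self):
        # only A vs C significant, means A > B > C
        labels = ["A", "B", "C"]
        c = contrasts_from_flags(labels, [("A", "C")])
        letters = fg.compact_letter_display(c, {"A": 3.0, "B": 2.0, "C": 1.0})
        assert letters["A"] == "a"
        assert set(letters["B"]) == {"a", "b"}
        assert letters["C"] == "b"
        assert letters_consistent(letters, c)

    def test_highest_mean_carries_first_letter(self):
        rng = np.random.default_rng(3)
        groups = {k: rng.normal(i * 2, 1, 12) for i, k in enumerate("abcd")}
        c = fg.bonferroni_pairwise(groups)
        means = {k: float(np.mean(v)) for k, v in groups.items()}
        letters = fg.compact_letter_display(c, means)
        top = max(means, key=means.get)
        assert "a" in letters[top]

    @given(st.integers(0, 2 ** 15 - 1))
    def test_sharing_iff_nonsignificant_exhaustive(self, pattern):
        # every subset of the 15 pairs of 6 groups as a significance pattern,
        # sampled over the full pattern space
        labels = [f"g{i}" for i in range(6)]
        pairs = list(itertools.combinations(labels, 2))
        sig = [p for i, p in enumerate(pairs) if pattern >> i & 1]
        c = contrasts_from_flags(labels, sig)
        means = {g: float(i) for i, g in enumerate(labels)}
        letters = fg.compact_letter_display(c, means)
        assert letters_consistent(letters, c)
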