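import numpy as np
import pandas as pd
import pytest

from headconc import rater_validation as rv


def _panel(ratings_by_rater: dict, item_class="calibration") -> pd.DataFrame:
    """Build a long response table: each rater rates items 0..k-1."""
    rows = []
    for rater, ratings in ratings_by_rater.items():
        for item, rating in enumerate(ratings):
            rows.append((rater, f"h{item}", item_class, rating))
    return pd.DataFrame(rows, columns=["rater_id", "headline_id", "item_class", "rating"])


class TestRaterQC:
    def test_zero_variance_excluded(self):
        panel = _panel({
            "good1": [1, 2, 3, 4, 5, 4, 3, 2],
            "good2": [1, 2, 3, 4, 5, 5, 3, 2],
            "flat": [3] * 8,
        })
        clean, results = rv.apply_rater_qc(panel)
        flat = next(r for r in results if r.rater_id == "flat")
        assert flat.excluded and flat.reason == rv.REASON_ZERO_VARIANCE
        assert "flat" not in set(clean["rater_id"])

    def test_perfectly_agreeing_rater_retained(self):
        # three identical raters: each correlates 1.0 with the others' mean
        panel = _panel({f"r{i}": [1, 2, 3, 4, 5, 4, 2, 1] for i in range(3)})
        clean, results = rv.apply_rater_qc(panel)
        assert all(not r.excluded for r in results)
        assert all(r.calibration_r == pytest.approx(1.0) for r in results)

    def test_adversarial_rater_excluded(self):
        base = [1, 2, 3, 4, 5, 4, 3, 2]
        panel = _panel({
            "good1": base,
            "good2": base,
            "good3": base,
            "adversary": [6 - r for r in base],  # anti-correlated with the LOO mean
        })
        clean, results = rv.apply_rater_qc(panel)
        adv = next(r for r in results if r.rater_id == "adversary")
        assert adv.excluded and adv.reason == rv.REASON_CALIBRATION
        assert adv.calibration_r < 0.2

    def test_attention_check(self):
        panel = _panel({"r1": [1, 2, 3, 4, 5, 4, 3, 2], "r2": [1, 2, 3, 4, 5, 4, 3, 1]})
        checks = pd.DataFrame(
            [("r1", "att", "attention_check", 5), ("r2", "att", "attention_check", 2)],
            columns=["rater_id", "headline_id", "item_class", "rating"],
        )
        full = pd.concat([panel, checks], ignore_index=True)
        _, results = rv.apply_rater_qc(full, attention_answers={"att": 5})
        by_id = {r.rater_id: r for r in results}
        assert not by_id["r1"].excluded
        assert by_id["r2"].excluded and by_id["r2"].reason == rv.REASON_ATTENTION

    def test_revoked_consent(self):
        panel = _panel({"r1": [1, 2, 3, 4, 5, 4, 3, 2], "r2": [1, 2, 3, 4, 5, 4, 3, 1]})
        _, results = rv.apply_rater_qc(panel, revoked_consent={"r2"})
        by_id = {r.rater_id: r for r in results}
        assert by_id["r2"].excluded and by_id["r2"].reason == rv.REASON_CONSENT

    def test_dont_understand_dropped(self):
        panel = _panel({"r1": [1, 2, 3, 4, 5, 4, 3, 2], "r2": [1, 2, 3, 4, 5, 4, 3, 1]})
        panel["dont_understand"] = False
        extra = pd.DataFrame(
            [("r1", "hx", "main", 9)], columns=["rater_id", "headline_id", "item_class", "rating"]
        ).assign(dont_understand=True)
        clean, _ = rv.apply_rater_qc(pd.concat([panel, extra], ignore_index=True))
        assert "hx" not in set(clean["headline_id"])

    def test_idempotent(self):
        panel = _panel({
            "good1": [1, 2, 3, 4, 5, 4, 3, 2],
            "good2": [1, 2, 3, 4, 5, 5, 3, 2],
            "flat": [3] * 8,
        })
        clean1, _ = rv.apply_rater_qc(panel)
        clean2, results2 = rv.apply_rater_qc(clean1)
        assert clean1.reset_index(drop=True).equals(clean2.reset_index(drop=True))
        assert all(not r.excluded for r in results2)

    def test_missing_columns(self):
        with pytest.raises(KeyError):
            rv.apply_rater_qc(pd.DataFrame({"rater_id": []}))


def _icc_oracle(df: pd.DataFrame) -> tuple[float, float]:
    """Independent one-way ANOVA mean-squares computation (loop-based)."""
    groups = [g["rating"].to_numpy(dtype=float) for _, g in df.groupby("headline_id")]
    grand = np.concatenate(groups).mean()
    n = len(groups)
    N = sum(len(g) for g in groups)
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    msb = ssb / (n - 1)
    msw = ssw / (N - n)
    k0 = (N - sum(len(g) ** 2 for g in groups) / N) / (n - 1)
    return (msb - msw) / (msb + (k0 - 1) * msw), (msb - msw) / msb


class TestICC:
    def test_perfect_agreement(self):
        df = pd.DataFrame({
            "headline_id": ["a"] * 3 + ["b"] * 3 + ["c"] * 3,
            "rating": [1, 1, 1, 3, 3, 3, 5, 5, 5],
        })
        icc_single, icc_average = rv.compute_icc(df)
        assert icc_single == pytest.approx(1.0)
        assert icc_average == pytest.approx(1.0)

    def test_pure_noise_near_zero(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({
            "headline_id": np.repeat(np.arange(1000), 5),
            "rating": rng.normal(3.0, 1.0, 5000),
        })
        icc_single, _ = rv.compute_icc(df)
        assert abs(icc_single) < 0.05

    def test_hand_example_matches_oracle(self):
        df = pd.DataFrame({
            "headline_id": ["a"] * 3 + ["b"] * 3 + ["c"] * 3,
            "rating": [1, 2, 2, 3, 4, 3, 5, 4, 5],
        })
        got = rv.compute_icc(df)
        want = _icc_oracle(df)
        assert got[0] == pytest.approx(want[0], abs=1e-9)
        assert got[1] == pytest.approx(want[1], abs=1e-9)

    def test_matches_pingouin_on_complete_design(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(11)
        n_items, n_raters = 12, 4
        truth = rng.normal(3, 1, n_items)
        long = pd.DataFrame({
            "headline_id": np.repeat(np.arange(n_items), n_raters),
            "rater": np.tile(np.arange(n_raters), n_items),
            "rating": np.repeat(truth, n_raters) + rng.normal(0, 0.5, n_items * n_raters),
        })
        icc = pingouin.intraclass_corr(
            data=long, targets="headline_id", raters="rater", ratings="rating"
        )
        one_way_single = float(icc.loc[icc["Type"].str.contains(r"1,?1"), "ICC"].iloc[0])
        one_way_avg = float(icc.loc[icc["Type"].str.contains(r"1,?k"), "ICC"].iloc[0])
        got_single, got_avg = rv.compute_icc(long)
        assert got_single == pytest.approx(one_way_single, abs=1e-6)
        assert got_avg == pytest.approx(one_way_avg, abs=1e-6)

    def test_unbalanced_matches_oracle(self):
        rng = np.random.default_rng(5)
        counts = rng.integers(2, 7, 40)
        df = pd.DataFrame({
            "headline_id": np.repeat(np.arange(40), counts),
            "rating": rng.normal(np.repeat(rng.normal(3, 0.8, 40), counts), 0.7),
        })
        got = rv.compute_icc(df)
        want = _icc_oracle(df)
        assert got == pytest.approx(want, abs=1e-9)

    def test_degenerate_ratings(self):
        df = pd.DataFrame({"headline_id": ["a", "a", "b", "b"], "rating": [2, 2, 2, 2]})
        with pytest.raises(ValueError, match="degenerate"):
            rv.compute_icc(df)

    def test_insufficient_design(self):
        df = pd.DataFrame({"headline_id": ["a", "a", "b"], "rating": [1, 2, 3]})
        with pytest.raises(ValueError):
            rv.compute_icc(df)

    def test_recovers_variance_ratio(self):
        # icc_single -> sb^2 / (sb^2 + sw^2) as headlines grow
        rng = np.random.default_rng(17)
        sb, sw = 0.8, 0.6
        n_items, k = 500, 10
        truth = sb**2 / (sb**2 + sw**2)
        df = pd.DataFrame({
            "headline_id": np.repeat(np.arange(n_items), k),
            "rating": np.repeat(rng.normal(0, sb, n_items), k)
            + rng.normal(0, sw, n_items * k),
        })
        icc_single, icc_average = rv.compute_icc(df)
        assert icc_single == pytest.approx(truth, abs=0.06)
        assert icc_average >= icc_single


class TestPearson:
    def test_identical(self):
        r, p = rv.correlate_with_computational([1, 2, 3, 4], [1, 2, 3, 4])
        assert r == pytest.approx(1.0)

    def test_negated(self):
        r, _ = rv.correlate_with_computational([1, 2, 3, 4], [-1, -2, -3, -4])
        assert r == pytest.approx(-1.0)

    def test_five_pair_fixture_matches_arithmetic(self):
        x = np.array([1.0, 2.0, 2.5, 4.0, 4.5])
        y = np.array([1.2, 2.2, 2.1, 3.9, 4.8])
        want = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        r, p = rv.correlate_with_computational(x, y)
        assert r == pytest.approx(want, abs=1e-12)
        assert 0 <= p <= 1

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            rv.correlate_with_computational([1, 1, 1], [1, 2, 3])

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            rv.correlate_with_computational([1, 2], [1, 2])


class TestStratifiedSample:
    @pytest.fixture()
    def corpus(self):
        rng = np.random.default_rng(23)
        n = 2000
        words = rng.integers(14, 17, n)
        return pd.DataFrame({
            "headline": [" ".join(["w"] * k) for k in words],
            "score": rng.uniform(0, 5, n),
        })

    def test_sample_sizes(self, corpus):
        out = rv.stratified_sample(corpus, per_bin=20, seed=1)
        assert len(out) == 80
        assert out["bin"].nunique() == 4

    def test_zero_per_bin(self, corpus):
        assert len(rv.stratified_sample(corpus, per_bin=0, seed=1)) == 0

    def test_deterministic(self, corpus):
        a = rv.stratified_sample(corpus, per_bin=10, seed=42)
        b = rv.stratified_sample(corpus, per_bin=10, seed=42)
        assert a.equals(b)

    def test_word_count_window(self, corpus):
        corpus2 = corpus.copy()
        corpus2.loc[0, "headline"] = "short one"
        out = rv.stratified_sample(corpus2, per_bin=20, seed=1)
        counts = out["headline"].str.split().str.len()
        assert counts.between(14, 16).all()

    def test_underpopulated_bin(self, corpus):
        with pytest.raises(ValueError, match="need"):
            rv.stratified_sample(corpus, per_bin=10_000, seed=1)

    def test_bins_cover_and_disjoint(self):
        bins = rv.DEFAULT_BINS
        assert bins[0][0] == 0.0 and bins[-1][1] == 5.0
        for (a, b), (c, d) in zip(bins, bins[1:]):
            assert b == c
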