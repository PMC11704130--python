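"""Human-rating validation: rater QC, ICC reliability, Pearson correlation,
and the stratified sampling design used to pick headlines for rating.

The rating design is incomplete — each rater sees a random subset of
headlines — so reliability uses one-way random-effects intraclass
correlations with the unbalanced-design effective ratings-per-headline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

ITEM_CALIBRATION = "calibration"
ITEM_ATTENTION = "attention_check"
ITEM_MAIN = "main"

REASON_NONE = "none"
REASON_CALIBRATION = "low_calibration_correlation"
REASON_ZERO_VARIANCE = "zero_variance"
REASON_ATTENTION = "failed_attention"
REASON_CONSENT = "revoked_consent"

CALIBRATION_R_THRESHOLD = 0.2


@dataclass(frozen=True)
class RaterQCResult:
    rater_id: str
    excluded: bool
    reason: str
    calibration_r: float

    def __post_init__(self) -> None:
        if self.excluded and self.reason == REASON_NONE:
            raise ValueError("excluded raters must carry a reason")


@dataclass(frozen=True)
class ReliabilityReport:
    icc_single: float
    icc_average: float
    pearson_r: float
    pearson_p: float
    n_ratings: int
    n_headlines: int
    mean_ratings_per_headline: float

    def to_dict(self) -> dict:
        return {
            "icc_single": self.icc_single,
            "icc_average": self.icc_average,
            "pearson_r": self.pearson_r,
            "pearson_p": self.pearson_p,
            "n_ratings": self.n_ratings,
            "n_headlines": self.n_headlines,
            "mean_ratings_per_headline": self.mean_ratings_per_headline,
        }


def _drop_dont_understand(responses: pd.DataFrame) -> pd.DataFrame:
    if "dont_understand" in responses.columns:
        flag = responses["dont_understand"].fillna(False).astype(bool)
        return responses.loc[~flag]
    return responses


def apply_rater_qc(
    responses: pd.DataFrame,
    attention_answers: dict | None = None,
    revoked_consent: set | None = None,
    exclude_unevaluable: bool = False,
) -> tuple[pd.DataFrame, list[RaterQCResult]]:
    """Exclude low-quality raters and return the cleaned response table.

    Exclusion rules, in the order reasons are assigned:

    - calibration ratings correlate < 0.2 (Pearson) with the leave-one-out
      mean of all other raters' calibration ratings;
    - zero variance across all of the rater's scale ratings;
    - wrong answer on any attention-check item (``attention_answers`` maps
      headline_id -> required rating);
    - rater listed in ``revoked_consent``.

    "Don't understand" responses are dropped before all statistics.  A rater
    with fewer than 2 usable calibration items has an undefined calibration
    correlation; ``exclude_unevaluable`` decides whether they are kept.
    """
    required = {"rater_id", "headline_id", "item_class", "rating"}
    missing = required - set(responses.columns)
    if missing:
        raise KeyError(f"missing response columns: {sorted(missing)}")
    usable = _drop_dont_understand(responses).copy()
    usable["rating"] = pd.to_numeric(usable["rating"], errors="coerce")
    usable = usable.loc[usable["rating"].notna()]

    calib = usable.loc[usable["item_class"] == ITEM_CALIBRATION]
    calib_means = calib.groupby("headline_id")["rating"].agg(["sum", "count"])

    attention_answers = attention_answers or {}
    revoked_consent = revoked_consent or set()

    results: list[RaterQCResult] = []
    for rater_id, grp in usable.groupby("rater_id", sort=True):
        my_calib = grp.loc[grp["item_class"] == ITEM_CALIBRATION]
        calib_r = np.nan
        if len(my_calib) >= 2:
            items = my_calib["headline_id"].to_numpy()
            mine = my_calib["rating"].to_numpy(dtype=float)
            sums = calib_means.reindex(items)
            loo = (sums["sum"].to_numpy() - mine) / np.maximum(
                sums["count"].to_numpy() - 1, 1
            )
            if np.std(mine) > 0 and np.std(loo) > 0:
                calib_r = float(np.corrcoef(mine, loo)[0, 1])

        reason = REASON_NONE
        if np.isfinite(calib_r) and calib_r < CALIBRATION_R_THRESHOLD:
            reason = REASON_CALIBRATION
        elif float(grp["rating"].std(ddof=0)) == 0.0:
            reason = REASON_ZERO_VARIANCE
        elif _failed_attention(grp, attention_answers):
            reason = REASON_ATTENTION
        elif rater_id in revoked_consent:
            reason = REASON_CONSENT
        elif not np.isfinite(calib_r) and exclude_unevaluable:
            reason = REASON_CALIBRATION
            logger.warning("rater %s: calibration correlation unevaluable", rater_id)
        results.append(
            RaterQCResult(str(rater_id), reason != REASON_NONE, reason, calib_r)
        )

    excluded_ids = {r.rater_id for r in results if r.excluded}
    clean = usable.loc[~usable["rater_id"].astype(str).isin(excluded_ids)].reset_index(
        drop=True
    )
    return clean, results


def _failed_attention(grp: pd.DataFrame, answers: dict) -> bool:
    checks = grp.loc[grp["item_class"] == ITEM_ATTENTION]
    for _, row in checks.iterrows():
        expected = answers.get(row["headline_id"])
        if expected is not None and float(row["rating"]) != float(expected):
            return True
    return False


def compute_icc(ratings: pd.DataFrame) -> tuple[float, float]:
    """One-way random-effects ICCs for an incomplete rating design.

    ``ratings`` needs columns ``headline_id`` and ``rating``.  Returns
    ``(icc_single, icc_average)`` where the averaged ICC uses the
    unbalanced-design effective number of ratings per headline
    ``k0 = (N - sum(k_i^2)/N) / (n_headlines - 1)``.
    """
    grp = ratings.groupby("headline_id")["rating"]
    counts = grp.count()
    if (counts < 2).any() or len(counts) < 2:
        raise ValueError("need >= 2 headlines each with >= 2 ratings")
    n = len(counts)
    total = int(counts.sum())
    grand = float(ratings["rating"].mean())
    means = grp.mean()
    ssb = float((counts * (means - grand) ** 2).sum())
    ssw = float(((ratings["rating"] - means.reindex(
        ratings["headline_id"]).to_numpy()) ** 2).sum())
    msb = ssb / (n - 1)
    msw = ssw / (total - n)
    if msb == 0.0 and msw == 0.0:
        raise ValueError("degenerate ratings: all values identical")
    k0 = (total - float((counts**2).sum()) / total) / (n - 1)
    icc_single = (msb - msw) / (msb + (k0 - 1.0) * msw)
    icc_average = (msb - msw) / msb if msb > 0 else float("nan")
    return float(icc_single), float(icc_average)


def correlate_with_computational(
    mean_human_ratings, computational_scores
) -> tuple[float, float]:
    """Pearson correlation between mean human ratings and machine scores."""
    x = np.asarray(mean_human_ratings, dtype=float)
    y = np.asarray(computational_scores, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the vectors")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


DEFAULT_BINS: tuple[tuple[float, float], ...] = (
    (0.0, 2.5), (2.5, 3.0), (3.0, 3.5), (3.5, 5.0),
)


def stratified_sample(
    scored: pd.DataFrame,
    per_bin: int,
    bins: tuple[tuple[float, float], ...] = DEFAULT_BINS,
    word_count_window: tuple[int, int] = (14, 16),
    seed: int = 0,
    score_column: str = "score",
    word_count_column: str = "word_count",
) -> pd.DataFrame:
    """Seeded stratified sample of headlines across concreteness bins.

    Bins are left-closed; the last bin is closed on both ends so the bins
    cover [0, 5].  Headlines are restricted to the word-count window before
    sampling.  Raises on an under-populated bin.
    """
    if word_count_column not in scored.columns:
        scored = scored.assign(
            **{word_count_column: scored["headline"].astype(str).str.split().str.len()}
        )
    lo, hi = word_count_window
    pool = scored.loc[
        scored[score_column].notna()
        & scored[word_count_column].between(lo, hi)
    ]
    rng = np.random.default_rng(seed)
    picks = []
    for i, (a, b) in enumerate(bins):
        last = i == len(bins) - 1
        in_bin = pool.loc[
            (pool[score_column] >= a)
            & ((pool[score_column] <= b) if last else (pool[score_column] < b))
        ]
        if len(in_bin) < per_bin:
            raise ValueError(
                f"bin [{a}, {b}{']' if last else ')'} has {len(in_bin)} headlines; "
                f"need {per_bin}"
            )
        idx = rng.choice(in_bin.index.to_numpy(), size=per_bin, replace=False)
        picks.append(scored.loc[np.sort(idx)].assign(bin=f"[{a},{b}]"))
    if not picks:
        return scored.iloc[0:0]
    return pd.concat(picks, ignore_index=True)
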