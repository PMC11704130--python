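"""Archive ingestion and preparation of comparable headline tests.

Reads a headline A/B-test archive table, splits tests by image so only
same-image headlines are compared, applies the inclusion rules, and
standardizes concreteness: within-test centering followed by division by two
standard deviations of the centered values (so +/-0.5 standardized units is
one SD from the test mean).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ColumnMap:
    """Archive dialect column names (defaults follow the public archive)."""

    test_id: str = "clickability_test_id"
    headline: str = "headline"
    image_id: str = "eyecatcher_id"
    impressions: str = "impressions"
    clicks: str = "clicks"


DEFAULT_COLUMNS = ColumnMap()

_STD_COLUMNS = [
    "derived_test_id",
    "headline",
    "score",
    "test_concreteness_mean",
    "headline_concreteness_std",
    "impressions",
    "clicks",
    "ctr",
]


def read_archive(path: str | Path, columns: ColumnMap = DEFAULT_COLUMNS) -> pd.DataFrame:
    """Load an archive CSV into the canonical Package table.

    Output columns: ``test_id, headline, image_id, impressions, clicks``.
    Rows with missing headlines, non-numeric counts, or clicks > impressions
    are dropped with a logged count.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path)
    required = [columns.test_id, columns.headline, columns.image_id,
                columns.impressions, columns.clicks]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise KeyError(f"{path}: missing required columns {missing}")
    df = raw[required].copy()
    df.columns = ["test_id", "headline", "image_id", "impressions", "clicks"]
    n0 = len(df)
    df["impressions"] = pd.to_numeric(df["impressions"], errors="coerce")
    df["clicks"] = pd.to_numeric(df["clicks"], errors="coerce")
    df["headline"] = df["headline"].astype("string")
    ok = (
        df["headline"].notna()
        & (df["headline"].str.strip() != "")
        & df["impressions"].notna()
        & df["clicks"].notna()
        & (df["impressions"] >= 0)
        & (df["clicks"] >= 0)
        & (df["clicks"] <= df["impressions"])
    )
    dropped = int((~ok).sum())
    if dropped:
        logger.warning("%s: dropped %d invalid rows of %d", path, dropped, n0)
    df = df.loc[ok].reset_index(drop=True)
    df["headline"] = df["headline"].astype(str)
    df["impressions"] = df["impressions"].astype(np.int64)
    df["clicks"] = df["clicks"].astype(np.int64)
    return df


def split_by_image(packages: pd.DataFrame) -> pd.DataFrame:
    """Partition each test by image; each (test, image) pair is a candidate.

    Adds ``derived_test_id`` = "<test_id>::<image_id>".  The partition is
    exact: no package is duplicated or lost.
    """
    out = packages.copy()
    out["derived_test_id"] = (
        out["test_id"].astype(str) + "::" + out["image_id"].astype(str)
    )
    return out


def _normalize_headline(s: pd.Series) -> pd.Series:
    return s.astype(str).str.split().str.join(" ")


def filter_valid(candidates: pd.DataFrame, scores: pd.DataFrame) -> pd.DataFrame:
    """Keep comparable tests: >= 2 distinct, scoreable headlines per image.

    ``scores`` is a scorer output table (``headline, score, excluded``).
    Packages whose headline was excluded by the scorer are dropped first;
    candidates left with fewer than two distinct headline strings
    (whitespace-normalized, case-sensitive) are removed.  Adds ``score`` and
    ``test_concreteness_mean`` columns.
    """
    if candidates.empty:
        return candidates.assign(score=pd.Series(dtype=float),
                                 test_concreteness_mean=pd.Series(dtype=float))
    score_map = scores.drop_duplicates("headline").set_index("headline")
    merged = candidates.copy()
    merged["score"] = merged["headline"].map(score_map["score"])
    merged["_excluded"] = merged["headline"].map(score_map["excluded"])
    merged = merged.loc[merged["_excluded"] == False].drop(columns="_excluded")  # noqa: E712
    merged = merged.loc[merged["score"].notna()]
    norm = _normalize_headline(merged["headline"])
    n_distinct = norm.groupby(merged["derived_test_id"]).transform("nunique")
    merged = merged.loc[n_distinct >= 2].copy()
    merged["test_concreteness_mean"] = (
        merged.groupby("derived_test_id")["score"].transform("mean")
    )
    return merged.reset_index(drop=True)


def standardize(
    tests: pd.DataFrame,
    centering: str = "group",
    scaling: dict | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Center concreteness and divide by two SDs of the centered values.

    ``centering='group'`` (default) centers each headline on its own test's
    mean; ``'grand'`` centers on the grand mean (sensitivity analysis).  The
    SD in the divisor is the sample SD of centered values over all retained
    headlines, unless a prior ``scaling`` report is supplied (then its
    divisor is reused, making the operation idempotent in distribution).

    Returns the analysis table plus a scaling report.
    """
    if tests["derived_test_id"].nunique() < 2:
        raise ValueError("need at least 2 comparable tests to standardize")
    df = tests.copy()
    grand_mean = float(df["score"].mean())
    if centering == "group":
        centered = df["score"] - df.groupby("derived_test_id")["score"].transform("mean")
    elif centering == "grand":
        centered = df["score"] - grand_mean
    else:
        raise ValueError(f"unknown centering mode {centering!r}")
    if scaling is not None:
        sd = float(scaling["sd_centered"])
    else:
        sd = float(centered.std(ddof=1))
    if not np.isfinite(sd) or sd <= 0:
        raise ValueError("zero variance in centered concreteness; cannot standardize")
    df["headline_concreteness_std"] = centered / (2.0 * sd)
    df["ctr"] = np.where(df["impressions"] > 0, df["clicks"] / df["impressions"], np.nan)
    report = {
        "centering": centering,
        "grand_mean": grand_mean,
        "sd_centered": sd,
        "divisor": 2.0 * sd,
        "n_tests": int(df["derived_test_id"].nunique()),
        "n_headlines": int(len(df)),
    }
    return df[[c for c in _STD_COLUMNS if c in df.columns]], report


def summarize_ctr(packages: pd.DataFrame) -> dict:
    """Mean/median CTR over packages plus test/headline counts.

    CTR is clicks/impressions; zero-impression packages are excluded from the
    CTR summaries and counted separately.
    """
    pos = packages.loc[packages["impressions"] > 0]
    ctr = pos["clicks"] / pos["impressions"]
    out = {
        "mean_ctr": float(ctr.mean()) if len(ctr) else float("nan"),
        "median_ctr": float(ctr.median()) if len(ctr) else float("nan"),
        "n_packages": int(len(packages)),
        "n_zero_impression": int((packages["impressions"] == 0).sum()),
        "n_headlines": int(packages["headline"].nunique()),
    }
    if "derived_test_id" in packages.columns:
        out["n_tests"] = int(packages["derived_test_id"].nunique())
    elif "test_id" in packages.columns:
        out["n_tests"] = int(packages["test_id"].nunique())
    return out
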