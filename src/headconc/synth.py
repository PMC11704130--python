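"""Synthetic headline-experiment archives with known ground truth.

Generates archive tables in the public A/B-test dialect whose headlines are
synthetic token strings built from a synthetic lexicon, so the scorer
recovers each headline's assigned concreteness exactly and every pipeline
stage can be exercised end to end.  Clicks are drawn from the binomial
random-intercepts, random-slopes model, enabling parameter-recovery and
power studies.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import truncnorm

from . import abtest_prep, moderation
from .abtest_prep import ColumnMap, DEFAULT_COLUMNS
from .glmm import GLMMData, fit_binomial_glmm
from .lexicon import Lexicon

#: Concreteness grid resolution of the synthetic lexicon (ratings i/100).
_GRID = 100
_KMAX = 5 * _GRID


@dataclass(frozen=True)
class GeneratorConfig:
    n_tests: int = 1000
    headlines_per_test: tuple[int, int] = (2, 5)
    beta: tuple[float, float, float, float] = (-4.929, 0.168, 0.102, -0.058)
    re_sd_intercept: float = 0.6534
    re_sd_slope: float = 0.3651
    re_corr: float = 0.0
    concreteness_mean: float = 3.08
    concreteness_sd: float = 0.27
    within_test_sd: float = 0.35
    impressions_median: float = 4000.0
    impressions_sigma: float = 0.6
    seed: int = 0
    p_tolerance: float = 1e-9

    def validate(self) -> None:
        if self.n_tests < 1:
            raise ValueError("n_tests must be >= 1")
        lo, hi = self.headlines_per_test
        if not (2 <= lo <= hi):
            raise ValueError("headlines_per_test range must satisfy 2 <= lo <= hi")
        if min(self.re_sd_intercept, self.re_sd_slope,
               self.concreteness_sd, self.within_test_sd) < 0:
            raise ValueError("standard deviations must be >= 0")
        if not -1.0 <= self.re_corr <= 1.0:
            raise ValueError("re_corr must lie in [-1, 1]")
        if self.impressions_median < 1:
            raise ValueError("impressions must be >= 1")


def make_synthetic_lexicon() -> Lexicon:
    """Lexicon of tokens ``w000 .. w500`` with rating k/100 in [0, 5]."""
    return Lexicon.from_mapping({f"w{k:03d}": k / _GRID for k in range(_KMAX + 1)})


def _headline_text(k: int, offset: int) -> str:
    return f"w{k - offset:03d} w{k + offset:03d}"


def generate_archive(
    config: GeneratorConfig,
    columns: ColumnMap = DEFAULT_COLUMNS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a synthetic archive plus its ground-truth sidecar table.

    Per test: a target concreteness level, 2-5 headlines scattered around
    it, a bivariate-normal random intercept/slope, and binomial clicks from
    the model probability.  Standardized concreteness follows the prep
    module's convention (group-mean centered, divided by two sample SDs of
    the centered values), so a pipeline rerun reproduces the generator's
    predictors.  Fully reproducible from ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    lo, hi = config.headlines_per_test
    n_h = rng.integers(lo, hi + 1, size=config.n_tests)
    total = int(n_h.sum())
    test_idx = np.repeat(np.arange(config.n_tests), n_h)

    a = (0.0 - config.concreteness_mean) / max(config.concreteness_sd, 1e-12)
    b = (5.0 - config.concreteness_mean) / max(config.concreteness_sd, 1e-12)
    centers = truncnorm.rvs(
        a, b, loc=config.concreteness_mean, scale=config.concreteness_sd,
        size=config.n_tests, random_state=rng,
    )
    raw = centers[test_idx] + rng.normal(0.0, config.within_test_sd, size=total)
    max_offset = int(n_h.max())  # offsets below stay inside the token grid
    k = np.clip(np.rint(raw * _GRID).astype(int), max_offset, _KMAX - max_offset)
    conc = k / _GRID

    # within-test headline index doubles as the hyphen-free token offset,
    # guaranteeing distinct headline strings inside a test
    offsets = np.concatenate([np.arange(c) for c in n_h])
    headlines = [_headline_text(int(ki), int(oi)) for ki, oi in zip(k, offsets)]

    df = pd.DataFrame({
        "test": test_idx,
        "concreteness": conc,
        "headline": headlines,
    })
    test_mean = df.groupby("test")["concreteness"].transform("mean").to_numpy()
    centered = conc - test_mean
    sd_centered = float(np.std(centered, ddof=1))
    if sd_centered <= 0:
        raise ValueError("degenerate concreteness draw: zero centered variance")
    hc_std = centered / (2.0 * sd_centered)

    # explicit Cholesky construction so zero SDs are legal
    z = rng.standard_normal((config.n_tests, 2))
    rho = config.re_corr
    u = np.column_stack([
        config.re_sd_intercept * z[:, 0],
        config.re_sd_slope * (rho * z[:, 0] + np.sqrt(1.0 - rho * rho) * z[:, 1]),
    ])
    b0, b1, b2, b3 = config.beta
    eta = (
        (b0 + u[test_idx, 0])
        + (b1 + u[test_idx, 1]) * hc_std
        + b2 * test_mean
        + b3 * hc_std * test_mean
    )
    p = expit(eta)
    if p.min() < config.p_tolerance or p.max() > 1.0 - config.p_tolerance:
        raise ValueError("configuration implies probabilities at the (0,1) boundary")

    impressions = np.maximum(
        1,
        np.rint(rng.lognormal(np.log(config.impressions_median),
                              config.impressions_sigma, size=total)),
    ).astype(np.int64)
    clicks = rng.binomial(impressions, p)

    archive = pd.DataFrame({
        columns.test_id: [f"t{j:06d}" for j in test_idx],
        columns.headline: headlines,
        columns.image_id: [f"img{j:06d}" for j in test_idx],
        columns.impressions: impressions,
        columns.clicks: clicks,
    })
    truth = pd.DataFrame({
        "test_id": archive[columns.test_id],
        "headline": headlines,
        "concreteness": conc,
        "test_concreteness_mean": test_mean,
        "headline_concreteness_std": hc_std,
        "u_intercept": u[test_idx, 0],
        "u_slope": u[test_idx, 1],
        "p": p,
        "impressions": impressions,
        "clicks": clicks,
    })
    return archive, truth


def _prep_from_archive(
    archive: pd.DataFrame,
    truth: pd.DataFrame,
    columns: ColumnMap = DEFAULT_COLUMNS,
) -> pd.DataFrame:
    """Run the prep stages (split, filter, standardize) on a generated archive."""
    packages = archive.rename(columns={
        columns.test_id: "test_id",
        columns.headline: "headline",
        columns.image_id: "image_id",
        columns.impressions: "impressions",
        columns.clicks: "clicks",
    })
    scores = truth[["headline", "concreteness"]].rename(
        columns={"concreteness": "score"}
    ).drop_duplicates("headline").assign(excluded=False)
    candidates = abtest_prep.split_by_image(packages)
    valid = abtest_prep.filter_valid(candidates, scores)
    std, _ = abtest_prep.standardize(valid)
    return std


def _fit_once(config: GeneratorConfig, seed: int):
    cfg = replace(config, seed=seed)
    archive, truth = generate_archive(cfg)
    std = _prep_from_archive(archive, truth)
    fit = fit_binomial_glmm(GLMMData.from_frame(std))
    mtc = std.groupby("derived_test_id")["test_concreteness_mean"].first().to_numpy()
    return fit, mtc


def recovery_harness(
    config: GeneratorConfig,
    n_replicates: int,
    seed: int = 0,
) -> dict:
    """Generate -> prep -> fit -> slopes over replicates; report bias/coverage.

    Returns per-coefficient bias, RMSE, and 95% CI coverage against the
    configured truth, plus the sampling distribution of the JN bounds and a
    count of failed fits (failures are recorded, not raised).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    truth_beta = np.asarray(config.beta)
    seeds = np.random.SeedSequence(seed).generate_state(n_replicates)
    estimates, covers, jn_lower, jn_upper = [], [], [], []
    n_failed = 0
    for s in seeds:
        try:
            fit, mtc = _fit_once(config, int(s))
        except Exception:
            n_failed += 1
            continue
        if not fit.converged:
            n_failed += 1
            continue
        estimates.append(fit.beta)
        covers.append(
            (fit.beta_ci[:, 0] <= truth_beta) & (truth_beta <= fit.beta_ci[:, 1])
        )
        try:
            region = moderation.johnson_neyman(fit.beta, fit.beta_vcov,
                                               moderator_values=mtc)
            jn_lower.append(region.lower_bound)
            jn_upper.append(region.upper_bound)
        except ValueError:
            jn_lower.append(None)
            jn_upper.append(None)
    est = np.array(estimates) if estimates else np.empty((0, 4))
    cov = np.array(covers) if covers else np.empty((0, 4))
    names = ["intercept", "headline_concreteness", "test_concreteness_mean",
             "interaction"]
    report = {
        "n_replicates": n_replicates,
        "n_failed": n_failed,
        "coefficients": {},
        "jn_lower_bounds": [x for x in jn_lower if x is not None],
        "jn_upper_bounds": [x for x in jn_upper if x is not None],
    }
    for i, name in enumerate(names):
        if len(est) == 0:
            report["coefficients"][name] = {}
            continue
        err = est[:, i] - truth_beta[i]
        report["coefficients"][name] = {
            "truth": float(truth_beta[i]),
            "mean_estimate": float(est[:, i].mean()),
            "bias": float(err.mean()),
            "rmse": float(np.sqrt((err**2).mean())),
            "coverage_95": float(cov[:, i].mean()),
        }
    return report


def _test_hypotheses(fit, mtc: np.ndarray, alpha: float) -> tuple[bool, bool, bool]:
    s_int = fit.beta[3]
    p1 = moderation.simple_slope(fit.beta, fit.beta_vcov, float(mtc.min()))
    p2 = moderation.simple_slope(fit.beta, fit.beta_vcov, float(mtc.max()))
    from .glmm import wald_p

    raw = np.array([wald_p(s_int, fit.beta_se[3]), p1.p, p2.p])
    adj = moderation.holm_adjust(raw)
    h1 = adj[0] < alpha
    h2 = adj[1] < alpha and p1.slope > 0
    h3 = adj[2] < alpha and p2.slope < 0
    return bool(h1), bool(h2), bool(h3)


def estimate_power(
    config: GeneratorConfig,
    n_tests_grid,
    alpha: float = 0.05,
    n_replicates: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulated power curve over a grid of archive sizes.

    Power is the fraction of replicates in which all three hypothesis tests
    reject after Holm adjustment (negative interaction test; positive simple
    slope at the observed minimum moderator value; negative simple slope at
    the observed maximum).  Monte-Carlo standard errors are included.
    """
    grid = list(n_tests_grid)
    if not grid:
        raise ValueError("n_tests_grid must be non-empty")
    rows = []
    ss = np.random.SeedSequence(seed)
    for n_tests, child in zip(grid, ss.spawn(len(grid))):
        cfg = replace(config, n_tests=int(n_tests))
        seeds = child.generate_state(n_replicates)
        h1 = h2 = h3 = joint = 0
        n_ok = 0
        for s in seeds:
            try:
                fit, mtc = _fit_once(cfg, int(s))
            except Exception:
                continue
            if not fit.converged:
                continue
            n_ok += 1
            r1, r2, r3 = _test_hypotheses(fit, mtc, alpha)
            h1 += r1; h2 += r2; h3 += r3
            joint += r1 and r2 and r3
        power = joint / n_ok if n_ok else float("nan")
        rows.append({
            "n_tests": int(n_tests),
            "n_replicates_ok": n_ok,
            "power": power,
            "mc_se": float(np.sqrt(power * (1 - power) / n_ok)) if n_ok else float("nan"),
            "rate_h1": h1 / n_ok if n_ok else float("nan"),
            "rate_h2": h2 / n_ok if n_ok else float("nan"),
            "rate_h3": h3 / n_ok if n_ok else float("nan"),
        })
    out = pd.DataFrame(rows)
    # monotone smoothing of the joint power curve (isotonic in n_tests)
    out = out.sort_values("n_tests").reset_index(drop=True)
    out["power_smoothed"] = np.maximum.accumulate(out["power"].to_numpy())
    return out
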