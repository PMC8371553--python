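"""Per-site differential methylation testing.

Each testable site is fit with a binomial logistic regression of
(methylated, unmethylated) counts on group membership plus covariates
(library kit by default); the group term is assessed with a 1-df
likelihood-ratio test. Sites with p below the per-site threshold (0.01 by
default, uncorrected) are classified hyper/hypo by the sign of the
difference in unweighted mean per-sample methylation fractions (test minus
reference). A BH-adjusted q-value column is emitted for reference but plays
no role downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import erfc, expit

from .enrich import bh_adjust
from .simulate import SiteCountsMatrix

logger = logging.getLogger(__name__)

STUDY_CONTRASTS = ("AC-YC", "AC-MC", "MC-YC", "YT-YC", "MT-MC", "AT-AC")

_MAX_ABS_COEF = 12.0  # |logit| beyond this is treated as separation


def _chi2_sf_1df(stat: float) -> float:
    """Upper tail of chi-square with 1 df (survival function)."""
    return float(erfc(np.sqrt(stat / 2.0)))


@dataclass
class Contrast:
    name: str
    test_group: list
    reference_group: list
    alpha_site: float = 0.01
    covariates: list = field(default_factory=lambda: ["kit"])
    #: scale the LRT statistic by the full-model Pearson dispersion
    #: (quasi-binomial style); off by default
    dispersion_correction: bool = False

    def validate(self) -> None:
        if not self.test_group or not self.reference_group:
            raise ValueError(f"contrast {self.name}: both groups must be non-empty")
        if set(self.test_group) & set(self.reference_group):
            raise ValueError(f"contrast {self.name}: groups overlap")
        if not 0.0 < self.alpha_site < 1.0:
            raise ValueError("alpha_site must be in (0, 1)")


@dataclass
class UniteConfig:
    min_coverage: int = 10
    min_samples_per_group: int | None = None  # None = all samples in the group

    def validate(self) -> None:
        if self.min_coverage < 1:
            raise ValueError("min_coverage must be >= 1")
        if self.min_samples_per_group is not None and self.min_samples_per_group < 1:
            raise ValueError("min_samples_per_group must be >= 1 when set")


def _group_samples(sheet: pd.DataFrame, spec: str) -> list:
    """Samples matching an 'XY' code (age letter + treatment letter)."""
    age, trt = spec[0], spec[1]
    sel = sheet[(sheet["age"] == age) & (sheet["treatment"] == trt)]
    return list(sel["sample_id"])


def study_contrasts(sheet: pd.DataFrame, alpha_site: float = 0.01) -> list[Contrast]:
    """The six study comparisons: three aging, three treatment contrasts.

    The first-named group is the test group (older vs younger; treated vs
    age-matched control).
    """
    out = []
    for name in STUDY_CONTRASTS:
        test_spec, ref_spec = name.split("-")
        out.append(
            Contrast(
                name=name,
                test_group=_group_samples(sheet, test_spec),
                reference_group=_group_samples(sheet, ref_spec),
                alpha_site=alpha_site,
            )
        )
    return out


def unite_sites(
    counts: SiteCountsMatrix, contrast: Contrast, unite_config: UniteConfig | None = None
) -> np.ndarray:
    """Boolean mask of sites testable under the coverage rule.

    A site is retained when at least ``min_samples_per_group`` samples of
    BOTH groups have total coverage >= ``min_coverage``.
    """
    cfg = unite_config or UniteConfig()
    cfg.validate()
    contrast.validate()
    col = {s: j for j, s in enumerate(counts.samples)}
    for s in contrast.test_group + contrast.reference_group:
        if s not in col:
            raise ValueError(f"contrast {contrast.name}: unknown sample {s!r}")
    mask = np.ones(len(counts.sites), dtype=bool)
    for group in (contrast.test_group, contrast.reference_group):
        need = len(group) if cfg.min_samples_per_group is None else min(
            cfg.min_samples_per_group, len(group)
        )
        cols = [col[s] for s in group]
        ok = (counts.total[:, cols] >= cfg.min_coverage).sum(axis=1) >= need
        mask &= ok
    if not mask.any():
        logger.warning("unite_sites: no sites pass coverage for contrast %s", contrast.name)
    return mask


# ---------------------------------------------------------------------------
# Binomial GLM via IRLS
# ---------------------------------------------------------------------------

def _binomial_deviance(y: np.ndarray, n: np.ndarray, p: np.ndarray) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = y * np.log(y / (n * p))
        t2 = (n - y) * np.log((n - y) / (n * (1 - p)))
    t1 = np.where(y == 0, 0.0, t1)
    t2 = np.where(n - y == 0, 0.0, t2)
    return float(2.0 * (t1.sum() + t2.sum()))


def _irls(
    X: np.ndarray, y: np.ndarray, n: np.ndarray, max_iter: int = 50, tol: float = 1e-10
) -> tuple[np.ndarray, float, np.ndarray, bool]:
    """Fit a binomial logistic GLM; returns (beta, deviance, p_hat, converged)."""
    beta = np.zeros(X.shape[1])
    pooled = (y.sum() + 0.5) / (n.sum() + 1.0)
    beta[0] = np.log(pooled / (1.0 - pooled))
    dev = np.inf
    p = np.full(len(y), pooled)
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        p = np.clip(expit(eta), 1e-12, 1.0 - 1e-12)
        w = n * p * (1.0 - p)
        z = eta + (y - n * p) / w
        WX = X * w[:, None]
        try:
            beta = np.linalg.solve(X.T @ WX, WX.T @ z)
        except np.linalg.LinAlgError:
            return beta, dev, p, False
        if not np.all(np.isfinite(beta)):
            return beta, dev, p, False
        new_p = np.clip(expit(X @ beta), 1e-12, 1.0 - 1e-12)
        new_dev = _binomial_deviance(y, n, new_p)
        if abs(dev - new_dev) < tol * (abs(new_dev) + 0.1):
            return beta, new_dev, new_p, True
        dev = new_dev
        p = new_p
    return beta, dev, p, converged


def _score_test(X_full: np.ndarray, y: np.ndarray, n: np.ndarray, p0: np.ndarray) -> float:
    """Rao score statistic for the last column of X_full at the reduced fit."""
    u = X_full.T @ (y - n * p0)
    w = n * p0 * (1.0 - p0)
    info = X_full.T @ (X_full * w[:, None])
    try:
        stat = float(u @ np.linalg.solve(info, u))
    except np.linalg.LinAlgError:
        return np.nan
    return max(stat, 0.0)


def _covariate_matrix(covariate_labels) -> np.ndarray:
    """Drop-first dummy coding of one or more categorical covariates.

    A float 2-D array is taken as an already-coded design block (fast path
    for repeated per-site calls).
    """
    if covariate_labels is None:
        return np.empty((0, 0))
    arr = np.asarray(covariate_labels)
    if arr.ndim == 2 and arr.dtype.kind == "f":
        return arr
    if arr.ndim == 1:
        arr = arr[:, None]
    cols = []
    for k in range(arr.shape[1]):
        levels = pd.unique(arr[:, k])
        for lev in levels[1:]:
            cols.append((arr[:, k] == lev).astype(float))
    if not cols:
        return np.empty((arr.shape[0], 0))
    return np.column_stack(cols)


def test_site(
    meth: Sequence[int],
    totals: Sequence[int],
    group_labels: Sequence[bool],
    covariate_labels=None,
    dispersion_correction: bool = False,
) -> tuple[float, float]:
    """LRT p-value and methylation difference for one site.

    ``group_labels`` is True for test-group samples. Samples with zero total
    are excluded. Returns (p_value, meth_difference) where the difference is
    the unweighted mean of per-sample fractions, test minus reference.
    Degenerate models (all per-sample fractions identical) return p = 1;
    separation falls back to the score test; non-convergence yields p = 1.
    """
    y = np.asarray(meth, dtype=float)
    n = np.asarray(totals, dtype=float)
    g = np.asarray(group_labels, dtype=bool)
    keep = n > 0
    y, n, g = y[keep], n[keep], g[keep]
    cov = _covariate_matrix(covariate_labels)
    if cov.size:
        cov = cov[keep]
    if not g.any() or g.all():
        raise ValueError("need at least one sample in each group")
    frac = y / n
    diff = float(frac[g].mean() - frac[~g].mean())
    if np.ptp(frac) < 1e-12:
        return 1.0, diff

    ones = np.ones(len(y))
    if cov.size:
        X_red = np.column_stack([ones, cov])
    else:
        X_red = ones[:, None]
    X_full = np.column_stack([X_red, g.astype(float)])

    beta_r, dev_r, p0, conv_r = _irls(X_red, y, n)
    beta_f, dev_f, p_hat, conv_f = _irls(X_full, y, n)
    separated = conv_f and abs(beta_f[-1]) > _MAX_ABS_COEF
    if conv_f and conv_r and not separated:
        stat = max(dev_r - dev_f, 0.0)
        if dispersion_correction:
            dof = len(y) - X_full.shape[1]
            if dof > 0:
                pearson = float(
                    (((y - n * p_hat) ** 2) / (n * p_hat * (1.0 - p_hat))).sum()
                )
                stat /= max(pearson / dof, 1.0)
        return _chi2_sf_1df(stat), diff
    if conv_r:
        stat = _score_test(X_full, y, n, p0)
        if np.isfinite(stat):
            return _chi2_sf_1df(stat), diff
    logger.debug("test_site: non-convergent fit, returning p=1")
    return 1.0, diff


# ---------------------------------------------------------------------------
# Contrast runner
# ---------------------------------------------------------------------------

@dataclass
class ContrastResult:
    contrast: Contrast
    table: pd.DataFrame  # chrom pos strand context p_value q_value meth_difference direction

    @property
    def n_tested(self) -> int:
        return len(self.table)

    @property
    def n_hyper(self) -> int:
        return int((self.table["direction"] == "hyper").sum())

    @property
    def n_hypo(self) -> int:
        return int((self.table["direction"] == "hypo").sum())

    @property
    def n_significant(self) -> int:
        return self.n_hyper + self.n_hypo

    def summary(self) -> dict:
        sig = self.table[self.table["direction"] != "ns"]

        def tally(frame: pd.DataFrame, key: str) -> dict:
            out: dict = {}
            for val, grp in frame.groupby(key, observed=True):
                out[str(val)] = {
                    "hyper": int((grp["direction"] == "hyper").sum()),
                    "hypo": int((grp["direction"] == "hypo").sum()),
                }
            return out

        return {
            "contrast": self.contrast.name,
            "alpha_site": self.contrast.alpha_site,
            "n_tested": self.n_tested,
            "n_significant": self.n_significant,
            "n_hyper": self.n_hyper,
            "n_hypo": self.n_hypo,
            "by_chromosome": tally(sig, "chrom"),
            "by_context": tally(sig, "context"),
        }


def run_contrast(
    dataset: SiteCountsMatrix,
    contrast: Contrast,
    unite_config: UniteConfig | None = None,
    contexts: Sequence[str] | None = None,
) -> ContrastResult:
    """Unite, test each site, and classify direction at ``alpha_site``.

    ``contexts`` optionally restricts testing to a subset of cytosine
    contexts (all three by default).
    """
    contrast.validate()
    mask = unite_sites(dataset, contrast, unite_config)
    if contexts is not None:
        mask = mask & dataset.sites["context"].isin(list(contexts)).to_numpy()
    sub = dataset.subset(mask)
    col = {s: j for j, s in enumerate(sub.samples)}
    cols = [col[s] for s in contrast.test_group + contrast.reference_group]
    is_test = np.array(
        [True] * len(contrast.test_group) + [False] * len(contrast.reference_group)
    )
    sheet = sub.sample_sheet.set_index("sample_id")
    cov = None
    if contrast.covariates:
        labels = np.column_stack(
            [
                sheet.loc[contrast.test_group + contrast.reference_group, c].to_numpy()
                for c in contrast.covariates
            ]
        )
        cov = _covariate_matrix(labels)  # dummy-code once; reused per site
    meth = sub.meth[:, cols]
    total = sub.total[:, cols]
    p_values = np.ones(len(sub.sites))
    diffs = np.zeros(len(sub.sites))
    for i in range(len(sub.sites)):
        p_values[i], diffs[i] = test_site(
            meth[i], total[i], is_test, cov,
            dispersion_correction=contrast.dispersion_correction,
        )
    q_values = bh_adjust(p_values) if len(p_values) else np.array([])
    direction = np.where(
        (p_values < contrast.alpha_site) & (diffs > 0),
        "hyper",
        np.where((p_values < contrast.alpha_site) & (diffs < 0), "hypo", "ns"),
    )
    table = sub.sites[["chrom", "pos", "strand", "context"]].copy()
    table["p_value"] = p_values
    table["q_value"] = q_values
    table["meth_difference"] = diffs
    table["direction"] = direction
    return ContrastResult(contrast, table)


# ---------------------------------------------------------------------------
# Independent oracle: two-sided Fisher exact by enumeration
# ---------------------------------------------------------------------------

def fisher_exact_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by full enumeration of the hypergeometric
    support, summing point probabilities <= that of the observed table.

    Exact rational arithmetic; intended as an independent oracle for the
    covariate-free test, not a production path.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("cell counts must be non-negative")
    n = a + b + c + d
    if n == 0:
        return 1.0
    r1, c1 = a + b, a + c
    denom = comb(n, c1)
    lo = max(0, c1 - (n - r1))
    hi = min(r1, c1)
    p_obs = Fraction(comb(r1, a) * comb(n - r1, c1 - a), denom)
    total = Fraction(0)
    for k in range(lo, hi + 1):
        p_k = Fraction(comb(r1, k) * comb(n - r1, c1 - k), denom)
        if p_k <= p_obs:
            total += p_k
    return float(min(total, Fraction(1)))
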