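"""Per-site methylation detection against the dam-mutant biological control.

For every GATC adenine in every sample the centered Box-Cox IPD values are
compared with the dam control's at the same stranded position using a Welch
two-sided t test, and the raw IPDs using a Wilcoxon rank-sum test.  The dam
strain cannot methylate GATC, so its IPD distribution is the per-site
unmodified reference — a biological rather than in-silico null.  Detection
calls use Storey q-values at the stated FDR, and sites that come out
non-significant are re-tested under equalized coverage (subsampling and
bootstrapping) to confirm the negative is not a coverage artifact.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats


@dataclass(frozen=True)
class TestOutcome:
    """Statistic + p-value of one hypothesis test, with a degeneracy flag."""

    statistic: float
    p_value: float
    flag: str | None = None


def welch_t_site(sample_values: Sequence[float], control_values: Sequence[float]) -> TestOutcome:
    """Welch unequal-variance t test, two-sided, Welch-Satterthwaite df."""
    x = np.asarray(sample_values, dtype=float)
    y = np.asarray(control_values, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs n >= 2")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        return TestOutcome(statistic=np.nan, p_value=np.nan, flag="degenerate")
    nx, ny = x.size, y.size
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * special.stdtr(df, -abs(t))
    return TestOutcome(statistic=float(t), p_value=float(p))


def wilcoxon_site(
    sample_values: Sequence[float],
    control_values: Sequence[float],
    exact_max_n: int = 25,
) -> TestOutcome:
    """Wilcoxon rank-sum (Mann-Whitney U), two-sided.

    Exact null distribution for combined n <= ``exact_max_n`` without ties;
    otherwise the normal approximation with mid-rank tie correction and
    continuity correction.
    """
    x = np.asarray(sample_values, dtype=float)
    y = np.asarray(control_values, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("each group needs n >= 1")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return TestOutcome(statistic=float(x.size * y.size / 2.0), p_value=1.0, flag="tied")
    has_ties = np.unique(pooled).size < pooled.size
    if pooled.size <= exact_max_n and not has_ties:
        u, p = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return TestOutcome(statistic=float(u), p_value=float(p))
    # normal approximation, mid-rank tie correction, continuity correction
    nx, ny = x.size, y.size
    ranks = stats.rankdata(pooled)
    u1 = ranks[:nx].sum() - nx * (nx + 1) / 2.0
    u = max(u1, nx * ny - u1)
    mu = nx * ny / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum()
    n = nx + ny
    sigma2 = nx * ny / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if sigma2 <= 0:
        return TestOutcome(statistic=float(u1), p_value=1.0, flag="tied")
    z = (u - mu - 0.5) / np.sqrt(sigma2)
    p = min(1.0, float(special.erfc(z / np.sqrt(2.0))))
    return TestOutcome(statistic=float(u1), p_value=p)


def _welch_p_matrix(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Two-sided Welch p for paired rows of x and y (vectorized over axis 0)."""
    nx, ny = x.shape[1], y.shape[1]
    mx, my = x.mean(axis=1), y.mean(axis=1)
    vx, vy = x.var(axis=1, ddof=1), y.var(axis=1, ddof=1)
    se2 = vx / nx + vy / ny
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mx - my) / np.sqrt(se2)
        df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
        p = 2.0 * special.stdtr(df, -np.abs(t))
    return np.where(se2 == 0.0, np.nan, p)


def equalize_coverage(
    sample_values: Sequence[float],
    control_values: Sequence[float],
    mode: str = "subsample",
    n_resamples: int = 100,
    seed: int = 0,
    test: str = "welch",
) -> float:
    """p-value under equalized coverage, summarized as the resample median.

    ``subsample`` draws the larger group down (without replacement) to the
    smaller group's n; when coverage is already equal the plain test's p is
    returned unchanged.  ``bootstrap`` resamples both groups with
    replacement at the common (smaller) n.  Deterministic given the seed.
    """
    x = np.asarray(sample_values, dtype=float)
    y = np.asarray(control_values, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    if mode not in ("subsample", "bootstrap"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "bootstrap" and n_resamples < 100:
        raise ValueError("bootstrap mode requires n_resamples >= 100")

    def plain_p(a: np.ndarray, b: np.ndarray) -> float:
        if test == "welch":
            return welch_t_site(a, b).p_value
        return wilcoxon_site(a, b).p_value

    if mode == "subsample" and x.size == y.size:
        return plain_p(x, y)

    rng = np.random.default_rng(seed)
    m = min(x.size, y.size)
    if test == "welch" and m >= 2:
        if mode == "subsample":
            if x.size > y.size:
                big, small = x, y
            else:
                big, small = y, x
            idx = rng.random((n_resamples, big.size)).argsort(axis=1)[:, :m]
            ps = _welch_p_matrix(big[idx], np.broadcast_to(small, (n_resamples, m)))
        else:
            xs = x[rng.integers(0, x.size, size=(n_resamples, m))]
            ys = y[rng.integers(0, y.size, size=(n_resamples, m))]
            ps = _welch_p_matrix(xs, ys)
        return float(np.nanmedian(ps))

    ps_list = []
    for _ in range(n_resamples):
        if mode == "subsample":
            xs = rng.choice(x, size=m, replace=False) if x.size > m else x
            ys = rng.choice(y, size=m, replace=False) if y.size > m else y
        else:
            xs = rng.choice(x, size=m, replace=True)
            ys = rng.choice(y, size=m, replace=True)
        ps_list.append(plain_p(xs, ys))
    return float(np.median(ps_list))


def detect_methylation(
    raw_by_site_sample: Mapping[tuple[int, str], Mapping[str, np.ndarray]],
    centered_by_site_sample: Mapping[tuple[int, str], Mapping[str, np.ndarray]],
    dam_sample_id: str,
    fdr: float = 0.05,
    equalize: bool = True,
    n_resamples: int = 100,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Detection cohort: both tests per (site, sample) vs the dam control.

    q-values are assigned per sample cohort and per method; ``detected`` is
    q_welch < fdr.  For non-detected sites the coverage-equalized p-values
    (subsample and bootstrap modes) are reported as robustness columns so a
    negative call can be checked against coverage imbalance.  Returns the
    per-(site, sample) results and a per-sample summary.
    """
    from .temporal import storey_qvalues  # local import: modules are mutually referential

    if not 0.0 < fdr < 1.0:
        raise ValueError("fdr must be in (0, 1)")
    sample_ids = sorted(
        {sid for per_site in raw_by_site_sample.values() for sid in per_site} - {dam_sample_id}
    )
    if not any(dam_sample_id in per_site for per_site in raw_by_site_sample.values()):
        raise ValueError(f"dam control sample {dam_sample_id!r} absent from the analysis table")

    rows = []
    rng = np.random.default_rng(seed)
    for key in sorted(raw_by_site_sample):
        raw_site = raw_by_site_sample[key]
        cen_site = centered_by_site_sample[key]
        if dam_sample_id not in raw_site:
            continue
        raw_ctrl = np.asarray(raw_site[dam_sample_id], dtype=float)
        cen_ctrl = np.asarray(cen_site[dam_sample_id], dtype=float)
        for sid in sample_ids:
            if sid not in raw_site:
                continue
            w = welch_t_site(cen_site[sid], cen_ctrl)
            u = wilcoxon_site(raw_site[sid], raw_ctrl)
            rows.append(
                {
                    "position": key[0],
                    "strand": key[1],
                    "sample_id": sid,
                    "t_stat": w.statistic,
                    "p_welch": w.p_value,
                    "u_stat": u.statistic,
                    "p_wilcoxon": u.p_value,
                    "n_sample": len(raw_site[sid]),
                    "n_control": raw_ctrl.size,
                    "flag": w.flag or u.flag or "",
                }
            )
    results = pd.DataFrame(rows)
    if results.empty:
        return results, pd.DataFrame()

    results["q_welch"] = np.nan
    results["q_wilcoxon"] = np.nan
    for sid in sample_ids:
        mask = (results["sample_id"] == sid) & results["p_welch"].notna()
        if mask.any():
            results.loc[mask, "q_welch"], _ = storey_qvalues(results.loc[mask, "p_welch"])
        mask_u = (results["sample_id"] == sid) & results["p_wilcoxon"].notna()
        if mask_u.any():
            results.loc[mask_u, "q_wilcoxon"], _ = storey_qvalues(results.loc[mask_u, "p_wilcoxon"])
    results["detected"] = results["q_welch"] < fdr
    results["detected_wilcoxon"] = results["q_wilcoxon"] < fdr

    results["p_eq_subsample"] = np.nan
    results["p_eq_bootstrap"] = np.nan
    if equalize:
        for i in results.index[~results["detected"]]:
            key = (results.at[i, "position"], results.at[i, "strand"])
            sid = results.at[i, "sample_id"]
            xs = np.asarray(centered_by_site_sample[key][sid], dtype=float)
            ys = np.asarray(centered_by_site_sample[key][dam_sample_id], dtype=float)
            s1, s2 = int(rng.integers(2**31)), int(rng.integers(2**31))
            results.at[i, "p_eq_subsample"] = equalize_coverage(
                xs, ys, mode="subsample", n_resamples=n_resamples, seed=s1
            )
            results.at[i, "p_eq_bootstrap"] = equalize_coverage(
                xs, ys, mode="bootstrap", n_resamples=max(100, n_resamples), seed=s2
            )

    summary = (
        results.groupby("sample_id")
        .agg(
            n_tested=("position", "size"),
            n_detected=("detected", "sum"),
            n_detected_wilcoxon=("detected_wilcoxon", "sum"),
        )
        .reset_index()
    )
    summary["fdr"] = fdr
    summary["seed"] = seed
    return results, summary
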