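"""Orthogonal quantification: LC-MS meA fraction and qRT-PCR fold changes.

LC-MS quantifies bulk N6-methyladenine as [meA]/([meA] + [A]) from
dilution-corrected extracted-ion peak areas, with Chargaff-pairing ratios
((A + meA)/T and G/C) as a signal-response sanity check and the percent
coefficient of variation as the error measure.  qRT-PCR fold changes between
the WT and dam strains use 2**dCT after normalizing each threshold cycle to
the RNA mass loaded and the primer-pair efficiency.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: Expected [M+H]+ m/z of each nucleobase analyte, for input validation.
ANALYTE_MZ = {"A": 136.0618, "T": 127.0502, "G": 152.0567, "C": 112.0505, "meA": 150.0774}


def _corrected_areas(peaks: pd.DataFrame, sample_id: str) -> pd.DataFrame:
    sub = peaks[peaks["sample_id"] == sample_id].copy()
    if sub.empty:
        raise ValueError(f"no peak rows for sample {sample_id!r}")
    sub["corrected"] = sub["peak_area"] * sub["dilution_factor"]
    return sub


def mea_fraction(peaks: pd.DataFrame, sample_id: str) -> float:
    """[meA]/([meA] + [A]) from dilution-corrected areas, replicate-averaged.

    NaN (with a warning) when both areas are zero in every replicate.
    """
    sub = _corrected_areas(peaks, sample_id)
    wide = sub.pivot_table(index="replicate", columns="analyte", values="corrected", aggfunc="sum")
    for col in ("A", "meA"):
        if col not in wide.columns:
            raise ValueError(f"sample {sample_id!r} lacks {col} peaks")
    denom = wide["meA"] + wide["A"]
    if (denom == 0).all():
        warnings.warn(f"sample {sample_id!r}: meA and A areas are all zero", stacklevel=2)
        return float("nan")
    frac = (wide["meA"] / denom).dropna()
    return float(frac.mean())


def replicate_fractions(peaks: pd.DataFrame, sample_id: str) -> np.ndarray:
    """Per-replicate meA fractions (for CV computation)."""
    sub = _corrected_areas(peaks, sample_id)
    wide = sub.pivot_table(index="replicate", columns="analyte", values="corrected", aggfunc="sum")
    return (wide["meA"] / (wide["meA"] + wide["A"])).to_numpy(dtype=float)


def percent_cv(values: Sequence[float]) -> float:
    """100 * sd / mean over replicates (sample sd, ddof=1)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("percent CV needs >= 2 replicates")
    m = v.mean()
    if m == 0:
        warnings.warn("mean of replicates is zero; CV undefined", stacklevel=2)
        return float("nan")
    return float(100.0 * v.std(ddof=1) / m)


def propagate_cv(fractions_by_sample: Mapping[str, Sequence[float]]) -> tuple[dict[str, float], float]:
    """Per-biological-sample %CV plus the root-sum-of-squares propagation."""
    per_sample = {sid: percent_cv(v) for sid, v in fractions_by_sample.items()}
    finite = [c for c in per_sample.values() if np.isfinite(c)]
    propagated = float(np.sqrt(np.sum(np.square(finite)))) if finite else float("nan")
    return per_sample, propagated


def chargaff_ratios(
    peaks: pd.DataFrame, sample_id: str, tolerance: float = 0.1
) -> dict[str, float | bool]:
    """(A + meA)/T and G/C corrected-area ratios with deviation flags.

    meA counts with A in the purine pool, so moving signal between the A and
    meA channels leaves the ratio unchanged.
    """
    sub = _corrected_areas(peaks, sample_id)
    totals = sub.groupby("analyte")["corrected"].mean()
    for b in "ATGC":
        if b not in totals.index:
            raise ValueError(f"sample {sample_id!r} lacks base {b}")
    mea = float(totals.get("meA", 0.0))
    out: dict[str, float | bool] = {}
    if totals["T"] == 0 or totals["C"] == 0:
        warnings.warn("zero denominator in Chargaff ratio", stacklevel=2)
        out["at_ratio"] = float("nan") if totals["T"] == 0 else (totals["A"] + mea) / totals["T"]
        out["gc_ratio"] = float("nan") if totals["C"] == 0 else totals["G"] / totals["C"]
    else:
        out["at_ratio"] = float((totals["A"] + mea) / totals["T"])
        out["gc_ratio"] = float(totals["G"] / totals["C"])
    out["at_flag"] = bool(not np.isfinite(out["at_ratio"]) or abs(out["at_ratio"] - 1) > tolerance)
    out["gc_flag"] = bool(not np.isfinite(out["gc_ratio"]) or abs(out["gc_ratio"] - 1) > tolerance)
    return out


def adjusted_ct(
    ct: np.ndarray, rna_mass: np.ndarray, efficiency: np.ndarray, reference_mass: float
) -> np.ndarray:
    """Normalize threshold cycles to primer efficiency and RNA mass.

    adjCT = CT * log2(1 + E) - log2(mass / reference mass): a primer pair
    amplifying with efficiency E gains log2(1+E) of signal per cycle, and
    loading twice the template advances the curve by one cycle.
    """
    return ct * np.log2(1.0 + efficiency) - np.log2(rna_mass / reference_mass)


def relative_expression(
    records: pd.DataFrame,
    gene: str,
    time_h: float,
    strain_pair: tuple[str, str] = ("WT", "dam"),
    reference_mass: float | None = None,
) -> tuple[float, float, np.ndarray]:
    """Fold change 2**(adjCT_test - adjCT_reference) for one gene and hour.

    The pair is (reference, test); fold > 1 means the test strain needs more
    cycles, i.e. *lower* transcript abundance is fold < 1 after inversion by
    the caller — here fold is reported exactly as 2**dCT with dCT =
    adjCT(test) - adjCT(reference), replicate-matched; returns
    (mean fold, sd over replicates, per-replicate folds).
    """
    ref_strain, test_strain = strain_pair
    sub = records[(records["gene"] == gene) & (records["time_h"] == time_h)]
    ref = sub[sub["strain"] == ref_strain].sort_values("replicate")
    test = sub[sub["strain"] == test_strain].sort_values("replicate")
    if ref.empty or test.empty:
        raise ValueError(f"gene {gene!r} at {time_h} h: both strains must be measured")
    if reference_mass is None:
        reference_mass = float(sub["rna_mass"].mean())

    def adj(df: pd.DataFrame) -> np.ndarray:
        return adjusted_ct(
            df["ct"].to_numpy(float),
            df["rna_mass"].to_numpy(float),
            df["primer_efficiency"].to_numpy(float),
            reference_mass,
        )

    a_ref, a_test = adj(ref), adj(test)
    m = min(a_ref.size, a_test.size)
    folds = 2.0 ** (a_test[:m] - a_ref[:m])
    sd = float(folds.std(ddof=1)) if m > 1 else 0.0
    return float(folds.mean()), sd, folds


def fold_change_table(
    records: pd.DataFrame, strain_pair: tuple[str, str] = ("WT", "dam")
) -> pd.DataFrame:
    """Per-gene, per-hour WT-vs-dam fold changes with replicate sd.

    Missing (gene, hour) cells are reported as NaN rather than dropped.
    """
    genes = sorted(records["gene"].unique())
    times = sorted(records["time_h"].unique())
    rows = []
    for g in genes:
        row: dict[str, float | str] = {"gene": g}
        for t in times:
            try:
                fold, sd, _ = relative_expression(records, g, t, strain_pair=strain_pair)
            except ValueError:
                fold, sd = float("nan"), float("nan")
            row[f"fold_{t:g}h"] = fold
            row[f"sd_{t:g}h"] = sd
        rows.append(row)
    return pd.DataFrame(rows)
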