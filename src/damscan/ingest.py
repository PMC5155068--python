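"""Reading and filtering long-format per-read IPD tables.

Filtering follows the study's two rules: raw IPDs above 50,000 are
instrument outliers and are discarded, and a site enters the analysis for a
given sample only if its post-filter coverage is at least 20 reads.  Both
rules are applied per stranded adenine position, per sample; exclusion in
one sample does not remove the site from others.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .motifs import MotifSite

OUTLIER_CUTOFF = 50_000.0
MIN_COVERAGE = 20

REQUIRED_COLUMNS = ["genome_id", "position", "strand", "base", "ipd", "sample_id"]

ROLES = ("timepoint", "dam_control", "wga_control")


@dataclass(frozen=True)
class SampleMetadata:
    sample_id: str
    role: str
    time_h: float | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        if self.role == "timepoint" and self.time_h is None:
            raise ValueError(f"timepoint sample {self.sample_id!r} needs time_h")


@dataclass
class IpdObservationSet:
    """Raw per-read IPDs at one site in one sample, pre/post filtering."""

    position: int
    strand: str
    sample_id: str
    raw_values: np.ndarray
    kept_values: np.ndarray
    excluded: bool = False

    @property
    def n_raw(self) -> int:
        return int(self.raw_values.size)

    @property
    def n_kept(self) -> int:
        return int(self.kept_values.size)


@dataclass
class ParseReport:
    n_rows: int = 0
    n_accepted: int = 0
    rejects: list[tuple[int, str]] = field(default_factory=list)  # (line number, reason)

    @property
    def n_rejected(self) -> int:
        return len(self.rejects)


@dataclass
class CleanReport:
    outliers_removed: dict[str, int] = field(default_factory=dict)  # per sample
    sites_excluded: dict[str, int] = field(default_factory=dict)  # per sample
    n_kept_total: int = 0
    n_raw_total: int = 0


def read_metadata(path: str | Path) -> list[SampleMetadata]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, r in df.iterrows():
        t = r.get("time_h")
        out.append(
            SampleMetadata(
                sample_id=str(r["sample_id"]),
                role=str(r["role"]),
                time_h=None if pd.isna(t) else float(t),
            )
        )
    return out


def read_ipd_table(
    path: str | Path,
    metadata: Sequence[SampleMetadata],
    genome_length: int | None = None,
) -> tuple[pd.DataFrame, ParseReport]:
    """Parse a TSV/CSV of per-read IPD observations.

    Malformed rows (non-numeric IPD, bad position, unknown sample id) are
    rejected individually with their line numbers; parsing continues.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"missing required column(s): {missing}")

    known = {m.sample_id for m in metadata}
    report = ParseReport(n_rows=len(raw))
    # header is line 1, first data row line 2
    lineno = raw.index.to_numpy() + 2

    pos = pd.to_numeric(raw["position"], errors="coerce")
    ipd = pd.to_numeric(raw["ipd"], errors="coerce")
    ok = pd.Series(True, index=raw.index)

    bad_ipd = ipd.isna() | (ipd <= 0)
    bad_pos = pos.isna() | (pos < 1) | (pos != pos.round())
    if genome_length is not None:
        bad_pos |= pos > genome_length
    bad_strand = ~raw["strand"].isin(["+", "-"])
    bad_sample = ~raw["sample_id"].isin(known)
    for mask, reason in (
        (bad_ipd, "non-positive or non-numeric ipd"),
        (bad_pos, "invalid position"),
        (bad_strand, "invalid strand"),
        (bad_sample, "unknown sample_id"),
    ):
        for i in raw.index[mask & ok]:
            report.rejects.append((int(lineno[i]), reason))
        ok &= ~mask

    kept = raw[ok].copy()
    kept["position"] = pos[ok].astype(int)
    kept["ipd"] = ipd[ok].astype(float)
    meta_df = pd.DataFrame(
        [{"sample_id": m.sample_id, "role": m.role, "time_h": m.time_h} for m in metadata]
    )
    kept = kept.drop(columns=[c for c in ("role", "time_h") if c in kept.columns])
    kept = kept.merge(meta_df, on="sample_id", how="left")
    report.n_accepted = len(kept)
    report.rejects.sort()
    return kept.reset_index(drop=True), report


def clean_observations(
    records: pd.DataFrame,
    outlier_cutoff: float = OUTLIER_CUTOFF,
    min_coverage: int = MIN_COVERAGE,
) -> tuple[dict[tuple[int, str, str], IpdObservationSet], CleanReport]:
    """Apply the outlier cutoff and per-sample coverage threshold.

    Returns one :class:`IpdObservationSet` per (position, strand, sample)
    with values above ``outlier_cutoff`` removed and the set flagged
    ``excluded`` when fewer than ``min_coverage`` reads survive.
    """
    if outlier_cutoff <= 0:
        raise ValueError("outlier_cutoff must be positive")
    if min_coverage < 1:
        raise ValueError("min_coverage must be >= 1")
    report = CleanReport()
    sets: dict[tuple[int, str, str], IpdObservationSet] = {}
    if records.empty:
        return sets, report

    grouped = records.groupby(["position", "strand", "sample_id"], sort=True)
    for (pos, strand, sample_id), idx in grouped.indices.items():
        raw = records["ipd"].to_numpy()[idx]
        kept = raw[raw <= outlier_cutoff]
        obs = IpdObservationSet(
            position=int(pos),
            strand=str(strand),
            sample_id=str(sample_id),
            raw_values=raw,
            kept_values=kept,
            excluded=kept.size < min_coverage,
        )
        sets[(obs.position, obs.strand, obs.sample_id)] = obs
        report.outliers_removed[obs.sample_id] = (
            report.outliers_removed.get(obs.sample_id, 0) + obs.n_raw - obs.n_kept
        )
        if obs.excluded:
            report.sites_excluded[obs.sample_id] = report.sites_excluded.get(obs.sample_id, 0) + 1
        report.n_raw_total += obs.n_raw
        report.n_kept_total += obs.n_kept
    return sets, report


def cleaned_frame(
    sets: Mapping[tuple[int, str, str], IpdObservationSet],
    include_excluded: bool = False,
) -> pd.DataFrame:
    """Flatten kept observations back to a long DataFrame."""
    rows = []
    for obs in sets.values():
        if obs.excluded and not include_excluded:
            continue
        rows.append(
            pd.DataFrame(
                {
                    "position": obs.position,
                    "strand": obs.strand,
                    "sample_id": obs.sample_id,
                    "ipd": obs.kept_values,
                }
            )
        )
    if not rows:
        return pd.DataFrame(columns=["position", "strand", "sample_id", "ipd"])
    return pd.concat(rows, ignore_index=True)


def partition_by_site(
    sets: Mapping[tuple[int, str, str], IpdObservationSet],
    sites: Sequence[MotifSite],
    samples: Sequence[str] | None = None,
    allow_extra: bool = False,
) -> dict[tuple[tuple[int, str], str], IpdObservationSet | None]:
    """Organize cleaned sets into a (site, sample) analysis table.

    Every cell is either an observation set or ``None`` (explicit missing /
    excluded marker).  Observation keys not in the motif list raise unless
    ``allow_extra`` (background reference positions are handled upstream).
    """
    site_keys = {s.key for s in sites}
    if not allow_extra:
        extra = {(p, st) for (p, st, _) in sets} - site_keys
        if extra:
            raise KeyError(f"observations at non-motif site(s): {sorted(extra)[:5]}")
    if samples is None:
        samples = sorted({sid for (_, _, sid) in sets})
    table: dict[tuple[tuple[int, str], str], IpdObservationSet | None] = {}
    for key in sorted(site_keys):
        for sid in samples:
            obs = sets.get((key[0], key[1], sid))
            table[(key, sid)] = None if obs is None or obs.excluded else obs
    return table
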