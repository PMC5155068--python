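"""Seeded generators for every input the analysis consumes.

The simulator emulates the study design: SMRT sequencing of wild-type
*E. coli* sampled at 8-120 h (into long-term stationary phase) plus two
negative controls — a *dam* deletion strain (no GATC adenine methylation)
and whole-genome-amplified DNA (no modifications at all).  Per-read IPDs at
a site are a two-component mixture: a read reports the methylated kinetic
law with probability f (the methylated fraction of the cell population at
that site and time) and the unmethylated law otherwise.  Both laws are
log-normal — raw IPDs are positive and right-skewed, which is exactly why
the analysis Box-Cox-transforms them.  Rare instrument glitches are modeled
as uniform outliers above the 50,000 cutoff the filtering stage removes.

Methylated-fraction trajectories follow four qualitative temporal templates
(patterns A-D) plus a constant background; unmethylated non-GATC adenine
positions ("none") are also emitted so that per-sample centering has the
genome-wide reference the real analysis uses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .motifs import GenomeSequence, MotifSite, scan_motif

DEFAULT_TIMEPOINTS: tuple[float, ...] = (8, 16, 24, 48, 72, 96, 120)

#: Methylated-fraction anchors at the default sampling hours for each
#: temporal template.  A: flat 8-16 h then gradual monotone increase;
#: B: decline 24-72 h then recovery to 120 h; C: maximum at 72 h then
#: decline; D: maximum at 24 h, trough, then increase after 72 h.
PATTERN_ANCHORS: dict[str, tuple[float, ...]] = {
    "A": (0.20, 0.20, 0.30, 0.45, 0.60, 0.75, 0.90),
    "B": (0.80, 0.80, 0.75, 0.55, 0.35, 0.55, 0.80),
    "C": (0.30, 0.45, 0.60, 0.75, 0.90, 0.60, 0.35),
    "constant": (0.90,) * 7,
    "D": (0.45, 0.70, 0.90, 0.55, 0.40, 0.60, 0.85),
}

PATTERN_LABELS = ("A", "B", "C", "D")

IPD_TABLE_COLUMNS = ["genome_id", "position", "strand", "base", "ipd", "sample_id", "role", "time_h"]


@dataclass(frozen=True)
class SimulationConfig:
    """Free parameters of the synthetic study.

    Defaults mirror the study conditions: seven sampling times from 8 to
    120 h, ~50x coverage (the study averaged 67x with a 49x minimum),
    log-normal IPDs with a one-log-unit methylation shift (~1.67 sigma),
    rare extreme outliers above the 50,000 filter cutoff, and a site
    population dominated by constant full methylation with a small minority
    of temporally changing sites (66 of 37,452 in the study).
    """

    genome_length: int = 50_000
    gatc_count_target: int = 500
    mu_unmeth: float = 0.0
    sigma_unmeth: float = 0.6
    mu_meth: float = 1.0
    sigma_meth: float = 0.6
    outlier_rate: float = 0.005
    outlier_floor: float = 50_001.0
    outlier_ceiling: float = 1e6
    coverage_mean: float = 50.0
    timepoints_h: tuple[float, ...] = DEFAULT_TIMEPOINTS
    pattern_mix: Mapping[str, float] = field(
        default_factory=lambda: {"A": 0.015, "B": 0.015, "C": 0.015, "D": 0.015, "constant": 0.94}
    )
    background_sites: int | None = None  # None -> two per duplex GATC
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length <= 0 or self.gatc_count_target <= 0:
            raise ValueError("genome_length and gatc_count_target must be positive")
        if not 0.0 <= self.outlier_rate <= 1.0:
            raise ValueError("outlier_rate must be in [0, 1]")
        if self.outlier_floor <= 0:
            raise ValueError("outlier_floor must be positive")
        if self.coverage_mean <= 0:
            raise ValueError("coverage_mean must be positive")
        if self.mu_meth <= self.mu_unmeth:
            raise ValueError("mu_meth must exceed mu_unmeth")
        tp = tuple(self.timepoints_h)
        if any(b <= a for a, b in zip(tp, tp[1:])):
            raise ValueError("timepoints_h must be strictly increasing")
        object.__setattr__(self, "timepoints_h", tp)
        mix = dict(self.pattern_mix)
        unknown = set(mix) - set(PATTERN_ANCHORS)
        if unknown:
            raise ValueError(f"unknown pattern labels in pattern_mix: {sorted(unknown)}")
        if any(v < 0 for v in mix.values()) or abs(sum(mix.values()) - 1.0) > 1e-9:
            raise ValueError("pattern_mix proportions must be non-negative and sum to 1")
        object.__setattr__(self, "pattern_mix", mix)


def pattern_fraction(label: str, time_h, timepoints_h=DEFAULT_TIMEPOINTS) -> np.ndarray:
    """Methylated fraction of a template at arbitrary hours.

    Templates are piecewise-linear between the anchor fractions defined at
    the default 8-120 h grid; other sampling grids interpolate on that curve.
    """
    if label == "none":
        return np.zeros_like(np.asarray(time_h, dtype=float))
    anchors = PATTERN_ANCHORS[label]
    return np.interp(np.asarray(time_h, dtype=float), DEFAULT_TIMEPOINTS, anchors)


def generate_genome(
    length: int, gatc_count_target: int, seed: int, genome_id: str = "synthetic"
) -> tuple[GenomeSequence, list[MotifSite]]:
    """Random genome containing exactly ``gatc_count_target`` duplex GATCs.

    The target occurrences are planted at seeded random non-overlapping
    positions; any spurious GATC created by the random background is mutated
    away.  Deterministic given the seed.
    """
    if length < 4 * gatc_count_target:
        raise ValueError(
            f"cannot place {gatc_count_target} non-overlapping GATCs in {length} bp"
        )
    rng = np.random.default_rng(seed)
    slack = length - 4 * gatc_count_target
    gaps = rng.multinomial(slack, np.full(gatc_count_target + 1, 1.0 / (gatc_count_target + 1)))
    alphabet = np.array(list("ACGT"))

    seq = np.empty(length, dtype="<U1")
    planted_starts = []
    protected = np.zeros(length, dtype=bool)
    cursor = 0
    for i in range(gatc_count_target):
        g = int(gaps[i])
        seq[cursor : cursor + g] = rng.choice(alphabet, size=g)
        cursor += g
        seq[cursor : cursor + 4] = list("GATC")
        protected[cursor : cursor + 4] = True
        planted_starts.append(cursor)
        cursor += 4
    g = int(gaps[-1])
    seq[cursor : cursor + g] = rng.choice(alphabet, size=g)

    planted = set(planted_starts)
    text = "".join(seq)
    for _ in range(1000):
        spurious = [
            i for i in _find_all(text, "GATC") if i not in planted
        ]
        if not spurious:
            break
        for s in spurious:
            # mutate one unprotected base inside the spurious occurrence
            for j in range(s, s + 4):
                if not protected[j]:
                    choices = [c for c in "ACGT" if c != seq[j]]
                    seq[j] = rng.choice(choices)
                    break
        text = "".join(seq)
    else:  # pragma: no cover - bounded retry exhausted
        raise RuntimeError("failed to eliminate spurious GATC occurrences")

    genome = GenomeSequence(id=genome_id, residues=text)
    sites = scan_motif(genome, "GATC", 1, motif_name="Dam_GATC")
    if len(sites) != 2 * gatc_count_target:  # pragma: no cover - construction guarantee
        raise RuntimeError("planted GATC count does not match scan")
    return genome, sites


def _find_all(text: str, sub: str) -> list[int]:
    out, i = [], text.find(sub)
    while i != -1:
        out.append(i)
        i = text.find(sub, i + 1)
    return out


def make_site_truths(
    sites: Sequence[MotifSite],
    config: SimulationConfig,
    seed: int,
    genome: GenomeSequence | None = None,
) -> pd.DataFrame:
    """Assign a temporal template per duplex GATC (both strands share it)
    and append unmethylated non-motif background adenine positions.

    Returns the ground-truth ledger: one row per stranded site with its
    pattern label and methylated fraction at every configured hour.
    """
    rng = np.random.default_rng(seed)
    duplex = sorted({s.position for s in sites if s.strand == "+"})
    n = len(duplex)
    labels_pool: list[str] = []
    mix = config.pattern_mix
    counts = {lab: int(np.floor(mix.get(lab, 0.0) * n)) for lab in PATTERN_ANCHORS}
    short = n - sum(counts.values())
    order = sorted(mix, key=lambda k: -mix[k])
    for lab in order:
        if short == 0:
            break
        counts[lab] += 1
        short -= 1
    for lab, c in counts.items():
        labels_pool.extend([lab] * c)
    labels = np.array(labels_pool)
    rng.shuffle(labels)

    rows = []
    tp = config.timepoints_h
    for pos, lab in zip(duplex, labels):
        fr = pattern_fraction(lab, tp)
        for strand, p in (("+", pos), ("-", pos + 1)):
            rows.append({"position": p, "strand": strand, "pattern": lab,
                         **{f"f_{t:g}h": f for t, f in zip(tp, fr)}})

    n_bg = config.background_sites
    if n_bg is None:
        n_bg = 2 * len(duplex)
    if n_bg:
        occupied = {r["position"] for r in rows}
        glen = len(genome) if genome is not None else config.genome_length
        bg_positions = []
        while len(bg_positions) < n_bg:
            cand = int(rng.integers(1, glen + 1))
            if cand not in occupied:
                occupied.add(cand)
                bg_positions.append(cand)
        for p in bg_positions:
            rows.append({"position": p, "strand": "+", "pattern": "none",
                         **{f"f_{t:g}h": 0.0 for t in tp}})
    truths = pd.DataFrame(rows).sort_values(["position", "strand"]).reset_index(drop=True)
    return truths


def simulate_sample_ipds(
    truths: pd.DataFrame,
    time_h: float | None,
    config: SimulationConfig,
    seed: int,
    sample_id: str | None = None,
    role: str = "timepoint",
    genome_id: str = "synthetic",
) -> pd.DataFrame:
    """Long-format per-read IPD table for one sample.

    Coverage per site is Poisson(coverage_mean) truncated at >= 1.  Each
    read draws from the methylated log-normal law with the site's fraction f
    at the requested hour (controls use f = 0), and is replaced by a uniform
    extreme outlier with probability ``outlier_rate``.
    """
    if role not in ("timepoint", "dam_control", "wga_control"):
        raise ValueError(f"unknown role {role!r}")
    if role == "timepoint":
        if time_h is None:
            raise ValueError("timepoint samples require time_h")
        col = f"f_{time_h:g}h"
        if col not in truths.columns:
            raise ValueError(f"truth ledger has no fraction column for {time_h} h")
        fractions = truths[col].to_numpy(dtype=float)
    else:
        fractions = np.zeros(len(truths))
    if sample_id is None:
        sample_id = f"t{time_h:03g}h" if role == "timepoint" else role.split("_")[0]

    rng = np.random.default_rng(seed)
    n_sites = len(truths)
    coverage = np.maximum(1, rng.poisson(config.coverage_mean, size=n_sites))
    total = int(coverage.sum())
    site_idx = np.repeat(np.arange(n_sites), coverage)
    f_read = fractions[site_idx]
    methylated = rng.random(total) < f_read
    mu = np.where(methylated, config.mu_meth, config.mu_unmeth)
    sigma = np.where(methylated, config.sigma_meth, config.sigma_unmeth)
    ipd = np.exp(rng.normal(mu, sigma))
    if config.outlier_rate > 0:
        is_out = rng.random(total) < config.outlier_rate
        ipd[is_out] = rng.uniform(config.outlier_floor, config.outlier_ceiling, size=int(is_out.sum()))

    return pd.DataFrame(
        {
            "genome_id": genome_id,
            "position": truths["position"].to_numpy()[site_idx],
            "strand": truths["strand"].to_numpy()[site_idx],
            "base": "A",
            "ipd": ipd,
            "sample_id": sample_id,
            "role": role,
            "time_h": time_h if role == "timepoint" else np.nan,
        }
    )


@dataclass
class TimecourseDataset:
    """Everything one synthetic study produces."""

    genome: GenomeSequence
    sites: list[MotifSite]
    truths: pd.DataFrame
    ipd_table: pd.DataFrame  # all samples concatenated, long format
    metadata: pd.DataFrame  # sample_id, role, time_h

    def sample_table(self, sample_id: str) -> pd.DataFrame:
        return self.ipd_table[self.ipd_table["sample_id"] == sample_id]


def simulate_timecourse(config: SimulationConfig) -> TimecourseDataset:
    """Full synthetic study: 7 time points + dam and WGA controls + truth ledger.

    Child seeds are spawned deterministically from ``config.seed`` so the
    whole bundle is reproducible byte-for-byte.
    """
    root = np.random.SeedSequence(config.seed)
    genome_seed, truth_seed, *sample_seeds = [
        int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(2 + len(config.timepoints_h) + 2)
    ]
    genome, sites = generate_genome(config.genome_length, config.gatc_count_target, genome_seed)
    truths = make_site_truths(sites, config, truth_seed, genome=genome)

    tables = []
    meta_rows = []
    for t, s in zip(config.timepoints_h, sample_seeds):
        df = simulate_sample_ipds(truths, t, config, s, genome_id=genome.id)
        tables.append(df)
        meta_rows.append({"sample_id": df["sample_id"].iloc[0], "role": "timepoint", "time_h": t})
    for role, s in zip(("dam_control", "wga_control"), sample_seeds[len(config.timepoints_h):]):
        df = simulate_sample_ipds(truths, None, config, s, role=role, genome_id=genome.id)
        tables.append(df)
        meta_rows.append({"sample_id": df["sample_id"].iloc[0], "role": role, "time_h": np.nan})

    return TimecourseDataset(
        genome=genome,
        sites=sites,
        truths=truths,
        ipd_table=pd.concat(tables, ignore_index=True),
        metadata=pd.DataFrame(meta_rows),
    )


def simulate_lcms_run(
    true_mea_fraction: float,
    noise_cv: float,
    n_injections: int,
    seed: int,
    sample_id: str = "sample",
    base_area: float = 1e6,
    dilution_factors: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Nucleobase peak-area table consistent with a true meA/(meA+A) fraction.

    Areas obey Chargaff pairing ((A + meA) = T, G = C) up to the stated
    multiplicative CV noise.  ``dilution_factors`` records analytes injected
    diluted; the stored peak area is divided by the factor so that
    dilution-corrected analysis recovers the undiluted signal.
    """
    if not 0.0 <= true_mea_fraction <= 1.0:
        raise ValueError("true_mea_fraction must be in [0, 1]")
    if not 0.0 <= noise_cv < 1.0:
        raise ValueError("noise_cv must be in [0, 1)")
    if n_injections < 1:
        raise ValueError("n_injections must be >= 1")
    rng = np.random.default_rng(seed)
    dilution_factors = dict(dilution_factors or {})
    ideal = {
        "A": base_area * (1.0 - true_mea_fraction),
        "meA": base_area * true_mea_fraction,
        "T": base_area,
        "G": base_area,
        "C": base_area,
    }
    rows = []
    for rep in range(1, n_injections + 1):
        for analyte, area in ideal.items():
            noisy = area * max(0.0, 1.0 + noise_cv * rng.standard_normal())
            factor = float(dilution_factors.get(analyte, 1.0))
            rows.append(
                {
                    "sample_id": sample_id,
                    "replicate": rep,
                    "analyte": analyte,
                    "peak_area": noisy / factor,
                    "dilution_factor": factor,
                }
            )
    return pd.DataFrame(rows)


def simulate_qpcr_plate(
    true_fold_changes: Mapping[str, float | Mapping[float, float]],
    ct_noise_sd: float,
    seed: int,
    replicates: int = 3,
    timepoints_h: Sequence[float] = (8.0, 72.0),
    primer_efficiency: float = 1.0,
    rna_mass: float = 25.0,
    base_ct: float = 20.0,
) -> pd.DataFrame:
    """CT table for WT and dam strains satisfying fold = 2**(adjCT_dam - adjCT_WT).

    ``true_fold_changes`` maps gene -> fold (applied at the last hour, 1.0
    before — the study saw no change at 8 h) or gene -> {hour: fold}.  The
    adjusted CT is ct * log2(1 + E) - log2(mass / reference mass); the dam
    CT is placed so the target fold holds exactly, then Gaussian noise of sd
    ``ct_noise_sd`` cycles is added per well.
    """
    if ct_noise_sd < 0:
        raise ValueError("ct_noise_sd must be non-negative")
    if not 0.0 < primer_efficiency <= 1.2:
        raise ValueError("primer_efficiency must be in (0, 1.2]")
    rng = np.random.default_rng(seed)
    scale = np.log2(1.0 + primer_efficiency)
    rows = []
    for gene, fold_spec in true_fold_changes.items():
        for t in timepoints_h:
            if isinstance(fold_spec, Mapping):
                fold = float(fold_spec.get(t, 1.0))
            else:
                fold = float(fold_spec) if t == timepoints_h[-1] else 1.0
            if fold <= 0:
                raise ValueError(f"fold change for {gene} must be positive, got {fold}")
            ct_wt = base_ct
            ct_dam = ct_wt + np.log2(fold) / scale
            for rep in range(1, replicates + 1):
                for strain, ct in (("WT", ct_wt), ("dam", ct_dam)):
                    rows.append(
                        {
                            "gene": gene,
                            "strain": strain,
                            "time_h": t,
                            "ct": ct + rng.normal(0.0, ct_noise_sd) if ct_noise_sd else ct,
                            "rna_mass": rna_mass,
                            "primer_efficiency": primer_efficiency,
                            "replicate": rep,
                        }
                    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# writers


def _check_path(path: str | Path, overwrite: bool) -> Path:
    p = Path(path)
    if p.exists() and not overwrite:
        raise FileExistsError(f"{p} exists (pass overwrite=True to replace)")
    return p


def write_table(df: pd.DataFrame, path: str | Path, overwrite: bool = False) -> None:
    df.to_csv(_check_path(path, overwrite), sep="\t", index=False)


def write_genome_fasta(genome: GenomeSequence, path: str | Path, overwrite: bool = False) -> None:
    p = _check_path(path, overwrite)
    with open(p, "w") as fh:
        fh.write(f">{genome.id}\n")
        for i in range(0, len(genome.residues), 70):
            fh.write(genome.residues[i : i + 70] + "\n")
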