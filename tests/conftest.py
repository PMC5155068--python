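import numpy as np
import pandas as pd
import pytest

import damscan as d
from damscan.ingest import clean_observations
from damscan.synthetic import make_site_truths, simulate_sample_ipds


@pytest.fixture(scope="session")
def small_timecourse() -> d.TimecourseDataset:
    """A compact full study: 60 duplex GATCs, all 9 samples, seeded."""
    cfg = d.SimulationConfig(
        genome_length=6000,
        gatc_count_target=60,
        coverage_mean=30,
        pattern_mix={"A": 0.1, "B": 0.1, "C": 0.1, "D": 0.1, "constant": 0.6},
        seed=11,
    )
    return d.simulate_timecourse(cfg)


@pytest.fixture(scope="session")
def analysis_maps(small_timecourse):
    """Cleaned observation sets and raw/centered value maps for the fixture."""
    sets, report = clean_observations(small_timecourse.ipd_table)
    raw_map, cen_map, offsets = d.assemble_site_maps(sets, d.DEFAULT_PARAMS)
    keys = [s.key for s in small_timecourse.sites]
    raw_sites = {k: raw_map[k] for k in keys if k in raw_map}
    cen_sites = {k: cen_map[k] for k in keys if k in cen_map}
    return {
        "sets": sets,
        "report": report,
        "raw": raw_sites,
        "cen": cen_sites,
        "offsets": offsets,
    }


def two_sample_dataset(
    n_duplex: int,
    fraction: float,
    seed: int,
    coverage: float = 50.0,
    mu_meth: float = 1.0,
    sigma: float = 0.6,
    outlier_rate: float = 0.0,
):
    """One WT sample + dam control over ``n_duplex`` GATCs at a fixed
    methylated fraction; returns (site keys, raw map, centered map)."""
    cfg = d.SimulationConfig(
        genome_length=max(1000, 40 * n_duplex),
        gatc_count_target=n_duplex,
        coverage_mean=coverage,
        mu_meth=mu_meth,
        sigma_unmeth=sigma,
        sigma_meth=sigma,
        outlier_rate=outlier_rate,
        pattern_mix={"constant": 1.0},
        seed=seed,
    )
    rng = np.random.default_rng(seed)
    genome, sites = d.generate_genome(cfg.genome_length, n_duplex, int(rng.integers(2**31)))
    truths = make_site_truths(sites, cfg, int(rng.integers(2**31)), genome=genome)
    fcols = [c for c in truths.columns if c.startswith("f_")]
    gatc = truths["pattern"] != "none"
    truths[fcols] = 0.0
    truths.loc[gatc, fcols] = fraction
    wt = simulate_sample_ipds(truths, 8.0, cfg, int(rng.integers(2**31)))
    dam = simulate_sample_ipds(truths, None, cfg, int(rng.integers(2**31)), role="dam_control")
    sets, _ = clean_observations(pd.concat([wt, dam], ignore_index=True))
    raw_map, cen_map, _ = d.assemble_site_maps(sets, d.DEFAULT_PARAMS)
    keys = [s.key for s in sites]
    raw_sites = {k: raw_map[k] for k in keys if k in raw_map}
    cen_sites = {k: cen_map[k] for k in keys if k in cen_map}
    return keys, raw_sites, cen_sites
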