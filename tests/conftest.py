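import numpy as np
import pytest

from editscape import EditingProfile, EditingSite, SimulationConfig, simulate_counts, simulate_site_catalog
from editscape.simulate import ReadSpec, simulate_sam_fixture

Q30 = chr(30 + 33)


def make_profile(n_i, n_a, groups=("A", "B"), sites=None):
    """Small profile from explicit count matrices; half the samples per group."""
    n_i = np.asarray(n_i)
    n_a = np.asarray(n_a)
    S, M = n_i.shape
    if sites is None:
        sites = [EditingSite("chr1", 100 + 10 * i, "+", f"G{i}", "UTR3", True) for i in range(S)]
    samples = [f"s{j}" for j in range(M)]
    half = M // 2
    labels = {s: (groups[0] if j < half else groups[1]) for j, s in enumerate(samples)}
    return EditingProfile(sites, samples, n_i, n_a, labels)


@pytest.fixture
def two_group_profile():
    cfg = SimulationConfig(
        n_sites=120,
        n_samples_per_group=(8, 8),
        coverage_mean=50,
        coverage_dispersion=0.0,
        baseline_editing_dist=(2.0, 6.0),
        n_differential=20,
        effect_size=0.25,
        snp_fraction=0.0,
        seed=42,
    )
    catalog = simulate_site_catalog(cfg)
    profile, truth = simulate_counts(cfg, catalog)
    return cfg, profile, truth


@pytest.fixture
def sam_fixture():
    """Hand-built SAM exercising every read filter, plus its expected counts."""
    catalog = [
        EditingSite("chr1", 110, "+", "GENE1", "UTR3", True),
        EditingSite("chr1", 140, "-", "GENE2", "intron", False),
    ]
    reads = [
        ReadSpec("edited_fwd", 101, "A" * 9 + "G" + "A" * 10, Q30 * 20),
        ReadSpec("unedited_fwd", 101, "A" * 20, Q30 * 20),
        ReadSpec("dup_of_unedited", 101, "A" * 20, chr(25 + 33) * 20),  # lower mean qual copy
        ReadSpec("low_mapq", 101, "A" * 20, Q30 * 20, mapq=9),
        ReadSpec("near_end", 109, "A" * 20, Q30 * 20),  # site at read offset 1
        ReadSpec("low_baseq", 101, "A" * 9 + "G" + "A" * 10, chr(19 + 33) * 20),
        ReadSpec("edited_rev", 131, "T" * 9 + "C" + "T" * 10, Q30 * 20),
        ReadSpec("unedited_rev", 131, "T" * 20, Q30 * 20),
    ]
    return simulate_sam_fixture(catalog, reads)
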