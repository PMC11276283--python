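"""Read filters and allele counting against the SAM fixture."""
import numpy as np
import pytest

from editscape import EditingSite, load_site_catalog, write_site_catalog
from editscape.errors import ParseError, ValidationError
from editscape.quantify import build_profile
from editscape.simulate import ReadSpec, simulate_sam_fixture

Q30 = chr(30 + 33)


def quantify_fixture(fixture, tmp_path, **kwargs):
    path = tmp_path / "sample.sam"
    fixture.write(path)
    return build_profile({"s1": path}, fixture.catalog, **kwargs)


def test_fixture_counts_reproduced_exactly(sam_fixture, tmp_path):
    profile = quantify_fixture(sam_fixture, tmp_path)
    frame = profile.counts_frame()
    assert frame["s1_nI"].tolist() == sam_fixture.expected["n_I"].tolist()
    assert frame["s1_nA"].tolist() == sam_fixture.expected["n_A"].tolist()


@pytest.mark.parametrize(
    "kwargs",
    [
        {"keep_duplicates": True},
        {"min_mapq": 0},
        {"min_baseq": 0},
        {"end_exclusion": 0},
        {"keep_duplicates": True, "min_mapq": 0, "min_baseq": 0, "end_exclusion": 0},
    ],
)
def test_each_filter_toggles_to_fixture_expectation(sam_fixture, tmp_path, kwargs):
    profile = quantify_fixture(sam_fixture, tmp_path, **kwargs)
    expected = sam_fixture.expected_counts(**kwargs)
    frame = profile.counts_frame()
    assert frame["s1_nI"].tolist() == expected["n_I"].tolist()
    assert frame["s1_nA"].tolist() == expected["n_A"].tolist()


def test_relaxing_filters_never_decreases_totals(sam_fixture, tmp_path):
    strict = quantify_fixture(sam_fixture, tmp_path).coverage
    for kwargs in ({"keep_duplicates": True}, {"min_mapq": 0}, {"min_baseq": 0}, {"end_exclusion": 0}):
        relaxed = quantify_fixture(sam_fixture, tmp_path, **kwargs).coverage
        assert (relaxed >= strict).all()


def test_duplicate_retention_prefers_highest_mean_quality(tmp_path):
    # the surviving duplicate copy determines the counted base quality
    site = [EditingSite("chr1", 110, "+")]
    seq = "A" * 9 + "G" + "A" * 10
    low = chr(19 + 33) * 20   # site base below the quality threshold
    high = Q30 * 20
    fx = simulate_sam_fixture(site, [ReadSpec("dup1", 101, seq, low), ReadSpec("dup2", 101, seq, high)])
    profile = quantify_fixture(fx, tmp_path)
    assert profile.counts_frame().loc["chr1:110:+"].tolist() == [1, 0]
    # with order reversed the high-quality copy still wins
    fx2 = simulate_sam_fixture(site, [ReadSpec("dup2", 101, seq, high), ReadSpec("dup1", 101, seq, low)])
    assert quantify_fixture(fx2, tmp_path).counts_frame().loc["chr1:110:+"].tolist() == [1, 0]


def test_threshold_boundaries_are_inclusive(tmp_path):
    site = [EditingSite("chr1", 110, "+")]
    reads = [  # distinct positions so the duplicate rule stays out of the way
        ReadSpec("mapq10", 101, "A" * 20, chr(20 + 33) * 20, mapq=10),  # exactly at both thresholds
        ReadSpec("mapq9", 100, "A" * 20, Q30 * 20, mapq=9),
    ]
    fx = simulate_sam_fixture(site, reads)
    profile = quantify_fixture(fx, tmp_path)
    assert profile.counts_frame().loc["chr1:110:+"].tolist() == [0, 1]


def test_end_exclusion_window(tmp_path):
    site = [EditingSite("chr1", 110, "+")]
    # site at offsets 0,1 (5' side) and len-2, len-1 (3' side) must be dropped; offset 2 kept
    reads = [
        ReadSpec("off0", 110, "A" * 20, Q30 * 20),
        ReadSpec("off1", 109, "A" * 20, Q30 * 20),
        ReadSpec("off2", 108, "A" * 20, Q30 * 20),
        ReadSpec("off18", 92, "A" * 20, Q30 * 20),
        ReadSpec("off19", 91, "A" * 20, Q30 * 20),
    ]
    fx = simulate_sam_fixture(site, reads)
    profile = quantify_fixture(fx, tmp_path)
    assert profile.counts_frame().loc["chr1:110:+"].tolist() == [0, 1]


def test_non_target_bases_are_ignored(tmp_path):
    site = [EditingSite("chr1", 110, "+")]
    reads = [
        ReadSpec("showsC", 101, "A" * 9 + "C" + "A" * 10, Q30 * 20),
        ReadSpec("showsA", 101, "A" * 20, Q30 * 20),
    ]
    fx = simulate_sam_fixture(site, reads)
    profile = quantify_fixture(fx, tmp_path)
    assert profile.counts_frame().loc["chr1:110:+"].tolist() == [0, 1]


def test_strand_symmetry(tmp_path):
    fwd_site = [EditingSite("chr1", 110, "+")]
    rev_site = [EditingSite("chr1", 110, "-")]
    fwd_reads = [
        ReadSpec("e", 101, "A" * 9 + "G" + "A" * 10, Q30 * 20),
        ReadSpec("u", 101, "A" * 20, Q30 * 20),
    ]
    rev_reads = [  # complemented bases at the site, opposite catalog strand
        ReadSpec("e", 101, "T" * 9 + "C" + "T" * 10, Q30 * 20),
        ReadSpec("u", 101, "T" * 20, Q30 * 20),
    ]
    fwd = quantify_fixture(simulate_sam_fixture(fwd_site, fwd_reads), tmp_path)
    rev = quantify_fixture(simulate_sam_fixture(rev_site, rev_reads), tmp_path)
    assert np.array_equal(fwd.n_i, rev.n_i) and np.array_equal(fwd.n_a, rev.n_a)


def test_quantify_is_byte_deterministic(sam_fixture, tmp_path):
    p1 = quantify_fixture(sam_fixture, tmp_path)
    p1.to_tsv(tmp_path / "a.tsv")
    p2 = quantify_fixture(sam_fixture, tmp_path)
    p2.to_tsv(tmp_path / "b.tsv")
    assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()


def test_empty_catalog_gives_empty_profile(sam_fixture, tmp_path):
    path = tmp_path / "sample.sam"
    sam_fixture.write(path)
    profile = build_profile({"s1": path}, [])
    assert profile.n_sites == 0


def test_catalog_parse_and_validation_errors(tmp_path):
    ok = tmp_path / "ok.tsv"
    write_site_catalog(
        [EditingSite("chr2", 5, "-", "g", "intron", False),
         EditingSite("chr1", 9, "+", "g", "UTR3", True),
         EditingSite("chr1", 3, "+", "g", "CDS", False)],
        ok,
    )
    sites = load_site_catalog(ok)
    assert [(s.chrom, s.pos) for s in sites] == [("chr1", 3), ("chr1", 9), ("chr2", 5)]

    bad_pos = tmp_path / "badpos.tsv"
    bad_pos.write_text("chrom\tpos\tstrand\tgene\tregion\trepeat\nchr1\t0\t+\tg\tCDS\trep\n")
    with pytest.raises(ParseError, match="line 2"):
        load_site_catalog(bad_pos)

    dup = tmp_path / "dup.tsv"
    dup.write_text(
        "chrom\tpos\tstrand\tgene\tregion\trepeat\n"
        "chr1\t5\t+\tg\tCDS\trep\nchr1\t5\t+\tg\tCDS\trep\n"
    )
    with pytest.raises(ValidationError, match="duplicate"):
        load_site_catalog(dup)
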