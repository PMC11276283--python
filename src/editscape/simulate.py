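"""Synthetic editing data: catalogs, pileup counts, expression, SAM fixtures.

The generator emulates the statistical structure the analysis assumes:

* per-site baseline editing efficiencies drawn from a Beta distribution;
* per-site per-sample read coverage from a (truncated) negative binomial,
  Poisson, or a fixed depth;
* edited read counts ``n_I ~ Binomial(n, p)`` — the sampling model under
  which the downstream variance weights are derived;
* group-structured effects: a configurable number of sites whose efficiency
  is shifted by ``effect_size`` in the second group;
* SNP-mimicking sites whose per-sample "efficiency" is drawn from a
  tri-modal genotype mixture concentrated near 0, 0.5 and 1;
* gene expression optionally coupled (positively or negatively) to the
  latent editing level of a gene's site.

All randomness flows from ``SimulationConfig.seed`` through per-function
substreams (``default_rng([seed, k])`` with k = 0 catalog, 1 counts,
2 expression), so every output is bit-reproducible.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, FixtureError
from .profile import EditingProfile
from .sites import REGIONS, EditingSite

_DEFAULT_REGION_PROBS = {
    # non-coding dominated, as in genome-wide A-to-I catalogs
    "CDS": 0.02,
    "UTR5": 0.05,
    "UTR3": 0.45,
    "intron": 0.35,
    "intergenic": 0.13,
}

# genotype modes for SNP-like sites: AA ~ 0.02, AG ~ 0.5, GG ~ 0.98
_GENOTYPE_MODES = (0.02, 0.5, 0.98)


@dataclass
class SimulationConfig:
    """Full generative description of a synthetic editing study.

    Defaults describe a two-group bulk RNA-Seq comparison: 15 samples per
    group at mean depth 50x with mild over-dispersion, baseline editing
    levels from Beta(2, 6) (mean 0.25, long right tail), and a tenth of
    sites carrying a 0.2 absolute group shift.
    """

    n_sites: int = 500
    n_samples_per_group: tuple[int, ...] = (15, 15)
    coverage_mean: float = 50.0
    coverage_dispersion: float = 0.3  # NB dispersion; 0 => Poisson
    coverage_fixed: bool = False  # True => every draw equals coverage_mean exactly
    baseline_editing_dist: tuple[float, float] = (2.0, 6.0)  # Beta(alpha, beta)
    n_differential: int = 50
    effect_size: float = 0.2  # absolute shift in the second group, clamped to [0, 1]
    snp_fraction: float = 0.0
    genotype_freqs: tuple[float, float, float] = (0.25, 0.5, 0.25)  # AA, AG, GG
    genotype_concentration: float = 100.0  # Beta concentration around each mode
    editing_noise_sd: float = 0.0  # optional extra-binomial per-sample jitter on p
    expression_coupling: float = 0.0  # slope linking latent p to log-expression
    expression_noise_sd: float = 0.25
    region_probs: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_REGION_PROBS))
    repeat_prob: float = 0.9
    group_names: tuple[str, ...] | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_sites < 1:
            raise ConfigurationError("n_sites must be >= 1")
        if len(self.n_samples_per_group) < 2 or any(m < 2 for m in self.n_samples_per_group):
            raise ConfigurationError(
                "n_samples_per_group needs >= 2 groups with >= 2 samples each"
            )
        if self.coverage_mean <= 0:
            raise ConfigurationError("coverage_mean must be positive")
        if self.coverage_dispersion < 0:
            raise ConfigurationError("coverage_dispersion must be >= 0")
        a, b = self.baseline_editing_dist
        if a <= 0 or b <= 0:
            raise ConfigurationError("baseline_editing_dist parameters must be positive")
        if not 0 <= self.snp_fraction <= 1:
            raise ConfigurationError("snp_fraction must be in [0, 1]")
        if self.n_differential < 0 or self.n_differential > self.n_sites:
            raise ConfigurationError("n_differential must be in [0, n_sites]")
        if not -1 <= self.effect_size <= 1:
            raise ConfigurationError("effect_size must be in [-1, 1]")
        if abs(sum(self.genotype_freqs) - 1.0) > 1e-9 or any(f < 0 for f in self.genotype_freqs):
            raise ConfigurationError("genotype_freqs must be non-negative and sum to 1")
        if self.editing_noise_sd < 0:
            raise ConfigurationError("editing_noise_sd must be >= 0")
        if self.expression_noise_sd < 0:
            raise ConfigurationError("expression_noise_sd must be >= 0")
        if not 0 <= self.repeat_prob <= 1:
            raise ConfigurationError("repeat_prob must be in [0, 1]")
        probs = dict(self.region_probs)
        if set(probs) - set(REGIONS):
            raise ConfigurationError(f"region_probs has unknown regions: {set(probs) - set(REGIONS)}")
        if abs(sum(probs.values()) - 1.0) > 1e-9 or any(p < 0 for p in probs.values()):
            raise ConfigurationError("region_probs must be non-negative and sum to 1")
        if self.group_names is not None and len(self.group_names) != len(self.n_samples_per_group):
            raise ConfigurationError("group_names length must match n_samples_per_group")

    @property
    def groups(self) -> tuple[str, ...]:
        if self.group_names is not None:
            return tuple(self.group_names)
        return tuple(f"G{i + 1}" for i in range(len(self.n_samples_per_group)))

    @property
    def sample_names(self) -> list[str]:
        names = []
        for g, m in zip(self.groups, self.n_samples_per_group):
            names += [f"{g}_s{j + 1}" for j in range(m)]
        return names

    @property
    def group_labels(self) -> dict[str, str]:
        labels = {}
        for g, m in zip(self.groups, self.n_samples_per_group):
            for j in range(m):
                labels[f"{g}_s{j + 1}"] = g
        return labels


@dataclass
class GroundTruth:
    """Per-site generative truth stored alongside simulated data."""

    is_differential: np.ndarray  # bool (S,)
    is_snp_like: np.ndarray  # bool (S,)
    group_efficiency: np.ndarray  # (S, n_groups) true mean efficiency per group
    true_p: np.ndarray  # (S, M) latent per-sample efficiency actually used


def simulate_site_catalog(config: SimulationConfig) -> list[EditingSite]:
    """Draw ``n_sites`` unique loci with region/repeat annotation.

    Positions are sampled without replacement on a toy chromosome, so
    (chrom, pos, strand) is unique by construction; one synthetic gene per
    site keeps the editing-vs-expression mapping one-to-one.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    span = max(10 * config.n_sites, 10_000)
    positions = np.sort(rng.choice(np.arange(1, span + 1), size=config.n_sites, replace=False))
    strands = rng.choice(["+", "-"], size=config.n_sites)
    regions = list(config.region_probs)
    region_draw = rng.choice(regions, size=config.n_sites, p=[config.region_probs[r] for r in regions])
    repeat_draw = rng.random(config.n_sites) < config.repeat_prob
    return [
        EditingSite(
            chrom="chr1",
            pos=int(positions[i]),
            strand=str(strands[i]),
            gene=f"GENE{i:05d}",
            region=str(region_draw[i]),
            repeat=bool(repeat_draw[i]),
        )
        for i in range(config.n_sites)
    ]


def _draw_coverage(rng: np.random.Generator, config: SimulationConfig, shape) -> np.ndarray:
    if config.coverage_fixed:
        return np.full(shape, int(round(config.coverage_mean)), dtype=np.int64)

    def draw(size):
        if config.coverage_dispersion == 0:
            return rng.poisson(config.coverage_mean, size=size)
        r = 1.0 / config.coverage_dispersion
        prob = r / (r + config.coverage_mean)
        return rng.negative_binomial(r, prob, size=size)

    n = draw(shape).astype(np.int64)
    # truncate at >= 1 by redrawing zeros
    for _ in range(100):
        zero = n == 0
        if not zero.any():
            break
        n[zero] = draw(int(zero.sum()))
    n[n == 0] = 1
    return n


def simulate_counts(
    config: SimulationConfig, catalog: Sequence[EditingSite]
) -> tuple[EditingProfile, GroundTruth]:
    """Generate the counts grid and its ground truth.

    Random draws are consumed in a fixed, documented order: baseline
    efficiencies, SNP flags, differential flags, genotype assignments,
    genotype-mode efficiencies, optional extra-binomial jitter, coverage,
    and finally the binomial edited counts.
    """
    config.validate()
    if len(catalog) != config.n_sites:
        raise ConfigurationError("catalog length does not match config.n_sites")
    rng = np.random.default_rng([config.seed, 1])
    S = config.n_sites
    M = sum(config.n_samples_per_group)
    n_groups = len(config.n_samples_per_group)
    group_index = np.repeat(np.arange(n_groups), config.n_samples_per_group)

    a, b = config.baseline_editing_dist
    baseline = rng.beta(a, b, size=S)

    n_snp = int(round(config.snp_fraction * S))
    snp_idx = rng.choice(S, size=n_snp, replace=False)
    is_snp = np.zeros(S, dtype=bool)
    is_snp[snp_idx] = True
    candidates = np.flatnonzero(~is_snp)
    if config.n_differential > candidates.size:
        raise ConfigurationError("n_differential exceeds the number of non-SNP sites")
    diff_idx = rng.choice(candidates, size=config.n_differential, replace=False)
    is_diff = np.zeros(S, dtype=bool)
    is_diff[diff_idx] = True

    # latent per-sample efficiency
    p = np.tile(baseline[:, None], (1, M))
    shifted = np.clip(baseline + config.effect_size, 0.0, 1.0)
    in_second = group_index == 1
    p[np.ix_(is_diff, in_second)] = np.tile(
        shifted[is_diff][:, None], (1, int(in_second.sum()))
    )

    group_eff = np.tile(baseline[:, None], (1, n_groups))
    group_eff[is_diff, 1] = shifted[is_diff]

    if n_snp:
        geno = rng.choice(3, size=(n_snp, M), p=list(config.genotype_freqs))
        modes = np.array(_GENOTYPE_MODES)[geno]
        k = config.genotype_concentration
        p[is_snp, :] = rng.beta(k * modes, k * (1.0 - modes))
        mix_mean = float(np.dot(config.genotype_freqs, _GENOTYPE_MODES))
        group_eff[is_snp, :] = mix_mean

    if config.editing_noise_sd > 0:
        p = np.clip(p + rng.normal(0.0, config.editing_noise_sd, size=p.shape), 1e-4, 1 - 1e-4)

    n = _draw_coverage(rng, config, (S, M))
    n_i = rng.binomial(n, p)
    n_a = n - n_i

    profile = EditingProfile(list(catalog), config.sample_names, n_i, n_a, config.group_labels)
    truth = GroundTruth(is_diff, is_snp, group_eff, p)
    return profile, truth


def simulate_expression(
    config: SimulationConfig, profile: EditingProfile, truth: GroundTruth
) -> pd.DataFrame:
    """Per-gene normalized coverage values, optionally coupled to editing.

    Returns a genes x samples DataFrame on the scale of exonic-reads /
    total-mapped-reads (~1e-4). When ``expression_coupling`` is non-zero,
    each gene's log-expression tracks the latent editing level of its site
    with that slope, so the expected rank correlation carries the coupling's
    sign; at zero coupling expression is independent of editing.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 2])
    genes: list[str] = []
    first_site: list[int] = []
    seen: dict[str, int] = {}
    for i, site in enumerate(profile.sites):
        if site.gene and site.gene not in seen:
            seen[site.gene] = i
            genes.append(site.gene)
            first_site.append(i)
    M = profile.n_samples
    base = rng.normal(np.log(1e-4), 1.0, size=len(genes))
    noise = rng.normal(0.0, config.expression_noise_sd, size=(len(genes), M))
    signal = config.expression_coupling * (
        truth.true_p[first_site, :] - truth.true_p[first_site, :].mean(axis=1, keepdims=True)
    )
    values = np.exp(base[:, None] + signal + noise)
    return pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=profile.samples)


# ---------------------------------------------------------------------------
# SAM fixture construction
# ---------------------------------------------------------------------------


@dataclass
class ReadSpec:
    """One constructed alignment for a desk-scale SAM fixture.

    ``pos`` is the 1-based leftmost mapping coordinate; ``quals`` is either a
    Phred+33 string or a sequence of integer qualities. ``mate_pos`` takes
    part in the duplicate key (reads with identical sequence, orientation,
    position and mate position are duplicates of each other).
    """

    name: str
    pos: int
    seq: str
    quals: str | Sequence[int]
    mapq: int = 60
    reverse: bool = False
    mate_pos: int = 0

    def qual_values(self) -> list[int]:
        if isinstance(self.quals, str):
            return [ord(c) - 33 for c in self.quals]
        return list(self.quals)

    def qual_string(self) -> str:
        return "".join(chr(q + 33) for q in self.qual_values())


@dataclass
class SamFixture:
    sam_text: str
    expected: pd.DataFrame  # index site_id, columns n_I / n_A (default filter settings)
    catalog: list[EditingSite]
    reads: list[ReadSpec]

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.sam_text)

    def expected_counts(self, **filter_kwargs) -> pd.DataFrame:
        """Expected (n_I, n_A) table under arbitrary filter settings."""
        return _expected_counts(self.catalog, self.reads, **filter_kwargs)


def _expected_counts(
    catalog: Sequence[EditingSite],
    reads: Sequence[ReadSpec],
    keep_duplicates: bool = False,
    min_mapq: int = 10,
    min_baseq: int = 20,
    end_exclusion: int = 2,
) -> pd.DataFrame:
    """Reference tally of the read-level filters, kept deliberately simple
    and separate from the alignment-file path so the two can be compared."""
    survivors = list(reads)
    if not keep_duplicates:
        by_key: dict[tuple, ReadSpec] = {}
        order: list[tuple] = []
        for r in reads:
            key = (r.pos, r.reverse, r.seq, r.mate_pos)
            if key not in by_key:
                by_key[key] = r
                order.append(key)
            else:
                kept = by_key[key]
                if float(np.mean(r.qual_values())) > float(np.mean(kept.qual_values())):
                    by_key[key] = r
        survivors = [by_key[k] for k in order]
    survivors = [r for r in survivors if r.mapq >= min_mapq]

    rows = []
    for site in catalog:
        n_i = n_a = 0
        for r in survivors:
            offset = site.pos - r.pos  # all-M alignments: reference offset == query offset
            if not (0 <= offset < len(r.seq)):
                continue
            if offset < end_exclusion or offset >= len(r.seq) - end_exclusion:
                continue
            if r.qual_values()[offset] < min_baseq:
                continue
            base = r.seq[offset].upper()
            if site.strand == "+":
                if base == "G":
                    n_i += 1
                elif base == "A":
                    n_a += 1
            else:
                if base == "C":
                    n_i += 1
                elif base == "T":
                    n_a += 1
        rows.append((site.site_id, n_i, n_a))
    return pd.DataFrame(rows, columns=["site", "n_I", "n_A"]).set_index("site")


def simulate_sam_fixture(
    catalog: Sequence[EditingSite], reads: Sequence[ReadSpec]
) -> SamFixture:
    """Emit a valid single-chromosome SAM file plus its expected counts.

    Every read must overlap at least one catalog site (otherwise the read
    spec is considered inconsistent with the catalog and a
    :class:`FixtureError` is raised). Reads are written coordinate-sorted.
    """
    if not catalog:
        raise FixtureError("empty catalog")
    chroms = {s.chrom for s in catalog}
    if len(chroms) != 1:
        raise FixtureError("SAM fixtures are single-chromosome; catalog spans " + ",".join(sorted(chroms)))
    chrom = chroms.pop()
    for r in reads:
        if len(r.seq) != len(r.qual_values()):
            raise FixtureError(f"read {r.name}: sequence and quality lengths differ")
        if len(r.seq) > 60:
            raise FixtureError(f"read {r.name}: fixture reads are limited to 60 bp")
        if not any(r.pos <= s.pos < r.pos + len(r.seq) for s in catalog):
            raise FixtureError(f"read {r.name} overlaps no catalog site")
    ref_len = max(max((r.pos + len(r.seq) for r in reads), default=0), max(s.pos for s in catalog)) + 100
    lines = ["@HD\tVN:1.6\tSO:coordinate", f"@SQ\tSN:{chrom}\tLN:{ref_len}"]
    for r in sorted(reads, key=lambda r: r.pos):
        flag = 16 if r.reverse else 0
        rnext = "=" if r.mate_pos else "*"
        lines.append(
            "\t".join(
                [
                    r.name,
                    str(flag),
                    chrom,
                    str(r.pos),
                    str(r.mapq),
                    f"{len(r.seq)}M",
                    rnext,
                    str(r.mate_pos),
                    "0",
                    r.seq,
                    r.qual_string(),
                ]
            )
        )
    expected = _expected_counts(catalog, reads)
    return SamFixture("\n".join(lines) + "\n", expected, list(catalog), list(reads))
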