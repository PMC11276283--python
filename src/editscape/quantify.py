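"""Per-sample allele counting at known editing sites from aligned reads.

Four read-level filters are applied, in order, to the reads overlapping a
site before counting:

1. duplicate removal (optional): reads with the same mapping position,
   orientation, sequence and mate position are collapsed to the copy with
   the highest mean base quality (ties: first in file order);
2. mapping quality >= 10;
3. the site must not lie within 2 bp of either end of the aligned read;
4. the base at the site must have quality >= 20.

Counting then follows the strand of the catalog site: on the forward strand
G reads are edited (n_I) and A reads unedited (n_A); on the reverse strand C
is edited and T unedited. Any other base is ignored entirely. Reads whose
alignment has a deletion or reference skip across the site observe no base
and contribute nothing.

Thresholds are parameters everywhere; the defaults are the stringent values
used for the published editing profiles.
"""
from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pysam

from .errors import ContractViolationError, EditscapeError
from .profile import AlleleCount, EditingProfile
from .sites import EditingSite

logger = logging.getLogger(__name__)

DEFAULT_MIN_MAPQ = 10
DEFAULT_MIN_BASEQ = 20
DEFAULT_END_EXCLUSION = 2


def _query_offset(read: pysam.AlignedSegment, ref_pos: int) -> int | None:
    """Query index observing 0-based ``ref_pos``, or None if no base aligns
    there (deletion / reference skip)."""
    for qpos, rpos in read.get_aligned_pairs(matches_only=False):
        if rpos == ref_pos:
            return qpos
    return None


def _mean_base_quality(read: pysam.AlignedSegment) -> float:
    quals = read.query_qualities
    if quals is None or len(quals) == 0:
        return 0.0
    return float(np.mean(quals))


def filter_alignments(
    reads: Sequence[pysam.AlignedSegment],
    site: EditingSite,
    keep_duplicates: bool = False,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    min_baseq: int = DEFAULT_MIN_BASEQ,
    end_exclusion: int = DEFAULT_END_EXCLUSION,
) -> list[pysam.AlignedSegment]:
    """Apply the ordered read-level filters; returns surviving reads.

    All input reads must be mapped and overlap the site position, otherwise
    a :class:`ContractViolationError` is raised. Duplicate detection is
    sequence/position based (alignment-flag duplicate marks are ignored).
    """
    ref_pos = site.pos - 1  # catalog is 1-based; pysam coordinates are 0-based
    for read in reads:
        if read.is_unmapped:
            raise ContractViolationError(f"unmapped read {read.query_name} passed to filter_alignments")
        if not (read.reference_start <= ref_pos < read.reference_end):
            raise ContractViolationError(
                f"read {read.query_name} does not overlap site {site.site_id}"
            )

    survivors = list(reads)

    if not keep_duplicates:
        best: dict[tuple, pysam.AlignedSegment] = {}
        order: list[tuple] = []
        for read in survivors:
            key = (
                read.reference_start,
                read.is_reverse,
                read.query_sequence,
                read.next_reference_start,
            )
            if key not in best:
                best[key] = read
                order.append(key)
            elif _mean_base_quality(read) > _mean_base_quality(best[key]):
                best[key] = read
        survivors = [best[k] for k in order]

    survivors = [r for r in survivors if r.mapping_quality >= min_mapq]

    kept: list[pysam.AlignedSegment] = []
    for read in survivors:
        qpos = _query_offset(read, ref_pos)
        if qpos is None:
            continue  # no base observed at the site
        rel = qpos - read.query_alignment_start
        aligned_len = read.query_alignment_length
        if rel < end_exclusion or rel >= aligned_len - end_exclusion:
            continue
        if read.query_qualities is not None and read.query_qualities[qpos] < min_baseq:
            continue
        kept.append(read)
    return kept


def count_site_alleles(
    reads: Iterable[pysam.AlignedSegment], site: EditingSite
) -> AlleleCount:
    """Tally edited/unedited bases among surviving reads at one site."""
    ref_pos = site.pos - 1
    n_i = n_a = 0
    for read in reads:
        qpos = _query_offset(read, ref_pos)
        if qpos is None:
            continue
        base = read.query_sequence[qpos].upper()
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
    return AlleleCount(n_i, n_a)


def _site_reads_indexed(
    af: pysam.AlignmentFile, sites: Sequence[EditingSite]
) -> list[list[pysam.AlignedSegment]]:
    out = []
    for site in sites:
        try:
            reads = [
                r
                for r in af.fetch(site.chrom, site.pos - 1, site.pos)
                if not r.is_unmapped
            ]
        except ValueError:
            reads = []
        out.append(reads)
    return out


def _site_reads_streaming(
    af: pysam.AlignmentFile, sites: Sequence[EditingSite]
) -> list[list[pysam.AlignedSegment]]:
    """Single pass for (small) non-indexed SAM inputs."""
    buckets: list[list[pysam.AlignedSegment]] = [[] for _ in sites]
    by_chrom: dict[str, list[int]] = {}
    for i, s in enumerate(sites):
        by_chrom.setdefault(s.chrom, []).append(i)
    for read in af.fetch(until_eof=True):
        if read.is_unmapped or read.reference_name not in by_chrom:
            continue
        for i in by_chrom[read.reference_name]:
            if read.reference_start <= sites[i].pos - 1 < read.reference_end:
                buckets[i].append(read)
    return buckets


def build_profile(
    alignments: Mapping[str, str | Path],
    catalog: Sequence[EditingSite],
    groups: Mapping[str, str] | None = None,
    keep_duplicates: bool = False,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    min_baseq: int = DEFAULT_MIN_BASEQ,
    end_exclusion: int = DEFAULT_END_EXCLUSION,
) -> EditingProfile:
    """Count alleles at every catalog site for every sample.

    ``alignments`` maps sample name -> SAM/BAM path. BAM/CRAM inputs must be
    coordinate-sorted and indexed (random access); plain SAM inputs are
    streamed in one pass. An empty catalog yields an empty profile.
    """
    S, samples = len(catalog), list(alignments)
    n_i = np.zeros((S, len(samples)), dtype=np.int64)
    n_a = np.zeros((S, len(samples)), dtype=np.int64)
    for j, sample in enumerate(samples):
        path = Path(alignments[sample])
        if not path.exists():
            raise EditscapeError(f"alignment file for sample {sample!r} not found: {path}")
        with pysam.AlignmentFile(str(path)) as af:
            if path.suffix in (".bam", ".cram"):
                if not af.has_index():
                    raise EditscapeError(f"missing index for {path}; sort and index the file first")
                buckets = _site_reads_indexed(af, catalog)
            else:
                buckets = _site_reads_streaming(af, catalog)
            for i, site in enumerate(catalog):
                surviving = filter_alignments(
                    buckets[i],
                    site,
                    keep_duplicates=keep_duplicates,
                    min_mapq=min_mapq,
                    min_baseq=min_baseq,
                    end_exclusion=end_exclusion,
                )
                count = count_site_alleles(surviving, site)
                n_i[i, j], n_a[i, j] = count.n_i, count.n_a
        logger.info(
            "sample %s: %d edited / %d unedited reads counted over %d sites",
            sample, int(n_i[:, j].sum()), int(n_a[:, j].sum()), S,
        )
    return EditingProfile(list(catalog), samples, n_i, n_a, groups)
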