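"""Editing profiles: per-site per-sample edited/unedited read counts.

The central container is :class:`EditingProfile`, a sites x samples grid of
allele counts with optional group labels. Editing efficiency at a site in a
sample is ``n_I / (n_I + n_A)``, the fraction of reads carrying the edited
base (G on the forward strand, C on the reverse strand).

Serialisation uses a TSV matrix: rows keyed by ``chrom:pos:strand``, one
``<sample>_nI`` / ``<sample>_nA`` column pair per sample. Group labels live
in a two-column TSV ``sample  group``.
"""
from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .sites import EditingSite


class AlleleCount(NamedTuple):
    """Edited (n_I) and unedited (n_A) read tallies at one site in one sample."""

    n_i: int
    n_a: int

    @property
    def n(self) -> int:
        return self.n_i + self.n_a

    @property
    def efficiency(self) -> float:
        """n_I / n; NaN when no read was observed."""
        return self.n_i / self.n if self.n > 0 else float("nan")


class EditingProfile:
    """Sites x samples matrix of allele counts, plus sample group labels.

    Parameters
    ----------
    sites
        Ordered catalog subset (length S).
    samples
        Ordered sample identifiers (length M).
    n_i, n_a
        Integer arrays of shape (S, M): edited / unedited read counts.
    groups
        Optional mapping sample -> group label; required for comparisons.
    """

    def __init__(
        self,
        sites: Sequence[EditingSite],
        samples: Sequence[str],
        n_i: np.ndarray,
        n_a: np.ndarray,
        groups: Mapping[str, str] | None = None,
    ) -> None:
        self.sites = list(sites)
        self.samples = list(samples)
        self.n_i = np.asarray(n_i, dtype=np.int64)
        self.n_a = np.asarray(n_a, dtype=np.int64)
        shape = (len(self.sites), len(self.samples))
        if self.n_i.shape != shape or self.n_a.shape != shape:
            raise ValidationError(
                f"count grids must have shape {shape}, got {self.n_i.shape} / {self.n_a.shape}"
            )
        if (self.n_i < 0).any() or (self.n_a < 0).any():
            raise ValidationError("negative allele counts")
        self.groups = dict(groups) if groups is not None else None
        if self.groups is not None:
            missing = [s for s in self.samples if s not in self.groups]
            if missing:
                raise ConfigurationError(f"samples without group label: {missing}")

    # ---- basic views -------------------------------------------------

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def coverage(self) -> np.ndarray:
        """Total read count n = n_I + n_A, shape (S, M)."""
        return self.n_i + self.n_a

    @property
    def efficiency(self) -> np.ndarray:
        """n_I / n with NaN where coverage is zero, shape (S, M)."""
        n = self.coverage.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            eff = np.where(n > 0, self.n_i / n, np.nan)
        return eff

    @property
    def site_ids(self) -> list[str]:
        return [s.site_id for s in self.sites]

    def allele_count(self, site_index: int, sample: str) -> AlleleCount:
        j = self.samples.index(sample)
        return AlleleCount(int(self.n_i[site_index, j]), int(self.n_a[site_index, j]))

    def group_mask(self, group: str) -> np.ndarray:
        """Boolean mask over samples belonging to ``group``."""
        if self.groups is None:
            raise ConfigurationError("profile has no group labels")
        return np.array([self.groups[s] == group for s in self.samples], dtype=bool)

    # ---- subsetting --------------------------------------------------

    def subset_sites(self, index: Sequence[int] | np.ndarray) -> "EditingProfile":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return EditingProfile(
            [self.sites[i] for i in index],
            self.samples,
            self.n_i[index, :],
            self.n_a[index, :],
            self.groups,
        )

    def subset_samples(self, samples: Sequence[str]) -> "EditingProfile":
        idx = [self.samples.index(s) for s in samples]
        groups = {s: self.groups[s] for s in samples} if self.groups is not None else None
        return EditingProfile(
            self.sites, list(samples), self.n_i[:, idx], self.n_a[:, idx], groups
        )

    def drop_sample(self, sample: str) -> "EditingProfile":
        return self.subset_samples([s for s in self.samples if s != sample])

    # ---- I/O ---------------------------------------------------------

    def counts_frame(self) -> pd.DataFrame:
        """Counts as a DataFrame in the TSV dialect (site rows, _nI/_nA column pairs)."""
        data: dict[str, np.ndarray] = {}
        for j, sample in enumerate(self.samples):
            data[f"{sample}_nI"] = self.n_i[:, j]
            data[f"{sample}_nA"] = self.n_a[:, j]
        return pd.DataFrame(data, index=pd.Index(self.site_ids, name="site"))

    def to_tsv(self, path: str | Path) -> None:
        self.counts_frame().to_csv(path, sep="\t")

    @classmethod
    def from_tsv(
        cls,
        path: str | Path,
        sites: Sequence[EditingSite] | None = None,
        groups: Mapping[str, str] | None = None,
    ) -> "EditingProfile":
        """Load a counts TSV. If ``sites`` is given, rows are matched to it by
        site id; otherwise placeholder sites are reconstructed from the ids."""
        frame = pd.read_csv(path, sep="\t", index_col=0)
        samples: list[str] = []
        for col in frame.columns:
            if col.endswith("_nI"):
                samples.append(col[: -len("_nI")])
        for s in samples:
            if f"{s}_nA" not in frame.columns:
                raise ValidationError(f"missing column {s}_nA")
        if sites is None:
            site_objs = []
            for sid in frame.index:
                chrom, pos, strand = str(sid).rsplit(":", 2)
                site_objs.append(EditingSite(chrom, int(pos), strand))
        else:
            by_id = {s.site_id: s for s in sites}
            try:
                site_objs = [by_id[str(sid)] for sid in frame.index]
            except KeyError as exc:
                raise ValidationError(f"site {exc} not present in catalog") from None
        n_i = frame[[f"{s}_nI" for s in samples]].to_numpy(dtype=np.int64)
        n_a = frame[[f"{s}_nA" for s in samples]].to_numpy(dtype=np.int64)
        return cls(site_objs, samples, n_i, n_a, groups)


def read_groups(path: str | Path) -> dict[str, str]:
    """Read a two-column ``sample  group`` TSV (header optional)."""
    groups: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValidationError(f"line {lineno}: expected 2 columns")
            if lineno == 1 and fields == ["sample", "group"]:
                continue
            groups[fields[0]] = fields[1]
    return groups


def write_groups(groups: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tgroup\n")
        for sample, group in groups.items():
            fh.write(f"{sample}\t{group}\n")
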