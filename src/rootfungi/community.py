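"""Community tables, sample metadata, depth filtering and coverage-based rarefaction.

The universal exchange object is :class:`CommunityTable`, an integer read-count
matrix with samples as rows and fungal OTUs as columns, together with
:class:`SampleMetadata` describing each sample's habitat (root vs. bulk soil),
sampling position, coordinates and — for root-tip samples — the host plant
genus.  Coverage-based rarefaction follows the sample-coverage estimator of
Chao & Jost: every sample is subsampled without replacement to the smallest
depth whose expected coverage reaches a common target (by default the minimum
full-depth coverage across samples).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "CommunityTable",
    "SampleMetadata",
    "GuildMap",
    "CommunityDataError",
    "GUILDS",
    "read_community",
    "write_community",
    "read_metadata",
    "write_metadata",
    "read_guilds",
    "filter_low_depth",
    "to_binary",
    "sample_coverage",
    "expected_coverage",
    "coverage_rarefy",
    "accumulation_curve",
]

#: Controlled vocabulary of fungal functional guilds.
GUILDS = (
    "EcMF",
    "AMF",
    "Endophyte",
    "Pathogen",
    "Mycoparasite",
    "Nematophagous",
    "Other_RAF",
    "Unassigned",
    "Unidentified",
)


class CommunityDataError(ValueError):
    """Raised when a community table or metadata file violates its invariants."""


@dataclass(frozen=True)
class CommunityTable:
    """Integer count matrix, samples x OTUs.

    Parameters
    ----------
    data : pandas.DataFrame
        Non-negative integer counts; index holds unique sample ids, columns
        unique OTU ids.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise CommunityDataError(f"duplicate sample id {dup!r}")
        if df.columns.has_duplicates:
            dup = df.columns[df.columns.duplicated()][0]
            raise CommunityDataError(f"duplicate OTU id {dup!r}")
        arr = df.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            # accept floats that are exactly integral (e.g. parsed CSV)
            if not np.all(np.isfinite(arr)) or np.any(arr != np.floor(arr)):
                r, c = np.argwhere((arr != np.floor(arr)) | ~np.isfinite(arr))[0]
                raise CommunityDataError(
                    f"non-integer count at sample {df.index[r]!r}, OTU {df.columns[c]!r}"
                )
            object.__setattr__(self, "data", df.astype(np.int64))
            arr = self.data.to_numpy()
        if arr.size and arr.min() < 0:
            r, c = np.argwhere(arr < 0)[0]
            raise CommunityDataError(
                f"negative count at sample {df.index[r]!r}, OTU {df.columns[c]!r}"
            )

    # -- basic accessors ---------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def subset_samples(self, sample_ids: Iterable[str]) -> "CommunityTable":
        return CommunityTable(self.data.loc[list(sample_ids)])

    def subset_otus(self, otu_ids: Iterable[str]) -> "CommunityTable":
        return CommunityTable(self.data.loc[:, list(otu_ids)])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CommunityTable):
            return NotImplemented
        return self.data.equals(other.data)


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample metadata: habitat kind, sampling position, coordinates, host.

    ``kind`` is ``"root"`` or ``"soil"``; every root sample carries a host
    plant genus and each position holds at most one soil sample.
    """

    data: pd.DataFrame

    REQUIRED = ("sample_id", "kind", "position_id", "x", "y", "host_plant")

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise CommunityDataError(f"metadata missing columns {missing}")
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise CommunityDataError(f"duplicate sample id {dup!r} in metadata")
        bad_kind = set(df["kind"]) - {"root", "soil"}
        if bad_kind:
            raise CommunityDataError(f"unknown sample kind(s) {sorted(bad_kind)}")
        if not np.all(np.isfinite(df[["x", "y"]].to_numpy(dtype=float))):
            raise CommunityDataError("non-finite coordinates in metadata")
        roots = df[df["kind"] == "root"]
        if roots["host_plant"].isna().any():
            sid = roots.loc[roots["host_plant"].isna(), "sample_id"].iloc[0]
            raise CommunityDataError(f"root sample {sid!r} lacks a host plant")
        soil = df[df["kind"] == "soil"]
        if soil["position_id"].duplicated().any():
            pos = soil.loc[soil["position_id"].duplicated(), "position_id"].iloc[0]
            raise CommunityDataError(f"position {pos!r} has multiple soil samples")
        object.__setattr__(self, "data", df.reset_index(drop=True))

    def loc(self, sample_ids: Iterable[str]) -> pd.DataFrame:
        idx = self.data.set_index("sample_id")
        return idx.loc[list(sample_ids)].reset_index()

    def subset(self, sample_ids: Iterable[str]) -> "SampleMetadata":
        return SampleMetadata(self.loc(sample_ids))

    @property
    def roots(self) -> pd.DataFrame:
        return self.data[self.data["kind"] == "root"].reset_index(drop=True)

    @property
    def soils(self) -> pd.DataFrame:
        return self.data[self.data["kind"] == "soil"].reset_index(drop=True)

    def positions(self) -> pd.DataFrame:
        """Unique positions with coordinates (first occurrence wins)."""
        pos = self.data.drop_duplicates("position_id")[["position_id", "x", "y"]]
        return pos.reset_index(drop=True)


class GuildMap(dict):
    """Total mapping otu_id -> functional guild (controlled vocabulary)."""

    def __init__(self, mapping: Mapping[str, str]):
        bad = {g for g in mapping.values() if g not in GUILDS}
        if bad:
            raise CommunityDataError(f"unknown guild label(s) {sorted(bad)}")
        super().__init__(mapping)

    def guild_of(self, otu_ids: Iterable[str]) -> np.ndarray:
        missing = [o for o in otu_ids if o not in self]
        if missing:
            raise CommunityDataError(f"OTUs without guild annotation: {missing[:5]}")
        return np.array([self[o] for o in otu_ids])

    def members(self, guild: str, otu_ids: Iterable[str]) -> list[str]:
        return [o for o in otu_ids if self.get(o) == guild]


# ---------------------------------------------------------------------------
# I/O (tab-separated by default, comma via dialect="comma")
# ---------------------------------------------------------------------------

_SEPS = {"tab": "\t", "comma": ","}


def read_community(path, dialect: str = "tab") -> CommunityTable:
    """Read a samples x OTUs count table (header = OTU ids, col 1 = sample ids)."""
    df = pd.read_csv(path, sep=_SEPS[dialect], index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return CommunityTable(df)


def write_community(table: CommunityTable, path, dialect: str = "tab") -> None:
    table.data.to_csv(path, sep=_SEPS[dialect], index_label="sample_id")


def read_metadata(path, dialect: str = "tab") -> SampleMetadata:
    df = pd.read_csv(path, sep=_SEPS[dialect], dtype={"sample_id": str, "position_id": str})
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path, dialect: str = "tab") -> None:
    meta.data.to_csv(path, sep=_SEPS[dialect], index=False)


def read_guilds(path, dialect: str = "tab") -> GuildMap:
    df = pd.read_csv(path, sep=_SEPS[dialect], header=0)
    return GuildMap(dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str))))


# ---------------------------------------------------------------------------
# Filtering and transforms
# ---------------------------------------------------------------------------

def filter_low_depth(table: CommunityTable, min_reads: int) -> CommunityTable:
    """Drop samples whose total read count is below ``min_reads`` (>= keeps)."""
    if min_reads < 0:
        raise ValueError("min_reads must be >= 0")
    keep = table.row_sums() >= min_reads
    if not keep.any():
        warnings.warn("depth filter removed every sample", stacklevel=2)
    return CommunityTable(table.data.loc[keep])


def to_binary(table: CommunityTable) -> CommunityTable:
    """Presence/absence (0/1) version of a count table."""
    return CommunityTable((table.data > 0).astype(np.int64))


# ---------------------------------------------------------------------------
# Sample coverage and coverage-based rarefaction
# ---------------------------------------------------------------------------

def sample_coverage(counts_row: np.ndarray) -> float:
    """Chao–Jost estimate of sample coverage for one sample's count vector.

    C = 1 - (f1/n) * [(n-1) f1 / ((n-1) f1 + 2 f2)] with n the read depth and
    f1/f2 the numbers of OTUs observed exactly once/twice.
    """
    row = np.asarray(counts_row)
    n = int(row.sum())
    if n <= 0:
        raise CommunityDataError("sample coverage undefined for an empty sample")
    f1 = int(np.sum(row == 1))
    f2 = int(np.sum(row == 2))
    if f1 == 0:
        return 1.0
    denom = (n - 1) * f1 + 2 * f2
    if denom == 0:  # n == 1 with a single singleton
        return 0.0
    return 1.0 - (f1 / n) * ((n - 1) * f1 / denom)


def expected_coverage(counts_row: np.ndarray, depth: int) -> float:
    """Expected coverage of a hypergeometric subsample of size ``depth``.

    For depth m < n the expectation has the closed form
    C(m) = 1 - sum_i (x_i/n) * C(n - x_i, m) / C(n - 1, m); at full depth the
    Chao–Jost estimator is used.  Computed in log space for numerical safety.
    """
    row = np.asarray(counts_row)
    n = int(row.sum())
    if n <= 0:
        raise CommunityDataError("coverage undefined for an empty sample")
    if depth >= n:
        return sample_coverage(row)
    if depth < 1:
        raise ValueError("depth must be >= 1")
    x = row[row > 0].astype(np.int64)
    m = depth
    # log C(n - x, m) - log C(n - 1, m); zero term when n - x < m
    ok = (n - x) >= m
    lognum = gammaln(n - x[ok] + 1) - gammaln(m + 1) - gammaln(n - x[ok] - m + 1)
    logden = gammaln(n) - gammaln(m + 1) - gammaln(n - m)
    deficit = np.sum((x[ok] / n) * np.exp(lognum - logden))
    return float(1.0 - deficit)


def _depth_for_coverage(row: np.ndarray, target: float) -> int:
    """Smallest subsampling depth whose expected coverage reaches ``target``."""
    n = int(np.asarray(row).sum())
    if target <= 0.0:
        return 1
    lo, hi = 1, n
    if expected_coverage(row, 1) >= target:
        return 1
    while lo < hi:
        mid = (lo + hi) // 2
        if expected_coverage(row, mid) >= target:
            hi = mid
        else:
            lo = mid + 1
    return lo


def coverage_rarefy(
    table: CommunityTable,
    target_coverage: float | None = None,
    seed: int | np.random.Generator = 0,
) -> CommunityTable:
    """Coverage-based rarefaction: subsample each sample (without replacement)
    to the smallest depth whose expected coverage reaches the target.

    ``target_coverage`` defaults to the minimum full-depth coverage across
    samples; samples sitting at that minimum are then returned unchanged.  A
    single hypergeometric draw per sample; reproducible for a fixed seed.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    counts = table.counts
    if counts.shape[0] == 0:
        return table
    full_cov = np.array([sample_coverage(r) for r in counts])
    at_floor = np.zeros(len(full_cov), dtype=bool)
    if target_coverage is None:
        target_coverage = float(full_cov.min())
        at_floor = full_cov <= target_coverage + 1e-12
    low = full_cov < target_coverage - 1e-12
    if low.any():
        bad = [table.sample_ids[i] for i in np.where(low)[0]]
        raise CommunityDataError(
            f"target coverage {target_coverage:.6f} exceeds full-depth coverage of {bad}"
        )
    out = np.empty_like(counts)
    for i, row in enumerate(counts):
        n = int(row.sum())
        depth = n if at_floor[i] else _depth_for_coverage(row, target_coverage)
        if depth >= n:
            out[i] = row
            continue
        out[i] = rng.multivariate_hypergeometric(row, depth)
    return CommunityTable(pd.DataFrame(out, index=table.data.index, columns=table.data.columns))


def accumulation_curve(
    table: CommunityTable, n_trials: int = 100, seed: int = 0
) -> pd.DataFrame:
    """Mean OTU richness as a function of the number of samples pooled.

    Samples are accumulated in ``n_trials`` random orders; the mean detected
    richness after 1..n samples is returned (columns ``n_samples``,
    ``mean_richness``).
    """
    rng = np.random.default_rng(seed)
    presence = table.counts > 0
    n = presence.shape[0]
    if n == 0:
        raise CommunityDataError("accumulation curve needs at least one sample")
    acc = np.zeros(n)
    for _ in range(n_trials):
        order = rng.permutation(n)
        seen = np.cumsum(presence[order], axis=0) > 0
        acc += seen.sum(axis=1)
    return pd.DataFrame(
        {"n_samples": np.arange(1, n + 1), "mean_richness": acc / n_trials}
    )
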