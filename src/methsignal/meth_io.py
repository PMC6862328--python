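"""Read/write per-cytosine methylation count data in Bismark coverage format.

A *coverage* ("COV") file has six tab-separated columns::

    chrom  start  end  methylation%  count_methylated  count_unmethylated

with 1-based inclusive coordinates and ``start == end`` for single
cytosines.  The percentage column is redundant (recomputable from the two
counts) and is ignored on input.

Samples are held as :class:`MethSample` objects wrapping a sorted,
per-site-unique :class:`pandas.DataFrame` with columns
``chrom, pos, n_mc, n_uc``.  A *reference* individual — the common origin
for all divergence measurements — is built by pooling counts of several
independent control-process samples (:func:`pool_reference`).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MethSample",
    "ReferenceSample",
    "read_cov",
    "write_cov",
    "pool_reference",
    "common_sites",
    "read_chrom_sizes",
]

COLUMNS = ["chrom", "pos", "n_mc", "n_uc"]

Group = Literal["control", "treatment", "reference"]


class CovParseError(ValueError):
    """Malformed coverage file content (carries the offending line number)."""


def _validate_records(data: pd.DataFrame, context: str = "") -> pd.DataFrame:
    """Sort by (chrom, pos), enforce uniqueness and non-negative counts."""
    if list(data.columns) != COLUMNS:
        data = data.loc[:, COLUMNS]
    data = data.astype({"chrom": object, "pos": np.int64, "n_mc": np.int64, "n_uc": np.int64})
    if len(data) == 0:
        return data.reset_index(drop=True)
    if (data["pos"] < 1).any():
        raise ValueError(f"{context}: positions must be >= 1 (1-based coordinates)")
    if (data["n_mc"] < 0).any() or (data["n_uc"] < 0).any():
        raise ValueError(f"{context}: negative read counts")
    data = data.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    dup = data.duplicated(subset=["chrom", "pos"])
    if dup.any():
        site = data.loc[dup.idxmax()]
        raise ValueError(
            f"{context}: duplicate cytosine site {site['chrom']}:{site['pos']}"
        )
    return data


@dataclass
class MethSample:
    """Per-cytosine methylated/unmethylated read counts for one individual."""

    sample_id: str
    group: Group
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.data = _validate_records(self.data, self.sample_id)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def coverage(self) -> np.ndarray:
        return (self.data["n_mc"] + self.data["n_uc"]).to_numpy()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MethSample):
            return NotImplemented
        return (
            self.sample_id == other.sample_id
            and self.group == other.group
            and self.data.equals(other.data)
        )


@dataclass(eq=False)
class ReferenceSample(MethSample):
    """Virtual individual pooled from independent control-process samples."""

    pooled_from: list[str] = field(default_factory=list)
    pooling_statistic: str = "sum"


def read_cov(
    path: str | Path,
    sample_id: str | None = None,
    group: Group = "control",
) -> MethSample:
    """Read a Bismark coverage file (optionally gzip-compressed).

    Raises :class:`CovParseError` with the 1-based line number on malformed
    lines and :class:`ValueError` on duplicate sites or negative counts.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    chroms: list[str] = []
    poss: list[int] = []
    mcs: list[int] = []
    ucs: list[int] = []
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise CovParseError(
                    f"{path}:{lineno}: expected 6 tab-separated fields, got {len(parts)}"
                )
            try:
                pos = int(parts[1])
                end = int(parts[2])
                n_mc = int(parts[4])
                n_uc = int(parts[5])
            except ValueError as exc:
                raise CovParseError(f"{path}:{lineno}: non-integer field ({exc})") from None
            if end != pos:
                raise CovParseError(
                    f"{path}:{lineno}: start != end ({pos} != {end}) for a single cytosine"
                )
            chroms.append(parts[0])
            poss.append(pos)
            mcs.append(n_mc)
            ucs.append(n_uc)
    data = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": np.asarray(poss, dtype=np.int64),
            "n_mc": np.asarray(mcs, dtype=np.int64),
            "n_uc": np.asarray(ucs, dtype=np.int64),
        }
    )
    if sample_id is None:
        name = path.name
        for suffix in (".gz", ".cov"):
            if name.endswith(suffix):
                name = name[: -len(suffix)]
        sample_id = name
    return MethSample(sample_id=sample_id, group=group, data=data)


def write_cov(sample: MethSample, path: str | Path) -> Path:
    """Write a sample as a Bismark coverage file (round-trips via read_cov).

    The methylation percentage is recomputed as ``100*n_mc/(n_mc+n_uc)``;
    zero-coverage sites are written with percentage 0.
    """
    path = Path(path)
    data = sample.data
    cov = (data["n_mc"] + data["n_uc"]).to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(cov > 0, 100.0 * data["n_mc"].to_numpy() / np.maximum(cov, 1), 0.0)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for chrom, pos, p, mc, uc in zip(
            data["chrom"], data["pos"], pct, data["n_mc"], data["n_uc"]
        ):
            fh.write(f"{chrom}\t{pos}\t{pos}\t{p:g}\t{mc}\t{uc}\n")
    return path


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5).astype(np.int64)


def pool_reference(
    samples: Sequence[MethSample],
    statistic: Literal["sum", "mean", "median"] = "sum",
    sample_id: str = "reference",
) -> ReferenceSample:
    """Pool member counts site-wise into a reference (centroid) individual.

    The site universe is the union of member sites; counts missing in a
    member are treated as 0.  ``n_mc`` and ``n_uc`` are combined separately;
    mean/median are rounded half-up to integers.
    """
    if len(samples) == 0:
        raise ValueError("pool_reference requires at least one sample")
    if statistic not in ("sum", "mean", "median"):
        raise ValueError(f"unknown pooling statistic {statistic!r}")
    frames = [s.data.set_index(["chrom", "pos"]) for s in samples]
    mc = pd.concat([f["n_mc"] for f in frames], axis=1).fillna(0)
    uc = pd.concat([f["n_uc"] for f in frames], axis=1).fillna(0)
    if statistic == "sum":
        mc_pooled = mc.sum(axis=1).astype(np.int64)
        uc_pooled = uc.sum(axis=1).astype(np.int64)
    elif statistic == "mean":
        mc_pooled = pd.Series(_round_half_up(mc.mean(axis=1).to_numpy()), index=mc.index)
        uc_pooled = pd.Series(_round_half_up(uc.mean(axis=1).to_numpy()), index=uc.index)
    else:
        mc_pooled = pd.Series(_round_half_up(mc.median(axis=1).to_numpy()), index=mc.index)
        uc_pooled = pd.Series(_round_half_up(uc.median(axis=1).to_numpy()), index=uc.index)
    data = pd.DataFrame({"n_mc": mc_pooled, "n_uc": uc_pooled}).reset_index()
    data["chrom"] = data["chrom"].astype(object)
    data["pos"] = data["pos"].astype(np.int64)
    return ReferenceSample(
        sample_id=sample_id,
        group="reference",
        data=data[COLUMNS],
        pooled_from=[s.sample_id for s in samples],
        pooling_statistic=statistic,
    )


def common_sites(samples: Sequence[MethSample], min_coverage: int = 10) -> pd.MultiIndex:
    """(chrom, pos) sites covered at >= min_coverage in *every* sample."""
    if len(samples) < 2:
        raise ValueError("common_sites requires at least two samples")
    index: pd.MultiIndex | None = None
    for s in samples:
        cov = s.data["n_mc"] + s.data["n_uc"]
        keep = s.data.loc[cov >= min_coverage, ["chrom", "pos"]]
        idx = pd.MultiIndex.from_frame(keep)
        index = idx if index is None else index.intersection(idx)
    assert index is not None
    return index.sortlevel([0, 1])[0]


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a two-column TSV of (chrom, length) into a dict."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated fields")
            sizes[parts[0]] = int(parts[1])
    return sizes
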