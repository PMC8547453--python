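"""Per-base depth extraction, fixed-width coverage binning, and contig filters.

Coverage profiles are the substrate of replication-rate inference: read depth
along a bacterial contig carries the replication gradient (higher coverage
near the origin of replication in growing populations).  Depth is computed
from coordinate-sorted alignments or read from a 3-column TSV, averaged into
100-bp bins (0-based half-open ``[k*w, (k+1)*w)`` internally; a trailing
partial bin is dropped so edge bins never carry a downward-biased mean), and
contigs are admitted to inference only when long enough (>= 11,000 bp) and
covered deeply enough (mean >= 2x).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "BinnedCoverage",
    "depth_from_alignment",
    "read_depth_table",
    "bin_coverage",
    "filter_contigs",
    "read_binned_tsv",
    "write_binned_tsv",
]

#: exclusion reason codes used by :func:`filter_contigs`
REASON_SHORT = "length_below_minimum"
REASON_LOW_COVERAGE = "mean_coverage_below_minimum"


@dataclass
class BinnedCoverage:
    """Ordered per-bin mean read depth along one contig."""

    contig_id: str
    contig_length: int
    bin_width: int
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = self.contig_length // self.bin_width
        if len(self.values) != expected:
            raise ValueError(
                f"{self.contig_id}: expected {expected} bins for length "
                f"{self.contig_length} at width {self.bin_width}, "
                f"got {len(self.values)}"
            )
        if np.any(self.values < 0):
            raise ValueError(f"{self.contig_id}: negative bin coverage")

    @property
    def mean_coverage(self) -> float:
        return float(np.mean(self.values)) if len(self.values) else 0.0


def depth_from_alignment(
    alignment_file: str | Path, min_mapq: int = 0
) -> dict[str, pd.DataFrame]:
    """Per-base depth from a SAM/BAM file, one DepthTable per contig.

    Depth at a base is the number of primary, non-supplementary, mapped reads
    whose alignment span (reference start to end) covers that base and whose
    mapping quality is at least ``min_mapq``.  Positions are reported 1-based;
    zero-depth positions are omitted.

    Returns a mapping ``contig_id -> DataFrame(contig_id, position, depth)``
    covering every contig in the header (contigs with no reads map to empty
    tables).
    """
    import pysam

    path = Path(alignment_file)
    if not path.exists():
        raise IOError(f"alignment file not found: {path}")
    mode = "rb" if path.suffix == ".bam" else "r"
    with pysam.AlignmentFile(str(path), mode) as af:
        lengths: dict[str, int] = dict(zip(af.references, af.lengths))
        counts = {name: np.zeros(length, dtype=np.int64) for name, length in lengths.items()}
        for read in af:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.mapping_quality < min_mapq:
                continue
            name = read.reference_name
            if name not in counts:
                raise ValueError(f"contig {name!r} absent from header")
            start = read.reference_start
            end = read.reference_end
            if end is None:
                continue
            counts[name][start:end] += 1
    tables: dict[str, pd.DataFrame] = {}
    for name, arr in counts.items():
        pos = np.nonzero(arr)[0]
        tables[name] = pd.DataFrame(
            {"contig_id": name, "position": pos + 1, "depth": arr[pos]}
        )
    return tables


def read_depth_table(path: str | Path) -> dict[str, pd.DataFrame]:
    """Read a 3-column depth TSV (contig, 1-based position, depth)."""
    df = pd.read_csv(
        path, sep="\t", names=["contig_id", "position", "depth"], comment="#"
    )
    if df["position"].min() < 1:
        raise ValueError("depth table positions must be 1-based (>= 1)")
    if (df["depth"] < 0).any():
        raise ValueError("depth table contains negative depths")
    return {str(cid): sub for cid, sub in df.groupby("contig_id", sort=False)}


def bin_coverage(
    depth: pd.DataFrame, contig_length: int, bin_width: int = 100
) -> BinnedCoverage:
    """Average per-base depth into fixed-width bins.

    ``depth`` is a DepthTable for a single contig (columns ``contig_id``,
    ``position`` 1-based, ``depth``); positions absent from the table count as
    zero.  Bin k averages bases ``[k*w, (k+1)*w)`` (0-based); a trailing
    partial bin is dropped.
    """
    if bin_width < 1:
        raise ValueError(f"bin_width must be >= 1, got {bin_width}")
    if contig_length < bin_width:
        raise ValueError(
            f"contig length {contig_length} is shorter than one bin "
            f"({bin_width} bp)"
        )
    n_bins = contig_length // bin_width
    contig_ids = depth["contig_id"].unique() if len(depth) else []
    if len(contig_ids) > 1:
        raise ValueError(f"depth table mixes contigs: {list(contig_ids)}")
    contig_id = str(contig_ids[0]) if len(contig_ids) else ""

    per_base = np.zeros(n_bins * bin_width, dtype=float)
    if len(depth):
        pos = depth["position"].to_numpy(dtype=np.int64) - 1  # to 0-based
        if np.any(pos >= contig_length):
            raise ValueError("depth position beyond contig length")
        keep = pos < n_bins * bin_width
        per_base[pos[keep]] = depth["depth"].to_numpy(dtype=float)[keep]
    values = per_base.reshape(n_bins, bin_width).mean(axis=1)
    return BinnedCoverage(contig_id, contig_length, bin_width, values)


def filter_contigs(
    profiles: Iterable[BinnedCoverage],
    min_profile_length: int = 5_000,
    min_irep_length: int = 11_000,
    min_mean_cov: float = 2.0,
) -> tuple[list[BinnedCoverage], pd.DataFrame]:
    """Apply contig eligibility rules for replication inference.

    A contig is eligible iff ``contig_length >= min_irep_length`` and mean
    binned coverage ``>= min_mean_cov`` (both inclusive).  Profiles shorter
    than ``min_profile_length`` should not normally be built at all; they are
    rejected here with the length reason as well.

    Returns ``(eligible_profiles, exclusion_log)`` where the log has columns
    ``contig_id, contig_length, mean_coverage, reason`` listing every excluded
    contig with the first threshold it failed.
    """
    eligible: list[BinnedCoverage] = []
    rows: list[dict] = []
    for prof in profiles:
        if prof.contig_length < min_irep_length:
            reason = REASON_SHORT
        elif prof.mean_coverage < min_mean_cov:
            reason = REASON_LOW_COVERAGE
        else:
            eligible.append(prof)
            continue
        rows.append(
            {
                "contig_id": prof.contig_id,
                "contig_length": prof.contig_length,
                "mean_coverage": prof.mean_coverage,
                "reason": reason,
            }
        )
    log = pd.DataFrame(
        rows, columns=["contig_id", "contig_length", "mean_coverage", "reason"]
    )
    return eligible, log


def write_binned_tsv(
    profiles: Iterable[BinnedCoverage], path: str | Path
) -> None:
    """Emit binned coverage as TSV: contig_id, bin_index, mean_depth.

    Contig length and bin width are recorded in ``#`` header lines so the
    table round-trips through :func:`read_binned_tsv`.
    """
    profiles = list(profiles)
    with open(path, "w") as fh:
        for prof in profiles:
            fh.write(
                f"#contig\t{prof.contig_id}\t{prof.contig_length}\t{prof.bin_width}\n"
            )
        fh.write("contig_id\tbin_index\tmean_depth\n")
        for prof in profiles:
            for k, v in enumerate(prof.values):
                fh.write(f"{prof.contig_id}\t{k}\t{v:.6g}\n")


def read_binned_tsv(path: str | Path) -> list[BinnedCoverage]:
    """Read the binned-coverage TSV written by :func:`write_binned_tsv`."""
    meta: dict[str, tuple[int, int]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#contig\t"):
                break
            _, cid, length, width = line.rstrip("\n").split("\t")
            meta[cid] = (int(length), int(width))
    df = pd.read_csv(path, sep="\t", comment="#")
    profiles = []
    for cid, sub in df.groupby("contig_id", sort=False):
        cid = str(cid)
        values = sub.sort_values("bin_index")["mean_depth"].to_numpy()
        if cid in meta:
            length, width = meta[cid]
        else:  # fall back: assume default width, exact multiple
            width = 100
            length = width * len(values)
        profiles.append(BinnedCoverage(cid, length, width, values))
    return profiles
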