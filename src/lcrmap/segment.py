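"""Threshold segmentation, size filtering, soft masking, and the mapper pipeline.

The mapper turns each record into regions in three steps: bidirectional
minimum profile → moving-average smoothing → extraction of maximal runs of
positions *strictly below* the threshold T, discarding runs shorter than the
minimum size s. The default threshold is log₂|Θ|/2 — half the bits of an
incompressible symbol.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Optional, Union

import numpy as np

from .alphabet import Alphabet, detect_alphabet
from .models import CompressorConfig
from .profile import ComplexityProfile, bidirectional_min_profile, smooth_profile
from .seqio import SequenceRecord


@dataclass
class Region:
    """1-based inclusive low-complexity interval on a named sequence."""

    seq_id: str
    start: int
    end: int
    track: str = "lcr"
    mean_bits: float = math.nan

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid region [{self.start}, {self.end}]")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, start: int, end: int) -> bool:
        return self.start <= end and start <= self.end


@dataclass
class MapperParams:
    """Full parameter set of one mapper run.

    ``threshold=None`` resolves to the default log₂|Θ|/2 from the detected
    alphabet. ``join_gap`` optionally merges runs separated by at most that
    many positions before the size filter (off by default).
    """

    config: CompressorConfig
    window: int = 10
    threshold: Optional[float] = None
    min_size: int = 1
    join_gap: int = 0
    track: str = "lcr"

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError(f"window must be >= 1, got {self.window}")
        if self.threshold is not None and self.threshold <= 0:
            raise ValueError(f"threshold must be > 0, got {self.threshold}")
        if self.min_size < 1:
            raise ValueError(f"min size must be >= 1, got {self.min_size}")
        if self.join_gap < 0:
            raise ValueError(f"join gap must be >= 0, got {self.join_gap}")


def default_threshold(alphabet_size: int) -> float:
    """Default segmentation threshold: log₂(|Θ|)/2."""
    if alphabet_size < 2:
        raise ValueError(f"alphabet size must be >= 2, got {alphabet_size}")
    return math.log2(alphabet_size) / 2.0


def segment_regions(
    smoothed: ComplexityProfile,
    threshold: float,
    min_size: int = 1,
    join_gap: int = 0,
    track: str = "lcr",
) -> List[Region]:
    """Maximal runs strictly below the threshold, size-filtered and sorted.

    ``join_gap`` > 0 first merges runs separated by at most that many
    positions; the size filter applies afterwards and filtered runs are not
    merged into neighbours.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be > 0, got {threshold}")
    if min_size < 1:
        raise ValueError(f"min size must be >= 1, got {min_size}")
    values = smoothed.values
    below = values < threshold
    runs: List[List[int]] = []
    start = None
    for i, flag in enumerate(below):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append([start, i - 1])
            start = None
    if start is not None:
        runs.append([start, len(values) - 1])
    if join_gap > 0 and runs:
        merged = [runs[0]]
        for run in runs[1:]:
            if run[0] - merged[-1][1] - 1 <= join_gap:
                merged[-1][1] = run[1]
            else:
                merged.append(run)
        runs = merged
    regions = []
    for lo, hi in runs:
        if hi - lo + 1 < min_size:
            continue
        regions.append(
            Region(
                smoothed.seq_id,
                lo + 1,
                hi + 1,
                track=track,
                mean_bits=float(values[lo:hi + 1].mean()),
            )
        )
    return regions


def map_lcrs(
    records: Iterable[SequenceRecord],
    params: MapperParams,
    alphabet: Optional[Alphabet] = None,
    concatenate: bool = False,
) -> List[Region]:
    """Map low-complexity regions of every record.

    By default each record is mapped independently (model state is reset per
    record and per direction); regions carry the record id and the params'
    track label. With ``concatenate`` the records are mapped as one
    concatenated sequence — so repeats *shared between* records are found —
    separated by sentinel runs of k ambiguity symbols that break contexts at
    the joins; region coordinates are re-projected into the originating
    records.
    """
    if concatenate:
        return _map_concatenated(list(records), params, alphabet)
    regions: List[Region] = []
    for record in records:
        if record.length == 0:
            continue
        rec_alphabet = alphabet if alphabet is not None else detect_alphabet(record.sequence)
        threshold = (
            params.threshold
            if params.threshold is not None
            else default_threshold(rec_alphabet.size)
        )
        profile = bidirectional_min_profile(record, params.config, rec_alphabet)
        smoothed = smooth_profile(profile, params.window)
        regions.extend(
            segment_regions(
                smoothed,
                threshold,
                min_size=params.min_size,
                join_gap=params.join_gap,
                track=params.track,
            )
        )
    return regions


def _map_concatenated(
    records: List[SequenceRecord],
    params: MapperParams,
    alphabet: Optional[Alphabet],
) -> List[Region]:
    records = [r for r in records if r.length > 0]
    if not records:
        return []
    if alphabet is None:
        alphabet = detect_alphabet("".join(r.sequence for r in records))
    threshold = (
        params.threshold
        if params.threshold is not None
        else default_threshold(alphabet.size)
    )
    kmax = max(m.order for m in params.config.models)
    sentinel_symbol = next(s for s in "N?X!" if s not in alphabet)
    sentinel = sentinel_symbol * kmax
    spans = []  # (record, 1-based start, end) in concatenated coordinates
    pieces = []
    position = 0
    for record in records:
        if pieces:
            pieces.append(sentinel)
            position += kmax
        pieces.append(record.sequence)
        spans.append((record, position + 1, position + record.length))
        position += record.length
    merged = SequenceRecord("<concat>", "".join(pieces))
    profile = bidirectional_min_profile(merged, params.config, alphabet)
    smoothed = smooth_profile(profile, params.window)
    raw = segment_regions(
        smoothed, threshold, min_size=params.min_size,
        join_gap=params.join_gap, track=params.track,
    )
    regions: List[Region] = []
    for region in raw:
        for record, lo, hi in spans:
            start = max(region.start, lo)
            end = min(region.end, hi)
            if start > end or end - start + 1 < params.min_size:
                continue
            regions.append(
                Region(
                    record.id,
                    start - lo + 1,
                    end - lo + 1,
                    track=params.track,
                    mean_bits=float(smoothed.values[start - 1:end].mean()),
                )
            )
    regions.sort(key=lambda r: ([rec.id for rec, _, _ in spans].index(r.seq_id), r.start))
    return regions


def soft_mask(record: SequenceRecord, regions: Iterable[Region]) -> SequenceRecord:
    """Lowercase exactly the union of region positions of this record.

    Uppercasing the result restores the original sequence.
    """
    chars = list(record.sequence)
    for region in regions:
        if region.seq_id != record.id:
            continue
        if region.end > record.length:
            raise ValueError(
                f"region [{region.start}, {region.end}] exceeds {record.id} "
                f"length {record.length}"
            )
        for i in range(region.start - 1, region.end):
            chars[i] = chars[i].lower()
    return SequenceRecord(record.id, "".join(chars), record.description)


def write_bed(regions: Iterable[Region], path_or_handle) -> None:
    """BED-like TSV: seq_id, start−1 (0-based), end, track, mean_bits."""

    def _emit(handle) -> None:
        for r in regions:
            handle.write(f"{r.seq_id}\t{r.start - 1}\t{r.end}\t{r.track}\t{r.mean_bits:.4f}\n")

    if hasattr(path_or_handle, "write"):
        _emit(path_or_handle)
    else:
        with open(path_or_handle, "w") as handle:
            _emit(handle)


def read_bed(path: Union[str, Path], track: Optional[str] = None) -> List[Region]:
    """Read a BED-like file back into 1-based inclusive regions."""
    regions = []
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ValueError(f"{path}: malformed BED line: {line!r}")
            name = cols[3] if len(cols) > 3 else "lcr"
            bits = float(cols[4]) if len(cols) > 4 else math.nan
            regions.append(
                Region(
                    cols[0],
                    int(cols[1]) + 1,
                    int(cols[2]),
                    track=track if track is not None else name,
                    mean_bits=bits,
                )
            )
    return regions
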