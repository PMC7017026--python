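"""The discovery core: quality filtering, windowed heterozygous-SNP density,
segment calling, artifact triage, and variant-devoid gap detection.

On an inbred (reference-strain) background, a donor-derived introgressed
segment announces itself as a dense run of *heterozygous non-reference* SNP
calls.  The scan therefore: (1) removes calls that failed the caller's status
check or fall below a mapping-quality threshold, (2) keeps heterozygous
calls, (3) counts them in fixed non-overlapping windows (default 1 Mb,
grid anchored at bp 1), (4) calls maximal runs of above-threshold windows as
segments — bridging short below-threshold stretches so that the
reference-homozygous blocks and variant-devoid gaps of a backcross mosaic do
not split the region — and (5) triages short runs as artifact candidates.

The model/results pair (:class:`IntrogressionScan` / fit ->
:class:`IntrogressionScanResult`) wraps these steps; each step is also
exposed as a standalone function.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import GenomicSegment, read_vcf

__all__ = [
    "ScanParams",
    "FilterReport",
    "WindowDensityTrack",
    "DevoidGap",
    "apply_quality_filters",
    "select_het_nonref",
    "window_density",
    "call_segments",
    "flag_artifact_clusters",
    "find_devoid_gaps",
    "annotate_intervals",
    "IntrogressionScan",
    "IntrogressionScanResult",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScanParams:
    """Tunable parameters of the region scan.

    mq_threshold
        Calls with mapping quality strictly below this score are removed
        (default 200; missing scores never pass).
    window_size
        Density window in bp (default 1 Mb).
    min_snps_per_window
        Minimum heterozygous calls for a window to count as part of a
        significant cluster (default 5 — small enough to keep true
        introgression windows, large enough to exclude error-scale clusters
        of a ~13x depth call set).
    max_gap_windows
        Number of consecutive below-threshold windows bridged within one
        segment (default 5: a backcross mosaic legitimately contains
        reference-homozygous blocks and multi-Mb variant-devoid stretches
        that must not split the region).
    min_segment_windows
        Runs spanning fewer windows than this are classified
        ``artifact_candidate`` (default 3).
    """

    mq_threshold: float = 200.0
    window_size: int = 1_000_000
    min_snps_per_window: int = 5
    max_gap_windows: int = 5
    min_segment_windows: int = 3

    def __post_init__(self) -> None:
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")
        for name in ("mq_threshold", "min_snps_per_window", "max_gap_windows",
                     "min_segment_windows"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class FilterReport:
    """Counts removed by each quality criterion (non-exclusive)."""

    n_input: int
    n_failed_status: int
    n_low_mq: int
    n_removed: int
    n_retained: int


def apply_quality_filters(
    calls: pd.DataFrame, params: ScanParams | None = None
) -> tuple[pd.DataFrame, FilterReport]:
    """Remove calls that failed the caller status check or have MQ below threshold.

    A call is retained iff ``status_pass`` is True AND
    ``mapping_quality >= mq_threshold``.  NaN mapping qualities never pass.
    Returns the retained calls plus per-criterion removal counts.
    """
    params = params or ScanParams()
    status_ok = calls["status_pass"].to_numpy(dtype=bool)
    mq = calls["mapping_quality"].to_numpy(dtype=float)
    mq_ok = mq >= params.mq_threshold  # NaN compares False
    keep = status_ok & mq_ok
    report = FilterReport(
        n_input=len(calls),
        n_failed_status=int((~status_ok).sum()),
        n_low_mq=int((~mq_ok).sum()),
        n_removed=int((~keep).sum()),
        n_retained=int(keep.sum()),
    )
    return calls[keep].reset_index(drop=True), report


def select_het_nonref(calls: pd.DataFrame) -> pd.DataFrame:
    """Keep heterozygous non-reference calls only (idempotent projection)."""
    return calls[calls["genotype"] == "het"].reset_index(drop=True)


@dataclass
class WindowDensityTrack:
    """Per-window SNP counts on one chromosome.

    Window ``i`` (0-based) covers bp ``[i*w + 1, (i+1)*w]`` on the fixed grid
    anchored at bp 1; the last window may be partial.  Optional aligned
    private/shared splits must sum to ``counts``.
    """

    chromosome: str
    window_size: int
    counts: np.ndarray
    private_counts: np.ndarray | None = None
    shared_counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.private_counts is not None:
            self.private_counts = np.asarray(self.private_counts, dtype=np.int64)
            self.shared_counts = np.asarray(self.shared_counts, dtype=np.int64)
            if not np.array_equal(
                self.private_counts + self.shared_counts, self.counts
            ):
                raise ValueError("private + shared counts must equal total counts")

    @property
    def n_windows(self) -> int:
        return len(self.counts)

    def window_start(self, i: int) -> int:
        """1-based start position of window i."""
        return i * self.window_size + 1

    def to_frame(self, chromosome_length: int | None = None) -> pd.DataFrame:
        """Tidy per-window table (0-based half-open coordinates, track style)."""
        w = self.window_size
        starts = np.arange(self.n_windows, dtype=np.int64) * w
        ends = starts + w
        if chromosome_length is not None:
            ends = np.minimum(ends, chromosome_length)
        out = pd.DataFrame(
            {
                "chromosome": self.chromosome,
                "start": starts,
                "end": ends,
                "count": self.counts,
            }
        )
        if self.private_counts is not None:
            out["private_count"] = self.private_counts
            out["shared_count"] = self.shared_counts
        return out


def window_density(
    calls: pd.DataFrame,
    chromosome: str,
    chromosome_length: int,
    params: ScanParams | None = None,
    labels: Sequence[str] | None = None,
) -> WindowDensityTrack:
    """Count calls per fixed window on one chromosome.

    ``labels``, when given, is an aligned per-call sequence of
    ``private``/``shared`` labels used to populate the track's class split.

    Raises
    ------
    ValueError
        If any call position exceeds ``chromosome_length`` (or is < 1).
    """
    params = params or ScanParams()
    w = params.window_size
    mask = (calls["chromosome"] == chromosome).to_numpy()
    pos = calls["position"].to_numpy(dtype=np.int64)[mask]
    if len(pos) and (pos.max() > chromosome_length or pos.min() < 1):
        bad = pos[(pos > chromosome_length) | (pos < 1)][0]
        raise ValueError(
            f"position {bad} outside chromosome {chromosome} "
            f"(length {chromosome_length})"
        )
    n_windows = -(-int(chromosome_length) // w)  # ceil; last partial included
    idx = (pos - 1) // w
    counts = np.bincount(idx, minlength=n_windows).astype(np.int64)
    private = shared = None
    if labels is not None:
        lab = np.asarray(labels, dtype=object)[mask]
        private = np.bincount(idx[lab == "private"], minlength=n_windows).astype(np.int64)
        shared = np.bincount(idx[lab == "shared"], minlength=n_windows).astype(np.int64)
    return WindowDensityTrack(
        chromosome=chromosome,
        window_size=w,
        counts=counts,
        private_counts=private,
        shared_counts=shared,
    )


def call_segments(
    track: WindowDensityTrack,
    params: ScanParams | None = None,
    positions: Sequence[int] | np.ndarray | None = None,
) -> list[GenomicSegment]:
    """Call segments as maximal runs of above-threshold windows.

    A run extends over windows with ``count >= min_snps_per_window``, allowing
    up to ``max_gap_windows`` consecutive below-threshold windows inside it.
    When the supporting call ``positions`` are supplied, segment boundaries
    are trimmed to the first/last supporting SNP inside the run's window
    span (sub-window resolution); otherwise window edges are used.  Runs
    spanning fewer than ``min_segment_windows`` windows are classified
    ``artifact_candidate``.
    """
    params = params or ScanParams()
    w = track.window_size
    above = np.flatnonzero(track.counts >= params.min_snps_per_window)
    if above.size == 0:
        return []
    if positions is not None:
        positions = np.sort(np.asarray(positions, dtype=np.int64))

    runs: list[tuple[int, int]] = []
    run_start = prev = int(above[0])
    for i in above[1:]:
        i = int(i)
        if i - prev - 1 > params.max_gap_windows:
            runs.append((run_start, prev))
            run_start = i
        prev = i
    runs.append((run_start, prev))

    segments: list[GenomicSegment] = []
    for a, b in runs:
        lo, hi = a * w + 1, (b + 1) * w  # 1-based inclusive window span
        n_windows = b - a + 1
        classification = (
            "introgressed" if n_windows >= params.min_segment_windows
            else "artifact_candidate"
        )
        if positions is not None:
            inside = positions[(positions >= lo) & (positions <= hi)]
            if inside.size == 0:  # inconsistent inputs; keep window edges
                start, end, n_snps = lo, hi, int(track.counts[a : b + 1].sum())
            else:
                start, end = int(inside[0]), int(inside[-1])
                n_snps = int(inside.size)
        else:
            start, end = lo, hi
            n_snps = int(track.counts[a : b + 1].sum())
        segments.append(
            GenomicSegment(
                chromosome=track.chromosome,
                start=start,
                end=end,
                n_supporting_snps=n_snps,
                classification=classification,
            )
        )
    return segments


def flag_artifact_clusters(
    segments: Sequence[GenomicSegment], calls: pd.DataFrame
) -> list[GenomicSegment]:
    """Annotate segments with the mean mapping quality of their calls.

    Artifact candidates carry the annotation for triage reporting (small,
    isolated, quality-suspect clusters); introgressed segments are annotated
    identically for symmetry.
    """
    out: list[GenomicSegment] = []
    for seg in segments:
        mask = (
            (calls["chromosome"] == seg.chromosome)
            & (calls["position"] >= seg.start)
            & (calls["position"] <= seg.end)
        )
        mq = calls.loc[mask, "mapping_quality"]
        mean_mq = float(mq.mean()) if len(mq) else None
        out.append(seg.annotated(mean_mapping_quality=mean_mq))
    return out


@dataclass(frozen=True)
class DevoidGap:
    """A variant-devoid interval (1-based inclusive) inside a segment."""

    chromosome: str
    start: int
    end: int

    @property
    def width(self) -> int:
        return self.end - self.start + 1

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end


def find_devoid_gaps(
    segment: GenomicSegment,
    calls: pd.DataFrame,
    min_gap_bp: int = 1_000_000,
) -> list[DevoidGap]:
    """Maximal call-free intervals of width >= ``min_gap_bp`` inside a segment.

    Gaps are measured between consecutive heterozygous calls (and against
    the segment edges) and returned sorted by width descending, ties by
    start position.
    """
    mask = (
        (calls["chromosome"] == segment.chromosome)
        & (calls["position"] >= segment.start)
        & (calls["position"] <= segment.end)
    )
    pos = np.sort(calls.loc[mask, "position"].to_numpy(dtype=np.int64))
    bounds = np.concatenate(([segment.start - 1], pos, [segment.end + 1]))
    gaps = [
        DevoidGap(segment.chromosome, int(p) + 1, int(q) - 1)
        for p, q in zip(bounds[:-1], bounds[1:])
        if q - p - 1 >= min_gap_bp
    ]
    return sorted(gaps, key=lambda g: (-g.width, g.start))


def annotate_intervals(
    segments: Sequence[GenomicSegment],
    features: pd.DataFrame,
    devoid_gaps: Sequence[DevoidGap] = (),
) -> pd.DataFrame:
    """Overlap report of features (BED convention) against segments and gaps.

    ``features`` needs columns ``chromosome, start, end`` (0-based half-open)
    and optionally ``name``.  A feature *overlaps* a segment if the intervals
    intersect by at least one bp; it is *in a gap* if wholly contained in a
    devoid gap.  Both inputs must share the assembly and naming convention —
    a mismatch is not detectable here.
    """
    rows = []
    for r in features.itertuples(index=False):
        fs, fe = int(r.start) + 1, int(r.end)  # to 1-based inclusive
        chrom = str(r.chromosome)
        hits = [
            s for s in segments
            if s.chromosome == chrom and fs <= s.end and s.start <= fe
        ]
        in_gap = any(
            g.chromosome == chrom and g.start <= fs and fe <= g.end
            for g in devoid_gaps
        )
        rows.append(
            (
                getattr(r, "name", None) or f"{chrom}:{r.start}-{r.end}",
                chrom,
                int(r.start),
                int(r.end),
                bool(hits),
                hits[0].classification if hits else "",
                in_gap,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "name", "chromosome", "start", "end",
            "overlaps_segment", "segment_classification", "in_devoid_gap",
        ],
    )


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------


class IntrogressionScan:
    """Genome scan model for introgressed-segment discovery.

    Parameters
    ----------
    calls
        Canonical call frame (see :mod:`introscan.io`); typically the full
        call set of one congenic individual.
    chromosome_lengths
        Mapping chromosome label -> length in bp; defines the window grids.
    params
        :class:`ScanParams`; defaults used when omitted.

    Examples
    --------
    >>> scan = IntrogressionScan(calls, {"13": 120_421_639})
    >>> result = scan.fit()
    >>> result.largest_segment()          # doctest: +SKIP
    GenomicSegment(chromosome='13', start=..., classification='introgressed')
    """

    def __init__(
        self,
        calls: pd.DataFrame,
        chromosome_lengths: Mapping[str, int],
        params: ScanParams | None = None,
    ) -> None:
        self.calls = calls
        self.chromosome_lengths = dict(chromosome_lengths)
        self.params = params or ScanParams()

    @classmethod
    def from_vcf(
        cls,
        path,
        chromosome_lengths: Mapping[str, int],
        params: ScanParams | None = None,
        region: str | None = None,
    ) -> "IntrogressionScan":
        return cls(read_vcf(path, region=region), chromosome_lengths, params)

    def fit(self) -> "IntrogressionScanResult":
        """Run filter -> het selection -> density -> segments -> triage."""
        filtered, report = apply_quality_filters(self.calls, self.params)
        het = select_het_nonref(filtered)
        if het.empty:
            log.warning("no heterozygous calls survive filtering; empty scan result")
        tracks: dict[str, WindowDensityTrack] = {}
        segments: list[GenomicSegment] = []
        for chrom, length in self.chromosome_lengths.items():
            track = window_density(het, chrom, length, self.params)
            tracks[chrom] = track
            pos = het.loc[het["chromosome"] == chrom, "position"].to_numpy()
            segments.extend(call_segments(track, self.params, positions=pos))
        segments = flag_artifact_clusters(segments, het)
        return IntrogressionScanResult(
            params=self.params,
            chromosome_lengths=self.chromosome_lengths,
            filter_report=report,
            het_calls=het,
            tracks=tracks,
            segments=segments,
        )


@dataclass
class IntrogressionScanResult:
    """Fitted scan: filtered calls, density tracks, called segments."""

    params: ScanParams
    chromosome_lengths: dict[str, int]
    filter_report: FilterReport
    het_calls: pd.DataFrame
    tracks: dict[str, WindowDensityTrack]
    segments: list[GenomicSegment]

    def introgressed_segments(self) -> list[GenomicSegment]:
        return [s for s in self.segments if s.classification == "introgressed"]

    def artifact_candidates(self) -> list[GenomicSegment]:
        return [s for s in self.segments if s.classification == "artifact_candidate"]

    def largest_segment(self) -> GenomicSegment | None:
        """The longest introgressed segment, or None if nothing was called."""
        intro = self.introgressed_segments()
        if not intro:
            return None
        return max(intro, key=lambda s: (s.length, -s.start))

    def devoid_gaps(
        self,
        min_gap_bp: int = 1_000_000,
        segment: GenomicSegment | None = None,
    ) -> list[DevoidGap]:
        """Variant-devoid gaps inside ``segment`` (default: largest segment)."""
        seg = segment or self.largest_segment()
        if seg is None:
            return []
        return find_devoid_gaps(seg, self.het_calls, min_gap_bp)

    def track_frame(self) -> pd.DataFrame:
        """All density tracks as one tidy table."""
        frames = [
            t.to_frame(self.chromosome_lengths.get(c))
            for c, t in self.tracks.items()
        ]
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
            columns=["chromosome", "start", "end", "count"]
        )

    def segment_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "chromosome": s.chromosome,
                    "start": s.start,
                    "end": s.end,
                    "length_bp": s.length,
                    "n_supporting_snps": s.n_supporting_snps,
                    "classification": s.classification,
                    "mean_mapping_quality": s.mean_mapping_quality,
                }
                for s in sorted(
                    self.segments, key=lambda s: (s.chromosome, s.start)
                )
            ]
        )

    def summary(self) -> str:
        """Human-readable account of the fitted scan."""
        fr = self.filter_report
        lines = [
            "Introgression scan",
            "==================",
            f"input calls:            {fr.n_input}",
            f"  failed status check:  {fr.n_failed_status}",
            f"  mapping quality < {self.params.mq_threshold:g}: {fr.n_low_mq}",
            f"  removed (either):     {fr.n_removed}",
            f"retained calls:         {fr.n_retained}",
            f"heterozygous non-ref:   {len(self.het_calls)}",
            f"window size:            {self.params.window_size} bp",
            "",
            f"segments called:        {len(self.segments)} "
            f"({len(self.introgressed_segments())} introgressed, "
            f"{len(self.artifact_candidates())} artifact candidates)",
        ]
        top = self.largest_segment()
        if top is not None:
            lines.append(
                f"largest introgressed:   {top.chromosome}:{top.start}-{top.end} "
                f"({top.length / 1e6:.1f} Mb, {top.n_supporting_snps} SNPs)"
            )
        return "\n".join(lines)
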