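"""Fragment-density tracks and two-stage between-species normalization.

Binding signal is estimated by extending each mapped sequence tag to the
library's average fragment length and accumulating per-base coverage.
Normalization proceeds in two steps: (1) per-library scaling of the total
tag count to a fixed target, and (2) a comparative step that scales one
genome's signal so that binding strength over the most highly bound peaks
near known developmental target genes agrees between species, via
least-squares regression through the origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TagSet",
    "SignalTrack",
    "NormalizationResult",
    "read_tags_bed",
    "fragment_density",
    "libsize_normalize",
    "comparative_scale",
    "select_anchor_pairs",
    "track_correlation",
]

DEFAULT_TARGET_TAGS = 10_000_000


@dataclass
class TagSet:
    """Mapped tag 5' positions for one experiment.

    ``tags`` columns: chrom, pos (5' end, 0-based), strand ('+'/'-').
    """

    genome_label: str
    factor_label: str
    fragment_length: int
    tags: pd.DataFrame

    def __post_init__(self):
        if self.fragment_length <= 0:
            raise ValueError("fragment_length must be positive")

    @property
    def n_tags(self) -> int:
        return len(self.tags)


@dataclass
class SignalTrack:
    """Per-base fragment coverage for one genome, arbitrary units."""

    genome_label: str
    data: dict[str, np.ndarray]
    scale_history: list[float] = field(default_factory=list)

    def max_in(self, chrom: str, start: int, end: int) -> float:
        arr = self.data[chrom]
        start = max(0, start)
        end = min(len(arr), end)
        if end <= start:
            return 0.0
        return float(arr[start:end].max())

    def argmax_in(self, chrom: str, start: int, end: int) -> int:
        """Leftmost position of the maximum density within [start, end)."""
        arr = self.data[chrom]
        start = max(0, start)
        end = min(len(arr), end)
        if end <= start:
            raise ValueError("empty interval")
        return start + int(np.argmax(arr[start:end]))

    def scaled(self, factor: float) -> "SignalTrack":
        if not np.isfinite(factor) or factor <= 0:
            raise ValueError("scale factor must be positive and finite")
        return SignalTrack(
            self.genome_label,
            {c: a * factor for c, a in self.data.items()},
            self.scale_history + [float(factor)],
        )

    def total(self) -> float:
        return float(sum(a.sum() for a in self.data.values()))

    def to_bedgraph(self, path, header: str | None = None):
        """Run-length-encoded bedGraph export (zero runs omitted)."""
        with open(path, "w") as fh:
            if header:
                for line in header.splitlines():
                    fh.write(f"# {line}\n")
            for chrom in sorted(self.data):
                arr = self.data[chrom]
                if arr.size == 0:
                    continue
                change = np.flatnonzero(np.diff(arr) != 0)
                starts = np.concatenate(([0], change + 1))
                ends = np.concatenate((change + 1, [arr.size]))
                for s, e in zip(starts, ends):
                    v = arr[s]
                    if v != 0:
                        fh.write(f"{chrom}\t{s}\t{e}\t{v:.10g}\n")


@dataclass(frozen=True)
class NormalizationResult:
    """Outcome of the comparative normalization step."""

    scale_factor: float
    anchor_pairs: np.ndarray  # shape (n, 2): reference and scaled strengths
    rss: float

    @property
    def n_anchors(self) -> int:
        return len(self.anchor_pairs)


def read_tags_bed(path, genome_label, factor_label, fragment_length) -> TagSet:
    """Read a 6-column BED of mapped tags; the 5' end is the start on '+'
    records and ``end - 1`` on '-' records."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        usecols=[0, 1, 2, 5],
        names=["chrom", "start", "end", "strand"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "strand": str},
    )
    pos = np.where(df["strand"] == "-", df["end"] - 1, df["start"])
    tags = pd.DataFrame(
        {"chrom": df["chrom"], "pos": pos, "strand": df["strand"]}
    )
    return TagSet(genome_label, factor_label, fragment_length, tags)


def fragment_density(tags: TagSet, chrom_lengths: dict[str, int]) -> SignalTrack:
    """Accumulate fragment coverage from tag 5' ends.

    Each tag contributes +1 over ``fragment_length`` bases extending 3'-ward
    from its 5' end (rightward on '+', leftward on '-'), truncated at
    chromosome boundaries.  A tag whose 5' end lies outside its chromosome
    raises ``ValueError``.
    """
    L = tags.fragment_length
    data = {c: np.zeros(n, dtype=np.float64) for c, n in chrom_lengths.items()}
    for chrom, sub in tags.tags.groupby("chrom", sort=False):
        if chrom not in data:
            raise ValueError(f"tag on unknown chromosome {chrom!r}")
        n = chrom_lengths[chrom]
        pos = sub["pos"].to_numpy()
        if (pos < 0).any() or (pos >= n).any():
            raise ValueError(f"tag beyond chromosome end on {chrom}")
        minus = (sub["strand"] == "-").to_numpy()
        starts = np.where(minus, pos - L + 1, pos)
        ends = np.where(minus, pos + 1, pos + L)
        starts = np.clip(starts, 0, n)
        ends = np.clip(ends, 0, n)
        delta = np.zeros(n + 1, dtype=np.float64)
        np.add.at(delta, starts, 1.0)
        np.add.at(delta, ends, -1.0)
        data[chrom] = np.cumsum(delta[:-1])
    return SignalTrack(tags.genome_label, data)


def libsize_normalize(
    track: SignalTrack, target_total_tags: float, actual_total_tags: float
) -> SignalTrack:
    """Scale a track by ``target/actual`` total sequenced tags."""
    if target_total_tags <= 0 or actual_total_tags <= 0:
        raise ValueError("tag totals must be positive")
    return track.scaled(target_total_tags / actual_total_tags)


def comparative_scale(
    strengths_ref: np.ndarray, strengths_other: np.ndarray
) -> NormalizationResult:
    """Least-squares scale factor mapping one genome's anchor-peak strengths
    onto the other's.

    Minimizes sum_i (m_i - s * y_i)^2 over s, giving
    ``s = sum(m*y) / sum(y*y)``.  The other genome's track is multiplied by
    `s` downstream.
    """
    m = np.asarray(strengths_ref, dtype=float)
    y = np.asarray(strengths_other, dtype=float)
    if m.size == 0 or m.shape != y.shape:
        raise ValueError("anchor strength vectors must be non-empty and matched")
    denom = float(np.dot(y, y))
    if denom == 0:
        raise ValueError("all-zero strengths in the genome being scaled")
    s = float(np.dot(m, y)) / denom
    rss = float(np.sum((m - s * y) ** 2))
    return NormalizationResult(s, np.column_stack([m, y]), rss)


def select_anchor_pairs(matched_ref, matched_other, n_top: int = 50):
    """Build the comparative-normalization anchor set.

    Takes the `n_top` most highly bound developmental-target-proximal peaks
    called in each genome (with identified orthologs), expresses each as a
    ``(reference strength, other-genome strength)`` pair, and unions the two
    lists, dropping duplicate pairs where a top peak of one genome projects
    onto a top peak of the other.

    Parameters
    ----------
    matched_ref, matched_other : sequence of MatchedPeak
        Peaks called in the reference genome and in the other genome,
        respectively, already matched through the alignment and annotated
        with target-gene proximity.
    """
    pairs: dict[tuple, tuple[float, float]] = {}

    def key_of(p):
        if p.ortholog_intervals:
            o = p.ortholog_intervals[0]
            okey = (o[0], o[1] // 100)
        else:
            okey = None
        return (p.chrom, p.window[0] // 100, okey)

    def top(peaks):
        usable = [
            p
            for p in peaks
            if p.is_ap_target and p.status != "unalignable"
        ]
        usable.sort(key=lambda p: -p.strength)
        return usable[:n_top]

    for p in top(matched_ref):
        pairs.setdefault(key_of(p), (p.strength, p.ortholog_strength))
    for p in top(matched_other):
        k = key_of(p)
        # same matched pair seen from the other side: normalize the key
        k = (k[2][0] if k[2] else p.chrom, k[2][1] if k[2] else p.window[0] // 100,
             (p.chrom, p.window[0] // 100))
        pairs.setdefault(k, (p.ortholog_strength, p.strength))
    arr = np.array(list(pairs.values()), dtype=float)
    if arr.size == 0:
        raise ValueError("empty anchor set")
    return arr[:, 0], arr[:, 1]


def track_correlation(track_a: SignalTrack, track_b: SignalTrack, regions) -> float:
    """Pearson correlation of per-region maximum densities."""
    regions = list(regions)
    if not regions:
        raise ValueError("regions must be non-empty")
    a = np.array([track_a.max_in(*r) for r in regions])
    b = np.array([track_b.max_in(*r) for r in regions])
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance in region summaries")
    return float(np.corrcoef(a, b)[0, 1])
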