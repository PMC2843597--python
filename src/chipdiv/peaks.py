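"""Peak matching across species, gain/loss classification, divergence
statistics, cohort curves, and target-gene annotation.

A peak is summarized by a 100 bp window centered on the empirical maximum
of the fragment density; its binding strength is the maximum density in
that window.  Matching projects the window through the whole-genome
alignment and takes the maximum density over the orthologous intervals,
so the effective spatial resolution of the comparison is 50 bp.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import PairwiseGenomeAlignment
from .signal import SignalTrack

__all__ = [
    "Peak",
    "MatchedPeak",
    "read_peaks",
    "match_ortholog",
    "classify_absent",
    "fractional_divergence",
    "annotate_ap",
    "gain_loss_table",
    "absent_rate_percent",
    "cohort_curves",
    "write_matched_peaks",
    "read_gene_table",
]

WINDOW_HALF = 50
ABSENT_FOLD = 10.0
AP_DISTANCE = 10_000
COVERAGE_THRESHOLD = 0.5


@dataclass
class Peak:
    """A called peak with summit and strength recomputed from the track."""

    factor: str
    genome_label: str
    chrom: str
    summit: int
    strength: float

    @property
    def window(self) -> tuple[int, int]:
        return self.summit - WINDOW_HALF, self.summit + WINDOW_HALF


@dataclass
class MatchedPeak:
    """A peak with its orthologous strength and divergence statistics."""

    factor: str
    genome_label: str
    chrom: str
    summit: int
    strength: float
    ortholog_intervals: list = field(default_factory=list)
    ortholog_strength: float = 0.0
    coverage: float = 0.0
    status: str = "unalignable"  # matched | absent | unalignable
    signed_frac_div: float = float("nan")
    abs_frac_div: float = float("nan")
    abs_div: float = float("nan")
    is_ap_target: bool = False

    @property
    def window(self) -> tuple[int, int]:
        return self.summit - WINDOW_HALF, self.summit + WINDOW_HALF


def read_peaks(path, track: SignalTrack, factor: str) -> list[Peak]:
    """Ingest MACS-style peak records (BED: chrom, start, end, [name, score,
    summit offset]) and recompute summit and strength from the track.

    The summit is the leftmost argmax of the density within the record's
    span; strength is the track maximum over the 100 bp summit window.
    """
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    peaks = []
    for row in df.itertuples(index=False):
        chrom, start, end = str(row[0]), int(row[1]), int(row[2])
        if chrom not in track.data:
            raise ValueError(f"peak on unknown chromosome {chrom!r}")
        n = len(track.data[chrom])
        if not (0 <= start < end <= n):
            raise ValueError(f"peak record off chromosome: {chrom}:{start}-{end}")
        summit = track.argmax_in(chrom, start, end)
        strength = track.max_in(chrom, summit - WINDOW_HALF, summit + WINDOW_HALF)
        peaks.append(Peak(factor, track.genome_label, chrom, summit, strength))
    return peaks


def classify_absent(m: float, y: float, fold: float = ABSENT_FOLD) -> str:
    """Absence rule: a peak is absent in its ortholog if the orthologous
    signal is reduced `fold`-fold or more (boundary inclusive; zero signal
    is the limiting case and counts as absent)."""
    if m <= 0:
        raise ValueError("source strength must be positive")
    return "absent" if y <= m / fold else "matched"


def fractional_divergence(m: float, y: float) -> tuple[float, float]:
    """Signed and absolute fractional binding divergence (m-y)/(m+y)."""
    if m < 0 or y < 0 or m + y == 0:
        raise ValueError("require m >= 0, y >= 0, m + y > 0")
    signed = (m - y) / (m + y)
    return signed, abs(signed)


def match_ortholog(
    peak: Peak,
    aln: PairwiseGenomeAlignment,
    other_track: SignalTrack,
    coverage_threshold: float = COVERAGE_THRESHOLD,
) -> MatchedPeak:
    """Project a peak's 100 bp window onto the other genome and compare
    binding strengths.

    The orthologous strength is the maximum density over all projected
    intervals.  Windows with aligned-coverage fraction below
    `coverage_threshold` are flagged ``unalignable`` and must be excluded
    from gain/loss denominators.
    """
    start, end = peak.window
    intervals, coverage = aln.project_interval(
        peak.genome_label, peak.chrom, max(0, start), end
    )
    mp = MatchedPeak(
        peak.factor,
        peak.genome_label,
        peak.chrom,
        peak.summit,
        peak.strength,
        ortholog_intervals=intervals,
        coverage=coverage,
    )
    if coverage < coverage_threshold or not intervals:
        return mp
    y = max(other_track.max_in(c, s, e) for c, s, e in intervals)
    mp.ortholog_strength = y
    if peak.strength <= 0:
        # a record with no quantifiable source signal cannot be classified;
        # it stays out of the gain/loss denominators like unalignable peaks
        return mp
    mp.status = classify_absent(peak.strength, y)
    if peak.strength + y > 0:
        mp.signed_frac_div, mp.abs_frac_div = fractional_divergence(
            peak.strength, y
        )
        mp.abs_div = abs(peak.strength - y)
    return mp


def read_gene_table(path) -> pd.DataFrame:
    """Gene table TSV: gene, chrom, strand, five_prime_pos."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"gene", "chrom", "strand", "five_prime_pos"}
    if not required.issubset(df.columns):
        raise ValueError(f"gene table must have columns {sorted(required)}")
    return df


def annotate_ap(
    peaks: list[MatchedPeak],
    gene_table: pd.DataFrame,
    chrom_lengths: dict[str, int] | None = None,
    max_distance: int = AP_DISTANCE,
) -> list[MatchedPeak]:
    """Flag peaks whose summit lies within `max_distance` (inclusive) of a
    listed gene's 5' end.  Gene 5' ends are strand-aware and given in the
    reference genome's coordinates."""
    if chrom_lengths is not None:
        for chrom in gene_table["chrom"].unique():
            if chrom not in chrom_lengths:
                raise ValueError(f"gene chromosome {chrom!r} absent from genome")
    by_chrom = {
        c: np.sort(sub["five_prime_pos"].to_numpy())
        for c, sub in gene_table.groupby("chrom")
    }
    for p in peaks:
        ends = by_chrom.get(p.chrom)
        if ends is None or ends.size == 0:
            p.is_ap_target = False
            continue
        i = np.searchsorted(ends, p.summit)
        d = min(
            abs(p.summit - ends[max(i - 1, 0)]),
            abs(p.summit - ends[min(i, ends.size - 1)]),
        )
        p.is_ap_target = bool(d <= max_distance)
    return peaks


def absent_rate_percent(absent: int, total: int) -> float | None:
    """Absent-peak rate as a percentage rounded to one decimal; ``None``
    when the stratum is empty (rate undefined)."""
    if total == 0:
        return None
    if not 0 <= absent <= total:
        raise ValueError("require 0 <= absent <= total")
    return round(100.0 * absent / total, 1)


def gain_loss_table(matched_peaks: list[MatchedPeak]) -> pd.DataFrame:
    """Per factor x genome x {A-P, non-A-P} counts of peaks absent in the
    ortholog.  Denominators include only peaks with identifiable orthologs
    (``unalignable`` excluded)."""
    rows = []
    usable = [p for p in matched_peaks if p.status != "unalignable"]
    keys = sorted({(p.factor, p.genome_label) for p in usable})
    for factor, genome in keys:
        for ap_class, flag in (("A-P", True), ("non-A-P", False)):
            stratum = [
                p
                for p in usable
                if p.factor == factor
                and p.genome_label == genome
                and p.is_ap_target == flag
            ]
            total = len(stratum)
            absent = sum(1 for p in stratum if p.status == "absent")
            rows.append(
                {
                    "factor": factor,
                    "genome": genome,
                    "class": ap_class,
                    "total": total,
                    "absent": absent,
                    "rate_pct": absent_rate_percent(absent, total),
                }
            )
    return pd.DataFrame(rows)


def cohort_curves(
    values,
    order_key,
    cohort_size: int = 250,
    stride: int = 25,
    descending: bool = True,
) -> pd.DataFrame:
    """Sliding-cohort summaries of `values` ordered by `order_key`.

    Peaks are sorted by `order_key` (default direction: descending, i.e.
    binding rank order); overlapping cohorts of exactly `cohort_size`
    members are taken every `stride` positions, dropping a trailing partial
    cohort.  If there are fewer values than `cohort_size`, a single cohort
    of all values is returned.
    """
    values = np.asarray(values, dtype=float)
    order_key = np.asarray(order_key)
    if values.shape != order_key.shape:
        raise ValueError("values and order_key must have equal length")
    order = np.argsort(-order_key if descending else order_key, kind="stable")
    v = values[order]
    n = v.size
    if n < cohort_size:
        starts = [0]
        cohort_size = n
    else:
        starts = list(range(0, n - cohort_size + 1, stride))
    rows = []
    for s in starts:
        chunk = v[s : s + cohort_size]
        rows.append(
            {
                "start_rank": s,
                "median": float(np.median(chunk)),
                "mean": float(chunk.mean()),
                "sd": float(chunk.std(ddof=1)) if chunk.size > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)


def write_matched_peaks(matched: list[MatchedPeak], path, header: str | None = None):
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        cols = [
            "factor", "genome", "chrom", "summit", "strength",
            "ortholog_strength", "coverage", "status", "signed_frac_div",
            "abs_frac_div", "abs_div", "is_ap_target", "ortholog_intervals",
        ]
        fh.write("\t".join(cols) + "\n")
        for p in matched:
            ivs = ",".join(f"{c}:{s}-{e}" for c, s, e in p.ortholog_intervals)
            fh.write(
                "\t".join(
                    str(x)
                    for x in [
                        p.factor, p.genome_label, p.chrom, p.summit,
                        f"{p.strength:.6g}", f"{p.ortholog_strength:.6g}",
                        f"{p.coverage:.4f}", p.status,
                        f"{p.signed_frac_div:.6g}", f"{p.abs_frac_div:.6g}",
                        f"{p.abs_div:.6g}", int(p.is_ap_target), ivs,
                    ]
                )
                + "\n"
            )
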