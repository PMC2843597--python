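"""PCA of multi-factor binding and divergence matrices, coherence shuffle
controls, and word discovery on principal-component projections.

Rows are the union of regions bound by any factor; columns are the six
factors.  Each column is centered and scaled to unit variance before a
singular value decomposition.  A first component with same-sign loadings
across all factors indicates a coherent, factor-independent ("chromatin")
mode of variation; shuffling a column across rows destroys the spatial
correlation that produces it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alignment import PairwiseGenomeAlignment
from .ddw import ConservationChecker, ddw_scan, discover_ddws
from .peaks import WINDOW_HALF, MatchedPeak
from .signal import SignalTrack

__all__ = [
    "BindingMatrix",
    "PCAResult",
    "merge_peak_windows",
    "build_matrix",
    "pca",
    "coherence_shuffle",
    "project_scores",
    "pc_ddw_discovery",
]


@dataclass
class BindingMatrix:
    """Factor-by-region value matrix plus the standardization parameters.

    ``mode`` is one of ``species_ref``, ``species_other``, ``divergence``.
    """

    values: pd.DataFrame
    mode: str
    windows: list  # representative (chrom, start, end) per row

    def standardized(self) -> pd.DataFrame:
        return standardize(self.values)


def standardize(values: pd.DataFrame) -> pd.DataFrame:
    """Center each column and scale to unit variance (population variance)."""
    v = values.astype(float)
    std = v.std(axis=0, ddof=0)
    if (std == 0).any():
        bad = list(std.index[std == 0])
        raise ValueError(f"zero-variance columns cannot be standardized: {bad}")
    return (v - v.mean(axis=0)) / std


def merge_peak_windows(peaks_by_factor: dict[str, list[MatchedPeak]]):
    """Merge overlapping 100 bp windows across factors into union regions.

    Each merged region is represented by the 100 bp window centered on the
    summit of its strongest contributing peak.
    """
    items = []
    for factor, plist in peaks_by_factor.items():
        for p in plist:
            items.append((p.chrom, p.window[0], p.window[1], p.strength, p.summit))
    if not items:
        raise ValueError("no peaks to merge")
    items.sort()
    merged = []
    cur = None
    for chrom, s, e, strength, summit in items:
        if cur is not None and chrom == cur[0] and s < cur[2]:
            cur[2] = max(cur[2], e)
            if strength > cur[3]:
                cur[3], cur[4] = strength, summit
        else:
            if cur is not None:
                merged.append(cur)
            cur = [chrom, s, e, strength, summit]
    merged.append(cur)
    return [
        (chrom, summit - WINDOW_HALF, summit + WINDOW_HALF)
        for chrom, _, _, _, summit in merged
    ]


def build_matrix(
    peaks_by_factor: dict[str, list[MatchedPeak]],
    ref_tracks: dict[str, SignalTrack],
    other_tracks: dict[str, SignalTrack],
    aln: PairwiseGenomeAlignment,
    mode: str,
    ref_genome: str | None = None,
    log: bool = False,
) -> BindingMatrix:
    """Assemble the region-by-factor matrix for one PCA mode.

    Union regions come from merging all factors' windows in the reference
    genome; per factor, the reference strength is the track maximum in the
    representative window and the other-genome strength is the maximum over
    its projected intervals.  ``divergence`` mode stores the signed
    fractional divergence (m - y)/(m + y); regions where a factor has zero
    signal in both genomes get divergence 0.  With ``log=True`` the species
    modes store log1p-strengths (documented hook; default is linear scale).
    """
    if mode not in {"species_ref", "species_other", "divergence"}:
        raise ValueError(f"unknown mode {mode!r}")
    windows = merge_peak_windows(peaks_by_factor)
    if ref_genome is None:
        ref_genome = next(iter(ref_tracks.values())).genome_label
    factors = sorted(peaks_by_factor)
    cols = {}
    proj = [
        aln.project_interval(ref_genome, c, s, e)[0] for c, s, e in windows
    ]
    for f in factors:
        m = np.array([ref_tracks[f].max_in(c, s, e) for c, s, e in windows])
        y = np.array(
            [
                max((other_tracks[f].max_in(c, s, e) for c, s, e in ivs), default=0.0)
                for ivs in proj
            ]
        )
        if mode == "species_ref":
            cols[f] = np.log1p(m) if log else m
        elif mode == "species_other":
            cols[f] = np.log1p(y) if log else y
        else:
            tot = m + y
            with np.errstate(invalid="ignore", divide="ignore"):
                d = np.where(tot > 0, (m - y) / np.where(tot > 0, tot, 1.0), 0.0)
            cols[f] = d
    values = pd.DataFrame(cols, columns=factors)
    return BindingMatrix(values, mode, windows)


@dataclass
class PCAResult:
    """Loadings (rows = components), per-row scores, and explained-variance
    fractions, components ordered by decreasing fraction.

    Sign convention: each loading is flipped so its largest-magnitude entry
    is positive.
    """

    loadings: pd.DataFrame
    scores: np.ndarray
    explained: np.ndarray

    def loading(self, i: int) -> np.ndarray:
        return self.loadings.iloc[i].to_numpy()


def pca(values: pd.DataFrame, standardize_input: bool = True) -> PCAResult:
    """PCA via singular value decomposition of the standardized matrix.

    Explained fraction of component i is sigma_i^2 / sum_j sigma_j^2.
    Rank-deficient inputs yield trailing zero-variance components.
    """
    vdf = pd.DataFrame(values)
    if len(vdf) < vdf.shape[1]:
        raise ValueError("need at least as many rows as columns")
    X = standardize(vdf).to_numpy() if standardize_input else vdf.to_numpy(
        dtype=float
    )
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    total = float((s**2).sum())
    explained = (s**2) / total if total > 0 else np.zeros_like(s)
    # deterministic sign: largest-magnitude loading entry positive
    for i in range(Vt.shape[0]):
        j = int(np.argmax(np.abs(Vt[i])))
        if Vt[i, j] < 0:
            Vt[i] *= -1
            U[:, i] *= -1
    loadings = pd.DataFrame(
        Vt, columns=vdf.columns, index=[f"PC{i+1}" for i in range(Vt.shape[0])]
    )
    scores = U * s
    return PCAResult(loadings, scores, explained)


def coherence_shuffle(
    values: pd.DataFrame,
    which: str = "all",
    seed: int | np.random.Generator | None = 0,
) -> pd.DataFrame:
    """Row-shuffle one factor's column (or every column independently),
    destroying its spatial correlation with the other factors while
    preserving each column's multiset of values."""
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    out = pd.DataFrame(values).copy()
    targets = list(out.columns) if which == "all" else [which]
    for c in targets:
        out[c] = rng.permutation(out[c].to_numpy())
    return out


def project_scores(values_std: pd.DataFrame, loading: np.ndarray) -> np.ndarray:
    """Per-row score along one component: row . loading."""
    X = np.asarray(values_std, dtype=float)
    loading = np.asarray(loading, dtype=float)
    if X.shape[1] != loading.size:
        raise ValueError("dimension mismatch between matrix and loading")
    return X @ loading


def pc_ddw_discovery(
    component_scores: np.ndarray,
    windows,
    aln: PairwiseGenomeAlignment,
    ref_genome: str,
    seqs: dict[str, dict[str, str]],
    k: int,
    min_count: int = 20,
    alpha: float = 0.01,
):
    """DDW discovery with the per-peak response replaced by a principal
    component score, over the union peak windows, in both directions.

    Yak-direction windows are 100 bp windows centered on the midpoint of
    each region's projected span in the other genome; regions with less
    than half their bases aligned are skipped in that direction.

    Returns ``(ddws, results_ref, results_other)``.
    """
    scores = np.asarray(component_scores, dtype=float)
    if scores.std() == 0:
        return set(), {}, {}
    other = aln.other(ref_genome)
    checker_ref = ConservationChecker(aln, ref_genome, seqs[ref_genome])
    checker_other = ConservationChecker(aln, other, seqs[other])
    res_ref, cand_ref = ddw_scan(
        k, windows, scores, checker_ref, min_count=min_count, alpha=alpha
    )
    other_windows, other_scores = [], []
    for (chrom, s, e), v in zip(windows, scores):
        ivs, cov = aln.project_interval(ref_genome, chrom, s, e)
        if cov < 0.5 or not ivs:
            continue
        c = ivs[0][0]
        lo = min(iv[1] for iv in ivs if iv[0] == c)
        hi = max(iv[2] for iv in ivs if iv[0] == c)
        mid = (lo + hi) // 2
        start = max(0, mid - WINDOW_HALF)
        end = min(len(seqs[other][c]), start + 2 * WINDOW_HALF)
        other_windows.append((c, start, end))
        other_scores.append(v)
    res_other, cand_other = ddw_scan(
        k,
        other_windows,
        np.asarray(other_scores),
        checker_other,
        min_count=min_count,
        alpha=alpha,
    )
    return discover_ddws(cand_ref, cand_other), res_ref, res_other
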