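"""Divergence-driving word (DDW) discovery and PWM matching.

For every k-mer, all non-softmasked instances (both strands) inside the
100 bp peak windows of one genome are split into conserved instances —
those whose orthologous aligned bases spell the identical word with no
gaps — and diverged instances.  Each instance contributes its peak's
binding-divergence value, giving two samples, p_cons and p_div, compared
with a two-sample Kolmogorov-Smirnov test.  Words significant at p < 0.01
in both calling directions (peaks called in either genome, conservation
assessed in the other) are the final DDWs.

Words are also matched to position weight matrices by a Patser-style
p-value: the probability that a random background k-mer scores at least as
high on the best-matching PWM columns, computed by exact dynamic
programming over discretized column score distributions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .alignment import GAP, PairwiseGenomeAlignment

__all__ = [
    "revcomp",
    "canonical",
    "WordInstance",
    "KSWordResult",
    "PWM",
    "PwmMatch",
    "ConservationChecker",
    "enumerate_instances",
    "ks_two_sample",
    "ddw_scan",
    "discover_ddws",
    "pwm_ln_pvalue",
    "enumerate_pwm_kmers",
    "read_pwm_file",
    "enrichment_conservation_curves",
]

_COMP = str.maketrans("ACGTacgt", "TGCAtgca")
BASES = "ACGT"
KS_ALPHA = 0.01
MIN_COUNT = 20


def revcomp(word: str) -> str:
    return word.translate(_COMP)[::-1]


def canonical(word: str) -> str:
    """Lexicographically smaller of a word and its reverse complement; used
    to report strand-symmetric results once."""
    rc = revcomp(word)
    return word if word <= rc else rc


@dataclass(frozen=True)
class WordInstance:
    peak_index: int
    chrom: str
    position: int
    strand: str
    conserved: bool


@dataclass
class KSWordResult:
    """KS comparison of divergence at conserved vs diverged word instances."""

    word: str
    n_cons: int
    n_div: int
    statistic: float
    p_value: float
    p_cons: np.ndarray | None = None
    p_div: np.ndarray | None = None

    @property
    def revcomp(self) -> str:
        return revcomp(self.word)


class ConservationChecker:
    """Vectorized word-conservation lookups for one projection direction.

    Flattens the block structure of a pairwise alignment into, per source
    chromosome, a position -> global-column map plus a global array of the
    other genome's column characters.  Global column ids leave a hole
    between blocks so that a column-contiguity test cannot run across block
    boundaries.
    """

    def __init__(
        self,
        aln: PairwiseGenomeAlignment,
        source_genome: str,
        source_seqs: dict[str, str],
        target_seqs: dict[str, str] | None = None,
    ):
        self.aln = aln
        self.source = source_genome
        self.target = aln.other(source_genome)
        self.source_seqs = source_seqs
        self._colmap: dict[str, np.ndarray] = {}
        tchars = [np.frombuffer(b"--", dtype=np.uint8)]  # columns 0-1: sentinel
        offset = 2
        for chrom, n in ((c, len(source_seqs[c])) for c in source_seqs):
            self._colmap[chrom] = np.full(n, -1, dtype=np.int64)
        for b in aln.blocks:
            chrom = b.chroms[self.source]
            if chrom not in self._colmap:
                continue
            src = b.positions(self.source)
            nong = src >= 0
            cols = np.flatnonzero(nong)
            self._colmap[chrom][src[nong]] = offset + cols
            trow = b.row_bytes(self.target).copy()
            # uppercase target row for case-insensitive comparison
            lower = (trow >= 97) & (trow <= 122)
            trow[lower] -= 32
            tchars.append(trow)
            tchars.append(np.frombuffer(b"--", dtype=np.uint8))
            offset += b.n_columns + 2
        self._tchars = np.concatenate(tchars)

    def conserved(self, chrom: str, positions: np.ndarray, words_u8: np.ndarray):
        """Vectorized conservation test.

        Parameters
        ----------
        chrom : str
            Source chromosome.
        positions : (n,) int array
            Instance start positions.
        words_u8 : (n, k) uint8 array
            Uppercase instance text as written on the forward strand.

        Returns
        -------
        (n,) bool array; an instance is conserved iff its k columns are all
        aligned, gap-free, column-contiguous, and the orthologous bases
        spell the identical word.
        """
        positions = np.asarray(positions, dtype=np.int64)
        n, k = words_u8.shape
        if n == 0:
            return np.zeros(0, dtype=bool)
        cm = self._colmap[chrom]
        idx = positions[:, None] + np.arange(k)[None, :]
        cols = cm[idx]
        ok = (cols >= 0).all(axis=1)
        contiguous = (np.diff(cols, axis=1) == 1).all(axis=1)
        safe_cols = np.where(cols >= 0, cols, 0)
        tch = self._tchars[safe_cols]
        same = (tch == words_u8).all(axis=1) & (tch != GAP).all(axis=1)
        return ok & contiguous & same


def enumerate_instances(
    word: str, windows, seqs: dict[str, str]
) -> list[WordInstance]:
    """All exact, non-softmasked matches of `word` or its reverse complement
    on the forward sequence text, fully inside the given 100 bp windows.

    `windows` is a sequence of ``(chrom, start, end)`` tuples; conservation
    flags are left False (use :func:`ddw_scan` for classified instances).
    """
    word = word.upper()
    rc = revcomp(word)
    k = len(word)
    out = []
    for i, (chrom, start, end) in enumerate(windows):
        text = seqs[chrom][start:end]
        for off in range(0, len(text) - k + 1):
            sub = text[off : off + k]
            if not sub.isupper():
                continue  # softmasked base inside the instance
            if sub == word:
                out.append(WordInstance(i, chrom, start + off, "+", False))
            elif sub == rc:
                out.append(WordInstance(i, chrom, start + off, "-", False))
    return out


def ks_two_sample(a, b, method: str = "auto") -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test.

    Returns ``(D, p)`` with D = sup |ECDF_a - ECDF_b|.  The exact p-value
    is used for small samples and the asymptotic one for large samples.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def _window_instances(windows, seqs, k):
    """Enumerate every non-softmasked k-mer instance in the windows.

    Returns per-chromosome arrays of (position, window index, text) where
    text is the literal uppercase forward-strand k-mer.
    """
    per_chrom: dict[str, list] = {}
    for i, (chrom, start, end) in enumerate(windows):
        text = seqs[chrom][start:end]
        arr = np.frombuffer(text.encode("ascii"), dtype=np.uint8)
        if arr.size < k:
            continue
        shape = (arr.size - k + 1, k)
        kmers = np.lib.stride_tricks.as_strided(
            arr, shape=shape, strides=(arr.strides[0], arr.strides[0])
        )
        upper = ((kmers >= 65) & (kmers <= 90)).all(axis=1)
        acgt = (
            (kmers == 65) | (kmers == 67) | (kmers == 71) | (kmers == 84)
        ).all(axis=1)
        keep = np.flatnonzero(upper & acgt)
        if keep.size == 0:
            continue
        per_chrom.setdefault(chrom, []).append(
            (start + keep, np.full(keep.size, i), kmers[keep].copy())
        )
    out = {}
    for chrom, parts in per_chrom.items():
        pos = np.concatenate([p[0] for p in parts])
        win = np.concatenate([p[1] for p in parts])
        txt = np.concatenate([p[2] for p in parts])
        out[chrom] = (pos, win, txt)
    return out


def ddw_scan(
    k: int,
    windows,
    divergences,
    checker: ConservationChecker,
    min_count: int = MIN_COUNT,
    alpha: float = KS_ALPHA,
    keep_samples: bool = False,
):
    """Scan all 4^k words for association between word turnover and binding
    divergence in one calling direction.

    Parameters
    ----------
    windows : sequence of (chrom, start, end)
        100 bp peak windows in the checker's source genome.
    divergences : (n_windows,) array
        Per-peak binding-divergence value (normalized reference - other).
    min_count : int
        Minimum size of both the conserved and diverged classes for a word
        to be testable.
    alpha : float
        KS significance threshold for calling a candidate DDW.

    Returns
    -------
    results : dict mapping canonical word -> KSWordResult
        One entry per testable word (a word and its reverse complement share
        one instance set and one result).
    candidates : set of canonical words with KS p < alpha.
    """
    divergences = np.asarray(divergences, dtype=float)
    inst = _window_instances(windows, checker.source_seqs, k)
    texts, wins, cons = [], [], []
    for chrom, (pos, win, txt) in sorted(inst.items()):
        flags = checker.conserved(chrom, pos, txt)
        texts.append(txt)
        wins.append(win)
        cons.append(flags)
    if not texts:
        return {}, set()
    texts = np.concatenate(texts)
    wins = np.concatenate(wins)
    cons = np.concatenate(cons)
    # group instances by canonical word
    words = ["".join(map(chr, row)) for row in texts]
    groups: dict[str, list[int]] = {}
    for i, w in enumerate(words):
        groups.setdefault(canonical(w), []).append(i)
    results: dict[str, KSWordResult] = {}
    candidates: set[str] = set()
    for w, idx in groups.items():
        idx = np.asarray(idx)
        flags = cons[idx]
        n_cons = int(flags.sum())
        n_div = int(idx.size - n_cons)
        if n_cons < min_count or n_div < min_count:
            continue
        vals = divergences[wins[idx]]
        p_cons = vals[flags]
        p_div = vals[~flags]
        d, p = ks_two_sample(p_cons, p_div)
        res = KSWordResult(w, n_cons, n_div, d, p)
        if keep_samples:
            res.p_cons, res.p_div = p_cons, p_div
        results[w] = res
        if p < alpha:
            candidates.add(w)
    return results, candidates


def discover_ddws(candidates_ref: set, candidates_other: set) -> set:
    """Final DDW set: intersection of the two directional candidate sets."""
    return set(candidates_ref) & set(candidates_other)


# ---------------------------------------------------------------------------
# PWM matching


class PWM:
    """Position weight matrix over A, C, G, T.

    Columns are base-probability vectors; a pseudocount is added to every
    cell before renormalization so all entries are strictly positive.
    """

    def __init__(self, name: str, probs: np.ndarray, pseudocount: float = 0.01):
        probs = np.asarray(probs, dtype=float)
        if probs.ndim != 2 or probs.shape[0] != 4:
            raise ValueError("PWM must be a 4 x width matrix (rows A,C,G,T)")
        probs = probs + pseudocount
        probs = probs / probs.sum(axis=0, keepdims=True)
        self.name = name
        self.probs = probs
        self.pseudocount = pseudocount

    @property
    def width(self) -> int:
        return self.probs.shape[1]

    @classmethod
    def from_counts(cls, name, counts, pseudocount: float = 0.01) -> "PWM":
        counts = np.asarray(counts, dtype=float)
        return cls(name, counts / counts.sum(axis=0, keepdims=True), pseudocount)


@dataclass(frozen=True)
class PwmMatch:
    word: str
    pwm_name: str
    ln_p: float
    offset: int
    strand: str
    matched: bool


def read_pwm_file(path, pseudocount: float = 0.01) -> list[PWM]:
    """Read simple JASPAR-like PWM text: ``>name`` header then 4 rows
    (A, C, G, T) of whitespace-separated counts or probabilities."""
    pwms, name, rows = [], None, []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                if name is not None:
                    pwms.append(PWM.from_counts(name, rows, pseudocount))
                name, rows = line[1:].strip(), []
            else:
                fields = line.replace("[", " ").replace("]", " ").split()
                fields = [f for f in fields if f not in "ACGT"]
                rows.append([float(x) for x in fields])
    if name is not None:
        pwms.append(PWM.from_counts(name, rows, pseudocount))
    return pwms


class _OffsetScorer:
    """Exact tail p-values for k contiguous PWM columns by dynamic
    programming over discretized per-column log-odds scores."""

    def __init__(self, pwm: PWM, start: int, k: int, background, bin_width: float):
        cols = pwm.probs[:, start : start + k]
        self.scores = np.log(cols / background[:, None])  # (4, k)
        self.ints = np.rint(self.scores / bin_width).astype(np.int64)
        self.bg = background
        # distribution of the summed integer score of a random background word
        cur = {0: 1.0}
        for j in range(k):
            nxt: dict[int, float] = {}
            for s, p in cur.items():
                for b in range(4):
                    key = s + int(self.ints[b, j])
                    nxt[key] = nxt.get(key, 0.0) + p * background[b]
            cur = nxt
        keys = np.array(sorted(cur))
        probs = np.array([cur[s] for s in keys])
        # suffix sums: P(S >= s)
        self._keys = keys
        self._tail = np.cumsum(probs[::-1])[::-1]

    def word_score_int(self, codes: np.ndarray) -> int:
        return int(self.ints[codes, np.arange(codes.size)].sum())

    def tail_p(self, score_int: int) -> float:
        i = np.searchsorted(self._keys, score_int, side="left")
        if i >= self._keys.size:
            return 0.0
        return float(self._tail[i])


_CODE = {c: i for i, c in enumerate(BASES)}


def _codes(word: str) -> np.ndarray:
    return np.array([_CODE[c] for c in word], dtype=np.intp)


def pwm_ln_pvalue(
    word: str,
    pwm: PWM,
    background: np.ndarray | None = None,
    bin_width: float = 1e-3,
    ln_threshold: float = -4.0,
) -> PwmMatch:
    """Best Patser-style ln p-value of a word against a PWM.

    For each offset of the word along the PWM and for both strands, the
    word's log-odds score over the k aligned columns is compared with the
    exact distribution of a random background k-mer on those columns; the
    p-value is the probability of an equal-or-higher score.  The minimum
    ln p over offsets and strands is returned.
    """
    word = word.upper()
    k = len(word)
    if k > pwm.width:
        raise ValueError("word longer than PWM")
    if background is None:
        background = np.full(4, 0.25)
    best = (0.0, 0, "+")  # ln p = 0 is the worst possible value
    first = True
    for start in range(pwm.width - k + 1):
        scorer = _OffsetScorer(pwm, start, k, background, bin_width)
        for strand, text in (("+", word), ("-", revcomp(word))):
            s = scorer.word_score_int(_codes(text))
            p = scorer.tail_p(s)
            lnp = math.log(p) if p > 0 else -math.inf
            if first or lnp < best[0]:
                best = (lnp, start, strand)
                first = False
    lnp, off, strand = best
    return PwmMatch(word, pwm.name, lnp, off, strand, lnp < ln_threshold)


def enumerate_pwm_kmers(
    pwm: PWM,
    k: int,
    ln_threshold: float = -8.0,
    background: np.ndarray | None = None,
    bin_width: float = 1e-3,
) -> list[str]:
    """All k-mers matching a subsequence of the PWM with ln p below the
    threshold (strand-symmetric; canonical words returned)."""
    if background is None:
        background = np.full(4, 0.25)
    scorers = [
        _OffsetScorer(pwm, s, k, background, bin_width)
        for s in range(pwm.width - k + 1)
    ]
    hits: set[str] = set()
    for i in range(4**k):
        codes = np.array(
            [(i >> (2 * (k - 1 - j))) & 3 for j in range(k)], dtype=np.intp
        )
        word = "".join(BASES[c] for c in codes)
        for scorer in scorers:
            p = scorer.tail_p(scorer.word_score_int(codes))
            if p > 0 and math.log(p) < ln_threshold:
                hits.add(canonical(word))
                break
        else:
            rc = _codes(revcomp(word))
            for scorer in scorers:
                p = scorer.tail_p(scorer.word_score_int(rc))
                if p > 0 and math.log(p) < ln_threshold:
                    hits.add(canonical(word))
                    break
    return sorted(hits)


# ---------------------------------------------------------------------------
# Enrichment / conservation cohort curves


def enrichment_conservation_curves(
    ddws: set,
    windows,
    strengths,
    checker: ConservationChecker,
    chrom_lengths: dict[str, int],
    rng: np.random.Generator,
    cohort_size: int = 250,
    stride: int = 25,
    n_background: int = 2000,
):
    """Cohort curves of DDW enrichment and conservation versus binding rank.

    Per cohort (peaks ordered by descending strength): the fraction of
    peaks containing at least one DDW instance, and the fraction of DDW
    instances that are conserved.  Backgrounds are the same statistics over
    random non-peak 100 bp genomic windows.
    """
    if not ddws:
        raise ValueError("DDW set is empty")
    k = len(next(iter(ddws)))
    ddw_all = {w for d in ddws for w in (d, revcomp(d))}

    def stats_for(wins):
        inst = _window_instances(wins, checker.source_seqs, k)
        has = np.zeros(len(wins), dtype=bool)
        n_inst = 0
        n_cons = 0
        for chrom, (pos, win, txt) in sorted(inst.items()):
            words = ["".join(map(chr, row)) for row in txt]
            sel = np.array([w in ddw_all for w in words], dtype=bool)
            if not sel.any():
                continue
            flags = checker.conserved(chrom, pos[sel], txt[sel])
            has[np.unique(win[sel])] = True
            n_inst += int(sel.sum())
            n_cons += int(flags.sum())
        return has, n_inst, n_cons

    strengths = np.asarray(strengths, dtype=float)
    order = np.argsort(-strengths, kind="stable")
    wins_sorted = [windows[i] for i in order]
    has, _, _ = stats_for(wins_sorted)

    n = len(wins_sorted)
    size = min(cohort_size, n)
    starts = list(range(0, n - size + 1, stride)) or [0]
    rows = []
    for s in starts:
        sub = wins_sorted[s : s + size]
        sub_has = has[s : s + size]
        _, ni, nc = stats_for(sub)
        rows.append(
            {
                "start_rank": s,
                "frac_peaks_with_ddw": float(sub_has.mean()),
                "frac_instances_conserved": nc / ni if ni else float("nan"),
            }
        )
    curves = pd.DataFrame(rows)

    # genome-wide background: random 100 bp windows avoiding peak windows
    peak_ivs: dict[str, list[tuple[int, int]]] = {}
    for c, s, e in windows:
        peak_ivs.setdefault(c, []).append((s, e))
    bg_wins = []
    chroms = sorted(c for c in chrom_lengths if chrom_lengths[c] > 100)
    tries = 0
    while len(bg_wins) < n_background and tries < 50 * n_background:
        tries += 1
        c = chroms[rng.integers(len(chroms))]
        s = int(rng.integers(0, chrom_lengths[c] - 100))
        if any(s < e and p_s < s + 100 for p_s, e in peak_ivs.get(c, [])):
            continue
        bg_wins.append((c, s, s + 100))
    bg_has, bg_ni, bg_nc = stats_for(bg_wins)
    background = {
        "frac_windows_with_ddw": float(bg_has.mean()) if bg_wins else float("nan"),
        "frac_instances_conserved": bg_nc / bg_ni if bg_ni else float("nan"),
        "n_windows": len(bg_wins),
    }
    return curves, background
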