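"""Parameter-recovery benchmarks on ground-truth synthetic data.

Each function regenerates data under the default study conditions and
measures how well the analysis recovers what was planted: discovery of
words with real effects, calibration of the KS null, the comparative
normalization factor, and the planted share of the coherent binding mode.
Used by the validation suite and the reproduction script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ddw import (
    ConservationChecker,
    canonical,
    ddw_scan,
    discover_ddws,
    ks_two_sample,
    revcomp,
)
from .pca import pc_ddw_discovery, pca, project_scores, standardize
from .signal import comparative_scale
from .simulate import SyntheticConfig, expected_pc1_fraction, generate

__all__ = [
    "words_related",
    "word_recovery_experiment",
    "ks_null_rejection_rate",
    "scale_recovery_error",
    "pc1_recovery",
    "pc1_word_recovery",
    "divergence_fraction_frame",
]


def words_related(v: str, w: str) -> bool:
    """True when two words overlap by at least k-1 contiguous bases under a
    single-offset shift, on either strand.

    One-off "shadow" variants of a planted word carry genuine turnover
    signal (their instances coincide with the planted word's), so they are
    counted as related rather than false discoveries.
    """
    for a in (v, revcomp(v)):
        for b in (w, revcomp(w)):
            if a == b or a[1:] == b[: len(b) - 1] or a[: len(a) - 1] == b[1:]:
                return True
    return False


def _scan_factor(ds, factor, checkers, windows, k=7, min_count=20, alpha=0.01):
    div = ds.strengths(factor, "mel") - ds.strengths(factor, "yak")
    _, cand_ref = ddw_scan(
        k, windows["mel"], div, checkers["mel"], min_count=min_count,
        alpha=alpha,
    )
    _, cand_oth = ddw_scan(
        k, windows["yak"], div, checkers["yak"], min_count=min_count,
        alpha=alpha,
    )
    return discover_ddws(cand_ref, cand_oth)


def word_recovery_experiment(
    seeds, n_peaks: int = 2000, k: int = 7, **cfg_kwargs
) -> dict:
    """Planted-word recovery and false-discovery counts over seeded runs.

    One run = word discovery for one factor on one dataset (true binding
    strengths, both calling directions, intersected).  A discovered word is
    a false positive when it is unrelated to both the factor's planted word
    and the shared-term word.
    """
    recovered = 0
    runs = 0
    false_total = 0
    per_seed = []
    for seed in seeds:
        cfg = SyntheticConfig(seed=int(seed), n_peaks=n_peaks, **cfg_kwargs)
        ds = generate(cfg)
        checkers = {
            g: ConservationChecker(ds.aln, g, ds.genomes[g])
            for g in cfg.genomes
        }
        windows = {g: ds.windows(g) for g in cfg.genomes}
        seed_false = 0
        seed_rec = 0
        for f in cfg.factors:
            final = _scan_factor(ds, f, checkers, windows, k=k)
            planted = cfg.factor_words[f]
            runs += 1
            if canonical(planted) in final:
                recovered += 1
                seed_rec += 1
            fps = [
                w
                for w in final
                if not (
                    words_related(w, planted)
                    or words_related(w, cfg.common_word)
                )
            ]
            false_total += len(fps)
            seed_false += len(fps)
        per_seed.append({"seed": int(seed), "recovered": seed_rec,
                         "false": seed_false})
    return {
        "n_runs": runs,
        "recovery_rate": recovered / runs,
        "false_per_run": false_total / runs,
        "per_seed": per_seed,
    }


def ks_null_rejection_rate(
    seed: int, n_draws: int = 10_000, sizes=(30, 40), alpha: float = 0.01
) -> float:
    """Fraction of same-distribution sample pairs rejected at `alpha`."""
    rng = np.random.default_rng(seed)
    rej = 0
    for _ in range(n_draws):
        a = rng.random(sizes[0])
        b = rng.random(sizes[1])
        _, p = ks_two_sample(a, b)
        rej += p < alpha
    return rej / n_draws


def scale_recovery_error(
    seed: int, kappa: float = 1.7, n_anchors: int = 100,
    noise_sd: float = 0.01,
) -> float:
    """Relative error of the comparative normalization factor when the
    other genome's anchor strengths are reference/kappa plus small noise."""
    rng = np.random.default_rng(seed)
    m = np.exp(rng.normal(4.0, 1.0, n_anchors))
    y = m / kappa * (1 + rng.normal(0.0, noise_sd, n_anchors))
    s = comparative_scale(m, y).scale_factor
    return abs(s - kappa) / kappa


def pc1_recovery(seed: int, n_peaks: int = 2000, **cfg_kwargs) -> dict:
    """Measured vs planted first-component fraction of the log-binding
    matrix, plus loading sign coherence."""
    cfg = SyntheticConfig(seed=seed, n_peaks=n_peaks, **cfg_kwargs)
    ds = generate(cfg)
    res = pca(ds.log_binding_matrix("mel"))
    l0 = res.loading(0)
    return {
        "pc1_explained": float(res.explained[0]),
        "planted_phi": expected_pc1_fraction(cfg),
        "sign_coherent": bool((np.sign(l0) == np.sign(l0[0])).all()),
        "dataset": ds,
    }


def divergence_fraction_frame(ds) -> pd.DataFrame:
    """Signed fractional divergence per factor from true strengths."""
    cfg = ds.config
    return pd.DataFrame(
        {
            f: (ds.strengths(f, "mel") - ds.strengths(f, "yak"))
            / (ds.strengths(f, "mel") + ds.strengths(f, "yak"))
            for f in cfg.factors
        }
    )


def pc1_word_recovery(ds, k: int = 7, min_count: int = 20) -> dict:
    """Whether word discovery on the first component of the divergence
    matrix recovers the planted shared-term word."""
    D = divergence_fraction_frame(ds)
    res = pca(D)
    scores = project_scores(standardize(D), res.loading(0))
    ddws, _, _ = pc_ddw_discovery(
        scores, ds.windows("mel"), ds.aln, "mel", ds.genomes, k,
        min_count=min_count,
    )
    return {
        "recovered": canonical(ds.config.common_word) in ddws,
        "n_ddws": len(ddws),
        "pc1_explained": float(res.explained[0]),
    }
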