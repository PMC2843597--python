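"""End-to-end orchestration of the comparative binding-divergence analysis.

Chains the stages over on-disk inputs: fragment densities, two-stage
normalization, cross-species peak matching, gain/loss tabulation, word
discovery, divergence modeling, and multi-factor PCA.  Each stage is also
usable on its own through the library modules; this module only wires
them together and owns the file layout of a run directory.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ddw as ddw_mod
from . import divergence_model as dm
from . import pca as pca_mod
from .alignment import read_maf
from .peaks import (
    annotate_ap,
    gain_loss_table,
    match_ortholog,
    read_gene_table,
    read_peaks,
    write_matched_peaks,
)
from .seqio import chrom_lengths, read_fasta
from .signal import (
    DEFAULT_TARGET_TAGS,
    comparative_scale,
    fragment_density,
    libsize_normalize,
    read_tags_bed,
    select_anchor_pairs,
)

__all__ = ["DatasetPaths", "run_report", "normalize_factor"]


class DatasetPaths:
    """File layout of a simulated (or identically structured) dataset."""

    def __init__(self, root):
        self.root = Path(root)
        cfgfile = self.root / "config.yaml"
        if cfgfile.exists():
            with open(cfgfile) as fh:
                self.config = yaml.safe_load(fh)
        else:
            self.config = {}
        self.genomes = sorted(
            p.stem.replace("genome_", "") for p in self.root.glob("genome_*.fa")
        )
        self.factors = self.config.get("factors") or sorted(
            {
                p.stem.split("_")[1]
                for p in self.root.glob("peaks_*_*.bed")
            }
        )

    def genome(self, label):
        return self.root / f"genome_{label}.fa"

    def tags(self, factor, label):
        return self.root / f"tags_{factor}_{label}.bed"

    def peaks(self, factor, label):
        return self.root / f"peaks_{factor}_{label}.bed"

    @property
    def maf(self):
        return self.root / "alignment.maf"

    @property
    def genes(self):
        return self.root / "genes.tsv"


def _annotate_other_genome(matched, gene_table, max_distance=10_000):
    """Target-gene proximity for peaks called in the non-reference genome:
    the distance is measured at the ortholog's midpoint in the reference
    genome, where the gene coordinates live."""
    by_chrom = {
        c: np.sort(sub["five_prime_pos"].to_numpy())
        for c, sub in gene_table.groupby("chrom")
    }
    for p in matched:
        if not p.ortholog_intervals:
            p.is_ap_target = False
            continue
        c, s, e = p.ortholog_intervals[0]
        pos = (s + e) // 2
        ends = by_chrom.get(c)
        if ends is None or ends.size == 0:
            p.is_ap_target = False
            continue
        i = np.searchsorted(ends, pos)
        d = min(
            abs(pos - ends[max(i - 1, 0)]),
            abs(pos - ends[min(i, ends.size - 1)]),
        )
        p.is_ap_target = bool(d <= max_distance)
    return matched


def normalize_factor(
    ds: DatasetPaths,
    factor: str,
    ref: str,
    other: str,
    seqs: dict,
    aln,
    gene_table,
    fragment_length: int,
    target_total: float = DEFAULT_TARGET_TAGS,
):
    """Density + library-size + comparative normalization for one factor.

    Returns ``(track_ref, track_other_scaled, matched_ref, matched_other,
    scale_result)`` with both directions re-matched after scaling.
    """
    lens = {g: chrom_lengths(seqs[g]) for g in (ref, other)}
    tags_ref = read_tags_bed(ds.tags(factor, ref), ref, factor, fragment_length)
    tags_oth = read_tags_bed(
        ds.tags(factor, other), other, factor, fragment_length
    )
    tr = libsize_normalize(
        fragment_density(tags_ref, lens[ref]), target_total, tags_ref.n_tags
    )
    to = libsize_normalize(
        fragment_density(tags_oth, lens[other]), target_total, tags_oth.n_tags
    )

    def match_all(track_src, track_dst):
        pk = read_peaks(
            ds.peaks(factor, track_src.genome_label), track_src, factor
        )
        return [m for m in (match_ortholog(p, aln, track_dst) for p in pk)]

    m_ref = annotate_ap(match_all(tr, to), gene_table, lens[ref])
    m_oth = _annotate_other_genome(match_all(to, tr), gene_table)
    anchors_ref, anchors_oth = select_anchor_pairs(m_ref, m_oth)
    norm = comparative_scale(anchors_ref, anchors_oth)
    to_scaled = to.scaled(norm.scale_factor)
    m_ref = annotate_ap(match_all(tr, to_scaled), gene_table, lens[ref])
    m_oth = _annotate_other_genome(match_all(to_scaled, tr), gene_table)
    return tr, to_scaled, m_ref, m_oth, norm


def run_report(
    dataset_dir,
    outdir,
    k: int = 6,
    seed: int = 0,
    target_total: float = DEFAULT_TARGET_TAGS,
    min_count: int = 20,
    alpha: float = 0.01,
):
    """Run the full analysis over a dataset directory and write TSV reports.

    Stages: normalization and matching per factor, gain/loss table, DDW
    discovery per factor (both directions, intersected), lasso divergence
    model with shuffled-word control, and PCA of the divergence matrix with
    component-projected word discovery.
    """
    ds = DatasetPaths(dataset_dir)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    ref, other = ds.genomes if not ds.config.get("genomes") else ds.config[
        "genomes"
    ]
    seqs = {g: read_fasta(ds.genome(g)) for g in (ref, other)}
    aln = read_maf(ds.maf)
    gene_table = read_gene_table(ds.genes)
    frag = int(ds.config.get("fragment_length", 225))
    provenance = (
        f"chipdiv report k={k} seed={seed} alpha={alpha} min_count={min_count}"
    )

    checker_ref = ddw_mod.ConservationChecker(aln, ref, seqs[ref])
    checker_oth = ddw_mod.ConservationChecker(aln, other, seqs[other])

    all_matched = []
    tracks_ref, tracks_oth = {}, {}
    matched_by_factor = {}
    ddws_by_factor = {}
    norm_rows = []
    for factor in ds.factors:
        tr, to, m_ref, m_oth, norm = normalize_factor(
            ds, factor, ref, other, seqs, aln, gene_table, frag, target_total
        )
        tracks_ref[factor], tracks_oth[factor] = tr, to
        matched_by_factor[factor] = m_ref
        all_matched.extend(m_ref + m_oth)
        norm_rows.append(
            {
                "factor": factor,
                "scale_factor": norm.scale_factor,
                "n_anchors": norm.n_anchors,
                "rss": norm.rss,
            }
        )
        write_matched_peaks(
            m_ref + m_oth, out / f"matched_{factor}.tsv", provenance
        )

        def direction(matched, checker, flip):
            wins, vals = [], []
            for p in matched:
                if p.status == "unalignable":
                    continue
                s, e = p.window
                wins.append((p.chrom, max(0, s), e))
                d = p.strength - p.ortholog_strength
                vals.append(-d if flip else d)
            return ddw_mod.ddw_scan(
                k, wins, np.array(vals), checker, min_count=min_count,
                alpha=alpha,
            )

        _, cand_ref = direction(m_ref, checker_ref, False)
        _, cand_oth = direction(m_oth, checker_oth, True)
        ddws_by_factor[factor] = ddw_mod.discover_ddws(cand_ref, cand_oth)

    pd.DataFrame(norm_rows).to_csv(
        out / "normalization.tsv", sep="\t", index=False
    )
    gl = gain_loss_table(all_matched)
    gl.to_csv(out / "gain_loss.tsv", sep="\t", index=False)

    ddw_rows = []
    model_rows = []
    for factor, words in sorted(ddws_by_factor.items()):
        for w in sorted(words):
            ddw_rows.append(
                {"factor": factor, "word": w, "revcomp": ddw_mod.revcomp(w)}
            )
        usable = [
            p for p in matched_by_factor[factor] if p.status != "unalignable"
        ]
        if words and len(usable) > 5:
            feats = dm.build_features(words, usable, aln, seqs[ref], seqs[other])
            if len(feats.y) >= 10 and feats.X.shape[1] > 0:
                model = dm.fit_divergence_model(feats.X, feats.y, seed=seed)
                for w, c in zip(model.words, model.coefficients):
                    model_rows.append(
                        {
                            "factor": factor,
                            "word": w,
                            "coefficient": c,
                            "beta": model.beta,
                            "train_r": model.train_r,
                        }
                    )
    pd.DataFrame(ddw_rows).to_csv(out / "ddws.tsv", sep="\t", index=False)
    pd.DataFrame(model_rows).to_csv(out / "model.tsv", sep="\t", index=False)

    matrix = pca_mod.build_matrix(
        matched_by_factor, tracks_ref, tracks_oth, aln, "divergence", ref
    )
    res = pca_mod.pca(matrix.values)
    res.loadings.to_csv(out / "pca_loadings.tsv", sep="\t")
    pd.DataFrame(
        {"component": res.loadings.index, "explained": res.explained}
    ).to_csv(out / "pca_explained.tsv", sep="\t", index=False)
    scores = pca_mod.project_scores(matrix.standardized(), res.loading(0))
    pc_ddws, _, _ = pca_mod.pc_ddw_discovery(
        scores, matrix.windows, aln, ref, seqs, k,
        min_count=min_count, alpha=alpha,
    )
    pd.DataFrame(
        {"word": sorted(pc_ddws)}
    ).to_csv(out / "pc1_ddws.tsv", sep="\t", index=False)
    with open(out / "report.yaml", "w") as fh:
        yaml.safe_dump(
            {
                "provenance": provenance,
                "factors": list(ds.factors),
                "genomes": [ref, other],
                "k": k,
                "n_ddws": {f: len(w) for f, w in ddws_by_factor.items()},
                "pc1_explained": float(res.explained[0]),
                "n_pc1_ddws": len(pc_ddws),
            },
            fh,
            sort_keys=True,
        )
    return out
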