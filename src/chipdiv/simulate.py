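"""Ground-truth synthetic datasets: two diverged genomes with an exact
pairwise alignment, planted motif words, latent coherent binding, and
sequenced-tag pileups for six factors.

The generator emulates the statistical structure the analysis assumes.  An
ancestral chromosome of peak regions separated by softmasked spacers is
mutated independently along two lineages (substitutions plus geometric
indels); the alignment is taken from the mutation history, so projection
has an exact oracle.  Log binding strength of factor f at peak p in
species s is

    log B[f,p,s] = mu + lam * c[p,s] + sum_w a[f,w] * n[w,p,s] + eps[f,p,s]

where n[w,p,s] counts instances of word w in the species' 100 bp core
window, and c[p,s] is a latent "chromatin" term shared by all factors:
a peak-level Gaussian plus a species-specific Gaussian increment plus a
fixed effect per occurrence of a common word (a TAGteam-like heptamer).
Tags are Poisson-sampled per peak with triangular positional falloff
around the true summit, giving pileups with a defined argmax.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .alignment import AlignmentBlock, PairwiseGenomeAlignment, write_maf
from .ddw import revcomp
from .signal import TagSet

__all__ = [
    "SyntheticConfig",
    "SyntheticDataset",
    "generate",
    "mutate_lineages",
    "expected_pairwise_identity",
    "expected_pc1_fraction",
    "count_word",
]

_DEFAULT_WORDS = {
    "BCD": "TAATCCC",
    "HB": "TTTTTTG",
    "KR": "AAGGGGT",
    "GT": "TTACGTA",
    "KNI": "AACTAGA",
    "CAD": "TTTATGG",
}

_LUT = np.frombuffer(b"ACGTacgt", dtype=np.uint8)


@dataclass
class SyntheticConfig:
    """Study-design parameters of the synthetic two-species experiment.

    Defaults emulate the target system: two genomes at ~5% per-lineage
    substitution divergence, six factors, thousands of peak regions whose
    100 bp cores carry planted heptamer words, a shared latent chromatin
    term, and log-scale Gaussian noise.
    """

    seed: int
    n_peaks: int = 2000
    window_len: int = 500  # bases; the 100 bp core sits centered inside
    core_len: int = 100
    spacer_len: int = 300  # softmasked intergenic spacer between regions
    chrom: str = "chr2L"
    genomes: tuple = ("mel", "yak")
    factors: tuple = ("BCD", "HB", "KR", "GT", "KNI", "CAD")
    factor_words: dict = field(default_factory=lambda: dict(_DEFAULT_WORDS))
    effect_size: float = 0.4  # log-units per instance of the factor's word
    common_word: str = "CAGGTAG"
    common_effect: float = 0.5  # log-units on the shared term per instance
    common_loading: float = 1.0  # weight of the shared term in every factor
    lambda_plant: float = 0.5  # Poisson planting rate per core per word
    lambda_common: float = 0.3
    p_sub: float = 0.05  # per-base substitution rate per lineage
    p_indel: float = 0.005  # per-site indel-event rate per lineage
    indel_geom_p: float = 0.5  # geometric length parameter (mean 2)
    sigma_c: float = 1.0  # sd of the shared peak-level term
    sigma_dc: float = 0.3  # sd of the species-specific increment
    sigma_eps: float = 0.3  # per-factor noise sd
    mu: float = 3.0  # baseline log binding
    shared_noise: bool = False  # same eps in both species (null device)
    depth_scale: float = 2.0  # expected tags per unit binding strength
    other_depth_factor: float = 0.6  # library-size imbalance of species 2
    fragment_length: int = 225
    tag_halfwidth: int = 150  # triangular falloff half-width around summit
    n_ap: int = 50  # designated developmental-target peaks
    ap_gene_offset: int = 200

    def validate(self):
        if self.window_len < self.core_len:
            raise ValueError("window_len must be >= core_len")
        for r in (self.p_sub, self.p_indel):
            if not 0 <= r <= 1:
                raise ValueError("rates must lie in [0, 1]")
        for s in (self.sigma_c, self.sigma_dc, self.sigma_eps):
            if s < 0:
                raise ValueError("standard deviations must be >= 0")
        if self.depth_scale <= 0 or self.fragment_length <= 0:
            raise ValueError("depth and fragment length must be positive")


def expected_pairwise_identity(p_sub: float) -> float:
    """Expected per-base identity between the two descendants under the
    uniform substitution model: both unchanged, or both hit and coinciding."""
    return (1 - p_sub) ** 2 + p_sub**2 / 3


def expected_pc1_fraction(cfg: SyntheticConfig) -> float:
    """Closed-form planted share of the first principal component for the
    standardized log-binding matrix of one species.

    Columns are equicorrelated with correlation rho = (shared variance) /
    (total variance); for p equicorrelated columns the leading eigenvalue
    fraction is (1 + (p-1) rho) / p.  Word-count variance is approximated
    as Poisson planting thinned by per-base survival of substitutions and
    indels, plus the random-occurrence background.
    """
    k = len(cfg.common_word)
    surv = ((1 - cfg.p_sub) * (1 - cfg.p_indel)) ** k
    bg = 2 * (cfg.core_len - k + 1) / 4**k
    var_word = cfg.effect_size**2 * (cfg.lambda_plant * surv + bg)
    var_common = cfg.common_effect**2 * (cfg.lambda_common * surv + bg)
    var_c = cfg.sigma_c**2 + cfg.sigma_dc**2 + var_common
    shared = cfg.common_loading**2 * var_c
    rho = shared / (shared + var_word + cfg.sigma_eps**2)
    p = len(cfg.factors)
    return (1 + (p - 1) * rho) / p


def count_word(text: str, word: str) -> int:
    """Overlapping occurrences of a word or its reverse complement in the
    non-softmasked (uppercase) parts of `text`."""
    rc = revcomp(word)
    k = len(word)
    n = 0
    for off in range(len(text) - k + 1):
        sub = text[off : off + k]
        if not sub.isupper():
            continue
        if sub == word or (rc != word and sub == rc):
            n += 1
    return n


_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i


def _word_codes(word: str) -> np.ndarray:
    return _BASE_CODE[np.frombuffer(word.upper().encode(), dtype=np.uint8)]


def _mutate_one(codes, rng, p_sub, p_indel, geom_p):
    """One lineage's substitutions and indel events on ancestor `codes`.

    Returns (derived per-site codes, deletion mask, insertions dict mapping
    site -> inserted codes placed immediately after that site, event count).
    """
    n = codes.size
    out = codes.copy()
    sub = rng.random(n) < p_sub
    nsub = int(sub.sum())
    if nsub:
        out[sub] = (out[sub] + rng.integers(1, 4, nsub).astype(np.uint8)) % 4
    deleted = np.zeros(n, dtype=bool)
    insertions: dict[int, np.ndarray] = {}
    ev_sites = np.flatnonzero(rng.random(n) < p_indel)
    n_ev = ev_sites.size
    if n_ev:
        is_ins = rng.random(n_ev) < 0.5
        lengths = rng.geometric(geom_p, n_ev)
        for site, ins, length in zip(ev_sites, is_ins, lengths):
            if ins:
                prev = insertions.get(int(site))
                new = rng.integers(0, 4, int(length)).astype(np.uint8)
                insertions[int(site)] = (
                    np.concatenate([prev, new]) if prev is not None else new
                )
            else:
                deleted[site : site + int(length)] = True
    return out, deleted, insertions, n_ev


def _assemble_rows(anc_mask, rows_sites, insertions_by_genome):
    """Build full aligned rows (ASCII bytes with gaps) from per-site columns
    and sparse insertions; also return per-site base-column indices.

    Insertions after site i occupy the columns between that site's base
    column and the next site's; at a site where both lineages inserted, the
    first genome's insertion columns precede the second's (the two are not
    aligned to each other).
    """
    n = anc_mask.size
    g0, g1 = list(rows_sites)
    ins_len = np.zeros(n, dtype=np.int64)
    for g in (g0, g1):
        for site, seg in insertions_by_genome[g].items():
            ins_len[site] += seg.size
    basecol = np.arange(n, dtype=np.int64)
    if ins_len.any():
        basecol += np.concatenate(([0], np.cumsum(ins_len)[:-1]))
    total_cols = n + int(ins_len.sum())
    rows = {g: np.full(total_cols, ord("-"), dtype=np.uint8) for g in (g0, g1)}
    for g in (g0, g1):
        rows[g][basecol] = rows_sites[g]
    for site, seg in insertions_by_genome[g0].items():
        here = basecol[site] + 1
        rows[g0][here : here + seg.size] = _LUT[seg + 4 * anc_mask[site]]
    for site, seg in insertions_by_genome[g1].items():
        lead = insertions_by_genome[g0].get(site)
        here = basecol[site] + 1 + (lead.size if lead is not None else 0)
        rows[g1][here : here + seg.size] = _LUT[seg + 4 * anc_mask[site]]
    return rows, basecol, total_cols


def mutate_lineages(
    ancestral: str,
    p_sub: float,
    p_indel: float,
    seed,
    geom_p: float = 0.5,
    labels: tuple = ("mel", "yak"),
    chrom: str = "chr2L",
):
    """Mutate an ancestral sequence independently along two lineages and
    return the descendants plus the exact alignment of their histories.

    Returns ``(seq_a, seq_b, alignment, info)`` where `info` records the
    per-lineage substitution and indel-event counts.  Lowercase (softmask)
    state of ancestral bases is inherited by descendants and insertions.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    raw = np.frombuffer(ancestral.encode("ascii"), dtype=np.uint8)
    mask = (raw >= 97) & (raw <= 122)
    codes = _BASE_CODE[np.where(mask, raw - 32, raw)]
    if (codes == 255).any():
        raise ValueError("ancestral sequence must be over {A,C,G,T} (any case)")
    rows_sites, ins_by_g, info = {}, {}, {}
    for g in labels:
        derived, deleted, insertions, n_ev = _mutate_one(
            codes, rng, p_sub, p_indel, geom_p
        )
        ascii_sites = _LUT[derived + 4 * mask.astype(np.uint8)]
        ascii_sites = np.where(deleted, np.uint8(ord("-")), ascii_sites)
        rows_sites[g] = ascii_sites
        ins_by_g[g] = insertions
        info[g] = {
            "n_sub": int(((derived != codes) & ~deleted).sum()),
            "n_indel_events": n_ev,
            "n_deleted_sites": int(deleted.sum()),
            "n_inserted_bases": int(sum(s.size for s in insertions.values())),
        }
    rows, basecol, total_cols = _assemble_rows(
        mask.astype(np.uint8), rows_sites, ins_by_g
    )
    texts = {g: rows[g].tobytes().decode("ascii") for g in labels}
    seqs = {g: texts[g].replace("-", "") for g in labels}
    block = AlignmentBlock(
        labels,
        {g: chrom for g in labels},
        {g: 0 for g in labels},
        {g: 1 for g in labels},
        texts,
    )
    aln = PairwiseGenomeAlignment([block])
    info["basecol"] = basecol
    info["rows"] = rows
    info["total_cols"] = total_cols
    return seqs[labels[0]], seqs[labels[1]], aln, info


@dataclass
class SyntheticDataset:
    """In-memory synthetic dataset plus ground truth."""

    config: SyntheticConfig
    genomes: dict  # label -> {chrom: sequence string, case = softmask}
    aln: PairwiseGenomeAlignment
    truth: pd.DataFrame
    tags: dict  # (factor, species) -> TagSet
    peak_records: dict  # species -> list of (chrom, start, end, summit)
    gene_table: pd.DataFrame

    @property
    def chrom_lengths(self) -> dict:
        return {
            g: {c: len(s) for c, s in chroms.items()}
            for g, chroms in self.genomes.items()
        }

    def strengths(self, factor: str, species: str) -> np.ndarray:
        return self.truth[f"B_{factor}_{species}"].to_numpy()

    def log_binding_matrix(self, species: str) -> pd.DataFrame:
        cfg = self.config
        return pd.DataFrame(
            {f: self.truth[f"logB_{f}_{species}"] for f in cfg.factors}
        )

    def windows(self, species: str) -> list:
        half = self.config.core_len // 2
        return [
            (self.config.chrom, s - half, s + half)
            for s in self.truth[f"summit_{species}"]
        ]

    def write(self, outdir):
        """Emit the dataset as plain-text files (FASTA, MAF, BED, TSV)."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        cfg = self.config
        stamp = f"chipdiv synthetic dataset seed={cfg.seed}"
        for g, chroms in self.genomes.items():
            with open(out / f"genome_{g}.fa", "w") as fh:
                for chrom, seq in chroms.items():
                    fh.write(f">{chrom} {stamp}\n")
                    for i in range(0, len(seq), 70):
                        fh.write(seq[i : i + 70] + "\n")
        write_maf(self.aln, out / "alignment.maf", header_comment=stamp)
        for (factor, species), ts in self.tags.items():
            with open(out / f"tags_{factor}_{species}.bed", "w") as fh:
                fh.write(f"# {stamp} factor={factor} species={species}\n")
                for row in ts.tags.itertuples(index=False):
                    if row.strand == "+":
                        s, e = row.pos, row.pos + 20
                    else:
                        s, e = row.pos - 19, row.pos + 1
                    fh.write(
                        f"{row.chrom}\t{max(0, s)}\t{e}\t.\t0\t{row.strand}\n"
                    )
        for species, recs in self.peak_records.items():
            for factor in cfg.factors:
                with open(out / f"peaks_{factor}_{species}.bed", "w") as fh:
                    fh.write(f"# {stamp} factor={factor} species={species}\n")
                    for i, (chrom, s, e, summit) in enumerate(recs):
                        fh.write(
                            f"{chrom}\t{s}\t{e}\tpeak{i}\t0\t+\t{summit - s}\n"
                        )
        self.gene_table.to_csv(out / "genes.tsv", sep="\t", index=False)
        self.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        with open(out / "config.yaml", "w") as fh:
            cfg_dict = dataclasses.asdict(cfg)
            cfg_dict["factors"] = list(cfg.factors)
            cfg_dict["genomes"] = list(cfg.genomes)
            yaml.safe_dump(cfg_dict, fh, sort_keys=True)


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Generate a full synthetic dataset from a seeded configuration."""
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    R = cfg.spacer_len + cfg.window_len
    n_sites = cfg.n_peaks * R + cfg.spacer_len
    codes = rng.integers(0, 4, n_sites).astype(np.uint8)
    mask = np.zeros(n_sites, dtype=bool)
    for i in range(cfg.n_peaks + 1):
        s = i * R
        mask[s : s + cfg.spacer_len] = True

    core_off = cfg.spacer_len + (cfg.window_len - cfg.core_len) // 2
    core_starts = np.array([i * R + core_off for i in range(cfg.n_peaks)])

    words = [cfg.factor_words[f] for f in cfg.factors] + [cfg.common_word]
    rates = [cfg.lambda_plant] * len(cfg.factors) + [cfg.lambda_common]
    for p in range(cfg.n_peaks):
        cs = int(core_starts[p])
        occupied = np.zeros(cfg.core_len, dtype=bool)
        for w, lam in zip(words, rates):
            wc = _word_codes(w)
            k = wc.size
            for _ in range(rng.poisson(lam)):
                for _try in range(10):
                    off = int(rng.integers(0, cfg.core_len - k + 1))
                    if not occupied[off : off + k].any():
                        codes[cs + off : cs + off + k] = wc
                        occupied[off : off + k] = True
                        break

    # mutate both lineages and take the alignment from the edit history
    anc_ascii = _LUT[codes + 4 * mask.astype(np.uint8)].tobytes().decode("ascii")
    seq_a, seq_b, history_aln, info = mutate_lineages(
        anc_ascii,
        cfg.p_sub,
        cfg.p_indel,
        rng,
        geom_p=cfg.indel_geom_p,
        labels=cfg.genomes,
        chrom=cfg.chrom,
    )
    basecol = info["basecol"]
    rows = info["rows"]
    total_cols = info["total_cols"]
    ga, gb = cfg.genomes
    nongap = {g: rows[g] != ord("-") for g in cfg.genomes}
    cnt = {
        g: np.concatenate(([0], np.cumsum(nongap[g]))) for g in cfg.genomes
    }

    def col_of(site: int) -> int:
        return int(basecol[site]) if site < n_sites else total_cols

    # split the history into one block per region so the map is
    # block-structured like a real orthology map
    bounds = [i * R for i in range(cfg.n_peaks + 1)] + [n_sites]
    blocks = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        c0, c1 = col_of(lo), col_of(hi)
        if c1 <= c0:
            continue
        starts = {g: int(cnt[g][c0]) for g in cfg.genomes}
        sizes = {g: int(cnt[g][c1] - cnt[g][c0]) for g in cfg.genomes}
        if any(sz == 0 for sz in sizes.values()):
            continue
        texts = {
            g: rows[g][c0:c1].tobytes().decode("ascii") for g in cfg.genomes
        }
        blocks.append(
            AlignmentBlock(
                cfg.genomes,
                {g: cfg.chrom for g in cfg.genomes},
                starts,
                {g: 1 for g in cfg.genomes},
                texts,
            )
        )
    aln = PairwiseGenomeAlignment(blocks)
    genomes = {ga: {cfg.chrom: seq_a}, gb: {cfg.chrom: seq_b}}

    # per-species core coordinates, summits, and word counts
    half = cfg.core_len // 2
    truth_cols: dict[str, list] = {"peak": list(range(cfg.n_peaks))}
    summits = {}
    counts: dict[tuple[str, str], np.ndarray] = {}
    all_words = sorted(set(words))
    for g in cfg.genomes:
        seq = genomes[g][cfg.chrom]
        cs_g = np.array(
            [cnt[g][col_of(int(s))] for s in core_starts], dtype=np.int64
        )
        ce_g = np.array(
            [cnt[g][col_of(int(s) + cfg.core_len)] for s in core_starts],
            dtype=np.int64,
        )
        sm = (cs_g + ce_g) // 2
        summits[g] = sm
        truth_cols[f"core_start_{g}"] = cs_g.tolist()
        truth_cols[f"core_end_{g}"] = ce_g.tolist()
        truth_cols[f"summit_{g}"] = sm.tolist()
        for w in all_words:
            counts[(w, g)] = np.array(
                [
                    count_word(seq[s - half : s + half], w)
                    for s in sm
                ]
            )
            truth_cols[f"n_{w}_{g}"] = counts[(w, g)].tolist()

    c_peak = rng.normal(0.0, cfg.sigma_c, cfg.n_peaks)
    c_species = {}
    for g in cfg.genomes:
        dc = rng.normal(0.0, cfg.sigma_dc, cfg.n_peaks)
        c_species[g] = (
            c_peak + dc + cfg.common_effect * counts[(cfg.common_word, g)]
        )
        truth_cols[f"c_{g}"] = c_species[g].tolist()

    logB = {}
    for f in cfg.factors:
        eps_shared = rng.normal(0.0, cfg.sigma_eps, cfg.n_peaks)
        for g in cfg.genomes:
            eps = (
                eps_shared
                if cfg.shared_noise
                else rng.normal(0.0, cfg.sigma_eps, cfg.n_peaks)
            )
            lb = (
                cfg.mu
                + cfg.common_loading * c_species[g]
                + cfg.effect_size * counts[(cfg.factor_words[f], g)]
                + eps
            )
            logB[(f, g)] = lb
            truth_cols[f"logB_{f}_{g}"] = lb.tolist()
            truth_cols[f"B_{f}_{g}"] = np.exp(lb).tolist()

    # tag sampling: Poisson depth proportional to strength, triangular falloff
    tags = {}
    for f in cfg.factors:
        for g in cfg.genomes:
            depth = cfg.depth_scale * (
                cfg.other_depth_factor if g == gb else 1.0
            )
            lam = depth * np.exp(logB[(f, g)])
            n_tags = rng.poisson(lam)
            total = int(n_tags.sum())
            centers = np.repeat(summits[g], n_tags) + np.rint(
                rng.triangular(
                    -cfg.tag_halfwidth, 0, cfg.tag_halfwidth, total
                )
            ).astype(np.int64)
            minus = rng.random(total) < 0.5
            L = cfg.fragment_length
            pos = np.where(minus, centers + L // 2, centers - L // 2)
            pos = np.clip(pos, 0, len(genomes[g][cfg.chrom]) - 1)
            tags[(f, g)] = TagSet(
                g,
                f,
                L,
                pd.DataFrame(
                    {
                        "chrom": cfg.chrom,
                        "pos": pos,
                        "strand": np.where(minus, "-", "+"),
                    }
                ),
            )

    peak_records = {
        g: [
            (cfg.chrom, int(s) - half, int(s) + half, int(s))
            for s in summits[g]
        ]
        for g in cfg.genomes
    }

    ap_idx = np.sort(rng.choice(cfg.n_peaks, min(cfg.n_ap, cfg.n_peaks), False))
    win_starts_ref = [
        int(cnt[ga][col_of(i * R + cfg.spacer_len)]) for i in ap_idx
    ]
    gene_table = pd.DataFrame(
        {
            "gene": [f"apg{i:03d}" for i in range(len(ap_idx))],
            "chrom": cfg.chrom,
            "strand": "+",
            "five_prime_pos": [
                max(0, ws - cfg.ap_gene_offset) for ws in win_starts_ref
            ],
        }
    )
    is_ap = np.zeros(cfg.n_peaks, dtype=bool)
    is_ap[ap_idx] = True
    truth_cols["is_ap_target"] = is_ap.tolist()

    truth = pd.DataFrame(truth_cols)
    return SyntheticDataset(
        cfg, genomes, aln, truth, tags, peak_records, gene_table
    )
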