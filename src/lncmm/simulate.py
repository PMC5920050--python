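"""Synthetic-cohort generator.

Emits a complete, fully synthetic stand-in for the study inputs: a gene
annotation (GTF) with anchor genes and lncRNAs placed at controlled genomic
distances, a negative-binomial fragment-count matrix with sample size
factors, mean-dependent dispersion and planted subgroup fold changes, a
per-sample molecular-annotation table reproducing the cohort's published
feature frequencies exactly, an array-style matrix derived from the counts,
and truth tables recording every planted effect.

The generative model matches what the analysis assumes:

* counts[g, s] ~ NB(mean = f_s * mu_g * 2**(delta_gs + l_gs),
  dispersion alpha(mu_g) = a0 + a1/mu_g), with f_s log-normal size factors;
* delta_gs is the planted log2 fold change when sample s carries the
  subgroup lesion assigned to gene g;
* l_gs is a latent log2-scale Gaussian term: members of a planted cis-pair
  share a per-sample factor scaled so the realized Pearson correlation of
  their log2(FPKM+1) profiles equals the requested rho (the scaling adds
  the NB measurement variance analytically, see :func:`_pair_scales`);
* the genome layout isolates every anchor "locus block" by more than the
  proximity window, so the true candidate-pair set is exactly the planted
  plus null pairs.

Everything is a pure function of the integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import GeneRecord, LNCRNA_BIOTYPES, write_gtf
from .expression import CountMatrix, fpkm

__all__ = [
    "SimulationConfig",
    "SyntheticDataset",
    "FEATURE_TABLE",
    "PRIMARY_SUBGROUPS",
    "simulate",
    "sim_annotation",
    "sim_counts",
    "sim_cohort",
    "sim_array",
    "null_config",
]

#: Published cohort feature frequencies: feature -> (positive, negative, NA).
FEATURE_TABLE: dict[str, tuple[int, int, int]] = {
    "HD": (8, 20, 2),
    "t(11;14)": (8, 22, 0),
    "t(4;14)": (7, 23, 0),
    "MAF-trx": (4, 26, 0),
    "del(17)": (3, 27, 0),
    "del(13)": (18, 12, 0),
    "1q-gain": (15, 13, 2),
    "NRAS": (3, 20, 7),
    "KRAS": (7, 16, 7),
    "BRAF": (4, 19, 7),
    "DIS3": (6, 17, 7),
    "P53": (2, 20, 8),
    "FAM46C": (1, 21, 8),
}

#: The four mutually exclusive molecular subgroups carrying planted effects.
PRIMARY_SUBGROUPS = ("HD", "t(11;14)", "t(4;14)", "MAF-trx")

_CHROMS = [str(i) for i in range(1, 23)] + ["X"]
_LN2SQ = np.log(2.0) ** 2


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort; defaults mirror the study conditions."""

    seed: int = 0
    n_samples: int = 30
    n_controls: int = 4
    feature_table: dict[str, tuple[int, int, int]] = field(
        default_factory=lambda: dict(FEATURE_TABLE)
    )
    subgroup_sizes: dict[str, int] = field(
        default_factory=lambda: {"HD": 8, "t(11;14)": 8, "t(4;14)": 7, "MAF-trx": 4}
    )
    # Genome / annotation
    n_coding_background: int = 400
    n_anchors_solo: int = 40
    n_pairs: int = 20
    n_null_anchors: int = 40
    lncs_per_null_anchor: int = 5
    n_de_per_subgroup: int = 30  # planted DE lncRNAs per primary subgroup
    n_lncrnas: int = 1500  # total lncRNA genes incl. pair members and DE set
    window: int = 4_000_000
    chrom_length: int = 1_000_000_000
    block_margin: int = 1_000_000
    pair_gaps: Sequence[int] | None = None  # default: drawn in [50 kb, 3.9 Mb]
    # Expression model
    de_log2fc: float = 2.0  # planted 4-fold changes
    frac_de_up: float = 0.5
    pair_rho: float = 0.8
    pair_bio_var: float = 1.5  # latent log2-scale variance of pair members
    disp_a0: float = 0.05
    disp_a1: float = 1.0
    size_factor_sigma: float = 0.3
    mean_log_coding: tuple[float, float] = (np.log(50.0), 1.2)
    mean_log_pair: tuple[float, float] = (np.log(500.0), 0.5)
    mean_log_de: tuple[float, float] = (np.log(100.0), 0.5)
    mean_log_decoy: tuple[float, float] = (0.7, 1.8)  # scarce, lncRNA-like
    length_log: tuple[float, float] = (np.log(1500.0), 0.6)
    # Array model
    array_sigma: float = 0.5
    array_detect_frac: float = 0.67

    def __post_init__(self) -> None:
        for feat, (pos, _neg, na) in self.feature_table.items():
            if pos + na > self.n_samples:
                raise ValueError(
                    f"feature {feat!r}: positive + NA ({pos}+{na}) exceeds "
                    f"n_samples ({self.n_samples})"
                )
        if not -1.0 < self.pair_rho < 1.0:
            raise ValueError("pair_rho must lie in (-1, 1)")
        if sum(self.subgroup_sizes.values()) > self.n_samples:
            raise ValueError("subgroup sizes exceed n_samples")

    @property
    def n_de_total(self) -> int:
        return self.n_de_per_subgroup * len(self.subgroup_sizes)

    @property
    def n_pair_lncs(self) -> int:
        return self.n_pairs + self.n_null_anchors * self.lncs_per_null_anchor

    @property
    def n_anchors(self) -> int:
        return self.n_pairs + self.n_null_anchors + self.n_anchors_solo

    @property
    def sample_ids(self) -> list[str]:
        return [f"MM_{i + 1:02d}" for i in range(self.n_samples)]

    @property
    def control_ids(self) -> list[str]:
        return [f"N_{i + 1:02d}" for i in range(self.n_controls)]


def null_config(seed: int = 0, **overrides) -> SimulationConfig:
    """A configuration with no planted effects (for calibration tests)."""
    defaults = dict(
        seed=seed,
        n_pairs=0,
        n_null_anchors=0,
        n_de_per_subgroup=0,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@dataclass
class SyntheticDataset:
    """All emitted synthetic inputs plus the planted-truth tables."""

    config: SimulationConfig
    annotation: list[GeneRecord]
    gene_lengths: pd.Series
    counts: CountMatrix
    control_counts: pd.DataFrame
    cohort: pd.DataFrame
    array: pd.DataFrame
    truth_de: pd.DataFrame  # gene_id, contrast, log2fc
    truth_pairs: pd.DataFrame  # anchor_id, lnc_id, rho, gap, kind
    anchor_symbols: list[str]

    @property
    def cohort_with_controls(self) -> pd.DataFrame:
        """Cohort table extended with control samples: every molecular
        feature negative plus a distinguishing 'control' flag column."""
        cohort = self.cohort.copy()
        cohort["control"] = "negative"
        ctrl = pd.DataFrame(
            "negative",
            index=self.config.control_ids,
            columns=cohort.columns,
        )
        ctrl["control"] = "positive"
        return pd.concat([cohort, ctrl])

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "gtf": outdir / "annotation.gtf",
            "lengths": outdir / "gene_lengths.tsv",
            "counts": outdir / "counts.tsv",
            "control_counts": outdir / "control_counts.tsv",
            "cohort": outdir / "cohort.tsv",
            "array": outdir / "array.tsv",
            "anchors": outdir / "anchor_genes.txt",
            "truth_de": outdir / "truth_de.tsv",
            "truth_pairs": outdir / "truth_pairs.tsv",
        }
        write_gtf(self.annotation, paths["gtf"])
        self.gene_lengths.to_csv(paths["lengths"], sep="\t", header=False)
        self.counts.to_tsv(paths["counts"])
        self.control_counts.to_csv(
            paths["control_counts"], sep="\t", index_label="gene_id"
        )
        self.cohort.to_csv(paths["cohort"], sep="\t", index_label="sample_id")
        self.array.to_csv(
            paths["array"], sep="\t", index_label="gene_id", float_format="%.6g"
        )
        paths["anchors"].write_text("".join(s + "\n" for s in self.anchor_symbols))
        self.truth_de.to_csv(paths["truth_de"], sep="\t", index=False)
        self.truth_pairs.to_csv(paths["truth_pairs"], sep="\t", index=False)
        return paths


# ---------------------------------------------------------------------------
# Annotation stage


class _Layout:
    """Sequential allocator of isolated locus blocks along chromosomes."""

    def __init__(self, cfg: SimulationConfig) -> None:
        self.cfg = cfg
        self.chrom_i = 0
        self.cursor = 1

    def place(self, span: int) -> tuple[str, int]:
        spacing = self.cfg.window + self.cfg.block_margin
        if span > self.cfg.chrom_length:
            raise ValueError(
                f"block of {span} bp does not fit on a chromosome of "
                f"{self.cfg.chrom_length} bp"
            )
        if self.cursor + span > self.cfg.chrom_length:
            self.chrom_i += 1
            self.cursor = 1
            if self.chrom_i >= len(_CHROMS):
                raise ValueError(
                    "annotation does not fit the configured genome; increase "
                    "chrom_length or reduce gene numbers"
                )
        chrom, start = _CHROMS[self.chrom_i], self.cursor
        self.cursor += span + spacing
        return chrom, start


def _draw_length(rng: np.random.Generator, cfg: SimulationConfig) -> int:
    mu, sd = cfg.length_log
    return max(200, int(rng.lognormal(mu, sd)))


def sim_annotation(
    cfg: SimulationConfig,
) -> tuple[list[GeneRecord], pd.Series, pd.DataFrame, list[str]]:
    """Build the synthetic gene annotation and the pair-geometry truth.

    Returns (records, gene_lengths, truth_pairs, anchor_symbols).  Planted
    and null cis-pairs sit in isolated blocks at their configured
    edge-to-edge gaps; all other genes are farther than the window from
    every anchor.
    """
    if cfg.n_lncrnas < cfg.n_pair_lncs + cfg.n_de_total:
        raise ValueError("n_lncrnas too small for pair members plus DE set")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    layout = _Layout(cfg)
    records: list[GeneRecord] = []
    lengths: dict[str, int] = {}
    lnc_biotypes = sorted(LNCRNA_BIOTYPES)

    def add_gene(gene_id: str, symbol: str, chrom: str, start: int, length: int,
                 biotype: str) -> GeneRecord:
        rec = GeneRecord(
            gene_id=gene_id,
            symbol=symbol,
            chrom=chrom,
            start=start,
            end=start + length - 1,
            strand="+" if rng.random() < 0.5 else "-",
            biotype=biotype,
            is_lncRNA=biotype in LNCRNA_BIOTYPES,
        )
        records.append(rec)
        lengths[gene_id] = length
        return rec

    anchor_symbols: list[str] = []
    pair_rows: list[dict] = []
    lnc_counter = 0
    anchor_counter = 0

    if cfg.pair_gaps is not None and len(cfg.pair_gaps) != cfg.n_pairs:
        raise ValueError("pair_gaps must have one gap per planted pair")

    def next_gap() -> int:
        return int(rng.integers(50_000, cfg.window - 100_000))

    def new_anchor_block(n_lncs: int, gaps: list[int], kind: str, rho: float) -> None:
        nonlocal anchor_counter, lnc_counter
        anchor_counter += 1
        a_len = _draw_length(rng, cfg)
        lnc_lens = [_draw_length(rng, cfg) for _ in range(n_lncs)]
        span = a_len + sum(g + l for g, l in zip(gaps, lnc_lens))
        chrom, start = layout.place(span)
        a_sym = f"MMG{anchor_counter:04d}"
        a = add_gene(f"SIMG{anchor_counter:06d}", a_sym, chrom, start, a_len,
                     "protein_coding")
        anchor_symbols.append(a_sym)
        cursor = a.end
        for g, l_len in zip(gaps, lnc_lens):
            lnc_counter += 1
            l = add_gene(
                f"SIML{lnc_counter:06d}",
                f"LNC{lnc_counter:05d}",
                chrom,
                cursor + g,
                l_len,
                lnc_biotypes[lnc_counter % len(lnc_biotypes)],
            )
            cursor = l.end
            # anchor-to-lncRNA edge gap; later lncRNAs of a block sit
            # farther out than their inter-gene gap
            actual_gap = max(0, l.start - a.end)
            if actual_gap <= cfg.window:
                pair_rows.append(
                    {
                        "anchor_id": a.gene_id,
                        "lnc_id": l.gene_id,
                        "rho": rho,
                        "gap": actual_gap,
                        "kind": kind,
                    }
                )

    for i in range(cfg.n_pairs):
        gap = int(cfg.pair_gaps[i]) if cfg.pair_gaps is not None else next_gap()
        if gap > cfg.window:
            raise ValueError(f"planted pair gap {gap} exceeds the window")
        new_anchor_block(1, [gap], "planted", cfg.pair_rho)
    for _ in range(cfg.n_null_anchors):
        gaps = sorted(next_gap() for _ in range(cfg.lncs_per_null_anchor))
        # Place consecutively; convert anchor-relative gaps to inter-gene gaps.
        inter = [gaps[0]] + [max(50_000, gaps[j] - gaps[j - 1])
                             for j in range(1, len(gaps))]
        new_anchor_block(len(inter), inter, "null", 0.0)
    for _ in range(cfg.n_anchors_solo):
        new_anchor_block(0, [], "solo", 0.0)

    for i in range(cfg.n_coding_background):
        length = _draw_length(rng, cfg)
        chrom, start = layout.place(length)
        add_gene(f"SIMC{i + 1:06d}", f"BG{i + 1:05d}", chrom, start, length,
                 "protein_coding")

    n_free_lncs = cfg.n_lncrnas - cfg.n_pair_lncs
    for _ in range(n_free_lncs):
        lnc_counter += 1
        length = _draw_length(rng, cfg)
        chrom, start = layout.place(length)
        add_gene(
            f"SIML{lnc_counter:06d}",
            f"LNC{lnc_counter:05d}",
            chrom,
            start,
            length,
            lnc_biotypes[lnc_counter % len(lnc_biotypes)],
        )

    truth_pairs = pd.DataFrame(
        pair_rows, columns=["anchor_id", "lnc_id", "rho", "gap", "kind"]
    )
    gene_lengths = pd.Series(lengths, name="length")
    return records, gene_lengths, truth_pairs, anchor_symbols


# ---------------------------------------------------------------------------
# Cohort stage


def sim_cohort(cfg: SimulationConfig) -> pd.DataFrame:
    """Per-sample molecular table reproducing the configured frequencies
    exactly.  The four primary subgroups occupy disjoint sample blocks (the
    planted-effect assignment); secondary lesions/mutations are assigned at
    random subject to their exact positive/negative/NA counts."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    samples = cfg.sample_ids
    n = cfg.n_samples
    cohort = pd.DataFrame("negative", index=samples, columns=list(cfg.feature_table))

    # Primary subgroups: consecutive blocks, mutually exclusive.
    offset = 0
    blocks: dict[str, list[str]] = {}
    for sg, size in cfg.subgroup_sizes.items():
        blocks[sg] = samples[offset : offset + size]
        offset += size
    for sg in cfg.subgroup_sizes:
        if sg not in cfg.feature_table:
            continue
        pos, _neg, na = cfg.feature_table[sg]
        if pos != len(blocks[sg]):
            raise ValueError(
                f"subgroup {sg!r}: block size {len(blocks[sg])} != "
                f"configured positive count {pos}"
            )
        cohort.loc[blocks[sg], sg] = "positive"
        if na:
            rest = [s for s in samples if s not in blocks[sg]]
            na_samples = rng.choice(rest, size=na, replace=False)
            cohort.loc[na_samples, sg] = "NA"

    for feat, (pos, neg, na) in cfg.feature_table.items():
        if feat in cfg.subgroup_sizes:
            continue
        if pos + neg + na != n:
            raise ValueError(f"feature {feat!r}: counts do not sum to {n}")
        perm = rng.permutation(samples)
        cohort.loc[perm[:pos], feat] = "positive"
        cohort.loc[perm[pos : pos + na], feat] = "NA"
        cohort.loc[perm[pos + na :], feat] = "negative"
    return cohort


# ---------------------------------------------------------------------------
# Counts stage


def _pair_scales(
    rho: float, bio_var: float, v_meas: np.ndarray
) -> tuple[float, np.ndarray]:
    """Latent scales for a pair: shared sd and per-member independent sd.

    Targets a realized Pearson correlation of *rho* on the log2 expression
    scale, where each member's profile carries its NB measurement variance
    v_meas[g] (log2^2 units) on top of the latent biology.  Both members are
    given the same total variance C = bio_var + mean(v_meas); the shared
    component has variance rho*C, so corr = rho*C / C = rho.
    """
    C = bio_var + float(np.mean(v_meas))
    shared_var = abs(rho) * C
    indep_var = np.maximum(C - v_meas - shared_var, 0.0)
    return float(np.sqrt(shared_var)), np.sqrt(indep_var)


def sim_counts(
    cfg: SimulationConfig,
    annotation: list[GeneRecord],
    gene_lengths: pd.Series,
    truth_pairs: pd.DataFrame,
    cohort: pd.DataFrame,
) -> tuple[CountMatrix, pd.DataFrame, pd.DataFrame]:
    """Draw the NB count matrix; returns (counts, control_counts, truth_de)."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 3]))
    gene_ids = [r.gene_id for r in annotation]
    gindex = {g: i for i, g in enumerate(gene_ids)}
    G = len(gene_ids)
    all_samples = cfg.sample_ids + cfg.control_ids
    S = len(all_samples)

    pair_members = set(truth_pairs["anchor_id"]) | set(truth_pairs["lnc_id"])
    lnc_ids = [r.gene_id for r in annotation if r.is_lncRNA]
    free_lncs = [g for g in lnc_ids if g not in pair_members]

    # Baseline means by gene class.
    mu = np.empty(G)
    de_pool = free_lncs[: cfg.n_de_total]
    de_set = set(de_pool)
    for rec in annotation:
        i = gindex[rec.gene_id]
        if rec.gene_id in pair_members:
            mlog, sdlog = cfg.mean_log_pair
        elif rec.gene_id in de_set:
            mlog, sdlog = cfg.mean_log_de
        elif rec.is_lncRNA:
            mlog, sdlog = cfg.mean_log_decoy
        else:
            mlog, sdlog = cfg.mean_log_coding
        mu[i] = rng.lognormal(mlog, sdlog)
    alpha = cfg.disp_a0 + cfg.disp_a1 / mu

    # Planted subgroup fold changes on the free lncRNA pool.
    log2_mult = np.zeros((G, S))
    de_rows: list[dict] = []
    pool_iter = iter(de_pool)
    n_up = int(round(cfg.n_de_per_subgroup * cfg.frac_de_up))
    for sg in cfg.subgroup_sizes:
        sg_samples = [
            s for s in cfg.sample_ids if cohort.loc[s, sg] == "positive"
        ]
        cols = [all_samples.index(s) for s in sg_samples]
        for j in range(cfg.n_de_per_subgroup):
            g = next(pool_iter)
            lfc = cfg.de_log2fc if j < n_up else -cfg.de_log2fc
            log2_mult[gindex[g], cols] += lfc
            de_rows.append({"gene_id": g, "contrast": sg, "log2fc": lfc})

    # Latent co-expression of cis-pairs (shared factor on the log2 scale).
    v_meas_all = (1.0 / mu + alpha) / _LN2SQ
    for _, row in truth_pairs.iterrows():
        ia, il = gindex[row["anchor_id"]], gindex[row["lnc_id"]]
        v_pair = v_meas_all[[ia, il]]
        # rho = 0 (null pairs) makes the shared scale vanish and hands the
        # whole variance budget to the independent terms.
        s_shared, s_indep = _pair_scales(row["rho"], cfg.pair_bio_var, v_pair)
        z = rng.standard_normal(S)
        sign = np.sign(row["rho"]) if row["rho"] != 0 else 1.0
        for k, (i, se) in enumerate(zip((ia, il), s_indep)):
            flip = sign if k == 1 else 1.0
            log2_mult[i] += flip * s_shared * z + se * rng.standard_normal(S)

    factors = rng.lognormal(0.0, cfg.size_factor_sigma, size=S)
    factors /= np.exp(np.mean(np.log(factors)))

    mean = factors[None, :] * mu[:, None] * np.exp2(log2_mult)
    r_nb = 1.0 / alpha
    p_nb = r_nb[:, None] / (r_nb[:, None] + mean)
    counts = rng.negative_binomial(np.broadcast_to(r_nb[:, None], mean.shape), p_nb)

    full = pd.DataFrame(counts, index=gene_ids, columns=all_samples)
    cm = CountMatrix(full[cfg.sample_ids], gene_lengths)
    control = full[cfg.control_ids]
    truth_de = pd.DataFrame(de_rows, columns=["gene_id", "contrast", "log2fc"])
    return cm, control, truth_de


# ---------------------------------------------------------------------------
# Array stage


def sim_array(
    cfg: SimulationConfig,
    counts: CountMatrix,
    control_counts: pd.DataFrame,
) -> pd.DataFrame:
    """Array-style matrix: per-gene affine transform of log2(FPKM+1) of the
    combined MM + control samples, plus Gaussian noise, restricted to a
    detectable gene subset."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 4]))
    combined = CountMatrix(
        pd.concat([counts.counts, control_counts.astype(np.int64)], axis=1),
        counts.gene_lengths,
    )
    expr = np.log2(fpkm(combined) + 1.0)
    n_detect = int(round(cfg.array_detect_frac * expr.shape[0]))
    detected = np.sort(
        rng.choice(expr.shape[0], size=max(n_detect, 1), replace=False)
    )
    sub = expr.iloc[detected]
    a = rng.uniform(0.5, 1.5, size=len(sub))
    b = rng.uniform(-2.0, 2.0, size=len(sub))
    noise = rng.normal(0.0, cfg.array_sigma, size=sub.shape)
    vals = sub.to_numpy() * a[:, None] + b[:, None] + noise
    return pd.DataFrame(vals, index=sub.index, columns=sub.columns)


def simulate(cfg: SimulationConfig) -> SyntheticDataset:
    """Run all generator stages and assemble the dataset."""
    annotation, gene_lengths, truth_pairs, anchor_symbols = sim_annotation(cfg)
    cohort = sim_cohort(cfg)
    counts, control_counts, truth_de = sim_counts(
        cfg, annotation, gene_lengths, truth_pairs, cohort
    )
    array = sim_array(cfg, counts, control_counts)
    return SyntheticDataset(
        config=cfg,
        annotation=annotation,
        gene_lengths=gene_lengths,
        counts=counts,
        control_counts=control_counts,
        cohort=cohort,
        array=array,
        truth_de=truth_de,
        truth_pairs=truth_pairs,
        anchor_symbols=anchor_symbols,
    )
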