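"""End-to-end orchestration: annotation -> expression filter -> per-contrast
NB differential expression -> signatures -> clustering + association ->
cis-pair discovery -> optional cross-platform validation.

A :class:`RunConfig` names the input files and every analysis threshold;
:func:`run_all` executes the stages in dependency order, writes each
stage's outputs under the run directory and returns a manifest with content
hashes so reruns can be verified bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotation as ann
from . import cispair as cp
from . import crossplatform as xp
from . import diffexp as de
from . import expression as ex
from . import unsup

__all__ = ["RunConfig", "run_all", "load_config"]

log = logging.getLogger("lncmm")


@dataclass
class RunConfig:
    """Input paths plus every named analysis parameter (study defaults)."""

    gtf: str
    counts: str
    lengths: str
    cohort: str
    anchors: str
    outdir: str
    array: str | None = None
    biotypes: list[str] = field(
        default_factory=lambda: sorted(ann.LNCRNA_BIOTYPES)
    )
    exclude_ambiguous: bool = True
    fdr: float = 0.01
    top_n: int = 500
    window: int = 4_000_000
    r_min: float = 0.4
    p_max: float = 0.01
    min_group: int = 3
    linkage: str = "average"
    n_clusters: int = 5
    pseudocount: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        for name in ("gtf", "counts", "lengths", "cohort", "anchors"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name} file not found: {p}")
        if self.array is not None and not Path(self.array).exists():
            raise FileNotFoundError(f"array file not found: {self.array}")
        if not 0 < self.fdr < 1:
            raise ValueError(f"fdr must be in (0,1): {self.fdr}")
        if not 0 < self.p_max < 1:
            raise ValueError(f"p_max must be in (0,1): {self.p_max}")
        if not 0 <= self.r_min < 1:
            raise ValueError(f"r_min must be in [0,1): {self.r_min}")
        if self.window <= 0 or self.top_n <= 0 or self.min_group < 1:
            raise ValueError("window, top_n and min_group must be positive")


def load_config(path: str | Path) -> RunConfig:
    with Path(path).open() as fh:
        raw = yaml.safe_load(fh)
    return RunConfig(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(cfg: RunConfig) -> dict:
    """Execute every stage; returns the run manifest (also written to disk)."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log.info("parameters: %s", {k: v for k, v in asdict(cfg).items()})

    # --- annotation
    records = ann.parse_gtf(cfg.gtf)
    records = ann.flag_ambiguous(records)
    lncs = ann.select_lncrnas(records, cfg.biotypes)
    if cfg.exclude_ambiguous:
        lncs = [r for r in lncs if not r.is_ambiguous]
    anchors = ann.load_anchor_genes(cfg.anchors, records)
    log.info(
        "annotation: %d genes, %d lncRNAs (%d ambiguous excluded), "
        "%d/%d anchors resolved",
        len(records), len(lncs),
        sum(r.is_ambiguous for r in ann.select_lncrnas(records, cfg.biotypes)),
        len(anchors.resolved), len(anchors),
    )
    ann.write_gene_table(records, outdir / "genes.tsv")
    ann.write_bed(lncs, outdir / "lncrnas.bed")

    # --- expression
    counts = ex.load_counts(cfg.counts, cfg.lengths)
    lnc_ids = [r.gene_id for r in lncs]
    lnc_counts = ex.filter_expressed(counts.subset_genes(lnc_ids))
    summary = ex.summarize(lnc_counts)
    (outdir / "expression_summary.json").write_text(
        json.dumps(summary.to_dict(), indent=2) + "\n"
    )
    log.info("expression: %d detectable lncRNAs", lnc_counts.shape[0])
    expr_all = np.log2(ex.fpkm(ex.filter_expressed(counts)) + 1.0)
    expr_lnc = np.log2(ex.fpkm(lnc_counts) + 1.0)

    # --- differential expression per contrast
    cohort = pd.read_csv(cfg.cohort, sep="\t", index_col=0).astype(str)
    contrasts = de.contrasts_from_cohort(cohort, min_group=cfg.min_group)
    tables: dict[str, pd.DataFrame] = {}
    for contrast in contrasts:
        model = de.NBDifferential(
            lnc_counts, contrast, pseudocount=cfg.pseudocount,
            min_group=cfg.min_group,
        )
        res = model.fit(fdr=cfg.fdr)
        tables[contrast.name] = res.table
        safe = contrast.name.replace("(", "").replace(")", "").replace(";", "_")
        res.to_tsv(outdir / f"de_{safe}.tsv")
        sig = res.signature
        log.info(
            "DE %s: %d up, %d down", contrast.name, len(sig.up), len(sig.down)
        )
    signatures = de.build_signatures(tables, fdr=cfg.fdr)
    union = de.signature_union(signatures)
    (outdir / "signature_union.txt").write_text(
        "".join(g + "\n" for g in union)
    )
    log.info("signatures: %d unique genes across contrasts", len(union))

    # --- unsupervised clustering + association
    fpkm_lnc = ex.fpkm(lnc_counts)
    top = unsup.top_variable(fpkm_lnc, n=cfg.top_n)
    clust_input = unsup.zscore_rows(expr_lnc.loc[top])
    dendro = unsup.hclust_pearson(clust_input, linkage=cfg.linkage)
    report = unsup.associate_features(
        dendro, cohort, k=min(cfg.n_clusters, dendro.n_leaves)
    )
    (outdir / "dendrogram.nwk").write_text(dendro.to_newick() + "\n")
    (outdir / "association.json").write_text(
        json.dumps(report.to_dict(), indent=2) + "\n"
    )
    log.info("clustering: MH stat %.3f (p=%.3g)", report.mh_stat, report.mh_p)

    # --- cis-pair discovery
    lnc_set = set(lnc_counts.gene_ids)
    lnc_records = [r for r in lncs if r.gene_id in lnc_set]
    candidates = cp.neighbors_within(anchors, lnc_records, window=cfg.window)
    correlated = cp.correlate_pairs(candidates, expr_all)
    kept = cp.filter_pairs(correlated, r_min=cfg.r_min, p_max=cfg.p_max)
    annotated = cp.intersect_de(kept, signatures)
    cp.write_pairs(annotated, outdir / "cis_pairs.tsv")
    log.info(
        "cis-pairs: %d candidates, %d pass |r|>%g & p<%g",
        len(candidates), len(kept), cfg.r_min, cfg.p_max,
    )

    # --- optional cross-platform validation
    if cfg.array is not None:
        array = pd.read_csv(cfg.array, sep="\t", index_col=0)
        pairing = xp.match_platforms(expr_lnc, array, union)
        xreport = xp.validate_clustering(
            array, union, cohort, linkage=cfg.linkage
        )
        (outdir / "crossplatform.json").write_text(
            json.dumps(
                {
                    "n_shared_genes": len(pairing.shared_genes),
                    "median_r": pairing.median_r,
                    "association": xreport.to_dict(),
                },
                indent=2,
            )
            + "\n"
        )
        log.info(
            "cross-platform: %d shared genes, median r %.3f, MH p %.3g",
            len(pairing.shared_genes), pairing.median_r, xreport.mh_p,
        )

    manifest = {
        "parameters": asdict(cfg),
        "outputs": {
            p.name: _sha256(p)
            for p in sorted(outdir.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
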