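"""Self-contained benchmark workflows on synthetic cohorts.

Each function generates its own data from an integer seed, runs one analysis
stage end to end, and returns the measured quantity: statistical calibration
(type-I error, realized FDR), parameter recovery (planted differential
lncRNAs, planted cis-pairs, planted subgroup structure), and the reference
cis-pair table summaries.  These drive both the test suite and the
reproduction script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import cispair as cp
from . import diffexp as de
from . import expression as ex
from . import unsup
from .annotation import AnchorGeneList
from .simulate import (
    FEATURE_TABLE,
    PRIMARY_SUBGROUPS,
    SimulationConfig,
    SyntheticDataset,
    null_config,
    simulate,
)

__all__ = [
    "DE_RECOVERY_CONDITION",
    "STRONG_CLUSTER_CONDITION",
    "NULL_CALIBRATION_CONDITION",
    "de_recovery",
    "cispair_screen",
    "clustering_ari",
    "null_type1_rate",
    "realized_fdr",
    "reference_table_stats",
    "cohort_frequencies",
]

#: Power/recovery condition: 4-fold planted changes, NB dispersion 0.05.
DE_RECOVERY_CONDITION = dict(disp_a0=0.05, disp_a1=0.0)

#: Strong-effect clustering condition: 16-fold changes on 50 scarce
#: lncRNAs per subgroup (large test statistics at low base means, as the
#: strongest subgroup markers show in practice).
STRONG_CLUSTER_CONDITION = dict(
    de_log2fc=4.0,
    n_de_per_subgroup=50,
    mean_log_de=(np.log(10.0), 0.8),
)

#: Null calibration is assessed at detectable expression levels; the Wald
#: test is intentionally conservative for near-zero genes.
NULL_CALIBRATION_CONDITION = dict(mean_log_decoy=(np.log(50.0), 1.0))


def _lnc_counts(ds: SyntheticDataset) -> ex.CountMatrix:
    lnc_ids = [r.gene_id for r in ds.annotation if r.is_lncRNA]
    return ex.filter_expressed(ds.counts.subset_genes(lnc_ids))


def _contrast(ds: SyntheticDataset, name: str = "HD") -> de.Contrast:
    return [c for c in de.contrasts_from_cohort(ds.cohort) if c.name == name][0]


def de_recovery(seed: int, fdr: float = 0.01) -> tuple[float, int]:
    """Fraction of planted HD lncRNAs called at the FDR cut, and the number
    of false positives, on one synthetic cohort."""
    ds = simulate(SimulationConfig(seed=seed, **DE_RECOVERY_CONDITION))
    lnc = _lnc_counts(ds)
    res = de.NBDifferential(lnc, _contrast(ds)).fit(fdr=fdr)
    sig = res.signature
    found = set(sig.up) | set(sig.down)
    truth = set(ds.truth_de.query("contrast == 'HD'").gene_id)
    return len(found & truth) / len(truth), len(found - truth)


def cispair_screen(seed: int) -> tuple[int, int]:
    """(planted pairs kept, null pairs kept) after the correlation filter."""
    ds = simulate(SimulationConfig(seed=seed))
    anchors = AnchorGeneList(
        symbols=ds.anchor_symbols,
        resolved={
            r.symbol: r
            for r in ds.annotation
            if r.symbol in set(ds.anchor_symbols)
        },
    )
    lncs = [r for r in ds.annotation if r.is_lncRNA]
    cand = cp.neighbors_within(anchors, lncs)
    expr = np.log2(ex.fpkm(ex.filter_expressed(ds.counts)) + 1.0)
    kept = {
        (p.gene_id, p.lnc_id)
        for p in cp.filter_pairs(cp.correlate_pairs(cand, expr))
    }
    planted = set(
        map(tuple, ds.truth_pairs.query("kind == 'planted'")[
            ["anchor_id", "lnc_id"]].values)
    )
    null = set(
        map(tuple, ds.truth_pairs.query("kind == 'null'")[
            ["anchor_id", "lnc_id"]].values)
    )
    return len(kept & planted), len(kept & null)


def clustering_ari(seed: int, top_n: int = 500, k: int = 5) -> float:
    """Adjusted Rand agreement between the dendrogram cut and the planted
    subgroups, over the samples belonging to the four subgroups."""
    from sklearn.metrics import adjusted_rand_score

    ds = simulate(SimulationConfig(seed=seed, **STRONG_CLUSTER_CONDITION))
    lnc = _lnc_counts(ds)
    f = ex.fpkm(lnc)
    top = unsup.top_variable(f, top_n)
    expr = unsup.zscore_rows(np.log2(f + 1.0).loc[top])
    labels = unsup.hclust_pearson(expr, linkage="average").cut(k)
    truth = pd.Series("none", index=ds.cohort.index)
    for sg in PRIMARY_SUBGROUPS:
        truth[ds.cohort[sg] == "positive"] = sg
    keep = truth.index[truth != "none"]
    return float(
        adjusted_rand_score(truth[keep], [labels[s] for s in keep])
    )


def null_type1_rate(seed: int, level: float = 0.05) -> float:
    """Fraction of null genes passing p < level in a no-effect cohort."""
    ds = simulate(null_config(seed=seed, **NULL_CALIBRATION_CONDITION))
    tab = de.nb_wald_test(_lnc_counts(ds), _contrast(ds))
    return float((tab.p_value < level).mean())


def realized_fdr(seed: int, nominal: float = 0.01) -> float:
    """Realized false-discovery proportion at the nominal BH cut on a
    signal-plus-null cohort (planted HD effects are the signal)."""
    ds = simulate(SimulationConfig(seed=seed))
    tab = de.nb_wald_test(_lnc_counts(ds), _contrast(ds))
    q = de.bh_adjust(tab.p_value.to_numpy())
    rejected = set(tab.index[q < nominal])
    truth = set(ds.truth_de.query("contrast == 'HD'").gene_id)
    return len(rejected - truth) / max(len(rejected), 1)


def reference_table_stats() -> dict:
    """Summaries of the packaged published cis-pair table."""
    ref = cp.load_reference_pairs()
    return {
        "n_pairs": int(len(ref)),
        "n_genes": int(ref["gene_symbol"].nunique()),
        "n_lncrnas": int(ref["lnc_symbol"].nunique()),
        "max_r": float(ref["r"].max()),
        "min_r": float(ref["r"].min()),
        "all_positive": bool((ref["r"] > 0).all()),
        "max_r_pair": "/".join(
            ref.loc[ref["r"].idxmax(), ["gene_symbol", "lnc_symbol"]]
        ),
        "min_r_pair": "/".join(
            ref.loc[ref["r"].idxmin(), ["gene_symbol", "lnc_symbol"]]
        ),
    }


def cohort_frequencies(seed: int = 0) -> dict[str, dict[str, int]]:
    """Feature frequencies of the default simulated cohort."""
    from .simulate import sim_cohort

    cohort = sim_cohort(SimulationConfig(seed=seed))
    out = {}
    for feat in FEATURE_TABLE:
        counts = cohort[feat].value_counts()
        out[feat] = {
            "positive": int(counts.get("positive", 0)),
            "negative": int(counts.get("negative", 0)),
            "NA": int(counts.get("NA", 0)),
        }
    return out
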