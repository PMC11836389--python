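"""oxRRBS-style 5mC/5hmC differential-methylation stage.

In an oxRRBS experiment every CpG is assayed twice: a conventional bisulfite
(BS) library reads 5mC + 5hmC together, and an oxidative-bisulfite (oxBS)
library reads 5mC alone.  Per replicate,

    beta_BS   = meth_BS / total_BS        (5mC + 5hmC)
    beta_oxBS = meth_oxBS / total_oxBS    (5mC)
    beta_5mC  = beta_oxBS
    beta_5hmC = max(0, beta_BS - beta_oxBS)   (clipped at 0)

Differentially (hydroxy)methylated positions (DMPs/DhMPs) are sites with
p < alpha and |delta beta| > delta between two conditions; hyper- vs
hypo-methylation is the sign of the treated-minus-control difference.
Annotation places each CpG in exactly one class relative to CpG islands
(island / shore <=2 kb / shelf 2-4 kb / open sea) and one functional-element
category (promoter, UTRs, exon, intron, enhancers, intergenic).

The expected input is a long-format count table (one row per site x
condition x replicate x assay) as read by :func:`notet.io.read_counts_table`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InsufficientDataError, InvalidParameterError

__all__ = [
    "CPG_CLASSES",
    "FEATURE_PRECEDENCE",
    "compute_betas",
    "call_dmps",
    "annotate_sites",
    "summarize_by_annotation",
    "CorrelationResult",
    "methylation_expression_correlation",
]

CPG_CLASSES = ("island", "shore", "shelf", "open_sea")

SHORE_BP = 2000
SHELF_BP = 4000

#: Feature precedence when a site overlaps several tracks (lower = stronger).
FEATURE_PRECEDENCE = {
    "promoter": 0,
    "5'UTR": 1,
    "3'UTR": 2,
    "exon": 3,
    "intron": 4,
    "enhancer": 5,
    "super_enhancer": 6,
}

_COUNT_COLS = ["chrom", "pos", "strand", "condition", "replicate", "assay", "meth", "total"]


def _pivot_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Wide table: one row per (chrom, pos, condition, replicate) with BS/oxBS counts."""
    missing = [c for c in _COUNT_COLS if c not in counts.columns]
    if missing:
        raise InvalidParameterError(f"count table missing columns: {missing}")
    wide = counts.pivot_table(
        index=["chrom", "pos", "condition", "replicate"],
        columns="assay",
        values=["meth", "total"],
        aggfunc="sum",
    )
    wide.columns = [f"{a}_{b.lower()}" for a, b in wide.columns]
    for col in ("meth_bs", "total_bs", "meth_oxbs", "total_oxbs"):
        if col not in wide.columns:
            wide[col] = np.nan
    return wide.reset_index()


def compute_betas(counts: pd.DataFrame, min_coverage: int = 1) -> pd.DataFrame:
    """Per-replicate beta values from paired BS/oxBS counts.

    Returns one row per (chrom, pos, condition, replicate) with beta_bs,
    beta_oxbs, beta_5mc, beta_5hmc plus ``masked`` (either assay below
    ``min_coverage``) and ``clipped`` (negative raw 5hmC clipped to 0) flags.
    Masked rows keep NaN betas.
    """
    if min_coverage < 1:
        raise InvalidParameterError("min_coverage must be >= 1")
    wide = _pivot_counts(counts)
    masked = (
        wide["total_bs"].fillna(0).lt(min_coverage)
        | wide["total_oxbs"].fillna(0).lt(min_coverage)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        beta_bs = wide["meth_bs"] / wide["total_bs"]
        beta_oxbs = wide["meth_oxbs"] / wide["total_oxbs"]
    raw_hmc = beta_bs - beta_oxbs
    out = wide[["chrom", "pos", "condition", "replicate",
                "meth_bs", "total_bs", "meth_oxbs", "total_oxbs"]].copy()
    out["beta_bs"] = beta_bs
    out["beta_oxbs"] = beta_oxbs
    out["beta_5mc"] = beta_oxbs
    out["beta_5hmc"] = raw_hmc.clip(lower=0.0)
    out["clipped"] = raw_hmc.lt(0).fillna(False)
    out["masked"] = masked
    beta_cols = ["beta_bs", "beta_oxbs", "beta_5mc", "beta_5hmc"]
    out.loc[masked, beta_cols] = np.nan
    return out


def _pooled_test(group_t: pd.DataFrame, group_c: pd.DataFrame, mark: str):
    """Pooled-count test for one site: Fisher exact (5mC) or delta-method z (5hmC)."""
    if mark == "5mC":
        mt, tt = group_t["meth_oxbs"].sum(), group_t["total_oxbs"].sum()
        mc, tc = group_c["meth_oxbs"].sum(), group_c["total_oxbs"].sum()
        if tt == 0 or tc == 0:
            return np.nan
        table = [[int(mt), int(tt - mt)], [int(mc), int(tc - mc)]]
        return float(stats.fisher_exact(table)[1])
    # 5hmC: difference of two binomial proportions per condition
    def diff_and_var(g):
        bm, bt = g["meth_bs"].sum(), g["total_bs"].sum()
        om, ot = g["meth_oxbs"].sum(), g["total_oxbs"].sum()
        if bt == 0 or ot == 0:
            return np.nan, np.nan
        pb, po = bm / bt, om / ot
        var = pb * (1 - pb) / bt + po * (1 - po) / ot
        return pb - po, var
    dt, vt = diff_and_var(group_t)
    dc, vc = diff_and_var(group_c)
    if np.isnan(dt) or np.isnan(dc):
        return np.nan
    se = np.sqrt(vt + vc)
    if se == 0:
        return 1.0 if dt == dc else 0.0
    z = (dt - dc) / se
    return float(2.0 * stats.norm.sf(abs(z)))


def call_dmps(
    counts: pd.DataFrame,
    control: str,
    treated: str,
    mark: str = "5mC",
    alpha: float = 0.05,
    delta: float = 0.1,
    test: str = "fisher_pooled",
    min_coverage: int = 10,
) -> pd.DataFrame:
    """Call differentially (hydroxy)methylated positions between two conditions.

    Parameters
    ----------
    counts : DataFrame
        Long-format count table (see module docstring).
    control, treated : str
        Condition labels; delta beta is treated minus control.
    mark : {"5mC", "5hmC"}
    alpha, delta : float
        Significance and effect-size thresholds; a site is called hyper
        (hypo) when p < alpha and delta_beta > delta (< -delta).
    test : {"fisher_pooled", "welch"}
        ``fisher_pooled`` pools counts across replicates and applies an exact
        count test (the default; appropriate for 1-2 replicates).  ``welch``
        is a two-sample Welch t-test on per-replicate betas (>= 2 replicates
        per condition).
    min_coverage : int
        Replicates with either assay below this total are masked.

    Returns
    -------
    DataFrame with chrom, pos, mark, delta_beta, p_value, fdr, call and the
    per-condition mean betas.  Sites with no usable data in either condition
    are excluded.
    """
    if mark not in ("5mC", "5hmC"):
        raise InvalidParameterError(f"mark must be 5mC or 5hmC, got {mark!r}")
    if test not in ("fisher_pooled", "welch"):
        raise InvalidParameterError(f"unknown test {test!r}")
    betas = compute_betas(counts, min_coverage=min_coverage)
    betas = betas[~betas["masked"]]
    betas = betas[betas["condition"].isin([control, treated])]
    if betas.empty:
        import warnings

        warnings.warn("no covered sites overlap the two conditions", stacklevel=2)
        return pd.DataFrame(
            columns=["chrom", "pos", "mark", "beta_control", "beta_treated",
                     "delta_beta", "p_value", "fdr", "call"]
        )
    beta_col = "beta_5mc" if mark == "5mC" else "beta_5hmc"

    rows = []
    for (chrom, pos), site in betas.groupby(["chrom", "pos"], sort=True):
        g_c = site[site["condition"] == control]
        g_t = site[site["condition"] == treated]
        if g_c.empty or g_t.empty:
            continue
        mean_c = g_c[beta_col].mean()
        mean_t = g_t[beta_col].mean()
        d = mean_t - mean_c
        if test == "welch":
            if len(g_c) < 2 or len(g_t) < 2:
                continue
            if g_c[beta_col].var() == 0 and g_t[beta_col].var() == 0:
                p = 1.0 if d == 0 else 0.0
            else:
                p = float(stats.ttest_ind(g_t[beta_col], g_c[beta_col],
                                          equal_var=False).pvalue)
        else:
            p = _pooled_test(g_t, g_c, mark)
        rows.append((chrom, pos, mean_c, mean_t, d, p))

    out = pd.DataFrame(
        rows, columns=["chrom", "pos", "beta_control", "beta_treated",
                       "delta_beta", "p_value"]
    )
    out.insert(2, "mark", mark)
    valid = out["p_value"].notna()
    out["fdr"] = np.nan
    if valid.any():
        out.loc[valid, "fdr"] = multipletests(out.loc[valid, "p_value"],
                                              method="fdr_bh")[1]
    sig = valid & (out["p_value"] < alpha)
    out["call"] = "none"
    out.loc[sig & (out["delta_beta"] > delta), "call"] = "hyper"
    out.loc[sig & (out["delta_beta"] < -delta), "call"] = "hypo"
    return out


def _island_class(pos: int, starts: np.ndarray, ends: np.ndarray) -> str:
    """CpG class of a position against sorted, per-chromosome island intervals."""
    i = np.searchsorted(starts, pos, side="right") - 1
    dist = None
    if i >= 0:
        if pos < ends[i]:
            return "island"
        dist = pos - (ends[i] - 1)
    if i + 1 < len(starts):
        d2 = starts[i + 1] - pos
        dist = d2 if dist is None else min(dist, d2)
    if dist is None:
        return "open_sea"
    if dist <= SHORE_BP:
        return "shore"
    if dist <= SHELF_BP:
        return "shelf"
    return "open_sea"


def annotate_sites(
    sites: pd.DataFrame,
    cpg_islands: pd.DataFrame,
    features: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Attach CpG class and functional-element annotations to sites.

    Parameters
    ----------
    sites : DataFrame with ``chrom`` and ``pos`` columns (0-based positions).
    cpg_islands : DataFrame with chrom/start/end (BED, 0-based half-open).
    features : optional DataFrame with chrom/start/end/label.

    Returns a copy of ``sites`` with ``cpg_class`` (island / shore / shelf /
    open_sea), ``feature`` (highest-precedence overlapping label, else
    ``intergenic``), ``in_enhancer`` / ``in_super_enhancer`` overlap flags and
    ``annotated`` (False for chromosomes absent from the island track, where
    the open_sea class is a default rather than a measured distance).
    """
    for col in ("chrom", "pos"):
        if col not in sites.columns:
            raise InvalidParameterError(f"sites table missing column {col!r}")
    islands_by_chrom = {}
    for chrom, grp in cpg_islands.groupby("chrom"):
        grp = grp.sort_values("start")
        islands_by_chrom[chrom] = (
            grp["start"].to_numpy(dtype=np.int64),
            grp["end"].to_numpy(dtype=np.int64),
        )
    trees: dict[str, IntervalTree] = {}
    if features is not None and len(features):
        for chrom, grp in features.groupby("chrom"):
            trees[chrom] = IntervalTree.from_tuples(
                (int(s), int(e), lab)
                for s, e, lab in zip(grp["start"], grp["end"], grp["label"])
                if e > s
            )

    out = sites.copy()
    classes, feats, enh, senh, annotated = [], [], [], [], []
    for chrom, pos in zip(out["chrom"], out["pos"]):
        pos = int(pos)
        if chrom in islands_by_chrom:
            starts, ends = islands_by_chrom[chrom]
            classes.append(_island_class(pos, starts, ends))
            annotated.append(True)
        else:
            classes.append("open_sea")
            annotated.append(False)
        labels = set()
        if chrom in trees:
            labels = {iv.data for iv in trees[chrom][pos]}
        enh.append("enhancer" in labels)
        senh.append("super_enhancer" in labels)
        if labels:
            feats.append(min(labels, key=lambda l: FEATURE_PRECEDENCE.get(l, 50)))
        else:
            feats.append("intergenic")
    out["cpg_class"] = classes
    out["feature"] = feats
    out["in_enhancer"] = enh
    out["in_super_enhancer"] = senh
    out["annotated"] = annotated
    return out


def summarize_by_annotation(dmps: pd.DataFrame) -> pd.DataFrame:
    """Counts and fractions of hyper/hypo calls per CpG class and per feature.

    ``dmps`` must carry ``call``, ``cpg_class`` and ``feature`` columns (the
    output of :func:`call_dmps` passed through :func:`annotate_sites`).
    Fractions are of all hyper+hypo calls, so within each category type the
    fractions sum to 1 (when any calls exist).
    """
    for col in ("call", "cpg_class", "feature"):
        if col not in dmps.columns:
            raise InvalidParameterError(f"dmps table missing column {col!r}")
    called = dmps[dmps["call"].isin(["hyper", "hypo"])]
    n_calls = len(called)
    rows = []
    for kind, values in (("cpg_class", CPG_CLASSES),
                         ("feature", tuple(FEATURE_PRECEDENCE) + ("intergenic",))):
        cats = list(values)
        for extra in called[kind].unique():
            if extra not in cats:
                cats.append(extra)
        for cat in cats:
            sub = called[called[kind] == cat]
            n_hyper = int((sub["call"] == "hyper").sum())
            n_hypo = int((sub["call"] == "hypo").sum())
            frac = (n_hyper + n_hypo) / n_calls if n_calls else 0.0
            rows.append((kind, cat, n_hyper, n_hypo, frac))
    return pd.DataFrame(
        rows, columns=["category_type", "category", "n_hyper", "n_hypo", "fraction"]
    )


@dataclass(frozen=True)
class CorrelationResult:
    """Spearman rank correlation between promoter betas and expression."""

    rho: float
    p_value: float
    n: int


def methylation_expression_correlation(promoter_betas, expression) -> CorrelationResult:
    """Spearman correlation of per-gene promoter beta vs expression level.

    Both arguments map gene -> value (dict or Series); only shared genes are
    used and at least 10 are required.
    """
    b = pd.Series(promoter_betas, dtype=float)
    e = pd.Series(expression, dtype=float)
    shared = b.index.intersection(e.index)
    if len(shared) < 10:
        raise InsufficientDataError(
            f"only {len(shared)} shared genes; need at least 10"
        )
    rho, p = stats.spearmanr(b.loc[shared], e.loc[shared])
    return CorrelationResult(rho=float(rho), p_value=float(p), n=len(shared))
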