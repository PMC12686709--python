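"""Differential polyadenylation statistics.

Quantifies per-PAC usage within genes, tests differential gene
expression (negative-binomial Wald test on normalized counts) and
differential PAC usage (Welch t-test on variance-stabilized replicate
usages), computes the distal polyA-usage index (PDU) and its
between-condition difference, and classifies gene-level APA events as
lengthening, shortening, "both", or splicing.

PDU definition
--------------
For a gene whose retained PACs all lie in the last exon, order them by
exonic distance from the stop codon d_1 <= ... <= d_K and weight each
PAC linearly in distance, w_i = (d_i - d_1) / (d_K - d_1). With
condition-mean usages u_i (renormalized over the retained PACs),

    PDU = sum_i u_i * w_i

so the most proximal PAC contributes 0, the most distal 1, and the
two-PAC case reduces exactly to LU / (LU + SU), the long-isoform share.
delta PDU = PDU(treated) - PDU(control); positive values mean 3'-UTR
lengthening.

The gene-expression and usage tests are deliberately lightweight
stand-ins for a full GLM framework: method-of-moments dispersion with a
Wald test, and Welch t on arcsine-square-root transformed usage, both
with Benjamini-Hochberg adjustment. Acceptance is calibration (false
call rates at the nominal level), not parity with any particular
implementation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import PipelineConfig
from .clusters import REGION_INTRON, REGION_UTR3

CATEGORY_LENGTHENING = "lengthening"
CATEGORY_SHORTENING = "shortening"
CATEGORY_BOTH = "both"
CATEGORY_SPLICING = "splicing"


class UndefinedStatistic(ValueError):
    """Raised when a statistic is requested outside its domain."""


@dataclass
class APAEvent:
    """Gene-level APA verdict."""

    gene_id: str
    category: str
    delta_pdu: float
    pdu_control: float
    pdu_treated: float
    pac_records: pd.DataFrame = field(repr=False)


def gene_counts(pacs: pd.DataFrame, samples: list[str]) -> pd.DataFrame:
    """Per-gene per-sample counts: sum of the gene's PAC counts.

    PACs without a gene assignment are dropped; genes with no PACs are
    absent from the table.
    """
    assigned = pacs.dropna(subset=["gene_id"])
    if assigned.empty:
        return pd.DataFrame(columns=samples)
    table = assigned.groupby("gene_id")[samples].sum()
    table.index.name = "gene_id"
    return table


def size_factors(counts: pd.DataFrame, min_reference_genes: int = 10) -> pd.Series:
    """Median-of-ratios sample scaling factors.

    The reference is the per-gene geometric mean over genes with no
    zero counts; each sample's factor is the median ratio of its counts
    to the reference. When fewer than ``min_reference_genes`` zero-free
    genes exist, falls back to total-count ratios (normalized to
    geometric mean 1).
    """
    if counts.empty or not (counts.to_numpy() > 0).any():
        raise UndefinedStatistic("size factors undefined for an all-zero table")
    mat = counts.to_numpy(dtype=float)
    nonzero = (mat > 0).all(axis=1)
    if nonzero.sum() >= min_reference_genes:
        sub = mat[nonzero]
        ref = np.exp(np.log(sub).mean(axis=1, keepdims=True))
        factors = np.median(sub / ref, axis=0)
    else:
        totals = mat.sum(axis=0)
        if (totals == 0).any():
            raise UndefinedStatistic("a sample has zero total counts")
        factors = totals / np.exp(np.log(totals).mean())
    return pd.Series(factors, index=counts.columns, name="size_factor")


def _split_samples(design: pd.DataFrame) -> tuple[str, str, list[str], list[str]]:
    conditions = list(pd.unique(design["condition"]))
    if len(conditions) != 2:
        raise ValueError(f"expected exactly 2 conditions, got {conditions}")
    ctrl, trt = conditions
    a = design.loc[design["condition"] == ctrl, "sample_id"].tolist()
    b = design.loc[design["condition"] == trt, "sample_id"].tolist()
    return ctrl, trt, a, b


def test_gene_de(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    config: PipelineConfig,
    dispersion_floor: float = 0.01,
) -> pd.DataFrame:
    """Per-gene differential expression between two conditions.

    Counts are scaled by median-of-ratios size factors; the log2 fold
    change (treated over control) gets a Wald test whose standard error
    uses a method-of-moments negative-binomial dispersion (pooled
    within-condition, floored). P-values are BH-adjusted; a gene is
    ``called`` iff its fold change strictly exceeds ``fc_min`` in either
    direction and padj < ``padj_max``.
    """
    _, _, ctrl_samples, trt_samples = _split_samples(design)
    n1, n2 = len(ctrl_samples), len(trt_samples)
    if min(n1, n2) < 2:
        raise ValueError(
            "differential expression needs >=2 replicates per condition; "
            "run in descriptive mode (usage tables) instead"
        )
    sf = size_factors(counts)
    norm = counts / sf
    a = norm[ctrl_samples].to_numpy(dtype=float)
    b = norm[trt_samples].to_numpy(dtype=float)
    mu1, mu2 = a.mean(axis=1), b.mean(axis=1)
    s2w = ((n1 - 1) * a.var(axis=1, ddof=1) + (n2 - 1) * b.var(axis=1, ddof=1)) / (
        n1 + n2 - 2
    )
    mu_bar = np.maximum((mu1 * n1 + mu2 * n2) / (n1 + n2), 1e-8)
    alpha = np.maximum(dispersion_floor, (s2w - mu_bar) / mu_bar**2)

    eps = 0.5  # pseudocount keeps zero-count conditions finite
    log2fc = np.log2((mu2 + eps) / (mu1 + eps))
    v1 = (mu1 + alpha * mu1**2) / n1
    v2 = (mu2 + alpha * mu2**2) / n2
    se = np.sqrt(v1 / (mu1 + eps) ** 2 + v2 / (mu2 + eps) ** 2) / np.log(2)
    wald = np.where(se > 0, log2fc / np.where(se > 0, se, 1.0), 0.0)
    # few replicates: a t reference absorbs the dispersion-estimate noise
    pvals = 2 * stats.t.sf(np.abs(wald), df=n1 + n2 - 2)
    padj = multipletests(pvals, method="fdr_bh")[1]
    fold = np.exp2(np.abs(log2fc))
    out = pd.DataFrame(
        {
            "gene_id": counts.index,
            "log2fc": log2fc,
            "fold_change": fold,
            "p": pvals,
            "padj": padj,
            "called": (fold > config.fc_min) & (padj < config.padj_max),
        }
    ).set_index("gene_id")
    return out


def usage_table(
    pacs: pd.DataFrame, samples: list[str]
) -> pd.DataFrame:
    """Per-PAC per-sample usage (PAC count / gene total in that sample).

    Samples where the gene total is zero yield missing usage. Adds the
    pooled-mean ``occupancy`` per PAC (mean usage over samples with a
    nonzero gene total).
    """
    assigned = pacs.dropna(subset=["gene_id"]).copy()
    totals = assigned.groupby("gene_id")[samples].transform("sum")
    usage = assigned[samples] / totals.where(totals > 0)
    usage.columns = [f"usage_{s}" for s in samples]
    out = pd.concat(
        [assigned[["pac_id", "gene_id", "region", "exon_index",
                   "dist_from_stop"]], usage],
        axis=1,
    )
    out["occupancy"] = usage.mean(axis=1, skipna=True).fillna(0.0)
    return out.reset_index(drop=True)


def test_pac_usage(
    usage: pd.DataFrame,
    design: pd.DataFrame,
    config: PipelineConfig,
) -> pd.DataFrame:
    """Per-PAC differential usage between two conditions.

    Only PACs passing the occupancy threshold, within genes carrying at
    least two such PACs, are tested. The fractional change is the
    difference of condition-mean usages (treated minus control,
    percentage points); the p-value comes from a Welch t-test on
    arcsine-square-root transformed replicate usages, BH-adjusted over
    all tested PACs. A PAC is significant iff padj < ``padj_max`` and
    |fractional change| >= ``usage_change_min`` (inclusive). PACs with
    fewer than two informative replicates in either arm are untested
    (p = 1).
    """
    _, _, ctrl_samples, trt_samples = _split_samples(design)
    ctrl_cols = [f"usage_{s}" for s in ctrl_samples]
    trt_cols = [f"usage_{s}" for s in trt_samples]

    eligible_genes = (
        usage.loc[usage["occupancy"] >= config.occupancy_min]
        .groupby("gene_id")["pac_id"]
        .count()
    )
    eligible_genes = set(eligible_genes.index[eligible_genes >= 2])
    tested = usage.loc[
        (usage["occupancy"] >= config.occupancy_min)
        & usage["gene_id"].isin(eligible_genes)
    ].copy()
    if tested.empty:
        return pd.DataFrame(
            columns=["pac_id", "gene_id", "frac_change", "p", "padj",
                     "significant", "tested"]
        )

    a = tested[ctrl_cols].to_numpy(dtype=float)
    b = tested[trt_cols].to_numpy(dtype=float)
    frac_change = np.nanmean(b, axis=1) - np.nanmean(a, axis=1)

    ta, tb = np.arcsin(np.sqrt(np.clip(a, 0, 1))), np.arcsin(np.sqrt(np.clip(b, 0, 1)))
    pvals = np.ones(len(tested))
    informative = (np.sum(~np.isnan(ta), axis=1) >= 2) & (
        np.sum(~np.isnan(tb), axis=1) >= 2
    )
    if informative.any():
        res = stats.ttest_ind(
            ta[informative], tb[informative], axis=1,
            equal_var=False, nan_policy="omit",
        )
        p = np.asarray(res.pvalue, dtype=float)
        p[~np.isfinite(p)] = 1.0  # zero within-arm variance etc.
        pvals[informative] = p
    padj = multipletests(pvals, method="fdr_bh")[1]
    out = tested[["pac_id", "gene_id"]].copy()
    out["frac_change"] = frac_change
    out["p"] = pvals
    out["padj"] = padj
    out["tested"] = informative
    out["significant"] = (padj < config.padj_max) & (
        np.abs(frac_change) >= config.usage_change_min
    )
    return out.reset_index(drop=True)


def pdu_from_usage(usages: np.ndarray, dists: np.ndarray) -> float:
    """PDU of one gene from PAC usages and stop-codon distances.

    ``usages`` need not be normalized; they are renormalized over the
    given PACs. Weights are linear in distance between the most
    proximal (0) and most distal (1) PAC.
    """
    usages = np.asarray(usages, dtype=float)
    dists = np.asarray(dists, dtype=float)
    if usages.shape != dists.shape or usages.size < 2:
        raise UndefinedStatistic("PDU needs >=2 PACs with distances")
    if np.any(np.isnan(dists)):
        raise UndefinedStatistic("PDU needs exonic stop-codon distances")
    total = usages.sum()
    if total <= 0:
        raise UndefinedStatistic("PDU undefined for all-zero usage")
    span = dists.max() - dists.min()
    if span <= 0:
        raise UndefinedStatistic("PDU undefined when all PACs are equidistant")
    weights = (dists - dists.min()) / span
    return float(np.dot(usages / total, weights))


def compute_pdu(
    gene_usage: pd.DataFrame,
    design: pd.DataFrame,
    condition: str,
    config: PipelineConfig,
) -> float:
    """Condition-level PDU of one gene from its usage records.

    Retains occupancy-passing PACs (all must be in the last exon,
    3' of the stop codon), averages replicate usages within the
    condition, renormalizes over the retained PACs and applies the
    distance weighting. Raises :class:`UndefinedStatistic` when fewer
    than two PACs qualify.
    """
    samples = design.loc[design["condition"] == condition, "sample_id"]
    if samples.empty:
        raise UndefinedStatistic(f"no samples for condition {condition!r}")
    retained = gene_usage.loc[gene_usage["occupancy"] >= config.occupancy_min]
    if len(retained) < 2:
        raise UndefinedStatistic("PDU needs >=2 occupancy-passing PACs")
    if not (retained["region"] == REGION_UTR3).all():
        raise UndefinedStatistic("PDU defined only for last-exon 3'-UTR PACs")
    cols = [f"usage_{s}" for s in samples]
    mean_usage = retained[cols].mean(axis=1, skipna=True).to_numpy()
    return pdu_from_usage(mean_usage, retained["dist_from_stop"].to_numpy())


def pdui_from_intensities(
    lu: float, su: float, loading_lu: float = 1.0, loading_su: float = 1.0
) -> float:
    """PDUI from two isoform band intensities, LU' / (LU' + SU').

    Intensities are first divided by their loading-control intensities
    (e.g. 18S rRNA band of the same lane).
    """
    if min(lu, su) < 0 or min(loading_lu, loading_su) <= 0:
        raise UndefinedStatistic("intensities must be >=0 with positive loading")
    lu_n, su_n = lu / loading_lu, su / loading_su
    if lu_n + su_n <= 0:
        raise UndefinedStatistic("PDUI undefined when LU + SU is zero")
    return lu_n / (lu_n + su_n)


def classify_event(
    gene_id: str,
    gene_usage: pd.DataFrame,
    pac_tests: pd.DataFrame,
    design: pd.DataFrame,
    config: PipelineConfig,
) -> APAEvent | None:
    """Classify one gene's APA event, or return None when there is none.

    Retains occupancy-passing PACs. No event unless >=2 are retained
    and >=1 is significantly shifted. Category:

    - ``splicing`` when the retained PACs span more than one exon or
      include an intronic PAC;
    - otherwise (all in the last exon) ``both`` when a strictly
      internal PAC among >=3 retained is significant;
    - otherwise ``lengthening``/``shortening`` by the sign of delta
      PDU; an exact zero falls back to the sign of the distal-most
      significant PAC's usage change, and a still-undecided gene is no
      event.
    """
    if "region" not in gene_usage.columns:
        raise ValueError("usage records lack annotation; annotate PACs first")
    retained = gene_usage.loc[
        gene_usage["occupancy"] >= config.occupancy_min
    ].copy()
    if len(retained) < 2:
        return None
    sig_map = pac_tests.set_index("pac_id")["significant"]
    chg_map = pac_tests.set_index("pac_id")["frac_change"]
    retained["significant"] = (
        retained["pac_id"].map(sig_map).fillna(False).astype(bool)
    )
    retained["frac_change"] = retained["pac_id"].map(chg_map)
    if not retained["significant"].any():
        return None

    ctrl, trt, _, _ = _split_samples(design)
    spans_regions = (
        (retained["region"] == REGION_INTRON).any()
        or retained["exon_index"].dropna().nunique() > 1
        or retained["exon_index"].isna().any()
    )
    if spans_regions:
        return APAEvent(gene_id, CATEGORY_SPLICING, float("nan"),
                        float("nan"), float("nan"), retained)

    try:
        pdu_c = compute_pdu(gene_usage, design, ctrl, config)
        pdu_t = compute_pdu(gene_usage, design, trt, config)
    except UndefinedStatistic:
        # e.g. a retained last-exon PAC 5' of the stop codon: single-exon
        # configuration but no defined distal index -> no verdict
        return None
    delta = pdu_t - pdu_c

    retained = retained.sort_values("dist_from_stop", kind="stable")
    if len(retained) >= 3 and retained["significant"].iloc[1:-1].any():
        category = CATEGORY_BOTH
    elif delta > 0:
        category = CATEGORY_LENGTHENING
    elif delta < 0:
        category = CATEGORY_SHORTENING
    else:
        sig = retained.loc[retained["significant"]]
        change = float(sig["frac_change"].iloc[-1])  # distal-most significant
        if change > 0:
            category = CATEGORY_LENGTHENING
        elif change < 0:
            category = CATEGORY_SHORTENING
        else:
            return None
    return APAEvent(gene_id, category, float(delta), float(pdu_c),
                    float(pdu_t), retained)


def classify_events(
    usage: pd.DataFrame,
    pac_tests: pd.DataFrame,
    design: pd.DataFrame,
    config: PipelineConfig,
) -> tuple[pd.DataFrame, dict[str, APAEvent]]:
    """Classify every gene; returns an events table and the event objects."""
    events: dict[str, APAEvent] = {}
    rows = []
    for gene_id, gene_usage in usage.groupby("gene_id", sort=True):
        event = classify_event(
            gene_id, gene_usage,
            pac_tests.loc[pac_tests["gene_id"] == gene_id],
            design, config,
        )
        if event is None:
            continue
        events[gene_id] = event
        rows.append(
            {
                "gene_id": gene_id,
                "category": event.category,
                "pdu_control": event.pdu_control,
                "pdu_treated": event.pdu_treated,
                "delta_pdu": event.delta_pdu,
                "n_pacs_retained": len(event.pac_records),
                "n_significant": int(event.pac_records["significant"].sum()),
            }
        )
    columns = ["gene_id", "category", "pdu_control", "pdu_treated",
               "delta_pdu", "n_pacs_retained", "n_significant"]
    table = pd.DataFrame(rows, columns=columns)
    return table, events
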