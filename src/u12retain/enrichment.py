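"""Enrichment and set-overlap statistics for differential splicing results.

The central question: among intron-retention events upregulated in the
mutant, are U12-type introns over-represented relative to their genome-wide
share (~0.04% of introns)?  The null is an exact binomial at the expected
fraction; proportion comparisons use the pooled two-proportion z-test;
per-event-class tests are Benjamini-Hochberg corrected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportions_ztest

from .intron_catalog import IntronRecord, intron_rank_distance

__all__ = [
    "EnrichmentResult",
    "OverlapResult",
    "ZTestResult",
    "binomial_enrichment",
    "u12_ir_enrichment",
    "adjacency_to_u12",
    "two_proportion_ztest",
    "set_overlap_summary",
    "consensus_de_intersection",
    "classwise_u12_gene_enrichment",
    "DEFAULT_EXPECTED_U12_FRACTION",
]

# Genome-wide share of U12-type introns used as the default enrichment null.
DEFAULT_EXPECTED_U12_FRACTION = 0.0004


@dataclass
class EnrichmentResult:
    observed: int
    total: int
    observed_fraction: float
    expected_fraction: float
    fold: float
    p_value: float


def binomial_enrichment(observed: int, total: int, expected_fraction: float) -> EnrichmentResult:
    """Exact binomial upper-tail enrichment of ``observed`` successes in ``total``."""
    if not 0 < expected_fraction < 1:
        raise ValueError("expected_fraction must be in (0, 1)")
    if not 0 <= observed <= total:
        raise ValueError("need 0 <= observed <= total")
    if total == 0:
        return EnrichmentResult(0, 0, 0.0, expected_fraction, 0.0, 1.0)
    frac = observed / total
    # P(X >= observed) under Binomial(total, expected_fraction)
    p = float(stats.binom.sf(observed - 1, total, expected_fraction))
    return EnrichmentResult(
        observed=observed,
        total=total,
        observed_fraction=frac,
        expected_fraction=expected_fraction,
        fold=frac / expected_fraction,
        p_value=min(p, 1.0),
    )


def u12_ir_enrichment(
    calls: pd.DataFrame,
    classifications: pd.DataFrame,
    expected_fraction: float = DEFAULT_EXPECTED_U12_FRACTION,
) -> EnrichmentResult:
    """U12 enrichment among IR events upregulated in the mutant.

    ``calls`` is a differential-call table (:func:`u12retain.splicing.call_differential`);
    ``classifications`` the table from :func:`u12retain.classify.classify_catalog`.
    Every selected IR event must map, via intron_id, to a classified intron.
    """
    sel = calls[(calls["call"] == "up_in_MU") & (calls["event_class"] == "IR")]
    cls_by_id = classifications.set_index("intron_id")["assigned_class"]
    missing = [i for i in sel["intron_id"] if i not in cls_by_id.index]
    if missing:
        raise KeyError(f"IR events with unclassified introns: {sorted(missing)[:10]}")
    assigned = cls_by_id.loc[sel["intron_id"]]
    observed = int(assigned.str.startswith("U12").sum())
    return binomial_enrichment(observed, len(sel), expected_fraction)


def adjacency_to_u12(
    u2_ir_event_introns: Iterable[str],
    catalog: Sequence[IntronRecord],
    classifications: pd.DataFrame,
) -> tuple[dict[int, int], float, list[str]]:
    """Rank distances from affected U2 introns to U12 introns in the same gene.

    Returns (distance histogram, fraction at distance 1, excluded intron ids).
    Distance 1 means immediately upstream or downstream of a U12 intron.
    Events in genes without a classified U12 intron are excluded with a
    warning and reported separately.
    """
    u12_ids = set(
        classifications.loc[
            classifications["assigned_class"].str.startswith("U12"), "intron_id"
        ]
    )
    hist: dict[int, int] = {}
    excluded: list[str] = []
    n = 0
    for intron_id in u2_ir_event_introns:
        d = intron_rank_distance(catalog, intron_id, u12_ids)
        if d is None:
            excluded.append(intron_id)
            continue
        hist[d] = hist.get(d, 0) + 1
        n += 1
    if excluded:
        warnings.warn(
            f"{len(excluded)} events lie in genes with no U12 intron; excluded",
            stacklevel=2,
        )
    frac1 = hist.get(1, 0) / n if n else 0.0
    return dict(sorted(hist.items())), frac1, excluded


@dataclass
class ZTestResult:
    z: float
    p_value: float
    degenerate: bool = False

    def __iter__(self):  # allow tuple unpacking (z, p)
        yield self.z
        yield self.p_value


def two_proportion_ztest(k1: int, n1: int, k2: int, n2: int) -> ZTestResult:
    """Pooled two-proportion z-test, two-sided.

    Degenerate pooled proportions (0 or 1) leave z undefined; the result then
    carries p = 1 and the ``degenerate`` flag.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("counts must satisfy 0 <= k <= n")
    pooled = (k1 + k2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        return ZTestResult(z=float("nan"), p_value=1.0, degenerate=True)
    z, p = proportions_ztest([k1, k2], [n1, n2], alternative="two-sided")
    return ZTestResult(z=float(z), p_value=float(p))


@dataclass
class OverlapResult:
    n_a: int
    n_b: int
    n_both: int
    pct_a_in_b: float
    pct_b_in_a: float
    z: float
    p_value: float


def set_overlap_summary(set_a: Iterable, set_b: Iterable) -> OverlapResult:
    """Intersection counts/percentages for two identifier sets.

    The attached z-test compares the overlap proportion computed against each
    set's own size (n_both/n_a vs n_both/n_b); cross-context comparisons
    (the same overlap fraction in two different backgrounds) should call
    :func:`two_proportion_ztest` directly.
    """
    a, b = set(set_a), set(set_b)
    both = len(a & b)
    pct_a = 100.0 * both / len(a) if a else 0.0
    pct_b = 100.0 * both / len(b) if b else 0.0
    if a and b:
        zt = two_proportion_ztest(both, len(a), both, len(b))
        z, p = zt.z, zt.p_value
    else:
        z, p = float("nan"), 1.0
    return OverlapResult(len(a), len(b), both, pct_a, pct_b, z, p)


def consensus_de_intersection(
    results_a: pd.DataFrame | Mapping,
    results_b: pd.DataFrame | Mapping,
    alpha: float = 0.01,
) -> set[str]:
    """Genes significant in BOTH differential-expression tables, same direction.

    Tables carry ``gene`` (or index), ``log_fold_change`` and ``adjusted_p``;
    a mapping gene -> (log_fold_change, adjusted_p) is also accepted.  A gene
    absent from one table is treated as not significant there.
    """

    def as_frame(r):
        if isinstance(r, pd.DataFrame):
            df = r.copy()
            if "gene" in df.columns:
                df = df.set_index("gene")
            return df[["log_fold_change", "adjusted_p"]]
        return pd.DataFrame.from_dict(
            r, orient="index", columns=["log_fold_change", "adjusted_p"]
        )

    a, b = as_frame(results_a), as_frame(results_b)
    common = a.index.intersection(b.index)
    a, b = a.loc[common], b.loc[common]
    keep = (
        (a["adjusted_p"] < alpha)
        & (b["adjusted_p"] < alpha)
        & (np.sign(a["log_fold_change"]) == np.sign(b["log_fold_change"]))
        & (a["log_fold_change"] != 0)
    )
    return set(common[keep])


def classwise_u12_gene_enrichment(
    calls: pd.DataFrame,
    u12_gene_ids: Iterable[str],
    all_gene_ids: Iterable[str],
    directions: tuple[str, ...] = ("up_in_MU", "down_in_MU"),
) -> pd.DataFrame:
    """Per-event-class enrichment of called events in U12-intron-bearing genes.

    Expected fraction = share of U12-bearing genes in the full gene set; one
    exact binomial per class, Benjamini-Hochberg corrected across classes.
    """
    u12_genes = set(u12_gene_ids)
    all_genes = set(all_gene_ids)
    expected = len(u12_genes & all_genes) / len(all_genes)
    called = calls[calls["call"].isin(directions)]
    rows = []
    for cls, sub in called.groupby("event_class"):
        obs = int(sub["gene_id"].isin(u12_genes).sum())
        res = binomial_enrichment(obs, len(sub), expected)
        rows.append(
            {
                "event_class": cls,
                "observed": res.observed,
                "total": res.total,
                "observed_fraction": res.observed_fraction,
                "expected_fraction": expected,
                "fold": res.fold,
                "p_value": res.p_value,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    else:
        out["q_value"] = []
    return out
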