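"""Parameter-recovery benchmarks on fully synthetic data.

Each function generates data with :mod:`u12retain.simulate`, runs the
corresponding analysis stage, and scores it against the generator's truth.
They are used both by the test suite and by the reproduction script.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .classify import classify_catalog
from .enrichment import u12_ir_enrichment
from .intron_catalog import extract_introns
from .simulate import SimConfig, simulate_catalog_truth, simulate_event_counts, simulate_intron_catalog
from .splicing import call_differential

__all__ = [
    "classifier_recovery",
    "direction_recovery",
    "enrichment_rejection_rate",
]


def classifier_recovery(config: SimConfig) -> dict:
    """Sensitivity/specificity of U12 classification on a planted catalog.

    Runs the full path: synthetic genome + GTF -> intron extraction ->
    classification, scored against the generator's true classes.
    """
    genome, gtf, truth = simulate_intron_catalog(config)
    catalog = extract_introns(genome, gtf)
    table, _ = classify_catalog(catalog)
    merged = table.merge(truth[["intron_id", "true_class"]], on="intron_id")
    pred = merged["assigned_class"].str.startswith("U12")
    true = merged["true_class"].str.startswith("U12")
    tp = int((pred & true).sum())
    fn = int((~pred & true).sum())
    fp = int((pred & ~true).sum())
    tn = int((~pred & ~true).sum())
    return {
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
        "subtype_accuracy": float(
            (merged.loc[true, "assigned_class"] == merged.loc[true, "true_class"]).mean()
        )
        if true.any()
        else float("nan"),
        "n_introns": len(merged),
        "n_u12_true": int(true.sum()),
    }


def direction_recovery(
    config: SimConfig, n_seeds: int = 25, threshold_percent: float = 10.0, min_reads: int = 10
) -> dict:
    """Fraction of planted retention effects called in the planted direction.

    Aggregated over ``n_seeds`` independent count tables (catalog skeletons
    only; sequence synthesis is not needed for PSI statistics).  Only
    passing-coverage planted events enter the denominator.
    """
    recovered = 0
    total = 0
    false_calls = 0
    n_null = 0
    for i in range(n_seeds):
        cfg = replace(config, seed=config.seed + i)
        truth = simulate_catalog_truth(cfg)
        counts, etruth = simulate_event_counts(truth, cfg)
        calls = call_differential(counts, threshold_percent, min_reads)
        m = calls.merge(etruth[["event_id", "planted"]], on="event_id")
        planted = m[m["planted"] & m["passed_coverage"]]
        want = "up_in_MU" if config.planted_ir_effect > 0 else "down_in_MU"
        recovered += int((planted["call"] == want).sum())
        total += len(planted)
        null = m[~m["planted"]]
        false_calls += int(null["call"].isin(["up_in_MU", "down_in_MU"]).sum())
        n_null += len(null)
    return {
        "recovery": recovered / total if total else float("nan"),
        "n_planted": total,
        "false_call_rate": false_calls / n_null if n_null else float("nan"),
        "n_null": n_null,
    }


def enrichment_rejection_rate(
    config: SimConfig, n_seeds: int = 100, alpha: float = 0.01, null: bool = False
) -> dict:
    """Fraction of seeded pipeline runs whose U12 IR enrichment rejects.

    Each run simulates a catalog skeleton and count table, calls differential
    events, and tests the called IR events for U12 enrichment against the
    *generated* catalog's U12 intron fraction (the correct null for the
    generator's deliberately inflated U12 share).  With ``null=True`` the
    planted effects land uniformly over introns (planted_u12_bias set to the
    catalog's own U12 fraction), so rejections are type-I errors.
    """
    rejections = 0
    for i in range(n_seeds):
        cfg = replace(config, seed=config.seed + i)
        truth = simulate_catalog_truth(cfg)
        catalog_u12_fraction = float(truth["true_class"].str.startswith("U12").mean())
        if null:
            cfg = replace(cfg, planted_u12_bias=catalog_u12_fraction)
        counts, etruth = simulate_event_counts(truth, cfg)
        calls = call_differential(counts)
        classifications = etruth.rename(columns={"true_class": "assigned_class"})[
            ["intron_id", "assigned_class"]
        ]
        res = u12_ir_enrichment(calls, classifications, catalog_u12_fraction)
        if res.p_value < alpha:
            rejections += 1
    return {"rejection_rate": rejections / n_seeds, "n_seeds": n_seeds, "alpha": alpha}
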