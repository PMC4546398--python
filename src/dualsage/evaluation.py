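"""Calibration and recovery benchmarks on synthetic libraries.

These routines measure the pipeline against its own simulator's ground
truth: the type-I error of the two-library test under a null simulation,
and sensitivity / false-positive rate / attribution accuracy on libraries
with injected effects at the study's depths.  They are used by the test
suite and the reproduction script, and are ordinary library code — the
problem sizes are arguments.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .annotate import attribute_all, build_tag_index
from .de import call_significant
from .simulate import SimConfig, simulate_tag_libraries, simulate_transcriptomes
from .tags import clean_table


def null_type1_rate(
    n_tags: int = 10_000,
    depth: int = 1_000_000,
    n_seeds: int = 20,
    base_seed: int = 0,
    alpha: float = 0.05,
    method: str = "audic-claverie",
    error_rate: float = 0.0,
    polya_artifact_rate: float = 0.0,
) -> dict:
    """Fraction of tags with p < alpha under a no-effect simulation.

    One host transcriptome of ``n_tags`` transcripts is drawn once; the two
    libraries (equal depths) are resampled ``n_seeds`` times.  Tables are
    cleaned as in the real pipeline before testing.  Observation artifacts
    are off by default so the calibration measures the test on exactly
    ``n_tags`` null tags; with artifacts on, low-count error tags join the
    denominator and dilute the rate.  The discrete test is conservative at
    low counts, so the rate sits somewhat below the nominal level.
    """
    cfg = SimConfig(
        n_host_transcripts=n_tags,
        n_symbiont_transcripts=0,
        de_fraction=0.0,
        depth_ctl=depth,
        depth_inf=depth,
        error_rate=error_rate,
        polya_artifact_rate=polya_artifact_rate,
        seed=base_seed,
    )
    host, symbiont = simulate_transcriptomes(cfg)
    rates = []
    n_tested = 0
    for s in range(n_seeds):
        cfg_s = dataclasses.replace(cfg, seed=base_seed + s)
        table, _ = simulate_tag_libraries(cfg_s, host, symbiont)
        table, _ = clean_table(table)
        results, _ = call_significant(table, alpha=alpha, method=method)
        rates.append(float((results["pvalue"] < alpha).mean()))
        n_tested += len(results)
    return {
        "rate": float(np.mean(rates)),
        "per_seed": rates,
        "n_tags_tested": n_tested,
    }


def _unambiguous_truth(truth: pd.DataFrame) -> pd.DataFrame:
    """Truth rows whose canonical tag maps to exactly one transcript."""
    return truth[~truth["tag"].duplicated(keep=False)]


def recovery_metrics(
    seed: int = 1,
    n_host: int = 2000,
    n_symbiont: int = 500,
    de_fraction: float = 0.1,
    effect_size: tuple[float, float] = (4.0, 128.0),
    min_true_fc: float = 4.0,
    min_cpm: float = 20.0,
    alpha: float = 0.05,
    min_fc: float = 2.0,
) -> dict:
    """Effect recovery and attribution accuracy at the study's library depths.

    Sensitivity is measured over host tags with a true fold change of at
    least ``min_true_fc`` and an expected abundance of at least ``min_cpm``
    tags-per-million in both libraries; a truly regulated tag counts as
    recovered when the (p < alpha, FC >= min_fc) rule flags it.  The
    false-positive rate is taken over host tags with no injected effect
    (symbiont tags are structurally library-specific — absent from the
    control — so they carry a real between-library difference and are not
    a null set).  Attribution accuracy checks every unambiguous canonical
    tag against its true species at perfect-match stringency.
    """
    cfg = SimConfig(
        n_host_transcripts=n_host,
        n_symbiont_transcripts=n_symbiont,
        de_fraction=de_fraction,
        effect_size=effect_size,
        seed=seed,
    )
    host, symbiont = simulate_transcriptomes(cfg)
    table, truth = simulate_tag_libraries(cfg, host, symbiont)
    table, clean_report = clean_table(table)
    results, summary = call_significant(table, alpha=alpha, min_fc=min_fc)

    truth_u = _unambiguous_truth(truth)
    merged = truth_u.merge(
        results[["tag", "pvalue", "fc", "sig_2fold"]], on="tag", how="left"
    )
    merged["sig_2fold"] = merged["sig_2fold"].notna() & merged["sig_2fold"].eq(True)

    host_rows = merged[merged["species"] == "host"]
    eligible = host_rows[
        (host_rows["true_fc"] >= min_true_fc)
        & (host_rows["expected_cpm_ctl"] >= min_cpm)
        & (host_rows["expected_cpm_inf"] >= min_cpm)
    ]
    sensitivity = float(eligible["sig_2fold"].mean()) if len(eligible) else float("nan")

    null_rows = host_rows[host_rows["true_fc"] == 1.0]
    fpr = float(null_rows["sig_2fold"].mean()) if len(null_rows) else float("nan")

    attrib = attribute_all(
        truth_u["tag"].tolist(),
        build_tag_index(host),
        build_tag_index(symbiont),
        stringencies=(0,),
    )
    att = truth_u.merge(attrib, on="tag")
    att = att[att["category"] != "ambiguous"]
    attribution_accuracy = float((att["category"] == att["species"]).mean())

    return {
        "sensitivity": sensitivity,
        "n_eligible": int(len(eligible)),
        "fpr": fpr,
        "n_null": int(len(null_rows)),
        "attribution_accuracy": attribution_accuracy,
        "n_attributed": int(len(att)),
        "n_sig": summary.n_sig,
        "clean_report": clean_report,
    }
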