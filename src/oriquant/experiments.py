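"""End-to-end synthetic experiments: simulate, process, quantify, compare.

These drivers wire the full pipeline together the way the real analyses run:
simulate genotype panels of QBU/ChIP tracks, median-smooth and average
replicates, scale-normalize across strains (QBU only), quantify 500 bp origin
windows, and summarize the genotype-contrast structure. They are the basis
of the reproducibility checks in ``scripts/acceptance.py`` and of the
integration tests.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .origins import classify_cen_proximal, exclude_rdna
from .preprocess import (
    ReplicateSet,
    StrainProfile,
    average_replicates,
    median_smooth,
    scale_normalize,
)
from .quantify import peak_width_fwhm, two_sided_ttest, window_signal
from .simulate import (
    GENOTYPES,
    Genotype,
    SimConfig,
    assign_firing_weights,
    brdu_track,
    build_sim_fixture,
    dbf4_chip_track,
    sample_fired,
    simulate_cells,
    simulate_experiment,
)

__all__ = [
    "process_replicates",
    "quantify_genotype_panel",
    "mechanism_recovery",
    "fwhm_vs_pool_size",
    "chip_cen_contrast",
    "firing_frequency_chisq",
]

CONTRAST_GENOTYPES = {
    k: GENOTYPES[k]
    for k in ("WT", "ctf19∆", "dbf4-Zn*", "fkh1∆ fkh2-dsm", "dbf4∆C")
}


def process_replicates(
    repsets: dict[str, ReplicateSet],
    smooth_bp: int = 1000,
    normalize: bool = True,
) -> dict[str, StrainProfile]:
    """Smooth each replicate, average, then (optionally) scale-normalize."""
    profiles = []
    for label, reps in repsets.items():
        smoothed = ReplicateSet(
            label, [median_smooth(t, smooth_bp) for t in reps.tracks]
        )
        prof = average_replicates(smoothed)
        prof.provenance.insert(0, f"median_smooth(window_bp={smooth_bp})")
        profiles.append(prof)
    if normalize and len(profiles) >= 2:
        profiles = scale_normalize(profiles)
    return {p.strain_label: p for p in profiles}


def quantify_genotype_panel(
    seed: int,
    config: SimConfig | None = None,
    genotypes: dict[str, Genotype] | None = None,
    window_bp: int = 500,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a genotype panel and return group medians of window signal.

    Returns (window table with group medians per strain, per-strain group
    median frame) for the cen_proximal and fkh_activated groups.
    """
    config = replace(config or SimConfig(), seed=seed)
    genotypes = genotypes or CONTRAST_GENOTYPES
    repsets, truth, fixture = simulate_experiment(config, genotypes, seed=seed)
    profiles = process_replicates(repsets)
    oset = classify_cen_proximal(exclude_rdna(fixture.origin_set), fixture.centromeres)
    confirmed = oset.groups["confirmed"]
    table = pd.concat(
        [window_signal(p, confirmed, window_bp) for p in profiles.values()], axis=1
    )
    groups = {
        "cen_proximal": oset.group_names("cen_proximal"),
        "fkh_activated": oset.group_names("fkh_activated"),
    }
    med = pd.DataFrame(
        {
            g: {s: float(table.loc[names, s].median()) for s in table.columns}
            for g, names in groups.items()
        }
    )
    return table, med


def mechanism_recovery(
    seeds: range | list[int], config: SimConfig | None = None
) -> pd.DataFrame:
    """Per-seed genotype-contrast checks (the dQBU structure of the model).

    For each seed: dMedian(group) = median_WT - median_mutant of 500 bp
    window signal. Checks that ctf19∆ and Zn* hit CEN-proximal origins harder
    than Fkh-activated ones, the fkh1∆ fkh2-dsm double does the reverse, and
    the dC hypomorph reduces both groups.
    """
    rows = []
    for seed in seeds:
        _, med = quantify_genotype_panel(seed, config)
        d = med.loc["WT"] - med  # rows: strains; positive = activity lost
        rows.append(
            {
                "seed": seed,
                "ctf19_cen_gt_fkh": bool(
                    d.loc["ctf19∆", "cen_proximal"] > d.loc["ctf19∆", "fkh_activated"]
                ),
                "zn_cen_gt_fkh": bool(
                    d.loc["dbf4-Zn*", "cen_proximal"] > d.loc["dbf4-Zn*", "fkh_activated"]
                ),
                "fkh_reverse": bool(
                    d.loc["fkh1∆ fkh2-dsm", "fkh_activated"]
                    > d.loc["fkh1∆ fkh2-dsm", "cen_proximal"]
                ),
                "dc_both_reduced": bool(
                    (d.loc["dbf4∆C", "cen_proximal"] > 0)
                    and (d.loc["dbf4∆C", "fkh_activated"] > 0)
                ),
            }
        )
    df = pd.DataFrame(rows).set_index("seed")
    df["all_pass"] = df.all(axis=1)
    return df


def fwhm_vs_pool_size(
    seeds: range | list[int],
    pool_sizes: tuple[int, ...] = (5, 10, 20, 40),
    config: SimConfig | None = None,
    min_firing_frequency: float = 0.05,
) -> tuple[pd.DataFrame, float]:
    """Mean fired-origin-peak FWHM per (pool size, seed) and Spearman rho vs K.

    With a shared per-cell synthesis budget, more concurrent forks each
    travel less, so peaks narrow as the firing pool grows. Width is measured
    at origins that fired detectably (empirical firing frequency at least
    ``min_firing_frequency``, i.e. the peak stands clear of read noise).
    """
    base = config or SimConfig()
    rows = []
    for k in pool_sizes:
        for seed in seeds:
            cfg = replace(base, pool_size=k, seed=seed)
            repsets, truth, fixture = simulate_experiment(
                cfg, {"WT": GENOTYPES["WT"]}, replicates=1, seed=seed
            )
            profile = process_replicates(repsets, normalize=False)["WT"]
            search = int(0.8 * cfg.origin_spacing)
            fired = set(
                truth.loc[truth["firing_frequency"] >= min_firing_frequency,
                          "origin"]
            )
            widths = []
            for o in fixture.origin_set.origins:
                if o.name not in fired:
                    continue
                try:
                    pw = peak_width_fwhm(profile, o, search_bp=search)
                except ValueError:
                    continue
                if not pw.censored:
                    widths.append(pw.width_bp)
            rows.append(
                {"pool_size": k, "seed": seed,
                 "mean_fwhm_bp": float(np.mean(widths)), "n_peaks": len(widths)}
            )
    df = pd.DataFrame(rows)
    rho = float(
        stats.spearmanr(df["pool_size"], df["mean_fwhm_bp"]).statistic
    )
    return df, rho


def chip_cen_contrast(
    seeds: range | list[int], config: SimConfig | None = None
) -> pd.DataFrame:
    """WT vs Zn* Dbf4-occupancy tests at CENs and at non-CEN-proximal origins.

    Per seed: Welch two-sided t-tests on 500 bp windows centered on the 16
    centromeres (expected to reject: recruitment lost in Zn*) and on the
    non-CEN-proximal confirmed origins (expected null: no strain-dependent
    enrichment there). ChIP tracks are smoothed but not scale-normalized.
    """
    base = config or SimConfig()
    rows = []
    for seed in seeds:
        cfg = replace(base, seed=seed)
        rng = np.random.default_rng(seed)
        fixture = build_sim_fixture(cfg, rng=np.random.default_rng(seed))
        oset = classify_cen_proximal(fixture.origin_set, fixture.centromeres)
        prox = oset.cen_proximal
        tracks = {}
        for label, allele in (("WT", "WT"), ("dbf4-Zn*", "Zn*")):
            track = dbf4_chip_track(
                fixture, Genotype(dbf4_allele=allele), cfg, rng,
                cen_proximal_names=prox,
            )
            tracks[label] = StrainProfile(label, median_smooth(track), ["chip"])
        cen_w = {
            label: window_signal(p, fixture.centromeres)
            for label, p in tracks.items()
        }
        nonprox = [
            o for o in oset.groups["confirmed"] if o.name not in prox
        ]
        ori_w = {
            label: window_signal(p, nonprox) for label, p in tracks.items()
        }
        cen_test = two_sided_ttest(cen_w["WT"], cen_w["dbf4-Zn*"])
        ori_test = two_sided_ttest(ori_w["WT"], ori_w["dbf4-Zn*"])
        rows.append(
            {"seed": seed, "cen_p": cen_test["p"], "nonprox_p": ori_test["p"],
             "cen_reject_001": cen_test["p"] < 0.01,
             "nonprox_retain_005": ori_test["p"] >= 0.05}
        )
    return pd.DataFrame(rows).set_index("seed")


def firing_frequency_chisq(
    seed: int, n_cells: int = 10_000, n_origins: int = 12
) -> dict[str, float]:
    """Chi-square goodness of fit of K=1 firing frequencies vs weight/sum.

    With a pool of one, the sampled origin's distribution is exactly
    proportional to weight, so empirical counts over many cells should pass
    a goodness-of-fit test against that law.
    """
    rng = np.random.default_rng(seed)
    weights = rng.uniform(0.2, 2.0, size=n_origins)
    fired = sample_fired(weights, 1, rng, n_cells)[:, 0]
    observed = np.bincount(fired, minlength=n_origins)
    expected = n_cells * weights / weights.sum()
    chi2, p = stats.chisquare(observed, expected)
    return {"chi2": float(chi2), "p": float(p), "n_cells": n_cells}
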