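"""End-to-end validation measurements used by tests and the results script.

Each function regenerates its inputs from the synthetic-data module, runs
the analysis pipeline, and returns measured quantities: spike-episode
recovery rates, sleep-stager accuracy, and the cohort-level phenotype
effects (group contrasts and protein-level regressions).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import polyspike, sleep, spectral
from .association import fit_all_phenotypes, phenotype_protein_table
from .preprocess import preprocess_recording
from .simulate import (
    SimConfig,
    inject_polyspikes,
    simulate_hypnogram,
    synthesize_signals,
)

#: Sampling rate used for the validation studies; Nyquist 250 Hz covers the
#: 1-100 Hz analysis range.
STUDY_FS = 500.0


def polyspike_recovery(
    n_recordings: int = 20,
    rate_per_h: float = 10.0,
    duration_h: float = 1.0,
    seed: int = 0,
    match_tol_s: float = 1.0,
) -> dict:
    """Inject poly-spike episodes and measure detector recovery.

    Returns sensitivity (fraction of injected episodes matched by a
    detected episode within ``match_tol_s``) and the spurious fraction
    (detected episodes matching no injected episode), pooled over
    ``n_recordings`` seeded recordings.
    """
    n_injected = n_detected = n_hit = n_spurious = 0
    for i in range(n_recordings):
        cfg = SimConfig(sampling_rate=STUDY_FS, duration_h=duration_h,
                        seed=seed + i, artifact_rate=0.0)
        hyp = simulate_hypnogram(cfg)
        rec, truth = synthesize_signals(hyp, cfg)
        rec, truth = inject_polyspikes(rec, rate_per_h, cfg,
                                       np.random.default_rng(seed + 10_000 + i),
                                       truth)
        clean, mask = preprocess_recording(rec)
        spikes = polyspike.detect_spikes(clean)
        episodes = polyspike.cluster_episodes(spikes)
        episodes = polyspike.drop_artifact_episodes(episodes, mask)
        inj = np.asarray(truth.spike_episode_times)
        det = np.asarray([ep.start_s for ep in episodes])
        n_injected += len(inj)
        n_detected += len(det)
        if len(inj):
            n_hit += int(sum(np.any(np.abs(det - t) <= match_tol_s) for t in inj))
            n_spurious += int(sum(
                not np.any((inj - match_tol_s <= d) & (d <= inj + 2.0)) for d in det
            ))
        else:
            n_spurious += len(det)
    return {
        "sensitivity": n_hit / n_injected if n_injected else float("nan"),
        "spurious_fraction": n_spurious / n_detected if n_detected else 0.0,
        "n_injected": n_injected,
        "n_detected": n_detected,
    }


def stager_accuracy(
    n_recordings: int = 4,
    duration_h: float = 3.0,
    seed: int = 0,
) -> dict:
    """Epoch accuracy of the sleep stager against generator ground truth."""
    correct = total = 0
    for i in range(n_recordings):
        cfg = SimConfig(sampling_rate=250.0, duration_h=duration_h,
                        seed=seed + i, artifact_rate=0.0)
        hyp = simulate_hypnogram(cfg)
        rec, _ = synthesize_signals(hyp, cfg)
        feats = sleep.extract_epoch_features(rec)
        pred = sleep.classify_epochs(feats, random_state=seed)
        truth = np.asarray(hyp.labels[: len(pred)], dtype=object)
        pred_a = np.asarray(pred.labels, dtype=object)
        correct += int((truth == pred_a).sum())
        total += len(truth)
    return {"accuracy": correct / total, "n_epochs": total}


def cohort_phenotypes(
    n_per_group: int = 8,
    signal_hours: float = 2.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Phenotype one synthetic WT-control vs mutant-control cohort.

    Per animal: the (α+β1+β2)/γ2 ratio and per-band relative powers from a
    ``signal_hours`` EEG window, and light-phase REM minutes from a 48 h
    hypnogram.  Returns one row per animal with covariates.
    """
    rows = []
    groups = [("WT", "control", 1.0), ("mutant", "control", 0.0)]
    idx = 0
    for genotype, treatment, protein in groups:
        for j in range(n_per_group):
            aseed = int((seed * 100003 + idx * 7919 + 1) % (2**31 - 1))
            cfg_sig = SimConfig(sampling_rate=STUDY_FS, duration_h=signal_hours,
                                seed=aseed, protein_level=protein,
                                artifact_rate=0.0)
            hyp = simulate_hypnogram(cfg_sig)
            rec, _ = synthesize_signals(hyp, cfg_sig)
            res = spectral.welch_psd(rec.signals[:3], STUDY_FS,
                                     channel_labels=rec.channel_labels[:3])
            res = spectral.interpolate_notch_band(res)
            tab = spectral.band_powers(res)
            rel = tab.relative.mean(axis=0)
            cfg_hyp = SimConfig(sampling_rate=STUDY_FS, duration_h=48.0,
                                seed=aseed + 1, protein_level=protein)
            hyp48 = simulate_hypnogram(cfg_hyp)
            budget = sleep.time_budget(hyp48, cfg_hyp.start_time)
            rows.append({
                "animal_id": f"{genotype}_{treatment}_{idx:03d}",
                "genotype": genotype,
                "treatment": treatment,
                "protein_level": protein,
                "ratio_low_high": float(tab.ratio_low_high.mean()),
                "rem_light_min": budget.minutes("REM", "light"),
                **{f"rel_{b}": float(rel[b]) for b in rel.index},
            })
            idx += 1
    return pd.DataFrame(rows)


def cohort_effects(cohort: pd.DataFrame) -> dict:
    """Group contrasts and protein-level regressions on a cohort table.

    One-sided Welch tests for the directional hypotheses (mutant ratio
    higher, mutant light-phase REM lower), plus per-phenotype linear
    regressions of WT-normalized values on protein level.
    """
    wt = cohort[cohort["genotype"] == "WT"]
    mut = cohort[cohort["genotype"] == "mutant"]
    t_ratio = stats.ttest_ind(mut["ratio_low_high"], wt["ratio_low_high"],
                              equal_var=False, alternative="greater")
    t_rem = stats.ttest_ind(mut["rem_light_min"], wt["rem_light_min"],
                            equal_var=False, alternative="less")
    pheno_cols = ["ratio_low_high", "rem_light_min"] + [
        c for c in cohort.columns if c.startswith("rel_")
    ]
    table = phenotype_protein_table(
        cohort[["animal_id", "genotype", "treatment", "protein_level"]],
        cohort[["animal_id"] + pheno_cols],
    )
    fits = fit_all_phenotypes(table).set_index("phenotype")
    return {
        "ratio_wt_mean": float(wt["ratio_low_high"].mean()),
        "ratio_mutant_mean": float(mut["ratio_low_high"].mean()),
        "p_ratio_mutant_higher": float(t_ratio.pvalue),
        "rem_light_wt_mean_min": float(wt["rem_light_min"].mean()),
        "rem_light_mutant_mean_min": float(mut["rem_light_min"].mean()),
        "p_rem_mutant_lower": float(t_rem.pvalue),
        "fits": fits,
    }
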