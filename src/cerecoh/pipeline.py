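"""End-to-end orchestration of the two study workflows.

``run_coherence_study`` mirrors the awake dual-site workflow: behavioral
segmentation, per-state multitaper spectra/coherence with the theta-ratio
statistic, directed coherence, and across-session rank-sum comparisons.
``run_stimulation_study`` mirrors the stimulation workflows: evoked-field
metrics per recording depth with amplitude normalization, permutation-based
unit classification with a χ² group comparison, and pre/stim correlogram
comparison.

Reports are plain nested dicts (JSON-serializable) so every numeric traces
back to a stage output; a RunManifest records config, seed and input
digests for reproducibility.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from typing import Any

import numpy as np

from . import behavior, directed, evoked, spectral, units
from .config import AnalysisConfig
from .core import ContinuousSignal, EpochSet, SpeedTrace, SpikeTrain, StimProtocol
from .stats import chi_square, wilcoxon_rank_sum

__all__ = ["RunManifest", "run_coherence_study", "run_stimulation_study",
           "CoherenceSession"]

log = logging.getLogger("cerecoh.pipeline")


@dataclass
class RunManifest:
    config: dict
    seed: int
    input_digests: dict[str, str] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)

    @staticmethod
    def digest(arr: np.ndarray) -> str:
        return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=str)


@dataclass
class CoherenceSession:
    """One dual-site recording: two LFP channels plus the speed trace."""
    x: ContinuousSignal
    y: ContinuousSignal
    speed: SpeedTrace
    name: str = ""


def _stage(name: str):
    log.info("stage: %s", name)


def run_coherence_study(sessions: list[CoherenceSession],
                        config: AnalysisConfig | None = None,
                        seed: int = 0,
                        surrogates: int = 0) -> dict[str, Any]:
    """Segment → spectra/coherence/theta-ratio per state → directed
    coherence → group comparisons.  Returns a JSON-able report."""
    cfg = config or AnalysisConfig()
    if not sessions:
        raise ValueError("no sessions supplied")
    report: dict[str, Any] = {"sessions": [], "group": {}}
    ratios = {"locomotion": [], "rest": []}
    dc_means = {"locomotion": {"fwd": [], "rev": []},
                "rest": {"fwd": [], "rev": []}}
    for si, sess in enumerate(sessions):
        name = sess.name or f"session{si}"
        _stage(f"{name}: segmentation")
        try:
            seg = behavior.segment_states(sess.speed, sess.y, cfg)
        except Exception as e:
            raise RuntimeError(f"[segmentation] {name}: {e}") from e
        entry: dict[str, Any] = {"name": name,
                                 "coverage": seg.coverage,
                                 "states": {}}
        for state, eps in (("locomotion", seg.locomotion), ("rest", seg.rest)):
            _stage(f"{name}: spectra ({state})")
            try:
                px = spectral.multitaper_psd(sess.x, eps, cfg)
                py = spectral.multitaper_psd(sess.y, eps, cfg)
                coh = spectral.multitaper_coherence(sess.x, sess.y, eps, cfg)
            except ValueError as e:
                log.warning("%s/%s skipped: %s", name, state, e)
                entry["states"][state] = {"skipped": str(e)}
                continue
            summ = spectral.theta_summary(px, py, coh, cfg,
                                          (sess.x.label or "x",
                                           sess.y.label or "y"))
            _stage(f"{name}: directed coherence ({state})")
            try:
                if surrogates > 0:
                    dc = directed.surrogate_threshold(
                        sess.x, sess.y, eps, surrogates, cfg.alpha, cfg,
                        fs_target=cfg.ar_fs, seed=seed + si)
                else:
                    res = directed.fit_bivariate_ar(sess.x, sess.y, eps,
                                                    fs_target=cfg.ar_fs,
                                                    p_max=cfg.ar_order_max)
                    dc = res.directed_coherence()
                fwd, rev = dc.band_mean(cfg.theta_band)
            except ValueError as e:
                raise RuntimeError(f"[directed] {name}/{state}: {e}") from e
            entry["states"][state] = {
                "theta_power_db": summ.theta_power_db,
                "theta_coherence": summ.theta_coherence,
                "theta_ratio": summ.theta_ratio,
                "dc_theta_x_to_y": fwd,
                "dc_theta_y_to_x": rev,
                "coherence_sig_level": coh.sig_level,
                "n_windows": coh.n_windows,
            }
            ratios[state].append(summ.theta_ratio)
            dc_means[state]["fwd"].append(fwd)
            dc_means[state]["rev"].append(rev)
        report["sessions"].append(entry)
    for state in ("locomotion", "rest"):
        if dc_means[state]["fwd"] and len(dc_means[state]["fwd"]) >= 1:
            fwd, rev = dc_means[state]["fwd"], dc_means[state]["rev"]
            if np.allclose(fwd, rev):
                report["group"][f"directionality_{state}"] = {
                    "p": 1.0, "mean_fwd": float(np.mean(fwd)),
                    "mean_rev": float(np.mean(rev))}
            else:
                tr = wilcoxon_rank_sum(np.array(fwd), np.array(rev))
                report["group"][f"directionality_{state}"] = {
                    "p": tr.p_value, "mean_fwd": float(np.mean(fwd)),
                    "mean_rev": float(np.mean(rev))}
    if ratios["locomotion"] and ratios["rest"]:
        tr = wilcoxon_rank_sum(np.array(ratios["locomotion"]),
                               np.array(ratios["rest"]))
        report["group"]["theta_ratio_locomotion_vs_rest"] = {
            "p": tr.p_value,
            "mean_locomotion": float(np.mean(ratios["locomotion"])),
            "mean_rest": float(np.mean(ratios["rest"]))}
    return report


def run_stimulation_study(inputs: dict[str, Any],
                          config: AnalysisConfig | None = None,
                          seed: int = 0,
                          n_permutations: int | None = None,
                          allow_fewer: bool = False) -> dict[str, Any]:
    """Evoked metrics per depth, unit classification tables with χ²
    comparison, and pre/stim correlogram comparison.

    ``inputs`` keys (all optional except a stimulation protocol wherever a
    stage needs one):

    * ``evoked``: list of ``(ContinuousSignal, StimProtocol, depth_label)``
    * ``units``: list of ``(SpikeTrain, group_label)``; ``unit_protocol``
    * ``correlogram_trains``: list of SpikeTrain; ``correlogram_protocol``
    """
    cfg = config or AnalysisConfig()
    report: dict[str, Any] = {}
    ev_in = inputs.get("evoked") or []
    if ev_in:
        _stage("evoked metrics")
        metrics = []
        for sig, proto, depth in ev_in:
            if proto.n_events == 0:
                raise RuntimeError("[evoked] protocol with zero events")
            metrics.append(evoked.evoked_metrics(sig, proto, depth, cfg))
        evoked.normalize_by_depth(metrics)
        report["evoked"] = [
            {"depth": m.depth_label, "onset_latency_ms": m.onset_latency_ms,
             "peak_to_trough_mv": m.peak_to_trough_mv,
             "normalized_amplitude_pct": m.normalized_amplitude}
            for m in metrics]
    unit_in = inputs.get("units") or []
    if unit_in:
        proto: StimProtocol = inputs["unit_protocol"]
        if proto.n_events == 0:
            raise RuntimeError("[units] protocol with zero events")
        _stage("unit classification")
        classes, labels = [], []
        for i, (train, group) in enumerate(unit_in):
            cls = units.classify_unit(train, proto, cfg, n_permutations,
                                      allow_fewer, seed=seed + i)
            cls.group = group
            classes.append(cls)
            labels.append(group)
        table = units.tabulate_categories(classes, labels)
        report["units"] = {
            "classifications": [
                {"unit": c.unit_id, "group": c.group, "category": c.category,
                 "magnitude_pct": c.magnitude_pct,
                 "time_to_peak_s": c.time_to_peak} for c in classes],
            "table": {"groups": table.group_labels,
                      "categories": table.category_labels,
                      "counts": table.counts.tolist()},
        }
        if len(table.group_labels) >= 2:
            try:
                tr = chi_square(table)
                report["units"]["chi_square"] = {"statistic": tr.statistic,
                                                 "df": tr.df, "p": tr.p_value}
            except ValueError as e:          # degenerate margins on small cohorts
                report["units"]["chi_square"] = {"error": str(e)}
    else:
        log.info("units stage skipped (no unit inputs)")
    corr_in = inputs.get("correlogram_trains") or []
    if corr_in:
        proto = inputs.get("correlogram_protocol") or inputs.get("unit_protocol")
        _stage("correlograms")
        pre, stim = [], []
        trains = corr_in
        for i in range(len(trains)):
            for j in range(i + 1, len(trains)):
                pre.append(units.crosscorrelogram(trains[i], trains[j], proto,
                                                  "pre", cfg, seed=seed))
                stim.append(units.crosscorrelogram(trains[i], trains[j], proto,
                                                   "stim", cfg, seed=seed))
        cmp = units.correlogram_state_compare(pre, stim)
        report["correlograms"] = {
            "n_pairs": len(pre),
            "tests": {k: (None if v is None else
                          {"statistic": v.statistic, "p": v.p_value})
                      for k, v in cmp.tests.items()}}
    return report
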