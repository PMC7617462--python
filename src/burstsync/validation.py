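"""End-to-end validation experiments on synthetic cohorts.

These are the expensive ground-truth checks the package ships with: burst
detector fidelity at high SNR, type-I calibration of the cluster test,
and power / false-positive rates of the full IMC pipeline on coupled
versus uncoupled cohorts.  Used by the test suite and the reproduction
script.
"""

from __future__ import annotations

import numpy as np

from . import bursts as bu
from . import preprocess as pp
from .pipeline import RunConfig, run_cohort
from .synth import fast_coupling_spec, fast_task_config, generate_participant

__all__ = [
    "burst_detector_fidelity",
    "short_burst_yields_nothing",
    "imc_cluster_detection_rate",
]


def high_snr_spec():
    """Generator preset where injected burst envelopes dominate the cortical
    beta background: ~30% Steady occupancy, constant baseline, weak 1/f.

    The burst gain is moderate (2.5x) on purpose: the pooled 75th-percentile
    threshold then cuts the Morlet-smoothed envelope near its half-rise, so
    detected onsets land within one map time step of the injection."""
    return fast_coupling_spec(
        burst_rate={c: 1.2 for c in ("F0", "F1", "F2")},
        burst_duration_median_s={c: 0.25 for c in ("F0", "F1", "F2")},
        burst_gain={c: 2.5 for c in ("F0", "F1", "F2")},
        beta_am_sigma=0.0,
        pink_amp=0.3,
        gamma_amp=0.0,
    )


def burst_detector_fidelity(seed: int = 1, n_participants: int = 3, decim: int = 16) -> dict:
    """Recall, false positives per Steady phase, and median onset error (in
    map time steps) of the percentile/duration burst detector on high-SNR
    injections."""
    cfg = fast_task_config()
    spec = high_snr_spec()
    errs: list[float] = []
    n_hit = n_inj = n_fp = n_phases = 0
    for i in range(n_participants):
        _, recs, gt = generate_participant(cfg, spec, seed + i)
        for rec in recs:
            filt = pp.preprocess_filter(rec, notch=None)
            m = pp.cwt_amplitude(filt, "CTX", np.arange(15.0, 36.0, 2.0), decim=decim)
            z = pp.zscore_block(m, pp.block_stats(m))
            beta = pp.band_series(z, pp.BANDS["beta"])
            thr = bu.compute_threshold(beta, 75.0, block=rec.block)
            det = bu.detect_bursts(beta, z.times, thr, 0.1, rec.events)
            det = det[det["phase"] == "steady"]
            inj = gt.bursts[gt.bursts["block"] == rec.block]
            n_inj += len(inj)
            n_phases += len(rec.events)
            for g in inj.itertuples():
                hit = det[(det["onset_s"] < g.offset_s) & (det["offset_s"] > g.onset_s)]
                if len(hit):
                    n_hit += 1
                    errs.append(abs(hit.iloc[0]["onset_s"] - g.onset_s))
            for d in det.itertuples():
                if not ((inj["onset_s"] < d.offset_s) & (inj["offset_s"] > d.onset_s)).any():
                    n_fp += 1
    step = decim / cfg.fs
    return dict(
        recall=n_hit / n_inj,
        false_positives_per_steady_phase=n_fp / n_phases,
        median_onset_error_steps=float(np.median(errs)) / step,
        n_injected=n_inj,
    )


def short_burst_yields_nothing(fs_map: float = 32.0) -> int:
    """An 80 ms supra-threshold injection fails the 100 ms rule: returns the
    number of detections (expected 0)."""
    rng = np.random.default_rng(0)
    s = rng.uniform(0, 0.5, 4000)
    n = int(round(0.08 * fs_map))
    s[1000 : 1000 + n] = 2.0
    thr = bu.BurstThreshold(level=75.0, value=1.0)
    det = bu.detect_bursts(s, np.arange(4000) / fs_map, thr, min_duration=0.1)
    return len(det)


def imc_cluster_detection_rate(
    coupled: bool,
    n_cohorts: int = 10,
    n_participants: int = 16,
    seed: int = 1000,
    n_perm: int = 200,
    alpha: float = 0.05,
) -> float:
    """Fraction of replicate synthetic cohorts in which the pipeline finds a
    significant burst-aligned beta-band IMC cluster in the F0 condition.

    ``coupled=True`` uses the default burst-locked coupling (kappa = 8 in
    F0); ``coupled=False`` zeroes the coupling everywhere (the F1-like
    null), so the rate estimates the pipeline-level false-positive rate.
    """
    spec = None if coupled else fast_coupling_spec(
        kappa_burst={"F0": 0.0, "F1": 0.0, "F2": 0.0}
    )
    hits = 0
    for i in range(n_cohorts):
        cfg = RunConfig(
            n_participants=n_participants,
            seed=seed + i,
            include_cmc=False,
            include_emg_amplitude=False,
            include_behaviour=False,
            include_figures=False,
            n_perm=n_perm,
        )
        res = run_cohort(cfg, spec=spec)
        cr = res.cluster_results[("imc", "F0")]
        if cr is not None and cr.p_accumulated_t < alpha:
            hits += 1
    return hits / n_cohorts
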