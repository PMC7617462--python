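"""End-to-end orchestration: simulate -> preprocess -> bursts ->
connectivity -> stats -> report.

The pipeline runs a synthetic cohort through the full analysis and emits
the study's four headline artefacts: condition-wise band-amplitude
summaries, burst-aligned minus no-burst-aligned IMC difference maps
(with significance contours from the cluster permutation test),
burst-aligned CMC difference maps against an EMG-shuffled surrogate,
per-condition beta-band deltas with post-hoc tests, and burst-aligned
EMG amplitude maps.  Control analyses (median split on burst amplitude
or duration; equal-count subsampling) reuse each participant's stored
continuous IMC map, so they re-align epochs without recomputing PLV.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import bursts as bu
from . import connectivity as conn
from . import preprocess as pp
from . import stats as st
from .behaviour import behaviour_table
from .synth import (
    CouplingSpec,
    TaskConfig,
    fast_coupling_spec,
    fast_task_config,
    generate_kinematics,
    generate_participant,
)

log = logging.getLogger("burstsync")

__all__ = ["RunConfig", "ParticipantResult", "CohortResult", "run_participant",
           "run_cohort", "run_pipeline", "report_burst_controls"]


@dataclass
class RunConfig:
    """Flat, serialisable run configuration (see docs/methods.md)."""

    n_participants: int = 10
    seed: int = 7
    preset: str = "fast"  # "fast" (fs=512, 2 short blocks) or "full" (paper-scale layout)
    # analysis parameters
    amp_freqs: tuple = (5.0, 95.0, 3.0)  # (low, high, step) for amplitude maps
    plv_freqs: tuple = (6.0, 45.0, 3.0)  # (low, high, step) for PLV maps
    phase_bandwidth: float = 8.0
    plv_window_s: float = 0.25
    epoch_window: tuple = (-0.4, 0.8)
    decim: int = 16
    burst_percentile: float = 75.0
    noburst_percentile: float = 50.0
    min_burst_s: float = 0.1
    noburst_min_s: float = 0.5
    noburst_guard_s: float = 0.5
    cluster_threshold: float = 1.645
    n_perm: int = 500
    min_epochs: int = 3  # participant enters a condition's group test only
    # with at least this many burst AND no-burst epochs (few-epoch means
    # are heavy-tailed and destabilise the group t statistics)
    n_cmc_shuffles: int = 8
    # stage toggles
    include_cmc: bool = True
    include_emg_amplitude: bool = True
    include_behaviour: bool = True
    include_figures: bool = True

    def task_config(self) -> TaskConfig:
        if self.preset == "full":
            return TaskConfig()
        return fast_task_config()

    def coupling_spec(self) -> CouplingSpec:
        if self.preset == "full":
            return CouplingSpec()
        return fast_coupling_spec()

    def amp_grid(self) -> np.ndarray:
        lo, hi, step = self.amp_freqs
        return np.arange(lo, hi + 0.5 * step, step)

    def plv_grid(self) -> np.ndarray:
        lo, hi, step = self.plv_freqs
        return np.arange(lo, hi + 0.5 * step, step)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("amp_freqs", "plv_freqs", "epoch_window"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump({k: list(v) if isinstance(v, tuple) else v
                            for k, v in asdict(self).items()}, fh, sort_keys=True)


@dataclass
class ParticipantResult:
    participant: int
    bursts: pd.DataFrame
    nobursts: pd.DataFrame
    rejected: pd.DataFrame
    band_amplitude: pd.DataFrame  # condition x band mean z during Steady
    # per-condition epoch-aligned maps (None when no usable epochs)
    imc_burst: dict
    imc_noburst: dict
    cmc_burst: dict
    cmc_surrogate: dict
    emg_burst: dict
    emg_noburst: dict
    epoch_counts: dict
    # continuous pair-averaged maps per block for control re-alignments
    imc_continuous: dict  # block -> (values FxT, times)
    cmc_continuous: dict  # block -> (values FxT, times); empty when CMC disabled
    map_freqs: np.ndarray
    amp_map_freqs: np.ndarray
    epoch_times: np.ndarray | None
    behaviour: pd.DataFrame | None
    ground_truth_bursts: pd.DataFrame


def _steady_band_amplitude(zmap: pp.TimeFrequencyMap, events: pd.DataFrame) -> pd.DataFrame:
    """Mean z amplitude per band over Steady samples, per condition."""
    rows = []
    for band in pp.BANDS.values():
        if band.high > zmap.freqs.max() or band.low < zmap.freqs.min():
            continue
        series = pp.band_series(zmap, band)
        for cond, grp in events.groupby("condition"):
            sel = np.zeros(len(zmap.times), dtype=bool)
            for r in grp.itertuples():
                sel |= (zmap.times >= r.t_steady) & (zmap.times < r.t_go)
            if sel.any():
                rows.append(dict(band=band.name, condition=cond, amplitude=float(series[sel].mean())))
    return pd.DataFrame(rows)


def run_participant(
    cfg: RunConfig,
    participant: int,
    seed: int,
    task: TaskConfig | None = None,
    spec: CouplingSpec | None = None,
) -> ParticipantResult:
    """Analyse one simulated participant end to end."""
    task = task or cfg.task_config()
    spec = spec or cfg.coupling_spec()
    schedule, recs, gt = generate_participant(task, spec, seed)
    conds = task.conditions
    plv_grid = cfg.plv_grid()
    window = tuple(cfg.epoch_window)

    all_bursts, all_nobursts, all_rejected, band_rows = [], [], [], []
    # accumulators: condition -> list of per-block aligned maps (weighted by epochs)
    acc: dict[str, dict[str, list]] = {
        name: {c: [] for c in conds}
        for name in ("imc_b", "imc_n", "cmc_b", "cmc_s", "emg_b", "emg_n")
    }
    counts = {c: dict(burst=0, noburst=0) for c in conds}
    imc_continuous: dict[int, tuple] = {}
    cmc_continuous: dict[int, tuple] = {}
    epoch_times = None

    for rec in recs:
        filt = pp.preprocess_filter(rec, notch=50.0 if spec.line_noise_amp else None)
        events = rec.events

        # --- burst detection on the z-scored beta-band series
        det_freqs = cfg.amp_grid() if cfg.include_emg_amplitude else np.arange(15.0, 36.0, 2.0)
        ctx_map = pp.cwt_amplitude(filt, "CTX", det_freqs, decim=cfg.decim)
        zmap = pp.zscore_block(ctx_map, pp.block_stats(ctx_map))
        beta = pp.band_series(zmap, pp.BANDS["beta"])
        thr_hi = bu.compute_threshold(beta, cfg.burst_percentile, block=rec.block)
        thr_lo = bu.compute_threshold(beta, cfg.noburst_percentile, block=rec.block)
        bursts_df = bu.detect_bursts(beta, zmap.times, thr_hi, cfg.min_burst_s, events)
        nobursts_df = bu.detect_noburst(beta, zmap.times, thr_lo, bursts_df,
                                        cfg.noburst_min_s, cfg.noburst_guard_s, events)

        rej = pp.reject_trials(filt)
        kept = set(rej[rej["keep"]]["trial"])
        steady_bursts = bursts_df[(bursts_df["phase"] == "steady") & bursts_df["trial"].isin(kept)]
        nobursts_df = nobursts_df[nobursts_df["trial"].isin(kept)]
        all_bursts.append(bursts_df)
        all_nobursts.append(nobursts_df)
        all_rejected.append(rej)
        if cfg.include_emg_amplitude:
            band_rows.append(_steady_band_amplitude(zmap, events))

        # --- phase stacks per channel: (n_freqs, n_samples)
        roles = rec.roles
        phases = {}
        for role in roles if cfg.include_cmc else roles[1:]:
            phases[role] = np.stack(
                [conn.instantaneous_phase(filt, role, f, cfg.phase_bandwidth).phase for f in plv_grid]
            )

        # --- continuous pair-averaged PLV maps (full rate, then decimated)
        from scipy.ndimage import uniform_filter1d

        def pair_plv(pa: str, pb: str) -> np.ndarray:
            z = np.exp(1j * (phases[pa] - phases[pb]))
            win = int(round(cfg.plv_window_s * filt.fs))
            sm = uniform_filter1d(z.real, win, axis=-1, mode="nearest") + 1j * uniform_filter1d(
                z.imag, win, axis=-1, mode="nearest"
            )
            plv = np.minimum(np.abs(sm), 1.0)
            half = win // 2
            plv[:, :half] = np.nan
            plv[:, plv.shape[1] - (win - 1 - half):] = np.nan
            return plv[:, :: cfg.decim]

        imc_cont = np.mean([pair_plv(pa, pb) for pa, pb in conn.imc_pairs()], axis=0)
        times_dec = np.arange(rec.n_samples)[:: cfg.decim] / rec.fs
        imc_continuous[rec.block] = (imc_cont, times_dec)
        if cfg.include_cmc:
            cmc_continuous[rec.block] = (
                np.mean([pair_plv(pa, pb) for pa, pb in conn.cmc_pairs()], axis=0),
                times_dec,
            )

        # --- EMG amplitude maps (z-scored) for the burst-aligned analogue
        emg_zmaps = None
        if cfg.include_emg_amplitude:
            emg_zmaps = []
            for role in roles[1:]:
                m = pp.cwt_amplitude(filt, role, cfg.amp_grid(), decim=cfg.decim)
                emg_zmaps.append(pp.zscore_block(m, pp.block_stats(m)).values)
            emg_zmaps = np.mean(emg_zmaps, axis=0)

        # --- align per condition
        for cond in conds:
            b_on = steady_bursts[steady_bursts["condition"] == cond]["onset_s"].to_numpy()
            n_on = nobursts_df[nobursts_df["condition"] == cond]["onset_s"].to_numpy()
            if len(b_on):
                try:
                    m, epoch_times, k = conn.align_epochs(imc_cont, times_dec, b_on, window)
                    acc["imc_b"][cond].append((m, k))
                    counts[cond]["burst"] += k
                except ValueError:
                    pass
                if emg_zmaps is not None:
                    try:
                        m, _, k = conn.align_epochs(emg_zmaps, times_dec, b_on, window)
                        acc["emg_b"][cond].append((m, k))
                    except ValueError:
                        pass
            if len(n_on):
                try:
                    m, epoch_times, k = conn.align_epochs(imc_cont, times_dec, n_on, window)
                    acc["imc_n"][cond].append((m, k))
                    counts[cond]["noburst"] += k
                except ValueError:
                    pass
                if emg_zmaps is not None:
                    try:
                        m, _, k = conn.align_epochs(emg_zmaps, times_dec, n_on, window)
                        acc["emg_n"][cond].append((m, k))
                    except ValueError:
                        pass
            # --- CMC: epoch phases, identity vs shuffled EMG assignment
            if cfg.include_cmc and len(b_on) >= 2:
                try:
                    ep_ctx, _ = conn.epoch_phase(phases["CTX"], rec.fs, b_on, window)
                except ValueError:
                    continue
                cmc_b, cmc_s = [], []
                for emg_role in roles[1:]:
                    ep_emg, _ = conn.epoch_phase(phases[emg_role], rec.fs, b_on, window)
                    cmc_b.append(conn.plv_from_phase_epochs(ep_ctx, ep_emg, rec.fs, cfg.plv_window_s))
                    cmc_s.append(conn.cmc_null_shuffle(ep_ctx, ep_emg, rec.fs,
                                                       seed=seed + rec.block, n_shuffles=cfg.n_cmc_shuffles,
                                                       window_s=cfg.plv_window_s))
                k = ep_ctx.shape[0]
                acc["cmc_b"][cond].append((_decim_epoch(np.mean(cmc_b, axis=0), cfg.decim), k))
                acc["cmc_s"][cond].append((_decim_epoch(np.mean(cmc_s, axis=0), cfg.decim), k))

    def weighted(acc_list):
        if not acc_list:
            return None
        w = np.array([k for _, k in acc_list], dtype=float)
        stack = np.stack([_strip_nan_cols(m) for m, _ in acc_list])
        return np.tensordot(w / w.sum(), stack, axes=1)

    behaviour = None
    if cfg.include_behaviour:
        kin = generate_kinematics(schedule, task, spec, seed=seed + 991)
        behaviour = behaviour_table(kin, schedule.trials, spec.reach_distance_m)

    band_amp = (
        pd.concat(band_rows).groupby(["band", "condition"], as_index=False)["amplitude"].mean()
        if band_rows
        else pd.DataFrame(columns=["band", "condition", "amplitude"])
    )
    return ParticipantResult(
        participant=participant,
        bursts=pd.concat(all_bursts, ignore_index=True),
        nobursts=pd.concat(all_nobursts, ignore_index=True),
        rejected=pd.concat(all_rejected, ignore_index=True),
        band_amplitude=band_amp,
        imc_burst={c: weighted(acc["imc_b"][c]) for c in conds},
        imc_noburst={c: weighted(acc["imc_n"][c]) for c in conds},
        cmc_burst={c: weighted(acc["cmc_b"][c]) for c in conds},
        cmc_surrogate={c: weighted(acc["cmc_s"][c]) for c in conds},
        emg_burst={c: weighted(acc["emg_b"][c]) for c in conds},
        emg_noburst={c: weighted(acc["emg_n"][c]) for c in conds},
        epoch_counts=counts,
        imc_continuous=imc_continuous,
        cmc_continuous=cmc_continuous,
        map_freqs=plv_grid,
        amp_map_freqs=cfg.amp_grid(),
        epoch_times=epoch_times,
        behaviour=behaviour,
        ground_truth_bursts=pd.DataFrame(),
    )


def _decim_epoch(m: np.ndarray, decim: int) -> np.ndarray:
    return m[:, ::decim]


def _strip_nan_cols(m: np.ndarray) -> np.ndarray:
    return m


@dataclass
class CohortResult:
    config: RunConfig
    participants: list
    cluster_results: dict  # (measure, condition) -> ClusterResult | None
    delta_tables: dict  # measure -> DataFrame participant x condition
    anova: dict
    posthoc: pd.DataFrame
    band_amplitude: pd.DataFrame
    burst_summary: pd.DataFrame


def _beta_delta(pr: ParticipantResult, a: dict, b: dict, cond: str) -> float | None:
    """Beta-band, post-onset mean of an aligned difference map."""
    if a.get(cond) is None or b.get(cond) is None:
        return None
    diff = a[cond] - b[cond]
    freqs = pr.map_freqs if diff.shape[0] == len(pr.map_freqs) else pr.amp_map_freqs
    rows = (freqs >= 15) & (freqs <= 35)
    post = pr.epoch_times >= 0 if pr.epoch_times is not None else slice(None)
    sub = diff[rows][:, post] if pr.epoch_times is not None else diff[rows]
    return float(np.nanmean(sub))


def run_cohort(
    cfg: RunConfig,
    task: TaskConfig | None = None,
    spec: CouplingSpec | None = None,
) -> CohortResult:
    """Simulate and analyse a cohort, then run the group statistics."""
    rng = np.random.SeedSequence(cfg.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in rng.spawn(cfg.n_participants)]
    participants = []
    for i, s in enumerate(seeds):
        t0 = time.time()
        participants.append(run_participant(cfg, i, s, task, spec))
        log.info("participant %d analysed in %.1f s", i, time.time() - t0)

    conds = (task or cfg.task_config()).conditions
    measures = {
        "imc": ("imc_burst", "imc_noburst"),
        "cmc": ("cmc_burst", "cmc_surrogate"),
        "emg": ("emg_burst", "emg_noburst"),
    }
    cluster_results: dict = {}
    delta_tables: dict = {}
    for name, (attr_a, attr_b) in measures.items():
        deltas = pd.DataFrame(index=range(cfg.n_participants), columns=list(conds), dtype=float)
        for cond in conds:
            stack_a, stack_b = [], []
            for pr in participants:
                a = getattr(pr, attr_a).get(cond)
                b = getattr(pr, attr_b).get(cond)
                k = pr.epoch_counts[cond]
                if k["burst"] < cfg.min_epochs:
                    a = None
                if attr_b in ("imc_noburst", "emg_noburst") and k["noburst"] < cfg.min_epochs:
                    b = None
                if a is not None and b is not None:
                    stack_a.append(a)
                    stack_b.append(b)
                    deltas.loc[pr.participant, cond] = _beta_delta(pr, getattr(pr, attr_a),
                                                                   getattr(pr, attr_b), cond)
            if len(stack_a) >= 2 and not all(s is None for s in stack_a):
                cluster_results[(name, cond)] = st.cluster_permutation(
                    np.stack(stack_a), np.stack(stack_b),
                    threshold=cfg.cluster_threshold, n_perm=cfg.n_perm, seed=cfg.seed,
                )
            else:
                cluster_results[(name, cond)] = None
        delta_tables[name] = deltas

    # ANOVA + post-hoc on the beta-band deltas across conditions
    anova: dict = {}
    posthoc_rows = []
    for name, deltas in delta_tables.items():
        complete = deltas.dropna()
        if len(complete) >= 3 and complete.shape[1] >= 2:
            anova[name] = st.rm_anova(complete.to_numpy())
            pvals, labels, zs, rs = [], [], [], []
            for i in range(len(conds)):
                for j in range(i + 1, len(conds)):
                    w = st.wilcoxon_signed_rank(complete[conds[i]], complete[conds[j]])
                    pvals.append(w.p)
                    labels.append(f"{conds[i]} v {conds[j]}")
                    zs.append(w.extras["Z"])
                    rs.append(w.effect_size)
            adj = st.holm_bonferroni(pvals)
            for lab, z, r, p, ap in zip(labels, zs, rs, pvals, adj):
                posthoc_rows.append(dict(measure=name, comparison=lab, Z=z, r=r, p=p, p_holm=ap))
        else:
            anova[name] = None
    posthoc = pd.DataFrame(posthoc_rows, columns=["measure", "comparison", "Z", "r", "p", "p_holm"])

    band_amp = (
        pd.concat([pr.band_amplitude.assign(participant=pr.participant) for pr in participants],
                  ignore_index=True)
        if any(len(pr.band_amplitude) for pr in participants)
        else pd.DataFrame(columns=["band", "condition", "amplitude", "participant"])
    )
    burst_summary = pd.concat(
        [bu.burst_metrics(pr.bursts).assign(participant=pr.participant) for pr in participants],
        ignore_index=True,
    )
    return CohortResult(cfg, participants, cluster_results, delta_tables, anova,
                        posthoc, band_amp, burst_summary)


def report_burst_controls(result: CohortResult, n_sub: int = 100, reps: int = 100) -> dict:
    """Median-split and subsampling controls on the F0 bursts.

    Re-aligns each participant's stored continuous IMC map to burst
    subsets, so no PLV is recomputed.  Returns delta tables and Wilcoxon
    comparisons (low-F0 vs normal F1/F2), plus a skip record when a
    participant lacks the bursts for subsampling.
    """
    cfg = result.config
    window = tuple(cfg.epoch_window)
    out: dict = {"median_split": {}, "subsample": {}, "skipped": []}

    def aligned_mean(cont_maps: dict, onsets_by_block: dict):
        maps = []
        for block, (values, times) in cont_maps.items():
            ons = onsets_by_block.get(block)
            if ons is None or len(ons) == 0:
                continue
            try:
                m, rel_t, k = conn.align_epochs(values, times, ons, window)
                maps.append((m, k, rel_t))
            except ValueError:
                continue
        if not maps:
            return None, None
        w = np.array([k for _, k, _ in maps], dtype=float)
        return np.tensordot(w / w.sum(), np.stack([m for m, _, _ in maps]), axes=1), maps[0][2]

    def delta_for(pr: ParticipantResult, measure: str, onsets_by_block: dict, cond: str) -> float | None:
        """Beta-band post-onset burst-vs-no-burst delta for a burst subset,
        re-aligned from the participant's stored continuous map."""
        cont = pr.imc_continuous if measure == "imc" else pr.cmc_continuous
        if not cont:
            return None
        nob = pr.nobursts[pr.nobursts["condition"] == cond]
        nob_ons = {b: g["onset_s"].to_numpy() for b, g in nob.groupby("block")}
        burst_map, rel_t = aligned_mean(cont, onsets_by_block)
        base_map, _ = aligned_mean(cont, nob_ons)
        if burst_map is None or base_map is None:
            return None
        rows = (pr.map_freqs >= 15) & (pr.map_freqs <= 35)
        diff = burst_map - base_map
        return float(np.nanmean(diff[rows][:, rel_t >= 0]))

    measures = ["imc"] + (["cmc"] if cfg.include_cmc else [])
    for key in ("peak_amp", "duration_s"):
        for measure in measures:
            rows = []
            for pr in result.participants:
                f0 = pr.bursts[(pr.bursts["condition"] == "F0") & (pr.bursts["phase"] == "steady")]
                if len(f0) < 2:
                    continue
                low, _high = bu.median_split(f0, key)
                ons = {b: g["onset_s"].to_numpy() for b, g in low.groupby("block")}
                d_low = delta_for(pr, measure, ons, "F0")
                rows.append(dict(participant=pr.participant, delta_low_f0=d_low,
                                 delta_f1=result.delta_tables[measure].loc[pr.participant, "F1"],
                                 delta_f2=result.delta_tables[measure].loc[pr.participant, "F2"],
                                 low_mean=float(low[key].mean())))
            tab = pd.DataFrame(rows).dropna()
            tests = {}
            if len(tab) >= 5:
                for other in ("delta_f1", "delta_f2"):
                    w = st.wilcoxon_signed_rank(tab["delta_low_f0"], tab[other])
                    tests[other] = dict(Z=w.extras["Z"], p=w.p, r=w.effect_size)
            out["median_split"][(measure, key)] = dict(table=tab, tests=tests)

    rng = np.random.default_rng(cfg.seed + 17)
    rows = []
    for pr in result.participants:
        steady = pr.bursts[pr.bursts["phase"] == "steady"]
        counts = steady.groupby("condition").size()
        if len(counts) < 3 or int(counts.min()) < n_sub:
            out["skipped"].append(dict(participant=pr.participant,
                                       reason=f"insufficient bursts (counts={counts.to_dict()}, need {n_sub})"))
            continue
        n_eff = n_sub
        sets = bu.subsample_bursts(steady, n=n_eff, reps=reps, seed=int(rng.integers(2**31)))
        deltas = {c: [] for c in ("F0", "F1", "F2")}
        for s in sets:
            for cond in deltas:
                sub = s[s["condition"] == cond]
                ons = {b: g["onset_s"].to_numpy() for b, g in sub.groupby("block")}
                d = delta_for(pr, "imc", ons, cond)
                if d is not None:
                    deltas[cond].append(d)
        rows.append(dict(participant=pr.participant, n_subsampled=n_eff,
                         **{f"delta_{c}": float(np.mean(v)) if v else np.nan
                            for c, v in deltas.items()}))
    out["subsample"]["table"] = pd.DataFrame(rows)
    return out


def run_pipeline(cfg: RunConfig, out_dir: str | Path) -> dict:
    """Full run with persisted artefacts; returns the run report dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "run_config.yaml")
    t0 = time.time()
    result = run_cohort(cfg)

    report: dict = {"stages": {}, "seed": cfg.seed, "n_participants": cfg.n_participants}
    result.burst_summary.to_csv(out / "burst_summary.csv", index=False)
    result.band_amplitude.to_csv(out / "band_amplitude.csv", index=False)
    result.posthoc.to_csv(out / "posthoc_tests.csv", index=False)
    for name, deltas in result.delta_tables.items():
        deltas.to_csv(out / f"delta_{name}.csv")

    stats_rows = []
    for (name, cond), cr in result.cluster_results.items():
        stats_rows.append(dict(
            measure=name, condition=cond,
            p_accumulated_t=cr.p_accumulated_t if cr else np.nan,
            p_size=cr.p_size if cr else np.nan,
            max_cluster_size=cr.max_size if cr else 0,
            max_accumulated_t=cr.max_accumulated_t if cr else 0.0,
        ))
    cluster_df = pd.DataFrame(stats_rows)
    cluster_df.to_csv(out / "cluster_tests.csv", index=False)

    anova_rows = []
    for name, a in result.anova.items():
        if a is not None:
            anova_rows.append(dict(measure=name, F=a.statistic, df1=a.df[0], df2=a.df[1],
                                   p=a.p, partial_eta_sq=a.effect_size,
                                   epsilon=a.extras["epsilon"]))
    pd.DataFrame(anova_rows).to_csv(out / "anova_tests.csv", index=False)

    from .io import save_map

    h5 = out / "maps.h5"
    pr0 = result.participants[0]
    for (name, cond), cr in result.cluster_results.items():
        if cr is None or pr0.epoch_times is None:
            continue
        freqs = pr0.amp_map_freqs if name == "emg" else pr0.map_freqs
        save_map(h5, f"{name}/{cond}/t_map", cr.t_map, freqs, pr0.epoch_times,
                 attrs=dict(p_accumulated_t=cr.p_accumulated_t, threshold=cr.threshold))

    if cfg.include_behaviour:
        beh = pd.concat([pr.behaviour.assign(participant=pr.participant)
                         for pr in result.participants if pr.behaviour is not None],
                        ignore_index=True)
        beh.to_csv(out / "behaviour.csv", index=False)

    if cfg.include_figures:
        _figures(result, out)

    report["stages"]["pipeline"] = dict(
        elapsed_s=round(time.time() - t0, 1),
        bursts_detected=int(result.burst_summary["count"].sum()),
        cluster_tests={f"{m}/{c}": (cr.p_accumulated_t if cr else None)
                       for (m, c), cr in result.cluster_results.items()},
    )
    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report


def _figures(result: CohortResult, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cfg = result.config
    conds = list(result.delta_tables["imc"].columns)
    pr0 = result.participants[0]

    # band amplitude bars
    if len(result.band_amplitude):
        fig, axes = plt.subplots(1, 2, figsize=(7, 3))
        for ax, band in zip(axes, ("beta", "gamma")):
            sub = result.band_amplitude[result.band_amplitude["band"] == band]
            if len(sub):
                sub.groupby("condition")["amplitude"].mean().plot.bar(ax=ax)
            ax.set_title(f"{band} amplitude (z)")
        fig.tight_layout()
        fig.savefig(out / "fig_band_amplitude.png", dpi=110)
        plt.close(fig)

    # difference maps with significance contours
    for name in ("imc", "cmc", "emg"):
        maps = []
        for cond in conds:
            cr = result.cluster_results.get((name, cond))
            maps.append(cr)
        if all(m is None for m in maps) or pr0.epoch_times is None:
            continue
        mfreqs = pr0.amp_map_freqs if name == "emg" else pr0.map_freqs
        fig, axes = plt.subplots(1, len(conds), figsize=(4 * len(conds), 3), squeeze=False)
        for ax, cond, cr in zip(axes[0], conds, maps):
            if cr is None:
                ax.set_visible(False)
                continue
            extent = [pr0.epoch_times[0], pr0.epoch_times[-1], mfreqs[0], mfreqs[-1]]
            ax.imshow(cr.t_map, aspect="auto", origin="lower", extent=extent, cmap="RdBu_r",
                      vmin=-4, vmax=4)
            mask = cr.significant_mask
            if mask.any():
                ax.contour(pr0.epoch_times, mfreqs, mask.astype(float), levels=[0.5],
                           colors="k")
            ax.axvline(0, color="r", lw=1)
            ax.set_title(f"{name.upper()} {cond} (p={cr.p_accumulated_t:.3f})")
        fig.tight_layout()
        fig.savefig(out / f"fig_{name}_difference.png", dpi=110)
        plt.close(fig)

    # per-condition beta-band deltas
    fig, axes = plt.subplots(1, len(result.delta_tables), figsize=(9, 3))
    for ax, (name, deltas) in zip(np.atleast_1d(axes), result.delta_tables.items()):
        deltas.mean().plot.bar(ax=ax, yerr=deltas.sem())
        ax.set_title(f"beta-band delta {name.upper()}")
        ax.axhline(0, color="k", lw=0.5)
    fig.tight_layout()
    fig.savefig(out / "fig_delta_summary.png", dpi=110)
    plt.close(fig)
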