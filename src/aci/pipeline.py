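"""End-to-end orchestration of a simulated classification-image study.

:func:`run_simulated_study` chains all stages — target synthesis,
observer population construction, staircase experiments, trial
balancing, template estimation, prediction matrix, and group statistics
— under a single master seed, writing every artifact plus a manifest of
content checksums to one output directory.  Defaults in
:class:`RunConfig` reproduce the published experiment layout (20
sessions x 500 trials, initial SNR -11 dB, 54-channel 96-7760 Hz grid,
15.6 ms frames); simulations in tests and analysis scripts override the
scale, never the rules.

:func:`import_experiment_log` rebuilds a trial table from an exported
delimited-text log plus its JSON config sidecar by regenerating the
logged stimuli (targets from labels, noise from stored seeds) — the
same path a re-analysis of deposited trial logs would take.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import groupstats, io, prediction
from .cochleogram import CochleogramConfig, compute_cochleogram, make_filterbank
from .estimation import balance_trials, fit_aci, select_penalty, table_from_log, zscore_aci
from .observer import matched_observer, perturbed_observer
from .staircase import StaircaseConfig, simulate_experiment
from .stimuli import default_targets, generate_noise, mix_at_snr


@dataclass
class RunConfig:
    """All experiment parameters; defaults are the published values."""

    n_sessions: int = 20
    trials_per_session: int = 500
    initial_snr_db: float = -11.0
    initial_step_db: float = 2.0
    step_decay: float = 0.9
    step_floor_db: float = 0.2
    sample_rate: int = 48_000
    n_channels: int = 54
    f_min: float = 96.0
    f_max: float = 7760.0
    time_bin: float = 0.0156
    penalty_grid: tuple = tuple(np.geomspace(1e0, 1e6, 15))
    fixed_penalty: float | None = None  # skip CV selection when set
    n_folds: int = 10
    n_per_group: int = 19
    observer_gain: float = 50.0
    heterogeneity: float = 0.3
    # group-2 observers get an extra smooth template feature added inside
    # this pixel block ((t0, t1), (f0, f1)); None disables the injected
    # group difference.  The weight is the feature's norm relative to the
    # (unit-norm) base template.
    group2_extra_region: tuple | None = None
    group2_extra_weight: float = 0.5
    fdr_q: float = 0.01
    cluster_alpha: float = 0.05
    n_permutations: int = 1000

    def staircase(self) -> StaircaseConfig:
        return StaircaseConfig(initial_snr_db=self.initial_snr_db,
                               initial_step_db=self.initial_step_db,
                               step_decay=self.step_decay,
                               step_floor_db=self.step_floor_db)

    def cochleogram(self) -> CochleogramConfig:
        return CochleogramConfig(sample_rate=self.sample_rate,
                                 n_channels=self.n_channels,
                                 f_min=self.f_min, f_max=self.f_max,
                                 time_bin=self.time_bin)


def _sha256(data: bytes) -> str:
    return hashlib.sha256(data).hexdigest()


def _array_checksum(arr: np.ndarray) -> str:
    return _sha256(np.ascontiguousarray(arr).tobytes())


@dataclass
class StudyBundle:
    config: RunConfig
    master_seed: int
    tables: list
    models: list
    z_maps: np.ndarray
    group_labels: list
    pred_matrix: prediction.PredictionMatrix
    specificities: list
    sdt: list
    group_results: dict
    weight_sets: list
    roi_report: pd.DataFrame
    manifest: dict


def _reference_mixes(targets, fb, ccfg, snr_grid, seed, n_per_target=8):
    """Noisy-mix cochleograms over the staircase's working SNR range.

    Returns (refs, labels, common_modes): reference cochleograms for
    bias centering, their response classes, and an orthonormal basis of
    mean-stimulus patterns (one per probed SNR, plus the flat map) used
    to stabilize observer criteria across difficulty.
    """
    refs, labels = [], []
    modes = []
    for s_idx, snr_db in enumerate(snr_grid):
        level_refs = []
        for j, t in enumerate(targets):
            for i in range(n_per_target):
                noise = generate_noise(len(t.samples), seed,
                                       index=s_idx * 10_000 + j * 1000 + i)
                mix = mix_at_snr(t, noise, snr_db)
                coch = compute_cochleogram(mix.samples, fb, ccfg).values
                level_refs.append(coch)
                labels.append(t.response_class)
        refs.extend(level_refs)
        modes.append(np.mean(level_refs, axis=0))
    modes.append(np.ones_like(modes[0]))  # global level
    basis = []
    for m in modes:
        v = m.astype(np.float64).copy()
        for b in basis:
            v -= np.vdot(v, b) * b
        norm = np.linalg.norm(v)
        if norm > 1e-10:
            basis.append(v / norm)
    return refs, labels, basis


def _stabilize_template(template, common_modes):
    """Project the common stimulus modes out of a template and renormalize.

    The decision variable then ignores the stimulus structure shared by
    all targets at any difficulty level, so the observer's criterion
    stays put as the staircase moves the SNR.
    """
    t = template.astype(np.float64).copy()
    for b in common_modes:
        t -= np.vdot(t, b) * b
    norm = np.linalg.norm(t)
    if norm == 0:
        raise ValueError("template lies entirely in the common-mode span")
    return t / norm


def _build_population(config: RunConfig, target_coch, labels, refs,
                      ref_labels, common_modes, seed_seq):
    """Two groups of observers around the ideal contrast template.

    Every template is stabilized against the common stimulus modes and
    its bias centered on the reference mixes, so the simulated listeners
    hold a steady criterion while the staircase sweeps the SNR.
    """
    from .observer import ObserverSpec, centered_bias

    base = matched_observer(target_coch, labels, gain=config.observer_gain,
                            reference_cochleograms=refs,
                            reference_labels=ref_labels)
    observers, groups = [], []
    n = config.n_per_group
    for g, group in enumerate(("group1", "group2")):
        for k in range(n):
            obs = perturbed_observer(base, config.heterogeneity,
                                     seed=int(seed_seq[g * n + k]))
            tpl = obs.template
            if group == "group2" and config.group2_extra_region is not None:
                from scipy.ndimage import gaussian_filter

                (t0, t1), (f0, f1) = config.group2_extra_region
                bump = np.zeros_like(tpl)
                bump[t0:t1, f0:f1] = 1.0
                bump = gaussian_filter(bump, 1.5)
                bump /= np.linalg.norm(bump)
                tpl = tpl + config.group2_extra_weight * bump
            tpl = _stabilize_template(tpl, common_modes)
            obs = ObserverSpec(
                template=tpl,
                bias=centered_bias(tpl, obs.gain, refs, ref_labels),
                gain=obs.gain, seed=obs.seed)
            observers.append(obs)
            groups.append(group)
    return observers, groups


def run_simulated_study(config: RunConfig, seed: int,
                        out_dir=None) -> StudyBundle:
    """Simulate a two-group study end to end; reproducible from the seed."""
    rng = np.random.default_rng(seed)
    child = rng.integers(2**31, size=1000)
    ccfg = config.cochleogram()
    scfg = config.staircase()
    targets = default_targets(config.sample_rate)
    fb = make_filterbank(ccfg)
    target_coch = [compute_cochleogram(t.samples, fb, ccfg) for t in targets]
    labels = [t.response_class for t in targets]

    snr_grid = (config.initial_snr_db, config.initial_snr_db + 8,
                config.initial_snr_db + 16)
    refs, ref_labels, common_modes = _reference_mixes(
        targets, fb, ccfg, snr_grid, int(child[500]))
    observers, groups = _build_population(config, target_coch, labels, refs,
                                          ref_labels, common_modes,
                                          child[:100])
    tables, full_tables, logs = [], [], []
    for k, obs in enumerate(observers):
        log = simulate_experiment(
            obs, targets, noise_seed=int(child[100 + k]),
            n_sessions=config.n_sessions,
            trials_per_session=config.trials_per_session,
            staircase_config=scfg, cochleogram_config=ccfg,
            seed=int(child[200 + k]))
        full = table_from_log(log, listener_id=f"L{k:02d}")
        table = balance_trials(full,
                               np.random.default_rng(int(child[300 + k])))
        logs.append(log)
        full_tables.append(full)
        tables.append(table)

    if config.fixed_penalty is not None:
        lam = float(config.fixed_penalty)
        curve = None
    else:
        lam, curve = select_penalty(tables, config.penalty_grid,
                                    n_folds=config.n_folds,
                                    seed=int(child[400]))
    models = [fit_aci(t, lam) for t in tables]
    z_maps = np.array([zscore_aci(m) for m in models])

    pm = prediction.prediction_matrix(tables, lam, n_folds=config.n_folds,
                                      seed=int(child[401]))
    specs = [prediction.specificity(pm, i) for i in range(len(tables))]
    # SDT metrics describe raw task performance: computed on the full
    # (unbalanced) runs, not the balanced estimation tables
    sdt = [prediction.sdt_metrics(t) for t in full_tables]

    g1 = z_maps[[i for i, g in enumerate(groups) if g == "group1"]]
    g2 = z_maps[[i for i, g in enumerate(groups) if g == "group2"]]
    t_map, p_map, fdr_mask = groupstats.pixel_ttest_fdr(z_maps, config.fdr_q)
    clusters, diff_t = groupstats.cluster_permutation_test(
        g1, g2, config.cluster_alpha, config.n_permutations,
        np.random.default_rng(int(child[402])))
    sets = groupstats.extract_weight_sets(z_maps, ccfg.time_bin,
                                          fb.center_freqs)
    roi = (groupstats.roi_group_test(sets, g1, g2) if sets
           else pd.DataFrame())

    group_results = {
        "mean_map": z_maps.mean(axis=0), "t_map": t_map, "p_map": p_map,
        "fdr_mask": fdr_mask, "clusters": clusters, "diff_t_map": diff_t,
        "penalty": lam, "penalty_curve": curve,
    }

    manifest = {
        "master_seed": seed,
        "penalty": lam,
        "n_listeners": len(tables),
        "checksums": {
            "z_maps": _array_checksum(z_maps),
            "deviance_matrix": _array_checksum(pm.deviance),
            "accuracy_matrix": _array_checksum(pm.accuracy),
            "specificities": _array_checksum(np.asarray(specs)),
            **{f"trial_log_L{k:02d}": _sha256(
                logs[k].trials.to_csv(index=False).encode())
               for k in range(len(logs))},
        },
    }

    bundle = StudyBundle(config=config, master_seed=seed, tables=tables,
                         models=models, z_maps=z_maps, group_labels=groups,
                         pred_matrix=pm, specificities=specs, sdt=sdt,
                         group_results=group_results, weight_sets=sets,
                         roi_report=roi, manifest=manifest)
    if out_dir is not None:
        _write_bundle(Path(out_dir), bundle, logs)
    return bundle


def _write_bundle(out: Path, bundle: StudyBundle, logs) -> None:
    out.mkdir(parents=True, exist_ok=True)
    for k, (log, model) in enumerate(zip(logs, bundle.models)):
        io.export_trial_log(out / f"trials_L{k:02d}.tsv", log)
        io.save_aci_model(out / f"aci_L{k:02d}.h5", model)
    bundle.pred_matrix.to_frame("deviance").to_csv(out / "deviance_matrix.tsv",
                                                   sep="\t")
    bundle.pred_matrix.to_frame("accuracy").to_csv(out / "accuracy_matrix.tsv",
                                                   sep="\t")
    pd.DataFrame({
        "listener": bundle.pred_matrix.listener_ids,
        "group": bundle.group_labels,
        "specificity": bundle.specificities,
        "d_prime": [s.d_prime for s in bundle.sdt],
        "criterion": [s.criterion for s in bundle.sdt],
    }).to_csv(out / "listener_summary.tsv", sep="\t", index=False)
    if len(bundle.roi_report):
        bundle.roi_report.to_csv(out / "weight_sets.tsv", sep="\t",
                                 index=False)
    cfg = asdict(bundle.config)
    cfg["penalty_grid"] = list(map(float, cfg["penalty_grid"]))
    io.export_run_config(out / "config.json", cfg)
    with open(out / "manifest.json", "w") as f:
        json.dump(bundle.manifest, f, indent=2, sort_keys=True)


def import_experiment_log(log_path, config_path) -> "pd.DataFrame":
    """Rebuild a TrialTable from an exported log + JSON config sidecar.

    Stimuli are regenerated deterministically: targets from their labels
    and the timing defaults, noise from the logged (seed, index) pairs.
    A malformed or incomplete row raises an error naming the trial.
    """
    with open(config_path) as f:
        cfg = json.load(f)
    trials = pd.read_csv(log_path, sep="\t")
    required = {"target_id", "noise_seed", "noise_index", "snr_db",
                "response", "correct"}
    missing = required - set(trials.columns)
    if missing:
        raise ValueError(f"log is missing columns: {sorted(missing)}")
    if "cochleogram" in cfg:  # ExperimentLog-style sidecar
        ccfg = CochleogramConfig(**cfg["cochleogram"])
    else:                     # RunConfig-style sidecar
        ccfg = CochleogramConfig(
            sample_rate=int(cfg["sample_rate"]),
            n_channels=int(cfg["n_channels"]), f_min=cfg["f_min"],
            f_max=cfg["f_max"], time_bin=cfg["time_bin"])
    fb = make_filterbank(ccfg)
    targets = {t.target_id: t for t in default_targets(ccfg.sample_rate)}
    X = None
    for i, row in trials.iterrows():
        if row["target_id"] not in targets:
            raise ValueError(f"trial {i}: unknown target {row['target_id']!r}")
        target = targets[row["target_id"]]
        try:
            noise = generate_noise(len(target.samples),
                                   int(row["noise_seed"]),
                                   int(row["noise_index"]))
        except (ValueError, TypeError) as e:
            raise ValueError(f"trial {i}: cannot regenerate noise: {e}")
        mix = mix_at_snr(target, noise, float(row["snr_db"]))
        coch = compute_cochleogram(mix.samples, fb, ccfg)
        if X is None:
            X = np.empty((len(trials), coch.values.size))
            grid = coch.values.shape
        X[i] = coch.values.ravel()
    from .estimation import TrialTable
    return TrialTable(X=X, response=trials["response"].to_numpy(),
                      correct=trials["correct"].to_numpy(dtype=bool),
                      grid_shape=grid,
                      target_id=trials["target_id"].to_numpy(),
                      target_class=np.array([targets[t].response_class
                                             for t in trials["target_id"]]),
                      snr_db=trials["snr_db"].to_numpy(),
                      session=trials.get("session",
                                         pd.Series(np.zeros(len(trials),
                                                            dtype=int))
                                         ).to_numpy())
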