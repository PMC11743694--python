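"""End-to-end orchestration: simulate (or load) -> preprocess -> ERP ->
spatial filter -> statistics, with provenance.

A :class:`RunConfig` gathers the stage parameters; :func:`run_pipeline`
executes the stages for every subject and paradigm, writes tab-separated
result tables into a run directory, and returns the in-memory results.
Every output table carries the config hash in its metadata header, and a
fixed seed makes the whole run reproducible.

Per paradigm the condition contrasts follow the standard analysis:
``P1`` the single target vs non-target contrast; competing-stream
paradigms the four panels AT-AN, AT-UT, AN-UT and UT-UN.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import dataio
from .core import EpochSet, ERPWave, ValidationError, concatenate_epochs
from .erp import average_epochs, difference_wave, grand_average, quantify_peak
from .preprocess import preprocess_recording
from .simulate import SimulationConfig, simulate_recording
from .spatialfilter import cross_task_validate
from .stats import (
    bonferroni_alpha,
    cosine_similarity_test,
    spatial_cluster_test,
    temporal_cluster_test,
)

logger = logging.getLogger("attnerp")

#: Contrast pairs per paradigm (minuend condition, subtrahend condition).
CONTRASTS = {
    "P1": [("TARGET", "NONTARGET")],
    "P2": [("AT", "AN"), ("AT", "UT"), ("AN", "UT"), ("UT", "UN")],
    "P3": [("AT", "AN"), ("AT", "UT"), ("AN", "UT"), ("UT", "UN")],
}

#: Condition tokens entering the ear-EEG target / non-target pools.
EAR_TARGET = ("TARGET", "AT")
EAR_NONTARGET = ("NONTARGET", "AN")


@dataclass
class RunConfig:
    """Serializable configuration of a full pipeline run."""

    paradigms: list[str] = field(default_factory=lambda: ["P1", "P2", "P3"])
    n_subjects: int = 10
    seed: int = 0
    input_dir: str | None = None     # load instead of simulate when set
    # simulation
    sampling_rate: float = 1000.0
    n_trials: int | None = None      # None -> per-paradigm default
    noise_sigma: float = 10.0
    noise_exponent: float = 1.0
    eog_rate: float = 0.12
    erp_latency: float = 625.0
    erp_width: float = 300.0
    # preprocessing
    low: float = 0.1
    high: float = 40.0
    run_ica: bool = True
    r_threshold: float = 0.8
    p2p_threshold: float = 200.0
    # statistics
    channel: str = "Pz"
    n_perm: int = 1000
    scalp_threshold: float = 1.0
    ear_threshold: float = 0.5
    alpha: float = 0.05
    topo_window: tuple[float, float] = (400.0, 800.0)
    shrinkage: float = 0.05
    log_level: str = "INFO"

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["topo_window"] = list(d["topo_window"])
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        if "topo_window" in d:
            d["topo_window"] = tuple(d["topo_window"])
        return cls(**d)

    def config_hash(self) -> str:
        return hashlib.sha1(self.to_json().encode()).hexdigest()[:12]

    def sim_config(self, paradigm: str, seed: int) -> SimulationConfig:
        return SimulationConfig(
            paradigm=paradigm,
            n_trials=self.n_trials,
            sampling_rate=self.sampling_rate,
            erp_latency=self.erp_latency,
            erp_width=self.erp_width,
            noise_sigma=self.noise_sigma,
            noise_exponent=self.noise_exponent,
            eog_rate=self.eog_rate,
            seed=seed,
        )


@dataclass
class ParadigmResult:
    """Per-paradigm scalp-level results."""

    grand_diffs: dict[tuple[str, str], ERPWave]
    cluster_results: dict[tuple[str, str], object]
    spatial_result: object | None
    peaks: dict[tuple[str, str], object]


@dataclass
class RunResult:
    out_dir: Path
    config: RunConfig
    paradigms: dict[str, ParadigmResult]
    similarity: pd.DataFrame | None
    summary: pd.DataFrame


def _subject_epochs(config: RunConfig, paradigm: str, subject_seeds) -> list[EpochSet]:
    """Simulate (or load) and preprocess every subject of one paradigm."""
    out = []
    if config.input_dir is not None:
        layout = dataio.DatasetLayout.scan(config.input_dir)
        subjects = [s for (s, p) in layout.entries if p == paradigm]
        if not subjects:
            raise dataio.ParseError(
                f"no recordings for paradigm {paradigm!r} under {config.input_dir}"
            )
        for sub in sorted(set(subjects)):
            rec, events = layout.load(sub, paradigm)
            eps, log, _ = preprocess_recording(
                rec, events, config.low, config.high, config.run_ica,
                r_threshold=config.r_threshold,
                p2p_threshold=config.p2p_threshold,
            )
            logger.info("%s/%s: %d epochs (%d rejected)", sub, paradigm,
                        eps.n_epochs, log.n_rejected)
            out.append(eps)
    else:
        for i, child in enumerate(subject_seeds):
            sim = config.sim_config(paradigm, seed=0)
            rec, events = simulate_recording(sim, rng=np.random.default_rng(child))
            eps, log, _ = preprocess_recording(
                rec, events, config.low, config.high, config.run_ica,
                r_threshold=config.r_threshold,
                p2p_threshold=config.p2p_threshold,
            )
            logger.info("sub-%02d/%s: %d epochs (%d rejected)", i + 1, paradigm,
                        eps.n_epochs, log.n_rejected)
            out.append(eps)
    return out


def run_pipeline(config: RunConfig, out_dir: str | Path) -> RunResult:
    """Execute the full analysis and write result tables under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    chash = config.config_hash()
    (out_dir / "config.json").write_text(config.to_json())
    meta = {"config_hash": chash, "seed": config.seed}

    if config.input_dir is not None and not Path(config.input_dir).is_dir():
        raise FileNotFoundError(
            f"stage simulate/load: input directory not found: {config.input_dir}"
        )

    root_ss = np.random.SeedSequence(config.seed)
    paradigm_seeds = {
        p: root_ss.spawn(1)[0].spawn(config.n_subjects) for p in config.paradigms
    }
    stat_rng = np.random.default_rng(root_ss.spawn(1)[0])

    summary_rows = []
    paradigm_results: dict[str, ParadigmResult] = {}
    # per-paradigm pooled single-channel epochs for ear-stage + cosine test
    ear_pools: dict[str, dict[str, list]] = {}
    scalp_diffs: dict[str, ERPWave] = {}

    for paradigm in config.paradigms:
        logger.info("=== paradigm %s ===", paradigm)
        try:
            all_eps = _subject_epochs(config, paradigm, paradigm_seeds[paradigm])
        except Exception as exc:
            raise RuntimeError(f"stage preprocess [{paradigm}]: {exc}") from exc

        contrasts = CONTRASTS[paradigm]
        grand_diffs, cluster_results, peaks = {}, {}, {}
        # single-channel pooled epochs per condition (for cluster tests)
        chan_pool: dict[str, list[np.ndarray]] = {}
        topo_pool: list[EpochSet] = []
        per_subject_diffs: dict[tuple[str, str], list[ERPWave]] = {
            c: [] for c in contrasts
        }
        for eps in all_eps:
            for cond in set(sum(([a, b] for a, b in contrasts), [])):
                chan_pool.setdefault(cond, []).append(
                    eps.get_channel(config.channel)[eps.conditions == cond]
                )
            topo_pool.append(
                eps.pick_group("scalp").crop(*config.topo_window)
            )
            for a, b in contrasts:
                per_subject_diffs[(a, b)].append(
                    difference_wave(average_epochs(eps, a), average_epochs(eps, b))
                )
        times_ms = all_eps[0].times_ms

        for a, b in contrasts:
            ga = grand_average(per_subject_diffs[(a, b)])
            grand_diffs[(a, b)] = ga
            dataio.write_table(
                out_dir / f"erp_{paradigm}_{a}-{b}.tsv",
                ga.to_frame(),
                {**meta, "paradigm": paradigm, "contrast": f"{a}-{b}",
                 "n_subjects": ga.n},
            )
            A = np.concatenate(chan_pool[a], axis=0)
            B = np.concatenate(chan_pool[b], axis=0)
            res = temporal_cluster_test(
                A, B, threshold=config.scalp_threshold, n_perm=config.n_perm,
                sided="two", seed=stat_rng, alpha=bonferroni_alpha(
                    config.alpha, max(len(contrasts), 1)),
                times_ms=times_ms,
            )
            cluster_results[(a, b)] = res
            sig = res.significant()
            for k, (ext, stat, p) in enumerate(
                zip(res.extents_ms(), res.cluster_stats, res.p_values)
            ):
                summary_rows.append(
                    (paradigm, f"{a}-{b}", f"{ext[0]:.0f}", f"{ext[1]:.0f}",
                     f"{stat:.3f}", f"{p:.4g}", bool(sig[k]))
                )
            if not res.n_clusters:
                summary_rows.append(
                    (paradigm, f"{a}-{b}", "", "", "", "", False)
                )
            # peak inside the most significant cluster, if any
            if res.n_clusters and sig.any():
                kbest = int(np.argmin(res.p_values))
                window = res.extents_ms()[kbest]
                peaks[(a, b)] = quantify_peak(ga, config.channel, window)

        # spatial test on the first contrast
        a, b = contrasts[0]
        topo = concatenate_epochs(topo_pool)
        spatial = spatial_cluster_test(
            topo.select(a), topo.select(b),
            window=config.topo_window,
            threshold=config.scalp_threshold, n_perm=config.n_perm,
            sided="two", seed=stat_rng, alpha=config.alpha,
        )
        dataio.write_table(
            out_dir / f"spatial_clusters_{paradigm}.tsv", spatial.to_frame(),
            {**meta, "paradigm": paradigm, "contrast": f"{a}-{b}",
             "threshold": config.scalp_threshold},
        )

        paradigm_results[paradigm] = ParadigmResult(
            grand_diffs, cluster_results, spatial, peaks
        )
        scalp_diffs[paradigm] = ERPWave(
            grand_diffs[contrasts[0]].get_channel(config.channel)[None, :],
            times_ms, f"{a}-{b}", grand_diffs[contrasts[0]].n, [config.channel],
        )
        # collect per-subject ear epochs for the ear stage
        ear_pools[paradigm] = {"subjects": []}
        for eps in all_eps:
            per_sub = {}
            for ear in ("ear_left", "ear_right"):
                ear_eps = eps.pick_group(ear)
                per_sub[ear] = (
                    ear_eps.select(list(EAR_TARGET)),
                    ear_eps.select(list(EAR_NONTARGET)),
                )
            ear_pools[paradigm]["subjects"].append(per_sub)
        del all_eps, topo_pool, chan_pool

    # ------------------------------------------------------------------ ear
    similarity = None
    if len(config.paradigms) >= 2:
        sim_rows = []
        n_sim_tests = 2  # two ears per paradigm
        for ear, side in (("ear_left", "left"), ("ear_right", "right")):
            filtered: dict[str, dict[str, list]] = {
                p: {"t": [], "n": []} for p in config.paradigms
            }
            n_sub = len(ear_pools[config.paradigms[0]]["subjects"])
            for i in range(n_sub):
                data = {
                    p: ear_pools[p]["subjects"][i][ear]
                    for p in config.paradigms
                }
                try:
                    cv = cross_task_validate(data, ear=side,
                                             shrinkage=config.shrinkage)
                except ValidationError as exc:
                    raise RuntimeError(f"stage spatial-filter [{side}]: {exc}")
                for p, outp in cv.items():
                    filtered[p]["t"].append(outp.filtered_target)
                    filtered[p]["n"].append(outp.filtered_nontarget)
                    if i == 0:
                        dataio.write_filter(
                            out_dir / f"filter_{side}_holdout-{p}.json",
                            outp.filter,
                        )
            for p in config.paradigms:
                ft = concatenate_epochs(filtered[p]["t"])
                fn = concatenate_epochs(filtered[p]["n"])
                score, pval = cosine_similarity_test(
                    ft, fn, scalp_diffs[p], n_perm=config.n_perm, seed=stat_rng
                )
                sim_rows.append((side, p, score, pval))
                # held-out temporal cluster test on the filtered channel
                res = temporal_cluster_test(
                    ft, fn, threshold=config.ear_threshold,
                    n_perm=config.n_perm, sided="two", seed=stat_rng,
                    alpha=bonferroni_alpha(config.alpha, n_sim_tests),
                    times_ms=ft.times_ms,
                )
                for ext, stat, pv in zip(res.extents_ms(), res.cluster_stats,
                                         res.p_values):
                    summary_rows.append(
                        (p, f"ear-{side}", f"{ext[0]:.0f}", f"{ext[1]:.0f}",
                         f"{stat:.3f}", f"{pv:.4g}",
                         bool(pv <= res.alpha))
                    )
        similarity = pd.DataFrame(
            sim_rows, columns=["ear", "paradigm", "score", "p_value"]
        )
        dataio.write_table(
            out_dir / "similarity.tsv", similarity,
            {**meta, "alpha": bonferroni_alpha(config.alpha, 2),
             "note": "cosine similarity of ear vs scalp difference ERPs"},
        )

    summary = pd.DataFrame(
        summary_rows,
        columns=["paradigm", "contrast", "cluster_start_ms", "cluster_end_ms",
                 "cluster_stat", "p_value", "significant"],
    )
    dataio.write_table(out_dir / "summary.tsv", summary, meta)
    logger.info("run complete: %s", out_dir)
    return RunResult(out_dir, config, paradigm_results, similarity, summary)
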