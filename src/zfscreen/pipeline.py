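"""End-to-end screen orchestration from a plain-text config.

``run_screen`` executes the whole synthetic screen: atlas generation,
per-condition calcium recordings (wild-type and mutant, before and after
compound exposure), supervoxel reduction, fingerprint assembly, clustering
and polytherapy selection, stationarity QA, and LFP/behavioral scoring of
the selected hits. Every output is stamped with the config hash and seed;
fixed seed and config give byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clustering, connectivity, io, screen, stationarity
from .atlas import generate_atlas
from .behavior import compute_behavioral_features, track_from_points
from .lfp import detect_seizures, train_default_detector
from .protocol import StimulusSchedule, segment_states
from .synth import ImagingParams, MotionProgram, make_ground_truth
from .synth.behavior import simulate_behavior
from .synth.calcium import simulate_condition_recording
from .synth.lfp import simulate_lfp
from .voxels import process_volume

logger = logging.getLogger(__name__)

CONFIG_SCHEMA_VERSION = 1

_SCHEMA: dict[str, set[str]] = {
    "": {"schema_version", "seed", "atlas", "schedule", "imaging", "screen", "analysis"},
    "atlas": {"shape", "n_regions"},
    "schedule": {"pre_duration", "stimulus_interval", "n_stimuli"},
    "imaging": {"rate", "noise_sd", "n_neurons_per_region", "spike_rate"},
    "screen": {"n_larvae", "compounds", "n_connected_pairs", "rho_wt", "mutant_shift"},
    "analysis": {"c_active", "k_max", "n_rounds", "qa_pairs"},
}


@dataclass
class ScreenConfig:
    """Validated screen configuration."""

    seed: int = 0
    atlas_shape: tuple[int, int, int] = (3, 20, 20)
    n_regions: int = 11
    pre_duration: float = 40.0
    stimulus_interval: float = 120.0
    n_stimuli: int = 1
    rate: float = 20.0
    noise_sd: float = 2.0
    n_neurons_per_region: int = 3
    spike_rate: float = 0.1
    n_larvae: int = 2
    compounds: dict[str, float] = field(default_factory=lambda: {"drugA": 0.8, "drugB": 0.3})
    n_connected_pairs: int = 6
    rho_wt: float = 0.5
    mutant_shift: float = 0.3
    c_active: float = 4.5
    k_max: int = 6
    n_rounds: int = 2
    qa_pairs: int = 3

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScreenConfig":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        raw = yaml.safe_load(path.read_text()) or {}
        _validate_keys(raw)
        cfg = cls()
        cfg.seed = int(raw.get("seed", cfg.seed))
        a = raw.get("atlas", {})
        cfg.atlas_shape = tuple(a.get("shape", cfg.atlas_shape))
        cfg.n_regions = int(a.get("n_regions", cfg.n_regions))
        s = raw.get("schedule", {})
        cfg.pre_duration = float(s.get("pre_duration", cfg.pre_duration))
        cfg.stimulus_interval = float(s.get("stimulus_interval", cfg.stimulus_interval))
        cfg.n_stimuli = int(s.get("n_stimuli", cfg.n_stimuli))
        im = raw.get("imaging", {})
        cfg.rate = float(im.get("rate", cfg.rate))
        cfg.noise_sd = float(im.get("noise_sd", cfg.noise_sd))
        cfg.n_neurons_per_region = int(im.get("n_neurons_per_region", cfg.n_neurons_per_region))
        cfg.spike_rate = float(im.get("spike_rate", cfg.spike_rate))
        sc = raw.get("screen", {})
        cfg.n_larvae = int(sc.get("n_larvae", cfg.n_larvae))
        cfg.compounds = dict(sc.get("compounds", cfg.compounds))
        cfg.n_connected_pairs = int(sc.get("n_connected_pairs", cfg.n_connected_pairs))
        cfg.rho_wt = float(sc.get("rho_wt", cfg.rho_wt))
        cfg.mutant_shift = float(sc.get("mutant_shift", cfg.mutant_shift))
        an = raw.get("analysis", {})
        cfg.c_active = float(an.get("c_active", cfg.c_active))
        cfg.k_max = int(an.get("k_max", cfg.k_max))
        cfg.n_rounds = int(an.get("n_rounds", cfg.n_rounds))
        cfg.qa_pairs = int(an.get("qa_pairs", cfg.qa_pairs))
        return cfg

    def digest(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _validate_keys(raw: dict) -> None:
    unknown = set(raw) - _SCHEMA[""]
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for section, allowed in _SCHEMA.items():
        if not section or section not in raw:
            continue
        bad = set(raw[section]) - allowed
        if bad:
            raise ValueError(f"unknown keys in '{section}': {sorted(bad)}")


def planted_screen_truth(
    cfg: ScreenConfig, rng: np.random.Generator
) -> tuple[dict, dict, dict[str, dict]]:
    """Wild-type / mutant connectivity maps and per-compound perturbations.

    Wild-type connectivity puts rho_wt on a random subset of area pairs
    (respecting the per-area shared-rate budget). The mutant shifts those
    values by +-mutant_shift. A compound with restore fraction f moves the
    mutant back towards wild-type by f, plus a small seeded idiosyncrasy.
    """
    pairs = connectivity.area_pairs(cfg.n_regions)
    chosen: list[tuple[int, int]] = []
    load = np.zeros(cfg.n_regions + 1)
    order = rng.permutation(len(pairs))
    for k in order:
        i, j = pairs[k]
        if load[i] + cfg.rho_wt <= 0.95 and load[j] + cfg.rho_wt <= 0.95:
            chosen.append((i, j))
            load[i] += cfg.rho_wt
            load[j] += cfg.rho_wt
        if len(chosen) >= cfg.n_connected_pairs:
            break
    wt = {p: cfg.rho_wt for p in chosen}
    mut = {}
    for k, p in enumerate(chosen):
        sign = -1.0 if k % 2 == 0 else 0.5
        mut[p] = float(np.clip(cfg.rho_wt + sign * cfg.mutant_shift, 0.0, 0.95))
    effects: dict[str, dict] = {}
    for name in sorted(cfg.compounds):
        f = float(cfg.compounds[name])
        eff = {}
        for p in chosen:
            delta = f * (wt[p] - mut[p]) + float(rng.normal(0.0, 0.02))
            for s in ("pre", "early", "late"):
                eff[(p[0], p[1], s)] = delta
        effects[name] = eff
    return wt, mut, effects


def run_screen(config_path: str | Path, out_dir: str | Path) -> Path:
    """Run the full synthetic screen; returns the output directory."""
    cfg = ScreenConfig.from_yaml(config_path)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "run.log", mode="w")
    fh.setLevel(logging.INFO)
    logging.getLogger("zfscreen").addHandler(fh)
    stamp = {"config_hash": cfg.digest(), "seed": cfg.seed,
             "schema_version": CONFIG_SCHEMA_VERSION}
    try:
        _run(cfg, out, stamp)
    finally:
        logging.getLogger("zfscreen").removeHandler(fh)
        fh.close()
    return out


def _run(cfg: ScreenConfig, out: Path, stamp: dict) -> None:
    ss = np.random.SeedSequence(cfg.seed)
    seeds = {name: int(s.generate_state(1)[0] % (2**31)) for name, s in zip(
        ["truth", "imaging", "qa", "lfp", "behavior"], ss.spawn(5)
    )}
    (out / "stamp.json").write_text(json.dumps(stamp, sort_keys=True, indent=2) + "\n")

    atlas = generate_atlas(cfg.atlas_shape, cfg.n_regions, seed=seeds["truth"])
    stim = tuple(
        cfg.pre_duration + k * cfg.stimulus_interval for k in range(cfg.n_stimuli)
    )
    schedule = StimulusSchedule(pre_duration=cfg.pre_duration, stimulus_times=stim)
    duration = schedule.duration_hint
    windows = segment_states(schedule, duration)
    imaging = ImagingParams(
        rate=cfg.rate, noise_sd=cfg.noise_sd,
        n_neurons_per_region=cfg.n_neurons_per_region, spike_rate=cfg.spike_rate,
    )
    rng = np.random.default_rng(seeds["truth"])
    wt, mut, effects = planted_screen_truth(cfg, rng)

    conditions: dict[str, tuple[dict, str, dict]] = {"WT-0h": (wt, "wild_type", {})}
    conditions["Mut-0h"] = (mut, "mutant", {})
    for name in sorted(effects):
        conditions[f"Mut-4h-{name}"] = (mut, "mutant", effects[name])

    fps = {}
    per_larva_store: dict[str, list[pd.Series]] = {}
    rec_rng = np.random.default_rng(seeds["imaging"])
    first_wt_sv = None
    for label, (rho, genotype, effect) in conditions.items():
        per_larva = []
        for _ in range(cfg.n_larvae):
            truth = make_ground_truth(rho, condition=genotype, drug_effect=effect)
            vol, truth = simulate_condition_recording(
                atlas, truth, schedule, imaging, seed=int(rec_rng.integers(2**31)),
            )
            sv = process_volume(
                vol, atlas, (0.0, cfg.pre_duration), c=cfg.c_active,
                k_range=range(1, cfg.k_max + 1),
            )
            if first_wt_sv is None and label == "WT-0h":
                first_wt_sv = sv
            per_larva.append(connectivity.larva_metrics(sv, atlas, windows))
        per_larva_store[label] = per_larva
        fps[label] = connectivity.assemble_fingerprint(per_larva, min_larvae=1)

    io.fingerprints_to_tidy(fps, atlas).to_csv(out / "fingerprints_tidy.csv", index=False)
    wide = io.fingerprints_to_wide(fps, atlas)
    wide.to_csv(out / "fingerprints_wide.csv")

    raw = pd.DataFrame({g: fp.values for g, fp in fps.items()}).T
    M = clustering.normalize_matrix(raw)
    compound_rows = [r for r in M.index if r.startswith("Mut-4h-")]
    tree = clustering.cluster_fingerprints(M, reference_rows=["WT-0h"])
    pd.DataFrame(tree.linkage, columns=["a", "b", "height", "size"]).to_csv(
        out / "linkage.csv", index=False
    )
    io.write_newick(out / "dendrogram.nwk", tree)
    pd.DataFrame({"row": tree.labels, "cluster": tree.assignment}).to_csv(
        out / "clusters.csv", index=False
    )
    sel = clustering.select_polytherapy(
        M, reference_rows=["WT-0h"], compound_rows=compound_rows,
        context_rows=["Mut-0h"], n_rounds=min(cfg.n_rounds, len(compound_rows)),
    )
    io.write_selection(out / "selection.json", sel)

    # Stationarity QA on the first wild-type larva.
    qa_rows = []
    if first_wt_sv is not None:
        qa_rng = np.random.default_rng(seeds["qa"])
        pairs = connectivity.area_pairs(atlas.n_regions)[: cfg.qa_pairs]
        for (i, j) in pairs:
            ii = first_wt_sv.in_region(i)
            jj = first_wt_sv.in_region(j)
            if ii.size == 0 or jj.size == 0:
                continue
            a = first_wt_sv.dff[ii].mean(axis=0)
            b = first_wt_sv.dff[jj].mean(axis=0)
            try:
                swc = stationarity.swc_kappa(a, b, first_wt_sv.frame_rate)
                verdict, p = stationarity.arr_surrogate_test(
                    swc, n_surrogates=200, seed=int(qa_rng.integers(2**31)),
                    traces=(a, b), rate=first_wt_sv.frame_rate,
                )
                qa_rows.append({"area_i": i, "area_j": j, "kappa": swc.kappa,
                                "p": p, "verdict": verdict})
            except ValueError as e:
                logger.warning("QA pair (%d, %d) skipped: %s", i, j, e)
    qa = pd.DataFrame(qa_rows)
    if not qa.empty:
        frac = float((qa["verdict"] == "stationary").mean())
        qa.to_csv(out / "qa_stationarity.csv", index=False)
        (out / "qa_summary.json").write_text(json.dumps({
            "median_p": float(qa["p"].median()), "stationary_fraction": frac,
        }, sort_keys=True) + "\n")

    # Efficacy + side-effect scoring of the selected compounds.
    detector = train_default_detector(seed=seeds["lfp"])
    lfp_rng = np.random.default_rng(seeds["lfp"] + 1)
    beh_rng = np.random.default_rng(seeds["behavior"])
    score_rows = []
    hits = [r.selected.removeprefix("Mut-4h-") for r in sel.rounds]
    baseline_feats = _behavior_group(cfg.n_larvae, 0.0, beh_rng)
    for name in hits:
        restore = float(cfg.compounds[name])
        pairs = []
        for _ in range(cfg.n_larvae):
            base = simulate_lfp(300.0, event_rate=2.0, seed=int(lfp_rng.integers(2**31)))
            post = simulate_lfp(300.0, event_rate=2.0 * (1.0 - restore),
                                seed=int(lfp_rng.integers(2**31)))
            pairs.append((detect_seizures(base, detector), detect_seizures(post, detector)))
        cond = screen.TreatmentCondition((name,), (1.0,), cfg.n_larvae)
        try:
            cs = screen.scores_from_callsets(cond, pairs)
        except ValueError as e:
            logger.warning("scoring %s failed: %s", name, e)
            continue
        treated_feats = _behavior_group(cfg.n_larvae, 0.3 * (1 - restore), beh_rng)
        from .behavior import side_effect_score
        se = side_effect_score(treated_feats, baseline_feats)
        score_rows.append({
            "compound": name, "efficacy_mean": cs.efficacy_mean,
            "efficacy_sd": cs.efficacy_sd, "side_effect": se.x_combined,
            "side_effect_sd": se.sd,
        })
    pd.DataFrame(score_rows).to_csv(out / "scores.csv", index=False)


def _behavior_group(n_larvae: int, slow_fraction: float, rng: np.random.Generator) -> pd.DataFrame:
    """Behavioral feature table for a synthetic treatment group.

    ``slow_fraction`` scales down swimming to emulate a sedative side
    effect; 0 reproduces the untreated baseline program.
    """
    rows = []
    for _ in range(n_larvae):
        v = 30.0 * (1.0 - slow_fraction) * float(rng.uniform(0.9, 1.1))
        amp = 12.0 * (1.0 - 0.5 * slow_fraction) * float(rng.uniform(0.9, 1.1))
        program = MotionProgram(velocity=v, tail_beat_amp=amp)
        _frames, track = simulate_behavior(
            4.0, 25.0, program, seed=int(rng.integers(2**31)), frame_shape=(192, 192)
        )
        feats = compute_behavioral_features(track_from_points(track, 25.0))
        rows.append(feats.as_series())
    return pd.DataFrame(rows)
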