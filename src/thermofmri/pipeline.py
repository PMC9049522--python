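"""End-to-end orchestration of the baseline-vs-desensitized phantom study.

The study emulates a two-group thermal-stimulation experiment: 18 baseline
and 9 desensitized ("rtx") animals, each with one stimulus-driven session
and two resting-state sessions (RS_pre, RS_post). Stages: phantom
simulation, preprocessing, voxel-wise GLM with FDR masks, atlas-ROI metrics,
max-amplitude maps, stimulus-driven networks (global regression, Fisher-z
adjacency, k-standardization, small-world, communities), multi-seed
resting-state matrices, and the group statistics (ANOVA + Tukey, t-test
tables with BH-FDR, NBS per temperature, voxel-wise and paired permutation
tests).

Two scale presets exist: ``desk`` (32x32x8 voxels, 40 structures, 1 stimulus
set) for test-sized runs and ``full`` (64x64x22, 202 structures, 3 sets)
matching the acquisition geometry of the emulated experiment.
"""
from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import glm as glm_mod
from . import netbuild, preprocess, roi, rsnet, stats
from .core import BoldSeries, ConfigError
from .phantom import (
    EffectModel,
    HRFParams,
    StimulusProtocol,
    SyntheticAtlas,
    TEMPERATURES,
    build_stimulus_protocol,
    build_synthetic_atlas,
    simulate_resting_state,
    simulate_session,
)

#: Functional groups whose structures respond to thermal stimulation in the
#: phantom (a cortical and a subcortical subnetwork).
RESPONSIVE_GROUPS = ("somatosensory_cortex", "thalamus")


@dataclass
class ScalePreset:
    shape: tuple[int, int, int]
    n_structures: int
    n_sets: int
    voxel_size: tuple[float, float, float]
    n_rs_volumes: int
    highpass_cycles: int
    tr: float = 2.0

    @property
    def n_stim_volumes(self) -> int:
        # lead-in 120 s + n_sets * 8 events * 240 s, at TR 2 s
        return int((120.0 + self.n_sets * 8 * 240.0) / self.tr)


# The desk preset keeps the temporal design (one full stimulus set) but
# shrinks the grid; the high-pass cycle count preserves the full-scale cutoff
# frequency (9 cycles / 6000 s = 1.5 mHz -> 3 cycles / 2040 s).
PRESETS: dict[str, ScalePreset] = {
    "desk": ScalePreset(
        shape=(32, 32, 8), n_structures=40, n_sets=1,
        voxel_size=(0.391, 0.391, 1.0), n_rs_volumes=300, highpass_cycles=3,
    ),
    "full": ScalePreset(
        shape=(64, 64, 22), n_structures=202, n_sets=3,
        voxel_size=(0.391, 0.391, 1.0), n_rs_volumes=300, highpass_cycles=9,
    ),
}


@dataclass
class RunConfig:
    """Configuration of one full phantom study."""

    scale: str = "desk"
    seed: int = 0
    outdir: str | None = None
    n_baseline: int = 18
    n_rtx: int = 9
    k: int = 10
    q: float = 0.05
    alpha: float = 0.05
    n_perm: int = 200
    lowpass_hz: float = 0.1
    atlas_seed: int = 1000
    protocol_seed: int = 2000
    hrf: HRFParams = field(default_factory=HRFParams)
    write_volumes: bool = False
    run_resting_state: bool = True
    run_voxelwise: bool = True

    def __post_init__(self) -> None:
        if self.scale not in PRESETS:
            raise ConfigError(f"unknown scale preset: {self.scale}")

    @property
    def preset(self) -> ScalePreset:
        return PRESETS[self.scale]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "hrf" in raw:
            raw["hrf"] = HRFParams(**raw["hrf"])
        return cls(**raw)


# --------------------------------------------------------------------------
# Study inputs
# --------------------------------------------------------------------------
def study_inputs(cfg: RunConfig) -> tuple[SyntheticAtlas, StimulusProtocol, EffectModel, EffectModel]:
    """Atlas, protocol and both group effect models for the configured scale."""
    p = cfg.preset
    atlas = build_synthetic_atlas(p.shape, p.n_structures, seed=cfg.atlas_seed, voxel_size=p.voxel_size)
    protocol = build_stimulus_protocol(n_sets=p.n_sets, seed=cfg.protocol_seed)
    responsive = frozenset(
        int(lid)
        for lid, grp in zip(atlas.structure_table["label_id"], atlas.structure_table["functional_group"])
        if grp in RESPONSIVE_GROUPS
    )
    baseline = EffectModel.baseline(responsive)
    rtx = EffectModel.rtx(responsive)
    return atlas, protocol, baseline, rtx


def stimulus_preprocess_config(cfg: RunConfig) -> preprocess.PreprocessConfig:
    return preprocess.PreprocessConfig(
        n_discard_volumes=2,
        pairwise_average=True,
        slice_order="none",  # phantoms are generated without slice-time offsets
        smoothing_fwhm=2.0,
        highpass_fwhm=12.0,
        highpass_cycles=cfg.preset.highpass_cycles,
        motion_correction="none",  # phantoms are motion-free by default
    )


def resting_preprocess_config(cfg: RunConfig) -> preprocess.PreprocessConfig:
    return preprocess.PreprocessConfig(
        n_discard_volumes=2,
        pairwise_average=False,
        slice_order="none",
        smoothing_fwhm=0.0,
        lowpass_hz=cfg.lowpass_hz,
        motion_correction="none",
    )


# --------------------------------------------------------------------------
# Per-animal first level
# --------------------------------------------------------------------------
def parcel_mean_traces(series: BoldSeries, atlas: SyntheticAtlas) -> np.ndarray:
    """Mean time course of every structure, (n_structures, n_t)."""
    vox_labels = atlas.label_volume[atlas.brain_mask]
    data = np.asarray(series.data[atlas.brain_mask], dtype=float)
    order = np.argsort(vox_labels, kind="stable")
    sorted_labels = vox_labels[order]
    starts = np.searchsorted(sorted_labels, atlas.label_ids)
    ends = np.searchsorted(sorted_labels, atlas.label_ids, side="right")
    sums = np.add.reduceat(data[order], starts, axis=0)
    counts = (ends - starts).astype(float)
    return sums / counts[:, None]


def temperature_window_traces(
    traces: np.ndarray,
    protocol: StimulusProtocol,
    tr_eff: float,
    t0: float,
    pre: int = roi.PRE_POINTS,
    post: int = roi.POST_POINTS,
) -> dict[int, np.ndarray]:
    """Per temperature: concatenated event windows of the (residual) traces.

    Returns temperature -> (n_structures, n_events * window_length).
    """
    out: dict[int, np.ndarray] = {}
    dur = roi.n_during_points(tr_eff)
    length = pre + dur + post
    n_t = traces.shape[1]
    for temp in protocol.temperatures:
        segs = []
        for onset in protocol.onsets(temp):
            i0 = int(round((onset - t0) / tr_eff))
            lo, hi = i0 - pre, i0 - pre + length
            if lo < 0 or hi > n_t:
                continue
            segs.append(traces[:, lo:hi])
        if segs:
            out[int(temp)] = np.concatenate(segs, axis=1)
    return out


def animal_first_level(
    raw: BoldSeries,
    atlas: SyntheticAtlas,
    protocol: StimulusProtocol,
    cfg: RunConfig,
    run_glm: bool = True,
    run_maps: bool = True,
    run_metrics: bool = True,
) -> dict:
    """Preprocess one stimulus run and compute all per-animal artifacts.

    Returns a dict with the preprocessed series' timing, the SPMap with FDR
    masks, per-structure metrics (FDR-restricted and whole-parcel), the
    whole-brain activation summary, per-temperature residual network traces,
    and voxel-wise max-amplitude maps.
    """
    pcfg = stimulus_preprocess_config(cfg)
    series = preprocess.preprocess_stimulus_run(raw, pcfg)
    out: dict = {"tr_eff": series.tr, "t0": series.t0}
    onsets_by_temp = {int(t): protocol.onsets(t) for t in protocol.temperatures}

    fdr_masks = None
    if run_glm:
        offsets = (-raw.tr / 2.0, raw.tr / 2.0) if pcfg.pairwise_average else (0.0,)
        design = glm_mod.build_design(
            protocol, cfg.hrf, series.n_volumes, series.tr, t0=series.t0, sample_offsets=offsets
        )
        # filter the regressors with the same operator applied to the data
        design.matrix = preprocess.highpass_design(design.matrix, pcfg.highpass_cycles)
        spm = glm_mod.fit_glm(series, design).significance(cfg.q)
        out["spm"] = spm
        fdr_masks = {
            int(t): spm.fdr_mask[..., spm.predictor_index(glm_mod.temperature_predictor_name(t))]
            for t in protocol.temperatures
        }
        rows = []
        union_rows = []
        for temp, fmask in fdr_masks.items():
            table, whole_pct = roi.activated_volume(fmask, atlas)
            trace = roi.event_related_average(series, onsets_by_temp[temp], fmask & atlas.brain_mask)
            union_rows.append(
                {
                    "temperature_C": temp,
                    "activated_pct": whole_pct,
                    "amplitude_pct": roi.response_amplitude(trace),
                }
            )
            rows.append(table.assign(temperature_C=temp))
        out["whole_brain"] = pd.DataFrame(union_rows)
        out["activated"] = pd.concat(rows, ignore_index=True)
        out["metrics_fdr"] = roi.structure_metrics(series, atlas, onsets_by_temp, fdr_masks)

    if run_metrics:
        out["metrics_parcel"] = roi.structure_metrics(series, atlas, onsets_by_temp, fdr_masks=None)

    # global regression is applied per temperature window: the global mean of
    # a full task run is response-dominated, which would remove the shared
    # signal unevenly between groups and conditions
    traces = parcel_mean_traces(series, atlas)
    windows = temperature_window_traces(traces, protocol, series.tr, series.t0)
    out["network_traces"] = {temp: netbuild.global_regression(w) for temp, w in windows.items()}

    if run_maps:
        out["max_amp_maps"] = roi.max_amplitude_map(series, onsets_by_temp, atlas.brain_mask)
    return out


# --------------------------------------------------------------------------
# Network stage
# --------------------------------------------------------------------------
def adjacency_by_temperature(
    network_traces: dict[int, np.ndarray], nodes: list[int], provenance: dict | None = None
) -> dict[int, netbuild.AdjacencyMatrix]:
    return {
        temp: netbuild.build_adjacency(tr, nodes=nodes, provenance={**(provenance or {}), "temperature": temp})
        for temp, tr in network_traces.items()
    }


def network_metrics_for_group(
    matrices: dict[int, netbuild.AdjacencyMatrix],
    atlas: SyntheticAtlas,
    cfg: RunConfig,
    group: str,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[int, "netbuild.nx.Graph"]]:
    """k-standardize group-mean matrices and compute small-world metrics and
    Louvain communities per temperature."""
    groups_of = atlas.functional_group_of()
    sw_rows, comm_rows = [], []
    networks = {}
    for temp, mat in sorted(matrices.items()):
        net = netbuild.k_standardize(mat, k=cfg.k, node_attrs={n: {"functional_group": groups_of[n]} for n in mat.nodes})
        networks[temp] = net
        sw = netbuild.small_world(net, n_random=100, seed=seed + temp)
        sw_rows.append(
            {
                "group": group,
                "temperature_C": temp,
                "gamma": sw.gamma,
                "lambda": sw.lam,
                "sigma": sw.sigma,
                "clustering": sw.c_raw,
                "path_length": sw.l_raw,
                "fragmented": sw.fragmented,
            }
        )
        part = netbuild.blondel_communities(net, seed=seed + temp)
        for node, comm in sorted(part.membership.items()):
            comm_rows.append(
                {
                    "group": group,
                    "temperature_C": temp,
                    "label_id": node,
                    "community": comm,
                    "modularity": part.modularity,
                }
            )
    return pd.DataFrame(sw_rows), pd.DataFrame(comm_rows), networks


def nbs_by_temperature(
    per_animal_a: list[dict[int, netbuild.AdjacencyMatrix]],
    per_animal_b: list[dict[int, netbuild.AdjacencyMatrix]],
    cfg: RunConfig,
    seed: int = 0,
) -> pd.DataFrame:
    """NBS comparing the two groups' per-animal matrices at every temperature."""
    rows = []
    temps = sorted(set.intersection(*[set(d) for d in per_animal_a + per_animal_b]))
    for temp in temps:
        res = stats.nbs_unpaired(
            [d[temp] for d in per_animal_a],
            [d[temp] for d in per_animal_b],
            alpha=cfg.alpha,
            n_perm=cfg.n_perm,
            seed=seed + temp,
        )
        rows.append(
            {
                "temperature_C": temp,
                "max_component_edges": res.max_component_size,
                "p_value": res.p_value,
                "significant": res.p_value <= 0.05 and res.max_component_size > 0,
                "n_increased": sum(1 for s in res.edge_signs.values() if s > 0),
                "n_decreased": sum(1 for s in res.edge_signs.values() if s < 0),
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Full study
# --------------------------------------------------------------------------
def _animal_seeds(cfg: RunConfig) -> dict[str, list[int]]:
    rng = np.random.default_rng(cfg.seed)
    draw = lambda n: [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]
    return {
        "baseline_stim": draw(cfg.n_baseline),
        "rtx_stim": draw(cfg.n_rtx),
        "baseline_rs": draw(2 * cfg.n_baseline),
        "rtx_rs": draw(2 * cfg.n_rtx),
        "stats": draw(4),
    }


def _rs_correlation(atlas: SyntheticAtlas, r_within: float = 0.4) -> np.ndarray:
    """Planted resting-state correlation: block structure by functional group."""
    groups = atlas.structure_table["functional_group"].to_numpy()
    same = groups[:, None] == groups[None, :]
    corr = np.where(same, r_within, 0.0)
    np.fill_diagonal(corr, 1.0)
    return corr


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the complete phantom study and return (and optionally write) results.

    Produces, per group and temperature: SPMaps, ROI tables, max-amplitude
    maps, networks with small-world metrics and communities, NBS and
    voxel-wise permutation tests, resting-state matrices and their paired
    pre/post comparison; a manifest links every stage to its parameters and
    seeds.
    """
    t_start = time.time()
    atlas, protocol, baseline_model, rtx_model = study_inputs(cfg)
    seeds = _animal_seeds(cfg)
    preset = cfg.preset
    timings = {}

    groups = [("baseline", baseline_model, cfg.n_baseline, seeds["baseline_stim"], seeds["baseline_rs"]),
              ("rtx", rtx_model, cfg.n_rtx, seeds["rtx_stim"], seeds["rtx_rs"])]

    amp_rows, whole_rows = [], []
    per_animal_nets: dict[str, list[dict[int, netbuild.AdjacencyMatrix]]] = {"baseline": [], "rtx": []}
    max_maps: dict[str, list[dict[int, np.ndarray]]] = {"baseline": [], "rtx": []}
    rs_matrices: dict[str, dict[str, list[netbuild.AdjacencyMatrix]]] = {
        "baseline": {"pre": [], "post": []},
        "rtx": {"pre": [], "post": []},
    }
    rs_corr = _rs_correlation(atlas)

    t0 = time.time()
    for group, model, n_animals, stim_seeds, rs_seeds in groups:
        for a in range(n_animals):
            raw = simulate_session(
                atlas, protocol, model, cfg.hrf, tr=preset.tr,
                n_volumes=preset.n_stim_volumes, seed=stim_seeds[a],
            )
            fl = animal_first_level(raw, atlas, protocol, cfg, run_maps=cfg.run_voxelwise)
            for df, restricted in ((fl.get("metrics_fdr"), True), (fl["metrics_parcel"], False)):
                if df is None:
                    continue
                amp_rows.append(df.assign(animal=f"{group}_{a:02d}", group=group, fdr_restricted=restricted))
            if "whole_brain" in fl:
                whole_rows.append(fl["whole_brain"].assign(animal=f"{group}_{a:02d}", group=group))
            per_animal_nets[group].append(
                adjacency_by_temperature(fl["network_traces"], [int(l) for l in atlas.label_ids],
                                         provenance={"group": group, "animal": a})
            )
            if cfg.run_voxelwise:
                max_maps[group].append(fl["max_amp_maps"])
            if cfg.run_resting_state:
                for si, session in enumerate(("pre", "post")):
                    rs_raw = simulate_resting_state(
                        atlas, model, tr=preset.tr, n_volumes=preset.n_rs_volumes,
                        seed=rs_seeds[2 * a + si], correlation=rs_corr,
                    )
                    rs_series = preprocess.preprocess_resting_run(rs_raw, resting_preprocess_config(cfg))
                    rs_matrices[group][session].append(
                        rsnet.multi_seed_matrix(rs_series, atlas,
                                                provenance={"group": group, "animal": a, "session": f"RS_{session}"})
                    )
    timings["first_level_s"] = time.time() - t0

    amplitudes = pd.concat(amp_rows, ignore_index=True)
    whole_brain = pd.concat(whole_rows, ignore_index=True) if whole_rows else pd.DataFrame()

    # ---- stimulus-driven networks -------------------------------------
    t0 = time.time()
    group_mean_mats = {}
    sw_tables, comm_tables = [], []
    networks = {}
    for group in ("baseline", "rtx"):
        temps = sorted(set.intersection(*[set(d) for d in per_animal_nets[group]]))
        group_mean_mats[group] = {
            temp: netbuild.mean_adjacency([d[temp] for d in per_animal_nets[group]],
                                          provenance={"group": group, "temperature": temp})
            for temp in temps
        }
        sw, comm, nets = network_metrics_for_group(
            group_mean_mats[group], atlas, cfg, group, seed=seeds["stats"][0]
        )
        sw_tables.append(sw)
        comm_tables.append(comm)
        networks[group] = nets
    small_world_table = pd.concat(sw_tables, ignore_index=True)
    communities_table = pd.concat(comm_tables, ignore_index=True)

    nbs_table = nbs_by_temperature(
        per_animal_nets["baseline"], per_animal_nets["rtx"], cfg, seed=seeds["stats"][1]
    )
    timings["networks_s"] = time.time() - t0

    # ---- statistics -----------------------------------------------------
    t0 = time.time()
    parcel_amp = amplitudes[~amplitudes["fdr_restricted"]]
    anova_rows, tukey_tables = [], []
    for group in ("baseline", "rtx"):
        sub = parcel_amp[parcel_amp["group"] == group]
        per_temp = {
            int(t): sub[sub["temperature_C"] == t].groupby("animal")["amplitude_pct"].mean().to_numpy()
            for t in sorted(sub["temperature_C"].unique())
        }
        F, p, tukey = stats.anova_tukey(per_temp)
        anova_rows.append({"group": group, "F": F, "p": p})
        tukey_tables.append(tukey.assign(group=group))
    anova_table = pd.DataFrame(anova_rows)
    tukey_table = pd.concat(tukey_tables, ignore_index=True)

    ttest_table = stats.group_ttests_fdr(
        parcel_amp, value_col="amplitude_pct", group_col="group",
        by=["label_id", "temperature_C"], q=cfg.q,
    )

    voxelwise_table = pd.DataFrame()
    if cfg.run_voxelwise:
        mask = atlas.brain_mask
        vw_rows = []
        for temp in protocol.temperatures:
            a = np.stack([m[int(temp)][mask] for m in max_maps["baseline"]])
            b = np.stack([m[int(temp)][mask] for m in max_maps["rtx"]])
            res = stats.voxelwise_perm_ttest(a, b, n_perm=cfg.n_perm, seed=seeds["stats"][2] + temp)
            vw_rows.append(
                {
                    "temperature_C": int(temp),
                    "n_significant_voxels": int(res.significant.sum()),
                    "min_fwe_p": float(res.fwe_p.min()),
                }
            )
        voxelwise_table = pd.DataFrame(vw_rows)

    rs_paired_table = pd.DataFrame()
    if cfg.run_resting_state:
        rs_rows = []
        for group in ("baseline", "rtx"):
            res = stats.paired_perm_matrix_test(
                rs_matrices[group]["pre"], rs_matrices[group]["post"],
                n_perm=cfg.n_perm, seed=seeds["stats"][3],
            )
            rs_rows.append(
                {
                    "group": group,
                    "n_significant_elements": int(res.significant.sum()),
                    "min_fwe_p": float(res.fwe_p.min()),
                }
            )
        rs_paired_table = pd.DataFrame(rs_rows)
    timings["stats_s"] = time.time() - t0
    timings["total_s"] = time.time() - t_start

    results = {
        "config": cfg,
        "atlas": atlas,
        "protocol": protocol,
        "amplitudes": amplitudes,
        "whole_brain": whole_brain,
        "group_mean_matrices": group_mean_mats,
        "networks": networks,
        "small_world": small_world_table,
        "communities": communities_table,
        "nbs": nbs_table,
        "anova": anova_table,
        "tukey": tukey_table,
        "group_ttests": ttest_table,
        "voxelwise": voxelwise_table,
        "rs_matrices": rs_matrices,
        "rs_paired": rs_paired_table,
        "timings": timings,
    }
    if cfg.outdir is not None:
        results["manifest"] = write_outputs(results, cfg)
    return results


def write_outputs(results: dict, cfg: RunConfig) -> dict:
    """Persist tables, edge lists and the manifest under ``cfg.outdir``."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    atlas: SyntheticAtlas = results["atlas"]
    protocol: StimulusProtocol = results["protocol"]

    protocol.to_tsv(out / "protocol_events.tsv")
    atlas.structure_table.to_csv(out / "atlas_structures.tsv", sep="\t", index=False)
    if cfg.write_volumes:
        atlas.save(out / "atlas_labels.nii.gz", out / "atlas_structures.tsv")

    tables = {
        "roi_amplitudes": "amplitudes",
        "whole_brain_activation": "whole_brain",
        "small_world_metrics": "small_world",
        "communities": "communities",
        "nbs_per_temperature": "nbs",
        "anova": "anova",
        "tukey_pairs": "tukey",
        "group_ttests_fdr": "group_ttests",
        "voxelwise_permutation": "voxelwise",
        "rs_paired_permutation": "rs_paired",
    }
    written = {}
    for fname, key in tables.items():
        df = results[key]
        path = out / f"{fname}.tsv"
        if isinstance(df, pd.DataFrame) and not df.empty:
            df.to_csv(path, sep="\t", index=False, float_format="%.6g")
            written[key] = path.name

    edges_dir = out / "networks"
    edges_dir.mkdir(exist_ok=True)
    for group, nets in results["networks"].items():
        for temp, net in nets.items():
            netbuild.edge_list(net).to_csv(
                edges_dir / f"{group}_T{temp}_edges.tsv", sep="\t", index=False, float_format="%.6g"
            )
            netbuild.kamada_kawai_coordinates(net).to_csv(
                edges_dir / f"{group}_T{temp}_layout.tsv", sep="\t", index=False, float_format="%.6g"
            )

    manifest = {
        "seed": cfg.seed,
        "scale": cfg.scale,
        "config": {k: v for k, v in asdict(cfg).items() if k != "hrf"},
        "hrf": asdict(cfg.hrf),
        "timings_s": results["timings"],
        "stages": {
            "protocol": "protocol_events.tsv",
            "atlas": "atlas_structures.tsv",
            "glm_roi": written.get("amplitudes", ""),
            "whole_brain": written.get("whole_brain", ""),
            "networks": "networks/",
            "small_world": written.get("small_world", ""),
            "statistics": written.get("nbs", ""),
            "resting_state": written.get("rs_paired", ""),
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


# --------------------------------------------------------------------------
# Light replication path (network emulation without GLM / maps / RS)
# --------------------------------------------------------------------------
def run_network_replication(
    cfg: RunConfig,
    rep_seed: int,
    atlas: SyntheticAtlas | None = None,
    protocol: StimulusProtocol | None = None,
) -> pd.DataFrame:
    """One seeded replication of the baseline-vs-rtx NBS comparison.

    Simulates both cohorts' stimulus runs, preprocesses them, builds the
    per-animal per-temperature adjacency matrices from global-regressed
    parcel traces, and runs the NBS at every temperature. Skips the GLM,
    max-amplitude and resting-state stages for speed; returns the NBS table.
    """
    if atlas is None or protocol is None:
        atlas, protocol, baseline_model, rtx_model = study_inputs(cfg)
    else:
        _, _, baseline_model, rtx_model = study_inputs(cfg)
    preset = cfg.preset
    rng = np.random.default_rng(rep_seed)
    nodes = [int(l) for l in atlas.label_ids]
    nets: dict[str, list] = {"baseline": [], "rtx": []}
    for group, model, n_animals in (
        ("baseline", baseline_model, cfg.n_baseline),
        ("rtx", rtx_model, cfg.n_rtx),
    ):
        for _ in range(n_animals):
            raw = simulate_session(
                atlas, protocol, model, cfg.hrf, tr=preset.tr,
                n_volumes=preset.n_stim_volumes, seed=int(rng.integers(2**31 - 1)),
            )
            fl = animal_first_level(raw, atlas, protocol, cfg, run_glm=False, run_maps=False, run_metrics=False)
            nets[group].append(adjacency_by_temperature(fl["network_traces"], nodes))
    return nbs_by_temperature(nets["baseline"], nets["rtx"], cfg, seed=int(rng.integers(2**31 - 1)))
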