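"""Synthetic study inputs: stimulation protocols, HRF, atlases and BOLD phantoms.

This module generates everything the downstream analysis consumes, with the
statistical structure the analysis assumes:

* pseudo-randomized thermal stimulation protocols (eight temperatures,
  40-54 degC in 2 degC steps, 20 s stimuli, 220 s rest, no repeated
  temperature across set transitions),
* a two-gamma hemodynamic response function with a 16 s response peak and a
  40 s undershoot peak (rodent BOLD timing),
* synthetic label atlases (ellipsoidal brain mask partitioned into contiguous
  parcels with hemisphere and functional-group annotations),
* stimulus-driven 4D BOLD sessions for two effect models ("baseline":
  response amplitude rising with temperature above 48 degC; "rtx": flat
  response with an optional small 54 degC term), and
* resting-state sessions with a planted inter-regional correlation structure.

All generators are deterministic under a fixed seed.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sp_signal
from scipy import stats as sp_stats
from scipy.spatial import cKDTree

from .core import DesignError, GenerationError, ParameterError, BoldSeries

#: The eight stimulation temperatures in degC.
TEMPERATURES: tuple[int, ...] = tuple(range(40, 56, 2))

RAMP_S = 5.0
PLATEAU_S = 15.0
STIM_DURATION_S = RAMP_S + PLATEAU_S
LEAD_IN_S = 120.0
INTER_STIMULUS_REST_S = 220.0

#: Functional-group vocabulary used by the synthetic atlas.
FUNCTIONAL_GROUPS: tuple[str, ...] = (
    "somatosensory_cortex",
    "motor_cortex",
    "cingulate_cortex",
    "thalamus",
    "hippocampus",
    "hypothalamus",
    "brainstem",
    "cerebellum",
)


# --------------------------------------------------------------------------
# Stimulation protocol
# --------------------------------------------------------------------------
@dataclass(frozen=True)
class StimEvent:
    """One thermal stimulus: a 5 s ramp plus 15 s plateau at one temperature."""

    onset: float  # s
    ramp: float  # s
    plateau: float  # s
    temperature: int  # degC
    set_index: int

    @property
    def duration(self) -> float:
        return self.ramp + self.plateau


@dataclass
class StimulusProtocol:
    """Timed temperature events defining one stimulation session."""

    events: list[StimEvent]
    lead_in: float = LEAD_IN_S
    inter_stimulus_rest: float = INTER_STIMULUS_REST_S
    tr: float = 2.0

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def temperatures(self) -> tuple[int, ...]:
        return tuple(sorted({e.temperature for e in self.events}))

    @property
    def duration(self) -> float:
        """Protocol length in seconds including the final rest period."""
        if not self.events:
            return self.lead_in
        last = self.events[-1]
        return last.onset + last.duration + self.inter_stimulus_rest

    def onsets(self, temperature: int) -> list[float]:
        """Onset times (s) of all events at ``temperature``."""
        return [e.onset for e in self.events if e.temperature == temperature]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "onset_s": [e.onset for e in self.events],
                "duration_s": [e.duration for e in self.events],
                "temperature_C": [e.temperature for e in self.events],
                "set_index": [e.set_index for e in self.events],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, ramp: float = RAMP_S, tr: float = 2.0) -> "StimulusProtocol":
        df = pd.read_csv(path, sep="\t")
        events = [
            StimEvent(
                onset=float(r.onset_s),
                ramp=ramp,
                plateau=float(r.duration_s) - ramp,
                temperature=int(r.temperature_C),
                set_index=int(r.set_index),
            )
            for r in df.itertuples()
        ]
        return cls(events=events, tr=tr)


def build_stimulus_protocol(n_sets: int = 3, seed: int = 0) -> StimulusProtocol:
    """Build a pseudo-randomized thermal stimulation protocol.

    Each set presents all eight temperatures exactly once in random order;
    permutations are re-drawn so that the first stimulus of a set never
    repeats the last stimulus of the previous set. Events start after a
    120 s lead-in and are separated by 220 s of rest (240 s onset-to-onset).
    """
    if n_sets < 1:
        raise ParameterError("n_sets must be >= 1")
    rng = np.random.default_rng(seed)
    events: list[StimEvent] = []
    prev_last: int | None = None
    onset = LEAD_IN_S
    for set_index in range(n_sets):
        for _attempt in range(1000):
            perm = [int(t) for t in rng.permutation(TEMPERATURES)]
            if perm[0] != prev_last:
                break
        else:  # pragma: no cover - unreachable for 8 distinct temperatures
            raise GenerationError("could not satisfy the no-adjacent-repeat constraint")
        for temp in perm:
            events.append(
                StimEvent(onset=onset, ramp=RAMP_S, plateau=PLATEAU_S, temperature=temp, set_index=set_index)
            )
            onset += STIM_DURATION_S + INTER_STIMULUS_REST_S
        prev_last = perm[-1]
    return StimulusProtocol(events=events)


# --------------------------------------------------------------------------
# Hemodynamic response function
# --------------------------------------------------------------------------
@dataclass(frozen=True)
class HRFParams:
    """Two-gamma HRF parameters (all times in seconds).

    Defaults reproduce the rodent-calibrated kernel used for the thermal
    stimulation analysis: response peak at 16 s, undershoot peak at 40 s,
    unit dispersions, undershoot ratio 1.
    """

    onset: float = 0.0
    time_to_peak: float = 16.0
    response_dispersion: float = 1.0
    undershoot_ratio: float = 1.0
    time_to_undershoot_peak: float = 40.0
    undershoot_dispersion: float = 1.0

    def __post_init__(self) -> None:
        if self.response_dispersion <= 0 or self.undershoot_dispersion <= 0:
            raise ParameterError("HRF dispersions must be positive")
        if self.time_to_peak <= self.onset:
            raise ParameterError("time_to_peak must exceed onset")
        if self.time_to_undershoot_peak <= self.time_to_peak:
            raise ParameterError("time_to_undershoot_peak must exceed time_to_peak")
        if self.undershoot_ratio < 0:
            raise ParameterError("undershoot_ratio must be >= 0")


def two_gamma_hrf(params: HRFParams, dt: float, length: float) -> np.ndarray:
    """Sample the two-gamma HRF kernel on a grid of step ``dt`` up to ``length``.

    Each lobe is a gamma density with scale equal to its dispersion and shape
    chosen so the density mode falls exactly on the stated peak time
    (shape = (peak - onset)/dispersion + 1). The undershoot lobe is scaled by
    ``undershoot_ratio`` and subtracted; the kernel is rescaled to a maximum
    of 1.
    """
    if dt <= 0:
        raise ParameterError("dt must be positive")
    if length <= params.time_to_undershoot_peak:
        raise ParameterError("length must exceed the undershoot peak time")
    t = np.arange(0.0, length + 0.5 * dt, dt)
    ts = t - params.onset
    k1 = (params.time_to_peak - params.onset) / params.response_dispersion + 1.0
    k2 = (params.time_to_undershoot_peak - params.onset) / params.undershoot_dispersion + 1.0
    lobe1 = sp_stats.gamma.pdf(ts, k1, scale=params.response_dispersion)
    lobe2 = sp_stats.gamma.pdf(ts, k2, scale=params.undershoot_dispersion)
    kernel = lobe1 - params.undershoot_ratio * lobe2
    peak = kernel.max()
    if peak <= 0:  # pragma: no cover - defensive
        raise ParameterError("degenerate HRF: non-positive peak")
    return kernel / peak


def stimulus_response_shape(
    hrf: HRFParams,
    duration: float = STIM_DURATION_S,
    fine_dt: float = 0.1,
    hrf_length: float = 60.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Unit-peak response shape of a single stimulus: boxcar convolved with the HRF.

    Returns ``(times, values)`` on a fine grid starting at stimulus onset.
    Shared between the phantom generator and the GLM design builder so the
    planted and modelled responses use the identical shape.
    """
    kernel = two_gamma_hrf(hrf, fine_dt, hrf_length)
    n_box = max(1, int(round(duration / fine_dt)))
    boxcar = np.ones(n_box)
    resp = np.convolve(boxcar, kernel) * fine_dt
    times = np.arange(resp.size) * fine_dt
    return times, resp / resp.max()


# --------------------------------------------------------------------------
# Synthetic atlas
# --------------------------------------------------------------------------
@dataclass
class SyntheticAtlas:
    """A label volume partitioning an ellipsoidal brain mask into parcels.

    ``structure_table`` has one row per parcel with columns ``label_id``,
    ``name``, ``hemisphere`` and ``functional_group``.
    """

    label_volume: np.ndarray
    structure_table: pd.DataFrame
    voxel_size: tuple[float, float, float]
    brain_mask: np.ndarray

    @property
    def n_structures(self) -> int:
        return len(self.structure_table)

    @property
    def label_ids(self) -> np.ndarray:
        return self.structure_table["label_id"].to_numpy()

    def voxels_of(self, label_id: int) -> np.ndarray:
        """Boolean mask of the parcel's voxels."""
        return self.label_volume == label_id

    def centers_of_mass_mm(self) -> dict[int, np.ndarray]:
        """Unweighted center of mass of each parcel at voxel centers, in mm."""
        vs = np.asarray(self.voxel_size)
        out = {}
        for lid in self.label_ids:
            idx = np.argwhere(self.label_volume == lid)
            out[int(lid)] = (idx.mean(axis=0) + 0.5) * vs
        return out

    def functional_group_of(self) -> dict[int, str]:
        return dict(
            zip(
                self.structure_table["label_id"].astype(int),
                self.structure_table["functional_group"],
            )
        )

    def save(self, label_path, table_path) -> None:
        from .core import save_mask

        save_mask(self.label_volume, self.voxel_size, label_path)
        self.structure_table.to_csv(table_path, sep="\t", index=False)


def build_synthetic_atlas(
    shape: tuple[int, int, int],
    n_structures: int,
    seed: int = 0,
    voxel_size: tuple[float, float, float] = (0.391, 0.391, 1.0),
    n_groups: int = len(FUNCTIONAL_GROUPS),
) -> SyntheticAtlas:
    """Partition an ellipsoidal brain mask into ``n_structures`` contiguous parcels.

    Parcels grow as Voronoi cells (in mm metric) around randomly seeded
    in-mask voxels; each parcel receives a hemisphere (left/right of the
    volume midline) and one of ``n_groups`` functional groups assigned by
    spatial position (caudal-to-rostral chunks), so groups are spatially
    coherent as in a real atlas.
    """
    if n_structures < 2:
        raise ParameterError("n_structures must be >= 2")
    nx, ny, nz = shape
    gx, gy, gz = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    center = (np.array(shape) - 1) / 2.0
    radii = 0.45 * np.array(shape)
    mask = (
        ((gx - center[0]) / radii[0]) ** 2
        + ((gy - center[1]) / radii[1]) ** 2
        + ((gz - center[2]) / radii[2]) ** 2
    ) <= 1.0
    in_idx = np.argwhere(mask)
    if len(in_idx) < n_structures:
        raise GenerationError(
            f"cannot pack {n_structures} parcels into a mask of {len(in_idx)} voxels"
        )
    rng = np.random.default_rng(seed)
    chosen = in_idx[rng.choice(len(in_idx), size=n_structures, replace=False)]
    vs = np.asarray(voxel_size)
    tree = cKDTree(chosen * vs)
    _, nearest = tree.query(in_idx * vs)
    labels = np.zeros(shape, dtype=np.int32)
    labels[tuple(in_idx.T)] = nearest + 1

    rows = []
    centroids = np.zeros((n_structures, 3))
    for i in range(n_structures):
        vox = in_idx[nearest == i]
        centroids[i] = vox.mean(axis=0)
    # spatially coherent functional groups: chunk parcels along z then y
    order = np.lexsort((centroids[:, 1], centroids[:, 2]))
    group_of = np.empty(n_structures, dtype=object)
    for g, chunk in enumerate(np.array_split(order, n_groups)):
        group_of[chunk] = FUNCTIONAL_GROUPS[g % len(FUNCTIONAL_GROUPS)]
    for i in range(n_structures):
        hemi = "L" if centroids[i, 0] < center[0] else "R"
        group = group_of[i]
        rows.append(
            {
                "label_id": i + 1,
                "name": f"{group}_{hemi}_{i + 1:03d}",
                "hemisphere": hemi,
                "functional_group": group,
            }
        )
    table = pd.DataFrame(rows)
    return SyntheticAtlas(labels, table, tuple(voxel_size), mask)


# --------------------------------------------------------------------------
# Effect models
# --------------------------------------------------------------------------
@dataclass
class EffectModel:
    """Group-level BOLD effect model for phantom generation.

    The amplitude curve maps stimulation temperature to the peak %BOLD change
    of responsive structures. The baseline group rises linearly from 0 at
    48 degC to ``amp_max`` at 54 degC and is 0 below; the desensitized (rtx)
    group is flat with an optional small 54 degC term.

    Noise structure: per-voxel AR(1) Gaussian noise, a per-voxel linear
    drift, and a shared global signal. Stimulus responses additionally carry
    per-event multiplicative gain jitter and onset latency jitter, drawn per
    functional-group subnetwork, which is what gives responsive regions a
    stimulus-driven covariance beyond the global mean response.
    """

    group: str  # "baseline" or "rtx"
    responsive_structures: frozenset = frozenset()
    amp_max: float = 1.5  # % BOLD at 54 degC
    threshold_c: float = 48.0
    rtx_bump_54: float = 0.3  # % BOLD at 54 degC for the rtx group
    noise_sigma: float = 1.0  # % signal, per-voxel AR(1) noise sd
    ar1_coefficient: float = 0.3
    drift_amplitude: float = 0.5  # % signal peak-to-mid linear drift scale
    global_signal_sigma: float = 0.3  # % signal, shared across voxels
    trial_amplitude_jitter: float = 0.3  # fractional gain sd per event/subnetwork
    latency_jitter_s: float = 0.75  # onset jitter sd per event/subnetwork
    structure_gain: dict | None = None  # optional per-structure amplitude scaling

    def amplitude(self, temperature: float) -> float:
        """Peak %BOLD change planted for a stimulus at ``temperature``."""
        if self.group == "rtx":
            return self.rtx_bump_54 if temperature >= 54 else 0.0
        if temperature <= self.threshold_c:
            return 0.0
        span = 54.0 - self.threshold_c
        return self.amp_max * (temperature - self.threshold_c) / span

    def amplitude_curve(self) -> dict[int, float]:
        return {t: self.amplitude(t) for t in TEMPERATURES}

    @classmethod
    def baseline(cls, responsive_structures, **kwargs) -> "EffectModel":
        return cls(group="baseline", responsive_structures=frozenset(responsive_structures), **kwargs)

    @classmethod
    def rtx(cls, responsive_structures, **kwargs) -> "EffectModel":
        return cls(group="rtx", responsive_structures=frozenset(responsive_structures), **kwargs)


def _ar1_noise(rng: np.random.Generator, n_series: int, n_t: int, rho: float, sigma: float) -> np.ndarray:
    """Stationary AR(1) Gaussian noise with marginal sd ``sigma``."""
    eps = rng.standard_normal((n_series, n_t), dtype=np.float32)
    if sigma == 0:
        return np.zeros((n_series, n_t), dtype=np.float32)
    if rho == 0:
        return sigma * eps
    innov = eps * np.float32(np.sqrt(1.0 - rho**2))
    innov[:, 0] = eps[:, 0]  # stationary start
    x = sp_signal.lfilter([1.0], [1.0, -rho], innov, axis=-1)
    return (sigma * x).astype(np.float32)


def _structure_subnetworks(atlas: SyntheticAtlas, model: EffectModel) -> dict[int, str]:
    """Map each responsive structure to its jitter subnetwork (functional group)."""
    groups = atlas.functional_group_of()
    return {int(s): groups[int(s)] for s in sorted(model.responsive_structures)}


def simulate_session(
    atlas: SyntheticAtlas,
    protocol: StimulusProtocol,
    model: EffectModel,
    hrf: HRFParams,
    tr: float = 2.0,
    n_volumes: int | None = None,
    seed: int = 0,
    include_ramp: bool = True,
    baseline_level: float = 100.0,
) -> BoldSeries:
    """Simulate one stimulus-driven BOLD session on the atlas grid.

    Per-voxel signal is
    ``baseline * (1 + (response + drift + global + noise)/100)`` where the
    response of a voxel in a responsive structure sums, over events, the
    amplitude-curve value at the event temperature times a unit-peak
    boxcar-convolved-HRF shape, modulated by per-event subnetwork gain and
    latency jitter. All terms are in % signal.
    """
    if n_volumes is None:
        n_volumes = int(np.ceil(protocol.duration / tr))
    run_end = n_volumes * tr
    if protocol.events and protocol.events[-1].onset + protocol.events[-1].duration > run_end:
        raise DesignError(
            f"protocol ends at {protocol.events[-1].onset + protocol.events[-1].duration:.0f} s "
            f"but the series covers only {run_end:.0f} s"
        )
    rng = np.random.default_rng(seed)
    vol_times = tr * np.arange(n_volumes)
    duration = STIM_DURATION_S if include_ramp else PLATEAU_S
    onset_shift = 0.0 if include_ramp else RAMP_S
    shape_t, shape_v = stimulus_response_shape(hrf, duration=duration)

    subnet_of = _structure_subnetworks(atlas, model)
    subnets = sorted(set(subnet_of.values()))
    # per-event, per-subnetwork response modulation (drawn even when unused,
    # so the noise stream does not depend on the effect model)
    gains = {
        (e_i, sn): 1.0 + rng.normal(0.0, model.trial_amplitude_jitter)
        for e_i in range(protocol.n_events)
        for sn in subnets
    }
    lats = {
        (e_i, sn): rng.normal(0.0, model.latency_jitter_s)
        for e_i in range(protocol.n_events)
        for sn in subnets
    }

    subnet_traces = {sn: np.zeros(n_volumes) for sn in subnets}
    for e_i, ev in enumerate(protocol.events):
        amp = model.amplitude(ev.temperature)
        if amp == 0.0:
            continue
        for sn in subnets:
            tau = vol_times - (ev.onset + onset_shift) - lats[(e_i, sn)]
            subnet_traces[sn] += amp * gains[(e_i, sn)] * np.interp(tau, shape_t, shape_v, left=0.0, right=0.0)

    labels = atlas.label_volume
    mask = atlas.brain_mask
    vox_labels = labels[mask]
    n_vox = vox_labels.size

    pct = np.zeros((n_vox, n_volumes), dtype=np.float32)
    for s, sn in subnet_of.items():
        gain_s = 1.0 if model.structure_gain is None else model.structure_gain.get(s, 1.0)
        sel = vox_labels == s
        if sel.any():
            pct[sel] += (gain_s * subnet_traces[sn]).astype(np.float32)

    slope = (rng.uniform(-1.0, 1.0, size=n_vox) * model.drift_amplitude).astype(np.float32)
    ramp01 = (vol_times / max(run_end - tr, tr) - 0.5).astype(np.float32)
    pct += slope[:, None] * ramp01[None, :]
    pct += _ar1_noise(rng, 1, n_volumes, model.ar1_coefficient, model.global_signal_sigma)
    pct += _ar1_noise(rng, n_vox, n_volumes, model.ar1_coefficient, model.noise_sigma)

    data = np.zeros((*labels.shape, n_volumes), dtype=np.float32)
    data[mask] = baseline_level * (1.0 + pct / 100.0)
    return BoldSeries(
        data=data,
        tr=tr,
        voxel_size=atlas.voxel_size,
        brain_mask=mask,
        t0=0.0,
        provenance={
            "kind": "stimulus_session",
            "seed": seed,
            "group": model.group,
            "amplitude_curve": model.amplitude_curve(),
            "model": {
                k: v
                for k, v in dataclasses.asdict(model).items()
                if k not in ("responsive_structures", "structure_gain")
            },
            "responsive_structures": sorted(int(s) for s in model.responsive_structures),
        },
    )


def simulate_resting_state(
    atlas: SyntheticAtlas,
    model: EffectModel,
    tr: float = 2.0,
    n_volumes: int = 300,
    seed: int = 0,
    correlation: np.ndarray | dict | None = None,
    latent_amplitude: float = 1.0,
    baseline_level: float = 100.0,
) -> BoldSeries:
    """Simulate a resting-state session with planted inter-regional correlation.

    ``correlation`` is either a full structure-by-structure correlation
    matrix (ordered by ``atlas.label_ids``), a dict mapping structure-id
    pairs to a correlation (identity elsewhere), or None for independent
    regions. Every voxel of structure ``s`` receives ``latent_amplitude``
    times the structure latent (in % signal) plus the model's drift, global
    signal and AR(1) voxel noise. The planted matrix is recorded in the
    provenance.
    """
    n_struct = atlas.n_structures
    if correlation is None:
        corr = np.eye(n_struct)
    elif isinstance(correlation, dict):
        corr = np.eye(n_struct)
        pos = {int(lid): i for i, lid in enumerate(atlas.label_ids)}
        for (a, b), r in correlation.items():
            corr[pos[int(a)], pos[int(b)]] = corr[pos[int(b)], pos[int(a)]] = float(r)
    else:
        corr = np.asarray(correlation, dtype=float)
        if corr.shape != (n_struct, n_struct):
            raise ParameterError("correlation matrix shape does not match the atlas")
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        # nudge to the nearest PSD matrix
        w, v = np.linalg.eigh(corr)
        chol = np.linalg.cholesky(v @ np.diag(np.clip(w, 1e-8, None)) @ v.T)

    rng = np.random.default_rng(seed)
    latents = chol @ rng.standard_normal((n_struct, n_volumes))

    labels = atlas.label_volume
    mask = atlas.brain_mask
    vox_labels = labels[mask]
    n_vox = vox_labels.size
    pos = {int(lid): i for i, lid in enumerate(atlas.label_ids)}
    lat_idx = np.array([pos[int(l)] for l in vox_labels])

    pct = latent_amplitude * latents[lat_idx]
    run_end = n_volumes * tr
    vol_times = tr * np.arange(n_volumes)
    slope = rng.uniform(-1.0, 1.0, size=n_vox) * model.drift_amplitude
    pct = pct + slope[:, None] * (vol_times / max(run_end - tr, tr) - 0.5)[None, :]
    pct += _ar1_noise(rng, 1, n_volumes, model.ar1_coefficient, model.global_signal_sigma)
    pct += _ar1_noise(rng, n_vox, n_volumes, model.ar1_coefficient, model.noise_sigma)

    data = np.zeros((*labels.shape, n_volumes), dtype=np.float32)
    data[mask] = baseline_level * (1.0 + pct / 100.0)
    return BoldSeries(
        data=data,
        tr=tr,
        voxel_size=atlas.voxel_size,
        brain_mask=mask,
        t0=0.0,
        provenance={
            "kind": "resting_state",
            "seed": seed,
            "group": model.group,
            "planted_correlation": corr.tolist(),
            "latent_amplitude": latent_amplitude,
        },
    )
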