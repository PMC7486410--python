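"""Synthetic calcium-imaging sessions with known ground truth.

Two generators are provided:

* :func:`gen_slice_session` emulates a developing-slice recording:
  sparse asynchronous background onsets plus recurrent network bursts
  (GDPs) at a Poisson rate (defaults near 0.02 Hz, the median rate of
  spontaneous GDPs in developing hippocampus), with optional
  single-cell stimulation effects — either extra, stimulation-locked
  GDPs at a configurable latency or a GDP-rate change during the
  stimulation epoch.

* :func:`gen_invivo_session` emulates an adult head-fixed session
  (default 9.85 frames/s): alternating locomotion/rest bouts, a subset
  of locomotion-modulated cells, rest-restricted synchronous calcium
  events (SCEs, default rate 0.08 Hz), planted co-activation assemblies
  whose joint spikes land in single 200 ms analysis bins, and planted
  directed-lag hub cells whose spikes are followed by target spikes at
  a fixed lag with given transmission probability.

Every generator consumes a frozen spec carrying its own ``seed``;
identical spec + seed yields a bit-identical session.  Ground truth is
returned as a plain JSON-serialisable dict so recovery tests never
re-derive it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from cahub._util import poisson_times
from cahub.raster import ActivityRaster, EpochSet, StimulationProtocol


class InvalidSpecError(ValueError):
    """Raised when a simulation spec violates its invariants."""


@dataclass(frozen=True)
class HubEffect:
    """Effect of stimulating the candidate hub cell in a slice session.

    ``kind`` is one of ``"none"``, ``"locking"`` (extra GDPs follow each
    stimulation after a normally distributed latency) or ``"frequency"``
    (GDP rate multiplied during the stimulation epoch).
    """

    kind: str = "none"
    latency_s: float = 2.2
    latency_sd_s: float = 0.3
    lock_prob: float = 0.9
    multiplier: float = 1.0

    @classmethod
    def none(cls) -> "HubEffect":
        return cls(kind="none")

    @classmethod
    def locking(
        cls,
        latency_s: float = 2.2,
        latency_sd_s: float = 0.3,
        lock_prob: float = 0.9,
    ) -> "HubEffect":
        return cls(
            kind="locking",
            latency_s=latency_s,
            latency_sd_s=latency_sd_s,
            lock_prob=lock_prob,
        )

    @classmethod
    def frequency(cls, multiplier: float) -> "HubEffect":
        return cls(kind="frequency", multiplier=multiplier)


@dataclass(frozen=True)
class SliceSimSpec:
    """Parameters of a synthetic developing-slice session.

    Defaults reflect a typical usable slice experiment: 100 imaged
    cells at 5 frames/s, GDPs at 0.02 Hz recruiting 80% of cells with a
    ~0.6 s onset-recruitment jitter, ~0.08 Hz asynchronous background
    onsets per cell, and a 1500 s session with a short (150 s)
    stimulation epoch flanked by long control and recovery epochs so
    that the locking test's surrogate segment is representative of the
    spontaneous rhythm.
    """

    n_cells: int = 100
    duration_s: float = 1500.0
    frame_rate_hz: float = 5.0
    gdp_rate_hz: float = 0.02
    gdp_participation: float = 0.8
    gdp_jitter_frames: float = 3.0
    baseline_event_rate_hz: float = 0.08
    hub_effect: HubEffect = field(default_factory=HubEffect.none)
    stim_rate_hz: float = 0.1
    trial_len_s: float = 5.0
    pre_frac: float = 0.45
    stim_frac: float = 0.10
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells < 1:
            raise InvalidSpecError("n_cells must be >= 1")
        if self.duration_s <= 0 or self.frame_rate_hz <= 0:
            raise InvalidSpecError("duration and frame rate must be positive")
        if self.duration_s * self.frame_rate_hz < 1:
            raise InvalidSpecError("session must span at least one frame")
        for name in ("gdp_rate_hz", "baseline_event_rate_hz", "stim_rate_hz"):
            if getattr(self, name) < 0:
                raise InvalidSpecError(f"{name} must be >= 0")
        if not 0 < self.gdp_participation <= 1:
            raise InvalidSpecError("gdp_participation must be in (0, 1]")
        if not (0 < self.pre_frac and 0 < self.stim_frac
                and self.pre_frac + self.stim_frac < 1):
            raise InvalidSpecError("epoch fractions must partition the session")
        if self.hub_effect.kind not in ("none", "locking", "frequency"):
            raise InvalidSpecError(f"unknown hub effect {self.hub_effect.kind!r}")


@dataclass(frozen=True)
class AssemblySpec:
    """One planted co-activation assembly."""

    members: tuple[int, ...]
    rate_hz: float = 0.05
    member_prob: float = 0.9


@dataclass(frozen=True)
class HubConnectionSpec:
    """One planted directed-lag hub: source spikes are echoed by targets.

    ``lag_jitter_frames`` is the SD of the per-spike transmission jitter
    (synaptic delay variability plus spike-inference timing noise); it
    also determines how sharply common-drive correlations between two
    targets of the same source concentrate at zero lag.
    """

    source: int
    targets: tuple[int, ...]
    lag_ms: float = 300.0
    prob: float = 0.9
    lag_jitter_frames: float = 1.0


@dataclass(frozen=True)
class InVivoSimSpec:
    """Parameters of a synthetic adult in vivo session.

    Defaults reflect a stratum-pyramidale field of view: 150 cells (the
    real sessions held 77-236), 9.85 frames/s, exponential alternation
    of locomotion (~10 s) and rest (~20 s) bouts, rest-only SCEs at
    0.08 Hz recruiting 30% of cells, and ~0.4 Hz per-cell baseline
    inferred-spike rates.
    """

    n_cells: int = 150
    duration_s: float = 1200.0
    frame_rate_hz: float = 9.85
    locomotion_bout_s: float = 10.0
    rest_bout_s: float = 20.0
    loco_modulated_fraction: float = 0.1
    loco_rate_gain: float = 3.0
    sce_rate_hz: float = 0.08
    sce_participation: float = 0.3
    assemblies: tuple[AssemblySpec, ...] = ()
    hub_spec: tuple[HubConnectionSpec, ...] = ()
    baseline_rate_hz: float = 0.4
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells < 1:
            raise InvalidSpecError("n_cells must be >= 1")
        if self.duration_s <= 0 or self.frame_rate_hz <= 0:
            raise InvalidSpecError("duration and frame rate must be positive")
        if self.duration_s * self.frame_rate_hz < 1:
            raise InvalidSpecError("session must span at least one frame")
        for name in ("sce_rate_hz", "baseline_rate_hz"):
            if getattr(self, name) < 0:
                raise InvalidSpecError(f"{name} must be >= 0")
        if not 0 <= self.loco_modulated_fraction <= 1:
            raise InvalidSpecError("loco_modulated_fraction must be in [0, 1]")
        if not 0 < self.sce_participation <= 1:
            raise InvalidSpecError("sce_participation must be in (0, 1]")
        if self.locomotion_bout_s <= 0 or self.rest_bout_s <= 0:
            raise InvalidSpecError("bout durations must be positive")
        for a in self.assemblies:
            if not a.members or min(a.members) < 0 or max(a.members) >= self.n_cells:
                raise InvalidSpecError("assembly members outside cell index range")
            if a.rate_hz < 0 or not 0 <= a.member_prob <= 1:
                raise InvalidSpecError("invalid assembly rate or member_prob")
        for h in self.hub_spec:
            cells = (h.source, *h.targets)
            if min(cells) < 0 or max(cells) >= self.n_cells:
                raise InvalidSpecError("hub cells outside cell index range")
            if abs(h.lag_ms) > 1000:
                raise InvalidSpecError("hub lag must be within +/-1000 ms")
            if not 0 <= h.prob <= 1:
                raise InvalidSpecError("hub transmission prob must be in [0, 1]")


@dataclass
class SessionEpochs:
    """Locomotion/rest epoch pair of one in vivo session."""

    locomotion: EpochSet
    rest: EpochSet


def gen_slice_session(
    spec: SliceSimSpec,
) -> tuple[ActivityRaster, StimulationProtocol, dict]:
    """Simulate one slice session with single-cell stimulation.

    Returns the onset raster, the stimulation protocol (equal pre /
    stim / post epochs; pulses at ``stim_rate_hz`` whose trials fit
    inside the stim epoch) and a ground-truth dict listing true GDP
    frames (spontaneous and stimulation-locked separately) and the
    effect type.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    fs = spec.frame_rate_hz
    n_frames = int(round(spec.duration_s * fs))
    f1 = int(round(n_frames * spec.pre_frac))
    f2 = int(round(n_frames * (spec.pre_frac + spec.stim_frac)))

    trial_len_frames = max(1, int(round(spec.trial_len_s * fs)))
    spacing = max(trial_len_frames, int(round(fs / spec.stim_rate_hz)))
    stim_frames = np.arange(f1, f2, spacing, dtype=np.int64)
    stim_frames = stim_frames[stim_frames + trial_len_frames <= f2]

    eff = spec.hub_effect
    # Locking is modelled as entrainment: stimulation-triggered GDPs
    # replace the spontaneous rhythm during the stimulation epoch
    # rather than adding to it.
    if eff.kind == "frequency":
        stim_rate = spec.gdp_rate_hz * eff.multiplier
    elif eff.kind == "locking":
        stim_rate = 0.0
    else:
        stim_rate = spec.gdp_rate_hz
    t1, t2 = f1 / fs, f2 / fs
    spont = np.concatenate([
        poisson_times(spec.gdp_rate_hz, 0.0, t1, rng),
        poisson_times(stim_rate, t1, t2, rng),
        poisson_times(spec.gdp_rate_hz, t2, spec.duration_s, rng),
    ])
    locked = np.empty(0)
    if eff.kind == "locking" and len(stim_frames):
        hit = rng.random(len(stim_frames)) < eff.lock_prob
        lat = rng.normal(eff.latency_s, eff.latency_sd_s, size=len(stim_frames))
        t = stim_frames[hit] / fs + lat[hit]
        locked = t[(t >= 0) & (t < spec.duration_s)]

    spont_frames = np.unique(
        np.clip(np.round(spont * fs).astype(np.int64), 0, n_frames - 1)
    )
    locked_frames = np.unique(
        np.clip(np.round(locked * fs).astype(np.int64), 0, n_frames - 1)
    )
    gdp_frames = np.unique(np.concatenate([spont_frames, locked_frames]))

    onsets = (
        rng.random((spec.n_cells, n_frames))
        < spec.baseline_event_rate_hz / fs
    ).astype(np.uint8)
    for g in gdp_frames:
        members = rng.random(spec.n_cells) < spec.gdp_participation
        jit = np.round(
            rng.normal(0.0, spec.gdp_jitter_frames, size=int(members.sum()))
        ).astype(np.int64)
        frames = np.clip(g + jit, 0, n_frames - 1)
        onsets[np.flatnonzero(members), frames] = 1

    raster = ActivityRaster(onsets, fs)
    proto = StimulationProtocol(
        stim_frames, trial_len_frames,
        pre=(0, f1), stim=(f1, f2), post=(f2, n_frames),
        stim_rate_hz=spec.stim_rate_hz,
    )
    ground_truth = {
        "effect": eff.kind,
        "gdp_frames": gdp_frames.tolist(),
        "spontaneous_gdp_frames": spont_frames.tolist(),
        "locked_gdp_frames": locked_frames.tolist(),
        "latency_s": eff.latency_s if eff.kind == "locking" else None,
        "n_frames": n_frames,
        "frame_rate_hz": fs,
    }
    return raster, proto, ground_truth


def _alternating_bouts(
    spec: InVivoSimSpec, rng: np.random.Generator, n_frames: int
) -> tuple[EpochSet, EpochSet]:
    """Exponential locomotion/rest alternation, rest first.

    Rest bouts are floored at 2.5 s so that every rest epoch is
    unambiguous (> 0.2 s) and can host an SCE with a 1 s flanking
    margin; locomotion bouts are floored at 0.5 s.
    """
    fs = spec.frame_rate_hz
    loco_iv: list[tuple[int, int]] = []
    rest_iv: list[tuple[int, int]] = []
    f = 0
    resting = True
    while f < n_frames:
        mean = spec.rest_bout_s if resting else spec.locomotion_bout_s
        floor = 2.5 if resting else 0.5
        d = max(rng.exponential(mean), floor)
        e = min(n_frames, f + int(round(d * fs)))
        if e > f:
            (rest_iv if resting else loco_iv).append((f, e))
        f = e
        resting = not resting
    loco = EpochSet("locomotion", np.asarray(loco_iv, dtype=np.int64).reshape(-1, 2))
    rest = EpochSet("rest", np.asarray(rest_iv, dtype=np.int64).reshape(-1, 2))
    return loco, rest


def gen_invivo_session(
    spec: InVivoSimSpec,
) -> tuple[ActivityRaster, SessionEpochs, dict]:
    """Simulate one adult in vivo session.

    Returns the onset raster, the locomotion/rest epoch pair, and a
    ground-truth dict enumerating locomotion-modulated cells, SCE
    frames, assembly memberships and activation frames, and planted
    directed edges.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    fs = spec.frame_rate_hz
    n_frames = int(round(spec.duration_s * fs))
    loco, rest = _alternating_bouts(spec, rng, n_frames)
    loco_mask = loco.mask(n_frames)

    n_mod = int(round(spec.loco_modulated_fraction * spec.n_cells))
    mod_cells = np.sort(rng.choice(spec.n_cells, size=n_mod, replace=False))

    p = np.full((spec.n_cells, n_frames), spec.baseline_rate_hz / fs)
    p[np.ix_(mod_cells, np.flatnonzero(loco_mask))] *= spec.loco_rate_gain
    onsets = (rng.random((spec.n_cells, n_frames)) < np.minimum(p, 1.0)).astype(
        np.uint8
    )

    # SCEs: rest only, >= 1 s margin from rest-epoch edges, >= 1 s apart.
    margin_f = int(np.ceil(1.0 * fs))
    sce_frames: list[int] = []
    for s, e in rest.intervals:
        lo, hi = s + margin_f, e - margin_f
        if hi <= lo:
            continue
        times = poisson_times(spec.sce_rate_hz, lo / fs, hi / fs, rng)
        for t in times:
            f = int(round(t * fs))
            if not sce_frames or (f - sce_frames[-1]) / fs >= 1.0:
                sce_frames.append(f)
    for f in sce_frames:
        members = rng.random(spec.n_cells) < spec.sce_participation
        onsets[members, f] = 1

    # Assemblies: joint spikes at single rest frames away from bin-dropped
    # epoch tails so each activation falls inside one full 200 ms bin.
    asm_margin = int(np.ceil(0.5 * fs))
    assembly_truth = []
    for a in spec.assemblies:
        act_frames: list[int] = []
        for s, e in rest.intervals:
            lo, hi = s + asm_margin, e - asm_margin
            if hi <= lo:
                continue
            for t in poisson_times(a.rate_hz, lo / fs, hi / fs, rng):
                act_frames.append(int(round(t * fs)))
        members = np.asarray(a.members, dtype=np.int64)
        for f in act_frames:
            firing = members[rng.random(len(members)) < a.member_prob]
            onsets[firing, f] = 1
        assembly_truth.append(
            {"members": sorted(a.members), "activation_frames": sorted(act_frames)}
        )

    edges = []
    for h in spec.hub_spec:
        lag_f = int(round(h.lag_ms / 1000.0 * fs))
        src_spikes = np.flatnonzero(onsets[h.source])
        for tgt in h.targets:
            hit = rng.random(len(src_spikes)) < h.prob
            jit = np.round(
                rng.normal(0.0, h.lag_jitter_frames, size=int(hit.sum()))
            ).astype(np.int64)
            frames = src_spikes[hit] + lag_f + jit
            frames = frames[(frames >= 0) & (frames < n_frames)]
            onsets[tgt, frames] = 1
            edges.append([int(h.source), int(tgt), float(h.lag_ms)])

    raster = ActivityRaster(onsets, fs)
    ground_truth = {
        "loco_modulated_cells": mod_cells.tolist(),
        "sce_frames": sce_frames,
        "assemblies": assembly_truth,
        "edges": edges,
        "locomotion_intervals": loco.intervals.tolist(),
        "rest_intervals": rest.intervals.tolist(),
        "n_frames": n_frames,
        "frame_rate_hz": fs,
    }
    return raster, SessionEpochs(loco, rest), ground_truth
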