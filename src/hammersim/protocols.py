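"""Trial schedules of the four experiments and cohort-level simulation.

Trials always come in CCW-then-CW pairs of 40 deg rotations.  Schedules are
deterministic given a seed; randomized elements (error-clamp positions,
probe-orientation order, mass order) are drawn without replacement where
the design is balanced.

Experiment 1: 5 visual orientations x 4 trial pairs, all error-clamp.
Experiment 2: blocks of 90 trials at one head mass (0.7/1.0/1.3 % of body
    mass): 60 training trials at 0 deg, then 30 trials containing 24
    training trials and 6 randomly placed error-clamps (3 at 0 deg, 3 at
    -90 deg).
Experiment 3: 64 training trials at 0 deg, then 15 blocks of 26 trials:
    8 zero-force probes at one of {0, -22.5, -45, -90, 180} deg, 2
    error-clamps at 0 deg, 16 full-dynamics trials at 0 deg; each probe
    orientation appears 3 times.
Experiment 4: 24 zero-force pre-exposure trials, 248 full-dynamics
    exposure trials, 256 trials with one error-clamp randomly placed in
    every consecutive 8-trial window (training or -90 deg transfer
    orientation), and 48 zero-force post-exposure trials.  The visual
    orientation either matches the dynamics (congruent) or is rotated
    180 deg (incongruent).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .angles import wrap_deg
from .dynamics import HandImpedance
from .subject import SubjectState, TrialSpec, simulate_trial

__all__ = [
    "ExperimentSchedule",
    "build_experiment",
    "run_experiment",
    "EXP1_ORIENTATIONS",
    "EXP3_PROBE_ORIENTATIONS",
    "MASS_PCT_LEVELS",
]

EXP1_ORIENTATIONS = (-90.0, -45.0, 0.0, 45.0, 90.0)
EXP3_PROBE_ORIENTATIONS = (0.0, -22.5, -45.0, -90.0, 180.0)
MASS_PCT_LEVELS = (0.7, 1.0, 1.3)  # head mass as % of body mass


@dataclass
class ExperimentSchedule:
    experiment_id: int
    trials: list  # list[TrialSpec]
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.trials)

    def to_json(self, path=None) -> Optional[str]:
        payload = {
            "experiment_id": self.experiment_id,
            "metadata": self.metadata,
            "trials": [asdict(t) for t in self.trials],
        }
        text = json.dumps(payload, indent=1)
        if path is None:
            return text
        with open(path, "w") as fh:
            fh.write(text)
        return None


def _pair_direction(i: int) -> str:
    """Trials alternate CCW (even index) and CW (odd index)."""
    return "CCW" if i % 2 == 0 else "CW"


def build_experiment(
    experiment_id: int,
    body_mass: float = 70.0,
    seed: Optional[int] = None,
    congruent: bool = True,
    train_visual: float = 0.0,
    pre_exposure_trials: int = 24,
    mass_pct: float = 1.0,
) -> ExperimentSchedule:
    """Build the trial schedule of one experiment (deterministic given seed)."""
    rng = np.random.default_rng(seed)
    mass = mass_pct / 100.0 * body_mass
    trials: list[TrialSpec] = []

    def add(condition, visual, dynamics, head_mass, block, phase, probe=float("nan")):
        trials.append(
            TrialSpec(
                condition=condition,
                rotation_direction=_pair_direction(len(trials)),
                visual_orientation=float(wrap_deg(visual)),
                dynamics_orientation=float(wrap_deg(dynamics)),
                head_mass=float(head_mass),
                block=block,
                phase=phase,
                probe_orientation=probe,
                trial_index=len(trials),
            )
        )

    if experiment_id == 1:
        for sweep in range(4):
            order = rng.permutation(len(EXP1_ORIENTATIONS))
            for oi in order:
                phi = EXP1_ORIENTATIONS[oi]
                for _ in range(2):  # one CCW/CW pair
                    add("error_clamp", phi, phi, mass, sweep, "clamp")
        meta = {"orientations": list(EXP1_ORIENTATIONS), "mass_pct": mass_pct}

    elif experiment_id == 2:
        mass_order = rng.permutation(len(MASS_PCT_LEVELS))
        for b, mi in enumerate(mass_order):
            m = MASS_PCT_LEVELS[mi] / 100.0 * body_mass
            for _ in range(60):
                add("full_dynamics", 0.0, 0.0, m, b, "train")
            clamp_pos = rng.choice(30, size=6, replace=False)
            clamp_orients = rng.permutation([0.0, 0.0, 0.0, -90.0, -90.0, -90.0])
            pos_to_orient = dict(zip(sorted(clamp_pos), clamp_orients))
            for j in range(30):
                if j in pos_to_orient:
                    phi = pos_to_orient[j]
                    add("error_clamp", phi, phi, m, b, "clamp")
                else:
                    add("full_dynamics", 0.0, 0.0, m, b, "train")
        meta = {
            "mass_pct_levels": list(MASS_PCT_LEVELS),
            "mass_order": [MASS_PCT_LEVELS[i] for i in mass_order],
            "training_orientation": 0.0,
            "transfer_orientation": -90.0,
        }

    elif experiment_id == 3:
        for _ in range(64):
            add("full_dynamics", 0.0, 0.0, mass, 0, "train", probe=0.0)
        probe_order = rng.permutation(np.repeat(EXP3_PROBE_ORIENTATIONS, 3))
        for b, phi in enumerate(probe_order, start=1):
            for _ in range(8):
                add("zero_force", phi, phi, mass, b, "probe", probe=phi)
            for _ in range(2):
                add("error_clamp", 0.0, 0.0, mass, b, "post_clamp", probe=phi)
            for _ in range(16):
                add("full_dynamics", 0.0, 0.0, mass, b, "relearn", probe=phi)
        meta = {
            "probe_orientations": list(EXP3_PROBE_ORIENTATIONS),
            "mass_pct": mass_pct,
        }

    elif experiment_id == 4:
        dyn_train = train_visual if congruent else wrap_deg(train_visual - 180.0)
        offset = dyn_train - train_visual  # 0 or -180
        for _ in range(pre_exposure_trials):
            add("zero_force", train_visual, dyn_train, mass, 0, "pre")
        for _ in range(248):
            add("full_dynamics", train_visual, dyn_train, mass, 1, "exposure")
        n_windows = 256 // 8
        clamp_orients = rng.permutation(
            [train_visual] * (n_windows // 2) + [train_visual - 90.0] * (n_windows // 2)
        )
        for w in range(n_windows):
            pos = int(rng.integers(8))
            for j in range(8):
                if j == pos:
                    phi = clamp_orients[w]
                    add("error_clamp", phi, phi + offset, mass, 2, "clamp_phase")
                else:
                    add(
                        "full_dynamics",
                        train_visual,
                        dyn_train,
                        mass,
                        2,
                        "clamp_phase",
                    )
        for _ in range(48):
            add("zero_force", train_visual, dyn_train, mass, 3, "post")
        meta = {
            "congruent": congruent,
            "train_visual": float(train_visual),
            "train_dynamics": float(dyn_train),
            "transfer_visual": float(wrap_deg(train_visual - 90.0)),
            "pre_exposure_trials": pre_exposure_trials,
        }
    else:
        raise ValueError(f"unknown experiment_id: {experiment_id!r}")

    meta["body_mass"] = body_mass
    meta["seed"] = seed
    return ExperimentSchedule(experiment_id=experiment_id, trials=trials, metadata=meta)


def run_experiment(
    schedule: ExperimentSchedule,
    cohort: Sequence[SubjectState],
    impedance: HandImpedance = HandImpedance(),
    seed: Optional[int] = None,
    rod_length: float = 0.3,
    duration: float = 0.7,
    sample_rate: float = 1000.0,
) -> pd.DataFrame:
    """Simulate every subject through the schedule, carrying state across
    trials; returns one flat trial table (one row per subject x trial)."""
    if len(cohort) == 0:
        raise ValueError("cohort must be nonempty")
    if any(t.head_mass <= 0 for t in schedule.trials):
        raise ValueError("schedule contains non-positive head masses")
    rows = []
    roots = np.random.SeedSequence(seed).spawn(len(cohort))
    for subj, ss in zip(cohort, roots):
        rng = np.random.default_rng(ss)
        state = subj
        for trial in schedule.trials:
            rec, state = simulate_trial(
                state,
                trial,
                impedance=impedance,
                rng=rng,
                rod_length=rod_length,
                duration=duration,
                sample_rate=sample_rate,
            )
            rows.append(
                {
                    "subject_id": rec.subject_id,
                    "trial_index": rec.trial_index,
                    "block": rec.block,
                    "phase": rec.phase,
                    "condition": rec.condition,
                    "rotation_direction": rec.rotation_direction,
                    "visual_orientation": rec.visual_orientation,
                    "dynamics_orientation": rec.dynamics_orientation,
                    "probe_orientation": rec.probe_orientation,
                    "head_mass": rec.head_mass,
                    "required_peak_force": rec.required_peak_force,
                    "peak_force_mag": rec.peak_force_mag,
                    "peak_force_dir": rec.peak_force_dir,
                    "peak_disp_mag": rec.peak_disp_mag,
                    "peak_disp_angle": rec.peak_disp_angle,
                }
            )
    df = pd.DataFrame(rows)
    df.attrs["experiment_id"] = schedule.experiment_id
    df.attrs["metadata"] = dict(schedule.metadata)
    return df
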