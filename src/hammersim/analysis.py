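"""Measurement pipeline: peak extraction, compensated object mass,
compensation regressions, half-Gaussian generalization/deadaptation fits,
and force-vector summaries.

Angular offsets between the presented tool orientation and anticipatory
forces are reported in the display frame, which is mirror-reflected
relative to the force frame:  ``offset = wrap(180 - (force_dir -
presented))``.  In this convention a fully compensating subject shows an
offset of -93 deg on CW rotations and +93 deg on CCW rotations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares

from .angles import ang_diff_deg, bearing_to_vec, vec_to_bearing, wrap_deg
from .circstats import circ_mean_sd, circ_tlinear_assoc
from .dynamics import HandImpedance, KinematicProfile, first_peak_index, simulate_handle_motion
from .subject import TrialRecord, _signed_amplitude, _unit_loads

__all__ = [
    "PeakMeasures",
    "CompensatedMass",
    "GeneralizationFit",
    "EllipseSummary",
    "SlopeSummary",
    "extract_peaks",
    "anticipatory_offset",
    "compensated_object_mass",
    "regress_compensation",
    "fit_half_gaussian",
    "probe_generalization",
    "generalization_fit",
    "deadaptation_increase",
    "deadaptation_fit",
    "confidence_ellipse",
    "exp1_summary",
    "exp2_compensation_table",
    "exp4_transfer_summary",
]

SIGMA_BOUNDS = (5.0, 200.0)
SIGMA_STARTS = (20.0, 40.0, 80.0)


@dataclass(frozen=True)
class PeakMeasures:
    peak_force_mag: float  # N
    peak_force_dir: float  # deg
    peak_disp_mag: float  # m
    peak_disp_angle: float  # deg (PDA)
    peak_force_time: float  # s
    peak_disp_time: float  # s
    undefined_direction: bool = False


@dataclass(frozen=True)
class CompensatedMass:
    mass: float  # kg
    mass_pct_body: Optional[float] = None  # % of body mass


@dataclass(frozen=True)
class GeneralizationFit:
    amplitude: float
    sd: float  # deg
    residual_rms: float
    unidentifiable: bool = False
    per_subject_sds: Optional[np.ndarray] = None


@dataclass(frozen=True)
class EllipseSummary:
    center: np.ndarray
    axes: np.ndarray  # semi-axis lengths, descending
    angle: float  # deg, bearing of the major axis
    level: float
    degenerate: bool = False


@dataclass(frozen=True)
class SlopeSummary:
    per_subject: pd.DataFrame  # columns: subject_id, orientation, slope
    mean: dict  # orientation -> mean slope
    sd: dict  # orientation -> SD of slopes
    t_vs_zero: dict  # orientation -> (t, p)
    paired_t: Optional[tuple] = None  # (t, p) training vs transfer


def extract_peaks(record: TrialRecord) -> PeakMeasures:
    """Peak force/displacement magnitude, direction and timing of a trial.

    The peak is the first sample attaining the maximal magnitude; an
    all-zero series yields zero magnitude and an undefined direction.
    """
    F = np.asarray(record.force_series, dtype=float)
    X = np.asarray(record.displacement_series, dtype=float)
    t = np.asarray(record.times, dtype=float)
    if F.size == 0:
        raise ValueError("empty series")
    fmag = np.linalg.norm(F, axis=1)
    xmag = np.linalg.norm(X, axis=1)
    i_f, i_d = first_peak_index(fmag), first_peak_index(xmag)
    undef = fmag[i_f] == 0.0 and xmag[i_d] == 0.0
    return PeakMeasures(
        peak_force_mag=float(fmag[i_f]),
        peak_force_dir=float(vec_to_bearing(F[i_f])) if fmag[i_f] > 0 else float("nan"),
        peak_disp_mag=float(xmag[i_d]),
        peak_disp_angle=float(vec_to_bearing(X[i_d])) if xmag[i_d] > 0 else float("nan"),
        peak_force_time=float(t[i_f]),
        peak_disp_time=float(t[i_d]),
        undefined_direction=bool(undef),
    )


def anticipatory_offset(force_dir_deg, presented_deg):
    """Offset between anticipatory-force direction and presented orientation,
    in the mirrored display frame (deg, CCW-positive)."""
    return wrap_deg(180.0 - (np.asarray(force_dir_deg, float) - np.asarray(presented_deg, float)))


def compensated_object_mass(
    peak_force: float,
    rod_length: float,
    profile: KinematicProfile,
    body_mass: Optional[float] = None,
) -> CompensatedMass:
    """Head mass for which a measured anticipatory peak force would have
    been appropriate under the simulated rotation (linear in the force)."""
    if peak_force < 0:
        raise ValueError("peak_force must be >= 0")
    om = np.deg2rad(profile.omega)
    al = np.deg2rad(profile.alpha)
    unit_peak = float(np.sqrt(al**2 + om**4).max())  # |accel| per unit r
    if unit_peak == 0.0:
        raise ValueError("degenerate profile: no motion")
    mass = peak_force / (rod_length * unit_peak)
    pct = 100.0 * mass / body_mass if body_mass else None
    return CompensatedMass(mass=float(mass), mass_pct_body=pct)


def regress_compensation(
    table: pd.DataFrame,
    x: str = "true_mass",
    y: str = "compensated_mass",
    orientation_col: str = "orientation",
    training_label="training",
    transfer_label="transfer",
) -> SlopeSummary:
    """Per-subject OLS slopes of compensated vs experienced mass, summarized
    across subjects, with one-sample t vs zero and a paired training-vs-
    transfer t test when both orientations are present."""
    rows = []
    for (sid, orient), grp in table.groupby(["subject_id", orientation_col]):
        if grp[x].nunique() < 2:
            raise ValueError("need >= 2 distinct mass levels per subject")
        slope = float(np.polyfit(grp[x].to_numpy(float), grp[y].to_numpy(float), 1)[0])
        rows.append({"subject_id": sid, "orientation": orient, "slope": slope})
    per = pd.DataFrame(rows)
    mean, sd, tz = {}, {}, {}
    for orient, grp in per.groupby("orientation"):
        s = grp["slope"].to_numpy(float)
        mean[orient] = float(s.mean())
        sd[orient] = float(s.std(ddof=1)) if s.size > 1 else 0.0
        t, p = stats.ttest_1samp(s, 0.0)
        tz[orient] = (float(t), float(p))
    paired = None
    have = set(per["orientation"])
    if {training_label, transfer_label} <= have:
        wide = per.pivot(index="subject_id", columns="orientation", values="slope")
        t, p = stats.ttest_rel(wide[training_label], wide[transfer_label])
        paired = (float(t), float(p))
    return SlopeSummary(per_subject=per, mean=mean, sd=sd, t_vs_zero=tz, paired_t=paired)


def _half_gaussian(phi, a, sd):
    return a * np.exp(-(phi**2) / (2.0 * sd**2))


def fit_half_gaussian(
    orientations_deg: Sequence[float], values: Sequence[float]
) -> GeneralizationFit:
    """Least-squares fit of ``a * exp(-phi^2 / (2 sd^2))`` over absolute
    orientation distances in [0, 180] deg, with multi-start optimization."""
    phi = np.abs(np.asarray(orientations_deg, dtype=float))
    v = np.asarray(values, dtype=float)
    if phi.shape != v.shape or phi.size < 3:
        raise ValueError("need >= 3 (orientation, value) points")
    if not np.any(phi == 0.0):
        raise ValueError("fit requires a 0 deg (training) point")
    if np.allclose(v, 0.0):
        raise ValueError("all-zero values: amplitude unidentifiable")
    a0 = max(float(v.max()), 1e-12)
    best = None
    for s0 in SIGMA_STARTS:
        res = least_squares(
            lambda p: _half_gaussian(phi, p[0], p[1]) - v,
            x0=[a0, s0],
            bounds=([0.0, SIGMA_BOUNDS[0]], [np.inf, SIGMA_BOUNDS[1]]),
        )
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        raise RuntimeError("half-Gaussian fit failed from all starts")
    a, sd = best.x
    rms = float(np.sqrt(np.mean(best.fun**2)))
    flat = np.ptp(v) < 1e-9 * max(abs(v).max(), 1.0)
    unident = bool(flat or sd >= SIGMA_BOUNDS[1] - 1e-6)
    return GeneralizationFit(
        amplitude=float(a), sd=float(sd), residual_rms=rms, unidentifiable=unident
    )


def _expected_force_direction(direction: str, presented: float,
                              duration: float, sample_rate: float) -> float:
    """Bearing of the fully compensating force at its (first) peak."""
    signed = _signed_amplitude(direction)
    _, unit_F, _ = _unit_loads(signed, duration, sample_rate)
    i = first_peak_index(np.linalg.norm(unit_F, axis=1))
    base = float(vec_to_bearing(unit_F[i]))
    return float(wrap_deg(base + presented - signed / 2.0))


def probe_generalization(
    table: pd.DataFrame,
) -> pd.DataFrame:
    """Per subject x probe-orientation peak displacement on zero-force
    probe trials (Experiment 3), as the signed component along the
    direction the anticipated compensatory force predicts.

    Projecting instead of taking raw magnitudes keeps measurement noise
    symmetric at far transfer orientations, where the displacement is close
    to zero and magnitudes would be biased upward.
    """
    probes = table[table["condition"] == "zero_force"]
    if "phase" in table.columns and (table["phase"] == "probe").any():
        probes = probes[probes["phase"] == "probe"]
    if probes.empty:
        raise ValueError("no zero-force probe trials in table")
    duration = float(table.attrs.get("duration", 0.7))
    sample_rate = float(table.attrs.get("sample_rate", 1000.0))
    rows = []
    for (sid, phi), grp in probes.groupby(["subject_id", "probe_orientation"]):
        projs = []
        for _, r in grp.iterrows():
            exp_dir = _expected_force_direction(
                r["rotation_direction"], r["visual_orientation"], duration, sample_rate
            )
            projs.append(
                r["peak_disp_mag"]
                * np.cos(np.deg2rad(ang_diff_deg(r["peak_disp_angle"], exp_dir)))
            )
        rows.append(
            {
                "subject_id": sid,
                "orientation": float(abs(wrap_deg(phi))),
                "displacement": float(np.mean(projs)),
                "n_trials": len(grp),
            }
        )
    out = pd.DataFrame(rows)
    return out.groupby(["subject_id", "orientation"], as_index=False)["displacement"].mean()


def generalization_fit(table: pd.DataFrame) -> GeneralizationFit:
    """Half-Gaussian generalization fit per subject, averaged across the
    cohort (Experiment 3 probe displacements)."""
    tidy = probe_generalization(table)
    sds, amps, rmss = [], [], []
    for _, grp in tidy.groupby("subject_id"):
        f = fit_half_gaussian(grp["orientation"], grp["displacement"])
        sds.append(f.sd)
        amps.append(f.amplitude)
        rmss.append(f.residual_rms)
    sds = np.asarray(sds)
    return GeneralizationFit(
        amplitude=float(np.mean(amps)),
        sd=float(np.mean(sds)),
        residual_rms=float(np.mean(rmss)),
        per_subject_sds=sds,
    )


def _plant_peak_gain(
    impedance: HandImpedance, direction: str, duration: float, sample_rate: float
) -> float:
    """Peak displacement (m) of the hand plant per newton of peak force with
    the temporal shape of the required load."""
    signed = _signed_amplitude(direction)
    prof, unit_F, unit_peak = _unit_loads(signed, duration, sample_rate)
    disp = simulate_handle_motion(
        unit_F / unit_peak, "zero_force", None, impedance, times=prof.times
    )
    return float(np.linalg.norm(disp, axis=1).max())


def deadaptation_increase(
    table: pd.DataFrame,
    impedance: HandImpedance = HandImpedance(),
    duration: float = 0.7,
    sample_rate: float = 1000.0,
) -> pd.DataFrame:
    """Per-block increase in the training-orientation force deficit caused
    by the preceding zero-force probes (Experiment 3).

    For each block, the post-probe measure is the mean shortfall of the
    anticipatory force on the two error-clamp trials (required peak minus
    the force component along the compensating direction).  The pre-probe
    baseline is the equivalent shortfall inferred from the peak handle
    displacement on the last two full-dynamics trials of the previous
    block, converted to force units through the hand plant.  Both are
    signed projections, so measurement noise enters symmetrically.
    Returns one row per subject x probe orientation (mean over blocks), in
    newtons.
    """
    needed = {"phase", "block", "probe_orientation"}
    if not needed <= set(table.columns):
        raise ValueError("table lacks the Experiment-3 block structure")
    out = []
    for sid, sub in table.groupby("subject_id"):
        blocks = sorted(sub.loc[sub["phase"] == "probe", "block"].unique())
        if not blocks:
            raise ValueError("no probe blocks found")
        incs = {}
        for b in blocks:
            clamps = sub[(sub["block"] == b) & (sub["phase"] == "post_clamp")]
            prev = sub[
                (sub["block"] == b - 1)
                & (sub["phase"].isin(["train", "relearn"]))
                & (sub["condition"] == "full_dynamics")
            ].tail(4)
            if clamps.empty or prev.empty:
                raise ValueError(f"block {b}: missing clamp or baseline trials")
            post_vals = []
            for _, r in clamps.iterrows():
                exp_dir = _expected_force_direction(
                    r["rotation_direction"], r["visual_orientation"], duration, sample_rate
                )
                proj = r["peak_force_mag"] * np.cos(
                    np.deg2rad(ang_diff_deg(r["peak_force_dir"], exp_dir))
                )
                post_vals.append(r["required_peak_force"] - proj)
            pre_vals = []
            for _, r in prev.iterrows():
                exp_dir = _expected_force_direction(
                    r["rotation_direction"], r["visual_orientation"], duration, sample_rate
                )
                gain = _plant_peak_gain(
                    impedance, r["rotation_direction"], duration, sample_rate
                )
                # under-compensation displaces the handle opposite to the
                # compensating direction
                proj = r["peak_disp_mag"] * np.cos(
                    np.deg2rad(ang_diff_deg(r["peak_disp_angle"], exp_dir + 180.0))
                )
                pre_vals.append(proj / gain)
            phi = float(sub.loc[sub["block"] == b, "probe_orientation"].iloc[0])
            incs.setdefault(abs(wrap_deg(phi)), []).append(
                float(np.mean(post_vals) - np.mean(pre_vals))
            )
        for phi, vals in sorted(incs.items()):
            out.append(
                {
                    "subject_id": sid,
                    "orientation": float(phi),
                    "increase": float(np.mean(vals)),
                    "n_blocks": len(vals),
                }
            )
    return pd.DataFrame(out)


def deadaptation_fit(
    table: pd.DataFrame,
    impedance: HandImpedance = HandImpedance(),
    duration: float = 0.7,
    sample_rate: float = 1000.0,
) -> GeneralizationFit:
    """Half-Gaussian fit of the deadaptation increase per subject, averaged
    across the cohort."""
    tidy = deadaptation_increase(table, impedance, duration, sample_rate)
    sds, amps, rmss = [], [], []
    for _, grp in tidy.groupby("subject_id"):
        f = fit_half_gaussian(grp["orientation"], grp["increase"])
        sds.append(f.sd)
        amps.append(f.amplitude)
        rmss.append(f.residual_rms)
    sds = np.asarray(sds)
    return GeneralizationFit(
        amplitude=float(np.mean(amps)),
        sd=float(np.mean(sds)),
        residual_rms=float(np.mean(rmss)),
        per_subject_sds=sds,
    )


def confidence_ellipse(vectors: np.ndarray, level: float = 0.99) -> EllipseSummary:
    """Covariance confidence ellipse of planar vectors at the given level
    (chi-square with 2 degrees of freedom)."""
    V = np.asarray(vectors, dtype=float)
    if V.ndim != 2 or V.shape[1] != 2 or V.shape[0] < 3:
        raise ValueError("need >= 3 planar vectors")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    center = V.mean(axis=0)
    cov = np.cov(V.T)
    evals, evecs = np.linalg.eigh(cov)
    degenerate = bool(evals.min() <= 1e-15 * max(evals.max(), 1.0))
    q = stats.chi2.ppf(level, df=2)
    axes = np.sqrt(np.maximum(evals, 0.0) * q)[::-1]  # descending
    major = evecs[:, -1]
    return EllipseSummary(
        center=center,
        axes=axes,
        angle=float(vec_to_bearing(major)),
        level=float(level),
        degenerate=degenerate,
    )


def exp1_summary(
    table: pd.DataFrame, n_perm: int = 2000, seed: Optional[int] = None
) -> pd.DataFrame:
    """Experiment-1 pipeline: per subject and rotation direction, the
    circular-mean anticipatory-force offset, the mean peak magnitude and
    the T-linear association between visual orientation and force
    direction."""
    clamps = table[table["condition"] == "error_clamp"]
    rows = []
    for (sid, d), grp in clamps.groupby(["subject_id", "rotation_direction"]):
        offs = anticipatory_offset(
            grp["peak_force_dir"].to_numpy(float),
            grp["visual_orientation"].to_numpy(float),
        )
        summ = circ_mean_sd(offs)
        assoc = circ_tlinear_assoc(
            grp["visual_orientation"].to_numpy(float),
            grp["peak_force_dir"].to_numpy(float),
            n_perm=n_perm,
            seed=seed,
        )
        rows.append(
            {
                "subject_id": sid,
                "rotation_direction": d,
                "mean_offset": summ.mean_angle,
                "offset_sd": summ.circular_sd,
                "mean_peak_force": float(grp["peak_force_mag"].mean()),
                "rho": assoc.rho,
                "rho_p": assoc.p_value,
                "n_trials": len(grp),
            }
        )
    return pd.DataFrame(rows)


def exp2_compensation_table(
    table: pd.DataFrame,
    rod_length: float = 0.3,
    duration: float = 0.7,
    sample_rate: float = 1000.0,
    body_mass: Optional[float] = None,
) -> pd.DataFrame:
    """Compensated object mass on Experiment-2 error-clamp trials, labelled
    by training (0 deg) vs transfer (-90 deg) orientation, as % of body
    mass when ``body_mass`` is given (otherwise kg)."""
    clamps = table[table["condition"] == "error_clamp"].copy()
    if clamps.empty:
        raise ValueError("no error-clamp trials in table")
    prof, _, unit_peak = _unit_loads(40.0, duration, sample_rate)
    comp_kg = clamps["peak_force_mag"].to_numpy(float) / (rod_length * unit_peak)
    true_kg = clamps["head_mass"].to_numpy(float)
    if body_mass:
        comp, true = 100.0 * comp_kg / body_mass, 100.0 * true_kg / body_mass
    else:
        comp, true = comp_kg, true_kg
    clamps["compensated_mass"] = comp
    clamps["true_mass"] = true
    clamps["orientation"] = np.where(
        np.isclose(wrap_deg(clamps["visual_orientation"].to_numpy(float)), 0.0),
        "training",
        "transfer",
    )
    return clamps[
        ["subject_id", "orientation", "true_mass", "compensated_mass", "block"]
    ]


def exp4_transfer_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Mean anticipatory force vectors at the training and -90 deg transfer
    orientations on Experiment-4 error-clamp trials, with the direction
    change and magnitude ratio between them (per subject)."""
    meta = table.attrs.get("metadata", {})
    train_vis = float(meta.get("train_visual", 0.0))
    clamps = table[(table["condition"] == "error_clamp")]
    rows = []
    # CCW and CW rotations mirror the force direction, so vectors are
    # averaged within rotation direction and the contrasts averaged after
    for (sid, d), grp in clamps.groupby(["subject_id", "rotation_direction"]):
        at_train = grp[np.isclose(wrap_deg(grp["visual_orientation"]), wrap_deg(train_vis))]
        at_transfer = grp[~np.isclose(wrap_deg(grp["visual_orientation"]), wrap_deg(train_vis))]
        if at_train.empty or at_transfer.empty:
            raise ValueError("missing training or transfer clamp trials")

        def mean_vec(g):
            return (
                g["peak_force_mag"].to_numpy(float)[:, None]
                * bearing_to_vec(g["peak_force_dir"].to_numpy(float))
            ).mean(axis=0)

        v_tr, v_tf = mean_vec(at_train), mean_vec(at_transfer)
        rows.append(
            {
                "subject_id": sid,
                "rotation_direction": d,
                "train_mag": float(np.linalg.norm(v_tr)),
                "transfer_mag": float(np.linalg.norm(v_tf)),
                "train_dir": float(vec_to_bearing(v_tr)),
                "transfer_dir": float(vec_to_bearing(v_tf)),
                "direction_change": float(
                    ang_diff_deg(vec_to_bearing(v_tf), vec_to_bearing(v_tr))
                ),
                "magnitude_ratio": float(
                    np.linalg.norm(v_tf) / np.linalg.norm(v_tr)
                ),
            }
        )
    per_dir = pd.DataFrame(rows)
    out = per_dir.groupby("subject_id", as_index=False).agg(
        train_mag=("train_mag", "mean"),
        transfer_mag=("transfer_mag", "mean"),
        direction_change=("direction_change", "mean"),
        magnitude_ratio=("magnitude_ratio", "mean"),
    )
    return out
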