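"""Synthetic dynamic-PET data with known ground truth.

Emulates the three-scan challenge design: per subject a baseline scan, a
post-amphetamine scan, and a post-amphetamine scan preceded by the study
drug, in two dose groups of five subjects.  The reference-region (cerebellar)
curve is generated by a one-tissue compartment model driven by a Feng
tri-exponential plasma input; target-region curves follow the SRTM forward
model with per-region kinetics, and frame noise follows the count-statistics
heuristic sigma ~ sqrt(C / duration).

The generator is purely generative: the input function and compartment
constants are never fitted anywhere downstream.  All randomness flows from
one seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .frames import FrameSchedule, TimeActivityCurve, STUDY_FRAME_DURATIONS
from .kinetics import SRTMParams, srtm_forward, _fine_grid, _exp_conv_fine, _frame_average
from .challenge import BPTable, SCANS, REGIONS

__all__ = [
    "RegionSpec",
    "SimConfig",
    "GroundTruth",
    "CohortData",
    "simulate_reference_tac",
    "simulate_target_tac",
    "simulate_cohort",
    "frame_noise_sigma",
    "add_frame_noise",
]

REFERENCE_LABEL = "Cer"

# Feng tri-exponential plasma input (arbitrary units, rates in 1/min):
# Cp(t) = (A1*t - A2 - A3) e^{-l1 t} + A2 e^{-l2 t} + A3 e^{-l3 t}
FENG_A = (851.1225, 21.8798, 20.8113)
FENG_L = (4.133859, 0.1190996, 0.01043449)


@dataclass(frozen=True)
class RegionSpec:
    """Generative kinetics of one target region.

    Baseline BP_ND is drawn per subject from N(base_mean, base_sd); the
    amphetamine effect dBP (percent) from a truncated normal; delivery
    ratio R1 and reference-scaled efflux k2 (1/min) are fixed.
    """

    base_mean: float
    base_sd: float
    dbp_mean: float
    dbp_sd: float
    r1: float = 0.9
    k2: float = 0.25


def _default_regions() -> dict:
    # baseline means/SDs and challenge effects at the magnitudes of the
    # clinical study (striatal BP_ND ~ 1-2.5, 16-28 % displacement)
    return {
        "Ca": RegionSpec(1.27, 0.37, 15.6, 5.7),
        "Pu": RegionSpec(2.08, 0.19, 21.6, 5.1),
        "VSt": RegionSpec(2.48, 0.19, 26.5, 7.7),
        "SN": RegionSpec(1.11, 0.19, 27.8, 10.9),
        "GP": RegionSpec(2.22, 0.26, 15.9, 7.7),
    }


def _default_ddbp() -> dict:
    # per dose group, per region: mean/SD of the attenuation ddBP (percent)
    return {
        "20 mg": {
            "Ca": (-4.2, 59.2),
            "Pu": (16.4, 11.3),
            "VSt": (13.8, 14.1),
            "SN": (25.6, 49.7),
            "GP": (-3.2, 19.7),
        },
        "40 mg": {
            "Ca": (24.8, 26.7),
            "Pu": (36.4, 7.7),
            "VSt": (22.6, 20.3),
            "SN": (40.8, 58.6),
            "GP": (66.6, 32.4),
        },
    }


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults emulate the clinical study: a 26-frame 90-min scan, five
    target regions with striatal-range baseline BP_ND, a cerebellar
    reference, two dose groups of five subjects, a 16-28 % amphetamine
    displacement and dose-dependent attenuation of that displacement.
    """

    frame_durations: tuple = STUDY_FRAME_DURATIONS
    regions: dict = field(default_factory=_default_regions)
    ddbp: dict = field(default_factory=_default_ddbp)
    n_per_group: dict = field(default_factory=lambda: {"20 mg": 5, "40 mg": 5})
    noise_scale: float = 0.2
    dbp_bounds: tuple = (-50.0, 80.0)
    ref_k1: float = 0.1      # mL/min/mL, reference-region uptake
    ref_k2: float = 0.35     # 1/min, reference-region clearance
    ref_peak: float = 30.0   # kBq/mL, target peak of the reference curve
    input_scale: float = 1.0  # multiplies the plasma input amplitude

    def __post_init__(self) -> None:
        for name, spec in self.regions.items():
            if spec.base_sd < 0 or spec.dbp_sd < 0:
                raise ValueError(f"negative SD in region spec {name!r}")
        for group, per_region in self.ddbp.items():
            for name, (_, sd) in per_region.items():
                if sd < 0:
                    raise ValueError(f"negative ddBP SD for {group}/{name}")
        for group, n in self.n_per_group.items():
            if n < 2:
                raise ValueError(f"need >= 2 subjects per group, got {n} for {group}")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be non-negative")

    @property
    def schedule(self) -> FrameSchedule:
        return FrameSchedule.from_durations(self.frame_durations)

    def to_yaml(self, path) -> None:
        payload = asdict(self)
        payload["regions"] = {k: asdict(v) for k, v in self.regions.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        payload["regions"] = {
            k: RegionSpec(**v) for k, v in payload.get("regions", {}).items()
        }
        payload["frame_durations"] = tuple(payload.get("frame_durations", STUDY_FRAME_DURATIONS))
        if "dbp_bounds" in payload:
            payload["dbp_bounds"] = tuple(payload["dbp_bounds"])
        payload["ddbp"] = {
            g: {r: tuple(v) for r, v in per.items()}
            for g, per in payload.get("ddbp", _default_ddbp()).items()
        }
        return cls(**payload)


@dataclass(frozen=True)
class GroundTruth:
    """True per-subject effects behind a simulated cohort.

    ``effects`` has one row per (subject, region) with the true baseline
    BP_ND, dBP^AMPH, dBP^AMPH+TAK and ddBP; ``bp`` is the true BP_ND table
    for all three scans.  The effects are exactly consistent with the
    challenge formulas applied to ``bp``.
    """

    bp: BPTable
    effects: "object"  # pandas.DataFrame


@dataclass(frozen=True)
class CohortData:
    """A simulated cohort: TACs, true BP table and ground truth."""

    tacs: dict  # (subject_id, scan) -> {region: TimeActivityCurve}, incl. "Cer"
    truth: BPTable
    ground_truth: GroundTruth
    config: SimConfig


# ---------------------------------------------------------------------------

def _feng_input(t: np.ndarray, scale: float) -> np.ndarray:
    a1, a2, a3 = FENG_A
    l1, l2, l3 = FENG_L
    cp = (a1 * t - a2 - a3) * np.exp(-l1 * t) + a2 * np.exp(-l2 * t) + a3 * np.exp(-l3 * t)
    return scale * np.maximum(cp, 0.0)


def simulate_reference_tac(
    config: SimConfig | None = None, seed=None
) -> TimeActivityCurve:
    """Noiseless cerebellar reference TAC on the configured schedule.

    One-tissue compartment response K1 * [Cp (x) exp(-k2 t)] to the Feng
    input, frame-averaged and scaled so the fine-grid curve peaks at
    ``config.ref_peak``.  Deterministic for a given config (``seed`` is
    accepted for API symmetry and unused).
    """
    config = config or SimConfig()
    schedule = config.schedule
    step = 0.02
    t = _fine_grid(schedule, step)
    cp = _feng_input(t, config.input_scale)
    cr_fine = config.ref_k1 * _exp_conv_fine(cp, config.ref_k2, step)
    peak = cr_fine.max()
    if peak > 0:
        cr_fine = cr_fine * (config.ref_peak / peak)
    activity = _frame_average(cr_fine, t, schedule)
    return TimeActivityCurve(schedule, activity, REFERENCE_LABEL)


def frame_noise_sigma(activity: np.ndarray, durations: np.ndarray, noise_scale: float) -> np.ndarray:
    """Count-statistics frame noise SD: noise_scale * sqrt(max(C,0)/duration)."""
    if noise_scale < 0:
        raise ValueError("noise_scale must be non-negative")
    return noise_scale * np.sqrt(np.maximum(np.asarray(activity, float), 0.0) / durations)


def add_frame_noise(
    tac: TimeActivityCurve, noise_scale: float, rng: np.random.Generator
) -> TimeActivityCurve:
    """Add zero-mean Gaussian frame noise with the count-statistics SD."""
    sigma = frame_noise_sigma(tac.activity, tac.schedule.duration, noise_scale)
    return tac.with_activity(tac.activity + rng.normal(0.0, 1.0, tac.activity.size) * sigma)


def simulate_target_tac(
    ref_tac: TimeActivityCurve,
    true_params: SRTMParams,
    noise_scale: float = 0.0,
    seed=None,
    region_label: str = "",
) -> TimeActivityCurve:
    """SRTM forward model plus optional count-statistics frame noise."""
    clean = srtm_forward(true_params, ref_tac, region_label=region_label)
    if noise_scale == 0:
        return clean
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return add_frame_noise(clean, noise_scale, rng)


def _truncated_normal(rng, mean, sd, lo, hi, max_tries=100):
    if sd == 0:
        if not (lo < mean < hi):
            raise ValueError(f"degenerate draw {mean} outside ({lo}, {hi})")
        return mean
    for _ in range(max_tries):
        x = rng.normal(mean, sd)
        if lo < x < hi:
            return x
    raise RuntimeError(
        f"could not draw a value in ({lo}, {hi}) from N({mean}, {sd}) in {max_tries} tries"
    )


def simulate_cohort(config: SimConfig | None = None, seed=0) -> CohortData:
    """Simulate a full three-scan cohort with known ground truth.

    For each subject: draw baseline BP_ND per region, an amphetamine
    displacement dBP per region and a dose-group attenuation ddBP per
    region (all truncated so implied displacements stay inside
    ``config.dbp_bounds``); invert the challenge formulas to get the true
    scan-2 and scan-3 BP_ND; emit noisy reference and target TACs for
    every scan.
    """
    import pandas as pd

    config = config or SimConfig()
    rng = np.random.default_rng(seed)
    ref_clean = simulate_reference_tac(config)
    lo, hi = config.dbp_bounds

    tacs = {}
    bp_records = []
    effect_rows = []
    subject_id = 0
    for group, n in config.n_per_group.items():
        for _ in range(n):
            subject_id += 1
            true_bp = {scan: {} for scan in SCANS}
            for region, spec in config.regions.items():
                base = _truncated_normal(rng, spec.base_mean, spec.base_sd, 0.05, np.inf)
                dbp = _truncated_normal(rng, spec.dbp_mean, spec.dbp_sd, lo, hi)
                dd_mean, dd_sd = config.ddbp[group][region]
                # accept ddBP only if the implied post-TAK displacement is in bounds
                for attempt in range(100):
                    ddbp = rng.normal(dd_mean, dd_sd) if dd_sd > 0 else dd_mean
                    dbp_tak = dbp * (1.0 - ddbp / 100.0)
                    if lo < dbp_tak < hi:
                        break
                else:
                    raise RuntimeError(
                        f"could not draw an admissible attenuation for {group}/{region}"
                    )
                bp_amph = base * (1.0 - dbp / 100.0)
                bp_tak = base * (1.0 - dbp_tak / 100.0)
                effect_rows.append(
                    {
                        "subject_id": subject_id,
                        "dose_group": group,
                        "region": region,
                        "bp_baseline": base,
                        "dbp_amph": dbp,
                        "dbp_amph_tak": dbp_tak,
                        "ddbp": ddbp,
                    }
                )
                for scan, bp in zip(SCANS, (base, bp_amph, bp_tak)):
                    if bp <= -1:
                        raise RuntimeError("drawn effects imply BP_ND <= -1")
                    true_bp[scan][region] = bp
                    bp_records.append(
                        {
                            "subject_id": subject_id,
                            "dose_group": group,
                            "scan": scan,
                            "region": region,
                            "bp_nd": bp,
                        }
                    )
            # emit the three scans' TACs
            for scan in SCANS:
                curves = {
                    REFERENCE_LABEL: add_frame_noise(ref_clean, config.noise_scale, rng)
                }
                for region, spec in config.regions.items():
                    params = SRTMParams.from_bp(spec.r1, spec.k2, true_bp[scan][region])
                    clean = srtm_forward(params, ref_clean, region_label=region)
                    curves[region] = add_frame_noise(clean, config.noise_scale, rng)
                tacs[(subject_id, scan)] = curves

    truth = BPTable(pd.DataFrame.from_records(bp_records))
    effects = pd.DataFrame.from_records(effect_rows)
    return CohortData(
        tacs=tacs,
        truth=truth,
        ground_truth=GroundTruth(bp=truth, effects=effects),
        config=config,
    )
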