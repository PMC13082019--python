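"""Ground-truth generators for every input the analysis pipeline consumes.

Each generator draws additive Gaussian noise around an exact forward-model
mean and returns the data container together with a machine-readable truth
record, so recovery tests always compare against the generating parameters
rather than hard-coded numbers. Generators are pure functions of
(config, seed): the same config yields bit-identical output.

Assay noise is homoscedastic Gaussian on the signal scale (constant
absolute spread, matching the roughly constant SEM bars such assays show on
a normalized % scale); a lognormal multiplicative option exists for raw
binding counts. Default designs and truth magnitudes follow the wild-type
receptor regime the package targets: agonist pEC50 near 9.8, radioligand
Kd near 4.7 nM, competitor logKi near -8.2, and an operational surface with
logKA -8.6, logKB -6.2, log(alpha) 1.6, log(beta) 0.3, tau_A 5, tau_B 0.3
on an 8x5 concentration grid with 3 replicates and SD 5 % points.

The trajectory generator emulates MD frame stacks as a template structure
plus per-atom Gaussian jitter, optional rigid displacement of a helix
segment over a frame window, and an optional per-frame forced polar-contact
schedule (contact "in" places the designated atom pair at 3.5 A, "out" at
6.0 A).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .assay_io import BindingIsotherm, DoseResponseSeries, ResponseSurface
from .curves import CompetitionParams, LogisticParams, SaturationParams, \
    competition_predict, logistic3_predict, saturation_predict
from .operational import OperationalParams, operational_effect
from .trajectory import FrameSet, SegmentSpec

__all__ = [
    "SimConfig",
    "TrajectorySimConfig",
    "SegmentEvent",
    "ContactSchedule",
    "simulate_assay",
    "simulate_trajectory",
    "make_synthetic_receptor",
    "preset",
    "PRESETS",
]


@dataclass
class SimConfig:
    """Assay simulation recipe: model, truth, design, noise, seed."""

    model: str  # logistic | saturation | competition | operational
    truth: dict
    design: dict = field(default_factory=dict)
    noise_sd: float = 0.0
    noise_kind: str = "gaussian"  # or "lognormal" (multiplicative, for counts)
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.model not in ("logistic", "saturation", "competition", "operational"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.noise_kind not in ("gaussian", "lognormal"):
            raise ValueError(f"unknown noise kind {self.noise_kind!r}")


def _default_design(model: str) -> dict:
    if model == "logistic":
        return {
            "concentrations": np.logspace(-11.5, -8.0, 8).tolist(),
            "n_replicates": 3,
            "include_vehicle": True,
        }
    if model == "saturation":
        return {
            "radioligand_concs": np.logspace(-10, -7.5, 8).tolist(),
            "n_replicates": 3,
        }
    if model == "competition":
        return {
            "competitor_concs": np.logspace(-10.5, -6.0, 10).tolist(),
            "n_replicates": 3,
            "include_vehicle": True,
        }
    # operational: 8 A-levels (vehicle + 7 spanning the potency window) x 5 B-levels
    return {
        "a_grid": [0.0] + np.logspace(-11.5, -8.5, 7).tolist(),
        "b_grid": [0.0, 1e-7, 3.16e-7, 1e-6, 3.16e-6],
        "n_replicates": 3,
    }


def _noise(rng: np.random.Generator, mean: np.ndarray, cfg: SimConfig) -> np.ndarray:
    if cfg.noise_sd == 0:
        return mean.copy()
    if cfg.noise_kind == "gaussian":
        return mean + rng.normal(0.0, cfg.noise_sd, size=mean.shape)
    # lognormal multiplicative: sd interpreted as sigma of log-scale factor
    return mean * rng.lognormal(0.0, cfg.noise_sd, size=mean.shape)


def simulate_assay(cfg: SimConfig):
    """Simulate one assay table from its forward model.

    Returns ``(container, truth_record)`` where the truth record serializes
    the generating parameters, design, noise level and seed.
    """
    design = {**_default_design(cfg.model), **cfg.design}
    rng = np.random.default_rng(cfg.seed)
    nrep = int(design.get("n_replicates", 3))

    if cfg.model == "logistic":
        p = LogisticParams(**cfg.truth)
        concs = np.asarray(design["concentrations"], float)
        if design.get("include_vehicle", True):
            concs = np.concatenate([[0.0], concs])
        conc = np.repeat(concs, nrep)
        mean = np.asarray(logistic3_predict(p, conc))
        sig = _noise(rng, mean, cfg)
        data = DoseResponseSeries(
            ligand_id=design.get("ligand", "agonist"),
            conc=conc,
            signal=sig,
            replicate=np.tile(np.arange(nrep), concs.size),
            is_vehicle=conc == 0.0,
        )
    elif cfg.model == "saturation":
        p = SaturationParams(**cfg.truth)
        concs = np.asarray(design["radioligand_concs"], float)
        conc = np.repeat(concs, nrep)
        mean = np.asarray(saturation_predict(p, conc))
        sig = _noise(rng, mean, cfg)
        data = BindingIsotherm(
            mode="saturation",
            radioligand_conc=conc,
            signal=sig,
            replicate=np.tile(np.arange(nrep), concs.size),
        )
    elif cfg.model == "competition":
        p = CompetitionParams(**cfg.truth)
        concs = np.asarray(design["competitor_concs"], float)
        if design.get("include_vehicle", True):
            concs = np.concatenate([[0.0], concs])
        conc = np.repeat(concs, nrep)
        mean = np.asarray(competition_predict(p, conc))
        sig = _noise(rng, mean, cfg)
        data = BindingIsotherm(
            mode="competition",
            radioligand_conc=p.radioligand_conc,
            competitor_conc=conc,
            signal=sig,
            replicate=np.tile(np.arange(nrep), concs.size),
            radioligand_kd=p.radioligand_kd,
        )
    else:  # operational surface
        p = OperationalParams(**cfg.truth)
        a_grid = np.asarray(design["a_grid"], float)
        b_grid = np.asarray(design["b_grid"], float)
        aa, bb = np.meshgrid(a_grid, b_grid, indexing="ij")
        a = np.repeat(aa.ravel(), nrep)
        b = np.repeat(bb.ravel(), nrep)
        mean = np.asarray(operational_effect(p, a, b))
        sig = _noise(rng, mean, cfg)
        data = ResponseSurface(
            ortho_ligand=design.get("ortho_ligand", "agonist"),
            allo_ligand=design.get("allo_ligand", "modulator"),
            conc_a=a,
            conc_b=b,
            signal=sig,
            replicate=np.tile(np.arange(nrep), aa.size),
        )

    truth = {
        "model": cfg.model,
        "params": dict(cfg.truth),
        "design": {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                   for k, v in design.items()},
        "noise_sd": cfg.noise_sd,
        "noise_kind": cfg.noise_kind,
        "seed": cfg.seed,
    }
    return data, truth


# ---------------------------------------------------------------------------
# Presets (magnitudes inspired by published wild-type/mutant regimes; these
# are generator parameters, not experimental data)
# ---------------------------------------------------------------------------

PRESETS: dict[str, SimConfig] = {
    # wild-type receptor, G-protein activation readout
    "wildtype_gtpgammaS": SimConfig(
        model="operational",
        truth=dict(emax=110.0, log_ka=-8.83, log_kb=-6.16, tau_a=5.0,
                   tau_b=0.3, log_alpha=1.62, log_beta=0.3, n=1.0),
        noise_sd=5.0,
        seed=0,
    ),
    # orthosteric-affinity-reduced, cooperativity-raised mutant regime
    "mutant_N362S": SimConfig(
        model="operational",
        truth=dict(emax=110.0, log_ka=-7.66, log_kb=-5.43, tau_a=5.0,
                   tau_b=0.3, log_alpha=2.75, log_beta=0.3, n=1.0),
        noise_sd=5.0,
        seed=0,
    ),
    # single-agonist curve at wild-type potency
    "wildtype_agonist_logistic": SimConfig(
        model="logistic",
        truth=dict(bottom=0.0, top=100.0, log_ec50=-9.83),
        noise_sd=5.0,
        seed=0,
    ),
    # radioligand saturation at wild-type affinity
    "wildtype_saturation": SimConfig(
        model="saturation",
        truth=dict(bmax=1000.0, kd=4.74e-9),
        noise_sd=20.0,
        seed=0,
    ),
    # agonist-vs-radioligand competition, modulator-free
    "wildtype_competition": SimConfig(
        model="competition",
        truth=dict(log_ki=-8.20, top=100.0, bottom=0.0,
                   radioligand_conc=4.74e-9, radioligand_kd=4.74e-9),
        noise_sd=3.0,
        seed=0,
    ),
}


def preset(name: str, **overrides) -> SimConfig:
    """A copy of a named preset with optional field overrides."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; have {sorted(PRESETS)}")
    base = PRESETS[name]
    cfg = SimConfig(
        model=base.model,
        truth=dict(base.truth),
        design=dict(base.design),
        noise_sd=base.noise_sd,
        noise_kind=base.noise_kind,
        seed=base.seed,
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


# ---------------------------------------------------------------------------
# Trajectory simulation
# ---------------------------------------------------------------------------


@dataclass
class SegmentEvent:
    """Rigid displacement of a residue segment over a frame window."""

    segment: SegmentSpec
    displacement: tuple[float, float, float]
    frame_range: tuple[int, int]  # [start, stop) in frame indices


@dataclass
class ContactSchedule:
    """Per-frame forced contact states for one residue pair.

    Frames where ``schedule`` is True place the designated polar atom of
    ``res_j`` exactly ``in_distance`` from that of ``res_i``; False frames
    use ``out_distance``.
    """

    res_i: int
    res_j: int
    schedule: np.ndarray  # bool per frame
    in_distance: float = 3.5
    out_distance: float = 6.0
    atom_name: str = "OG"


@dataclass
class TrajectorySimConfig:
    template: FrameSet  # single frame
    n_frames: int = 100
    n_replicates: int = 1
    jitter_sd: float = 0.0  # Angstrom, isotropic per atom
    segment_events: list[SegmentEvent] = field(default_factory=list)
    contact_schedule: ContactSchedule | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")
        for i, e1 in enumerate(self.segment_events):
            for e2 in self.segment_events[i + 1:]:
                frames_overlap = (e1.frame_range[0] < e2.frame_range[1]
                                  and e2.frame_range[0] < e1.frame_range[1])
                res_overlap = (e1.segment.start <= e2.segment.stop
                               and e2.segment.start <= e1.segment.stop)
                if frames_overlap and res_overlap:
                    raise ValueError(
                        f"overlapping segment events {e1.segment.name!r} and "
                        f"{e2.segment.name!r}"
                    )


def make_synthetic_receptor(
    n_residues: int = 40, n_helices: int = 1, seed: int = 0
) -> FrameSet:
    """A synthetic stand-in backbone for contact/displacement tests.

    Builds ``n_helices`` idealized straight helical segments of equal
    length, each residue carrying main-chain N, CA, C, O plus one polar
    sidechain oxygen (name OG). This is a geometric scaffold, not a real
    receptor structure.
    """
    rng = np.random.default_rng(seed)
    per = n_residues // n_helices
    rows, coords = [], []
    resid = 0
    for h in range(n_helices):
        # helices arranged on a circle, axis along z
        angle = 2 * np.pi * h / max(n_helices, 1)
        cx, cy = 12.0 * np.cos(angle), 12.0 * np.sin(angle)
        for k in range(per):
            resid += 1
            t = 100.0 * np.pi / 180.0 * k  # ~100 deg helical twist
            ca = np.array([cx + 2.3 * np.cos(t), cy + 2.3 * np.sin(t), 1.5 * k])
            n_at = ca + np.array([-0.7, 0.8, -0.6])
            c_at = ca + np.array([0.9, -0.6, 0.7])
            o_at = c_at + np.array([0.4, 0.9, 0.2])
            og = ca + np.array([1.4, 1.2, 0.3])
            for name, elem, xyz in (
                ("N", "N", n_at), ("CA", "C", ca), ("C", "C", c_at),
                ("O", "O", o_at), ("OG", "O", og),
            ):
                rows.append((name, elem, resid, "SER", "A"))
                coords.append(xyz)
    atoms = pd.DataFrame(rows, columns=["name", "element", "resid", "resname", "chain"])
    return FrameSet(np.asarray(coords)[None], atoms)


def simulate_trajectory(cfg: TrajectorySimConfig):
    """Simulate replicate frame stacks from a template structure.

    Per-frame coordinates are template + isotropic Gaussian jitter +
    scheduled rigid segment displacements; a forced contact schedule is
    applied last so scheduled distances are exact. Returns
    ``(frame_sets, truth_record)`` where ``frame_sets`` is a list with one
    FrameSet per replicate.
    """
    if cfg.template.n_frames != 1:
        raise ValueError("template must be a single frame")
    if cfg.template.n_atoms < 2:
        raise ValueError("template needs >= 2 atoms")
    rng = np.random.default_rng(cfg.seed)
    base = cfg.template.coords[0]
    atoms = cfg.template.atoms
    reps = []
    for r in range(cfg.n_replicates):
        coords = np.repeat(base[None], cfg.n_frames, axis=0)
        if cfg.jitter_sd > 0:
            coords = coords + rng.normal(0.0, cfg.jitter_sd, size=coords.shape)
        for ev in cfg.segment_events:
            m = (
                (atoms["resid"].to_numpy() >= ev.segment.start)
                & (atoms["resid"].to_numpy() <= ev.segment.stop)
            )
            if ev.segment.chain is not None:
                m &= atoms["chain"].to_numpy() == ev.segment.chain
            lo, hi = ev.frame_range
            coords[lo:hi, m] += np.asarray(ev.displacement, float)
        if cfg.contact_schedule is not None:
            cs = cfg.contact_schedule
            sched = np.asarray(cs.schedule, bool)
            if sched.size != cfg.n_frames:
                raise ValueError("contact schedule length must equal n_frames")
            sel_i = np.flatnonzero(
                (atoms["resid"].to_numpy() == cs.res_i)
                & (atoms["name"].to_numpy() == cs.atom_name)
            )
            sel_j = np.flatnonzero(
                (atoms["resid"].to_numpy() == cs.res_j)
                & (atoms["name"].to_numpy() == cs.atom_name)
            )
            if sel_i.size != 1 or sel_j.size != 1:
                raise ValueError("contact schedule atoms unresolvable")
            direction = np.array([1.0, 0.0, 0.0])
            for f in range(cfg.n_frames):
                d = cs.in_distance if sched[f] else cs.out_distance
                coords[f, sel_j[0]] = coords[f, sel_i[0]] + d * direction
        reps.append(
            FrameSet(coords, atoms.copy(), replicate_id=f"rep{r + 1}",
                     frame_spacing=cfg.template.frame_spacing)
        )
    truth = {
        "n_frames": cfg.n_frames,
        "n_replicates": cfg.n_replicates,
        "jitter_sd": cfg.jitter_sd,
        "segment_events": [
            {
                "segment": ev.segment.name,
                "residues": [ev.segment.start, ev.segment.stop],
                "displacement": list(ev.displacement),
                "frame_range": list(ev.frame_range),
            }
            for ev in cfg.segment_events
        ],
        "contact_schedule": (
            None if cfg.contact_schedule is None else {
                "res_i": cfg.contact_schedule.res_i,
                "res_j": cfg.contact_schedule.res_j,
                "n_in": int(np.asarray(cfg.contact_schedule.schedule).sum()),
            }
        ),
        "seed": cfg.seed,
    }
    return reps, truth
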