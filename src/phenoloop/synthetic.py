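"""Virtual dose-stress phenotyping experiments.

Generates studies with the statistical structure the downstream analysis
assumes: per-plant copper dose (uM CuSO4), logistic latent root/shoot growth
whose rate is inhibited dose-dependently after an amendment day, per-day
root-scan and three-view shoot pixel counts with multiplicative lognormal
observation noise, a saturating shoot-health decline with its own EC50 and
onset lag, harvest fresh weights proportional to final latent size, and
(optionally) small hyperspectral cubes mixing green/brown endmember spectra.

The model, informally::

    dS/dt = r * S * (1 - S/K) * I(d, t)
    I(d, t) = 1                      for t < t0
            = ramp to I_inf over lag for t0 <= t < t0 + lag
            = I_inf = 1/(1+(d/EC50)^hill)   afterwards

so inhibition acts on the growth *rate* (sizes diverge gradually after the
amendment, not instantaneously).  Per-plant biological variation enters as a
shared lognormal size multiplier, so pixel counts and fresh weights of the
same plant are correlated through their common latent size.

Ground truth (latent daily trajectories, the rate-level EC50 parameters and
the realized size-level EC50s) is carried on every study so that
parameter-recovery tests need no re-derivation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq

from .spectral import BandWindows, ndvi_pixel

__all__ = [
    "WAVELENGTH_GRID",
    "SimParams",
    "DoseDesign",
    "SyntheticStudy",
    "HyperspectralCube",
    "default_params",
    "simulate_experiment",
    "make_cube",
    "green_endmember",
    "brown_endmember",
    "save_cube",
    "load_cube",
]

#: Default reflectance wavelength grid (nm), restricted to the retained
#: 430-800 nm range, 5 nm spacing.
WAVELENGTH_GRID = np.arange(430.0, 801.0, 5.0)

SHOOT_VIEWS = ("shoot_top", "shoot_side", "shoot_front")
DEFAULT_SCHEDULE = (4, 6, 8, 10, 12, 14, 16, 18, 20, 22, 24, 25)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def green_endmember(wavelengths: np.ndarray = WAVELENGTH_GRID) -> np.ndarray:
    """Healthy-leaf reflectance: green bump at 550 nm, red-edge NIR plateau."""
    wl = np.asarray(wavelengths, dtype=float)
    r = (0.04
         + 0.06 * np.exp(-0.5 * ((wl - 550.0) / 25.0) ** 2)
         + 0.46 * _sigmoid((wl - 710.0) / 15.0))
    return np.clip(r, 0.0, 1.0)


def brown_endmember(wavelengths: np.ndarray = WAVELENGTH_GRID) -> np.ndarray:
    """Senescent-tissue reflectance: flat, slowly rising toward the NIR."""
    wl = np.asarray(wavelengths, dtype=float)
    r = 0.14 + 0.22 * _sigmoid((wl - 640.0) / 60.0)
    return np.clip(r, 0.0, 1.0)


@dataclass
class SimParams:
    """Generator parameters.  Units in field comments.

    The default parameterization mirrors the study's observed copper
    phenomenology: roots are the most sensitive phenotype (low EC50, short
    onset lag), shoot size intermediate, shoot health least sensitive, with
    the amendment on day 10 and imaging roughly every other day from day 4
    to day 25.
    """

    growth_rate: float = 0.35          # 1/day logistic rate
    k_root: float = 1.0                # latent carrying capacity, root
    k_shoot: float = 1.0               # latent carrying capacity, shoot
    s0_frac: float = 0.001             # initial size as a fraction of K
    ec50_root: float = 45.0            # uM, rate-level half inhibition
    ec50_shoot: float = 160.0          # uM
    ec50_health: float = 300.0         # uM
    hill_root: float = 2.2
    hill_shoot: float = 2.5
    hill_health: float = 3.0
    onset_lag_root: float = 1.0        # days, linear ramp of I after t0
    onset_lag_shoot: float = 3.0
    onset_lag_health: float = 5.0
    amendment_day: float = 10.0        # t0
    plant_cv: float = 0.15             # lognormal sd of per-plant size multiplier
    obs_noise_cv: float = 0.25         # lognormal sd of observation noise
    health_decline_tau: float = 4.0    # days, health decay time constant
    health_floor: float = 0.10         # asymptotic health at saturating dose
    baseline_health: float = 0.97
    health_plant_sd: float = 0.02      # per-plant baseline-health jitter
    health_obs_sd: float = 0.03        # per-view health observation noise
    ndvi_obs_sd: float = 0.02          # per-view NDVI observation noise
    weight_per_size_root: float = 0.12   # g per latent unit (a_root)
    weight_per_size_shoot: float = 0.30  # g per latent unit (a_shoot)
    root_gain: float = 50_000.0          # root-scan pixels per latent unit
    view_gains: tuple[float, float, float] = (30_000.0, 45_000.0, 40_000.0)
    schedule: tuple[int, ...] = DEFAULT_SCHEDULE
    wavelengths: np.ndarray = field(default_factory=lambda: WAVELENGTH_GRID.copy())
    endmember_green: np.ndarray | None = None
    endmember_brown: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.endmember_green is None:
            self.endmember_green = green_endmember(self.wavelengths)
        if self.endmember_brown is None:
            self.endmember_brown = brown_endmember(self.wavelengths)
        self.validate()

    def validate(self) -> None:
        if not (self.ec50_root < self.ec50_shoot < self.ec50_health):
            raise ValueError("sensitivity ordering requires ec50_root < ec50_shoot < ec50_health")
        positives = dict(
            growth_rate=self.growth_rate, k_root=self.k_root, k_shoot=self.k_shoot,
            s0_frac=self.s0_frac, root_gain=self.root_gain,
            weight_per_size_root=self.weight_per_size_root,
            weight_per_size_shoot=self.weight_per_size_shoot,
        )
        for name, value in positives.items():
            if value <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if any(g <= 0 for g in self.view_gains):
            raise ValueError("view gains must be strictly positive")
        if min(self.schedule) < 4 or max(self.schedule) > 25:
            raise ValueError("imaging schedule must lie within days [4, 25]")
        for name in ("plant_cv", "obs_noise_cv", "health_obs_sd", "ndvi_obs_sd",
                     "health_plant_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        for em in (self.endmember_green, self.endmember_brown):
            if np.any(em < 0) or np.any(em > 1):
                raise ValueError("endmember reflectance must lie in [0, 1]")

    # -- serialization ----------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        for key in ("wavelengths", "endmember_green", "endmember_brown"):
            d[key] = np.asarray(d[key]).tolist()
        d["view_gains"] = list(self.view_gains)
        d["schedule"] = list(self.schedule)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimParams":
        d = yaml.safe_load(Path(path).read_text())
        for key in ("wavelengths", "endmember_green", "endmember_brown"):
            if key in d and d[key] is not None:
                d[key] = np.asarray(d[key], dtype=float)
        if "view_gains" in d:
            d["view_gains"] = tuple(d["view_gains"])
        if "schedule" in d:
            d["schedule"] = tuple(d["schedule"])
        return cls(**d)


def default_params(**overrides) -> SimParams:
    """The documented default parameter set (see class docstring)."""
    return SimParams(**overrides)


@dataclass(frozen=True)
class DoseDesign:
    """One experimental round: list of (dose uM, n replicates) arms."""

    round_id: int
    arms: tuple[tuple[float, int], ...]

    def __post_init__(self) -> None:
        if not self.arms:
            raise ValueError("design needs at least one arm")
        for dose, n in self.arms:
            if dose < 0 or dose > 500:
                raise ValueError("doses must lie in [0, 500] uM")
            if n < 1:
                raise ValueError("replicate counts must be >= 1")

    @classmethod
    def round1(cls, n_replicates: int = 6) -> "DoseDesign":
        return cls(round_id=1,
                   arms=tuple((d, n_replicates) for d in (0, 25, 50, 100, 200, 300, 500)))


@dataclass
class SyntheticStudy:
    """Plants table, observations table and generating ground truth."""

    plants: pd.DataFrame
    observations: pd.DataFrame
    truth: dict

    def to_csv(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.plants.to_csv(outdir / "plants.csv", index=False)
        self.observations.to_csv(outdir / "observations.csv", index=False)


def _inhibition(dose: np.ndarray, t: float, ec50: float, hill: float,
                lag: float, t0: float) -> np.ndarray:
    """Rate multiplier I(d, t): 1 pre-amendment, linear ramp to the Hill asymptote."""
    dose = np.asarray(dose, dtype=float)
    i_inf = 1.0 / (1.0 + (dose / ec50) ** hill)
    if t < t0:
        return np.ones_like(i_inf)
    if lag > 0 and t < t0 + lag:
        frac = (t - t0) / lag
        return 1.0 + (i_inf - 1.0) * frac
    return i_inf


def latent_trajectory(doses, t_eval, params: SimParams, phenotype: str,
                      dt: float = 0.05) -> np.ndarray:
    """Noiseless latent size S(d, t) by RK4 integration of the logistic ODE.

    Returns an array of shape (len(doses), len(t_eval)).
    """
    doses = np.atleast_1d(np.asarray(doses, dtype=float))
    t_eval = np.asarray(t_eval, dtype=float)
    if phenotype == "root":
        K, ec50, hill, lag = params.k_root, params.ec50_root, params.hill_root, params.onset_lag_root
    elif phenotype == "shoot":
        K, ec50, hill, lag = (params.k_shoot, params.ec50_shoot, params.hill_shoot,
                              params.onset_lag_shoot)
    else:
        raise ValueError(f"unknown phenotype {phenotype!r}")
    r, t0 = params.growth_rate, params.amendment_day
    t_end = float(t_eval.max())
    n_steps = int(np.ceil(t_end / dt))
    ts = np.linspace(0.0, t_end, n_steps + 1)
    S = np.full(doses.shape, params.s0_frac * K)
    out = np.empty((doses.size, t_eval.size))
    # record via linear interpolation on the fine grid
    traj = np.empty((doses.size, ts.size))
    traj[:, 0] = S

    def f(s, t):  # noqa: ANN001
        return r * s * (1.0 - s / K) * _inhibition(doses, t, ec50, hill, lag, t0)

    h = ts[1] - ts[0]
    for i in range(n_steps):
        t = ts[i]
        k1 = f(S, t)
        k2 = f(S + 0.5 * h * k1, t + 0.5 * h)
        k3 = f(S + 0.5 * h * k2, t + 0.5 * h)
        k4 = f(S + h * k3, t + h)
        S = S + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        traj[:, i + 1] = S
    for j, tq in enumerate(t_eval):
        out[:, j] = [np.interp(tq, ts, traj[i]) for i in range(doses.size)]
    return out


def _health_curve(dose: float, t: np.ndarray, params: SimParams,
                  h0: float | np.ndarray | None = None) -> np.ndarray:
    """Saturating health-fraction decline with its own EC50 and onset lag."""
    t = np.asarray(t, dtype=float)
    if h0 is None:
        h0 = params.baseline_health
    frac = 1.0 / (1.0 + (dose / params.ec50_health) ** params.hill_health)
    h_inf = params.health_floor + (h0 - params.health_floor) * frac
    tau_start = params.amendment_day + params.onset_lag_health
    expo = np.maximum(0.0, t - tau_start) / params.health_decline_tau
    return h_inf + (h0 - h_inf) * np.exp(-expo)


def size_ec50(params: SimParams, phenotype: str, final_day: float = 25.0) -> float:
    """Dose at which the noiseless final latent size is 50% of the control's."""
    control = latent_trajectory([0.0], [final_day], params, phenotype)[0, 0]

    def rel(d):  # noqa: ANN001
        return latent_trajectory([d], [final_day], params, phenotype)[0, 0] / control - 0.5

    lo, hi = 1e-3, 2000.0
    if rel(hi) > 0:  # never reaches 50% inhibition in range
        return float("inf")
    return float(brentq(rel, lo, hi, xtol=1e-3))


def simulate_experiment(design: DoseDesign, params: SimParams | None = None,
                        seed: int = 0, dropout_rate: float = 0.0) -> SyntheticStudy:
    """Simulate one experimental round.

    Every plant gets, per scheduled imaging day, one root scan and three
    shoot views; harvest fresh weights are recorded for every plant.
    Identical (design, params, seed) yield identical studies.
    """
    params = params or default_params()
    rng = np.random.default_rng(seed)
    days = np.asarray(sorted(set(params.schedule)), dtype=float)
    doses = np.array([dose for dose, _ in design.arms], dtype=float)

    root_base = latent_trajectory(doses, days, params, "root")
    shoot_base = latent_trajectory(doses, days, params, "shoot")
    final_root = latent_trajectory(doses, [25.0], params, "root")[:, 0]
    final_shoot = latent_trajectory(doses, [25.0], params, "shoot")[:, 0]

    ndvi_green = ndvi_pixel(params.endmember_green, params.wavelengths)
    ndvi_brown = ndvi_pixel(params.endmember_brown, params.wavelengths)

    plants_rows, obs_rows = [], []
    truth_traj = []
    plant_idx = 0
    for arm_idx, (dose, n_rep) in enumerate(design.arms):
        for _ in range(n_rep):
            pid = f"r{design.round_id}_p{plant_idx:03d}"
            mult = float(np.exp(rng.normal(0.0, params.plant_cv)))
            h0 = float(np.clip(params.baseline_health
                               + rng.normal(0.0, params.health_plant_sd), 0.5, 1.0))
            h_true = _health_curve(dose, days, params, h0=h0)
            root_true = mult * root_base[arm_idx]
            shoot_true = mult * shoot_base[arm_idx]

            def _noisy(x, sd):  # noqa: ANN001 - multiplicative lognormal noise
                if sd == 0:
                    return np.asarray(x, dtype=float)
                return np.asarray(x, dtype=float) * np.exp(rng.normal(0.0, sd, np.shape(x)))

            root_px = _noisy(params.root_gain * root_true, params.obs_noise_cv)
            for di, day in enumerate(days):
                obs_rows.append(dict(plant_id=pid, round_id=design.round_id,
                                     dose_uM=dose, day=int(day), modality="root_scan",
                                     pixel_count=root_px[di],
                                     health_fraction=np.nan, mean_ndvi=np.nan))
                for view, gain in zip(SHOOT_VIEWS, params.view_gains):
                    px = float(_noisy(gain * shoot_true[di], params.obs_noise_cv))
                    hv = float(np.clip(h_true[di] + rng.normal(0.0, params.health_obs_sd),
                                       0.0, 1.0))
                    nd = float(ndvi_brown + (ndvi_green - ndvi_brown) * hv
                               + rng.normal(0.0, params.ndvi_obs_sd))
                    obs_rows.append(dict(plant_id=pid, round_id=design.round_id,
                                         dose_uM=dose, day=int(day), modality=view,
                                         pixel_count=px, health_fraction=hv,
                                         mean_ndvi=nd))
            fw_root = float(_noisy(params.weight_per_size_root * mult * final_root[arm_idx],
                                   params.obs_noise_cv))
            fw_shoot = float(_noisy(params.weight_per_size_shoot * mult * final_shoot[arm_idx],
                                    params.obs_noise_cv))
            excluded = bool(dropout_rate > 0 and rng.random() < dropout_rate)
            plants_rows.append(dict(plant_id=pid, round_id=design.round_id, dose_uM=dose,
                                    fw_root_g=fw_root, fw_shoot_g=fw_shoot,
                                    excluded=excluded,
                                    reason="synthetic dropout (imaging artifact)" if excluded else ""))
            truth_traj.append(pd.DataFrame(dict(
                plant_id=pid, day=days.astype(int), latent_root=root_true,
                latent_shoot=shoot_true, health=h_true)))
            plant_idx += 1

    truth = dict(
        params=params,
        multipliers=None,
        ec50_rate=dict(root=params.ec50_root, shoot=params.ec50_shoot,
                       health=params.ec50_health),
        ec50_size=dict(root=size_ec50(params, "root"), shoot=size_ec50(params, "shoot")),
        trajectories=pd.concat(truth_traj, ignore_index=True),
    )
    return SyntheticStudy(plants=pd.DataFrame(plants_rows),
                          observations=pd.DataFrame(obs_rows), truth=truth)


# ---------------------------------------------------------------------------
# Hyperspectral cube fixtures
# ---------------------------------------------------------------------------

@dataclass
class HyperspectralCube:
    """Band-sequential reflectance cube with wavelength grid and plant mask."""

    data: np.ndarray          # (rows, cols, bands)
    wavelengths: np.ndarray   # (bands,) nm
    mask: np.ndarray          # (rows, cols) bool


def make_cube(n_rows: int, n_cols: int, green_fraction: float,
              params: SimParams | None = None, seed: int = 0,
              noise_sd: float = 0.01,
              mask: np.ndarray | None = None) -> HyperspectralCube:
    """Two-endmember cube: in-mask pixels are green (w=1) or brown (w=0).

    The number of green pixels is round(green_fraction * n_in_mask) exactly;
    Gaussian reflectance noise of sd ``noise_sd`` is added and clipped at 0.
    """
    if not 0.0 <= green_fraction <= 1.0:
        raise ValueError("green_fraction must lie in [0, 1]")
    params = params or default_params()
    rng = np.random.default_rng(seed)
    if mask is None:
        mask = np.ones((n_rows, n_cols), dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (n_rows, n_cols):
        raise ValueError("mask shape must be (n_rows, n_cols)")
    n_in = int(mask.sum())
    if n_in == 0:
        raise ValueError("empty mask")
    n_bands = params.wavelengths.size
    n_green = int(round(green_fraction * n_in))
    w = np.zeros(n_in)
    w[rng.permutation(n_in)[:n_green]] = 1.0
    spectra = (w[:, None] * params.endmember_green[None, :]
               + (1.0 - w[:, None]) * params.endmember_brown[None, :])
    if noise_sd > 0:
        spectra = np.clip(spectra + rng.normal(0.0, noise_sd, spectra.shape), 0.0, None)
    data = np.zeros((n_rows, n_cols, n_bands))
    data[mask] = spectra
    return HyperspectralCube(data=data, wavelengths=params.wavelengths.copy(), mask=mask)


def save_cube(cube: HyperspectralCube, prefix: str | Path) -> None:
    """Write a raw band-sequential float32 file plus a JSON sidecar."""
    prefix = Path(prefix)
    arr = np.ascontiguousarray(np.moveaxis(cube.data, -1, 0), dtype="<f4")  # BSQ
    arr.tofile(prefix.with_suffix(".bsq"))
    sidecar = dict(rows=int(cube.data.shape[0]), cols=int(cube.data.shape[1]),
                   bands=int(cube.data.shape[2]), interleave="bsq", dtype="float32",
                   wavelengths=cube.wavelengths.tolist(),
                   mask=cube.mask.astype(int).tolist())
    prefix.with_suffix(".json").write_text(json.dumps(sidecar))


def load_cube(prefix: str | Path) -> HyperspectralCube:
    """Read a cube written by :func:`save_cube`, or an ENVI-style pair.

    An ENVI-style header (``.hdr`` with ``samples/lines/bands/wavelength``
    fields, BSQ interleave, float32) next to the binary file is accepted when
    no JSON sidecar exists.
    """
    prefix = Path(prefix)
    json_path = prefix.with_suffix(".json")
    if json_path.exists():
        meta = json.loads(json_path.read_text())
        rows, cols, bands = meta["rows"], meta["cols"], meta["bands"]
        wavelengths = np.asarray(meta["wavelengths"], dtype=float)
        mask = np.asarray(meta["mask"], dtype=bool)
    else:
        hdr_path = prefix.with_suffix(".hdr")
        if not hdr_path.exists():
            raise FileNotFoundError(f"no JSON sidecar or ENVI header for {prefix}")
        meta = _parse_envi_header(hdr_path.read_text())
        rows, cols, bands = meta["lines"], meta["samples"], meta["bands"]
        wavelengths = np.asarray(meta["wavelength"], dtype=float)
        mask = np.ones((rows, cols), dtype=bool)
    raw = np.fromfile(prefix.with_suffix(".bsq"), dtype="<f4")
    data = np.moveaxis(raw.reshape(bands, rows, cols), 0, -1).astype(float)
    return HyperspectralCube(data=data, wavelengths=wavelengths, mask=mask)


def _parse_envi_header(text: str) -> dict:
    meta: dict = {}
    body = text.replace("\r", "")
    # fold braced multi-line values
    import re

    for m in re.finditer(r"(\w[\w ]*?)\s*=\s*(\{[^}]*\}|[^\n]*)", body):
        key = m.group(1).strip().lower()
        val = m.group(2).strip()
        if val.startswith("{"):
            items = [v.strip() for v in val[1:-1].split(",") if v.strip()]
            meta[key] = [float(v) for v in items]
        else:
            try:
                meta[key] = int(val)
            except ValueError:
                meta[key] = val
    return meta
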