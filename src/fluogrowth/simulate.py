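"""Mechanistic synthetic-data generator for the whole pipeline.

The generator produces plate-reader experiments (multi-channel
:class:`~fluogrowth.platedata.PlateTimeSeries` with ground truth), CFU
samples, and microscopy image pairs, so every analysis stage can be
exercised — and validated against known truth — without instrument data.

Growth model (per condition, shared well):

    dX_i/dt = r_i X_i (1 - sum_j alpha_ij X_j / K) - delta_i X_i [exhausted_i]

a Lotka–Volterra competitive logistic: ``K`` is the carrying capacity set by
the nutrient strength, ``alpha`` the competition-coefficient matrix
(``alpha_ii = 1``), and ``delta`` a lysis rate that removes biomass only
after strain *i* perceives resource exhaustion (its weighted load reaches
0.99 K, a latched switch — consumed resources do not return).

Reporter model (two-stage maturation):

    dD_i/dt = s_i X+_i - m_i D_i        (dark, immature fluorophore)
    dF_i/dt = m_i D_i                   (mature, detected signal)

``X+`` is the production biomass: identical to ``X`` until exhaustion and
held at its exhaustion value afterwards, so the fluorescence signal persists
— and keeps maturing — through the optical-density decline caused by lysis.
This reproduces the characteristic phenomenology: fluorescence lags OD
(maturation), and late-phase OD drops while fluorescence stays stable.

Measurement model: OD reads are ``od_blank + total biomass x (1 + od_cv e)``
and fluorescence reads ``autofluorescence + F x (1 + fluo_cv e)`` with
standard-normal ``e`` from one seeded generator; OD noise exceeds
fluorescence noise by default.  CFU samples are
``round(conversion x X x lognormal error)``.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage as ndi

from .errors import ConfigurationError, IntegrationError, PlacementError
from .imaging import MicroscopyImage
from .platedata import ChannelDef, PlateLayout, PlateTimeSeries, WellSpec

__all__ = [
    "CompetitionSim",
    "NoiseSim",
    "StrainSim",
    "Trajectories",
    "competition_design",
    "default_params",
    "dilution_series_design",
    "isogenic_competition_design",
    "models_from_params",
    "simulate_competition",
    "simulate_image_pair",
    "simulate_plate",
]

EXHAUSTION_FRACTION = 0.99  # load/K at which a strain perceives exhaustion
MAX_STEP_H = 0.01           # RK4 fixed step cap

DEFAULT_STRENGTHS = (0.0, 0.017, 0.034, 0.0675, 0.125, 0.25,
                     0.5, 0.6, 0.7, 0.8, 0.9, 1.0)


def default_params() -> dict:
    """The versioned default parameter set (see ``defaults.yaml``)."""
    text = (
        importlib.resources.files("fluogrowth").joinpath("defaults.yaml").read_text()
    )
    return yaml.safe_load(text)


@dataclass
class StrainSim:
    """One strain's growth and reporter parameters."""

    name: str
    r: float = 1.0               # h^-1
    x0: float = 0.005            # OD-equivalent
    s: float = 2300.0            # A.U. OD^-1 h^-1
    m: float = 0.5               # h^-1
    reporter_channel: str | None = None
    lysis_rate: float = 0.0      # h^-1, post-exhaustion only

    def __post_init__(self):
        if min(self.r, self.x0, self.s, self.m, self.lysis_rate) < 0:
            raise ConfigurationError(f"strain {self.name!r}: negative parameter")


@dataclass
class CompetitionSim:
    """Strains sharing one well: carrying capacity and competition matrix."""

    strains: list[StrainSim]
    K: float = 1.2
    alpha: np.ndarray | None = None     # defaults to all-ones

    def __post_init__(self):
        n = len(self.strains)
        if self.K < 0:
            raise ConfigurationError("K must be non-negative")
        self.alpha = (
            np.ones((n, n)) if self.alpha is None else np.asarray(self.alpha, float)
        )
        if self.alpha.shape != (n, n) or np.any(self.alpha < 0):
            raise ConfigurationError("alpha must be a non-negative n x n matrix")


@dataclass
class NoiseSim:
    """Measurement-noise model; all randomness flows from ``rng_seed``."""

    od_cv: float = 0.05
    fluo_cv: float = 0.01
    blank_autofluorescence: dict[str, float] = field(default_factory=dict)
    od_blank: float = 0.04
    rng_seed: int = 0

    def __post_init__(self):
        if self.od_cv < 0 or self.fluo_cv < 0:
            raise ConfigurationError("noise cvs must be non-negative")


@dataclass
class Trajectories:
    """Ground-truth trajectories of one condition, one row per strain."""

    times_h: np.ndarray
    strain_names: list[str]
    X: np.ndarray    # biomass (lysis applies)
    Xp: np.ndarray   # production biomass (held through lysis)
    D: np.ndarray    # dark fluorophore pool
    F: np.ndarray    # mature fluorescence signal

    def strain_index(self, name: str) -> int:
        return self.strain_names.index(name)

    def total_biomass(self) -> np.ndarray:
        return self.X.sum(axis=0)


def simulate_competition(model: CompetitionSim, t_grid) -> Trajectories:
    """Integrate the competition + maturation ODEs onto ``t_grid``.

    Classical fixed-step RK4 with step ``min(0.01 h, grid spacing)``;
    the exhaustion switch is latched between steps.  Raises
    :class:`IntegrationError` on a non-finite state.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 2 or t_grid[0] != 0 or np.any(
        np.diff(t_grid) <= 0
    ):
        raise ConfigurationError("t_grid must be strictly increasing from 0")
    n = len(model.strains)
    r = np.array([s.r for s in model.strains])
    x0 = np.array([s.x0 for s in model.strains])
    s_prod = np.array([s.s for s in model.strains])
    m_mat = np.array([s.m for s in model.strains])
    delta = np.array([s.lysis_rate for s in model.strains])
    alpha, K = model.alpha, model.K

    def deriv(state, exhausted):
        X, Xp, D, F = state
        if K > 0:
            gf = 1.0 - (alpha @ np.maximum(X, 0.0)) / K
        else:
            gf = np.zeros(n)
        dX = r * X * gf - delta * X * exhausted
        dXp = np.where(exhausted, 0.0, r * Xp * gf)
        dD = s_prod * Xp - m_mat * D
        dF = m_mat * D
        return np.stack([dX, dXp, dD, dF])

    state = np.stack([x0, x0, np.zeros(n), np.zeros(n)])
    exhausted = (
        np.ones(n, dtype=bool) if K <= 0
        else (alpha @ x0) >= EXHAUSTION_FRACTION * K
    )
    h_base = min(MAX_STEP_H, float(np.min(np.diff(t_grid))))
    out = np.empty((4, n, len(t_grid)))
    out[:, :, 0] = state
    for k in range(len(t_grid) - 1):
        dt = t_grid[k + 1] - t_grid[k]
        n_sub = max(1, int(np.ceil(dt / h_base - 1e-12)))
        h = dt / n_sub
        for _ in range(n_sub):
            ex = exhausted.astype(float)
            k1 = deriv(state, ex)
            k2 = deriv(state + 0.5 * h * k1, ex)
            k3 = deriv(state + 0.5 * h * k2, ex)
            k4 = deriv(state + h * k3, ex)
            state = state + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            if K > 0:
                exhausted |= (alpha @ state[0]) >= EXHAUSTION_FRACTION * K
        if not np.all(np.isfinite(state)):
            raise IntegrationError(
                f"non-finite state at t={t_grid[k + 1]:.3f} h"
            )
        out[:, :, k + 1] = state
    return Trajectories(
        times_h=t_grid,
        strain_names=[s.name for s in model.strains],
        X=out[0], Xp=out[1], D=out[2], F=out[3],
    )


def simulate_plate(
    layout: PlateLayout,
    models: dict[str, CompetitionSim],
    noise: NoiseSim,
    t_grid,
    cfu_times=None,
    cfu_conversion: float = 8.0e8,
    cfu_sigma: float = 0.1,
):
    """Simulate one plate: reads per channel, ground truth, optional CFU.

    ``models`` maps each sample-well condition label to its
    :class:`CompetitionSim`.  Every distinct condition is integrated once;
    the same seed gives bit-identical output.  Returns
    ``(PlateTimeSeries, {condition: Trajectories}, cfu DataFrame or None)``.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    rng = np.random.default_rng(noise.rng_seed)
    conditions = sorted(
        {spec.condition for spec in layout.wells.values() if spec.role == "sample"}
    )
    missing = [c for c in conditions if c not in models]
    if missing:
        raise ConfigurationError(f"no model for condition(s) {missing}")
    truth = {c: simulate_competition(models[c], t_grid) for c in conditions}

    wells = list(layout.wells)
    T = len(t_grid)
    channel_names = [c.name for c in layout.channels]
    data = {name: np.zeros((len(wells), T)) for name in channel_names}
    for i, well in enumerate(wells):
        spec = layout.wells[well]
        traj = truth[spec.condition] if spec.role == "sample" else None
        for cdef in layout.channels:
            eps = rng.standard_normal(T)
            if cdef.kind == "absorbance":
                cv, baseline = noise.od_cv, noise.od_blank
                signal = traj.total_biomass() if traj is not None else None
            else:
                cv = noise.fluo_cv
                baseline = noise.blank_autofluorescence.get(cdef.name, 0.0)
                if traj is not None:
                    idx = [
                        traj.strain_index(n)
                        for n, ch in _model_reporters(models[spec.condition])
                        if ch == cdef.name
                    ]
                    signal = traj.F[idx].sum(axis=0) if idx else np.zeros(T)
                else:
                    signal = None
            if spec.role == "sample":
                read = baseline + signal * (1.0 + cv * eps)
            elif spec.role == "blank":
                read = baseline * (1.0 + cv * eps)
            else:  # empty well: nothing to read
                read = np.zeros(T)
            data[cdef.name][i] = read

    ts = PlateTimeSeries(
        times_h=t_grid, wells=wells, data=data, layout_ref=layout.plate_id
    )

    cfu = None
    if cfu_times is not None:
        rows = []
        for well in wells:
            spec = layout.wells[well]
            if spec.role != "sample":
                continue
            traj = truth[spec.condition]
            for t_req in np.asarray(cfu_times, dtype=float):
                k = int(np.argmin(np.abs(t_grid - t_req)))
                for j, name in enumerate(traj.strain_names):
                    err = np.exp(
                        rng.standard_normal() * cfu_sigma - cfu_sigma**2 / 2
                    )
                    rows.append(
                        {
                            "well": well,
                            "condition": spec.condition,
                            "strain": name,
                            "time_h": float(t_grid[k]),
                            "cfu": float(np.round(cfu_conversion * traj.X[j, k] * err)),
                            "true_biomass": float(traj.X[j, k]),
                        }
                    )
        cfu = pd.DataFrame(rows)
    return ts, truth, cfu


def _model_reporters(model: CompetitionSim):
    return [(s.name, s.reporter_channel) for s in model.strains]


# ---------------------------------------------------------------------------
# experiment-design builders


def _noise_from_params(params: dict, seed: int) -> NoiseSim:
    n = params["noise"]
    return NoiseSim(
        od_cv=float(n["od_cv"]),
        fluo_cv=float(n["fluo_cv"]),
        blank_autofluorescence={
            k: float(v) for k, v in n.get("blank_autofluorescence", {}).items()
        },
        od_blank=float(n["od_blank"]),
        rng_seed=seed,
    )


def _strain_from_params(name, channel, params, **overrides) -> StrainSim:
    p = dict(params["strain"])
    p.update(overrides)
    return StrainSim(
        name=name,
        r=float(p["r"]),
        x0=float(p["x0"]),
        s=float(p["s"]),
        m=float(p["m"]),
        reporter_channel=channel,
        lysis_rate=float(p["lysis_rate"]),
    )


def _standard_channels(fluo=("red",)) -> list[ChannelDef]:
    bands = {
        "red": ((567.0, 587.0), (613.0, 626.0)),
        "yellow": ((475.0, 492.0), (511.0, 550.0)),
        "green": ((475.0, 492.0), (511.0, 550.0)),
    }
    channels = [ChannelDef(name="OD600", kind="absorbance")]
    for name in fluo:
        ex, em = bands[name]
        channels.append(
            ChannelDef(name=name, kind="fluorescence", excitation_nm=ex, emission_nm=em)
        )
    return channels


def dilution_series_design(
    strengths=DEFAULT_STRENGTHS,
    n_replicates: int = 4,
    strain_name: str = "Pe_red",
    channel: str = "red",
    seed: int = 0,
    params: dict | None = None,
    n_blanks: int = 4,
):
    """Nutrient-broth dilution series: K proportional to medium strength.

    One condition per strength (``"NB <percent>%"``), ``n_replicates`` wells
    each, plus medium blanks in row H.  Returns ``(layout, models, noise)``.
    """
    params = params or default_params()
    K_full = float(params["K"])
    wells: dict[str, WellSpec] = {}
    models: dict[str, CompetitionSim] = {}
    rows = "ABCDEFG"
    for i, strength in enumerate(strengths):
        condition = f"NB {100 * strength:g}%"
        models[condition] = CompetitionSim(
            strains=[_strain_from_params(strain_name, channel, params)],
            K=K_full * float(strength),
        )
        for j in range(n_replicates):
            idx = i * n_replicates + j
            well = f"{rows[idx // 12]}{idx % 12 + 1}"
            wells[well] = WellSpec(
                role="sample",
                strains=[(strain_name, channel)],
                medium=condition,
                condition=condition,
                replicate_group=f"rep{j + 1}",
            )
    for b in range(n_blanks):
        wells[f"H{b + 1}"] = WellSpec(role="blank", medium="NB")
    layout = PlateLayout(
        plate_id="dilution_series",
        wells=wells,
        channels=_standard_channels((channel,)),
    )
    return layout, models, _noise_from_params(params, seed)


def competition_design(
    focal: StrainSim,
    competitor: StrainSim,
    K: float | None = None,
    alpha=None,
    n_monoculture: int = 10,
    n_coculture: int = 10,
    seed: int = 0,
    params: dict | None = None,
    n_blanks: int = 4,
):
    """1:1 competition assay: focal monoculture vs focal + competitor.

    Conditions are ``"monoculture"`` (focal alone) and ``"vs <competitor>"``
    (both strains, sharing the resource through ``alpha``).  The focal
    inoculum is the same in both conditions, as in a paired assay.
    Returns ``(layout, models, noise)``.
    """
    params = params or default_params()
    K = float(params["K"]) if K is None else float(K)
    co_condition = f"vs {competitor.name}"
    models = {
        "monoculture": CompetitionSim(strains=[focal], K=K),
        co_condition: CompetitionSim(
            strains=[focal, competitor], K=K, alpha=alpha
        ),
    }
    wells: dict[str, WellSpec] = {}
    for j in range(n_monoculture):
        wells[f"{'ABCDEFG'[j // 12]}{j % 12 + 1}"] = WellSpec(
            role="sample",
            strains=[(focal.name, focal.reporter_channel)],
            medium="NB",
            condition="monoculture",
            replicate_group=f"rep{j + 1}",
        )
    offset = 12 * (1 + (n_monoculture - 1) // 12)
    for j in range(n_coculture):
        idx = offset + j
        wells[f"{'ABCDEFG'[idx // 12]}{idx % 12 + 1}"] = WellSpec(
            role="sample",
            strains=[
                (focal.name, focal.reporter_channel),
                (competitor.name, competitor.reporter_channel),
            ],
            medium="NB",
            condition=co_condition,
            replicate_group=f"rep{j + 1}",
        )
    for b in range(n_blanks):
        wells[f"H{b + 1}"] = WellSpec(role="blank", medium="NB")
    fluo = [
        ch for ch in (focal.reporter_channel, competitor.reporter_channel) if ch
    ]
    layout = PlateLayout(
        plate_id=f"competition_{focal.name}_{competitor.name}",
        wells=wells,
        channels=_standard_channels(tuple(dict.fromkeys(fluo))),
    )
    return layout, models, _noise_from_params(params, seed)


def isogenic_competition_design(
    n_monoculture: int = 10,
    n_coculture: int = 10,
    seed: int = 0,
    params: dict | None = None,
):
    """Fluorescent strain vs untagged isogenic wild type (alpha = 1).

    Both strains share every growth parameter; only the focal carries a
    reporter.  The textbook expectation is a relative AUC near 0.5: the two
    strains split the shared resource evenly.
    """
    params = params or default_params()
    focal = _strain_from_params("Pe_red", "red", params)
    wt = _strain_from_params("PeWT", None, params)
    return competition_design(
        focal,
        wt,
        n_monoculture=n_monoculture,
        n_coculture=n_coculture,
        seed=seed,
        params=params,
    )


def models_from_params(doc: dict) -> dict[str, CompetitionSim]:
    """Build condition models from a simulation-parameters document.

    Expected shape::

        conditions:
          monoculture:
            K: 1.2
            alpha: [[1.0]]        # optional, defaults to all ones
            strains:
              - {name: Pe_red, channel: red, r: 1.0, x0: 0.005,
                 s: 2300.0, m: 0.5, lysis_rate: 0.0}
    """
    defaults = default_params()["strain"]
    models = {}
    for condition, spec in doc.get("conditions", {}).items():
        strains = []
        for s in spec["strains"]:
            p = dict(defaults)
            p.update({k: v for k, v in s.items() if k not in ("name", "channel")})
            strains.append(
                StrainSim(
                    name=str(s["name"]),
                    r=float(p["r"]),
                    x0=float(p["x0"]),
                    s=float(p["s"]),
                    m=float(p["m"]),
                    reporter_channel=s.get("channel"),
                    lysis_rate=float(p["lysis_rate"]),
                )
            )
        models[str(condition)] = CompetitionSim(
            strains=strains,
            K=float(spec.get("K", default_params()["K"])),
            alpha=spec.get("alpha"),
        )
    return models


# ---------------------------------------------------------------------------
# microscopy fixture generator


def simulate_image_pair(
    n_cells: int = 20,
    shape: tuple[int, int] = (400, 400),
    pixel_size_um: float = 0.1,
    seed: int = 0,
    exposure_ms: float = 400.0,
    reference_exposure_ms: float = 400.0,
    area_range_um2: tuple[float, float] = (0.9, 1.9),
    intensity_range: tuple[float, float] = (400.0, 2000.0),
    phase_background: float = 200.0,
    phase_cell: float = 60.0,
    fluo_background: float = 100.0,
    noise_sd: float = 2.0,
    border_margin_px: int = 5,
    max_tries: int = 5000,
):
    """Synthetic phase + fluorescence pair with per-cell ground truth.

    Plants ``n_cells`` non-overlapping ellipses (dark on the bright phase
    background) with areas in ``area_range_um2`` and uniform per-cell
    fluorescence drawn from ``intensity_range`` (defined at the reference
    exposure; the image is scaled by ``exposure_ms / reference_exposure_ms``
    to emulate linear exposure response).  Gaussian read noise is added to
    both rasters.  Returns ``(MicroscopyImage, ground-truth DataFrame)``
    with rows ordered like the raster-scan labels of ``segment_cells``.
    """
    rng = np.random.default_rng(seed)
    H, W = shape
    occupied = np.zeros(shape, dtype=bool)
    forbidden = np.zeros(shape, dtype=bool)
    yy, xx = np.mgrid[0:H, 0:W]
    phase = np.full(shape, phase_background, dtype=float)
    fluo = np.full(shape, fluo_background, dtype=float)
    records = []
    tries = 0
    placed = 0
    while placed < n_cells:
        if tries >= max_tries:
            raise PlacementError(
                f"placed only {placed}/{n_cells} cells in {max_tries} tries"
            )
        tries += 1
        area_um2 = rng.uniform(*area_range_um2)
        area_px = area_um2 / pixel_size_um**2
        q = rng.uniform(1.2, 2.2)                 # major/minor axis ratio
        b = np.sqrt(area_px / (np.pi * q))
        a = q * b
        theta = rng.uniform(0, np.pi)
        pad = int(np.ceil(a)) + border_margin_px
        if 2 * pad >= min(H, W):
            continue
        cy = rng.uniform(pad, H - 1 - pad)
        cx = rng.uniform(pad, W - 1 - pad)
        dy, dx = yy - cy, xx - cx
        u = dx * np.cos(theta) + dy * np.sin(theta)
        v = -dx * np.sin(theta) + dy * np.cos(theta)
        mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        if not mask.any() or (mask & forbidden).any():
            continue
        intensity = rng.uniform(*intensity_range)
        phase[mask] = phase_cell
        fluo[mask] = fluo_background + intensity
        occupied |= mask
        # keep an exclusion zone so neighbours never touch or merge
        forbidden |= ndi.binary_dilation(mask, iterations=3)
        first_px = int(np.flatnonzero(mask.ravel())[0])
        records.append(
            {
                "area_um2": float(mask.sum() * pixel_size_um**2),
                "centroid_row": float(yy[mask].mean()),
                "centroid_col": float(xx[mask].mean()),
                "mean_intensity": float(intensity),
                "_first_px": first_px,
            }
        )
        placed += 1
    scale = exposure_ms / reference_exposure_ms
    phase = phase + rng.standard_normal(shape) * noise_sd
    fluo = fluo * scale + rng.standard_normal(shape) * noise_sd
    truth = (
        pd.DataFrame(records)
        .sort_values("_first_px", kind="stable")
        .drop(columns="_first_px")
        .reset_index(drop=True)
    )
    truth.insert(0, "label", np.arange(1, len(truth) + 1))
    image = MicroscopyImage(
        phase=np.clip(phase, 0, None),
        fluorescence=np.clip(fluo, 0, None),
        pixel_size_um=pixel_size_um,
        exposure_ms=exposure_ms,
    )
    return image, truth
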