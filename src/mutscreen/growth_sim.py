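"""Two-subpopulation logistic simulator of mutator cultures under drug selection.

A batch culture of a mismatch-repair-deficient (mutator) strain inoculated
into drug contains a standing minority of resistant mutants.  Resistant cells
grow toward a shared carrying capacity while sensitive cells stall or die, so
the optical density trace shows a *prolonged lag*: the smaller the resistant
fraction, the later the culture becomes detectable.  This module produces
plate-reader-style OD600 time series exhibiting exactly that phenomenology.

Model
-----
Let ``N_r`` and ``N_s`` be resistant / sensitive cell densities (cells/mL)::

    dN_r/dt = g(r_res)  * N_r
    dN_s/dt = g(r_sens) * N_s

where ``g(r) = r * (1 - (N_r + N_s)/K)`` when ``r > 0`` (logistic braking
toward the shared capacity ``K``) and ``g(r) = r`` when ``r <= 0`` (death is
not capacity-limited).  Optionally, sensitive births convert to resistant at
rate ``mu_res`` per division (Poisson per step).  The observed signal is::

    OD(t) = od_per_cell * (N_r + N_s) + od_offset + N(0, noise_sd), clipped at 0

``od_offset`` models absorbance of a coloured compound.  Integration is
fixed-step Euler at ``dt/10`` internal resolution, sampled every ``dt``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimParams",
    "GrowthCurve",
    "simulate_culture",
    "simulate_plate",
    "drug_free_control",
    "response_regimes",
    "write_plate_csv",
    "read_plate_csv",
]

#: internal Euler substeps per sampling interval
_SUBSTEPS = 10


@dataclass(frozen=True)
class SimParams:
    """Parameters of one simulated culture.

    Defaults describe the screening conditions: a saturated culture
    (~1e8 cells/mL) diluted 1:200 into a microtiter well, OD read every
    15 min for 48 h, resistant cells growing at the drug-free rate
    (doubling time ~90 min) and sensitive cells slowly dying under drug.
    """

    r_res: float = 0.46  # resistant growth rate under drug, 1/h
    r_sens: float = -0.05  # sensitive net rate under drug (<=0 = killing), 1/h
    r_nodrug: float = 0.46  # drug-free growth rate, 1/h
    K: float = 1e8  # carrying capacity, cells/mL
    N0: float = 5e5  # inoculum density (1:200 of saturation), cells/mL
    f_res: float = 1e-5  # initial resistant fraction
    mu_res: float = 0.0  # new resistance mutations per division
    od_per_cell: float = 1e-8  # OD600 units per cell/mL
    od_offset: float = 0.0  # additive OD baseline (coloured drug)
    noise_sd: float = 0.0  # OD measurement noise (sd)
    dt: float = 0.25  # sampling interval, h (15 min)
    t_end: float = 48.0  # duration, h
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not (0.0 <= self.f_res <= 1.0):
            raise ValueError(f"f_res must lie in [0, 1], got {self.f_res}")
        if not (self.K > self.N0 > 0):
            raise ValueError(f"require K > N0 > 0, got K={self.K}, N0={self.N0}")
        if self.dt <= 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")
        if self.t_end < self.dt:
            raise ValueError(f"t_end must be >= dt, got t_end={self.t_end}, dt={self.dt}")
        if self.od_offset < 0:
            raise ValueError(f"od_offset must be >= 0, got {self.od_offset}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.mu_res < 0:
            raise ValueError(f"mu_res must be >= 0, got {self.mu_res}")
        if self.od_per_cell <= 0:
            raise ValueError(f"od_per_cell must be > 0, got {self.od_per_cell}")


@dataclass
class GrowthCurve:
    """One well's OD600 time series with its labels."""

    well_id: str
    times: np.ndarray  # hours, strictly increasing, uniform spacing
    od: np.ndarray  # OD600, same length as times, >= 0
    strain: str = "msh2"  # {"WT", "msh2"}
    compound: str = "DMSO"
    dose: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if len(self.times) != len(self.od):
            raise ValueError("times and od must have equal length")
        if len(self.times) >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.od < 0):
            raise ValueError("od values must be >= 0")


def _effective_rate(r: float, crowding: float) -> float:
    # logistic braking applies to growth only; death is not capacity-limited
    return r * crowding if r > 0 else r


def simulate_culture(
    params: SimParams, *, return_populations: bool = False
) -> GrowthCurve | tuple[GrowthCurve, np.ndarray, np.ndarray]:
    """Simulate one well.

    With ``noise_sd == 0`` and ``mu_res == 0`` the output is deterministic
    and seed-independent (no RNG is consumed).

    Parameters
    ----------
    params
        Culture parameters (validated on construction).
    return_populations
        Also return the resistant and sensitive densities at the sampled
        timepoints (used by the discovery pipeline to carry the evolved
        resistant fraction through a passage).
    """
    params.validate()
    n_samples = int(round(params.t_end / params.dt))
    times = np.arange(n_samples + 1) * params.dt
    h = params.dt / _SUBSTEPS

    rng = None
    if params.mu_res > 0:
        rng = np.random.default_rng(params.seed)

    n_r = params.f_res * params.N0
    n_s = (1.0 - params.f_res) * params.N0
    traj_r = np.empty(n_samples + 1)
    traj_s = np.empty(n_samples + 1)
    traj_r[0], traj_s[0] = n_r, n_s

    for i in range(1, n_samples + 1):
        for _ in range(_SUBSTEPS):
            crowding = 1.0 - (n_r + n_s) / params.K
            g_r = _effective_rate(params.r_res, crowding)
            g_s = _effective_rate(params.r_sens, crowding)
            converted = 0.0
            if rng is not None:
                births_s = max(g_s, 0.0) * n_s * h
                if births_s > 0:
                    converted = float(rng.poisson(params.mu_res * births_s))
                    converted = min(converted, n_s)
            n_r = max(n_r + g_r * n_r * h + converted, 0.0)
            n_s = max(n_s + g_s * n_s * h - converted, 0.0)
        traj_r[i], traj_s[i] = n_r, n_s

    od = params.od_per_cell * (traj_r + traj_s) + params.od_offset
    if params.noise_sd > 0:
        noise_rng = np.random.default_rng(params.seed + 1)
        od = od + noise_rng.normal(0.0, params.noise_sd, size=od.shape)
    od = np.clip(od, 0.0, None)

    curve = GrowthCurve(well_id="A1", times=times, od=od)
    if return_populations:
        return curve, traj_r, traj_s
    return curve


def drug_free_control(params: SimParams) -> SimParams:
    """The matched no-drug (DMSO) condition: every cell grows at ``r_nodrug``."""
    return dataclasses.replace(
        params, r_res=params.r_nodrug, r_sens=params.r_nodrug, f_res=1.0
    )


def _well_seed(seed: int, well_id: str) -> int:
    digest = hashlib.sha256(f"{seed}:{well_id}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def simulate_plate(
    params_grid: Sequence[tuple[str, SimParams]],
    *,
    labels: dict[str, tuple[str, str, str]] | None = None,
) -> list[GrowthCurve]:
    """Simulate a plate: one curve per (well_id, params) entry.

    Each well gets an independent RNG stream derived from (params.seed,
    well_id), so results are reproducible per well regardless of order.
    ``labels`` optionally maps well_id -> (strain, compound, dose).
    """
    seen: set[str] = set()
    for well_id, _ in params_grid:
        if well_id in seen:
            raise ValueError(f"duplicate well_id: {well_id!r}")
        seen.add(well_id)

    curves = []
    for well_id, params in params_grid:
        p = dataclasses.replace(params, seed=_well_seed(params.seed, well_id))
        curve = simulate_culture(p)
        curve.well_id = well_id
        if labels and well_id in labels:
            curve.strain, curve.compound, curve.dose = labels[well_id]
        curves.append(curve)
    return curves


def response_regimes(
    *, noise_sd: float = 0.01, seed: int = 0
) -> dict[str, tuple[SimParams, SimParams]]:
    """Parameter regimes generating the five screen response categories.

    Returns ``{category: (wt_params, mutator_params)}`` for the drug wells;
    the matched DMSO controls are ``drug_free_control`` of either member.
    The categories (see :mod:`mutscreen.growth_metrics`):

    - ``no_effect``      — drug inert; both strains grow like the control.
    - ``sensitive``      — drug kills both strains regardless of MMR status.
    - ``resistant_short_lag`` — resistance is a direct consequence of MMR
      loss: the whole mutator culture is resistant, no lag.
    - ``resistant_long_lag``  — resistance requires a mutational event
      carried by a ~1e-5 subpopulation, giving a prolonged lag.
    - ``synthetic_growth_defect`` — drug specifically inhibits the
      MMR-deficient strain.
    """
    base = SimParams(noise_sd=noise_sd, seed=seed)
    grow = dataclasses.replace(base, f_res=1.0, r_res=base.r_nodrug)
    die = dataclasses.replace(base, f_res=0.0, r_sens=-0.05)
    select = dataclasses.replace(base, f_res=1e-5, r_res=base.r_nodrug, r_sens=-0.05)
    return {
        "no_effect": (grow, grow),
        "sensitive": (die, die),
        "resistant_short_lag": (die, grow),
        "resistant_long_lag": (die, select),
        "synthetic_growth_defect": (grow, die),
    }


# ---------------------------------------------------------------------------
# plate CSV I/O (schema shared with growth_metrics)

def write_plate_csv(
    curves: Iterable[GrowthCurve],
    path: str | Path,
    params: dict[str, SimParams] | None = None,
) -> None:
    """Write one row per reading: well, time_h, od600, strain, compound, dose.

    When ``params`` is given, a JSON sidecar ``<path>.params.json`` records
    the SimParams of each well.
    """
    rows = []
    for c in curves:
        for t, od in zip(c.times, c.od):
            rows.append((c.well_id, t, od, c.strain, c.compound, c.dose))
    df = pd.DataFrame(
        rows, columns=["well", "time_h", "od600", "strain", "compound", "dose"]
    )
    path = Path(path)
    df.to_csv(path, index=False)
    if params is not None:
        sidecar = {w: dataclasses.asdict(p) for w, p in params.items()}
        path.with_suffix(path.suffix + ".params.json").write_text(
            json.dumps(sidecar, indent=1)
        )


def read_plate_csv(path: str | Path) -> list[GrowthCurve]:
    df = pd.read_csv(path, keep_default_na=False)
    curves = []
    for well, grp in df.groupby("well", sort=False):
        grp = grp.sort_values("time_h")
        curves.append(
            GrowthCurve(
                well_id=str(well),
                times=grp["time_h"].to_numpy(),
                od=grp["od600"].to_numpy(),
                strain=str(grp["strain"].iloc[0]),
                compound=str(grp["compound"].iloc[0]),
                dose=str(grp["dose"].iloc[0]),
            )
        )
    return curves
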