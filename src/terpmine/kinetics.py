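"""Coupled pyrophosphate-assay simulation and Michaelis-Menten fitting.

The cyclase releases inorganic pyrophosphate, which a commercial coupled
enzyme cascade converts into NADH oxidation; the assay reads A340 decay.
In the initial-rate regime the trace is linear:

    A(t) = A0 - eps * path * nadh_per_ppi * v * t + noise,
    v    = kcat * [E] * [S] / (Km + [S])

with eps the NADH molar extinction coefficient (6220 M^-1 cm^-1 at
340 nm), path the cuvette path length in cm, and nadh_per_ppi the number
of NADH oxidized per pyrophosphate (2 for the standard coupled system).
Substrate depletion is ignored over the fit window (a few percent
conversion at the assay concentrations).

Units: concentrations in uM, velocities in uM/min, time points in
seconds, kcat in min^-1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "AssayTrace",
    "KineticFit",
    "EPSILON_NADH",
    "CHARACTERIZED_ENZYMES",
    "enzyme_conc_um",
    "simulate_trace",
    "initial_velocity",
    "fit_mm",
    "fit_traces",
]

EPSILON_NADH = 6220.0  # M^-1 cm^-1 at 340 nm
DEFAULT_NADH_PER_PPI = 2
DEFAULT_PATH_CM = 1.0
DEFAULT_A0 = 1.0  # AU of NADH loaded by the coupled reagent


@dataclass(frozen=True)
class AssayTrace:
    substrate_conc: float  # uM
    times: np.ndarray  # s
    absorbance340: np.ndarray  # AU
    enzyme_conc: float  # uM
    replicate_id: int = 0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if len(self.times) != len(self.absorbance340):
            raise ValueError("times and absorbance arrays differ in length")


@dataclass(frozen=True)
class KineticFit:
    Km: float  # uM
    Vmax: float  # uM/min
    kcat: float  # min^-1
    Km_sd: float
    kcat_sd: float
    residual_sse: float


def enzyme_conc_um(mass_ug: float, volume_ul: float, molar_mass_da: float) -> float:
    """Molar enzyme concentration (uM) from a protein loading.

    E.g. 532 ug in 800 uL of a 42 kDa monomer -> 15.83 uM.
    """
    if min(mass_ug, volume_ul, molar_mass_da) <= 0:
        raise ValueError("mass, volume and molar mass must be positive")
    g_per_l = mass_ug / volume_ul  # ug/uL == g/L
    return g_per_l / molar_mass_da * 1e6


# Reported steady-state parameters and assay loadings for the two
# characterized cyclases.  Monomer molar masses are the SDS-PAGE estimates
# (42 / 38 kDa); enzyme_conc is the molar loading of the 800 uL assay.
CHARACTERIZED_ENZYMES: dict[str, dict[str, float]] = {
    "DtcycA": {
        "Km": 93.7,  # uM
        "kcat": 2.8,  # min^-1
        "enzyme_conc": 0.0,  # filled below
        "mass_ug": 532.0,
        "volume_ul": 800.0,
        "molar_mass_da": 42_000.0,
    },
    "DtcycB": {
        "Km": 42.1,
        "kcat": 1.3,
        "enzyme_conc": 0.0,
        "mass_ug": 466.0,
        "volume_ul": 800.0,
        "molar_mass_da": 38_000.0,
    },
}

for _params in CHARACTERIZED_ENZYMES.values():
    _params["enzyme_conc"] = (
        _params["mass_ug"] / _params["volume_ul"] / _params["molar_mass_da"] * 1e6
    )
del _params


def michaelis_menten(s: np.ndarray, vmax: float, km: float) -> np.ndarray:
    return vmax * s / (km + s)


def _slope_au_per_min(
    v_um_per_min: float, epsilon: float, path_length: float, nadh_per_ppi: float
) -> float:
    return epsilon * path_length * nadh_per_ppi * v_um_per_min * 1e-6


def simulate_trace(
    Km: float,
    kcat: float,
    enzyme_conc: float,
    substrate_conc: float,
    duration: float = 180.0,
    dt: float = 2.0,
    epsilon: float = EPSILON_NADH,
    path_length: float = DEFAULT_PATH_CM,
    nadh_per_ppi: float = DEFAULT_NADH_PER_PPI,
    noise_sd: float = 0.0,
    seed: int | None = None,
    a0: float = DEFAULT_A0,
    replicate_id: int = 0,
) -> AssayTrace:
    """Simulate one A340-vs-time trace at a single substrate concentration."""
    for name, val in (
        ("Km", Km),
        ("kcat", kcat),
        ("enzyme_conc", enzyme_conc),
        ("substrate_conc", substrate_conc),
        ("duration", duration),
        ("dt", dt),
        ("epsilon", epsilon),
        ("path_length", path_length),
        ("nadh_per_ppi", nadh_per_ppi),
    ):
        if val <= 0:
            raise ValueError(f"{name} must be positive, got {val}")
    times = np.arange(0.0, duration + dt / 2, dt)
    v = kcat * enzyme_conc * substrate_conc / (Km + substrate_conc)  # uM/min
    slope = _slope_au_per_min(v, epsilon, path_length, nadh_per_ppi)  # AU/min
    absorbance = a0 - slope * times / 60.0
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        absorbance = absorbance + rng.normal(0.0, noise_sd, size=times.shape)
    return AssayTrace(
        substrate_conc=substrate_conc,
        times=times,
        absorbance340=absorbance,
        enzyme_conc=enzyme_conc,
        replicate_id=replicate_id,
        noise_sd=noise_sd,
    )


def initial_velocity(
    trace: AssayTrace,
    fit_window: float = 60.0,
    epsilon: float = EPSILON_NADH,
    path_length: float = DEFAULT_PATH_CM,
    nadh_per_ppi: float = DEFAULT_NADH_PER_PPI,
) -> float:
    """Initial velocity (uM/min) from the early-trace least-squares slope."""
    mask = trace.times <= fit_window
    if mask.sum() < 3:
        raise ValueError("need at least 3 points inside the fit window")
    slope_per_s = np.polyfit(trace.times[mask], trace.absorbance340[mask], 1)[0]
    slope_per_min = -slope_per_s * 60.0  # AU/min of NADH consumption
    v_m_per_min = slope_per_min / (epsilon * path_length * nadh_per_ppi)
    return v_m_per_min * 1e6


def fit_mm(
    velocities: list[tuple[float, float]],
    enzyme_conc: float,
) -> KineticFit:
    """Nonlinear least-squares fit of v = Vmax*S/(Km+S).

    Starting values: Vmax0 = max observed v, Km0 = median S.  If the
    first attempt fails or lands on a nonpositive parameter, one restart
    from a perturbed initialization is tried before raising.
    """
    s = np.asarray([p[0] for p in velocities], dtype=float)
    v = np.asarray([p[1] for p in velocities], dtype=float)
    if len(np.unique(s)) < 4:
        raise ValueError("need at least 4 distinct substrate concentrations")
    if enzyme_conc <= 0:
        raise ValueError("enzyme_conc must be positive")
    p0 = (float(v.max()), float(np.median(s)))
    last_err: Exception | None = None
    for attempt, init in enumerate((p0, (p0[0] * 1.5, p0[1] * 0.5))):
        try:
            popt, pcov = curve_fit(michaelis_menten, s, v, p0=init, maxfev=10_000)
        except RuntimeError as err:
            last_err = err
            continue
        vmax, km = popt
        if vmax > 0 and km > 0:
            perr = np.sqrt(np.diag(pcov))
            sse = float(np.sum((v - michaelis_menten(s, *popt)) ** 2))
            return KineticFit(
                Km=float(km),
                Vmax=float(vmax),
                kcat=float(vmax / enzyme_conc),
                Km_sd=float(perr[1]),
                kcat_sd=float(perr[0] / enzyme_conc),
                residual_sse=sse,
            )
        last_err = RuntimeError(
            f"attempt {attempt}: nonpositive parameters Vmax={vmax}, Km={km}"
        )
    raise RuntimeError(f"Michaelis-Menten fit failed to converge: {last_err}")


def fit_traces(
    traces: list[AssayTrace],
    fit_window: float = 60.0,
    epsilon: float = EPSILON_NADH,
    path_length: float = DEFAULT_PATH_CM,
    nadh_per_ppi: float = DEFAULT_NADH_PER_PPI,
) -> KineticFit:
    """Traces -> initial velocities -> Michaelis-Menten fit, in one call.

    The enzyme concentration is taken from the traces (they must agree).
    """
    if not traces:
        raise ValueError("no traces")
    enzyme_concs = {t.enzyme_conc for t in traces}
    if len(enzyme_concs) != 1:
        raise ValueError("traces were recorded at different enzyme concentrations")
    velocities = [
        (
            t.substrate_conc,
            initial_velocity(
                t,
                fit_window=fit_window,
                epsilon=epsilon,
                path_length=path_length,
                nadh_per_ppi=nadh_per_ppi,
            ),
        )
        for t in traces
    ]
    return fit_mm(velocities, enzyme_conc=enzyme_concs.pop())
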