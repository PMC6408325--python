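"""One-site binding thermodynamics: sequestration equilibrium and ITC.

Two closely related models live here.  The closed-form 1:1 mass-action
equilibrium predicts how much assembly-competent (unbound) tubulin remains
when a sequestering binder is added — the quantitative reading of a
dose-dependent turbidity suppression.  The one-site (Wiseman) isotherm
model simulates and fits per-injection ITC heats for the same interaction,
parameterised by stoichiometry ``n``, dissociation constant ``K_D`` and
enthalpy ``ΔH``, with ``ΔG = RT ln K_D`` and ``TΔS = ΔH − ΔG``.

Units: concentrations are molar, volumes litres, enthalpies kcal·mol⁻¹
and per-injection heats μcal throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import FitError

#: Gas constant in kcal·mol⁻¹·K⁻¹.
R_KCAL = 1.9872e-3

KCAL_TO_UCAL = 1e9

#: Wiseman c-value range in which a one-site fit is well conditioned.
C_VALUE_RANGE = (1.0, 1000.0)


@dataclass
class BindingParameters:
    """One-site thermodynamic parameters."""

    n: float  # sites per macromolecule
    kd: float  # dissociation constant, M
    dh: float  # binding enthalpy, kcal/mol
    temperature: float = 293.15  # K (experiments at 20 °C)

    def __post_init__(self) -> None:
        if self.kd <= 0:
            raise ValueError(f"kd must be positive, got {self.kd}")
        if self.n <= 0:
            raise ValueError(f"n must be positive, got {self.n}")


@dataclass
class BindingSystem:
    """Totals for the closed-form 1:1 equilibrium."""

    total_macromolecule: float  # M (tubulin)
    total_ligand: float  # M (binder)
    kd: float  # M

    def __post_init__(self) -> None:
        if self.total_macromolecule < 0 or self.total_ligand < 0:
            raise ValueError("totals must be non-negative")
        if self.kd <= 0:
            raise ValueError("kd must be positive")


@dataclass
class ITCGeometry:
    """Instrument geometry of a titration."""

    cell_volume: float  # L
    injection_volumes: list[float]  # L, per injection
    syringe_concentration: float  # M, titrant
    cell_concentration: float  # M, macromolecule

    def __post_init__(self) -> None:
        if self.cell_volume <= 0 or any(v <= 0 for v in self.injection_volumes):
            raise ValueError("volumes must be positive")
        if not self.injection_volumes:
            raise ValueError("at least one injection required")

    @classmethod
    def standard(cls, n_injections: int = 19) -> "ITCGeometry":
        """2 μL injections of 160 μM titrant into 0.24 mL of 15 μM cell."""
        return cls(
            cell_volume=0.24e-3,
            injection_volumes=[2e-6] * n_injections,
            syringe_concentration=160e-6,
            cell_concentration=15e-6,
        )


@dataclass
class TitrationSeries:
    """Per-injection integrated heats (μcal) plus the geometry behind them."""

    heats_ucal: np.ndarray
    geometry: ITCGeometry

    def __post_init__(self) -> None:
        self.heats_ucal = np.asarray(self.heats_ucal, dtype=float)
        if len(self.heats_ucal) != len(self.geometry.injection_volumes):
            raise ValueError("one heat per injection required")

    def molar_ratios(self) -> np.ndarray:
        """Cumulative titrant/macromolecule molar ratio in the cell."""
        _, x_tot, m_tot = _cell_concentration_ladder(self.geometry)
        return x_tot / m_tot

    def to_csv(self, path_or_buf) -> None:
        pd.DataFrame(
            {
                "injection": np.arange(1, len(self.heats_ucal) + 1),
                "volume_uL": np.asarray(self.geometry.injection_volumes) * 1e6,
                "heat_ucal": self.heats_ucal,
            }
        ).to_csv(path_or_buf, index=False)

    @classmethod
    def from_csv(
        cls,
        path_or_buf,
        cell_volume: float = 0.24e-3,
        syringe_concentration: float = 160e-6,
        cell_concentration: float = 15e-6,
    ) -> "TitrationSeries":
        df = pd.read_csv(path_or_buf)
        required = {"volume_uL", "heat_ucal"}
        if not required.issubset(df.columns):
            raise ValueError(f"titration CSV needs columns {sorted(required)}")
        geometry = ITCGeometry(
            cell_volume=cell_volume,
            injection_volumes=(df["volume_uL"].to_numpy() * 1e-6).tolist(),
            syringe_concentration=syringe_concentration,
            cell_concentration=cell_concentration,
        )
        return cls(heats_ucal=df["heat_ucal"].to_numpy(), geometry=geometry)


@dataclass
class ITCFitResult:
    """Fitted one-site parameters and derived state functions."""

    params: BindingParameters
    dg: float  # kcal/mol
    tds: float  # kcal/mol
    residual_norm: float
    stderr: dict[str, float] = field(default_factory=dict)
    c_value: float = float("nan")
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n": self.params.n,
            "kd_M": self.params.kd,
            "dh_kcal_mol": self.params.dh,
            "dg_kcal_mol": self.dg,
            "tds_kcal_mol": self.tds,
            "temperature_K": self.params.temperature,
            "residual_norm": self.residual_norm,
            "stderr": self.stderr,
            "c_value": self.c_value,
            "warnings": self.warnings,
        }


# ---------------------------------------------------------------------------
# Closed-form equilibrium


def free_species_1to1(system: BindingSystem) -> dict[str, float]:
    """Exact species concentrations for a 1:1 equilibrium.

    The complex concentration is the physical root of
    ``C² − (T + A + K_D)·C + T·A = 0`` with ``0 ≤ C ≤ min(T, A)``,
    evaluated in the numerically stable form; mass conservation holds
    exactly by construction.
    """
    t, a, kd = system.total_macromolecule, system.total_ligand, system.kd
    if t == 0.0 or a == 0.0:
        complex_c = 0.0
    else:
        b = t + a + kd
        disc = np.sqrt(b * b - 4.0 * t * a)
        complex_c = 2.0 * t * a / (b + disc)  # stable quadratic root
    complex_c = min(complex_c, t, a)
    return {
        "free_macromolecule": t - complex_c,
        "free_ligand": a - complex_c,
        "complex": complex_c,
    }


def effective_free_tubulin(
    total_tubulin: float, total_arep: float, kd: float, round_to_uM: bool = False
) -> float:
    """Assembly-competent (unbound) tubulin concentration, in molar.

    Convenience wrapper over :func:`free_species_1to1`; with
    ``round_to_uM=True`` the result is rounded to the nearest integer μM
    and returned in molar.
    """
    free = free_species_1to1(
        BindingSystem(total_macromolecule=total_tubulin, total_ligand=total_arep, kd=kd)
    )["free_macromolecule"]
    if round_to_uM:
        return round(free * 1e6) * 1e-6
    return free


# ---------------------------------------------------------------------------
# ITC simulation


def _cell_concentration_ladder(
    geometry: ITCGeometry, displaced_volume: bool = True
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-injection dilution factors and total concentrations in the cell.

    Returns ``(f, x_tot, m_tot)`` where ``f[i]`` is the dilution factor of
    injection i and ``x_tot[i]`` / ``m_tot[i]`` the total titrant and
    macromolecule concentrations after injection i.

    With the displaced-volume convention each injection of volume ``dv``
    expels an equal volume of (pre-injection) cell content, so existing
    concentrations scale by ``1 − dv/V0`` before the titrant aliquot mixes
    in.  The naive alternative lets the cell volume grow instead.
    """
    v0 = geometry.cell_volume
    dvs = np.asarray(geometry.injection_volumes)
    n = len(dvs)
    x_tot = np.empty(n)
    m_tot = np.empty(n)
    f = np.empty(n)
    if displaced_volume:
        x, m = 0.0, geometry.cell_concentration
        for i, dv in enumerate(dvs):
            fi = 1.0 - dv / v0
            x = x * fi + geometry.syringe_concentration * dv / v0
            m = m * fi
            f[i], x_tot[i], m_tot[i] = fi, x, m
    else:
        cum = np.cumsum(dvs)
        vols = v0 + cum
        x_tot = geometry.syringe_concentration * cum / vols
        m_tot = geometry.cell_concentration * v0 / vols
        f[:] = 1.0
    return f, x_tot, m_tot


def predicted_heats(
    params: BindingParameters,
    geometry: ITCGeometry,
    displaced_volume: bool = True,
) -> np.ndarray:
    """Noise-free per-injection heats (μcal) under the one-site model.

    The heat of injection i is the enthalpy times the change in the amount
    of complex in the cell across the injection,
    ``q_i = ΔH · V0 · (B_i − f_i·B_{i−1})``, where ``B`` is the bound-site
    concentration from the exact 1:1 quadratic with site concentration
    ``n·[M]`` and the factor ``f_i`` accounts for complex expelled by the
    displaced volume.
    """
    f, x_tot, m_tot = _cell_concentration_ladder(geometry, displaced_volume)
    bound = np.array(
        [
            free_species_1to1(
                BindingSystem(params.n * m, x, params.kd)
            )["complex"]
            for m, x in zip(m_tot, x_tot)
        ]
    )
    prev = np.concatenate([[0.0], bound[:-1]])
    dq_molar = bound - f * prev
    return params.dh * geometry.cell_volume * dq_molar * KCAL_TO_UCAL


def simulate_itc(
    params: BindingParameters,
    geometry: ITCGeometry,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
    displaced_volume: bool = True,
) -> TitrationSeries:
    """Simulate a titration; Gaussian noise of *noise_sd* μcal if requested.

    ``noise_sd = 0`` gives deterministic output; the same seed reproduces
    the same series bit for bit.
    """
    heats = predicted_heats(params, geometry, displaced_volume)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        heats = heats + rng.normal(0.0, noise_sd, size=heats.shape)
    return TitrationSeries(heats_ucal=heats, geometry=geometry)


# ---------------------------------------------------------------------------
# Derived state functions and fitting


def thermo_derive(kd: float, dh: float, temperature: float = 293.15) -> dict[str, float]:
    """ΔG and TΔS (kcal·mol⁻¹) from K_D and ΔH at a given temperature."""
    if kd <= 0:
        raise ValueError(f"kd must be positive, got {kd}")
    dg = R_KCAL * temperature * np.log(kd)
    return {"dg": float(dg), "tds": float(dh - dg)}


def fit_one_site(
    series: TitrationSeries,
    initial: Optional[BindingParameters] = None,
    temperature: float = 293.15,
    displaced_volume: bool = True,
) -> ITCFitResult:
    """Nonlinear least-squares fit of the one-site model to a titration.

    Fits ``(n, K_D, ΔH)`` to the per-injection heats in μcal; ΔG and TΔS
    follow from the fitted K_D.  Standard errors come from the Jacobian at
    the optimum.  A Wiseman c-value (``n·[M]₀/K_D``) outside [1, 1000]
    attaches an ill-conditioned-regime warning rather than failing.

    Raises
    ------
    FitError
        On non-convergence or a heat series carrying no binding signal.
    """
    q_obs = series.heats_ucal
    if len(q_obs) < 8:
        raise FitError(f"need ≥8 injections spanning the transition, got {len(q_obs)}")
    peak = np.abs(q_obs).max()
    if peak < 1e-9:
        raise FitError("no measurable heat signal: ΔH ≈ 0, K_D unidentifiable")
    geometry = series.geometry
    if initial is None:
        dvs = np.asarray(geometry.injection_volumes)
        moles_ligand = geometry.syringe_concentration * dvs.sum()
        moles_macro = geometry.cell_concentration * geometry.cell_volume
        dh0 = (q_obs.sum() / KCAL_TO_UCAL) / min(moles_ligand, moles_macro)
        if abs(dh0) < 1e-3:
            dh0 = -1.0
        initial = BindingParameters(
            n=1.0, kd=max(geometry.cell_concentration / 50.0, 1e-12), dh=dh0,
            temperature=temperature,
        )

    def residuals(x: np.ndarray) -> np.ndarray:
        n, log10_kd, dh = x
        p = BindingParameters(n=n, kd=10.0 ** log10_kd, dh=dh,
                              temperature=temperature)
        return predicted_heats(p, geometry, displaced_volume) - q_obs

    x0 = np.array([initial.n, np.log10(initial.kd), initial.dh])
    sol = least_squares(
        residuals,
        x0,
        bounds=([1e-3, -15.0, -np.inf], [10.0, 0.0, np.inf]),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    if not sol.success:
        raise FitError(f"one-site fit did not converge: {sol.message}")
    n_fit, log10_kd, dh_fit = sol.x
    kd_fit = 10.0 ** log10_kd
    params = BindingParameters(n=float(n_fit), kd=float(kd_fit), dh=float(dh_fit),
                               temperature=temperature)
    derived = thermo_derive(params.kd, params.dh, temperature)

    dof = max(len(q_obs) - 3, 1)
    s2 = 2.0 * sol.cost / dof
    jtj = sol.jac.T @ sol.jac
    stderr: dict[str, float] = {}
    try:
        cov = np.linalg.inv(jtj) * s2
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        stderr = {
            "n": float(se[0]),
            # propagate from log10(kd) to kd
            "kd_M": float(se[1] * kd_fit * np.log(10.0)),
            "dh_kcal_mol": float(se[2]),
        }
    except np.linalg.LinAlgError:
        stderr = {}

    c_value = float(params.n * geometry.cell_concentration / params.kd)
    warnings = []
    if not (C_VALUE_RANGE[0] <= c_value <= C_VALUE_RANGE[1]):
        warnings.append(
            f"c-value {c_value:.3g} outside {C_VALUE_RANGE}: "
            "parameters may be poorly determined"
        )
    return ITCFitResult(
        params=params,
        dg=derived["dg"],
        tds=derived["tds"],
        residual_norm=float(np.sqrt(2.0 * sol.cost)),
        stderr=stderr,
        c_value=c_value,
        warnings=warnings,
    )


def heats_per_mole_injectant(series: TitrationSeries) -> np.ndarray:
    """Convert μcal per injection to kcal per mole of injected titrant."""
    dvs = np.asarray(series.geometry.injection_volumes)
    moles = series.geometry.syringe_concentration * dvs
    return series.heats_ucal / KCAL_TO_UCAL / moles
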