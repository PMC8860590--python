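"""Isothermal titration calorimetry: binding models, simulation and fitting.

The macromolecule (antitoxin RNA) sits in the cell and is titrated with the
toxin protein from the syringe. Three isotherm models are provided:

* ``one_site`` — n equivalent sites, closed-form quadratic equilibrium;
* ``two_site_independent`` — two independent classes of sites;
* ``two_site_sequential`` — ordered binding M + X = MX, MX + X = MX2, the
  default two-site variant (consistent with stepwise assembly of the
  toxin-antitoxin complex: the 3' site first, then ring closure via the 5'
  site).

Thermodynamic bookkeeping uses dG = RT ln K_D (R in kcal/mol/K, so dG of a
nanomolar binder is about -11 kcal/mol at 288 K) and T dS = dH - dG.

Usage follows the Model/Results idiom::

    model = IsothermModel(data, setup, variant="two_site_sequential")
    res = model.fit(starts=16, seed=7)
    print(res.summary())
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import lmfit
import numpy as np
import pandas as pd

from .io import ISOTHERM_COLUMNS

__all__ = [
    "R_KCAL",
    "TitrationSetup",
    "BindingModel",
    "Isotherm",
    "ThermoProfile",
    "IsothermModel",
    "IsothermResults",
    "ModelSelection",
    "equilibrium_species",
    "simulate_isotherm",
    "subtract_dilution",
    "fit_isotherm",
    "thermo_profile",
    "select_model",
]

R_KCAL = 1.98720425e-3  # kcal / (mol K)
DEFAULT_TEMPERATURE_K = 288.15  # 15 C
DEFAULT_CELL_VOLUME_UL = 1400.0

Variant = Literal["one_site", "two_site_independent", "two_site_sequential"]


# ---------------------------------------------------------------------------
# containers


@dataclass
class TitrationSetup:
    """Geometry and concentrations of one titration experiment."""

    cell_conc_uM: float
    syringe_conc_uM: float
    injection_volumes_uL: Sequence[float]
    cell_volume_uL: float = DEFAULT_CELL_VOLUME_UL
    temperature_K: float = DEFAULT_TEMPERATURE_K

    def __post_init__(self):
        if self.cell_conc_uM <= 0 or self.syringe_conc_uM <= 0:
            raise ValueError("concentrations must be > 0")
        self.injection_volumes_uL = list(self.injection_volumes_uL)
        if len(self.injection_volumes_uL) < 5:
            raise ValueError("need at least 5 injections")
        if any(v <= 0 for v in self.injection_volumes_uL):
            raise ValueError("injection volumes must be > 0")
        if any(v > self.cell_volume_uL for v in self.injection_volumes_uL):
            raise ValueError("injection volume exceeds cell volume")

    @classmethod
    def uniform(cls, cell_conc_uM, syringe_conc_uM, n_injections=30, injection_uL=8.0, **kw):
        return cls(cell_conc_uM, syringe_conc_uM, [injection_uL] * n_injections, **kw)


@dataclass
class BindingModel:
    """A parameter set for one of the three isotherm variants.

    ``kd`` (molar) and ``dh`` (kcal/mol) hold one value per binding step;
    ``n`` (sites per macromolecule, per step) applies to the one-site and
    independent variants and is fixed at 1 per step by default.
    """

    variant: Variant
    kd: list[float]
    dh: list[float]
    n: list[float] = field(default_factory=list)

    def __post_init__(self):
        self.kd = [float(k) for k in self.kd]
        self.dh = [float(h) for h in self.dh]
        n_steps = 1 if self.variant == "one_site" else 2
        if len(self.kd) != n_steps or len(self.dh) != n_steps:
            raise ValueError(f"{self.variant} needs {n_steps} kd and dh values")
        if any(k <= 0 for k in self.kd):
            raise ValueError("K_D must be > 0")
        if not self.n:
            self.n = [1.0] * n_steps
        if any(x <= 0 for x in self.n):
            raise ValueError("stoichiometry must be > 0")

    @classmethod
    def one_site(cls, kd, dh, n=1.0):
        return cls("one_site", [kd], [dh], [n])

    @classmethod
    def two_site_sequential(cls, kd1, kd2, dh1, dh2):
        return cls("two_site_sequential", [kd1, kd2], [dh1, dh2])

    @classmethod
    def two_site_independent(cls, kd1, kd2, dh1, dh2, n1=1.0, n2=1.0):
        return cls("two_site_independent", [kd1, kd2], [dh1, dh2], [n1, n2])

    def simulate(self, setup: TitrationSetup) -> "Isotherm":
        return simulate_isotherm(self, setup)

    def thermo(self, temperature_K: float = DEFAULT_TEMPERATURE_K) -> list["ThermoProfile"]:
        return [thermo_profile(k, h, temperature_K) for k, h in zip(self.kd, self.dh)]


@dataclass
class Isotherm:
    """Per-injection heats; wraps a DataFrame with the canonical columns."""

    data: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        missing = [c for c in ISOTHERM_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"isotherm table missing columns: {missing}")
        if not np.all(np.isfinite(self.data["heat_ucal"])):
            raise ValueError("non-finite heats")
        ratios = self.data["ratio"].to_numpy()
        if not np.all(np.diff(ratios) > 0):
            raise ValueError("molar ratio must be strictly increasing")

    @property
    def heats_ucal(self) -> np.ndarray:
        return self.data["heat_ucal"].to_numpy()

    @property
    def ndh(self) -> np.ndarray:
        return self.data["ndh_kcal_per_mol"].to_numpy()

    @property
    def ratio(self) -> np.ndarray:
        return self.data["ratio"].to_numpy()

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Isotherm":
        return cls(pd.read_csv(path))


@dataclass
class ThermoProfile:
    """K_D, dG, dH and TdS at temperature T, linked by dG = RT ln K_D and
    TdS = dH - dG."""

    kd: float
    dg: float
    dh: float
    tds: float
    temperature_K: float

    def __post_init__(self):
        if abs(self.tds - (self.dh - self.dg)) > 1e-9:
            raise ValueError("TdS != dH - dG")


def thermo_profile(kd: float, dh: float, temperature_K: float = DEFAULT_TEMPERATURE_K) -> ThermoProfile:
    """Full thermodynamic profile from K_D (molar) and dH (kcal/mol)."""
    if kd <= 0 or temperature_K <= 0:
        raise ValueError("kd and temperature must be > 0")
    dg = R_KCAL * temperature_K * math.log(kd)
    return ThermoProfile(kd=kd, dg=dg, dh=dh, tds=dh - dg, temperature_K=temperature_K)


# ---------------------------------------------------------------------------
# equilibrium solvers


def _solve_cubic_roots(a, b, c, d):
    """Real roots of a x^3 + b x^2 + c x + d (vectorized Cardano).

    Returns an (n, 3) complex array of roots.
    """
    a, b, c, d = (np.asarray(v, dtype=complex) for v in (a, b, c, d))
    p = (3 * a * c - b ** 2) / (3 * a ** 2)
    q = (2 * b ** 3 - 9 * a * b * c + 27 * a ** 2 * d) / (27 * a ** 3)
    disc = (q / 2) ** 2 + (p / 3) ** 3
    s = np.sqrt(disc)
    u = -q / 2 + s
    # avoid cancellation: pick the larger magnitude branch
    alt = -q / 2 - s
    use_alt = np.abs(alt) > np.abs(u)
    u = np.where(use_alt, alt, u)
    C = u ** (1 / 3)
    C = np.where(np.abs(C) < 1e-300, 1e-300, C)
    omega = complex(-0.5, math.sqrt(3) / 2)
    roots = []
    for kpow in range(3):
        w = omega ** kpow
        t = w * C - p / (3 * w * C)
        roots.append(t - b / (3 * a))
    return np.stack(roots, axis=-1)


def _free_titrant_two_site(model: BindingModel, Mt: np.ndarray, Xt: np.ndarray) -> np.ndarray:
    """Free titrant concentration for the two-site variants.

    Mass balance reduces to a cubic in the free titrant x; the physical root
    in [0, Xt] is selected and polished with Newton steps to relative
    tolerance 1e-10. Concentrations are scaled to uM internally for
    conditioning.
    """
    scale = 1e6  # work in uM
    Mt = np.asarray(Mt, dtype=float) * scale
    Xt = np.asarray(Xt, dtype=float) * scale
    k1, k2 = model.kd[0] * scale, model.kd[1] * scale
    if model.variant == "two_site_sequential":
        # Xt = x + Mt (x/k1 + 2 x^2/(k1 k2)) / (1 + x/k1 + x^2/(k1 k2))
        # -> cubic: x^3 + x^2 (k2 + 2 Mt - Xt) + x k2 (k1 + Mt - Xt) - k1 k2 Xt = 0
        a = np.ones_like(Xt)
        b = k2 + 2 * Mt - Xt
        c = k2 * (k1 + Mt - Xt)
        d = -k1 * k2 * Xt
    else:  # two_site_independent
        n1, n2 = model.n
        # Xt = x + n1 Mt x/(k1+x) + n2 Mt x/(k2+x)
        a = np.ones_like(Xt)
        b = k1 + k2 + (n1 + n2) * Mt - Xt
        c = k1 * k2 + n1 * Mt * k2 + n2 * Mt * k1 - Xt * (k1 + k2)
        d = -Xt * k1 * k2
    roots = _solve_cubic_roots(a, b, c, d)

    def balance(x):
        M = Mt[..., None] if np.ndim(x) > Mt.ndim else Mt
        X = Xt[..., None] if np.ndim(x) > Xt.ndim else Xt
        if model.variant == "two_site_sequential":
            z = 1 + x / k1 + x ** 2 / (k1 * k2)
            bound = M * (x / k1 + 2 * x ** 2 / (k1 * k2)) / z
        else:
            n1, n2 = model.n
            bound = M * (n1 * x / (k1 + x) + n2 * x / (k2 + x))
        return X - x - bound

    real = np.abs(roots.imag) < 1e-6 * (1 + np.abs(roots.real))
    xr = roots.real
    feasible = real & (xr >= -1e-9) & (xr <= Xt[..., None] * (1 + 1e-9) + 1e-12)
    resid = np.abs(balance(np.clip(xr, 0, None)))
    resid = np.where(feasible, resid, np.inf)
    pick = np.argmin(resid, axis=-1)
    x = np.clip(np.take_along_axis(xr, pick[..., None], axis=-1)[..., 0], 0.0, None)
    if not np.all(np.isfinite(x)):
        raise RuntimeError("two-site equilibrium solve failed: non-finite root")
    # Newton polish
    for _ in range(4):
        eps = np.maximum(x, 1e-12) * 1e-7
        f = balance(x)
        fp = (balance(x + eps) - f) / eps
        step = np.where(np.abs(fp) > 0, f / fp, 0.0)
        x_new = np.clip(x - step, 0.0, Xt)
        x = np.where(np.isfinite(x_new), x_new, x)
    err = np.abs(balance(x)) / np.maximum(Xt, 1e-30)
    if np.any(err[Xt > 0] > 1e-8):
        raise RuntimeError(f"two-site equilibrium solve did not converge (max rel err {err.max():.2e})")
    return x / scale


def equilibrium_species(model: BindingModel, total_macromolecule, total_titrant) -> dict[str, np.ndarray]:
    """Equilibrium species concentrations (molar) at the given totals.

    Returns free macromolecule/titrant and per-step complex concentrations.
    For the sequential variant the complexes are MX and MX2; for the others,
    the per-site-class bound concentrations.
    """
    Mt = np.atleast_1d(np.asarray(total_macromolecule, dtype=float))
    Xt = np.atleast_1d(np.asarray(total_titrant, dtype=float))
    Mt, Xt = np.broadcast_arrays(Mt, Xt)
    if (Mt < 0).any() or (Xt < 0).any():
        raise ValueError("totals must be >= 0")
    if model.variant == "one_site":
        kd = model.kd[0]
        n = model.n[0]
        cap = n * Mt
        b = cap + Xt + kd
        bound = (b - np.sqrt(b ** 2 - 4 * cap * Xt)) / 2
        bound = np.clip(bound, 0.0, np.minimum(cap, Xt))
        return {
            "free_macromolecule": Mt - bound / max(n, 1e-300),
            "free_titrant": Xt - bound,
            "complex": [bound],
        }
    x = _free_titrant_two_site(model, Mt, Xt)
    k1, k2 = model.kd
    if model.variant == "two_site_sequential":
        z = 1 + x / k1 + x ** 2 / (k1 * k2)
        m = Mt / z
        mx = m * x / k1
        mx2 = m * x ** 2 / (k1 * k2)
        return {"free_macromolecule": m, "free_titrant": x, "complex": [mx, mx2]}
    n1, n2 = model.n
    b1 = n1 * Mt * x / (k1 + x)
    b2 = n2 * Mt * x / (k2 + x)
    return {"free_macromolecule": Mt - b1 / max(n1, 1e-300), "free_titrant": x, "complex": [b1, b2]}


# ---------------------------------------------------------------------------
# simulation


def _step_enthalpy_content(model: BindingModel, species: dict) -> np.ndarray:
    """Sum over steps of dH_step x cumulative complex through that step
    (kcal per litre of cell volume ... actually kcal/mol x mol/L)."""
    if model.variant == "two_site_sequential":
        mx, mx2 = species["complex"]
        return model.dh[0] * (mx + mx2) + model.dh[1] * mx2
    total = np.zeros_like(species["complex"][0])
    for dh, conc in zip(model.dh, species["complex"]):
        total = total + dh * conc
    return total


def titration_totals(setup: TitrationSetup) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cell totals (molar) after each injection under the perfusion
    (constant-volume displacement) model: each injection of dV displaces a
    fraction dV/V0 of the current cell content."""
    V0 = setup.cell_volume_uL
    M = setup.cell_conc_uM * 1e-6
    X = 0.0
    Xs = setup.syringe_conc_uM * 1e-6
    Ms, Xts, fs = [], [], []
    for dV in setup.injection_volumes_uL:
        f = dV / V0
        M = M * (1 - f)
        X = X * (1 - f) + Xs * f
        Ms.append(M)
        Xts.append(X)
        fs.append(f)
    return np.array(Ms), np.array(Xts), np.array(fs)


def simulate_isotherm(model: BindingModel, setup: TitrationSetup) -> Isotherm:
    """Noiseless per-injection heats for a titration.

    The heat of injection i is the change in cell enthalpy content,
    accounting for the complex displaced out of the active volume:
    q_i = V0 * (H_i - (1 - f_i) * H_{i-1}) where H is the dH-weighted
    complex concentration and f_i the displaced fraction.
    """
    Mt, Xt, fs = titration_totals(setup)
    species = equilibrium_species(model, Mt, Xt)
    H = _step_enthalpy_content(model, species)  # kcal/L
    V0_L = setup.cell_volume_uL * 1e-6
    heats_kcal = np.empty_like(H)
    prev = 0.0
    for i in range(len(H)):
        heats_kcal[i] = V0_L * (H[i] - (1 - fs[i]) * prev)
        prev = H[i]
    heats_ucal = heats_kcal * 1e9
    inj_vol = np.asarray(setup.injection_volumes_uL, dtype=float)
    mol_injected = inj_vol * 1e-6 * setup.syringe_conc_uM * 1e-6
    ndh = heats_kcal / mol_injected
    df = pd.DataFrame(
        {
            "injection": np.arange(1, len(H) + 1),
            "volume_uL": inj_vol,
            "heat_ucal": heats_ucal,
            "ratio": Xt / Mt,
            "ndh_kcal_per_mol": ndh,
        }
    )
    return Isotherm(df, meta={"model": model.variant, "temperature_K": setup.temperature_K})


def subtract_dilution(data: Isotherm, blank: "Isotherm | float") -> Isotherm:
    """Subtract a heat-of-dilution blank (a constant in ucal, or a matched
    blank titration) from the raw heats; normalized heats are recomputed."""
    df = data.data.copy()
    if isinstance(blank, Isotherm):
        if len(blank.data) != len(df) or not np.allclose(
            blank.data["volume_uL"], df["volume_uL"]
        ):
            raise ValueError("blank injection schedule does not match the data")
        offset = blank.heats_ucal
        desc = "isotherm blank"
    else:
        offset = float(blank)
        desc = f"constant {float(blank):g} ucal"
    df["heat_ucal"] = df["heat_ucal"] - offset
    meta = dict(data.meta)
    meta["dilution_correction"] = desc
    # recompute ndh = q / (dV * [syringe]); the moles injected per shot are
    # recovered from the original table as q * 1e-9 / ndh
    with np.errstate(divide="ignore", invalid="ignore"):
        mol_injected = data.data["heat_ucal"] * 1e-9 / data.data["ndh_kcal_per_mol"]
    mol_injected = mol_injected.replace([np.inf, -np.inf], np.nan)
    if mol_injected.isna().any():
        fill = mol_injected.dropna()
        mol_injected = mol_injected.fillna(fill.iloc[0] if len(fill) else np.nan)
    df["ndh_kcal_per_mol"] = df["heat_ucal"] * 1e-9 / mol_injected
    return Isotherm(df, meta=meta)


# ---------------------------------------------------------------------------
# fitting


def _variant_params(variant: Variant, rng: np.random.Generator, data: Isotherm, setup: TitrationSetup, free_n: bool):
    """One seeded multi-start draw of lmfit Parameters for a variant."""
    n_steps = 1 if variant == "one_site" else 2
    total_heat_kcal = float(np.sum(data.heats_ucal)) * 1e-9
    cap = min(
        setup.cell_conc_uM * 1e-6 * setup.cell_volume_uL * 1e-6 * n_steps,
        np.sum(setup.injection_volumes_uL) * 1e-6 * setup.syringe_conc_uM * 1e-6,
    )
    dh_est = total_heat_kcal / max(cap, 1e-30) / n_steps
    params = lmfit.Parameters()
    for s in range(n_steps):
        params.add(f"log10_kd{s + 1}", value=float(rng.uniform(-11, -5)), min=-14, max=-2)
        params.add(f"dh{s + 1}", value=dh_est * float(rng.uniform(0.5, 2.0)), min=-200, max=200)
    if variant != "two_site_sequential":
        for s in range(n_steps):
            params.add(f"n{s + 1}", value=1.0, min=0.1, max=4.0, vary=free_n)
    return params


def _step_order(variant: Variant, params) -> list[int]:
    """Canonical step order for a fitted parameter set.

    The independent-sites model is invariant under site-class exchange, so
    fitted steps are reported weakest-affinity first (descending K_D, the
    Table-2 convention). The sequential model is not exchangeable.
    """
    if variant != "two_site_independent":
        return list(range(1 if variant == "one_site" else 2))
    v = params.valuesdict()
    kd = [v["log10_kd1"], v["log10_kd2"]]
    return [0, 1] if kd[0] >= kd[1] else [1, 0]


def _model_from_params(variant: Variant, params) -> BindingModel:
    v = params.valuesdict()
    order = _step_order(variant, params)
    kd = [10 ** v[f"log10_kd{s + 1}"] for s in order]
    dh = [v[f"dh{s + 1}"] for s in order]
    n = [v.get(f"n{s + 1}", 1.0) for s in order]
    if variant == "two_site_sequential":
        n = [1.0] * len(order)
    return BindingModel(variant, kd, dh, n)


class IsothermModel:
    """A binding-isotherm model bound to one titration dataset.

    Parameters
    ----------
    data : Isotherm or DataFrame with the canonical isotherm columns.
    setup : TitrationSetup describing the experiment geometry.
    variant : one of "one_site", "two_site_independent", "two_site_sequential".
    weights : per-injection weights for the least squares (default uniform).
    """

    def __init__(self, data, setup: TitrationSetup, variant: Variant = "one_site", weights=None):
        if isinstance(data, pd.DataFrame):
            data = Isotherm(data)
        self.data = data
        self.setup = setup
        self.variant = variant
        self.weights = np.ones(len(data.data)) if weights is None else np.asarray(weights, float)
        n_params = (2 if variant == "one_site" else 4)
        if len(data.data) < n_params + 2:
            raise ValueError("need at least 2 more data points than free parameters")

    @classmethod
    def from_csv(cls, path, setup: TitrationSetup, variant: Variant = "one_site"):
        return cls(Isotherm.from_csv(path), setup, variant)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, setup: TitrationSetup, variant: Variant = "one_site"):
        return cls(Isotherm(df), setup, variant)

    def _residuals(self, params) -> np.ndarray:
        model = _model_from_params(self.variant, params)
        sim = simulate_isotherm(model, self.setup)
        return (sim.heats_ucal - self.data.heats_ucal) * self.weights

    def fit(self, starts: int = 16, seed: int = 0, free_n: bool = False) -> "IsothermResults":
        """Multi-start weighted least squares in log10(K_D) space.

        The best of `starts` seeded starts is returned; the first start uses
        a deterministic mid-range K_D guess so small `starts` stay sensible.
        """
        rng = np.random.default_rng(seed)
        best = None
        for s in range(starts):
            params = _variant_params(self.variant, rng, self.data, self.setup, free_n)
            if s == 0:
                for name in params:
                    if name.startswith("log10_kd"):
                        params[name].value = -8.0 - 0.5 * int(name[-1])
            try:
                mini = lmfit.minimize(
                    self._residuals, params, method="least_squares", nan_policy="raise"
                )
            except Exception:
                continue
            if best is None or mini.chisqr < best.chisqr:
                best = mini
        if best is None:
            raise RuntimeError("all fit starts failed")
        return IsothermResults(self, best)


class IsothermResults:
    """Fit results: parameter estimates, uncertainties and diagnostics."""

    def __init__(self, model: IsothermModel, minimizer_result):
        self.model = model
        self.minres = minimizer_result
        self.params = _model_from_params(model.variant, minimizer_result.params)

    # -- parameter access ---------------------------------------------------
    @property
    def kd(self) -> list[float]:
        return self.params.kd

    @property
    def dh(self) -> list[float]:
        return self.params.dh

    @property
    def stderr(self) -> dict[str, float | None]:
        return {name: p.stderr for name, p in self.minres.params.items() if p.vary}

    @property
    def kd_stderr(self) -> list[float | None]:
        """Standard errors propagated from log10 K_D to K_D (delta method),
        in the same canonical step order as `params`."""
        out = []
        for s in _step_order(self.model.variant, self.minres.params):
            p = self.minres.params[f"log10_kd{s + 1}"]
            if p.stderr is None:
                out.append(None)
            else:
                out.append(abs(10 ** p.value * math.log(10) * p.stderr))
        return out

    @property
    def chisqr(self) -> float:
        return float(self.minres.chisqr)

    @property
    def residuals(self) -> np.ndarray:
        return np.asarray(self.minres.residual)

    @property
    def aicc(self) -> float:
        """Small-sample corrected Akaike information criterion."""
        n = len(self.model.data.data)
        k = self.minres.nvarys
        rss = self.chisqr
        aic = n * math.log(max(rss, 1e-300) / n) + 2 * k
        denom = n - k - 1
        if denom <= 0:
            return math.inf
        return aic + 2 * k * (k + 1) / denom

    @property
    def identifiable(self) -> bool:
        """False when the covariance is unavailable or any K_D is pinned to
        a bound / has an exploding relative error."""
        if self.minres.covar is None:
            return False
        for name, p in self.minres.params.items():
            if not p.vary:
                continue
            if p.stderr is None or not np.isfinite(p.stderr):
                return False
            if name.startswith("log10_kd") and p.stderr > 2.0:
                return False
        return True

    def thermo(self) -> list[ThermoProfile]:
        return self.params.thermo(self.model.setup.temperature_K)

    def predicted(self) -> Isotherm:
        return simulate_isotherm(self.params, self.model.setup)

    def summary(self) -> str:
        lines = [
            "Isotherm fit summary",
            "====================",
            f"variant:            {self.model.variant}",
            f"injections:         {len(self.model.data.data)}",
            f"temperature (K):    {self.model.setup.temperature_K:.2f}",
            f"chi-square (ucal^2):{self.chisqr: .4g}",
            f"AICc:               {self.aicc: .4g}",
            f"identifiable:       {self.identifiable}",
            "",
            f"{'step':>4} {'K_D (nM)':>12} {'+/- (nM)':>10} {'dH (kcal/mol)':>14} "
            f"{'dG (kcal/mol)':>14} {'TdS (kcal/mol)':>15} {'n':>6}",
        ]
        kd_err = self.kd_stderr
        for s, tp in enumerate(self.thermo()):
            err = kd_err[s]
            err_s = f"{err * 1e9:10.3g}" if err is not None else f"{'--':>10}"
            lines.append(
                f"{s + 1:>4} {tp.kd * 1e9:12.4g} {err_s} {tp.dh:14.2f} "
                f"{tp.dg:14.2f} {tp.tds:15.2f} {self.params.n[s]:6.2f}"
            )
        return "\n".join(lines)

    def plot(self, ax=None):
        """Normalized heats vs molar ratio with the fitted curve."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.model.data.ratio, self.model.data.ndh, "o", label="data", mfc="none")
        pred = self.predicted()
        ax.plot(pred.ratio, pred.ndh, "-", label=f"fit ({self.model.variant})")
        ax.set_xlabel("molar ratio (titrant / macromolecule)")
        ax.set_ylabel("kcal per mol of injectant")
        ax.legend()
        return ax


def fit_isotherm(
    data: Isotherm,
    setup: TitrationSetup,
    variant: Variant = "one_site",
    starts: int = 16,
    seed: int = 0,
    free_n: bool = False,
) -> tuple[BindingModel, IsothermResults]:
    """Functional wrapper around IsothermModel(...).fit(...)."""
    res = IsothermModel(data, setup, variant).fit(starts=starts, seed=seed, free_n=free_n)
    return res.params, res


@dataclass
class ModelSelection:
    """Outcome of a one-site vs two-site comparison on one dataset."""

    choice: str  # "one_site" | "two_site" | "non-identifiable"
    delta_aicc: float  # AICc(two_site) - AICc(one_site)
    one_site: IsothermResults | None
    two_site: IsothermResults | None


def select_model(
    data: Isotherm,
    setup: TitrationSetup,
    starts: int = 16,
    seed: int = 0,
    two_site_variant: Variant = "two_site_sequential",
) -> ModelSelection:
    """Compare one-site and two-site fits by corrected AIC.

    Data that neither binding model explains better than a constant baseline
    is flagged "non-identifiable" instead of forcing a choice.
    """
    results = {}
    errors = []
    for variant in ("one_site", two_site_variant):
        try:
            results[variant] = IsothermModel(data, setup, variant).fit(starts=starts, seed=seed)
        except Exception as exc:  # pragma: no cover - defensive
            errors.append(f"{variant}: {exc}")
            results[variant] = None
    if all(r is None for r in results.values()):
        raise RuntimeError("both fits failed: " + "; ".join(errors))
    one = results["one_site"]
    two = results[two_site_variant]
    # constant-baseline AICc as the identifiability yardstick
    y = data.heats_ucal
    n = len(y)
    rss0 = float(np.sum((y - y.mean()) ** 2))
    aicc0 = n * math.log(max(rss0, 1e-300) / n) + 2 + 4 / max(n - 2, 1)
    best_aicc = min(r.aicc for r in results.values() if r is not None)
    if best_aicc >= aicc0:
        choice = "non-identifiable"
    elif one is None:
        choice = "two_site"
    elif two is None:
        choice = "one_site"
    elif one.identifiable and not two.identifiable:
        # a two-site fit with a phantom, unconstrained second site (K_D at a
        # bound, exploding errors) is not evidence for two sites
        choice = "one_site"
    elif two.identifiable and not one.identifiable:
        choice = "two_site"
    else:
        choice = "two_site" if two.aicc < one.aicc else "one_site"
    delta = (two.aicc if two else math.inf) - (one.aicc if one else math.inf)
    return ModelSelection(choice=choice, delta_aicc=delta, one_site=one, two_site=two)
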