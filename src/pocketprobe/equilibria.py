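"""One-site mass-action equilibria and association-constant estimation.

All concentrations are molar internally.  The binding model is 1:1
(single colchicine-type site per receptor):

    Kb = Cb / (Cf · Tf)

For a competition between a reference ligand (known Kb) and a test
ligand, the ratio of the two isotherms at a shared free-receptor
concentration gives

    Kb_x = Kb_ref · (Cf_ref / Cb_ref) / (Cf_x / Cb_x)

which is the estimator applied to centrifugation free/bound measurements.
Three estimation routes are provided: direct titration fitting,
fluorescence-displacement fitting against a reference ligand, and the
competition/centrifugation ratio method.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "EquilibriumState",
    "BindingConstant",
    "TitrationSeries",
    "CompetitionExperiment",
    "solve_single",
    "solve_competition",
    "kb_point",
    "kb_competition",
    "fit_direct",
    "fit_displacement",
    "estimate_kb_centrifugation",
    "read_titration_csv",
    "write_titration_csv",
    "read_competition_csv",
    "write_competition_csv",
]

# Paper-design competitor totals for displacement titrations, µM.
DEFAULT_COMPETITOR_SERIES_UM = (0.0, 0.05, 0.2, 0.5, 2.0, 5.0, 10.0, 30.0, 50.0, 70.0)


@dataclass(frozen=True)
class EquilibriumState:
    """Free receptor Tf plus per-ligand free (Cf) and bound (Cb) concentrations, M."""

    Tf: float
    Cf: tuple[float, ...]
    Cb: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.Tf < 0 or any(c < 0 for c in self.Cf + self.Cb):
            raise ValueError("negative concentration in equilibrium state")
        if len(self.Cf) != len(self.Cb):
            raise ValueError("Cf/Cb length mismatch")


@dataclass(frozen=True)
class BindingConstant:
    """An association constant Kb (M⁻¹) with optional replicate SD."""

    value: float
    sd: float | None = None
    method: str = "direct"
    n: int | None = None
    saturated: bool = False  # True when the design only supports a lower bound

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError("Kb must be positive")


@dataclass
class TitrationSeries:
    """A displacement titration: competitor totals vs fluorescence intensity.

    Receptor and reference-ligand totals are fixed across the series
    (0.2 µM each in the source protocol); the competitor is titrated
    (default 0–70 µM).  Intensity is in arbitrary fluorescence units
    (456 nm emission / 374 nm excitation in the source protocol).
    """

    receptor_total: float
    reference_total: float
    competitor_totals: np.ndarray
    intensity: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.competitor_totals = np.asarray(self.competitor_totals, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.competitor_totals.shape != self.intensity.shape:
            raise ValueError("competitor_totals and intensity must have equal length")
        if self.receptor_total < 0 or self.reference_total < 0 or np.any(self.competitor_totals < 0):
            raise ValueError("totals must be nonnegative")


@dataclass(frozen=True)
class CompetitionExperiment:
    """One centrifugation replicate: measured free/bound for both ligands, M."""

    receptor_total: float
    ref_total: float
    test_total: float
    Cf_ref: float
    Cb_ref: float
    Cf_test: float
    Cb_test: float
    replicate: int = 0
    order: str = "ref_first"  # which ligand was pre-incubated


def solve_single(Tt: float, Lt: float, Kb: float) -> EquilibriumState:
    """Closed-form 1:1 equilibrium for totals Tt (receptor) and Lt (ligand).

    Cb is the smaller root of the binding quadratic,
    Cb = [S − sqrt(S² − 4·Tt·Lt)]/2 with S = Tt + Lt + 1/Kb.
    """
    if Tt < 0 or Lt < 0:
        raise ValueError("totals must be nonnegative")
    if Kb <= 0:
        raise ValueError("Kb must be positive")
    s = Tt + Lt + 1.0 / Kb
    disc = s * s - 4.0 * Tt * Lt
    cb = (s - np.sqrt(max(disc, 0.0))) / 2.0
    cb = min(cb, Tt, Lt)  # guard rounding at the stoichiometric limit
    return EquilibriumState(Tf=Tt - cb, Cf=(Lt - cb,), Cb=(cb,))


def _free_ligand(Lt: float, Kb: float, Tf: float) -> float:
    """Free ligand given free receptor: Lf = Lt / (1 + Kb·Tf)."""
    return Lt / (1.0 + Kb * Tf)


def solve_competition(
    Tt: float, At: float, Bt: float, KbA: float, KbB: float
) -> EquilibriumState:
    """Two ligands competing for one site: root of the receptor balance
    Tf·(1 + KbA·Af(Tf) + KbB·Bf(Tf)) = Tt, solved by bracketed root-finding
    on Tf ∈ (0, Tt]."""
    if min(Tt, At, Bt) < 0:
        raise ValueError("totals must be nonnegative")
    if KbA <= 0 or KbB <= 0:
        raise ValueError("binding constants must be positive")
    if Tt == 0:
        return EquilibriumState(Tf=0.0, Cf=(At, Bt), Cb=(0.0, 0.0))

    def balance(tf: float) -> float:
        return tf * (1.0 + KbA * _free_ligand(At, KbA, tf) + KbB * _free_ligand(Bt, KbB, tf)) - Tt

    # balance is strictly increasing in Tf; bracket between ~0 and Tt.
    lo = Tt * 1e-18
    if balance(lo) > 0:
        lo = 0.0
    tf = optimize.brentq(balance, lo, Tt, xtol=Tt * 1e-18, rtol=8.9e-16, maxiter=300)

    def dbalance(tf: float) -> float:
        return (1.0 + KbA * At / (1.0 + KbA * tf) ** 2 + KbB * Bt / (1.0 + KbB * tf) ** 2)

    # Newton polish: brentq stops on bracket width, which on steep objectives
    # (strong binders, tiny Tf) can leave a visible receptor-balance residual.
    for _ in range(50):
        f = balance(tf)
        if abs(f) <= Tt * 1e-14:
            break
        step = f / dbalance(tf)
        tf_new = tf - step
        if tf_new <= 0:
            tf_new = tf / 2.0
        tf = tf_new
    af, bf = _free_ligand(At, KbA, tf), _free_ligand(Bt, KbB, tf)
    # bound fractions computed directly (At − Af cancels badly for weak binding)
    cba = At * KbA * tf / (1.0 + KbA * tf)
    cbb = Bt * KbB * tf / (1.0 + KbB * tf)
    state = EquilibriumState(Tf=tf, Cf=(af, bf), Cb=(cba, cbb))
    resid = abs(state.Tf + sum(state.Cb) - Tt) / max(Tt, 1e-300)
    if resid > 1e-10:
        raise RuntimeError(f"competition solver did not converge (residual {resid:.2e})")
    return state


def kb_point(Cb: float, Cf: float, Tf: float) -> float:
    """Association constant from one equilibrium point: Kb = Cb/(Cf·Tf)."""
    if Cf <= 0 or Tf <= 0:
        raise ValueError("Cf and Tf must be positive")
    return Cb / (Cf * Tf)


def kb_competition(Kb_ref: float, Cf_ref: float, Cb_ref: float, Cf_x: float, Cb_x: float) -> float:
    """Competition estimator: Kb_x = Kb_ref·(Cf_ref/Cb_ref)/(Cf_x/Cb_x)."""
    if min(Cf_ref, Cb_ref, Cf_x, Cb_x) <= 0:
        raise ValueError("all concentrations must be positive")
    return Kb_ref * (Cf_ref / Cb_ref) / (Cf_x / Cb_x)


# ---------------------------------------------------------------------------
# Fitting


def _direct_signal(Tt: np.ndarray, Lt: np.ndarray, Kb: float,
                   alpha: float, beta: float, gamma: float) -> np.ndarray:
    cf = np.empty_like(Lt, dtype=float)
    cb = np.empty_like(Lt, dtype=float)
    for i, (tt, lt) in enumerate(zip(Tt, Lt)):
        st = solve_single(tt, lt, Kb)
        cf[i], cb[i] = st.Cf[0], st.Cb[0]
    return alpha * cf + beta * cb + gamma


def fit_direct(
    receptor_totals: Sequence[float],
    ligand_totals: Sequence[float],
    intensity: Sequence[float],
    kb_seeds: Sequence[float] | None = None,
) -> BindingConstant:
    """Fit Kb from direct titration data with the linear signal model
    F = α·Cf + β·Cb + γ.

    For each candidate Kb the conditionally-linear (α, β, γ) are solved by
    ordinary least squares; Kb is then optimized over a log grid of
    multistart seeds with local polish, best SSE winning.  Raises if the
    signal carries no binding information (α ≈ β, flat response).
    """
    Tt = np.asarray(receptor_totals, dtype=float)
    Lt = np.asarray(ligand_totals, dtype=float)
    F = np.asarray(intensity, dtype=float)
    if len(F) < 4:
        raise ValueError("need at least 4 titration points")
    if np.ptp(F) <= 1e-9 * max(float(np.max(np.abs(F))), 1e-300):
        raise ValueError("flat signal: Kb is unidentifiable from this design")
    if kb_seeds is None:
        kb_seeds = np.logspace(3, 12, 19)

    def sse_for(log_kb: float) -> tuple[float, np.ndarray]:
        kb = 10.0 ** log_kb
        cf = np.empty_like(Lt)
        cb = np.empty_like(Lt)
        for i, (tt, lt) in enumerate(zip(Tt, Lt)):
            st = solve_single(tt, lt, kb)
            cf[i], cb[i] = st.Cf[0], st.Cb[0]
        X = np.column_stack([cf, cb, np.ones_like(cf)])
        coef, *_ = np.linalg.lstsq(X, F, rcond=None)
        resid = F - X @ coef
        return float(resid @ resid), coef

    grid = [np.log10(s) for s in kb_seeds]
    best_lk = min(grid, key=lambda lk: sse_for(lk)[0])
    res = optimize.minimize_scalar(
        lambda lk: sse_for(lk)[0],
        bounds=(best_lk - 1.0, best_lk + 1.0), method="bounded",
        options={"xatol": 1e-8},
    )
    kb = 10.0 ** res.x
    sse, coef = sse_for(res.x)
    alpha, beta, _ = coef
    scale = max(abs(alpha), abs(beta), 1e-300)
    if abs(alpha - beta) / scale < 1e-6:
        raise ValueError("free and bound signals are spectrally identical; Kb unidentifiable")
    return BindingConstant(value=kb, method="direct", n=len(F))


def _displacement_curve(series: TitrationSeries, Kb_ref: float, Kb_x: float) -> tuple[np.ndarray, np.ndarray]:
    """Reference-ligand (Cf, Cb) along the competitor titration."""
    cf = np.empty_like(series.competitor_totals)
    cb = np.empty_like(series.competitor_totals)
    for i, xt in enumerate(series.competitor_totals):
        st = solve_competition(series.receptor_total, series.reference_total, xt, Kb_ref, Kb_x)
        cf[i], cb[i] = st.Cf[0], st.Cb[0]
    return cf, cb


def fit_displacement(
    series: TitrationSeries,
    Kb_ref: float,
    kb_seeds: Sequence[float] | None = None,
    saturation_ratio: float = 0.05,
) -> BindingConstant:
    """Fit the competitor's Kb from a fluorescence-displacement series.

    At each titration point the reference ligand's free/bound split is
    obtained from the two-ligand competition equilibrium; the intensity is
    modelled as F = α·Cf_ref + β·Cb_ref + γ with conditionally-linear
    (α, β, γ).  When the fitted Kb drives the reference ligand essentially
    fully displaced over most of the series (or the response is flat), the
    result is flagged ``saturated`` — the design then supports only a bound.
    """
    if Kb_ref <= 0:
        raise ValueError("Kb_ref must be positive")
    x = series.competitor_totals
    if not np.any(x == 0):
        raise ValueError("series must include the zero-competitor point")
    if np.all(x == 0):
        raise ValueError("competitor was never titrated; no displacement information")
    F = series.intensity
    if kb_seeds is None:
        kb_seeds = np.logspace(2, 13, 23)

    def sse_for(log_kb: float) -> float:
        cf, cb = _displacement_curve(series, Kb_ref, 10.0 ** log_kb)
        X = np.column_stack([cf, cb, np.ones_like(cf)])
        coef, *_ = np.linalg.lstsq(X, F, rcond=None)
        resid = F - X @ coef
        return float(resid @ resid)

    grid = [np.log10(s) for s in kb_seeds]
    best_lk = min(grid, key=sse_for)
    res = optimize.minimize_scalar(
        sse_for, bounds=(best_lk - 1.0, best_lk + 1.0), method="bounded",
        options={"xatol": 1e-8},
    )
    kb_x = 10.0 ** res.x

    # Saturation diagnostics: beyond the design's dynamic range the bound
    # curve collapses to the stoichiometric limit and becomes independent of
    # Kb_x, so the likelihood is flat upward and only a lower bound is
    # supported.  Flag when an order of magnitude less affinity fits the data
    # essentially as well as the optimum.
    ss_tot = float(np.sum((F - F.mean()) ** 2))
    sse_fit = sse_for(res.x)
    sse_low = sse_for(res.x - 1.0)
    saturated = bool((sse_low - sse_fit) < saturation_ratio * max(ss_tot, 1e-300))
    flat = bool(np.ptp(F) < 1e-12 * max(np.max(np.abs(F)), 1.0))
    return BindingConstant(
        value=kb_x, method="displacement", n=len(F), saturated=saturated or flat
    )


def estimate_kb_centrifugation(
    experiments: Sequence[CompetitionExperiment], Kb_ref: float
) -> BindingConstant:
    """Competition/centrifugation estimate: per-replicate Kb ratios, pooled
    over both displacement orders; mean ± SD across usable replicates."""
    if Kb_ref <= 0:
        raise ValueError("Kb_ref must be positive")
    values = []
    for exp in experiments:
        if min(exp.Cb_test, exp.Cb_ref, exp.Cf_test, exp.Cf_ref) <= 0:
            import warnings

            warnings.warn(
                f"replicate {exp.replicate} ({exp.order}): nonpositive Cf/Cb, excluded"
            )
            continue
        values.append(kb_competition(Kb_ref, exp.Cf_ref, exp.Cb_ref, exp.Cf_test, exp.Cb_test))
    if not values:
        raise ValueError("no usable replicates (all had zero bound ligand)")
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if len(values) > 1 else None
    return BindingConstant(value=mean, sd=sd, method="centrifugation", n=len(values))


# ---------------------------------------------------------------------------
# CSV I/O (concentrations stored in µM for readability)


def write_titration_csv(series: TitrationSeries, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "competitor_total_uM": series.competitor_totals * 1e6,
            "intensity": series.intensity,
        }
    )
    df.attrs = {}
    header = (
        f"# receptor_total_uM={series.receptor_total * 1e6:.6g} "
        f"reference_total_uM={series.reference_total * 1e6:.6g} label={series.label}\n"
    )
    Path(path).write_text(header + df.to_csv(index=False))


def read_titration_csv(path: str | Path) -> TitrationSeries:
    text = Path(path).read_text().splitlines()
    meta = {}
    if text and text[0].startswith("#"):
        for tok in text[0][1:].split():
            if "=" in tok:
                k, v = tok.split("=", 1)
                meta[k] = v
        text = text[1:]
    from io import StringIO

    df = pd.read_csv(StringIO("\n".join(text)))
    return TitrationSeries(
        receptor_total=float(meta.get("receptor_total_uM", "0")) * 1e-6,
        reference_total=float(meta.get("reference_total_uM", "0")) * 1e-6,
        competitor_totals=df["competitor_total_uM"].to_numpy() * 1e-6,
        intensity=df["intensity"].to_numpy(),
        label=meta.get("label", ""),
    )


def write_competition_csv(experiments: Sequence[CompetitionExperiment], path: str | Path) -> None:
    rows = [
        {
            "replicate": e.replicate,
            "order": e.order,
            "receptor_total_uM": e.receptor_total * 1e6,
            "ref_total_uM": e.ref_total * 1e6,
            "test_total_uM": e.test_total * 1e6,
            "cf_ref_uM": e.Cf_ref * 1e6,
            "cb_ref_uM": e.Cb_ref * 1e6,
            "cf_test_uM": e.Cf_test * 1e6,
            "cb_test_uM": e.Cb_test * 1e6,
        }
        for e in experiments
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_competition_csv(path: str | Path) -> list[CompetitionExperiment]:
    df = pd.read_csv(path)
    return [
        CompetitionExperiment(
            receptor_total=row.receptor_total_uM * 1e-6,
            ref_total=row.ref_total_uM * 1e-6,
            test_total=row.test_total_uM * 1e-6,
            Cf_ref=row.cf_ref_uM * 1e-6,
            Cb_ref=row.cb_ref_uM * 1e-6,
            Cf_test=row.cf_test_uM * 1e-6,
            Cb_test=row.cb_test_uM * 1e-6,
            replicate=int(row.replicate),
            order=str(row.order),
        )
        for row in df.itertuples(index=False)
    ]
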