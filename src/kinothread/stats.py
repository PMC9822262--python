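"""Weighted two-sample inference, calibrated regressions, hit rates, and
binding free-energy bookkeeping.

Unit conventions: dissociation constants in molar, free energies in
kcal/mol, ΔG_exp = k_B·T·ln(K_d / 1 M) at T = 298.15 K by default.  IC50
values are treated like K_d — a documented simplification.  The weighted
Welch test uses effective counts N_eff = Σw, the weighted variance
s² = Σw(x − x̄_w)² / (N_eff − 1), and standard errors s/√N_eff; degrees of
freedom follow Welch–Satterthwaite with ν_i = N_eff,i − 1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

KB_KCAL = 0.0019872041  # Boltzmann constant, kcal/(mol K)
STANDARD_TEMPERATURE = 298.15
STANDARD_CONCENTRATION = 1.0  # molar
HIT_THRESHOLD = 1e-5  # 10 uM, molar
P_FLOOR = 1e-15


def kd_to_dg(
    kd: float,
    temperature: float = STANDARD_TEMPERATURE,
    kb: float = KB_KCAL,
) -> float:
    """Standard binding free energy (kcal/mol) from a dissociation constant
    in molar: k_B·T·ln(K_d / C0) with C0 = 1 M."""
    if kd <= 0:
        raise ValueError(f"dissociation constant must be positive, got {kd}")
    return kb * temperature * math.log(kd / STANDARD_CONCENTRATION)


def dg_reorg(dg_exp: float, dg_bind: float) -> float:
    """Reorganization free energy: the excess of the experimental binding
    free energy over the absolute binding free energy to the
    pre-reorganized (DFG-out) receptor."""
    return dg_exp - dg_bind


DDM_REQUIRED_LEGS = ("restrain_bound", "ddg_coulomb", "ddg_lj", "restrain_gas")


def ddm_combine(legs: dict) -> float:
    """Absolute binding free energy from double-decoupling legs:

        ΔG_bind = −ΔG_restrain^bound + ΔΔG_Coulomb + ΔΔG_LJ + ΔG_restrain^gas
                  [+ finite-size electrostatic correction]

    The finite-size correction leg is optional (0 if absent); any other
    missing leg is a hard error naming it.
    """
    missing = [k for k in DDM_REQUIRED_LEGS if k not in legs or legs[k] is None]
    if missing:
        raise ValueError(f"missing double-decoupling legs: {missing}")
    fs = legs.get("finite_size_correction", 0.0) or 0.0
    return (
        -legs["restrain_bound"]
        + legs["ddg_coulomb"]
        + legs["ddg_lj"]
        + legs["restrain_gas"]
        + fs
    )


def hit_rate(kds, threshold: float = HIT_THRESHOLD) -> int:
    """Number of ligands binding with K_d ≤ threshold (inclusive; default
    10 μM).  Missing affinities are excluded and logged."""
    n = 0
    skipped = 0
    for kd in kds:
        if kd is None or (isinstance(kd, float) and math.isnan(kd)):
            skipped += 1
            continue
        if kd <= threshold:
            n += 1
    if skipped:
        logger.info("hit_rate: excluded %d ligands with missing K_d", skipped)
    return n


@dataclass
class WelchResult:
    """Weighted Welch two-sample result (one-tailed, X greater)."""

    t: float
    df: float
    p_one_tailed: float
    mean_x: float
    mean_y: float
    se_x: float
    se_y: float
    n_eff_x: float
    n_eff_y: float

    @property
    def p_label(self) -> str:
        """Reporting form: p-values below 1e-15 are reported as a bound."""
        if self.p_one_tailed < P_FLOOR:
            return "< 1e-15"
        return f"{self.p_one_tailed:.3g}"


def _weighted_mean_se(x: np.ndarray, w: np.ndarray) -> tuple[float, float, float]:
    n_eff = w.sum()
    if n_eff <= 1:
        raise ValueError("effective sample size must exceed 1")
    mean = float(np.average(x, weights=w))
    var = float((w * (x - mean) ** 2).sum() / (n_eff - 1))
    if var == 0:
        raise ValueError("degenerate (zero-variance) sample")
    se = math.sqrt(var / n_eff)
    return mean, se, float(n_eff)


def welch_weighted(
    x, y, weights_x=None, weights_y=None
) -> WelchResult:
    """Weighted Welch test of H1: mean(x) > mean(y).

    t = (x̄_w − ȳ_w) / sqrt(se_x² + se_y²); ν by Welch–Satterthwaite with
    effective counts; one-tailed p = 1 − F_t(t; ν).  With unit weights this
    reduces exactly to the textbook Welch test.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    wx = np.ones_like(x) if weights_x is None else np.asarray(weights_x, dtype=float)
    wy = np.ones_like(y) if weights_y is None else np.asarray(weights_y, dtype=float)
    mx, sex, nx = _weighted_mean_se(x, wx)
    my, sey, ny = _weighted_mean_se(y, wy)
    t = (mx - my) / math.sqrt(sex**2 + sey**2)
    df = (sex**2 + sey**2) ** 2 / (sex**4 / (nx - 1) + sey**4 / (ny - 1))
    p = float(sps.t.sf(t, df))
    return WelchResult(
        t=float(t), df=float(df), p_one_tailed=p,
        mean_x=mx, mean_y=my, se_x=sex, se_y=sey, n_eff_x=nx, n_eff_y=ny,
    )


def pearson(x, y) -> tuple[float, float]:
    """Product-moment correlation and its square."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    r = float(sps.pearsonr(x, y).statistic)
    return r, r * r


def fit_through_origin(x, y) -> float:
    """Least-squares slope with zero intercept: Σxy / Σx²."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sxx = float((x * x).sum())
    if sxx == 0:
        raise ValueError("all-zero x")
    return float((x * y).sum() / sxx)


def fit_ols(x, y) -> tuple[float, float]:
    """Ordinary least squares (slope, intercept) — emitted alongside the
    through-origin calibration for comparison."""
    res = sps.linregress(np.asarray(x, float), np.asarray(y, float))
    return float(res.slope), float(res.intercept)


def fit_slope_one(x, y) -> tuple[float, float]:
    """Regression of y on x with the slope constrained to one.

    Returns (intercept, standard error): the intercept is mean(y − x) — for
    ΔG_exp vs ΔG_bind pairs this is the per-target ΔG_reorg estimate — and
    the error is the standard error of the differences (0 for n = 1).
    """
    d = np.asarray(y, dtype=float) - np.asarray(x, dtype=float)
    if d.size == 0:
        raise ValueError("need at least one complex")
    intercept = float(d.mean())
    err = float(d.std(ddof=1) / math.sqrt(d.size)) if d.size > 1 else 0.0
    return intercept, err


@dataclass
class FreeEnergyRecord:
    """Per-complex free-energy bookkeeping (kcal/mol, K_d in molar)."""

    kinase: str
    ligand: str
    kd_molar: float | None = None
    dg_exp: float | None = None
    dg_bind_abfe: float | None = None
    dg_bind_err: float | None = None
    legs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dg_exp is None and self.kd_molar is not None:
            self.dg_exp = kd_to_dg(self.kd_molar)
        if self.dg_bind_abfe is None and self.legs:
            self.dg_bind_abfe = ddm_combine(self.legs)

    @property
    def dg_reorg(self) -> float | None:
        if self.dg_exp is None or self.dg_bind_abfe is None:
            return None
        return dg_reorg(self.dg_exp, self.dg_bind_abfe)


def records_from_table(
    df: pd.DataFrame, temperature: float = STANDARD_TEMPERATURE
) -> list[FreeEnergyRecord]:
    """Build records from a per-complex TSV table with columns kinase,
    ligand, kd_molar (or ic50_molar), dg_bind_abfe, dg_bind_err."""
    records = []
    for _, row in df.iterrows():
        kd = row.get("kd_molar")
        if kd is None or (isinstance(kd, float) and math.isnan(kd)):
            kd = row.get("ic50_molar")
        kd = None if kd is None or (isinstance(kd, float) and math.isnan(kd)) else float(kd)
        dg_exp = kd_to_dg(kd, temperature) if kd is not None else None
        bind = row.get("dg_bind_abfe")
        bind = None if bind is None or (isinstance(bind, float) and math.isnan(bind)) else float(bind)
        records.append(
            FreeEnergyRecord(
                kinase=str(row["kinase"]),
                ligand=str(row["ligand"]),
                kd_molar=kd,
                dg_exp=dg_exp,
                dg_bind_abfe=bind,
                dg_bind_err=row.get("dg_bind_err"),
            )
        )
    return records


def load_reorg_benchmark() -> pd.DataFrame:
    """Curated benchmark of five TK and five STK targets: type-II hit rates,
    Potts threading penalties and simulation-derived reorganization free
    energies (kcal/mol).  Used to calibrate the statistical-energy scale."""
    from importlib.resources import files

    path = files("kinothread").joinpath("data/kinase_reorg_benchmark.tsv")
    with path.open() as fh:
        return pd.read_csv(fh, sep="\t")


def calibrate_energy_scale(benchmark: pd.DataFrame | None = None) -> dict:
    """Regress ΔG_reorg on the Potts penalty over the benchmark targets.

    Returns the Pearson r/r², the through-origin slope (kcal/mol per Potts
    unit), the unconstrained OLS fit, and the per-class mean ΔG_reorg.
    """
    df = load_reorg_benchmark() if benchmark is None else benchmark
    x = df["potts_penalty"].to_numpy(float)
    y = df["dg_reorg"].to_numpy(float)
    r, r2 = pearson(x, y)
    slope0 = fit_through_origin(x, y)
    slope, intercept = fit_ols(x, y)
    out = {
        "n": int(len(df)),
        "r": r,
        "r2": r2,
        "slope_through_origin": slope0,
        "ols_slope": slope,
        "ols_intercept": intercept,
    }
    for cls, grp in df.groupby("class"):
        out[f"mean_dg_reorg_{cls}"] = float(grp["dg_reorg"].mean())
    return out


def reorg_summary(records: list[FreeEnergyRecord]) -> pd.DataFrame:
    """Per-kinase ΔG_reorg via the slope-one regression of ΔG_exp on
    ΔG_bind over that kinase's complexes."""
    rows = []
    by_kinase: dict[str, list[FreeEnergyRecord]] = {}
    for rec in records:
        if rec.dg_exp is not None and rec.dg_bind_abfe is not None:
            by_kinase.setdefault(rec.kinase, []).append(rec)
    for kinase, recs in sorted(by_kinase.items()):
        x = [r.dg_bind_abfe for r in recs]
        y = [r.dg_exp for r in recs]
        intercept, err = fit_slope_one(x, y)
        rows.append((kinase, len(recs), intercept, err))
    return pd.DataFrame(rows, columns=["kinase", "n_complexes", "dg_reorg", "dg_reorg_err"])
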